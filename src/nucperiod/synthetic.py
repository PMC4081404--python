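"""Synthetic chromatin genomes, four-species divergence and population samples.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any sequencing data:

* nucleosome arrays with a core-plus-linker repeat (147 bp core, default
  180 bp repeat);
* ~10 bp rotational dinucleotide enrichment inside cores: AA/TT starts are
  favored where the minor groove faces the histone core (superhelix
  locations +/-(i+0.5), i.e. at distances T*(i+1/2) from the dyad) and GC
  starts in antiphase;
* GC-enriched linkers;
* lineage-specific substitution on a star phylogeny (focal, sibling, two
  outgroups) with an optional positional modulation of the focal-lineage
  GC->AT transition rates, in phase with the AA/TT preference;
* population SNPs with derived-allele counts drawn from the neutral
  spectrum G_n(i) ~ (1/i)/a_n or, under scaled selection coefficient gamma,
  from the Poisson-random-field stationary density
  f(x) ~ (1 - exp(-gamma (1-x))) / (x (1-x) (1 - exp(-gamma))).

Sites evolve independently (no linkage); at most one substitution per site
per branch (infinite-sites style), with probability 1 - exp(-rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BASES, Genome, decode
from .sfs import harmonic

logger = logging.getLogger(__name__)

CORE_LEN = 147
HALF = 73

BASE_ORDER = "ACGT"
_CODE = {b: k for k, b in enumerate(BASE_ORDER)}

#: default per-branch substitution rates (ancestral -> derived), per unit
#: branch length; GC->AT transitions exceed AT->GC, mirroring the observed
#: melanogaster-lineage excess, transversions are uniform and lower.
DEFAULT_RATES: dict[tuple[str, str], float] = {
    ("G", "A"): 0.05,
    ("C", "T"): 0.05,
    ("A", "G"): 0.03,
    ("T", "C"): 0.03,
    ("A", "C"): 0.012,
    ("A", "T"): 0.012,
    ("C", "A"): 0.012,
    ("C", "G"): 0.012,
    ("G", "C"): 0.012,
    ("G", "T"): 0.012,
    ("T", "A"): 0.012,
    ("T", "G"): 0.012,
}

DEFAULT_BRANCH_SCALE = {"focal": 1.0, "sib": 1.0, "out1": 2.5, "out2": 2.5}


@dataclass(frozen=True)
class ChromatinModel:
    """Parameters of the synthetic chromatin sequence model.

    ``phase`` is the distance from the dyad of the first AA/TT enrichment
    peak; with the default T/2 = 5 bp, peaks sit at |d| = 5, 15, ..., 65 --
    the superhelix locations +/-(i+0.5).
    """

    repeat_length: int = 180
    helical_period: float = 10.0
    rotational_amplitude: float = 0.3
    phase: float = 5.0
    linker_gc_boost: float = 0.3
    composition: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "intergenic": (0.30, 0.20, 0.20, 0.30),
            "intronic": (0.29, 0.21, 0.21, 0.29),
        }
    )

    @property
    def core_length(self) -> int:
        return CORE_LEN

    @property
    def linker_length(self) -> int:
        return self.repeat_length - CORE_LEN

    def __post_init__(self):
        if self.repeat_length < CORE_LEN:
            raise ValueError("repeat_length must be >= core length 147")
        if self.rotational_amplitude < 0:
            raise ValueError("rotational_amplitude must be >= 0")
        if self.rotational_amplitude > 1:
            raise ValueError(
                "rotational_amplitude > 1 drives antiphase weights negative"
            )
        if self.linker_gc_boost < -1:
            raise ValueError("linker_gc_boost must be > -1 (weights must stay >= 0)")
        for cls, comp in self.composition.items():
            if abs(sum(comp) - 1.0) > 1e-9:
                raise ValueError(f"composition for {cls!r} must sum to 1")

    def rotational_factor(self, d) -> np.ndarray:
        """1 + A cos(2 pi (|d| - phase) / T) at dyad offset(s) d."""
        d = np.abs(np.asarray(d, dtype=float))
        return 1.0 + self.rotational_amplitude * np.cos(
            2 * np.pi * (d - self.phase) / self.helical_period
        )


@dataclass(frozen=True)
class EvolParams:
    """Evolutionary parameters for divergence and polymorphism simulation.

    ``beta`` modulates the focal-lineage rates inside cores at dyad offset
    d by 1 + beta*cos(2 pi (|d|-phase)/T) for GC->AT transitions (in phase
    with the AA/TT preference) and by the antiphase factor for AT->GC.
    ``gamma`` is the scaled selection coefficient of derived alleles;
    ``gamma_amplitude`` adds an in-phase cosine modulation inside cores.
    """

    rates: dict[tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    branch_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_SCALE)
    )
    beta: float = 0.0
    theta: float = 0.02
    gamma: float = 0.0
    gamma_amplitude: float = 0.0
    ts_fraction: float = 0.7
    sample_size: int = 34
    helical_period: float = 10.0
    phase: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("substitution rates must be >= 0")
        if self.sample_size < 4:
            raise ValueError("sample_size must be >= 4")
        for g in (self.gamma, self.gamma + self.gamma_amplitude,
                  self.gamma - self.gamma_amplitude):
            if abs(g) > 50:
                raise ValueError("|gamma| > 50 would overflow the PRF density")
        for name in ("focal", "sib", "out1", "out2"):
            total = max(
                sum(r for (x, _), r in self.rates.items() if x == b) for b in BASE_ORDER
            ) * self.branch_scale.get(name, 1.0) * (1 + abs(self.beta))
            if -np.expm1(-total) >= 0.75:
                raise ValueError(
                    f"branch {name}: per-site substitution probability >= 0.75"
                )


# ---------------------------------------------------------------------------
# genome generation


def _layout(model: ChromatinModel, n_arrays: int, nucleosomes_per_array: int,
            pad: int | None) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Positions of cores and annotation blocks on a single chromosome.

    By default consecutive arrays are separated by a nucleosome-free gap of
    one full repeat plus one linker, so core starts across the array
    boundary sit exactly two repeats apart and the translational phase is
    continuous genome-wide (an explicit ``pad`` overrides this with
    symmetric pads of that size).
    """
    linker = model.linker_length
    if pad is None:
        gap = model.repeat_length + linker
        pad_l, pad_r = gap // 2, gap - gap // 2
    else:
        pad_l = pad_r = pad
    array_len = pad_l + pad_r + nucleosomes_per_array * CORE_LEN + (nucleosomes_per_array - 1) * linker
    cores, blocks = [], []
    pos = 0
    for a in range(n_arrays):
        cls = "intergenic" if a % 2 == 0 else "intronic"
        blocks.append((pos, pos + array_len, cls))
        start = pos + pad_l
        for _ in range(nucleosomes_per_array):
            cores.append((start, start + CORE_LEN))
            start += CORE_LEN + linker
        pos += array_len
    core_df = pd.DataFrame(cores, columns=["start", "end"])
    block_df = pd.DataFrame(blocks, columns=["start", "end", "region_class"])
    return pos, core_df, block_df


def core_offsets(length: int, cores: pd.DataFrame) -> np.ndarray:
    """Signed dyad offset (-73..73) per position; NaN outside cores."""
    off = np.full(length, np.nan)
    for s, e in zip(cores["start"], cores["end"]):
        off[s:e] = np.arange(s, e) - (s + HALF)
    return off


def generate_genome(
    model: ChromatinModel,
    n_arrays: int,
    nucleosomes_per_array: int = 1,
    seed: int = 0,
    pad: int | None = None,
    chrom: str = "chrS",
) -> tuple[Genome, pd.DataFrame, pd.DataFrame]:
    """Sample a genome of nucleosome arrays under the chromatin model.

    Returns (genome, true core intervals, region annotation), intervals
    0-based half-open.  Arrays alternate intergenic/intronic labels.  The
    sequence is sampled left to right; at each position the background
    composition of the block's class is reweighted multiplicatively:
    completing an AA or TT dinucleotide whose start lies in a core at dyad
    offset d is scaled by the rotational factor 1 + A cos(2 pi (|d|-phase)/T),
    completing GC by the antiphase factor, and G/C bases in linkers (and
    pads) by 1 + linker_gc_boost.
    """
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    if pad is not None and pad < 0:
        raise ValueError("pad must be >= 0")
    rng = np.random.default_rng(seed)
    length, cores, blocks = _layout(model, n_arrays, nucleosomes_per_array, pad)
    cores.insert(0, "chrom", chrom)
    blocks.insert(0, "chrom", chrom)

    off = core_offsets(length, cores)
    in_core = ~np.isnan(off)
    rot = np.ones(length)
    rot[in_core] = model.rotational_factor(off[in_core])
    anti = 2.0 - rot  # 1 - A cos(...)
    if rot.min() < 0 or anti.min() < 0:
        raise ValueError("rotational amplitude drives a sampling weight negative")
    gc_mult = np.where(in_core, 1.0, 1.0 + model.linker_gc_boost)

    cls_idx = np.zeros(length, dtype=np.int8)
    classes = []
    for k, (_, row) in enumerate(blocks.iterrows()):
        if row["region_class"] not in classes:
            classes.append(row["region_class"])
        cls_idx[row["start"]:row["end"]] = classes.index(row["region_class"])
    comps = [model.composition[c] for c in classes]

    u = rng.random(length)
    seq = np.empty(length, dtype=np.uint8)
    prev = -1  # 0=A 1=C 2=G 3=T
    rot_l, anti_l, gc_l, cls_l, u_l = rot.tolist(), anti.tolist(), gc_mult.tolist(), cls_idx.tolist(), u.tolist()
    out = []
    for p in range(length):
        ca, cc, cg, ct = comps[cls_l[p]]
        m = gc_l[p]
        cc *= m
        cg *= m
        if prev == 0:      # previous A: AA start at p-1
            ca *= rot_l[p - 1]
        elif prev == 3:    # previous T: TT start at p-1
            ct *= rot_l[p - 1]
        elif prev == 2:    # previous G: GC start at p-1, antiphase
            cc *= anti_l[p - 1]
        t = u_l[p] * (ca + cc + cg + ct)
        if t < ca:
            prev = 0
        elif t < ca + cc:
            prev = 1
        elif t < ca + cc + cg:
            prev = 2
        else:
            prev = 3
        out.append(prev)
    seq[:] = BASES[np.array(out, dtype=np.int8)]
    return Genome({chrom: seq}), cores, blocks


# ---------------------------------------------------------------------------
# divergence simulation


def _positional_multipliers(
    length: int, cores: pd.DataFrame, params: EvolParams
) -> tuple[np.ndarray, np.ndarray]:
    """(in-phase, antiphase) focal-rate multipliers per position."""
    off = core_offsets(length, cores)
    in_core = ~np.isnan(off)
    cosv = np.zeros(length)
    cosv[in_core] = np.cos(
        2 * np.pi * (np.abs(off[in_core]) - params.phase) / params.helical_period
    )
    return 1.0 + params.beta * cosv, 1.0 - params.beta * cosv


def _mutate_branch(
    ancestor: np.ndarray,
    params: EvolParams,
    branch: str,
    rng: np.random.Generator,
    in_phase: np.ndarray | None = None,
    antiphase: np.ndarray | None = None,
) -> np.ndarray:
    """One round of at-most-one-substitution-per-site evolution."""
    scale = params.branch_scale.get(branch, 1.0)
    derived = ancestor.copy()
    modulated = branch == "focal" and in_phase is not None
    for anc_base in BASE_ORDER:
        anc_code = ord(anc_base)
        idx = np.nonzero(ancestor == anc_code)[0]
        if idx.size == 0:
            continue
        targets = [b for b in BASE_ORDER if b != anc_base]
        rmat = np.empty((idx.size, 3))
        for k, tgt in enumerate(targets):
            r = params.rates.get((anc_base, tgt), 0.0) * scale
            col = np.full(idx.size, r)
            if modulated and (anc_base, tgt) in (("G", "A"), ("C", "T")):
                col = col * in_phase[idx]
            elif modulated and (anc_base, tgt) in (("A", "G"), ("T", "C")):
                col = col * antiphase[idx]
            rmat[:, k] = col
        total = rmat.sum(axis=1)
        p_sub = -np.expm1(-total)
        hit = rng.random(idx.size) < p_sub
        if not hit.any():
            continue
        sub_idx = idx[hit]
        cum = np.cumsum(rmat[hit], axis=1)
        pick = (rng.random(hit.sum())[:, None] * total[hit, None] > cum).sum(axis=1)
        pick = np.minimum(pick, 2)
        tcodes = np.array([ord(t) for t in targets], dtype=np.uint8)
        derived[sub_idx] = tcodes[pick]
    return derived


def simulate_divergence(
    genome: Genome,
    true_nucleosomes: pd.DataFrame,
    params: EvolParams,
) -> dict[str, Genome]:
    """Evolve the sequence independently along focal, sib and two outgroup
    branches; the input sequence is the common ancestor.

    Focal-lineage G->A and C->T rates inside cores are modulated in phase
    with the AA/TT rotational preference (amplitude ``params.beta``),
    A->G/T->C in antiphase; the other branches use unmodulated rates.
    """
    rng = np.random.default_rng(params.seed)
    out: dict[str, Genome] = {}
    for branch in ("focal", "sib", "out1", "out2"):
        chroms = {}
        for chrom in genome:
            anc = genome[chrom]
            if anc.size == 0:
                raise ValueError("empty ancestral sequence")
            cores = true_nucleosomes[true_nucleosomes["chrom"] == chrom]
            inp, ant = _positional_multipliers(len(anc), cores, params)
            chroms[chrom] = _mutate_branch(anc, params, branch, rng, inp, ant)
        out[branch] = Genome(chroms)
    return out


def alignment_to_site_table(alignment: dict[str, Genome], chrom: str) -> pd.DataFrame:
    """Flatten a four-way alignment into the per-site base table."""
    cols = {}
    for name in ("focal", "sib", "out1", "out2"):
        cols[name] = np.frombuffer(
            alignment[name][chrom].tobytes(), dtype="S1"
        ).astype("U1")
    n = len(cols["focal"])
    return pd.DataFrame({"chrom": chrom, "pos": np.arange(n), **cols})


# ---------------------------------------------------------------------------
# polymorphism simulation


def prf_density(x: np.ndarray, gamma: float) -> np.ndarray:
    """Poisson-random-field stationary density of derived-allele frequency
    (up to the theta scale factor): (1-e^{-g(1-x)}) / (x (1-x) (1-e^{-g}))."""
    x = np.asarray(x, dtype=float)
    if abs(gamma) < 1e-9:
        return 1.0 / x
    return np.expm1(-gamma * (1 - x)) / (x * (1 - x) * np.expm1(-gamma))


def _sample_counts_neutral(n: int, size: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(1, n)
    p = (1.0 / i) / harmonic(n)
    return rng.choice(i, size=size, p=p)


def _sample_counts_selected(
    gamma: float, n: int, size: int, rng: np.random.Generator, grid: int = 10_000
) -> np.ndarray:
    """Inverse-CDF draw of x from the PRF density weighted by the chance of
    segregating in the sample, then i ~ Binomial(n, x) conditioned on
    1 <= i <= n-1."""
    if abs(gamma) < 1e-9:
        return _sample_counts_neutral(n, size, rng)
    x = (np.arange(grid) + 0.5) / grid
    p_seg = 1.0 - (1 - x) ** n - x**n
    w = prf_density(x, gamma) * p_seg
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    xs = x[np.searchsorted(cdf, rng.random(size))]
    i = rng.binomial(n, xs)
    bad = (i == 0) | (i == n)
    tries = 0
    while bad.any():
        i[bad] = rng.binomial(n, xs[bad])
        bad = (i == 0) | (i == n)
        tries += 1
        if tries > 100_000:  # pragma: no cover - p_seg-weighted x makes this moot
            raise RuntimeError("conditioned binomial resampling did not converge")
    return i


TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def simulate_polymorphism(
    genome: Genome,
    true_nucleosomes: pd.DataFrame,
    params: EvolParams,
) -> pd.DataFrame:
    """Scatter segregating sites on the genome and sample their frequencies.

    Each site is polymorphic with probability ``theta``.  The derived base
    is a transition with probability ``ts_fraction`` (else one of the two
    transversions, equally).  The derived sample count i in 1..n-1 follows
    the neutral spectrum when the site's gamma is 0, otherwise the PRF
    spectrum.  Inside cores gamma(d) = gamma + gamma_amplitude *
    cos(2 pi (|d|-phase)/T); outside cores gamma(d) = gamma.

    Returns columns chrom, pos, ancestral, derived, i, n, core_offset.
    """
    if params.sample_size < 4:
        raise ValueError("sample_size must be >= 4")
    rng = np.random.default_rng(params.seed + 1)
    n = params.sample_size
    frames = []
    for chrom in genome:
        seq = genome[chrom]
        hit = rng.random(len(seq)) < params.theta
        pos = np.nonzero(hit & np.isin(seq, BASES))[0]
        if pos.size == 0:
            continue
        anc = np.frombuffer(seq[pos].tobytes(), dtype="S1").astype("U1")
        # derived base: transition vs transversion
        is_ts = rng.random(pos.size) < params.ts_fraction
        derived = np.array([TRANSITION[a] for a in anc], dtype="U1")
        tv_choice = rng.integers(0, 2, size=pos.size)
        for k in np.nonzero(~is_ts)[0]:
            tvs = [b for b in BASE_ORDER if b != anc[k] and b != TRANSITION[anc[k]]]
            derived[k] = tvs[tv_choice[k]]
        cores = true_nucleosomes[true_nucleosomes["chrom"] == chrom]
        off = core_offsets(len(seq), cores)[pos]
        g = np.full(pos.size, float(params.gamma))
        in_core = ~np.isnan(off)
        if params.gamma_amplitude != 0.0:
            g[in_core] += params.gamma_amplitude * np.cos(
                2 * np.pi * (np.abs(off[in_core]) - params.phase) / params.helical_period
            )
        i_counts = np.empty(pos.size, dtype=np.int64)
        # gamma takes at most ~75 distinct values (one per |offset| + baseline)
        for gv in np.unique(np.round(g, 9)):
            m = np.round(g, 9) == gv
            i_counts[m] = _sample_counts_selected(gv, n, int(m.sum()), rng)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ancestral": anc,
                    "derived": derived,
                    "i": i_counts,
                    "n": n,
                    "core_offset": off,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "ancestral", "derived", "i", "n", "core_offset"]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# fragment simulation


def simulate_fragments(
    true_nucleosomes: pd.DataFrame,
    jitter_sd: float = 0.0,
    length_range=(147,),
    depth: int = 1,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Emit sequenced-fragment intervals around the true cores.

    Each core yields ``depth`` fragments; each is the core shifted by a
    rounded Normal(0, jitter_sd) with a length drawn uniformly from
    ``length_range`` (dyad kept centered).  Fragments running past a contig
    end are dropped and logged.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.asarray(sorted(length_range), dtype=np.int64)
    chroms = np.repeat(true_nucleosomes["chrom"].to_numpy(), depth)
    starts = np.repeat(true_nucleosomes["start"].to_numpy(), depth)
    m = starts.size
    shift = np.round(rng.normal(0.0, jitter_sd, size=m)).astype(np.int64) \
        if jitter_sd > 0 else np.zeros(m, dtype=np.int64)
    ln = lengths[rng.integers(0, lengths.size, size=m)] if lengths.size > 1 \
        else np.full(m, lengths[0])
    fstart = starts + shift - (ln - CORE_LEN) // 2
    fend = fstart + ln
    keep = fstart >= 0
    if chrom_sizes is not None:
        ends = np.array([chrom_sizes[c] for c in chroms])
        keep &= fend <= ends
    dropped = int((~keep).sum())
    if dropped:
        logger.info("simulate_fragments: dropped %d fragments past contig ends", dropped)
    out = pd.DataFrame(
        {"chrom": chroms[keep], "start": fstart[keep], "end": fend[keep]}
    )
    out["length"] = out["end"] - out["start"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# file output

def write_bed(df: pd.DataFrame, path, name_column: str | None = None) -> None:
    """Write intervals as BED (0-based half-open), optional name column."""
    cols = df[["chrom", "start", "end"]].copy()
    if name_column is not None:
        cols["name"] = df[name_column]
    cols.to_csv(path, sep="\t", header=False, index=False)


def write_alignment_fasta(alignment: dict[str, Genome], chrom: str, path) -> None:
    """Write the 4 aligned sequences of one chromosome as FASTA records."""
    with open(path, "w") as fh:
        for name in ("focal", "sib", "out1", "out2"):
            fh.write(f">{name}\n{decode(alignment[name][chrom])}\n")


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)
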