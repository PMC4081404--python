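"""Dyad-symmetrized per-offset profiles across 147 bp nucleosomal fragments.

The nucleosome is symmetric about its dyad, so the two halves of each
fragment are pooled: the top strand from offsets -73..0 is taken as-is and
the top strand from offsets 0..+73 is reverse-complemented, giving two
half-observations per fragment over offset columns -73..0 (the dyad base
belongs to both halves).  Dinucleotide columns run -73..-1; the column -1
dinucleotide spans the dyad base.  Flanking sequence is handled the same
way (left flank as-is, right flank reverse-complemented), extending the
columns to -(73+flank)..0.

Offsets are negative and increase toward the dyad, matching the plotting
convention of nucleosome positional studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import COMPLEMENT, N, Genome, decode

CORE_LEN = 147
HALF = 73

FINE_KERNEL = np.array([0.125, 0.250, 0.250, 0.250, 0.125])


@dataclass
class PositionalProfile:
    """A per-dyad-offset statistic with observation counts.

    ``value`` is NaN at masked columns.  Rate-like profiles additionally
    carry the weighted event (``numer``) and opportunity (``denom``)
    counts so that profiles can be pooled count-wise.
    """

    offsets: np.ndarray
    value: np.ndarray
    count: np.ndarray
    masked: np.ndarray
    statistic: str = ""
    numer: np.ndarray | None = None
    denom: np.ndarray | None = None

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        self.masked = np.asarray(self.masked, dtype=bool)

    def to_frame(self, smoothed: "PositionalProfile | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "offset": self.offsets,
                "value": self.value,
                "count": self.count,
                "masked": self.masked.astype(int),
            }
        )
        if smoothed is not None:
            df["smoothed"] = smoothed.value
        return df

    def write_tsv(self, path, smoothed: "PositionalProfile | None" = None) -> None:
        self.to_frame(smoothed).to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# symmetrization


def symmetrize(genome: Genome, chrom: str, start: int, end: int,
               flank: int = 0) -> tuple[str, str]:
    """The two dyad-symmetric half-sequences of a 147 bp fragment.

    Left half: top strand at offsets -(73+flank)..0, 5'->3'.  Right half:
    reverse complement of the top strand at offsets 0..+(73+flank).  Both
    strings have length 74+flank and end on the dyad base.  Positions past
    the contig edge are returned as N.
    """
    if end - start != CORE_LEN:
        raise ValueError(f"fragment must be {CORE_LEN} bp, got {end - start}")
    left = genome.fetch(chrom, start - flank, start + HALF + 1)
    right = COMPLEMENT[genome.fetch(chrom, start + HALF, end + flank)][::-1]
    return decode(left), decode(right)


def half_matrices(
    n147: pd.DataFrame, genome: Genome, flank: int = 0
) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome stacked half-observations of an n147 set.

    For each chromosome returns ``seq`` (uint8, rows = 2 x fragments,
    columns = 74+flank half positions, right halves complemented and
    reversed), ``pos`` (genomic position per cell, -1 where off-contig) and
    ``frag`` (source row in ``n147`` per matrix row).  Row order is all
    left halves then all right halves.
    """
    width = HALF + 1 + flank
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, grp in n147.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if np.any(ends - starts != CORE_LEN):
            raise ValueError("all fragments in an n147 set must be 147 bp")
        m = len(grp)
        seq = genome[chrom]
        L = len(seq)
        j = np.arange(width)
        pos_left = starts[:, None] - flank + j[None, :]
        pos_right = ends[:, None] - 1 + flank - j[None, :]
        pos = np.vstack([pos_left, pos_right])
        valid = (pos >= 0) & (pos < L)
        smat = np.full(pos.shape, N, dtype=np.uint8)
        smat[valid] = seq[pos[valid]]
        smat[m:] = COMPLEMENT[smat[m:]]
        pos = np.where(valid, pos, -1)
        out[chrom] = {
            "seq": smat,
            "pos": pos,
            "frag": np.concatenate([grp.index.to_numpy(), grp.index.to_numpy()]),
        }
    return out


def site_offsets(flank: int = 0) -> np.ndarray:
    """Offset labels -(73+flank)..0 for per-site (mononucleotide) columns."""
    return np.arange(-(HALF + flank), 1)


def dinuc_offsets(flank: int = 0) -> np.ndarray:
    """Offset labels -(73+flank)..-1 for dinucleotide-start columns."""
    return np.arange(-(HALF + flank), 0)


# ---------------------------------------------------------------------------
# dinucleotide profiles


def _check_dinuc(dinucleotide: str) -> tuple[int, int]:
    if len(dinucleotide) != 2 or any(b not in "ACGT" for b in dinucleotide.upper()):
        raise ValueError(f"dinucleotide must be 2 bases over ACGT, got {dinucleotide!r}")
    d = dinucleotide.upper()
    return ord(d[0]), ord(d[1])


def dinucleotide_profile(
    n147: pd.DataFrame,
    genome: Genome,
    dinucleotide: str,
    flank: int = 0,
    edge_trim: int = 0,
) -> PositionalProfile:
    """Frequency of a dinucleotide start at each symmetrized offset column.

    ``value[c]`` is the fraction of half-observations whose bases at
    columns (c, c+1) equal the dinucleotide, among halves with data at
    both columns.  Through the strand flip of the right halves, AA counts
    include genomic TT on the right half, etc.
    """
    b0, b1 = _check_dinuc(dinucleotide)
    offs = dinuc_offsets(flank)
    match = np.zeros(len(offs))
    total = np.zeros(len(offs))
    for mats in half_matrices(n147, genome, flank).values():
        s = mats["seq"]
        ok = (s[:, :-1] != N) & (s[:, 1:] != N)
        hit = (s[:, :-1] == b0) & (s[:, 1:] == b1) & ok
        match += hit.sum(axis=0)
        total += ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = match / total
    masked = total == 0
    if edge_trim:
        masked = masked | _edge_mask(offs, edge_trim)
    value[masked] = np.nan
    return PositionalProfile(
        offs, value, total, masked, f"dinuc:{dinucleotide.upper()}",
        numer=match, denom=total,
    )


def pooled_dinucleotide_profile(
    n147: pd.DataFrame,
    genome: Genome,
    dinucleotides=("AA", "TT"),
    flank: int = 0,
    edge_trim: int = 0,
) -> PositionalProfile:
    """Union frequency of several dinucleotides (e.g. AA/TT) per column."""
    parts = [
        dinucleotide_profile(n147, genome, d, flank=flank, edge_trim=edge_trim)
        for d in dinucleotides
    ]
    numer = np.sum([p.numer for p in parts], axis=0)
    denom = parts[0].denom
    with np.errstate(invalid="ignore", divide="ignore"):
        value = numer / denom
    masked = parts[0].masked.copy()
    value[masked] = np.nan
    return PositionalProfile(
        parts[0].offsets, value, denom, masked,
        "dinuc:" + "/".join(d.upper() for d in dinucleotides),
        numer=numer, denom=denom,
    )


def large_scale_profile(
    n147: pd.DataFrame,
    genome: Genome,
    dinucleotides=("AA", "TT"),
    flank: int = 1000,
    edge_trim: int = 5,
) -> PositionalProfile:
    """Pooled dinucleotide frequency over +/-``flank`` bp around the dyad.

    Columns within ``edge_trim`` bp of the fragment edges (offset -73) are
    masked: they largely reflect nuclease sequence bias, not chromatin.
    """
    return pooled_dinucleotide_profile(
        n147, genome, dinucleotides, flank=flank, edge_trim=edge_trim
    )


def _edge_mask(offsets: np.ndarray, trim: int) -> np.ndarray:
    """Columns within ``trim`` bp of the fragment edge at offset -73."""
    return (offsets >= -HALF - trim) & (offsets <= -HALF + trim - 1)


def edge_mask(offsets: np.ndarray, trim: int) -> np.ndarray:
    return _edge_mask(offsets, trim)


# ---------------------------------------------------------------------------
# enrichment and composition


def base_composition(genome: Genome, intervals: pd.DataFrame) -> dict[str, float]:
    """Mononucleotide frequencies over a set of intervals (N excluded)."""
    counts = {b: 0 for b in "ACGT"}
    for chrom, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"]):
        seq = genome.fetch(chrom, s, e)
        for b in "ACGT":
            counts[b] += int((seq == ord(b)).sum())
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError("no ACGT bases in the given intervals")
    return {b: c / tot for b, c in counts.items()}


def enrichment(observed, composition: dict[str, float], dinucleotide: str):
    """Relative deviation (obs - exp)/exp with exp(XY) = f(X) f(Y)."""
    _check_dinuc(dinucleotide)
    d = dinucleotide.upper()
    exp = composition[d[0]] * composition[d[1]]
    if exp <= 0:
        raise ValueError(f"expected frequency of {d} is zero")
    return (np.asarray(observed, dtype=float) - exp) / exp


# ---------------------------------------------------------------------------
# smoothing


def _renorm_smooth(values, masked, kernel) -> tuple[np.ndarray, np.ndarray]:
    """Masked-aware running average; kernel renormalized over available taps."""
    valid = (~masked).astype(float)
    v = np.where(masked, 0.0, values)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    out = np.full(values.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out, ~ok | masked


def smooth(profile: PositionalProfile, mode: str = "fine",
           edge_trim: int = 5) -> PositionalProfile:
    """Running-average smoothing with the standard plotting conventions.

    ``fine``: 5-tap kernel (0.125, 0.250, 0.250, 0.250, 0.125).

    ``large_scale``: columns within ``edge_trim`` bp of the fragment edge
    are dropped first, then the flank segment (offsets < -73) is smoothed
    with a 50-column equal-weight window and the core segment with a
    30-column window, each separately.  At segment edges and around masked
    columns the kernel is renormalized over the available taps.
    """
    offs = profile.offsets
    if mode == "fine":
        if len(offs) < len(FINE_KERNEL):
            raise ValueError("profile shorter than the 5-column smoothing window")
        val, msk = _renorm_smooth(profile.value, profile.masked, FINE_KERNEL)
        return replace_profile(profile, val, msk)
    if mode != "large_scale":
        raise ValueError(f"unknown smoothing mode {mode!r}")
    masked = profile.masked | _edge_mask(offs, edge_trim)
    value = np.full(profile.value.shape, np.nan)
    out_mask = np.ones(profile.value.shape, dtype=bool)
    core = offs >= -HALF
    for seg, window in ((core, 30), (~core, 50)):
        if not seg.any():
            continue
        if seg.sum() < window:
            raise ValueError(
                f"segment of {int(seg.sum())} columns shorter than the "
                f"{window}-column smoothing window"
            )
        v, m = _renorm_smooth(profile.value[seg], masked[seg], np.full(window, 1.0 / window))
        value[seg] = v
        out_mask[seg] = m
    value[out_mask] = np.nan
    return replace_profile(profile, value, out_mask)


def replace_profile(profile: PositionalProfile, value, masked) -> PositionalProfile:
    return PositionalProfile(
        profile.offsets.copy(), value, profile.count.copy(), masked,
        profile.statistic, numer=profile.numer, denom=profile.denom,
    )
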