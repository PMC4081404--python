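"""Polarized lineage-specific divergence across nucleosomal fragments.

A site is polarized on the focal lineage when the sibling species and at
least one of the two outgroups carry the identical base (standard mode), or
when sibling and both outgroups agree (stringent mode); that shared base is
the inferred ancestral state.  A polarized site is diverged when the focal
base differs from the ancestral base, defining a substitution pathway
ancestral->focal.

Per-offset divergence is the weighted count of a specific substitution
divided by the weighted count of polarized sites with that ancestral state.
Substitutional pathways are switched at the dyad axis: a genomic C->T at
offset +k counts toward G->A at column -k, because the right half of each
fragment enters the analysis reverse-complemented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genome import COMPLEMENT, Genome, N
from .profiles import (
    PositionalProfile,
    half_matrices,
    site_offsets,
    _edge_mask,
)

_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True

COMP_CHAR = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement_pathway(pathway: tuple[str, str]) -> tuple[str, str]:
    return COMP_CHAR[pathway[0]], COMP_CHAR[pathway[1]]


# ---------------------------------------------------------------------------
# polarization


def polarize(sites: pd.DataFrame, mode: str = "standard") -> pd.DataFrame:
    """Infer per-site ancestral states from the four-species base table.

    ``sites`` has columns chrom, pos, focal, sib, out1, out2 (single
    characters; anything outside ACGT counts as missing).  Adds columns
    ``ancestral`` ('N' when unpolarizable), ``polarized`` and ``diverged``.
    Swapping out1 and out2 never changes the result.
    """
    if mode not in ("standard", "stringent"):
        raise ValueError(f"unknown polarization mode {mode!r}")
    out = sites.copy()

    def codes(col):
        return np.frombuffer(
            "".join(out[col].astype(str).str.upper().str[0]).encode("ascii"),
            dtype=np.uint8,
        )

    focal, sib, o1, o2 = (codes(c) for c in ("focal", "sib", "out1", "out2"))
    vf, vs, v1, v2 = _VALID[focal], _VALID[sib], _VALID[o1], _VALID[o2]
    if mode == "standard":
        ok = vf & vs & ((v1 & (o1 == sib)) | (v2 & (o2 == sib)))
    else:
        ok = vf & vs & v1 & v2 & (o1 == sib) & (o2 == sib)
    anc = np.where(ok, sib, ord("N")).astype(np.uint8)
    out["ancestral"] = np.frombuffer(anc.tobytes(), dtype="S1").astype("U1")
    out["polarized"] = ok
    out["diverged"] = ok & (focal != anc)
    return out


def site_arrays(
    polarized: pd.DataFrame, chrom_sizes: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Genome-length (ancestral, focal) uint8 arrays; 0 marks no data."""
    out = {}
    for chrom, size in chrom_sizes.items():
        anc = np.zeros(size, dtype=np.uint8)
        foc = np.zeros(size, dtype=np.uint8)
        grp = polarized[polarized["chrom"] == chrom]
        if len(grp):
            pos = grp["pos"].to_numpy()
            a = np.frombuffer(
                "".join(grp["ancestral"]).encode("ascii"), dtype=np.uint8
            ).copy()
            a[~_VALID[a]] = 0
            f = np.frombuffer(
                "".join(grp["focal"].astype(str).str.upper().str[0]).encode("ascii"),
                dtype=np.uint8,
            ).copy()
            f[~_VALID[f]] = 0
            anc[pos] = a
            foc[pos] = f
        out[chrom] = (anc, foc)
    return out


# ---------------------------------------------------------------------------
# profiles


def _site_multiplicity(mats: dict, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Half-observation count per genomic position over the analysis set."""
    mult = {c: np.zeros(s, dtype=np.int64) for c, s in chrom_sizes.items()}
    for chrom, m in mats.items():
        pos = m["pos"]
        ok = pos >= 0
        np.add.at(mult[chrom], pos[ok], 1)
    return mult


def _gather_halves(mats_chrom, arrays, is_right_complement=True):
    """Per-cell (ancestral, focal) codes for one chromosome's half matrix,
    with right-half rows complemented so pathways fold at the dyad."""
    anc_full, foc_full = arrays
    pos = mats_chrom["pos"]
    ok = pos >= 0
    anc = np.zeros(pos.shape, dtype=np.uint8)
    foc = np.zeros(pos.shape, dtype=np.uint8)
    anc[ok] = anc_full[pos[ok]]
    foc[ok] = foc_full[pos[ok]]
    if is_right_complement:
        half = pos.shape[0] // 2
        comp = COMPLEMENT.copy()
        comp[0] = 0
        anc[half:] = comp[anc[half:]]
        foc[half:] = comp[foc[half:]]
    return anc, foc


def divergence_profile(
    polarized: pd.DataFrame,
    n147: pd.DataFrame,
    chrom_sizes: dict[str, int],
    pathway: tuple[str, str] = ("G", "A"),
    weighting: str = "per_n147",
    trim: int = 5,
    flank: int = 0,
) -> PositionalProfile:
    """Per-offset substitution rate for one pathway over an n147 set.

    ``weighting='per_n147'`` counts every half-observation once (sites
    recurring in overlapping fragments get proportionally more weight);
    ``'per_site'`` downweights each occurrence of a genomic site by its
    total number of half-observations, so every site contributes weight 1.
    Columns within ``trim`` bp of the fragment edges are masked.
    """
    x, y = pathway[0].upper(), pathway[1].upper()
    if x == y or x not in "ACGT" or y not in "ACGT":
        raise ValueError(f"pathway must be an ordered pair of distinct bases, got {pathway}")
    if weighting not in ("per_n147", "per_site"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(chrom_sizes, Genome):
        chrom_sizes = chrom_sizes.lengths()
    genome_stub = Genome({c: np.zeros(s, dtype=np.uint8) for c, s in chrom_sizes.items()})
    mats = half_matrices(n147, genome_stub, flank)
    arrays = site_arrays(polarized, chrom_sizes)
    mult = _site_multiplicity(mats, chrom_sizes) if weighting == "per_site" else None

    offs = site_offsets(flank)
    anc_count = np.zeros(len(offs))
    div_count = np.zeros(len(offs))
    for chrom, m in mats.items():
        anc, foc = _gather_halves(m, arrays[chrom])
        if weighting == "per_site":
            w = np.zeros(m["pos"].shape)
            ok = m["pos"] >= 0
            w[ok] = 1.0 / mult[chrom][m["pos"][ok]]
        else:
            w = np.ones(m["pos"].shape)
        is_anc = anc == ord(x)
        anc_count += (is_anc * w).sum(axis=0)
        div_count += ((is_anc & (foc == ord(y))) * w).sum(axis=0)
    masked = (anc_count == 0) | _edge_mask(offs, trim)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(masked, np.nan, div_count / np.where(anc_count == 0, 1, anc_count))
    return PositionalProfile(
        offs, value, anc_count, masked, f"div:{x}->{y}",
        numer=div_count, denom=anc_count,
    )


def merge_complementary(a: PositionalProfile, b: PositionalProfile) -> PositionalProfile:
    """Pool two rate profiles count-wise (sum events / sum opportunities).

    Masked columns contribute nothing; the pooled column is masked only
    where neither profile has data (deliberate trims are shared by
    construction since both profiles use the same conventions).
    """
    if not np.array_equal(a.offsets, b.offsets):
        raise ValueError("profiles must share offset columns")
    if a.numer is None or b.numer is None:
        raise ValueError("count-wise merge needs numer/denom counts")
    numer = np.where(a.masked, 0, a.numer) + np.where(b.masked, 0, b.numer)
    denom = np.where(a.masked, 0, a.denom) + np.where(b.masked, 0, b.denom)
    masked = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(masked, np.nan, numer / np.where(denom == 0, 1, denom))
    return PositionalProfile(
        a.offsets.copy(), value, denom, masked,
        f"{a.statistic}+{b.statistic}", numer=numer, denom=denom,
    )


# ---------------------------------------------------------------------------
# per-region rates and correlations


def per_fragment_rate(
    polarized: pd.DataFrame,
    n147: pd.DataFrame,
    chrom_sizes: dict[str, int],
    pathway: tuple[str, str] = ("G", "A"),
    trim: int = 5,
) -> pd.DataFrame:
    """Pathway rate per n147 region (pathway pooled with its complement).

    Returns a frame aligned with ``n147``: ancestral and diverged counts
    over the trimmed core, the number of polarizable bases in the full
    fragment, and the rate (NaN when no ancestral sites).
    """
    x, y = pathway[0].upper(), pathway[1].upper()
    cx, cy = complement_pathway((x, y))
    arrays = site_arrays(polarized, chrom_sizes)
    anc_n, div_n, polarizable = [], [], []
    for chrom, start, end in zip(n147["chrom"], n147["start"], n147["end"]):
        anc, foc = arrays[chrom]
        a = anc[start + trim : end - trim]
        f = foc[start + trim : end - trim]
        is_anc = (a == ord(x)) | (a == ord(cx))
        hit = ((a == ord(x)) & (f == ord(y))) | ((a == ord(cx)) & (f == ord(cy)))
        anc_n.append(int(is_anc.sum()))
        div_n.append(int(hit.sum()))
        polarizable.append(int((anc[start:end] != 0).sum()))
    out = n147[["chrom", "start", "end"]].copy()
    out["ancestral_count"] = anc_n
    out["diverged_count"] = div_n
    out["polarizable"] = polarizable
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rate"] = np.where(
            out["ancestral_count"] > 0,
            out["diverged_count"] / out["ancestral_count"].replace(0, 1),
            np.nan,
        )
    return out


def correlate_with_occupancy(
    polarized: pd.DataFrame,
    n147: pd.DataFrame,
    track: dict[str, np.ndarray],
    genome: Genome,
    pathway: tuple[str, str] = ("G", "A"),
    trim: int = 5,
    min_polarizable: int = 50,
) -> dict[str, float]:
    """Spearman's rho of per-n147 pathway rate vs log10 coverage and vs GC.

    Only regions with at least ``min_polarizable`` of their 147 bases
    polarizable enter; coverage is the summed 142-152 bp pileup over the
    region and GC is computed from fragment bases 6..141.
    """
    from .fragments import gc_fraction

    rates = per_fragment_rate(polarized, n147, genome.lengths(), pathway, trim)
    cov = np.array(
        [track[c][s:e].sum() for c, s, e in zip(rates["chrom"], rates["start"], rates["end"])],
        dtype=float,
    )
    gc = np.array(
        [gc_fraction(genome, c, s, e) for c, s, e in
         zip(rates["chrom"], rates["start"], rates["end"])]
    )
    keep = (
        (rates["polarizable"].to_numpy() >= min_polarizable)
        & np.isfinite(rates["rate"].to_numpy())
        & (cov > 0)
        & np.isfinite(gc)
    )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 regions pass the polarizability filter")
    r = rates["rate"].to_numpy()[keep]
    rho_cov, p_cov = stats.spearmanr(r, np.log10(cov[keep]))
    rho_gc, p_gc = stats.spearmanr(r, gc[keep])
    return {
        "rho_coverage": float(rho_cov),
        "p_coverage": float(p_cov),
        "rho_gc": float(rho_gc),
        "p_gc": float(p_gc),
        "n_regions": int(keep.sum()),
    }


def window_gc_correlation(
    polarized: pd.DataFrame,
    genome: Genome,
    pathway: tuple[str, str] = ("G", "A"),
    window: int = 500,
    min_polarizable: int = 166,
    max_n: int = 250,
) -> dict[str, float]:
    """Spearman's rho of pathway rate vs GC in non-overlapping 500 bp
    windows with >= ``min_polarizable`` polarizable bases and <= ``max_n``
    reference Ns."""
    arrays = site_arrays(polarized, genome.lengths())
    x, y = pathway[0].upper(), pathway[1].upper()
    cx, cy = complement_pathway((x, y))
    rates, gcs = [], []
    for chrom, (anc, foc) in arrays.items():
        seq = genome[chrom]
        for s in range(0, len(seq) - window + 1, window):
            a = anc[s : s + window]
            f = foc[s : s + window]
            n_pol = int((a != 0).sum())
            n_missing = int((seq[s : s + window] == N).sum())
            if n_pol < min_polarizable or n_missing > max_n:
                continue
            is_anc = (a == ord(x)) | (a == ord(cx))
            if is_anc.sum() == 0:
                continue
            hit = ((a == ord(x)) & (f == ord(y))) | ((a == ord(cx)) & (f == ord(cy)))
            rates.append(hit.sum() / is_anc.sum())
            w = seq[s : s + window]
            ok = w != N
            gcs.append(float(np.isin(w[ok], [ord("G"), ord("C")]).sum() / ok.sum()))
    if len(rates) < 3:
        raise ValueError("fewer than 3 windows pass the filters")
    rho, p = stats.spearmanr(rates, gcs)
    return {"rho_gc": float(rho), "p_gc": float(p), "n_windows": len(rates)}


def dinuc_divergence_correlation(
    rate_profile: PositionalProfile,
    dinuc_profile: PositionalProfile,
    min_columns: int = 10,
) -> float:
    """Pearson r between an unsmoothed rate profile and a dinucleotide
    frequency profile over their shared unmasked columns."""
    shared, ia, ib = np.intersect1d(
        rate_profile.offsets, dinuc_profile.offsets, return_indices=True
    )
    ok = ~rate_profile.masked[ia] & ~dinuc_profile.masked[ib]
    if ok.sum() < min_columns:
        raise ValueError(
            f"only {int(ok.sum())} shared unmasked columns (< {min_columns})"
        )
    r, _ = stats.pearsonr(rate_profile.value[ia][ok], dinuc_profile.value[ib][ok])
    return float(r)
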