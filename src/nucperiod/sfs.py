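"""Site-frequency-spectrum statistics: per-SNP heterozygosity and the
delta-pi skew index.

delta-pi is an *index* (not a test statistic) of the deviation of per-SNP
sample heterozygosity from its expectation under neutral mutation-drift
equilibrium in a Wright-Fisher population.  For a biallelic SNP with derived
count ``i`` in a sample of ``n`` chromosomes the unbiased sample
heterozygosity is

    h(i, n) = n/(n-1) * 2 * (i/n) * ((n-i)/n) = 2 i (n-i) / (n (n-1))

Under the neutral equilibrium the probability that a segregating site has
derived count i is G_n(i) = (1/i) / a_n with a_n = sum_{i=1}^{n-1} 1/i, and
the expected per-SNP heterozygosity is exactly

    E_n = sum_i G_n(i) h(i, n) = 1/a_n

delta_pi(i, n) = h(i, n) - 1/a_n.  Because h is invariant under i <-> n-i
the index is a *folded* statistic: mis-polarized ancestral states do not
change it, and it emphasizes mid-frequency variation.  Weak positive
selection on derived alleles shifts the spectrum toward intermediate
frequencies and makes the average delta-pi more positive; weak negative
selection makes it more negative.

Sites with heterogeneous sample sizes are combined by weighting each
sample-size class by the reciprocal of the neutral per-SNP variance of h
(times the class SNP count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "harmonic",
    "pi_per_snp",
    "expected_h",
    "delta_pi",
    "var_delta_pi",
    "DeltaPiAccumulator",
    "aggregate_delta_pi",
    "filter_snps",
]


@lru_cache(maxsize=None)
def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the (n-1)-th harmonic number."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return float(np.sum(1.0 / np.arange(1, n)))


def neutral_sfs(n: int) -> np.ndarray:
    """G_n(i) for i = 1..n-1: neutral probability of derived count i."""
    i = np.arange(1, n)
    return (1.0 / i) / harmonic(n)


def pi_per_snp(i, n):
    """Unbiased sample heterozygosity h(i, n) of one segregating site.

    Vectorized over ``i``; raises if any i is 0 or n (not segregating).
    """
    i = np.asarray(i)
    n = np.asarray(n)
    if np.any(n < 2):
        raise ValueError("sample size n must be >= 2")
    if np.any((i <= 0) | (i >= n)):
        raise ValueError("derived count i must satisfy 1 <= i <= n-1 (segregating)")
    h = 2.0 * i * (n - i) / (n * (n - 1.0))
    return float(h) if h.ndim == 0 else h


@lru_cache(maxsize=None)
def expected_h(n: int) -> float:
    """Neutral expectation of h at a segregating site; equals 1/a_n."""
    return 1.0 / harmonic(n)


def expected_h_bruteforce(n: int) -> float:
    """Direct sum over the neutral spectrum; guards the closed form."""
    i = np.arange(1, n)
    return float(np.sum(neutral_sfs(n) * pi_per_snp(i, n)))


def delta_pi(i, n):
    """Per-SNP deviation h(i, n) - E_n of heterozygosity from neutrality."""
    n_arr = np.asarray(n)
    if n_arr.ndim == 0:
        e = expected_h(int(n))
    else:
        e = np.array([expected_h(int(v)) for v in n_arr.ravel()]).reshape(n_arr.shape)
    return pi_per_snp(i, n) - e


@lru_cache(maxsize=None)
def var_delta_pi(n: int) -> float:
    """Neutral per-SNP variance of h (hence of delta-pi) at sample size n."""
    if n < 4:
        raise ValueError(f"sample size n must be >= 4, got {n}")
    i = np.arange(1, n)
    g = neutral_sfs(n)
    h = pi_per_snp(i, n)
    e = expected_h(n)
    return float(np.sum(g * h * h) - e * e)


@dataclass
class DeltaPiAccumulator:
    """Per-sample-size running sums for inverse-variance delta-pi pooling.

    ``s[n]`` is the (possibly weighted) SNP count of class n and ``sum_h[n]``
    the matching weighted sum of per-SNP heterozygosities.
    """

    s: dict[int, float] = field(default_factory=dict)
    sum_h: dict[int, float] = field(default_factory=dict)

    def add(self, i, n, weight=None) -> None:
        i = np.atleast_1d(np.asarray(i))
        n = np.atleast_1d(np.asarray(n))
        if n.size == 1:
            n = np.full(i.shape, int(n[0]))
        w = np.ones(i.shape) if weight is None else np.atleast_1d(np.asarray(weight, float))
        h = pi_per_snp(i, n)
        for nv in np.unique(n):
            m = n == nv
            key = int(nv)
            self.s[key] = self.s.get(key, 0.0) + float(w[m].sum())
            self.sum_h[key] = self.sum_h.get(key, 0.0) + float((w[m] * h[m]).sum())

    def mean_by_n(self) -> dict[int, float]:
        return {n: self.sum_h[n] / self.s[n] - expected_h(n) for n in self.s if self.s[n] > 0}

    def combine(self) -> tuple[float, float, float]:
        """Inverse-variance weighted (delta_pi, standard error, total S)."""
        means = self.mean_by_n()
        if not means:
            raise ValueError("no SNPs accumulated")
        wsum = vsum = 0.0
        for n, m in means.items():
            w = self.s[n] / var_delta_pi(n)
            wsum += w * m
            vsum += w
        return wsum / vsum, vsum**-0.5, float(sum(self.s.values()))


def filter_snps(
    snps: pd.DataFrame,
    n_min: int | None = None,
    n_max: int | None = None,
    drop_singletons: bool = False,
    ancestral_in_strain: bool = False,
    strain_column: str = "strain_allele",
) -> pd.DataFrame:
    """Apply the standard SNP filters.

    - sample-size window [n_min, n_max]
    - singleton removal: drop sites where either allele occurs once,
      i.e. min(i, n-i) == 1
    - ascertainment filter: keep only sites where the experimental strain
      carries the inferred ancestral allele (needs ``strain_column``)
    """
    keep = np.ones(len(snps), dtype=bool)
    if n_min is not None:
        keep &= snps["n"].to_numpy() >= n_min
    if n_max is not None:
        keep &= snps["n"].to_numpy() <= n_max
    if drop_singletons:
        i = snps["i"].to_numpy()
        n = snps["n"].to_numpy()
        keep &= np.minimum(i, n - i) > 1
    if ancestral_in_strain:
        if strain_column not in snps.columns:
            raise ValueError(f"missing column {strain_column!r} for ascertainment filter")
        keep &= (snps[strain_column] == snps["ancestral"]).to_numpy()
    return snps.loc[keep]


def aggregate_delta_pi(
    snps: pd.DataFrame,
    n_min: int = 4,
    n_max: int | None = None,
    weights=None,
) -> tuple[float, float, float]:
    """Weighted average delta-pi over a SNP table with columns ``i`` and ``n``.

    Returns (delta_pi, standard error, effective SNP count).  Sample-size
    classes are weighted by S_n / Var_n; within a class SNPs may carry
    occurrence weights (per-site weighting passes 1/multiplicity).
    """
    if n_min <= 3:
        raise ValueError("n_min must be > 3")
    n = snps["n"].to_numpy()
    mask = n >= n_min
    if n_max is not None:
        mask &= n <= n_max
    if not mask.any():
        raise ValueError("no SNPs in the requested sample-size range")
    acc = DeltaPiAccumulator()
    w = None if weights is None else np.asarray(weights, float)[mask]
    acc.add(snps["i"].to_numpy()[mask], n[mask], w)
    return acc.combine()


def drop_multiallelic(snps: pd.DataFrame) -> pd.DataFrame:
    """Remove all records at positions with more than one segregating pair.

    Pathway labels are biallelic (ancestral plus one derived base), so a
    position appearing in several records cannot be assigned one.
    """
    dup = snps.duplicated(["chrom", "pos"], keep=False)
    return snps.loc[~dup].reset_index(drop=True)


def delta_pi_profile(
    snps: pd.DataFrame,
    n147: pd.DataFrame,
    chrom_sizes: dict[str, int],
    pathway: tuple[str, str] = ("G", "A"),
    weighting: str = "per_n147",
    trim: int = 5,
    flank: int = 0,
    n_min: int | None = None,
    n_max: int | None = None,
    drop_singletons: bool = False,
    ancestral_in_strain: bool = False,
):
    """Per-offset average delta-pi for one polymorphism pathway.

    ``pathway=('G', 'A')`` selects G->GA SNPs: inferred ancestral G with a
    derived A segregating.  Dyad symmetrization folds pathways at the dyad
    axis: a genomic C->CT SNP at offset +k counts toward G->GA at column
    -k.  Per column, sample-size classes are pooled by inverse-variance
    weighting; ``weighting`` follows the divergence-profile conventions.
    Columns within ``trim`` bp of the fragment edges, or with no SNPs, are
    masked.
    """
    from .divergence import _site_multiplicity, complement_pathway
    from .genome import Genome
    from .profiles import _edge_mask, half_matrices, site_offsets

    x, y = pathway[0].upper(), pathway[1].upper()
    cx, cy = complement_pathway((x, y))
    if weighting not in ("per_n147", "per_site"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if hasattr(chrom_sizes, "lengths"):
        chrom_sizes = chrom_sizes.lengths()
    snps = drop_multiallelic(snps)
    snps = filter_snps(
        snps, n_min, n_max, drop_singletons=drop_singletons,
        ancestral_in_strain=ancestral_in_strain,
    ).reset_index(drop=True)

    genome_stub = Genome({c: np.zeros(s, dtype=np.uint8) for c, s in chrom_sizes.items()})
    mats = half_matrices(n147, genome_stub, flank)
    mult = _site_multiplicity(mats, chrom_sizes) if weighting == "per_site" else None

    offs = site_offsets(flank)
    n_values = np.sort(snps["n"].unique()) if len(snps) else np.array([], dtype=int)
    n_index = {int(v): k for k, v in enumerate(n_values)}
    S = np.zeros((len(offs), max(len(n_values), 1)))
    H = np.zeros_like(S)

    snp_anc = snps["ancestral"].str.upper().map(ord).to_numpy(dtype=np.uint8) \
        if len(snps) else np.array([], dtype=np.uint8)
    snp_der = snps["derived"].str.upper().map(ord).to_numpy(dtype=np.uint8) \
        if len(snps) else np.array([], dtype=np.uint8)
    snp_i = snps["i"].to_numpy() if len(snps) else np.array([], dtype=int)
    snp_n = snps["n"].to_numpy() if len(snps) else np.array([], dtype=int)

    for chrom, m in mats.items():
        idx = np.full(chrom_sizes[chrom], -1, dtype=np.int64)
        grp = snps[snps["chrom"] == chrom]
        if len(grp):
            idx[grp["pos"].to_numpy()] = grp.index.to_numpy()
        pos = m["pos"]
        sid = np.where(pos >= 0, idx[np.clip(pos, 0, None)], -1)
        half_rows = pos.shape[0] // 2
        hit = sid >= 0
        a = np.zeros(pos.shape, dtype=np.uint8)
        d = np.zeros(pos.shape, dtype=np.uint8)
        a[hit] = snp_anc[sid[hit]]
        d[hit] = snp_der[sid[hit]]
        match = np.zeros(pos.shape, dtype=bool)
        match[:half_rows] = hit[:half_rows] & (a[:half_rows] == ord(x)) & (d[:half_rows] == ord(y))
        match[half_rows:] = hit[half_rows:] & (a[half_rows:] == ord(cx)) & (d[half_rows:] == ord(cy))
        rows, cols = np.nonzero(match)
        if rows.size == 0:
            continue
        s_ids = sid[rows, cols]
        if weighting == "per_site":
            w = 1.0 / mult[chrom][pos[rows, cols]]
        else:
            w = np.ones(rows.size)
        h = pi_per_snp(snp_i[s_ids], snp_n[s_ids])
        n_idx = np.array([n_index[int(v)] for v in snp_n[s_ids]])
        np.add.at(S, (cols, n_idx), w)
        np.add.at(H, (cols, n_idx), w * h)

    count = S.sum(axis=1)
    value = np.full(len(offs), np.nan)
    for j in range(len(offs)):
        wsum = vsum = 0.0
        for nv, k in n_index.items():
            if S[j, k] <= 0:
                continue
            mean = H[j, k] / S[j, k] - expected_h(nv)
            wgt = S[j, k] / var_delta_pi(nv)
            wsum += wgt * mean
            vsum += wgt
        if vsum > 0:
            value[j] = wsum / vsum
    masked = (count == 0) | _edge_mask(offs, trim)
    value[masked] = np.nan

    from .profiles import PositionalProfile

    return PositionalProfile(offs, value, count, masked, f"dpi:{x}->{x}{y}")
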