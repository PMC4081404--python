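"""Dominant-period estimation for positional profiles and the
pathway-dinucleotide correlation matrix.

Positional profiles carry masked columns (edge trims, zero-count columns),
so spectral power is computed with the Lomb-Scargle periodogram over the
unmasked columns only; the profile is detrended first (mean removal,
linear fit, or subtraction of a broad running mean to strip low-frequency
structure such as the overall AT-content skew around nucleosome arrays).
The reported period is the argmax over a dense period grid refined by
quadratic interpolation; prominence is the peak variance-normalized power
(the fraction of detrended profile variance concentrated at the dominant
period), which is invariant under positive rescaling of the profile.
Significance is assessed against a permutation null (column shuffles), not
an analytic distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal



@dataclass(frozen=True)
class PeriodEstimate:
    period: float
    prominence: float
    method: str
    n_columns: int

    def __post_init__(self):
        if not self.period > 2:
            raise ValueError("estimated period must exceed 2 columns (Nyquist)")


def _profile_xy(profile) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(profile, "offsets"):  # PositionalProfile or compatible
        ok = ~profile.masked & np.isfinite(profile.value)
        return profile.offsets[ok].astype(float), profile.value[ok]
    values = np.asarray(profile, dtype=float)
    ok = np.isfinite(values)
    return np.arange(len(values), dtype=float)[ok], values[ok]


def _detrend(x: np.ndarray, y: np.ndarray, mode: str, lowfreq_window: int) -> np.ndarray:
    if mode == "mean":
        return y - y.mean()
    if mode == "linear":
        coef = np.polyfit(x, y, 1)
        return y - np.polyval(coef, x)
    if mode == "lowfreq":
        # subtract a broad running mean over the (possibly gapped) columns
        half = lowfreq_window // 2
        trend = np.array([
            y[(x >= xi - half) & (x <= xi + half)].mean() for xi in x
        ])
        return y - trend
    raise ValueError(f"unknown detrend mode {mode!r}")


def estimate_period(
    profile,
    period_range: tuple[float, float] = (5.0, 20.0),
    detrend: str = "linear",
    n_grid: int = 2000,
    min_cycles: float = 3.0,
    lowfreq_window: int = 601,
) -> PeriodEstimate:
    """Dominant period of a profile within a candidate period band.

    Accepts a PositionalProfile (masked columns are skipped) or a plain
    value array (NaNs skipped).  Raises when the unmasked span holds fewer
    than ``min_cycles`` cycles of the largest candidate period.
    """
    lo, hi = float(period_range[0]), float(period_range[1])
    if not (2 < lo < hi):
        raise ValueError("period_range must satisfy 2 < lo < hi")
    x, y = _profile_xy(profile)
    if x.size < 8:
        raise ValueError("too few unmasked columns for period estimation")
    span = x.max() - x.min()
    if span < min_cycles * hi:
        raise ValueError(
            f"span of {span:.0f} columns holds fewer than {min_cycles} cycles "
            f"of period {hi:.0f}"
        )
    yd = _detrend(x, y, detrend, lowfreq_window)
    periods = np.linspace(lo, hi, n_grid)
    omega = 2 * np.pi / periods
    power = signal.lombscargle(x, yd, omega, normalize=True)
    k = int(np.argmax(power))
    period = periods[k]
    if 0 < k < n_grid - 1:
        # quadratic interpolation of the peak on the period grid
        p0, p1, p2 = power[k - 1], power[k], power[k + 1]
        denom = p0 - 2 * p1 + p2
        if denom != 0:
            period = period + 0.5 * (p0 - p2) / denom * (periods[1] - periods[0])
    return PeriodEstimate(float(period), float(power[k]), "periodogram", int(x.size))


def permutation_null(
    profile,
    period_range: tuple[float, float] = (5.0, 20.0),
    detrend: str = "linear",
    n_permutations: int = 200,
    seed: int = 0,
    **kwargs,
) -> tuple[float, np.ndarray]:
    """Observed prominence and its column-shuffle null distribution.

    Returns (observed prominence, null prominences).  The observed value
    exceeding the 95th percentile of the null flags significant
    periodicity.
    """
    rng = np.random.default_rng(seed)
    obs = estimate_period(profile, period_range, detrend, **kwargs).prominence
    x, y = _profile_xy(profile)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = estimate_period(
            _Shuffled(x, rng.permutation(y)), period_range, detrend, **kwargs,
        ).prominence
    return obs, null


class _Shuffled:
    """Adapter presenting shuffled values on the original columns."""

    def __init__(self, x, y):
        self.offsets = x.astype(np.int64)
        self.value = y
        self.masked = np.zeros(len(x), dtype=bool)


def best_lag(a, b, max_lag: int = 5) -> int:
    """Number of columns ``b`` must be shifted rightward to best match ``a``.

    Both inputs are value arrays on the same columns (NaNs allowed); used
    to measure the phase alignment of two periodic profiles.  A lag of 0
    means the peaks coincide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share columns")
    scores = {}
    for lag in range(-max_lag, max_lag + 1):
        if lag > 0:
            aa, bb = a[lag:], b[: len(b) - lag]
        elif lag < 0:
            aa, bb = a[:lag], b[-lag:]
        else:
            aa, bb = a, b
        ok = np.isfinite(aa) & np.isfinite(bb)
        if ok.sum() < 10:
            continue
        scores[lag] = float(np.corrcoef(aa[ok], bb[ok])[0, 1])
    if not scores:
        raise ValueError("no lag with enough overlapping finite columns")
    return max(scores, key=scores.get)


# ---------------------------------------------------------------------------
# Table-1-style correlation matrix

#: divergence/polymorphism pathway paired with its preferred dinucleotide
DEFAULT_PAIRS = [(("G", "A"), "AA"), (("C", "T"), "TT"), (("A", "G"), "GC")]


def table1_matrix(
    divergence_profiles: dict,
    delta_pi_profiles: dict,
    dinuc_profiles: dict,
    classes=("intronic", "intergenic"),
    pairs=None,
) -> pd.DataFrame:
    """Pearson correlations of per-site divergence / delta-pi with the
    matched dinucleotide frequency, per region class.

    Inputs are nested dicts ``profiles[region_class][key]`` where keys are
    pathway tuples for the rate profiles and dinucleotide strings for the
    frequency profiles.  Missing cells are reported as NaN and the run
    continues.
    """
    from .divergence import dinuc_divergence_correlation

    pairs = DEFAULT_PAIRS if pairs is None else pairs
    columns = [f"{p[0]}->{p[1]} & {d}" for p, d in pairs]
    rows = {}
    for cls in classes:
        for label, profs in (("divergence", divergence_profiles),
                             ("delta_pi", delta_pi_profiles)):
            vals = []
            for pathway, dinuc in pairs:
                try:
                    r = dinuc_divergence_correlation(
                        profs[cls][pathway], dinuc_profiles[cls][dinuc]
                    )
                except (KeyError, ValueError):
                    r = np.nan
                vals.append(r)
            rows[f"{cls} {label}"] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
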