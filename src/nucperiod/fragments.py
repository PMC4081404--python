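"""Classification, filtering and resampling of nucleosomal fragment intervals.

All intervals are 0-based half-open.  A fragment is assigned to a region
class (intergenic/intronic) only if the fragment plus its +/-flank lies
wholly inside one contiguous annotation interval of that class and outside
every mask interval; otherwise it is excluded.  The canonical analysis set
("n147") keeps exactly the classified fragments of length 147, duplicates
included -- identical intervals carry the per-fragment occupancy weighting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import C as _C, G as _G, N as _N

logger = logging.getLogger(__name__)

CORE_LEN = 147


def _interval_index(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) sorted by start."""
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        out[chrom] = (g["start"].to_numpy(), g["end"].to_numpy())
    return out


def _containing_interval(index, chrom, start, end) -> bool:
    """True if [start, end) lies wholly inside one interval of the index."""
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    k = np.searchsorted(starts, start, side="right") - 1
    return k >= 0 and ends[k] >= end


def _overlaps_any(index, chrom, start, end) -> bool:
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    k = np.searchsorted(starts, end, side="left")
    # any interval starting before `end` that has not ended by `start`
    return bool(k > 0 and np.any(ends[:k] > start))


def classify_fragments(
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = 50,
    mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign region_class to each fragment by flank-padded containment.

    ``annotation`` has columns chrom, start, end, region_class with
    non-overlapping intervals within each class.  Fragments whose padded
    span is not contained in a single interval of one class, or overlaps a
    mask interval, or sits on an unannotated chromosome, get class
    "excluded".
    """
    by_class = {
        cls: _interval_index(grp)
        for cls, grp in annotation.groupby("region_class", sort=False)
    }
    mask_idx = _interval_index(mask) if mask is not None and len(mask) else None
    ann_chroms = set(annotation["chrom"])

    out = fragments.copy().reset_index(drop=True)
    if "length" not in out.columns:
        out["length"] = out["end"] - out["start"]
    classes = []
    n_missing_chrom = 0
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        s, e = start - flank, end + flank
        label = "excluded"
        if chrom not in ann_chroms:
            n_missing_chrom += 1
        elif mask_idx is not None and _overlaps_any(mask_idx, chrom, s, e):
            pass
        else:
            for cls, idx in by_class.items():
                if _containing_interval(idx, chrom, s, e):
                    label = cls
                    break
        classes.append(label)
    if n_missing_chrom:
        logger.info(
            "classify_fragments: %d fragments on chromosomes absent from the "
            "annotation were excluded", n_missing_chrom,
        )
    out["region_class"] = classes
    return out


def select_n147(fragments: pd.DataFrame) -> pd.DataFrame:
    """Keep length-147 fragments classified intergenic or intronic.

    Duplicate identical intervals are retained: they encode the per-n147
    occupancy weighting.
    """
    keep = (fragments["length"] == CORE_LEN) & fragments["region_class"].isin(
        ["intergenic", "intronic"]
    )
    return fragments.loc[keep].reset_index(drop=True)


def occupancy_track(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    length_min: int = 142,
    length_max: int = 152,
) -> dict[str, np.ndarray]:
    """Per-base pileup coverage by fragments of length 142-152 bp."""
    lengths = fragments["end"] - fragments["start"]
    sub = fragments.loc[(lengths >= length_min) & (lengths <= length_max)]
    track = {c: np.zeros(l, dtype=np.int64) for c, l in chrom_sizes.items()}
    for chrom, grp in sub.groupby("chrom", sort=False):
        if chrom not in track:
            continue
        cov = track[chrom]
        delta = np.zeros(len(cov) + 1, dtype=np.int64)
        starts = np.clip(grp["start"].to_numpy(), 0, len(cov))
        ends = np.clip(grp["end"].to_numpy(), 0, len(cov))
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        cov += np.cumsum(delta[:-1])
    return track


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Run-length-encoded bedGraph of an occupancy track."""
    with open(path, "w") as fh:
        for chrom, cov in track.items():
            if cov.size == 0:
                continue
            change = np.nonzero(np.diff(cov))[0] + 1
            bounds = np.concatenate([[0], change, [cov.size]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                if cov[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cov[s]}\n")


def sample_nonoverlapping(
    fragments: pd.DataFrame,
    seed: int = 0,
    prefilter=None,
) -> pd.DataFrame:
    """Greedy random non-overlapping subset, drawn without replacement.

    Fragments are visited in a seeded random order; a fragment joins the
    subset only if it shares no position with any previously accepted one.
    ``prefilter`` is an optional boolean predicate (row -> bool) or boolean
    array applied before sampling (e.g. "contains the relevant SNP class").
    """
    frags = fragments.reset_index(drop=True)
    if prefilter is not None:
        if callable(prefilter):
            keep = frags.apply(prefilter, axis=1).to_numpy(dtype=bool)
        else:
            keep = np.asarray(prefilter, dtype=bool)
        frags = frags.loc[keep].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frags))
    accepted: dict[str, list[tuple[int, int]]] = {}
    chosen = []
    chroms = frags["chrom"].to_numpy()
    starts = frags["start"].to_numpy()
    ends = frags["end"].to_numpy()
    import bisect

    for k in order:
        c, s, e = chroms[k], starts[k], ends[k]
        taken = accepted.setdefault(c, [])
        j = bisect.bisect_right(taken, (s, e))
        # neighbor on the left must end by s; on the right must start at/after e
        if j > 0 and taken[j - 1][1] > s:
            continue
        if j < len(taken) and taken[j][0] < e:
            continue
        taken.insert(j, (s, e))
        chosen.append(k)
    return frags.iloc[sorted(chosen)].reset_index(drop=True)


def gc_fraction(genome, chrom: str, start: int, end: int,
                inner: tuple[int, int] = (5, 141)) -> float:
    """GC fraction of bases 6..141 (1-based) of a 147 bp fragment."""
    seq = genome.fetch(chrom, start + inner[0], start + inner[1])
    ok = seq != _N
    if not ok.any():
        return np.nan
    gc = np.isin(seq, [_G, _C])
    return float(gc[ok].sum() / ok.sum())


def bin_by_occupancy(
    n147: pd.DataFrame,
    track: dict[str, np.ndarray] | None = None,
    n_bins: int = 5,
    key: str = "coverage",
    genome=None,
) -> np.ndarray:
    """Rank n147 regions by summed coverage (or GC of bases 6..141) and
    split into ``n_bins`` near-equal groups (sizes differing by <= 1).

    Ties are broken by genomic order.  Returns an integer bin label per
    input row (0 = lowest key values).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(n147) < n_bins:
        raise ValueError("fewer n147 regions than bins")
    if key == "coverage":
        if track is None:
            raise ValueError("coverage binning needs an occupancy track")
        vals = np.array(
            [track[c][s:e].sum() for c, s, e in
             zip(n147["chrom"], n147["start"], n147["end"])],
            dtype=float,
        )
    elif key == "gc":
        if genome is None:
            raise ValueError("gc binning needs the genome")
        vals = np.array(
            [gc_fraction(genome, c, s, e) for c, s, e in
             zip(n147["chrom"], n147["start"], n147["end"])]
        )
    else:
        raise ValueError(f"unknown binning key {key!r}")
    order = np.lexsort(
        (n147["start"].to_numpy(), n147["chrom"].to_numpy(), vals)
    )
    labels = np.empty(len(n147), dtype=np.int64)
    chunks = np.array_split(order, n_bins)
    for b, chunk in enumerate(chunks):
        labels[chunk] = b
    return labels
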