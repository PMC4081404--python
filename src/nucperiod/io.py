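"""Readers for the tabular input formats (BED, GFF3, site and SNP tables).

Everything is converted to 0-based half-open intervals on read; GFF3
coordinates (1-based closed) are shifted accordingly.
"""

from __future__ import annotations

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, class_column: bool = False) -> pd.DataFrame:
    """Read a BED3+ file; with ``class_column`` the 4th column is the
    region class label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[6:])
    if class_column:
        if df.shape[1] < 4:
            raise ValueError("annotation BED needs a 4th (class) column")
        df = df.rename(columns={"name": "region_class"})
    df["length"] = df["end"] - df["start"]
    return df


def read_gff_annotation(path, class_features=("intron", "intergenic_region")) -> pd.DataFrame:
    """Extract region-class intervals from a GFF3 file.

    Feature types listed in ``class_features`` become region classes
    (``intron`` -> intronic, ``intergenic_region`` -> intergenic; other
    types pass through as their own label).
    """
    rename = {"intron": "intronic", "intergenic_region": "intergenic"}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 5 or f[2] not in class_features:
                continue
            rows.append((f[0], int(f[3]) - 1, int(f[4]), rename.get(f[2], f[2])))
    if not rows:
        raise ValueError(f"no {class_features} features found in {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_class"])


def read_site_table(path) -> pd.DataFrame:
    """Four-species per-site base table: chrom, pos, focal, sib, out1, out2."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "focal", "sib", "out1", "out2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df


def read_snp_table(path) -> pd.DataFrame:
    """SNP records: chrom, pos, ancestral, derived, i, n [, strain_allele]."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ancestral", "derived", "i", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    bad = (df["i"] < 1) | (df["i"] > df["n"] - 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} SNP records violate 1 <= i <= n-1")
    return df
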