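"""In-memory genome sequences with FASTA round-trip.

Sequences are held as uint8 arrays of ASCII codes (A/C/G/T/N, upper case).
All coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import io
from collections.abc import Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

A, C, G, T, N = (ord(b) for b in "ACGTN")
BASES = np.array([A, C, G, T], dtype=np.uint8)

# ASCII complement lookup; anything unrecognised maps to N.
COMPLEMENT = np.full(256, N, dtype=np.uint8)
for _x, _y in [(A, T), (C, G), (G, C), (T, A), (N, N)]:
    COMPLEMENT[_x] = _y
for _x, _y in zip(b"acgtn", b"TGCAN"):
    COMPLEMENT[_x] = _y


def encode(seq: str) -> np.ndarray:
    """Encode a string sequence as an upper-case ASCII uint8 array."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr[::-1]]


class Genome(Mapping):
    """A mapping of chromosome name -> uint8 ASCII sequence array."""

    def __init__(self, chroms: dict[str, np.ndarray]):
        self._chroms = {k: np.asarray(v, dtype=np.uint8) for k, v in chroms.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._chroms.items()}

    def fetch(self, chrom: str, start: int, end: int, pad: bool = True) -> np.ndarray:
        """Sequence for [start, end); out-of-range positions padded with N.

        With ``pad=False`` out-of-range coordinates raise IndexError instead.
        """
        seq = self._chroms[chrom]
        if start >= 0 and end <= len(seq):
            return seq[start:end]
        if not pad:
            raise IndexError(f"{chrom}:{start}-{end} outside contig of length {len(seq)}")
        out = np.full(end - start, N, dtype=np.uint8)
        lo, hi = max(start, 0), min(end, len(seq))
        if hi > lo:
            out[lo - start : hi - start] = seq[lo:hi]
        return out

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        chroms = {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(decode(arr)), id=name, description="")
            for name, arr in self._chroms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def to_fasta_str(self) -> str:
        buf = io.StringIO()
        records = [
            SeqRecord(Seq(decode(arr)), id=name, description="")
            for name, arr in self._chroms.items()
        ]
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()
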