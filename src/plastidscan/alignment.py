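"""Multiple-sequence-alignment container.

Rows are stored as a (taxa x columns) uint8 matrix of ASCII codes over
``A C G T N -``; ambiguity codes other than N are mapped to N on load.  A
designated reference row defines the mapping between alignment columns and
ungapped reference coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Alignment", "GAP", "NBYTE"]

GAP = ord("-")
NBYTE = ord("N")
_VALID = frozenset(b"ACGTN-")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN-", dtype=np.uint8))
    arr[bad] = NBYTE
    return arr


@dataclass
class Alignment:
    """Equal-length gapped rows with a reference taxon."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_cols) uint8
    ref_taxon: str = ""

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if not self.ref_taxon and self.taxa:
            self.ref_taxon = self.taxa[0]
        if self.ref_taxon not in self.taxa:
            raise ValueError(f"reference taxon {self.ref_taxon!r} not in alignment")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sequences(cls, named_seqs: dict[str, str], ref_taxon: str = "") -> "Alignment":
        taxa = list(named_seqs)
        lengths = {len(s) for s in named_seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        mat = np.vstack([_encode(named_seqs[t]) for t in taxa]) if taxa else np.zeros((0, 0), np.uint8)
        return cls(taxa=taxa, matrix=mat, ref_taxon=ref_taxon)

    @classmethod
    def from_fasta(cls, path, ref_taxon: str = "") -> "Alignment":
        from Bio import SeqIO

        named = {}
        for sr in SeqIO.parse(str(path), "fasta"):
            named[sr.id] = str(sr.seq)
        if not named:
            raise ValueError(f"{path}: empty alignment file")
        return cls.from_sequences(named, ref_taxon=ref_taxon)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n")
                row = self.matrix[i].tobytes().decode("ascii")
                for j in range(0, len(row), 70):
                    fh.write(row[j : j + 70] + "\n")

    # -- basic access ------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)].tobytes().decode("ascii")

    def ungapped(self, taxon: str) -> str:
        r = self.matrix[self.taxa.index(taxon)]
        return r[r != GAP].tobytes().decode("ascii")

    @property
    def ref_row(self) -> np.ndarray:
        return self.matrix[self.taxa.index(self.ref_taxon)]

    # -- coordinate maps ---------------------------------------------------
    def ref_coord_of_col(self) -> np.ndarray:
        """For each column, the 0-based reference coordinate of its base,
        or -1 where the reference is gapped."""
        nongap = self.ref_row != GAP
        coord = np.cumsum(nongap) - 1
        out = np.where(nongap, coord, -1)
        return out.astype(np.int64)

    def col_of_ref_coord(self) -> np.ndarray:
        """For each reference coordinate, its alignment column."""
        return np.nonzero(self.ref_row != GAP)[0]

    # -- derived alignments ------------------------------------------------
    def subset(self, taxa: list[str], strip_gap_only: bool = True, ref_taxon: str = "") -> "Alignment":
        """Row subset, optionally removing columns gapped in every kept row."""
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise ValueError(f"taxa not in alignment: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        mat = self.matrix[idx]
        if strip_gap_only and mat.size:
            keep = ~(mat == GAP).all(axis=0)
            mat = mat[:, keep]
        ref = ref_taxon or (self.ref_taxon if self.ref_taxon in taxa else taxa[0])
        return Alignment(taxa=list(taxa), matrix=mat.copy(), ref_taxon=ref)

    def slice_cols(self, start: int, end: int) -> "Alignment":
        return Alignment(
            taxa=list(self.taxa),
            matrix=self.matrix[:, start:end].copy(),
            ref_taxon=self.ref_taxon,
        )

    def concat(self, other: "Alignment") -> "Alignment":
        if self.taxa != other.taxa:
            raise ValueError("cannot concatenate alignments with different taxa")
        return Alignment(
            taxa=list(self.taxa),
            matrix=np.hstack([self.matrix, other.matrix]),
            ref_taxon=self.ref_taxon,
        )
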