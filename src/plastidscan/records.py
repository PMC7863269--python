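"""Core domain types for annotated plastomes.

A chloroplast genome is modelled as a circular DNA sequence with gene
features, partitioned into the canonical quadripartite layout: a large
single-copy region (LSC), a small single-copy region (SSC), and two
inverted repeats (IRb/IRa) whose sequences are exact reverse complements.
Coordinates are 0-based, half-open throughout; 1-based inclusive numbers
appear only in human-readable reports.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "revcomp",
    "gc_fraction",
    "GeneFeature",
    "PlastomeRecord",
    "QuadripartiteStructure",
    "GenomeSummary",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PROTEIN_CODING = "protein_coding"
TRNA = "tRNA"
RRNA = "rRNA"
FEATURE_KINDS = (PROTEIN_CODING, TRNA, RRNA)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC content over unambiguous bases; N is excluded from the denominator."""
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    a = seq.count("A") + seq.count("a")
    t = seq.count("T") + seq.count("t")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (g + c) / denom


@dataclass(frozen=True)
class GeneFeature:
    """One gene with an ordered list of exonic parts.

    ``parts`` holds ``(start, end, strand)`` intervals, 0-based half-open,
    ordered along the genome; the gaps between consecutive parts are the
    gene's introns.  ``copy_tag`` marks which IR copy a duplicated gene
    belongs to (e.g. ``"IRa"``); the empty string means a single-copy gene
    or the IRb copy.
    """

    gene_name: str
    kind: str
    parts: tuple[tuple[int, int, int], ...]
    copy_tag: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise ValueError(f"gene {self.gene_name}: no parts")
        for s, e, strand in self.parts:
            if e <= s:
                raise ValueError(f"gene {self.gene_name}: empty part ({s},{e})")
            if strand not in (1, -1):
                raise ValueError(f"gene {self.gene_name}: bad strand {strand}")
        starts = [p[0] for p in self.parts]
        ends = [p[1] for p in self.parts]
        for i in range(1, len(self.parts)):
            if starts[i] < ends[i - 1]:
                raise ValueError(f"gene {self.gene_name}: overlapping/unordered parts")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first part start to last part end."""
        return self.parts[0][0], self.parts[-1][1]

    @property
    def strand(self) -> int:
        return self.parts[0][2]

    @property
    def has_intron(self) -> bool:
        return len(self.parts) > 1

    def shifted(self, delta: int, length: int) -> "GeneFeature":
        """Feature with all coordinates shifted by ``delta`` modulo ``length``.

        A part that would wrap the origin after the shift is split in two.
        """
        new_parts: list[tuple[int, int, int]] = []
        for s, e, strand in self.parts:
            ns, ne = (s + delta) % length, (e + delta) % length
            if ns < ne or ne == 0:
                new_parts.append((ns, ne if ne else length, strand))
            else:  # wraps the origin
                new_parts.append((ns, length, strand))
                new_parts.append((0, ne, strand))
        new_parts.sort()
        return replace(self, parts=tuple(new_parts))


@dataclass
class PlastomeRecord:
    """One genome: circular uppercase sequence plus gene features."""

    taxon_id: str
    sequence: str
    accession: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.taxon_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.taxon_id}: non-ACGTN characters {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e, _ in f.parts:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"{self.taxon_id}: feature {f.gene_name} part ({s},{e}) "
                        f"outside [0,{n})"
                    )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals on the canonical orientation.

    Canonical orientation: the genome starts at the LSC start and the SSC
    immediately follows IRb, so the four intervals tile
    ``[0, genome_length)`` in the order LSC, IRb, SSC, IRa.
    ``rotation`` records the offset (bases) by which the source record must
    be rotated left to reach this frame; 0 means the record is already
    canonical.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    rotation: int = 0

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def genome_length(self) -> int:
        return self.ira[1]

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    def region_of(self, position: int) -> str:
        """Region label (``LSC``/``SSC``/``IR``) of a canonical-frame position."""
        if not 0 <= position < self.genome_length:
            raise ValueError(f"position {position} outside genome")
        if self.lsc[0] <= position < self.lsc[1]:
            return "LSC"
        if self.ssc[0] <= position < self.ssc[1]:
            return "SSC"
        return "IR"

    def region_intervals(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}


@dataclass(frozen=True)
class GenomeSummary:
    """Per-genome size, GC and gene-count statistics (one table row)."""

    taxon_id: str
    total_bp: int
    lsc_bp: int
    ir_bp: int
    ssc_bp: int
    gc_total: float
    gc_lsc: float
    gc_ir: float
    gc_ssc: float
    n_genes: int
    n_protein: int
    n_trna: int
    n_rrna: int

    def __post_init__(self) -> None:
        if self.n_genes != self.n_protein + self.n_trna + self.n_rrna:
            raise ValueError("gene counts do not cross-foot")
        for gc in (self.gc_total, self.gc_lsc, self.gc_ir, self.gc_ssc):
            if not 0.0 <= gc <= 1.0:
                raise ValueError("GC fraction outside [0,1]")
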