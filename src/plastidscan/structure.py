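"""Quadripartite structure delimitation and per-genome summaries.

The inverted-repeat pair of a plastome is found as the longest exact
inverted repeat: k-mer seeds between the (doubled, to honour circularity)
sequence and its reverse complement are extended ungapped, and the maximal
pair partitions the circle into four arcs.  The longer single-copy arc is
the LSC.  Exact matching is sufficient for plastome IRs, which are long and
kept identical by concerted evolution, and it makes the mirror invariant
``revcomp(IRb) == IRa`` testable byte-for-byte.
"""
from __future__ import annotations

import warnings
from collections import defaultdict

from .records import (
    GeneFeature,
    GenomeSummary,
    PlastomeRecord,
    QuadripartiteStructure,
    gc_fraction,
    revcomp,
)

__all__ = [
    "StructureNotFoundError",
    "AmbiguousStructureError",
    "detect_quadripartite",
    "canonicalize",
    "summarize_genome",
    "classify_position",
]


class StructureNotFoundError(ValueError):
    """No inverted repeat of the required minimum length exists."""


class AmbiguousStructureError(ValueError):
    """Several non-nested maximal IR pairs of equal length were found."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "ambiguous quadripartite structure; candidate IR pairs: "
            + ", ".join(f"({a},{b},len={m})" for a, b, m in candidates)
        )


def _max_ir_pairs(seq: str, min_ir: int, seed_k: int) -> list[tuple[int, int, int]]:
    """All maximal exact inverted-repeat pairs of maximal length >= min_ir.

    Returns deduplicated ``(start_a, start_b, length)`` triples with
    coordinates mod genome length, ``start_a < start_b``.
    """
    n = len(seq)
    s2 = seq + seq
    rc = revcomp(seq)
    k = seed_k

    # Index seed k-mers of the doubled sequence.
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, 2 * n - k + 1):
        index[s2[i : i + k]].append(i)

    # A hit rc[j:j+k] == s2[i:i+k] pairs s2[i:i+k] with revcomp of
    # seq[p:p+k], p = n-j-k.  For an inverted pair (a, b, m) the quantity
    # a+b+m is invariant under ungapped extension, so seeds are grouped by
    # that anti-diagonal and each group is extended once.
    diagonals: dict[int, tuple[int, int]] = {}
    for j in range(0, n - k + 1):
        kmer = rc[j : j + k]
        hits = index.get(kmer)
        if not hits:
            continue
        p = n - j - k
        for i in hits:
            diag = i + p + k
            if diag not in diagonals or i < diagonals[diag][0]:
                diagonals[diag] = (i, p)

    best: dict[tuple[int, int], int] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": None}
    for diag, (a, b) in diagonals.items():
        if a > b:
            a, b = b, a
        m = k
        # extend right end of copy A / left end of copy B
        while a + m < b and b > 0 and comp.get(s2[a + m]) == s2[b - 1]:
            m += 1
            b -= 1
        # extend left end of copy A / right end of copy B
        while a > 0 and b + m < 2 * n and comp.get(s2[a - 1]) == s2[b + m]:
            a -= 1
            m += 1
        if m < min_ir or a + m > b:
            continue
        key = (min(a % n, b % n), max(a % n, b % n))
        if m > best.get(key, 0):
            best[key] = m

    if not best:
        return []
    top = max(best.values())
    return sorted((a, b, m) for (a, b), m in best.items() if m == top)


def detect_quadripartite(
    record: PlastomeRecord, min_ir: int = 10_000, seed_k: int = 25
) -> QuadripartiteStructure:
    """Delimit LSC/IRb/SSC/IRa on the canonical orientation.

    The sequence is treated as circular; the returned intervals live on the
    canonical frame (LSC starts at 0, SSC follows IRb) and ``rotation``
    records the left-rotation taking the input record to that frame.

    Raises
    ------
    StructureNotFoundError
        if no exact inverted repeat of length >= ``min_ir`` exists.
    AmbiguousStructureError
        if several non-nested maximal pairs of equal length exist.
    """
    n = record.length_bp
    if n <= 2 * min_ir:
        raise StructureNotFoundError(
            f"{record.taxon_id}: genome ({n} bp) not longer than 2*min_ir"
        )
    pairs = _max_ir_pairs(record.sequence, min_ir, seed_k)
    if not pairs:
        raise StructureNotFoundError(
            f"{record.taxon_id}: no inverted repeat >= {min_ir} bp"
        )
    if len(pairs) > 1:
        raise AmbiguousStructureError(pairs)
    a, b, m = pairs[0]

    arc_ab = (b - (a + m)) % n  # arc from end of copy at a to start of copy at b
    arc_ba = (a - (b + m)) % n  # arc from end of copy at b back to copy at a
    if arc_ab == arc_ba:
        raise AmbiguousStructureError(pairs)
    if arc_ab > arc_ba:
        lsc_len, ssc_len = arc_ab, arc_ba
        lsc_start, irb_start = (a + m) % n, b
    else:
        lsc_len, ssc_len = arc_ba, arc_ab
        lsc_start, irb_start = (b + m) % n, a

    rotation = lsc_start
    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + m)
    ssc = (lsc_len + m, lsc_len + m + ssc_len)
    ira = (lsc_len + m + ssc_len, n)
    assert ira[1] - ira[0] == m
    return QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira, rotation=rotation)


def canonicalize(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Rotate a record (sequence and features) into the canonical frame."""
    n = record.length_bp
    if structure.genome_length != n:
        raise ValueError("structure does not belong to this record")
    r = structure.rotation % n
    if r == 0:
        return record, structure
    seq = record.sequence[r:] + record.sequence[:r]
    feats = [f.shifted(-r, n) for f in record.features]
    rec = PlastomeRecord(
        taxon_id=record.taxon_id,
        sequence=seq,
        accession=record.accession,
        features=feats,
    )
    struct = QuadripartiteStructure(
        lsc=structure.lsc,
        irb=structure.irb,
        ssc=structure.ssc,
        ira=structure.ira,
        rotation=0,
    )
    return rec, struct


def _counted_features(
    features: list[GeneFeature], structure: QuadripartiteStructure
) -> list[GeneFeature]:
    """Features that enter gene counts: IRa-resident duplicates suppressed.

    A gene whose whole span lies inside IRa is treated as the second copy of
    an IR-duplicated gene and excluded, so each duplicated gene is counted
    once (the convention under which a typical plastome has 113 genes).
    """
    s, e = structure.ira
    kept = []
    for f in features:
        fs, fe = f.span
        if f.copy_tag == "IRa" or (s <= fs and fe <= e):
            continue
        kept.append(f)
    return kept


def summarize_genome(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> GenomeSummary:
    """Size, per-region GC, and de-duplicated gene counts for one genome.

    GC uses (G+C)/(A+C+G+T); N never enters the denominator.  The record
    must already be on the canonical orientation of ``structure``.
    """
    if structure.genome_length != record.length_bp:
        raise ValueError("structure/record length mismatch")
    seq = record.sequence
    lsc_seq = seq[slice(*structure.lsc)]
    ssc_seq = seq[slice(*structure.ssc)]
    ir_seq = seq[slice(*structure.irb)] + seq[slice(*structure.ira)]
    counted = _counted_features(record.features, structure)
    kinds = [f.kind for f in counted]
    return GenomeSummary(
        taxon_id=record.taxon_id,
        total_bp=record.length_bp,
        lsc_bp=structure.lsc_length,
        ir_bp=structure.ir_length,
        ssc_bp=structure.ssc_length,
        gc_total=gc_fraction(seq),
        gc_lsc=gc_fraction(lsc_seq),
        gc_ir=gc_fraction(ir_seq),
        gc_ssc=gc_fraction(ssc_seq),
        n_genes=len(counted),
        n_protein=kinds.count("protein_coding"),
        n_trna=kinds.count("tRNA"),
        n_rrna=kinds.count("rRNA"),
    )


def classify_position(
    structure: QuadripartiteStructure,
    features: list[GeneFeature],
    position: int,
) -> tuple[str, str, str]:
    """Genic context and region of one canonical-frame position.

    Returns ``(context, region, locus_name)`` where context is one of
    ``exon``/``intron``/``intergenic_spacer``.  Exon beats intron beats
    spacer when features overlap.  Spacer loci are named by their flanking
    genes (circular scan), e.g. ``"trnT-trnL"``.
    """
    n = structure.genome_length
    if not 0 <= position < n:
        raise ValueError(f"position {position} outside [0,{n})")
    region = structure.region_of(position)

    intron_hit: str | None = None
    for f in features:
        s, e = f.span
        if s <= position < e:
            for ps, pe, _ in f.parts:
                if ps <= position < pe:
                    return "exon", region, f.gene_name
            if intron_hit is None:
                intron_hit = f.gene_name
    if intron_hit is not None:
        return "intron", region, intron_hit

    # spacer: nearest feature end at/before and nearest start after, circularly
    best_left, left_name = None, ""
    best_right, right_name = None, ""
    for f in features:
        s, e = f.span
        dl = (position - e) % n  # distance back to the gene's end
        dr = (s - position) % n  # distance forward to the gene's start
        if best_left is None or dl < best_left:
            best_left, left_name = dl, f.gene_name
        if best_right is None or dr < best_right:
            best_right, right_name = dr, f.gene_name
    if best_left is None:
        return "intergenic_spacer", region, ""
    return "intergenic_spacer", region, f"{left_name}-{right_name}"


def write_summary_tsv(summaries: list[GenomeSummary], path) -> None:
    """Write a per-genome summary table (percentages as printed figures)."""
    import pandas as pd

    rows = []
    for s in summaries:
        rows.append(
            {
                "taxon": s.taxon_id,
                "total_bp": s.total_bp,
                "lsc_bp": s.lsc_bp,
                "ir_bp": s.ir_bp,
                "ssc_bp": s.ssc_bp,
                "gc_total_pct": round(100 * s.gc_total, 2),
                "gc_lsc_pct": round(100 * s.gc_lsc, 2),
                "gc_ir_pct": round(100 * s.gc_ir, 2),
                "gc_ssc_pct": round(100 * s.gc_ssc, 2),
                "n_genes": s.n_genes,
                "n_protein": s.n_protein,
                "n_trna": s.n_trna,
                "n_rrna": s.n_rrna,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
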