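"""Perfect microsatellite (SSR) detection and tabulation.

An SSR is a maximal perfect tandem repeat of a primitive 1-6 bp motif whose
whole-unit copy number meets a per-motif-length minimum (defaults
10/5/4/3/3/3 for mono- through hexanucleotides, the thresholds commonly
used for plastome scans).  Runs are reported at their leftmost phase; a run
reportable under two motif lengths is reported once, under the shortest
(primitive) motif, and a reported locus strictly contained in another
reported locus is suppressed.  N breaks runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .records import PlastomeRecord, QuadripartiteStructure, revcomp
from .structure import classify_position

__all__ = ["SSRThresholds", "SSRLocus", "find_ssrs", "annotate_ssrs", "tabulate_ssrs"]

_MOTIF_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum whole-unit repeat counts keyed by motif length 1..6."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    )

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("thresholds must cover motif lengths 1..6 exactly")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")

    def __getitem__(self, motif_len: int) -> int:
        return self.min_repeats[motif_len]


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat: ``sequence[start:end] == motif * repeat_count``."""

    motif: str
    repeat_count: int
    start: int
    end: int
    taxon_id: str = ""
    region: str = ""
    context: str = ""
    locus_name: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("locus span inconsistent with motif * count")

    @property
    def motif_class(self) -> str:
        return _MOTIF_CLASS[len(self.motif)]

    def canonical_motif(self) -> str:
        """Lexicographically smallest rotation over both strands."""
        rots = {self.motif[i:] + self.motif[:i] for i in range(len(self.motif))}
        rc = revcomp(self.motif)
        rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
        return min(rots)


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_ssrs(sequence: str, thresholds: SSRThresholds | None = None) -> list[SSRLocus]:
    """Scan a sequence for perfect SSRs meeting the thresholds.

    For each motif length m the maximal runs of period m are located via the
    self-match profile ``seq[i] == seq[i+m]``; each maximal run is truncated
    to whole motif copies from its leftmost phase.  Non-primitive motifs are
    skipped (the run is already reported under its shortest unit), and
    containment between loci of different motif lengths is resolved by
    dropping the contained locus.
    """
    if thresholds is None:
        thresholds = SSRThresholds()
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    for m in range(1, 7):
        if n < 2 * m:
            continue
        min_count = thresholds[m]
        i = 0
        run_start = None
        # match[j] for j in [0, n-m): seq[j] == seq[j+m], with N never matching
        for j in range(0, n - m + 1):
            ok = j < n - m and seq[j] == seq[j + m] and seq[j] != "N"
            if ok and run_start is None:
                run_start = j
            elif not ok and run_start is not None:
                total = (j - run_start) + m  # run of period m in [run_start, j+m)
                count = total // m
                if count >= min_count:
                    motif = seq[run_start : run_start + m]
                    if "N" not in motif and _is_primitive(motif):
                        loci.append(
                            SSRLocus(
                                motif=motif,
                                repeat_count=count,
                                start=run_start,
                                end=run_start + count * m,
                            )
                        )
                run_start = None
    # drop loci strictly contained in another reported locus
    kept: list[SSRLocus] = []
    for a in loci:
        contained = any(
            (b.start <= a.start and a.end <= b.end and (b.end - b.start) > (a.end - a.start))
            for b in loci
        )
        if not contained:
            kept.append(a)
    kept.sort(key=lambda l: (l.start, l.end, l.motif))
    return kept


def annotate_ssrs(
    loci: list[SSRLocus],
    record: PlastomeRecord,
    structure: QuadripartiteStructure,
) -> list[SSRLocus]:
    """Attach taxon, region and genic context (taken at the locus start)."""
    out = []
    for l in loci:
        if not 0 <= l.start < l.end <= record.length_bp:
            raise ValueError(f"locus {l.start}-{l.end} outside genome bounds")
        context, region, name = classify_position(structure, record.features, l.start)
        out.append(
            replace(l, taxon_id=record.taxon_id, region=region, context=context, locus_name=name)
        )
    return out


def _in_ira(locus: SSRLocus, structure: QuadripartiteStructure) -> bool:
    s, e = structure.ira
    return s <= locus.start and locus.end <= e


def tabulate_ssrs(
    loci_by_taxon: dict[str, list[SSRLocus]],
    structures: dict[str, QuadripartiteStructure] | None = None,
    dedup_ir: bool = False,
) -> pd.DataFrame:
    """Long-format count table: taxon x region x context x motif class.

    With ``dedup_ir`` the IRa copy of each duplicated locus is dropped so IR
    loci count once per genome; the default counts both IR copies.  Marginal
    totals are consistent by construction (the table is a partition of the
    locus set).
    """
    rows = []
    for taxon, loci in loci_by_taxon.items():
        for l in loci:
            if dedup_ir:
                if structures is None:
                    raise ValueError("dedup_ir requires structures")
                if _in_ira(l, structures[taxon]):
                    continue
            rows.append(
                {
                    "taxon": taxon,
                    "region": l.region,
                    "context": l.context,
                    "motif_class": l.motif_class,
                    "motif": l.motif,
                    "canonical_motif": l.canonical_motif(),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["taxon", "region", "context", "motif_class", "motif", "canonical_motif", "n"]
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["taxon", "region", "context", "motif_class", "motif", "canonical_motif"])
        .size()
        .rename("n")
        .reset_index()
    )


def ssr_locus_table(loci_by_taxon: dict[str, list[SSRLocus]]) -> pd.DataFrame:
    """Per-locus table suitable for TSV export."""
    rows = [
        {
            "taxon": l.taxon_id or taxon,
            "motif": l.motif,
            "repeat_count": l.repeat_count,
            "start": l.start,
            "end": l.end,
            "region": l.region,
            "context": l.context,
            "locus_name": l.locus_name,
        }
        for taxon, loci in loci_by_taxon.items()
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=["taxon", "motif", "repeat_count", "start", "end", "region", "context", "locus_name"],
    )
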