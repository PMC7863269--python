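"""Indel extraction from a whole-genome alignment, slippage classification,
spectra, and binary indel coding.

An event is a maximal run of gap-bearing alignment columns over which the
per-taxon gap pattern is constant; taxa sharing the identical span form one
multi-carrier event.  Polarity is expressed against the designated
reference row only: a run gapped in the reference is an insertion (carried
by the residue-bearing taxa), a run gapped in other taxa is a deletion.
Events are left-normalized on the ungapped reference, the indel-placement
convention used for VCF, so repeats cannot smear positions between runs.

An event is *SSR-related* (replication slippage) when its sequence is whole
copies of some unit u and the allele carrying more copies forms, together
with the adjacent sequence, a perfect tandem run meeting the SSR threshold
for |u|; everything else is non-SSR.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment
from .records import GeneFeature, QuadripartiteStructure
from .ssr import SSRThresholds
from .structure import classify_position

__all__ = [
    "IndelEvent",
    "IndelMatrix",
    "MalformedAlignmentError",
    "call_indels",
    "classify_indel",
    "annotate_indels",
    "indel_spectrum",
    "build_indel_matrix",
    "left_normalize",
]

SSR_RELATED = "SSR_related"
NON_SSR = "non_SSR"


class MalformedAlignmentError(ValueError):
    """The alignment contains an all-gap column run."""


@dataclass(frozen=True)
class IndelEvent:
    """One insertion/deletion event on reference coordinates.

    ``ref_pos`` is the reference coordinate of the base immediately left of
    the (left-normalized) event; -1 means the event precedes the first
    reference base.  ``carriers`` are the taxa whose state differs from the
    reference.
    """

    ref_pos: int
    length: int
    seq: str
    polarity: str  # "insertion" | "deletion" (relative to the reference)
    carriers: frozenset[str]
    klass: str = ""  # SSR_related | non_SSR, filled by classify_indel
    context: str = ""
    region: str = ""
    locus_name: str = ""

    def __post_init__(self) -> None:
        if self.length < 1 or len(self.seq) != self.length:
            raise ValueError("event length inconsistent with sequence")
        if self.polarity not in ("insertion", "deletion"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if not self.carriers:
            raise ValueError("event carried by no taxon")


@dataclass
class IndelMatrix:
    """Binary presence/absence coding: one character per indel fragment."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_events) of 0/1
    events: list[IndelEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix row count does not match taxa")


def left_normalize(
    ref_seq: str, start: int, seq: str, polarity: str
) -> tuple[int, str]:
    """Shift an event to its leftmost equivalent placement.

    ``start`` is the reference coordinate of the first event base (deletion)
    or of the reference base immediately right of the insertion point.
    Returns the normalized ``(start, seq)``.
    """
    L = len(seq)
    if polarity == "deletion":
        while start > 0 and ref_seq[start - 1] == ref_seq[start + L - 1]:
            start -= 1
        return start, ref_seq[start : start + L]
    while start > 0 and ref_seq[start - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        start -= 1
    return start, seq


def call_indels(alignment: Alignment) -> list[IndelEvent]:
    """Extract left-normalized indel events against the reference row."""
    mat = alignment.matrix
    n, L = mat.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    gaps = mat == GAP
    if bool(gaps.all(axis=0).any()):
        raise MalformedAlignmentError("alignment contains an all-gap column")
    ref_idx = alignment.taxa.index(alignment.ref_taxon)
    ref_seq = alignment.ungapped(alignment.ref_taxon)
    ref_nongap_cum = np.concatenate([[0], np.cumsum(mat[ref_idx] != GAP)])

    gap_cols = np.nonzero(gaps.any(axis=0))[0]
    events: list[IndelEvent] = []
    i = 0
    while i < len(gap_cols):
        c0 = gap_cols[i]
        pattern = gaps[:, c0]
        j = i + 1
        while (
            j < len(gap_cols)
            and gap_cols[j] == gap_cols[j - 1] + 1
            and np.array_equal(gaps[:, gap_cols[j]], pattern)
        ):
            j += 1
        c1 = gap_cols[j - 1] + 1
        events.append(
            _event_from_run(alignment, mat, pattern, ref_idx, ref_seq, ref_nongap_cum, c0, c1)
        )
        i = j
    events.sort(key=lambda e: (e.ref_pos, e.length, e.seq))
    return events


def _event_from_run(
    alignment: Alignment,
    mat: np.ndarray,
    pattern: np.ndarray,
    ref_idx: int,
    ref_seq: str,
    ref_nongap_cum: np.ndarray,
    c0: int,
    c1: int,
) -> IndelEvent:
    length = c1 - c0
    n_ref_left = int(ref_nongap_cum[c0])  # ref bases strictly left of the run
    if pattern[ref_idx]:  # reference gapped -> insertion in the other taxa
        carriers = [alignment.taxa[k] for k in range(mat.shape[0]) if not pattern[k]]
        first = alignment.taxa.index(carriers[0])
        seq = mat[first, c0:c1].tobytes().decode("ascii")
        start, seq = left_normalize(ref_seq, n_ref_left, seq, "insertion")
        return IndelEvent(
            ref_pos=start - 1,
            length=length,
            seq=seq,
            polarity="insertion",
            carriers=frozenset(carriers),
        )
    carriers = [alignment.taxa[k] for k in range(mat.shape[0]) if pattern[k]]
    start, seq = left_normalize(ref_seq, n_ref_left, ref_seq[n_ref_left : n_ref_left + length], "deletion")
    return IndelEvent(
        ref_pos=start - 1,
        length=length,
        seq=seq,
        polarity="deletion",
        carriers=frozenset(carriers),
    )


def _unit_lengths(L: int) -> list[int]:
    return [u for u in range(1, 7) if L % u == 0]


def classify_indel(
    event: IndelEvent,
    ref_seq: str,
    thresholds: SSRThresholds | None = None,
) -> IndelEvent:
    """Label an event SSR-related or non-SSR (slippage test on the longer allele)."""
    if thresholds is None:
        thresholds = SSRThresholds()
    s = event.seq
    L = event.length
    p = event.ref_pos + 1
    if event.polarity == "deletion":
        allele = ref_seq
        e0 = p
    else:
        allele = ref_seq[:p] + s + ref_seq[p:]
        e0 = p
    e1 = e0 + L
    for u in _unit_lengths(L):
        unit = s[:u]
        if "N" in unit or s != unit * (L // u):
            continue
        copies = L // u
        i = e0 - u
        while i >= 0 and allele[i : i + u] == unit:
            copies += 1
            i -= u
        j = e1
        while j + u <= len(allele) and allele[j : j + u] == unit:
            copies += 1
            j += u
        if copies >= thresholds[u]:
            return replace(event, klass=SSR_RELATED)
    return replace(event, klass=NON_SSR)


def annotate_indels(
    events: list[IndelEvent],
    structure: QuadripartiteStructure,
    ref_features: list[GeneFeature],
) -> list[IndelEvent]:
    """Attach region and genic context from the reference annotation.

    Deletions are classified at their first deleted reference base,
    insertions at the flanking base left of the insertion point.  The
    reference record must be on the canonical orientation of ``structure``.
    """
    out = []
    for e in events:
        pos = e.ref_pos + 1 if e.polarity == "deletion" else max(e.ref_pos, 0)
        pos = min(pos, structure.genome_length - 1)
        context, region, name = classify_position(structure, ref_features, pos)
        out.append(replace(e, context=context, region=region, locus_name=name))
    return out


def indel_spectrum(events: list[IndelEvent]) -> dict[str, pd.DataFrame]:
    """Size histogram by class, context table, and the largest event."""
    if not events:
        empty = pd.DataFrame()
        return {"by_size": empty, "by_context": empty, "largest": empty}
    df = pd.DataFrame(
        {
            "ref_pos": [e.ref_pos for e in events],
            "length": [e.length for e in events],
            "polarity": [e.polarity for e in events],
            "klass": [e.klass for e in events],
            "context": [e.context for e in events],
            "locus_name": [e.locus_name for e in events],
            "n_carriers": [len(e.carriers) for e in events],
            "carriers": [",".join(sorted(e.carriers)) for e in events],
        }
    )
    by_size = df.groupby(["klass", "length"]).size().rename("n").reset_index()
    by_context = df.groupby(["klass", "context"]).size().rename("n").reset_index()
    largest = df.sort_values(["length", "ref_pos"], ascending=[False, True]).head(1)
    return {"by_size": by_size, "by_context": by_context, "largest": largest, "events": df}


def build_indel_matrix(events: list[IndelEvent], taxa: list[str], ref_taxon: str) -> IndelMatrix:
    """Simple indel coding: fragment presence/absence, one binary character
    per event; constant characters are dropped."""
    if not events:
        raise ValueError("no events to code")
    cols = []
    kept_events = []
    for e in events:
        if e.polarity == "deletion":
            present = {t for t in taxa if t not in e.carriers}
        else:
            present = set(e.carriers)
        col = np.array([1 if t in present else 0 for t in taxa], dtype=np.int8)
        if col.min() == col.max():
            continue
        cols.append(col)
        kept_events.append(e)
    if not cols:
        raise ValueError("all indel characters are constant")
    return IndelMatrix(taxa=list(taxa), matrix=np.column_stack(cols), events=kept_events)


def indel_table(events: list[IndelEvent]) -> pd.DataFrame:
    """Flat per-event table (1-based positions for human consumption)."""
    return pd.DataFrame(
        {
            "ref_pos_1based": [e.ref_pos + 2 if e.polarity == "deletion" else e.ref_pos + 1 for e in events],
            "polarity": [e.polarity for e in events],
            "length": [e.length for e in events],
            "seq": [e.seq if e.length <= 50 else e.seq[:47] + "..." for e in events],
            "klass": [e.klass for e in events],
            "region": [e.region for e in events],
            "context": [e.context for e in events],
            "locus_name": [e.locus_name for e in events],
            "carriers": [",".join(sorted(e.carriers)) for e in events],
        }
    )
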