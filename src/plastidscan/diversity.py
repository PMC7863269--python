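"""Site classification, nucleotide diversity, sliding windows, markers.

Nucleotide diversity follows the complete-deletion convention: a column
enters the computation only if every row carries an unambiguous base (no
gap, no N).  With n rows and L such columns,

    pi = (1 / C(n,2)) * sum_{i<j} d_ij / L

where d_ij counts pairwise differences over the valid columns.  Site-count
percentages, in contrast, are quoted against the full aligned length, the
way comparative plastome tables usually print them.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, NBYTE, Alignment
from .records import GeneFeature

__all__ = [
    "SiteCounts",
    "WindowDiversity",
    "UndefinedPiError",
    "classify_sites",
    "nucleotide_diversity",
    "sliding_window_pi",
    "extract_marker",
    "marker_report",
]


class UndefinedPiError(ValueError):
    """pi is undefined because no gap- and N-free column exists."""


@dataclass(frozen=True)
class SiteCounts:
    """Variable / parsimony-informative site tallies for one alignment."""

    aligned_length: int
    valid_sites: int
    variable_sites: int
    informative_sites: int

    def __post_init__(self) -> None:
        if not (
            self.informative_sites
            <= self.variable_sites
            <= self.valid_sites
            <= self.aligned_length
        ):
            raise ValueError("site counts violate ordering invariant")

    @property
    def pct_variable(self) -> float:
        return 100.0 * self.variable_sites / self.aligned_length if self.aligned_length else 0.0

    @property
    def pct_informative(self) -> float:
        return 100.0 * self.informative_sites / self.aligned_length if self.aligned_length else 0.0


@dataclass(frozen=True)
class WindowDiversity:
    """One sliding window: ``pi`` is None where no valid site exists."""

    window_start: int
    window_end: int
    pi: float | None
    valid_sites: int
    partial: bool = False

    @property
    def midpoint(self) -> float:
        return (self.window_start + self.window_end) / 2.0


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    return ~((mat == GAP) | (mat == NBYTE)).any(axis=0)


def _pair_diff_per_col(mat: np.ndarray) -> np.ndarray:
    """Number of differing pairs at each column (meaningful on valid cols)."""
    n, L = mat.shape
    diffs = np.zeros(L, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            diffs += mat[i] != mat[j]
    return diffs


def classify_sites(alignment: Alignment) -> SiteCounts:
    """Count valid, variable and parsimony-informative columns.

    A column is valid if it carries no gap and no N; variable if at least
    two distinct bases occur; parsimony-informative if at least two distinct
    bases each occur in at least two rows.
    """
    mat = alignment.matrix
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    valid = _valid_mask(mat)
    vcols = mat[:, valid]
    variable = 0
    informative = 0
    if vcols.size:
        counts = np.stack([(vcols == b).sum(axis=0) for b in b"ACGT"])  # (4, L)
        n_states = (counts > 0).sum(axis=0)
        n_states_ge2 = (counts >= 2).sum(axis=0)
        variable = int((n_states >= 2).sum())
        informative = int((n_states_ge2 >= 2).sum())
    return SiteCounts(
        aligned_length=mat.shape[1],
        valid_sites=int(valid.sum()),
        variable_sites=variable,
        informative_sites=informative,
    )


def nucleotide_diversity(alignment: Alignment) -> float:
    """Average pairwise difference per valid site (complete deletion)."""
    mat = alignment.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    valid = _valid_mask(mat)
    L = int(valid.sum())
    if L == 0:
        raise UndefinedPiError("no gap- and N-free columns")
    diffs = _pair_diff_per_col(mat[:, valid])
    npairs = n * (n - 1) // 2
    return float(diffs.sum()) / (npairs * L)


def sliding_window_pi(
    alignment: Alignment,
    window: int = 600,
    step: int = 100,
    include_partial: bool = False,
) -> list[WindowDiversity]:
    """Windowed pi over alignment columns.

    Windows start at 0 and advance by ``step``; pi is computed with complete
    deletion inside each window.  A trailing partial window is emitted only
    when ``include_partial`` is set and at least half the window length
    remains (it is flagged ``partial``).
    """
    if window <= 0 or step <= 0 or window < step:
        raise ValueError("require window >= step > 0")
    mat = alignment.matrix
    n, L = mat.shape
    if L < window:
        raise ValueError(f"alignment length {L} shorter than window {window}")
    valid = _valid_mask(mat)
    diffs = _pair_diff_per_col(mat) * valid
    cum_valid = np.concatenate([[0], np.cumsum(valid)])
    cum_diffs = np.concatenate([[0], np.cumsum(diffs)])
    npairs = n * (n - 1) // 2

    out: list[WindowDiversity] = []
    start = 0
    while start + window <= L:
        out.append(_window(cum_valid, cum_diffs, npairs, start, start + window, False))
        start += step
    if include_partial and start < L and (L - start) >= window / 2:
        out.append(_window(cum_valid, cum_diffs, npairs, start, L, True))
    return out


def _window(cum_valid, cum_diffs, npairs, s, e, partial) -> WindowDiversity:
    nvalid = int(cum_valid[e] - cum_valid[s])
    if nvalid == 0:
        pi = None
    else:
        pi = float(cum_diffs[e] - cum_diffs[s]) / (npairs * nvalid)
    return WindowDiversity(window_start=s, window_end=e, pi=pi, valid_sites=nvalid, partial=partial)


def rank_hotspots(windows: list[WindowDiversity], top: int = 10) -> list[WindowDiversity]:
    """Windows sorted by decreasing pi (undefined-pi windows excluded)."""
    scored = [w for w in windows if w.pi is not None]
    return sorted(scored, key=lambda w: (-w.pi, w.window_start))[:top]


def _marker_ref_interval(
    anchors: list[str], features: list[GeneFeature]
) -> tuple[int, int]:
    """Reference interval of a marker given anchor gene names.

    One anchor: the gene's own span.  Several anchors: from the end of the
    first gene to the start of the last (the intergenic spacer for two
    adjacent genes; a composite spacer+gene span for three or more).
    Strand-agnostic: intervals are genomic spans.
    """
    by_name: dict[str, GeneFeature] = {}
    for f in features:
        if f.copy_tag:  # use the single-copy / IRb instance for anchoring
            continue
        by_name.setdefault(f.gene_name, f)
    missing = [a for a in anchors if a not in by_name]
    if missing:
        raise KeyError(f"anchor gene(s) not in reference annotation: {missing}")
    if len(anchors) == 1:
        return by_name[anchors[0]].span
    first, last = by_name[anchors[0]], by_name[anchors[-1]]
    s = first.span[1]
    e = last.span[0]
    if e < s:
        s, e = last.span[1], first.span[0]
    if e <= s:
        raise ValueError(f"anchors {anchors} delimit an empty interval")
    return s, e


def extract_marker(
    alignment: Alignment,
    ref_features: list[GeneFeature],
    anchors: list[str],
) -> Alignment:
    """Sub-alignment spanning a marker, mapped through the reference row."""
    s, e = _marker_ref_interval(anchors, ref_features)
    cols = alignment.col_of_ref_coord()
    if e > len(cols):
        raise ValueError("marker interval exceeds ungapped reference length")
    c0 = int(cols[s])
    c1 = int(cols[e - 1]) + 1
    return alignment.slice_cols(c0, c1)


def marker_report(markers: dict[str, Alignment], concatenate: bool = True) -> pd.DataFrame:
    """Per-marker variability table (plus a concatenated row).

    Columns mirror the usual barcode-evaluation layout: aligned length,
    variable sites (n, % of aligned length), informative sites (n, %), pi.
    """
    rows = []

    def _row(name: str, aln: Alignment) -> dict:
        sc = classify_sites(aln)
        try:
            pi = nucleotide_diversity(aln)
        except UndefinedPiError:
            pi = float("nan")
        return {
            "marker": name,
            "length": sc.aligned_length,
            "variable_sites": sc.variable_sites,
            "pct_variable": round(sc.pct_variable, 2),
            "informative_sites": sc.informative_sites,
            "pct_informative": round(sc.pct_informative, 2),
            "pi": round(pi, 5),
        }

    for name, aln in markers.items():
        rows.append(_row(name, aln))
    if concatenate and len(markers) > 1:
        alns = list(markers.values())
        combined = alns[0]
        for a in alns[1:]:
            combined = combined.concat(a)
        rows.append(_row("+".join(markers), combined))
    return pd.DataFrame(rows)
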