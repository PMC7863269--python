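"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with naive
algorithms (quadratic scans, graph shortest paths) and share no code with
the implementation they check.
"""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def _primitive(motif: str) -> bool:
    m = len(motif)
    return not any(m % d == 0 and motif == motif[:d] * (m // d) for d in range(1, m))


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[int, int, str]]:
    """All maximal primitive perfect tandem runs meeting the thresholds,
    reported at leftmost phase and truncated to whole units, with contained
    loci suppressed.  Returns {(start, end, motif)}."""
    seq = seq.upper()
    n = len(seq)
    runs: list[tuple[int, int, str]] = []
    for m in range(1, 7):
        for i in range(n - m):
            if i > 0 and seq[i - 1] == seq[i - 1 + m] and seq[i - 1] != "N":
                continue  # not the leftmost start of this period-m run
            j = i
            while j < n - m and seq[j] == seq[j + m] and seq[j] != "N":
                j += 1
            if j == i:
                continue
            count = (j - i + m) // m
            motif = seq[i : i + m]
            if count >= thresholds[m] and "N" not in motif and _primitive(motif):
                runs.append((i, i + count * m, motif))
    kept = set()
    for a in runs:
        if not any(
            b[0] <= a[0] and a[1] <= b[1] and (b[1] - b[0]) > (a[1] - a[0])
            for b in runs
        ):
            kept.add(a)
    return kept


def pairwise_pi(rows: list[str]) -> float:
    """Nucleotide diversity recomputed from its definition (complete deletion)."""
    L = len(rows[0])
    valid = [
        c
        for c in range(L)
        if all(r[c] not in "-N" for r in rows)
    ]
    if not valid:
        raise ZeroDivisionError("no valid columns")
    total = 0
    npairs = 0
    for a, b in itertools.combinations(rows, 2):
        npairs += 1
        total += sum(1 for c in valid if a[c] != b[c])
    return total / (npairs * len(valid))


def count_sites(rows: list[str]) -> tuple[int, int, int]:
    """(valid, variable, informative) via a per-column recount."""
    L = len(rows[0])
    valid = variable = informative = 0
    for c in range(L):
        col = [r[c] for r in rows]
        if any(x in "-N" for x in col):
            continue
        valid += 1
        counts = {b: col.count(b) for b in set(col)}
        if len(counts) >= 2:
            variable += 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative += 1
    return valid, variable, informative


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree; returns (taxa, distance matrix,
    bipartition set) with distances as exact path lengths."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    g = nx.Graph()
    g.add_edge(taxa[0], "x0", weight=float(rng.uniform(0.05, 1.0)))
    g.add_edge(taxa[1], "x0", weight=float(rng.uniform(0.05, 1.0)))
    g.add_edge(taxa[2], "x0", weight=float(rng.uniform(0.05, 1.0)))
    inner = 1
    for leaf in taxa[3:]:
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"x{inner}"
        inner += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(leaf, mid, weight=float(rng.uniform(0.05, 1.0)))
    d = np.zeros((n_leaves, n_leaves))
    sp = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            d[i, j] = sp[a][b]
    bips = set()
    for u, v in list(g.edges()):
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v, weight=w)
        side = frozenset(t for t in taxa if t in comp)
        other = frozenset(taxa) - side
        if len(side) >= 2 and len(other) >= 2:
            bips.add(min(side, other, key=sorted) if len(side) == len(other)
                     else (side if len(side) < len(other) else other))
    return taxa, d, bips


def random_dna(rng: np.random.Generator, n: int, at: float = 0.6) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
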