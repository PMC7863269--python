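"""Distance phylogenetics: p-distance, indel distance, NJ topology
recovery on additive matrices, newick round trips, bootstrap support."""
import numpy as np
import pytest

from plastidscan.alignment import Alignment
from plastidscan.indels import IndelMatrix
from plastidscan.phylo import (
    DistanceMatrix,
    bootstrap_support,
    indel_distance,
    neighbor_joining,
    p_distance,
    tree_bipartitions,
    write_nexus,
    write_relaxed_phylip,
)

from oracles import random_additive_tree, random_dna


def aln(named, ref=""):
    return Alignment.from_sequences(named, ref_taxon=ref)


def test_p_distance_basics():
    a = aln({"a": "A" * 100, "b": "A" * 98 + "CC", "c": "A" * 100})
    d = p_distance(a)
    assert d.d[0, 2] == 0.0
    assert d.d[0, 1] == pytest.approx(0.02)


def test_p_distance_pairwise_deletion():
    a = aln({"a": "AAAA--CC", "b": "AAAATTCC", "c": "CCAA--CC"})
    d = p_distance(a)
    # a vs c compare over the 6 mutually ungapped columns
    assert d.d[0, 2] == pytest.approx(2 / 6)


def test_p_distance_matches_recount():
    rng = np.random.default_rng(2)
    named = {}
    base = random_dna(rng, 400)
    for t in "abcde":
        row = list(base)
        for pos in rng.integers(0, 400, size=12):
            row[pos] = "ACGT"[int(rng.integers(4))]
        named[t] = "".join(row)
    d = p_distance(aln(named))
    taxa = list(named)
    for i in range(5):
        for j in range(5):
            manual = sum(1 for x, y in zip(named[taxa[i]], named[taxa[j]]) if x != y) / 400
            assert d.d[i, j] == pytest.approx(manual)


def test_p_distance_no_comparable_columns():
    a = aln({"a": "AA--", "b": "--TT", "c": "AATT"})
    with pytest.raises(ValueError):
        p_distance(a)


def test_indel_distance():
    m = IndelMatrix(taxa=["a", "b"], matrix=np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
    assert indel_distance(m).d[0, 1] == 1.0
    m2 = IndelMatrix(taxa=["a", "b", "c"], matrix=np.array([[1, 0], [1, 0], [0, 1]]))
    d2 = indel_distance(m2)
    assert d2.d[0, 1] == 0.0
    with pytest.raises(ValueError):
        indel_distance(IndelMatrix(taxa=["a", "b"], matrix=np.ones((2, 3), dtype=int)))


def test_nj_three_taxa_additive():
    taxa = ("a", "b", "c")
    d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    t = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    dt = t.as_dendropy()
    pdm = dt.phylogenetic_distance_matrix()
    lab = {x.label: x for x in dt.taxon_namespace}
    assert pdm.distance(lab["a"], lab["b"]) == pytest.approx(0.3, abs=1e-9)
    assert pdm.distance(lab["a"], lab["c"]) == pytest.approx(0.5, abs=1e-9)
    assert pdm.distance(lab["b"], lab["c"]) == pytest.approx(0.6, abs=1e-9)


def test_nj_quartet_recovery():
    # additive quartet ((a,b),(c,d)): internal edge 0.2
    taxa = ("a", "b", "c", "d")
    d = np.array(
        [
            [0.0, 0.2, 0.7, 0.8],
            [0.2, 0.0, 0.7, 0.8],
            [0.7, 0.7, 0.0, 0.3],
            [0.8, 0.8, 0.3, 0.0],
        ]
    )
    t = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    assert frozenset({"a", "b"}) in t.bipartitions()


@pytest.mark.parametrize("n_leaves", [4, 5, 6])
@pytest.mark.parametrize("seed", range(5))
def test_nj_recovers_additive_topologies(n_leaves, seed):
    rng = np.random.default_rng(1000 * n_leaves + seed)
    taxa, d, bips = random_additive_tree(rng, n_leaves)
    t = neighbor_joining(DistanceMatrix(taxa=tuple(taxa), d=d))
    assert t.bipartitions() == bips


def test_nj_label_permutation_invariance():
    rng = np.random.default_rng(77)
    taxa, d, _ = random_additive_tree(rng, 6)
    t1 = neighbor_joining(DistanceMatrix(taxa=tuple(taxa), d=d))
    perm = np.array([3, 1, 5, 0, 2, 4])
    t2 = neighbor_joining(
        DistanceMatrix(taxa=tuple(np.array(taxa)[perm]), d=d[np.ix_(perm, perm)])
    )
    assert t1.bipartitions() == t2.bipartitions()


def test_nj_nonfinite_rejected():
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=("a", "b", "c"), d=np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]]))


def test_newick_roundtrip():
    rng = np.random.default_rng(9)
    taxa, d, _ = random_additive_tree(rng, 6)
    t = neighbor_joining(DistanceMatrix(taxa=tuple(taxa), d=d))
    reparsed = t.as_dendropy()
    total_in = sum(e.length for e in reparsed.edges() if e.length)
    assert set(x.taxon.label for x in reparsed.leaf_node_iter()) == set(taxa)
    assert tree_bipartitions(reparsed.as_string(schema="newick")) == t.bipartitions()
    assert total_in == pytest.approx(sum(float(x) for x in
        __import__("re").findall(r":([0-9.]+)", t.newick)), abs=1e-9)


def test_bootstrap_congruent_signal_full_support():
    # two clean synapomorphies per split, no homoplasy
    named = {
        "a": "AAAAAAAATT",
        "b": "AAAAAAAATT",
        "c": "CCAAAAAAAA",
        "d": "CCAAAAAAAA",
    }
    t = bootstrap_support(aln(named), replicates=50, seed=3)
    assert t.supports
    assert all(v == 1.0 for v in t.supports.values())


def test_bootstrap_single_replicate_and_determinism(toy_truth):
    a = toy_truth.alignment
    t1 = bootstrap_support(a, replicates=1, seed=5)
    assert set(t1.supports.values()) <= {0.0, 1.0}
    t2 = bootstrap_support(a, replicates=10, seed=5)
    t3 = bootstrap_support(a, replicates=10, seed=5)
    assert t2.supports == t3.supports
    with pytest.raises(ValueError):
        bootstrap_support(a, replicates=0, seed=1)


def test_alignment_format_writers(tmp_path, toy_truth):
    a = toy_truth.alignment
    write_relaxed_phylip(a, tmp_path / "a.phy")
    write_nexus(a, tmp_path / "a.nex")
    phy = (tmp_path / "a.phy").read_text().splitlines()
    assert phy[0].split() == [str(a.n_taxa), str(a.n_cols)]
    import dendropy

    mat = dendropy.DnaCharacterMatrix.get(path=str(tmp_path / "a.nex"), schema="nexus")
    assert len(mat) == a.n_taxa
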