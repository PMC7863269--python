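"""Diversity statistics: site classification, pi, sliding windows,
marker extraction and reporting."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidscan.alignment import Alignment
from plastidscan.diversity import (
    UndefinedPiError,
    classify_sites,
    extract_marker,
    marker_report,
    nucleotide_diversity,
    sliding_window_pi,
)
from plastidscan.records import GeneFeature

from oracles import count_sites, pairwise_pi, random_dna


def aln(*rows, ref=""):
    return Alignment.from_sequences({f"t{i}": r for i, r in enumerate(rows)}, ref_taxon=ref)


def test_informative_vs_variable_columns():
    a = aln("AC", "AC", "CA", "CA")
    sc = classify_sites(a)
    assert (sc.variable_sites, sc.informative_sites) == (2, 2)
    b = aln("AG", "AG", "AG", "CG")
    sb = classify_sites(b)
    assert (sb.variable_sites, sb.informative_sites) == (1, 0)


def test_gap_and_n_columns_invalid():
    a = aln("A-CN", "AACA", "AACC")
    sc = classify_sites(a)
    assert sc.valid_sites == 2  # columns 0 and 2
    assert sc.aligned_length == 4


def test_unequal_rows_rejected():
    with pytest.raises(ValueError):
        Alignment.from_sequences({"a": "ACG", "b": "AC"})


@pytest.mark.parametrize("seed", range(6))
def test_site_counts_match_oracle(seed):
    rng = np.random.default_rng(seed)
    rows = []
    base = random_dna(rng, 200)
    for _ in range(6):
        row = list(base)
        for pos in rng.integers(0, 200, size=8):
            row[pos] = "ACGT-"[int(rng.integers(5))]
        rows.append("".join(row))
    sc = classify_sites(aln(*rows))
    assert (sc.valid_sites, sc.variable_sites, sc.informative_sites) == count_sites(rows)


def test_pi_two_rows_one_difference():
    a = aln("A" * 99 + "C", "A" * 100)
    assert nucleotide_diversity(a) == pytest.approx(0.01)


def test_pi_identical_rows_zero():
    assert nucleotide_diversity(aln("ACGT" * 10, "ACGT" * 10)) == 0.0


def test_pi_undefined_without_valid_columns():
    with pytest.raises(UndefinedPiError):
        nucleotide_diversity(aln("A---", "-CGT"))


@pytest.mark.parametrize("seed", range(8))
def test_pi_matches_bruteforce(seed):
    rng = np.random.default_rng(100 + seed)
    rows = []
    base = random_dna(rng, 150)
    for _ in range(4):
        row = list(base)
        for pos in rng.integers(0, 150, size=6):
            row[pos] = "ACGT-"[int(rng.integers(5))]
        rows.append("".join(row))
    assert nucleotide_diversity(aln(*rows)) == pytest.approx(pairwise_pi(rows))


@given(st.integers(0, 5000))
@settings(max_examples=20, deadline=None)
def test_pi_row_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    rows = [random_dna(rng, 80) for _ in range(4)]
    a = nucleotide_diversity(aln(*rows))
    b = nucleotide_diversity(aln(*reversed(rows)))
    assert a == pytest.approx(b)


def test_pi_estimator_unbiased():
    """With two rows differing independently per site with probability p,
    the mean of pi over replicates is p within 3 standard errors."""
    rng = np.random.default_rng(0)
    p, L, reps = 0.001, 10_000, 200
    ests = []
    for _ in range(reps):
        base = np.frombuffer(random_dna(rng, L).encode(), dtype=np.uint8).copy()
        other = base.copy()
        flip = np.nonzero(rng.random(L) < p)[0]
        for i in flip:
            choices = [b for b in b"ACGT" if b != other[i]]
            other[i] = choices[int(rng.integers(3))]
        a = Alignment(taxa=["x", "y"], matrix=np.vstack([base, other]))
        ests.append(nucleotide_diversity(a))
    mean = float(np.mean(ests))
    se = float(np.std(ests, ddof=1) / np.sqrt(reps))
    assert abs(mean - p) < 3 * se + 1e-12


def test_window_arithmetic():
    a = aln(random_dna(np.random.default_rng(0), 1000), random_dna(np.random.default_rng(1), 1000))
    wd = sliding_window_pi(a, window=600, step=100)
    assert [w.window_start for w in wd] == [0, 100, 200, 300, 400]
    assert all(w.window_end - w.window_start == 600 for w in wd)
    with_partial = sliding_window_pi(a, window=600, step=100, include_partial=True)
    assert with_partial[-1].partial and with_partial[-1].window_end == 1000


def test_window_tiling_covers_all_columns():
    a = aln("ACGT" * 300, "ACGT" * 300)
    wd = sliding_window_pi(a, window=200, step=50)
    covered = np.zeros(wd[-1].window_end, dtype=bool)
    for w in wd:
        covered[w.window_start : w.window_end] = True
    assert covered.all()


def test_windows_identical_alignment_zero():
    a = aln("ACGT" * 200, "ACGT" * 200, "ACGT" * 200)
    assert all(w.pi == 0.0 for w in sliding_window_pi(a, window=600, step=100))


def test_window_config_errors():
    a = aln("ACGT" * 200, "ACGT" * 200)
    with pytest.raises(ValueError):
        sliding_window_pi(a, window=100, step=200)
    with pytest.raises(ValueError):
        sliding_window_pi(a, window=0, step=0)


def test_variable_sites_monotone_under_mutation():
    rng = np.random.default_rng(4)
    rows = [random_dna(rng, 300) for _ in range(4)]
    base = classify_sites(aln(*rows)).variable_sites
    mutated = list(rows)
    row = list(mutated[0])
    pos = int(rng.integers(300))
    row[pos] = "A" if row[pos] != "A" else "C"
    mutated[0] = "".join(row)
    assert classify_sites(aln(*mutated)).variable_sites >= base


def test_concatenation_weighted_mean():
    """pi of a concatenation is the valid-site-weighted mean of component pi."""
    rng = np.random.default_rng(5)
    rows1 = [random_dna(rng, 120) for _ in range(3)]
    rows2 = [r[:40] + "-" * 5 + r[45:] for r in (random_dna(rng, 90) for _ in range(3))]
    a1, a2 = aln(*rows1), aln(*rows2)
    pi1, pi2 = nucleotide_diversity(a1), nucleotide_diversity(a2)
    L1 = classify_sites(a1).valid_sites
    L2 = classify_sites(a2).valid_sites
    combined = nucleotide_diversity(a1.concat(a2))
    assert combined == pytest.approx((pi1 * L1 + pi2 * L2) / (L1 + L2))


def _toy_marker_setup():
    feats = [
        GeneFeature("geneA", "protein_coding", ((0, 100, 1),)),
        GeneFeature("geneB", "protein_coding", ((150, 250, -1),)),
    ]
    seqs = {"r": random_dna(np.random.default_rng(6), 250), }
    seqs["s"] = seqs["r"][:200] + random_dna(np.random.default_rng(7), 50)
    return Alignment.from_sequences(seqs, ref_taxon="r"), feats


def test_extract_marker_spacer():
    a, feats = _toy_marker_setup()
    sub = extract_marker(a, feats, ["geneA", "geneB"])
    assert sub.n_cols == 50
    assert sub.row("r") == a.row("r")[100:150]
    # anchor order reversed gives the same genomic span
    sub2 = extract_marker(a, feats, ["geneB", "geneA"])
    assert sub2.row("r") == sub.row("r")


def test_extract_marker_missing_anchor():
    a, feats = _toy_marker_setup()
    with pytest.raises(KeyError):
        extract_marker(a, feats, ["geneA", "nope"])


def test_extract_marker_through_gapped_reference():
    feats = [
        GeneFeature("gA", "protein_coding", ((0, 4, 1),)),
        GeneFeature("gB", "protein_coding", ((8, 12, 1),)),
    ]
    a = Alignment.from_sequences(
        {"r": "ACGT--AACCGGTT", "s": "ACGTTTAACCGGTT"}, ref_taxon="r"
    )
    sub = extract_marker(a, feats, ["gA", "gB"])
    # ref positions [4, 8) map through the gapped reference row
    assert sub.row("r") == "AACC"


def test_marker_report_sums():
    rng = np.random.default_rng(8)
    rows = [random_dna(rng, 60) for _ in range(3)]
    inv = aln(*(["ACGT" * 10] * 3))
    var = aln(*rows)
    df = marker_report({"m_inv": inv, "m_var": var})
    row_inv = df[df.marker == "m_inv"].iloc[0]
    assert row_inv.variable_sites == 0 and row_inv.pi == 0.0
    concat = df.iloc[-1]
    assert concat.length == 40 + 60
    assert concat.variable_sites == df.variable_sites.iloc[:2].sum()
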