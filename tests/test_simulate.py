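"""Simulator: determinism, zero-rate degeneracy, substitution expectation,
IR mirroring, truth consistency across modules, fixture round trip."""
import numpy as np
import pytest

from plastidscan.indels import call_indels, classify_indel
from plastidscan.records import revcomp
from plastidscan.simulate import (
    SimParams,
    enumerate_ssrs,
    simulate,
    toy_params,
    write_fixture,
)
from plastidscan.ssr import find_ssrs
from plastidscan.structure import detect_quadripartite


def test_zero_rates_identical_leaves():
    params = toy_params(
        seed=1,
        region_rate_scale={"LSC": 0.0, "IR": 0.0, "SSC": 0.0},
        hotspot_markers={},
        ssr_slippage_rate=0.0,
        non_ssr_indel_rate=0.0,
    )
    truth = simulate(params)
    assert truth.events == []
    seqs = {r.sequence for r in truth.leaf_records.values()}
    assert len(seqs) == 1
    assert seqs.pop() == truth.ancestor.sequence


def test_same_seed_byte_identical():
    a = simulate(toy_params(seed=9))
    b = simulate(toy_params(seed=9))
    assert a.alignment.matrix.tobytes() == b.alignment.matrix.tobytes()
    assert a.events == b.events
    assert {t: r.sequence for t, r in a.leaf_records.items()} == {
        t: r.sequence for t, r in b.leaf_records.items()
    }


def test_different_seeds_differ():
    a = simulate(toy_params(seed=1))
    b = simulate(toy_params(seed=2))
    assert a.alignment.matrix.tobytes() != b.alignment.matrix.tobytes()


def test_contradictory_params_rejected():
    with pytest.raises(ValueError):
        toy_params(ssc_len=400)  # largest indel no longer fits
    with pytest.raises(ValueError):
        SimParams(lsc_len=0)
    with pytest.raises(ValueError):
        toy_params(non_ssr_indel_rate=-1)


def test_pairwise_divergence_matches_binomial_expectation():
    """On a 3-leaf star with branch length t and uniform rates, mean
    pairwise difference per site approximates 2t within 3 SE."""
    t = 0.002
    reps = 40
    obs = []
    for seed in range(reps):
        params = toy_params(
            seed=seed,
            lsc_len=4000,
            ir_len=1200,
            ssc_len=1500,
            tree=f"(X:{t},Y:{t},Z:{t});",
            region_rate_scale={"LSC": 1.0, "IR": 1.0, "SSC": 1.0},
            hotspot_markers={},
            ssr_tracts=(),
            ssr_slippage_rate=0.0,
            non_ssr_indel_rate=0.0,
        )
        truth = simulate(params)
        rows = [
            np.frombuffer(r.sequence.encode(), dtype=np.uint8)
            for r in truth.leaf_records.values()
        ]
        pair_d = [
            float((rows[i] != rows[j]).mean())
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        obs.append(np.mean(pair_d))
    mean = float(np.mean(obs))
    se = float(np.std(obs, ddof=1) / np.sqrt(reps))
    assert abs(mean - 2 * t) < 3 * se + 1e-9


def test_ir_mirror_maintained(toy_truth):
    lsc, ir, ssc = (
        toy_truth.params.lsc_len,
        toy_truth.params.ir_len,
        toy_truth.params.ssc_len,
    )
    for taxon, rec in toy_truth.leaf_records.items():
        l, i, s = toy_truth.region_lengths[taxon]
        assert i == ir  # indels never touch the IR
        irb = rec.sequence[l : l + i]
        ira = rec.sequence[l + i + s :]
        assert revcomp(irb) == ira


def test_structure_detection_exact_on_leaves(toy_truth):
    for taxon, rec in toy_truth.leaf_records.items():
        st = detect_quadripartite(rec, min_ir=1000)
        assert (st.lsc_length, st.ir_length, st.ssc_length) == toy_truth.region_lengths[taxon]


def test_truth_alignment_consistent_with_leaves(toy_truth):
    for taxon in toy_truth.alignment.taxa:
        assert toy_truth.alignment.ungapped(taxon) == toy_truth.leaf_records[taxon].sequence


@pytest.mark.parametrize("seed", [11, 21])
def test_event_recovery_and_classification(seed):
    truth = simulate(toy_params(seed=seed))
    called = call_indels(truth.alignment)
    ref_seq = truth.alignment.ungapped(truth.alignment.ref_taxon)
    called = [classify_indel(e, ref_seq) for e in called]
    tmap = {
        (e.ref_pos, e.length, e.polarity): e
        for e in truth.events_vs_reference()
    }
    hits = [e for e in called if (e.ref_pos, e.length, e.polarity) in tmap]
    recall = len(hits) / len(tmap)
    assert recall >= 0.95
    agree = sum(
        1 for e in hits if tmap[(e.ref_pos, e.length, e.polarity)].klass == e.klass
    )
    assert agree / len(hits) >= 0.9
    carrier_ok = sum(
        1 for e in hits if tmap[(e.ref_pos, e.length, e.polarity)].carriers == e.carriers
    )
    assert carrier_ok == len(hits)


def test_ssr_catalog_matches_scanner(toy_truth):
    for label in ["ancestor", "A_chinensis", "A_carlinoides"]:
        seq = (
            toy_truth.ancestor.sequence
            if label == "ancestor"
            else toy_truth.leaf_records[label].sequence
        )
        found = {(l.start, l.end, l.motif) for l in find_ssrs(seq)}
        catalog = {(l.start, l.end, l.motif) for l in toy_truth.ssr_catalogs[label]}
        assert found == catalog


def test_hotspot_elevates_local_rate():
    base = toy_params(seed=4, hotspot_markers={})
    hot = toy_params(seed=4, hotspot_markers={}, extra_hotspots=((1000, 2200, 10.0),))
    tb, th = simulate(base), simulate(hot)
    enc = lambda truth: truth.alignment.matrix
    # more mismatch columns inside the hotspot than in the matched baseline
    def var_cols(truth, lo, hi):
        m = truth.alignment.matrix[:, lo:hi]
        return int((m != m[0]).any(axis=0).sum())

    assert var_cols(th, 1000, 2200) > var_cols(tb, 1000, 2200)


def test_write_fixture_roundtrip(tmp_path, toy_truth):
    from plastidscan.io import read_plastome
    from plastidscan.alignment import Alignment

    write_fixture(toy_truth, tmp_path)
    rec = read_plastome(tmp_path / "genomes" / "A_chinensis.gb", taxon_id="A_chinensis")
    orig = toy_truth.leaf_records["A_chinensis"]
    assert rec.sequence == orig.sequence
    assert len(rec.features) == len(orig.features)
    aln = Alignment.from_fasta(tmp_path / "alignment.fasta", ref_taxon="A_chinensis")
    assert aln.matrix.tobytes() == toy_truth.alignment.matrix.tobytes()
    called = {(e.ref_pos, e.length, e.polarity) for e in call_indels(aln)}
    truth_keys = {(e.ref_pos, e.length, e.polarity) for e in toy_truth.events_vs_reference()}
    assert len(called & truth_keys) / len(truth_keys) >= 0.95
    for name in ["truth_events.tsv", "truth_ssrs.tsv", "truth_regions.tsv", "tree.nwk", "params.json"]:
        assert (tmp_path / name).is_file()


def test_enumerator_counts_n_free():
    # the internal truth enumerator honours the same definition boundaries
    assert {(l.start, l.end) for l in enumerate_ssrs("A" * 10)} == {(0, 10)}
    assert enumerate_ssrs("A" * 9) == []
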