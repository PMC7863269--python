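"""Indel caller: event extraction, left-normalization, slippage
classification, round-trip reconstruction, and binary coding."""
import numpy as np
import pytest

from plastidscan.alignment import Alignment
from plastidscan.indels import (
    MalformedAlignmentError,
    build_indel_matrix,
    call_indels,
    classify_indel,
    indel_spectrum,
    left_normalize,
)
from plastidscan.simulate import simulate, toy_params


def aln(**named):
    return Alignment.from_sequences(named, ref_taxon="ref")


def test_simple_deletion():
    a = aln(ref="ACGTACGT", alt="ACG--CGT")
    ev, = call_indels(a)
    assert ev.polarity == "deletion"
    assert ev.length == 2
    assert ev.seq == "TA"
    assert ev.ref_pos == 2  # base immediately left of the deleted "TA"
    assert ev.carriers == frozenset({"alt"})


def test_simple_insertion():
    a = aln(ref="ACG--CGT", alt="ACGTTCGT", other="ACG--CGT")
    ev, = call_indels(a)
    assert ev.polarity == "insertion"
    assert ev.seq == "TT"
    assert ev.carriers == frozenset({"alt"})


def test_shared_gap_run_is_one_event():
    a = aln(ref="AACGGTTACG", x="AAC---TACG", y="AAC---TACG", z="AACGGTTACG")
    ev, = call_indels(a)
    assert ev.carriers == frozenset({"x", "y"})
    assert ev.length == 3


def test_overlapping_unequal_spans_split():
    # x is gapped over 3 columns, y over the first 2: the shared-pattern run
    # and x's private extra column become two distinct events
    a = aln(ref="AACGGTTACG", x="AAC---TACG", y="AAC--TTACG")
    events = call_indels(a)
    assert len(events) == 2
    assert {(e.carriers, e.length) for e in events} == {
        (frozenset({"x", "y"}), 2),
        (frozenset({"x"}), 1),
    }


def test_all_gap_column_rejected():
    a = aln(ref="AC-GT", x="AC-GT")
    with pytest.raises(MalformedAlignmentError):
        call_indels(a)


def test_left_normalization_in_homopolymer():
    """Gaps placed anywhere inside a homopolymer yield the same event."""
    left = aln(ref="CAAAAG", x="C-AAAG")
    right = aln(ref="CAAAAG", x="CAAA-G")
    el, er = call_indels(left)[0], call_indels(right)[0]
    assert (el.ref_pos, el.seq) == (er.ref_pos, er.seq) == (0, "A")


def test_left_normalize_insertion_rotates_seq():
    # inserting "AT" after the ATx2 tract slides to the leftmost equivalent
    # placement, rotating through the repeat: CCATAT^ATG == CC^ATATATG
    pos, seq = left_normalize("CCATATG", 6, "AT", "insertion")
    assert pos == 2
    assert seq == "AT"


def test_classify_slippage_boundary():
    # 1-bp "A" insertion beside 9 A's: the longer allele reaches 10 -> slippage
    ref = "GGC" + "A" * 9 + "TTG"
    ev = call_indels(aln(ref="GGC-" + "A" * 9 + "TTG", x="GGCA" + "A" * 9 + "TTG"))[0]
    ev = classify_indel(ev, ref)
    assert ev.klass == "SSR_related"
    # same insertion beside only 8 A's stays below threshold
    ref8 = "GGC" + "A" * 8 + "TTG"
    ev8 = call_indels(aln(ref="GGC-" + "A" * 8 + "TTG", x="GGCA" + "A" * 8 + "TTG"))[0]
    assert classify_indel(ev8, ref8).klass == "non_SSR"


def test_classify_non_repetitive():
    ref = "ATCGATTGCAGGCAACTGTTCGA"
    a = aln(ref="ATCGATTGCAGGCAACTGTTCGA", x="ATCGATTGCA---AACTGTTCGA")
    ev = classify_indel(call_indels(a)[0], ref)
    assert ev.klass == "non_SSR"


def test_classify_multiunit_slippage():
    # deleting one "AT" unit from a 5-unit tract: longer (reference) allele
    # holds 5 copies, meeting the dinucleotide threshold
    ref = "GGC" + "AT" * 5 + "CGG"
    gapped = "GGC" + "AT" * 4 + "--" + "CGG"
    ev = classify_indel(call_indels(aln(ref=ref, x=gapped))[0], ref)
    assert ev.klass == "SSR_related"
    assert ev.length == 2


def test_class_exhaustive_on_simulation(toy_truth):
    ref_seq = toy_truth.alignment.ungapped(toy_truth.alignment.ref_taxon)
    events = [classify_indel(e, ref_seq) for e in call_indels(toy_truth.alignment)]
    assert events
    assert all(e.klass in ("SSR_related", "non_SSR") for e in events)


def test_taxon_order_invariance(toy_truth):
    a = toy_truth.alignment
    key = lambda evs: {(e.ref_pos, e.length, e.polarity, e.carriers) for e in evs}
    base = key(call_indels(a))
    perm = list(reversed(a.taxa))
    b = a.subset(perm, strip_gap_only=False, ref_taxon=a.ref_taxon)
    assert key(call_indels(b)) == base


def test_roundtrip_reconstruction_no_substitutions():
    """Applying every called event to the reference reconstructs each
    carrier sequence exactly (indel-only simulation)."""
    params = toy_params(
        seed=3,
        region_rate_scale={"LSC": 0.0, "IR": 0.0, "SSC": 0.0},
        hotspot_markers={},
    )
    truth = simulate(params)
    a = truth.alignment
    ref = a.ungapped(a.ref_taxon)
    events = call_indels(a)
    assert events, "simulation produced no indels; raise rates or reseed"
    for taxon in a.taxa:
        seq = ref
        for e in sorted(events, key=lambda e: -e.ref_pos):
            if taxon not in e.carriers:
                continue
            s = e.ref_pos + 1
            if e.polarity == "deletion":
                seq = seq[:s] + seq[s + e.length :]
            else:
                seq = seq[:s] + e.seq + seq[s:]
        assert seq == a.ungapped(taxon)


def test_event_recovery_against_truth(toy_truth):
    called = {(e.ref_pos, e.length, e.polarity) for e in call_indels(toy_truth.alignment)}
    truth = {(e.ref_pos, e.length, e.polarity) for e in toy_truth.events_vs_reference()}
    recall = len(called & truth) / len(truth)
    assert recall >= 0.95


def test_spectrum_tables(toy_truth):
    ref_seq = toy_truth.alignment.ungapped(toy_truth.alignment.ref_taxon)
    events = [classify_indel(e, ref_seq) for e in call_indels(toy_truth.alignment)]
    spec = indel_spectrum(events)
    assert spec["by_size"]["n"].sum() == len(events)
    assert spec["by_context"]["n"].sum() == len(events)
    assert int(spec["largest"]["length"].iloc[0]) == max(e.length for e in events)
    empty = indel_spectrum([])
    assert empty["by_size"].empty


def test_indel_matrix_coding():
    a = aln(ref="AACGGTTACG", x="AAC---TACG", y="AACGGTTACG", z="AACGGTTACG")
    events = call_indels(a)
    m = build_indel_matrix(events, a.taxa, "ref")
    assert m.matrix.shape == (4, 1)
    # fragment presence: the deleting taxon lacks it
    state = dict(zip(m.taxa, m.matrix[:, 0]))
    assert state["x"] == 0 and state["ref"] == 1 and state["y"] == 1


def test_indel_matrix_requires_events():
    with pytest.raises(ValueError):
        build_indel_matrix([], ["a", "b"], "a")
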