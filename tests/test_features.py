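"""Presence vectors, odds-ratio dictionaries and aggregation embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrdscreen.codes import DX, RX, PROC, CodeVocabulary, build_vocabulary
from adrdscreen.features import (
    AggregationSet,
    ORDictionary,
    assemble_features,
    build_feature_matrix,
    compute_or_embedding,
    compute_presence,
    fit_or_dictionary,
)

VOCAB = CodeVocabulary(DX, ("E", "E11", "E119", "I10"))


def test_presence_sets_code_and_prefix_bits():
    vec = compute_presence({"E119"}, VOCAB)
    assert vec.tolist() == [1, 1, 1, 0]


def test_presence_empty_and_fully_unseen_windows_are_zero():
    assert compute_presence(frozenset(), VOCAB).tolist() == [0, 0, 0, 0]
    # no tracked prefix of Z99 is in the vocabulary
    assert compute_presence({"Z99"}, VOCAB).tolist() == [0, 0, 0, 0]


def test_presence_out_of_vocabulary_code_contributes_prefixes_only():
    # E45 is unseen but its prefix E is tracked
    assert compute_presence({"E45"}, VOCAB).tolist() == [1, 0, 0, 0]


@settings(deadline=None, derandomize=True)
@given(st.sets(st.sampled_from(["E11", "E119", "E45", "I10", "I100", "Z99"]), max_size=5))
def test_presence_prefix_consistency(window):
    """If a full code's bit is set, its in-vocabulary tracked prefixes are set too."""
    vocab = build_vocabulary([{"E11", "E119", "I10", "I100"}], DX)
    vec = compute_presence(window, vocab)
    idx = vocab.index
    from adrdscreen.codes import expand_prefixes

    for entry, i in idx.items():
        if vec[i]:
            for prefix in expand_prefixes(entry, DX)[:-1]:
                if prefix in idx:
                    assert vec[idx[prefix]] == 1


def windows(label_sets):
    return [frozenset(s) for s in label_sets]


def test_or_dictionary_unsmoothed_ratio_cubed():
    cases = windows([{"X1"}] * 2 + [set()] * 2)  # 50% of cases
    ctrls = windows([{"X1"}] + [set()] * 3)  # 25% of controls
    d = fit_or_dictionary(cases, ctrls, DX, smoothing=0.0)
    assert d.ratios["X1"] == pytest.approx(8.0)


def test_or_dictionary_equal_prevalence_is_one():
    cases = windows([{"X1"}, set()])
    ctrls = windows([{"X1"}, set()])
    d = fit_or_dictionary(cases, ctrls, DX, smoothing=0.0)
    assert d.ratios["X1"] == pytest.approx(1.0)


def test_or_dictionary_smoothed_hand_value():
    # 3/10 cases, 1/20 controls, smoothing 0.5: ((3.5/11)/(1.5/21))^3
    cases = windows([{"X1"}] * 3 + [set()] * 7)
    ctrls = windows([{"X1"}] + [set()] * 19)
    d = fit_or_dictionary(cases, ctrls, DX, smoothing=0.5)
    expected = ((3.5 / 11) / (1.5 / 21)) ** 3
    assert d.ratios["X1"] == pytest.approx(expected)
    assert expected == pytest.approx(88.39, abs=0.01)


def test_or_dictionary_requires_both_classes():
    with pytest.raises(ValueError):
        fit_or_dictionary([], windows([{"X1"}]), DX)
    with pytest.raises(ValueError):
        fit_or_dictionary(windows([{"X1"}]), [], DX)


@settings(deadline=None, derandomize=True)
@given(
    k1=st.integers(0, 10),
    k2=st.integers(0, 10),
    m1=st.integers(0, 20),
    m2=st.integers(0, 20),
)
def test_cubing_preserves_ranking(k1, k2, m1, m2):
    cases = windows(
        [{"A1"} | ({"B2"} if i < k2 else set()) for i in range(k1)] + [set()] * (10 - k1)
    )
    cases = windows([{"A1"} if i < k1 else set() for i in range(10)])
    for i in range(min(k2, 10)):
        cases[i] = cases[i] | {"B2"}
    ctrls = windows([{"A1"} if i < m1 else set() for i in range(20)])
    for i in range(min(m2, 20)):
        ctrls[i] = ctrls[i] | {"B2"}
    d = fit_or_dictionary(cases, ctrls, DX, smoothing=0.5)
    raw_a = (k1 + 0.5) / (m1 + 0.5)
    raw_b = (k2 + 0.5) / (m2 + 0.5)
    if "A1" in d.ratios and "B2" in d.ratios:
        assert (d.ratios["A1"] > d.ratios["B2"]) == (raw_a > raw_b)


def or_dict(ratios):
    return ORDictionary(channel=DX, ratios=ratios, case_n=1, control_n=1)


def test_embedding_singleton_multiset():
    emb = compute_or_embedding({"X1"}, or_dict({"X1": 8.0}))
    aggs = AggregationSet()
    by_name = dict(zip(aggs.names, emb))
    for name in ("min", "max", "mean", "median"):
        assert by_name[name] == pytest.approx(8.0)
    assert by_name["count"] == 1


def test_embedding_empty_window_uses_declared_empty_value():
    emb = compute_or_embedding(frozenset(), or_dict({"X1": 8.0}))
    assert np.all(emb == 0.0)


def test_embedding_hand_values():
    emb = compute_or_embedding(
        {"A", "B", "C"}, or_dict({"A": 1.0, "B": 8.0, "C": 27.0})
    )
    by_name = dict(zip(AggregationSet().names, emb))
    assert by_name["mean"] == pytest.approx(12.0)
    assert by_name["max"] == pytest.approx(27.0)
    assert by_name["min"] == pytest.approx(1.0)
    assert by_name["sum"] == pytest.approx(36.0)


def test_embedding_duplicates_and_unknown_codes_ignored():
    emb1 = compute_or_embedding({"A", "Z"}, or_dict({"A": 5.0}))
    emb2 = compute_or_embedding({"A"}, or_dict({"A": 5.0}))
    assert np.array_equal(emb1, emb2)


def test_aggregation_set_requires_twelve():
    with pytest.raises(ValueError):
        AggregationSet(names=("mean",), functions=(np.mean,))


def _fixture_inputs():
    vocabs = {
        "DX": build_vocabulary([{"E11", "I10"}], DX),
        "RX": build_vocabulary([{"rxCHD1"}], RX),
        "PROC": build_vocabulary([{"12345"}], PROC),
    }
    or_dicts = {
        "DX": ORDictionary(DX, {"E11": 8.0}, 5, 5),
        "RX": ORDictionary(RX, {"rxCHD1": 2.0}, 5, 5),
        "PROC": ORDictionary(PROC, {"12345": 1.0}, 5, 5),
    }
    windows = {
        "DX": frozenset({"E11"}),
        "RX": frozenset({"rxCHD1"}),
        "PROC": frozenset(),
    }
    return windows, vocabs, or_dicts


def test_assemble_features_shapes_and_determinism():
    windows, vocabs, or_dicts = _fixture_inputs()
    b1 = assemble_features(windows, vocabs, or_dicts, sex=1, age_at_index_years=70.0)
    b2 = assemble_features(windows, vocabs, or_dicts, sex=1, age_at_index_years=70.0)
    for ch in ("DX", "RX", "PROC"):
        assert b1.presence[ch].shape == (len(vocabs[ch]),)
        assert b1.or_embedding[ch].shape == (12,)
        assert np.array_equal(b1.presence[ch], b2.presence[ch])
        assert np.array_equal(b1.or_embedding[ch], b2.or_embedding[ch])


def test_assemble_features_channel_mismatch_rejected():
    windows, vocabs, or_dicts = _fixture_inputs()
    swapped = dict(or_dicts)
    swapped["DX"], swapped["RX"] = (
        ORDictionary(RX, {}, 1, 1),
        ORDictionary(DX, {}, 1, 1),
    )
    with pytest.raises(ValueError, match="channel mismatch"):
        assemble_features(windows, vocabs, swapped, sex=0, age_at_index_years=60.0)


def test_assemble_features_leakage_guard():
    windows, vocabs, or_dicts = _fixture_inputs()
    tainted = dict(or_dicts)
    tainted["DX"] = ORDictionary(
        DX, {"E11": 8.0}, 5, 5, training_ids=frozenset({"p9"})
    )
    with pytest.raises(ValueError, match="leakage"):
        assemble_features(
            windows, vocabs, tainted, sex=0, age_at_index_years=60.0, eval_patient_id="p9"
        )
    # a patient outside the training split passes
    assemble_features(
        windows, vocabs, tainted, sex=0, age_at_index_years=60.0, eval_patient_id="p10"
    )


def test_or_dictionary_tsv_roundtrip(tmp_path):
    d = fit_or_dictionary(
        windows([{"E11"}, set()]), windows([{"E11"}, set(), set()]), DX,
        case_ids=["a", "b"], control_ids=["c", "d", "e"],
    )
    d.to_tsv(tmp_path / "ordict-DX.tsv")
    loaded = ORDictionary.from_tsv(tmp_path / "ordict-DX.tsv")
    assert loaded.ratios == dict(d.ratios)
    assert loaded.fingerprint == d.fingerprint


def test_build_feature_matrix_blocks_and_manifest():
    windows, vocabs, or_dicts = _fixture_inputs()
    blocks, manifest = build_feature_matrix([windows, windows], vocabs, or_dicts)
    assert blocks["DX-presence"].shape == (2, len(vocabs["DX"]))
    assert blocks["RX-OR"].shape == (2, 12)
    assert manifest["blocks"]["PROC-presence"] == len(vocabs["PROC"])
    assert np.array_equal(blocks["DX-presence"][0], blocks["DX-presence"][1])
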