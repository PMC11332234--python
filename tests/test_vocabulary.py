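import numpy as np
import pandas as pd
import pytest

from emoseg import (
    ConsensusEvent,
    EmbeddingSpace,
    NormsTable,
    clean_labels,
    compute_nul,
    compute_sas,
    compute_sds,
    lexical_complexity,
)
from emoseg.vocabulary import default_lemma_overrides, default_stopwords, lemmatize
from conftest import make_dataset


class TestCleanLabels:
    def test_derivational_variants_collapse_to_one_label(self):
        out = clean_labels(["Angry!", "anger", " angry "])
        assert out.lemmas == ["anger", "anger", "anger"]
        assert len(out.unique) == 1

    def test_stopwords_removed(self):
        out = clean_labels(["he is sad"])
        assert out.unique == {"sadness"}
        assert set(out.dropped) == {"he", "is"}

    def test_digits_and_punctuation_stripped(self):
        assert clean_labels(["2 upset!!"]).unique == {"upset"}

    def test_phrases_tokenize_per_word(self):
        out = clean_labels(["very happy and surprised"])
        assert out.unique == {"happiness", "surprise"}

    def test_empty_input_empty_output(self):
        out = clean_labels([])
        assert out.lemmas == [] and out.dropped == []

    def test_cleaning_is_idempotent(self):
        first = clean_labels(["Angry!", "worried dogs", "loathing", "2 upset"])
        second = clean_labels(first.lemmas)
        assert second.lemmas == first.lemmas

    def test_custom_stopwords_respected(self):
        out = clean_labels(["kind of sad"], custom_stopwords=frozenset({"kind"}))
        assert out.unique == {"sadness"}

    def test_plural_suffix_rule(self):
        assert lemmatize("surprises", default_lemma_overrides()) == "surprise"


class TestNul:
    def labeled_dataset(self):
        return make_dataset(
            {"p1": [1.0, 5.0, 9.0], "p2": [2.0, 6.0]},
            duration=30.0,
            labels={"p1": ["angry", "anger", "fury"], "p2": ["sad", "joyful"]},
        )

    def test_unique_after_lemmatization(self):
        # angry/anger merge; fury stays distinct
        nul = compute_nul(self.labeled_dataset())
        assert nul["p1"] == 2.0
        assert nul["p2"] == 2.0

    def test_mean_across_stimuli(self):
        from emoseg import Dataset, SegmentationRecord, StimulusInfo

        records = [
            SegmentationRecord("p1", "s1", 1.0, "sad"),
            SegmentationRecord("p1", "s1", 2.0, "joy"),
            SegmentationRecord("p1", "s2", 1.0, "sad"),
            SegmentationRecord("p1", "s2", 2.0, "fear"),
            SegmentationRecord("p1", "s2", 3.0, "rage"),
            SegmentationRecord("p1", "s2", 4.0, "awe"),
        ]
        stim = [StimulusInfo("s1", 10.0), StimulusInfo("s2", 10.0)]
        nul = compute_nul(Dataset(records, stim))
        assert nul["p1"] == 3.0  # (2 + 4) / 2

    def test_invariant_to_case_punctuation_duplicates(self):
        a = make_dataset({"p1": [1.0, 2.0]}, labels={"p1": ["SAD!", "sad"]})
        b = make_dataset({"p1": [1.0, 2.0]}, labels={"p1": ["sad", "sad."]})
        assert compute_nul(a)["p1"] == compute_nul(b)["p1"] == 1.0


class TestLexicalComplexity:
    def test_constant_norms_mean(self):
        norms = NormsTable(aoa={"sadness": 5.0, "joy": 5.0}, familiarity={"sadness": 6.0, "joy": 6.0})
        aoa, fam, cov = lexical_complexity(["sadness", "joy", "joy"], norms)
        assert (aoa, fam, cov) == (5.0, 6.0, 1.0)

    def test_partial_coverage_mean_and_fraction(self):
        norms = NormsTable(aoa={"a": 4.0, "b": 8.0}, familiarity={"a": 5.0, "b": 3.0})
        aoa, fam, cov = lexical_complexity(["a", "b", "c", "d"], norms, coverage_floor=0.5)
        assert aoa == 6.0 and fam == 4.0 and cov == 0.5

    def test_below_coverage_floor_is_missing(self):
        norms = NormsTable(aoa={"a": 4.0}, familiarity={"a": 5.0})
        aoa, fam, cov = lexical_complexity(["a", "b", "c"], norms, coverage_floor=0.5)
        assert np.isnan(aoa) and np.isnan(fam) and cov == pytest.approx(1 / 3)

    def test_no_lemmas_in_norms(self):
        norms = NormsTable(aoa={}, familiarity={})
        aoa, fam, cov = lexical_complexity(["x"], norms)
        assert np.isnan(aoa) and cov == 0.0

    def test_multiplicity_invariance(self):
        norms = NormsTable(aoa={"a": 4.0, "b": 8.0}, familiarity={"a": 1.0, "b": 2.0})
        once = lexical_complexity(["a", "b"], norms)
        many = lexical_complexity(["a", "a", "a", "b"], norms)
        assert once == many


def toy_embedding():
    return EmbeddingSpace(
        {"gloom": np.array([1.0, 0.0, 0.0]), "joy": np.array([0.0, 1.0, 0.0])},
        ["d1", "d2", "d3"],
    )


class TestSas:
    def one_event(self):
        return {"s1": [ConsensusEvent("s1", 5.0, 4.0, 6.0, 2.0)]}

    def test_sole_labeler_scores_one(self):
        ds = make_dataset({"p1": [5.0]}, labels={"p1": ["gloom"]})
        sas = compute_sas(ds, self.one_event(), toy_embedding())
        assert sas["p1"] == pytest.approx(1.0)

    def test_hand_computed_two_labeler_event(self):
        # p1 profile = e_gloom = [1,0,0]; group = ([1,0,0]+[0,1,0])/2 = [.5,.5,0]
        # Pearson([1,0,0], [.5,.5,0]) = 0.5 by hand
        ds = make_dataset({"p1": [5.0], "p2": [5.5]}, labels={"p1": ["gloom"], "p2": ["joy"]})
        sas = compute_sas(ds, self.one_event(), toy_embedding())
        assert sas["p1"] == pytest.approx(0.5)
        assert sas["p2"] == pytest.approx(0.5)

    def test_participant_outside_window_has_missing_sas(self):
        ds = make_dataset({"p1": [20.0]}, labels={"p1": ["gloom"]})
        assert np.isnan(compute_sas(ds, self.one_event(), toy_embedding())["p1"])

    def test_leave_one_out_sole_labeler_is_missing(self):
        ds = make_dataset({"p1": [5.0]}, labels={"p1": ["gloom"]})
        sas = compute_sas(ds, self.one_event(), toy_embedding(), leave_one_out=True)
        assert np.isnan(sas["p1"])

    def test_scores_bounded(self, embedding):
        ds = make_dataset(
            {"p1": [5.0], "p2": [5.2], "p3": [5.4]},
            labels={"p1": ["anger"], "p2": ["joy"], "p3": ["terror"]},
        )
        sas = compute_sas(ds, self.one_event(), embedding)
        for v in sas.values():
            assert -1.0 <= v <= 1.0


class TestSds:
    def test_identical_lemmas_fully_correlated(self, embedding):
        mat, summary = compute_sds(["anger", "anger"], ["anger", "fear"], embedding)
        assert np.isnan(summary) or summary == pytest.approx(1.0)
        # only one emotion represented -> no off-diagonal defined
        assert np.isnan(mat.loc["anger", "fear"])

    def test_disjoint_one_hot_profiles_hand_value(self):
        emb = EmbeddingSpace(
            {"w1": np.array([1.0, 0, 0, 0]), "w2": np.array([0, 1.0, 0, 0])},
            ["e1", "e2", "x1", "x2"],
        )
        mat, summary = compute_sds(["w1", "w2"], ["e1", "e2"], emb)
        # Pearson([1,0,0,0],[0,1,0,0]) = -1/3 by hand
        assert mat.loc["e1", "e2"] == pytest.approx(-1 / 3)
        assert summary == pytest.approx(-1 / 3)

    def test_single_emotion_summary_missing(self, embedding):
        _mat, summary = compute_sds(["anger"], ["anger", "fear"], embedding)
        assert np.isnan(summary)

    def test_distinct_words_less_correlated_than_same_tag(self, embedding):
        _, within = compute_sds(["anger", "rage", "fury"], ["anger", "fear"], embedding)
        mat, across = compute_sds(["anger", "terror", "joy"], ["anger", "fear", "happiness"], embedding)
        assert np.isnan(within)  # all one tag
        assert across < 1.0
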