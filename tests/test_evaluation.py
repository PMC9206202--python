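"""Evaluation metrics against hand-computed oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import phenossu as ph
from phenossu.evaluation import (
    attribute_scores,
    cohen_kappa,
    compare_instance_sets,
    entity_f1,
    evaluate,
    instance_accuracy,
    min_corpus_size,
    min_corpus_size_exact,
)


def _inst(phenotype, span, doc="d0", **attrs):
    return ph.PhenoSSUInstance(
        phenotype=phenotype,
        phenotype_span=span,
        attributes={k.replace("_", " "): (v, None) for k, v in attrs.items()},
        doc_id=doc,
    )


class TestEntityF1:
    def test_identity(self):
        spans = [(0, 2, "Phenotype"), (3, 5, "Phenotype")]
        assert entity_f1(spans, spans) == (1.0, 1.0, 1.0)

    def test_disjoint(self):
        assert entity_f1([(0, 2, "Phenotype")], [(5, 7, "Phenotype")]) == (0, 0, 0)

    def test_hand_computed(self):
        gold = [(0, 2, "P"), (3, 5, "P"), (6, 8, "P")]
        pred = [(0, 2, "P"), (9, 11, "P")]
        p, r, f1 = entity_f1(pred, gold)
        assert (p, r) == (0.5, pytest.approx(1 / 3))
        assert f1 == pytest.approx(0.4)

    def test_type_mismatch_not_counted(self):
        assert entity_f1([(0, 2, "A")], [(0, 2, "P")])[2] == 0.0

    def test_duplicate_gold_deduplicated(self):
        gold = [(0, 2, "P"), (0, 2, "P")]
        assert entity_f1([(0, 2, "P")], gold) == (1.0, 1.0, 1.0)


class TestAttributeScores:
    def test_all_correct(self):
        gold = [_inst("pain", (0, 2), severity="severe")]
        per, avg, weighted, uniform, _ = attribute_scores(gold, gold)
        assert avg == weighted == uniform == 1.0

    def test_all_wrong(self):
        gold = [_inst("pain", (0, 2), severity="severe")]
        pred = [_inst("pain", (0, 2), severity="mild")]
        per, avg, weighted, uniform, _ = attribute_scores(pred, gold)
        assert avg == weighted == uniform == 0.0

    def test_frequency_vs_uniform_weighting(self):
        """9/9 correct on one value, 0/1 on a rare one: frequency-weighted
        0.9 but uniform-over-values 0.5."""
        gold = [_inst("p", (i, i + 1), assertion="present") for i in range(9)]
        gold.append(_inst("p", (9, 10), assertion="absent"))
        pred = [_inst("p", (i, i + 1), assertion="present") for i in range(10)]
        per, avg, weighted, uniform, support = attribute_scores(pred, gold)
        assert weighted == pytest.approx(0.9)
        assert uniform == pytest.approx(0.5)
        assert support == {"assertion=present": 9, "assertion=absent": 1}

    def test_unmatched_gold_counts_wrong(self):
        gold = [_inst("pain", (0, 2), severity="severe")]
        per, avg, weighted, uniform, _ = attribute_scores([], gold)
        assert weighted == 0.0

    def test_out_of_schema_value_rejected(self, schema):
        pred = [_inst("pain", (0, 2), severity="apocalyptic")]
        gold = [_inst("pain", (0, 2), severity="severe")]
        with pytest.raises(Exception):
            attribute_scores(pred, gold, schema)

    def test_weighted_matches_independent_tally(self):
        rng = np.random.default_rng(0)
        values = ["mild", "moderate", "severe"]
        gold, pred = [], []
        for i in range(60):
            gv = values[rng.integers(3)]
            pv = values[rng.integers(3)]
            gold.append(_inst("p", (i, i + 1), severity=gv))
            pred.append(_inst("p", (i, i + 1), severity=pv))
        _, _, weighted, _, _ = attribute_scores(pred, gold)
        manual = np.mean(
            [
                p.attribute_values()["severity"] == g.attribute_values()["severity"]
                for p, g in zip(pred, gold)
            ]
        )
        assert weighted == pytest.approx(manual)


class TestInstanceAccuracy:
    def test_identity(self):
        gold = [_inst("pain", (0, 2), severity="severe")]
        assert instance_accuracy(gold, gold) == 1.0

    def test_half(self):
        gold = [
            _inst("pain", (0, 2), severity="severe"),
            _inst("cough", (3, 5), severity="mild"),
        ]
        pred = [
            _inst("pain", (0, 2), severity="severe"),
            _inst("cough", (3, 5), severity="severe"),
        ]
        assert instance_accuracy(pred, gold) == 0.5

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            instance_accuracy([], [])


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(list("abab"), list("abab")) == 1.0

    def test_hand_computed_2x2(self):
        """Contingency table [[20,5],[10,15]]: kappa = 0.4."""
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohen_kappa(a, b) == pytest.approx(0.4)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(1)
        a = list(rng.integers(0, 2, size=4000))
        b = list(rng.integers(0, 2, size=4000))
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = list(rng.integers(0, 3, size=50))
            b = list(rng.integers(0, 3, size=50))
            if a == b:
                continue
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])


class TestMinCorpusSize:
    def test_every_doc_covers_everything(self):
        corpus = ["AAPP"] * 5
        mean, sd, counts = min_corpus_size(corpus, ["A+P"], n_reps=50, seed=0)
        assert (mean, sd) == (1.0, 0.0)

    def test_two_docs_disjoint_halves(self):
        corpus = ["AAP", "LNU"]
        mean, sd, _ = min_corpus_size(corpus, ["A+P", "S*LNU"], n_reps=50, seed=0)
        assert (mean, sd) == (2.0, 0.0)

    def test_matches_exhaustive_enumeration(self):
        corpus = ["AAP", "LNU", "AAPLNU", "PPPP", "SLR"]
        targets = ["A+P", "S*LNU", "S*LR"]
        exact = min_corpus_size_exact(corpus, targets)
        mean, sd, counts = min_corpus_size(corpus, targets, n_reps=4000, seed=3)
        se = sd / np.sqrt(len(counts))
        assert abs(mean - exact) <= 3 * se + 1e-9

    def test_unmatched_pattern_rejected(self):
        with pytest.raises(ValueError, match="matched nowhere"):
            min_corpus_size(["AAP"], ["S*LNU"], n_reps=5, seed=0)

    def test_mean_nonincreasing_when_docs_enriched(self):
        sparse = ["AAP", "LNU", "OOO", "OOO"]
        rich = ["AAPLNU", "AAPLNU", "OOO", "OOO"]
        targets = ["A+P", "S*LNU"]
        m1, _, _ = min_corpus_size(sparse, targets, n_reps=300, seed=1)
        m2, _, _ = min_corpus_size(rich, targets, n_reps=300, seed=1)
        assert m2 <= m1


class TestCompareInstanceSets:
    def test_identical(self):
        a = [_inst("cough", (0, 2), temporal_pattern="chronic")]
        shared, only_a, only_b = compare_instance_sets(a, a)
        assert len(shared) == 1 and not only_a and not only_b

    def test_subset(self):
        a = [_inst("cough", (0, 2), temporal_pattern="chronic")]
        b = a + [_inst("cough", (3, 5), temporal_pattern="recurrent")]
        shared, only_a, only_b = compare_instance_sets(a, b)
        assert not only_a and len(only_b) == 1

    def test_guideline_vs_records_example(self):
        guideline = [
            _inst("cough", (0, 2), temporal_pattern="chronic"),
            _inst("cough", (3, 5), temporal_pattern="recurrent"),
        ]
        records = guideline + [
            _inst("cough", (6, 8), temporal_pattern="occasional"),
            _inst("cough", (9, 11), severity="severe"),
        ]
        shared, only_a, only_b = compare_instance_sets(guideline, records)
        assert (len(shared), len(only_a), len(only_b)) == (2, 0, 2)

    def test_symmetry(self):
        a = [_inst("pain", (0, 2), severity="severe")]
        b = [_inst("fever", (0, 2))]
        s1, oa1, ob1 = compare_instance_sets(a, b)
        s2, oa2, ob2 = compare_instance_sets(b, a)
        assert s1 == s2 and oa1 == ob2 and ob1 == oa2


class TestEvaluateReport:
    def test_report_invariants(self, small_corpus, lexicon, library, lab_kb, schema):
        pred, gold = [], []
        for d in small_corpus[:10]:
            pred.extend(
                ph.recognize_document(
                    d.text, lexicon, library, lab_kb=lab_kb, schema=schema, doc_id=d.doc_id
                )
            )
            gold.extend(d.instances)
        report = evaluate(pred, gold, schema=schema)
        d = report.to_dict()
        for metric in (report.precision, report.recall, report.f1,
                       report.average_accuracy, report.weighted_accuracy,
                       report.instance_accuracy):
            assert 0.0 <= metric <= 1.0
        p, r = report.precision, report.recall
        expected_f1 = 2 * p * r / (p + r) if p + r else 0.0
        assert abs(report.f1 - expected_f1) < 1e-12
        assert report.to_markdown().startswith("# Evaluation report")
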