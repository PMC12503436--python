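"""Strict-match P/R/F1, confusion matrix, error taxonomy, splits, statistics."""

import numpy as np
import pytest

from drkex import (
    DocumentAnnotation,
    EntityType,
    ErrorProfile,
    GeneratorConfig,
    classify_errors,
    classify_errors_corpus,
    compute_prf,
    confusion_matrix,
    corpus_statistics,
    evaluate_extraction,
    generate_gold_corpus,
    harmonic_f1,
    perturb_prediction,
    split_corpus,
)

from conftest import make_doc


class TestPRF:
    def test_hand_arithmetic(self):
        assert compute_prf(3, 1, 2) == pytest.approx((0.75, 0.60, 2 / 3))

    def test_zero_convention(self):
        assert compute_prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_harmonic_identity_on_percentages(self):
        assert harmonic_f1(83.37, 79.64) == pytest.approx(81.46, abs=0.005)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_prf(-1, 0, 0)


class TestEvaluateExtraction:
    def test_identical_corpora_score_100(self, small_corpus):
        for level in ("entity", "triplet"):
            table = evaluate_extraction(small_corpus, small_corpus, level)
            assert table.overall.f1 == 1.0
            assert table.overall.fp == 0 and table.overall.fn == 0

    def test_boundary_error_is_not_a_true_positive(self):
        gold = [make_doc("d", "BRCA2 was analyzed.", entities=[("BRCA2", "gene")])]
        pred = [make_doc("d", gold[0].text, entities=[("BRCA2 mutations", "gene")])]
        row = evaluate_extraction(gold, pred, "entity").rows["gene"]
        assert (row.tp, row.fp, row.fn) == (0, 1, 1)
        assert row.f1 == 0.0

    def test_micro_pooling(self):
        # two docs pooling to tp=3, fp=1, fn=2
        gold = [
            make_doc("a", "x.", entities=[("Metformin", "drug"), ("melanoma", "disease"),
                                          ("nausea", "symptom")]),
            make_doc("b", "y.", entities=[("Imatinib", "drug"), ("fatigue", "symptom")]),
        ]
        pred = [
            make_doc("a", "x.", entities=[("Metformin", "drug"), ("melanoma", "disease")]),
            make_doc("b", "y.", entities=[("Imatinib", "drug"), ("liver", "anatomy")]),
        ]
        table = evaluate_extraction(gold, pred, "entity", "micro")
        assert (table.overall.tp, table.overall.fp, table.overall.fn) == (3, 1, 2)
        assert table.overall.precision == pytest.approx(0.75)

    def test_missing_prediction_counts_as_empty(self, small_corpus):
        table = evaluate_extraction(small_corpus, small_corpus[:4], "entity")
        assert table.overall.fn > 0 and table.overall.fp == 0

    def test_duplicate_doc_id_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            evaluate_extraction(small_corpus + small_corpus[:1], small_corpus)

    def test_agreement_with_set_intersection_oracle(self):
        """Pooled counts must equal a flat set-intersection computation."""
        rng = np.random.default_rng(123)
        corpus = generate_gold_corpus(GeneratorConfig(n_docs=30, seed=21))
        for trial in range(10):
            preds = [
                perturb_prediction(
                    d,
                    ErrorProfile(
                        entity_omission=float(rng.uniform(0, 0.4)),
                        entity_spurious=float(rng.uniform(0, 0.4)),
                        entity_type_swap=float(rng.uniform(0, 0.4)),
                    ),
                    seed=int(rng.integers(2**31)),
                )[0]
                for d in corpus
            ]
            table = evaluate_extraction(corpus, preds, "entity", "micro")
            gold_items = {
                (d.doc_id, k) for d in corpus for k in d.entity_keys()
            }
            pred_items = {
                (d.doc_id, k) for d in preds for k in d.entity_keys()
            }
            tp = len(gold_items & pred_items)
            fp = len(pred_items - gold_items)
            fn = len(gold_items - pred_items)
            assert (table.overall.tp, table.overall.fp, table.overall.fn) == (tp, fp, fn)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert table.overall.precision == pytest.approx(p)
            assert table.overall.f1 == pytest.approx(harmonic_f1(p, r))

    def test_micro_f1_cross_checked_against_sklearn(self):
        from sklearn.metrics import precision_recall_fscore_support

        corpus = generate_gold_corpus(GeneratorConfig(n_docs=15, seed=33))
        preds = [
            perturb_prediction(d, ErrorProfile(entity_omission=0.3, entity_spurious=0.3), seed=i)[0]
            for i, d in enumerate(corpus)
        ]
        table = evaluate_extraction(corpus, preds, "entity", "micro")
        gold_items = {(d.doc_id, k) for d in corpus for k in d.entity_keys()}
        pred_items = {(d.doc_id, k) for d in preds for k in d.entity_keys()}
        universe = sorted(gold_items | pred_items, key=repr)
        y_true = [int(u in gold_items) for u in universe]
        y_pred = [int(u in pred_items) for u in universe]
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0
        )
        assert table.overall.precision == pytest.approx(p)
        assert table.overall.recall == pytest.approx(r)
        assert table.overall.f1 == pytest.approx(f)


class TestConfusionMatrix:
    def test_type_confusion_cell(self):
        gold = [make_doc("d", "p53 activity.", entities=[("p53", "gene")])]
        pred = [make_doc("d", gold[0].text, entities=[("p53", "target")])]
        mat = confusion_matrix(gold, pred)
        assert mat.loc["gene", "target"] == 1
        assert mat.values.sum() == 1

    def test_identical_corpora_are_diagonal(self, small_corpus):
        mat = confusion_matrix(small_corpus, small_corpus)
        off = mat.values.sum() - np.trace(mat.values)
        assert off == 0
        assert np.trace(mat.values) == sum(len(d.entity_keys()) for d in small_corpus)

    def test_swap_confusions_confined_to_confusable_block(self):
        # corpus restricted to the semantically adjacent molecular types, so
        # every type swap must stay inside the confusable block
        corpus = generate_gold_corpus(
            GeneratorConfig(
                n_docs=25,
                seed=9,
                entity_mixture={"biomarker": 0.4, "gene": 0.4, "target": 0.2},
                relation_mixture={"increases_expression_of": 1.0},
                cross_sentence_fraction=0.0,
            )
        )
        preds = [
            perturb_prediction(d, ErrorProfile(entity_type_swap=0.5), seed=i)[0]
            for i, d in enumerate(corpus)
        ]
        mat = confusion_matrix(corpus, preds)
        allowed = {
            ("biomarker", "gene"), ("biomarker", "target"),
            ("gene", "biomarker"), ("gene", "target"),
            ("target", "biomarker"), ("target", "gene"),
            ("side_effect", "complication"), ("complication", "side_effect"),
        }
        for g in mat.index:
            for p in mat.columns:
                if g != p and (g, p) not in allowed:
                    assert mat.loc[g, p] == 0


class TestClassifyErrors:
    def test_spurious_phrase(self):
        gold = make_doc("d", "Available therapies are effective.", sentence_bounds=[(0, 34)])
        pred = make_doc("d", gold.text, entities=[("severe side effects", "side_effect")])
        counts = classify_errors(gold, pred)
        assert counts.entity["incorrect_extraction"] == 1

    def test_missing_entity(self):
        gold = make_doc(
            "d", "Other findings were extensive hemorrhage.",
            entities=[("extensive hemorrhage", "complication")],
            sentence_bounds=[(0, 41)],
        )
        pred = make_doc("d", gold.text)
        assert classify_errors(gold, pred).entity["missing_entity"] == 1

    def test_cross_sentence_missed_triplet(self):
        text = (
            "Subjects exhibited recurrent distress with nausea. "
            "Testing confirmed celiac disease."
        )
        gold = make_doc(
            "d", text,
            triplets=[("nausea", "symptom", "is_symptom_of", "celiac disease", "disease")],
            sentence_bounds=[(0, 50), (51, 84)],
        )
        pred = make_doc(
            "d", text,
            entities=[("nausea", "symptom"), ("celiac disease", "disease")],
        )
        counts = classify_errors(gold, pred)
        assert counts.triplet["cross_sentence_error"] == 1

    def test_conservation_of_items(self, gold_corpus):
        """Every gold and predicted entity lands in exactly one category."""
        for i, doc in enumerate(gold_corpus[:15]):
            pred, _ = perturb_prediction(
                doc,
                ErrorProfile(
                    entity_omission=0.2, entity_spurious=0.2,
                    entity_type_swap=0.2, entity_boundary_shift=0.2,
                ),
                seed=3000 + i,
            )
            c = classify_errors(doc, pred)
            gold_side = (
                c.entity_exact + c.entity["incorrect_type"]
                + c.entity["boundary_error"] + c.entity["missing_entity"]
            )
            pred_side = (
                c.entity_exact + c.entity["incorrect_type"]
                + c.entity["boundary_error"] + c.entity["incorrect_extraction"]
            )
            assert gold_side == len(doc.entities)
            assert pred_side == len(pred.entities)


class TestSplit:
    def test_sizes_partition_and_order(self, gold_corpus):
        train, test = split_corpus(gold_corpus, 0.8, seed=4)
        assert (len(train), len(test)) == (32, 8)
        ids = [d.doc_id for d in gold_corpus]
        assert [d.doc_id for d in train] == [i for i in ids if i in {d.doc_id for d in train}]
        assert {d.doc_id for d in train} | {d.doc_id for d in test} == set(ids)
        assert {d.doc_id for d in train} & {d.doc_id for d in test} == set()

    def test_full_fraction(self, small_corpus):
        train, test = split_corpus(small_corpus, 1.0, seed=0)
        assert len(train) == len(small_corpus) and test == []

    def test_seed_changes_membership(self, gold_corpus):
        memberships = {
            frozenset(d.doc_id for d in split_corpus(gold_corpus, 0.8, seed=s)[0])
            for s in range(100)
        }
        assert all(len(m) == 32 for m in memberships)
        assert len(memberships) > 90  # overwhelmingly distinct draws

    def test_determinism(self, gold_corpus):
        a = split_corpus(gold_corpus, 0.8, seed=12)
        b = split_corpus(gold_corpus, 0.8, seed=12)
        assert [d.doc_id for d in a[0]] == [d.doc_id for d in b[0]]


class TestCorpusStatistics:
    def test_hand_built_counts(self):
        docs = [
            make_doc(
                "a", "x.",
                entities=[("Metformin", "drug"), ("melanoma", "disease")],
                triplets=[("Metformin", "drug", "treat", "melanoma", "disease")],
            ),
            make_doc("b", "y.", entities=[("nausea", "symptom")]),
        ]
        st = corpus_statistics(docs)
        assert st.entity_counts["drug"] == 1
        assert st.entity_counts["disease"] == 1
        assert st.entity_counts["symptom"] == 1
        assert st.relation_counts["treat"] == 1
        assert st.entity_frequency("drug") == pytest.approx(1 / 3)

    def test_empty_corpus(self):
        st = corpus_statistics([])
        assert st.entity_total == 0
        assert all(v == 0 for v in st.entity_counts.values())
        assert st.entity_frequency("drug") == 0.0

    def test_frequencies_sum_to_one(self, gold_corpus):
        st = corpus_statistics(gold_corpus)
        assert sum(st.entity_shares().values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(st.relation_shares().values()) == pytest.approx(1.0, abs=1e-9)
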