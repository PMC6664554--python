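import numpy as np
import pytest

from plasmasig import (
    BaggedEnsemble,
    SignatureRule,
    TreeNode,
    TripleSignature,
    aggregate_signature,
    apply_signature,
    evaluate_signature,
    extract_tree_triple,
    fit_ensemble,
    refine_cutoffs,
    select_trees,
)
from plasmasig.benchmarks import PUBLISHED_SIGNATURE
from plasmasig.npx_core import NPXMatrix, SampleMetadata
from plasmasig.synthetic import CohortConfig, EffectSpec, generate_cohort

import pandas as pd


def _leaf(pred, counts, n, depth):
    return TreeNode(n_train=n, counts=counts, depth=depth, prediction=pred)


def _internal(pid, thr, gain, n, depth, left, right):
    return TreeNode(
        n_train=n, counts=(n // 2, n - n // 2), depth=depth, feature=0,
        protein_id=pid, threshold=thr, impurity_decrease=gain, left=left, right=right,
    )


def _depth3_tree():
    # P1@2.0 (gain .30) at the root, P2@1.5 (.20), P3@0.7 (.10) below
    leaf_a = _leaf(0, (5, 0), 5, 3)
    leaf_b = _leaf(1, (0, 5), 5, 3)
    p3 = _internal("P3", 0.7, 0.10, 10, 2, leaf_a, leaf_b)
    p2 = _internal("P2", 1.5, 0.20, 20, 1, p3, _leaf(1, (0, 10), 10, 2))
    root = _internal("P1", 2.0, 0.30, 40, 0, p2, _leaf(0, (20, 0), 20, 1))
    return root


class TestExtractTreeTriple:
    def test_ranked_by_impurity_decrease(self):
        triple = extract_tree_triple(_depth3_tree())
        assert [(t[0], t[1]) for t in triple] == [("P1", 2.0), ("P2", 1.5), ("P3", 0.7)]

    def test_best_group_size_is_largest_pure_positive_leaf(self):
        triple = extract_tree_triple(_depth3_tree())
        assert all(t[3] == 10 for t in triple)  # the pure (0,10) leaf

    def test_repeated_protein_kept_once_at_higher_gain(self):
        low = _internal("P1", 0.5, 0.05, 10, 1, _leaf(0, (5, 0), 5, 2), _leaf(1, (0, 5), 5, 2))
        root = _internal("P1", 3.0, 0.4, 20, 0, low, _leaf(1, (0, 10), 10, 1))
        triple = extract_tree_triple(root)
        assert len(triple) == 1
        assert triple[0][1] == 3.0

    def test_stump_returns_single_entry(self):
        stump = _internal("P9", 1.0, 0.2, 10, 0, _leaf(0, (5, 0), 5, 1), _leaf(1, (0, 5), 5, 1))
        assert len(extract_tree_triple(stump)) == 1

    def test_leaf_only_tree_returns_empty(self):
        assert extract_tree_triple(_leaf(1, (0, 4), 4, 0)) == []


def _signal_cohort(shifts, seed=0, groups=None):
    cfg = CohortConfig(
        group_sizes=groups or {"LAC": 80, "benign": 50},
        n_proteins=10,
        effects=tuple(EffectSpec(p, "LAC", s) for p, s in shifts.items()),
        seed=seed,
    )
    matrix, metadata, _, _ = generate_cohort(cfg)
    return matrix, metadata.groups()


class TestAggregateSignature:
    def test_recovers_injected_proteins(self):
        matrix, labels = _signal_cohort({"CXCL17": 2.0, "CEACAM5": 2.0, "VEGFR2": 2.0}, seed=21)
        ens = fit_ensemble(matrix.values, labels, n_trees=60, seed=22,
                           positive_class="LAC", protein_ids=matrix.protein_ids)
        ens = select_trees(ens, 30)
        sig = aggregate_signature(ens, matrix.values, labels, "LAC")
        assert set(sig.protein_ids) == {"CXCL17", "CEACAM5", "VEGFR2"}
        for rule in sig.rules:
            assert rule.direction == "above"
            assert 5.0 < rule.cutoff < 7.0  # between the group means

    def test_negative_shifts_give_below_rules(self):
        matrix, labels = _signal_cohort(
            {"CXCL17": -2.0, "CEACAM5": -2.0, "VEGFR2": -2.0}, seed=31
        )
        ens = fit_ensemble(matrix.values, labels, n_trees=60, seed=32,
                           positive_class="LAC", protein_ids=matrix.protein_ids)
        sig = aggregate_signature(ens, matrix.values, labels, "LAC")
        assert all(r.direction == "below" for r in sig.rules)

    def test_too_few_distinct_proteins_errors(self):
        stump = _internal("P1", 1.0, 0.2, 10, 0, _leaf(0, (5, 0), 5, 1), _leaf(1, (0, 5), 5, 1))
        ens = BaggedEnsemble(
            trees=[stump] * 5,
            bootstrap_indices=[np.arange(10)] * 5,
            oob_error_per_tree=np.zeros(5),
            tree_weights=np.ones(5),
            selected=np.ones(5, dtype=bool),
            classes=("benign", "LAC"),
            protein_ids=("P1", "P2"),
            seed=0,
        )
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array(["LAC"] * 5 + ["benign"] * 5)
        with pytest.raises(ValueError, match="only 1 distinct"):
            aggregate_signature(ens, X, y, "LAC")


class TestApplySignature:
    def test_published_cutoffs_conjunction(self):
        m = NPXMatrix(
            ("s1",), ("CEACAM5", "WFDC2", "TCL1A"),
            np.array([[5.0, 80.0, 9.0]]),
        )
        assert apply_signature(PUBLISHED_SIGNATURE, m)[0]

    def test_boundary_value_is_negative(self):
        m = NPXMatrix(
            ("s1",), ("CEACAM5", "WFDC2", "TCL1A"),
            np.array([[5.0, 80.0, 8.34]]),  # TCL1A exactly at cut-off
        )
        assert not apply_signature(PUBLISHED_SIGNATURE, m)[0]

    def test_very_low_values_negative_for_above_rules(self):
        m = NPXMatrix(
            ("s1",), ("CEACAM5", "WFDC2", "TCL1A"),
            np.array([[-1e300, -1e300, -1e300]]),
        )
        assert not apply_signature(PUBLISHED_SIGNATURE, m)[0]

    def test_missing_protein_rejected(self):
        m = NPXMatrix(("s1",), ("CEACAM5",), np.array([[5.0]]))
        with pytest.raises(KeyError):
            apply_signature(PUBLISHED_SIGNATURE, m)

    def test_raising_a_cutoff_shrinks_positive_set(self, rng):
        X = rng.normal(size=(200, 3)) * 2
        ids = ("A", "B", "C")
        base = TripleSignature(
            (SignatureRule("A", 0.0, "above"), SignatureRule("B", 0.0, "above"),
             SignatureRule("C", 0.0, "below")),
            positive_class="pos",
        )
        calls = apply_signature(base, X, ids)
        for delta in (0.5, 1.0, 2.0):
            tighter = TripleSignature(
                (SignatureRule("A", delta, "above"), base.rules[1], base.rules[2]),
                positive_class="pos",
            )
            tight_calls = apply_signature(tighter, X, ids)
            assert not np.any(tight_calls & ~calls)
            calls = tight_calls

    def test_conjunction_specificity_dominates_components(self, rng):
        X = rng.normal(size=(300, 3))
        ids = ("A", "B", "C")
        truth = rng.random(300) < 0.5
        sig = TripleSignature(
            (SignatureRule("A", 0.3, "above"), SignatureRule("B", -0.2, "above"),
             SignatureRule("C", 0.1, "below")),
            positive_class="pos",
        )
        conj = apply_signature(sig, X, ids)
        spec_conj = np.mean(~conj[~truth])
        for rule in sig.rules:
            single = rule.holds(X[:, ids.index(rule.protein_id)])
            assert spec_conj >= np.mean(~single[~truth]) - 1e-12


class TestEvaluateAndRoundTrip:
    def _toy(self):
        values = np.array([
            [6.0, 80.0, 9.0],   # fires
            [6.0, 80.0, 8.0],   # TCL1A too low
            [4.0, 70.0, 7.0],   # benign-like
            [4.5, 60.0, 6.0],
        ])
        m = NPXMatrix(("t1", "t2", "b1", "b2"), ("CEACAM5", "WFDC2", "TCL1A"), values)
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["t1", "t2", "b1", "b2"],
            "group": ["LAC", "LAC", "benign", "benign"],
        }))
        return m, meta

    def test_evaluate_counts(self):
        m, meta = self._toy()
        sig = TripleSignature(
            (SignatureRule("CEACAM5", 4.92, "above"), SignatureRule("WFDC2", 75.57, "above"),
             SignatureRule("TCL1A", 8.34, "above")),
            positive_class="LAC",
        )
        cm, metrics = evaluate_signature(sig, m, meta, "LAC", "benign")
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 2, 0)
        assert metrics.specificity == 1.0 and metrics.sensitivity == 0.5

    def test_signature_firing_on_nothing(self):
        m, meta = self._toy()
        sig = TripleSignature(
            (SignatureRule("CEACAM5", 100.0, "above"), SignatureRule("WFDC2", 100.0, "above"),
             SignatureRule("TCL1A", 100.0, "above")),
            positive_class="LAC",
        )
        cm, metrics = evaluate_signature(sig, m, meta, "LAC", "benign")
        assert metrics.specificity == 1.0 and metrics.sensitivity == 0.0

    def test_serialize_round_trip_identical_predictions(self, tmp_path, rng):
        X = rng.normal(size=(50, 3))
        ids = ("A", "B", "C")
        sig = TripleSignature(
            (SignatureRule("A", 0.1, "above"), SignatureRule("B", -0.4, "below"),
             SignatureRule("C", 0.2, "above")),
            positive_class="pos",
            provenance={"A": {"frequency": 3}},
        )
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = TripleSignature.from_json(path)
        np.testing.assert_array_equal(
            apply_signature(sig, X, ids), apply_signature(back, X, ids)
        )
        assert back.provenance == sig.provenance

    def test_refine_reaches_perfect_training_specificity(self):
        matrix, labels = _signal_cohort({"CXCL17": 2.0, "CEACAM5": 2.0, "VEGFR2": 2.0}, seed=41)
        ens = fit_ensemble(matrix.values, labels, n_trees=40, seed=42,
                           positive_class="LAC", protein_ids=matrix.protein_ids)
        sig = aggregate_signature(ens, matrix.values, labels, "LAC")
        refined = refine_cutoffs(sig, matrix.values, labels, matrix.protein_ids)
        pred = apply_signature(refined, matrix.values, matrix.protein_ids)
        assert not np.any(pred[labels == "benign"])
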