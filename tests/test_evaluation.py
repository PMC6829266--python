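"""Metric suite, cross-validation, independent test, candidate validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neglog.evaluation import (
    ConfusionMatrix,
    PairClassifier,
    co_annotation_counts,
    compute_metrics,
    cross_validate,
    f1_score,
    independent_test,
    roc_auc,
    validate_candidates,
)
from neglog.features import AnnotationStore
from neglog.io_formats import PairList
from neglog.synthetic import training_data


def binary_reference(tp, fn, fp, tn):
    """Textbook TP/FP/TN/FN formulas for the positive class."""
    pr = tp / (tp + fp) if tp + fp else 0.0
    se = tp / (tp + fn) if tp + fn else 0.0
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    acc = (tp + tn) / (tp + fn + fp + tn)
    return pr, se, mcc, acc


class TestComputeMetrics:
    def test_perfect_diagonal(self):
        rep = compute_metrics(ConfusionMatrix(m=[[40, 0], [0, 60]]))
        assert rep.acc == rep.overall_mcc == rep.f1_positive == 1.0
        for cm in rep.per_class.values():
            assert cm.precision == cm.sensitivity == cm.mcc == 1.0

    def test_binary_example_against_textbook_formulas(self):
        # rows: true positive class then true negative class
        rep = compute_metrics(ConfusionMatrix(m=[[40, 10], [5, 45]]))
        pos = rep.per_class[1]
        assert pos.precision == pytest.approx(40 / 45)
        assert pos.sensitivity == pytest.approx(40 / 50)
        assert rep.acc == pytest.approx(85 / 100)
        pr, se, mcc, acc = binary_reference(tp=40, fn=10, fp=5, tn=45)
        assert pos.mcc == pytest.approx(mcc)

    def test_zero_denominator_mcc_convention(self):
        rep = compute_metrics(ConfusionMatrix(m=[[3, 0], [2, 0]]))
        assert np.isfinite(rep.per_class[1].mcc)
        assert rep.per_class[-1].precision == 0.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_metrics(ConfusionMatrix(m=[[0, 0], [0, 0]]))

    @settings(max_examples=80, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4))
    def test_random_binary_matrices_match_reference(self, counts):
        tp, fn, fp, tn = counts
        if tp + fn + fp + tn == 0:
            return
        rep = compute_metrics(ConfusionMatrix(m=[[tp, fn], [fp, tn]]))
        pr, se, mcc, acc = binary_reference(tp, fn, fp, tn)
        pos = rep.per_class[1]
        assert pos.precision == pytest.approx(pr)
        assert pos.sensitivity == pytest.approx(se)
        assert pos.mcc == pytest.approx(mcc)
        assert rep.acc == pytest.approx(acc)
        assert rep.f1_positive == pytest.approx(f1_score(pr, se))

    def test_from_predictions_excludes_undetermined(self):
        cm = ConfusionMatrix.from_predictions(
            truth=[1, 1, -1, -1, 1], predicted=[1, 0, -1, 1, -1]
        )
        assert cm.n_undetermined == 1
        assert cm.m.sum() == 4
        assert cm.m[0, 0] == 1 and cm.m[1, 0] == 1 and cm.m[1, 1] == 1 and cm.m[0, 1] == 1


def auc_pair_counting(decisions, truth):
    """O(n^2) Mann-Whitney oracle with ties counted 1/2."""
    pos = [d for d, t in zip(decisions, truth) if t == 1]
    neg = [d for d, t in zip(decisions, truth) if t == -1]
    score = 0.0
    for p in pos:
        for n in neg:
            score += 1.0 if p > n else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_and_constant_scores(self):
        truth = [1, 1, -1, -1]
        assert roc_auc([0.9, 0.8, -0.8, -0.9], truth) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], truth) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_six_point_toy_matches_pair_counting(self):
        decisions = [0.9, 0.6, 0.6, -0.5, -0.6, 0.7]
        truth = [1, 1, -1, -1, -1, 1]
        assert roc_auc(decisions, truth) == pytest.approx(auc_pair_counting(decisions, truth))

    @settings(max_examples=60, deadline=None)
    @given(
        decisions=st.lists(
            st.floats(min_value=-1, max_value=1).map(lambda x: round(x, 2)),
            min_size=4, max_size=30,
        ),
        split=st.integers(min_value=1, max_value=29),
    )
    def test_matches_pair_counting_oracle(self, decisions, split):
        n = len(decisions)
        split = min(max(split, 1), n - 1)
        truth = [1] * split + [-1] * (n - split)
        assert roc_auc(decisions, truth) == pytest.approx(auc_pair_counting(decisions, truth))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        decisions = rng.normal(size=40)
        truth = np.where(rng.random(40) < 0.5, 1, -1)
        if len(set(truth)) < 2:
            truth[0] = -truth[0]
        assert roc_auc(np.tanh(3 * decisions), truth) == pytest.approx(roc_auc(decisions, truth))


class TestCrossValidate:
    def test_separable_synthetic_reaches_high_accuracy(self):
        from neglog.synthetic import generate_world

        world = generate_world(
            n_families=12, family_size=3, n_go_modules=8, terms_per_module=4,
            deficient_fraction=0.5, annotation_noise=0.0,
            interaction_rule_strength=1.0, n_seeds=400, rng_seed=11,
        )
        pos, neg, store, _ = training_data(world, rng_seed=11)
        rep = cross_validate(pos, neg, store, k=3, setting="combined", rng_seed=11)
        assert rep.acc > 0.9
        assert rep.roc_auc > 0.95
        # pooled counts: every determinate prediction lands in the matrix
        assert rep.n_undetermined == 0  # delta = 0 leaves nothing undetermined

    def test_target_setting_never_fits_homolog_model(self, small_world, monkeypatch):
        import neglog.evaluation as ev

        fitted_kinds = []
        orig = ev.train

        def spy(ts, C=1.0):
            fitted_kinds.append(ts.instance_kind)
            return orig(ts, C)

        monkeypatch.setattr(ev, "train", spy)
        pos, neg, store, _ = training_data(small_world, rng_seed=11)
        cross_validate(pos, neg, store, k=2, setting="target", rng_seed=0)
        assert set(fitted_kinds) == {"target"}

    def test_protein_level_split_runs(self, default_training):
        b = default_training
        rep = cross_validate(
            b["positives"], b["negatives"], b["store"],
            k=3, setting="target", rng_seed=4, split="protein",
        )
        assert 0.0 <= rep.acc <= 1.0

    def test_bad_k_rejected(self, small_world):
        pos, neg, store, _ = training_data(small_world, rng_seed=11)
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(pos, neg, store, k=1)


class TestIndependentTest:
    def _fitted(self, world_bundle):
        b = world_bundle
        return PairClassifier(setting="combined").fit(b["positives"], b["negatives"], b["store"])

    def test_leakage_guard_lists_offending_pairs(self, default_training):
        clf = self._fitted(default_training)
        with pytest.raises(ValueError, match="overlap the training set"):
            independent_test(clf, default_training["positives"], default_training["store"])

    def test_recall_matches_naive_per_pair_loop(self, default_world, default_training):
        from neglog.synthetic import heldout_curated_negatives

        clf = self._fitted(default_training)
        held = heldout_curated_negatives(default_world, 60, rng_seed=99)
        held = PairList(
            pairs=[p for p in held if p not in clf.training_pairs], label=-1
        )
        res = independent_test(clf, held, default_training["store"], delta=0.1)
        # naive re-scoring oracle, one pair at a time
        hits = det = 0
        for pair in held:
            _, lab = clf.predict([pair], default_training["store"], delta=0.1)
            if lab[0] != 0:
                det += 1
                hits += int(lab[0] == -1)
        assert res.recall == pytest.approx(hits / det if det else 0.0, abs=1e-12)
        assert res.fraction_undetermined == pytest.approx(1 - det / len(held))

    def test_unlabeled_test_list_rejected(self, default_training):
        clf = self._fitted(default_training)
        with pytest.raises(ValueError, match="label"):
            independent_test(clf, PairList(pairs=[("zz1", "zz2")]), default_training["store"])


class _ConstantClassifier(PairClassifier):
    """Scores every pair with a fixed decision value (test double)."""

    def __init__(self, d):
        super().__init__(setting="combined")
        self._d = d
        self.training_pairs = set()

    def decisions(self, pairs, store):
        return np.full(len(list(pairs)), self._d)


class TestValidateCandidates:
    def _frame(self):
        return pd.DataFrame(
            {
                "protein1": ["a", "b", "c", "d", "e"],
                "protein2": ["x", "y", "z", "w", "v"],
                "channel": ["textmining", "textmining", "cooccurrence", "cooccurrence", "textmining"],
                "score": [250, 150, 900, 700, 990],
            }
        )

    def test_all_positive_predictions_give_rate_one(self):
        clf = _ConstantClassifier(+0.99)
        out = validate_candidates(
            clf, self._frame(), {"textmining": 200, "cooccurrence": 800}, AnnotationStore()
        )
        assert out.rates() == {"textmining": 1.0, "cooccurrence": 1.0}
        # threshold filter: one textmining and one cooccurrence row dropped
        assert out.channels["textmining"].n_candidates == 2
        assert out.channels["cooccurrence"].n_candidates == 1

    def test_unknown_channel_errors(self):
        clf = _ConstantClassifier(+0.99)
        with pytest.raises(ValueError, match="cooccurrence"):
            validate_candidates(clf, self._frame(), {"textmining": 200}, AnnotationStore())

    def test_empty_candidate_file_errors(self, tmp_path):
        f = tmp_path / "cands.tsv"
        f.write_text("")
        clf = _ConstantClassifier(+0.99)
        with pytest.raises(Exception):
            validate_candidates(clf, f, {}, AnnotationStore())

    def test_rates_match_hand_computed_fractions(self, monkeypatch):
        clf = _ConstantClassifier(0.0)
        # hand-assigned decisions per (sorted) kept candidates
        assigned = {
            ("a", "x"): +0.9,   # positive
            ("e", "v"): -0.8,   # negative
            ("c", "z"): +0.55,  # undetermined at delta=0.1
        }

        def fake_decisions(pairs, store):
            return np.array([assigned[p] for p in pairs])

        monkeypatch.setattr(clf, "decisions", fake_decisions)
        frame = self._frame()
        out = validate_candidates(
            clf, frame, {"textmining": 200, "cooccurrence": 900}, AnnotationStore(), delta=0.1
        )
        tm = out.channels["textmining"]
        assert (tm.n_positive, tm.n_negative, tm.n_undetermined) == (1, 1, 0)
        assert tm.positive_rate == pytest.approx(0.5)
        cc = out.channels["cooccurrence"]
        assert (cc.n_positive, cc.n_negative, cc.n_undetermined) == (0, 0, 1)
        assert out.validated.pair_set == {("a", "x")}
        assert out.rejected.pair_set == {("e", "v")}


def test_co_annotation_counts(toy_store):
    counts = co_annotation_counts([("p1", "p2"), ("p1", "h1")], toy_store)
    assert counts[("p1", "p2")] == 1  # share GO:0000001
    assert counts[("h1", "p1")] == 0
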