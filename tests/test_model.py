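"""Forest scorer: split, grid, metrics vs brute-force oracles, cutoff rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tp53tx.model import (
    HyperParams,
    cross_validate,
    enrichment_test,
    evaluate_scores,
    fit_forest,
    hyperparameter_grid,
    predict_biallelic,
    select_best_model,
    select_cutoff,
    stratified_split,
    train_signature_model,
    TrainedSignatureModel,
)


def auroc_concordance_oracle(scores, labels):
    """Brute-force pairwise concordance: P(score_pos > score_neg) + 0.5 ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auprc_enumeration_oracle(scores, labels):
    """Step-integrated precision over recall via exhaustive thresholds."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = y.sum()
    thresholds = np.unique(s)[::-1]
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        called = s >= t
        tp = int((y[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestStratifiedSplit:
    def test_study_scale_proportions(self):
        """23 positives + 549 negatives split 7:3 -> 16/7 and ~384/165."""
        ids = [f"S{i}" for i in range(572)]
        labels = [1] * 23 + [0] * 549
        train, val = stratified_split(ids, labels, seed=0)
        pos = set(ids[:23])
        assert (len([s for s in train if s in pos]),
                len([s for s in val if s in pos])) == (16, 7)
        assert len(train) == 400 and len(val) == 172

    def test_partition_and_determinism(self):
        ids = [f"S{i}" for i in range(40)]
        labels = [1] * 8 + [0] * 32
        t1, v1 = stratified_split(ids, labels, seed=3)
        t2, v2 = stratified_split(ids, labels, seed=3)
        assert (t1, v1) == (t2, v2)
        assert set(t1) | set(v1) == set(ids)
        assert not set(t1) & set(v1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["a", "b", "c"], [1, 1, 1], seed=0)


class TestHyperparameterGrid:
    def test_grid_shape_for_16_genes(self):
        grid = hyperparameter_grid(16)
        trees = {p.n_trees for p in grid}
        fracs = {p.min_samples_leaf_fraction for p in grid}
        assert trees == set(range(2, 16))  # 14 values from the open interval
        assert len(fracs) == 19  # 0.05 steps over (0, 1)
        assert len(grid) == 14 * 19 * 19

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_grid(2)


class TestFitForest:
    PARAMS = HyperParams(10, 0.05, 0.05)

    def test_separable_toy_is_perfect(self):
        X = np.array([[0.1], [0.2], [0.3], [0.9], [1.0], [1.1]])
        y = [0, 0, 0, 1, 1, 1]
        forest = fit_forest(X, y, self.PARAMS, seed=0)
        assert evaluate_scores(forest.predict(X), y).auroc == 1.0

    def test_permuted_labels_near_chance(self):
        aurocs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 4))
            y = np.array([1] * 20 + [0] * 60)
            r.shuffle(y)
            if y[:40].sum() in (0, 40):
                continue
            forest = fit_forest(X[:40], y[:40], self.PARAMS, seed=seed)
            aurocs.append(evaluate_scores(forest.predict(X[40:]), y[40:]).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_degenerate_leaf_collapses_to_label_mean(self):
        X = np.linspace(0, 1, 40).reshape(-1, 1)
        y = np.array([0] * 20 + [1] * 20)
        forest = fit_forest(X, y, HyperParams(5, 0.99, 0.99), seed=0)
        assert np.allclose(forest.predict(X), y.mean(), atol=0.15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_forest(np.zeros((4, 2)), [1, 1, 1, 1], self.PARAMS, seed=0)

    def test_scores_within_unit_interval(self, rng):
        X = rng.normal(size=(60, 3))
        y = (rng.random(60) < 0.3).astype(int)
        y[0], y[1] = 0, 1
        forest = fit_forest(X, y, self.PARAMS, seed=1)
        s = forest.predict(X)
        assert (s >= 0).all() and (s <= 1).all()


class TestEvaluateScores:
    def test_perfect_and_inverted(self):
        y = [0, 0, 1, 1]
        assert evaluate_scores([0.1, 0.2, 0.8, 0.9], y).auroc == 1.0
        assert evaluate_scores([0.1, 0.2, 0.8, 0.9], y).auprc == 1.0
        assert evaluate_scores([0.9, 0.8, 0.2, 0.1], y).auroc == 0.0

    def test_matches_brute_force_oracles(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 16))
            y = np.zeros(n, int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # rounding forces score ties
            ev = evaluate_scores(s, y)
            assert ev.auroc == pytest.approx(auroc_concordance_oracle(s, y), abs=1e-12)
            assert ev.auprc == pytest.approx(auprc_enumeration_oracle(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores([0.1, 0.9], [1, 1])


class TestSelectBestModel:
    P = HyperParams

    def test_highest_auprc_wins(self):
        evaluated = [(self.P(5, 0.1, 0.1), 0.9, 0.6), (self.P(7, 0.1, 0.1), 0.9, 0.7)]
        params, _, auprc, ok = select_best_model(evaluated)
        assert params.n_trees == 7 and auprc == 0.7 and ok

    def test_auroc_floor_enforced(self):
        evaluated = [(self.P(5, 0.1, 0.1), 0.7, 0.9), (self.P(7, 0.1, 0.1), 0.85, 0.6)]
        params, auroc, _, ok = select_best_model(evaluated)
        assert params.n_trees == 7 and auroc == 0.85 and ok

    def test_no_member_passes_floor_warns(self):
        evaluated = [(self.P(5, 0.1, 0.1), 0.7, 0.9), (self.P(7, 0.1, 0.1), 0.6, 0.6)]
        params, _, _, ok = select_best_model(evaluated)
        assert params.n_trees == 5 and not ok

    def test_tie_breaks_fewer_trees_then_larger_leaf(self):
        evaluated = [
            (self.P(25, 0.1, 0.1), 0.9, 0.7),
            (self.P(5, 0.1, 0.1), 0.9, 0.7),
            (self.P(5, 0.3, 0.1), 0.9, 0.7),
        ]
        params, _, _, _ = select_best_model(evaluated)
        assert (params.n_trees, params.min_samples_leaf_fraction) == (5, 0.3)


class TestCrossValidate:
    def test_strong_signal_all_folds_high(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (150, 4)), rng.normal(2, 0.3, (30, 4))])
        y = np.array([0] * 150 + [1] * 30)
        aurocs = cross_validate(X, y, HyperParams(10, 0.05, 0.05), k=5, seed=0)
        assert len(aurocs) == 5
        assert min(aurocs) > 0.8

    def test_too_few_positives_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError):
            cross_validate(X, y, HyperParams(5, 0.1, 0.1), k=5, seed=0)


class TestCutoffRule:
    def test_worked_example(self):
        scores = [0.7, 0.4, 0.9, 0.3, 0.1]
        labels = [1, 1, 0, 0, 0]
        cutoff = select_cutoff(scores, labels)
        assert cutoff == 0.4
        pred = np.asarray(scores) >= cutoff
        y = np.asarray(labels)
        assert pred[y == 1].mean() == 1.0          # sensitivity
        assert (~pred[y == 0]).mean() == pytest.approx(2 / 3)  # specificity

    def test_separable_case_full_specificity(self):
        cutoff = select_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert cutoff == 0.8

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
        st.data(),
    )
    def test_sensitivity_always_one_on_deriving_set(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) == 0:
            labels[0] = 1
        cutoff = select_cutoff(scores, labels)
        pred = np.asarray(scores) >= cutoff
        assert pred[np.asarray(labels) == 1].all()

    def test_tightening_cutoff_never_adds_positives(self, rng):
        scores = rng.random(50)
        n1 = (scores >= 0.3).sum()
        n2 = (scores >= 0.5).sum()
        assert n2 <= n1


class TestPredict:
    def _model(self):
        X = pd.DataFrame(
            {"g1": [0.1, 0.2, 0.9, 1.0], "g2": [0.0, 0.1, 0.8, 0.9]},
            index=["a", "b", "c", "d"],
        )
        y = pd.Series([0, 0, 1, 1], index=X.index)
        forest = fit_forest(X.to_numpy(), y, HyperParams(5, 0.05, 0.05), seed=0)
        return TrainedSignatureModel(
            signature_genes=["g1", "g2"], params=HyperParams(5, 0.05, 0.05),
            forest=forest, cutoff=0.5, seed=0,
        )

    def test_boundary_score_is_predicted_biallelic(self):
        model = self._model()
        feats = pd.DataFrame({"g1": [0.95], "g2": [0.85]}, index=["q"])
        model.cutoff = float(model.score(feats)[0])  # score == cutoff exactly
        pred = predict_biallelic(model, feats)
        assert pred.loc[0, "predicted_label"] == "predicted_biallelic"

    def test_missing_gene_named_in_error(self):
        model = self._model()
        feats = pd.DataFrame({"g1": [0.5]}, index=["q"])
        with pytest.raises(KeyError, match="g2"):
            predict_biallelic(model, feats)

    def test_empty_discovery_set(self):
        pred = predict_biallelic(self._model(), pd.DataFrame())
        assert pred.empty


class TestEnrichment:
    def test_flat_table_null(self):
        stat, p = enrichment_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        # margins 25/25, expected 12.5 in each cell: sum (O-E)^2/E = 18
        stat, _ = enrichment_test([[20, 5], [5, 20]])
        assert stat == pytest.approx(18.0)

    def test_row_swap_invariant(self):
        a, _ = enrichment_test([[20, 5], [5, 20]])
        b, _ = enrichment_test([[5, 20], [20, 5]])
        assert a == pytest.approx(b)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[0, 0], [5, 20]])


class TestTrainEndToEnd:
    def test_random_scorer_auprc_near_prevalence(self, rng):
        """AUPRC of a random scorer converges to the positive prevalence."""
        vals = []
        for _ in range(100):
            y = (rng.random(500) < 0.1).astype(int)
            if y.sum() == 0:
                continue
            s = rng.random(500)
            vals.append(evaluate_scores(s, y).auprc)
        assert np.mean(vals) == pytest.approx(0.1, abs=0.02)

    def test_trained_model_recovers_planted_signal(self, small_cohort):
        from tp53tx.expression import log_transform

        truth = small_cohort.ground_truth.set_index("sample_id")["true_status"]
        bi = truth[truth == "biallelic"].index.tolist()
        wt = truth[truth == "WT"].index.tolist()
        labels = pd.Series(0, index=bi + wt, dtype=int)
        labels.loc[bi] = 1
        genes = [f"SIG{k + 1:03d}" for k in range(16)]
        model = train_signature_model(
            log_transform(small_cohort.expression), genes, labels, seed=0,
            fraction_values=(0.05, 0.45), tree_values=(5, 10),
        )
        assert model.validation_auroc > 0.9
        assert model.cutoff is not None
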