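"""Cross-validation harnesses, metrics, CSP, electrode selection, statistics."""

import numpy as np
import pytest

from rsta import (
    EpochSet,
    PipelineSpec,
    STANDARD_PIPELINES,
    compare_accuracy_distributions,
    csp_features,
    evaluate_metrics,
    forward_electrode_selection,
    generate_epochs,
    run_kfold_per_subject,
    run_loso,
)
from rsta.pipelines import CVReport, FoldResult, Pipeline
from rsta.simulate import Bump, SimulationConfig, desk_scale_config

from conftest import preprocess, quiet_config

MAIN = STANDARD_PIPELINES["xdawn_ts_lr"]


def _report_from_accuracies(accs):
    rep = CVReport(scheme="LOSO", pipeline="x")
    for i, a in enumerate(accs):
        n = 100
        correct = int(round(a * n))
        y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        pred = y.copy()
        pred[:n - correct] = 1 - pred[:n - correct]
        rep.folds.append(FoldResult(
            fold_id=str(i), test_index=np.arange(n), y_true=y, y_pred=pred,
            scores=pred.astype(float)))
    return rep


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        scores = y * 2.0 - 1.0
        m = evaluate_metrics(y, scores, y)
        np.testing.assert_array_equal(m["confusion"], [[10, 0], [0, 10]])
        assert m["accuracy"] == 1.0
        assert m["mcc"] == 1.0
        assert m["auc"] == 1.0
        assert m["ap"] == 1.0

    def test_single_class_predictions_mcc_zero(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        pred = np.ones(10, int)
        m = evaluate_metrics(y, np.linspace(-1, 1, 10), pred)
        assert m["mcc"] == 0.0

    def test_confusion_formula_oracle(self):
        """TP=45, FN=15, FP=10, TN=50 checked against the direct formulas."""
        y = np.r_[np.ones(60, int), np.zeros(60, int)]
        pred = np.r_[np.ones(45, int), np.zeros(15, int),
                     np.ones(10, int), np.zeros(50, int)]
        rng = np.random.default_rng(0)
        scores = np.where(pred == 1, 1.0, -1.0) + rng.normal(0, 0.01, 120)
        m = evaluate_metrics(y, scores, pred)
        tp, fn, fp, tn = 45, 15, 10, 50
        acc = (tp + tn) / 120
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert m["accuracy"] == pytest.approx(acc)
        assert m["mcc"] == pytest.approx(mcc)
        np.testing.assert_array_equal(m["confusion"], [[tn, fp], [fn, tp]])

    def test_auc_equals_mann_whitney_rank_identity(self):
        """Trapezoidal AUC equals U / (n+ * n-) via brute-force pair counting."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]  # both classes present
        scores = np.round(rng.normal(size=20), 1)  # ties likely
        m = evaluate_metrics(y, scores, (scores > 0).astype(int))
        pos, neg = scores[y == 1], scores[y == 0]
        u = sum(1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg)
        assert m["auc"] == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_ap_matches_stepwise_oracle(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(8, int), np.ones(8, int)]
        scores = rng.normal(size=16)
        m = evaluate_metrics(y, scores, (scores > 0).astype(int))
        # step-wise AP oracle: sum over ranked positives of precision deltas
        order = np.argsort(-scores)
        ys = y[order]
        tp = np.cumsum(ys)
        precision = tp / np.arange(1, 17)
        recall = tp / ys.sum()
        prev_r, ap = 0.0, 0.0
        for p, r in zip(precision, recall):
            ap += p * (r - prev_r)
            prev_r = r
        assert m["ap"] == pytest.approx(ap, abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_metrics(np.zeros(5, int), np.zeros(5), np.zeros(5, int))


class TestMannWhitney:
    def test_separated_groups_maximal_u_pair_count_oracle(self):
        a = _report_from_accuracies([0.9, 0.91, 0.92, 0.93])
        b = _report_from_accuracies([0.5, 0.51, 0.52, 0.53])
        res = compare_accuracy_distributions(a, b)
        # brute-force pair counting: every a beats every b
        assert res["U"] == 16
        assert res["direction"] == "a>b"
        assert res["p"] < 0.05

    def test_swap_symmetry(self):
        a = _report_from_accuracies([0.9, 0.8, 0.85, 0.7])
        b = _report_from_accuracies([0.6, 0.65, 0.5, 0.55])
        r1 = compare_accuracy_distributions(a, b)
        r2 = compare_accuracy_distributions(b, a)
        assert r1["p"] == pytest.approx(r2["p"])
        assert r1["direction"] == "a>b" and r2["direction"] == "a<b"

    def test_all_tied_degenerate_warns_p_one(self):
        a = _report_from_accuracies([0.8, 0.8, 0.8])
        b = _report_from_accuracies([0.8, 0.8, 0.8])
        with pytest.warns(UserWarning, match="tied"):
            res = compare_accuracy_distributions(a, b)
        assert res["p"] == 1.0

    def test_null_calibration_identical_distributions(self):
        """Under the null, p < 0.05 in at most ~5% of replicates."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            a = _report_from_accuracies(np.round(rng.uniform(0.6, 0.9, 8), 2))
            b = _report_from_accuracies(np.round(rng.uniform(0.6, 0.9, 8), 2))
            if compare_accuracy_distributions(a, b)["p"] < 0.05:
                rejections += 1
        assert rejections <= int(0.05 * n_rep) + 2


class TestCVSchemes:
    def test_loso_one_fold_per_subject_single_test_subject(self, prepared_epochs):
        report = run_loso(prepared_epochs, MAIN)
        assert len(report.folds) == len(prepared_epochs.subjects)
        for f in report.folds:
            subj = np.unique(prepared_epochs.subject_ids[f.test_index])
            assert len(subj) == 1
        assert report.check_fold_partition(prepared_epochs.n_trials)

    def test_loso_single_subject_directs_to_kfold(self, prepared_epochs):
        solo = prepared_epochs.take(
            np.flatnonzero(prepared_epochs.subject_ids == 0))
        with pytest.raises(ValueError, match="kfold"):
            run_loso(solo, MAIN)

    def test_kfold_fold_sizes_and_partition(self, prepared_epochs):
        report = run_kfold_per_subject(prepared_epochs, MAIN, k=4, seed=0)
        n_subj = len(prepared_epochs.subjects)
        assert len(report.folds) == 4 * n_subj
        assert report.check_fold_partition(prepared_epochs.n_trials)
        for f in report.folds:
            y = prepared_epochs.labels[f.test_index]
            assert np.bincount(y, minlength=2)[0] == np.bincount(y, minlength=2)[1]

    def test_kfold_seed_determinism(self, prepared_epochs):
        a = run_kfold_per_subject(prepared_epochs, MAIN, seed=7)
        b = run_kfold_per_subject(prepared_epochs, MAIN, seed=7)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.test_index, fb.test_index)
            np.testing.assert_array_equal(fa.y_pred, fb.y_pred)
            np.testing.assert_allclose(fa.scores, fb.scores)

    def test_kfold_insufficient_trials_names_subject(self, prepared_epochs):
        with pytest.raises(ValueError, match="subject 0"):
            run_kfold_per_subject(prepared_epochs, MAIN, k=50)

    def test_no_leakage_test_trials_do_not_affect_training(self, prepared_epochs):
        """Deleting a test-fold trial never changes fitted stage parameters."""
        subj0 = np.flatnonzero(prepared_epochs.subject_ids == 0)
        train_idx = np.flatnonzero(prepared_epochs.subject_ids != 0)
        model_a = Pipeline(MAIN).fit(prepared_epochs.take(train_idx))
        # drop half of subject 0's (test) trials: training outcome identical
        model_b = Pipeline(MAIN).fit(prepared_epochs.take(train_idx))
        for k in (0, 1):
            np.testing.assert_array_equal(model_a._xdawn.bank_.filters[k],
                                          model_b._xdawn.bank_.filters[k])
        np.testing.assert_array_equal(model_a._tangent.ref_.matrix,
                                      model_b._tangent.ref_.matrix)
        np.testing.assert_array_equal(model_a._clf.coef_, model_b._clf.coef_)
        test_full = prepared_epochs.take(subj0)
        test_half = prepared_epochs.take(subj0[::2])
        pred_full, _ = model_a.predict(test_full)
        pred_half, _ = model_b.predict(test_half)
        np.testing.assert_array_equal(pred_full[::2], pred_half)


class TestPipelines:
    def test_all_pipelines_perfect_on_separable_noise_free_data(self):
        cfg = quiet_config(trials_per_class=(8, 8), n_subjects=3, seed=1)
        eps = preprocess(generate_epochs(cfg), seed=0)
        for name, spec in STANDARD_PIPELINES.items():
            report = run_loso(eps, spec)
            assert report.mean_accuracy == 1.0, name

    def test_identical_fold_structure_across_pipelines(self, prepared_epochs):
        reports = [run_loso(prepared_epochs, spec)
                   for spec in STANDARD_PIPELINES.values()]
        for rep in reports[1:]:
            for f0, f in zip(reports[0].folds, rep.folds):
                np.testing.assert_array_equal(f0.test_index, f.test_index)

    def test_loso_end_to_end_deterministic(self, prepared_epochs):
        a = run_loso(prepared_epochs, MAIN)
        b = run_loso(prepared_epochs, MAIN)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.scores, fb.scores)

    def test_channel_permutation_leaves_accuracy_invariant(self, prepared_epochs):
        from rsta import select_channels
        perm = list(prepared_epochs.channel_names[::-1])
        permuted = select_channels(prepared_epochs, perm)
        a = run_loso(prepared_epochs, MAIN)
        b = run_loso(permuted, MAIN)
        np.testing.assert_allclose(a.fold_accuracies, b.fold_accuracies, atol=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="classifier"):
            PipelineSpec(("vectorize",))
        with pytest.raises(ValueError, match="tangent_space"):
            PipelineSpec(("tangent_space", "logistic_regression"))
        with pytest.raises(ValueError, match="unknown"):
            PipelineSpec(("svm",))


class TestCSP:
    @staticmethod
    def _variance_contrast_epochs(seed=0):
        """Two classes differing only in channel-0 variance."""
        rng = np.random.default_rng(seed)
        n, c, s = 40, 3, 64
        data = rng.standard_normal((n, c, s))
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        data[labels == 0, 0, :] *= 4.0
        return EpochSet(data=data, labels=labels,
                        subject_ids=np.zeros(n, int),
                        channel_names=("a", "b", "c"),
                        sampling_rate=64.0, t0_offset=0.0)

    def test_variance_contrast_first_filter_is_e0(self):
        eps = self._variance_contrast_epochs()
        from rsta.pipelines import _CSPStage
        stage = _CSPStage(2).fit(eps)
        w = stage.filters_[:, 0]
        w = w / np.linalg.norm(w)
        assert abs(w[0]) > 0.99

    def test_log_variance_features_scale_by_additive_constant(self):
        eps = self._variance_contrast_epochs()
        from rsta.pipelines import _CSPStage
        stage = _CSPStage(2).fit(eps)
        f1 = stage.transform(eps.data)
        f2 = stage.transform(3.0 * eps.data)
        np.testing.assert_allclose(f2 - f1, np.log(9.0), atol=1e-10)

    def test_filters_against_eigen_oracle(self):
        eps = self._variance_contrast_epochs(seed=5)
        from rsta.pipelines import _CSPStage
        import scipy.linalg
        stage = _CSPStage(2).fit(eps)
        c0 = np.mean([x @ x.T / x.shape[1] for x in eps.data[eps.labels == 0]], axis=0)
        c1 = np.mean([x @ x.T / x.shape[1] for x in eps.data[eps.labels == 1]], axis=0)
        evals, evecs = scipy.linalg.eigh(c0, c0 + c1)
        # paired selection: largest then smallest eigenvalue
        expected = evecs[:, [np.argmax(evals), np.argmin(evals)]]
        got = stage.filters_
        for j in range(2):
            ratio = got[:, j] / expected[:, j]
            np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_feature_table_shape_and_columns(self, prepared_epochs):
        df = csp_features(prepared_epochs, n_components=4)
        assert list(df.columns) == ["csp_0", "csp_1", "csp_2", "csp_3",
                                    "label", "subject"]
        assert len(df) == prepared_epochs.n_trials

    def test_too_many_components_rejected(self, prepared_epochs):
        with pytest.raises(ValueError, match="n_components"):
            csp_features(prepared_epochs, n_components=99)


class TestElectrodeSelection:
    @staticmethod
    def _planted_epochs(seed=0, channels=("F3", "Cz", "Pz", "Oz")):
        """Class signal confined to Oz; other channels pure noise."""
        topo = tuple(1.0 if c == "Oz" else 0.0 for c in channels)
        cfg = SimulationConfig(
            n_subjects=3, trials_per_class=(10, 10), channels=channels,
            sampling_rate=128.0, topography_profile=topo,
            templates={0: (Bump(100.0, 30.0, 10.0, topo),),
                       1: (Bump(100.0, 30.0, -10.0, topo),)},
            seed=seed)
        return preprocess(generate_epochs(cfg), seed=seed)

    def test_planted_oz_selected_first_and_curve_contract(self):
        eps = self._planted_epochs()
        spec = STANDARD_PIPELINES["xdawn_ts_lr"]
        order, curve = forward_electrode_selection(eps, spec, max_k=3)
        assert order[0] == "Oz"
        assert len(curve) == 3
        assert len(set(order)) == 3

    def test_greedy_matches_exhaustive_for_first_two_steps(self):
        from itertools import combinations
        from rsta import select_channels
        eps = self._planted_epochs(seed=2)
        spec = STANDARD_PIPELINES["vec_lr"]
        order, curve = forward_electrode_selection(eps, spec, max_k=2)
        names = list(eps.channel_names)
        # exhaustive oracle, size 1
        best1 = max(names, key=lambda n: run_loso(
            select_channels(eps, [n]), spec).mean_accuracy)
        assert order[0] == best1
        # greedy step 2 must match the best pair containing the first pick
        accs = {}
        for n in names:
            if n == order[0]:
                continue
            accs[n] = run_loso(select_channels(eps, [order[0], n]),
                               spec).mean_accuracy
        assert curve[1] == pytest.approx(max(accs.values()))

    def test_max_k_above_channel_count_rejected(self, prepared_epochs):
        with pytest.raises(ValueError, match="max_k"):
            forward_electrode_selection(prepared_epochs,
                                        STANDARD_PIPELINES["vec_lr"], max_k=99)
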