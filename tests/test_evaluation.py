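import numpy as np
import pytest
import scipy.stats

import mvbiomarkers as mv
from mvbiomarkers.evaluation import (
    CVConfig,
    auc_score,
    auxiliary_size_sweep,
    confusion_metrics,
    default_grids,
    fit_self_model,
    grid_search,
    grid_size,
    make_folds,
    paired_accuracy_ttest,
    run_protocol,
)


def small_cohort(delta=2.0, seed=9, n_aux=40, n_tgt=20):
    spec = mv.CohortSpec(
        n_per_group={"AD": n_aux, "NC": n_aux, "pMCI": n_tgt, "sMCI": n_tgt},
        d=20, delta=delta, rho=0.7, n_informative=8, seed=seed,
    )
    c = mv.generate_cohort(spec)
    aux = c.subset(np.isin(c.group_labels, ["AD", "NC"]))
    tgt = c.subset(np.isin(c.group_labels, ["pMCI", "sMCI"]))
    return aux, tgt


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics(["p", "s", "p"], ["p", "s", "p"], "p")
        assert (m.acc, m.sen, m.spe) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        m = confusion_metrics(["p", "s", "s"], ["p", "p", "p"], "p")
        assert m.sen == 1.0 and m.spe == 0.0

    def test_hand_confusion_table(self):
        y_true = ["p"] * 4 + ["s"] * 4
        y_pred = ["p", "p", "p", "s", "s", "s", "p", "p"]  # TP=3 FN=1 TN=2 FP=2
        m = confusion_metrics(y_true, y_pred, "p")
        assert m.acc == pytest.approx(0.625)
        assert m.sen == pytest.approx(0.75)
        assert m.spe == pytest.approx(0.5)

    def test_undefined_metric_is_nan_not_zero(self):
        m = confusion_metrics(["s", "s"], ["s", "p"], "p")
        assert np.isnan(m.sen) and m.spe == 0.5


class TestAucScore:
    def test_perfect_and_inverted(self):
        y = ["p", "p", "s", "s"]
        assert auc_score(y, [4, 3, 2, 1], "p") == 1.0
        assert auc_score(y, [1, 2, 3, 4], "p") == 0.0

    def test_tie_matches_pairwise_oracle(self):
        y = np.array(["p", "p", "p", "s", "s", "s"])
        s = np.array([3.0, 2.0, 1.0, 3.0, 0.5, 0.2])  # one cross-class tie
        wins = halves = 0
        for sp in s[y == "p"]:
            for sn in s[y == "s"]:
                wins += sp > sn
                halves += sp == sn
        expect = (wins + 0.5 * halves) / 9
        assert auc_score(y, s, "p") == pytest.approx(expect)

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(4, 30))
            y = rng.choice(["p", "s"], size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding makes ties likely
            assert auc_score(y, s, "p") == pytest.approx(
                roc_auc_score((y == "p").astype(int), s)
            )

    def test_single_class_flagged(self):
        assert np.isnan(auc_score(["p", "p"], [1.0, 2.0], "p"))


class TestMakeFolds:
    def test_even_split(self):
        cfg = CVConfig(n_folds=10, base_seed=1)
        folds = make_folds(["a"] * 10 + ["b"] * 10, cfg, 0)
        counts = np.bincount(folds, minlength=10)
        assert np.all(counts == 2)

    def test_deterministic(self):
        cfg = CVConfig(base_seed=3)
        labels = ["a"] * 12 + ["b"] * 8
        np.testing.assert_array_equal(make_folds(labels, cfg, 4), make_folds(labels, cfg, 4))
        assert not np.array_equal(make_folds(labels, cfg, 4), make_folds(labels, cfg, 5))

    def test_stratified_balance(self):
        cfg = CVConfig(n_folds=10, base_seed=2)
        labels = np.array(["pos"] * 12 + ["neg"] * 8)
        folds = make_folds(labels, cfg, 0)
        pos_counts = [np.sum((folds == f) & (labels == "pos")) for f in range(10)]
        assert max(pos_counts) - min(pos_counts) <= 1
        with pytest.warns(UserWarning, match="samples"):
            make_folds(labels, cfg, 1)  # class of 8 < 10 folds warns

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(["a"] * 5, CVConfig(n_folds=10), 0)


class TestPairedTtest:
    def test_identical_vectors_give_p_one(self):
        assert paired_accuracy_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]) == 1.0

    def test_textbook_t_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.zeros(4)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        expect = 2 * scipy.stats.t.sf(abs(t), df=3)
        assert paired_accuracy_ttest(a, b) == pytest.approx(expect, rel=1e-12)
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_symmetry(self, rng):
        a = rng.uniform(size=10)
        b = rng.uniform(size=10)
        assert paired_accuracy_ttest(a, b) == pytest.approx(paired_accuracy_ttest(b, a))

    def test_constant_nonzero_difference(self):
        assert paired_accuracy_ttest([0.8, 0.8], [0.7, 0.7]) == 0.0


class TestRunProtocol:
    def test_deterministic_given_seeds(self):
        aux, tgt = small_cohort()
        hp = mv.HyperParams(k_ct=5, k_cv=5)
        cfg = CVConfig(n_repeats=2, base_seed=7)
        r1 = run_protocol(aux, tgt, hp, cfg)
        r2 = run_protocol(aux, tgt, hp, cfg)
        assert [m.acc for m in r1.per_repeat] == [m.acc for m in r2.per_repeat]
        assert r1.mean.auc == r2.mean.auc

    def test_mean_is_arithmetic_mean_and_acc_pooled(self):
        aux, tgt = small_cohort()
        cfg = CVConfig(n_repeats=3, base_seed=1)
        res = run_protocol(aux, tgt, mv.HyperParams(k_ct=5, k_cv=5), cfg)
        assert res.mean.acc == pytest.approx(np.mean([m.acc for m in res.per_repeat]), abs=1e-12)
        n = tgt.X_CT.shape[1]
        for m in res.per_repeat:  # pooled predictions make acc a multiple of 1/n
            assert (m.acc * n) == pytest.approx(round(m.acc * n), abs=1e-9)

    def test_single_class_target_rejected(self):
        aux, tgt = small_cohort()
        bad = tgt.subset(tgt.group_labels == "pMCI")
        with pytest.raises(ValueError):
            run_protocol(aux, bad, mv.HyperParams(), CVConfig())

    def test_self_protocol_runs_and_differs_from_auxiliary(self):
        aux, tgt = small_cohort()
        hp = mv.HyperParams(k_ct=5, k_cv=5)
        cfg = CVConfig(n_repeats=2, base_seed=7, n_folds=5)
        ra = run_protocol(aux, tgt, hp, cfg, protocol="auxiliary")
        rs = run_protocol(aux, tgt, hp, cfg, protocol="self")
        assert rs.protocol == "self" and ra.protocol == "auxiliary"

    def test_self_protocol_no_leakage(self):
        """Perturbing held-out columns does not change the fold model."""
        _, tgt = small_cohort()
        views = mv.evaluation.as_labeled_views(tgt)
        train_idx = np.arange(0, 30)
        m1 = fit_self_model(views, train_idx, mv.HyperParams(k_ct=5, k_cv=5))
        corrupted = mv.evaluation.LabeledViews(
            views.X_CT.copy(), views.X_CV.copy(), views.labels.copy()
        )
        corrupted.X_CT[:, 30:] = 1e6
        corrupted.X_CV[:, 30:] = -1e6
        m2 = fit_self_model(corrupted, train_idx, mv.HyperParams(k_ct=5, k_cv=5))
        np.testing.assert_array_equal(m1.pair.U, m2.pair.U)
        np.testing.assert_array_equal(m1.pair.V, m2.pair.V)
        np.testing.assert_array_equal(m1.scaler_ct.scale_, m2.scaler_ct.scale_)


class TestGrids:
    def test_reference_grid_cardinality(self):
        grids = default_grids()
        assert [len(grids[k]) for k in ("lam", "alpha", "beta", "k_ct", "k_cv", "eta")] == [9, 5, 3, 7, 7, 18]
        assert grid_size() == 119_070

    def test_singleton_grid_equals_direct_run(self):
        aux, tgt = small_cohort()
        cfg = CVConfig(n_repeats=2, base_seed=4)
        grids = {"lam": [0.5], "alpha": [0.1], "beta": [1.0], "k_ct": [5], "k_cv": [5], "eta": [0.3]}
        table = grid_search(aux, tgt, grids, cfg, screening_repeats=2)
        assert len(table) == 1
        direct = run_protocol(aux, tgt, mv.HyperParams(lam=0.5, alpha=0.1, beta=1.0, k_ct=5, k_cv=5, eta=0.3), cfg)
        assert table.loc[0, "mean_acc"] == pytest.approx(direct.mean.acc)

    def test_rows_ranked_by_accuracy(self):
        aux, tgt = small_cohort()
        cfg = CVConfig(n_repeats=2, base_seed=4)
        grids = {"lam": [0.2, 0.8], "alpha": [0.1], "beta": [1.0], "k_ct": [5], "k_cv": [5], "eta": [0.1, 0.9]}
        table = grid_search(aux, tgt, grids, cfg, screening_repeats=2)
        accs = table["mean_acc"].to_numpy()
        assert np.all(accs[:-1] >= accs[1:])

    def test_empty_grid_rejected(self):
        aux, tgt = small_cohort()
        with pytest.raises(ValueError):
            grid_search(aux, tgt, {"lam": []}, CVConfig())


class TestAuxiliarySizeSweep:
    def test_full_size_single_resample_matches_direct_run(self):
        aux, tgt = small_cohort(n_aux=20)
        hp = mv.HyperParams(k_ct=5, k_cv=5)
        cfg = CVConfig(n_repeats=2, base_seed=3)
        table = auxiliary_size_sweep(aux, tgt, hp, cfg, sizes=(40,), n_resamples=1)
        direct = run_protocol(aux, tgt, hp, cfg)
        assert table.loc[0, "mean_acc"] == pytest.approx(direct.mean.acc)

    def test_balance_constraints_enforced(self):
        aux, tgt = small_cohort(n_aux=20)
        hp = mv.HyperParams()
        with pytest.raises(ValueError, match="even"):
            auxiliary_size_sweep(aux, tgt, hp, CVConfig(), sizes=(7,))
        with pytest.raises(ValueError, match="available"):
            auxiliary_size_sweep(aux, tgt, hp, CVConfig(), sizes=(100,))

    def test_deterministic(self):
        aux, tgt = small_cohort(n_aux=20)
        hp = mv.HyperParams(k_ct=3, k_cv=3)
        cfg = CVConfig(n_repeats=1, base_seed=5)
        t1 = auxiliary_size_sweep(aux, tgt, hp, cfg, sizes=(20,), n_resamples=2)
        t2 = auxiliary_size_sweep(aux, tgt, hp, cfg, sizes=(20,), n_resamples=2)
        assert t1.loc[0, "mean_acc"] == t2.loc[0, "mean_acc"]
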