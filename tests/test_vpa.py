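"""Concentration-prediction branch: importance, ComBat, eGPR, CCC."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathtdm.cohort import CohortConfig, simulate_feature_table_inputs, truth_to_feature_table
from breathtdm.vpa import (
    combat_adjust,
    combine_and_select,
    exponential_kernel,
    filter_drug_features,
    fit_egpr,
    forest_importance,
    lin_ccc,
    pathway_activity_ratio,
    predict_egpr,
    rrelieff_weights,
    screen_regressors,
)


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient

class TestLinCCC:
    def test_identity_gives_one(self, rng):
        x = rng.random(50)
        assert lin_ccc(x, x).ccc == pytest.approx(1.0)

    def test_reversed_sequence_gives_minus_one(self):
        # equal means and s_xy = -s_x^2 -> ccc = -1
        assert lin_ccc([1, 2, 3], [3, 2, 1]).ccc == pytest.approx(-1.0)

    def test_doubling_case_equals_4_over_11(self):
        # x=(1,2,3), y=2x: s_xy=4/3, s_x2=2/3, s_y2=8/3, (dmu)^2=4
        # ccc = (8/3)/(2/3+8/3+4) = 4/11
        assert lin_ccc([1, 2, 3], [2, 4, 6]).ccc == pytest.approx(4 / 11)

    def test_degenerate_conventions(self):
        assert lin_ccc([2.0, 2.0], [2.0, 2.0]).ccc == 1.0
        assert lin_ccc([2.0, 2.0], [1.0, 3.0]).ccc == 0.0

    def test_matches_direct_formula_on_random_pairs(self, rng):
        for _ in range(200):
            x, y = rng.normal(size=20), rng.normal(size=20)
            res = lin_ccc(x, y)
            expected = (2 * np.cov(x, y, bias=True)[0, 1]
                        / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))
            assert res.ccc == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_ccc_magnitude_never_exceeds_pearson(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=15), r.normal(size=15)
        res = lin_ccc(x, y)
        assert abs(res.ccc) <= abs(res.pearson_r) + 1e-12

    def test_ccc_equals_pearson_when_moments_match(self, rng):
        x = rng.normal(size=2000)
        y = np.roll(x, 1)  # same marginal moments, weaker correlation
        res = lin_ccc(x, y)
        assert res.ccc == pytest.approx(
            res.pearson_r * 2 * x.std() * y.std()
            / (x.var() + y.var() + (x.mean() - y.mean()) ** 2))


# ---------------------------------------------------------------------------
# presence filter + importance

def test_drug_presence_filter_counts():
    truth, _ = simulate_feature_table_inputs(CohortConfig(n_subjects=10, seed=2))
    table = truth_to_feature_table(truth)
    sub = filter_drug_features(table, min_presence=0.8)
    drug_ids = set(truth.features.index[truth.features["kind"] == "drug"])
    # endogenous features are present everywhere so they pass; the point is
    # that no drug feature is lost among VPA takers
    assert drug_ids <= set(sub.values.columns)

    # hand case: feature present in 9/10 vs 7/10 VPA measurements
    vals = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)},
                        index=[f"m{i}" for i in range(10)])
    pres = vals.astype(bool).copy()
    pres.iloc[0, 0] = False                      # a: 9/10
    pres.iloc[:3, 1] = False                     # b: 7/10
    obs = pd.DataFrame({"on_vpa": True, "subject_id": "s"}, index=vals.index)
    var = pd.DataFrame({"mz": [100.0, 200.0]}, index=["a", "b"])
    from breathtdm.traces import FeatureTable
    t = FeatureTable(vals, obs, var, pres)
    kept = filter_drug_features(t, min_presence=0.8)
    assert list(kept.values.columns) == ["a"]

    with pytest.raises(ValueError):
        filter_drug_features(t, on_vpa=np.zeros(10, bool))


class TestRReliefF:
    def test_signal_feature_ranks_first(self, rng):
        n = 200
        X = rng.normal(size=(n, 10))
        y = 3 * X[:, 0] ** 2 + X[:, 0]
        w = rrelieff_weights(X, y, k_neighbors=10, seed=0)
        assert np.argmax(w) == 0

    def test_duplicated_columns_get_equal_weights(self, rng):
        X = rng.normal(size=(60, 3))
        X = np.column_stack([X, X[:, 0]])
        y = X[:, 0] + rng.normal(size=60) * 0.1
        w = rrelieff_weights(X, y, k_neighbors=8, seed=1)
        assert w[0] == pytest.approx(w[3], abs=1e-12)

    def test_constant_target_gives_zero_weights(self, rng):
        X = rng.normal(size=(50, 4))
        w = rrelieff_weights(X, np.ones(50), k_neighbors=5)
        assert np.allclose(w, 0.0)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            rrelieff_weights(rng.normal(size=(10, 2)), rng.normal(size=10),
                             k_neighbors=10)


class TestForestImportance:
    def test_signal_feature_dominates(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(150, 10))
            y = 2 * X[:, 0] + r.normal(size=150) * 0.3
            imp = forest_importance(X, y, n_trees=60, seed=seed)
            hits += int(np.argmax(imp) == 0)
        assert hits >= 9

    def test_constant_target_gives_negligible_importance(self, rng):
        X = rng.normal(size=(80, 5))
        imp = forest_importance(X, np.full(80, 3.0), n_trees=40, seed=0)
        assert np.all(np.abs(imp) < 1e-9)


class TestCombineAndSelect:
    def test_agreeing_rankers(self):
        rep = combine_and_select([1.0, 0.0], [1.0, 0.0], cutoff=0.1)
        assert list(rep.table["combined_weight"]) == [1.0, 0.0]
        assert list(rep.table["selected"]) == [True, False]

    def test_disagreeing_rankers_renormalised(self):
        # scaled (1,0) and (0,1) -> mean (0.5,0.5) -> renormalised (1,1)
        rep = combine_and_select([1.0, 0.0], [0.0, 1.0], cutoff=0.1)
        assert list(rep.table["combined_weight"]) == [1.0, 1.0]
        assert rep.table["selected"].all()

    def test_cutoff_is_strict(self):
        rep = combine_and_select([1.0, 0.0], [1.0, 0.0], cutoff=1.0)
        assert not rep.table["selected"].any()

    def test_uninformative_ranker_contributes_half(self):
        rep = combine_and_select([0.5, 0.5], [1.0, 0.0], cutoff=0.1)
        # relief all-equal -> 0.5 each; combined = (0.75, 0.25) -> /0.75
        assert rep.table["combined_weight"].iloc[0] == pytest.approx(1.0)
        assert rep.table["combined_weight"].iloc[1] == pytest.approx(0.25 / 0.75)


# ---------------------------------------------------------------------------
# batch adjustment

class TestCombat:
    def test_single_batch_identity(self, rng):
        X = rng.normal(size=(12, 5))
        out = combat_adjust(X, ["B1"] * 12)
        assert np.allclose(out, X, atol=1e-10)

    def test_additive_shift_removed(self, rng):
        n = 200
        base = rng.normal(size=(2 * n, 6))
        shift = np.array([2.0, -1.5, 3.0, 0.5, -2.5, 1.0])
        X = base.copy()
        X[n:] += shift
        batches = ["A"] * n + ["B"] * n
        before = np.abs(X[:n].mean(0) - X[n:].mean(0))
        out = combat_adjust(X, batches)
        after = np.abs(out[:n].mean(0) - out[n:].mean(0))
        assert np.all(after < 0.05 * before)

    def test_variance_homogenised_on_null_features(self):
        from scipy import stats
        ok = 0
        n_feat = 60
        r = np.random.default_rng(7)
        X = r.normal(size=(120, n_feat))
        X[60:] *= 1.8  # scale batch effect
        out = combat_adjust(X, ["A"] * 60 + ["B"] * 60)
        for j in range(n_feat):
            p = stats.levene(out[:60, j], out[60:, j]).pvalue
            ok += int(p > 0.05)
        assert ok / n_feat >= 0.90

    def test_exact_mode_idempotent(self, rng):
        X = rng.normal(size=(80, 10))
        X[40:] += 1.0
        batches = ["A"] * 40 + ["B"] * 40
        once = combat_adjust(X, batches, parametric=False)
        twice = combat_adjust(once, batches, parametric=False)
        rel = np.linalg.norm(twice - once) / np.linalg.norm(once)
        assert rel < 1e-6

    def test_eb_mode_approaches_idempotence_with_batch_size(self, rng):
        # EB shrinkage under-corrects on purpose, so a second parametric
        # pass still moves the data a little; the leftover shrinks with n
        rels = []
        for n in (50, 400):
            X = rng.normal(size=(2 * n, 8))
            X[n:] += rng.normal(0, 2, size=8)
            b = ["A"] * n + ["B"] * n
            once = combat_adjust(X, b)
            twice = combat_adjust(once, b)
            rels.append(np.linalg.norm(twice - once) / np.linalg.norm(once))
        assert rels[1] < rels[0] < 0.05

    def test_small_batch_rejected_with_name(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="B2"):
            combat_adjust(X, ["B1"] * 4 + ["B2"])

    def test_matches_reference_bioconductor_implementation(self, tmp_path):
        """Cross-check the empirical-Bayes adjustment against sva::ComBat."""
        rng = np.random.default_rng(3)
        X = np.round(rng.normal(5, 2, size=(8, 5)), 4)
        X[4:] += 1.5
        batches = [1, 1, 1, 1, 2, 2, 2, 2]
        mine = combat_adjust(X, batches)

        r_script = tmp_path / "combat.R"
        xs = ",".join(repr(float(v)) for v in X.T.ravel())  # features x samples
        r_script.write_text(
            "suppressMessages(library(sva))\n"
            f"X <- matrix(c({xs}), nrow={X.shape[1]}, byrow=TRUE)\n"
            f"batch <- c({','.join(map(str, batches))})\n"
            "out <- ComBat(dat=X, batch=batch, par.prior=TRUE)\n"
            "cat(format(t(out), digits=15), sep='\\n')\n"
        )
        res = subprocess.run(["Rscript", str(r_script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = np.array([float(v) for v in res.stdout.split()]).reshape(
            X.shape, order="F")
        assert np.allclose(mine, ref, atol=1e-8)


# ---------------------------------------------------------------------------
# exponential-kernel GP regression

class TestEgpr:
    def test_interpolates_training_points_at_low_noise(self, rng):
        X = rng.uniform(-2, 2, size=(25, 2))
        y = np.abs(np.sin(X[:, 0]) + 0.5 * X[:, 1]) * 10
        model = fit_egpr(X, y, n_restarts=4, seed=0)
        pred = predict_egpr(model, X)
        if model.sigma_n2 < 1e-6:
            assert np.allclose(pred, np.clip(y, 0, None), atol=1e-4)
        # even with estimated noise the fit must track the targets closely
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_kernel_identities(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 0.0]])
        K = exponential_kernel(x, x, sigma_f2=2.5, length_scale=1.3)
        assert np.allclose(np.diag(K), 2.5)
        d01 = np.linalg.norm(x[0] - x[1])
        d02 = np.linalg.norm(x[0] - x[2])
        assert d01 < d02 and K[0, 1] > K[0, 2]

    def test_predictions_never_negative(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)  # includes negative targets
        model = fit_egpr(X, y, n_restarts=2, seed=1)
        assert (predict_egpr(model, rng.normal(size=(50, 3))) >= 0).all()

    def test_recovers_programmed_vpa_on_held_out_subjects(self):
        cfg = CohortConfig(n_subjects=75, visits_per_subject=2, noise_cv=0.1,
                           seed=9)
        truth, _ = simulate_feature_table_inputs(cfg)
        table = truth_to_feature_table(truth)
        drug = list(truth.features.index[truth.features["kind"] == "drug"])
        X = table.values[drug].values
        y = table.obs["total_vpa_mgL"].values
        n_tr = 100
        model = fit_egpr(X[:n_tr], y[:n_tr], n_restarts=4, seed=0)
        pred = predict_egpr(model, X[n_tr:])
        assert lin_ccc(y[n_tr:], pred).ccc >= 0.8


def test_screen_regressors_contract(rng):
    X = rng.uniform(-2, 2, size=(60, 3))
    y = np.exp(-np.abs(X[:, 0])) * 20 + rng.normal(size=60)
    tab = screen_regressors(X, y, folds=4, seeds=(0,))
    assert set(tab["family"]) == {"egpr", "ridge", "bagged_trees"}
    assert tab["ccc_mean"].is_monotonic_decreasing
    with pytest.raises(ValueError):
        screen_regressors(X, y, folds=100)


def test_pathway_activity_ratio():
    from breathtdm.traces import FeatureTable
    vals = pd.DataFrame({"num": [20.0, 10.0, 5.0], "den": [10.0, 0.0, 2.0]},
                        index=["m1", "m2", "m3"])
    obs = pd.DataFrame({"subject_id": ["s1", "s1", "s2"]}, index=vals.index)
    var = pd.DataFrame({"mz": [115.1, 143.1]}, index=["num", "den"])
    t = FeatureTable(vals, obs, var, vals > 0)
    ratio, per_subject = pathway_activity_ratio(t, "num", "den")
    assert ratio["m1"] == pytest.approx(2.0)
    assert np.isnan(ratio["m2"])  # zero denominator -> missing
    assert per_subject.loc["s1", "n_visits"] == 1  # m2 excluded
    assert per_subject.loc["s2", "median"] == pytest.approx(2.5)
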