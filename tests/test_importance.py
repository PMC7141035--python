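import numpy as np
import pandas as pd
import pytest

import phyloldg as pl
from phyloldg.importance import (ModelSpec, _great_circle_km, morans_i,
                                 prune_predictors, rf_importance, vif)


def _design(n=200, seed=0, p=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"x{i + 1}" for i in range(p)]), rng


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 400
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        v = vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert v["x1"] == pytest.approx(1.0, abs=1e-12)
        assert v["x2"] == pytest.approx(1.0, abs=1e-12)

    def test_correlation_point_nine_closed_form(self):
        # construct sample correlation exactly 0.9 via orthonormal basis
        n = 100
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, n))
        a = (a - a.mean()) / np.linalg.norm(a - a.mean())
        b -= b.mean() + (b - b.mean()) @ a * a
        b /= np.linalg.norm(b)
        x2 = 0.9 * a + np.sqrt(1 - 0.81) * b
        v = vif(pd.DataFrame({"x1": a, "x2": x2}))
        assert v["x1"] == pytest.approx(1 / (1 - 0.81), abs=1e-3)

    def test_perfect_collinearity_infinite(self):
        df, _ = _design(50, 2, 2)
        df["x3"] = 2.0 * df["x1"]
        v = vif(df)
        assert np.isinf(v["x1"]) and np.isinf(v["x3"])

    def test_constant_column_named(self):
        df, _ = _design(50, 3, 2)
        df["flat"] = 7.0
        with pytest.raises(ValueError, match="flat"):
            vif(df)


class TestPrunePredictors:
    def test_noise_predictor_dropped_by_aic(self):
        # response = x1 + eps; x2 pure noise. Backward AIC removes a noise
        # predictor iff its chi2(1) deviance gain is < 2, i.e. with
        # probability P(chi2_1 < 2) ~ 0.843 — so expect ~84/100, never the
        # signal predictor dropped.
        hits = 0
        for seed in range(100):
            X, rng = _design(200, seed, 2)
            data = X.assign(y=X["x1"] + rng.normal(0, 1, 200))
            log = prune_predictors(data, ModelSpec("y", ("x1", "x2"), seed=seed))
            assert "x1" in log.retained
            if log.retained == ("x1",) and log.dropped == (("x2", "AIC"),):
                hits += 1
        assert hits >= 70

    def test_collinear_pair_resolved_by_vif(self):
        X, rng = _design(100, 7, 1)
        X["x3"] = X["x1"] + rng.normal(0, 1e-4, 100)
        data = X.assign(y=X["x1"] + X["x3"] + rng.normal(0, 2.0, 100))
        log = prune_predictors(data, ModelSpec("y", ("x1", "x3"), seed=7,
                                               prune_order="vif-then-aic"))
        vif_drops = [nm for nm, why in log.dropped if why == "VIF"]
        assert len(vif_drops) == 1 and vif_drops[0] in ("x1", "x3")

    def test_single_candidate_untouched(self):
        X, rng = _design(50, 0, 1)
        data = X.assign(y=X["x1"] * 2 + rng.normal(0, 0.5, 50))
        log = prune_predictors(data, ModelSpec("y", ("x1",), seed=0))
        assert log.retained == ("x1",) and log.dropped == ()

    def test_too_few_cases_rejected(self):
        X, rng = _design(5, 0, 3)
        data = X.assign(y=rng.normal(size=5))
        with pytest.raises(ValueError):
            prune_predictors(data, ModelSpec("y", ("x1", "x2", "x3"), seed=0))


class TestRfImportance:
    def test_max_importance_is_exactly_one(self):
        X, rng = _design(120, 3, 3)
        data = X.assign(y=X["x1"] + rng.normal(0, 0.5, 120))
        res = rf_importance(data, ["x1", "x2", "x3"], ModelSpec("y", ("x1", "x2", "x3"), seed=3))
        assert res.importance.max() == 1.0
        assert (res.importance >= 0).all()

    def test_signal_dominates_noise_across_seeds(self):
        # response = 3*x1 + eps, x2/x3 noise: x1 tops, noise stays < 0.3
        for seed in range(20):
            X, rng = _design(300, seed, 3)
            data = X.assign(y=3.0 * X["x1"] + rng.normal(0, 1, 300))
            res = rf_importance(data, ["x1", "x2", "x3"],
                                ModelSpec("y", ("x1", "x2", "x3"), seed=seed))
            assert res.importance["x1"] == 1.0
            assert res.importance["x2"] < 0.3 and res.importance["x3"] < 0.3

    def test_symmetric_contributions_both_high(self):
        X, rng = _design(300, 11, 2)
        data = X.assign(y=X["x1"] + X["x2"])
        res = rf_importance(data, ["x1", "x2"], ModelSpec("y", ("x1", "x2"), seed=11))
        assert res.importance.min() > 0.5

    def test_bitwise_reproducible_for_fixed_seed(self):
        X, rng = _design(150, 5, 3)
        data = X.assign(y=X["x1"] - X["x2"] + rng.normal(0, 1, 150))
        spec = ModelSpec("y", ("x1", "x2", "x3"), seed=99)
        r1 = rf_importance(data, ["x1", "x2", "x3"], spec)
        r2 = rf_importance(data, ["x1", "x2", "x3"], spec)
        assert (r1.importance == r2.importance).all()
        assert np.array_equal(r1.oob_residuals, r2.oob_residuals)

    def test_leakage_canary_warns(self):
        X, rng = _design(100, 0, 2)
        data = X.assign(y=X["x1"])
        with pytest.warns(UserWarning, match="leakage"):
            res = rf_importance(data, ["x1", "x2"], ModelSpec("y", ("x1", "x2"), seed=0))
        assert res.importance["x1"] == 1.0

    def test_zero_variance_response_rejected(self):
        X, _ = _design(50, 0, 2)
        data = X.assign(y=1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            rf_importance(data, ["x1", "x2"], ModelSpec("y", ("x1", "x2"), seed=0))


def _transect(n=10):
    """Evenly spaced points along the equator; (lon, lat) pairs."""
    return np.column_stack([np.arange(n, dtype=float), np.zeros(n)])


class TestMoransI:
    def test_alternating_transect_nearest_class_is_minus_one(self):
        # 45 pairs, 9 nearest-neighbor; 5 equal-count classes put exactly
        # the nearest-neighbor pairs in class 0
        coords = _transect(10)
        values = np.tile([1.0, -1.0], 5)
        res = morans_i(values, coords, n_classes=5, n_perm=99, seed=0)
        assert res[0].n_pairs == 9
        assert res[0].I == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_positive_and_significant(self):
        coords = _transect(20)
        values = np.linspace(0, 1, 20)
        res = morans_i(values, coords, n_classes=5, n_perm=999, seed=1)
        assert res[0].I > 0
        assert res[0].p_value <= 0.05

    def test_double_loop_oracle_equality(self):
        rng = np.random.default_rng(8)
        n = 25
        coords = np.column_stack([rng.uniform(82, 130, n), rng.uniform(19, 52, n)])
        values = rng.normal(size=n)
        res = morans_i(values, coords, n_classes=4, n_perm=9, seed=0)
        d = _great_circle_km(coords)
        z = values - values.mean()
        for cls in res:
            num = s0 = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    lo_ok = d[i, j] >= cls.d_lo if cls.k > 0 else d[i, j] >= cls.d_lo - 1e-9
                    if lo_ok and (d[i, j] < cls.d_hi or
                                  (cls.k == len(res) - 1 and d[i, j] <= cls.d_hi)):
                        num += z[i] * z[j]
                        s0 += 1.0
            expected = (n / s0) * num / (z @ z)
            assert cls.I == pytest.approx(expected, abs=1e-12)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(12), _transect(12), n_classes=2, n_perm=9, seed=0)

    def test_haversine_against_spherical_law_of_cosines(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(-180, 180, 30), rng.uniform(-60, 60, 30)])
        d = _great_circle_km(pts)
        lam, phi = np.radians(pts[:, 0]), np.radians(pts[:, 1])
        for i in range(0, 30, 7):
            for j in range(0, 30, 5):
                cosd = (np.sin(phi[i]) * np.sin(phi[j])
                        + np.cos(phi[i]) * np.cos(phi[j]) * np.cos(lam[i] - lam[j]))
                expected = 6371.0 * np.arccos(np.clip(cosd, -1, 1))
                assert d[i, j] == pytest.approx(expected, abs=1e-6)


class TestRunImportanceStage:
    def test_stage_composition_and_report_bookkeeping(self):
        rng = np.random.default_rng(21)
        n = 120
        data = pd.DataFrame({
            "lon": rng.uniform(82, 130, n), "lat": rng.uniform(19, 52, n),
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        })
        data["y"] = 2 * data["x1"] + rng.normal(0, 0.5, n)
        spec = ModelSpec("y", ("x1", "x2", "x3"), seed=21, moran_permutations=199)
        rep = pl.run_importance_stage(data, spec)
        accounted = set(rep.retained) | {nm for nm, _ in rep.dropped}
        assert accounted == {"x1", "x2", "x3"}
        assert max(rep.importance.values()) == 1.0
        assert rep.seed == 21

    def test_null_residual_autocorrelation_is_calibrated(self):
        # iid response: per-class Moran tests should reject at ~alpha, and
        # the joint independence flag should hold for most seeds
        flags, n_sig, n_classes = 0, 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 80
            data = pd.DataFrame({
                "lon": rng.uniform(82, 130, n), "lat": rng.uniform(19, 52, n),
                "x1": rng.normal(size=n), "x2": rng.normal(size=n),
            })
            data["y"] = data["x1"] + rng.normal(0, 1, n)
            rep = pl.run_importance_stage(
                data, ModelSpec("y", ("x1", "x2"), seed=seed,
                                moran_permutations=199))
            flags += rep.residuals_spatially_independent
            for m in rep.moran:
                if not m.empty:
                    n_classes += 1
                    n_sig += m.p_value < 0.05
        assert n_sig <= 0.15 * n_classes   # per-class size near nominal 5%
        assert flags >= 5                  # familywise: most seeds fully clean
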