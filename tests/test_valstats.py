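"""Validation statistics: spike estimators, nested variance components
(with a numerical REML oracle), linear range and fold-change accuracy."""
import numpy as np
import pytest
from scipy import optimize, stats

import lcmsqc as L
from lcmsqc.valstats import NoLinearRangeError, SpikeGroups

from conftest import nested_lognormal


class TestRecoveryRate:
    def test_perfect_recovery(self):
        g = SpikeGroups(mean_a=220.0, mean_b=220.0, mean_c=200.0, mean_d=20.0)
        assert L.recovery_rate(g) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        g = SpikeGroups(mean_a=184.0, mean_b=220.0, mean_c=200.0, mean_d=20.0)
        assert L.recovery_rate(g) == pytest.approx(0.82)

    def test_background_dominates_spike_error(self):
        g = SpikeGroups(mean_a=100.0, mean_b=50.0, mean_c=10.0, mean_d=50.0)
        with pytest.raises(ValueError):
            L.recovery_rate(g)

    @pytest.mark.parametrize("k", [0.1, 3.0, 1e4])
    def test_rescaling_invariance(self, k):
        g = SpikeGroups(184.0, 220.0, 200.0, 20.0)
        gk = SpikeGroups(184.0 * k, 220.0 * k, 200.0 * k, 20.0 * k)
        assert L.recovery_rate(gk) == pytest.approx(L.recovery_rate(g))
        assert L.matrix_effect(gk)[0] == pytest.approx(L.matrix_effect(g)[0])


class TestMatrixEffect:
    @pytest.mark.parametrize(
        "b,d,c,me,band",
        [
            (120.0, 20.0, 100.0, 1.0, "none"),
            (70.0, 10.0, 100.0, 0.60, "medium"),
            (140.0, 20.0, 100.0, 1.20, "enhancement"),
            (90.0, 10.0, 100.0, 0.80, "weak"),
            (45.0, 10.0, 100.0, 0.35, "strong"),
        ],
    )
    def test_value_and_band(self, b, d, c, me, band):
        got_me, got_band = L.matrix_effect(SpikeGroups(100.0, b, c, d))
        assert got_me == pytest.approx(me)
        assert got_band == band

    def test_zero_solvent_blank_error(self):
        with pytest.raises(ValueError):
            L.matrix_effect(SpikeGroups(10.0, 10.0, 0.0, 1.0))


def reml_oracle(y: np.ndarray) -> tuple[float, float, float]:
    """Numerical REML for the balanced nested model via explicit covariance.

    Independent of the mean-squares path: builds V(theta) for the vectorized
    data, evaluates the restricted log-likelihood with dense linear algebra
    and maximizes it numerically.
    """
    n_b, n_e, n_r = y.shape
    n = y.size
    yv = y.reshape(-1)
    X = np.ones((n, 1))
    Zb = np.zeros((n, n_b))
    Ze = np.zeros((n, n_b * n_e))
    idx = 0
    for b in range(n_b):
        for e in range(n_e):
            for r in range(n_r):
                Zb[idx, b] = 1.0
                Ze[idx, b * n_e + e] = 1.0
                idx += 1

    def neg_restricted_ll(log_theta):
        s2b, s2e, s2i = np.exp(log_theta)  # log-parametrized: interior search
        V = s2i * np.eye(n) + s2e * (Ze @ Ze.T) + s2b * (Zb @ Zb.T)
        try:
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e12
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ yv)
            resid = yv - X @ beta
            return 0.5 * (
                logdet + np.log(np.linalg.det(XtViX)) + resid @ Vi @ resid
            )
        except np.linalg.LinAlgError:
            return 1e12

    var0 = yv.var()
    res = optimize.minimize(
        neg_restricted_ll,
        x0=np.log(np.full(3, var0 / 3)),
        method="Nelder-Mead",
        options=dict(xatol=1e-13, fatol=1e-15, maxiter=50000, maxfev=50000),
    )
    return tuple(np.exp(res.x))


class TestVarianceComponents:
    def test_all_identical_values(self):
        vc = L.variance_components(np.full((3, 3, 2), 5.0))
        assert (vc.sigma2_batch, vc.sigma2_extract, vc.sigma2_injection) == (
            0.0, 0.0, 0.0,
        )

    def test_unbalanced_rejected(self):
        y = np.ones((3, 3, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            L.variance_components(y)
        with pytest.raises(ValueError):
            L.variance_components(np.ones((1, 3, 2)))

    def test_truth_recovery_5x5x4(self):
        # true CVs: batch 31.2%, extraction 0.6%, injection 8.6%
        rng = np.random.default_rng(101)
        ests = np.array(
            [
                [
                    (vc := L.variance_components(
                        nested_lognormal(rng, (0.312, 0.006, 0.086))
                    )).cv_batch,
                    vc.cv_extract,
                    vc.cv_injection,
                ]
                for _ in range(300)
            ]
        )
        mean = ests.mean(axis=0)
        assert mean[0] == pytest.approx(0.312, rel=0.15)
        assert mean[2] == pytest.approx(0.086, rel=0.15)
        assert mean[1] < 0.02  # near-zero truth, truncation inflates slightly

    def test_null_simulation_truncates_upper_components(self):
        rng = np.random.default_rng(7)
        flags = []
        upper = []
        for _ in range(200):
            y = nested_lognormal(rng, (0.0, 0.0, 0.086))
            vc = L.variance_components(y)
            upper.append([vc.sigma2_batch, vc.sigma2_extract])
            flags.append(len(vc.truncated) > 0)
        upper = np.array(upper)
        # injection-only noise: batch and extract estimates average ~0
        grand = 1e5
        assert np.sqrt(upper.mean(axis=0)).max() / grand < 0.02
        assert np.mean(flags) > 0.5  # truncation is common under the null

    def test_matches_numerical_reml_when_untruncated(self):
        rng = np.random.default_rng(11)
        compared = 0
        while compared < 3:
            y = nested_lognormal(rng, (0.312, 0.05, 0.086), shape=(4, 3, 3))
            y = y / y.mean()  # unit scale for comparable tolerances
            vc = L.variance_components(y)
            if vc.truncated:
                continue
            s2b, s2e, s2i = reml_oracle(y)
            assert vc.sigma2_batch == pytest.approx(s2b, rel=1e-5, abs=1e-8)
            assert vc.sigma2_extract == pytest.approx(s2e, rel=1e-5, abs=1e-8)
            assert vc.sigma2_injection == pytest.approx(s2i, rel=1e-5, abs=1e-8)
            compared += 1

    def test_log_scale_option(self):
        rng = np.random.default_rng(5)
        y = nested_lognormal(rng, (0.3, 0.01, 0.08))
        vc = L.variance_components(y, scale="log")
        assert 0.1 < vc.cv_batch < 0.6
        assert 0.04 < vc.cv_injection < 0.15


class TestLinearRange:
    def test_random_responses_never_exceed_r2_of_one(self):
        rng = np.random.default_rng(2)
        levels = np.geomspace(4, 400, 11)
        try:
            res = L.linear_range(levels, rng.uniform(0, 1e5, (11, 2)))
            assert res.r_squared <= 1.0
        except NoLinearRangeError:
            pass  # acceptable outcome for random data

    def test_retained_levels_always_a_prefix(self):
        rng = np.random.default_rng(3)
        levels = np.geomspace(4, 400, 11)
        for trial in range(20):
            resp = np.outer(levels, [1000.0, 1000.0])
            resp *= np.exp(rng.normal(0, 0.05, resp.shape))
            try:
                res = L.linear_range(levels, resp)
            except NoLinearRangeError:
                continue
            np.testing.assert_array_equal(
                res.retained_levels, levels[: len(res.retained_levels)]
            )

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            L.linear_range(np.array([1, 2, 3, 4.0]), np.ones((4, 2)))


class TestFoldChange:
    def test_identical_per_batch_means_give_fc_one_p_one(self):
        # hand-built series whose per-batch means agree between the two
        # levels: FC = 1, t = 0, P = 1
        import pandas as pd

        from lcmsqc.tables import FeatureTable, InjectionRecord

        records, cols = [], {}
        for b in (1, 2, 3):
            for li, lev in enumerate((100.0, 200.0), start=1):
                for r in (1, 2):
                    inj = f"B{b}_L{li}_{r}"
                    records.append(
                        InjectionRecord(inj, f"B{b:02d}", li * 2 + r,
                                        "biological", class_label=f"{lev:g}")
                    )
                    cols[inj] = [1000.0 + 10 * b + (5 if r == 1 else -5)]
        table = FeatureTable.from_records(
            pd.DataFrame(cols, index=pd.Index(["C1"], name="feature_id")),
            records,
        )
        table.injections["nominal_level"] = [
            float(r.class_label) for r in records
        ]
        r = L.fold_change_accuracy(table)[0]
        assert r.experimental_fc == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_power_monotone_in_fold_change(self):
        powers = [L.fold_change_power(fc, cv=0.03)
                  for fc in (1.05, 1.10, 1.20, 1.50)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_monte_carlo_detection_matches_analytic(self):
        fc, cv, n = 1.10, 0.03, 400
        hits = 0
        for i in range(n):
            table = L.simulate_accuracy_experiment(
                nominal_levels=[100, 100 * fc], cv=cv, seed=50_000 + i
            )
            hits += L.fold_change_accuracy(table)[0].p_value <= 0.01
        mc = hits / n
        analytic = L.fold_change_power(fc, cv)
        assert mc == pytest.approx(analytic, abs=0.06)

    def test_relative_error_on_concentration_difference(self):
        table = L.simulate_accuracy_experiment(
            nominal_levels=[100, 120], cv=0.0, seed=0
        )
        r = L.fold_change_accuracy(table)[0]
        assert r.nominal_fc == pytest.approx(1.2)
        assert r.relative_error == pytest.approx(0.0, abs=1e-12)
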