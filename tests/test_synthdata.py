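"""Generator contracts: batch-design layout arithmetic, determinism and
noise-free limits that downstream estimators must invert exactly."""
import numpy as np
import pandas as pd
import pytest

import lcmsqc as L
from lcmsqc.synthdata import (
    SyntheticConfig,
    cv_to_sigma,
    dilution_arrays,
    saturation_capacity,
)
from lcmsqc.tables import records_to_frame


class TestBatchDesign:
    def test_small_batch_layout(self):
        # 4 samples: 7 lead QCs, one 4-sample segment, 2 tail QCs
        d = L.generate_batch_design(["a", "b", "c", "d"], shuffle=False)
        assert len(d) == 13
        assert sum(r.sample_type == "QC" for r in d) == 9
        types = [r.sample_type for r in d]
        assert types[:7] == ["QC"] * 7 and types[-2:] == ["QC"] * 2
        assert [r.injection_id for r in d[7:11]] == ["a", "b", "c", "d"]

    def test_64_sample_batch_arithmetic(self):
        # 16 segments of 4 + 15 interior QCs + 7 + 2 = 88 injections;
        # 24 QCs of which 19 usable for drift fitting
        d = L.generate_batch_design([f"s{i}" for i in range(64)], seed=1)
        qcs = [r for r in d if r.sample_type == "QC"]
        assert len(d) == 88
        assert len(qcs) == 24
        assert sum(r.usable_for_drift for r in qcs) == 19
        assert len({r.batch_id for r in d}) == 1

    def test_batch_capacity_respected(self):
        d = L.generate_batch_design([f"s{i}" for i in range(200)], seed=0)
        meta = records_to_frame(d)
        per_batch = meta.groupby("batch_id").size()
        assert (per_batch <= 95).all()
        assert set(meta.loc[meta["sample_type"] == "biological"].index) == {
            f"s{i}" for i in range(200)
        }

    def test_interior_qc_between_segments(self):
        d = L.generate_batch_design([f"s{i}" for i in range(8)], shuffle=False)
        types = [r.sample_type for r in d]
        # 7 QC, 4 samples, 1 QC, 4 samples, 2 QC
        assert types == ["QC"] * 7 + ["biological"] * 4 + ["QC"] + \
            ["biological"] * 4 + ["QC"] * 2

    def test_orders_unique_and_increasing(self):
        d = L.generate_batch_design([f"s{i}" for i in range(30)], seed=2)
        meta = records_to_frame(d)
        for _, sub in meta.groupby("batch_id"):
            assert list(sub["order"]) == sorted(sub["order"])
            assert sub["order"].is_unique

    @pytest.mark.parametrize(
        "kwargs", [dict(sample_ids=[]), dict(sample_ids=["a"], segment=0)]
    )
    def test_degenerate_inputs_error(self, kwargs):
        with pytest.raises(ValueError):
            L.generate_batch_design(**kwargs)

    def test_shuffle_is_seeded(self):
        ids = [f"s{i}" for i in range(20)]
        d1 = L.generate_batch_design(ids, seed=11)
        d2 = L.generate_batch_design(ids, seed=11)
        d3 = L.generate_batch_design(ids, seed=12)
        assert [r.injection_id for r in d1] == [r.injection_id for r in d2]
        assert [r.injection_id for r in d1] != [r.injection_id for r in d3]


class TestFeatureTableSimulation:
    def test_noise_free_qc_constant_without_drift(self, cultivar_design_1batch):
        cfg = SyntheticConfig(
            n_features=5, n_batches=0, drift_amplitude=0.0,
            cv_injection=0, cv_extraction=0, cv_batch=0, seed=1,
        )
        table, _ = L.simulate_feature_table(cfg, cultivar_design_1batch)
        qc = table.intensities[table.qc_ids]
        assert np.allclose(qc.to_numpy(), qc.to_numpy()[:, [0]])

    def test_determinism_bit_identical(self, cultivar_design_1batch):
        cfg = SyntheticConfig(n_features=10, n_batches=0, missing_rate=0.05, seed=42)
        t1, _ = L.simulate_feature_table(cfg, cultivar_design_1batch)
        t2, _ = L.simulate_feature_table(cfg, cultivar_design_1batch)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        pd.testing.assert_frame_equal(t1.injections, t2.injections)

    @pytest.mark.parametrize("shape", ["linear", "exponential", "spline_knots"])
    def test_drift_amplitude_realized(self, cultivar_design_1batch, shape):
        # expected last-QC / first-injection sensitivity ratio is 1 - amplitude
        amp = 0.3
        cfg = SyntheticConfig(
            n_features=4, n_batches=0, drift_amplitude=amp, drift_shape=shape,
            cv_injection=0, cv_extraction=0, cv_batch=0, seed=9,
        )
        table, truth = L.simulate_feature_table(cfg, cultivar_design_1batch)
        meta = table.injections
        o_lo, o_hi = meta["order"].min(), meta["order"].max()
        for (fid, batch), curve in truth.drift_curves.items():
            assert curve(np.array([o_lo]))[0] == pytest.approx(1.0, abs=1e-12)
            assert curve(np.array([o_hi]))[0] == pytest.approx(1.0 - amp, abs=1e-12)
            vals = curve(np.arange(o_lo, o_hi + 1))
            assert np.all(np.diff(vals) <= 1e-9)  # monotone decay

    def test_injection_cv_realized_on_qcs(self, cultivar_design_1batch):
        cfg = SyntheticConfig(
            n_features=300, n_batches=0, drift_amplitude=0.0,
            cv_injection=0.086, cv_extraction=0, cv_batch=0, seed=21,
        )
        table, _ = L.simulate_feature_table(cfg, cultivar_design_1batch)
        qc = table.intensities[table.usable_qc_ids]
        cvs = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
        assert cvs.mean() == pytest.approx(0.086, rel=0.10)

    def test_missingness_is_nan_not_zero(self, cultivar_design_1batch):
        cfg = SyntheticConfig(n_features=20, n_batches=0, missing_rate=0.2, seed=2)
        table, _ = L.simulate_feature_table(cfg, cultivar_design_1batch)
        vals = table.intensities
        assert vals.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.03)
        assert (vals.fillna(1.0) > 0).all().all()

    def test_inconsistent_config_errors(self, cultivar_design_1batch):
        cfg = SyntheticConfig(n_features=5, n_batches=3, seed=0)
        with pytest.raises(ValueError):
            L.simulate_feature_table(cfg, cultivar_design_1batch)


class TestValidationExperiment:
    def test_identity_configuration(self, spike_compounds):
        comp = spike_compounds.copy()
        comp["recovery"] = 1.0
        comp["matrix_effect"] = 1.0
        table, _ = L.simulate_validation_experiment(comp)
        for cid in comp.index:
            g = L.spike_groups_from_table(table, cid)
            # A - D = B - D = C when recovery and matrix effect are 1
            assert g.mean_a - g.mean_d == pytest.approx(g.mean_c)
            assert g.mean_b - g.mean_d == pytest.approx(g.mean_c)

    def test_estimators_return_configured_truth(self, spike_compounds):
        table, truth = L.simulate_validation_experiment(spike_compounds)
        for cid in spike_compounds.index:
            g = L.spike_groups_from_table(table, cid)
            assert L.recovery_rate(g) == pytest.approx(truth.loc[cid, "recovery"])
            me, _ = L.matrix_effect(g)
            assert me == pytest.approx(truth.loc[cid, "matrix_effect"])

    def test_strong_suppression_band(self, spike_compounds):
        comp = spike_compounds.copy()
        comp["matrix_effect"] = 0.4  # suppression 60% -> strong
        table, _ = L.simulate_validation_experiment(comp)
        _, band = L.matrix_effect(L.spike_groups_from_table(table, "c1"))
        assert band == "strong"

    def test_too_few_replicates_error(self, spike_compounds):
        with pytest.raises(ValueError):
            L.simulate_validation_experiment(spike_compounds, n_per_group=1)


class TestDilutionSeries:
    def test_exact_linearity(self):
        table = L.simulate_dilution_series(slope=3.0)
        lv, resp = dilution_arrays(table)
        res = L.linear_range(lv, resp)
        assert res.slope == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)
        assert len(res.retained_levels) == 11

    def test_saturating_preset_excludes_top_levels(self):
        levels = np.geomspace(4.0, 400.0, 11)
        cap = saturation_capacity(levels, slope=1000.0, n_flattened=2)
        table = L.simulate_dilution_series(levels, slope=1000.0, capacity=cap)
        lv, resp = dilution_arrays(table)
        res = L.linear_range(lv, resp)
        np.testing.assert_allclose(res.excluded_levels, levels[-2:])

    def test_non_monotone_levels_error(self):
        with pytest.raises(ValueError):
            L.simulate_dilution_series(levels=[1.0, 3.0, 2.0])
        with pytest.raises(ValueError):
            L.simulate_dilution_series(levels=[-1.0, 2.0, 3.0])


class TestAccuracyExperiment:
    def test_noise_free_fold_changes_exact(self):
        table = L.simulate_accuracy_experiment(cv=0.0, seed=0)
        results = L.fold_change_accuracy(table)
        for r in results:
            assert r.experimental_fc == pytest.approx(r.nominal_fc)
            assert r.relative_error == pytest.approx(0.0, abs=1e-12)
            assert r.df == 4

    def test_seeded_reproducibility(self):
        t1 = L.simulate_accuracy_experiment(cv=0.05, seed=3)
        t2 = L.simulate_accuracy_experiment(cv=0.05, seed=3)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)


class TestEICSimulation:
    def test_single_gaussian_closed_form_area(self):
        t = np.arange(0.0, 2.0, 0.002)
        trace = L.simulate_eic([(1.0, 1000.0, 0.05)], t)
        area = np.trapezoid(trace.intensities, t)
        assert area == pytest.approx(1000.0 * 0.05 * np.sqrt(2 * np.pi), rel=1e-4)

    def test_empty_peak_list_zero_trace(self):
        t = np.linspace(0, 1, 50)
        trace = L.simulate_eic([], t)
        assert np.all(trace.intensities == 0.0)

    def test_disjoint_peak_areas_additive(self):
        t = np.arange(0.0, 4.0, 0.002)
        both = L.simulate_eic([(1.0, 500.0, 0.04), (3.0, 800.0, 0.04)], t)
        a1 = L.integrate_peak(both, 1.0, 0.3)
        a2 = L.integrate_peak(both, 3.0, 0.3)
        single1 = L.integrate_peak(L.simulate_eic([(1.0, 500.0, 0.04)], t), 1.0, 0.3)
        single2 = L.integrate_peak(L.simulate_eic([(3.0, 800.0, 0.04)], t), 3.0, 0.3)
        assert a1 == pytest.approx(single1, rel=1e-6)
        assert a2 == pytest.approx(single2, rel=1e-6)
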