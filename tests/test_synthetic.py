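"""Generator contracts: determinism, parameter ranges, composition rules,
and distributional properties of simulated events and traces."""

import numpy as np
import pandas as pd
import pytest

from stresscreen.synthetic import (
    NO_GFP,
    PlateLayout,
    PulseShape,
    TruthConfig,
    default_pulse,
    expected_gfp,
    genotype_name,
    make_truth,
    matrix_from_truth,
    simulate_event_table,
    simulate_localization_trace,
    simulate_plate_stream,
)


class TestMakeTruth:
    def test_identity_perturbation_has_no_effect(self):
        cfg = TruthConfig(m_range=(1.0, 1.0), a_frac_range=(0.0, 0.0))
        truth = make_truth(["g1"], ["c"], cfg, seed=0)
        assert truth.single_ko_expectation("g1", "c") == pytest.approx(
            float(truth.wt_baseline["c"])
        )

    def test_determinism_and_shape(self):
        genes = [f"q{i}" for i in range(30)] + [f"t{i}" for i in range(56)]
        conds = ["log", "heat", "KCl", "diamide", "post-diauxic"]
        t1 = make_truth(genes, conds, seed=7)
        t2 = make_truth(genes, conds, seed=7)
        assert len(t1.genes) == 86 and len(t1.wt_baseline) == 5
        pd.testing.assert_frame_equal(t1.m, t2.m)
        pd.testing.assert_frame_equal(t1.a, t2.a)
        pd.testing.assert_series_equal(t1.wt_baseline, t2.wt_baseline)
        assert t1.to_yaml() == t2.to_yaml()

    def test_sampled_components_respect_ranges(self):
        cfg = TruthConfig(m_range=(0.3, 3.0), a_frac_range=(-0.3, 0.5))
        truth = make_truth([f"g{i}" for i in range(40)], ["c1", "c2"], cfg, seed=5)
        assert ((truth.m.values >= 0.3) & (truth.m.values <= 3.0)).all()
        lo = -0.3 * truth.wt_baseline.values[None, :]
        hi = 0.5 * truth.wt_baseline.values[None, :]
        assert ((truth.a.values >= lo) & (truth.a.values <= hi)).all()
        assert (truth.wt_baseline > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_truth([], ["c"], seed=0)
        with pytest.raises(ValueError):
            make_truth(["g"], [], seed=0)
        with pytest.raises(ValueError):
            make_truth(["g"], ["c"], TruthConfig(baseline_range=(-1.0, 2.0)), seed=0)


class TestExpectedGfp:
    def test_wt_is_baseline(self, small_truth):
        for c in small_truth.conditions:
            assert expected_gfp([], c, small_truth) == float(small_truth.wt_baseline[c])

    def test_single_ko_model_definition(self):
        cfg = TruthConfig(m_range=(1.5, 1.5), a_frac_range=(0.0, 0.0),
                          baseline_range=(100.0, 100.0))
        truth = make_truth(["g1"], ["c"], cfg, seed=0)
        assert expected_gfp(["g1"], "c", truth) == pytest.approx(150.0)

    def test_fully_dependent_triple_equals_msn24_double(self):
        truth = make_truth(["g1"], ["c"], TruthConfig(d_frac_range=(1.0, 1.0)), seed=1)
        triple = expected_gfp(["g1", "msn2", "msn4"], "c", truth)
        double = expected_gfp(["msn2", "msn4"], "c", truth)
        assert triple == pytest.approx(double)

    def test_double_composition_is_combined_form(self, small_truth):
        t = small_truth
        c = "KCl"
        wt = float(t.wt_baseline[c])
        v = expected_gfp(["g1", "g2"], c, t)
        expected = (
            wt * float(t.m.loc["g1", c]) * float(t.m.loc["g2", c])
            + float(t.a.loc["g1", c]) + float(t.a.loc["g2", c])
        )
        assert v == pytest.approx(expected)

    def test_unknown_gene_raises(self, small_truth):
        with pytest.raises(KeyError):
            expected_gfp(["nonexistent"], "KCl", small_truth)

    def test_injected_interaction_term(self, small_truth):
        t = small_truth
        base = expected_gfp(["g1", "g2"], "heat", t)
        t.interactions[("g1", "g2", "heat")] = 123.0
        try:
            assert expected_gfp(["g1", "g2"], "heat", t) == pytest.approx(base + 123.0)
        finally:
            t.interactions.clear()


class TestEventTable:
    def test_wt_median_near_offset_plus_baseline(self, small_truth):
        ev = simulate_event_table([], "KCl", small_truth, 5000, seed=1)
        assert len(ev) == 5000
        target = float(small_truth.autofluorescence["KCl"] + small_truth.wt_baseline["KCl"])
        assert np.median(ev["gfp"]) == pytest.approx(target, rel=0.05)

    def test_no_gfp_control_shows_only_autofluorescence(self, small_truth):
        ev = simulate_event_table(NO_GFP, "KCl", small_truth, 5000, seed=2)
        assert np.median(ev["gfp"]) == pytest.approx(
            float(small_truth.autofluorescence["KCl"]), rel=0.05
        )

    def test_zero_outlier_fraction_stays_in_dense_cloud(self, small_truth):
        ev = simulate_event_table([], "KCl", small_truth, 4000, seed=3, outlier_fraction=0.0)
        assert not ev["is_outlier"].any()
        # brute-force containment: all events inside the cloud's 99.9% ellipse
        from stresscreen.synthetic import _FSC_MEAN, _FSC_SD, _SSC_MEAN, _SSC_SD, _SCATTER_CORR
        from scipy import stats
        d = np.column_stack(
            [(ev["fsc"] - _FSC_MEAN) / _FSC_SD, (ev["ssc"] - _SSC_MEAN) / _SSC_SD]
        )
        rho = _SCATTER_CORR
        mahal2 = (d[:, 0] ** 2 - 2 * rho * d[:, 0] * d[:, 1] + d[:, 1] ** 2) / (1 - rho**2)
        assert (mahal2 <= stats.chi2.ppf(0.9999, df=2)).mean() > 0.999

    def test_median_converges_to_expectation_at_large_n(self, small_truth):
        ev = simulate_event_table(["g3"], "heat", small_truth, 50_000, seed=4)
        target = float(small_truth.autofluorescence["heat"]) + expected_gfp(
            ["g3"], "heat", small_truth
        )
        assert np.median(ev["gfp"]) == pytest.approx(target, rel=0.02)

    def test_timestamps_monotone_and_errors(self, small_truth):
        ev = simulate_event_table([], "KCl", small_truth, 100, seed=5)
        assert (np.diff(ev["time"]) >= 0).all()
        with pytest.raises(ValueError):
            simulate_event_table([], "KCl", small_truth, 0, seed=0)


class TestPlateStream:
    def test_burst_structure(self, small_truth):
        layout = PlateLayout([(f"w{i}", "WT", "KCl", 0) for i in range(3)])
        stream = simulate_plate_stream(layout, small_truth, 100, gap_seconds=5.0, seed=0)
        assert len(stream) == 300
        gaps = np.diff(stream["time"].to_numpy())
        assert (gaps >= 0).all()
        assert (gaps >= 5.0).sum() == 2

    def test_full_plate_monotone(self, small_truth):
        layout = PlateLayout([(f"w{i}", "WT", "KCl", 0) for i in range(96)])
        stream = simulate_plate_stream(layout, small_truth, 20, gap_seconds=5.0, seed=1)
        assert stream["true_well"].nunique() == 96
        assert (np.diff(stream["time"]) >= 0).all()

    def test_duplicate_well_ids_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout([("w0", "WT", "c", 0), ("w0", "WT", "c", 1)])


class TestLocalizationSimulation:
    timepoints = np.arange(0.0, 105.0, 7.0)

    def test_zero_amplitude_is_flat_baseline(self, small_truth):
        cells = simulate_localization_trace(
            "WT", "KCl", small_truth, self.timepoints, n_cells=20, seed=0,
            pulse=PulseShape(baseline=1.0, amplitude=0.0), cell_noise_sd=0.0,
        )
        ratios = cells["nuclear"] / cells["cytoplasmic"]
        assert np.allclose(ratios, 1.0)

    def test_kcl_pulse_peaks_nearest_15_min(self, small_truth):
        cells = simulate_localization_trace(
            "WT", "KCl", small_truth, self.timepoints, n_cells=200, seed=1
        )
        pop = cells.groupby("time").apply(
            lambda s: (s["nuclear"] / s["cytoplasmic"]).median(), include_groups=False
        )
        t_peak = float(pop.idxmax())
        nearest_to_15 = self.timepoints[np.argmin(np.abs(self.timepoints - 15.0))]
        assert t_peak == nearest_to_15
        # KCl-like pulse has adapted by ~45-50 min
        assert pop.loc[49.0] < 1.0 + 0.2 * (pop.max() - 1.0)

    def test_diamide_pulse_is_sustained(self, small_truth):
        p = default_pulse("diamide")
        r = p.ratio(np.array([0.0, 15.0, 100.0]))
        assert r[2] > r[0] + 0.5 * (r[1] - r[0])  # no return within 100 min
        assert p.amplitude < default_pulse("KCl").amplitude

    def test_determinism_and_errors(self, small_truth):
        a = simulate_localization_trace("WT", "KCl", small_truth, self.timepoints, 10, seed=9)
        b = simulate_localization_trace("WT", "KCl", small_truth, self.timepoints, 10, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            simulate_localization_trace("WT", "KCl", small_truth, [10.0, 5.0], 10, seed=0)


class TestMatrixFromTruth:
    def test_noiseless_matrix_matches_expectations(self, small_screen):
        truth, pairs, matrix = small_screen
        for c in truth.conditions:
            assert matrix.wt(c) == pytest.approx(float(truth.wt_baseline[c]))
            for g in truth.genes:
                assert matrix.value(genotype_name([g]), c) == pytest.approx(
                    truth.single_ko_expectation(g, c)
                )

    def test_replicate_noise_is_seeded(self, small_truth):
        m1 = matrix_from_truth(small_truth, replicate_cv=0.05, n_replicates=2, seed=3)
        m2 = matrix_from_truth(small_truth, replicate_cv=0.05, n_replicates=2, seed=3)
        pd.testing.assert_frame_equal(m1.values, m2.values)
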