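"""Synthetic cohort generator: metadata, connectomes, oscillator dynamics."""

import numpy as np
import pytest

from foldconn import (
    EdgeClass,
    GeneratorConfig,
    PhaseBundle,
    build_sc,
    class_mean_strength,
    classify_edges,
    classify_vertices,
    gen_cohort_metadata,
    gen_sc,
    gen_surface_fixture,
    kop,
    phase_pipeline,
    roi_timeseries,
    build_roi_set,
    simulate_kuramoto,
)
from foldconn.stats import validate_cohort

TABLE1_FT_M_GA = (40.07, 0.88)


class TestCohortMetadata:
    def test_ft_male_gestational_age_calibration(self):
        """Large FT draw recovers the configured male GA mean."""
        cfg = GeneratorConfig(n_per_group=1000)
        df = gen_cohort_metadata(cfg, seed=4)
        males = df[(df.group == "FT") & (df.sex == "M")]
        mean, sd = TABLE1_FT_M_GA
        se = sd / np.sqrt(len(males))
        assert abs(males.gestational_age_weeks.mean() - mean) < 3 * se

    def test_group_constraints_hold(self):
        cfg = GeneratorConfig(n_per_group=200)
        df = gen_cohort_metadata(cfg, seed=5)
        validate_cohort(df)
        pp = df[df.group == "PP"]
        assert (pp.scan_age_weeks <= 37).all()
        assert (df.scan_age_weeks >= df.gestational_age_weeks).all()

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_per_group=20)
        a = gen_cohort_metadata(cfg, seed=9)
        b = gen_cohort_metadata(cfg, seed=9)
        assert a.equals(b)


class TestGenSc:
    def test_attenuation_one_is_null_case(self, rois64):
        cfg = GeneratorConfig(preterm_gg_attenuation=1.0)
        classes = classify_edges(rois64)
        ggs = {}
        for group in ("FT", "PT"):
            vals = []
            for s in range(20):
                sc, _, _ = gen_sc(cfg, group, seed=s if group == "FT" else 500 + s)
                vals.append(class_mean_strength(sc, classes, EdgeClass.GG))
            ggs[group] = np.mean(vals)
        assert ggs["FT"] == pytest.approx(ggs["PT"], rel=0.05)

    def test_attenuation_recovered_from_class_means(self, rois64):
        """FT/PT mean GG ratio ~ 1/0.7 within 10% at n=40 per group."""
        cfg = GeneratorConfig(preterm_gg_attenuation=0.7)
        classes = classify_edges(rois64)
        ft = [
            class_mean_strength(
                gen_sc(cfg, "FT", seed=s)[0], classes, EdgeClass.GG
            )
            for s in range(40)
        ]
        pt = [
            class_mean_strength(
                gen_sc(cfg, "PT", seed=1000 + s)[0], classes, EdgeClass.GG
            )
            for s in range(40)
        ]
        assert np.mean(ft) / np.mean(pt) == pytest.approx(1 / 0.7, rel=0.10)

    def test_endpoint_roundtrip_reproduces_matrix(self, rois64):
        cfg = GeneratorConfig()
        sc, endpoints, _ = gen_sc(cfg, "FT", seed=3)
        rebuilt = build_sc(endpoints, rois64, cfg.streamline_total)
        np.testing.assert_array_equal(rebuilt.values, sc.values)

    def test_normalization_budget(self, rois64):
        """Pair sum + unassigned fraction = 1 for every generated SC."""
        cfg = GeneratorConfig()
        sc, endpoints, _ = gen_sc(cfg, "PT", seed=8)
        unassigned = (endpoints == -1).any(axis=1).sum()
        assert sc.pair_sum() + unassigned / cfg.streamline_total == pytest.approx(1.0)

    def test_block_ordering_gg_gs_ss(self, rois64):
        classes = classify_edges(rois64)
        sc, _, _ = gen_sc(GeneratorConfig(), "FT", seed=11)
        gg = class_mean_strength(sc, classes, EdgeClass.GG)
        gs = class_mean_strength(sc, classes, EdgeClass.GS)
        ss = class_mean_strength(sc, classes, EdgeClass.SS)
        assert gg > gs > ss


class TestKuramoto:
    def test_uncoupled_phases_follow_intrinsic_frequency(self, rois64):
        cfg = GeneratorConfig(
            coupling=0.0,
            duration_s=120,
            phase_noise_sd=0.02,
            observation_noise_sd=0.0,
        )
        sc, _, _ = gen_sc(cfg, "FT", seed=2)
        series = simulate_kuramoto(sc, cfg, seed=2)
        # gyral node frequencies cluster near the configured 0.05 Hz
        from scipy.signal import periodogram

        freqs, px = periodogram(series[:32], fs=1 / cfg.tr, axis=-1)
        peak = freqs[px.argmax(axis=-1)]
        assert abs(np.median(peak) - 0.05) < 0.01

    def test_two_identical_oscillators_lock_at_strong_coupling(self):
        cfg = GeneratorConfig(
            duration_s=120,
            coupling=50.0,
            freq_sd_hz={"GYRAL": 0.0, "SULCAL": 0.0},
            observation_noise_sd=0.0,
            phase_noise_sd=0.05,
        )
        adj = np.array([[0.0, 0.5], [0.5, 0.0]])
        series = simulate_kuramoto(adj, cfg, seed=1,
                                   gyral_mask=np.array([True, True]))
        ph = phase_pipeline(series, tr=cfg.tr, n_trim=20)
        assert kop(ph, range(2)).mean_sync > 0.99

    def test_mean_kop_nondecreasing_in_coupling(self, rois64):
        """Global synchronization rises with coupling over a sweep."""
        means = []
        for k_val in [0.0, 2.0, 5.0, 10.0]:
            vals = []
            for seed in range(4):
                cfg = GeneratorConfig(duration_s=120, coupling=k_val)
                sc, _, _ = gen_sc(cfg, "FT", seed=seed)
                series = simulate_kuramoto(sc, cfg, seed=100 + seed)
                pb = phase_pipeline(series, tr=cfg.tr, rois=rois64)
                vals.append(kop(pb, "global").mean_sync)
            means.append(np.mean(vals))
        diffs = np.diff(means)
        assert (diffs > -0.05).all()  # non-decreasing within noise
        assert means[-1] > means[0] + 0.2

    def test_unstable_step_rejected(self):
        cfg = GeneratorConfig(duration_s=10, coupling=1e5, substeps=1)
        adj = np.full((4, 4), 0.25)
        np.fill_diagonal(adj, 0)
        with pytest.raises(RuntimeError, match="substeps"):
            simulate_kuramoto(adj, cfg, seed=0,
                              gyral_mask=np.ones(4, bool))

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(duration_s=40)
        sc, _, _ = gen_sc(cfg, "FT", seed=6)
        s1 = simulate_kuramoto(sc, cfg, seed=77)
        s2 = simulate_kuramoto(sc, cfg, seed=77)
        np.testing.assert_array_equal(s1, s2)


class TestSurfaceFixture:
    def test_designed_folds_recovered_by_threshold(self):
        cfg = GeneratorConfig(duration_s=40)
        surface, designed, _ = gen_surface_fixture(cfg, seed=3)
        got = classify_vertices(surface.curvature, 0.15)
        assert (got == designed).mean() >= 0.99

    def test_noiseless_modes_give_perfect_recovery(self):
        cfg = GeneratorConfig(
            duration_s=40, curvature_modes=(1.0, -1.0), curvature_sd=0.0
        )
        surface, designed, _ = gen_surface_fixture(cfg, seed=3)
        got = classify_vertices(surface.curvature, 0.15)
        assert (got == designed).all()

    def test_roi_timeseries_correlates_with_generating_series(self):
        cfg = GeneratorConfig(duration_s=120)
        surface, _, roi_series = gen_surface_fixture(cfg, seed=12)
        rois = build_roi_set(surface, 0.15)
        ts = roi_timeseries(surface, rois)
        cors = [
            np.corrcoef(ts[i], roi_series[i])[0, 1]
            for i in range(64)
            if not np.isnan(ts[i]).any()
        ]
        assert np.median(cors) > 0.9

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(duration_s=30)
        s1, d1, r1 = gen_surface_fixture(cfg, seed=21)
        s2, d2, r2 = gen_surface_fixture(cfg, seed=21)
        np.testing.assert_array_equal(s1.curvature, s2.curvature)
        np.testing.assert_array_equal(r1, r2)


class TestMechanismProperty:
    def test_ratio_and_kop_positively_correlated_across_subjects(self, rois64):
        """When GG coupling varies across subjects, the GG/GS ratio and
        mean global synchronization co-vary positively."""
        from foldconn import gg_gs_ratio

        cfg = GeneratorConfig(duration_s=160, gg_subject_sd=0.35)
        classes = classify_edges(rois64)
        ratios, kops = [], []
        rng = np.random.default_rng(2024)
        for _ in range(24):
            sc, _, _ = gen_sc(cfg, "FT", seed=rng)
            series = simulate_kuramoto(sc, cfg, seed=rng)
            pb = phase_pipeline(series, tr=cfg.tr, rois=rois64)
            ratios.append(gg_gs_ratio(sc, classes))
            kops.append(kop(pb, "global").mean_sync)
        r = np.corrcoef(ratios, kops)[0, 1]
        assert r > 0.3
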