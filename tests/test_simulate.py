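"""Synthetic-cohort generator: determinism, planted-signal contracts,
and the analytic carrier-location oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from cnvscreen.caller import CallThresholds, call_cohort
from cnvscreen.features import compute_features
from cnvscreen.normalize import inverse_normal_transform, sum_to_locus
from cnvscreen.simulate import (
    SimulationConfig,
    assign_sample_classes,
    default_locus_map,
    expected_feature_location,
    simulate_cohort,
)

SMALL = dict(n_samples=300, baseline_mean=1000.0)


def run_pipeline(cohort):
    summed = sum_to_locus(cohort.intensities, cohort.locus_map)
    normed = inverse_normal_transform(summed)
    return compute_features(normed, cohort.locus_map)


class TestConfig:
    def test_rejects_infeasible(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_samples=0)
        with pytest.raises(ValueError):
            SimulationConfig(carrier_fraction=0.8, noisy_fraction=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(deletion_signal_ratio=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_deletion_loci=18, n_probe_sets_deletion=17)

    def test_default_locus_map_shape(self):
        m = default_locus_map(SimulationConfig())
        assert len(m.deletion_loci) == 18
        n_del_probes = sum(len(l.probe_set_ids) for l in m.deletion_loci)
        assert n_del_probes == 21
        assert len(m.flank_loci) == 50
        # flanking probe sets are shared across both array versions
        for l in m.flank_loci:
            assert all(vs == frozenset({"v1", "v2"}) for vs in l.array_versions)
        # every deletion locus keeps at least one shared probe set
        for l in m.deletion_loci:
            assert any(vs == frozenset({"v1", "v2"}) for vs in l.array_versions)


class TestSimulateCohort:
    def test_deterministic_given_seed(self):
        a = simulate_cohort(SimulationConfig(rng_seed=3, **SMALL))
        b = simulate_cohort(SimulationConfig(rng_seed=3, **SMALL))
        pd.testing.assert_frame_equal(a.manifest.frame, b.manifest.frame)
        pd.testing.assert_frame_equal(a.intensities.frame, b.intensities.frame)
        c = simulate_cohort(SimulationConfig(rng_seed=4, **SMALL))
        assert not a.intensities.frame["intensity"].equals(
            c.intensities.frame["intensity"])

    def test_zero_carrier_fraction_gives_no_carrier_labels(self):
        cohort = simulate_cohort(
            SimulationConfig(carrier_fraction=0.0, rng_seed=0, **SMALL))
        assert (cohort.truth == "negative").all()

    def test_exact_carrier_planting(self):
        cohort = simulate_cohort(SimulationConfig(n_carriers=5, rng_seed=0, **SMALL))
        assert int((cohort.truth == "carrier").sum()) == 5

    def test_carrier_count_is_binomial(self):
        """Carrier counts across seeds follow Binomial(n, p): at
        n=10 000, p=0.00024 the mean over 200 seeds is within 3 standard
        errors of n*p = 2.4 (exercised on the class-assignment stage)."""
        cfg = SimulationConfig(n_samples=10_000, carrier_fraction=0.00024)
        counts = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            is_carrier, _, _ = assign_sample_classes(cfg, rng)
            counts.append(int(is_carrier.sum()))
        mean = np.mean(counts)
        se = np.sqrt(2.4 * (1 - 0.00024) / 200)
        assert abs(mean - 2.4) < 3 * se

    def test_class_assignment_matches_cohort_truth(self):
        cfg = SimulationConfig(rng_seed=11, carrier_fraction=0.05, **SMALL)
        cohort = simulate_cohort(cfg)
        is_carrier, is_noisy, is_v1 = assign_sample_classes(
            cfg, np.random.default_rng(cfg.rng_seed))
        assert (cohort.truth.to_numpy() ==
                np.where(is_carrier, "carrier", "negative")).all()
        assert (cohort.manifest.frame["is_noisy"].to_numpy() == is_noisy).all()

    def test_carrier_noncarrier_ratio_exact_without_noise(self):
        # all probe sets shared across versions, so every sample sees the
        # same probe content and the per-locus ratio is exactly 0.5
        cfg = SimulationConfig(
            n_samples=40, n_carriers=10, sample_scale_sd=0.0,
            probe_noise_sd=0.0, noisy_fraction=0.0,
            n_version_specific_deletion=0, rng_seed=5)
        cohort = simulate_cohort(cfg)
        summed = sum_to_locus(cohort.intensities, cohort.locus_map)
        truth = cohort.truth.reindex(summed.values.index)
        is_del = np.array([l.region == "deletion" for l in cohort.locus_map.loci])
        car = summed.values.loc[truth == "carrier"].to_numpy()[:, is_del]
        neg = summed.values.loc[truth == "negative"].to_numpy()[:, is_del]
        np.testing.assert_allclose(car.mean(axis=0) / neg.mean(axis=0), 0.5,
                                   rtol=1e-12)

    def test_ratio_approaches_target_at_small_noise(self):
        cfg = SimulationConfig(
            n_samples=2000, n_carriers=500, sample_scale_sd=0.0,
            probe_noise_sd=0.01, noisy_fraction=0.0, rng_seed=5)
        cohort = simulate_cohort(cfg)
        summed = sum_to_locus(cohort.intensities, cohort.locus_map)
        truth = cohort.truth.reindex(summed.values.index)
        is_del = np.array([l.region == "deletion" for l in cohort.locus_map.loci])
        car = summed.values.loc[truth == "carrier"].to_numpy()[:, is_del]
        neg = summed.values.loc[truth == "negative"].to_numpy()[:, is_del]
        np.testing.assert_allclose(car.mean() / neg.mean(), 0.5, rtol=0.01)


class TestExpectedFeatureLocation:
    def test_single_noiseless_carrier_analytic_value(self):
        cfg = SimulationConfig(n_samples=1000)
        md, mad = expected_feature_location(cfg, n_carriers=1)
        assert md == pytest.approx(ndtri(0.5 / 1000))  # about -3.29
        assert md == pytest.approx(-3.2905, abs=5e-4)
        assert mad == 0.0

    def test_no_deletion_effect_gives_zero(self):
        cfg = SimulationConfig(n_samples=1000, deletion_signal_ratio=1.0)
        assert expected_feature_location(cfg, n_carriers=1) == (0.0, 0.0)

    def test_all_carriers_gives_zero(self):
        cfg = SimulationConfig(n_samples=1000)
        assert expected_feature_location(cfg, n_carriers=1000) == (0.0, 0.0)

    def test_zero_carriers_is_error(self):
        with pytest.raises(ValueError):
            expected_feature_location(SimulationConfig(carrier_fraction=0.0))


class TestEndToEndProperties:
    def test_rank_invariance_to_per_sample_scaling(self):
        """Multiplying one sample's intensities by a small order-preserving
        factor changes nothing; a large factor only moves that sample's
        own ranks (other samples keep their relative order)."""
        cfg = SimulationConfig(n_samples=50, n_carriers=2, rng_seed=9,
                               noisy_fraction=0.0)
        cohort = simulate_cohort(cfg)
        base = inverse_normal_transform(
            sum_to_locus(cohort.intensities, cohort.locus_map))

        def scaled(factor):
            frame = cohort.intensities.frame.copy()
            target = frame["sample_id"] == "S000007"
            frame.loc[target, "intensity"] *= factor
            from cnvscreen.intensity_io import IntensityTable
            return inverse_normal_transform(
                sum_to_locus(IntensityTable(frame), cohort.locus_map))

        # factor close to 1: no rank changes anywhere -> identical output
        pd.testing.assert_frame_equal(scaled(1.0 + 1e-12).values, base.values)

        # huge factor: the sample jumps to the top rank at every locus and
        # the remaining samples keep their relative order per locus
        big = scaled(1e6).values
        assert (big.loc["S000007"] == big.values.max(axis=0)).all()
        others = [s for s in base.values.index if s != "S000007"]
        for col in base.values.columns:
            a = base.values.loc[others, col].rank()
            b = big.loc[others, col].rank()
            pd.testing.assert_series_equal(a, b)

    def test_all_carrier_cohort_yields_no_calls(self):
        """Rank normalization is blind to population-wide loss: if every
        sample carries the deletion the pipeline must find nobody."""
        cfg = SimulationConfig(n_samples=400, carrier_fraction=1.0,
                               noisy_fraction=0.0, rng_seed=21)
        cohort = simulate_cohort(cfg)
        feats = run_pipeline(cohort)
        calls = call_cohort(feats, CallThresholds())
        assert calls.counts["carrier"] == 0

    def test_noiseless_carrier_matches_analytic_location(self):
        cfg = SimulationConfig(n_samples=1000, n_carriers=1,
                               sample_scale_sd=0.0, probe_noise_sd=0.0,
                               noisy_fraction=0.0, rng_seed=13)
        cohort = simulate_cohort(cfg)
        feats = run_pipeline(cohort).merge(cohort.manifest.frame, on="sample_id")
        carrier = feats[feats["truth_label"] == "carrier"].iloc[0]
        md, mad = expected_feature_location(cfg, n_carriers=1)
        assert carrier["median_difference"] == pytest.approx(md, abs=1e-6)
        assert carrier["piecewise_mad"] == pytest.approx(mad, abs=1e-6)
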