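"""Simulator: Poisson statistics, dead time, drug effects, cohorts, voltage."""

import numpy as np
import pytest

from spikepharm import (
    PRESETS,
    EffectStratum,
    GroupSpec,
    SimulationConfig,
    enforce_refractory,
    generate_cohort,
    ground_truth_label,
    simulate_drug_response_train,
    simulate_homogeneous_train,
    synthesize_voltage,
)


class TestHomogeneous:
    def test_zero_rate_gives_empty_train(self):
        train = simulate_homogeneous_train(0.0, 7200.0, seed=0)
        assert train.n_spikes == 0

    def test_poisson_count_and_isi_cv(self):
        # Without dead time the count is Poisson(rT) and the ISI CV is ~1.
        train = simulate_homogeneous_train(4.0, 7200.0, refractory=0.0, seed=42)
        expected = 4.0 * 7200.0
        assert abs(train.n_spikes - expected) <= 4 * np.sqrt(expected)
        isi = np.diff(train.times)
        cv = isi.std() / isi.mean()
        assert 0.95 <= cv <= 1.05

    def test_dead_time_bounds_min_isi(self):
        train = simulate_homogeneous_train(4.0, 3600.0, refractory=0.01, seed=3)
        assert np.diff(train.times).min() >= 0.01

    def test_determinism_bitwise(self):
        a = simulate_homogeneous_train(6.0, 1200.0, seed=7)
        b = simulate_homogeneous_train(6.0, 1200.0, seed=7)
        assert np.array_equal(a.times, b.times)
        c = simulate_homogeneous_train(6.0, 1200.0, seed=8)
        assert not np.array_equal(a.times, c.times)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            simulate_homogeneous_train(-1.0, 100.0)
        with pytest.raises(ValueError):
            simulate_homogeneous_train(1.0, 0.0)

    def test_rate_calibration_monte_carlo(self):
        # Empirical count within 4*sqrt(rT) of rT in >= 99% of seeded runs.
        rate, duration = 5.0, 100.0
        hits = 0
        n_runs = 1000
        for seed in range(n_runs):
            n = simulate_homogeneous_train(
                rate, duration, refractory=0.0, seed=seed
            ).n_spikes
            hits += abs(n - rate * duration) <= 4 * np.sqrt(rate * duration)
        assert hits / n_runs >= 0.99


class TestDrugResponse:
    def test_null_multiplier_preserves_rate(self):
        cfg = SimulationConfig(baseline_rate=4.0, effect_multiplier=1.0,
                               refractory=0.0, seed=11)
        train = simulate_drug_response_train(cfg)
        post = train.mean_rate(900.0, 7200.0)
        se = np.sqrt(4.0 / 6300.0)
        assert abs(post - 4.0) <= 3 * se

    @pytest.mark.parametrize(
        "multiplier, onset", [(2.8, 3000.0), (0.2, 3000.0)],
        ids=["plus180pct", "minus80pct"],
    )
    def test_step_effect_rate(self, multiplier, onset):
        # Post-onset empirical rate matches baseline*multiplier (no dead time,
        # so the Poisson closed form is exact).
        cfg = SimulationConfig(baseline_rate=4.0, effect_multiplier=multiplier,
                               onset_time=onset, refractory=0.0, seed=5)
        train = simulate_drug_response_train(cfg)
        target = 4.0 * multiplier
        t0 = cfg.injection_time + onset
        post = train.mean_rate(t0, 7200.0)
        se = np.sqrt(target / (7200.0 - t0))
        assert abs(post - target) <= 3 * se
        # Pre-onset stays at baseline.
        pre = train.mean_rate(0.0, t0)
        assert abs(pre - 4.0) <= 3 * np.sqrt(4.0 / t0)

    def test_dead_time_thinning_correction(self):
        # With a refractory period r the observed rate is ~ lambda/(1+lambda*r).
        cfg = SimulationConfig(baseline_rate=4.0, effect_multiplier=2.8,
                               onset_time=3000.0, seed=2)
        train = simulate_drug_response_train(cfg)
        lam = 11.2
        expected = lam / (1 + lam * cfg.refractory)
        post = train.mean_rate(3900.0, 7200.0)
        assert abs(post - expected) <= 3 * np.sqrt(expected / 3300.0)

    def test_ramp_zero_equals_step_bitwise(self):
        step = SimulationConfig(baseline_rate=5.0, effect_multiplier=3.0,
                                onset_time=2000.0, ramp_duration=0.0, seed=9)
        ramp0 = SimulationConfig(baseline_rate=5.0, effect_multiplier=3.0,
                                 onset_time=2000.0, ramp_duration=0.0, seed=9)
        a = simulate_drug_response_train(step)
        b = simulate_drug_response_train(ramp0)
        assert np.array_equal(a.times, b.times)

    def test_ramp_interpolates_rate(self):
        cfg = SimulationConfig(baseline_rate=4.0, effect_multiplier=3.0,
                               onset_time=2000.0, ramp_duration=1000.0,
                               refractory=0.0, seed=13)
        mid = cfg.rate_at(np.array([cfg.onset_abs + 500.0]))[0]
        assert mid == pytest.approx(4.0 * 2.0)  # halfway up the ramp

    def test_ground_truth_attached_and_reproducible(self):
        cfg = SimulationConfig(baseline_rate=3.0, effect_multiplier=2.0, seed=21)
        train = simulate_drug_response_train(cfg)
        assert train.ground_truth == cfg
        again = simulate_drug_response_train(train.ground_truth)
        assert np.array_equal(train.times, again.times)

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(baseline_rate=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(baseline_rate=1.0, effect_multiplier=-0.5)
        with pytest.raises(ValueError):
            SimulationConfig(baseline_rate=1.0, onset_time=7000.0)  # past session end


class TestRefractoryEnforcement:
    def test_no_isi_below_refractory(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 10, 5000))
        out = enforce_refractory(times, 0.005)
        assert np.diff(out).min() >= 0.005

    def test_greedy_keeps_resolvable_spikes(self):
        # a,b,c with gaps 1 ms then 1.5 ms at r=2 ms: drop b, keep c (c-a=2.5 ms).
        out = enforce_refractory(np.array([0.0, 0.001, 0.0025]), 0.002)
        assert np.allclose(out, [0.0, 0.0025])


class TestCohort:
    def test_preset_sizes_match_reported_groups(self):
        assert PRESETS["saline"].n_neurons == 15
        assert PRESETS["don5"].n_neurons == 16
        assert PRESETS["don10"].n_neurons == 14
        assert PRESETS["don15"].n_neurons == 16

    def test_don15_ground_truth_label_counts(self, don15_cohort):
        labels = [ground_truth_label(t.ground_truth) for t in don15_cohort]
        assert labels.count("excitatory") == 10
        assert labels.count("inhibitory") == 2
        assert labels.count("unaffected") == 4

    def test_all_null_spec_labels_null(self):
        spec = GroupSpec("null", (EffectStratum(5, 1.0, 1.0),))
        trains = generate_cohort([spec], seed=1)
        assert all(
            ground_truth_label(t.ground_truth) == "unaffected" for t in trains
        )

    def test_single_unit_passthrough(self):
        spec = GroupSpec("one", (EffectStratum(1, 3.0, 3.0),),
                         onset_min=(50.0, 50.0), baseline_hz=(4.0, 4.0))
        (train,) = generate_cohort([spec], seed=2)
        gt = train.ground_truth
        assert gt.effect_multiplier == 3.0
        assert gt.baseline_rate == 4.0
        assert gt.onset_time == 3000.0

    def test_cohort_deterministic_and_unitwise_reproducible(self):
        a = generate_cohort(["don10"], seed=5)
        b = generate_cohort(["don10"], seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.times, tb.times)
        # any single unit regenerates from its own ground truth
        t3 = simulate_drug_response_train(a[3].ground_truth)
        assert np.array_equal(a[3].times, t3.times)

    def test_baselines_respect_pyramidal_cap(self, don15_cohort):
        assert all(t.ground_truth.baseline_rate <= 8.0 for t in don15_cohort)

    def test_empty_spec_raises(self):
        with pytest.raises(ValueError):
            generate_cohort([], seed=0)


class TestVoltage:
    def test_empty_train_is_noise_only(self):
        train = simulate_homogeneous_train(0.0, 20.0, seed=0)
        trace = synthesize_voltage(train, noise_sd=1.0, sampling_rate=10_000, seed=4)
        assert abs(trace.samples.std() - 1.0) / 1.0 <= 0.05
        assert trace.true_spike_times.size == 0

    def test_constructed_snr_is_peak_over_noise(self):
        train = simulate_homogeneous_train(2.0, 10.0, seed=1)
        trace = synthesize_voltage(train, peak_amplitude=5.0, noise_sd=1.0,
                                   sampling_rate=10_000, seed=2)
        assert trace.noise_sd == 1.0  # constructed SNR = 5/1 by definition

    def test_noiseless_single_spike_peaks_at_spike_time(self):
        from spikepharm import SpikeTrain
        train = SpikeTrain(times=np.array([10.0]), duration=20.0)
        fs = 10_000.0
        trace = synthesize_voltage(train, peak_amplitude=5.0, noise_sd=0.0,
                                   sampling_rate=fs, seed=0)
        peak = np.argmax(np.abs(trace.samples))
        assert abs(peak / fs - 10.0) <= 1.0 / fs
        assert np.abs(trace.samples).max() == pytest.approx(5.0, rel=1e-6)

    def test_undersampled_waveform_raises(self):
        train = simulate_homogeneous_train(1.0, 5.0, seed=0)
        with pytest.raises(ValueError):
            synthesize_voltage(train, waveform_width=0.001, sampling_rate=5_000)
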