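import numpy as np
import pytest

from gammalfp.spectral import welch_psd
from gammalfp.synthlfp import (
    ArtifactSpec,
    EntrainmentSpec,
    GroupSpec,
    OscillatorSpec,
    PacSpec,
    SimConfig,
    TrialSchedule,
    canonical_oscillators,
    default_sim_config,
    derive_subject_seed,
    generate_entrained_trials,
    generate_oscillator,
    generate_pac_component,
    generate_pink_noise,
    render_artifact,
    simulate_cohort,
    simulate_recording_pair,
)


def fitted_psd_slope(x: np.ndarray, fs: float, f_lo=2.0, f_hi=100.0) -> float:
    psd = welch_psd(x, fs=fs, window_length=2.0)
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    return float(
        np.polyfit(np.log(psd.freqs[mask]), np.log(psd.density[mask]), 1)[0]
    )


class TestPinkNoise:
    def test_white_noise_limit(self):
        x = generate_pink_noise(60, 1000, exponent=0.0, rms=1.0, seed=0)
        assert abs(fitted_psd_slope(x, 1000)) < 0.2

    def test_pink_slope(self):
        x = generate_pink_noise(300, 1000, exponent=1.0, rms=1.0, seed=1)
        assert fitted_psd_slope(x, 1000) == pytest.approx(-1.0, abs=0.2)

    @pytest.mark.parametrize("exponent", [0.5, 1.5, 2.0])
    def test_other_exponents(self, exponent):
        x = generate_pink_noise(120, 500, exponent=exponent, rms=1.0, seed=2)
        assert fitted_psd_slope(x, 500) == pytest.approx(-exponent, abs=0.2)

    def test_rms(self):
        x = generate_pink_noise(30, 500, 1.0, rms=2.5, seed=3)
        assert np.std(x) == pytest.approx(2.5, rel=0.05)
        assert len(x) == 15000

    def test_determinism(self):
        a = generate_pink_noise(10, 500, 1.0, 1.0, seed=42)
        b = generate_pink_noise(10, 500, 1.0, 1.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_seed_changes_output(self):
        a = generate_pink_noise(10, 500, 1.0, 1.0, seed=1)
        b = generate_pink_noise(10, 500, 1.0, 1.0, seed=2)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("duration,fs", [(0, 500), (-1, 500), (10, 0)])
    def test_invalid_inputs_rejected(self, duration, fs):
        with pytest.raises(ValueError):
            generate_pink_noise(duration, fs, 1.0, 1.0, 0)


class TestOscillator:
    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            OscillatorSpec(center_freq=2.0, bandwidth=6.0, rms_amplitude=1.0)
        with pytest.raises(ValueError):
            OscillatorSpec(center_freq=-5.0, bandwidth=2.0, rms_amplitude=1.0)
        with pytest.raises(ValueError):
            OscillatorSpec(center_freq=10.0, bandwidth=2.0, rms_amplitude=-1.0)

    def test_spectral_fidelity(self, fs):
        # >= 90% of power inside [center - bw/2, center + bw/2]
        spec = OscillatorSpec(center_freq=50.0, bandwidth=40.0, rms_amplitude=1.0)
        x = generate_oscillator(spec, 60, fs, seed=0)
        psd = welch_psd(x, fs=fs)
        inside = psd.integral(30, 70)
        assert inside / psd.integral() >= 0.90

    def test_target_rms(self, fs):
        spec = OscillatorSpec(center_freq=10.0, bandwidth=4.0, rms_amplitude=0.7)
        x = generate_oscillator(spec, 30, fs, seed=1)
        assert np.std(x) == pytest.approx(0.7, rel=1e-9)


class TestPacComponent:
    @staticmethod
    def envelope_phase_correlation(kappa: float, fs: float, seed: int = 0) -> float:
        """Correlation of the amp-band envelope with cos(driver phase),
        both extracted from the trace itself."""
        from gammalfp.pac import analytic_amplitude, analytic_phase, bandpass

        pac = PacSpec(phase_freq=6.0, amp_band=(30, 70), coupling_strength=kappa)
        x = generate_pac_component(pac, 60, fs, base_rms=1.0, seed=seed)
        env = analytic_amplitude(bandpass(x, 30, 70, fs))
        phase = analytic_phase(bandpass(x, 4, 8, fs))
        return float(np.corrcoef(env, np.cos(phase))[0, 1])

    def test_envelope_correlates_with_driver_phase(self, fs):
        assert self.envelope_phase_correlation(0.8, fs) > 0.3

    def test_zero_coupling_is_independent(self, fs):
        assert abs(self.envelope_phase_correlation(0.0, fs)) < 0.1

    def test_nyquist_rejected(self):
        pac = PacSpec(phase_freq=6.0, amp_band=(30, 300), coupling_strength=0.5)
        with pytest.raises(ValueError, match="Nyquist"):
            generate_pac_component(pac, 10, 500, 1.0, 0)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            PacSpec(phase_freq=6.0, amp_band=(30, 70), coupling_strength=1.5)

    def test_phase_freq_must_be_below_band(self):
        with pytest.raises(ValueError):
            PacSpec(phase_freq=35.0, amp_band=(30, 70), coupling_strength=0.5)


class TestEntrainedTrials:
    def test_event_arithmetic(self):
        # 1 s on, 10 s off -> floor(300/11) = 27 onsets fit in 300 s
        assert TrialSchedule.max_trials(300, 1.0, 10.0) == 27
        schedule = TrialSchedule(1.0, 10.0, 27, start=0.0)
        spec = EntrainmentSpec(prf=40, evoked_rms=1.0, locking_concentration=5.0)
        trace, events = generate_entrained_trials(spec, schedule, 300.0, 500.0, 0)
        assert events.size == 27
        np.testing.assert_allclose(np.diff(events), 11.0)

    def test_silent_outside_sonication(self, fs):
        schedule = TrialSchedule(0.5, 1.0, 5, start=0.5)
        spec = EntrainmentSpec(prf=40, evoked_rms=1.0, locking_concentration=5.0)
        trace, events = generate_entrained_trials(spec, schedule, 10.0, fs, 0)
        # sample mid-ISI
        mid_isi = int((events[0] + 0.75) * fs)
        assert trace[mid_isi] == 0.0
        in_window = int((events[0] + 0.25) * fs)
        assert trace[in_window] != 0.0

    def test_prf_energy_in_window(self, fs):
        schedule = TrialSchedule(1.0, 1.0, 10, start=0.5)
        spec = EntrainmentSpec(prf=40, evoked_rms=1.0, locking_concentration=100.0)
        trace, events = generate_entrained_trials(spec, schedule, 21.0, fs, 0)
        i0 = int(events[0] * fs)
        window = trace[i0 : i0 + int(fs)]
        spectrum = np.abs(np.fft.rfft(window))
        freqs = np.fft.rfftfreq(window.size, 1 / fs)
        assert freqs[np.argmax(spectrum)] == pytest.approx(40.0, abs=1.0)

    def test_overflow_rejected(self, fs):
        schedule = TrialSchedule(1.0, 10.0, 30, start=0.0)
        spec = EntrainmentSpec(prf=40, evoked_rms=1.0, locking_concentration=0.0)
        with pytest.raises(ValueError, match="duration"):
            generate_entrained_trials(spec, schedule, 300.0, fs, 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            EntrainmentSpec(prf=40, evoked_rms=1.0, locking_concentration=-1.0)


class TestRecordingPair:
    def test_construction_identity(self, paired_config):
        # sensor noise off: live - dead == neural exactly
        live, dead = simulate_recording_pair(paired_config)
        neural_only, _ = simulate_recording_pair(
            SimConfig.from_dict({**paired_config.to_dict(), "artifact": None})
        )
        np.testing.assert_allclose(
            live.samples - dead.samples, neural_only.samples, atol=1e-12
        )
        np.testing.assert_array_equal(live.events, dead.events)

    def test_zero_artifact_means_flat_dead(self, paired_config):
        config = SimConfig.from_dict(
            {
                **paired_config.to_dict(),
                "artifact": {"prf": 40.0, "amplitude": 0.0, "waveform": None},
            }
        )
        live, dead = simulate_recording_pair(config)
        assert np.all(dead.samples == 0.0)
        assert np.std(live.samples) > 0

    def test_pure_artifact_means_live_equals_dead(self, fs):
        schedule = TrialSchedule(0.5, 1.0, 5, start=0.5)
        config = SimConfig(
            duration=8.0,
            fs=fs,
            seed=0,
            pink_rms=0.0,
            artifact=ArtifactSpec(prf=40.0, amplitude=1.0),
            trial_schedule=schedule,
        )
        live, dead = simulate_recording_pair(config)
        np.testing.assert_array_equal(live.samples, dead.samples)

    def test_determinism(self, paired_config):
        a, _ = simulate_recording_pair(paired_config)
        b, _ = simulate_recording_pair(paired_config)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_component_additivity(self, fs):
        # rendered trace equals the sum of its rendered components
        schedule = TrialSchedule(0.5, 1.0, 5, start=0.5)
        osc = OscillatorSpec(center_freq=10.0, bandwidth=4.0, rms_amplitude=1.0)
        ent = EntrainmentSpec(prf=40.0, evoked_rms=1.0, locking_concentration=10.0)
        config = SimConfig(
            duration=10.0, fs=fs, seed=9, pink_exponent=1.0, pink_rms=0.7,
            oscillators=(osc,), entrainment=ent, trial_schedule=schedule,
        )
        live, _ = simulate_recording_pair(config)
        pink = generate_pink_noise(10.0, fs, 1.0, 0.7, seed=9)
        osc_trace = generate_oscillator(osc, 10.0, fs, seed=9)
        evoked, _ = generate_entrained_trials(ent, schedule, 10.0, fs, seed=9)
        np.testing.assert_allclose(
            live.samples, pink + osc_trace + evoked, atol=1e-12
        )

    def test_prf_mismatch_warns(self, fs):
        schedule = TrialSchedule(0.5, 1.0, 3, start=0.5)
        with pytest.warns(UserWarning, match="PRF"):
            SimConfig(
                duration=6.0, fs=fs, seed=0,
                entrainment=EntrainmentSpec(prf=40.0, evoked_rms=1.0,
                                            locking_concentration=1.0),
                artifact=ArtifactSpec(prf=30.0, amplitude=1.0),
                trial_schedule=schedule,
            )

    def test_artifact_template_length(self, fs):
        spec = ArtifactSpec(prf=40.0, amplitude=1.0)
        assert spec.render_template(fs).size == round(fs / 40.0)
        with pytest.raises(ValueError, match="template"):
            ArtifactSpec(prf=40.0, amplitude=1.0, waveform=(1.0, 2.0)).render_template(fs)

    def test_artifact_deterministic(self, fs):
        schedule = TrialSchedule(0.5, 1.0, 3, start=0.5)
        spec = ArtifactSpec(prf=40.0, amplitude=1.0)
        a = render_artifact(spec, schedule, 6.0, fs)
        b = render_artifact(spec, schedule, 6.0, fs)
        np.testing.assert_array_equal(a, b)


class TestSimConfig:
    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="fs"):
            SimConfig(duration=10, fs=100, seed=0,
                      oscillators=(OscillatorSpec(50.0, 40.0, 1.0),))

    def test_schedule_must_fit(self):
        with pytest.raises(ValueError, match="schedule"):
            SimConfig(duration=5.0, fs=500, seed=0,
                      trial_schedule=TrialSchedule(1.0, 10.0, 5))

    def test_json_round_trip(self, paired_config):
        restored = SimConfig.from_json(paired_config.to_json())
        assert restored == paired_config
        live_a, _ = simulate_recording_pair(paired_config)
        live_b, _ = simulate_recording_pair(restored)
        np.testing.assert_array_equal(live_a.samples, live_b.samples)

    def test_default_matches_recording_conditions(self):
        config = default_sim_config()
        assert config.fs == 1000.0
        assert config.duration == 300.0


class TestCohort:
    @staticmethod
    def base(seed=0):
        return SimConfig(
            duration=12.0, fs=250.0, seed=seed, pink_exponent=1.0,
            pink_rms=0.5, oscillators=canonical_oscillators(),
        )

    def test_recording_count(self):
        groups = [GroupSpec(f"G{i}", 2) for i in range(3)]
        recs = simulate_cohort(groups, self.base())
        assert len(recs) == 6

    def test_duplicate_labels_rejected(self):
        groups = [GroupSpec("A", 2), GroupSpec("A", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort(groups, self.base())

    def test_unknown_multiplier_rejected(self):
        groups = [GroupSpec("A", 2, {"sigma": 0.5}), GroupSpec("B", 2)]
        with pytest.raises(ValueError, match="unknown"):
            simulate_cohort(groups, self.base())

    def test_ground_truth_records_multipliers(self):
        groups = [GroupSpec("AD", 2, {"gamma": 0.5}), GroupSpec("WT", 2)]
        recs = simulate_cohort(groups, self.base())
        ad = [r for r in recs if r.label.startswith("AD/")][0]
        gamma = [o for o in ad.ground_truth.oscillators if o.name == "gamma"][0]
        wt_gamma = [o for o in canonical_oscillators() if o.name == "gamma"][0]
        assert gamma.rms_amplitude == pytest.approx(0.5 * wt_gamma.rms_amplitude)

    def test_seed_derivation_deterministic_and_distinct(self):
        s1 = derive_subject_seed(7, "WT", 0)
        assert s1 == derive_subject_seed(7, "WT", 0)
        assert s1 != derive_subject_seed(7, "WT", 1)
        assert s1 != derive_subject_seed(7, "AD", 0)
        assert s1 != derive_subject_seed(8, "WT", 0)

    def test_subjects_differ_within_group(self):
        recs = simulate_cohort([GroupSpec("WT", 3)], self.base())
        assert not np.array_equal(recs[0].samples, recs[1].samples)

    def test_min_group_size_enforced(self):
        with pytest.raises(ValueError, match="n_subjects"):
            GroupSpec("A", 1)
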