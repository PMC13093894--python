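"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pytest

from gammalfp.synthlfp import (
    ArtifactSpec,
    EntrainmentSpec,
    LfpRecording,
    SimConfig,
    TrialSchedule,
)


@pytest.fixture
def fs() -> float:
    return 500.0


@pytest.fixture
def tone():
    """Factory for a pure tone trace."""

    def make(freq: float, duration: float, fs: float, amplitude: float = 1.0,
             phase: float = 0.0) -> np.ndarray:
        t = np.arange(int(round(duration * fs))) / fs
        return amplitude * np.cos(2 * np.pi * freq * t + phase)

    return make


@pytest.fixture
def paired_config(fs) -> SimConfig:
    """Live/dead simulation with evoked 40-Hz locking and artifact on,
    sensor noise off."""
    schedule = TrialSchedule(
        sonication_duration=0.5, inter_stimulus_interval=1.0, n_trials=40,
        start=0.5,
    )
    return SimConfig(
        duration=62.0,
        fs=fs,
        seed=11,
        pink_exponent=1.0,
        pink_rms=0.5,
        entrainment=EntrainmentSpec(
            prf=40.0, evoked_rms=2.0, locking_concentration=1e6
        ),
        artifact=ArtifactSpec(prf=40.0, amplitude=0.3),
        trial_schedule=schedule,
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def tort_mi_oracle_cosine_law(n_bins: int) -> float:
    """Closed-form Tort MI for the noiseless modulation law A(phi)=1+cos(phi):
    per-bin mean amplitude from the analytic integral, then the entropy
    formula. Independent of the package's binning code."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    width = 2 * np.pi / n_bins
    means = 1.0 + (np.sin(edges[1:]) - np.sin(edges[:-1])) / width
    p = means / means.sum()
    entropy = -np.sum(p * np.log(p))
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


def uniform_resultant_expectation(n: int) -> float:
    """E[R] for N uniform unit phasors, large-N Rayleigh limit."""
    return 0.5 * np.sqrt(np.pi / n)


def naive_welch_oracle(x: np.ndarray, fs: float, nperseg: int):
    """Direct periodogram averaging: non-overlapping boxcar segments, no
    taper, one-sided density. Independent of scipy.signal.welch."""
    n_seg = len(x) // nperseg
    segs = x[: n_seg * nperseg].reshape(n_seg, nperseg)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(segs, axis=1)
    density = (np.abs(spec) ** 2).mean(axis=0) / (fs * nperseg)
    density[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, density


@pytest.fixture
def make_tone_trials(fs):
    """Factory: TrialSet of 40-Hz tone trials with per-trial phase offsets."""
    from gammalfp.entrainment import TrialSet

    def make(phases: np.ndarray, duration: float = 0.6, freq: float = 40.0,
             sample_rate: float = None) -> TrialSet:
        sr = sample_rate or fs
        t = np.arange(int(round(duration * sr))) / sr
        trials = np.cos(2 * np.pi * freq * t[np.newaxis, :] + phases[:, np.newaxis])
        return TrialSet(
            trials=trials,
            fs=sr,
            window=(0.0, duration),
            onset_times=np.arange(len(phases), dtype=float),
        )

    return make
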