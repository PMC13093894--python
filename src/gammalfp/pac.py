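"""Phase-amplitude coupling via the Tort modulation index.

Pipeline: band-pass the trace at the phase band and take the Hilbert
instantaneous phase; band-pass at the amplitude band and take the Hilbert
envelope; bin phases into equal bins over (-pi, pi]; normalize the mean
envelope per bin into a distribution p; the modulation index is the
Kullback-Leibler divergence of p from uniform, normalized by log(n_bins):

    MI = (log N - H(p)) / log N,   H(p) = -sum p_j log p_j.

Phase convention: (-pi, pi], phase 0 at the oscillation peak of the real
(cosine) part. Significance uses time-shift surrogates of the amplitude
envelope, which preserve both marginals' autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import signal as sps

from .synthlfp import LfpRecording

__all__ = [
    "PacResult",
    "SurrogateNull",
    "bandpass",
    "analytic_phase",
    "analytic_amplitude",
    "modulation_index",
    "tort_mi",
    "pac_surrogate_test",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 18  # 20-degree bins


def bandpass(
    signal: np.ndarray, low: float, high: float, fs: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, no group delay).

    The effective order is ``2 * order``; stop-band attenuation one octave
    outside the band comfortably exceeds 20 dB.
    """
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band [{low}, {high}) must lie strictly inside (0, {nyq}) Hz"
        )
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def analytic_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of the analytic signal."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return np.angle(sps.hilbert(x, axis=-1))


def analytic_amplitude(signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude (Hilbert envelope)."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return np.abs(sps.hilbert(x, axis=-1))


@dataclass
class PacResult:
    """Phase-binned amplitude distribution and modulation index for one
    (phase band, amplitude band) pair."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    n_bins: int
    bin_centers: np.ndarray  # radians
    mean_amp_per_bin: np.ndarray  # signal units; NaN where a bin is empty
    p_j: np.ndarray  # normalized distribution, empty bins contribute 0
    mi: float
    empty_bins: int = 0

    @property
    def preferred_phase(self) -> float:
        """Circular mean of the bin centers weighted by p_j."""
        z = np.sum(self.p_j * np.exp(1j * self.bin_centers))
        return float(np.angle(z))

    def to_dict(self) -> dict:
        return {
            "phase_band": list(self.phase_band),
            "amp_band": list(self.amp_band),
            "n_bins": self.n_bins,
            "bin_centers": self.bin_centers.tolist(),
            "mean_amp_per_bin": [
                None if not np.isfinite(v) else float(v)
                for v in self.mean_amp_per_bin
            ],
            "p_j": self.p_j.tolist(),
            "mi": self.mi,
            "empty_bins": self.empty_bins,
            "preferred_phase": self.preferred_phase,
        }


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    """Bin ``amplitude`` by ``phase`` and compute the Tort modulation index.

    Bins are equal-width over (-pi, pi]. Empty bins contribute p_j = 0 to the
    entropy (0 log 0 = 0) and are counted.

    Returns ``(bin_centers, mean_amp_per_bin, p_j, mi, empty_bins)``.
    """
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise ValueError("phase and amplitude must have equal length")
    if phase.size == 0:
        raise ValueError("empty input")
    width = 2 * np.pi / n_bins
    # map (-pi, pi] -> bin index 0..n_bins-1; phase == -pi folds into bin 0
    idx = np.ceil((phase + np.pi) / width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    mean_amp = np.full(n_bins, np.nan)
    nonzero = counts > 0
    mean_amp[nonzero] = sums[nonzero] / counts[nonzero]
    filled = np.where(nonzero, mean_amp, 0.0)
    total = filled.sum()
    if total <= 0:
        raise ValueError("mean amplitude per bin sums to zero; cannot normalize")
    p = filled / total
    pos = p > 0
    entropy = float(-np.sum(p[pos] * np.log(p[pos])))
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    centers = -np.pi + (np.arange(n_bins) + 0.5) * width
    return centers, mean_amp, p, float(mi), int(n_bins - nonzero.sum())


_SignalLike = Union[LfpRecording, np.ndarray, Sequence[float]]


def _trace_fs(signal: _SignalLike, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(signal, LfpRecording):
        return signal.samples, signal.fs
    if fs is None:
        raise ValueError("fs is required when the input is a bare array")
    return np.asarray(signal, dtype=float), float(fs)


def _phase_amp(
    signal: _SignalLike,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    fs: float | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    x, fs = _trace_fs(signal, fs)
    n_cycles = x.size / fs * phase_band[0]
    if n_cycles < 10:
        raise ValueError(
            f"recording holds only {n_cycles:.1f} cycles of the phase band's "
            f"low edge ({phase_band[0]} Hz); >= 10 required"
        )
    phase = analytic_phase(bandpass(x, *phase_band, fs=fs))
    amp = analytic_amplitude(bandpass(x, *amp_band, fs=fs))
    return phase, amp, fs


def tort_mi(
    signal: _SignalLike,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
    fs: float | None = None,
) -> PacResult:
    """Tort modulation index of one recording for one band pair."""
    phase, amp, _ = _phase_amp(signal, phase_band, amp_band, fs)
    centers, mean_amp, p, mi, empty = modulation_index(phase, amp, n_bins)
    return PacResult(
        phase_band=tuple(phase_band),
        amp_band=tuple(amp_band),
        n_bins=n_bins,
        bin_centers=centers,
        mean_amp_per_bin=mean_amp,
        p_j=p,
        mi=mi,
        empty_bins=empty,
    )


@dataclass
class SurrogateNull:
    """Time-shift surrogate null distribution for one PAC measurement."""

    n_surrogates: int
    method: str
    mi_null: np.ndarray
    percentile_95: float
    observed_mi: float
    seed: int

    @property
    def significant(self) -> bool:
        return self.observed_mi > self.percentile_95

    def to_dict(self) -> dict:
        return {
            "n_surrogates": self.n_surrogates,
            "method": self.method,
            "percentile_95": self.percentile_95,
            "observed_mi": self.observed_mi,
            "significant": self.significant,
            "seed": self.seed,
        }


def pac_surrogate_test(
    signal: _SignalLike,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
    n_surrogates: int = 200,
    seed: int = 0,
    fs: float | None = None,
    min_shift_s: float = 1.0,
) -> SurrogateNull:
    """Compare the observed MI against circular time shifts of the envelope.

    Surrogates circularly shift the amplitude envelope by uniform random
    offsets of at least ``min_shift_s`` seconds, destroying the phase-
    amplitude relationship while preserving both marginals.
    """
    if n_surrogates < 100:
        raise ValueError(f"n_surrogates must be >= 100, got {n_surrogates}")
    phase, amp, fs = _phase_amp(signal, phase_band, amp_band, fs)
    min_shift = int(round(min_shift_s * fs))
    n = phase.size
    if n <= 2 * min_shift:
        raise ValueError(
            f"recording too short for >= {min_shift_s} s circular shifts"
        )
    _, _, _, observed, _ = modulation_index(phase, amp, n_bins)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    null = np.empty(n_surrogates)
    for i, s in enumerate(shifts):
        _, _, _, null[i], _ = modulation_index(phase, np.roll(amp, int(s)), n_bins)
    return SurrogateNull(
        n_surrogates=n_surrogates,
        method="time-shift",
        mi_null=null,
        percentile_95=float(np.percentile(null, 95)),
        observed_mi=observed,
        seed=seed,
    )
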