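"""Synthetic LFP generator with known ground truth.

Builds continuous single-channel recordings from additive components:

* 1/f^a ("pink") background noise, rendered by FFT spectral shaping;
* band-limited oscillators (Gaussian noise through a zero-phase band-pass),
  one per canonical band by default;
* a phase-amplitude-coupled component: band-limited carrier noise whose
  envelope follows ``1 + kappa * cos(phase)`` of a low-frequency driver;
* a pulse-locked evoked component: during each sonication window an
  oscillation at the pulse repetition frequency whose per-trial phase offset
  is drawn from a von Mises distribution (concentration 0 = no locking);
* a deterministic electromagnetic-style artifact: a biphasic transient
  repeated at the PRF during sonication windows, identical across the
  live/dead pair.

Every generator is fully determined by a seed; the live/dead pair shares the
artifact sample-for-sample so that ``live - dead`` equals the neural-only
signal exactly when sensor noise is disabled.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "OscillatorSpec",
    "PacSpec",
    "EntrainmentSpec",
    "ArtifactSpec",
    "TrialSchedule",
    "SimConfig",
    "LfpRecording",
    "GroupSpec",
    "generate_pink_noise",
    "generate_oscillator",
    "generate_pac_component",
    "generate_entrained_trials",
    "render_artifact",
    "simulate_recording",
    "simulate_recording_pair",
    "simulate_cohort",
    "canonical_oscillators",
    "default_sim_config",
    "derive_subject_seed",
]

# Stream offsets so each component draws from an independent substream of the
# recording seed.
_STREAM_PINK = 0
_STREAM_OSC = 10  # + oscillator index
_STREAM_PAC = 100
_STREAM_ENTRAIN = 200
_STREAM_SENSOR_LIVE = 300
_STREAM_SENSOR_DEAD = 301


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillatorSpec:
    """A band-limited noise oscillator: Gaussian noise through a zero-phase
    band-pass centered at ``center_freq`` with full width ``bandwidth``."""

    center_freq: float  # Hz
    bandwidth: float  # Hz
    rms_amplitude: float  # arbitrary voltage units
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.center_freq > 0):
            raise ValueError(f"center_freq must be > 0, got {self.center_freq!r}")
        if not (self.bandwidth > 0):
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth!r}")
        if not (self.center_freq - self.bandwidth / 2 > 0):
            raise ValueError(
                "band edge must stay above 0 Hz: "
                f"center {self.center_freq} - bw/2 {self.bandwidth / 2}"
            )
        if self.rms_amplitude < 0:
            raise ValueError(f"rms_amplitude must be >= 0, got {self.rms_amplitude!r}")

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2, self.center_freq + self.bandwidth / 2)


@dataclass(frozen=True)
class PacSpec:
    """Ground-truth phase-amplitude coupling.

    The amplitude-band carrier's envelope follows
    ``1 + coupling_strength * cos(driver_phase - preferred_phase)`` where the
    driver is a sinusoid at ``phase_freq``. The rendered component includes
    the driver tone so the coupling is recoverable from the trace alone.
    """

    phase_freq: float  # Hz
    amp_band: tuple[float, float]  # Hz
    coupling_strength: float  # kappa in [0, 1]
    preferred_phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        low, high = self.amp_band
        if not (0 < low < high):
            raise ValueError(f"amp_band must satisfy 0 < low < high, got {self.amp_band!r}")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError(
                f"coupling_strength must be in [0, 1], got {self.coupling_strength!r}"
            )
        if not (self.phase_freq > 0):
            raise ValueError(f"phase_freq must be > 0, got {self.phase_freq!r}")
        if not (self.phase_freq < low):
            raise ValueError(
                f"phase_freq ({self.phase_freq}) must lie below amp_band.low ({low})"
            )


@dataclass(frozen=True)
class EntrainmentSpec:
    """Pulse-locked evoked oscillation at the PRF.

    ``locking_concentration`` is the von Mises concentration of the per-trial
    phase offset: 0 means phases are uniform (no locking), large values mean
    near-perfect locking at ``preferred_phase``.
    """

    prf: float  # Hz
    evoked_rms: float  # voltage units, within sonication windows
    locking_concentration: float  # von Mises kappa >= 0
    preferred_phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if not (self.prf > 0):
            raise ValueError(f"prf must be > 0, got {self.prf!r}")
        if self.evoked_rms < 0:
            raise ValueError(f"evoked_rms must be >= 0, got {self.evoked_rms!r}")
        if self.locking_concentration < 0:
            raise ValueError(
                f"locking_concentration must be >= 0, got {self.locking_concentration!r}"
            )


@dataclass(frozen=True)
class ArtifactSpec:
    """Deterministic stimulation artifact: one pulse-period template repeated
    at the PRF during sonication windows, identical in live/dead recordings.

    ``waveform`` is an optional explicit one-period template (rendered at the
    recording sampling rate it must have ``round(fs / prf)`` samples); if
    omitted a short biphasic transient of peak ``amplitude`` is used.
    """

    prf: float  # Hz
    amplitude: float  # peak, voltage units
    waveform: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not (self.prf > 0):
            raise ValueError(f"prf must be > 0, got {self.prf!r}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude!r}")

    def render_template(self, fs: float) -> np.ndarray:
        """One pulse-period template at sampling rate ``fs``."""
        n_period = int(round(fs / self.prf))
        if self.waveform is not None:
            template = np.asarray(self.waveform, dtype=float)
            if template.size != n_period:
                raise ValueError(
                    f"waveform template has {template.size} samples; "
                    f"round(fs/prf) = {n_period} required at fs={fs}"
                )
            return template * self.amplitude
        template = np.zeros(n_period)
        width_s = min(0.004, 0.5 / self.prf)  # biphasic transient width
        n_pulse = max(2, int(round(width_s * fs)))
        # midpoint sampling keeps the biphasic shape at coarse sampling rates
        template[:n_pulse] = np.sin(2 * np.pi * (np.arange(n_pulse) + 0.5) / n_pulse)
        return template * self.amplitude


@dataclass(frozen=True)
class TrialSchedule:
    """Stimulation timing: ``n_trials`` sonications of ``sonication_duration``
    seconds separated by ``inter_stimulus_interval`` seconds of silence,
    starting at ``start`` seconds."""

    sonication_duration: float  # s
    inter_stimulus_interval: float  # s
    n_trials: int
    start: float = 0.5  # s

    def __post_init__(self) -> None:
        if not (self.sonication_duration > 0):
            raise ValueError("sonication_duration must be > 0")
        if self.inter_stimulus_interval < 0:
            raise ValueError("inter_stimulus_interval must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def period(self) -> float:
        return self.sonication_duration + self.inter_stimulus_interval

    def onsets(self) -> np.ndarray:
        return self.start + np.arange(self.n_trials) * self.period

    def required_duration(self) -> float:
        return self.start + self.n_trials * self.period

    @staticmethod
    def max_trials(
        duration: float,
        sonication_duration: float,
        inter_stimulus_interval: float,
        start: float = 0.0,
    ) -> int:
        """How many full (sonication + ISI) periods fit in ``duration``."""
        period = sonication_duration + inter_stimulus_interval
        return int(np.floor((duration - start) / period))


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic recording; the seed fixes the output
    bitwise."""

    duration: float  # s
    fs: float  # Hz
    seed: int
    pink_exponent: float = 1.0
    pink_rms: float = 1.0
    oscillators: tuple[OscillatorSpec, ...] = ()
    pac: Optional[PacSpec] = None
    entrainment: Optional[EntrainmentSpec] = None
    artifact: Optional[ArtifactSpec] = None
    trial_schedule: Optional[TrialSchedule] = None
    sensor_noise_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration!r}")
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs!r}")
        if not (0.0 <= self.pink_exponent <= 2.0):
            raise ValueError(
                f"pink_exponent must be in [0, 2], got {self.pink_exponent!r}"
            )
        if self.pink_rms < 0 or self.sensor_noise_rms < 0:
            raise ValueError("rms values must be >= 0")
        object.__setattr__(self, "oscillators", tuple(self.oscillators))
        top = 0.0
        for osc in self.oscillators:
            top = max(top, osc.band[1])
        if self.pac is not None:
            top = max(top, self.pac.amp_band[1])
        if self.entrainment is not None:
            top = max(top, self.entrainment.prf)
        if self.fs < 2 * top:
            raise ValueError(
                f"fs = {self.fs} Hz cannot represent the highest component "
                f"frequency {top} Hz (need fs >= {2 * top})"
            )
        if self.trial_schedule is not None:
            need = self.trial_schedule.required_duration()
            if need > self.duration + 1e-9:
                raise ValueError(
                    f"trial schedule needs {need:.3f} s but duration is "
                    f"{self.duration:.3f} s"
                )
        if (self.entrainment is not None or self.artifact is not None) and (
            self.trial_schedule is None
        ):
            raise ValueError(
                "entrainment/artifact components require a trial_schedule"
            )
        if (
            self.artifact is not None
            and self.entrainment is not None
            and not np.isclose(self.artifact.prf, self.entrainment.prf)
        ):
            warnings.warn(
                "artifact PRF differs from entrainment PRF; they are "
                "physically independent but this is unusual",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if d.get("oscillators"):
            d["oscillators"] = tuple(
                o if isinstance(o, OscillatorSpec) else OscillatorSpec(**o)
                for o in d["oscillators"]
            )
        for key, typ in (
            ("pac", PacSpec),
            ("entrainment", EntrainmentSpec),
            ("artifact", ArtifactSpec),
            ("trial_schedule", TrialSchedule),
        ):
            if d.get(key) is not None and not isinstance(d[key], typ):
                sub = dict(d[key])
                if key == "pac":
                    sub["amp_band"] = tuple(sub["amp_band"])
                if key == "artifact" and sub.get("waveform") is not None:
                    sub["waveform"] = tuple(sub["waveform"])
                d[key] = typ(**sub)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class LfpRecording:
    """A continuous voltage trace with sampling rate and stimulation-onset
    event markers."""

    samples: np.ndarray
    fs: float
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = ""
    ground_truth: Optional[SimConfig] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs!r}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        dur = self.duration
        if self.events.size and (
            np.min(self.events) < 0 or np.max(self.events) >= dur
        ):
            bad = self.events[(self.events < 0) | (self.events >= dur)]
            raise ValueError(
                f"event times outside [0, {dur:.3f}): {bad.tolist()}"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------


def generate_pink_noise(
    duration: float, fs: float, exponent: float, rms: float, seed: int
) -> np.ndarray:
    """1/f^exponent Gaussian noise via FFT spectral shaping.

    The trace is zero-mean with sample standard deviation exactly ``rms``;
    its power spectral density follows ``f**-exponent``.
    """
    if not (duration > 0):
        raise ValueError(f"duration must be > 0, got {duration!r}")
    if not (fs > 0):
        raise ValueError(f"fs must be > 0, got {fs!r}")
    if not (0.0 <= exponent <= 2.0):
        raise ValueError(f"exponent must be in [0, 2], got {exponent!r}")
    if rms < 0:
        raise ValueError(f"rms must be >= 0, got {rms!r}")
    n = int(round(duration * fs))
    rng = _rng(seed, _STREAM_PINK)
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * shaping, n=n)
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _bandpass_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-rms Gaussian noise band-limited with a zero-phase Butterworth."""
    low, high = band
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band!r} must lie strictly inside (0, fs/2)")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def generate_oscillator(
    spec: OscillatorSpec, duration: float, fs: float, seed: int, stream: int = _STREAM_OSC
) -> np.ndarray:
    """Render one band-limited oscillator at its target rms."""
    n = int(round(duration * fs))
    if spec.rms_amplitude == 0:
        return np.zeros(n)
    x = _bandpass_noise(n, fs, spec.band, _rng(seed, stream))
    return x * spec.rms_amplitude


def generate_pac_component(
    pac: PacSpec, duration: float, fs: float, base_rms: float, seed: int
) -> np.ndarray:
    """Driver tone plus carrier noise whose envelope follows the driver phase.

    The driver is narrowband Gaussian noise at ``phase_freq +/- 20%`` (a
    stochastic rhythm, not a pure tone, so that time-shift surrogates can
    destroy the coupling); the amplitude-band carrier is multiplied by
    ``1 + kappa * cos(phi_driver - preferred_phase)`` where ``phi_driver`` is
    the driver's Hilbert phase, then rescaled so the modulated carrier has
    rms ``base_rms``. The driver itself is added to the returned trace so
    downstream phase extraction has a signal to lock onto.

    The carrier is rendered with a guard band of ``1.5 * phase_freq`` inside
    ``amp_band`` (where the band is wide enough) so the modulation sidebands
    at +/- phase_freq stay inside the analysis band and the coupling strength
    survives downstream band-pass filtering.
    """
    low, high = pac.amp_band
    if high >= fs / 2:
        raise ValueError(
            f"amp_band upper edge {high} Hz exceeds Nyquist {fs / 2} Hz"
        )
    n = int(round(duration * fs))
    if base_rms == 0:
        return np.zeros(n)
    rng = _rng(seed, _STREAM_PAC)
    driver = _bandpass_noise(
        n, fs, (0.8 * pac.phase_freq, 1.2 * pac.phase_freq), rng
    )
    driver_phase = np.angle(sps.hilbert(driver))
    guard = min(1.5 * pac.phase_freq, (high - low) / 4.0)
    carrier = _bandpass_noise(n, fs, (low + guard, high - guard), rng)
    modulation = 1.0 + pac.coupling_strength * np.cos(
        driver_phase - pac.preferred_phase
    )
    modulated = carrier * modulation
    sd = modulated.std()
    if sd > 0:
        modulated *= base_rms / sd
    return base_rms * driver + modulated


def generate_entrained_trials(
    spec: EntrainmentSpec,
    schedule: TrialSchedule,
    duration: float,
    fs: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Evoked PRF oscillation within each sonication window.

    Each trial's phase offset is drawn von Mises(preferred_phase,
    locking_concentration); concentration 0 draws uniform phases. The
    component is exactly zero outside sonication windows.

    Returns ``(trace, onset_times)``.
    """
    if schedule.required_duration() > duration + 1e-9:
        raise ValueError(
            f"schedule needs {schedule.required_duration():.3f} s but "
            f"duration is {duration:.3f} s"
        )
    n = int(round(duration * fs))
    trace = np.zeros(n)
    onsets = schedule.onsets()
    rng = _rng(seed, _STREAM_ENTRAIN)
    kappa = spec.locking_concentration
    if kappa == 0:
        offsets = rng.uniform(-np.pi, np.pi, size=onsets.size)
    else:
        offsets = rng.vonmises(spec.preferred_phase, kappa, size=onsets.size)
    n_win = int(round(schedule.sonication_duration * fs))
    amp = np.sqrt(2.0) * spec.evoked_rms
    for onset, phi in zip(onsets, offsets):
        i0 = int(round(onset * fs))
        i1 = min(i0 + n_win, n)
        tt = np.arange(i1 - i0) / fs
        trace[i0:i1] += amp * np.cos(2 * np.pi * spec.prf * tt + phi)
    return trace, onsets


def render_artifact(
    spec: ArtifactSpec, schedule: TrialSchedule, duration: float, fs: float
) -> np.ndarray:
    """Deterministic artifact: the one-period template tiled at the PRF
    within each sonication window. No randomness."""
    n = int(round(duration * fs))
    trace = np.zeros(n)
    if spec.amplitude == 0:
        return trace
    template = spec.render_template(fs)
    n_period = template.size
    n_pulses = int(round(schedule.sonication_duration * spec.prf))
    burst = np.tile(template, n_pulses)
    for onset in schedule.onsets():
        i0 = int(round(onset * fs))
        i1 = min(i0 + burst.size, n)
        trace[i0:i1] += burst[: i1 - i0]
    return trace


# ---------------------------------------------------------------------------
# Recording assembly
# ---------------------------------------------------------------------------


def _render_neural(config: SimConfig) -> np.ndarray:
    n = config.n_samples
    x = generate_pink_noise(
        config.duration, config.fs, config.pink_exponent, config.pink_rms, config.seed
    )
    for i, osc in enumerate(config.oscillators):
        x = x + generate_oscillator(
            osc, config.duration, config.fs, config.seed, stream=_STREAM_OSC + i
        )
    if config.pac is not None:
        x = x + generate_pac_component(
            config.pac, config.duration, config.fs, base_rms=1.0, seed=config.seed
        )
    if config.entrainment is not None:
        evoked, _ = generate_entrained_trials(
            config.entrainment,
            config.trial_schedule,
            config.duration,
            config.fs,
            config.seed,
        )
        x = x + evoked
    return x[:n]


def simulate_recording(config: SimConfig, label: str = "live") -> LfpRecording:
    """Render the live recording only (neural + artifact + sensor noise)."""
    live, _ = simulate_recording_pair(config, label_prefix=label)
    return live


def simulate_recording_pair(
    config: SimConfig, label_prefix: str = ""
) -> tuple[LfpRecording, LfpRecording]:
    """Render a paired live/dead recording.

    ``dead`` contains only the deterministic artifact (plus independently
    seeded sensor noise if configured); ``live`` adds every neural component.
    With sensor noise off, ``live.samples - dead.samples`` equals the neural
    signal exactly. Both share identical event times.
    """
    neural = _render_neural(config)
    n = config.n_samples
    if config.artifact is not None:
        artifact = render_artifact(
            config.artifact, config.trial_schedule, config.duration, config.fs
        )
    else:
        artifact = np.zeros(n)
    if config.sensor_noise_rms > 0:
        noise_live = config.sensor_noise_rms * _rng(
            config.seed, _STREAM_SENSOR_LIVE
        ).standard_normal(n)
        noise_dead = config.sensor_noise_rms * _rng(
            config.seed, _STREAM_SENSOR_DEAD
        ).standard_normal(n)
    else:
        noise_live = noise_dead = 0.0
    if config.trial_schedule is not None:
        events = config.trial_schedule.onsets()
    else:
        events = np.empty(0)
    prefix = f"{label_prefix}/" if label_prefix else ""
    live = LfpRecording(
        samples=neural + artifact + noise_live,
        fs=config.fs,
        events=events,
        label=f"{prefix}live",
        ground_truth=config,
    )
    dead = LfpRecording(
        samples=artifact + noise_dead,
        fs=config.fs,
        events=events.copy(),
        label=f"{prefix}dead",
        ground_truth=replace(config, pink_rms=0.0, oscillators=(), pac=None,
                             entrainment=None),
    )
    return live, dead


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: per-oscillator rms multipliers applied to the
    base configuration's named oscillators."""

    label: str
    n_subjects: int
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(
                f"n_subjects must be >= 2 per group, got {self.n_subjects}"
            )
        for name, m in self.multipliers.items():
            if m < 0:
                raise ValueError(f"multiplier for {name!r} must be >= 0, got {m}")


def derive_subject_seed(base_seed: int, label: str, index: int) -> int:
    """Deterministic per-subject seed: SeedSequence over
    ``(base_seed, crc32(label), index)``."""
    entropy = [int(base_seed), zlib.crc32(label.encode("utf-8")), int(index)]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def simulate_cohort(
    group_specs: Sequence[GroupSpec], base: SimConfig
) -> list[LfpRecording]:
    """One recording per subject, seeds derived from (base.seed, label, index).

    Multiplier keys must name oscillators present in ``base``; oscillators
    not named keep multiplier 1.
    """
    labels = [g.label for g in group_specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    osc_names = {o.name for o in base.oscillators}
    recordings: list[LfpRecording] = []
    for group in group_specs:
        unknown = set(group.multipliers) - osc_names
        if unknown:
            raise ValueError(
                f"group {group.label!r} multipliers name unknown oscillators "
                f"{sorted(unknown)}; base defines {sorted(osc_names)}"
            )
        for idx in range(group.n_subjects):
            oscillators = tuple(
                replace(
                    o,
                    rms_amplitude=o.rms_amplitude
                    * group.multipliers.get(o.name, 1.0),
                )
                for o in base.oscillators
            )
            config = replace(
                base,
                oscillators=oscillators,
                seed=derive_subject_seed(base.seed, group.label, idx),
            )
            rec = simulate_recording(config, label=f"{group.label}/s{idx:02d}")
            rec.label = f"{group.label}/s{idx:02d}"
            recordings.append(rec)
    return recordings


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------


def canonical_oscillators(
    rms: Mapping[str, float] | None = None,
) -> tuple[OscillatorSpec, ...]:
    """Five oscillators spanning the canonical bands delta [1,4), theta
    [4,8), alpha [8,13), beta [13,30), gamma [30,70) Hz, with 1/f-like
    default amplitudes."""
    defaults = {"delta": 1.0, "theta": 0.8, "alpha": 0.6, "beta": 0.5, "gamma": 0.4}
    if rms:
        defaults.update(rms)
    edges = {
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 70.0),
    }
    return tuple(
        OscillatorSpec(
            center_freq=(lo + hi) / 2,
            bandwidth=hi - lo,
            rms_amplitude=defaults[name],
            name=name,
        )
        for name, (lo, hi) in edges.items()
    )


def default_sim_config(seed: int = 0, duration: float = 300.0, fs: float = 1000.0) -> SimConfig:
    """A recording emulating the study's conditions: 5 min at 1 kHz, pink
    background plus the five canonical band oscillators."""
    return SimConfig(
        duration=duration,
        fs=fs,
        seed=seed,
        pink_exponent=1.0,
        pink_rms=1.0,
        oscillators=canonical_oscillators(),
    )
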