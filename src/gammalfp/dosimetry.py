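"""Pulsed transcranial ultrasound dose arithmetic.

Encodes a pulse scheme (carrier frequency, pulse repetition frequency,
tone-burst duration, sonication/ISI timing, one intensity figure) and derives
duty cycle, temporal-average vs pulse-average intensity, a plane-wave peak
pressure estimate, the mechanical index, and regulatory-bound flags.

Conventions
-----------
* Duty cycle is the within-sonication value ``prf * burst_duration``; the
  inter-stimulus interval is reported separately as
  ``within_sonication_fraction``.
* The peak-pressure estimate assumes plane-wave propagation in a medium of
  acoustic impedance ``Z`` (default 1.5 MRayl, soft tissue / water):
  ``p = sqrt(2 * Z * I_sppa)``.
* Mechanical index: ``MI = p[MPa] / sqrt(f[MHz])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PulseScheme",
    "DoseReport",
    "FDA_ISPPA_LIMIT_W_CM2",
    "MI_LIMIT",
    "DEFAULT_IMPEDANCE_MRAYL",
    "duty_cycle",
    "convert_intensity",
    "peak_pressure_from_isppa",
    "mechanical_index",
    "dose_report",
    "named_protocols",
]

#: Diagnostic-ultrasound spatial-peak pulse-average intensity ceiling, W/cm^2.
FDA_ISPPA_LIMIT_W_CM2 = 190.0

#: Mechanical-index ceiling below which inertial cavitation is not expected.
MI_LIMIT = 1.9

#: Plane-wave acoustic impedance of soft tissue / water, MRayl.
DEFAULT_IMPEDANCE_MRAYL = 1.5


@dataclass(frozen=True)
class PulseScheme:
    """A pulsed-ultrasound stimulation protocol.

    Exactly one of ``i_spta`` / ``i_sppa`` must be given; the other is
    derived through the duty cycle.

    Parameters
    ----------
    center_freq_mhz : carrier frequency in MHz.
    prf_hz : pulse repetition frequency in Hz.
    burst_duration_s : tone-burst duration in seconds.
    sonication_duration_s : length of one sonication (pulse train) in seconds.
    inter_stimulus_interval_s : silent gap between sonications in seconds.
    i_spta / i_sppa : spatial-peak temporal-average / pulse-average intensity,
        W/cm^2 (within-sonication time base).
    session_minutes, sessions_per_day, total_days : treatment bookkeeping.
    """

    center_freq_mhz: float
    prf_hz: float
    burst_duration_s: float
    sonication_duration_s: float
    inter_stimulus_interval_s: float
    i_spta: Optional[float] = None
    i_sppa: Optional[float] = None
    session_minutes: float = 20.0
    sessions_per_day: int = 2
    total_days: int = 14

    def __post_init__(self) -> None:
        for name in (
            "center_freq_mhz",
            "prf_hz",
            "burst_duration_s",
            "sonication_duration_s",
            "inter_stimulus_interval_s",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be > 0, got {value!r}")
        dc = self.prf_hz * self.burst_duration_s
        if dc > 1.0 + 1e-12:
            raise ValueError(
                f"duty cycle prf*burst = {dc:.6g} exceeds 1 (100%): "
                "bursts overlap"
            )
        given = [x is not None for x in (self.i_spta, self.i_sppa)]
        if sum(given) != 1:
            raise ValueError(
                "exactly one of i_spta / i_sppa must be provided "
                f"(got i_spta={self.i_spta!r}, i_sppa={self.i_sppa!r})"
            )
        primary = self.i_spta if self.i_spta is not None else self.i_sppa
        if not (primary > 0):
            raise ValueError(f"intensity must be > 0, got {primary!r}")

    @property
    def primary_intensity(self) -> str:
        """Which intensity figure was supplied: ``'i_spta'`` or ``'i_sppa'``."""
        return "i_spta" if self.i_spta is not None else "i_sppa"


@dataclass(frozen=True)
class DoseReport:
    """All derived dose quantities for one :class:`PulseScheme`."""

    duty_cycle: float
    i_spta: float  # W/cm^2
    i_sppa: float  # W/cm^2
    primary_intensity: str
    peak_pressure_mpa: float
    mechanical_index: float
    fda_isppa_ok: bool
    mi_ok: bool
    within_sonication_fraction: float
    impedance_mrayl: float


def duty_cycle(scheme: PulseScheme) -> float:
    """Within-sonication duty cycle, ``prf * burst_duration`` in (0, 1]."""
    return scheme.prf_hz * scheme.burst_duration_s


def convert_intensity(scheme: PulseScheme) -> tuple[float, float]:
    """Return ``(i_spta, i_sppa)`` in W/cm^2, deriving the missing one.

    The two are related by ``i_spta = i_sppa * duty_cycle``.
    """
    dc = duty_cycle(scheme)
    if scheme.i_sppa is not None:
        return scheme.i_sppa * dc, scheme.i_sppa
    return scheme.i_spta, scheme.i_spta / dc


def peak_pressure_from_isppa(
    i_sppa_w_cm2: float, acoustic_impedance_mrayl: float = DEFAULT_IMPEDANCE_MRAYL
) -> float:
    """Plane-wave peak pressure in MPa from pulse-average intensity.

    ``p[Pa] = sqrt(2 * Z[Rayl] * I[W/m^2])``, returned in MPa.
    """
    if not (i_sppa_w_cm2 > 0):
        raise ValueError(f"i_sppa must be > 0, got {i_sppa_w_cm2!r}")
    if not (acoustic_impedance_mrayl > 0):
        raise ValueError(
            f"acoustic impedance must be > 0, got {acoustic_impedance_mrayl!r}"
        )
    intensity_w_m2 = i_sppa_w_cm2 * 1e4
    impedance_rayl = acoustic_impedance_mrayl * 1e6
    p_pa = math.sqrt(2.0 * impedance_rayl * intensity_w_m2)
    return p_pa / 1e6


def mechanical_index(peak_pressure_mpa: float, center_freq_mhz: float) -> float:
    """``MI = p[MPa] / sqrt(f[MHz])``."""
    if not (peak_pressure_mpa > 0):
        raise ValueError(f"peak pressure must be > 0, got {peak_pressure_mpa!r}")
    if not (center_freq_mhz > 0):
        raise ValueError(f"center frequency must be > 0, got {center_freq_mhz!r}")
    return peak_pressure_mpa / math.sqrt(center_freq_mhz)


def dose_report(
    scheme: PulseScheme,
    acoustic_impedance_mrayl: float = DEFAULT_IMPEDANCE_MRAYL,
) -> DoseReport:
    """Compute every derived dose quantity and the two safety flags."""
    dc = duty_cycle(scheme)
    i_spta, i_sppa = convert_intensity(scheme)
    p_mpa = peak_pressure_from_isppa(i_sppa, acoustic_impedance_mrayl)
    mi = mechanical_index(p_mpa, scheme.center_freq_mhz)
    period = scheme.sonication_duration_s + scheme.inter_stimulus_interval_s
    return DoseReport(
        duty_cycle=dc,
        i_spta=i_spta,
        i_sppa=i_sppa,
        primary_intensity=scheme.primary_intensity,
        peak_pressure_mpa=p_mpa,
        mechanical_index=mi,
        fda_isppa_ok=i_sppa <= FDA_ISPPA_LIMIT_W_CM2,
        mi_ok=mi < MI_LIMIT,
        within_sonication_fraction=scheme.sonication_duration_s / period,
        impedance_mrayl=acoustic_impedance_mrayl,
    )


def named_protocols() -> dict[str, PulseScheme]:
    """The four treatment protocols: I_spta 0.33 or 2.14 W/cm^2 x 7 or 14 d.

    All share the 0.5-MHz carrier, 40-Hz PRF, 1.25-ms tone burst, 1-s
    sonication, 10-s inter-stimulus interval, 20-min sessions twice daily.
    """
    def scheme(i_spta: float, days: int) -> PulseScheme:
        return PulseScheme(
            center_freq_mhz=0.5,
            prf_hz=40.0,
            burst_duration_s=1.25e-3,
            sonication_duration_s=1.0,
            inter_stimulus_interval_s=10.0,
            i_spta=i_spta,
            session_minutes=20.0,
            sessions_per_day=2,
            total_days=days,
        )

    return {
        "TUS1": scheme(0.33, 7),
        "TUS2": scheme(2.14, 7),
        "TUS3": scheme(0.33, 14),
        "TUS4": scheme(2.14, 14),
    }
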