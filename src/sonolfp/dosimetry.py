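"""Ultrasound exposure arithmetic and thermal safety estimates.

Closed-form dosimetry for rectangular pulse trains:

* duty cycle ``DC = TBD x PRF`` (ms x kHz);
* temporal-average from pulse-average intensity, ``Ispta = Isppa x DC``;
* mechanical index ``MI = PNP / sqrt(fc)`` (MPa, MHz) with the regulatory
  ceiling MI = 1.9 flagged;
* a zero-dimensional Pennes-style bio-heat estimate of tissue temperature
  rise over a sonication train: absorption heating at rate
  ``dT/dt = 2 alpha I / (rho c)`` during each sonication, Newtonian perfusion
  cooling with time constant ``tau_perf`` throughout. The piecewise-constant
  heating ODE is integrated exactly per step.

Pressure-intensity pairs are empirical calibration data and are looked up,
not derived; a plane-wave converter ``I = p^2 / (2 rho c)`` is provided
separately as an approximation for sanity checks only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocol import StimProtocol

__all__ = [
    "TissueParams",
    "DoseReport",
    "duty_cycle",
    "ispta_from_isppa",
    "mechanical_index",
    "bioheat_rise",
    "calibration_lookup",
    "plane_wave_isppa",
    "FDA_MI_LIMIT",
]

#: Regulatory mechanical-index ceiling for general tissue.
FDA_MI_LIMIT = 1.9


@dataclass
class TissueParams:
    """Brain-tissue thermal/acoustic constants (literature-standard defaults).

    alpha : acoustic amplitude absorption coefficient, Np/cm at the working
        frequency (~0.04 Np/cm for brain at 1 MHz).
    rho : density, kg/m³.
    c_heat : specific heat capacity, J/(kg K).
    tau_perf : perfusion cooling time constant, s (np.inf disables cooling).
    """

    alpha: float = 0.04
    rho: float = 1040.0
    c_heat: float = 3630.0
    tau_perf: float = 60.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.rho <= 0 or self.c_heat <= 0 or self.tau_perf <= 0:
            raise ValueError("tissue parameters must be positive")


@dataclass
class DoseReport:
    """Exposure summary for one stimulation setting."""

    ispta: float  # mW/cm²
    isppa: float  # mW/cm²
    dc: float
    pnp: float | None  # MPa, from the calibration table when available
    mi: float | None
    dt_max: float  # °C
    dt_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    dt_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def duty_cycle(tbd: float, prf: float) -> float:
    """Duty cycle from tone burst duration (ms) and PRF (kHz)."""
    if tbd <= 0 or prf <= 0:
        raise ValueError("tbd and prf must be positive")
    if tbd > 1.0 / prf:
        raise ValueError(f"tone burst ({tbd} ms) exceeds the pulse period ({1.0 / prf} ms)")
    return tbd * prf


def ispta_from_isppa(isppa: float, dc: float) -> float:
    """Temporal-average intensity from pulse-average intensity and duty cycle."""
    if not 0 <= dc <= 1:
        raise ValueError("duty cycle must be in [0, 1]")
    return isppa * dc


def mechanical_index(pnp: float, fc: float) -> float:
    """MI = peak negative pressure (MPa) / sqrt(center frequency in MHz).

    Emits a warning above the regulatory limit of 1.9.
    """
    if pnp <= 0 or fc <= 0:
        raise ValueError("pnp and fc must be positive")
    mi = pnp / np.sqrt(fc)
    if mi > FDA_MI_LIMIT:
        warnings.warn(f"MI {mi:.2f} exceeds the regulatory limit {FDA_MI_LIMIT}")
    return float(mi)


def _heating_rate(ispta_mw_cm2: float, tissue: TissueParams) -> float:
    """°C/s during sonication from the temporal-average intensity."""
    alpha_np_m = tissue.alpha * 100.0  # Np/cm -> Np/m
    intensity_w_m2 = ispta_mw_cm2 * 1e-3 * 1e4  # mW/cm² -> W/m²
    return 2.0 * alpha_np_m * intensity_w_m2 / (tissue.rho * tissue.c_heat)


def _step(temp: float, heat: float, dt: float, tau: float) -> float:
    # exact solution of dT/dt = heat - T/tau over a constant-heat interval
    if np.isinf(tau):
        return temp + heat * dt
    decay = np.exp(-dt / tau)
    return temp * decay + heat * tau * (1.0 - decay)


def bioheat_rise(
    protocol: StimProtocol,
    ispta_level: float,
    tissue: TissueParams | None = None,
    n_pulses: int = 50,
    trace_dt: float = 0.01,
) -> DoseReport:
    """Temperature rise over an ``n_pulses`` sonication train.

    ``ispta_level`` (mW/cm²) is the temporal-average intensity during each
    sonication (SD on, ISI off). The trace is sampled every ``trace_dt``
    seconds using the exact piecewise solution, so the time step affects only
    the trace resolution, not the accuracy.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if ispta_level < 0:
        raise ValueError("intensity must be non-negative")
    tissue = TissueParams() if tissue is None else tissue
    heat = _heating_rate(ispta_level, tissue)
    cycle = protocol.cycle
    total = n_pulses * cycle
    times = np.arange(0.0, total + trace_dt / 2, trace_dt)
    # segment the timeline at every sample time and every on/off boundary;
    # within a segment the heating rate is constant, so each step is exact
    pulses = np.arange(n_pulses) * cycle
    boundaries = np.concatenate([times, pulses, pulses + protocol.sd])
    bounds = np.unique(boundaries[boundaries <= total + 1e-12])
    temps = np.empty_like(bounds)
    temp = 0.0
    temps[0] = temp
    for i in range(1, len(bounds)):
        mid = 0.5 * (bounds[i - 1] + bounds[i])
        h = heat if (mid % cycle) < protocol.sd else 0.0
        temp = _step(temp, h, bounds[i] - bounds[i - 1], tissue.tau_perf)
        temps[i] = temp
    trace = temps[np.searchsorted(bounds, times)]
    pnp = None
    mi = None
    try:
        pnp = calibration_lookup(ispta_level, protocol.levels)
        mi = mechanical_index(pnp, protocol.ff)
    except LookupError:
        pass
    return DoseReport(
        ispta=ispta_level,
        isppa=ispta_level / protocol.dc,
        dc=protocol.dc,
        pnp=pnp,
        mi=mi,
        dt_max=float(temps.max()),  # peaks fall at sonication offsets, which are boundaries
        dt_times=times,
        dt_trace=trace,
    )


def calibration_lookup(
    level: float,
    table: list[tuple[float, float]],
    interpolate: bool = False,
    atol: float = 1e-9,
) -> float:
    """Peak negative pressure (MPa) for an intensity level from the empirical
    calibration table; linear interpolation between entries when enabled."""
    pairs = sorted(table)
    for ispta, pnp in pairs:
        if abs(ispta - level) <= atol:
            return float(pnp)
    if interpolate:
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        if xs[0] <= level <= xs[-1]:
            return float(np.interp(level, xs, ys))
    raise LookupError(f"level {level} mW/cm² not in calibration table")


def plane_wave_isppa(pnp_mpa: float, rho: float = 1000.0, c: float = 1500.0) -> float:
    """Approximate plane-wave pulse-average intensity I = p²/(2 rho c), mW/cm².

    For sanity checks only — calibrated pressure-intensity pairs are empirical
    and take precedence.
    """
    p = pnp_mpa * 1e6  # Pa
    i_w_m2 = p**2 / (2.0 * rho * c)
    return i_w_m2 / 10.0  # W/m² -> mW/cm²
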