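"""Phenomenological model of a gradual-oxide volatile memristor.

The device is described by a normalized internal state ``w`` in [0, 1] with
conductance ``G = g_off + w * (g_on - g_off)``.  Set pulses potentiate the
state with a saturating geometric update; between pulses the state relaxes
exponentially toward zero (short-term memory).  Reads are rectified and
non-perturbing.

All quantities are SI internally (seconds, siemens, volts, kelvin); only the
configuration layer accepts ms/nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Boltzmann constant in eV/K, used by the Arrhenius temperature law.
K_B_EV = 8.617333262e-5

# Calibration anchor for the default set protocol (4.5 V, 100 us): sixteen
# pulses from the fresh state must land the conductance at this value.
_ANCHOR_PULSES = 16
_ANCHOR_CONDUCTANCE = 1200e-9
_REF_SET_AMPLITUDE = 4.5
_REF_SET_WIDTH = 100e-6
#: Below this set amplitude no potentiation occurs.
V_SET_MIN = 3.0

# Duty-cycle -> decay time constant map: linear through the two measured
# endpoints, extrapolated across (0, 1) so distinct duties always give
# distinct decay rates.
_DUTY_LO, _TAU_LO = 0.15, 15e-3
_DUTY_HI, _TAU_HI = 0.85, 40e-3


class CalibrationError(ValueError):
    """Raised for set pulses outside the calibrated protocol envelope."""


def _solve_eta16(g_off: float, g_on: float, g_target: float = _ANCHOR_CONDUCTANCE) -> float:
    """Per-pulse gain such that 16 reference pulses reach ``g_target``.

    Closed-form inversion of ``g_off + (1 - (1-eta)^16) (g_on - g_off)``.
    """
    w16 = (g_target - g_off) / (g_on - g_off)
    return 1.0 - (1.0 - w16) ** (1.0 / _ANCHOR_PULSES)


@dataclass(frozen=True)
class DeviceParams:
    """Static parameters of one volatile memristor.

    Defaults reproduce the measured device: 55 nS baseline, ~2700x on/off,
    40 ms decay time constant at 300 K, 0.21 eV activation energy, 1e4
    rectification, and 3.87% / 1.39% spatial / cycle variation.
    """

    g_off: float = 55e-9          # S
    g_on: float = 1.5e-4          # S
    tau_ref: float = 40e-3        # s, at reference conditions (no duty, t_ref)
    ea: float = 0.21              # eV
    t_ref: float = 300.0          # K
    rectification_ratio: float = 1e4
    eta16: float = field(default=_solve_eta16(55e-9, 1.5e-4))
    cv_spatial: float = 0.0387
    cv_cycle: float = 0.0139

    def __post_init__(self) -> None:
        if not self.g_off < self.g_on:
            raise ValueError("g_off must be smaller than g_on")
        if self.tau_ref <= 0:
            raise ValueError("tau_ref must be positive")
        if self.ea < 0:
            raise ValueError("activation energy must be non-negative")
        if self.rectification_ratio < 1:
            raise ValueError("rectification_ratio must be >= 1")
        if not 0 < self.eta16 < 1:
            raise ValueError("eta16 must lie in (0, 1)")
        if self.cv_spatial < 0 or self.cv_cycle < 0:
            raise ValueError("variation coefficients must be >= 0")


@dataclass
class DeviceState:
    """Dynamic state of one device: normalized conductance, clock, temperature."""

    w: float = 0.0
    t: float = 0.0
    temperature: float = 300.0

    def conductance(self, params: DeviceParams) -> float:
        """Conductance in siemens implied by the current state."""
        return params.g_off + self.w * (params.g_on - params.g_off)


@dataclass(frozen=True)
class PulseSpec:
    """One voltage pulse: amplitude (V), width (s), polarity."""

    amplitude: float
    width: float
    polarity: str = "set"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if self.amplitude <= 0:
            raise ValueError("pulse amplitude must be positive")
        if self.polarity not in ("set", "reset", "read"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def set_gain(params: DeviceParams, amplitude: float, width: float) -> float:
    """Per-pulse potentiation gain for a set pulse of given amplitude/width.

    Width scaling follows a first-order rule anchored at the reference width:
    ``eta(width) = 1 - (1 - eta_ref)^(width / width_ref)``.  Amplitude scales
    the gain linearly between the no-potentiation floor (3.0 V) and the
    reference 4.5 V.
    """
    if amplitude <= V_SET_MIN or amplitude > _REF_SET_AMPLITUDE:
        raise CalibrationError(
            f"set pulse amplitude {amplitude} V outside calibrated range "
            f"({V_SET_MIN}, {_REF_SET_AMPLITUDE}] V; supply an explicit gain"
        )
    width_factor = 1.0 - (1.0 - params.eta16) ** (width / _REF_SET_WIDTH)
    amp_factor = (amplitude - V_SET_MIN) / (_REF_SET_AMPLITUDE - V_SET_MIN)
    return amp_factor * width_factor


def apply_set_pulse(
    state: DeviceState,
    pulse: PulseSpec,
    params: DeviceParams,
    gain: float | None = None,
) -> DeviceState:
    """Potentiate the device with one set pulse: ``w <- w + eta (1 - w)``.

    Time advances by the pulse width.  ``gain`` overrides the calibrated
    protocol gain for uncalibrated pulse shapes.
    """
    if pulse.polarity != "set":
        raise ValueError("apply_set_pulse requires a set-polarity pulse")
    eta = set_gain(params, pulse.amplitude, pulse.width) if gain is None else gain
    w = state.w + eta * (1.0 - state.w)
    return DeviceState(w=min(w, 1.0), t=state.t + pulse.width, temperature=state.temperature)


def apply_reset_pulse(
    state: DeviceState, pulse: PulseSpec, params: DeviceParams, gain: float
) -> DeviceState:
    """Depress the device: ``w <- w (1 - eta_reset)``.  Unused by default."""
    if pulse.polarity != "reset":
        raise ValueError("apply_reset_pulse requires a reset-polarity pulse")
    return DeviceState(
        w=state.w * (1.0 - gain), t=state.t + pulse.width, temperature=state.temperature
    )


def tau_of_duty(duty: float | None, params: DeviceParams) -> float:
    """Decay time constant for a duty-cycled drive, in seconds.

    Linear in duty through (0.15, 15 ms) and (0.85, 40 ms), extended across
    the full (0, 1) range so the decay rate orders strictly with duty;
    ``duty=None`` means the undriven reference constant.
    """
    if duty is None:
        return params.tau_ref
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    return _TAU_LO + (duty - _DUTY_LO) / (_DUTY_HI - _DUTY_LO) * (_TAU_HI - _TAU_LO)


def tau_effective(
    params: DeviceParams, duty: float | None = None, temperature: float | None = None
) -> float:
    """Temperature- and duty-adjusted decay constant (Arrhenius law)."""
    tau = tau_of_duty(duty, params)
    if temperature is not None and temperature != params.t_ref:
        tau *= math.exp((params.ea / K_B_EV) * (1.0 / temperature - 1.0 / params.t_ref))
    return tau


def decay(
    state: DeviceState,
    dt: float,
    params: DeviceParams,
    duty: float | None = None,
    temperature: float | None = None,
) -> DeviceState:
    """Exponential self-decay of the state over ``dt`` seconds."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    temp = temperature if temperature is not None else state.temperature
    tau = tau_effective(params, duty=duty, temperature=temp)
    return DeviceState(w=state.w * math.exp(-dt / tau), t=state.t + dt, temperature=temp)


def read_current(state: DeviceState, v_read: float, params: DeviceParams) -> float:
    """Rectified read current in amperes; non-perturbing.

    Forward reads are ohmic; reverse reads are suppressed by the
    rectification ratio.
    """
    if v_read == 0:
        raise ValueError("v_read must be non-zero")
    g = state.conductance(params)
    if v_read > 0:
        return g * v_read
    return g * v_read / params.rectification_ratio


def fit_time_constant(
    trace: list[tuple[float, float]] | np.ndarray, g_off: float = 55e-9
) -> float:
    """Least-squares exponential fit of a self-decay trace; tau in seconds.

    Fits ``log(G - g_off)`` linearly against time; samples at or below the
    baseline are rejected.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (time, conductance) samples")
    t, g = arr[:, 0], arr[:, 1]
    excess = g - g_off
    if np.any(excess <= 0):
        raise ValueError("all samples must lie strictly above the g_off baseline")
    slope = np.polyfit(t, np.log(excess), 1)[0]
    if slope >= 0:
        raise ValueError("trace does not decay; cannot fit a time constant")
    return -1.0 / slope


def estimate_activation_energy(taus: list[tuple[float, float]]) -> float:
    """Arrhenius slope of ln(tau) vs 1/T, in eV.

    ``taus`` is a list of (temperature K, tau s) pairs at >= 2 distinct
    temperatures.
    """
    arr = np.asarray(taus, dtype=float)
    if arr.ndim != 2 or len(np.unique(arr[:, 0])) < 2:
        raise ValueError("need tau measurements at >= 2 distinct temperatures")
    slope = np.polyfit(1.0 / arr[:, 0], np.log(arr[:, 1]), 1)[0]
    return slope * K_B_EV


def sample_device(params: DeviceParams, rng_seed: int) -> DeviceParams:
    """Draw one device realization with spatial (device-to-device) variation.

    ``g_on``, ``eta16`` and ``tau_ref`` are multiplied by independent
    lognormal factors with mean 1 and coefficient of variation
    ``cv_spatial``.  Deterministic for a given seed.
    """
    if params.cv_spatial == 0:
        return params
    rng = np.random.default_rng(rng_seed)
    sigma2 = math.log(1.0 + params.cv_spatial**2)
    factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=3)
    return replace(
        params,
        g_on=params.g_on * factors[0],
        eta16=min(params.eta16 * factors[1], 1.0 - 1e-12),
        tau_ref=params.tau_ref * factors[2],
    )
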