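"""Stimulus front-end: a moving contrast patch scaled by a magnocellular-LGN gain.

The network input is *undirectional*: a binary indicator ``K_{i,v}(t)`` that marks
which spatial position the contrast patch currently occupies, multiplied by a
speed-dependent activity level ``J_v`` modelling the temporal-frequency response
of magnocellular LGN cells (Benardete-Kaplan transfer-function form).  The patch
appears at ``start_pos`` at ``t = 0``, steps through one position per ``1/v``
time units, and vanishes after leaving ``end_pos``; the two boundary positions of
the default seven-position grid never receive input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "LGNParams",
    "StimulusSpec",
    "contrast_indicator",
    "occupancy_interval",
    "switch_times",
    "input_vanishing_time",
    "tau_S_effective",
    "temporal_frequency",
    "lgn_gain",
    "peak_lgn_gain",
    "input_drive",
]


@dataclass(frozen=True)
class LGNParams:
    """Constants of the magnocellular-LGN temporal transfer function.

    ``F`` normalizes the peak gain to 1; ``H_S`` is the strength of the
    contrast-gain (high-pass) stage; ``tau_L`` and ``N_L`` describe the cascade
    of low-pass filter stages; ``T_0`` is the zero-contrast time constant of the
    high-pass stage, shortened with contrast ``c`` relative to the
    half-saturation contrast ``C_half``; ``f_S`` (cycles/degree) maps stimulus
    speed to temporal frequency.
    """

    F: float = 2.206
    H_S: float = 1.00
    tau_L: float = 1.68e-3  # s
    N_L: float = 25.50
    T_0: float = 4.496e-2  # s
    C_half: float = 0.048
    f_S: float = 2.181  # cycles / degree
    contrast: float = 0.1

    def __post_init__(self) -> None:
        for name in ("F", "tau_L", "N_L", "T_0", "C_half", "f_S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LGNParams.{name} must be > 0")
        if not 0.0 <= self.H_S <= 1.0:
            raise ValueError("LGNParams.H_S must lie in [0, 1]")
        if self.contrast < 0:
            raise ValueError("LGNParams.contrast must be >= 0")


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and speed of the moving contrast patch.

    ``v_model`` is in positions per simulation-time unit.  ``w`` converts model
    speed to physical speed in degrees/second (``v_physical = v_model * w``).
    ``end_pos < start_pos`` describes the mirror-image (leftward) stimulus.
    """

    v_model: float = 1.0
    n_positions: int = 7
    start_pos: int = 2
    end_pos: int = 6
    w: float = 10.0  # degrees/second per model-speed unit

    def __post_init__(self) -> None:
        if self.v_model <= 0:
            raise ValueError("StimulusSpec.v_model must be > 0")
        if self.w <= 0:
            raise ValueError("StimulusSpec.w must be > 0")
        if not (1 <= self.start_pos <= self.n_positions
                and 1 <= self.end_pos <= self.n_positions):
            raise ValueError("start_pos/end_pos must lie within the grid")

    @property
    def rightward(self) -> bool:
        return self.end_pos >= self.start_pos

    @property
    def n_swept(self) -> int:
        """Number of positions the patch visits."""
        return abs(self.end_pos - self.start_pos) + 1

    @property
    def v_physical(self) -> float:
        return self.v_model * self.w


def contrast_indicator(spec: StimulusSpec, i: int, t: float) -> int:
    """Binary occupancy ``K_{i,v}(t)`` of position ``i`` at time ``t``.

    Equals 1 iff ``i`` lies in the swept range and ``floor(t * v)`` matches the
    step count from the starting position.  Occupancy intervals are half-open:
    the switch instant belongs to the later interval.
    """
    if not 1 <= i <= spec.n_positions:
        raise IndexError(f"position index {i} outside 1..{spec.n_positions}")
    if t < 0:
        raise ValueError("time must be >= 0")
    lo, hi = sorted((spec.start_pos, spec.end_pos))
    if not lo <= i <= hi:
        return 0
    step = (i - spec.start_pos) if spec.rightward else (spec.start_pos - i)
    return int(math.floor(t * spec.v_model) == step)


def occupancy_interval(spec: StimulusSpec, i: int) -> tuple[float, float] | None:
    """Half-open time interval ``[t0, t1)`` during which position ``i`` is occupied.

    ``None`` for positions the patch never visits.  Derived from the floor
    formula: step ``m`` occupies ``[m/v, (m+1)/v)``.
    """
    if not 1 <= i <= spec.n_positions:
        raise IndexError(f"position index {i} outside 1..{spec.n_positions}")
    lo, hi = sorted((spec.start_pos, spec.end_pos))
    if not lo <= i <= hi:
        return None
    step = (i - spec.start_pos) if spec.rightward else (spec.start_pos - i)
    return (step / spec.v_model, (step + 1) / spec.v_model)


def switch_times(spec: StimulusSpec) -> np.ndarray:
    """Times ``m/v`` at which the input steps, including onset 0 and vanishing."""
    return np.arange(spec.n_swept + 1) / spec.v_model


def input_vanishing_time(spec: StimulusSpec) -> float:
    """Time after which the input is zero at every position."""
    return spec.n_swept / spec.v_model


def tau_S_effective(p: LGNParams) -> float:
    """Contrast-shortened time constant ``tau_S = T_0 / (1 + (c/C_half)^2)``."""
    return p.T_0 / (1.0 + (p.contrast / p.C_half) ** 2)


def temporal_frequency(p: LGNParams, v_physical: float) -> float:
    """Temporal frequency ``omega = 2 pi f_S v`` (radians/second) swept by the patch."""
    v = np.asarray(v_physical, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be >= 0")
    return 2.0 * np.pi * p.f_S * v_physical


def lgn_gain(p: LGNParams, v_physical):
    """Magnocellular gain ``J_v`` at physical speed ``v_physical`` (degrees/second).

    Modulus of a single high-pass (contrast gain) stage times a cascade of
    ``N_L`` low-pass stages; band-pass in speed, vanishing in both the v -> 0
    limit (for H_S = 1) and the v -> infinity limit.  Accepts scalars or arrays.
    """
    v = np.asarray(v_physical, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be >= 0")
    omega = 2.0 * np.pi * p.f_S * v
    tau_S = tau_S_effective(p)
    highpass = 1.0 - (2.0 * p.H_S - p.H_S**2) / (1.0 + (omega * tau_S) ** 2)
    lowpass = (1.0 + (omega * p.tau_L) ** 2) ** (-p.N_L)
    radicand = highpass * lowpass
    if np.any(radicand < 0):
        raise ValueError("negative radicand in LGN gain (requires H_S <= 1)")
    out = p.F * np.sqrt(radicand)
    return float(out) if np.isscalar(v_physical) else out


def peak_lgn_gain(p: LGNParams) -> tuple[float, float]:
    """Location and value of the maximum of ``lgn_gain`` over speed.

    Coarse scan over 400 log-spaced speeds in [1e-2, 1e3] degrees/second,
    refined by golden-section search in log-speed to 1e-8 relative tolerance.
    """
    grid = np.logspace(-2, 3, 400)
    vals = lgn_gain(p, grid)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lv: -lgn_gain(p, float(np.exp(lv))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    v_peak = float(np.exp(res.x))
    return v_peak, float(lgn_gain(p, v_peak))


def drive_amplitude(spec: StimulusSpec, p: LGNParams) -> float:
    """LGN activity level of the occupied position; zero for an invisible patch.

    ``lgn_gain`` is the transfer-function modulus for a fixed-contrast patch;
    a patch with zero contrast produces no LGN response at all.
    """
    if p.contrast == 0:
        return 0.0
    return float(lgn_gain(p, spec.v_physical))


def input_drive(spec: StimulusSpec, p: LGNParams, i: int, t: float) -> float:
    """Undirectional input ``I_i(t) = J_v * K_{i,v}(t)``.

    The gain is evaluated at the physical speed ``v_model * w``.
    """
    k = contrast_indicator(spec, i, t)
    if k == 0:
        return 0.0
    return drive_amplitude(spec, p)


def input_drive_vector(spec: StimulusSpec, p: LGNParams, t: float,
                       J: float | None = None) -> np.ndarray:
    """All-position drive vector at time ``t``; ``J`` may be precomputed."""
    if J is None:
        J = drive_amplitude(spec, p)
    out = np.zeros(spec.n_positions)
    if t < 0:
        return out
    lo, hi = sorted((spec.start_pos, spec.end_pos))
    m = math.floor(t * spec.v_model)
    i = spec.start_pos + m if spec.rightward else spec.start_pos - m
    if lo <= i <= hi:
        out[i - 1] = J
    return out
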