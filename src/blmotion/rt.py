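"""Reaction-time transform: from accumulator selectivity to predicted manual RT.

Under a low-noise diffusion account of decision making, mean reaction time is
inversely related to the rate of evidence accumulation, here proxied by peak
accumulator activity (selectivity).  Model RT at physical speed ``v`` is

    RT(v) = c / s(v / w) + r,

with ``c`` a scale (ms), ``r`` a speed-independent motor offset (ms), and ``w``
the degrees-per-second value of one model-speed unit.  Empirical simple-RT
curves follow the power-law form ``RT = c v^(-beta) + r`` and are provided for
overlay only, never fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RTParams", "EmpiricalFit", "model_reaction_time", "rt_curve",
           "empirical_rt"]

#: Selectivities below this are treated as "no response" (missing RT).
MIN_SELECTIVITY = 1e-6


@dataclass(frozen=True)
class RTParams:
    c_scale: float = 100.0   # ms
    r_offset: float = 175.0  # ms
    w: float = 10.0          # degrees/second per model-speed unit

    def __post_init__(self) -> None:
        if self.c_scale <= 0 or self.r_offset <= 0 or self.w <= 0:
            raise ValueError("RTParams fields must be > 0")


@dataclass(frozen=True)
class EmpiricalFit:
    """Power-law simple-RT fit ``RT = c_fit * v^(-beta) + r_fit``."""

    c_fit: float
    beta: float
    r_fit: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("EmpiricalFit.beta must be > 0")


def model_reaction_time(s: float, p: RTParams = RTParams()) -> float | None:
    """``c / s + r`` in ms; ``None`` when selectivity is effectively zero."""
    if s < 0:
        raise ValueError("selectivity must be >= 0")
    if s < MIN_SELECTIVITY:
        return None
    return p.c_scale / s + p.r_offset


def rt_curve(sweep: pd.DataFrame, p: RTParams = RTParams()) -> pd.DataFrame:
    """Elementwise RT transform of a speed sweep's onset/offset selectivities.

    Expects columns ``v_model``, ``s_on``, ``s_off``; returns a table with
    ``v_physical_deg_per_s``, ``rt_on_ms``, ``rt_off_ms`` (missing where the
    selectivity is below threshold).
    """
    def transform(s: pd.Series) -> pd.Series:
        return s.where(s >= MIN_SELECTIVITY).rdiv(p.c_scale) + p.r_offset

    return pd.DataFrame({
        "v_physical_deg_per_s": sweep["v_model"] * p.w,
        "rt_on_ms": transform(sweep["s_on"]),
        "rt_off_ms": transform(sweep["s_off"]),
    })


def empirical_rt(v, fit: EmpiricalFit):
    """Power-law RT at physical speed ``v`` (degrees/second); scalar or array."""
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr <= 0):
        raise ValueError("speed must be > 0")
    out = fit.c_fit * v_arr ** (-fit.beta) + fit.r_fit
    return float(out) if np.isscalar(v) else out
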