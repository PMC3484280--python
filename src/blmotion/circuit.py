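"""Shunting-ODE network: nulling-inhibition motion circuit with onset/offset stages.

Every cell obeys the shunting membrane equation

    tau dx/dt = A(0 - x) + (alpha - x) I_exc - B(omega + x) I_inh,

so activity is confined to [-omega, alpha]: excitation drives the cell toward the
ceiling ``alpha``, inhibition toward the hyperpolarization floor ``-omega``, and
passive decay (rate ``A/tau``) pulls it back to rest.  Five ODE layers sit above
the explicit undirectional input at each of ``n`` positions, for each of the two
directions (leftward ``l``, rightward ``r``):

* interneurons (``inh``) -- excited by the local input, inhibited by the
  opposite-direction interneuron one position ahead (mutual nulling inhibition);
* directional cells (``dir``) -- same synaptic taps as their interneuron;
* short-range-filter cells (``srf``) -- excited by the *product* of own-position
  and behind-position directional activity, which silences isolated (spurious)
  motion signals;
* onset cells (``on``) -- excited by the SRF signal one position ahead, vetoed by
  the SRF signal at their own position (motion that already passed through);
* offset cells (``off``) -- excited by the SRF signal one position behind
  (approaching motion), vetoed when the motion continues into their own position.

Off-grid taps contribute exactly zero.  The slow passive decay of interneurons
supplies the temporal "delay" of the Barlow-Levick scheme without explicit lags.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .stimulus import (
    LGNParams,
    StimulusSpec,
    drive_amplitude,
    input_drive_vector,
    input_vanishing_time,
    switch_times,
)

__all__ = [
    "LAYERS",
    "ShuntingParams",
    "Direction",
    "NetworkState",
    "Trajectory",
    "SimulationError",
    "rectify",
    "shunting_rhs",
    "neighbor_ahead",
    "neighbor_behind",
    "interneuron_rhs",
    "directional_rhs",
    "srf_rhs",
    "onset_rhs",
    "offset_rhs",
    "full_rhs",
    "simulate",
    "cell_count",
]

#: ODE layers in state-vector order (the undirectional input layer is not state).
LAYERS = ("inh", "dir", "srf", "on", "off")

#: Gain on the SRF product nonlinearity.
SRF_GAIN = 10.0


@dataclass(frozen=True)
class ShuntingParams:
    """Circuit constants shared by every cell.

    ``A`` passive decay, ``B`` inhibitory gain, ``tau`` time constant, ``alpha``
    excitatory ceiling, ``omega_bound`` hyperpolarization floor magnitude, ``C``
    slowdown factor of the evidence accumulators.
    """

    A: float = 0.1
    B: float = 10.0
    tau: float = 1.0
    alpha: float = 1.0
    omega_bound: float = 0.3
    C: float = 10.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "tau", "alpha", "omega_bound", "C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ShuntingParams.{name} must be > 0")


class Direction(enum.Enum):
    L = "l"
    R = "r"

    @property
    def opposite(self) -> "Direction":
        return Direction.R if self is Direction.L else Direction.L

    @property
    def index(self) -> int:
        """Column index in the (position, direction) arrays: l -> 0, r -> 1."""
        return 0 if self is Direction.L else 1


def rectify(x):
    """Threshold-linear firing rate ``[x]^+ = max(x, 0)``."""
    return np.maximum(x, 0)


def shunting_rhs(x, I_exc, I_inh, p: ShuntingParams, slowdown: float = 1.0):
    """Right-hand side of the shunting membrane equation (activity/time-unit)."""
    if np.any(np.asarray(I_exc) < 0) or np.any(np.asarray(I_inh) < 0):
        raise ValueError("synaptic drives must be nonnegative")
    return (-p.A * x + (p.alpha - x) * I_exc
            - p.B * (p.omega_bound + x) * I_inh) / (slowdown * p.tau)


def neighbor_ahead(i: int, d: Direction, n: int) -> int | None:
    """Position one step along the preferred direction; ``None`` off-grid."""
    if not 1 <= i <= n:
        raise IndexError(f"position {i} outside 1..{n}")
    j = i + 1 if d is Direction.R else i - 1
    return j if 1 <= j <= n else None


def neighbor_behind(i: int, d: Direction, n: int) -> int | None:
    """Position one step against the preferred direction; ``None`` off-grid."""
    if not 1 <= i <= n:
        raise IndexError(f"position {i} outside 1..{n}")
    k = i - 1 if d is Direction.R else i + 1
    return k if 1 <= k <= n else None


@dataclass
class NetworkState:
    """All cell activities at one instant, indexed by (position 1..n, direction)."""

    inh: np.ndarray
    dir: np.ndarray
    srf: np.ndarray
    on: np.ndarray
    off: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, n_positions: int, time: float = 0.0) -> "NetworkState":
        return cls(*(np.zeros((n_positions, 2)) for _ in LAYERS), time=time)

    @property
    def n_positions(self) -> int:
        return self.inh.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def get(self, layer: str, i: int, d: Direction) -> float:
        return float(self.layer(layer)[i - 1, d.index])

    def to_flat(self) -> np.ndarray:
        return np.concatenate([self.layer(name).ravel() for name in LAYERS])

    @classmethod
    def from_flat(cls, y: np.ndarray, n_positions: int,
                  time: float = 0.0) -> "NetworkState":
        if y.size != 10 * n_positions:
            raise ValueError(
                f"flat state length {y.size} != {10 * n_positions}")
        blocks = y.reshape(len(LAYERS), n_positions, 2)
        return cls(*(blocks[k].copy() for k in range(len(LAYERS))), time=time)


def _tap(state: NetworkState, layer: str, i: int | None, d: Direction) -> float:
    """Rectified activity of a tapped cell; off-grid taps are silent."""
    if i is None:
        return 0.0
    return float(rectify(state.get(layer, i, d)))


def interneuron_rhs(state: NetworkState, i: int, d: Direction, I_i: float,
                    p: ShuntingParams) -> float:
    """Interneuron: excited by the local input, nulled by the opposite-direction
    interneuron one position ahead."""
    j = neighbor_ahead(i, d, state.n_positions)
    inh = _tap(state, "inh", j, d.opposite)
    return float(shunting_rhs(state.get("inh", i, d), I_i, inh, p))


def directional_rhs(state: NetworkState, i: int, d: Direction, I_i: float,
                    p: ShuntingParams) -> float:
    """Directional cell: same synaptic taps as its associated interneuron."""
    j = neighbor_ahead(i, d, state.n_positions)
    inh = _tap(state, "inh", j, d.opposite)
    return float(shunting_rhs(state.get("dir", i, d), I_i, inh, p))


def srf_rhs(state: NetworkState, i: int, d: Direction, p: ShuntingParams) -> float:
    """Short-range filter: product-gated by own- and behind-position directional
    activity in the same direction; purely excitatory."""
    k = neighbor_behind(i, d, state.n_positions)
    exc = SRF_GAIN * _tap(state, "dir", i, d) * _tap(state, "dir", k, d)
    return float(shunting_rhs(state.get("srf", i, d), exc, 0.0, p))


def onset_rhs(state: NetworkState, i: int, d: Direction, p: ShuntingParams,
              inh_opposite: bool = False) -> float:
    """Onset cell: excited by the SRF one position ahead, vetoed by the SRF at
    its own position (same direction by default; ``inh_opposite`` selects the
    opposite-direction variant for sensitivity analysis)."""
    j = neighbor_ahead(i, d, state.n_positions)
    exc = _tap(state, "srf", j, d)
    inh = _tap(state, "srf", i, d.opposite if inh_opposite else d)
    return float(shunting_rhs(state.get("on", i, d), exc, inh, p))


def offset_rhs(state: NetworkState, i: int, d: Direction, p: ShuntingParams) -> float:
    """Offset cell: excited by the SRF one position behind (approaching motion),
    vetoed when the SRF is active at its own position (motion continued)."""
    k = neighbor_behind(i, d, state.n_positions)
    exc = _tap(state, "srf", k, d)
    inh = _tap(state, "srf", i, d)
    return float(shunting_rhs(state.get("off", i, d), exc, inh, p))


# --- vectorized right-hand side -------------------------------------------------

def _shift_toward_start(a: np.ndarray) -> np.ndarray:
    """out[i] = a[i+1] (zero at the top edge), applied along axis 0."""
    out = np.zeros_like(a)
    out[:-1] = a[1:]
    return out


def _shift_toward_end(a: np.ndarray) -> np.ndarray:
    """out[i] = a[i-1] (zero at the bottom edge), applied along axis 0."""
    out = np.zeros_like(a)
    out[1:] = a[:-1]
    return out


def _ahead_same(a: np.ndarray) -> np.ndarray:
    """Tap at the ahead position, same direction: out[i,d] = a[ahead(i,d), d]."""
    out = np.empty_like(a)
    out[:, 0] = _shift_toward_end(a[:, 0])      # leftward: ahead = i - 1
    out[:, 1] = _shift_toward_start(a[:, 1])    # rightward: ahead = i + 1
    return out


def _ahead_opposite(a: np.ndarray) -> np.ndarray:
    """Tap at the ahead position, opposite direction: out[i,d] = a[ahead(i,d), D]."""
    out = np.empty_like(a)
    out[:, 0] = _shift_toward_end(a[:, 1])
    out[:, 1] = _shift_toward_start(a[:, 0])
    return out


def _behind_same(a: np.ndarray) -> np.ndarray:
    """Tap at the behind position, same direction: out[i,d] = a[behind(i,d), d]."""
    out = np.empty_like(a)
    out[:, 0] = _shift_toward_start(a[:, 0])    # leftward: behind = i + 1
    out[:, 1] = _shift_toward_end(a[:, 1])      # rightward: behind = i - 1
    return out


def network_derivatives(x: np.ndarray, I: np.ndarray, p: ShuntingParams,
                        onset_inh_opposite: bool = False) -> np.ndarray:
    """Layer-stacked derivatives; ``x`` has shape (5, n, 2), ``I`` shape (n,)."""
    inh, dr, srf, on, off = x
    r_inh, r_dir, r_srf = rectify(inh), rectify(dr), rectify(srf)
    Ie = I[:, None]
    null_inh = _ahead_opposite(r_inh)
    own_srf = r_srf[:, ::-1] if onset_inh_opposite else r_srf

    inv_tau = 1.0 / p.tau
    def f(xl, exc, ih):
        return (-p.A * xl + (p.alpha - xl) * exc
                - p.B * (p.omega_bound + xl) * ih) * inv_tau

    return np.stack([
        f(inh, Ie, null_inh),
        f(dr, Ie, null_inh),
        f(srf, SRF_GAIN * r_dir * _behind_same(r_dir), 0.0),
        f(on, _ahead_same(r_srf), own_srf),
        f(off, _behind_same(r_srf), r_srf),
    ])


def full_rhs(t: float, y: np.ndarray, spec: StimulusSpec, lgn: LGNParams,
             p: ShuntingParams, onset_inh_opposite: bool = False,
             J: float | None = None) -> np.ndarray:
    """Flat right-hand side over all (layer, position, direction) cells.

    State ordering is layer-major (inh, dir, srf, on, off), then position, then
    direction (l before r).
    """
    n = spec.n_positions
    if y.size != 10 * n:
        raise ValueError(f"state vector length {y.size} != {10 * n}")
    x = y.reshape(len(LAYERS), n, 2)
    I = input_drive_vector(spec, lgn, t, J=J)
    return network_derivatives(x, I, p, onset_inh_opposite).ravel()


def cell_count(spec: StimulusSpec) -> int:
    """Total cells across the six layer types, undirectional input included."""
    return spec.n_positions * (2 * len(LAYERS) + 1)


class SimulationError(RuntimeError):
    """Integrator failure, carrying the time at which it occurred."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (at t = {t:g})")
        self.t = t


@dataclass
class Trajectory:
    """Dense time courses of all network cells (and optional extra states)."""

    t: np.ndarray                       # (ns,), strictly increasing, t[0] = 0
    states: np.ndarray                  # (ns, 5, n, 2)
    inputs: np.ndarray                  # (ns, n)
    spec: StimulusSpec
    lgn: LGNParams
    params: ShuntingParams
    extra: np.ndarray | None = None     # (ns, k) co-integrated extra states
    extra_labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.spec.n_positions

    def activity(self, layer: str, i: int, d: Direction) -> np.ndarray:
        """Time course of one cell (1-based position)."""
        return self.states[:, LAYERS.index(layer), i - 1, d.index]

    def layer_max(self, layer: str) -> float:
        return float(self.states[:, LAYERS.index(layer)].max())

    def state_at(self, k: int) -> NetworkState:
        return NetworkState(*(self.states[k, j].copy() for j in range(len(LAYERS))),
                            time=float(self.t[k]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: t, layer, position, direction, activity."""
        rows = []
        for j, layer in enumerate(LAYERS):
            for i in range(self.n_positions):
                for d, dname in ((0, "l"), (1, "r")):
                    rows.append(pd.DataFrame({
                        "t": self.t,
                        "layer": layer,
                        "position": i + 1,
                        "direction": dname,
                        "activity": self.states[:, j, i, d],
                    }))
        for i in range(self.n_positions):
            rows.append(pd.DataFrame({
                "t": self.t, "layer": "input", "position": i + 1,
                "direction": "-", "activity": self.inputs[:, i],
            }))
        return pd.concat(rows, ignore_index=True)


def _sample_grid(spec: StimulusSpec, t_end: float, dense_dt: float) -> np.ndarray:
    uniform = np.arange(0.0, t_end + 0.5 * dense_dt, dense_dt)
    uniform = uniform[uniform <= t_end]
    sw = switch_times(spec)
    ts = np.unique(np.concatenate([uniform, sw[sw <= t_end], [t_end]]))
    return ts


def simulate(spec: StimulusSpec, lgn: LGNParams, p: ShuntingParams,
             t_end: float | None = None, dense_dt: float | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             onset_inh_opposite: bool = False,
             extra_rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | None = None,
             n_extra: int = 0,
             extra_labels: tuple[str, ...] = ()) -> Trajectory:
    """Integrate the network from rest, restarting at every input switch time.

    The drive is piecewise constant with discontinuities at ``m / v``; the
    adaptive Runge-Kutta 4(5) integrator is run separately on each interval so
    it never steps across a discontinuity.  ``extra_rhs(t, y_net, y_extra)``
    optionally co-integrates additional states (e.g. evidence accumulators)
    that read the network but never feed back.
    """
    if t_end is None:
        t_end = input_vanishing_time(spec) + 100.0 * p.tau
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dense_dt is None:
        dense_dt = 0.01 * p.tau

    n = spec.n_positions
    n_net = 10 * n
    J = drive_amplitude(spec, lgn)

    def drive_for_step(m: int) -> np.ndarray:
        """Constant drive vector during occupancy step ``m`` (zero after sweep)."""
        I = np.zeros(n)
        if 0 <= m < spec.n_swept:
            i = spec.start_pos + m if spec.rightward else spec.start_pos - m
            I[i - 1] = J
        return I

    ts = _sample_grid(spec, t_end, dense_dt)
    sw = switch_times(spec)
    breaks = np.unique(np.concatenate([sw[sw < t_end], [t_end]]))

    y0 = np.zeros(n_net + n_extra)
    out = np.empty((ts.size, y0.size))
    out[0] = y0
    filled = 1
    a = 0.0
    for b in breaks:
        if b <= a:
            continue
        I_seg = drive_for_step(int(np.searchsorted(sw, a, side="right")) - 1)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            x = y[:n_net].reshape(len(LAYERS), n, 2)
            dnet = network_derivatives(
                x, I_seg, p, onset_inh_opposite=onset_inh_opposite).ravel()
            if extra_rhs is None:
                return dnet
            return np.concatenate([dnet, extra_rhs(t, y[:n_net], y[n_net:])])

        seg_mask = (ts > a) & (ts <= b)
        seg_eval = ts[seg_mask]
        if seg_eval.size == 0 or seg_eval[-1] < b:
            seg_eval = np.concatenate([seg_eval, [b]])
        sol = solve_ivp(rhs, (a, b), y0, method="RK45", t_eval=seg_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}", a)
        k = int(seg_mask.sum())
        if k:
            out[filled:filled + k] = sol.y[:, :k].T
            filled += k
        y0 = sol.y[:, -1]
        a = b
    if filled != ts.size:
        raise SimulationError(
            f"sample grid not fully covered ({filled}/{ts.size})", a)

    # inputs are right-continuous at the switch instants
    step_of = np.searchsorted(sw, ts, side="right") - 1
    inputs = np.stack([drive_for_step(m) for m in step_of])
    states = out[:, :n_net].reshape(ts.size, len(LAYERS), n, 2)
    extra = out[:, n_net:] if n_extra else None
    meta = {"rtol": rtol, "atol": atol, "dense_dt": dense_dt, "t_end": t_end,
            "onset_inh_opposite": onset_inh_opposite, "J_v": J,
            "method": "RK45 piecewise over input-switch intervals"}
    return Trajectory(t=ts, states=states, inputs=inputs, spec=spec, lgn=lgn,
                      params=p, extra=extra, extra_labels=extra_labels, meta=meta)
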