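"""Experiment orchestration: single runs, speed sweeps, parameter sweeps, tables.

Everything here is deterministic -- there is no randomness anywhere in the
model -- so repeated runs with the same configuration produce byte-identical
output tables.  A YAML configuration file with sections ``model`` / ``lgn`` /
``stimulus`` / ``readout`` / ``rt`` / ``sweep`` / ``integrator`` names every
circuit constant; omitted keys take the standard defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import ShuntingParams, Trajectory, cell_count
from .readout import DEFAULT_THRESHOLD, RunReadout, measure_run
from .rt import RTParams, rt_curve
from .stimulus import (
    LGNParams,
    StimulusSpec,
    drive_amplitude,
    input_vanishing_time,
    lgn_gain,
    occupancy_interval,
)

logger = logging.getLogger("blmotion")

__all__ = [
    "Config",
    "SweepResult",
    "ParamSweepResult",
    "SingleRunResult",
    "default_config",
    "load_config",
    "run_single",
    "speed_sweep",
    "parameter_sweep",
    "write_tables",
    "lgn_curve_table",
]

SWEEP_COLUMNS = ("v_model", "v_physical", "s_on", "s_dir", "s_off",
                 "t_on", "t_dir", "t_off")


@dataclass(frozen=True)
class SweepSettings:
    n_speeds: int = 60
    v_min: float = 1e-2
    v_max: float = 1e2
    param_multipliers: tuple[float, ...] = (0.1, 1.0, 10.0)
    param_names: tuple[str, ...] = ("A", "B", "tau")


@dataclass(frozen=True)
class ReadoutSettings:
    threshold: float = DEFAULT_THRESHOLD
    onset_inh_opposite: bool = False


@dataclass(frozen=True)
class IntegratorSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    dense_dt: float | None = None   # default: 0.01 * tau
    t_end: float | None = None      # default: n_swept / v + 100 * tau


@dataclass(frozen=True)
class Config:
    model: ShuntingParams = ShuntingParams()
    lgn: LGNParams = LGNParams()
    stimulus: StimulusSpec = StimulusSpec()
    readout: ReadoutSettings = ReadoutSettings()
    rt: RTParams = RTParams()
    sweep: SweepSettings = SweepSettings()
    integrator: IntegratorSettings = IntegratorSettings()

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in ("model", "lgn", "stimulus", "readout", "rt",
                             "sweep", "integrator")}

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        sections = {"model": ShuntingParams, "lgn": LGNParams,
                    "stimulus": StimulusSpec, "readout": ReadoutSettings,
                    "rt": RTParams, "sweep": SweepSettings,
                    "integrator": IntegratorSettings}
        kwargs = {}
        for name, typ in sections.items():
            raw = dict(d.get(name) or {})
            valid = {f.name for f in dataclasses.fields(typ)}
            unknown = set(raw) - valid
            if unknown:
                raise ValueError(
                    f"config section {name!r}: unknown keys {sorted(unknown)}")
            for key, val in raw.items():
                if isinstance(val, list):
                    raw[key] = tuple(val)
            kwargs[name] = typ(**raw)
        extra = set(d) - set(sections)
        if extra:
            raise ValueError(f"unknown config sections {sorted(extra)}")
        return cls(**kwargs)


def default_config() -> Config:
    return Config()


def load_config(path: str | Path) -> Config:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return Config.from_dict(raw)


def _provenance(config: Config) -> dict:
    from . import __version__
    return {"config": config.to_dict(), "code_version": __version__}


@dataclass
class SweepResult:
    """One readout row per stimulus speed, speeds strictly increasing."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class ParamSweepResult:
    """Speed sweeps repeated over multiplicative perturbations of A, B, tau."""

    blocks: dict[str, dict[float, SweepResult]]
    provenance: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        frames = []
        for pname, by_mult in self.blocks.items():
            for mult, sweep in by_mult.items():
                f = sweep.table.copy()
                f.insert(0, "parameter", pname)
                f.insert(1, "multiplier", mult)
                frames.append(f)
        return pd.concat(frames, ignore_index=True)


@dataclass
class SingleRunResult:
    """Trajectory, accumulator courses, and event summary of one default run."""

    trajectory: Trajectory
    accumulators: pd.DataFrame          # t, y_on, y_dir, y_off
    readout: RunReadout
    events: pd.DataFrame                # event, position, time
    occupancy: pd.DataFrame             # position, t_start, t_end (Fig-style table)
    n_cells: int


def run_single(config: Config = None) -> SingleRunResult:
    """The standard single-run protocol at the configured speed (default v = 1)."""
    config = config or default_config()
    spec, lgn, p = config.stimulus, config.lgn, config.model
    intg = config.integrator
    readout, traj = measure_run(
        spec, lgn, p, threshold=config.readout.threshold,
        t_end=intg.t_end, dense_dt=intg.dense_dt,
        rtol=intg.rtol, atol=intg.atol,
        onset_inh_opposite=config.readout.onset_inh_opposite,
        return_trajectory=True)
    acc = pd.DataFrame({"t": traj.t,
                        "y_on": traj.extra[:, 0],
                        "y_dir": traj.extra[:, 1],
                        "y_off": traj.extra[:, 2]})
    occ_rows = []
    ev_rows = []
    if drive_amplitude(spec, lgn) > 0:
        for i in range(1, spec.n_positions + 1):
            iv = occupancy_interval(spec, i)
            if iv is not None:
                occ_rows.append({"position": i, "t_start": iv[0], "t_end": iv[1]})
        ev_rows.append({"event": "motion_onset", "position": spec.start_pos,
                        "time": 0.0})
        ev_rows.append({"event": "input_vanishes", "position": spec.end_pos,
                        "time": input_vanishing_time(spec)})
    occupancy = pd.DataFrame(occ_rows, columns=["position", "t_start", "t_end"])
    events = pd.DataFrame(ev_rows, columns=["event", "position", "time"])
    return SingleRunResult(trajectory=traj, accumulators=acc, readout=readout,
                           events=events, occupancy=occupancy,
                           n_cells=cell_count(spec))


def default_speed_grid(settings: SweepSettings) -> np.ndarray:
    return np.logspace(np.log10(settings.v_min), np.log10(settings.v_max),
                       settings.n_speeds)


def speed_sweep(config: Config = None, speeds=None,
                model: ShuntingParams | None = None) -> SweepResult:
    """Readout at every speed of the grid; a failed speed yields a missing row."""
    config = config or default_config()
    p = model if model is not None else config.model
    if speeds is None:
        speeds = default_speed_grid(config.sweep)
    speeds = np.asarray(speeds, dtype=float)
    if speeds.ndim != 1 or np.any(np.diff(speeds) <= 0):
        raise ValueError("speeds must be a strictly increasing 1-D grid")
    intg = config.integrator
    rows = []
    for v in speeds:
        try:
            r = measure_run(config.stimulus, config.lgn, p, v_model=float(v),
                            threshold=config.readout.threshold,
                            t_end=intg.t_end, dense_dt=intg.dense_dt,
                            rtol=intg.rtol, atol=intg.atol,
                            onset_inh_opposite=config.readout.onset_inh_opposite)
            rows.append(r.as_dict())
        except Exception as exc:  # record, do not abort the sweep
            logger.warning("speed %g failed: %s", v, exc)
            rows.append({"v_model": float(v),
                         "v_physical": float(v) * config.stimulus.w,
                         **{c: np.nan for c in SWEEP_COLUMNS[2:]}})
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS).astype(float)
    return SweepResult(table=table, provenance=_provenance(config))


def parameter_sweep(config: Config = None, speeds=None) -> ParamSweepResult:
    """Speed sweeps with A, B, tau each scaled over the configured multipliers.

    The unscaled (multiplier 1) block is computed once and shared across the
    parameter blocks, so those rows are bitwise identical by construction.
    """
    config = config or default_config()
    base = config.model
    baseline: SweepResult | None = None
    blocks: dict[str, dict[float, SweepResult]] = {}
    for pname in config.sweep.param_names:
        if pname not in {f.name for f in dataclasses.fields(ShuntingParams)}:
            raise ValueError(f"unknown sweep parameter {pname!r}")
        blocks[pname] = {}
        for mult in config.sweep.param_multipliers:
            if mult == 1.0:
                if baseline is None:
                    baseline = speed_sweep(config, speeds=speeds, model=base)
                blocks[pname][mult] = SweepResult(
                    table=baseline.table.copy(), provenance=baseline.provenance)
            else:
                scaled = replace(base, **{pname: getattr(base, pname) * mult})
                blocks[pname][mult] = speed_sweep(config, speeds=speeds,
                                                  model=scaled)
    return ParamSweepResult(blocks=blocks, provenance=_provenance(config))


def lgn_curve_table(config: Config = None, speeds=None) -> pd.DataFrame:
    """LGN gain over a physical-speed grid (columns: v_physical, J)."""
    config = config or default_config()
    if speeds is None:
        speeds = np.logspace(-2, 3, 200)
    return pd.DataFrame({"v_physical": speeds,
                         "J": lgn_gain(config.lgn, np.asarray(speeds))})


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def write_tables(result, out_prefix: str | Path, config: Config = None) -> list[Path]:
    """Write deterministic CSV tables plus a JSON sidecar for any result object.

    Missing latencies / reaction times are serialized as empty fields.
    Re-running an identical configuration reproduces byte-identical files.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def sidecar(provenance: dict) -> None:
        path = out_prefix.with_name(out_prefix.name + "_meta.json")
        payload = dict(provenance)
        if config is not None:
            payload["config"] = config.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)

    if isinstance(result, SingleRunResult):
        pairs = [("_trajectory.csv", result.trajectory.to_frame()),
                 ("_accumulators.csv", result.accumulators),
                 ("_events.csv", result.events),
                 ("_occupancy.csv", result.occupancy),
                 ("_readout.csv", pd.DataFrame([result.readout.as_dict()]))]
        for suffix, df in pairs:
            path = out_prefix.with_name(out_prefix.name + suffix)
            _write_csv(df, path)
            written.append(path)
        meta = dict(result.trajectory.meta)
        meta["n_cells"] = result.n_cells
        sidecar({"run": meta,
                 "config": (config or default_config()).to_dict()})
    elif isinstance(result, SweepResult):
        path = out_prefix.with_name(out_prefix.name + "_sweep.csv")
        _write_csv(result.table, path)
        written.append(path)
        sidecar(result.provenance)
    elif isinstance(result, ParamSweepResult):
        path = out_prefix.with_name(out_prefix.name + "_param_sweep.csv")
        _write_csv(result.table(), path)
        written.append(path)
        sidecar(result.provenance)
    elif isinstance(result, pd.DataFrame):
        path = out_prefix.with_name(out_prefix.name + ".csv")
        _write_csv(result, path)
        written.append(path)
        if config is not None:
            sidecar({})
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")
    return written


def rt_table(sweep: SweepResult, config: Config = None) -> pd.DataFrame:
    """Reaction-time curve of a sweep, with optional empirical overlay columns."""
    config = config or default_config()
    return rt_curve(sweep.table, config.rt)
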