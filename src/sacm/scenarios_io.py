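"""Scenario definitions, the scenario runner, telemetry, and analysis.

A scenario is an ordered list of normalized time intervals.  Each interval
injects events at its start (open the extremity bleed valve, set the
internal hemorrhage pump, loosen the tourniquet cuff, start SACM) and ends
when its ``until`` condition is met (a MAP threshold crossing, the next
occurrence of a supervisor event, or a fixed duration).  The five bundled
scenarios reproduce the benchtop trauma test matrix: an initial hemorrhage
to ~75 mmHg, extremity bleed + tourniquet engagement, resuscitation to
95 mmHg, and then combinations of tourniquet-loosening and
internal-hemorrhage complications handled by the monitoring phase.

Telemetry records five channels per 50 Hz tick — distal MAP, cuff
pressure, central MAP, infusion rate, and fluid balance (cumulative
infused minus cumulative hemorrhage volume) — plus the supervisor event
stream and the interval boundary timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .arc import ArcConfig, ResuscitationResult, run_resuscitation
from .atkt import TkConfig
from .plant import (
    ActuatorCommands,
    FlowLoopPlant,
    PlantConfig,
    default_curve,
)
from .supervisor import EventKind, Supervisor, SupervisorConfig, SupervisorEvent

__all__ = [
    "ScenarioSpec",
    "TelemetryLog",
    "load_scenario",
    "bundled_scenario",
    "bundled_scenario_names",
    "run_scenario",
    "run_sacm",
    "fluid_balance",
    "bin_intervals",
    "export_heatmap",
    "write_heatmap",
    "ARC_TEST_MATRIX",
    "run_arc_condition",
]


# --------------------------------------------------------------------------
# scenario schema
# --------------------------------------------------------------------------

class EventSpec(BaseModel):
    """One injected scenario event."""

    model_config = ConfigDict(extra="forbid")

    action: Literal[
        "set_internal_hemorrhage",
        "open_extremity_valve",
        "close_extremity_valve",
        "loosen_tourniquet",
        "start_sacm",
    ]
    rate_ml_min: Optional[float] = None  # set_internal_hemorrhage
    fraction: Optional[float] = None  # loosen_tourniquet
    delay_s: float = 0.0  # offset from interval start

    @model_validator(mode="after")
    def _check_params(self) -> "EventSpec":
        if self.action == "set_internal_hemorrhage":
            if self.rate_ml_min is None or self.rate_ml_min < 0:
                raise ValueError(
                    "set_internal_hemorrhage requires rate_ml_min >= 0"
                )
        if self.action == "loosen_tourniquet":
            if self.fraction is None or not (0.0 <= self.fraction < 1.0):
                raise ValueError("loosen_tourniquet requires fraction in [0, 1)")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        return self


class UntilSpec(BaseModel):
    """Interval end condition; exactly one field must be set."""

    model_config = ConfigDict(extra="forbid")

    map_below: Optional[float] = None
    event: Optional[Literal[
        "atkt_engaged", "arc_started", "arc_completed", "atkt_reengaged",
        "loose_detected", "low_map_detected",
    ]] = None
    duration_s: Optional[float] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "UntilSpec":
        n = sum(x is not None for x in (self.map_below, self.event, self.duration_s))
        if n != 1:
            raise ValueError("exactly one of map_below/event/duration_s required")
        return self


class IntervalSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    events: list[EventSpec] = []
    until: UntilSpec
    on_end: list[EventSpec] = []
    settle_s: float = 0.0


class ScenarioSpec(BaseModel):
    """Validated scenario definition."""

    model_config = ConfigDict(extra="forbid")

    name: str
    infusate: Literal["whole_blood", "crystalloid"] = "whole_blood"
    initial_map: float = 95.0
    seed: Optional[int] = None
    intervals: list[IntervalSpec]

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load and validate a YAML scenario file.

    Unknown keys and malformed values raise a descriptive error naming the
    offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return ScenarioSpec.model_validate(raw)
    except ValidationError as exc:
        raise ValueError(f"invalid scenario file {path}:\n{exc}") from exc


def bundled_scenario_names() -> list[str]:
    files = resources.files("sacm").joinpath("scenarios")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def bundled_scenario(name: str) -> ScenarioSpec:
    """Load one of the packaged scenarios, e.g. ``scenario_1`` .. ``scenario_5``."""
    ref = resources.files("sacm").joinpath(f"scenarios/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ValueError(
            f"unknown bundled scenario {name!r}; "
            f"available: {bundled_scenario_names()}"
        ) from None
    return ScenarioSpec.model_validate(raw)


# --------------------------------------------------------------------------
# telemetry
# --------------------------------------------------------------------------

@dataclass
class TelemetryLog:
    """Per-tick records of the five reported channels plus events."""

    frame: pd.DataFrame
    events: list[SupervisorEvent]
    interval_boundaries: list[float]
    scenario_name: str = ""
    seed: int = 0

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")

    def events_to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario_name,
            "seed": self.seed,
            "interval_boundaries": self.interval_boundaries,
            "events": [
                {"t": e.t, "kind": e.kind.value, "detail": e.detail}
                for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def event_times(self, kind: EventKind | str) -> list[float]:
        kind = EventKind(kind)
        return [e.t for e in self.events if e.kind is kind]


def fluid_balance(log: TelemetryLog) -> pd.Series:
    """Per-tick fluid balance (mL): cumulative infused minus hemorrhage."""
    return log.frame.set_index("t")["fluid_balance"]


# --------------------------------------------------------------------------
# scenario runner
# --------------------------------------------------------------------------

@dataclass
class _Schedule:
    """Mutable hemorrhage/valve schedule the scenario events act on."""

    internal_hem_rate: float = 0.0
    extremity_valve_open: bool = False


def _apply_event(
    ev: EventSpec, sched: _Schedule, sup: Supervisor, t: float
) -> None:
    if ev.action == "set_internal_hemorrhage":
        sched.internal_hem_rate = float(ev.rate_ml_min)
    elif ev.action == "open_extremity_valve":
        sched.extremity_valve_open = True
    elif ev.action == "close_extremity_valve":
        sched.extremity_valve_open = False
    elif ev.action == "loosen_tourniquet":
        sup.loosen_cuff(float(ev.fraction))
    elif ev.action == "start_sacm":
        sup.start(t)


def run_scenario(
    spec: ScenarioSpec,
    plant_cfg: PlantConfig | None = None,
    tk_cfg: TkConfig | None = None,
    arc_cfg: ArcConfig | None = None,
    sup_cfg: SupervisorConfig | None = None,
    seed: int = 0,
) -> TelemetryLog:
    """Drive the plant and SACM through every interval of a scenario.

    Deterministic given ``seed`` (which seeds sensor noise, when enabled).
    Returns the full telemetry log with interval boundary timestamps.
    """
    if spec.seed is not None:
        seed = spec.seed
    if plant_cfg is None:
        plant_cfg = PlantConfig(curve=default_curve(spec.infusate))
    plant_cfg.noise_seed = seed
    plant = FlowLoopPlant(plant_cfg, initial_map=spec.initial_map)
    sup = Supervisor(plant, tk_cfg, arc_cfg, sup_cfg)
    sched = _Schedule()
    dt = plant_cfg.dt
    max_t = sup.cfg.max_scenario_time

    rows_t: list[float] = []
    rows: list[tuple[float, float, float, float, float]] = []
    boundaries: list[float] = [0.0]
    truncated = False

    for interval in spec.intervals:
        t0 = plant.state.t
        pending = sorted(interval.events, key=lambda e: e.delay_s)
        n_events_at_start = len(sup.events)
        settle_deadline: float | None = None

        while True:
            t = plant.state.t
            if t > max_t:
                truncated = True
                break
            while pending and t >= t0 + pending[0].delay_s - 1e-9:
                _apply_event(pending.pop(0), sched, sup, t)

            infusion, cuff = sup.update(t)
            plant.step(
                ActuatorCommands(
                    infusion_rate=infusion,
                    internal_hem_rate=sched.internal_hem_rate,
                    cuff_pressure_target=cuff,
                    extremity_valve_open=sched.extremity_valve_open,
                ),
                dt,
            )
            s = plant.state
            central, distal, cuff_s = plant.latest_samples()
            rows_t.append(s.t)
            rows.append(
                (distal, cuff_s, central, s.infusion_rate,
                 plant.fluid_balance, s.v_vessel)
            )

            if settle_deadline is not None:
                if s.t >= settle_deadline:
                    break
                continue
            if pending:
                continue  # injected events must land before the interval can end
            u = interval.until
            met = False
            if u.map_below is not None:
                met = plant.windowed_map() < u.map_below
            elif u.duration_s is not None:
                met = s.t - t0 >= u.duration_s
            else:
                kind = EventKind(u.event)
                met = any(
                    e.kind is kind for e in sup.events[n_events_at_start:]
                )
            if met:
                for ev in interval.on_end:
                    _apply_event(ev, sched, sup, s.t)
                if interval.settle_s > 0:
                    settle_deadline = s.t + interval.settle_s
                else:
                    break
        boundaries.append(plant.state.t)
        if truncated:
            sup.events.append(
                SupervisorEvent(plant.state.t, EventKind.ERROR, "time cap: log truncated")
            )
            break

    frame = pd.DataFrame(
        rows,
        columns=["distal_map", "cuff_pressure", "central_map",
                 "infusion_rate", "fluid_balance", "v_vessel"],
    )
    frame.insert(0, "t", np.asarray(rows_t))
    return TelemetryLog(
        frame=frame,
        events=sup.events,
        interval_boundaries=boundaries,
        scenario_name=spec.name,
        seed=seed,
    )


def run_sacm(
    plant_cfg: PlantConfig | None,
    scenario: ScenarioSpec,
    tk_cfg: TkConfig | None = None,
    arc_cfg: ArcConfig | None = None,
    sup_cfg: SupervisorConfig | None = None,
    seed: int = 0,
) -> TelemetryLog:
    """Alias of :func:`run_scenario` with an explicit plant configuration."""
    return run_scenario(scenario, plant_cfg, tk_cfg, arc_cfg, sup_cfg, seed)


# --------------------------------------------------------------------------
# analysis
# --------------------------------------------------------------------------

def bin_intervals(
    log: TelemetryLog, n_bins: int | None = None, points_per_bin: int = 100
) -> pd.DataFrame:
    """Map telemetry onto normalized interval coordinates.

    Time within interval ``n`` is mapped to the coordinate range
    ``[n-1, n]``, confining each scenario into its three or five bins so
    replicate runs with different absolute interval durations align.
    Returns a frame indexed by the normalized coordinate with each channel
    resampled to ``points_per_bin`` points per bin.
    """
    bounds = log.interval_boundaries
    if len(bounds) < 2:
        raise ValueError("telemetry log has no recorded interval boundaries")
    if n_bins is None:
        n_bins = len(bounds) - 1
    elif n_bins != len(bounds) - 1:
        raise ValueError(
            f"log has {len(bounds) - 1} intervals, not {n_bins}"
        )
    t = log.frame["t"].to_numpy()
    channels = [c for c in log.frame.columns if c != "t"]
    coords = []
    resampled = {c: [] for c in channels}
    for i in range(n_bins):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            raise ValueError("interval boundaries must be strictly increasing")
        grid = np.linspace(lo, hi, points_per_bin, endpoint=False)
        coords.append(i + (grid - lo) / (hi - lo))
        for c in channels:
            resampled[c].append(
                np.interp(grid, t, log.frame[c].to_numpy())
            )
    out = pd.DataFrame(
        {c: np.concatenate(v) for c, v in resampled.items()},
        index=pd.Index(np.concatenate(coords), name="interval_coord"),
    )
    return out


def export_heatmap(
    rate_traces: list[list[tuple[float, float]]],
    q_max: float = 1200.0,
    sample_period: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Build the replicate-by-time infusion heatmap matrix.

    Rows are replicates; columns a common 1 Hz time grid spanning the
    longest trace (shorter replicates are padded with zero flow after
    completion).  Values are normalized to [0, 1] by the maximum infusion
    rate (1200 mL/min), so ``value * q_max`` recovers the rate.
    """
    if not rate_traces:
        raise ValueError("need at least one rate trace")
    durations = []
    for trace in rate_traces:
        if not trace:
            raise ValueError("empty rate trace")
        durations.append(trace[-1][0] - trace[0][0])
    longest = max(durations)
    n_cols = int(round(longest / sample_period)) + 1
    grid = np.arange(n_cols) * sample_period
    matrix = np.zeros((len(rate_traces), n_cols))
    for i, trace in enumerate(rate_traces):
        tt = np.array([p[0] for p in trace]) - trace[0][0]
        rr = np.array([p[1] for p in trace])
        matrix[i] = np.interp(grid, tt, rr, right=0.0)
    matrix = np.clip(matrix / q_max, 0.0, 1.0)
    meta = {
        "q_max_ml_min": q_max,
        "sample_period_s": sample_period,
        "longest_duration_s": longest,
        "n_replicates": len(rate_traces),
    }
    return matrix, meta


def write_heatmap(
    matrix: np.ndarray, meta: dict, out_csv: str | Path
) -> None:
    """Write the heatmap matrix as CSV with a JSON sidecar of scaling constants."""
    out_csv = Path(out_csv)
    pd.DataFrame(matrix).to_csv(out_csv, index=False, float_format="%.6f")
    out_csv.with_suffix(".json").write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------------
# ARC test matrix
# --------------------------------------------------------------------------

#: the eight controller test-bench conditions: scaling-factor sweep and
#: hemorrhage-rate sweep on whole blood, baseline and 240 mL/min hemorrhage
#: on crystalloid
ARC_TEST_MATRIX: dict[str, dict] = {
    "wb_scale_0.5": {"infusate": "whole_blood", "scaling_factor": 0.5, "hem_rate": 0.0},
    "wb_baseline": {"infusate": "whole_blood", "scaling_factor": 1.0, "hem_rate": 0.0},
    "wb_scale_2": {"infusate": "whole_blood", "scaling_factor": 2.0, "hem_rate": 0.0},
    "wb_hem_120": {"infusate": "whole_blood", "scaling_factor": 1.0, "hem_rate": 120.0},
    "wb_hem_240": {"infusate": "whole_blood", "scaling_factor": 1.0, "hem_rate": 240.0},
    "wb_hem_360": {"infusate": "whole_blood", "scaling_factor": 1.0, "hem_rate": 360.0},
    "cryst_baseline": {"infusate": "crystalloid", "scaling_factor": 1.0, "hem_rate": 0.0},
    "cryst_hem_240": {"infusate": "crystalloid", "scaling_factor": 1.0, "hem_rate": 240.0},
}


def run_arc_condition(
    condition: str,
    seed: int = 0,
    start_map: float = 75.0,
    map_target: float = 95.0,
    noise_sd: float = 0.0,
) -> ResuscitationResult:
    """Run one controller test-bench condition from ~75 to 95 mmHg."""
    try:
        params = ARC_TEST_MATRIX[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; pick from {sorted(ARC_TEST_MATRIX)}"
        ) from None
    curve = default_curve(params["infusate"])
    plant = FlowLoopPlant(
        PlantConfig(curve=curve, noise_sd=noise_sd, noise_seed=seed),
        initial_map=start_map,
    )
    cfg = ArcConfig(
        map_target=map_target,
        scaling_factor=params["scaling_factor"],
        curve=curve,
    )
    return run_resuscitation(plant, cfg, internal_hem_rate=params["hem_rate"])
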