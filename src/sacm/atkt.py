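"""Automated tourniquet (aTKT) controller.

The cuff is tightened in fixed pressure increments, dwelling at each level,
until the arterial pulse distal to the cuff disappears — the plateau that
verifies occlusion.  After engagement, two loosening checks protect the
occlusion:

* **re-bleed**: arterial oscillations transmitted into the cuff air
  pressure mean the artery has reopened under the cuff;
* **mechanical failure**: the cuff air pressure has dropped more than 33%
  from the recorded engagement pressure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .plant import ActuatorCommands, FlowLoopPlant

__all__ = [
    "TkConfig",
    "EngagementResult",
    "LooseStatus",
    "detect_loose",
    "TourniquetController",
    "engage",
]


@dataclass
class TkConfig:
    """Tourniquet controller parameters.

    Attributes
    ----------
    pressure_step : float
        Cuff pressure added per tightening increment, mmHg.
    step_dwell : float
        Hold time at each increment before re-checking pulsatility, s.
    occlusion_pulse_epsilon : float
        Distal peak-to-peak pulsatility below which flow counts as
        occluded, mmHg.
    oscillation_threshold : float
        Cuff peak-to-peak oscillation at/above which a re-bleed is flagged,
        mmHg.
    failure_drop_fraction : float
        Fractional cuff-pressure drop from the engagement pressure beyond
        which (strictly greater) a mechanical failure is flagged.
    max_cuff_pressure : float
        Safety ceiling on cuff inflation, mmHg.
    loose_window : float
        Length of the cuff sample window used by loosening detection, s;
        must span at least two cardiac cycles.
    """

    pressure_step: float = 25.0
    step_dwell: float = 2.0
    occlusion_pulse_epsilon: float = 0.5
    oscillation_threshold: float = 2.0
    failure_drop_fraction: float = 0.33
    max_cuff_pressure: float = 400.0
    loose_window: float = 4.0

    def __post_init__(self) -> None:
        if self.pressure_step <= 0:
            raise ValueError("pressure_step must be positive")
        if not (0.0 < self.failure_drop_fraction < 1.0):
            raise ValueError("failure_drop_fraction must be in (0, 1)")
        if self.step_dwell <= 0:
            raise ValueError("step_dwell must be positive")


@dataclass
class EngagementResult:
    """Outcome of one tightening run."""

    engagement_pressure: float  # mmHg recorded at occlusion verification
    n_steps: int
    occluded: bool
    cuff_trace: list[tuple[float, float]]  # (t, commanded cuff pressure)


class LooseStatus(str, Enum):
    OK = "ok"
    REBLEED_OSCILLATION = "rebleed_oscillation"
    MECHANICAL_FAILURE = "mechanical_failure"


def detect_loose(
    cuff_window: np.ndarray, engagement_pressure: float, cfg: TkConfig
) -> LooseStatus:
    """Classify the recent cuff-pressure window against the loosening rules.

    Mechanical failure (large pressure drop) takes precedence over the
    oscillation re-bleed criterion: a collapsed bladder implicates the
    hardware regardless of any transmitted pulse.
    """
    cuff_window = np.asarray(cuff_window, dtype=float)
    if cuff_window.size == 0:
        raise ValueError("cuff window is empty")
    if engagement_pressure <= 0:
        raise ValueError("engagement_pressure must be positive")
    drop = (engagement_pressure - float(cuff_window.mean())) / engagement_pressure
    if drop > cfg.failure_drop_fraction:
        return LooseStatus.MECHANICAL_FAILURE
    if float(cuff_window.max() - cuff_window.min()) >= cfg.oscillation_threshold:
        return LooseStatus.REBLEED_OSCILLATION
    return LooseStatus.OK


class TourniquetController:
    """Incremental tightening state machine for cooperative scheduling.

    Call :meth:`start`, then :meth:`update` every plant step; actions occur
    only at dwell boundaries.  The commanded cuff pressure is returned and
    must be applied to the plant by the caller.
    """

    def __init__(self, cfg: TkConfig) -> None:
        self.cfg = cfg
        self.active = False
        self.done = False
        self.occluded = False
        self.engagement_pressure = 0.0
        self.n_steps = 0
        self.cuff_target = 0.0
        self.cuff_trace: list[tuple[float, float]] = []
        self._next_check = 0.0

    def start(self, t: float, cuff_target: float = 0.0) -> None:
        if self.active:
            raise RuntimeError("aTKT instance already running")
        self.active = True
        self.done = False
        self.occluded = False
        self.n_steps = 0
        self.cuff_target = cuff_target
        self.cuff_trace = [(t, cuff_target)]
        # observe one full dwell before the first decision, so the
        # pulsatility window reflects the current cuff level (and an
        # already-occluded start terminates with zero tightening steps)
        self._next_check = t + self.cfg.step_dwell

    def due(self, t: float) -> bool:
        """True when a dwell boundary requires a pulsatility check at ``t``."""
        return self.active and t + 1e-9 >= self._next_check

    def update(self, t: float, distal_peak_to_peak: float) -> float:
        """Advance the tightening logic; returns the commanded cuff pressure."""
        if not self.active:
            return self.cuff_target
        if t + 1e-9 < self._next_check:
            return self.cuff_target
        if distal_peak_to_peak < self.cfg.occlusion_pulse_epsilon:
            self.occluded = True
            self.engagement_pressure = self.cuff_target
            self.done = True
            self.active = False
        elif self.cuff_target + self.cfg.pressure_step > self.cfg.max_cuff_pressure:
            # cannot occlude within the safety ceiling; surface to supervisor
            self.done = True
            self.active = False
            self.occluded = False
        else:
            self.cuff_target += self.cfg.pressure_step
            self.n_steps += 1
            self.cuff_trace.append((t, self.cuff_target))
            self._next_check = t + self.cfg.step_dwell
        return self.cuff_target

    def result(self) -> EngagementResult:
        return EngagementResult(
            engagement_pressure=self.engagement_pressure,
            n_steps=self.n_steps,
            occluded=self.occluded,
            cuff_trace=list(self.cuff_trace),
        )


def engage(
    plant: FlowLoopPlant,
    cfg: TkConfig,
    internal_hem_rate: float = 0.0,
    extremity_valve_open: bool = True,
    infusion_rate: float = 0.0,
) -> EngagementResult:
    """Tighten the cuff on the plant until arterial occlusion is verified.

    Pressurizes in ``pressure_step`` increments, dwelling ``step_dwell``
    seconds at each, until the distal pulsatility stays below
    ``occlusion_pulse_epsilon`` for a full dwell.  Distal MAP falls to near
    zero under full occlusion while central MAP is unaffected.
    """
    ctrl = TourniquetController(cfg)
    ctrl.start(plant.state.t, cuff_target=plant.state.cuff_pressure)
    dt = plant.config.dt
    max_steps = int((cfg.max_cuff_pressure / cfg.pressure_step + 2)
                    * cfg.step_dwell / dt) + 100
    cuff = ctrl.cuff_target
    for _ in range(max_steps):
        if ctrl.due(plant.state.t):
            cuff = ctrl.update(
                plant.state.t, plant.distal_peak_to_peak(cfg.step_dwell)
            )
        if ctrl.done:
            break
        plant.step(
            ActuatorCommands(
                infusion_rate=infusion_rate,
                internal_hem_rate=internal_hem_rate,
                cuff_pressure_target=cuff,
                extremity_valve_open=extremity_valve_open,
            ),
            dt,
        )
    return ctrl.result()
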