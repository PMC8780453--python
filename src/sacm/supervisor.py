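"""Supervisory Algorithm for Casualty Management (SACM).

SACM coordinates the two sub-controllers over a shared simulated patient:

* **Active intervention** (sequential): on being started it yields control
  to the tourniquet controller until extremity occlusion is verified, then
  runs an ARC resuscitation to the target MAP.
* **Monitoring** (concurrent): afterwards it checks two logical conditions
  every 15 s — has the tourniquet come loose (cuff oscillations or a >33%
  cuff-pressure drop), and has the central MAP fallen below the 85 mmHg
  intervention threshold — and dispatches the corresponding sub-controller
  when one fires.  Both sub-controllers can run at the same time; a
  sub-controller that is already running is never started twice.

Concurrency is realized as cooperative scheduling on the single simulation
clock: each plant step, every active sub-controller contributes its
actuator command, and monitoring ticks interleave without blocking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .arc import ArcConfig, ArcController
from .atkt import LooseStatus, TkConfig, TourniquetController, detect_loose
from .plant import ActuatorCommands, FlowLoopPlant

__all__ = [
    "SupervisorConfig",
    "SupervisorEvent",
    "EventKind",
    "Action",
    "monitoring_step",
    "Supervisor",
    "run_active_intervention",
]


@dataclass
class SupervisorConfig:
    """Monitoring-phase parameters.

    ``monitoring_period`` is the spacing of condition checks (s);
    ``map_intervention_threshold`` the MAP (mmHg) below which a
    resuscitation is dispatched.  ``reentrancy_policy`` is fixed to
    "skip_if_running": a condition firing while its sub-controller is
    already active is ignored at that tick.
    """

    monitoring_period: float = 15.0
    map_intervention_threshold: float = 85.0
    reentrancy_policy: str = "skip_if_running"
    max_scenario_time: float = 3600.0

    def __post_init__(self) -> None:
        if self.monitoring_period <= 0:
            raise ValueError("monitoring_period must be positive")
        if self.reentrancy_policy != "skip_if_running":
            raise ValueError("only the skip_if_running policy is implemented")


class EventKind(str, Enum):
    PHASE_START = "phase_start"
    ATKT_ENGAGED = "atkt_engaged"
    ARC_STARTED = "arc_started"
    ARC_COMPLETED = "arc_completed"
    LOOSE_DETECTED = "loose_detected"
    LOW_MAP_DETECTED = "low_map_detected"
    ATKT_REENGAGED = "atkt_reengaged"
    ERROR = "error"


@dataclass
class SupervisorEvent:
    """Time-stamped audit-trail entry."""

    t: float
    kind: EventKind
    detail: str = ""


class Action(str, Enum):
    REENGAGE_TOURNIQUET = "reengage_tourniquet"
    START_RESUSCITATION = "start_resuscitation"


def monitoring_step(
    central_map: float,
    tk_status: LooseStatus,
    subcontrollers_running: set[str],
    cfg: SupervisorConfig,
) -> list[Action]:
    """One 15-s monitoring check; returns the sub-controller dispatches.

    The two conditions are evaluated independently, so a loose tourniquet
    and a low MAP in the same tick yield both actions (simultaneous
    re-tightening and resuscitation).
    """
    actions: list[Action] = []
    if tk_status is not LooseStatus.OK and "atkt" not in subcontrollers_running:
        actions.append(Action.REENGAGE_TOURNIQUET)
    if (
        central_map < cfg.map_intervention_threshold
        and "arc" not in subcontrollers_running
    ):
        actions.append(Action.START_RESUSCITATION)
    return actions


class Phase(str, Enum):
    IDLE = "idle"
    ACTIVE_TKT = "active_tkt"
    ACTIVE_ARC = "active_arc"
    MONITORING = "monitoring"
    FAILED = "failed"


class Supervisor:
    """Per-tick SACM state machine over one plant.

    The owner of the simulation loop calls :meth:`update` every plant step
    and applies the returned ``(infusion_rate, cuff_pressure_target)`` to
    the plant together with the scenario's hemorrhage schedule.
    """

    def __init__(
        self,
        plant: FlowLoopPlant,
        tk_cfg: TkConfig | None = None,
        arc_cfg: ArcConfig | None = None,
        cfg: SupervisorConfig | None = None,
    ) -> None:
        self.plant = plant
        self.tk_cfg = tk_cfg or TkConfig()
        self.arc_cfg = arc_cfg or ArcConfig(curve=plant.config.curve)
        self.cfg = cfg or SupervisorConfig()
        self.phase = Phase.IDLE
        self.events: list[SupervisorEvent] = []
        self.tkt = TourniquetController(self.tk_cfg)
        self.arc = ArcController(self.arc_cfg)
        self.engagement_pressure = 0.0
        self.cuff_target = 0.0
        self._next_tick = 0.0
        self._arc_runs_completed = 0

    # -- lifecycle ---------------------------------------------------------

    def start(self, t: float) -> None:
        """Manually trigger SACM: begins the active-intervention phase."""
        if self.phase is not Phase.IDLE:
            raise RuntimeError("SACM already started")
        self._event(t, EventKind.PHASE_START, "active_intervention")
        self.phase = Phase.ACTIVE_TKT
        self.tkt.start(t, cuff_target=self.cuff_target)

    def begin_monitoring(self, t: float, engagement_pressure: float | None = None) -> None:
        """Enter the monitoring phase directly (e.g. from a stabilized state)."""
        if engagement_pressure is not None:
            self.engagement_pressure = engagement_pressure
            self.cuff_target = engagement_pressure
        self.phase = Phase.MONITORING
        self._event(t, EventKind.PHASE_START, "monitoring")
        self._next_tick = t + self.cfg.monitoring_period

    def loosen_cuff(self, fraction: float) -> None:
        """External (scenario) loosening: cuff holds only ``fraction`` of its pressure."""
        self.cuff_target *= fraction

    def running(self) -> set[str]:
        active = set()
        if self.tkt.active:
            active.add("atkt")
        if self.arc.active:
            active.add("arc")
        return active

    @property
    def arc_runs_completed(self) -> int:
        return self._arc_runs_completed

    def _event(self, t: float, kind: EventKind, detail: str = "") -> None:
        self.events.append(SupervisorEvent(t=t, kind=kind, detail=detail))

    # -- per-tick update ---------------------------------------------------

    def update(self, t: float) -> tuple[float, float]:
        """Advance SACM to time ``t``; returns (infusion_rate, cuff_target)."""
        plant = self.plant

        if self.tkt.active and self.tkt.due(t):
            self.cuff_target = self.tkt.update(
                t, plant.distal_peak_to_peak(self.tk_cfg.step_dwell)
            )
            if self.tkt.done:
                if not self.tkt.occluded:
                    self._event(
                        t, EventKind.ERROR,
                        "aTKT reached max cuff pressure without occlusion",
                    )
                    if self.phase is Phase.ACTIVE_TKT:
                        self.phase = Phase.FAILED
                else:
                    self.engagement_pressure = self.tkt.engagement_pressure
                    self._event(
                        t, EventKind.ATKT_ENGAGED,
                        f"engagement_pressure={self.engagement_pressure:.1f} mmHg",
                    )
                    if self.phase is Phase.ACTIVE_TKT:
                        self.phase = Phase.ACTIVE_ARC
                        self.arc.start(t)
                        self._event(t, EventKind.ARC_STARTED, "initial resuscitation")

        infusion = 0.0
        if self.arc.active:
            if self.arc.due(t):
                infusion = self.arc.update(t, plant.windowed_map())
                if self.arc.done:
                    infusion = 0.0
                    self._arc_runs_completed += 1
                    self._event(
                        t, EventKind.ARC_COMPLETED,
                        f"final_map={self.arc.final_map:.2f} mmHg "
                        f"reached={self.arc.reached_target}",
                    )
                    if self.phase is Phase.ACTIVE_ARC:
                        # monitoring starts the instant the initial
                        # resuscitation completes
                        self.begin_monitoring(t)
            else:
                infusion = self.arc.state.commanded_rate

        if self.phase is Phase.MONITORING and t + 1e-9 >= self._next_tick:
            self._next_tick += self.cfg.monitoring_period
            self._monitoring_tick(t)

        return infusion, self.cuff_target

    def _monitoring_tick(self, t: float) -> None:
        plant = self.plant
        tk_status = LooseStatus.OK
        if self.engagement_pressure > 0 and not self.tkt.active:
            tk_status = detect_loose(
                plant.cuff_window(self.tk_cfg.loose_window),
                self.engagement_pressure,
                self.tk_cfg,
            )
        map_w = plant.windowed_map()
        actions = monitoring_step(map_w, tk_status, self.running(), self.cfg)
        for action in actions:
            if action is Action.REENGAGE_TOURNIQUET:
                self._event(t, EventKind.LOOSE_DETECTED, tk_status.value)
                self.tkt.start(t, cuff_target=self.cuff_target)
                self._event(t, EventKind.ATKT_REENGAGED, "")
            elif action is Action.START_RESUSCITATION:
                self._event(
                    t, EventKind.LOW_MAP_DETECTED, f"map={map_w:.2f} mmHg"
                )
                self.arc.start(t)
                self._event(t, EventKind.ARC_STARTED, "monitoring intervention")


def run_active_intervention(
    plant: FlowLoopPlant,
    tk_cfg: TkConfig | None = None,
    arc_cfg: ArcConfig | None = None,
    cfg: SupervisorConfig | None = None,
    internal_hem_rate: float = 0.0,
    extremity_valve_open: bool = True,
) -> list[SupervisorEvent]:
    """Run SACM's sequential active-intervention phase to completion.

    Engages the tourniquet, then resuscitates to the target MAP; returns
    the supervisor's event stream.  The plant is left in the monitoring
    phase's starting state.
    """
    sup = Supervisor(plant, tk_cfg, arc_cfg, cfg)
    sup.start(plant.state.t)
    dt = plant.config.dt
    max_steps = int(sup.cfg.max_scenario_time / dt)
    for _ in range(max_steps):
        if sup.phase in (Phase.MONITORING, Phase.FAILED):
            break
        infusion, cuff = sup.update(plant.state.t)
        plant.step(
            ActuatorCommands(
                infusion_rate=infusion,
                internal_hem_rate=internal_hem_rate,
                cuff_pressure_target=cuff,
                extremity_valve_open=extremity_valve_open,
            ),
            dt,
        )
    return sup.events
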