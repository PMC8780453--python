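"""Adaptive Resuscitation Controller (ARC).

ARC closes the loop between measured mean arterial pressure (MAP) and a
volumetric infusion pump.  Each cycle it:

1. picks an intermediate MAP setpoint between the measured MAP and the
   overall target,
2. converts the pressure gap into a fractional volume deficit using the
   vessel's pressure-volume (P-V) curve and computes the infusion rate

       rate = (Q_max - Q_min) * volume_error + Q_min,

3. infuses at that rate, sampling MAP at 1 Hz, until the intermediate
   setpoint is reached, and
4. updates a multiplicative correction factor from the ratio of the actual
   to the P-V-predicted cycle time,

       cf_{n+1} = cf_n * (t_actual / t_predicted) * scaling_factor,

   which rescales the rate of subsequent cycles.

The same time-prediction discrepancy drives hemorrhage detection: whenever
the elapsed cycle time reaches twice the predicted time (100% prediction
error), a "suspected hemorrhage" flag forces the infusion to Q_max until
the criterion is no longer met.  The controller terminates once the
windowed MAP is within 99.5% of the overall target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .plant import ActuatorCommands, FlowLoopPlant, PVCurve, pv_volume, whole_blood_curve

__all__ = [
    "ArcConfig",
    "ArcState",
    "ResuscitationResult",
    "intermediate_setpoint",
    "volume_percent_error",
    "arc_flow_rate",
    "update_correction_factor",
    "predicted_time",
    "check_suspected_hemorrhage",
    "ArcController",
    "run_resuscitation",
]


@dataclass
class ArcConfig:
    """Controller parameters.

    Attributes
    ----------
    map_target : float
        Overall target MAP, mmHg.
    q_min, q_max : float
        Infusion rate bounds, mL/min.  ``q_max`` defaults to the pump's
        1200 mL/min maximum; ``q_min`` keeps a small priming flow.
    scaling_factor : float
        User multiplier inside the correction-factor update; >1 makes
        adaptation more aggressive, <1 gentler.
    alpha_intermediate : float
        Fraction of the remaining pressure gap targeted each cycle.
    termination_fraction : float
        Stop once windowed MAP >= termination_fraction * map_target.
    sample_period : float
        MAP sampling / rate-update period, s.
    hemorrhage_error_threshold : float
        Fractional time-prediction error at which the suspected-hemorrhage
        flag raises (1.0 == the actual time is twice the predicted time).
    cf_min, cf_max : float
        Clamp on the multiplicative correction factor.
    adaptation : str
        "multiplicative" uses the ratio update above; "deviation_scaled"
        is an experimental variant cf' = cf * (1 + sf*(t_act/t_pred - 1)).
    max_duration : float
        Wall-clock cap on a single resuscitation, s.
    curve : PVCurve
        P-V relationship used for volume-deficit and time predictions.
    """

    map_target: float = 95.0
    q_min: float = 50.0
    q_max: float = 1200.0
    scaling_factor: float = 1.0
    alpha_intermediate: float = 0.5
    termination_fraction: float = 0.995
    sample_period: float = 1.0
    hemorrhage_error_threshold: float = 1.0
    cf_min: float = 0.1
    cf_max: float = 10.0
    adaptation: str = "multiplicative"
    max_duration: float = 3600.0
    curve: PVCurve = field(default_factory=whole_blood_curve)

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_min < self.q_max):
            raise ValueError("require 0 <= q_min < q_max")
        if not (0.0 < self.termination_fraction <= 1.0):
            raise ValueError("termination_fraction must be in (0, 1]")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be positive")
        if not (0.0 < self.alpha_intermediate <= 1.0):
            raise ValueError("alpha_intermediate must be in (0, 1]")
        if not (0.0 < self.cf_min <= self.cf_max):
            raise ValueError("require 0 < cf_min <= cf_max")
        if self.adaptation not in ("multiplicative", "deviation_scaled"):
            raise ValueError("adaptation must be 'multiplicative' or 'deviation_scaled'")


@dataclass
class ArcState:
    """Evolving controller quantities (one resuscitation run)."""

    correction_factor: float = 1.0
    intermediate_setpoint: float = 0.0
    t_actual: float = 0.0
    t_predicted: float = 0.0
    suspected_hemorrhage: bool = False
    cycle_index: int = 0
    commanded_rate: float = 0.0


@dataclass
class ResuscitationResult:
    """Outcome of one closed-loop resuscitation."""

    reached_target: bool
    final_map: float
    total_infused: float
    duration: float
    rate_trace: list[tuple[float, float]]  # (t, commanded rate) at 1 Hz
    flag_intervals: list[tuple[float, float]]  # suspected-hemorrhage spans


def intermediate_setpoint(map_meas: float, map_target: float, alpha: float) -> float:
    """Next-cycle MAP setpoint between the measured MAP and the target."""
    if map_meas > map_target:
        raise ValueError("measured MAP already above target; controller terminates")
    return map_meas + alpha * (map_target - map_meas)


def volume_percent_error(map_meas: float, map_set: float, curve: PVCurve) -> float:
    """Fractional volume deficit of the measured MAP relative to the setpoint.

    The deficit volume between the two pressures is normalized by the total
    fillable volume below the setpoint, giving a value in [0, 1]; 0 when
    the measured MAP is at or above the setpoint.
    """
    if map_meas >= map_set:
        return 0.0
    v_set = pv_volume(map_set, curve)
    v_meas = pv_volume(map_meas, curve)
    denom = v_set - curve.v_min
    if denom <= 0:
        return 0.0
    return min(max((v_set - v_meas) / denom, 0.0), 1.0)


def arc_flow_rate(v_err: float, cfg: ArcConfig, correction_factor: float = 1.0) -> float:
    """Commanded infusion rate (mL/min) for a fractional volume error.

    The linear rate law is scaled by the adaptive correction factor and
    clamped to the configured pump range.
    """
    if not (0.0 <= v_err <= 1.0):
        raise ValueError("v_err must be in [0, 1]")
    if correction_factor <= 0:
        raise ValueError("correction_factor must be positive")
    rate = correction_factor * ((cfg.q_max - cfg.q_min) * v_err + cfg.q_min)
    return min(max(rate, cfg.q_min), cfg.q_max)


def update_correction_factor(
    cf: float,
    t_actual: float,
    t_predicted: float,
    scaling_factor: float,
    cf_min: float = 0.1,
    cf_max: float = 10.0,
    adaptation: str = "multiplicative",
) -> float:
    """Adaptive correction-factor update from the cycle-time discrepancy.

    When the plant responds slower than the P-V data predicted
    (t_actual > t_predicted) the factor grows, raising subsequent rates;
    when faster, it shrinks.  The result is clamped to [cf_min, cf_max].
    A non-positive ``t_predicted`` is guarded: the update is skipped.
    """
    if cf <= 0:
        raise ValueError("correction factor must be positive")
    if t_predicted <= 0:
        warnings.warn("t_predicted <= 0; skipping correction-factor update")
        return cf
    if adaptation == "deviation_scaled":
        new = cf * (1.0 + scaling_factor * (t_actual / t_predicted - 1.0))
    else:
        new = cf * (t_actual / t_predicted) * scaling_factor
    return min(max(new, cf_min), cf_max)


def predicted_time(
    map_from: float, map_to: float, rate: float, curve: PVCurve
) -> float:
    """Seconds the P-V curve predicts to raise MAP at a constant infusion rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if map_to <= map_from:
        return 0.0
    dv = pv_volume(map_to, curve) - pv_volume(map_from, curve)
    return 60.0 * dv / rate


def check_suspected_hemorrhage(
    t_actual: float, t_predicted: float, threshold: float = 1.0
) -> bool:
    """True when the fractional time-prediction error reaches the threshold.

    At the default threshold of 1.0 the flag raises exactly when the actual
    time is twice the predicted time.
    """
    if t_predicted <= 0:
        return False
    return (t_actual - t_predicted) / t_predicted >= threshold


class ArcController:
    """Incremental ARC suitable for cooperative scheduling.

    Call :meth:`start` once, then :meth:`update` every plant step; the
    controller acts only on its internal 1 Hz sample clock and returns the
    currently commanded infusion rate between samples.
    """

    def __init__(self, cfg: ArcConfig) -> None:
        self.cfg = cfg
        self.state = ArcState()
        self.active = False
        self.done = False
        self.reached_target = False
        self.rate_trace: list[tuple[float, float]] = []
        self.flag_intervals: list[tuple[float, float]] = []
        self._t_start = 0.0
        self._next_sample = 0.0
        self._cycle_start: float | None = None
        self._base_rate = 0.0
        self._flag_since: float | None = None
        self.final_map = float("nan")

    def start(self, t: float) -> None:
        if self.active:
            raise RuntimeError("ARC instance already running")
        self.__init__(self.cfg)
        self.active = True
        self._t_start = t
        self._next_sample = t

    def _begin_cycle(self, t: float, map_w: float) -> None:
        cfg = self.cfg
        st = self.state
        setp = intermediate_setpoint(min(map_w, cfg.map_target), cfg.map_target,
                                     cfg.alpha_intermediate)
        st.intermediate_setpoint = setp
        v_err = volume_percent_error(map_w, setp, cfg.curve)
        self._base_rate = arc_flow_rate(v_err, cfg, st.correction_factor)
        st.t_predicted = (
            predicted_time(map_w, setp, self._base_rate, cfg.curve)
            if setp > map_w
            else 0.0
        )
        st.t_actual = 0.0
        self._cycle_start = t
        st.commanded_rate = self._base_rate

    def _end_flag(self, t: float) -> None:
        if self._flag_since is not None:
            self.flag_intervals.append((self._flag_since, t))
            self._flag_since = None

    def _finish(self, t: float, map_w: float, reached: bool) -> None:
        self.done = True
        self.active = False
        self.reached_target = reached
        self.final_map = map_w
        self.state.commanded_rate = 0.0
        self.state.suspected_hemorrhage = False
        self._end_flag(t)
        self.rate_trace.append((t, 0.0))

    def due(self, t: float) -> bool:
        """True when the 1 Hz sample clock requires a controller action at ``t``."""
        return self.active and t + 1e-9 >= self._next_sample

    def update(self, t: float, map_windowed: float) -> float:
        """Advance the controller to time ``t``; returns the commanded rate."""
        if not self.active:
            return 0.0
        if t + 1e-9 < self._next_sample:
            return self.state.commanded_rate
        self._next_sample += self.cfg.sample_period

        cfg = self.cfg
        st = self.state
        if map_windowed >= cfg.termination_fraction * cfg.map_target:
            self._finish(t, map_windowed, reached=True)
            return 0.0
        if t - self._t_start > cfg.max_duration:
            self._finish(t, map_windowed, reached=False)
            return 0.0

        if self._cycle_start is None or map_windowed >= st.intermediate_setpoint:
            # cycle boundary: adapt, then plan the next intermediate setpoint
            if self._cycle_start is not None:
                st.t_actual = t - self._cycle_start
                st.correction_factor = update_correction_factor(
                    st.correction_factor,
                    st.t_actual,
                    st.t_predicted,
                    cfg.scaling_factor,
                    cfg.cf_min,
                    cfg.cf_max,
                    cfg.adaptation,
                )
                st.cycle_index += 1
            if st.suspected_hemorrhage:
                st.suspected_hemorrhage = False
                self._end_flag(t)
            self._begin_cycle(t, map_windowed)
        else:
            # mid-cycle: track elapsed time and the hemorrhage criterion
            st.t_actual = t - self._cycle_start
            flag = check_suspected_hemorrhage(
                st.t_actual, st.t_predicted, cfg.hemorrhage_error_threshold
            )
            if flag and not st.suspected_hemorrhage:
                self._flag_since = t
            elif not flag and st.suspected_hemorrhage:
                self._end_flag(t)
            st.suspected_hemorrhage = flag
            st.commanded_rate = cfg.q_max if flag else self._base_rate

        self.rate_trace.append((t, st.commanded_rate))
        return st.commanded_rate

    def result(self, total_infused: float) -> ResuscitationResult:
        trace = list(self.rate_trace)
        duration = (trace[-1][0] - self._t_start) if trace else 0.0
        return ResuscitationResult(
            reached_target=self.reached_target,
            final_map=self.final_map,
            total_infused=total_infused,
            duration=duration,
            rate_trace=trace,
            flag_intervals=list(self.flag_intervals),
        )


def run_resuscitation(
    plant: FlowLoopPlant,
    cfg: ArcConfig,
    internal_hem_rate: float = 0.0,
    extremity_valve_open: bool = False,
    cuff_pressure: float = 0.0,
) -> ResuscitationResult:
    """Drive the plant with ARC until the target MAP is reached.

    The optional hemorrhage arguments hold a constant disturbance during
    the run (the standalone analogue of the controller test bench).  If the
    measured MAP already satisfies the termination criterion the function
    returns immediately with no volume infused.
    """
    ctrl = ArcController(cfg)
    map_w = plant.windowed_map()
    if map_w >= cfg.termination_fraction * cfg.map_target:
        return ResuscitationResult(
            reached_target=True,
            final_map=map_w,
            total_infused=0.0,
            duration=0.0,
            rate_trace=[],
            flag_intervals=[],
        )
    infused0 = plant.state.cum_infused
    ctrl.start(plant.state.t)
    dt = plant.config.dt
    max_steps = int(cfg.max_duration / dt) + 1
    rate = 0.0
    for _ in range(max_steps):
        if ctrl.due(plant.state.t):
            rate = ctrl.update(plant.state.t, plant.windowed_map())
        if ctrl.done:
            break
        plant.step(
            ActuatorCommands(
                infusion_rate=rate,
                internal_hem_rate=internal_hem_rate,
                cuff_pressure_target=cuff_pressure,
                extremity_valve_open=extremity_valve_open,
            ),
            dt,
        )
    else:
        ctrl._finish(plant.state.t, plant.windowed_map(), reached=False)
    return ctrl.result(plant.state.cum_infused - infused0)
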