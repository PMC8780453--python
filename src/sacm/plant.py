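"""Discrete-time simulator of a benchtop circulatory flow-loop "patient".

The plant is a fluid vessel whose column height encodes a normalized
pressure-volume (P-V) relationship, connected in a loop with a pulsatile
circulatory pump, a silicone arm analogue carrying a pneumatic tourniquet
cuff, and an extremity bleed site distal to the arm.  Three external flows
act on the vessel: a resuscitation infusion, an internal hemorrhage
withdrawal, and the extremity bleed.  Pressure transducers report the
central mean arterial pressure (MAP, upstream of the arm), the distal MAP
(at the bleed site), and the cuff air pressure.

All controllers in this package sense and actuate only through this module:
they read windowed sensor samples and write :class:`ActuatorCommands`.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InfusateKind",
    "PVCurve",
    "whole_blood_curve",
    "crystalloid_curve",
    "random_monotone_curve",
    "pv_pressure",
    "pv_volume",
    "instantaneous_pressure",
    "extremity_bleed_flow",
    "cuff_oscillation_amplitude",
    "ActuatorCommands",
    "LoopState",
    "PlantConfig",
    "FlowLoopPlant",
]


class InfusateKind(str, Enum):
    WHOLE_BLOOD = "whole_blood"
    CRYSTALLOID = "crystalloid"


@dataclass(frozen=True)
class PVCurve:
    """Monotone normalized pressure-volume relationship of the vessel.

    ``coefficients`` are polynomial coefficients (ascending powers) mapping
    the normalized volume ``u = (v - v_min) / (v_max - v_min)`` in [0, 1]
    to pressure in mmHg.  The curve is anchored so that the full vessel
    (``u = 1``) sits at ``p_baseline``.

    Parameters
    ----------
    infusate_kind : InfusateKind
        Which resuscitation fluid the curve was fit for.  Crystalloid
        redistributes out of the vascular compartment, so restoring a given
        pressure rise takes substantially more crystalloid than whole blood.
    coefficients : tuple of float
        Ascending polynomial coefficients of u -> pressure (mmHg).
    v_min, v_max : float
        Volume range of the vessel in mL.
    p_baseline : float
        Pressure at the full vessel (mmHg); default target of resuscitation.
    """

    infusate_kind: InfusateKind
    coefficients: tuple[float, ...]
    v_min: float
    v_max: float
    p_baseline: float = 95.0

    def __post_init__(self) -> None:
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        u = np.linspace(0.0, 1.0, 2001)
        p = np.polynomial.polynomial.polyval(u, self.coefficients)
        if not np.all(np.diff(p) > 0):
            raise ValueError("P-V curve must be strictly increasing in volume")
        if abs(p[-1] - self.p_baseline) > 1e-6 * max(1.0, abs(self.p_baseline)):
            raise ValueError(
                f"curve must be anchored at p_baseline: p(v_max)={p[-1]:.6f} "
                f"!= {self.p_baseline}"
            )

    @property
    def p_min(self) -> float:
        """Pressure at the empty end of the admissible volume range."""
        return float(self.coefficients[0])

    def pressure(self, v: float) -> float:
        return pv_pressure(v, self)

    def volume(self, p: float) -> float:
        return pv_volume(p, self)

    def capacity(self, p_lo: float, p_hi: float) -> float:
        """Fluid volume (mL) needed to traverse the pressure span p_lo -> p_hi."""
        return self.volume(p_hi) - self.volume(p_lo)


def _polyval(coeffs: Sequence[float], u: float) -> float:
    # Horner on scalars; hot path at the 50 Hz step rate.
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * u + c
    return acc


def pv_pressure(v: float, curve: PVCurve) -> float:
    """Pressure (mmHg) supplied by the fluid column at vessel volume ``v`` (mL)."""
    span = curve.v_max - curve.v_min
    tol = 1e-9 * span
    if v < curve.v_min - tol or v > curve.v_max + tol:
        raise ValueError(
            f"volume {v} mL outside [{curve.v_min}, {curve.v_max}] mL"
        )
    u = (v - curve.v_min) / span
    u = min(max(u, 0.0), 1.0)
    return _polyval(curve.coefficients, u)


def pv_volume(p: float, curve: PVCurve) -> float:
    """Invert the P-V curve: vessel volume (mL) at which pressure equals ``p``.

    Uses bracketed root finding; the round trip
    ``pv_volume(pv_pressure(v))`` recovers ``v`` to 1e-6 of the volume span.
    """
    p_lo, p_hi = curve.p_min, curve.p_baseline
    tol = 1e-9 * max(1.0, p_hi - p_lo)
    if p < p_lo - tol or p > p_hi + tol:
        raise ValueError(
            f"pressure {p} mmHg outside achievable range [{p_lo}, {p_hi}] mmHg"
        )
    p = min(max(p, p_lo), p_hi)
    span = curve.v_max - curve.v_min
    f = lambda v: pv_pressure(v, curve) - p
    return float(
        brentq(f, curve.v_min, curve.v_max, xtol=1e-9 * span, rtol=1e-14)
    )


def whole_blood_curve(v_min: float = 0.0, v_max: float = 500.0) -> PVCurve:
    """Default whole-blood P-V curve (monotone cubic, anchored at 95 mmHg)."""
    return PVCurve(
        infusate_kind=InfusateKind.WHOLE_BLOOD,
        coefficients=(30.0, 80.0, -20.0, 5.0),
        v_min=v_min,
        v_max=v_max,
    )


def crystalloid_curve(v_min: float = 0.0, v_max: float = 1500.0) -> PVCurve:
    """Default crystalloid P-V curve.

    Parameterized so that the fluid volume needed to raise pressure from
    75 to 95 mmHg is more than twice that of the whole-blood curve,
    reflecting crystalloid redistribution out of the circulation.
    """
    return PVCurve(
        infusate_kind=InfusateKind.CRYSTALLOID,
        coefficients=(30.0, 120.0, -60.0, 5.0),
        v_min=v_min,
        v_max=v_max,
    )


def random_monotone_curve(
    seed: int,
    infusate_kind: InfusateKind | str = InfusateKind.WHOLE_BLOOD,
    p_baseline: float = 95.0,
) -> PVCurve:
    """Random strictly monotone cubic P-V curve anchored at ``p_baseline``.

    The cubic is the normalized antiderivative of a positive quadratic, so
    monotonicity holds by construction; the empty-vessel pressure and the
    vessel capacity are drawn from physiologically plausible ranges.  Used
    to exercise the controllers on plants other than the two defaults.
    """
    rng = np.random.default_rng(seed)
    p_low = float(rng.uniform(25.0, 45.0))
    v_max = float(rng.uniform(300.0, 800.0))
    c = rng.uniform(0.2, 2.0, size=3)  # positive quadratic du-coefficients
    q1 = c[0] + c[1] / 2.0 + c[2] / 3.0  # integral over [0, 1]
    gain = (p_baseline - p_low) / q1
    coeffs = (p_low, gain * c[0], gain * c[1] / 2.0, gain * c[2] / 3.0)
    return PVCurve(
        infusate_kind=InfusateKind(infusate_kind),
        coefficients=coeffs,
        v_min=0.0,
        v_max=v_max,
        p_baseline=p_baseline,
    )


def default_curve(kind: InfusateKind | str) -> PVCurve:
    kind = InfusateKind(kind)
    if kind is InfusateKind.WHOLE_BLOOD:
        return whole_blood_curve()
    return crystalloid_curve()


def instantaneous_pressure(
    mean: float, pulse_pressure: float, t: float, heart_rate: float = 60.0
) -> float:
    """Pulsatile pressure sample: mean plus a zero-mean sinusoidal pulse.

    ``pulse_pressure`` is the peak-to-peak swing; the time average over any
    whole cardiac cycle equals ``mean``.
    """
    if pulse_pressure < 0:
        raise ValueError("pulse_pressure must be >= 0")
    return mean + 0.5 * pulse_pressure * math.sin(
        2.0 * math.pi * (heart_rate / 60.0) * t
    )


def extremity_bleed_flow(
    distal_map: float,
    occlusion_fraction: float,
    valve_open: bool,
    r_bleed: float,
) -> float:
    """Flow (mL/min) out of the bleed site distal to the arm.

    Linear orifice law: flow is the distal driving pressure over the bleed
    resistance, scaled by how much of the artery the tourniquet leaves open.
    """
    if r_bleed <= 0:
        raise ValueError("r_bleed must be positive")
    if not valve_open or occlusion_fraction >= 1.0:
        return 0.0
    return (1.0 - occlusion_fraction) * max(distal_map, 0.0) / r_bleed


def cuff_oscillation_amplitude(
    occlusion_fraction: float,
    pulse_pressure: float,
    cuff_engaged: bool,
    k_transmit: float = 0.2,
) -> float:
    """Peak-to-peak arterial oscillation (mmHg) transmitted into the cuff bladder.

    A fully occluding cuff sees no transmitted pulse; a partially occluding
    one couples a fraction ``k_transmit`` of the remaining arterial pulse
    into its air pressure signal -- the oscillometric signature the
    supervisor uses to detect a re-bleed.
    """
    if not cuff_engaged or occlusion_fraction >= 1.0:
        return 0.0
    return (1.0 - occlusion_fraction) * k_transmit * pulse_pressure


@dataclass
class ActuatorCommands:
    """Set-points for the three pumps and the bleed valve."""

    infusion_rate: float = 0.0  # mL/min, resuscitation pump into the vessel
    internal_hem_rate: float = 0.0  # mL/min, hemorrhage pump out of the vessel
    cuff_pressure_target: float = 0.0  # mmHg, tourniquet cuff inflation
    extremity_valve_open: bool = False  # bleed-site valve distal to the arm

    def __post_init__(self) -> None:
        if self.infusion_rate < 0 or self.internal_hem_rate < 0:
            raise ValueError("flow rates must be >= 0")
        if self.cuff_pressure_target < 0:
            raise ValueError("cuff pressure target must be >= 0")


@dataclass
class LoopState:
    """Full simulated plant state at one instant."""

    t: float = 0.0  # s
    v_vessel: float = 0.0  # mL
    central_map: float = 0.0  # mmHg (mean, PT1)
    distal_map: float = 0.0  # mmHg (mean, PT2)
    pulse_pressure: float = 0.0  # mmHg peak-to-peak, central
    cuff_pressure: float = 0.0  # mmHg (mean cuff air pressure)
    extremity_valve_open: bool = False
    internal_hem_rate: float = 0.0  # mL/min
    infusion_rate: float = 0.0  # mL/min
    occlusion_fraction: float = 0.0  # in [0, 1]
    cum_extremity_bleed: float = 0.0  # mL
    cum_internal_hem: float = 0.0  # mL
    cum_infused: float = 0.0  # mL


@dataclass
class PlantConfig:
    """Physical parameterization of the flow loop.

    Attributes
    ----------
    curve : PVCurve
        Pressure-volume relationship of the vessel.
    heart_rate : float
        Circulatory pump pulse rate, 1/min.
    pulse_pressure : float
        Central peak-to-peak pulse amplitude, mmHg.
    r_bleed : float
        Extremity bleed resistance, mmHg*min/mL; the default makes an
        unoccluded bleed at ~75 mmHg lose volume at a few hundred mL/min,
        comparable to the internal hemorrhage rates studied.
    arm_pressure_drop : float
        Static pressure drop across the arm analogue, mmHg.
    occlusion_cuff_threshold : float
        Cuff pressure at and above which arterial flow is fully occluded;
        occlusion rises piecewise-linearly from zero cuff pressure.
    k_transmit : float
        Fraction of the residual arterial pulse coupled into the cuff.
    cuff_engage_min : float
        Cuff pressure above which the cuff counts as engaged, mmHg.
    dt : float
        Fixed simulation step, s (default 0.02 s = 50 Hz sensor sampling).
    noise_sd : float
        Additive Gaussian sensor noise SD, mmHg; 0 disables noise.
    noise_seed : int
        Seed for the noise generator (required reproducibility contract).
    """

    curve: PVCurve = field(default_factory=whole_blood_curve)
    heart_rate: float = 60.0
    pulse_pressure: float = 20.0
    r_bleed: float = 0.25
    arm_pressure_drop: float = 2.0
    occlusion_cuff_threshold: float = 180.0
    k_transmit: float = 0.2
    cuff_engage_min: float = 5.0
    dt: float = 0.02
    noise_sd: float = 0.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 0.1):
            raise ValueError("dt must be in (0, 0.1] s")
        if self.r_bleed <= 0:
            raise ValueError("r_bleed must be positive")
        if self.occlusion_cuff_threshold <= 0:
            raise ValueError("occlusion_cuff_threshold must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class FlowLoopPlant:
    """Stateful flow-loop simulator advanced by :meth:`step`.

    Maintains short ring buffers of the 50 Hz sensor samples (central,
    distal, cuff) so controllers can request windowed statistics the same
    way they would from a live data-acquisition stream.
    """

    #: seconds of sensor history retained for windowed queries
    BUFFER_SECONDS = 6.0

    def __init__(
        self,
        config: PlantConfig | None = None,
        initial_map: float | None = None,
        initial_volume: float | None = None,
    ) -> None:
        self.config = config or PlantConfig()
        curve = self.config.curve
        if initial_volume is not None:
            v0 = float(initial_volume)
        elif initial_map is not None:
            v0 = pv_volume(initial_map, curve)
        else:
            v0 = curve.v_max
        self.state = LoopState(
            t=0.0,
            v_vessel=v0,
            central_map=pv_pressure(v0, curve),
            pulse_pressure=self.config.pulse_pressure,
        )
        self.state.distal_map = self._distal_mean(self.state.central_map, 0.0)
        self.clamp_events: list[tuple[float, str]] = []
        maxlen = int(round(self.BUFFER_SECONDS / self.config.dt))
        self._t_buf: deque[float] = deque(maxlen=maxlen)
        self._central_buf: deque[float] = deque(maxlen=maxlen)
        self._distal_buf: deque[float] = deque(maxlen=maxlen)
        self._cuff_buf: deque[float] = deque(maxlen=maxlen)
        self._rng = np.random.default_rng(self.config.noise_seed)
        self._record_samples(0.0)

    # -- internal pieces ---------------------------------------------------

    def occlusion_from_cuff(self, cuff_pressure: float) -> float:
        """Piecewise-linear saturating occlusion law of the tourniquet."""
        return min(max(cuff_pressure / self.config.occlusion_cuff_threshold, 0.0), 1.0)

    def _distal_mean(self, central_mean: float, occ: float) -> float:
        return max(
            0.0, central_mean * (1.0 - occ) - self.config.arm_pressure_drop
        )

    def _noise(self) -> float:
        if self.config.noise_sd == 0.0:
            return 0.0
        return float(self._rng.normal(0.0, self.config.noise_sd))

    def _record_samples(self, cuff_target: float) -> None:
        cfg = self.config
        s = self.state
        occ = s.occlusion_fraction
        central = instantaneous_pressure(
            s.central_map, cfg.pulse_pressure, s.t, cfg.heart_rate
        )
        distal = instantaneous_pressure(
            s.distal_map, cfg.pulse_pressure * (1.0 - occ), s.t, cfg.heart_rate
        )
        engaged = cuff_target > cfg.cuff_engage_min
        osc = cuff_oscillation_amplitude(
            occ, cfg.pulse_pressure, engaged, cfg.k_transmit
        )
        cuff = instantaneous_pressure(cuff_target, osc, s.t, cfg.heart_rate)
        self._t_buf.append(s.t)
        self._central_buf.append(central + self._noise())
        # distal transducer may read slightly negative around zero; do not
        # clamp, or residual pulsatility near full occlusion is masked
        self._distal_buf.append(distal + self._noise())
        self._cuff_buf.append(max(0.0, cuff + self._noise()))

    # -- stepping ----------------------------------------------------------

    def step(self, cmd: ActuatorCommands, dt: float | None = None) -> LoopState:
        """Advance the plant one step under the given actuator commands.

        Volume bookkeeping is exactly conservative: the change in vessel
        volume equals infused minus withdrawn volume on every step.  When
        the vessel would run past a bound, the responsible flows are scaled
        back for that step (an empty vessel cannot bleed) and a clamp event
        is logged.
        """
        cfg = self.config
        if dt is None:
            dt = cfg.dt
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > 0.1:
            raise ValueError("dt must be <= 0.1 s")
        s = self.state
        curve = cfg.curve

        occ = self.occlusion_from_cuff(cmd.cuff_pressure_target)
        distal_mean = self._distal_mean(s.central_map, occ)
        q_bleed = extremity_bleed_flow(
            distal_mean, occ, cmd.extremity_valve_open, cfg.r_bleed
        )
        dt_min = dt / 60.0
        vol_in = cmd.infusion_rate * dt_min
        vol_internal = cmd.internal_hem_rate * dt_min
        vol_bleed = q_bleed * dt_min

        headroom = curve.v_max - s.v_vessel
        if vol_in - (vol_internal + vol_bleed) > headroom:
            vol_in = headroom + vol_internal + vol_bleed
            self.clamp_events.append((s.t, "v_max"))
        available = (s.v_vessel - curve.v_min) + vol_in
        vol_out = vol_internal + vol_bleed
        if vol_out > available:
            scale = available / vol_out if vol_out > 0 else 0.0
            vol_internal *= scale
            vol_bleed *= scale
            self.clamp_events.append((s.t, "v_min"))

        v_new = s.v_vessel + vol_in - vol_internal - vol_bleed
        v_new = min(max(v_new, curve.v_min), curve.v_max)

        s.t += dt
        s.v_vessel = v_new
        s.central_map = pv_pressure(v_new, curve)
        s.occlusion_fraction = occ
        s.distal_map = self._distal_mean(s.central_map, occ)
        s.cuff_pressure = cmd.cuff_pressure_target
        s.extremity_valve_open = cmd.extremity_valve_open
        s.internal_hem_rate = cmd.internal_hem_rate
        s.infusion_rate = cmd.infusion_rate
        s.cum_infused += vol_in
        s.cum_internal_hem += vol_internal
        s.cum_extremity_bleed += vol_bleed

        self._record_samples(cmd.cuff_pressure_target)
        return s

    # -- windowed sensor queries ------------------------------------------

    def _window(self, buf: deque[float], seconds: float) -> np.ndarray:
        n = max(1, int(round(seconds / self.config.dt)))
        n = min(n, len(buf))
        return np.array([buf[i] for i in range(len(buf) - n, len(buf))])

    def windowed_map(self, seconds: float = 1.0) -> float:
        """Mean of the central pressure samples over the trailing window."""
        return float(self._window(self._central_buf, seconds).mean())

    def windowed_distal_map(self, seconds: float = 1.0) -> float:
        return float(self._window(self._distal_buf, seconds).mean())

    def distal_peak_to_peak(self, seconds: float) -> float:
        """Distal pulsatility: peak-to-peak swing over the trailing window."""
        w = self._window(self._distal_buf, seconds)
        return float(w.max() - w.min())

    def cuff_window(self, seconds: float) -> np.ndarray:
        """Recent cuff air-pressure samples (oldest first)."""
        return self._window(self._cuff_buf, seconds)

    def latest_samples(self) -> tuple[float, float, float]:
        """Most recent (central, distal, cuff) sensor samples."""
        return (
            self._central_buf[-1],
            self._distal_buf[-1],
            self._cuff_buf[-1],
        )

    @property
    def fluid_balance(self) -> float:
        """Cumulative infused minus cumulative hemorrhage volume (mL)."""
        s = self.state
        return s.cum_infused - s.cum_internal_hem - s.cum_extremity_bleed
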