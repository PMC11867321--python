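"""Synthetic vertical-jump force recordings with known ground truth.

A jump trial is rendered from a prescribed, piecewise raised-cosine COM
acceleration profile:

* quiet standing at body weight ``m*g``;
* (CMJ only) an unweighting lobe ``a(t) = -A1 * hann(t/T_uw)`` taking the COM
  velocity down to its most negative value;
* a push lobe ``a(t) = +A2 * hann(t/T_push)`` spanning braking + propulsion
  (propulsion alone for SJ), scaled in closed form so the velocity at the
  instant of zero force equals the requested take-off velocity;
* a short half-cosine force release from body weight to 0 N (take-off);
* ballistic flight of duration ``2*v_to/g`` at exactly 0 N;
* a half-sine landing pulse sized to absorb the landing momentum, then quiet
  standing again.

Hann lobes integrate to ``A*T/2`` and join with zero slope, so the force
trace is C1-continuous everywhere except the landing pulse and the analytic
impulse bookkeeping is exact.  Ground truth is evaluated on a 10x oversampled
noiseless grid; measurement noise (ground-contact samples only, flight held
at exactly 0 N) is added afterwards.

The event ground truth uses the *operational* movement onset — the standard
thresholded-onset rule (first departure of force from body weight beyond a
threshold, backed off 30 ms) evaluated on the continuous noiseless profile —
so that analyses of noiseless recordings are compared against the quantity
the detection rule is actually estimating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .errors import SpecificationError
from .io import ForceRecording

G = 9.81  # m/s^2, acceleration due to gravity

#: duration of the half-cosine force drop at take-off (s); kept short so that
#: peak COM velocity falls within a couple of samples of take-off.
RELEASE_DURATION = 0.002
#: duration of the half-sine landing pulse (s); plumbing only.
LANDING_PULSE_DURATION = 0.050


@dataclass(frozen=True)
class JumpSpec:
    """Prescription for one synthetic jump trial.

    Defaults emulate the study conditions this simulator stands in for:
    1000 Hz plate, five seconds of quiet standing before the jump and after
    landing, and a trained-adult countermovement jump (take-off velocity
    2.8 m/s, i.e. a 40 cm jump).
    """

    body_mass: float = 70.0                  # kg
    jump_type: str = "CMJ"                   # "CMJ" | "SJ"
    target_takeoff_velocity: float = 2.8     # m/s
    countermovement_depth: float = 0.25      # m (0 for SJ)
    quiet_stand_duration: float = 5.0        # s
    unweighting_duration: float = 0.35       # s (0 for SJ)
    braking_duration: float = 0.18           # s (0 for SJ)
    propulsion_duration: float = 0.27        # s
    post_landing_duration: float = 5.0       # s
    noise_sd: float = 3.0                    # N, plate noise during contact
    flight_noise: bool = False               # add noise to flight samples too
    sampling_rate: float = 1000.0            # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        def err(msg: str) -> None:
            raise SpecificationError(msg)

        if self.body_mass <= 0:
            err("body_mass must be positive")
        if self.jump_type not in ("CMJ", "SJ"):
            err(f"jump_type must be 'CMJ' or 'SJ', got {self.jump_type!r}")
        if self.target_takeoff_velocity < 0:
            err("target_takeoff_velocity must be >= 0")
        if self.quiet_stand_duration < 0.5:
            err("quiet_stand_duration must be >= 0.5 s")
        if self.sampling_rate < 200:
            err("sampling_rate must be >= 200 Hz")
        if self.noise_sd < 0:
            err("noise_sd must be >= 0")
        if self.propulsion_duration <= 0:
            err("propulsion_duration must be positive")
        if self.jump_type == "CMJ":
            if not self.countermovement_depth > 0:
                err("CMJ requires countermovement_depth > 0")
            if self.unweighting_duration <= 0 or self.braking_duration <= 0:
                err("CMJ requires positive unweighting and braking durations")
        else:
            if self.countermovement_depth != 0:
                err("SJ requires countermovement_depth = 0")
            if self.unweighting_duration != 0 or self.braking_duration != 0:
                err("SJ requires unweighting_duration = braking_duration = 0")

    @classmethod
    def sj(cls, **kwargs) -> "JumpSpec":
        """Squat-jump spec with SJ-appropriate defaults."""
        defaults = dict(
            jump_type="SJ",
            target_takeoff_velocity=2.45,
            countermovement_depth=0.0,
            unweighting_duration=0.0,
            braking_duration=0.0,
            propulsion_duration=0.30,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    @classmethod
    def cmj(cls, **kwargs) -> "JumpSpec":
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless reference values for one simulated trial."""

    takeoff_velocity: float       # m/s
    jump_height: float            # m, = v_to^2 / 2g
    peak_power: float             # W
    mean_power: float             # W over [onset_time, takeoff_time]
    relative_net_impulse: float   # N*s/kg, = takeoff velocity from rest
    peak_kinetic_energy: float    # J, = m * v_peak^2 / 2
    onset_time: float             # s, operational movement onset
    takeoff_time: float           # s, instant of zero force
    peak_velocity: float = float("nan")  # m/s
    flight_time: float = float("nan")    # s, = 2 v_to / g
    movement_start_time: float = float("nan")  # s, prescribed pulse start


def _hann(tau: np.ndarray, duration: float) -> np.ndarray:
    """Raised-cosine lobe on [0, duration]: 0 at both ends, 1 at the centre."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / duration))


class _Profile:
    """Continuous noiseless force profile F(t) for one spec."""

    def __init__(self, spec: JumpSpec, unweighting_velocity: float):
        m, g = spec.body_mass, G
        self.spec = spec
        self.bw = m * g
        v_to = spec.target_takeoff_velocity
        self.v_un = unweighting_velocity
        t1 = spec.unweighting_duration
        t_push = spec.braking_duration + spec.propulsion_duration
        t_rel = RELEASE_DURATION
        # impulse bookkeeping (exact): -v_un + A2*t_push/2 - g*t_rel/2 = v_to
        self.a1 = 2.0 * self.v_un / t1 if t1 > 0 else 0.0
        self.a2 = 2.0 * (v_to + self.v_un + g * t_rel / 2.0) / t_push
        self.t_move = spec.quiet_stand_duration
        self.t_push_start = self.t_move + t1
        self.t_rel_start = self.t_push_start + t_push
        self.t_takeoff = self.t_rel_start + t_rel
        self.t_land = self.t_takeoff + 2.0 * v_to / g
        self.t_land_end = self.t_land + LANDING_PULSE_DURATION
        self.t_end = self.t_land_end + spec.post_landing_duration
        # landing half-sine absorbs flight momentum m*v_to plus gravity impulse
        t_lp = LANDING_PULSE_DURATION
        self.landing_amp = np.pi * (m * v_to + self.bw * t_lp) / (2.0 * t_lp)

    def force(self, t: np.ndarray) -> np.ndarray:
        spec = self.spec
        m = spec.body_mass
        f = np.full_like(t, self.bw, dtype=float)
        t1 = spec.unweighting_duration
        if t1 > 0:
            sel = (t >= self.t_move) & (t < self.t_push_start)
            tau = t[sel] - self.t_move
            f[sel] = self.bw - m * self.a1 * _hann(tau, t1)
        t_push = self.t_rel_start - self.t_push_start
        sel = (t >= self.t_push_start) & (t < self.t_rel_start)
        tau = t[sel] - self.t_push_start
        f[sel] = self.bw + m * self.a2 * _hann(tau, t_push)
        sel = (t >= self.t_rel_start) & (t < self.t_takeoff)
        tau = t[sel] - self.t_rel_start
        f[sel] = self.bw * 0.5 * (1.0 + np.cos(np.pi * tau / RELEASE_DURATION))
        f[(t >= self.t_takeoff) & (t < self.t_land)] = 0.0
        sel = (t >= self.t_land) & (t < self.t_land_end)
        tau = t[sel] - self.t_land
        f[sel] = self.landing_amp * np.sin(np.pi * tau / LANDING_PULSE_DURATION)
        return f

    def countermovement_depth(self, oversample_rate: float = 10000.0) -> float:
        """Depth of the downward COM excursion for this profile (m)."""
        t = np.arange(self.t_move, self.t_rel_start, 1.0 / oversample_rate)
        a = self.force(t) / self.spec.body_mass - G
        v = cumulative_trapezoid(a, t, initial=0.0)
        s = cumulative_trapezoid(v, t, initial=0.0)
        return float(-s.min())


def _calibrated_profile(spec: JumpSpec) -> _Profile:
    """Build the force profile, solving the unweighting amplitude (CMJ) so the
    rendered countermovement depth matches the spec."""
    if spec.jump_type == "SJ" or spec.unweighting_duration == 0:
        return _Profile(spec, 0.0)
    target = spec.countermovement_depth

    def depth_err(v_un: float) -> float:
        return _Profile(spec, v_un).countermovement_depth() - target

    # unweighting velocity bracket: 0 gives depth 0; grow upper bound until
    # the rendered depth exceeds the target (force may go negative for
    # physically impossible prescriptions -> SpecificationError below)
    hi = 2.0 * target / (spec.unweighting_duration + spec.braking_duration)
    for _ in range(40):
        if depth_err(hi) > 0:
            break
        hi *= 1.5
    else:  # pragma: no cover - unreachable for sane specs
        raise SpecificationError("could not calibrate countermovement depth")
    v_un = brentq(depth_err, 0.0, hi, xtol=1e-10)
    prof = _Profile(spec, v_un)
    if spec.body_mass * (G - prof.a1) < 0:
        raise SpecificationError(
            "countermovement_depth too large for the given unweighting/braking "
            "durations: the prescribed force would go negative"
        )
    return prof


def _ground_truth(
    prof: _Profile,
    onset_threshold_n: float,
    onset_backoff_s: float,
    oversample: float = 10.0,
) -> GroundTruth:
    spec = prof.spec
    m = spec.body_mass
    v_to = spec.target_takeoff_velocity
    dt = 1.0 / (oversample * spec.sampling_rate)
    t = np.arange(0.0, prof.t_takeoff + dt, dt)
    f = prof.force(t)
    # operational onset: first departure beyond the threshold, backed off
    cross = np.flatnonzero(np.abs(f - prof.bw) > onset_threshold_n)
    onset_time = float(t[cross[0]]) - onset_backoff_s
    sel = t >= onset_time
    ts, fs = t[sel], f[sel]
    v = cumulative_trapezoid(fs / m - G, ts, initial=0.0)
    power = fs * v
    v_peak = float(v.max())
    return GroundTruth(
        takeoff_velocity=v_to,
        jump_height=v_to**2 / (2.0 * G),
        peak_power=float(power.max()),
        mean_power=float(np.trapezoid(power, ts) / (ts[-1] - ts[0])),
        relative_net_impulse=v_to,
        peak_kinetic_energy=0.5 * m * v_peak**2,
        onset_time=onset_time,
        takeoff_time=prof.t_takeoff,
        peak_velocity=v_peak,
        flight_time=2.0 * v_to / G,
        movement_start_time=prof.t_move,
    )


def simulate_jump(
    spec: JumpSpec,
    *,
    onset_threshold_n: float = 2.5,
    onset_backoff_s: float = 0.030,
) -> tuple[ForceRecording, GroundTruth]:
    """Render one synthetic trial and its noiseless ground truth.

    ``onset_threshold_n`` is the force-departure threshold used for the
    *operational* onset in the ground truth; the default matches the
    analyzer's noiseless threshold (5 x the 0.5 N resting-noise floor).

    Returns
    -------
    (ForceRecording, GroundTruth)
        The recording carries seeded Gaussian noise of ``spec.noise_sd`` on
        ground-contact samples (flight stays at exactly 0 N unless
        ``spec.flight_noise``); the ground truth is evaluated on the 10x
        oversampled noiseless profile.
    """
    rng = np.random.default_rng(spec.seed)
    meta = dict(jump_type=spec.jump_type)
    if spec.target_takeoff_velocity == 0:
        # zero-jump limit: the jumper never moves
        n = int(round((spec.quiet_stand_duration + spec.post_landing_duration)
                      * spec.sampling_rate))
        force = np.full(n, spec.body_mass * G)
        if spec.noise_sd > 0:
            force = force + rng.normal(0.0, spec.noise_sd, size=n)
        rec = ForceRecording(force=force, sampling_rate=spec.sampling_rate, **meta)
        gt = GroundTruth(
            takeoff_velocity=0.0, jump_height=0.0, peak_power=0.0,
            mean_power=0.0, relative_net_impulse=0.0, peak_kinetic_energy=0.0,
            onset_time=float("nan"), takeoff_time=float("nan"),
            peak_velocity=0.0, flight_time=0.0,
        )
        return rec, gt

    prof = _calibrated_profile(spec)
    gt = _ground_truth(prof, onset_threshold_n, onset_backoff_s)
    t = np.arange(0.0, prof.t_end, 1.0 / spec.sampling_rate)
    force = prof.force(t)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=force.size)
        if not spec.flight_noise:
            noise[force == 0.0] = 0.0
        force = force + noise
    rec = ForceRecording(force=force, sampling_rate=spec.sampling_rate, **meta)
    return rec, gt


#: Table-2-like cohort operating point: CMJ peak kinetic energy distribution,
#: the published PKE->1RM line, and a residual sd giving population R^2 = 0.90.
DEFAULT_COHORT_METRICS = {"peak_kinetic_energy_j": (315.7, 113.1)}
DEFAULT_COHORT_SLOPE = 0.352
DEFAULT_COHORT_INTERCEPT = 12.775
DEFAULT_COHORT_RESIDUAL_SD = 13.27


def simulate_cohort(
    n: int = 13,
    metrics: dict[str, tuple[float, float]] | None = None,
    *,
    slope: float = DEFAULT_COHORT_SLOPE,
    intercept: float = DEFAULT_COHORT_INTERCEPT,
    residual_sd: float = DEFAULT_COHORT_RESIDUAL_SD,
    predictor: str | None = None,
    seed: int = 0,
):
    """Draw a cohort of jumpers with a known linear metric -> 1RM relationship.

    Each metric is drawn independently from its normal distribution
    (redrawn while non-positive, i.e. truncated at the physical lower bound),
    and measured 1RM is ``slope * predictor + intercept + N(0, residual_sd)``
    where ``predictor`` defaults to the first metric.  Defaults reproduce the
    published cohort operating point (n = 13, PKE ~ N(315.7, 113.1^2) J,
    1RM = 0.352 * PKE + 12.775 kg with ~13.3 kg residual sd).

    Returns a DataFrame with ``participant``, one column per metric, and
    ``measured_1rm_kg``.
    """
    import pandas as pd

    if n < 3:
        raise ValueError("cohort needs n >= 3 participants for any downstream fit")
    metrics = dict(metrics if metrics is not None else DEFAULT_COHORT_METRICS)
    if not metrics:
        raise ValueError("at least one metric distribution is required")
    for name, (mean, sd) in metrics.items():
        if sd < 0:
            raise ValueError(f"metric {name!r} sd must be >= 0")
    if residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    predictor = predictor or next(iter(metrics))
    if predictor not in metrics:
        raise ValueError(f"predictor {predictor!r} not among metrics")

    rng = np.random.default_rng(seed)
    data = {"participant": [f"P{i + 1:02d}" for i in range(n)]}
    for name, (mean, sd) in metrics.items():
        x = rng.normal(mean, sd, size=n)
        for _ in range(1000):
            bad = x <= 0
            if not bad.any():
                break
            x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:
            raise ValueError(
                f"metric {name!r} distribution N({mean}, {sd}^2) yields almost "
                "no positive mass; cannot truncate"
            )
        data[name] = x
    y = slope * data[predictor] + intercept
    if residual_sd > 0:
        y = y + rng.normal(0.0, residual_sd, size=n)
    data["measured_1rm_kg"] = y
    return pd.DataFrame(data)


def residual_sd_for_r2(slope: float, metric_sd: float, r2: float) -> float:
    """Residual sd giving population R^2 = ``r2`` for a single-predictor line."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    return abs(slope) * metric_sd * np.sqrt((1.0 - r2) / r2)
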