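"""Jump event detection, COM kinematics and the five GRF-derived metrics.

The analysis follows the standard impulse–momentum treatment of a vertical
jump on a force plate:

* body weight (and its standard deviation) from the first 0.5 s of quiet
  standing;
* movement onset: 30 ms before the force first departs from body weight by
  more than 5 resting standard deviations (two-sided — CMJ unweights
  downward, SJ pushes upward);
* take-off / landing at the 20 N force threshold;
* COM acceleration ``a = (F - W)/m``, velocity and displacement by
  cumulative trapezoidal integration from rest at onset, power ``P = F v``;
* phases: weighting, unweighting (CMJ), braking (CMJ), propulsion, flight,
  landing;
* metrics over the movement interval (onset → take-off): peak and mean
  power, relative net impulse, jump height ``v_to^2 / 2g`` and peak kinetic
  energy ``m v_peak^2 / 2``.

:class:`JumpAnalyzer` carries the thresholds as scikit-learn style
parameters (``get_params``/``set_params``) so a configured analyzer can be
cloned, serialized and swept; the module-level functions are thin wrappers
over a default-configured instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator

from .errors import (
    InvalidJumpError,
    NoCountermovementError,
    NoFlightError,
    NoLandingError,
    NoMovementError,
    SpecificationError,
)
from .io import ForceRecording

G = 9.81  # m/s^2


@dataclass(frozen=True)
class BodyWeightEstimate:
    """Quiet-standing weight estimate from the start of a recording."""

    weight: float        # N
    weight_sd: float     # N, sample sd over the window
    mass: float          # kg, weight / g
    window: tuple[int, int]  # [start, end) sample indices


@dataclass(frozen=True)
class JumpEvents:
    """Anchor sample indices of one jump (0-based; None where undefined)."""

    onset: int                      # movement onset (point A)
    takeoff: int                    # first sample below the take-off threshold
    landing: int | None = None      # first sample back above the threshold
    bw_return: int | None = None    # CMJ: force back to >= body weight (point C)
    zero_velocity: int | None = None  # CMJ: braking end, v back to >= 0 (point D)
    velocity_min: int | None = None   # CMJ: most negative COM velocity


@dataclass(frozen=True)
class KinematicsTrace:
    """Per-sample COM kinematics over [onset, takeoff] (inclusive)."""

    start: int               # sample index of the first element (onset)
    time: np.ndarray         # s
    acceleration: np.ndarray  # m/s^2
    velocity: np.ndarray     # m/s
    displacement: np.ndarray  # m
    power: np.ndarray        # W, force * velocity


PHASES_CMJ = ("weighting", "unweighting", "braking", "propulsion", "flight", "landing")
PHASES_SJ = ("weighting", "propulsion", "flight", "landing")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Contiguous half-open sample intervals labelled by phase."""

    phases: Mapping[str, tuple[int, int]]

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.phases[name]

    def __contains__(self, name: str) -> bool:
        return name in self.phases

    def labels(self) -> tuple[str, ...]:
        return tuple(self.phases)


@dataclass(frozen=True)
class JumpMetrics:
    """The five GRF-derived scalar variables of one trial (SI units)."""

    peak_power: float            # W
    mean_power: float            # W
    relative_net_impulse: float  # N*s/kg
    jump_height: float           # m
    peak_kinetic_energy: float   # J
    takeoff_velocity: float      # m/s
    peak_velocity: float         # m/s

    def as_row(self) -> dict:
        return {
            "peak_power_w": self.peak_power,
            "mean_power_w": self.mean_power,
            "relative_net_impulse_ns_kg": self.relative_net_impulse,
            "jump_height_m": self.jump_height,
            "peak_kinetic_energy_j": self.peak_kinetic_energy,
        }


@dataclass(frozen=True)
class JumpAnalysis:
    """Bundle of everything derived from one recording."""

    recording: ForceRecording
    body_weight: BodyWeightEstimate
    events: JumpEvents
    kinematics: KinematicsTrace
    segmentation: PhaseSegmentation
    metrics: JumpMetrics


class JumpAnalyzer(BaseEstimator):
    """Configured vertical-jump analysis of force recordings.

    Parameters
    ----------
    bw_window_s : float
        Quiet-standing window over which body weight is averaged (0.5 s,
        i.e. the first 500 samples at 1000 Hz).
    onset_sd_mult : float
        Onset threshold in resting standard deviations (5).
    onset_backoff_s : float
        Back-off applied before the threshold crossing (0.030 s).
    takeoff_threshold_n : float
        Take-off / landing force threshold (20 N).
    sd_floor_n : float
        Lower floor on the resting sd before forming the onset threshold;
        guards against a degenerate zero-width threshold on noiseless
        synthetic traces (0.5 N).
    lowpass_hz : float or None
        Optional Butterworth low-pass cut-off applied to the force before
        kinematic integration (off by default; event thresholds always see
        the raw force).
    g : float
        Acceleration due to gravity (9.81 m/s^2).
    """

    def __init__(
        self,
        bw_window_s: float = 0.5,
        onset_sd_mult: float = 5.0,
        onset_backoff_s: float = 0.030,
        takeoff_threshold_n: float = 20.0,
        sd_floor_n: float = 0.5,
        lowpass_hz: float | None = None,
        g: float = G,
    ):
        self.bw_window_s = bw_window_s
        self.onset_sd_mult = onset_sd_mult
        self.onset_backoff_s = onset_backoff_s
        self.takeoff_threshold_n = takeoff_threshold_n
        self.sd_floor_n = sd_floor_n
        self.lowpass_hz = lowpass_hz
        self.g = g

    # -- individual steps --------------------------------------------------

    def estimate_body_weight(self, rec: ForceRecording) -> BodyWeightEstimate:
        """Mean and sd of force over the first ``bw_window_s`` of standing."""
        win = int(round(self.bw_window_s * rec.sampling_rate))
        if rec.n_samples < win:
            raise ValueError(
                f"recording too short for the {self.bw_window_s} s body-weight "
                f"window ({rec.n_samples} < {win} samples)"
            )
        seg = rec.force[:win]
        weight = float(seg.mean())
        if weight <= 0:
            raise ValueError("non-positive body weight estimate")
        return BodyWeightEstimate(
            weight=weight,
            weight_sd=float(seg.std(ddof=1)),
            mass=weight / self.g,
            window=(0, win),
        )

    def _onset_threshold(self, bw: BodyWeightEstimate) -> float:
        sd = max(bw.weight_sd, self.sd_floor_n)
        if sd <= 0:
            raise SpecificationError(
                "resting force sd is zero and sd_floor_n is disabled; the "
                "onset threshold is degenerate — set sd_floor_n > 0"
            )
        return self.onset_sd_mult * sd

    def detect_onset(self, rec: ForceRecording, bw: BodyWeightEstimate) -> int:
        """Movement onset: back-off before the first |F - W| threshold exit."""
        thr = self._onset_threshold(bw)
        start = bw.window[1]
        dev = np.abs(rec.force[start:] - bw.weight) > thr
        idx = np.flatnonzero(dev)
        if idx.size == 0:
            raise NoMovementError(
                f"no movement detected: |F - {bw.weight:.1f} N| never exceeds "
                f"{thr:.2f} N after the body-weight window"
            )
        cross = start + int(idx[0])
        return max(0, cross - int(round(self.onset_backoff_s * rec.sampling_rate)))

    def detect_takeoff(self, rec: ForceRecording, onset: int) -> int:
        """First sample after onset with force below the take-off threshold."""
        idx = np.flatnonzero(rec.force[onset + 1:] < self.takeoff_threshold_n)
        if idx.size == 0:
            raise NoFlightError(
                f"no flight detected: force never drops below "
                f"{self.takeoff_threshold_n} N after onset"
            )
        return onset + 1 + int(idx[0])

    def detect_landing(self, rec: ForceRecording, takeoff: int) -> int:
        """First sample after take-off with force back above the threshold."""
        idx = np.flatnonzero(rec.force[takeoff + 1:] > self.takeoff_threshold_n)
        if idx.size == 0:
            raise NoLandingError("no landing detected: flight extends to end of file")
        return takeoff + 1 + int(idx[0])

    def _integration_force(self, rec: ForceRecording) -> np.ndarray:
        if self.lowpass_hz is None:
            return rec.force
        nyq = rec.sampling_rate / 2.0
        if not 0 < self.lowpass_hz < nyq:
            raise SpecificationError(f"lowpass_hz must lie in (0, {nyq}) Hz")
        b, a = butter(4, self.lowpass_hz / nyq)
        return filtfilt(b, a, rec.force)

    def integrate_kinematics(
        self, rec: ForceRecording, bw: BodyWeightEstimate, onset: int, takeoff: int
    ) -> KinematicsTrace:
        """COM kinematics over [onset, takeoff] from rest at onset."""
        if bw.mass <= 0:
            raise ValueError("non-positive mass")
        if not 0 <= onset < takeoff < rec.n_samples:
            raise ValueError("need 0 <= onset < takeoff within the recording")
        force = self._integration_force(rec)[onset:takeoff + 1]
        t = rec.time[onset:takeoff + 1]
        acc = (force - bw.weight) / bw.mass
        vel = cumulative_trapezoid(acc, t, initial=0.0)
        disp = cumulative_trapezoid(vel, t, initial=0.0)
        return KinematicsTrace(
            start=onset, time=t, acceleration=acc, velocity=vel,
            displacement=disp, power=force * vel,
        )

    def locate_events(
        self, rec: ForceRecording, bw: BodyWeightEstimate, jump_type: str
    ) -> tuple[JumpEvents, KinematicsTrace]:
        onset = self.detect_onset(rec, bw)
        takeoff = self.detect_takeoff(rec, onset)
        try:
            landing = self.detect_landing(rec, takeoff)
        except NoLandingError:
            landing = None
        kin = self.integrate_kinematics(rec, bw, onset, takeoff)
        bw_return = zero_velocity = velocity_min = None
        if jump_type == "CMJ":
            v = kin.velocity
            if v.min() >= 0:
                raise NoCountermovementError(
                    "no countermovement detected (COM velocity never negative); "
                    "analyze as SJ?"
                )
            velocity_min = onset + int(np.argmin(v))
            # force return to body weight after the downward excursion
            f = rec.force
            thr = self._onset_threshold(bw)
            below = np.flatnonzero(f[onset:takeoff] < bw.weight - thr)
            if below.size:
                drop = onset + int(below[0])
                back = np.flatnonzero(f[drop:takeoff] >= bw.weight)
                if back.size:
                    bw_return = drop + int(back[0])
            after_min = np.flatnonzero(v[velocity_min - onset:] >= 0.0)
            if after_min.size == 0:
                raise InvalidJumpError("COM velocity never returns to zero before take-off")
            zero_velocity = velocity_min + int(after_min[0])
        return (
            JumpEvents(
                onset=onset, takeoff=takeoff, landing=landing,
                bw_return=bw_return, zero_velocity=zero_velocity,
                velocity_min=velocity_min,
            ),
            kin,
        )

    def segment_phases(
        self, rec: ForceRecording, events: JumpEvents, jump_type: str
    ) -> PhaseSegmentation:
        """Label contiguous half-open phase intervals over the recording.

        For the CMJ the unweighting/braking boundary is placed at the
        velocity minimum (the braking definition); at a velocity extremum
        the acceleration is zero, so on clean data this is also where force
        crosses back through body weight (recorded in ``events.bw_return``).
        """
        end = events.landing if events.landing is not None else rec.n_samples
        a, f_to = events.onset, events.takeoff
        if jump_type == "CMJ":
            c = events.velocity_min
            d = events.zero_velocity
            if c is None or d is None:
                raise NoCountermovementError("CMJ segmentation needs countermovement events")
            phases = {
                "weighting": (0, a),
                "unweighting": (a, c),
                "braking": (c, d),
                "propulsion": (d, f_to),
                "flight": (f_to, end),
            }
        else:
            phases = {
                "weighting": (0, a),
                "propulsion": (a, f_to),
                "flight": (f_to, end),
            }
        if events.landing is not None:
            phases["landing"] = (events.landing, rec.n_samples)
        return PhaseSegmentation(phases=phases)

    def compute_metrics(
        self,
        rec: ForceRecording,
        bw: BodyWeightEstimate,
        kin: KinematicsTrace,
        events: JumpEvents,
    ) -> JumpMetrics:
        """The five metrics over the movement interval onset → take-off.

        For the CMJ this interval spans unweighting through propulsion (the
        signed power over braking is included in the time average, which is
        why CMJ mean power is far below its peak power); for the SJ it is
        the propulsion phase itself.
        """
        t, v, p = kin.time, kin.velocity, kin.power
        force = rec.force[events.onset:events.takeoff + 1]
        v_to = float(v[-1])
        if v_to <= 0:
            raise InvalidJumpError(f"invalid jump: take-off velocity {v_to:.3f} <= 0")
        duration = t[-1] - t[0]
        net_impulse = trapezoid(force - bw.weight, t)
        v_peak = float(v.max())
        return JumpMetrics(
            peak_power=float(p.max()),
            mean_power=float(trapezoid(p, t) / duration),
            relative_net_impulse=float(net_impulse / bw.mass),
            jump_height=v_to**2 / (2.0 * self.g),
            peak_kinetic_energy=0.5 * bw.mass * v_peak**2,
            takeoff_velocity=v_to,
            peak_velocity=v_peak,
        )

    # -- full pipeline -----------------------------------------------------

    def analyze(self, rec: ForceRecording, jump_type: str | None = None) -> JumpAnalysis:
        """Run the full chain on one recording.

        ``jump_type`` defaults to the recording's metadata; it decides the
        phase vocabulary (CMJ vs SJ) and the countermovement sanity check.
        """
        jump_type = jump_type or rec.jump_type
        if jump_type not in ("CMJ", "SJ"):
            raise SpecificationError(
                "jump_type must be 'CMJ' or 'SJ' (pass it or set it on the recording)"
            )
        bw = self.estimate_body_weight(rec)
        events, kin = self.locate_events(rec, bw, jump_type)
        seg = self.segment_phases(rec, events, jump_type)
        metrics = self.compute_metrics(rec, bw, kin, events)
        return JumpAnalysis(
            recording=rec, body_weight=bw, events=events,
            kinematics=kin, segmentation=seg, metrics=metrics,
        )


def select_best_trial(trials: list) -> int:
    """Index of the best trial: maximum jump height, earliest on ties.

    ``trials`` holds :class:`JumpMetrics` (or anything with ``jump_height``).
    """
    if not trials:
        raise ValueError("no trials to select from")
    heights = [t.jump_height for t in trials]
    return int(np.argmax(heights))  # argmax returns the first maximum


# -- thin functional wrappers over a default analyzer -----------------------

_DEFAULT = JumpAnalyzer()


def estimate_body_weight(rec: ForceRecording) -> BodyWeightEstimate:
    return _DEFAULT.estimate_body_weight(rec)


def detect_onset(rec: ForceRecording, bw: BodyWeightEstimate) -> int:
    return _DEFAULT.detect_onset(rec, bw)


def detect_takeoff(rec: ForceRecording, onset: int) -> int:
    return _DEFAULT.detect_takeoff(rec, onset)


def detect_landing(rec: ForceRecording, takeoff: int) -> int:
    return _DEFAULT.detect_landing(rec, takeoff)


def integrate_kinematics(rec, bw, onset, takeoff) -> KinematicsTrace:
    return _DEFAULT.integrate_kinematics(rec, bw, onset, takeoff)


def analyze(rec: ForceRecording, jump_type: str | None = None) -> JumpAnalysis:
    return _DEFAULT.analyze(rec, jump_type)
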