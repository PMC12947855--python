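"""Reach-trace processing: filtering, differentiation, onset detection,
per-trial kinematic metrics, exclusion rules, and difference traces.

Traces are radial position/velocity time series sampled at 1000 Hz with the
home circle at the origin.  The processing chain mirrors standard robotic
reaching pipelines: a third-order zero-phase (double-pass) Butterworth
low-pass at 10 Hz, a second-order centered finite difference for radial
velocity, velocity-threshold movement-onset detection, and per-trial metrics
(outgoing/return peak radial velocity, time to target, maximum excursion,
angular error at the 10 cm ring crossing).

Trials are excluded — flagged, never dropped — when the movement fails
(no onset within 4 s), never reaches the 10 cm ring on the initial outward
reach (a "double-peak" movement), or misses the target by >= 22.5 degrees.
Excluded trials still count for reward-history bookkeeping but as unrewarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

FS_HZ = 1000.0
DT_MS = 1.0
TARGET_RADIUS_M = 0.10
ANGULAR_ERROR_LIMIT_DEG = 22.5
ONSET_TIMEOUT_MS = 4000.0

EXCLUSION_NONE = "none"
EXCLUSION_FAILURE = "failure"
EXCLUSION_DOUBLE_PEAK = "double_peak"
EXCLUSION_MISS = "miss"


@dataclass
class VelocityTrace:
    """One trial's 1 kHz radial kinematics with event timestamps (ms).

    ``events`` must contain ``cue``; ``onset``/``hit``/``feedback`` are added
    by the pipeline (feedback coincides with the target hit).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    radial_pos: np.ndarray
    radial_vel: np.ndarray | None = None
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), DT_MS):
            raise ValueError("trace must be uniformly sampled at 1 ms")
        order = [self.events.get(k) for k in ("cue", "onset", "hit")
                 if self.events.get(k) is not None]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("event timestamps must be monotone (cue <= onset <= hit)")

    @property
    def n(self) -> int:
        return len(self.t)


def butter_double_pass_sos(cutoff_hz: float = 10.0, order: int = 3,
                           fs: float = FS_HZ) -> np.ndarray:
    """Third-order Butterworth sections with the single-pass cutoff pre-warped
    so the *double-pass* -3 dB point lands at ``cutoff_hz``."""
    # single-pass |H(f)|^2 = 1/(1+(f/fc)^2n); double pass squares it, so the
    # -3 dB point sits where (f/fc)^2n = sqrt(2)-1
    correction = (np.sqrt(2.0) - 1.0) ** (-0.5 / order)  # ~1.158 for order 3
    return signal.butter(order, cutoff_hz * correction, fs=fs, output="sos")


def lowpass_filter(x: np.ndarray, cutoff_hz: float = 10.0, order: int = 3,
                   fs: float = FS_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass; DC gain exactly 1."""
    x = np.asarray(x, float)
    if x.size < 3 * (order + 1):
        raise ValueError(f"trace too short to filter ({x.size} samples)")
    sos = butter_double_pass_sos(cutoff_hz, order, fs)
    return signal.sosfiltfilt(sos, x)


def filter_trace(trace: VelocityTrace, cutoff_hz: float = 10.0) -> VelocityTrace:
    """Filter the positional channels of a trace (velocity is recomputed later)."""
    return VelocityTrace(
        t=trace.t,
        x=lowpass_filter(trace.x, cutoff_hz),
        y=lowpass_filter(trace.y, cutoff_hz),
        radial_pos=lowpass_filter(trace.radial_pos, cutoff_hz),
        radial_vel=None,
        events=dict(trace.events),
    )


def radial_velocity(radial_pos: np.ndarray, dt_s: float = 1.0 / FS_HZ) -> np.ndarray:
    """Second-order centered finite difference; one-sided at the endpoints.

    Exact for linear and quadratic position profiles in the interior.
    """
    p = np.asarray(radial_pos, float)
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt_s)
    v[0] = (p[1] - p[0]) / dt_s
    v[-1] = (p[-1] - p[-2]) / dt_s
    return v


def attach_radial_velocity(trace: VelocityTrace) -> VelocityTrace:
    trace.radial_vel = radial_velocity(trace.radial_pos)
    return trace


def detect_onset(trace: VelocityTrace, threshold_frac: float = 0.05,
                 timeout_ms: float = ONSET_TIMEOUT_MS) -> float | None:
    """Movement onset after the cue, or None when no movement occurs.

    A stand-in for acceleration-profile onset detectors: find the first
    post-cue sample whose |radial velocity| exceeds ``threshold_frac`` of the
    post-cue peak, then backtrack to the nearest preceding local minimum of
    |velocity|.  Scale-invariant by construction (the threshold is relative).
    """
    if trace.radial_vel is None:
        attach_radial_velocity(trace)
    cue = trace.events.get("cue")
    if cue is None:
        raise ValueError("trace has no cue event")
    i_cue = int(np.searchsorted(trace.t, cue))
    i_stop = int(np.searchsorted(trace.t, cue + timeout_ms))
    v = np.abs(trace.radial_vel[i_cue:i_stop])
    if v.size == 0 or v.max() <= 1e-6:
        return None
    thresh = threshold_frac * v.max()
    above = np.nonzero(v >= thresh)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    while i > 0 and v[i - 1] < v[i]:
        i -= 1
    return float(trace.t[i_cue + i])


@dataclass
class TrialKinematics:
    """Scalar per-trial kinematic metrics plus the exclusion flag."""

    reaction_time: float = np.nan
    out_peak_vel: float = np.nan
    return_peak_vel: float = np.nan
    time_to_target: float = np.nan
    max_excursion: float = np.nan
    angular_error: float = np.nan
    excluded: bool = False
    exclusion_reason: str = EXCLUSION_NONE

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def extract_metrics(trace: VelocityTrace, target_angle_deg: float | None = None,
                    onset_threshold: float = 0.05) -> TrialKinematics:
    """Compute the per-trial metric set from a filtered trace.

    Outgoing peak velocity is the maximum radial velocity between onset and
    the first crossing of the 10 cm ring; return peak velocity is the largest
    inward speed after maximum excursion; angular error is measured where the
    hand crosses the ring.
    """
    if trace.radial_vel is None:
        attach_radial_velocity(trace)
    onset = detect_onset(trace, threshold_frac=onset_threshold)
    if onset is None:
        return TrialKinematics(excluded=True, exclusion_reason=EXCLUSION_FAILURE)
    cue = trace.events["cue"]
    i_on = int(np.searchsorted(trace.t, onset))
    pos = trace.radial_pos
    crossings = np.nonzero(pos[i_on:] >= TARGET_RADIUS_M)[0]
    if crossings.size == 0:
        return TrialKinematics(
            reaction_time=onset - cue, max_excursion=float(pos.max()),
            excluded=True, exclusion_reason=EXCLUSION_DOUBLE_PEAK)
    i_hit = i_on + int(crossings[0])
    out_peak = float(np.max(trace.radial_vel[i_on:i_hit + 1]))
    i_max = int(np.argmax(pos))
    inward = -trace.radial_vel[i_max:]
    ret_peak = float(np.max(inward)) if inward.size else np.nan
    km = TrialKinematics(
        reaction_time=float(onset - cue),
        out_peak_vel=out_peak,
        return_peak_vel=ret_peak,
        time_to_target=float(trace.t[i_hit] - onset),
        max_excursion=float(pos.max()),
    )
    if target_angle_deg is not None:
        hand_angle = np.degrees(np.arctan2(trace.y[i_hit], trace.x[i_hit]))
        err = abs((hand_angle - target_angle_deg + 180.0) % 360.0 - 180.0)
        km.angular_error = float(err)
        if err >= ANGULAR_ERROR_LIMIT_DEG:
            km.excluded = True
            km.exclusion_reason = EXCLUSION_MISS
    trace.events.setdefault("onset", onset)
    trace.events.setdefault("hit", float(trace.t[i_hit]))
    trace.events.setdefault("feedback", float(trace.t[i_hit]))
    return km


def apply_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Finalize exclusion flags and the reward stream used for history.

    Excluded trials are kept in the table but contribute zero reward to the
    leaky-integrator reward history (``reward_for_history``).
    """
    out = records.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = EXCLUSION_NONE
    out["excluded"] = out["excluded"].astype(bool)
    out["reward_for_history"] = out["reward"].to_numpy(float) * (~out["excluded"]).to_numpy(float)
    return out


def normalize_velocity(radial_vel: np.ndarray, out_peak_vel: float) -> np.ndarray:
    """Express instantaneous velocity as a fraction of the trial's outgoing peak."""
    if not np.isfinite(out_peak_vel) or out_peak_vel <= 0:
        raise ValueError("outgoing peak velocity must be positive")
    return np.asarray(radial_vel, float) / out_peak_vel


def extract_aligned_window(trace: VelocityTrace, align_event: str = "feedback",
                           window_ms: tuple[float, float] = (-150.0, 300.0),
                           normalize: bool = True,
                           out_peak_vel: float | None = None) -> np.ndarray:
    """Velocity samples in a half-open window around an event, optionally
    normalized by the outgoing peak; pads with NaN past the trace end."""
    if trace.radial_vel is None:
        attach_radial_velocity(trace)
    t0 = trace.events.get(align_event)
    if t0 is None:
        raise ValueError(f"trace has no {align_event!r} event")
    n = int(window_ms[1] - window_ms[0])
    i0 = int(np.searchsorted(trace.t, t0 + window_ms[0]))
    seg = np.full(n, np.nan)
    avail = trace.radial_vel[max(i0, 0):i0 + n]
    seg[:len(avail)] = avail
    if normalize:
        peak = out_peak_vel
        if peak is None:
            peak = float(np.max(trace.radial_vel))
        seg = normalize_velocity(seg, peak)
    return seg


def difference_traces(curves: np.ndarray, subjects: Sequence, groups: Sequence,
                      baseline_groups: set, time_ms: np.ndarray) -> pd.DataFrame:
    """Participant-wise baseline-subtracted mean curves with across-subject SEM.

    For each participant the pointwise mean curve of their baseline trials
    (e.g. the zero-expectation condition, or all RPE = 0 trials) is
    subtracted from every trial; group means are then averaged across
    participants.  Participants lacking baseline trials are dropped with a
    warning.  Returns long-format (time, group, mean, sem, n_subjects).
    """
    curves = np.asarray(curves, float)
    subjects = np.asarray(subjects)
    groups = np.asarray(groups)
    per_subject: dict[object, dict[object, np.ndarray]] = {}
    for s in np.unique(subjects):
        m_s = subjects == s
        m_base = m_s & np.isin(groups, list(baseline_groups))
        if not m_base.any():
            warnings.warn(f"participant {s!r} has no baseline trials; dropped")
            continue
        baseline = np.nanmean(curves[m_base], axis=0)
        per_subject[s] = {
            g: np.nanmean(curves[m_s & (groups == g)], axis=0) - baseline
            for g in np.unique(groups[m_s])
        }
    rows = []
    all_groups = np.unique(groups)
    for g in all_groups:
        stack = np.array([d[g] for d in per_subject.values() if g in d])
        if stack.size == 0:
            continue
        mean = np.nanmean(stack, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(stack.shape[0])
        for i, tm in enumerate(time_ms):
            rows.append(dict(time_ms=float(tm), group=g, mean=float(mean[i]),
                             sem=float(sem[i]) if stack.shape[0] > 1 else 0.0,
                             n_subjects=stack.shape[0]))
    return pd.DataFrame(rows)


def metrics_table(traces: Mapping[object, VelocityTrace],
                  target_angles: Mapping[object, float] | None = None) -> pd.DataFrame:
    """Run filter -> differentiate -> metrics over a keyed trace collection."""
    rows = []
    for key, tr in traces.items():
        filt = filter_trace(tr)
        attach_radial_velocity(filt)
        angle = target_angles.get(key) if target_angles else None
        km = extract_metrics(filt, target_angle_deg=angle)
        rows.append(dict(key=key, **km.to_dict()))
    return pd.DataFrame(rows)
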