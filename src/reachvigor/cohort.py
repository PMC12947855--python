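"""Synthetic behavioral cohorts: learning agents, choices, and kinematics.

Generates participant cohorts with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised and validated
without human data:

* Subject parameters (logit learning rate ``zeta``, effort cost ``e``,
  inverse temperature ``tau``) are drawn from population normals exactly as
  the hierarchical model specifies; ``eta = logistic(zeta)``.
* Values evolve by the VPE delta rule over single-target trials; choices are
  softmax in end-of-block value differences; choice trials give no feedback
  and trigger no update.
* Outgoing peak velocity is log-linear in the trial's value drive, the
  target direction offset and the integrated reward history, with
  mean-one multiplicative Gamma noise (matching the heteroskedastic,
  right-skewed velocity distributions that motivate Gamma log-link models).
* Reaction time is log-linear in reward expectation and reward history.
* Optionally, full 1 kHz out-and-back traces are synthesized: minimum-jerk
  excursion to the 10 cm ring, with the return phase multiplicatively scaled
  by ``1 + rpe_gain * RPE`` from ``rpe_latency_ms`` (default 212 ms) after
  feedback, smoothed over 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

from . import design as dg
from .kinematics import VelocityTrace
from .learning import EFFORT_MASK

#: population defaults: eta ~= 0.182, e ~= -0.429 (reported population means)
DEFAULT_ZETA_BAR = float(special.logit(0.182))
DEFAULT_E_BAR = -0.429
DEFAULT_TAU_BAR = 3.0


@dataclass(frozen=True)
class PopulationHyperParams:
    """Population-level means and SDs of the subject parameters."""

    zeta_bar: float = DEFAULT_ZETA_BAR
    e_bar: float = DEFAULT_E_BAR
    tau_bar: float = DEFAULT_TAU_BAR
    sigma_zeta: float = 0.3
    sigma_e: float = 0.3
    sigma_tau: float = 0.8

    def __post_init__(self) -> None:
        if min(self.sigma_zeta, self.sigma_e, self.sigma_tau) < 0:
            raise ValueError("population SDs must be nonnegative")


@dataclass(frozen=True)
class AgentParams:
    """One subject's learning parameters."""

    zeta: float
    e: float
    tau: float
    subject: int = 0

    @property
    def eta(self) -> float:
        return float(special.expit(self.zeta))


@dataclass(frozen=True)
class KinematicGenParams:
    """Generative kinematic model settings (artifact choices, not data claims).

    Gains are on the log-velocity scale per unit regressor, mirroring the
    magnitudes of the fitted Gamma log-link coefficients; ``gamma_shape``
    controls the multiplicative noise CV (CV = 1/sqrt(shape)).
    """

    base_peak_velocity: float = 0.60           # m/s toward the reference target
    value_gain: float = 0.0223                 # log-velocity per unit value
    direction_offsets: tuple = (0.04, -0.05, 0.0, -0.03)  # targets 1..4
    history_gain: float = 0.0209               # log-velocity per unit Rbar
    history_alpha: float = 0.647               # generator's smoothing factor
    rpe_gain: float = 0.04                     # fractional return-velocity per unit RPE
    rpe_latency_ms: float = 212.0
    rpe_ramp_ms: float = 50.0
    return_ratio: float = 0.90                 # unmodulated return/outgoing peak ratio
    gamma_shape: float = 100.0                 # velocity noise (CV 10%)
    rt_intercept: float = float(np.log(300.0))  # log ms
    rt_er_slope: float = -0.08                 # log-RT per unit expectation/value
    rt_history_slope: float = -0.10            # log-RT per unit Rbar
    rt_gamma_shape: float = 150.0
    rt_subject_sd: float = 0.08                # between-subject log-RT intercept SD
    pv_subject_sd: float = 0.05                # between-subject log-velocity intercept SD
    failure_rate: float = 0.0                  # injected double-peak trials

    def __post_init__(self) -> None:
        if self.base_peak_velocity <= 0 or self.gamma_shape <= 0:
            raise ValueError("base_peak_velocity and gamma_shape must be positive")
        if self.rpe_latency_ms < 0:
            raise ValueError("rpe_latency_ms must be nonnegative")


def sample_population(hyper: PopulationHyperParams, n_subjects: int,
                      seed: int = 0) -> list[AgentParams]:
    """Draw a cohort from the population normals; deterministic per seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    zeta = rng.normal(hyper.zeta_bar, hyper.sigma_zeta, n_subjects)
    e = rng.normal(hyper.e_bar, hyper.sigma_e, n_subjects)
    tau = rng.normal(hyper.tau_bar, hyper.sigma_tau, n_subjects)
    return [AgentParams(zeta=float(z), e=float(ee), tau=float(t), subject=s)
            for s, (z, ee, t) in enumerate(zip(zeta, e, tau))]


def simulate_choice(tau: float, v_a: float, v_b: float,
                    rng: np.random.Generator) -> str:
    """Softmax draw: returns 'A' with probability logistic(tau (vA - vB))."""
    p_a = special.expit(tau * (v_a - v_b))
    return "A" if rng.random() < p_a else "B"


def _gamma_noise(rng: np.random.Generator, shape: float, n: int | None = None):
    """Mean-one multiplicative Gamma noise; shape=inf disables it."""
    if np.isinf(shape):
        return 1.0 if n is None else np.ones(n)
    return rng.gamma(shape, 1.0 / shape, n)


def _min_jerk_vel(amplitude: float, duration_s: float, fs: float = 1000.0) -> np.ndarray:
    """Minimum-jerk speed profile: peak velocity = 1.875 * A / T."""
    n = max(int(round(duration_s * fs)), 8)
    s = np.linspace(0.0, 1.0, n, endpoint=False)
    return amplitude * 30.0 * s ** 2 * (1.0 - s) ** 2 / duration_s


def simulate_trace(out_peak: float, return_peak: float, rpe: float,
                   kin: KinematicGenParams, angle_deg: float,
                   rt_ms: float = 300.0, cue_delay_ms: float = 900.0,
                   max_excursion: float = 0.105) -> VelocityTrace:
    """Synthesize one out-and-back radial trace at 1 kHz.

    The outgoing phase is a minimum-jerk excursion to ``max_excursion``
    (past the 10 cm ring so a hit occurs); after an 80 ms dwell the return
    phase mirrors it at ``return_peak``.  From ``rpe_latency_ms`` after the
    ring crossing, instantaneous velocity is scaled by ``1 + rpe_gain*rpe``
    with a linear ramp over ``rpe_ramp_ms``.
    """
    if out_peak <= 0 or return_peak <= 0:
        raise ValueError("velocity peaks must be positive")
    fs = 1000.0
    t_out = 1.875 * max_excursion / out_peak
    t_ret = 1.875 * max_excursion / return_peak
    v_out = _min_jerk_vel(max_excursion, t_out, fs)
    v_ret = -_min_jerk_vel(max_excursion, t_ret, fs)
    n_pre = int(round(cue_delay_ms + rt_ms))
    n_dwell = 80
    v = np.concatenate([np.zeros(n_pre), v_out, np.zeros(n_dwell), v_ret,
                        np.zeros(150)])
    pos = np.cumsum(v) / fs
    # feedback at the outward 10 cm crossing
    hit_idx = int(np.argmax(pos >= 0.10)) if pos.max() >= 0.10 else None
    if hit_idx is not None and rpe != 0.0 and kin.rpe_gain != 0.0:
        i0 = hit_idx + int(kin.rpe_latency_ms)
        ramp_n = max(int(kin.rpe_ramp_ms), 1)
        gain = np.ones(v.size)
        ramp_end = min(i0 + ramp_n, v.size)
        if i0 < v.size:
            gain[i0:ramp_end] = 1.0 + kin.rpe_gain * rpe * \
                np.linspace(0, 1, ramp_end - i0, endpoint=False)
            gain[ramp_end:] = 1.0 + kin.rpe_gain * rpe
            v = v * gain
            pos = np.cumsum(v) / fs
    pos = np.clip(pos, 0.0, None)
    t = np.arange(v.size, dtype=float)
    rad = np.radians(angle_deg)
    events = {"cue": float(cue_delay_ms), "true_onset": float(n_pre)}
    if hit_idx is not None:
        events["hit"] = float(hit_idx)
        events["feedback"] = float(hit_idx)
    return VelocityTrace(t=t, x=pos * np.cos(rad), y=pos * np.sin(rad),
                         radial_pos=pos, radial_vel=v.copy(), events=events)


def simulate_experiment(
    agent: AgentParams,
    schedules: Sequence[dg.BlockSchedule],
    kin: KinematicGenParams = KinematicGenParams(),
    seed: int = 0,
    mode: str | None = None,
    include_traces: bool = False,
) -> tuple[pd.DataFrame, dict[int, VelocityTrace]]:
    """Run one agent through an experiment, emitting the trial-record table
    and (optionally) per-trial velocity traces keyed by row index.

    In ``learned`` mode the velocity drive is the agent's current learned
    value of the cued target; in ``instructed`` mode it is the announced
    reward probability plus the agent's effort cost.
    """
    rng = np.random.default_rng(seed)
    mode = mode or schedules[0].mode
    subj_rt = rng.normal(0.0, kin.rt_subject_sd)
    subj_pv = rng.normal(0.0, kin.pv_subject_sd)
    eta, e_cost, tau = agent.eta, agent.e, agent.tau

    rows = []
    traces: dict[int, VelocityTrace] = {}
    r_bar = 0.5
    row_idx = 0
    for sched in schedules:
        V = np.zeros(4)
        for tr in sched.trials.itertuples(index=False):
            is_fam = bool(tr.familiarization)
            if tr.trial_type == "single":
                tgt = int(tr.target)
                er = float(tr.e_r)
                reward = int(tr.reward) if not is_fam else 0
                if mode == "learned":
                    drive = V[tgt - 1]
                else:
                    drive = er + e_cost * EFFORT_MASK[tgt - 1]
                chosen = tgt
                alt = None
            else:  # choice trial: random A/B labeling, softmax pick, no feedback
                a, b = int(tr.target), int(tr.alt_target)
                if rng.random() < 0.5:
                    a, b = b, a
                v_a = V[a - 1] if mode == "learned" else \
                    float(sched.probabilities[a]) + e_cost * EFFORT_MASK[a - 1]
                v_b = V[b - 1] if mode == "learned" else \
                    float(sched.probabilities[b]) + e_cost * EFFORT_MASK[b - 1]
                pick = simulate_choice(tau, v_a, v_b, rng)
                chosen = a if pick == "A" else b
                tgt, alt = a, b
                er = np.nan
                reward = 0
                drive = v_a if pick == "A" else v_b

            rpe = (reward - er) if (tr.trial_type == "single" and not is_fam) else 0.0
            log_pv = (np.log(kin.base_peak_velocity) + subj_pv
                      + kin.value_gain * drive
                      + kin.direction_offsets[chosen - 1]
                      + kin.history_gain * r_bar)
            out_pv = float(np.exp(log_pv) * _gamma_noise(rng, kin.gamma_shape))
            ret_base = out_pv * kin.return_ratio
            ret_pv = float(ret_base * (1.0 + kin.rpe_gain * rpe)
                           * _gamma_noise(rng, kin.gamma_shape))
            rt_drive = drive if mode == "learned" else (er if np.isfinite(er) else drive)
            log_rt = (kin.rt_intercept + subj_rt + kin.rt_er_slope * rt_drive
                      + kin.rt_history_slope * r_bar)
            rt_ms = float(np.exp(log_rt) * _gamma_noise(rng, kin.rt_gamma_shape))
            gen_failure = bool(rng.random() < kin.failure_rate)

            vpe = np.nan
            value_pre = V[chosen - 1]
            r_bar_pre = r_bar
            if tr.trial_type == "single" and not is_fam:
                vpe = reward + e_cost * EFFORT_MASK[tgt - 1] - V[tgt - 1]
                V[tgt - 1] += eta * vpe
                r_bar = kin.history_alpha * (0 if gen_failure else reward) \
                    + (1 - kin.history_alpha) * r_bar

            rows.append(dict(
                subject=agent.subject, block=int(tr.block), trial=int(tr.trial),
                trial_type=tr.trial_type, target=int(tr.target),
                alt_target=(int(tr.alt_target) if tr.trial_type == "choice" else pd.NA),
                choice=(chosen if tr.trial_type == "choice" else pd.NA),
                e_r=er, reward=reward, familiarization=is_fam,
                rpe=(rpe if tr.trial_type == "single" and not is_fam else np.nan),
                value=float(value_pre), vpe=vpe, r_bar_gen=float(r_bar_pre),
                reaction_time=rt_ms, out_peak_vel=out_pv, return_peak_vel=ret_pv,
                cue_delay_ms=float(tr.cue_delay_ms), gen_failure=gen_failure,
                excluded=gen_failure,
                exclusion_reason=("double_peak" if gen_failure else "none"),
            ))
            if include_traces:
                angle = dg.TARGET_ANGLES[chosen]
                excursion = 0.09 if gen_failure else 0.105
                traces[row_idx] = simulate_trace(
                    out_pv, ret_base, rpe, kin, angle, rt_ms=rt_ms,
                    cue_delay_ms=float(tr.cue_delay_ms), max_excursion=excursion)
            row_idx += 1
    return pd.DataFrame(rows), traces


def simulate_cohort(
    n_subjects: int = 22,
    hyper: PopulationHyperParams = PopulationHyperParams(),
    kin: KinematicGenParams = KinematicGenParams(),
    mode: str = "learned",
    seed: int = 0,
    include_traces: bool = False,
    familiarization: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[int, int], VelocityTrace]]:
    """Full cohort: per-subject schedules, agents, trials and (optionally)
    traces keyed by (subject, row index)."""
    agents = sample_population(hyper, n_subjects, seed=seed)
    all_rows = []
    all_traces: dict[tuple[int, int], VelocityTrace] = {}
    for s, agent in enumerate(agents):
        scheds = dg.build_experiment_schedule(mode=mode, seed=seed * 10007 + s,
                                              familiarization=familiarization)
        rec, traces = simulate_experiment(agent, scheds, kin,
                                          seed=seed * 20011 + s,
                                          include_traces=include_traces)
        all_rows.append(rec)
        for k, v in traces.items():
            all_traces[(s, k)] = v
    records = pd.concat(all_rows, ignore_index=True)
    return records, all_traces


def cohort_true_params(hyper: PopulationHyperParams, n_subjects: int,
                       seed: int = 0) -> pd.DataFrame:
    """Ground-truth subject parameters for recovery checks (same draws as
    :func:`simulate_cohort` uses)."""
    agents = sample_population(hyper, n_subjects, seed=seed)
    return pd.DataFrame(dict(
        subject=[a.subject for a in agents], zeta=[a.zeta for a in agents],
        eta=[a.eta for a in agents], e=[a.e for a in agents],
        tau=[a.tau for a in agents],
    ))
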