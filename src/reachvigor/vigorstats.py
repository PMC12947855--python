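"""Statistical analyses of vigor: mixed regressions, within-trial velocity
difference models, 1D time-series (SPM-style) inference, correlations, and
the choice-velocity link.

Gamma log-link mixed models are estimated by a two-stage procedure:
per-subject Gamma GLM fits (statsmodels, log link) followed by one-sample
t tests on the subject-level coefficients.  This treats subjects as the
unit of inference — asymptotically equivalent to the random-effects mean
and far more robust than a fragile joint GLMM fit.  Gaussian identity-link
models use statsmodels MixedLM.

The 1D analysis regresses normalized velocity on a per-trial regressor at
every millisecond within subject (first level), then tests the subject beta
curves against zero pointwise (second level), controlling the family-wise
error over time with a max-|t| sign-flip permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .learning import aicc


class RankDeficientDesignError(ValueError):
    """Raised when the fixed-effect design is collinear."""


@dataclass
class RegressionSpec:
    """Declarative regression request.

    ``fixed`` holds patsy formula terms (e.g. ``["e_r", "C(target)",
    "block", "trial_z"]``); the response family must match the metric
    (``gamma_log`` for strictly positive, right-skewed vigor metrics,
    ``gaussian_identity`` for velocity differences).
    """

    response: str
    fixed: list[str]
    family: Literal["gamma_log", "gaussian_identity"] = "gamma_log"
    group: str = "subject"


def _check_rank(df: pd.DataFrame, formula: str) -> None:
    import patsy

    X = patsy.dmatrix(formula.split("~", 1)[1], df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise RankDeficientDesignError(
            f"design is rank deficient ({rank}/{X.shape[1]}); "
            f"most collinear terms: {worst}")


def _sign_flip_pvalue(vals: np.ndarray, n_flips: int = 4000, seed: int = 0) -> float:
    """Two-sided one-sample test of zero mean by sign flipping.

    Exact (full enumeration) for up to 12 subjects, Monte Carlo otherwise;
    valid under symmetry of the null distribution regardless of
    between-subject variance heterogeneity.
    """
    n = vals.size
    obs = abs(vals.mean())
    if n <= 12:
        signs = np.array(np.meshgrid(*[[-1.0, 1.0]] * n)).T.reshape(-1, n)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_flips, n))
        signs[0] = 1.0  # include the identity
    flipped = np.abs((signs * vals).mean(axis=1))
    return float(np.mean(flipped >= obs - 1e-15))


def fit_vigor_model(records: pd.DataFrame, spec: RegressionSpec,
                    min_trials: int = 20, seed: int = 0) -> pd.DataFrame:
    """Two-stage mixed-model estimate of the fixed effects in ``spec``.

    Stage 1 fits the per-subject GLM (Gamma log-link or Gaussian); stage 2
    tests each coefficient's across-subject mean against zero with an exact
    sign-flip test (the t statistic is reported alongside for reference).
    Returns a coefficient table (term, beta, se, t, p, n_subjects) with the
    per-subject estimates attached as ``.attrs['subject_coefs']``.
    """
    rec = records
    if "excluded" in rec.columns:
        rec = rec[~rec["excluded"].astype(bool)]
    rec = rec[np.isfinite(rec[spec.response])]
    formula = f"{spec.response} ~ " + " + ".join(spec.fixed)
    _check_rank(rec, formula)

    per_subject = []
    for s, g in rec.groupby(spec.group):
        if len(g) < min_trials:
            warnings.warn(f"subject {s!r} has <{min_trials} trials; dropped")
            continue
        try:
            if spec.family == "gamma_log":
                fit = smf.glm(formula, data=g,
                              family=sm.families.Gamma(sm.families.links.Log())).fit()
            else:
                fit = smf.ols(formula, data=g).fit()
        except Exception as err:  # singular subject design
            warnings.warn(f"subject {s!r} fit failed ({err}); dropped")
            continue
        per_subject.append(pd.Series(fit.params, name=s))
    if len(per_subject) < 2:
        raise ValueError("need >=2 successfully fitted subjects")
    coefs = pd.DataFrame(per_subject)
    rows = []
    for term in coefs.columns:
        vals = coefs[term].dropna().to_numpy()
        t, _ = stats.ttest_1samp(vals, 0.0)
        p = _sign_flip_pvalue(vals, seed=seed)
        rows.append(dict(term=term, beta=float(vals.mean()),
                         se=float(vals.std(ddof=1) / np.sqrt(vals.size)),
                         t=float(t), p=float(p), n_subjects=int(vals.size)))
    out = pd.DataFrame(rows)
    out.attrs["subject_coefs"] = coefs
    out.attrs["method"] = "two_stage"
    return out


def velocity_difference_model(records: pd.DataFrame,
                              predictor: Literal["rpe", "vpe"] = "rpe") -> dict:
    """Within-trial (return - outgoing) peak-velocity model.

    Fits ``vdiff ~ predictor * reward`` with a subject random intercept
    (Gaussian identity link); reports the coefficient table, the ML AICc,
    and whether the predictor x reward interaction is distinguishable from 0.
    """
    rec = records[(records.trial_type == "single")
                  & ~records["familiarization"].astype(bool)].copy()
    if "excluded" in rec.columns:
        rec = rec[~rec["excluded"].astype(bool)]
    rec = rec[np.isfinite(rec[predictor])]
    rec["vdiff"] = rec.return_peak_vel - rec.out_peak_vel
    formula = f"vdiff ~ {predictor} * reward"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, rec, groups=rec["subject"])
        fit = md.fit(reml=False)
    k = len(fit.fe_params) + 2
    table = pd.DataFrame(dict(
        term=fit.fe_params.index,
        beta=fit.fe_params.to_numpy(),
        se=fit.bse_fe.to_numpy(),
        p=fit.pvalues[fit.fe_params.index].to_numpy(),
    ))
    inter = f"{predictor}:reward"
    return dict(
        table=table,
        aicc=float(aicc(fit.llf, k, len(rec))),
        beta_predictor=float(fit.fe_params[predictor]),
        p_predictor=float(fit.pvalues[predictor]),
        beta_reward=float(fit.fe_params["reward"]),
        p_reward=float(fit.pvalues["reward"]),
        beta_interaction=float(fit.fe_params[inter]),
        interaction_significant=bool(fit.pvalues[inter] < 0.05),
    )


# ---------------------------------------------------------------------------
# 1D time-series inference
# ---------------------------------------------------------------------------


@dataclass
class SPMResult:
    """Second-level 1D inference output."""

    time_ms: np.ndarray
    t_curve: np.ndarray
    threshold: float
    mask: np.ndarray
    onset_ms: float | None
    first_level_betas: np.ndarray = field(repr=False, default=None)


def spm_first_level(curves: np.ndarray, regressor: np.ndarray,
                    subjects: np.ndarray, min_trials: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject OLS slope of the curves on the regressor at every sample.

    ``curves`` is (n_trials, T); returns (betas (S, T), subject ids).
    Subjects with fewer than ``min_trials`` usable trials are dropped.
    """
    curves = np.asarray(curves, float)
    regressor = np.asarray(regressor, float)
    subjects = np.asarray(subjects)
    if np.ptp(regressor) == 0:
        raise ValueError("regressor has zero variance")
    betas, ids = [], []
    for s in np.unique(subjects):
        m = subjects == s
        x = regressor[m]
        Y = curves[m]
        ok = np.isfinite(x) & np.all(np.isfinite(Y), axis=1)
        x, Y = x[ok], Y[ok]
        if x.size < min_trials:
            warnings.warn(f"subject {s!r} has <{min_trials} trials; dropped")
            continue
        if np.ptp(x) == 0:
            warnings.warn(f"subject {s!r} regressor is constant; dropped")
            continue
        xc = x - x.mean()
        betas.append((xc @ (Y - Y.mean(axis=0))) / (xc @ xc))
        ids.append(s)
    if not betas:
        raise ValueError("no usable subjects")
    return np.asarray(betas), np.asarray(ids)


def spm_second_level(betas: np.ndarray, time_ms: np.ndarray, alpha: float = 0.05,
                     n_perm: int = 1000, seed: int = 0) -> SPMResult:
    """Pointwise one-sample t across subjects with max-|t| sign-flip control.

    The permutation distribution of the maximum |t| over time under random
    sign flips of whole subject curves provides the family-wise threshold;
    this is exact under exchangeability of the subject effect signs.
    """
    betas = np.asarray(betas, float)
    S = betas.shape[0]
    if S < 5:
        raise ValueError("second-level test needs >=5 subjects")

    def t_of(b):
        sd = b.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.finfo(float).tiny, sd)
        return b.mean(axis=0) / (sd / np.sqrt(S))

    t_obs = t_of(betas)
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=S)[:, None]
        max_t[i] = np.max(np.abs(t_of(betas * flips)))
    threshold = float(np.quantile(max_t, 1.0 - alpha))
    mask = np.abs(t_obs) > threshold
    onset = float(time_ms[np.argmax(mask)]) if mask.any() else None
    return SPMResult(time_ms=np.asarray(time_ms, float), t_curve=t_obs,
                     threshold=threshold, mask=mask, onset_ms=onset,
                     first_level_betas=betas)


# ---------------------------------------------------------------------------
# correlations and the choice-velocity link
# ---------------------------------------------------------------------------


def correlation_battery(pairs: dict[str, tuple[Sequence, Sequence]]) -> pd.DataFrame:
    """Kendall tau and Pearson r (with p-values) for each named paired set."""
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError(f"pairing {name!r} has <3 observations")
        tau, p_tau = stats.kendalltau(x, y)
        r, p_r = stats.pearsonr(x, y)
        rows.append(dict(pairing=name, n=int(x.size), kendall_tau=float(tau),
                         kendall_p=float(p_tau), pearson_r=float(r),
                         pearson_p=float(p_r)))
    return pd.DataFrame(rows)


def end_of_block_velocities(records: pd.DataFrame, n_last: int = 36) -> pd.DataFrame:
    """Per (subject, block, target) mean outgoing peak velocity over the
    final ``n_last`` single-target trials of the block."""
    rec = records[(records.trial_type == "single")
                  & ~records["familiarization"].astype(bool)]
    if "excluded" in rec.columns:
        rec = rec[~rec["excluded"].astype(bool)]
    rows = []
    for (s, b), g in rec.groupby(["subject", "block"]):
        tail = g.sort_values("trial").tail(n_last)
        for t, gg in tail.groupby("target"):
            rows.append(dict(subject=s, block=b, target=int(t),
                             mean_pv=float(gg.out_peak_vel.mean())))
    return pd.DataFrame(rows)


def choice_velocity_link(records: pd.DataFrame, dpv_example: float = 0.115) -> dict:
    """Logistic regression of choice on the end-of-block velocity difference.

    For every choice trial, the predictor is the difference of the two
    presented targets' mean outgoing velocities over the final 36
    single-target trials of that block; the outcome is whether the first
    target of the pair was selected.  Reports the slope and the implied
    selection odds at ``dpv_example`` m/s.
    """
    eob = end_of_block_velocities(records)
    pv = {(r.subject, r.block, r.target): r.mean_pv for r in eob.itertuples()}
    cho = records[(records.trial_type == "choice")
                  & ~records["familiarization"].astype(bool)]
    x, y = [], []
    for r in cho.itertuples():
        a, b = int(r.target), int(r.alt_target)
        va = pv.get((r.subject, r.block, a))
        vb = pv.get((r.subject, r.block, b))
        if va is None or vb is None or pd.isna(r.choice):
            continue
        x.append(va - vb)
        y.append(1.0 if int(r.choice) == a else 0.0)
    x = np.asarray(x)
    y = np.asarray(y)
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    slope = float(fit.params[1])
    return dict(
        slope=slope, se=float(fit.bse[1]), p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]), n=int(y.size),
        odds_at_example=float(np.exp(slope * dpv_example)),
        selection_prob_at_example=float(1 / (1 + np.exp(-(fit.params[0] + slope * dpv_example)))),
    )
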