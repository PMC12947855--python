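"""Leaky-integrator reward history and its reaction-time likelihood fit.

Recent reward reception is summarized by an exponential moving average of
the binary reward stream::

    Rbar_{i+1} = alpha * R_i + (1 - alpha) * Rbar_i

with smoothing factor ``alpha`` in [0, 1] — a behavioral proxy for tonic
motivational state.  ``alpha`` is estimated by profile likelihood: for each
candidate value the per-subject history series is recomputed and the
maximized likelihood of a log-scale reaction-time regression with a subject
random intercept (controls: block, direction repeat, trial, trial x E[R],
target) is recorded; the estimate is the grid argmax.

The random-intercept Gaussian likelihood is solved in closed form for fixed
variance ratio (per-group shrinkage transform + GLS) and concentrated over
the ratio with a scalar search, which makes a dense alpha grid affordable.
Excluded and familiarization trials contribute zero reward to the history
but remain in the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats


@dataclass
class RewardHistoryState:
    """Current integrated reward history and its smoothing factor."""

    r_bar: float = 0.5
    alpha: float = 0.647

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.r_bar <= 1.0:
            raise ValueError("r_bar must lie in [0, 1]")


def update_history(state: RewardHistoryState, reward: float) -> RewardHistoryState:
    """One exponential-moving-average step for a binary reward."""
    if reward not in (0, 0.0, 1, 1.0):
        raise ValueError("reward must be binary")
    new = state.alpha * float(reward) + (1.0 - state.alpha) * state.r_bar
    return RewardHistoryState(r_bar=new, alpha=state.alpha)


def history_series(rewards: Sequence[float], alpha: float, r0: float = 0.5) -> np.ndarray:
    """Pre-trial history values: out[i] is Rbar *before* reward i lands.

    ``out[0] = r0``; ``out[i] = alpha * R_{i-1} + (1-alpha) * out[i-1]``.
    Implemented as a first-order IIR filter.
    """
    r = np.asarray(rewards, float)
    if r.size == 0:
        return np.array([])
    if alpha == 0.0:
        return np.full(r.size, r0)
    filtered, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], r,
                                 zi=[(1.0 - alpha) * r0])
    return np.concatenate([[r0], filtered[:-1]])


def closed_form_history(rewards: Sequence[float], alpha: float, r0: float = 0.5) -> float:
    """Direct geometric-sum evaluation of Rbar after n rewards (oracle form):
    ``alpha * sum_k (1-alpha)^(n-1-k) R_k + (1-alpha)^n r0``."""
    r = np.asarray(rewards, float)
    n = r.size
    weights = alpha * (1.0 - alpha) ** (n - 1 - np.arange(n))
    return float(weights @ r + (1.0 - alpha) ** n * r0)


# ---------------------------------------------------------------------------
# fast random-intercept Gaussian ML
# ---------------------------------------------------------------------------


def random_intercept_loglik(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                            return_fit: bool = False):
    """Maximized ML log-likelihood of y = X b + u_g + e with one random
    intercept per group.

    For a fixed variance ratio r = var(u)/var(e) the GLS solution is obtained
    by the within-group shrinkage transform ``y - theta_g * ybar_g`` with
    ``theta_g = 1 - 1/sqrt(1 + n_g r)``; the profile over r is maximized with
    a bounded scalar search on log r.  Verified against statsmodels MixedLM.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = codes.max() + 1
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    N = y.size

    def profile_negll(log_r: float):
        r = np.exp(log_r)
        theta = 1.0 - 1.0 / np.sqrt(1.0 + counts * r)
        ybar = np.bincount(codes, weights=y, minlength=n_groups) / counts
        yt = y - theta[codes] * ybar[codes]
        Xt = X - theta[codes, None] * (
            np.vstack([np.bincount(codes, weights=X[:, j], minlength=n_groups)
                       for j in range(X.shape[1])]).T / counts[:, None]
        )[codes]
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        sigma2 = rss / N
        ll = (-0.5 * N * np.log(2 * np.pi * sigma2) - 0.5 * N
              - 0.5 * np.sum(np.log(1.0 + counts * r)))
        return -ll, beta, sigma2, r

    res = optimize.minimize_scalar(lambda lr: profile_negll(lr)[0],
                                   bounds=(-12.0, 6.0), method="bounded",
                                   options=dict(xatol=1e-6))
    negll_r, beta, sigma2, r = profile_negll(res.x)
    # compare against the no-random-effect boundary (r -> 0)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss0 = float(np.sum((y - X @ beta0) ** 2))
    ll0 = -0.5 * N * np.log(2 * np.pi * rss0 / N) - 0.5 * N
    ll = max(-negll_r, ll0)
    if return_fit:
        if ll0 > -negll_r:
            beta, sigma2, r = beta0, rss0 / N, 0.0
        return ll, beta, sigma2, r
    return ll


_RT_CONTROLS = ("block", "repeat", "trial_z", "e_r", "trial_x_er")


def _rt_design(records: pd.DataFrame, r_bar: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the log reaction-time control regression."""
    g = records
    trial_z = (g.trial - g.trial.mean()) / max(g.trial.std(), 1e-9)
    cols = {
        "intercept": np.ones(len(g)),
        "block": g.block.to_numpy(float),
        "r_bar": r_bar,
        "repeat": g.get("repeat", pd.Series(np.zeros(len(g)), index=g.index)).to_numpy(float),
        "trial_z": trial_z.to_numpy(float),
        "e_r": g.e_r.to_numpy(float),
        "trial_x_er": (trial_z * g.e_r).to_numpy(float),
    }
    for t in (2, 3, 4):  # target 1 is the reference direction
        cols[f"target_{t}"] = (g.target.to_numpy(int) == t).astype(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    y = np.log(g.reaction_time.to_numpy(float))
    return y, X, g.subject.to_numpy(), names


def _with_repeat_column(records: pd.DataFrame) -> pd.DataFrame:
    """Direction-repeat indicator: same target as the previous trial."""
    out = records.copy()
    prev = out.groupby(["subject", "block"])["target"].shift(1)
    out["repeat"] = (out["target"] == prev).astype(float)
    return out


def compute_r_bar(records: pd.DataFrame, alpha: float, r0: float = 0.5,
                  reward_col: str | None = None) -> np.ndarray:
    """Per-subject pre-trial history values over the full trial sequence
    (no reset between blocks); choice trials hold the history constant."""
    col = reward_col or ("reward_for_history" if "reward_for_history" in records.columns else "reward")
    out = np.empty(len(records))
    for _, idx in records.groupby("subject").groups.items():
        g = records.loc[idx].sort_values(["block", "trial"])
        rewards = g[col].to_numpy(float)
        feedback = ((g.trial_type == "single") & ~g.familiarization.astype(bool)).to_numpy()
        fb_rewards = rewards[feedback]
        pre = history_series(fb_rewards, alpha, r0=r0)
        if fb_rewards.size:
            final = alpha * fb_rewards[-1] + (1 - alpha) * pre[-1] if alpha > 0 else r0
            h_ext = np.concatenate([pre, [final]])
        else:
            h_ext = np.array([r0])
        n_before = np.cumsum(feedback) - feedback  # feedback trials strictly before i
        out[records.index.get_indexer(g.index)] = h_ext[n_before]
    return out


def fit_alpha(records: pd.DataFrame, alphas: np.ndarray | None = None,
              r0: float = 0.5) -> tuple[float, pd.DataFrame]:
    """Profile-likelihood grid search for the smoothing factor.

    Returns the argmax alpha and the full (alpha, loglik) profile.  Only
    single-target, non-familiarization trials with valid reaction times enter
    the regression; the history itself integrates over the same stream.
    """
    if alphas is None:
        alphas = np.arange(0.0, 1.0005, 0.001)
    alphas = np.asarray(alphas, float)
    if alphas.size < 2 or np.any((alphas < 0) | (alphas > 1)):
        raise ValueError("alpha grid must contain >=2 values inside [0, 1]")
    rec = _with_repeat_column(records)
    mask = ((rec.trial_type == "single") & ~rec.familiarization.astype(bool)
            & np.isfinite(rec.reaction_time) & (rec.reaction_time > 0))
    if "excluded" in rec.columns:
        mask &= ~rec.excluded.astype(bool)
    fit_rec = rec[mask]
    lls = np.empty(alphas.size)
    for k, a in enumerate(alphas):
        r_bar_full = compute_r_bar(rec, a, r0=r0)
        r_bar = r_bar_full[mask.to_numpy()]
        y, X, groups, _ = _rt_design(fit_rec, r_bar)
        lls[k] = random_intercept_loglik(y, X, groups)
    profile = pd.DataFrame(dict(alpha=alphas, loglik=lls))
    return float(alphas[np.argmax(lls)]), profile


def profile_is_flat(profile: pd.DataFrame, df: int = 1, level: float = 0.95) -> bool:
    """True when the likelihood range is below the chi-square critical value,
    i.e. the data carry no evidence about alpha."""
    span = 2.0 * (profile.loglik.max() - profile.loglik.min())
    return bool(span < stats.chi2.ppf(level, df))


def history_regression(records: pd.DataFrame, alpha: float, r0: float = 0.5) -> dict:
    """Effect of reward history on outgoing peak velocity.

    Two-stage estimate of the history coefficient (per-subject log-velocity
    OLS with the control terms, then a one-sample t across subjects), plus an
    AICc comparison of the random-intercept log-velocity model with and
    without the history term.
    """
    rec = _with_repeat_column(records)
    mask = ((rec.trial_type == "single") & ~rec.familiarization.astype(bool)
            & np.isfinite(rec.out_peak_vel) & (rec.out_peak_vel > 0))
    if "excluded" in rec.columns:
        mask &= ~rec.excluded.astype(bool)
    fit_rec = rec[mask]
    r_bar = compute_r_bar(rec, alpha, r0=r0)[mask.to_numpy()]
    y, X, groups, names = _rt_design(fit_rec, r_bar)
    y = np.log(fit_rec.out_peak_vel.to_numpy(float))
    i_hist = names.index("r_bar")

    betas = []
    for s in np.unique(groups):
        m = groups == s
        Xs, ys = X[m], y[m]
        keep = [j for j in range(Xs.shape[1]) if np.ptp(Xs[:, j]) > 0 or j == 0]
        b, *_ = np.linalg.lstsq(Xs[:, keep], ys, rcond=None)
        betas.append(b[keep.index(i_hist)] if i_hist in keep else np.nan)
    betas = np.asarray(betas, float)
    betas = betas[np.isfinite(betas)]
    t, p = stats.ttest_1samp(betas, 0.0)

    k_full = X.shape[1] + 2
    ll_full = random_intercept_loglik(y, X, groups)
    X_red = np.delete(X, i_hist, axis=1)
    ll_red = random_intercept_loglik(y, X_red, groups)
    n = y.size

    def _aicc(ll, k):
        return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    return dict(
        beta_history=float(betas.mean()),
        se=float(betas.std(ddof=1) / np.sqrt(betas.size)),
        t=float(t), p=float(p), n_subjects=int(betas.size),
        aicc_with_history=float(_aicc(ll_full, k_full)),
        aicc_without_history=float(_aicc(ll_red, k_full - 1)),
    )
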