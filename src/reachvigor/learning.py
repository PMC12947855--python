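"""Hierarchical delta-rule value learning fitted to two-alternative choices.

The model assumes each participant ``s`` learns a value ``V^T`` for every
target ``T`` from the single-target trials of a block via a Rescorla-Wagner
update that folds the target's effort cost into the prediction error
(a *value* prediction error, VPE)::

    V'^T = V^T + eta_s * (R + e_s^T - V^T),        VPE = R + e_s^T - V^T

where ``R`` is the binary reward, ``e_s^T = e_s`` for the two high-effort
targets (135/315 deg) and 0 otherwise, and ``eta_s = logistic(zeta_s)``.
An alternative model learns reward alone (``Rhat' = Rhat + eta (R - Rhat)``)
and adds the effort cost only at decision time (``V = Rhat + e^T``).

Choices at the end of each block follow a softmax on the frozen end-of-block
values::

    P(choice = A) = logistic(tau_s * (V_A - V_B))

Subject parameters are drawn from population normals, with the population
hierarchy::

    zeta_bar ~ N(0, 10);  e_bar ~ N(0, 5);  tau_bar ~ N(0, 5)
    sigma_zeta, sigma_e, sigma_tau ~ Gamma(shape=2, rate=0.01)
    zeta_s ~ N(zeta_bar, sigma_zeta);  e_s ~ N(e_bar, sigma_e);  tau_s ~ N(tau_bar, sigma_tau)

Fitting offers a joint MAP (L-BFGS on the unconstrained parameterization,
Laplace covariance for standard errors) and full-posterior ensemble MCMC
(emcee) initialized at the MAP.  Values reset to 0 at each block start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


EFFORT_MASK = np.array([0.0, 1.0, 0.0, 1.0])  # targets 1..4 -> high effort on 2, 4

MODEL_VPE = 0
MODEL_REWARD_ONLY = 1
_MODEL_CODES = {"vpe": MODEL_VPE, "alternative": MODEL_REWARD_ONLY}


# ---------------------------------------------------------------------------
# choice data container
# ---------------------------------------------------------------------------


@dataclass
class ChoiceData:
    """Stacked single-trial and choice-trial arrays for a cohort.

    Shapes: ``single_targets``/``single_rewards`` are (S, B, n_single) with
    0-based target indices; ``choice_a``/``choice_b``/``chose_a`` are
    (S, B, n_choice).  ``chose_a`` is 1 when the target in ``choice_a`` was
    selected (A/B labels are arbitrary per trial).
    """

    single_targets: np.ndarray
    single_rewards: np.ndarray
    choice_a: np.ndarray
    choice_b: np.ndarray
    chose_a: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.single_targets.shape[0]

    @property
    def n_choices(self) -> int:
        return int(self.chose_a.size)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ChoiceData":
        """Build from a trial-record table (columns: subject, block, trial,
        trial_type, target, alt_target, reward, choice, familiarization)."""
        rec = records[~records["familiarization"].astype(bool)]
        subjects = sorted(rec["subject"].unique())
        blocks = sorted(rec["block"].unique())
        st, sr, ca, cb, ya = [], [], [], [], []
        for s in subjects:
            st_b, sr_b, ca_b, cb_b, ya_b = [], [], [], [], []
            for b in blocks:
                g = rec[(rec.subject == s) & (rec.block == b)].sort_values("trial")
                sing = g[g.trial_type == "single"]
                cho = g[g.trial_type == "choice"]
                st_b.append(sing["target"].to_numpy(int) - 1)
                sr_b.append(sing["reward"].to_numpy(float))
                ca_b.append(cho["target"].to_numpy(int) - 1)
                cb_b.append(cho["alt_target"].to_numpy(int) - 1)
                ya_b.append((cho["choice"].to_numpy(int) == cho["target"].to_numpy(int)).astype(float))
            st.append(st_b), sr.append(sr_b), ca.append(ca_b), cb.append(cb_b), ya.append(ya_b)
        return cls(
            np.asarray(st, dtype=np.int64),
            np.asarray(sr, dtype=np.float64),
            np.asarray(ca, dtype=np.int64),
            np.asarray(cb, dtype=np.int64),
            np.asarray(ya, dtype=np.float64),
        )


# ---------------------------------------------------------------------------
# delta-rule updates (scalar API)
# ---------------------------------------------------------------------------


@dataclass
class ValueState:
    """Per-target learned values and reward estimates at one trial index."""

    V: np.ndarray = field(default_factory=lambda: np.zeros(4))
    R_hat: np.ndarray = field(default_factory=lambda: np.zeros(4))
    trial: int = 0


def effort_for_target(target: int, effort_cost: float) -> float:
    """Effort term e^T: the subject's effort cost on high-effort targets, else 0."""
    return effort_cost * EFFORT_MASK[target - 1]


def update_value(state: ValueState, target: int, reward: float, eta: float,
                 effort_cost: float) -> tuple[ValueState, float]:
    """One VPE-model update for the presented target; returns (state, vpe)."""
    if not 0.0 < eta < 1.0:
        raise ValueError("learning rate eta must lie in (0, 1)")
    V = state.V.copy()
    e_t = effort_for_target(target, effort_cost)
    vpe = reward + e_t - V[target - 1]
    V[target - 1] += eta * vpe
    return ValueState(V=V, R_hat=state.R_hat.copy(), trial=state.trial + 1), vpe


def update_value_alternative(state: ValueState, target: int, reward: float,
                             eta: float, effort_cost: float) -> tuple[ValueState, float]:
    """Reward-only update; decision values are ``R_hat + e^T`` on demand."""
    if not 0.0 < eta < 1.0:
        raise ValueError("learning rate eta must lie in (0, 1)")
    R_hat = state.R_hat.copy()
    rpe = reward - R_hat[target - 1]
    R_hat[target - 1] += eta * rpe
    new = ValueState(V=state.V.copy(), R_hat=R_hat, trial=state.trial + 1)
    return new, rpe


def decision_values(state: ValueState, effort_cost: float,
                    model: Literal["vpe", "alternative"] = "vpe") -> np.ndarray:
    """Values entering the softmax for each of the 4 targets."""
    if model == "vpe":
        return state.V.copy()
    return state.R_hat + effort_cost * EFFORT_MASK


# ---------------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cohort_loglik(zeta, e, tau, st, sr, ca, cb, ya, model):  # pragma: no cover
    S, B, n_single = st.shape
    n_choice = ca.shape[2]
    ll = 0.0
    for s in range(S):
        eta = 1.0 / (1.0 + np.exp(-zeta[s]))
        for b in range(B):
            V = np.zeros(4)
            for i in range(n_single):
                t = st[s, b, i]
                if model == 0:
                    eff = e[s] if (t == 1 or t == 3) else 0.0
                    V[t] += eta * (sr[s, b, i] + eff - V[t])
                else:
                    V[t] += eta * (sr[s, b, i] - V[t])
            if model == 1:
                V = V.copy()
                V[1] += e[s]
                V[3] += e[s]
            for j in range(n_choice):
                d = tau[s] * (V[ca[s, b, j]] - V[cb[s, b, j]])
                if ya[s, b, j] > 0.5:
                    ll += -np.log1p(np.exp(-d)) if d > -30.0 else d
                else:
                    ll += -np.log1p(np.exp(d)) if d < 30.0 else -d
    return ll


def cohort_loglik(zeta: np.ndarray, e: np.ndarray, tau: np.ndarray,
                  data: ChoiceData, model: str = "vpe") -> float:
    """Summed Bernoulli choice log-likelihood for all subjects."""
    out = _cohort_loglik(
        np.asarray(zeta, float), np.asarray(e, float), np.asarray(tau, float),
        data.single_targets, data.single_rewards,
        data.choice_a, data.choice_b, data.chose_a, _MODEL_CODES[model],
    )
    if not np.isfinite(out):
        raise FloatingPointError("non-finite choice log-likelihood")
    return float(out)


def choice_loglik(value_diffs: Sequence[float], choices_a: Sequence[int],
                  tau: float) -> float:
    """Softmax Bernoulli log-likelihood for explicit value differences.

    ``value_diffs[i]`` is V_A - V_B on choice i; ``choices_a[i]`` is 1 when
    A was chosen.
    """
    d = tau * np.asarray(value_diffs, float)
    y = np.asarray(choices_a, float)
    return float(np.sum(y * -np.logaddexp(0.0, -d) + (1 - y) * -np.logaddexp(0.0, d)))


def choice_loglik_grad(zeta: float, e: float, tau: float, st: np.ndarray,
                       sr: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                       ya: np.ndarray, model: str = "vpe") -> np.ndarray:
    """Analytic gradient of one subject's choice log-likelihood wrt (zeta, e, tau).

    Propagates dV/deta and dV/de through the delta-rule recursion; used to
    validate the likelihood implementation against finite differences.
    """
    mcode = _MODEL_CODES[model]
    eta = special.expit(zeta)
    deta_dzeta = eta * (1 - eta)
    g = np.zeros(3)
    B, n_single = st.shape
    for b in range(B):
        V = np.zeros(4)
        dV_deta = np.zeros(4)
        dV_de = np.zeros(4)
        for i in range(n_single):
            t = st[b, i]
            eff = e * EFFORT_MASK[t] if mcode == MODEL_VPE else 0.0
            pe = sr[b, i] + eff - V[t]
            dV_deta[t] = dV_deta[t] * (1 - eta) + pe
            dV_de[t] = dV_de[t] * (1 - eta) + eta * (EFFORT_MASK[t] if mcode == MODEL_VPE else 0.0)
            V[t] += eta * pe
        if mcode == MODEL_REWARD_ONLY:
            V = V + e * EFFORT_MASK
            dV_de = dV_de + EFFORT_MASK
        for j in range(ca.shape[1]):
            a, bb = ca[b, j], cb[b, j]
            d = tau * (V[a] - V[bb])
            resid = ya[b, j] - special.expit(d)  # d loglik / dd * (1/tau)... see below
            # d ll / dd = y - sigmoid(d)
            g[0] += resid * tau * (dV_deta[a] - dV_deta[bb]) * deta_dzeta
            g[1] += resid * tau * (dV_de[a] - dV_de[bb])
            g[2] += resid * (V[a] - V[bb])
    return g


# ---------------------------------------------------------------------------
# priors and posterior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchicalPriors:
    """Population-level priors (normal SDs; Gamma shape/rate on the group SDs)."""

    zeta_bar_sd: float = 10.0
    e_bar_sd: float = 5.0
    tau_bar_sd: float = 5.0
    sigma_shape: float = 2.0
    sigma_rate: float = 0.01


def _unpack(params: np.ndarray, S: int):
    """Non-centered parameterization: subject values are derived as
    ``theta_s = theta_bar + sigma * z_s`` with standard-normal offsets ``z``.

    This removes the funnel coupling between the group SDs and the subject
    block that cripples both optimizers and ensemble samplers on the
    centered form.
    """
    zeta_bar, e_bar, tau_bar = params[0], params[1], params[2]
    log_sig = params[3:6]
    sig = np.exp(np.clip(log_sig, -12, 12))
    z_zeta = params[6 : 6 + S]
    z_e = params[6 + S : 6 + 2 * S]
    z_tau = params[6 + 2 * S : 6 + 3 * S]
    zeta = zeta_bar + sig[0] * z_zeta
    e = e_bar + sig[1] * z_e
    tau = tau_bar + sig[2] * z_tau
    return zeta_bar, e_bar, tau_bar, log_sig, zeta, e, tau


def log_posterior(params: np.ndarray, data: ChoiceData, priors: HierarchicalPriors,
                  model: str = "vpe") -> float:
    """Unnormalized log posterior on the unconstrained parameterization.

    Group SDs live on the log scale; the Jacobian log sigma is included so the
    density is that of the stated Gamma(shape, rate) prior on sigma itself.
    Subject offsets are standard normal (non-centered form).
    """
    S = data.n_subjects
    log_sig_raw = params[3:6]
    if np.any(np.abs(log_sig_raw) > 12):
        return -np.inf
    zeta_bar, e_bar, tau_bar, log_sig, zeta, e, tau = _unpack(params, S)
    sig = np.exp(log_sig)
    _L2PI = 0.9189385332046727  # 0.5*log(2*pi)

    def _nlp(x, mu, sd):  # sum of normal logpdfs
        z = (np.asarray(x) - mu) / sd
        return float(np.sum(-0.5 * z * z - np.log(sd) - _L2PI))

    lp = 0.0
    lp += _nlp(zeta_bar, 0.0, priors.zeta_bar_sd)
    lp += _nlp(e_bar, 0.0, priors.e_bar_sd)
    lp += _nlp(tau_bar, 0.0, priors.tau_bar_sd)
    # Gamma(shape, rate) on sigma, plus log-Jacobian for the log-sigma parameterization
    lp += np.sum((priors.sigma_shape - 1) * np.log(sig) - priors.sigma_rate * sig
                 + priors.sigma_shape * np.log(priors.sigma_rate)
                 - special.gammaln(priors.sigma_shape) + log_sig)
    # standard-normal offsets (non-centered form)
    z = params[6:]
    lp += float(np.sum(-0.5 * z * z - _L2PI))
    if not np.isfinite(lp):
        return -np.inf
    ll = _cohort_loglik(zeta, e, tau, data.single_targets, data.single_rewards,
                        data.choice_a, data.choice_b, data.chose_a,
                        _MODEL_CODES[model])
    return float(lp + ll)


# ---------------------------------------------------------------------------
# fit result + fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Hierarchical fit output: point estimates, uncertainty, fit quality."""

    model: str
    method: str
    eta_pop_mean: float
    eta_pop_sd: float
    e_pop_mean: float
    e_pop_sd: float
    tau_pop_mean: float
    tau_pop_sd: float
    subject_params: pd.DataFrame
    loglik: float
    aicc: float
    accuracy: float
    n_choices: int
    n_params: int
    map_params: np.ndarray
    draws: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "eta_pop_mean": self.eta_pop_mean,
            "eta_pop_sd": self.eta_pop_sd,
            "e_pop_mean": self.e_pop_mean,
            "e_pop_sd": self.e_pop_sd,
            "tau_pop_mean": self.tau_pop_mean,
            "tau_pop_sd": self.tau_pop_sd,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "accuracy": self.accuracy,
            "n_choices": self.n_choices,
            "n_params": self.n_params,
            "diagnostics": {k: float(v) if np.isscalar(v) else v
                            for k, v in self.diagnostics.items()},
        }


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _map_estimate(data: ChoiceData, priors: HierarchicalPriors, model: str,
                  seed: int, n_restarts: int = 3):
    S = data.n_subjects
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        x0 = np.zeros(6 + 3 * S)
        x0[0] = rng.normal(-1.0, 0.5)      # zeta_bar
        x0[1] = rng.normal(0.0, 0.3)       # e_bar
        x0[2] = rng.normal(2.0, 1.0)       # tau_bar
        x0[3:6] = np.log(0.5)
        x0[6:] = rng.normal(0, 0.1, 3 * S)  # standard-normal subject offsets
        res = optimize.minimize(
            lambda p: -log_posterior(p, data, priors, model), x0,
            method="L-BFGS-B", options=dict(maxiter=2000, maxfun=200000),
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _laplace_hyper_sd(map_params: np.ndarray, data: ChoiceData,
                      priors: HierarchicalPriors, model: str) -> np.ndarray:
    """Posterior SDs of the first 6 (hyper) parameters via a Laplace step."""
    def f(p):
        return -log_posterior(p, data, priors, model)

    n = map_params.size
    h = 1e-4 * np.maximum(1.0, np.abs(map_params))
    H = np.zeros((n, n))
    f0 = f(map_params)
    fp = np.zeros(n)
    for i in range(n):
        xp = map_params.copy(); xp[i] += h[i]
        fp[i] = f(xp)
    for i in range(n):
        for j in range(i, n):
            xij = map_params.copy(); xij[i] += h[i]; xij[j] += h[j]
            H[i, j] = H[j, i] = (f(xij) - fp[i] - fp[j] + f0) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        sd = np.full(n, np.nan)
    return sd


def _fit_summary(model: str, method: str, data: ChoiceData, zeta_hat, e_hat,
                 tau_hat, hyper_summary: dict, map_params, draws=None,
                 diagnostics=None) -> FitResult:
    S = data.n_subjects
    ll = cohort_loglik(zeta_hat, e_hat, tau_hat, data, model)
    k = 3 * S + 6
    n = data.n_choices
    probs = predict_choice_probs(zeta_hat, e_hat, tau_hat, data, model)
    acc = float(np.mean((probs > 0.5) == (data.chose_a.ravel() > 0.5)))
    subj = pd.DataFrame(dict(
        subject=np.arange(S), zeta=zeta_hat, eta=special.expit(zeta_hat),
        e=e_hat, tau=tau_hat,
    ))
    return FitResult(
        model=model, method=method,
        subject_params=subj, loglik=ll, aicc=aicc(ll, k, n), accuracy=acc,
        n_choices=n, n_params=k, map_params=np.asarray(map_params),
        draws=draws, diagnostics=diagnostics or {}, **hyper_summary,
    )


def _subject_loglik(s: int, zeta: float, e: float, tau: float,
                    data: ChoiceData, model_code: int) -> float:
    return _cohort_loglik(
        np.array([zeta]), np.array([e]), np.array([tau]),
        data.single_targets[s:s + 1], data.single_rewards[s:s + 1],
        data.choice_a[s:s + 1], data.choice_b[s:s + 1], data.chose_a[s:s + 1],
        model_code)


def _slice_sample_sigma(devs: np.ndarray, sigma: float, shape: float,
                        rate: float, rng: np.random.Generator) -> float:
    """Slice sample a group SD given centered deviations.

    Target (in log sigma, Jacobian included): shape*log(s) - rate*s
    - S*log(s) - sum(d^2)/(2 s^2).
    """
    S = devs.size
    ss = float(np.sum(devs ** 2))

    def logf(ls: float) -> float:
        s = np.exp(ls)
        return shape * ls - rate * s - S * ls - ss / (2.0 * s * s)

    ls0 = np.log(sigma)
    y = logf(ls0) + np.log(rng.random())
    w = 0.5
    lo = ls0 - w * rng.random()
    hi = lo + w
    for _ in range(50):
        if logf(lo) < y:
            break
        lo -= w
    for _ in range(50):
        if logf(hi) < y:
            break
        hi += w
    for _ in range(100):
        ls1 = rng.uniform(lo, hi)
        if logf(ls1) >= y:
            return float(np.exp(ls1))
        if ls1 < ls0:
            lo = ls1
        else:
            hi = ls1
    return sigma


def _gibbs_sample(data: ChoiceData, priors: HierarchicalPriors, model: str,
                  seed: int, n_iter: int, n_burn: int, thin: int,
                  init: np.ndarray) -> dict:
    """Metropolis-within-Gibbs: per-subject 3-dim random-walk Metropolis,
    exact Gibbs for the population means, slice updates for the group SDs.

    Proposal scales adapt toward ~30% acceptance during burn-in only.
    """
    S = data.n_subjects
    mcode = _MODEL_CODES[model]
    rng = np.random.default_rng(seed)
    zeta_bar, e_bar, tau_bar, log_sig, zeta, e, tau = _unpack(init, S)
    zeta, e, tau = zeta.copy(), e.copy(), tau.copy()
    sig = np.exp(np.asarray(log_sig, float)).copy()
    mu = np.array([zeta_bar, e_bar, tau_bar])
    mu0_sd = np.array([priors.zeta_bar_sd, priors.e_bar_sd, priors.tau_bar_sd])
    ll = np.array([_subject_loglik(s, zeta[s], e[s], tau[s], data, mcode)
                   for s in range(S)])
    step = np.full(S, 0.15)
    acc = np.zeros(S)
    kept_hyper, kept_subject = [], []
    for it in range(n_iter):
        for s in range(S):
            prop = np.array([zeta[s], e[s], tau[s]]) + step[s] * rng.standard_normal(3)
            ll_new = _subject_loglik(s, prop[0], prop[1], prop[2], data, mcode)
            cur = np.array([zeta[s], e[s], tau[s]])
            lp_new = float(np.sum(-0.5 * ((prop - mu) / sig) ** 2))
            lp_old = float(np.sum(-0.5 * ((cur - mu) / sig) ** 2))
            if np.log(rng.random()) < (ll_new + lp_new) - (ll[s] + lp_old):
                zeta[s], e[s], tau[s] = prop
                ll[s] = ll_new
                acc[s] += 1
        if it < n_burn and (it + 1) % 50 == 0:  # adapt during burn-in only
            rate = acc / 50.0
            step *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            acc[:] = 0.0
        # population means: normal-normal conjugate updates
        for j, vals in enumerate((zeta, e, tau)):
            prec = 1.0 / mu0_sd[j] ** 2 + S / sig[j] ** 2
            mean = (np.sum(vals) / sig[j] ** 2) / prec
            mu[j] = mean + rng.standard_normal() / np.sqrt(prec)
        # group SDs: slice sampling
        for j, vals in enumerate((zeta, e, tau)):
            sig[j] = _slice_sample_sigma(vals - mu[j], sig[j],
                                         priors.sigma_shape, priors.sigma_rate, rng)
        if it >= n_burn and (it - n_burn) % thin == 0:
            kept_hyper.append([mu[0], mu[1], mu[2], sig[0], sig[1], sig[2]])
            kept_subject.append(np.concatenate([zeta, e, tau]))
    return dict(hyper=np.asarray(kept_hyper), subject=np.asarray(kept_subject),
                accept_rate=float(np.mean(np.minimum(acc / max(n_iter - n_burn, 1), 1.0))))


def fit_hierarchical(
    data: ChoiceData | pd.DataFrame,
    priors: HierarchicalPriors | None = None,
    model: Literal["vpe", "alternative"] = "vpe",
    method: Literal["map", "mcmc", "gibbs"] = "mcmc",
    seed: int = 0,
    n_walkers: int = 160,
    n_steps: int = 2500,
    n_burn: int = 1250,
    map_restarts: int = 3,
) -> FitResult:
    """Fit the hierarchical choice model.

    ``method="map"`` returns the joint posterior mode with Laplace standard
    errors (fast point estimate).  ``method="mcmc"`` (default) runs an
    affine-invariant ensemble sampler (emcee) on the non-centered posterior,
    initialized in a small ball around the MAP.  ``method="gibbs"`` runs
    Metropolis-within-Gibbs (per-subject Metropolis blocks, conjugate draws
    for the population means, slice updates for the group SDs) on the
    centered form; it mixes more slowly along the learning-rate /
    temperature ridge and is kept as a cross-check.
    Population summaries are posterior means/SDs over retained draws; the
    population learning rate is summarized on the eta scale through the
    logistic link.
    """
    if isinstance(data, pd.DataFrame):
        data = ChoiceData.from_records(data)
    if data.n_subjects < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    priors = priors or HierarchicalPriors()
    S = data.n_subjects
    res = _map_estimate(data, priors, model, seed, n_restarts=map_restarts)
    map_params = res.x
    zeta_bar, e_bar, tau_bar, log_sig, zeta, e, tau = _unpack(map_params, S)

    if method == "map":
        sd = _laplace_hyper_sd(map_params, data, priors, model)
        eta_sd = sd[0] * special.expit(zeta_bar) * (1 - special.expit(zeta_bar))
        hyper = dict(
            eta_pop_mean=float(special.expit(zeta_bar)), eta_pop_sd=float(eta_sd),
            e_pop_mean=float(e_bar), e_pop_sd=float(sd[1]),
            tau_pop_mean=float(tau_bar), tau_pop_sd=float(sd[2]),
        )
        return _fit_summary(model, "map", data, zeta, e, tau, hyper, map_params,
                            diagnostics=dict(map_neg_logpost=float(res.fun),
                                             converged=float(res.success)))

    if method == "gibbs":
        out = _gibbs_sample(data, priors, model, seed + 3, n_iter=n_steps,
                            n_burn=n_burn, thin=2, init=map_params)
        hyp = out["hyper"]  # columns: zeta_bar, e_bar, tau_bar, sigmas
        subj = out["subject"]
        eta_bar_draws = special.expit(hyp[:, 0])
        half = len(eta_bar_draws) // 2
        diagnostics = dict(
            accept_rate=out["accept_rate"],
            split_delta_eta=float(abs(eta_bar_draws[:half].mean()
                                      - eta_bar_draws[half:].mean())),
            n_draws=float(hyp.shape[0]),
        )
        hyper = dict(
            eta_pop_mean=float(eta_bar_draws.mean()), eta_pop_sd=float(eta_bar_draws.std()),
            e_pop_mean=float(hyp[:, 1].mean()), e_pop_sd=float(hyp[:, 1].std()),
            tau_pop_mean=float(hyp[:, 2].mean()), tau_pop_sd=float(hyp[:, 2].std()),
        )
        zeta_pm = subj[:, :S].mean(axis=0)
        e_pm = subj[:, S:2 * S].mean(axis=0)
        tau_pm = subj[:, 2 * S:].mean(axis=0)
        draws = pd.DataFrame(dict(
            zeta_bar=hyp[:, 0], eta_bar=eta_bar_draws, e_bar=hyp[:, 1],
            tau_bar=hyp[:, 2], sigma_zeta=hyp[:, 3], sigma_e=hyp[:, 4],
            sigma_tau=hyp[:, 5],
        ))
        return _fit_summary(model, "gibbs", data, zeta_pm, e_pm, tau_pm, hyper,
                            map_params, draws=draws, diagnostics=diagnostics)

    import emcee

    ndim = map_params.size
    n_walkers = max(n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(seed + 1)
    p0 = map_params + 0.02 * rng.standard_normal((n_walkers, ndim)) \
        * np.maximum(0.05, np.abs(map_params))
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_posterior, args=(data, priors, model))
    start = emcee.State(p0, random_state=np.random.RandomState(seed + 2).get_state())
    sampler.run_mcmc(start, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, thin=4)  # (n_kept, walkers, ndim)
    flat = chain.reshape(-1, ndim)
    eta_bar_draws = special.expit(flat[:, 0])
    half = flat.shape[0] // 2
    diagnostics = dict(
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        split_delta_eta=float(abs(eta_bar_draws[:half].mean() - eta_bar_draws[half:].mean())),
        n_draws=float(flat.shape[0]),
    )
    hyper = dict(
        eta_pop_mean=float(eta_bar_draws.mean()), eta_pop_sd=float(eta_bar_draws.std()),
        e_pop_mean=float(flat[:, 1].mean()), e_pop_sd=float(flat[:, 1].std()),
        tau_pop_mean=float(flat[:, 2].mean()), tau_pop_sd=float(flat[:, 2].std()),
    )
    sig_draws = np.exp(flat[:, 3:6])
    zeta_pm = (flat[:, [0]] + sig_draws[:, [0]] * flat[:, 6:6 + S]).mean(axis=0)
    e_pm = (flat[:, [1]] + sig_draws[:, [1]] * flat[:, 6 + S:6 + 2 * S]).mean(axis=0)
    tau_pm = (flat[:, [2]] + sig_draws[:, [2]] * flat[:, 6 + 2 * S:]).mean(axis=0)
    draws = pd.DataFrame(dict(
        zeta_bar=flat[:, 0], eta_bar=eta_bar_draws, e_bar=flat[:, 1],
        tau_bar=flat[:, 2], sigma_zeta=np.exp(flat[:, 3]),
        sigma_e=np.exp(flat[:, 4]), sigma_tau=np.exp(flat[:, 5]),
    ))
    return _fit_summary(model, "mcmc", data, zeta_pm, e_pm, tau_pm, hyper,
                        map_params, draws=draws, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# prediction + model comparison
# ---------------------------------------------------------------------------


def predict_choice_probs(zeta, e, tau, data: ChoiceData, model: str = "vpe") -> np.ndarray:
    """Per-choice P(selected the A-labeled target) at the given parameters."""
    S, B, n_single = data.single_targets.shape
    probs = np.empty((S, B, data.choice_a.shape[2]))
    for s in range(S):
        eta = special.expit(zeta[s])
        for b in range(B):
            V = np.zeros(4)
            for i in range(n_single):
                t = data.single_targets[s, b, i]
                if _MODEL_CODES[model] == MODEL_VPE:
                    eff = e[s] * EFFORT_MASK[t]
                    V[t] += eta * (data.single_rewards[s, b, i] + eff - V[t])
                else:
                    V[t] += eta * (data.single_rewards[s, b, i] - V[t])
            if _MODEL_CODES[model] == MODEL_REWARD_ONLY:
                V = V + e[s] * EFFORT_MASK
            d = tau[s] * (V[data.choice_a[s, b]] - V[data.choice_b[s, b]])
            probs[s, b] = special.expit(d)
    return probs.ravel()


def compare_models(fit_vpe: FitResult, fit_alt: FitResult, data: ChoiceData,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """AICc, aggregate accuracy, ROC AUC and a paired bootstrap AUC test.

    The bootstrap resamples choices with replacement, recomputes each model's
    AUC for predicting the observed choice and forms D = mean(dAUC)/sd(dAUC)
    with a two-sided normal p-value.
    """
    from sklearn.metrics import roc_auc_score

    y = data.chose_a.ravel()

    def probs_of(fit: FitResult) -> np.ndarray:
        sp = fit.subject_params
        return predict_choice_probs(sp.zeta.to_numpy(), sp.e.to_numpy(),
                                    sp.tau.to_numpy(), data, fit.model)

    p1, p2 = probs_of(fit_vpe), probs_of(fit_alt)
    auc1, auc2 = roc_auc_score(y, p1), roc_auc_score(y, p2)
    rng = np.random.default_rng(seed)
    n = y.size
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].min() == y[idx].max():  # degenerate resample
            diffs[b] = 0.0
            continue
        diffs[b] = roc_auc_score(y[idx], p1[idx]) - roc_auc_score(y[idx], p2[idx])
    sd = diffs.std(ddof=1)
    D = float(diffs.mean() / sd) if sd > 0 else 0.0
    p_value = float(2 * stats.norm.sf(abs(D)))
    return dict(
        aicc_vpe=fit_vpe.aicc, aicc_alternative=fit_alt.aicc,
        accuracy_vpe=fit_vpe.accuracy, accuracy_alternative=fit_alt.accuracy,
        auc_vpe=float(auc1), auc_alternative=float(auc2),
        auc_difference=float(auc1 - auc2), D=D, p_value=p_value, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# trajectories + kinematic correlates
# ---------------------------------------------------------------------------


def attach_value_trajectories(records: pd.DataFrame, agents: pd.DataFrame,
                              model: str = "vpe") -> pd.DataFrame:
    """Add per-trial learned value ``V`` and ``vpe`` columns to a record table.

    ``agents`` needs columns subject, eta, e.  Values reset at block starts;
    choice and familiarization trials carry the pre-trial value and NaN VPE.
    """
    out = records.copy()
    out["value"] = np.nan
    out["vpe"] = np.nan
    for (s, b), idx in out.groupby(["subject", "block"]).groups.items():
        row = agents[agents.subject == s].iloc[0]
        state = ValueState()
        g = out.loc[idx].sort_values("trial")
        for i, tr in g.iterrows():
            t = int(tr.target)
            out.at[i, "value"] = decision_values(state, row.e, model)[t - 1]
            if tr.trial_type == "single" and not tr.familiarization:
                if model == "vpe":
                    state, pe = update_value(state, t, tr.reward, row.eta, row.e)
                else:
                    state, pe = update_value_alternative(state, t, tr.reward, row.eta, row.e)
                out.at[i, "vpe"] = pe
    return out


def value_update_correlates(records: pd.DataFrame, min_pairs: int = 3) -> dict:
    """Correlate the VPE on a trial with the velocity change at the next
    repetition of the same target, plus an effort-matched control.

    The main analysis pairs consecutive cued occurrences of the same target
    within a block: x = VPE at occurrence k, y = out_peak_vel(k+1) -
    out_peak_vel(k).  The control pairs each trial with the next trial toward
    a different target of the same effort class, where no target-specific
    value carryover exists.
    """
    need = {"vpe", "out_peak_vel"}
    if not need.issubset(records.columns):
        raise ValueError(f"records must contain columns {need}")
    rec = records[(records.trial_type == "single") & ~records["familiarization"].astype(bool)]
    if "excluded" in rec.columns:
        rec = rec[~rec["excluded"].astype(bool)]

    xs, ys, xc, yc = [], [], [], []
    for (_, _), g in rec.groupby(["subject", "block"]):
        g = g.sort_values("trial")
        tgt = g.target.to_numpy(int)
        vpe = g.vpe.to_numpy(float)
        pv = g.out_peak_vel.to_numpy(float)
        effort = EFFORT_MASK[tgt - 1]
        last_seen: dict[int, int] = {}
        for i in range(len(g)):
            if tgt[i] in last_seen:
                k = last_seen[tgt[i]]
                xs.append(vpe[k]); ys.append(pv[i] - pv[k])
            last_seen[tgt[i]] = i
        # control: next different-direction, same-effort-class trial
        for i in range(len(g) - 1):
            for j in range(i + 1, len(g)):
                if tgt[j] != tgt[i] and effort[j] == effort[i]:
                    xc.append(vpe[i]); yc.append(pv[j] - pv[i])
                    break
                if tgt[j] == tgt[i]:
                    break
    def _finite(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        return x[ok], y[ok]

    xs, ys = _finite(xs, ys)
    if len(xs) < min_pairs:
        raise ValueError("insufficient same-target repetition pairs")
    r, p = stats.pearsonr(xs, ys)
    out = dict(r=float(r), p=float(p), n=len(xs))
    xc, yc = _finite(xc, yc)
    if len(xc) >= min_pairs:
        rc, pc = stats.pearsonr(xc, yc)
        out.update(control_r=float(rc), control_p=float(pc), control_n=len(xc))
    return out
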