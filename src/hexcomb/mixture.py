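"""Two-component binomial mixture with a covariate-dependent mixing weight.

For group ``i`` with outcome ``y_i`` (arrivals, 0..8) and covariate row
``x_i`` (including a constant), the model is

    f(y_i | x_i) = alpha_i * B(y_i; 8, pi1) + (1 - alpha_i) * B(y_i; 8, pi2),
    alpha_i = logistic(x_i' beta),

where ``B`` is the binomial pmf with eight trials.  The logit-linked weight
multiplies the *low*-success component ``pi1 < pi2``, so a positive
coefficient means a lower expected number of arrivals.  Estimation is by
maximum likelihood (multi-start quasi-Newton over ``(beta, logit pi1,
logit pi2)``, with an EM-based start for the intercept-only weight); z-values
come from the inverse observed information (central-difference Hessian);
model selection uses AIC = 2(-l) + 2p and BIC = 2(-l) + p ln N.

Near-separated designs drive some coefficients toward +/- infinity; those are
capped at a configurable bound and flagged, and their z-values are marked
unreliable (they come with correspondingly huge standard errors).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit
from scipy.stats import binom

DEFAULT_TRIALS = 8


def _check_prob(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name}={v} outside [0, 1]")


def mixture_pmf(y, alpha: float, pi1: float, pi2: float, trials: int = DEFAULT_TRIALS):
    """``alpha * B(y; n, pi1) + (1 - alpha) * B(y; n, pi2)``; sums to one over y."""
    _check_prob("alpha", alpha)
    _check_prob("pi1", pi1)
    _check_prob("pi2", pi2)
    return alpha * binom.pmf(y, trials, pi1) + (1 - alpha) * binom.pmf(y, trials, pi2)


def mixture_mean(alpha: float, pi1: float, pi2: float, trials: int = DEFAULT_TRIALS) -> float:
    """Expected outcome ``n * [alpha pi1 + (1 - alpha) pi2]``."""
    return trials * (alpha * pi1 + (1 - alpha) * pi2)


def _binom_logpmf(y: np.ndarray, n: int, p: float) -> np.ndarray:
    p = min(max(p, 1e-14), 1 - 1e-14)
    return (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
            + y * math.log(p) + (n - y) * math.log1p(-p))


def neg_loglik(beta, pi1: float, pi2: float, y, X, trials: int = DEFAULT_TRIALS) -> float:
    """Negative log-likelihood of the mixture at ``(beta, pi1, pi2)``.

    ``X`` must carry the constant column; ``alpha_i = logistic(X_i beta)``
    weights the ``pi1`` component.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates")
    eta = X @ beta
    l1 = _binom_logpmf(y, trials, pi1)
    l2 = _binom_logpmf(y, trials, pi2)
    # log[ a e^{l1} + (1-a) e^{l2} ] with a = expit(eta), done stably:
    # = -log(1+e^{-eta}) + log[ e^{l1} + e^{-eta} e^{l2} ]
    ll = -np.logaddexp(0.0, -eta) + np.logaddexp(l1, l2 - eta)
    return float(-np.sum(ll))


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of the two-component mixture."""

    pi1: float
    pi2: float
    beta: np.ndarray
    beta_names: list
    loglik: float
    n_groups: int
    trials: int = DEFAULT_TRIALS
    se: np.ndarray | None = None
    z_values: np.ndarray | None = None
    converged: bool = True
    capped: np.ndarray | None = None      # per-beta |coefficient| at the cap
    degenerate: bool = False              # pi1 ~ pi2 (one-component-equivalent)
    z_reliable: bool = True
    n_starts: int = 0
    data_hash: str = ""

    @property
    def neg_loglik(self) -> float:
        return -self.loglik

    @property
    def n_params(self) -> int:
        return 2 + len(self.beta)

    @property
    def aic(self) -> float:
        return 2 * self.neg_loglik + 2 * self.n_params

    @property
    def bic(self) -> float:
        return 2 * self.neg_loglik + self.n_params * math.log(self.n_groups)

    def alpha(self, X=None) -> np.ndarray:
        """Mixing weight of the low-success component, per group (or at the
        intercept when ``X`` is omitted and the model is intercept-only)."""
        if X is None:
            if len(self.beta) != 1:
                raise ValueError("pass X for a model with covariates")
            return expit(np.atleast_1d(self.beta[0]))
        return expit(np.asarray(X, float) @ self.beta)

    def implied_mean(self) -> float:
        """Fitted marginal mean of an intercept-only model."""
        a = float(self.alpha()[0])
        return mixture_mean(a, self.pi1, self.pi2, self.trials)


def information_criteria(neg_ll: float, n_params: int, n_groups: int) -> tuple:
    """``(AIC, BIC)`` from a retained minimum of the negative log-likelihood."""
    aic = 2 * neg_ll + 2 * n_params
    bic = 2 * neg_ll + n_params * math.log(n_groups) if n_groups > 0 else float("nan")
    return aic, bic


def design_matrix(features: pd.DataFrame, covariates=()) -> tuple:
    """Intercept-plus-covariates design from a features table.

    ``"first_x_local"`` is synthesised as ``first * local`` when requested
    and absent; any other name must be a column of ``features``.
    Returns ``(X, names)``.
    """
    cols = [np.ones(len(features))]
    names = ["intercept"]
    for c in covariates:
        if c == "first_x_local" and c not in features.columns:
            v = features["first"].to_numpy(float) * features["local"].to_numpy(float)
        else:
            v = features[c].to_numpy(float)
        cols.append(v)
        names.append(c)
    return np.column_stack(cols), names


def _hash_data(y: np.ndarray, X: np.ndarray) -> str:
    hy = hashlib.md5(np.ascontiguousarray(y, dtype=np.int64).tobytes()).hexdigest()
    hx = hashlib.md5(np.ascontiguousarray(X, dtype=np.float64).tobytes()).hexdigest()
    return f"{hy}:{hx}"


# ---------------------------------------------------------------------------
# Vectorised EM for intercept-only mixtures (used for starts and for the
# parametric-bootstrap LRT, where hundreds of refits are needed).

def em_intercept_mixture(Y: np.ndarray, trials: int = DEFAULT_TRIALS,
                         max_iter: int = 500, tol: float = 1e-12) -> dict:
    """Intercept-only two-binomial-mixture MLE for each row of ``Y``.

    Runs EM from several starts per dataset and keeps the best; the label
    constraint ``pi1 < pi2`` is applied afterwards.  Returns arrays
    ``alpha``, ``pi1``, ``pi2``, ``loglik`` of length ``Y.shape[0]``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, N = Y.shape
    ybar = Y.mean(axis=1) / trials
    lo = np.minimum(np.quantile(Y, 0.25, axis=1) / trials, ybar * 0.5)
    hi = np.maximum(np.quantile(Y, 0.75, axis=1) / trials, ybar * 1.5)
    starts = [
        (np.full(B, 0.5), np.clip(lo, 1e-3, 1 - 1e-3), np.clip(hi, 1e-3, 1 - 1e-3)),
        (np.full(B, 0.5), np.full(B, 0.05), np.full(B, 0.6)),
        (np.full(B, 0.7), np.full(B, 0.02), np.full(B, 0.8)),
        # perturbed one-component start: keeps the attained likelihood at
        # least near the single-binomial optimum
        (np.full(B, 0.5), np.clip(ybar * 0.7, 1e-4, 1 - 1e-4),
         np.clip(ybar * 1.3 + 1e-3, 1e-4, 1 - 1e-4)),
    ]
    lgamma = (gammaln(trials + 1) - gammaln(Y + 1) - gammaln(trials - Y + 1))

    def loglik(a, p1, p2):
        p1 = np.clip(p1, 1e-12, 1 - 1e-12)[:, None]
        p2 = np.clip(p2, 1e-12, 1 - 1e-12)[:, None]
        f1 = lgamma + Y * np.log(p1) + (trials - Y) * np.log1p(-p1)
        f2 = lgamma + Y * np.log(p2) + (trials - Y) * np.log1p(-p2)
        m = np.logaddexp(np.log(np.clip(a, 1e-300, 1))[:, None] + f1,
                         np.log(np.clip(1 - a, 1e-300, 1))[:, None] + f2)
        return m.sum(axis=1), f1, f2

    best_ll = np.full(B, -np.inf)
    best = (np.full(B, 0.5), ybar.copy(), ybar.copy())
    for a, p1, p2 in starts:
        a, p1, p2 = a.copy(), p1.copy(), p2.copy()
        for _ in range(max_iter):
            ll, f1, f2 = loglik(a, p1, p2)
            la = np.log(np.clip(a, 1e-300, 1))[:, None]
            l1a = np.log(np.clip(1 - a, 1e-300, 1))[:, None]
            r = np.exp(la + f1 - np.logaddexp(la + f1, l1a + f2))
            a_new = r.mean(axis=1)
            s1 = r.sum(axis=1)
            s2 = N - s1
            p1_new = np.where(s1 > 1e-12, (r * Y).sum(axis=1) / (trials * np.maximum(s1, 1e-12)), p1)
            p2_new = np.where(s2 > 1e-12, ((1 - r) * Y).sum(axis=1) / (trials * np.maximum(s2, 1e-12)), p2)
            delta = max(np.abs(a_new - a).max(), np.abs(p1_new - p1).max(),
                        np.abs(p2_new - p2).max())
            a, p1, p2 = a_new, p1_new, p2_new
            if delta < tol:
                break
        ll, _, _ = loglik(a, p1, p2)
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best = (np.where(better, a, best[0]), np.where(better, p1, best[1]),
                np.where(better, p2, best[2]))
    a, p1, p2 = best
    swap = p1 > p2
    p1s = np.where(swap, p2, p1)
    p2s = np.where(swap, p1, p2)
    a = np.where(swap, 1 - a, a)
    # the single-binomial fit is nested: never report a worse likelihood
    ph = np.clip(ybar, 1e-12, 1 - 1e-12)[:, None]
    ll0 = (lgamma + Y * np.log(ph) + (trials - Y) * np.log1p(-ph)).sum(axis=1)
    worse = best_ll < ll0
    return {
        "alpha": np.where(worse, 0.5, a),
        "pi1": np.where(worse, ybar, p1s),
        "pi2": np.where(worse, ybar, p2s),
        "loglik": np.maximum(best_ll, ll0),
    }


def fit_single_binomial(y, trials: int = DEFAULT_TRIALS) -> tuple:
    """Closed-form MLE of one binomial: ``(pi_hat, loglik)``."""
    y = np.asarray(y, dtype=int)
    pi_hat = float(y.mean() / trials)
    p = min(max(pi_hat, 1e-12), 1 - 1e-12)
    ll = float(np.sum(_binom_logpmf(y, trials, p)))
    return pi_hat, ll


@dataclass(frozen=True)
class FitConfig:
    """Optimisation settings for :func:`fit_mixture`."""

    n_starts: int = 20
    seed: int = 0
    beta_cap: float = 50.0
    pi_logit_cap: float = 15.0
    hessian_step: float = 1e-5


def fit_mixture(features: pd.DataFrame, covariates=(),
                config: FitConfig | None = None,
                outcome: str = "arrivals",
                trials: int = DEFAULT_TRIALS) -> MixtureFit:
    """Maximum-likelihood fit of the mixture on a features table.

    Parameters
    ----------
    features : DataFrame
        Per-group table with the outcome column and any covariate columns.
    covariates : sequence of str
        Covariates of the mixing weight besides the intercept (e.g.
        ``("same", "direction")``); ``"first_x_local"`` is built on the fly.
    config : FitConfig
        Multi-start and capping settings; the seed makes the fit
        reproducible.
    """
    config = config or FitConfig()
    y = features[outcome].to_numpy(dtype=int)
    if len(y) < 3:
        raise ValueError("need at least 3 groups")
    if y.min() < 0 or y.max() > trials:
        raise ValueError(f"outcome must lie in 0..{trials}")
    X, names = design_matrix(features, covariates)
    k = X.shape[1]
    rng = np.random.default_rng(config.seed)

    def unpack(theta):
        return theta[:k], expit(theta[k]), expit(theta[k + 1])

    def objective(theta):
        b, p1, p2 = unpack(theta)
        return neg_loglik(b, p1, p2, y, X, trials)

    em = em_intercept_mixture(y[None, :], trials)
    a0 = float(np.clip(em["alpha"][0], 1e-6, 1 - 1e-6))
    p10 = float(np.clip(em["pi1"][0], 1e-6, 1 - 1e-6))
    p20 = float(np.clip(em["pi2"][0], 1e-6, 1 - 1e-6))
    starts = [np.concatenate([[logit(a0)], np.zeros(k - 1), [logit(p10), logit(p20)]])]
    while len(starts) < max(1, config.n_starts):
        p = np.sort(rng.uniform(0.02, 0.98, size=2))
        b = rng.normal(0.0, 1.5, size=k)
        starts.append(np.concatenate([b, logit(p)]))

    bounds = ([(-config.beta_cap, config.beta_cap)] * k
              + [(-config.pi_logit_cap, config.pi_logit_cap)] * 2)
    best = None
    for theta0 in starts:
        res = minimize(objective, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    beta, pi1, pi2 = unpack(best.x)
    beta = np.array(beta, dtype=float)
    if pi1 > pi2:
        pi1, pi2 = pi2, pi1
        beta = -beta

    capped = np.abs(beta) >= config.beta_cap - 1e-6
    degenerate = abs(pi2 - pi1) < 1e-4

    # Observed information from a central-difference Hessian in the natural
    # parameters (beta..., pi1, pi2); z-values reported for the betas.
    theta_nat = np.concatenate([beta, [pi1, pi2]])

    def nat_obj(th):
        return neg_loglik(th[:k], float(np.clip(th[k], 1e-10, 1 - 1e-10)),
                          float(np.clip(th[k + 1], 1e-10, 1 - 1e-10)), y, X, trials)

    m = k + 2
    H = np.empty((m, m))
    h = np.maximum(config.hessian_step, config.hessian_step * np.abs(theta_nat))
    f0 = nat_obj(theta_nat)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                val = (nat_obj(theta_nat + ei) - 2 * f0 + nat_obj(theta_nat - ei)) / h[i] ** 2
            else:
                val = (nat_obj(theta_nat + ei + ej) - nat_obj(theta_nat + ei - ej)
                       - nat_obj(theta_nat - ei + ej) + nat_obj(theta_nat - ei - ej)
                       ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    z_reliable = not (capped.any() or degenerate)
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.pinv(H)
        d = np.diag(cov)[:k]
        with np.errstate(invalid="ignore"):
            se = np.where(d > 0, np.sqrt(np.maximum(d, 0)), np.nan)
    except np.linalg.LinAlgError:
        z_reliable = False
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se

    return MixtureFit(
        pi1=float(pi1), pi2=float(pi2), beta=beta, beta_names=names,
        loglik=-float(best.fun), n_groups=len(y), trials=trials,
        se=se, z_values=z, converged=bool(best.success),
        capped=capped, degenerate=degenerate, z_reliable=z_reliable,
        n_starts=len(starts), data_hash=_hash_data(y, X),
    )


def compare_models(fits) -> pd.DataFrame:
    """Rank fitted model variants of the same data by AIC (BIC shown).

    Flags the variants that beat the intercept-only ("empty") model on both
    criteria.  Raises if the fits do not share the outcome data.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    yhashes = {f.data_hash.split(":")[0] for f in fits if f.data_hash}
    if len(yhashes) > 1:
        raise ValueError("fits are not on identical outcome data (hash mismatch)")
    empty = [f for f in fits if len(f.beta) == 1]
    ref = min(empty, key=lambda f: f.aic) if empty else None
    rows = []
    for f in fits:
        rows.append({
            "model": "+".join(f.beta_names[1:]) or "empty",
            "n_covariates": len(f.beta) - 1,
            "neg_loglik": f.neg_loglik,
            "p": f.n_params,
            "AIC": f.aic,
            "BIC": f.bic,
            "beats_empty_on_both": (
                ref is not None and f is not ref
                and f.aic < ref.aic and f.bic < ref.bic
            ),
        })
    out = pd.DataFrame(rows).sort_values(
        ["AIC", "p"], kind="stable").reset_index(drop=True)
    return out
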