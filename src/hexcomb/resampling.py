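"""Bootstrap and exact inference for the arrival data.

Three procedures: a two-stage (cluster) bootstrap of the overall arrival
rate that respects the grouping of players into games, a parametric
bootstrap likelihood-ratio test of one versus two binomial mixture
components, and an exact binomial tail test (used for the starting-rank
hypothesis).  Resampling p-values use the add-one convention
``p = (1 + #extreme) / (reps + 1)``, which avoids exact zeros from a finite
number of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .mixture import DEFAULT_TRIALS, em_intercept_mixture, fit_single_binomial


@dataclass
class BootstrapResult:
    """Observed statistic, replicate distribution, and add-one p-value."""

    statistic: str
    observed: float
    replicates: np.ndarray
    p_value: float
    reps: int
    seed: int
    null: str
    n_failures: int = 0


def two_stage_bootstrap(player_table, null_rate: float = 1.0 / 6.0,
                        reps: int = 1000, seed: int = 0) -> BootstrapResult:
    """Cluster bootstrap of the arrival rate against ``H0: rate <= null_rate``.

    ``player_table`` holds one row per group of per-player 0/1 arrival
    indicators (a 2-D array or DataFrame, e.g. 40 x 8).  Each replicate
    resamples groups with replacement, then players within each sampled
    group with replacement, and records the overall arrival rate; the
    one-sided p-value is the add-one fraction of replicates at or below
    ``null_rate``.
    """
    data = np.asarray(player_table, dtype=float)
    if data.ndim != 2:
        raise ValueError("player_table must be 2-D (groups x players)")
    if np.isnan(data).any():
        raise ValueError("ragged groups: every group needs the same player count")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < null_rate < 1.0:
        raise ValueError("null_rate must lie in (0, 1)")
    G, P = data.shape
    rng = np.random.default_rng(seed)
    g_idx = rng.integers(0, G, size=(reps, G))
    p_idx = rng.integers(0, P, size=(reps, G, P))
    draws = data[g_idx[..., None], p_idx]
    rates = draws.mean(axis=(1, 2))
    p = (1 + int(np.sum(rates <= null_rate))) / (reps + 1)
    return BootstrapResult(
        statistic="arrival_rate",
        observed=float(data.mean()),
        replicates=rates,
        p_value=float(p),
        reps=reps,
        seed=seed,
        null=f"rate <= {null_rate:.6g}",
    )


def mclachlan_lrt(arrivals, B: int = 200, seed: int = 0,
                  trials: int = DEFAULT_TRIALS) -> BootstrapResult:
    """Parametric-bootstrap LRT of one vs. two binomial mixture components.

    Fits a single binomial and a two-component intercept-only mixture to the
    per-group counts; the observed statistic is ``2 (l1 - l0) >= 0``.  ``B``
    datasets of the same size are simulated from the fitted null and both
    models refitted to each; the p-value is the add-one fraction of
    bootstrap statistics at or above the observed one.
    """
    y = np.asarray(arrivals, dtype=int)
    if B < 1:
        raise ValueError("B must be >= 1")
    if y.min() < 0 or y.max() > trials:
        raise ValueError(f"counts must lie in 0..{trials}")
    N = len(y)
    pi0, l0 = fit_single_binomial(y, trials)
    alt = em_intercept_mixture(y[None, :], trials)
    obs = max(0.0, 2.0 * (float(alt["loglik"][0]) - l0))

    rng = np.random.default_rng(seed)
    Yb = rng.binomial(trials, pi0, size=(B, N))
    l0b = np.array([fit_single_binomial(row, trials)[1] for row in Yb])
    altb = em_intercept_mixture(Yb, trials)
    lrt_b = np.maximum(0.0, 2.0 * (altb["loglik"] - l0b))
    ok = np.isfinite(lrt_b)
    p = (1 + int(np.sum(lrt_b[ok] >= obs))) / (int(ok.sum()) + 1)
    return BootstrapResult(
        statistic="mixture_lrt",
        observed=float(obs),
        replicates=lrt_b[ok],
        p_value=float(p),
        reps=int(ok.sum()),
        seed=seed,
        null=f"single Binomial({trials}, {pi0:.4f})",
        n_failures=int(B - ok.sum()),
    )


def exact_binomial_test(k: int, n: int, p0: float,
                        alternative: str = "greater") -> float:
    """Exact binomial tail probability by direct pmf summation.

    ``greater``/``less`` sum the corresponding tail including ``k``;
    ``two-sided`` sums all outcome probabilities not exceeding the
    probability of ``k`` (the minimum-likelihood convention).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    ks = np.arange(n + 1)
    pmf = binom.pmf(ks, n, p0)
    if alternative == "greater":
        return float(pmf[k:].sum())
    if alternative == "less":
        return float(pmf[:k + 1].sum())
    if alternative == "two-sided":
        return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")
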