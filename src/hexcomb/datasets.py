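"""Synthetic reference cohort matching the original study's printed summaries.

The deposited per-player spreadsheet of the original 40-group experiment is
not redistributable here, so this module ships a *synthetic reconstruction*.
The arrivals histogram below is the unique integer histogram over 40 groups
(searched exhaustively) satisfying every published summary of the outcome:
total arrivals 110 of 320 (34.37%), mean 2.75, sd 3.38, at least eight
zero-arrival groups (the games whose informed pair did not start toward
their goal all had zero arrivals), and an intercept-only two-binomial
mixture MLE of pi1 = 0.016, pi2 = 0.836 with intercept 0.405
(negative log-likelihood 62.43).

Covariate and control columns are synthetic assignments consistent with the
published marginals — a 20/20 local/global split, informed first mover in
11/40 games (4 of them global), first-step categories same 8 / direction 24 /
other 8, and an informed mean starting rank below 5.50 in 29/40 (72.5%) of
groups — but their joint distribution with the outcome beyond these
constraints is invented, so covariate-model coefficients fitted to this
table are illustrative only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: groups with 0..8 uninformed arrivals on the high-value depot
REFERENCE_HISTOGRAM = (21, 3, 0, 0, 2, 1, 3, 4, 6)

#: arrivals by first-step category of the informed pair (synthetic assignment;
#: the eight "other" games are all zero per the published account)
_SAME_ARRIVALS = [8, 8, 8, 8, 7, 7, 6, 0]
_DIRECTION_ARRIVALS = [8, 8, 7, 7, 6, 6, 5, 4, 4, 1, 1, 1] + [0] * 12
_OTHER_ARRIVALS = [0] * 8


def reference_arrivals() -> np.ndarray:
    """The 40 per-group arrival counts, in group order."""
    return np.array(_SAME_ARRIVALS + _DIRECTION_ARRIVALS + _OTHER_ARRIVALS, dtype=int)


def reference_player_table() -> np.ndarray:
    """Per-player 0/1 arrival indicators, one row of eight per group."""
    y = reference_arrivals()
    table = np.zeros((len(y), 8), dtype=int)
    for i, k in enumerate(y):
        table[i, :k] = 1
    return table


def reference_cohort() -> pd.DataFrame:
    """The synthetic 40-group features table (canonical schema).

    Deterministic; suitable as input to the mixture fits and the resampling
    tests wherever the original per-group data would be used.
    """
    y = reference_arrivals()
    n = len(y)
    same = np.array([1] * 8 + [0] * 32)
    direction = np.array([0] * 8 + [1] * 24 + [0] * 8)
    # 20/20 condition split, interleaved so both conditions span all
    # first-step categories
    local = np.array([i % 2 for i in range(n)])
    # informed first mover in 11 games, 4 of them under global perception
    first = np.zeros(n, dtype=int)
    first[np.where(local == 1)[0][:7]] = 1
    first[np.where(local == 0)[0][:4]] = 1
    # informed mean starting rank: below the middle rank 5.50 in 29 groups
    rng = np.random.default_rng(20140403)
    rank = np.empty(n)
    rank[:29] = np.round(rng.uniform(1.5, 5.0, size=29), 1)
    rank[29:] = np.round(rng.uniform(6.0, 9.5, size=11), 1)
    order = rng.permutation(n)
    rank = rank[order]
    # control movement variables: plausible synthetic values, tighter paths
    # and shorter latencies in the higher-arrival games
    path_sim = np.round(np.clip(rng.normal(2.5 - 0.2 * y, 0.6), 0.0, None), 2)
    path_len = np.round(np.clip(rng.normal(7.0, 1.0, size=n), 6.0, 15.0), 1)
    latency = np.round(np.clip(rng.normal(6.0 + 0.3 * rank, 1.5), 0.5, None), 2)
    return pd.DataFrame({
        "group_id": np.arange(1, n + 1),
        "arrivals": y,
        "local": local,
        "first": first,
        "same": same,
        "direction": direction,
        "informed_mean_start_rank": rank,
        "path_similarity": path_sim,
        "informed_mean_path_length": path_len,
        "informed_mean_latency": latency,
        "n_uninformed": 8,
        "tie_flag": False,
    })
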