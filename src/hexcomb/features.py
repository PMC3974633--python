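"""Per-group outcome and covariate coding from validated game logs.

The outcome is ``arrivals``: how many of the eight uninformed players end
the game on the informed pair's high-value depot.  The covariates describe
the informed minority's initial behaviour: whether the game's very first
move was theirs (``first``), and whether their first steps were the
identical shortest-route cell (``same``), the two distinct shortest-route
cells (``direction``), or anything else (the omitted baseline).  Control
movement variables (starting ranks, path similarity, path length, movement
latency) summarise their behaviour over the whole game.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .board import hex_distance, shortest_step_options
from .game import GameLog, INFORMED, replay_and_validate


def code_arrivals(log: GameLog) -> int:
    """Number of uninformed players ending on the high-value depot (0..8)."""
    pos = replay_and_validate(log)
    ee = log.board.ee_cell
    return sum(1 for p in log.uninformed_players() if pos[p] == ee)


def code_first(log: GameLog) -> tuple:
    """``(first, tie_flag)``: was the game's earliest move by an informed player?

    Ties at the earliest time are resolved by the replay tie-break (lowest
    player id) and flagged.
    """
    events = log.sorted_events()
    if not events:
        raise ValueError("cannot code first-mover on a log with no events")
    t0 = events[0].time
    tied = [e.player_id for e in events if e.time == t0]
    first = int(log.roles[events[0].player_id] == INFORMED)
    return first, len(tied) > 1


def _first_steps(log: GameLog) -> dict:
    steps = {}
    for ev in log.sorted_events():
        if ev.player_id not in steps:
            steps[ev.player_id] = ev.to_cell
    return steps


def code_initial_moves(log: GameLog) -> tuple:
    """``(category, flag)`` with category in ``{"same", "direction", "other"}``.

    Classified against the shortest-route first-step options from the start
    cell toward the high-value depot; a game in which an informed player
    never moved is ``"other"`` with the flag set.
    """
    informed = log.informed_players()
    if len(informed) != 2:
        raise ValueError("initial-move coding needs exactly two informed players")
    steps = _first_steps(log)
    if any(p not in steps for p in informed):
        return "other", True
    options = shortest_step_options(log.board.start_cell, log.board.ee_cell, log.board)
    a, b = (steps[p] for p in informed)
    if a in options and b in options:
        return ("same", False) if a == b else ("direction", False)
    return "other", False


def starting_ranks(log: GameLog) -> tuple:
    """``(ranks, informed_mean)``: rank of each player's first-move time.

    Rank 1 is the earliest; ties receive average ranks, and players who
    never moved share the worst average rank.  ``informed_mean`` averages
    the informed players' ranks (in [1.5, 9.5] for a ten-player game).
    """
    players = sorted(log.roles)
    first_time = {p: np.inf for p in players}
    for ev in log.sorted_events():
        if first_time[ev.player_id] is np.inf or ev.time < first_time[ev.player_id]:
            first_time[ev.player_id] = min(first_time[ev.player_id], ev.time)
    times = np.array([first_time[p] for p in players])
    ranks = dict(zip(players, rankdata(times, method="average")))
    informed = log.informed_players()
    informed_mean = float(np.mean([ranks[p] for p in informed])) if informed else np.nan
    return ranks, informed_mean


def _positions_by_move(log: GameLog, player: int) -> list:
    pos = [log.board.start_cell]
    for ev in log.sorted_events():
        if ev.player_id == player:
            pos.append(ev.to_cell)
    return pos


def path_metrics(log: GameLog) -> tuple:
    """``(path_similarity, mean_path_length, mean_latency)`` of the informed pair.

    Path similarity is the mean hex distance between the two informed
    players' positions at aligned move indices, the shorter path padded with
    its final position (0 = identical paths).  Path length is the mean
    number of moves they used; latency the mean of their first-move times.
    """
    informed = log.informed_players()
    if len(informed) != 2:
        raise ValueError("path metrics need exactly two informed players")
    pa, pb = (_positions_by_move(log, p) for p in informed)
    L = max(len(pa), len(pb))
    pa = pa + [pa[-1]] * (L - len(pa))
    pb = pb + [pb[-1]] * (L - len(pb))
    similarity = float(np.mean([hex_distance(a, b) for a, b in zip(pa, pb)]))
    mean_path_length = float(np.mean([len(_positions_by_move(log, p)) - 1 for p in informed]))
    firsts = []
    for p in informed:
        t = [ev.time for ev in log.sorted_events() if ev.player_id == p]
        firsts.append(t[0] if t else np.nan)
    mean_latency = float(np.nanmean(firsts)) if not all(np.isnan(firsts)) else np.nan
    return similarity, mean_path_length, mean_latency


FEATURE_COLUMNS = [
    "group_id", "arrivals", "local", "first", "same", "direction",
    "informed_mean_start_rank", "path_similarity", "informed_mean_path_length",
    "informed_mean_latency", "n_uninformed", "tie_flag",
]


def code_group(log: GameLog) -> dict:
    """All per-group features for one validated game log."""
    first, tie = code_first(log)
    category, cat_flag = code_initial_moves(log)
    _, informed_rank = starting_ranks(log)
    similarity, length, latency = path_metrics(log)
    return {
        "group_id": log.group_id,
        "arrivals": code_arrivals(log),
        "local": int(log.condition == "local"),
        "first": first,
        "same": int(category == "same"),
        "direction": int(category == "direction"),
        "informed_mean_start_rank": informed_rank,
        "path_similarity": similarity,
        "informed_mean_path_length": length,
        "informed_mean_latency": latency,
        "n_uninformed": len(log.uninformed_players()),
        "tie_flag": tie or cat_flag,
    }


def features_table(cohort) -> pd.DataFrame:
    """One feature row per group for a list of validated game logs."""
    rows = [code_group(log) for log in cohort]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if df["group_id"].duplicated().any():
        dupes = df.loc[df["group_id"].duplicated(), "group_id"].tolist()
        raise ValueError(f"duplicate group ids {dupes}")
    return df


def summary_statistics(features: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of outcome and covariates across groups."""
    cols = ["arrivals", "local", "first", "same", "direction"]
    rows = [
        {"variable": c,
         "mean": float(features[c].mean()),
         "sd": float(features[c].std(ddof=1))}
        for c in cols if c in features.columns
    ]
    return pd.DataFrame(rows)
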