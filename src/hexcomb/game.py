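"""Game-log data model, replay validation, payoffs, and log serialisation.

A game is played by ten avatars that all start on the centre cell and move
stepwise (at most 15 moves each, one neighbour cell per move, a 1.5 s lockout
between a player's consecutive moves).  The game ends as soon as every avatar
stands on a money depot, or when no moves remain.  Payoffs multiply with
co-occupancy of the final depot, which is the cohesion incentive of the
paradigm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .board import Cell, HexBoard, build_board, hex_distance

#: Minimum time between a player's consecutive moves, seconds.
LOCKOUT_SECONDS = 1.5
#: Moves available to each player.
MAX_MOVES = 15
#: Numerical slack when checking the lockout on float times.
_EPS = 1e-9

INFORMED = "informed"
UNINFORMED = "uninformed"


class GameRuleError(ValueError):
    """A move event violates the game rules; the message names the event."""


@dataclass(frozen=True)
class MoveEvent:
    """One avatar step: ``player_id`` moved ``from_cell`` -> ``to_cell`` at ``time`` s."""

    time: float
    player_id: int
    from_cell: Cell
    to_cell: Cell


@dataclass
class GameLog:
    """Ordered move events plus roles and condition for one ten-player game."""

    board: HexBoard
    condition: str                      # "local" | "global"
    roles: dict                         # player_id -> "informed" | "uninformed"
    events: list                        # time-ordered MoveEvents
    perception_radius: int | None = None  # local condition only
    group_id: int = 0
    seed: int | None = None
    final_positions: dict = field(default_factory=dict)

    def informed_players(self) -> list:
        return sorted(p for p, r in self.roles.items() if r == INFORMED)

    def uninformed_players(self) -> list:
        return sorted(p for p, r in self.roles.items() if r == UNINFORMED)

    def sorted_events(self) -> list:
        # Stable tie-break for simultaneous events: (time, player_id).
        return sorted(self.events, key=lambda e: (e.time, e.player_id))


def replay_and_validate(log: GameLog) -> dict:
    """Replay ``log`` from the start cell, enforcing every movement rule.

    Returns the final position of every player and checks it against
    ``log.final_positions`` when that is non-empty.

    Raises
    ------
    GameRuleError
        On a step between non-adjacent or off-board cells, a ``from_cell``
        inconsistent with the replayed position, more than 15 moves by one
        player, a violation of the 1.5 s lockout, or a move after the game
        already ended (all avatars standing on depots).
    """
    board = log.board
    pos = {p: board.start_cell for p in log.roles}
    moves_used = {p: 0 for p in log.roles}
    last_time: dict = {}
    depot_set = set(board.depot_cells)

    def _ended() -> bool:
        return all(c in depot_set for c in pos.values())

    for i, ev in enumerate(log.sorted_events()):
        what = f"event {i} (t={ev.time:.3f}, player {ev.player_id})"
        if ev.player_id not in pos:
            raise GameRuleError(f"{what}: unknown player")
        if ev.time < 0:
            raise GameRuleError(f"{what}: negative time")
        if _ended():
            raise GameRuleError(f"{what}: move after game end (all avatars on depots)")
        if pos[ev.player_id] != ev.from_cell:
            raise GameRuleError(
                f"{what}: from_cell {ev.from_cell} but player stands on {pos[ev.player_id]}"
            )
        if ev.to_cell not in board.cells:
            raise GameRuleError(f"{what}: to_cell {ev.to_cell} off board")
        if hex_distance(ev.from_cell, ev.to_cell) != 1:
            raise GameRuleError(
                f"{what}: step {ev.from_cell}->{ev.to_cell} is not a single-cell move"
            )
        if moves_used[ev.player_id] >= MAX_MOVES:
            raise GameRuleError(f"{what}: more than {MAX_MOVES} moves")
        prev = last_time.get(ev.player_id)
        if prev is not None and ev.time - prev < LOCKOUT_SECONDS - _EPS:
            raise GameRuleError(
                f"{what}: lockout violated (gap {ev.time - prev:.3f}s < {LOCKOUT_SECONDS}s)"
            )
        pos[ev.player_id] = ev.to_cell
        moves_used[ev.player_id] += 1
        last_time[ev.player_id] = ev.time

    if log.final_positions and dict(log.final_positions) != pos:
        raise GameRuleError("recorded final_positions disagree with replay")
    return pos


def final_payoffs(
    log: GameLog,
    base_values: dict | None = None,
    ee_value: float = 2.0,
    include_self: bool = False,
) -> dict:
    """Per-player monetary payoff at the end of the game.

    A player standing on depot ``d`` earns ``base(d) * m`` where ``m`` counts
    the co-players on ``d`` (``include_self=True`` switches to total
    occupancy).  Players elsewhere earn nothing.  Informed players standing on
    the high-value depot earn from ``ee_value`` instead of the base; the
    high-value reward is invisible to (and unearnable by) uninformed players.
    """
    base_values = base_values if base_values is not None else {d: 1.0 for d in log.board.depot_cells}
    unknown = set(base_values) - set(log.board.depot_cells)
    if unknown:
        raise GameRuleError(f"base_values for non-depot cells {sorted(unknown)}")
    pos = replay_and_validate(log)
    occupancy: dict = {}
    for c in pos.values():
        occupancy[c] = occupancy.get(c, 0) + 1
    payoffs = {}
    for p, c in pos.items():
        if c not in base_values:
            payoffs[p] = 0.0
            continue
        m = occupancy[c] if include_self else occupancy[c] - 1
        base = base_values[c]
        if c == log.board.ee_cell and log.roles[p] == INFORMED:
            base = ee_value
        payoffs[p] = base * m
    return payoffs


# ---------------------------------------------------------------------------
# Serialisation: JSONL game logs and a flat CSV event export.

def _cell_to_list(c: Cell) -> list:
    return [int(c[0]), int(c[1])]


def write_game_logs(path: "str | Path", logs: "list[GameLog]") -> None:
    """Write games as JSONL: a header record per game, then its move events."""
    with open(path, "w") as fh:
        for log in logs:
            header = {
                "type": "game",
                "group_id": log.group_id,
                "board": log.board.name,
                "ee_cell": _cell_to_list(log.board.ee_cell),
                "condition": log.condition,
                "perception_radius": log.perception_radius,
                "roles": {str(p): r for p, r in log.roles.items()},
                "seed": log.seed,
                "final_positions": {
                    str(p): _cell_to_list(c) for p, c in log.final_positions.items()
                },
            }
            fh.write(json.dumps(header) + "\n")
            for ev in log.sorted_events():
                fh.write(json.dumps({
                    "type": "move",
                    "time": ev.time,
                    "player_id": ev.player_id,
                    "from": _cell_to_list(ev.from_cell),
                    "to": _cell_to_list(ev.to_cell),
                }) + "\n")


def read_game_logs(path: "str | Path", board: HexBoard | None = None) -> "list[GameLog]":
    """Read games written by :func:`write_game_logs`.

    Boards are rebuilt from the named default layout (with the recorded
    high-value cell); pass ``board`` to override for custom layouts.
    """
    logs: list[GameLog] = []
    current: GameLog | None = None
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["type"] == "game":
                b = board if board is not None else build_board(rec["board"])
                b = b.with_ee(tuple(rec["ee_cell"]))
                current = GameLog(
                    board=b,
                    condition=rec["condition"],
                    perception_radius=rec["perception_radius"],
                    roles={int(p): r for p, r in rec["roles"].items()},
                    events=[],
                    group_id=rec["group_id"],
                    seed=rec["seed"],
                    final_positions={
                        int(p): tuple(c) for p, c in rec["final_positions"].items()
                    },
                )
                logs.append(current)
            elif rec["type"] == "move":
                if current is None:
                    raise GameRuleError("move record before any game header")
                current.events.append(MoveEvent(
                    time=rec["time"],
                    player_id=rec["player_id"],
                    from_cell=tuple(rec["from"]),
                    to_cell=tuple(rec["to"]),
                ))
    return logs


def events_csv(logs: "list[GameLog]") -> pd.DataFrame:
    """Flat event table (group_id, time, player_id, from_q, from_r, to_q, to_r)."""
    rows = []
    for log in logs:
        for ev in log.sorted_events():
            rows.append((log.group_id, ev.time, ev.player_id,
                         ev.from_cell[0], ev.from_cell[1],
                         ev.to_cell[0], ev.to_cell[1]))
    return pd.DataFrame(
        rows, columns=["group_id", "time", "player_id", "from_q", "from_r", "to_q", "to_r"]
    )
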