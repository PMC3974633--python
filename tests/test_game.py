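import numpy as np
import pytest

import hexcomb as hc
from hexcomb.game import (
    GameLog, GameRuleError, LOCKOUT_SECONDS, MAX_MOVES, MoveEvent,
    final_payoffs, read_game_logs, replay_and_validate, write_game_logs,
)


def _tiny_log(board, events, roles=None, **kw):
    roles = roles or {1: "informed", 2: "informed",
                      **{p: "uninformed" for p in range(3, 11)}}
    return GameLog(board=board, condition="global", roles=roles,
                   events=events, **kw)


def _walk(board, player, goal, t0=0.0, gap=2.0):
    """Straight-line walk events from the start cell to ``goal``."""
    pos = board.start_cell
    t = t0
    events = []
    while pos != goal:
        step = sorted(hc.shortest_step_options(pos, goal, board))[0]
        events.append(MoveEvent(time=t, player_id=player, from_cell=pos, to_cell=step))
        pos = step
        t += gap
    return events


def test_replay_of_simulated_games_is_clean(small_cohort):
    for log in small_cohort:
        pos = replay_and_validate(log)
        assert pos == log.final_positions


def test_replay_rejects_non_adjacent_step(board):
    ev = [MoveEvent(0.0, 1, (0, 0), (2, 0))]
    with pytest.raises(GameRuleError, match="single-cell"):
        replay_and_validate(_tiny_log(board, ev))


def test_replay_rejects_wrong_from_cell(board):
    ev = [MoveEvent(0.0, 1, (1, 0), (2, 0))]
    with pytest.raises(GameRuleError, match="from_cell"):
        replay_and_validate(_tiny_log(board, ev))


def test_replay_rejects_off_board_step(board):
    # walk straight east off the field
    ev = [MoveEvent(2.0 * i, 1, (i, 0), (i + 1, 0)) for i in range(7)]
    with pytest.raises(GameRuleError, match="off board"):
        replay_and_validate(_tiny_log(board, ev))


def test_replay_enforces_lockout(board):
    ev = [MoveEvent(0.0, 1, (0, 0), (1, 0)),
          MoveEvent(1.0, 1, (1, 0), (2, 0))]
    with pytest.raises(GameRuleError, match="lockout"):
        replay_and_validate(_tiny_log(board, ev))
    ok = [MoveEvent(0.0, 1, (0, 0), (1, 0)),
          MoveEvent(LOCKOUT_SECONDS, 1, (1, 0), (2, 0))]
    replay_and_validate(_tiny_log(board, ok))


def test_replay_enforces_move_budget(board):
    # shuttle between two cells, 16 moves
    ev = []
    for i in range(MAX_MOVES + 1):
        frm = (0, 0) if i % 2 == 0 else (1, 0)
        to = (1, 0) if i % 2 == 0 else (0, 0)
        ev.append(MoveEvent(2.0 * i, 1, frm, to))
    with pytest.raises(GameRuleError, match="moves"):
        replay_and_validate(_tiny_log(board, ev))


def test_replay_rejects_moves_after_game_end(board):
    roles = {1: "informed", 2: "uninformed"}
    d1, d2 = board.depot_cells[0], board.depot_cells[1]
    ev = _walk(board, 1, d1) + _walk(board, 2, d2)
    late = MoveEvent(100.0, 1, d1, board.on_board_neighbours(d1)[0])
    with pytest.raises(GameRuleError, match="after game end"):
        replay_and_validate(_tiny_log(board, ev + [late], roles=roles))


def test_replay_checks_recorded_final_positions(board):
    roles = {1: "informed"}
    ev = [MoveEvent(0.0, 1, (0, 0), (1, 0))]
    bad = _tiny_log(board, ev, roles=roles, final_positions={1: (0, 1)})
    with pytest.raises(GameRuleError, match="final_positions"):
        replay_and_validate(bad)


def test_payoffs_multiply_with_co_occupancy(board):
    ee = board.ee_cell
    other = next(d for d in board.depot_cells if d != ee)
    roles = {1: "informed", 2: "uninformed", 3: "uninformed", 4: "uninformed"}
    ev = (_walk(board, 1, ee) + _walk(board, 2, ee)
          + _walk(board, 3, other) + _walk(board, 4, other))
    log = _tiny_log(board, ev, roles=roles)
    pay = final_payoffs(log)
    # co-player counts: one co-player each; informed on ee earns double base
    assert pay[1] == pytest.approx(2.0)
    assert pay[2] == pytest.approx(1.0)   # ee premium invisible to uninformed
    assert pay[3] == pay[4] == pytest.approx(1.0)
    total = final_payoffs(log, include_self=True)
    assert total[3] == pytest.approx(2.0)


def test_payoff_zero_off_depot(board):
    roles = {1: "uninformed"}
    ev = [MoveEvent(0.0, 1, (0, 0), (1, 0))]
    pay = final_payoffs(_tiny_log(board, ev, roles=roles))
    assert pay[1] == 0.0


def test_jsonl_round_trip(tmp_path, small_cohort):
    path = tmp_path / "games.jsonl"
    write_game_logs(path, small_cohort)
    back = read_game_logs(path)
    assert len(back) == len(small_cohort)
    for a, b in zip(small_cohort, back):
        assert a.condition == b.condition
        assert a.roles == b.roles
        assert a.board.ee_cell == b.board.ee_cell
        assert a.final_positions == b.final_positions
        assert [(e.time, e.player_id, e.from_cell, e.to_cell)
                for e in a.sorted_events()] == \
               [(e.time, e.player_id, e.from_cell, e.to_cell)
                for e in b.sorted_events()]
        replay_and_validate(b)


def test_events_csv_schema(small_cohort):
    df = hc.events_csv(small_cohort)
    assert list(df.columns) == ["group_id", "time", "player_id",
                                "from_q", "from_r", "to_q", "to_r"]
    assert (df.groupby("group_id")["time"].apply(lambda s: s.is_monotonic_increasing)).all()
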