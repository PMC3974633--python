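import numpy as np
import pytest

import hexcomb as hc
from hexcomb.features import FEATURE_COLUMNS
from hexcomb.game import GameLog, MoveEvent


def _scripted_log(board, informed_steps, first_informed=True):
    """Two informed (1, 2) + eight uninformed; informed first steps scripted."""
    roles = {1: "informed", 2: "informed",
             **{p: "uninformed" for p in range(3, 11)}}
    t_inf = 0.0 if first_informed else 10.0
    events = [
        MoveEvent(t_inf, 1, board.start_cell, informed_steps[0]),
        MoveEvent(t_inf + 0.2, 2, board.start_cell, informed_steps[1]),
        MoveEvent(5.0, 3, board.start_cell, board.on_board_neighbours(board.start_cell)[0]),
    ]
    return GameLog(board=board, condition="global", roles=roles, events=events)


def test_code_initial_moves_categories(board):
    opts = sorted(hc.shortest_step_options(board.start_cell, board.ee_cell, board))
    off = sorted(set(board.on_board_neighbours(board.start_cell)) - set(opts))
    assert hc.code_initial_moves(_scripted_log(board, [opts[0], opts[0]])) == ("same", False)
    assert hc.code_initial_moves(_scripted_log(board, [opts[0], opts[1]])) == ("direction", False)
    assert hc.code_initial_moves(_scripted_log(board, [opts[0], off[0]])) == ("other", False)


def test_code_initial_moves_flags_missing_informed_move(board):
    roles = {1: "informed", 2: "informed",
             **{p: "uninformed" for p in range(3, 11)}}
    log = GameLog(board=board, condition="global", roles=roles,
                  events=[MoveEvent(0.0, 3, board.start_cell,
                                    board.on_board_neighbours(board.start_cell)[0])])
    assert hc.code_initial_moves(log) == ("other", True)


def test_code_first(board):
    opts = sorted(hc.shortest_step_options(board.start_cell, board.ee_cell, board))
    assert hc.code_first(_scripted_log(board, [opts[0], opts[1]]))[0] == 1
    assert hc.code_first(_scripted_log(board, [opts[0], opts[1]],
                                       first_informed=False))[0] == 0


def test_code_arrivals_counts_only_uninformed(board):
    # scripted: both informed and three uninformed end on the ee depot
    roles = {1: "informed", 2: "informed",
             **{p: "uninformed" for p in range(3, 11)}}
    events = []
    for i, p in enumerate([1, 2, 3, 4, 5]):
        pos = board.start_cell
        t = 0.1 * i
        while pos != board.ee_cell:
            step = sorted(hc.shortest_step_options(pos, board.ee_cell, board))[0]
            events.append(MoveEvent(t, p, pos, step))
            pos = step
            t += 2.0
    log = GameLog(board=board, condition="global", roles=roles, events=events)
    assert hc.code_arrivals(log) == 3


def test_starting_ranks_ties_and_nonmovers(board):
    roles = {p: ("informed" if p <= 2 else "uninformed") for p in range(1, 11)}
    events = [
        MoveEvent(1.0, 1, board.start_cell, (1, 0)),
        MoveEvent(1.0, 2, board.start_cell, (0, 1)),   # tie with player 1
        MoveEvent(3.0, 3, board.start_cell, (1, 0)),
    ]
    log = GameLog(board=board, condition="global", roles=roles, events=events)
    ranks, informed_mean = hc.starting_ranks(log)
    assert informed_mean == pytest.approx(1.5)         # tied earliest
    assert ranks[3] == pytest.approx(3.0)
    # the seven non-movers share the average of ranks 4..10
    assert ranks[4] == pytest.approx(np.mean(range(4, 11)))


def test_path_metrics_identical_paths_are_zero_distance(board):
    opts = sorted(hc.shortest_step_options(board.start_cell, board.ee_cell, board))
    log = _scripted_log(board, [opts[0], opts[0]])
    similarity, length, latency = hc.path_metrics(log)
    assert similarity == 0.0
    assert length == 1.0
    assert latency == pytest.approx(0.1, abs=0.2)


def test_features_table_schema_and_ranges(small_features):
    assert list(small_features.columns) == FEATURE_COLUMNS
    assert small_features["arrivals"].between(0, 8).all()
    assert small_features["local"].isin([0, 1]).all()
    assert ((small_features["same"] + small_features["direction"]) <= 1).all()
    assert small_features["informed_mean_start_rank"].between(1.5, 9.5).all()
    assert small_features["group_id"].is_unique


def test_features_table_rejects_duplicate_groups(small_cohort):
    with pytest.raises(ValueError, match="duplicate"):
        hc.features_table([small_cohort[0], small_cohort[0]])


def test_summary_statistics(small_features):
    s = hc.summary_statistics(small_features)
    assert set(s["variable"]) == {"arrivals", "local", "first", "same", "direction"}
    row = s.set_index("variable").loc["arrivals"]
    assert row["mean"] == pytest.approx(small_features["arrivals"].mean())
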