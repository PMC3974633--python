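"""A first look at the playfield and one simulated game.

Builds the 97-cell hexagonal field, shows its geometry, simulates a single
ten-player game with the default (strong-leadership) behaviour, replays the
log through the rule validator, and prints the final payoffs.
"""

import hexcomb as hc

board = hc.build_board("honeycomb97")
print(f"board '{board.name}': {len(board.cells)} cells, start {board.start_cell}")
for d in board.depot_cells:
    opts = sorted(hc.shortest_step_options(board.start_cell, d, board))
    tag = "  <- high-value" if d == board.ee_cell else ""
    print(f"  depot {d}: distance {hc.hex_distance(board.start_cell, d)}, "
          f"first-step options {opts}{tag}")

log = hc.simulate_game(board, condition="global",
                       params=hc.BehaviourParams(), seed=11)
positions = hc.replay_and_validate(log)          # raises on any rule violation
arrivals = hc.code_arrivals(log)
print(f"\none game (seed 11): {len(log.events)} moves, "
      f"{arrivals}/8 uninformed players reached the high-value depot")

payoffs = hc.final_payoffs(log)
for player in sorted(payoffs):
    print(f"  player {player:2d} ({log.roles[player]:10s}) "
          f"ends {positions[player]} payoff {payoffs[player]:.1f}")
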