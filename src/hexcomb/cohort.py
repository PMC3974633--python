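"""Agent-based generator of synthetic game cohorts.

The generator emulates the statistical structure of the 40-group experiment
(ten players per group, two informed of the high-value depot, a 20/20
local/global perception split) with deliberately minimal agent rules: a
first-move latency, a consistency rule for the informed pair's first steps,
and, for the uninformed majority, a quorum response — commitment to a
personal depot that is abandoned for a visible vote leader — layered with
weighted local heuristics (cohesion toward the visible crowd, alignment
with visible headings, noise).
The point is to produce game logs carrying the observed signatures —
informed players moving earlier, a bimodal distribution of arrivals on the
high-value depot — not to model human players faithfully.

Perception in the local condition masks other players' avatars outside the
perception radius; depot locations are part of the playfield and always
known to every agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .board import Cell, HexBoard, build_board, hex_distance, shortest_step_options
from .game import (
    GameLog, INFORMED, LOCKOUT_SECONDS, MAX_MOVES, MoveEvent, UNINFORMED,
    replay_and_validate,
)

#: Seconds between re-checks by an agent content to stay on its depot.
_RECHECK = 2.0


@dataclass(frozen=True)
class BehaviourParams:
    """Tunable agent behaviour.

    Parameters
    ----------
    informed_latency_mean, uninformed_latency_mean : float
        Mean first-move waiting times, seconds.  Informed agents moving
        earlier than uninformed ones is the main first-mover mechanism.
    consistency_mode : dict
        Probabilities over ``{"same", "direction", "other"}`` for the
        informed pair's first steps: both take the identical shortest-route
        cell, the two distinct shortest-route cells, or at least one steps
        off the shortest route.
    goal_weight : float
        Per-step probability that an informed agent steps along a shortest
        route to the high-value depot (otherwise a uniform permitted step).
        An informed pair whose first steps are inconsistent (``"other"``)
        does not lead at all: after the off-route first step it behaves like
        the uninformed majority.
    cohesion_weight, alignment_weight, noise : float
        Per-step probabilities that an uninformed agent steps toward the
        centroid of visible co-players, along their modal recent heading, or
        uniformly at random; the remaining mass goes to committed depot
        seeking (see ``quorum``).
    uninformed_strategy : str
        ``"social"`` for the heuristics above; ``"random_depot"`` for the
        null behaviour in which each uninformed agent ignores everyone,
        picks one of the six depots uniformly and walks straight to it.
    asocial_fraction : float
        Probability that an uninformed agent individually plays the
        ``"random_depot"`` behaviour even in a social group — the handful
        of players who ignore the crowd, producing the shortfall from
        perfect convergence seen in real groups.
    quorum, switch_slack, capitulate_lead : int
        The quorum response that herds the majority.  Each social
        uninformed agent commits to a personal depot (uniform over the six)
        at its first decision.  Visible players who have left the start vote
        for the depot they appear headed to (nearest depot, ties broken by
        heading).  The agent abandons its commitment for a unique vote
        leader once the leader's margin over its own depot reaches
        ``quorum`` votes — but, while en route, only if that costs at most
        ``switch_slack`` extra cells of travel (spatial commitment, the
        primacy effect that lets an early majority stick).  The distance
        condition is waived when the agent stands on a depot it can see is
        outvoted or when the leader's margin reaches ``capitulate_lead``.
    step_gap_mean : float
        Mean extra delay (beyond the 1.5 s lockout) between an agent's
        consecutive moves, seconds.
    latency_dist : str
        ``"exponential"`` (default) or ``"gamma"`` first-move latencies;
        gamma uses ``gamma_shape`` with the scale set to match the mean.
    """

    informed_latency_mean: float = 5.5
    uninformed_latency_mean: float = 7.5
    consistency_mode: dict = field(
        default_factory=lambda: {"same": 0.2, "direction": 0.6, "other": 0.2}
    )
    goal_weight: float = 0.65
    cohesion_weight: float = 0.1
    alignment_weight: float = 0.05
    noise: float = 0.02
    uninformed_strategy: str = "social"
    asocial_fraction: float = 0.07
    quorum: int = 1
    switch_slack: int = 2
    capitulate_lead: int = 3
    step_gap_mean: float = 2.0
    latency_dist: str = "gamma"
    gamma_shape: float = 1.5

    def __post_init__(self) -> None:
        for name in ("goal_weight", "cohesion_weight", "alignment_weight", "noise",
                     "asocial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cohesion_weight + self.alignment_weight + self.noise > 1.0 + 1e-12:
            raise ValueError("cohesion + alignment + noise must not exceed 1")
        if self.informed_latency_mean <= 0 or self.uninformed_latency_mean <= 0:
            raise ValueError("latency means must be positive")
        if self.step_gap_mean < 0:
            raise ValueError("step_gap_mean must be non-negative")
        if self.quorum < 1:
            raise ValueError("quorum must be at least 1")
        if self.switch_slack < 0:
            raise ValueError("switch_slack must be non-negative")
        if self.capitulate_lead < 1:
            raise ValueError("capitulate_lead must be at least 1")
        total = sum(self.consistency_mode.get(k, 0.0) for k in ("same", "direction", "other"))
        if abs(total - 1.0) > 1e-9 or set(self.consistency_mode) - {"same", "direction", "other"}:
            raise ValueError("consistency_mode must be a distribution over same/direction/other")
        if self.uninformed_strategy not in ("social", "random_depot"):
            raise ValueError(f"unknown uninformed_strategy {self.uninformed_strategy!r}")
        if self.latency_dist not in ("exponential", "gamma"):
            raise ValueError(f"unknown latency_dist {self.latency_dist!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group count, condition split, group composition, seed."""

    n_groups: int = 40
    n_local: int = 20
    n_players: int = 10
    n_informed: int = 2
    params: BehaviourParams = field(default_factory=BehaviourParams)
    master_seed: int = 0
    perception_radius: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.n_local <= self.n_groups:
            raise ValueError("need 0 <= n_local <= n_groups")
        if not 0 <= self.n_informed <= self.n_players:
            raise ValueError("need 0 <= n_informed <= n_players")


def leadership_presets(name: str) -> BehaviourParams:
    """Named behaviour regimes.

    ``"strong"`` produces a bimodal across-group arrivals distribution (the
    informed pair moves early and mostly consistently, and the majority herds
    to a single depot); ``"null"`` makes each uninformed agent pick a depot
    uniformly at random, so arrivals are Binomial(8, 1/6); ``"weak"`` is
    intermediate.
    """
    if name == "strong":
        return BehaviourParams()
    if name == "weak":
        return BehaviourParams(
            informed_latency_mean=7.5,
            consistency_mode={"same": 0.1, "direction": 0.3, "other": 0.6},
            goal_weight=0.5,
        )
    if name == "null":
        return BehaviourParams(uninformed_strategy="random_depot")
    raise ValueError(f"unknown preset {name!r}")


def _latency(rng: np.random.Generator, params: BehaviourParams, mean: float) -> float:
    if params.latency_dist == "gamma":
        return float(rng.gamma(params.gamma_shape, mean / params.gamma_shape))
    return float(rng.exponential(mean))


def _cube(c: Cell) -> tuple:
    return (c[0], -c[0] - c[1], c[1])


def _choice(rng: np.random.Generator, seq):
    seq = sorted(seq)
    return seq[rng.integers(len(seq))]


def simulate_game(
    board: HexBoard,
    condition: str,
    params: BehaviourParams,
    seed: int,
    group_id: int = 0,
    n_players: int = 10,
    n_informed: int = 2,
    perception_radius: int = 4,
) -> GameLog:
    """Simulate one rule-conforming game; identical seeds give identical logs.

    The high-value depot is drawn uniformly among the six depots, and
    ``n_informed`` players are drawn uniformly to be informed of it.
    """
    if condition not in ("local", "global"):
        raise ValueError(f"condition must be 'local' or 'global', got {condition!r}")
    rng = np.random.default_rng(seed)
    board = board.with_ee(board.depot_cells[rng.integers(6)])
    ee = board.ee_cell
    depots = list(board.depot_cells)
    players = list(range(1, n_players + 1))
    informed = sorted(rng.choice(players, size=n_informed, replace=False).tolist())
    roles = {p: (INFORMED if p in informed else UNINFORMED) for p in players}
    # A fraction of uninformed players ignores the crowd entirely and just
    # walks to a personally chosen depot (the "asocial" minority).
    asocial = {p: (roles[p] == UNINFORMED
                   and rng.random() < params.asocial_fraction)
               for p in players}

    start = board.start_cell
    pos = {p: start for p in players}
    moves = {p: 0 for p in players}
    heading = {p: None for p in players}   # last move direction, axial offset
    done = {p: False for p in players}     # permanently finished acting
    target = {p: None for p in players}    # random_depot strategy only
    next_time = {}
    for p in players:
        mean = (params.informed_latency_mean if roles[p] == INFORMED
                else params.uninformed_latency_mean)
        next_time[p] = _latency(rng, params, mean)

    # The informed pair's first steps, fixed at game start.
    options = sorted(shortest_step_options(start, ee, board))
    mode_names = ("same", "direction", "other")
    probs = [params.consistency_mode.get(m, 0.0) for m in mode_names]
    first_mode = mode_names[rng.choice(3, p=probs)]
    first_step: dict = {}
    if n_informed == 2 and len(options) == 2:
        if first_mode == "same":
            shared = options[rng.integers(2)]
            first_step = {informed[0]: shared, informed[1]: shared}
        elif first_mode == "direction":
            order = rng.permutation(2)
            first_step = {informed[0]: options[order[0]], informed[1]: options[order[1]]}
        else:
            off = sorted(set(board.on_board_neighbours(start)) - set(options))
            first_step = {p: off[rng.integers(len(off))] for p in informed}

    depot_set = set(depots)
    local = condition == "local"

    def visible_others(p: int) -> list:
        me = pos[p]
        return [o for o in players
                if o != p and (not local or hex_distance(pos[o], me) <= perception_radius)]

    def _depot_votes(p: int) -> dict:
        """Visible support per depot: each visible player who has left the
        start counts toward the depot it currently stands nearest to.  Ties
        are broken by the player's heading (the depot it appears to walk
        toward); players whose target stays ambiguous abstain."""
        votes = {d: 0 for d in depots}
        for o in visible_others(p):
            c = pos[o]
            if c == start:
                continue
            dists = [hex_distance(c, d) for d in depots]
            m = min(dists)
            nearest = [d for d, dd in zip(depots, dists) if dd == m]
            if len(nearest) > 1 and heading[o] is not None:
                ahead = (c[0] + heading[o][0], c[1] + heading[o][1])
                m2 = min(hex_distance(ahead, d) for d in nearest)
                nearest = [d for d in nearest if hex_distance(ahead, d) == m2]
            if len(nearest) == 1:
                votes[nearest[0]] += 1
        return votes

    def seek_step(p: int):
        """Step toward the agent's committed depot, with a quorum response.

        Each uninformed agent commits to a personal depot (uniform among the
        six) on its first decision and abandons it only when some other depot
        has visibly more support — at least ``quorum`` more visible players
        whose nearest depot it is.  The quorum response is the
        positive-feedback channel: a small early majority flips the
        committed targets of everyone who can see it, herding the group
        onto one depot.
        """
        me = pos[p]
        votes = _depot_votes(p)
        if target[p] is None:
            target[p] = depots[rng.integers(6)]
        lead = [d for d in depots
                if votes[d] - votes[target[p]] >= params.quorum]
        if lead:
            top = max(votes[d] for d in lead)
            tops = [d for d in lead if votes[d] == top]
            # Switch only to a unique leader (ties keep the commitment) and,
            # while en route, only when it costs little extra travel: spatial
            # commitment is the primacy effect that lets an early majority
            # stick.  The commitment is dropped regardless of distance when
            # the agent stands on a depot it can see is outvoted, or when the
            # leader's margin reaches ``capitulate_lead`` (a visibly decided
            # majority).
            if len(tops) == 1 and (
                    me == target[p]
                    or votes[tops[0]] - votes[target[p]] >= params.capitulate_lead
                    or hex_distance(me, tops[0])
                    <= hex_distance(me, target[p]) + params.switch_slack):
                target[p] = tops[0]
        tgt = target[p]
        if tgt == me:
            return None
        opts = shortest_step_options(me, tgt, board)
        return _choice(rng, opts) if opts else None

    def uninformed_step(p: int):
        me = pos[p]
        if params.uninformed_strategy == "random_depot" or asocial[p]:
            if target[p] is None:
                target[p] = depots[rng.integers(6)]
            if me == target[p]:
                done[p] = True
                return None
            opts = shortest_step_options(me, target[p], board)
            return _choice(rng, opts) if opts else None

        vis = visible_others(p)
        # Content to stay when standing on a depot with at least as much
        # visible support as any other (support of self included).
        if me in depot_set:
            votes = _depot_votes(p)
            if votes[me] + 1 >= max(votes.values()):
                target[p] = me
                return None
        w = [params.cohesion_weight, params.alignment_weight, params.noise]
        w.append(max(0.0, 1.0 - sum(w)))
        mode = ("cohesion", "alignment", "noise", "seek")[rng.choice(4, p=np.array(w) / sum(w))]
        if mode == "cohesion" and vis:
            cx = np.mean([_cube(pos[o]) for o in vis], axis=0)
            best, best_d = None, sum(abs(np.array(_cube(me)) - cx)) / 2
            for n in sorted(board.on_board_neighbours(me)):
                d = sum(abs(np.array(_cube(n)) - cx)) / 2
                if d < best_d - 1e-9:
                    best, best_d = n, d
            if best is not None:
                return best
        elif mode == "alignment":
            hs = [heading[o] for o in vis if heading[o] is not None]
            if hs:
                counts: dict = {}
                for h in hs:
                    counts[h] = counts.get(h, 0) + 1
                top = max(counts.values())
                h = _choice(rng, [h for h, c in counts.items() if c == top])
                cand = (me[0] + h[0], me[1] + h[1])
                if cand in board.cells:
                    return cand
        elif mode == "noise":
            return _choice(rng, board.on_board_neighbours(me))
        return seek_step(p)

    def informed_step(p: int):
        me = pos[p]
        if moves[p] == 0 and p in first_step:
            return first_step[p]
        if first_mode == "other":
            # An inconsistent informed pair does not lead: after the
            # off-route first step it behaves like the uninformed majority.
            return uninformed_step(p)
        if me == ee:
            done[p] = True
            return None
        if rng.random() < params.goal_weight:
            opts = shortest_step_options(me, ee, board)
            if opts:
                return _choice(rng, opts)
        return _choice(rng, board.on_board_neighbours(me))

    events: list = []
    stays_in_a_row = 0
    while True:
        if pos and all(c in depot_set for c in pos.values()):
            break
        active = [p for p in players if moves[p] < MAX_MOVES and not done[p]]
        if not active or stays_in_a_row > len(players):
            break
        p = min(active, key=lambda q: (next_time[q], q))
        t = next_time[p]
        step = informed_step(p) if roles[p] == INFORMED else uninformed_step(p)
        if step is None:
            next_time[p] = t + _RECHECK
            stays_in_a_row += 1
            continue
        stays_in_a_row = 0
        events.append(MoveEvent(time=t, player_id=p, from_cell=pos[p], to_cell=step))
        heading[p] = (step[0] - pos[p][0], step[1] - pos[p][1])
        pos[p] = step
        moves[p] += 1
        next_time[p] = t + LOCKOUT_SECONDS + rng.exponential(params.step_gap_mean)

    log = GameLog(
        board=board,
        condition=condition,
        roles=roles,
        events=events,
        perception_radius=perception_radius if local else None,
        group_id=group_id,
        seed=int(seed),
        final_positions=dict(pos),
    )
    replay_and_validate(log)
    return log


def _child_seed(master_seed: int, group_index: int) -> int:
    """Counter-based child seed: reproducible across platforms."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index,))
    return int(ss.generate_state(1)[0])


def simulate_cohort(spec: CohortSpec, board: HexBoard | None = None) -> list:
    """Simulate ``spec.n_groups`` games; the first ``n_local`` are local."""
    board = board if board is not None else build_board("honeycomb97")
    logs = []
    for g in range(spec.n_groups):
        condition = "local" if g < spec.n_local else "global"
        logs.append(simulate_game(
            board, condition, spec.params,
            seed=_child_seed(spec.master_seed, g),
            group_id=g + 1,
            n_players=spec.n_players,
            n_informed=spec.n_informed,
            perception_radius=spec.perception_radius,
        ))
    return logs


def pretest_scenario(spec: CohortSpec, board: HexBoard | None = None) -> list:
    """All-uninformed games with six equal depots, for cohesion calibration."""
    return simulate_cohort(replace(spec, n_informed=0), board=board)


def largest_depot_occupancy(log: GameLog) -> float:
    """Fraction of players ending on the single most occupied depot."""
    pos = replay_and_validate(log)
    depots = log.board.depot_cells
    occ = [sum(1 for c in pos.values() if c == d) for d in depots]
    return max(occ) / len(pos)
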