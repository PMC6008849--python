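"""Deterministic synchronous simulation of discrete network dynamics.

The transition rule: the *effect* of node *i* on node *j* is the product of
*i*'s state and the weight of the edge *i*->*j*; the *net effect* on *j* is
the sum over its (non-blocked) incoming edges.  At every time step all
non-signal nodes update simultaneously:

    s_j(t+1) = clamp(s_j(t) + sign(net_j(t)), 0, 9)

i.e. the state increases, decreases or stays put according to the sign of
the net effect, saturating at the 0 and 9 bounds.  Signal nodes ignore the
rule and replay their preset pattern cyclically.  An edge with delay *d*
reads the source state *d* steps in the past (pre-history is padded with
the initial state).

Because the extended dynamical state -- the window of the last D+1
configurations (D = maximal delay) together with every signal's phase -- is
finite, a deterministic run must eventually reach a *steady state* (fixed
point) or a *cycle*; both are detected exactly.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    STATE_MAX,
    STATE_MIN,
    Configuration,
    Network,
    NetworkError,
    Trajectory,
)

logger = logging.getLogger(__name__)


def _sign(x: int) -> int:
    return (x > 0) - (x < 0)


@dataclass
class DynamicalState:
    """Everything the dynamics needs to be Markovian: the configuration
    window covering the maximal edge delay, plus each signal's phase."""

    window: List[Configuration]  # oldest first; length D+1 (padded early on)
    signal_phase: Dict[str, int]

    def key(self, order: Sequence[str]) -> tuple:
        return (
            tuple(c.as_tuple(order) for c in self.window),
            tuple(sorted(self.signal_phase.items())),
        )


def _state_at(window: List[Configuration], t: int, lookup_t: int, node: str) -> int:
    """Source state at time ``lookup_t`` given the window ending at ``t``.

    Times before 0 read the initial configuration (the window is padded
    with it while t < D).
    """
    idx = len(window) - 1 - (t - max(lookup_t, 0))
    if idx < 0:
        idx = 0
    return window[idx].states[node]


def net_effect(network: Network, state: DynamicalState, node_id: str, t: int) -> int:
    """Net effect on ``node_id`` at step ``t``: sum of source-state x weight
    over incoming edges, skipping edges suppressed by an active blocking rule."""
    if node_id not in network.nodes:
        raise NetworkError(f"unknown node {node_id!r}")
    current = state.window[-1].states
    blocked_pairs = {
        rule.edge
        for rule in network.blocking_rules
        if rule.is_active(current, t)
    }
    total = 0
    for edge in network.in_edges(node_id):
        if (edge.source, edge.target) in blocked_pairs:
            continue
        s = _state_at(state.window, t, t - edge.delay, edge.source)
        total += s * edge.weight
    return total


def step(network: Network, state: DynamicalState, t: int) -> Configuration:
    """One synchronous update from the configuration at step ``t``.

    All nodes read the same pre-step window; signal nodes take the next
    pattern value, everything else moves by the sign of its net effect.
    """
    nxt: Dict[str, int] = {}
    current = state.window[-1].states
    for nid, node in network.nodes.items():
        if node.is_signal:
            nxt[nid] = node.signal_pattern[(t + 1) % len(node.signal_pattern)]
        else:
            delta = _sign(net_effect(network, state, nid, t))
            nxt[nid] = min(STATE_MAX, max(STATE_MIN, current[nid] + delta))
    return Configuration(nxt, time=t + 1)


def _advance(state: DynamicalState, network: Network, config: Configuration) -> None:
    depth = network.max_delay + 1
    state.window.append(config)
    if len(state.window) > depth:
        state.window.pop(0)
    for nid, node in network.nodes.items():
        if node.is_signal:
            state.signal_phase[nid] = config.time % len(node.signal_pattern)


def _initial_dynamical_state(network: Network, config: Configuration) -> DynamicalState:
    depth = network.max_delay + 1
    phases = {
        nid: 0 for nid, n in network.nodes.items() if n.is_signal
    }
    return DynamicalState(window=[config] * depth, signal_phase=phases)


def simulate(
    network: Network,
    max_steps: Optional[int] = 100,
    initial: Optional[Dict[str, int]] = None,
) -> Trajectory:
    """Run the dynamics from the network's initial configuration.

    Parameters
    ----------
    network:
        A finalized network (non-signal nodes missing their
        self-degradation loop trigger a warning, not an error).
    max_steps:
        Cap on the number of transitions (default 100, which suffices for
        the steady states seen on pathway-scale networks).  ``None`` runs
        until a steady state or cycle is found, which is guaranteed because
        the extended state space is finite.
    initial:
        Optional override of initial states (node id -> state) applied on
        a copy; signal nodes cannot be overridden.

    Termination:

    * ``steady_state`` -- the last D+2 configurations are identical (two
      consecutive when no delays) and every signal pattern is constant, so
      the final configuration is a verified fixed point;
    * ``cycle`` -- the extended dynamical state recurred; ``cycle_start``
      is the step of its earlier occurrence;
    * ``max_steps`` -- the cap was reached first.
    """
    if max_steps is not None and max_steps < 1:
        raise NetworkError("max_steps must be >= 1 (or None for unbounded)")
    if not network.nodes:
        raise NetworkError("cannot simulate an empty network")
    if not network.is_finalized():
        logger.warning(
            "network is not finalized: some non-signal nodes lack a "
            "self-degradation loop; simulating as-is"
        )
    if initial:
        network = network.copy()
        for nid, s in initial.items():
            if network.nodes[nid].is_signal:
                continue
            network.set_initial_state(nid, s)

    order = network.node_ids()
    depth = network.max_delay + 1
    signals_constant = all(
        len(set(n.signal_pattern)) == 1
        for n in network.nodes.values()
        if n.is_signal
    )

    config = network.initial_configuration()
    state = _initial_dynamical_state(network, config)
    configs: List[Configuration] = [config]
    seen = {state.key(order): 0}

    t = 0
    while max_steps is None or t < max_steps:
        config = step(network, state, t)
        configs.append(config)
        _advance(state, network, config)
        t += 1

        # steady state: the whole delay window plus the step that produced
        # the newest configuration are identical, so this is a fixed point
        if signals_constant and len(configs) >= depth + 1:
            tail = configs[-(depth + 1):]
            if all(c.states == tail[0].states for c in tail[1:]):
                return Trajectory(configs, "steady_state")

        key = state.key(order)
        if key in seen:
            return Trajectory(configs, "cycle", cycle_start=seen[key])
        seen[key] = t

    return Trajectory(configs, "max_steps")


# ---------------------------------------------------------------------------
# batch mode


@dataclass
class BatchSummary:
    """Statistics over a set of simulations: the attractors reached, how
    often, and the mean number of steps to absorption."""

    attractors: list = field(default_factory=list)
    # each item: {"kind": "steady_state"|"cycle"|"max_steps",
    #             "representative": tuple of state-dicts (length 1 if steady),
    #             "frequency": int, "mean_steps": float}
    total_runs: int = 0

    def to_dict(self) -> dict:
        return {
            "total_runs": self.total_runs,
            "attractors": [
                {
                    "kind": a["kind"],
                    "representative": [dict(s) for s in a["representative"]],
                    "frequency": a["frequency"],
                    "mean_steps": a["mean_steps"],
                }
                for a in self.attractors
            ],
        }

    def table(self) -> str:
        lines = [f"{'kind':<13}{'freq':>6}{'mean steps':>12}  representative"]
        for a in self.attractors:
            rep = a["representative"][0]
            shown = ",".join(f"{k}={v}" for k, v in sorted(rep.items()))
            if len(a["representative"]) > 1:
                shown += f" ... (period {len(a['representative'])})"
            lines.append(
                f"{a['kind']:<13}{a['frequency']:>6}{a['mean_steps']:>12.2f}  {shown}"
            )
        lines.append(f"total runs: {self.total_runs}")
        return "\n".join(lines)


def _attractor_representative(traj: Trajectory, order: Sequence[str]) -> Tuple[str, tuple]:
    """Canonical label of the attractor a trajectory fell into.

    Steady states are represented by the final configuration; cycles by the
    lexicographically least rotation of the cycle's configuration sequence.
    """
    if traj.termination == "steady_state":
        return "steady_state", (traj.final.as_tuple(order),)
    if traj.termination == "cycle":
        period = [
            c.as_tuple(order) for c in traj.configurations[traj.cycle_start:-1]
        ]
        if not period:
            period = [traj.final.as_tuple(order)]
        rotations = [
            tuple(period[i:] + period[:i]) for i in range(len(period))
        ]
        return "cycle", min(rotations)
    return "max_steps", (traj.final.as_tuple(order),)


def _absorption_steps(traj: Trajectory) -> int:
    if traj.termination == "cycle":
        return traj.cycle_start
    # steady_state / max_steps: first step of the final run of identical
    # configurations
    final = traj.final.states
    i = len(traj.configurations) - 1
    while i > 0 and traj.configurations[i - 1].states == final:
        i -= 1
    return i


def batch_simulate(
    network: Network,
    initial_conditions: Optional[Iterable[Dict[str, int]]] = None,
    exhaustive_nodes: Optional[Sequence[str]] = None,
    n_random: Optional[int] = None,
    seed: Optional[int] = None,
    max_steps: Optional[int] = 100,
) -> BatchSummary:
    """Gather attractor statistics over many initial conditions.

    Exactly one of the three modes must be chosen: an explicit list of
    initial-state mappings, an exhaustive sweep over all 10^k assignments
    to ``exhaustive_nodes``, or ``n_random`` uniform draws (``seed``
    mandatory for reproducibility).
    """
    modes = sum(x is not None for x in (initial_conditions, exhaustive_nodes, n_random))
    if modes != 1:
        raise NetworkError(
            "choose exactly one of initial_conditions / exhaustive_nodes / n_random"
        )

    if exhaustive_nodes is not None:
        if not exhaustive_nodes:
            raise NetworkError("exhaustive mode needs at least one node")
        conditions = (
            dict(zip(exhaustive_nodes, combo))
            for combo in itertools.product(range(STATE_MAX + 1), repeat=len(exhaustive_nodes))
        )
    elif n_random is not None:
        if seed is None:
            raise NetworkError("random batch mode requires an explicit seed")
        rng = random.Random(seed)
        free = [nid for nid, n in network.nodes.items() if not n.is_signal]
        conditions = (
            {nid: rng.randint(STATE_MIN, STATE_MAX) for nid in free}
            for _ in range(n_random)
        )
    else:
        conditions = iter(initial_conditions)

    order = network.node_ids()
    buckets: Dict[tuple, dict] = {}
    total = 0
    for cond in conditions:
        traj = simulate(network, max_steps=max_steps, initial=cond)
        kind, rep = _attractor_representative(traj, order)
        steps = _absorption_steps(traj)
        b = buckets.setdefault(
            (kind, rep), {"kind": kind, "rep": rep, "freq": 0, "steps": 0}
        )
        b["freq"] += 1
        b["steps"] += steps
        total += 1
    if total == 0:
        raise NetworkError("batch mode received an empty set of initial conditions")

    summary = BatchSummary(total_runs=total)
    for b in sorted(buckets.values(), key=lambda b: (-b["freq"], b["rep"])):
        reps = [dict(zip(order, states)) for states in b["rep"]]
        summary.attractors.append(
            {
                "kind": b["kind"],
                "representative": reps,
                "frequency": b["freq"],
                "mean_steps": b["steps"] / b["freq"],
            }
        )
    return summary
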