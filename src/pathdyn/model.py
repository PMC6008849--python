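"""Core data model for discrete regulatory networks.

A network is a directed graph of typed nodes (genes, compounds, complexes,
external signals) connected by signed, integer-weighted edges that may carry
a propagation delay.  Node activity is an integer state on the 0--9 scale
(0 = inactive, 9 = maximal activity).  Edges of type ``self_degradation``
model the routine decay of biological material and are added automatically
to every non-signal node by :meth:`Network.finalize`.

The model also supports *blocking rules* -- conditions under which a set of
blocker nodes suppresses the contribution of one specific edge -- and
*signal nodes*, whose state follows a user-defined periodic pattern instead
of the transition rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

STATE_MIN = 0
STATE_MAX = 9

NODE_KINDS = ("gene", "compound", "complex", "signal", "custom")

SELF_DEGRADATION = "self_degradation"


class NetworkError(ValueError):
    """Raised when an operation would violate a network invariant."""


def _check_state(value: int, what: str = "state") -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise NetworkError(f"{what} must be an integer, got {value!r}")
    if not (STATE_MIN <= value <= STATE_MAX):
        raise NetworkError(
            f"{what} must lie in [{STATE_MIN}, {STATE_MAX}], got {value}"
        )
    return int(value)


@dataclass(frozen=True)
class NodeSpec:
    """A network node.

    Parameters
    ----------
    id:
        Unique, case-sensitive identifier.
    aliases:
        All entity names the node answers to (database names are preserved
        when nodes are fused so the same entity can be matched under
        different names).  Always contains ``id``.
    kind:
        One of ``gene``, ``compound``, ``complex``, ``signal``, ``custom``.
    initial_state:
        Integer activity level in [0, 9] at time step 0.
    signal_pattern:
        For ``signal`` nodes only: the periodic sequence of states the node
        cycles through, overriding the transition rule.
    """

    id: str
    aliases: frozenset = field(default_factory=frozenset)
    kind: str = "gene"
    initial_state: int = 0
    signal_pattern: Optional[tuple] = None

    def __post_init__(self):
        if not self.id or not isinstance(self.id, str):
            raise NetworkError(f"node id must be a nonempty string, got {self.id!r}")
        if self.kind not in NODE_KINDS:
            raise NetworkError(
                f"node {self.id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}"
            )
        aliases = frozenset(self.aliases) | {self.id}
        object.__setattr__(self, "aliases", aliases)
        _check_state(self.initial_state, f"node {self.id!r} initial_state")
        if self.kind == "signal":
            if not self.signal_pattern:
                raise NetworkError(
                    f"signal node {self.id!r} requires a nonempty signal_pattern"
                )
            pattern = tuple(
                _check_state(s, f"signal {self.id!r} pattern value")
                for s in self.signal_pattern
            )
            object.__setattr__(self, "signal_pattern", pattern)
        elif self.signal_pattern:
            raise NetworkError(
                f"node {self.id!r}: signal_pattern is only valid for signal nodes"
            )
        else:
            object.__setattr__(self, "signal_pattern", None)

    @property
    def is_signal(self) -> bool:
        return self.kind == "signal"


@dataclass(frozen=True)
class EdgeSpec:
    """A directed interaction ``source -> target``.

    ``weight`` is a nonzero signed integer (positive = activation-like,
    negative = inhibition-like); ``delay`` is the number of time steps by
    which the source state is read in the past.
    """

    source: str
    target: str
    interaction_type: str = "custom"
    weight: int = 1
    delay: int = 0

    def __post_init__(self):
        if self.weight == 0:
            raise NetworkError(
                f"edge {self.source!r}->{self.target!r}: weight must be nonzero"
            )
        if not isinstance(self.weight, int) or isinstance(self.weight, bool):
            raise NetworkError(
                f"edge {self.source!r}->{self.target!r}: weight must be an integer"
            )
        if self.delay < 0 or not isinstance(self.delay, int):
            raise NetworkError(
                f"edge {self.source!r}->{self.target!r}: delay must be a nonnegative integer"
            )

    @property
    def key(self) -> tuple:
        return (self.source, self.target, self.interaction_type)


@dataclass(frozen=True)
class BlockingRule:
    """Blocker nodes suppressing one edge's contribution.

    When active, the rule removes every parallel edge between ``edge``'s
    endpoints from the net-effect sum.  ``mode='all'`` requires every
    blocker to be active (state >= ``threshold``); ``mode='any'`` requires
    at least one.  ``active_steps`` restricts the rule to specific time
    steps (``None`` = every step).
    """

    blockers: frozenset
    edge: tuple  # (source id, target id)
    mode: str = "all"
    active_steps: Optional[frozenset] = None
    threshold: int = 1

    def __post_init__(self):
        blockers = frozenset(self.blockers)
        if not blockers:
            raise NetworkError("blocking rule requires at least one blocker node")
        object.__setattr__(self, "blockers", blockers)
        object.__setattr__(self, "edge", (self.edge[0], self.edge[1]))
        if self.mode not in ("all", "any"):
            raise NetworkError(f"blocking mode must be 'all' or 'any', got {self.mode!r}")
        if self.active_steps is not None:
            object.__setattr__(self, "active_steps", frozenset(self.active_steps))
        if self.threshold < 1:
            raise NetworkError("blocker activity threshold must be >= 1")

    def is_active(self, states, t: int) -> bool:
        """Whether the rule suppresses its edge at step ``t`` given pre-step states."""
        if self.active_steps is not None and t not in self.active_steps:
            return False
        hits = (states[b] >= self.threshold for b in self.blockers)
        return all(hits) if self.mode == "all" else any(hits)


@dataclass(frozen=True)
class Configuration:
    """Total assignment of a state in [0, 9] to every node at one time step."""

    states: dict
    time: int = 0

    def __post_init__(self):
        object.__setattr__(self, "states", dict(self.states))
        for node, s in self.states.items():
            _check_state(s, f"state of {node!r}")
        if self.time < 0:
            raise NetworkError("time step must be nonnegative")

    def __getitem__(self, node_id: str) -> int:
        return self.states[node_id]

    def as_tuple(self, order: Sequence[str]) -> tuple:
        return tuple(self.states[n] for n in order)

    def same_states(self, other: "Configuration") -> bool:
        return self.states == other.states


@dataclass(frozen=True)
class Trajectory:
    """An ordered run of configurations with a termination verdict.

    ``termination`` is ``steady_state`` (a fixed point was reached),
    ``cycle`` (the dynamical state recurred; ``cycle_start`` indexes the
    earlier occurrence) or ``max_steps`` (the step cap was hit first).
    """

    configurations: tuple
    termination: str
    cycle_start: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "configurations", tuple(self.configurations))
        if self.termination not in ("steady_state", "cycle", "max_steps"):
            raise NetworkError(f"unknown termination {self.termination!r}")
        if self.termination == "cycle" and self.cycle_start is None:
            raise NetworkError("cycle termination requires cycle_start")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def node_ids(self) -> frozenset:
        return frozenset(self.configurations[0].states)

    def series(self, node_id: str) -> tuple:
        """The node's state at every recorded time step."""
        return tuple(c.states[node_id] for c in self.configurations)

    @property
    def final(self) -> Configuration:
        return self.configurations[-1]


class Network:
    """Mutable directed network of :class:`NodeSpec` / :class:`EdgeSpec`.

    Editing operations (``add_node``, ``add_edge``, ``remove_node``,
    ``remove_edge``, ``finalize``) mutate in place and return ``self`` so
    they chain; :meth:`copy` gives an independent deep copy.  Two networks
    compare equal when they hold the same nodes, edges and blocking rules.
    """

    def __init__(
        self,
        nodes: Iterable[NodeSpec] = (),
        edges: Iterable[EdgeSpec] = (),
        blocking_rules: Iterable[BlockingRule] = (),
    ):
        self._nodes: dict = {}
        self._edges: dict = {}
        self._rules: list = []
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)
        for r in blocking_rules:
            self.add_blocking_rule(r)

    # -- access ---------------------------------------------------------

    @property
    def nodes(self) -> dict:
        """Mapping node id -> :class:`NodeSpec` (read-only view semantics)."""
        return self._nodes

    @property
    def edges(self) -> dict:
        """Mapping (source, target, interaction_type) -> :class:`EdgeSpec`."""
        return self._edges

    @property
    def blocking_rules(self) -> tuple:
        return tuple(self._rules)

    def node_ids(self) -> list:
        return sorted(self._nodes)

    def in_edges(self, node_id: str) -> list:
        return [e for e in self._edges.values() if e.target == node_id]

    def out_edges(self, node_id: str) -> list:
        return [e for e in self._edges.values() if e.source == node_id]

    @property
    def max_delay(self) -> int:
        return max((e.delay for e in self._edges.values()), default=0)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __eq__(self, other):
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and self._edges == other._edges
            and sorted(self._rules, key=repr) == sorted(other._rules, key=repr)
        )

    def __repr__(self):
        return (
            f"Network({len(self._nodes)} nodes, {len(self._edges)} edges, "
            f"{len(self._rules)} blocking rules)"
        )

    def copy(self) -> "Network":
        return Network(self._nodes.values(), self._edges.values(), self._rules)

    # -- editing --------------------------------------------------------

    def add_node(self, node: NodeSpec) -> "Network":
        """Add ``node``; rejects a duplicate id.

        No self-degradation loop is attached here -- :meth:`finalize` does
        that, and signal nodes never receive one.
        """
        if node.id in self._nodes:
            raise NetworkError(f"node id {node.id!r} already present")
        self._nodes[node.id] = node
        return self

    def add_edge(self, edge: EdgeSpec) -> "Network":
        """Add ``edge``, replacing any edge with the same (source, target, type)."""
        if edge.source not in self._nodes:
            raise NetworkError(f"edge source {edge.source!r} is not a network node")
        if edge.target not in self._nodes:
            raise NetworkError(f"edge target {edge.target!r} is not a network node")
        self._edges[edge.key] = edge
        return self

    def add_blocking_rule(self, rule: BlockingRule) -> "Network":
        missing = [b for b in rule.blockers if b not in self._nodes]
        if missing:
            raise NetworkError(f"blocking rule references unknown nodes {sorted(missing)}")
        src, tgt = rule.edge
        if not any(k[0] == src and k[1] == tgt for k in self._edges):
            raise NetworkError(f"blocking rule targets absent edge {src!r}->{tgt!r}")
        self._rules.append(rule)
        return self

    def remove_node(self, node_id: str) -> "Network":
        """Remove the node, all incident edges and any blocking rule naming it."""
        if node_id not in self._nodes:
            raise NetworkError(f"cannot remove unknown node {node_id!r}")
        del self._nodes[node_id]
        self._edges = {
            k: e
            for k, e in self._edges.items()
            if e.source != node_id and e.target != node_id
        }
        kept = []
        for r in self._rules:
            touches = (
                node_id in r.blockers or node_id in r.edge
                or not any(k[0] == r.edge[0] and k[1] == r.edge[1] for k in self._edges)
            )
            if touches:
                logger.info(
                    "dropping blocking rule on edge %s->%s: depends on removed node %r",
                    r.edge[0], r.edge[1], node_id,
                )
            else:
                kept.append(r)
        self._rules = kept
        return self

    def remove_edge(self, source: str, target: str, interaction_type: str) -> "Network":
        key = (source, target, interaction_type)
        if key not in self._edges:
            raise NetworkError(
                f"cannot remove absent edge {source!r}->{target!r} ({interaction_type})"
            )
        del self._edges[key]
        if not any(k[0] == source and k[1] == target for k in self._edges):
            kept = []
            for r in self._rules:
                if r.edge == (source, target):
                    logger.info(
                        "dropping blocking rule on removed edge %s->%s", source, target
                    )
                else:
                    kept.append(r)
            self._rules = kept
        return self

    def set_initial_state(self, node_id: str, state: int) -> "Network":
        if node_id not in self._nodes:
            raise NetworkError(f"unknown node {node_id!r}")
        _check_state(state, f"initial state of {node_id!r}")
        self._nodes[node_id] = replace(self._nodes[node_id], initial_state=state)
        return self

    def finalize(self, self_weight: int = -1) -> "Network":
        """Attach a self-degradation loop to every non-signal node.

        Biological material decays, so each gene/compound/complex/custom
        node gets one ``self_degradation`` self-edge of weight
        ``self_weight`` (default -1).  Signal nodes follow their preset
        pattern and are exempt.  Idempotent: existing loops are kept as-is.
        """
        if self_weight == 0:
            raise NetworkError("self-degradation weight must be nonzero")
        for node_id, node in self._nodes.items():
            if node.is_signal:
                continue
            key = (node_id, node_id, SELF_DEGRADATION)
            if key not in self._edges:
                self._edges[key] = EdgeSpec(
                    node_id, node_id, SELF_DEGRADATION, self_weight
                )
        return self

    def is_finalized(self) -> bool:
        return all(
            n.is_signal or (nid, nid, SELF_DEGRADATION) in self._edges
            for nid, n in self._nodes.items()
        )

    def initial_configuration(self) -> Configuration:
        """The t=0 configuration: initial states, signal nodes at pattern[0]."""
        states = {}
        for nid, n in self._nodes.items():
            states[nid] = n.signal_pattern[0] if n.is_signal else n.initial_state
        return Configuration(states, time=0)

    def validate(self) -> None:
        """Check referential and (per-kind) alias-disjointness invariants."""
        for e in self._edges.values():
            if e.source not in self._nodes or e.target not in self._nodes:
                raise NetworkError(f"edge {e.key} references unknown nodes")
        seen: dict = {}
        for n in self._nodes.values():
            for a in n.aliases:
                key = (n.kind, a)
                if key in seen and seen[key] != n.id:
                    raise NetworkError(
                        f"alias {a!r} shared by nodes {seen[key]!r} and {n.id!r} "
                        f"of kind {n.kind!r}"
                    )
                seen[key] = n.id


# Thin functional wrappers over the Network methods; they operate on a copy
# so callers that prefer a value-style API keep the original untouched.

def add_node(network: Network, node: NodeSpec) -> Network:
    return network.copy().add_node(node)


def add_edge(network: Network, edge: EdgeSpec) -> Network:
    return network.copy().add_edge(edge)


def remove_node(network: Network, node_id: str) -> Network:
    return network.copy().remove_node(node_id)


def remove_edge(network: Network, source: str, target: str, interaction_type: str) -> Network:
    return network.copy().remove_edge(source, target, interaction_type)


def finalize(network: Network, self_weight: int = -1) -> Network:
    return network.copy().finalize(self_weight)
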