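"""Shared fixtures and independent oracles.

The oracle functions here deliberately re-derive behavior from first
principles (literal readings of the transition rule, brute-force graph
scans, naive set algebra) and never call the code paths they check.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from pathdyn.fixtures import random_network, toy_feedback_network

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from pathdyn.model import EdgeSpec, Network, NodeSpec


@pytest.fixture
def toy_network():
    return toy_feedback_network()


@pytest.fixture
def small_network():
    """Two genes with mutual activation, finalized."""
    net = Network(
        nodes=[NodeSpec("A", initial_state=5), NodeSpec("B", initial_state=0)],
        edges=[
            EdgeSpec("A", "B", "activation", 2),
            EdgeSpec("B", "A", "activation", 2),
        ],
    )
    return net.finalize(-1)


# ---------------------------------------------------------------------------
# oracles


def naive_run(network: Network, n_steps: int):
    """Literal transition rule, no delays/blocks: next state moves by the
    sign of sum(state(source) * weight) over incoming edges, clamped to
    [0, 9]; signal nodes replay their pattern.  Returns the list of state
    dicts for t = 0..n_steps."""
    states = {}
    for nid, node in network.nodes.items():
        states[nid] = node.signal_pattern[0] if node.is_signal else node.initial_state
    out = [dict(states)]
    for t in range(n_steps):
        nxt = {}
        for nid, node in network.nodes.items():
            if node.is_signal:
                nxt[nid] = node.signal_pattern[(t + 1) % len(node.signal_pattern)]
                continue
            net_eff = 0
            for e in network.edges.values():
                if e.target == nid:
                    net_eff += states[e.source] * e.weight
            if net_eff > 0:
                nxt[nid] = min(9, states[nid] + 1)
            elif net_eff < 0:
                nxt[nid] = max(0, states[nid] - 1)
            else:
                nxt[nid] = states[nid]
        states = nxt
        out.append(dict(states))
    return out


def naive_diff(series_a, series_b):
    """Literal differential definition on two equal-length series."""
    dist = sum((x - y) ** 2 for x, y in zip(series_a, series_b)) ** 0.5
    gaps = [abs(x - y) for x, y in zip(series_a, series_b)]
    return dist, gaps[0], max(gaps), max(gaps) > gaps[0]


def naive_components(network: Network):
    """Union-find over undirected edge pairs, self-loops ignored."""
    parent = {n: n for n in network.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in network.edges.values():
        if e.source == e.target:
            continue
        ra, rb = find(e.source), find(e.target)
        if ra != rb:
            parent[rb] = ra
    comps = {}
    for n in network.nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=lambda c: (-len(c), sorted(c)))


def naive_out_degrees(network: Network):
    """Per-node count of outgoing non-self-degradation edges."""
    from pathdyn.model import SELF_DEGRADATION

    deg = {n: 0 for n in network.nodes}
    for e in network.edges.values():
        if e.interaction_type == SELF_DEGRADATION and e.source == e.target:
            continue
        deg[e.source] += 1
    return deg


def naive_alias_classes(alias_sets):
    """Transitive closure of alias overlap by repeated pairwise merging."""
    classes = [set(a) for a in alias_sets]
    changed = True
    while changed:
        changed = False
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if classes[i] & classes[j]:
                    classes[i] |= classes[j]
                    del classes[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(frozenset(c) for c in classes)


def random_trajectory_pair(rng: random.Random, n_nodes=4, length=12):
    """Two random same-shape state series sets, as plain dicts."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    a = {n: [rng.randint(0, 9) for _ in range(length)] for n in nodes}
    b = {n: [rng.randint(0, 9) for _ in range(length)] for n in nodes}
    return nodes, a, b


__all__ = [
    "naive_run", "naive_diff", "naive_components", "naive_out_degrees",
    "naive_alias_classes", "random_trajectory_pair", "random_network",
]
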