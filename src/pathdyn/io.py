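"""Serialization: GraphML / SIF network exchange, trajectory CSV, sidecars.

Networks round-trip through GraphML (node attributes ``kind``,
``initial_state``, ``aliases`` joined by ``|``, and a ``gray`` intensity in
0--255 derived from the initial state for generic graph viewers; edge
attributes ``interaction_type``, ``weight``, ``delay``).  Signal patterns
and blocking rules do not fit GraphML's flat attribute model and live in a
YAML sidecar (``<network>.rules.yaml`` by default) with the schema::

    signal_patterns:
      NODE_ID: [9, 0, 9]        # states replayed cyclically
    blocking_rules:
      - blockers: [X1, X2]
        edge: [Y, Z]
        mode: all               # or "any"
        active_steps: [3, 4]    # omit for "every step"
        threshold: 1

Trajectories are written as wide CSV (one row per time step, one column
per node) with a JSON sidecar holding the termination verdict, and can be
re-read losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd
import yaml

from .model import (
    STATE_MAX,
    BlockingRule,
    Configuration,
    EdgeSpec,
    Network,
    NetworkError,
    NodeSpec,
    Trajectory,
)

ALIAS_SEP = "|"


def _gray(state: int) -> int:
    # darker = more active, for viewers that only understand a scalar
    return round(255 * (1 - state / STATE_MAX))


def network_to_graphml(network: Network, path, sidecar: Optional[str] = None) -> None:
    """Write the network as GraphML plus a rules sidecar (YAML).

    ``sidecar`` defaults to ``<path>.rules.yaml``; it is written only when
    the network has signal patterns or blocking rules.
    """
    g = nx.MultiDiGraph()
    for nid, node in network.nodes.items():
        g.add_node(
            nid,
            kind=node.kind,
            initial_state=node.initial_state,
            aliases=ALIAS_SEP.join(sorted(node.aliases)),
            gray=_gray(node.initial_state),
        )
    for e in network.edges.values():
        g.add_edge(
            e.source,
            e.target,
            key=e.interaction_type,
            interaction_type=e.interaction_type,
            weight=e.weight,
            delay=e.delay,
        )
    nx.write_graphml(g, path)

    patterns = {
        nid: list(n.signal_pattern)
        for nid, n in network.nodes.items()
        if n.signal_pattern
    }
    rules = [
        {
            "blockers": sorted(r.blockers),
            "edge": list(r.edge),
            "mode": r.mode,
            **({"active_steps": sorted(r.active_steps)} if r.active_steps is not None else {}),
            "threshold": r.threshold,
        }
        for r in network.blocking_rules
    ]
    if patterns or rules:
        target = Path(sidecar) if sidecar else Path(str(path) + ".rules.yaml")
        with open(target, "w") as fh:
            yaml.safe_dump(
                {"signal_patterns": patterns, "blocking_rules": rules}, fh
            )


def network_from_graphml(path, sidecar: Optional[str] = None) -> Network:
    """Re-read a network written by :func:`network_to_graphml`."""
    g = nx.read_graphml(path, force_multigraph=True)

    patterns: dict = {}
    rules_doc: list = []
    target = Path(sidecar) if sidecar else Path(str(path) + ".rules.yaml")
    if target.exists():
        with open(target) as fh:
            doc = yaml.safe_load(fh) or {}
        patterns = doc.get("signal_patterns", {}) or {}
        rules_doc = doc.get("blocking_rules", []) or []

    nodes = []
    for nid, attrs in g.nodes(data=True):
        kind = attrs.get("kind", "gene")
        aliases = frozenset(
            a for a in str(attrs.get("aliases", nid)).split(ALIAS_SEP) if a
        )
        nodes.append(
            NodeSpec(
                id=str(nid),
                aliases=aliases,
                kind=kind,
                initial_state=int(attrs.get("initial_state", 0)),
                signal_pattern=tuple(patterns[nid]) if nid in patterns else None,
            )
        )
    edges = [
        EdgeSpec(
            source=str(u),
            target=str(v),
            interaction_type=str(attrs.get("interaction_type", key)),
            weight=int(attrs.get("weight", 1)),
            delay=int(attrs.get("delay", 0)),
        )
        for u, v, key, attrs in g.edges(keys=True, data=True)
    ]
    rules = [
        BlockingRule(
            blockers=frozenset(r["blockers"]),
            edge=tuple(r["edge"]),
            mode=r.get("mode", "all"),
            active_steps=frozenset(r["active_steps"]) if "active_steps" in r else None,
            threshold=r.get("threshold", 1),
        )
        for r in rules_doc
    ]
    return Network(nodes=nodes, edges=edges, blocking_rules=rules)


def network_to_sif(network: Network, path) -> None:
    """Write ``source <tab> interaction_type <tab> target`` lines."""
    with open(path, "w") as fh:
        for key in sorted(network.edges):
            src, tgt, typ = key
            fh.write(f"{src}\t{typ}\t{tgt}\n")


# ---------------------------------------------------------------------------
# trajectories


def trajectory_to_csv(traj: Trajectory, path, long: bool = False) -> None:
    """Write a trajectory as CSV plus a ``.meta.json`` termination sidecar.

    Wide layout (default): one row per time step, one column per node.
    Long layout: columns ``node,time,state``.
    """
    order = sorted(traj.node_ids)
    if long:
        rows = [
            {"node": n, "time": c.time, "state": c.states[n]}
            for c in traj.configurations
            for n in order
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        df = pd.DataFrame(
            [[c.time] + [c.states[n] for n in order] for c in traj.configurations],
            columns=["time"] + order,
        )
        df.to_csv(path, index=False)
    meta = {"termination": traj.termination, "cycle_start": traj.cycle_start,
            "layout": "long" if long else "wide"}
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def trajectory_from_csv(path) -> Trajectory:
    """Re-read a wide or long trajectory CSV written by :func:`trajectory_to_csv`."""
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    else:
        meta = {"termination": "max_steps", "cycle_start": None, "layout": "wide"}

    df = pd.read_csv(path)
    if meta.get("layout") == "long" or set(df.columns) == {"node", "time", "state"}:
        df = df.pivot(index="time", columns="node", values="state").reset_index()
        df.columns.name = None
    configs = []
    node_cols = [c for c in df.columns if c != "time"]
    for _, row in df.iterrows():
        configs.append(
            Configuration(
                {n: int(row[n]) for n in node_cols}, time=int(row["time"])
            )
        )
    return Trajectory(
        configs,
        termination=meta.get("termination", "max_steps"),
        cycle_start=meta.get("cycle_start"),
    )


def plot_trajectory(traj: Trajectory, path, nodes: Optional[list] = None) -> None:
    """State-versus-time line plot (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = nodes or sorted(traj.node_ids)
    times = [c.time for c in traj.configurations]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for n in order:
        ax.step(times, traj.series(n), where="post", label=n)
    ax.set_xlabel("time step")
    ax.set_ylabel("state")
    ax.set_ylim(-0.5, STATE_MAX + 0.5)
    ax.set_yticks(range(STATE_MAX + 1))
    ax.legend(loc="upper right", fontsize="small", ncol=2)
    ax.set_title(f"termination: {traj.termination}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def diff_report_to_csv(report, path) -> None:
    """``node,distance,initial_gap,max_gap,differential`` rows."""
    pd.DataFrame(report.to_rows()).to_csv(path, index=False)
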