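"""Per-node comparison of two simulations of the same network.

Given trajectories of the same network under two conditions (e.g. disease
vs. healthy expression, or drug vs. control), each node gets a plain
Euclidean distance between its two state series and a *differential* flag.
The flag filters out nodes whose difference is merely inherited from their
different initial states: a node is differential only when the gap between
its states in the two runs grows, at some time step, strictly beyond the
initial gap.  The constant-offset case (e.g. [5,5,5] vs [3,3,3]) is
therefore never flagged even though its distance is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

from .model import NetworkError, Trajectory


@dataclass
class NodeDiff:
    euclidean_distance: float
    initial_gap: int
    max_gap: int
    differential: bool


@dataclass
class DiffReport:
    """Per-node distances and differential flags for one trajectory pair."""

    nodes: Dict[str, NodeDiff] = field(default_factory=dict)
    aligned_length: int = 0

    @property
    def differential_nodes(self) -> list:
        return sorted(n for n, d in self.nodes.items() if d.differential)

    @property
    def differential_fraction(self) -> float:
        if not self.nodes:
            return 0.0
        return len(self.differential_nodes) / len(self.nodes)

    def to_rows(self) -> list:
        rows = []
        for name in sorted(self.nodes):
            d = self.nodes[name]
            rows.append(
                {
                    "node": name,
                    "distance": d.euclidean_distance,
                    "initial_gap": d.initial_gap,
                    "max_gap": d.max_gap,
                    "differential": d.differential,
                }
            )
        return rows

    def summary(self) -> str:
        k = len(self.differential_nodes)
        n = len(self.nodes)
        pct = 100.0 * k / n if n else 0.0
        return f"differential nodes: {k}/{n} ({pct:.1f}%)"


def _extend(traj: Trajectory, length: int, node: str) -> Tuple[int, ...]:
    """The node's series extended to ``length`` steps.

    A steady (or capped) trajectory repeats its final state; a cyclic one
    continues around its cycle.
    """
    series = traj.series(node)
    if len(series) >= length:
        return series[:length]
    if traj.termination == "cycle":
        period = series[traj.cycle_start:-1] or (series[-1],)
        ext = list(series)
        while len(ext) < length:
            ext.append(period[(len(ext) - traj.cycle_start) % len(period)])
        return tuple(ext)
    return series + (series[-1],) * (length - len(series))


def align(
    a: Trajectory, b: Trajectory, truncate: bool = False
) -> Tuple[Dict[str, Tuple[tuple, tuple]], int]:
    """Equal-length per-node state series for two trajectories.

    By default the shorter trajectory is continued (final state repeated,
    or cycle unrolled) up to the longer one's length; with
    ``truncate=True`` both are cut to the shorter length instead.
    """
    if a.node_ids != b.node_ids:
        only_a = sorted(a.node_ids - b.node_ids)
        only_b = sorted(b.node_ids - a.node_ids)
        raise NetworkError(
            f"trajectories cover different node sets: only in first {only_a}, "
            f"only in second {only_b}"
        )
    length = min(len(a), len(b)) if truncate else max(len(a), len(b))
    out = {
        n: (_extend(a, length, n), _extend(b, length, n)) for n in sorted(a.node_ids)
    }
    return out, length


def node_distance(series_a: Sequence[int], series_b: Sequence[int]) -> float:
    """Euclidean distance between two equal-length state series:
    sqrt(sum_t (a(t) - b(t))^2)."""
    if len(series_a) != len(series_b):
        raise NetworkError(
            f"series length mismatch: {len(series_a)} vs {len(series_b)}"
        )
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(series_a, series_b)))


def differential_nodes(
    a: Trajectory, b: Trajectory, truncate: bool = False
) -> DiffReport:
    """Full per-node comparison of two runs.

    For each node: ``initial_gap = |a(0) - b(0)|``, ``max_gap`` the largest
    per-step gap over the aligned range, the Euclidean distance, and
    ``differential = (max_gap > initial_gap)`` -- strictly larger, so a
    constant inherited offset never counts.
    """
    aligned, length = align(a, b, truncate=truncate)
    report = DiffReport(aligned_length=length)
    for node, (sa, sb) in aligned.items():
        gaps = [abs(x - y) for x, y in zip(sa, sb)]
        initial_gap = gaps[0]
        max_gap = max(gaps)
        report.nodes[node] = NodeDiff(
            euclidean_distance=node_distance(sa, sb),
            initial_gap=initial_gap,
            max_gap=max_gap,
            differential=max_gap > initial_gap,
        )
    return report


def intersect_differential(r1: DiffReport, r2: DiffReport) -> list:
    """Nodes flagged differential in both reports (downstream plumbing)."""
    return sorted(set(r1.differential_nodes) & set(r2.differential_nodes))
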