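"""Expression input and discretization to initial node states.

Expression levels arrive as a two-column ``name,value`` CSV.  Values are
normalized to the model's 0--9 activity scale **for the whole network at
once**, dividing by the maximal expression level matched anywhere in the
network rather than per-gene.  A consequence the user should know: a single
extreme outlier compresses every other node into a narrow low range, so
log-scale expression data is recommended; no log transform is applied
automatically.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Dict

from .model import STATE_MAX, Network, NetworkError

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Raised for malformed expression input."""


@dataclass
class ExpressionTable:
    """Mapping entity name -> real-valued expression level."""

    values: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.values.items():
            if not name or not isinstance(name, str):
                raise ExpressionError(f"entity name must be a nonempty string: {name!r}")
            if not (float("-inf") < float(v) < float("inf")):
                raise ExpressionError(f"expression value for {name!r} is not finite: {v!r}")
            self.values[name] = float(v)


def read_expression_csv(source, sep: str = ",") -> ExpressionTable:
    """Read a two-column ``name,value`` file (path, file object or string).

    An optional header row (non-numeric second field on line 1) is skipped.
    Duplicate names keep the last occurrence, with a warning.  A
    non-numeric value on a data row is an error naming the line.
    """
    if hasattr(source, "read"):
        fh = source
        close = False
    elif isinstance(source, str) and ("\n" in source or sep in source):
        fh = io.StringIO(source)
        close = False
    else:
        fh = open(source)
        close = True
    try:
        values: Dict[str, float] = {}
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise ExpressionError(
                    f"line {lineno}: expected 'name{sep}value', got {raw!r}"
                )
            name, value_str = parts[0], parts[1]
            try:
                value = float(value_str)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ExpressionError(
                    f"line {lineno}: non-numeric value {value_str!r} for {name!r}"
                ) from None
            if name in values:
                logger.warning(
                    "duplicate expression entry for %r at line %d; keeping the last",
                    name, lineno,
                )
            values[name] = value
        return ExpressionTable(values)
    finally:
        if close:
            fh.close()


def write_states_csv(states: Dict[str, int], path) -> None:
    """Write a ``name,state`` CSV of discretized states."""
    with open(path, "w") as fh:
        fh.write("name,state\n")
        for name in sorted(states):
            fh.write(f"{name},{states[name]}\n")


def _round_half_up(x: float) -> int:
    # round half away from zero; inputs here are nonnegative
    return int(x + 0.5)


def normalize_states(table: ExpressionTable, network: Network) -> Dict[str, int]:
    """Discretize expression values onto [0, 9] for every network node.

    A node matches a table row when any of its aliases equals the row name
    (exact, case-sensitive).  With ``M`` the maximal matched value over the
    whole network, a matched node gets ``round(9 * value / M)`` (half away
    from zero), clamped to [0, 9]; nonpositive values and unmatched nodes
    (typically compounds and complexes absent from expression data) get 0.
    """
    if not network.nodes:
        raise NetworkError("cannot normalize states for an empty network")

    matched: Dict[str, float] = {}
    for nid, node in network.nodes.items():
        hits = {a: table.values[a] for a in node.aliases if a in table.values}
        if not hits:
            continue
        if len(set(hits.values())) > 1:
            logger.warning(
                "node %r matches %d expression rows with differing values %s; "
                "taking the maximum", nid, len(hits), sorted(hits.values()),
            )
        matched[nid] = max(hits.values())

    positive = [v for v in matched.values() if v > 0]
    states = {nid: 0 for nid in network.nodes}
    if not positive:
        return states
    m = max(positive)
    for nid, v in matched.items():
        if v <= 0:
            continue
        states[nid] = min(STATE_MAX, _round_half_up(STATE_MAX * v / m))
    return states


def apply_initial_states(network: Network, states: Dict[str, int]) -> Network:
    """Set initial states in place; signal nodes keep their preset pattern.

    Names in ``states`` that are not node ids are matched through aliases.
    Out-of-range states raise; unknown names are ignored with a notice.
    """
    alias_index = {}
    for nid, node in network.nodes.items():
        for a in node.aliases:
            alias_index.setdefault(a, nid)

    for name, state in states.items():
        nid = alias_index.get(name)
        if nid is None:
            logger.info("initial state for unknown entity %r ignored", name)
            continue
        node = network.nodes[nid]
        if node.is_signal:
            logger.info(
                "initial state for signal node %r ignored: its pattern governs it", nid
            )
            continue
        network.set_initial_state(nid, state)
    return network
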