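"""KGML pathway parsing and multi-pathway merging.

KGML (KEGG Markup Language) is the per-pathway XML format distributed by
the KEGG database: ``entry`` elements are molecular entities (genes,
compounds, complexes-as-groups, links to other pathway maps), ``relation``
elements are interactions between them, and each relation carries one or
more ``subtype`` elements naming the interaction class (activation,
inhibition, phosphorylation, ...).

This module turns one or more KGML documents into a single
:class:`~pathdyn.model.Network`:

* each relation subtype becomes a signed, weighted edge per a
  :class:`WeightScheme` (unmapped subtypes are skipped, never sign-guessed);
* entities that share any KEGG name -- within one pathway or across
  pathways -- are fused into a single node that keeps the union of names
  as aliases, with all incoming and outgoing edges re-targeted to it;
* self-degradation loops are attached to every non-signal node at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple
from xml.etree import ElementTree

from .model import SELF_DEGRADATION, EdgeSpec, Network, NetworkError, NodeSpec

logger = logging.getLogger(__name__)

#: KGML relation subtypes mapped by default.  Activation-like interactions
#: get +2 to overcome the automatic -1 self-degradation loop; inhibition-like
#: interactions get -1.
DEFAULT_SUBTYPE_WEIGHTS = {
    "activation": 2,
    "expression": 2,
    "phosphorylation": 2,
    "inhibition": -1,
    "repression": -1,
    "dephosphorylation": -1,
}

_ENTRY_KIND = {
    "gene": "gene",
    "ortholog": "gene",
    "enzyme": "gene",
    "compound": "compound",
    "group": "complex",
}


class KGMLParseError(ValueError):
    """Raised for malformed KGML input."""


@dataclass(frozen=True)
class WeightScheme:
    """Assignment of edge weights per KGML relation subtype.

    ``subtype_weights`` maps subtype names to nonzero signed integers;
    subtypes absent from the mapping are skipped during import.
    ``self_weight`` is the weight of the automatic self-degradation loop.
    """

    subtype_weights: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_WEIGHTS))
    self_weight: int = -1

    def __post_init__(self):
        object.__setattr__(self, "subtype_weights", dict(self.subtype_weights))
        for name, w in self.subtype_weights.items():
            if not isinstance(w, int) or isinstance(w, bool) or w == 0:
                raise NetworkError(
                    f"weight for subtype {name!r} must be a nonzero integer, got {w!r}"
                )
        if self.self_weight == 0:
            raise NetworkError("self-degradation weight must be nonzero")

    @classmethod
    def from_file(cls, path) -> "WeightScheme":
        """Load a scheme from YAML or JSON: ``{subtypes: {name: weight}, self_weight: int}``."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise KGMLParseError(f"weight scheme file {path}: expected a mapping")
        return cls(
            subtype_weights=doc.get("subtypes", dict(DEFAULT_SUBTYPE_WEIGHTS)),
            self_weight=doc.get("self_weight", -1),
        )

    def to_file(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {"subtypes": dict(self.subtype_weights), "self_weight": self.self_weight},
                fh,
            )


@dataclass
class PathwayEntry:
    entry_id: str
    entry_type: str
    names: tuple
    members: tuple = ()  # entry ids, for groups


@dataclass
class PathwayRelation:
    source: str
    target: str
    subtypes: tuple


@dataclass
class PathwayGraph:
    """Parsed content of one KGML document."""

    pathway_id: str
    entries: List[PathwayEntry]
    relations: List[PathwayRelation]


@dataclass
class ImportReport:
    """Provenance of an import: what was fused, skipped, and counted."""

    fused_groups: list = field(default_factory=list)  # list of sorted alias lists
    skipped_relations: list = field(default_factory=list)  # (pathway, src, tgt, subtype, reason)
    weight_collisions: list = field(default_factory=list)  # (src, tgt, type, kept, dropped)
    per_pathway_counts: dict = field(default_factory=dict)  # id -> {"nodes": n, "edges": m}
    merged_counts: dict = field(default_factory=dict)

    SKIP_REASONS = ("unmapped_subtype", "dangling_endpoint", "map_entry")

    def skip(self, pathway: str, src: str, tgt: str, subtype: str, reason: str) -> None:
        assert reason in self.SKIP_REASONS
        self.skipped_relations.append(
            {"pathway": pathway, "source": src, "target": tgt,
             "subtype": subtype, "reason": reason}
        )

    def extend(self, other: "ImportReport") -> None:
        self.fused_groups.extend(other.fused_groups)
        self.skipped_relations.extend(other.skipped_relations)
        self.weight_collisions.extend(other.weight_collisions)
        self.per_pathway_counts.update(other.per_pathway_counts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "fused_groups": [sorted(g) for g in self.fused_groups],
                "skipped_relations": self.skipped_relations,
                "weight_collisions": self.weight_collisions,
                "per_pathway_counts": self.per_pathway_counts,
                "merged_counts": self.merged_counts,
            },
            indent=2,
            sort_keys=True,
        )

    def summary(self) -> str:
        lines = [
            f"pathways imported: {len(self.per_pathway_counts)}",
            f"fused alias groups: {len(self.fused_groups)}",
            f"skipped relations: {len(self.skipped_relations)}",
            f"weight collisions: {len(self.weight_collisions)}",
        ]
        if self.merged_counts:
            lines.append(
                "merged network: "
                f"{self.merged_counts.get('nodes', '?')} nodes, "
                f"{self.merged_counts.get('edges', '?')} edges"
            )
        return "\n".join(lines)


def parse_kgml(source) -> PathwayGraph:
    """Parse one KGML document (path, file object, or XML string).

    Every ``entry`` and ``relation`` of the file is represented; entry
    ``name`` attributes are split on whitespace into the name list.
    """
    try:
        if isinstance(source, str) and source.lstrip().startswith("<"):
            root = ElementTree.fromstring(source)
            origin = "<string>"
        else:
            root = ElementTree.parse(source).getroot()
            origin = str(source)
    except ElementTree.ParseError as exc:
        raise KGMLParseError(f"malformed KGML in {source!r}: {exc}") from exc
    except OSError as exc:
        raise KGMLParseError(f"cannot read KGML file {source!r}: {exc}") from exc

    if root.tag != "pathway":
        raise KGMLParseError(f"{origin}: root element is {root.tag!r}, expected 'pathway'")

    pathway_id = root.get("name", root.get("title", origin))
    entries: List[PathwayEntry] = []
    entry_ids = set()
    for el in root.findall("entry"):
        eid = el.get("id")
        etype = el.get("type", "gene")
        if eid is None:
            raise KGMLParseError(f"{origin}: entry element without id")
        names = tuple(el.get("name", "").split())
        members = tuple(
            c.get("id") for c in el.findall("component") if c.get("id") is not None
        )
        entries.append(PathwayEntry(eid, etype, names, members))
        entry_ids.add(eid)

    relations: List[PathwayRelation] = []
    for el in root.findall("relation"):
        src, tgt = el.get("entry1"), el.get("entry2")
        if src is None or tgt is None:
            raise KGMLParseError(f"{origin}: relation element missing entry1/entry2")
        subtypes = tuple(
            s.get("name") for s in el.findall("subtype") if s.get("name") is not None
        )
        relations.append(PathwayRelation(src, tgt, subtypes))

    return PathwayGraph(pathway_id=pathway_id, entries=entries, relations=relations)


def _entry_aliases(entry: PathwayEntry, graph: PathwayGraph) -> tuple:
    if entry.entry_type == "group":
        by_id = {e.entry_id: e for e in graph.entries}
        names: set = set()
        for mid in entry.members:
            member = by_id.get(mid)
            if member is not None:
                names.update(member.names)
        return tuple(sorted(names))
    return tuple(sorted(set(entry.names)))


def _fuse_alias_classes(items: Iterable[Tuple[str, frozenset]]) -> dict:
    """Union-find over alias overlap: map each item key to its class root."""
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    items = list(items)
    for key, _ in items:
        parent[key] = key
    owner: dict = {}
    for key, aliases in items:
        for a in aliases:
            if a in owner:
                union(owner[a], key)
            else:
                owner[a] = key
    return {key: find(key) for key, _ in items}


def pathway_to_network(
    graph: PathwayGraph, scheme: Optional[WeightScheme] = None
) -> Tuple[Network, ImportReport]:
    """Convert one parsed pathway to an (unfinalized) network.

    Gene/ortholog/enzyme entries become ``gene`` nodes, compounds become
    ``compound`` nodes, groups become one ``complex`` node whose aliases
    are the union of the member names, and pathway-map link entries are
    dropped.  Duplicate entries naming the same entity are fused
    immediately.  Each relation yields one edge per subtype recognized by
    ``scheme``; unrecognized subtypes are skipped and reported.
    """
    scheme = scheme or WeightScheme()
    report = ImportReport()

    # node construction, fusing same-kind entries with overlapping names
    entry_node: dict = {}  # entry id -> node id (or None if dropped)
    per_kind: dict = {}
    for entry in graph.entries:
        kind = _ENTRY_KIND.get(entry.entry_type)
        if kind is None:  # "map" and anything else non-molecular
            entry_node[entry.entry_id] = None
            continue
        aliases = _entry_aliases(entry, graph)
        if not aliases:
            entry_node[entry.entry_id] = None
            continue
        per_kind.setdefault(kind, []).append((entry.entry_id, frozenset(aliases)))

    node_specs: dict = {}
    for kind, items in per_kind.items():
        roots = _fuse_alias_classes(items)
        classes: dict = {}
        for (eid, aliases) in items:
            classes.setdefault(roots[eid], []).append((eid, aliases))
        for root, members in classes.items():
            alias_union = frozenset().union(*(a for _, a in members))
            if kind == "complex":
                node_id = "+".join(sorted(alias_union))
            else:
                node_id = min(alias_union)
            if len(members) > 1:
                report.fused_groups.append(sorted(alias_union))
            node_specs[node_id] = NodeSpec(
                id=node_id, aliases=alias_union | {node_id}, kind=kind
            )
            for eid, _ in members:
                entry_node[eid] = node_id

    net = Network(nodes=node_specs.values())

    for rel in graph.relations:
        src = entry_node.get(rel.source)
        tgt = entry_node.get(rel.target)
        for subtype in rel.subtypes or ("",):
            if src is None or tgt is None:
                reason = (
                    "map_entry"
                    if _is_map(rel, graph)
                    else "dangling_endpoint"
                )
                report.skip(graph.pathway_id, rel.source, rel.target, subtype, reason)
                continue
            if subtype not in scheme.subtype_weights:
                report.skip(
                    graph.pathway_id, rel.source, rel.target, subtype, "unmapped_subtype"
                )
                continue
            edge = EdgeSpec(src, tgt, subtype, scheme.subtype_weights[subtype])
            if edge.key in net.edges:
                kept, dropped = _stronger(net.edges[edge.key].weight, edge.weight)
                report.weight_collisions.append(
                    {"source": src, "target": tgt, "type": subtype,
                     "kept": kept, "dropped": dropped}
                )
                edge = EdgeSpec(src, tgt, subtype, kept)
            net.add_edge(edge)

    report.per_pathway_counts[graph.pathway_id] = {
        "nodes": len(net.nodes),
        "edges": len(net.edges),
    }
    return net, report


def _is_map(rel: PathwayRelation, graph: PathwayGraph) -> bool:
    types = {e.entry_id: e.entry_type for e in graph.entries}
    return types.get(rel.source) == "map" or types.get(rel.target) == "map"


def _stronger(w1: int, w2: int) -> Tuple[int, int]:
    """Pick the larger-magnitude weight (ties broken toward the positive one)."""
    kept = max((w1, w2), key=lambda w: (abs(w), w))
    dropped = w1 if kept == w2 else w2
    return kept, dropped


def merge_networks(parts: List[Network]) -> Tuple[Network, ImportReport]:
    """Fuse several networks into one.

    Nodes of the same kind whose alias sets intersect (transitively, i.e.
    connected components of the alias-overlap relation) become one node
    whose alias set is the union of the class; all incoming and outgoing
    edges are re-targeted to the fused node.  When the same
    (source, target, type) edge arrives with different weights, the
    larger-magnitude weight is kept and the collision reported.
    """
    report = ImportReport()
    if not parts:
        raise NetworkError("merge_networks requires at least one network")

    items = []  # ((part index, node id), alias set) per kind
    per_kind: dict = {}
    for i, part in enumerate(parts):
        for node in part.nodes.values():
            per_kind.setdefault(node.kind, []).append(((i, node.id), frozenset(node.aliases)))

    node_map: dict = {}  # (part index, node id) -> merged node id
    merged_nodes: dict = {}
    for kind, items in per_kind.items():
        roots = _fuse_alias_classes(items)
        classes: dict = {}
        for key, aliases in items:
            classes.setdefault(roots[key], []).append(key)
        for root, members in classes.items():
            alias_union = frozenset()
            specs = []
            for (i, nid) in members:
                spec = parts[i].nodes[nid]
                specs.append(spec)
                alias_union |= spec.aliases
            if kind == "complex":
                member_ids = sorted({s.id for s in specs})
                node_id = min(member_ids)
            else:
                node_id = min(alias_union)
            if len(members) > 1:
                report.fused_groups.append(sorted(alias_union))
            # initial state / signal pattern: keep the maximum initial state,
            # and the first-seen pattern for signals (they should agree)
            init = max(s.initial_state for s in specs)
            pattern = next((s.signal_pattern for s in specs if s.signal_pattern), None)
            merged_nodes[node_id] = NodeSpec(
                id=node_id,
                aliases=alias_union | {node_id},
                kind=kind,
                initial_state=init,
                signal_pattern=pattern,
            )
            for key in members:
                node_map[key] = node_id

    merged = Network(nodes=merged_nodes.values())

    for i, part in enumerate(parts):
        for edge in part.edges.values():
            src = node_map[(i, edge.source)]
            tgt = node_map[(i, edge.target)]
            key = (src, tgt, edge.interaction_type)
            if key in merged.edges:
                # a collision, even at equal weight: two input relations
                # landed on one merged edge
                existing = merged.edges[key]
                kept, dropped = _stronger(existing.weight, edge.weight)
                report.weight_collisions.append(
                    {"source": src, "target": tgt, "type": edge.interaction_type,
                     "kept": kept, "dropped": dropped}
                )
                merged.add_edge(
                    EdgeSpec(src, tgt, edge.interaction_type, kept,
                             max(existing.delay, edge.delay))
                )
                continue
            merged.add_edge(EdgeSpec(src, tgt, edge.interaction_type, edge.weight, edge.delay))

        for rule in part.blocking_rules:
            remapped = rule.__class__(
                blockers=frozenset(node_map[(i, b)] for b in rule.blockers),
                edge=(node_map[(i, rule.edge[0])], node_map[(i, rule.edge[1])]),
                mode=rule.mode,
                active_steps=rule.active_steps,
                threshold=rule.threshold,
            )
            try:
                merged.add_blocking_rule(remapped)
            except NetworkError:
                logger.warning("dropping blocking rule on %s: edge lost in merge", rule.edge)

    report.merged_counts = {"nodes": len(merged.nodes), "edges": len(merged.edges)}
    return merged, report


def import_pathways(
    files: List, scheme: Optional[WeightScheme] = None
) -> Tuple[Network, ImportReport]:
    """Parse, convert, merge and finalize a list of KGML documents."""
    if not files:
        raise NetworkError("import_pathways requires at least one KGML file")
    scheme = scheme or WeightScheme()
    parts = []
    report = ImportReport()
    for f in files:
        graph = parse_kgml(f)
        net, rep = pathway_to_network(graph, scheme)
        parts.append(net)
        report.extend(rep)
    merged, merge_rep = merge_networks(parts)
    report.extend(merge_rep)
    merged.finalize(scheme.self_weight)
    report.merged_counts = {"nodes": len(merged.nodes), "edges": len(merged.edges)}
    merged.validate()
    return merged, report
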