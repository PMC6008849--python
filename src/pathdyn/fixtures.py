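"""Programmatic generators of KGML documents and toy networks.

Everything here is synthetic: the generators emulate the structure of
KEGG's per-pathway XML (entries, relations, subtypes, groups) so the whole
import / merge / simulate / compare workflow runs offline and
deterministically, without touching the KEGG database.  Real KGML files
drop in unchanged wherever these fixtures are used.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Sequence, Tuple
from xml.etree import ElementTree

from .kgml import WeightScheme, import_pathways
from .model import EdgeSpec, Network, NodeSpec


def make_kgml(
    pathway_name: str,
    entries: Sequence[Tuple[str, str, Sequence[str]]],
    relations: Sequence[Tuple[str, str, Sequence[str]]],
    groups: Sequence[Tuple[str, Sequence[str]]] = (),
) -> str:
    """Serialize a KGML document from a compact description.

    ``entries``: (entry id, entry type, names); ``relations``:
    (source entry id, target entry id, subtype names); ``groups``:
    (group entry id, member entry ids).  Output is deterministic and
    parses back with :func:`pathdyn.kgml.parse_kgml`.
    """
    root = ElementTree.Element("pathway", name=pathway_name, title=pathway_name)
    for eid, etype, names in entries:
        ElementTree.SubElement(
            root, "entry", id=str(eid), type=etype, name=" ".join(names)
        )
    for gid, members in groups:
        group = ElementTree.SubElement(root, "entry", id=str(gid), type="group", name="")
        for m in members:
            ElementTree.SubElement(group, "component", id=str(m))
    for src, tgt, subtypes in relations:
        rel = ElementTree.SubElement(
            root, "relation", entry1=str(src), entry2=str(tgt), type="PPrel"
        )
        for s in subtypes:
            ElementTree.SubElement(rel, "subtype", name=s, value="")
    ElementTree.indent(root)
    return ElementTree.tostring(root, encoding="unicode", xml_declaration=True)


def toy_feedback_network() -> Network:
    """The four-node demonstration network: a constant external signal
    feeding a negative-feedback loop.

    signal --(+1)--> A --(+2)--> B --(+2)--> C --(-2)--> A, plus the
    automatic -1 self-degradation loops.  Started from nonzero states the
    dynamics never settle: A, B and C repeatedly rise and fall while the
    signal stays constant, so the run terminates with a detected cycle.
    """
    net = Network(
        nodes=[
            NodeSpec("signal", kind="signal", signal_pattern=(1,)),
            NodeSpec("A", initial_state=3),
            NodeSpec("B", initial_state=2),
            NodeSpec("C", initial_state=5),
        ],
        edges=[
            EdgeSpec("signal", "A", "activation", 1),
            EdgeSpec("A", "B", "activation", 2),
            EdgeSpec("B", "C", "activation", 2),
            EdgeSpec("C", "A", "inhibition", -2),
        ],
    )
    return net.finalize(-1)


_SUBTYPE_POOL = (
    "activation",
    "inhibition",
    "expression",
    "repression",
    "phosphorylation",
    "dephosphorylation",
)


def random_pathway_specs(
    n_pathways: int,
    seed: int,
    n_entries: int = 6,
    n_relations: int = 7,
    shared_names: int = 1,
) -> List[str]:
    """Generate a family of random KGML documents with controlled overlap.

    ``shared_names`` gene names appear in every pathway (these drive
    fusion on merge); the remaining entries are unique per pathway.
    Deterministic for a fixed seed.
    """
    rng = random.Random(seed)
    shared = [f"SHARED{i}" for i in range(shared_names)]
    docs = []
    for p in range(n_pathways):
        entries = []
        for e in range(n_entries):
            eid = str(10 + e)
            if e < shared_names:
                names = [shared[e]]
            else:
                names = [f"P{p}G{e}"]
            entries.append((eid, "gene", names))
        relations = []
        seen = set()
        for _ in range(n_relations):
            src = str(10 + rng.randrange(n_entries))
            tgt = str(10 + rng.randrange(n_entries))
            if src == tgt or (src, tgt) in seen:
                continue
            seen.add((src, tgt))
            relations.append((src, tgt, [rng.choice(_SUBTYPE_POOL)]))
        docs.append(make_kgml(f"synthetic{p:02d}", entries, relations))
    return docs


def random_network(
    n_nodes: int,
    seed: int,
    edge_prob: float = 0.4,
    max_delay: int = 0,
    with_signal: bool = False,
    finalized: bool = True,
) -> Network:
    """A random finalized network for property testing.

    Gene nodes with uniform random initial states, random signed edges
    (weights in {-2, -1, 1, 2}), optional delays, and optionally one
    signal node with a random short pattern.
    """
    rng = random.Random(seed)
    nodes = [
        NodeSpec(f"n{i}", initial_state=rng.randint(0, 9)) for i in range(n_nodes)
    ]
    if with_signal:
        pattern = tuple(rng.randint(0, 9) for _ in range(rng.randint(1, 3)))
        nodes.append(NodeSpec("sig", kind="signal", signal_pattern=pattern))
    net = Network(nodes=nodes)
    ids = [n.id for n in nodes]
    for src in ids:
        for tgt in ids:
            if src == tgt or rng.random() >= edge_prob:
                continue
            weight = rng.choice([-2, -1, 1, 2])
            delay = rng.randint(0, max_delay) if max_delay else 0
            net.add_edge(EdgeSpec(src, tgt, "custom", weight, delay))
    if finalized:
        net.finalize(-1)
    return net


def import_random_pathways(
    n_pathways: int, seed: int, scheme: Optional[WeightScheme] = None, **kw
) -> Tuple[Network, Dict]:
    """Convenience: generate random pathways and run the full import."""
    docs = random_pathway_specs(n_pathways, seed, **kw)
    net, report = import_pathways(docs, scheme)
    return net, {"n_pathways": n_pathways, "report": report}
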