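"""GraphML writer/reader with typed keys; the round trip is the identity."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

from mpdiag.builder import CONSUMPTION, ComplexNode, MPDArc, MPDGraph, ProcessNode
from mpdiag.export.layout import LayoutAssignment

__all__ = ["to_graphml", "from_graphml"]

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

_NODE_KEYS = (
    ("nkind", "kind", "string"),
    ("nlabel", "label", "string"),
    ("ncomposition", "composition", "string"),
    ("nmembers", "member_patterns", "string"),
    ("nrule", "rule_id", "string"),
    ("nreversible", "reversible", "boolean"),
    ("nordinal", "ordinal", "int"),
    ("nx", "x", "double"),
    ("ny", "y", "double"),
    ("nw", "w", "double"),
    ("nh", "h", "double"),
)
_EDGE_KEYS = (
    ("ekind", "kind", "string"),
    ("estoich", "stoichiometry", "int"),
    ("esites", "site_labels", "string"),
    ("econtext", "context_labels", "string"),
)
_GRAPH_KEYS = (
    ("glevel", "level", "int"),
    ("gprov", "provenance", "string"),
    ("gtypes", "molecule_types", "string"),
)


def _data(parent: ET.Element, key: str, value: str) -> None:
    el = ET.SubElement(parent, "data", {"key": key})
    el.text = value


def to_graphml(graph: MPDGraph, layout: LayoutAssignment | None = None) -> str:
    """Serialize a diagram (optionally with node geometry) to GraphML text."""
    root = ET.Element("graphml", {"xmlns": GRAPHML_NS})
    scopes = (("node", _NODE_KEYS), ("edge", _EDGE_KEYS), ("graph", _GRAPH_KEYS))
    for domain, keys in scopes:
        for kid, name, ktype in keys:
            ET.SubElement(
                root, "key", {"id": kid, "for": domain, "attr.name": name, "attr.type": ktype}
            )
    g = ET.SubElement(root, "graph", {"id": "mpd", "edgedefault": "directed"})
    _data(g, "glevel", str(graph.level))
    _data(g, "gprov", json.dumps(dict(graph.provenance), sort_keys=True))
    _data(g, "gtypes", json.dumps([[n, list(cs)] for n, cs in graph.molecule_types]))
    for i, node in enumerate(graph.complex_nodes):
        el = ET.SubElement(g, "node", {"id": f"c{i}"})
        _data(el, "nkind", "complex")
        _data(el, "nlabel", node.display_label)
        _data(el, "ncomposition", node.composition_key)
        _data(el, "nmembers", json.dumps([list(m) for m in node.member_patterns]))
        if layout is not None:
            box = layout[f"c{i}"]
            for kid, val in (("nx", box.x), ("ny", box.y), ("nw", box.w), ("nh", box.h)):
                _data(el, kid, repr(val))
    for node in graph.process_nodes:
        el = ET.SubElement(g, "node", {"id": f"p{node.ordinal}"})
        _data(el, "nkind", "process")
        _data(el, "nlabel", node.rule_id)
        _data(el, "nrule", node.rule_id)
        _data(el, "nreversible", "true" if node.reversible else "false")
        _data(el, "nordinal", str(node.ordinal))
        if layout is not None:
            box = layout[f"p{node.ordinal}"]
            for kid, val in (("nx", box.x), ("ny", box.y), ("nw", box.w), ("nh", box.h)):
                _data(el, kid, repr(val))
    for i, arc in enumerate(graph.arcs):
        cid = graph.complex_id(arc.complex_key)
        pid = graph.process_id(arc.rule_id)
        src, tgt = (cid, pid) if arc.kind == CONSUMPTION else (pid, cid)
        el = ET.SubElement(g, "edge", {"id": f"e{i}", "source": src, "target": tgt})
        _data(el, "ekind", arc.kind)
        _data(el, "estoich", str(arc.stoichiometry))
        _data(el, "esites", json.dumps(list(arc.site_labels)))
        _data(el, "econtext", json.dumps(list(arc.context_labels)))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _collect_data(el: ET.Element) -> dict[str, str]:
    out = {}
    for d in el.findall(f"{{{GRAPHML_NS}}}data"):
        out[d.get("key", "")] = d.text or ""
    return out


def from_graphml(text: str) -> MPDGraph:
    """Reconstruct an :class:`MPDGraph` from :func:`to_graphml` output."""
    root = ET.fromstring(text)
    g = root.find(f"{{{GRAPHML_NS}}}graph")
    if g is None:
        raise ValueError("no <graph> element found")
    gdata = _collect_data(g)
    level = int(gdata["glevel"])
    provenance = tuple(sorted(json.loads(gdata["gprov"]).items()))
    molecule_types = tuple(
        (name, tuple(comps)) for name, comps in json.loads(gdata["gtypes"])
    )
    complexes: list[tuple[str, ComplexNode]] = []
    processes: list[ProcessNode] = []
    node_kind: dict[str, str] = {}
    node_payload: dict[str, dict[str, str]] = {}
    for el in g.findall(f"{{{GRAPHML_NS}}}node"):
        data = _collect_data(el)
        nid = el.get("id", "")
        node_kind[nid] = data["nkind"]
        node_payload[nid] = data
        if data["nkind"] == "complex":
            complexes.append(
                (
                    nid,
                    ComplexNode(
                        composition_key=data["ncomposition"],
                        display_label=data["nlabel"],
                        member_patterns=tuple(
                            tuple(m) for m in json.loads(data["nmembers"])
                        ),
                    ),
                )
            )
        else:
            processes.append(
                ProcessNode(
                    rule_id=data["nrule"],
                    reversible=data["nreversible"] == "true",
                    ordinal=int(data["nordinal"]),
                )
            )
    complexes.sort(key=lambda item: int(item[0][1:]))
    processes.sort(key=lambda p: p.ordinal)
    arcs: list[MPDArc] = []
    for el in g.findall(f"{{{GRAPHML_NS}}}edge"):
        data = _collect_data(el)
        kind = data["ekind"]
        src, tgt = el.get("source", ""), el.get("target", "")
        cid = src if kind == CONSUMPTION else tgt
        pid = tgt if kind == CONSUMPTION else src
        ckey = next(node.composition_key for nid, node in complexes if nid == cid)
        rid = node_payload[pid]["nrule"]
        arcs.append(
            MPDArc(
                kind=kind,
                complex_key=ckey,
                rule_id=rid,
                stoichiometry=int(data["estoich"]),
                site_labels=tuple(json.loads(data["esites"])),
                context_labels=tuple(json.loads(data["econtext"])),
            )
        )
    return MPDGraph(
        complex_nodes=tuple(node for _, node in complexes),
        process_nodes=tuple(processes),
        arcs=tuple(arcs),
        level=level,
        provenance=provenance,
        molecule_types=molecule_types,
    )
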