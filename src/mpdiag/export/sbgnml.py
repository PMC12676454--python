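"""SBGN-ML 0.2 Process Description writer with diagram-level extensions.

Complex nodes map onto standard PD glyphs (macromolecule, complex container,
multimer with cardinality); process nodes onto process glyphs; arcs onto
consumption/production arcs with cardinality glyphs for stoichiometry.

All site-level annotations live in ``<extension>`` elements (modified-site
labels on arcs) or in clearly marked annotation glyphs (context boxes), so
stripping them yields a conventional PD document: ``strip_mpd_extensions``
applied to a level-3 export equals the level-1 export after canonical XML
normalization.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET

from mpdiag.builder import CONSUMPTION, MPDGraph
from mpdiag.export.layout import Box, LayoutAssignment

__all__ = [
    "SBGN_NS",
    "MPD_NS",
    "to_sbgnml",
    "strip_mpd_extensions",
    "canonical_xml",
    "validate_structure",
]

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
MPD_NS = "urn:mpdiag:annotations"

_PD_GLYPH_CLASSES = {
    "macromolecule",
    "macromolecule multimer",
    "complex",
    "process",
    "state variable",
    "unit of information",
    "cardinality",
    "annotation",
}

_TRANSITION_RE = re.compile(r"^(?P<before>[^→@]*)→(?P<after>[^@]*)@(?P<site>.+)$")

ET.register_namespace("", SBGN_NS)
ET.register_namespace("mpd", MPD_NS)


def _bbox(parent: ET.Element, box: Box) -> None:
    ET.SubElement(
        parent,
        "bbox",
        {"x": f"{box.x:g}", "y": f"{box.y:g}", "w": f"{box.w:g}", "h": f"{box.h:g}"},
    )


def _label(parent: ET.Element, text: str) -> None:
    ET.SubElement(parent, "label", {"text": text})


def _state_variables(parent: ET.Element, owner_id: str, box: Box, comps: tuple[str, ...]) -> None:
    # one state-variable glyph per site, laid out along the bottom edge
    if not comps:
        return
    step = box.w / max(len(comps), 1)
    for i, comp in enumerate(comps):
        sv = ET.SubElement(
            parent, "glyph", {"class": "state variable", "id": f"{owner_id}_sv{i}"}
        )
        ET.SubElement(sv, "state", {"value": "", "variable": comp})
        _bbox(sv, Box(box.x + i * step, box.y + box.h - 8, min(step, 30.0), 12.0))


def _split_arc_label(label: str, kind: str) -> str:
    """Degrade a builder transition label to the SBGN arc form.

    ``U→P@Y1`` becomes ``U@Y1`` on consumption arcs and ``P@Y1`` on production
    arcs; bond labels pass through unchanged.
    """
    m = _TRANSITION_RE.match(label)
    if not m:
        return label
    value = m.group("before") if kind == CONSUMPTION else m.group("after")
    return f"{value}@{m.group('site')}"


def to_sbgnml(graph: MPDGraph, layout: LayoutAssignment, level: int | None = None) -> str:
    """Serialize the diagram to SBGN-ML 0.2 (map language "process description")."""
    if level is None:
        level = graph.level
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level!r}")
    if level > graph.level:
        raise ValueError(
            f"requested level {level} exceeds the graph annotation level {graph.level}"
        )
    comp_names = dict(graph.molecule_types)
    root = ET.Element("sbgn", {"xmlns": SBGN_NS})
    sbgn_map = ET.SubElement(root, "map", {"language": "process description"})

    for i, node in enumerate(graph.complex_nodes):
        cid = f"c{i}"
        box = layout[cid]
        members = node.composition_key.split("|")
        bare = [m.split("@", 1)[0] for m in members]
        if len(members) == 1:
            glyph = ET.SubElement(sbgn_map, "glyph", {"class": "macromolecule", "id": cid})
            _label(glyph, node.display_label)
            _bbox(glyph, box)
            _state_variables(glyph, cid, box, comp_names.get(bare[0], ()))
        elif len(set(members)) == 1:
            glyph = ET.SubElement(
                sbgn_map, "glyph", {"class": "macromolecule multimer", "id": cid}
            )
            _label(glyph, bare[0])
            _bbox(glyph, box)
            card = ET.SubElement(
                glyph, "glyph", {"class": "unit of information", "id": f"{cid}_card"}
            )
            _label(card, f"N:{len(members)}")
            _bbox(card, Box(box.x + box.w - 30, box.y - 6, 30.0, 12.0))
            _state_variables(glyph, cid, box, comp_names.get(bare[0], ()))
        else:
            glyph = ET.SubElement(sbgn_map, "glyph", {"class": "complex", "id": cid})
            _label(glyph, node.display_label)
            _bbox(glyph, box)
            inner_h = max((box.h - 4) / len(members), 14.0)
            for j, member in enumerate(members):
                sub = ET.SubElement(
                    glyph, "glyph", {"class": "macromolecule", "id": f"{cid}_m{j}"}
                )
                _label(sub, member)
                sub_box = Box(box.x + 2, box.y + 2 + j * inner_h, box.w - 4, inner_h - 2)
                _bbox(sub, sub_box)
                _state_variables(
                    sub, f"{cid}_m{j}", sub_box, comp_names.get(member.split("@", 1)[0], ())
                )

    for node in graph.process_nodes:
        pid = f"p{node.ordinal}"
        glyph = ET.SubElement(sbgn_map, "glyph", {"class": "process", "id": pid})
        _label(glyph, node.rule_id)
        _bbox(glyph, layout[pid])

    # context boxes come last among glyphs so that stripping leaves a document
    # identical to the lower-level export
    context_glyphs: list[tuple[str, tuple[str, ...], Box]] = []

    arc_ids: list[str] = []
    for i, arc in enumerate(graph.arcs):
        aid = f"a{i}"
        arc_ids.append(aid)
        cid = graph.complex_id(arc.complex_key)
        pid = graph.process_id(arc.rule_id)
        src, tgt = (cid, pid) if arc.kind == CONSUMPTION else (pid, cid)
        sbox, tbox = layout[src], layout[tgt]
        el = ET.SubElement(
            sbgn_map, "arc", {"class": arc.kind, "id": aid, "source": src, "target": tgt}
        )
        if level >= 2 and arc.site_labels:
            ext = ET.SubElement(el, "extension")
            sites = ET.SubElement(ext, f"{{{MPD_NS}}}siteLabels")
            for lab in arc.site_labels:
                site = ET.SubElement(sites, f"{{{MPD_NS}}}siteLabel")
                site.text = _split_arc_label(lab, arc.kind)
        ET.SubElement(
            el, "start", {"x": f"{sbox.x + sbox.w:g}", "y": f"{sbox.y + sbox.h / 2:g}"}
        )
        ET.SubElement(el, "end", {"x": f"{tbox.x:g}", "y": f"{tbox.y + tbox.h / 2:g}"})
        if arc.stoichiometry > 1:
            card = ET.SubElement(el, "glyph", {"class": "cardinality", "id": f"{aid}_card"})
            _label(card, str(arc.stoichiometry))
            mid_x = (sbox.x + sbox.w + tbox.x) / 2
            mid_y = (sbox.y + tbox.y) / 2 + sbox.h / 2
            _bbox(card, Box(mid_x - 10, mid_y - 8, 20.0, 16.0))
        if level >= 3 and arc.context_labels:
            mid_x = (sbox.x + sbox.w + tbox.x) / 2
            mid_y = (sbox.y + tbox.y) / 2 + sbox.h / 2
            context_glyphs.append(
                (aid, arc.context_labels, Box(mid_x - 40, mid_y + 12, 80.0, 14.0))
            )

    for aid, labels, box in context_glyphs:
        glyph = ET.SubElement(
            sbgn_map, "glyph", {"class": "annotation", "id": f"ctx_{aid}"}
        )
        _label(glyph, "; ".join(labels))
        ET.SubElement(glyph, "callout", {"target": aid})
        _bbox(glyph, box)

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def strip_mpd_extensions(text: str) -> str:
    """Remove every extension element and every MPD context-annotation glyph."""
    root = ET.fromstring(text)

    def scrub(el: ET.Element) -> None:
        for child in list(el):
            tag = child.tag
            if tag == f"{{{SBGN_NS}}}extension" or tag == "extension":
                el.remove(child)
                continue
            if (
                tag in (f"{{{SBGN_NS}}}glyph", "glyph")
                and child.get("class") == "annotation"
                and (child.get("id") or "").startswith("ctx_")
            ):
                el.remove(child)
                continue
            scrub(child)

    scrub(root)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def canonical_xml(text: str) -> str:
    """W3C canonical form (C14N 2.0) for byte-level document comparison."""
    out = io.StringIO()
    ET.canonicalize(text, out=out, strip_text=True)
    return out.getvalue()


def validate_structure(text: str) -> list[str]:
    """Structural conformance checks for the emitted SBGN-ML.

    Offline stand-in for XSD validation: verifies the namespace and map
    language, glyph class vocabulary, unique ids, mandatory bounding boxes,
    state elements on state variables, and that every arc references existing
    glyph ids.  Returns a list of problems (empty when the document conforms).
    """
    problems: list[str] = []
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{SBGN_NS}}}sbgn":
        problems.append(f"root element is {root.tag!r}, expected sbgn in {SBGN_NS}")
        return problems
    sbgn_map = root.find(f"{{{SBGN_NS}}}map")
    if sbgn_map is None:
        return ["missing <map> element"]
    if sbgn_map.get("language") != "process description":
        problems.append("map language is not 'process description'")
    ids: set[str] = set()

    def walk_glyph(glyph: ET.Element) -> None:
        gid = glyph.get("id")
        if not gid:
            problems.append("glyph without id")
        elif gid in ids:
            problems.append(f"duplicate id {gid!r}")
        else:
            ids.add(gid)
        cls = glyph.get("class")
        if cls not in _PD_GLYPH_CLASSES:
            problems.append(f"glyph {gid!r} has unknown class {cls!r}")
        if glyph.find(f"{{{SBGN_NS}}}bbox") is None:
            problems.append(f"glyph {gid!r} lacks a bbox")
        if cls == "state variable" and glyph.find(f"{{{SBGN_NS}}}state") is None:
            problems.append(f"state variable {gid!r} lacks a state element")
        for sub in glyph.findall(f"{{{SBGN_NS}}}glyph"):
            walk_glyph(sub)

    for glyph in sbgn_map.findall(f"{{{SBGN_NS}}}glyph"):
        walk_glyph(glyph)
    for arc in sbgn_map.findall(f"{{{SBGN_NS}}}arc"):
        aid = arc.get("id")
        if not aid:
            problems.append("arc without id")
        elif aid in ids:
            problems.append(f"duplicate id {aid!r}")
        else:
            ids.add(aid)
        if arc.get("class") not in ("consumption", "production"):
            problems.append(f"arc {aid!r} has class {arc.get('class')!r}")
        for ref_attr in ("source", "target"):
            ref = arc.get(ref_attr)
            if ref not in ids and not any(
                g.get("id") == ref for g in sbgn_map.iter(f"{{{SBGN_NS}}}glyph")
            ):
                problems.append(f"arc {aid!r} {ref_attr} {ref!r} does not resolve")
        for sub in arc.findall(f"{{{SBGN_NS}}}glyph"):
            walk_glyph(sub)
    return problems
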