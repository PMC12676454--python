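"""Deterministic DOT writer for quick rendering with Graphviz."""

from __future__ import annotations

from mpdiag.builder import CONSUMPTION, MPDGraph

__all__ = ["to_dot"]


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(graph: MPDGraph) -> str:
    """Boxes for complexes, small squares for processes, labeled directed edges."""
    lines = ["digraph MPD {", "  rankdir=LR;"]
    for i, node in enumerate(graph.complex_nodes):
        lines.append(f"  c{i} [shape=box, label={_quote(node.display_label)}];")
    for node in graph.process_nodes:
        shape = "Msquare" if node.reversible else "square"
        lines.append(
            f"  p{node.ordinal} [shape={shape}, label={_quote(node.rule_id)}, "
            "width=0.3, height=0.3, fixedsize=true];"
        )
    for arc in graph.arcs:
        cid = graph.complex_id(arc.complex_key)
        pid = graph.process_id(arc.rule_id)
        src, tgt = (cid, pid) if arc.kind == CONSUMPTION else (pid, cid)
        parts = []
        if arc.stoichiometry > 1:
            parts.append(str(arc.stoichiometry))
        parts.extend(arc.site_labels)
        parts.extend(arc.context_labels)
        attrs = f" [label={_quote('; '.join(parts))}]" if parts else ""
        lines.append(f"  {src} -> {tgt}{attrs};")
    lines.append("}")
    return "\n".join(lines) + "\n"
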