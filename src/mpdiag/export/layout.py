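"""Deterministic layered layout so exporters have well-defined bounding boxes."""

from __future__ import annotations

from dataclasses import dataclass

from mpdiag.builder import CONSUMPTION, MPDGraph

__all__ = ["Box", "LayoutAssignment", "layout", "COMPLEX_W", "COMPLEX_H", "PROCESS_W", "GUTTER"]

COMPLEX_W = 80.0
COMPLEX_H = 40.0
PROCESS_W = 24.0
GUTTER = 40.0


@dataclass(frozen=True)
class Box:
    x: float
    y: float
    w: float
    h: float


@dataclass(frozen=True)
class LayoutAssignment:
    boxes: dict[str, Box]  # node id -> box

    def __getitem__(self, node_id: str) -> Box:
        return self.boxes[node_id]


def _node_order(graph: MPDGraph) -> list[str]:
    ids = [graph.complex_id(n.composition_key) for n in graph.complex_nodes]
    ids += [f"p{n.ordinal}" for n in graph.process_nodes]
    return ids


def _edges(graph: MPDGraph) -> list[tuple[str, str]]:
    out = []
    for arc in graph.arcs:
        cid = graph.complex_id(arc.complex_key)
        pid = graph.process_id(arc.rule_id)
        out.append((cid, pid) if arc.kind == CONSUMPTION else (pid, cid))
    return out


def _ranks(graph: MPDGraph) -> dict[str, int]:
    """Longest-path ranks after dropping cycle-closing edges (DFS back edges)."""
    nodes = _node_order(graph)
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in _edges(graph):
        if b not in succ[a]:
            succ[a].append(b)
    # iterative DFS marking back edges
    color = {n: 0 for n in nodes}  # 0 unseen, 1 on stack, 2 done
    kept: dict[str, list[str]] = {n: [] for n in nodes}
    for root in nodes:
        if color[root]:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        color[root] = 1
        while stack:
            node, i = stack.pop()
            if i < len(succ[node]):
                stack.append((node, i + 1))
                nxt = succ[node][i]
                if color[nxt] == 1:
                    continue  # back edge: dropped
                kept[node].append(nxt)
                if color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, 0))
            else:
                color[node] = 2
    pred: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for a in nodes:
        for b in kept[a]:
            pred[b].append(a)
            indeg[b] += 1
    ranks = {n: 0 for n in nodes}
    queue = [n for n in nodes if indeg[n] == 0]
    while queue:
        node = queue.pop(0)
        for b in kept[node]:
            ranks[b] = max(ranks[b], ranks[node] + 1)
            indeg[b] -= 1
            if indeg[b] == 0:
                queue.append(b)
    return ranks


def layout(graph: MPDGraph) -> LayoutAssignment:
    """Left-to-right layered placement; ties broken by node declaration order."""
    nodes = _node_order(graph)
    if not nodes:
        return LayoutAssignment(boxes={})
    ranks = _ranks(graph)
    columns: dict[int, list[str]] = {}
    for n in nodes:
        columns.setdefault(ranks[n], []).append(n)
    boxes: dict[str, Box] = {}
    for rank in sorted(columns):
        x = rank * (COMPLEX_W + GUTTER) + GUTTER
        for row, node in enumerate(columns[rank]):
            y = row * (COMPLEX_H + GUTTER) + GUTTER
            if node.startswith("p"):
                # small square centered in the column
                off = (COMPLEX_W - PROCESS_W) / 2
                boxes[node] = Box(x + off, y + (COMPLEX_H - PROCESS_W) / 2, PROCESS_W, PROCESS_W)
            else:
                boxes[node] = Box(x, y, COMPLEX_W, COMPLEX_H)
    return LayoutAssignment(boxes=boxes)
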