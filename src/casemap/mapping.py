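"""Deterministic DOT emission of case maps with cohort traffic.

The map follows the field's visual conventions for branched-case
assessment: treatment prompts are circles, hydration prompts diamonds and
endings squares; the expert route runs along the top band ending in the
FINISH square, incorrect endings sit in the bottom band, and everything
else occupies the middle. Cohort traffic is superimposed by widening each
edge in proportion to the fraction of users who took it and colouring it
by its role: expert-route edges black, deviations orange, re-joins to the
expert route teal, harmful choices magenta, untravelled routes gray.

Output is plain Graphviz DOT text, byte-identical across runs for
identical inputs; rasterising it is left to any standard DOT processor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .model import CaseGraph, ChoiceEdge, require_valid
from .responses import UserPath

UNTRAVELED = "untraveled"
EXPERT_STYLE = "expert"
DEVIATION = "deviation"
REJOIN = "rejoin"
INCORRECT_STYLE = "incorrect"

DEFAULT_SHAPES = {"treatment": "circle", "hydration": "diamond", "endpoint": "square"}
DEFAULT_PALETTE = {
    UNTRAVELED: "gray70",
    EXPERT_STYLE: "black",
    DEVIATION: "orange",
    REJOIN: "teal",
    INCORRECT_STYLE: "magenta",
}


class RenderError(Exception):
    pass


@dataclass(frozen=True)
class MapStyle:
    """Visual parameters: node shapes, status palette, edge-width rule.

    Edge pen width is linear in the cohort fraction travelling the edge:
    ``w_min + (w_max - w_min) * fraction``.
    """

    shapes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    palette: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    w_min: float = 1.0
    w_max: float = 8.0
    rankdir: str = "LR"
    fontname: str = "Helvetica"

    def validate(self) -> None:
        if self.w_min <= 0:
            raise RenderError(f"w_min must be positive, got {self.w_min}")
        if self.w_max < self.w_min:
            raise RenderError(f"w_max ({self.w_max}) must be >= w_min ({self.w_min})")

    def width(self, fraction: float) -> float:
        return self.w_min + (self.w_max - self.w_min) * fraction


@dataclass(frozen=True)
class EdgeUsageRecord:
    count: int
    fraction: float
    style_class: str


@dataclass
class EdgeUsage:
    """Per-edge traversal counts and style classes for one cohort.

    Keyed by (source node id, option text); ``n_users`` is the cohort
    size used as the denominator of the fractions.
    """

    per_edge: dict[tuple[str, str], EdgeUsageRecord]
    n_users: int

    def record(self, edge: ChoiceEdge) -> EdgeUsageRecord:
        return self.per_edge[(edge.source, edge.option_text)]


def _taxonomy(case: CaseGraph, edge: ChoiceEdge) -> str:
    """Style class of an edge from its role in the graph (ignoring traffic)."""
    route = case.expert_route
    pos = {nid: i for i, nid in enumerate(route)}
    if edge.classification == "incorrect":
        return INCORRECT_STYLE
    src, dst = edge.source, edge.destination
    if src in pos and dst in pos and pos[dst] == pos[src] + 1:
        return EXPERT_STYLE
    if src not in pos and dst in pos:
        return REJOIN
    return DEVIATION


def edge_usage(case: CaseGraph, paths: Iterable[UserPath]) -> EdgeUsage:
    """Count traversals of every case edge over a cohort of replayed paths.

    Fractions are relative to the cohort size; an edge nobody travelled is
    styled ``untraveled`` whatever its taxonomy.
    """
    require_valid(case)
    paths = list(paths)
    n = len(paths)
    counts: dict[tuple[str, str], int] = {
        (e.source, e.option_text): 0 for e in case.edges
    }
    for p in paths:
        for e in p.edges:
            key = (e.source, e.option_text)
            if key not in counts:
                raise ValueError(
                    f"path of user {p.user_id!r} uses edge {key!r} not in case {case.case_id!r}"
                )
            counts[key] += 1
    per_edge = {}
    for e in case.edges:
        key = (e.source, e.option_text)
        c = counts[key]
        style = _taxonomy(case, e) if c > 0 else UNTRAVELED
        per_edge[key] = EdgeUsageRecord(count=c, fraction=(c / n if n else 0.0), style_class=style)
    return EdgeUsage(per_edge=per_edge, n_users=n)


# ---------------------------------------------------------------------------
# DOT emission


def _q(text: str) -> str:
    """Quote a DOT identifier/label."""
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _fmt_width(w: float) -> str:
    return f"{w:.3f}"


def _node_sort_key(case: CaseGraph):
    pos = {nid: i for i, nid in enumerate(case.expert_route)}

    def key(nid: str):
        return (pos.get(nid, len(pos)), nid)

    return key


def render_dot(
    case: CaseGraph,
    usage: EdgeUsage | None = None,
    style: MapStyle | None = None,
    graph_label: str | None = None,
) -> str:
    """Emit the case map as DOT text.

    Without ``usage`` the base map is produced: every route drawn in the
    untravelled style (the blank map a cohort is later superimposed on).
    Nodes are grouped into three tier bands — the expert row first (in
    route order, so it renders as the top band), then the middle tier,
    then the incorrect-endpoint row — plus a key listing the meaning of
    every node id. Emission order is fully sorted, so identical inputs
    yield byte-identical output.
    """
    require_valid(case)
    style = style or MapStyle()
    style.validate()
    title = graph_label if graph_label is not None else case.title

    lines: list[str] = []
    add = lines.append
    add(f"digraph {_q(case.case_id)} {{")
    add(f"  graph [label={_q(title)}, labelloc=t, rankdir={style.rankdir}, fontname={_q(style.fontname)}];")
    add(f"  node [fontname={_q(style.fontname)}, fontsize=10];")
    add(f"  edge [fontname={_q(style.fontname)}];")

    key_fn = _node_sort_key(case)
    by_tier: dict[str, list[str]] = {"expert_row": [], "middle": [], "endpoint_row": []}
    for nid in sorted(case.nodes, key=key_fn):
        by_tier[case.nodes[nid].tier].append(nid)
    # Expert-row nodes strictly in route order on the top band.
    by_tier["expert_row"] = [n for n in case.expert_route if case.nodes[n].tier == "expert_row"] + [
        n for n in by_tier["expert_row"] if n not in case.expert_route
    ]

    for tier in ("expert_row", "middle", "endpoint_row"):
        add(f"  subgraph cluster_tier_{tier} {{")
        add("    graph [style=invis];")
        for nid in by_tier[tier]:
            node = case.nodes[nid]
            shape = style.shapes.get(node.kind, "ellipse")
            attrs = [f"shape={shape}", f"label={_q(node.node_id)}"]
            if nid == case.finish_node:
                attrs.append("penwidth=2.000")
            add(f"    {_q(nid)} [{', '.join(attrs)}];")
        add("  }")

    # Map key: node id -> display label, as a single note so no node id is
    # emitted twice.
    key_lines = [f"{nid} = {case.nodes[nid].label}" for nid in sorted(case.nodes, key=key_fn)]
    key_label = "\\l".join(["Key"] + key_lines) + "\\l"
    add("  subgraph cluster_key {")
    add("    graph [style=invis];")
    add(f"    __key__ [shape=note, label={_q_raw(key_label)}];")
    add("  }")

    for e in sorted(case.edges, key=lambda e: (e.source, e.option_text)):
        if usage is None:
            color = style.palette[UNTRAVELED]
            width = style.w_min
        else:
            rec = usage.record(e)
            color = style.palette[rec.style_class]
            width = style.width(rec.fraction)
        weight = 10 if _taxonomy(case, e) == EXPERT_STYLE else 1
        attrs = [
            f"color={_q(color)}",
            f"penwidth={_fmt_width(width)}",
            f"tooltip={_q(e.option_text)}",
            f"weight={weight}",
        ]
        add(f"  {_q(e.source)} -> {_q(e.destination)} [{', '.join(attrs)}];")
    add("}")
    return "\n".join(lines) + "\n"


def _q_raw(text: str) -> str:
    """Quote a label that already contains DOT escapes (\\l line breaks)."""
    return '"' + text.replace('"', '\\"') + '"'


def render_comparison(
    case: CaseGraph,
    usages: Mapping[str, EdgeUsage],
    style: MapStyle | None = None,
) -> dict[str, str]:
    """Render one traffic map per group with an identical node layout.

    All maps share the same node statements, tier bands and emission
    order, so they can be placed side by side and read edge-for-edge;
    only edge styling and the graph title differ. Requires at least two
    groups (a single cohort is just :func:`render_dot`).
    """
    if len(usages) < 2:
        raise RenderError(f"comparison needs at least 2 groups, got {len(usages)}")
    out = {}
    for label in sorted(usages):
        out[label] = render_dot(
            case,
            usage=usages[label],
            style=style,
            graph_label=f"{case.title} — {label} (n={usages[label].n_users})",
        )
    return out
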