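"""Branched-case graph model.

A *case* is a directed acyclic graph of prompts. Each non-endpoint node
poses one form question (a hydration yes/no prompt or a treatment menu);
every answer option is an edge that routes the user to another node or to
an ending. Exactly one option per decision node is the *expert* choice —
the choice a panel of specialists would make — so following expert edges
from the start node traces a unique expert route that terminates at the
FINISH node (the successful-treatment ending). Non-expert options are
*tolerable* (off the expert route but not immediately harmful) or
*incorrect* (harmful; these typically route to collapsed failure endings).

The module loads case definitions from a YAML document, validates the
structural rules above, and derives the expert route and its checkpoint
sequence (the rows of the cohort behavior table).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import yaml

NODE_KINDS = ("treatment", "hydration", "endpoint")
TIERS = ("expert_row", "middle", "endpoint_row")
CLASSIFICATIONS = ("expert", "tolerable", "incorrect")

#: Observed range of treatment-menu sizes in authored cases; decision nodes
#: with a non-binary menu outside this band draw a MENU_SIZE warning.
MENU_SIZE_RANGE = (8, 14)


class CaseError(Exception):
    """Base class for case-definition problems."""


class CaseFormatError(CaseError):
    """The case file could not be parsed into the expected schema."""


class CaseValidationError(CaseError):
    """The parsed case violates a structural rule.

    Carries the full :class:`ValidationReport` in ``report``.
    """

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"{i.code} at {i.ref}: {i.message}" for i in report.errors]
        super().__init__("invalid case:\n" + "\n".join(lines))


@dataclass(frozen=True)
class CaseNode:
    """One prompt or ending in the case.

    ``timepoint_hours`` is the case-clock time of the prompt (endpoints may
    omit it); ``question_key`` names the form question answered at this
    node and is absent exactly for endpoints; ``tier`` places the node in
    the map's row layout.
    """

    node_id: str
    label: str
    kind: str
    timepoint_hours: float | None = None
    question_key: str | None = None
    tier: str = "middle"

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise CaseFormatError(
                f"node {self.node_id!r}: kind must be one of {NODE_KINDS}, got {self.kind!r}"
            )
        if self.tier not in TIERS:
            raise CaseFormatError(
                f"node {self.node_id!r}: tier must be one of {TIERS}, got {self.tier!r}"
            )

    @property
    def is_endpoint(self) -> bool:
        return self.kind == "endpoint"


@dataclass(frozen=True)
class ChoiceEdge:
    """One answer option: verbatim option text, routing destination and
    its expert/tolerable/incorrect classification."""

    source: str
    option_text: str
    destination: str
    classification: str

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise CaseFormatError(
                f"edge {self.source!r} -> {self.destination!r}: classification must be "
                f"one of {CLASSIFICATIONS}, got {self.classification!r}"
            )


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    ref: str
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, ref: str, message: str) -> None:
        self.errors.append(ValidationIssue(code, ref, message))

    def warn(self, code: str, ref: str, message: str) -> None:
        self.warnings.append(ValidationIssue(code, ref, message))


@dataclass
class CaseGraph:
    """The full branched case: nodes, classified edges, the expert route.

    Nodes are held in a dict keyed by ``node_id``; edges are kept in a
    canonical sort order (source, option text) so that loading, building
    and re-serialising a case are all order-stable.
    """

    case_id: str
    title: str
    nodes: dict[str, CaseNode]
    edges: list[ChoiceEdge]
    start_node: str
    expert_route: list[str] = field(default_factory=list)
    finish_node: str = ""

    def __post_init__(self) -> None:
        self.nodes = {nid: self.nodes[nid] for nid in sorted(self.nodes)}
        self.edges = sorted(self.edges, key=lambda e: (e.source, e.option_text))
        self._out: dict[str, list[ChoiceEdge]] = {nid: [] for nid in self.nodes}
        for e in self.edges:
            self._out.setdefault(e.source, []).append(e)
        if not self.expert_route:
            self.expert_route = self._derive_expert_route()
        if not self.finish_node:
            self.finish_node = self.expert_route[-1]

    # -- structure queries -------------------------------------------------

    def node(self, node_id: str) -> CaseNode:
        return self.nodes[node_id]

    def outgoing(self, node_id: str) -> list[ChoiceEdge]:
        """Outgoing options of a node, in canonical (option text) order."""
        return list(self._out.get(node_id, []))

    def edge_for(self, source: str, option_text: str) -> ChoiceEdge | None:
        key = _norm(option_text)
        for e in self._out.get(source, []):
            if _norm(e.option_text) == key:
                return e
        return None

    def has_edge(self, edge: ChoiceEdge) -> bool:
        return edge in self._out.get(edge.source, [])

    @property
    def decision_nodes(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if not n.is_endpoint]

    @property
    def endpoints(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.is_endpoint]

    @property
    def expert_edges(self) -> list[ChoiceEdge]:
        """The edges joining consecutive expert-route nodes, in route order."""
        out = []
        for a, b in zip(self.expert_route, self.expert_route[1:]):
            match = [
                e
                for e in self._out.get(a, [])
                if e.destination == b and e.classification == "expert"
            ]
            if len(match) != 1:
                raise CaseValidationError(
                    _report_single(
                        "BROKEN_EXPERT_ROUTE",
                        a,
                        f"expected exactly one expert edge {a!r} -> {b!r}, found {len(match)}",
                    )
                )
            out.append(match[0])
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(case_id=self.case_id)
        for nid, n in self.nodes.items():
            g.add_node(nid, kind=n.kind, tier=n.tier, label=n.label)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.destination,
                key=e.option_text,
                classification=e.classification,
            )
        return g

    # -- derivation --------------------------------------------------------

    def _derive_expert_route(self) -> list[str]:
        """Follow the unique expert edge from the start until an endpoint.

        Bounded by the node count, so a mistakenly cyclic expert chain is
        reported rather than looping forever.
        """
        route = [self.start_node]
        seen = {self.start_node}
        while True:
            here = route[-1]
            if here not in self.nodes:
                raise CaseValidationError(
                    _report_single("DANGLING_DEST", here, "expert route leaves the node set")
                )
            if self.nodes[here].is_endpoint:
                return route
            expert = [e for e in self._out.get(here, []) if e.classification == "expert"]
            if len(expert) != 1:
                raise CaseValidationError(
                    _report_single(
                        "EXPERT_EDGE_COUNT",
                        here,
                        f"decision node has {len(expert)} expert edges (need exactly 1)",
                    )
                )
            nxt = expert[0].destination
            if nxt in seen:
                raise CaseValidationError(
                    _report_single("CYCLE", here, f"expert route revisits node {nxt!r}")
                )
            seen.add(nxt)
            route.append(nxt)


def _norm(text: str) -> str:
    """Whitespace-normalised option text: trimmed, internal runs collapsed."""
    return " ".join(text.split())


def _report_single(code: str, ref: str, message: str) -> ValidationReport:
    rep = ValidationReport()
    rep.error(code, ref, message)
    return rep


# ---------------------------------------------------------------------------
# Loading / saving


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise CaseFormatError(f"{where}: missing required key {key!r}")
    return mapping[key]


def case_from_dict(doc: Mapping) -> CaseGraph:
    """Build a CaseGraph from the parsed case-definition document."""
    if not isinstance(doc, Mapping):
        raise CaseFormatError("case file must be a mapping at the top level")
    case_id = str(_require(doc, "case_id", "top level"))
    title = str(_require(doc, "title", "top level"))
    start = str(_require(doc, "start", "top level"))
    raw_nodes = _require(doc, "nodes", "top level")
    raw_edges = _require(doc, "edges", "top level")
    if not isinstance(raw_nodes, list) or not isinstance(raw_edges, list):
        raise CaseFormatError("'nodes' and 'edges' must be lists")

    nodes: dict[str, CaseNode] = {}
    for i, nd in enumerate(raw_nodes):
        where = f"nodes[{i}]"
        if not isinstance(nd, Mapping):
            raise CaseFormatError(f"{where}: node entries must be mappings")
        nid = str(_require(nd, "id", where))
        if nid in nodes:
            raise CaseFormatError(f"{where}: duplicate node id {nid!r}")
        tp = nd.get("timepoint_hours")
        if tp is not None:
            tp = float(tp)
            if tp < 0:
                raise CaseFormatError(f"{where}: timepoint_hours must be nonnegative")
        qk = nd.get("question_key")
        nodes[nid] = CaseNode(
            node_id=nid,
            label=str(_require(nd, "label", where)),
            kind=str(_require(nd, "kind", where)),
            timepoint_hours=tp,
            question_key=None if qk is None else str(qk),
            tier=str(nd.get("tier", "middle")),
        )

    edges: list[ChoiceEdge] = []
    seen_opts: set[tuple[str, str]] = set()
    for i, ed in enumerate(raw_edges):
        where = f"edges[{i}]"
        if not isinstance(ed, Mapping):
            raise CaseFormatError(f"{where}: edge entries must be mappings")
        e = ChoiceEdge(
            source=str(_require(ed, "from", where)),
            option_text=str(_require(ed, "option", where)),
            destination=str(_require(ed, "to", where)),
            classification=str(_require(ed, "class", where)),
        )
        key = (e.source, _norm(e.option_text))
        if key in seen_opts:
            raise CaseFormatError(
                f"{where}: duplicate option {e.option_text!r} at node {e.source!r}"
            )
        seen_opts.add(key)
        edges.append(e)

    if start not in nodes:
        raise CaseFormatError(f"start node {start!r} is not in the node set")
    for e in edges:
        if e.source not in nodes or e.destination not in nodes:
            raise CaseValidationError(
                _report_single(
                    "DANGLING_DEST",
                    f"{e.source}->{e.destination}",
                    f"edge references unknown node "
                    f"{(e.source if e.source not in nodes else e.destination)!r}",
                )
            )

    return CaseGraph(case_id=case_id, title=title, nodes=nodes, edges=edges, start_node=start)


def load_case(path: str | Path, strict: bool = True) -> CaseGraph:
    """Load a case-definition YAML file.

    With ``strict`` (the default) the case is validated and a
    :class:`CaseValidationError` is raised on any structural error, so
    downstream operations only ever see well-formed cases.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8-sig"))
    except yaml.YAMLError as exc:
        raise CaseFormatError(f"{path}: not valid YAML: {exc}") from exc
    case = case_from_dict(doc)
    if strict:
        report = validate_case(case)
        if not report.ok:
            raise CaseValidationError(report)
    return case


def case_to_dict(case: CaseGraph) -> dict:
    """Canonical plain-dict form: sorted nodes/edges, fixed key order."""

    def node_entry(n: CaseNode) -> dict:
        d = {"id": n.node_id, "label": n.label, "kind": n.kind}
        if n.timepoint_hours is not None:
            tp = float(n.timepoint_hours)
            d["timepoint_hours"] = int(tp) if tp.is_integer() else tp
        if n.question_key is not None:
            d["question_key"] = n.question_key
        d["tier"] = n.tier
        return d

    return {
        "case_id": case.case_id,
        "title": case.title,
        "start": case.start_node,
        "nodes": [node_entry(case.nodes[nid]) for nid in sorted(case.nodes)],
        "edges": [
            {
                "from": e.source,
                "option": e.option_text,
                "to": e.destination,
                "class": e.classification,
            }
            for e in sorted(case.edges, key=lambda e: (e.source, e.option_text))
        ],
    }


def dumps_case(case: CaseGraph) -> str:
    """Serialise to YAML text; byte-stable for a given case."""
    buf = io.StringIO()
    yaml.safe_dump(case_to_dict(case), buf, sort_keys=False, allow_unicode=True)
    return buf.getvalue()


def save_case(case: CaseGraph, path: str | Path) -> None:
    Path(path).write_text(dumps_case(case), encoding="utf-8")


# ---------------------------------------------------------------------------
# Validation


def validate_case(case: CaseGraph) -> ValidationReport:
    """Check the structural rules of a branched case.

    Errors: endpoints with outgoing edges, decision nodes without outgoing
    edges or without exactly one expert edge, dangling destinations, nodes
    unreachable from the start, directed cycles, and a broken expert-route
    chain. Warnings: menu sizes outside the authored range and duplicate
    option text at a node. A report is always returned; callers that need
    a hard failure should check ``report.ok``.
    """
    rep = ValidationReport()

    for e in case.edges:
        if e.destination not in case.nodes:
            rep.error(
                "DANGLING_DEST",
                f"{e.source}->{e.destination}",
                f"edge option {e.option_text!r} routes to unknown node {e.destination!r}",
            )
        if e.source not in case.nodes:
            rep.error("DANGLING_DEST", e.source, "edge leaves an unknown node")

    for nid, node in case.nodes.items():
        out = case.outgoing(nid)
        if node.is_endpoint:
            if out:
                rep.error("ENDPOINT_OUTGOING", nid, f"endpoint has {len(out)} outgoing edges")
            if node.question_key is not None:
                rep.error("ENDPOINT_QUESTION", nid, "endpoint carries a question_key")
        else:
            if not out:
                rep.error("NO_OUTGOING", nid, "decision node has no outgoing edges")
            if node.question_key is None:
                rep.error("MISSING_QUESTION", nid, "decision node has no question_key")
            n_expert = sum(1 for e in out if e.classification == "expert")
            if n_expert != 1:
                rep.error(
                    "EXPERT_EDGE_COUNT",
                    nid,
                    f"decision node has {n_expert} expert-classified options (need exactly 1)",
                )
            # Binary hydration prompts are exempt from the menu-size band.
            lo, hi = MENU_SIZE_RANGE
            if len(out) != 2 and not (lo <= len(out) <= hi):
                rep.warn(
                    "MENU_SIZE",
                    nid,
                    f"menu of {len(out)} options lies outside the expected range [{lo}, {hi}]",
                )
            seen: set[str] = set()
            for e in out:
                key = _norm(e.option_text)
                if key in seen:
                    rep.warn("DUP_OPTION", nid, f"duplicate option text {e.option_text!r}")
                seen.add(key)

    # Question keys must be unique across decision nodes for replay to be
    # well defined (each form question belongs to one section).
    qk_owner: dict[str, str] = {}
    for nid in case.decision_nodes:
        qk = case.nodes[nid].question_key
        if qk is None:
            continue
        if qk in qk_owner:
            rep.error("DUP_QUESTION_KEY", nid, f"question_key {qk!r} also used by node {qk_owner[qk]!r}")
        qk_owner[qk] = nid

    g = nx.DiGraph()
    g.add_nodes_from(case.nodes)
    g.add_edges_from((e.source, e.destination) for e in case.edges if e.destination in case.nodes)
    if case.start_node in g:
        unreachable = set(case.nodes) - set(nx.descendants(g, case.start_node)) - {case.start_node}
        for nid in sorted(unreachable):
            rep.error("UNREACHABLE", nid, "node is not reachable from the start node")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        rep.error("CYCLE", cycle[0][0], f"directed cycle: {' -> '.join(a for a, _ in cycle)}")

    # Expert-route chain checks (only meaningful if local rules hold).
    if rep.ok:
        route = case.expert_route
        if route[0] != case.start_node:
            rep.error("BROKEN_EXPERT_ROUTE", route[0], "expert route does not start at the start node")
        if route[-1] != case.finish_node:
            rep.error("BROKEN_EXPERT_ROUTE", route[-1], "expert route does not end at the FINISH node")
        finish = case.nodes.get(case.finish_node)
        if finish is None or not finish.is_endpoint:
            rep.error("BROKEN_EXPERT_ROUTE", case.finish_node, "FINISH node is not an endpoint")
        elif finish.tier != "expert_row":
            rep.warn("FINISH_TIER", case.finish_node, "FINISH node is not on the expert row")
        for a, b in zip(route, route[1:]):
            ok = any(
                e.destination == b and e.classification == "expert" for e in case.outgoing(a)
            )
            if not ok:
                rep.error(
                    "BROKEN_EXPERT_ROUTE", a, f"no expert edge joins {a!r} to {b!r}"
                )
    return rep


def require_valid(case: CaseGraph) -> CaseGraph:
    """Raise CaseValidationError unless the case validates cleanly."""
    report = validate_case(case)
    if not report.ok:
        raise CaseValidationError(report)
    return case


def expert_checkpoints(case: CaseGraph) -> list[tuple[str, str]]:
    """Expert-route nodes in traversal order, as (node_id, label) pairs.

    These checkpoints are the rows of the cohort behavior table: the first
    entry is the start node and the last is the FINISH node.
    """
    require_valid(case)
    return [(nid, case.nodes[nid].label) for nid in case.expert_route]


def normalize_option(text: str) -> str:
    """Public alias for the option-text normalisation used in matching."""
    return _norm(text)
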