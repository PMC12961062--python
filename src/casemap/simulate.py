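"""Synthetic cases and stochastic respondent cohorts.

The demo case builder produces a structurally faithful stand-in for a
published branched chemotherapy-monitoring scenario: an expert spine of
alternating timepoint prompts (circles, binary hydration choice) and
fluid-state prompts (diamonds, multi-option treatment menus), tolerable
detours that rejoin the spine one timepoint later, and harmful options
collapsed onto shared failure endings, with a single FINISH.

The cohort simulator emulates respondents making per-node stochastic
choices: at each decision node a class (expert / tolerable / incorrect)
is drawn from a mixture, then an option uniformly within the class.
Every user gets an independent, counter-derived random substream, so a
cohort is bit-reproducible from its seed and growing ``n_users`` never
reshuffles earlier users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import CaseGraph, CaseNode, ChoiceEdge, require_valid
from .responses import ResponseRecord, UserPath, record_for_path

CLASS_ORDER = ("expert", "tolerable", "incorrect")


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class BehaviorProfile:
    """Mixture over choice classes, with optional per-node overrides.

    At a node offering only a subset of classes the mixture is
    renormalised over the present classes; a node whose present classes
    all carry zero mass is a configuration error.
    """

    p_expert: float = 0.8
    p_tolerable: float = 0.15
    p_incorrect: float = 0.05
    node_overrides: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mix in [self.mixture(), *self.node_overrides.values()]:
            if any(p < 0 or p > 1 for p in mix):
                raise SimulationError(f"probabilities must lie in [0, 1]: {mix}")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise SimulationError(f"mixture must sum to 1: {mix}")

    def mixture(self, node_id: str | None = None) -> tuple[float, float, float]:
        if node_id is not None and node_id in self.node_overrides:
            return tuple(self.node_overrides[node_id])
        return (self.p_expert, self.p_tolerable, self.p_incorrect)

    def class_probs(self, node_id: str, present: Sequence[str]) -> dict[str, float]:
        """Mixture restricted to the classes offered at a node."""
        mix = dict(zip(CLASS_ORDER, self.mixture(node_id)))
        mass = sum(mix[c] for c in present)
        if mass <= 0:
            raise SimulationError(
                f"node {node_id!r}: classes {list(present)} all have zero probability"
            )
        return {c: mix[c] / mass for c in present}


@dataclass(frozen=True)
class CohortSpec:
    """How to generate one synthetic cohort."""

    n_users: int
    seed: int
    profile: BehaviorProfile = field(default_factory=BehaviorProfile)
    group_label: str | None = None
    role_labels: Sequence[tuple[str, int]] | None = None
    p_backtrack: float = 0.0  # chance a user leaves one stray (orphan) answer

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise SimulationError(f"n_users must be >= 1, got {self.n_users}")
        if not 0.0 <= self.p_backtrack <= 1.0:
            raise SimulationError("p_backtrack must lie in [0, 1]")


@dataclass
class CohortResult:
    records: list[ResponseRecord]
    paths: list[UserPath]  # ground truth, before any replay
    n_backtracks_injected: int


# ---------------------------------------------------------------------------
# Demo case construction


def make_demo_case(n_treatment_stages: int = 5, options_per_menu: int = 8) -> CaseGraph:
    """Build a valid branched demo case shaped like a published scenario.

    With the defaults (5 stages, 8-option menus) the expert route runs
    through timepoint prompts at 24/42/48/54/60 h, each followed by a
    fluid prompt, and ends at a FINISH square at 66 h — eleven checkpoints
    in all. Each fluid diamond poses a treatment menu with exactly one
    expert option, tolerable options collapsing onto an early-check detour
    circle (which can rejoin the spine), and harmful options collapsing
    onto shared failure endings; one harmful option (premature rescue
    dosing) always routes to the same ending, whatever the stage.
    """
    if n_treatment_stages < 1:
        raise SimulationError("n_treatment_stages must be >= 1")
    if options_per_menu < 3:
        raise SimulationError("options_per_menu must be >= 3 (one option per class)")

    times = [24]
    for i in range(1, n_treatment_stages):
        times.append(42 if i == 1 else times[-1] + 6)
    finish_time = times[-1] + 6

    nodes: dict[str, CaseNode] = {}
    edges: list[ChoiceEdge] = []
    harm_endpoints = ["End1", "End2", "End3", "End4"]
    used_endpoints: set[str] = set()
    rr = 0  # round-robin pointer over non-rescue failure endings

    def next_endpoint() -> str:
        nonlocal rr
        eid = harm_endpoints[1 + (rr % (len(harm_endpoints) - 1))]
        rr += 1
        used_endpoints.add(eid)
        return eid

    def add_node(nid: str, label: str, kind: str, t: float | None, tier: str) -> None:
        qk = None if kind == "endpoint" else f"q_{nid}"
        nodes[nid] = CaseNode(
            node_id=nid, label=label, kind=kind, timepoint_hours=t, question_key=qk, tier=tier
        )

    n_tol = max(1, (options_per_menu - 1) // 2)
    n_inc = options_per_menu - 1 - n_tol

    incorrect_texts = [
        "Administer leucovorin 100 mg/m2/dose now",
        "Discharge the patient",
        "Stop hydration and recheck tomorrow",
        "Hold all monitoring for 24 h",
        "Administer high-dose leucovorin and discharge",
        "Skip the next level entirely",
    ]
    tolerable_texts = [
        "Obtain the next level in 12 h",
        "Obtain the next level in 18 h",
        "Obtain the next level in 24 h",
        "Recheck creatinine before the next level",
        "Consult the pharmacy team before acting",
        "Repeat urine studies and wait",
    ]

    for i, t in enumerate(times):
        c, h, g, d = f"T{t}", f"F{t}", f"F{t}x", f"T{t}d"
        add_node(c, f"{t}Hr", "treatment", t, "expert_row")
        add_node(h, f"{t}Hr fluid", "hydration", t, "expert_row")
        add_node(g, f"{t}Hr fluid (alt)", "hydration", t, "middle")
        add_node(d, f"{t + 6}Hr early check", "treatment", t + 6, "middle")

        nxt = "FINISH" if i == n_treatment_stages - 1 else f"T{times[i + 1]}"

        # Timepoint prompt: binary hydration choice. Which answer is the
        # expert one alternates with stage, as in authored cases.
        yes, no = "Increase hydration rate", "Maintain current hydration rate"
        exp_opt, tol_opt = (no, yes) if i % 2 == 0 else (yes, no)
        edges.append(ChoiceEdge(c, exp_opt, h, "expert"))
        edges.append(ChoiceEdge(c, tol_opt, g, "tolerable"))

        # Treatment menus at both fluid diamonds (expert arm and detour arm).
        for menu_node in (h, g):
            edges.append(
                ChoiceEdge(menu_node, "Obtain the next level in 6 h", nxt, "expert")
            )
            for j in range(n_tol):
                edges.append(
                    ChoiceEdge(menu_node, tolerable_texts[j % len(tolerable_texts)], d, "tolerable")
                )
            for j in range(n_inc):
                if j == 0:
                    dest = "End1"  # premature rescue dosing always collapses here
                    used_endpoints.add("End1")
                else:
                    dest = next_endpoint()
                edges.append(
                    ChoiceEdge(
                        menu_node,
                        incorrect_texts[j % len(incorrect_texts)],
                        dest,
                        "incorrect",
                    )
                )

        # Detour circle: rejoins the spine or fails.
        edges.append(ChoiceEdge(d, "Resume the recommended monitoring schedule", nxt, "expert"))
        edges.append(ChoiceEdge(d, "Continue the current monitoring schedule", nxt, "tolerable"))
        edges.append(ChoiceEdge(d, "Discharge the patient now", next_endpoint(), "incorrect"))

    add_node("FINISH", f"FINISH {finish_time}Hr", "endpoint", finish_time, "expert_row")
    endpoint_labels = {
        "End1": "Premature rescue dose",
        "End2": "Delayed evaluation",
        "End3": "Inappropriate discharge",
        "End4": "Renal injury",
    }
    for eid in sorted(used_endpoints):
        add_node(eid, endpoint_labels[eid], "endpoint", None, "endpoint_row")

    case = CaseGraph(
        case_id=f"demo-{n_treatment_stages}x{options_per_menu}",
        title="Demo branched monitoring case",
        nodes=nodes,
        edges=edges,
        start_node=f"T{times[0]}",
    )
    return require_valid(case)


# ---------------------------------------------------------------------------
# Stochastic cohorts


def _user_rng(seed: int, index: int) -> np.random.Generator:
    # Counter-based derivation: user index extends the seed sequence, so
    # each user's stream is fixed regardless of cohort size.
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def simulate_cohort(case: CaseGraph, spec: CohortSpec) -> CohortResult:
    """Walk stochastic users through the case and emit their raw answers.

    Returns the response records (ready for :func:`casemap.simulate.write_cohort`),
    the ground-truth paths, and how many stray back-button answers were
    injected (when ``p_backtrack`` > 0, a user may leave one answer at a
    node their final path never visits).
    """
    require_valid(case)
    records: list[ResponseRecord] = []
    paths: list[UserPath] = []
    n_injected = 0
    width = max(3, len(str(spec.n_users)))

    role_cycle: list[str | None] = []
    if spec.role_labels:
        for label, count in spec.role_labels:
            role_cycle.extend([label] * count)
        if len(role_cycle) < spec.n_users:
            raise SimulationError(
                f"role_labels cover {len(role_cycle)} users but n_users={spec.n_users}"
            )

    for u in range(spec.n_users):
        rng = _user_rng(spec.seed, u)
        node = case.start_node
        walked: list[ChoiceEdge] = []
        node_seq = [node]
        while not case.nodes[node].is_endpoint:
            out = case.outgoing(node)
            present = []
            for c in CLASS_ORDER:
                if any(e.classification == c for e in out):
                    present.append(c)
            probs = spec.profile.class_probs(node, present)
            cls = rng.choice(present, p=[probs[c] for c in present])
            options = sorted(
                (e for e in out if e.classification == cls), key=lambda e: e.option_text
            )
            edge = options[rng.integers(len(options))]
            walked.append(edge)
            node_seq.append(edge.destination)
            node = edge.destination

        user_id = f"u{u + 1:0{width}d}"
        role = role_cycle[u] if role_cycle else None
        rec = record_for_path(
            case, user_id, walked, group=spec.group_label, role=role
        )
        if spec.p_backtrack > 0 and rng.random() < spec.p_backtrack:
            unvisited = sorted(
                nid
                for nid in case.decision_nodes
                if nid not in node_seq
            )
            if unvisited:
                nid = unvisited[rng.integers(len(unvisited))]
                opts = case.outgoing(nid)
                stray = opts[rng.integers(len(opts))]
                qk = case.nodes[nid].question_key
                assert qk is not None
                rec.answers.setdefault(qk, []).append(stray.option_text)
                n_injected += 1
        records.append(rec)
        paths.append(
            UserPath(
                user_id=user_id,
                nodes=node_seq,
                edges=walked,
                terminal=node_seq[-1],
                complete=True,
                anomalies=[],
                group=spec.group_label,
                role=role,
            )
        )
    return CohortResult(records=records, paths=paths, n_backtracks_injected=n_injected)


def make_archetype_cohort(
    case: CaseGraph,
    n_expert: int,
    n_rejoin: int,
    n_incorrect: int,
    group: str | None = None,
) -> list[ResponseRecord]:
    """Deterministic cohort of three behavioural archetypes.

    * *expert* users take the expert option at every node;
    * *rejoin* users deviate tolerably at the very first prompt, then take
      the locally expert option at every later node, rejoining the route
      and finishing without ever choosing a harmful option;
    * *incorrect* users follow the expert route for one decision and then
      take the first harmful option on the second menu.

    Useful for constructing cohorts with an exact behavioural composition
    (e.g. reproducing a published table row).
    """
    require_valid(case)
    records: list[ResponseRecord] = []
    counter = 0

    def expert_edge(nid: str) -> ChoiceEdge:
        (e,) = [e for e in case.outgoing(nid) if e.classification == "expert"]
        return e

    def walk(first_rule: str) -> list[ChoiceEdge]:
        node = case.start_node
        out: list[ChoiceEdge] = []
        step = 0
        while not case.nodes[node].is_endpoint:
            if step == 0 and first_rule == "tolerable":
                cands = [e for e in case.outgoing(node) if e.classification == "tolerable"]
                if not cands:
                    raise SimulationError(f"node {node!r} offers no tolerable option")
                edge = cands[0]
            elif step == 1 and first_rule == "incorrect":
                cands = [e for e in case.outgoing(node) if e.classification == "incorrect"]
                if not cands:
                    raise SimulationError(f"node {node!r} offers no incorrect option")
                edge = cands[0]
            else:
                edge = expert_edge(node)
            out.append(edge)
            node = edge.destination
            step += 1
        return out

    for rule, n in (("expert", n_expert), ("tolerable", n_rejoin), ("incorrect", n_incorrect)):
        for _ in range(n):
            counter += 1
            records.append(
                record_for_path(case, f"a{counter:03d}", walk(rule), group=group)
            )
    return records


# ---------------------------------------------------------------------------
# Log writing


def write_cohort(
    records: Sequence[ResponseRecord],
    path: str | Path,
    case: CaseGraph | None = None,
) -> None:
    """Write records in the wide response-log dialect read by
    :func:`casemap.responses.read_responses`.

    One column per question key (every key of ``case`` when given, else
    the union over records, sorted); a key holding several recorded
    values for some user is emitted as that many identically-headed
    columns, preserving submission order. Reading the file back recovers
    user_id, group, role and answers exactly.
    """
    import csv

    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if case is not None:
        keys = sorted(
            case.nodes[nid].question_key for nid in case.decision_nodes
        )
    else:
        keys = sorted({k for r in records for k in r.answers})
    depth = {k: 1 for k in keys}
    for r in records:
        for k, vals in r.answers.items():
            depth[k] = max(depth.get(k, 1), len(vals))

    header = ["user_id", "group", "role"]
    for k in keys:
        header.extend([k] * depth[k])

    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(header)
        for r in records:
            row = [r.user_id, r.group or "", r.role or ""]
            for k in keys:
                vals = r.answers.get(k, [])
                row.extend(vals + [""] * (depth[k] - len(vals)))
            w.writerow(row)


def estimate_expert_rate(case: CaseGraph, paths: Sequence[UserPath]) -> tuple[float, int]:
    """Maximum-likelihood estimate of the per-decision expert-choice rate.

    Counts decision encounters at expert-route nodes across the cohort
    and returns (fraction choosing the expert option, number of
    encounters). Under the simulator's independence assumptions this
    recovers the profile's ``p_expert``.
    """
    route = set(case.expert_route)
    n_enc = 0
    n_exp = 0
    for p in paths:
        for e in p.edges:
            if e.source in route:
                n_enc += 1
                n_exp += e.classification == "expert"
    if n_enc == 0:
        return float("nan"), 0
    return n_exp / n_enc, n_enc
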