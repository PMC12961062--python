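"""Cumulative decision-making classification and cohort summary tables.

At every checkpoint along the expert route the cohort is partitioned by
the quality of the decisions made so far:

* ``expert`` — every decision to date is exactly the expert choice;
* ``tolerable_only`` — the user has strayed from the expert route but has
  never taken a harmful option;
* ``incorrect`` — at least one decision would harm the patient.

Incorrect is absorbing and expert is monotone-decreasing: once a user
errs they can rejoin the route but never regain expert status, and once
they pick a harmful option they stay incorrect. Checkpoint ``k`` is
scored from the user's first ``min(k, D)`` decisions (``D`` = total
decisions made), which freezes users at their terminal classification
after they reach an ending and makes the published table arithmetic hold:
at every row ``tolerable + incorrect = N`` (reported *tolerable* counts
expert users too) and the expert/incorrect counts are monotone down the
table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .model import CaseGraph, require_valid
from .responses import UserPath

log = logging.getLogger(__name__)

EXPERT = "expert"
TOLERABLE_ONLY = "tolerable_only"
INCORRECT = "incorrect"


def percentage(count: int, cohort_size: int) -> float:
    """Percentage of the cohort, rounded half-up to one decimal.

    This is the rounding used in published behavior tables (e.g. 14/54 ->
    25.9, 28/54 -> 51.9). An empty cohort reports 0.0.
    """
    if cohort_size == 0:
        return 0.0
    q = (Decimal(100) * Decimal(count) / Decimal(cohort_size)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class CheckpointStatus:
    user_id: str
    checkpoint_index: int
    status: str  # EXPERT | TOLERABLE_ONLY | INCORRECT


@dataclass(frozen=True)
class CheckpointRow:
    node_id: str
    label: str
    n_tolerable: int
    pct_tolerable: float
    n_expert: int
    pct_expert: float
    n_incorrect: int
    pct_incorrect: float


@dataclass
class BehaviorTable:
    """Per-checkpoint counts and percentages over a cohort of size N."""

    rows: list[CheckpointRow]
    cohort_size: int

    COLUMNS = (
        "node_id",
        "label",
        "n_tolerable",
        "pct_tolerable",
        "n_expert",
        "pct_expert",
        "n_incorrect",
        "pct_incorrect",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows], columns=list(self.COLUMNS))

    def write(self, path: str | Path, sep: str | None = None) -> None:
        """Write as CSV/TSV (by extension) with one-decimal percentages."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = self.to_frame()
        for col in ("pct_tolerable", "pct_expert", "pct_incorrect"):
            df[col] = df[col].map(lambda v: f"{v:.1f}")
        df.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class RouteTally:
    route: tuple[str, ...]
    count: int


# ---------------------------------------------------------------------------
# Per-user classification


def classify_user(case: CaseGraph, path: UserPath) -> list[CheckpointStatus]:
    """Score one user at every expert-route checkpoint.

    At checkpoint index ``k`` the first ``min(k, D)`` decisions are
    examined: any incorrect edge makes the status ``incorrect``; a prefix
    identical to the expert route's own edges keeps the user ``expert``;
    anything else is ``tolerable_only``. Index 0 precedes all decisions,
    so every user starts expert.
    """
    require_valid(case)
    for e in path.edges:
        if not case.has_edge(e):
            raise ValueError(
                f"path for user {path.user_id!r} contains edge "
                f"{e.source!r} -> {e.destination!r} not present in case {case.case_id!r}"
            )
    expert_edges = case.expert_edges
    statuses: list[CheckpointStatus] = []
    for k in range(len(case.expert_route)):
        prefix = path.edges[: min(k, len(path.edges))]
        if any(e.classification == "incorrect" for e in prefix):
            status = INCORRECT
        elif all(a == b for a, b in zip(prefix, expert_edges)) and len(prefix) <= len(expert_edges):
            status = EXPERT
        else:
            status = TOLERABLE_ONLY
        statuses.append(CheckpointStatus(path.user_id, k, status))
    return statuses


def behavior_table(
    case: CaseGraph, paths: Iterable[UserPath], strict: bool = False
) -> BehaviorTable:
    """Aggregate per-user checkpoint statuses into the cohort table.

    ``n_tolerable`` counts users whose decisions so far are harmless —
    expert users included — so every row satisfies
    ``n_tolerable + n_incorrect = N``. Incomplete paths are retained and
    frozen at their last status unless ``strict`` drops them.
    """
    require_valid(case)
    paths = list(paths)
    if strict:
        paths = [p for p in paths if p.complete]
    n = len(paths)
    if n == 0:
        warnings.warn("behavior_table called with an empty cohort", stacklevel=2)
    route = case.expert_route
    counts = [{EXPERT: 0, TOLERABLE_ONLY: 0, INCORRECT: 0} for _ in route]
    for path in paths:
        for st in classify_user(case, path):
            counts[st.checkpoint_index][st.status] += 1
    rows = []
    for (nid, by_status) in zip(route, counts):
        n_exp = by_status[EXPERT]
        n_inc = by_status[INCORRECT]
        n_tol = n_exp + by_status[TOLERABLE_ONLY]
        rows.append(
            CheckpointRow(
                node_id=nid,
                label=case.nodes[nid].label,
                n_tolerable=n_tol,
                pct_tolerable=percentage(n_tol, n),
                n_expert=n_exp,
                pct_expert=percentage(n_exp, n),
                n_incorrect=n_inc,
                pct_incorrect=percentage(n_inc, n),
            )
        )
    return BehaviorTable(rows=rows, cohort_size=n)


# ---------------------------------------------------------------------------
# Descriptive tallies (complete paths only, deterministic ordering)


def endpoint_distribution(paths: Iterable[UserPath]) -> dict[str, int]:
    """Count of users finishing at each ending, over complete paths."""
    out: dict[str, int] = {}
    for p in paths:
        if p.complete:
            out[p.terminal] = out.get(p.terminal, 0) + 1
    return dict(sorted(out.items()))


def nodes_visited(paths: Iterable[UserPath]) -> dict[str, int]:
    """Number of nodes on each user's path (incomplete paths included)."""
    return {p.user_id: len(p.nodes) for p in paths}


def route_frequency(paths: Iterable[UserPath]) -> list[RouteTally]:
    """Distinct complete routes, most-travelled first (ties lexicographic)."""
    tally: dict[tuple[str, ...], int] = {}
    for p in paths:
        if p.complete:
            key = tuple(p.nodes)
            tally[key] = tally.get(key, 0) + 1
    return [
        RouteTally(route=r, count=c)
        for r, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupResult:
    label: str
    table: BehaviorTable
    usage: "EdgeUsage"  # noqa: F821 - forward ref to mapping module
    n_users: int


def compare_groups(
    case: CaseGraph,
    paths: Iterable[UserPath],
    grouping: Mapping[str, str] | Callable[[str], str] | None = None,
    labels: Iterable[str] | None = None,
    strict: bool = False,
) -> dict[str, GroupResult]:
    """Split the cohort by label and summarise each group separately.

    ``grouping`` maps user_id to a label (mapping or callable); if omitted
    the ``group`` attribute carried on each path is used. Every user must
    resolve to exactly one label. ``labels`` may name expected groups so
    that an empty group still yields an (empty, warned-about) table —
    useful when one study arm recorded no finishers.
    """
    from .mapping import edge_usage  # local import to avoid a cycle

    require_valid(case)
    paths = list(paths)

    def label_of(p: UserPath) -> str | None:
        if grouping is None:
            return p.group
        if callable(grouping):
            return grouping(p.user_id)
        return grouping.get(p.user_id)

    by_label: dict[str, list[UserPath]] = {lab: [] for lab in (labels or [])}
    for p in paths:
        lab = label_of(p)
        if lab is None:
            raise KeyError(f"user {p.user_id!r} has no group label")
        by_label.setdefault(lab, []).append(p)

    out: dict[str, GroupResult] = {}
    for lab in sorted(by_label):
        members = by_label[lab]
        if not members:
            warnings.warn(f"group {lab!r} has no users", stacklevel=2)
        out[lab] = GroupResult(
            label=lab,
            table=behavior_table(case, members, strict=strict),
            usage=edge_usage(case, members),
            n_users=len(members),
        )
    return out


# ---------------------------------------------------------------------------
# Plain-text exports


def write_endpoint_distribution(dist: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        {"endpoint": list(dist.keys()), "n_users": list(dist.values())}
    ).to_csv(path, sep=sep, index=False)


def write_nodes_visited(visited: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        {"user_id": list(visited.keys()), "n_nodes": list(visited.values())}
    ).to_csv(path, sep=sep, index=False)


def write_route_frequency(tallies: list[RouteTally], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        {
            "route": [" > ".join(t.route) for t in tallies],
            "n_users": [t.count for t in tallies],
        }
    ).to_csv(path, sep=sep, index=False)
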