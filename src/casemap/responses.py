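"""Reading branching-form response logs and replaying them into paths.

Response logs are wide-format tables exported from a branching survey:
one row per submission, one column per form question, and most cells
blank because each respondent only sees the questions along their own
branch. Replay walks the case graph from the start node, consuming the
recorded answer at each visited node, and reconstructs the respondent's
path. Answers recorded for questions the replayed path never visits are
flagged (back-button artifacts), as are missing and multiply-recorded
answers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .model import CaseGraph, ChoiceEdge, normalize_option, require_valid

log = logging.getLogger(__name__)

# Anomaly codes attached to replayed paths.
MISSING_ANSWER = "MISSING_ANSWER"
ORPHAN_ANSWER = "ORPHAN_ANSWER"
MULTI_ANSWER = "MULTI_ANSWER"


class ResponseFormatError(Exception):
    """The response log does not match the expected table dialect."""


class ReplayError(Exception):
    """A recorded answer cannot be reconciled with the case graph."""

    def __init__(self, code: str, node_id: str, detail: str):
        self.code = code
        self.node_id = node_id
        super().__init__(f"{code} at node {node_id!r}: {detail}")


@dataclass
class ResponseRecord:
    """One respondent's raw submission.

    ``answers`` maps question_key to the recorded values in submission
    order; branching legitimately leaves unvisited questions absent.
    """

    user_id: str
    answers: dict[str, list[str]] = field(default_factory=dict)
    group: str | None = None
    role: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ResponseFormatError("user_id must be nonempty")


@dataclass
class UserPath:
    """A replayed route through the case for one respondent."""

    user_id: str
    nodes: list[str]
    edges: list[ChoiceEdge]
    terminal: str
    complete: bool
    anomalies: list[tuple[str, str]] = field(default_factory=list)
    group: str | None = None
    role: str | None = None


# ---------------------------------------------------------------------------
# Log reading


def _open_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    """Return (header, data rows) for CSV/TSV/XLSX, dialect by extension."""
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        try:
            import openpyxl
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ResponseFormatError("reading .xlsx requires openpyxl") from exc
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.active
        rows = [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
    else:
        delim = "\t" if suffix in (".tsv", ".tab") else ","
        with path.open("r", encoding="utf-8-sig", newline="") as fh:
            rows = [list(r) for r in csv.reader(fh, delimiter=delim)]
    if not rows:
        raise ResponseFormatError(f"{path}: empty file (header row required)")
    header = [h.strip() for h in rows[0]]
    return header, rows[1:]


def read_responses(
    path: str | Path,
    case: CaseGraph,
    *,
    id_col: str = "user_id",
    group_col: str | None = "group",
    role_col: str | None = "role",
    timestamp_col: str | None = "timestamp",
    question_cols: dict[str, str | int] | None = None,
) -> list[ResponseRecord]:
    """Read a wide-format response log into one record per row.

    Question columns are matched to the case's question keys by exact
    header text, or through ``question_cols`` (question_key -> header name
    or 0-based column index) when the export headers differ. Duplicate
    headers are legal — repeated columns for one question are collected in
    column order as multiple recorded values. Blank cells are omitted.

    Raises :class:`ResponseFormatError` if the user-id column is missing
    or any case question key matches no column. Duplicate user ids are
    kept as separate records with ``#2``, ``#3`` … suffixes (a warning is
    logged); the log dialect gives no safe way to merge them.
    """
    path = Path(path)
    header, rows = _open_rows(path)
    positions: dict[str, list[int]] = {}
    for i, h in enumerate(header):
        positions.setdefault(h, []).append(i)

    if id_col not in positions:
        raise ResponseFormatError(f"{path}: user-id column {id_col!r} not found in header")
    id_idx = positions[id_col][0]

    def single(colname: str | None) -> int | None:
        if colname is None or colname not in positions:
            return None
        return positions[colname][0]

    group_idx = single(group_col)
    role_idx = single(role_col)
    ts_idx = single(timestamp_col)

    question_cols = question_cols or {}
    qkey_positions: dict[str, list[int]] = {}
    unmatched: list[str] = []
    for nid in case.decision_nodes:
        qk = case.nodes[nid].question_key
        assert qk is not None
        spec = question_cols.get(qk, qk)
        if isinstance(spec, int):
            if spec >= len(header):
                unmatched.append(qk)
            else:
                qkey_positions[qk] = [spec]
        elif spec in positions:
            qkey_positions[qk] = positions[spec]
        else:
            unmatched.append(qk)
    if unmatched:
        raise ResponseFormatError(
            f"{path}: no column found for question keys: {', '.join(sorted(unmatched))}"
        )

    records: list[ResponseRecord] = []
    seen_ids: dict[str, int] = {}
    for r, row in enumerate(rows, start=2):
        def cell(i: int | None) -> str:
            if i is None or i >= len(row) or row[i] is None:
                return ""
            return str(row[i]).strip()

        uid = cell(id_idx)
        if not uid:
            raise ResponseFormatError(f"{path}: row {r}: blank user id")
        seen_ids[uid] = seen_ids.get(uid, 0) + 1
        if seen_ids[uid] > 1:
            log.warning("duplicate user id %r (row %d); keeping as %s#%d", uid, r, uid, seen_ids[uid])
            uid = f"{uid}#{seen_ids[uid]}"

        answers: dict[str, list[str]] = {}
        for qk, idxs in qkey_positions.items():
            vals = [cell(i) for i in idxs]
            vals = [v for v in vals if v]
            if vals:
                answers[qk] = vals
        records.append(
            ResponseRecord(
                user_id=uid,
                answers=answers,
                group=cell(group_idx) or None,
                role=cell(role_idx) or None,
                timestamp=cell(ts_idx) or None,
            )
        )
    log.info("read %d response records from %s", len(records), path)
    return records


# ---------------------------------------------------------------------------
# Replay


def replay_path(case: CaseGraph, record: ResponseRecord) -> UserPath:
    """Replay one respondent's answers into a path through the case.

    Starting at the start node, the answer recorded for each visited
    node's question selects the outgoing edge (exact option-text match
    after whitespace normalisation). The walk stops at an endpoint
    (``complete=True``) or at the first decision node with no recorded
    answer (``complete=False`` plus a MISSING_ANSWER anomaly). If a
    visited question holds several recorded values the last one is used
    (MULTI_ANSWER); answers for questions the path never visits are
    reported as ORPHAN_ANSWER — the signature of a survey back button.

    Raises :class:`ReplayError` (UNMATCHED_OPTION) when a recorded answer
    matches no option at the visited node.
    """
    require_valid(case)
    nodes = [case.start_node]
    edges: list[ChoiceEdge] = []
    anomalies: list[tuple[str, str]] = []
    complete = False
    visited_keys: set[str] = set()

    while True:
        here = case.nodes[nodes[-1]]
        if here.is_endpoint:
            complete = True
            break
        qk = here.question_key
        assert qk is not None
        values = record.answers.get(qk, [])
        if not values:
            anomalies.append((MISSING_ANSWER, qk))
            break
        visited_keys.add(qk)
        if len(values) > 1:
            anomalies.append((MULTI_ANSWER, qk))
        answer = values[-1]
        edge = case.edge_for(here.node_id, answer)
        if edge is None:
            options = [e.option_text for e in case.outgoing(here.node_id)]
            raise ReplayError(
                "UNMATCHED_OPTION",
                here.node_id,
                f"answer {answer!r} (user {record.user_id!r}) matches none of {options!r}",
            )
        edges.append(edge)
        nodes.append(edge.destination)

    for qk in sorted(set(record.answers) - visited_keys):
        anomalies.append((ORPHAN_ANSWER, qk))

    return UserPath(
        user_id=record.user_id,
        nodes=nodes,
        edges=edges,
        terminal=nodes[-1],
        complete=complete,
        anomalies=anomalies,
        group=record.group,
        role=record.role,
    )


def replay_cohort(
    case: CaseGraph, records: list[ResponseRecord], strict: bool = False
) -> list[UserPath]:
    """Replay every record; with ``strict`` drop incomplete paths."""
    paths = [replay_path(case, rec) for rec in records]
    n_incomplete = sum(1 for p in paths if not p.complete)
    if n_incomplete:
        log.info("%d of %d paths are incomplete", n_incomplete, len(paths))
    if strict:
        paths = [p for p in paths if p.complete]
    return paths


def record_for_path(case: CaseGraph, user_id: str, edge_seq: list[ChoiceEdge], **kw) -> ResponseRecord:
    """Build the response record whose replay yields the given edge walk."""
    answers: dict[str, list[str]] = {}
    for e in edge_seq:
        qk = case.nodes[e.source].question_key
        assert qk is not None
        answers.setdefault(qk, []).append(e.option_text)
    return ResponseRecord(user_id=user_id, answers=answers, **kw)
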