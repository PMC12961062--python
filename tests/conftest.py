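import pytest

from casemap import make_demo_case
from casemap.model import case_from_dict


@pytest.fixture(scope="session")
def demo_case():
    """The full-size demo case: 5 timepoint stages, 8-option menus."""
    return make_demo_case(5, 8)


@pytest.fixture(scope="session")
def small_case():
    """A small case whose root-to-leaf paths are cheap to enumerate."""
    return make_demo_case(2, 3)


@pytest.fixture()
def minimal_case():
    """Smallest legal case: one decision, two endings, one expert option."""
    return case_from_dict(
        {
            "case_id": "minimal",
            "title": "One decision",
            "start": "S",
            "nodes": [
                {"id": "S", "label": "Start", "kind": "treatment",
                 "timepoint_hours": 0, "question_key": "q_S", "tier": "expert_row"},
                {"id": "FINISH", "label": "Done", "kind": "endpoint", "tier": "expert_row"},
                {"id": "End1", "label": "Fail", "kind": "endpoint", "tier": "endpoint_row"},
            ],
            "edges": [
                {"from": "S", "option": "Treat now", "to": "FINISH", "class": "expert"},
                {"from": "S", "option": "Wait", "to": "End1", "class": "tolerable"},
            ],
        }
    )


def iter_edge_paths(case, limit=None):
    """Exhaustively enumerate all root-to-leaf edge sequences (oracle)."""
    out = []

    def rec(node, acc):
        if case.nodes[node].is_endpoint:
            out.append(list(acc))
            if limit is not None and len(out) > limit:
                raise RuntimeError("too many paths to enumerate")
            return
        for e in case.outgoing(node):
            acc.append(e)
            rec(e.destination, acc)
            acc.pop()

    rec(case.start_node, [])
    return out


def forward_scan_status(case, path):
    """Independent re-derivation of per-checkpoint statuses: a forward
    walk that tracks status as decisions accumulate, instead of scoring
    each checkpoint from a prefix slice."""
    expert_edges = case.expert_edges
    statuses = ["expert"]
    status = "expert"
    route_pos = 0
    for e in path.edges:
        if status != "incorrect" and e.classification == "incorrect":
            status = "incorrect"
        elif status == "expert":
            if route_pos < len(expert_edges) and e == expert_edges[route_pos]:
                route_pos += 1
            else:
                status = "tolerable_only"
        statuses.append(status)
    # Freeze at the terminal status out to the last checkpoint.
    k = len(case.expert_route)
    while len(statuses) < k:
        statuses.append(statuses[-1])
    return statuses[:k]
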