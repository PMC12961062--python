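import pytest
from hypothesis import given, settings, strategies as st

from casemap import (
    BehaviorProfile,
    CohortSpec,
    behavior_table,
    classify_user,
    compare_groups,
    endpoint_distribution,
    make_archetype_cohort,
    nodes_visited,
    percentage,
    replay_cohort,
    replay_path,
    route_frequency,
    simulate_cohort,
)
from casemap.behavior import EXPERT, INCORRECT, TOLERABLE_ONLY
from casemap.responses import record_for_path
from conftest import forward_scan_status


class TestPercentage:
    @pytest.mark.parametrize(
        "count,expected",
        # Every distinct count printed in the published N=54 table.
        [(54, 100.0), (53, 98.1), (43, 79.6), (41, 75.9), (33, 61.1), (26, 48.1),
         (17, 31.5), (14, 25.9), (13, 24.1), (11, 20.4), (21, 38.9), (28, 51.9),
         (0, 0.0)],
    )
    def test_reproduces_published_rounding(self, count, expected):
        assert percentage(count, 54) == expected

    def test_rounds_halves_up(self):
        assert percentage(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert percentage(1, 1600) == 0.1  # 0.0625

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(1, 500))
    def test_half_up_matches_integer_arithmetic_oracle(self, count, n):
        count = min(count, n)
        # floor(1000*count/n + 1/2) / 10, in exact integer arithmetic
        expected = (2000 * count + n) // (2 * n) / 10
        assert percentage(count, n) == expected


class TestClassifyUser:
    def test_fully_expert_path_is_expert_at_every_checkpoint(self, demo_case):
        rec = record_for_path(demo_case, "u1", demo_case.expert_edges)
        statuses = classify_user(demo_case, replay_path(demo_case, rec))
        assert [s.status for s in statuses] == [EXPERT] * len(demo_case.expert_route)

    def test_tolerable_deviation_then_rejoin_never_incorrect(self, demo_case):
        # Deviate at the very first hydration prompt, then act expertly.
        recs = make_archetype_cohort(demo_case, 0, 1, 0)
        path = replay_path(demo_case, recs[0])
        assert path.terminal == demo_case.finish_node
        statuses = [s.status for s in classify_user(demo_case, path)]
        assert statuses[0] == EXPERT  # no decisions made yet
        assert all(s == TOLERABLE_ONLY for s in statuses[1:])

    def test_incorrect_is_absorbing(self, demo_case):
        recs = make_archetype_cohort(demo_case, 0, 0, 1)
        path = replay_path(demo_case, recs[0])
        statuses = [s.status for s in classify_user(demo_case, path)]
        assert statuses[:2] == [EXPERT, EXPERT]  # first decision was expert
        assert all(s == INCORRECT for s in statuses[2:])

    def test_incomplete_path_frozen_at_last_status(self, demo_case):
        rec = record_for_path(demo_case, "u1", demo_case.expert_edges[:2])
        statuses = [s.status for s in classify_user(demo_case, replay_path(demo_case, rec))]
        assert all(s == EXPERT for s in statuses)

    def test_path_from_another_case_refused(self, demo_case, minimal_case):
        path = replay_path(minimal_case, record_for_path(minimal_case, "u1",
                                                         minimal_case.expert_edges))
        with pytest.raises(ValueError, match="not present in case"):
            classify_user(demo_case, path)

    def test_agrees_with_forward_scan_oracle(self, demo_case):
        res = simulate_cohort(demo_case, CohortSpec(n_users=60, seed=11))
        for path in res.paths:
            got = [s.status for s in classify_user(demo_case, path)]
            assert got == forward_scan_status(demo_case, path)


class TestBehaviorTable:
    def test_all_expert_cohort(self, demo_case):
        recs = make_archetype_cohort(demo_case, 7, 0, 0)
        table = behavior_table(demo_case, replay_cohort(demo_case, recs))
        for row in table.rows:
            assert (row.n_tolerable, row.pct_tolerable) == (7, 100.0)
            assert (row.n_expert, row.pct_expert) == (7, 100.0)
            assert (row.n_incorrect, row.pct_incorrect) == (0, 0.0)

    def test_single_incorrect_user_absorbs(self, demo_case):
        recs = make_archetype_cohort(demo_case, 0, 0, 1)
        table = behavior_table(demo_case, replay_cohort(demo_case, recs))
        for row in table.rows[2:]:
            assert (row.n_tolerable, row.pct_tolerable) == (0, 0.0)
            assert (row.n_expert, row.pct_expert) == (0, 0.0)
            assert (row.n_incorrect, row.pct_incorrect) == (1, 100.0)

    def test_empty_cohort_warns_and_reports_zero(self, demo_case):
        with pytest.warns(UserWarning, match="empty cohort"):
            table = behavior_table(demo_case, [])
        assert table.cohort_size == 0
        assert all(r.pct_tolerable == 0.0 for r in table.rows)

    def test_tsv_export_has_one_decimal_percentages(self, demo_case, tmp_path):
        recs = make_archetype_cohort(demo_case, 14, 12, 28)
        table = behavior_table(demo_case, replay_cohort(demo_case, recs))
        out = tmp_path / "table.tsv"
        table.write(out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == list(table.COLUMNS)
        finish = lines[-1].split("\t")
        assert finish[3:] == ["48.1", "14", "25.9", "28", "51.9"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.integers(1, 3), st.integers(3, 9), st.integers(0, 10_000),
        st.floats(0.05, 0.9),
    )
    def test_partition_and_monotonicity_invariants(self, stages, options, seed, p_exp):
        from casemap import make_demo_case

        case = make_demo_case(stages, options)
        rest = 1.0 - p_exp
        profile = BehaviorProfile(p_exp, rest * 0.6, rest - rest * 0.6)
        res = simulate_cohort(case, CohortSpec(n_users=25, seed=seed, profile=profile))
        table = behavior_table(case, res.paths)
        prev_exp, prev_inc = None, None
        for row in table.rows:
            assert row.n_tolerable + row.n_incorrect == 25
            assert row.n_expert <= row.n_tolerable
            if prev_exp is not None:
                assert row.n_expert <= prev_exp
                assert row.n_incorrect >= prev_inc
            prev_exp, prev_inc = row.n_expert, row.n_incorrect


class TestTallies:
    @pytest.fixture()
    def five_paths(self, small_case):
        recs = make_archetype_cohort(small_case, 2, 1, 2)
        return replay_cohort(small_case, recs)

    def test_tallies_match_naive_counting(self, small_case, five_paths):
        dist = endpoint_distribution(five_paths)
        naive = {}
        for p in five_paths:
            naive[p.terminal] = naive.get(p.terminal, 0) + 1
        assert dist == naive
        assert sum(dist.values()) == 5
        assert dist[small_case.finish_node] == 3  # 2 expert + 1 rejoin

        visited = nodes_visited(five_paths)
        assert visited == {p.user_id: len(p.nodes) for p in five_paths}

        tallies = route_frequency(five_paths)
        assert sum(t.count for t in tallies) == 5
        assert tallies[0].count == max(t.count for t in tallies)
        # Two expert users share one route; two incorrect users share another.
        assert sorted((t.count for t in tallies), reverse=True) == [2, 2, 1]

    def test_all_expert_cohort_funnels_to_finish(self, small_case):
        recs = make_archetype_cohort(small_case, 4, 0, 0)
        paths = replay_cohort(small_case, recs)
        assert endpoint_distribution(paths) == {small_case.finish_node: 4}
        (tally,) = route_frequency(paths)
        assert tally.route == tuple(small_case.expert_route)
        assert tally.count == 4

    def test_incomplete_paths_excluded_from_endpoint_distribution(self, demo_case):
        recs = make_archetype_cohort(demo_case, 1, 0, 0)
        recs.append(record_for_path(demo_case, "stub", demo_case.expert_edges[:1]))
        paths = replay_cohort(demo_case, recs)
        assert sum(endpoint_distribution(paths).values()) == 1
        assert sum(t.count for t in route_frequency(paths)) == 1
        assert len(nodes_visited(paths)) == 2  # but everyone is listed here


class TestCompareGroups:
    def test_group_counts_sum_to_whole_cohort(self, demo_case):
        recs = make_archetype_cohort(demo_case, 6, 4, 8)
        paths = replay_cohort(demo_case, recs)
        grouping = {p.user_id: ("SOC" if i % 2 else "MTX") for i, p in enumerate(paths)}
        results = compare_groups(demo_case, paths, grouping)
        assert set(results) == {"MTX", "SOC"}
        whole = behavior_table(demo_case, paths)
        for i, row in enumerate(whole.rows):
            for attr in ("n_tolerable", "n_expert", "n_incorrect"):
                split = sum(getattr(r.table.rows[i], attr) for r in results.values())
                assert split == getattr(row, attr)
        for key in results["SOC"].usage.per_edge:
            total = (results["SOC"].usage.per_edge[key].count
                     + results["MTX"].usage.per_edge[key].count)
            assert total == sum(1 for p in paths for e in p.edges
                                if (e.source, e.option_text) == key)

    def test_single_label_partition_identity(self, demo_case):
        recs = make_archetype_cohort(demo_case, 3, 2, 1)
        paths = replay_cohort(demo_case, recs)
        results = compare_groups(demo_case, paths, lambda uid: "all")
        assert results["all"].table == behavior_table(demo_case, paths)

    def test_missing_user_is_an_error(self, demo_case):
        paths = replay_cohort(demo_case, make_archetype_cohort(demo_case, 1, 0, 0))
        with pytest.raises(KeyError, match="a001"):
            compare_groups(demo_case, paths, {})

    def test_empty_group_yields_warned_empty_table(self, demo_case):
        paths = replay_cohort(demo_case, make_archetype_cohort(demo_case, 2, 0, 0))
        with pytest.warns(UserWarning, match="no users"):
            results = compare_groups(
                demo_case, paths, lambda uid: "SOC", labels=["SOC", "MTX"]
            )
        assert results["MTX"].n_users == 0
        assert results["SOC"].n_users == 2

    def test_role_disaggregation_via_path_labels(self, demo_case):
        res = simulate_cohort(
            demo_case,
            CohortSpec(
                n_users=54, seed=2, group_label="SOC",
                role_labels=[("medical student", 36), ("pharmacy resident", 8), ("nurse", 10)],
            ),
        )
        for p in res.paths:
            p.group = p.role
        results = compare_groups(demo_case, res.paths)
        assert sum(r.n_users for r in results.values()) == 54
        assert results["medical student"].n_users == 36
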