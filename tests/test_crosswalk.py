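"""Mapping-table construction: classification, composition, overlap merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arealink.core import ConfigError
from arealink.crosswalk import (
    LinkageGraph,
    build_mapping_table,
    choose_direction,
    classify_components,
    compose,
    merge_overlapping,
)

from conftest import make_matrix
from oracles import flood_fill_components, median, path_composition, shared_eco_partition


class TestChooseDirection:
    def test_larger_median_side_wins(self):
        # medians 70 km² (medical) vs 10.8 km² (ecological)
        med = [21.6, 70.0, 147.6]
        eco = [6.4, 10.8, 18.4]
        assert choose_direction(med, eco) == "medical"
        assert choose_direction(eco, med) == "eco"

    def test_tie_is_ambiguous(self):
        with pytest.raises(ConfigError, match="ambiguous"):
            choose_direction([1.0, 2.0], [2.0, 1.0])

    def test_agrees_with_sort_based_median(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = list(rng.uniform(1, 100, size=201))
            b = list(rng.uniform(1, 100, size=201))
            expected = "medical" if median(a) > median(b) else "eco"
            assert choose_direction(a, b) == expected


class TestClassifyComponents:
    @pytest.mark.parametrize(
        "links,expected",
        [
            ({("e1", "z1")}, ["one_to_one"]),
            ({("e1", "z1"), ("e2", "z1")}, ["many_to_one"]),
            ({("e1", "z1"), ("e1", "z2")}, ["one_to_many"]),
            ({("e1", "z1"), ("e1", "z2"), ("e2", "z2")}, ["many_to_many"]),
            ({("e1", "z1"), ("e2", "z2")}, ["one_to_one", "one_to_one"]),
        ],
    )
    def test_cardinality_patterns(self, links, expected):
        comps = classify_components(make_matrix(links))
        assert sorted(c.situation for c in comps) == sorted(expected)

    def test_components_partition_links(self):
        links = {("e1", "z1"), ("e2", "z1"), ("e3", "z2"), ("e3", "z3")}
        comps = classify_components(make_matrix(links))
        assert set().union(*(c.links for c in comps)) == links
        assert sum(len(c.links) for c in comps) == len(links)

    def test_matches_flood_fill_on_all_small_bipartite_graphs(self):
        # every non-empty link set over 3 sources x 3 targets
        sources, targets = ["e1", "e2", "e3"], ["z1", "z2", "z3"]
        all_links = list(itertools.product(sources, targets))
        rng = np.random.default_rng(1)
        for _ in range(300):
            mask = rng.random(9) < 0.4
            links = {l for l, m in zip(all_links, mask) if m}
            if not links:
                continue
            comps = classify_components(make_matrix(links))
            got = {frozenset(c.sources) | frozenset("T" + t for t in c.targets)
                   for c in comps}
            nodes = {s for s, _ in links} | {"T" + t for _, t in links}
            expected = flood_fill_components(
                nodes, [(s, "T" + t) for s, t in links]
            )
            assert got == expected


class TestCompose:
    def test_path_composition(self):
        m1 = make_matrix({("e1", "z1"), ("e2", "z1")}, k=1)
        m2 = make_matrix({("z1", "m1")}, k=2)
        g = compose([m1, m2])
        assert g.links == frozenset({("e1", "m1"), ("e2", "m1")})

    def test_single_matrix_is_identity(self):
        m = make_matrix({("e1", "m1")})
        assert compose([m]).links == m.links

    def test_chain_break_detected(self):
        m1 = make_matrix({("e1", "z1")}, k=1, source_level=1, target_level=2)
        m3 = make_matrix({("y1", "m1")}, k=2, source_level=3, target_level=4)
        with pytest.raises(ConfigError, match="chain break"):
            compose([m1, m3])

    def test_dangling_ids_reported_not_silent(self):
        m1 = make_matrix({("e1", "z1"), ("e2", "z9")}, k=1)
        m2 = make_matrix({("z1", "m1")}, k=2)
        g = compose([m1, m2])
        assert g.links == frozenset({("e1", "m1")})
        assert g.dangling == {1: ["z9"]}

    def test_random_chains_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        ids = [[f"a{i}" for i in range(50)], [f"b{i}" for i in range(50)],
               [f"c{i}" for i in range(50)]]
        for _ in range(5):
            chains = []
            for lvl in range(2):
                links = {
                    (s, t)
                    for s in ids[lvl]
                    for t in ids[lvl + 1]
                    if rng.random() < 0.05
                }
                if not links:
                    links = {(ids[lvl][0], ids[lvl + 1][0])}
                chains.append(links)
            ms = [make_matrix(c, k=i + 1) for i, c in enumerate(chains)]
            assert compose(ms).links == frozenset(path_composition(chains))


class TestMergeOverlapping:
    def test_direct_overlap_merges(self):
        g = LinkageGraph(links=frozenset({("e1", "m1"), ("e1", "m2")}))
        t = merge_overlapping(g)
        assert t.partition() == {frozenset({"m1", "m2"})}
        assert t.analysis_units == {"m1+m2": frozenset({"m1", "m2"})}

    def test_no_overlap_no_merge(self):
        g = LinkageGraph(links=frozenset({("e1", "m1"), ("e2", "m2")}))
        t = merge_overlapping(g)
        assert t.partition() == {frozenset({"m1"}), frozenset({"m2"})}

    def test_matches_union_find_oracle_on_random_graphs(self):
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            links = {
                (f"e{i}", f"m{j}")
                for i in range(100)
                for j in range(30)
                if rng.random() < 0.03
            }
            links |= {(f"e{i}", f"m{i % 30}") for i in range(100)}  # cover all
            t = merge_overlapping(LinkageGraph(links=frozenset(links)))
            assert t.partition() == shared_eco_partition(links)

    def test_eco_to_analysis_is_a_function(self, mixed_mapping):
        table, _ = mixed_mapping
        per_eco = table.rows.groupby("eco_id")["analysis_id"].nunique()
        assert (per_eco == 1).all()

    def test_idempotent(self):
        g = LinkageGraph(
            links=frozenset({("e1", "m1"), ("e1", "m2"), ("e2", "m3")})
        )
        t1 = merge_overlapping(g)
        relinked = frozenset(
            (e, t1.eco_to_analysis[e]) for e, _ in g.links
        )
        t2 = merge_overlapping(LinkageGraph(links=relinked))
        assert {frozenset({a}) for a in t1.analysis_units} == t2.partition()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        links=st.sets(
            st.tuples(
                st.sampled_from([f"e{i}" for i in range(8)]),
                st.sampled_from([f"m{i}" for i in range(5)]),
            ),
            min_size=1,
            max_size=20,
        ),
        extra=st.tuples(
            st.sampled_from([f"e{i}" for i in range(8)]),
            st.sampled_from([f"m{i}" for i in range(5)]),
        ),
    )
    def test_adding_a_link_never_splits_units(self, links, extra):
        before = merge_overlapping(LinkageGraph(links=frozenset(links)))
        after = merge_overlapping(LinkageGraph(links=frozenset(links | {extra})))
        assert after.n_analysis_units <= before.n_analysis_units + 1
        # every pre-existing unit is contained in some post-addition unit
        for unit in before.partition():
            assert any(unit <= u for u in after.partition())


class TestBuildMappingTable:
    def test_two_matrix_toy_single_target(self):
        # four communes -> two zips -> one medical unit
        m1 = make_matrix(
            {("e1", "z1"), ("e2", "z1"), ("e3", "z2"), ("e4", "z2")}, k=1
        )
        m2 = make_matrix({("z1", "m1"), ("z2", "m1")}, k=2)
        table, census = build_mapping_table([m1, m2])
        assert table.n_analysis_units == 1
        assert set(table.eco_to_analysis) == {"e1", "e2", "e3", "e4"}
        assert census["matrices"]["M_1"]["many_to_one"]["links"] == 4

    def test_no_overlap_means_analysis_equals_medical(self):
        from arealink.synthgeo import GeographyParams, generate_geography

        g = generate_geography(
            GeographyParams(seed=3, overlap_rate=0.0, fragmentation_rate=0.0)
        )
        table, census = build_mapping_table([g.m1, g.m2])
        assert table.n_analysis_units == g.params.n_medical
        assert census["overlap_merges"]["analysis_units_created"] == 0

    def test_recovers_planted_partition(self, mixed_geography, mixed_mapping):
        table, _ = mixed_mapping
        assert table.partition() == mixed_geography.truth.analysis_partition

    def test_census_percentages_sum_to_100(self, mixed_mapping):
        _, census = mixed_mapping
        for stats in census["matrices"].values():
            assert sum(s["pct_links"] for s in stats.values()) == pytest.approx(100.0)

    def test_base_eco_reverses_the_chain(self):
        m1 = make_matrix({("e1", "z1"), ("e2", "z1")}, k=1)
        m2 = make_matrix({("z1", "m1")}, k=2)
        table, _ = build_mapping_table([m1, m2], base="eco")
        # seen from the ecological side, the medical unit maps onto both ecos,
        # which now overlap and merge into one analysis unit
        assert set(table.eco_to_analysis) == {"m1"}
        assert table.partition() == {frozenset({"e1", "e2"})}
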