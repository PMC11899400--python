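"""ROAV scoring, retention indices, radar grading and the flavor network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harvestomics import flavor
from harvestomics.errors import InvalidArgumentError, InvalidInputError, OutOfRangeError


def _odor(rows):
    return pd.DataFrame(rows, columns=["compound_id", "group", "peak_area", "odor_threshold"])


class TestRoav:
    def test_hand_oav_ratio(self):
        table = _odor([("A", "g", 10.0, 0.1), ("B", "g", 5.0, 1.0)])
        recs = {r.compound_id: r for r in flavor.compute_roav(table)}
        assert recs["A"].roav == pytest.approx(100.0)
        assert recs["A"].is_reference
        assert recs["B"].roav == pytest.approx(5.0)  # OAV 5 vs reference OAV 100

    def test_single_compound_scores_100(self):
        table = _odor([("X", "g", 3.0, 0.5)])
        (rec,) = flavor.compute_roav(table)
        assert rec.roav == pytest.approx(100.0) and rec.is_reference

    def test_reference_scores_100_in_literal_mode_too(self):
        table = _odor([("A", "g", 10.0, 0.1), ("B", "g", 5.0, 1.0)])
        recs = {r.compound_id: r for r in flavor.compute_roav(table, mode="literal_eq3")}
        ref = [r for r in recs.values() if r.is_reference]
        assert len(ref) == 1 and ref[0].roav == pytest.approx(100.0)

    def test_default_mode_bounded_and_ranking_matches_oav(self, odor_table):
        table, truth = odor_table
        recs = flavor.compute_roav(table)
        frame = flavor.roav_frame(recs)
        assert (frame["roav"] > 0).all() and (frame["roav"] <= 100 + 1e-9).all()
        for group, sub in frame.groupby("group"):
            by_roav = sub.sort_values("roav", ascending=False, kind="stable")["compound_id"].tolist()
            assert by_roav == truth.oav_ranking[group]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_uniform_area_rescaling(self, scale):
        table = _odor([("A", "g", 10.0, 0.1), ("B", "g", 5.0, 1.0), ("C", "g", 2.0, 0.01)])
        base = {r.compound_id: r.roav for r in flavor.compute_roav(table)}
        scaled_table = table.assign(peak_area=table["peak_area"] * scale)
        scaled = {r.compound_id: r.roav for r in flavor.compute_roav(scaled_table)}
        for c in base:
            assert scaled[c] == pytest.approx(base[c], rel=1e-9)

    def test_global_scope_single_reference(self, odor_table):
        table, _ = odor_table
        frame = flavor.roav_frame(flavor.compute_roav(table, reference_scope="global"))
        assert frame[frame["is_reference"]]["compound_id"].nunique() == 1

    def test_zero_threshold_rejected(self):
        table = _odor([("A", "g", 1.0, 0.0)])
        with pytest.raises(InvalidInputError):
            flavor.compute_roav(table)


class TestKeyCompounds:
    def _records(self):
        table = _odor([("A", "g", 100.0, 0.1), ("B", "g", 1.5, 1.0), ("C", "g", 1.0, 1.0)])
        return flavor.compute_roav(table)

    def test_strict_threshold_semantics(self):
        recs = [
            flavor.RoavRecord("a", "g", 1.5, 1.5, False, True),
            flavor.RoavRecord("b", "g", 0.5, 0.5, False, False),
            flavor.RoavRecord("c", "g", 1.0, 1.0, False, False),
        ]
        keys = flavor.select_key_compounds(recs)
        assert set(keys["compound_id"]) == {"a"}  # exactly 1 is NOT key

    def test_counts_match_flags(self, odor_table):
        table, _ = odor_table
        recs = flavor.compute_roav(table)
        keys = flavor.select_key_compounds(recs)
        assert len(keys) == sum(r.is_key for r in recs)
        assert sum(keys.attrs["key_counts"].values()) == len(keys)


class TestRetentionIndex:
    ALKANES = {7: 5.0, 8: 10.0, 9: 12.0, 10: 15.5}

    def test_node_value(self):
        assert flavor.retention_index(12.0, self.ALKANES).ri == pytest.approx(900.0)

    def test_midpoint_arithmetic(self):
        res = flavor.retention_index(11.0, {8: 10.0, 9: 12.0})
        assert res.ri == pytest.approx(850.0)
        assert (res.lower_carbon, res.upper_carbon) == (8, 9)

    def test_bracketing_bound(self):
        res = flavor.retention_index(14.0, self.ALKANES)
        assert 900 <= res.ri <= 1000

    def test_out_of_span_and_non_monotone_rejected(self):
        with pytest.raises(OutOfRangeError):
            flavor.retention_index(99.0, self.ALKANES)
        with pytest.raises(InvalidInputError):
            flavor.retention_index(1.0, {8: 10.0, 9: 9.0})
        with pytest.raises(InvalidArgumentError):
            flavor.retention_index(1.0, {8: 10.0})


class TestRadar:
    KEYS = pd.DataFrame({
        "compound_id": ["c1", "c2", "c3", "c4"],
        "group": ["g1"] * 4,
        "roav": [50.0, 20.0, 10.0, 5.0],
    })
    DESC = {"c1": ["sweet", "green"], "c2": ["sweet"], "c3": ["sweet"], "c4": ["woody"]}

    def test_most_frequent_gets_grade_5(self):
        radar = flavor.descriptor_radar(self.KEYS, self.DESC)
        grades = dict(zip(radar["descriptor"], radar["grade"]))
        assert grades["sweet"] == 5
        assert grades["woody"] == 1
        assert set(radar["grade"]) <= set(range(1, 6))

    def test_single_descriptor_degenerate_grade_5(self):
        radar = flavor.descriptor_radar(self.KEYS.iloc[:1], {"c1": ["sweet"]})
        assert radar["grade"].tolist() == [5]

    def test_uncovered_compound_goes_to_unknown(self):
        radar = flavor.descriptor_radar(self.KEYS.iloc[:1], {})
        assert radar["descriptor"].tolist() == ["unknown"]

    def test_empty_keys_empty_radar(self):
        assert flavor.descriptor_radar(pd.DataFrame(columns=self.KEYS.columns), {}).empty


class TestNetwork:
    def test_incidence_degrees(self):
        keys = pd.DataFrame({"compound_id": ["c1", "c2"], "group": ["g", "g"], "roav": [10, 5]})
        graph, degrees = flavor.flavor_network(keys, {"c1": ["sweet"], "c2": ["sweet", "green"]})
        deg = dict(zip(degrees["node"], degrees["degree"]))
        assert deg["sweet"] == 2
        assert graph.number_of_edges() == 3  # total descriptor incidences

    def test_isolated_compound_retained(self):
        keys = pd.DataFrame({"compound_id": ["lonely"], "group": ["g"], "roav": [2.0]})
        graph, degrees = flavor.flavor_network(keys, {})
        assert "lonely" in graph.nodes and graph.degree["lonely"] == 0

    def test_edge_count_matches_toy_map(self, odor_table):
        table, _ = odor_table
        keys = flavor.select_key_compounds(flavor.compute_roav(table))
        dmap = {
            c: d.split(";") for c, d in table.drop_duplicates("compound_id")[
                ["compound_id", "descriptors"]].itertuples(index=False)
        }
        graph, _ = flavor.flavor_network(keys, dmap)
        expected = sum(len(dmap[c]) for c in set(keys["compound_id"]))
        assert graph.number_of_edges() == len(
            {(c, d) for c in set(keys["compound_id"]) for d in dmap[c]}
        ) == expected
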