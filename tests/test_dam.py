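"""Pairwise differential screening and multi-comparison integration."""

import numpy as np
import pandas as pd
import pytest

from harvestomics import dam, synthetic
from harvestomics.errors import InvalidArgumentError
from harvestomics.feature_table import FeatureTable


def _two_group_table(n_per_group=10, n_features=200, n_dam=60, effect=2.0,
                     noise_cv=0.05, seed=23):
    """First vs last group of a synthetic design, spiked truth recorded."""
    table, truth = synthetic.generate_feature_table(
        n_groups=2, n_reps=n_per_group, n_qc=4, n_features=n_features,
        n_dam=n_dam, effect_log2=effect, drift_amplitude=0.0,
        noise_cv=noise_cv, seed=seed,
    )
    return table.without_qc(), truth


@pytest.fixture(scope="module")
def spiked():
    return _two_group_table()


class TestPairwiseDam:
    def test_identical_groups_yield_no_calls(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(10, 0.2, size=(12, 30))
        samples = pd.DataFrame(
            {"group": ["A"] * 6 + ["B"] * 6, "injection_order": range(1, 13)},
            index=pd.Index([f"s{i}" for i in range(12)], name="sample_id"),
        )
        table = FeatureTable(samples, pd.DataFrame(values, index=samples.index,
                                                   columns=[f"f{i}" for i in range(30)]))
        records = dam.pairwise_dam(table, "A", "B")
        flagged = [r for r in records if r.status != "ns"]
        # exchangeable groups: expect ~5% false positives at most by chance
        assert len(flagged) <= 0.15 * len(records)

    def test_spike_recovery_sensitivity_and_fpr(self, spiked):
        table, truth = spiked
        ga, gb = table.groups()
        records = dam.pairwise_dam(table, ga, gb)
        by_id = {r.feature_id: r for r in records}
        spiked_ids = set(truth.dam_features)
        hits = {f for f, r in by_id.items() if r.status != "ns"}
        sensitivity = len(hits & spiked_ids) / len(spiked_ids)
        fpr = len(hits - spiked_ids) / (len(by_id) - len(spiked_ids))
        assert sensitivity >= 0.95
        assert fpr <= 0.05

    def test_direction_matches_truth_sign(self, spiked):
        table, truth = spiked
        ga, gb = table.groups()
        records = {r.feature_id: r for r in dam.pairwise_dam(table, ga, gb)}
        for feat, effect in truth.dam_features.items():
            rec = records[feat]
            if rec.status == "ns":
                continue
            assert (rec.status == "up") == (effect > 0)
            assert np.sign(rec.log2fc) == np.sign(effect)

    def test_swap_flips_fc_and_labels_keeps_p(self, spiked):
        table, _ = spiked
        ga, gb = table.groups()
        fwd = {r.feature_id: r for r in dam.pairwise_dam(table, ga, gb)}
        rev = {r.feature_id: r for r in dam.pairwise_dam(table, gb, ga)}
        for feat, f in fwd.items():
            r = rev[feat]
            assert r.log2fc == pytest.approx(-f.log2fc, abs=1e-9)
            assert r.p_value == pytest.approx(f.p_value, rel=1e-9)
            assert {f.status, r.status} in ({"ns"}, {"up", "down"}, {"up"}, {"down"}) or \
                (f.status, r.status) in [("up", "down"), ("down", "up"), ("ns", "ns")]

    def test_column_order_invariance(self, spiked):
        table, _ = spiked
        ga, gb = table.groups()
        shuffled = table.with_values(table.values[table.values.columns[::-1]])
        fwd = {r.feature_id: r.status for r in dam.pairwise_dam(table, ga, gb)}
        rev = {r.feature_id: r.status for r in dam.pairwise_dam(shuffled, ga, gb)}
        assert fwd == rev

    def test_absent_group_rejected(self, spiked):
        table, _ = spiked
        with pytest.raises(InvalidArgumentError):
            dam.pairwise_dam(table, "G1", "nope")

    def test_default_thresholds(self):
        assert dam.DEFAULT_VIP_THRESHOLD == 1.0
        assert dam.DEFAULT_P_THRESHOLD == 0.05


class TestVolcano:
    def test_partition_and_boundary(self, spiked):
        table, _ = spiked
        ga, gb = table.groups()
        records = dam.pairwise_dam(table, ga, gb)
        frame = dam.volcano_table(records)
        counts = frame.attrs["counts"]
        assert counts["up"] + counts["down"] + counts["ns"] == len(frame)
        sig = frame[frame["status"] != "ns"]
        # VIP passed for these rows, so p < 0.05 <=> y > -log10(0.05)
        assert (sig["neg_log10_p"] > -np.log10(0.05) - 1e-12).all()
        assert -np.log10(0.05) == pytest.approx(1.301, abs=1e-3)

    def test_p_equal_one_maps_to_zero(self):
        rec = dam.DAMRecord("f", "A vs B", 0.0, 1.0, 1.0, 0.5, "ns")
        frame = dam.volcano_table([rec])
        assert frame["neg_log10_p"].iloc[0] == 0.0

    def test_empty_input(self):
        assert dam.volcano_table([]).empty


class TestIntegration:
    @staticmethod
    def _recs(name, features):
        return [dam.DAMRecord(f, name, 1.0, 0.01, 0.01, 2.0, "up") for f in features]

    def test_hand_enumerated_intersections(self):
        comps = {
            "c1": self._recs("c1", ["a", "b", "c"]),
            "c2": self._recs("c2", ["b", "c", "d"]),
        }
        upset, union = dam.integrate_comparisons(comps)
        assert upset == {"c1": 1, "c2": 1, "c1&c2": 2}
        assert len(union) == 4
        assert set(union[union["consistent"]]["feature_id"]) == {"b", "c"}

    def test_identical_sets_all_shared(self):
        comps = {"c1": self._recs("c1", ["x", "y"]), "c2": self._recs("c2", ["x", "y"])}
        upset, _ = dam.integrate_comparisons(comps)
        assert upset == {"c1&c2": 2}

    def test_classes_disjoint_and_exhaustive(self):
        comps = {
            "c1": self._recs("c1", ["a", "b"]),
            "c2": self._recs("c2", ["b", "c"]),
            "c3": self._recs("c3", ["c", "d", "a"]),
        }
        upset, union = dam.integrate_comparisons(comps)
        assert sum(upset.values()) == len(union)

    def test_single_comparison_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dam.integrate_comparisons({"only": self._recs("only", ["a"])})


class TestSuperclassComposition:
    def test_proportions(self):
        ann = synthetic.AnnotationMap(
            superclass={f"f{i}": ("Lipids" if i < 2 else "Acids") for i in range(10)},
            pathways={},
        )
        comp = dam.superclass_composition([f"f{i}" for i in range(10)], ann)
        assert dict(zip(comp["superclass"], comp["percent"]))["Lipids"] == pytest.approx(20.0)
        assert comp["percent"].sum() == pytest.approx(100.0)
        assert (comp["count"].diff().dropna() <= 0).all()  # sorted descending

    def test_unannotated_bucket_and_count_oracle(self):
        ann = synthetic.AnnotationMap(superclass={"a": "Lipids"}, pathways={})
        comp = dam.superclass_composition(["a", "b", "c"], ann)
        as_dict = dict(zip(comp["superclass"], comp["count"]))
        assert as_dict == {"unclassified": 2, "Lipids": 1}
        recomputed = comp["count"] / comp["count"].sum() * 100
        assert np.allclose(comp["percent"], recomputed, atol=0.01)

    def test_empty(self):
        ann = synthetic.AnnotationMap(superclass={}, pathways={})
        assert dam.superclass_composition([], ann).empty
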