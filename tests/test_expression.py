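"""Probe collapsing, sample filtering, case/control aggregation, weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocktailnet import (
    aggregate_case_control,
    collapse_probes,
    compute_ratios,
    compute_weights,
    drug_profile,
    filter_samples,
)
from cocktailnet.expression import ExpressionProfile, abs_log2


class TestCollapseProbes:
    def test_mean_over_probes(self):
        mat = pd.DataFrame({"s1": [2.0, 4.0]}, index=["p1", "p2"])
        out = collapse_probes(mat, {"p1": "X", "p2": "X"})
        assert out.loc["X", "s1"] == 3.0

    def test_composite_symbol_two_step_rule(self):
        # per-string means first, then gene = mean over strings containing it
        mat = pd.DataFrame({"s1": [2.0, 6.0]}, index=["p1", "p2"])
        out = collapse_probes(mat, {"p1": "X", "p2": "X /// Y"})
        assert out.loc["X", "s1"] == 4.0
        assert out.loc["Y", "s1"] == 6.0

    def test_single_probe_identity(self):
        mat = pd.DataFrame({"s1": [5.0], "s2": [7.0]}, index=["p1"])
        out = collapse_probes(mat, {"p1": "X"})
        assert out.loc["X"].tolist() == [5.0, 7.0]

    def test_zero_samples_is_error(self):
        with pytest.raises(ValueError):
            collapse_probes(pd.DataFrame(index=["p1"]), {"p1": "X"})

    def test_unmapped_probes_dropped(self):
        mat = pd.DataFrame({"s1": [1.0, 9.0]}, index=["p1", "p_unknown"])
        out = collapse_probes(mat, {"p1": "X"})
        assert list(out.index) == ["X"]

    @pytest.mark.parametrize("seed", range(5))
    def test_values_within_probe_range(self, seed):
        rng = np.random.default_rng(seed)
        probes = [f"p{i}" for i in range(12)]
        mapping = {p: rng.choice(["A", "B", "A /// B", "C"]) for p in probes}
        mat = pd.DataFrame(rng.uniform(1, 100, (12, 3)), index=probes,
                           columns=["s1", "s2", "s3"])
        out = collapse_probes(mat, mapping)
        assert (out.values >= mat.values.min() - 1e-12).all()
        assert (out.values <= mat.values.max() + 1e-12).all()


class TestFilterSamples:
    def _meta(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "batch_id", "cell_line",
                                           "perturbagen", "dose", "control_ids"])

    def test_single_drug_batch_removed(self):
        meta = self._meta([
            ("c1", "1", "MCF7", "CONTROL", 0.0, []),
            ("x1", "1", "MCF7", "D1", 1.0, ["c1"]),
        ])
        assert filter_samples(meta).empty

    def test_merge_happens_before_single_drug_test(self):
        # batch "2" alone has one drug, "2a" another; merged they survive
        meta = self._meta([
            ("c1", "2", "MCF7", "CONTROL", 0.0, []),
            ("x1", "2", "MCF7", "D1", 1.0, ["c1"]),
            ("c2", "2a", "MCF7", "CONTROL", 0.0, []),
            ("x2", "2a", "MCF7", "D3", 1.0, ["c2"]),
        ])
        out = filter_samples(meta)
        assert set(out["batch_id"]) == {"2"}
        assert set(out["perturbagen"]) == {"CONTROL", "D1", "D3"}

    def test_cell_line_restriction(self):
        meta = self._meta([
            ("c1", "1", "MCF7", "CONTROL", 0.0, []),
            ("x1", "1", "MCF7", "D1", 1.0, ["c1"]),
            ("x2", "1", "HL60", "D2", 1.0, ["c1"]),
        ])
        out = filter_samples(meta, cell_line="MCF7")
        assert set(out["sample_id"]) == {"c1", "x1"}

    def test_bad_control_reference_rejected(self):
        meta = self._meta([("x1", "1", "MCF7", "D1", 1.0, ["ghost"])])
        with pytest.raises(ValueError, match="unknown controls"):
            filter_samples(meta)


class TestAggregateCaseControl:
    def test_means_within_batch(self, tiny_meta):
        gm = pd.DataFrame({"c1": [1.0, 3.0], "c2": [3.0, 5.0],
                           "case1": [2.0, 4.0], "case2": [9.0, 9.0]},
                          index=["g1", "g2"])
        T, C = aggregate_case_control(gm, tiny_meta, "DRUGX", 10.0)
        assert T.tolist() == [2.0, 4.0]
        assert C.tolist() == [2.0, 4.0]

    def test_batches_averaged(self):
        meta = pd.DataFrame({
            "sample_id": ["c1", "x1", "y1", "c2", "x2", "y2"],
            "batch_id": ["1", "1", "1", "3", "3", "3"],
            "cell_line": ["MCF7"] * 6,
            "perturbagen": ["CONTROL", "D", "E", "CONTROL", "D", "E"],
            "dose": [0.0, 1.0, 1.0, 0.0, 1.0, 1.0],
            "control_ids": [[], ["c1"], ["c1"], [], ["c2"], ["c2"]],
        })
        gm = pd.DataFrame({"c1": [1.0], "x1": [2.0], "y1": [0.0],
                           "c2": [1.0], "x2": [4.0], "y2": [0.0]}, index=["g"])
        T, _ = aggregate_case_control(gm, meta, "D", 1.0)
        assert T.tolist() == [3.0]

    def test_replicate_cases_averaged(self):
        meta = pd.DataFrame({
            "sample_id": ["c1", "x1", "x2", "y1"],
            "batch_id": ["1"] * 4, "cell_line": ["MCF7"] * 4,
            "perturbagen": ["CONTROL", "D", "D", "E"],
            "dose": [0.0, 1.0, 1.0, 1.0],
            "control_ids": [[], ["c1"], ["c1"], ["c1"]],
        })
        gm = pd.DataFrame({"c1": [1.0, 1.0], "x1": [1.0, 1.0],
                           "x2": [3.0, 3.0], "y1": [9.0, 9.0]}, index=["g1", "g2"])
        T, _ = aggregate_case_control(gm, meta, "D", 1.0)
        assert T.tolist() == [2.0, 2.0]

    def test_missing_case_is_error(self, tiny_meta):
        gm = pd.DataFrame({"c1": [1.0], "c2": [1.0], "case1": [1.0], "case2": [1.0]},
                          index=["g"])
        with pytest.raises(ValueError, match="NOSUCH"):
            aggregate_case_control(gm, tiny_meta, "NOSUCH", 10.0)

    def test_case_without_controls_is_error(self):
        meta = pd.DataFrame({
            "sample_id": ["x1", "y1", "c0"], "batch_id": ["1"] * 3,
            "cell_line": ["MCF7"] * 3, "perturbagen": ["D", "E", "CONTROL"],
            "dose": [1.0, 1.0, 0.0], "control_ids": [[], ["c0"], []],
        })
        gm = pd.DataFrame({"x1": [1.0], "y1": [1.0], "c0": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="x1"):
            aggregate_case_control(gm, meta, "D", 1.0)

    def test_invariant_to_order_and_duplicate_control(self, tiny_meta):
        gm = pd.DataFrame({"c1": [1.0], "c2": [3.0], "case1": [2.0], "case2": [5.0]},
                          index=["g"])
        T0, C0 = aggregate_case_control(gm, tiny_meta, "DRUGX", 10.0)
        shuffled = tiny_meta.sample(frac=1, random_state=1).reset_index(drop=True)
        T1, C1 = aggregate_case_control(gm, shuffled, "DRUGX", 10.0)
        dup = tiny_meta.copy()
        dup["control_ids"] = dup["control_ids"].map(lambda v: v + v if v else v)
        T2, C2 = aggregate_case_control(gm, dup, "DRUGX", 10.0)
        for T, C in [(T1, C1), (T2, C2)]:
            assert T.tolist() == T0.tolist() and C.tolist() == C0.tolist()


class TestRatiosAndWeights:
    def test_ratio_examples(self):
        T = pd.Series({"a": 4.0, "b": 2.0, "c": 1.0})
        C = pd.Series({"a": 2.0, "b": 2.0, "c": 0.0})
        r = compute_ratios(T, C)
        assert r["a"] == 2.0 and r["b"] == 1.0
        assert "c" not in r.index  # control at the floor is dropped

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError):
            compute_ratios(pd.Series({"a": 1.0}), pd.Series({"a": 0.0}))

    @pytest.mark.parametrize("ratio,expected", [(2.0, 1.0), (0.5, 1.0), (1.0, 0.0)])
    def test_weight_examples(self, ratio, expected):
        w = compute_weights(pd.Series({"g": ratio}))
        assert w["g"] == pytest.approx(expected)

    def test_nonpositive_ratio_is_error(self):
        with pytest.raises(ValueError):
            compute_weights(pd.Series({"g": -1.0}))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_weight_symmetric_and_monotone(self, r):
        w = abs_log2(pd.Series([r, 1.0 / r, 2 * r]))
        assert w.iloc[0] == pytest.approx(w.iloc[1], rel=1e-9, abs=1e-12)
        if r >= 1.0:
            assert w.iloc[2] >= w.iloc[0]

    def test_profile_weight_zero_iff_ratio_one(self):
        p = ExpressionProfile("d", pd.Series({"a": 1.0, "b": 2.0}))
        assert p.weights["a"] == 0.0 and p.weights["b"] > 0.0


class TestDrugProfile:
    def test_mean_over_doses(self):
        meta = pd.DataFrame({
            "sample_id": ["c1", "x1", "x2", "y1"],
            "batch_id": ["1"] * 4, "cell_line": ["MCF7"] * 4,
            "perturbagen": ["CONTROL", "D", "D", "E"],
            "dose": [0.0, 1.0, 2.0, 1.0],
            "control_ids": [[], ["c1"], ["c1"], ["c1"]],
        })
        gm = pd.DataFrame({"c1": [2.0], "x1": [4.0], "x2": [8.0], "y1": [2.0]},
                          index=["g"])
        prof = drug_profile(gm, meta, "D")            # mean of ratios 2 and 4
        assert prof.ratios["g"] == pytest.approx(3.0)
        prof1 = drug_profile(gm, meta, "D", dose=1.0)  # single dose
        assert prof1.ratios["g"] == pytest.approx(2.0)
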