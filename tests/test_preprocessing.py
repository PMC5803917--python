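import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import skinora as sk
from skinora.preprocessing import filter_by_detection, median_normalize


def make_matrix(values, calls=None, probes=None, samples=None):
    probes = probes or [f"pr{i}" for i in range(len(values))]
    samples = samples or [f"s{j}" for j in range(len(values[0]))]
    vdf = pd.DataFrame(values, index=probes, columns=samples, dtype=float)
    cdf = None
    if calls is not None:
        cdf = pd.DataFrame(calls, index=probes, columns=samples)
    return sk.ExpressionMatrix(values=vdf, calls=cdf)


class TestMedianNormalize:
    def test_divides_by_sample_median(self):
        m = make_matrix([[2.0], [4.0], [8.0]])
        out = median_normalize(m)
        assert list(out.values.iloc[:, 0]) == [0.5, 1.0, 2.0]

    def test_identity_when_median_already_one(self):
        m = make_matrix([[0.5], [1.0], [2.0]])
        out = median_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_columns_scaled_independently_and_medians_become_one(self):
        # medians 4 and 10, recomputed here by direct sort
        m = make_matrix([[2.0, 5.0], [4.0, 10.0], [8.0, 20.0]])
        for col in m.values.columns:
            ordered = sorted(m.values[col])
            assert ordered[len(ordered) // 2] == {"s0": 4.0, "s1": 10.0}[col]
        out = median_normalize(m)
        assert out.values.median(axis=0).tolist() == [1.0, 1.0]

    def test_all_zero_sample_error_names_sample(self):
        m = make_matrix([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]])
        with pytest.raises(sk.DataError, match="s0"):
            median_normalize(m)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1e4), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_idempotent(self, rows):
        m = make_matrix(rows, samples=["a", "b", "c"])
        once = median_normalize(m)
        twice = median_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-12
        )


class TestDetectionFilter:
    def design(self, n=10):
        rows = []
        for i in range(n):
            for cond, tag in (("baseline", "t0"), ("treated", "t1")):
                rows.append({"sample": f"BM_p{i:02d}_{tag}", "patient": f"p{i:02d}",
                             "arm": "BM", "condition": cond})
        return sk.StudyDesign(pd.DataFrame(rows).set_index("sample"))

    def matrix_with_pm_counts(self, n_base, n_treat, n=10):
        design = self.design(n)
        samples = design.sample_ids
        values = [[1.0] * len(samples)]
        base = ["P"] * n_base + ["A"] * (n - n_base)
        treat = ["P"] * n_treat + ["A"] * (n - n_treat)
        calls_row = []
        for s in samples:
            i = int(s.split("_p")[1][:2])
            calls_row.append(base[i] if s.endswith("t0") else treat[i])
        return make_matrix(values, [calls_row], samples=samples), design

    def test_seven_of_ten_in_both_groups_is_kept(self):
        m, design = self.matrix_with_pm_counts(7, 7)
        assert len(filter_by_detection(m, design, 0.70).probe_ids) == 1

    def test_six_of_ten_in_one_group_is_dropped(self):
        m, design = self.matrix_with_pm_counts(7, 6)
        assert len(filter_by_detection(m, design, 0.70).probe_ids) == 0

    def test_any_group_mode_keeps_probe_passing_one_group(self):
        m, design = self.matrix_with_pm_counts(7, 6)
        assert len(filter_by_detection(m, design, 0.70, require="any").probe_ids) == 1

    def test_all_absent_probe_dropped_regardless_of_intensity(self):
        design = self.design(2)
        samples = design.sample_ids
        m = make_matrix([[9e9] * 4], [["A"] * 4], samples=samples)
        assert len(filter_by_detection(m, design, 0.70).probe_ids) == 0

    def test_marginal_counts_like_present(self):
        m, design = self.matrix_with_pm_counts(0, 0)
        m.calls.iloc[0, :] = "M"
        assert len(filter_by_detection(m, design, 0.70).probe_ids) == 1

    @pytest.mark.parametrize("threshold", [0.0, -0.3, 1.2])
    def test_threshold_outside_unit_interval_rejected(self, threshold):
        m, design = self.matrix_with_pm_counts(7, 7)
        with pytest.raises(sk.ConfigError):
            filter_by_detection(m, design, threshold)

    def test_kept_probes_shrink_as_threshold_grows(self):
        rng = np.random.default_rng(0)
        design = self.design(10)
        samples = design.sample_ids
        calls = rng.choice(["P", "M", "A"], size=(60, len(samples)), p=[0.6, 0.1, 0.3])
        m = make_matrix(np.ones((60, len(samples))), calls, samples=samples)
        kept_sets = [
            set(filter_by_detection(m, design, t).probe_ids)
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        for tighter, looser in zip(kept_sets[1:], kept_sets):
            assert tighter <= looser


class TestCollapseProbes:
    def test_median_of_probe_values(self):
        m = make_matrix([[3.0], [5.0], [7.0]], probes=["a", "b", "c"])
        mapping = pd.DataFrame({"probe": ["a", "b", "c"], "gene": ["G1"] * 3})
        out = sk.collapse_probes(m, mapping)
        assert out.values.loc["G1", "s0"] == 5.0

    def test_even_probe_count_uses_mean_of_central_pair(self):
        m = make_matrix([[3.0], [5.0]], probes=["a", "b"])
        mapping = pd.DataFrame({"probe": ["a", "b"], "gene": ["G1", "G1"]})
        assert sk.collapse_probes(m, mapping).values.loc["G1", "s0"] == 4.0

    def test_unmapped_probe_dropped_and_logged(self, caplog):
        m = make_matrix([[3.0], [5.0]], probes=["a", "zz"])
        mapping = pd.DataFrame({"probe": ["a"], "gene": ["G1"]})
        with caplog.at_level("INFO", logger="skinora.preprocessing"):
            out = sk.collapse_probes(m, mapping)
        assert list(out.values.index) == ["G1"]
        assert any("unmapped" in r.message for r in caplog.records)

    def test_probe_mapping_to_two_genes_rejected(self):
        m = make_matrix([[3.0]], probes=["a"])
        mapping = pd.DataFrame({"probe": ["a", "a"], "gene": ["G1", "G2"]})
        with pytest.raises(sk.DataError, match="multiple genes"):
            sk.collapse_probes(m, mapping)

    def test_one_to_one_mapping_is_pure_relabeling(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.uniform(1, 9, (5, 3)), probes=[f"pr{i}" for i in range(5)])
        mapping = pd.DataFrame(
            {"probe": m.probe_ids, "gene": [f"GENE{i}" for i in range(5)]}
        )
        out = sk.collapse_probes(m, mapping)
        relabeled = m.values.rename(
            index=dict(zip(m.probe_ids, mapping["gene"]))
        ).sort_index()
        pd.testing.assert_frame_equal(out.values, relabeled, check_names=False)


class TestStudyDesign:
    def test_treated_sample_without_baseline_rejected(self):
        rows = pd.DataFrame(
            {"patient": ["p1"], "arm": ["BM"], "condition": ["treated"]},
            index=["BM_p1_t1"],
        )
        with pytest.raises(sk.DesignError, match="BM_p1_t1"):
            sk.StudyDesign(rows)

    def test_groups_are_arm_condition_pairs(self, tiny_design):
        groups = tiny_design.groups(arm="BM")
        assert set(groups) == {("BM", "baseline"), ("BM", "treated")}
        assert all(len(v) == 2 for v in groups.values())
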