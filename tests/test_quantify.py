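"""Normalization, fold changes, response ranking, clustering, CV gate."""
import numpy as np
import pandas as pd
import pytest

from bcstarprom.errors import ConfigError, QCError
from bcstarprom.quantify import (
    control_samples,
    cv_filter,
    drug_response_score,
    fold_changes,
    median_normalize,
    merge_replicates_and_cluster,
    promoter_profiles,
)
from bcstarprom.read_processing import SampleSheet


def sheet_for(samples):
    rows = []
    for sid, treat, t in samples:
        rows.append({"sample_id": sid, "index": None, "treatment": treat, "time": t})
    frame = pd.DataFrame(rows)
    # bypass index validation: these sheets never touch demultiplexing
    obj = SampleSheet.__new__(SampleSheet)
    obj.frame = frame.assign(replicate=1)
    obj.min_index_dist = 3
    return obj


def screen_sheet():
    samples = [(f"drug_t{t}", "drug", t) for t in (0, 1, 2, 4, 8)]
    samples += [(f"DMSO_t{t}", "DMSO", t) for t in (0, 1, 2, 4, 8)]
    return sheet_for(samples)


class TestMedianNormalize:
    def test_hand_computed_example(self):
        t = pd.DataFrame({"A": [1, 2, 3], "B": [2, 4, 6]}, dtype=float)
        norm = median_normalize(t)
        # column medians 2 and 4; median of all entries 2.5
        expect = pd.DataFrame({"A": [1.25, 2.5, 3.75], "B": [1.25, 2.5, 3.75]})
        pd.testing.assert_frame_equal(norm, expect)

    def test_fixed_point(self):
        t = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(median_normalize(t), t)

    def test_zero_median_column_named(self):
        t = pd.DataFrame({"A": [1, 2, 3], "B": [0, 0, 5]})
        with pytest.raises(QCError, match="B"):
            median_normalize(t)

    def test_column_medians_equalized(self, rng):
        t = pd.DataFrame(rng.integers(1, 500, size=(101, 4)), columns=list("ABCD"))
        norm = median_normalize(t)
        med = norm.median(axis=0)
        assert np.allclose(med, med.iloc[0])


class TestFoldChanges:
    def test_constant_barcode_gives_unit_fc(self):
        sheet = screen_sheet()
        t = pd.DataFrame(
            {s: [100.0, 50.0] for s in sheet.sample_ids},
            index=["b1", "b2"],
        )
        fc = fold_changes(median_normalize(t), sheet)
        assert np.allclose(fc.to_numpy(), 1.0)

    def test_control_mean_is_one_by_construction(self, rng):
        sheet = screen_sheet()
        t = pd.DataFrame(
            rng.integers(10, 1000, size=(50, 10)).astype(float),
            columns=sheet.sample_ids,
        )
        fc = fold_changes(median_normalize(t), sheet)
        controls = fc.attrs["controls"]
        assert set(controls) == set(control_samples(sheet))
        assert np.allclose(fc[controls].mean(axis=1), 1.0)

    def test_no_controls_is_design_error(self):
        sheet = sheet_for([("drug_t1", "drug", 1)])
        t = pd.DataFrame({"drug_t1": [5.0]})
        with pytest.raises(ConfigError):
            fold_changes(median_normalize(t), sheet)

    def test_depth_invariance_bitwise(self, rng):
        # scaling any sample column leaves fold changes bit-identical
        sheet = screen_sheet()
        counts = pd.DataFrame(
            rng.integers(1, 2000, size=(200, 10)),
            columns=sheet.sample_ids,
        )
        scaled = counts.copy()
        scaled["drug_t2"] = scaled["drug_t2"] * 10
        fc1 = fold_changes(median_normalize(counts), sheet)
        fc2 = fold_changes(median_normalize(scaled), sheet)
        assert fc1.equals(fc2)


class TestDrugResponseScore:
    def test_hand_arithmetic(self):
        sheet = screen_sheet()
        fc = pd.DataFrame(
            {
                "drug_t0": [1.0, 1.0], "drug_t1": [4.0, 1.0], "drug_t2": [8.0, 1.0],
                "drug_t4": [8.0, 1.0], "drug_t8": [4.0, 1.0],
                "DMSO_t0": [1.0, 1.0], "DMSO_t1": [1.0, 1.0], "DMSO_t2": [1.0, 1.0],
                "DMSO_t4": [1.0, 1.0], "DMSO_t8": [1.0, 1.0],
            },
            index=["induced", "flat"],
        )
        ranked = drug_response_score(fc, sheet, "drug")
        assert ranked.loc["induced", "score"] == pytest.approx(6.0)
        assert ranked.loc["flat", "score"] == pytest.approx(1.0)
        assert list(ranked.index) == ["induced", "flat"]
        assert list(ranked["rank"]) == [1, 2]

    def test_missing_time_point_listed(self):
        sheet = sheet_for(
            [("drug_t1", "drug", 1), ("DMSO_t1", "DMSO", 1), ("DMSO_t0", "DMSO", 0)]
        )
        fc = pd.DataFrame({"drug_t1": [2.0], "DMSO_t1": [1.0], "DMSO_t0": [1.0]})
        with pytest.raises(ConfigError, match=r"\[2, 4, 8\]"):
            drug_response_score(fc, sheet, "drug")

    def test_tie_break_lexicographic(self):
        sheet = sheet_for(
            [(f"drug_t{t}", "drug", t) for t in (1, 2, 4, 8)]
            + [(f"DMSO_t{t}", "DMSO", t) for t in (1, 2, 4, 8)]
        )
        fc = pd.DataFrame(
            {s: [2.0, 2.0, 3.0] for s in sheet.sample_ids if "drug" in s}
            | {s: [1.0, 1.0, 1.0] for s in sheet.sample_ids if "DMSO" in s},
            index=["zeta", "alpha", "top"],
        )
        ranked = drug_response_score(fc, sheet, "drug")
        assert list(ranked.index) == ["top", "alpha", "zeta"]


class TestClustering:
    def test_two_archetypes_separate(self, rng):
        # immediate-early vs delayed pulses: well-separated log2 profiles
        times = np.array([0, 1, 2, 4, 8], dtype=float)
        ie = np.log2(1 + 9 * (times / 1) * np.exp(1 - times / 1))
        delayed = np.log2(1 + 9 * (times / 4) * np.exp(1 - times / 4))
        rows, names = [], []
        for i in range(6):
            rows.append(ie + rng.normal(0, 0.05, 5))
            names.append(f"IE{i}")
        for i in range(6):
            rows.append(delayed + rng.normal(0, 0.05, 5))
            names.append(f"D{i}")
        profiles = pd.DataFrame(rows, index=names)
        ranking = pd.DataFrame({"score": np.ones(12)}, index=names)
        groups = merge_replicates_and_cluster([ranking], profiles, top_k=12, k_groups=2)
        ie_groups = {groups[n] for n in names if n.startswith("IE")}
        d_groups = {groups[n] for n in names if n.startswith("D")}
        assert len(ie_groups) == 1 and len(d_groups) == 1
        assert ie_groups != d_groups

    def test_identical_vectors_same_group(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 0.0], [0.0, 5.0]],
            index=["a", "b", "c", "d"],
        )
        ranking = pd.DataFrame({"score": [4, 3, 2, 1]}, index=["a", "b", "c", "d"])
        groups = merge_replicates_and_cluster([ranking], profiles, top_k=4, k_groups=3)
        assert groups["a"] == groups["b"]

    def test_merged_set_too_small(self):
        profiles = pd.DataFrame([[1.0], [2.0], [3.0]], index=list("abc"))
        ranking = pd.DataFrame({"score": [3, 2, 1]}, index=list("abc"))
        with pytest.raises(ConfigError):
            merge_replicates_and_cluster([ranking], profiles, top_k=3, k_groups=4)

    def test_replicate_union(self):
        profiles = pd.DataFrame(
            np.eye(4), index=["a", "b", "c", "d"]
        )
        r1 = pd.DataFrame({"score": [9, 1]}, index=["a", "c"])
        r2 = pd.DataFrame({"score": [9, 1]}, index=["b", "d"])
        groups = merge_replicates_and_cluster([r1, r2], profiles, top_k=1, k_groups=2)
        assert set(groups.index) == {"a", "b"}


class TestPromoterProfiles:
    def test_multi_barcode_promoters_averaged(self):
        fc = pd.DataFrame(
            {"s1": [2.0, 4.0, 8.0], "s2": [1.0, 1.0, 2.0]},
            index=["bc1", "bc2", "bc3"],
        )
        b2p = {"bc1": "P1", "bc2": "P1", "bc3": "P2"}
        prof = promoter_profiles(fc, b2p, log2=False)
        assert prof.loc["P1", "s1"] == pytest.approx(3.0)
        assert prof.loc["P2", "s2"] == pytest.approx(2.0)


class TestCVFilter:
    def test_hand_computed(self):
        kept, cv = cv_filter([100, 110, 105, 90])
        assert kept and cv == pytest.approx(0.0843, abs=0.0005)

    def test_identical_values(self):
        kept, cv = cv_filter([7.0, 7.0, 7.0])
        assert kept and cv == 0.0

    def test_rejection(self):
        kept, cv = cv_filter([100, 200])
        assert not kept and cv == pytest.approx(0.4714, abs=0.001)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            cv_filter([1.0])
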