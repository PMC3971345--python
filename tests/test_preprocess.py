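"""Probe-level preprocessing: normalization, detection, collapsing,
filtering, sample QC, and the comparative-CT transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emphymir.preprocess import (
    collapse_replicates,
    comparative_ct,
    correlate_with_array,
    detection_call,
    filter_features,
    preprocess_probe_table,
    qc_samples,
    quantile_normalize,
)


def probe_frame(rows, samples):
    """rows: (probe_id, feature_id, replicate, is_background, *values)."""
    head = pd.DataFrame(
        [r[:4] for r in rows],
        columns=["probe_id", "feature_id", "replicate", "is_background"],
    )
    body = pd.DataFrame([r[4:] for r in rows], columns=samples)
    return pd.concat([head, body], axis=1)


class TestQuantileNormalize:
    def test_single_sample_unchanged(self):
        m = pd.DataFrame({"s1": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_permuted_columns_become_identical(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 9.0, 2.0], "b": [2.0, 9.0, 1.0, 5.0]})
        out = quantile_normalize(m)
        assert sorted(out["a"]) == sorted(out["b"])
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_three_by_three_hand_computation(self):
        # sorted columns: (1,4,7), (2,5,8), (3,6,9) -> target (2,5,8)
        m = pd.DataFrame({"a": [4.0, 1.0, 7.0], "b": [2.0, 8.0, 5.0],
                          "c": [9.0, 6.0, 3.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [5.0, 2.0, 8.0])
        np.testing.assert_allclose(out["b"], [2.0, 8.0, 5.0])
        np.testing.assert_allclose(out["c"], [8.0, 5.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(size=(50, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame())


class TestDetectionCall:
    def test_zero_sd_background_threshold(self):
        rows = [
            ("p1", "f1", 1, False, 100.1),
            ("p2", "f1", 2, False, 99.9),
            ("b1", "", 0, True, 100.0),
            ("b2", "", 0, True, 100.0),
            ("b3", "", 0, True, 100.0),
            ("b4", "", 0, True, 100.0),
        ]
        calls, thr = detection_call(probe_frame(rows, ["s1"]))
        assert thr["s1"] == pytest.approx(100.0)
        assert bool(calls.loc["p1", "s1"]) is True
        assert bool(calls.loc["p2", "s1"]) is False

    def test_sample_sd_arithmetic(self):
        # background {90,100,110}: mean 100, sample SD 10 -> threshold 120
        rows = [
            ("p1", "f1", 1, False, 125.0),
            ("p2", "f1", 2, False, 115.0),
            ("b1", "", 0, True, 90.0),
            ("b2", "", 0, True, 100.0),
            ("b3", "", 0, True, 110.0),
        ]
        calls, thr = detection_call(probe_frame(rows, ["s1"]))
        assert thr["s1"] == pytest.approx(120.0)
        assert bool(calls.loc["p1", "s1"]) is True
        assert bool(calls.loc["p2", "s1"]) is False

    def test_too_few_background_probes(self):
        rows = [("p1", "f1", 1, False, 5.0), ("b1", "", 0, True, 1.0)]
        with pytest.raises(ValueError, match="background"):
            detection_call(probe_frame(rows, ["s1"]))

    @given(st.floats(min_value=0.1, max_value=1e6),
           st.floats(min_value=1.0, max_value=2.0))
    @settings(max_examples=30, deadline=None)
    def test_raising_intensity_never_loses_present(self, inten, factor):
        rows = [
            ("p1", "f1", 1, False, inten),
            ("b1", "", 0, True, 10.0),
            ("b2", "", 0, True, 12.0),
        ]
        calls1, _ = detection_call(probe_frame(rows, ["s1"]))
        rows[0] = ("p1", "f1", 1, False, inten * factor)
        calls2, _ = detection_call(probe_frame(rows, ["s1"]))
        if calls1.loc["p1", "s1"]:
            assert calls2.loc["p1", "s1"]


class TestCollapseReplicates:
    def make(self, values, present):
        rows = [
            (f"p{i}", "f1", i + 1, False, float(2**v)) for i, v in enumerate(values)
        ] + [("b1", "", 0, True, 1.0), ("b2", "", 0, True, 1.0)]
        table = probe_frame(rows, ["s1"])
        calls = pd.DataFrame(
            {"s1": present}, index=[f"p{i}" for i in range(len(values))]
        )
        return table, calls

    def test_median_of_present_two_of_three(self):
        table, calls = self.make([5.0, 6.0, 7.0], [True, True, False])
        values, present = collapse_replicates(table, calls)
        assert values.loc["f1", "s1"] == pytest.approx(5.5)
        assert bool(present.loc["f1", "s1"]) is True

    def test_median_of_three_present(self):
        table, calls = self.make([5.0, 6.0, 7.0], [True, True, True])
        values, present = collapse_replicates(table, calls)
        assert values.loc["f1", "s1"] == pytest.approx(6.0)

    def test_single_present_is_absent_with_imputed_value(self):
        table, calls = self.make([5.0, 6.0, 7.0], [True, False, False])
        values, present = collapse_replicates(table, calls)
        assert bool(present.loc["f1", "s1"]) is False
        assert values.loc["f1", "s1"] == pytest.approx(6.0)  # median of all

    def test_replicate_order_invariance(self):
        t1, c1 = self.make([5.0, 6.0, 7.0], [True, False, True])
        t2, c2 = self.make([7.0, 6.0, 5.0], [True, False, True])
        v1, p1 = collapse_replicates(t1, c1)
        v2, p2 = collapse_replicates(t2, c2)
        assert v1.loc["f1", "s1"] == pytest.approx(v2.loc["f1", "s1"])
        assert p1.equals(p2)


class TestFilterFeatures:
    def frame(self, n_present, n_samples=64):
        present = pd.DataFrame(
            [[True] * n_present + [False] * (n_samples - n_present)],
            index=["f1"],
        )
        values = pd.DataFrame(np.zeros((1, n_samples)), index=["f1"])
        return values, present

    def test_52_of_64_retained(self):
        v, p = self.frame(52)
        kept, _, dropped = filter_features(v, p)
        assert "f1" in kept.index and not dropped

    def test_51_of_64_dropped(self):
        v, p = self.frame(51)
        kept, _, dropped = filter_features(v, p)
        assert kept.empty and dropped == ["f1"]

    def test_constructed_pass_set(self):
        # 25 features, exactly 10 built to pass the 80% rule
        rng = np.random.default_rng(0)
        n_samples = 20
        present = np.zeros((25, n_samples), bool)
        present[:10, :16] = True   # 0.8 exactly -> retained
        present[10:, :10] = True   # 0.5 -> dropped
        v = pd.DataFrame(rng.normal(size=(25, n_samples)))
        kept, _, dropped = filter_features(
            v, pd.DataFrame(present, index=v.index)
        )
        assert len(kept) == 10 and len(dropped) == 15


class TestQcSamples:
    def test_clean_cohort_keeps_all(self, small_cohort):
        from emphymir.preprocess import preprocess_probe_table

        res = preprocess_probe_table(small_cohort.probe_table)
        assert res.qc["n_kept"] == res.qc["n_samples"]

    def test_shifted_sample_flagged_by_pca(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(8, 1, size=(100, 20)),
                           columns=[f"s{i}" for i in range(20)])
        mat["s0"] += 10.0
        present = pd.DataFrame(True, index=mat.index, columns=mat.columns)
        kept, report = qc_samples(mat, present)
        assert "s0" in report["excluded_pca"]
        assert "s0" not in kept

    def test_low_present_fraction_flagged(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(50, 10)),
                           columns=[f"s{i}" for i in range(10)])
        present = pd.DataFrame(True, index=mat.index, columns=mat.columns)
        present.loc[present.index[:30], "s3"] = False  # 40% present
        kept, report = qc_samples(mat, present)
        assert "s3" in report["excluded_present_frac"]

    def test_all_excluded_is_hard_error(self):
        mat = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        present = pd.DataFrame(False, index=mat.index, columns=mat.columns)
        with pytest.raises(ValueError):
            qc_samples(mat, present)


class TestComparativeCt:
    def table(self, target_cts):
        rows = []
        for s, ct in target_cts.items():
            rows += [("miR-X", s, ct)] * 3 + [("U6", s, 20.0)] * 3
        return pd.DataFrame(rows, columns=["feature_id", "sample_id", "ct"])

    def test_calibrator_gives_unity(self):
        rel = comparative_ct(self.table({"cal": 25.0, "s2": 25.0}),
                             calibrator_sample="cal")
        assert rel.loc["miR-X", "cal"] == pytest.approx(1.0)
        assert rel.loc["miR-X", "s2"] == pytest.approx(1.0)

    def test_one_cycle_doubles_expression(self):
        rel = comparative_ct(self.table({"cal": 25.0, "s2": 24.0}),
                             calibrator_sample="cal")
        assert rel.loc["miR-X", "s2"] == pytest.approx(2.0)

    def test_missing_reference_rejected(self):
        t = pd.DataFrame([("miR-X", "s1", 25.0)],
                         columns=["feature_id", "sample_id", "ct"])
        with pytest.raises(ValueError, match="U6"):
            comparative_ct(t)

    def test_proportional_series_correlates_perfectly(self):
        samples = [f"s{i}" for i in range(6)]
        cts = {s: 25.0 - i for i, s in enumerate(samples)}
        rel = comparative_ct(self.table(cts), calibrator_sample="s0")
        array = pd.Series(np.arange(6.0) + 7.0, index=samples)
        r, p = correlate_with_array(rel.loc["miR-X"], array)
        assert r == pytest.approx(1.0)
        assert p < 1e-6


class TestPipelineOrder:
    def test_failed_array_excluded_end_to_end(self, small_cohort):
        # a sample whose probes all sit at background level fails the
        # present-fraction rule after normalization and calls
        rng = np.random.default_rng(3)
        table = small_cohort.probe_table.copy()
        sample = small_cohort.mirna.columns[5]
        table[sample] = 2.0 ** rng.normal(3.0, 0.3, size=len(table))
        res = preprocess_probe_table(table)
        assert sample not in res.matrix.columns
        assert sample in res.qc["excluded_present_frac"]
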