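import numpy as np
import pandas as pd
import pytest

import spermsnc as s
from spermsnc.annotate import BatchAnnotation, ReadAnnotation
from spermsnc.errors import ValidationError
from spermsnc.quantify import CLASS_TO_FEATURE_CLASS


class TestAssignGroup:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (0.75, "H-GQE"),
            (0.25, "L-GQE"),
            (0.50, "excluded"),
            (1.0, "H-GQE"),
            (0.0, "L-GQE"),
            (0.7499, "excluded"),
            (0.2501, "excluded"),
        ],
    )
    def test_thresholds(self, rate, expected):
        assert s.assign_group(rate) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            s.assign_group(1.2)

    def test_total_on_grid(self):
        for rate in np.linspace(0, 1, 101):
            assert s.assign_group(float(rate)) in ("H-GQE", "L-GQE", "excluded")


def _mirna_refset():
    refs = s.ReferenceSet()
    refs.add(s.ReferenceRecord(id="miR-a", sequence="ACGTACGTACGTACGTACGTA",
                               class_label="miRNA"))
    refs.add(s.ReferenceRecord(id="miR-b", sequence="TTGCATTGCATTGCATTGCAT",
                               class_label="miRNA"))
    return refs


class TestAggregateCounts:
    def test_shared_feature_across_samples(self):
        refs = _mirna_refset()
        index = s.build_index(refs)
        seq = refs["miR-a"].sequence
        bas = {
            "s1": s.annotate_batch(s.ReadBatch("s1", [seq] * 3), index),
            "s2": s.annotate_batch(s.ReadBatch("s2", [seq] * 5), index),
        }
        cm = s.aggregate_counts(bas, refs)
        assert cm.counts.shape == (1, 2)
        assert list(cm.counts.loc["miR-a"]) == [3, 5]

    def test_feature_absent_in_one_sample_is_zero(self):
        refs = _mirna_refset()
        index = s.build_index(refs)
        bas = {
            "s1": s.annotate_batch(
                s.ReadBatch("s1", [refs["miR-a"].sequence]), index),
            "s2": s.annotate_batch(
                s.ReadBatch("s2", [refs["miR-b"].sequence]), index),
        }
        cm = s.aggregate_counts(bas, refs)
        assert cm.counts.loc["miR-a", "s2"] == 0
        assert cm.counts.loc["miR-b", "s1"] == 0

    def test_counts_match_simulator_truth(self, toy_refset, small_cohort):
        """For exact-match features the aggregated counts equal the
        simulator's per-feature true counts (joined on sequence)."""
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        bas = {sid: s.annotate_batch(b, index) for sid, b in data.batches.items()}
        cm = s.aggregate_counts(bas, toy_refset)
        seq_to_name = pd.Series(cm.feature_meta.index, index=cm.feature_meta["sequence"])
        truth_counts = data.true_counts
        matched = 0
        for fid in truth_counts.index:
            seq = data.catalog.loc[fid, "sequence"]
            if truth_counts.loc[fid].sum() == 0:
                continue
            name = seq_to_name[seq]
            assert (cm.counts.loc[name] == truth_counts.loc[fid]).all(), fid
            matched += 1
        assert matched > 50

    def test_column_sums_conserve_reads(self, toy_refset, small_cohort):
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        bas = {sid: s.annotate_batch(b, index) for sid, b in data.batches.items()}
        cm = s.aggregate_counts(bas, toy_refset)
        for sid, ba in bas.items():
            unann = ba.class_counts["unannotated"]
            total = cm.counts[sid].sum() + cm.full_length_excluded[sid] + unann
            assert total == ba.surviving


class TestRpm:
    def _matrix(self, counts, samples=("s1",)):
        arr = np.asarray(counts).reshape(len(counts), len(samples))
        cm = s.CountMatrix(
            counts=pd.DataFrame(arr, columns=list(samples),
                                index=[f"f{i}" for i in range(len(counts))]),
            feature_meta=pd.DataFrame(index=[f"f{i}" for i in range(len(counts))]),
        )
        return cm

    def test_single_feature_full_library(self):
        rpm = s.rpm_normalize(self._matrix([5]))
        assert rpm.iloc[0, 0] == 1_000_000

    def test_arithmetic(self):
        rpm = s.rpm_normalize(self._matrix([1, 1, 2]))
        assert list(rpm["s1"]) == [250_000, 250_000, 500_000]

    def test_column_sums_are_one_million(self, toy_refset, small_cohort):
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        bas = {sid: s.annotate_batch(b, index) for sid, b in data.batches.items()}
        cm = s.aggregate_counts(bas, toy_refset)
        rpm = s.rpm_normalize(cm)
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_zero_denominator_names_sample(self):
        cm = self._matrix([0])
        with pytest.raises(ValidationError, match="s1"):
            s.rpm_normalize(cm)


class TestExpressionFloor:
    def test_strict_inequality_at_threshold(self):
        rpm = pd.DataFrame({"s1": [10.0, 0.0], "s2": [10.0, 30.0]},
                           index=["at", "above"])
        kept = s.filter_by_mean_rpm(rpm, 10.0)
        assert list(kept) == ["above"]  # mean 10 excluded, mean 15 kept

    def test_zero_threshold_keeps_positive_matrix(self):
        rpm = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        assert len(s.filter_by_mean_rpm(rpm, 0.0)) == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        rpm = pd.DataFrame(rng.gamma(2, 20, size=(50, 4)))
        kept = [set(s.filter_by_mean_rpm(rpm, t)) for t in (0, 5, 20, 80)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a


class TestComposition:
    def test_all_mirna_sample_is_100_percent(self):
        refs = _mirna_refset()
        index = s.build_index(refs)
        ba = s.annotate_batch(s.ReadBatch("s", [refs["miR-a"].sequence] * 10), index)
        summ = s.composition_summary(ba, refs)
        assert summ["class_pct"]["miRNA"] == 100.0

    def test_class_percentages_match_design(self, toy_refset, small_cohort):
        design, data = small_cohort
        index = s.build_index(toy_refset)
        batch = next(iter(data.batches.values()))
        ba = s.annotate_batch(batch, index)
        summ = s.composition_summary(ba, toy_refset)
        n = ba.surviving
        for fclass, frac in design.composition_dict.items():
            got = summ["class_pct_total"][fclass] / 100
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(got - frac) <= 3 * se

    def test_five_prime_dominance(self, toy_refset, small_cohort):
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        shares = []
        for batch in data.batches.values():
            ba = s.annotate_batch(batch, index)
            shares.append(s.composition_summary(ba, toy_refset)["five_prime_tsrna_pct"])
        assert np.mean(shares) > 75.0

    def test_28s_dominance(self, toy_refset, small_cohort):
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        shares = []
        for batch in data.batches.values():
            ba = s.annotate_batch(batch, index)
            shares.append(
                s.composition_summary(ba, toy_refset)["rsrna_subtype_pct"]["28S"])
        assert np.mean(shares) > 55.0

    def test_zero_annotated_reported_missing(self, toy_refset):
        index = s.build_index(toy_refset)
        ba = s.annotate_batch(s.ReadBatch("s", ["A" * 30]), index)
        assert s.composition_summary(ba, toy_refset)["class_pct"] is None


class TestLengthDistribution:
    def test_histogram_counts(self):
        ba = BatchAnnotation(
            sample_id="s",
            annotations=[
                ReadAnnotation("A" * 30, "tRNA", "t", 0, 30, 1),
                ReadAnnotation("C" * 22, "tRNA", "t", 0, 22, 1),
            ],
            multiplicities=[2, 1],
            class_counts={"tRNA": 3},
            surviving=3,
        )
        assert s.length_distribution(ba, "tsRNA") == {30: 2, 22: 1}

    def test_empty_class(self):
        ba = BatchAnnotation("s", [], [], {"tRNA": 0}, 0)
        assert s.length_distribution(ba, "miRNA") == {}

    def test_mirna_modal_length_in_range(self, toy_refset, small_cohort):
        _design, data = small_cohort
        index = s.build_index(toy_refset)
        batch = next(iter(data.batches.values()))
        ba = s.annotate_batch(batch, index)
        hist = s.length_distribution(ba, "miRNA")
        mode = max(hist, key=hist.get)
        assert 20 <= mode <= 23
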