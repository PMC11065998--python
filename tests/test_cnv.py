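import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cfmm.cnv import (BinCounts, bisquare_weight, build_control_baseline,
                      call_cfdna_events, cnv_positive, count_fragments_per_bin,
                      log2_ratio, loess_gc_correct, recurrent_regions,
                      region_key, segment_gmm_hmm, segments_to_bin_states,
                      select_differential_cnv_regions, tricube_weight,
                      viterbi_decode)
from cfmm.genome import GenomeLayout, make_bins
from oracles import enumerate_best_path
from conftest import make_fragments


def _bins(n, size=1000, gc=None, chrom="chr1"):
    lay = GenomeLayout(((chrom, n * size),))
    bins = make_bins(lay, size)
    bins["gc"] = gc if gc is not None else 0.45
    return bins


class TestKernels:
    def test_tricube_and_bisquare_values(self):
        assert tricube_weight(0.5) == pytest.approx(0.669921875)
        assert bisquare_weight(0.5) == pytest.approx(0.5625)
        assert bisquare_weight(1.2) == 0.0
        assert tricube_weight(1.0) == 0.0
        assert tricube_weight(0.0) == 1.0


class TestCounting:
    def test_all_in_first_bin_rescaled(self):
        bins = _bins(5)
        frags = make_fragments("chr1", [10] * 10, [110] * 10)
        bc = count_fragments_per_bin(frags, bins, target_depth=100)
        assert bc.y.tolist() == [100, 0, 0, 0, 0]

    def test_midpoint_rule_for_straddling_fragment(self):
        bins = _bins(5)
        # fragment 950-1150: midpoint 1050 -> bin 2 (index 1)
        frags = make_fragments("chr1", [950], [1150])
        bc = count_fragments_per_bin(frags, bins, target_depth=1)
        assert bc.y[1] == 1 and bc.y[0] == 0

    def test_matches_brute_force_assignment(self, rng):
        bins = _bins(20)
        starts = rng.integers(0, 19_000, 500)
        frags = make_fragments("chr1", starts, starts + 150)
        bc = count_fragments_per_bin(frags, bins, target_depth=500)
        brute = np.zeros(20)
        for s in starts:
            mid = s + 75
            brute[mid // 1000] += 1
        assert np.allclose(bc.y, brute)

    def test_zero_fragments_error(self):
        with pytest.raises(ValueError):
            count_fragments_per_bin(make_fragments("chr1", [], []), _bins(5), 10)

    def test_depth_standardisation_preserved(self, rng):
        bins = _bins(50)
        starts = rng.integers(0, 49_000, 2000)
        bc = count_fragments_per_bin(make_fragments("chr1", starts, starts + 100),
                                     bins, target_depth=123_456)
        assert bc.y.sum() == pytest.approx(123_456, rel=1e-3)


class TestLoess:
    def test_flat_counts_are_untouched(self, rng):
        gc = rng.uniform(0.32, 0.58, 200)
        bins = _bins(200, gc=gc)
        y = np.full(200, 100.0) + rng.normal(0, 1, 200)
        model, corr = loess_gc_correct(BinCounts(bins, y))
        mad = np.median(np.abs(corr[model["mask"]] - y[model["mask"]]))
        assert mad / 100.0 < 0.01

    def test_removes_quadratic_bias(self, rng):
        gc = rng.uniform(0.3, 0.6, 500)
        bins = _bins(500, gc=gc)
        # quadratic in GC, centred at the low edge so the bias is monotone
        # (and hence visible to a rank correlation) over the admissible range
        y = 100.0 * (1 + 3 * (gc - 0.3) ** 2) + rng.normal(0, 2, 500)
        model, corr = loess_gc_correct(BinCounts(bins, y))
        m = model["mask"]
        assert abs(spearmanr(y[m], gc[m]).statistic) > 0.5
        assert abs(spearmanr(corr[m], gc[m]).statistic) < 0.1

    def test_masks_out_of_range_gc(self, rng):
        gc = np.concatenate([np.full(40, 0.25), rng.uniform(0.35, 0.55, 160)])
        bins = _bins(200, gc=gc)
        y = np.full(200, 50.0)
        model, corr = loess_gc_correct(BinCounts(bins, y))
        assert np.isnan(corr[:40]).all()
        assert np.isfinite(corr[40:]).all()

    def test_too_few_admissible_bins_error(self):
        bins = _bins(40, gc=np.full(40, 0.9))
        with pytest.raises(ValueError):
            loess_gc_correct(BinCounts(bins, np.ones(40)))

    def test_preserves_copy_number_structure(self, rng):
        gc = rng.uniform(0.3, 0.6, 400)
        bins = _bins(400, gc=gc)
        base = 100.0 * (1 + 1.5 * (gc - 0.45) ** 2)
        ratio = np.ones(400)
        ratio[100:150] = 2.0
        y = base * ratio + rng.normal(0, 1, 400)
        model, corr = loess_gc_correct(BinCounts(bins, y))
        m = model["mask"]
        inside = np.zeros(400, bool)
        inside[100:150] = True
        seg_ratio = (np.median(corr[m & inside]) / np.median(corr[m & ~inside]))
        assert seg_ratio == pytest.approx(2.0, rel=0.05)


class TestLog2Ratio:
    def test_canonical_values(self):
        out = log2_ratio(np.array([200.0, 137.0, 50.0]),
                         np.array([100.0, 137.0, 100.0]))
        assert out.tolist() == pytest.approx([1.0, 0.0, -1.0])

    def test_missing_where_zero_or_nan(self):
        out = log2_ratio(np.array([0.0, np.nan, 10.0]),
                         np.array([5.0, 5.0, 0.0]))
        assert np.isnan(out).all()

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            log2_ratio(np.ones(3), np.ones(4))


class TestSegmentation:
    def test_decode_matches_enumeration_small(self, rng):
        means = np.array([-0.5, 0.0, 0.5])
        var = np.array([0.02, 0.02, 0.02])
        for _ in range(20):
            n = int(rng.integers(2, 8))
            x = rng.normal(0, 0.5, n)
            got = viterbi_decode(x, means, var, 0.97)
            want = enumerate_best_path(x, means, var, 0.97)
            assert np.array_equal(got, want)

    def test_all_neutral_track(self, rng):
        bins = _bins(100)
        vals = rng.normal(0, 0.05, 100)
        segs = segment_gmm_hmm(vals, bins)
        assert len(segs) == 1
        assert segs["state"].iloc[0] == "NEUT"

    def test_recovers_amplified_block(self, rng):
        bins = _bins(100)
        vals = rng.normal(0, 0.05, 100)
        vals[40:60] += 1.0
        segs = segment_gmm_hmm(vals, bins)
        amp = segs[segs["state"] == "AMP"]
        assert len(amp) == 1
        assert abs(int(amp["first_bin"].iloc[0]) - 40) <= 1
        assert abs(int(amp["last_bin"].iloc[0]) - 59) <= 1

    def test_chromosomes_decoded_separately(self, rng):
        lay = GenomeLayout((("chr1", 50_000), ("chr2", 50_000)))
        bins = make_bins(lay, 1000)
        bins["gc"] = 0.45
        vals = rng.normal(0, 0.05, 100)
        segs = segment_gmm_hmm(vals, bins)
        assert set(segs["chrom"]) == {"chr1", "chr2"}

    def test_minimum_bins_required(self):
        bins = _bins(10)
        with pytest.raises(ValueError):
            segment_gmm_hmm(np.zeros(10), bins)


class TestRecurrence:
    @staticmethod
    def _segs_from_states(states, bins):
        segs = []
        vals = np.where(np.array(states) == 2, 1.0, np.where(np.array(states) == 0, -1.0, 0.0))
        i = 0
        rows = []
        arr = np.array(states)
        while i < len(arr):
            j = i
            while j + 1 < len(arr) and arr[j + 1] == arr[i]:
                j += 1
            rows.append((str(bins["chrom"].iloc[i]), int(bins["start"].iloc[i]),
                         int(bins["end"].iloc[j]), ("DEL", "NEUT", "AMP")[arr[i]],
                         float(vals[i]), j - i + 1, i, j))
            i = j + 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                           "mean_log2", "n_bins", "first_bin",
                                           "last_bin"])

    def test_min_recurrence_threshold(self):
        bins = _bins(10)
        amp = [2] * 3 + [1] * 7
        neut = [1] * 10
        samples = [self._segs_from_states(amp, bins)] * 3 + \
                  [self._segs_from_states(neut, bins)] * 2
        out = recurrent_regions(samples, bins, min_recurrence=3)
        assert len(out) == 1
        assert out["state"].iloc[0] == "AMP"
        out1 = recurrent_regions(samples, bins, min_recurrence=1)
        assert len(out1) == 1  # same single region at threshold 1

    def test_matches_brute_force_counts(self, rng):
        bins = _bins(30)
        state_mat = rng.integers(0, 3, size=(6, 30))
        samples = [self._segs_from_states(row, bins) for row in state_mat]
        out = recurrent_regions(samples, bins, min_recurrence=2)
        kept = set()
        for seg in out.itertuples():
            for b in range(seg.first_bin, seg.last_bin + 1):
                kept.add((b, seg.state))
        brute = set()
        for b in range(30):
            if (state_mat[:, b] == 2).sum() >= 2:
                brute.add((b, "AMP"))
            if (state_mat[:, b] == 0).sum() >= 2:
                brute.add((b, "DEL"))
        assert kept == brute

    def test_roundtrip_bin_states(self):
        bins = _bins(10)
        segs = self._segs_from_states([1, 1, 2, 2, 1, 0, 0, 1, 1, 1], bins)
        states = segments_to_bin_states(segs, 10)
        assert states.tolist() == [1, 1, 2, 2, 1, 0, 0, 1, 1, 1]


class TestCfdnaEvents:
    def test_sample_equal_to_baseline_has_no_events(self, rng):
        gc = rng.uniform(0.32, 0.58, 120)
        bins = _bins(120, gc=gc)
        y = rng.poisson(500, 120).astype(float)
        controls = [BinCounts(bins, rng.poisson(500, 120).astype(float))
                    for _ in range(10)]
        baseline = build_control_baseline(controls)
        regions = pd.DataFrame({"chrom": "chr1", "start": [10_000], "end": [20_000],
                                "state": ["AMP"], "support": [5],
                                "first_bin": [10], "last_bin": [19]})
        calls = call_cfdna_events(BinCounts(bins, y), baseline, regions)
        assert (calls["event"] == "none").all()
        assert calls["testable"].all()

    def test_strong_amplification_is_called(self, rng):
        gc = rng.uniform(0.32, 0.58, 120)
        bins = _bins(120, gc=gc)
        controls = [BinCounts(bins, rng.poisson(2000, 120).astype(float))
                    for _ in range(10)]
        baseline = build_control_baseline(controls)
        y = rng.poisson(2000, 120).astype(float)
        y[10:20] *= 1.4  # log2 ~ 0.49 against baseline
        regions = pd.DataFrame({"chrom": "chr1", "start": [10_000], "end": [20_000],
                                "state": ["AMP"], "support": [5],
                                "first_bin": [10], "last_bin": [19]})
        calls = call_cfdna_events(BinCounts(bins, y), baseline, regions)
        assert calls["event"].iloc[0] == "AMP"

    def test_direction_mismatch_not_called(self, rng):
        gc = rng.uniform(0.32, 0.58, 120)
        bins = _bins(120, gc=gc)
        controls = [BinCounts(bins, rng.poisson(2000, 120).astype(float))
                    for _ in range(10)]
        baseline = build_control_baseline(controls)
        y = rng.poisson(2000, 120).astype(float)
        y[10:20] *= 1.4  # amplification in a region expected to delete
        regions = pd.DataFrame({"chrom": "chr1", "start": [10_000], "end": [20_000],
                                "state": ["DEL"], "support": [5],
                                "first_bin": [10], "last_bin": [19]})
        calls = call_cfdna_events(BinCounts(bins, y), baseline, regions)
        assert calls["event"].iloc[0] == "none"


class TestDifferentialRegions:
    def test_case_enriched_region_retained(self):
        events = pd.DataFrame({"r1": [1] * 20 + [0] * 80 + [0] * 100,
                               "r2": [0] * 100 + [0] * 100})
        labels = np.array([1] * 100 + [0] * 100)
        out = select_differential_cnv_regions(events, labels)
        assert list(out["region"]) == ["r1"]

    def test_identical_rates_not_retained(self):
        events = pd.DataFrame({"r1": [1, 0] * 50})
        labels = np.array([1] * 50 + [0] * 50)
        out = select_differential_cnv_regions(events, labels)
        assert len(out) == 0

    def test_permuted_labels_rate(self, rng):
        events = pd.DataFrame(rng.binomial(1, 0.1, size=(100, 40)),
                              columns=[f"r{i}" for i in range(40)])
        labels = rng.permutation([1] * 50 + [0] * 50)
        out = select_differential_cnv_regions(events, labels, alpha=0.05)
        assert len(out) <= 6  # ~ alpha * n_regions with direction factor


class TestCnvPositive:
    def test_event_in_selected_region(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "state": ["AMP"], "event": ["AMP"],
                              "testable": [True]})
        selected = pd.DataFrame({"region": region_key(calls)})
        assert cnv_positive(calls, selected)

    def test_event_outside_selected_regions(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "state": ["AMP"], "event": ["AMP"],
                              "testable": [True]})
        selected = pd.DataFrame({"region": ["chr2:0-10:AMP"]})
        assert not cnv_positive(calls, selected)

    def test_empty_selection_always_negative(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "state": ["AMP"], "event": ["AMP"],
                              "testable": [True]})
        assert not cnv_positive(calls, pd.DataFrame({"region": []}))
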