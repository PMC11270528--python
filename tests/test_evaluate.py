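import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jressr.core_io import Axis, Spectrum2D
from jressr.degrade import degrade
from jressr.evaluate import (
    Peak,
    PeakPair,
    categorize,
    form_pairs,
    match_position,
    pick_peaks,
    records_to_frame,
    reliability,
    resolvability,
    score_pairs,
    summarize,
    valley_height,
)


def make_spectrum(grid):
    grid = np.asarray(grid, dtype=np.float64)
    return Spectrum2D(
        grid,
        Axis(grid.shape[0], -1.0, 1.0, "Hz"),
        Axis(grid.shape[1], 0.0, 1.0, "ppm"),
    )


def peaks_at(positions, heights=None, shape=(64, 64), width=0.0):
    """Grid with isolated single-pixel (or small Gaussian) peaks."""
    g = np.zeros(shape)
    for k, (r, c) in enumerate(positions):
        h = 1.0 if heights is None else heights[k]
        if width > 0:
            rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
            g += h * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * width**2))
        else:
            g[r, c] = max(g[r, c], h)
    return make_spectrum(g)


class TestPickPeaks:
    def test_rendered_singlet_gives_one_centred_peak(self, demo_axes):
        from jressr.simulate import Metabolite, Multiplet, render_metabolite, scaled_linewidths

        lw1, lw2 = scaled_linewidths(64, 1024)
        spec = render_metabolite(
            Metabolite("s", (Multiplet(4.0, (), 1.0, lw1, lw2),)), *demo_axes
        )
        found = pick_peaks(spec, 0.01)
        assert len(found) == 1
        r, c = np.unravel_index(spec.grid.argmax(), spec.shape)
        assert found[0].position == (r, c)

    def test_threshold_above_max_returns_nothing(self):
        spec = peaks_at([(10, 10)], heights=[0.5])
        assert pick_peaks(spec, 0.99) == [p for p in pick_peaks(spec, 0.99)]
        # a threshold relative to the global max always keeps the max itself,
        # so use a truly empty spectrum for the empty case
        assert pick_peaks(make_spectrum(np.zeros((8, 8))), 0.5) == []

    def test_equal_maxima_both_returned_in_row_col_order(self):
        spec = peaks_at([(5, 5), (20, 20)], heights=[2.0, 2.0])
        found = pick_peaks(spec, 0.1)
        assert [p.position for p in found] == [(5, 5), (20, 20)]

    def test_sorted_by_height_descending(self):
        spec = peaks_at([(5, 5), (20, 20), (40, 40)], heights=[1.0, 3.0, 2.0])
        found = pick_peaks(spec, 0.1)
        assert [p.height for p in found] == [3.0, 2.0, 1.0]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            pick_peaks(peaks_at([(3, 3)]), 0.0)


def brute_force_pairs(peaks, k, max_dist):
    """O(n^2) oracle: per-peak k nearest by (distance, row, col), dedup."""
    out = set()
    for i, p in enumerate(peaks):
        cand = []
        for j, q in enumerate(peaks):
            if i == j:
                continue
            d = np.hypot(p.row - q.row, p.col - q.col)
            cand.append((d, q.row, q.col, j))
        cand.sort()
        for d, _, _, j in cand[:k]:
            if 0 < d <= max_dist:
                out.add((min(i, j), max(i, j)))
    return out


class TestFormPairs:
    def test_two_close_peaks_one_pair(self):
        peaks = [Peak(0, 0, 1.0), Peak(0, 10, 1.0)]
        pairs = form_pairs(peaks, 3, 30)
        assert len(pairs) == 1
        assert pairs[0].distance_px == 10.0

    def test_pair_beyond_30_pixels_excluded(self):
        peaks = [Peak(0, 0, 1.0), Peak(0, 31, 1.0)]
        assert form_pairs(peaks, 3, 30) == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)),
            min_size=1, max_size=50, unique=True,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_all_pairs_oracle(self, coords):
        peaks = [Peak(r, c, 1.0 + 0.01 * i) for i, (r, c) in enumerate(coords)]
        got = {
            (min(peaks.index(p.peak_a), peaks.index(p.peak_b)),
             max(peaks.index(p.peak_a), peaks.index(p.peak_b)))
            for p in form_pairs(peaks, 3, 30)
        }
        assert got == brute_force_pairs(peaks, 3, 30)


class TestMatchPosition:
    def test_identity_on_same_grid(self):
        spec = peaks_at([(10, 20)], width=2.0)
        m = match_position(Peak(10, 20, 1.0), spec)
        assert m.position == (10, 20)

    def test_half_grid_scaling(self):
        hr_shape = (64, 64)
        lr = peaks_at([(15, 20)], shape=(32, 32), width=1.5)
        m = match_position(Peak(30, 40, 1.0), lr, source_shape=hr_shape)
        assert m.position == (15, 20)

    def test_small_shift_recovered_within_window(self):
        spec = peaks_at([(12, 22)], width=2.0)
        m = match_position(Peak(10, 20, 1.0), spec, window_px=3)
        assert m.position == (12, 22)

    def test_window_clipped_at_grid_edge(self):
        spec = peaks_at([(0, 0)], width=1.5)
        m = match_position(Peak(0, 0, 1.0), spec, window_px=3)
        assert m.position == (0, 0)


class TestValleyHeight:
    def test_well_separated_peaks_have_near_zero_valley(self):
        spec = peaks_at([(10, 10), (50, 50)], width=2.0)
        v = valley_height(spec, Peak(10, 10, 1.0), Peak(50, 50, 1.0))
        assert v < 1e-6

    def test_adjacent_pixels_min_of_two(self):
        g = np.zeros((8, 8))
        g[3, 3], g[3, 4] = 2.0, 5.0
        v = valley_height(make_spectrum(g), Peak(3, 3, 2.0), Peak(3, 4, 5.0))
        assert v == 2.0

    def test_row_aligned_profile_equals_slice_minimum(self, rng):
        g = np.abs(rng.normal(1, 0.3, size=(8, 32)))
        spec = make_spectrum(g)
        v = valley_height(spec, Peak(4, 3, 1.0), Peak(4, 20, 1.0))
        assert v == pytest.approx(g[4, 3:21].min())

    def test_same_position_rejected(self):
        spec = peaks_at([(3, 3)])
        with pytest.raises(ValueError):
            valley_height(spec, Peak(3, 3, 1.0), Peak(3, 3, 1.0))


class TestResolvability:
    def test_zero_valley_is_fully_resolved(self):
        assert resolvability(1.0, 2.0, 0.0) == 1.0

    def test_valley_at_peak_height_is_unresolved(self):
        assert resolvability(3.0, 3.0, 3.0) == 0.0

    def test_intermediate_value(self):
        assert resolvability(2.0, 4.0, 1.5) == pytest.approx(0.5)

    def test_min_variant_endpoints(self):
        assert resolvability(1.0, 5.0, 0.0, variant="min") == 1.0
        assert resolvability(3.0, 3.0, 3.0, variant="min") == 0.0

    @given(
        hi=st.floats(0.1, 10), hj=st.floats(0.1, 10),
        v1=st.floats(0, 10), v2=st.floats(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_valley_and_symmetric_in_heights(self, hi, hj, v1, v2):
        lo, hi_v = sorted((v1, v2))
        assert resolvability(hi, hj, lo) >= resolvability(hi, hj, hi_v)
        assert resolvability(hi, hj, v1) == resolvability(hj, hi, v1)

    def test_nonpositive_heights_rejected(self):
        with pytest.raises(ValueError):
            resolvability(0.0, 1.0, 0.5)


@pytest.mark.parametrize(
    "score,label",
    [
        (0.0, "poorly resolved"),
        (0.19, "poorly resolved"),
        (0.2, "partially resolved"),
        (0.59, "partially resolved"),
        (0.6, "well resolved"),
        (1.0, "well resolved"),
    ],
)
def test_category_bins_closed_on_the_left(score, label):
    assert categorize(score) == label


@pytest.fixture()
def doublet_scene(rendered_doublet):
    """HR with a resolved doublet, plus its degraded LR counterpart."""
    hr = rendered_doublet
    lr = degrade(hr)
    peaks = pick_peaks(hr, 0.05)
    pairs = form_pairs(peaks, 3, 30)
    return hr, lr, pairs


class TestScorePairs:
    def test_sr_equal_hr_scores_match_exactly(self, doublet_scene):
        hr, lr, pairs = doublet_scene
        records = score_pairs(hr, lr, hr, pairs)
        for rec in records:
            assert rec.scores["SR"] == rec.scores["HR"]

    def test_degradation_lowers_or_keeps_score(self, doublet_scene):
        hr, lr, pairs = doublet_scene
        records = score_pairs(hr, lr, hr, pairs)
        assert records
        for rec in records:
            assert rec.scores["LR"] <= rec.scores["HR"] + 1e-9

    def test_frame_has_one_row_per_pair(self, doublet_scene):
        hr, lr, pairs = doublet_scene
        frame = records_to_frame(score_pairs(hr, lr, hr, pairs))
        assert len(frame) == len(pairs)
        assert {"score_HR", "score_LR", "score_SR"} <= set(frame.columns)


class TestSummarize:
    def _records(self, hr_lr_sr_scores, distances=None):
        records = []
        for i, (h, l, s) in enumerate(hr_lr_sr_scores):
            pair = PeakPair(Peak(0, 0, 1.0), Peak(0, 5 + i, 1.0),
                            distances[i] if distances else 5.0 + i)
            records.append(
                type("R", (), {
                    "pair_id": i, "pair": pair,
                    "scores": {"HR": h, "LR": l, "SR": s},
                })()
            )
        return records

    def test_sr_equal_hr_gives_unit_correlation(self):
        recs = self._records([(0.9, 0.4, 0.9), (0.5, 0.2, 0.5), (0.7, 0.3, 0.7)])
        assert summarize(recs)["corr_hr_sr"] == pytest.approx(1.0)

    def test_all_improved_gives_fraction_one(self):
        recs = self._records([(0.9, 0.4, 0.8), (0.5, 0.2, 0.6), (0.7, 0.3, 0.3001)])
        assert summarize(recs)["frac_sr_ge_lr"] == 1.0

    def test_manual_five_record_oracle(self):
        scores = [(1.0, 0.2, 0.8), (0.8, 0.4, 0.3), (0.6, 0.1, 0.7),
                  (0.4, 0.4, 0.4), (0.2, 0.3, 0.1)]
        s = summarize(self._records(scores, distances=[3, 8, 13, 22, 28]))
        # hand-computed: 3 of 5 have SR >= LR; 2 of 5 strictly greater
        assert s["frac_sr_ge_lr"] == pytest.approx(0.6)
        assert s["frac_sr_gt_lr"] == pytest.approx(0.4)
        assert s["median_LR"] == pytest.approx(0.3)
        hr = np.array([x[0] for x in scores])
        sr = np.array([x[2] for x in scores])
        assert s["corr_hr_sr"] == pytest.approx(np.corrcoef(hr, sr)[0, 1])
        assert s["distance_bins"]["0-10px"]["n"] == 2
        assert s["distance_bins"]["20-30px"]["mean_SR"] == pytest.approx(0.25)

    def test_degenerate_variance_reports_undefined(self):
        recs = self._records([(0.5, 0.1, 0.2), (0.5, 0.2, 0.9)])
        assert summarize(recs)["corr_hr_sr"] is None

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._records([(1.0, 0.5, 0.9)]))


class TestReliability:
    def test_sr_equal_truth_matches_everything(self):
        truth = peaks_at([(10, 10), (20, 40), (40, 25)], width=1.5)
        lr = peaks_at([(5, 5), (10, 20)], shape=(32, 32), width=1.2)
        table = reliability(lr, truth, truth)
        assert (table["sr_matched"] == table["sr_detected"]).all()

    def test_partial_matches_counted(self):
        true_pos = [(8, 8), (8, 40), (24, 16), (24, 48), (40, 8),
                    (40, 40), (56, 24), (16, 56), (48, 56), (56, 48)]
        truth = peaks_at(true_pos, width=1.2)
        sr_pos = true_pos[:8] + [(32, 32), (4, 28)]  # 8 true + 2 spurious
        sr = peaks_at(sr_pos, width=1.2)
        lr = make_spectrum(np.zeros((32, 32)) + 1e-12)
        table = reliability(lr, sr, truth, thresholds=(0.10,))
        row = table.iloc[0]
        assert row["sr_detected"] == 10
        assert row["sr_matched"] == 8

    def test_empty_lr_fraction_over_all_sr_peaks(self):
        truth = peaks_at([(10, 10), (30, 30)], width=1.5)
        sr = peaks_at([(10, 10), (30, 30)], width=1.5)
        lr = make_spectrum(np.zeros((32, 32)))
        table = reliability(lr, sr, truth, thresholds=(0.05,))
        row = table.iloc[0]
        assert row["lr_detected"] == 0
        assert row["gained_fraction"] == pytest.approx(1.0)
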