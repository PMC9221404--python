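"""Comparison/audit statistics: matching, recovery, size audit, CDFs,
regressions, edge heatmap."""

import numpy as np
import pytest

from ctcsegaudit.evaluate import (
    HeatmapGrid,
    MatchRecord,
    SizeBins,
    density_cdf,
    edge_heatmap,
    gain_analysis,
    match_events,
    recovery_report,
    size_audit,
    spikein_correlation,
)


def oracle_match(truth_masks, test_labels, tau_min=0.2, tau_cov=0.8):
    """Brute-force reference implementation: explicit pairwise pixel
    overlaps via boolean masks and literal rule application."""
    test_ids = [k for k in np.unique(test_labels) if k > 0]
    test_masks = {k: test_labels == k for k in test_ids}
    n = len(truth_masks)
    overlap = [
        {k: int((tm & test_masks[k]).sum()) for k in test_ids} for tm in truth_masks
    ]
    qualities = []
    for i in range(n):
        area = int(truth_masks[i].sum())
        matched = [k for k in test_ids if overlap[i][k] >= tau_min * area]
        if not matched:
            qualities.append("missed")
            continue
        best = max(test_ids, key=lambda k: (overlap[i][k], -k))
        best_covers_other = any(
            j != i and overlap[j][best] >= tau_min * int(truth_masks[j].sum())
            for j in range(n)
        )
        if best_covers_other:
            qualities.append("merged")
        elif len(matched) >= 2:
            qualities.append("split")
        elif sum(overlap[i][k] for k in matched) < tau_cov * area:
            qualities.append("partial")
        else:
            qualities.append("correct")
    return qualities


def blob_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


class TestMatchEvents:
    def test_identity_all_correct(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:15, 5:15] = 1
        labels[20:30, 20:30] = 2
        recs = match_events(labels.copy(), labels)
        assert [r.quality for r in recs] == ["correct", "correct"]

    def test_bisected_truth_is_split(self):
        truth = np.zeros((40, 40), dtype=int)
        truth[10:30, 10:30] = 1
        test = np.zeros((40, 40), dtype=int)
        test[10:30, 10:20] = 1
        test[10:30, 20:30] = 2
        (rec,) = match_events(truth, test)
        assert rec.quality == "split"
        assert rec.matched_test_ids == [1, 2]

    def test_one_test_label_covering_two_truths_is_merged(self):
        truth = np.zeros((40, 40), dtype=int)
        truth[10:20, 5:15] = 1
        truth[10:20, 25:35] = 2
        test = np.zeros((40, 40), dtype=int)
        test[8:22, 3:37] = 1
        recs = match_events(truth, test)
        assert [r.quality for r in recs] == ["merged", "merged"]

    def test_low_coverage_is_partial(self):
        truth = np.zeros((40, 40), dtype=int)
        truth[10:30, 10:30] = 1  # 400 px
        test = np.zeros((40, 40), dtype=int)
        test[10:30, 10:20] = 1  # covers half (>= tau_min, < tau_cov)
        (rec,) = match_events(truth, test)
        assert rec.quality == "partial"

    def test_no_overlap_is_missed(self):
        truth = np.zeros((40, 40), dtype=int)
        truth[5:10, 5:10] = 1
        test = np.zeros((40, 40), dtype=int)
        test[30:35, 30:35] = 1
        (rec,) = match_events(truth, test)
        assert rec.quality == "missed"
        assert rec.matched_test_ids == []

    def test_geometry_mismatch_raises(self):
        truth = [np.ones((50, 50), dtype=bool)]
        with pytest.raises(ValueError):
            match_events(truth, np.zeros((40, 40), dtype=int))

    def test_agreement_with_bruteforce_oracle(self):
        """Random <= 10-object frames classified identically by the
        pairwise-overlap oracle, over 30 seeded trials."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            shape = (64, 64)
            n_truth = int(rng.integers(1, 11))
            truth_masks = [
                blob_mask(shape, rng.uniform(8, 56, 2), rng.uniform(3, 9))
                for _ in range(n_truth)
            ]
            # build a test segmentation by perturbing truth: drop some,
            # split some, merge neighbours via dilated boxes
            test = np.zeros(shape, dtype=int)
            k = 1
            for tm in truth_masks:
                u = rng.random()
                if u < 0.2:
                    continue  # dropped -> missed
                if u < 0.4:  # split vertically
                    rows, cols = np.nonzero(tm)
                    mid = int(np.median(cols))
                    left = tm & (np.arange(shape[1])[None, :] < mid)
                    right = tm & ~left
                    if left.any():
                        test[left] = k
                        k += 1
                    if right.any():
                        test[right] = k
                        k += 1
                else:
                    test[tm] = k
                    k += 1
            got = [r.quality for r in match_events(truth_masks, test)]
            want = oracle_match(truth_masks, test)
            assert got == want

    def test_quality_classes_partition(self, mixed_archive):
        from ctcsegaudit.segmenter import segment
        from ctcsegaudit.simcartridge import truth_label_map

        labels, _ = segment(mixed_archive.frames[0])
        tl, _ = truth_label_map(mixed_archive, 0)
        recs = match_events(tl, labels)
        rep = recovery_report(recs)
        assert sum(rep.counts.values()) == rep.n_reference == len(recs)


class TestRecoveryReport:
    def test_published_style_tallies(self):
        """1948 references with 1 missed, 14 split, 8 partial, 11 merged:
        recovery 99.95%, rates 0.7/0.4/0.6%."""
        rep = recovery_report(
            {"correct": 1914, "split": 14, "partial": 8, "merged": 11, "missed": 1}
        )
        assert rep.n_reference == 1948
        assert rep.recovery_pct == 99.95
        assert rep.percentages["split"] == 0.7
        assert rep.percentages["partial"] == 0.4
        assert rep.percentages["merged"] == 0.6

    def test_all_correct(self):
        rep = recovery_report({"correct": 25})
        assert rep.recovery_pct == 100.0
        assert all(
            rep.percentages[q] == 0.0 for q in ("split", "partial", "merged", "missed")
        )

    def test_half_missed(self):
        rep = recovery_report({"correct": 5, "missed": 5})
        assert rep.recovery_pct == 50.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            recovery_report([])

    def test_match_record_invariants(self):
        with pytest.raises(ValueError):
            MatchRecord(0, "missed", [1])
        with pytest.raises(ValueError):
            MatchRecord(0, "bogus", [])


class TestSizeAudit:
    def test_sample_fraction_in_largest_bin(self):
        """55 of 601 samples containing a >100k px segmentation -> 9.15%."""
        samples = [[200_000.0, 100.0] for _ in range(55)]
        samples += [[100.0] for _ in range(601 - 55)]
        table = size_audit(samples)
        row = table[table["size_bin"] == ">100000"].iloc[0]
        assert row["pct_samples"] == 9.15

    def test_single_small_segmentation(self):
        table = size_audit([[100.0]])
        small = table.iloc[0]
        assert small["pct_samples"] == 100.0
        assert small["pct_segmented_area_mean"] == 100.0
        assert table.iloc[1:]["pct_segmented_area_mean"].fillna(0).eq(0).all()

    def test_two_bin_split_arithmetic(self):
        table = size_audit([[1000.0, 30_000.0]])
        assert table.iloc[0]["pct_segmented_area_mean"] == pytest.approx(
            100 * 1000 / 31_000, abs=0.01
        )
        assert table.iloc[2]["pct_segmented_area_mean"] == pytest.approx(
            100 * 30_000 / 31_000, abs=0.01
        )

    def test_segmented_area_sums_to_100(self, rng):
        samples = [
            list(rng.uniform(50, 200_000, rng.integers(1, 40))) for _ in range(25)
        ]
        table = size_audit(samples)
        assert table["pct_segmented_area_mean_exact"].sum() == pytest.approx(100.0, abs=0.1)

    def test_bin_edges_follow_half_open_convention(self):
        bins = SizeBins()
        assert list(bins.assign(np.array([2500.0, 2500.1, 25_000.0, 100_000.0, 100_001.0]))) == [
            0, 1, 1, 2, 3
        ]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            size_audit([[0.5]])
        with pytest.raises(ValueError):
            size_audit([[10.0]], cartridge_area_px=0)
        with pytest.raises(ValueError):
            SizeBins(boundaries=(5, 4, 3))


class TestDensityCdf:
    def test_identical_groups_no_dominance(self):
        res = density_cdf({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert not res["dominance"][("a", "b")]
        assert not res["dominance"][("b", "a")]

    def test_shifted_group_is_dominated(self):
        """Adding a positive constant to every sample shifts the CDF right:
        the original group stochastically dominates (fewer events)."""
        a = [10, 20, 30, 40]
        b = [x + 5 for x in a]
        res = density_cdf({"a": a, "b": b})
        assert res["dominance"][("a", "b")]
        assert not res["dominance"][("b", "a")]

    def test_median_and_cdf_values(self):
        res = density_cdf({"g": [1, 2, 3]})
        assert res["medians"]["g"] == 2
        g = res["groups"]["g"]
        assert g["cdf"][np.searchsorted(g["x"], 2)] == pytest.approx(2 / 3)

    def test_cdf_monotone_reaching_one(self, rng):
        res = density_cdf({"g": rng.integers(0, 1000, 50)})
        cdf = res["groups"]["g"]["cdf"]
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0

    def test_dominance_antisymmetric(self, rng):
        groups = {k: rng.integers(0, 100, 30) for k in "abcd"}
        res = density_cdf(groups)
        for a in "abcd":
            for b in "abcd":
                if a != b:
                    assert not (
                        res["dominance"][(a, b)] and res["dominance"][(b, a)]
                    )

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = density_cdf({"a": [1, 2], "b": []})
        assert "b" not in res["groups"]


class TestSpikeinCorrelation:
    def test_exact_identity_line(self):
        pts = [(0, 0), (1000, 1000), (2000, 2000), (4000, 4000)]
        fit, excess = spikein_correlation(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_excess_becomes_intercept(self):
        pts = [(x, x + 30_000) for x in (0, 50_000, 100_000, 200_000, 400_000)]
        fit, excess = spikein_correlation(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(30_000.0)
        assert np.allclose(excess, 30_000.0)

    def test_noisy_slope_recovery(self, rng):
        x = np.array([0, 50, 100, 150, 200, 300, 400], dtype=float) * 1000
        y = 0.9 * x + rng.normal(0, 1000, x.size)
        fit, _ = spikein_correlation(list(zip(x, y)))
        assert 0.85 <= fit.slope <= 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spikein_correlation([(0, 0), (1, 1)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            spikein_correlation([(5, 1), (5, 2), (5, 3)])


class TestEdgeHeatmap:
    FRAME = (977, 1211)

    def test_interior_events_zero_edge_fraction(self):
        pos = np.tile([[488.0, 605.0]], (20, 1))
        res = edge_heatmap(pos, self.FRAME)
        assert res["edge_fraction"] == 0.0

    def test_corner_events_edge_fraction_one(self):
        pos = np.array([[1.0, 1.0], [970.0, 1205.0]])
        res = edge_heatmap(pos, self.FRAME)
        assert res["edge_fraction"] == 1.0

    def test_uniform_positions_match_area_expectation(self, rng):
        pos = np.column_stack(
            [rng.uniform(0, self.FRAME[0], 100_000), rng.uniform(0, self.FRAME[1], 100_000)]
        )
        res = edge_heatmap(pos, self.FRAME)
        assert abs(res["edge_fraction"] - res["uniform_expected_fraction"]) < 0.01

    def test_grid_tiles_frame_and_expectation(self):
        res = edge_heatmap(np.empty((0, 2)), self.FRAME, HeatmapGrid(25, 31))
        assert res["counts"].shape == (25, 31)
        # equal-size bins: expectation = perimeter-bin count fraction
        assert res["uniform_expected_fraction"] == pytest.approx(108 / 775)
        assert np.isnan(res["edge_fraction"])

    def test_out_of_frame_positions_rejected(self):
        with pytest.raises(ValueError):
            edge_heatmap(np.array([[2000.0, 5.0]]), self.FRAME)


class TestGainAnalysis:
    def test_identity_no_gain(self):
        x = np.array([0, 1, 2, 5, 10], dtype=float)
        fit, risk = gain_analysis(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert risk["risk_conversions"] == 0
        assert risk["zero_to_nonzero"] == 0

    def test_exact_linear_gain(self):
        x = np.array([0, 2, 4, 10, 20], dtype=float)
        y = 1.2 * x + 1
        fit, _ = gain_analysis(x, y)
        assert fit.slope == pytest.approx(1.2)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_threshold_crossings_counted(self):
        orig = np.array([4, 4, 0], dtype=float)
        comb = np.array([5, 4, 1], dtype=float)
        _, risk = gain_analysis(orig, comb)
        assert risk["risk_conversions"] == 1
        assert risk["zero_to_nonzero"] == 1

    def test_review_only_adds(self):
        with pytest.raises(ValueError):
            gain_analysis(np.array([3.0]), np.array([2.0]))

    def test_slope_recovery_on_simulated_review(self):
        """Counts generated as round(1.2*orig + 1 + noise) recover the
        slope within +-0.05 at n=400."""
        rng = np.random.default_rng(7)
        orig = rng.poisson(6, 400).astype(float)
        comb = np.round(1.2 * orig + 1 + rng.normal(0, 0.5, 400))
        comb = np.maximum(comb, orig)
        fit, _ = gain_analysis(orig, comb)
        assert abs(fit.slope - 1.2) <= 0.05
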