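"""Comparison and audit statistics for segmentation quality and CTC yield.

Covers: per-reference segmentation-quality classification (correct / split
/ partial / merged / missed) and recovery percentage; the segmentation-size
audit table; per-group empirical CDFs of event counts with first-order
stochastic dominance flags; spike-in correlation; the edge heatmap of
novel-candidate positions; and the CTC-gain regression with risk-group
conversion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MatchRecord",
    "ComparisonReport",
    "SizeBins",
    "RegressionFit",
    "HeatmapGrid",
    "match_events",
    "recovery_report",
    "size_audit",
    "density_cdf",
    "spikein_correlation",
    "edge_heatmap",
    "gain_analysis",
]

QUALITY_CLASSES = ("correct", "split", "partial", "merged", "missed")


@dataclass
class MatchRecord:
    """Quality verdict for one reference (ground-truth) object."""

    reference_id: int
    quality: str
    matched_test_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.quality not in QUALITY_CLASSES:
            raise ValueError(f"unknown quality class {self.quality!r}")
        if (self.quality == "missed") != (len(self.matched_test_ids) == 0):
            raise ValueError("missed iff no matched test events")


@dataclass
class ComparisonReport:
    """Recovery and per-quality tallies over a set of reference objects.

    Quality rates are rounded to 1 decimal, recovery to 2 decimals (the
    conventional reporting precision); unrounded values are kept alongside.
    """

    n_reference: int
    counts: dict[str, int]
    percentages: dict[str, float]
    recovery_pct: float
    percentages_exact: dict[str, float]
    recovery_pct_exact: float

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "recovery_pct": self.recovery_pct,
            "percentages_exact": dict(self.percentages_exact),
            "recovery_pct_exact": self.recovery_pct_exact,
        }


@dataclass
class SizeBins:
    """Boundaries splitting segmentation areas into four categories:
    regular (<= first), larger than a cell, too large to review, and very
    large (> last)."""

    boundaries: tuple[float, float, float] = (2500.0, 25_000.0, 100_000.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (b[0] < b[1] < b[2]):
            raise ValueError("bin boundaries must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        b = self.boundaries
        return [
            f"<={b[0]:g}",
            f"{b[0]:g}-{b[1]:g}",
            f"{b[1]:g}-{b[2]:g}",
            f">{b[2]:g}",
        ]

    def assign(self, areas: np.ndarray) -> np.ndarray:
        """Bin index 0..3 per area; intervals are (low, high]."""
        return np.searchsorted(np.asarray(self.boundaries), areas, side="left")


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class HeatmapGrid:
    """Equal-size spatial bins tiling a frame exactly."""

    n_rows: int = 25
    n_cols: int = 31

    def edges(self, frame_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        h, w = frame_shape
        return (
            np.linspace(0.0, float(h), self.n_rows + 1),
            np.linspace(0.0, float(w), self.n_cols + 1),
        )


# ---------------------------------------------------------------------------
# Segmentation-quality matching


def _truth_masks(truth) -> list[tuple[int, tuple[np.ndarray, np.ndarray]]]:
    """Normalize truth input to (id, (rows, cols)) pairs.

    Accepts a label map (ids = labels) or a sequence of boolean masks /
    (rows, cols) index pairs (ids = positions)."""
    if isinstance(truth, np.ndarray) and truth.ndim == 2 and truth.dtype != bool:
        out = []
        for lab in np.unique(truth):
            if lab <= 0:
                continue
            rows, cols = np.nonzero(truth == lab)
            out.append((int(lab), (rows, cols)))
        return out
    out = []
    for i, m in enumerate(truth):
        if isinstance(m, np.ndarray):
            rows, cols = np.nonzero(m)
        else:
            rows, cols = m
        out.append((i, (np.asarray(rows), np.asarray(cols))))
    return out


def match_events(
    truth,
    test_labels: np.ndarray,
    tau_min: float = 0.2,
    tau_cov: float = 0.8,
) -> list[MatchRecord]:
    """Classify every reference object against a test label map.

    A reference is *missed* when no test label overlaps at least ``tau_min``
    of its mask; *merged* when its best-matching test label also overlaps at
    least ``tau_min`` of another reference; *split* when two or more test
    labels each overlap at least ``tau_min`` of it; *partial* when its
    matched labels cover less than ``tau_cov`` of it; otherwise *correct*.

    ``truth`` may be a ground-truth label map or a sequence of boolean
    masks / ``(rows, cols)`` index pairs with the same frame geometry as
    ``test_labels``.
    """
    test_labels = np.asarray(test_labels)
    refs = _truth_masks(truth)
    for _, (rows, cols) in refs:
        if rows.size and (
            rows.max() >= test_labels.shape[0] or cols.max() >= test_labels.shape[1]
        ):
            raise ValueError("truth mask exceeds test label-map geometry")

    # Per reference: overlap pixel counts with each test label.
    overlaps: list[dict[int, int]] = []
    areas: list[int] = []
    for _, (rows, cols) in refs:
        vals = test_labels[rows, cols]
        vals = vals[vals > 0]
        counts: dict[int, int] = {}
        if vals.size:
            uniq, cnt = np.unique(vals, return_counts=True)
            counts = {int(u): int(c) for u, c in zip(uniq, cnt)}
        overlaps.append(counts)
        areas.append(int(rows.size))

    # Reverse index: test label -> references it covers substantially.
    covered_by: dict[int, list[int]] = {}
    matched_sets: list[list[int]] = []
    for i, counts in enumerate(overlaps):
        matched = [j for j, c in counts.items() if c >= tau_min * areas[i]]
        matched_sets.append(sorted(matched))
        for j in matched:
            covered_by.setdefault(j, []).append(i)

    records: list[MatchRecord] = []
    for i, (ref_id, _) in enumerate(refs):
        counts = overlaps[i]
        matched = matched_sets[i]
        if not matched:
            records.append(MatchRecord(ref_id, "missed", []))
            continue
        best = max(counts, key=lambda j: (counts[j], -j))
        if len(covered_by.get(best, [])) > 1:
            quality = "merged"
        elif len(matched) >= 2:
            quality = "split"
        elif sum(counts[j] for j in matched) < tau_cov * areas[i]:
            quality = "partial"
        else:
            quality = "correct"
        records.append(MatchRecord(ref_id, quality, matched))
    return records


def recovery_report(
    matches: list[MatchRecord] | dict[str, int],
) -> ComparisonReport:
    """Tally quality classes and the recovery percentage.

    Accepts either match records or a precomputed ``{class: count}`` tally.
    Recovery = 100 * (n_reference - missed) / n_reference.
    """
    if isinstance(matches, dict):
        counts = {q: int(matches.get(q, 0)) for q in QUALITY_CLASSES}
    else:
        if len(matches) == 0:
            raise ValueError("recovery_report needs at least one reference")
        counts = {q: 0 for q in QUALITY_CLASSES}
        for m in matches:
            counts[m.quality] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("recovery_report needs at least one reference")
    pct_exact = {q: 100.0 * c / n for q, c in counts.items()}
    recovery_exact = 100.0 * (n - counts["missed"]) / n
    return ComparisonReport(
        n_reference=n,
        counts=counts,
        percentages={q: round(p, 1) for q, p in pct_exact.items()},
        recovery_pct=round(recovery_exact, 2),
        percentages_exact=pct_exact,
        recovery_pct_exact=recovery_exact,
    )


# ---------------------------------------------------------------------------
# Size audit


def size_audit(
    sample_areas: list[list[float]],
    bins: SizeBins | None = None,
    cartridge_area_px: float = 140 * 977 * 1211,
) -> pd.DataFrame:
    """Per-size-category audit across samples.

    For each category: the percentage of samples containing at least one
    segmentation in the category; the mean (and range) percentage of the
    cartridge area covered by that category's segmentations; and the mean
    (and range) percentage of the sample's total segmented area falling in
    the category (samples without any segmentation are excluded from the
    latter).  Cell percentages are reported to 2 decimals alongside exact
    values.
    """
    if bins is None:
        bins = SizeBins()
    if cartridge_area_px <= 0:
        raise ValueError("cartridge area must be positive")
    n_samples = len(sample_areas)
    if n_samples == 0:
        raise ValueError("size_audit needs at least one sample")
    n_bins = 4
    has_bin = np.zeros((n_samples, n_bins), dtype=bool)
    cart_pct = np.zeros((n_samples, n_bins))
    seg_pct = np.full((n_samples, n_bins), np.nan)
    for s, areas in enumerate(sample_areas):
        areas = np.asarray(areas, dtype=float)
        if np.any(areas < 1):
            raise ValueError("segmentation areas must be >= 1 px")
        if areas.size == 0:
            continue
        idx = bins.assign(areas)
        total = areas.sum()
        for b in range(n_bins):
            in_bin = areas[idx == b]
            has_bin[s, b] = in_bin.size > 0
            cart_pct[s, b] = 100.0 * in_bin.sum() / cartridge_area_px
            seg_pct[s, b] = 100.0 * in_bin.sum() / total
    rows = []
    for b in range(n_bins):
        seg_col = seg_pct[:, b]
        seg_col = seg_col[~np.isnan(seg_col)]
        rows.append(
            {
                "size_bin": bins.labels[b],
                "pct_samples_exact": 100.0 * has_bin[:, b].mean(),
                "pct_samples": round(100.0 * has_bin[:, b].mean(), 2),
                "pct_cartridge_area_mean": round(float(cart_pct[:, b].mean()), 2),
                "pct_cartridge_area_min": round(float(cart_pct[:, b].min()), 2),
                "pct_cartridge_area_max": round(float(cart_pct[:, b].max()), 2),
                "pct_segmented_area_mean_exact": float(seg_col.mean())
                if seg_col.size
                else np.nan,
                "pct_segmented_area_mean": round(float(seg_col.mean()), 2)
                if seg_col.size
                else np.nan,
                "pct_segmented_area_min": round(float(seg_col.min()), 2)
                if seg_col.size
                else np.nan,
                "pct_segmented_area_max": round(float(seg_col.max()), 2)
                if seg_col.size
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density CDFs


def density_cdf(
    counts_by_group: dict, warn: bool = True
) -> dict:
    """Empirical CDFs of per-sample event counts, grouped (e.g. by days
    between collection and preparation).

    Returns, per group, the sorted support and right-continuous CDF values,
    plus the median, and pairwise first-order stochastic dominance flags:
    ``dominance[(a, b)]`` is True when group *a*'s CDF lies at or above
    group *b*'s everywhere on the pooled support, strictly somewhere —
    i.e. *a* has stochastically fewer events.  Empty groups are dropped.
    """
    groups = {}
    for k, v in counts_by_group.items():
        arr = np.sort(np.asarray(v, dtype=float))
        if arr.size == 0:
            if warn:
                import warnings

                warnings.warn(f"group {k!r} is empty; excluded", stacklevel=2)
            continue
        groups[k] = arr
    pooled = np.unique(np.concatenate(list(groups.values()))) if groups else np.array([])

    def cdf_at(arr: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.searchsorted(arr, x, side="right") / arr.size

    result = {
        "groups": {},
        "medians": {},
        "dominance": {},
    }
    for k, arr in groups.items():
        result["groups"][k] = {
            "x": arr,
            "cdf": cdf_at(arr, arr),
        }
        result["medians"][k] = float(np.median(arr))
    keys = list(groups)
    for a in keys:
        for b in keys:
            if a == b:
                continue
            ca = cdf_at(groups[a], pooled)
            cb = cdf_at(groups[b], pooled)
            result["dominance"][(a, b)] = bool(
                np.all(ca >= cb) and np.any(ca > cb)
            )
    return result


# ---------------------------------------------------------------------------
# Regressions


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
    )


def spikein_correlation(
    series: list[tuple[float, float]],
) -> tuple[RegressionFit, np.ndarray]:
    """Ordinary least squares of detected counts on spiked counts.

    The intercept estimates the low-concentration excess of detected
    events; also returns the per-point excess (detected minus spiked).
    """
    if len(series) < 3:
        raise ValueError("spike-in correlation needs at least 3 points")
    spiked = np.asarray([p[0] for p in series], dtype=float)
    detected = np.asarray([p[1] for p in series], dtype=float)
    fit = _ols(spiked, detected)
    return fit, detected - spiked


def edge_heatmap(
    positions: np.ndarray,
    frame_shape: tuple[int, int],
    grid: HeatmapGrid | None = None,
) -> dict:
    """Spatial histogram of candidate positions plus the edge-bin fraction.

    Edge bins are the first/last row and column of the grid.  The uniform
    expectation is area-weighted: the total edge-bin area divided by the
    frame area (with equal-size bins this is the edge-bin count fraction).
    With zero events the edge fraction is reported as NaN.
    """
    if grid is None:
        grid = HeatmapGrid()
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    h, w = frame_shape
    if positions.size and (
        positions[:, 0].min() < 0
        or positions[:, 1].min() < 0
        or positions[:, 0].max() > h
        or positions[:, 1].max() > w
    ):
        raise ValueError("positions must lie within the frame")
    r_edges, c_edges = grid.edges(frame_shape)
    counts, _, _ = np.histogram2d(
        positions[:, 0] if positions.size else np.empty(0),
        positions[:, 1] if positions.size else np.empty(0),
        bins=(r_edges, c_edges),
    )
    edge_mask = np.zeros_like(counts, dtype=bool)
    edge_mask[0, :] = edge_mask[-1, :] = True
    edge_mask[:, 0] = edge_mask[:, -1] = True
    total = counts.sum()
    edge_fraction = float(counts[edge_mask].sum() / total) if total > 0 else float("nan")
    r_sizes = np.diff(r_edges)[:, None]
    c_sizes = np.diff(c_edges)[None, :]
    areas = r_sizes * c_sizes
    uniform_expected = float(areas[edge_mask].sum() / areas.sum())
    return {
        "counts": counts.astype(int),
        "edge_fraction": edge_fraction,
        "uniform_expected_fraction": uniform_expected,
        "n_events": int(total),
        "row_edges": r_edges,
        "col_edges": c_edges,
    }


def gain_analysis(
    original: np.ndarray,
    combined: np.ndarray,
    risk_threshold: float = 5.0,
) -> tuple[RegressionFit, dict]:
    """OLS of the combined (original + novel) CTC count on the original
    count, plus risk-group conversion tallies.

    Reviewing extra candidates can only add CTC, so ``combined`` must be
    at least ``original`` sample-wise.  The risk table counts samples that
    cross the 5-CTC prognostic threshold and samples gaining their first
    CTC.
    """
    original = np.asarray(original, dtype=float)
    combined = np.asarray(combined, dtype=float)
    if original.shape != combined.shape:
        raise ValueError("original and combined must align sample-wise")
    if np.any(combined < original):
        raise ValueError("combined counts must be >= original counts")
    fit = _ols(original, combined)
    risk = {
        "n_samples": int(original.size),
        "risk_conversions": int(
            np.count_nonzero((original < risk_threshold) & (combined >= risk_threshold))
        ),
        "zero_to_nonzero": int(np.count_nonzero((original == 0) & (combined > 0))),
        "n_zero_original": int(np.count_nonzero(original == 0)),
    }
    return fit, risk
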