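"""Per-event feature extraction and the candidate-CTC gate.

An event is a labeled region of a segmented frame.  Features are computed
on the raw (unenhanced) channel images, since the gate thresholds refer to
instrument intensities.  The gate selects possible circulating tumor cells:
cytokeratin-PE bright (max > 75, mean > 45), nucleated (DAPI max > 60,
mean > 50), leukocyte-marker negative (CD45-APC mean < 50) unless the PE
signal is so bright that spectral crosstalk explains the APC signal
(PE mean > 1000), with a plausible cell size (area 36..1000 px inclusive)
and at least 30 PE-stained pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmenter import ChannelStack

__all__ = [
    "EventRecord",
    "GateThresholds",
    "extract_features",
    "candidate_gate",
    "apply_gate",
    "select_candidates",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "id",
    "frame",
    "row",
    "col",
    "area_px",
    "dapi_mean",
    "dapi_max",
    "pe_mean",
    "pe_max",
    "apc_mean",
    "stained_pe_area_px",
    "gate_pass",
    "failed_criteria",
]


@dataclass
class EventRecord:
    """Intensity/morphology summary of one segmented event."""

    id: int
    frame: int
    row: float
    col: float
    area_px: int
    dapi_mean: float
    dapi_max: float
    pe_mean: float
    pe_max: float
    apc_mean: float
    stained_pe_area_px: int

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")
        if self.stained_pe_area_px > self.area_px:
            raise ValueError("stained_pe_area_px cannot exceed area_px")


@dataclass
class GateThresholds:
    """Candidate-CTC gate thresholds (instrument counts / pixels).

    Intensity clauses are strict inequalities; the area bounds are
    inclusive ("between 36 and 1000 pixels"); ``strict_area`` switches them
    to strict if desired.  ``stain_thresh`` defines a PE-stained pixel for
    ``stained_pe_area_px`` (the same intensity scale as the PE mean
    clause).
    """

    pe_max_min: float = 75.0
    pe_mean_min: float = 45.0
    dapi_max_min: float = 60.0
    dapi_mean_min: float = 50.0
    apc_mean_max: float = 50.0
    pe_mean_crosstalk_override: float = 1000.0
    area_min_px: float = 36.0
    area_max_px: float = 1000.0
    stained_pe_area_min_px: float = 30.0
    stain_thresh: float = 45.0
    strict_area: bool = False

    def __post_init__(self) -> None:
        if self.area_min_px >= self.area_max_px:
            raise ValueError("area_min_px must be < area_max_px")
        for name, val in asdict(self).items():
            if name != "strict_area" and val < 0:
                raise ValueError(f"{name} must be >= 0")


def extract_features(
    labels: np.ndarray,
    stack: ChannelStack,
    stain_thresh: float = 45.0,
    frame: int = 0,
) -> pd.DataFrame:
    """One row per nonzero label: centroid, area, per-channel mean/max on
    the raw channels, and the count of in-label pixels with PE above
    ``stain_thresh``.

    Returns an empty table (with the standard columns) for an empty label
    map.
    """
    labels = np.asarray(labels)
    if labels.shape != stack.shape:
        raise ValueError("label map and stack shapes differ")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS[:11]).astype(
            {"id": int, "frame": int, "area_px": int, "stained_pe_area_px": int},
            errors="ignore",
        )
    index = ids
    area = ndi.sum_labels(np.ones_like(labels), labels, index=index).astype(int)
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, index=index)
    rows = {"id": index.astype(int), "frame": frame}
    rows["row"] = [float(r) for r, _ in centroids]
    rows["col"] = [float(c) for _, c in centroids]
    rows["area_px"] = area
    for ch in ("dapi", "pe", "apc"):
        img = stack.channel(ch).astype(float)
        rows[f"{ch}_mean"] = ndi.mean(img, labels, index=index)
        rows[f"{ch}_max"] = ndi.maximum(img, labels, index=index)
    pe = stack.channel("pe").astype(float)
    stained = np.bincount(
        labels[(labels > 0) & (pe > stain_thresh)].ravel(),
        minlength=int(index.max()) + 1,
    )
    rows["stained_pe_area_px"] = stained[index].astype(int)
    df = pd.DataFrame(rows)
    df = df.drop(columns=["apc_max"], errors="ignore")
    return df[
        [
            "id",
            "frame",
            "row",
            "col",
            "area_px",
            "dapi_mean",
            "dapi_max",
            "pe_mean",
            "pe_max",
            "apc_mean",
            "stained_pe_area_px",
        ]
    ]


def candidate_gate(
    r: EventRecord | pd.Series | dict, t: GateThresholds | None = None
) -> tuple[bool, list[str]]:
    """Apply the candidate-CTC gate to one event.

    Returns the pass decision together with the names of every violated
    clause (empty on pass).  The APC clause is an OR: a low leukocyte-marker
    mean, or a PE mean bright enough that PE->APC crosstalk explains the
    APC signal.
    """
    if t is None:
        t = GateThresholds()
    g = (lambda k: getattr(r, k)) if isinstance(r, EventRecord) else (lambda k: r[k])
    failed: list[str] = []
    if not g("pe_max") > t.pe_max_min:
        failed.append("pe_max")
    if not g("pe_mean") > t.pe_mean_min:
        failed.append("pe_mean")
    if not g("dapi_max") > t.dapi_max_min:
        failed.append("dapi_max")
    if not g("dapi_mean") > t.dapi_mean_min:
        failed.append("dapi_mean")
    if not (
        g("apc_mean") < t.apc_mean_max
        or g("pe_mean") > t.pe_mean_crosstalk_override
    ):
        failed.append("apc_mean")
    if t.strict_area:
        area_ok = t.area_min_px < g("area_px") < t.area_max_px
    else:
        area_ok = t.area_min_px <= g("area_px") <= t.area_max_px
    if not area_ok:
        failed.append("area")
    if not g("stained_pe_area_px") >= t.stained_pe_area_min_px:
        failed.append("stained_pe_area")
    return (len(failed) == 0), failed


def apply_gate(
    events: pd.DataFrame, t: GateThresholds | None = None
) -> pd.DataFrame:
    """Gate a whole event table; adds ``gate_pass`` and ``failed_criteria``
    (semicolon-joined clause names) columns.  Row order has no effect on
    decisions."""
    if t is None:
        t = GateThresholds()
    out = events.copy()
    passes, faileds = [], []
    for _, row in events.iterrows():
        ok, failed = candidate_gate(row, t)
        passes.append(ok)
        faileds.append(";".join(failed))
    out["gate_pass"] = passes
    out["failed_criteria"] = faileds
    return out


def select_candidates(
    events: pd.DataFrame,
    reference_rects: list[tuple[int, int, int, int, int]],
    t: GateThresholds | None = None,
) -> pd.DataFrame:
    """Gate-passing events whose centroid lies inside no reference
    rectangle — the novel candidates the reference segmentation never
    presented for review.

    ``reference_rects`` are half-open ``(frame, r0, c0, r1, c1)``.
    """
    gated = apply_gate(events, t) if "gate_pass" not in events.columns else events
    passing = gated[gated["gate_pass"]]
    by_frame: dict[int, list[tuple[int, int, int, int]]] = {}
    for f, r0, c0, r1, c1 in reference_rects:
        by_frame.setdefault(int(f), []).append((r0, c0, r1, c1))
    keep = []
    for _, row in passing.iterrows():
        inside = any(
            r0 <= row["row"] < r1 and c0 <= row["col"] < c1
            for r0, c0, r1, c1 in by_frame.get(int(row["frame"]), [])
        )
        keep.append(not inside)
    return passing[np.asarray(keep, dtype=bool)] if len(passing) else passing
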