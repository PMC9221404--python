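"""Ground-truthed synthetic cartridge simulator.

CellSearch-style cartridges are scanned as 140 four-channel fluorescence
frames (DAPI nuclear stain, cytokeratin-PE, CD45-APC, plus an unused spare
channel).  Clinical archives are not publicly available, so this module
emulates their salient features with full ground truth: nucleated
leukocytes (DAPI+/APC+/PE-), tumor cells (DAPI+/PE+/APC-), small
tumor-derived extracellular vesicles (PE+/DAPI-), bare nuclei (DAPI+ only),
touching-cell clumps, densities up to ~3000 objects per frame, PE->APC
spectral crosstalk, vignetting (lower signal-to-noise near frame edges) and
sample-age-dependent leukocyte carryover.

Every simulated object carries its true pixel mask and class label, so the
downstream segmentation, gating and audit stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .segmenter import CHANNELS, ChannelStack
from .starconvex import StarPolygon, polygon_to_mask

__all__ = [
    "CartridgeSpec",
    "SimConfig",
    "GroundTruthObject",
    "SampleArchive",
    "PlacementError",
    "generate_cartridge",
    "render_frame",
    "spike_in_series",
    "emulate_reference_segmentation",
    "carryover_multiplier",
    "truth_label_map",
    "DEFAULT_INTENSITY",
]

OBJECT_CLASSES = ("tumor", "leukocyte", "tdev", "bare_nucleus")

# Per-class lognormal intensity medians per channel (CellTracks-like 12-bit
# counts).  Anchored so that the candidate-CTC gate thresholds are
# meaningful: tumor PE and nucleated DAPI medians sit near 300, leukocyte
# APC near 300, background near 20.
DEFAULT_INTENSITY: dict[str, dict[str, tuple[float, float]]] = {
    # channel: (lognormal median, sigma of log)
    "tumor": {"dapi": (300.0, 0.35), "pe": (300.0, 0.35), "apc": (0.0, 0.0)},
    "leukocyte": {"dapi": (300.0, 0.35), "pe": (0.0, 0.0), "apc": (300.0, 0.35)},
    "tdev": {"dapi": (0.0, 0.0), "pe": (200.0, 0.45), "apc": (0.0, 0.0)},
    "bare_nucleus": {"dapi": (250.0, 0.35), "pe": (0.0, 0.0), "apc": (0.0, 0.0)},
}

# Object radius ranges in pixels (uniform draw); at 0.64 um/px a tumor cell
# of radius 8 px is ~10 um across the radius, i.e. a 16-20 um cell.
_RADIUS_PX = {
    "tumor": (7.0, 10.0),
    "leukocyte": (5.0, 7.0),
    "tdev": (1.5, 3.0),
    "bare_nucleus": (4.0, 6.0),
}


class PlacementError(RuntimeError):
    """Raised when the requested object density cannot be placed (more than
    90% of the frame area would be covered, or no free center was found)."""


@dataclass
class CartridgeSpec:
    """Geometry of a simulated cartridge scan."""

    n_frames: int = 140
    frame_height_px: int = 977
    frame_width_px: int = 1211
    pixel_pitch_um: float = 0.64
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_height_px < 64 or self.frame_width_px < 64:
            raise ValueError("frame dimensions must be >= 64 px")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height_px, self.frame_width_px)

    @property
    def frame_area_px(self) -> int:
        return self.frame_height_px * self.frame_width_px


@dataclass
class SimConfig:
    """Content of a simulated cartridge.

    Counts are totals over the whole cartridge.  ``clump_fraction`` is the
    probability that an object is deliberately placed touching an existing
    one; ``nonstarconvex_fraction`` is the probability that a tumor cell is
    rendered as a dumbbell of two fused lobes (a shape a star-convex model
    cannot represent with one polygon).  ``pe_to_apc_crosstalk`` bleeds a
    fraction of the PE signal into the APC channel, as seen on real
    CellTracks scans.  ``vignetting_strength`` is the fractional signal loss
    at the frame corner relative to the center.
    """

    tumor_cells: int = 0
    leukocytes: int = 0
    tdevs: int = 0
    bare_nuclei: int = 0
    clump_fraction: float = 0.1
    nonstarconvex_fraction: float = 0.05
    intensity: dict = field(default_factory=lambda: DEFAULT_INTENSITY)
    pe_to_apc_crosstalk: float = 0.05
    vignetting_strength: float = 0.3
    background_level: float = 20.0
    noise_sd: float = 4.0
    poisson_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_cells", "leukocytes", "tdevs", "bare_nuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("clump_fraction", "nonstarconvex_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pe_to_apc_crosstalk < 0:
            raise ValueError("pe_to_apc_crosstalk must be >= 0")
        if not (0.0 <= self.vignetting_strength <= 1.0):
            raise ValueError("vignetting_strength must lie in [0, 1]")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "tumor": self.tumor_cells,
            "leukocyte": self.leukocytes,
            "tdev": self.tdevs,
            "bare_nucleus": self.bare_nuclei,
        }

    @property
    def total_objects(self) -> int:
        return sum(self.class_counts.values())


@dataclass
class GroundTruthObject:
    """One simulated object with its true mask.

    ``mask_indices`` stores the in-frame pixel coordinates as a
    ``(rows, cols)`` pair of integer arrays (full-frame boolean masks would
    be wasteful at clinical densities).
    """

    id: int
    object_class: str
    frame_index: int
    center: tuple[float, float]
    mask_indices: tuple[np.ndarray, np.ndarray]
    base_intensity: dict[str, float]

    @property
    def area_px(self) -> int:
        return int(self.mask_indices[0].size)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.mask_indices] = True
        return out


@dataclass
class SampleArchive:
    """A simulated cartridge: frames plus ground truth plus metadata."""

    spec: CartridgeSpec
    frames: list[ChannelStack]
    truth: list[GroundTruthObject]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != self.spec.n_frames:
            raise ValueError("frame count must equal spec.n_frames")
        for obj in self.truth:
            if not (0 <= obj.frame_index < self.spec.n_frames):
                raise ValueError("truth object frame_index out of range")

    def truth_in_frame(self, frame_index: int) -> list[GroundTruthObject]:
        return [t for t in self.truth if t.frame_index == frame_index]


def square_area_px(side_um: float, pixel_pitch_um: float) -> int:
    """Pixel area of a square region with the given physical side length.

    The instrument convention ties segmentation sizes to physical scales:
    a 32 um square is 2500 px at the default pitch, and the 70 um square
    where thumbnail review degrades is 11,881 px.
    """
    if side_um <= 0 or pixel_pitch_um <= 0:
        raise ValueError("lengths must be positive")
    side_px = round(side_um / pixel_pitch_um)
    return int(side_px) ** 2


def carryover_multiplier(days_to_prep: int, sample_kind: str = "blood") -> float:
    """Leukocyte-count multiplier for sample age (days between collection
    and preparation).

    Older samples carry over more leukocytes during immunomagnetic
    enrichment.  The blood multipliers are calibrated to reproduce the
    per-day median event counts of the clinical cohorts (13/28/37/54
    thousand for 1/2/3/4+ days); the DLA effect is much milder
    (108/136/138/156 thousand).  This is a calibration, not a mechanistic
    model.
    """
    day = min(max(int(days_to_prep), 1), 4)
    table = {
        "blood": {1: 1.0, 2: 28 / 13, 3: 37 / 13, 4: 54 / 13},
        "dla": {1: 1.0, 2: 136 / 108, 3: 138 / 108, 4: 156 / 108},
    }
    if sample_kind not in table:
        raise ValueError("sample_kind must be 'blood' or 'dla'")
    return table[sample_kind][day]


# ---------------------------------------------------------------------------
# Shape synthesis


def _random_blob_polygon(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    n_rays: int = 32,
    roughness: float = 0.18,
) -> StarPolygon:
    """Star-convex blob: radius modulated by smoothed circular noise."""
    noise = rng.normal(0.0, 1.0, n_rays)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(noise, 3), kernel, mode="same")[n_rays : 2 * n_rays]
    dists = radius * np.clip(1.0 + roughness * smooth, 0.5, 1.6)
    return StarPolygon(center=center, distances=dists)


def _blob_mask(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    shape: tuple[int, int],
    dumbbell: bool = False,
) -> np.ndarray:
    """Binary mask of a blob; dumbbells are two fused, offset lobes."""
    if not dumbbell:
        return polygon_to_mask(_random_blob_polygon(rng, center, radius), shape)
    ang = rng.uniform(0.0, 2.0 * np.pi)
    off = 0.7 * radius
    lobe_r = 0.75 * radius
    c1 = (center[0] + off * np.sin(ang), center[1] + off * np.cos(ang))
    c2 = (center[0] - off * np.sin(ang), center[1] - off * np.cos(ang))
    m1 = polygon_to_mask(_random_blob_polygon(rng, c1, lobe_r), shape)
    m2 = polygon_to_mask(_random_blob_polygon(rng, c2, lobe_r), shape)
    return m1 | m2


def _nucleus_mask(
    rng: np.random.Generator,
    cell_mask: np.ndarray,
    center: tuple[float, float],
    radius: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Nucleus rendered inside the cytoplasm: a smaller concentric blob."""
    nuc = polygon_to_mask(_random_blob_polygon(rng, center, 0.65 * radius), shape)
    nuc &= cell_mask
    if not nuc.any():  # degenerate tiny cell: nucleus fills the cell
        nuc = cell_mask.copy()
    return nuc


# ---------------------------------------------------------------------------
# Placement and rendering


def _place_objects_in_frame(
    rng: np.random.Generator,
    classes: list[str],
    spec: CartridgeSpec,
    cfg: SimConfig,
) -> list[dict]:
    """Choose a center, radius and shape for each object of one frame.

    With probability ``clump_fraction`` a center is drawn within 1.2
    diameters of an already placed object (touching clumps); otherwise
    centers are uniform, rejecting centers that land inside an existing
    object (cheap occupancy test) so objects touch rather than coincide.
    """
    h, w = spec.frame_shape
    occupied = np.zeros((h, w), dtype=bool)
    placed: list[dict] = []
    est_area = 0.0
    for cls in classes:
        est_area += np.pi * np.mean(_RADIUS_PX[cls]) ** 2
    if est_area > 0.9 * spec.frame_area_px:
        raise PlacementError(
            f"requested density covers {est_area / spec.frame_area_px:.0%} "
            "of the frame (limit 90%)"
        )
    for cls in classes:
        radius = rng.uniform(*_RADIUS_PX[cls])
        dumbbell = cls == "tumor" and rng.random() < cfg.nonstarconvex_fraction
        clump = bool(placed) and rng.random() < cfg.clump_fraction
        center = None
        for _ in range(200):
            if clump:
                anchor = placed[rng.integers(len(placed))]
                dist = rng.uniform(0.9, 1.2) * (radius + anchor["radius"])
                ang = rng.uniform(0.0, 2.0 * np.pi)
                r = anchor["center"][0] + dist * np.sin(ang)
                c = anchor["center"][1] + dist * np.cos(ang)
            else:
                r = rng.uniform(radius, h - radius)
                c = rng.uniform(radius, w - radius)
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                continue
            if not occupied[ri, ci]:
                center = (r, c)
                break
        if center is None:
            raise PlacementError(
                f"could not place a {cls} after 200 tries "
                f"({len(placed)} objects already in frame)"
            )
        mask = _blob_mask(rng, center, radius, spec.frame_shape, dumbbell)
        if not mask.any():
            mask = np.zeros(spec.frame_shape, dtype=bool)
            mask[int(round(center[0])), int(round(center[1]))] = True
        occupied |= mask
        placed.append(
            {"cls": cls, "center": center, "radius": radius, "mask": mask}
        )
    return placed


def _vignette(spec: CartridgeSpec, cfg: SimConfig) -> np.ndarray:
    """Radial illumination falloff: 1 at frame center, 1-strength at the
    corners (quadratic profile)."""
    h, w = spec.frame_shape
    rr = (np.arange(h) - (h - 1) / 2.0)[:, None]
    cc = (np.arange(w) - (w - 1) / 2.0)[None, :]
    d2 = rr**2 + cc**2
    d2max = ((h - 1) / 2.0) ** 2 + ((w - 1) / 2.0) ** 2
    return 1.0 - cfg.vignetting_strength * d2 / d2max


def render_frame(
    objects: list[GroundTruthObject],
    spec: CartridgeSpec,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> ChannelStack:
    """Render one frame from ground-truth objects.

    Channels are co-registered by construction.  Object signal is scaled by
    the vignetting profile, PE bleeds into APC with coefficient
    ``pe_to_apc_crosstalk``, then background, Gaussian read noise and a
    signal-dependent (Poisson-like) term are added and the result is clipped
    to the bit depth.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = spec.frame_shape
    signal = {ch: np.zeros((h, w), dtype=float) for ch in ("dapi", "pe", "apc")}
    vign = _vignette(spec, cfg)
    for obj in objects:
        mask = obj.mask(spec.frame_shape)
        soft = ndi.gaussian_filter(mask.astype(float), 1.0)
        v = vign[int(round(obj.center[0])), int(round(obj.center[1]))]
        if obj.object_class == "tumor":
            # nucleus inside cytoplasm: DAPI confined to an inner blob
            nuc = _nucleus_mask(
                rng, mask, obj.center, max(obj.area_px / np.pi, 1.0) ** 0.5,
                spec.frame_shape,
            )
            soft_nuc = ndi.gaussian_filter(nuc.astype(float), 1.0)
            signal["dapi"] += obj.base_intensity["dapi"] * v * soft_nuc
            signal["pe"] += obj.base_intensity["pe"] * v * soft
        else:
            for ch in ("dapi", "pe", "apc"):
                if obj.base_intensity.get(ch, 0.0) > 0:
                    signal[ch] += obj.base_intensity[ch] * v * soft
    signal["apc"] = signal["apc"] + cfg.pe_to_apc_crosstalk * signal["pe"]

    data = np.zeros((len(CHANNELS), h, w), dtype=float)
    for i, ch in enumerate(CHANNELS):
        img = cfg.background_level + signal.get(ch, np.zeros((h, w)))
        if cfg.noise_sd > 0 or cfg.poisson_scale > 0:
            sd = cfg.noise_sd + cfg.poisson_scale * np.sqrt(np.maximum(img, 0.0))
            img = img + rng.normal(0.0, 1.0, (h, w)) * sd
        data[i] = img
    data = np.clip(np.rint(data), 0, spec.max_value).astype(np.uint16)
    return ChannelStack(data=data, bit_depth=spec.bit_depth)


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    """Counter-based per-frame stream: results never depend on the order in
    which frames are rendered."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(frame_index,))
    )


def generate_cartridge(spec: CartridgeSpec, cfg: SimConfig) -> SampleArchive:
    """Simulate a full cartridge.

    Deterministic given ``cfg.seed``; the number of truth objects equals the
    sum of the requested class counts whenever placement succeeds.

    Raises
    ------
    PlacementError
        If the requested density cannot be placed in some frame.
    """
    root = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    # Assign each object to a frame up front (uniform), then render each
    # frame from its own counter-based stream.
    assignment: dict[int, list[str]] = {i: [] for i in range(spec.n_frames)}
    for cls, count in cfg.class_counts.items():
        frames = root.integers(0, spec.n_frames, size=count)
        for f in frames:
            assignment[int(f)].append(cls)

    truth: list[GroundTruthObject] = []
    stacks: list[ChannelStack] = []
    next_id = 0
    for f in range(spec.n_frames):
        rng = _frame_rng(cfg.seed, f)
        classes = sorted(assignment[f])  # deterministic order within a frame
        placed = _place_objects_in_frame(rng, classes, spec, cfg)
        objs = []
        for p in placed:
            base = {}
            for ch in ("dapi", "pe", "apc"):
                median, sigma = cfg.intensity[p["cls"]].get(ch, (0.0, 0.0))
                if median > 0:
                    base[ch] = float(
                        median * np.exp(rng.normal(0.0, sigma))
                    )
                else:
                    base[ch] = 0.0
            rows, cols = np.nonzero(p["mask"])
            objs.append(
                GroundTruthObject(
                    id=next_id,
                    object_class=p["cls"],
                    frame_index=f,
                    center=p["center"],
                    mask_indices=(rows, cols),
                    base_intensity=base,
                )
            )
            next_id += 1
        stacks.append(render_frame(objs, spec, cfg, rng=rng))
        truth.extend(objs)
    return SampleArchive(spec=spec, frames=stacks, truth=truth)


def spike_in_series(
    wbc_counts: list[int],
    tumor_count: int,
    spec: CartridgeSpec,
    cfg: SimConfig,
) -> list[SampleArchive]:
    """Simulate the spike-in titration: a fixed number of tumor cells plus
    an increasing number of white blood cells per cartridge.

    One archive per WBC count; each archive's seed is derived
    deterministically from ``cfg.seed`` and the series index.
    """
    if tumor_count < 0 or any(n < 0 for n in wbc_counts):
        raise ValueError("counts must be >= 0")
    archives = []
    for i, n_wbc in enumerate(wbc_counts):
        child_seed = int(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1000 + i,))
            .generate_state(1)[0]
            % (2**31)
        )
        sub = replace(
            cfg, tumor_cells=tumor_count, leukocytes=int(n_wbc), seed=child_seed
        )
        arch = generate_cartridge(spec, sub)
        arch.metadata["wbc_count"] = int(n_wbc)
        arch.metadata["tumor_count"] = int(tumor_count)
        archives.append(arch)
    return archives


def emulate_reference_segmentation(
    truth: list[GroundTruthObject],
    spec: CartridgeSpec,
    margin_px: int = 10,
    merge_overlapping: bool = False,
) -> list[tuple[int, int, int, int, int]]:
    """Rectangles mimicking the instrument's built-in segmentation.

    The reference draws an axis-aligned rectangle with a fixed pixel margin
    around every DAPI+/PE+ event (i.e. tumor-class objects).  Rectangles are
    half-open ``(frame, r0, c0, r1, c1)`` and clipped to the frame.  With
    ``merge_overlapping`` the dense-sample failure mode is emulated:
    overlapping rectangles in a frame are repeatedly replaced by their joint
    bounding rectangle until no overlaps remain.
    """
    h, w = spec.frame_shape
    rects: list[tuple[int, int, int, int, int]] = []
    for obj in truth:
        if obj.base_intensity.get("dapi", 0.0) <= 0 or obj.base_intensity.get(
            "pe", 0.0
        ) <= 0:
            continue
        rows, cols = obj.mask_indices
        r0 = max(int(rows.min()) - margin_px, 0)
        c0 = max(int(cols.min()) - margin_px, 0)
        r1 = min(int(rows.max()) + 1 + margin_px, h)
        c1 = min(int(cols.max()) + 1 + margin_px, w)
        rects.append((obj.frame_index, r0, c0, r1, c1))
    if not merge_overlapping:
        return rects
    merged: list[tuple[int, int, int, int, int]] = []
    by_frame: dict[int, list[list[int]]] = {}
    for f, r0, c0, r1, c1 in rects:
        by_frame.setdefault(f, []).append([r0, c0, r1, c1])
    for f, boxes in sorted(by_frame.items()):
        changed = True
        while changed:
            changed = False
            out: list[list[int]] = []
            for b in boxes:
                for o in out:
                    if b[0] < o[2] and o[0] < b[2] and b[1] < o[3] and o[1] < b[3]:
                        o[0] = min(o[0], b[0])
                        o[1] = min(o[1], b[1])
                        o[2] = max(o[2], b[2])
                        o[3] = max(o[3], b[3])
                        changed = True
                        break
                else:
                    out.append(list(b))
            boxes = out
        merged.extend((f, *b) for b in boxes)
    return merged


def truth_label_map(
    archive: SampleArchive, frame_index: int
) -> tuple[np.ndarray, list[int]]:
    """Rasterize a frame's ground truth to a label map (later objects
    overwrite earlier ones on the rare overlapping pixels); returns the map
    and the truth ids in label order (label k = ids[k-1])."""
    labels = np.zeros(archive.spec.frame_shape, dtype=np.int32)
    ids = []
    for k, obj in enumerate(archive.truth_in_frame(frame_index), start=1):
        labels[obj.mask_indices] = k
        ids.append(obj.id)
    return labels, ids
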