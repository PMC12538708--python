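"""Synthetic seed-scene generation.

Emulates a single-layer spread of imported soybeans mixed with quarantine
weed seeds (*Ambrosia trifida*, *Ambrosia artemisiifolia*) on a light
conveyor belt, imaged from above. Three pieces:

* :func:`sample_layout` — draw seed centres from a spatial point process
  (homogeneous Poisson, hard-core inhibition, or Thomas clusters) so
  layouts span the real device's range from clumped/occluded to evenly
  singulated;
* :func:`render_scene` — rasterise a layout to an RGB frame plus an
  exact ground-truth mask and per-class counts (seeds are filled rotated
  ellipses with Gaussian colour jitter);
* :func:`simulate_detections` — a stochastic stand-in for an object
  detector, with per-class recall, a confusion matrix and Poisson false
  positives.

Default geometry: a 384 x 216 mm virtual field at 10 px/mm, i.e. the
3840 x 2160 px frames the uniformity grid assumes. All randomness stems
from a single scene seed; placement, colour jitter and detection use
deterministic sub-streams of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as _draw_ellipse

from .segmentation import BinaryMask

__all__ = [
    "SeedSpec",
    "LayoutScene",
    "ProcessParams",
    "BackgroundModel",
    "DetectorModel",
    "DEFAULT_PALETTE",
    "DEFAULT_BACKGROUND",
    "sample_layout",
    "render_scene",
    "simulate_detections",
]

SOYBEAN = "soybean"
A_TRIFIDA = "a_trifida"
A_ARTEMISIIFOLIA = "a_artemisiifolia"

# sub-stream indices of the per-scene SeedSequence
_STREAM_PLACEMENT, _STREAM_COLOR, _STREAM_DETECT = 0, 1, 2


@dataclass(frozen=True)
class SeedSpec:
    """One seed class: mean caliper dimensions (mm) and render colour."""

    class_label: str
    length_mm: float
    width_mm: float
    color_mean: tuple[int, int, int]
    color_sd: float = 6.0

    def __post_init__(self):
        if not self.length_mm >= self.width_mm > 0:
            raise ValueError(f"{self.class_label}: need length_mm >= width_mm > 0")
        if self.color_sd < 0:
            raise ValueError("color_sd must be nonnegative")


#: Mean caliper dimensions of the three seed classes; colours are chosen
#: for clean HSV separation from the near-white belt, not photometric
#: realism.
DEFAULT_PALETTE = (
    SeedSpec(SOYBEAN, 7.65, 6.52, (218, 180, 90)),
    SeedSpec(A_TRIFIDA, 7.57, 4.57, (150, 110, 60)),
    SeedSpec(A_ARTEMISIIFOLIA, 3.22, 2.84, (92, 66, 40)),
)


@dataclass(frozen=True)
class BackgroundModel:
    """Belt background: near-white base, optional diamond weave texture."""

    color: tuple[int, int, int] = (246, 244, 240)
    noise_sd: float = 1.5
    diamond: bool = False
    diamond_period_mm: float = 8.0
    diamond_contrast: int = 6


DEFAULT_BACKGROUND = BackgroundModel()


@dataclass(frozen=True)
class ProcessParams:
    """Spatial point-process configuration for seed placement.

    ``process`` is one of ``poisson`` (complete spatial randomness),
    ``hardcore`` (minimum pairwise centre distance — idealised
    singulation), or ``thomas`` (Poisson cluster process — adhesion and
    clumping). ``mix_counts`` fixes exact per-class counts; otherwise the
    total count is Poisson(intensity_per_mm2 * area) and classes are
    drawn uniformly from the palette.
    """

    process: str = "poisson"
    intensity_per_mm2: float = 0.0
    hardcore_radius_mm: float = 0.0
    cluster_parent_intensity: float = 0.0
    cluster_mean_children: float = 0.0
    cluster_sd_mm: float = 0.0
    mix_counts: dict[str, int] | None = None

    def __post_init__(self):
        if self.process not in ("poisson", "hardcore", "thomas"):
            raise ValueError(f"unknown process {self.process!r}")
        if (self.process == "hardcore") != (self.hardcore_radius_mm > 0):
            raise ValueError("hardcore_radius_mm must be > 0 iff process == 'hardcore'")
        if self.process != "thomas" and (
            self.cluster_parent_intensity or self.cluster_mean_children or self.cluster_sd_mm
        ):
            raise ValueError("cluster_* fields are only valid for the thomas process")


@dataclass(frozen=True)
class LayoutScene:
    """Ground-truth seed placements on the virtual belt.

    ``placements`` rows are ``(class_label, (cx_mm, cy_mm),
    (length_mm, width_mm), orientation_rad)`` with x rightward, y
    downward from the top-left belt corner. Reproducible bit-identically
    from (parameters, rng_seed).
    """

    belt_width_mm: float
    belt_height_mm: float
    px_per_mm: float
    placements: tuple
    rng_seed: int

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label, *_ in self.placements:
            out[label] = out.get(label, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.placements)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "class": label,
                    "x_mm": xy[0],
                    "y_mm": xy[1],
                    "len_mm": axes[0],
                    "wid_mm": axes[1],
                    "theta_rad": theta,
                }
                for label, xy, axes, theta in self.placements
            ],
            columns=["class", "x_mm", "y_mm", "len_mm", "wid_mm", "theta_rad"],
        ).to_csv(path, index=False)

    def counts_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counts(), indent=2) + "\n")


@dataclass(frozen=True)
class DetectorModel:
    """Stochastic detector: per-class recall, confusion rows, Poisson FPs."""

    recall: dict[str, float]
    fp_rate_per_image: float = 0.0
    confusion: dict[str, dict[str, float]] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        for label, r in self.recall.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"recall[{label!r}] outside [0, 1]")
        if self.confusion is not None:
            for label, row in self.confusion.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row for {label!r} does not sum to 1")


def _stream(seed: int, idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


def _interior(belt_w: float, belt_h: float, inset: float) -> tuple[float, float, float, float]:
    x0, y0 = inset, inset
    x1, y1 = belt_w - inset, belt_h - inset
    if x1 <= x0 or y1 <= y0:
        raise ValueError("belt too small for the requested seed size inset")
    return x0, y0, x1, y1


def _sample_uniform(rng, n, box):
    x0, y0, x1, y1 = box
    xs = rng.uniform(x0, x1, n)
    ys = rng.uniform(y0, y1, n)
    return np.column_stack([xs, ys])


def _sample_hardcore(rng, n, box, radius, max_attempts):
    """Grid-accelerated dart throwing with a minimum centre distance."""
    x0, y0, x1, y1 = box
    cell = radius / np.sqrt(2.0)
    nx = max(1, int(np.ceil((x1 - x0) / cell)))
    ny = max(1, int(np.ceil((y1 - y0) / cell)))
    grid: dict[tuple[int, int], int] = {}
    pts = np.empty((n, 2))
    placed = 0
    r2 = radius * radius
    for _ in range(max_attempts):
        if placed == n:
            break
        px = rng.uniform(x0, x1)
        py = rng.uniform(y0, y1)
        gx = int((px - x0) / cell)
        gy = int((py - y0) / cell)
        ok = True
        for ix in range(gx - 2, gx + 3):
            for iy in range(gy - 2, gy + 3):
                j = grid.get((ix, iy))
                if j is not None:
                    dx = pts[j, 0] - px
                    dy = pts[j, 1] - py
                    if dx * dx + dy * dy < r2:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            pts[placed] = (px, py)
            grid[(gx, gy)] = placed
            placed += 1
    if placed < n:
        raise RuntimeError(
            f"hard-core packing infeasible: placed {placed}/{n} seeds at "
            f"radius {radius} mm after {max_attempts} attempts"
        )
    return pts


def _sample_thomas(rng, n, box, params: ProcessParams):
    x0, y0, x1, y1 = box
    area = (x1 - x0) * (y1 - y0)
    n_parents = rng.poisson(max(params.cluster_parent_intensity, 0.0) * area)
    n_parents = max(int(n_parents), 1)
    parents = _sample_uniform(rng, n_parents, box)
    sd = params.cluster_sd_mm
    pts = np.empty((n, 2))
    placed = 0
    while placed < n:
        parent = parents[rng.integers(n_parents)]
        p = parent + rng.normal(0.0, sd, 2)
        if x0 <= p[0] <= x1 and y0 <= p[1] <= y1:
            pts[placed] = p
            placed += 1
    return pts


def sample_layout(
    params: ProcessParams,
    specs=DEFAULT_PALETTE,
    seed: int = 0,
    belt_width_mm: float = 384.0,
    belt_height_mm: float = 216.0,
    px_per_mm: float = 10.0,
    allow_edge_clip: bool = False,
    max_attempts_per_seed: int = 500,
) -> LayoutScene:
    """Draw a seed layout from the configured point process.

    By default centres are sampled in the belt interior inset by the
    largest semi-major axis so no seed is clipped at the frame edge;
    ``allow_edge_clip=True`` samples over the full belt instead. For the
    hard-core process a bounded dart-throwing budget
    (``max_attempts_per_seed`` per requested seed) guards against
    infeasible packings: failure raises rather than silently placing
    fewer seeds.
    """
    if belt_width_mm <= 0 or belt_height_mm <= 0 or px_per_mm <= 0:
        raise ValueError("belt dimensions and px_per_mm must be positive")
    specs = tuple(specs)
    labels = [s.class_label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in palette")
    rng = _stream(seed, _STREAM_PLACEMENT)

    inset = 0.0 if allow_edge_clip else max(s.length_mm for s in specs) / 2.0
    box = _interior(belt_width_mm, belt_height_mm, inset)
    area = (box[2] - box[0]) * (box[3] - box[1])

    if params.mix_counts is not None:
        unknown = set(params.mix_counts) - set(labels)
        if unknown:
            raise ValueError(f"mix_counts classes not in palette: {sorted(unknown)}")
        class_list = [
            label for label, k in params.mix_counts.items() for _ in range(int(k))
        ]
    else:
        total = int(rng.poisson(params.intensity_per_mm2 * area))
        class_list = [labels[i] for i in rng.integers(len(labels), size=total)]
    n = len(class_list)

    if n == 0:
        return LayoutScene(belt_width_mm, belt_height_mm, px_per_mm, (), seed)

    if params.process == "poisson":
        pts = _sample_uniform(rng, n, box)
    elif params.process == "hardcore":
        pts = _sample_hardcore(
            rng, n, box, params.hardcore_radius_mm, max_attempts_per_seed * n
        )
    else:
        pts = _sample_thomas(rng, n, box, params)

    # shuffle class labels over positions so weed seeds share the pattern
    order = rng.permutation(n)
    thetas = rng.uniform(0.0, np.pi, n)
    by_label = {s.class_label: s for s in specs}
    placements = tuple(
        (
            class_list[order[i]],
            (float(pts[i, 0]), float(pts[i, 1])),
            (by_label[class_list[order[i]]].length_mm, by_label[class_list[order[i]]].width_mm),
            float(thetas[i]),
        )
        for i in range(n)
    )
    return LayoutScene(belt_width_mm, belt_height_mm, px_per_mm, placements, seed)


def render_scene(
    layout: LayoutScene,
    palette=DEFAULT_PALETTE,
    background: BackgroundModel = DEFAULT_BACKGROUND,
) -> tuple[np.ndarray, BinaryMask, dict[str, int]]:
    """Rasterise a layout to (RGB uint8 image, ground-truth mask, counts).

    Each seed is a filled rotated ellipse (semi-axes = length/2, width/2
    in px) with iid Gaussian jitter per pixel around the class colour;
    the ground-truth mask is the union of ellipse footprints, so
    overlapping seeds occlude and reduce mask area, as on the device.
    """
    h = int(round(layout.belt_height_mm * layout.px_per_mm))
    w = int(round(layout.belt_width_mm * layout.px_per_mm))
    if h <= 0 or w <= 0:
        raise ValueError("raster would be empty: check px_per_mm and belt size")
    if h * w > 4096 * 4096:
        raise ValueError("raster exceeds the configured maximum size (4096x4096)")
    by_label = {s.class_label: s for s in palette}
    missing = {p[0] for p in layout.placements} - set(by_label)
    if missing:
        raise ValueError(f"palette missing classes present in layout: {sorted(missing)}")

    rng = _stream(layout.rng_seed, _STREAM_COLOR)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = background.color
    if background.diamond:
        period_px = max(2, int(round(background.diamond_period_mm * layout.px_per_mm)))
        yy, xx = np.mgrid[0:h, 0:w]
        weave = ((xx + yy) // (period_px // 2) + (xx - yy) // (period_px // 2)) % 2
        img += background.diamond_contrast * (weave[..., None] - 0.5)
    if background.noise_sd > 0:
        img += rng.normal(0.0, background.noise_sd, img.shape)

    mask = np.zeros((h, w), dtype=np.uint8)
    for label, (cx, cy), (length, width), theta in layout.placements:
        spec = by_label[label]
        rr, cc = _draw_ellipse(
            cy * layout.px_per_mm,
            cx * layout.px_per_mm,
            width / 2.0 * layout.px_per_mm,
            length / 2.0 * layout.px_per_mm,
            shape=(h, w),
            rotation=theta,
        )
        mask[rr, cc] = 1
        col = np.asarray(spec.color_mean, dtype=float)
        img[rr, cc] = col + rng.normal(0.0, spec.color_sd, (len(rr), 3))

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return image, BinaryMask(pixels=mask), layout.counts()


def layout_mask(layout: LayoutScene) -> BinaryMask:
    """Rasterise only the ground-truth mask (union of ellipse footprints).

    Identical to the mask returned by :func:`render_scene` but without
    the RGB pass — the fast path when scoring uniformity on ground truth.
    """
    h = int(round(layout.belt_height_mm * layout.px_per_mm))
    w = int(round(layout.belt_width_mm * layout.px_per_mm))
    mask = np.zeros((h, w), dtype=np.uint8)
    for _, (cx, cy), (length, width), theta in layout.placements:
        rr, cc = _draw_ellipse(
            cy * layout.px_per_mm,
            cx * layout.px_per_mm,
            width / 2.0 * layout.px_per_mm,
            length / 2.0 * layout.px_per_mm,
            shape=(h, w),
            rotation=theta,
        )
        mask[rr, cc] = 1
    return BinaryMask(pixels=mask)


def save_scene(
    image: np.ndarray, mask: BinaryMask, layout: LayoutScene, out_dir: str | Path, stem: str
) -> None:
    """Write image/mask PNGs plus ground-truth CSV and count JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image, mode="RGB").save(out / f"{stem}.png")
    mask.to_png(out / f"{stem}_mask.png")
    layout.to_csv(out / f"{stem}_truth.csv")
    layout.counts_json(out / f"{stem}_counts.json")


def simulate_detections(
    layout: LayoutScene, det: DetectorModel, seed: int | None = None
) -> dict[str, int]:
    """Simulate per-class detected counts for a layout.

    Each true seed is detected independently with probability
    ``recall[class]``, then relabelled by its confusion row; false
    positives are added as Poisson(``fp_rate_per_image``) with labels
    uniform over the detector's classes. ``seed`` overrides the
    detector's own ``rng_seed`` (useful for replicate draws).
    """
    classes_in_layout = {p[0] for p in layout.placements}
    missing = classes_in_layout - set(det.recall)
    if missing:
        raise ValueError(f"detector recall undefined for classes: {sorted(missing)}")
    rng = _stream(det.rng_seed if seed is None else seed, _STREAM_DETECT)
    det_classes = sorted(det.recall)
    counts: dict[str, int] = {c: 0 for c in det_classes}
    for label, *_ in layout.placements:
        if rng.random() >= det.recall[label]:
            continue
        if det.confusion is not None and label in det.confusion:
            row = det.confusion[label]
            keys = sorted(row)
            probs = np.array([row[k] for k in keys])
            pred = keys[rng.choice(len(keys), p=probs / probs.sum())]
        else:
            pred = label
        counts[pred] = counts.get(pred, 0) + 1
    n_fp = int(rng.poisson(det.fp_rate_per_image))
    for _ in range(n_fp):
        counts[det_classes[rng.integers(len(det_classes))]] += 1
    return counts
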