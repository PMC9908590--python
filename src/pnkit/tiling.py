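"""Slide-to-patch pipeline.

Slides plus decision-layer annotations become labeled 256x256 patches:

* Otsu thresholding on a smoothed grayscale separates tissue (dark, light-
  absorbing) from background (bright glass).
* Macenko stain normalization maps every slide into a reference H&E color
  space: pixel intensities are converted to optical density (OD), the two
  stain directions are the extreme-percentile angles within the top-2
  singular plane of the OD cloud, and concentrations are rescaled to a
  target model before recombination.
* The central-pixel rule labels a patch with the decision region containing
  its center; overlaps are resolved by a severity priority
  (adenocarcinoma > adenoma > normal).
* Train/test splits are made per whole slide so no slide leaks across, class
  targets are sampled without replacement, and test slides are tiled with a
  non-overlapping stride.

Coordinates are 0-based, origin top-left, x right / y down; a patch ``(i, j)``
covers the half-open box ``[i*stride, i*stride+size) x [j*stride,
j*stride+size)`` so patches at stride = size tile the plane exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateHistogramError,
    DegenerateStainsError,
    EmptyCohortError,
    InsufficientPatchesError,
    InsufficientTissueError,
    PnkitError,
)
from .schema import Region

DEFAULT_PRIORITY = ("c-adenocarcinoma", "c-adenoma", "c-normal")


@dataclass(frozen=True)
class PatchGridSpec:
    """Regular patch grid at the slide's reference magnification."""

    patch_size: int = 256
    stride: int | None = None  # defaults to patch_size (non-overlapping)
    magnification: float = 20.0

    @property
    def step(self) -> int:
        return self.patch_size if self.stride is None else self.stride

    def bounds(self, i: int, j: int) -> tuple[int, int, int, int]:
        x0, y0 = i * self.step, j * self.step
        return x0, y0, x0 + self.patch_size, y0 + self.patch_size

    def center(self, i: int, j: int) -> tuple[float, float]:
        x0, y0 = i * self.step, j * self.step
        return x0 + self.patch_size / 2, y0 + self.patch_size / 2


@dataclass
class PatchRecord:
    wsi_id: str
    i: int
    j: int
    x0: int
    y0: int
    label_class: str | None = None
    label_subtype: str | None = None
    tissue_frac: float = 0.0
    split: str = "none"
    seed: int = 0

    def as_row(self) -> dict:
        return {
            "wsi_id": self.wsi_id,
            "i": self.i,
            "j": self.j,
            "x0": self.x0,
            "y0": self.y0,
            "label_class": self.label_class or "",
            "label_subtype": self.label_subtype or "",
            "tissue_frac": self.tissue_frac,
            "split": self.split,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Otsu thresholding / tissue mask
# ---------------------------------------------------------------------------

def otsu_threshold(histogram: Sequence[int]) -> int:
    """Threshold index maximizing between-class variance.

    The split is bins ``<= t`` versus ``> t``; among equal maximizers the
    smallest ``t`` is returned.  A histogram with all mass in one bin has no
    valid split and raises :class:`DegenerateHistogramError`.
    """
    h = np.asarray(histogram, dtype=float)
    total = h.sum()
    if total <= 0:
        raise DegenerateHistogramError("histogram is empty")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("all mass in a single bin")
    bins = np.arange(h.size)
    w0 = np.cumsum(h)[:-1]                # mass of bins <= t, t = 0..n-2
    w1 = total - w0
    cum_mean = np.cumsum(h * bins)[:-1]
    grand_mean = (h * bins).sum()
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mean / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (grand_mean - cum_mean) / np.where(w1 > 0, w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b))


def tissue_mask(rgb: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Boolean foreground mask: pixels darker than the Otsu threshold.

    Tissue absorbs light, so foreground is the dark class of the smoothed
    luminance histogram.  A degenerate histogram (e.g., a blank slide) yields
    an all-background mask rather than an error.
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise PnkitError(f"expected HxWx3 RGB image, got shape {rgb.shape}")
    gray = (
        0.299 * rgb[:, :, 0].astype(float)
        + 0.587 * rgb[:, :, 1].astype(float)
        + 0.114 * rgb[:, :, 2].astype(float)
    )
    if smooth_sigma > 0:
        gray = ndimage.gaussian_filter(gray, sigma=smooth_sigma)
    gray_u8 = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    hist = np.bincount(gray_u8.ravel(), minlength=256)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return np.zeros(rgb.shape[:2], dtype=bool)
    return gray_u8 <= t


# ---------------------------------------------------------------------------
# Macenko stain normalization
# ---------------------------------------------------------------------------

@dataclass
class StainModel:
    """Two unit stain vectors (hematoxylin, eosin) in OD space plus the
    99th-percentile reference concentrations."""

    stain_matrix: np.ndarray        # (3, 2), columns H then E, unit norm
    max_concentrations: np.ndarray  # (2,)
    io_white: float = 255.0


def _optical_density(rgb: np.ndarray, io_white: float) -> np.ndarray:
    flat = rgb.reshape(-1, 3).astype(float)
    return -np.log10((flat + 1.0) / io_white)


def macenko_fit(
    rgb: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentile: float = 1.0,
    io_white: float = 255.0,
    min_pixels: int = 100,
) -> StainModel:
    """Estimate the H&E stain model of an image (Macenko method).

    OD vectors of non-background pixels are projected onto their top-2
    singular plane; the stain directions are the ``alpha`` and ``100-alpha``
    percentile angles of the projected cloud.  Hematoxylin is the vector
    with the larger blue-channel OD component.
    """
    od = _optical_density(rgb, io_white)
    keep = od.max(axis=1) >= od_threshold  # drop near-transparent pixels
    od = od[keep]
    if od.shape[0] < min_pixels:
        raise InsufficientTissueError(
            f"only {od.shape[0]} usable pixels (< {min_pixels})", n=od.shape[0]
        )
    # top-2 right-singular vectors of the OD cloud (plane of the two stains)
    _, _, vt = np.linalg.svd(od, full_matrices=False)
    basis = vt[:2].T  # (3, 2)
    # orient basis vectors toward positive OD so angles are well-defined
    for k in range(2):
        if basis[:, k].sum() < 0:
            basis[:, k] = -basis[:, k]
    proj = od @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angle_percentile)
    hi = np.percentile(phi, 100.0 - angle_percentile)
    if abs(hi - lo) < np.deg2rad(1.0):
        raise DegenerateStainsError(
            "percentile angles collapse; image appears single-stain",
            spread_deg=float(np.rad2deg(abs(hi - lo))),
        )
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    # hematoxylin absorbs more in the blue channel
    if v1[2] >= v2[2]:
        stains = np.column_stack([v1, v2])
    else:
        stains = np.column_stack([v2, v1])
    conc, *_ = np.linalg.lstsq(stains, od.T, rcond=None)
    conc = np.clip(conc, 0.0, None)
    max_c = np.percentile(conc, 99.0, axis=1)
    return StainModel(stain_matrix=stains, max_concentrations=max_c, io_white=io_white)


def macenko_normalize(
    rgb: np.ndarray, source: StainModel, target: StainModel, clip_negative: bool = False
) -> np.ndarray:
    """Map an image from its own stain model into the target's color space.

    Slightly negative concentrations (pixels in the angular tails beyond the
    percentile stain vectors) are kept by default so that normalizing an
    image to its own model is the identity up to quantization;
    ``clip_negative`` forces them to zero.
    """
    shape = rgb.shape
    od = _optical_density(rgb, source.io_white)
    conc, *_ = np.linalg.lstsq(source.stain_matrix, od.T, rcond=None)
    if clip_negative:
        conc = np.clip(conc, 0.0, None)
    scale = np.where(
        source.max_concentrations > 0,
        target.max_concentrations / np.where(source.max_concentrations > 0, source.max_concentrations, 1.0),
        1.0,
    )
    od_new = target.stain_matrix @ (conc * scale[:, None])
    out = target.io_white * np.power(10.0, -od_new.T) - 1.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8).reshape(shape)


# ---------------------------------------------------------------------------
# central-pixel labeling
# ---------------------------------------------------------------------------

def assign_patch_label(
    center: tuple[float, float],
    decision_regions: Sequence[Region],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple[str, str | None] | None:
    """Label of the decision region containing the center pixel.

    Boundary points count as inside (favors lesion recall).  Among several
    containing regions the highest-priority class wins; ties within a class
    go to the earliest region in document order.  Returns
    ``(class_label, subtype_label)`` or ``None`` when the center is in no
    region.
    """
    from shapely.geometry import Point, Polygon

    pt = Point(center)
    rank = {c: k for k, c in enumerate(priority)}
    best: tuple[int, int] | None = None
    best_region: Region | None = None
    for idx, r in enumerate(decision_regions):
        if r.layer != "decision":
            continue
        if Polygon(r.polygon).covers(pt):
            key = (rank.get(r.class_label, len(priority)), idx)
            if best is None or key < best:
                best = key
                best_region = r
    if best_region is None:
        return None
    return best_region.class_label, best_region.subtype_label


# ---------------------------------------------------------------------------
# splits, sampling, tiling
# ---------------------------------------------------------------------------

def split_by_wsi(
    wsi_ids: Sequence[str],
    test_fraction: float | None = None,
    test_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Slide-level train/test assignment (no slide in both splits)."""
    ids = list(wsi_ids)
    if len(set(ids)) != len(ids):
        raise PnkitError("wsi ids must be unique")
    if not ids:
        raise EmptyCohortError("empty cohort")
    if test_ids is not None:
        unknown = set(test_ids) - set(ids)
        if unknown:
            raise PnkitError(f"test ids not in cohort: {sorted(unknown)}")
        return {w: ("test" if w in set(test_ids) else "train") for w in ids}
    if test_fraction is None:
        raise PnkitError("provide test_fraction or test_ids")
    rng = np.random.default_rng(seed)
    order = sorted(ids)
    rng.shuffle(order)
    n_test = int(round(test_fraction * len(order)))
    test = set(order[:n_test])
    return {w: ("test" if w in test else "train") for w in ids}


def sample_training_patches(
    records: Iterable[PatchRecord],
    class_targets: Mapping[str, int],
    seed: int = 0,
    normal_class: str = "c-normal",
    normal_wsi_ids: set[str] | None = None,
) -> list[PatchRecord]:
    """Sample per-class patch counts from training slides, without replacement.

    ``normal_wsi_ids`` restricts the normal class to slides whose annotation
    contains no tumor region — normal-looking patches on tumor slides never
    enter as normal.  Pass ``None`` to disable the restriction.
    """
    pools: dict[str, list[PatchRecord]] = {c: [] for c in class_targets}
    for rec in records:
        if rec.split != "train" or rec.label_class not in pools:
            continue
        if (
            rec.label_class == normal_class
            and normal_wsi_ids is not None
            and rec.wsi_id not in normal_wsi_ids
        ):
            continue
        pools[rec.label_class].append(rec)
    out: list[PatchRecord] = []
    rng = np.random.default_rng(seed)
    for cls in sorted(class_targets):
        target = class_targets[cls]
        pool = sorted(pools[cls], key=lambda r: (r.wsi_id, r.j, r.i))
        if target > len(pool):
            raise InsufficientPatchesError(
                f"class {cls!r}: requested {target}, only {len(pool)} available",
                label=cls,
                available=len(pool),
            )
        idx = rng.choice(len(pool), size=target, replace=False)
        chosen = [pool[k] for k in sorted(idx)]
        for rec in chosen:
            rec.seed = seed
        out.extend(chosen)
    return out


def label_grid_patches(
    wsi_id: str,
    image_size: tuple[int, int],
    regions: Sequence[Region],
    grid: PatchGridSpec = PatchGridSpec(),
    mask: np.ndarray | None = None,
    tissue_threshold: float = 0.5,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[PatchRecord]:
    """Enumerate grid patches fully inside the image and label their centers.

    Patches below ``tissue_threshold`` foreground fraction are skipped when a
    mask is given.  ``image_size`` is (width, height).
    """
    w, h = image_size
    step, ps = grid.step, grid.patch_size
    decision = [r for r in regions if r.layer == "decision"]
    out = []
    for j in range((h - ps) // step + 1 if h >= ps else 0):
        for i in range((w - ps) // step + 1 if w >= ps else 0):
            x0, y0, x1, y1 = grid.bounds(i, j)
            frac = 1.0
            if mask is not None:
                frac = float(mask[y0:y1, x0:x1].mean())
                if frac < tissue_threshold:
                    continue
            label = assign_patch_label(grid.center(i, j), decision, priority)
            rec = PatchRecord(wsi_id=wsi_id, i=i, j=j, x0=x0, y0=y0, tissue_frac=frac)
            if label is not None:
                rec.label_class, rec.label_subtype = label
            out.append(rec)
    return out


def tile_test_wsi(
    wsi_id: str,
    image_size: tuple[int, int],
    mask: np.ndarray,
    grid: PatchGridSpec = PatchGridSpec(),
    tissue_threshold: float = 0.5,
    regions: Sequence[Region] = (),
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> list[PatchRecord]:
    """Non-overlapping tiling of a test slide (stride must equal patch size)."""
    if grid.step != grid.patch_size:
        raise PnkitError("test tiling requires stride == patch_size")
    recs = label_grid_patches(
        wsi_id, image_size, regions, grid, mask, tissue_threshold, priority
    )
    for r in recs:
        r.split = "test"
    return recs
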