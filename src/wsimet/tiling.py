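"""Slide tiling with tissue/tumor validity rules and input-sampling modes.

A slide image is cut into a non-overlapping grid of square tiles from the
origin (partial edge tiles are discarded). A tile is *valid* when more than
50% of its pixels are tissue under a combined binary + Otsu threshold, and
a *tumor* tile when more than 50% of its pixels fall inside the annotation
mask; tumor tiles inherit the slide's cohort label. Three input-sampling
modes are provided: every tumor tile (single-tile), tiles at the invasive
front (annotation boundary), and disjoint random stacks of n tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "TileRecord",
    "TileStack",
    "compute_tissue_mask",
    "extract_tiles",
    "select_invasive_front",
    "make_tile_stacks",
    "BINARY_BACKGROUND_THRESHOLD",
    "RESIZE_PX",
]

# Fixed background cutoff on the 0-255 grayscale: pixels at least this
# bright are never tissue, whatever Otsu decides.
BINARY_BACKGROUND_THRESHOLD = 220.0
RESIZE_PX = 299  # classifier input side length

_GRAY_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])  # ITU-R 709 luminance


@dataclass(frozen=True)
class TileRecord:
    """One grid tile of a slide with its validity/tumor fractions and label."""

    slide_id: str
    patient_id: str
    row: int
    col: int
    pixel_box: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)
    tissue_fraction: float
    tumor_fraction: float
    is_valid: bool
    is_tumor: bool
    label: str | None = None
    scan_batch: str = "A"


@dataclass(frozen=True)
class TileStack:
    """Disjoint random sample of n tumor tiles from one slide."""

    stack_id: str
    tiles: tuple[TileRecord, ...]
    label: str | None

    def __post_init__(self) -> None:
        if len({t.slide_id for t in self.tiles}) > 1:
            raise ValueError("all stack members must come from one slide")


def compute_tissue_mask(rgb_image: np.ndarray) -> np.ndarray:
    """Tissue mask from combined binary and Otsu thresholding.

    A pixel is tissue iff its grayscale intensity is below *both* the fixed
    background cutoff and the per-image Otsu split, which keeps near-white
    scanner background out even when Otsu degenerates on almost-empty
    slides. On a constant image Otsu is undefined and the fixed cutoff
    alone is used.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    gray = img.astype(np.float64) @ _GRAY_WEIGHTS
    if gray.min() == gray.max():
        # Otsu is undefined on a constant image; fixed cutoff alone
        otsu = np.inf
    else:
        otsu = float(threshold_otsu(gray))
    return gray < min(BINARY_BACKGROUND_THRESHOLD, otsu)


def _resize_tile(tile: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an 8-bit RGB tile to size x size."""
    return np.asarray(
        Image.fromarray(tile).resize((size, size), Image.BILINEAR))


def extract_tiles(rgb_image: np.ndarray, annotation_mask: np.ndarray,
                  tile_px: int = 512, *, slide_id: str = "slide",
                  patient_id: str = "patient", label: str | None = None,
                  scan_batch: str = "A", images_for: str = "tumor",
                  resize_px: int = RESIZE_PX,
                  ) -> tuple[list[TileRecord], dict[tuple[int, int], np.ndarray]]:
    """Cut a slide into labeled grid tiles.

    Returns all full grid tiles as records (partial edge tiles discarded)
    plus resized ``resize_px``-square tile images keyed by (row, col):
    for the valid tumor tiles (``images_for='tumor'``, the training set),
    for every valid tile (``'valid'``, needed by the outside invasive-front
    mode) or none (``'none'``). Validity uses a strict majority (> 0.5) of
    tissue pixels, tumor status a strict majority of annotated pixels.
    """
    if images_for not in {"tumor", "valid", "none"}:
        raise ValueError("images_for must be 'tumor', 'valid' or 'none'")
    img = np.asarray(rgb_image)
    mask = np.asarray(annotation_mask).astype(bool)
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"image {img.shape[:2]} and mask {mask.shape} shapes differ")
    if tile_px < 1:
        raise ValueError("tile_px must be positive")
    tissue = compute_tissue_mask(img)
    n_rows, n_cols = img.shape[0] // tile_px, img.shape[1] // tile_px
    area = float(tile_px * tile_px)
    records: list[TileRecord] = []
    images: dict[tuple[int, int], np.ndarray] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_px, c * tile_px
            sl = (slice(y0, y0 + tile_px), slice(x0, x0 + tile_px))
            tissue_frac = float(tissue[sl].sum()) / area
            tumor_frac = float(mask[sl].sum()) / area
            is_valid = tissue_frac > 0.5
            is_tumor = tumor_frac > 0.5
            records.append(TileRecord(
                slide_id=slide_id, patient_id=patient_id, row=r, col=c,
                pixel_box=(x0, y0, x0 + tile_px, y0 + tile_px),
                tissue_fraction=tissue_frac, tumor_fraction=tumor_frac,
                is_valid=is_valid, is_tumor=is_tumor,
                label=label, scan_batch=scan_batch))
            want = (images_for == "valid" and is_valid) or (
                images_for == "tumor" and is_valid and is_tumor)
            if want:
                images[(r, c)] = _resize_tile(img[sl], resize_px)
    return records, images


def select_invasive_front(tiles: list[TileRecord], side: str = "both",
                          ) -> list[TileRecord]:
    """Tiles at the annotation boundary of one slide.

    The boundary is defined at tile resolution: a tumor tile is on the
    inside front when any of its 4-neighbors in the grid is a non-tumor
    tile, and a non-tumor tile is on the outside front when any 4-neighbor
    is a tumor tile. ``side`` selects ``inside``, ``outside`` or ``both``
    (their union). An annotation covering the whole grid has no boundary.
    """
    if side not in {"inside", "outside", "both"}:
        raise ValueError("side must be 'inside', 'outside' or 'both'")
    if len({t.slide_id for t in tiles}) > 1:
        raise ValueError("tiles must come from a single slide")
    tumor_at = {(t.row, t.col): t.is_tumor for t in tiles}
    selected = []
    for t in tiles:
        neighbors = [(t.row - 1, t.col), (t.row + 1, t.col),
                     (t.row, t.col - 1), (t.row, t.col + 1)]
        adjacent_other = any(
            n in tumor_at and tumor_at[n] != t.is_tumor for n in neighbors)
        if not adjacent_other:
            continue
        if side == "both" or (side == "inside") == t.is_tumor:
            selected.append(t)
    return selected


def make_tile_stacks(tiles: list[TileRecord], n: int, seed: int = 0,
                     ) -> list[TileStack]:
    """Random partition of each slide's valid tumor tiles into stacks of n.

    Tiles never repeat across stacks; per slide, leftover tiles that cannot
    fill a stack are dropped, so the stack count is sum over slides of
    floor(T_s / n). Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("stack size must be >= 1")
    rng = np.random.default_rng(seed)
    by_slide: dict[str, list[TileRecord]] = {}
    for t in tiles:
        if t.is_valid and t.is_tumor:
            by_slide.setdefault(t.slide_id, []).append(t)
    stacks: list[TileStack] = []
    for slide_id in sorted(by_slide):
        pool = sorted(by_slide[slide_id], key=lambda t: (t.row, t.col))
        order = rng.permutation(len(pool))
        for i in range(len(pool) // n):
            members = tuple(pool[j] for j in order[i * n:(i + 1) * n])
            stacks.append(TileStack(
                stack_id=f"{slide_id}:stack{i}", tiles=members,
                label=members[0].label))
    if not stacks:
        warnings.warn(
            f"stack size n={n} exceeds the tumor tile count of every slide; "
            "no stacks produced", stacklevel=2)
    return stacks
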