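"""Tile-score aggregation: shifted score grids, spatial median smoothing,
slide-level decisions, ROC summaries and probability-map rendering.

Out-of-fold tile probabilities p in [0,1] are rescaled to scores
s = 100*p - 50 in [-50, 50], arranged on the slide's tile grid, spatially
smoothed with a forward 2x2 median window, and averaged into a slide-level
score; a slide is called metastatic when its mean score exceeds the
decision threshold 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ScoreGrid",
    "SlideDecision",
    "shift_scale",
    "inverse_shift_scale",
    "score_grid_from_tiles",
    "median_smooth",
    "slide_score",
    "roc_curve",
    "confusion_summary",
    "render_probability_map",
]


@dataclass
class ScoreGrid:
    """2-D lattice of shifted tile scores with a validity mask.

    ``scores[r, c]`` is meaningful only where ``valid[r, c]``; invalid cells
    (non-tumor or low-tissue tiles) carry no score and are rendered white.
    """

    slide_id: str
    scores: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.scores.shape != self.valid.shape or self.scores.ndim != 2:
            raise ValueError("scores and valid must be aligned 2-D arrays")
        if self.valid.any() and np.max(np.abs(self.scores[self.valid])) > 50 + 1e-9:
            raise ValueError("valid scores must lie in [-50, 50]")


@dataclass(frozen=True)
class SlideDecision:
    slide_id: str
    mean_score: float
    predicted_label: str  # "met" | "non_met"
    true_label: str | None = None


def shift_scale(p) -> np.ndarray | float:
    """Map probability p in [0,1] to the shifted score 100*p - 50 in [-50,50]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out = 100.0 * arr - 50.0
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_shift_scale(s) -> np.ndarray | float:
    """Inverse of :func:`shift_scale`: (s + 50) / 100."""
    arr = np.asarray(s, dtype=float)
    out = (arr + 50.0) / 100.0
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


def score_grid_from_tiles(slide_id: str, records: Iterable, probabilities,
                          n_rows: int | None = None,
                          n_cols: int | None = None) -> ScoreGrid:
    """Arrange per-tile probabilities on the slide's tile grid.

    ``records`` are TileRecords of one slide aligned with ``probabilities``;
    cells become valid where the record is a valid tile carrying a finite
    probability (NaN marks unscored tiles), so the grid reflects exactly
    the scored subset — all tumor tiles in the default mode, the invasive
    front in the front modes.
    """
    records = list(records)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(records) != probabilities.size:
        raise ValueError("records and probabilities must be aligned")
    if n_rows is None:
        n_rows = max(t.row for t in records) + 1
    if n_cols is None:
        n_cols = max(t.col for t in records) + 1
    scores = np.zeros((n_rows, n_cols), dtype=float)
    valid = np.zeros((n_rows, n_cols), dtype=bool)
    for rec, p in zip(records, probabilities):
        if rec.is_valid and np.isfinite(p):
            scores[rec.row, rec.col] = shift_scale(float(p))
            valid[rec.row, rec.col] = True
    return ScoreGrid(slide_id, scores, valid)


def median_smooth(grid: ScoreGrid, window: int = 2) -> ScoreGrid:
    """Spatial median filter over the tile grid with a forward window.

    For each valid cell (r, c) the window covers rows [r, r+window) x cols
    [c, c+window), clipped at the grid border, and the cell value is
    replaced by the median of the *valid* scores inside the window (an even
    count of values yields the mean of the two central order statistics).
    Cells whose window holds no valid score, and invalid cells, are left
    unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    scores, valid = grid.scores, grid.valid
    out = scores.copy()
    n_rows, n_cols = scores.shape
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            rs, cs = slice(r, min(r + window, n_rows)), slice(c, min(c + window, n_cols))
            vals = scores[rs, cs][valid[rs, cs]]
            if vals.size:
                out[r, c] = np.median(vals)
    return ScoreGrid(grid.slide_id, out, valid.copy())


def slide_score(grid: ScoreGrid, true_label: str | None = None,
                vote: str = "mean", threshold: float = 0.0) -> SlideDecision:
    """Slide-level decision from a (smoothed) score grid.

    ``vote='mean'`` (default): the slide score is the arithmetic mean of the
    valid tile scores and the label is the strict sign of the mean against
    the threshold — the operational form of the slide-level majority vote.
    ``vote='count'``: literal tile-count majority (metastatic iff strictly
    more valid tiles above the threshold than not). Ties are called
    non-metastatic in both rules.
    """
    if not grid.valid.any():
        raise ValueError(f"slide {grid.slide_id}: no valid tiles to score")
    vals = grid.scores[grid.valid]
    mean = float(vals.mean())
    if vote == "mean":
        met = mean > threshold
    elif vote == "count":
        met = (vals > threshold).sum() > (vals <= threshold).sum()
    else:
        raise ValueError("vote must be 'mean' or 'count'")
    return SlideDecision(grid.slide_id, mean, "met" if met else "non_met", true_label)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]):
    """ROC curve and AUROC of continuous scores against boolean labels.

    AUROC equals the tie-corrected rank (Mann-Whitney) statistic
    (W + T/2)/(n1*n0). Returns ``(fpr, tpr, thresholds, auroc)``.
    """
    from sklearn import metrics

    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = metrics.roc_curve(y, s)
    auroc = float(metrics.roc_auc_score(y, s))
    return fpr, tpr, thr, auroc


def confusion_summary(decisions: Iterable[SlideDecision] | None = None, *,
                      counts: dict[str, int] | None = None) -> dict[str, float]:
    """Sensitivity, specificity and accuracy (percent) of slide decisions.

    Positive class is ``met``. Either pass decisions with true labels, or
    raw 2x2 counts ``{'tp':…, 'fn':…, 'tn':…, 'fp':…}``. Exact percentage
    fractions are returned; round for display.
    """
    if counts is None:
        tp = fn = tn = fp = 0
        n = 0
        for d in decisions:
            if d.true_label is None:
                raise ValueError("decisions must carry true labels")
            n += 1
            if d.true_label == "met":
                tp += d.predicted_label == "met"
                fn += d.predicted_label != "met"
            else:
                tn += d.predicted_label == "non_met"
                fp += d.predicted_label != "non_met"
        if n == 0:
            raise ValueError("need at least one decision")
    else:
        tp, fn, tn, fp = counts["tp"], counts["fn"], counts["tn"], counts["fp"]
    return {
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "accuracy": 100.0 * (tp + tn) / (tp + fn + tn + fp),
    }


def render_probability_map(grid: ScoreGrid, tile_px: int,
                           image_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Render a score grid as an RGB heatmap at slide resolution.

    Valid tiles are painted with a diverging blue-white-red palette over
    [-50, 50] (red = high metastasis score); everything outside the scored
    annotation is white. Returns an 8-bit RGB array.
    """
    from matplotlib import colormaps

    n_rows, n_cols = grid.scores.shape
    if image_shape is None:
        image_shape = (n_rows * tile_px, n_cols * tile_px)
    img = np.full((*image_shape, 3), 255, dtype=np.uint8)
    cmap = colormaps["bwr"]
    for r in range(n_rows):
        for c in range(n_cols):
            if not grid.valid[r, c]:
                continue
            frac = (grid.scores[r, c] + 50.0) / 100.0
            rgb = (np.asarray(cmap(frac))[:3] * 255).astype(np.uint8)
            img[r * tile_px:(r + 1) * tile_px, c * tile_px:(c + 1) * tile_px] = rgb
    return img


def save_probability_map(grid: ScoreGrid, tile_px: int, path: str) -> None:
    """Write the heatmap as a PNG with an embedded score legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm
    from matplotlib.colors import Normalize

    img = render_probability_map(grid, tile_px)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img)
    ax.set_axis_off()
    sm = cm.ScalarMappable(norm=Normalize(-50, 50), cmap="bwr")
    fig.colorbar(sm, ax=ax, fraction=0.046, label="metastasis score")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
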