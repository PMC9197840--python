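"""Synthetic study data with the statistical structure the pipeline assumes.

Real whole-slide images and patient tables from the source cohorts are not
shareable, so this module generates stand-ins end to end: annotated slide
images in which the two cohorts differ by a controllable nuclear texture
effect, clinicopathological cohort tables sampled from the published
per-cohort marginal distributions, exponential survival times with
five-year administrative censoring, and the bundled verbatim case/control
count tables from the published risk analysis.

The slide generator paints a pale scanner background, a tissue region
around each annotation polygon, and dark nucleus-like ellipses whose
density and radius inside the annotation are shifted between cohorts by
``texture_effect`` (0 = classes indistinguishable in expectation, 1 = the
default, well-separated condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .risk_stats import ContingencyCounts

__all__ = [
    "SyntheticSlideSpec",
    "PaperFixtures",
    "generate_slide",
    "generate_cohort",
    "generate_survival",
    "load_paper_fixtures",
    "default_annotation_polygon",
    "COHORTS",
]

COHORTS = ("non_met", "rapid_met", "slow_met")

# Texture parameters of the slide generator. Tones are chosen so the
# dominant grayscale split lies between tissue (~162) and background
# (~245): tissue falls below the 220 background cutoff, and the nuclei
# (~93 gray) stay a small enough area fraction (<5%) that Otsu separates
# tissue from background rather than nuclei from the rest. Nuclear density
# is ~40 nuclei per 512x512 px of tissue.
_BACKGROUND_RGB = np.array([245.0, 245.0, 245.0])
_TISSUE_RGB = np.array([200.0, 150.0, 170.0])
_NUCLEUS_RGB = np.array([120.0, 80.0, 140.0])
_BASE_NUCLEUS_DENSITY = 1.5e-4  # nuclei per pixel of tissue
_BASE_NUCLEUS_RADIUS = 5.0      # pixels (major semi-axis scale)
_DENSITY_GAIN = 1.2             # metastatic density = base * (1 + gain * effect)
_RADIUS_GAIN = 0.5              # metastatic radius = base * (1 + gain * effect)
_TISSUE_MARGIN_SCALE = 1.18     # tissue region = annotation scaled outward

_DEFAULT_HAZARDS = {  # per-day exponential hazards matching reported medians
    "rapid_met": np.log(2) / (1.2 * 365.25),
    "slow_met": np.log(2) / (3.4 * 365.25),
    "non_met": -np.log(0.7) / 1826.0,  # ~70% five-year overall survival
}
_DEFAULT_DSS_FLIP = {  # fraction of OS events censored in the DSS endpoint
    "non_met": 1.0,    # deaths in the non-metastatic cohort are unrelated
    "rapid_met": 0.1,
    "slow_met": 0.2,
}


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic annotated slide."""

    slide_id: str
    patient_id: str
    cohort: str
    width_px: int = 4096
    height_px: int = 4096
    texture_effect: float = 1.0
    annotation_polygons: tuple = ()  # closed (x, y) vertex lists
    scan_batch: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if not 0 <= self.texture_effect <= 1:
            raise ValueError("texture_effect must lie in [0, 1]")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        for poly in self.annotation_polygons:
            arr = np.asarray(poly, dtype=float)
            if (arr[:, 0].min() < 0 or arr[:, 1].min() < 0
                    or arr[:, 0].max() >= self.width_px
                    or arr[:, 1].max() >= self.height_px):
                raise ValueError(
                    "annotation polygon extends outside the image bounds")


def default_annotation_polygon(width_px: int, height_px: int,
                               rng: np.random.Generator,
                               radius_frac: float = 0.40,
                               n_vertices: int = 10) -> tuple:
    """Irregular convex-ish blob polygon centered in the slide."""
    cx, cy = width_px / 2, height_px / 2
    base_r = radius_frac * min(width_px, height_px)
    angles = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    radii = base_r * rng.uniform(0.85, 1.0, size=n_vertices)
    xs = np.clip(cx + radii * np.cos(angles), 0, width_px - 1)
    ys = np.clip(cy + radii * np.sin(angles), 0, height_px - 1)
    return tuple((float(x), float(y)) for x, y in zip(xs, ys))


def _fill_polygon(mask: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> None:
    """Even-odd scanline fill at pixel centers, in place."""
    height, width = mask.shape
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)
    y_lo = max(int(np.floor(ys.min())), 0)
    y_hi = min(int(np.ceil(ys.max())), height - 1)
    for y in range(y_lo, y_hi + 1):
        yc = y + 0.5
        crosses = ((ys <= yc) & (yc < y2)) | ((y2 <= yc) & (yc < ys))
        if not crosses.any():
            continue
        t = (yc - ys[crosses]) / (y2[crosses] - ys[crosses])
        xints = np.sort(xs[crosses] + t * (x2[crosses] - xs[crosses]))
        for a, b in zip(xints[0::2], xints[1::2]):
            lo = max(int(np.ceil(a - 0.5)), 0)
            hi = min(int(np.floor(b - 0.5)) + 1, width)
            if hi > lo:
                mask[y, lo:hi] = True


def _rasterize(polygons, width: int, height: int, scale: float = 1.0) -> np.ndarray:
    """Binary mask of polygons, optionally scaled outward about each centroid."""
    mask = np.zeros((height, width), dtype=bool)
    for poly in polygons:
        arr = np.asarray(poly, dtype=float)
        if scale != 1.0:
            centroid = arr.mean(axis=0)
            arr = centroid + scale * (arr - centroid)
        _fill_polygon(mask, arr[:, 0].copy(), arr[:, 1].copy())
    return mask


def _scatter_nuclei(img: np.ndarray, region: np.ndarray, density: float,
                    radius: float, rng: np.random.Generator) -> None:
    """Draw dark elliptical nuclei uniformly over a boolean region, in place.

    Nucleus centers follow a homogeneous Poisson process over the region
    (rejection-sampled from its bounding box); each nucleus is painted as a
    rotated ellipse stamp on a local window, which keeps the cost per
    nucleus at tens of pixels instead of a full-image draw call.
    """
    area = int(region.sum())
    if area == 0:
        return
    n = int(rng.poisson(density * area))
    if n == 0:
        return
    rows = np.nonzero(region.any(axis=1))[0]
    cols = np.nonzero(region.any(axis=0))[0]
    y_lo, y_hi, x_lo, x_hi = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    h, w = img.shape[:2]
    placed = 0
    while placed < n:
        batch = max(64, 2 * (n - placed))
        ys = rng.integers(y_lo, y_hi, size=batch)
        xs = rng.integers(x_lo, x_hi, size=batch)
        keep = region[ys, xs]
        ys, xs = ys[keep], xs[keep]
        take = min(len(ys), n - placed)
        for y, x in zip(ys[:take], xs[:take]):
            ry = radius * rng.uniform(0.7, 1.3)
            rx = ry * rng.uniform(0.5, 0.9)
            theta = rng.uniform(0, np.pi)
            shade = rng.uniform(0.85, 1.15)
            s = int(np.ceil(ry)) + 1
            yy, xx = np.ogrid[-s:s + 1, -s:s + 1]
            ca, sa = np.cos(theta), np.sin(theta)
            u = ca * xx + sa * yy
            v = -sa * xx + ca * yy
            stamp = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
            y0, y1 = max(y - s, 0), min(y + s + 1, h)
            x0, x1 = max(x - s, 0), min(x + s + 1, w)
            sub = stamp[y0 - (y - s):y1 - (y - s), x0 - (x - s):x1 - (x - s)]
            img[y0:y1, x0:x1][sub] = np.clip(_NUCLEUS_RGB * shade, 0, 255)
        placed += take


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic annotated slide.

    Returns ``(rgb_image, annotation_mask)``: an 8-bit RGB array with a
    near-white background, a pink tissue field extending slightly beyond
    the annotation, and nucleus-like ellipses whose density and size inside
    the annotation depend on cohort and ``texture_effect``; the mask is 1
    inside the annotation polygons. Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    annotation = _rasterize(spec.annotation_polygons, w, h)
    tissue = _rasterize(spec.annotation_polygons, w, h, scale=_TISSUE_MARGIN_SCALE)
    # Clip the dilated tissue field to the image; polygons themselves were
    # validated in-bounds by the spec.
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = _BACKGROUND_RGB
    img[tissue] = _TISSUE_RGB

    effect = spec.texture_effect if spec.cohort == "rapid_met" else 0.0
    density = _BASE_NUCLEUS_DENSITY * (1.0 + _DENSITY_GAIN * effect)
    radius = _BASE_NUCLEUS_RADIUS * (1.0 + _RADIUS_GAIN * effect)
    # Neutral texture on the peritumoral ring, cohort texture inside the
    # annotation: the class signal lives only in annotated tumor tissue.
    _scatter_nuclei(img, tissue & ~annotation, _BASE_NUCLEUS_DENSITY,
                    _BASE_NUCLEUS_RADIUS, rng)
    _scatter_nuclei(img, annotation, density, radius, rng)

    noise = 2.0 * rng.standard_normal(size=(h, w), dtype=np.float32)
    img += noise[:, :, None]
    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return rgb, annotation.astype(np.uint8)


def _load_json(name: str) -> dict:
    with resources.files("wsimet.fixtures").joinpath(name).open() as fh:
        return json.load(fh)


def generate_cohort(n_non_met: int, n_rapid_met: int = 0, n_slow_met: int = 0,
                    seed: int = 0) -> pd.DataFrame:
    """Sample a clinicopathological cohort table from the published marginals.

    Each categorical variable is drawn independently from its per-cohort
    level frequencies (the slow-metastasis cohort, which has no published
    baseline table, reuses the non-metastatic marginals); ages are drawn
    from a truncated normal matched to the reported summaries. Survival
    columns (os/dss days and events) are filled by :func:`generate_survival`
    with the default per-cohort hazards. Deterministic for a given seed.
    """
    marg = _load_json("cohort_marginals.json")["cohorts"]
    rng = np.random.default_rng(seed)
    rows = []
    sizes = {"non_met": n_non_met, "rapid_met": n_rapid_met, "slow_met": n_slow_met}
    for cohort, n in sizes.items():
        if n < 0:
            raise ValueError("cohort sizes must be non-negative")
        m = marg.get(cohort, marg["non_met"])
        for i in range(n):
            row = {"tumor_id": f"{cohort}_{i:05d}", "cohort": cohort}
            for var in ("sex", "grade", "diameter_class", "clark",
                        "invasion_beyond_fat", "ajcc8", "bwh", "pathologist_pred"):
                levels = list(m[var].keys())
                weights = np.asarray(list(m[var].values()), dtype=float)
                row[var] = str(rng.choice(levels, p=weights / weights.sum()))
            a = m["age"]
            age = rng.normal(a["mean"], a["sd"])
            row["age_years"] = int(np.clip(np.rint(age), a["min"], a["max"]))
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    surv = generate_survival(table, seed=int(rng.integers(2**31)))
    os_part = surv[surv["endpoint"] == "OS"].set_index("tumor_id")
    dss_part = surv[surv["endpoint"] == "DSS"].set_index("tumor_id")
    table = table.set_index("tumor_id")
    table["os_days"] = os_part["time_days"].astype(int)
    table["os_event"] = os_part["event"]
    table["dss_days"] = dss_part["time_days"].astype(int)
    table["dss_event"] = dss_part["event"]
    return table.reset_index()


def generate_survival(cohort_table: pd.DataFrame,
                      hazards_by_stratum: dict[str, float] | None = None,
                      follow_up_cap_days: int = 1826,
                      dss_flip_fraction: dict[str, float] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential survival times per stratum with censoring at the cap.

    Overall-survival event times are drawn from Exp(hazard) per stratum and
    administratively censored at ``follow_up_cap_days``. The disease-
    specific endpoint is derived from OS by flipping a per-stratum fraction
    of events to censored (at the same time), so DSS events are a subset of
    OS events. Returns a long table with columns
    ``tumor_id, stratum, endpoint, time_days, event``.
    """
    hazards = dict(_DEFAULT_HAZARDS if hazards_by_stratum is None
                   else hazards_by_stratum)
    flip = dict(_DEFAULT_DSS_FLIP if dss_flip_fraction is None
                else dss_flip_fraction)
    for stratum, lam in hazards.items():
        if lam <= 0:
            raise ValueError(f"hazard for stratum {stratum!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in cohort_table.iterrows():
        stratum = rec["cohort"]
        if stratum not in hazards:
            raise ValueError(f"no hazard given for stratum {stratum!r}")
        t_event = rng.exponential(1.0 / hazards[stratum])
        days = max(1, int(np.ceil(t_event)))
        if days >= follow_up_cap_days:
            os_days, os_event = follow_up_cap_days, False
        else:
            os_days, os_event = days, True
        dss_event = os_event and rng.random() >= flip.get(stratum, 0.0)
        rows.append({"tumor_id": rec["tumor_id"], "stratum": stratum,
                     "endpoint": "OS", "time_days": os_days, "event": os_event})
        rows.append({"tumor_id": rec["tumor_id"], "stratum": stratum,
                     "endpoint": "DSS", "time_days": os_days, "event": dss_event})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PaperFixtures:
    """Bundled verbatim count tables from the published risk analysis.

    ``tables`` maps variable names to case/control counts per ordered level
    (cases = rapid-metastasis cohort, controls = non-metastatic cohort);
    ``ai_confusion`` holds the slide-level AI prediction counts per cohort.
    """

    tables: dict[str, ContingencyCounts]
    ai_confusion: dict[str, dict[str, int]]


def load_paper_fixtures() -> PaperFixtures:
    """Load the bundled published count tables."""
    raw = _load_json("risk_tables.json")
    tables = {
        name: ContingencyCounts(tuple(t["levels"]), tuple(t["cases"]),
                                tuple(t["controls"]))
        for name, t in raw["tables"].items()
    }
    return PaperFixtures(tables=tables, ai_confusion=raw["ai_confusion"])
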