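"""Cross-validated tile classification.

Binary classification of tumor tiles (metastatic vs non-metastatic cohort
label) under patient-exclusive stratified k-fold cross-validation, yielding
exactly one out-of-fold probability per tile. The model is a lightweight
residual network that runs comfortably on one CPU: a fixed average-pooling
trunk turns each 299x299 RGB tile into pooled color/texture features, which
feed a stack of residual dense blocks and a head of average-pooled features
-> dense layer with heavy dropout -> sigmoid unit, trained with binary
cross-entropy and Adam. Depth presets trade blocks/width for runtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tiling import TileRecord, TileStack

__all__ = [
    "FoldAssignment",
    "TrainConfig",
    "CVResult",
    "assign_folds",
    "augment_tile",
    "featurize_tile",
    "ResidualMLP",
    "train_cv",
    "filter_scan_batch",
]

_DEPTH_PRESETS = {  # (residual blocks, block width)
    "tiny": (4, 32),
    "resnet18-like": (8, 128),
    "resnet50-like": (16, 256),
}


@dataclass(frozen=True)
class FoldAssignment:
    """Patient -> fold mapping for k-fold cross-validation.

    All tiles of a patient share one fold, preventing leakage between
    training and validation splits.
    """

    k: int
    fold_of: dict[str, int]

    def __post_init__(self) -> None:
        bad = [p for p, f in self.fold_of.items() if not 0 <= f < self.k]
        if bad:
            raise ValueError(f"fold index out of range for patients {bad}")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The optimizer, learning rate and batch size have no published reference
    values; the defaults below are documented, seeded choices made for
    reproducibility. ``dropout`` defaults to a heavy 0.5 in the head.
    """

    depth: str = "tiny"
    head_width: int = 256
    dropout: float = 0.5
    epochs: int = 10
    lr: float = 1e-3
    batch_size: int = 64
    weight_decay: float = 1e-4
    class_weight: bool = False
    stack_mode: str = "mean_features"  # how stacks are scored
    seed: int = 0


def assign_folds(patients: pd.DataFrame, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified-by-cohort patient partition into k folds.

    ``patients`` needs columns ``patient_id`` and ``cohort`` (one row per
    patient). Within each cohort patients are shuffled and dealt round-robin,
    so per-fold cohort counts are balanced within one patient. Every cohort
    must have at least k patients.
    """
    pats = patients.drop_duplicates("patient_id")
    if pats["patient_id"].duplicated().any():
        raise ValueError("conflicting cohort labels for a patient")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for cohort, group in pats.groupby("cohort", sort=True):
        ids = sorted(group["patient_id"])
        if len(ids) < k:
            raise ValueError(
                f"cohort {cohort!r} has {len(ids)} patients, fewer than k={k}")
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            fold_of[ids[idx]] = pos % k
    return FoldAssignment(k=k, fold_of=fold_of)


def augment_tile(tile_image: np.ndarray, seed: int = 0, *,
                 flips: bool = True, rotations: bool = True,
                 hue_range: float = 0.05, saturation_range: float = 0.2,
                 brightness_range: float = 0.2) -> np.ndarray:
    """Random flip/rotation and color (hue/saturation/brightness) jitter.

    Color jitter works in HSV space: hue is shifted by U(-hue_range,
    +hue_range) (wrapping), saturation and value are scaled by
    U(1-range, 1+range). With flips and rotations disabled and all ranges
    zero the tile is returned unchanged, bit for bit.
    """
    img = np.asarray(tile_image)
    rng = np.random.default_rng(seed)
    out = img
    if flips:
        if rng.random() < 0.5:
            out = out[:, ::-1]
        if rng.random() < 0.5:
            out = out[::-1, :]
    if rotations:
        out = np.rot90(out, k=int(rng.integers(4)))
    if hue_range > 0 or saturation_range > 0 or brightness_range > 0:
        from skimage.color import hsv2rgb, rgb2hsv

        hsv = rgb2hsv(out.astype(np.float64) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-hue_range, hue_range)) % 1.0
        hsv[..., 1] = np.clip(
            hsv[..., 1] * rng.uniform(1 - saturation_range, 1 + saturation_range), 0, 1)
        hsv[..., 2] = np.clip(
            hsv[..., 2] * rng.uniform(1 - brightness_range, 1 + brightness_range), 0, 1)
        out = np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(out)


def featurize_tile(tile_image: np.ndarray, pool_grid: int = 7) -> np.ndarray:
    """Average-pooling feature trunk for one RGB tile.

    The tile is trimmed to a multiple of ``pool_grid`` and pooled into a
    pool_grid x pool_grid lattice: per-cell channel means (color), per-cell
    grayscale standard deviations (texture), plus global grayscale mean and
    standard deviation. Nuclear density and size shift both the local means
    and the local variance, which is what the downstream net learns from.
    """
    img = np.asarray(tile_image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB tile")
    side = min(img.shape[0], img.shape[1])
    cell = side // pool_grid
    crop = img[:cell * pool_grid, :cell * pool_grid]
    blocks = crop.reshape(pool_grid, cell, pool_grid, cell, 3)
    channel_means = blocks.mean(axis=(1, 3))  # (g, g, 3)
    gray = crop @ np.array([0.2125, 0.7154, 0.0721])
    gblocks = gray.reshape(pool_grid, cell, pool_grid, cell)
    gray_stds = gblocks.std(axis=(1, 3))  # (g, g)
    return np.concatenate([
        channel_means.ravel(), gray_stds.ravel(),
        [gray.mean(), gray.std()],
    ])


class ResidualMLP:
    """Residual dense network with a dropout head, trained by Adam on BCE.

    Layers: input projection -> ``n_blocks`` residual blocks
    h <- relu(h + W2 relu(W1 h)) -> head dense layer with inverted dropout
    -> sigmoid output. Inputs are standardized with training-set statistics.
    """

    def __init__(self, n_features: int, n_blocks: int = 4, width: int = 32,
                 head_width: int = 256, dropout: float = 0.5,
                 weight_decay: float = 1e-4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        self.weight_decay = float(weight_decay)
        self.rng = rng

        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        self.W0, self.b0 = he(n_features, width), np.zeros(width)
        self.blocks = [
            (he(width, width), np.zeros(width), he(width, width), np.zeros(width))
            for _ in range(n_blocks)
        ]
        self.Wh, self.bh = he(width, head_width), np.zeros(head_width)
        self.Wo, self.bo = he(head_width, 1), np.zeros(1)
        self.mu = np.zeros(n_features)
        self.sigma = np.ones(n_features)
        self.loss_history: list[float] = []

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool):
        cache = {}
        h = np.maximum(X @ self.W0 + self.b0, 0.0)
        cache["h0"] = h
        hs = []
        for (W1, b1, W2, b2) in self.blocks:
            a = np.maximum(h @ W1 + b1, 0.0)
            h_new = np.maximum(h + a @ W2 + b2, 0.0)
            hs.append((h, a, h_new))
            h = h_new
        cache["blocks"] = hs
        g = np.maximum(h @ self.Wh + self.bh, 0.0)
        cache["g_pre_drop"] = g
        if train and self.dropout > 0:
            mask = (self.rng.random(g.shape) >= self.dropout) / (1 - self.dropout)
            g = g * mask
            cache["mask"] = mask
        cache["g"] = g
        z = g @ self.Wo + self.bo
        p = 1.0 / (1.0 + np.exp(-z))
        return p.ravel(), cache

    # -- training --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, *, epochs: int = 10,
            lr: float = 1e-3, batch_size: int = 64,
            sample_weight: np.ndarray | None = None) -> "ResidualMLP":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self.mu = X.mean(axis=0)
        self.sigma = X.std(axis=0)
        self.sigma[self.sigma < 1e-9] = 1.0
        Xs = (X - self.mu) / self.sigma
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)

        params = self._param_list()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = Xs.shape[0]
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb, wb = Xs[idx], y[idx], w[idx]
                p, cache = self._forward(xb, train=True)
                p_c = np.clip(p, 1e-12, 1 - 1e-12)
                loss = -np.mean(wb * (yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c)))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate")
                epoch_loss += loss * len(idx)
                seen += len(idx)
                grads = self._backward(xb, yb, wb, p, cache)
                step += 1
                for i, (par, gr) in enumerate(zip(params, grads)):
                    gr = gr + self.weight_decay * par if par.ndim == 2 else gr
                    m[i] = beta1 * m[i] + (1 - beta1) * gr
                    v[i] = beta2 * v[i] + (1 - beta2) * gr * gr
                    mhat = m[i] / (1 - beta1 ** step)
                    vhat = v[i] / (1 - beta2 ** step)
                    par -= lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(epoch_loss / max(seen, 1))
        return self

    def _param_list(self):
        params = [self.W0, self.b0]
        for (W1, b1, W2, b2) in self.blocks:
            params += [W1, b1, W2, b2]
        params += [self.Wh, self.bh, self.Wo, self.bo]
        return params

    def _backward(self, xb, yb, wb, p, cache):
        nb = len(yb)
        dz = (wb * (p - yb) / nb)[:, None]
        g = cache["g"]
        dWo = g.T @ dz
        dbo = dz.sum(axis=0)
        dg = dz @ self.Wo.T
        if "mask" in cache:
            dg = dg * cache["mask"]
        dg_pre = dg * (cache["g_pre_drop"] > 0)
        h_last = cache["blocks"][-1][2] if self.blocks else cache["h0"]
        dWh = h_last.T @ dg_pre
        dbh = dg_pre.sum(axis=0)
        dh = dg_pre @ self.Wh.T
        block_grads = []
        for (W1, b1, W2, b2), (h_in, a, h_out) in zip(
                reversed(self.blocks), reversed(cache["blocks"])):
            dpre = dh * (h_out > 0)
            da = dpre @ W2.T
            dW2 = a.T @ dpre
            db2 = dpre.sum(axis=0)
            dpre_a = da * (a > 0)
            dW1 = h_in.T @ dpre_a
            db1 = dpre_a.sum(axis=0)
            dh = dpre + dpre_a @ W1.T  # skip connection + branch
            block_grads.append((dW1, db1, dW2, db2))
        dpre0 = dh * (cache["h0"] > 0)
        dW0 = xb.T @ dpre0
        db0 = dpre0.sum(axis=0)
        grads = [dW0, db0]
        for (dW1, db1, dW2, db2) in reversed(block_grads):
            grads += [dW1, db1, dW2, db2]
        grads += [dWh, dbh, dWo, dbo]
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=np.float64) - self.mu) / self.sigma
        p, _ = self._forward(Xs, train=False)
        return p

    # -- checkpoints -----------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights and standardization constants as an .npz file."""
        arrays = {
            "W0": self.W0, "b0": self.b0, "Wh": self.Wh, "bh": self.bh,
            "Wo": self.Wo, "bo": self.bo, "mu": self.mu, "sigma": self.sigma,
            "dropout": np.array(self.dropout),
            "weight_decay": np.array(self.weight_decay),
            "n_blocks": np.array(len(self.blocks)),
            "loss_history": np.array(self.loss_history),
        }
        for i, (W1, b1, W2, b2) in enumerate(self.blocks):
            arrays |= {f"blk{i}_W1": W1, f"blk{i}_b1": b1,
                       f"blk{i}_W2": W2, f"blk{i}_b2": b2}
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ResidualMLP":
        data = np.load(path)
        n_blocks = int(data["n_blocks"])
        model = cls(n_features=data["W0"].shape[0], n_blocks=n_blocks,
                    width=data["W0"].shape[1], head_width=data["Wh"].shape[1],
                    dropout=float(data["dropout"]),
                    weight_decay=float(data["weight_decay"]))
        model.W0, model.b0 = data["W0"], data["b0"]
        model.blocks = [
            (data[f"blk{i}_W1"], data[f"blk{i}_b1"],
             data[f"blk{i}_W2"], data[f"blk{i}_b2"])
            for i in range(n_blocks)]
        model.Wh, model.bh = data["Wh"], data["bh"]
        model.Wo, model.bo = data["Wo"], data["bo"]
        model.mu, model.sigma = data["mu"], data["sigma"]
        model.loss_history = list(data["loss_history"])
        return model


@dataclass
class CVResult:
    """Outcome of cross-validated training.

    ``oof`` holds exactly one out-of-fold probability per manifest row,
    produced by the model whose validation fold contains that row's
    patient. ``loss_history`` is the per-epoch training loss per fold.
    """

    oof: np.ndarray
    models: list[ResidualMLP]
    folds: FoldAssignment
    loss_history: list[list[float]] = field(default_factory=list)


def _build_model(n_features: int, config: TrainConfig, seed: int) -> ResidualMLP:
    if config.depth not in _DEPTH_PRESETS:
        raise ValueError(f"unknown depth preset {config.depth!r}")
    n_blocks, width = _DEPTH_PRESETS[config.depth]
    return ResidualMLP(n_features, n_blocks=n_blocks, width=width,
                       head_width=config.head_width, dropout=config.dropout,
                       weight_decay=config.weight_decay, seed=seed)


def train_cv(manifest: pd.DataFrame, features: np.ndarray,
             folds: FoldAssignment, config: TrainConfig,
             stacks: list[TileStack] | None = None) -> CVResult:
    """Patient-exclusive k-fold training with out-of-fold probabilities.

    ``manifest`` has one row per tile with columns ``slide_id, patient_id,
    label`` (label in {non_met, met}); ``features`` is the aligned feature
    matrix. In stack mode (``stacks`` given) member-tile features are
    averaged, the model trains and predicts per stack, and the stack's
    probability is assigned to every member tile for slide mapping.
    """
    if len(manifest) != len(features):
        raise ValueError("manifest and features must be aligned")
    y = (manifest["label"] == "met").to_numpy()
    patients = manifest["patient_id"].to_numpy()
    missing = set(patients) - set(folds.fold_of)
    if missing:
        raise ValueError(f"patients without fold assignment: {sorted(missing)}")

    if stacks is not None:
        return _train_cv_stacks(manifest, features, folds, config, stacks)

    oof = np.full(len(manifest), np.nan)
    models, histories = [], []
    fold_ids = np.array([folds.fold_of[p] for p in patients])
    for f in range(folds.k):
        train_idx = np.nonzero(fold_ids != f)[0]
        val_idx = np.nonzero(fold_ids == f)[0]
        y_train = y[train_idx]
        if y_train.all() or not y_train.any():
            raise ValueError(f"fold {f}: training split contains one class only")
        weight = None
        if config.class_weight:
            n_pos, n_neg = y_train.sum(), (~y_train).sum()
            weight = np.where(y_train, n_neg / n_pos, 1.0)
        model = _build_model(features.shape[1], config, seed=config.seed + f)
        model.fit(features[train_idx], y_train.astype(float),
                  epochs=config.epochs, lr=config.lr,
                  batch_size=config.batch_size, sample_weight=weight)
        if val_idx.size:
            oof[val_idx] = model.predict_proba(features[val_idx])
        models.append(model)
        histories.append(model.loss_history)
    return CVResult(oof=oof, models=models, folds=folds, loss_history=histories)


def _train_cv_stacks(manifest, features, folds, config, stacks):
    """Stack mode: average member features, predict per stack, broadcast back."""
    pos_of = {(r.slide_id, r.row, r.col): i
              for i, r in manifest.reset_index(drop=True).iterrows()}
    stack_feats, stack_rows = [], []
    for s in stacks:
        idx = [pos_of[(t.slide_id, t.row, t.col)] for t in s.tiles]
        stack_feats.append(features[idx].mean(axis=0))
        stack_rows.append({
            "stack_id": s.stack_id,
            "slide_id": s.tiles[0].slide_id,
            "patient_id": s.tiles[0].patient_id,
            "label": s.label,
            "member_idx": idx,
        })
    stack_manifest = pd.DataFrame(stack_rows)
    inner = train_cv(stack_manifest[["slide_id", "patient_id", "label"]],
                     np.asarray(stack_feats), folds, config, stacks=None)
    oof = np.full(len(manifest), np.nan)
    for prob, row in zip(inner.oof, stack_rows):
        oof[row["member_idx"]] = prob
    return CVResult(oof=oof, models=inner.models, folds=folds,
                    loss_history=inner.loss_history)


def filter_scan_batch(slides: pd.DataFrame, batch: str) -> pd.DataFrame:
    """Restrict a slide table to one scan batch.

    Slides digitized in different scanning sessions can differ in color and
    noise statistics and confound the cohort label; restricting to a single
    batch removes that shortcut. Warns when nothing remains.
    """
    if "scan_batch" not in slides.columns:
        raise ValueError("slide table lacks a scan_batch column")
    out = slides[slides["scan_batch"] == batch]
    if out.empty:
        warnings.warn(f"no slides in scan batch {batch!r}", stacklevel=2)
    return out
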