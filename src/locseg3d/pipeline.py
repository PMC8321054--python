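"""Training and inference orchestration for the two strategies.

Multi-stage: a low-resolution localizer is trained first (binary union
of foreground, downsampled input); its gradient-weighted activation map
yields a fixed-size ROI per case; a separate segmenter is then trained
on full-resolution crops. The two trainings are disjoint — no gradient
crosses the crop.

End-to-end: localizer and segmenter are trained jointly by a single
optimizer. The localizer's single-channel sigmoid output is upsampled
to input resolution and fused with the input, either multiplicatively
(attention) or as an extra channel.

The module exposes plain functions (`train_localizer`,
`train_segmenter`, `train_end_to_end`, `predict`, `make_splits`) and
scikit-learn style estimators built on them
(:class:`MultiStageSegmenter3D`, :class:`EndToEndSegmenter3D`,
:class:`SingleStageLowRes3D`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .arch import DRUNet3D, NetworkSpec, build_network
from .config import RunConfig
from .io import LabelVolume, Volume
from .localization import (
    DensityMap,
    NoLocalizationError,
    ROIBox,
    crop,
    density_to_roi,
    derive_crop_shape,
    gcam,
    uncrop,
)
from .losses import bce_dice_loss, multiclass_dice_loss
from .metrics import dsc
from .nn import Adam, Tensor, concatenate, upsample_nearest3d
from .preprocess import (
    PadCropRecord,
    clahe_slicewise,
    downsample_for_localizer,
    pad_or_crop,
    znormalize,
)

__all__ = [
    "TrainState",
    "PredictionResult",
    "train_localizer",
    "train_segmenter",
    "train_end_to_end",
    "predict",
    "make_splits",
    "MultiStageSegmenter3D",
    "EndToEndSegmenter3D",
    "SingleStageLowRes3D",
]


@dataclass
class TrainState:
    epoch: int = 0
    best_validation_dice: float = -np.inf
    seed: int = 0
    history: list[dict] = field(default_factory=list)


@dataclass
class PredictionResult:
    label: LabelVolume
    density: DensityMap | None = None
    box: ROIBox | None = None
    used_fallback: bool = False


# ---------------------------------------------------------------------------
# preparation helpers
# ---------------------------------------------------------------------------


def _block(cfg: RunConfig) -> tuple[int, int, int]:
    """Per-axis divisibility required of the padded full-resolution shape."""
    div = cfg.pool_divisor()
    f = cfg.downsample
    if cfg.keep_z:
        f = (1,) + tuple(f[1:])
    return tuple(d * ff for d, ff in zip(div, f))


def _padded_shape(shape, cfg: RunConfig) -> tuple[int, int, int]:
    blk = _block(cfg)
    return tuple(-(-n // b) * b for n, b in zip(shape, blk))


def _prepare_volume(v: Volume, cfg: RunConfig) -> tuple[Volume, PadCropRecord]:
    if cfg.use_clahe:
        v = clahe_slicewise(v, cfg.clahe_clip_limit, cfg.clahe_tiles)
    v = znormalize(v)
    return pad_or_crop(v, _padded_shape(v.shape, cfg))


def _prepare_label(lv: LabelVolume, cfg: RunConfig) -> tuple[LabelVolume, PadCropRecord]:
    return pad_or_crop(lv, _padded_shape(lv.shape, cfg))


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    out = np.zeros((num_classes,) + labels.shape, dtype=np.float32)
    for k in range(num_classes):
        out[k] = labels == k
    return out


def _gt_box(lv: LabelVolume, crop_shape, threshold_frac=0.5) -> ROIBox:
    """Teacher-forcing box: centred on the ground-truth foreground."""
    fg = (np.asarray(lv.data) > 0).astype(np.float32)
    if not fg.any():
        raise NoLocalizationError("label volume has no foreground")
    return density_to_roi(DensityMap(fg, lv.shape), crop_shape, threshold_frac)


def _center_box(full_shape, crop_shape) -> ROIBox:
    start, shape = [], []
    for full, n in zip(full_shape, crop_shape):
        if n >= full:
            start.append(0)
            shape.append(full)
        else:
            start.append((full - n) // 2)
            shape.append(n)
    return ROIBox(tuple(start), tuple(shape))


def _localizer_density(
    loc: DRUNet3D, low: Volume, cfg: RunConfig, full_shape
) -> DensityMap:
    """Run the localizer and derive a density map (GCAM or direct sigmoid)."""
    loc.eval()
    x = Tensor(low.data[None, None])
    out = loc(x)
    if cfg.roi_source == "gcam":
        density = gcam(out.features, lambda f: loc.head(f)[:, 0].sum())[0]
    else:
        density = np.asarray(out.probs.data[0, 0])
    return DensityMap(np.maximum(density, 0.0), tuple(full_shape))


# ---------------------------------------------------------------------------
# generic training loop
# ---------------------------------------------------------------------------


def _snapshot(modules) -> list[np.ndarray]:
    return [a.copy() for m in modules for a in m.state_arrays()]


def _restore(modules, snap: list[np.ndarray]) -> None:
    i = 0
    for m in modules:
        arrays = m.state_arrays()
        m.load_state_arrays(snap[i : i + len(arrays)])
        i += len(arrays)


def _run_training(
    modules: Sequence,
    loss_fn: Callable[[np.ndarray, np.ndarray], "object"],
    x_train: np.ndarray,
    y_train: np.ndarray,
    val_dice_fn: Callable[[], float],
    cfg: RunConfig,
) -> TrainState:
    params = [p for m in modules for p in m.parameters()]
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    state = TrainState(seed=cfg.seed)
    best_snap = _snapshot(modules)
    epochs_since_best = 0
    n = len(x_train)
    for epoch in range(cfg.max_epochs):
        for m in modules:
            m.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            lv = loss_fn(x_train[idx], y_train[idx])
            lv.backward()
            opt.step()
            losses.append(lv.value)
        for m in modules:
            m.eval()
        val_dice = val_dice_fn()
        state.epoch = epoch + 1
        state.history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "val_dice": float(val_dice),
            }
        )
        if val_dice > state.best_validation_dice + 1e-6:
            state.best_validation_dice = float(val_dice)
            best_snap = _snapshot(modules)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break
    _restore(modules, best_snap)
    for m in modules:
        m.eval()
    return state


def _split_train_val(n: int, seed: int, val_frac: float = 0.2):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n))) if n > 1 else 0
    return order[n_val:], order[:n_val]


def _foreground_dice(pred_labels: np.ndarray, true_labels: np.ndarray, k: int) -> float:
    """Mean per-structure dice over foreground classes."""
    if k <= 1:
        return dsc(true_labels > 0, pred_labels > 0)
    vals = [dsc(true_labels == c, pred_labels == c) for c in range(1, k)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# stage trainers
# ---------------------------------------------------------------------------


def _check_cases(cases, cfg: RunConfig) -> None:
    if len(cases) < cfg.min_cases:
        raise ValueError(f"need at least {cfg.min_cases} cases, got {len(cases)}")
    if not any((np.asarray(lv.data) > 0).any() for _, lv in cases):
        raise ValueError("no case has foreground labels")


def train_localizer(
    cases: list[tuple[Volume, LabelVolume]], cfg: RunConfig
) -> tuple[DRUNet3D, TrainState]:
    """Train the low-resolution localizer on the binarized foreground."""
    _check_cases(cases, cfg)
    xs, ys = [], []
    for v, lv in cases:
        pv, _ = _prepare_volume(v, cfg)
        pl, _ = _prepare_label(lv, cfg)
        low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
        low_lab = downsample_for_localizer(pl, cfg.downsample, keep_z=cfg.keep_z)
        xs.append(low.data[None])
        ys.append((np.asarray(low_lab.data) > 0).astype(np.float32)[None])
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    tr, va = _split_train_val(len(cases), cfg.seed)
    spec = NetworkSpec(
        in_channels=1,
        num_classes=1,
        base_filters=cfg.base_filters_localizer,
        keep_z=cfg.keep_z,
    )
    model = build_network(spec, seed=cfg.seed)

    def loss_fn(xb, yb):
        out = model(Tensor(xb))
        return bce_dice_loss(Tensor(yb), out.probs, variant=cfg.loss_variant)

    def val_dice():
        scores = []
        for i in va:
            out = model(Tensor(x[i : i + 1]))
            scores.append(dsc(y[i, 0] > 0.5, out.probs.data[0, 0] > 0.5))
        return float(np.mean(scores)) if scores else 0.0

    state = _run_training([model], loss_fn, x[tr], y[tr], val_dice, cfg)
    return model, state


def train_segmenter(
    cases: list[tuple[Volume, LabelVolume]],
    boxes: list[ROIBox],
    cfg: RunConfig,
) -> tuple[DRUNet3D, TrainState]:
    """Train the high-resolution segmenter on fixed-size crops."""
    _check_cases(cases, cfg)
    if len(boxes) != len(cases):
        raise ValueError("one ROI box per case required")
    k = cfg.num_classes
    xs, ys = [], []
    for (v, lv), box in zip(cases, boxes):
        pv, _ = _prepare_volume(v, cfg)
        pl, _ = _prepare_label(lv, cfg)
        cv, cl = crop(pv, box), crop(pl, box)
        if cv.shape != cl.shape:
            raise ValueError("crop/label misalignment")
        xs.append(cv.data[None])
        if k == 1:
            ys.append((np.asarray(cl.data) > 0).astype(np.float32)[None])
        else:
            ys.append(_one_hot(np.asarray(cl.data), k))
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    tr, va = _split_train_val(len(cases), cfg.seed + 1)
    spec = NetworkSpec(
        in_channels=1,
        num_classes=k,
        base_filters=cfg.base_filters_segmenter,
        keep_z=cfg.keep_z,
    )
    model = build_network(spec, seed=cfg.seed + 1)

    def loss_fn(xb, yb):
        out = model(Tensor(xb))
        if k == 1:
            return bce_dice_loss(Tensor(yb), out.probs, variant=cfg.loss_variant)
        return multiclass_dice_loss(Tensor(yb), out.probs, variant=cfg.loss_variant)

    def _hard(probs):
        if k == 1:
            return (probs[0, 0] > 0.5).astype(np.int16)
        return probs[0].argmax(axis=0).astype(np.int16)

    def _true(yi):
        return (yi[0] > 0.5).astype(np.int16) if k == 1 else yi.argmax(axis=0)

    def val_dice():
        scores = []
        for i in va:
            out = model(Tensor(x[i : i + 1]))
            scores.append(
                _foreground_dice(_hard(out.probs.data), _true(y[i]), max(k, 2))
            )
        return float(np.mean(scores)) if scores else 0.0

    state = _run_training([model], loss_fn, x[tr], y[tr], val_dice, cfg)
    return model, state


def localize_boxes(
    loc: DRUNet3D,
    cases: list[tuple[Volume, LabelVolume]],
    cfg: RunConfig,
) -> list[ROIBox]:
    """ROI boxes for each case from the trained localizer (GT fallback)."""
    boxes = []
    for v, lv in cases:
        pv, _ = _prepare_volume(v, cfg)
        low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
        try:
            density = _localizer_density(loc, low, cfg, pv.shape)
            boxes.append(
                density_to_roi(density, cfg.crop_shape, cfg.roi_threshold_frac)
            )
        except NoLocalizationError:
            pl, _ = _prepare_label(lv, cfg)
            boxes.append(_gt_box(pl, cfg.crop_shape, cfg.roi_threshold_frac))
    return boxes


def train_end_to_end(
    cases: list[tuple[Volume, LabelVolume]], cfg: RunConfig
) -> tuple[tuple[DRUNet3D, DRUNet3D], TrainState]:
    """Jointly train localizer and segmenter with attention fusion."""
    _check_cases(cases, cfg)
    k = cfg.num_classes
    xs_full, xs_low, ys = [], [], []
    for v, lv in cases:
        pv, _ = _prepare_volume(v, cfg)
        pl, _ = _prepare_label(lv, cfg)
        low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
        xs_full.append(pv.data[None])
        xs_low.append(low.data[None])
        if k == 1:
            ys.append((np.asarray(pl.data) > 0).astype(np.float32)[None])
        else:
            ys.append(_one_hot(np.asarray(pl.data), k))
    x_full = np.stack(xs_full).astype(np.float32)
    x_low = np.stack(xs_low).astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    tr, va = _split_train_val(len(cases), cfg.seed)

    factor = (1,) + tuple(cfg.downsample[1:]) if cfg.keep_z else tuple(cfg.downsample)
    loc_spec = NetworkSpec(1, 1, cfg.base_filters_localizer, keep_z=cfg.keep_z)
    seg_in = 2 if cfg.e2e_fusion == "concat" else 1
    seg_spec = NetworkSpec(seg_in, k, cfg.base_filters_segmenter, keep_z=cfg.keep_z)
    loc = build_network(loc_spec, seed=cfg.seed)
    seg = build_network(seg_spec, seed=cfg.seed + 1)

    def fuse(xb_full: Tensor, attention: Tensor) -> Tensor:
        if attention.shape[1] != 1:
            raise ValueError("attention fusion requires a single-channel localizer")
        up = upsample_nearest3d(attention, factor)
        if cfg.e2e_fusion == "multiply":
            return xb_full * up
        return concatenate([xb_full, up], axis=1)

    def forward(xb_full, xb_low) -> Tensor:
        att = loc(Tensor(xb_low)).probs
        return seg(fuse(Tensor(xb_full), att)).probs

    def loss_fn(xb, yb):
        # xb carries indices into the paired full/low arrays
        idx = xb.astype(int).ravel()
        probs = forward(x_full[idx], x_low[idx])
        if k == 1:
            return bce_dice_loss(Tensor(y[idx]), probs, variant=cfg.loss_variant)
        return multiclass_dice_loss(Tensor(y[idx]), probs, variant=cfg.loss_variant)

    def val_dice():
        scores = []
        for i in va:
            probs = forward(x_full[i : i + 1], x_low[i : i + 1]).data
            if k == 1:
                pred = (probs[0, 0] > 0.5).astype(np.int16)
                true = (y[i, 0] > 0.5).astype(np.int16)
            else:
                pred = probs[0].argmax(axis=0)
                true = y[i].argmax(axis=0)
            scores.append(_foreground_dice(pred, true, max(k, 2)))
        return float(np.mean(scores)) if scores else 0.0

    idx_train = np.arange(len(cases), dtype=np.float32)[:, None]
    state = _run_training(
        [loc, seg], loss_fn, idx_train[tr], idx_train[tr], val_dice, cfg
    )
    return (loc, seg), state


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    vol: Volume,
    models: dict,
    cfg: RunConfig,
    class_names: list[str] | None = None,
) -> PredictionResult:
    """Full-resolution prediction aligned with the input geometry.

    `models` holds ``{"strategy": "multistage"|"end2end", "localizer": m,
    "segmenter": m}``.
    """
    strategy = models.get("strategy", "multistage")
    loc: DRUNet3D = models["localizer"]
    seg: DRUNet3D = models["segmenter"]
    k = seg.spec.num_classes
    if class_names is None:
        class_names = [f"structure_{i}" for i in range(1, max(k, 2))]
    pv, rec = _prepare_volume(vol, cfg)
    low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
    loc.eval()
    seg.eval()

    if strategy == "end2end":
        factor = (1,) + tuple(cfg.downsample[1:]) if cfg.keep_z else tuple(cfg.downsample)
        att = loc(Tensor(low.data[None, None])).probs
        up = upsample_nearest3d(att, factor)
        x_full = Tensor(pv.data[None, None])
        if cfg.e2e_fusion == "multiply":
            fused = x_full * up
        else:
            fused = concatenate([x_full, up], axis=1)
        probs = seg(fused).probs.data
        hard = (
            (probs[0, 0] > 0.5).astype(np.int16)
            if k == 1
            else probs[0].argmax(axis=0).astype(np.int16)
        )
        restored = rec.restore(hard)
        label = LabelVolume(restored, vol.spacing, vol.origin, list(class_names))
        density = DensityMap(np.asarray(att.data[0, 0]), tuple(pv.shape))
        return PredictionResult(label, density, None, False)

    # multi-stage path
    used_fallback = False
    density = _localizer_density(loc, low, cfg, pv.shape)
    try:
        box = density_to_roi(density, cfg.crop_shape, cfg.roi_threshold_frac)
    except NoLocalizationError:
        box = _center_box(pv.shape, cfg.crop_shape)
        used_fallback = True
    cv = crop(pv, box)
    probs = seg(Tensor(cv.data[None, None])).probs.data
    hard = (
        (probs[0, 0] > 0.5).astype(np.int16)
        if k == 1
        else probs[0].argmax(axis=0).astype(np.int16)
    )
    full = uncrop(hard, box, pv.shape)
    restored = rec.restore(full)
    label = LabelVolume(restored, vol.spacing, vol.origin, list(class_names))
    return PredictionResult(label, density, box, used_fallback)


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------


def make_splits(
    case_ids: list,
    n_folds: int = 5,
    test_frac: float = 0.2,
    strata: list | None = None,
    seed: int = 0,
) -> dict:
    """Disjoint test hold-out plus n-fold cross-validation assignment.

    Returns ``{"test": [...], "folds": [{"train": [...], "val": [...]}]}``;
    folds are stratified when `strata` is given. Deterministic under seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = list(case_ids)
    if len(ids) < n_folds:
        raise ValueError(f"fewer cases ({len(ids)}) than folds ({n_folds})")
    idx = np.arange(len(ids))
    if test_frac > 0:
        dev_idx, test_idx = train_test_split(
            idx,
            test_size=test_frac,
            random_state=seed,
            stratify=None if strata is None else np.asarray(strata),
        )
    else:
        dev_idx, test_idx = idx, np.array([], dtype=int)
    dev_idx = np.sort(dev_idx)
    if strata is not None:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        dev_strata = np.asarray(strata)[dev_idx]
        fold_iter = splitter.split(dev_idx, dev_strata)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_iter = splitter.split(dev_idx)
    folds = []
    for tr, va in fold_iter:
        folds.append(
            {
                "train": [ids[i] for i in dev_idx[tr]],
                "val": [ids[i] for i in dev_idx[va]],
            }
        )
    return {"test": [ids[i] for i in test_idx], "folds": folds}


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class _BaseSegmenter(BaseEstimator):
    """Shared fit/predict plumbing. X is a list of Volume, y of LabelVolume."""

    def _config(self) -> RunConfig:
        p = self.get_params()
        return RunConfig(
            crop_shape=getattr(self, "crop_shape_", None),
            keep_z=p["keep_z"],
            downsample=tuple(p["downsample"]),
            base_filters_localizer=p["base_filters_localizer"],
            base_filters_segmenter=p["base_filters_segmenter"],
            num_classes=self.num_classes_,
            learning_rate=p["learning_rate"],
            batch_size=p["batch_size"],
            max_epochs=p["max_epochs"],
            patience=p["patience"],
            seed=p["seed"],
            loss_variant=p["loss_variant"],
            e2e_fusion=getattr(self, "fusion", "multiply"),
            roi_source=getattr(self, "roi_source", "gcam"),
            use_clahe=p["use_clahe"],
        )

    def _validate_xy(self, X, y):
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        for v, lv in zip(X, y):
            if v.shape != lv.shape:
                raise ValueError("image/label shape mismatch")
        max_label = max(int(np.asarray(lv.data).max()) for lv in y)
        self.num_classes_ = 1 if max_label <= 1 else max_label + 1
        self.class_names_ = list(y[0].class_names)
        return list(zip(X, y))

    def predict(self, X) -> list[LabelVolume]:
        return [self._predict_one(v).label for v in X]

    def predict_full(self, X) -> list[PredictionResult]:
        return [self._predict_one(v) for v in X]

    def score(self, X, y) -> float:
        """Mean foreground dice over cases."""
        preds = self.predict(X)
        k = max(self.num_classes_, 2)
        return float(
            np.mean(
                [
                    _foreground_dice(np.asarray(p.data), np.asarray(t.data), k)
                    for p, t in zip(preds, y)
                ]
            )
        )


class MultiStageSegmenter3D(_BaseSegmenter):
    """Localize-then-segment pipeline with disjoint stage training.

    Parameters follow the run configuration; `crop_shape=None` derives
    the fixed crop size from the training labels (max bounding box plus
    a 10-voxel margin, rounded to pooling divisibility).
    """

    def __init__(
        self,
        base_filters_localizer: int = 8,
        base_filters_segmenter: int = 8,
        crop_shape: tuple[int, int, int] | None = None,
        keep_z: bool = False,
        downsample: tuple[int, int, int] = (1, 4, 4),
        learning_rate: float = 1e-3,
        batch_size: int = 2,
        max_epochs: int = 30,
        patience: int = 10,
        loss_variant: str = "factor2",
        roi_source: str = "gcam",
        teacher_forcing: bool = False,
        use_clahe: bool = False,
        seed: int = 0,
    ):
        self.base_filters_localizer = base_filters_localizer
        self.base_filters_segmenter = base_filters_segmenter
        self.crop_shape = crop_shape
        self.keep_z = keep_z
        self.downsample = downsample
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.loss_variant = loss_variant
        self.roi_source = roi_source
        self.teacher_forcing = teacher_forcing
        self.use_clahe = use_clahe
        self.seed = seed

    def fit(self, X, y):
        cases = self._validate_xy(X, y)
        if self.crop_shape is not None:
            self.crop_shape_ = tuple(self.crop_shape)
        else:
            cfg0 = self._config()
            div = cfg0.pool_divisor()
            padded = [_padded_shape(v.shape, cfg0) for v, _ in cases]
            max_shape = tuple(int(np.min([s[a] for s in padded])) for a in range(3))
            self.crop_shape_ = derive_crop_shape(
                [lv for _, lv in cases], margin=10, divisors=div, max_shape=max_shape
            )
        cfg = self._config()
        self.localizer_, self.localizer_state_ = train_localizer(cases, cfg)
        if self.teacher_forcing:
            boxes = [
                _gt_box(_prepare_label(lv, cfg)[0], cfg.crop_shape) for _, lv in cases
            ]
        else:
            boxes = localize_boxes(self.localizer_, cases, cfg)
        self.boxes_ = boxes
        self.segmenter_, self.segmenter_state_ = train_segmenter(cases, boxes, cfg)
        return self

    def _predict_one(self, v: Volume) -> PredictionResult:
        cfg = self._config()
        return predict(
            v,
            {
                "strategy": "multistage",
                "localizer": self.localizer_,
                "segmenter": self.segmenter_,
            },
            cfg,
            class_names=self.class_names_,
        )


class EndToEndSegmenter3D(_BaseSegmenter):
    """Jointly trained localizer+segmenter with attention fusion."""

    def __init__(
        self,
        base_filters_localizer: int = 8,
        base_filters_segmenter: int = 8,
        keep_z: bool = False,
        downsample: tuple[int, int, int] = (1, 4, 4),
        fusion: str = "multiply",
        learning_rate: float = 1e-3,
        batch_size: int = 2,
        max_epochs: int = 30,
        patience: int = 10,
        loss_variant: str = "factor2",
        use_clahe: bool = False,
        seed: int = 0,
    ):
        self.base_filters_localizer = base_filters_localizer
        self.base_filters_segmenter = base_filters_segmenter
        self.keep_z = keep_z
        self.downsample = downsample
        self.fusion = fusion
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.loss_variant = loss_variant
        self.use_clahe = use_clahe
        self.seed = seed

    def fit(self, X, y):
        cases = self._validate_xy(X, y)
        cfg = self._config()
        (self.localizer_, self.segmenter_), self.train_state_ = train_end_to_end(
            cases, cfg
        )
        return self

    def _predict_one(self, v: Volume) -> PredictionResult:
        cfg = self._config()
        return predict(
            v,
            {
                "strategy": "end2end",
                "localizer": self.localizer_,
                "segmenter": self.segmenter_,
            },
            cfg,
            class_names=self.class_names_,
        )


class SingleStageLowRes3D(_BaseSegmenter):
    """Baseline: one network trained on downsampled volumes; predictions
    are nearest-upsampled back to full resolution."""

    def __init__(
        self,
        base_filters_segmenter: int = 8,
        base_filters_localizer: int = 8,  # unused; kept for a uniform surface
        keep_z: bool = False,
        downsample: tuple[int, int, int] = (1, 4, 4),
        learning_rate: float = 1e-3,
        batch_size: int = 2,
        max_epochs: int = 30,
        patience: int = 10,
        loss_variant: str = "factor2",
        use_clahe: bool = False,
        seed: int = 0,
    ):
        self.base_filters_segmenter = base_filters_segmenter
        self.base_filters_localizer = base_filters_localizer
        self.keep_z = keep_z
        self.downsample = downsample
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.loss_variant = loss_variant
        self.use_clahe = use_clahe
        self.seed = seed

    def fit(self, X, y):
        cases = self._validate_xy(X, y)
        cfg = self._config()
        k = self.num_classes_
        xs, ys = [], []
        for v, lv in cases:
            pv, _ = _prepare_volume(v, cfg)
            pl, _ = _prepare_label(lv, cfg)
            low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
            low_lab = downsample_for_localizer(pl, cfg.downsample, keep_z=cfg.keep_z)
            xs.append(low.data[None])
            if k == 1:
                ys.append((np.asarray(low_lab.data) > 0).astype(np.float32)[None])
            else:
                ys.append(_one_hot(np.asarray(low_lab.data), k))
        x = np.stack(xs).astype(np.float32)
        yarr = np.stack(ys).astype(np.float32)
        tr, va = _split_train_val(len(cases), cfg.seed)
        spec = NetworkSpec(1, k, cfg.base_filters_segmenter, keep_z=cfg.keep_z)
        model = build_network(spec, seed=cfg.seed)

        def loss_fn(xb, yb):
            out = model(Tensor(xb))
            if k == 1:
                return bce_dice_loss(Tensor(yb), out.probs, variant=cfg.loss_variant)
            return multiclass_dice_loss(Tensor(yb), out.probs, variant=cfg.loss_variant)

        def val_dice():
            scores = []
            for i in va:
                probs = model(Tensor(x[i : i + 1])).probs.data
                if k == 1:
                    pred = (probs[0, 0] > 0.5).astype(np.int16)
                    true = (yarr[i, 0] > 0.5).astype(np.int16)
                else:
                    pred = probs[0].argmax(axis=0)
                    true = yarr[i].argmax(axis=0)
                scores.append(_foreground_dice(pred, true, max(k, 2)))
            return float(np.mean(scores)) if scores else 0.0

        self.model_ = model
        self.train_state_ = _run_training([model], loss_fn, x[tr], yarr[tr], val_dice, cfg)
        return self

    def _predict_one(self, v: Volume) -> PredictionResult:
        cfg = self._config()
        k = self.num_classes_
        pv, rec = _prepare_volume(v, cfg)
        low = downsample_for_localizer(pv, cfg.downsample, keep_z=cfg.keep_z)
        self.model_.eval()
        probs = self.model_(Tensor(low.data[None, None])).probs.data
        hard = (
            (probs[0, 0] > 0.5).astype(np.int16)
            if k == 1
            else probs[0].argmax(axis=0).astype(np.int16)
        )
        factor = (1,) + tuple(cfg.downsample[1:]) if cfg.keep_z else tuple(cfg.downsample)
        up = hard
        for ax, f in enumerate(factor):
            if f > 1:
                up = np.repeat(up, f, axis=ax)
        up = up[: pv.shape[0], : pv.shape[1], : pv.shape[2]]
        restored = rec.restore(up)
        label = LabelVolume(restored, v.spacing, v.origin, self.class_names_)
        return PredictionResult(label)
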