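"""Patch-level IC scorer: CNN feature extractor + random-forest head,
master training and the transfer-learning calibration step.

Training discipline (shared by the master and the calibration phase):
binary cross entropy, Adam at initial learning rate 0.001, no frozen
layers, early stopping on validation loss, augmentation from
:class:`~icdetect.augment.AugmentConfig`. The network is fed x5 context
images; the predicted IC score is attributed to the x20 base patch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import slide_io
from .augment import AugmentConfig, augment
from .backbone import Adam, TinyCNN, bce_with_logits, sigmoid
from .errors import ConfigError, ContractError, DataError, StateError


@dataclass(frozen=True)
class TrainConfig:
    backbone_arch: str = "tiny_cnn"
    init: str = "random"  # "random" | "imagenet" | path to a weights file
    freeze_layers: str = "none"  # anything else is rejected
    loss: str = "bce"
    optimizer: str = "adam"
    initial_lr: float = 0.001
    es_metric: str = "val_loss"
    es_patience: int = 3
    es_min_delta: float = 0.0
    batch_size: int = 32
    max_epochs: int = 20
    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32)
    rf_n_trees: int = 200
    rf_max_depth: int | None = None
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.freeze_layers != "none":
            raise ConfigError("freeze_layers must be 'none': no layer is ever frozen")
        if self.loss != "bce" or self.optimizer != "adam":
            raise ConfigError("only bce loss with the adam optimizer is supported")
        if self.initial_lr <= 0:
            raise ConfigError("initial_lr must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["augment"] = self.augment.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("augment"), dict):
            aug = dict(d["augment"])
            for k, v in aug.items():
                if isinstance(v, list):
                    aug[k] = tuple(v)
            d["augment"] = AugmentConfig(**aug)
        if isinstance(d.get("channels"), list):
            d["channels"] = tuple(d["channels"])
        return cls(**d)


def build_backbone(cfg: TrainConfig):
    """Instantiate the feature extractor named by ``cfg.backbone_arch``.

    ``tiny_cnn`` is the self-contained NumPy network. ``resnet50`` (the
    full-scale architecture, ImageNet-initializable) needs torch /
    torchvision and is only available where they are installed.
    """
    if cfg.backbone_arch == "tiny_cnn":
        backbone = TinyCNN(input_size=cfg.input_size, channels=cfg.channels, seed=cfg.seed)
        if cfg.init not in ("random", "imagenet"):
            backbone.set_weights(dict(np.load(cfg.init)))
        return backbone
    if cfg.backbone_arch == "resnet50":
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ConfigError(
                "backbone_arch='resnet50' requires torch and torchvision; "
                "use 'tiny_cnn' in a framework-free environment"
            ) from exc
        from torchvision.models import resnet50

        model = resnet50(weights="IMAGENET1K_V1" if cfg.init == "imagenet" else None)
        return model
    raise ConfigError(f"unknown backbone_arch {cfg.backbone_arch!r}")


# ---------------------------------------------------------------------------
# Backbone training
# ---------------------------------------------------------------------------


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise DataError(f"{what} contains a single class")


def _eval_loss_acc(model: TinyCNN, images: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    scores = predict_images(model, images)
    eps = 1e-12
    p = np.clip(scores, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    acc = float(np.mean((scores > 0.5) == (y > 0.5)))
    return loss, acc


def predict_images(model: TinyCNN, images: np.ndarray, batch: int = 256) -> np.ndarray:
    """Sigmoid head scores for a stack of uint8 images (inference mode)."""
    out = []
    for i in range(0, len(images), batch):
        x = model.prepare(images[i : i + batch])
        logits, _ = model.forward_logits(x)
        out.append(sigmoid(logits))
    return np.concatenate(out) if out else np.empty(0)


def train_backbone(
    backbone: TinyCNN,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Fine-tune the backbone (sigmoid head attached) with BCE + Adam and
    early stopping on validation loss.

    Returns the best weights seen (by validation loss, including the
    initial state) and a per-epoch log. ``max_epochs=0`` is a no-op that
    returns the initial weights unchanged.
    """
    if not isinstance(backbone, TinyCNN):
        raise ConfigError("train_backbone supports the tiny_cnn backbone")
    y_train = np.asarray(train_labels, dtype=np.float64)
    y_val = np.asarray(val_labels, dtype=np.float64)
    _check_two_classes(y_train, "training set")

    log: list[dict] = []
    if cfg.max_epochs == 0:
        return backbone.get_weights(), log

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.initial_lr)
    best_loss, _ = _eval_loss_acc(backbone, val_images, y_val)
    best_weights = backbone.get_weights()
    log.append({"epoch": 0, "val_loss": best_loss})
    bad = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_images))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            imgs = train_images[idx]
            if not cfg.augment.is_identity:
                seeds = rng.integers(0, 2**31, size=len(idx))
                imgs = np.stack(
                    [augment(im, cfg.augment, int(s)) for im, s in zip(imgs, seeds)]
                )
            x = backbone.prepare(imgs)
            logits, cache = backbone.forward_logits(x)
            loss, dz = bce_with_logits(logits, y_train[idx])
            backbone.backward(dz, cache)
            opt.step(backbone)
            epoch_loss += loss
            n_batches += 1
        val_loss, val_acc = _eval_loss_acc(backbone, val_images, y_val)
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_loss - cfg.es_min_delta:
            best_loss = val_loss
            best_weights = backbone.get_weights()
            bad = 0
        else:
            bad += 1
            if bad > cfg.es_patience:
                log.append({"early_stop": True, "epoch": epoch})
                break
    backbone.set_weights(best_weights)
    return best_weights, log


# ---------------------------------------------------------------------------
# Random-forest head
# ---------------------------------------------------------------------------


def fit_rf_head(
    backbone: TinyCNN,
    images: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> RandomForestClassifier:
    """Fit the random forest on pooled backbone feature vectors; its
    predicted probability for class 1 (IC) is the patch score."""
    y = np.asarray(labels)
    _check_two_classes(y, "random-forest training set")
    feats = backbone_features(backbone, images)
    rf = RandomForestClassifier(
        n_estimators=cfg.rf_n_trees,
        max_depth=cfg.rf_max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(feats, y)
    return rf


def backbone_features(backbone: TinyCNN, images: np.ndarray, batch: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(images), batch):
        out.append(backbone.features(images[i : i + batch]))
    return np.concatenate(out) if out else np.empty((0, backbone.feature_dim))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class ClassifierBundle:
    """Trained scorer: backbone weights + RF head + thresholds + provenance."""

    backbone: TinyCNN
    rf: RandomForestClassifier
    train_config: TrainConfig
    p0: float | None = None
    slide_threshold: float | None = None
    provenance: str = "master"

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    def score_images(self, images: np.ndarray) -> np.ndarray:
        """IC probabilities in [0, 1] (fraction-of-trees) per image."""
        feats = backbone_features(self.backbone, images)
        proba = self.rf.predict_proba(feats)
        col = list(self.rf.classes_).index(1)
        return proba[:, col]

    def require_p0(self) -> float:
        if self.p0 is None:
            raise StateError("bundle has no patch threshold P0; fit one first")
        return self.p0

    # -- persistence --------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "backbone.npz", **self.backbone.get_weights())
        joblib.dump(self.rf, out_dir / "rf.joblib")
        meta = {
            "p0": self.p0,
            "slide_threshold": self.slide_threshold,
            "provenance": self.provenance,
            "feature_dim": self.feature_dim,
            "train_config": self.train_config.to_dict(),
        }
        (out_dir / "bundle.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "ClassifierBundle":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "bundle.json").read_text())
        cfg = TrainConfig.from_dict(meta["train_config"])
        backbone = build_backbone(dataclasses.replace(cfg, init="random"))
        backbone.set_weights(dict(np.load(out_dir / "backbone.npz")))
        rf = joblib.load(out_dir / "rf.joblib")
        return cls(
            backbone=backbone,
            rf=rf,
            train_config=cfg,
            p0=meta["p0"],
            slide_threshold=meta["slide_threshold"],
            provenance=meta["provenance"],
        )


def train_bundle(
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
    *,
    provenance: str = "master",
    init_weights: dict[str, np.ndarray] | None = None,
) -> ClassifierBundle:
    """Train backbone + RF head and select P0 on the validation scores."""
    from .scoring import select_threshold

    backbone = build_backbone(cfg)
    if init_weights is not None:
        backbone.set_weights(init_weights)
    train_backbone(backbone, train_images, train_labels, val_images, val_labels, cfg)
    rf = fit_rf_head(backbone, train_images, train_labels, cfg)
    bundle = ClassifierBundle(backbone=backbone, rf=rf, train_config=cfg, provenance=provenance)
    val_scores = bundle.score_images(val_images)
    if len(np.unique(val_labels)) >= 2:
        fit = select_threshold(val_scores, np.asarray(val_labels), level="patch")
        bundle.p0 = fit.threshold
    return bundle


def predict_scores(
    bundle: ClassifierBundle,
    pairs: Sequence[slide_io.PatchPair],
    slide: slide_io.SlidePyramid,
) -> np.ndarray:
    """Score filtered patch pairs (their x5 context image is the network
    input), preserving order. Flagged pairs are a contract violation."""
    for p in pairs:
        if p.base.quality_flags:
            raise ContractError(
                f"pair at {p.center_xy} carries quality flags {set(p.base.quality_flags)}; "
                "only filtered pairs may be scored"
            )
    if not pairs:
        return np.empty(0)
    images = np.stack(
        [slide_io.read_patch(slide, p.center_xy, "x5") for p in pairs]
    )
    return bundle.score_images(images)


def calibrate(
    master: ClassifierBundle,
    target_train_images: np.ndarray,
    target_train_labels: np.ndarray,
    target_val_images: np.ndarray,
    target_val_labels: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    center_id: str = "target",
) -> ClassifierBundle:
    """Transfer-learn the master onto a target center.

    The master weights are the starting state (no layers frozen), training
    uses the same hyperparameters/strategy as the master phase, the RF
    head is refitted on the calibrated backbone's target features and a
    new P0 is selected on target validation data.
    """
    if master.backbone is None:
        raise StateError("master bundle has no backbone weights")
    cfg = cfg or master.train_config
    if (cfg.backbone_arch, cfg.input_size, cfg.channels) != (
        master.train_config.backbone_arch,
        master.train_config.input_size,
        master.train_config.channels,
    ):
        raise ConfigError("calibration must reuse the master architecture")
    bundle = train_bundle(
        target_train_images,
        target_train_labels,
        target_val_images,
        target_val_labels,
        cfg,
        provenance=f"calibrated({center_id})",
        init_weights=master.backbone.get_weights(),
    )
    if bundle.p0 is None:
        bundle.p0 = master.p0
    return bundle
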