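import dataclasses

import numpy as np
import pytest

from icdetect import slide_io
from icdetect.augment import AugmentConfig
from icdetect.classifier import (
    ClassifierBundle,
    TrainConfig,
    build_backbone,
    calibrate,
    fit_rf_head,
    predict_images,
    predict_scores,
    train_backbone,
    train_bundle,
)
from icdetect.errors import ConfigError, ContractError, DataError, StateError

# ---------------------------------------------------------------------------
# TrainConfig / build_backbone
# ---------------------------------------------------------------------------


def test_frozen_layers_forbidden():
    with pytest.raises(ConfigError):
        TrainConfig(freeze_layers="conv1")


def test_default_lr_is_0_001():
    assert TrainConfig().initial_lr == 0.001


def test_unknown_arch_rejected():
    with pytest.raises(ConfigError):
        build_backbone(TrainConfig(backbone_arch="vgg"))


def test_resnet50_needs_torch():
    try:
        import torch  # noqa: F401

        pytest.skip("torch available; resnet50 path not exercised here")
    except ImportError:
        pass
    with pytest.raises(ConfigError, match="torch"):
        build_backbone(TrainConfig(backbone_arch="resnet50"))


def test_backbone_zero_image_finite_features():
    bb = build_backbone(TrainConfig(seed=1))
    feats = bb.features(np.zeros((2, 64, 64, 3), np.uint8))
    assert feats.shape == (2, bb.feature_dim)
    assert np.all(np.isfinite(feats))


def test_backbone_deterministic_inference():
    bb = build_backbone(TrainConfig(seed=2))
    img = np.random.default_rng(0).integers(0, 255, (1, 64, 64, 3)).astype(np.uint8)
    assert np.array_equal(bb.features(img), bb.features(img))


def test_feature_dim_matches_declared():
    bb = build_backbone(TrainConfig(channels=(4, 8, 16)))
    assert bb.feature_dim == 16
    assert bb.features(np.zeros((1, 64, 64, 3), np.uint8)).shape[1] == 16


def test_larger_inputs_are_block_averaged():
    bb = build_backbone(TrainConfig(input_size=64))
    big = np.full((1, 256, 256, 3), 128, np.uint8)
    assert np.all(np.isfinite(bb.features(big)))
    with pytest.raises(ConfigError):
        bb.features(np.zeros((1, 100, 100, 3), np.uint8))


# ---------------------------------------------------------------------------
# train_backbone
# ---------------------------------------------------------------------------


def test_single_class_training_set_rejected(toy_set):
    (xt, yt), (xv, yv) = toy_set
    bb = build_backbone(TrainConfig())
    with pytest.raises(DataError):
        train_backbone(bb, xt, np.zeros_like(yt), xv, yv, TrainConfig())


def test_separable_toy_reaches_high_accuracy(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=10, es_patience=5, seed=0)
    bb = build_backbone(cfg)
    _, log = train_backbone(bb, xt, yt, xv, yv, cfg)
    acc = np.mean((predict_images(bb, xv) > 0.5) == (yv > 0.5))
    assert acc >= 0.95
    assert log[-1].get("epoch", 0) <= 10


def test_final_val_loss_not_worse_than_initial(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=5, seed=1)
    bb = build_backbone(cfg)
    _, log = train_backbone(bb, xt, yt, xv, yv, cfg)
    initial = log[0]["val_loss"]
    final = min(e["val_loss"] for e in log if "val_loss" in e)
    assert final <= initial


def test_patience_zero_stops_at_first_non_improving_epoch(toy_set):
    (xt, yt), (xv, yv) = toy_set
    # min_delta of 10 makes every epoch "non-improving" by definition
    cfg = TrainConfig(max_epochs=8, es_patience=0, es_min_delta=10.0, seed=0)
    bb = build_backbone(cfg)
    _, log = train_backbone(bb, xt, yt, xv, yv, cfg)
    epochs_run = [e["epoch"] for e in log if "train_loss" in e]
    assert epochs_run == [1]  # stopped right after the first epoch
    assert log[-1].get("early_stop") is True


def test_training_reproducible(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=3, seed=7, augment=AugmentConfig.default_training())
    bb1 = build_backbone(cfg)
    _, log1 = train_backbone(bb1, xt, yt, xv, yv, cfg)
    bb2 = build_backbone(cfg)
    _, log2 = train_backbone(bb2, xt, yt, xv, yv, cfg)
    v1 = [e["val_loss"] for e in log1 if "val_loss" in e]
    v2 = [e["val_loss"] for e in log2 if "val_loss" in e]
    assert v1 == pytest.approx(v2, abs=1e-6)


def test_max_epochs_zero_is_noop(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=0, seed=0)
    bb = build_backbone(cfg)
    before = bb.get_weights()
    weights, log = train_backbone(bb, xt, yt, xv, yv, cfg)
    assert log == []
    for k in before:
        assert np.array_equal(weights[k], before[k])


# ---------------------------------------------------------------------------
# Random-forest head
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_backbone(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=5, seed=0)
    bb = build_backbone(cfg)
    train_backbone(bb, xt, yt, xv, yv, cfg)
    return bb, cfg


def test_rf_single_class_rejected(toy_set, toy_backbone):
    (xt, yt), _ = toy_set
    bb, cfg = toy_backbone
    with pytest.raises(DataError):
        fit_rf_head(bb, xt, np.ones_like(yt), cfg)


def test_rf_duplicate_training_point_scored_on_own_class(toy_set, toy_backbone):
    (xt, yt), _ = toy_set
    bb, cfg = toy_backbone
    rf = fit_rf_head(bb, xt, yt, cfg)
    feats = bb.features(xt[:20])
    proba = rf.predict_proba(feats)[:, list(rf.classes_).index(1)]
    for p, y in zip(proba, yt[:20]):
        assert (p >= 0.5) == (y == 1)


def test_rf_probabilities_in_unit_interval(toy_set, toy_backbone):
    (xt, yt), (xv, _) = toy_set
    bb, cfg = toy_backbone
    rf = fit_rf_head(bb, xt, yt, cfg)
    proba = rf.predict_proba(bb.features(xv))
    assert np.all(proba >= 0) and np.all(proba <= 1)


def test_rf_beats_chance_on_synthetic_holdout():
    from icdetect.synthetic import REFERENCE_STYLE, render_patch_dataset

    xt, yt = render_patch_dataset(300, 0.5, REFERENCE_STYLE, seed=1)
    xh, yh = render_patch_dataset(200, 0.5, REFERENCE_STYLE, seed=2)
    cfg = TrainConfig(max_epochs=4, seed=0)
    bb = build_backbone(cfg)
    train_backbone(bb, xt, yt, xh[:50], yh[:50], cfg)
    rf = fit_rf_head(bb, xt, yt, cfg)
    proba = rf.predict_proba(bb.features(xh))[:, list(rf.classes_).index(1)]
    acc = np.mean((proba > 0.5) == (yh > 0.5))
    assert acc > 0.5


# ---------------------------------------------------------------------------
# Bundle, predict_scores, calibrate
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_bundle(toy_set):
    (xt, yt), (xv, yv) = toy_set
    cfg = TrainConfig(max_epochs=5, seed=0)
    return train_bundle(xt, yt, xv, yv, cfg)


def test_bundle_scores_in_range_and_ordered(toy_set, toy_bundle):
    _, (xv, yv) = toy_set
    scores = toy_bundle.score_images(xv)
    assert scores.shape == (len(xv),)
    assert np.all((scores >= 0) & (scores <= 1))
    assert scores[yv == 1].mean() > scores[yv == 0].mean()


def test_bundle_p0_selected(toy_bundle):
    assert toy_bundle.p0 is not None
    assert 0.0 <= toy_bundle.p0 <= 1.0


def test_bundle_without_p0_raises():
    bundle = ClassifierBundle(
        backbone=build_backbone(TrainConfig()),
        rf=None,
        train_config=TrainConfig(),
    )
    with pytest.raises(StateError):
        bundle.require_p0()


def test_bundle_save_load_roundtrip(toy_set, toy_bundle, tmp_path):
    _, (xv, _) = toy_set
    toy_bundle.save(tmp_path / "bundle")
    loaded = ClassifierBundle.load(tmp_path / "bundle")
    assert loaded.p0 == toy_bundle.p0
    assert loaded.provenance == toy_bundle.provenance
    assert np.allclose(loaded.score_images(xv), toy_bundle.score_images(xv))


def test_predict_scores_order_and_determinism(toy_bundle):
    # interior centers: every x5 window sits fully inside the slide
    big = slide_io.pyramid_from_array(
        np.full((2048, 2048, 3), 200, np.uint8), "big_uniform", 0.44
    )
    pairs = [slide_io.make_pair("big_uniform", (c, c)) for c in (512, 1024, 1536)]
    s1 = predict_scores(toy_bundle, pairs, big)
    s2 = predict_scores(toy_bundle, pairs, big)
    assert len(s1) == 3
    assert np.array_equal(s1, s2)
    assert s1[0] == s1[1] == s1[2]  # identical uniform patches


def test_predict_scores_rejects_flagged_pairs(toy_bundle, uniform_slide):
    base = slide_io.PatchRecord(
        "uniform", (512, 512), "x20", quality_flags=frozenset({"no_tissue"})
    )
    ctx = slide_io.PatchRecord("uniform", (512, 512), "x5")
    pair = slide_io.PatchPair(base=base, context=ctx)
    with pytest.raises(ContractError):
        predict_scores(toy_bundle, [pair], uniform_slide)


def test_calibrate_zero_epochs_keeps_master_weights(toy_set, toy_bundle):
    (xt, yt), (xv, yv) = toy_set
    cfg = dataclasses.replace(toy_bundle.train_config, max_epochs=0)
    calibrated = calibrate(toy_bundle, xt, yt, xv, yv, cfg, center_id="c2")
    mw = toy_bundle.backbone.get_weights()
    cw = calibrated.backbone.get_weights()
    for k in mw:
        assert np.array_equal(mw[k], cw[k])
    assert calibrated.provenance == "calibrated(c2)"


def test_calibrate_on_same_distribution_not_worse(toy_set, toy_bundle):
    """Control: calibrating on the reference distribution itself is just
    continued training and must not hurt."""
    (xt, yt), (xv, yv) = toy_set
    cfg = dataclasses.replace(toy_bundle.train_config, max_epochs=3)
    calibrated = calibrate(toy_bundle, xt, yt, xv, yv, cfg)
    acc_master = np.mean(
        (toy_bundle.score_images(xv) > toy_bundle.require_p0()) == (yv > 0.5)
    )
    acc_cal = np.mean(
        (calibrated.score_images(xv) > calibrated.require_p0()) == (yv > 0.5)
    )
    assert acc_cal >= acc_master - 0.05


def test_calibrate_rejects_architecture_change(toy_set, toy_bundle):
    (xt, yt), (xv, yv) = toy_set
    cfg = dataclasses.replace(toy_bundle.train_config, channels=(4, 8, 16))
    with pytest.raises(ConfigError):
        calibrate(toy_bundle, xt, yt, xv, yv, cfg)
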