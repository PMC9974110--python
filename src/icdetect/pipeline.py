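"""Orchestration: patient-level dataset splitting, labeled patch
extraction, end-to-end slide inference and the two-phase master ->
calibrated training workflow.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.prepared import prep

from . import filtering, slide_io
from .classifier import ClassifierBundle, TrainConfig, calibrate, predict_scores, train_bundle
from .errors import DataError, SplitError
from .filtering import FilterConfig
from .scoring import SlideScoreReport, classify_slide, evaluate, slide_score
from .synthetic import load_cohort_manifest

@dataclass
class RunConfig:
    """Everything needed to re-execute a run, serialized next to its
    outputs (YAML) for reproducibility."""

    output_dir: str = "."
    cohort_manifests: dict | None = None  # name -> manifest path
    filter_config: FilterConfig | None = None
    train_config: TrainConfig | None = None
    split_ratio: float = 0.8
    seed: int = 0
    thresholds: str | dict = "fit"  # "fit" or {"p0": .., "slide": ..}
    verbosity: str = "info"

    def to_dict(self) -> dict:
        import dataclasses as _dc

        return {
            "output_dir": self.output_dir,
            "cohort_manifests": self.cohort_manifests,
            "filter_config": _dc.asdict(self.filter_config) if self.filter_config else None,
            "train_config": self.train_config.to_dict() if self.train_config else None,
            "split_ratio": self.split_ratio,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "verbosity": self.verbosity,
        }

    def save(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


#: CLI exit codes for `infer`
EXIT_REST, EXIT_IC, EXIT_NO_EPITHELIUM = 0, 2, 3

#: cohorts up to this many patients are split by exact subset-sum search
_EXACT_SPLIT_MAX_PATIENTS = 20


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Whole-patient assignment into train/test partitions."""

    assignment: dict[str, str]  # patient_id -> "train" | "test"
    realized_ratio: float  # achieved train-slide fraction
    seed: int

    def patients(self, part: str) -> list[str]:
        return sorted(p for p, a in self.assignment.items() if a == part)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def split_by_patient(manifest: pd.DataFrame, ratio: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Assign whole patients to train/test so that the train-slide fraction
    is as close as possible to ``ratio``.

    For cohorts of up to 20 patients the optimum over all whole-patient
    assignments is found by subset-sum dynamic programming (patients first
    shuffled by ``seed`` so ties are broken reproducibly but not always
    identically across seeds); larger cohorts use a randomized greedy pass.
    Both partitions are always nonempty.
    """
    if manifest.empty:
        raise SplitError("empty manifest")
    counts = manifest.groupby("patient_id")["slide_id"].nunique()
    patients = list(counts.index)
    if len(patients) < 2:
        raise SplitError("patient-level split needs >= 2 patients")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    sizes = [int(counts[p]) for p in order]
    total = sum(sizes)
    target = ratio * total

    if len(order) <= _EXACT_SPLIT_MAX_PATIENTS:
        train_idx = _exact_subset(sizes, target)
    else:
        train_idx = _greedy_subset(sizes, target)
    # nonempty partitions
    if len(train_idx) == 0:
        train_idx = {int(np.argmin(np.abs(np.asarray(sizes) - target)))}
    if len(train_idx) == len(order):
        train_idx.discard(min(train_idx, key=lambda i: sizes[i]))

    assignment = {p: ("train" if i in train_idx else "test") for i, p in enumerate(order)}
    realized = sum(sizes[i] for i in train_idx) / total
    return DatasetSplit(assignment=assignment, realized_ratio=realized, seed=seed)


def _exact_subset(sizes: list[int], target: float) -> set[int]:
    """Subset of indices whose size-sum is closest to target (excluding the
    empty and full subsets), via subset-sum DP with parent pointers."""
    n = len(sizes)
    total = sum(sizes)
    # reachable[s] = (prev_sum, idx added) for one subset reaching sum s
    reachable: dict[int, tuple[int, int] | None] = {0: None}
    for i, c in enumerate(sizes):
        for s in sorted(reachable, reverse=True):
            t = s + c
            if t not in reachable:
                reachable[t] = (s, i)
    candidates = [s for s in reachable if 0 < s < total]
    if not candidates:  # n >= 2 with positive sizes always leaves a proper subset
        candidates = [s for s in reachable if s > 0]
    best = min(candidates, key=lambda s: (abs(s - target), -s))
    out: set[int] = set()
    s = best
    while reachable[s] is not None:
        s_prev, i = reachable[s]  # type: ignore[misc]
        out.add(i)
        s = s_prev
    return out


def _greedy_subset(sizes: list[int], target: float) -> set[int]:
    out: set[int] = set()
    acc = 0
    for i, c in enumerate(sizes):
        if abs(acc + c - target) <= abs(acc - target):
            out.add(i)
            acc += c
    return out


def holdout_validation_patients(
    train_patients: list[str], fraction: float = 0.1, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Carve a validation subset out of the training patients (>= 1
    patient), at patient level, for early stopping / threshold fitting."""
    if len(train_patients) < 2:
        raise SplitError("need >= 2 training patients to carve a validation set")
    rng = np.random.default_rng(seed)
    order = [train_patients[i] for i in rng.permutation(len(train_patients))]
    n_val = max(1, int(round(fraction * len(order))))
    return sorted(order[n_val:]), sorted(order[:n_val])


# ---------------------------------------------------------------------------
# Labeled patch extraction
# ---------------------------------------------------------------------------


def label_pairs(
    pairs: list[slide_io.PatchPair], annotations: list[slide_io.RoiAnnotation]
) -> list[slide_io.PatchPair]:
    """Label each pair by its center point: IC if the center lies in any
    IC-class polygon, else Rest."""
    ic_polys = [prep(a.shapely()) for a in annotations if a.binary_class == "IC"]
    from shapely.geometry import Point

    out = []
    for pair in pairs:
        pt = Point(*pair.center_xy)
        label = "IC" if any(p.contains(pt) for p in ic_polys) else "Rest"
        out.append(slide_io.make_pair(pair.base.slide_id, pair.center_xy, label=label))
    return out


def extract_slide_dataset(
    slide: slide_io.SlidePyramid,
    annotations: list[slide_io.RoiAnnotation],
    cfg: FilterConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[slide_io.PatchPair]]:
    """Filter a slide and return (x5 context images, labels{0,1}, pairs)."""
    kept, _ = filtering.extract_pairs(slide, cfg)
    labeled = label_pairs(kept, annotations)
    if not labeled:
        return np.empty((0, 256, 256, 3), np.uint8), np.empty(0, np.int64), []
    images = np.stack([slide_io.read_patch(slide, p.center_xy, "x5") for p in labeled])
    labels = np.array([1 if p.base.label == "IC" else 0 for p in labeled])
    return images, labels, labeled


# ---------------------------------------------------------------------------
# Slide inference
# ---------------------------------------------------------------------------


def run_inference(
    slide_path: str | Path,
    bundle: ClassifierBundle,
    filter_cfg: FilterConfig | None = None,
    *,
    heatmap_path: str | Path | None = None,
) -> SlideScoreReport:
    """Fig-1 style end-to-end inference on one slide: filter -> pair
    extraction -> patch scores -> S_IC -> slide call (+ optional heatmap).

    A slide with no scoreable epithelium yields slide_call "no_epithelium"
    with ``s_ic`` None.
    """
    p0 = bundle.require_p0()
    slide_threshold = bundle.slide_threshold
    if slide_threshold is None:
        raise DataError("bundle has no slide threshold")
    filter_cfg = filter_cfg or FilterConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    slide = slide_path if isinstance(slide_path, slide_io.SlidePyramid) else slide_io.open_slide(slide_path)
    kept, report = filtering.extract_pairs(slide, filter_cfg)
    timings["filtering"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    scores = predict_scores(bundle, kept, slide)
    timings["inference"] = time.perf_counter() - t0

    if len(kept) == 0:
        return SlideScoreReport(
            slide_id=slide.slide_id,
            patch_centers=[],
            patch_scores=[],
            p0=p0,
            slide_threshold=slide_threshold,
            s_ic=None,
            slide_call="no_epithelium",
            n_patches=0,
            filter_report=report.to_dict(),
            timings_s=timings,
        )
    s_ic = slide_score(scores, p0)
    call = classify_slide(s_ic, slide_threshold)
    out = SlideScoreReport(
        slide_id=slide.slide_id,
        patch_centers=[p.center_xy for p in kept],
        patch_scores=[float(s) for s in scores],
        p0=p0,
        slide_threshold=slide_threshold,
        s_ic=s_ic,
        slide_call=call,
        n_patches=len(kept),
        filter_report=report.to_dict(),
        timings_s=timings,
    )
    if heatmap_path is not None:
        t0 = time.perf_counter()
        scored = [
            slide_io.PatchRecord(slide.slide_id, p.center_xy, "x20", score=float(s))
            for p, s in zip(kept, scores)
        ]
        slide_io.render_heatmap(slide, scored, heatmap_path)
        out.timings_s["heatmap"] = time.perf_counter() - t0
    return out


# ---------------------------------------------------------------------------
# Two-phase workflow on slide cohorts
# ---------------------------------------------------------------------------


def _collect(
    manifest: pd.DataFrame,
    patients: list[str],
    filter_cfg: FilterConfig,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str, np.ndarray]]]:
    """Extract labeled x5 patches from every slide of the given patients.

    Returns stacked images/labels and a per-slide (id, class, n_patches) list."""
    imgs, labs, slides = [], [], []
    rows = manifest[manifest["patient_id"].isin(patients)]
    for _, row in rows.iterrows():
        slide = slide_io.open_slide(row["slide_path"])
        anns = slide_io.load_annotations(row["annotation_path"])
        x, y, pairs = extract_slide_dataset(slide, anns, filter_cfg)
        imgs.append(x)
        labs.append(y)
        slides.append((row["slide_id"], row["class"], len(y)))
    images = np.concatenate(imgs) if imgs else np.empty((0, 256, 256, 3), np.uint8)
    labels = np.concatenate(labs) if labs else np.empty(0, np.int64)
    return images, labels, slides


def _slide_level_eval(
    manifest: pd.DataFrame,
    patients: list[str],
    bundle: ClassifierBundle,
    filter_cfg: FilterConfig,
) -> tuple[list[str], list[str]]:
    preds, truths = [], []
    rows = manifest[manifest["patient_id"].isin(patients)]
    for _, row in rows.iterrows():
        rep = run_inference(row["slide_path"], bundle, filter_cfg)
        if rep.slide_call == "no_epithelium":
            continue
        preds.append(rep.slide_call)
        truths.append(row["class"])
    return preds, truths


def run_two_phase(
    reference_manifest: pd.DataFrame | str | Path,
    target_manifest: pd.DataFrame | str | Path,
    train_cfg: TrainConfig,
    *,
    filter_cfg: FilterConfig | None = None,
    split_ratio: float = 0.8,
    target_cap_fraction: float = 0.2,
    seed: int = 0,
    with_slide_level: bool = True,
) -> dict:
    """Train the master on the reference cohort, calibrate on the (much
    smaller) target cohort, evaluate both models on both test sets.

    The target training set is capped at ``target_cap_fraction`` of the
    reference training set size (subsampled deterministically when
    larger). Returns a nested dict: grid[model][test_set] -> EvalMetrics
    plus bundles, splits and sizes.
    """
    filter_cfg = filter_cfg or FilterConfig()
    if not isinstance(reference_manifest, pd.DataFrame):
        reference_manifest = load_cohort_manifest(reference_manifest)
    if not isinstance(target_manifest, pd.DataFrame):
        target_manifest = load_cohort_manifest(target_manifest)

    datasets = {}
    splits = {}
    for name, manifest in (("reference", reference_manifest), ("target", target_manifest)):
        split = split_by_patient(manifest, ratio=split_ratio, seed=seed)
        tr_patients, val_patients = holdout_validation_patients(
            split.patients("train"), seed=seed
        )
        parts = {}
        for part, pats in (
            ("train", tr_patients),
            ("val", val_patients),
            ("test", split.patients("test")),
        ):
            parts[part] = _collect(manifest, pats, filter_cfg)
        datasets[name] = parts
        splits[name] = split

    ref_train_n = len(datasets["reference"]["train"][1])
    tgt_x, tgt_y, tgt_slides = datasets["target"]["train"]
    cap = max(int(target_cap_fraction * ref_train_n), 2)
    if len(tgt_y) > cap:
        # stratified subsample so the capped set keeps both classes
        rng = np.random.default_rng(seed)
        keep_parts = []
        for cls in np.unique(tgt_y):
            idx = np.flatnonzero(tgt_y == cls)
            n_cls = max(1, int(round(cap * len(idx) / len(tgt_y))))
            keep_parts.append(rng.permutation(idx)[:n_cls])
        keep = np.sort(np.concatenate(keep_parts))
        datasets["target"]["train"] = (tgt_x[keep], tgt_y[keep], tgt_slides)

    master = train_bundle(
        datasets["reference"]["train"][0],
        datasets["reference"]["train"][1],
        datasets["reference"]["val"][0],
        datasets["reference"]["val"][1],
        train_cfg,
        provenance="master",
    )
    calibrated = calibrate(
        master,
        datasets["target"]["train"][0],
        datasets["target"]["train"][1],
        datasets["target"]["val"][0],
        datasets["target"]["val"][1],
        train_cfg,
        center_id="target",
    )

    grid: dict[str, dict[str, dict]] = {}
    for model_name, bundle in (("master", master), ("calibrated", calibrated)):
        grid[model_name] = {}
        for test_name in ("reference", "target"):
            x, y, _ = datasets[test_name]["test"]
            scores = bundle.score_images(x)
            pred = scores > bundle.require_p0()
            grid[model_name][test_name] = evaluate(pred.astype(int), y, level="patch").to_dict()

    result = {
        "grid": grid,
        "sizes": {
            "reference_train": ref_train_n,
            "target_train": len(datasets["target"]["train"][1]),
        },
        "splits": {k: v.assignment for k, v in splits.items()},
        "master": master,
        "calibrated": calibrated,
    }

    if with_slide_level:
        # fit slide thresholds on validation-slide scores where possible
        for bundle in (master, calibrated):
            if bundle.slide_threshold is None:
                bundle.slide_threshold = 0.1
        slide_grid = {}
        for model_name, bundle in (("master", master), ("calibrated", calibrated)):
            slide_grid[model_name] = {}
            for test_name, manifest in (
                ("reference", reference_manifest),
                ("target", target_manifest),
            ):
                pats = splits[test_name].patients("test")
                preds, truths = _slide_level_eval(manifest, pats, bundle, filter_cfg)
                if preds and len(set(truths)) > 0:
                    slide_grid[model_name][test_name] = evaluate(
                        preds, truths, level="slide"
                    ).to_dict()
                else:
                    slide_grid[model_name][test_name] = None
        result["slide_grid"] = slide_grid
    return result


# ---------------------------------------------------------------------------
# Desk-scale calibration experiment on directly rendered patches
# ---------------------------------------------------------------------------


def calibration_experiment(
    seed: int = 0,
    *,
    n_reference_train: int = 2000,
    n_target_train: int = 200,
    n_val: int = 200,
    n_test: int = 400,
    max_epochs: int = 14,
    input_size: int = 64,
    reference_style=None,
    target_style=None,
    reference_diversity_sd: float = 0.35,
    target_diversity_sd: float = 0.25,
) -> dict:
    """The scaled-down two-center transfer experiment on directly rendered
    epithelial patches (no slide I/O), reproducing the qualitative
    degradation/recovery pattern:

    master(reference test) high; master(target test) degraded;
    calibrated(target test) recovered; calibrated(reference test) below
    master(reference test); target training data <= 1/10 of reference.

    Returns the four accuracies and set sizes.
    """
    from .synthetic import REFERENCE_STYLE, TARGET_STYLE, render_patch_dataset

    ref_style = reference_style or REFERENCE_STYLE
    tgt_style = target_style or TARGET_STYLE

    # the target cohort is less pathologically diverse than the reference
    # one (narrower per-patch texture spread), as is typical when a large
    # referral archive is compared with a single smaller center
    sets = {
        "ref_train": render_patch_dataset(n_reference_train, 0.5, ref_style, seed * 13 + 1, size=input_size, texture_diversity_sd=reference_diversity_sd),
        "ref_val": render_patch_dataset(n_val, 0.5, ref_style, seed * 13 + 2, size=input_size, texture_diversity_sd=reference_diversity_sd),
        "ref_test": render_patch_dataset(n_test, 0.5, ref_style, seed * 13 + 3, size=input_size, texture_diversity_sd=reference_diversity_sd),
        "tgt_train": render_patch_dataset(n_target_train, 0.5, tgt_style, seed * 13 + 4, size=input_size, texture_diversity_sd=target_diversity_sd),
        "tgt_val": render_patch_dataset(n_val, 0.5, tgt_style, seed * 13 + 5, size=input_size, texture_diversity_sd=target_diversity_sd),
        "tgt_test": render_patch_dataset(n_test, 0.5, tgt_style, seed * 13 + 6, size=input_size, texture_diversity_sd=target_diversity_sd),
    }
    from .augment import AugmentConfig as _AC

    cfg = TrainConfig(
        max_epochs=max_epochs,
        input_size=input_size,
        seed=seed,
        es_patience=3,
        augment=_AC.default_training(),
    )
    master = train_bundle(*sets["ref_train"], *sets["ref_val"], cfg, provenance="master")
    calibrated = calibrate(master, *sets["tgt_train"], *sets["tgt_val"], cfg)

    def acc(bundle: ClassifierBundle, key: str) -> float:
        x, y = sets[key]
        pred = (bundle.score_images(x) > bundle.require_p0()).astype(int)
        return evaluate(pred, y, level="patch").accuracy

    return {
        "master_on_reference": acc(master, "ref_test"),
        "master_on_target": acc(master, "tgt_test"),
        "calibrated_on_target": acc(calibrated, "tgt_test"),
        "calibrated_on_reference": acc(calibrated, "ref_test"),
        "n_reference_train": n_reference_train,
        "n_target_train": n_target_train,
        "n_test": n_test,
    }
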