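"""Pyramidal slide, annotation, patch-manifest and heatmap I/O.

This module owns every coordinate convention in the package:

* all patch addresses are **level-0 pixels**, 0-based;
* a patch is addressed by its *center*; the x20 window of a patch centered
  at ``(cx, cy)`` is the half-open square ``[cx-128, cx+128) x [cy-128, cy+128)``;
* "zoom x20" is pyramid level 0 of whatever file is opened, "x5" is the
  downsample-4 level; zoom is relative, not a physical magnification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.transform import downscale_local_mean

from .errors import (
    BoundsError,
    ContractError,
    FormatError,
    GeometryError,
    IntegrityError,
)

#: Pyramid layout used throughout the package: level 0 ("x20"), the
#: downsample-4 level ("x5") and a downsample-16 thumbnail.
LEVEL_DOWNSAMPLES = (1, 4, 16)

#: Patch edge length in pixels, at every zoom.
PATCH_SIZE = 256

#: Grey value used to pad windows that extend beyond the slide
#: (near-white, matching the synthetic background range).
PAD_VALUE = 245

#: Diagnosis labels that map to the positive (IC) class.
IC_LABELS = frozenset(
    {"invasive ductal carcinoma", "invasive lobular carcinoma", "mucinous carcinoma"}
)

QUALITY_FLAGS = ("blur", "no_tissue", "no_nuclei")


def label_to_class(label: str) -> str:
    """Map a free-text diagnosis label to the binary class {IC, Rest}."""
    return "IC" if label.strip().lower() in IC_LABELS else "Rest"


# ---------------------------------------------------------------------------
# SlidePyramid
# ---------------------------------------------------------------------------


@dataclass
class LevelInfo:
    downsample: float
    width: int
    height: int


class SlidePyramid:
    """A multi-level tiled image with lazy per-level pixel access.

    Either backed by a multi-page TIFF on disk (see :func:`open_slide`)
    or by in-memory arrays (as produced by the synthetic generator).
    """

    def __init__(
        self,
        slide_id: str,
        levels: Sequence[LevelInfo],
        resolution_um_per_px: float,
        *,
        arrays: Sequence[np.ndarray] | None = None,
        path: Path | None = None,
    ):
        if arrays is None and path is None:
            raise ValueError("SlidePyramid needs arrays or a path")
        self.slide_id = slide_id
        self.levels = list(levels)
        self.resolution_um_per_px = float(resolution_um_per_px)
        self._path = Path(path) if path is not None else None
        self._cache: dict[int, np.ndarray] = (
            {i: np.asarray(a) for i, a in enumerate(arrays)} if arrays is not None else {}
        )
        downs = [lv.downsample for lv in self.levels]
        if downs[0] != 1 or any(b <= a for a, b in zip(downs, downs[1:])):
            raise FormatError(f"downsamples must increase strictly from 1, got {downs}")
        w0, h0 = self.levels[0].width, self.levels[0].height
        for lv in self.levels:
            if abs(lv.width - w0 / lv.downsample) > 1 or abs(lv.height - h0 / lv.downsample) > 1:
                raise FormatError(
                    f"level {lv.downsample}x size {lv.width}x{lv.height} inconsistent "
                    f"with level 0 {w0}x{h0}"
                )

    # -- basic geometry -----------------------------------------------------
    @property
    def width(self) -> int:
        return self.levels[0].width

    @property
    def height(self) -> int:
        return self.levels[0].height

    def level_for_downsample(self, downsample: float) -> int:
        for i, lv in enumerate(self.levels):
            if lv.downsample == downsample:
                return i
        raise FormatError(f"slide {self.slide_id!r} has no level at downsample {downsample}")

    # -- pixels -------------------------------------------------------------
    def level_image(self, level: int) -> np.ndarray:
        """Full RGB uint8 image of one pyramid level (cached after first read)."""
        if level not in self._cache:
            with tifffile.TiffFile(self._path) as tif:
                self._cache[level] = tif.pages[level].asarray()
        return self._cache[level]


def build_levels(level0: np.ndarray) -> list[np.ndarray]:
    """Derive the downsample-4 and -16 levels of a level-0 image by 4x4
    block averaging (applied twice), rounded to uint8."""
    out = [np.ascontiguousarray(level0)]
    cur = level0.astype(np.float64)
    for _ in range(2):
        cur = downscale_local_mean(cur, (4, 4, 1))
        out.append(np.rint(cur).astype(np.uint8))
    return out


def write_pyramid(
    path: str | Path,
    level0: np.ndarray,
    slide_id: str,
    resolution_um_per_px: float,
) -> list[np.ndarray]:
    """Write a 3-level pyramidal tiled TIFF; returns the level arrays."""
    arrays = build_levels(level0)
    meta = {
        "slide_id": slide_id,
        "resolution_um_per_px": resolution_um_per_px,
        "downsamples": list(LEVEL_DOWNSAMPLES),
    }
    with tifffile.TiffWriter(path) as tw:
        for i, arr in enumerate(arrays):
            tw.write(
                arr,
                tile=(256, 256),
                photometric="rgb",
                description=json.dumps(meta) if i == 0 else None,
            )
    return arrays


def pyramid_from_array(
    level0: np.ndarray, slide_id: str, resolution_um_per_px: float
) -> SlidePyramid:
    """Wrap a level-0 RGB array in an in-memory 3-level pyramid."""
    arrays = build_levels(level0)
    levels = [
        LevelInfo(d, a.shape[1], a.shape[0]) for d, a in zip(LEVEL_DOWNSAMPLES, arrays)
    ]
    return SlidePyramid(slide_id, levels, resolution_um_per_px, arrays=arrays)


def open_slide(path: str | Path) -> SlidePyramid:
    """Open a pyramidal TIFF written by :func:`write_pyramid`.

    Raises FileNotFoundError for a missing file and :class:`FormatError`
    for single-level or otherwise unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            n = len(tif.pages)
            if n < 2:
                raise FormatError(f"{path} is not pyramidal ({n} level)")
            sizes = [(p.imagewidth, p.imagelength) for p in tif.pages]
            desc = tif.pages[0].description
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises a zoo of exceptions
        raise FormatError(f"cannot read {path}: {exc}") from exc
    slide_id, res = path.stem, 0.44
    downsamples = [sizes[0][0] / w for w, _ in sizes]
    if desc:
        try:
            meta = json.loads(desc)
            slide_id = meta.get("slide_id", slide_id)
            res = float(meta.get("resolution_um_per_px", res))
            downsamples = [float(d) for d in meta.get("downsamples", downsamples)]
        except (json.JSONDecodeError, TypeError, ValueError):
            pass
    levels = [LevelInfo(d, w, h) for d, (w, h) in zip(downsamples, sizes)]
    return SlidePyramid(slide_id, levels, res, path=path)


# ---------------------------------------------------------------------------
# Patch records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchRecord:
    """A 256x256 patch addressed by its level-0 center."""

    slide_id: str
    center_xy: tuple[int, int]
    zoom: str  # "x20" | "x5"
    label: str = "unlabeled"  # "IC" | "Rest" | "unlabeled"
    quality_flags: frozenset = field(default_factory=frozenset)
    score: float | None = None
    size_px: int = PATCH_SIZE

    def __post_init__(self):
        if self.zoom not in ("x20", "x5"):
            raise ContractError(f"unknown zoom {self.zoom!r}")
        if self.score is not None:
            if not (0.0 <= self.score <= 1.0):
                raise IntegrityError(f"score {self.score} outside [0, 1]")
            if self.quality_flags:
                raise IntegrityError("a scored record must have empty quality_flags")
        if not set(self.quality_flags) <= set(QUALITY_FLAGS):
            raise IntegrityError(f"unknown quality flags {set(self.quality_flags)}")


@dataclass(frozen=True)
class PatchPair:
    """An x20 base patch and its same-center x5 context patch."""

    base: PatchRecord
    context: PatchRecord

    def __post_init__(self):
        if self.base.center_xy != self.context.center_xy:
            raise IntegrityError("base and context centers differ")
        if (self.base.zoom, self.context.zoom) != ("x20", "x5"):
            raise IntegrityError("pair must be (x20 base, x5 context)")

    @property
    def center_xy(self) -> tuple[int, int]:
        return self.base.center_xy


def make_pair(slide_id: str, center_xy: tuple[int, int], label: str = "unlabeled") -> PatchPair:
    cx, cy = int(center_xy[0]), int(center_xy[1])
    return PatchPair(
        base=PatchRecord(slide_id, (cx, cy), "x20", label=label),
        context=PatchRecord(slide_id, (cx, cy), "x5", label=label),
    )


# ---------------------------------------------------------------------------
# Patch reading
# ---------------------------------------------------------------------------


def _crop_padded(img: np.ndarray, x0: int, y0: int, size: int) -> tuple[np.ndarray, float]:
    """Crop a half-open window [x0, x0+size) x [y0, y0+size), padding parts
    outside the image with PAD_VALUE. Returns (crop, padded_fraction)."""
    h, w = img.shape[:2]
    out = np.full((size, size, 3), PAD_VALUE, dtype=img.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + size, w), min(y0 + size, h)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
        inside = (sx1 - sx0) * (sy1 - sy0)
    else:
        inside = 0
    return out, 1.0 - inside / (size * size)


def read_patch(
    slide: SlidePyramid,
    center_xy: tuple[int, int],
    zoom: str,
    *,
    return_pad_fraction: bool = False,
):
    """Read the 256x256 RGB patch centered at ``center_xy`` (level-0 px).

    x20 reads the level-0 window ``[cx-128, cx+128)``; x5 reads the
    1024x1024 level-0 window through the downsample-4 level (whose pixels
    are 4x4 block means of level 0). Out-of-slide parts are padded with
    :data:`PAD_VALUE`; the padded fraction is available on request.
    """
    cx, cy = int(center_xy[0]), int(center_xy[1])
    if not (0 <= cx < slide.width and 0 <= cy < slide.height):
        raise BoundsError(
            f"center {(cx, cy)} outside slide {slide.slide_id!r} "
            f"({slide.width}x{slide.height})"
        )
    half = PATCH_SIZE // 2
    if zoom == "x20":
        img = slide.level_image(0)
        crop, pad = _crop_padded(img, cx - half, cy - half, PATCH_SIZE)
    elif zoom == "x5":
        lvl = slide.level_for_downsample(4)
        img = slide.level_image(lvl)
        # level-0 window [cx-512, cx+512) maps onto level-1 origin (cx-512)/4
        x0 = int(np.floor((cx - 4 * half) / 4))
        y0 = int(np.floor((cy - 4 * half) / 4))
        crop, pad = _crop_padded(img, x0, y0, PATCH_SIZE)
    else:
        raise ContractError(f"unknown zoom {zoom!r}")
    return (crop, pad) if return_pad_fraction else crop


# ---------------------------------------------------------------------------
# Annotations (GeoJSON)
# ---------------------------------------------------------------------------


@dataclass
class RoiAnnotation:
    """A labeled region-of-interest polygon in level-0 pixel coordinates."""

    polygon: np.ndarray  # (N, 2) float64 vertices, unclosed
    label: str
    binary_class: str = field(init=False)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise GeometryError("polygon needs >= 3 (x, y) vertices")
        shp = ShapelyPolygon(self.polygon)
        if not shp.is_valid or shp.area <= 0:
            raise GeometryError(f"polygon is not simple or has zero area: {self.label!r}")
        self.binary_class = label_to_class(self.label)

    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.polygon)


def save_annotations(annotations: Iterable[RoiAnnotation], path: str | Path) -> None:
    """Write annotations as a GeoJSON FeatureCollection (label property)."""
    features = []
    for ann in annotations:
        ring = ann.polygon.tolist()
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"label": ann.label},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def load_annotations(path: str | Path) -> list[RoiAnnotation]:
    """Load a GeoJSON FeatureCollection; vertices round-trip to < 1e-6 px."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    out = []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise FormatError(f"feature {i}: expected Polygon, got {geom.get('type')!r}")
        ring = np.asarray(geom["coordinates"][0], dtype=np.float64)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        label = str(feat.get("properties", {}).get("label", ""))
        out.append(RoiAnnotation(polygon=ring, label=label))
    return out


# ---------------------------------------------------------------------------
# Patch manifests (TSV)
# ---------------------------------------------------------------------------

_MANIFEST_COLS = [
    "slide_id",
    "center_x",
    "center_y",
    "size_px",
    "zoom",
    "label",
    "quality_flags",
    "score",
]


def _records_to_frame(records: Sequence[PatchRecord]) -> pd.DataFrame:
    rows = [
        {
            "slide_id": r.slide_id,
            "center_x": r.center_xy[0],
            "center_y": r.center_xy[1],
            "size_px": r.size_px,
            "zoom": r.zoom,
            "label": r.label,
            "quality_flags": ",".join(sorted(r.quality_flags)),
            "score": "" if r.score is None else repr(float(r.score)),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    return df.sort_values(["slide_id", "center_y", "center_x", "zoom"], kind="stable").reset_index(
        drop=True
    )


def _check_duplicates(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=["slide_id", "center_x", "center_y", "zoom"])
    if dup.any():
        rows = df[dup].head(3).to_dict("records")
        raise IntegrityError(f"duplicate patch rows in {path}: {rows}")


def write_patch_manifest(records: Sequence[PatchRecord], path: str | Path) -> None:
    """Write records as a TSV sorted by (slide_id, center_y, center_x)."""
    df = _records_to_frame(records)
    _check_duplicates(df, path)
    df.to_csv(path, sep="\t", index=False)


def read_patch_manifest(path: str | Path) -> list[PatchRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _MANIFEST_COLS:
        raise FormatError(f"{path}: unexpected manifest columns {list(df.columns)}")
    _check_duplicates(df, path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PatchRecord(
                slide_id=row.slide_id,
                center_xy=(int(row.center_x), int(row.center_y)),
                zoom=row.zoom,
                label=row.label,
                quality_flags=frozenset(f for f in row.quality_flags.split(",") if f),
                score=None if row.score == "" else float(row.score),
                size_px=int(row.size_px),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------


def score_to_rgb(score: float) -> tuple[int, int, int]:
    """Blue (score 0) -> red (score 1) linear ramp."""
    s = float(np.clip(score, 0.0, 1.0))
    return (int(round(255 * s)), 0, int(round(255 * (1.0 - s))))


def render_heatmap(
    slide: SlidePyramid,
    records: Sequence[PatchRecord],
    out_path: str | Path,
    *,
    alpha: float = 0.55,
) -> np.ndarray:
    """Overlay per-patch scores on the downsample-16 thumbnail and save a PNG.

    Each scored x20 patch footprint (16x16 thumbnail px) is blended with the
    blue->red ramp color; unscored tissue is left untouched.
    """
    for r in records:
        if r.slide_id != slide.slide_id:
            raise IntegrityError(
                f"record from slide {r.slide_id!r} passed with slide {slide.slide_id!r}"
            )
    lvl = slide.level_for_downsample(16)
    thumb = slide.level_image(lvl).astype(np.float64).copy()
    h, w = thumb.shape[:2]
    cell = PATCH_SIZE // 16
    for r in records:
        if r.score is None or r.zoom != "x20":
            continue
        x0 = (r.center_xy[0] - PATCH_SIZE // 2) // 16
        y0 = (r.center_xy[1] - PATCH_SIZE // 2) // 16
        x1, y1 = min(x0 + cell, w), min(y0 + cell, h)
        x0, y0 = max(x0, 0), max(y0, 0)
        color = np.array(score_to_rgb(r.score), dtype=np.float64)
        thumb[y0:y1, x0:x1] = (1 - alpha) * thumb[y0:y1, x0:x1] + alpha * color
    out = np.clip(np.rint(thumb), 0, 255).astype(np.uint8)
    Image.fromarray(out).save(out_path)
    return out
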