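"""Epithelial-region filtering: tissue mask, nuclear-region detection,
x20 patch parsing and blur / no-tissue / no-nuclei rejection.

All criteria are deliberately simple, fast, non-learned image operators:

* tissue      — HSV saturation above a threshold (stroma and nuclei are
                stained, the background is near-achromatic);
* nuclei      — hematoxylin channel of a color-deconvolved (HED) image
                above an optical-density threshold;
* epithelium  — connected components of locally nucleus-dense tissue,
                morphologically closed, small components dropped;
* blur        — variance of the Laplacian of the (lightly pre-smoothed)
                x20 grayscale patch.

Quality flags are computed on the x20 base patch only; the x5 context is
never filtered. Patches are laid on a non-overlapping 256-px grid aligned
to the level-0 origin.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import (
    binary_closing,
    binary_erosion,
    gaussian_filter,
    laplace,
    uniform_filter,
)
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.geometry import box as shapely_box
from shapely.prepared import prep
from skimage.color import rgb2gray, rgb2hed, rgb2hsv
from skimage.measure import find_contours, label as label_components
from skimage.morphology import disk

from .errors import ParameterError
from .slide_io import PATCH_SIZE, PatchPair, SlidePyramid, make_pair, read_patch

#: level the tissue mask is computed at
TISSUE_MASK_DOWNSAMPLE = 16
#: level epithelial regions are detected at
EPITHELIUM_DOWNSAMPLE = 4
#: window (in downsample-4 px) of the local nuclear-density estimate
DENSITY_WINDOW = 33


@dataclass
class FilterConfig:
    """Thresholds for the filtering stage.

    Defaults are calibrated against the synthetic generator and serialized
    with every run for reproducibility.
    """

    tissue_saturation_min: float = 0.08
    tissue_fraction_min: float = 0.10  # min fraction of tissue px in a patch
    blur_laplacian_var_min: float = 2e-4  # on grayscale in [0, 1]
    nuclei_fraction_min: float = 0.02
    hematoxylin_od_min: float = 0.05
    epithelial_density_min: float = 0.10
    min_region_area_px: int = 30_000  # level-0 px^2
    patch_keep_overlap_min: float = 0.5

    def __post_init__(self):
        for name in (
            "tissue_saturation_min",
            "tissue_fraction_min",
            "nuclei_fraction_min",
            "epithelial_density_min",
            "patch_keep_overlap_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.blur_laplacian_var_min < 0:
            raise ParameterError("blur_laplacian_var_min must be >= 0")
        if self.hematoxylin_od_min < 0:
            raise ParameterError("hematoxylin_od_min must be >= 0")
        if self.min_region_area_px < 0:
            raise ParameterError("min_region_area_px must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass
class FilterReport:
    """Bookkeeping of one filtering run.

    ``n_discarded_by_flag`` counts flags with multiplicity (a patch carrying
    two flags is counted under both), while ``n_kept + n_discarded ==
    n_candidate_patches`` where a patch is discarded iff it carries >= 1 flag.
    """

    n_candidate_patches: int
    n_kept: int
    n_discarded_by_flag: dict[str, int]

    @property
    def n_discarded(self) -> int:
        return self.n_candidate_patches - self.n_kept

    @property
    def discard_fraction(self) -> float:
        if self.n_candidate_patches == 0:
            return 0.0
        return 1.0 - self.n_kept / self.n_candidate_patches

    def to_dict(self) -> dict:
        return {
            "n_candidate_patches": self.n_candidate_patches,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "n_discarded_by_flag": dict(self.n_discarded_by_flag),
            "discard_fraction": self.discard_fraction,
        }


# ---------------------------------------------------------------------------
# Stage operators
# ---------------------------------------------------------------------------


def _saturation(img_u8: np.ndarray) -> np.ndarray:
    return rgb2hsv(img_u8 / 255.0)[..., 1]


def _hematoxylin(img_u8: np.ndarray) -> np.ndarray:
    """Hematoxylin optical-density channel via HED color deconvolution."""
    return rgb2hed(img_u8 / 255.0)[..., 0]


def compute_tissue_mask(slide: SlidePyramid, cfg: FilterConfig | None = None) -> np.ndarray:
    """Binary tissue mask at the downsample-16 level: smoothed HSV
    saturation >= ``tissue_saturation_min``."""
    cfg = cfg or FilterConfig()
    img = slide.level_image(slide.level_for_downsample(TISSUE_MASK_DOWNSAMPLE))
    sat = gaussian_filter(_saturation(img), 1.0)
    return sat >= cfg.tissue_saturation_min


def detect_epithelial_regions(
    slide: SlidePyramid, cfg: FilterConfig | None = None
) -> list[ShapelyPolygon]:
    """Detect nucleus-dense (epithelial) regions; returns level-0 polygons.

    At the downsample-4 level, hematoxylin-positive pixels are located,
    their local density is estimated with a uniform filter, thresholded,
    morphologically closed and small components are removed. Each
    connected component is returned as its outer contour polygon scaled
    back to level-0 coordinates.
    """
    cfg = cfg or FilterConfig()
    ds = EPITHELIUM_DOWNSAMPLE
    img = slide.level_image(slide.level_for_downsample(ds))
    nuclear = _hematoxylin(img) >= cfg.hematoxylin_od_min
    density = uniform_filter(nuclear.astype(np.float64), size=DENSITY_WINDOW)
    mask = density >= cfg.epithelial_density_min
    mask = binary_closing(mask, structure=disk(3))
    # the density window slightly dilates region borders; pull back
    mask = binary_erosion(mask, structure=disk(2))
    min_area_ds = max(int(cfg.min_region_area_px / (ds * ds)), 1)
    labeled = label_components(mask)
    counts = np.bincount(labeled.ravel())
    small = np.flatnonzero(counts < min_area_ds)
    mask[np.isin(labeled, small)] = False
    labeled = label_components(mask)
    polygons: list[ShapelyPolygon] = []
    for lab in range(1, labeled.max() + 1):
        comp = np.pad(labeled == lab, 1)
        contours = find_contours(comp.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary
        # (row, col) in padded ds-space -> (x, y) level-0
        xy = np.column_stack([contour[:, 1] - 1, contour[:, 0] - 1]) * ds
        poly = ShapelyPolygon(xy).buffer(0)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        poly = poly.simplify(ds / 2)
        if poly.area >= cfg.min_region_area_px:
            polygons.append(poly)
    return polygons


def parse_patches(
    slide: SlidePyramid,
    regions: Sequence[ShapelyPolygon],
    cfg: FilterConfig | None = None,
) -> list[PatchPair]:
    """Lay a non-overlapping 256-px grid (aligned to the level-0 origin)
    over each region's bounding box; a cell becomes a PatchPair iff its
    overlap with the region is >= ``patch_keep_overlap_min``."""
    cfg = cfg or FilterConfig()
    size = PATCH_SIZE
    cell_area = float(size * size)
    centers: set[tuple[int, int]] = set()
    for region in regions:
        minx, miny, maxx, maxy = region.bounds
        prepared = prep(region)
        for gy in range(int(miny // size), int(maxy // size) + 1):
            for gx in range(int(minx // size), int(maxx // size) + 1):
                x0, y0 = gx * size, gy * size
                cell = shapely_box(x0, y0, x0 + size, y0 + size)
                if not prepared.intersects(cell):
                    continue
                if region.intersection(cell).area / cell_area >= cfg.patch_keep_overlap_min:
                    cx, cy = x0 + size // 2, y0 + size // 2
                    if 0 <= cx < slide.width and 0 <= cy < slide.height:
                        centers.add((cx, cy))
    return [
        make_pair(slide.slide_id, c)
        for c in sorted(centers, key=lambda c: (c[1], c[0]))
    ]


def whole_grid_pairs(slide: SlidePyramid) -> list[PatchPair]:
    """All grid cells fully inside the slide — the unfiltered candidate set."""
    size = PATCH_SIZE
    return [
        make_pair(slide.slide_id, (x0 + size // 2, y0 + size // 2))
        for y0 in range(0, slide.height - size + 1, size)
        for x0 in range(0, slide.width - size + 1, size)
    ]


def quality_flags(
    pair: PatchPair, slide: SlidePyramid, cfg: FilterConfig | None = None
) -> frozenset:
    """Quality flags of the x20 base patch; any subset of
    {blur, no_tissue, no_nuclei} may fire independently."""
    cfg = cfg or FilterConfig()
    img = read_patch(slide, pair.center_xy, "x20")
    flags = set()
    gray = rgb2gray(img / 255.0)
    # pre-smooth so sensor noise does not mask optical blur
    if laplace(gaussian_filter(gray, 1.0)).var() < cfg.blur_laplacian_var_min:
        flags.add("blur")
    if (_saturation(img) >= cfg.tissue_saturation_min).mean() < cfg.tissue_fraction_min:
        flags.add("no_tissue")
    if (_hematoxylin(img) >= cfg.hematoxylin_od_min).mean() < cfg.nuclei_fraction_min:
        flags.add("no_nuclei")
    return frozenset(flags)


def filter_patches(
    pairs: Sequence[PatchPair],
    slide: SlidePyramid,
    cfg: FilterConfig | None = None,
) -> tuple[list[PatchPair], FilterReport]:
    """Keep pairs with no quality flags; flagged pairs are recorded in the
    report. Flags are attached to the returned (new) records."""
    cfg = cfg or FilterConfig()
    kept: list[PatchPair] = []
    by_flag = {"blur": 0, "no_tissue": 0, "no_nuclei": 0}
    for pair in pairs:
        flags = quality_flags(pair, slide, cfg)
        if flags:
            for f in flags:
                by_flag[f] += 1
        else:
            kept.append(pair)
    report = FilterReport(
        n_candidate_patches=len(pairs), n_kept=len(kept), n_discarded_by_flag=by_flag
    )
    return kept, report


def extract_pairs(
    slide: SlidePyramid, cfg: FilterConfig | None = None
) -> tuple[list[PatchPair], FilterReport]:
    """Full filtering stage: epithelial regions -> grid parse -> quality
    filter. The report counts the parsed-grid candidates."""
    cfg = cfg or FilterConfig()
    regions = detect_epithelial_regions(slide, cfg)
    pairs = parse_patches(slide, regions, cfg)
    return filter_patches(pairs, slide, cfg)
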