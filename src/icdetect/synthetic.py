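"""Synthetic pyramidal slides with labeled epithelial / IC regions.

Real training data for this kind of pipeline lives in hospital archives;
this module stands in for it. Slides are epithelium-sparse HES-like
renderings: a near-white background, eosin-pink stroma with a smooth
"Perlin-like" texture, and hematoxylin-dark disc nuclei scattered inside
epithelial polygons. Invasive-carcinoma (IC) regions reuse the same nuclear
palette but with larger, denser, more pleomorphic nuclei, so the IC/benign
distinction is a texture problem rather than a raw color one.

Rendering constants (level-0 px at the nominal 0.44 um/px resolution):

========================  =======  ====
quantity                  benign   IC
========================  =======  ====
nucleus mean radius       7.0 px   x1.6
nucleus density / px^2    2.0e-3   x2.0
radius coeff. of var.     0.15     0.40
========================  =======  ====

Radius scales inversely with a center's um/px resolution and density
scales with its square, so centers with different scanners render nuclei
at different pixel sizes — one of the domain shifts the calibration step
has to absorb.

Per-center appearance (:class:`CenterStyle`) adds hue rotation, brightness
scaling and sensor noise on top of the shared geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon as ShapelyPolygon
from PIL import Image, ImageDraw
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import disk as draw_disk

from . import slide_io
from .errors import GeometryError, ParameterError
from .slide_io import RoiAnnotation, SlidePyramid

# -- rendering constants (documented in the module docstring) ---------------
NUCLEUS_RADIUS_PX = 7.0  # benign mean radius at 0.44 um/px, level 0
NUCLEUS_DENSITY = 2.0e-3  # benign nuclei per level-0 px^2 at 0.44 um/px
IC_RADIUS_FACTOR = 1.6
IC_DENSITY_FACTOR = 2.0
RADIUS_CV_BENIGN = 0.15
RADIUS_CV_IC = 0.40
NOMINAL_RESOLUTION = 0.44  # um/px the constants above are quoted at
STROMA_TEXTURE_AMP = 10.0  # gray-level amplitude of the stroma texture
BLUR_SIGMA = 8.0  # Gaussian sigma applied inside blur polygons

IC_LABEL = "invasive ductal carcinoma"
BENIGN_LABEL = "benign"

DEFAULT_SLIDE_SIZE = 4096  # level-0 px; desk-scale default


# ---------------------------------------------------------------------------
# CenterStyle
# ---------------------------------------------------------------------------

_STYLE_RANGES = {
    "brightness_scale": (0.0, 3.0),  # open at 0
    "hue_shift_deg": (-180.0, 180.0),
    "noise_sd": (0.0, 50.0),
}


@dataclass(frozen=True)
class CenterStyle:
    """Per-acquisition-center appearance parameters."""

    name: str = "center"
    nuclear_color: tuple[int, int, int] = (70, 50, 130)
    stroma_color: tuple[int, int, int] = (228, 162, 188)
    background_color: tuple[int, int, int] = (244, 242, 246)
    brightness_scale: float = 1.0
    hue_shift_deg: float = 0.0
    noise_sd: float = 3.0
    resolution_um_per_px: float = 0.44

    def __post_init__(self):
        for fname in ("nuclear_color", "stroma_color", "background_color"):
            col = getattr(self, fname)
            if len(col) != 3 or not all(0 <= c <= 255 for c in col):
                raise ParameterError(f"{fname}={col!r} has channels outside [0, 255]")
        if not (0.0 < self.brightness_scale <= 3.0):
            raise ParameterError(f"brightness_scale={self.brightness_scale} outside (0, 3]")
        lo, hi = _STYLE_RANGES["hue_shift_deg"]
        if not (lo <= self.hue_shift_deg <= hi):
            raise ParameterError(f"hue_shift_deg={self.hue_shift_deg} outside [{lo}, {hi}]")
        if not (0.0 <= self.noise_sd <= 50.0):
            raise ParameterError(f"noise_sd={self.noise_sd} outside [0, 50]")
        if self.resolution_um_per_px <= 0:
            raise ParameterError(
                f"resolution_um_per_px={self.resolution_um_per_px} must be > 0"
            )


def make_center_style(overrides: dict | None = None, seed: int = 0) -> CenterStyle:
    """Draw a CenterStyle; unspecified fields come from documented default
    ranges, deterministically for a fixed (overrides, seed)."""
    rng = np.random.default_rng(seed)
    jit = lambda base, a: tuple(
        int(np.clip(c + rng.integers(-a, a + 1), 0, 255)) for c in base
    )
    drawn = {
        "name": f"center-{seed}",
        "nuclear_color": jit((70, 50, 130), 10),
        "stroma_color": jit((228, 162, 188), 10),
        "background_color": jit((244, 242, 246), 3),
        "brightness_scale": float(rng.uniform(0.9, 1.1)),
        "hue_shift_deg": float(rng.uniform(-15.0, 15.0)),
        "noise_sd": float(rng.uniform(2.0, 8.0)),
        "resolution_um_per_px": float(rng.uniform(0.25, 0.5)),
    }
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(drawn)
    if unknown:
        raise ParameterError(f"unknown style fields: {sorted(unknown)}")
    drawn.update(overrides)
    return CenterStyle(**drawn)


#: Default two-center setup for the transfer-learning experiments: the
#: target center differs in stain hue, brightness, noise and scanner
#: resolution — large enough that a model trained on one measurably fails
#: on the other (the shift the calibration step exists to absorb).
REFERENCE_STYLE = CenterStyle(name="reference")
TARGET_STYLE = CenterStyle(
    name="target",
    nuclear_color=(95, 60, 110),
    stroma_color=(235, 140, 160),
    background_color=(240, 238, 244),
    brightness_scale=0.78,
    hue_shift_deg=-15.0,
    noise_sd=12.0,
    resolution_um_per_px=0.27,
)


# ---------------------------------------------------------------------------
# Slide spec
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSlideSpec:
    """Geometry of one synthetic slide, all coordinates in level-0 px."""

    width_px: int
    height_px: int
    tissue_polygons: list[np.ndarray] = field(default_factory=list)
    epithelial_polygons: list[np.ndarray] = field(default_factory=list)
    ic_polygons: list[np.ndarray] = field(default_factory=list)
    blur_polygons: list[np.ndarray] = field(default_factory=list)
    epithelial_area_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for group, polys in (
            ("tissue", self.tissue_polygons),
            ("epithelial", self.epithelial_polygons),
            ("ic", self.ic_polygons),
            ("blur", self.blur_polygons),
        ):
            for p in polys:
                p = np.asarray(p)
                if p.min() < 0 or p[:, 0].max() > self.width_px or p[:, 1].max() > self.height_px:
                    raise GeometryError(f"{group} polygon exceeds slide bounds")
        if self.ic_polygons:
            epi = _union([ShapelyPolygon(p) for p in self.epithelial_polygons])
            for p in self.ic_polygons:
                sp = ShapelyPolygon(p)
                if sp.area <= 0 or epi.intersection(sp).area < 0.99 * sp.area:
                    raise GeometryError("IC polygon not nested (>=99%) inside epithelium")

    @property
    def is_ic(self) -> bool:
        return len(self.ic_polygons) > 0


def _union(polys):
    from shapely.ops import unary_union

    return unary_union([p.buffer(0) for p in polys]) if polys else ShapelyPolygon()


def _blob_polygon(rng, cx, cy, radius, n_vertices=24, wobble=0.25) -> np.ndarray:
    """A smooth random blob: radius modulated by low-order harmonics."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    amp = rng.uniform(-wobble, wobble, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    r = radius * (1.0 + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amp, phase))))
    r = np.clip(r, 0.3 * radius, 1.8 * radius)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def random_slide_spec(
    width_px: int = DEFAULT_SLIDE_SIZE,
    height_px: int = DEFAULT_SLIDE_SIZE,
    *,
    with_ic: bool = False,
    epithelial_area_fraction: float = 0.08,
    n_epithelial: int = 3,
    with_blur: bool = False,
    seed: int = 0,
) -> SyntheticSlideSpec:
    """Random but deterministic slide layout: one large tissue blob,
    ``n_epithelial`` epithelial blobs inside it (targeting the requested
    area fraction) and optionally one IC blob nested in an epithelial one."""
    rng = np.random.default_rng(seed)
    w, h = width_px, height_px
    tissue_r = 0.38 * min(w, h)
    tissue = _blob_polygon(rng, w / 2, h / 2, tissue_r, n_vertices=36, wobble=0.15)
    tissue = np.clip(tissue, 8, [w - 8, h - 8])
    tissue_shp = ShapelyPolygon(tissue).buffer(0)

    target_area = epithelial_area_fraction * tissue_shp.area
    epi_r = np.sqrt(target_area / max(n_epithelial, 1) / np.pi)
    epithelial = []
    tries = 0
    while len(epithelial) < n_epithelial and tries < 200:
        tries += 1
        cx = rng.uniform(w * 0.2, w * 0.8)
        cy = rng.uniform(h * 0.2, h * 0.8)
        blob = _blob_polygon(rng, cx, cy, epi_r, wobble=0.2)
        shp = ShapelyPolygon(blob).buffer(0)
        if not shp.is_valid or shp.is_empty:
            continue
        if tissue_shp.contains(shp) and all(
            not shp.intersects(ShapelyPolygon(e)) for e in epithelial
        ):
            epithelial.append(blob)
    ic = []
    if with_ic and epithelial:
        # a carcinoma nodule inside every epithelial blob, so IC slides carry
        # a usable number of IC-labeled patches
        for host in epithelial:
            host_shp = ShapelyPolygon(host)
            hx, hy = host_shp.centroid.x, host_shp.centroid.y
            for _ in range(100):
                blob = _blob_polygon(rng, hx, hy, 0.68 * epi_r, wobble=0.15)
                shp = ShapelyPolygon(blob).buffer(0)
                if shp.is_valid and host_shp.contains(shp):
                    ic.append(blob)
                    break
    blur = []
    if with_blur:
        bx = rng.uniform(w * 0.3, w * 0.7)
        by = rng.uniform(h * 0.3, h * 0.7)
        blur.append(_blob_polygon(rng, bx, by, 0.12 * min(w, h), wobble=0.1))
    return SyntheticSlideSpec(
        width_px=w,
        height_px=h,
        tissue_polygons=[tissue],
        epithelial_polygons=epithelial,
        ic_polygons=ic,
        blur_polygons=blur,
        epithelial_area_fraction=epithelial_area_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _polygon_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # PIL's scanline fill is ~100x faster than per-pixel point-in-polygon
    img = Image.new("1", (shape[1], shape[0]), 0)
    ImageDraw.Draw(img).polygon([(float(x), float(y)) for x, y in poly], fill=1)
    return np.asarray(img, dtype=bool)


def _smooth_noise(rng, shape, sigma: float, upsample: int = 1) -> np.ndarray:
    """Low-frequency unit-variance noise field (Perlin-like stand-in)."""
    small = (max(1, shape[0] // upsample), max(1, shape[1] // upsample))
    f = gaussian_filter(rng.standard_normal(small), sigma)
    sd = f.std()
    if sd > 0:
        f /= sd
    if upsample > 1:
        f = np.repeat(np.repeat(f, upsample, axis=0), upsample, axis=1)
        f = f[: shape[0], : shape[1]]
    return f


def _nucleus_params(style: CenterStyle, ic: bool, zoom_scale: float = 1.0):
    """(mean radius px, density per px^2, radius CV) at the rendered scale.

    ``zoom_scale`` > 1 renders at a coarser effective magnification
    (1 rendered px = zoom_scale level-0 px)."""
    px_scale = NOMINAL_RESOLUTION / (style.resolution_um_per_px * zoom_scale)
    radius = NUCLEUS_RADIUS_PX * px_scale * (IC_RADIUS_FACTOR if ic else 1.0)
    # physical density is fixed; a rendered px covers (1/px_scale)^2 nominal px
    density = NUCLEUS_DENSITY / (px_scale**2) * (IC_DENSITY_FACTOR if ic else 1.0)
    cv = RADIUS_CV_IC if ic else RADIUS_CV_BENIGN
    return radius, density, cv


def _scatter_nuclei(
    img: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    style: CenterStyle,
    *,
    ic: bool,
    zoom_scale: float = 1.0,
    density_factor: float = 1.0,
    radius_factor: float = 1.0,
) -> None:
    """Poisson-scatter disc nuclei over the True pixels of ``mask``."""
    radius, density, cv = _nucleus_params(style, ic, zoom_scale)
    radius *= radius_factor
    density *= density_factor
    area = int(mask.sum())
    if area == 0:
        return
    n = rng.poisson(density * area)
    if n == 0:
        return
    ys, xs = np.nonzero(mask)
    idx = rng.integers(0, len(ys), size=n)
    radii = np.clip(rng.normal(radius, cv * radius, size=n), 0.35 * radius, 2.5 * radius)
    shade = rng.uniform(0.85, 1.1, size=n)
    color = np.asarray(style.nuclear_color, dtype=np.float64)
    h, w = mask.shape
    for i in range(n):
        rr, cc = draw_disk((ys[idx[i]], xs[idx[i]]), max(radii[i], 0.8), shape=(h, w))
        img[rr, cc] = np.clip(color * shade[i], 0, 255)


def _apply_style(img: np.ndarray, style: CenterStyle, rng: np.random.Generator) -> np.ndarray:
    """Hue rotation, brightness scaling and additive Gaussian noise.

    ``img`` is float64 RGB in [0, 255]; returns uint8."""
    out = img
    if style.hue_shift_deg != 0.0:
        hsv = rgb2hsv(np.clip(out, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + style.hue_shift_deg / 360.0) % 1.0
        out = hsv2rgb(hsv) * 255.0
    if style.brightness_scale != 1.0:
        out = out * style.brightness_scale
    if style.noise_sd > 0:
        out = out + rng.normal(0.0, style.noise_sd, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_slide_image(spec: SyntheticSlideSpec, style: CenterStyle) -> np.ndarray:
    """Render the level-0 RGB image of a slide spec under a style."""
    spec.validate()
    h, w = spec.height_px, spec.width_px
    geom_rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(style.background_color, dtype=np.float64)

    # stroma with a smooth texture
    if spec.tissue_polygons:
        tex = _smooth_noise(geom_rng, (h, w), sigma=2.0, upsample=4) * STROMA_TEXTURE_AMP
        stroma = np.asarray(style.stroma_color, dtype=np.float64)
        for poly in spec.tissue_polygons:
            m = _polygon_mask(np.asarray(poly), (h, w))
            img[m] = stroma + tex[m, None]

    # nuclei: benign epithelium first, IC drawn on top of its nested area
    for poly in spec.epithelial_polygons:
        m = _polygon_mask(np.asarray(poly), (h, w))
        _scatter_nuclei(img, m, geom_rng, style, ic=False)
    for poly in spec.ic_polygons:
        m = _polygon_mask(np.asarray(poly), (h, w))
        _scatter_nuclei(img, m, geom_rng, style, ic=True)

    # out-of-focus regions
    for poly in spec.blur_polygons:
        m = _polygon_mask(np.asarray(poly), (h, w))
        if not m.any():
            continue
        ys, xs = np.nonzero(m)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        pad = int(3 * BLUR_SIGMA)
        yy0, yy1 = max(0, y0 - pad), min(h, y1 + pad)
        xx0, xx1 = max(0, x0 - pad), min(w, x1 + pad)
        blurred = gaussian_filter(img[yy0:yy1, xx0:xx1], (BLUR_SIGMA, BLUR_SIGMA, 0))
        sub = m[yy0:yy1, xx0:xx1]
        img[yy0:yy1, xx0:xx1][sub] = blurred[sub]

    # per-center appearance, in strips to bound memory on large slides
    style_rng = np.random.default_rng(spec.seed + 1)
    out = np.empty((h, w, 3), dtype=np.uint8)
    strip = 1024
    for y0 in range(0, h, strip):
        out[y0 : y0 + strip] = _apply_style(img[y0 : y0 + strip], style, style_rng)
    return out


def spec_annotations(spec: SyntheticSlideSpec) -> list[RoiAnnotation]:
    """Ground-truth annotations: benign epithelial polygons + IC polygons."""
    anns = [RoiAnnotation(polygon=np.asarray(p), label=BENIGN_LABEL) for p in spec.epithelial_polygons]
    anns += [RoiAnnotation(polygon=np.asarray(p), label=IC_LABEL) for p in spec.ic_polygons]
    return anns


def generate_slide(
    spec: SyntheticSlideSpec, style: CenterStyle, slide_id: str = "synthetic"
) -> tuple[SlidePyramid, list[RoiAnnotation]]:
    """Render a spec into an in-memory 3-level pyramid plus its annotations."""
    level0 = render_slide_image(spec, style)
    pyramid = slide_io.pyramid_from_array(level0, slide_id, style.resolution_um_per_px)
    return pyramid, spec_annotations(spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["patient_id", "slide_id", "class", "slide_path", "annotation_path"]


@dataclass
class SyntheticCohort:
    patients: list[str]
    manifest: pd.DataFrame
    style: CenterStyle
    out_dir: Path


def generate_cohort(
    n_patients: int,
    slides_per_patient: int,
    ic_slide_fraction: float,
    epithelial_area_fraction: float,
    style: CenterStyle,
    seed: int,
    out_dir: str | Path,
    *,
    slide_size: int = DEFAULT_SLIDE_SIZE,
) -> SyntheticCohort:
    """Write a cohort of synthetic slides + GeoJSON annotations + a TSV
    manifest. A slide is labeled IC iff its spec contains an IC polygon;
    the number of IC slides is round(fraction * n_slides)."""
    if n_patients < 1 or slides_per_patient < 1:
        raise ParameterError("n_patients and slides_per_patient must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_slides = n_patients * slides_per_patient
    n_ic = int(round(ic_slide_fraction * n_slides))
    ic_flags = np.zeros(n_slides, dtype=bool)
    ic_flags[rng.permutation(n_slides)[:n_ic]] = True

    rows = []
    patients = [f"P{p:03d}" for p in range(n_patients)]
    k = 0
    for pi, patient in enumerate(patients):
        for si in range(slides_per_patient):
            slide_id = f"{patient}_S{si}"
            spec = random_slide_spec(
                slide_size,
                slide_size,
                with_ic=bool(ic_flags[k]),
                epithelial_area_fraction=epithelial_area_fraction,
                seed=seed * 1_000_003 + k,
            )
            level0 = render_slide_image(spec, style)
            slide_path = out_dir / f"{slide_id}.tiff"
            ann_path = out_dir / f"{slide_id}.geojson"
            slide_io.write_pyramid(slide_path, level0, slide_id, style.resolution_um_per_px)
            slide_io.save_annotations(spec_annotations(spec), ann_path)
            rows.append(
                {
                    "patient_id": patient,
                    "slide_id": slide_id,
                    "class": "IC" if spec.is_ic else "Rest",
                    "slide_path": str(slide_path),
                    "annotation_path": str(ann_path),
                }
            )
            k += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return SyntheticCohort(patients=patients, manifest=manifest, style=style, out_dir=out_dir)


def load_cohort_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        from .errors import FormatError

        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Direct patch rendering (desk-scale training sets)
# ---------------------------------------------------------------------------


#: slide-to-slide appearance variability within one center, applied on top
#: of the center style when rendering standalone patches
INTRA_CENTER_HUE_SD = 4.0  # degrees
INTRA_CENTER_BRIGHTNESS_SD = 0.05
#: per-patch biological variability of the nuclear texture (log-normal
#: sigmas): creates honest class overlap so patch accuracy does not saturate
PATCH_DENSITY_JITTER_SD = 0.35
PATCH_RADIUS_JITTER_SD = 0.15


def render_patch(
    label: str,
    style: CenterStyle,
    rng: np.random.Generator,
    *,
    size: int = 64,
    zoom_scale: float = 2.0,
    intra_center_jitter: bool = True,
    density_jitter_sd: float = PATCH_DENSITY_JITTER_SD,
    radius_jitter_sd: float = PATCH_RADIUS_JITTER_SD,
) -> np.ndarray:
    """Render one epithelial patch of class ``label`` ("IC" or "Rest").

    ``zoom_scale`` sets the effective magnification: 1 rendered px covers
    ``zoom_scale`` level-0 px, mimicking a context view without paying for
    a full-slide render. With ``intra_center_jitter`` the patch gets a
    small random hue/brightness offset around the center style, emulating
    slide-to-slide staining variability within one center."""
    if intra_center_jitter:
        hue = float(
            np.clip(style.hue_shift_deg + rng.normal(0, INTRA_CENTER_HUE_SD), -180, 180)
        )
        bright = float(
            np.clip(
                style.brightness_scale * (1 + rng.normal(0, INTRA_CENTER_BRIGHTNESS_SD)),
                1e-3,
                3.0,
            )
        )
        style = dataclasses.replace(style, hue_shift_deg=hue, brightness_scale=bright)
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = np.asarray(style.stroma_color, dtype=np.float64)
    img += _smooth_noise(rng, (size, size), sigma=1.5)[..., None] * STROMA_TEXTURE_AMP
    mask = np.ones((size, size), dtype=bool)
    _scatter_nuclei(
        img,
        mask,
        rng,
        style,
        ic=(label == "IC"),
        zoom_scale=zoom_scale,
        density_factor=float(np.exp(rng.normal(0, density_jitter_sd))),
        radius_factor=float(np.exp(rng.normal(0, radius_jitter_sd))),
    )
    return _apply_style(img, style, rng)


def render_patch_dataset(
    n: int,
    ic_fraction: float,
    style: CenterStyle,
    seed: int,
    *,
    size: int = 64,
    zoom_scale: float = 2.0,
    texture_diversity_sd: float = PATCH_DENSITY_JITTER_SD,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ``n`` labeled epithelial patches; returns (images, labels)
    with images uint8 of shape (n, size, size, 3) and labels in {0, 1}
    (1 = IC). Deterministic in (args, seed).

    ``texture_diversity_sd`` controls the per-patch nuclear-density spread
    — a case-mix diversity knob: cohorts from different centers can be
    more or less pathologically diverse."""
    rng = np.random.default_rng(seed)
    n_ic = int(round(ic_fraction * n))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_ic]] = 1
    images = np.empty((n, size, size, 3), dtype=np.uint8)
    for i in range(n):
        images[i] = render_patch(
            "IC" if labels[i] else "Rest",
            style,
            rng,
            size=size,
            zoom_scale=zoom_scale,
            density_jitter_sd=texture_diversity_sd,
        )
    return images, labels
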