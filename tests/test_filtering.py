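import dataclasses

import numpy as np
import pytest
from shapely.geometry import Polygon
from shapely.ops import unary_union

from icdetect import filtering, slide_io, synthetic
from icdetect.errors import ParameterError
from icdetect.filtering import (
    FilterConfig,
    FilterReport,
    compute_tissue_mask,
    detect_epithelial_regions,
    filter_patches,
    parse_patches,
    quality_flags,
    whole_grid_pairs,
)
from icdetect.slide_io import make_pair
from icdetect.synthetic import SyntheticSlideSpec, generate_slide

from conftest import square

# ---------------------------------------------------------------------------
# FilterConfig
# ---------------------------------------------------------------------------


def test_config_yaml_roundtrip(tmp_path):
    cfg = FilterConfig(tissue_saturation_min=0.12, min_region_area_px=12345)
    cfg.to_yaml(tmp_path / "f.yaml")
    assert FilterConfig.from_yaml(tmp_path / "f.yaml") == cfg


@pytest.mark.parametrize(
    "kwargs",
    [
        {"tissue_saturation_min": 1.5},
        {"patch_keep_overlap_min": -0.1},
        {"blur_laplacian_var_min": -1.0},
        {"min_region_area_px": -5},
    ],
)
def test_config_out_of_range(kwargs):
    with pytest.raises(ParameterError):
        FilterConfig(**kwargs)


# ---------------------------------------------------------------------------
# Tissue mask
# ---------------------------------------------------------------------------


def test_tissue_mask_empty_on_background(background_slide):
    assert compute_tissue_mask(background_slide).sum() == 0


def test_tissue_mask_iou_against_rasterized_polygon(random_slide):
    spec, slide, _ = random_slide
    mask = compute_tissue_mask(slide)
    oracle = np.zeros(mask.shape, bool)
    for poly in spec.tissue_polygons:
        oracle |= synthetic._polygon_mask(np.asarray(poly) / 16.0, mask.shape)
    iou = (mask & oracle).sum() / (mask | oracle).sum()
    assert iou >= 0.9


def test_tissue_mask_full_tissue_slide(ref_style):
    spec = SyntheticSlideSpec(
        width_px=1024, height_px=1024, tissue_polygons=[square(0, 0, 1024)], seed=2
    )
    slide, _ = generate_slide(spec, ref_style)
    assert compute_tissue_mask(slide).mean() >= 0.95


# ---------------------------------------------------------------------------
# Epithelial region detection
# ---------------------------------------------------------------------------


def test_no_epithelium_no_regions(ref_style):
    # stroma-only tissue: no nuclei anywhere
    spec = SyntheticSlideSpec(
        width_px=1024, height_px=1024, tissue_polygons=[square(64, 64, 896)], seed=3
    )
    slide, _ = generate_slide(spec, ref_style)
    assert detect_epithelial_regions(slide) == []


def test_single_square_region_iou(square_slide):
    spec, slide, _ = square_slide
    regions = detect_epithelial_regions(slide)
    assert len(regions) == 1
    truth = Polygon(spec.epithelial_polygons[0])
    iou = regions[0].intersection(truth).area / regions[0].union(truth).area
    assert iou >= 0.8


def test_two_disjoint_regions_found(ref_style):
    spec = SyntheticSlideSpec(
        width_px=2048,
        height_px=2048,
        tissue_polygons=[square(64, 64, 1920)],
        epithelial_polygons=[square(256, 256, 512), square(1280, 1280, 512)],
        seed=6,
    )
    slide, _ = generate_slide(spec, ref_style)
    assert len(detect_epithelial_regions(slide)) == 2


# ---------------------------------------------------------------------------
# parse_patches
# ---------------------------------------------------------------------------


def test_grid_aligned_square_yields_four_pairs(uniform_slide):
    region = Polygon([(256, 256), (768, 256), (768, 768), (256, 768)])
    pairs = parse_patches(uniform_slide, [region])
    assert len(pairs) == 4
    assert {p.center_xy for p in pairs} == {
        (384, 384),
        (640, 384),
        (384, 640),
        (640, 640),
    }


def test_tiny_region_yields_no_pairs(uniform_slide):
    region = Polygon([(300, 300), (400, 300), (400, 400), (300, 400)])
    assert parse_patches(uniform_slide, [region]) == []


def test_parse_patches_matches_bruteforce_grid_oracle(uniform_slide):
    rng = np.random.default_rng(9)
    regions = []
    for _ in range(5):
        cx, cy = rng.uniform(200, 824, 2)
        r = rng.uniform(80, 280)
        theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        regions.append(Polygon(np.clip(pts, 0, 1024)).buffer(0))
    cfg = FilterConfig()
    pairs = parse_patches(uniform_slide, regions, cfg)

    # oracle: exhaustively test every 256-px cell of the slide
    expected = set()
    for y0 in range(0, 1024, 256):
        for x0 in range(0, 1024, 256):
            cell = Polygon([(x0, y0), (x0 + 256, y0), (x0 + 256, y0 + 256), (x0, y0 + 256)])
            overlap = max(reg.intersection(cell).area for reg in regions)
            if overlap / cell.area >= cfg.patch_keep_overlap_min:
                expected.add((x0 + 128, y0 + 128))
    assert {p.center_xy for p in pairs} == expected


# ---------------------------------------------------------------------------
# quality_flags
# ---------------------------------------------------------------------------


def test_uniform_white_patch_all_flags(uniform_slide):
    white = slide_io.pyramid_from_array(
        np.full((1024, 1024, 3), 245, np.uint8), "white", 0.44
    )
    flags = quality_flags(make_pair("white", (512, 512)), white)
    assert flags == {"blur", "no_tissue", "no_nuclei"}


def test_sharp_epithelial_patch_unflagged(square_slide):
    _, slide, _ = square_slide
    assert quality_flags(make_pair(slide.slide_id, (896, 896)), slide) == frozenset()


def test_blurred_patch_flagged_and_laplacian_monotone(square_slide):
    from scipy.ndimage import gaussian_filter, laplace
    from skimage.color import rgb2gray

    _, slide, _ = square_slide
    img = slide_io.read_patch(slide, (896, 896), "x20")
    gray = rgb2gray(img / 255.0)
    variances = [laplace(gaussian_filter(gray, s)).var() for s in (0, 2, 4, 8)]
    assert all(a > b for a, b in zip(variances, variances[1:]))  # monotone in sigma

    blurred = gaussian_filter(img.astype(float), (8, 8, 0))
    level0 = np.tile(np.rint(blurred).astype(np.uint8), (4, 4, 1))
    bslide = slide_io.pyramid_from_array(level0, "blur", 0.44)
    assert "blur" in quality_flags(make_pair("blur", (512, 512)), bslide)


def test_rendered_blur_region_flagged(ref_style):
    spec = SyntheticSlideSpec(
        width_px=1024,
        height_px=1024,
        tissue_polygons=[square(0, 0, 1024)],
        epithelial_polygons=[square(256, 256, 512)],
        blur_polygons=[square(256, 256, 512)],
        seed=4,
    )
    slide, _ = generate_slide(spec, ref_style)
    assert "blur" in quality_flags(make_pair(slide.slide_id, (512, 512)), slide)


# ---------------------------------------------------------------------------
# filter_patches
# ---------------------------------------------------------------------------


def test_all_background_candidates_discarded(background_slide):
    pairs = whole_grid_pairs(background_slide)
    kept, report = filter_patches(pairs, background_slide)
    assert kept == []
    assert report.discard_fraction == 1.0
    assert report.n_candidate_patches == len(pairs)


def test_sparse_epithelium_discards_most_of_grid(random_slide):
    # ~10% of tissue is epithelial; tissue is ~45% of the slide
    _, slide, _ = random_slide
    pairs = whole_grid_pairs(slide)
    kept, report = filter_patches(pairs, slide)
    assert report.discard_fraction >= 0.9


def test_kept_set_invariant_to_input_order(square_slide):
    _, slide, _ = square_slide
    pairs = whole_grid_pairs(slide)
    kept1, _ = filter_patches(pairs, slide)
    kept2, _ = filter_patches(list(reversed(pairs)), slide)
    assert {p.center_xy for p in kept1} == {p.center_xy for p in kept2}


def test_filtering_deterministic(square_slide):
    _, slide, _ = square_slide
    kept1, rep1 = filtering.extract_pairs(slide)
    kept2, rep2 = filtering.extract_pairs(slide)
    assert [p.center_xy for p in kept1] == [p.center_xy for p in kept2]
    assert rep1.to_dict() == rep2.to_dict()


def test_every_kept_center_inside_a_region(random_slide):
    _, slide, _ = random_slide
    cfg = FilterConfig()
    regions = detect_epithelial_regions(slide, cfg)
    pairs = parse_patches(slide, regions, cfg)
    kept, _ = filter_patches(pairs, slide, cfg)
    from shapely.geometry import Point

    union = unary_union(regions)
    for p in kept:
        assert union.buffer(192).contains(Point(*p.center_xy))


@pytest.mark.parametrize(
    "field,raised",
    [
        ("tissue_saturation_min", 0.4),
        ("blur_laplacian_var_min", 1.0),
        ("nuclei_fraction_min", 0.6),
        ("hematoxylin_od_min", 0.5),
        ("epithelial_density_min", 0.6),
        ("min_region_area_px", 10_000_000),
        ("patch_keep_overlap_min", 1.0),
    ],
)
def test_raising_any_threshold_never_increases_kept_count(square_slide, field, raised):
    _, slide, _ = square_slide
    base_cfg = FilterConfig()
    kept_base, _ = filtering.extract_pairs(slide, base_cfg)
    cfg = dataclasses.replace(base_cfg, **{field: raised})
    kept_high, _ = filtering.extract_pairs(slide, cfg)
    assert len(kept_high) <= len(kept_base)
    assert len(kept_base) > 0  # the comparison is not vacuous


def test_report_accounting():
    rep = FilterReport(n_candidate_patches=10, n_kept=4, n_discarded_by_flag={"blur": 2, "no_tissue": 5, "no_nuclei": 1})
    assert rep.n_discarded == 6
    assert rep.discard_fraction == pytest.approx(0.6)
    assert rep.to_dict()["n_discarded_by_flag"]["no_tissue"] == 5
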