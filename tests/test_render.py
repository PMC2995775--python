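"""Rasterization, flood fill, region tracing, hit testing, composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmdx.model import MaskSurface, Shape
from cmdx.render import (
    MultiComponentError,
    flood_fill,
    hit_test,
    polygon_area,
    polygon_mask,
    rasterize_surface,
    render_document,
    save_png,
    trace_region_polygon,
)

from conftest import bfs_flood_reference, fill_holes_reference, point_in_polygon_reference


# -- rasterize_surface -------------------------------------------------------


def test_rectangle_pixel_count_is_exact():
    s = MaskSurface(id="r", shape=Shape.RECTANGLE, rect=(2.0, 2.0, 10.0, 10.0))
    _, count = rasterize_surface(s, (16, 16))
    assert count == 100  # half-open 10x10 square


def test_ellipse_count_close_to_analytic_area():
    s = MaskSurface(id="e", shape=Shape.ELLIPSE, rect=(10.0, 10.0, 100.0, 60.0))
    _, count = rasterize_surface(s, (512, 512))
    assert abs(count - math.pi * 50 * 30) < 0.01 * math.pi * 50 * 30


def test_triangle_count_matches_exhaustive_oracle():
    tri = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)]
    mask = polygon_mask(tri, 16, 16)
    brute = sum(
        point_in_polygon_reference(i + 0.5, j + 0.5, tri) for i in range(16) for j in range(16)
    )
    assert 45 <= mask.sum() <= 55
    assert int(mask.sum()) == brute


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25)
def test_polygon_mask_equals_pointwise_oracle(seed):
    """Vectorised even-odd rasterization agrees with the scalar crossing test."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    poly = [(float(x), float(y)) for x, y in rng.uniform(0, 24, size=(n, 2))]
    mask = polygon_mask(poly, 24, 24)
    for i in range(24):
        for j in range(24):
            assert mask[j, i] == point_in_polygon_reference(i + 0.5, j + 0.5, poly)


def test_degenerate_geometry_rejected():
    s = MaskSurface(id="z", shape=Shape.RECTANGLE, rect=(0.0, 0.0, 0.0, 5.0))
    with pytest.raises(ValueError):
        rasterize_surface(s, (16, 16))


def test_resolution_consistency_of_area_fraction():
    """Convex-surface area fractions converge across grid resolutions."""
    s = MaskSurface(id="e", shape=Shape.ELLIPSE, rect=(50.0, 80.0, 300.0, 180.0))
    _, c512 = rasterize_surface(s, (512, 512))
    hi = MaskSurface(id="e", shape=Shape.ELLIPSE, rect=(100.0, 160.0, 600.0, 360.0))
    _, c1024 = rasterize_surface(hi, (1024, 1024))
    assert abs(c512 / 512**2 - c1024 / 1024**2) < 0.005


# -- flood fill --------------------------------------------------------------


def test_uniform_image_selects_everything():
    img = np.full((20, 30, 3), 128, np.uint8)
    region = flood_fill(img, (5, 5), tolerance=0)
    assert region.count == 20 * 30


def test_diagonal_touch_is_connected():
    img = np.full((4, 4, 3), 255, np.uint8)
    img[0, 0] = img[1, 1] = 0  # two dark pixels touching only diagonally
    region = flood_fill(img, (0, 0), tolerance=0)
    assert region.data[0, 0] and region.data[1, 1]
    assert region.count == 2


def test_annulus_contour_modes():
    img = np.full((40, 40, 3), 255, np.uint8)
    yy, xx = np.mgrid[0:40, 0:40]
    ring = ((xx - 20) ** 2 + (yy - 20) ** 2 <= 15**2) & ((xx - 20) ** 2 + (yy - 20) ** 2 >= 8**2)
    img[ring] = 0
    ring_only = flood_fill(img, (20, 6), 0, outside_contour_only=False)
    with_hole = flood_fill(img, (20, 6), 0, outside_contour_only=True)
    assert ring_only.count == int(ring.sum())
    hole = ((xx - 20) ** 2 + (yy - 20) ** 2 < 8**2).sum()
    assert with_hole.count == int(ring.sum() + hole)


@pytest.mark.parametrize("outside_only", [False, True])
def test_flood_fill_equals_bfs_reference(outside_only):
    """Exact set equality with an independent BFS on random images."""
    rng = np.random.default_rng(2024)
    palette = np.array([[255, 255, 255], [0, 0, 0], [200, 30, 30], [30, 30, 200]], np.uint8)
    for _ in range(30):
        labels = rng.integers(0, 4, size=(16, 16))
        labels = np.kron(labels, np.ones((4, 4), dtype=int))  # 64x64 blocky image
        img = palette[labels]
        seed = (int(rng.integers(0, 64)), int(rng.integers(0, 64)))
        tol = int(rng.choice([0, 10, 60]))
        ours = flood_fill(img, seed, tol, outside_contour_only=outside_only).data
        ref = bfs_flood_reference(img, seed, tol)
        if outside_only:
            ref = fill_holes_reference(ref)
        assert (ours == ref).all()


# -- region tracing ----------------------------------------------------------


def test_trace_square_is_four_vertex_polygon():
    mask = np.zeros((16, 16), bool)
    mask[3:13, 2:12] = True
    poly = trace_region_polygon(mask)
    assert len(poly) == 4
    assert polygon_area(poly) == 100.0


def test_trace_disk_area_within_three_percent():
    yy, xx = np.mgrid[0:48, 0:48]
    disk = (xx - 24) ** 2 + (yy - 24) ** 2 <= 20**2
    poly = trace_region_polygon(disk)
    assert abs(polygon_area(poly) - math.pi * 400) < 0.03 * math.pi * 400


def test_trace_multi_component_error_reports_count():
    mask = np.zeros((10, 10), bool)
    mask[1:3, 1:3] = True
    mask[6:8, 6:8] = True
    with pytest.raises(MultiComponentError) as err:
        trace_region_polygon(mask)
    assert err.value.n_components == 2


def test_trace_preserves_holes_via_keyhole():
    yy, xx = np.mgrid[0:40, 0:40]
    r2 = (xx - 20) ** 2 + (yy - 20) ** 2
    ring = (r2 <= 15**2) & (r2 >= 8**2)
    poly = trace_region_polygon(ring)
    remask = polygon_mask(poly, 40, 40)
    assert (remask == ring).all()


def test_trace_reconstruction_jaccard_on_random_blobs(template):
    """Re-rasterized boundary polygons reproduce the masks they trace."""
    from cmdx.synth import _place_blob, _ellipse_polygon

    rng = np.random.default_rng(7)
    region = _ellipse_polygon((5.0, 5.0, 110.0, 80.0))
    for _ in range(50):
        pts, _ = _place_blob(region, float(rng.uniform(200, 1500)), rng)
        mask = polygon_mask(pts, 128, 128)
        poly = trace_region_polygon(mask)
        remask = polygon_mask(poly, 128, 128)
        jaccard = (remask & mask).sum() / (remask | mask).sum()
        assert jaccard >= 0.96
        # coverage / spill against the spec'd reconstruction quality
        assert (remask & mask).sum() >= 0.98 * mask.sum()
        assert (remask & ~mask).sum() <= 0.02 * mask.sum()


# -- hit test + composition --------------------------------------------------


def test_hit_test_slice_centroid_and_outside(template):
    s = template.mask[0]
    x, y, w, h = s.rect
    assert hit_test(template, (x + w / 2, y + h / 2)) == s.id
    assert hit_test(template, (2.0, 2.0)) is None


def test_hit_test_agrees_with_rasterization(template):
    rng = np.random.default_rng(3)
    grid_size = (512, 512)
    masks = {}
    for s in template.mask:
        grid, _ = rasterize_surface(s, grid_size)
        masks[s.id] = grid.data
    order = [s.id for s in template.mask]
    for _ in range(1000):
        px, py = int(rng.integers(0, 512)), int(rng.integers(0, 512))
        expected = None
        for sid in reversed(order):  # topmost = last in document order
            if masks[sid][py, px]:
                expected = sid
                break
        assert hit_test(template, (px + 0.2, py + 0.7), grid_size) == expected


def test_clip_invariant_no_pixels_outside_surface(tiny_doc):
    """Objects with the clip flag never paint outside their drawing surface."""
    doc = tiny_doc
    focus = doc.map_objects[0]
    focus.points = [(0.0, 0.0), (200.0, 0.0), (200.0, 80.0)]  # spills past slice s1
    focus.style.set_clip = True
    doc.map_objects = [focus]
    img = np.asarray(render_document(doc, grid_size=(160, 160), layers=("draw",)))
    painted = (img != np.array([255, 255, 255, 255], np.uint8)).any(axis=2)
    smask = rasterize_surface(doc.mask[0], (160, 160))[0].data
    assert painted.any()
    assert not (painted & ~smask).any()


def test_render_is_deterministic(specimen, tmp_path):
    doc, _ = specimen
    a, b = tmp_path / "a.png", tmp_path / "b.png"
    save_png(render_document(doc), a)
    save_png(render_document(doc), b)
    assert a.read_bytes() == b.read_bytes()


def test_render_empty_map_is_background_plus_mask(template):
    with_layers = np.asarray(render_document(template))
    without_draw = np.asarray(render_document(template, layers=("background", "mask")))
    assert (with_layers == without_draw).all()
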