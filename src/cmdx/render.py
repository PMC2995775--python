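"""Rasterization and the four-layer visualization model.

All pixel-based quantities in the package (surface pixel volumes, cancer
area fractions, cumulative maps) come from one sampling convention defined
here: pixel ``(i, j)`` covers the half-open unit square ``[i, i+1) x
[j, j+1)`` and belongs to a shape iff its *center* ``(i+0.5, j+0.5)``
passes the shape test — the even-odd rule for polygons, the standard
inequalities for rectangles and ellipses.  The convention is deterministic
and directly checkable against brute-force per-pixel loops.

Rendering composes three drawable layers in a fixed order — background
image, mask (drawing surfaces + border decorations), drawing layer (the
mapped pathology objects) — while the interactive input layer of the
original four-layer model is realized non-interactively as
:func:`hit_test`.  Objects whose style sets the clip flag never paint
outside their drawing surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .model import (
    ArbgColor,
    CmdxDocument,
    MapObject,
    MaskSurface,
    ObjectKind,
    Point,
    PresentationStyle,
    Rect,
    Shape,
)

#: Longest background-image side at the reference resolution used for all
#: pixel-volume and area-fraction computations.
REFERENCE_LONG_SIDE = 512

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class RasterGrid:
    """A pixel grid: binary mask, label/count grid, or RGB(A) image."""

    width: int
    height: int
    data: np.ndarray  # shape (height, width) or (height, width, channels)
    resolution_tag: str = ""

    def __post_init__(self) -> None:
        assert self.data.shape[:2] == (self.height, self.width)

    @property
    def count(self) -> int:
        """Number of set pixels (binary grids)."""
        return int(np.count_nonzero(self.data))


# ---------------------------------------------------------------------------
# Point-membership tests (vectorised over arrays of sample points).


def _polygon_contains(px: np.ndarray, py: np.ndarray, poly: Sequence[Point]) -> np.ndarray:
    """Even-odd (crossing-number) test of sample points against a polygon."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        if y1 == y2:
            continue
        straddles = (y1 <= py) != (y2 <= py)
        with np.errstate(invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (px < xint)
    return inside


def _rect_contains(px: np.ndarray, py: np.ndarray, rect: Rect) -> np.ndarray:
    x, y, w, h = rect
    return (px >= x) & (px < x + w) & (py >= y) & (py < y + h)


def _ellipse_contains(px: np.ndarray, py: np.ndarray, rect: Rect) -> np.ndarray:
    x, y, w, h = rect
    cx, cy = x + w / 2.0, y + h / 2.0
    a, b = w / 2.0, h / 2.0
    return ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 1.0


def _pixel_centers(width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    xs = np.arange(width, dtype=float) + 0.5
    ys = np.arange(height, dtype=float) + 0.5
    return np.meshgrid(xs, ys)


def polygon_mask(poly: Sequence[Point], width: int, height: int) -> np.ndarray:
    """Binary mask of a polygon under the pixel-center even-odd rule."""
    if len(poly) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(poly)}")
    px, py = _pixel_centers(width, height)
    return _polygon_contains(px, py, poly)


def shape_mask(
    shape: Shape,
    width: int,
    height: int,
    points: Optional[Sequence[Point]] = None,
    rect: Optional[Rect] = None,
) -> np.ndarray:
    """Binary mask for any of the three surface shapes."""
    if shape is Shape.POLYGON:
        if points is None:
            raise ValueError("polygon shape requires points")
        return polygon_mask(points, width, height)
    if rect is None:
        raise ValueError(f"{shape.value} shape requires rect")
    if rect[2] <= 0 or rect[3] <= 0:
        raise ValueError(f"degenerate {shape.value}: zero-area rect {rect!r}")
    px, py = _pixel_centers(width, height)
    test = _rect_contains if shape is Shape.RECTANGLE else _ellipse_contains
    return test(px, py, rect)


def rasterize_surface(surface: MaskSurface, grid_size: tuple[int, int]) -> tuple[RasterGrid, int]:
    """Rasterize one drawing surface; returns the mask and its pixel count.

    The count at the reference resolution is the surface's pixel volume.
    """
    width, height = grid_size
    mask = shape_mask(surface.shape, width, height, surface.points, surface.rect)
    count = int(np.count_nonzero(mask))
    if count == 0:
        raise ValueError(f"surface {surface.id!r} rasterizes to zero pixels at {grid_size}")
    tag = f"{width}x{height}"
    return RasterGrid(width, height, mask, tag), count


def reference_grid_size(doc: CmdxDocument) -> tuple[int, int]:
    """Grid size with the longest background side scaled to the reference.

    Documents without a background image use the reference square.
    """
    if doc.background is None:
        return (REFERENCE_LONG_SIDE, REFERENCE_LONG_SIDE)
    from io import BytesIO

    with Image.open(BytesIO(doc.background.data)) as im:
        w, h = im.size
    scale = REFERENCE_LONG_SIDE / max(w, h)
    return (max(1, round(w * scale)), max(1, round(h * scale)))


# ---------------------------------------------------------------------------
# Flood fill (the magic-wand selection) and region tracing.


def flood_fill(
    image: RasterGrid | np.ndarray,
    seed: tuple[int, int],
    tolerance: int = 0,
    outside_contour_only: bool = False,
) -> RasterGrid:
    """8-connected magic-wand selection around a seed pixel.

    Selects the maximal 8-connected set of pixels whose colour lies within
    ``tolerance`` of the seed colour in every channel (Chebyshev distance).
    With ``outside_contour_only`` the selection keeps only its outside
    contour, i.e. interior holes are filled and the region becomes simply
    connected; otherwise holes stay excluded.
    """
    data = image.data if isinstance(image, RasterGrid) else image
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    h, w = arr.shape[:2]
    x, y = seed
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"seed {seed!r} outside {w}x{h} image")
    seed_color = arr[y, x].astype(np.int64)
    within = (np.abs(arr.astype(np.int64) - seed_color) <= tolerance).all(axis=2)
    labels, _ = ndimage.label(within, structure=_EIGHT_CONNECTED)
    region = labels == labels[y, x]
    if outside_contour_only:
        # holes = complement components not reaching the border (4-connected
        # background, the dual of 8-connected foreground)
        region = ndimage.binary_fill_holes(region)
    return RasterGrid(w, h, region, "")


class MultiComponentError(ValueError):
    """Region tracing requires a single connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(f"mask has {n_components} connected components, expected 1")


def trace_region_polygon(mask: RasterGrid | np.ndarray) -> list[Point]:
    """Closed boundary polygon of a one-component binary mask.

    The boundary follows the pixel edges exactly (the union of the covered
    unit squares), so re-rasterizing the polygon under the pixel-center rule
    reproduces the mask.  Interior holes are encoded keyhole-style: the hole
    rings are stitched into the vertex list through doubled bridge edges,
    which cancel under the even-odd rule.
    """
    import shapely
    from shapely.ops import unary_union

    data = mask.data if isinstance(mask, RasterGrid) else mask
    data = np.asarray(data, dtype=bool)
    if not data.any():
        raise ValueError("empty mask")
    _, n = ndimage.label(data, structure=_EIGHT_CONNECTED)
    if n != 1:
        raise MultiComponentError(n)
    ys, xs = np.nonzero(data)
    boxes = shapely.box(xs.astype(float), ys.astype(float), xs + 1.0, ys + 1.0)
    union = unary_union(boxes.tolist())
    if union.geom_type == "MultiPolygon":  # diagonal-only contact: keep them all
        polys = list(union.geoms)
    else:
        polys = [union]
    verts: list[Point] = []
    anchor: Optional[Point] = None
    for poly in polys:
        poly = shapely.simplify(poly, 0)  # merge collinear edge runs
        ext = [(float(x), float(y)) for x, y in poly.exterior.coords[:-1]]
        if anchor is None:
            verts.extend(ext)
            anchor = ext[-1]
        else:
            # bridge from the running polygon into this part and back; the
            # doubled bridge edges cancel under the even-odd rule
            verts.extend(ext + [ext[0], anchor])
        for ring in poly.interiors:
            hole = [(float(x), float(y)) for x, y in ring.coords[:-1]]
            verts.extend(hole + [hole[0], anchor])
    return verts


def polygon_area(poly: Sequence[Point]) -> float:
    """Shoelace area (absolute value) of a closed polygon."""
    arr = np.asarray(poly, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


# ---------------------------------------------------------------------------
# Layer composition.


def _blend_color(color: ArbgColor, opacity: int) -> tuple[int, int, int, int]:
    r, g, b, a = color.rgba
    return (r, g, b, round(a * opacity / 255))


def _object_overlay(obj: MapObject, width: int, height: int) -> Image.Image:
    """Render one map object onto its own transparent RGBA overlay."""
    overlay = Image.new("RGBA", (width, height), (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)
    style = obj.style
    fill = _blend_color(style.brush_color, style.brush_opacity)
    stroke = _blend_color(style.stroke_color, style.stroke_opacity)
    stroke_w = max(1, int(round(style.stroke_width)))
    if obj.points is not None and len(obj.points) >= 3:
        if style.is_filled:
            fmask = polygon_mask(obj.points, width, height)
            layer = np.zeros((height, width, 4), dtype=np.uint8)
            layer[fmask] = fill
            overlay = Image.alpha_composite(overlay, Image.fromarray(layer, "RGBA"))
            draw = ImageDraw.Draw(overlay)
        closed = list(obj.points) + [obj.points[0]]
        draw.line(closed, fill=stroke, width=stroke_w)
    elif obj.points is not None:  # open polyline (capsular invasion etc.)
        if len(obj.points) >= 2:
            draw.line(list(obj.points), fill=stroke, width=stroke_w)
    elif obj.rect is not None:
        x, y, w, h = obj.rect
        if style.is_filled:
            draw.rectangle([x, y, x + w, y + h], fill=fill)
        draw.rectangle([x, y, x + w, y + h], outline=stroke, width=stroke_w)
    elif obj.anchor is not None:
        x, y = obj.anchor
        r = 5
        if obj.kind is ObjectKind.POSITIVE_MARGIN:  # cross marker
            draw.line([x - r, y, x + r, y], fill=stroke, width=2)
            draw.line([x, y - r, x, y + r], fill=stroke, width=2)
        else:  # dot marker (HGPIN and other symbols)
            draw.ellipse([x - r, y - r, x + r, y + r], outline=stroke, fill=fill, width=1)
    return overlay


def _clip_overlay(overlay: Image.Image, surface_mask: np.ndarray) -> Image.Image:
    arr = np.array(overlay)
    arr[~surface_mask, 3] = 0
    return Image.fromarray(arr, "RGBA")


def render_document(
    doc: CmdxDocument,
    grid_size: Optional[tuple[int, int]] = None,
    layers: Iterable[str] = ("background", "mask", "draw"),
) -> Image.Image:
    """Compose the document into an RGBA image, background to drawing layer.

    ``layers`` selects any subset of ``background`` / ``mask`` / ``draw``;
    composition order is fixed regardless of the subset.  Objects with the
    clip flag are intersected with their drawing surface, so they never
    paint outside it.
    """
    if grid_size is None:
        grid_size = reference_grid_size(doc)
    width, height = grid_size
    layers = set(layers)
    canvas = Image.new("RGBA", (width, height), (255, 255, 255, 255))

    if "background" in layers and doc.background is not None:
        from io import BytesIO

        with Image.open(BytesIO(doc.background.data)) as bg:
            bg = bg.convert("RGBA").resize((width, height), Image.BILINEAR)
        canvas = Image.alpha_composite(canvas, bg)

    surface_masks: dict[str, np.ndarray] = {}

    def _surface_mask(surface_id: str) -> np.ndarray:
        if surface_id not in surface_masks:
            grid, _ = rasterize_surface(doc.surface(surface_id), (width, height))
            surface_masks[surface_id] = grid.data
        return surface_masks[surface_id]

    if "mask" in layers:
        for s in doc.mask:  # document order; later surfaces composite on top
            overlay = Image.new("RGBA", (width, height), (0, 0, 0, 0))
            if s.style.is_filled:
                smask = _surface_mask(s.id)
                layer = np.zeros((height, width, 4), dtype=np.uint8)
                layer[smask] = _blend_color(s.style.brush_color, s.style.brush_opacity)
                overlay = Image.alpha_composite(overlay, Image.fromarray(layer, "RGBA"))
            draw = ImageDraw.Draw(overlay)
            if s.border_paint:
                border_col = _blend_color(s.border_stroke_color, 255)
                if s.border_points:
                    draw.line(list(s.border_points) + [s.border_points[0]], fill=border_col, width=2)
                elif s.border_rect:
                    x, y, w, h = s.border_rect
                    draw.rectangle([x, y, x + w, y + h], outline=border_col, width=2)
            canvas = Image.alpha_composite(canvas, overlay)

    if "draw" in layers:
        for obj in doc.map_objects:
            overlay = _object_overlay(obj, width, height)
            if obj.style.set_clip and obj.surface_id is not None:
                overlay = _clip_overlay(overlay, _surface_mask(obj.surface_id))
            canvas = Image.alpha_composite(canvas, overlay)

    return canvas


def hit_test(doc: CmdxDocument, point: Point, grid_size: Optional[tuple[int, int]] = None) -> Optional[str]:
    """Id of the topmost mask surface whose pixel contains ``point``.

    Membership matches :func:`rasterize_surface` exactly: the containing
    pixel's center is tested, so a point and its pixel always agree.
    Surfaces later in document order are on top.
    """
    if grid_size is None:
        grid_size = reference_grid_size(doc)
    width, height = grid_size
    x, y = point
    px, py = int(np.floor(x)), int(np.floor(y))
    if not (0 <= px < width and 0 <= py < height):
        return None
    cx = np.asarray([px + 0.5])
    cy = np.asarray([py + 0.5])
    for s in reversed(doc.mask):
        if s.shape is Shape.POLYGON:
            hit = _polygon_contains(cx, cy, s.points)[0]
        elif s.shape is Shape.RECTANGLE:
            hit = _rect_contains(cx, cy, s.rect)[0]
        else:
            hit = _ellipse_contains(cx, cy, s.rect)[0]
        if hit:
            return s.id
    return None


def save_png(image: Image.Image, path) -> None:
    """Write a PNG with fixed encoder settings (deterministic bytes)."""
    image.save(path, format="PNG", optimize=False, compress_level=6)
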