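"""Domain model for cMDX documents.

A cMDX document describes the pathology report of a radical prostatectomy
specimen.  It is split into *template data* (the reusable anatomical schema:
drawing surfaces for the eight prostate slices and both seminal vesicles,
drawing-tool definitions, a schematic background image) and *patient data*
(the drawn pathology map — carcinoma foci, HGPIN markers, capsular invasion,
surgical-margin symbols — plus the textual findings form).

This module holds the pure in-memory types and their validation; the zip/XML
serialization lives in :mod:`cmdx.package_io`, rasterization and rendering in
:mod:`cmdx.render`, and the cohort analysis engine in :mod:`cmdx.analysis`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Union

from .crypto import CipherEnvelope

Point = tuple[float, float]
Rect = tuple[float, float, float, float]  # x, y, width, height


class Shape(str, enum.Enum):
    """Drawing-surface shape; surfaces are polygons, rectangles or ellipses."""

    POLYGON = "polygon"
    RECTANGLE = "rectangle"
    ELLIPSE = "ellipse"


class BrushType(str, enum.Enum):
    SOLID = "solid"
    HATCH = "hatch"


class ToolType(str, enum.Enum):
    """The four drawing-tool types of the format."""

    POLYGON = "Polygon"
    FLOOD_FILL = "FloodFill"
    CLIP = "Clip"
    IMAGE_WITHOUT_SIZING = "ImageWithoutSizing"


class ObjectKind(str, enum.Enum):
    """What a drawn map object documents."""

    PCA_FOCUS = "pca_focus"
    HGPIN = "hgpin"
    CAPSULAR_INVASION = "capsular_invasion"
    EXTRACAPSULAR_EXTENSION = "extracapsular_extension"
    POSITIVE_MARGIN = "positive_margin"


class SliceLevel(str, enum.Enum):
    """Section level of a drawing surface, base to apex; vesicles separate."""

    BASE = "base"
    MIDDLE1 = "middle1"
    MIDDLE2 = "middle2"
    APEX = "apex"
    VESICLE = "vesicle"


@dataclass
class ArbgColor:
    """A colour with channels stored in the format's A;R;B;G order.

    Note the unconventional channel order (alpha, red, *blue*, green): the
    format serializes colours that way and this type preserves it end to end.
    """

    alpha: int = 255
    red: int = 0
    blue: int = 0
    green: int = 0

    def to_text(self) -> str:
        return f"{self.alpha};{self.red};{self.blue};{self.green}"

    @classmethod
    def from_text(cls, text: str) -> "ArbgColor":
        parts = [int(p.strip() or "0") for p in text.split(";")]
        if len(parts) != 4:
            raise ValueError(f"colour needs 4 channels (A;R;B;G), got {text!r}")
        return cls(*parts)

    @property
    def rgba(self) -> tuple[int, int, int, int]:
        """Channels reordered to the conventional (R, G, B, A)."""
        return (self.red, self.green, self.blue, self.alpha)


@dataclass
class PresentationStyle:
    """Fill and stroke attributes of a surface or drawn object."""

    is_filled: bool = True
    set_clip: bool = False
    brush_type: BrushType = BrushType.SOLID
    brush_color: ArbgColor = field(default_factory=lambda: ArbgColor(180, 255, 0, 0))
    brush_opacity: int = 255
    stroke_color: ArbgColor = field(default_factory=lambda: ArbgColor(255, 0, 0, 0))
    stroke_opacity: int = 255
    stroke_width: float = 1.0
    stroke_dash_style: str = "Solid"
    stroke_start_cap: str = "Flat"
    stroke_end_cap: str = "Flat"
    stroke_line_join: str = "Miter"
    stroke_pen_type: str = "SolidColor"
    stroke_alignment: str = "Center"


@dataclass
class MaskSurface:
    """One drawing surface of the template mask.

    The prostate schema consists of eight slice surfaces plus two seminal
    vesicles.  ``percentage`` is the slice factor: the fraction of whole
    prostate volume attributed to this slice (vesicles carry 0 and are
    excluded from volume estimation).  ``pixel_volume`` is the pixel count of
    the surface at the reference resolution; it is derived at save time.
    ``zone_labels`` holds named sub-region polygons (e.g. ``"PZ"`` for the
    peripheral zone) used by the zone-localization analysis.
    """

    id: str
    name: str = ""
    shape: Shape = Shape.ELLIPSE
    points: Optional[list[Point]] = None
    rect: Optional[Rect] = None
    percentage: float = 0.0
    pixel_volume: Optional[int] = None
    size_of_slice: Optional[tuple[float, float]] = None  # mm
    border_points: Optional[list[Point]] = None
    border_rect: Optional[Rect] = None
    border_stroke_color: ArbgColor = field(default_factory=lambda: ArbgColor(255, 255, 0, 0))
    border_paint: bool = False
    style: PresentationStyle = field(default_factory=PresentationStyle)
    zone_labels: dict[str, list[Point]] = field(default_factory=dict)
    level: Optional[SliceLevel] = None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def is_prostate_slice(self) -> bool:
        return self.level is not SliceLevel.VESICLE


@dataclass
class DrawTool:
    """A drawing-tool definition: a disease code bound to a tool type and style."""

    name: str
    description: str = ""
    text: str = ""
    image_filename: str = ""
    type: ToolType = ToolType.POLYGON
    type_of_clip: Optional[str] = None
    style: PresentationStyle = field(default_factory=PresentationStyle)
    properties: dict[str, str] = field(default_factory=dict)
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class BefundRecord:
    """Histological findings of one carcinoma focus (Gleason patterns etc.)."""

    id: str = ""
    show_gleason: bool = False
    gleason1: Optional[int] = None  # primary pattern, 1-5
    gleason2: Optional[int] = None  # secondary pattern, 1-5
    gleason_score: Optional[int] = None  # 2-10, sum of the patterns
    grading: str = ""
    length: Optional[float] = None  # mm
    width: Optional[float] = None  # mm
    slice_thick: Optional[float] = None  # mm

    @classmethod
    def empty(cls, id: str = "") -> "BefundRecord":
        return cls(id=id, show_gleason=False)


@dataclass
class MapObject:
    """One drawn pathology element on the map.

    Carcinoma foci are polygons; margin and HGPIN markers are anchored
    symbols; capsular invasion / extracapsular extension are open polylines
    stored in ``points``.  ``relation`` / ``relation_slide`` are opaque
    topographical-linkage strings preserved verbatim; analysis only uses
    their equality to link foci across slices.
    """

    id: str
    tool_name: str = ""
    kind: ObjectKind = ObjectKind.PCA_FOCUS
    points: Optional[list[Point]] = None
    rect: Optional[Rect] = None
    anchor: Optional[Point] = None
    style: PresentationStyle = field(default_factory=PresentationStyle)
    relation: str = ""
    relation_slide: str = ""
    befund: Optional[BefundRecord] = None
    surface_id: Optional[str] = None
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class PatientField:
    """One personal-data entry of the form; sensitive entries get encrypted."""

    name: str
    value: Union[str, CipherEnvelope]
    sensitive: bool = True

    @property
    def is_encrypted(self) -> bool:
        return isinstance(self.value, CipherEnvelope)


@dataclass
class FormRecord:
    """Textual findings of the report: staging, grading, node counts, sizes."""

    pT: str = ""
    pN: str = ""
    pM: str = ""
    datum: Optional[date] = None
    kernatypie: str = ""
    diff_muster: str = ""
    klassifizierung_adeno: str = ""
    gls1: str = ""
    gls2: str = ""
    gls_total: str = ""
    g_grading: str = ""
    helpap: str = ""
    L: str = ""
    V: str = ""
    R: str = ""
    lk_b: Optional[int] = None  # lymph nodes with metastases
    lk_g: Optional[int] = None  # extirpated lymph nodes
    prostat_length: Optional[float] = None  # mm
    prostat_width: Optional[float] = None  # mm
    prostat_volumen: Optional[float] = None  # cm^3 (specimen weight in g)
    patient_fields: list[PatientField] = field(default_factory=list)
    encrypted: bool = False
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class BackgroundImage:
    """Raster background (the schematic diagram) as encoded bytes + format."""

    data: bytes
    format: str = "png"  # png / jpeg / bmp / gif / tiff


@dataclass
class CmdxDocument:
    """The full in-memory document: template data + patient data."""

    mask: list[MaskSurface] = field(default_factory=list)
    tools: list[DrawTool] = field(default_factory=list)
    background: Optional[BackgroundImage] = None
    map_objects: list[MapObject] = field(default_factory=list)
    form: FormRecord = field(default_factory=FormRecord)
    template_complete: bool = True
    extras: dict[str, str] = field(default_factory=dict)

    def surface(self, surface_id: str) -> MaskSurface:
        for s in self.mask:
            if s.id == surface_id:
                return s
        raise KeyError(surface_id)

    def tool(self, name: str) -> DrawTool:
        for t in self.tools:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def prostate_slices(self) -> list[MaskSurface]:
        return [s for s in self.mask if s.is_prostate_slice]

    @property
    def foci(self) -> list[MapObject]:
        return [o for o in self.map_objects if o.kind is ObjectKind.PCA_FOCUS]


@dataclass
class Violation:
    """One validation failure: the offending element and the broken rule."""

    element: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.element}] {self.rule}: {self.message}"


def _check_channel(violations: list[Violation], element: str, label: str, value: int) -> None:
    if not (0 <= int(value) <= 255):
        violations.append(
            Violation(element, "channel-range", f"{label} = {value} outside [0, 255]")
        )


def _check_style(violations: list[Violation], element: str, style: PresentationStyle) -> None:
    for label, color in (("brush_color", style.brush_color), ("stroke_color", style.stroke_color)):
        for ch in ("alpha", "red", "blue", "green"):
            _check_channel(violations, element, f"{label}.{ch}", getattr(color, ch))
    _check_channel(violations, element, "brush_opacity", style.brush_opacity)
    _check_channel(violations, element, "stroke_opacity", style.stroke_opacity)
    if style.stroke_width < 0:
        violations.append(
            Violation(element, "stroke-width", f"stroke_width = {style.stroke_width} < 0")
        )


def _check_surface(violations: list[Violation], s: MaskSurface) -> None:
    el = f"MaskSurface:{s.id}"
    has_points = s.points is not None
    has_rect = s.rect is not None
    if s.shape is Shape.POLYGON:
        if not has_points or has_rect:
            violations.append(Violation(el, "geometry-kind", "polygon surface must carry points, not rect"))
        elif len(s.points) < 3:
            violations.append(Violation(el, "polygon-arity", f"polygon has {len(s.points)} vertices (< 3)"))
    else:
        if not has_rect or has_points:
            violations.append(Violation(el, "geometry-kind", f"{s.shape.value} surface must carry rect, not points"))
        elif s.rect[2] <= 0 or s.rect[3] <= 0:
            violations.append(Violation(el, "rect-extent", f"rect width/height must be > 0, got {s.rect!r}"))
    if not (0.0 <= s.percentage <= 1.0):
        violations.append(Violation(el, "slice-factor-range", f"percentage = {s.percentage} outside [0, 1]"))
    if s.pixel_volume is not None and s.pixel_volume <= 0:
        violations.append(Violation(el, "pixel-volume", f"pixel_volume = {s.pixel_volume} must be > 0"))
    for zone, poly in s.zone_labels.items():
        if len(poly) < 3:
            violations.append(Violation(el, "zone-polygon-arity", f"zone {zone!r} has {len(poly)} vertices (< 3)"))
    _check_style(violations, el, s.style)


def _check_tool(violations: list[Violation], t: DrawTool) -> None:
    el = f"DrawTool:{t.name}"
    if not isinstance(t.type, ToolType):
        violations.append(Violation(el, "tool-type", f"unknown tool type {t.type!r}"))
    elif t.type is ToolType.CLIP and not t.type_of_clip:
        violations.append(Violation(el, "clip-needs-type", "type == Clip requires type_of_clip"))
    _check_style(violations, el, t.style)


def _check_befund(violations: list[Violation], element: str, b: BefundRecord) -> None:
    for label, v in (("gleason1", b.gleason1), ("gleason2", b.gleason2)):
        if v is not None and not (1 <= v <= 5):
            violations.append(Violation(element, "gleason-pattern-range", f"{label} = {v} outside [1, 5]"))
    if b.gleason_score is not None and not (2 <= b.gleason_score <= 10):
        violations.append(Violation(element, "gleason-score-range", f"gleason_score = {b.gleason_score} outside [2, 10]"))
    if b.gleason1 is not None and b.gleason2 is not None and b.gleason_score is not None:
        if b.gleason_score != b.gleason1 + b.gleason2:
            violations.append(
                Violation(
                    element,
                    "gleason-score-sum",
                    f"gleason_score {b.gleason_score} != gleason1 {b.gleason1} + gleason2 {b.gleason2}",
                )
            )


def _check_map_object(violations: list[Violation], doc: CmdxDocument, o: MapObject) -> None:
    el = f"MapObject:{o.id}"
    tool_names = {t.name for t in doc.tools}
    surface_ids = {s.id for s in doc.mask}
    if o.tool_name and o.tool_name not in tool_names:
        violations.append(Violation(el, "tool-ref", f"tool_name {o.tool_name!r} does not resolve"))
    if o.surface_id is not None and o.surface_id not in surface_ids:
        violations.append(Violation(el, "surface-ref", f"surface_id {o.surface_id!r} does not resolve"))
    if o.kind is ObjectKind.PCA_FOCUS:
        if o.points is None or len(o.points) < 3:
            n = 0 if o.points is None else len(o.points)
            violations.append(Violation(el, "focus-polygon", f"PCa focus must be a polygon with >= 3 vertices, has {n}"))
    elif o.befund is not None:
        violations.append(Violation(el, "befund-on-non-focus", f"befund not permitted on kind {o.kind.value}"))
    if o.befund is not None:
        _check_befund(violations, el, o.befund)
    _check_style(violations, el, o.style)


def _check_form(violations: list[Violation], f: FormRecord) -> None:
    el = "Form"
    if f.lk_b is not None and f.lk_g is not None and f.lk_b > f.lk_g:
        violations.append(
            Violation(el, "node-counts", f"positive nodes lk_b = {f.lk_b} exceed extirpated lk_g = {f.lk_g}")
        )
    for label, v in (("lk_b", f.lk_b), ("lk_g", f.lk_g)):
        if v is not None and v < 0:
            violations.append(Violation(el, "node-counts", f"{label} = {v} must be >= 0"))
    if f.prostat_volumen is not None and f.prostat_volumen <= 0:
        violations.append(Violation(el, "prostate-volume", f"prostat_volumen = {f.prostat_volumen} must be > 0"))


def validate_document(doc: CmdxDocument) -> list[Violation]:
    """Check every document invariant; return one record per violation.

    Validation never raises: a structurally odd document yields records
    naming the offending element and rule, and an empty list means valid.
    """
    violations: list[Violation] = []
    seen_ids: set[str] = set()
    for s in doc.mask:
        if s.id in seen_ids:
            violations.append(Violation(f"MaskSurface:{s.id}", "duplicate-id", "surface id not unique"))
        seen_ids.add(s.id)
        _check_surface(violations, s)
    for t in doc.tools:
        _check_tool(violations, t)
    for o in doc.map_objects:
        _check_map_object(violations, doc, o)
    _check_form(violations, doc.form)
    if doc.template_complete and doc.prostate_slices:
        total = sum(s.percentage for s in doc.prostate_slices)
        if not (0.99 <= total <= 1.01):
            violations.append(
                Violation(
                    "Mask",
                    "slice-factor-sum",
                    f"slice factors of a complete template must sum to 1 (+-0.01), got {total:.4f}",
                )
            )
    return violations


class DuplicateFocusError(ValueError):
    """Two carcinoma foci share one identifier."""


def resolve_focus_records(doc: CmdxDocument) -> list[tuple[MapObject, BefundRecord]]:
    """Pair every carcinoma focus with its histology record.

    Foci without an embedded record are paired with an empty one
    (``show_gleason`` false) so downstream consumers see a uniform shape.
    """
    pairs: list[tuple[MapObject, BefundRecord]] = []
    seen: dict[str, MapObject] = {}
    for obj in doc.foci:
        if obj.id in seen:
            raise DuplicateFocusError(
                f"duplicate focus id {obj.id!r} on MapObject:{seen[obj.id].id} and MapObject:{obj.id}"
            )
        seen[obj.id] = obj
        pairs.append((obj, obj.befund if obj.befund is not None else BefundRecord.empty(obj.id)))
    return pairs
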