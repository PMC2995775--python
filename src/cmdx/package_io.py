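"""Reading and writing cMDX zip packages.

A cMDX package is a plain zip archive laid out in the spirit of the Open
Packaging Conventions: the ``Resource`` folder holds the reusable template
data (``Mask.xml``, ``Tools.xml`` and the schematic background image) and
the ``Content`` folder the per-patient data (``Map.xml``, ``Form.xml``),
plus a ``[Content_Types].xml`` declaring media types.  The XML vocabulary
follows the format's printed attribute names verbatim (``IsFilled``,
``BrushColor`` in A;R;B;G channel order, ``Points`` as ``"X1;Y1 X2;Y2"``,
``Rectangle`` as ``"X;Y;Width;Height"``, ...).  The histology record of a
carcinoma focus (the ``Befund`` element) travels inside a CDATA section of
its graphic object.

Zone polygons, section levels and object kinds — needed by the analysis
layer but not part of the printed vocabulary — are serialized under a
separate extension namespace so format-conformant readers can ignore them.
Unknown attributes on known elements are preserved in an ``extras`` bag and
round-trip on re-save.  Sensitive patient fields are replaced by
authenticated cipher envelopes when a passphrase is supplied (one key
derivation per save, a fresh nonce per field).
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from datetime import date
from io import BytesIO
from pathlib import Path
from typing import Optional, Sequence

from lxml import etree

from . import crypto
from .crypto import AuthenticationError, CipherEnvelope
from .model import (
    ArbgColor,
    BackgroundImage,
    BefundRecord,
    CmdxDocument,
    DrawTool,
    FormRecord,
    MapObject,
    MaskSurface,
    ObjectKind,
    PatientField,
    Point,
    PresentationStyle,
    Rect,
    Shape,
    SliceLevel,
    ToolType,
    validate_document,
)

CMDX_NS = "urn:cmdx:document:2010"
CMDX_EXT_NS = "urn:cmdx:extensions:2010"
_E = "{%s}" % CMDX_EXT_NS
CONTENT_TYPES_NS = "http://schemas.openxmlformats.org/package/2006/content-types"

_IMAGE_EXTS = {"png": "image/png", "jpg": "image/jpeg", "jpeg": "image/jpeg",
               "bmp": "image/bmp", "gif": "image/gif", "tif": "image/tiff", "tiff": "image/tiff"}


class PackageLayout:
    """Fixed part names of the package."""

    RESOURCE_DIR = "Resource"
    CONTENT_DIR = "Content"
    MASK_PART = "Resource/Mask.xml"
    TOOLS_PART = "Resource/Tools.xml"
    MAP_PART = "Content/Map.xml"
    FORM_PART = "Content/Form.xml"
    CONTENT_TYPES_PART = "[Content_Types].xml"
    NAMESPACE = CMDX_NS


class PackageError(Exception):
    """Base class for package-level failures."""


class PackageStructureError(PackageError):
    """A mandatory part is missing or duplicated."""


class PackageParseError(PackageError):
    """Malformed XML in one part; carries part name and line."""

    def __init__(self, part: str, cause: etree.XMLSyntaxError):
        self.part = part
        self.line = cause.lineno
        super().__init__(f"{part}: malformed XML at line {cause.lineno}: {cause.msg}")


class InvalidDocumentError(PackageError):
    """Refusing to write a document that fails validation."""

    def __init__(self, violations):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:5])
        super().__init__(f"document fails validation ({len(violations)} violations): {lines}")


# ---------------------------------------------------------------------------
# Scalar (de)serialization helpers.


def _num(v: float) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def _bool(v: bool) -> str:
    return "True" if v else "False"


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def format_points(points: Sequence[Point]) -> str:
    """``"X1;Y1 X2;Y2 ..."`` — the format's polygon coordinate syntax."""
    return " ".join(f"{_num(x)};{_num(y)}" for x, y in points)


def parse_points(text: str) -> list[Point]:
    pts = []
    for token in text.split():
        x, y = token.split(";")
        pts.append((float(x), float(y)))
    return pts


def format_rect(rect: Rect) -> str:
    """``"X;Y;Width;Height"`` — the format's rectangle syntax."""
    return ";".join(_num(v) for v in rect)


def parse_rect(text: str) -> Rect:
    x, y, w, h = (float(p) for p in text.split(";"))
    return (x, y, w, h)


_BRUSH_TYPE_TEXT = {"solid": "SolidBrush", "hatch": "HatchBrush"}
_BRUSH_TYPE_FROM = {v: k for k, v in _BRUSH_TYPE_TEXT.items()}


# ---------------------------------------------------------------------------
# Style attributes (Table-1 vocabulary), shared by surfaces, tools, objects.

_STYLE_ATTRS = [
    "IsFilled", "SetClip", "BrushType", "BrushOpacity", "BrushColor",
    "Stroke-Alignment", "StrokeOpacity", "StrokeColor", "StrokeDashstyle",
    "StrokeStartCap", "StrokeEndCap", "StrokeLineJoin", "StrokePentype", "StrokeWidth",
]


def _write_style(el: etree._Element, style: PresentationStyle) -> None:
    el.set("IsFilled", _bool(style.is_filled))
    el.set("SetClip", _bool(style.set_clip))
    el.set("BrushType", _BRUSH_TYPE_TEXT[style.brush_type.value])
    el.set("BrushOpacity", str(int(style.brush_opacity)))
    el.set("BrushColor", style.brush_color.to_text())
    el.set("Stroke-Alignment", style.stroke_alignment)
    el.set("StrokeOpacity", str(int(style.stroke_opacity)))
    el.set("StrokeColor", style.stroke_color.to_text())
    el.set("StrokeDashstyle", style.stroke_dash_style)
    el.set("StrokeStartCap", style.stroke_start_cap)
    el.set("StrokeEndCap", style.stroke_end_cap)
    el.set("StrokeLineJoin", style.stroke_line_join)
    el.set("StrokePentype", style.stroke_pen_type)
    el.set("StrokeWidth", _num(style.stroke_width))


def _read_style(attrs: dict[str, str]) -> PresentationStyle:
    style = PresentationStyle()
    if "IsFilled" in attrs:
        style.is_filled = _parse_bool(attrs["IsFilled"])
    if "SetClip" in attrs:
        style.set_clip = _parse_bool(attrs["SetClip"])
    if "BrushType" in attrs:
        from .model import BrushType
        style.brush_type = BrushType(_BRUSH_TYPE_FROM.get(attrs["BrushType"], "solid"))
    if "BrushOpacity" in attrs:
        style.brush_opacity = int(float(attrs["BrushOpacity"]))
    if "BrushColor" in attrs:
        style.brush_color = ArbgColor.from_text(attrs["BrushColor"])
    if "Stroke-Alignment" in attrs:
        style.stroke_alignment = attrs["Stroke-Alignment"]
    if "StrokeOpacity" in attrs:
        style.stroke_opacity = int(float(attrs["StrokeOpacity"]))
    if "StrokeColor" in attrs:
        style.stroke_color = ArbgColor.from_text(attrs["StrokeColor"])
    if "StrokeDashstyle" in attrs:
        style.stroke_dash_style = attrs["StrokeDashstyle"]
    if "StrokeStartCap" in attrs:
        style.stroke_start_cap = attrs["StrokeStartCap"]
    if "StrokeEndCap" in attrs:
        style.stroke_end_cap = attrs["StrokeEndCap"]
    if "StrokeLineJoin" in attrs:
        style.stroke_line_join = attrs["StrokeLineJoin"]
    if "StrokePentype" in attrs:
        style.stroke_pen_type = attrs["StrokePentype"]
    if "StrokeWidth" in attrs:
        style.stroke_width = float(attrs["StrokeWidth"])
    return style


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _attrs_of(el: etree._Element) -> dict[str, str]:
    """Attribute map with extension-namespace attrs prefixed ``ext:``."""
    out: dict[str, str] = {}
    for k, v in el.attrib.items():
        if k.startswith("{%s}" % CMDX_EXT_NS):
            out["ext:" + k.split("}", 1)[1]] = v
        elif k.startswith("{"):
            out[k] = v  # foreign-namespace attr: preserve raw
        else:
            out[k] = v
    return out


def _collect_extras(attrs: dict[str, str], known: set[str]) -> dict[str, str]:
    return {k: v for k, v in attrs.items() if k not in known}


def _parse_xml(text: str | bytes, part: str) -> etree._Element:
    try:
        if isinstance(text, str):
            text = text.encode("utf-8")
        return etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise PackageParseError(part, exc) from exc


# ---------------------------------------------------------------------------
# Mask part.

_SHAPE_TAG = {Shape.POLYGON: "Polygon", Shape.RECTANGLE: "Rectangle", Shape.ELLIPSE: "Ellipse"}
_TAG_SHAPE = {v: k for k, v in _SHAPE_TAG.items()}

_SURFACE_KNOWN = set(_STYLE_ATTRS) | {
    "Id", "Name", "Percentage", "PixelVolume", "SizeOfSlice", "Points", "Rectangle",
    "Border-Points", "Border-Rectangle", "Border-StrokeColor", "BorderPaint", "ext:Level",
}


def serialize_mask_part(doc: CmdxDocument) -> bytes:
    root = etree.Element("{%s}Mask" % CMDX_NS, nsmap={None: CMDX_NS, "ext": CMDX_EXT_NS})
    root.set("Complete", _bool(doc.template_complete))
    for s in doc.mask:
        el = etree.SubElement(root, "{%s}%s" % (CMDX_NS, _SHAPE_TAG[s.shape]))
        el.set("Id", s.id)
        el.set("Name", s.name)
        el.set("Percentage", _num(s.percentage))
        if s.pixel_volume is not None:
            el.set("PixelVolume", str(int(s.pixel_volume)))
        if s.size_of_slice is not None:
            el.set("SizeOfSlice", f"{_num(s.size_of_slice[0])};{_num(s.size_of_slice[1])}")
        if s.points is not None:
            el.set("Points", format_points(s.points))
        if s.rect is not None:
            el.set("Rectangle", format_rect(s.rect))
        if s.border_points is not None:
            el.set("Border-Points", format_points(s.border_points))
        if s.border_rect is not None:
            el.set("Border-Rectangle", format_rect(s.border_rect))
        el.set("Border-StrokeColor", s.border_stroke_color.to_text())
        el.set("BorderPaint", _bool(s.border_paint))
        _write_style(el, s.style)
        if s.level is not None:
            el.set(_E + "Level", s.level.value)
        for k, v in s.extras.items():
            el.set(k.replace("ext:", _E), v)
        for zone_name, poly in s.zone_labels.items():
            z = etree.SubElement(el, _E + "Zone")
            z.set("Name", zone_name)
            z.set("Points", format_points(poly))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def parse_mask_part(text: str | bytes) -> tuple[list[MaskSurface], bool]:
    """Parse Mask.xml; returns surfaces and the template-complete flag."""
    root = _parse_xml(text, PackageLayout.MASK_PART)
    complete = _parse_bool(root.get("Complete", "True"))
    surfaces: list[MaskSurface] = []
    for el in root:
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag not in _TAG_SHAPE:
            continue
        attrs = _attrs_of(el)
        s = MaskSurface(
            id=attrs.get("Id", ""),
            name=attrs.get("Name", ""),
            shape=_TAG_SHAPE[tag],
            percentage=float(attrs.get("Percentage", "0")),
            style=_read_style(attrs),
        )
        if "PixelVolume" in attrs:
            s.pixel_volume = int(float(attrs["PixelVolume"]))
        if "SizeOfSlice" in attrs:
            a, b = attrs["SizeOfSlice"].split(";")
            s.size_of_slice = (float(a), float(b))
        if "Points" in attrs:
            s.points = parse_points(attrs["Points"])
        if "Rectangle" in attrs:
            s.rect = parse_rect(attrs["Rectangle"])
        if "Border-Points" in attrs:
            s.border_points = parse_points(attrs["Border-Points"])
        if "Border-Rectangle" in attrs:
            s.border_rect = parse_rect(attrs["Border-Rectangle"])
        if "Border-StrokeColor" in attrs:
            s.border_stroke_color = ArbgColor.from_text(attrs["Border-StrokeColor"])
        if "BorderPaint" in attrs:
            s.border_paint = _parse_bool(attrs["BorderPaint"])
        if "ext:Level" in attrs:
            s.level = SliceLevel(attrs["ext:Level"])
        s.extras = _collect_extras(attrs, _SURFACE_KNOWN)
        for child in el:
            if isinstance(child.tag, str) and _localname(child) == "Zone":
                s.zone_labels[child.get("Name", "")] = parse_points(child.get("Points", ""))
        surfaces.append(s)
    return surfaces, complete


# ---------------------------------------------------------------------------
# Tools part.

_TOOL_KNOWN = set(_STYLE_ATTRS) | {"Description", "Name", "Image-Filename", "Text", "Type", "TypeOfClip"}


def serialize_tools_part(doc: CmdxDocument) -> bytes:
    root = etree.Element("{%s}Tools" % CMDX_NS, nsmap={None: CMDX_NS, "ext": CMDX_EXT_NS})
    for t in doc.tools:
        el = etree.SubElement(root, "{%s}DrawTool" % CMDX_NS)
        el.set("Description", t.description)
        el.set("Name", t.name)
        el.set("Image-Filename", t.image_filename)
        el.set("Text", t.text)
        el.set("Type", t.type.value)
        if t.type_of_clip:
            el.set("TypeOfClip", t.type_of_clip)
        _write_style(el, t.style)
        for k, v in t.extras.items():
            el.set(k.replace("ext:", _E), v)
        if t.properties:
            props = etree.SubElement(el, "{%s}Properties" % CMDX_NS)
            for key, value in t.properties.items():
                p = etree.SubElement(props, "{%s}Property" % CMDX_NS)
                p.set("Key", key)
                p.set("Value", value)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def parse_tools_part(text: str | bytes) -> list[DrawTool]:
    root = _parse_xml(text, PackageLayout.TOOLS_PART)
    tools: list[DrawTool] = []
    for el in root:
        if not isinstance(el.tag, str) or _localname(el) != "DrawTool":
            continue
        attrs = _attrs_of(el)
        t = DrawTool(
            name=attrs.get("Name", ""),
            description=attrs.get("Description", ""),
            text=attrs.get("Text", ""),
            image_filename=attrs.get("Image-Filename", ""),
            type=ToolType(attrs.get("Type", "Polygon")),
            type_of_clip=attrs.get("TypeOfClip"),
            style=_read_style(attrs),
        )
        t.extras = _collect_extras(attrs, _TOOL_KNOWN)
        for child in el:
            if isinstance(child.tag, str) and _localname(child) == "Properties":
                for p in child:
                    if isinstance(p.tag, str) and _localname(p) == "Property":
                        t.properties[p.get("Key", "")] = p.get("Value", "")
        tools.append(t)
    return tools


# ---------------------------------------------------------------------------
# Map part.

_KIND_DEFAULT_TAG = {
    ObjectKind.PCA_FOCUS: "Polygon",
    ObjectKind.HGPIN: "Symbol",
    ObjectKind.CAPSULAR_INVASION: "Polyline",
    ObjectKind.EXTRACAPSULAR_EXTENSION: "Polyline",
    ObjectKind.POSITIVE_MARGIN: "Symbol",
}
_TAG_DEFAULT_KIND = {
    "Polygon": ObjectKind.PCA_FOCUS,
    "Polyline": ObjectKind.CAPSULAR_INVASION,
    "Symbol": ObjectKind.POSITIVE_MARGIN,
    "Rectangle": ObjectKind.PCA_FOCUS,
}

_MAP_KNOWN = set(_STYLE_ATTRS) | {
    "Id", "ToolName", "Points", "Rectangle", "Position", "Relation", "RelationSlide",
    "ext:Kind", "ext:SurfaceId",
}


def _serialize_befund(b: BefundRecord) -> str:
    el = etree.Element("Befund")
    el.set("ID", b.id)
    el.set("ShowGleason", _bool(b.show_gleason))
    for attr, value in (
        ("Gleason1", b.gleason1), ("Gleason2", b.gleason2), ("GleasonScore", b.gleason_score),
    ):
        if value is not None:
            el.set(attr, str(int(value)))
    if b.grading:
        el.set("Grading", b.grading)
    for attr, value in (("Length", b.length), ("Width", b.width), ("SliceThick", b.slice_thick)):
        if value is not None:
            el.set(attr, _num(value))
    return etree.tostring(el, encoding="unicode")


def _parse_befund(text: str) -> Optional[BefundRecord]:
    try:
        el = etree.fromstring(text.strip().encode("utf-8"))
    except etree.XMLSyntaxError:
        return None
    if _localname(el) != "Befund":
        return None
    b = BefundRecord(id=el.get("ID", ""), show_gleason=_parse_bool(el.get("ShowGleason", "False")))
    for attr, name in (("Gleason1", "gleason1"), ("Gleason2", "gleason2"), ("GleasonScore", "gleason_score")):
        if el.get(attr) is not None:
            setattr(b, name, int(float(el.get(attr))))
    b.grading = el.get("Grading", "")
    for attr, name in (("Length", "length"), ("Width", "width"), ("SliceThick", "slice_thick")):
        if el.get(attr) is not None:
            setattr(b, name, float(el.get(attr)))
    return b


def serialize_map_part(doc: CmdxDocument) -> bytes:
    root = etree.Element("{%s}Map" % CMDX_NS, nsmap={None: CMDX_NS, "ext": CMDX_EXT_NS})
    for o in doc.map_objects:
        tag = _KIND_DEFAULT_TAG[o.kind]
        if o.rect is not None:
            tag = "Rectangle"
        el = etree.SubElement(root, "{%s}%s" % (CMDX_NS, tag))
        el.set("Id", o.id)
        el.set("ToolName", o.tool_name)
        el.set(_E + "Kind", o.kind.value)
        if o.points is not None:
            el.set("Points", format_points(o.points))
        if o.rect is not None:
            el.set("Rectangle", format_rect(o.rect))
        if o.anchor is not None:
            el.set("Position", f"{_num(o.anchor[0])};{_num(o.anchor[1])}")
        if o.relation:
            el.set("Relation", o.relation)
        if o.relation_slide:
            el.set("RelationSlide", o.relation_slide)
        if o.surface_id is not None:
            el.set(_E + "SurfaceId", o.surface_id)
        _write_style(el, o.style)
        for k, v in o.extras.items():
            el.set(k.replace("ext:", _E), v)
        if o.befund is not None:
            el.text = etree.CDATA(_serialize_befund(o.befund))
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def parse_map_part(text: str | bytes) -> list[MapObject]:
    """Parse Map.xml.  A CDATA payload that is not a parseable ``Befund``
    element keeps its object with no record (per-object leniency)."""
    root = _parse_xml(text, PackageLayout.MAP_PART)
    objects: list[MapObject] = []
    for el in root:
        if not isinstance(el.tag, str):
            continue
        tag = _localname(el)
        if tag not in _TAG_DEFAULT_KIND and tag != "Symbol":
            continue
        attrs = _attrs_of(el)
        kind = ObjectKind(attrs["ext:Kind"]) if "ext:Kind" in attrs else _TAG_DEFAULT_KIND.get(tag, ObjectKind.PCA_FOCUS)
        o = MapObject(
            id=attrs.get("Id", ""),
            tool_name=attrs.get("ToolName", ""),
            kind=kind,
            style=_read_style(attrs),
            relation=attrs.get("Relation", ""),
            relation_slide=attrs.get("RelationSlide", ""),
            surface_id=attrs.get("ext:SurfaceId"),
        )
        if "Points" in attrs:
            o.points = parse_points(attrs["Points"])
        if "Rectangle" in attrs:
            o.rect = parse_rect(attrs["Rectangle"])
        if "Position" in attrs:
            x, y = attrs["Position"].split(";")
            o.anchor = (float(x), float(y))
        o.extras = _collect_extras(attrs, _MAP_KNOWN)
        if el.text and el.text.strip():
            o.befund = _parse_befund(el.text)
        objects.append(o)
    return objects


# ---------------------------------------------------------------------------
# Form part.

_FORM_FIELD_ATTRS = [
    ("pT", "pT"), ("pN", "pN"), ("pM", "pM"), ("Kernatypie", "kernatypie"),
    ("DiffMuster", "diff_muster"), ("KlassifizierungAdeno", "klassifizierung_adeno"),
    ("GLS1", "gls1"), ("GLS2", "gls2"), ("GLSTotal", "gls_total"),
    ("GGrading", "g_grading"), ("HELPAP", "helpap"), ("L", "L"), ("V", "V"), ("R", "R"),
]
_FORM_NUM_ATTRS = [
    ("LK-B", "lk_b", int), ("LK-G", "lk_g", int),
    ("ProstatLength", "prostat_length", float), ("ProstatWidth", "prostat_width", float),
    ("Prostatvolumen", "prostat_volumen", float),
]
_FORM_KNOWN = {a for a, _ in _FORM_FIELD_ATTRS} | {a for a, _, _ in _FORM_NUM_ATTRS} | {"Datum"}


def serialize_form_part(doc: CmdxDocument, keys: Optional[crypto.KeyMaterial] = None) -> bytes:
    root = etree.Element("{%s}Form" % CMDX_NS, nsmap={None: CMDX_NS, "ext": CMDX_EXT_NS})
    f = doc.form
    el = etree.SubElement(root, "{%s}Formular" % CMDX_NS)
    for attr, name in _FORM_FIELD_ATTRS:
        value = getattr(f, name)
        if value:
            el.set(attr, value)
    if f.datum is not None:
        el.set("Datum", f.datum.isoformat())
    for attr, name, kind in _FORM_NUM_ATTRS:
        value = getattr(f, name)
        if value is not None:
            el.set(attr, str(int(value)) if kind is int else _num(value))
    for k, v in f.extras.items():
        el.set(k.replace("ext:", _E), v)
    for pf in f.patient_fields:
        fe = etree.SubElement(el, "{%s}Field" % CMDX_NS)
        fe.set("Name", pf.name)
        fe.set("Sensitive", _bool(pf.sensitive))
        value = pf.value
        if keys is not None and pf.sensitive and isinstance(value, str):
            value = crypto.encrypt_field(value, keys=keys)
        if isinstance(value, CipherEnvelope):
            fe.set("Encrypted", "True")
            fe.set("Value", value.to_text())
        else:
            fe.set("Encrypted", "False")
            fe.set("Value", value)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def parse_form_part(text: str | bytes, passphrase: Optional[str] = None) -> FormRecord:
    root = _parse_xml(text, PackageLayout.FORM_PART)
    f = FormRecord()
    formular = None
    for el in root:
        if isinstance(el.tag, str) and _localname(el) == "Formular":
            formular = el
            break
    if formular is None:
        return f
    attrs = _attrs_of(formular)
    for attr, name in _FORM_FIELD_ATTRS:
        if attr in attrs:
            setattr(f, name, attrs[attr])
    if "Datum" in attrs:
        f.datum = date.fromisoformat(attrs["Datum"])
    for attr, name, kind in _FORM_NUM_ATTRS:
        if attr in attrs:
            setattr(f, name, kind(float(attrs[attr])))
    f.extras = _collect_extras(attrs, _FORM_KNOWN)
    any_encrypted = False
    for el in formular:
        if not isinstance(el.tag, str) or _localname(el) != "Field":
            continue
        value: str | CipherEnvelope = el.get("Value", "")
        if _parse_bool(el.get("Encrypted", "False")):
            envelope = CipherEnvelope.from_text(value)
            if passphrase is not None:
                value = crypto.decrypt_field(envelope, passphrase)
            else:
                value = envelope
                any_encrypted = True
        f.patient_fields.append(
            PatientField(name=el.get("Name", ""), value=value, sensitive=_parse_bool(el.get("Sensitive", "True")))
        )
    f.encrypted = any_encrypted
    return f


# ---------------------------------------------------------------------------
# Whole-package read/write.


@dataclass
class PackageSummary:
    """Part names and sizes of a written package."""

    path: Path
    parts: list[tuple[str, int]]


def _content_types_part(image_ext: str) -> bytes:
    root = etree.Element("{%s}Types" % CONTENT_TYPES_NS, nsmap={None: CONTENT_TYPES_NS})
    for ext, mime in (("xml", "application/xml"), (image_ext, _IMAGE_EXTS.get(image_ext, "application/octet-stream"))):
        d = etree.SubElement(root, "{%s}Default" % CONTENT_TYPES_NS)
        d.set("Extension", ext)
        d.set("ContentType", mime)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def refresh_pixel_volumes(doc: CmdxDocument) -> None:
    """Recompute every surface's pixel volume at the reference resolution.

    Pixel volume is treated as derived data, rewritten on each save.
    """
    from .render import rasterize_surface, reference_grid_size

    grid_size = reference_grid_size(doc)
    for s in doc.mask:
        _, count = rasterize_surface(s, grid_size)
        s.pixel_volume = count


def write_cmdx(doc: CmdxDocument, destination, passphrase: Optional[str] = None) -> PackageSummary:
    """Write a document to a cMDX zip package.

    Validates first and refuses invalid documents.  With a passphrase,
    sensitive patient fields are encrypted (one key derivation per save,
    fresh nonce per field).  Surfaces' pixel volumes are recomputed at the
    reference resolution and recorded both in the package and on ``doc``.
    """
    violations = validate_document(doc)
    if violations:
        raise InvalidDocumentError(violations)
    refresh_pixel_volumes(doc)
    keys = crypto.derive_keys(passphrase) if passphrase else None
    image_ext = (doc.background.format if doc.background else "png").lower()
    if image_ext == "svg":
        raise PackageError("SVG backgrounds are not supported; rasterize to PNG first")
    parts: list[tuple[str, bytes]] = [
        (PackageLayout.CONTENT_TYPES_PART, _content_types_part(image_ext)),
        (PackageLayout.MASK_PART, serialize_mask_part(doc)),
        (PackageLayout.TOOLS_PART, serialize_tools_part(doc)),
        (PackageLayout.MAP_PART, serialize_map_part(doc)),
        (PackageLayout.FORM_PART, serialize_form_part(doc, keys)),
    ]
    if doc.background is not None:
        parts.append((f"{PackageLayout.RESOURCE_DIR}/BGImage.{image_ext}", doc.background.data))
    destination = Path(destination)
    with zipfile.ZipFile(destination, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in parts:
            # fixed timestamp so identical documents give identical archives
            info = zipfile.ZipInfo(name, date_time=(2010, 11, 15, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)
    return PackageSummary(destination, [(name, len(data)) for name, data in parts])


def read_cmdx(source, passphrase: Optional[str] = None) -> CmdxDocument:
    """Read a cMDX zip package into a document.

    Encrypted fields are decrypted when a passphrase is supplied, otherwise
    kept as opaque envelopes with the form's ``encrypted`` flag set.
    """
    source = Path(source)
    try:
        zf = zipfile.ZipFile(source)
    except (zipfile.BadZipFile, FileNotFoundError) as exc:
        raise PackageStructureError(f"{source}: not a readable zip package ({exc})") from exc
    with zf:
        names = set(zf.namelist())
        for part in (PackageLayout.MASK_PART, PackageLayout.TOOLS_PART,
                     PackageLayout.MAP_PART, PackageLayout.FORM_PART):
            if part not in names:
                raise PackageStructureError(f"{part.split('/')[-1]} missing from package {source.name}")
        images = [n for n in names
                  if n.startswith(PackageLayout.RESOURCE_DIR + "/")
                  and n.rsplit(".", 1)[-1].lower() in _IMAGE_EXTS]
        if len(images) > 1:
            raise PackageStructureError(f"package has {len(images)} background images, expected one")
        surfaces, complete = parse_mask_part(zf.read(PackageLayout.MASK_PART))
        tools = parse_tools_part(zf.read(PackageLayout.TOOLS_PART))
        map_objects = parse_map_part(zf.read(PackageLayout.MAP_PART))
        form = parse_form_part(zf.read(PackageLayout.FORM_PART), passphrase)
        background = None
        if images:
            ext = images[0].rsplit(".", 1)[-1].lower()
            background = BackgroundImage(zf.read(images[0]), "jpeg" if ext == "jpg" else ext)
    return CmdxDocument(
        mask=surfaces,
        tools=tools,
        background=background,
        map_objects=map_objects,
        form=form,
        template_complete=complete,
    )


# Convenience re-exports used by the CLI and analysis layers.
encrypt_field = crypto.encrypt_field
decrypt_field = crypto.decrypt_field
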