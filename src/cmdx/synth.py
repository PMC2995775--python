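"""Synthetic specimen generator with recorded ground truth.

No real patient data ships with the package; every analysis stage is
exercised against synthetic radical-prostatectomy specimens drawn on the
default template (eight elliptical prostate slices at four section levels —
base, two middle levels, apex — plus both seminal vesicles, each slice
carrying a slice factor and a dorsal peripheral-zone sub-polygon).

Foci are random star-convex blobs scaled to an exact target area fraction
of their slice and placed fully inside the peripheral zone (with
probability ``pz_bias``) or fully outside it, so the generator knows each
focus's zone membership and area fraction exactly.  Multifocal specimens
receive their foci in distinct slices ("well separated"); a configurable
fraction instead receives a pair of thin diagonal foci in one slice whose
polygons are disjoint but whose bounding rectangles overlap — the geometry
that makes rectangle-based clustering falsely merge adjacent foci.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date, timedelta
from io import BytesIO
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from shapely.geometry import Point as ShapelyPoint
from shapely.geometry import Polygon as ShapelyPolygon

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
    Shape,
    SliceLevel,
    ToolType,
)

_TEMPLATE_SIZE = 512
# dyadic slice factors (exact binary fractions, per-slice, summing to 1)
_LEVEL_FACTORS = {
    SliceLevel.BASE: 17 / 128,
    SliceLevel.MIDDLE1: 19 / 128,
    SliceLevel.MIDDLE2: 17 / 128,
    SliceLevel.APEX: 11 / 128,
}
_PZ_CHORD = 0.15  # dorsal chord position (fraction of the semi-minor axis)


class PlacementError(RuntimeError):
    """Focus placement failed after bounded retries."""


def _ellipse_polygon(rect, n: int = 96) -> ShapelyPolygon:
    x, y, w, h = rect
    cx, cy, a, b = x + w / 2, y + h / 2, w / 2, h / 2
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ShapelyPolygon(np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)]))


def _pz_polygon(rect, n: int = 24) -> list[Point]:
    """Dorsal (image-lower) segment of a slice ellipse below a chord."""
    x, y, w, h = rect
    cx, cy, a, b = x + w / 2, y + h / 2, w / 2, h / 2
    t1 = float(np.arcsin(_PZ_CHORD))
    t = np.linspace(t1, np.pi - t1, n)
    arc = [(cx + a * np.cos(tt), cy + b * np.sin(tt)) for tt in t]
    return arc  # chord closes the polygon implicitly


def _draw_background() -> bytes:
    img = Image.new("RGB", (_TEMPLATE_SIZE, _TEMPLATE_SIZE), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    for rect, _, _ in _surface_layout():
        x, y, w, h = rect
        draw.ellipse([x, y, x + w, y + h], outline=(120, 120, 120), width=2)
    buf = BytesIO()
    img.save(buf, format="PNG", optimize=False, compress_level=6)
    return buf.getvalue()


def _surface_layout() -> list[tuple[tuple, str, SliceLevel]]:
    rows = [
        (84, SliceLevel.BASE, "base"),
        (188, SliceLevel.MIDDLE1, "middle1"),
        (292, SliceLevel.MIDDLE2, "middle2"),
        (396, SliceLevel.APEX, "apex"),
    ]
    layout = []
    for yy, level, tag in rows:
        layout.append(((36.0, float(yy), 200.0, 96.0), f"slice_{tag}_l", level))
        layout.append(((276.0, float(yy), 200.0, 96.0), f"slice_{tag}_r", level))
    layout.append(((120.0, 14.0, 80.0, 56.0), "vesicle_l", SliceLevel.VESICLE))
    layout.append(((312.0, 14.0, 80.0, 56.0), "vesicle_r", SliceLevel.VESICLE))
    return layout


def make_default_template() -> CmdxDocument:
    """Build the default anatomical template.

    Eight elliptical prostate slices (two per section level, base to apex)
    with slice factors summing to one, two seminal-vesicle surfaces with
    factor zero, a dorsal peripheral-zone polygon per slice, the standard
    drawing-tool set, and a programmatically drawn schematic background.
    """
    surfaces: list[MaskSurface] = []
    for rect, sid, level in _surface_layout():
        is_slice = level is not SliceLevel.VESICLE
        s = MaskSurface(
            id=sid,
            name=sid.replace("_", " "),
            shape=Shape.ELLIPSE,
            rect=rect,
            percentage=_LEVEL_FACTORS[level] if is_slice else 0.0,
            border_rect=rect,
            border_paint=True,
            border_stroke_color=ArbgColor(255, 220, 60, 60),
            style=PresentationStyle(is_filled=False, stroke_width=1.0),
            level=level,
        )
        if is_slice:
            s.zone_labels["PZ"] = _pz_polygon(rect)
        surfaces.append(s)

    red_fill = PresentationStyle(
        is_filled=True,
        set_clip=True,
        brush_color=ArbgColor(160, 220, 40, 40),
        stroke_color=ArbgColor(255, 160, 20, 20),
        stroke_width=1.5,
    )
    tools = [
        DrawTool(name="HGPIN", description="High grade Prostatic Intraepithelial Neoplasia",
                 text="High grade Prostatic Intraepithelial Neoplasia",
                 image_filename="hgpin.png", type=ToolType.IMAGE_WITHOUT_SIZING),
        DrawTool(name="PCA", description="Adenocarcinoma", text="Adenocarcinoma of the prostate",
                 type=ToolType.POLYGON, style=red_fill),
        DrawTool(name="PCA_WAND", description="Adenocarcinoma", text="Adenocarcinoma of the prostate",
                 type=ToolType.FLOOD_FILL, style=red_fill),
        DrawTool(name="CAPS_INV", description="Capsular invasion", text="Capsular invasion",
                 type=ToolType.CLIP, type_of_clip="Polygon"),
        DrawTool(name="EXTRACAPS", description="Extracapsular extension", text="Extracapsular extension",
                 type=ToolType.CLIP, type_of_clip="Polygon"),
        DrawTool(name="MARGIN", description="positive surgical margin", text="Positive surgical margin",
                 image_filename="margin.png", type=ToolType.IMAGE_WITHOUT_SIZING),
    ]
    return CmdxDocument(
        mask=surfaces,
        tools=tools,
        background=BackgroundImage(_draw_background(), "png"),
        template_complete=True,
    )


# ---------------------------------------------------------------------------
# Cohort parameters + ground truth containers.


@dataclass
class CohortParams:
    """Study conditions of a synthetic cohort.

    Defaults emulate the reference cohort scale: 255 specimens, a 52.5%
    multifocal rate, cancer predominantly in the peripheral zone.
    ``adjacency_fraction`` is the fraction of multifocal specimens whose
    foci get overlapping bounding rectangles (the false-merge failure mode
    of rectangle clustering); the default keeps foci well separated.
    """

    n_specimens: int = 255
    seed: int = 0
    foci_mean: float = 2.8  # truncated-Poisson mean cluster count of multifocal specimens
    focus_size_a: float = 2.0  # Beta shape parameters of the per-slice area fraction
    focus_size_b: float = 18.0
    focus_size_min: float = 0.01
    focus_size_max: float = 0.35
    multifocal_rate: float = 0.525
    pz_bias: float = 0.75
    prostate_volume_mean: float = 40.0  # cm^3
    prostate_volume_sd: float = 12.0
    prostate_volume_min: float = 15.0
    adjacency_fraction: float = 0.0

    def validate(self) -> None:
        for name in ("multifocal_rate", "pz_bias", "adjacency_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if not (0.0 < self.focus_size_min < self.focus_size_max <= 1.0):
            raise ValueError("focus size bounds must satisfy 0 < min < max <= 1")
        if self.prostate_volume_min <= 0:
            raise ValueError("prostate_volume_min must be > 0")


@dataclass
class FocusTruth:
    focus_id: str
    surface_id: str
    area_fraction: float  # of the slice, analytic (shoelace / ellipse area)
    in_pz: bool
    cluster_id: int


@dataclass
class SpecimenTruth:
    specimen_id: str
    focality: str  # true label from the placement, not from any classifier
    n_clusters: int
    prostate_volume: float
    relative_volume: float  # sum of area_fraction * slice factor
    foci: list[FocusTruth] = field(default_factory=list)
    slices_with_cancer: set[str] = field(default_factory=set)
    adjacency_pair: bool = False


@dataclass
class CohortTruth:
    specimens: list[SpecimenTruth]

    @property
    def multifocal_rate(self) -> float:
        n = len(self.specimens)
        return sum(s.focality == "multifocal" for s in self.specimens) / n if n else 0.0

    @property
    def n_foci(self) -> int:
        return sum(len(s.foci) for s in self.specimens)

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.specimens:
            rows.append(
                {
                    "id": s.specimen_id,
                    "focality": s.focality,
                    "n_clusters": s.n_clusters,
                    "n_foci": len(s.foci),
                    "prostate_volume_cm3": s.prostate_volume,
                    "relative_volume": s.relative_volume,
                    "tumour_volume_cm3": s.relative_volume * s.prostate_volume,
                    "adjacency_pair": s.adjacency_pair,
                    "slices_with_cancer": ";".join(sorted(s.slices_with_cancer)),
                    "pz_foci": sum(f.in_pz for f in s.foci),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Focus geometry.


def _star_blob_unit(rng: np.random.Generator, n_vertices: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed star-convex radial profile around the unit circle."""
    noise = rng.normal(0.0, 1.0, n_vertices)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    wrapped = np.r_[noise[-2:], noise, noise[:2]]
    smooth = np.convolve(wrapped, kernel, mode="valid")
    radii = np.exp(0.25 * smooth)  # positive, ~ +-30% modulation
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return radii, angles


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _sample_point_in(region, rng: np.random.Generator, tries: int = 400) -> Optional[tuple[float, float]]:
    minx, miny, maxx, maxy = region.bounds
    for _ in range(tries):
        p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if region.contains(ShapelyPoint(p)):
            return p
    return None


def _largest_piece(geom) -> Optional[ShapelyPolygon]:
    if geom.is_empty:
        return None
    if geom.geom_type == "Polygon":
        return geom
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        polys = [g for g in geom.geoms if g.geom_type == "Polygon" and g.area > 0]
        return max(polys, key=lambda g: g.area) if polys else None
    return None


def _place_blob(
    region, target_area: float, rng: np.random.Generator
) -> tuple[list[Point], float]:
    """Place a star-convex blob of ``target_area`` inside ``region``.

    The blob is clipped to the region and iteratively rescaled about its
    center until the clipped area matches the target (0.5% tolerance, or
    the region's capacity if the target exceeds it).  Returns the polygon
    and the realized area, which downstream ground truth records.
    """
    area = target_area
    for _ in range(10):
        radii, angles = _star_blob_unit(rng)
        unit = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
        scale = float(np.sqrt(area / _shoelace(unit)))
        rmax = scale * float(radii.max())
        center = None
        for margin in (1.0, 0.6, 0.3, 0.05):  # prefer fully interior placements
            allowed = region.buffer(-margin * rmax)
            if not allowed.is_empty:
                center = _sample_point_in(allowed, rng)
                if center is not None:
                    break
        if center is None:
            area *= 0.6  # shrink and retry: focus did not fit the region
            continue
        c = np.asarray(center)
        piece = None
        for _ in range(20):
            pts = unit * scale + c
            piece = _largest_piece(ShapelyPolygon(pts).intersection(region))
            if piece is None or piece.area <= 0:
                scale *= 0.7
                continue
            if abs(piece.area - area) <= 0.005 * area:
                break
            factor = float(np.sqrt(area / piece.area))
            scale *= float(np.clip(factor, 0.6, 1.6))
        if piece is not None and piece.area > 0:
            out = [(float(x), float(y)) for x, y in piece.exterior.coords[:-1]]
            return out, float(piece.area)
        area *= 0.6
    raise PlacementError(f"could not fit a focus of area {target_area:.1f} px^2 into the region")


def _diagonal_strip_pair(
    slice_poly: ShapelyPolygon, rng: np.random.Generator
) -> tuple[list[Point], list[Point], float]:
    """Two thin disjoint diagonal foci whose bounding rectangles overlap."""
    half_len, half_w, offset = 22.0, 3.5, 9.0
    u = np.array([1.0, 1.0]) / np.sqrt(2.0)  # strip direction (45 degrees)
    v = np.array([-1.0, 1.0]) / np.sqrt(2.0)  # perpendicular
    margin = half_len + offset + half_w + 2.0
    allowed = slice_poly.buffer(-margin)
    if allowed.is_empty:
        raise PlacementError("slice too small for an adjacent-foci pair")
    center = _sample_point_in(allowed, rng)
    if center is None:
        raise PlacementError("could not sample a center for the adjacent-foci pair")
    c = np.asarray(center)
    strips = []
    for sign in (+1.0, -1.0):
        ci = c + sign * offset * v
        corners = [
            ci + half_len * u + half_w * v,
            ci + half_len * u - half_w * v,
            ci - half_len * u - half_w * v,
            ci - half_len * u + half_w * v,
        ]
        strips.append([tuple(p) for p in corners])
    area_each = (2 * half_len) * (2 * half_w)
    return strips[0], strips[1], area_each


# ---------------------------------------------------------------------------
# Specimen + cohort simulation.


def _slice_regions(template: CmdxDocument) -> dict[str, dict]:
    regions = {}
    for s in template.prostate_slices:
        poly = _ellipse_polygon(s.rect)
        pz = ShapelyPolygon(s.zone_labels["PZ"]) if "PZ" in s.zone_labels else None
        non_pz = poly.difference(pz.buffer(1.0)) if pz is not None else poly
        regions[s.id] = {
            "surface": s,
            "poly": poly,
            "area": poly.area,
            "pz": pz,
            "non_pz": non_pz,
            "factor": s.percentage,
        }
    return regions


def _focus_style() -> PresentationStyle:
    return PresentationStyle(
        is_filled=True,
        set_clip=True,
        brush_color=ArbgColor(160, 220, 40, 40),
        stroke_color=ArbgColor(255, 160, 20, 20),
        stroke_width=1.5,
    )


def simulate_specimen(
    template: CmdxDocument,
    params: CohortParams,
    seed: Union[int, np.random.Generator],
    specimen_id: str = "specimen",
) -> tuple[CmdxDocument, SpecimenTruth]:
    """Draw one synthetic specimen on the template; reproducible given a seed."""
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = _slice_regions(template)
    slice_ids = list(regions)

    doc = copy.deepcopy(template)
    doc.map_objects = []

    multifocal = bool(rng.random() < params.multifocal_rate)
    if multifocal:
        extra = rng.poisson(max(params.foci_mean - 2.0, 0.0))
        n_clusters = int(min(2 + extra, len(slice_ids)))
    else:
        n_clusters = 1
    adjacency = multifocal and bool(rng.random() < params.adjacency_fraction)

    truth = SpecimenTruth(
        specimen_id=specimen_id,
        focality="multifocal" if multifocal else "unifocal",
        n_clusters=n_clusters,
        prostate_volume=float(
            max(rng.normal(params.prostate_volume_mean, params.prostate_volume_sd), params.prostate_volume_min)
        ),
        relative_volume=0.0,
        adjacency_pair=adjacency,
    )

    def _add_focus(pts: list[Point], sid: str, frac: float, in_pz: bool, cluster: int) -> None:
        idx = len(truth.foci)
        fid = f"{specimen_id}_f{idx}"
        g1, g2 = (int(rng.choice([3, 4, 5], p=[0.5, 0.35, 0.15])) for _ in range(2))
        doc.map_objects.append(
            MapObject(
                id=fid,
                tool_name="PCA",
                kind=ObjectKind.PCA_FOCUS,
                points=pts,
                style=_focus_style(),
                surface_id=sid,
                befund=BefundRecord(id=fid, show_gleason=True, gleason1=g1, gleason2=g2,
                                    gleason_score=g1 + g2),
            )
        )
        truth.foci.append(FocusTruth(fid, sid, frac, in_pz, cluster))
        truth.slices_with_cancer.add(sid)
        truth.relative_volume += frac * regions[sid]["factor"]

    def _sample_fraction() -> float:
        f = rng.beta(params.focus_size_a, params.focus_size_b)
        return float(np.clip(f, params.focus_size_min, params.focus_size_max))

    if adjacency:
        # one slice holds the deliberately adjacent pair; remaining clusters
        # (if any) go to other slices
        order = list(rng.permutation(slice_ids))
        pair_slice = order.pop(0)
        r = regions[pair_slice]
        a_pts, b_pts, area_each = _diagonal_strip_pair(r["poly"], rng)
        frac = area_each / r["area"]
        _add_focus(a_pts, pair_slice, frac, False, cluster=0)
        _add_focus(b_pts, pair_slice, frac, False, cluster=1)
        remaining = max(n_clusters - 2, 0)
        targets = order[:remaining]
        next_cluster = 2
    else:
        order = list(rng.permutation(slice_ids))
        targets = order[:n_clusters]
        next_cluster = 0

    for sid in targets:
        r = regions[sid]
        in_pz = bool(r["pz"] is not None and rng.random() < params.pz_bias)
        region = r["pz"] if in_pz else r["non_pz"]
        frac = _sample_fraction()
        pts, area = _place_blob(region, frac * r["area"], rng)
        _add_focus(pts, sid, area / r["area"], in_pz, cluster=next_cluster)
        next_cluster += 1

    # occasional non-carcinoma annotations, for serialization coverage
    if rng.random() < 0.3:
        sid = str(rng.choice(slice_ids))
        x, y, w, h = regions[sid]["surface"].rect
        doc.map_objects.append(
            MapObject(id=f"{specimen_id}_margin", tool_name="MARGIN", kind=ObjectKind.POSITIVE_MARGIN,
                      anchor=(x + w / 2, y + h), surface_id=sid,
                      style=PresentationStyle(is_filled=False)))
    if rng.random() < 0.3:
        sid = str(rng.choice(slice_ids))
        c = regions[sid]["poly"].centroid
        doc.map_objects.append(
            MapObject(id=f"{specimen_id}_hgpin", tool_name="HGPIN", kind=ObjectKind.HGPIN,
                      anchor=(c.x, c.y), surface_id=sid,
                      style=PresentationStyle(is_filled=False)))

    pt_stage = str(rng.choice(["pT2a", "pT2b", "pT2c", "pT3a", "pT3b"], p=[0.1, 0.1, 0.45, 0.25, 0.1]))
    lk_g = int(rng.integers(4, 21))
    lk_b = int(rng.integers(0, min(lk_g, 3) + 1))
    scores = [f.cluster_id for f in truth.foci]  # noqa: F841  (kept for symmetry)
    g1s = [o.befund.gleason1 for o in doc.foci if o.befund]
    g2s = [o.befund.gleason2 for o in doc.foci if o.befund]
    doc.form = FormRecord(
        pT=pt_stage, pN="pN0" if lk_b == 0 else "pN1", pM="pM0",
        datum=date(2010, 1, 1) + timedelta(days=int(rng.integers(0, 300))),
        gls1=str(max(g1s)) if g1s else "", gls2=str(max(g2s)) if g2s else "",
        gls_total=str(max(g1s) + max(g2s)) if g1s else "",
        helpap=str(rng.choice(["IIa", "IIb", "IIIa"])),
        L=str(rng.choice(["L0", "L1"], p=[0.8, 0.2])),
        V=str(rng.choice(["V0", "V1"], p=[0.9, 0.1])),
        R=str(rng.choice(["R0", "R1"], p=[0.85, 0.15])),
        lk_b=lk_b, lk_g=lk_g,
        prostat_volumen=round(truth.prostate_volume, 1),
        patient_fields=[
            PatientField("PatientName", f"Synthetic Patient {specimen_id}", sensitive=True),
            PatientField("PatientID", f"SYN-{specimen_id}", sensitive=True),
            PatientField("Birthdate", "1950-01-01", sensitive=True),
        ],
    )
    truth.prostate_volume = float(doc.form.prostat_volumen)
    return doc, truth


def simulate_cohort(
    params: CohortParams,
    template: Optional[CmdxDocument] = None,
    outdir: Optional[Union[str, Path]] = None,
    passphrase: Optional[str] = None,
) -> tuple[list[CmdxDocument], CohortTruth, pd.DataFrame]:
    """Simulate a cohort; optionally write packages and a manifest CSV.

    With ``outdir`` the documents are written as ``<id>.cmdx`` packages
    next to a ``manifest.csv`` of the ground truth.
    """
    params.validate()
    if template is None:
        template = make_default_template()
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_specimens)
    docs: list[CmdxDocument] = []
    specimens: list[SpecimenTruth] = []
    for k, ss in enumerate(seeds):
        sid = f"S{k:04d}"
        doc, truth = simulate_specimen(template, params, np.random.default_rng(ss), specimen_id=sid)
        docs.append(doc)
        specimens.append(truth)
    truth = CohortTruth(specimens)
    manifest = truth.to_manifest()
    if outdir is not None:
        from .package_io import write_cmdx

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for spec, doc in zip(specimens, docs):
            write_cmdx(doc, outdir / f"{spec.specimen_id}.cmdx", passphrase=passphrase)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return docs, truth, manifest
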