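"""Cohort analysis of cMDX documents.

This is the computational-results engine of the package: slice-factor
weighted tumour-volume estimation, multifocality classification, focality
concordance against a reference reading, per-slice cancer incidence,
peripheral-zone localization, cumulative frequency maps over a cohort, and
CSV/PDF export.

The volume model: each prostate slice ``s`` carries a slice factor ``w_s``
(its fraction of whole prostate volume).  The cancer area in a slice is the
number of pixels covered by at least one carcinoma-focus polygon (clipped to
the slice), divided by the slice's pixel count, giving an area fraction
``f_s``.  The relative cancer volume is ``sum_s f_s * w_s`` and the absolute
volume multiplies that by the prostate volume in cm^3 (specimen weight in
grams taken as cm^3).  Overlapping foci are counted once: containing cancer
is a property of the pixel, not of the focus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CmdxDocument, MapObject, MaskSurface, ObjectKind, SliceLevel
from .render import RasterGrid, polygon_mask, rasterize_surface, reference_grid_size


# ---------------------------------------------------------------------------
# Template raster cache: surface and zone masks shared across a cohort.


class TemplateRaster:
    """Per-surface and per-zone pixel masks of one template at one grid size.

    Cohort analyses rasterize the template once and reuse the masks for
    every specimen.
    """

    def __init__(self, doc: CmdxDocument, grid_size: Optional[tuple[int, int]] = None):
        if grid_size is None:
            grid_size = reference_grid_size(doc)
        self.grid_size = grid_size
        w, h = grid_size
        self.surface_masks: dict[str, np.ndarray] = {}
        self.surface_counts: dict[str, int] = {}
        self.zone_masks: dict[tuple[str, str], np.ndarray] = {}
        self.surfaces: dict[str, MaskSurface] = {}
        for s in doc.mask:
            grid, count = rasterize_surface(s, grid_size)
            self.surface_masks[s.id] = grid.data
            self.surface_counts[s.id] = count
            self.surfaces[s.id] = s
            for zone_name, poly in s.zone_labels.items():
                self.zone_masks[(s.id, zone_name)] = polygon_mask(poly, w, h) & grid.data

    def focus_mask(self, obj: MapObject) -> np.ndarray:
        """Pixel mask of one focus, clipped to its drawing surface."""
        w, h = self.grid_size
        mask = polygon_mask(obj.points, w, h)
        if obj.surface_id is not None and obj.surface_id in self.surface_masks:
            mask = mask & self.surface_masks[obj.surface_id]
        return mask


def mask_signature(doc: CmdxDocument) -> tuple:
    """Geometry fingerprint of the template mask, for cohort compatibility."""
    return tuple(
        (s.id, s.shape.value, tuple(map(tuple, s.points)) if s.points else None, s.rect, round(s.percentage, 9))
        for s in doc.mask
    )


class TemplateMismatchError(ValueError):
    """Documents in one cohort analysis do not share a template."""


def _check_shared_template(docs: Sequence[CmdxDocument], template: CmdxDocument) -> None:
    ref = mask_signature(template)
    bad = [i for i, d in enumerate(docs) if mask_signature(d) != ref]
    if bad:
        raise TemplateMismatchError(f"documents at positions {bad} do not share the cohort template")


# ---------------------------------------------------------------------------
# Tumour volume.


@dataclass
class SliceVolume:
    slice_id: str
    cancer_pixels: int
    slice_pixels: int
    slice_factor: float

    @property
    def area_fraction(self) -> float:
        return self.cancer_pixels / self.slice_pixels

    @property
    def relative_contribution(self) -> float:
        return self.area_fraction * self.slice_factor


@dataclass
class VolumeEstimate:
    """Tumour volume of one specimen: per-slice terms and the totals."""

    per_slice: list[SliceVolume]
    relative_volume: float
    volume_cm3: Optional[float]  # absent when the form has no prostate volume


def estimate_volume(doc: CmdxDocument, raster: Optional[TemplateRaster] = None) -> VolumeEstimate:
    """Estimate tumour volume by pixel counting over the slice surfaces."""
    if raster is None:
        raster = TemplateRaster(doc)
    per_slice: list[SliceVolume] = []
    foci_by_surface: dict[str, list[MapObject]] = {}
    for obj in doc.foci:
        if obj.surface_id is not None:
            foci_by_surface.setdefault(obj.surface_id, []).append(obj)
    for s in doc.prostate_slices:
        smask = raster.surface_masks[s.id]
        cancer = np.zeros_like(smask)
        for obj in foci_by_surface.get(s.id, ()):  # union: overlapping foci count once
            cancer |= raster.focus_mask(obj)
        per_slice.append(
            SliceVolume(s.id, int(np.count_nonzero(cancer)), raster.surface_counts[s.id], s.percentage)
        )
    relative = sum(sv.relative_contribution for sv in per_slice)
    vol = doc.form.prostat_volumen
    return VolumeEstimate(per_slice, relative, relative * vol if vol is not None else None)


# ---------------------------------------------------------------------------
# Multifocality.


@dataclass
class FocalityResult:
    n_drawn_foci: int
    n_clusters: int
    label: Literal["unifocal", "multifocal"]
    cluster_members: list[list[str]]  # focus ids per cluster


def _bbox(points: Sequence[tuple[float, float]]) -> tuple[float, float, float, float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return (min(xs), min(ys), max(xs), max(ys))


def _bboxes_intersect(a, b) -> bool:
    return a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_foci(doc: CmdxDocument, mode: Literal["bbox", "polygon"] = "bbox") -> FocalityResult:
    """Partition drawn foci into spatial clusters and classify focality.

    The default ``bbox`` mode reproduces the original tool's rule: each
    focus is replaced by its axis-aligned bounding rectangle and foci whose
    rectangles intersect merge into one cluster (transitive closure).  The
    rectangularization inflates thin diagonal foci and can falsely merge
    adjacent separate foci — the known cost of the rule.  ``polygon`` mode
    tests exact polygon intersection instead and is offered for sensitivity
    analysis.  Foci on different slices never merge unless their opaque
    ``relation`` metadata links them.
    """
    foci = doc.foci
    n = len(foci)
    uf = _UnionFind(n)
    if mode == "polygon":
        from shapely.geometry import Polygon

        shapes = [Polygon(o.points) if o.points and len(o.points) >= 3 else None for o in foci]
    boxes = [_bbox(o.points) if o.points else None for o in foci]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = foci[i], foci[j]
            if a.relation and a.relation == b.relation:
                uf.union(i, j)  # template-declared cross-slice linkage
                continue
            if a.surface_id != b.surface_id:
                continue
            if mode == "bbox":
                if boxes[i] and boxes[j] and _bboxes_intersect(boxes[i], boxes[j]):
                    uf.union(i, j)
            else:
                if shapes[i] is not None and shapes[j] is not None and shapes[i].intersects(shapes[j]):
                    uf.union(i, j)
    clusters: dict[int, list[str]] = {}
    for i, obj in enumerate(foci):
        clusters.setdefault(uf.find(i), []).append(obj.id)
    members = [clusters[k] for k in sorted(clusters)]
    n_clusters = len(members)
    return FocalityResult(n, n_clusters, "multifocal" if n_clusters >= 2 else "unifocal", members)


# ---------------------------------------------------------------------------
# Focality concordance.


@dataclass
class ConcordanceTable:
    """2x2 focality agreement: tool classification vs reference reading."""

    tool_uni_ref_uni: int
    tool_uni_ref_multi: int
    tool_multi_ref_uni: int
    tool_multi_ref_multi: int

    @property
    def total(self) -> int:
        return (self.tool_uni_ref_uni + self.tool_uni_ref_multi
                + self.tool_multi_ref_uni + self.tool_multi_ref_multi)

    @property
    def counts(self) -> np.ndarray:
        """Rows: tool unifocal/multifocal; columns: reference unifocal/multifocal."""
        return np.array(
            [[self.tool_uni_ref_uni, self.tool_uni_ref_multi],
             [self.tool_multi_ref_uni, self.tool_multi_ref_multi]]
        )

    @property
    def sensitivity_multifocal(self) -> float:
        """% of reference-multifocal specimens the tool detects as multifocal."""
        ref_multi = self.tool_uni_ref_multi + self.tool_multi_ref_multi
        return 100.0 * self.tool_multi_ref_multi / ref_multi if ref_multi else float("nan")

    @property
    def specificity(self) -> float:
        ref_uni = self.tool_uni_ref_uni + self.tool_multi_ref_uni
        return 100.0 * self.tool_uni_ref_uni / ref_uni if ref_uni else float("nan")

    @property
    def reference_multifocal_rate(self) -> float:
        return 100.0 * (self.tool_uni_ref_multi + self.tool_multi_ref_multi) / self.total

    @property
    def tool_multifocal_rate(self) -> float:
        return 100.0 * (self.tool_multi_ref_uni + self.tool_multi_ref_multi) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(["unifocal", "multifocal"], name="tool"),
            columns=pd.Index(["unifocal", "multifocal"], name="reference"),
        )


def _as_label(value) -> str:
    if isinstance(value, str):
        if value not in ("unifocal", "multifocal"):
            raise ValueError(f"focality label must be unifocal/multifocal, got {value!r}")
        return value
    return "multifocal" if value else "unifocal"


def focality_concordance(pairs: Sequence[tuple]) -> ConcordanceTable:
    """Cross-tabulate (tool label, reference label) pairs.

    Labels may be the strings ``unifocal``/``multifocal`` or booleans
    (true = multifocal).
    """
    if not pairs:
        raise ValueError("concordance needs at least one (tool, reference) pair")
    counts = {("unifocal", "unifocal"): 0, ("unifocal", "multifocal"): 0,
              ("multifocal", "unifocal"): 0, ("multifocal", "multifocal"): 0}
    for tool, ref in pairs:
        counts[(_as_label(tool), _as_label(ref))] += 1
    return ConcordanceTable(
        counts[("unifocal", "unifocal")], counts[("unifocal", "multifocal")],
        counts[("multifocal", "unifocal")], counts[("multifocal", "multifocal")],
    )


# ---------------------------------------------------------------------------
# Cohort maps, zone localization, incidence.


def cumulative_map(
    docs: Sequence[CmdxDocument],
    template: Optional[CmdxDocument] = None,
    raster: Optional[TemplateRaster] = None,
) -> RasterGrid:
    """Per-pixel count of carcinoma foci over a cohort sharing one template.

    Every focus adds one to each pixel it covers, so overlapping foci of one
    specimen accumulate individually (the map counts foci, not specimens).
    """
    if template is None:
        if not docs:
            raise ValueError("empty cohort")
        template = docs[0]
    _check_shared_template(docs, template)
    if raster is None:
        raster = TemplateRaster(template)
    w, h = raster.grid_size
    counts = np.zeros((h, w), dtype=np.uint32)
    for doc in docs:
        for obj in doc.foci:
            counts += raster.focus_mask(obj).astype(np.uint32)
    return RasterGrid(w, h, counts, f"{w}x{h}")


def render_heatmap(grid: RasterGrid, template: Optional[CmdxDocument] = None):
    """Colour-code a cumulative grid blue (low) to red (high) over the schema."""
    from matplotlib import cm
    from PIL import Image

    counts = grid.data.astype(float)
    vmax = counts.max() if counts.max() > 0 else 1.0
    rgba = (cm.jet(counts / vmax) * 255).astype(np.uint8)
    rgba[..., 3] = np.where(counts > 0, 200, 0)  # transparent where no focus
    overlay = Image.fromarray(rgba, "RGBA")
    if template is not None and template.background is not None:
        from .render import render_document

        base = render_document(template, (grid.width, grid.height), layers=("background", "mask"))
        return Image.alpha_composite(base, overlay)
    return overlay


def summarize_level_percentages(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample standard deviation and median of per-level percentages."""
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, float(np.median(arr))


@dataclass
class ZoneSummary:
    """Per-level peripheral-zone localization of cancer, with summary stats."""

    per_level: dict[str, float]  # level -> % of cancer pixels inside the zone
    mean: float
    sd: float
    median: float
    zone: str = "PZ"
    mode: str = "pooled"
    excluded_levels: list[str] = field(default_factory=list)


_LEVEL_ORDER = [SliceLevel.BASE, SliceLevel.MIDDLE1, SliceLevel.MIDDLE2, SliceLevel.APEX]


def zone_localization(
    docs: Sequence[CmdxDocument],
    template: CmdxDocument,
    zone: str = "PZ",
    mode: Literal["pooled", "per-specimen"] = "pooled",
    raster: Optional[TemplateRaster] = None,
) -> ZoneSummary:
    """Fraction of cancer localized in a named zone, per section level.

    ``pooled`` divides the cohort's total in-zone cancer pixels of a level
    by its total cancer pixels (pixel-weighted); ``per-specimen`` averages
    the per-specimen percentages instead.  Levels with no cancer pixels are
    excluded from the summary with a warning.
    """
    _check_shared_template(docs, template)
    if raster is None:
        raster = TemplateRaster(template)
    levels = [lv for lv in _LEVEL_ORDER if any(s.level is lv for s in template.mask)]
    surfaces_by_level = {
        lv: [s.id for s in template.mask if s.level is lv] for lv in levels
    }
    per_level: dict[str, float] = {}
    excluded: list[str] = []
    for lv in levels:
        sids = surfaces_by_level[lv]
        zone_masks = {sid: raster.zone_masks.get((sid, zone)) for sid in sids}
        ratios: list[float] = []
        pooled_in = pooled_total = 0
        for doc in docs:
            doc_in = doc_total = 0
            for sid in sids:
                cancer = None
                for obj in doc.foci:
                    if obj.surface_id == sid:  # pixel union: overlaps count once
                        fmask = raster.focus_mask(obj)
                        cancer = fmask if cancer is None else (cancer | fmask)
                if cancer is None:
                    continue
                doc_total += int(np.count_nonzero(cancer))
                zm = zone_masks.get(sid)
                if zm is not None:
                    doc_in += int(np.count_nonzero(cancer & zm))
            pooled_in += doc_in
            pooled_total += doc_total
            if doc_total > 0:
                ratios.append(100.0 * doc_in / doc_total)
        if mode == "pooled":
            if pooled_total == 0:
                excluded.append(lv.value)
                continue
            per_level[lv.value] = 100.0 * pooled_in / pooled_total
        else:
            if not ratios:
                excluded.append(lv.value)
                continue
            per_level[lv.value] = float(np.mean(ratios))
    if excluded:
        warnings.warn(f"levels without cancer pixels excluded from zone summary: {excluded}")
    if per_level:
        mean, sd, median = summarize_level_percentages(list(per_level.values()))
    else:
        mean = sd = median = float("nan")
    return ZoneSummary(per_level, mean, sd, median, zone=zone, mode=mode, excluded_levels=excluded)


def slice_incidence(
    docs: Sequence[CmdxDocument],
    template: Optional[CmdxDocument] = None,
    raster: Optional[TemplateRaster] = None,
) -> dict[str, float]:
    """Per slice: fraction of specimens with any cancer pixel in it."""
    if template is None:
        if not docs:
            return {}
        template = docs[0]
    _check_shared_template(docs, template)
    if raster is None:
        raster = TemplateRaster(template)
    slice_ids = [s.id for s in template.prostate_slices]
    hits = {sid: 0 for sid in slice_ids}
    for doc in docs:
        seen: set[str] = set()
        for obj in doc.foci:
            if obj.surface_id in hits and obj.surface_id not in seen:
                if np.count_nonzero(raster.focus_mask(obj)):
                    seen.add(obj.surface_id)
        for sid in seen:
            hits[sid] += 1
    n = len(docs)
    return {sid: hits[sid] / n if n else 0.0 for sid in slice_ids}


# ---------------------------------------------------------------------------
# Cohort assembly + export.


@dataclass
class CohortResult:
    """Per-specimen rows plus cohort aggregates."""

    rows: pd.DataFrame
    incidence: dict[str, float]
    cumulative_grid: RasterGrid
    zone_summary: ZoneSummary
    n_specimens: int
    n_foci: int


def analyze_cohort(
    docs: Sequence[CmdxDocument],
    template: Optional[CmdxDocument] = None,
    ids: Optional[Sequence[str]] = None,
    clustering: Literal["bbox", "polygon"] = "bbox",
    zone_mode: Literal["pooled", "per-specimen"] = "pooled",
) -> CohortResult:
    """Run the full analysis pipeline over a cohort of documents."""
    if not docs:
        raise ValueError("empty cohort")
    if template is None:
        template = docs[0]
    _check_shared_template(docs, template)
    raster = TemplateRaster(template)
    slice_ids = [s.id for s in template.prostate_slices]
    rows = []
    n_foci = 0
    for k, doc in enumerate(docs):
        doc_id = ids[k] if ids is not None else f"specimen_{k:04d}"
        vol = estimate_volume(doc, raster)
        foc = cluster_foci(doc, mode=clustering)
        n_foci += foc.n_drawn_foci
        row = {
            "id": doc_id,
            "relative_volume": vol.relative_volume,
            "volume_cm3": vol.volume_cm3 if vol.volume_cm3 is not None else np.nan,
            "n_foci": foc.n_drawn_foci,
            "n_clusters": foc.n_clusters,
            "focality": foc.label,
        }
        for sv in vol.per_slice:
            row[f"cancer_in_{sv.slice_id}"] = int(sv.cancer_pixels > 0)
        rows.append(row)
    frame = pd.DataFrame(rows)
    incidence = {sid: float(frame[f"cancer_in_{sid}"].mean()) for sid in slice_ids}
    grid = cumulative_map(docs, template, raster)
    zones = zone_localization(docs, template, mode=zone_mode, raster=raster)
    return CohortResult(frame, incidence, grid, zones, len(docs), n_foci)


def export_csv(result: CohortResult, destination) -> dict[str, Path]:
    """Write the cohort result as UTF-8 RFC-4180 CSV files with headers."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = destination / "specimens.csv"
    result.rows.to_csv(p, index=False)
    paths["specimens"] = p
    p = destination / "slice_incidence.csv"
    pd.DataFrame(
        {"slice_id": list(result.incidence), "incidence": list(result.incidence.values())}
    ).to_csv(p, index=False)
    paths["slice_incidence"] = p
    p = destination / "zone_summary.csv"
    zs = result.zone_summary
    zone_rows = [{"level": lv, "percent_in_zone": pct} for lv, pct in zs.per_level.items()]
    zone_rows.append({"level": "mean", "percent_in_zone": zs.mean})
    zone_rows.append({"level": "sd", "percent_in_zone": zs.sd})
    zone_rows.append({"level": "median", "percent_in_zone": zs.median})
    pd.DataFrame(zone_rows).to_csv(p, index=False)
    paths["zone_summary"] = p
    return paths


def export_report(doc: CmdxDocument, destination, title: str = "Radical prostatectomy report") -> Path:
    """Render a one-page PDF report: schematic map, findings, volume table.

    Output is deterministic (fixed PDF metadata dates).  Personal fields
    that are still encrypted render masked.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import datetime as _dt

    import matplotlib.pyplot as plt

    from .render import render_document

    destination = Path(destination)
    vol = estimate_volume(doc)
    foc = cluster_foci(doc)
    image = render_document(doc)

    fig = plt.figure(figsize=(8.27, 11.69))  # A4
    fig.suptitle(title, fontsize=14)
    ax_map = fig.add_axes([0.08, 0.45, 0.55, 0.45])
    ax_map.imshow(np.asarray(image))
    ax_map.set_axis_off()
    ax_map.set_title("Tumour map", fontsize=10)

    f = doc.form
    lines = [
        f"pT/pN/pM: {f.pT or '-'} / {f.pN or '-'} / {f.pM or '-'}",
        f"Gleason: {f.gls1 or '-'} + {f.gls2 or '-'} = {f.gls_total or '-'}   Helpap: {f.helpap or '-'}",
        f"L/V/R: {f.L or '-'} / {f.V or '-'} / {f.R or '-'}",
        f"Lymph nodes: {f.lk_b if f.lk_b is not None else '-'} / {f.lk_g if f.lk_g is not None else '-'}",
        f"Prostate volume: {f.prostat_volumen if f.prostat_volumen is not None else '-'} cm3",
        f"Report date: {f.datum.isoformat() if f.datum else '-'}",
    ]
    for pf in f.patient_fields:
        shown = "***" if pf.is_encrypted else str(pf.value)
        lines.append(f"{pf.name}: {shown}")
    lines.append("")
    lines.append(f"Foci drawn: {foc.n_drawn_foci}   clusters: {foc.n_clusters}   focality: {foc.label}")
    lines.append(f"Relative tumour volume: {vol.relative_volume:.4f}")
    if vol.volume_cm3 is not None:
        lines.append(f"Tumour volume: {vol.volume_cm3:.2f} cm3")
    ax_text = fig.add_axes([0.66, 0.45, 0.30, 0.45])
    ax_text.set_axis_off()
    ax_text.text(0, 1, "\n".join(lines), va="top", fontsize=8, family="monospace")

    ax_tab = fig.add_axes([0.08, 0.08, 0.88, 0.30])
    ax_tab.set_axis_off()
    table_rows = [
        [sv.slice_id, sv.cancer_pixels, sv.slice_pixels, f"{sv.slice_factor:.4f}", f"{sv.relative_contribution:.5f}"]
        for sv in vol.per_slice
    ]
    tab = ax_tab.table(
        cellText=table_rows,
        colLabels=["slice", "cancer px", "slice px", "slice factor", "rel. contribution"],
        loc="center",
    )
    tab.auto_set_font_size(False)
    tab.set_fontsize(8)
    fixed = _dt.datetime(2010, 11, 15)
    fig.savefig(destination, format="pdf", metadata={"CreationDate": fixed, "ModDate": fixed})
    plt.close(fig)
    return destination
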