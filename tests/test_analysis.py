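"""Volume estimation, focality, concordance, zone and cohort analytics."""

import copy
import csv
import math

import numpy as np
import pytest

from cmdx.analysis import (
    TemplateMismatchError,
    TemplateRaster,
    analyze_cohort,
    cluster_foci,
    cumulative_map,
    estimate_volume,
    export_csv,
    export_report,
    focality_concordance,
    render_heatmap,
    slice_incidence,
    summarize_level_percentages,
    zone_localization,
)
from cmdx.model import MapObject, ObjectKind, PresentationStyle
from cmdx.render import polygon_area
from cmdx.synth import CohortParams, _ellipse_polygon, _place_blob, simulate_specimen

from conftest import build_tiny_document, transitive_closure_clusters


def _focus(fid, sid, pts):
    return MapObject(id=fid, tool_name="PCA", kind=ObjectKind.PCA_FOCUS, points=pts,
                     surface_id=sid, style=PresentationStyle(set_clip=True))


# -- tumour volume -----------------------------------------------------------


def test_no_foci_gives_zero_volume(template):
    est = estimate_volume(template)
    assert est.relative_volume == 0.0
    assert est.volume_cm3 is None  # template has no prostate volume on file


def test_complete_coverage_returns_whole_prostate_volume(template):
    """Foci covering every slice, factors summing to 1, 40 cm^3 -> 40 cm^3."""
    doc = copy.deepcopy(template)
    doc.form.prostat_volumen = 40.0
    for s in doc.prostate_slices:
        x, y, w, h = s.rect
        big = [(x - 5, y - 5), (x + w + 5, y - 5), (x + w + 5, y + h + 5), (x - 5, y + h + 5)]
        doc.map_objects.append(_focus(f"cover_{s.id}", s.id, big))
    est = estimate_volume(doc)
    assert est.relative_volume == 1.0  # dyadic slice factors sum exactly
    assert est.volume_cm3 == 40.0


def test_half_slice_rectangle_focus():
    """A focus covering half of a factor-0.2 slice of a 50 cm^3 prostate -> 5 cm^3."""
    doc = build_tiny_document()
    doc.map_objects = []
    s1, s2 = doc.mask
    s1.percentage, s2.percentage = 0.2, 0.8
    doc.form.prostat_volumen = 50.0
    x, y, w, h = s1.rect  # rectangle slice: exact half-coverage
    doc.map_objects.append(_focus("half", "s1", [(x, y), (x + w / 2, y), (x + w / 2, y + h), (x, y + h)]))
    est = estimate_volume(doc, TemplateRaster(doc, (160, 160)))
    assert abs(est.relative_volume - 0.1) < 0.001
    assert abs(est.volume_cm3 - 5.0) < 0.05


def test_pixel_estimate_matches_shoelace_oracle(template):
    """Polygonal foci: pixel-count area vs analytic area within 1% of slice area."""
    raster = TemplateRaster(template)
    rng = np.random.default_rng(42)
    s = template.mask[2]
    region = _ellipse_polygon(s.rect)
    slice_px = raster.surface_counts[s.id]
    for _ in range(50):
        pts, _ = _place_blob(region, float(rng.uniform(300, 4000)), rng)
        doc = copy.deepcopy(template)
        doc.map_objects = [_focus("f", s.id, pts)]
        sv = next(v for v in estimate_volume(doc, raster).per_slice if v.slice_id == s.id)
        assert abs(sv.cancer_pixels - polygon_area(pts)) < 0.01 * slice_px


def test_overlapping_foci_counted_once(template):
    raster = TemplateRaster(template)
    s = template.mask[0]
    x, y, w, h = s.rect
    box = [(x + 40, y + 30), (x + 120, y + 30), (x + 120, y + 60), (x + 40, y + 60)]
    doc = copy.deepcopy(template)
    doc.map_objects = [_focus("a", s.id, box), _focus("b", s.id, box)]  # identical foci
    doubled = estimate_volume(doc, raster).relative_volume
    doc.map_objects = [_focus("a", s.id, box)]
    single = estimate_volume(doc, raster).relative_volume
    assert doubled == single


def test_volume_monotonicity(specimen, template):
    doc, _ = specimen
    raster = TemplateRaster(template)
    base = estimate_volume(doc, raster).relative_volume
    grown = copy.deepcopy(doc)
    s = template.mask[4]
    x, y, w, h = s.rect
    grown.map_objects.append(_focus("extra", s.id, [(x + 20, y + 20), (x + 80, y + 22), (x + 50, y + 70)]))
    added = estimate_volume(grown, raster).relative_volume
    assert added >= base
    # growing a focus to a superset polygon never decreases the estimate
    sup = copy.deepcopy(doc)
    for obj in sup.foci:
        cx = np.mean([p[0] for p in obj.points])
        cy = np.mean([p[1] for p in obj.points])
        obj.points = [(cx + (px - cx) * 1.3, cy + (py - cy) * 1.3) for px, py in obj.points]
    assert estimate_volume(sup, raster).relative_volume >= base


# -- clustering --------------------------------------------------------------


def test_single_focus_is_unifocal(specimen):
    doc, _ = specimen
    single = copy.deepcopy(doc)
    single.map_objects = [o for o in doc.foci][:1]
    res = cluster_foci(single)
    assert (res.n_clusters, res.label) == (1, "unifocal")


def test_zero_foci(template):
    res = cluster_foci(template)
    assert res.n_drawn_foci == 0
    assert res.label == "unifocal"


def test_diagonal_foci_falsely_merge_in_bbox_mode(template):
    """Disjoint diagonal polygons with overlapping bounding rectangles merge
    under the rectangle rule but stay separate under exact polygons."""
    from cmdx.synth import _diagonal_strip_pair

    rng = np.random.default_rng(1)
    s = template.mask[0]
    a, b, _ = _diagonal_strip_pair(_ellipse_polygon(s.rect), rng)
    doc = copy.deepcopy(template)
    doc.map_objects = [_focus("a", s.id, a), _focus("b", s.id, b)]
    assert cluster_foci(doc, mode="bbox").n_clusters == 1
    assert cluster_foci(doc, mode="polygon").n_clusters == 2


def test_cross_slice_linkage_via_relation(template):
    doc = copy.deepcopy(template)
    s1, s2 = template.mask[0], template.mask[1]

    def tri(s):
        x, y, w, h = s.rect
        return [(x + 40, y + 30), (x + 90, y + 32), (x + 60, y + 70)]

    a, b = _focus("a", s1.id, tri(s1)), _focus("b", s2.id, tri(s2))
    doc.map_objects = [a, b]
    assert cluster_foci(doc).n_clusters == 2  # different slices: separate
    a.relation = b.relation = "link-1"
    assert cluster_foci(doc).n_clusters == 1  # relation metadata joins them


def test_cluster_partition_equals_transitive_closure(template):
    """Union-find partition vs boolean-matrix closure on random focus sets."""
    rng = np.random.default_rng(5)
    s = template.mask[0]
    x0, y0, w0, h0 = s.rect
    for _ in range(40):
        n = int(rng.integers(2, 11))
        doc = copy.deepcopy(template)
        doc.map_objects = []
        boxes = []
        for i in range(n):
            cx = rng.uniform(x0 + 20, x0 + w0 - 20)
            cy = rng.uniform(y0 + 15, y0 + h0 - 15)
            hw, hh = rng.uniform(3, 25), rng.uniform(3, 18)
            pts = [(cx - hw, cy - hh), (cx + hw, cy - hh), (cx + hw, cy + hh), (cx - hw, cy + hh)]
            boxes.append((cx - hw, cy - hh, cx + hw, cy + hh))
            doc.map_objects.append(_focus(f"f{i}", s.id, pts))
        adj = np.zeros((n, n), bool)
        for i in range(n):
            for j in range(n):
                a, b = boxes[i], boxes[j]
                adj[i, j] = a[0] <= b[2] and b[0] <= a[2] and a[1] <= b[3] and b[1] <= a[3]
        expected = transitive_closure_clusters(adj)
        result = cluster_foci(doc, mode="bbox")
        got = sorted(
            (frozenset(int(fid[1:]) for fid in c) for c in result.cluster_members), key=min
        )
        assert got == expected


# -- concordance -------------------------------------------------------------


def test_concordance_reproduces_printed_counts():
    pairs = (
        [("unifocal", "unifocal")] * 121 + [("unifocal", "multifocal")] * 13
        + [("multifocal", "unifocal")] * 0 + [("multifocal", "multifocal")] * 121
    )
    table = focality_concordance(pairs)
    assert table.total == 255
    assert round(table.sensitivity_multifocal, 1) == 90.3
    assert round(table.reference_multifocal_rate, 1) == 52.5
    assert round(table.tool_multifocal_rate, 1) == 47.5
    assert table.to_frame().to_numpy().tolist() == [[121, 13], [0, 121]]


def test_concordance_perfect_agreement():
    table = focality_concordance([("multifocal", "multifocal")] * 6 + [("unifocal", "unifocal")] * 4)
    assert table.sensitivity_multifocal == 100.0
    assert table.tool_multi_ref_uni == 0 and table.tool_uni_ref_multi == 0


def test_concordance_all_unifocal_tool():
    table = focality_concordance([("unifocal", "multifocal")] * 3 + [("unifocal", "unifocal")] * 2)
    assert table.sensitivity_multifocal == 0.0


def test_concordance_empty_errors():
    with pytest.raises(ValueError):
        focality_concordance([])


def test_concordance_accepts_booleans():
    table = focality_concordance([(True, True), (False, False), (False, True)])
    assert table.tool_multi_ref_multi == 1 and table.tool_uni_ref_multi == 1


# -- zone localization -------------------------------------------------------


def test_zone_summary_of_printed_level_values():
    mean, sd, median = summarize_level_percentages([36.0, 80.0, 87.0, 89.0])
    assert mean == 73.0
    assert median == 83.5
    assert sd > 0


def test_all_pz_foci_give_hundred_percent(template):
    params = CohortParams(seed=0, pz_bias=1.0, multifocal_rate=0.5)
    docs = [simulate_specimen(template, params, k, f"Z{k}")[0] for k in range(6)]
    summary = zone_localization(docs, template)
    assert summary.per_level  # at least one level has cancer
    for pct in summary.per_level.values():
        assert pct == 100.0


def test_levels_without_cancer_are_excluded_with_warning(template):
    doc = copy.deepcopy(template)
    s = next(s for s in template.mask if s.level.value == "base")
    x, y, w, h = s.rect
    doc.map_objects = [_focus("f", s.id, [(x + 50, y + 60), (x + 120, y + 60), (x + 80, y + 85)])]
    with pytest.warns(UserWarning, match="excluded"):
        summary = zone_localization([doc], template)
    assert set(summary.per_level) == {"base"}
    assert set(summary.excluded_levels) == {"middle1", "middle2", "apex"}


def test_pooled_zone_recovery_tracks_generator_bias(small_cohort, template):
    docs, truth, _ = small_cohort
    summary = zone_localization(docs, template)
    # every generator focus is wholly in or out of the PZ; pooled percentage
    # must equal the area-weighted in-PZ share of the foci
    in_pz = out_pz = 0.0
    for spec in truth.specimens:
        for f in spec.foci:
            (in_pz, out_pz) = (in_pz + f.area_fraction, out_pz) if f.in_pz else (in_pz, out_pz + f.area_fraction)
    expected = 100.0 * in_pz / (in_pz + out_pz)
    pooled = []
    for lv, pct in summary.per_level.items():
        pooled.append(pct)
    # cross-check at cohort scale rather than per level (levels fluctuate)
    total_in = total_out = 0
    raster = TemplateRaster(template)
    for doc in docs:
        for obj in doc.foci:
            fmask = raster.focus_mask(obj)
            zm = raster.zone_masks.get((obj.surface_id, "PZ"))
            inz = int(np.count_nonzero(fmask & zm)) if zm is not None else 0
            total_in += inz
            total_out += int(np.count_nonzero(fmask)) - inz
    measured = 100.0 * total_in / (total_in + total_out)
    assert abs(measured - expected) < 1.0


# -- cumulative map, incidence -----------------------------------------------


def test_cumulative_map_single_doc_equals_focus_mask(template):
    s = template.mask[3]
    x, y, w, h = s.rect
    pts = [(x + 30, y + 25), (x + 110, y + 28), (x + 70, y + 70)]
    doc = copy.deepcopy(template)
    doc.map_objects = [_focus("f", s.id, pts)]
    raster = TemplateRaster(template)
    grid = cumulative_map([doc], template, raster)
    assert (grid.data == raster.focus_mask(doc.map_objects[0]).astype(np.uint32)).all()
    twice = cumulative_map([doc, copy.deepcopy(doc)], template, raster)
    assert (twice.data == 2 * grid.data).all()


def test_cumulative_map_additivity(small_cohort, template):
    docs, _, _ = small_cohort
    raster = TemplateRaster(template)
    total = cumulative_map(docs, template, raster)
    summed = np.zeros_like(total.data)
    for doc in docs:
        summed += cumulative_map([doc], template, raster).data
    assert (total.data == summed).all()
    assert total.data.max() <= sum(len(d.foci) for d in docs)


def test_cumulative_map_rejects_foreign_template(template, tiny_doc):
    with pytest.raises(TemplateMismatchError):
        cumulative_map([tiny_doc], template)


def test_heatmap_renders(template, small_cohort):
    docs, _, _ = small_cohort
    grid = cumulative_map(docs, template)
    img = render_heatmap(grid, template)
    assert img.size == (grid.width, grid.height)


def test_slice_incidence_extremes_and_truth(template, small_cohort):
    empty = copy.deepcopy(template)
    inc = slice_incidence([empty], template)
    assert all(v == 0.0 for v in inc.values())
    docs, truth, _ = small_cohort
    inc = slice_incidence(docs, template)
    for sid in inc:
        expected = sum(sid in s.slices_with_cancer for s in truth.specimens) / len(docs)
        assert inc[sid] == expected


# -- export ------------------------------------------------------------------


def test_export_csv_roundtrip(small_cohort, template, tmp_path):
    docs, _, _ = small_cohort
    result = analyze_cohort(docs, template)
    paths = export_csv(result, tmp_path)
    with open(paths["specimens"], newline="", encoding="utf-8") as fh:  # independent reader
        rows = list(csv.DictReader(fh))
    assert len(rows) == len(docs)
    assert abs(float(rows[0]["relative_volume"]) - result.rows.iloc[0]["relative_volume"]) < 1e-12
    with open(paths["slice_incidence"], newline="", encoding="utf-8") as fh:
        inc_rows = list(csv.DictReader(fh))
    assert len(inc_rows) == 8  # one row per prostate slice
    with open(paths["zone_summary"], newline="", encoding="utf-8") as fh:
        zone_rows = list(csv.DictReader(fh))
    assert {"mean", "sd", "median"} <= {r["level"] for r in zone_rows}


def test_export_report_pdf(specimen, tmp_path):
    doc, _ = specimen
    out = export_report(doc, tmp_path / "report.pdf")
    data = out.read_bytes()
    assert data.startswith(b"%PDF")
    again = export_report(doc, tmp_path / "report2.pdf")
    assert again.read_bytes() == data  # deterministic bytes, fixed metadata


def test_export_report_zero_foci_shows_zero_volume(template, tmp_path):
    doc = copy.deepcopy(template)
    doc.form.prostat_volumen = 40.0
    out = export_report(doc, tmp_path / "empty.pdf")
    assert out.exists()
    assert estimate_volume(doc).volume_cm3 == 0.0
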