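import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmdx.model import (
    ArbgColor,
    BefundRecord,
    CmdxDocument,
    DrawTool,
    FormRecord,
    MapObject,
    MaskSurface,
    ObjectKind,
    PatientField,
    PresentationStyle,
    Shape,
    SliceLevel,
    ToolType,
)
from cmdx.synth import CohortParams, make_default_template, simulate_cohort, simulate_specimen

settings.register_profile(
    "package", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def template():
    return make_default_template()


@pytest.fixture(scope="session")
def specimen(template):
    """One deterministic synthetic specimen with its ground truth."""
    return simulate_specimen(template, CohortParams(seed=0), 7, specimen_id="FIX")


@pytest.fixture(scope="session")
def small_cohort(template):
    """20-specimen cohort for fast aggregate checks."""
    docs, truth, manifest = simulate_cohort(CohortParams(n_specimens=20, seed=11), template=template)
    return docs, truth, manifest


@pytest.fixture(scope="session")
def recovery_cohort(template):
    """200-specimen cohort at the study's multifocal rate, well-separated foci."""
    params = CohortParams(n_specimens=200, seed=123, multifocal_rate=0.525, adjacency_fraction=0.0)
    docs, truth, manifest = simulate_cohort(params, template=template)
    return params, docs, truth, manifest


def build_tiny_document() -> CmdxDocument:
    """A minimal hand-built valid document: two slices, a focus, a margin mark."""
    style = PresentationStyle()
    surfaces = [
        MaskSurface(id="s1", name="slice 1", shape=Shape.RECTANGLE, rect=(10.0, 10.0, 100.0, 60.0),
                    percentage=0.5, level=SliceLevel.BASE, style=style,
                    zone_labels={"PZ": [(10.0, 50.0), (110.0, 50.0), (110.0, 70.0), (10.0, 70.0)]}),
        MaskSurface(id="s2", name="slice 2", shape=Shape.ELLIPSE, rect=(10.0, 90.0, 100.0, 60.0),
                    percentage=0.5, level=SliceLevel.APEX, style=PresentationStyle()),
    ]
    tools = [
        DrawTool(name="PCA", type=ToolType.POLYGON),
        DrawTool(name="MARGIN", type=ToolType.IMAGE_WITHOUT_SIZING),
        DrawTool(name="CAPS", type=ToolType.CLIP, type_of_clip="Polygon"),
    ]
    focus = MapObject(
        id="f1", tool_name="PCA", kind=ObjectKind.PCA_FOCUS,
        points=[(20.0, 20.0), (60.0, 22.0), (40.0, 50.0)], surface_id="s1",
        style=PresentationStyle(brush_color=ArbgColor(160, 220, 40, 40)),
        befund=BefundRecord(id="f1", show_gleason=True, gleason1=3, gleason2=4, gleason_score=7),
    )
    margin = MapObject(
        id="m1", tool_name="MARGIN", kind=ObjectKind.POSITIVE_MARGIN,
        anchor=(60.0, 70.0), surface_id="s1", style=PresentationStyle(is_filled=False),
    )
    form = FormRecord(
        pT="pT2c", lk_b=1, lk_g=12, prostat_volumen=40.0,
        patient_fields=[PatientField("PatientName", "Synthetic Fixture", sensitive=True)],
    )
    return CmdxDocument(mask=surfaces, tools=tools, map_objects=[focus, margin], form=form)


@pytest.fixture
def tiny_doc():
    return build_tiny_document()


# Independent oracles, shared across test modules --------------------------------


def point_in_polygon_reference(px: float, py: float, poly) -> bool:
    """Scalar even-odd crossing test, written independently of the package."""
    inside = False
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        if y1 == y2:
            continue
        if (y1 <= py) != (y2 <= py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def bfs_flood_reference(image: np.ndarray, seed: tuple[int, int], tolerance: int) -> np.ndarray:
    """Queue-based 8-connected flood fill used as the magic-wand oracle."""
    from collections import deque

    arr = image if image.ndim == 3 else image[:, :, None]
    h, w = arr.shape[:2]
    x0, y0 = seed
    seed_color = arr[y0, x0].astype(np.int64)
    visited = np.zeros((h, w), dtype=bool)

    def matches(x, y):
        return bool(np.max(np.abs(arr[y, x].astype(np.int64) - seed_color)) <= tolerance)

    queue = deque([(x0, y0)])
    visited[y0, x0] = True
    out = np.zeros((h, w), dtype=bool)
    while queue:
        x, y = queue.popleft()
        out[y, x] = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                nx, ny = x + dx, y + dy
                if 0 <= nx < w and 0 <= ny < h and not visited[ny, nx] and matches(nx, ny):
                    visited[ny, nx] = True
                    queue.append((nx, ny))
    return out


def fill_holes_reference(mask: np.ndarray) -> np.ndarray:
    """Hole filling by 4-connected border flood of the complement."""
    from collections import deque

    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    queue = deque()
    for x in range(w):
        for y in (0, h - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                queue.append((x, y))
    for y in range(h):
        for x in (0, w - 1):
            if not mask[y, x] and not outside[y, x]:
                outside[y, x] = True
                queue.append((x, y))
    while queue:
        x, y = queue.popleft()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < w and 0 <= ny < h and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                queue.append((nx, ny))
    return ~outside


def transitive_closure_clusters(adjacency: np.ndarray) -> list[frozenset]:
    """Connected components by boolean-matrix closure (independent of union-find)."""
    n = adjacency.shape[0]
    reach = (adjacency | np.eye(n, dtype=bool)).astype(np.int64)
    for _ in range(n):
        new = ((reach @ reach) > 0).astype(np.int64)
        if (new == reach).all():
            break
        reach = new
    clusters = {frozenset(np.nonzero(reach[i])[0].tolist()) for i in range(n)}
    return sorted(clusters, key=min)
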