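"""MCP construction, shape indices and hull diameter against brute-force
oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beeranges.errors import DegenerateHullError, InsufficientDataError
from beeranges.home_range import (
    compute_mcp,
    max_flight_distance,
    shape_metrics,
    summarize_stage_table,
)


def brute_force_hull_vertices(pts: np.ndarray) -> set[tuple[float, float]]:
    """O(n^3) hull oracle: (i, j) is a hull edge iff every point lies on
    one side of the line through them; hull vertices are edge endpoints."""
    n = len(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if (cross >= -1e-12).all() and (np.abs(cross) > 1e-12).any():
                verts.add(tuple(pts[i]))
                verts.add(tuple(pts[j]))
    return verts


def test_interior_point_dropped_and_triangle_metrics():
    hr = compute_mcp(np.array([[0, 0], [4, 0], [0, 3], [1, 1]]), min_points=3)
    assert len(hr.hull_vertices) - 1 == 3  # closed ring
    assert hr.area_m2 == pytest.approx(6.0)
    assert hr.perimeter_m == pytest.approx(12.0)
    assert hr.max_flight_m == pytest.approx(5.0)


def test_hull_matches_brute_force_oracle(rng):
    for _ in range(25):
        pts = rng.uniform(0, 1, size=(50, 2))
        hr = compute_mcp(pts, min_points=5)
        ours = {tuple(v) for v in hr.hull_vertices[:-1]}
        assert ours == brute_force_hull_vertices(pts)


def test_duplicate_vertex_is_idempotent(rng):
    pts = rng.uniform(0, 100, size=(20, 2))
    hr = compute_mcp(pts)
    dup = np.vstack([pts, hr.hull_vertices[0]])
    hr2 = compute_mcp(dup)
    assert hr2.area_m2 == pytest.approx(hr.area_m2)
    assert hr2.perimeter_m == pytest.approx(hr.perimeter_m)
    assert np.allclose(np.sort(hr2.hull_vertices[:-1], axis=0),
                       np.sort(hr.hull_vertices[:-1], axis=0))


def test_filters_and_degenerate_inputs():
    with pytest.raises(InsufficientDataError):
        compute_mcp(np.zeros((4, 2)), min_points=5)
    with pytest.raises(DegenerateHullError):
        compute_mcp(np.array([[i, 2 * i] for i in range(6)], dtype=float))


def test_shape_metrics_closed_forms():
    """Circle limit: Kc -> 1, Rci -> 1; unit square: Rci = 0.785,
    Kc = 2/sqrt(pi)."""
    theta = np.linspace(0, 2 * np.pi, 721)[:-1]
    circle = np.c_[np.cos(theta), np.sin(theta)]
    hr = compute_mcp(circle)
    assert hr.kc == pytest.approx(1.0, abs=1e-4)
    assert hr.rci == pytest.approx(1.0, abs=1e-4)

    kc, rci = shape_metrics(1.0, 4.0)
    assert round(rci, 3) == 0.785
    assert kc == pytest.approx(2.0 / math.sqrt(math.pi), abs=1e-9)

    with pytest.raises(DegenerateHullError):
        shape_metrics(0.0, 4.0)


def test_rci_kc_identity_and_isoperimetric_bound(rng):
    """Rci * Kc^2 = 1 on random hulls, and Rci <= 1 always."""
    for _ in range(200):
        pts = rng.normal(size=(rng.integers(5, 40), 2)) * rng.uniform(0.1, 1e3)
        try:
            hr = compute_mcp(pts)
        except DegenerateHullError:
            continue
        assert hr.rci * hr.kc**2 == pytest.approx(1.0, abs=1e-9)
        assert 0 < hr.rci <= 1.0 + 1e-12


def test_hull_contains_all_points_and_is_monotone(rng):
    import shapely
    from shapely.geometry import Point

    pts = rng.uniform(-50, 50, size=(40, 2))
    hr = compute_mcp(pts)
    pad = hr.hull.buffer(1e-9 * 100)
    assert all(pad.covers(Point(*p)) for p in pts)
    # adding a point never shrinks area or diameter
    extra = np.vstack([pts, [[60.0, 60.0]]])
    hr2 = compute_mcp(extra)
    assert hr2.area_m2 >= hr.area_m2
    assert hr2.max_flight_m >= hr.max_flight_m


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    scale=st.floats(min_value=0.01, max_value=1000),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_scale_equivariance(scale, seed):
    """Scaling coordinates by s multiplies area by s^2, perimeter and
    diameter by s, and leaves both shape indices unchanged."""
    pts = np.random.default_rng(seed).uniform(0, 10, size=(15, 2))
    a = compute_mcp(pts)
    b = compute_mcp(pts * scale)
    assert b.area_m2 == pytest.approx(a.area_m2 * scale**2, rel=1e-9)
    assert b.perimeter_m == pytest.approx(a.perimeter_m * scale, rel=1e-9)
    assert b.max_flight_m == pytest.approx(a.max_flight_m * scale, rel=1e-9)
    assert b.kc == pytest.approx(a.kc, rel=1e-9)
    assert b.rci == pytest.approx(a.rci, rel=1e-9)


def test_diameter_matches_all_pairs_oracle(rng):
    pts = rng.normal(size=(100, 2)) * 37.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    assert max_flight_distance(pts) == pytest.approx(np.sqrt(d2.max()))
    with pytest.raises(InsufficientDataError):
        max_flight_distance(np.array([[1.0, 1.0], [1.0, 1.0]]))


def test_stage_summary_reproduces_published_table(table1):
    """Stage means/SDs of the per-bee table match the published stage
    summary (areas 22.7 / 3.56 ha; distances 813.82 / 522.71 m; pooled
    642.58 +- 396.89 m)."""
    df = table1.rename(columns={"mcp_ha": "area_ha", "max_homing_m": "max_flight_m"})
    out = summarize_stage_table(df[["stage", "area_ha", "max_flight_m"]])
    out = out.set_index("stage")
    assert out.loc["before_nest", "area_ha_mean"] == pytest.approx(22.7, abs=0.05)
    assert out.loc["after_nest", "area_ha_mean"] == pytest.approx(3.56, abs=0.01)
    assert out.loc["before_nest", "max_flight_m_mean"] == pytest.approx(813.82, abs=0.005)
    assert out.loc["after_nest", "max_flight_m_mean"] == pytest.approx(522.71, abs=0.005)
    assert out.loc["all", "max_flight_m_mean"] == pytest.approx(642.58, abs=0.005)
    assert out.loc["all", "max_flight_m_sd"] == pytest.approx(396.89, abs=0.005)
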