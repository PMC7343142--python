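"""Generator determinism, landscape fractions, track geometry and the
distributional contrasts the analysis is meant to detect."""

import io as std_io
from dataclasses import replace

import numpy as np
import pytest
from shapely.geometry import Point

from beeranges.errors import ConfigError
from beeranges.home_range import compute_mcp
from beeranges.io import write_landuse, write_waypoints
from beeranges.synthetic import (
    SimConfig,
    generate_landscape,
    generate_pollen,
    generate_tracks,
    pollen_mean_recovery,
    stage_mean_fractions,
)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(luc_fractions={"blueberry": 0.5, "plantation": 0.2})
    with pytest.raises(ConfigError):
        SimConfig(elongation_after=0.5)
    with pytest.raises(ConfigError):
        SimConfig(habitat_affinity={"blueberry": 0.0})


def test_single_luc_config_gives_one_polygon():
    frac = {"blueberry": 1.0, "plantation": 0.0, "semi_natural": 0.0,
            "other_fruits": 0.0, "developed": 0.0}
    ls = generate_landscape(SimConfig(seed=1, luc_fractions=frac))
    assert ls.labels == ["blueberry"]
    x0, y0, x1, y1 = SimConfig().bbox
    assert ls.geometries[0].area == pytest.approx((x1 - x0) * (y1 - y0))


def test_landscape_fractions_within_tolerance():
    cfg = SimConfig(seed=1)
    ls = generate_landscape(cfg)
    areas = ls.area_by_label()
    total = sum(areas.values())
    for luc, frac in cfg.luc_fractions.items():
        if frac > 0:
            assert areas[luc] / total == pytest.approx(frac, abs=0.02)
    # windbreak strips present: plantation appears in >= 3 pieces
    assert ls.labels.count("plantation") >= 3


def test_landscape_determinism_bytes(tmp_path):
    buf1, buf2 = std_io.StringIO(), std_io.StringIO()
    for i in range(2):
        ls = generate_landscape(SimConfig(seed=42))
        p = tmp_path / f"l{i}.geojson"
        write_landuse(ls, p)
    assert (tmp_path / "l0.geojson").read_bytes() == (tmp_path / "l1.geojson").read_bytes()


def test_tracks_deterministic_and_inside_bbox(tmp_path):
    cfg = SimConfig(seed=7)
    ls = generate_landscape(cfg)
    t1, truth1 = generate_tracks(ls, cfg)
    t2, truth2 = generate_tracks(ls, cfg)
    assert t1.df.equals(t2.df)
    assert truth1 == truth2
    x0, y0, x1, y1 = cfg.bbox
    assert ((t1.df.x >= x0) & (t1.df.x <= x1)).all()
    assert ((t1.df.y >= y0) & (t1.df.y <= y1)).all()
    for p in (tmp_path / "a.csv", tmp_path / "b.csv"):
        write_waypoints(t1, p)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_every_bee_has_at_least_five_fixes_and_stage_counts():
    cfg = SimConfig(seed=3)
    tracks, _ = generate_tracks(generate_landscape(cfg), cfg)
    counts = tracks.counts()
    assert (counts >= 5).all()
    stages = tracks.df.groupby("bee_id")["stage"].first()
    assert (stages == "before_nest").sum() == cfg.n_bees_before
    assert (stages == "after_nest").sum() == cfg.n_bees_after


def test_nests_sit_on_plantation_edges():
    cfg = SimConfig(seed=5)
    ls = generate_landscape(cfg)
    _, truth = generate_tracks(ls, cfg)
    plantations = [g for g, lab in zip(ls.geometries, ls.labels) if lab == "plantation"]
    for nest in truth["nests"].values():
        d = min(g.exterior.distance(Point(*nest)) for g in plantations)
        assert d <= cfg.nest_edge_offset + 1e-6


def test_isotropic_after_stage_ranges_are_round():
    """With elongation 1 and uniform affinity, post-nest ranges come out
    near-circular: mean Rci over 200 bees exceeds 0.6."""
    cfg = SimConfig(seed=11, elongation_after=1.0, n_bees_before=0, n_bees_after=200)
    tracks, _ = generate_tracks(generate_landscape(cfg), cfg)
    rci = [compute_mcp(tracks.coords(b), bee_id=b).rci for b in tracks.bees()]
    assert np.mean(rci) > 0.6


def test_elongation_raises_compactness():
    """4:1 anisotropy yields clearly higher mean Kc than isotropic clouds
    (one-sided Monte-Carlo over 200 bees each)."""
    kcs = {}
    for e in (1.0, 4.0):
        cfg = SimConfig(seed=13, elongation_after=e, n_bees_before=0, n_bees_after=200)
        tracks, _ = generate_tracks(generate_landscape(cfg), cfg)
        kcs[e] = np.array([compute_mcp(tracks.coords(b), bee_id=b).kc
                           for b in tracks.bees()])
    assert kcs[4.0].mean() > kcs[1.0].mean()
    # crude z-test for the one-sided contrast
    z = (kcs[4.0].mean() - kcs[1.0].mean()) / np.sqrt(
        kcs[4.0].var() / 200 + kcs[1.0].var() / 200
    )
    assert z > 2.33  # p < 0.01


def test_area_scales_with_ranging_scale_squared():
    """Doubling the pre-nest ranging SD quadruples the mean MCP area
    (within 15% over 200 bees), the variance-scaling law for Gaussian
    scatter hulls."""
    means = {}
    for s in (80.0, 160.0):
        cfg = SimConfig(seed=17, ranging_scale_before=s,
                        n_bees_before=200, n_bees_after=0)
        tracks, _ = generate_tracks(generate_landscape(cfg), cfg)
        means[s] = np.mean(
            [compute_mcp(tracks.coords(b), bee_id=b).area_ha for b in tracks.bees()]
        )
    assert means[160.0] / means[80.0] == pytest.approx(4.0, rel=0.15)


def test_pollen_sums_and_determinism():
    cfg = SimConfig(seed=19)
    s1 = generate_pollen(cfg)
    s2 = generate_pollen(cfg)
    assert all(a.counts == b.counts for a, b in zip(s1, s2))
    assert all(s.total == cfg.grains_per_sample for s in s1)
    n_by_stage = {}
    for s in s1:
        n_by_stage[s.stage] = n_by_stage.get(s.stage, 0) + 1
    assert n_by_stage == cfg.pollen_stage_n


def test_single_species_concentration_gives_richness_one():
    from beeranges.pollen import richness
    from beeranges import synthetic

    cfg = SimConfig(seed=23, pollen_stage_n={"peak": 20})
    samples = generate_pollen(cfg)
    assert all(s.total == 100 for s in samples)
    # degenerate one-species check via a direct multinomial draw
    rng = np.random.default_rng(0)
    comp = np.zeros(len(synthetic.ALL_SPECIES))
    comp[0] = 1.0
    counts = rng.multinomial(100, comp)
    from beeranges.pollen import PollenSample
    from datetime import date

    s = PollenSample("x", date(2015, 8, 15),
                     {sp: int(c) for sp, c in zip(synthetic.ALL_SPECIES, counts) if c})
    assert richness(s) == 1


def test_peak_crop_mean_recovered_within_3se():
    """500 simulated peak loads recover the generator's crop-pollen mean
    fraction (the reported 61.75%) within 3 SE."""
    rec = pollen_mean_recovery(SimConfig(seed=29), stage="peak", n_samples=500)
    assert rec["within_3se"]
    assert rec["true_mean_pct"] == pytest.approx(61.75, abs=0.1)


def test_stage_mean_fractions_normalized():
    for st in ("early", "peak", "post_peak"):
        v = stage_mean_fractions(st)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert (v > 0).all()
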