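"""Matched-design construction: availability sampling and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from cranesel.design import (
    PolygonMask,
    RasterMask,
    annotate_diurnal,
    annotate_roost,
    build_strata,
    sample_available,
)
from cranesel.exceptions import AnnotationError, StratumError
from cranesel.grid import Raster
from cranesel.simulate import LandscapeConfig, generate_landscape
from cranesel.simulate.landscape import LAND_USE_CLASSES


class _AllMask:
    def contains(self, x, y):
        return np.ones(np.shape(x), dtype=bool)


def test_sample_available_count_and_radius(rng):
    pts = sample_available((0.0, 0.0), 6700.0, _AllMask(), 50, rng)
    assert pts.shape == (50, 2)
    assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= 6700.0)


def test_sample_available_uniform_on_disc(rng):
    """With the mask covering the disc, draws are uniform: chi-square over
    equal-area annuli and quadrant sectors must not reject at alpha=0.01."""
    n = 100_000
    pts = sample_available((0.0, 0.0), 1.0, _AllMask(), n, rng)
    r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2  # uniform disc => r^2 ~ U(0,1)
    counts, _ = np.histogram(r2, bins=10, range=(0, 1))
    _, p = chisquare(counts)
    assert p > 0.01
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    counts_t, _ = np.histogram(theta, bins=8, range=(-np.pi, np.pi))
    _, p_t = chisquare(counts_t)
    assert p_t > 0.01


def test_sample_available_empty_support_raises(rng):
    empty = Raster(np.zeros((10, 10), dtype=bool), 0, 0, 100.0)
    with pytest.raises(StratumError):
        sample_available((500.0, 500.0), 300.0, RasterMask(empty), 10, rng)


def test_sample_available_deterministic():
    a = sample_available((0, 0), 100.0, _AllMask(), 20, np.random.default_rng(5))
    b = sample_available((0, 0), 100.0, _AllMask(), 20, np.random.default_rng(5))
    assert np.array_equal(a, b)


def test_structure_counts_at_three_radii():
    """Structures at 90, 400, and 900 m give counts (1, 2, 3) at radii
    100/500/1000 m."""
    cfg = LandscapeConfig(
        width_m=4000, height_m=4000, cell_m=100, structure_clusters=0, seed=1
    )
    ls = generate_landscape(cfg)
    ls.structures = np.array([[2090.0, 2000.0], [2000.0, 2400.0], [1100.0, 2000.0]])
    ann = annotate_diurnal(np.array([[2000.0, 2000.0]]), ls)
    assert ann["struct_100"].iloc[0] == 1
    assert ann["struct_500"].iloc[0] == 2
    assert ann["struct_1000"].iloc[0] == 3
    assert ann["dist_structure"].iloc[0] == pytest.approx(90.0)


def test_no_structures_sentinel():
    cfg = LandscapeConfig(
        width_m=3000, height_m=4000, cell_m=100, structure_clusters=0, seed=2
    )
    ls = generate_landscape(cfg)
    assert len(ls.structures) == 0
    ann = annotate_diurnal(np.array([[1500.0, 1500.0]]), ls)
    assert ann["struct_500"].iloc[0] == 0
    assert ann["dist_structure"].iloc[0] == pytest.approx(np.hypot(3000, 4000))


def test_annotate_diurnal_matches_bruteforce(landscape, rng):
    """Vectorized annotation equals plain point-in-cell and pairwise loops."""
    elig = landscape.eligible.data.astype(bool)
    X, Y = landscape.land_use.cell_centers()
    idx = rng.choice(np.flatnonzero(elig.ravel()), size=30, replace=False)
    pts = np.column_stack([X.ravel()[idx], Y.ravel()[idx]])
    ann = annotate_diurnal(pts, landscape)
    for i, (px, py) in enumerate(pts):
        r = int(py // 100)
        c = int(px // 100)
        assert ann["land_use"].iloc[i] == LAND_USE_CLASSES[landscape.land_use.data[r, c]]
        d = np.hypot(landscape.structures[:, 0] - px, landscape.structures[:, 1] - py)
        assert ann["dist_structure"].iloc[i] == pytest.approx(d.min(), rel=1e-12)
        for rad in (100, 500, 1000):
            assert ann[f"struct_{rad}"].iloc[i] == int(np.sum(d <= rad))


def test_annotate_diurnal_off_raster_raises(landscape):
    with pytest.raises(AnnotationError):
        annotate_diurnal(np.array([[-50.0, -50.0]]), landscape)


def test_annotate_roost_width_is_nearest_station(river):
    """A point between stations takes the width of the nearer station."""
    i = 100
    st = river.stations[i]
    ann = annotate_roost(np.array([[st[0], st[1] + 10.0]]), river, "dec-jan")
    assert ann["width"].iloc[0] == pytest.approx(river.widths[i])


def test_annotate_roost_unknown_period_raises(river):
    with pytest.raises(AnnotationError):
        annotate_roost(np.array([river.stations[50]]), river, "jun-jul")


def test_bank_stretch_mean_matches_window_oracle(river, rng):
    """Stretch means equal a brute-force along-centerline window average."""
    bx, by, bh, bs = river.bank_cells()
    pts_idx = rng.choice(len(river.stations), size=12, replace=False)
    pts = river.stations[pts_idx]
    for stretch in (100.0, 500.0, 1000.0):
        got = river.bank_stretch_mean(pts[:, 0], pts[:, 1], stretch)
        for k, i in enumerate(pts_idx):
            s0 = river.chainage[i]
            sel = np.abs(bs - s0) <= stretch / 2.0
            assert sel.any()
            assert got[k] == pytest.approx(bh[sel].mean(), rel=1e-12)


def test_bank_stretch_simple_average():
    """Bank heights 1, 2, 3 in the window average to 2."""

    class _R:
        chainage = np.array([0.0, 30.0, 60.0])
        stations = np.array([[0, 0], [0, 30], [0, 60.0]])

        def nearest_station(self, x, y):
            from scipy.spatial import cKDTree

            return cKDTree(self.stations).query(np.column_stack([x, y]))[1]

        def bank_cells(self):
            return (
                np.zeros(3),
                np.array([0.0, 30.0, 60.0]),
                np.array([1.0, 2.0, 3.0]),
                np.array([0.0, 30.0, 60.0]),
            )

    from cranesel.simulate.river import RiverModel

    got = RiverModel.bank_stretch_mean(_R(), np.array([0.0]), np.array([30.0]), 500.0)
    assert got[0] == pytest.approx(2.0)


def test_build_strata_closure_and_radius(track_sim, landscape):
    from cranesel.telemetry import partition_diel
    from cranesel.simulate import generate_river, RiverConfig

    river = generate_river(RiverConfig(seed=13))
    part = partition_diel(track_sim.fixes, river.polygon)
    used = part.diurnal.head(40)
    ss = build_strata(used, "diurnal", landscape=landscape, seed=3)
    assert ss.n_strata == 40
    assert len(ss.df) == 40 * 51
    assert ss.validate(radius=6700.0, n_available=50) == []
    # used rows carry the original coordinates
    u = ss.df[ss.df.is_used == 1]
    assert np.allclose(np.sort(u.x.to_numpy()), np.sort(used.x.to_numpy()))


def test_build_strata_deterministic(track_sim, landscape, river):
    from cranesel.telemetry import partition_diel

    part = partition_diel(track_sim.fixes, river.polygon)
    used = part.diurnal.head(5)
    a = build_strata(used, "diurnal", landscape=landscape, seed=11)
    b = build_strata(used, "diurnal", landscape=landscape, seed=11)
    pd.testing.assert_frame_equal(a.df, b.df)


def test_build_roost_strata(track_sim, landscape, river):
    from cranesel.telemetry import partition_diel

    part = partition_diel(track_sim.fixes, river.polygon)
    used = part.roost.head(25)
    ss = build_strata(used, "roost", landscape=landscape, river=river, seed=4)
    assert ss.validate(radius=6700.0, n_available=50) == []
    inside = PolygonMask(river.polygon).contains(
        ss.df.x.to_numpy(), ss.df.y.to_numpy()
    )
    avail = ss.df.is_used.to_numpy() == 0
    assert inside[avail].all()
    closure = ss.df[["water", "sandbar", "vegetation"]].sum(axis=1)
    assert np.allclose(closure, 1.0, atol=1e-6)


def test_strataset_roundtrip_csv(tmp_path, track_sim, landscape, river):
    from cranesel.telemetry import partition_diel

    part = partition_diel(track_sim.fixes, river.polygon)
    ss = build_strata(part.diurnal.head(3), "diurnal", landscape=landscape, seed=5)
    path = tmp_path / "strata.csv"
    ss.to_csv(path)
    back = pd.read_csv(path)
    assert len(back) == len(ss.df)
    import json

    side = json.loads((tmp_path / "strata.csv.json").read_text())
    assert side["categorical"]["land_use"]["reference"] == "alfalfa_hay"
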