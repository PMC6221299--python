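"""NDWI, endmember extraction, constrained unmixing, compositing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cranesel.exceptions import ConfigurationError
from cranesel.sma import (
    EndmemberSet,
    composite_period,
    extract_endmembers,
    ndwi,
    ndwi_mask,
    unmix,
)
from cranesel.simulate import SpectraConfig, simulate_spectra

E = SpectraConfig().validate()
EMS = EndmemberSet(("water", "sandbar", "vegetation"), E)


# ------------------------------------------------------------------- NDWI


def test_ndwi_basic_values():
    g = np.array([[0.2, 0.3, 0.0]])
    n = np.array([[0.2, 0.0, 0.0]])
    out = ndwi(g, n)
    assert out[0, 0] == pytest.approx(0.0)
    assert out[0, 1] == pytest.approx(1.0)
    assert np.isnan(out[0, 2])


def test_ndwi_matches_elementwise_loop(rng):
    g = rng.random((20, 15))
    n = rng.random((20, 15))
    out = ndwi(g, n)
    for i in range(20):
        for j in range(15):
            assert out[i, j] == (g[i, j] - n[i, j]) / (g[i, j] + n[i, j])


def test_ndwi_shape_mismatch():
    with pytest.raises(ConfigurationError):
        ndwi(np.zeros((3, 3)), np.zeros((3, 4)))


def test_ndwi_mask_exact_percentile_count():
    vals = np.linspace(-1, 1, 1000).reshape(40, 25)
    mask = ndwi_mask(vals, percentile=98)
    assert mask.sum() == 20  # top 2% of 1000 distinct values


def test_ndwi_mask_constant_raster_warns_and_flags_all():
    with pytest.warns(RuntimeWarning):
        mask = ndwi_mask(np.full((10, 10), 0.5))
    assert mask.all()


def test_ndwi_mask_flagged_fraction_on_continuous_raster(rng):
    frac = ndwi_mask(rng.normal(size=(200, 200))).mean()
    assert 0.015 <= frac <= 0.025


def test_ndwi_mask_too_few_valid_pixels():
    arr = np.full((10, 10), np.nan)
    arr[0, :5] = 1.0
    with pytest.raises(ConfigurationError):
        ndwi_mask(arr)


# ------------------------------------------------------------- endmembers


def test_extract_endmembers_means(rng):
    img = np.zeros((4, 4, 3))
    img[0, 0] = [1, 2, 3]
    img[0, 1] = [3, 4, 5]
    img[1, 0] = [10, 0, 10]
    regions = {
        "a": np.zeros((4, 4), bool),
        "b": np.zeros((4, 4), bool),
        "c": np.zeros((4, 4), bool),
    }
    regions["a"][0, 0] = True           # single pixel: endmember equals it
    regions["b"][0, :2] = True          # two pixels: arithmetic mean
    regions["c"][1, 0] = True
    ems = extract_endmembers(img, regions)
    assert np.allclose(ems.spectra[0], [1, 2, 3])
    assert np.allclose(ems.spectra[1], [2, 3, 4])


def test_extract_endmembers_empty_region():
    img = np.ones((3, 3, 4))
    with pytest.raises(ConfigurationError):
        extract_endmembers(img, {"a": np.zeros((3, 3), bool)})


def test_extract_endmembers_recovers_known_means(rng):
    """Noisy monotypic regions recover class means within the noise SE."""
    sd = 0.02
    img = np.zeros((30, 30, 6))
    regions = {}
    for k, name in enumerate(("water", "sandbar", "vegetation")):
        mask = np.zeros((30, 30), bool)
        mask[k * 10 : (k + 1) * 10] = True
        img[mask] = E[k] + rng.normal(0, sd, size=(mask.sum(), 6))
        regions[name] = mask
    ems = extract_endmembers(img, regions)
    se = sd / np.sqrt(300)
    assert np.all(np.abs(ems.spectra - E) < 6 * se)


# ------------------------------------------------------------------ unmix


def test_unmix_pure_pixel_exact():
    res = unmix(E[0], EMS)
    assert np.allclose(res.proportions, [[1, 0, 0]], atol=1e-8)
    assert res.residual[0] < 1e-8


def test_unmix_worked_water_sandbar_mixture():
    """A 0.4 water / 0.6 sandbar pixel (emergent sandbars with shallow
    water) is recovered exactly from its noiseless spectrum."""
    s = 0.4 * E[0] + 0.6 * E[1]
    res = unmix(s, EMS)
    assert np.allclose(res.proportions, [[0.4, 0.6, 0.0]], atol=1e-8)
    assert res.residual[0] < 1e-8


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_unmix_simplex_feasibility_and_noiseless_recovery(seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet([1, 1, 1])
    res = unmix(p @ E, EMS)
    got = res.proportions[0]
    assert got.min() >= 0
    assert got.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(got, p, atol=1e-7)
    assert res.residual[0] < 1e-7


def test_unmix_matches_grid_oracle():
    """Noisy pixels: the active-set solution matches a fine simplex grid
    search within 1e-3 per component."""
    spectra, _ = simulate_spectra(SpectraConfig(noise_sd=0.01, seed=9), 40)
    res = unmix(spectra, EMS)
    # fine barycentric grid
    step = 1.0 / 400
    grid = []
    for i in range(401):
        for j in range(401 - i):
            grid.append((i * step, j * step, 1 - (i + j) * step))
    grid = np.array(grid)
    pred = grid @ E
    for k in range(len(spectra)):
        errs = np.sum((pred - spectra[k]) ** 2, axis=1)
        best = grid[np.argmin(errs)]
        assert np.all(np.abs(res.proportions[k] - best) < step + 1e-3)


def test_unmix_permutation_equivariant():
    s = 0.25 * E[0] + 0.45 * E[1] + 0.30 * E[2]
    res = unmix(s, EMS)
    perm = EndmemberSet(("vegetation", "water", "sandbar"), E[[2, 0, 1]])
    res_p = unmix(s, perm)
    assert np.allclose(res_p.proportions[0], res.proportions[0][[2, 0, 1]], atol=1e-8)


def test_unmix_rank_deficient_endmembers_rejected():
    bad = EndmemberSet(("a", "b", "c"), np.vstack([E[0], E[0], E[1]]))
    with pytest.raises(ConfigurationError):
        unmix(E[0], bad)


def test_unmix_nonfinite_spectrum_rejected():
    s = E[0].copy()
    s[2] = np.nan
    with pytest.raises(ConfigurationError):
        unmix(s, EMS)


# -------------------------------------------------------------- composite


def test_composite_single_image_identity(rng):
    img = rng.random((1, 5, 5))
    assert np.allclose(composite_period(img), img[0])


def test_composite_complementary_masks(rng):
    a = np.full((4, 4), 2.0)
    b = np.full((4, 4), 4.0)
    valid = np.ones((2, 4, 4), bool)
    valid[0, 0, 0] = False  # only b contributes at (0,0)
    valid[1, 1, 1] = False  # only a contributes at (1,1)
    out = composite_period(np.stack([a, b]), valid)
    assert out[0, 0] == 4.0
    assert out[1, 1] == 2.0
    assert out[2, 2] == 3.0


def test_composite_matches_loop_oracle(rng):
    stack = rng.random((5, 6, 7))
    valid = rng.random((5, 6, 7)) > 0.3
    out = composite_period(stack, valid)
    for i in range(6):
        for j in range(7):
            vals = [stack[t, i, j] for t in range(5) if valid[t, i, j]]
            if vals:
                assert out[i, j] == pytest.approx(np.mean(vals), rel=1e-12)
            else:
                assert np.isnan(out[i, j])


def test_composite_empty_stack_rejected():
    with pytest.raises(ConfigurationError):
        composite_period(np.empty((0, 3, 3)))


def test_simulated_pure_and_mixture_examples():
    cfg = SpectraConfig(noise_sd=0.0, seed=1)
    spectra, props = simulate_spectra(cfg, 200)
    assert np.allclose(props.sum(axis=1), 1.0)
    assert np.allclose(spectra, props @ E)
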