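"""Candidate sets, term expansion, and QIC ranking."""

import numpy as np
import pytest

from cranesel.clogit import ClogitData, fit_clogit, qic, robust_variance
from cranesel.exceptions import ConfigurationError
from cranesel.model_selection import ModelSpec, enumerate_candidates, rank_models
from cranesel.simulate import simulate_choice_strata
from cranesel.terms import expand_terms

DIURNAL_CATALOG = [
    "land_use", "ownership", "dist_structure",
    "struct_100", "struct_500", "struct_1000",
]
ROOST_CATALOG = [
    "width", "water", "sandbar", "vegetation",
    "bank_100", "bank_500", "bank_1000", "dist_bridge",
]


def test_factorial_expansion_includes_main_effects():
    terms = expand_terms(["width*water*sandbar"])
    assert ("width",) in terms and ("water",) in terms and ("sandbar",) in terms
    assert ("width", "water") in terms
    assert ("width", "water", "sandbar") in terms
    assert len(terms) == 7


def test_diurnal_candidates_contain_top_model():
    """The published top diurnal structure (land use + ownership + density
    at 500 m) must be in the default candidate set."""
    specs = enumerate_candidates("diurnal", DIURNAL_CATALOG)
    key = lambda s: tuple(sorted(s.terms))
    assert key(ModelSpec("", "diurnal", ["land_use", "ownership", "struct_500"])) in {
        key(s) for s in specs
    }
    # density variants at all three radii are present
    radii = {s.radius_m for s in specs if s.radius_m}
    assert radii == {100.0, 500.0, 1000.0}


def test_roost_candidates_contain_top_model():
    specs = enumerate_candidates("roost", ROOST_CATALOG)
    top = [s for s in specs if s.name == "morphology+bank+bridge"]
    assert top
    expanded = expand_terms(top[0].terms)
    for needed in [
        ("width",), ("water",), ("sandbar",), ("bank_500",), ("dist_bridge",),
        ("width", "water"), ("width", "sandbar"), ("water", "sandbar"),
        ("width", "water", "sandbar"), ("width", "bank_500"),
    ]:
        assert tuple(sorted(needed)) in {tuple(sorted(t)) for t in expanded}


def test_empty_catalog_rejected():
    with pytest.raises(ConfigurationError):
        enumerate_candidates("diurnal", [])


def test_unknown_covariate_rejected():
    with pytest.raises(ConfigurationError):
        enumerate_candidates(
            "diurnal", ["land_use"],
            extra=[ModelSpec("bad", "diurnal", ["no_such_cov"])],
        )


def _fit(ss, terms):
    data = ClogitData.from_strata(ss, terms=terms, standardize=False)
    fit = fit_clogit(data)
    robust_variance(fit, data)
    qic(fit)
    return fit


def test_single_model_weight_one():
    ss = simulate_choice_strata(
        np.array([0.5]), n_clusters=4, strata_per_cluster=30, n_available=10, rng=0
    )
    table = rank_models({"only": _fit(ss, ["cov1"])})
    assert table["weight"].iloc[0] == pytest.approx(1.0)


def test_equal_qic_gives_half_weights():
    ss = simulate_choice_strata(
        np.array([0.5]), n_clusters=4, strata_per_cluster=30, n_available=10, rng=1
    )
    fit = _fit(ss, ["cov1"])
    table = rank_models({"a": fit, "b": fit})
    assert np.allclose(table["weight"], 0.5)


def test_weights_sum_to_one_and_ranking_order_invariant():
    ss = simulate_choice_strata(
        np.array([0.6, -0.2]), n_clusters=5, strata_per_cluster=40,
        n_available=15, rng=2,
    )
    fits = {"f1": _fit(ss, ["cov1"]), "f2": _fit(ss, ["cov2"]),
            "f12": _fit(ss, ["cov1", "cov2"])}
    t1 = rank_models(fits)
    t2 = rank_models(dict(reversed(list(fits.items()))))
    assert t1["weight"].sum() == pytest.approx(1.0)
    assert list(t1["model"]) == list(t2["model"])
    assert (t1["qic"].diff().dropna() >= 0).all()
    assert t1["delta_qic"].iloc[0] == 0.0


def test_differing_strata_not_comparable():
    ss1 = simulate_choice_strata(
        np.array([0.5]), n_clusters=4, strata_per_cluster=30, n_available=10, rng=3
    )
    ss2 = simulate_choice_strata(
        np.array([0.5]), n_clusters=4, strata_per_cluster=20, n_available=10, rng=3
    )
    with pytest.raises(ConfigurationError):
        rank_models({"a": _fit(ss1, ["cov1"]), "b": _fit(ss2, ["cov1"])})


def test_fit_model_can_drop_inestimable_level():
    """A categorical level never observed as the used row makes its dummy
    coefficient unbounded; on_separation='drop' removes it and records
    the drop, while the default raises."""
    import pandas as pd

    from cranesel.design import StrataSet
    from cranesel.exceptions import SeparationError
    from cranesel.model_selection import fit_model

    rng = np.random.default_rng(9)
    n_strata, S = 60, 6
    rows = n_strata * S
    lu = np.array(["alfalfa_hay", "corn"])[rng.integers(0, 2, rows)]
    # plant a rare level among available rows only
    avail_rows = np.flatnonzero(np.arange(rows) % S != 0)
    lu[rng.choice(avail_rows, size=15, replace=False)] = "other"
    df = pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n_strata), S),
            "cluster_id": np.repeat(np.arange(n_strata) % 5, S),
            "is_used": np.tile([1] + [0] * (S - 1), n_strata),
            "period": "diurnal",
            "land_use": lu,
            "z": rng.normal(size=rows),
        }
    )
    strata = StrataSet(
        df=df,
        categorical={"land_use": (["alfalfa_hay", "corn", "other"], "alfalfa_hay")},
        continuous=["z"],
    )
    with pytest.raises(SeparationError):
        fit_model(strata, ["land_use", "z"], vif_threshold=None)
    fit = fit_model(strata, ["land_use", "z"], vif_threshold=None,
                    on_separation="drop")
    assert fit.metadata["separation_dropped"] == ["land_use[other]"]
    assert "land_use[other]" not in fit.names
    assert fit.converged


def test_generating_model_usually_wins_qic():
    """Small-scale check that the generating model beats an overfit
    alternative with extra noise covariates (full scale in acceptance)."""
    wins = 0
    reps = 20
    for r in range(reps):
        ss = simulate_choice_strata(
            np.array([0.6, -0.4, 0.3, 0.0, 0.0]),
            n_clusters=10, strata_per_cluster=40, n_available=20,
            rng=500 + r,
        )
        gen = _fit(ss, ["cov1", "cov2", "cov3"])
        over = _fit(ss, ["cov1", "cov2", "cov3", "cov4", "cov5"])
        wins += gen.qic < over.qic
    assert wins >= reps * 0.6
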