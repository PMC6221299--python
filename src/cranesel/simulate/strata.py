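"""Direct simulation of matched case-control strata from a known model.

This generator samples the conditional-logistic model exactly: each stratum
holds one used and M available rows; covariates are drawn i.i.d. and the
used row is selected with probability proportional to exp(x'beta) (via the
Gumbel-max trick). Because the data-generating process *is* the estimation
model, parameter-recovery, coverage, and model-selection behaviour of the
fitting code are meaningful acceptance checks.

Two covariate regimes are available: ``"normal"`` (independent standard
normals, for neutral numerical checks) and ``"diurnal"`` (land-use
category drawn with floodplain-like availability, public/private
ownership, and a standardized structure-density count, mimicking the
study's diurnal design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..exceptions import ConfigurationError
from .landscape import LAND_USE_CLASSES

#: Availability of each land-use class among available rows in the
#: diurnal-like regime (alfalfa/hay-dominated floodplain).
DIURNAL_AVAILABILITY = (0.88, 0.05, 0.03, 0.02, 0.015, 0.005)
DIURNAL_PUBLIC_FRACTION = 0.12


def simulate_choice_design(
    beta,
    n_clusters: int = 38,
    strata_per_cluster: int = 150,
    n_available: int = 50,
    covariates: str = "normal",
    rng=None,
):
    """Array-path variant of :func:`simulate_choice_strata`.

    Returns a ready-to-fit :class:`~cranesel.clogit.ClogitData` (skipping
    the DataFrame layer), which keeps large replicated simulations cheap.
    The data-generating process is identical to the StrataSet path.
    """
    from ..clogit import ClogitData  # deferred: avoids cycle

    rng = np.random.default_rng(rng)
    n_strata = n_clusters * strata_per_cluster
    S = n_available + 1
    n_rows = n_strata * S

    if covariates == "normal":
        beta_vec = np.asarray(beta, dtype=float)
        names = [f"cov{i + 1}" for i in range(beta_vec.size)]
        X = rng.standard_normal((n_rows, beta_vec.size))
    elif covariates == "diurnal":
        if not isinstance(beta, dict):
            raise ConfigurationError("diurnal regime expects a dict of coefficients")
        names = [
            "land_use[corn]",
            "land_use[fallow]",
            "land_use[small_grain]",
            "land_use[wetland]",
            "land_use[other]",
            "ownership[public]",
            "struct_500",
        ]
        codes = rng.choice(
            len(LAND_USE_CLASSES), size=n_rows, p=np.asarray(DIURNAL_AVAILABILITY)
        )
        X = np.zeros((n_rows, 7))
        for k in range(1, 6):  # dummies against alfalfa/hay
            X[:, k - 1] = codes == k
        X[:, 5] = rng.random(n_rows) < DIURNAL_PUBLIC_FRACTION
        X[:, 6] = (rng.poisson(2.0, size=n_rows) - 2.0) / np.sqrt(2.0)
        beta_vec = np.array([beta.get(n, 0.0) for n in names])
    else:
        raise ConfigurationError(f"unknown covariate regime {covariates!r}")

    eta = (X @ beta_vec).reshape(n_strata, S)
    winner = np.argmax(eta + rng.gumbel(size=(n_strata, S)), axis=1)
    idx = np.arange(n_rows).reshape(n_strata, S)
    first = idx[:, 0].copy()
    win_idx = idx[np.arange(n_strata), winner]
    order = idx.copy()
    order[:, 0] = win_idx
    order[np.arange(n_strata), winner] = first

    starts = np.arange(0, n_rows + 1, S)
    return ClogitData(
        X=X[order.ravel()],
        starts=starts,
        used_rows=starts[:-1],
        cluster_of_stratum=np.arange(n_strata) // strata_per_cluster,
        names=names,
    ), beta_vec


def simulate_choice_strata(
    beta,
    n_clusters: int = 38,
    strata_per_cluster: int = 300,
    n_available: int = 50,
    covariates: str = "normal",
    rng=None,
    names: list | None = None,
) -> StrataSet:
    """Simulate a StrataSet whose used rows follow exp(x'beta) selection.

    Parameters
    ----------
    beta : array-like or dict
        True coefficients. For ``covariates="normal"``, a vector of length
        p over anonymous N(0,1) covariates ``cov1..covp``. For
        ``covariates="diurnal"``, a dict over the diurnal design columns
        ``land_use[corn] .. land_use[other], ownership[public],
        struct_500`` (missing keys default to 0).
    """
    from ..design import CATEGORICAL_META, StrataSet  # deferred: avoids cycle

    rng = np.random.default_rng(rng)
    n_strata = n_clusters * strata_per_cluster
    S = n_available + 1
    n_rows = n_strata * S

    if covariates == "normal":
        beta = np.asarray(beta, dtype=float)
        p = beta.size
        names = names or [f"cov{i + 1}" for i in range(p)]
        X = rng.standard_normal((n_rows, p))
        covframe = pd.DataFrame(X, columns=names)
        categorical = {}
        continuous = list(names)
        eta = X @ beta
    elif covariates == "diurnal":
        if not isinstance(beta, dict):
            raise ConfigurationError("diurnal regime expects a dict of coefficients")
        classes = np.array(LAND_USE_CLASSES)
        lu = classes[
            rng.choice(len(classes), size=n_rows, p=np.asarray(DIURNAL_AVAILABILITY))
        ]
        own = np.where(rng.random(n_rows) < DIURNAL_PUBLIC_FRACTION, "public", "private")
        dens = rng.poisson(2.0, size=n_rows).astype(float)
        dens = (dens - 2.0) / np.sqrt(2.0)  # known standardization of Poisson(2)
        covframe = pd.DataFrame(
            {"land_use": lu, "ownership": own, "struct_500": dens}
        )
        categorical = dict(CATEGORICAL_META)
        continuous = ["struct_500"]
        eta = np.zeros(n_rows)
        for cls in LAND_USE_CLASSES[1:]:
            eta += beta.get(f"land_use[{cls}]", 0.0) * (lu == cls)
        eta += beta.get("ownership[public]", 0.0) * (own == "public")
        eta += beta.get("struct_500", 0.0) * dens
    else:
        raise ConfigurationError(f"unknown covariate regime {covariates!r}")

    # Gumbel-max: the within-stratum argmax of eta + Gumbel noise is an
    # exact draw from the softmax over the stratum.
    gumbel = rng.gumbel(size=n_rows).reshape(n_strata, S)
    winner = np.argmax(eta.reshape(n_strata, S) + gumbel, axis=1)

    # Swap the winning row to position 0 so the used row leads its stratum.
    idx = np.arange(n_rows).reshape(n_strata, S)
    first = idx[:, 0].copy()
    win_idx = idx[np.arange(n_strata), winner]
    order = idx.copy()
    order[:, 0] = win_idx
    order[np.arange(n_strata), winner] = first
    order = order.ravel()

    covframe = covframe.iloc[order].reset_index(drop=True)
    is_used = np.zeros(n_rows, dtype=int)
    is_used[:: S] = 1
    df = pd.DataFrame(
        {
            "stratum_id": np.repeat(np.arange(n_strata), S),
            "cluster_id": np.repeat(np.arange(n_strata) // strata_per_cluster, S),
            "is_used": is_used,
            "period": "synthetic",
        }
    )
    df = pd.concat([df, covframe], axis=1)
    return StrataSet(
        df=df,
        categorical=categorical,
        continuous=continuous,
        meta={"truth": beta if isinstance(beta, dict) else beta.tolist(),
              "regime": covariates},
    )
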