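"""Candidate model sets, fitting with VIF screening, and QIC ranking."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clogit import ClogitData, FitResult, fit_clogit, qic, robust_variance, vif_screen
from .design import StrataSet
from .exceptions import ConfigurationError, SeparationError
from .terms import expand_terms


@dataclass
class ModelSpec:
    """A named model structure for one diel period.

    ``terms`` use the package's term language; interactions always imply
    their main effects via ``*`` expansion at build time.
    """

    name: str
    period: str
    terms: list
    radius_m: float | None = None

    def check_catalog(self, catalog):
        base = {n for t in expand_terms(self.terms) for n in t}
        unknown = base - set(catalog)
        if unknown:
            raise ConfigurationError(
                f"model {self.name!r} references unknown covariates {sorted(unknown)}"
            )


def enumerate_candidates(period: str, catalog, extra: list | None = None):
    """Built-in candidate model sets for a diel period.

    The diurnal set nests land use, ownership, and structure-density (at
    each of the three radii) or distance-to-structure effects; the roost
    set nests channel morphology up to the width x sandbar x water
    factorial with the width x bank-height interaction and distance to
    bridge. ``extra`` appends user-defined ModelSpecs (checked against the
    catalog), so the exact published candidate sets can be replicated via
    configuration.
    """
    catalog = list(catalog)
    if not catalog:
        raise ConfigurationError("empty covariate catalog")
    if period == "diurnal":
        specs = [
            ModelSpec("landuse", period, ["land_use"]),
            ModelSpec("landuse+ownership", period, ["land_use", "ownership"]),
        ]
        for r in (100, 500, 1000):
            specs.append(
                ModelSpec(
                    f"landuse+ownership+density{r}",
                    period,
                    ["land_use", "ownership", f"struct_{r}"],
                    radius_m=float(r),
                )
            )
        specs.append(
            ModelSpec(
                "landuse+ownership+diststructure",
                period,
                ["land_use", "ownership", "dist_structure"],
            )
        )
    elif period == "roost":
        specs = [
            ModelSpec("width", period, ["width"]),
            ModelSpec("width+water+sandbar", period, ["width", "water", "sandbar"]),
            ModelSpec("width*water*sandbar", period, ["width*water*sandbar"]),
            ModelSpec(
                "morphology+bank", period,
                ["width*water*sandbar", "bank_500", "width:bank_500"],
            ),
            ModelSpec(
                "morphology+bank+bridge", period,
                ["width*water*sandbar", "bank_500", "width:bank_500", "dist_bridge"],
            ),
        ]
    else:
        raise ConfigurationError(f"unknown period {period!r}")
    for spec in specs:
        spec.check_catalog(catalog)
    for spec in extra or []:
        spec.check_catalog(catalog)
        specs.append(spec)
    return specs


def fit_model(
    strata: StrataSet,
    model: ModelSpec | list,
    standardize: bool = True,
    constants: dict | None = None,
    vif_threshold: float | None = 5.0,
    compute_qic: bool = True,
    on_separation: str = "raise",
) -> FitResult:
    """Fit one model on a StrataSet: VIF screen, Newton fit, sandwich, QIC.

    Covariates whose VIF meets the threshold are dropped from this model's
    design matrix before fitting (recorded in the result metadata).
    ``on_separation="drop"`` removes covariate columns along which the
    likelihood is unbounded (e.g., a one-hot level never observed as the
    used row) instead of raising, recording them in the metadata.
    """
    if on_separation not in ("raise", "drop"):
        raise ConfigurationError("on_separation must be 'raise' or 'drop'")
    terms = model.terms if isinstance(model, ModelSpec) else list(model)
    data = ClogitData.from_strata(
        strata, terms=terms, standardize=standardize, constants=constants
    )
    dropped = []
    if vif_threshold is not None and data.X.shape[1] >= 2:
        kept, table = vif_screen(data.X, data.names, threshold=vif_threshold)
        if len(kept) < len(data.names):
            dropped = [n for n in data.names if n not in kept]
            data = data.drop_columns(dropped)
    separation_dropped = []
    while True:
        try:
            fit = fit_clogit(data)
            break
        except SeparationError as err:
            if on_separation != "drop":
                raise
            separation_dropped.append(err.covariate)
            data = data.drop_columns([err.covariate])
    robust_variance(fit, data)
    if compute_qic:
        qic(fit)
    fit.metadata.update(
        {
            "model": model.name if isinstance(model, ModelSpec) else "custom",
            "terms": list(terms),
            "vif_dropped": dropped,
            "separation_dropped": separation_dropped,
            "standardize": standardize,
            "standardization": {
                k: list(map(float, v)) for k, v in data.standardization.items()
            },
        }
    )
    return fit


def rank_models(fits: dict) -> pd.DataFrame:
    """QIC ranking table with delta-QIC and Akaike-style weights.

    All fits must be on identical strata and row counts (checked); weights
    are exp(-delta/2) normalized to sum to one.
    """
    if not fits:
        raise ConfigurationError("no fits to rank")
    items = list(fits.items())
    n_strata = {f.n_strata for _, f in items}
    if len(n_strata) > 1:
        raise ConfigurationError("fits were made on differing strata; not comparable")
    for name, f in items:
        if f.qic is None:
            raise ConfigurationError(f"fit {name!r} has no QIC")
    qics = np.array([f.qic for _, f in items])
    delta = qics - qics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    table = pd.DataFrame(
        {
            "model": [name for name, _ in items],
            "qic": qics,
            "delta_qic": delta,
            "weight": w,
            "n_params": [len(f.names) for _, f in items],
        }
    ).sort_values("qic", kind="stable").reset_index(drop=True)
    return table
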