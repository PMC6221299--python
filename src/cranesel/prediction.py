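"""Relative-probability-of-use surfaces from fitted selection models.

In a use-availability design exp(x'beta) is a relative (not absolute)
probability of use, defined up to a positive factor. Surfaces are computed
cell-wise over a masked domain — the eligible field/pasture/wetland cells
for the diurnal model, the active channel with period-matched proportion
rasters for the roost model — and min-max rescaled to [0, 1] for display
comparability; the raw exp-scores are returned alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clogit import FitResult
from .constants import StudyConstants
from .design import CATEGORICAL_META
from .exceptions import ConfigurationError
from .grid import Raster
from .simulate.landscape import LAND_USE_CLASSES, Landscape
from .simulate.river import RiverModel
from .terms import build_design_matrix


def predict_surface(
    fit: FitResult,
    layers: dict,
    terms,
    mask: np.ndarray,
    categorical: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a fitted model over raster layers.

    Parameters
    ----------
    fit : FitResult
        Fitted model; its stored standardization constants are applied to
        continuous covariates so cells are scored on the training scale.
    layers : dict
        Covariate name -> 2-D array (all same shape). Categorical layers
        hold level strings (or integer codes for land use).
    terms : list
        The model's term list.
    mask : 2-D bool array
        Domain over which the surface is defined; cells outside are NaN.

    Returns
    -------
    scaled : 2-D array in [0, 1] on the mask (NaN outside); an all-equal
        surface is 0 by convention.
    raw : 2-D array of exp(x'beta) scores (NaN outside the mask).
    """
    shapes = {np.shape(v) for v in layers.values()} | {np.shape(mask)}
    if len(shapes) != 1:
        raise ConfigurationError("layers and mask must share one shape")
    mask = np.asarray(mask, dtype=bool)
    df = {}
    for name, layer in layers.items():
        vals = np.asarray(layer)[mask]
        if name == "land_use" and np.issubdtype(vals.dtype, np.integer):
            vals = np.array(LAND_USE_CLASSES)[vals]
        df[name] = vals
    df = pd.DataFrame(df)
    X, names, _ = build_design_matrix(
        df,
        terms,
        categorical=categorical if categorical is not None else CATEGORICAL_META,
        standardize=bool(fit.metadata.get("standardize", True)),
        constants={
            k: tuple(v) for k, v in fit.metadata.get("standardization", {}).items()
        },
    )
    if names != list(fit.names):
        missing = set(fit.names) - set(names)
        if missing:
            raise ConfigurationError(f"missing covariate columns {sorted(missing)}")
        X = X[:, [names.index(n) for n in fit.names]]
    eta = X @ fit.beta
    raw_vals = np.exp(eta - eta.max())  # stable; relative scale is arbitrary
    span = raw_vals.max() - raw_vals.min()
    scaled_vals = (
        np.zeros_like(raw_vals) if span == 0 else (raw_vals - raw_vals.min()) / span
    )
    raw = np.full(mask.shape, np.nan)
    scaled = np.full(mask.shape, np.nan)
    raw[mask] = np.exp(eta)
    scaled[mask] = scaled_vals
    return scaled, raw


def predict_diurnal(
    fit: FitResult,
    landscape: Landscape,
    terms=None,
    constants: StudyConstants = StudyConstants(),
) -> tuple[Raster, Raster]:
    """Diurnal surface over the eligible mask of a landscape."""
    terms = terms if terms is not None else fit.metadata["terms"]
    mask = landscape.eligible.data.astype(bool)
    layers = {
        "land_use": np.where(mask, landscape.land_use.data, 0),
        "ownership": np.where(landscape.ownership.data == 1, "public", "private"),
    }
    needed = {n for col in fit.names for n in _base_names(col)}
    X, Y = landscape.land_use.cell_centers()
    for r in constants.density_radii_m:
        key = f"struct_{int(r)}"
        if key in needed:
            layers[key] = landscape.structure_density_raster(r).data
    if "dist_structure" in needed:
        layers["dist_structure"] = landscape.structure_distance(
            X.ravel(), Y.ravel()
        ).reshape(X.shape)
    scaled, raw = predict_surface(fit, layers, terms, mask)
    return landscape.land_use.like(scaled), landscape.land_use.like(raw)


def predict_roost(
    fit: FitResult,
    river: RiverModel,
    period: str,
    constants: StudyConstants = StudyConstants(),
) -> tuple[Raster, Raster]:
    """Roost surface over the active channel for one bi-monthly period."""
    if period not in river.proportions:
        raise ConfigurationError(f"no proportion rasters for period {period!r}")
    mask = river.channel_mask.data.astype(bool)
    X, Y = river.channel_mask.cell_centers()
    layer_set = river.proportions[period]
    xs, ys = X[mask], Y[mask]

    def full(values):
        out = np.zeros(mask.shape)
        out[mask] = values
        return out

    layers = {
        "width": full(river.width_at(xs, ys)),
        "water": np.where(mask, layer_set["water"].data, 0.0),
        "sandbar": np.where(mask, layer_set["sandbar"].data, 0.0),
        "vegetation": np.where(mask, layer_set["vegetation"].data, 0.0),
        "dist_bridge": full(river.bridge_distance(xs, ys)),
    }
    needed = {n for col in fit.names for n in _base_names(col)}
    for r in constants.stretch_radii_m:
        key = f"bank_{int(r)}"
        if key in needed:
            layers[key] = full(river.bank_stretch_mean(xs, ys, r))
    scaled, raw = predict_surface(fit, layers, fit.metadata["terms"], mask,
                                  categorical={})
    return river.channel_mask.like(scaled), river.channel_mask.like(raw)


def _base_names(column: str):
    """Base covariate names referenced by a design-matrix column label."""
    if "[" in column:
        return [column.split("[")[0]]
    return column.split(":")
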