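"""Matched 1:50 used-available strata: sampling and covariate annotation.

Each used GPS location is matched with 50 available locations drawn
uniformly from the intersection of a 6.7 km disc around it with the period
availability mask (eligible field/pasture/wetland cells by day, the active
river channel by night). Every row is then annotated with the period's
covariates, and strata are labelled by individual for cluster-robust
inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .constants import StudyConstants, period_of_month
from .exceptions import AnnotationError, StratumError
from .grid import Raster
from .simulate.landscape import BACKGROUND, LAND_USE_CLASSES, Landscape
from .simulate.river import RiverModel
from .terms import build_design_matrix

logger = logging.getLogger(__name__)

#: Categorical covariate metadata shared by annotation and model fitting:
#: reference categories are alfalfa/hay fields and private ownership.
CATEGORICAL_META = {
    "land_use": (list(LAND_USE_CLASSES), "alfalfa_hay"),
    "ownership": (["private", "public"], "private"),
}


class RasterMask:
    """Availability mask backed by a boolean raster (diurnal eligibility)."""

    def __init__(self, raster: Raster):
        self.raster = raster

    def contains(self, x, y):
        ok = self.raster.contains_xy(x, y)
        out = np.zeros(np.shape(ok), dtype=bool)
        if np.any(ok):
            r, c = self.raster.xy_to_rc(np.asarray(x)[ok], np.asarray(y)[ok])
            out[ok] = self.raster.data[r, c].astype(bool)
        return out


class PolygonMask:
    """Availability mask backed by a polygon (the active river channel)."""

    def __init__(self, polygon):
        self.polygon = polygon
        shapely.prepare(polygon)

    def contains(self, x, y):
        return shapely.contains_xy(self.polygon, np.asarray(x), np.asarray(y))


def sample_available(used_xy, radius, mask, n, rng, max_batches: int = 200):
    """Draw ``n`` points uniformly on disc(used_xy, radius) ∩ mask.

    Uniform candidates are drawn on the disc (r = R*sqrt(u)) and rejected
    against the mask. Raises StratumError if the intersection appears
    empty after ``max_batches`` rejection rounds with no acceptances.
    """
    x0, y0 = float(used_xy[0]), float(used_xy[1])
    out = np.empty((0, 2))
    batch = max(4 * n, 64)
    ever_accepted = False
    for attempt in range(max_batches):
        u = rng.random(batch)
        theta = rng.uniform(0, 2 * np.pi, batch)
        r = radius * np.sqrt(u)
        xs = x0 + r * np.cos(theta)
        ys = y0 + r * np.sin(theta)
        keep = mask.contains(xs, ys)
        if np.any(keep):
            ever_accepted = True
            out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
            if len(out) >= n:
                return out[:n]
        if attempt >= 20 and not ever_accepted:
            break
    raise StratumError(
        f"availability disc around ({x0:.1f}, {y0:.1f}) has empty or "
        "near-empty intersection with the mask"
    )


def annotate_diurnal(
    points,
    landscape: Landscape,
    constants: StudyConstants = StudyConstants(),
) -> pd.DataFrame:
    """Diurnal covariates for an array of points.

    Each point receives its land-use category, ownership, distance to the
    nearest human structure, and structure counts within the 100/500/1000 m
    radii (boundary-inclusive). Points off the raster or on unclassified
    background raise AnnotationError.
    """
    points = np.atleast_2d(np.asarray(points, float))
    x, y = points[:, 0], points[:, 1]
    codes = landscape.land_use.sample(x, y)
    if np.any(codes == BACKGROUND):
        i = int(np.argmax(codes == BACKGROUND))
        raise AnnotationError(
            f"point ({x[i]:.1f}, {y[i]:.1f}) lies on unclassified background, "
            "not an eligible field/pasture/wetland cell"
        )
    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "land_use": np.array(LAND_USE_CLASSES)[codes],
            "ownership": np.where(
                landscape.ownership.sample(x, y) == 1, "public", "private"
            ),
            "dist_structure": landscape.structure_distance(x, y),
        }
    )
    for r in constants.density_radii_m:
        out[f"struct_{int(r)}"] = landscape.structure_counts(x, y, r)
    return out


def annotate_roost(
    points,
    river: RiverModel,
    period: str,
    landscape: Landscape | None = None,
    constants: StudyConstants = StudyConstants(),
) -> pd.DataFrame:
    """Roost covariates for an array of in-channel points.

    Each point receives the channel width of its nearest centerline station
    (no interpolation), the period-matched water/sandbar/vegetation
    proportions of its 30 m pixel, mean bank vegetation height within the
    100/500/1000 m along-river stretches, distance to the nearest bridge,
    and — when a landscape is supplied — distance to the nearest structure
    and the structure count within 1000 m.
    """
    if period not in river.proportions:
        raise AnnotationError(
            f"period {period!r} has no proportion rasters "
            f"(available: {sorted(river.proportions)})"
        )
    points = np.atleast_2d(np.asarray(points, float))
    x, y = points[:, 0], points[:, 1]
    layer = river.proportions[period]
    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "width": river.width_at(x, y),
            "water": np.asarray(layer["water"].sample(x, y), float),
            "sandbar": np.asarray(layer["sandbar"].sample(x, y), float),
            "vegetation": np.asarray(layer["vegetation"].sample(x, y), float),
        }
    )
    bad = out[["water", "sandbar", "vegetation"]].isna().any(axis=1).to_numpy()
    if bad.any():
        # A point can sit inside the channel polygon while its 30 m pixel
        # center falls outside (proportions are defined on center-in-channel
        # pixels); annotate such points from the nearest channel pixel.
        from scipy.spatial import cKDTree

        cx, cy = river.channel_pixel_centers()
        if len(cx) == 0:
            raise AnnotationError("river has no channel pixels")
        d, j = cKDTree(np.column_stack([cx, cy])).query(
            np.column_stack([x[bad], y[bad]])
        )
        too_far = d > 2.0 * river.channel_mask.cell
        if np.any(too_far):
            i = int(np.argmax(bad)) if bad.sum() == 1 else int(np.flatnonzero(bad)[np.argmax(too_far)])
            raise AnnotationError(
                f"point ({x[i]:.1f}, {y[i]:.1f}) is not on or near the active "
                "channel proportion grid"
            )
        for name in ("water", "sandbar", "vegetation"):
            vals = np.asarray(layer[name].sample(cx[j], cy[j]), float)
            col = out[name].to_numpy()
            col[bad] = vals
            out[name] = col
    for r in constants.stretch_radii_m:
        out[f"bank_{int(r)}"] = river.bank_stretch_mean(x, y, r)
    out["dist_bridge"] = river.bridge_distance(x, y)
    if landscape is not None:
        out["dist_structure"] = landscape.structure_distance(x, y)
        out["struct_1000"] = landscape.structure_counts(x, y, 1000.0)
    return out


@dataclass
class StrataSet:
    """Matched case-control strata with annotated covariates.

    ``df`` holds one row per design row with columns ``stratum_id``,
    ``cluster_id``, ``is_used``, ``period`` plus covariates; within each
    stratum the used row comes first. ``categorical`` maps covariate name
    to (levels, reference); ``continuous`` lists the continuous covariates.
    """

    df: pd.DataFrame
    categorical: dict = field(default_factory=dict)
    continuous: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return self.df["stratum_id"].nunique()

    @property
    def n_clusters(self) -> int:
        return self.df["cluster_id"].nunique()

    def design_matrix(self, terms, standardize: bool = True, constants: dict | None = None):
        """Design matrix for a term list (see :mod:`cranesel.terms`)."""
        return build_design_matrix(
            self.df, terms, categorical=self.categorical,
            standardize=standardize, constants=constants,
        )

    def validate(self, radius: float | None = None, n_available: int | None = None):
        """Check stratum closure and (optionally) the disc constraint.

        Returns a list of human-readable violation strings (empty = valid).
        """
        issues = []
        g = self.df.groupby("stratum_id", sort=False)
        used_per = g["is_used"].sum()
        if not (used_per == 1).all():
            issues.append(
                f"{(used_per != 1).sum()} strata without exactly one used row"
            )
        if n_available is not None:
            sizes = g.size()
            if not (sizes == n_available + 1).all():
                issues.append(
                    f"{(sizes != n_available + 1).sum()} strata with wrong size"
                )
        if self.df.groupby("stratum_id", sort=False)["cluster_id"].nunique().max() > 1:
            issues.append("stratum spanning multiple clusters")
        if radius is not None and {"x", "y"}.issubset(self.df.columns):
            d = self.df.merge(
                self.df[self.df.is_used == 1][["stratum_id", "x", "y"]],
                on="stratum_id",
                suffixes=("", "_used"),
            )
            dist = np.hypot(d.x - d.x_used, d.y - d.y_used)
            if (dist > radius * (1 + 1e-9)).any():
                issues.append(
                    f"{int((dist > radius).sum())} rows outside the availability disc"
                )
        cov_cols = list(self.continuous) + list(self.categorical)
        if self.df[cov_cols].isna().any().any():
            issues.append("missing covariate values")
        return issues

    def to_csv(self, path, sidecar: bool = True):
        """Persist as flat CSV plus a JSON sidecar with metadata."""
        self.df.to_csv(path, index=False)
        if sidecar:
            side = {
                "categorical": {
                    k: {"levels": list(v[0]), "reference": v[1]}
                    for k, v in self.categorical.items()
                },
                "continuous": list(self.continuous),
                "meta": self.meta,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(side, fh, indent=2, default=str)


def build_strata(
    used_fixes: pd.DataFrame,
    period: str,
    landscape: Landscape | None = None,
    river: RiverModel | None = None,
    constants: StudyConstants = StudyConstants(),
    seed: int = 0,
) -> StrataSet:
    """Build the full matched design for one diel period.

    Parameters
    ----------
    used_fixes : DataFrame
        Used locations with columns ``individual_id``, ``timestamp``,
        ``x``, ``y`` (timestamp only required for roost period matching).
    period : str
        ``"diurnal"`` or ``"roost"``.
    landscape, river
        Landscape is required for the diurnal period (and optional for
        roost structure covariates); river is required for roost.
    """
    rng = np.random.default_rng(seed)
    if period == "diurnal":
        if landscape is None:
            raise StratumError("diurnal strata require a landscape")
        mask = RasterMask(landscape.eligible)
    elif period == "roost":
        if river is None:
            raise StratumError("roost strata require a river model")
        mask = PolygonMask(river.polygon)
    else:
        raise StratumError(f"unknown period {period!r}")

    M = constants.n_available
    R = constants.availability_radius_m
    used = used_fixes.reset_index(drop=True)

    rows_x, rows_y, strat, clust, is_used, fix_period = [], [], [], [], [], []
    for sid, rec in used.iterrows():
        pts = sample_available((rec.x, rec.y), R, mask, M, rng)
        rows_x.extend([rec.x, *pts[:, 0]])
        rows_y.extend([rec.y, *pts[:, 1]])
        strat.extend([sid] * (M + 1))
        clust.extend([rec.individual_id] * (M + 1))
        is_used.extend([1] + [0] * M)
        if period == "roost":
            month = pd.Timestamp(rec.timestamp).month
            fix_period.extend([period_of_month(month)] * (M + 1))

    base = pd.DataFrame(
        {
            "stratum_id": strat,
            "cluster_id": clust,
            "is_used": is_used,
            "period": period,
        }
    )
    pts = np.column_stack([rows_x, rows_y])
    if period == "diurnal":
        ann = annotate_diurnal(pts, landscape, constants)
        categorical = dict(CATEGORICAL_META)
        continuous = ["dist_structure"] + [
            f"struct_{int(r)}" for r in constants.density_radii_m
        ]
    else:
        base["bimonthly"] = fix_period
        parts = []
        for per in base["bimonthly"].unique():
            sel = (base["bimonthly"] == per).to_numpy()
            parts.append(
                annotate_roost(pts[sel], river, per, landscape, constants).set_index(
                    np.flatnonzero(sel)
                )
            )
        ann = pd.concat(parts).sort_index()
        categorical = {}
        continuous = [
            "width",
            "water",
            "sandbar",
            "vegetation",
            *[f"bank_{int(r)}" for r in constants.stretch_radii_m],
            "dist_bridge",
        ]
        if landscape is not None:
            continuous += ["dist_structure", "struct_1000"]

    df = pd.concat([base, ann.reset_index(drop=True)], axis=1)
    meta = {
        "seed": seed,
        "radius_m": R,
        "n_available": M,
        "period": period,
        "no_structures_sentinel": (
            float(np.hypot(landscape.config.width_m, landscape.config.height_m))
            if landscape is not None and len(landscape.structures) == 0
            else None
        ),
    }
    return StrataSet(df=df, categorical=categorical, continuous=continuous, meta=meta)
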