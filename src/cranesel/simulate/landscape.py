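"""Synthetic floodplain landscape generator.

The landscape is a grid of axis-aligned field blocks, each assigned one of
six land-use classes (alfalfa/hay dominating at ~88% of classified area),
or left as unclassified background (riparian corridor, urban matrix). A
single rectangular block of public ownership is embedded in an otherwise
private floodplain, and wetland patches are preferentially swapped into the
public block. Human structures follow a Thomas (Poisson cluster) point
process, reproducing density clustered near settlements.

The eligible-diurnal mask — the cells from which daytime availability is
drawn — is every classified field, pasture, or wetland cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..exceptions import ConfigurationError
from ..grid import Raster

#: Land-use class codes in raster order; alfalfa/hay is the reference class.
LAND_USE_CLASSES = ("alfalfa_hay", "corn", "fallow", "small_grain", "wetland", "other")

#: Raster code for unclassified background (not a field, never eligible).
BACKGROUND = -1

_DEFAULT_PROPORTIONS = {
    "alfalfa_hay": 0.88,
    "corn": 0.05,
    "fallow": 0.03,
    "small_grain": 0.02,
    "wetland": 0.015,
    "other": 0.005,
}


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic floodplain.

    ``proportions`` are fractions of *classified* (field/wetland) area and
    must sum to one; ``field_cover`` is the fraction of the grid covered by
    classified blocks at all. Structures are generated by a Thomas process
    with ``structure_clusters`` parents, mean ``structure_intensity``
    offspring each, and Gaussian dispersion ``structure_dispersion_m``.
    """

    width_m: float = 15_000.0
    height_m: float = 15_000.0
    cell_m: float = 100.0
    proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    field_cover: float = 0.75
    field_size_m: float = 500.0
    public_fraction: float = 0.12
    structure_clusters: int = 25
    structure_intensity: float = 30.0
    structure_dispersion_m: float = 150.0
    seed: int = 0

    def validate(self):
        p = np.array([self.proportions.get(c, 0.0) for c in LAND_USE_CLASSES])
        extra = set(self.proportions) - set(LAND_USE_CLASSES)
        if extra:
            raise ConfigurationError(f"unknown land-use classes {sorted(extra)}")
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigurationError("class proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must sum to 1 (got {p.sum():.12f})"
            )
        if self.cell_m <= 0:
            raise ConfigurationError("cell size must be positive")
        if not 0 < self.field_cover <= 1:
            raise ConfigurationError("field_cover must be in (0, 1]")
        if not 0 <= self.public_fraction < 1:
            raise ConfigurationError("public_fraction must be in [0, 1)")
        return p


@dataclass
class Landscape:
    """A generated landscape: land-use and ownership rasters, structures,
    and the eligible-diurnal mask (all classified cells)."""

    land_use: Raster          # int codes into LAND_USE_CLASSES, BACKGROUND elsewhere
    ownership: Raster         # 1 public, 0 private
    structures: np.ndarray    # (n, 2) x/y, all inside the extent
    eligible: Raster          # bool, True where diurnal availability is defined
    config: LandscapeConfig

    def class_fractions(self) -> dict:
        """Empirical class fractions among classified cells."""
        codes = self.land_use.data
        classified = codes >= 0
        n = classified.sum()
        return {
            name: float((codes == i).sum() / n) if n else 0.0
            for i, name in enumerate(LAND_USE_CLASSES)
        }

    def structure_counts(self, x, y, radius: float) -> np.ndarray:
        """Number of structures within ``radius`` (boundary-inclusive) of
        each point."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if len(self.structures) == 0:
            return np.zeros(x.shape, dtype=int)
        tree = cKDTree(self.structures)
        # query_ball_point with a small epsilon keeps boundary points in
        counts = tree.query_ball_point(
            np.column_stack([x, y]), r=radius * (1 + 1e-12), return_length=True
        )
        return np.asarray(counts, dtype=int)

    def structure_distance(self, x, y) -> np.ndarray:
        """Distance to the nearest structure; the landscape diagonal is
        returned as a finite sentinel when no structures exist."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if len(self.structures) == 0:
            diag = float(np.hypot(self.config.width_m, self.config.height_m))
            return np.full(x.shape, diag)
        tree = cKDTree(self.structures)
        d, _ = tree.query(np.column_stack([x, y]))
        return np.asarray(d, dtype=float)

    def structure_density_raster(self, radius: float) -> Raster:
        """Structure count within ``radius`` of every cell center."""
        X, Y = self.land_use.cell_centers()
        counts = self.structure_counts(X.ravel(), Y.ravel(), radius)
        return self.land_use.like(counts.reshape(X.shape).astype(float))


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a landscape; a pure function of the configuration."""
    p = config.validate()
    rng = np.random.default_rng(config.seed)

    nx = int(round(config.width_m / config.cell_m))
    ny = int(round(config.height_m / config.cell_m))
    nbx = max(1, int(round(config.width_m / config.field_size_m)))
    nby = max(1, int(round(config.height_m / config.field_size_m)))

    # Per-block land-use assignment: background with prob 1 - field_cover,
    # otherwise a class drawn from the stated proportions.
    classified = rng.random((nby, nbx)) < config.field_cover
    codes = rng.choice(len(LAND_USE_CLASSES), size=(nby, nbx), p=p)
    blocks = np.where(classified, codes, BACKGROUND)

    # Ownership: one rectangle of public land with the requested area.
    own_blocks = np.zeros((nby, nbx), dtype=np.int8)
    if config.public_fraction > 0:
        side = np.sqrt(config.public_fraction)
        pw = max(1, int(round(side * nbx)))
        ph = max(1, int(round(side * nby)))
        r0 = int(rng.integers(0, nby - ph + 1))
        c0 = int(rng.integers(0, nbx - pw + 1))
        own_blocks[r0 : r0 + ph, c0 : c0 + pw] = 1

    # Wetland patches belong inside public polygons: swap wetland labels
    # sitting on private blocks with non-wetland labels on public blocks.
    wet = LAND_USE_CLASSES.index("wetland")
    if config.public_fraction > 0:
        wet_private = np.argwhere((blocks == wet) & (own_blocks == 0))
        host_public = np.argwhere((blocks >= 0) & (blocks != wet) & (own_blocks == 1))
        n_swap = min(len(wet_private), len(host_public))
        if n_swap:
            pick = rng.choice(len(host_public), size=n_swap, replace=False)
            for (r1, c1), (r2, c2) in zip(wet_private[:n_swap], host_public[pick]):
                blocks[r1, c1], blocks[r2, c2] = blocks[r2, c2], blocks[r1, c1]

    # Expand blocks to cells.
    cells_per_bx = nx / nbx
    cells_per_by = ny / nby
    bc = np.minimum((np.arange(nx) / cells_per_bx).astype(int), nbx - 1)
    br = np.minimum((np.arange(ny) / cells_per_by).astype(int), nby - 1)
    land = blocks[np.ix_(br, bc)].astype(np.int16)
    own = own_blocks[np.ix_(br, bc)]

    # Thomas process for human structures; offspring outside the extent are
    # discarded so every point lies inside.
    parents = rng.uniform(
        [0, 0], [config.width_m, config.height_m], size=(config.structure_clusters, 2)
    )
    pts = []
    for px, py in parents:
        n = rng.poisson(config.structure_intensity)
        if n:
            off = rng.normal(0.0, config.structure_dispersion_m, size=(n, 2))
            pts.append(np.array([px, py]) + off)
    structures = (
        np.concatenate(pts) if pts else np.empty((0, 2), dtype=float)
    )
    inside = (
        (structures[:, 0] >= 0)
        & (structures[:, 0] <= config.width_m)
        & (structures[:, 1] >= 0)
        & (structures[:, 1] <= config.height_m)
    )
    structures = structures[inside]

    land_r = Raster(land, 0.0, 0.0, config.cell_m)
    return Landscape(
        land_use=land_r,
        ownership=land_r.like(own),
        structures=structures,
        eligible=land_r.like(land >= 0),
        config=config,
    )
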