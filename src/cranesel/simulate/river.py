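"""Synthetic river model: centerline, widths, channel composition, banks.

The river is a sinuous south-to-north centerline sampled at ~30 m stations,
each carrying an active-channel width. The active-channel polygon is built
from perpendicular offsets of half the station width. Within the channel,
30 m pixels carry water/sandbar/vegetation proportions produced by a
softmax over smooth random fields (so the three proportions close to one
exactly, as a constrained spectral unmixing of real imagery would yield),
independently perturbed for each bi-monthly period. A 10 m bank-vegetation
height raster covers cells within 50 m laterally of the active channel,
and bridges are dropped at regular intervals along the centerline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
import shapely
from shapely.geometry import Polygon

from ..constants import PERIODS
from ..exceptions import ConfigurationError
from ..grid import Raster

PROPORTION_CLASSES = ("water", "sandbar", "vegetation")


@dataclass
class RiverConfig:
    length_m: float = 12_000.0
    station_spacing_m: float = 30.0
    width_range_m: tuple = (40.0, 200.0)
    meander_amplitude_m: float = 250.0
    meander_wavelength_m: float = 4_000.0
    width_wavelength_m: float = 3_000.0
    x_center_m: float = 7_500.0
    y_start_m: float = 1_500.0
    periods: tuple = PERIODS
    proportion_cell_m: float = 30.0
    bank_cell_m: float = 10.0
    bank_buffer_m: float = 50.0
    bridge_spacing_m: float = 4_000.0
    smooth_sigma_px: float = 3.0
    period_perturbation: float = 0.5
    seed: int = 0

    def validate(self):
        lo, hi = self.width_range_m
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ConfigurationError("width range must be positive with lo <= hi")
        if len(self.periods) < 1:
            raise ConfigurationError("at least one period required")
        if self.station_spacing_m <= 0 or self.length_m <= 0:
            raise ConfigurationError("length and station spacing must be positive")


@dataclass
class RiverModel:
    """Centerline stations with widths, active-channel polygon, per-period
    proportion rasters, bank-vegetation-height raster, and bridges."""

    stations: np.ndarray          # (S, 2) ordered x/y at ~30 m spacing
    widths: np.ndarray            # (S,) active-channel width (m)
    chainage: np.ndarray          # (S,) along-centerline distance (m)
    polygon: Polygon              # active channel
    channel_mask: Raster          # bool on the 30 m proportion grid
    proportions: dict             # period -> {class -> Raster}, NaN off-channel
    bank_height: Raster           # 10 m, NaN outside the 50 m bank band
    bank_chainage: Raster         # chainage of nearest station per bank cell
    bridges: np.ndarray           # (B, 2)
    config: RiverConfig

    _station_tree: cKDTree | None = field(default=None, repr=False)

    def station_tree(self) -> cKDTree:
        if self._station_tree is None:
            self._station_tree = cKDTree(self.stations)
        return self._station_tree

    def nearest_station(self, x, y):
        """Indices of the nearest centerline station (no interpolation)."""
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        _, idx = self.station_tree().query(pts)
        return idx

    def width_at(self, x, y) -> np.ndarray:
        """Channel width at the nearest station."""
        return self.widths[self.nearest_station(x, y)]

    def in_channel(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.polygon, np.atleast_1d(x), np.atleast_1d(y))

    def bridge_distance(self, x, y) -> np.ndarray:
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        if len(self.bridges) == 0:
            return np.full(pts.shape[0], np.inf)
        d, _ = cKDTree(self.bridges).query(pts)
        return np.asarray(d, float)

    def bank_cells(self):
        """(x, y, height, chainage) arrays of valid bank cells."""
        h = self.bank_height.data
        valid = np.isfinite(h)
        X, Y = self.bank_height.cell_centers()
        return X[valid], Y[valid], h[valid], self.bank_chainage.data[valid]

    def bank_stretch_mean(self, x, y, stretch: float) -> np.ndarray:
        """Mean bank vegetation height within an along-centerline window of
        +/- stretch/2 around each point's projection onto the centerline.

        Falls back to the chainage-nearest bank cell if the window is
        empty (only possible for extreme configurations).
        """
        _, _, bh, bs = self.bank_cells()
        order = np.argsort(bs, kind="stable")
        bs_sorted = bs[order]
        bh_sorted = bh[order]
        csum = np.concatenate([[0.0], np.cumsum(bh_sorted)])
        s0 = self.chainage[self.nearest_station(x, y)]
        lo = np.searchsorted(bs_sorted, s0 - stretch / 2.0, side="left")
        hi = np.searchsorted(bs_sorted, s0 + stretch / 2.0, side="right")
        out = np.empty(len(np.atleast_1d(s0)), dtype=float)
        for i, (a, b, s) in enumerate(zip(np.atleast_1d(lo), np.atleast_1d(hi), np.atleast_1d(s0))):
            if b > a:
                out[i] = (csum[b] - csum[a]) / (b - a)
            else:
                j = np.argmin(np.abs(bs_sorted - s))
                out[i] = bh_sorted[j]
        return out

    def channel_pixel_centers(self):
        """(x, y) arrays of channel-pixel centers on the 30 m grid."""
        X, Y = self.channel_mask.cell_centers()
        m = self.channel_mask.data
        return X[m], Y[m]


def _smooth_field(rng, shape, sigma):
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    s = f.std()
    return f / s if s > 0 else f


def generate_river(config: RiverConfig) -> RiverModel:
    """Generate a river model; a pure function of the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_st = int(config.length_m / config.station_spacing_m) + 1
    s = np.arange(n_st) * config.station_spacing_m
    phase = rng.uniform(0, 2 * np.pi, size=3)

    # Sinuous centerline running south to north.
    wobble = gaussian_filter(rng.normal(0, 40.0, n_st), 25.0, mode="nearest")
    xs = (
        config.x_center_m
        + config.meander_amplitude_m * np.sin(2 * np.pi * s / config.meander_wavelength_m + phase[0])
        + wobble
    )
    ys = config.y_start_m + s
    stations = np.column_stack([xs, ys])

    # Smoothly varying width profile within the stated range.
    lo, hi = config.width_range_m
    wnoise = gaussian_filter(rng.normal(0, 0.15, n_st), 20.0, mode="nearest")
    widths = lo + (hi - lo) * np.clip(
        0.5 + 0.5 * np.sin(2 * np.pi * s / config.width_wavelength_m + phase[1]) + wnoise,
        0.0,
        1.0,
    )
    widths = np.maximum(widths, lo)

    # Active-channel polygon from perpendicular half-width offsets.
    tang = np.gradient(stations, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    left = stations + normal * (widths[:, None] / 2.0)
    right = stations - normal * (widths[:, None] / 2.0)
    polygon = Polygon(np.vstack([left, right[::-1]]))
    if not polygon.is_valid:
        polygon = polygon.buffer(0)

    # 30 m proportion grid over the channel bounding box.
    pad = 2 * config.proportion_cell_m
    xmin, ymin, xmax, ymax = polygon.bounds
    gx0 = np.floor((xmin - pad) / config.proportion_cell_m) * config.proportion_cell_m
    gy0 = np.floor((ymin - pad) / config.proportion_cell_m) * config.proportion_cell_m
    nxp = int(np.ceil((xmax + pad - gx0) / config.proportion_cell_m))
    nyp = int(np.ceil((ymax + pad - gy0) / config.proportion_cell_m))
    ref = Raster(np.zeros((nyp, nxp)), gx0, gy0, config.proportion_cell_m)
    Xc, Yc = ref.cell_centers()
    ch_mask = shapely.contains_xy(polygon, Xc.ravel(), Yc.ravel()).reshape(Xc.shape)
    channel_mask = ref.like(ch_mask)

    # Lateral position within the channel biases water toward the thalweg
    # and vegetation toward the margins.
    st_tree = cKDTree(stations)
    dlat, idx = st_tree.query(np.column_stack([Xc.ravel(), Yc.ravel()]))
    rho = np.clip(dlat / (widths[idx] / 2.0 + 1e-9), 0, 1.5).reshape(Xc.shape)

    base_w = _smooth_field(rng, (nyp, nxp), config.smooth_sigma_px)
    base_s = _smooth_field(rng, (nyp, nxp), config.smooth_sigma_px)
    proportions: dict[str, dict[str, Raster]] = {}
    for period in config.periods:
        dw = config.period_perturbation * _smooth_field(rng, (nyp, nxp), config.smooth_sigma_px)
        ds = config.period_perturbation * _smooth_field(rng, (nyp, nxp), config.smooth_sigma_px)
        logit_w = 1.0 - 2.0 * rho + base_w + dw
        logit_s = 0.1 + 0.8 * base_s + ds
        logit_v = -1.0 + 1.8 * rho
        logits = np.stack([logit_w, logit_s, logit_v])
        logits -= logits.max(axis=0, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=0, keepdims=True)
        layer = {}
        for k, name in enumerate(PROPORTION_CLASSES):
            arr = np.where(ch_mask, probs[k], np.nan)
            layer[name] = ref.like(arr)
        proportions[period] = layer

    # 10 m bank-vegetation-height raster within 50 m of the active channel.
    bpad = config.bank_buffer_m + 2 * config.bank_cell_m
    bx0 = np.floor((xmin - bpad) / config.bank_cell_m) * config.bank_cell_m
    by0 = np.floor((ymin - bpad) / config.bank_cell_m) * config.bank_cell_m
    nxb = int(np.ceil((xmax + bpad - bx0) / config.bank_cell_m))
    nyb = int(np.ceil((ymax + bpad - by0) / config.bank_cell_m))
    bref = Raster(np.zeros((nyb, nxb)), bx0, by0, config.bank_cell_m)
    Xb, Yb = bref.cell_centers()
    pts = shapely.points(Xb.ravel(), Yb.ravel())
    dist = shapely.distance(polygon, pts).reshape(Xb.shape)
    band = (dist > 0) & (dist <= config.bank_buffer_m)

    hfield = _smooth_field(rng, (nyb, nxb), 4.0)
    heights = np.log1p(np.exp(1.5 * hfield)) * 2.0  # softplus: >= 0, mean ~1.7 m
    bank_height = bref.like(np.where(band, heights, np.nan))
    _, bidx = st_tree.query(np.column_stack([Xb.ravel(), Yb.ravel()]))
    chain_arr = np.where(band, s[bidx].reshape(Xb.shape), np.nan)
    bank_chainage = bref.like(chain_arr)

    # Bridges at regular chainage intervals (excluding the endpoints).
    n_bridges = int(config.length_m // config.bridge_spacing_m)
    bridge_chain = (np.arange(n_bridges) + 0.5) * config.bridge_spacing_m
    bridge_idx = np.clip(
        np.round(bridge_chain / config.station_spacing_m).astype(int), 0, n_st - 1
    )
    bridges = stations[bridge_idx]

    return RiverModel(
        stations=stations,
        widths=widths,
        chainage=s,
        polygon=polygon,
        channel_mask=channel_mask,
        proportions=proportions,
        bank_height=bank_height,
        bank_chainage=bank_chainage,
        bridges=bridges,
        config=config,
    )
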