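"""Constrained spectral mixture analysis of river pixels.

A moderate-resolution channel pixel mixes water, sandbar, and riparian
vegetation. Fully constrained least squares recovers the per-pixel
proportions p minimizing ||E'p - s||^2 subject to p >= 0 and sum(p) = 1,
where E stacks the endmember spectra. The water endmember is extracted
from a 98th-percentile NDWI mask over deep-water reference scenes; sandbar
and vegetation endmembers come from static monotypic polygons. Bi-monthly
composites average all valid (cloud-mask-passing) observations per pixel.

The constrained solver enumerates active sets exactly: for each subset of
components pinned at zero it solves the equality-constrained least-squares
KKT system and keeps the feasible solution with the smallest residual.
With three endmembers this is seven tiny linear solves, deterministic and
accurate to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .exceptions import ConfigurationError


def ndwi(green, nir) -> np.ndarray:
    """Normalized difference water index (G - NIR)/(G + NIR).

    Pixels where G + NIR = 0 are undefined and returned as NaN.
    """
    green = np.asarray(green, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if green.shape != nir.shape:
        raise ConfigurationError("green and NIR bands must share a shape")
    denom = green + nir
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (green - nir) / denom
    out = np.where(denom == 0, np.nan, out)
    return out


def ndwi_mask(index, percentile: float = 98.0) -> np.ndarray:
    """Boolean mask of pixels at or above the given NDWI percentile.

    The percentile is the linear-interpolation quantile over valid
    (finite) pixels, so roughly (100 - percentile)% of pixels are flagged.
    A constant raster degenerates to flagging everything; a warning is
    emitted in that case.
    """
    index = np.asarray(index, dtype=float)
    valid = np.isfinite(index)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ConfigurationError("NDWI raster has no valid pixels")
    if n_valid < 50:
        raise ConfigurationError(
            f"NDWI percentile mask needs >= 50 valid pixels (got {n_valid})"
        )
    vals = index[valid]
    if np.all(vals == vals[0]):
        warnings.warn(
            "constant NDWI raster: percentile threshold degenerates, all "
            "valid pixels flagged",
            RuntimeWarning,
        )
    thresh = np.percentile(vals, percentile, method="linear")
    mask = np.zeros(index.shape, dtype=bool)
    mask[valid] = vals >= thresh
    return mask


@dataclass
class EndmemberSet:
    """Labelled endmember spectra over B bands."""

    labels: tuple
    spectra: np.ndarray  # (K, B)
    provenance: str = ""

    def validate(self):
        E = np.asarray(self.spectra, dtype=float)
        if E.ndim != 2 or E.shape[0] != len(self.labels):
            raise ConfigurationError("spectra must be (n_labels, bands)")
        if E.shape[1] < E.shape[0]:
            raise ConfigurationError("need at least as many bands as endmembers")
        if np.linalg.matrix_rank(E) < E.shape[0]:
            raise ConfigurationError("endmember matrix is rank deficient")
        return E


def extract_endmembers(image, regions: dict, provenance: str = "") -> EndmemberSet:
    """Mean spectrum per labelled region of a (ny, nx, B) image.

    ``regions`` maps label -> boolean mask; the water region is typically
    an NDWI-percentile mask, the others static monotypic polygons
    rasterized to masks. Empty regions raise.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ConfigurationError("image must be (ny, nx, bands)")
    labels, rows = [], []
    for label, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape[:2]:
            raise ConfigurationError(f"region {label!r} mask shape mismatch")
        if not mask.any():
            raise ConfigurationError(f"region {label!r} is empty")
        labels.append(label)
        rows.append(image[mask].mean(axis=0))
    ems = EndmemberSet(tuple(labels), np.vstack(rows), provenance=provenance)
    ems.validate()
    return ems


@dataclass
class UnmixResult:
    """Per-pixel simplex proportions and residual norms."""

    proportions: np.ndarray  # (n, K), each row on the simplex
    residual: np.ndarray     # (n,) L2 norm of E'p - s
    labels: tuple


def unmix(spectra, endmembers: EndmemberSet) -> UnmixResult:
    """Fully constrained least-squares unmixing (p >= 0, sum p = 1).

    Exact active-set enumeration: every subset of components constrained
    to zero yields an equality-constrained LS problem solved through its
    KKT system; the feasible candidate with minimal residual wins.
    Deterministic and permutation-equivariant in the endmember order.
    """
    E = endmembers.validate()
    K = E.shape[0]
    S = np.atleast_2d(np.asarray(spectra, dtype=float))
    if not np.all(np.isfinite(S)):
        raise ConfigurationError("non-finite values in pixel spectra")
    if S.shape[1] != E.shape[1]:
        raise ConfigurationError("spectrum band count does not match endmembers")
    n = S.shape[0]

    best_p = np.zeros((n, K))
    best_r2 = np.full(n, np.inf)
    G = E @ E.T  # (K, K) Gram matrix
    ES = E @ S.T  # (K, n)
    ss = np.einsum("ij,ij->i", S, S)

    for k in range(1, K + 1):
        for active in combinations(range(K), k):
            a = list(active)
            # KKT for min ||E_a' p - s||^2 s.t. 1'p = 1
            A = np.zeros((k + 1, k + 1))
            A[:k, :k] = 2.0 * G[np.ix_(a, a)]
            A[:k, k] = 1.0
            A[k, :k] = 1.0
            rhs = np.vstack([2.0 * ES[a], np.ones((1, n))])  # (k+1, n)
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            p_a = sol[:k]  # (k, n)
            feas = np.all(p_a >= -1e-10, axis=0)
            if not feas.any():
                continue
            # residual^2 = s's - 2 p'E s + p'G p
            r2 = (
                ss
                - 2.0 * np.einsum("kn,kn->n", p_a, ES[a])
                + np.einsum("kn,kl,ln->n", p_a, G[np.ix_(a, a)], p_a)
            )
            better = feas & (r2 < best_r2 - 1e-14)
            if better.any():
                best_r2[better] = r2[better]
                best_p[better] = 0.0
                for i, comp in enumerate(a):
                    best_p[better, comp] = p_a[i, better]
    best_p = np.clip(best_p, 0.0, None)
    best_p /= best_p.sum(axis=1, keepdims=True)
    # residual evaluated directly (the quadratic expansion used for
    # candidate comparison cancels catastrophically near zero)
    residual = np.linalg.norm(best_p @ E - S, axis=1)
    return UnmixResult(
        proportions=best_p,
        residual=residual,
        labels=endmembers.labels,
    )


def composite_period(stack, valid=None) -> np.ndarray:
    """Per-pixel mean of a (T, ...) image stack over valid observations.

    ``valid`` is an optional (T, ...) boolean mask (e.g., from a cloud
    mask); pixels with zero valid observations come back NaN.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] == 0:
        raise ConfigurationError("empty image stack")
    if valid is None:
        valid = np.isfinite(stack)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != stack.shape:
            raise ConfigurationError("validity mask shape mismatch")
        valid = valid & np.isfinite(stack)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out
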