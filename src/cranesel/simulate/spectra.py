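"""Synthetic multispectral pixels for testing spectral-mixture unmixing.

Pixels are convex combinations of three endmember spectra (water, sandbar,
vegetation) over Landsat-8-like reflective bands plus Gaussian noise, with
true proportions drawn from a Dirichlet distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import ConfigurationError

# Typical surface-reflectance shapes over six reflective bands
# (blue, green, red, NIR, SWIR1, SWIR2): water dark and decreasing,
# sandbar bright and flat, vegetation with the NIR plateau.
_DEFAULT_ENDMEMBERS = np.array(
    [
        [0.06, 0.08, 0.06, 0.04, 0.02, 0.01],  # water
        [0.18, 0.22, 0.26, 0.30, 0.34, 0.30],  # sandbar
        [0.04, 0.07, 0.05, 0.45, 0.22, 0.10],  # vegetation
    ]
)


@dataclass
class SpectraConfig:
    n_bands: int = 6
    endmembers: np.ndarray = field(default_factory=lambda: _DEFAULT_ENDMEMBERS.copy())
    noise_sd: float = 0.01
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self):
        E = np.asarray(self.endmembers, dtype=float)
        if E.ndim != 2 or E.shape[1] != self.n_bands:
            raise ConfigurationError(
                f"endmember matrix must be (classes, {self.n_bands})"
            )
        if np.linalg.matrix_rank(E) < E.shape[0]:
            raise ConfigurationError("endmember matrix is rank deficient")
        if self.noise_sd < 0:
            raise ConfigurationError("noise standard deviation must be >= 0")
        return E


def simulate_spectra(config: SpectraConfig, n_pixels: int):
    """Simulate mixed pixels.

    Returns
    -------
    spectra : ndarray (n_pixels, n_bands)
        pixel = proportions @ endmembers + Gaussian noise.
    proportions : ndarray (n_pixels, n_classes)
        True simplex proportions per pixel.
    """
    E = config.validate()
    rng = np.random.default_rng(config.seed)
    props = rng.dirichlet(config.dirichlet_alpha, size=n_pixels)
    spectra = props @ E
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, size=spectra.shape)
    return spectra, props
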