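"""The hyperspectral cube container and band-level utilities.

A :class:`SpectralCube` is the unit every stage of the pipeline consumes and
produces: an ``H x W x B`` reflectance array paired with a strictly increasing
wavelength vector in nanometres.  Reflectance is unitless; values are expected
in ``[0, 1]`` with small excursions above 1 tolerated (specular highlights,
noise), but never negative on write and never non-finite.

Pixel flattening order is row-major ``(row, col)`` throughout the package, so
``cube.pixels()[i]`` corresponds to ``mask.ravel()[i]`` for any congruent mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionMismatchError, NonFiniteError, OutOfRangeError

#: Default spectral grid: 900-1700 nm sampled every 5 nm (161 bands), the
#: short-wave-infrared range where water, lipid and collagen absorption
#: features are distinct.
DEFAULT_WAVELENGTHS = np.arange(900.0, 1700.0 + 2.5, 5.0)

#: NIR-II biological-window bands used for pseudocolor composites (nm).
NIR2_PSEUDOCOLOR_BANDS = (1091.0, 1211.0, 1318.0)


def default_wavelengths(n_bands: int = 161, lo: float = 900.0, hi: float = 1700.0) -> np.ndarray:
    """Evenly spaced wavelength grid over ``[lo, hi]`` nm with ``n_bands`` bands."""
    if n_bands < 2:
        raise ValueError("need at least two bands")
    return np.linspace(lo, hi, n_bands)


@dataclass
class SpectralCube:
    """Reflectance cube ``data[row, col, band]`` plus its wavelength axis.

    Parameters
    ----------
    data:
        ``H x W x B`` float array of unitless reflectance.
    wavelengths:
        Length-``B`` strictly increasing vector of band centres in nm.
    """

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"cube data must be H x W x B, got shape {self.data.shape}"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise DimensionMismatchError(
                f"cube has {self.data.shape[2]} bands but "
                f"{np.atleast_1d(self.wavelengths).size} wavelengths"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise DimensionMismatchError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise NonFiniteError("cube contains non-finite reflectance values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixels(self) -> np.ndarray:
        """All pixel spectra as an ``N x B`` matrix, row-major pixel order."""
        return self.data.reshape(-1, self.n_bands)

    def band_image(self, target_nm: float) -> np.ndarray:
        """The ``H x W`` reflectance plane at the band nearest ``target_nm``."""
        return self.data[:, :, nearest_band(self, target_nm)]


def nearest_band(cube: SpectralCube, target_nm: float) -> int:
    """Index of the band whose centre is closest to ``target_nm``.

    Ties (a target exactly midway between two bands) resolve to the lower
    index.  Targets farther than one band spacing beyond either end of the
    grid are rejected rather than silently clamped.
    """
    w = cube.wavelengths
    lo_margin = w[1] - w[0]
    hi_margin = w[-1] - w[-2]
    if target_nm < w[0] - lo_margin or target_nm > w[-1] + hi_margin:
        raise OutOfRangeError(
            f"{target_nm} nm is outside the cube range [{w[0]}, {w[-1]}] nm "
            "(tolerance: one band spacing)"
        )
    return int(np.argmin(np.abs(w - target_nm)))


def pseudocolor(
    cube: SpectralCube,
    bands_nm: tuple[float, float, float] = NIR2_PSEUDOCOLOR_BANDS,
) -> np.ndarray:
    """Three-band false-colour composite, each channel min-max normalised.

    The default bands sit in the NIR-II biological window, where tissue
    absorption is low and penetration depth is greatest.  A channel with zero
    dynamic range maps to 0 everywhere.
    """
    if len(bands_nm) != 3:
        raise ValueError("pseudocolor needs exactly three wavelengths")
    out = np.zeros(cube.data.shape[:2] + (3,), dtype=np.float64)
    for c, nm in enumerate(bands_nm):
        plane = cube.data[:, :, nearest_band(cube, nm)].astype(np.float64)
        lo, hi = plane.min(), plane.max()
        if hi > lo:
            out[:, :, c] = (plane - lo) / (hi - lo)
    return out
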