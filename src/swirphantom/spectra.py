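"""Synthetic endmember reflectance spectra for SWIR tissue constituents.

Water, lipid and collagen have distinct absorption features in the 900-1700 nm
short-wave-infrared range: water absorbs near 970, 1180 and 1430 nm; lipids
near 920, 1210, 1730 and 1760 nm; collagen near 1200, 1500 and 1725 nm.  A
constituent's reflectance spectrum is modelled as a Beer-Lambert-style
exponential of a smooth absorbance curve, with each absorption feature a
Gaussian of given centre, depth and width on top of a flat baseline:

    reflectance(lambda) = exp(-baseline - sum_i depth_i * g(lambda; c_i, w_i))

where ``g`` is a unit-height Gaussian.  Peak centres above the spectral grid
maximum cannot be realised and are dropped with a logged notice (the 1725-1760
nm lipid/collagen features fall just outside a 900-1700 nm sensor).

Absorbance magnitudes here are declared simulation defaults, not fits to any
particular camera: they are chosen so that constituent spectra are cleanly
separable yet overlapping, the regime that makes subpixel detection and
unmixing non-trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cube import DEFAULT_WAVELENGTHS

logger = logging.getLogger(__name__)

#: Default Gaussian full width parameter of an absorption feature, nm.
DEFAULT_PEAK_WIDTH = 30.0

#: Absorption-feature tables: (centers nm, depths in absorbance, baseline).
_CONSTITUENTS: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "water": ((970.0, 1180.0, 1430.0), (0.35, 0.5, 1.2), 0.15),
    "lipid": ((920.0, 1210.0, 1730.0, 1760.0), (0.4, 0.9, 1.0, 0.8), 0.08),
    "collagen": ((1200.0, 1500.0, 1725.0), (0.5, 0.9, 0.7), 0.12),
}


@dataclass
class EndmemberSpectrum:
    """A named pure-constituent reflectance spectrum on a wavelength grid."""

    name: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if np.any(self.reflectance <= 0) or np.any(self.reflectance > 1):
            raise ValueError("reflectance must lie in (0, 1]")


def build_endmember(
    name: str,
    peak_centers: Sequence[float],
    peak_depths: Sequence[float],
    peak_widths: Sequence[float] | float = DEFAULT_PEAK_WIDTH,
    baseline: float = 0.1,
    wavelengths: np.ndarray | None = None,
) -> EndmemberSpectrum:
    """Build a reflectance spectrum from a table of absorption features.

    Peaks whose centre exceeds the grid maximum are silently dropped (with a
    log notice): a sensor cannot see features beyond its spectral range.
    """
    wl = np.asarray(DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths, dtype=np.float64)
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    centers = np.atleast_1d(np.asarray(peak_centers, dtype=np.float64))
    depths = np.atleast_1d(np.asarray(peak_depths, dtype=np.float64))
    widths = np.broadcast_to(np.asarray(peak_widths, dtype=np.float64), centers.shape)
    if centers.shape != depths.shape:
        raise ValueError("peak_centers and peak_depths must have equal length")
    if np.any(depths < 0):
        raise ValueError("peak depths must be nonnegative")
    if np.any(widths <= 0):
        raise ValueError("peak widths must be positive")

    keep = centers <= wl.max()
    dropped = centers[~keep]
    if dropped.size:
        logger.info(
            "%s: dropping %d absorption peak(s) above the grid maximum (%s nm)",
            name, dropped.size, ", ".join(format(c, "g") for c in dropped),
        )

    absorbance = np.full_like(wl, float(baseline))
    for c, d, w in zip(centers[keep], depths[keep], widths[keep]):
        absorbance += d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return EndmemberSpectrum(name=name, wavelengths=wl, reflectance=np.exp(-absorbance))


def constituent(name: str, wavelengths: np.ndarray | None = None) -> EndmemberSpectrum:
    """One of the built-in constituents: ``water``, ``lipid`` or ``collagen``."""
    try:
        centers, depths, baseline = _CONSTITUENTS[name]
    except KeyError:
        raise KeyError(f"unknown constituent {name!r}; options: {sorted(_CONSTITUENTS)}")
    return build_endmember(name, centers, depths, baseline=baseline, wavelengths=wavelengths)


def collagen_at_concentration(
    base: EndmemberSpectrum,
    concentration: float,
    reference_concentration: float = 4.0,
    mode: str = "beer_lambert",
    low: EndmemberSpectrum | None = None,
    high: EndmemberSpectrum | None = None,
) -> EndmemberSpectrum:
    """Collagen spectrum at a given mass concentration (percent).

    ``beer_lambert`` mode scales absorbance proportionally to concentration,
    i.e. ``reflectance = base ** (c / c_ref)`` — the physical model for a
    chromophore whose concentration multiplies its absorption coefficient.
    ``linear_reflectance`` mode instead interpolates linearly between the 2 %
    and 5 % endpoint spectra (weight ``(5 - c) / 3`` on the 2 % spectrum),
    which is the mixing rule the concentration-panel phantom realises.
    """
    if concentration <= 0 or reference_concentration <= 0:
        raise ValueError("concentrations must be positive")
    if mode == "beer_lambert":
        refl = base.reflectance ** (concentration / reference_concentration)
        return EndmemberSpectrum(
            name=f"{base.name}_{concentration:g}pct",
            wavelengths=base.wavelengths,
            reflectance=refl,
        )
    if mode == "linear_reflectance":
        if not 2.0 <= concentration <= 5.0:
            raise ValueError(
                "linear_reflectance mode interpolates the 2-5% range only; "
                f"cannot extrapolate to {concentration:g}%"
            )
        lo = low if low is not None else collagen_at_concentration(base, 2.0, reference_concentration)
        hi = high if high is not None else collagen_at_concentration(base, 5.0, reference_concentration)
        w_lo = (5.0 - concentration) / 3.0
        refl = w_lo * lo.reflectance + (1.0 - w_lo) * hi.reflectance
        return EndmemberSpectrum(
            name=f"{base.name}_{concentration:g}pct",
            wavelengths=base.wavelengths,
            reflectance=refl,
        )
    raise ValueError(f"unknown mode {mode!r}")


def load_signature(path) -> EndmemberSpectrum:
    """Read a two-column text signature (wavelength nm, reflectance)."""
    arr = np.loadtxt(path, comments="#")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("signature file must have two columns: nm, reflectance")
    return EndmemberSpectrum(name="custom", wavelengths=arr[:, 0], reflectance=arr[:, 1])


def save_signature(spectrum: EndmemberSpectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths, spectrum.reflectance]),
        header=f"{spectrum.name}: wavelength_nm reflectance",
    )
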