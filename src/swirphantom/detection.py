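"""Constrained energy minimization (CEM) subpixel target detection.

CEM designs a finite-impulse-response filter ``w`` over the L spectral bands
that minimizes the average output energy of the whole image,

    min_w  w' R w    subject to   d' w = 1,

where ``R = (1/N) sum_i r_i r_i'`` is the sample autocorrelation matrix over
all N pixel spectra and ``d`` is the target signature (here: lard/lipid).
The closed-form optimum is

    w* = R^-1 d / (d' R^-1 d),

and the per-pixel filter output ``A(r) = w*' r`` is an abundance-like map
that is exactly 1 on a pixel whose spectrum equals ``d`` and is suppressed on
background-dominated pixels.  The map is binarized with Otsu's threshold and
scored against ground truth with the Tanimoto (Jaccard) index.

Because synthetic scenes can make ``R`` numerically singular (few distinct
spectra), a small ridge ``eps * trace(R) / L`` is added before the symmetric
solve; the ridge actually applied is recorded on the returned filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cube import SpectralCube
from .errors import (
    ConstantMapError,
    DimensionMismatchError,
    NumericalError,
    UndefinedIndexError,
)

#: Relative ridge added to R before inversion: ``eps * trace(R) / L``.
DEFAULT_RIDGE_SCALE = 1e-6


@dataclass
class CemFilter:
    """A fitted CEM filter: weights ``w``, the matrix ``R`` it was built from,
    and the ridge actually applied."""

    w: np.ndarray
    R: np.ndarray
    d: np.ndarray
    ridge: float

    def response(self, spectra: np.ndarray) -> np.ndarray:
        """Filter output ``w' r`` for one spectrum or an ``N x L`` stack."""
        return np.asarray(spectra, dtype=np.float64) @ self.w


def autocorrelation_matrix(cube_or_pixels: SpectralCube | np.ndarray) -> np.ndarray:
    """Sample autocorrelation ``R = (1/N) sum_i r_i r_i'`` over all pixels.

    Symmetric positive semidefinite by construction; computed over every
    pixel, target pixels included (global background statistics).
    """
    if isinstance(cube_or_pixels, SpectralCube):
        X = cube_or_pixels.pixels().astype(np.float64)
    else:
        X = np.atleast_2d(np.asarray(cube_or_pixels, dtype=np.float64))
    if X.shape[0] == 0:
        raise DimensionMismatchError("cannot form autocorrelation of an empty pixel set")
    R = (X.T @ X) / X.shape[0]
    return (R + R.T) / 2.0  # exact symmetry against fp drift


def cem_filter(
    R: np.ndarray,
    d: np.ndarray,
    ridge: float | str = "auto",
) -> CemFilter:
    """Fit the CEM weight vector ``w = R^-1 d / (d' R^-1 d)``.

    ``ridge='auto'`` applies ``1e-6 * trace(R) / L``; an explicit float is
    used as-is.  Solved as a symmetric linear system, never by forming the
    explicit inverse.
    """
    R = np.asarray(R, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64).ravel()
    if R.shape != (d.size, d.size):
        raise DimensionMismatchError(f"R is {R.shape}, signature has {d.size} bands")
    if not np.any(d):
        raise ValueError("target signature must not be all-zero")

    L = d.size
    eps = DEFAULT_RIDGE_SCALE * np.trace(R) / L if ridge == "auto" else float(ridge)
    Rinv_d = scipy.linalg.solve(R + eps * np.eye(L), d, assume_a="pos")
    denom = float(d @ Rinv_d)
    if denom <= 0:
        raise NumericalError(
            f"d' R^-1 d = {denom:.3e} <= 0; R + ridge*I is not positive definite "
            f"(ridge={eps:.3e}, trace(R)={np.trace(R):.3e})"
        )
    return CemFilter(w=Rinv_d / denom, R=R, d=d, ridge=eps)


def cem_detect(
    cube: SpectralCube,
    d: np.ndarray,
    ridge: float | str = "auto",
) -> tuple[np.ndarray, CemFilter]:
    """Abundance map ``A[i, j] = w' r_ij`` for the target signature ``d``.

    Returns the H x W map together with the fitted filter (whose ridge and
    unit-response constraint can be inspected).
    """
    d = np.asarray(d, dtype=np.float64).ravel()
    if d.size != cube.n_bands:
        raise DimensionMismatchError(
            f"signature has {d.size} bands, cube has {cube.n_bands}"
        )
    filt = cem_filter(autocorrelation_matrix(cube), d, ridge=ridge)
    amap = filt.response(cube.pixels()).reshape(cube.shape[:2])
    return amap, filt


def otsu_threshold(values: np.ndarray, bins: int = 256) -> tuple[float, np.ndarray]:
    """Otsu's threshold of a scalar map, plus the mask ``values > threshold``.

    Candidate thresholds are the interior edges of a ``bins``-bin histogram
    of the min-max-normalized values; the chosen edge maximizes the
    between-class variance ``w0 w1 (mu0 - mu1)^2`` computed from the actual
    values (not bin centres), so the result coincides exactly with an
    exhaustive search over bin-edge thresholds.  Variance ties resolve to the
    lower threshold.  The returned threshold is on the original value scale.
    """
    v = np.asarray(values, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ConstantMapError("cannot threshold a constant map")
    norm = (v - lo) / (hi - lo)
    idx = np.minimum((norm * bins).astype(np.intp), bins - 1)

    counts = np.bincount(idx.ravel(), minlength=bins).astype(np.float64)
    sums = np.bincount(idx.ravel(), weights=norm.ravel(), minlength=bins)
    n = v.size
    # class 0 = bins [0, k], threshold candidate = edge (k+1)/bins
    n0 = np.cumsum(counts)[:-1]
    s0 = np.cumsum(sums)[:-1]
    n1 = n - n0
    total = sums.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / n0
        mu1 = (total - s0) / n1
        between = n0 * n1 * (mu0 - mu1) ** 2
    between[(n0 == 0) | (n1 == 0)] = -np.inf
    k = int(np.argmax(between))  # first max -> lower threshold
    t_norm = (k + 1) / bins
    threshold = lo + t_norm * (hi - lo)
    return float(threshold), v > threshold


def tanimoto_index(x: np.ndarray, y: np.ndarray) -> float:
    """Tanimoto (Jaccard) index ``|X & Y| / |X | Y|`` of two boolean masks.

    1 means the masks are identical, 0 means they are disjoint.  Two empty
    masks have no defined index (0/0) and raise rather than returning a
    silently misleading 0 or 1.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise DimensionMismatchError(f"mask shapes differ: {x.shape} vs {y.shape}")
    union = np.count_nonzero(x | y)
    if union == 0:
        raise UndefinedIndexError("Tanimoto index of two empty masks is undefined")
    return np.count_nonzero(x & y) / union
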