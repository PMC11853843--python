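"""Linear spectral unmixing: LS, sum-to-one LS, and fully constrained LS.

The linear mixing model writes a pixel spectrum as ``r = M a + n``, with
``M`` the ``L x p`` matrix of endmember spectra (columns), ``a`` the
abundance fractions and ``n`` noise.  Three estimators are provided:

* ``ls_unmix``      — unconstrained least squares ``(M'M)^-1 M' r``;
* ``scls_unmix``    — least squares under the sum-to-one equality constraint
  ``1' a = 1`` (closed form via the Lagrange correction of the LS solution);
* ``fcls_unmix``    — fully constrained least squares over the probability
  simplex (sum-to-one and nonnegativity), solved by a Heinz-Chang-style
  active-set iteration: start from the sum-to-one solution, clamp the most
  negative coordinate to zero, re-solve on the surviving support, repeat.

The active set only shrinks (no re-entry of clamped variables), so the loop
terminates in at most ``p - 1`` clamps; ``max_iter`` defaults to ``10 p`` as
a safety net.  All solves go through least-squares factorizations, never an
explicit ``(M'M)^-1``; condition numbers above 1e10 trip a singular-design
error naming the offending endmembers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .cube import SpectralCube
from .errors import DimensionMismatchError, NonConvergenceError, SingularDesignError

_COND_LIMIT = 1e10


@dataclass
class EndmemberMatrix:
    """``L x p`` matrix of endmember spectra as columns, with labels."""

    M: np.ndarray
    names: tuple[str, ...]
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2:
            raise DimensionMismatchError("endmember matrix must be 2-D (bands x endmembers)")
        if self.M.shape[1] < 2:
            raise SingularDesignError("need at least two endmembers")
        if len(self.names) != self.M.shape[1]:
            raise DimensionMismatchError("one name per endmember column required")
        _check_rank(self.M, self.names)

    @property
    def n_endmembers(self) -> int:
        return self.M.shape[1]


@dataclass
class AbundanceVector:
    """Per-pixel unmixing result: fractions, residual, and the model used."""

    alpha: np.ndarray
    residual: float       # squared residual norm ||r - M a||^2
    model: str            # LS | SCLS | FCLS


def _check_rank(M: np.ndarray, names) -> None:
    s = np.linalg.svd(M, compute_uv=False)
    if s[-1] == 0 or s[0] / s[-1] > _COND_LIMIT:
        # identify near-collinear columns by pairwise cosine similarity
        norms = np.linalg.norm(M, axis=0)
        bad: list[str] = []
        with np.errstate(invalid="ignore"):
            cos = (M.T @ M) / np.outer(norms, norms)
        for i in range(M.shape[1]):
            for j in range(i + 1, M.shape[1]):
                if not np.isfinite(cos[i, j]) or abs(cos[i, j]) > 1 - 1e-12:
                    bad.extend([str(names[i]), str(names[j])])
        detail = f" (near-collinear: {sorted(set(bad))})" if bad else ""
        raise SingularDesignError(
            f"endmember matrix numerically rank-deficient, cond={s[0] / max(s[-1], 1e-300):.2e}{detail}"
        )


def _prepare(r: np.ndarray, M: EndmemberMatrix | np.ndarray):
    A = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, dtype=np.float64)
    names = M.names if isinstance(M, EndmemberMatrix) else tuple(map(str, range(A.shape[1])))
    r = np.asarray(r, dtype=np.float64).ravel()
    if r.size != A.shape[0]:
        raise DimensionMismatchError(f"spectrum has {r.size} bands, endmembers have {A.shape[0]}")
    return r, A, names


def ls_unmix(r: np.ndarray, M: EndmemberMatrix | np.ndarray) -> AbundanceVector:
    """Unconstrained least-squares abundances ``argmin ||r - M a||^2``."""
    r, A, names = _prepare(r, M)
    _check_rank(A, names)
    alpha, *_ = np.linalg.lstsq(A, r, rcond=None)
    res = float(np.sum((r - A @ alpha) ** 2))
    return AbundanceVector(alpha=alpha, residual=res, model="LS")


def scls_unmix(r: np.ndarray, M: EndmemberMatrix | np.ndarray) -> AbundanceVector:
    """Least squares under the sum-to-one constraint ``1' a = 1``.

    Uses the standard Lagrange correction of the unconstrained solution:
    ``a = a_LS + (M'M)^-1 1 * (1 - 1' a_LS) / (1' (M'M)^-1 1)``.
    """
    r, A, names = _prepare(r, M)
    _check_rank(A, names)
    alpha = _scls_from_factor(*_gram_factor(A), A, r)
    res = float(np.sum((r - A @ alpha) ** 2))
    return AbundanceVector(alpha=alpha, residual=res, model="SCLS")


def _gram_factor(A: np.ndarray):
    """Cholesky of the Gram matrix plus the (M'M)^-1 1 direction."""
    G = A.T @ A
    c, low = scipy.linalg.cho_factor(G)
    ones = np.ones(A.shape[1])
    Ginv_1 = scipy.linalg.cho_solve((c, low), ones)
    return (c, low), Ginv_1


def _scls_from_factor(factor, Ginv_1, A: np.ndarray, r: np.ndarray) -> np.ndarray:
    alpha_ls = scipy.linalg.cho_solve(factor, A.T @ r)
    deficit = 1.0 - alpha_ls.sum()
    return alpha_ls + Ginv_1 * (deficit / Ginv_1.sum())


def fcls_unmix(
    r: np.ndarray,
    M: EndmemberMatrix | np.ndarray,
    tol: float = 1e-9,
    max_iter: int | None = None,
) -> AbundanceVector:
    """Fully constrained least squares: ``a >= 0`` and ``sum(a) = 1``.

    Active-set iteration starting from the sum-to-one solution; one variable
    is clamped per iteration and never re-enters.  The final solution is
    cleaned by zeroing magnitudes below ``tol`` and renormalizing.
    """
    r, A, names = _prepare(r, M)
    _check_rank(A, names)
    p = A.shape[1]
    if max_iter is None:
        max_iter = 10 * p

    support = list(range(p))
    alpha = np.zeros(p)
    last = None
    for _ in range(max_iter):
        sub = A[:, support]
        if len(support) == 1:
            sub_alpha = np.array([1.0])
        else:
            factor, Ginv_1 = _gram_factor(sub)
            sub_alpha = _scls_from_factor(factor, Ginv_1, sub, r)
        alpha = np.zeros(p)
        alpha[support] = sub_alpha
        last = alpha
        if np.all(sub_alpha >= -tol):
            alpha[np.abs(alpha) < tol] = 0.0
            alpha = np.clip(alpha, 0.0, None)
            alpha /= alpha.sum()
            res = float(np.sum((r - A @ alpha) ** 2))
            return AbundanceVector(alpha=alpha, residual=res, model="FCLS")
        worst = support[int(np.argmin(sub_alpha))]
        support.remove(worst)
    raise NonConvergenceError(
        f"FCLS did not converge within {max_iter} iterations", last_iterate=last
    )


def unmix_cube(
    cube: SpectralCube,
    M: EndmemberMatrix,
    model: str = "FCLS",
    tol: float = 1e-9,
) -> np.ndarray:
    """Per-pixel unmixing of a whole cube: returns ``H x W x p`` planes.

    For FCLS, the sum-to-one solution is first computed for every pixel in
    one vectorized pass; only pixels with a negative coordinate fall back to
    the per-pixel active-set solver.  FCLS planes satisfy the simplex
    constraints at every pixel.
    """
    model = model.upper()
    if model not in ("LS", "SCLS", "FCLS"):
        raise ValueError(f"unknown model {model!r}")
    A = M.M
    if A.shape[0] != cube.n_bands:
        raise DimensionMismatchError(
            f"endmembers have {A.shape[0]} bands, cube has {cube.n_bands}"
        )
    X = cube.pixels().astype(np.float64)          # N x L
    factor, Ginv_1 = _gram_factor(A)
    alpha_ls = scipy.linalg.cho_solve(factor, A.T @ X.T).T   # N x p

    if model == "LS":
        planes = alpha_ls
    else:
        deficit = 1.0 - alpha_ls.sum(axis=1)
        planes = alpha_ls + np.outer(deficit / Ginv_1.sum(), Ginv_1)
        if model == "FCLS":
            negative = np.any(planes < -tol, axis=1)
            for i in np.flatnonzero(negative):
                planes[i] = fcls_unmix(X[i], M, tol=tol).alpha
            planes[np.abs(planes) < tol] = 0.0
            planes = np.clip(planes, 0.0, None)
            planes /= planes.sum(axis=1, keepdims=True)
    return planes.reshape(cube.shape[:2] + (A.shape[1],))


def select_endmembers_from_image(
    cube: SpectralCube,
    regions,
    names: tuple[str, ...] | None = None,
) -> EndmemberMatrix:
    """Endmember matrix from in-image reference regions.

    Each region selects pixels — a boolean mask, an ``(row, col)`` pixel, or
    a numpy slice/index pair — and contributes its mean spectrum as one
    endmember column.  Using in-scene references (e.g. the shallowest and
    deepest wedge columns, or the extreme concentration panels) mirrors how
    endmembers are picked when no spectral library is available.
    """
    columns = []
    for region in regions:
        if isinstance(region, np.ndarray) and region.dtype == bool:
            if region.shape != cube.shape[:2]:
                raise DimensionMismatchError("region mask shape differs from cube")
            pixels = cube.data[region]
        else:
            sel = cube.data[region]
            pixels = sel.reshape(-1, cube.n_bands)
        if pixels.size == 0:
            raise ValueError("empty endmember region")
        columns.append(pixels.astype(np.float64).mean(axis=0))
    if names is None:
        names = tuple(f"endmember_{i + 1}" for i in range(len(columns)))
    return EndmemberMatrix(M=np.column_stack(columns), names=names, wavelengths=cube.wavelengths)


def load_endmembers(path) -> EndmemberMatrix:
    """Read an endmember text matrix: header of names, then nm + p columns."""
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
    arr = np.loadtxt(path, skiprows=1)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise DimensionMismatchError("endmember file needs nm column plus >= 2 spectra")
    names = tuple(header[1:]) if len(header) == arr.shape[1] else tuple(
        f"endmember_{i + 1}" for i in range(arr.shape[1] - 1)
    )
    return EndmemberMatrix(M=arr[:, 1:], names=names, wavelengths=arr[:, 0])


def save_endmembers(M: EndmemberMatrix, path) -> None:
    wl = M.wavelengths if M.wavelengths is not None else np.arange(M.M.shape[0], dtype=float)
    np.savetxt(
        path,
        np.column_stack([wl, M.M]),
        header="wavelength_nm " + " ".join(M.names),
    )
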