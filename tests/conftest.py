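import numpy as np
import pytest

from swirphantom import SpectralCube, default_wavelengths


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_cube(rng):
    """Small random reflectance cube on a uniform 7-band grid."""
    def make(h=4, w=5, b=7, lo=900.0, hi=1700.0):
        data = rng.uniform(0.05, 0.95, size=(h, w, b)).astype(np.float32)
        return SpectralCube(data=data, wavelengths=default_wavelengths(b, lo, hi))
    return make


def otsu_bruteforce(values, bins=256):
    """Exhaustive between-class-variance maximization over bin-edge thresholds.

    Independent of the package implementation: normalizes, assigns bins,
    and for every interior bin edge computes the class weights and means of
    the actual normalized values directly.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = v.min(), v.max()
    norm = (v - lo) / (hi - lo)
    idx = np.minimum((norm * bins).astype(int), bins - 1)
    best_var, best_k = -np.inf, None
    for k in range(bins - 1):
        in0 = idx <= k
        n0 = in0.sum()
        n1 = v.size - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = norm[in0].mean()
        mu1 = norm[~in0].mean()
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return lo + (best_k + 1) / bins * (hi - lo)


def simplex_grid_search(r, M, step=1e-3):
    """Exhaustive FCLS oracle: minimize ||r - M a||^2 over a simplex grid."""
    r = np.asarray(r, dtype=float)
    M = np.asarray(M, dtype=float)
    p = M.shape[1]
    n = int(round(1.0 / step))
    if p == 2:
        a1 = np.arange(n + 1) / n
        grid = np.column_stack([a1, 1.0 - a1])
    elif p == 3:
        i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
        keep = (i + j) <= n
        a1, a2 = i[keep] / n, j[keep] / n
        grid = np.column_stack([a1, a2, 1.0 - a1 - a2])
    else:
        raise NotImplementedError("oracle supports p in {2, 3}")
    G = M.T @ M
    h = M.T @ r
    # ||r - Ma||^2 = a'Ga - 2h'a + r'r, vectorized over the grid
    obj = np.einsum("ij,jk,ik->i", grid, G, grid) - 2.0 * grid @ h
    best = grid[np.argmin(obj)]
    return best, float(obj.min() + r @ r)
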