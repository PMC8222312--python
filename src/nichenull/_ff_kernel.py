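"""Compiled inner loop for the fixed-fixed (FF) sequential swap chain.

The chain state is a binary species × site matrix.  One attempted swap
picks 2 distinct rows and 2 distinct columns uniformly at random and, if
the 2×2 submatrix is a checkerboard (10/01 or 01/10), flips it to the
other checkerboard; any other submatrix leaves the state unchanged.  Both
row and column totals are conserved exactly, and because the proposal is
symmetric the stationary distribution is uniform over the fixed-marginal
matrix class reachable by swaps.

A pure-NumPy fallback with identical semantics (different random stream)
is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _attempt_swap(mat, r, c):
    i1 = np.random.randint(0, r)
    i2 = np.random.randint(0, r - 1)
    if i2 >= i1:
        i2 += 1
    j1 = np.random.randint(0, c)
    j2 = np.random.randint(0, c - 1)
    if j2 >= j1:
        j2 += 1
    a = mat[i1, j1]
    b = mat[i1, j2]
    cc = mat[i2, j1]
    d = mat[i2, j2]
    if a == d and b == cc and a != b:
        mat[i1, j1] = 1 - a
        mat[i1, j2] = 1 - b
        mat[i2, j1] = 1 - cc
        mat[i2, j2] = 1 - d


@njit(cache=True)
def _cscore_mean(mat, r, c):
    rt = np.zeros(r, dtype=np.int64)
    for j in range(r):
        s = 0
        for i in range(c):
            s += mat[j, i]
        rt[j] = s
    total = 0.0
    npairs = 0
    for j in range(r):
        for k in range(j + 1, r):
            ss = 0
            for i in range(c):
                if mat[j, i] == 1 and mat[k, i] == 1:
                    ss += 1
            total += (rt[j] - ss) * (rt[k] - ss)
            npairs += 1
    return total / npairs


@njit(cache=True)
def ff_chain(mat, n_samples, burn_in, thin, seed):
    """Run the swap chain in place; return the C-score mean at each sample."""
    np.random.seed(seed)
    r, c = mat.shape
    out = np.empty(n_samples)
    for _ in range(burn_in):
        _attempt_swap(mat, r, c)
    for s in range(n_samples):
        for _ in range(thin):
            _attempt_swap(mat, r, c)
        out[s] = _cscore_mean(mat, r, c)
    return out


def ff_chain_python(mat: np.ndarray, n_samples: int, burn_in: int, thin: int, seed: int) -> np.ndarray:
    """Reference/fallback chain, same semantics as :func:`ff_chain`."""
    rng = np.random.default_rng(seed)
    r, c = mat.shape
    out = np.empty(n_samples)

    def attempt() -> None:
        i1 = int(rng.integers(r))
        i2 = int(rng.integers(r - 1))
        if i2 >= i1:
            i2 += 1
        j1 = int(rng.integers(c))
        j2 = int(rng.integers(c - 1))
        if j2 >= j1:
            j2 += 1
        a, b = mat[i1, j1], mat[i1, j2]
        cc, d = mat[i2, j1], mat[i2, j2]
        if a == d and b == cc and a != b:
            mat[i1, j1] = 1 - a
            mat[i1, j2] = 1 - b
            mat[i2, j1] = 1 - cc
            mat[i2, j2] = 1 - d

    bf = None
    for _ in range(burn_in):
        attempt()
    for s in range(n_samples):
        for _ in range(thin):
            attempt()
        bf = mat.astype(float)
        ss = bf @ bf.T
        rt = bf.sum(axis=1)
        cm = (rt[:, None] - ss) * (rt[None, :] - ss)
        iu = np.triu_indices(r, k=1)
        out[s] = cm[iu].mean()
    return out
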