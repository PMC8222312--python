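"""Monte-Carlo null models for niche overlap and co-occurrence statistics.

Two families of randomization are implemented:

* **RA1–RA4** act on a utilization matrix (rows sum to 1) and differ in
  whether entries are *replaced* by fresh uniform draws or *reshuffled*,
  and in whether the observed zero structure is retained:

  - RA1: replace every entry (zeros included) by a uniform(0,1) draw,
    then renormalize each row.  Relaxes both niche breadth and the zero
    structure.
  - RA2: replace only the non-zero entries by uniform(0,1) draws, keep
    zeros in place, renormalize.  Conserves the guild (zero) structure
    but relaxes niche breadth ("random equiprobable specialization").
  - RA3: permute each species row across all site positions.  Conserves
    niche breadth (the row's value multiset) but reshuffles which sites
    are used, destroying the zero structure's placement.
  - RA4: permute only the non-zero entries among the non-zero positions.
    Conserves both niche breadth and the zero structure.

* **FF** (fixed row totals, fixed column totals) acts on a binary
  presence matrix via sequential 2×2 checkerboard swaps, conserving each
  species' incidence and each site's richness exactly.

:func:`run_null` wraps either family: it computes the observed
matrix-wide statistic (mean pairwise Pianka overlap, or mean pairwise
C-score), simulates the null distribution, and reports both tail
probabilities and the one-/two-tailed 95% limits of the simulated
distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _ff_kernel
from .cooccurrence import PresenceMatrix, mean_cscore, to_presence, _pairwise_cscores
from .matrix_io import AbundanceMatrix, MatrixValidationError
from .overlap import UtilizationMatrix, to_utilization, pairwise_overlap_matrix

__all__ = [
    "NullModelResult",
    "as_rng",
    "randomize_ra1",
    "randomize_ra2",
    "randomize_ra3",
    "randomize_ra4",
    "swap_step_ff",
    "sample_ff",
    "count_checkerboard_units",
    "run_null",
    "OVERLAP_ALGORITHMS",
]

log = logging.getLogger(__name__)

OVERLAP_ALGORITHMS = ("RA1", "RA2", "RA3", "RA4")

RandomSource = np.random.Generator


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or generator to a numpy Generator (fresh entropy if None)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class NullModelResult:
    """Observed statistic, its simulated null distribution, and tail tests.

    ``limits`` maps ``"one_tailed"`` to the (5th, 95th) and ``"two_tailed"``
    to the (2.5th, 97.5th) percentiles of the simulated vector (nearest
    order statistics).  ``p_lower`` = P(null ≤ observed), ``p_upper`` =
    P(null ≥ observed); with the default add-one convention both lie in
    (0, 1] and ties count toward both tails.
    """

    statistic_name: str
    observed: float
    observed_variance: float
    simulated: np.ndarray = field(repr=False)
    expected: float
    expected_variance: float
    p_lower: float
    p_upper: float
    limits: dict
    algorithm: str
    iterations: int
    seed: int
    label: str = ""


# ---------------------------------------------------------------- RA family


def _ra1(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    x = rng.random(p.shape)
    return x / x.sum(axis=1, keepdims=True)


def _ra2(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mask = p > 0
    if not mask.any(axis=1).all():
        raise MatrixValidationError("RA2 cannot renormalize an all-zero row")
    x = rng.random(p.shape) * mask
    return x / x.sum(axis=1, keepdims=True)


def _ra3(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(p, axis=1)


def _ra4(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = p.copy()
    for row in out:
        nz = np.flatnonzero(row)
        if len(nz) > 1:
            row[nz] = row[nz[rng.permutation(len(nz))]]
    return out


_RA_FUNCS = {"RA1": _ra1, "RA2": _ra2, "RA3": _ra3, "RA4": _ra4}


def _wrap_ra(name: str):
    fn = _RA_FUNCS[name]

    def randomize(u: UtilizationMatrix, rng: np.random.Generator | int | None) -> UtilizationMatrix:
        return UtilizationMatrix(
            species_ids=list(u.species_ids),
            site_ids=list(u.site_ids),
            p=fn(u.p, as_rng(rng)),
        )

    return randomize


randomize_ra1 = _wrap_ra("RA1")
randomize_ra1.__doc__ = "RA1: replace every entry by a uniform(0,1) draw, renormalize rows."
randomize_ra2 = _wrap_ra("RA2")
randomize_ra2.__doc__ = "RA2: keep zeros, replace non-zero entries by uniform(0,1) draws, renormalize."
randomize_ra3 = _wrap_ra("RA3")
randomize_ra3.__doc__ = "RA3: permute each row across all site positions (niche breadth conserved)."
randomize_ra4 = _wrap_ra("RA4")
randomize_ra4.__doc__ = "RA4: permute non-zero entries among non-zero positions (zeros fixed)."


# ---------------------------------------------------------------- FF family


def swap_step_ff(p: PresenceMatrix, rng: np.random.Generator | int | None) -> PresenceMatrix:
    """One attempted checkerboard swap, in place; returns the same matrix.

    Picks 2 distinct rows and 2 distinct columns uniformly at random; if
    the 2×2 submatrix is a checkerboard it is flipped, otherwise nothing
    changes.  Either way one attempt is counted.
    """
    r, c = p.values.shape
    if r < 2 or c < 2:
        raise MatrixValidationError("FF swap needs a matrix of at least 2×2")
    g = as_rng(rng)
    i1 = int(g.integers(r))
    i2 = int(g.integers(r - 1))
    if i2 >= i1:
        i2 += 1
    j1 = int(g.integers(c))
    j2 = int(g.integers(c - 1))
    if j2 >= j1:
        j2 += 1
    m = p.values
    a, b, cc, d = m[i1, j1], m[i1, j2], m[i2, j1], m[i2, j2]
    if a == d and b == cc and a != b:
        m[i1, j1] = 1 - a
        m[i1, j2] = 1 - b
        m[i2, j1] = 1 - cc
        m[i2, j2] = 1 - d
    return p


def count_checkerboard_units(b: np.ndarray) -> int:
    """Number of swappable 2×2 checkerboard submatrices in a binary matrix."""
    b = np.asarray(b, dtype=int)
    total = 0
    for j in range(b.shape[0]):
        for k in range(j + 1, b.shape[0]):
            only_j = int(((b[j] == 1) & (b[k] == 0)).sum())
            only_k = int(((b[j] == 0) & (b[k] == 1)).sum())
            total += only_j * only_k
    return total


def sample_ff(
    p: PresenceMatrix,
    iterations: int,
    burn_in: int | None = None,
    thin: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample matrix-wide C-scores along the FF swap chain.

    Performs ``burn_in`` attempted swaps (default ``10 * n_rows * n_cols``),
    then records the matrix-wide C-score every ``thin`` attempted swaps
    (default ``n_rows * n_cols``), ``iterations`` times.  The input matrix
    is not modified.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    r, c = p.values.shape
    if r < 2 or c < 2:
        raise MatrixValidationError("FF sampling needs a matrix of at least 2×2")
    if burn_in is None:
        burn_in = 10 * r * c
    if thin is None:
        thin = r * c
    if burn_in < 0 or thin < 0:
        raise ValueError("burn_in and thin must be >= 0")
    if count_checkerboard_units(p.values) == 0:
        warnings.warn(
            "matrix has no checkerboard units: the FF null distribution is a "
            "point mass at the observed C-score",
            stacklevel=2,
        )
    kernel_seed = int(as_rng(rng).integers(2**31))
    work = np.ascontiguousarray(p.values.astype(np.uint8, copy=True))
    if _ff_kernel.HAVE_NUMBA:
        return _ff_kernel.ff_chain(work, iterations, burn_in, thin, kernel_seed)
    return _ff_kernel.ff_chain_python(work, iterations, burn_in, thin, kernel_seed)


# ---------------------------------------------------------------- run_null


def _tail_ps(sim: np.ndarray, obs: float, n: int, method: str) -> tuple[float, float]:
    k_le = int((sim <= obs).sum())
    k_ge = int((sim >= obs).sum())
    if method == "add-one":
        return (1 + k_le) / (n + 1), (1 + k_ge) / (n + 1)
    if method == "raw":
        return k_le / n, k_ge / n
    raise ValueError(f"unknown p_value_method {method!r}")


def _limits(sim: np.ndarray) -> dict:
    lo1, hi1 = np.percentile(sim, [5, 95], method="nearest")
    lo2, hi2 = np.percentile(sim, [2.5, 97.5], method="nearest")
    return {"one_tailed": (float(lo1), float(hi1)), "two_tailed": (float(lo2), float(hi2))}


def run_null(
    observed_matrix: AbundanceMatrix | UtilizationMatrix | PresenceMatrix,
    statistic: str,
    algorithm: str,
    iterations: int = 10_000,
    seed: int | None = None,
    *,
    burn_in: int | None = None,
    thin: int | None = None,
    label: str = "",
    p_value_method: str = "add-one",
) -> NullModelResult:
    """Full Monte-Carlo null-model test of one matrix-wide statistic.

    Compatible pairings: ``statistic="pianka-mean"`` with one of RA1–RA4
    (acting on the utilization matrix), or ``statistic="cscore-mean"``
    with ``"FF"`` (acting on the presence matrix).  Species with no
    occurrences are dropped before analysis (with a logged warning).

    Tail probabilities use the add-one Monte-Carlo convention
    ``(1 + k) / (iterations + 1)`` by default; ``p_value_method="raw"``
    gives the plain proportions.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    seed = int(seed)
    rng = np.random.default_rng(seed)

    if statistic == "pianka-mean":
        if algorithm not in OVERLAP_ALGORITHMS:
            raise ValueError(
                f"statistic 'pianka-mean' requires one of {OVERLAP_ALGORITHMS}, got {algorithm!r}"
            )
        if isinstance(observed_matrix, PresenceMatrix):
            raise ValueError("pianka-mean needs abundances, not a presence matrix")
        u = (
            observed_matrix
            if isinstance(observed_matrix, UtilizationMatrix)
            else to_utilization(observed_matrix, drop_empty=True)
        )
        if u.n_species < 2:
            raise MatrixValidationError("need at least 2 species with positive abundance")
        iu = np.triu_indices(u.n_species, k=1)
        obs_pairs = pairwise_overlap_matrix(u.p)[iu]
        observed = float(obs_pairs.mean())
        observed_variance = float(obs_pairs.var())
        ra = _RA_FUNCS[algorithm]
        sim = np.empty(iterations)
        for i in range(iterations):
            sim[i] = float(pairwise_overlap_matrix(ra(u.p, rng))[iu].mean())
    elif statistic == "cscore-mean":
        if algorithm != "FF":
            raise ValueError("statistic 'cscore-mean' requires algorithm 'FF'")
        pm = (
            observed_matrix
            if isinstance(observed_matrix, PresenceMatrix)
            else to_presence(observed_matrix)
        )
        if pm.empty_species:
            keep = np.flatnonzero(pm.R > 0)
            log.warning("dropping %d never-present species before FF null", pm.n_species - len(keep))
            pm = PresenceMatrix(
                species_ids=[pm.species_ids[i] for i in keep],
                site_ids=list(pm.site_ids),
                values=pm.values[keep, :],
            )
        if pm.n_species < 2:
            raise MatrixValidationError("need at least 2 occurring species")
        obs_pairs = _pairwise_cscores(pm.values)
        observed = float(obs_pairs.mean())
        observed_variance = float(obs_pairs.var())
        sim = sample_ff(pm, iterations, burn_in=burn_in, thin=thin, rng=rng)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    p_lower, p_upper = _tail_ps(sim, observed, iterations, p_value_method)
    return NullModelResult(
        statistic_name=statistic,
        observed=observed,
        observed_variance=observed_variance,
        simulated=sim,
        expected=float(sim.mean()),
        expected_variance=float(sim.var()),
        p_lower=float(p_lower),
        p_upper=float(p_upper),
        limits=_limits(sim),
        algorithm=algorithm,
        iterations=iterations,
        seed=seed,
        label=label,
    )
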