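"""Pianka pairwise niche overlap on species × site utilization matrices.

The Pianka index between species *j* and *k* is

    O_jk = sum_i p_ij p_ik / sqrt(sum_i p_ij^2 * sum_i p_ik^2)

where p_ij is the proportion of species j's total abundance found at
resource state (site) i.  It is symmetric, correlation-like, and ranges
from 0 (disjoint spatial utilization) to 1 (proportional utilization).
The matrix-wide summary is the mean over all unordered species pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import AbundanceMatrix, MatrixValidationError

__all__ = [
    "UtilizationMatrix",
    "OverlapResult",
    "to_utilization",
    "pianka_pair",
    "pairwise_overlap_matrix",
    "overlap_summary",
]

log = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-9


@dataclass
class UtilizationMatrix:
    """Row-normalized proportions p_ij: species rows summing to 1 over sites."""

    species_ids: list[str]
    site_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2:
            raise MatrixValidationError("utilization matrix must be 2-D")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise MatrixValidationError("utilization proportions must lie in [0, 1]")
        sums = self.p.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise MatrixValidationError(
                f"row for species {self.species_ids[bad]!r} sums to {sums[bad]!r}, not 1"
            )

    @property
    def n_species(self) -> int:
        return self.p.shape[0]

    @property
    def n_sites(self) -> int:
        return self.p.shape[1]


@dataclass(frozen=True)
class OverlapResult:
    """All pairwise Pianka values plus their mean and population variance.

    ``pairs`` holds the unordered species-id pairs in the same order as
    ``values`` (condensed upper-triangle order).
    """

    pairs: tuple[tuple[str, str], ...]
    values: np.ndarray
    mean_overlap: float
    var_overlap: float


def to_utilization(m: AbundanceMatrix, drop_empty: bool = False) -> UtilizationMatrix:
    """Convert abundances to utilization proportions by row normalization.

    Species with zero total abundance carry no utilization information:
    with ``drop_empty`` they are removed (with a logged warning), otherwise
    they raise an error.
    """
    totals = m.values.sum(axis=1)
    if not np.any(totals > 0):
        raise MatrixValidationError("no species with positive abundance")
    empty = np.flatnonzero(totals == 0)
    if len(empty):
        if not drop_empty:
            raise MatrixValidationError(
                f"species {m.species_ids[empty[0]]!r} has zero total abundance; "
                "pass drop_empty=True to remove such species"
            )
        log.warning(
            "dropping %d zero-abundance species: %s",
            len(empty),
            [m.species_ids[i] for i in empty],
        )
    keep = np.flatnonzero(totals > 0)
    p = m.values[keep, :] / totals[keep, None]
    return UtilizationMatrix(
        species_ids=[m.species_ids[i] for i in keep],
        site_ids=list(m.site_ids),
        p=p,
    )


def pianka_pair(pj: np.ndarray, pk: np.ndarray) -> float:
    """Pianka overlap between two utilization rows (need not be normalized:
    the index is invariant to positive rescaling of either row)."""
    pj = np.asarray(pj, dtype=float)
    pk = np.asarray(pk, dtype=float)
    if pj.shape != pk.shape or pj.ndim != 1:
        raise ValueError("utilization rows must be 1-D and of equal length")
    sj = float(pj @ pj)
    sk = float(pk @ pk)
    if sj == 0.0 or sk == 0.0:
        raise MatrixValidationError("Pianka index undefined for an all-zero row")
    return float(pj @ pk) / np.sqrt(sj * sk)


def pairwise_overlap_matrix(p: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of Pianka overlaps between the rows of ``p``."""
    p = np.asarray(p, dtype=float)
    num = p @ p.T
    norms = np.einsum("ij,ij->i", p, p)
    if np.any(norms == 0):
        raise MatrixValidationError("Pianka index undefined for an all-zero row")
    o = num / np.sqrt(np.outer(norms, norms))
    return np.clip(o, 0.0, 1.0)


def mean_pairwise_overlap(p: np.ndarray) -> float:
    """Mean Pianka overlap over all unordered row pairs (fast path for nulls)."""
    o = pairwise_overlap_matrix(p)
    r = o.shape[0]
    iu = np.triu_indices(r, k=1)
    return float(o[iu].mean())


def overlap_summary(m: AbundanceMatrix | UtilizationMatrix, drop_empty: bool = True) -> OverlapResult:
    """All-pairs Pianka overlap for a community matrix.

    Accepts an abundance matrix (normalized internally, empty species
    dropped when ``drop_empty``) or an already-normalized utilization
    matrix.  The variance is the population variance of the enumerated
    pairwise values — a descriptive summary of the full set of pairs,
    not a sample estimate.
    """
    u = m if isinstance(m, UtilizationMatrix) else to_utilization(m, drop_empty=drop_empty)
    if u.n_species < 2:
        raise MatrixValidationError("overlap analysis needs at least 2 species with positive abundance")
    o = pairwise_overlap_matrix(u.p)
    iu = np.triu_indices(u.n_species, k=1)
    values = o[iu]
    pairs = tuple(
        (u.species_ids[i], u.species_ids[j]) for i, j in zip(*iu)
    )
    return OverlapResult(
        pairs=pairs,
        values=values,
        mean_overlap=float(values.mean()),
        var_overlap=float(values.var()),  # population convention
    )
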