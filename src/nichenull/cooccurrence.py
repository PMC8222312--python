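"""Checkerboard (C-score) co-occurrence statistic on presence/absence matrices.

For a species pair (j, k) with row totals R_j, R_k and SS shared sites,

    C_jk = (R_j - SS)(R_k - SS)

ranging from 0 (maximally aggregated: one species' sites contain the
other's) to R_j * R_k (maximally segregated: no shared sites).  The
matrix-wide C-score is the mean of C_jk over all unordered pairs; high
values indicate species segregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import AbundanceMatrix, MatrixValidationError

__all__ = [
    "PresenceMatrix",
    "CScoreResult",
    "to_presence",
    "cscore_pair",
    "cscore_summary",
    "mean_cscore",
]

log = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Binary incidence matrix with row totals R (occupied sites per species)
    and column totals C (species richness per site)."""

    species_ids: list[str]
    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise MatrixValidationError("presence matrix must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise MatrixValidationError("presence matrix entries must be 0 or 1")
        self.values = v.astype(np.uint8)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def R(self) -> np.ndarray:
        """Row totals: number of occupied sites per species."""
        return self.values.sum(axis=1).astype(int)

    @property
    def C(self) -> np.ndarray:
        """Column totals: species richness per site."""
        return self.values.sum(axis=0).astype(int)

    @property
    def empty_species(self) -> list[str]:
        return [s for s, r in zip(self.species_ids, self.R) if r == 0]

    def copy(self) -> "PresenceMatrix":
        return PresenceMatrix(
            species_ids=list(self.species_ids),
            site_ids=list(self.site_ids),
            values=self.values.copy(),
        )


@dataclass(frozen=True)
class CScoreResult:
    """Pairwise C-scores with their mean and population variance."""

    pairs: tuple[tuple[str, str], ...]
    values: np.ndarray
    mean_cscore: float
    var_cscore: float


def to_presence(m: AbundanceMatrix, threshold: float = 0.0) -> PresenceMatrix:
    """Binarize an abundance matrix: presence where abundance > threshold.

    The default (0.0) marks any strictly positive abundance as a presence.
    Species never present (R = 0) are retained here; summary functions
    decide whether to keep them.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    b = (m.values > threshold).astype(np.uint8)
    p = PresenceMatrix(
        species_ids=list(m.species_ids), site_ids=list(m.site_ids), values=b
    )
    if p.empty_species:
        log.warning("presence matrix has %d never-present species", len(p.empty_species))
    return p


def cscore_pair(row_j: np.ndarray, row_k: np.ndarray) -> float:
    """C-score for one species pair: (R_j - SS)(R_k - SS)."""
    rj = np.asarray(row_j)
    rk = np.asarray(row_k)
    if rj.shape != rk.shape or rj.ndim != 1:
        raise ValueError("rows must be 1-D and of equal length")
    if not (np.isin(rj, (0, 1)).all() and np.isin(rk, (0, 1)).all()):
        raise MatrixValidationError("C-score rows must be binary")
    Rj = int(rj.sum())
    Rk = int(rk.sum())
    ss = int((rj.astype(int) & rk.astype(int)).sum())
    return float((Rj - ss) * (Rk - ss))


def _pairwise_cscores(b: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise C-scores for a binary matrix."""
    bf = b.astype(float)
    ss = bf @ bf.T
    r = bf.sum(axis=1)
    c = (r[:, None] - ss) * (r[None, :] - ss)
    iu = np.triu_indices(b.shape[0], k=1)
    return c[iu]


def mean_cscore(b: np.ndarray) -> float:
    """Matrix-wide C-score of a binary array (fast path for null chains)."""
    if b.shape[0] < 2:
        raise MatrixValidationError("C-score needs at least 2 species")
    return float(_pairwise_cscores(b).mean())


def cscore_summary(p: PresenceMatrix, drop_empty: bool = True) -> CScoreResult:
    """All-pairs C-score summary of a presence matrix.

    Never-present species (R = 0) are dropped by default — an unobserved
    species carries no co-occurrence information; every pair it forms is
    trivially C = 0.  With ``drop_empty=False`` those zero pairs are kept
    in the mean.  Variance is the population variance of the pairwise
    values, matching the overlap module's convention.
    """
    values_matrix = p.values
    ids = list(p.species_ids)
    if drop_empty and p.empty_species:
        keep = np.flatnonzero(p.R > 0)
        log.warning("dropping %d never-present species before C-score", p.n_species - len(keep))
        values_matrix = p.values[keep, :]
        ids = [p.species_ids[i] for i in keep]
    if values_matrix.shape[0] < 2:
        raise MatrixValidationError("C-score analysis needs at least 2 species")
    values = _pairwise_cscores(values_matrix)
    iu = np.triu_indices(values_matrix.shape[0], k=1)
    pairs = tuple((ids[i], ids[j]) for i, j in zip(*iu))
    return CScoreResult(
        pairs=pairs,
        values=values,
        mean_cscore=float(values.mean()),
        var_cscore=float(values.var()),
    )
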