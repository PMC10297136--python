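"""PCA fusion of the three mutation-rate covariates.

Regional mutational heterogeneity — the variation in background mutation
rate from gene to gene — is strongly associated with three per-gene
covariates: expression level, replication time, and chromosome (open/closed
chromatin) status.  Because the three are themselves strongly correlated,
they are collapsed into a single per-gene weight by principal component
analysis:

1. z-score each covariate column (population convention, 1/n variance);
2. form the 3×3 covariance matrix of the standardized columns (i.e. their
   correlation matrix);
3. take its leading eigenvalue λ and unit eigenvector a = [a1, a2, a3];
4. the raw fused covariate is υ = a1·x′ + a2·y′ + a3·z′.

The raw first-component scores are then affinely rescaled to a positive
band (default [0.5, 1.5], midpoint 1 = neutral) so they can multiply the
per-gene mutation counts in the weighted submatrix objective without
flipping the sign of the exclusivity penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import FusionCovariates, InputError, MutationMatrix

__all__ = [
    "CovariateTable",
    "FusionReport",
    "normalize_covariates",
    "covariance_matrix",
    "leading_eigenpair",
    "fuse_covariates",
    "covariates_for_matrix",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class CovariateTable:
    """Raw per-gene covariates: expression, replication time, chromosome status."""

    gene_ids: tuple[str, ...]
    expression: np.ndarray
    replication_time: np.ndarray
    chromosome_status: np.ndarray

    def __post_init__(self) -> None:
        cols = {}
        for name in ("expression", "replication_time", "chromosome_status"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.ndim != 1:
                raise InputError(f"covariate column {name!r} must be 1-D")
            if not np.isfinite(v).all():
                raise InputError(f"covariate column {name!r} contains non-finite values")
            cols[name] = v
            object.__setattr__(self, name, v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        n = len(self.gene_ids)
        if n < 2:
            raise InputError("covariate table needs at least 2 genes")
        for name, v in cols.items():
            if len(v) != n:
                raise InputError(
                    f"covariate column {name!r} has length {len(v)}, expected {n}"
                )
        if len(set(self.gene_ids)) != n:
            raise InputError("covariate table gene labels are not unique")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def columns(self) -> np.ndarray:
        """The n×3 covariate matrix in fixed column order."""
        return np.column_stack([self.expression, self.replication_time, self.chromosome_status])


@dataclass(frozen=True)
class FusionReport:
    """Diagnostics of the PCA fusion: λ, loadings, raw scores, rescale band."""

    eigenvalue: float
    loadings: np.ndarray  # unit vector [a1, a2, a3]
    raw_fused: np.ndarray
    rescale_bounds: tuple[float, float]


def _zscore(v: np.ndarray) -> np.ndarray:
    mu = v.mean()
    sd = v.std()  # population convention (ddof=0)
    if sd == 0.0:
        return np.zeros_like(v)
    return (v - mu) / sd


def normalize_covariates(table: CovariateTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score each covariate column; a constant column maps to all-zeros."""
    return (
        _zscore(table.expression),
        _zscore(table.replication_time),
        _zscore(table.chromosome_status),
    )


def covariance_matrix(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """3×3 covariance (1/n) of the three columns.

    With z-scored inputs this is their correlation matrix, up to
    zero-variance columns which contribute zero rows/columns.
    """
    v = np.vstack([x, y, z])
    n = v.shape[1]
    return (v @ v.T) / n - np.outer(v.mean(axis=1), v.mean(axis=1))


def leading_eigenpair(cov: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and its unit eigenvector, deterministically.

    Sign convention: component sum > 0 (first nonzero component positive if
    the sum vanishes).  Degenerate top eigenspace (multiplicity > 1): the
    returned vector is the normalized projection of the first standard basis
    vector with nonzero projection onto that eigenspace, so e.g. the
    identity matrix yields (1, 0, 0).
    """
    cov = np.asarray(cov, dtype=np.float64)
    if cov.shape != (cov.shape[0], cov.shape[0]):
        raise InputError(f"covariance matrix must be square; got shape {cov.shape}")
    if np.abs(cov - cov.T).max() > _SYM_TOL:
        raise InputError("covariance matrix is not symmetric")
    cov = (cov + cov.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam = float(eigvals[-1])
    top = eigvals > lam - 1e-9
    if top.sum() > 1:
        # degenerate leading eigenspace: project standard basis vectors
        basis = eigvecs[:, top]  # d × r orthonormal
        vec = None
        for i in range(cov.shape[0]):
            proj = basis @ basis[i, :]
            norm = np.linalg.norm(proj)
            if norm > 1e-12:
                vec = proj / norm
                break
        assert vec is not None  # an orthonormal basis has a nonzero row
    else:
        vec = eigvecs[:, -1]
    s = vec.sum()
    if s < 0:
        vec = -vec
    elif abs(s) < 1e-12:
        first = vec[np.abs(vec) > 1e-12]
        if first.size and first[0] < 0:
            vec = -vec
    return lam, vec


def fuse_covariates(
    table: CovariateTable, *, bounds: tuple[float, float] = (0.5, 1.5)
) -> tuple[FusionCovariates, FusionReport]:
    """Fuse the three covariates into one positive per-gene weight vector.

    Returns the rescaled weights (order matching ``table.gene_ids``) and a
    report with the eigenvalue, loadings and raw first-component scores.
    A degenerate table whose raw scores are constant yields all-ones
    (neutral) weights.
    """
    low, high = bounds
    if not (0.0 < low < high):
        raise InputError(f"rescale bounds must satisfy 0 < low < high; got {bounds}")
    xp, yp, zp = normalize_covariates(table)
    cov = covariance_matrix(xp, yp, zp)
    lam, a = leading_eigenpair(cov)
    raw = a[0] * xp + a[1] * yp + a[2] * zp
    span = raw.max() - raw.min()
    if span < 1e-12:
        values = np.ones(table.n)
    else:
        values = low + (raw - raw.min()) * (high - low) / span
    report = FusionReport(eigenvalue=lam, loadings=a, raw_fused=raw, rescale_bounds=(low, high))
    return FusionCovariates(values), report


def covariates_for_matrix(
    table: CovariateTable | None,
    matrix: MutationMatrix,
    *,
    bounds: tuple[float, float] = (0.5, 1.5),
) -> FusionCovariates:
    """Fused weights aligned to the matrix gene order.

    Genes in the matrix but absent from the table receive the neutral
    weight 1.0 (with a warning); table genes absent from the matrix are
    ignored.  ``table=None`` returns all-neutral weights, the convention
    used for simulated matrices whose genes carry no covariate meaning.
    """
    if table is None:
        return FusionCovariates.neutral(matrix.n)
    fused, _ = fuse_covariates(table, bounds=bounds)
    by_label = dict(zip(table.gene_ids, fused.values))
    values = np.ones(matrix.n)
    missing = []
    for j, gene in enumerate(matrix.gene_ids):
        if gene in by_label:
            values[j] = by_label[gene]
        else:
            missing.append(gene)
    if missing:
        logger.warning(
            "%d matrix genes missing from covariate table; neutral weight 1.0 used (e.g. %s)",
            len(missing),
            ", ".join(missing[:5]),
        )
    extra = len(set(table.gene_ids) - set(matrix.gene_ids))
    if extra:
        logger.info("%d covariate-table genes not in the matrix were ignored", extra)
    return FusionCovariates(values)
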