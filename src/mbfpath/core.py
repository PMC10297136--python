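"""Mutation-matrix data model and gene-set scoring.

The central object is a binary patient × gene incidence matrix ``A`` where
``A[i, j] = 1`` means gene *j* carries a somatic mutation in patient *i*.
A candidate driver pathway is a fixed-size set ``M`` of gene columns scored
by the maximum-weight-submatrix objective

    W(M) = |Γ(M)| − ω(M) = 2·|Γ(M)| − Σ_{j∈M} |Γ(j)|

where ``Γ(j)`` is the set of patients mutated in gene *j* and
``Γ(M) = ∪_{j∈M} Γ(j)``.  ``|Γ(M)|`` rewards coverage; ``ω(M)`` penalizes
overlap between the genes' patient supports, so a high score requires both
high coverage and near-mutual-exclusivity.  The covariate-weighted variant
replaces each per-gene count by ``v_j·|Γ(j)|`` with a positive per-gene
weight ``v_j`` that encodes regional mutation-rate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "InputError",
    "MutationMatrix",
    "GeneSet",
    "FusionCovariates",
    "PathwayResult",
    "patient_support",
    "weight",
    "weighted_objective",
    "coverage_fraction",
    "mutex_degree",
    "accuracy_vs_reference",
]


class InputError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise InputError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class MutationMatrix:
    """Binary m × n patient-by-gene incidence matrix with row/column labels.

    Parameters
    ----------
    entries
        Array of shape ``(m, n)`` containing only 0/1 values.  Stored as
        ``uint8`` internally.
    patient_ids
        ``m`` unique patient labels (rows).
    gene_ids
        ``n`` unique gene labels (columns).
    """

    entries: np.ndarray
    patient_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InputError(f"matrix must be 2-D with m ≥ 1, n ≥ 1; got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise InputError(
                f"matrix entries must be 0 or 1; found {arr[tuple(bad)]!r} at "
                f"(row {bad[0]}, column {bad[1]})"
            )
        object.__setattr__(self, "entries", np.ascontiguousarray(arr, dtype=np.uint8))
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.patient_ids) != arr.shape[0]:
            raise InputError(
                f"{len(self.patient_ids)} patient labels for {arr.shape[0]} rows"
            )
        if len(self.gene_ids) != arr.shape[1]:
            raise InputError(f"{len(self.gene_ids)} gene labels for {arr.shape[1]} columns")
        _check_unique(self.patient_ids, "patient")
        _check_unique(self.gene_ids, "gene")

    @property
    def m(self) -> int:
        """Number of patients (rows)."""
        return self.entries.shape[0]

    @property
    def n(self) -> int:
        """Number of genes (columns)."""
        return self.entries.shape[1]

    def column_counts(self) -> np.ndarray:
        """Per-gene mutation counts |Γ(j)| as a length-n int array."""
        return self.entries.sum(axis=0, dtype=np.int64)

    def gene_index(self, label: str) -> int:
        try:
            return self.gene_ids.index(label)
        except ValueError:
            raise InputError(f"unknown gene label: {label!r}") from None


@dataclass(frozen=True)
class GeneSet:
    """A fixed-cardinality set of gene column indices (0-based, ascending).

    Equivalent to the binary indicator vector ``y`` with ``Σ_j y_j = k``.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise InputError(f"gene indices contain duplicates: {idx}")
        if any(i < 0 for i in idx):
            raise InputError(f"gene indices must be non-negative: {idx}")
        object.__setattr__(self, "indices", tuple(sorted(idx)))

    @property
    def k(self) -> int:
        return len(self.indices)

    def labels(self, gene_ids: Sequence[str]) -> tuple[str, ...]:
        return tuple(gene_ids[i] for i in self.indices)

    def to_vector(self, n: int) -> np.ndarray:
        """Indicator vector y of length n with Σ y_j = k."""
        y = np.zeros(n, dtype=np.uint8)
        y[list(self.indices)] = 1
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "GeneSet":
        return cls(tuple(np.flatnonzero(y)))


@dataclass(frozen=True)
class FusionCovariates:
    """Length-n vector of strictly positive per-gene weights v_j."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1:
            raise InputError("covariate weights must be a 1-D vector")
        if not np.isfinite(vals).all():
            raise InputError("covariate weights must be finite")
        if (vals <= 0).any():
            j = int(np.argmax(vals <= 0))
            raise InputError(f"covariate weight for gene index {j} is not strictly positive")
        object.__setattr__(self, "values", vals)

    @classmethod
    def neutral(cls, n: int) -> "FusionCovariates":
        """All-ones weights: the objective reduces to the unweighted W(M)."""
        return cls(np.ones(n))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PathwayResult:
    """One identified pathway: gene set plus its scores and provenance."""

    gene_set: GeneSet
    weight: float
    coverage: float
    mutex_degree: float
    k: int
    seed: int
    p_value: Optional[float] = None

    def with_p_value(self, p: float) -> "PathwayResult":
        return replace(self, p_value=float(p))


def _validated_indices(matrix: MutationMatrix, genes: GeneSet) -> list[int]:
    for i in genes.indices:
        if i >= matrix.n:
            raise InputError(f"gene index {i} out of range for n={matrix.n}")
    return list(genes.indices)


def _mutation_counts(matrix: MutationMatrix, genes: GeneSet) -> np.ndarray:
    """Per-patient number of mutated genes within the set (length m)."""
    idx = _validated_indices(matrix, genes)
    if not idx:
        return np.zeros(matrix.m, dtype=np.int64)
    return matrix.entries[:, idx].sum(axis=1, dtype=np.int64)


def patient_support(matrix: MutationMatrix, genes: GeneSet) -> set[int]:
    """Γ(M): the set of patients with ≥1 mutation among the genes in M."""
    counts = _mutation_counts(matrix, genes)
    return set(np.flatnonzero(counts > 0).tolist())


def weight(matrix: MutationMatrix, genes: GeneSet) -> int:
    """Unweighted objective W(M) = 2·|Γ(M)| − Σ_{j∈M} |Γ(j)|."""
    idx = _validated_indices(matrix, genes)
    counts = _mutation_counts(matrix, genes)
    covered = int((counts > 0).sum())
    total = int(counts.sum())  # Σ_j |Γ(j)| restricted to M
    return 2 * covered - total


def weighted_objective(
    matrix: MutationMatrix, genes: GeneSet, covariates: FusionCovariates
) -> float:
    """Covariate-weighted objective 2·|Γ(M)| − Σ_{j∈M} v_j·|Γ(j)|.

    Equals the integer-program objective max_x 2·Σ x_i − Σ_j y_j v_j |Γ(j)|
    subject to x_i ≤ [patient i covered], at the maximizing assignment of x.
    """
    if len(covariates) != matrix.n:
        raise InputError(
            f"covariate length {len(covariates)} does not match n={matrix.n}"
        )
    idx = _validated_indices(matrix, genes)
    counts = _mutation_counts(matrix, genes)
    covered = int((counts > 0).sum())
    col_counts = matrix.entries[:, idx].sum(axis=0, dtype=np.int64) if idx else np.zeros(0)
    penalty = float((covariates.values[idx] * col_counts).sum()) if idx else 0.0
    return 2.0 * covered - penalty


def coverage_fraction(matrix: MutationMatrix, genes: GeneSet) -> float:
    """|Γ(M)| / m — fraction of patients with at least one mutation in M."""
    counts = _mutation_counts(matrix, genes)
    return float((counts > 0).sum()) / matrix.m


def mutex_degree(
    matrix: MutationMatrix, genes: GeneSet, *, covered_only: bool = False
) -> float:
    """Fraction of patients with *exactly one* mutated gene in M.

    The denominator is all m patients by default; set ``covered_only=True``
    to divide by |Γ(M)| instead (the strictly-within-pathway variant).
    """
    counts = _mutation_counts(matrix, genes)
    exclusive = int((counts == 1).sum())
    if covered_only:
        covered = int((counts > 0).sum())
        return exclusive / covered if covered else 0.0
    return exclusive / matrix.m


def accuracy_vs_reference(
    genes: GeneSet,
    reference: Iterable[str],
    gene_ids: Sequence[str],
    *,
    case_insensitive: bool = False,
) -> float:
    """Fraction of the identified genes present in a reference driver list."""
    ref = set(reference)
    if not ref:
        raise InputError("reference gene list is empty")
    if case_insensitive:
        ref = {r.upper() for r in ref}
    if genes.k == 0:
        raise InputError("gene set is empty")
    hits = 0
    for i in genes.indices:
        lab = gene_ids[i]
        if case_insensitive:
            lab = lab.upper()
        if lab in ref:
            hits += 1
    return hits / genes.k
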