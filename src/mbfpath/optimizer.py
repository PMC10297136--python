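"""Mouth Brooding Fish (MBF) metaheuristic over fixed-size gene sets.

The search space is the set of binary vectors y with Σ_j y_j = k (all
k-subsets of the n genes); the fitness is the covariate-weighted
maximum-weight-submatrix objective.  Each "cichlid" carries a continuous
position in [0,1]^n which is decoded to a gene set by taking the k largest
coordinates (ties to the lowest gene index), so every candidate satisfies
the cardinality constraint by construction.

One iteration mimics a brood of fry around the mother fish:

* attraction — every non-best fish moves toward the incumbent best
  position by ``sp·u∘(best − self)``, with u uniform per coordinate; the
  mother-influence factor ``sp`` is damped each iteration by ``sp_damp``;
* dispersal — with probability ``p_dis`` a fish has ⌈dis⌉ of its
  coordinates perturbed by uniform noise of half-width ``dis / n_span``,
  maintaining exploration as the brood contracts.

At the end of each run the incumbent is polished by a deterministic
steepest-ascent single-gene-swap hill climb, which realizes the improving
one-gene exchanges that are hard for the continuous encoding to express
(they require two coordinates to cross the top-k threshold jointly).

Positions are clamped to [0,1].  The incumbent best never worsens, and the
whole procedure is deterministic for a fixed seed.  ``exhaustive_search``
provides a brute-force oracle for small instances, and ``multi_k_scan``
runs independent optimizations over a range of pathway sizes k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import (
    FusionCovariates,
    GeneSet,
    InputError,
    MutationMatrix,
    PathwayResult,
    coverage_fraction,
    mutex_degree,
    weighted_objective,
)

__all__ = [
    "MBFParams",
    "Cichlid",
    "decode_position",
    "initialize_population",
    "mbf_step",
    "optimize",
    "exhaustive_search",
    "multi_k_scan",
    "ScanResult",
]

EXHAUSTIVE_GUARD = 1_000_000


@dataclass(frozen=True)
class MBFParams:
    """Parameters of the MBF search.

    ``sp`` (mother-position influence 0.6), ``n_fish`` (50), ``dis``
    (dispersal distance 1.8), ``p_dis`` (dispersal probability 0.2) and
    ``sp_damp`` (per-iteration damping 0.95) are the algorithm's five named
    behavioural parameters.  ``n_span`` scales ``dis`` into coordinate
    units: the dispersal noise half-width is ``dis / n_span``, and the
    default 2.0 makes it 0.9 — wide enough that one dispersal event can
    re-rank any coordinate of the unit cube.  ``max_iter``/``stagnation``
    bound a single run, and ``restarts`` independent runs are pooled.
    """

    sp: float = 0.6
    n_fish: int = 50
    dis: float = 1.8
    p_dis: float = 0.2
    sp_damp: float = 0.95
    max_iter: int = 200
    stagnation: int = 50
    restarts: int = 3
    n_span: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sp <= 0:
            raise InputError("sp must be > 0")
        if not (0.0 <= self.p_dis <= 1.0):
            raise InputError("p_dis must be in [0, 1]")
        if not (0.0 < self.sp_damp <= 1.0):
            raise InputError("sp_damp must be in (0, 1]")
        if self.n_fish < 2:
            raise InputError("n_fish must be ≥ 2")
        if self.max_iter < 1:
            raise InputError("max_iter must be ≥ 1")
        if self.restarts < 1:
            raise InputError("restarts must be ≥ 1")
        if self.n_span <= 0:
            raise InputError("n_span must be > 0")


@dataclass
class Cichlid:
    """One candidate: continuous position, decoded gene set, fitness."""

    position: np.ndarray
    decoded: GeneSet
    fitness: float


def decode_position(position: np.ndarray, k: int) -> GeneSet:
    """Top-k decode: indices of the k largest coordinates, ties → lowest index."""
    position = np.asarray(position, dtype=np.float64)
    n = position.shape[-1]
    if k > n:
        raise InputError(f"k={k} exceeds number of genes n={n}")
    idx = _decode_batch(position[None, :], k)[0]
    return GeneSet(tuple(int(i) for i in idx))


def _decode_batch(positions: np.ndarray, k: int) -> np.ndarray:
    # stable sort on -position: ties keep original (lowest-index-first) order
    order = np.argsort(-positions, axis=1, kind="stable")[:, :k]
    order.sort(axis=1)
    return order


class _Evaluator:
    """Vectorized fitness of a decoded population on one fixed instance."""

    def __init__(self, matrix: MutationMatrix, covariates: FusionCovariates):
        if len(covariates) != matrix.n:
            raise InputError(
                f"covariate length {len(covariates)} does not match n={matrix.n}"
            )
        self.genes_by_patients = np.ascontiguousarray(matrix.entries.T.astype(bool))
        self.patients_by_genes = matrix.entries.astype(np.int64)
        self.col_weighted = covariates.values * matrix.column_counts()

    def fitness(self, decoded: np.ndarray) -> np.ndarray:
        sub = self.genes_by_patients[decoded]  # (n_fish, k, m)
        covered = sub.any(axis=1).sum(axis=1)
        return 2.0 * covered - self.col_weighted[decoded].sum(axis=1)

    def polish(self, genes: Sequence[int]) -> tuple[tuple[int, ...], float]:
        """Steepest-ascent single-gene-swap hill climb to a local optimum.

        Realizes the improving one-gene exchanges that the continuous top-k
        encoding struggles to express (they require two coordinates to move
        in a coordinated way).  Deterministic: the best improving swap is
        taken each pass, ties to the lowest (g_out, g_in) index pair.
        """
        E = self.patients_by_genes
        cw = self.col_weighted
        current = list(genes)
        counts = E[:, current].sum(axis=1)
        penalty = cw[current].sum()
        fit = 2.0 * (counts > 0).sum() - penalty
        in_set = np.zeros(E.shape[1], dtype=bool)
        in_set[current] = True
        while True:
            best_fit, best_move = fit, None
            for pos, g_out in enumerate(current):
                c_minus = counts - E[:, g_out]
                cov_new = ((c_minus[:, None] + E) > 0).sum(axis=0)
                fit_new = 2.0 * cov_new - (penalty - cw[g_out] + cw)
                fit_new[in_set] = -np.inf
                g_in = int(np.argmax(fit_new))
                if fit_new[g_in] > best_fit:
                    best_fit, best_move = float(fit_new[g_in]), (pos, g_in)
            if best_move is None:
                return tuple(sorted(current)), float(fit)
            pos, g_in = best_move
            g_out = current[pos]
            counts += E[:, g_in] - E[:, g_out]
            penalty += cw[g_in] - cw[g_out]
            in_set[g_out] = False
            in_set[g_in] = True
            current[pos] = g_in
            fit = best_fit


def initialize_population(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    k: int,
    params: MBFParams,
    rng: np.random.Generator,
) -> list[Cichlid]:
    """Uniform random positions on [0,1]^n, decoded and evaluated."""
    if k > matrix.n:
        raise InputError(f"k={k} exceeds number of genes n={matrix.n}")
    ev = _Evaluator(matrix, covariates)
    positions = rng.random((params.n_fish, matrix.n))
    decoded = _decode_batch(positions, k)
    fit = ev.fitness(decoded)
    return [
        Cichlid(positions[i].copy(), GeneSet(tuple(int(j) for j in decoded[i])), float(fit[i]))
        for i in range(params.n_fish)
    ]


def _step_arrays(
    positions: np.ndarray,
    fitness: np.ndarray,
    best_position: np.ndarray,
    best_fitness: float,
    sp_current: float,
    k: int,
    params: MBFParams,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """One MBF iteration on raw arrays; returns updated state and sp."""
    n_fish, n = positions.shape
    # attraction toward the incumbent; the current top fish (the mother)
    # holds its position
    mother = int(np.argmax(fitness))
    u = rng.random((n_fish, n))
    moved = positions + sp_current * u * (best_position[None, :] - positions)
    moved[mother] = positions[mother]
    # dispersal: perturb ⌈dis⌉ random coordinates of selected fish
    n_coords = min(n, int(math.ceil(params.dis)))
    half_width = params.dis / params.n_span
    flags = rng.random(n_fish) < params.p_dis
    for i in np.flatnonzero(flags):
        coords = rng.choice(n, size=n_coords, replace=False)
        moved[i, coords] += rng.uniform(-half_width, half_width, size=n_coords)
    np.clip(moved, 0.0, 1.0, out=moved)
    decoded = _decode_batch(moved, k)
    fit = evaluator.fitness(decoded)
    top = int(np.argmax(fit))
    if fit[top] > best_fitness:
        best_fitness = float(fit[top])
        best_position = moved[top].copy()
    return moved, fit, decoded, best_position, best_fitness, sp_current * params.sp_damp


def mbf_step(
    population: list[Cichlid],
    best: Cichlid,
    sp_current: float,
    params: MBFParams,
    rng: np.random.Generator,
    matrix: MutationMatrix,
    covariates: FusionCovariates,
) -> tuple[list[Cichlid], Cichlid, float]:
    """One iteration over a Cichlid population; incumbent never worsens."""
    if not population:
        raise InputError("population is empty")
    k = best.decoded.k
    ev = _Evaluator(matrix, covariates)
    positions = np.vstack([c.position for c in population])
    fitness = np.array([c.fitness for c in population])
    moved, fit, decoded, best_pos, best_fit, sp_next = _step_arrays(
        positions, fitness, best.position, best.fitness, sp_current, k, params, rng, ev
    )
    new_pop = [
        Cichlid(moved[i].copy(), GeneSet(tuple(int(j) for j in decoded[i])), float(fit[i]))
        for i in range(len(population))
    ]
    new_best = Cichlid(best_pos.copy(), decode_position(best_pos, k), best_fit)
    return new_pop, new_best, sp_next


def _run_single(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    k: int,
    params: MBFParams,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One restart; returns (best fitness, best position, final decoded, final fitness)."""
    positions = rng.random((params.n_fish, matrix.n))
    decoded = _decode_batch(positions, k)
    fitness = evaluator.fitness(decoded)
    top = int(np.argmax(fitness))
    best_fit = float(fitness[top])
    best_pos = positions[top].copy()
    sp = params.sp
    since_improve = 0
    for _ in range(params.max_iter):
        prev_best = best_fit
        positions, fitness, decoded, best_pos, best_fit, sp = _step_arrays(
            positions, fitness, best_pos, best_fit, sp, k, params, rng, evaluator
        )
        if best_fit > prev_best:
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= params.stagnation:
                break
    # memetic polish: improving single-gene swaps from the incumbent
    best_genes = tuple(int(i) for i in _decode_batch(best_pos[None, :], k)[0])
    polished, polished_fit = evaluator.polish(best_genes)
    if polished_fit > best_fit:
        best_fit = polished_fit
        best_pos = np.zeros(matrix.n)
        best_pos[list(polished)] = 1.0
    return best_fit, best_pos, decoded, fitness


def _make_result(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    genes: GeneSet,
    seed: int,
) -> PathwayResult:
    return PathwayResult(
        gene_set=genes,
        weight=weighted_objective(matrix, genes, covariates),
        coverage=coverage_fraction(matrix, genes),
        mutex_degree=mutex_degree(matrix, genes),
        k=genes.k,
        seed=seed,
    )


def optimize(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    k: int,
    params: MBFParams,
    *,
    return_candidates: bool = False,
):
    """Maximize the weighted objective over k-subsets with the MBF search.

    Pools ``params.restarts`` independent runs (seeded from ``params.seed``)
    and returns the best :class:`PathwayResult`.  With
    ``return_candidates=True`` also returns the deduplicated final
    candidate gene sets of all restarts, ranked by fitness (descending,
    ties by gene indices) — the list the significance fallback walks.
    """
    if matrix.n < 1 or matrix.m < 1:
        raise InputError("matrix must be non-empty")
    if k < 1 or k > matrix.n:
        raise InputError(f"k must satisfy 1 ≤ k ≤ n={matrix.n}; got {k}")
    ev = _Evaluator(matrix, covariates)
    pool: dict[tuple[int, ...], float] = {}
    for r in range(params.restarts):
        rng = np.random.default_rng([params.seed, r])
        fit_r, pos_r, decoded_r, fitness_r = _run_single(
            matrix, covariates, k, params, rng, ev
        )
        genes_r = tuple(int(i) for i in _decode_batch(pos_r[None, :], k)[0])
        candidates = [genes_r] + [tuple(int(j) for j in row) for row in decoded_r]
        fits = [fit_r] + list(map(float, fitness_r))
        for g, f in zip(candidates, fits):
            if g not in pool or f > pool[g]:
                pool[g] = f
    # rank by fitness (descending), ties lexicographic; the best result is
    # the head of the same ranking so both views always agree
    ranked_keys = sorted(pool, key=lambda g: (-pool[g], g))
    result = _make_result(matrix, covariates, GeneSet(ranked_keys[0]), params.seed)
    if not return_candidates:
        return result
    ranked = [_make_result(matrix, covariates, GeneSet(g), params.seed) for g in ranked_keys]
    return result, ranked


def exhaustive_search(
    matrix: MutationMatrix, covariates: FusionCovariates, k: int
) -> tuple[GeneSet, float]:
    """Global optimum over all k-subsets by enumeration (oracle).

    Refuses instances with more than 10^6 subsets.  Ties are broken
    lexicographically on the sorted index tuple (combinations are visited
    in lexicographic order; strictly-better replaces).
    """
    if k < 1 or k > matrix.n:
        raise InputError(f"k must satisfy 1 ≤ k ≤ n={matrix.n}; got {k}")
    n_subsets = math.comb(matrix.n, k)
    if n_subsets > EXHAUSTIVE_GUARD:
        raise InputError(
            f"C({matrix.n},{k}) = {n_subsets} subsets exceeds the exhaustive-search "
            f"guard of {EXHAUSTIVE_GUARD}"
        )
    if len(covariates) != matrix.n:
        raise InputError(
            f"covariate length {len(covariates)} does not match n={matrix.n}"
        )
    genes_by_patients = matrix.entries.T.astype(bool)
    col_weighted = covariates.values * matrix.column_counts()
    best_val = -np.inf
    best: Optional[tuple[int, ...]] = None
    for combo in combinations(range(matrix.n), k):
        idx = list(combo)
        covered = int(genes_by_patients[idx].any(axis=0).sum())
        val = 2.0 * covered - float(col_weighted[idx].sum())
        if val > best_val:
            best_val = val
            best = combo
    assert best is not None
    return GeneSet(best), float(best_val)


@dataclass(frozen=True)
class ScanResult:
    """Per-k pathway results plus the union of all identified driver genes."""

    results: tuple[PathwayResult, ...]
    driver_genes: GeneSet


def multi_k_scan(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    k_range: Sequence[int],
    params: MBFParams,
) -> ScanResult:
    """Independent MBF optimizations for each k (seed offset by k)."""
    if not k_range:
        raise InputError("k_range is empty")
    results = []
    union: set[int] = set()
    for k in k_range:
        res = optimize(matrix, covariates, k, replace(params, seed=params.seed + k))
        results.append(res)
        union.update(res.gene_set.indices)
    return ScanResult(tuple(results), GeneSet(tuple(sorted(union))))
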