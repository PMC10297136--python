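"""Permutation significance test for identified pathways.

The null model permutes each gene column independently across patients:
per-gene mutation frequencies — the quantity the covariates model — are
preserved exactly, while any coverage/exclusivity structure between genes
is destroyed.  The null statistic is the *re-optimized* maximum weight on
each permuted matrix (at a reduced optimizer budget), which accounts for
the selection effect of having searched for the best set on the observed
data; a fixed-set variant that re-scores the observed genes on permuted
data is available as a config switch.

p-values use the plus-one estimator p = (1 + #{null ≥ observed}) / (B + 1),
so they are never exactly zero.  When the top-ranked pathway fails the
α = 0.05 threshold, candidates are tested in decreasing fitness order and
the first significant one is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    FusionCovariates,
    InputError,
    MutationMatrix,
    PathwayResult,
    weighted_objective,
)
from .optimizer import MBFParams, optimize

__all__ = [
    "PermutationConfig",
    "permute_matrix",
    "permutation_test",
    "select_significant_pathway",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation test.

    ``budget_factor`` scales the optimizer's ``max_iter`` for the per-
    permutation re-optimization (a single restart is used there; the null
    optimum needs far less polish than the headline search).
    ``null_statistic`` is ``"reoptimized"`` (default) or ``"fixed-set"``.
    """

    n_permutations: int = 100
    alpha: float = 0.05
    budget_factor: float = 0.5
    seed: int = 0
    null_statistic: str = "reoptimized"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InputError("n_permutations must be ≥ 1")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")
        if not (0.0 < self.budget_factor <= 1.0):
            raise InputError("budget_factor must be in (0, 1]")
        if self.null_statistic not in ("reoptimized", "fixed-set"):
            raise InputError(
                f"null_statistic must be 'reoptimized' or 'fixed-set'; got {self.null_statistic!r}"
            )


def permute_matrix(matrix: MutationMatrix, rng: np.random.Generator) -> MutationMatrix:
    """Independently permute each gene column across patients.

    Column sums (per-gene mutation counts) are preserved exactly; row sums
    generally are not.
    """
    permuted = rng.permuted(matrix.entries, axis=0)
    return MutationMatrix(permuted, matrix.patient_ids, matrix.gene_ids)


def _reduced_params(params: MBFParams, config: PermutationConfig, seed: int) -> MBFParams:
    return replace(
        params,
        max_iter=max(1, round(params.max_iter * config.budget_factor)),
        restarts=1,
        seed=seed,
    )


def permutation_test(
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    result: PathwayResult,
    config: PermutationConfig,
    params: MBFParams,
) -> float:
    """Plus-one permutation p-value for the pathway's weight."""
    observed = result.weight
    count = 0
    for b in range(config.n_permutations):
        rng = np.random.default_rng([config.seed, b])
        permuted = permute_matrix(matrix, rng)
        if config.null_statistic == "fixed-set":
            null_stat = weighted_objective(permuted, result.gene_set, covariates)
        else:
            perm_seed = (config.seed * 1_000_003 + b + 1) % _SEED_MOD
            null = optimize(
                permuted, covariates, result.k, _reduced_params(params, config, perm_seed)
            )
            null_stat = null.weight
        if null_stat >= observed:
            count += 1
    return (1 + count) / (config.n_permutations + 1)


def select_significant_pathway(
    ranked: Sequence[PathwayResult],
    matrix: MutationMatrix,
    covariates: FusionCovariates,
    config: PermutationConfig,
    params: MBFParams,
) -> Optional[PathwayResult]:
    """Walk the ranked candidate list; return the first significant pathway.

    Candidates are tested in decreasing-fitness order and the first with
    p ≤ α is returned with its p-value attached; ``None`` if the list is
    exhausted (all tested p-values are logged).
    """
    if not ranked:
        raise InputError("ranked candidate list is empty")
    for rank, cand in enumerate(ranked):
        p = permutation_test(matrix, covariates, cand, config, params)
        if p <= config.alpha:
            if rank > 0:
                logger.info(
                    "top %d candidate(s) not significant; reporting rank %d (p=%.4g)",
                    rank,
                    rank + 1,
                    p,
                )
            return cand.with_p_value(p)
        logger.info(
            "candidate rank %d (weight %.4g) not significant: p=%.4g > α=%.3g",
            rank + 1,
            cand.weight,
            p,
            config.alpha,
        )
    logger.warning("no candidate pathway reached significance α=%.3g", config.alpha)
    return None
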