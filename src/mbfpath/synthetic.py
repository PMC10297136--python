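"""Synthetic mutation matrices and covariate tables.

Generators for the statistical structure the method assumes: i.i.d.
Bernoulli background matrices, matrices with a planted high-coverage /
high-exclusivity gene set, and three mutually correlated per-gene
covariates drawn from a shared latent factor.  Defaults are desk-scale
(hundreds of patients, around a hundred genes) so full pipelines run in
seconds; the generators accept arbitrary sizes.

All generators are deterministic for a fixed seed and produce the same
labelled objects the TSV readers produce, so synthetic fixtures exercise
the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GeneSet, InputError, MutationMatrix
from .fusion import CovariateTable

__all__ = [
    "PlantedScenario",
    "random_matrix",
    "planted_matrix",
    "correlated_covariates",
]


def _labels(prefix: str, count: int) -> tuple[str, ...]:
    width = max(3, len(str(count - 1)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(count))


def random_matrix(m: int, n: int, rate: float, seed: int) -> MutationMatrix:
    """i.i.d. Bernoulli(rate) binary matrix with P###/G### labels."""
    if m < 1 or n < 1:
        raise InputError(f"m and n must be ≥ 1; got m={m}, n={n}")
    if not (0.0 <= rate <= 1.0):
        raise InputError(f"rate must be in [0, 1]; got {rate}")
    rng = np.random.default_rng(seed)
    entries = (rng.random((m, n)) < rate).astype(np.uint8)
    return MutationMatrix(entries, _labels("P", m), _labels("G", n))


@dataclass(frozen=True)
class PlantedScenario:
    """Parameters of a planted-pathway mutation matrix.

    A random ``k_planted``-gene set is embedded so that each patient is
    covered by it with probability ``coverage``; a covered patient carries
    exactly one planted mutation (uniformly chosen) with probability
    ``1 − co_mutation_rate`` and two distinct planted mutations otherwise.
    All remaining (passenger) columns are i.i.d. Bernoulli(background_rate).
    """

    m: int = 200
    n: int = 100
    k_planted: int = 4
    coverage: float = 0.8
    co_mutation_rate: float = 0.05
    background_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise InputError("m and n must be ≥ 1")
        if not (0.0 <= self.coverage <= 1.0):
            raise InputError("coverage must be in [0, 1]")
        if not (0.0 <= self.co_mutation_rate <= 1.0):
            raise InputError("co_mutation_rate must be in [0, 1]")
        if not (0.0 <= self.background_rate < max(self.coverage, 1e-12)):
            raise InputError(
                "background_rate must satisfy 0 ≤ background_rate < coverage "
                "(otherwise the planted set is undetectable by construction)"
            )
        if self.k_planted < 1 or self.k_planted > self.n:
            raise InputError("k_planted must satisfy 1 ≤ k_planted ≤ n")


def planted_matrix(scenario: PlantedScenario) -> tuple[MutationMatrix, GeneSet]:
    """Matrix with a planted high-coverage, near-exclusive gene set.

    Planted columns are filled solely by the planting process, so the
    planted set's coverage is exactly Binomial(m, coverage)/m.  Returns the
    matrix and the planted gene indices.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    planted = np.sort(rng.choice(s.n, size=s.k_planted, replace=False))
    entries = np.zeros((s.m, s.n), dtype=np.uint8)
    passenger = np.setdiff1d(np.arange(s.n), planted)
    entries[:, passenger] = (rng.random((s.m, passenger.size)) < s.background_rate).astype(
        np.uint8
    )
    covered = rng.random(s.m) < s.coverage
    for i in np.flatnonzero(covered):
        if s.k_planted >= 2 and rng.random() < s.co_mutation_rate:
            hit = rng.choice(s.k_planted, size=2, replace=False)
        else:
            hit = [rng.integers(s.k_planted)]
        entries[i, planted[hit]] = 1
    matrix = MutationMatrix(entries, _labels("P", s.m), _labels("G", s.n))
    return matrix, GeneSet(tuple(int(j) for j in planted))


def correlated_covariates(n: int, correlation: float, seed: int) -> CovariateTable:
    """Three covariate columns sharing a standard-normal latent factor.

    Each column is √ρ·latent + √(1−ρ)·noise, so every pair has population
    correlation ρ — emulating the strong mutual correlation of expression
    level, replication time and chromosome status.
    """
    if not (0.0 <= correlation < 1.0):
        raise InputError(f"correlation must be in [0, 1); got {correlation}")
    if n < 2:
        raise InputError("n must be ≥ 2")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    w = np.sqrt(correlation)
    cols = [w * latent + np.sqrt(1.0 - correlation) * rng.standard_normal(n) for _ in range(3)]
    return CovariateTable(_labels("G", n), cols[0], cols[1], cols[2])
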