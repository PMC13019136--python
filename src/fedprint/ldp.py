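"""Randomized response over ternary genotype dosages.

The mechanism keeps each dosage value with probability
``p = exp(eps) / (exp(eps) + 2)`` and otherwise replaces it uniformly
at random by one of the two alternative values.  This is a pure
eps-local-differential-privacy mechanism (delta = 0): for the induced
3x3 transition matrix, the likelihood ratio any output induces between
two inputs is at most ``exp(eps)``, attained as p / ((1-p)/2).

``eps = math.inf`` is the no-perturbation sentinel; ``eps = 0`` is
allowed and yields the uniform channel (keep probability 1/3).
"""

from __future__ import annotations

import math

import numpy as np

from .cohort import GenotypeMatrix

__all__ = ["keep_probability", "transition_matrix", "perturb_genotypes"]


def _check_epsilon(epsilon: float) -> float:
    epsilon = float(epsilon)
    if math.isnan(epsilon) or epsilon < 0:
        raise ValueError(f"epsilon must be >= 0 or inf, got {epsilon}")
    return epsilon


def keep_probability(epsilon: float) -> float:
    """p = exp(eps) / (exp(eps) + 2); 1 at eps = inf, 1/3 at eps = 0."""
    epsilon = _check_epsilon(epsilon)
    if math.isinf(epsilon):
        return 1.0
    # equivalent stable form: 1 / (1 + 2 exp(-eps))
    return 1.0 / (1.0 + 2.0 * math.exp(-epsilon))


def transition_matrix(epsilon: float) -> np.ndarray:
    """3x3 row-stochastic channel: diagonal p, off-diagonal (1-p)/2."""
    p = keep_probability(epsilon)
    q = (1.0 - p) / 2.0
    return np.full((3, 3), q) + (p - q) * np.eye(3)


def perturb_genotypes(
    G: GenotypeMatrix, epsilon: float, seed: int = 0
) -> GenotypeMatrix:
    """Apply randomized response independently to every dosage entry.

    Raises ``ValueError`` (naming the offending cell) if any entry is
    outside {0, 1, 2}.  Deterministic under a fixed seed.
    """
    G.require_dosage()
    epsilon = _check_epsilon(epsilon)
    if math.isinf(epsilon):
        return G.copy()
    p = keep_probability(epsilon)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    keep = rng.random(G.values.shape) < p
    # +1 or +2 mod 3 picks one of the two alternatives uniformly
    shift = rng.integers(1, 3, size=G.values.shape)
    perturbed = np.where(keep, G.values, (G.values + shift) % 3)
    return GenotypeMatrix(perturbed, list(G.sample_ids), list(G.locus_ids))
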