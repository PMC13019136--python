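"""Synthetic cohort generator.

Emulates the statistical structure the verification protocol assumes:
Hardy-Weinberg genotypes at independent loci with per-locus allele
frequencies drawn from a MAF window, a logistic binary phenotype with a
calibrated prevalence, and injected duplicate records / distance
outliers that give the duplicate-removal and outlier-filtering pipeline
steps real work to do.

All randomness flows from one integer seed per operation through
``numpy.random.SeedSequence`` so identical specs give bit-identical
cohorts.

For privacy (membership-inference) experiments a second generator,
:func:`sample_haplotype_panel`, simulates a contiguous SNP slice with a
coalescent model (msprime) so that the panel has realistic haplotype
sharing; see its docstring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cohort import GenotypeMatrix, PhenotypeVector, check_aligned

__all__ = [
    "CohortSpec",
    "sample_genotypes",
    "sample_phenotypes",
    "generate_cohort",
    "inject_duplicates",
    "inject_outliers",
    "filter_maf",
    "partition_sites",
    "sample_haplotype_panel",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic case/control cohort.

    Defaults reflect a common-variant case/control slice: MAF uniform in
    [0.05, 0.5], five causal loci with log-odds 1.0 per dosage unit,
    30% case prevalence (imbalanced, so resampling matters), and 5%
    injected duplicates and outliers (so those filters matter).
    """

    n_samples: int = 400
    n_loci: int = 100
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 5
    effect_size: float = 1.0
    prevalence: float = 0.3
    dup_fraction: float = 0.05
    outlier_fraction: float = 0.05
    n_rare: int = 0  # extra near-monomorphic loci (MAF < 0.01) to exercise the MAF filter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 <= maf_low <= maf_high <= 0.5")
        if not (0 <= self.dup_fraction < 0.5):
            raise ValueError("dup_fraction must be in [0, 0.5)")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.n_samples < 1 or self.n_loci < 1:
            raise ValueError("n_samples and n_loci must be positive")
        if self.n_causal > self.n_loci:
            raise ValueError("n_causal cannot exceed n_loci")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def sample_genotypes(spec: CohortSpec) -> GenotypeMatrix:
    """Draw an HWE dosage matrix with independent loci.

    Each locus ``j`` gets an allele frequency ``f_j ~ U(maf_low,
    maf_high)`` and dosages are Binomial(2, f_j), i.e. the sum of two
    Bernoulli allele draws.  If ``spec.n_rare > 0``, that many extra
    loci with allele frequency 0.002 (below the usual 0.01 MAF filter)
    are appended.
    """
    rng = _rng(spec.seed, 1)
    freqs = rng.uniform(spec.maf_low, spec.maf_high, size=spec.n_loci)
    if spec.n_rare:
        freqs = np.concatenate([freqs, np.full(spec.n_rare, 0.002)])
    values = rng.binomial(2, freqs, size=(spec.n_samples, freqs.size)).astype(float)
    return GenotypeMatrix(values)


def _calibrate_intercept(
    scores: np.ndarray, prevalence: float, tol: float = 0.02
) -> float:
    """Bisect the logistic intercept so mean sigmoid(a + s) ~= prevalence."""

    def mean_prob(a: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(a + scores)))).mean())

    lo, hi = -40.0, 40.0
    if not (mean_prob(lo) - 1e-12 <= prevalence <= mean_prob(hi) + 1e-12):
        raise ValueError(f"prevalence {prevalence} unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    a = 0.5 * (lo + hi)
    if abs(mean_prob(a) - prevalence) > tol:
        raise ValueError("intercept calibration failed")
    return a


def sample_phenotypes(G: GenotypeMatrix, spec: CohortSpec) -> PhenotypeVector:
    """Draw binary labels from a logistic model on randomly chosen causal loci.

    logit P(y=1 | g) = alpha + effect_size * sum of causal dosages, with
    alpha calibrated by bisection so the expected case fraction matches
    ``spec.prevalence`` to within 0.02.
    """
    if spec.n_causal > G.n_loci:
        raise ValueError("n_causal exceeds locus count")
    rng = _rng(spec.seed, 2)
    causal = rng.choice(G.n_loci, size=spec.n_causal, replace=False)
    scores = spec.effect_size * G.values[:, causal].sum(axis=1)
    alpha = _calibrate_intercept(scores, spec.prevalence)
    probs = 1.0 / (1.0 + np.exp(-(alpha + scores)))
    labels = (rng.random(G.n_samples) < probs).astype(int)
    return PhenotypeVector(labels)


def generate_cohort(
    spec: CohortSpec, inject: bool = True
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes + phenotypes, with the spec's duplicate/outlier injections."""
    G = sample_genotypes(spec)
    Y = sample_phenotypes(G, spec)
    if inject and spec.dup_fraction > 0:
        G, Y = inject_duplicates(G, Y, spec.dup_fraction, seed=spec.seed + 3)
    if inject and spec.outlier_fraction > 0:
        G = inject_outliers(G, spec.outlier_fraction, seed=spec.seed + 4)
    return G, Y


def inject_duplicates(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    fraction: float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Append ceil(fraction * n) exact copies of randomly chosen rows."""
    check_aligned(G, Y)
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    if fraction == 0:
        return G, Y
    n = G.n_samples
    k = math.ceil(fraction * n)
    rng = _rng(seed, 10)
    src = rng.integers(0, n, size=k)
    values = np.vstack([G.values, G.values[src]])
    ids = list(G.sample_ids) + [f"dup{i}_{G.sample_ids[s]}" for i, s in enumerate(src)]
    labels = np.concatenate([Y.labels, Y.labels[src]])
    return GenotypeMatrix(values, ids, list(G.locus_ids)), PhenotypeVector(labels)


def inject_outliers(
    G: GenotypeMatrix,
    fraction: float,
    magnitude: float = 1.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Replace ceil(fraction * n) rows by valid-dosage rows far from the mean.

    Each injected row sits at Euclidean distance at least
    ``max_i d_i + magnitude`` from the pre-injection cohort mean, where
    ``d_i`` are the original row distances, while still containing only
    values in {0, 1, 2}.  Rows are built from the per-locus extreme
    dosage (0 or 2, whichever is farther from the column mean) and then
    randomly relaxed coordinate-by-coordinate while the distance margin
    allows, so injected rows differ from one another.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if fraction == 0:
        return G
    n = G.n_samples
    k = math.ceil(fraction * n)
    rng = _rng(seed, 11)
    mu = G.values.mean(axis=0)
    d = np.linalg.norm(G.values - mu, axis=1)
    required_sq = (d.max() + magnitude) ** 2

    far = np.where(mu > 1.0, 0.0, 2.0)  # farthest extreme per column
    near = 2.0 - far
    far_gain = (far - mu) ** 2
    near_gain = (near - mu) ** 2
    max_sq = far_gain.sum()
    if max_sq < required_sq:
        raise ValueError(
            "cannot inject outliers: extreme dosage rows are not far enough "
            f"from the cohort mean (max {math.sqrt(max_sq):.2f}, "
            f"need {math.sqrt(required_sq):.2f})"
        )

    rows = np.empty((k, G.n_loci))
    for i in range(k):
        row = far.copy()
        total = max_sq
        for j in rng.permutation(G.n_loci):
            loss = far_gain[j] - near_gain[j]
            # flip to the nearer extreme when the margin survives
            if total - loss >= required_sq and rng.random() < 0.5:
                row[j] = near[j]
                total -= loss
        rows[i] = row

    target = rng.choice(n, size=k, replace=False)
    values = G.values.copy()
    values[target] = rows
    return GenotypeMatrix(values, list(G.sample_ids), list(G.locus_ids))


def filter_maf(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Keep loci whose minor allele frequency strictly exceeds ``threshold``.

    The allele frequency at a locus is mean dosage / 2; the MAF folds it
    onto [0, 0.5].
    """
    if not (0 <= threshold < 0.5):
        raise ValueError("threshold must be in [0, 0.5)")
    f = G.values.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = np.where(maf > threshold)[0]
    if keep.size == 0:
        raise ValueError(f"MAF filter at {threshold} removed every locus")
    return G.take_loci(keep)


def partition_sites(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    K: int,
    seed: int = 0,
) -> list[tuple[GenotypeMatrix, PhenotypeVector]]:
    """Random disjoint near-equal split across ``K >= 2`` sites."""
    check_aligned(G, Y)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > G.n_samples:
        raise ValueError(f"cannot split {G.n_samples} samples across {K} sites")
    rng = _rng(seed, 12)
    order = rng.permutation(G.n_samples)
    parts = np.array_split(order, K)
    return [(G.take_rows(p), Y.take(p)) for p in parts]


def sample_haplotype_panel(
    n_members: int,
    n_controls: int,
    n_loci: int,
    maf_threshold: float = 0.01,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate a contiguous common-SNP slice with realistic haplotype sharing.

    The independent-locus generator is the right null model for the
    verification experiments, but it badly misrepresents one feature
    that privacy attacks exploit: in real panels, a contiguous slice of
    SNPs is inherited on shared haplotypes, so the nearest-neighbour
    Hamming distance between individuals is far smaller than under
    locus independence.  Membership-inference power against an
    LDP-perturbed release depends directly on that distance scale, so
    the attack experiments use this coalescent panel instead.

    Members and controls are simulated in one panmictic population
    (msprime; Ne = 10,000 diploids, mu = 1.25e-8, r = 1e-8 per bp, region
    length grown until at least ``n_loci`` sites pass the MAF filter),
    then split, so controls are population-matched non-members.
    Returns ``(members, controls)`` sharing the same locus list.
    """
    import msprime  # deferred: only privacy experiments need it

    n_total = n_members + n_controls
    length = max(4000 * n_loci, 50_000)
    rng = _rng(seed, 13)
    for attempt in range(6):
        ts = msprime.sim_ancestry(
            samples=n_total,
            population_size=10_000,
            sequence_length=length,
            recombination_rate=1e-8,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=1.25e-8,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        geno = ts.genotype_matrix()  # sites x haplotypes, in {0,1}
        dosage = geno[:, 0::2] + geno[:, 1::2]  # diploid dosage, sites x samples
        f = dosage.mean(axis=1) / 2.0
        common = np.where(np.minimum(f, 1 - f) > maf_threshold)[0]
        if common.size >= n_loci:
            keep = common[:n_loci]
            values = dosage[keep].T.astype(float)
            ids = [f"slice{int(ts.site(int(s)).position)}" for s in keep]
            # site positions can collide after rounding; disambiguate
            seen: dict[str, int] = {}
            for i, lid in enumerate(ids):
                if lid in seen:
                    seen[lid] += 1
                    ids[i] = f"{lid}.{seen[lid]}"
                else:
                    seen[lid] = 0
            sample_ids = [f"ind{i}" for i in range(n_total)]
            panel = GenotypeMatrix(values, sample_ids, ids)
            members = panel.take_rows(np.arange(n_members))
            controls = panel.take_rows(np.arange(n_members, n_total))
            return members, controls
        length *= 2
    raise RuntimeError("could not obtain enough common SNPs from the simulation")
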