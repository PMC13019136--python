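# Methods

`fedprint` verifies whether the sites of a federated genomic study
applied identical preprocessing pipelines, using only
differentially-private artifacts, and quantifies the residual
membership-inference risk of those artifacts.  This note documents the
models, the tunable parameters, the synthetic-data assumptions, and the
design choices made where the design was genuinely open.

## Protocol

Each site holds a dosage matrix `X_k` (samples × loci, entries in
{0, 1, 2}) with a binary phenotype `Y_k`.  The site protocol is

1. `X̃_k ← RandomizedResponse(X_k, ε)` — every entry is kept with
   probability `p = e^ε / (e^ε + 2)` and otherwise replaced uniformly
   by one of the two other dosage values.  The induced 3×3 channel has
   diagonal `p` and off-diagonals `(1−p)/2`; its worst-case likelihood
   ratio is exactly `e^ε`, i.e. pure ε-local-DP with δ = 0.  Everything
   downstream is post-processing of `X̃_k`, so the guarantee propagates.
2. `(X′_k, Y′_k) ← Pipeline(X̃_k, Y_k, P_k)` — any non-empty subset of
   four operations in fixed order: duplicate removal → outlier
   filtering → z-scoring → SMOTE resampling (15 possible fingerprints;
   the label of a configuration is `8·dedupe + 4·outlier + 2·scale +
   1·resample`).
3. A RandomForest is trained on `(X′_k, Y′_k)` and a single explanation
   vector `e_k` (one coefficient per locus) is extracted.
4. The site uploads `(X̃_k, Y_k, e_k)` — never raw genotypes, never
   model weights, never its configuration.

The server validates locus alignment, concatenates the perturbed
uploads into `X_ref`, replays all 15 pipelines on bootstrap subsamples
of `X_ref` (R replicates each), records the resulting labeled
explanation vectors, trains a 15-class RandomForest verifier on that
library, predicts each site's fingerprint from its uploaded `e_k`, and
returns COMPATIBLE exactly when all predicted fingerprints fall in the
same cluster of the label space (strict equality at C = 15; K-means
clusters of the 15 per-config mean vectors for C ∈ {5, 4, 3, 2}).

## The explanation vector

The explainer is the standard local-surrogate recipe for tabular data:
around an instance `x`, draw `n_samples` perturbed points by keeping
each feature of `x` with probability 0.5 and otherwise resampling it
from the background column's empirical distribution (drawn through the
inverted empirical CDF); weight each point by `exp(−d²/kw²)` where `d`
is the Euclidean distance to `x` in background-standardized space and
`kw = 0.75·√m` by default; fit a weighted ridge regression (small
penalty, α = 1) of the model's class-1 probability on the perturbed
features; the instance's explanation is the ridge coefficient vector.

Choices made where the recipe is under-determined:

- **Aggregation.** The site vector is the mean of per-instance
  coefficient vectors over 50 explained instances (distinct rows of the
  post-pipeline matrix, weighted by their multiplicity).  Every
  instance shares one surrogate seed, which makes the vector invariant
  to uniform duplication of the explain set and lets the model be
  queried in a single batched call.
- **Signed coefficients**, not absolute importances: the verifier is
  agnostic, and signs carry information.
- **Ridge, not lasso.** The full dense vector is the artifact;
  sparsity would only discard signal.
- Coefficients are finite by construction; zero-variance background
  columns standardize with sd 1 (they contribute zero distance).

On a model with a known linear probability surface the surrogate
recovers the true weights (correlation > 0.99 at n_samples = 5000); on
a cohort with five causal loci the five largest |coefficients| identify
at least four of them (both are test-asserted).

## Membership-inference attack

The adversary holds a target genome and the released `X̃` and flags the
target as a member when its minimum Hamming distance to any released
row is at or below a threshold calibrated on known non-members.  Per
repetition (50 total): 25 member and 25 non-member genomes are drawn;
the threshold is the largest value such that at most 5% of that
repetition's controls fall at or below it; power is the fraction of
members flagged.  The result carries a bootstrap 95% CI over the
per-repetition powers.  Min-distance matching is the strongest natural
variant of the Hamming attack, hence conservative for privacy claims;
per-repetition calibration keeps repetitions exchangeable for the
bootstrap.

Attack power is governed by the gap between (i) a member's distance to
its own perturbed row — Binomial(m, 1−p), e.g. mean ≈ 9 of 100 SNPs at
ε = 3 — and (ii) a non-member's nearest-neighbour distance to the
release.  That second scale is a property of the cohort, which is why
the attack experiments do **not** use the independent-locus generator
(see below).

## Synthetic data

Two generators, for two different purposes:

**Independent-locus cohort** (`sample_genotypes` et al.): per-locus
allele frequency `f_j ~ U(0.05, 0.5)`, dosages Binomial(2, f_j) (HWE),
no linkage disequilibrium.  Binary phenotype from a logistic model on 5
randomly chosen causal loci with log-odds 1.0 per dosage unit and an
intercept bisection-calibrated to a 30% case prevalence (imbalanced, so
resampling has work to do).  5% exact duplicate rows and 5% distance
outliers are injected by default (so those filters have work to do);
injected outliers are guaranteed to exceed every original row's
distance to the cohort mean by a margin, making the outlier filter's
behavior deterministic in tests.  All randomness flows from one integer
seed per operation via `numpy.random.SeedSequence`.

**Haplotype panel** (`sample_haplotype_panel`): a contiguous common-SNP
slice simulated with msprime (panmictic coalescent, Ne = 10,000
diploids, μ = 1.25e−8, r = 1e−8 per bp, region grown until the
requested number of MAF > 0.01 sites exists; members and controls drawn
from one simulation so controls are population-matched).  This panel
exists because nearest-neighbour Hamming distances — the quantity the
MI attack lives on — are tiny on real genomic slices (haplotype
sharing) and large under locus independence.  On the independent
cohort, min-Hamming membership inference is essentially always
successful at ε = 3 (the ~9-flip noise is far below the ~30+ mismatch
nearest-neighbour floor), which misstates the privacy of real releases;
on the coalescent panel the two scales overlap and power lands near the
false-positive floor, the regime reported for real slice data.

What the generators do **not** emulate: population structure and
admixture, genotyping error, informative missingness, LD between the
phenotype model and haplotype structure, and real ascertainment of SNP
panels.  Passing tests therefore show the protocol's behavior under
clean HWE sampling, not performance on any particular real cohort.

A degenerate limit worth knowing: on haplotype panels some non-members
carry slices identical to members', so at ε = ∞ the calibrated
threshold collapses below zero and measured power drops to 0 — member-
ship of a shared haplotype slice is genuinely undecidable.  The
monotonicity-in-ε property is therefore asserted on distinct-genome
cohorts.

## Verifier accuracy: what is attainable

Replicate reference vectors are generated by bootstrap sampling
`X_ref` **with replacement** (the replicate scheme is not dictated by
the protocol; without replicates a 15-class classifier cannot
generalize).  Resampling with replacement also gives duplicate removal
server-side work, since exact duplicates cannot survive randomized
response (P ≈ 0.91^100 ≈ 8e−5 per row at ε = 3).

Measured on the default cohort (n = 2504 × 100, full-size bootstrap,
R = 20): the scaling and resampling flags are recovered from
explanation vectors almost perfectly (≈ 0.98 each), the outlier flag
weakly (≈ 0.6), and the dedupe flag not at all (≈ 0.5 even at ε = ∞) —
re-weighting duplicated rows barely moves a RandomForest's probability
surface where the bulk instances are explained.  Held-out 15-class
accuracy consequently saturates near 0.26 at ε = 3 (chance 1/15) and
two-cluster accuracy near 0.99 at ε = 3 but ≈ 0.77 at ε = 0.1.  These
ceilings are structural under the protocol's LDP-before-preprocessing
order; the package reports whatever its runs measure.

## Operating sizes

Defaults: 100-tree forests; surrogate n_samples = 1000, 50 instances;
R = 20 replicates; outlier threshold mean + 3 sd of row distances
(scale-free; the protocol names a Euclidean threshold but no value);
SMOTE k_neighbors = 1 with one interpolation weight per synthetic row
and nearest-neighbour ties broken by lowest row index; per-locus mode
imputation for missing entries (exercised only by masked-entry
fixtures; the generators produce complete data).

The reproduction script (`scripts/acceptance.py`) scales some of this
down to keep a full run in the tens of minutes on one core: reference
libraries use 60-tree forests with 40 instances × 400 surrogate samples
(R = 20, full-size bootstrap of n = 2504), held-out accuracy averages
five stratified-split/classifier seeds, and the three-site federated
trials use R = 3, 500-row subsamples, 40 trees and 15 × 200 surrogate
queries per replicate.  The test suite uses smaller sizes again, chosen
for runtime; thresholds are never adjusted to the sizes.

## Known limitations

- The dedupe flag is unidentifiable in the live protocol (above); a
  consortium that needs it verified must either move deduplication
  before perturbation (changing the privacy analysis) or accept
  verification of the other three operations.
- Labels `Y_k` travel unperturbed: the server cannot train surrogate
  models from `(X̃_k, e_k)` alone, and the protocol does not specify a
  label mechanism.  Phenotype privacy is therefore *not* protected.
- Federation is simulated in-process with exactly the protocol's
  message contents; no network transport is included.
- Honest-but-curious parties only; a malicious site could forge `e_k`.
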