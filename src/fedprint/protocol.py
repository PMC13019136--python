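"""End-to-end preprocessing-verification protocol.

Site side: perturb the local dosage matrix with randomized response,
run the site's preprocessing pipeline, train a RandomForest, extract
one aggregated local-surrogate explanation vector, and upload only the
perturbed matrix, the phenotype labels and the explanation vector.

Server side: validate locus alignment, concatenate the perturbed site
matrices into a reference cohort, replay all 15 candidate pipelines on
bootstrap subsamples to build a labeled library of reference
explanation vectors, train a 15-class verifier on the library
(optionally coarsened by K-means clustering of the label space), and
predict each site's fingerprint from its uploaded vector.  Sites are
compatible when all predicted fingerprints fall in the same cluster.

The server functions accept only :class:`SiteArtifact` fields — never a
raw matrix, a site model or a site's true configuration — which is the
structural form of the protocol's information barrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cohort import GenotypeMatrix, PhenotypeVector, check_aligned
from .explain import (
    ExplanationVector,
    SurrogateSettings,
    site_explanation_vector,
    train_classifier,
)
from .ldp import perturb_genotypes
from .preprocess import (
    FLAG_NAMES,
    PreprocConfig,
    apply_pipeline,
    enumerate_configs,
)
from .synth import partition_sites

__all__ = [
    "SiteArtifact",
    "AlignmentResult",
    "ReferenceLibrary",
    "VerifierModel",
    "VerificationReport",
    "run_site",
    "validate_alignment",
    "build_reference",
    "simulate_references",
    "train_verifier",
    "evaluate_verifier",
    "verify",
    "run_federated_experiment",
    "binary_compatibility_accuracy",
    "TrialOutcome",
]

ALLOWED_CLUSTER_COUNTS = (15, 5, 4, 3, 2)


@dataclass
class SiteArtifact:
    """Everything a site uploads: (perturbed matrix, labels, explanation)."""

    site_id: str
    perturbed: GenotypeMatrix
    phenotypes: PhenotypeVector
    explanation: ExplanationVector
    epsilon: float

    def __post_init__(self) -> None:
        check_aligned(self.perturbed, self.phenotypes)
        if list(self.explanation.locus_ids) != list(self.perturbed.locus_ids):
            raise ValueError("explanation locus order differs from matrix")
        self.perturbed.require_dosage()


@dataclass
class AlignmentResult:
    ok: bool
    message: str = "ok"


@dataclass
class ReferenceLibrary:
    """Labeled reference explanation vectors: 15 configs x R replicates."""

    vectors: np.ndarray  # (15 * R, n_loci)
    labels: np.ndarray  # (15 * R,), values 1..15
    locus_ids: list[str]
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.vectors.shape[0] != self.labels.shape[0]:
            raise ValueError("vectors/labels length mismatch")
        present = set(np.unique(self.labels))
        if present != set(range(1, 16)):
            raise ValueError(f"library must contain labels 1..15, has {sorted(present)}")

    def config_means(self) -> np.ndarray:
        """(15, n_loci) per-config mean reference vectors, label order 1..15."""
        return np.vstack(
            [self.vectors[self.labels == lab].mean(axis=0) for lab in range(1, 16)]
        )


@dataclass
class VerifierModel:
    """15-class verifier plus a label -> cluster-id map for C-cluster scoring."""

    classifier: RandomForestClassifier
    cluster_count: int
    label_to_cluster: dict[int, int]
    locus_ids: list[str]

    def predict_labels(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        if vectors.shape[1] != len(self.locus_ids):
            raise ValueError(
                f"vector dimension {vectors.shape[1]} != verifier dimension "
                f"{len(self.locus_ids)}"
            )
        return self.classifier.predict(vectors).astype(int)

    def cluster_of(self, label: int) -> int:
        return self.label_to_cluster[int(label)]


@dataclass
class VerificationReport:
    verdict: str  # "COMPATIBLE" | "INCOMPATIBLE"
    per_site: list[dict] = field(default_factory=list)
    differing_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "per_site": self.per_site,
            "differing_flags": self.differing_flags,
        }


def run_site(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    config: PreprocConfig,
    epsilon: float,
    seed: int = 0,
    n_trees: int = 100,
    n_instances: int = 50,
    settings: SurrogateSettings | None = None,
    site_id: str = "site",
) -> SiteArtifact:
    """Execute the site protocol: LDP -> pipeline -> train -> explain."""
    check_aligned(G, Y)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 51]))
    s_ldp, s_pipe, s_rf, s_lime = (int(x) for x in rng.integers(0, 2**31 - 1, 4))
    X_tilde = perturb_genotypes(G, epsilon, seed=s_ldp)
    result = apply_pipeline(X_tilde, Y, config, seed=s_pipe)
    model = train_classifier(result.genotypes, result.phenotypes, n_trees, seed=s_rf)
    evec = site_explanation_vector(
        model, result.genotypes, n_instances=n_instances, settings=settings, seed=s_lime
    )
    return SiteArtifact(
        site_id=site_id,
        perturbed=X_tilde,
        phenotypes=Y.copy(),
        explanation=evec,
        epsilon=float(epsilon),
    )


def validate_alignment(artifacts: list[SiteArtifact]) -> AlignmentResult:
    """Check shared locus order and dosage-valid entries across artifacts.

    Failures are reported as results (first mismatching locus position,
    or the first invalid cell), not raised.
    """
    if len(artifacts) < 2:
        raise ValueError("alignment validation needs at least 2 artifacts")
    ref = artifacts[0].perturbed.locus_ids
    for art in artifacts[1:]:
        ids = art.perturbed.locus_ids
        if ids != ref:
            if len(ids) != len(ref):
                return AlignmentResult(
                    False,
                    f"site {art.site_id}: locus count {len(ids)} != {len(ref)}",
                )
            pos = next(i for i, (a, b) in enumerate(zip(ref, ids)) if a != b)
            return AlignmentResult(
                False,
                f"site {art.site_id}: locus mismatch at position {pos} "
                f"({ids[pos]!r} vs {ref[pos]!r})",
            )
    for art in artifacts:
        v = art.perturbed.values
        bad = ~np.isin(v, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            return AlignmentResult(
                False,
                f"site {art.site_id}: invalid dosage {v[i, j]!r} at cell "
                f"({int(i)}, {int(j)})",
            )
    return AlignmentResult(True)


def build_reference(
    artifacts: list[SiteArtifact],
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Row-concatenate the perturbed site matrices (site order stable)."""
    if not artifacts:
        raise ValueError("no artifacts")
    if len(artifacts) > 1:
        res = validate_alignment(artifacts)
        if not res.ok:
            raise ValueError(f"artifacts not aligned: {res.message}")
    values = np.vstack([a.perturbed.values for a in artifacts])
    ids = [
        f"{a.site_id}:{sid}" for a in artifacts for sid in a.perturbed.sample_ids
    ]
    labels = np.concatenate([a.phenotypes.labels for a in artifacts])
    G = GenotypeMatrix(values, ids, list(artifacts[0].perturbed.locus_ids))
    return G, PhenotypeVector(labels)


def simulate_references(
    X_ref: GenotypeMatrix,
    Y_ref: PhenotypeVector,
    R: int = 20,
    subsample: int = 500,
    seed: int = 0,
    n_trees: int = 100,
    n_instances: int = 50,
    settings: SurrogateSettings | None = None,
) -> ReferenceLibrary:
    """Replay all 15 pipelines on bootstrap subsamples of the reference.

    For each configuration and each of ``R`` replicates, draw
    ``subsample`` rows with replacement (bootstrap), run the pipeline,
    train a surrogate RandomForest and record its explanation vector.
    Sampling with replacement deliberately creates repeated rows, which
    is what gives the duplicate-removal flag a detectable effect on the
    reference side (LDP noise destroys exact duplicates that existed in
    the raw site data).
    """
    check_aligned(X_ref, Y_ref)
    if np.unique(Y_ref.labels).size < 2:
        raise ValueError("reference phenotypes must contain both classes")
    n = X_ref.n_samples
    size = min(int(subsample), n) if subsample else n
    vectors, labels = [], []
    for config in enumerate_configs():
        for r in range(R):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 61, config.label, r])
            )
            for _ in range(20):  # redraw if the bootstrap missed a class
                idx = rng.integers(0, n, size=size)
                if np.unique(Y_ref.labels[idx]).size == 2:
                    break
            else:
                raise RuntimeError(
                    f"config {config.label} replicate {r}: bootstrap could not "
                    "capture both classes"
                )
            Gb = GenotypeMatrix(
                X_ref.values[idx].copy(),
                [f"b{r}_{i}" for i in range(size)],
                list(X_ref.locus_ids),
            )
            Yb = PhenotypeVector(Y_ref.labels[idx].copy())
            s_pipe, s_rf, s_lime = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
            try:
                res = apply_pipeline(Gb, Yb, config, seed=s_pipe)
                model = train_classifier(
                    res.genotypes, res.phenotypes, n_trees, seed=s_rf
                )
                evec = site_explanation_vector(
                    model,
                    res.genotypes,
                    n_instances=n_instances,
                    settings=settings,
                    seed=s_lime,
                )
            except Exception as exc:  # identify the failing replicate
                raise RuntimeError(
                    f"reference simulation failed for config {config.label} "
                    f"replicate {r}: {exc}"
                ) from exc
            vectors.append(evec.coefficients)
            labels.append(config.label)
    return ReferenceLibrary(
        vectors=np.vstack(vectors),
        labels=np.asarray(labels),
        locus_ids=list(X_ref.locus_ids),
        replicates=R,
        seed=int(seed),
    )


def train_verifier(
    library: ReferenceLibrary,
    C: int = 15,
    seed: int = 0,
    n_trees: int = 100,
) -> VerifierModel:
    """Fit the 15-class verifier; coarsen labels by K-means when C < 15.

    K-means (10 restarts, seeded) runs on the 15 per-config mean
    reference vectors, so the label -> cluster map is deterministic and
    auditable; with C = 15 the map is the identity.
    """
    if C not in ALLOWED_CLUSTER_COUNTS:
        raise ValueError(f"C must be one of {ALLOWED_CLUSTER_COUNTS}, got {C}")
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed), n_jobs=1
    )
    clf.fit(library.vectors, library.labels)
    if C == 15:
        mapping = {lab: lab - 1 for lab in range(1, 16)}
    else:
        km = KMeans(n_clusters=C, n_init=10, random_state=int(seed))
        assign = km.fit_predict(library.config_means())
        mapping = {lab: int(assign[lab - 1]) for lab in range(1, 16)}
    return VerifierModel(
        classifier=clf,
        cluster_count=C,
        label_to_cluster=mapping,
        locus_ids=list(library.locus_ids),
    )


def evaluate_verifier(
    library: ReferenceLibrary,
    C: int = 15,
    seed: int = 0,
    test_size: float = 0.25,
    n_trees: int = 100,
) -> float:
    """Held-out accuracy of the verifier on library replicates.

    Stratified split of the replicate vectors; a prediction is correct
    when its cluster matches the true label's cluster (exact label
    match at C = 15).
    """
    idx_train, idx_test = train_test_split(
        np.arange(library.labels.size),
        test_size=test_size,
        random_state=int(seed),
        stratify=library.labels,
    )
    train_lib = ReferenceLibrary(
        vectors=library.vectors[idx_train],
        labels=library.labels[idx_train],
        locus_ids=list(library.locus_ids),
        replicates=library.replicates,
        seed=library.seed,
    )
    verifier = train_verifier(train_lib, C=C, seed=seed)
    pred = verifier.predict_labels(library.vectors[idx_test])
    truth = library.labels[idx_test]
    pred_c = np.array([verifier.cluster_of(p) for p in pred])
    true_c = np.array([verifier.cluster_of(t) for t in truth])
    return float((pred_c == true_c).mean())


def verify(artifacts: list[SiteArtifact], verifier: VerifierModel) -> VerificationReport:
    """Predict each site's fingerprint and issue the compatibility verdict.

    COMPATIBLE iff all predicted labels fall in the same cluster.  The
    differing-flags summary lists the operations on which the predicted
    fingerprints disagree.
    """
    if not artifacts:
        raise ValueError("no artifacts to verify")
    per_site = []
    clusters = []
    flag_sets: dict[str, set[bool]] = {name: set() for name in FLAG_NAMES}
    for art in artifacts:
        label = int(verifier.predict_labels(art.explanation.coefficients)[0])
        cfg = PreprocConfig.from_label(label)
        cluster = verifier.cluster_of(label)
        clusters.append(cluster)
        for name, val in zip(FLAG_NAMES, cfg.flags):
            flag_sets[name].add(val)
        per_site.append(
            {
                "site": art.site_id,
                "label": label,
                "cluster": cluster,
                "flags": dict(zip(FLAG_NAMES, cfg.flags)),
            }
        )
    compatible = len(set(clusters)) == 1
    differing = [] if compatible else [n for n in FLAG_NAMES if len(flag_sets[n]) > 1]
    return VerificationReport(
        verdict="COMPATIBLE" if compatible else "INCOMPATIBLE",
        per_site=per_site,
        differing_flags=differing,
    )


@dataclass
class TrialOutcome:
    scenario: str
    expected_verdict: str
    report: VerificationReport
    site_configs: list[int]  # ground-truth bookkeeping only
    correct: bool


def run_federated_experiment(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    K: int = 3,
    epsilon: float = 3.0,
    scenario: str = "all-same",
    seed: int = 0,
    C: int = 15,
    R: int = 20,
    subsample: int = 500,
    n_trees: int = 100,
    n_instances: int = 50,
    settings: SurrogateSettings | None = None,
) -> TrialOutcome:
    """One full trial: partition, run sites, run the server, check verdict.

    ``scenario`` is ``"all-same"`` (every site draws the same random
    configuration; ground truth COMPATIBLE) or ``"one-differs"`` (one
    site draws a different configuration; ground truth INCOMPATIBLE).
    """
    if scenario not in ("all-same", "one-differs"):
        raise ValueError("scenario must be 'all-same' or 'one-differs'")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 71]))
    base = int(rng.integers(1, 16))
    configs = [base] * K
    if scenario == "one-differs":
        other = int(rng.integers(1, 16))
        while other == base:
            other = int(rng.integers(1, 16))
        configs[int(rng.integers(0, K))] = other
    parts = partition_sites(G, Y, K, seed=int(rng.integers(0, 2**31 - 1)))
    artifacts = []
    for k, ((Gk, Yk), lab) in enumerate(zip(parts, configs)):
        artifacts.append(
            run_site(
                Gk,
                Yk,
                PreprocConfig.from_label(lab),
                epsilon,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_trees=n_trees,
                n_instances=n_instances,
                settings=settings,
                site_id=f"site{k}",
            )
        )
    res = validate_alignment(artifacts)
    if not res.ok:
        raise RuntimeError(f"site artifacts failed alignment: {res.message}")
    X_ref, Y_ref = build_reference(artifacts)
    library = simulate_references(
        X_ref,
        Y_ref,
        R=R,
        subsample=subsample,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_trees=n_trees,
        n_instances=n_instances,
        settings=settings,
    )
    verifier = train_verifier(
        library, C=C, seed=int(rng.integers(0, 2**31 - 1)), n_trees=n_trees
    )
    report = verify(artifacts, verifier)
    expected = "COMPATIBLE" if scenario == "all-same" else "INCOMPATIBLE"
    return TrialOutcome(
        scenario=scenario,
        expected_verdict=expected,
        report=report,
        site_configs=configs,
        correct=report.verdict == expected,
    )


def binary_compatibility_accuracy(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    n_repetitions: int = 5,
    K: int = 3,
    epsilon: float = 3.0,
    seed: int = 0,
    **kwargs,
) -> tuple[float, list[TrialOutcome]]:
    """Verdict accuracy over n_repetitions x {all-same, one-differs} trials."""
    outcomes = []
    for rep in range(n_repetitions):
        for scenario in ("all-same", "one-differs"):
            outcomes.append(
                run_federated_experiment(
                    G,
                    Y,
                    K=K,
                    epsilon=epsilon,
                    scenario=scenario,
                    seed=int(np.random.default_rng(
                        np.random.SeedSequence([int(seed), 72, rep, scenario == "one-differs"])
                    ).integers(0, 2**31 - 1)),
                    **kwargs,
                )
            )
    acc = float(np.mean([o.correct for o in outcomes]))
    return acc, outcomes
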