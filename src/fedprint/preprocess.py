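"""The four optional preprocessing operations and their fingerprint space.

Sites may enable any non-empty subset of four operations, always applied
in the fixed order

    duplicate removal -> outlier filtering -> feature scaling -> resampling

giving 2**4 - 1 = 15 valid pipeline fingerprints.  The label of a
configuration is its binary encoding ``dedupe*8 + outlier*4 + scale*2 +
resample*1`` (so labels run 1..15 in increasing encoding order, and the
all-off combination, encoding 0, is excluded).

Mandatory steps (missing-value imputation, dosage encoding) are not part
of the fingerprint: imputation is per-locus mode and runs first whenever
missing entries are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import GenotypeMatrix, PhenotypeVector, check_aligned

__all__ = [
    "PreprocConfig",
    "FLAG_NAMES",
    "enumerate_configs",
    "impute_missing",
    "remove_duplicates",
    "filter_outliers",
    "scale_features",
    "resample_smote",
    "apply_pipeline",
    "PipelineRecord",
    "PipelineResult",
]

FLAG_NAMES = ("dedupe", "outlier", "scale", "resample")


@dataclass(frozen=True)
class PreprocConfig:
    """One preprocessing fingerprint: four flags plus its 1..15 label."""

    dedupe: bool = False
    outlier: bool = False
    scale: bool = False
    resample: bool = False

    def __post_init__(self) -> None:
        if not (self.dedupe or self.outlier or self.scale or self.resample):
            raise ValueError("at least one preprocessing flag must be enabled")

    @property
    def label(self) -> int:
        return (
            8 * self.dedupe + 4 * self.outlier + 2 * self.scale + 1 * self.resample
        )

    @classmethod
    def from_label(cls, label: int) -> "PreprocConfig":
        if not 1 <= label <= 15:
            raise ValueError(f"label must be in 1..15, got {label}")
        return cls(
            dedupe=bool(label & 8),
            outlier=bool(label & 4),
            scale=bool(label & 2),
            resample=bool(label & 1),
        )

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.dedupe, self.outlier, self.scale, self.resample)

    def to_dict(self) -> dict:
        return {
            "dedupe": self.dedupe,
            "outlier": self.outlier,
            "scale": self.scale,
            "resample": self.resample,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocConfig":
        cfg = cls(**{k: bool(d[k]) for k in FLAG_NAMES})
        if "label" in d and int(d["label"]) != cfg.label:
            raise ValueError(
                f"label {d['label']} inconsistent with flags (expect {cfg.label})"
            )
        return cfg


def enumerate_configs() -> list[PreprocConfig]:
    """All 15 valid fingerprints, ordered by label."""
    return [PreprocConfig.from_label(lab) for lab in range(1, 16)]


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace NaN entries by the per-locus mode (lowest dosage on ties)."""
    v = G.values
    if not np.isnan(v).any():
        return G
    out = v.copy()
    for j in range(G.n_loci):
        col = out[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            mode = 0.0
        else:
            vals, counts = np.unique(observed, return_counts=True)
            mode = vals[np.argmax(counts)]  # np.unique sorts, so ties -> lowest
        col[miss] = mode
    return GenotypeMatrix(out, list(G.sample_ids), list(G.locus_ids))


def remove_duplicates(
    G: GenotypeMatrix, Y: PhenotypeVector
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Keep the first occurrence of each distinct genotype row.

    Duplicate identity is genotype-row equality only; labels are
    ignored for matching but filtered alongside.
    """
    check_aligned(G, Y)
    seen: set[bytes] = set()
    keep: list[int] = []
    for i in range(G.n_samples):
        key = G.values[i].tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(i)
    if len(keep) == G.n_samples:
        return G, Y
    return G.take_rows(keep), Y.take(keep)


def filter_outliers(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    k_sigma: float = 3.0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Drop rows whose distance to the column-mean exceeds mean + k_sigma * sd.

    Distances are Euclidean to the cohort mean vector.  With k_sigma=3
    this is a scale-free version of a fixed Euclidean threshold.  Never
    empties the cohort (an all-removed outcome raises).
    """
    check_aligned(G, Y)
    if G.n_samples < 3:
        raise ValueError("outlier filtering needs at least 3 samples")
    mu = G.values.mean(axis=0)
    d = np.linalg.norm(G.values - mu, axis=1)
    thr = d.mean() + k_sigma * d.std()
    keep = np.where(d <= thr)[0]
    if keep.size == 0:
        raise ValueError("outlier filter would remove every sample")
    if keep.size == G.n_samples:
        return G, Y
    return G.take_rows(keep), Y.take(keep)


def scale_features(G: GenotypeMatrix) -> GenotypeMatrix:
    """Z-score each column (population sd); constant columns map to zeros."""
    if G.n_samples < 2:
        raise ValueError("scaling needs at least 2 samples")
    mu = G.values.mean(axis=0)
    sd = G.values.std(axis=0)
    centred = G.values - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    return GenotypeMatrix(scaled, list(G.sample_ids), list(G.locus_ids))


def resample_smote(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    k_neighbors: int = 1,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Equalize class counts by SMOTE interpolation of minority samples.

    Each synthetic row is ``x + lambda * (x_nn - x)`` for a randomly
    chosen minority sample ``x``, one of its ``k_neighbors`` nearest
    minority neighbours ``x_nn`` (Euclidean; distance ties broken by
    lowest row index), and a single ``lambda ~ U(0, 1)`` shared across
    coordinates.  Synthetic rows are appended with generated ids.
    """
    check_aligned(G, Y)
    counts = np.bincount(Y.labels, minlength=2)
    if counts[0] == counts[1]:
        return G, Y
    minority = int(np.argmin(counts))
    n_needed = int(abs(counts[1] - counts[0]))
    min_idx = np.where(Y.labels == minority)[0]
    if min_idx.size < 2:
        raise ValueError(
            "SMOTE with k_neighbors=1 needs at least 2 minority samples, "
            f"got {min_idx.size}"
        )
    k = min(k_neighbors, min_idx.size - 1)
    X_min = G.values[min_idx]
    # pairwise distances within the minority class; stable tie-break on index
    d2 = cdist(X_min, X_min, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    nn_order = np.argsort(d2, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    base = rng.integers(0, min_idx.size, size=n_needed)
    which_nn = rng.integers(0, k, size=n_needed)
    lam = rng.random(n_needed)
    x = X_min[base]
    x_nn = X_min[nn_order[base, which_nn]]
    synth = x + lam[:, None] * (x_nn - x)

    values = np.vstack([G.values, synth])
    ids = list(G.sample_ids) + [f"smote{i}" for i in range(n_needed)]
    labels = np.concatenate([Y.labels, np.full(n_needed, minority)])
    return GenotypeMatrix(values, ids, list(G.locus_ids)), PhenotypeVector(labels)


@dataclass
class PipelineRecord:
    """Row-count ledger for one pipeline run."""

    n_input: int
    removed_duplicates: int = 0
    removed_outliers: int = 0
    synthesized: int = 0
    imputed_cells: int = 0

    @property
    def n_output(self) -> int:
        return (
            self.n_input
            - self.removed_duplicates
            - self.removed_outliers
            + self.synthesized
        )


@dataclass
class PipelineResult:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeVector
    record: PipelineRecord


def apply_pipeline(
    G: GenotypeMatrix,
    Y: PhenotypeVector,
    config: PreprocConfig,
    seed: int = 0,
    k_sigma: float = 3.0,
) -> PipelineResult:
    """Run the enabled operations in the fixed order on a copy of the data.

    Missing entries (NaN) are mode-imputed first regardless of the
    configuration; the four optional steps then run in the order
    dedupe -> outlier -> scale -> resample.
    """
    check_aligned(G, Y)
    record = PipelineRecord(n_input=G.n_samples)
    record.imputed_cells = int(np.isnan(G.values).sum())
    G = impute_missing(G)
    Y = Y.copy()
    if config.dedupe:
        n0 = G.n_samples
        G, Y = remove_duplicates(G, Y)
        record.removed_duplicates = n0 - G.n_samples
    if config.outlier:
        n0 = G.n_samples
        G, Y = filter_outliers(G, Y, k_sigma=k_sigma)
        record.removed_outliers = n0 - G.n_samples
    if config.scale:
        G = scale_features(G)
    if config.resample:
        n0 = G.n_samples
        G, Y = resample_smote(G, Y, k_neighbors=1, seed=seed)
        record.synthesized = G.n_samples - n0
    return PipelineResult(G, Y, record)
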