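"""Core in-memory containers for dosage cohorts.

A cohort is a samples x loci matrix of allele dosages plus a binary
phenotype.  Dosages count alternate (or minor) alleles at a biallelic
locus, so every entry lies in {0, 1, 2} until a pipeline step (feature
scaling, SMOTE interpolation) makes the matrix real-valued.  The locus
order of a matrix is the canonical feature order for every downstream
vector (explanation vectors, verifier features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "PhenotypeVector", "DOSAGE_VALUES"]

DOSAGE_VALUES = (0, 1, 2)


@dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix with sample and locus identifiers.

    Parameters
    ----------
    values
        ``(n_samples, n_loci)`` array.  Integer-valued in {0, 1, 2} for
        raw and LDP-perturbed data; real-valued after scaling or
        resampling.  ``NaN`` marks a missing genotype awaiting
        imputation.
    sample_ids
        Unique row identifiers, one per sample.
    locus_ids
        Unique, *ordered* column identifiers, one per locus.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    locus_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x loci array")
        n, m = self.values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if self.locus_ids is None:
            self.locus_ids = [f"locus{j}" for j in range(m)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"sample_ids length {len(self.sample_ids)} != row count {n}"
            )
        if len(self.locus_ids) != m:
            raise ValueError(
                f"locus_ids length {len(self.locus_ids)} != column count {m}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def is_dosage(self) -> bool:
        """True iff every (non-missing) entry is in {0, 1, 2}."""
        v = self.values
        finite = v[~np.isnan(v)]
        return bool(np.isin(finite, DOSAGE_VALUES).all())

    def require_dosage(self) -> None:
        """Raise ``ValueError`` naming the first non-ternary cell."""
        v = self.values
        bad = ~np.isin(v, DOSAGE_VALUES) & ~np.isnan(v)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-dosage entry {v[i, j]!r} at sample "
                f"{self.sample_ids[i]!r} (row {i}), locus "
                f"{self.locus_ids[j]!r} (column {j}); expected one of {DOSAGE_VALUES}"
            )

    def take_rows(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx].copy(),
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
        )

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx].copy(),
            list(self.sample_ids),
            [self.locus_ids[j] for j in idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(), list(self.sample_ids), list(self.locus_ids)
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a :class:`GenotypeMatrix`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")

    def __len__(self) -> int:
        return int(self.labels.shape[0])

    @property
    def case_fraction(self) -> float:
        return float(self.labels.mean()) if len(self) else float("nan")

    def take(self, idx: np.ndarray | list[int]) -> "PhenotypeVector":
        return PhenotypeVector(self.labels[np.asarray(idx)].copy())

    def copy(self) -> "PhenotypeVector":
        return PhenotypeVector(self.labels.copy())


def check_aligned(G: GenotypeMatrix, Y: PhenotypeVector) -> None:
    """Raise if the phenotype vector is not row-aligned with the matrix."""
    if len(Y) != G.n_samples:
        raise ValueError(
            f"phenotype length {len(Y)} does not match sample count {G.n_samples}"
        )
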