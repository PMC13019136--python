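"""Readers and writers for cohorts and wire artifacts.

Genotype matrices travel as delimited text: one row per sample, first
column ``sample_id``, remaining columns headed by locus ids (order
significant).  Phenotypes are two-column text (``sample_id,label``).
Explanation vectors and verification reports are JSON.  VCF import
converts GT fields of biallelic records to alternate-allele dosages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, PhenotypeVector
from .explain import ExplanationVector
from .protocol import SiteArtifact, VerificationReport

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_phenotypes",
    "read_phenotypes",
    "import_vcf",
    "write_artifact",
    "read_artifact",
    "write_report",
]

logger = logging.getLogger("fedprint")


def write_matrix(G: GenotypeMatrix, path: str | Path, sep: str = ",") -> None:
    values = G.values
    # integer dosages are written as integers (compact, loss-free)
    if not np.isnan(values).any() and np.all(values == np.round(values)):
        values = values.astype(int)
    df = pd.DataFrame(values, columns=G.locus_ids)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep=sep, index=False)


def read_matrix(path: str | Path, sep: str = ",") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    ids = df["sample_id"].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample_id {dup[0]!r}")
    values = df.drop(columns="sample_id").to_numpy(dtype=float)
    return GenotypeMatrix(values, ids, [str(c) for c in df.columns[1:]])


def write_phenotypes(
    Y: PhenotypeVector, sample_ids: list[str], path: str | Path, sep: str = ","
) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": Y.labels}).to_csv(
        path, sep=sep, index=False
    )


def read_phenotypes(
    path: str | Path, sample_ids: list[str] | None = None, sep: str = ","
) -> PhenotypeVector:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if sample_ids is not None:
        df = df.set_index("sample_id").loc[sample_ids].reset_index()
    return PhenotypeVector(df["label"].to_numpy(dtype=int))


def import_vcf(
    path: str | Path, samples: list[str] | None = None
) -> GenotypeMatrix:
    """Build a dosage matrix from the GT fields of a VCF.

    Dosage is the alternate-allele count (0/0 -> 0, 0/1 -> 1, 1/1 -> 2);
    missing genotypes become NaN for downstream mode imputation.
    Multiallelic records are skipped with a logged count.  Locus ids are
    CHROM:POS:REF:ALT for traceability.
    """
    from cyvcf2 import VCF  # deferred: only VCF import needs it

    vcf = VCF(str(path), samples=samples)
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        columns.append(col)
        locus_ids.append(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
    vcf.close()
    if n_multi:
        logger.warning("import_vcf: skipped %d multiallelic record(s)", n_multi)
    if not columns:
        raise ValueError(f"{path}: no biallelic records with GT fields")
    return GenotypeMatrix(np.column_stack(columns), sample_ids, locus_ids)


def write_artifact(artifact: SiteArtifact, directory: str | Path) -> Path:
    """Serialize one site upload: JSON metadata + delimited matrix."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(artifact.perturbed, directory / "matrix.csv")
    write_phenotypes(
        artifact.phenotypes, artifact.perturbed.sample_ids, directory / "phenotypes.csv"
    )
    meta = {
        "site_id": artifact.site_id,
        "epsilon": artifact.epsilon,
        "explanation": artifact.explanation.to_dict(),
    }
    out = directory / "artifact.json"
    out.write_text(json.dumps(meta, indent=1))
    return out


def read_artifact(directory: str | Path) -> SiteArtifact:
    directory = Path(directory)
    meta = json.loads((directory / "artifact.json").read_text())
    G = read_matrix(directory / "matrix.csv")
    Y = read_phenotypes(directory / "phenotypes.csv", G.sample_ids)
    return SiteArtifact(
        site_id=meta["site_id"],
        perturbed=G,
        phenotypes=Y,
        explanation=ExplanationVector.from_dict(meta["explanation"]),
        epsilon=float(meta["epsilon"]),
    )


def write_report(report: VerificationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
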