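"""Input/output, validation, and gene-level filtering.

Genotype matrices are stored as minor-allele copy counts: on load, any
variant whose counted allele has sample frequency above 0.5 is recoded
(count -> 2 - count) so that the counted allele is always the minor one.
This makes the per-variant MAF the frequency of the counted allele, which
is what the variable-threshold inclusion rule operates on.

Formats
-------
* genotype TSV matrix: header row of variant ids, first column subject id,
  tab-separated integer counts in {0, 1, 2};
* VCF: biallelic SNVs with a GT field (via cyvcf2), converted to alternate
  allele counts and then minor-allele recoded;
* annotation TSV: columns ``variant_id, gene, is_nonsynonymous,
  sift_score, polyphen_score`` (empty cell = missing score);
* phenotype TSV: columns ``subject_id, status`` with status in {0, 1}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

ANNOTATION_COLUMNS = ["variant_id", "gene", "is_nonsynonymous", "sift_score", "polyphen_score"]


@dataclass
class GenotypeMatrix:
    """Subjects x variants matrix of minor-allele copy counts.

    Attributes
    ----------
    subject_ids, variant_ids : lists of identifiers
    counts : int array (n_subjects, n_variants) with entries in {0, 1, 2}
    maf : per-variant minor allele frequency in [0, 0.5]
    """

    subject_ids: list[str]
    variant_ids: list[str]
    counts: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, m = self.counts.shape
        if n != len(self.subject_ids) or m != len(self.variant_ids):
            raise ValidationError("counts shape does not match id lists")
        if not np.isin(self.counts, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.counts, (0, 1, 2)))[0]
            raise ValidationError(
                f"genotype count outside {{0,1,2}} at subject "
                f"{self.subject_ids[bad[0]]!r}, variant {self.variant_ids[bad[1]]!r}"
            )
        if self.maf is None:
            self.maf = self._compute_maf(self.counts)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @staticmethod
    def _compute_maf(counts: np.ndarray) -> np.ndarray:
        f = counts.sum(axis=0) / (2.0 * counts.shape[0])
        return np.minimum(f, 1.0 - f)

    @classmethod
    def from_counts(
        cls,
        subject_ids: Sequence[str],
        variant_ids: Sequence[str],
        counts: np.ndarray,
        recode_minor: bool = True,
    ) -> "GenotypeMatrix":
        """Build a matrix, recoding columns so the counted allele is minor."""
        counts = np.asarray(counts, dtype=np.int16)
        if recode_minor and counts.size:
            f = counts.sum(axis=0) / (2.0 * counts.shape[0])
            flip = f > 0.5
            if flip.any():
                counts = counts.copy()
                counts[:, flip] = 2 - counts[:, flip]
        return cls(list(subject_ids), list(variant_ids), counts)

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]


@dataclass
class PhenotypeVector:
    """Binary phenotype aligned to a subject list (0 = control, 1 = case)."""

    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.values) != len(self.subject_ids):
            raise ValidationError("phenotype length does not match subject ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("phenotype values must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def mean(self) -> float:
        """Fraction of cases."""
        return float(self.values.mean())

    @property
    def n_cases(self) -> int:
        return int(self.values.sum())


# A GeneIndex maps gene -> ordered array of variant column indices.
GeneIndex = Mapping[str, np.ndarray]


def read_genotypes(path: str | Path, format: str = "tsv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix from a TSV matrix or a VCF.

    Counts are recoded to minor-allele copies; per-variant MAF is computed
    from the loaded sample. Missing genotypes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv_matrix":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        variant_ids = header[1:]
        if not variant_ids:
            raise ParseError(f"{path}: header has no variant columns")
        subject_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(header)}"
                )
            subject_ids.append(row[0])
            try:
                rows.append([int(x) for x in row[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer genotype ({exc})") from None
        if not rows:
            raise ParseError(f"{path}: no genotype rows")
    return GenotypeMatrix.from_counts(subject_ids, variant_ids, np.array(rows, dtype=np.int16))


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires cyvcf2 (install vtcombine[vcf])") from exc
    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            raise ValidationError(f"only biallelic SNVs supported: {v.CHROM}:{v.POS}")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        if (gt == 2).any():
            raise ValidationError(f"missing genotype at {v.CHROM}:{v.POS}; not supported")
        columns.append(np.where(gt == 3, 2, gt))
        variant_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if not columns:
        raise ParseError(f"{path}: VCF contains no variants")
    counts = np.column_stack(columns)
    return GenotypeMatrix.from_counts(subject_ids, variant_ids, counts)


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    """Read a two-column TSV of subject id and case/control status."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns subject_id and status")
    return PhenotypeVector(df.iloc[:, 0].tolist(), df.iloc[:, 1].to_numpy())


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the variant annotation table.

    Returns a DataFrame with columns ``variant_id, gene, is_nonsynonymous,
    sift_score, polyphen_score``; missing scores are NaN. Scores, when
    present, must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: annotation missing columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["is_nonsynonymous"] = df["is_nonsynonymous"].astype(bool)
    return validate_annotation(df)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check score ranges; synonymous variants may carry missing scores freely."""
    for col in ("sift_score", "polyphen_score"):
        s = annotation[col].astype(float)
        bad = s.notna() & ((s < 0) | (s > 1))
        if bad.any():
            vid = annotation.loc[bad, "variant_id"].iloc[0]
            raise ValidationError(f"{col} outside [0,1] for variant {vid!r}")
        annotation[col] = s
    return annotation


def build_gene_index(
    annotation: pd.DataFrame, variant_ids: Sequence[str] | None = None
) -> dict[str, np.ndarray]:
    """Map each gene to the ordered column indices of its variants.

    Indices refer to positions in ``variant_ids`` (default: the annotation's
    own row order). Variant order within each gene follows the annotation.
    """
    if variant_ids is None:
        pos = {v: i for i, v in enumerate(annotation["variant_id"])}
    else:
        pos = {v: i for i, v in enumerate(variant_ids)}
    index: dict[str, list[int]] = {}
    for vid, gene in zip(annotation["variant_id"], annotation["gene"]):
        if vid not in pos:
            raise ValidationError(f"annotated variant {vid!r} absent from genotype matrix")
        index.setdefault(gene, []).append(pos[vid])
    return {g: np.array(ix, dtype=np.intp) for g, ix in index.items()}


def filter_genes(
    annotation: pd.DataFrame | Mapping[str, Sequence[int]],
    min_snps: int = 2,
    variant_ids: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Drop genes with fewer than ``min_snps`` variants.

    Accepts either an annotation table (a gene index is built first) or an
    existing gene index. Variant order within retained genes is preserved.
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    if isinstance(annotation, pd.DataFrame):
        index = build_gene_index(annotation, variant_ids)
    else:
        index = {g: np.asarray(ix, dtype=np.intp) for g, ix in annotation.items()}
    return {g: ix for g, ix in index.items() if len(ix) >= min_snps}


def gene_size_summary(gene_index: GeneIndex) -> dict[str, float]:
    """Five-number summary (min, q25, median, q75, max) of variants per gene.

    Quartiles use linear interpolation (numpy's default, R type-7).
    """
    if not gene_index:
        raise ValueError("gene index is empty")
    sizes = np.array([len(ix) for ix in gene_index.values()], dtype=float)
    q = np.percentile(sizes, [0, 25, 50, 75, 100])
    return {"min": q[0], "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]}


RESULT_COLUMNS = ["gene", "scheme", "z_max", "threshold", "p_value", "n_snps", "n_nonsyn"]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write per-gene, per-scheme test results as a TSV.

    Columns: gene, scheme, z_max, threshold, p_value, n_snps, n_nonsyn,
    plus a trailing mid_p column (tie-corrected permutation p, preferred
    input for downstream p-value combination).
    """
    if not len(results):
        raise ValueError("no results to write")
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "scheme": r.scheme,
                "z_max": r.z_max,
                "threshold": r.best_threshold,
                "p_value": r.p_value,
                "n_snps": r.n_snps,
                "n_nonsyn": r.n_nonsyn,
                "mid_p": getattr(r, "mid_p", float("nan")),
            }
        )
    cols = RESULT_COLUMNS + ["mid_p"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: results missing columns {missing}")
    return df


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype matrix in the TSV dialect read_genotypes expects."""
    df = pd.DataFrame(
        genotypes.counts, index=genotypes.subject_ids, columns=genotypes.variant_ids
    )
    df.to_csv(path, sep="\t", index_label="subject_id")


def write_phenotypes(phenotype: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"subject_id": phenotype.subject_ids, "status": phenotype.values}).to_csv(
        path, sep="\t", index=False
    )


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)
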