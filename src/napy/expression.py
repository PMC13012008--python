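"""Expression matrix container, I/O, log transformation and gene-wise z-scaling.

Expression values are handled on three scales, tracked by a ``scale_tag``:
raw TPM (``tpm``), log2(TPM+1) (``log2_tpm1``) and gene-wise z-scores
(``zscore``).  Scaling is split into separate fit and apply steps so that
parameters estimated on a training cohort can be frozen and applied to new
samples without leaking test-set information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    IdentifierError,
    InsufficientDataError,
    MatrixParseError,
    MissingGeneError,
)

SCALE_TAGS = ("tpm", "log2_tpm1", "zscore")


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix with identifier-based addressing.

    Parameters
    ----------
    values
        DataFrame with gene IDs as the index and sample IDs as columns.
    scale_tag
        One of ``tpm``, ``log2_tpm1`` or ``zscore``.
    """

    values: pd.DataFrame
    scale_tag: str = "log2_tpm1"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise DomainError(f"unknown scale_tag {self.scale_tag!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate gene identifiers: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise DomainError("expression matrix contains non-finite values")
        if self.scale_tag == "tpm" and arr.size and (arr < 0).any():
            raise DomainError("TPM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise IdentifierError(f"unknown sample identifiers: {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale_tag)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise MissingGeneError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.scale_tag)


@dataclass
class GeneScalingParams:
    """Per-gene mean and sample standard deviation (n-1 denominator).

    ``zero_variance`` flags genes whose sd is exactly zero; those genes map
    to z = 0 everywhere when the parameters are applied.
    """

    mean: pd.Series
    sd: pd.Series
    zero_variance: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = self.sd == 0.0
        if not ((self.sd == 0.0) == self.zero_variance).all():
            raise DomainError("zero_variance flags inconsistent with sd values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mean.index)


def read_expression(path, delimiter: str = "\t", scale_tag: str = "log2_tpm1") -> ExpressionMatrix:
    """Read a delimited gene-by-sample matrix (first column gene IDs, header sample IDs).

    Lines starting with ``#`` are treated as comments and skipped.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#",
                         dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixParseError(f"could not parse {path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell at gene {df.index[gi]!r}, sample {df.columns[si]!r} "
            f"(value {df.iat[gi, si]!r})"
        )
    return ExpressionMatrix(numeric.astype(float), scale_tag)


def write_expression(m: ExpressionMatrix, path, delimiter: str = "\t",
                     header_comment: str | None = None) -> None:
    """Write a matrix as delimited text, optionally with a ``#`` header line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.values.to_csv(fh, sep=delimiter, index_label="gene_id")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transformation; requires a ``tpm``-scale matrix."""
    if m.scale_tag != "tpm":
        raise DomainError(f"log_transform expects scale_tag 'tpm', got {m.scale_tag!r}")
    if m.values.size and (m.values.to_numpy() < 0).any():
        raise DomainError("negative TPM value in log_transform input")
    return ExpressionMatrix(np.log2(m.values + 1.0), "log2_tpm1")


def fit_gene_scaling(m: ExpressionMatrix) -> GeneScalingParams:
    """Estimate per-gene mean and sample sd (denominator n-1) from a cohort."""
    if m.n_samples < 2:
        raise InsufficientDataError(
            f"gene scaling needs >= 2 samples, got {m.n_samples}"
        )
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=1)
    return GeneScalingParams(mean=mean, sd=sd)


def apply_gene_scaling(m: ExpressionMatrix, p: GeneScalingParams) -> ExpressionMatrix:
    """z = (v - mean) / sd per gene; zero-variance genes map to 0.

    The parameters may come from a different (training) cohort than ``m``.
    """
    missing = m.values.index.difference(p.mean.index)
    if len(missing):
        raise MissingGeneError(f"genes missing from scaling parameters: {list(missing)}")
    mean = p.mean.reindex(m.values.index)
    sd = p.sd.reindex(m.values.index)
    safe_sd = sd.replace(0.0, 1.0)
    z = m.values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[sd == 0.0] = 0.0
    return ExpressionMatrix(z, "zscore")


def zscore_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convenience: fit and apply gene scaling on the same cohort."""
    return apply_gene_scaling(m, fit_gene_scaling(m))
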