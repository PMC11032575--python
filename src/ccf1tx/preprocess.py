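"""Expression-matrix filtering, sequencing PCs and covariate residualization.

Implements the standard bulk RNA-seq preprocessing the downstream analyses
assume: removal of genes not expressed in enough samples, principal
components of per-sample sequencing QC metrics ("Seq.PCs"), and per-gene
ordinary-least-squares residualization of log2 expression against the
model ``expression ~ line + genotype + sex + age + Seq.PC1..5``.

Which terms are regressed out is configurable because the factors removed
for one analysis (e.g. sequencing PCs) are the factors tested by another
(genotype, age, sex): differential-expression and network stages should
residualize technical terms only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "RegressionFit",
    "DEFAULT_FORMULA_TERMS",
    "TECHNICAL_TERMS",
    "filter_low_expressed",
    "compute_seq_pcs",
    "log2_transform",
    "regress_covariates",
]

CATEGORICAL_TERMS = ("line", "genotype", "sex")
NUMERIC_TERMS = ("age_months",)
SEQ_PC_TERMS = tuple(f"seq_pc_{i}" for i in range(1, 6))

#: The full stated covariate model.
DEFAULT_FORMULA_TERMS = CATEGORICAL_TERMS + NUMERIC_TERMS + SEQ_PC_TERMS
#: Technical-only subset appropriate before testing biological factors.
TECHNICAL_TERMS = SEQ_PC_TERMS


@dataclass
class SampleMetadata:
    """Validated per-sample annotation table."""

    table: pd.DataFrame

    GENOTYPES = ("WT", "5x")
    SEXES = ("F", "M")
    AGES = (4, 12)

    def __post_init__(self):
        t = self.table
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if not t["genotype"].isin(self.GENOTYPES).all():
            raise ValueError(f"genotype must be one of {self.GENOTYPES}")
        if not t["sex"].isin(self.SEXES).all():
            raise ValueError(f"sex must be one of {self.SEXES}")
        if not t["age_months"].isin(self.AGES).all():
            raise ValueError(f"age_months must be one of {self.AGES}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with an attached metadata table.

    ``transform`` records the scale: ``"tpm"`` for raw TPM, ``"log2"`` for
    log2(TPM + 1) or any additive log2 scale.
    """

    values: pd.DataFrame
    transform: str = "tpm"
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if self.metadata is not None:
            meta_ids = set(self.metadata["sample_id"])
            missing = [s for s in self.values.columns if s not in meta_ids]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def aligned_metadata(self) -> pd.DataFrame:
        if self.metadata is None:
            raise ValueError("no metadata attached")
        return (
            self.metadata.set_index("sample_id")
            .loc[self.values.columns]
            .rename_axis("sample_id")
            .reset_index()
        )


def filter_low_expressed(
    matrix: ExpressionMatrix,
    expressed_min_frac: float = 0.2,
    expressed_tpm_min: float = 0.1,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes not expressed in enough samples.

    A gene is retained iff TPM > ``expressed_tpm_min`` in strictly more than
    ``expressed_min_frac`` of samples (the default reproduces "not expressed
    in 80% of the samples" removal).  Returns the filtered matrix and the
    removed gene IDs.
    """
    if matrix.transform != "tpm":
        raise ValueError("low-expression filtering expects a TPM-scale matrix")
    frac = (matrix.values > expressed_tpm_min).mean(axis=1)
    keep = frac > expressed_min_frac
    removed = matrix.values.index[~keep].tolist()
    if keep.sum() == 0:
        raise ValueError(
            "all genes removed by the low-expression filter; "
            "review expressed_tpm_min / expressed_min_frac"
        )
    return (
        ExpressionMatrix(matrix.values.loc[keep], matrix.transform, matrix.metadata),
        removed,
    )


def compute_seq_pcs(qc_metrics: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Principal-component scores of z-scored sequencing QC metrics.

    Columns are metrics, rows samples.  Constant metric columns are dropped
    with a warning.  The sign of each component is fixed so its
    largest-magnitude loading is positive, making reruns identical.
    Returns a samples x ``seq_pc_1..k`` DataFrame.
    """
    X = qc_metrics.astype(float)
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant QC metrics: {constant}")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        # no sample-to-sample QC variation at all: every PC score is zero
        return pd.DataFrame(
            0.0, index=qc_metrics.index, columns=[f"seq_pc_{i + 1}" for i in range(k)]
        )
    if X.shape[1] < k:
        raise ValueError(f"need >= {k} non-constant metrics, have {X.shape[1]}")
    if X.shape[0] < k + 1:
        raise ValueError(f"need >= {k + 1} samples, have {X.shape[0]}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z.values)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=qc_metrics.index, columns=[f"seq_pc_{i + 1}" for i in range(k)]
    )


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform."""
    if matrix.transform == "log2":
        return matrix
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), "log2", matrix.metadata
    )


@dataclass
class RegressionFit:
    """Design matrix and per-gene coefficients of a covariate regression."""

    design: pd.DataFrame  # samples x design columns (incl. intercept)
    coefficients: pd.DataFrame = field(default=None)  # genes x design columns


def build_design(metadata: pd.DataFrame, terms) -> pd.DataFrame:
    """Dummy-coded (treatment/reference) design matrix with intercept."""
    cols = {"intercept": np.ones(len(metadata))}
    for term in terms:
        if term not in metadata.columns:
            raise KeyError(f"term {term!r} not in metadata")
        col = metadata[term]
        if term in CATEGORICAL_TERMS:
            levels = sorted(col.unique())
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (col == lev).to_numpy(dtype=float)
        else:
            cols[term] = col.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=metadata["sample_id"])
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        aliased = _find_aliased(design.values, list(design.columns))
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return design


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    aliased = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, kept + [j]])
        if r > rank:
            kept.append(j)
            rank = r
        else:
            aliased.append(names[j])
    return aliased


def regress_covariates(
    matrix: ExpressionMatrix,
    terms=DEFAULT_FORMULA_TERMS,
    metadata: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, RegressionFit]:
    """OLS-residualize each gene against the covariate design.

    Fits log2 expression on the dummy-coded design per gene and returns the
    residuals with each gene's grand mean added back (so the matrix stays on
    an interpretable log2 scale), plus the design and coefficient table.
    """
    if matrix.transform != "log2":
        matrix = log2_transform(matrix)
    meta = metadata if metadata is not None else matrix.aligned_metadata()
    meta = (
        meta.set_index("sample_id")
        .loc[matrix.samples]
        .rename_axis("sample_id")
        .reset_index()
    )
    design = build_design(meta, terms)
    X = design.values
    Y = matrix.values.values.T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    grand_mean = matrix.values.mean(axis=1).values
    out = pd.DataFrame(
        resid.T + grand_mean[:, None],
        index=matrix.values.index,
        columns=matrix.values.columns,
    )
    fit = RegressionFit(
        design=design,
        coefficients=pd.DataFrame(
            beta.T, index=matrix.values.index, columns=design.columns
        ),
    )
    return ExpressionMatrix(out, "log2", matrix.metadata), fit
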