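"""Two-group differential expression, strain-divergence matrices and
conserved-DEG intersection.

The test is a per-gene Welch two-sample t on log2 expression with
Benjamini-Hochberg FDR control; a gene is called a DEG at
|log2 fold change| > 1 and FDR < 0.05.  The fold change is the difference
of group means on the log2 scale (group2 minus group1).  The test function
is isolated so a negative-binomial variant could be swapped in without
touching the thresholding, pairwise-matrix or intersection logic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix, log2_transform

__all__ = [
    "DEResult",
    "de_test",
    "deg_count_matrix",
    "conserved_degs",
]

DEFAULT_LFC = 1.0
DEFAULT_FDR = 0.05

CLASS_NS = "NS"
CLASS_FC_ONLY = "FC-only"
CLASS_FDR_ONLY = "FDR-only"
CLASS_DEG = "DEG"


@dataclass
class DEResult:
    """Per-gene differential expression table for one two-group comparison.

    ``table`` columns: log2_fc (group2 - group1), statistic, p_value, fdr,
    de_class.  ``de_class`` follows the volcano-plot partition: DEG
    (|log2FC| > lfc and FDR < fdr), FC-only, FDR-only, NS.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    lfc_thresh: float = DEFAULT_LFC
    fdr_thresh: float = DEFAULT_FDR

    def deg_genes(self) -> pd.Index:
        return self.table.index[self.table["de_class"] == CLASS_DEG]

    def deg_signs(self) -> pd.Series:
        """+1 / -1 direction of each DEG's fold change."""
        degs = self.deg_genes()
        return np.sign(self.table.loc[degs, "log2_fc"])


def _classify(lfc: np.ndarray, fdr: np.ndarray, lfc_thresh: float, fdr_thresh: float):
    big_fc = np.abs(lfc) > lfc_thresh
    sig = fdr < fdr_thresh
    out = np.full(len(lfc), CLASS_NS, dtype=object)
    out[big_fc & ~sig] = CLASS_FC_ONLY
    out[~big_fc & sig] = CLASS_FDR_ONLY
    out[big_fc & sig] = CLASS_DEG
    return out


def de_test(
    matrix,
    group_labels,
    group_order: tuple[str, str] | None = None,
    lfc_thresh: float = DEFAULT_LFC,
    fdr_thresh: float = DEFAULT_FDR,
) -> DEResult:
    """Welch two-sample t per gene with BH FDR.

    ``matrix`` is an :class:`ExpressionMatrix` (log2-transformed if needed)
    or a plain genes x samples DataFrame already on the log2 scale.
    ``group_labels`` aligns to the samples and must contain exactly two
    levels; log2FC is group2 minus group1 (alphabetical unless
    ``group_order`` is given).  Genes with zero variance in both groups and
    equal means get statistic 0 and p 1.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = log2_transform(matrix).values
    else:
        values = matrix
    labels = pd.Series(np.asarray(group_labels), index=values.columns)
    levels = sorted(labels.unique()) if group_order is None else list(group_order)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g1, g2 = levels
    a = values.loc[:, labels[labels == g1].index].values
    b = values.loc[:, labels[labels == g2].index].values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate genes (zero variance in both groups): identical means are a
    # certain null, differing means a certain difference
    bad = ~np.isfinite(p)
    if bad.any():
        same = bad & (np.abs(lfc) < 1e-12)
        p[same] = 1.0
        stat[same] = 0.0
        diff = bad & ~same
        p[diff] = 0.0
        stat[diff] = np.sign(lfc[diff]) * np.inf
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "statistic": stat,
            "p_value": p,
            "fdr": fdr,
            "de_class": _classify(lfc, fdr, lfc_thresh, fdr_thresh),
        },
        index=values.index,
    )
    return DEResult(table, group1=g1, group2=g2, lfc_thresh=lfc_thresh,
                    fdr_thresh=fdr_thresh)


def deg_count_matrix(
    matrix,
    metadata: pd.DataFrame,
    group_col: str = "line",
    stratify_by: str | None = None,
    lfc_thresh: float = DEFAULT_LFC,
    fdr_thresh: float = DEFAULT_FDR,
):
    """Symmetric lines x lines matrix of pairwise DEG counts.

    For every unordered pair of levels of ``group_col`` the two-group test
    is run on their samples and the DEG count recorded.  Levels with fewer
    than 2 samples are excluded with a warning.  ``stratify_by="sex"``
    returns a dict of per-stratum matrices instead.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = log2_transform(matrix).values
        meta = metadata.set_index("sample_id").loc[values.columns]
    else:
        values = matrix
        meta = metadata.set_index("sample_id").loc[values.columns]

    if stratify_by is not None:
        out = {}
        for stratum, sub in meta.groupby(stratify_by):
            out[stratum] = deg_count_matrix(
                values.loc[:, sub.index],
                sub.rename_axis("sample_id").reset_index(),
                group_col=group_col,
                stratify_by=None, lfc_thresh=lfc_thresh, fdr_thresh=fdr_thresh,
            )
        return out

    counts = meta[group_col].value_counts()
    usable = sorted(counts.index[counts >= 2])
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        warnings.warn(f"excluding {group_col} levels with < 2 samples: {dropped}")
    if len(usable) < 2:
        raise ValueError(f"need >= 2 {group_col} levels with >= 2 samples")

    mat = pd.DataFrame(0, index=usable, columns=usable, dtype=int)
    for l1, l2 in itertools.combinations(usable, 2):
        samples = meta.index[meta[group_col].isin([l1, l2])]
        res = de_test(
            values.loc[:, samples], meta.loc[samples, group_col],
            group_order=(l1, l2), lfc_thresh=lfc_thresh, fdr_thresh=fdr_thresh,
        )
        n = len(res.deg_genes())
        mat.loc[l1, l2] = n
        mat.loc[l2, l1] = n
    return mat


def conserved_degs(de_results: list[DEResult]) -> set[str]:
    """Genes called DEG with concordant direction in every comparison."""
    if len(de_results) < 2:
        raise ValueError("need at least two DE result sets")
    common = set(de_results[0].deg_genes())
    for res in de_results[1:]:
        common &= set(res.deg_genes())
    conserved = set()
    for g in common:
        signs = {int(np.sign(r.table.loc[g, "log2_fc"])) for r in de_results}
        if len(signs) == 1:
            conserved.add(g)
    return conserved
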