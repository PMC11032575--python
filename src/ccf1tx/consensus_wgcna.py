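"""Consensus signed weighted gene co-expression network analysis.

The pipeline: biweight midcorrelation between all gene pairs, signed
soft-threshold adjacency ``a_ij = ((1 + cor_ij)/2)^beta``, topological
overlap, quantile-scaled component-wise-minimum consensus across datasets,
average-linkage clustering of ``1 - TOM`` with a dynamic branch cut, module
merging by eigengene correlation, kME-based membership pruning and
module-trait correlation.

Module labels follow the conventional color naming, assigned in decreasing
module size (turquoise, blue, brown, ...); unassigned genes are "grey".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NetworkConfig",
    "ModuleAssignment",
    "MODULE_COLORS",
    "UNASSIGNED",
    "bicor_matrix",
    "signed_adjacency",
    "signed_tom",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_cor",
]

UNASSIGNED = "grey"

#: Conventional module color order (largest module first).
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

#: deep_split sensitivity -> quantile of within-branch merge-height gaps a
#: branch's top gap must exceed before the branch is split further.
_DEEP_SPLIT_GAP_QUANTILE = {0: 0.95, 1: 0.85, 2: 0.75, 3: 0.65, 4: 0.55}


@dataclass
class NetworkConfig:
    """Network construction parameters.

    ``beta=16`` is the soft power used for the age/sex consensus network and
    ``beta=14`` for the genotype network; ``merge_thresh`` is 0.25 and 0.2
    respectively.  The defaults reproduce the age/sex configuration.
    """

    beta: float = 16.0
    consensus_quantile: float = 0.2
    deep_split: int = 4
    cut_height: float = 0.999
    min_module_size: int = 100
    merge_thresh: float = 0.25
    kme_min: float = 0.7
    pam_stage: bool = False

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.consensus_quantile < 1:
            raise ValueError("consensus_quantile must be in (0, 1)")
        for name in ("cut_height", "merge_thresh", "kme_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.deep_split not in _DEEP_SPLIT_GAP_QUANTILE:
            raise ValueError("deep_split must be 0..4")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.pam_stage:
            raise NotImplementedError("PAM reassignment stage is not implemented")


# ---------------------------------------------------------------------------
# Correlation, adjacency, TOM
# ---------------------------------------------------------------------------

def bicor_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs.

    For each gene vector x: ``u_i = (x_i - med(x)) / (9 MAD(x))``,
    weights ``w_i = (1 - u_i^2)^2 1[|u_i| < 1]``, transformed values
    ``x~_i = (x_i - med(x)) w_i``; the correlation is the normalized inner
    product of transformed vectors.  Genes with MAD 0 fall back to Pearson
    (mean-centering, unit weights) with a warning; constant genes are
    dropped with a warning.
    """
    X = matrix.values.astype(float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("need >= 4 samples for robust correlation")

    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant genes: "
            f"{list(matrix.index[constant][:5])}..."
        )
        X = X[~constant]
        matrix = matrix.loc[~constant]

    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} genes have MAD 0; using Pearson fallback"
        )
    centered = X - med
    with np.errstate(divide="ignore", invalid="ignore"):
        u = centered / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = centered * w
    if zero_mad.any():
        xt[zero_mad] = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xt, axis=1, keepdims=True)
    xt = xt / norms
    C = np.clip(xt @ xt.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=matrix.index, columns=matrix.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency ``((1 + cor)/2)^beta`` with zero diagonal."""
    c = cor.values if isinstance(cor, pd.DataFrame) else np.asarray(cor, dtype=float)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def signed_tom(cor: pd.DataFrame | np.ndarray, beta: float) -> pd.DataFrame:
    """Topological overlap of the signed adjacency.

    ``tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    unit diagonal; values lie in [0, 1].
    """
    idx = cor.index if isinstance(cor, pd.DataFrame) else None
    a = signed_adjacency(cor, beta)
    k = a.sum(axis=1)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if idx is not None:
        return pd.DataFrame(tom, index=idx, columns=idx)
    return pd.DataFrame(tom)


def consensus_tom(
    toms: list[pd.DataFrame], quantile: float = 0.2
) -> pd.DataFrame:
    """Component-wise minimum of quantile-scaled TOMs.

    Each dataset's TOM is power-scaled so the chosen quantile of its
    off-diagonal values matches the first dataset
    (``TOM_s ** (log q_1 / log q_s)``), keeping values within [0, 1]; the
    consensus is the element-wise minimum of the scaled matrices.
    """
    if not toms:
        raise ValueError("no TOMs provided")
    genes = toms[0].index
    for t in toms[1:]:
        if not t.index.equals(genes):
            raise ValueError("TOMs must share an identical gene set and order")
    mask = ~np.eye(len(genes), dtype=bool)
    qs = [float(np.quantile(t.values[mask], quantile)) for t in toms]
    if any(q <= 0 for q in qs):
        raise ValueError("degenerate network: TOM quantile is zero")
    scaled = [toms[0].values]
    for t, q in zip(toms[1:], qs[1:]):
        exponent = np.log(qs[0]) / np.log(q)
        scaled.append(np.clip(t.values**exponent, 0.0, 1.0))
    cons = np.minimum.reduce(scaled)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=genes, columns=genes)


# ---------------------------------------------------------------------------
# Dynamic branch cutting
# ---------------------------------------------------------------------------

def _subtree_leaves(node) -> list[int]:
    return node.pre_order(lambda n: n.id) if not node.is_leaf() else [node.id]


def _internal_nodes(node) -> list:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.is_leaf():
            out.append(n)
            stack.extend((n.left, n.right))
    return out


def _branch_gaps(internal) -> np.ndarray:
    gaps = []
    for n in internal:
        child_max = max(
            n.left.dist if not n.left.is_leaf() else 0.0,
            n.right.dist if not n.right.is_leaf() else 0.0,
        )
        gaps.append(n.dist - child_max)
    return np.asarray(gaps)


def _dynamic_cut(Z: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Dynamic branch cut of an average-linkage dendrogram.

    A static cut at ``cut_height`` yields initial branches; each branch is
    then recursively split whenever the merge-height gap at its top exceeds
    the deep_split-mapped quantile of the gaps within the branch.  A split
    that would leave one side below ``min_module_size`` instead peels that
    side off as unassigned while the larger side is revisited; a split
    leaving both sides undersized is not taken.  Surviving branches of at
    least ``min_module_size`` genes become modules (labels 1..m in
    decreasing size); everything else is 0 (unassigned).
    """
    n = Z.shape[0] + 1
    q = _DEEP_SPLIT_GAP_QUANTILE[config.deep_split]
    root = hierarchy.to_tree(Z)

    # static branches: maximal subtrees merged entirely below cut_height
    static: list = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() or node.dist <= config.cut_height:
            static.append(node)
        else:
            stack.extend((node.left, node.right))

    modules: list[list[int]] = []

    def split(node) -> None:
        leaves = _subtree_leaves(node)
        if len(leaves) < config.min_module_size:
            return  # unassigned
        internal = _internal_nodes(node)
        if len(internal) < 3:
            modules.append(leaves)
            return
        gaps = _branch_gaps(internal)
        top_gap = gaps[0] if internal[0] is node else node.dist - max(
            node.left.dist if not node.left.is_leaf() else 0.0,
            node.right.dist if not node.right.is_leaf() else 0.0,
        )
        if top_gap <= np.quantile(gaps, q):
            modules.append(leaves)
            return
        left, right = node.left, node.right
        sizes = (left.count, right.count)
        small, big = (left, right) if sizes[0] <= sizes[1] else (right, left)
        if small.count >= config.min_module_size:
            split(big)
            split(small)
        elif big.count >= config.min_module_size:
            # peel the undersized side to unassigned, keep splitting the rest
            split(big)
        else:
            modules.append(leaves)

    for branch in static:
        split(branch)

    labels = np.zeros(n, dtype=int)
    modules.sort(key=len, reverse=True)
    for m, leaves in enumerate(modules, start=1):
        labels[leaves] = m
    return labels


# ---------------------------------------------------------------------------
# Eigengenes, kME, module detection
# ---------------------------------------------------------------------------

def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _stack_expression(expression_per_dataset) -> pd.DataFrame:
    """Concatenate datasets along samples after per-dataset z-scoring."""
    if isinstance(expression_per_dataset, pd.DataFrame):
        expression_per_dataset = [expression_per_dataset]
    parts = []
    for d, df in enumerate(expression_per_dataset):
        Z = pd.DataFrame(
            _zscore_rows(df.values.astype(float)), index=df.index,
            columns=[f"d{d}:{c}" for c in df.columns],
        )
        parts.append(Z)
    genes = parts[0].index
    for p in parts[1:]:
        if not p.index.equals(genes):
            raise ValueError("datasets must share an identical gene set and order")
    return pd.concat(parts, axis=1)


def module_eigengene(expression: pd.DataFrame, genes) -> pd.Series:
    """First principal component of the z-scored module submatrix.

    Returned as a unit-norm per-sample score vector with the sign fixed so
    the mean correlation of member genes with the eigengene is positive.
    """
    sub = _zscore_rows(expression.loc[genes].values.astype(float))
    # right singular vector = per-sample scores of PC1
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    me = vt[0]
    kme = _pearson_vs_vector(sub, me)
    if np.nanmean(kme) < 0:
        me = -me
    return pd.Series(me, index=expression.columns)


def _pearson_vs_vector(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(vc)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (Xc @ vc) / denom


@dataclass
class ModuleAssignment:
    """Gene-to-module labels with eigengenes, kME and trait correlations."""

    labels: pd.Series  # gene -> color label ("grey" = unassigned)
    eigengenes: pd.DataFrame  # modules x samples (unit-norm rows)
    kme: pd.DataFrame  # genes x modules (Pearson gene~eigengene)
    trait_cor: pd.DataFrame | None = None
    dendrogram: np.ndarray | None = field(default=None, repr=False)

    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()

    def genes_in(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def detect_modules(
    cons_tom: pd.DataFrame,
    config: NetworkConfig,
    expression_per_dataset,
) -> ModuleAssignment:
    """Cluster the consensus TOM into modules and summarize them.

    Steps: average-linkage clustering of ``1 - TOM``; dynamic branch cut
    (see :func:`_dynamic_cut`); iterative merging of modules whose eigengene
    dissimilarity ``1 - cor(ME)`` is below ``merge_thresh``; removal of
    genes whose own-module kME falls below ``kme_min``; color labels in
    decreasing module size.  Eigengenes and kME are computed on the
    per-dataset z-scored, sample-concatenated expression.
    """
    genes = cons_tom.index
    expr = _stack_expression(expression_per_dataset)
    expr = expr.loc[genes]

    if len(genes) < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return _empty_assignment(genes, expr.columns)

    dissim = 1.0 - cons_tom.values
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    labels = _dynamic_cut(Z, config)
    if labels.max() == 0:
        warnings.warn("no module exceeded min_module_size; all genes unassigned")
        return _empty_assignment(genes, expr.columns, dendrogram=Z)

    groups: dict[int, list[str]] = {
        m: list(genes[labels == m]) for m in range(1, labels.max() + 1)
    }

    # iterative eigengene-correlation merging
    while len(groups) > 1:
        mods = sorted(groups)
        mes = {m: module_eigengene(expr, groups[m]).values for m in mods}
        best, best_cor = None, -np.inf
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1 :]:
                r = float(np.corrcoef(mes[m1], mes[m2])[0, 1])
                if r > best_cor:
                    best_cor, best = r, (m1, m2)
        if 1.0 - best_cor < config.merge_thresh:
            m1, m2 = best
            groups[m1] = groups[m1] + groups.pop(m2)
        else:
            break

    # color labels by decreasing size
    ordered = sorted(groups.values(), key=len, reverse=True)
    color_of_gene = pd.Series(UNASSIGNED, index=genes, dtype=object)
    module_genes: dict[str, list[str]] = {}
    for i, members in enumerate(ordered):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        module_genes[color] = members
        color_of_gene.loc[members] = color

    # eigengenes, kME, pruning
    me_rows = {}
    for color, members in module_genes.items():
        me_rows[color] = module_eigengene(expr, members)
    eigengenes = pd.DataFrame(me_rows).T
    eigengenes = eigengenes.div(np.linalg.norm(eigengenes.values, axis=1), axis=0)

    Xz = _zscore_rows(expr.values.astype(float))
    kme = pd.DataFrame(
        {c: _pearson_vs_vector(Xz, eigengenes.loc[c].values) for c in eigengenes.index},
        index=genes,
    )
    for color in list(module_genes):
        members = pd.Index(module_genes[color])
        low = members[kme.loc[members, color] < config.kme_min]
        if len(low):
            color_of_gene.loc[low] = UNASSIGNED

    # drop modules emptied (or shrunk below size) by pruning, relabel by size
    surviving = [
        (color, list(color_of_gene.index[color_of_gene == color]))
        for color in module_genes
        if (color_of_gene == color).sum() >= max(3, 0)
    ]
    surviving.sort(key=lambda cm: len(cm[1]), reverse=True)
    final_labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    final_me = {}
    for i, (_, members) in enumerate(surviving):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        final_labels.loc[members] = color
        me = module_eigengene(expr, members)
        final_me[color] = me / np.linalg.norm(me.values)
    if not final_me:
        warnings.warn("all modules emptied by kME pruning; all genes unassigned")
        return _empty_assignment(genes, expr.columns, dendrogram=Z)
    eigengenes = pd.DataFrame(final_me).T
    kme = pd.DataFrame(
        {c: _pearson_vs_vector(Xz, eigengenes.loc[c].values) for c in eigengenes.index},
        index=genes,
    )
    return ModuleAssignment(
        labels=final_labels, eigengenes=eigengenes, kme=kme, dendrogram=Z
    )


def _empty_assignment(genes, samples, dendrogram=None) -> ModuleAssignment:
    return ModuleAssignment(
        labels=pd.Series(UNASSIGNED, index=genes, dtype=object),
        eigengenes=pd.DataFrame(columns=samples),
        kme=pd.DataFrame(index=genes),
        dendrogram=dendrogram,
    )


# ---------------------------------------------------------------------------
# Module-trait correlation
# ---------------------------------------------------------------------------

TRAIT_CODES = {
    "age_months": {4: 0.0, 12: 1.0},
    "sex": {"F": 0.0, "M": 1.0},
    "genotype": {"WT": 0.0, "5x": 1.0},
}


def encode_traits(metadata: pd.DataFrame, traits=("age_months", "sex", "genotype")) -> pd.DataFrame:
    """Numeric 0/1 coding of the standard biological traits."""
    out = {}
    for t in traits:
        col = metadata[t]
        coded = col.map(TRAIT_CODES[t]) if t in TRAIT_CODES else col.astype(float)
        out[t] = coded.to_numpy(dtype=float)
    return pd.DataFrame(out, index=pd.Index(metadata["sample_id"], name="sample_id"))


def module_trait_cor(
    assignment: ModuleAssignment,
    traits: pd.DataFrame,
    fdr_thresh: float = 0.05,
    r_min: float = 0.1,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    p-values come from the t distribution with n - 2 degrees of freedom and
    are BH-adjusted over the full module x trait table; a pair is flagged
    significant at FDR < 0.05 and |r| >= 0.1.
    """
    me = assignment.eigengenes
    if me.empty:
        raise ValueError("assignment has no modules")
    # eigengene columns carry a "d<i>:" dataset prefix when built from
    # stacked multi-dataset expression; strip it to match metadata sample IDs
    sample_ids = [
        c if c in traits.index else c.split(":", 1)[-1] for c in me.columns
    ]
    tr = traits.loc[sample_ids]
    rows = []
    n = me.shape[1]
    for module in me.index:
        for trait in tr.columns:
            x = tr[trait].to_numpy(dtype=float)
            if np.std(x) == 0:
                raise ValueError(f"trait {trait!r} is constant")
            r, p = stats.pearsonr(me.loc[module].values, x)
            rows.append((module, trait, r, p))
    table = pd.DataFrame(rows, columns=["module", "trait", "r", "p_value"])
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = (table["fdr"] < fdr_thresh) & (table["r"].abs() >= r_min)
    return table.set_index(["module", "trait"])
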