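"""Gene-set enrichment, gene-set eigengenes and module preservation.

Enrichment is a two-sided Fisher exact test of query-gene overlap against
named gene sets within a declared background universe, with BH FDR across
the collection; directional variants split a differential-expression result
into up- and down-regulated gene sets.  Module preservation compares a
reference co-expression network's modules against an independent test
dataset with permutation Z statistics for module density and intramodular
connectivity, summarized as Z_summary with the conventional interpretation
bands (< 2 not preserved, 2-5 moderate, 5-10 preserved, > 10 highly
preserved).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus_wgcna import signed_adjacency, bicor_matrix
from .diffexpr import DEResult

__all__ = [
    "GeneSetCollection",
    "PreservationResult",
    "read_gmt",
    "write_gmt",
    "fisher_enrich",
    "directional_overlap",
    "deg_module_correlation",
    "geneset_eigengene",
    "module_preservation",
]


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        self.universe = set(self.universe)
        harmonized = {}
        for name, genes in self.sets.items():
            inter = set(genes) & self.universe
            if not inter:
                raise ValueError(f"gene set {name!r} is empty after harmonization")
            harmonized[name] = inter
        self.sets = harmonized


def read_gmt(path, universe) -> GeneSetCollection:
    """Read GMT-style text: set name, description, tab-separated gene IDs."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(fields[2:])
    return GeneSetCollection(sets=sets, universe=set(universe))


def write_gmt(collection: GeneSetCollection, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """ad/bc with a 0.5 continuity correction when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of a query set in each collection set.

    The 2x2 table counts (query∩set, query only, set only, neither) within
    the universe; the two-sided p sums hypergeometric point probabilities no
    larger than the observed table's.  Odds ratios use a 0.5 continuity
    correction when a cell is zero (p-values are never corrected).  BH FDR
    is applied across the collection.
    """
    query = set(query) & collection.universe
    if not query:
        raise ValueError("query has no genes in the universe")
    N = len(collection.universe)
    rows = []
    for name in sorted(collection.sets):
        s = collection.sets[name]
        a = len(query & s)
        b = len(query) - a
        c = len(s) - a
        d = N - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, len(s), _odds_ratio(a, b, c, d), p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "odds_ratio", "p_value"]
    ).set_index("set")
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def directional_overlap(
    de: DEResult, collection: GeneSetCollection
) -> dict[str, pd.DataFrame]:
    """Enrich up- and down-regulated DEGs separately against the collection.

    Up: log2FC > lfc and FDR < fdr; down: log2FC < -lfc and FDR < fdr.  An
    empty direction yields an all-null table (overlap 0, p 1) rather than an
    error.
    """
    t = de.table
    sig = t["fdr"] < de.fdr_thresh
    up = set(t.index[sig & (t["log2_fc"] > de.lfc_thresh)])
    down = set(t.index[sig & (t["log2_fc"] < -de.lfc_thresh)])
    out = {}
    for direction, genes in (("up", up), ("down", down)):
        if genes & collection.universe:
            out[direction] = fisher_enrich(genes, collection)
        else:
            out[direction] = pd.DataFrame(
                {
                    "overlap": 0,
                    "set_size": [len(collection.sets[n]) for n in sorted(collection.sets)],
                    "odds_ratio": np.nan,
                    "p_value": 1.0,
                    "fdr": 1.0,
                },
                index=pd.Index(sorted(collection.sets), name="set"),
            )
    return out


def deg_module_correlation(
    de: DEResult,
    signatures: dict[str, pd.Series],
    r_min: float = 0.20,
    p_max: float = 0.05,
    min_shared: int = 10,
) -> pd.DataFrame:
    """Pearson correlation between a DE log2FC vector and per-gene module
    signatures over shared genes.

    Rows with fewer than ``min_shared`` shared genes are marked unreliable.
    A correlation is flagged when |r| >= 0.20 and p < 0.05.
    """
    lfc = de.table["log2_fc"]
    rows = []
    for name in sorted(signatures):
        sig = signatures[name]
        shared = lfc.index.intersection(sig.index)
        if len(shared) < 2:
            rows.append((name, len(shared), np.nan, np.nan, False, False))
            continue
        r, p = stats.pearsonr(lfc.loc[shared], sig.loc[shared])
        reliable = len(shared) >= min_shared
        flagged = bool(reliable and abs(r) >= r_min and p < p_max)
        rows.append((name, len(shared), r, p, flagged, reliable))
    return pd.DataFrame(
        rows, columns=["signature", "n_shared", "r", "p_value", "significant", "reliable"]
    ).set_index("signature")


def geneset_eigengene(
    matrix: pd.DataFrame, gene_list, grouping: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """PC1 eigengene of a supplied gene list, with per-group summaries.

    The eigengene is the first principal component of the z-scored
    submatrix of listed genes, sign-fixed so the mean gene correlation with
    it is positive.  Requires at least 3 listed genes present in the matrix
    (the error lists the missing IDs).  If ``grouping`` (sample -> group) is
    given, per-group means and standard errors are returned too.
    """
    present = [g for g in gene_list if g in matrix.index]
    if len(present) < 3:
        missing = [g for g in gene_list if g not in matrix.index]
        raise ValueError(
            f"need >= 3 listed genes in the matrix, found {len(present)}; "
            f"missing: {missing}"
        )
    X = matrix.loc[present].values.astype(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc1 = vt[0]
    cors = np.array([stats.pearsonr(Z[i], pc1)[0] for i in range(Z.shape[0])])
    if np.nanmean(cors) < 0:
        pc1 = -pc1
    scores = pd.Series(pc1, index=matrix.columns, name="eigengene")
    summary = None
    if grouping is not None:
        grouping = grouping.loc[scores.index]
        summary = scores.groupby(grouping).agg(["mean", "sem", "count"])
    return scores, summary


# ---------------------------------------------------------------------------
# Module preservation
# ---------------------------------------------------------------------------

BANDS = ("not_preserved", "moderate", "preserved", "highly_preserved")


def preservation_band(z_summary: float) -> str:
    """Interpretation band: <2 not preserved; [2,5) moderate; [5,10]
    preserved; >10 highly preserved."""
    if z_summary < 2.0:
        return "not_preserved"
    if z_summary < 5.0:
        return "moderate"
    if z_summary <= 10.0:
        return "preserved"
    return "highly_preserved"


@dataclass
class PreservationResult:
    """Permutation Z statistics per module."""

    table: pd.DataFrame  # module x [n_genes, z_density, z_connectivity, z_summary, band]

    def band(self, module: str) -> str:
        return self.table.loc[module, "band"]


def _module_stats(
    adj_ref: np.ndarray, adj_test: np.ndarray, idx: np.ndarray
) -> tuple[float, float]:
    """(test density, ref-vs-test intramodular connectivity correlation)."""
    sub_t = adj_test[np.ix_(idx, idx)]
    m = len(idx)
    density = sub_t.sum() / (m * (m - 1))
    k_ref = adj_ref[np.ix_(idx, idx)].sum(axis=1)
    k_test = sub_t.sum(axis=1)
    if np.std(k_ref) == 0 or np.std(k_test) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(k_ref, k_test)[0, 1])
    return float(density), r


def module_preservation(
    ref_expression: pd.DataFrame,
    test_expression: pd.DataFrame,
    labels: pd.Series,
    beta: float,
    n_perm: int = 100,
    seed: int = 0,
    min_module_genes: int = 3,
) -> PreservationResult:
    """Permutation Z-summary preservation of reference modules in test data.

    For each module, the observed statistics are (a) module density — the
    mean within-module signed adjacency in the test data — and (b)
    connectivity preservation — the Pearson correlation between
    intramodular connectivity computed in the reference versus the test
    network.  The null draws ``n_perm`` random gene sets of the same size
    from the shared gene universe; each statistic is standardized as
    ``Z = (obs - null mean) / null sd`` and ``Z_summary`` is their mean.
    Modules with fewer than 3 genes in the shared universe are skipped with
    a warning.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    shared = ref_expression.index.intersection(test_expression.index)
    labels = labels.loc[labels.index.intersection(shared)]
    ref = ref_expression.loc[shared]
    test = test_expression.loc[shared]

    adj_ref = signed_adjacency(bicor_matrix(ref), beta)
    adj_test = signed_adjacency(bicor_matrix(test), beta)
    pos = {g: i for i, g in enumerate(shared)}

    rng = np.random.default_rng(seed)
    modules = [m for m in labels.unique() if m != "grey"]
    rows = []
    for module in sorted(modules):
        genes = labels.index[labels == module]
        idx = np.array([pos[g] for g in genes if g in pos])
        if len(idx) < min_module_genes:
            warnings.warn(
                f"module {module!r} has < {min_module_genes} genes in the "
                "shared universe; skipped"
            )
            continue
        obs_d, obs_c = _module_stats(adj_ref, adj_test, idx)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for p in range(n_perm):
            rand = rng.choice(len(shared), size=len(idx), replace=False)
            null_d[p], null_c[p] = _module_stats(adj_ref, adj_test, rand)
        # degenerate nulls (e.g. test data identical to ref makes every
        # permuted connectivity correlation exactly 1): floor the sd so the
        # Z statistic stays finite and near zero instead of exploding
        sd_d = max(null_d.std(ddof=1), 1e-6)
        sd_c = max(null_c.std(ddof=1), 1e-6)
        z_d = (obs_d - null_d.mean()) / sd_d
        z_c = (obs_c - null_c.mean()) / sd_c
        z_sum = (z_d + z_c) / 2.0
        rows.append((module, len(idx), z_d, z_c, z_sum, preservation_band(z_sum)))
    table = pd.DataFrame(
        rows,
        columns=["module", "n_genes", "z_density", "z_connectivity",
                 "z_summary", "band"],
    ).set_index("module")
    return PreservationResult(table=table)
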