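"""Gene-level differential expression in the SAM style.

Gene expression is summarized per sample as the median log2 intensity over
the gene's constitutive probes only, so alternative regions never leak into
the expression estimate.  Differential expression between two groups uses a
moderated t-like statistic

    d = (mean_A - mean_B) / (s + s0)

where s is the pooled standard error of the mean difference and s0 a small
positive "fudge" constant that keeps low-variance genes from dominating.
Here s0 is the 5th percentile of the gene-wise s distribution, a
deterministic and transparent stand-in for the classical coefficient-of-
variation optimization.  q-values come from the same exhaustive balanced
label-permutation engine used for splicing calls (s recomputed per
permutation, s0 held at its observed value).  A gene is selected when its
fold change is at least 2 (|log2fc| >= 1, boundary included) and q < 0.05.

Fold-change profiles across several comparisons can be clustered with
average-linkage hierarchical clustering under a 1 - Pearson correlation
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._permutation import balanced_assignments, qvalues_from_scores

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_gene_expression",
    "sam_statistic",
    "differential_expression",
    "select_changed_genes",
    "cluster_fold_changes",
    "ClusterResult",
    "FOLD_THRESHOLD",
    "Q_THRESHOLD",
    "S0_PERCENTILE",
]

FOLD_THRESHOLD = 2.0
Q_THRESHOLD = 0.05
S0_PERCENTILE = 5.0


def summarize_gene_expression(
    table: pd.DataFrame, samples: Sequence[str]
) -> pd.DataFrame:
    """Per-sample log2 expression per gene from constitutive probes.

    Value = median over the gene's constitutive probes of log2 intensity.
    Genes without any constitutive probe are skipped with a warning.
    Returns genes x samples.
    """
    const = table[table["role"] == "constitutive"]
    missing = set(table["gene_id"].unique()) - set(const["gene_id"].unique())
    if missing:
        logger.warning(
            "skipping %d gene(s) without constitutive probes", len(missing)
        )
    if const.empty:
        return pd.DataFrame(columns=list(samples))
    log2 = np.log2(const[list(samples)].to_numpy(dtype=float))
    df = pd.DataFrame(log2, columns=list(samples))
    df["gene_id"] = const["gene_id"].to_numpy()
    return df.groupby("gene_id", sort=True).median()


def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of the difference of group means (genes x reps)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return np.sqrt(pooled * (1.0 / na + 1.0 / nb))


def sam_statistic(
    expr_a: pd.DataFrame | np.ndarray,
    expr_b: pd.DataFrame | np.ndarray,
    s0: float | None = None,
) -> pd.Series | np.ndarray:
    """Moderated d statistic per gene; rows are genes, columns replicates.

    ``s0`` defaults to the 5th percentile of the gene-wise pooled standard
    errors.  With all variances zero an explicit nonzero s0 is required.
    """
    index = expr_a.index if isinstance(expr_a, pd.DataFrame) else None
    a = np.atleast_2d(np.asarray(expr_a, dtype=float))
    b = np.atleast_2d(np.asarray(expr_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least two replicates per group")
    s = _pooled_se(a, b)
    if s0 is None:
        s0 = float(np.percentile(s, S0_PERCENTILE))
    if s0 == 0 and np.any(s == 0):
        raise ValueError(
            "zero variance with s0=0 gives an undefined statistic; "
            "pass a nonzero s0"
        )
    d = (a.mean(axis=1) - b.mean(axis=1)) / (s + s0)
    return pd.Series(d, index=index, name="d") if index is not None else d


def differential_expression(
    table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    s0_percentile: float = S0_PERCENTILE,
    min_fold: float = FOLD_THRESHOLD,
    max_q: float = Q_THRESHOLD,
    n_perm: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """SAM-style differential expression with permutation q-values.

    Returns a DataFrame indexed by gene_id with columns
    ``log2fc, d, q, selected``.
    """
    samples = list(group_a) + list(group_b)
    expr = summarize_gene_expression(table, samples)
    if expr.empty:
        raise ValueError("no genes with constitutive probes")
    mat = expr.to_numpy()
    col = {s: i for i, s in enumerate(expr.columns)}
    ia = [col[s] for s in group_a]
    ib = [col[s] for s in group_b]

    a, b = mat[:, ia], mat[:, ib]
    s = _pooled_se(a, b)
    s0 = float(np.percentile(s, s0_percentile))
    d_obs = (a.mean(axis=1) - b.mean(axis=1)) / (s + s0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    assignments = balanced_assignments(group_a, group_b, n_perm=n_perm, rng=rng)
    perm_abs = np.empty((len(assignments), mat.shape[0]))
    for i, (pa, pb) in enumerate(assignments):
        pa_i = [col[x] for x in pa]
        pb_i = [col[x] for x in pb]
        aa, bb = mat[:, pa_i], mat[:, pb_i]
        sp = _pooled_se(aa, bb)
        perm_abs[i] = np.abs((aa.mean(axis=1) - bb.mean(axis=1)) / (sp + s0))

    q = qvalues_from_scores(np.abs(d_obs), perm_abs)
    out = pd.DataFrame(
        {"log2fc": log2fc, "d": d_obs, "q": q}, index=expr.index
    )
    out["selected"] = (out["log2fc"].abs() >= np.log2(min_fold)) & (out["q"] < max_q)
    return out


def select_changed_genes(
    calls: pd.DataFrame,
    min_fold: float = FOLD_THRESHOLD,
    max_q: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Genes with at least ``min_fold`` change (boundary included) and q below ``max_q``."""
    mask = (calls["log2fc"].abs() >= np.log2(min_fold)) & (calls["q"] < max_q)
    return calls[mask]


@dataclass
class ClusterResult:
    """Average-linkage clustering of fold-change profiles."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def _correlation_distance(mat: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows sit at distance 1."""
    sd = mat.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant row(s): correlation undefined, distance set to 1",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    return np.clip(dist, 0.0, None)


def _to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_fold_changes(matrix: pd.DataFrame) -> ClusterResult:
    """Cluster genes by their fold-change profiles across comparisons.

    Hierarchical agglomerative clustering, average linkage, distance
    1 - Pearson correlation across the comparison columns.  Leaf order is
    deterministic, with ties resolved by input order.  Returns the linkage
    matrix, the leaf order and a Newick rendering of the tree.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    labels = [str(x) for x in matrix.index]
    dist = _correlation_distance(matrix.to_numpy(dtype=float))
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    tree = hierarchy.to_tree(z)
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(linkage=z, labels=labels, leaf_order=order, newick=newick)
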