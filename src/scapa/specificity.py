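"""Cell-type specificity of APA via similarity networks and neighbor voting.

For each multi-isoform gene the per-cell usage vectors live on a simplex;
pairwise Hellinger distance d(u, v) = (1/sqrt(2)) * ||sqrt(u) - sqrt(v)||_2
is bounded in [0, 1], so S = 1 - d defines a cell-to-cell similarity
network over the cells where the gene is detected.  Cross-validated
neighbor voting on that network (hidden cells vote for a type with the
degree-normalised sum of their similarity to training cells of that type)
yields a per-type AUROC: 0.5 means the gene's usage carries no type
information, 1 means it separates the type perfectly.

A one-versus-rest differential-usage test on artificial bulk (per-type
summed counts) corroborates the ranking: per gene an isoform x {type,rest}
contingency table is tested for independence (chi-square, or Fisher's
exact for sparse 2x2 tables) with Benjamini-Hochberg correction per type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency, fisher_exact, rankdata
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hellinger_distance",
    "build_network",
    "neighbor_voting_auroc",
    "specificity_table",
    "specific_apa_genes",
    "differential_usage",
]


def hellinger_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Hellinger distance between two usage simplex vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("usage vectors must have the same length")
    return float(np.sqrt(0.5 * np.sum((np.sqrt(u) - np.sqrt(v)) ** 2)))


@dataclass
class SimilarityNetwork:
    gene_id: str
    cells: List[str]
    S: np.ndarray  # symmetric, S_jj = 1, entries in [0, 1]


def build_network(usage_df: pd.DataFrame, isoform_cols: Sequence[str],
                  gene_id: str) -> Optional[SimilarityNetwork]:
    """Similarity network over the cells where the gene is detected.

    ``usage_df`` is cells x isoforms with NaN for undetected genes; cells
    with NaN usage are excluded.  Returns None (gene skipped) when fewer
    than two cells detect the gene.
    """
    sub = usage_df[list(isoform_cols)].dropna()
    if len(sub) < 2:
        return None
    U = sub.to_numpy(dtype=float)
    dist = squareform(pdist(np.sqrt(U), metric="euclidean")) / np.sqrt(2.0)
    S = np.clip(1.0 - dist, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(gene_id=gene_id, cells=list(sub.index), S=S)


def _auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUROC with midranks for ties."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    ranks = rankdata(scores)
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def neighbor_voting_auroc(network: SimilarityNetwork,
                          labels: Mapping[str, str],
                          folds: int = 3, repeats: int = 10,
                          seed: int = 0,
                          min_cells: int = 10) -> Dict[str, float]:
    """Cross-validated neighbor-voting AUROC per cell type.

    Per repeat the network's cells are split into stratified folds; each
    hidden cell's vote for type t is the sum of its similarity to training
    cells of type t divided by its total similarity to the training set
    (vote 0.5 when the denominator is zero).  AUROC ranks hidden-cell votes
    against true one-versus-rest membership; the mean over folds and
    repeats is returned for every type with >= ``min_cells`` detected
    cells.  Deterministic given ``seed``.
    """
    cells = network.cells
    y = np.array([labels[c] for c in cells])
    types = [t for t in np.unique(y) if (y == t).sum() >= min_cells]
    if not types:
        return {}
    aurocs: Dict[str, List[float]] = {t: [] for t in types}
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train_idx, test_idx in skf.split(np.zeros(len(cells)), y):
            S_tt = network.S[np.ix_(test_idx, train_idx)]
            denom = S_tt.sum(axis=1)
            for t in types:
                pos_train = (y[train_idx] == t)
                votes = np.full(len(test_idx), 0.5)
                ok = denom > 0
                votes[ok] = S_tt[ok][:, pos_train].sum(axis=1) / denom[ok]
                truth = (y[test_idx] == t)
                if truth.all() or not truth.any():
                    continue  # fold with no positives or no negatives
                aurocs[t].append(_auroc(votes, truth))
    return {t: float(np.mean(v)) for t, v in aurocs.items() if v}


def specificity_table(usage_df: pd.DataFrame, var: pd.DataFrame,
                      labels: Mapping[str, str], folds: int = 3,
                      repeats: int = 10, seed: int = 0,
                      min_cells: int = 10) -> pd.DataFrame:
    """Mean neighbor-voting AUROC per (gene, cell type).

    ``var`` maps isoform columns to genes (index = isoform, ``gene_id``
    column).  Single-isoform genes are skipped; per gene, only cell types
    with >= ``min_cells`` detected cells are scored.
    """
    rows = []
    for gi, (gene, gvar) in enumerate(var.groupby("gene_id")):
        if len(gvar) < 2:
            continue
        network = build_network(usage_df, list(gvar.index), gene)
        if network is None:
            continue
        y = pd.Series([labels[c] for c in network.cells])
        counts = y.value_counts()
        res = neighbor_voting_auroc(network, labels, folds=folds,
                                    repeats=repeats, seed=seed + gi,
                                    min_cells=min_cells)
        for t, auc in res.items():
            rows.append((gene, t, auc, int(counts[t])))
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "auroc",
                                       "n_cells"])


def specific_apa_genes(table: pd.DataFrame,
                       threshold: float = 0.8) -> Dict[str, List[str]]:
    """Per-type genes with AUROC strictly above ``threshold``."""
    out: Dict[str, List[str]] = {}
    for t, grp in table.groupby("cell_type"):
        out[t] = sorted(grp.loc[grp["auroc"] > threshold, "gene_id"])
    return out


def _test_contingency(table: np.ndarray) -> Tuple[float, float]:
    """Independence test on an isoforms x {type, rest} count table.

    Chi-square without continuity correction; Fisher's exact test for 2x2
    tables with any expected cell below 5.  Returns (statistic, p-value).
    """
    if table.shape == (2, 2):
        expected = (table.sum(1, keepdims=True) * table.sum(0, keepdims=True)
                    / table.sum())
        if (expected < 5).any():
            res = fisher_exact(table)
            return float(res[0]), float(res[1])
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def differential_usage(counts: ad.AnnData,
                       labels: Mapping[str, str]) -> pd.DataFrame:
    """One-versus-rest differential poly(A)-site usage on artificial bulk.

    Per cell type, isoform counts are summed over the type's cells and over
    all other cells; per gene with >= 2 isoforms an independence test is
    run on the resulting contingency table, with BH correction across genes
    within the type.  Genes whose table has a zero margin are reported with
    NA p-values.
    """
    y = np.array([labels[c] for c in counts.obs_names])
    X = np.asarray(counts.X, dtype=np.int64)
    gene_ids = counts.var["gene_id"].to_numpy()
    types = sorted(np.unique(y))
    if len(types) < 2:
        raise ValueError("differential usage needs at least two cell types")
    rows = []
    for t in types:
        in_type = X[y == t].sum(axis=0)
        in_rest = X[y != t].sum(axis=0)
        for gene in pd.unique(gene_ids):
            cols = np.flatnonzero(gene_ids == gene)
            if len(cols) < 2:
                continue
            tab = np.stack([in_type[cols], in_rest[cols]], axis=1)
            tot_type, tot_rest = tab[:, 0].sum(), tab[:, 1].sum()
            u_type = tab[:, 0] / tot_type if tot_type > 0 else None
            u_rest = tab[:, 1] / tot_rest if tot_rest > 0 else None
            nz = tab.sum(axis=1) > 0
            tab_nz = tab[nz]
            if tab_nz.shape[0] < 2 or (tab_nz.sum(axis=0) == 0).any():
                rows.append((gene, t, np.nan, np.nan, u_type, u_rest))
                continue
            stat, p = _test_contingency(tab_nz)
            rows.append((gene, t, stat, p, u_type, u_rest))
    df = pd.DataFrame(rows, columns=["gene_id", "cell_type", "statistic",
                                     "pvalue", "usage_type", "usage_rest"])
    df["qvalue"] = np.nan
    for t in types:
        mask = (df["cell_type"] == t) & df["pvalue"].notna()
        if mask.any():
            df.loc[mask, "qvalue"] = multipletests(
                df.loc[mask, "pvalue"], method="fdr_bh")[1]
    return df
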