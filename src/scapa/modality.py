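"""Modality classification of distal poly(A)-site usage across cells.

A gene's distal-site usage distribution over the cells of a type is binned
into thirds ([0, 1/3], (1/3, 2/3], (2/3, 1]) and compared, by base-2
Jensen-Shannon divergence, to five reference shapes: distal (0,0,1),
proximal (1,0,0), middle (0,1,0), bimodal (1/2,0,1/2) and multimodal
(1/3,1/3,1/3).  The closest reference gives the modality label.  Bimodal
genes — two cell subpopulations preferring opposite sites — carry the most
usage variance and can demarcate subpopulations: genes whose expression
correlates (or anticorrelates) most strongly with the target gene's distal
usage are used to cut the cells into two groups by hierarchical
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "MODALITY_REFERENCES",
    "MODALITY_ORDER",
    "distal_usage",
    "bin_usage",
    "jsd",
    "assign_modality",
    "usage_variability",
    "modality_table",
    "correlated_genes",
    "CorrelationResult",
]

# tie-break order is the listing order
MODALITY_ORDER: Tuple[str, ...] = ("distal", "proximal", "middle",
                                   "bimodal", "multimodal")
MODALITY_REFERENCES: Dict[str, np.ndarray] = {
    "distal": np.array([0.0, 0.0, 1.0]),
    "proximal": np.array([1.0, 0.0, 0.0]),
    "middle": np.array([0.0, 1.0, 0.0]),
    "bimodal": np.array([0.5, 0.0, 0.5]),
    "multimodal": np.array([1 / 3, 1 / 3, 1 / 3]),
}


def distal_usage(usage_df: pd.DataFrame, var: pd.DataFrame,
                 gene_id: str) -> pd.Series:
    """Per-cell usage of the gene's 3'-most site in transcription direction.

    The distal isoform has the maximum site coordinate on the + strand and
    the minimum on the - strand.  NA propagates from undetected cells.
    Raises for single-isoform genes (distal usage is not meaningful).
    """
    gvar = var[var["gene_id"] == gene_id]
    if len(gvar) < 2:
        raise ValueError(f"gene {gene_id} has fewer than two isoforms")
    strand = gvar["strand"].iloc[0]
    distal_iso = (gvar["site_pos"].idxmax() if strand == "+"
                  else gvar["site_pos"].idxmin())
    return usage_df[distal_iso]


def bin_usage(values: Sequence[float], min_cells: int = 10) -> np.ndarray:
    """Proportions of cells in the thirds of the usage range.

    Boundary values fall in the lower bin: v <= 1/3 is low, 1/3 < v <= 2/3
    is middle, v > 2/3 is high.  Requires >= ``min_cells`` non-NA values.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(v) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(v)}")
    low = (v <= 1 / 3).sum()
    mid = ((v > 1 / 3) & (v <= 2 / 3)).sum()
    high = (v > 2 / 3).sum()
    return np.array([low, mid, high], dtype=float) / len(v)


def jsd(p: Sequence[float], q: Sequence[float]) -> float:
    """Base-2 Jensen-Shannon divergence between two simplexes, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for vec in (p, q):
        if vec.ndim != 1 or (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must be probability vectors")
    if p.shape != q.shape:
        raise ValueError("vectors must have the same length")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        nz = a > 0
        return float(np.sum(a[nz] * np.log2(a[nz] / b[nz])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def assign_modality(binned: np.ndarray,
                    refs: Optional[Mapping[str, np.ndarray]] = None
                    ) -> Tuple[str, Dict[str, float]]:
    """Label of the JSD-closest reference distribution.

    Ties resolve in :data:`MODALITY_ORDER`.  Returns (label, JSD to every
    reference).
    """
    refs = MODALITY_REFERENCES if refs is None else refs
    dists = {label: jsd(binned, refs[label]) for label in refs}
    order = [l for l in MODALITY_ORDER if l in refs] + \
            [l for l in refs if l not in MODALITY_ORDER]
    label = min(order, key=lambda l: dists[l])
    return label, dists


def usage_variability(values: Sequence[float]) -> float:
    """Sample variance (ddof=1) of distal usage across cells."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(v) < 2:
        return 0.0
    return float(np.var(v, ddof=1))


def modality_table(usage_df: pd.DataFrame, var: pd.DataFrame,
                   labels: Mapping[str, str],
                   min_cells: int = 10) -> pd.DataFrame:
    """Per (gene, cell type) modality assignment.

    Genes are scored within each cell type where they are detected in at
    least ``min_cells`` cells; single-isoform genes are skipped.  Columns:
    gene, cell type, label, the five JSDs, n_cells, distal-usage variance.
    """
    y = pd.Series({c: labels[c] for c in usage_df.index})
    rows = []
    for gene in pd.unique(var["gene_id"]):
        if (var["gene_id"] == gene).sum() < 2:
            continue
        du = distal_usage(usage_df, var, gene)
        for t in sorted(y.unique()):
            vals = du[y == t].dropna()
            if len(vals) < min_cells:
                continue
            binned = bin_usage(vals, min_cells=min_cells)
            label, dists = assign_modality(binned)
            rows.append((gene, t, label,
                         *[dists[l] for l in MODALITY_ORDER],
                         len(vals), usage_variability(vals)))
    cols = (["gene_id", "cell_type", "modality"]
            + [f"jsd_{l}" for l in MODALITY_ORDER] + ["n_cells", "variance"])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CorrelationResult:
    gene_id: str
    correlations: pd.Series          # Pearson r per gene (NaN-free)
    top_correlated: List[str]
    top_anticorrelated: List[str]
    groups: pd.Series                # cell -> {1, 2}


def correlated_genes(expr: pd.DataFrame, target_usage: pd.Series,
                     gene_id: str = "", k: int = 50,
                     min_cells: int = 10) -> CorrelationResult:
    """Expression programs coupled to a gene's distal usage.

    ``expr`` is cells x genes log2(uTPM+1); Pearson r is computed over the
    cells with defined target usage, genes with undefined r (zero variance)
    are excluded, and the top-k / bottom-k genes by r are selected.  Cells
    are then cut into two groups by average-linkage hierarchical clustering
    (Euclidean) on the z-scored expression of the selected genes.
    """
    u = target_usage.dropna()
    if len(u) < min_cells:
        raise ValueError(f"need at least {min_cells} cells with defined usage")
    E = expr.loc[u.index]
    uc = u - u.mean()
    Ec = E - E.mean(axis=0)
    denom = np.sqrt((Ec ** 2).sum(axis=0) * (uc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec.mul(uc, axis=0).sum(axis=0) / denom)
    r = r.dropna()
    ranked = r.sort_values(ascending=False)
    top = list(ranked.index[:k])
    bottom = list(ranked.index[::-1][:k])
    selected = list(dict.fromkeys(top + bottom))
    sub = E[selected]
    std = sub.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = (sub - sub.mean(axis=0)) / std
    link = linkage(Z.to_numpy(), method="average", metric="euclidean")
    groups = pd.Series(fcluster(link, t=2, criterion="maxclust"),
                       index=u.index, name="group")
    return CorrelationResult(gene_id=gene_id, correlations=r,
                             top_correlated=top, top_anticorrelated=bottom,
                             groups=groups)
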