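"""Peak regions, per-cell isoform counting, usage fractions and uTPM.

Peak regions are found by parametric density clustering of pooled read
3'-ends: a cluster is a contiguous run of tag positions that is the
maximal-scoring segment of score(d) = total_tags - d * span over some range
of density parameters d.  Each cluster carries the minimum density at which
it appears (d_min, the break density of its parent in the nest) and the
maximum density at which it is still maximal (d_max, its own break
density); d_max / d_min measures the cluster's stability.  Root clusters
take d_min equal to their own overall tag density, so only internally
stable structure is ever reported.

Retained peaks are merged across cell types, restricted to gene bodies,
assigned to poly(A) sites (splitting multi-site peaks at the inter-site
pileup minimum), and used to count per-cell UMIs per poly(A) isoform.
Usage is the within-gene fraction U_i = C_i / sum(C) (NA when the gene is
undetected in a cell); uTPM normalises per-cell gene counts to one million.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .preprocess import DedupedTag

__all__ = [
    "paraclu_cluster",
    "merge_peaks",
    "restrict_to_genes",
    "assign_peaks_to_sites",
    "count_isoforms",
    "usage",
    "gene_level_counts",
    "utpm",
    "tags_to_pileup",
]

PEAK_COLS = ["chrom", "strand", "start", "end", "total",
             "min_density", "max_density"]


def tags_to_pileup(tags: Iterable[DedupedTag],
                   polya_only: bool = False) -> pd.DataFrame:
    """Per-position 3'-end counts (all deduplicated tags by default)."""
    counts: Dict[Tuple[str, str, int], int] = {}
    for t in tags:
        if polya_only and not t.polya_flag:
            continue
        key = (t.chrom, t.strand, t.end3)
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame([(c, s, p, n) for (c, s, p), n in counts.items()],
                      columns=["chrom", "strand", "pos", "count"])
    return df.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


def _break_density(pos: np.ndarray, val: np.ndarray, beg: int, end: int
                   ) -> Tuple[float, int]:
    """Weakest prefix/suffix density of segment [beg, end) and split index.

    Trimming the prefix sites[beg..i] stops paying off once the density
    parameter drops below total(prefix) / (pos[i+1] - pos[beg]); likewise
    for suffixes.  The minimum over all proper trims is the density at
    which the segment splits.
    """
    best = math.inf
    mid = beg + 1
    tot = 0.0
    for i in range(beg, end - 1):
        tot += val[i]
        den = tot / (pos[i + 1] - pos[beg])
        if den < best:
            best, mid = den, i + 1
    tot = 0.0
    for i in range(end - 1, beg, -1):
        tot += val[i]
        den = tot / (pos[end - 1] - pos[i - 1])
        if den < best:
            best, mid = den, i
    return best, mid


def _paraclu_one(pos: np.ndarray, val: np.ndarray, min_total: int,
                 max_length: int, min_density_ratio: float
                 ) -> List[Tuple[int, int, int, float, float]]:
    """Stable clusters of one (chrom, strand) pileup, largest per nest.

    Returns (start_pos, end_pos_inclusive, total, d_min, d_max) tuples.
    DFS over the nest; a node that passes all filters is reported and its
    subtree pruned, so exactly the largest passing cluster per nest
    survives.
    """
    out: List[Tuple[int, int, int, float, float]] = []
    n = len(pos)
    if n == 0:
        return out
    prefix = np.concatenate([[0.0], np.cumsum(val)])

    # (beg, end, sweep d_min, is_root); the root's reported d_min is floored
    # at its overall density (stability convention) but its children inherit
    # the root's break density, exactly as interior nodes do.
    stack: List[Tuple[int, int, float, bool]] = [(0, n, 0.0, True)]
    while stack:
        beg, end, dmin, is_root = stack.pop()
        total = prefix[end] - prefix[beg]
        if end - beg == 1:
            dmax = math.inf
        else:
            dmax, mid = _break_density(pos, val, beg, end)
        report_dmin = dmin
        if is_root and end - beg > 1:
            report_dmin = float(total) / (pos[end - 1] - pos[beg])
        if dmax > report_dmin:
            length = pos[end - 1] - pos[beg] + 1
            ratio = math.inf if report_dmin == 0 else dmax / report_dmin
            if (total >= min_total and length <= max_length
                    and ratio >= min_density_ratio):
                out.append((int(pos[beg]), int(pos[end - 1]), int(total),
                            report_dmin, dmax))
                continue  # keep largest passing cluster per nest
        if end - beg > 1:
            child_dmin = max(dmax, dmin)
            stack.append((beg, mid, child_dmin, False))
            stack.append((mid, end, child_dmin, False))
    return out


def paraclu_cluster(pileup: pd.DataFrame, min_total: int = 10,
                    max_length: int = 200,
                    min_density_ratio: float = 2.0) -> pd.DataFrame:
    """Parametric density clustering of a 3'-end pileup into peak regions.

    Filters: cluster tag total >= ``min_total``, genomic span <=
    ``max_length`` nt, stability d_max/d_min >= ``min_density_ratio``.
    Nested passing clusters are resolved to the largest per nest.  Returns
    a peak frame with 0-based half-open start/end.
    """
    rows = []
    for (chrom, strand), grp in pileup.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        val = grp["count"].to_numpy(dtype=np.float64)
        for s, e, tot, dmin, dmax in _paraclu_one(
                pos, val, min_total, max_length, min_density_ratio):
            rows.append((chrom, strand, s, e + 1, tot, dmin, dmax))
    df = pd.DataFrame(rows, columns=PEAK_COLS)
    return df.sort_values(["chrom", "strand", "start"]).reset_index(drop=True)


def merge_peaks(peak_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Interval union per (chrom, strand); overlapping or bookended merge."""
    frames = [p for p in peak_lists if len(p)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "strand", "start", "end"])
    allp = pd.concat(frames, ignore_index=True)[["chrom", "strand", "start", "end"]]
    rows = []
    for (chrom, strand), grp in allp.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = int(row.start), int(row.end)
            elif int(row.start) <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, int(row.end))
            else:
                rows.append((chrom, strand, cur_s, cur_e))
                cur_s, cur_e = int(row.start), int(row.end)
        if cur_s is not None:
            rows.append((chrom, strand, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "strand", "start", "end"])


def restrict_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame
                      ) -> pd.DataFrame:
    """Keep peaks with >= 1 bp same-strand gene-body overlap.

    Each retained peak carries the list of overlapping gene ids in a
    ``gene_ids`` column; multi-gene peaks are resolved against the assigned
    site downstream (see :func:`assign_peaks_to_sites` callers).
    """
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for g in genes.itertuples(index=False):
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
            int(g.start), int(g.end), g.gene_id)
    keep = []
    gene_lists = []
    for row in peaks.itertuples(index=False):
        tree = trees.get((row.chrom, row.strand))
        hits = (sorted({iv.data for iv in tree.overlap(int(row.start), int(row.end))})
                if tree is not None else [])
        if hits:
            keep.append(True)
            gene_lists.append(hits)
        else:
            keep.append(False)
    out = peaks.loc[keep].reset_index(drop=True)
    out["gene_ids"] = gene_lists
    return out


def _split_boundary(pileup_pos: Dict[int, int], a: int, b: int) -> int:
    """Split point between adjacent sites a < b: the minimum-pileup position
    in (a, b], ties resolved toward the midpoint."""
    candidates = range(a + 1, b + 1)
    midpoint = (a + b + 1) // 2
    best_pos, best = None, None
    for p in candidates:
        c = pileup_pos.get(p, 0)
        if (best is None or c < best
                or (c == best and abs(p - midpoint) < abs(best_pos - midpoint))):
            best, best_pos = c, p
    return best_pos if best_pos is not None else midpoint


def assign_peaks_to_sites(peaks: pd.DataFrame, sites: pd.DataFrame,
                          pileup: Optional[pd.DataFrame] = None,
                          assign_dist: int = 50) -> pd.DataFrame:
    """Assign each peak exactly one poly(A) site.

    A peak containing one site keeps it; a peak containing k >= 2 sites is
    split into k sub-peaks at the minimum-pileup position between adjacent
    sites; a siteless peak is rescued by the nearest site within
    ``assign_dist`` nt of its edges, else dropped.  Returns peaks with
    site_pos / site_name columns and an ``n_dropped`` attribute in
    ``DataFrame.attrs``.
    """
    pileup_by_key: Dict[Tuple[str, str], Dict[int, int]] = {}
    if pileup is not None:
        for row in pileup.itertuples(index=False):
            pileup_by_key.setdefault((row.chrom, row.strand), {})[int(row.pos)] = \
                int(row.count)
    sites_by_key: Dict[Tuple[str, str], pd.DataFrame] = {
        key: grp.sort_values("pos").reset_index(drop=True)
        for key, grp in sites.groupby(["chrom", "strand"])
    }
    rows = []
    n_dropped = 0
    for row in peaks.itertuples(index=False):
        key = (row.chrom, row.strand)
        ssub = sites_by_key.get(key)
        extra = {c: getattr(row, c) for c in peaks.columns
                 if c not in ("chrom", "strand", "start", "end")}
        if ssub is None or ssub.empty:
            n_dropped += 1
            continue
        pos_arr = ssub["pos"].to_numpy(dtype=int)
        inside = np.flatnonzero((pos_arr >= int(row.start)) & (pos_arr < int(row.end)))
        if len(inside) == 1:
            s = ssub.iloc[inside[0]]
            rows.append((row.chrom, row.strand, int(row.start), int(row.end),
                         int(s["pos"]), s["name"], extra))
        elif len(inside) == 0:
            dist_left = pos_arr - int(row.end) + 1   # >0 when site right of peak
            dist_right = int(row.start) - pos_arr    # >0 when site left of peak
            dist = np.maximum(np.maximum(dist_left, dist_right), 0)
            j = int(np.argmin(dist))
            if dist[j] <= assign_dist:
                s = ssub.iloc[j]
                rows.append((row.chrom, row.strand, int(row.start), int(row.end),
                             int(s["pos"]), s["name"], extra))
            else:
                n_dropped += 1
        else:
            pp = pileup_by_key.get(key, {})
            bounds = [int(row.start)]
            in_pos = pos_arr[inside]
            for a, b in zip(in_pos[:-1], in_pos[1:]):
                bounds.append(_split_boundary(pp, int(a), int(b)))
            bounds.append(int(row.end))
            for k, idx in enumerate(inside):
                s = ssub.iloc[idx]
                rows.append((row.chrom, row.strand, bounds[k], bounds[k + 1],
                             int(s["pos"]), s["name"], extra))
    out_rows = []
    for chrom, strand, start, end, spos, sname, extra in rows:
        rec = {"chrom": chrom, "strand": strand, "start": start, "end": end,
               "site_pos": spos, "site_name": sname}
        rec.update(extra)
        out_rows.append(rec)
    out = pd.DataFrame(out_rows)
    if out.empty:
        out = pd.DataFrame(columns=["chrom", "strand", "start", "end",
                                    "site_pos", "site_name"])
    out.attrs["n_dropped"] = n_dropped
    return out.reset_index(drop=True)


def resolve_peak_genes(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Pick the single gene whose body contains each peak's assigned site.

    Peaks whose candidate ``gene_ids`` list has one entry keep it; multi-
    gene peaks resolve to the candidate covering ``site_pos``; unresolvable
    peaks are dropped and counted in ``attrs['n_gene_unresolved']``.
    """
    span = {g.gene_id: (int(g.start), int(g.end)) for g in genes.itertuples(index=False)}
    keep, gene_col = [], []
    n_unresolved = 0
    for row in peaks.itertuples(index=False):
        cands = list(row.gene_ids)
        if len(cands) == 1:
            keep.append(True)
            gene_col.append(cands[0])
            continue
        covering = [g for g in cands
                    if span[g][0] <= int(row.site_pos) < span[g][1]]
        if len(covering) >= 1:
            keep.append(True)
            gene_col.append(covering[0])
        else:
            keep.append(False)
            n_unresolved += 1
    out = peaks.loc[keep].reset_index(drop=True)
    out["gene_id"] = gene_col
    out = out.drop(columns=["gene_ids"])
    out.attrs["n_gene_unresolved"] = n_unresolved
    return out


def count_isoforms(cell_tags: Dict[str, List[DedupedTag]],
                   peaks: pd.DataFrame) -> ad.AnnData:
    """Count per-cell deduplicated tags inside each peak region.

    Both poly(A) and non-poly(A) tags count; a tag contributes to at most
    one isoform (peaks are disjoint after splitting).  Peaks sharing one
    (gene, site) — e.g. a summit peak plus a rescued nearby fragment — are
    aggregated into a single isoform.  Returns an AnnData (cells x
    isoforms) whose ``var`` carries gene/site/interval metadata and whose
    ``uns['n_tags_outside_peaks']`` counts ignored tags.
    """
    peaks = peaks.reset_index(drop=True)
    has_gene = "gene_id" in peaks.columns
    keys = [f"{row.gene_id}:{row.site_name}" if has_gene
            else f"iso_{row.site_name}"
            for row in peaks.itertuples(index=False)]
    isoforms = list(dict.fromkeys(keys))
    iso_of_key = {k: j for j, k in enumerate(isoforms)}
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for key, row in zip(keys, peaks.itertuples(index=False)):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            int(row.start), int(row.end), iso_of_key[key])
    cells = sorted(cell_tags)
    X = np.zeros((len(cells), len(isoforms)), dtype=np.int64)
    outside = 0
    for ci, cell in enumerate(cells):
        for t in cell_tags[cell]:
            tree = trees.get((t.chrom, t.strand))
            hit = tree.at(t.end3) if tree is not None else set()
            if hit:
                X[ci, next(iter(hit)).data] += 1
            else:
                outside += 1
    peaks["_iso"] = keys
    agg = {"chrom": "first", "strand": "first", "start": "min", "end": "max",
           "site_pos": "first", "site_name": "first"}
    if has_gene:
        agg["gene_id"] = "first"
    var = peaks.groupby("_iso", sort=False).agg(agg)
    var = var.loc[isoforms]
    var["n_intervals"] = peaks.groupby("_iso", sort=False).size().loc[isoforms]
    var.index.name = "isoform"
    peaks.drop(columns=["_iso"], inplace=True)
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
                       var=var)
    adata.uns["n_tags_outside_peaks"] = outside
    return adata


def usage(counts: ad.AnnData) -> pd.DataFrame:
    """Per-cell within-gene usage fractions U_i = C_i / sum_i C_i.

    NA for every isoform of a gene in cells where the gene has zero total
    count (usage is undefined for undetected genes).  Returns a cells x
    isoforms frame aligned with ``counts``.
    """
    X = np.asarray(counts.X, dtype=float)
    gene_ids = counts.var["gene_id"].to_numpy()
    out = np.full_like(X, np.nan)
    for gene in pd.unique(gene_ids):
        cols = np.flatnonzero(gene_ids == gene)
        sub = X[:, cols]
        totals = sub.sum(axis=1)
        detected = totals > 0
        out[np.ix_(detected, cols)] = (sub[detected] /
                                       totals[detected, None])
    return pd.DataFrame(out, index=counts.obs_names, columns=counts.var_names)


def gene_level_counts(counts: ad.AnnData) -> pd.DataFrame:
    """Sum isoform UMIs to gene level (cells x genes)."""
    df = pd.DataFrame(np.asarray(counts.X), index=counts.obs_names,
                      columns=counts.var["gene_id"].to_numpy())
    return df.T.groupby(level=0).sum().T


def utpm(gene_counts: pd.DataFrame, log: bool = False
         ) -> Tuple[pd.DataFrame, List[str]]:
    """Unique-transcripts-per-million per cell; optionally log2(uTPM + 1).

    Cells with zero total UMIs are excluded and returned in the second
    element.  Per retained cell the values sum to 1e6.
    """
    totals = gene_counts.sum(axis=1)
    excluded = list(gene_counts.index[totals == 0])
    kept = gene_counts.loc[totals > 0]
    mat = kept.div(totals[totals > 0], axis=0) * 1e6
    if log:
        mat = np.log2(mat + 1.0)
    return mat, excluded
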