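"""End-to-end orchestration: tags -> poly(A) sites -> isoform counts.

Thin composition of the module-level operations, shared by the CLI, the
test-suite and the acceptance harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import anndata as ad
import pandas as pd

from . import annotation, pas_call, quantify
from .preprocess import DedupedTag, demultiplex

__all__ = ["call_polya_sites", "quantify_isoforms", "SiteCallResult"]


@dataclass
class SiteCallResult:
    sites: pd.DataFrame
    pileup: pd.DataFrame               # post-filter poly(A) tag pileup
    n_positions_filtered: int
    total_polya_tags: int


def call_polya_sites(tags: Sequence[DedupedTag], genome,
                     utr3: Optional[pd.DataFrame] = None,
                     restrict_to_utr3: bool = True,
                     max_gap: int = 20, ip_window: int = 20, ip_run: int = 6,
                     min_raw_count: int = 3, min_norm_count: float = 1.0
                     ) -> SiteCallResult:
    """Pooled poly(A)-site calling from deduplicated tags.

    Pileup of poly(A)-flagged 3'-ends (3'UTR-restricted unless disabled),
    internal-priming filtering against the genome, distance clustering and
    count thresholds; the library size for normalisation is the total
    deduplicated poly(A) tag count before any filtering.
    """
    total_polya = sum(1 for t in tags if t.polya_flag)
    pileup = pas_call.collect_polya_tags(tags, utr3=utr3,
                                         restrict_to_utr3=restrict_to_utr3)
    filtered = pas_call.filter_internal_priming(pileup, genome,
                                                window=ip_window,
                                                min_run=ip_run)
    clusters = pas_call.cluster_tags(filtered, max_gap=max_gap)
    sites = pas_call.call_sites(clusters, total_polya_tags=max(total_polya, 1),
                                min_norm_count=min_norm_count,
                                min_raw_count=min_raw_count)
    return SiteCallResult(sites=sites, pileup=filtered,
                          n_positions_filtered=len(pileup) - len(filtered),
                          total_polya_tags=total_polya)


def quantify_isoforms(tags: Sequence[DedupedTag], sites: pd.DataFrame,
                      gtf: pd.DataFrame,
                      cell_map: Optional[Mapping[str, str]] = None,
                      min_total: int = 10, max_length: int = 200,
                      min_density_ratio: float = 2.0,
                      assign_dist: int = 50,
                      polya_only: bool = False,
                      peaks_by_group: Optional[Mapping[str, Sequence[DedupedTag]]]
                      = None) -> ad.AnnData:
    """Peak regions + per-cell isoform counting in one call.

    Peaks come from the pooled 3'-end pileup (per cell-type pileups may be
    passed via ``peaks_by_group`` and are merged); they are restricted to
    gene bodies, assigned to the site set, and used to count each cell's
    deduplicated tags.  ``cell_map`` maps barcodes to cell ids (identity
    when omitted).
    """
    if peaks_by_group:
        peak_lists = []
        for _, group_tags in sorted(peaks_by_group.items()):
            pl = quantify.tags_to_pileup(group_tags, polya_only=polya_only)
            peak_lists.append(quantify.paraclu_cluster(
                pl, min_total=min_total, max_length=max_length,
                min_density_ratio=min_density_ratio))
        peaks = quantify.merge_peaks(peak_lists)
    else:
        pileup = quantify.tags_to_pileup(tags, polya_only=polya_only)
        peaks = quantify.merge_peaks([quantify.paraclu_cluster(
            pileup, min_total=min_total, max_length=max_length,
            min_density_ratio=min_density_ratio)])
    genes = annotation.gene_bodies(gtf)
    peaks = quantify.restrict_to_genes(peaks, genes)
    full_pileup = quantify.tags_to_pileup(tags, polya_only=polya_only)
    peaks = quantify.assign_peaks_to_sites(peaks, sites, pileup=full_pileup,
                                           assign_dist=assign_dist)
    peaks = quantify.resolve_peak_genes(peaks, genes)
    if cell_map is None:
        barcodes = sorted({t.cell_barcode for t in tags})
        cell_map = {bc: bc for bc in barcodes}
    buckets, unassigned = demultiplex(tags, dict(cell_map))
    adata = quantify.count_isoforms(buckets, peaks)
    adata.uns["n_tags_unassigned_cells"] = len(unassigned)
    return adata
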