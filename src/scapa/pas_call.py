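"""Poly(A)-site identification from pooled poly(A)-flagged tag 3'-ends.

The caller piles up deduplicated poly(A)-tagged 3'-ends (optionally
restricted to annotated 3'UTRs), removes internal-priming artifacts whose
downstream genomic sequence is adenine-rich, clusters nearby positions by
single-linkage distance clustering, thresholds clusters on raw and
library-normalised tag counts, and reports cluster summits as
single-nucleotide poly(A) sites.  Sites are then classified against an
annotated site set and profiled for the canonical AAUAAA signal, which for
genuine cleavage sites concentrates ~21 nt upstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import StrandedIntervals
from .preprocess import DedupedTag

__all__ = [
    "TagCluster",
    "SignalProfile",
    "collect_polya_tags",
    "filter_internal_priming",
    "cluster_tags",
    "call_sites",
    "classify_vs_annotation",
    "motif_profile",
    "merge_site_sets",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TagCluster:
    chrom: str
    strand: str
    start: int  # 0-based half-open over member positions
    end: int
    positions: List[int]
    counts: List[int]
    summit: int
    total: int


@dataclass
class SignalProfile:
    motif: str
    offsets: np.ndarray          # -flank .. +flank
    freq: np.ndarray             # fraction of sites with occurrence at offset
    upstream_fraction: float
    n_sites: int
    n_excluded: int = 0


def collect_polya_tags(tags: Iterable[DedupedTag],
                       utr3: Optional[pd.DataFrame] = None,
                       restrict_to_utr3: bool = True) -> pd.DataFrame:
    """Pile up poly(A)-flagged tag 3'-ends into per-position counts.

    With ``restrict_to_utr3`` (the default) only tags whose 3'-end falls in
    a same-strand 3'UTR interval are kept; disabling the restriction admits
    intronic/intergenic candidate sites.  Returns a pileup frame with
    columns chrom/strand/pos/count.
    """
    trees = None
    if restrict_to_utr3:
        if utr3 is None or len(utr3) == 0:
            raise ValueError("3'UTR restriction enabled but no annotation given")
        trees = StrandedIntervals(utr3)
    counts: Dict[Tuple[str, str, int], int] = {}
    for t in tags:
        if not t.polya_flag:
            continue
        if trees is not None and not trees.contains(t.chrom, t.strand, t.end3):
            continue
        key = (t.chrom, t.strand, t.end3)
        counts[key] = counts.get(key, 0) + 1
    rows = [(c, s, p, n) for (c, s, p), n in counts.items()]
    df = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "count"])
    return df.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)


def downstream_sequence(genome, chrom: str, strand: str, pos: int,
                        window: int) -> str:
    """Sense-strand genomic sequence immediately 3' of ``pos``.

    Truncated at chromosome ends.  ``genome`` is any mapping of chromosome
    name to sliceable sequence (e.g. pyfaidx.Fasta records or plain strings).
    """
    chrom_seq = genome[chrom]
    n = len(chrom_seq)
    if strand == "+":
        seq = str(chrom_seq[min(pos + 1, n):min(pos + 1 + window, n)])
    else:
        seq = revcomp(str(chrom_seq[max(pos - window, 0):max(pos, 0)]))
    return seq.upper()


def filter_internal_priming(pileup: pd.DataFrame, genome,
                            window: int = 20, min_run: int = 6) -> pd.DataFrame:
    """Drop positions whose downstream genomic window holds an A-run.

    A candidate 3'-end with ``min_run`` or more consecutive adenines in the
    ``window`` nt immediately downstream (transcription direction) is most
    likely an oligo-dT internal-priming artifact, not a cleavage site.
    """
    if pileup.empty:
        return pileup.copy()
    pat = re.compile("A{%d,}" % min_run)
    keep = []
    for row in pileup.itertuples(index=False):
        seq = downstream_sequence(genome, row.chrom, row.strand,
                                  int(row.pos), window)
        keep.append(pat.search(seq) is None)
    return pileup.loc[keep].reset_index(drop=True)


def cluster_tags(pileup: pd.DataFrame, max_gap: int = 20) -> List[TagCluster]:
    """Single-linkage distance clustering of pileup positions.

    Two positions join the same cluster iff a chain of consecutive gaps
    <= ``max_gap`` connects them.  The summit is the member with the highest
    count; ties break to the 5'-most position in transcription direction.
    """
    clusters: List[TagCluster] = []
    for (chrom, strand), grp in pileup.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=int)
        cnt = grp["count"].to_numpy(dtype=int)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk_pos, chunk_cnt in zip(np.split(pos, breaks), np.split(cnt, breaks)):
            best = chunk_cnt.max()
            summit_candidates = chunk_pos[chunk_cnt == best]
            summit = int(summit_candidates.min() if strand == "+"
                         else summit_candidates.max())
            clusters.append(TagCluster(
                chrom=chrom, strand=strand,
                start=int(chunk_pos.min()), end=int(chunk_pos.max()) + 1,
                positions=[int(p) for p in chunk_pos],
                counts=[int(c) for c in chunk_cnt],
                summit=summit, total=int(chunk_cnt.sum())))
    return clusters


def call_sites(clusters: Sequence[TagCluster], total_polya_tags: int,
               min_norm_count: float = 1.0, min_raw_count: int = 3
               ) -> pd.DataFrame:
    """Threshold clusters and emit summits as poly(A) sites.

    ``min_norm_count`` is in tags-per-million of the library-wide
    deduplicated poly(A) tag count.  Returns a site frame with columns
    chrom/strand/pos/tag_count/norm_count (plus a stable site name).
    """
    if total_polya_tags <= 0:
        raise ValueError("total_polya_tags must be positive")
    rows = []
    for cl in clusters:
        norm = cl.total * 1e6 / total_polya_tags
        if cl.total >= min_raw_count and norm >= min_norm_count:
            rows.append((cl.chrom, cl.strand, cl.summit, cl.total, norm))
    df = pd.DataFrame(rows, columns=["chrom", "strand", "pos",
                                     "tag_count", "norm_count"])
    df = df.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    df["name"] = [f"pas_{i}" for i in range(len(df))]
    return df


def classify_vs_annotation(sites: pd.DataFrame, annotated: pd.DataFrame,
                           match_dist: int = 24
                           ) -> Tuple[pd.DataFrame, Dict[int, int]]:
    """Signed distance to the nearest same-strand annotated site.

    The distance is measured in transcription direction (positive = the
    annotated site lies downstream of the called site).  Sites within
    ``match_dist`` of an annotated site are labelled ``annotated``, the rest
    ``novel``; a histogram of distances within +/-100 nt is also returned.
    """
    out = sites.copy()
    dists: List[Optional[int]] = []
    ann_by_key: Dict[Tuple[str, str], np.ndarray] = {
        key: np.sort(grp["pos"].to_numpy(dtype=int))
        for key, grp in annotated.groupby(["chrom", "strand"])
    } if len(annotated) else {}
    for row in sites.itertuples(index=False):
        arr = ann_by_key.get((row.chrom, row.strand))
        if arr is None or len(arr) == 0:
            dists.append(None)
            continue
        i = np.searchsorted(arr, row.pos)
        best = min((int(arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)),
                   key=lambda a: abs(a - row.pos))
        d = best - int(row.pos)
        if row.strand == "-":
            d = -d
        dists.append(int(d))
    out["nearest_annotated_dist"] = pd.array(dists, dtype="Int64")
    out["status"] = np.where(
        out["nearest_annotated_dist"].notna()
        & (out["nearest_annotated_dist"].abs() <= match_dist),
        "annotated", "novel")
    hist: Dict[int, int] = {}
    for d in dists:
        if d is not None and -100 <= d <= 100:
            hist[d] = hist.get(d, 0) + 1
    return out, hist


def _site_sense_window(genome, chrom: str, strand: str, pos: int,
                       flank: int, motif_len: int) -> Optional[str]:
    """Sense-strand sequence covering motif starts at offsets -flank..+flank."""
    chrom_seq = genome[chrom]
    n = len(chrom_seq)
    if strand == "+":
        lo, hi = pos - flank, pos + flank + motif_len
        if lo < 0 or hi > n:
            return None
        return str(chrom_seq[lo:hi]).upper()
    lo, hi = pos - flank - motif_len + 1, pos + flank + 1
    if lo < 0 or hi > n:
        return None
    return revcomp(str(chrom_seq[lo:hi]).upper())


def motif_profile(sites: pd.DataFrame, genome, motif: str = "AATAAA",
                  flank: int = 50,
                  upstream_window: Tuple[int, int] = (-50, -1)) -> SignalProfile:
    """Positional frequency of a hexamer around sites (offset 0 = site).

    freq[o] is the fraction of profiled sites whose sense-strand sequence
    carries a motif occurrence *starting* at offset o; upstream_fraction is
    the fraction with at least one occurrence starting inside
    ``upstream_window``.  Sites whose flanks run off the chromosome are
    excluded from the denominator and counted.
    """
    offsets = np.arange(-flank, flank + 1)
    hits = np.zeros(len(offsets), dtype=float)
    n_used = 0
    n_excluded = 0
    n_upstream = 0
    for row in sites.itertuples(index=False):
        seq = _site_sense_window(genome, row.chrom, row.strand, int(row.pos),
                                 flank, len(motif))
        if seq is None:
            n_excluded += 1
            continue
        n_used += 1
        site_hit_upstream = False
        for i in range(len(seq) - len(motif) + 1):
            if seq[i:i + len(motif)] == motif:
                o = i - flank
                hits[o + flank] += 1
                if upstream_window[0] <= o <= upstream_window[1]:
                    site_hit_upstream = True
        if site_hit_upstream:
            n_upstream += 1
    freq = hits / n_used if n_used else hits
    return SignalProfile(motif=motif, offsets=offsets, freq=freq,
                         upstream_fraction=(n_upstream / n_used if n_used else 0.0),
                         n_sites=n_used, n_excluded=n_excluded)


def merge_site_sets(site_sets: Sequence[pd.DataFrame],
                    match_dist: int = 24) -> pd.DataFrame:
    """Merge per-cell-type site sets by single-linkage within ``match_dist``.

    Sites from different sets within ``match_dist`` of each other (chained)
    collapse to one representative: the member with the highest tag count.
    A ``n_sets`` column records how many input sets support each merged site.
    """
    frames = []
    for k, df in enumerate(site_sets):
        if len(df):
            d = df.copy()
            d["_set"] = k
            frames.append(d)
    if not frames:
        return pd.DataFrame(columns=["chrom", "strand", "pos", "tag_count",
                                     "norm_count", "name", "n_sets"])
    allsites = pd.concat(frames, ignore_index=True)
    rows = []
    for (chrom, strand), grp in allsites.groupby(["chrom", "strand"]):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=int)
        breaks = np.flatnonzero(np.diff(pos) > match_dist) + 1
        idx_chunks = np.split(np.arange(len(grp)), breaks)
        for idx in idx_chunks:
            sub = grp.iloc[idx]
            rep = sub.loc[sub["tag_count"].idxmax()]
            rows.append((chrom, strand, int(rep["pos"]), int(sub["tag_count"].sum()),
                         float(sub["norm_count"].max()), sub["_set"].nunique()))
    out = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "tag_count",
                                      "norm_count", "n_sets"])
    out = out.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)
    out["name"] = [f"pas_{i}" for i in range(len(out))]
    return out
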