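"""Strand-aware interval sets from GTF and BED annotation.

Provides the two region sets the pipeline needs from a gene annotation:
per-transcript 3'UTRs (for restricting candidate poly(A) tags) and gene
bodies (for assigning peak regions to genes), plus BED6 readers/writers for
annotated poly(A)-site sets.  Coordinates are 0-based half-open internally;
GTF is 1-based inclusive on disk, BED is 0-based half-open.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, Optional, Tuple

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "read_gtf",
    "three_prime_utrs",
    "gene_bodies",
    "read_bed_sites",
    "write_bed_sites",
    "StrandedIntervals",
]

_GTF_COLS = ["chrom", "source", "feature", "start", "end",
             "score", "strand", "frame", "attributes"]


def _attr(attributes: pd.Series, key: str) -> pd.Series:
    return attributes.str.extract(rf'{key} "([^"]+)"', expand=False)


def read_gtf(path: str) -> pd.DataFrame:
    """Read a GTF file into a tidy frame (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=_GTF_COLS, dtype={"chrom": str})
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    df["gene_id"] = _attr(df["attributes"], "gene_id")
    df["transcript_id"] = _attr(df["attributes"], "transcript_id")
    return df.drop(columns=["attributes"])


def three_prime_utrs(gtf: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript 3'UTR intervals.

    For transcripts with CDS records the 3'UTR is the exonic region strictly
    3' of the CDS end (in transcription direction); transcripts without CDS
    contribute their terminal exon.  Returns columns chrom/start/end/strand/
    gene_id/transcript_id.
    """
    out = []
    exons = gtf[gtf.feature == "exon"]
    cds = gtf[gtf.feature == "CDS"]
    cds_by_tx = dict(tuple(cds.groupby("transcript_id"))) if len(cds) else {}
    for tx_id, tx_exons in exons.groupby("transcript_id"):
        strand = tx_exons.strand.iloc[0]
        chrom = tx_exons.chrom.iloc[0]
        gene = tx_exons.gene_id.iloc[0]
        tx_cds = cds_by_tx.get(tx_id)
        if tx_cds is None or tx_cds.empty:
            # terminal exon in transcription direction
            term = (tx_exons.loc[tx_exons.end.idxmax()] if strand == "+"
                    else tx_exons.loc[tx_exons.start.idxmin()])
            out.append((chrom, int(term.start), int(term.end), strand, gene, tx_id))
            continue
        if strand == "+":
            cds_end = int(tx_cds.end.max())
            for _, ex in tx_exons.iterrows():
                s, e = max(int(ex.start), cds_end), int(ex.end)
                if s < e:
                    out.append((chrom, s, e, strand, gene, tx_id))
        else:
            cds_end = int(tx_cds.start.min())
            for _, ex in tx_exons.iterrows():
                s, e = int(ex.start), min(int(ex.end), cds_end)
                if s < e:
                    out.append((chrom, s, e, strand, gene, tx_id))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "strand",
                                      "gene_id", "transcript_id"])


def gene_bodies(gtf: pd.DataFrame) -> pd.DataFrame:
    """Per-gene [min start, max end) span, from gene records when present."""
    genes = gtf[gtf.feature == "gene"]
    if genes.empty:
        base = gtf[gtf.feature.isin(["transcript", "exon"])]
        genes = (base.groupby("gene_id")
                 .agg(chrom=("chrom", "first"), start=("start", "min"),
                      end=("end", "max"), strand=("strand", "first"))
                 .reset_index())
        return genes[["chrom", "start", "end", "strand", "gene_id"]]
    return genes[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def read_bed_sites(path: str) -> pd.DataFrame:
    """Read single-nucleotide poly(A) sites from BED6 (pos = interval start)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=range(6),
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    df["pos"] = df["start"].astype(int)
    return df


def write_bed_sites(sites: pd.DataFrame, path: str,
                    name_col: str = "name", score_col: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(sites.itertuples(index=False)):
            name = getattr(row, name_col, None) or f"site_{i}"
            score = getattr(row, score_col) if score_col else 0
            pos = int(row.pos)
            fh.write(f"{row.chrom}\t{pos}\t{pos + 1}\t{name}\t{score}\t{row.strand}\n")


class StrandedIntervals:
    """Interval membership / overlap queries keyed by (chrom, strand)."""

    def __init__(self, intervals: pd.DataFrame, data_col: Optional[str] = None):
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for row in intervals.itertuples(index=False):
            key = (row.chrom, row.strand)
            tree = self._trees.setdefault(key, IntervalTree())
            data = getattr(row, data_col) if data_col else None
            if int(row.end) > int(row.start):
                tree.addi(int(row.start), int(row.end), data)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def contains(self, chrom: str, strand: str, pos: int) -> bool:
        tree = self._trees.get((chrom, strand))
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> list:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]
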