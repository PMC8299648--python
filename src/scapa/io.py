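"""On-disk exchange formats: tag tables, site tables, count matrices.

Deduplicated tags travel as TSV (one molecule per row); sites as BED6 plus
a TSV sidecar with normalised counts and annotation status; count matrices
as MatrixMarket with barcode / isoform sidecars (the layout count-matrix
consumers expect); usage and uTPM as TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, List

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .preprocess import DedupedTag

__all__ = [
    "write_tags", "read_tags",
    "write_sites", "read_sites_tsv",
    "write_counts", "read_counts",
]

_TAG_COLS = ["cell_barcode", "umi", "chrom", "strand", "end3", "polya"]


def write_tags(tags: Iterable[DedupedTag], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(_TAG_COLS) + "\n")
        for t in tags:
            fh.write(f"{t.cell_barcode}\t{t.umi}\t{t.chrom}\t{t.strand}"
                     f"\t{t.end3}\t{1 if t.polya_flag else 0}\n")
            n += 1
    return n


def read_tags(path: str) -> List[DedupedTag]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell_barcode": str,
                                            "umi": str})
    return [DedupedTag(cell_barcode=r.cell_barcode, umi=r.umi, chrom=r.chrom,
                       strand=r.strand, end3=int(r.end3),
                       polya_flag=bool(r.polya))
            for r in df.itertuples(index=False)]


def write_sites(sites: pd.DataFrame, bed_path: str, tsv_path: str) -> None:
    with open(bed_path, "w") as fh:
        for row in sites.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.name}"
                     f"\t{int(row.tag_count)}\t{row.strand}\n")
    sites.to_csv(tsv_path, sep="\t", index=False)


def read_sites_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_counts(adata: ad.AnnData, outdir: str) -> None:
    """MTX (cells x isoforms) + barcodes.tsv + isoforms.tsv."""
    os.makedirs(outdir, exist_ok=True)
    X = scipy.sparse.csr_matrix(np.asarray(adata.X))
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X)
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False,
        header=False)
    adata.var.to_csv(os.path.join(outdir, "isoforms.tsv"), sep="\t")


def read_counts(outdir: str) -> ad.AnnData:
    X = scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).tocsr()
    barcodes = pd.read_csv(os.path.join(outdir, "barcodes.tsv"), sep="\t",
                           header=None)[0].astype(str).tolist()
    var = pd.read_csv(os.path.join(outdir, "isoforms.tsv"), sep="\t",
                      index_col=0)
    return ad.AnnData(X=np.asarray(X.todense()),
                      obs=pd.DataFrame(index=pd.Index(barcodes, name="cell")),
                      var=var)
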