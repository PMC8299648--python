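"""Synthetic genomes, cells and reads with known APA ground truth.

The generator builds the structures every downstream stage assumes, at
parameters chosen to resemble a 3'-tag scRNA-seq experiment:

* a genome of multi-poly(A)-site genes on both strands, each site with the
  canonical AATAAA signal planted ~21 nt upstream (jittered a few nt, as in
  real data), plus genomic adenine-run decoys that act as internal-priming
  traps, placed well away from true sites;
* per-cell isoform counts: each cell's usage vector is a Dirichlet draw
  around its type's mean, UMI totals are Poisson, and the isoform split is
  multinomial — "specific" genes have their mean usage shifted in one focal
  type, bimodal genes mix two cell subpopulations preferring opposite
  sites, with an expression program coupled to the subpopulation;
* reads: per UMI one read2 ending at the site with a templated poly(A)
  tail; a fraction end upstream without a tail (the peak body) and a
  fraction misprime at decoy A-runs.  A truth SAM is emitted alongside the
  FASTQ so tests can bypass an external aligner.

Everything is deterministic given the seed, and every random draw is
recorded in a returned truth table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import pysam

from .pas_call import revcomp

__all__ = [
    "SimGenomeSpec",
    "SimCellSpec",
    "SimReference",
    "SimCounts",
    "make_reference",
    "synthetic_sites",
    "simulate_counts",
    "simulate_modality_counts",
    "simulate_reads",
    "write_reference",
]

_CHROM = "chrSim"
_SIGNAL = "AATAAA"

# 3'-end jitter of tailed reads around the true cleavage site; the mode
# stays at the site so cluster summits recover it exactly
_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_JITTER_PROBS = np.array([0.10, 0.15, 0.50, 0.15, 0.10])


@dataclass
class SimGenomeSpec:
    n_genes: int = 10
    sites_per_gene: int = 2
    utr_len: int = 600
    upstream_len: int = 200
    intergenic_len: int = 200
    signal_offset: int = -21
    signal_jitter: int = 3
    decoy_a_run_len: int = 10
    decoys_per_gene: int = 1
    seed: int = 0


@dataclass
class SimReference:
    genome: Dict[str, str]
    gtf: pd.DataFrame           # 0-based half-open, scapa.annotation layout
    sites: pd.DataFrame         # truth poly(A) sites
    decoys: pd.DataFrame        # internal-priming trap positions
    spec: SimGenomeSpec


@dataclass
class SimCellSpec:
    cell_types: Dict[str, int] = field(default_factory=lambda: {"typeA": 200})
    concentration: float = 10.0           # Dirichlet concentration; inf = fixed
    depth_per_gene: float = 30.0          # Poisson mean UMIs / gene / cell
    specific_genes: Dict[str, str] = field(default_factory=dict)
    shift: float = 0.4                    # programmed between-type usage shift
    bimodal_genes: List[str] = field(default_factory=list)
    subpop_fracs: Tuple[float, float] = (0.5, 0.5)
    subpop_distal_means: Tuple[float, float] = (0.15, 0.85)
    program_genes: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SimCounts:
    counts: ad.AnnData                    # cells x isoforms
    labels: Dict[str, str]                # cell -> type
    truth_usage: pd.DataFrame             # cells x isoforms (the Dirichlet draw)
    subpops: Optional[pd.Series] = None   # cell -> {1, 2} for bimodal presets
    truth_modality: Optional[pd.Series] = None


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    seq = "".join(rng.choice(list("ACGT"), size=n))
    # suppress background adenine runs so only planted decoys can misprime
    while True:
        m = re.search("A{4,}", seq)
        if m is None:
            return seq
        seq = seq[:m.start() + 3] + "G" + seq[m.start() + 4:]


def _plant(seq: List[str], start: int, motif: str) -> None:
    seq[start:start + len(motif)] = list(motif)


def make_reference(spec: SimGenomeSpec) -> SimReference:
    """Genome + annotation + truth site/decoy tables, deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    k = spec.sites_per_gene
    spacing = spec.utr_len // (k + 1)
    if spacing < 100:
        raise ValueError("utr_len too small for the requested sites_per_gene: "
                         "inter-site spacing must be >= 100 nt")
    gene_len = spec.upstream_len + spec.utr_len
    unit = gene_len + spec.intergenic_len
    chrom_len = spec.n_genes * unit + spec.intergenic_len
    seq = list(_random_sequence(rng, chrom_len))

    gtf_rows, site_rows, decoy_rows = [], [], []
    for i in range(spec.n_genes):
        gene_id = f"g{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        g0 = spec.intergenic_len + i * unit
        g1 = g0 + gene_len
        gtf_rows += [
            (_CHROM, "sim", "gene", g0, g1, ".", strand, ".", gene_id, None),
            (_CHROM, "sim", "transcript", g0, g1, ".", strand, ".",
             gene_id, gene_id + ".t1"),
            (_CHROM, "sim", "exon", g0, g1, ".", strand, ".",
             gene_id, gene_id + ".t1"),
        ]
        # site positions, proximal -> distal in transcription direction
        for j in range(1, k + 1):
            rel = j * spacing
            if strand == "+":
                pos = g0 + spec.upstream_len + rel
            else:
                pos = g1 - spec.upstream_len - rel
            offset = spec.signal_offset + int(
                rng.integers(-spec.signal_jitter, spec.signal_jitter + 1))
            if strand == "+":
                _plant(seq, pos + offset, _SIGNAL)
            else:
                _plant(seq, pos - offset - len(_SIGNAL) + 1, revcomp(_SIGNAL))
            site_rows.append((_CHROM, strand, pos, gene_id, j, offset))
        # internal-priming decoys inside the 3'UTR, >= 50 nt from any site
        for m in range(spec.decoys_per_gene):
            rel = spacing // 2 - m * (spec.decoy_a_run_len + 15)
            if rel < 10:
                raise ValueError("too many decoys for the inter-site spacing")
            if strand == "+":
                run_start = g0 + spec.upstream_len + rel
                _plant(seq, run_start, "A" * spec.decoy_a_run_len)
                ip_end3 = run_start - 1
            else:
                run_end = g1 - spec.upstream_len - rel  # 5'-most sense base
                run_start = run_end - spec.decoy_a_run_len + 1
                _plant(seq, run_start, "T" * spec.decoy_a_run_len)
                ip_end3 = run_end + 1
            decoy_rows.append((_CHROM, strand, ip_end3, gene_id,
                               run_start, spec.decoy_a_run_len))

    gtf = pd.DataFrame(gtf_rows, columns=["chrom", "source", "feature",
                                          "start", "end", "score", "strand",
                                          "frame", "gene_id", "transcript_id"])
    sites = pd.DataFrame(site_rows, columns=["chrom", "strand", "pos",
                                             "gene_id", "site_rank",
                                             "signal_offset"])
    sites["name"] = [f"{g}.s{r}" for g, r in zip(sites.gene_id, sites.site_rank)]
    decoys = pd.DataFrame(decoy_rows, columns=["chrom", "strand", "pos",
                                               "gene_id", "run_start",
                                               "run_len"])
    return SimReference(genome={_CHROM: "".join(seq)}, gtf=gtf, sites=sites,
                        decoys=decoys, spec=spec)


def write_reference(ref: SimReference, fasta_path: str, gtf_path: str,
                    sites_bed: Optional[str] = None,
                    decoys_bed: Optional[str] = None) -> None:
    with open(fasta_path, "w") as fh:
        for chrom, seq in ref.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    with open(gtf_path, "w") as fh:
        for row in ref.gtf.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            if row.transcript_id:
                attrs += f' transcript_id "{row.transcript_id}";'
            fh.write(f"{row.chrom}\t{row.source}\t{row.feature}\t"
                     f"{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n")
    if sites_bed:
        with open(sites_bed, "w") as fh:
            for row in ref.sites.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.name}"
                         f"\t0\t{row.strand}\n")
    if decoys_bed:
        with open(decoys_bed, "w") as fh:
            for i, row in enumerate(ref.decoys.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\tdecoy_{i}"
                         f"\t0\t{row.strand}\n")


def synthetic_sites(n_genes: int, sites_per_gene: int = 2,
                    spacing: int = 200) -> pd.DataFrame:
    """Minimal truth site table for count-only simulations (no genome)."""
    rows = []
    for i in range(n_genes):
        gene_id = f"g{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        base = 1000 + i * 10 * spacing
        for j in range(1, sites_per_gene + 1):
            pos = base + j * spacing if strand == "+" else base - j * spacing
            rows.append((_CHROM, strand, pos, gene_id, j,
                         f"{gene_id}.s{j}"))
    return pd.DataFrame(rows, columns=["chrom", "strand", "pos", "gene_id",
                                       "site_rank", "name"])


def _isoform_var(sites: pd.DataFrame) -> pd.DataFrame:
    var = sites.copy()
    var["site_pos"] = var["pos"]
    var["site_name"] = var["name"]
    var.index = pd.Index([f"{g}:{n}" for g, n in zip(var.gene_id, var.name)],
                         name="isoform")
    return var[["chrom", "strand", "gene_id", "site_pos", "site_name",
                "site_rank"]]


def _distal_first_means(sites_gene: pd.DataFrame, distal_mean: float
                        ) -> np.ndarray:
    """Mean usage vector placing ``distal_mean`` on the 3'-most isoform and
    the rest evenly on the others (isoforms in site_rank order)."""
    n = len(sites_gene)
    m = np.full(n, (1.0 - distal_mean) / (n - 1))
    m[-1] = distal_mean  # highest site_rank = most distal
    return m


def simulate_counts(cellspec: SimCellSpec, sites: pd.DataFrame) -> SimCounts:
    """Per-cell isoform UMI counts with Dirichlet-multinomial usage.

    Null genes share one mean usage vector across all cell types; genes in
    ``specific_genes`` have their distal mean shifted by ``shift`` in the
    focal type; genes in ``bimodal_genes`` draw their mean from the cell's
    subpopulation; ``program_genes`` are expression-only markers whose
    Poisson depth depends on the subpopulation.
    """
    rng = np.random.default_rng(cellspec.seed)
    var = _isoform_var(sites)
    genes = list(pd.unique(var["gene_id"]))
    cells, labels = [], {}
    for t, n in cellspec.cell_types.items():
        for i in range(n):
            cid = f"{t}_c{i:04d}"
            cells.append(cid)
            labels[cid] = t
    subpop = pd.Series(
        rng.choice([1, 2], size=len(cells), p=list(cellspec.subpop_fracs)),
        index=cells, name="subpop")

    # per-gene mean usage, possibly type- or subpopulation-dependent
    base_distal = {}
    for g in genes:
        base_distal[g] = 0.3 if g in cellspec.specific_genes else \
            float(rng.uniform(0.35, 0.65))
    iso_by_gene = {g: var.index[var["gene_id"] == g].tolist() for g in genes}
    gene_rows = {g: sites[sites.gene_id == g].sort_values("site_rank")
                 for g in genes}

    X = np.zeros((len(cells), len(var)), dtype=np.int64)
    U = np.full((len(cells), len(var)), np.nan)
    col_of = {iso: j for j, iso in enumerate(var.index)}
    for ci, cell in enumerate(cells):
        ctype = labels[cell]
        for g in genes:
            isoforms = iso_by_gene[g]
            if g in cellspec.program_genes:
                lo, hi = cellspec.program_genes[g]
                rate = hi if subpop[cell] == 2 else lo
                total = rng.poisson(rate)
                X[ci, col_of[isoforms[0]]] = total
                if total > 0:
                    U[ci, col_of[isoforms[0]]] = 1.0
                continue
            if g in cellspec.bimodal_genes:
                m_d = cellspec.subpop_distal_means[subpop[cell] - 1]
                m = _distal_first_means(gene_rows[g], m_d)
            elif (g in cellspec.specific_genes
                  and cellspec.specific_genes[g] == ctype):
                m = _distal_first_means(gene_rows[g],
                                        base_distal[g] + cellspec.shift)
            else:
                m = _distal_first_means(gene_rows[g], base_distal[g])
            if np.isfinite(cellspec.concentration):
                u = rng.dirichlet(cellspec.concentration * m)
            else:
                u = m.copy()
            total = rng.poisson(cellspec.depth_per_gene)
            c = rng.multinomial(total, u) if total > 0 else np.zeros(len(u), int)
            for iso, uu, cc in zip(isoforms, u, c):
                X[ci, col_of[iso]] = cc
                U[ci, col_of[iso]] = uu
    adata = ad.AnnData(X=X,
                       obs=pd.DataFrame({"cell_type": [labels[c] for c in cells]},
                                        index=pd.Index(cells, name="cell")),
                       var=var.copy())
    truth_usage = pd.DataFrame(U, index=cells, columns=var.index)
    return SimCounts(counts=adata, labels=labels, truth_usage=truth_usage,
                     subpops=subpop)


_MODALITY_GENERATORS = ("distal", "proximal", "middle", "bimodal", "multimodal")


def _draw_distal_usage(rng: np.random.Generator, modality: str,
                       n: int) -> np.ndarray:
    if modality == "distal":
        return rng.beta(8, 1, size=n)
    if modality == "proximal":
        return rng.beta(1, 8, size=n)
    if modality == "middle":
        return 1 / 3 + rng.beta(8, 8, size=n) / 3
    if modality == "bimodal":
        hi = rng.random(n) < 0.5
        return np.where(hi, rng.beta(8, 1, size=n), rng.beta(1, 8, size=n))
    if modality == "multimodal":
        return rng.uniform(0, 1, size=n)
    raise ValueError(f"unknown modality generator {modality!r}")


def simulate_modality_counts(n_genes_per_modality: int = 40,
                             n_cells: int = 100,
                             depth_per_gene: float = 30.0,
                             seed: int = 0) -> SimCounts:
    """Two-isoform genes whose distal usage follows one of five generators.

    Per gene the per-cell distal usage v is drawn from the generator of its
    assigned modality (beta / mixture / uniform families), and counts split
    the Poisson UMI total binomially.  Truth modality labels are returned.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_genes_per_modality * len(_MODALITY_GENERATORS)
    sites = synthetic_sites(n_genes, sites_per_gene=2)
    var = _isoform_var(sites)
    cells = [f"typeA_c{i:04d}" for i in range(n_cells)]
    labels = {c: "typeA" for c in cells}
    truth = {}
    X = np.zeros((n_cells, len(var)), dtype=np.int64)
    U = np.full((n_cells, len(var)), np.nan)
    genes = list(pd.unique(var["gene_id"]))
    for gi, g in enumerate(genes):
        modality = _MODALITY_GENERATORS[gi // n_genes_per_modality]
        truth[g] = modality
        v = _draw_distal_usage(rng, modality, n_cells)
        cols = np.flatnonzero((var["gene_id"] == g).to_numpy())
        # column order follows site_rank; the last is the distal isoform
        totals = rng.poisson(depth_per_gene, size=n_cells)
        distal_counts = rng.binomial(totals, v)
        X[:, cols[0]] = totals - distal_counts
        X[:, cols[1]] = distal_counts
        U[:, cols[0]] = 1 - v
        U[:, cols[1]] = v
    adata = ad.AnnData(X=X,
                       obs=pd.DataFrame({"cell_type": ["typeA"] * n_cells},
                                        index=pd.Index(cells, name="cell")),
                       var=var.copy())
    return SimCounts(counts=adata, labels=labels,
                     truth_usage=pd.DataFrame(U, index=cells, columns=var.index),
                     truth_modality=pd.Series(truth, name="modality"))


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 12
                     ) -> List[str]:
    out: List[str] = []
    seen = set()
    while len(out) < n:
        bc = "".join(rng.choice(list("ACGT"), size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_reads(sim: SimCounts, ref: SimReference,
                   r1_path: str, r2_path: str, sam_path: str,
                   read_len: int = 60, tail_len: int = 12,
                   nonpolya_frac: float = 0.3, ip_frac: float = 0.1,
                   error_rate: float = 0.0, seed: int = 0,
                   barcode_len: int = 12, umi_len: int = 8
                   ) -> pd.DataFrame:
    """Paired FASTQ plus a truth-aligned SAM for the simulated counts.

    Per UMI one read2: with probability ``nonpolya_frac`` it ends upstream
    of the site without a tail (peak body), otherwise it ends at the site
    (small 3' jitter) with a ``tail_len`` poly(A) tail appended.  Per gene
    and cell, extra internal-priming molecules arrive at rate ``ip_frac`` x
    depth, ending immediately 5' of a decoy A-run whose templated adenines
    mimic a tail.  Returns the cell -> barcode map as a DataFrame.
    """
    if tail_len < 8:
        raise ValueError("tail_len must be >= 8 so tails are recognisable")
    rng = np.random.default_rng(seed)
    genome = ref.genome[_CHROM]
    chrom_len = len(genome)
    adata = sim.counts
    cells = list(adata.obs_names)
    barcodes = _random_barcodes(rng, len(cells), barcode_len)
    bc_of = dict(zip(cells, barcodes))
    var = adata.var
    decoys_by_gene = {g: grp for g, grp in ref.decoys.groupby("gene_id")}
    body_len = read_len - tail_len

    records = []  # (refstart, raw_seq, aligned_seq, strand, bc, umi, pa, name)
    serial = 0

    def add_read(end3: int, strand: str, tailed: bool, bc: str,
                 tail_seq: Optional[str] = None) -> None:
        nonlocal serial
        if strand == "+":
            lo = max(0, end3 - body_len + 1)
            aligned = genome[lo:end3 + 1]
            sense = aligned
        else:
            hi = min(chrom_len, end3 + body_len)
            aligned = genome[end3:hi]
            sense = revcomp(aligned)
        if tailed:
            tail = tail_seq if tail_seq is not None else "A" * tail_len
            raw = sense + tail
        else:
            raw = sense
        if error_rate > 0:
            raw_l = list(raw)
            for i in np.flatnonzero(rng.random(len(raw_l)) < error_rate):
                raw_l[i] = rng.choice([b for b in "ACGT" if b != raw_l[i]])
            raw = "".join(raw_l)
        umi = "".join(rng.choice(list("ACGT"), size=umi_len))
        name = f"read{serial:07d}"
        serial += 1
        refstart = end3 - len(aligned) + 1 if strand == "+" else end3
        records.append((refstart, raw, aligned, strand, bc, umi, tailed, name))

    site_rows = {g: grp.sort_values("site_rank")
                 for g, grp in ref.sites.groupby("gene_id")}
    X = np.asarray(adata.X)
    for ci, cell in enumerate(cells):
        bc = bc_of[cell]
        for g, grp in site_rows.items():
            iso_idx = [var.index.get_loc(f"{g}:{n}") for n in grp["name"]]
            gene_total = 0
            for (_, site), col in zip(grp.iterrows(), iso_idx):
                c = int(X[ci, col])
                gene_total += c
                for _ in range(c):
                    if rng.random() < nonpolya_frac:
                        off = int(rng.integers(20, 151))
                        end3 = (site.pos - off if site.strand == "+"
                                else site.pos + off)
                        add_read(end3, site.strand, tailed=False, bc=bc)
                    else:
                        j = int(rng.choice(_JITTER_OFFSETS, p=_JITTER_PROBS))
                        end3 = site.pos + (j if site.strand == "+" else -j)
                        add_read(end3, site.strand, tailed=True, bc=bc)
            # internal-priming molecules at this gene's decoys
            dec = decoys_by_gene.get(g)
            if dec is not None and ip_frac > 0 and gene_total > 0:
                n_ip = rng.poisson(ip_frac * gene_total)
                for _ in range(n_ip):
                    d = dec.iloc[int(rng.integers(len(dec)))]
                    if d.strand == "+":
                        tail_seq = genome[d.pos + 1:d.pos + 1 + tail_len]
                    else:
                        tail_seq = revcomp(genome[d.pos - tail_len:d.pos])
                    add_read(int(d.pos), d.strand, tailed=True, bc=bc,
                             tail_seq=tail_seq)

    # FASTQ pair (read1 = barcode + UMI, read2 = cDNA with tail)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for refstart, raw, aligned, strand, bc, umi, pa, name in records:
            r1 = bc + umi
            f1.write(f"@{name}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}\n{raw}\n+\n{'I' * len(raw)}\n")

    # truth SAM with the trimmed alignments, coordinate-sorted
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": _CHROM, "LN": chrom_len}]}
    records.sort(key=lambda r: r[0])
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for refstart, raw, aligned, strand, bc, umi, pa, name in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{name}_CB:{bc}_UB:{umi}_PA:{1 if pa else 0}"
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = refstart
            a.mapping_quality = 60
            a.cigarstring = f"{len(aligned)}M"
            a.query_sequence = aligned if strand == "+" else aligned
            a.query_qualities = pysam.qualitystring_to_array("I" * len(aligned))
            a.set_tag("CB", bc)
            a.set_tag("UB", umi)
            a.set_tag("XA", 1 if pa else 0, value_type="i")
            out.write(a)
    return pd.DataFrame({"cell": cells, "barcode": [bc_of[c] for c in cells]})
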