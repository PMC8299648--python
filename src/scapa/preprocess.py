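"""Raw-read labelling, poly(A) trimming, deduplication and demultiplexing.

3'-tag scRNA-seq protocols put the cell barcode and UMI on read1 and the
cDNA on read2.  This module moves the barcode/UMI onto the read2 name (so
any aligner passes them through), trims templated poly(A) tails while
flagging the reads that carried one, and — after external alignment —
collapses PCR duplicates on (cell barcode, UMI, chromosome, strand, 3'-end
coordinate) into :class:`DedupedTag` records, the atomic evidence unit for
everything downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import pysam

__all__ = [
    "RawReadPair",
    "BarcodeLayout",
    "TaggedRead",
    "DedupedTag",
    "LabelStats",
    "DedupStats",
    "label_reads",
    "trim_polya_and_tag",
    "process_read_pairs",
    "read_fastq_pairs",
    "write_tagged_fastq",
    "parse_labeled_name",
    "dedup",
    "demultiplex",
]

# read-name suffix carrying barcode / UMI / polyA flag through an aligner
_NAME_SUFFIX_RE = re.compile(r"_CB:([ACGTN]+)_UB:([ACGTN]+)(?:_PA:([01]))?$")


@dataclass(frozen=True)
class RawReadPair:
    """One FASTQ record pair: read1 = barcode+UMI, read2 = cDNA."""

    name: str
    read1_seq: str
    read2_seq: str
    read2_qual: str


@dataclass(frozen=True)
class BarcodeLayout:
    """Positions (0-based) of the cell barcode and UMI within read1."""

    barcode_start: int
    barcode_length: int
    umi_start: int
    umi_length: int
    whitelist: Optional[Set[str]] = None

    def __post_init__(self) -> None:
        if self.barcode_start < 0 or self.umi_start < 0:
            raise ValueError("barcode/UMI start must be non-negative")
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode/UMI length must be positive")
        b = (self.barcode_start, self.barcode_start + self.barcode_length)
        u = (self.umi_start, self.umi_start + self.umi_length)
        if max(b[0], u[0]) < min(b[1], u[1]):
            raise ValueError("barcode and UMI intervals overlap")

    @property
    def min_read1_length(self) -> int:
        return max(self.barcode_start + self.barcode_length,
                   self.umi_start + self.umi_length)


@dataclass(frozen=True)
class TaggedRead:
    """A labelled (and possibly poly(A)-trimmed) read2."""

    name: str
    seq: str
    qual: str
    cell_barcode: str
    umi: str
    polya_flag: bool = False

    @property
    def labeled_name(self) -> str:
        return (f"{self.name}_CB:{self.cell_barcode}_UB:{self.umi}"
                f"_PA:{1 if self.polya_flag else 0}")


@dataclass(frozen=True, order=True)
class DedupedTag:
    """One deduplicated molecule: its cell, UMI and aligned 3'-end."""

    cell_barcode: str
    umi: str
    chrom: str
    strand: str
    end3: int
    polya_flag: bool = False


@dataclass
class LabelStats:
    total_pairs: int = 0
    labeled: int = 0
    dropped_short_read1: int = 0
    dropped_not_whitelisted: int = 0
    trimmed_polya: int = 0
    dropped_short_after_trim: int = 0
    barcodes_seen: Set[str] = field(default_factory=set)


@dataclass
class DedupStats:
    total_records: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_low_mapq: int = 0
    skipped_unlabeled: int = 0
    duplicates_removed: int = 0


def label_reads(pairs: Iterable[RawReadPair], layout: BarcodeLayout,
                stats: Optional[LabelStats] = None) -> Iterator[TaggedRead]:
    """Extract barcode/UMI from read1 and attach them to read2.

    Pairs whose read1 is shorter than the layout are dropped and counted;
    when a whitelist is given, pairs with non-whitelisted barcodes are
    dropped and counted.  Yields untrimmed :class:`TaggedRead` precursors
    (``polya_flag`` still False).
    """
    st = stats if stats is not None else LabelStats()
    for idx, pair in enumerate(pairs):
        st.total_pairs += 1
        if not pair.read2_seq or len(pair.read2_seq) != len(pair.read2_qual):
            raise ValueError(f"malformed FASTQ record at index {idx}: {pair.name!r}")
        if len(pair.read1_seq) < layout.min_read1_length:
            st.dropped_short_read1 += 1
            continue
        bc = pair.read1_seq[layout.barcode_start:
                            layout.barcode_start + layout.barcode_length]
        umi = pair.read1_seq[layout.umi_start:
                             layout.umi_start + layout.umi_length]
        if layout.whitelist is not None and bc not in layout.whitelist:
            st.dropped_not_whitelisted += 1
            continue
        st.labeled += 1
        st.barcodes_seen.add(bc)
        yield TaggedRead(name=pair.name, seq=pair.read2_seq,
                         qual=pair.read2_qual, cell_barcode=bc, umi=umi)


def trim_polya_and_tag(read: TaggedRead, polya_run: int = 8,
                       min_len: int = 20) -> Optional[TaggedRead]:
    """Trim at the first run of >= ``polya_run`` adenines, flagging the read.

    The read is truncated at the start of the first (5'->3') run of at least
    ``polya_run`` consecutive A's; anything 3' of the tail start is treated
    as tail/adapter.  N never counts toward a run.  Returns None when the
    trimmed sequence is shorter than ``min_len``.
    """
    m = re.search("A{%d,}" % polya_run, read.seq)
    if m is None:
        return None if len(read.seq) < min_len else read
    trimmed = read.seq[:m.start()]
    if len(trimmed) < min_len:
        return None
    return TaggedRead(name=read.name, seq=trimmed, qual=read.qual[:m.start()],
                      cell_barcode=read.cell_barcode, umi=read.umi,
                      polya_flag=True)


def process_read_pairs(pairs: Iterable[RawReadPair], layout: BarcodeLayout,
                       polya_run: int = 8, min_len: int = 20
                       ) -> Tuple[List[TaggedRead], LabelStats]:
    """label_reads followed by trim_polya_and_tag, with bookkeeping."""
    stats = LabelStats()
    out: List[TaggedRead] = []
    for read in label_reads(pairs, layout, stats):
        trimmed = trim_polya_and_tag(read, polya_run=polya_run, min_len=min_len)
        if trimmed is None:
            st_flag = re.search("A{%d,}" % polya_run, read.seq) is not None
            if st_flag:
                stats.trimmed_polya += 1
            stats.dropped_short_after_trim += 1
            continue
        if trimmed.polya_flag:
            stats.trimmed_polya += 1
        out.append(trimmed)
    return out, stats


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[RawReadPair]:
    """Stream paired FASTQ (gzip-transparent via pysam)."""
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for rec1, rec2 in zip(f1, f2):
            yield RawReadPair(name=rec2.name, read1_seq=rec1.sequence.upper(),
                              read2_seq=rec2.sequence.upper(),
                              read2_qual=rec2.quality or "I" * len(rec2.sequence))


def write_tagged_fastq(reads: Iterable[TaggedRead], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.labeled_name}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def parse_labeled_name(name: str) -> Optional[Tuple[str, str, bool]]:
    """Recover (barcode, UMI, polya_flag) from a labelled read name."""
    m = _NAME_SUFFIX_RE.search(name)
    if m is None:
        return None
    return m.group(1), m.group(2), m.group(3) == "1"


def _tag_from_alignment(aln: "pysam.AlignedSegment", antisense: bool
                        ) -> Optional[DedupedTag]:
    if aln.has_tag("CB") and aln.has_tag("UB"):
        bc, umi = aln.get_tag("CB"), aln.get_tag("UB")
        pa = bool(aln.get_tag("XA")) if aln.has_tag("XA") else False
    else:
        parsed = parse_labeled_name(aln.query_name)
        if parsed is None:
            return None
        bc, umi, pa = parsed
    strand = "-" if aln.is_reverse else "+"
    if antisense:
        strand = "-" if strand == "+" else "+"
    # 3'-most aligned base in transcription direction of the tag
    end3 = aln.reference_end - 1 if strand == "+" else aln.reference_start
    return DedupedTag(cell_barcode=bc, umi=umi, chrom=aln.reference_name,
                      strand=strand, end3=end3, polya_flag=pa)


def dedup(alignments: Iterable["pysam.AlignedSegment"], mapq: int = 20,
          antisense: bool = False,
          stats: Optional[DedupStats] = None) -> List[DedupedTag]:
    """Collapse aligned, labelled reads into unique molecules.

    Only primary, uniquely mapped records (mapping quality >= ``mapq``) are
    admitted.  One tag survives per (cell barcode, UMI, chrom, strand,
    3'-end); if any duplicate carried the poly(A) flag the survivor does,
    making the result independent of input order.
    """
    st = stats if stats is not None else DedupStats()
    seen: Dict[Tuple[str, str, str, str, int], bool] = {}
    for aln in alignments:
        st.total_records += 1
        if aln.is_unmapped:
            st.skipped_unmapped += 1
            continue
        if aln.is_secondary or aln.is_supplementary:
            st.skipped_secondary += 1
            continue
        if aln.mapping_quality < mapq:
            st.skipped_low_mapq += 1
            continue
        tag = _tag_from_alignment(aln, antisense)
        if tag is None:
            st.skipped_unlabeled += 1
            continue
        key = (tag.cell_barcode, tag.umi, tag.chrom, tag.strand, tag.end3)
        if key in seen:
            st.duplicates_removed += 1
            seen[key] = seen[key] or tag.polya_flag
        else:
            seen[key] = tag.polya_flag
    return [DedupedTag(*key, polya_flag=pa) for key, pa in seen.items()]


def dedup_tags(tags: Iterable[DedupedTag]) -> List[DedupedTag]:
    """Deduplicate already-constructed tags (idempotent merge of the flag)."""
    seen: Dict[Tuple[str, str, str, str, int], bool] = {}
    for t in tags:
        key = (t.cell_barcode, t.umi, t.chrom, t.strand, t.end3)
        seen[key] = seen.get(key, False) or t.polya_flag
    return [DedupedTag(*key, polya_flag=pa) for key, pa in seen.items()]


def demultiplex(tags: Iterable[DedupedTag], cell_map: Dict[str, str]
                ) -> Tuple[Dict[str, List[DedupedTag]], List[DedupedTag]]:
    """Partition tags into per-cell buckets by barcode.

    Tags whose barcode is absent from ``cell_map`` go to the returned
    "unassigned" list; bucket sizes always sum to the input size.
    """
    if len(set(cell_map.values())) != len(cell_map):
        raise ValueError("cell_map must be injective (one barcode per cell id)")
    buckets: Dict[str, List[DedupedTag]] = {cid: [] for cid in cell_map.values()}
    unassigned: List[DedupedTag] = []
    for t in tags:
        cid = cell_map.get(t.cell_barcode)
        if cid is None:
            unassigned.append(t)
        else:
            buckets[cid].append(t)
    return buckets, unassigned
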