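"""Collection and allele-partitioning of RNA reads at a variant locus.

Each read overlapping a variant is decomposed via its CIGAR into a
(prefix, allele, suffix) triple around the variant interval, then
partitioned into alt / ref / other support by exact allele match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import pysam

from .variant_effects import Variant

logger = logging.getLogger(__name__)

_CIGAR_M_OPS = (0, 7, 8)  # M, =, X


@dataclass(frozen=True)
class ReadFilters:
    """Quality thresholds applied before a read may contribute evidence."""

    min_mapq: int = 1
    min_base_quality: int = 20
    exclude_duplicates: bool = True


@dataclass(frozen=True)
class AlleleRead:
    """A single read's evidence at a variant locus.

    ``prefix``/``suffix`` are the aligned bases 5'/3' of the locus in
    genomic plus-strand orientation (soft-clipped bases excluded);
    ``allele`` is what the read observed over the variant interval
    (empty for deletion support).
    """

    read_name: str
    prefix: str
    allele: str
    suffix: str
    mapq: int
    base_qualities: Tuple[int, ...] = ()
    is_read2: bool = False


@dataclass
class AlleleReadGroup:
    """Disjoint partition of locus-spanning reads by supported allele."""

    variant: Variant
    alt_reads: List[AlleleRead] = field(default_factory=list)
    ref_reads: List[AlleleRead] = field(default_factory=list)
    other_reads: List[AlleleRead] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.alt_reads) + len(self.ref_reads) + len(self.other_reads)


def _decompose(read: pysam.AlignedSegment, vs: int, ve: int):
    """Split a read's aligned bases around the locus ``[vs, ve)``.

    Returns ``(prefix, allele, suffix, allele_quals)``, the string
    ``"gap"`` when the locus falls inside an N (splice) gap, or ``None``
    when the read does not fully span the locus.
    """
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None:
        return None
    if quals is None:
        quals = [255] * len(seq)
    if read.cigartuples is None:
        return None

    pre: List[str] = []
    at: List[str] = []
    post: List[str] = []
    at_quals: List[int] = []
    covered = set()
    flank_left = flank_right = False
    n_gap = False
    is_insertion_variant = ve == vs

    qpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in _CIGAR_M_OPS:
            for k in range(length):
                r = rpos + k
                base = seq[qpos + k]
                if is_insertion_variant:
                    if r == vs - 1:
                        flank_left = True
                    elif r == vs:
                        flank_right = True
                    (pre if r < vs else post).append(base)
                elif r < vs:
                    pre.append(base)
                elif r >= ve:
                    post.append(base)
                else:
                    at.append(base)
                    at_quals.append(quals[qpos + k])
                    covered.add(r)
            qpos += length
            rpos += length
        elif op == 1:  # insertion relative to reference, sits at junction rpos
            bases = seq[qpos : qpos + length]
            bquals = quals[qpos : qpos + length]
            if is_insertion_variant and rpos == vs:
                at.extend(bases)
                at_quals.extend(bquals)
            elif rpos <= vs:
                pre.extend(bases)
            elif rpos >= ve:
                post.extend(bases)
            else:
                at.extend(bases)
                at_quals.extend(bquals)
            qpos += length
        elif op == 2:  # deletion: covers reference positions with no bases
            for r in range(rpos, rpos + length):
                if vs <= r < ve:
                    covered.add(r)
            rpos += length
        elif op == 3:  # N: spliced-out region carries no base evidence
            if is_insertion_variant:
                if rpos <= vs - 1 < rpos + length or rpos <= vs < rpos + length:
                    n_gap = True
            elif rpos < ve and rpos + length > vs:
                n_gap = True
            rpos += length
        elif op == 4:  # soft clip: unaligned, excluded
            qpos += length
        # H (5) and P (6) consume nothing we track

    if n_gap:
        return "gap"
    if is_insertion_variant:
        if not (flank_left and flank_right):
            return None
    elif covered != set(range(vs, ve)):
        return None
    return "".join(pre), "".join(at), "".join(post), tuple(at_quals)


def _iter_alignments(alignments, contig: str):
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments)) as fh:
            yield from fh.fetch(until_eof=True)
    elif isinstance(alignments, pysam.AlignmentFile):
        yield from alignments.fetch(until_eof=True)
    else:
        yield from alignments


def collect_reads(
    alignments,
    v: Variant,
    filters: Optional[ReadFilters] = None,
) -> AlleleReadGroup:
    """Partition locus-spanning reads into alt / ref / other support.

    ``alignments`` may be a SAM/BAM path, an open
    :class:`pysam.AlignmentFile`, or an iterable of aligned segments.
    Reads failing quality filters, or not fully spanning the variant
    interval, are excluded; reads whose alignment skips the locus through
    an N (splice) gap are assigned to ``other_reads``.
    """
    filters = filters or ReadFilters()
    group = AlleleReadGroup(variant=v)
    vs, ve = v.pos, v.end
    for read in _iter_alignments(alignments, v.contig):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if filters.exclude_duplicates and read.is_duplicate:
            continue
        if read.reference_name != v.contig:
            continue
        if read.mapping_quality < filters.min_mapq:
            continue
        if read.reference_end is None:
            continue
        if read.reference_start > vs - (1 if vs == ve else 0) or read.reference_end < ve + (1 if vs == ve else 0):
            # cheap reject: cannot span the locus (+flanks for insertions)
            if read.reference_start >= ve + 1 or read.reference_end <= vs - 1:
                continue
        result = _decompose(read, vs, ve)
        if result is None:
            continue
        if result == "gap":
            group.other_reads.append(
                AlleleRead(read.query_name, "", "", "", read.mapping_quality,
                           (), bool(read.is_read2))
            )
            continue
        prefix, allele, suffix, at_quals = result
        if at_quals and min(at_quals) < filters.min_base_quality:
            continue
        record = AlleleRead(
            read_name=read.query_name,
            prefix=prefix,
            allele=allele,
            suffix=suffix,
            mapq=read.mapping_quality,
            base_qualities=at_quals,
            is_read2=bool(read.is_read2),
        )
        if allele == v.alt:
            group.alt_reads.append(record)
        elif allele == v.ref:
            group.ref_reads.append(record)
        else:
            group.other_reads.append(record)
    return group


def alt_read_count(group: AlleleReadGroup, count_mates_separately: bool = False) -> int:
    """Number of templates (fragments) supporting the alt allele.

    Two mates of one template both supporting alt count once unless
    ``count_mates_separately`` is set.
    """
    if count_mates_separately:
        return len(group.alt_reads)
    return len({r.read_name for r in group.alt_reads})
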