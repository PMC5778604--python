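"""Assembly of the most abundant mutant coding sequence from alt reads.

Alt reads are grouped by overlap agreement around the variant anchor,
the largest group's consensus is anchored to a transcript to establish
reading frame, and the anchored sequence is translated into a mutant
protein fragment.  Because the consensus is built from whole reads,
nearby germline or somatic variants present in the supporting reads are
phased into it automatically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .genome_model import ReferenceGenome, Transcript, reverse_complement, translate
from .read_evidence import AlleleRead
from .variant_effects import Variant, cds_edit_coordinates

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 3
DEFAULT_PEPTIDE_RADIUS = 12


@dataclass
class SequenceGroup:
    """Reads whose sequences agree on every overlapping position relative
    to the variant anchor; the consensus spans the union of its reads."""

    prefix: str
    allele: str
    suffix: str
    reads: List[AlleleRead] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return self.prefix + self.allele + self.suffix

    @property
    def count(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class CodingSequenceCandidate:
    """Consensus coding sequence around one variant.

    Before anchoring, ``cdna`` is in genomic plus-strand orientation;
    :func:`anchor_to_transcript` reorients it to the coding strand and
    fills ``frame_offset`` / ``transcript_id``.
    """

    variant: Variant
    cdna: str
    variant_interval: Tuple[int, int]
    supporting_read_names: frozenset
    ref_length: int
    frame_offset: Optional[int] = None
    transcript_id: Optional[str] = None
    strand: Optional[str] = None

    @property
    def num_supporting_reads(self) -> int:
        return len(self.supporting_read_names)


@dataclass(frozen=True)
class ProteinSequenceCandidate:
    amino_acids: str
    mutant_aa_interval: Tuple[int, int]
    num_supporting_reads: int
    source_transcripts: Tuple[str, ...]
    variant: Variant
    is_frameshift: bool = False


def _prefixes_compatible(a: str, b: str) -> bool:
    # prefixes are anchored at their right edge (the variant)
    return a.endswith(b) or b.endswith(a)


def _suffixes_compatible(a: str, b: str) -> bool:
    return a.startswith(b) or b.startswith(a)


def reads_compatible(a: AlleleRead, b: AlleleRead) -> bool:
    """Two reads are compatible when their sequences agree on every
    overlapping position relative to the variant anchor."""
    return (
        a.allele == b.allele
        and _prefixes_compatible(a.prefix, b.prefix)
        and _suffixes_compatible(a.suffix, b.suffix)
    )


def group_reads_by_sequence(alt_reads: Sequence[AlleleRead]) -> List[SequenceGroup]:
    """Group alt reads into maximal mutually-compatible sets.

    Groups are the maximal cliques of the pairwise-compatibility graph,
    so the best-supported group is exactly the largest set of reads that
    agree on every overlapping base (a read carrying a sequencing error
    can never fragment the error-free majority).  A read may appear in
    more than one group when it is consistent with several consensi.
    Output order is deterministic: by support, then consensus length,
    then consensus, then member names.
    """
    import networkx as nx

    if not alt_reads:
        return []
    ordered = sorted(
        alt_reads,
        key=lambda r: (-(len(r.prefix) + len(r.suffix)), r.prefix, r.suffix,
                       r.read_name),
    )
    graph = nx.Graph()
    graph.add_nodes_from(range(len(ordered)))
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if reads_compatible(ordered[i], ordered[j]):
                graph.add_edge(i, j)
    groups = []
    for clique in nx.find_cliques(graph):
        members = [ordered[i] for i in clique]
        prefix = max((r.prefix for r in members), key=len)
        suffix = max((r.suffix for r in members), key=len)
        members.sort(key=lambda r: r.read_name)
        groups.append(SequenceGroup(prefix, members[0].allele, suffix, members))
    groups.sort(
        key=lambda g: (-g.count, -len(g.consensus), g.consensus,
                       tuple(r.read_name for r in g.reads))
    )
    return groups


def assemble_most_abundant(
    groups: Sequence[SequenceGroup],
    variant: Variant,
    min_reads: int = DEFAULT_MIN_READS,
) -> Optional[CodingSequenceCandidate]:
    """Pick the best-supported consensus as the coding-sequence candidate.

    Ties on supporting-read count break toward the longer consensus, then
    the lexicographically smaller sequence.  Returns ``None`` (caller
    logs the drop) when no group reaches ``min_reads``.
    """
    eligible = [g for g in groups if g.count >= min_reads]
    if not eligible:
        logger.info(
            "variant %s dropped: no read group reaches min_reads=%d "
            "(best had %d)",
            variant.short_id, min_reads, max((g.count for g in groups), default=0),
        )
        return None
    best = min(eligible, key=lambda g: (-g.count, -len(g.consensus), g.consensus))
    cdna = best.prefix + variant.alt + best.suffix
    interval = (len(best.prefix), len(best.prefix) + len(variant.alt))
    return CodingSequenceCandidate(
        variant=variant,
        cdna=cdna,
        variant_interval=interval,
        supporting_read_names=frozenset(r.read_name for r in best.reads),
        ref_length=len(variant.ref),
    )


def anchor_to_transcript(
    c: CodingSequenceCandidate,
    transcripts: Sequence[Transcript],
    genome: ReferenceGenome,
) -> Optional[CodingSequenceCandidate]:
    """Reorient the consensus to the coding strand and fix the reading frame.

    The consensus's reference-matching flanks are compared against each
    candidate transcript's spliced CDS; the transcript with the longest
    ungapped flank match wins (ties: longest CDS, then smaller id).
    Returns ``None`` when no transcript yields a frame.
    """
    v = c.variant
    vs, ve = c.variant_interval
    plus_prefix = c.cdna[:vs]
    plus_alt = c.cdna[vs:ve]
    plus_suffix = c.cdna[ve:]

    best = None  # (score, cds_length, tx, cds, cds_start, alt_coding)
    for t in transcripts:
        if not t.is_coding or t.contig != v.contig:
            continue
        coords = cds_edit_coordinates(t, v.pos, v.ref, v.alt)
        if coords is None:
            continue
        cds_start, ref_len, alt_coding = coords
        if t.strand == "+":
            pre_c, suf_c = plus_prefix, plus_suffix
        else:
            pre_c = reverse_complement(plus_suffix)
            suf_c = reverse_complement(plus_prefix)
        cds = t.spliced_cds(genome)
        left = cds[:cds_start]
        right = cds[cds_start + ref_len:]
        m_left = 0
        for a, b in zip(reversed(pre_c), reversed(left)):
            if a != b:
                break
            m_left += 1
        m_right = 0
        for a, b in zip(suf_c, right):
            if a != b:
                break
            m_right += 1
        score = m_left + m_right
        key = (-score, -t.cds_length, t.id)
        if best is None or key < best[0]:
            best = (key, t, cds_start, alt_coding, pre_c, suf_c)
    if best is None:
        logger.info("variant %s dropped: no transcript yields a reading frame",
                    v.short_id)
        return None

    _, t, cds_start, alt_coding, pre_c, suf_c = best
    cdna = pre_c + alt_coding + suf_c
    start_in_cds = cds_start - len(pre_c)
    prefix_len = len(pre_c)
    if start_in_cds < 0:
        # consensus extends 5' of the CDS start: trim the non-coding head
        trim = -start_in_cds
        cdna = cdna[trim:]
        prefix_len -= trim
        start_in_cds = 0
    frame_offset = (-start_in_cds) % 3
    return replace(
        c,
        cdna=cdna,
        variant_interval=(prefix_len, prefix_len + len(alt_coding)),
        frame_offset=frame_offset,
        transcript_id=t.id,
        strand=t.strand,
    )


def translate_candidate(
    c: CodingSequenceCandidate,
    peptide_radius: int = DEFAULT_PEPTIDE_RADIUS,
) -> Optional[ProteinSequenceCandidate]:
    """Translate an anchored candidate and mark the mutant residues.

    For frameshifts every residue downstream of the shift is mutant; the
    sequence is trimmed to ``peptide_radius`` residues either side of the
    mutant interval.  Returns ``None`` when a stop codon precedes the
    mutant interval.
    """
    if c.frame_offset is None:
        raise ValueError("candidate must be anchored before translation")
    protein = translate(c.cdna, c.frame_offset)
    vs, ve = c.variant_interval
    alt_len = ve - vs
    frameshift = (alt_len - c.ref_length) % 3 != 0
    vs = max(vs, c.frame_offset)
    aa_start = (vs - c.frame_offset) // 3
    if aa_start >= len(protein):
        logger.info("variant %s dropped: stop codon precedes the mutant interval",
                    c.variant.short_id)
        return None
    if frameshift:
        aa_end = len(protein)
    elif alt_len == 0:
        aa_end = aa_start + 1  # fused codon at a clean deletion junction
    else:
        aa_end = -(-(ve - c.frame_offset) // 3)
        aa_end = min(aa_end, len(protein))
        if aa_end <= aa_start:
            aa_end = aa_start + 1
    lo = max(0, aa_start - peptide_radius)
    hi = min(len(protein), aa_end + peptide_radius)
    return ProteinSequenceCandidate(
        amino_acids=protein[lo:hi],
        mutant_aa_interval=(aa_start - lo, aa_end - lo),
        num_supporting_reads=c.num_supporting_reads,
        source_transcripts=(c.transcript_id,) if c.transcript_id else (),
        variant=c.variant,
        is_frameshift=frameshift,
    )
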