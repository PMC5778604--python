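"""Reference genome and transcript annotation models.

Provides in-memory FASTA/GTF loading, strand-aware spliced CDS extraction
and standard-code translation.  All internal coordinates are 0-based
half-open; conversion from GTF's 1-based closed convention happens only
in :func:`load_annotations`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid, standard genetic code
CODON_TO_AA: Mapping[str, str] = dict(_STANDARD_TABLE.forward_table)

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

Interval = Tuple[int, int]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, frame_offset: int = 0) -> str:
    """Translate ``cds`` from ``frame_offset`` using the standard code.

    Stops at (and excludes) the first stop codon; a trailing partial codon
    is dropped.  Codons containing ``N`` yield ``X`` so that positional
    alignment with the nucleotide sequence is preserved.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset!r}")
    cds = cds.upper()
    out = []
    for i in range(frame_offset, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            break
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


class GenomeError(ValueError):
    """Raised for invalid reference-genome inputs or out-of-range lookups."""


@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by contig name."""

    contigs: dict

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise GenomeError(f"contig {name!r} has an empty sequence")

    def contig_length(self, contig: str) -> int:
        return len(self._get(contig))

    def _get(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise GenomeError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig`` over the 0-based half-open ``[start, end)``."""
        seq = self._get(contig)
        if not (0 <= start <= end <= len(seq)):
            raise GenomeError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]


def load_reference(path) -> ReferenceGenome:
    """Load a FASTA file into memory with uppercase normalization."""
    path = Path(path)
    if not path.exists():
        raise GenomeError(f"reference FASTA not found: {path}")
    contigs: dict = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise GenomeError(f"duplicate contig name {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise GenomeError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


@dataclass(frozen=True)
class Transcript:
    """Strand-aware exon/CDS model of a single transcript.

    ``exons`` are 0-based half-open genomic intervals sorted by start;
    ``cds_start``/``cds_end`` delimit the genomic extent of the coding
    region (``None`` for non-coding transcripts).
    """

    id: str
    gene: str
    contig: str
    strand: str
    exons: Tuple[Interval, ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.id}: degenerate exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = end
        if self.is_coding:
            blocks = self.cds_blocks()
            if not blocks:
                raise ValueError(f"{self.id}: CDS interval outside exons")
            covered = sum(e - s for s, e in blocks)
            if covered < 3:
                raise ValueError(f"{self.id}: spliced CDS shorter than one codon")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def genomic_start(self) -> int:
        return self.exons[0][0]

    @property
    def genomic_end(self) -> int:
        return self.exons[-1][1]

    def cds_blocks(self) -> Tuple[Interval, ...]:
        """Exon segments intersected with the CDS interval, genomic order."""
        if not self.is_coding:
            return ()
        blocks = []
        for start, end in self.exons:
            s = max(start, self.cds_start)
            e = min(end, self.cds_end)
            if s < e:
                blocks.append((s, e))
        return tuple(blocks)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks())

    def plus_cds_index(self, gpos: int) -> Optional[int]:
        """Index of genomic position ``gpos`` in the spliced CDS laid out in
        genomic (plus-strand) order, or ``None`` if not a CDS base."""
        offset = 0
        for start, end in self.cds_blocks():
            if start <= gpos < end:
                return offset + (gpos - start)
            offset += end - start
        return None

    def cds_index(self, gpos: int) -> Optional[int]:
        """Coding-orientation index of genomic position ``gpos`` in the
        spliced CDS (reversed for minus-strand transcripts)."""
        plus = self.plus_cds_index(gpos)
        if plus is None:
            return None
        if self.strand == "+":
            return plus
        return self.cds_length - 1 - plus

    def spliced_cds(self, genome: ReferenceGenome) -> str:
        """5'->3' coding sequence (reverse-complemented on the minus strand).

        A length that is not a multiple of 3 is tolerated (truncated
        annotations) but logged.
        """
        if not self.is_coding:
            raise ValueError(f"{self.id} is non-coding")
        seq = "".join(genome.fetch(self.contig, s, e) for s, e in self.cds_blocks())
        if self.strand == "-":
            seq = reverse_complement(seq)
        if len(seq) % 3 != 0:
            logger.warning("transcript %s: CDS length %d not a multiple of 3",
                           self.id, len(seq))
        return seq


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(raw: str) -> dict:
    return dict(_ATTR_RE.findall(raw))


def load_annotations(path) -> list:
    """Parse a GTF file into :class:`Transcript` objects.

    Only ``exon`` and ``CDS`` feature rows are consulted.  GTF 1-based
    closed coordinates are converted to 0-based half-open.  Transcripts
    without CDS rows are retained and flagged non-coding.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeError(f"annotation GTF not found: {path}")
    exons: dict = {}
    cds: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GenomeError(f"{path}:{line_no}: expected 9 GTF columns")
            contig, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise GenomeError(f"{path}:{line_no}: missing transcript_id attribute")
            interval = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
            meta.setdefault(tid, (attributes.get("gene_id", tid), contig, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append(interval)
            else:
                cds.setdefault(tid, []).append(interval)

    transcripts = []
    for tid, exon_list in exons.items():
        gene, contig, strand = meta[tid]
        exon_list = sorted(exon_list)
        cds_rows = sorted(cds.get(tid, []))
        cds_start = cds_end = None
        if cds_rows:
            for cs, ce in cds_rows:
                if not any(es <= cs and ce <= ee for es, ee in exon_list):
                    raise GenomeError(
                        f"transcript {tid}: CDS row [{cs}, {ce}) not contained "
                        f"in any exon"
                    )
            cds_start = cds_rows[0][0]
            cds_end = cds_rows[-1][1]
        else:
            logger.info("transcript %s has no CDS rows; flagged non-coding", tid)
        transcripts.append(
            Transcript(
                id=tid,
                gene=gene,
                contig=contig,
                strand=strand,
                exons=tuple(exon_list),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    transcripts.sort(key=lambda t: (t.contig, t.genomic_start, t.id))
    return transcripts
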