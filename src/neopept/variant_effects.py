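"""Variant normalization and protein-level effect classification.

Variants are normalized to a minimal left-aligned representation and then
classified per overlapping transcript by editing the spliced CDS and
comparing translations; silent and non-coding effects are filtered out
before any downstream peptide work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pysam

from .genome_model import ReferenceGenome, Transcript, reverse_complement, translate

logger = logging.getLogger(__name__)

#: effect categories that alter the protein and are eligible for vaccine candidacy
NONSILENT_CATEGORIES = frozenset(
    {"missense", "inframe_insertion", "inframe_deletion", "frameshift", "stop_lost"}
)

_VALID_BASES = frozenset("ACGTN")


class VariantError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """Normalized genomic substitution or indel.

    ``pos`` is the 0-based genomic start of the reference allele; ``ref``
    and ``alt`` carry no shared prefix/suffix (either may be empty, not
    both).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    provenance: str = "somatic"

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise VariantError("ref and alt may not both be empty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise VariantError(f"non-ACGTN allele {allele!r}")

    @property
    def end(self) -> int:
        """0-based half-open genomic end of the reference allele."""
        return self.pos + len(self.ref)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def short_id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref or '-'}>{self.alt or '-'}"


@dataclass(frozen=True)
class VariantEffect:
    variant: Variant
    transcript: Transcript
    category: str
    aa_pos: Optional[int] = None  # 0-based protein index of first changed residue


def _trim(pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Remove shared suffix then prefix; adjust pos for the prefix."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def read_vcf(path, keep_nonpass: bool = False) -> List[Variant]:
    """Read a VCF into trimmed :class:`Variant` records.

    VCF 1-based POS is converted to 0-based; multi-allelic rows are split
    into one variant per alternate allele.  Symbolic or otherwise
    unusable alleles are skipped with a logged running count.
    """
    path = Path(path)
    if not path.exists():
        raise VariantError(f"VCF not found: {path}")
    variants: List[Variant] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            filters = set(record.filter.keys())
            if not keep_nonpass and filters and filters != {"PASS"}:
                continue
            for alt in record.alts or ():
                try:
                    if alt is None or not set(alt.upper()) <= _VALID_BASES:
                        raise VariantError(f"unsupported ALT {alt!r}")
                    pos, ref, alt_a = _trim(
                        record.start, record.ref.upper(), alt.upper()
                    )
                    variants.append(Variant(record.contig, pos, ref, alt_a))
                except (VariantError, AttributeError) as exc:
                    skipped += 1
                    logger.warning(
                        "skipping malformed VCF allele at %s:%s (%s); %d skipped so far",
                        record.contig, record.pos, exc, skipped,
                    )
    return variants


def normalize(v: Variant, genome: ReferenceGenome) -> Variant:
    """Minimal left-aligned representation of ``v``.

    Shared prefix/suffix bases are trimmed and pure indels are shifted
    left along the reference until a mismatching base blocks the shift.
    Idempotent.  Raises if ``v.ref`` disagrees with the genome.
    """
    observed = genome.fetch(v.contig, v.pos, v.end)
    if observed != v.ref:
        raise VariantError(
            f"ref allele mismatch at {v.contig}:{v.pos}: variant says "
            f"{v.ref!r}, genome has {observed!r}"
        )
    pos, ref, alt = _trim(v.pos, v.ref, v.alt)
    # vt-style left alignment for pure indels
    while (not ref or not alt) and (ref or alt) and pos > 0:
        base = genome.fetch(v.contig, pos - 1, pos)
        longer = ref or alt
        if longer[-1] != base:
            break
        pos -= 1
        ref, alt = base + ref[:-1] if ref else "", base + alt[:-1] if alt else ""
        if ref and not ref:  # pragma: no cover - defensive
            break
    pos, ref, alt = _trim(pos, ref, alt)
    if not ref and not alt:
        raise VariantError(f"variant {v.short_id} normalizes to a no-op")
    return replace(v, pos=pos, ref=ref, alt=alt)


def cds_edit_coordinates(
    t: Transcript, pos: int, ref: str, alt: str
) -> Optional[Tuple[int, int, str]]:
    """Map a genomic edit onto the spliced CDS in coding orientation.

    Returns ``(cds_start, ref_len, alt_coding)`` or ``None`` when the edit
    does not fall cleanly inside the spliced CDS (including edits that
    straddle an intron).
    """
    if not t.is_coding:
        return None
    n = len(ref)
    if n > 0:
        first = t.plus_cds_index(pos)
        last = t.plus_cds_index(pos + n - 1)
        if first is None or last is None or last - first != n - 1:
            return None
        if t.strand == "+":
            return first, n, alt
        return t.cds_length - 1 - last, n, reverse_complement(alt)
    # insertion between genomic pos-1 and pos: both flanks must be adjacent CDS bases
    left = t.plus_cds_index(pos - 1)
    right = t.plus_cds_index(pos)
    if left is None or right is None or right - left != 1:
        return None
    if t.strand == "+":
        return right, 0, alt
    return t.cds_length - 1 - left, 0, reverse_complement(alt)


def _first_difference(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def classify_cds_edit(cds: str, cds_start: int, ref_len: int, alt: str
                      ) -> Tuple[str, Optional[int]]:
    """Classify the protein-level effect of editing ``cds``.

    Returns ``(category, aa_pos)`` where ``aa_pos`` is the 0-based index
    of the first changed residue (``None`` for silent).
    """
    mutant = cds[:cds_start] + alt + cds[cds_start + ref_len:]
    ref_protein = translate(cds, 0)
    mut_protein = translate(mutant, 0)
    if mut_protein == ref_protein:
        return "silent", None
    i = _first_difference(ref_protein, mut_protein)
    if cds_start < 3 and mutant[:3] != cds[:3] and cds[:3] == "ATG" and mutant[:3] != "ATG":
        return "start_lost", 0
    if (len(alt) - ref_len) % 3 != 0:
        return "frameshift", i
    if len(mut_protein) == len(ref_protein) and ref_len == len(alt):
        return "missense", i
    if len(mut_protein) < len(ref_protein) and mut_protein == ref_protein[: len(mut_protein)]:
        return "stop_gained", i
    if len(mut_protein) > len(ref_protein) and ref_protein == mut_protein[: len(ref_protein)]:
        return "stop_lost", i
    if len(alt) > ref_len:
        return "inframe_insertion", i
    if len(alt) < ref_len:
        return "inframe_deletion", i
    return "missense", i


def annotate_effects(
    v: Variant, transcripts: Sequence[Transcript], genome: ReferenceGenome
) -> List[VariantEffect]:
    """One :class:`VariantEffect` per transcript overlapping ``v``.

    The category is computed by editing the spliced CDS and comparing
    translations; non-overlapping transcripts contribute nothing.
    """
    effects: List[VariantEffect] = []
    span_start = v.pos if v.ref else v.pos - 1
    span_end = v.end if v.ref else v.pos + 1
    for t in transcripts:
        if t.contig != v.contig:
            continue
        if span_end <= t.genomic_start or span_start >= t.genomic_end:
            continue
        coords = cds_edit_coordinates(t, v.pos, v.ref, v.alt)
        if coords is None:
            in_exon = any(
                s < span_end and span_start < e for s, e in t.exons
            )
            category = "noncoding" if in_exon else "intronic"
            effects.append(VariantEffect(v, t, category, None))
            continue
        cds_start, ref_len, alt_coding = coords
        for es, ee in t.exons:  # splice-region proximity is logged only
            if abs(v.pos - es) <= 2 or abs(v.end - ee) <= 2:
                if (es, ee) != (t.genomic_start, t.genomic_end):
                    logger.debug("variant %s near splice site of %s", v.short_id, t.id)
        cds = t.spliced_cds(genome)
        category, aa_pos = classify_cds_edit(cds, cds_start, ref_len, alt_coding)
        effects.append(VariantEffect(v, t, category, aa_pos))
    return effects


def filter_nonsilent(effects: Iterable[VariantEffect]) -> List[VariantEffect]:
    """Retain only effects whose category alters the protein sequence."""
    return [e for e in effects if e.category in NONSILENT_CATEGORIES]
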