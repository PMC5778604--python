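"""Deterministic generator of toy genomes, annotations, variants and
aligned RNA reads.

Everything downstream of alignment is testable offline: the generator
emits FASTA + GTF + VCF + coordinate-sorted SAM plus a JSON manifest
recording per-read ground truth (haplotype label, injected errors) and
the expected mutant protein fragment for every planted variant — both
with and without its phased neighbor variants.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .genome_model import (
    CODON_TO_AA,
    STOP_CODONS,
    ReferenceGenome,
    Transcript,
    reverse_complement,
    translate,
)

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 125  # matches the sequencing protocol's RNA read length
_BASES = "ACGT"
_NONSTOP_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptLayout:
    """Shape of one generated transcript."""

    strand: str = "+"
    n_codons: int = 60
    exon_spliced_lengths: Optional[Tuple[int, ...]] = None  # None -> single exon
    utr5: int = 21
    utr3: int = 21
    intron_length: int = 100

    @property
    def spliced_length(self) -> int:
        return self.utr5 + 3 * self.n_codons + self.utr3


@dataclass(frozen=True)
class PlantedVariant:
    """A somatic variant planted inside one transcript's CDS.

    ``neighbor_offsets`` lists CDS offsets (nt) of germline SNVs present
    on the alt haplotype only — these drive the phasing behaviour.
    """

    name: str
    transcript_index: int
    kind: str = "snv"            # snv | ins | del
    cds_codon: Optional[int] = None
    indel_length: int = 1
    depth: int = 100
    alt_fraction: float = 0.5
    neighbor_offsets: Tuple[int, ...] = ()


@dataclass(frozen=True)
class FixtureSpec:
    transcripts: Tuple[TranscriptLayout, ...]
    variants: Tuple[PlantedVariant, ...]
    seed: int = 0
    contig: str = "chrT"
    read_length: int = DEFAULT_READ_LENGTH
    base_error_rate: float = 0.0
    intergenic: int = 120
    paired: bool = False


@dataclass
class Fixture:
    """Generated artifact paths plus the in-memory ground-truth manifest."""

    fasta: Path
    gtf: Path
    vcf: Path
    sam: Path
    manifest_path: Path
    manifest: dict


class _TxBuild:
    """A generated transcript plus its spliced<->genomic coordinate maps."""

    def __init__(self, layout: TranscriptLayout, index: int, rng) -> None:
        self.layout = layout
        self.id = f"TX{index:03d}"
        self.gene = f"GENE{index:03d}"
        n = layout.n_codons
        if n < 8:
            raise FixtureSpecError("transcripts need at least 8 codons")
        body = "".join(
            _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n - 2)
        )
        self.cds = "ATG" + body + "TAA"
        utr5 = "".join(_BASES[i] for i in rng.integers(0, 4, layout.utr5))
        utr3 = "".join(_BASES[i] for i in rng.integers(0, 4, layout.utr3))
        self.tx_seq = utr5 + self.cds + utr3  # transcript (coding) orientation
        splits = layout.exon_spliced_lengths or (len(self.tx_seq),)
        if sum(splits) != len(self.tx_seq):
            raise FixtureSpecError(
                f"{self.id}: exon lengths {splits} do not sum to transcript "
                f"length {len(self.tx_seq)}"
            )
        self.splits = splits
        # filled during layout on the contig:
        self.exons: List[Tuple[int, int]] = []   # genomic order
        self.offset = 0                          # genomic start on the contig
        self._g_of_spliced: Optional[np.ndarray] = None

    def place(self, offset: int, rng) -> Tuple[str, int]:
        """Return this transcript's genomic sequence chunk and its length."""
        self.offset = offset
        layout = self.layout
        pieces = []
        cursor = offset
        slices = []
        start = 0
        for length in self.splits:
            slices.append(self.tx_seq[start : start + length])
            start += length
        if layout.strand == "-":
            # leftmost genomic exon holds the 3'-most spliced slice
            slices = [reverse_complement(s) for s in reversed(slices)]
        g_of_spliced = np.empty(len(self.tx_seq), dtype=np.int64)
        exon_genomic = []
        for i, chunk in enumerate(slices):
            if i > 0:
                intron = "".join(
                    _BASES[j] for j in rng.integers(0, 4, layout.intron_length)
                )
                pieces.append(intron)
                cursor += layout.intron_length
            exon_genomic.append((cursor, cursor + len(chunk)))
            pieces.append(chunk)
            cursor += len(chunk)
        self.exons = exon_genomic
        # map spliced (transcript-orientation) position -> genomic position
        if layout.strand == "+":
            spliced = 0
            for (gs, ge) in exon_genomic:
                for g in range(gs, ge):
                    g_of_spliced[spliced] = g
                    spliced += 1
        else:
            spliced = 0
            for (gs, ge) in reversed(exon_genomic):
                for g in range(ge - 1, gs - 1, -1):
                    g_of_spliced[spliced] = g
                    spliced += 1
        self._g_of_spliced = g_of_spliced
        return "".join(pieces), cursor - offset

    def gpos(self, spliced_pos: int) -> int:
        return int(self._g_of_spliced[spliced_pos])

    @property
    def strand(self) -> str:
        return self.layout.strand

    @property
    def cds_spliced_start(self) -> int:
        return self.layout.utr5

    def transcript_model(self, contig: str) -> Transcript:
        cds_g = [self.gpos(self.cds_spliced_start + i) for i in range(len(self.cds))]
        return Transcript(
            id=self.id,
            gene=self.gene,
            contig=contig,
            strand=self.strand,
            exons=tuple(sorted(self.exons)),
            cds_start=min(cds_g),
            cds_end=max(cds_g) + 1,
        )


def _missense_snv(cds: str, codon_index: int, rng) -> Tuple[int, str, str]:
    """Pick a deterministic single-base change at ``codon_index`` that is
    missense (not silent, not stop-gaining).  Returns (cds_offset, ref, alt)."""
    codon = cds[3 * codon_index : 3 * codon_index + 3]
    aa = CODON_TO_AA[codon]
    choices = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TO_AA[mutant] != aa:
                choices.append((pos, base))
    if not choices:
        raise FixtureSpecError(f"no missense change available in codon {codon}")
    pos, base = choices[int(rng.integers(0, len(choices)))]
    return 3 * codon_index + pos, codon[pos], base


def _apply_spliced_edits(
    seq: str,
    g_of: np.ndarray,
    edits: Sequence[Tuple[int, str, str]],
) -> Tuple[str, List[Optional[int]]]:
    """Apply (spliced_pos, ref, alt) edits; return the haplotype sequence
    and a per-base genomic annotation (None for inserted bases)."""
    annotated: List[Tuple[str, Optional[int]]] = [
        (seq[i], int(g_of[i])) for i in range(len(seq))
    ]
    for spliced_pos, ref, alt in sorted(edits, key=lambda e: -e[0]):
        if ref:
            observed = seq[spliced_pos : spliced_pos + len(ref)]
            if observed != ref:
                raise FixtureSpecError(
                    f"edit ref {ref!r} does not match sequence {observed!r}"
                )
        if len(ref) == len(alt) and ref:
            replacement = [
                (alt[k], annotated[spliced_pos + k][1]) for k in range(len(ref))
            ]
        else:
            replacement = [(b, None) for b in alt]
        annotated[spliced_pos : spliced_pos + len(ref)] = replacement
    return "".join(b for b, _ in annotated), [g for _, g in annotated]


def _cigar_from_annotation(
    bases: Sequence[str],
    gpos: Sequence[Optional[int]],
    exonic: set,
) -> Tuple[int, List[Tuple[int, int]]]:
    """Build (POS, CIGAR) for bases annotated with ascending genomic
    positions (``None`` = inserted base).  Gaps between consecutive
    positions become D over exonic bases and N over intronic ones."""
    first = next((g for g in gpos if g is not None), None)
    if first is None:
        raise FixtureSpecError("read consists entirely of inserted bases")
    ops: List[Tuple[int, int]] = []

    def push(op: int, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    prev: Optional[int] = None
    for g in gpos:
        if g is None:
            push(1, 1)  # I
            continue
        if prev is not None and g != prev + 1:
            run_op = None
            run_len = 0
            for skipped in range(prev + 1, g):
                op = 2 if skipped in exonic else 3  # D over exon, N over intron
                if op == run_op:
                    run_len += 1
                else:
                    if run_op is not None:
                        push(run_op, run_len)
                    run_op, run_len = op, 1
            if run_op is not None:
                push(run_op, run_len)
        push(0, 1)  # M
        prev = g
    if ops and ops[0][0] == 1:
        raise FixtureSpecError("read starts with an insertion; widen margins")
    return first, ops


def generate_fixture(spec: FixtureSpec, out_dir) -> Fixture:
    """Write FASTA/GTF/VCF/SAM + manifest for ``spec`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    builds = [_TxBuild(layout, i, rng) for i, layout in enumerate(spec.transcripts)]
    contig_parts = []
    cursor = 0
    spacer = "".join(_BASES[i] for i in rng.integers(0, 4, spec.intergenic))
    contig_parts.append(spacer)
    cursor += spec.intergenic
    for build in builds:
        chunk, length = build.place(cursor, rng)
        contig_parts.append(chunk)
        cursor += length
        spacer = "".join(_BASES[i] for i in rng.integers(0, 4, spec.intergenic))
        contig_parts.append(spacer)
        cursor += spec.intergenic
    contig_seq = "".join(contig_parts)

    transcripts = [b.transcript_model(spec.contig) for b in builds]

    # -- genomic representation of an edit (plus-strand coordinates) ---
    def genomic_edit(build: _TxBuild, spliced_off: int, ref: str, alt: str):
        """(gpos, ref_g, alt_g) in plus-strand genomic coordinates."""
        spliced_pos = build.cds_spliced_start + spliced_off
        if build.strand == "+":
            if ref:
                g0 = build.gpos(spliced_pos)
                g1 = build.gpos(spliced_pos + len(ref) - 1)
                if g1 - g0 != len(ref) - 1:
                    raise FixtureSpecError("variant spans an exon junction")
                return g0, ref, alt
            return build.gpos(spliced_pos), "", alt
        if ref:
            g_last = build.gpos(spliced_pos)            # coding start = genomic max
            g_first = build.gpos(spliced_pos + len(ref) - 1)
            if g_last - g_first != len(ref) - 1:
                raise FixtureSpecError("variant spans an exon junction")
            return g_first, reverse_complement(ref), reverse_complement(alt)
        # insertion before coding position -> genomically after gpos(spliced_pos)
        return build.gpos(spliced_pos) + 1, "", reverse_complement(alt)

    def _is_left_aligned(gpos: int, ref_g: str, alt_g: str) -> bool:
        """True when genomic left-shifting cannot move this pure indel."""
        if ref_g and alt_g:
            return True  # substitution: nothing to shift
        longer = ref_g or alt_g
        return gpos == 0 or contig_seq[gpos - 1] != longer[-1]

    from .variant_effects import NONSILENT_CATEGORIES, classify_cds_edit

    # -- plant variants ------------------------------------------------
    planted = []
    for pv in spec.variants:
        if not 0 <= pv.transcript_index < len(builds):
            raise FixtureSpecError(f"{pv.name}: bad transcript index")
        build = builds[pv.transcript_index]
        n_codons = build.layout.n_codons
        codon = pv.cds_codon if pv.cds_codon is not None else n_codons // 2
        if not 1 <= codon < n_codons - 1:
            raise FixtureSpecError(f"{pv.name}: codon {codon} outside CDS body")

        def _acceptable(cds_off: int, ref: str, alt: str) -> bool:
            """Planted representation must already be normalized (so RNA
            reads and the normalized VCF agree on the locus) and must
            alter the protein (or it would be filtered as silent)."""
            gpos_, ref_g_, alt_g_ = genomic_edit(build, cds_off, ref, alt)
            if not _is_left_aligned(gpos_, ref_g_, alt_g_):
                return False
            category, _ = classify_cds_edit(build.cds, cds_off, len(ref), alt)
            return category in NONSILENT_CATEGORIES

        if pv.kind == "snv":
            cds_off, ref_c, alt_c = _missense_snv(build.cds, codon, rng)
        elif pv.kind == "ins":
            cds_off = 3 * codon
            ref_c = ""
            alt_c = None
            for _attempt in range(50):
                if pv.indel_length % 3 == 0:
                    candidate = "".join(
                        _NONSTOP_CODONS[i]
                        for i in rng.integers(0, len(_NONSTOP_CODONS),
                                              pv.indel_length // 3)
                    )
                else:
                    candidate = "".join(
                        _BASES[i] for i in rng.integers(0, 4, pv.indel_length)
                    )
                if _acceptable(cds_off, "", candidate):
                    alt_c = candidate
                    break
            if alt_c is None:
                raise FixtureSpecError(f"{pv.name}: no usable insertion found")
        elif pv.kind == "del":
            alt_c = ""
            chosen = None
            for shift in range(0, 9):
                off = 3 * codon + shift
                ref_candidate = build.cds[off : off + pv.indel_length]
                if len(ref_candidate) < pv.indel_length:
                    break
                if _acceptable(off, ref_candidate, ""):
                    chosen = (off, ref_candidate)
                    break
            if chosen is None:
                raise FixtureSpecError(f"{pv.name}: no usable deletion found")
            cds_off, ref_c = chosen
        else:
            raise FixtureSpecError(f"{pv.name}: unknown kind {pv.kind!r}")

        neighbors = []
        for off in pv.neighbor_offsets:
            if not 3 <= off < 3 * n_codons - 3:
                raise FixtureSpecError(f"{pv.name}: neighbor offset {off} outside CDS")
            n_codon, n_pos = divmod(off, 3)
            n_off, n_ref, n_alt = _missense_snv(build.cds, n_codon, rng)
            # keep the requested codon but let the helper pick the base change
            neighbors.append((n_off, n_ref, n_alt))

        planted.append((pv, build, cds_off, ref_c, alt_c, neighbors))

    # -- reads ---------------------------------------------------------
    read_records = []
    manifest_variants = []
    manifest_reads: Dict[str, dict] = {}

    exonic_positions = {
        g for b in builds for (gs, ge) in b.exons for g in range(gs, ge)
    }

    for pv, build, cds_off, ref_c, alt_c, neighbors in planted:
        spliced_p = build.cds_spliced_start + cds_off
        tx_seq = build.tx_seq
        g_of = build._g_of_spliced

        ref_hap, ref_ann = _apply_spliced_edits(tx_seq, g_of, [])
        somatic_edit = (spliced_p, ref_c, alt_c)
        neighbor_edits = [
            (build.cds_spliced_start + off, r, a) for off, r, a in neighbors
        ]
        alt_hap, alt_ann = _apply_spliced_edits(
            tx_seq, g_of, [somatic_edit] + neighbor_edits
        )

        # span (in haplotype coordinates) every read must fully cover
        alt_span = (max(0, spliced_p - 1), spliced_p + max(1, len(alt_c)) + 1)
        ref_span = (max(0, spliced_p - 1), spliced_p + max(1, len(ref_c)) + 1)

        n_alt = int(round(pv.depth * pv.alt_fraction))
        read_len = spec.read_length
        for i in range(pv.depth):
            is_alt = i < n_alt
            hap, ann, span = (
                (alt_hap, alt_ann, alt_span) if is_alt else (ref_hap, ref_ann, ref_span)
            )
            lo = max(0, span[1] - read_len)
            hi = min(span[0], len(hap) - read_len)
            if hi < lo:
                raise FixtureSpecError(
                    f"{pv.name}: transcript too short for read length {read_len}"
                )
            label = "alt" if is_alt else "ref"
            name = f"{pv.name}_r{i:04d}_{label}"
            # paired mode: both mates of the fragment span the locus, so
            # fragment counting vs read counting differ by exactly 2x
            n_mates = 2 if spec.paired else 1
            errors = []
            for mate in range(n_mates):
                start = int(rng.integers(lo, hi + 1))
                bases = list(hap[start : start + read_len])
                ann_slice = list(ann[start : start + read_len])
                if spec.base_error_rate > 0:
                    for k in range(read_len):
                        if rng.random() < spec.base_error_rate:
                            alternatives = [b for b in _BASES if b != bases[k]]
                            bases[k] = alternatives[int(rng.integers(0, 3))]
                            errors.append(k)
                flag = 0
                if build.strand == "-":
                    bases = [reverse_complement(b) for b in reversed(bases)]
                    ann_slice = list(reversed(ann_slice))
                    flag |= 16
                if spec.paired:
                    flag |= 1 | (64 if mate == 0 else 128)
                pos, cigar = _cigar_from_annotation(
                    bases, ann_slice, exonic_positions
                )
                read_records.append(
                    {"name": name, "flag": flag, "pos": pos, "cigar": cigar,
                     "seq": "".join(bases)}
                )
            manifest_reads[name] = {
                "variant": pv.name,
                "label": label,
                "error_positions": errors,
                "n_mates": n_mates,
            }

        gpos_v, ref_g, alt_g = genomic_edit(build, cds_off, ref_c, alt_c)
        neighbor_genomic = []
        for off, r, a in neighbors:
            g, rg, ag = genomic_edit(build, off, r, a)
            neighbor_genomic.append(
                {"pos": g, "ref": rg, "alt": ag, "cds_offset": off}
            )

        # expected protein fragments (radius 12 around the mutant residue)
        def fragment(edits):
            mut_cds, _ = _apply_spliced_edits(
                build.cds, np.arange(len(build.cds)), edits
            )
            protein = translate(mut_cds, 0)
            aa = cds_off // 3
            shifted = (len(alt_c) - len(ref_c)) % 3 != 0
            if shifted:
                lo_, hi_ = max(0, aa - 12), len(protein)
            else:
                lo_, hi_ = max(0, aa - 12), min(len(protein), aa + 13)
            return protein[lo_:hi_]

        somatic_only = [(cds_off, ref_c, alt_c)]
        phased = somatic_only + [(off, r, a) for off, r, a in neighbors]
        manifest_variants.append(
            {
                "name": pv.name,
                "contig": spec.contig,
                "pos": gpos_v,
                "ref": ref_g,
                "alt": alt_g,
                "transcript_id": build.id,
                "strand": build.strand,
                "kind": pv.kind,
                "cds_offset": cds_off,
                "depth": pv.depth,
                "n_alt_reads": n_alt,
                "alt_fraction": pv.alt_fraction,
                "neighbors": neighbor_genomic,
                "expected_peptide_phased": fragment(phased),
                "expected_peptide_naive": fragment(somatic_only),
                "mutant_aa_index": cds_off // 3,
            }
        )

    # -- write artifacts ----------------------------------------------
    fasta_path = out_dir / "genome.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(f">{spec.contig}\n")
        for i in range(0, len(contig_seq), 60):
            fh.write(contig_seq[i : i + 60] + "\n")

    gtf_path = out_dir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene}"; transcript_id "{t.id}";'
            for (es, ee) in t.exons:
                fh.write(
                    f"{t.contig}\tneopept\texon\t{es + 1}\t{ee}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            for (cs, ce) in t.cds_blocks():
                fh.write(
                    f"{t.contig}\tneopept\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t.\t{attrs}\n"
                )

    vcf_path = out_dir / "somatic.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={spec.contig},length={len(contig_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for mv in sorted(manifest_variants, key=lambda m: m["pos"]):
            pos0, ref, alt = mv["pos"], mv["ref"], mv["alt"]
            if not ref or not alt:  # VCF indels need an anchor base
                anchor = contig_seq[pos0 - 1]
                row_pos = pos0  # 1-based position of the anchor base
                row_ref = anchor + ref
                row_alt = anchor + alt
            else:
                row_pos = pos0 + 1
                row_ref, row_alt = ref, alt
            fh.write(
                f"{spec.contig}\t{row_pos}\t{mv['name']}\t{row_ref}\t{row_alt}"
                f"\t.\tPASS\t.\n"
            )

    sam_path = out_dir / "alignments.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.contig, "LN": len(contig_seq)}],
    }
    read_records.sort(key=lambda r: (r["pos"], r["name"]))
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as fh:
        for rec in read_records:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = rec["name"]
            seg.flag = rec["flag"]
            seg.reference_id = 0
            seg.reference_start = rec["pos"]
            seg.mapping_quality = 60
            seg.cigartuples = rec["cigar"]
            seg.query_sequence = rec["seq"]
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
            fh.write(seg)

    manifest = {
        "spec": {
            "seed": spec.seed,
            "contig": spec.contig,
            "read_length": spec.read_length,
            "base_error_rate": spec.base_error_rate,
            "n_transcripts": len(builds),
        },
        "variants": manifest_variants,
        "reads": manifest_reads,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return Fixture(
        fasta=fasta_path,
        gtf=gtf_path,
        vcf=vcf_path,
        sam=sam_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def standard_spec(
    num_variants: int = 30,
    depth: int = 100,
    alt_fraction: float = 0.5,
    base_error_rate: float = 0.0,
    seed: int = 0,
    neighbor_offset_nt: Optional[int] = None,
    depths: Optional[Sequence[int]] = None,
    alt_fractions: Optional[Sequence[float]] = None,
    read_length: int = DEFAULT_READ_LENGTH,
    two_exon_every: int = 0,
) -> FixtureSpec:
    """Convenience spec: one transcript per variant, alternating strands.

    ``neighbor_offset_nt`` plants a phased germline SNV that many nt
    downstream of each somatic variant; ``depths`` overrides per-variant
    depth; ``two_exon_every > 0`` makes every k-th transcript two-exon.
    """
    layouts = []
    variants = []
    for i in range(num_variants):
        strand = "+" if i % 2 == 0 else "-"
        layout = TranscriptLayout(strand=strand, n_codons=60)
        if two_exon_every and (i + 1) % two_exon_every == 0:
            total = layout.spliced_length
            layout = dataclasses.replace(
                layout, exon_spliced_lengths=(total // 2, total - total // 2)
            )
        layouts.append(layout)
        codon = 30
        offsets: Tuple[int, ...] = ()
        if neighbor_offset_nt:
            offsets = (3 * codon + neighbor_offset_nt,)
        variants.append(
            PlantedVariant(
                name=f"VAR{i:03d}",
                transcript_index=i,
                kind="snv",
                cds_codon=codon,
                depth=depths[i] if depths is not None else depth,
                alt_fraction=(alt_fractions[i] if alt_fractions is not None
                              else alt_fraction),
                neighbor_offsets=offsets,
            )
        )
    return FixtureSpec(
        transcripts=tuple(layouts),
        variants=tuple(variants),
        seed=seed,
        base_error_rate=base_error_rate,
        read_length=read_length,
    )
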