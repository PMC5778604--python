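"""Tests for consensus grouping, transcript anchoring and translation.

The brute-force oracle for grouping enumerates maximal mutually
compatible read sets (cliques of the pairwise-compatibility graph).
"""

import itertools

import pytest

from neopept.coding_assembly import (
    CodingSequenceCandidate,
    anchor_to_transcript,
    assemble_most_abundant,
    group_reads_by_sequence,
    translate_candidate,
)
from neopept.genome_model import (
    ReferenceGenome,
    Transcript,
    load_annotations,
    load_reference,
    translate,
)
from neopept.read_evidence import AlleleRead, collect_reads
from neopept.variant_effects import Variant


def ar(name, prefix, allele, suffix):
    return AlleleRead(name, prefix, allele, suffix, 60, (40,) * max(1, len(allele)))


class TestGroupReads:
    def test_identical_reads_one_group(self):
        groups = group_reads_by_sequence([ar("a", "CC", "G", "TT"),
                                          ar("b", "CC", "G", "TT")])
        assert len(groups) == 1
        assert groups[0].count == 2

    def test_different_lengths_union_consensus(self):
        groups = group_reads_by_sequence([ar("a", "ACC", "G", "T"),
                                          ar("b", "CC", "G", "TTG")])
        assert len(groups) == 1
        assert groups[0].consensus == "ACCGTTG"

    def test_conflicting_base_two_groups(self):
        groups = group_reads_by_sequence([ar("a", "AC", "G", "T"),
                                          ar("b", "AG", "G", "T")])
        assert len(groups) == 2

    def _clique_oracle(self, reads):
        """Exhaustive: largest set of pairwise-compatible reads; ties by
        longer union consensus then lexicographically smaller sequence."""

        def compatible(x, y):
            return (
                x.allele == y.allele
                and (x.prefix.endswith(y.prefix) or y.prefix.endswith(x.prefix))
                and (x.suffix.startswith(y.suffix) or y.suffix.startswith(x.suffix))
            )

        best = None
        for size in range(len(reads), 0, -1):
            for subset in itertools.combinations(reads, size):
                if all(compatible(x, y) for x, y in itertools.combinations(subset, 2)):
                    prefix = max((r.prefix for r in subset), key=len)
                    suffix = max((r.suffix for r in subset), key=len)
                    consensus = prefix + subset[0].allele + suffix
                    key = (-size, -len(consensus), consensus)
                    if best is None or key < best[0]:
                        best = (key, size, consensus)
            if best is not None:
                break
        return best[1], best[2]

    def test_winner_matches_bruteforce_cliques(self, small_fixture):
        for m in small_fixture.manifest["variants"]:
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            group = collect_reads(str(small_fixture.sam), v)
            alt = group.alt_reads[:12]  # keep enumeration tractable
            groups = group_reads_by_sequence(alt)
            count, consensus = self._clique_oracle(alt)
            assert groups[0].count == count
            assert groups[0].consensus == consensus


class TestAssemble:
    def test_largest_group_wins(self):
        reads = [ar(f"a{i}", "AC", "G", "T") for i in range(12)]
        reads += [ar(f"b{i}", "AG", "G", "T") for i in range(3)]
        groups = group_reads_by_sequence(reads)
        v = Variant("chr1", 100, "A", "G")
        c = assemble_most_abundant(groups, v)
        assert c.num_supporting_reads == 12
        assert c.cdna == "ACGT"

    def test_min_reads_drop(self):
        groups = group_reads_by_sequence([ar("a", "AC", "G", "T")])
        v = Variant("chr1", 100, "A", "G")
        assert assemble_most_abundant(groups, v, min_reads=3) is None

    def test_equal_count_tiebreak_deterministic(self):
        # same count and consensus length: lexicographically smaller wins
        reads = [ar("a", "AC", "G", "TT"), ar("b", "AG", "G", "TT")]
        v = Variant("chr1", 100, "A", "G")
        c = assemble_most_abundant(group_reads_by_sequence(reads), v, min_reads=1)
        assert c.cdna == "ACGTT"

    def test_phased_neighbor_retained_in_consensus(self, phasing_fixture):
        genome = load_reference(phasing_fixture.fasta)
        for m in phasing_fixture.manifest["variants"]:
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            group = collect_reads(str(phasing_fixture.sam), v)
            c = assemble_most_abundant(group_reads_by_sequence(group.alt_reads), v)
            (neighbor,) = m["neighbors"]
            # every alt-haplotype read carries the neighbor allele, so the
            # consensus must contain it at the right genomic offset
            gap = neighbor["pos"] - (v.pos + len(v.ref))
            if gap >= 0:
                suffix = c.cdna[c.variant_interval[1]:]
                assert suffix[gap] == neighbor["alt"]
            else:
                prefix = c.cdna[: c.variant_interval[0]]
                offset = neighbor["pos"] - (v.pos - len(prefix))
                assert prefix[offset] == neighbor["alt"]


def _single_exon_setup(cds, flank=30):
    seq = "G" * flank + cds + "G" * flank
    genome = ReferenceGenome({"chr1": seq})
    t = Transcript("T1", "G1", "chr1", "+", ((0, len(seq)),),
                   flank, flank + len(cds))
    return genome, t


class TestAnchorAndTranslate:
    def test_frame_offset_positional_arithmetic(self):
        # consensus starts 10 nt into the CDS: first full codon begins at
        # CDS index 12, i.e. 2 bases into the consensus
        cds = "ATG" + "GCCGATTGGAAACCCGGGTTT" + "TAA"
        genome, t = _single_exon_setup(cds)
        v = Variant("chr1", 30 + 15, cds[15], "A" if cds[15] != "A" else "C")
        c = CodingSequenceCandidate(
            variant=v,
            cdna=cds[10:15] + v.alt + cds[16:24],
            variant_interval=(5, 6),
            supporting_read_names=frozenset({"r1", "r2", "r3"}),
            ref_length=1,
        )
        anchored = anchor_to_transcript(c, [t], genome)
        assert anchored.frame_offset == 2
        assert anchored.transcript_id == "T1"

    def test_consensus_extending_into_utr_is_trimmed(self):
        cds = "ATGGCCGATTGGTAA"
        genome, t = _single_exon_setup(cds)
        v = Variant("chr1", 30 + 4, cds[4], "T")
        prefix = "GGGG" + cds[:4]  # 4 UTR bases then CDS start
        c = CodingSequenceCandidate(
            variant=v, cdna=prefix + "T" + cds[5:],
            variant_interval=(len(prefix), len(prefix) + 1),
            supporting_read_names=frozenset({"a"}), ref_length=1,
        )
        anchored = anchor_to_transcript(c, [t], genome)
        assert anchored.frame_offset == 0
        assert anchored.cdna.startswith("ATG")

    def test_no_transcript_yields_none(self):
        genome, t = _single_exon_setup("ATGGCCTAA")
        v = Variant("chr1", 1, "G", "A")  # outside the CDS
        c = CodingSequenceCandidate(
            variant=v, cdna="GAG", variant_interval=(1, 2),
            supporting_read_names=frozenset({"a"}), ref_length=1,
        )
        assert anchor_to_transcript(c, [t], genome) is None

    def test_minus_strand_reverse_complemented(self, small_fixture):
        genome = load_reference(small_fixture.fasta)
        transcripts = {t.id: t for t in load_annotations(small_fixture.gtf)}
        for m in small_fixture.manifest["variants"]:
            t = transcripts[m["transcript_id"]]
            if t.strand != "-":
                continue
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            group = collect_reads(str(small_fixture.sam), v)
            c = assemble_most_abundant(group_reads_by_sequence(group.alt_reads), v)
            anchored = anchor_to_transcript(c, [t], genome)
            protein = translate_candidate(anchored)
            assert protein.amino_acids == m["expected_peptide_phased"]

    def test_translate_snv_single_mutant_residue(self):
        cds = "ATG" + "GCC" * 10 + "TAA"  # M AAAAAAAAAA *
        genome, t = _single_exon_setup(cds)
        # codon 5 GCC -> GTC (A->V); genomic pos of that base: 30+3*5+1
        v = Variant("chr1", 30 + 16, "C", "T")
        c = CodingSequenceCandidate(
            variant=v, cdna=cds[:16] + "T" + cds[17:],
            variant_interval=(16, 17),
            supporting_read_names=frozenset({"x", "y", "z"}), ref_length=1,
        )
        anchored = anchor_to_transcript(c, [t], genome)
        protein = translate_candidate(anchored, peptide_radius=12)
        ms, me = protein.mutant_aa_interval
        assert protein.amino_acids[ms:me] == "V"
        assert me - ms == 1

    def test_frameshift_marks_tail_as_mutant(self):
        cds = "ATG" + "GCC" * 10 + "TAA"
        genome, t = _single_exon_setup(cds)
        v = Variant("chr1", 30 + 15, "", "T")  # 1-nt insertion at codon 5
        c = CodingSequenceCandidate(
            variant=v, cdna=cds[:15] + "T" + cds[15:],
            variant_interval=(15, 16),
            supporting_read_names=frozenset({"x"}), ref_length=0,
        )
        anchored = anchor_to_transcript(c, [t], genome)
        protein = translate_candidate(anchored)
        assert protein.is_frameshift
        assert protein.mutant_aa_interval[1] == len(protein.amino_acids)

    def test_mutation_near_start_gives_short_fragment(self):
        cds = "ATGGCCGATTGGAAACCCGGGTTTTAA"
        genome, t = _single_exon_setup(cds)
        v = Variant("chr1", 30 + 4, "C", "T")  # codon 1
        c = CodingSequenceCandidate(
            variant=v, cdna=cds[:4] + "T" + cds[5:],
            variant_interval=(4, 5),
            supporting_read_names=frozenset({"x"}), ref_length=1,
        )
        protein = translate_candidate(anchor_to_transcript(c, [t], genome))
        ms, _ = protein.mutant_aa_interval
        assert ms == 1  # only one residue of context upstream


class TestEndToEndProperties:
    def test_flank_translation_matches_reference(self, small_fixture):
        """Reference-matching flanks translate to the reference protein."""
        genome = load_reference(small_fixture.fasta)
        transcripts = {t.id: t for t in load_annotations(small_fixture.gtf)}
        for m in small_fixture.manifest["variants"]:
            t = transcripts[m["transcript_id"]]
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            group = collect_reads(str(small_fixture.sam), v)
            c = assemble_most_abundant(group_reads_by_sequence(group.alt_reads), v)
            protein = translate_candidate(anchor_to_transcript(c, [t], genome))
            ref_protein = translate(t.spliced_cds(genome))
            ms, me = protein.mutant_aa_interval
            aa_index = m["mutant_aa_index"]
            left = protein.amino_acids[:ms]
            right = protein.amino_acids[me:]
            assert ref_protein[aa_index - len(left): aa_index] == left
            assert ref_protein[aa_index + 1: aa_index + 1 + len(right)] == right

    def test_winner_support_is_maximal(self, small_fixture):
        for m in small_fixture.manifest["variants"]:
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            group = collect_reads(str(small_fixture.sam), v)
            groups = group_reads_by_sequence(group.alt_reads)
            winner = assemble_most_abundant(groups, v)
            assert all(winner.num_supporting_reads >= g.count for g in groups)
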