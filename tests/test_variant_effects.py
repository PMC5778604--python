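import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from neopept.genome_model import ReferenceGenome, Transcript, load_reference
from neopept.variant_effects import (
    NONSILENT_CATEGORIES,
    Variant,
    VariantError,
    annotate_effects,
    classify_cds_edit,
    filter_nonsilent,
    normalize,
    read_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(tmp_path, rows):
    p = tmp_path / "v.vcf"
    p.write_text(VCF_HEADER + "".join(rows))
    return p


class TestReadVcf:
    def test_snv_coordinate_conversion(self, tmp_path):
        p = write_vcf(tmp_path, ["chr1\t100\t.\tA\tT\t.\tPASS\t.\n"])
        (v,) = read_vcf(p)
        assert (v.contig, v.pos, v.ref, v.alt) == ("chr1", 99, "A", "T")

    def test_deletion_trimming(self, tmp_path):
        p = write_vcf(tmp_path, ["chr1\t100\t.\tAT\tA\t.\tPASS\t.\n"])
        (v,) = read_vcf(p)
        assert (v.pos, v.ref, v.alt) == (100, "T", "")

    def test_multiallelic_split(self, tmp_path):
        p = write_vcf(tmp_path, ["chr1\t100\t.\tA\tT,G\t.\tPASS\t.\n"])
        variants = read_vcf(p)
        assert [v.alt for v in variants] == ["T", "G"]

    def test_nonpass_filtered_by_default(self, tmp_path):
        p = write_vcf(tmp_path, [
            "chr1\t100\t.\tA\tT\t.\tlowqual\t.\n",
            "chr1\t200\t.\tC\tG\t.\tPASS\t.\n",
        ])
        assert len(read_vcf(p)) == 1
        assert len(read_vcf(p, keep_nonpass=True)) == 2

    def test_symbolic_alt_skipped(self, tmp_path):
        p = write_vcf(tmp_path, [
            "chr1\t100\t.\tA\t<DEL>\t.\tPASS\t.\n",
            "chr1\t200\t.\tC\tG\t.\tPASS\t.\n",
        ])
        variants = read_vcf(p)
        assert len(variants) == 1 and variants[0].alt == "G"


class TestNormalize:
    def test_mnv_trims_to_snv(self):
        genome = ReferenceGenome({"chr1": "AAAAAAAAAACAGAAAA"})
        v = Variant("chr1", 10, "CAG", "CTG")
        n = normalize(v, genome)
        assert (n.pos, n.ref, n.alt) == (11, "A", "T")

    def test_deletion_left_aligned_to_run_start(self):
        # genome ...ATTTG...: deleting any single T yields the same sequence;
        # oracle: smallest equivalent position
        seq = "CCCATTTGCCC"
        genome = ReferenceGenome({"chr1": seq})
        stated = Variant("chr1", 6, "T", "")  # rightmost T of the run
        n = normalize(stated, genome)
        after = seq[:6] + seq[7:]
        equivalent = [
            p for p in range(len(seq)) if seq[:p] + seq[p + 1:] == after
        ]
        assert n.pos == min(equivalent)
        assert (n.ref, n.alt) == ("T", "")

    def test_insertion_left_aligned(self):
        seq = "CCCATTTGCCC"
        genome = ReferenceGenome({"chr1": seq})
        stated = Variant("chr1", 7, "", "T")  # insert T after the run
        n = normalize(stated, genome)
        after = seq[:7] + "T" + seq[7:]
        equivalent = [
            p for p in range(len(seq) + 1) if seq[:p] + "T" + seq[p:] == after
        ]
        assert n.pos == min(equivalent)

    def test_snv_idempotent(self):
        genome = ReferenceGenome({"chr1": "ACGTACGT"})
        v = Variant("chr1", 2, "G", "C")
        assert normalize(v, genome) == v

    @given(st.integers(0, 7))
    @settings(max_examples=20)
    def test_idempotence_property(self, pos):
        seq = "ATTTGGCA"
        genome = ReferenceGenome({"chr1": seq})
        v = Variant("chr1", pos, seq[pos], "")
        once = normalize(v, genome)
        assert normalize(once, genome) == once

    def test_ref_mismatch_names_locus(self):
        genome = ReferenceGenome({"chr1": "AAAA"})
        with pytest.raises(VariantError, match="chr1:1"):
            normalize(Variant("chr1", 1, "C", "T"), genome)


def _make_coding_setup(cds):
    """Single-exon plus-strand transcript whose CDS is `cds` at offset 5."""
    seq = "GGGGG" + cds + "GGGGG"
    genome = ReferenceGenome({"chr1": seq})
    t = Transcript("T1", "G1", "chr1", "+", ((0, len(seq)),), 5, 5 + len(cds))
    return genome, t


class TestAnnotateEffects:
    def test_silent(self):
        genome, t = _make_coding_setup("ATGGCCTAA")
        # GCC -> GCG, both Ala; codon 1 third base is genomic pos 5+5
        (e,) = annotate_effects(Variant("chr1", 10, "C", "G"), [t], genome)
        assert e.category == "silent"

    def test_missense(self):
        genome, t = _make_coding_setup("ATGGCCTAA")
        # GCC -> GTC (A->V)
        (e,) = annotate_effects(Variant("chr1", 9, "C", "T"), [t], genome)
        assert e.category == "missense"
        assert e.aa_pos == 1

    def test_start_lost(self):
        genome, t = _make_coding_setup("ATGGCCTAA")
        (e,) = annotate_effects(Variant("chr1", 5, "A", "G"), [t], genome)
        assert e.category == "start_lost"

    def test_stop_gained(self):
        genome, t = _make_coding_setup("ATGTGGGCCTAA")  # M W A *
        # TGG -> TGA
        (e,) = annotate_effects(Variant("chr1", 10, "G", "A"), [t], genome)
        assert e.category == "stop_gained"

    def test_stop_lost(self):
        genome, t = _make_coding_setup("ATGGCCTAAGCATGA")
        # TAA -> CAA extends translation to the downstream TGA
        (e,) = annotate_effects(Variant("chr1", 11, "T", "C"), [t], genome)
        assert e.category == "stop_lost"

    def test_frameshift_insertion_aa_pos(self):
        cds = "ATGGCCGATTGGTAA"
        genome, t = _make_coding_setup(cds)
        v = Variant("chr1", 11, "", "T")  # 1-nt insertion inside codon 2
        (e,) = annotate_effects(v, [t], genome)
        assert e.category == "frameshift"
        # oracle: translate the edited CDS and find the first changed residue
        edited = cds[:6] + "T" + cds[6:]
        ref_p = str(Seq(cds).translate(to_stop=True))
        mut_p = str(Seq(edited[: len(edited) - len(edited) % 3]).translate(to_stop=True))
        first_diff = next(
            (i for i in range(min(len(ref_p), len(mut_p))) if ref_p[i] != mut_p[i]),
            min(len(ref_p), len(mut_p)),
        )
        assert e.aa_pos == first_diff

    def test_inframe_insertion_and_deletion(self):
        genome, t = _make_coding_setup("ATGGCCGATTGGTAA")
        (e,) = annotate_effects(Variant("chr1", 8, "", "AAA"), [t], genome)
        assert e.category == "inframe_insertion"
        (e,) = annotate_effects(Variant("chr1", 8, "GCC", ""), [t], genome)
        assert e.category == "inframe_deletion"

    def test_intronic_and_noncoding(self):
        seq = "GG" + "ATG" + "GTTTTAG" + "GCCTAA" + "GG"
        genome = ReferenceGenome({"chr1": seq})
        t = Transcript("T", "G", "chr1", "+", ((0, 5), (12, 20)), 2, 18)
        (e,) = annotate_effects(Variant("chr1", 7, "T", "A"), [t], genome)
        assert e.category == "intronic"
        (e,) = annotate_effects(Variant("chr1", 18, "A", "C"), [t], genome)
        assert e.category == "noncoding"

    def test_no_overlap_yields_empty(self):
        genome, t = _make_coding_setup("ATGGCCTAA")
        # transcript spans [0, 19); place a variant beyond it
        genome = ReferenceGenome({"chr1": genome.contigs["chr1"] + "A" * 30})
        assert annotate_effects(Variant("chr1", 30, "A", "T"), [t], genome) == []

    def test_fixture_snvs_agree_with_bruteforce_oracle(self, small_fixture):
        from neopept.genome_model import load_annotations, load_reference

        genome = load_reference(small_fixture.fasta)
        transcripts = {t.id: t for t in load_annotations(small_fixture.gtf)}
        for m in small_fixture.manifest["variants"]:
            t = transcripts[m["transcript_id"]]
            v = Variant(m["contig"], m["pos"], m["ref"], m["alt"])
            effects = [
                e for e in annotate_effects(v, [t], genome)
                if e.transcript.id == t.id
            ]
            assert len(effects) == 1
            # oracle: edit full CDS, translate both with Biopython, compare
            cds = t.spliced_cds(genome)
            off = m["cds_offset"]
            ref_len = len(m["ref"])
            alt = m["alt"]
            if t.strand == "-":
                from neopept.genome_model import reverse_complement
                alt = reverse_complement(alt)
            edited = cds[:off] + alt + cds[off + ref_len:]
            ref_p = str(Seq(cds).translate(to_stop=True))
            mut_p = str(Seq(edited).translate(to_stop=True))
            assert ref_p != mut_p
            assert len(ref_p) == len(mut_p)  # planted missense
            assert effects[0].category == "missense"
            diff = [i for i in range(len(ref_p)) if ref_p[i] != mut_p[i]]
            assert effects[0].aa_pos == diff[0] == m["mutant_aa_index"]


class TestFilterNonsilent:
    def _effect(self, category):
        genome, t = _make_coding_setup("ATGGCCTAA")
        from neopept.variant_effects import VariantEffect
        return VariantEffect(Variant("chr1", 9, "C", "T"), t, category, 0)

    def test_drops_silent(self):
        effects = [self._effect("silent"), self._effect("missense")]
        assert [e.category for e in filter_nonsilent(effects)] == ["missense"]

    def test_empty_identity(self):
        assert filter_nonsilent([]) == []

    @given(st.lists(st.sampled_from([
        "silent", "missense", "inframe_insertion", "inframe_deletion",
        "frameshift", "stop_gained", "stop_lost", "noncoding", "intronic",
    ]), max_size=12))
    @settings(max_examples=30)
    def test_predicate_oracle(self, categories):
        effects = [self._effect(c) for c in categories]
        kept = filter_nonsilent(effects)
        assert [e.category for e in kept] == [
            c for c in categories if c in NONSILENT_CATEGORIES
        ]
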