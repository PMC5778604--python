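import pytest

from neopept.genome_model import ReferenceGenome, Transcript
from neopept.pipeline import PipelineConfig
from neopept.synthetic_fixtures import generate_fixture, standard_spec

HLA_ALLELES = ("HLA-A*02:01", "HLA-B*07:02")


def make_config(fixture, out_dir, **overrides) -> PipelineConfig:
    base = dict(
        vcf=str(fixture.vcf),
        bam=str(fixture.sam),
        ref=str(fixture.fasta),
        gtf=str(fixture.gtf),
        hla=HLA_ALLELES,
        out_dir=str(out_dir),
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Six SNVs, one per transcript, alternating strands, error-free."""
    d = tmp_path_factory.mktemp("fx_small")
    spec = standard_spec(num_variants=6, depth=40, seed=11)
    return generate_fixture(spec, d)


@pytest.fixture(scope="session")
def phasing_fixture(tmp_path_factory):
    """Each somatic SNV has a phased germline SNV 21 nt downstream; every
    third transcript is two-exon so reads span a splice junction."""
    d = tmp_path_factory.mktemp("fx_phasing")
    spec = standard_spec(
        num_variants=6, depth=40, seed=12, neighbor_offset_nt=21, two_exon_every=3
    )
    return generate_fixture(spec, d)


@pytest.fixture
def toy_genome():
    # single-exon plus-strand CDS "ATGGCCCTGAAGTAA" -> protein MALK
    seq = "GGGGG" + "ATGGCCCTGAAGTAA" + "CCCCC"
    return ReferenceGenome({"chr1": seq})


@pytest.fixture
def toy_transcript():
    return Transcript(
        id="T1", gene="G1", contig="chr1", strand="+",
        exons=((0, 25),), cds_start=5, cds_end=20,
    )
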