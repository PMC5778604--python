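# neopept

RNA-evidence-driven selection and ranking of neoantigen vaccine peptides.

Given somatic variants (VCF), tumor RNA alignments (SAM/BAM), a reference
genome (FASTA), transcript annotation (GTF) and the patient's HLA Class I
alleles, `neopept`:

1. normalizes variants and discards those that do not alter the protein
   (silent / non-coding / intronic effects are filtered per transcript);
2. collects RNA reads spanning each variant locus and partitions them into
   alt / ref / other support, estimating allele-specific expression from
   mutation-supporting read counts;
3. assembles the most abundant mutant coding sequence from the alt reads —
   nearby germline or somatic variants present in the supporting reads are
   phased into the consensus automatically — anchors it to a transcript to
   establish the reading frame, and translates it;
4. enumerates candidate vaccine peptide windows (default 25-mers containing
   the mutation), scores each as
   `TotalScore = ExpressionScore × BindingScore`, where the binding score
   sums logistic-normalized predicted MHC affinities of every mutant 8–11-mer
   epitope across all patient alleles (0.5 at the classical 500 nM
   threshold), and the expression score is a concave transform
   (default `sqrt`) of the supporting read count;
5. screens peptides with manufacturability heuristics (cysteine content,
   problematic N-termini, N–P bonds, hydrophobicity) used as ranking
   tie-breakers, and emits the top candidates (default 15).

MHC affinity prediction is pluggable: a deterministic built-in toy
predictor (anchor-residue position weights per allele), a pre-computed
TSV affinity table, or a locally installed NetMHCpan executable.

## CLI

Generate a deterministic synthetic fixture (toy genome, GTF, VCF and
aligned RNA reads with per-read ground truth):

```bash
neopept-fixtures --standard 6 --seed 1 --out fixture/
```

Run the pipeline:

```bash
neopept run \
  --vcf fixture/somatic.vcf \
  --bam fixture/alignments.sam \
  --ref fixture/genome.fasta \
  --gtf fixture/annotation.gtf \
  --hla "HLA-A*02:01,HLA-B*07:02" \
  --out report/
```

Outputs: `candidates.csv` (one row per ranked peptide), `candidates.json`
(full detail including per-epitope predictions), `drops.jsonl` (one reason
per excluded variant — every input variant is accounted for exactly once)
and `effective_config.yaml`. Reports contain no timestamps; identical
inputs and configuration give byte-identical outputs.

Useful flags: `--predictor {toy,table,netmhcpan}`, `--affinity-table TSV`,
`--min-alt-rna-reads`, `--peptide-length`, `--epitope-lengths`,
`--max-candidates`, `--binding-midpoint-nm`, `--binding-slope`,
`--expression-transform {sqrt,identity,log1p}`,
`--manufacturability {off,flags,strict}`, `--keep-nonpass`,
`--count-mates-separately`, `--resume`.

## Layout

- `src/neopept/genome_model.py` — FASTA/GTF models, spliced CDS, translation
- `src/neopept/variant_effects.py` — VCF reading, normalization, effect classes
- `src/neopept/read_evidence.py` — CIGAR-aware allele partitioning of reads
- `src/neopept/coding_assembly.py` — consensus assembly, anchoring, translation
- `src/neopept/mhc_binding.py` — predictors + logistic affinity normalization
- `src/neopept/ranking.py` — windows, epitopes, scores, ranked report
- `src/neopept/manufacturability.py` — synthesis-feasibility heuristics
- `src/neopept/synthetic_fixtures.py` — deterministic test-data generator
- `src/neopept/pipeline.py`, `src/neopept/cli.py` — orchestration and CLI
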