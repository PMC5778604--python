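"""End-to-end in-process orchestration: variants -> RNA evidence ->
mutant protein assembly -> MHC scoring -> ranked vaccine peptide report.

Every input variant is accounted for exactly once, either as a report
candidate or as a drop-log entry with a reason.  Reports contain no
timestamps, so identical configuration and inputs yield byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
import yaml

from . import coding_assembly, manufacturability, mhc_binding, ranking, read_evidence
from .genome_model import load_annotations, load_reference
from .ranking import RankedReport, VaccinePeptideCandidate
from .variant_effects import (
    Variant,
    annotate_effects,
    filter_nonsilent,
    normalize,
    read_vcf,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables; serialized into every report."""

    vcf: str
    bam: str
    ref: str
    gtf: str
    hla: Tuple[str, ...]
    out_dir: Optional[str] = None
    predictor: str = "toy"
    affinity_table: Optional[str] = None
    min_alt_rna_reads: int = 3
    peptide_length: int = 25
    epitope_lengths: Tuple[int, ...] = (8, 9, 10, 11)
    max_candidates: int = 15
    binding_midpoint_nm: float = 500.0
    binding_slope: float = 1.0
    expression_transform: str = "sqrt"
    manufacturability_mode: str = "flags"  # off | flags | strict
    keep_nonpass: bool = False
    count_mates_separately: bool = False
    min_mapq: int = 1
    min_base_quality: int = 20
    resume: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("hla", "epitope_lengths"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["hla"] = list(self.hla)
        out["epitope_lengths"] = list(self.epitope_lengths)
        return out


def _check_contig_consistency(config: PipelineConfig, genome_contigs) -> None:
    with pysam.AlignmentFile(config.bam) as fh:
        sam_contigs = set(fh.references)
    missing = sam_contigs - set(genome_contigs)
    if missing:
        raise PipelineError(
            f"alignment contigs {sorted(missing)} absent from the reference FASTA"
        )
    with pysam.VariantFile(config.vcf) as vcf:
        vcf_contigs = {rec.contig for rec in vcf}
    missing = vcf_contigs - set(genome_contigs)
    if missing:
        raise PipelineError(
            f"VCF contigs {sorted(missing)} absent from the reference FASTA"
        )


def _content_hash(config: PipelineConfig) -> str:
    digest = hashlib.sha256()
    for path in (config.vcf, config.bam, config.ref, config.gtf):
        digest.update(Path(path).read_bytes())
    digest.update(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    )
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> RankedReport:
    """Execute the full selection pipeline and (optionally) write reports."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    content_hash = _content_hash(config)
    if config.resume and out_dir is not None:
        existing = out_dir / "candidates.json"
        if existing.exists():
            try:
                payload = json.loads(existing.read_text())
            except json.JSONDecodeError:
                payload = {}
            if payload.get("input_hash") == content_hash:
                logger.info("resume: inputs unchanged, reusing existing report")
                return _report_from_payload(payload)

    genome = load_reference(config.ref)
    transcripts = load_annotations(config.gtf)
    _check_contig_consistency(config, genome.contigs)

    alleles = [mhc_binding.normalize_allele_name(a) for a in config.hla]
    predictor = mhc_binding.make_predictor(config.predictor, config.affinity_table)
    if config.predictor == "toy":
        supported = {a.name for a in predictor.supported_alleles()}
        unsupported = [a.name for a in alleles if a.name not in supported]
        if unsupported:
            raise PipelineError(
                f"alleles {unsupported} not supported by the built-in "
                f"predictor; supported: {sorted(supported)}"
            )

    raw_variants = read_vcf(config.vcf, keep_nonpass=config.keep_nonpass)
    variants: List[Variant] = []
    seen = set()
    drop_log: List[dict] = []
    for raw in raw_variants:
        v = normalize(raw, genome)
        if v in seen:
            drop_log.append({"variant": v.short_id, "stage": "input",
                             "reason": "duplicate after normalization"})
            continue
        seen.add(v)
        variants.append(v)

    filters = read_evidence.ReadFilters(
        min_mapq=config.min_mapq, min_base_quality=config.min_base_quality
    )
    # alignments are loaded once; fixture-scale data fits comfortably in memory
    with pysam.AlignmentFile(config.bam) as fh:
        alignments = list(fh.fetch(until_eof=True))

    peptide_radius = (config.peptide_length - 1) // 2
    per_variant: Dict[Variant, List[VaccinePeptideCandidate]] = {}
    for v in sorted(variants):
        effects = annotate_effects(v, transcripts, genome)
        nonsilent = filter_nonsilent(effects)
        if not nonsilent:
            categories = sorted({e.category for e in effects}) or ["no_overlap"]
            drop_log.append({"variant": v.short_id, "stage": "variant_effects",
                             "reason": f"no protein-altering effect "
                                       f"(categories: {','.join(categories)})"})
            continue

        group = read_evidence.collect_reads(alignments, v, filters)
        n_alt = read_evidence.alt_read_count(
            group, count_mates_separately=config.count_mates_separately
        )
        if n_alt < config.min_alt_rna_reads:
            drop_log.append({"variant": v.short_id, "stage": "read_evidence",
                             "reason": f"insufficient RNA support "
                                       f"({n_alt} < {config.min_alt_rna_reads})"})
            continue

        groups = coding_assembly.group_reads_by_sequence(group.alt_reads)
        candidate = coding_assembly.assemble_most_abundant(
            groups, v, min_reads=config.min_alt_rna_reads
        )
        if candidate is None:
            drop_log.append({"variant": v.short_id, "stage": "coding_assembly",
                             "reason": "no consensus group reaches min_reads"})
            continue

        eligible_transcripts = [e.transcript for e in nonsilent]
        anchored = coding_assembly.anchor_to_transcript(
            candidate, eligible_transcripts, genome
        )
        if anchored is None:
            drop_log.append({"variant": v.short_id, "stage": "coding_assembly",
                             "reason": "no transcript yields a reading frame"})
            continue

        protein = coding_assembly.translate_candidate(
            anchored, peptide_radius=peptide_radius
        )
        if protein is None:
            drop_log.append({"variant": v.short_id, "stage": "coding_assembly",
                             "reason": "stop codon precedes the mutant interval"})
            continue

        expression = ranking.expression_score(n_alt, config.expression_transform)
        windows = ranking.candidate_windows(protein, config.peptide_length)
        scored = []
        for window in windows:
            epitopes = ranking.mutant_epitopes(
                window.peptide, window.mutant_interval, config.epitope_lengths
            )
            bscore, predictions = ranking.binding_score(
                epitopes, alleles, predictor,
                midpoint_nM=config.binding_midpoint_nm,
                slope=config.binding_slope,
            )
            if config.manufacturability_mode == "off":
                flags = manufacturability.ManufacturabilityFlags()
            else:
                flags = manufacturability.manufacturability_flags(window.peptide)
            if (config.manufacturability_mode == "strict"
                    and manufacturability.manufacturability_rank_key(flags) > 0):
                continue
            scored.append(
                VaccinePeptideCandidate(
                    variant=v,
                    peptide=window.peptide,
                    mutant_interval=window.mutant_interval,
                    expression_score=expression,
                    binding_score=bscore,
                    total_score=ranking.total_score(expression, bscore),
                    manufacturability=flags,
                    epitope_predictions=tuple(predictions),
                    num_supporting_reads=n_alt,
                    window_flags=window.flags,
                )
            )
        if not scored:
            drop_log.append({"variant": v.short_id, "stage": "manufacturability",
                             "reason": "all windows excluded in strict mode"})
            continue
        per_variant[v] = scored

    report = ranking.rank_candidates(
        per_variant,
        max_candidates=config.max_candidates,
        drop_log=drop_log,
        config=config.to_dict(),
    )
    if out_dir is not None:
        write_reports(report, out_dir, content_hash)
    return report


def _candidate_payload(c: VaccinePeptideCandidate) -> dict:
    return {
        "contig": c.variant.contig,
        "pos": c.variant.pos,
        "ref": c.variant.ref,
        "alt": c.variant.alt,
        "peptide": c.peptide,
        "mutant_start": c.mutant_interval[0],
        "mutant_end": c.mutant_interval[1],
        "expression_score": c.expression_score,
        "binding_score": c.binding_score,
        "total_score": c.total_score,
        "num_supporting_reads": c.num_supporting_reads,
        "manufacturability_flags": list(c.manufacturability.set_flags()),
        "window_flags": list(c.window_flags),
        "notes": list(c.notes),
        "epitope_predictions": [
            {"peptide": p.peptide, "allele": p.allele.name,
             "affinity_nM": p.affinity_nM}
            for p in c.epitope_predictions
        ],
    }


def write_reports(report: RankedReport, out_dir, input_hash: str = "") -> None:
    """Write candidates.csv / candidates.json / drops.jsonl /
    effective_config.yaml (deterministic; no timestamps)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for rank, c in enumerate(report.candidates, 1):
        payload = _candidate_payload(c)
        rows.append(
            {
                "rank": rank,
                "contig": payload["contig"],
                "pos": payload["pos"],
                "ref": payload["ref"],
                "alt": payload["alt"],
                "peptide": payload["peptide"],
                "mutant_start": payload["mutant_start"],
                "mutant_end": payload["mutant_end"],
                "expression_score": payload["expression_score"],
                "binding_score": payload["binding_score"],
                "total_score": payload["total_score"],
                "num_supporting_reads": payload["num_supporting_reads"],
                "manufacturability_flags": ";".join(
                    payload["manufacturability_flags"]
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "rank", "contig", "pos", "ref", "alt", "peptide", "mutant_start",
            "mutant_end", "expression_score", "binding_score", "total_score",
            "num_supporting_reads", "manufacturability_flags",
        ],
    ).to_csv(out_dir / "candidates.csv", index=False)

    payload = {
        "input_hash": input_hash,
        "config": report.config,
        "warnings": report.warnings,
        "candidates": [_candidate_payload(c) for c in report.candidates],
        "drop_log": report.drop_log,
    }
    with open(out_dir / "candidates.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out_dir / "drops.jsonl", "w") as fh:
        for entry in report.drop_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")

    with open(out_dir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(report.config, fh, sort_keys=True)


def _report_from_payload(payload: dict) -> RankedReport:
    from .mhc_binding import BindingPrediction, HLAAllele

    candidates = []
    for c in payload.get("candidates", []):
        candidates.append(
            VaccinePeptideCandidate(
                variant=Variant(c["contig"], c["pos"], c["ref"], c["alt"]),
                peptide=c["peptide"],
                mutant_interval=(c["mutant_start"], c["mutant_end"]),
                expression_score=c["expression_score"],
                binding_score=c["binding_score"],
                total_score=c["total_score"],
                manufacturability=manufacturability.ManufacturabilityFlags(
                    **{name: name in c["manufacturability_flags"]
                       for name in manufacturability.FLAG_NAMES}
                ),
                epitope_predictions=tuple(
                    BindingPrediction(p["peptide"], HLAAllele(p["allele"]),
                                      p["affinity_nM"])
                    for p in c.get("epitope_predictions", [])
                ),
                num_supporting_reads=c["num_supporting_reads"],
                window_flags=tuple(c.get("window_flags", ())),
                notes=tuple(c.get("notes", ())),
            )
        )
    return RankedReport(
        candidates=candidates,
        drop_log=payload.get("drop_log", []),
        config=payload.get("config", {}),
        warnings=payload.get("warnings", []),
    )
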