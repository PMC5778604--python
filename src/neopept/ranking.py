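"""Window selection, scoring and ranking of candidate vaccine peptides.

A vaccine peptide is a window (default 25 residues) of the mutant
protein fragment that fully contains the mutant interval.  Each window
is scored as ``TotalScore = ExpressionScore x BindingScore`` where the
expression score is a concave transform of the mutation-supporting RNA
read count and the binding score sums logistic-normalized predicted
affinities of every mutant epitope across all patient alleles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .coding_assembly import ProteinSequenceCandidate
from .manufacturability import ManufacturabilityFlags, manufacturability_rank_key
from .mhc_binding import (
    DEFAULT_EPITOPE_LENGTHS,
    DEFAULT_MIDPOINT_NM,
    DEFAULT_SLOPE,
    BindingPrediction,
    HLAAllele,
    normalize_affinity,
)
from .variant_effects import Variant

logger = logging.getLogger(__name__)

DEFAULT_PEPTIDE_LENGTH = 25
DEFAULT_MAX_CANDIDATES = 15
EXPRESSION_TRANSFORMS = ("sqrt", "identity", "log1p")


def coding_span_nt(peptide_length: int = DEFAULT_PEPTIDE_LENGTH) -> int:
    """Nucleotides of coding sequence translated into one vaccine peptide."""
    if peptide_length <= 0:
        raise ValueError("peptide_length must be positive")
    return 3 * peptide_length


@dataclass(frozen=True)
class PeptideWindow:
    peptide: str
    mutant_interval: Tuple[int, int]  # relative to the window
    offset: int                       # start within the source fragment
    flags: Tuple[str, ...] = ()


def candidate_windows(
    p: ProteinSequenceCandidate,
    vaccine_peptide_length: int = DEFAULT_PEPTIDE_LENGTH,
) -> List[PeptideWindow]:
    """All windows of the configured length fully containing the mutant
    interval (shorter at sequence boundaries, flagged).

    When the mutant interval itself exceeds the window length (long
    frameshifts), windows covering the interval's start are emitted and
    flagged ``mutant_interval_truncated``.
    """
    seq = p.amino_acids
    ms, me = p.mutant_aa_interval
    if not (0 <= ms < me <= len(seq)):
        raise ValueError(f"mutant interval {p.mutant_aa_interval} outside peptide")
    n = len(seq)
    length = vaccine_peptide_length
    if n <= length:
        flags = ("short_sequence",) if n < length else ()
        if me - ms > length:
            flags += ("mutant_interval_truncated",)
        return [PeptideWindow(seq, (ms, me), 0, flags)]
    if me - ms > length:
        starts = range(max(0, ms - length + 1), min(ms, n - length) + 1)
        return [
            PeptideWindow(
                seq[s : s + length],
                (ms - s, length),
                s,
                ("mutant_interval_truncated",),
            )
            for s in starts
        ]
    starts = range(max(0, me - length), min(ms, n - length) + 1)
    return [
        PeptideWindow(seq[s : s + length], (ms - s, me - s), s) for s in starts
    ]


def mutant_epitopes(
    peptide: str,
    mutant_interval: Tuple[int, int],
    lengths: Iterable[int] = DEFAULT_EPITOPE_LENGTHS,
) -> List[str]:
    """Every subpeptide of the configured lengths overlapping >= 1 mutant
    residue; wild-type-only subpeptides are excluded."""
    ms, me = mutant_interval
    if not (0 <= ms < me <= len(peptide)):
        raise ValueError(f"invalid mutant interval {mutant_interval}")
    n = len(peptide)
    epitopes = []
    for length in sorted(set(lengths)):
        if length > n:
            continue
        for start in range(max(0, ms - length + 1), min(me - 1, n - length) + 1):
            epitopes.append(peptide[start : start + length])
    return epitopes


def binding_score(
    epitopes: Sequence[str],
    alleles: Sequence[HLAAllele],
    predictor,
    midpoint_nM: float = DEFAULT_MIDPOINT_NM,
    slope: float = DEFAULT_SLOPE,
) -> Tuple[float, List[BindingPrediction]]:
    """Sum of normalized affinities over all (epitope, allele) pairs.

    Returns the score together with the underlying predictions.
    """
    if not epitopes or not alleles:
        return 0.0, []
    predictions = predictor.predict(list(epitopes), list(alleles))
    expected = len(epitopes) * len(alleles)
    if len(predictions) != expected:
        raise RuntimeError(
            f"predictor returned {len(predictions)} predictions for "
            f"{expected} (epitope, allele) pairs"
        )
    score = sum(
        normalize_affinity(p.affinity_nM, midpoint_nM, slope) for p in predictions
    )
    return score, predictions


def expression_score(alt_read_count: int, transform: str = "sqrt") -> float:
    """Concave monotone transform of the mutation-supporting read count."""
    if alt_read_count < 0:
        raise ValueError("read count must be non-negative")
    if transform == "sqrt":
        return math.sqrt(alt_read_count)
    if transform == "identity":
        return float(alt_read_count)
    if transform == "log1p":
        return math.log1p(alt_read_count)
    raise ValueError(
        f"unknown expression transform {transform!r}; "
        f"choose from {EXPRESSION_TRANSFORMS}"
    )


def total_score(expression: float, binding: float) -> float:
    """Exact product; zero whenever either factor is zero."""
    if expression < 0 or binding < 0:
        raise ValueError("scores must be non-negative")
    return expression * binding


@dataclass(frozen=True)
class VaccinePeptideCandidate:
    variant: Variant
    peptide: str
    mutant_interval: Tuple[int, int]
    expression_score: float
    binding_score: float
    total_score: float
    manufacturability: ManufacturabilityFlags
    epitope_predictions: Tuple[BindingPrediction, ...] = ()
    num_supporting_reads: int = 0
    window_flags: Tuple[str, ...] = ()
    notes: Tuple[str, ...] = ()


@dataclass
class RankedReport:
    candidates: List[VaccinePeptideCandidate]
    drop_log: List[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)


def _window_sort_key(c: VaccinePeptideCandidate):
    return (
        -c.total_score,
        manufacturability_rank_key(c.manufacturability),
        c.peptide,
    )


def rank_candidates(
    per_variant: Mapping[Variant, Sequence[VaccinePeptideCandidate]],
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    drop_log: Optional[List[dict]] = None,
    config: Optional[dict] = None,
) -> RankedReport:
    """Pick the best window per variant, sort by total score and truncate.

    Per-variant ties break toward fewer manufacturability flags, then the
    lexicographically smaller peptide; the cross-variant order is fully
    deterministic.  Variants with zero expression never appear.
    """
    report = RankedReport([], list(drop_log or []), dict(config or {}))
    best_per_variant: List[VaccinePeptideCandidate] = []
    for variant in sorted(per_variant):
        windows = [c for c in per_variant[variant] if c.expression_score > 0]
        if not windows:
            report.drop_log.append(
                {"variant": variant.short_id, "stage": "ranking",
                 "reason": "no scoreable window (zero expression)"}
            )
            continue
        best_per_variant.append(min(windows, key=_window_sort_key))
    best_per_variant.sort(
        key=lambda c: _window_sort_key(c) + (c.variant.contig, c.variant.pos,
                                             c.variant.ref, c.variant.alt)
    )
    seen_peptides: Dict[str, Variant] = {}
    selected = []
    for candidate in best_per_variant[:max_candidates]:
        if candidate.peptide in seen_peptides:
            candidate = VaccinePeptideCandidate(
                **{**candidate.__dict__,
                   "notes": candidate.notes + (
                       f"peptide also produced by variant "
                       f"{seen_peptides[candidate.peptide].short_id}",)}
            )
        else:
            seen_peptides[candidate.peptide] = candidate.variant
        selected.append(candidate)
    for candidate in best_per_variant[max_candidates:]:
        report.drop_log.append(
            {"variant": candidate.variant.short_id, "stage": "ranking",
             "reason": f"below report cap (max_candidates={max_candidates})"}
        )
    report.candidates = selected
    if not selected:
        report.warnings.append("empty report: no variant produced a candidate")
        logger.warning("ranked report is empty")
    elif len(selected) < max_candidates:
        report.warnings.append(
            f"only {len(selected)} candidates available "
            f"(report cap is {max_candidates})"
        )
        logger.warning("fewer candidates than the report cap: %d < %d",
                       len(selected), max_candidates)
    return report
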