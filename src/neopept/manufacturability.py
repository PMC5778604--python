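"""Heuristic screening of peptides for solid-phase synthesis feasibility.

Flags never alter a candidate's score; they are used only as ranking
tie-breakers (or, in strict mode, to exclude flagged peptides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

FLAG_NAMES = (
    "excess_cysteine",
    "n_terminal_gln_glu_cys",
    "asparagine_proline_bond",
    "extreme_hydrophobicity",
    "hydrophobic_c_terminus",
)

DEFAULT_MAX_CYSTEINES = 3          # flag when count >= this
DEFAULT_HYDROPATHY_THRESHOLD = 2.5
DEFAULT_CTERM_WINDOW = 7
DEFAULT_CTERM_THRESHOLD = 2.5


@dataclass(frozen=True)
class ManufacturabilityFlags:
    excess_cysteine: bool = False
    n_terminal_gln_glu_cys: bool = False
    asparagine_proline_bond: bool = False
    extreme_hydrophobicity: bool = False
    hydrophobic_c_terminus: bool = False
    details: Tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    def set_flags(self) -> Tuple[str, ...]:
        return tuple(name for name in FLAG_NAMES if getattr(self, name))


def mean_hydropathy(peptide: str) -> float:
    """Mean Kyte-Doolittle hydropathy; unknown residues (X) count as 0."""
    if not peptide:
        raise ValueError("empty peptide")
    return sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in peptide) / len(peptide)


def manufacturability_flags(
    peptide: str,
    max_cysteines: int = DEFAULT_MAX_CYSTEINES,
    hydropathy_threshold: float = DEFAULT_HYDROPATHY_THRESHOLD,
    cterm_window: int = DEFAULT_CTERM_WINDOW,
    cterm_threshold: float = DEFAULT_CTERM_THRESHOLD,
) -> ManufacturabilityFlags:
    """Compute synthesis-feasibility flags from the sequence alone."""
    if not peptide:
        raise ValueError("empty peptide")
    details = []

    n_cys = peptide.count("C")
    excess_cysteine = n_cys >= max_cysteines
    if excess_cysteine:
        details.append(f"{n_cys} cysteines (threshold {max_cysteines})")

    n_terminal = peptide[0] in ("Q", "E", "C")
    if n_terminal:
        details.append(f"N-terminal residue {peptide[0]}")

    np_bond = "NP" in peptide
    if np_bond:
        details.append(f"N-P bond at index {peptide.index('NP')}")

    overall = mean_hydropathy(peptide)
    extreme = overall > hydropathy_threshold
    if extreme:
        details.append(f"mean hydropathy {overall:.2f} > {hydropathy_threshold}")

    tail = peptide[-cterm_window:]
    tail_hydro = mean_hydropathy(tail)
    hydrophobic_tail = tail_hydro > cterm_threshold
    if hydrophobic_tail:
        details.append(
            f"C-terminal {len(tail)}-residue hydropathy {tail_hydro:.2f} "
            f"> {cterm_threshold}"
        )

    return ManufacturabilityFlags(
        excess_cysteine=excess_cysteine,
        n_terminal_gln_glu_cys=n_terminal,
        asparagine_proline_bond=np_bond,
        extreme_hydrophobicity=extreme,
        hydrophobic_c_terminus=hydrophobic_tail,
        details=tuple(details),
    )


def manufacturability_rank_key(flags: ManufacturabilityFlags) -> int:
    """Number of set flags; a tie-breaker only, never part of the score."""
    return sum(1 for name in FLAG_NAMES if getattr(flags, name))
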