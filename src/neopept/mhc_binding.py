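"""Pluggable Class I peptide-MHC affinity prediction and normalization.

A deterministic built-in predictor scores anchor residues from a small
per-allele position-weight table (a stand-in for external tools such as
NetMHCpan); alternatively, pre-computed affinities may be loaded from a
TSV table.  Predicted IC50 affinities (nM) are mapped to [0, 1] with a
logistic centred on the classical 500-nM binder threshold.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

DEFAULT_MIDPOINT_NM = 500.0
DEFAULT_SLOPE = 1.0
DEFAULT_EPITOPE_LENGTHS = (8, 9, 10, 11)

_MIN_EPITOPE_LENGTH = 8
_MAX_EPITOPE_LENGTH = 15


class AlleleParseError(ValueError):
    pass


class UnsupportedAlleleError(KeyError):
    pass


class PredictionError(KeyError):
    pass


@dataclass(frozen=True, order=True)
class HLAAllele:
    """Canonical ``HLA-<gene>*<group>:<protein>`` allele name."""

    name: str

    def __str__(self) -> str:
        return self.name


def normalize_allele_name(raw: str) -> HLAAllele:
    """Parse common HLA dialects into the canonical form.

    Accepts e.g. ``A0201``, ``A*02:01``, ``HLA-A02:01`` and
    ``HLA-A*02:01``, all normalized to ``HLA-A*02:01``.
    """
    if not raw or not raw.strip():
        raise AlleleParseError(
            "empty allele name; accepted dialects: 'A0201', 'A*02:01', "
            "'HLA-A02:01', 'HLA-A*02:01'"
        )
    text = raw.strip().upper()
    if text.startswith("HLA-"):
        text = text[4:]
    gene = ""
    while text and text[0].isalpha():
        gene += text[0]
        text = text[1:]
    if not gene:
        raise AlleleParseError(
            f"cannot find gene in allele {raw!r}; accepted dialects: "
            "'A0201', 'A*02:01', 'HLA-A02:01', 'HLA-A*02:01'"
        )
    text = text.lstrip("*")
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 2 or not all(p.isdigit() and p for p in parts):
            raise AlleleParseError(f"cannot parse allele fields in {raw!r}")
        group, protein = parts
    else:
        if not text.isdigit() or len(text) != 4:
            raise AlleleParseError(
                f"cannot parse allele fields in {raw!r}; separator-free "
                "dialect must have exactly 4 digits (e.g. 'A0201')"
            )
        group, protein = text[:2], text[2:]
    return HLAAllele(f"HLA-{gene}*{int(group):02d}:{int(protein):02d}")


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: HLAAllele
    affinity_nM: float

    def __post_init__(self) -> None:
        if self.affinity_nM <= 0:
            raise ValueError("affinity must be positive")


def _check_peptides(peptides: Sequence[str]) -> None:
    for p in peptides:
        if not (_MIN_EPITOPE_LENGTH <= len(p) <= _MAX_EPITOPE_LENGTH):
            raise ValueError(
                f"peptide {p!r} has length {len(p)}; expected "
                f"{_MIN_EPITOPE_LENGTH}-{_MAX_EPITOPE_LENGTH}"
            )


class ToyMHCPredictor:
    """Deterministic closed-form predictor over a built-in anchor table.

    Each supported allele has residue preference weights at the two
    classical anchor positions (P2 and the C-terminus).  The mean anchor
    weight ``s`` in [0, 1] is mapped to an affinity ``50000**(1 - s)``
    nM, so a strictly better anchor match gives a strictly lower nM.
    """

    MAX_NM = 50000.0

    #: allele -> (P2 residue weights, C-terminal residue weights)
    ANCHOR_TABLE: Dict[str, Tuple[Dict[str, float], Dict[str, float]]] = {
        "HLA-A*01:01": ({"T": 1.0, "S": 0.7, "M": 0.4}, {"Y": 1.0, "F": 0.6, "W": 0.3}),
        "HLA-A*02:01": ({"L": 1.0, "M": 0.8, "I": 0.6, "V": 0.5},
                        {"V": 1.0, "L": 0.9, "I": 0.7, "A": 0.4}),
        "HLA-A*03:01": ({"L": 1.0, "V": 0.7, "I": 0.5}, {"K": 1.0, "R": 0.8, "Y": 0.4}),
        "HLA-A*24:02": ({"Y": 1.0, "F": 0.8, "W": 0.5}, {"F": 1.0, "L": 0.7, "I": 0.5}),
        "HLA-B*07:02": ({"P": 1.0, "A": 0.5, "V": 0.3}, {"L": 1.0, "F": 0.7, "M": 0.5}),
        "HLA-B*08:01": ({"K": 1.0, "R": 0.6}, {"L": 1.0, "I": 0.6, "F": 0.4}),
        "HLA-B*44:02": ({"E": 1.0, "D": 0.6}, {"Y": 1.0, "F": 0.8, "W": 0.4}),
        "HLA-C*04:01": ({"Y": 1.0, "F": 0.7, "P": 0.4}, {"L": 1.0, "F": 0.7, "M": 0.4}),
        "HLA-C*07:02": ({"Y": 1.0, "R": 0.6, "K": 0.4}, {"Y": 1.0, "L": 0.7, "F": 0.5}),
    }

    def supported_alleles(self) -> List[HLAAllele]:
        return [HLAAllele(name) for name in sorted(self.ANCHOR_TABLE)]

    def anchor_score(self, peptide: str, allele: HLAAllele) -> float:
        try:
            p2_weights, ct_weights = self.ANCHOR_TABLE[allele.name]
        except KeyError:
            raise UnsupportedAlleleError(
                f"allele {allele.name} not supported by the built-in "
                f"predictor; supported: {sorted(self.ANCHOR_TABLE)}"
            ) from None
        return (p2_weights.get(peptide[1], 0.0) + ct_weights.get(peptide[-1], 0.0)) / 2.0

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[HLAAllele]
    ) -> List[BindingPrediction]:
        _check_peptides(peptides)
        predictions = []
        for peptide in peptides:
            for allele in alleles:
                score = self.anchor_score(peptide, allele)
                affinity = self.MAX_NM ** (1.0 - score)
                predictions.append(BindingPrediction(peptide, allele, affinity))
        return predictions


class TableMHCPredictor:
    """Predictor answering from a pre-computed (peptide, allele) table."""

    def __init__(self, table: Dict[Tuple[str, str], float]):
        self._table = dict(table)

    def supported_alleles(self) -> List[HLAAllele]:
        return [HLAAllele(a) for a in sorted({a for _, a in self._table})]

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[HLAAllele]
    ) -> List[BindingPrediction]:
        _check_peptides(peptides)
        predictions = []
        for peptide in peptides:
            for allele in alleles:
                key = (peptide, allele.name)
                if key not in self._table:
                    raise PredictionError(
                        f"no affinity for pair peptide={peptide!r}, "
                        f"allele={allele.name!r} in the loaded table"
                    )
                predictions.append(
                    BindingPrediction(peptide, allele, self._table[key])
                )
        return predictions


def load_affinity_table(path) -> TableMHCPredictor:
    """Load a TSV with columns ``peptide``, ``allele``, ``affinity_nM``."""
    df = pd.read_csv(path, sep="\t")
    required = {"peptide", "allele", "affinity_nM"}
    if not required <= set(df.columns):
        raise ValueError(
            f"affinity table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    table: Dict[Tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        allele = normalize_allele_name(str(row.allele)).name
        key = (str(row.peptide), allele)
        value = float(row.affinity_nM)
        if key in table and table[key] != value:
            raise ValueError(
                f"conflicting duplicate rows for peptide={key[0]!r}, "
                f"allele={key[1]!r}: {table[key]} vs {value}"
            )
        table[key] = value
    return TableMHCPredictor(table)


class NetMHCpanPredictor:  # pragma: no cover - optional external adapter
    """Adapter for a locally installed ``netMHCpan`` executable.

    Never exercised by tests; available only when the binary is on PATH.
    """

    def __init__(self, executable: str = "netMHCpan"):
        resolved = shutil.which(executable)
        if resolved is None:
            raise RuntimeError(
                f"{executable} not found on PATH; use the built-in predictor "
                "or an affinity table instead"
            )
        self.executable = resolved

    def predict(self, peptides, alleles):
        import subprocess
        import tempfile

        predictions = []
        with tempfile.NamedTemporaryFile("w", suffix=".pep", delete=False) as fh:
            fh.write("\n".join(peptides) + "\n")
            pep_path = fh.name
        for allele in alleles:
            out = subprocess.run(
                [self.executable, "-p", pep_path, "-a",
                 allele.name.replace("*", "")],
                capture_output=True, text=True, check=True,
            ).stdout
            for line in out.splitlines():
                fields = line.split()
                if len(fields) > 15 and fields[0].isdigit():
                    predictions.append(
                        BindingPrediction(fields[2], allele, float(fields[15]))
                    )
        return predictions


def normalize_affinity(
    affinity_nM: float,
    midpoint_nM: float = DEFAULT_MIDPOINT_NM,
    slope: float = DEFAULT_SLOPE,
) -> float:
    """Logistic normalization of an IC50 affinity onto [0, 1].

    ``score = 1 / (1 + exp(slope * (ln(affinity) - ln(midpoint))))`` --
    strictly decreasing in affinity, exactly 0.5 at the midpoint, and
    symmetric about the midpoint on the log scale.
    """
    if affinity_nM <= 0:
        raise ValueError(f"affinity must be positive, got {affinity_nM}")
    if midpoint_nM <= 0 or slope <= 0:
        raise ValueError("midpoint and slope must be positive")
    return 1.0 / (1.0 + math.exp(slope * (math.log(affinity_nM) - math.log(midpoint_nM))))


def make_predictor(name: str = "toy", affinity_table=None):
    """Factory for the configured predictor backend."""
    if name == "toy":
        return ToyMHCPredictor()
    if name == "table":
        if affinity_table is None:
            raise ValueError("predictor 'table' requires an affinity table path")
        return load_affinity_table(affinity_table)
    if name == "netmhcpan":
        return NetMHCpanPredictor()
    raise ValueError(f"unknown predictor {name!r}; choose toy, table or netmhcpan")
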