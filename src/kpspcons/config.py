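"""Tunable thresholds for the conservation criteria and the aligners.

Defaults reproduce the published screen: a site is conserved when its best
15-mer hit shows fewer than seven differences, fewer than five of them
non-conservative, the hit position lies strictly within the query position
plus/minus 20% of the query-protein length, and the aligned residue is
phosphorylatable (or matches the query residue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds for the four site-conservation criteria.

    ``max_differences`` / ``max_nonconservative`` are inclusive maxima
    ("fewer than seven" == at most 6, "fewer than five" == at most 4).
    ``position_window`` is the fraction of query-protein length bounding the
    allowed positional drift, kept as an exact rational so the strict
    inequalities are evaluated without floating-point error.
    """

    max_differences: int = 6
    max_nonconservative: int = 4
    position_window: Fraction = Fraction(1, 5)
    conservative_threshold: int = 0  # BLOSUM62 score > threshold => conservative


@dataclass(frozen=True)
class AlignerConfig:
    """Smith–Waterman parameters for whole-protein (RBH) alignment."""

    gap_open: int = 11
    gap_extend: int = 1
    matrix_name: str = "BLOSUM62"


@dataclass(frozen=True)
class PipelineConfig:
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    check_residue_consistency: bool = True
    percent_decimals: int = 1


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file (missing keys keep defaults)."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    crit = data.get("criteria", {})
    alig = data.get("aligner", {})
    criteria = CriteriaConfig(
        max_differences=int(crit.get("max_differences", 6)),
        max_nonconservative=int(crit.get("max_nonconservative", 4)),
        position_window=Fraction(str(crit.get("position_window", "1/5"))),
        conservative_threshold=int(crit.get("conservative_threshold", 0)),
    )
    aligner = AlignerConfig(
        gap_open=int(alig.get("gap_open", 11)),
        gap_extend=int(alig.get("gap_extend", 1)),
        matrix_name=str(alig.get("matrix_name", "BLOSUM62")),
    )
    return PipelineConfig(
        criteria=criteria,
        aligner=aligner,
        check_residue_consistency=bool(data.get("check_residue_consistency", True)),
        percent_decimals=int(data.get("percent_decimals", 1)),
    )
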