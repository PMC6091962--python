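"""The four phosphosite-conservation criteria.

A site is conserved in a target organism iff its best peptide hit satisfies
all of:

1. fewer than seven sequence differences (``n_differences <= 6``);
2. fewer than five of those differences non-conservative
   (``n_nonconservative <= 4``);
3. the hit position P_H lies strictly inside ``P_Q - 0.2*L_Q < P_H <
   P_Q + 0.2*L_Q`` (P_Q: query-site position, L_Q: query-protein length);
4. the aligned residue is one of the canonical phosphoacceptors S/T/Y or
   matches the query residue (so e.g. a histidine site aligned to His counts).

With no hit at all, every flag is false.  The position window is evaluated in
exact rational arithmetic so the strict bounds are bit-exact (with the default
factor 1/5 this is the integer comparison ``5*P_Q - L_Q < 5*P_H < 5*P_Q + L_Q``).

Note criterion 4 as stated lets a phospho-Tyr query count as conserved when
aligned to Ser — a kinase-class switch; downstream output keeps the aligned
residue so users can filter such calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .config import CriteriaConfig
from .peptides import CenteredPeptide, PeptideHit

CANONICAL_PHOSPHOACCEPTORS = frozenset("STY")


@dataclass(frozen=True)
class ConservationDecision:
    """Per-criterion flags for one (site, organism) evaluation."""

    passes_differences: bool
    passes_nonconservative: bool
    passes_position: bool
    passes_residue: bool

    @property
    def conserved(self) -> bool:
        return (
            self.passes_differences
            and self.passes_nonconservative
            and self.passes_position
            and self.passes_residue
        )


NO_HIT_DECISION = ConservationDecision(False, False, False, False)


def check_position_criterion(
    p_q: int, l_q: int, p_h: int, window: Fraction = Fraction(1, 5)
) -> bool:
    """Strictly ``p_q - window*l_q < p_h < p_q + window*l_q``, exact arithmetic."""
    if min(p_q, l_q, p_h) < 1:
        raise ValueError("positions and length must be >= 1")
    num, den = window.numerator, window.denominator
    # den*p_q - num*l_q < den*p_h < den*p_q + num*l_q, all integers
    return den * p_q - num * l_q < den * p_h < den * p_q + num * l_q


def check_residue_criterion(query_residue: str, hit_residue: str) -> bool:
    """Hit residue is S/T/Y, or matches the query's phosphorylated residue."""
    return hit_residue in CANONICAL_PHOSPHOACCEPTORS or hit_residue == query_residue


def evaluate_site_conservation(
    query: CenteredPeptide,
    hit: PeptideHit | None,
    config: CriteriaConfig = CriteriaConfig(),
) -> ConservationDecision:
    """Apply all four criteria to a query peptide and its best hit."""
    if hit is None:
        return NO_HIT_DECISION
    return ConservationDecision(
        passes_differences=hit.n_differences <= config.max_differences,
        passes_nonconservative=hit.n_nonconservative <= config.max_nonconservative,
        passes_position=check_position_criterion(
            query.source_position,
            query.source_protein_length,
            hit.hit_position,
            config.position_window,
        ),
        passes_residue=check_residue_criterion(query.site_residue, hit.hit_residue),
    )
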