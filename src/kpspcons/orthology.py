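"""Kinase orthology calls: reciprocal best hits, plus precomputed-table readers.

The reciprocal-best-hit (RBH) test mirrors the site search: the kinase is
aligned against every target protein (full Smith–Waterman, BLOSUM62, affine
gaps 11/1), the best target hit is aligned back against the reference, and the
kinase is called conserved iff the reverse best hit is the kinase itself.
Isoforms are treated as one protein: accessions are isoform-stripped before
the reciprocity comparison, so a forward hit ``P67890-2`` whose reverse best
is ``P12345-4`` confirms the kinase ``P12345-3``.

Readers for two external orthology resources are provided as alternatives:
a pairs table (graph-based ortholog pairs, Hieranoid-style) and a ranked
prediction table (ensemble scores, DIOPT-style).  Both yield the same shape —
a set of reference accessions with an ortholog in a given organism — so the
three methods are interchangeable downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .config import AlignerConfig
from .io import Proteome, strip_isoform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologyCall:
    """Whether a reference kinase has an ortholog in one target organism."""

    kinase_accession: str
    organism: str
    method: str  # "rbh" | "hieranoid" | "diopt"
    conserved: bool
    evidence: tuple[str, str] | None = None  # (forward best, reverse best)


class ProteinAligner:
    """Score-only Smith–Waterman wrapper (BLOSUM62, affine gaps)."""

    def __init__(self, config: AlignerConfig = AlignerConfig()):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(config.matrix_name)
        aligner.open_gap_score = -config.gap_open
        aligner.extend_gap_score = -config.gap_extend
        self._aligner = aligner

    def score(self, a: str, b: str) -> float:
        return float(self._aligner.score(a, b))


def best_protein_hit(
    query_accession: str,
    query_proteome: Proteome,
    target: Proteome,
    aligner: ProteinAligner | None = None,
) -> str | None:
    """Accession of the highest-scoring target protein for a full-length query.

    Ties break lexicographically by accession; ``None`` when the target is
    empty or no alignment scores above 0.
    """
    if query_accession not in query_proteome:
        raise KeyError(f"query {query_accession!r} not in its proteome")
    aligner = aligner or ProteinAligner()
    query_seq = query_proteome[query_accession]
    best_acc: str | None = None
    best_score = 0.0
    for acc in sorted(target.entries):
        score = aligner.score(query_seq, target[acc])
        if score > best_score:
            best_acc, best_score = acc, score
    return best_acc


def reciprocal_best_hit(
    kinase_accession: str,
    reference: Proteome,
    target: Proteome,
    aligner: ProteinAligner | None = None,
    organism: str = "",
) -> OrthologyCall:
    """RBH orthology call for one reference kinase against one target proteome."""
    if kinase_accession not in reference:
        raise KeyError(f"kinase {kinase_accession!r} not in reference proteome")
    aligner = aligner or ProteinAligner()
    organism = organism or target.organism_label
    forward = best_protein_hit(kinase_accession, reference, target, aligner)
    if forward is None:
        return OrthologyCall(kinase_accession, organism, "rbh", False, None)
    reverse = best_protein_hit(forward, target, reference, aligner)
    if reverse is None:
        return OrthologyCall(kinase_accession, organism, "rbh", False, (forward, ""))
    conserved = strip_isoform(reverse) == strip_isoform(kinase_accession)
    return OrthologyCall(kinase_accession, organism, "rbh", conserved, (forward, reverse))


def load_hieranoid_orthologs(path: str | Path, organism: str) -> set[str]:
    """Reference accessions with an ortholog pair in ``organism``.

    Expects one pair per line, whitespace-separated:
    ``<reference accession> <partner accession> <partner organism>``.
    Lines without the three fields are skipped with a warning.  Accessions
    are isoform-stripped.
    """
    out: set[str] = set()
    organism = organism.lower()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if len(fields) < 3:
                logger.warning("skipping malformed pair line %d: %r", lineno, line.strip())
                continue
            ref_acc, _partner, partner_org = fields[0], fields[1], fields[2]
            if partner_org.lower() == organism:
                out.add(strip_isoform(ref_acc))
    return out


_DIOPT_REQUIRED = {"human_accession", "target_organism", "rank"}


def load_diopt_orthologs(path: str | Path, organism: str) -> set[str]:
    """Reference accessions whose prediction rank is "high" for ``organism``.

    Tab-separated with a header naming at least ``human_accession``,
    ``target_organism`` and ``rank`` (case-insensitive).  A kinase counts as
    having an ortholog if any of its rows for the organism has rank "high";
    an organism absent from the table yields an empty set.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"empty table {path}")
        colmap = {name.lower().strip(): name for name in reader.fieldnames}
        missing = _DIOPT_REQUIRED - set(colmap)
        if missing:
            raise ValueError(f"missing required column(s) {sorted(missing)} in {path}")
        out: set[str] = set()
        organism = organism.lower()
        for row in reader:
            if (row[colmap["target_organism"]] or "").strip().lower() != organism:
                continue
            if (row[colmap["rank"]] or "").strip().lower() == "high":
                out.add(strip_isoform(row[colmap["human_accession"]].strip()))
    return out
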