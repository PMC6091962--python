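"""Orchestration: KPSP database filtering, per-organism classification,
summaries, and validation against experimentally known sites.

A KPSP (kinase–phosphorylation-site pairing) is one kinase paired with one
substrate phosphosite.  For each KPSP and each target organism the screen
evaluates site conservation (15-mer homology + four criteria) and kinase
conservation (RBH or a precomputed orthology set) and assigns one of four
categories: both conserved, site only, kinase only, or neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .config import CriteriaConfig, PipelineConfig
from .criteria import ConservationDecision, NO_HIT_DECISION, evaluate_site_conservation
from .formatting import format_proportion, truncate_percent
from .io import KinaseSubstrateRecord, Proteome, strip_isoform
from .orthology import OrthologyCall, ProteinAligner, reciprocal_best_hit
from .peptides import (
    CenteredPeptide,
    PeptideHit,
    SubstitutionClassifier,
    best_peptide_hit,
    extract_site_peptide,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhosphoSite:
    accession: str
    position: int
    residue: str


@dataclass(frozen=True)
class KPSP:
    """One kinase paired with one substrate phosphosite."""

    kinase_accession: str
    site: PhosphoSite

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.kinase_accession, self.site.accession, self.site.position)


class Category(str, Enum):
    BOTH_CONSERVED = "both_conserved"
    SITE_ONLY = "site_only"
    KINASE_ONLY = "kinase_only"
    NEITHER = "neither"


def classify_kpsp(site_conserved: bool, kinase_conserved: bool) -> Category:
    """Map the two conservation booleans onto the four categories."""
    if site_conserved:
        return Category.BOTH_CONSERVED if kinase_conserved else Category.SITE_ONLY
    return Category.KINASE_ONLY if kinase_conserved else Category.NEITHER


@dataclass(frozen=True)
class ConservationCall:
    """Per-(KPSP, organism) verdict."""

    kpsp: KPSP
    organism: str
    site_decision: ConservationDecision
    kinase_call: OrthologyCall
    hit: PeptideHit | None = None

    @property
    def category(self) -> Category:
        return classify_kpsp(self.site_decision.conserved, self.kinase_call.conserved)


CATEGORY_ORDER = (
    Category.BOTH_CONSERVED,
    Category.SITE_ONLY,
    Category.KINASE_ONLY,
    Category.NEITHER,
)


@dataclass
class OrganismSummary:
    organism: str
    counts: dict[Category, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, category: Category) -> float:
        return 100.0 * self.counts[category] / self.total

    def formatted_percentage(self, category: Category, decimals: int = 1) -> str:
        return truncate_percent(self.counts[category], self.total, decimals)


def filter_kpsp_database(
    records: list[KinaseSubstrateRecord],
    reference: Proteome,
    check_residue_consistency: bool = True,
) -> list[KPSP]:
    """Apply the database filters, in input order.

    Drops exact duplicates; keeps only the first kinase listed per
    (substrate, position) site; drops KPSPs whose kinase or substrate
    accession (isoform-stripped) is missing from the reference proteome; and
    (optionally, default on) drops sites whose stated residue disagrees with
    the reference sequence at the stated position.  All removals are logged.
    """
    known = reference.accessions_stripped()
    stripped_lookup = {strip_isoform(a): a for a in sorted(reference.entries)}
    seen_exact: set[tuple[str, str, int, str]] = set()
    seen_sites: set[tuple[str, int]] = set()
    out: list[KPSP] = []
    for rec in records:
        exact = (
            rec.kinase_accession,
            rec.substrate_accession,
            rec.site_position,
            rec.site_residue,
        )
        if exact in seen_exact:
            logger.info("dropping duplicate KPSP %s", exact)
            continue
        seen_exact.add(exact)
        site_key = (strip_isoform(rec.substrate_accession), rec.site_position)
        if site_key in seen_sites:
            logger.info("dropping extra kinase %s for site %s", rec.kinase_accession, site_key)
            continue
        kin = strip_isoform(rec.kinase_accession)
        sub = strip_isoform(rec.substrate_accession)
        if kin not in known or sub not in known:
            logger.info("dropping KPSP %s: accession absent from reference", exact)
            continue
        seq = reference[stripped_lookup[sub]]
        if not 1 <= rec.site_position <= len(seq):
            logger.info("dropping KPSP %s: position beyond protein length", exact)
            continue
        if check_residue_consistency and seq[rec.site_position - 1] != rec.site_residue:
            logger.info(
                "dropping KPSP %s: reference residue %s disagrees with stated %s",
                exact, seq[rec.site_position - 1], rec.site_residue,
            )
            continue
        seen_sites.add(site_key)
        out.append(
            KPSP(
                kinase_accession=rec.kinase_accession,
                site=PhosphoSite(rec.substrate_accession, rec.site_position, rec.site_residue),
            )
        )
    return out


def _sorted_kpsps(kpsps: list[KPSP]) -> list[KPSP]:
    return sorted(kpsps, key=lambda k: k.key)


def run_conservation_screen(
    kpsps: list[KPSP],
    reference: Proteome,
    targets: dict[str, Proteome],
    orthology_method: str = "rbh",
    ortholog_sets: dict[str, set[str]] | None = None,
    criteria: CriteriaConfig = CriteriaConfig(),
    classifier: SubstitutionClassifier | None = None,
    aligner: ProteinAligner | None = None,
) -> list[ConservationCall]:
    """Classify every (KPSP, organism) pair.

    ``orthology_method`` is ``"rbh"`` (kinases aligned on the fly, memoised
    per kinase/organism) or ``"hieranoid"`` / ``"diopt"``, in which case
    ``ortholog_sets`` must map each organism to the set of isoform-stripped
    reference accessions having an ortholog there.  Processing order is
    deterministic (sorted by kinase, substrate, position) regardless of the
    input order.
    """
    classifier = classifier or SubstitutionClassifier(
        conservative_threshold=criteria.conservative_threshold
    )
    if orthology_method != "rbh":
        if ortholog_sets is None:
            raise ValueError(f"orthology method {orthology_method!r} needs ortholog_sets")
        missing = set(targets) - set(ortholog_sets)
        if missing:
            raise ValueError(f"no ortholog set for organism(s) {sorted(missing)}")
    else:
        aligner = aligner or ProteinAligner()

    stripped_lookup = {strip_isoform(a): a for a in sorted(reference.entries)}
    kinase_cache: dict[tuple[str, str], OrthologyCall] = {}
    peptide_cache: dict[tuple[str, int], CenteredPeptide] = {}
    calls: list[ConservationCall] = []

    for organism, target in sorted(targets.items()):
        for kpsp in _sorted_kpsps(kpsps):
            site = kpsp.site
            pep_key = (site.accession, site.position)
            query = peptide_cache.get(pep_key)
            if query is None:
                ref_acc = stripped_lookup[strip_isoform(site.accession)]
                query = extract_site_peptide(reference, ref_acc, site.position)
                peptide_cache[pep_key] = query
            hit = best_peptide_hit(query, target, classifier)
            decision = evaluate_site_conservation(query, hit, criteria)

            kin_key = (strip_isoform(kpsp.kinase_accession), organism)
            kin_call = kinase_cache.get(kin_key)
            if kin_call is None:
                if orthology_method == "rbh":
                    ref_kin = stripped_lookup[kin_key[0]]
                    kin_call = reciprocal_best_hit(
                        ref_kin, reference, target, aligner, organism
                    )
                else:
                    kin_call = OrthologyCall(
                        kinase_accession=kpsp.kinase_accession,
                        organism=organism,
                        method=orthology_method,
                        conserved=kin_key[0] in ortholog_sets[organism],
                    )
                kinase_cache[kin_key] = kin_call
            calls.append(ConservationCall(kpsp, organism, decision, kin_call, hit))
    return calls


def summarize_by_organism(calls: list[ConservationCall]) -> list[OrganismSummary]:
    """Per-organism category counts (and hence percentages)."""
    by_org: dict[str, dict[Category, int]] = {}
    for call in calls:
        counts = by_org.setdefault(call.organism, {c: 0 for c in CATEGORY_ORDER})
        counts[call.category] += 1
    return [OrganismSummary(org, counts) for org, counts in sorted(by_org.items())]


def n_conserved_in_all_organisms(calls: list[ConservationCall]) -> int:
    """Number of KPSPs classified both-conserved in every screened organism."""
    organisms = {c.organism for c in calls}
    ok: dict[tuple, set[str]] = {}
    for call in calls:
        if call.category is Category.BOTH_CONSERVED:
            ok.setdefault(call.kpsp.key, set()).add(call.organism)
    return sum(1 for orgs in ok.values() if orgs == organisms)


@dataclass(frozen=True)
class ValidationResult:
    """False-rejection check against experimentally known target-organism sites."""

    n_matching_known: int
    n_rejected: int

    @property
    def rejection_fraction(self) -> float | None:
        if self.n_matching_known == 0:
            return None
        return self.n_rejected / self.n_matching_known

    def formatted(self, decimals: int = 1) -> str:
        if self.n_matching_known == 0:
            return "N/A"
        return truncate_percent(self.n_rejected, self.n_matching_known, decimals) + "%"


def validate_against_known_sites(
    hits: list[tuple[CenteredPeptide, PeptideHit | None, ConservationDecision]],
    known_sites: list[PhosphoSite],
) -> ValidationResult:
    """Fraction of hits matching a known site that the criteria rejected.

    A hit matches a known site iff its (isoform-stripped accession, P_H)
    equals the known site's (isoform-stripped accession, position).
    """
    known = {(strip_isoform(s.accession), s.position) for s in known_sites}
    n_matching = 0
    n_rejected = 0
    for _query, hit, decision in hits:
        if hit is None:
            continue
        if (strip_isoform(hit.hit_accession), hit.hit_position) in known:
            n_matching += 1
            if not decision.conserved:
                n_rejected += 1
    return ValidationResult(n_matching, n_rejected)


# ---------------------------------------------------------------------------
# tabular output

CALL_COLUMNS = (
    "kinase",
    "substrate",
    "position",
    "residue",
    "organism",
    "hit_accession",
    "hit_position",
    "hit_residue",
    "n_differences",
    "n_nonconservative",
    "passes_differences",
    "passes_nonconservative",
    "passes_position",
    "passes_residue",
    "site_conserved",
    "kinase_conserved",
    "category",
)


def calls_to_rows(calls: list[ConservationCall]) -> list[dict]:
    rows = []
    for c in calls:
        d = c.site_decision
        rows.append(
            {
                "kinase": c.kpsp.kinase_accession,
                "substrate": c.kpsp.site.accession,
                "position": c.kpsp.site.position,
                "residue": c.kpsp.site.residue,
                "organism": c.organism,
                "hit_accession": c.hit.hit_accession if c.hit else "",
                "hit_position": c.hit.hit_position if c.hit else "",
                "hit_residue": c.hit.hit_residue if c.hit else "",
                "n_differences": c.hit.n_differences if c.hit else "",
                "n_nonconservative": c.hit.n_nonconservative if c.hit else "",
                "passes_differences": d.passes_differences,
                "passes_nonconservative": d.passes_nonconservative,
                "passes_position": d.passes_position,
                "passes_residue": d.passes_residue,
                "site_conserved": d.conserved,
                "kinase_conserved": c.kinase_call.conserved,
                "category": c.category.value,
            }
        )
    return rows


def write_calls_tsv(calls: list[ConservationCall], path) -> None:
    """One row per (KPSP, organism) with per-criterion flags and category."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=CALL_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(calls_to_rows(calls))


def write_summary_tsv(summaries: list[OrganismSummary], path, decimals: int = 1) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(
            ["organism", "total"]
            + [c.value for c in CATEGORY_ORDER]
            + [f"{c.value}_pct" for c in CATEGORY_ORDER]
        )
        for s in summaries:
            writer.writerow(
                [s.organism, s.total]
                + [s.counts[c] for c in CATEGORY_ORDER]
                + [s.formatted_percentage(c, decimals) for c in CATEGORY_ORDER]
            )
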