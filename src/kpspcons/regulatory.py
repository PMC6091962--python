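"""Regulatory-role annotation and the category-by-regulatory-status table.

Each KPSP's phosphosite is matched against the regulatory-sites table on
(isoform-stripped substrate accession, position, residue); sites without a
matching phospho record have no known regulatory role.  The proportion table
reports, per organism and conservation category, the fraction of KPSPs whose
site has a known regulatory role — optionally restricted to sites whose role
is supported by at least two low-throughput references.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .formatting import format_proportion
from .io import RegulatorySiteRecord, strip_isoform
from .pipeline import CATEGORY_ORDER, Category, ConservationCall, KPSP

CATEGORY_LABELS = {
    Category.BOTH_CONSERVED: "Both conserved",
    Category.KINASE_ONLY: "Only kinase conserved",
    Category.SITE_ONLY: "Only phosphosite conserved",
    Category.NEITHER: "Neither conserved",
}

#: column order of the published table
TABLE_CATEGORY_ORDER = (
    Category.BOTH_CONSERVED,
    Category.KINASE_ONLY,
    Category.SITE_ONLY,
    Category.NEITHER,
)


@dataclass(frozen=True)
class RegulatoryAnnotation:
    kpsp_key: tuple[str, str, int]
    has_regulatory_role: bool
    n_low_throughput_refs: int = 0


def annotate_regulatory_role(
    kpsps: list[KPSP],
    regulatory: list[RegulatorySiteRecord],
) -> dict[tuple[str, str, int], RegulatoryAnnotation]:
    """Annotate each KPSP with its site's regulatory status.

    Matching is on (isoform-stripped accession, position, residue); only
    phospho-type regulatory records participate.  The annotation depends only
    on the site, so the same KPSP gets the same annotation in every organism.
    """
    reg_index: dict[tuple[str, int, str], int] = {}
    for rec in regulatory:
        if rec.modification_kind != "phospho":
            continue
        key = (strip_isoform(rec.substrate_accession), rec.site_position, rec.site_residue)
        # a site listed more than once keeps its largest evidence count
        reg_index[key] = max(reg_index.get(key, 0), rec.n_low_throughput_refs)
    out: dict[tuple[str, str, int], RegulatoryAnnotation] = {}
    for kpsp in kpsps:
        site = kpsp.site
        key = (strip_isoform(site.accession), site.position, site.residue)
        if key in reg_index:
            out[kpsp.key] = RegulatoryAnnotation(kpsp.key, True, reg_index[key])
        else:
            out[kpsp.key] = RegulatoryAnnotation(kpsp.key, False, 0)
    return out


def regulatory_counts(
    calls: list[ConservationCall],
    annotations: dict[tuple[str, str, int], RegulatoryAnnotation],
    min_low_throughput_refs: int = 0,
) -> dict[str, dict[Category, tuple[int, int]]]:
    """Per organism and category: (n regulatory, n total) KPSP counts."""
    out: dict[str, dict[Category, tuple[int, int]]] = {}
    for call in calls:
        per_org = out.setdefault(call.organism, {c: (0, 0) for c in CATEGORY_ORDER})
        ann = annotations.get(call.kpsp.key)
        is_reg = (
            ann is not None
            and ann.has_regulatory_role
            and ann.n_low_throughput_refs >= min_low_throughput_refs
        )
        x, y = per_org[call.category]
        per_org[call.category] = (x + (1 if is_reg else 0), y + 1)
    return out


def regulatory_proportion_table(
    calls: list[ConservationCall],
    annotations: dict[tuple[str, str, int], RegulatoryAnnotation],
    min_low_throughput_refs: int = 0,
    decimals: int = 1,
) -> pd.DataFrame:
    """The published-table layout: organisms as rows, categories as columns,
    cells formatted ``"X/Y (P%)"`` (``"0/0 (N/A)"`` for empty categories)."""
    counts = regulatory_counts(calls, annotations, min_low_throughput_refs)
    rows = {}
    for organism, per_cat in sorted(counts.items()):
        rows[organism] = {
            CATEGORY_LABELS[c]: format_proportion(*per_cat[c], decimals=decimals)
            for c in TABLE_CATEGORY_ORDER
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        [CATEGORY_LABELS[c] for c in TABLE_CATEGORY_ORDER]
    ]
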