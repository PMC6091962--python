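"""Readers and writers for proteome FASTA files and PhosphoSitePlus-style tables.

Proteomes are plain multi-record FASTA; accessions are taken from UniProt-style
``sp|ACC|NAME`` / ``tr|ACC|NAME`` headers (middle field) or, failing that, from
the first whitespace-delimited header token.  The two tab-separated table
dialects (kinase–substrate pairings and regulatory sites) may carry preamble
lines before the header; parsing starts at the first line that contains all
required column names.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 canonical residues plus X for anything else
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = CANONICAL_RESIDUES + "X"

# ambiguity / rare-residue codes collapsed onto X so substitution scoring is total
_NONCANONICAL = {"B", "Z", "U", "O", "J"}

_ISOFORM_SUFFIX = re.compile(r"-\d+$")
_RESIDUE_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")
_MOD_TOKEN = re.compile(r"^([A-Za-z])(\d+)-(\w+)$")


def strip_isoform(accession: str) -> str:
    """Remove a UniProt splice-isoform suffix (``P12345-3`` -> ``P12345``).

    Idempotent; accessions without a ``-<digits>`` suffix are returned unchanged.
    """
    if not accession:
        raise ValueError("empty accession")
    return _ISOFORM_SUFFIX.sub("", accession)


@dataclass
class Proteome:
    """A set of protein sequences keyed by accession.

    Sequences are uppercase over the 20 canonical residues plus ``X``.
    """

    entries: dict[str, str] = field(default_factory=dict)
    organism_label: str = ""

    def __post_init__(self) -> None:
        for acc, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty sequence for {acc!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __getitem__(self, accession: str) -> str:
        return self.entries[accession]

    def accessions(self) -> list[str]:
        return list(self.entries)

    def accessions_stripped(self) -> set[str]:
        """Isoform-stripped accession set, for membership tests."""
        return {strip_isoform(a) for a in self.entries}


def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def _sanitize_sequence(seq: str, accession: str) -> str:
    seq = seq.upper()
    cleaned = []
    replaced = set()
    for ch in seq:
        if ch in _NONCANONICAL:
            replaced.add(ch)
            cleaned.append("X")
        elif ch in ALPHABET:
            cleaned.append(ch)
        elif ch == "*":
            continue  # trailing stop in some downloads
        else:
            raise ValueError(f"invalid residue {ch!r} in sequence for {accession!r}")
    if replaced:
        logger.warning(
            "replaced non-canonical residue(s) %s with X in %s",
            ",".join(sorted(replaced)), accession,
        )
    return "".join(cleaned)


def read_fasta_proteome(path: str | Path, organism_label: str = "") -> Proteome:
    """Read a multi-record FASTA file into a :class:`Proteome`.

    Raises on duplicate accessions and on empty files.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(record.description or record.id)
        if accession in entries:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seq = _sanitize_sequence(str(record.seq), accession)
        if not seq:
            raise ValueError(f"empty sequence for {accession!r} in {path}")
        entries[accession] = seq
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(entries=entries, organism_label=organism_label or path.stem)


def write_fasta_proteome(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as bare-header FASTA (round-trips through the reader)."""
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in proteome.entries.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


@dataclass(frozen=True)
class KinaseSubstrateRecord:
    """One kinase–substrate row: who phosphorylates which residue of which protein."""

    kinase_accession: str
    substrate_accession: str
    site_position: int
    site_residue: str
    kinase_organism: str
    substrate_organism: str

    def __post_init__(self) -> None:
        if self.site_position < 1:
            raise ValueError("site_position must be >= 1")
        if not (len(self.site_residue) == 1 and self.site_residue.isupper()):
            raise ValueError("site_residue must be a single uppercase letter")


@dataclass(frozen=True)
class RegulatorySiteRecord:
    """A modified residue with literature evidence for a regulatory role."""

    substrate_accession: str
    site_position: int
    site_residue: str
    modification_kind: str  # "phospho" or "other"
    n_low_throughput_refs: int = 0

    def __post_init__(self) -> None:
        if self.n_low_throughput_refs < 0:
            raise ValueError("n_low_throughput_refs must be >= 0")


def _find_header(lines: list[str], required: Iterable[str]) -> int:
    """Index of the first line containing every required column name."""
    required = list(required)
    for i, line in enumerate(lines):
        if all(name in line for name in required):
            return i
    raise ValueError(f"no header line with columns {required} found")


def _read_table(path: str | Path, required: Iterable[str]) -> Iterator[dict[str, str]]:
    with open(path, newline="") as handle:
        lines = handle.read().splitlines()
    start = _find_header(lines, required)
    reader = csv.DictReader(lines[start:], delimiter="\t")
    missing = set(required) - set(reader.fieldnames or ())
    if missing:
        raise ValueError(f"missing required column(s) {sorted(missing)} in {path}")
    yield from reader


_KS_REQUIRED = ("KIN_ACC_ID", "SUB_ACC_ID", "SUB_MOD_RSD", "KIN_ORGANISM", "SUB_ORGANISM")


def parse_kinase_substrate_table(
    path: str | Path,
    substrate_organism_filter: str | None = "human",
    kinase_organism_filter: str | None = "human",
) -> list[KinaseSubstrateRecord]:
    """Parse a kinase–substrate table in the PhosphoSitePlus tab-separated dialect.

    Modified-residue tokens like ``S473`` split into residue ``S`` / position 473;
    unparseable tokens drop the row with a warning.  Organism filtering is
    case-insensitive exact match; pass ``None`` to keep all rows for a field.
    """
    records: list[KinaseSubstrateRecord] = []
    sub_f = substrate_organism_filter.lower() if substrate_organism_filter else None
    kin_f = kinase_organism_filter.lower() if kinase_organism_filter else None
    for row in _read_table(path, _KS_REQUIRED):
        kin_org = (row["KIN_ORGANISM"] or "").strip()
        sub_org = (row["SUB_ORGANISM"] or "").strip()
        if kin_f is not None and kin_org.lower() != kin_f:
            continue
        if sub_f is not None and sub_org.lower() != sub_f:
            continue
        token = (row["SUB_MOD_RSD"] or "").strip()
        m = _RESIDUE_TOKEN.match(token)
        if not m:
            logger.warning("unparseable modified-residue token %r; row skipped", token)
            continue
        records.append(
            KinaseSubstrateRecord(
                kinase_accession=row["KIN_ACC_ID"].strip(),
                substrate_accession=row["SUB_ACC_ID"].strip(),
                site_position=int(m.group(2)),
                site_residue=m.group(1).upper(),
                kinase_organism=kin_org,
                substrate_organism=sub_org,
            )
        )
    return records


_REG_REQUIRED = ("ACC_ID", "MOD_RSD", "LT_LIT")


def _count_refs(field_value: str) -> int:
    value = (field_value or "").strip()
    if not value:
        return 0
    if value.isdigit():
        return int(value)
    return sum(1 for part in re.split(r"[;,]", value) if part.strip())


def parse_regulatory_sites(path: str | Path) -> list[RegulatorySiteRecord]:
    """Parse a regulatory-sites table; only phosphorylation rows are kept.

    Modified-residue tokens carry a modification suffix (``S473-p``); rows
    whose suffix is not ``p`` (e.g. ``K63-ub``) or that lack a suffix are
    excluded with a warning.  The low-throughput literature column may hold
    either an integer count or a delimiter-separated reference list.
    """
    records: list[RegulatorySiteRecord] = []
    for row in _read_table(path, _REG_REQUIRED):
        token = (row["MOD_RSD"] or "").strip()
        m = _MOD_TOKEN.match(token)
        if not m:
            logger.warning("modified-residue token %r lacks a modification suffix; excluded", token)
            continue
        if m.group(3).lower() != "p":
            continue
        records.append(
            RegulatorySiteRecord(
                substrate_accession=row["ACC_ID"].strip(),
                site_position=int(m.group(2)),
                site_residue=m.group(1).upper(),
                modification_kind="phospho",
                n_low_throughput_refs=_count_refs(row.get("LT_LIT", "")),
            )
        )
    return records
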