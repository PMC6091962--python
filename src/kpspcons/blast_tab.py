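"""Adapter for external BLAST tabular output (outfmt-6-style columns).

For full-proteome runs the built-in aligners can be replaced by an external
short-peptide BLAST: this module reads the 12-column tabular format
(qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart,
send, evalue, bitscore) and reduces it to best hits per query.  Differences
are taken as mismatches + gap openings (gap columns count as differences,
the closest analogue of the column-wise counter used by the built-in engine).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .io import strip_isoform

COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class BlastRow:
    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    @property
    def n_differences(self) -> int:
        return self.mismatch + self.gapopen


def parse_blast_tabular(path: str | Path) -> list[BlastRow]:
    rows: list[BlastRow] = []
    with open(path, newline="") as handle:
        for fields in csv.reader(handle, delimiter="\t"):
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < len(COLUMNS):
                raise ValueError(f"expected {len(COLUMNS)} columns, got {len(fields)}")
            rows.append(
                BlastRow(
                    qseqid=fields[0],
                    sseqid=fields[1],
                    pident=float(fields[2]),
                    length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return rows


def best_hits(rows: list[BlastRow]) -> dict[str, BlastRow]:
    """Best row per query by bitscore; ties by fewer differences, then
    lexicographically smallest subject id."""
    out: dict[str, BlastRow] = {}
    for row in rows:
        cur = out.get(row.qseqid)
        if cur is None:
            out[row.qseqid] = row
            continue
        key = (row.bitscore, -row.n_differences, _neg_str(row.sseqid))
        cur_key = (cur.bitscore, -cur.n_differences, _neg_str(cur.sseqid))
        if key > cur_key:
            out[row.qseqid] = row
    return out


class _neg_str(str):
    """Inverts string ordering so 'smaller accession wins' fits a max-key."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def rbh_conserved_from_tables(
    forward_path: str | Path, reverse_path: str | Path
) -> set[str]:
    """Reference accessions confirmed by reciprocal best hits across two
    external BLAST runs (reference->target and target->reference).

    Isoform suffixes are stripped on both ends before the reciprocity test.
    """
    forward = best_hits(parse_blast_tabular(forward_path))
    reverse = best_hits(parse_blast_tabular(reverse_path))
    conserved: set[str] = set()
    for query, fwd in forward.items():
        rev = reverse.get(fwd.sseqid)
        if rev is not None and strip_isoform(rev.sseqid) == strip_isoform(query):
            conserved.add(strip_isoform(query))
    return conserved
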