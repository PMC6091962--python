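"""15-mer phosphosite peptides and their best matches in a target proteome.

Known phosphosites are represented as short peptides with the phosphorylated
residue at the centre (seven flanking residues each side, truncated at protein
termini).  Each peptide is searched against every same-length window of every
target protein with ungapped BLOSUM62 scoring — exhaustive and deterministic,
so results do not depend on heuristics or input order.  Substitutions are
classified conservative when their BLOSUM62 score exceeds a threshold
(default 0) and non-conservative otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numpy.lib.stride_tricks import sliding_window_view

from .io import ALPHABET, Proteome

#: default half-window: 7 residues either side of the phosphosite
FLANK = 7

_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein string as uint8 indices into :data:`ALPHABET`."""
    try:
        return np.array([_INDEX[ch] for ch in seq], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - io sanitizes first
        raise ValueError(f"residue {exc.args[0]!r} outside alphabet") from None


@lru_cache(maxsize=None)
def _blosum(name: str = "BLOSUM62") -> np.ndarray:
    """Substitution matrix restricted to the package alphabet, as int array."""
    mat = substitution_matrices.load(name)
    n = len(ALPHABET)
    out = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(mat[a][b])
    return out


class SubstitutionClass(str, Enum):
    IDENTICAL = "identical"
    CONSERVATIVE = "conservative"
    NONCONSERVATIVE = "nonconservative"


class SubstitutionClassifier:
    """Classifies residue substitutions from a symmetric substitution matrix.

    A differing pair is conservative iff its matrix score is strictly greater
    than ``conservative_threshold``.
    """

    def __init__(self, matrix_name: str = "BLOSUM62", conservative_threshold: int = 0):
        self.matrix_name = matrix_name
        self.conservative_threshold = conservative_threshold
        self.matrix = _blosum(matrix_name)
        eye = np.eye(len(ALPHABET), dtype=bool)
        self.is_difference = ~eye
        self.is_nonconservative = (~eye) & (self.matrix <= conservative_threshold)

    def classify(self, a: str, b: str) -> SubstitutionClass:
        if a not in _INDEX or b not in _INDEX:
            raise ValueError(f"residue outside alphabet: {a!r}/{b!r}")
        if a == b:
            return SubstitutionClass.IDENTICAL
        if self.matrix[_INDEX[a], _INDEX[b]] > self.conservative_threshold:
            return SubstitutionClass.CONSERVATIVE
        return SubstitutionClass.NONCONSERVATIVE

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_INDEX[a], _INDEX[b]])


DEFAULT_CLASSIFIER = SubstitutionClassifier()


def classify_substitution(
    a: str, b: str, classifier: SubstitutionClassifier = DEFAULT_CLASSIFIER
) -> SubstitutionClass:
    """Classify a residue pair as identical / conservative / non-conservative."""
    return classifier.classify(a, b)


@dataclass(frozen=True)
class CenteredPeptide:
    """A phosphosite-centred query peptide.

    ``source_position`` is the 1-based phosphosite position in the query
    protein (P_Q); ``source_protein_length`` is the full query-protein length
    (L_Q).  ``center_offset`` records terminal truncation: it is the 0-based
    index of the phosphosite within ``sequence``.
    """

    sequence: str
    center_offset: int
    source_accession: str
    source_position: int
    source_protein_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.center_offset < len(self.sequence):
            raise ValueError("center_offset out of range")
        if len(self.sequence) > 2 * FLANK + 1:
            raise ValueError("peptide longer than the 15-mer window")

    @property
    def site_residue(self) -> str:
        return self.sequence[self.center_offset]


@dataclass(frozen=True)
class PeptideHit:
    """Best match of a query peptide in a target proteome.

    ``hit_position`` (P_H) is the 1-based position in the hit protein aligned
    to the query centre; ``hit_window_start`` is the 1-based position of the
    first aligned residue, so ``hit_position = hit_window_start + center_offset``.
    """

    hit_accession: str
    hit_window_start: int
    hit_position: int
    hit_residue: str
    n_differences: int
    n_nonconservative: int
    alignment_score: int

    def __post_init__(self) -> None:
        if self.n_nonconservative > self.n_differences:
            raise ValueError("n_nonconservative cannot exceed n_differences")


def extract_site_peptide(
    proteome: Proteome, accession: str, position: int, flank: int = FLANK
) -> CenteredPeptide:
    """Extract the site-centred peptide for ``(accession, position)``.

    The window spans positions ``position - flank .. position + flank``
    (1-based, inclusive), truncated at the protein termini without padding.
    """
    if accession not in proteome:
        raise KeyError(f"accession {accession!r} not in proteome")
    seq = proteome[accession]
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} out of range 1..{len(seq)} for {accession!r}"
        )
    start = max(1, position - flank)
    end = min(len(seq), position + flank)
    return CenteredPeptide(
        sequence=seq[start - 1 : end],
        center_offset=position - start,
        source_accession=accession,
        source_position=position,
        source_protein_length=len(seq),
    )


def count_differences(
    query: CenteredPeptide | str,
    hit_window: str,
    classifier: SubstitutionClassifier = DEFAULT_CLASSIFIER,
) -> tuple[int, int, int]:
    """Column-wise comparison of a query peptide against an equal-length window.

    Returns ``(n_differences, n_nonconservative, alignment_score)``.
    """
    qseq = query.sequence if isinstance(query, CenteredPeptide) else query
    if len(qseq) != len(hit_window):
        raise ValueError(
            f"window length {len(hit_window)} != query length {len(qseq)}"
        )
    q = encode_sequence(qseq)
    h = encode_sequence(hit_window)
    n_diff = int(classifier.is_difference[q, h].sum())
    n_noncons = int(classifier.is_nonconservative[q, h].sum())
    score = int(classifier.matrix[q, h].sum())
    return n_diff, n_noncons, score


def _encoded_entries(target: Proteome) -> list[tuple[str, np.ndarray]]:
    """Proteome entries encoded once, in sorted-accession order (cached)."""
    cache = getattr(target, "_encoded_cache", None)
    if cache is None:
        cache = [(acc, encode_sequence(target[acc])) for acc in sorted(target.entries)]
        target._encoded_cache = cache  # type: ignore[attr-defined]
    return cache


def best_peptide_hit(
    query: CenteredPeptide,
    target: Proteome,
    classifier: SubstitutionClassifier = DEFAULT_CLASSIFIER,
) -> PeptideHit | None:
    """Exhaustively scan every same-length window of every target protein.

    Returns the window maximising the ungapped substitution score; ties break
    by fewer differences, then lexicographically smallest accession, then
    smallest window start.  ``None`` only when no target protein is long
    enough to host a window.
    """
    w = len(query.sequence)
    q = encode_sequence(query.sequence)
    score_rows = classifier.matrix[q]          # (w, alphabet)
    diff_rows = classifier.is_difference[q]
    noncons_rows = classifier.is_nonconservative[q]
    cols = np.arange(w)

    best: tuple[int, int, str, int] | None = None  # (score, -ndiff) maximised
    best_fields: tuple[str, int, int, int, int] | None = None

    for acc, enc in _encoded_entries(target):
        if len(enc) < w:
            continue
        windows = sliding_window_view(enc, w)               # (n, w)
        scores = score_rows[cols, windows].sum(axis=1)      # (n,)
        diffs = diff_rows[cols, windows].sum(axis=1)
        # lexicographic (max score, min diffs); diffs <= w << 64
        key = scores * 64 - diffs
        idx = int(np.argmax(key))                           # first max = smallest start
        cand = (int(scores[idx]), -int(diffs[idx]))
        if best is None or cand > (best[0], best[1]):
            noncons = int(noncons_rows[cols, windows[idx]].sum())
            best = (cand[0], cand[1], acc, idx)
            best_fields = (acc, idx + 1, int(diffs[idx]), noncons, int(scores[idx]))

    if best_fields is None:
        return None
    acc, start, n_diff, n_noncons, score = best_fields
    pos = start + query.center_offset
    return PeptideHit(
        hit_accession=acc,
        hit_window_start=start,
        hit_position=pos,
        hit_residue=target[acc][pos - 1],
        n_differences=n_diff,
        n_nonconservative=n_noncons,
        alignment_score=score,
    )
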