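import numpy as np
import pytest
from Bio.Align import substitution_matrices

from kpspcons import Proteome
from kpspcons.synthetic import OrganismPlan, SyntheticStudyConfig

# independent scoring path for oracle checks: Biopython's matrix object, plain loops
_B62 = substitution_matrices.load("BLOSUM62")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def blosum62(a: str, b: str) -> int:
    return int(_B62[a][b])


def brute_force_best_hit(query_seq: str, target: Proteome):
    """Independent enumeration of every window: returns
    (accession, start_1based, n_diff, n_noncons, score) or None.

    Maximizes score, then fewest differences, then smallest accession, then
    smallest start — all via explicit Python loops and Biopython's matrix.
    """
    w = len(query_seq)
    best = None
    for acc in sorted(target.entries):
        seq = target[acc]
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            score = n_diff = n_noncons = 0
            for a, b in zip(query_seq, window):
                s = blosum62(a, b)
                score += s
                if a != b:
                    n_diff += 1
                    if s <= 0:
                        n_noncons += 1
            cand = (score, -n_diff)
            if best is None or cand > (best[0], -best[2]):
                best = (score, acc, n_diff, n_noncons, start + 1)
    if best is None:
        return None
    score, acc, n_diff, n_noncons, start = best
    return acc, start, n_diff, n_noncons, score


def random_proteome(rng: np.random.Generator, n_proteins: int, max_len: int,
                    min_len: int = 15, label: str = "random") -> Proteome:
    entries = {}
    for i in range(n_proteins):
        length = int(rng.integers(min_len, max_len + 1))
        entries[f"P{i:03d}"] = "".join(
            AA20[j] for j in rng.integers(0, 20, size=length)
        )
    return Proteome(entries=entries, organism_label=label)


@pytest.fixture
def ref_proteome() -> Proteome:
    return Proteome(
        entries={
            "P00001": "MKVLASDPTGYQRNEWHHCF" * 3,
            "P00002": "AAAGGGSSSTTTYYYWWWCC" * 3,
            "Q00003": "MNPQRSTVWYACDEFGHIKL" * 3,
        },
        organism_label="reference",
    )


@pytest.fixture
def small_study_config() -> SyntheticStudyConfig:
    """A miniature two-organism study that still spans all four categories."""
    return SyntheticStudyConfig(
        n_substrate_proteins=8,
        n_kinases=2,
        n_decoys=3,
        protein_length_range=(60, 90),
        n_kpsps=8,
        organisms=(
            OrganismPlan("orga", 0.5, 0.25, 0.0, 0.25),
            OrganismPlan("orgb", 0.25, 0.25, 0.25, 0.25, background_substitution_rate=0.05),
        ),
        seed=7,
    )
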