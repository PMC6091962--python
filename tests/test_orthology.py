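import numpy as np
import pytest

from kpspcons import (
    Proteome,
    ProteinAligner,
    best_protein_hit,
    load_diopt_orthologs,
    load_hieranoid_orthologs,
    reciprocal_best_hit,
)

from conftest import random_proteome


@pytest.fixture(scope="module")
def aligner():
    return ProteinAligner()


def mutate(seq: str, n: int, rng) -> str:
    out = list(seq)
    for i in rng.choice(len(seq), n, replace=False):
        choices = [c for c in "ACDEFGHIKLMNPQRSTVWY" if c != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


class TestBestProteinHit:
    def test_exact_copy_wins(self, aligner):
        rng = np.random.default_rng(0)
        ref = random_proteome(rng, 1, 80, min_len=80, label="ref")
        query_acc = ref.accessions()[0]
        target = random_proteome(rng, 2, 60, min_len=50, label="t")
        target.entries["COPY"] = ref[query_acc]
        assert best_protein_hit(query_acc, ref, target, aligner) == "COPY"

    def test_planted_ortholog_beats_decoy(self, aligner):
        rng = np.random.default_rng(1)
        ref = random_proteome(rng, 1, 100, min_len=100)
        query_acc = ref.accessions()[0]
        ortholog = mutate(ref[query_acc], 3, rng)
        decoy = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 100))
        target = Proteome(entries={"ORTH": ortholog, "DEC": decoy})
        # independent check: the planted ortholog really scores higher
        assert aligner.score(ref[query_acc], ortholog) > aligner.score(ref[query_acc], decoy)
        assert best_protein_hit(query_acc, ref, target, aligner) == "ORTH"

    def test_nothing_scores_above_zero_returns_none(self, aligner):
        # no residue of the query scores positively against G, so the only
        # target window never exceeds the local-alignment floor of 0
        ref = Proteome(entries={"Q1": "AKLMNPQRSTVW" * 4})
        assert best_protein_hit("Q1", ref, Proteome(entries={"X": "G"}), aligner) is None

    def test_absent_query_rejected(self, aligner):
        rng = np.random.default_rng(3)
        ref = random_proteome(rng, 1, 50, min_len=50)
        with pytest.raises(KeyError):
            best_protein_hit("NOPE", ref, ref, aligner)


class TestReciprocalBestHit:
    def test_isoform_suffixes_do_not_block_reciprocity(self, aligner):
        rng = np.random.default_rng(4)
        base = random_proteome(rng, 1, 120, min_len=120)
        seq = base[base.accessions()[0]]
        ref = Proteome(entries={"P12345-3": seq, "OTHER": mutate(seq, 60, rng)})
        target = Proteome(entries={"P67890-2": mutate(seq, 3, rng)})
        call = reciprocal_best_hit("P12345-3", ref, target, aligner)
        assert call.conserved
        assert call.evidence == ("P67890-2", "P12345-3")

    def test_no_homolog_means_not_conserved(self, aligner):
        ref = Proteome(entries={"Q1": "AKLMNPQRSTVW" * 5})
        target = Proteome(entries={"SHORT": "GG"})
        call = reciprocal_best_hit("Q1", ref, target, aligner)
        assert not call.conserved
        assert call.evidence is None

    def test_paralog_breaks_reciprocity(self, aligner):
        rng = np.random.default_rng(6)
        base = random_proteome(rng, 1, 100, min_len=100)
        seq = base[base.accessions()[0]]
        close = mutate(seq, 2, rng)   # target protein, closest to A_PRIME
        a_prime = mutate(close, 1, rng)
        # kinase A is further from the target protein than its paralog A'
        a = mutate(close, 8, rng)
        ref = Proteome(entries={"A": a, "APRIME": a_prime})
        target = Proteome(entries={"B": close})
        # independent score check of the fixture's construction
        assert aligner.score(close, a_prime) > aligner.score(close, a)
        call = reciprocal_best_hit("A", ref, target, aligner)
        assert not call.conserved
        assert call.evidence == ("B", "APRIME")

    def test_rbh_symmetry(self, aligner):
        rng = np.random.default_rng(7)
        ref = random_proteome(rng, 3, 90, min_len=70, label="ref")
        target = Proteome(
            entries={f"T{acc}": mutate(ref[acc], 4, rng) for acc in ref.accessions()},
            organism_label="t",
        )
        for acc in ref.accessions():
            fwd = reciprocal_best_hit(acc, ref, target, aligner)
            assert fwd.conserved
            back = reciprocal_best_hit(fwd.evidence[0], target, ref, aligner)
            assert back.conserved
            assert back.evidence[0] == acc

    def test_exact_copies_all_conserved(self, aligner):
        rng = np.random.default_rng(8)
        ref = random_proteome(rng, 4, 80, min_len=60)
        target = Proteome(
            entries={f"C{acc}": ref[acc] for acc in ref.accessions()}
        )
        assert all(
            reciprocal_best_hit(acc, ref, target, aligner).conserved
            for acc in ref.accessions()
        )


class TestOrthologTableReaders:
    def test_hieranoid_membership_and_filtering(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text(
            "P31749-2\tENSMUSP1\tmouse\n"
            "P31749\tYEAST1\tyeast\n"
            "Q00001\tENSMUSP2\tmouse\n"
            "malformed_line\n"
        )
        assert load_hieranoid_orthologs(p, "mouse") == {"P31749", "Q00001"}
        assert load_hieranoid_orthologs(p, "yeast") == {"P31749"}
        assert load_hieranoid_orthologs(tmp_path / "pairs.txt", "worm") == set()

    def test_hieranoid_empty_file(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("")
        assert load_hieranoid_orthologs(p, "mouse") == set()

    def test_diopt_rank_rule(self, tmp_path):
        p = tmp_path / "diopt.tsv"
        p.write_text(
            "human_accession\ttarget_organism\ttarget_accession\trank\n"
            "P31749\tmouse\tM1\thigh\n"
            "P31749\tfly\tF1\tmoderate\n"
            "Q00001\tmouse\tM2\tHigh\n"
            "Q00002\tmouse\tM3\tlow\n"
        )
        assert load_diopt_orthologs(p, "mouse") == {"P31749", "Q00001"}
        assert load_diopt_orthologs(p, "fly") == set()
        # organisms absent from the table simply have no predictions
        assert load_diopt_orthologs(p, "rhesus macaque") == set()

    def test_diopt_missing_rank_column_is_error(self, tmp_path):
        p = tmp_path / "diopt.tsv"
        p.write_text("human_accession\ttarget_organism\n P1\tmouse\n")
        with pytest.raises(ValueError):
            load_diopt_orthologs(p, "mouse")
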