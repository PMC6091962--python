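import numpy as np
import pytest

from kpspcons import (
    Proteome,
    SubstitutionClass,
    SubstitutionClassifier,
    best_peptide_hit,
    classify_substitution,
    count_differences,
    extract_site_peptide,
)
from kpspcons.synthetic import mutate_window

from conftest import brute_force_best_hit, random_proteome


class TestExtractSitePeptide:
    def test_interior_site_gives_full_15mer(self):
        prot = Proteome(entries={"A": "X" * 0 + "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLM"})  # length 31
        pep = extract_site_peptide(prot, "A", 16)
        assert len(pep.sequence) == 15
        assert pep.center_offset == 7
        assert pep.sequence == prot["A"][8:23]
        assert pep.site_residue == prot["A"][15]

    def test_near_terminus_truncates_without_padding(self):
        prot = Proteome(entries={"A": "MKVLASDPTGYQRNEW"})  # length 16
        pep = extract_site_peptide(prot, "A", 6)
        assert pep.sequence == "MKVLASDPTGYQR"
        assert pep.center_offset == 5
        assert pep.site_residue == "S"
        assert pep.source_protein_length == 16

    def test_out_of_range_position_rejected(self):
        prot = Proteome(entries={"A": "MKVLA"})
        with pytest.raises(ValueError):
            extract_site_peptide(prot, "A", 0)
        with pytest.raises(ValueError):
            extract_site_peptide(prot, "A", 6)

    def test_unknown_accession_rejected(self):
        with pytest.raises(KeyError):
            extract_site_peptide(Proteome(entries={"A": "MKVLA"}), "B", 1)


class TestSubstitutionClassification:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("S", "S", SubstitutionClass.IDENTICAL),
            ("S", "T", SubstitutionClass.CONSERVATIVE),   # BLOSUM62(S,T) = +1
            ("S", "W", SubstitutionClass.NONCONSERVATIVE),  # BLOSUM62(S,W) = -3
            ("S", "A", SubstitutionClass.CONSERVATIVE),   # BLOSUM62(S,A) = +1
        ],
    )
    def test_blosum62_boundary(self, a, b, expected):
        assert classify_substitution(a, b) == expected

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("S", "1")

    def test_symmetry(self):
        clf = SubstitutionClassifier()
        for a in "ACDEFGHIKLMNPQRSTVWYX":
            for b in "ACDEFGHIKLMNPQRSTVWYX":
                assert clf.classify(a, b) == clf.classify(b, a)


class TestCountDifferences:
    def test_identity_scores_self(self):
        clf = SubstitutionClassifier()
        n_diff, n_noncons, score = count_differences("AKSPR", "AKSPR", clf)
        assert (n_diff, n_noncons) == (0, 0)
        assert score == sum(clf.score(c, c) for c in "AKSPR")

    def test_single_conservative_column(self):
        n_diff, n_noncons, _ = count_differences("AKSPR", "AKTPR")
        assert (n_diff, n_noncons) == (1, 0)

    def test_single_nonconservative_column(self):
        n_diff, n_noncons, _ = count_differences("AKSPR", "AKWPR")
        assert (n_diff, n_noncons) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_differences("AKSPR", "AKSP")


def plant(sequence: str, payload: str, at: int) -> str:
    return sequence[:at] + payload + sequence[at + len(payload):]


class TestBestPeptideHit:
    def test_exact_copy_found_with_zero_differences(self, ref_proteome):
        query = extract_site_peptide(ref_proteome, "P00001", 11)
        rng = np.random.default_rng(0)
        target = random_proteome(rng, 3, 80, min_len=40, label="t")
        target.entries["T99"] = "G" * 10 + query.sequence + "G" * 10
        hit = best_peptide_hit(query, target)
        assert hit.hit_accession == "T99"
        assert hit.n_differences == 0
        assert hit.hit_position == 11 + query.center_offset
        assert hit.hit_residue == query.site_residue

    def test_planted_single_substitution_beats_decoys(self, ref_proteome):
        query = extract_site_peptide(ref_proteome, "P00001", 11)
        mutated = mutate_window(
            query.sequence, query.center_offset, 1, 0,
            rng=np.random.default_rng(3),
        )
        rng = np.random.default_rng(1)
        while True:  # draw decoys far from the query
            target = random_proteome(rng, 2, 60, min_len=30)
            far = all(
                count_differences(query.sequence, seq[i:i+15])[0] >= 8
                for seq in target.entries.values()
                for i in range(len(seq) - 14)
            )
            if far:
                break
        target.entries["T00"] = "A" * 5 + mutated + "A" * 5
        hit = best_peptide_hit(query, target)
        assert (hit.hit_accession, hit.n_differences, hit.n_nonconservative) == ("T00", 1, 0)
        # oracle agreement on the same instance
        assert brute_force_best_hit(query.sequence, target)[0] == "T00"

    def test_no_window_long_enough_returns_none(self, ref_proteome):
        query = extract_site_peptide(ref_proteome, "P00001", 11)
        target = Proteome(entries={"A": "MKV", "B": "STYSTY"})
        assert best_peptide_hit(query, target) is None

    def test_deterministic_under_entry_reordering(self, ref_proteome):
        query = extract_site_peptide(ref_proteome, "P00002", 30)
        rng = np.random.default_rng(5)
        target = random_proteome(rng, 6, 90, min_len=20)
        reordered = Proteome(
            entries=dict(reversed(list(target.entries.items()))),
            organism_label="r",
        )
        assert best_peptide_hit(query, target) == best_peptide_hit(query, reordered)

    def test_self_search_recovers_every_site(self, ref_proteome):
        for acc in ref_proteome.accessions():
            for pos in (1, 8, 30, len(ref_proteome[acc])):
                query = extract_site_peptide(ref_proteome, acc, pos)
                hit = best_peptide_hit(query, ref_proteome)
                assert hit.n_differences == 0

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            target = random_proteome(rng, int(rng.integers(1, 5)), 100, min_len=15)
            qlen = int(rng.integers(9, 16))
            query_seq = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=qlen)
            )
            from kpspcons import CenteredPeptide
            query = CenteredPeptide(query_seq, qlen // 2, "Q", 50, 100)
            hit = best_peptide_hit(query, target)
            oracle = brute_force_best_hit(query_seq, target)
            assert (
                hit.hit_accession, hit.hit_window_start,
                hit.n_differences, hit.n_nonconservative, hit.alignment_score,
            ) == oracle

    def test_extra_mutations_never_decrease_counts(self):
        rng = np.random.default_rng(9)
        base = "ACDEFGHIKLMNPQR"
        prev = (0, 0)
        window = base
        for k in range(1, 8):
            window = mutate_window(base, 7, max(0, k - 3), min(k, 3), rng=rng)
            n_diff, n_noncons, _ = count_differences(base, window)
            assert n_diff >= prev[0] and n_noncons >= prev[1]
            prev = (n_diff, n_noncons)
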