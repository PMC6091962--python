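import filecmp

import numpy as np
import pytest

from kpspcons import (
    count_differences,
    filter_kpsp_database,
    parse_kinase_substrate_table,
    parse_regulatory_sites,
    read_fasta_proteome,
    run_conservation_screen,
)
from kpspcons.orthology import load_diopt_orthologs, load_hieranoid_orthologs
from kpspcons.synthetic import (
    OrganismPlan,
    SyntheticStudyConfig,
    generate_synthetic_study,
    mutate_window,
    write_study,
)


class TestMutateWindow:
    WINDOW = "ACDEFGHSIKLMNPQ"

    def test_zero_mutations_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_window(self.WINDOW, 7, 0, 0, rng=rng) == self.WINDOW

    @pytest.mark.parametrize("n_cons,n_noncons", [(2, 1), (0, 6), (5, 3), (1, 0)])
    def test_counts_recovered_by_columnwise_counter(self, n_cons, n_noncons):
        rng = np.random.default_rng(42)
        mutated = mutate_window(self.WINDOW, 7, n_cons, n_noncons, rng=rng)
        n_diff, n_nc, _ = count_differences(self.WINDOW, mutated)
        assert (n_diff, n_nc) == (n_cons + n_noncons, n_noncons)
        assert mutated[7] == self.WINDOW[7]  # centre preserved

    def test_center_mutated_when_not_preserved(self):
        rng = np.random.default_rng(1)
        mutated = mutate_window("S" * 15, 7, 0, 15, preserve_center=False, rng=rng)
        n_diff, _, _ = count_differences("S" * 15, mutated)
        assert n_diff == 15

    def test_impossible_requests_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            mutate_window("A" * 15, 7, 0, 15, preserve_center=True, rng=rng)
        with pytest.raises(ValueError):
            # cysteine has no positive-scoring BLOSUM62 partner
            mutate_window("C" * 15, 7, 1, 0, preserve_center=True, rng=rng)

    def test_mild_choice_maximizes_score(self):
        rng = np.random.default_rng(3)
        mild = mutate_window("S" * 15, 7, 0, 6, rng=rng, choice="mild")
        _, _, mild_score = count_differences("S" * 15, mild)
        worst = min(
            count_differences("S" * 15, mutate_window("S" * 15, 7, 0, 6, rng=np.random.default_rng(s)))[2]
            for s in range(5)
        )
        assert mild_score >= worst


class TestStudyGeneration:
    def test_same_seed_gives_byte_identical_files(self, small_study_config, tmp_path):
        a = generate_synthetic_study(small_study_config)
        b = generate_synthetic_study(small_study_config)
        write_study(a, tmp_path / "a")
        write_study(b, tmp_path / "b")
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files and not cmp.left_only and not cmp.right_only
        sub = filecmp.dircmp(tmp_path / "a" / "targets", tmp_path / "b" / "targets")
        assert not sub.diff_files

    def test_written_files_roundtrip_through_readers(self, small_study_config, tmp_path):
        study = generate_synthetic_study(small_study_config)
        paths = write_study(study, tmp_path)
        ref = read_fasta_proteome(paths["reference"])
        assert ref.entries == study.reference.entries
        records = parse_kinase_substrate_table(paths["kinase_substrate"])
        assert records == study.ks_records
        regs = parse_regulatory_sites(paths["regulatory"])
        assert regs == study.regulatory_records
        for organism in study.targets:
            target = read_fasta_proteome(paths[f"target:{organism}"])
            assert target.entries == study.targets[organism].entries

    def test_filter_retains_exactly_the_planted_kpsps(self, small_study_config):
        study = generate_synthetic_study(small_study_config)
        kpsps = filter_kpsp_database(study.ks_records, study.reference)
        assert len(kpsps) == small_study_config.n_kpsps

    def test_fractions_realized_exactly(self, small_study_config):
        study = generate_synthetic_study(small_study_config)
        n = small_study_config.n_kpsps
        for plan in small_study_config.organisms:
            per_org = [t for t in study.truth if t.organism == plan.organism]
            counts = {
                "both_conserved": round(plan.f_both * n),
                "site_only": round(plan.f_site_only * n),
                "kinase_only": round(plan.f_kinase_only * n),
                "neither": round(plan.f_neither * n),
            }
            observed = {}
            for t in per_org:
                observed[t.category.value] = observed.get(t.category.value, 0) + 1
            for cat, expected in counts.items():
                assert observed.get(cat, 0) == expected

    def test_all_failure_modes_planted(self):
        config = SyntheticStudyConfig(seed=11)
        study = generate_synthetic_study(config)
        modes = {t.failure_mode for t in study.truth if not t.site_conserved}
        assert modes == {"differences", "nonconservative", "residue", "position", "missing"}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(
                organisms=(OrganismPlan("x", 0.5, 0.5, 0.5, 0.5),)
            ).validate()
        with pytest.raises(ValueError):
            SyntheticStudyConfig(
                n_substrate_proteins=2, n_kpsps=40, protein_length_range=(60, 60)
            ).validate()

    def test_ortholog_tables_match_kinase_truth(self, small_study_config, tmp_path):
        study = generate_synthetic_study(small_study_config)
        paths = write_study(study, tmp_path)
        for plan in small_study_config.organisms:
            expected = {
                kin for (kin, org), ok in study.kinase_truth.items()
                if org == plan.organism and ok
            }
            assert load_hieranoid_orthologs(paths["hieranoid"], plan.organism) == expected
            assert load_diopt_orthologs(paths["diopt"], plan.organism) == expected


class TestTruthRecovery:
    def test_screen_recovers_planted_truth(self, small_study_config):
        study = generate_synthetic_study(small_study_config)
        kpsps = filter_kpsp_database(study.ks_records, study.reference)
        calls = run_conservation_screen(kpsps, study.reference, study.targets)
        truth = study.truth_by_key()
        for call in calls:
            t = truth[(call.kpsp.kinase_accession, call.kpsp.site.accession,
                       call.kpsp.site.position, call.organism)]
            assert call.category == t.category
            assert call.site_decision.conserved == t.site_conserved
            assert call.kinase_call.conserved == t.kinase_conserved

    def test_single_criterion_failures_isolated(self, small_study_config):
        """Sites planted to fail one window-level criterion fail exactly that flag."""
        study = generate_synthetic_study(small_study_config)
        kpsps = filter_kpsp_database(study.ks_records, study.reference)
        calls = run_conservation_screen(kpsps, study.reference, study.targets)
        truth = study.truth_by_key()
        flag_for_mode = {
            "nonconservative": "passes_nonconservative",
            "residue": "passes_residue",
            "position": "passes_position",
        }
        checked = 0
        for call in calls:
            t = truth[(call.kpsp.kinase_accession, call.kpsp.site.accession,
                       call.kpsp.site.position, call.organism)]
            if t.failure_mode in flag_for_mode:
                d = call.site_decision
                assert getattr(d, flag_for_mode[t.failure_mode]) is False
                others = {
                    "passes_differences", "passes_nonconservative",
                    "passes_position", "passes_residue",
                } - {flag_for_mode[t.failure_mode]}
                assert all(getattr(d, f) for f in others)
                checked += 1
        assert checked > 0

    def test_memoization_transparency(self, small_study_config):
        """Kinase calls are memoized; per-call results equal an unmemoized re-run."""
        from kpspcons.orthology import reciprocal_best_hit

        study = generate_synthetic_study(small_study_config)
        kpsps = filter_kpsp_database(study.ks_records, study.reference)
        calls = run_conservation_screen(kpsps, study.reference, study.targets)
        for call in calls[:6]:
            fresh = reciprocal_best_hit(
                call.kinase_call.kinase_accession, study.reference,
                study.targets[call.organism], organism=call.organism,
            )
            assert fresh.conserved == call.kinase_call.conserved
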