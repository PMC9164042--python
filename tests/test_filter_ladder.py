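import pytest

from nsafpipe import (
    AnnotationTable,
    ContaminantList,
    LadderRules,
    OccupancyRule,
    SimulationParams,
    ValidationError,
    i_proteins,
    i_reliably,
    i_successful,
    p_placenta,
    p_total,
    q_reliably,
    run_ladder,
    simulate_study,
    summarize_counts,
)
from nsafpipe.filter_ladder import STAGES, required_count

from _oracles import oracle_ladder
from _toys import make_run, single_dataset_design, toy_study

RULES = LadderRules()


class TestPTotal:
    def test_union_over_runs(self):
        runs = [make_run("1_1_1", [("A", 100, 1), ("B", 100, 1)]),
                make_run("1_1_2", [("B", 100, 1), ("C", 100, 1)])]
        assert p_total(runs) == {"A", "B", "C"}

    def test_empty_run(self):
        assert p_total([make_run("1_1_1", [])]) == frozenset()

    def test_no_runs_rejected(self):
        with pytest.raises(ValidationError):
            p_total([])


class TestPPlacenta:
    ANN = AnnotationTable({"A": True, "B": True, "C": False, "P02768": True})

    def test_frequency_boundary_is_inclusive(self):
        cont = ContaminantList({"A": 0.67, "B": 0.66})
        kept = p_placenta(frozenset({"A", "B"}), cont, self.ANN, 0.67)
        assert kept == {"B"}  # exactly 0.67 is excluded, 0.66 retained

    def test_fixed_exclusions_removed_at_any_frequency(self):
        cont = ContaminantList({"P02768": 0.0})
        assert p_placenta(frozenset({"P02768", "A"}), cont, self.ANN, 0.67) == {"A"}

    def test_non_placenta_accessions_dropped(self):
        cont = ContaminantList({})
        assert p_placenta(frozenset({"A", "C"}), cont, self.ANN, 0.67) == {"A"}


class TestISuccessful:
    def test_two_peptides_at_99_in_one_run_qualifies(self):
        runs = [make_run("1_1_1", [("A", 100, 5)],
                         [("AAAK", {"A"}, 100.0), ("CCCK", {"A"}, 99.0)])]
        assert i_successful(runs, frozenset({"A"}), RULES) == {"A"}

    def test_one_peptide_below_99_fails_everywhere(self):
        runs = [make_run(f"1_1_{i}", [("A", 100, 5)],
                         [("AAAK", {"A"}, 100.0), ("CCCK", {"A"}, 98.9)])
                for i in (1, 2, 3)]
        assert i_successful(runs, frozenset({"A"}), RULES) == frozenset()

    def test_repeated_sequence_counts_once(self):
        runs = [make_run("1_1_1", [("A", 100, 5)],
                         [("AAAK", {"A"}, 100.0), ("AAAK", {"A"}, 100.0)])]
        assert i_successful(runs, frozenset({"A"}), RULES) == frozenset()


# toy accessions are single letters; peptide sequences must stay inside the
# 20-letter amino-acid alphabet, so map each accession to a distinct residue
_RES = dict(zip("ABCDEF", "GHILMN"))


def _two_pep_run(key, present):
    """A run where each accession in `present` has 2 low-scoring peptides."""
    prot = [(a, 100, 5) for a in present]
    peps = ([(f"AA{_RES[a]}K", {a}, 50.0) for a in present]
            + [(f"CC{_RES[a]}K", {a}, 50.0) for a in present])
    return make_run(key, prot, peps)


class TestIProteins:
    def test_two_thirds_of_three_replicates(self):
        runs = [_two_pep_run("1_1_1", ["A"]), _two_pep_run("1_1_2", ["A"]),
                make_run("1_1_3", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.TWO_THIRDS)
        assert i_proteins(runs, frozenset({"A"}), rules, 1) == {"A"}

    def test_all_rule_requires_every_replicate(self):
        runs = [_two_pep_run("1_1_1", ["A"]), make_run("1_1_2", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.ALL)
        assert i_proteins(runs, frozenset({"A"}), rules, 1) == frozenset()

    def test_one_of_three_fails_two_thirds(self):
        assert required_count(3, OccupancyRule.TWO_THIRDS) == 2
        runs = [_two_pep_run("1_1_1", ["A"]), make_run("1_1_2", []), make_run("1_1_3", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.TWO_THIRDS)
        assert i_proteins(runs, frozenset({"A"}), rules, 1) == frozenset()

    def test_adding_evidence_is_monotone(self):
        base = [_two_pep_run("1_1_1", ["A"]), make_run("1_1_2", []), make_run("1_1_3", [])]
        more = [_two_pep_run("1_1_1", ["A"]), _two_pep_run("1_1_2", ["A"]),
                make_run("1_1_3", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.TWO_THIRDS)
        before = i_proteins(base, frozenset({"A"}), rules, 1)
        after = i_proteins(more, frozenset({"A"}), rules, 1)
        assert before <= after


class TestIReliably:
    def test_two_of_three_samples_retained_under_two_thirds(self):
        runs = [_two_pep_run("1_1_1", ["A"]), _two_pep_run("1_1_2", ["A"]),
                _two_pep_run("1_2_1", ["A"]), _two_pep_run("1_2_2", ["A"]),
                make_run("1_3_1", []), make_run("1_3_2", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.ALL,
                            default_sample_rule=OccupancyRule.TWO_THIRDS)
        assert i_reliably(runs, frozenset({"A"}), rules, 1) == {"A"}

    def test_one_of_three_samples_dropped(self):
        runs = [_two_pep_run("1_1_1", ["A"]), _two_pep_run("1_1_2", ["A"]),
                make_run("1_2_1", []), make_run("1_2_2", []),
                make_run("1_3_1", []), make_run("1_3_2", [])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.ALL,
                            default_sample_rule=OccupancyRule.TWO_THIRDS)
        assert i_reliably(runs, frozenset({"A"}), rules, 1) == frozenset()

    def test_single_sample_dataset_degenerates_to_i_proteins(self):
        runs = [_two_pep_run("2_1_1", ["A", "B"]), _two_pep_run("2_1_2", ["A"]),
                _two_pep_run("2_1_3", ["A"])]
        rules = LadderRules(default_replicate_rule=OccupancyRule.TWO_THIRDS)
        surv = frozenset({"A", "B"})
        assert i_reliably(runs, surv, rules, 2) == i_proteins(runs, surv, rules, 2)


class TestQReliably:
    def test_low_cv_or_low_fc_qualifies(self):
        nsaf_by_run = {"1_1_1": {"A": 0.10}, "1_1_2": {"A": 0.12}, "1_1_3": {"A": 0.11}}
        assert q_reliably(nsaf_by_run, frozenset({"A"}), RULES) == {"A"}

    def test_high_cv_and_high_fc_fails(self):
        nsaf_by_run = {"1_1_1": {"A": 0.05}, "1_1_2": {"A": 0.20}}
        assert q_reliably(nsaf_by_run, frozenset({"A"}), RULES) == frozenset()

    def test_constant_values_qualify(self):
        nsaf_by_run = {f"1_1_{i}": {"A": 0.3} for i in (1, 2, 3)}
        assert q_reliably(nsaf_by_run, frozenset({"A"}), RULES) == {"A"}

    def test_single_observation_excluded(self):
        nsaf_by_run = {"1_1_1": {"A": 0.3}, "1_1_2": {}}
        assert q_reliably(nsaf_by_run, frozenset({"A"}), RULES) == frozenset()


class TestRunLadder:
    def _quant_study(self):
        """A, B quantified stably; C, D erratically; E fails the score
        filter; F is a contaminant."""
        counts = {"A": (1000, 1000, 1000), "B": (500, 510, 490),
                  "C": (1, 20, 40), "D": (2, 30, 60),
                  "E": (100, 100, 100), "F": (100, 100, 100)}
        runs = []
        for i in (1, 2, 3):
            prot = [(a, 100, counts[a][i - 1]) for a in counts]
            peps = []
            for a in "ABCDF":
                peps += [(f"AA{_RES[a]}K", {a}, 100.0), (f"CC{_RES[a]}K", {a}, 99.5)]
            peps += [("AAMK", {"E"}, 100.0), ("CCMK", {"E"}, 98.0)]
            runs.append(make_run(f"1_1_{i}", prot, peps))
        return toy_study(single_dataset_design(), runs,
                         contaminant_freqs={"F": 0.9})

    def test_attrition_counts_on_constructed_study(self):
        study = self._quant_study()
        ladder = run_ladder(study, LadderRules())
        counts = ladder.counts()[1]
        assert counts["P_total"] == 6
        assert counts["P_placenta"] == 5       # F removed
        assert counts["I_successful"] == 4     # E lacks 2 peptides >= 99
        assert counts["I_reliably"] == 4
        assert ladder.stage_set(1, "Q_reliably") == {"A", "B"}

    def test_matches_brute_force_oracle(self):
        study = self._quant_study()
        rules = LadderRules()
        ladder = run_ladder(study, rules)
        expected = oracle_ladder(study, rules)
        for stage in STAGES:
            assert ladder.stage_set(1, stage) == expected[1][stage]

    def test_all_contaminant_study_empties_after_p_total(self):
        runs = [make_run(f"1_1_{i}", [("A", 100, 5), ("B", 100, 5)]) for i in (1, 2, 3)]
        study = toy_study(single_dataset_design(), runs,
                          contaminant_freqs={"A": 0.9, "B": 1.0})
        ladder = run_ladder(study, LadderRules())
        assert ladder.stage_set(1, "P_total") == {"A", "B"}
        for stage in STAGES[1:]:
            assert ladder.stage_set(1, stage) == frozenset()

    def test_monotone_chain_on_synthetic_study(self, default_study):
        study, _ = default_study
        ladder = run_ladder(study, LadderRules.chorionic_villus_rules())
        for d in study.dataset_ids():
            for a, b in zip(STAGES, STAGES[1:]):
                assert ladder.stage_set(d, b) <= ladder.stage_set(d, a)


class TestSummarizeCounts:
    @pytest.mark.parametrize("values,expected", [
        ((884, 460, 298), (547, 303)),
        ((546, 449, 447), (481, 57)),
        ((120, 176, 113, 112, 154, 110), (131, 28)),
    ])
    def test_mean_sd_summaries_of_ladder_count_columns(self, values, expected):
        assert summarize_counts(values) == expected

    def test_rounding_is_half_away_from_zero(self):
        assert summarize_counts([1, 2]) == (2, 1)  # mean 1.5 -> 2, sd 0.707 -> 1

    def test_requires_two_values(self):
        with pytest.raises(ValidationError):
            summarize_counts([5])


def test_ladder_equals_oracle_on_randomized_small_studies(design):
    for seed in range(5):
        params = SimulationParams(n_proteins=30, seed=100 + seed)
        study, _ = simulate_study(design, params)
        rules = LadderRules.chorionic_villus_rules()
        ladder = run_ladder(study, rules)
        expected = oracle_ladder(study, rules)
        for d in study.dataset_ids():
            for stage in STAGES:
                assert ladder.stage_set(d, stage) == expected[d][stage], (seed, d, stage)
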