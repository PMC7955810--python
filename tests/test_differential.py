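"""Differential comparison: Welch test, three-criterion filter, summed profiles."""

import math

import numpy as np
import pytest
from scipy import stats

from hdxdyn.differential import (
    ComparisonResult,
    DifferenceRecord,
    Thresholds,
    compare_states,
    coverage_stats,
    peptide_significance,
    summed_difference,
    summed_differences,
    two_sample_test,
)
from hdxdyn.ingest import Peptide
from hdxdyn.synth import SimulationConfig, simulate_uptake


class TestWelch:
    def test_identical_samples_p_one(self):
        assert two_sample_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_zero_variance_limiting_case(self):
        p = two_sample_test([0.0, 0.0, 0.0], [10.0, 10.0, 10.0])
        assert p < 1e-10

    def test_matches_scipy_oracle(self):
        a, b = [1.0, 1.2, 0.9], [2.0, 2.1, 1.9]
        expected = stats.ttest_ind(b, a, equal_var=False).pvalue
        assert two_sample_test(a, b) == pytest.approx(expected, abs=1e-10)

    def test_single_replicate_undefined(self):
        assert math.isnan(two_sample_test([1.0], [1.0, 2.0]))

    def test_paired_variant(self):
        a, b = [1.0, 1.2, 0.9, 1.1], [1.4, 1.5, 1.4, 1.6]
        expected = stats.ttest_rel(b, a).pvalue
        assert two_sample_test(a, b, paired=True) == pytest.approx(expected, abs=1e-10)


def _record(delta_pct, delta_d, p, thr=Thresholds()):
    """Build a DifferenceRecord through the evaluation logic by synthesizing
    replicate values with the requested statistics."""
    from hdxdyn.differential import _evaluate

    passes, direction = _evaluate(delta_d, delta_pct, p, thr)
    pep = Peptide(1, 12, "A" * 12)
    return DifferenceRecord(pep, 3.0, delta_d, 0.0, delta_pct, p, passes, direction)


class TestCriteria:
    @pytest.mark.parametrize(
        "delta_pct,delta_d,p,expected_pass,expected_dir",
        [
            (6.0, 0.5, 0.005, True, "increase"),    # clears all three
            (6.0, 0.3, 0.001, False, "none"),       # mass criterion fails
            (5.0, 0.5, 0.001, False, "none"),       # strict inequality at 5%
            (6.0, 0.4, 0.001, False, "none"),       # strict inequality at 0.4 Da
            (6.0, 0.5, 0.01, False, "none"),        # strict inequality at alpha
            (-6.0, -0.5, 0.005, True, "decrease"),
        ],
    )
    def test_three_criterion_boundaries(self, delta_pct, delta_d, p, expected_pass, expected_dir):
        r = _record(delta_pct, delta_d, p)
        assert r.passes is expected_pass and r.direction == expected_dir

    def test_nan_p_never_passes(self):
        r = _record(50.0, 2.0, math.nan)
        assert not r.passes


class TestPeptideSignificance:
    def test_any_single_passing_timepoint_flags(self):
        recs = [_record(1.0, 0.1, 0.5)] * 3 + [_record(8.0, 0.6, 0.001)]
        assert peptide_significance(recs) == "increase"

    def test_none_passing(self):
        assert peptide_significance([_record(1.0, 0.1, 0.5)] * 4) == "none"

    def test_opposite_signs_mixed(self):
        recs = [_record(8.0, 0.6, 0.001), _record(-8.0, -0.6, 0.001)]
        assert peptide_significance(recs) == "mixed"


class TestSummedDifference:
    def test_quadrature_arithmetic(self):
        pep = Peptide(1, 12, "A" * 12)
        recs = [
            DifferenceRecord(pep, t, 0.5, 0.1, 5.0, 0.5, False, "none")
            for t in (3.0, 30.0, 300.0, 3000.0)
        ]
        s = summed_difference(recs)
        assert s.sum_delta_d == pytest.approx(2.0)
        assert s.sd_sum == pytest.approx(0.2)
        assert s.central_residue == pytest.approx(6.5)

    def test_zero_deltas_keep_quadrature_sd(self):
        pep = Peptide(1, 12, "A" * 12)
        recs = [DifferenceRecord(pep, t, 0.0, 0.3, 0.0, 1.0, False, "none") for t in (3.0, 30.0)]
        s = summed_difference(recs)
        assert s.sum_delta_d == 0.0
        assert s.sd_sum == pytest.approx(math.sqrt(2 * 0.09))

    def test_sd_sum_matches_monte_carlo(self):
        # generative truth for 4 timepoints, two states
        rng = np.random.default_rng(123)
        means_a = np.array([0.5, 1.0, 1.8, 2.5])
        means_b = means_a + 0.3
        sds = np.array([0.05, 0.08, 0.04, 0.06])
        pep = Peptide(1, 12, "A" * 12)
        recs = [
            DifferenceRecord(pep, t, float(means_b[i] - means_a[i]),
                             float(np.sqrt(2) * sds[i]), 0.0, 1.0, False, "none")
            for i, t in enumerate((3.0, 30.0, 300.0, 3000.0))
        ]
        sd_sum = summed_difference(recs).sd_sum
        # MC oracle: sums of single-replicate state differences
        draws = rng.normal(means_b, sds, size=(100_000, 4)) - rng.normal(
            means_a, sds, size=(100_000, 4)
        )
        empirical = draws.sum(axis=1).std(ddof=1)
        assert sd_sum == pytest.approx(empirical, rel=0.03)

    def test_missing_timepoint_excluded_with_warning(self):
        pep = Peptide(1, 12, "A" * 12)
        recs = [DifferenceRecord(pep, t, 0.1, 0.1, 1.0, 1.0, False, "none") for t in (3.0, 30.0)]
        comp = ComparisonResult(records=recs)
        with pytest.warns(UserWarning, match="missing timepoints"):
            out = summed_differences(comp, expected_timepoints=[3.0, 30.0, 300.0])
        assert out == []


class TestCompareStates:
    def test_antisymmetry(self, two_state_dataset):
        a = two_state_dataset.subset_state("reference")
        b = two_state_dataset.subset_state("perturbed")
        fwd = compare_states(a, b)
        rev = compare_states(b, a)
        key = lambda r: (r.peptide.key(), r.timepoint)
        fr = {key(r): r for r in fwd.records}
        for r in rev.records:
            twin = fr[key(r)]
            assert r.delta_d == pytest.approx(-twin.delta_d, abs=1e-12)
            assert r.delta_pct == pytest.approx(-twin.delta_pct, abs=1e-12)
            assert r.p_value == pytest.approx(twin.p_value, abs=1e-12)

    def test_recovery_of_perturbed_region(self, two_state_dataset, peptide_map, perturbed_region):
        a = two_state_dataset.subset_state("reference")
        b = two_state_dataset.subset_state("perturbed")
        comp = compare_states(a, b)
        lo, hi = perturbed_region
        region = set(range(lo, hi + 1))
        inside = [p for p in peptide_map if p.start >= lo and p.end <= hi]
        outside = [p for p in peptide_map if not (set(p.exchangeable_residues()) & region)]
        assert inside, "fixture must contain a fully-enclosed peptide"
        for pep in inside:
            assert peptide_significance(comp.for_peptide(pep)) == "increase"
        for pep in outside:
            assert peptide_significance(comp.for_peptide(pep)) == "none"

    def test_null_control_type_one_error(self, exchange_model, peptide_map):
        cfg_a = SimulationConfig(seed=21)
        cfg_b = SimulationConfig(seed=22)
        a = simulate_uptake(exchange_model, peptide_map, cfg_a)
        b = simulate_uptake(exchange_model, peptide_map, cfg_b)
        comp = compare_states(a, b)
        n_sig = sum(
            peptide_significance(comp.for_peptide(p)) != "none" for p in comp.peptides()
        )
        assert n_sig / len(comp.peptides()) <= 0.05

    def test_unmatched_peptides_reported(self, exchange_model, peptide_map, sim_config):
        a = simulate_uptake(exchange_model, peptide_map, sim_config)
        b = simulate_uptake(exchange_model, peptide_map[:-1], sim_config)
        comp = compare_states(a, b)
        assert [p.key() for p in comp.unmatched_a] == [peptide_map[-1].key()]
        assert not comp.unmatched_b

    def test_unequal_timepoint_grids_intersected_with_warning(
        self, exchange_model, peptide_map
    ):
        a = simulate_uptake(exchange_model, peptide_map, SimulationConfig(seed=1))
        b = simulate_uptake(
            exchange_model, peptide_map, SimulationConfig(timepoints=(3.0, 30.0, 300.0), seed=2)
        )
        with pytest.warns(UserWarning, match="dropped"):
            comp = compare_states(a, b)
        assert comp.dropped_timepoints == [3000.0]
        assert {r.timepoint for r in comp.records} == {3.0, 30.0, 300.0}


class TestCoverage:
    def test_full_tiling_is_100pct(self):
        seq = "A" * 60
        peps = [Peptide(i, min(i + 11, 60), seq[i - 1 : min(i + 11, 60)]) for i in range(1, 50, 6)]
        assert coverage_stats(peps, seq)["pct_exchangeable_covered"] == pytest.approx(100.0)

    def test_half_coverage_of_proline_free_toy(self):
        # 42 residues, exchangeable 3..42 (40 residues); peptide covering 1..22
        # has exchangeable 3..22 = 20 of them
        seq = "A" * 42
        pep = Peptide(1, 22, seq[:22])
        out = coverage_stats([pep], seq)
        assert out["pct_exchangeable_covered"] == pytest.approx(50.0)

    def test_empty_list_is_zero(self):
        assert coverage_stats([], "A" * 30)["pct_exchangeable_covered"] == 0.0

    def test_matches_brute_force_set_union(self, peptide_map, protein_sequence):
        from hdxdyn.ingest import exchangeable_positions

        out = coverage_stats(peptide_map, protein_sequence)
        total = set(exchangeable_positions(protein_sequence))
        union = set()
        for p in peptide_map:
            union |= set(p.exchangeable_residues())
        assert out["pct_exchangeable_covered"] == pytest.approx(
            100.0 * len(union & total) / len(total)
        )
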