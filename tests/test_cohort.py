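"""Synthetic cohort generator: calibration, invariants, determinism."""

import numpy as np
import pytest

from connclass.cohort import (
    PHENOTYPES,
    CohortConfig,
    ConfigurationError,
    GenerationError,
    SubjectRecord,
    cohort_to_frame,
    functional_rng,
    generate_cohort,
    overlap_percentage,
    phenotype_overlap_table,
    shared_structural_topology,
    simulate_functional,
    simulate_structural,
    structural_rng,
)
from connclass.features import proportional_threshold, vectorize_upper


def _subject(id, sex="female", age=60.0, icv=1.4e6, ctq=0.0, **flags):
    return SubjectRecord(
        id=id, index=int(id.lstrip("S")), age=age, sex=sex, icv=icv,
        ctq=ctq, ctq_items=(ctq,) * 5, **flags,
    )


# ---------------------------------------------------------------------------
# covariates and phenotypes
# ---------------------------------------------------------------------------

class TestCovariates:
    def test_deterministic_under_fixed_seed(self, small_config):
        a = cohort_to_frame(generate_cohort(small_config))
        b = cohort_to_frame(generate_cohort(small_config))
        assert a.equals(b)

    def test_ranges_and_ctq_item_mean(self, small_cohort):
        for s in small_cohort:
            assert 45.0 <= s.age <= 80.0
            assert s.icv > 0
            assert 0.0 <= s.ctq <= 1.0
            assert all(0.0 <= x <= 1.0 for x in s.ctq_items)
            assert s.ctq == pytest.approx(np.mean(s.ctq_items), abs=1e-12)

    def test_zero_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_subjects=0)

    def test_ctq_case_quantile_calibration(self, big_cohort):
        """The 0.2/0.4/0.6 thresholds sit near the 50th/70th/80th case percentile."""
        _, cohort = big_cohort
        case_ctq = np.array([s.ctq for s in cohort if s.ever])
        targets = {0.2: 0.50, 0.4: 0.70, 0.6: 0.80}
        for threshold, quantile in targets.items():
            assert np.mean(case_ctq < threshold) == pytest.approx(quantile, abs=0.05)

    def test_case_sex_ratio_near_two_to_one(self, big_cohort):
        _, cohort = big_cohort
        female = np.array([s.sex == "female" for s in cohort if s.ever])
        assert 0.60 <= female.mean() <= 0.75


class TestPhenotypes:
    def test_nesting_invariants(self, big_cohort):
        _, cohort = big_cohort
        for s in cohort:
            if s.current:
                assert s.ever
            if s.recurrent:
                assert s.ever
            # severe-without-current and current are disjoint by definition
            assert not (s.ever_severe and s.current)

    def test_excluded_subjects_carry_no_flags(self, big_cohort):
        _, cohort = big_cohort
        excluded = [s for s in cohort if s.excluded]
        assert excluded, "expected some excluded subjects at the default rate"
        assert not any(s.any_flag() for s in excluded)

    def test_all_pairwise_overlaps_positive(self, big_cohort):
        _, cohort = big_cohort
        table = phenotype_overlap_table(cohort)
        for i, a in enumerate(PHENOTYPES):
            for j, b in enumerate(PHENOTYPES):
                if i == j:
                    continue
                if {a, b} == {"ever_severe", "current"}:
                    # disjoint by definition: severe cases have current
                    # symptoms absent
                    assert table.counts.loc[a, b] == 0
                else:
                    assert table.counts.loc[a, b] >= 1, (a, b)

    def test_zero_case_threshold_raises_naming_phenotype(self):
        config = CohortConfig(n_subjects=2000, seed=0, ever_threshold=100.0)
        with pytest.raises(GenerationError, match="ever"):
            generate_cohort(config)


class TestOverlapTable:
    def test_percentage_worked_example(self):
        assert overlap_percentage(460, 703) == 65.4

    def test_disjoint_sets(self):
        subjects = [
            _subject("S000001", drug=True),
            _subject("S000002", ever=True),
            _subject("S000003"),
        ]
        t = phenotype_overlap_table(subjects, phenotypes=("drug", "ever"))
        assert t.counts.loc["drug", "ever"] == 0
        assert t.counts.loc["drug", "drug"] == 1  # unique cases on the diagonal
        assert t.counts.loc["ever", "ever"] == 1

    def test_identical_case_sets(self):
        subjects = [_subject(f"S{i:06d}", drug=True, ever=True) for i in range(4)]
        t = phenotype_overlap_table(subjects, phenotypes=("drug", "ever"))
        assert t.counts.loc["drug", "ever"] == 4
        assert t.percent.loc["drug", "ever"] == 100.0
        assert t.counts.loc["drug", "drug"] == 0  # nothing unique


# ---------------------------------------------------------------------------
# functional connectomes
# ---------------------------------------------------------------------------

class TestFunctional:
    def test_symmetric_zero_diagonal_finite(self, small_config, small_cohort):
        for s in small_cohort[:5]:
            for m in simulate_functional(s, small_config):
                assert np.array_equal(m, m.T)
                assert np.all(np.diag(m) == 0.0)
                assert np.isfinite(m).all()

    def test_per_subject_seeding_is_subset_stable(self, small_config, small_cohort):
        s = small_cohort[7]
        a, _ = simulate_functional(s, small_config, functional_rng(small_config, s))
        b, _ = simulate_functional(s, small_config, functional_rng(small_config, s))
        assert np.array_equal(a, b)

    @staticmethod
    def _group_block_means(config, subjects, case_flags, block=("VN", "VN")):
        from connclass.cohort import _block_mask

        mask = np.triu(_block_mask(config, *block), 1)
        means = np.array(
            [simulate_functional(s, config)[0][mask].mean() for s in subjects]
        )
        case_flags = np.asarray(case_flags)
        return means[case_flags], means[~case_flags]

    def test_null_effect_block_difference(self):
        """delta=0: case/control block means are statistically indistinguishable."""
        from scipy.stats import ttest_ind

        config = CohortConfig(
            n_subjects=1000, seed=5, functional_nodes=20,
            subnetwork_sizes=(4, 4, 4, 4, 2, 2), ts_length=120, delta=0.0,
        )
        cohort = generate_cohort(config)
        flags = [s.has_flag(config.effect_phenotype) or i < 500 for i, s in enumerate(cohort)]
        case, ctrl = self._group_block_means(config, cohort, flags)
        t, _ = ttest_ind(case, ctrl)
        assert abs(t) < 4.0

    def test_planted_shift_recovered_within_20_percent(self):
        """delta=0.3 in the target block shows up as a ~0.3 z-difference."""
        config = CohortConfig(
            n_subjects=1000, seed=6, functional_nodes=20,
            subnetwork_sizes=(4, 4, 4, 4, 2, 2), ts_length=120,
            delta=0.3, ctq_slope=0.0, effect_phenotype="ever",
        )
        cohort = generate_cohort(config)
        flags = [s.ever for s in cohort]
        assert sum(flags) > 150
        case, ctrl = self._group_block_means(config, cohort, flags)
        observed = case.mean() - ctrl.mean()
        assert observed == pytest.approx(0.3, rel=0.20)


# ---------------------------------------------------------------------------
# structural connectomes
# ---------------------------------------------------------------------------

class TestStructural:
    def test_symmetry_nonnegative_zero_diagonal(self, small_config, small_cohort):
        for s in small_cohort[:3]:
            stack = simulate_structural(s, small_config)
            assert stack.shape[0] == small_config.structural_channels
            for m in stack:
                assert np.array_equal(m, m.T)
                assert (m >= 0.0).all()
                assert np.all(np.diag(m) == 0.0)

    def test_density_matches_topology_times_reliability(self, small_config, small_cohort):
        n = small_config.structural_nodes
        iu = np.triu_indices(n, 1)
        densities = [
            np.count_nonzero(simulate_structural(s, small_config)[0][iu]) / len(iu[0])
            for s in small_cohort[:40]
        ]
        expected = small_config.edge_prob * small_config.reliability
        assert np.mean(densities) == pytest.approx(expected, abs=0.1)

    def test_full_reliability_reproduces_base_topology(self, small_config, small_cohort):
        config = small_config.replace(reliability=1.0)
        topology = shared_structural_topology(config)
        mats = [simulate_structural(s, config)[0] for s in small_cohort[:9]]
        kept = proportional_threshold(mats, 2.0 / 3.0)
        base_edges = np.flatnonzero(vectorize_upper(topology.astype(float)))
        assert np.array_equal(kept, base_edges)

    def test_invalid_reliability_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            small_config.replace(reliability=0.0)
        with pytest.raises(ConfigurationError):
            small_config.replace(reliability=1.5)

    def test_case_effect_raises_target_weights(self, small_config, small_cohort):
        config = small_config.replace(delta_s=1.0, effect_phenotype="ever", ctq_slope=0.0)
        cases = [s for s in small_cohort if s.ever][:40]
        ctrls = [s for s in small_cohort if not s.ever][:40]
        k = config.structural_target_nodes

        def target_mean(subjects):
            vals = []
            for s in subjects:
                m = simulate_structural(s, config)[0][:k, :k]
                vals.append(m[m > 0].mean())
            return np.mean(vals)

        assert target_mean(cases) > 1.5 * target_mean(ctrls)
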