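"""Synthetic-cohort generator: determinism, invariants, planted structure."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from gendulf import (
    CohortSpec,
    SpecificationError,
    run_step1,
    run_step2,
    simulate_case_control,
    simulate_healthy,
    simulate_isoforms,
)
from gendulf.simulate import LABEL_GCD


class TestCohortSpec:
    def test_too_many_planted(self):
        with pytest.raises(SpecificationError):
            CohortSpec(n_genes=10, n_planted_pm=8, n_decoy_coregulated=4)

    def test_true_dpm_bounded_by_planted(self):
        with pytest.raises(SpecificationError):
            CohortSpec(n_planted_pm=5, n_true_dpm=6, n_step3_modifiers=0)

    def test_rho_range(self):
        with pytest.raises(SpecificationError):
            CohortSpec(coupling_rho=1.5)


class TestSimulateHealthy:
    def test_deterministic(self, small_spec):
        a, _ = simulate_healthy(small_spec)
        b, _ = simulate_healthy(small_spec)
        assert a == b

    def test_matrix_invariants(self, small_cohort):
        healthy, truth, _ = small_cohort
        assert np.all(np.isfinite(healthy.values)) and np.all(healthy.values >= 0)
        assert len(set(healthy.gene_ids)) == healthy.n_genes

    def test_labels_partition_genes(self, small_cohort):
        healthy, truth, _ = small_cohort
        assert sorted(truth.labels) == sorted(healthy.gene_ids)
        assert sum(1 for v in truth.labels.values() if v == LABEL_GCD) == 1

    def test_rho_zero_gives_independence(self):
        """With no coupling, planted PMs behave like background at Step 1."""
        hits = 0
        for seed in range(30):
            spec = CohortSpec(
                n_samples=200, n_genes=60, n_planted_pm=10, n_decoy_coregulated=0,
                n_true_dpm=5, n_step3_modifiers=0, coupling_rho=0.0, seed=seed,
            )
            healthy, truth = simulate_healthy(spec)
            recs = run_step1(healthy, "GCD")
            hits += any(r.is_pm for r in recs)
        # family-wise alpha 0.01 plus generous binomial slack at 30 seeds
        assert hits / 30 <= 0.01 + 2.33 * np.sqrt(0.01 * 0.99 / 30) + 0.05

    def test_copula_lower_tail_cooccurrence(self):
        """Empirical P(PM low | GCD low) matches the Gaussian-copula orthant
        probability (Monte Carlo over planted genes and samples)."""
        spec = CohortSpec(n_samples=2000, n_genes=60, n_planted_pm=40,
                          n_decoy_coregulated=0, n_true_dpm=10,
                          n_step3_modifiers=0, seed=1)
        healthy, truth = simulate_healthy(spec)
        q = np.quantile(healthy.row("GCD"), 0.10)
        gcd_low = healthy.row("GCD") <= q
        cond = []
        for g in truth.planted_pm_ids:
            row = healthy.row(g)
            low = row <= np.quantile(row, 0.10)
            cond.append((low & gcd_low).sum() / gcd_low.sum())
        z = norm.ppf(0.10)
        rho = spec.coupling_rho
        orthant = multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]]
        ).cdf([z, z]) / 0.10
        assert np.mean(cond) == pytest.approx(orthant, abs=0.02)


class TestSimulateCaseControl:
    def test_deterministic_and_arm_sizes(self, small_spec):
        a = simulate_case_control(small_spec, simulate_healthy(small_spec)[1])
        b = simulate_case_control(small_spec, simulate_healthy(small_spec)[1])
        assert a.matrix == b.matrix
        assert len(a.case_sample_ids) == small_spec.n_cases
        assert len(a.control_sample_ids) == small_spec.n_controls

    def test_mismatched_truth_rejected(self, small_spec):
        _, truth = simulate_healthy(small_spec)
        other = replace(small_spec, seed=small_spec.seed + 1)
        with pytest.raises(SpecificationError):
            simulate_case_control(other, truth)

    def test_platform_scale_does_not_change_step2(self, small_spec):
        """The case-control matrix lives on an arbitrary scale; Step 2 is
        rank-based within dataset, so results are identical."""
        healthy, truth = simulate_healthy(small_spec)
        study1 = simulate_case_control(small_spec, truth)
        scaled = replace(small_spec, platform_scale=small_spec.platform_scale * 1000)
        healthy2, truth2 = simulate_healthy(scaled)
        study2 = simulate_case_control(scaled, truth2)
        genes = truth.true_dpm_ids[:3]
        r1 = run_step2(genes, healthy, "GCD", study1, reps=500, seed=1)
        r2 = run_step2(genes, healthy2, "GCD", study2, reps=500, seed=1)
        assert r1 == r2

    def test_decoy_effect_one_collapses_contrast(self):
        """With no case downregulation, decoys are generated exactly like
        true DPMs, so the two groups' Step-2 pass rates coincide up to
        Monte-Carlo noise."""
        spec = CohortSpec(
            n_samples=300, n_genes=120, n_planted_pm=24, n_decoy_coregulated=12,
            n_true_dpm=12, n_step3_modifiers=0, decoy_case_effect=1.0, seed=5,
        )
        healthy, truth = simulate_healthy(spec)
        study = simulate_case_control(spec, truth)
        dpm = {r.gene_id: r.status for r in run_step2(
            truth.true_dpm_ids + truth.decoy_ids, healthy, "GCD", study,
            reps=2000, seed=5,
        )}
        rate_true = np.mean([dpm[g] == "dpm" for g in truth.true_dpm_ids])
        rate_decoy = np.mean([dpm[g] == "dpm" for g in truth.decoy_ids])
        assert abs(rate_true - rate_decoy) <= 0.35


class TestSimulateIsoforms:
    def test_requires_step3_modifiers(self, small_spec):
        spec = replace(small_spec, n_step3_modifiers=0)
        healthy, truth = simulate_healthy(spec)
        with pytest.raises(SpecificationError):
            simulate_isoforms(spec, truth, healthy)

    def test_zero_link_weight_uniform_pvalues(self):
        """With no link, Step-3 p-values over many genes are uniform."""
        from scipy.stats import kstest

        from gendulf import IsoformPair, rank_sum_one_sided, ratio_groups

        spec = CohortSpec(n_samples=300, n_genes=220, n_planted_pm=10,
                          n_decoy_coregulated=0, n_true_dpm=5, n_step3_modifiers=1,
                          isoform_link_weight=0.0, seed=2)
        healthy, truth = simulate_healthy(spec)
        pair = simulate_isoforms(spec, truth, healthy)
        groups = ratio_groups(pair)
        hi = healthy.sample_indices(groups.high_ratio_samples)
        lo = healthy.sample_indices(groups.low_ratio_samples)
        pvals = [
            rank_sum_one_sided(healthy.row(g)[hi], healthy.row(g)[lo])
            for g in truth.background_ids[:200]
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_link_separates_modifier(self):
        """A near-deterministic link makes the planted modifier's healthy
        expression almost perfectly split by the ratio groups."""
        from gendulf import rank_sum_one_sided, ratio_groups

        spec = CohortSpec(n_samples=300, n_genes=60, n_planted_pm=6,
                          n_decoy_coregulated=0, n_true_dpm=3, n_step3_modifiers=1,
                          isoform_link_weight=200.0, seed=3)
        healthy, truth = simulate_healthy(spec)
        pair = simulate_isoforms(spec, truth, healthy)
        groups = ratio_groups(pair)
        hi = healthy.sample_indices(groups.high_ratio_samples)
        lo = healthy.sample_indices(groups.low_ratio_samples)
        mod = truth.step3_modifier_ids[0]
        p_mod = rank_sum_one_sided(healthy.row(mod)[hi], healthy.row(mod)[lo])
        p_bg = rank_sum_one_sided(
            healthy.row(truth.background_ids[0])[hi],
            healthy.row(truth.background_ids[0])[lo],
        )
        assert p_mod < 1e-10 < p_bg

    def test_deterministic(self, small_spec):
        healthy, truth = simulate_healthy(small_spec)
        a = simulate_isoforms(small_spec, truth, healthy)
        b = simulate_isoforms(small_spec, truth, healthy)
        assert np.array_equal(a.fl_values, b.fl_values)
        assert np.array_equal(a.trunc_values, b.trunc_values)


class TestLabelRecoverability:
    def test_planted_pm_p_below_background(self):
        """Across seeds, mean Step-1 p for planted PMs is far below the
        background mean."""
        diffs = []
        for seed in range(8):
            spec = CohortSpec(n_samples=200, n_genes=80, n_planted_pm=10,
                              n_decoy_coregulated=5, n_true_dpm=5,
                              n_step3_modifiers=0, seed=seed)
            healthy, truth = simulate_healthy(spec)
            p = {r.gene_id: r.p_raw for r in run_step1(healthy, "GCD")}
            planted = np.mean([p[g] for g in truth.planted_pm_ids])
            background = np.mean([p[g] for g in truth.background_ids if g in p])
            diffs.append(background - planted)
        diffs = np.array(diffs)
        assert diffs.mean() > 2 * diffs.std(ddof=1) / np.sqrt(len(diffs))
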