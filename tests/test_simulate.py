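"""Generator correctness: closed-form truths, determinism, noise structure."""

import numpy as np
import pytest

from rhizodmm import (
    Effect,
    SyntheticSpec,
    generate_truth,
    make_null_dataset,
    simulate_counts,
    simulate_phenotypes,
)


def two_group_spec(**kwargs):
    defaults = dict(n_taxa=20, replicates={"A": 4, "B": 4}, n_soil=0,
                    theta_true=200.0, depth_range=(500, 1000), seed=42)
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


class TestGenerateTruth:
    def test_no_effects_means_shared_composition(self):
        truth = generate_truth(two_group_spec())
        np.testing.assert_allclose(truth.pi.loc["A"], truth.pi.loc["B"])

    def test_fold_change_matches_renormalization_closed_form(self):
        # Oracle: multiply taxon 0 (baseline abundance b) by f in group B and
        # renormalize. The new abundance is f*b / (1 + (f-1)*b), so
        # log10 FC vs A is log10(f * c) with c = 1 / (1 + (f-1)*b).
        fold = 8.0
        spec = two_group_spec(effects=[Effect(0, ("B",), fold)],
                              fixed_baseline={0: 0.01})
        truth = generate_truth(spec)
        b = 0.01
        c = 1.0 / (1.0 + (fold - 1.0) * b)
        expected = np.log10(fold * c)
        assert truth.log10_fold_change("B", "A")[0] == pytest.approx(expected, abs=1e-12)
        # non-effect taxa shift by the renormalization alone
        assert truth.log10_fold_change("B", "A")[1] == pytest.approx(np.log10(c), abs=1e-12)

    def test_equal_seeds_identical_truths(self):
        t1 = generate_truth(two_group_spec())
        t2 = generate_truth(two_group_spec())
        np.testing.assert_array_equal(t1.pi.to_numpy(), t2.pi.to_numpy())

    def test_compositions_sum_to_one(self):
        truth = generate_truth(two_group_spec(effects=[Effect(3, ("A",), 2.5)]))
        np.testing.assert_allclose(truth.pi.sum(axis=1), 1.0, atol=1e-12)

    def test_effect_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            two_group_spec(effects=[Effect(99, ("A",), 2.0)])

    def test_differential_set_consistent_with_effects(self):
        spec = two_group_spec(effects=[Effect(2, ("B",), 4.0)])
        truth = generate_truth(spec)
        diff = truth.differential_taxa("A", "B", tol=1e-6)
        assert 2 in diff  # the planted taxon differs most; others only via renorm


class TestSimulateCounts:
    def test_row_sums_within_depth_range(self):
        spec = two_group_spec()
        ct, md = simulate_counts(generate_truth(spec), spec)
        depths = ct.depths
        assert (depths >= spec.depth_range[0]).all()
        assert (depths <= spec.depth_range[1]).all()

    def test_reproducible_given_seed(self):
        spec = two_group_spec()
        ct1, _ = simulate_counts(generate_truth(spec), spec)
        ct2, _ = simulate_counts(generate_truth(spec), spec)
        np.testing.assert_array_equal(ct1.counts, ct2.counts)

    def test_large_theta_and_depth_approach_truth(self):
        spec = two_group_spec(theta_true=1e7, depth_range=(200_000, 200_000),
                              replicates={"A": 3, "B": 3})
        truth = generate_truth(spec)
        ct, md = simulate_counts(truth, spec)
        props = ct.counts / ct.depths.to_numpy()[:, None]
        assert np.abs(props - truth.pi.loc["A"].to_numpy()).max() < 5e-3

    def test_empirical_mean_within_monte_carlo_error(self):
        # 200 replicates; SE per taxon ~ sqrt(pi(1-pi)/(theta+1))/sqrt(n)
        spec = two_group_spec(replicates={"A": 200}, theta_true=100.0,
                              depth_range=(5000, 5000))
        truth = generate_truth(spec)
        ct, _ = simulate_counts(truth, spec)
        pi = truth.pi.loc["A"].to_numpy()
        props = ct.counts / 5000.0
        se = np.sqrt(pi * (1 - pi) / (spec.theta_true + 1)) / np.sqrt(200)
        z = np.abs(props.mean(axis=0) - pi) / np.maximum(se, 1e-9)
        assert (z < 3.0).mean() >= 0.95  # a rare 3-SE excursion is allowed

    def test_metadata_covers_samples_and_groups(self):
        spec = SyntheticSpec(n_taxa=10, seed=1)
        ct, md = simulate_counts(generate_truth(spec), spec)
        assert md.sample_ids == ct.sample_ids
        assert set(md.groups) == {"Col-2x", "Col-4x", "Ler-2x", "Ler-4x", "soil"}
        assert (md.groups == "soil").sum() == 7


class TestNullDataset:
    def test_truth_identical_across_groups_and_no_differentials(self):
        ct, md, truth = make_null_dataset(two_group_spec(effects=[Effect(0, ("B",), 9.0)]))
        np.testing.assert_allclose(truth.pi.loc["A"], truth.pi.loc["B"])
        assert truth.differential_taxa("A", "B") == []

    def test_distinct_seeds_distinct_counts_same_truth_draw_mechanism(self):
        ct1, _, t1 = make_null_dataset(two_group_spec(seed=1))
        ct2, _, t2 = make_null_dataset(two_group_spec(seed=2))
        assert not np.array_equal(ct1.counts, ct2.counts)


class TestSimulatePhenotypes:
    def test_zero_effects_zero_noise_constant(self):
        tbl = simulate_phenotypes(noise_sd=0.0, grand_mean=50.0, n_per_cell=2)
        assert (tbl["aboveground_biomass"] == 50.0).all()

    def test_planted_inoculum_effect_recovered_in_cell_means(self):
        delta = -20.0
        tbl = simulate_phenotypes(inoculum_effects={"Col-4x": delta}, noise_sd=1.0,
                                  n_per_cell=50, seed=3)
        means = tbl.groupby("inoculum")["aboveground_biomass"].mean()
        others = means.drop("Col-4x").mean()
        se = 1.0 / np.sqrt(50 * 4)
        assert means["Col-4x"] - others == pytest.approx(delta, abs=5 * se)

    def test_equal_seeds_identical_tables(self):
        t1 = simulate_phenotypes(seed=9)
        t2 = simulate_phenotypes(seed=9)
        assert t1.equals(t2)

    def test_block_effects_additive(self):
        tbl = simulate_phenotypes(block_effects={"B1": 5.0}, noise_sd=0.0,
                                  grand_mean=0.0, n_per_cell=4)
        assert (tbl.loc[tbl.block == "B1", "aboveground_biomass"] == 5.0).all()
        assert (tbl.loc[tbl.block == "B2", "aboveground_biomass"] == 0.0).all()
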