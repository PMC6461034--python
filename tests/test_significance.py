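"""Permutation null model and p-value estimation."""

import numpy as np
import pandas as pd
import pytest

from inka import scoring, significance, synthetic
from inka.errors import InkaError
from inka.significance import CompiledSample, PermutationConfig


def tiny_merged(counts):
    n = len(counts)
    return pd.DataFrame(
        {
            "gene_symbol": [f"G{i}" for i in range(n)],
            "peptide_sequence": [f"PEP{i}K" for i in range(n)],
            "n_phospho": [1] * n,
            "accession": [f"A{i}" for i in range(n)],
            "position": [10 * (i + 1) for i in range(n)],
            "residue": ["Y"] * n,
            "localization_probability": [0.9] * n,
            "n_inferred_sites": [1] * n,
            "s1": list(map(float, counts)),
        }
    )


class TestPermuteExperiment:
    def test_nonzero_values_swap_with_equal_probability(self):
        merged = tiny_merged([3, 0, 5])
        outcomes = set()
        swapped = 0
        rng = np.random.default_rng(0)
        for _ in range(400):
            out = significance.permute_experiment(merged, "s1", rng)
            vals = tuple(out["s1"])
            outcomes.add(vals)
            if vals == (5.0, 0.0, 3.0):
                swapped += 1
        assert outcomes == {(3.0, 0.0, 5.0), (5.0, 0.0, 3.0)}
        assert 140 < swapped < 260  # ~Binomial(400, 0.5)

    def test_all_zero_sample_is_unchanged(self):
        merged = tiny_merged([0, 0, 0])
        out = significance.permute_experiment(merged, "s1", np.random.default_rng(1))
        assert (out["s1"] == 0).all()

    def test_count_multiset_is_conserved(self):
        merged = tiny_merged([3, 0, 5, 2, 2, 0])
        out = significance.permute_experiment(merged, "s1", np.random.default_rng(2))
        assert sorted(out["s1"]) == sorted(merged["s1"])

    def test_site_rows_of_a_peptide_stay_consistent(self):
        merged = pd.concat([tiny_merged([3, 5])] * 2, ignore_index=True)
        merged.loc[2:, "position"] += 5  # second site on each peptide
        out = significance.permute_experiment(merged, "s1", np.random.default_rng(3))
        per_pep = out.groupby("peptide_sequence")["s1"].nunique()
        assert (per_pep == 1).all()


class TestRandomizeRelations:
    def _relations(self, n, pool):
        return pd.DataFrame(
            {
                "kinase_symbol": [pool[i % len(pool)] for i in range(n)],
                "substrate_symbol": [f"S{i}" for i in range(n)],
                "position": list(range(1, n + 1)),
                "residue": ["Y"] * n,
                "source": ["PSP"] * n,
                "prediction_score": [np.nan] * n,
            }
        )

    def test_single_kinase_pool_is_a_forced_draw(self):
        rel = self._relations(1, ["K1"])
        out = significance.randomize_relations(rel, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, rel)

    def test_substrate_sites_and_count_invariant(self):
        rel = self._relations(30, [f"K{i}" for i in range(5)])
        out = significance.randomize_relations(rel, np.random.default_rng(1))
        assert len(out) == len(rel)
        pd.testing.assert_frame_equal(
            out.drop(columns="kinase_symbol"), rel.drop(columns="kinase_symbol")
        )

    def test_uniform_draw_matches_binomial_expectation(self):
        pool = [f"K{i}" for i in range(10)]
        rel = self._relations(100, pool)
        rng = np.random.default_rng(5)
        totals = {k: 0 for k in pool}
        n_rep = 200
        for _ in range(n_rep):
            out = significance.randomize_relations(rel, rng)
            for k, c in out["kinase_symbol"].value_counts().items():
                totals[k] += c
        means = np.array([totals[k] / n_rep for k in pool])
        # each kinase expects 10 relations; allow generous sampling error
        assert np.all(np.abs(means - 10) < 1.5)

    def test_empty_pool_is_fatal(self):
        with pytest.raises(InkaError):
            significance.randomize_relations(
                self._relations(0, ["K1"]).iloc[:0], np.random.default_rng(0)
            )


class TestPValues:
    def test_compiled_observed_matches_reference_scoring(self, toy_bundle):
        _, kb, merged = toy_bundle
        for sample in ("sample1", "sample2"):
            compiled = CompiledSample(merged, kb, sample)
            observed = pd.Series(compiled.observed(), index=compiled.kinases)
            reference = scoring.score_sample(merged, kb, sample)["inka"]
            assert np.allclose(
                observed.reindex(reference.index).to_numpy(), reference.to_numpy()
            )

    def test_same_seed_reproduces_p_values(self, toy_bundle):
        _, kb, merged = toy_bundle
        cfg = PermutationConfig(n_iterations=200, seed=9)
        a = significance.inka_p_values(merged, kb, "sample1", config=cfg)
        b = significance.inka_p_values(merged, kb, "sample1", config=cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_plus_one_estimator_bounds(self, toy_bundle):
        _, kb, merged = toy_bundle
        cfg = PermutationConfig(n_iterations=99, seed=0)
        out = significance.inka_p_values(merged, kb, "sample1", config=cfg)
        p = out["p_value"]
        assert (p > 0).all() and (p <= 1).all()
        assert (p >= 1 / 100).all()  # never below 1/(n+1)
        # a zero observed score can never beat the null
        zeros = out[out["inka"] == 0]
        assert (zeros["p_value"] == 1.0).all()

    def test_adjusted_p_values_are_monotone_in_raw(self, toy_bundle):
        _, kb, merged = toy_bundle
        cfg = PermutationConfig(n_iterations=99, seed=1, adjust=True)
        out = significance.inka_p_values(merged, kb, "sample1", config=cfg)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()

    def test_high_scores_get_low_p_on_driver_data(self):
        from scipy import stats

        exp = synthetic.generate(seed=3)
        kb, merged = exp.knowledgebase(), exp.merged_table()
        out = significance.inka_p_values(
            merged, kb, "sample1", config=PermutationConfig(n_iterations=500, seed=0)
        )
        pos = out[out["inka"] > 0]
        rho = stats.spearmanr(pos["inka"], pos["p_value"]).statistic
        assert rho < 0
        assert out.loc[exp.drivers[0], "p_value"] <= 2 / 501
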