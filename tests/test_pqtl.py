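"""Inverse-normal transform, cis enumeration, the pQTL scan and its null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serumpqtl as sp
from tests.conftest import make_cis_dataset


class TestInverseNormal:
    def test_blom_scores_small_example(self):
        out = sp.inverse_normal(np.array([5.0, 1.0, 9.0]))
        np.testing.assert_allclose(out, [0.0, -0.86942, 0.86942], atol=1e-4)

    def test_symmetry_sum_zero_odd_n(self, rng):
        x = rng.normal(size=31)
        assert abs(sp.inverse_normal(x).sum()) < 1e-8

    def test_ties_get_average_rank(self):
        out = sp.inverse_normal(np.array([1.0, 1.0, 2.0]))
        assert out[0] == out[1]
        assert out[2] > out[0]

    def test_sorted_output_equals_blom_quantiles(self, rng):
        """Shape check: empirical quantiles are exactly the Blom scores in
        the tie-free case."""
        x = rng.normal(size=50)
        out = np.sort(sp.inverse_normal(x))
        n = len(x)
        expected = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            sp.inverse_normal(np.full(5, 3.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            sp.inverse_normal(np.array([1.0, 2.0]))


class TestEnumerateCisPairs:
    def _probes(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "target", "gene", "chrom", "pos"]
                            ).set_index("probe_id")

    def _variants(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"]
                            ).set_index("variant_id")

    def test_window_boundaries_closed(self):
        probes = self._probes([("p", "t", "G", "1", 50_000_000)])
        variants = self._variants([("in", "1", 50_900_000),
                                   ("edge", "1", 51_000_000),
                                   ("out", "1", 51_000_001),
                                   ("other", "2", 50_000_000)])
        pairs = sp.enumerate_cis_pairs(probes, variants, window=1_000_000)
        assert set(pairs["variant_id"]) == {"in", "edge"}
        assert pairs.loc[pairs["variant_id"] == "in", "distance"].iloc[0] == 900_000

    def test_unanchored_probe_skipped_not_error(self):
        probes = self._probes([("p", "t", "G", None, None)])
        variants = self._variants([("v", "1", 1)])
        pairs = sp.enumerate_cis_pairs(probes, variants, window=10)
        assert len(pairs) == 0

    def test_matches_bruteforce_all_pairs_filter(self, rng):
        probes = self._probes([
            (f"p{i}", "t", "G", str(rng.integers(1, 4)), int(rng.integers(0, 10_000_000)))
            for i in range(50)
        ])
        variants = self._variants([
            (f"v{i}", str(rng.integers(1, 4)), int(rng.integers(0, 10_000_000)))
            for i in range(200)
        ])
        window = 500_000
        pairs = sp.enumerate_cis_pairs(probes, variants, window=window)
        got = set(zip(pairs["probe_id"], pairs["variant_id"]))
        expected = {
            (p, v)
            for p, prow in probes.iterrows()
            for v, vrow in variants.iterrows()
            if prow["chrom"] == vrow["chrom"] and abs(vrow["pos"] - prow["pos"]) <= window
        }
        assert got == expected


class TestScanPqtl:
    def test_single_visit_scan_equals_ols(self, rng):
        samples, genotypes, proteins = make_cis_dataset(seed=31, n_subjects=40)
        base = sp.SampleTable(samples.df[samples.df["time_point"] == "baseline"].copy())
        pairs = pd.DataFrame({"probe_id": ["SLCIS1"], "variant_id": ["rs_causal"],
                              "distance": [0]})
        res = sp.scan_pqtl(pairs, proteins, genotypes, base)
        # OLS oracle on the same covariates and INT trait
        df = base.df
        y = sp.inverse_normal(proteins.values.loc[df["sample_id"], "SLCIS1"].to_numpy())
        X = np.column_stack([
            np.ones(len(df)), df["age"], (df["sex"] == "M").astype(float),
            genotypes.dosages["rs_causal"].reindex(df["subject_id"]).to_numpy(),
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["estimate"].iloc[0] == pytest.approx(beta[-1], abs=1e-6)

    def test_monomorphic_variant_flagged(self):
        samples, genotypes, proteins = make_cis_dataset(seed=32, n_subjects=20)
        genotypes.dosages["rs_causal"] = 0.0
        gt = sp.GenotypeMatrix(genotypes.dosages, genotypes.variants)
        pairs = pd.DataFrame({"probe_id": ["SLCIS1"], "variant_id": ["rs_causal"],
                              "distance": [0]})
        res = sp.scan_pqtl(pairs, proteins, gt, samples)
        assert res["flag"].iloc[0] == "monomorphic"
        assert np.isnan(res["p"].iloc[0])

    def test_ungenotyped_subject_rejected(self):
        samples, genotypes, proteins = make_cis_dataset(seed=33, n_subjects=10)
        gt = sp.GenotypeMatrix(genotypes.dosages.iloc[1:], genotypes.variants)
        pairs = pd.DataFrame({"probe_id": ["SLCIS1"], "variant_id": ["rs_causal"]})
        with pytest.raises(ValueError, match="without genotypes"):
            sp.scan_pqtl(pairs, proteins, gt, samples)

    def test_null_pvalues_uniform(self):
        """No genotype effect anywhere: Wald p over 500 pairs is uniform."""
        samples = sp.simulate_cohort(51, 0, 0, seed=34)
        specs = [(f"rs{i:03d}", "1", 1_000_000 + 1000 * i, 0.3) for i in range(500)]
        genotypes = sp.simulate_genotypes(list(samples.subject_ids), specs, seed=34)
        proteins = sp.simulate_proteome(
            samples, None, [sp.EffectSpec("SLNULL", chrom="1", pos=1_000_000)], seed=34
        )
        pairs = pd.DataFrame({"probe_id": "SLNULL", "variant_id": [s[0] for s in specs],
                              "distance": 0})
        res = sp.scan_pqtl(pairs, proteins, genotypes, samples)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestPermuteGenotypes:
    def test_allele_frequencies_conserved(self):
        _, genotypes, _ = make_cis_dataset(seed=35, n_subjects=30, n_decoy_variants=5)
        perm = sp.permute_genotype_subjects(genotypes, seed=99)
        pd.testing.assert_series_equal(perm.frequencies(), genotypes.frequencies())
        # rows move as units
        orig_rows = {tuple(r) for r in genotypes.dosages.to_numpy()}
        perm_rows = {tuple(r) for r in perm.dosages.to_numpy()}
        assert orig_rows == perm_rows

    def test_identity_permutation_leaves_matrix_unchanged(self):
        _, genotypes, _ = make_cis_dataset(seed=36, n_subjects=3)
        identity_seed = next(
            s for s in range(1000)
            if (np.random.default_rng(s).permutation(3) == np.arange(3)).all()
        )
        perm = sp.permute_genotype_subjects(genotypes, seed=identity_seed)
        pd.testing.assert_frame_equal(perm.dosages, genotypes.dosages)

    def test_permutation_destroys_true_signal(self):
        """A strong cis effect vanishes under subject-label permutation."""
        big = 0
        n_seeds = 20
        for seed in range(n_seeds):
            samples, genotypes, proteins = make_cis_dataset(
                seed=500 + seed, n_subjects=51, beta_g=2.0)
            pairs = pd.DataFrame({"probe_id": ["SLCIS1"], "variant_id": ["rs_causal"],
                                  "distance": [0]})
            null_gt = sp.permute_genotype_subjects(genotypes, seed=900 + seed)
            res = sp.scan_pqtl(pairs, proteins, null_gt, samples)
            big += res["p"].iloc[0] > 0.01
        assert big >= 0.8 * n_seeds
        # sanity: unpermuted signal is overwhelming
        obs = sp.scan_pqtl(pairs, proteins, genotypes, samples)
        assert obs["p"].iloc[0] < 1e-6


class TestEmpiricalFdrScan:
    def test_mismatched_pair_lists_rejected(self):
        samples, genotypes, proteins = make_cis_dataset(seed=37, n_subjects=15,
                                                        n_decoy_variants=2)
        pairs = sp.enumerate_cis_pairs(proteins.probes, genotypes.variants, 10_000_000)
        obs = sp.scan_pqtl(pairs, proteins, genotypes, samples)
        with pytest.raises(ValueError, match="different pair list"):
            sp.empirical_fdr_scan(obs, [obs.iloc[:-1]])

    def test_clean_null_gives_zero_fdr(self):
        samples, genotypes, proteins = make_cis_dataset(seed=38, n_subjects=15,
                                                        n_decoy_variants=3)
        pairs = sp.enumerate_cis_pairs(proteins.probes, genotypes.variants, 10_000_000)
        obs = sp.scan_pqtl(pairs, proteins, genotypes, samples)
        null = obs.copy()
        null["p"] = 1.0  # all permuted p above every observed threshold
        out = sp.empirical_fdr_scan(obs, [null, null])
        assert (out["fdr_literal"] == 0).all()

    def test_pipeline_rerun_is_byte_identical(self):
        samples, genotypes, proteins = make_cis_dataset(seed=39, n_subjects=20,
                                                        n_decoy_variants=3)
        a = sp.run_pqtl_scan(proteins, genotypes, samples, n_perm=3, seed=5).to_csv()
        b = sp.run_pqtl_scan(proteins, genotypes, samples, n_perm=3, seed=5).to_csv()
        assert a == b

    def test_null_fdr_calibration(self):
        """Global null, scaled down (8 seeds x 120 pairs x 8 permutations):
        fraction of pairs at 10% empirical FDR stays within Monte-Carlo
        error of the nominal rate."""
        fracs = []
        for seed in range(8):
            samples = sp.simulate_cohort(30, 0, 0, seed=600 + seed)
            specs = [(f"rs{i:03d}", "1", 1_000_000 + 1000 * i, 0.3) for i in range(120)]
            genotypes = sp.simulate_genotypes(list(samples.subject_ids), specs,
                                              seed=600 + seed)
            proteins = sp.simulate_proteome(
                samples, None,
                [sp.EffectSpec("SLNULL", chrom="1", pos=1_000_000)], seed=600 + seed)
            res = sp.run_pqtl_scan(proteins, genotypes, samples, n_perm=8,
                                   seed=600 + seed)
            fracs.append((res["q_monotone"] <= 0.10).mean())
        mc_sd = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.10 + 3 * mc_sd


class TestLeadSnp:
    def _result(self, rows):
        return pd.DataFrame(rows, columns=["probe_id", "variant_id", "distance",
                                           "estimate", "se", "wald", "p", "n_obs", "flag"])

    def test_single_pair_is_its_own_lead(self):
        res = self._result([("p1", "v1", 10, 1, 0.1, 10, 1e-4, 30, "")])
        lead = sp.lead_snp(res)
        assert list(lead["variant_id"]) == ["v1"]

    def test_tie_broken_by_distance_then_id(self):
        res = self._result([
            ("p1", "far", 5000, 1, 0.1, 10, 1e-4, 30, ""),
            ("p1", "near", -100, 1, 0.1, 10, 1e-4, 30, ""),
            ("p1", "b_same_dist", 100, 1, 0.1, 10, 1e-4, 30, ""),
            ("p1", "a_same_dist", -100, 1, 0.1, 10, 1e-4, 30, ""),
        ])
        lead = sp.lead_snp(res)
        assert list(lead["variant_id"]) == ["a_same_dist"]

    def test_matches_argmin_oracle(self, rng):
        rows = []
        for pi in range(10):
            for vi in range(8):
                rows.append((f"p{pi}", f"v{vi}", int(rng.integers(-1e6, 1e6)),
                             0.1, 0.1, 1.0, float(rng.uniform()), 30, ""))
        res = self._result(rows)
        lead = sp.lead_snp(res).set_index("probe_id")
        for pi, grp in res.groupby("probe_id"):
            assert lead.loc[pi, "p"] == grp["p"].min()

    def test_all_flagged_rejected(self):
        res = self._result([("p1", "v1", 10, np.nan, np.nan, np.nan, np.nan, 30, "monomorphic")])
        with pytest.raises(ValueError, match="non-flagged"):
            sp.lead_snp(res)


class TestConditionalScan:
    def test_conditioning_variant_excluded_from_output(self):
        samples, genotypes, proteins = make_cis_dataset(seed=40, n_subjects=20,
                                                        n_decoy_variants=3)
        res = sp.conditional_scan("SLCIS1", ("1", 0, 2_000_000), "rs_causal",
                                  proteins, genotypes, samples)
        assert "rs_causal" not in set(res["variant_id"])
        assert len(res) == 3

    def test_collinear_with_conditioning_flagged(self):
        samples, genotypes, proteins = make_cis_dataset(seed=41, n_subjects=20,
                                                        n_decoy_variants=1)
        dup = genotypes.dosages.copy()
        dup["rs_twin"] = dup["rs_causal"]
        variants = genotypes.variants.reset_index()
        twin = variants[variants["variant_id"] == "rs_causal"].assign(
            variant_id="rs_twin", pos=1_500_000)
        gt = sp.GenotypeMatrix(dup, pd.concat([variants, twin]))
        res = sp.conditional_scan("SLCIS1", ("1", 0, 2_000_000), "rs_causal",
                                  proteins, gt, samples)
        assert res.set_index("variant_id").loc["rs_twin", "flag"] == "collinear"

    def test_conditioning_on_causal_absorbs_signal(self):
        """Conditioning on the causal variant leaves no residual association
        in the region (seeded, 30 replicates)."""
        absorbed = 0
        n_seeds = 30
        for seed in range(n_seeds):
            samples, genotypes, proteins = make_cis_dataset(
                seed=700 + seed, n_subjects=51, beta_g=2.0, n_decoy_variants=5)
            res = sp.conditional_scan("SLCIS1", ("1", 0, 2_000_000), "rs_causal",
                                      proteins, genotypes, samples)
            absorbed += res["p"].min() > 0.01
        assert absorbed / n_seeds >= 0.9

    def test_conditioning_on_unlinked_variant_keeps_signal(self):
        samples, genotypes, proteins = make_cis_dataset(
            seed=42, n_subjects=51, beta_g=2.0, n_decoy_variants=2)
        res = sp.conditional_scan("SLCIS1", ("1", 0, 2_000_000), "rs_decoy01",
                                  proteins, genotypes, samples)
        assert res.set_index("variant_id").loc["rs_causal", "p"] < 1e-4

    def test_unknown_conditioning_variant_rejected(self):
        samples, genotypes, proteins = make_cis_dataset(seed=43, n_subjects=10)
        with pytest.raises(ValueError, match="not genotyped"):
            sp.conditional_scan("SLCIS1", ("1", 0, 2_000_000), "rs_missing",
                                proteins, genotypes, samples)
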