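import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medipdmr as m


def lean_cohort_sim(seed=31, n_per_group=10, n_windows_chrom=100_000 * 5,
                    n_planted=50, fold=4.0):
    """Exposure cohort where the lean animals are exactly the planted carriers."""
    cfg = m.SimConfig(seed=seed, n_chrom=1, chrom_length=n_windows_chrom,
                      n_samples_per_group=n_per_group, mean_depth=30,
                      disease_frequencies={"lean": 0.5})
    cfg = m.plant_random_dmrs(cfg, n_dmrs=n_planted, n_windows=5, fold_change=fold)
    cfg = m.SimConfig(**{**cfg.__dict__,
                         "phenotype_link": {"lean": list(range(n_planted))}})
    return m.simulate(cfg)


def comparison_from(out, phenotype="lean"):
    cohort = out.cohort.set_index("animal_id")
    exposed = [s for s in out.matrix.sample_ids if cohort.loc[s, "lineage"] == "exposure"]
    case = [s for s in exposed if cohort.loc[s, phenotype] == "present"]
    noncase = [s for s in exposed if cohort.loc[s, phenotype] != "present"]
    return m.SignatureComparison(phenotype=phenotype, case_ids=case, noncase_ids=noncase)


class TestComparison:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            m.SignatureComparison("lean", ["a", "b"], ["b", "c"])

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            m.SignatureComparison("lean", ["a"], ["b", "c"])


class TestBuildSignature:
    def test_label_swap_preserves_dmr_count(self, small_sim):
        mat = small_sim.matrix
        ids = mat.sample_ids
        c1 = m.SignatureComparison("x", ids[:4], ids[4:])
        c2 = m.SignatureComparison("x", ids[4:], ids[:4])
        assert len(m.build_signature(mat, c1)) == len(m.build_signature(mat, c2))

    def test_planted_signature_recovery(self):
        out = lean_cohort_sim()
        sig = m.build_signature(out.matrix, comparison_from(out))
        rep = m.overlap_sets([out.truth, sig.dmrs], labels=["truth", "sig"])
        recovered = rep.shared("truth", "sig") / len(out.truth)
        assert recovered >= 0.9

    def test_recovery_degrades_towards_null_fold(self):
        counts = []
        for fold in (1.0, 2.0, 4.0):
            out = lean_cohort_sim(seed=77, n_planted=30, fold=fold,
                                  n_windows_chrom=200_000)
            sig = m.build_signature(out.matrix, comparison_from(out))
            rep = m.overlap_sets([out.truth, sig.dmrs], labels=["truth", "sig"])
            counts.append(rep.shared("truth", "sig"))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] <= 2 and counts[2] >= 27


class TestPermutationNull:
    def test_empirical_p_formula_against_returned_nulls(self, small_sim):
        mat = small_sim.matrix
        ids = mat.sample_ids
        cmp = m.SignatureComparison("x", ids[:4], ids[4:], seed_p=1e-3)
        res = m.permutation_null(mat, cmp, n_perm=10, seed=5)
        expected = (1 + sum(c >= res.observed for c in res.null_counts)) / 11
        assert res.empirical_p == pytest.approx(expected)
        assert res.empirical_p >= 1 / 11
        assert len(res.null_counts) == 10
        assert res.null_mean == pytest.approx(np.mean(res.null_counts))

    def test_twenty_exceedances_give_one_twentyfirst(self):
        # sparse planting (40 regions in 20k windows) so the extension rule
        # does not merge neighbouring planted regions into one span
        out = lean_cohort_sim(seed=41, n_planted=40, n_windows_chrom=2_000_000)
        res = m.permutation_null(out.matrix, comparison_from(out), n_perm=20, seed=9)
        assert res.observed > max(res.null_counts)
        assert res.empirical_p == pytest.approx(1 / 21)
        assert res.empirical_p < 0.05

    def test_oversized_case_group_rejected(self, small_sim):
        mat = small_sim.matrix
        ids = mat.sample_ids
        cmp = m.SignatureComparison("x", ids[:6], ids[6:])
        cmp.noncase_ids = []  # force the degenerate pool
        with pytest.raises(ValueError, match="pool"):
            m.permutation_null(mat, cmp, n_perm=2, seed=0)

    def test_null_data_rarely_significant(self):
        """Type-I of the permutation p at a reduced number of repeats."""
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            cfg = m.SimConfig(seed=500 + r, n_chrom=1, chrom_length=100_000,
                              n_samples_per_group=4, mean_depth=20)
            out = m.simulate(cfg)
            ids = out.matrix.sample_ids
            cmp = m.SignatureComparison("null", ids[:4], ids[4:], seed_p=1e-4)
            res = m.permutation_null(out.matrix, cmp, n_perm=19, seed=r, phi=0.1)
            hits += res.empirical_p < 0.05
        assert hits <= 4  # E[hits] = 1 under exchangeability


class TestPoolAndSubsample:
    def make_matrix(self, seed=0, n_windows=2000, depth=20, n_samples=6):
        rng = np.random.default_rng(seed)
        w = m.partition_genome({"chr1": n_windows * 100}, 100)
        counts = rng.poisson(depth, size=(n_windows, n_samples))
        samples = pd.DataFrame({"id": [f"s{i}" for i in range(n_samples)],
                                "lineage": "exposure", "generation": "F3"})
        return m.CountMatrix(windows=w, samples=samples, counts=counts)

    def test_pooling_without_rescale_conserves_sums(self):
        mat = self.make_matrix()
        pools = {"p1": ["s0", "s1", "s2"], "p2": ["s3", "s4", "s5"]}
        member_sum = int(mat.counts[:, :3].sum())
        target = member_sum  # identity subsample
        pooled = m.pool_and_subsample(mat, {"p1": ["s0", "s1", "s2"]}, target,
                                      seed=1, equalize=False)
        np.testing.assert_array_equal(pooled.counts[:, 0], mat.counts[:, :3].sum(axis=1))

    def test_subsampled_total_is_exact(self):
        mat = self.make_matrix(seed=1)
        target = 10_000
        pooled = m.pool_and_subsample(mat, {"p": ["s0", "s1", "s2"]}, target, seed=2)
        assert pooled.counts[:, 0].sum() == target
        assert (pooled.counts[:, 0] <= mat.counts[:, :3].sum(axis=1)).all()

    def test_target_above_total_rejected(self):
        mat = self.make_matrix(seed=2)
        with pytest.raises(ValueError, match="exceeds"):
            m.pool_and_subsample(mat, {"p": ["s0"]}, 10**9, seed=0)

    def test_window_proportions_preserved(self):
        """Hypergeometric halving keeps expected window proportions."""
        mat = self.make_matrix(seed=3, n_windows=10_000, depth=30, n_samples=3)
        total = int(mat.counts.sum())
        target = total // 2
        pooled = m.pool_and_subsample(mat, {"p": ["s0", "s1", "s2"]}, target,
                                      seed=4, equalize=False)
        obs = pooled.counts[:, 0]
        expected = mat.counts.sum(axis=1) * (target / total)
        chi2 = float((((obs - expected) ** 2) / expected).sum())
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_shared_members_rejected(self):
        mat = self.make_matrix(seed=4)
        with pytest.raises(ValueError, match="share"):
            m.pool_and_subsample(mat, {"a": ["s0", "s1"], "b": ["s1", "s2"]}, 10, seed=0)


class TestSignatureOverlap:
    def test_identical_signatures_fully_overlap(self, small_sim):
        mat = small_sim.matrix
        ids = mat.sample_ids
        cmp = m.SignatureComparison("x", ids[:4], ids[4:], seed_p=0.05)
        sig = m.build_signature(mat, cmp)
        assert len(sig) > 0
        rep = m.signature_overlap([sig, sig], labels=["a", "b"])
        assert rep.shared("a", "b") == len(sig)
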