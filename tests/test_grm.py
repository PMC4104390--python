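"""GRM estimation against brute-force oracles, plus LD adjustment and PCA."""

import numpy as np
import pandas as pd
import pytest

from snpherit import (
    GRM,
    MISSING,
    adjust_grm_ld,
    allele_frequencies,
    compute_grm,
    grm_pca,
    simulate_null_cohort,
)
from snpherit.containers import GenotypeMatrix

from conftest import make_genotypes


def brute_force_grm(dosages, p):
    """O(n^2 m) triple-loop evaluation of the GRM definition."""
    n, m = dosages.shape
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1):
            acc = cnt = 0.0
            for i in range(m):
                xj, xk = dosages[j, i], dosages[k, i]
                if xj == MISSING or xk == MISSING:
                    continue
                denom = 2 * p[i] * (1 - p[i])
                if j == k:
                    acc += (xj * xj - (1 + 2 * p[i]) * xj + 2 * p[i] ** 2) / denom
                else:
                    acc += (xj - 2 * p[i]) * (xk - 2 * p[i]) / denom
                cnt += 1
            val = acc / cnt
            if j == k:
                val += 1.0
            values[j, k] = values[k, j] = val
            counts[j, k] = counts[k, j] = cnt
    return values, counts


def tiny_matrix(dosage_rows, chrom="1"):
    dos = np.asarray(dosage_rows, dtype=np.int8)
    n, m = dos.shape
    meta = pd.DataFrame({"chrom": chrom, "snp_id": [f"s{i}" for i in range(m)],
                         "pos": np.arange(m) + 1, "a1": "A", "a2": "G"})
    ids = pd.DataFrame({"fid": [f"F{i}" for i in range(n)],
                        "iid": [f"I{i}" for i in range(n)]})
    return GenotypeMatrix(dos, meta, ids)


class TestAlleleFrequencies:
    def test_simple_counts(self):
        g = tiny_matrix([[0], [1], [2]])
        assert allele_frequencies(g)["freq"].iloc[0] == 0.5

    def test_missing_excluded_from_count(self):
        g = tiny_matrix([[2], [2], [MISSING]])
        tab = allele_frequencies(g)
        assert tab["freq"].iloc[0] == 1.0 and tab["n_obs"].iloc[0] == 2

    def test_matches_per_column_loop(self, small_genotypes):
        tab = allele_frequencies(small_genotypes)
        for i in range(small_genotypes.n_snps):
            col = small_genotypes.dosages[:, i]
            obs = col[col != MISSING]
            assert tab["freq"].iloc[i] == pytest.approx(obs.mean() / 2)

    def test_all_missing_snp_rejected(self):
        g = tiny_matrix([[MISSING, 1], [MISSING, 2]])
        with pytest.raises(ValueError, match="s0"):
            allele_frequencies(g)


class TestComputeGrm:
    def test_hand_off_diagonal(self):
        # 1 SNP, dosages [0, 2], p = 0.5: A_12 = (0-1)(2-1)/0.5 = -2
        grm = compute_grm(tiny_matrix([[0], [2]]), maf_min=0.0)
        assert grm.values[0, 1] == pytest.approx(-2.0)

    def test_hand_diagonal(self):
        # dosage 2 at p = 0.5: A_jj = 1 + (4 - 2*2 + 0.5)/0.5 = 2
        grm = compute_grm(tiny_matrix([[2], [0]]), maf_min=0.0)
        assert grm.values[0, 0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, small_genotypes):
        freqs = allele_frequencies(small_genotypes)
        grm = compute_grm(small_genotypes, maf_min=0.0)
        expected, counts = brute_force_grm(small_genotypes.dosages,
                                           freqs["freq"].to_numpy())
        np.testing.assert_allclose(grm.values, expected, atol=1e-10)
        np.testing.assert_allclose(grm.pair_counts, counts)

    def test_allele_flip_invariance(self, small_genotypes):
        grm = compute_grm(small_genotypes, maf_min=0.0)
        flipped = small_genotypes.dosages.copy()
        obs = flipped != MISSING
        flipped[obs] = 2 - flipped[obs]
        g2 = GenotypeMatrix(flipped, small_genotypes.snp_meta,
                            small_genotypes.sample_ids)
        grm2 = compute_grm(g2, maf_min=0.0)
        np.testing.assert_allclose(grm2.values, grm.values, atol=1e-10)

    def test_chromosome_additivity_of_numerators(self):
        g = make_genotypes(25, 120, seed=11, missing_rate=0.0, n_chroms=2)
        freqs = allele_frequencies(g)
        full = compute_grm(g, freqs=freqs, maf_min=0.0)
        c1 = compute_grm(g, freqs=freqs, maf_min=0.0, chroms=["1"])
        c2 = compute_grm(g, freqs=freqs, maf_min=0.0, exclude_chroms=["1"])
        lhs = full.pair_counts * (full.values - np.eye(25))
        rhs = (c1.pair_counts * (c1.values - np.eye(25))
               + c2.pair_counts * (c2.values - np.eye(25)))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_maf_filter_removing_everything_rejected(self, small_genotypes):
        with pytest.raises(ValueError, match="no SNPs left"):
            compute_grm(small_genotypes, maf_min=0.6)

    def test_mean_diagonal_near_one_at_many_snps(self):
        # homogeneous outbred sample at the generating frequencies:
        # E[A_jj] = 1 and E[A_jk] = 0 exactly (sample-estimated frequencies
        # would add an O(1/n) centering bias)
        rng = np.random.default_rng(13)
        m = 20_000
        p = rng.uniform(0.05, 0.5, size=m)
        g = make_genotypes(40, m, seed=13)
        g.dosages = rng.binomial(2, p, size=(40, m)).astype(np.int8)
        true_freqs = pd.DataFrame({"snp_id": g.snp_meta["snp_id"],
                                   "freq": p, "n_obs": 40})
        grm = compute_grm(g, freqs=true_freqs, maf_min=0.0)
        diag = np.diag(grm.values)
        off = grm.values[~np.eye(40, dtype=bool)]
        assert abs(diag.mean() - 1.0) < 3 * diag.std(ddof=1) / np.sqrt(len(diag))
        assert abs(off.mean()) < 3 * off.std(ddof=1) / np.sqrt(len(off))


class TestLdAdjustment:
    def test_large_n_limit_leaves_grm_unchanged(self):
        g = make_genotypes(20, 150, seed=5)
        grm = compute_grm(g)
        grm.n_snps = 10**12  # 1/N -> 0 => beta -> 1
        adjusted = adjust_grm_ld(grm, c=0.0)
        np.testing.assert_allclose(adjusted.values, grm.values, rtol=1e-6)

    def test_half_shrinkage_geometry(self):
        """When beta = 0.5, off-diagonals halve and diagonals move halfway to 1."""
        rng = np.random.default_rng(3)
        w = rng.normal(size=(10, 30))
        a = w @ w.T / 30
        ids = pd.DataFrame({"fid": [f"F{i}" for i in range(10)],
                            "iid": [f"I{i}" for i in range(10)]})
        grm = GRM(a, np.full((10, 10), 500.0), ids, n_snps=500)
        off = a[~np.eye(10, dtype=bool)]
        var_off = float(np.var(off))
        c = var_off / 2 - 1 / 500  # chosen so beta = 0.5 exactly
        adjusted = adjust_grm_ld(grm, c=c)
        np.testing.assert_allclose(adjusted.values[~np.eye(10, dtype=bool)], 0.5 * off)
        np.testing.assert_allclose(np.diag(adjusted.values), 1 + 0.5 * (np.diag(a) - 1))

    def test_not_idempotent(self):
        # structured sample so the off-diagonal variance exceeds 1/N and the
        # shrinkage factor is meaningfully below 1
        cohort = simulate_null_cohort(40, 40, {"1": 500}, seed=8, fst=0.1)
        grm = compute_grm(cohort.genotypes)
        once = adjust_grm_ld(grm, c=0.0)
        twice = adjust_grm_ld(once, c=0.0)
        assert not np.allclose(twice.values, once.values)

    def test_undefined_when_variance_too_small(self):
        ids = pd.DataFrame({"fid": ["F0", "F1"], "iid": ["I0", "I1"]})
        grm = GRM(np.eye(2), np.full((2, 2), 10.0), ids, n_snps=10)
        with pytest.raises(ValueError, match="undefined"):
            adjust_grm_ld(grm, c=0.0)


class TestPca:
    def test_two_subpopulations_separate_on_pc1(self):
        cohort = simulate_null_cohort(60, 60, {"1": 800}, seed=21, fst=0.05)
        grm = compute_grm(cohort.genotypes)
        pcs = grm_pca(grm, 2)
        group = (cohort.subpopulation == 1).astype(float)
        r = np.corrcoef(pcs.values[:, 0], group)[0, 1]
        assert abs(r) > 0.9
        assert pcs.values.shape[1] == 2 and pcs.names == ["PC1", "PC2"]

    def test_full_spectral_reconstruction(self):
        g = make_genotypes(15, 100, seed=2)
        grm = compute_grm(g)
        eigvals, eigvecs = np.linalg.eigh(grm.values)
        np.testing.assert_allclose(
            (eigvecs * eigvals) @ eigvecs.T, grm.values, atol=1e-10)

    def test_sign_convention_deterministic(self):
        g = make_genotypes(12, 60, seed=4)
        grm = compute_grm(g)
        pcs = grm_pca(grm, 3)
        for j in range(3):
            col = pcs.values[:, j]
            assert col[np.argmax(np.abs(col))] > 0
            assert np.linalg.norm(col) == pytest.approx(1.0)
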