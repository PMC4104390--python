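"""Genetic relationship matrix estimation, LD adjustment, and PCA.

The GRM follows the GREML definition: genotypes are centered and scaled by
sample-estimated allele frequencies, and relatedness between individuals j
and k is the average over SNPs non-missing in both of

    A_jk = (1/N_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with the GCTA-specific diagonal

    A_jj = 1 + (1/N_jj) * sum_i [x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2]
                               / (2 p_i (1 - p_i)),

which has expectation 1 under Hardy-Weinberg at the estimated frequency.
Allele frequencies are estimated from the pooled analysis sample (cases and
controls together), matching standard practice for case-control GREML.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .containers import GRM, MISSING, CovariateMatrix, GenotypeMatrix

log = logging.getLogger(__name__)


def allele_frequencies(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP frequency of the counted (A1) allele over non-missing genotypes.

    Returns a frame with columns ``snp_id, freq, n_obs``.  A SNP with no
    non-missing genotypes is an error (it cannot be centered or scaled).
    """
    dos = genotypes.dosages
    observed = dos != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = genotypes.snp_meta["snp_id"].iloc[int(np.argmin(n_obs))]
        raise ValueError(f"SNP {bad!r} has no non-missing genotypes")
    sums = np.where(observed, dos, 0).sum(axis=0, dtype=np.int64)
    return pd.DataFrame({
        "snp_id": genotypes.snp_meta["snp_id"].to_numpy(),
        "freq": sums / (2.0 * n_obs),
        "n_obs": n_obs,
    })


def compute_grm(genotypes: GenotypeMatrix, freqs: pd.DataFrame | None = None,
                maf_min: float = 0.01, snp_subset: np.ndarray | None = None,
                chroms=None, exclude_chroms=None) -> GRM:
    """Estimate the GRM from dosages, handling missingness per pair.

    Parameters
    ----------
    freqs
        Optional precomputed table from :func:`allele_frequencies`; computed
        from ``genotypes`` when omitted.
    maf_min
        SNPs with minor allele frequency below this (or monomorphic SNPs)
        are excluded; the count is logged.
    snp_subset
        Boolean mask (or index array) restricting the SNP set, e.g. a single
        chromosome; combined with the MAF filter.
    chroms, exclude_chroms
        Convenience chromosome include/exclude selectors (mutually
        exclusive with each other; intersected with ``snp_subset``).
    """
    mask = genotypes.chromosome_mask(chroms, exclude_chroms)
    if snp_subset is not None:
        snp_subset = np.asarray(snp_subset)
        if snp_subset.dtype == bool:
            mask &= snp_subset
        else:
            keep = np.zeros(genotypes.n_snps, dtype=bool)
            keep[snp_subset] = True
            mask &= keep

    if freqs is None:
        freqs = allele_frequencies(genotypes)
    p = np.asarray(freqs["freq"], dtype=np.float64)
    if len(p) != genotypes.n_snps:
        raise ValueError("frequency table length does not match SNP count")

    maf = np.minimum(p, 1.0 - p)
    poly = maf >= max(maf_min, np.finfo(float).tiny)
    n_dropped = int((mask & ~poly).sum())
    if n_dropped:
        log.info("GRM: excluding %d SNPs with MAF < %g or monomorphic", n_dropped, maf_min)
    mask = mask & poly
    m = int(mask.sum())
    if m == 0:
        raise ValueError("no SNPs left after MAF/subset filtering")

    dos = genotypes.dosages[:, mask].astype(np.float64)
    p = p[mask]
    observed = dos != MISSING
    dos[~observed] = 0.0

    denom = 2.0 * p * (1.0 - p)
    # Off-diagonal numerator: standardized cross-products, missing -> 0.
    w = np.where(observed, (dos - 2.0 * p) / np.sqrt(denom), 0.0)
    numer = w @ w.T
    pair_counts = observed.astype(np.float64) @ observed.T.astype(np.float64)
    if (pair_counts == 0).any():
        raise ValueError("some individual pair shares no non-missing SNP")

    values = numer / pair_counts
    # GCTA diagonal: 1 + mean of [x^2 - (1+2p)x + 2p^2] / (2p(1-p)).
    diag_terms = np.where(observed, (dos * dos - (1.0 + 2.0 * p) * dos + 2.0 * p * p) / denom, 0.0)
    np.fill_diagonal(values, 1.0 + diag_terms.sum(axis=1) / np.diag(pair_counts))

    return GRM(values=values, pair_counts=pair_counts,
               sample_ids=genotypes.sample_ids, n_snps=m)


def adjust_grm_ld(grm: GRM, c: float = 0.0) -> GRM:
    """Shrink the GRM toward its expectation to correct prediction errors
    from imperfect linkage disequilibrium between genotyped and causal SNPs.

    The off-diagonal entries are scaled by ``beta = 1 - (c + 1/N) / var(A_jk)``
    (N = number of SNPs, variance over the off-diagonal entries) and the
    diagonal is moved toward 1 by the same factor.  ``c = 0`` reproduces the
    default of the GCTA ``--grm-adj 0`` option.  Not idempotent: re-applying
    the adjustment shrinks again.
    """
    if not grm.n_snps:
        raise ValueError("GRM does not record the SNP count N needed for the adjustment")
    off = grm.values[~np.eye(grm.n, dtype=bool)]
    var_off = float(np.var(off))
    noise = c + 1.0 / grm.n_snps
    if var_off <= noise:
        raise ValueError(
            f"off-diagonal variance {var_off:.3e} <= c + 1/N = {noise:.3e}; "
            "LD adjustment undefined"
        )
    beta = 1.0 - noise / var_off
    values = beta * grm.values
    np.fill_diagonal(values, 1.0 + beta * (np.diag(grm.values) - 1.0))
    return GRM(values=values, pair_counts=grm.pair_counts.copy(),
               sample_ids=grm.sample_ids, n_snps=grm.n_snps)


def grm_pca(grm: GRM, k: int) -> CovariateMatrix:
    """Top-``k`` principal components of the GRM as covariates.

    Eigenvectors of the relatedness matrix in descending eigenvalue order,
    each with unit norm and a deterministic sign (the largest-magnitude
    loading is made positive).
    """
    n = grm.n
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if not np.isfinite(grm.values).all():
        raise ValueError("GRM contains non-finite entries")
    eigvals, eigvecs = eigh(grm.values, subset_by_index=(n - k, n - 1))
    order = np.argsort(eigvals)[::-1]
    vecs = eigvecs[:, order]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return CovariateMatrix(sample_ids=grm.sample_ids, values=vecs,
                           names=[f"PC{i + 1}" for i in range(k)])
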