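"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are additive dosages of the counted allele (the bim A1 allele),
  stored as ``int8`` with values in {0, 1, 2} and :data:`MISSING` (-1) as the
  missing sentinel.  Missing genotypes are never imputed here; downstream
  code handles them per SNP pair.
* Samples are identified by the (family_id, individual_id) pair, as in PLINK
  ``.fam`` files; alignment between containers is always by exact id match,
  never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-genotype sentinel (PLINK's "missing" 2-bit code maps here).
MISSING: int = -1

SNP_META_COLUMNS = ["chrom", "snp_id", "pos", "a1", "a2"]


class IdAlignmentError(ValueError):
    """Sample ids of two containers do not match."""


def _check_ids(sample_ids: pd.DataFrame, n: int, what: str) -> pd.DataFrame:
    sample_ids = pd.DataFrame(sample_ids)
    if list(sample_ids.columns) != ["fid", "iid"]:
        if sample_ids.shape[1] != 2:
            raise ValueError(f"{what}: sample_ids needs exactly fid and iid columns")
        sample_ids = sample_ids.set_axis(["fid", "iid"], axis=1)
    sample_ids = sample_ids.astype(str).reset_index(drop=True)
    if len(sample_ids) != n:
        raise ValueError(f"{what}: {len(sample_ids)} sample ids for {n} rows")
    if sample_ids.duplicated().any():
        raise ValueError(f"{what}: duplicate (fid, iid) pairs")
    return sample_ids


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP and sample metadata.

    Attributes
    ----------
    dosages
        ``(n_individuals, n_snps)`` int8 array; entries in {0, 1, 2, MISSING}.
    snp_meta
        One row per SNP with columns ``chrom, snp_id, pos, a1, a2``.
    sample_ids
        One row per individual with columns ``fid, iid``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise ValueError(f"invalid dosage values {bad!r}; expected 0/1/2/{MISSING}")
        self.snp_meta = pd.DataFrame(self.snp_meta).reset_index(drop=True)
        missing_cols = set(SNP_META_COLUMNS) - set(self.snp_meta.columns)
        if missing_cols:
            raise ValueError(f"snp_meta missing columns {sorted(missing_cols)}")
        self.snp_meta = self.snp_meta[SNP_META_COLUMNS].astype(
            {"chrom": str, "snp_id": str, "pos": np.int64, "a1": str, "a2": str}
        )
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError("snp_meta length does not match dosage columns")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_ids")
        self.sample_ids = _check_ids(self.sample_ids, self.dosages.shape[0], "GenotypeMatrix")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Restrict to SNP columns selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            snp_meta=self.snp_meta.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
            sample_ids=self.sample_ids,
        )

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Restrict to the individuals selected by an index or boolean array."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            snp_meta=self.snp_meta,
            sample_ids=self.sample_ids.iloc[idx],
        )

    def chromosome_mask(self, chroms=None, exclude=None) -> np.ndarray:
        """Boolean SNP mask for a chromosome include/exclude set."""
        labels = self.snp_meta["chrom"].to_numpy()
        if chroms is not None and exclude is not None:
            raise ValueError("give chroms or exclude, not both")
        if chroms is not None:
            return np.isin(labels, [str(c) for c in np.atleast_1d(chroms)])
        if exclude is not None:
            return ~np.isin(labels, [str(c) for c in np.atleast_1d(exclude)])
        return np.ones(self.n_snps, dtype=bool)


@dataclass
class PhenotypeVector:
    """Binary case/control status (1 = case, 0 = control) on the observed scale."""

    sample_ids: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("phenotype values must be a vector")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("phenotype values must be 0 (control) or 1 (case)")
        self.sample_ids = _check_ids(self.sample_ids, len(self.values), "PhenotypeVector")

    @property
    def n_cases(self) -> int:
        return int(self.values.sum())

    @property
    def n_controls(self) -> int:
        return int((self.values == 0).sum())

    @property
    def case_proportion(self) -> float:
        return self.n_cases / len(self.values)


@dataclass
class CovariateMatrix:
    """Quantitative fixed-effect covariates (e.g. principal components)."""

    sample_ids: pd.DataFrame
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2:
            raise ValueError("covariates must be 2-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("covariates contain missing/non-finite values")
        if not self.names:
            self.names = [f"c{i + 1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length does not match covariate columns")
        self.sample_ids = _check_ids(self.sample_ids, self.values.shape[0], "CovariateMatrix")


@dataclass
class GRM:
    """Genetic relationship matrix with per-pair non-missing SNP counts.

    ``values[j, k]`` is the realized-relatedness coefficient A_jk; the
    matching ``pair_counts[j, k]`` is the number of SNPs non-missing in both
    j and k that entered the average.  ``n_snps`` is the number of SNPs the
    matrix was built from (after any MAF filtering), needed by the
    imperfect-LD adjustment.
    """

    values: np.ndarray
    pair_counts: np.ndarray
    sample_ids: pd.DataFrame
    n_snps: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.pair_counts = np.asarray(self.pair_counts)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.pair_counts.shape != (n, n):
            raise ValueError("GRM values and pair_counts must be square and congruent")
        if not np.isfinite(self.values).all():
            raise ValueError("GRM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM is not symmetric")
        self.sample_ids = _check_ids(self.sample_ids, n, "GRM")
        if self.n_snps is None:
            self.n_snps = int(self.pair_counts.max()) if n else 0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def align_samples(reference_ids: pd.DataFrame, other_ids: pd.DataFrame,
                  allow_subset: bool = False, what: str = "samples") -> np.ndarray:
    """Indices into ``other_ids`` that reorder it to match ``reference_ids``.

    Matching is by exact (fid, iid) pair and order independent.  Ids present
    in the reference but absent from the other container raise
    :class:`IdAlignmentError`; extra ids in the other container are an error
    unless ``allow_subset`` is true.
    """
    ref = pd.MultiIndex.from_frame(reference_ids.astype(str))
    oth = pd.MultiIndex.from_frame(pd.DataFrame(other_ids).astype(str))
    idx = oth.get_indexer(ref)
    if (idx < 0).any():
        missing = [tuple(t) for t, i in zip(ref, idx) if i < 0][:5]
        raise IdAlignmentError(f"{what}: ids missing from the second container: {missing}")
    if not allow_subset and len(oth) != len(ref):
        raise IdAlignmentError(
            f"{what}: {len(oth)} ids where {len(ref)} expected "
            "(pass allow_subset=True to drop the extras)"
        )
    return idx
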