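"""Readers and writers for the standard file formats the pipeline touches.

PLINK v1 binary genotypes (``.bed``/``.bim``/``.fam``), GCTA binary GRMs
(``.grm.bin``/``.grm.N.bin``/``.grm.id``) and GCTA-style whitespace-delimited
phenotype (``.phen``) and quantitative-covariate (``.qcovar``) files.

PLINK v1 ``.bed`` layout (SNP-major): three header bytes ``6C 1B 01``, then
``ceil(n/4)`` bytes per SNP, two bits per individual, least-significant pair
first.  The 2-bit codes are::

    00  homozygous A1   -> dosage 2 (of the counted A1 allele)
    01  missing         -> MISSING
    10  heterozygous    -> dosage 1
    11  homozygous A2   -> dosage 0

GCTA GRM binary files store the lower triangle including the diagonal,
row-major over individuals, as 4-byte little-endian floats; ``.grm.N.bin``
stores the per-pair non-missing SNP counts in the same order, and
``.grm.id`` the (family id, individual id) pairs, one per line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GRM, MISSING, CovariateMatrix, GenotypeMatrix, PhenotypeVector

log = logging.getLogger(__name__)

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

# 2-bit code -> dosage of the A1 allele.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage (index 0,1,2; MISSING handled separately) -> 2-bit code
_DOSAGE_TO_CODE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}


class FormatError(ValueError):
    """File does not follow the expected binary format."""


class ConsistencyError(ValueError):
    """Files of a set disagree about dimensions."""


# ---------------------------------------------------------------------------
# PLINK v1 triples
# ---------------------------------------------------------------------------

def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK v1 triple into a :class:`GenotypeMatrix`.

    Accepts either a single path prefix (``prefix.bed`` etc.) or the three
    explicit paths.  Dosages count the bim A1 allele.
    """
    if bim_path is None and fam_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    else:
        bed_path = str(prefix_or_bed)

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phe"], dtype=str,
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed_path}: missing PLINK v1 magic/SNP-major header bytes")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != m * bytes_per_snp:
        raise ConsistencyError(
            f"{bed_path}: {body.size} data bytes but bim/fam imply "
            f"{m} SNPs x {bytes_per_snp} bytes"
        )

    if m == 0 or n == 0:
        dosages = np.zeros((n, m), dtype=np.int8)
    else:
        blocks = body.reshape(m, bytes_per_snp)
        codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
        for shift in range(4):  # LSB pair first
            codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
        dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # -> individuals x SNPs

    return GenotypeMatrix(
        dosages=dosages,
        snp_meta=bim[["chrom", "snp_id", "pos", "a1", "a2"]],
        sample_ids=fam[["fid", "iid"]],
    )


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write a PLINK v1 triple (SNP-major ``.bed`` plus ``.bim``/``.fam``)."""
    prefix = str(prefix)
    n, m = genotypes.n_individuals, genotypes.n_snps
    bytes_per_snp = (n + 3) // 4

    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0b01  # pad slots beyond n carry the missing code (ignored on read)
    dos = genotypes.dosages.T  # SNP-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[:, :n][dos == dosage] = code
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= codes[:, shift::4] << (2 * shift)

    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)

    bim = genotypes.snp_meta.copy()
    bim.insert(2, "cm", 0)
    bim[["chrom", "snp_id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix + ".bim", sep="\t", header=False, index=False
    )
    fam = genotypes.sample_ids.copy()
    for col, val in (("father", "0"), ("mother", "0"), ("sex", "0"), ("phe", "-9")):
        fam[col] = val
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GCTA GRM binaries
# ---------------------------------------------------------------------------

def _tril_order(n: int):
    """Row/col indices in GCTA storage order: (0,0),(1,0),(1,1),(2,0),..."""
    rows, cols = np.tril_indices(n)
    order = np.lexsort((cols, rows))
    return rows[order], cols[order]


def read_grm_gcta(prefix) -> GRM:
    """Read a GCTA binary GRM (``prefix.grm.bin``/``.grm.N.bin``/``.grm.id``)."""
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None,
                      names=["fid", "iid"], dtype=str)
    n = len(ids)
    n_entries = n * (n + 1) // 2

    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if vals.size != n_entries:
        raise ConsistencyError(
            f"{prefix}.grm.bin holds {vals.size} float32 values; "
            f"{n} ids require {n_entries}"
        )
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    if counts.size != n_entries:
        raise ConsistencyError(
            f"{prefix}.grm.N.bin holds {counts.size} values; expected {n_entries}"
        )

    rows, cols = _tril_order(n)
    values = np.zeros((n, n), dtype=np.float64)
    values[rows, cols] = vals
    values[cols, rows] = vals
    pair_counts = np.zeros((n, n), dtype=np.float64)
    pair_counts[rows, cols] = counts
    pair_counts[cols, rows] = counts
    return GRM(values=values, pair_counts=pair_counts, sample_ids=ids)


def write_grm_gcta(grm: GRM, prefix) -> None:
    """Write a GRM in GCTA binary format (float32 lower triangle)."""
    prefix = str(prefix)
    rows, cols = _tril_order(grm.n)
    grm.values[rows, cols].astype("<f4").tofile(prefix + ".grm.bin")
    np.asarray(grm.pair_counts, dtype=np.float64)[rows, cols].astype("<f4").tofile(
        prefix + ".grm.N.bin"
    )
    grm.sample_ids.to_csv(prefix + ".grm.id", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phenotype / covariate text files (FID IID value...)
# ---------------------------------------------------------------------------

def _read_id_value_table(path, min_value_cols: int) -> tuple[pd.DataFrame, np.ndarray]:
    path = Path(path)
    ids, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2 + min_value_cols:
                raise ValueError(f"{path}:{lineno}: expected at least "
                                 f"{2 + min_value_cols} columns, got {len(parts)}")
            try:
                values = [float(v) for v in parts[2:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            ids.append(parts[:2])
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (value column counts {sorted(widths)})")
    return (pd.DataFrame(ids, columns=["fid", "iid"]), np.asarray(rows, dtype=np.float64))


def read_phenotype(path) -> PhenotypeVector:
    """Read a GCTA-style ``.phen`` file (FID IID status).

    Accepts both {0,1} and PLINK-style {1,2} case/control codings; a {1,2}
    file is normalized to {0,1} with a logged notice.
    """
    ids, values = _read_id_value_table(path, min_value_cols=1)
    status = values[:, 0]
    uniq = set(np.unique(status).tolist())
    if uniq <= {0.0, 1.0}:
        pass
    elif uniq <= {1.0, 2.0} and 2.0 in uniq:
        log.info("%s: phenotype coded {1,2}; normalizing to {0,1} (2 -> case)", path)
        status = status - 1.0
    else:
        raise ValueError(f"{path}: phenotype values {sorted(uniq)} are neither "
                         "{0,1} nor {1,2} coded")
    return PhenotypeVector(sample_ids=ids, values=status.astype(np.int8))


def write_phenotype(phenotype: PhenotypeVector, path) -> None:
    df = phenotype.sample_ids.copy()
    df["phe"] = phenotype.values
    df.to_csv(path, sep="\t", header=False, index=False)


def read_covariates(path) -> CovariateMatrix:
    """Read a GCTA-style ``.qcovar`` file (FID IID c1 c2 ...)."""
    ids, values = _read_id_value_table(path, min_value_cols=1)
    return CovariateMatrix(sample_ids=ids, values=values)


def write_covariates(covariates: CovariateMatrix, path) -> None:
    df = covariates.sample_ids.copy()
    for i, name in enumerate(covariates.names):
        df[name] = covariates.values[:, i]
    df.to_csv(path, sep="\t", header=False, index=False)
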