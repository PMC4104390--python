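"""Synthetic case-control cohorts with a liability-threshold architecture.

The generator emulates the statistical structure a GREML case-control
analysis assumes: biallelic common SNPs spread over chromosomes, a latent
liability that is the sum of a genetic component (from standardized causal
dosages) and a normal residual, case status by thresholding the liability
at the prevalence K, and ascertained sampling of cases and controls at a
chosen ratio (1:3 by default, the design of small pharmacogenetic cohorts).

Causal placement is controlled per chromosome, so a cohort can concentrate
all of its heritability on one chromosome — mimicking a major-effect HLA
region on chromosome 6 — or split it between a focal chromosome and the
rest of the genome.

Ascertainment is by rejection: individuals are simulated from the
population model until the case quota fills, so case genotype distributions
are exactly those of the threshold model rather than a truncated-liability
approximation.  Only causal dosages are generated during rejection (the
liability depends on nothing else); non-causal dosages are drawn afterwards
for the retained individuals only, which is distributionally identical and
keeps very low prevalences tractable.

A single integer seed drives five named RNG streams (frequencies,
genotypes, effects, residuals, missingness), so e.g. toggling missingness
does not perturb the genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix, PhenotypeVector
from .io import write_phenotype, write_plink
from .liability import liability_threshold

_STREAMS = ("frequencies", "genotypes", "effects", "residuals", "missingness")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


@dataclass
class SimulationConfig:
    """Parameters of one simulated ascertained case-control cohort.

    ``causal_spec`` maps a chromosome label to ``(n_causal, h2_share)``;
    the shares must sum to ``h2_true`` (they partition the liability-scale
    heritability across chromosomes).  ``prevalence_K`` is the population
    prevalence of the trait; the sampled cohort has ``n_cases`` cases and
    ``round(case_control_ratio * n_cases)`` controls.  ``fst`` > 0 switches
    on a two-subpopulation Balding-Nichols structure model.
    """

    n_snps_per_chrom: dict[str, int]
    h2_true: float
    prevalence_K: float
    n_cases: int
    causal_spec: dict[str, tuple[int, float]] = field(default_factory=dict)
    maf_range: tuple[float, float] = (0.05, 0.5)
    case_control_ratio: float = 3.0
    fst: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    max_simulated: int = 10_000_000  # rejection-sampling cap

    def __post_init__(self) -> None:
        self.n_snps_per_chrom = {str(k): int(v) for k, v in self.n_snps_per_chrom.items()}
        if any(v <= 0 for v in self.n_snps_per_chrom.values()):
            raise ValueError("SNP counts must be positive")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")
        if not 0.0 < self.prevalence_K < 0.5:
            raise ValueError("prevalence_K must lie in (0, 0.5)")
        if self.n_cases <= 0 or self.case_control_ratio <= 0:
            raise ValueError("n_cases and case_control_ratio must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        self.causal_spec = {str(k): (int(n), float(s)) for k, (n, s) in self.causal_spec.items()}
        for chrom, (n_causal, share) in self.causal_spec.items():
            if chrom not in self.n_snps_per_chrom:
                raise ValueError(f"causal_spec chromosome {chrom!r} has no SNPs")
            if not 0 < n_causal <= self.n_snps_per_chrom[chrom]:
                raise ValueError(f"chromosome {chrom!r}: n_causal {n_causal} out of range")
            if share < 0:
                raise ValueError("h2 shares must be non-negative")
        total_share = sum(s for _, s in self.causal_spec.values())
        if self.causal_spec and abs(total_share - self.h2_true) > 1e-9:
            raise ValueError(
                f"h2 shares sum to {total_share}, must equal h2_true={self.h2_true}"
            )
        if not self.causal_spec and self.h2_true > 0:
            raise ValueError("h2_true > 0 requires a causal_spec")

    @property
    def n_controls(self) -> int:
        return int(round(self.case_control_ratio * self.n_cases))

    def to_dict(self) -> dict:
        return {
            "n_snps_per_chrom": self.n_snps_per_chrom,
            "h2_true": self.h2_true,
            "prevalence_K": self.prevalence_K,
            "n_cases": self.n_cases,
            "causal_spec": {k: list(v) for k, v in self.causal_spec.items()},
            "maf_range": list(self.maf_range),
            "case_control_ratio": self.case_control_ratio,
            "fst": self.fst,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON) file mirroring the fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "causal_spec" in raw:
            raw["causal_spec"] = {k: tuple(v) for k, v in raw["causal_spec"].items()}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector
    liabilities: np.ndarray | None
    true_effects: pd.DataFrame  # columns snp_id, chrom, beta (standardized scale)
    config: dict
    subpopulation: np.ndarray | None = None  # per-individual 0/1 when fst > 0


def _snp_layout(n_snps_per_chrom: dict[str, int]) -> pd.DataFrame:
    frames = []
    for chrom, m in n_snps_per_chrom.items():
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "snp_id": [f"chr{chrom}_snp{i + 1}" for i in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A", "a2": "G",
        }))
    return pd.concat(frames, ignore_index=True)


def _subpop_frequencies(p_anc: np.ndarray, fst: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols per-subpopulation frequencies (2 x n_snps)."""
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b, size=(2, p_anc.size)), 1e-4, 1.0 - 1e-4)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate one ascertained case-control cohort under the liability model.

    Raises if the expected number of individuals needed to fill the case
    quota exceeds ``config.max_simulated`` (raise the cap or the prevalence).
    """
    expected = config.n_cases / config.prevalence_K
    if expected > config.max_simulated:
        raise ValueError(
            f"filling {config.n_cases} cases at K={config.prevalence_K} needs about "
            f"{expected:.0f} simulated individuals, above the cap "
            f"{config.max_simulated}; raise max_simulated or the prevalence"
        )

    rng = _rng_streams(config.seed)
    meta = _snp_layout(config.n_snps_per_chrom)
    m_total = len(meta)
    lo, hi = config.maf_range
    p_anc = rng["frequencies"].uniform(lo, hi, size=m_total)
    p_sub = _subpop_frequencies(p_anc, config.fst, rng["frequencies"]) \
        if config.fst > 0 else None

    # Causal placement and effect sizes on the standardized-dosage scale;
    # each chromosome's effects are normalized so its genetic-liability
    # variance equals its h2 share exactly.
    causal_idx, betas = [], []
    chrom_labels = meta["chrom"].to_numpy()
    for chrom, (n_causal, share) in config.causal_spec.items():
        chrom_positions = np.flatnonzero(chrom_labels == chrom)
        chosen = rng["effects"].choice(chrom_positions, size=n_causal, replace=False)
        raw = rng["effects"].standard_normal(n_causal)
        scale = np.sqrt(share) / np.linalg.norm(raw) if share > 0 else 0.0
        order = np.argsort(chosen)
        causal_idx.append(chosen[order])
        betas.append(raw[order] * scale)
    if causal_idx:
        causal_idx = np.concatenate(causal_idx)
        betas = np.concatenate(betas)
    else:
        causal_idx = np.empty(0, dtype=int)
        betas = np.empty(0)

    t, _ = liability_threshold(config.prevalence_K)
    sd_resid = np.sqrt(max(1.0 - config.h2_true, 0.0))
    p_causal_anc = p_anc[causal_idx]
    z_scale = np.sqrt(2.0 * p_causal_anc * (1.0 - p_causal_anc)) if causal_idx.size else None

    need_cases, need_controls = config.n_cases, config.n_controls
    kept_dos, kept_liab, kept_case, kept_sub = [], [], [], []
    got_cases = got_controls = simulated = cases_seen = 0
    batch = min(max(4096, config.n_cases * 4), 200_000)
    while got_cases < need_cases or got_controls < need_controls:
        if simulated >= config.max_simulated:
            raise ValueError(
                f"rejection sampling exceeded the cap of {config.max_simulated} "
                f"individuals with {got_cases}/{need_cases} cases accrued; "
                "raise max_simulated or the prevalence"
            )
        b = int(min(batch, config.max_simulated - simulated))
        sub = rng["genotypes"].integers(0, 2, size=b) if config.fst > 0 else None
        if causal_idx.size:
            freq = (p_sub[sub][:, causal_idx] if config.fst > 0
                    else np.broadcast_to(p_causal_anc, (b, causal_idx.size)))
            dos = rng["genotypes"].binomial(2, freq).astype(np.int8)
            g = ((dos - 2.0 * p_causal_anc) / z_scale) @ betas
        else:
            dos = np.zeros((b, 0), dtype=np.int8)
            g = np.zeros(b)
        liab = g + rng["residuals"].normal(0.0, sd_resid, size=b)
        is_case = liab > t
        keep = (is_case & (got_cases + np.cumsum(is_case) <= need_cases)) | \
               (~is_case & (got_controls + np.cumsum(~is_case) <= need_controls))
        kept_dos.append(dos[keep])
        kept_liab.append(liab[keep])
        kept_case.append(is_case[keep])
        if sub is not None:
            kept_sub.append(sub[keep])
        got_cases += int((is_case & keep).sum())
        got_controls += int((~is_case & keep).sum())
        cases_seen += int(is_case.sum())
        simulated += b

    causal_dos = np.concatenate(kept_dos)
    liabilities = np.concatenate(kept_liab)
    status = np.concatenate(kept_case).astype(np.int8)
    subpop = np.concatenate(kept_sub) if kept_sub else None
    n = len(status)

    # Non-causal dosages for the retained individuals only.
    dosages = np.empty((n, m_total), dtype=np.int8)
    noncausal = np.setdiff1d(np.arange(m_total), causal_idx)
    if noncausal.size:
        freq = (p_sub[subpop][:, noncausal] if config.fst > 0
                else np.broadcast_to(p_anc[noncausal], (n, noncausal.size)))
        dosages[:, noncausal] = rng["genotypes"].binomial(2, freq).astype(np.int8)
    dosages[:, causal_idx] = causal_dos

    if config.missing_rate > 0:
        mask = rng["missingness"].random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    ids = pd.DataFrame({"fid": [f"F{i + 1}" for i in range(n)],
                        "iid": [f"I{i + 1}" for i in range(n)]})
    genotypes = GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=ids)
    phenotype = PhenotypeVector(sample_ids=ids, values=status)
    effects = pd.DataFrame({
        "snp_id": meta["snp_id"].iloc[causal_idx].to_numpy(),
        "chrom": meta["chrom"].iloc[causal_idx].to_numpy(),
        "beta": betas,
    })
    echo = config.to_dict()
    # pre-ascertainment bookkeeping: cases_seen / n_simulated estimates K
    echo["n_simulated"] = simulated
    echo["n_cases_seen"] = cases_seen
    return SimulatedCohort(genotypes=genotypes, phenotype=phenotype,
                           liabilities=liabilities, true_effects=effects,
                           config=echo, subpopulation=subpop)


def simulate_null_cohort(n_group_a: int, n_group_b: int,
                         n_snps_per_chrom: dict[str, int], seed: int,
                         fst: float = 0.0,
                         maf_range: tuple[float, float] = (0.05, 0.5)) -> SimulatedCohort:
    """Cohort whose case/control labels are independent of genotype.

    Emulates the controls-coded-as-cases negative control: group A
    (labelled cases) and group B (labelled controls) are drawn from the same
    homogeneous population, so any nonzero heritability estimate reflects an
    artifact of the pipeline, not signal.  With ``fst`` > 0 the two groups
    come from two differentiated subpopulations instead, producing a
    structure-confounded null for exercising PC adjustment.
    """
    if n_group_a <= 0 or n_group_b <= 0:
        raise ValueError("group sizes must be positive")
    rng = _rng_streams(seed)
    meta = _snp_layout({str(k): v for k, v in n_snps_per_chrom.items()})
    m = len(meta)
    n = n_group_a + n_group_b
    lo, hi = maf_range
    p_anc = rng["frequencies"].uniform(lo, hi, size=m)

    if fst > 0:
        p_sub = _subpop_frequencies(p_anc, fst, rng["frequencies"])
        subpop = np.concatenate([np.zeros(n_group_a, dtype=int),
                                 np.ones(n_group_b, dtype=int)])
        dosages = rng["genotypes"].binomial(2, p_sub[subpop]).astype(np.int8)
    else:
        subpop = None
        dosages = rng["genotypes"].binomial(
            2, np.broadcast_to(p_anc, (n, m))).astype(np.int8)

    status = np.concatenate([np.ones(n_group_a, dtype=np.int8),
                             np.zeros(n_group_b, dtype=np.int8)])
    ids = pd.DataFrame({"fid": [f"F{i + 1}" for i in range(n)],
                        "iid": [f"I{i + 1}" for i in range(n)]})
    return SimulatedCohort(
        genotypes=GenotypeMatrix(dosages=dosages, snp_meta=meta, sample_ids=ids),
        phenotype=PhenotypeVector(sample_ids=ids, values=status),
        liabilities=None,
        true_effects=pd.DataFrame(columns=["snp_id", "chrom", "beta"]),
        config={"design": "null", "n_group_a": n_group_a, "n_group_b": n_group_b,
                "n_snps_per_chrom": {str(k): v for k, v in n_snps_per_chrom.items()},
                "fst": fst, "seed": seed},
        subpopulation=subpop,
    )


def save_cohort(cohort: SimulatedCohort, prefix) -> None:
    """Write a cohort as a PLINK triple, a ``.phen`` file and a JSON sidecar
    holding the generating parameters and true effects."""
    prefix = str(prefix)
    write_plink(cohort.genotypes, prefix)
    write_phenotype(cohort.phenotype, prefix + ".phen")
    sidecar = {
        "config": cohort.config,
        "true_effects": cohort.true_effects.to_dict(orient="list"),
    }
    Path(prefix + ".truth.json").write_text(json.dumps(sidecar, indent=2))
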