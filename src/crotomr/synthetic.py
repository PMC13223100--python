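"""Seeded synthetic-data generators emulating the statistical structure of
every pipeline input: GWAS/eQTL summary-statistics pairs with configurable
pleiotropy and LD-block structure, three-trait mediation chains with a known
mediated proportion, spot-level spatial sections with Dirichlet cell-type
fractions, and clinical cohorts with exponential survival.

Every generator is a pure function of its seed and configuration. Binary-
outcome effects are generated directly on the log-odds scale — the form the
outcome GWAS reports — with per-variant standard errors shrinking as
1/sqrt(2·maf·(1-maf)·n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .clinical import PatientRecord
from .instruments import LDMatrix
from .spatial import TUMOR_KEY, SpotRecord, partition_regions
from .sumstats import SummaryDataset, VariantAssociation

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass(frozen=True)
class SyntheticMRConfig:
    """Generator settings for one exposure/outcome summary-statistics pair.

    ``theta`` is the true causal effect on the log-odds scale;
    ``pleiotropy`` the (mean, sd) of per-variant direct effects on the
    outcome (balanced when mean = 0); ``inside`` keeps those direct effects
    independent of instrument strength. Sample sizes follow the source
    cohorts the generator emulates: a blood cis-eQTL panel of ~30,000 for
    the exposure and a case-control effective size of ~15,000 for the
    outcome.
    """

    seed: int = 0
    k: int = 10
    theta: float = 0.173
    exposure_effect_dist: tuple = (0.15, 0.05)
    exposure_n: float = 30_000.0
    outcome_n: float = 15_000.0
    pleiotropy: tuple = (0.0, 0.0)
    inside: bool = True
    ld_blocks: tuple = ()  # sequence of (block_size, within_block_r2)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.exposure_effect_dist[1] < 0 or self.pleiotropy[1] < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticChainConfig:
    """Generator settings for an exposure → mediator → outcome chain.

    The implied total effect is ``direct + beta1 * beta2`` by construction,
    so the true mediated proportion is beta1*beta2 / total.
    """

    seed: int = 0
    beta1: float = -0.2      # exposure -> mediator
    beta2: float = -0.0865   # mediator -> outcome
    direct: float = 0.1557   # exposure -> outcome, not through the mediator
    k_exposure: int = 30
    k_mediator: int = 30
    exposure_n: float = 30_000.0
    mediator_n: float = 8_000.0
    outcome_n: float = 15_000.0

    @property
    def total(self) -> float:
        return self.direct + self.beta1 * self.beta2

    @property
    def proportion(self) -> float:
        return self.beta1 * self.beta2 / self.total


def _se_from_n(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300, 1.0)


def _records(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> list[VariantAssociation]:
    return [
        VariantAssociation(
            variant_id=ids[j], chromosome=chrom[j], position=int(pos[j]),
            effect_allele=ea[j], other_allele=oa[j], eaf=float(eaf[j]),
            beta=float(beta[j]), se=float(se[j]),
            pvalue=float(p), n=float(n),
        )
        for j, p in enumerate(_pvalues(beta, se))
    ]


def _ld_from_blocks(ids: list[str], blocks: Sequence[tuple]) -> LDMatrix:
    k = len(ids)
    r2 = np.eye(k)
    start = 0
    for size, rho2 in blocks:
        stop = min(start + size, k)
        r2[start:stop, start:stop] = rho2
        np.fill_diagonal(r2[start:stop, start:stop], 1.0)
        start = stop
        if start >= k:
            break
    return LDMatrix(variant_ids=list(ids), r2=r2)


def gen_sumstats_pair(cfg: SyntheticMRConfig):
    """Exposure/outcome summary statistics with known truth.

    Per variant j: true exposure effect b_Xj from the configured normal,
    observed with SE proportional to 1/sqrt(exposure_n); outcome effect
    theta*b_Xj + alpha_j observed with SE proportional to 1/sqrt(outcome_n);
    alpha_j from the pleiotropy distribution (correlated with b_Xj when
    ``inside`` is False). Returns (exposure, outcome, ld, truth dict); the
    truth records theta and the invalid-instrument mask (alpha_j != 0).
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom = [str(1 + j % 22) for j in range(k)]
    # instruments are generated pre-clumped: spread far apart
    pos = (1 + np.arange(k)) * 20_000_000
    allele_idx = rng.integers(0, len(_NONPALINDROMIC), size=k)
    ea = [_NONPALINDROMIC[i][0] for i in allele_idx]
    oa = [_NONPALINDROMIC[i][1] for i in allele_idx]
    maf = rng.uniform(0.05, 0.5, size=k)

    mu, sd = cfg.exposure_effect_dist
    bx_true = rng.normal(mu, sd, size=k)
    se_x = _se_from_n(maf, cfg.exposure_n)
    bx = bx_true + rng.normal(0.0, se_x)

    amu, asd = cfg.pleiotropy
    alpha = rng.normal(amu, asd, size=k) if (amu != 0 or asd > 0) else np.zeros(k)
    if not cfg.inside and asd > 0:
        # violate InSIDE: tie the direct effect to instrument strength
        alpha = amu + asd * (bx_true - mu) / max(sd, 1e-12)
    se_y = _se_from_n(maf, cfg.outcome_n)
    by = cfg.theta * bx_true + alpha + rng.normal(0.0, se_y)

    exposure = SummaryDataset("synthetic_exposure", "continuous",
                              _records(ids, chrom, pos, ea, oa, maf, bx, se_x, cfg.exposure_n),
                              source_tag=f"synthetic:seed={cfg.seed}")
    outcome = SummaryDataset("synthetic_outcome", "binary",
                             _records(ids, chrom, pos, ea, oa, maf, by, se_y, cfg.outcome_n),
                             source_tag=f"synthetic:seed={cfg.seed}")
    ld = _ld_from_blocks(ids, cfg.ld_blocks) if cfg.ld_blocks else _ld_from_blocks(ids, [])
    truth = {"theta": cfg.theta, "invalid_mask": (alpha != 0), "alpha": alpha,
             "bx_true": bx_true}
    return exposure, outcome, ld, truth


def gen_mediation_chain(cfg: SyntheticChainConfig):
    """Exposure, mediator and outcome summary statistics for a two-step
    mediation chain with known mediated proportion.

    The exposure's instruments affect the mediator through beta1 and the
    outcome through the total effect (direct + beta1*beta2); the mediator's
    own instruments affect the outcome through beta2. Returns (exposure,
    mediator, outcome, ld, truth dict).
    """
    rng = np.random.default_rng(cfg.seed)
    kx, km = cfg.k_exposure, cfg.k_mediator
    k = kx + km
    ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom = [str(1 + j % 22) for j in range(k)]
    pos = (1 + np.arange(k)) * 20_000_000
    allele_idx = rng.integers(0, len(_NONPALINDROMIC), size=k)
    ea = [_NONPALINDROMIC[i][0] for i in allele_idx]
    oa = [_NONPALINDROMIC[i][1] for i in allele_idx]
    maf = rng.uniform(0.05, 0.5, size=k)

    bx_true = np.zeros(k)
    bx_true[:kx] = rng.normal(0.15, 0.05, size=kx)     # exposure instruments
    bm_own = rng.normal(0.15, 0.05, size=km)           # mediator instruments

    # effects of every variant on each trait
    b_exposure = bx_true.copy()
    b_mediator = cfg.beta1 * bx_true
    b_mediator[kx:] = bm_own
    b_outcome = cfg.total * bx_true
    b_outcome[kx:] = cfg.beta2 * bm_own

    se_e = _se_from_n(maf, cfg.exposure_n)
    se_m = _se_from_n(maf, cfg.mediator_n)
    se_o = _se_from_n(maf, cfg.outcome_n)
    obs_e = b_exposure + rng.normal(0.0, se_e)
    obs_m = b_mediator + rng.normal(0.0, se_m)
    obs_o = b_outcome + rng.normal(0.0, se_o)

    exposure = SummaryDataset("synthetic_exposure", "continuous",
                              _records(ids[:kx], chrom[:kx], pos[:kx], ea[:kx], oa[:kx],
                                       maf[:kx], obs_e[:kx], se_e[:kx], cfg.exposure_n),
                              source_tag=f"synthetic:seed={cfg.seed}")
    mediator = SummaryDataset("synthetic_mediator", "continuous",
                              _records(ids, chrom, pos, ea, oa, maf, obs_m, se_m, cfg.mediator_n),
                              source_tag=f"synthetic:seed={cfg.seed}")
    outcome = SummaryDataset("synthetic_outcome", "binary",
                             _records(ids, chrom, pos, ea, oa, maf, obs_o, se_o, cfg.outcome_n),
                             source_tag=f"synthetic:seed={cfg.seed}")
    ld = _ld_from_blocks(ids, [])
    truth = {"beta1": cfg.beta1, "beta2": cfg.beta2, "direct": cfg.direct,
             "total": cfg.total, "proportion": cfg.proportion,
             "indirect": cfg.beta1 * cfg.beta2}
    return exposure, mediator, outcome, ld, truth


DEFAULT_CELL_TYPES = ("TumorCells", "Bcells", "TCells", "Myeloid",
                      "Fibroblasts", "Endothelial")


def gen_spatial_section(
    seed: int,
    n_spots: int = 400,
    types: Sequence[str] = DEFAULT_CELL_TYPES,
    tumor_enrichment: float = 1.0,
    tumor_region_frac: float = 0.5,
    baseline: float = 1.0,
    noise_sd: float = 0.3,
    section_id: str = "synthetic-section",
) -> list[SpotRecord]:
    """One spatial section of deconvolved spots with known structure.

    A ``tumor_region_frac`` share of spots lies in the malignant region
    (tumor fraction drawn within a Dirichlet composition over all types);
    the rest have an exactly-zero tumor fraction. Expression is
    baseline + tumor_enrichment x tumor fraction + normal noise, clipped at
    zero (log-normalized expression is non-negative).
    """
    rng = np.random.default_rng(seed)
    types = list(types)
    if TUMOR_KEY not in types:
        raise ValueError(f"types must include {TUMOR_KEY!r}")
    other = [t for t in types if t != TUMOR_KEY]
    spots = []
    grid = int(math.ceil(math.sqrt(n_spots)))
    in_tumor = rng.random(n_spots) < tumor_region_frac
    for i in range(n_spots):
        if in_tumor[i]:
            # tumor fraction tends to dominate inside the malignant region
            alloc = rng.dirichlet([4.0] + [1.0] * len(other))
            fractions = {TUMOR_KEY: float(alloc[0])}
            fractions.update({t: float(v) for t, v in zip(other, alloc[1:])})
        else:
            alloc = rng.dirichlet([1.0] * len(other))
            fractions = {TUMOR_KEY: 0.0}
            fractions.update({t: float(v) for t, v in zip(other, alloc)})
        expr = baseline + tumor_enrichment * fractions[TUMOR_KEY] + rng.normal(0.0, noise_sd)
        spots.append(SpotRecord(
            spot_id=f"spot-{i:04d}", section_id=section_id,
            x=float(i % grid), y=float(i // grid),
            expression=max(0.0, float(expr)), fractions=fractions,
        ))
    return partition_regions(spots)


DEFAULT_IRS_MIX = {
    # (intensity, proportion) -> probability; roughly the 33/27 low/high split
    (1, 1): 0.15, (1, 2): 0.15, (2, 2): 0.15, (1, 3): 0.10,
    (2, 3): 0.20, (3, 2): 0.10, (3, 3): 0.15,
}


def gen_cohort(
    seed: int,
    n: int = 60,
    hr: float = 2.5,
    censor_rate: float = 0.5,
    irs_mix: Optional[dict] = None,
    base_hazard: float = 0.02,
) -> list[PatientRecord]:
    """Clinical cohort with exponential survival and a group hazard ratio.

    IHC sub-scores are drawn from a categorical mixture over (intensity,
    proportion) pairs; survival times are exponential with hazard
    ``base_hazard`` (low group) or ``hr x base_hazard`` (high group), with
    independent exponential censoring tuned by ``censor_rate``. Other
    clinicopathological covariates are drawn independently (they carry no
    signal; the stage under test must not use them for survival).
    """
    rng = np.random.default_rng(seed)
    mix = irs_mix or DEFAULT_IRS_MIX
    combos = list(mix.keys())
    probs = np.array([mix[c] for c in combos], dtype=float)
    probs /= probs.sum()
    cohort = []
    for i in range(n):
        intensity, proportion = combos[rng.choice(len(combos), p=probs)]
        irs = intensity * proportion
        hazard = base_hazard * (hr if irs >= 6 else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / (base_hazard * censor_rate / max(1 - censor_rate, 1e-9)))
        time = min(t_event, t_cens)
        dead = t_event <= t_cens
        cohort.append(PatientRecord(
            patient_id=f"pt-{i:03d}",
            age=float(np.round(rng.normal(62, 10), 1)),
            sex=rng.choice(["male", "female"]),
            differentiation=rng.choice(["well", "moderate", "poor"], p=[0.3, 0.55, 0.15]),
            tnm_stage=rng.choice(["I", "II", "III", "IV"], p=[0.2, 0.3, 0.35, 0.15]),
            ln_metastasis=rng.choice(["no", "yes"], p=[0.65, 0.35]),
            distant_metastasis=rng.choice(["no", "yes"], p=[0.8, 0.2]),
            recurrence=rng.choice(["no", "yes"], p=[0.7, 0.3]),
            vital_status="dead" if dead else "alive",
            followup_months=float(time),
            intensity_score=int(intensity),
            proportion_score=int(proportion),
        ))
    return cohort
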