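"""Synthetic cohort and GWAS-summary-statistic generator for puberty-timing MR.

The generator encodes the causal triangle that motivates negative-control
Mendelian randomisation of a time-sensitive exposure: a pre-pubertal
confounder ``C`` (childhood adiposity, kg/m^2) that both advances the
exposure ``M`` (age at menarche, years) and tracks forward into the adult
outcome, SNPs that act on the exposure directly and/or through the
confounder, and optional horizontal pleiotropy. Structural equations
(``d_j`` = effect-allele dosage at SNP ``j``):

    C    = i_C  + sum_j gamma_j d_j + eps_C
    M    = i_M  + sum_j alpha_j d_j + delta_cm * C + eps_M
    Y8   = i_8  + theta_cy * C + sum_j pi_j d_j + eps_8          (pre-exposure)
    Y18  = i_18 + beta_my * M + theta_cy * track_cc * C
                + sum_j pi_j d_j + eps_18                        (post-exposure)

``Y8`` carries no ``M`` term: it is measured before the exposure completes,
which is what makes it usable as a negative-control outcome. All noise terms
are Gaussian. Randomness is driven by a named seed-sequence spawn so that the
two samples of a two-sample design are guaranteed disjoint streams.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpSpec",
    "StructuralParams",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_summary_stats",
    "simulate_binary_summary_stats",
    "TIME_ORDER",
]

_VALID_ALLELES = frozenset("ACGT")

#: Declared measurement ages (years) of the cohort columns. ``outcome_pre``
#: and ``confounder`` are timestamped before the exposure completes.
TIME_ORDER: dict[str, float] = {
    "confounder": 8.0,
    "outcome_pre": 8.0,
    "exposure": 12.0,
    "outcome_post": 18.0,
}


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP and its per-allele structural effects.

    ``gamma_c`` acts on the confounder, ``alpha_m`` directly on the exposure
    (years/allele) and ``pleio_y`` directly on the outcome (horizontal
    pleiotropy). The dosage counts copies of ``effect_allele``, drawn
    binomial(2, maf) so the effect-allele frequency equals ``maf``.
    """

    snp_id: str
    maf: float
    effect_allele: str = "A"
    other_allele: str = "G"
    gamma_c: float = 0.0
    alpha_m: float = 0.0
    pleio_y: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele must differ")
        for name in ("gamma_c", "alpha_m", "pleio_y"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.snp_id}: {name} must be finite")


@dataclass(frozen=True)
class StructuralParams:
    """Coefficients and noise scales of the structural equations.

    Units: ``beta_my`` outcome units per year; ``delta_cm`` years per
    confounder unit; ``theta_cy`` outcome units per confounder unit;
    ``track_cc`` is the raw tracking slope of the childhood confounder into
    its adult re-measurement (dimensionless ratio of outcome units).
    ``mean_*`` are target population means, converted internally to
    intercepts. ``round_exposure`` floors the *reported* exposure to whole
    years (self-report rounding); the latent exposure still drives outcomes.
    """

    beta_my: float = 0.0
    delta_cm: float = 0.0
    theta_cy: float = 0.0
    track_cc: float = 1.0
    sd_c: float = 1.0
    sd_m: float = 1.0
    sd_y8: float = 1.0
    sd_y18: float = 1.0
    mean_c: float = 0.0
    mean_m: float = 0.0
    mean_y8: float = 0.0
    mean_y18: float = 0.0
    round_exposure: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_c", "sd_m", "sd_y8", "sd_y18"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite")

    def replace(self, **kw) -> "StructuralParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """Per-individual effect-allele dosages plus per-SNP metadata.

    ``dosages`` is individuals x SNPs (values in [0, 2], fractional allowed
    for imputed data); ``snps`` holds snp_id, effect_allele, other_allele and
    the observed effect-allele frequency.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy()
        if np.isnan(vals).all(axis=0).any():
            raise ValueError("a SNP column is entirely missing")
        with np.errstate(invalid="ignore"):
            if ((vals < 0) | (vals > 2)).any():
                raise ValueError("dosages must lie in [0, 2]")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_id in genotype metadata")
        if list(self.snps["snp_id"]) != list(self.dosages.columns):
            raise ValueError("snp metadata order must match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)


def _check_snps(snps) -> list[SnpSpec]:
    snps = list(snps)
    if not snps:
        raise ValueError("SNP list must be non-empty")
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated snp_id in SNP specs")
    return snps


def simulate_genotypes(
    n: int,
    snps,
    seed: int | np.random.Generator = 0,
    ld_corr: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Draw ``n`` individuals' dosages, binomial(2, maf) per SNP.

    SNPs are independent unless ``ld_corr`` (a positive-definite correlation
    matrix) is given, in which case dosages are coupled through a Gaussian
    copula: latent MVN draws are pushed through the binomial quantile
    function, preserving Hardy-Weinberg margins while inducing LD.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    snps = _check_snps(snps)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.array([s.maf for s in snps])
    if ld_corr is None:
        dos = rng.binomial(2, mafs, size=(n, len(snps))).astype(float)
    else:
        ld_corr = np.asarray(ld_corr, dtype=float)
        if ld_corr.shape != (len(snps), len(snps)):
            raise ValueError("ld_corr shape must match the number of SNPs")
        z = rng.multivariate_normal(np.zeros(len(snps)), ld_corr, size=n, method="cholesky")
        u = stats.norm.cdf(z)
        dos = stats.binom.ppf(u, 2, mafs).astype(float)
    iids = [f"id_{i:06d}" for i in range(1, n + 1)]
    dosages = pd.DataFrame(dos, index=pd.Index(iids, name="iid"), columns=[s.snp_id for s in snps])
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "effect_allele": [s.effect_allele for s in snps],
            "other_allele": [s.other_allele for s in snps],
            "eaf": dos.mean(axis=0) / 2.0,
        }
    )
    return GenotypeMatrix(dosages, meta)


def simulate_cohort(n: int, snps, params: StructuralParams) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes and the phenotype table under the structural model.

    Returns the genotype matrix and a cohort table with columns ``sex``,
    ``age_months``, ``maternal_edu`` (inert covariates used only to exercise
    adjustment interfaces), ``confounder``, ``exposure``, ``outcome_pre``
    and ``outcome_post``. The table's ``attrs`` carry the declared time
    ordering and the ground-truth parameters.
    """
    snps = _check_snps(snps)
    ss = np.random.SeedSequence(params.seed)
    geno_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    geno = simulate_genotypes(n, snps, seed=geno_rng)
    D = geno.dosages.to_numpy()

    gamma = np.array([s.gamma_c for s in snps])
    alpha = np.array([s.alpha_m for s in snps])
    pleio = np.array([s.pleio_y for s in snps])
    two_maf = 2.0 * np.array([s.maf for s in snps])
    p = params

    i_c = p.mean_c - two_maf @ gamma
    i_m = p.mean_m - two_maf @ alpha - p.delta_cm * p.mean_c
    i_8 = p.mean_y8 - p.theta_cy * p.mean_c - two_maf @ pleio
    i_18 = (
        p.mean_y18
        - p.beta_my * p.mean_m
        - p.theta_cy * p.track_cc * p.mean_c
        - two_maf @ pleio
    )

    C = i_c + D @ gamma + noise_rng.normal(0.0, p.sd_c, n)
    M_latent = i_m + D @ alpha + p.delta_cm * C + noise_rng.normal(0.0, p.sd_m, n)
    Y8 = i_8 + p.theta_cy * C + D @ pleio + noise_rng.normal(0.0, p.sd_y8, n)
    Y18 = (
        i_18
        + p.beta_my * M_latent
        + p.theta_cy * p.track_cc * C
        + D @ pleio
        + noise_rng.normal(0.0, p.sd_y18, n)
    )
    M = np.floor(M_latent) if p.round_exposure else M_latent

    cohort = pd.DataFrame(
        {
            "sex": "F",
            "age_months": np.round(noise_rng.normal(222.0, 3.0, n), 1),
            "maternal_edu": noise_rng.integers(0, 2, n),
            "confounder": C,
            "exposure": M,
            "outcome_pre": Y8,
            "outcome_post": Y18,
        },
        index=geno.dosages.index,
    )
    cohort.attrs["time_order"] = dict(TIME_ORDER)
    cohort.attrs["ground_truth"] = dataclasses.asdict(p)
    return geno, cohort


def _per_snp_ols(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Univariable OLS of ``y`` on each dosage column; returns (beta, se, p)."""
    n = len(y)
    xc = D - D.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    if (sxx == 0).any():
        raise ValueError("monomorphic SNP in sample; cannot regress")
    beta = xc.T @ yc / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    with np.errstate(divide="ignore"):
        tval = np.abs(beta / se)
    pval = np.clip(2.0 * stats.t.sf(tval, n - 2), np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _stats_frame(geno: GenotypeMatrix, beta, se, pval, n) -> pd.DataFrame:
    out = geno.snps[["snp_id", "effect_allele", "other_allele", "eaf"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["pval"] = pval
    out["n"] = n
    return out


def simulate_summary_stats(
    snps,
    params: StructuralParams,
    n_exposure: int,
    n_outcome: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS-style summary statistics from disjoint cohorts.

    Two independent cohorts with the same data-generating process are
    simulated from named sub-seeds of ``seed``; per-SNP betas and SEs come
    from univariable OLS of the exposure (sample 1) and the post-exposure
    outcome (sample 2) on each dosage. Columns follow the summary-stat TSV
    contract: snp_id, effect_allele, other_allele, eaf, beta, se, pval, n.
    """
    if n_exposure < 100 or n_outcome < 100:
        raise ValueError("n_exposure and n_outcome must be >= 100")
    snps = _check_snps(snps)
    kids = np.random.SeedSequence(seed).spawn(2)
    sub_seeds = [int(k.generate_state(1)[0] % 2**31) for k in kids]

    geno_x, coh_x = simulate_cohort(n_exposure, snps, params.replace(seed=sub_seeds[0]))
    geno_y, coh_y = simulate_cohort(n_outcome, snps, params.replace(seed=sub_seeds[1]))

    bx, sx, px = _per_snp_ols(geno_x.dosages.to_numpy(), coh_x["exposure"].to_numpy())
    by, sy, py = _per_snp_ols(geno_y.dosages.to_numpy(), coh_y["outcome_post"].to_numpy())
    return (
        _stats_frame(geno_x, bx, sx, px, n_exposure),
        _stats_frame(geno_y, by, sy, py, n_outcome),
    )


def simulate_binary_summary_stats(
    snps,
    params: StructuralParams,
    n_exposure: int,
    n_outcome: int,
    seed: int,
    case_quantile: float = 0.95,
    control_quantile: float = 0.50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics with a binary (case/control) outcome sample.

    Mirrors the childhood-obesity contrast: cases have a pre-exposure outcome
    at or above ``case_quantile`` of its distribution, controls below
    ``control_quantile``; per-SNP logistic regressions give log-OR betas.
    """
    import statsmodels.api as sm

    if n_exposure < 100 or n_outcome < 100:
        raise ValueError("n_exposure and n_outcome must be >= 100")
    if not (0 < control_quantile <= case_quantile < 1):
        raise ValueError("require 0 < control_quantile <= case_quantile < 1")
    snps = _check_snps(snps)
    kids = np.random.SeedSequence(seed).spawn(2)
    sub_seeds = [int(k.generate_state(1)[0] % 2**31) for k in kids]

    geno_x, coh_x = simulate_cohort(n_exposure, snps, params.replace(seed=sub_seeds[0]))
    bx, sx, px = _per_snp_ols(geno_x.dosages.to_numpy(), coh_x["exposure"].to_numpy())
    exp_stats = _stats_frame(geno_x, bx, sx, px, n_exposure)

    geno_y, coh_y = simulate_cohort(n_outcome, snps, params.replace(seed=sub_seeds[1]))
    y8 = coh_y["outcome_pre"].to_numpy()
    hi, lo = np.quantile(y8, [case_quantile, control_quantile])
    keep = (y8 >= hi) | (y8 < lo)
    status = (y8[keep] >= hi).astype(float)
    D = geno_y.dosages.to_numpy()[keep]

    beta = np.empty(D.shape[1])
    se = np.empty(D.shape[1])
    pv = np.empty(D.shape[1])
    for j in range(D.shape[1]):
        res = sm.Logit(status, sm.add_constant(D[:, j])).fit(disp=False)
        beta[j], se[j], pv[j] = res.params[1], res.bse[1], res.pvalues[1]
    out_stats = geno_y.snps[["snp_id", "effect_allele", "other_allele"]].copy()
    out_stats["eaf"] = D.mean(axis=0) / 2.0
    out_stats["beta"] = beta
    out_stats["se"] = se
    out_stats["pval"] = np.clip(pv, np.finfo(float).tiny, 1.0)
    out_stats["n"] = int(keep.sum())
    return exp_stats, out_stats
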