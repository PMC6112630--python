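"""Named simulation presets.

Each preset bundles SNP specs, structural parameters and external weight
tables into a reproducible scenario:

``menarche_preset``
    The cohort-scale scenario the package is organised around. 100 menarche
    SNPs whose weighted score explains ~10.6% of exposure variance at
    realistic moments (menarche mean 12.4 y, SD 1.1 y), with 20% of every
    marginal SNP effect flowing through childhood BMI (mean 16.4, SD ~1.95
    kg/m^2); 50 further SNPs act on childhood BMI only and their score
    explains ~3.44% of its variance. Childhood BMI advances menarche by
    -0.26 y per kg/m^2 and tracks into adult BMI with raw slope 1.76 (the
    slope implied by a 0.8 tracking correlation and SDs of 2.0 at age 8 vs
    4.3 at age 18). The true causal effect of menarche age on the adult
    outcome is zero: every apparent effect is confounding, so the scenario
    has a known answer for negative-control and adjustment analyses.

``validation_preset``
    A clean estimator-consistency scenario: 8 strong independent instruments,
    no confounding, no pleiotropy, true effect 0.5 outcome units per year.
    Instrument heritability is deliberately high so that finite-sample
    (weak-instrument) attenuation of regression-based summary estimators is
    negligible at n = 5,000.

``heterogeneity_preset``
    20 instruments for Cochran-Q / MR-Egger calibration, optionally with
    balanced or directional horizontal pleiotropy.

``breakdown_preset``
    10 equal-strength instruments of which 4 (40% of weight) are invalid,
    shifting their Wald ratios from the true 0.3 to 1.0 -- the weighted
    median's breakdown scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SnpSpec, StructuralParams

__all__ = [
    "Preset",
    "menarche_preset",
    "power_params",
    "validation_preset",
    "heterogeneity_preset",
    "breakdown_preset",
    "get_preset",
]

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass(frozen=True)
class Preset:
    name: str
    snps: tuple[SnpSpec, ...]
    params: StructuralParams
    weights: dict[str, pd.DataFrame] = field(default_factory=dict)
    default_n: int = 2000
    notes: str = ""


def _weight_frame(snps: list[SnpSpec], w: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "effect_allele": [s.effect_allele for s in snps],
            "other_allele": [s.other_allele for s in snps],
            "weight": w,
        }
    )


def menarche_preset(seed: int = 0) -> Preset:
    """Cohort-scale puberty-timing scenario with a known all-confounding truth."""
    # Exposure variance budget: Var(M) = 1.1^2 = 1.21, of which the weighted
    # score explains 10.6% => genetic marginal variance 0.106 * 1.21.
    var_m = 1.1**2
    grs_var = 0.106 * var_m
    delta_cm = -0.26
    frac_c = 0.2  # share of each marginal effect flowing through childhood BMI
    theta_cy = 1.0
    track_cc = 1.76
    sd_c = 1.9

    j_m = 100
    maf_m = np.linspace(0.10, 0.50, j_m)
    shape = np.linspace(0.5, 1.5, j_m)
    two_pq = 2.0 * maf_m * (1.0 - maf_m)
    b = shape * np.sqrt(grs_var / np.sum(shape**2 * two_pq))  # marginal effect, y/allele
    gamma_m = frac_c * b / delta_cm
    alpha_m = (1.0 - frac_c) * b

    # BMI instruments: score explains 3.44% of Var(C).
    j_b = 50
    maf_b = np.linspace(0.10, 0.50, j_b)
    shape_b = np.linspace(0.5, 1.5, j_b)
    two_pq_b = 2.0 * maf_b * (1.0 - maf_b)
    gen_c_menarche = float(np.sum(gamma_m**2 * two_pq))
    r2_bmi = 0.0344
    gen_bmi = r2_bmi * (gen_c_menarche + sd_c**2) / (1.0 - r2_bmi)
    v = shape_b * np.sqrt(gen_bmi / np.sum(shape_b**2 * two_pq_b))

    # Residual exposure noise so Var(M) hits its budget.
    var_c_noise = delta_cm**2 * (sd_c**2 + gen_bmi)
    sd_m = float(np.sqrt(var_m - grs_var - var_c_noise))

    snps: list[SnpSpec] = []
    for j in range(j_m):
        ea, oa = _ALLELE_CYCLE[j % 4]
        snps.append(
            SnpSpec(
                f"rsM{j + 1:04d}", float(maf_m[j]), ea, oa,
                gamma_c=float(gamma_m[j]), alpha_m=float(alpha_m[j]),
            )
        )
    for j in range(j_b):
        ea, oa = _ALLELE_CYCLE[j % 4]
        snps.append(SnpSpec(f"rsB{j + 1:04d}", float(maf_b[j]), ea, oa, gamma_c=float(v[j])))

    params = StructuralParams(
        beta_my=0.0,
        delta_cm=delta_cm,
        theta_cy=theta_cy,
        track_cc=track_cc,
        sd_c=sd_c,
        sd_m=sd_m,
        sd_y8=1.0,
        sd_y18=2.6,
        mean_c=16.4,
        mean_m=12.4,
        mean_y8=16.4,
        mean_y18=23.0,
        seed=seed,
    )
    weights = {
        "menarche": _weight_frame(snps[:j_m], b),
        "bmi": _weight_frame(snps[j_m:], v),
    }
    return Preset(
        "menarche",
        tuple(snps),
        params,
        weights,
        default_n=2000,
        notes="all apparent exposure->outcome effect is confounding (beta_my = 0)",
    )


def power_params(preset: Preset) -> StructuralParams:
    """Variant of the confounder->outcome path sized for positive-control power.

    Widens the pre-exposure outcome noise so the standardised effect of the
    childhood confounder on that outcome is ~0.47 SD -- the size of a known
    strong positive-control association (childhood BMI on blood pressure).
    """
    return preset.params.replace(sd_y8=3.66)


def validation_preset(beta: float = 0.5, seed: int = 0) -> Preset:
    """Estimator-consistency scenario: strong instruments, no pleiotropy."""
    j = 8
    alphas = np.linspace(0.15, 1.25, j)
    snps = [
        SnpSpec(f"rsV{k + 1:03d}", 0.30, *_ALLELE_CYCLE[k % 4], alpha_m=float(alphas[k]))
        for k in range(j)
    ]
    params = StructuralParams(beta_my=beta, sd_m=0.5, sd_y8=1.0, sd_y18=4.0, seed=seed)
    return Preset(
        "validation",
        tuple(snps),
        params,
        {"exposure": _weight_frame(snps, alphas)},
        default_n=5000,
        notes=f"true causal effect {beta}; deliberately strong instruments",
    )


def heterogeneity_preset(
    pleiotropy: str = "none",
    pleiotropy_mean: float = 0.35,
    pleiotropy_spread: float = 0.10,
    seed: int = 0,
) -> Preset:
    """Calibration scenario for Cochran's Q and the MR-Egger intercept.

    ``pleiotropy`` is one of ``none`` (correctly specified model),
    ``balanced`` (alternating +/- spread, zero mean) or ``directional``
    (alternating around ``pleiotropy_mean``). The alternating pattern keeps
    pleiotropic effects uncorrelated with instrument strength (InSIDE).
    """
    j = 20
    alphas = np.linspace(0.3, 1.1, j)
    signs = np.where(np.arange(j) % 2 == 0, 1.0, -1.0)
    if pleiotropy == "none":
        pleio = np.zeros(j)
    elif pleiotropy == "balanced":
        pleio = signs * pleiotropy_spread
    elif pleiotropy == "directional":
        pleio = pleiotropy_mean + signs * pleiotropy_spread
    else:
        raise ValueError("pleiotropy must be 'none', 'balanced' or 'directional'")
    snps = [
        SnpSpec(
            f"rsH{k + 1:03d}", 0.30, *_ALLELE_CYCLE[k % 4],
            alpha_m=float(alphas[k]), pleio_y=float(pleio[k]),
        )
        for k in range(j)
    ]
    params = StructuralParams(beta_my=0.3, sd_m=0.5, sd_y8=1.0, sd_y18=5.0, seed=seed)
    return Preset(
        f"heterogeneity[{pleiotropy}]",
        tuple(snps),
        params,
        {"exposure": _weight_frame(snps, alphas)},
        default_n=5000,
    )


def breakdown_preset(
    valid_ratio: float = 0.3, invalid_ratio: float = 1.0, seed: int = 0
) -> Preset:
    """Weighted-median breakdown scenario: 40% of instrument weight invalid.

    All 10 SNPs have equal strength (equal inverse-variance weight); the true
    effect is ``valid_ratio`` and the 4 invalid SNPs carry horizontal
    pleiotropy sized to move their Wald ratios to ``invalid_ratio``.
    """
    j, j_invalid = 10, 4
    b = 0.7
    pleio = np.zeros(j)
    pleio[-j_invalid:] = (invalid_ratio - valid_ratio) * b
    snps = [
        SnpSpec(
            f"rsW{k + 1:03d}", 0.30, *_ALLELE_CYCLE[k % 4],
            alpha_m=b, pleio_y=float(pleio[k]),
        )
        for k in range(j)
    ]
    params = StructuralParams(beta_my=valid_ratio, sd_m=0.5, sd_y8=1.0, sd_y18=2.0, seed=seed)
    return Preset(
        "breakdown",
        tuple(snps),
        params,
        {"exposure": _weight_frame(snps, np.full(j, b))},
        default_n=5000,
        notes=f"valid ratio {valid_ratio}, 40% of weight at {invalid_ratio}",
    )


_PRESETS = {
    "menarche": menarche_preset,
    "validation": validation_preset,
    "heterogeneity": heterogeneity_preset,
    "breakdown": breakdown_preset,
}


def get_preset(name: str, seed: int = 0, **kw) -> Preset:
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    return factory(seed=seed, **kw)
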