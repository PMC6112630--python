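"""Externally weighted genetic risk scores and instrument-strength diagnostics.

The score for individual ``i`` is ``(sum_j w_j d_ij) / J_used`` where
``d_ij`` counts effect alleles and ``w_j`` are per-allele weights from an
external GWAS -- the average per-SNP effect on the exposure. Weight-table
SNPs absent from the genotypes, or whose alleles cannot be reconciled, are
dropped and logged; SNPs listed with swapped alleles are rescored via
``d -> 2 - d``. Missing dosages are mean-imputed per SNP (the observed mean
dosage), which keeps ``J_used`` stable across individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

__all__ = [
    "ScoreResult",
    "StrengthResult",
    "DegenerateInstrumentError",
    "compute_grs",
    "instrument_strength",
    "f_from_r2",
    "grs_outcome_association",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DegenerateInstrumentError(ValueError):
    """The score carries no usable variation (or fits the exposure exactly)."""


@dataclass
class ScoreResult:
    """Per-individual scores plus scoring bookkeeping."""

    scores: pd.Series
    j_used: int
    dropped: list[tuple[str, str]] = field(default_factory=list)
    mean_imputed: int = 0

    @property
    def dropped_ids(self) -> list[str]:
        return [s for s, _ in self.dropped]


@dataclass(frozen=True)
class StrengthResult:
    """Single-predictor instrument-strength summary: R^2, F, p, n.

    For one predictor, F = (n - 2) R^2 / (1 - R^2) exactly.
    """

    r2: float
    f: float
    p: float
    n: int


def _orient(w_ea: str, w_oa: str, g_ea: str, g_oa: str) -> int | None:
    """Return +1 (count as-is), -1 (count 2-d) or None (unresolvable).

    Direct label matches take precedence over strand-complement matches, so
    palindromic (A/T, C/G) SNPs resolve by label, which the synthetic data
    controls; real-data strand resolution is out of scope here.
    """
    if g_oa == "N":  # counted allele known but partner not recorded (.raw files)
        if w_ea == g_ea:
            return 1
        if w_oa == g_ea:
            return -1
        return None
    if (w_ea, w_oa) == (g_ea, g_oa):
        return 1
    if (w_ea, w_oa) == (g_oa, g_ea):
        return -1
    c_ea, c_oa = w_ea.translate(_COMPLEMENT), w_oa.translate(_COMPLEMENT)
    if (c_ea, c_oa) == (g_ea, g_oa):
        return 1
    if (c_ea, c_oa) == (g_oa, g_ea):
        return -1
    return None


def compute_grs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> ScoreResult:
    """Score individuals against an external weight table.

    ``weights`` needs columns snp_id, effect_allele, other_allele, weight.
    Raises if the weight table has duplicate SNPs or if no SNP overlaps the
    genotype matrix.
    """
    required = {"snp_id", "effect_allele", "other_allele", "weight"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if weights["snp_id"].duplicated().any():
        dups = weights.loc[weights["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP in weight table: {dups}")
    if not np.isfinite(weights["weight"].to_numpy(dtype=float)).all():
        raise ValueError("weights must be finite")

    meta = genotypes.snps.set_index("snp_id")
    cols: list[str] = []
    w_used: list[float] = []
    flip: list[int] = []
    dropped: list[tuple[str, str]] = []
    for row in weights.itertuples(index=False):
        if row.snp_id not in meta.index:
            dropped.append((row.snp_id, "missing_from_genotypes"))
            continue
        g = meta.loc[row.snp_id]
        sign = _orient(row.effect_allele, row.other_allele, g["effect_allele"], g["other_allele"])
        if sign is None:
            dropped.append((row.snp_id, "allele_mismatch"))
            continue
        cols.append(row.snp_id)
        w_used.append(float(row.weight))
        flip.append(sign)

    if not cols:
        raise ValueError("no weight-table SNP overlaps the genotype matrix")

    D = genotypes.dosages[cols].to_numpy(dtype=float)
    n_missing = int(np.isnan(D).sum())
    if n_missing:
        col_means = np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D[idx] = np.take(col_means, idx[1])
    flip_arr = np.asarray(flip)
    D = np.where(flip_arr == -1, 2.0 - D, D)
    w_arr = np.asarray(w_used)
    scores = pd.Series(D @ w_arr / len(cols), index=genotypes.dosages.index, name="grs")
    return ScoreResult(scores, j_used=len(cols), dropped=dropped, mean_imputed=n_missing)


def f_from_r2(r2: float, n: int) -> float:
    """Single-predictor F-statistic implied by a variance-explained and n."""
    if not (0 <= r2 < 1):
        raise ValueError("r2 must lie in [0, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    return (n - 2) * r2 / (1.0 - r2)


def instrument_strength(score, exposure) -> StrengthResult:
    """Simple linear regression of the exposure on the score.

    Returns variance explained, the single-predictor F, a two-sided p-value
    and the complete-pair count. A zero-variance score or a perfect fit is
    rejected as a degenerate instrument.
    """
    s = np.asarray(score, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if s.shape != x.shape:
        raise ValueError("score and exposure must have equal length")
    ok = np.isfinite(s) & np.isfinite(x)
    s, x = s[ok], x[ok]
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 complete score/exposure pairs")
    if np.var(s) == 0:
        raise DegenerateInstrumentError("score has zero variance")
    r = stats.pearsonr(s, x).statistic
    r2 = float(r * r)
    if 1.0 - r2 < 1e-12:
        raise DegenerateInstrumentError("perfect score-exposure fit (R^2 = 1)")
    f = f_from_r2(r2, n)
    p = float(stats.f.sf(f, 1, n - 2))
    return StrengthResult(r2=r2, f=float(f), p=p, n=n)


def grs_outcome_association(score, outcome, covariates: pd.DataFrame | None = None):
    """OLS of an outcome on the score (+ covariates) with HC1 robust SEs.

    Used as an instrument-validity screen: a score built for one exposure
    should not associate directly with another trait. Returns the fitted
    statsmodels results object (coefficient of interest is ``score``).
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"score": np.asarray(score, dtype=float)})
    df["outcome"] = np.asarray(outcome, dtype=float)
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        df = pd.concat([df.reset_index(drop=True), cov], axis=1)
    df = df.dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 complete cases")
    X = sm.add_constant(df.drop(columns="outcome"))
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    return sm.OLS(df["outcome"], X).fit(cov_type="HC1")
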