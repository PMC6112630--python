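"""Summary-statistics (two-sample) Mendelian randomisation.

Works on GWAS-style per-SNP tables (snp_id, effect_allele, other_allele,
eaf, beta, se, pval, n). ``harmonise`` aligns outcome effects to the
exposure's effect allele, dropping ambiguous palindromic SNPs; the
estimators then combine per-SNP Wald ratios:

* IVW -- weighted regression of outcome betas on exposure betas through the
  origin with weights 1/se_y^2, with multiplicative random-effects SE
  inflation when Cochran's Q exceeds its degrees of freedom;
* MR-Egger -- same regression with a free intercept; the intercept estimates
  the average directional pleiotropic effect, the slope a pleiotropy-robust
  causal effect under InSIDE;
* weighted median -- the ratio at 50% of cumulative inverse-variance weight,
  consistent when at least half the weight comes from valid instruments,
  with a seeded parametric-bootstrap SE.

For binary outcomes the betas are log odds ratios and estimates carry an
exponentiated OR scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "HeterogeneityStats",
    "harmonise",
    "ld_prune",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "funnel_data",
    "kept",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PALINDROMES = ({"A", "T"}, {"C", "G"})
Z95 = 1.96

KEPT_STATUSES = ("kept", "sign_flipped")


@dataclass
class MREstimate:
    """A pooled MR estimate. ``se`` is the reported SE (random-effects
    inflated for IVW when overdispersed); ``se_fixed`` the uninflated one."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    se_fixed: float | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    ci_df: int | None = None
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        # t reference when the SE carries an estimated scale (MR-Egger),
        # normal otherwise
        crit = float(stats.t.ppf(0.975, self.ci_df)) if self.ci_df else Z95
        self.ci_low = self.beta - crit * self.se
        self.ci_high = self.beta + crit * self.se
        if self.odds_ratio is not None:
            self.or_ci_low = float(np.exp(self.ci_low))
            self.or_ci_high = float(np.exp(self.ci_high))

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_snps": self.n_snps,
            "odds_ratio": self.odds_ratio,
        }


@dataclass
class HeterogeneityStats:
    """Cochran's Q for the IVW fit; per-SNP contributions sum to Q."""

    q: float
    df: int
    p: float
    per_snp: pd.Series

    def to_row(self) -> dict:
        return {"q": self.q, "df": self.df, "p": self.p}


def _check_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    req = {"snp_id", "effect_allele", "other_allele", "eaf", "beta", "se"}
    missing = req - set(df.columns)
    if missing:
        raise ValueError(f"{label} table missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id in {label} table: {dups}")
    return df


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMES


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome summary stats to the exposure's effect alleles.

    Returns one row per exposure SNP with columns beta_x/se_x/eaf_x,
    beta_y/se_y/eaf_y and ``status``: kept, sign_flipped (outcome listed the
    alleles the other way round; beta_y negated, eaf_y reflected),
    dropped_palindromic (A/T or C/G with ambiguous frequency in either
    study), dropped_missing (absent from the outcome table -- proxy lookup
    is not performed) or dropped_mismatch (irreconcilable alleles).
    """
    _check_table(exposure, "exposure")
    _check_table(outcome, "outcome")
    lo, hi = palindrome_eaf_window
    out_ix = outcome.set_index("snp_id")

    rows = []
    for e in exposure.itertuples(index=False):
        row = {
            "snp_id": e.snp_id,
            "effect_allele": e.effect_allele,
            "other_allele": e.other_allele,
            "beta_x": float(e.beta),
            "se_x": float(e.se),
            "eaf_x": float(e.eaf),
            "beta_y": np.nan,
            "se_y": np.nan,
            "eaf_y": np.nan,
        }
        if e.snp_id not in out_ix.index:
            row["status"] = "dropped_missing"
            rows.append(row)
            continue
        o = out_ix.loc[e.snp_id]
        sign = _orient_pair(e.effect_allele, e.other_allele, o["effect_allele"], o["other_allele"])
        if sign is None:
            row["status"] = "dropped_mismatch"
            rows.append(row)
            continue
        eaf_y = float(o["eaf"]) if sign == 1 else 1.0 - float(o["eaf"])
        if _is_palindromic(e.effect_allele, e.other_allele) and (
            lo <= row["eaf_x"] <= hi or lo <= eaf_y <= hi
        ):
            row["status"] = "dropped_palindromic"
            rows.append(row)
            continue
        row["beta_y"] = sign * float(o["beta"])
        row["se_y"] = float(o["se"])
        row["eaf_y"] = eaf_y
        row["status"] = "kept" if sign == 1 else "sign_flipped"
        rows.append(row)
    return pd.DataFrame(rows)


def _orient_pair(x_ea, x_oa, y_ea, y_oa):
    if (y_ea, y_oa) == (x_ea, x_oa):
        return 1
    if (y_ea, y_oa) == (x_oa, x_ea):
        return -1
    c_ea, c_oa = y_ea.translate(_COMPLEMENT), y_oa.translate(_COMPLEMENT)
    if (c_ea, c_oa) == (x_ea, x_oa):
        return 1
    if (c_ea, c_oa) == (x_oa, x_ea):
        return -1
    return None


def kept(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for estimation (kept or sign_flipped)."""
    return pairs[pairs["status"].isin(KEPT_STATUSES)].reset_index(drop=True)


def ld_prune(
    stats_df: pd.DataFrame,
    ld_r2: pd.DataFrame,
    positions,
    r2_max: float = 0.01,
    window_kb: float = 10_000.0,
) -> pd.DataFrame:
    """Greedy LD pruning by ascending p-value.

    SNPs are visited from smallest exposure p-value; a SNP is kept iff its
    r^2 with every already-kept SNP inside ``window_kb`` is below ``r2_max``.
    ``ld_r2`` must be a symmetric matrix with unit diagonal indexed by
    snp_id; ``positions`` maps snp_id to base-pair coordinate.
    """
    if "pval" not in stats_df.columns:
        raise ValueError("stats table needs a 'pval' column for pruning order")
    mat = ld_r2.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8) or not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError("ld_r2 must be symmetric with unit diagonal")
    pos = pd.Series(positions)

    order = stats_df.sort_values(["pval", "snp_id"], kind="mergesort")
    kept_ids: list[str] = []
    for snp in order["snp_id"]:
        if snp not in pos.index:
            raise ValueError(f"no position for SNP {snp!r}")
        ok = True
        for other in kept_ids:
            if abs(pos[snp] - pos[other]) > window_kb * 1_000.0:
                continue
            if snp not in ld_r2.index or other not in ld_r2.columns:
                raise ValueError(f"missing LD entry for pair ({snp}, {other})")
            if ld_r2.loc[snp, other] >= r2_max:
                ok = False
                break
        if ok:
            kept_ids.append(snp)
    return stats_df[stats_df["snp_id"].isin(kept_ids)].reset_index(drop=True)


def wald_ratio(pair) -> MREstimate:
    """Per-SNP causal estimate: beta_y / beta_x, SE = se_y / |beta_x|."""
    bx, by, sy = float(pair["beta_x"]), float(pair["beta_y"]), float(pair["se_y"])
    if bx == 0:
        raise ZeroDivisionError("beta_x = 0: Wald ratio undefined; exclude this SNP")
    beta = by / bx
    se = sy / abs(bx)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MREstimate(method="wald", beta=float(beta), se=float(se), p=p, n_snps=1)


def _arrays(pairs: pd.DataFrame):
    df = kept(pairs) if "status" in pairs.columns else pairs
    if len(df) == 0:
        raise ValueError("no usable (kept) SNP pairs")
    bx = df["beta_x"].to_numpy(dtype=float)
    by = df["beta_y"].to_numpy(dtype=float)
    sy = df["se_y"].to_numpy(dtype=float)
    sx = df["se_x"].to_numpy(dtype=float) if "se_x" in df else np.zeros_like(bx)
    ids = df["snp_id"] if "snp_id" in df else pd.Series(np.arange(len(df)).astype(str))
    if (sy <= 0).any():
        raise ValueError("se_y must be positive")
    return ids, bx, sx, by, sy


def ivw(
    pairs: pd.DataFrame,
    random_effects: bool = True,
    binary_outcome: bool = False,
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate plus Cochran's Q.

    Weighted regression of beta_y on beta_x through the origin with weights
    1/se_y^2; with a single SNP this is exactly that SNP's Wald ratio. The
    reported SE is inflated by sqrt(Q/df) when Q/df > 1 (multiplicative
    random effects) unless ``random_effects`` is False; the fixed-effect SE
    is always carried alongside.
    """
    ids, bx, _, by, sy = _arrays(pairs)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all beta_x are zero; IVW undefined")
    beta = float(np.sum(w * bx * by) / denom)
    se_fixed = float(np.sqrt(1.0 / denom))
    contrib = w * (by - beta * bx) ** 2
    q = float(np.sum(contrib))
    dfree = len(bx) - 1
    q_p = float(stats.chi2.sf(q, dfree)) if dfree > 0 else float("nan")
    se = se_fixed
    if random_effects and dfree > 0 and q / dfree > 1.0:
        se = se_fixed * float(np.sqrt(q / dfree))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    est = MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        p=p,
        n_snps=len(bx),
        se_fixed=se_fixed,
        odds_ratio=float(np.exp(beta)) if binary_outcome else None,
    )
    het = HeterogeneityStats(q=q, df=dfree, p=q_p, per_snp=pd.Series(contrib, index=ids.to_numpy()))
    return est, het


def mr_egger(pairs: pd.DataFrame, binary_outcome: bool = False) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    SNPs are re-oriented so every beta_x >= 0 (a joint sign flip of a pair
    leaves its Wald ratio unchanged). The weighted regression of beta_y on
    beta_x with a free intercept uses weights 1/se_y^2 and an estimated
    residual scale; p-values are from t with n_snps - 2 df.
    """
    ids, bx, _, by, sy = _arrays(pairs)
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs (intercept + slope)")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    XtW = X.T * w
    coef = np.linalg.solve(XtW @ X, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    cov = sigma2 * np.linalg.inv(XtW @ X)
    ses = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fit -> SE 0
        tvals = np.where(ses > 0, np.abs(coef) / np.where(ses > 0, ses, 1.0), np.inf)
    pvals = 2.0 * stats.t.sf(tvals, j - 2)
    slope = MREstimate(
        method="egger_slope",
        beta=float(coef[1]),
        se=float(ses[1]),
        p=float(pvals[1]),
        n_snps=j,
        ci_df=j - 2,
        odds_ratio=float(np.exp(coef[1])) if binary_outcome else None,
    )
    intercept = MREstimate(
        method="egger_intercept",
        beta=float(coef[0]),
        se=float(ses[0]),
        p=float(pvals[0]),
        n_snps=j,
        ci_df=j - 2,
    )
    return slope, intercept


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    pairs: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    binary_outcome: bool = False,
) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Wald ratios are ordered and the estimate interpolated at 50% of
    cumulative inverse-variance weight; it is consistent when valid
    instruments carry at least half the weight. The SE is the SD of the
    estimate over ``n_boot`` resamples of (beta_x, beta_y) from their
    reported sampling distributions, with a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    ids, bx, sx, by, sy = _arrays(pairs)
    if len(bx) < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    if (bx == 0).any():
        raise ZeroDivisionError("beta_x = 0 among pairs; exclude before weighted median")
    ratios = by / bx
    weights = bx**2 / sy**2  # 1 / Var(Wald ratio), first order
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(bx)))
    bxs = np.where(bxs == 0, np.finfo(float).eps, bxs)
    r = bys / bxs
    w = bxs**2 / sy**2
    order = np.argsort(r, axis=1, kind="mergesort")
    r_s = np.take_along_axis(r, order, axis=1)
    w_s = np.take_along_axis(w, order, axis=1)
    cums = np.cumsum(w_s, axis=1) - 0.5 * w_s
    cums /= w_s.sum(axis=1, keepdims=True)
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp is 1-D; loop stays cheap
        boots[i] = np.interp(0.5, cums[i], r_s[i])
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
    return MREstimate(
        method="weighted_median",
        beta=est,
        se=se,
        p=p,
        n_snps=len(bx),
        odds_ratio=float(np.exp(est)) if binary_outcome else None,
    )


def funnel_data(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios and precisions (1/SE) for funnel plots."""
    ids, bx, _, by, sy = _arrays(pairs)
    nz = bx != 0
    ratio = by[nz] / bx[nz]
    se = sy[nz] / np.abs(bx[nz])
    return pd.DataFrame({"snp_id": ids.to_numpy()[nz], "ratio": ratio, "precision": 1.0 / se})
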