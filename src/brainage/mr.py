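"""Two-sample Mendelian randomisation from GWAS summary statistics.

Given per-variant effect estimates of instruments on an exposure (one study)
and on an outcome (another study), the module harmonises effect alleles
between the two tables, prunes correlated instruments by greedy LD clumping,
and estimates the causal effect of the exposure on the outcome by three
estimators with complementary robustness:

* **IVW** — inverse-variance-weighted combination of per-variant Wald
  ratios; equivalently a weighted regression of outcome betas on exposure
  betas through the origin with weights 1/se_y^2 (fixed-effect).
* **MR-Egger** — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy and its test flags
  violation of the no-pleiotropy assumption.
* **Weighted median** — the weight-interpolated median of the Wald ratios;
  consistent whenever valid instruments carry more than half the weight.

Cochran's Q quantifies heterogeneity of the per-variant ratios (chi-square
with n-1 df under homogeneity for IVW; n-2 df for the Egger residual form).

Summary tables are pandas DataFrames with columns ``variant_id,
effect_allele, other_allele, beta, se, pval, eaf``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRResult",
    "harmonise",
    "ld_clump",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mr_suite",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MRResult:
    method: str                     # ivw | egger | weighted_median
    estimate: float
    se: float
    p_value: float
    n_variants: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    intercept: float | None = None          # Egger only
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    q_p: float | None = None


def _require_columns(df: pd.DataFrame, label: str) -> None:
    needed = {"variant_id", "effect_allele", "other_allele", "beta", "se"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{label} table missing columns: {sorted(missing)}")


def harmonise(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic: str = "drop",
              eaf_tolerance: float = 0.08) -> tuple[pd.DataFrame, list[dict]]:
    """Align outcome effect alleles to the exposure orientation.

    Variants present in both tables are kept.  Where the outcome's effect
    allele equals the exposure's other allele (and vice versa) the outcome
    beta is negated and its allele frequency complemented.  Palindromic
    variants (A/T, C/G) are ambiguous and dropped by default; with
    ``palindromic="infer"`` they are retained when both allele frequencies
    are far from 0.5 (``|eaf - 0.5| > eaf_tolerance``) and agree on strand.
    Allele pairs that match neither orientation are dropped.  Every flip and
    drop is recorded in the returned audit log.
    """
    if palindromic not in ("drop", "infer"):
        raise ValueError("palindromic must be 'drop' or 'infer'")
    _require_columns(exposure, "exposure")
    _require_columns(outcome, "outcome")

    exp = exposure.set_index("variant_id")
    out = outcome.set_index("variant_id")
    shared = exp.index.intersection(out.index)

    audit: list[dict] = []
    rows = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        oea, ooa = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()

        beta_y, eaf_y = float(o["beta"]), float(o.get("eaf", np.nan))
        if (ea, oa) in _PALINDROMIC:
            if palindromic == "drop":
                audit.append({"variant_id": vid, "action": "drop",
                              "reason": "palindromic"})
                continue
            eaf_x = float(e.get("eaf", np.nan))
            if (np.isnan(eaf_x) or np.isnan(eaf_y)
                    or abs(eaf_x - 0.5) <= eaf_tolerance
                    or abs(eaf_y - 0.5) <= eaf_tolerance):
                audit.append({"variant_id": vid, "action": "drop",
                              "reason": "palindromic, eaf uninformative"})
                continue
            # frequencies on opposite sides of 0.5 mean opposite orientation
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                audit.append({"variant_id": vid, "action": "flip",
                              "reason": "palindromic, eaf-inferred orientation"})
            else:
                audit.append({"variant_id": vid, "action": "keep",
                              "reason": "palindromic, eaf-consistent"})
        elif (oea, ooa) == (ea, oa):
            audit.append({"variant_id": vid, "action": "keep",
                          "reason": "aligned"})
        elif (oea, ooa) == (oa, ea):
            beta_y = -beta_y
            if not np.isnan(eaf_y):
                eaf_y = 1.0 - eaf_y
            audit.append({"variant_id": vid, "action": "flip",
                          "reason": "alleles swapped"})
        else:
            # try strand complement (e.g. A/G reported as T/C)
            cea = _COMPLEMENT.get(oea, "?")
            coa = _COMPLEMENT.get(ooa, "?")
            if (cea, coa) == (ea, oa):
                audit.append({"variant_id": vid, "action": "keep",
                              "reason": "strand-complemented, aligned"})
            elif (cea, coa) == (oa, ea):
                beta_y = -beta_y
                if not np.isnan(eaf_y):
                    eaf_y = 1.0 - eaf_y
                audit.append({"variant_id": vid, "action": "flip",
                              "reason": "strand-complemented, swapped"})
            else:
                audit.append({"variant_id": vid, "action": "drop",
                              "reason": f"incompatible alleles {oea}/{ooa} vs {ea}/{oa}"})
                continue

        rows.append({
            "variant_id": vid, "effect_allele": ea, "other_allele": oa,
            "beta_x": float(e["beta"]), "se_x": float(e["se"]),
            "p_x": float(e.get("pval", np.nan)),
            "beta_y": beta_y, "se_y": float(o["se"]),
            "eaf": float(e.get("eaf", np.nan)), "eaf_outcome": eaf_y,
        })
    harmonised = pd.DataFrame(rows, columns=[
        "variant_id", "effect_allele", "other_allele", "beta_x", "se_x",
        "p_x", "beta_y", "se_y", "eaf", "eaf_outcome"])
    return harmonised, audit


def ld_clump(variants: pd.DataFrame, ld_r2_matrix: np.ndarray,
             r2_threshold: float = 0.1) -> pd.DataFrame:
    """Greedy LD clumping: keep the most significant variant per clump.

    Repeatedly retains the remaining variant with the smallest exposure
    p-value (ties broken by ``variant_id``) and drops all remaining variants
    with r^2 >= threshold against it.
    """
    r2 = np.asarray(ld_r2_matrix, dtype=float)
    n = len(variants)
    if r2.shape != (n, n):
        raise ValueError(f"r2 matrix shape {r2.shape} does not match {n} variants")
    if not np.allclose(r2, r2.T, atol=1e-8):
        raise ValueError("r2 matrix must be symmetric")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")

    df = variants.reset_index(drop=True)
    order = df.sort_values(["p_x", "variant_id"], kind="mergesort").index.tolist()
    alive = np.ones(n, dtype=bool)
    keep: list[int] = []
    for idx in order:
        if not alive[idx]:
            continue
        keep.append(idx)
        alive[r2[idx] >= r2_threshold] = False
    keep.sort()
    return df.loc[keep].reset_index(drop=True)


def _check_variants(variants: pd.DataFrame, min_n: int, method: str) -> pd.DataFrame:
    needed = {"beta_x", "se_x", "beta_y", "se_y"}
    if not needed <= set(variants.columns):
        raise ValueError(f"harmonised table missing columns {needed - set(variants.columns)}")
    if len(variants) < min_n:
        raise ValueError(f"{method} needs at least {min_n} variants, got {len(variants)}")
    if (variants["se_y"] <= 0).any() or (variants["se_x"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return variants


def ivw(variants: pd.DataFrame) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    estimate = sum(bx*by/sy^2) / sum(bx^2/sy^2), the weighted regression of
    by on bx through the origin with weights 1/sy^2; Cochran's Q over the
    per-variant Wald ratios with n-1 df.
    """
    v = _check_variants(variants, 1, "IVW")
    bx = v["beta_x"].to_numpy(float)
    by = v["beta_y"].to_numpy(float)
    sy = v["se_y"].to_numpy(float)
    if len(v) == 1 and bx[0] == 0:
        raise ZeroDivisionError("single instrument with zero exposure effect")
    w = bx ** 2 / sy ** 2
    estimate = float(np.sum(bx * by / sy ** 2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = estimate / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bx != 0, by / bx, np.nan)
    q = float(np.nansum(w * (ratios - estimate) ** 2))
    q_df = len(v) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    ci = stats.norm.ppf(0.975) * se
    return MRResult(method="ivw", estimate=estimate, se=se, p_value=p,
                    n_variants=len(v), ci_low=estimate - ci, ci_high=estimate + ci,
                    q_statistic=q, q_df=q_df, q_p=q_p)


def mr_egger(variants: pd.DataFrame) -> MRResult:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Exposure effects are first oriented so all bx >= 0 (flipping the sign of
    both betas of a variant leaves its biology unchanged).  Slope = causal
    estimate; intercept = average directional pleiotropy with its own
    two-sided t test (df = n-2).  Inference uses the weighted-least-squares
    covariance with estimated scale.
    """
    import statsmodels.api as sm

    v = _check_variants(variants, 3, "MR-Egger")
    bx = v["beta_x"].to_numpy(float).copy()
    by = v["beta_y"].to_numpy(float).copy()
    sy = v["se_y"].to_numpy(float)
    flip = bx < 0
    bx[flip] = -bx[flip]
    by[flip] = -by[flip]
    if np.ptp(bx) == 0:
        raise ValueError("degenerate design: all exposure effects equal")

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy ** 2).fit()
    slope = float(fit.params[1])
    slope_se = float(fit.bse[1])
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    dof = len(v) - 2
    slope_p = float(2.0 * stats.t.sf(abs(slope / slope_se), dof))
    intercept_p = float(2.0 * stats.t.sf(abs(intercept / intercept_se), dof))
    resid = by - (intercept + slope * bx)
    q = float(np.sum(resid ** 2 / sy ** 2))
    q_p = float(stats.chi2.sf(q, dof)) if dof > 0 else float("nan")
    tcrit = stats.t.ppf(0.975, dof)
    return MRResult(method="egger", estimate=slope, se=slope_se, p_value=slope_p,
                    n_variants=len(v),
                    ci_low=slope - tcrit * slope_se, ci_high=slope + tcrit * slope_se,
                    intercept=intercept, intercept_se=intercept_se,
                    intercept_p=intercept_p, q_statistic=q, q_df=dof, q_p=q_p)


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Median of ratios under the cumulative-weight function, interpolated at 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def weighted_median(variants: pd.DataFrame, n_bootstrap: int = 1000,
                    seed: int = 0) -> MRResult:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Per-variant Wald ratios by/bx are weighted by the inverse of their
    first-order delta-method variance, w = bx^2/sy^2, and the estimate is the
    weight-interpolated median.  The SE is the standard deviation of the
    estimate over parametric redraws beta ~ N(beta_hat, se).
    """
    v = _check_variants(variants, 1, "weighted median")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    bx = v["beta_x"].to_numpy(float)
    by = v["beta_y"].to_numpy(float)
    sx = v["se_x"].to_numpy(float)
    sy = v["se_y"].to_numpy(float)
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure effect makes a Wald ratio undefined")
    weights = bx ** 2 / sy ** 2
    estimate = _weighted_median_estimate(by / bx, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb = np.where(bxb == 0, 1e-12, bxb)
        boots[b] = _weighted_median_estimate(byb / bxb, bxb ** 2 / sy ** 2)
    se = float(np.std(boots, ddof=1)) if n_bootstrap > 1 else float("nan")
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(estimate / se)))
        ci = stats.norm.ppf(0.975) * se
        ci_low, ci_high = estimate - ci, estimate + ci
    else:
        p, ci_low, ci_high = float("nan"), float("nan"), float("nan")
    return MRResult(method="weighted_median", estimate=estimate, se=se,
                    p_value=p, n_variants=len(v), ci_low=ci_low, ci_high=ci_high)


def mr_suite(exposure: pd.DataFrame, outcome: pd.DataFrame,
             ld_r2_matrix: np.ndarray | None = None,
             r2_threshold: float = 0.1,
             palindromic: str = "drop",
             n_bootstrap: int = 1000,
             seed: int = 0) -> dict:
    """Harmonise, clump, and run IVW + Egger + weighted median with Q tests.

    Returns a dict with the harmonised table, audit log, a per-method report
    DataFrame, and flags: pleiotropy when the Egger intercept p < 0.05,
    heterogeneity when the IVW Q p < 0.05.  With fewer than 3 post-clump
    variants the Egger fit is skipped and a warning is recorded.
    """
    harmonised, audit = harmonise(exposure, outcome, palindromic=palindromic)
    if ld_r2_matrix is not None:
        harmonised = ld_clump(harmonised, ld_r2_matrix, r2_threshold)
    if harmonised.empty:
        raise ValueError("no variants survived harmonisation/clumping")

    warnings_list: list[str] = []
    results = [ivw(harmonised),
               weighted_median(harmonised, n_bootstrap=n_bootstrap, seed=seed)]
    if len(harmonised) >= 3:
        results.insert(1, mr_egger(harmonised))
    else:
        warnings_list.append(
            f"only {len(harmonised)} variants after clumping; MR-Egger skipped")

    report = pd.DataFrame([{
        "method": r.method, "estimate": r.estimate, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
        "intercept": r.intercept, "intercept_se": r.intercept_se,
        "intercept_p": r.intercept_p, "q_statistic": r.q_statistic,
        "q_df": r.q_df, "q_p": r.q_p, "n_variants": r.n_variants,
    } for r in results])

    egger = next((r for r in results if r.method == "egger"), None)
    ivw_res = results[0]
    return {
        "harmonised": harmonised,
        "audit": audit,
        "report": report,
        "results": {r.method: r for r in results},
        "pleiotropy_flag": bool(egger and egger.intercept_p is not None
                                and egger.intercept_p < 0.05),
        "heterogeneity_flag": bool(ivw_res.q_p is not None
                                   and np.isfinite(ivw_res.q_p)
                                   and ivw_res.q_p < 0.05),
        "warnings": warnings_list,
    }
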