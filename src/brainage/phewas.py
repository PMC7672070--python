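"""Phenome-wide association scan of traits against the brain-age difference.

Each trait is regressed on the standardized brain-age difference (delta in
SD units, SD computed on the analysis cohort) with adjustment for age, sex
and assessment centre: ordinary least squares for continuous traits,
logistic regression for binary traits, and a cumulative-logit (proportional
odds) model for ordered traits.  Rows with missing values are excluded per
trait.  Multiplicity is controlled family-wise by Bonferroni and by the
Benjamini-Hochberg step-up rule at a chosen false-discovery rate.

Binary and ordinal effects are reported as odds ratios per SD of delta;
continuous effects as betas per SD.  Traits that cannot be analysed (too few
observations, degenerate classes, non-converged fits) are reported with a
status string, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "TraitTable",
    "AssocResult",
    "association_scan",
    "bonferroni_threshold",
    "bh_fdr",
    "scan_report",
]

MIN_N = 10
MIN_PER_CLASS = 2


@dataclass
class TraitTable:
    """A typed trait table: covariates plus trait columns with declared kinds."""

    data: pd.DataFrame
    types: Mapping[str, str]        # trait column -> continuous | binary | ordinal
    covariates: tuple[str, ...] = ("age", "sex", "centre")
    id_column: str = "subject_id"

    def __post_init__(self):
        if self.data[self.id_column].duplicated().any():
            raise ValueError("subject ids must be unique")
        missing = [c for c in self.types if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait columns absent from table: {missing}")
        bad = {k: v for k, v in self.types.items()
               if v not in ("continuous", "binary", "ordinal")}
        if bad:
            raise ValueError(f"unknown trait types: {bad}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.types)


@dataclass
class AssocResult:
    trait: str
    kind: str
    effect: float                   # beta per SD (continuous) or OR per SD (binary/ordinal)
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_missing: int
    n_cases: int | None = None
    n_controls: int | None = None
    status: str = "ok"

    def __post_init__(self):
        if self.status == "ok" and not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("effect must lie inside its confidence interval")


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Exposure + covariate design matrix with centre as fixed-effect dummies."""
    cols = {"z_delta": df["z_delta"].astype(float)}
    for cov in covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.update({c: dummies[c] for c in dummies.columns})
        else:
            cols[cov] = col.astype(float)
    X = pd.DataFrame(cols, index=df.index)
    return sm.add_constant(X, has_constant="add")


def _skip(trait: str, kind: str, n_used: int, n_missing: int, reason: str) -> AssocResult:
    return AssocResult(trait=trait, kind=kind, effect=np.nan, ci_low=np.nan,
                       ci_high=np.nan, p_value=np.nan, n_used=n_used,
                       n_missing=n_missing, status=reason)


def association_scan(deltas: pd.DataFrame | pd.Series,
                     traits: TraitTable) -> list[AssocResult]:
    """Regress every trait on the standardized brain-age difference.

    ``deltas`` is either a Series indexed by subject id or a DataFrame with
    ``subject_id`` and ``delta`` columns.  The exposure is standardized once,
    by the delta SD of the joined analysis cohort, so per-SD effects are
    comparable across traits and invariant to rescaling delta.
    """
    if isinstance(deltas, pd.Series):
        ddf = deltas.rename("delta").rename_axis(traits.id_column).reset_index()
    else:
        ddf = deltas[[traits.id_column, "delta"]].copy()
    merged = ddf.merge(traits.data, on=traits.id_column, how="inner")
    if merged.empty:
        raise ValueError("no overlapping subjects between deltas and trait table")

    sd = merged["delta"].std(ddof=0)
    if sd == 0:
        raise ValueError("delta has zero variance")
    merged["z_delta"] = merged["delta"] / sd

    results: list[AssocResult] = []
    n_total = len(merged)
    for trait in traits.trait_names:
        kind = traits.types[trait]
        cols = ["z_delta", trait] + [c for c in traits.covariates
                                     if c in merged.columns]
        sub = merged[cols].dropna()
        n_used, n_missing = len(sub), n_total - len(sub)
        if n_used < MIN_N:
            results.append(_skip(trait, kind, n_used, n_missing,
                                 f"skipped: n={n_used} < {MIN_N}"))
            continue
        y = sub[trait].astype(float)
        X = _design(sub, traits.covariates).astype(float)
        try:
            if kind == "continuous":
                fit = sm.OLS(y, X).fit()
                eff = float(fit.params["z_delta"])
                lo, hi = map(float, fit.conf_int().loc["z_delta"])
                p = float(fit.pvalues["z_delta"])
                results.append(AssocResult(trait, kind, eff, lo, hi, p,
                                           n_used, n_missing))
            elif kind == "binary":
                classes = y.value_counts()
                if len(classes) < 2 or classes.min() < MIN_PER_CLASS:
                    results.append(_skip(trait, kind, n_used, n_missing,
                                         "skipped: degenerate binary classes"))
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True):
                    results.append(_skip(trait, kind, n_used, n_missing,
                                         "failed: logistic fit did not converge"))
                    continue
                coef = float(fit.params["z_delta"])
                lo, hi = map(float, fit.conf_int().loc["z_delta"])
                p = float(fit.pvalues["z_delta"])
                results.append(AssocResult(
                    trait, kind, float(np.exp(coef)), float(np.exp(lo)),
                    float(np.exp(hi)), p, n_used, n_missing,
                    n_cases=int(classes.get(1.0, 0)),
                    n_controls=int(classes.get(0.0, 0))))
            else:  # ordinal: proportional-odds cumulative logit
                if y.nunique() < 2:
                    results.append(_skip(trait, kind, n_used, n_missing,
                                         "skipped: single ordinal level"))
                    continue
                exog = X.drop(columns="const")     # OrderedModel fits its own cutpoints
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = OrderedModel(y, exog, distr="logit").fit(
                        method="bfgs", disp=0, maxiter=200)
                coef = float(fit.params["z_delta"])
                lo, hi = map(float, fit.conf_int().loc["z_delta"])
                p = float(fit.pvalues["z_delta"])
                results.append(AssocResult(
                    trait, kind, float(np.exp(coef)), float(np.exp(lo)),
                    float(np.exp(hi)), p, n_used, n_missing))
        except (np.linalg.LinAlgError, ValueError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            results.append(_skip(trait, kind, n_used, n_missing,
                                 f"failed: {type(exc).__name__}: {exc}"))
    return results


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p_values: Sequence[float], q: float) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up rule at FDR level ``q``.

    Returns a boolean rejection mask aligned with the input and the adaptive
    threshold p(k) (0.0 when nothing is rejected).  NaN p-values are never
    rejected but still count toward m, the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), 0.0
    order = np.argsort(np.where(finite, p, np.inf))
    sorted_p = p[order]
    ks = np.arange(1, m + 1)
    ok = np.where(finite[order] & (sorted_p <= ks * q / m))[0]
    mask = np.zeros(m, dtype=bool)
    if len(ok) == 0:
        return mask, 0.0
    k = ok[-1]
    mask[order[:k + 1]] = True
    return mask, float(sorted_p[k])


def scan_report(results: Sequence[AssocResult], bonferroni_p: float,
                fdr_q: float = 0.05) -> pd.DataFrame:
    """Ranked association table with Bonferroni and FDR significance flags.

    ``direction`` is "direct" for effects above the null value (0 for betas,
    1 for odds ratios) and "inverse" below it.
    """
    if not len(results):
        raise ValueError("no results to report")
    rows = []
    for r in results:
        null_value = 1.0 if r.kind in ("binary", "ordinal") else 0.0
        if r.status == "ok":
            direction = "direct" if r.effect > null_value else "inverse"
        else:
            direction = ""
        rows.append({
            "trait": r.trait, "kind": r.kind, "effect": r.effect,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
            "n_used": r.n_used, "n_cases": r.n_cases, "n_controls": r.n_controls,
            "direction": direction, "status": r.status,
        })
    df = pd.DataFrame(rows)
    mask, fdr_thresh = bh_fdr(df["p_value"].to_numpy(), fdr_q)
    df["bonferroni_significant"] = (df["p_value"] < bonferroni_p).fillna(False)
    df["fdr_significant"] = mask
    df.attrs["bonferroni_threshold"] = bonferroni_p
    df.attrs["fdr_threshold"] = fdr_thresh
    df = df.sort_values("p_value", kind="mergesort", na_position="last")
    return df.reset_index(drop=True)


def manhattan_plot(report: pd.DataFrame, path: str,
                   bonferroni_p: float | None = None,
                   fdr_p: float | None = None) -> None:
    """Basic Manhattan-style export of the scan (-log10 p per trait)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = report[report["status"] == "ok"]
    fig, ax = plt.subplots(figsize=(max(6, len(ok) * 0.05), 4))
    ax.scatter(range(len(ok)), -np.log10(ok["p_value"].clip(lower=1e-300)), s=8)
    if bonferroni_p:
        ax.axhline(-np.log10(bonferroni_p), color="red", lw=1,
                   label="Bonferroni")
    if fdr_p:
        ax.axhline(-np.log10(fdr_p), color="blue", lw=1, label="5% FDR")
    ax.set_xlabel("trait index (sorted by p)")
    ax.set_ylabel("-log10 p")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
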