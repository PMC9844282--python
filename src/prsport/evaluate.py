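"""Phenotype preparation, dichotomization, and PRS predictive-power estimation.

Continuous traits are evaluated with ordinary least squares and the PRS
increment in R²; dichotomized traits with nested logistic regressions and
McFadden's pseudo-R² = 1 - d1/d0, where d1/d0 are the deviances
(-2 log-likelihood) of the models with and without the PRS.  Group and
extreme-tail contrasts use Welch's two-sample t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DICHOTOMIZE_RULES = (
    "chronotype_extremes",
    "sleep_extremes",
    "insomnia_finrisk",
    "insomnia_health",
)

SLEEP_MIN_H = 3.0  # exclusive lower cut, hours
SLEEP_MAX_H = 16.0  # exclusive upper cut


class EvaluateError(ValueError):
    pass


@dataclass
class EvalReport:
    """Result of one PRS-vs-trait evaluation."""

    n: int
    model: str  # "linear" | "logistic" | "ttest" | "tail"
    r2_full: float | None = None
    r2_base: float | None = None
    incremental_r2: float | None = None
    pseudo_r2: float | None = None
    deviance_full: float | None = None
    deviance_base: float | None = None
    prs_coef: float | None = None
    prs_se: float | None = None
    prs_pvalue: float | None = None
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)
    group_ns: dict = field(default_factory=dict)
    difference: float | None = None
    difference_minutes: float | None = None
    t_statistic: float | None = None
    t_pvalue: float | None = None
    converged: bool = True
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            out[k] = v
        return out


def prepare_phenotypes(
    raw: pd.DataFrame,
    seed: int,
    id_col: str = "sample",
    trait_cols: tuple[str, ...] = ("sleep_duration", "chronotype", "insomnia"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse repeated questionnaire answers and apply sleep-duration cuts.

    Participants may appear on several rows (follow-up waves).  For each
    participant and each trait with more than one non-missing answer,
    exactly one answer is retained, chosen by a seeded uniform draw so the
    selection is reproducible.  Sleep durations <= 3 h or >= 16 h are set to
    missing and counted.  Non-numeric trait values are treated as missing
    and counted.  Non-trait columns (age, sex, ...) take the value from the
    participant's first row.

    Returns the one-row-per-participant table and a counts dict
    (``sleep_excluded``, ``non_numeric``, ``multi_answer``).
    """
    rng = np.random.default_rng(seed)
    counts = {"sleep_excluded": 0, "non_numeric": 0, "multi_answer": 0}

    present_traits = [c for c in trait_cols if c in raw.columns]
    df = raw.copy()
    for c in present_traits:
        coerced = pd.to_numeric(df[c], errors="coerce")
        counts["non_numeric"] += int((coerced.isna() & df[c].notna()).sum())
        df[c] = coerced

    if "sleep_duration" in df.columns:
        bad = df["sleep_duration"].notna() & (
            (df["sleep_duration"] <= SLEEP_MIN_H) | (df["sleep_duration"] >= SLEEP_MAX_H)
        )
        counts["sleep_excluded"] = int(bad.sum())
        df.loc[bad, "sleep_duration"] = np.nan

    out_rows = []
    # stable participant order so the seeded draws are reproducible
    for pid, grp in df.groupby(id_col, sort=True):
        row = grp.iloc[0].copy()
        for c in present_traits:
            vals = grp[c].dropna().to_numpy()
            if len(vals) == 0:
                row[c] = np.nan
            elif len(vals) == 1:
                row[c] = vals[0]
            else:
                counts["multi_answer"] += 1
                row[c] = vals[rng.integers(len(vals))]
        out_rows.append(row)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return out, counts


def dichotomize(values, rule: str) -> tuple[np.ndarray, dict[str, int]]:
    """Map an ordinal/continuous trait to binary case labels.

    Returns a float array with 1.0 = case, 0.0 = control, NaN = excluded,
    plus the case/control/excluded counts.  Rules:

    - ``chronotype_extremes``: 1 (absolutely morning) -> case, 4 (absolutely
      evening) -> control, 2/3 -> excluded.
    - ``sleep_extremes``: <= 6 h -> case (short sleeper), >= 9 h -> control
      (long sleeper), otherwise excluded.
    - ``insomnia_finrisk`` (1-3 scale, often/sometimes/not at all):
      1 -> case (severe), 3 -> control (none), 2 -> excluded.
    - ``insomnia_health`` (1-5 scale, none..severe): 4 or 5 -> case,
      1 -> control, 2/3 -> excluded.
    """
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="raise"), dtype=float)
    out = np.full(v.shape, np.nan)
    present = ~np.isnan(v)

    if rule == "chronotype_extremes":
        valid = {1, 2, 3, 4}
        out[present & (v == 1)] = 1.0
        out[present & (v == 4)] = 0.0
    elif rule == "sleep_extremes":
        valid = None
        out[present & (v <= 6)] = 1.0
        out[present & (v >= 9)] = 0.0
    elif rule == "insomnia_finrisk":
        valid = {1, 2, 3}
        out[present & (v == 1)] = 1.0
        out[present & (v == 3)] = 0.0
    elif rule == "insomnia_health":
        valid = {1, 2, 3, 4, 5}
        out[present & ((v == 4) | (v == 5))] = 1.0
        out[present & (v == 1)] = 0.0
    else:
        raise EvaluateError(f"unknown rule {rule!r}; choose from {DICHOTOMIZE_RULES}")

    if valid is not None:
        bad = present & ~np.isin(v, list(valid))
        if bad.any():
            codes = sorted(set(v[bad].tolist()))
            raise EvaluateError(f"out-of-range code(s) {codes} for rule {rule!r}")

    counts = {
        "case": int(np.nansum(out == 1.0)),
        "control": int(np.nansum(out == 0.0)),
        "excluded": int(present.sum() - np.isfinite(out[present]).sum()),
        "missing": int((~present).sum()),
    }
    return out, counts


def _design(
    prs: np.ndarray, covars: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Base (intercept + covariates) and full (base + PRS) design matrices."""
    n = len(prs)
    if covars is None:
        c = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(covars, pd.DataFrame):
        c = covars.to_numpy(dtype=float)
        names = list(covars.columns)
    else:
        c = np.asarray(covars, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        names = [f"covar{i}" for i in range(c.shape[1])]
    base = np.column_stack([np.ones(n), c])
    full = np.column_stack([base, prs])
    return base, full, names


def _check_collinear(base: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(base)
    if rank < base.shape[1]:
        # locate a minimal offending column for the error message
        for j in range(1, base.shape[1]):
            if np.linalg.matrix_rank(base[:, : j + 1]) < j + 1:
                name = names[j - 1] if j - 1 < len(names) else f"column {j}"
                raise EvaluateError(f"collinear covariates: {name} is linearly dependent")
        raise EvaluateError("collinear covariates")


def _complete_cases(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        x = a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, dtype=float)
        if x.ndim == 1:
            ok &= np.isfinite(x)
        else:
            ok &= np.isfinite(x).all(axis=1)
    return ok


def linear_incremental_r2(y, prs, covars=None) -> EvalReport:
    """OLS with and without the PRS; reports the R² increment.

    ``incremental_r2 = R²_full - R²_base``; the full-model R² is also
    reported since some publications print that instead.
    """
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    ok = _complete_cases(y, prs, covars)
    y, prs = y[ok], prs[ok]
    if isinstance(covars, pd.DataFrame):
        covars = covars.loc[ok] if covars is not None else None
    elif covars is not None:
        covars = np.asarray(covars, dtype=float)[ok]

    base, full, names = _design(prs, covars)
    if len(y) <= full.shape[1]:
        raise EvaluateError(f"n={len(y)} too small for {full.shape[1]} predictors")
    _check_collinear(base, names)

    fit_base = sm.OLS(y, base).fit()
    fit_full = sm.OLS(y, full).fit()
    return EvalReport(
        n=len(y),
        model="linear",
        r2_full=float(fit_full.rsquared),
        r2_base=float(fit_base.rsquared),
        incremental_r2=float(fit_full.rsquared - fit_base.rsquared),
        prs_coef=float(fit_full.params[-1]),
        prs_se=float(fit_full.bse[-1]),
        prs_pvalue=float(fit_full.pvalues[-1]),
    )


def logistic_pseudo_r2(y, prs, covars=None) -> EvalReport:
    """Nested logistic fits; McFadden-style pseudo-R² on the PRS.

    d0 is the deviance (-2 log-likelihood) of the covariates-only model, d1
    of the model with the PRS added; pseudo-R² = 1 - d1/d0.  A constant PRS
    contributes nothing, so d1 = d0 and the value is exactly 0.  Perfect
    separation is reported with a flag rather than raised.
    """
    y = np.asarray(y, dtype=float)
    prs = np.asarray(prs, dtype=float)
    ok = _complete_cases(y, prs, covars)
    y, prs = y[ok], prs[ok]
    if isinstance(covars, pd.DataFrame):
        covars = covars.loc[ok] if covars is not None else None
    elif covars is not None:
        covars = np.asarray(covars, dtype=float)[ok]

    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) != 2:
        raise EvaluateError("y must contain both classes coded 0/1")

    base, full, names = _design(prs, covars)
    _check_collinear(base, names)

    flags: list[str] = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_base = sm.Logit(y, base).fit(disp=0, maxiter=200)
        d0 = -2.0 * fit_base.llf
        if np.ptp(prs) == 0.0:
            # PRS collinear with the intercept: the nested fit is the base fit
            d1 = d0
            coef = se = np.nan
            pval = np.nan
            flags.append("constant_prs")
        else:
            try:
                fit_full = sm.Logit(y, full).fit(disp=0, maxiter=200)
                d1 = -2.0 * fit_full.llf
                coef = float(fit_full.params[-1])
                se = float(fit_full.bse[-1])
                pval = float(fit_full.pvalues[-1])
                if not fit_full.mle_retvals.get("converged", True):
                    converged = False
                    flags.append("unconverged")
            except Exception:  # perfect separation and friends
                flags.append("perfect_separation")
                converged = False
                fit_full = sm.Logit(y, full).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
                d1 = -2.0 * float(fit_full.llf)
                coef = float(fit_full.params[-1])
                se = pval = np.nan

    pseudo = 0.0 if d1 == d0 else float(1.0 - d1 / d0)
    return EvalReport(
        n=len(y),
        model="logistic",
        pseudo_r2=pseudo,
        deviance_full=float(d1),
        deviance_base=float(d0),
        prs_coef=None if isinstance(coef, float) and math.isnan(coef) else coef,
        prs_se=None if isinstance(se, float) and math.isnan(se) else se,
        prs_pvalue=None if isinstance(pval, float) and math.isnan(pval) else pval,
        converged=converged,
        flags=flags,
    )


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p; degenerate cases handled."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / len(a) + vb / len(b)
    if se2 == 0:
        return (0.0, 1.0) if diff == 0 else (math.copysign(math.inf, diff), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def group_prs_compare(prs, labels) -> EvalReport:
    """Welch two-sample t-test on the PRS between two labelled groups.

    ``labels`` is binary (1 = case, 0 = control, NaN excluded).
    """
    prs = np.asarray(prs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ok = np.isfinite(prs) & np.isfinite(labels)
    prs, labels = prs[ok], labels[ok]
    a = prs[labels == 1.0]
    b = prs[labels == 0.0]
    if len(a) < 2 or len(b) < 2:
        raise EvaluateError("each group needs at least 2 members")
    t, p = _welch(a, b)
    return EvalReport(
        n=len(a) + len(b),
        model="ttest",
        group_means={"case": float(a.mean()), "control": float(b.mean())},
        group_sds={"case": float(a.std(ddof=1)), "control": float(b.std(ddof=1))},
        group_ns={"case": len(a), "control": len(b)},
        difference=float(a.mean() - b.mean()),
        t_statistic=t,
        t_pvalue=p,
    )


def tail_contrast(prs, trait, q: float = 0.05) -> EvalReport:
    """Compare a trait between the top and bottom q-tails of the PRS.

    Top group: samples with PRS >= the (1-q) nearest-rank quantile; bottom:
    PRS <= the q quantile.  Ties are kept, so groups may exceed q*n.  The
    trait difference is also reported in minutes (x60), for traits in hours.
    """
    prs = np.asarray(prs, dtype=float)
    trait = np.asarray(trait, dtype=float)
    ok = np.isfinite(prs) & np.isfinite(trait)
    prs, trait = prs[ok], trait[ok]
    n = len(prs)
    if n < 2.0 / q:
        raise EvaluateError(f"n={n} too small for q={q} tails")
    if np.ptp(prs) == 0.0:
        raise EvaluateError("degenerate PRS: all values equal")

    srt = np.sort(prs)
    k = max(1, math.ceil(q * n))  # nearest-rank tail size
    lo_cut = float(srt[k - 1])
    hi_cut = float(srt[n - k])
    bottom = trait[prs <= lo_cut]
    top = trait[prs >= hi_cut]
    t, p = _welch(top, bottom)
    diff = float(top.mean() - bottom.mean())
    return EvalReport(
        n=len(top) + len(bottom),
        model="tail",
        group_means={"top": float(top.mean()), "bottom": float(bottom.mean())},
        group_sds={"top": float(top.std(ddof=1)), "bottom": float(bottom.std(ddof=1))},
        group_ns={"top": len(top), "bottom": len(bottom)},
        difference=diff,
        difference_minutes=diff * 60.0,
        t_statistic=t,
        t_pvalue=p,
    )
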