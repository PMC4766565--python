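"""Conventional and instrumental-variable regression models, plus meta-analysis.

Three model tiers relate blood pressure to retinal vascular caliber:

* model1 — OLS adjusting for age, gender and ethnicity;
* model2 — model1 plus household income, BMI, total cholesterol, glucose,
  creatinine, hypertension and diabetes status, smoking and alcohol history;
* model3 — Mendelian randomisation: two-stage least squares with a weighted
  BP genetic risk score as instrument, adjusting for age, gender and the
  first five genetic principal components.

Effect sizes are reported per 10 mmHg of the exposure. 2SLS standard errors
use residuals computed with the observed (not predicted) exposure — the
standard correction without which naive two-stage OLS SEs are wrong.
Cross-stratum pooling is inverse-variance fixed-effects with Cochran's Q
and I² heterogeneity diagnostics (DerSimonian-Laird random effects offered).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "TIER_COVARIATES",
    "fit_ols",
    "fit_2sls",
    "pleiotropy_check",
    "fit_stratified",
    "meta_fixed",
    "meta_random",
    "build_table2",
    "results_table",
    "format_table2",
    "format_table3",
]

MODEL2_EXTRAS_METHODS = [
    "household_income",
    "bmi",
    "total_cholesterol",
    "glucose",
    "creatinine",
    "presence_of_hypertension",
    "presence_of_diabetes",
    "smoking",
    "alcohol",
]
# Alternative covariate list using medication/history indicators instead of
# the derived presence flags.
MODEL2_EXTRAS_FOOTNOTE = [
    "household_income",
    "bmi",
    "total_cholesterol",
    "glucose",
    "creatinine",
    "htn_medication",
    "diabetes_dx",
    "smoking",
    "alcohol",
]

TIER_COVARIATES: dict[str, list[str]] = {
    "model1": ["age", "gender", "stratum"],
    "model2": ["age", "gender", "stratum"] + MODEL2_EXTRAS_METHODS,
    "model3": ["age", "gender", "pc1", "pc2", "pc3", "pc4", "pc5"],
}


@dataclass(frozen=True)
class ModelSpec:
    """One exposure-outcome model cell."""

    outcome: str  # crae | crve
    exposure: str  # sbp | dbp | map
    tier: str  # model1 | model2 | model3
    covariates: tuple[str, ...] | None = None
    scale_per: float = 10.0  # report β per this many mmHg

    def __post_init__(self) -> None:
        if self.scale_per <= 0:
            raise ValueError("scale_per must be positive")
        if self.tier not in TIER_COVARIATES:
            raise ValueError(f"unknown tier {self.tier!r}")

    def covariate_list(self) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        return list(TIER_COVARIATES[self.tier])


@dataclass(frozen=True)
class FitResult:
    """Exposure coefficient for one fitted model (β per scale_per mmHg)."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    outcome: str
    exposure: str
    tier: str
    stratum: str = "pooled"
    method: str = "ols"
    first_stage_f: float | None = None
    q_stat: float | None = None
    i2: float | None = None
    k: int | None = None
    warnings: tuple[str, ...] = ()


def _expand_design(data: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix: booleans to ints, categoricals to dummies."""
    parts: list[pd.DataFrame] = []
    for c in columns:
        col = data[c]
        if col.dtype == bool or str(col.dtype) == "boolean":
            parts.append(col.astype("float").to_frame(c))
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(c))
    if not parts:
        return pd.DataFrame(index=data.index)
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        bad = [X.columns[i] for i in range(arr.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _prepare(data: pd.DataFrame, spec: ModelSpec, extra: Sequence[str] = ()):
    cols = [spec.outcome, spec.exposure, *spec.covariate_list(), *extra]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    d = data[list(dict.fromkeys(cols))].dropna()
    need = len(spec.covariate_list()) + 2
    if len(d) < need:
        raise ValueError(f"too few complete cases ({len(d)}) for {need} parameters")
    return d


def _result_from(beta, se, p, n, spec, stratum, method, fsf=None, warnings=()):
    s = spec.scale_per
    return FitResult(
        beta=beta * s,
        se=se * s,
        ci_low=(beta - 1.96 * se) * s,
        ci_high=(beta + 1.96 * se) * s,
        p_value=p,
        n=n,
        outcome=spec.outcome,
        exposure=spec.exposure,
        tier=spec.tier,
        stratum=stratum,
        method=method,
        first_stage_f=fsf,
        warnings=tuple(warnings),
    )


def fit_ols(data: pd.DataFrame, spec: ModelSpec, *, stratum: str = "pooled") -> FitResult:
    """Multiple linear regression of the outcome on the exposure + covariates."""
    d = _prepare(data, spec)
    X = _expand_design(d, [spec.exposure, *spec.covariate_list()])
    X = sm.add_constant(X, has_constant="add")
    _check_rank(X)
    fit = sm.OLS(d[spec.outcome].astype(float), X).fit()
    return _result_from(
        float(fit.params[spec.exposure]),
        float(fit.bse[spec.exposure]),
        float(fit.pvalues[spec.exposure]),
        int(fit.nobs),
        spec,
        stratum,
        "ols",
    )


def fit_2sls(
    data: pd.DataFrame,
    spec: ModelSpec,
    instrument: str,
    *,
    stratum: str = "pooled",
    weak_f_threshold: float = 10.0,
) -> FitResult:
    """Two-stage least squares with a genetic-risk-score instrument.

    Stage 1 regresses the exposure on the instrument and covariates; stage 2
    regresses the outcome on the predicted exposure and the same covariates.
    The reported SE uses stage-2 residuals recomputed with the observed
    exposure. The first-stage partial F of the instrument is attached; below
    ``weak_f_threshold`` a weak-instrument warning is recorded (not an error).
    """
    d = _prepare(data, spec, extra=[instrument])
    z = d[instrument].astype(float).to_numpy()
    if np.ptp(z) == 0:
        raise ValueError(f"instrument {instrument!r} is constant")
    W = _expand_design(d, spec.covariate_list())
    W = sm.add_constant(W, has_constant="add")
    x = d[spec.exposure].astype(float).to_numpy()
    y = d[spec.outcome].astype(float).to_numpy()
    Wz = np.column_stack([z, W.to_numpy(dtype=float)])
    _check_rank(pd.DataFrame(Wz, columns=[instrument, *W.columns]))

    # stage 1 + partial F of the instrument
    b1, *_ = np.linalg.lstsq(Wz, x, rcond=None)
    xhat = Wz @ b1
    r1 = x - xhat
    n, k1 = Wz.shape
    s2_1 = float(r1 @ r1) / (n - k1)
    fsf = float(b1[0] ** 2 / (s2_1 * np.linalg.pinv(Wz.T @ Wz)[0, 0]))

    # stage 2 on predicted exposure; SE from observed-exposure residuals
    Xh = np.column_stack([xhat, W.to_numpy(dtype=float)])
    b2, *_ = np.linalg.lstsq(Xh, y, rcond=None)
    Xobs = np.column_stack([x, W.to_numpy(dtype=float)])
    resid = y - Xobs @ b2
    k2 = Xh.shape[1]
    sigma2 = float(resid @ resid) / (n - k2)
    cov = sigma2 * np.linalg.pinv(Xh.T @ Xh)
    beta, se = float(b2[0]), float(np.sqrt(max(cov[0, 0], 0.0)))
    p = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    warns = []
    if fsf < weak_f_threshold:
        warns.append(f"weak_instrument: first-stage F={fsf:.2f} < {weak_f_threshold}")
    return _result_from(beta, se, p, n, spec, stratum, "2sls", fsf, warns)


def pleiotropy_check(
    data: pd.DataFrame,
    grs_columns: Sequence[str],
    confounder_columns: Sequence[str],
    *,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Regress each traditional confounder on each BP genetic risk score.

    Under the Mendelian-randomisation exclusion assumptions these
    associations should be null; systematic signal indicates pleiotropy.
    Returns one row per (confounder, GRS) pair with β, SE, p and n, the
    score entering per 1 score unit.
    """
    rows = []
    for conf in confounder_columns:
        for grs in grs_columns:
            spec = ModelSpec(
                outcome=conf, exposure=grs, tier="model1",
                covariates=tuple(covariates), scale_per=1.0,
            )
            d = _prepare(data, spec)
            if np.ptp(d[conf].astype(float).to_numpy()) == 0:
                raise ValueError(f"confounder {conf!r} is constant")
            r = fit_ols(data, spec)
            rows.append(
                {"confounder": conf, "grs": grs, "beta": r.beta, "se": r.se,
                 "p_value": r.p_value, "n": r.n}
            )
    return pd.DataFrame(rows)


def fit_stratified(
    data: pd.DataFrame,
    spec: ModelSpec,
    strata_column: str,
    *,
    fitter: Callable[..., FitResult] = fit_ols,
    **fit_kwargs,
) -> list[FitResult]:
    """Fit the spec separately within each level of a stratifying column.

    Covariates constant within a stratum (e.g. hypertension status inside
    hypertension-defined strata) are dropped automatically with a log note.
    """
    results = []
    for level in sorted(data[strata_column].dropna().unique(), key=str):
        sub = data[data[strata_column] == level]
        covs = []
        for c in spec.covariate_list():
            if c in sub.columns and sub[c].dropna().nunique() <= 1:
                log.info("stratum %s: dropping constant covariate %r", level, c)
            else:
                covs.append(c)
        sspec = replace(spec, covariates=tuple(covs))
        results.append(fitter(sub, sspec, stratum=str(level), **fit_kwargs))
    return results


def _check_meta_compatible(results: Sequence[FitResult]) -> None:
    if not results:
        raise ValueError("no results to pool")
    tags = {(r.outcome, r.exposure, r.tier) for r in results}
    if len(tags) > 1:
        raise ValueError(f"cannot pool results with mismatched specs: {sorted(tags)}")


def meta_fixed(results: Sequence[FitResult]) -> FitResult:
    """Inverse-variance fixed-effects pooling across strata.

    β* = Σwβ/Σw with w = 1/se²; se* = 1/√Σw. Cochran's Q and I² quantify
    heterogeneity. A single result pools to itself.
    """
    _check_meta_compatible(results)
    b = np.array([r.beta for r in results])
    w = np.array([1.0 / r.se**2 for r in results])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = len(results)
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    r0 = results[0]
    return FitResult(
        beta=beta, se=se, ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        p_value=float(2.0 * stats.norm.sf(abs(beta / se))),
        n=int(sum(r.n for r in results)),
        outcome=r0.outcome, exposure=r0.exposure, tier=r0.tier,
        stratum="meta", method="meta_fixed",
        first_stage_f=None, q_stat=q, i2=i2, k=k,
        warnings=tuple(w for r in results for w in r.warnings),
    )


def meta_random(results: Sequence[FitResult]) -> FitResult:
    """DerSimonian-Laird random-effects pooling."""
    _check_meta_compatible(results)
    fixed = meta_fixed(results)
    b = np.array([r.beta for r in results])
    w = np.array([1.0 / r.se**2 for r in results])
    k = len(results)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (fixed.q_stat - (k - 1)) / c) if c > 0 else 0.0
    wr = 1.0 / (np.array([r.se**2 for r in results]) + tau2)
    beta = float(np.sum(wr * b) / np.sum(wr))
    se = float(1.0 / np.sqrt(np.sum(wr)))
    return replace(
        fixed, beta=beta, se=se, ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se,
        p_value=float(2.0 * stats.norm.sf(abs(beta / se))), method="meta_random",
    )


EXPOSURES = ("sbp", "dbp", "map")
OUTCOMES = ("crae", "crve")
TIERS = ("model1", "model2", "model3")


def build_table2(
    data: pd.DataFrame,
    *,
    exposures: Sequence[str] = EXPOSURES,
    outcomes: Sequence[str] = OUTCOMES,
    tiers: Sequence[str] = TIERS,
    grs_prefix: str = "grs_",
    strata_column: str = "stratum",
    model3_mode: str = "meta",
    model2_covariates: str = "methods",
    scale_per: float = 10.0,
    weak_f_threshold: float = 10.0,
    meta_method: str = "fixed",
) -> list[FitResult]:
    """Fit the full exposures × outcomes × tiers grid.

    Tiers 1-2 are pooled OLS with ethnicity indicators. The MR tier uses the
    phenotype-matched GRS column (``grs_<exposure>``) as instrument, either
    fitted per ethnic stratum and pooled by fixed-effects meta-analysis
    (``model3_mode="meta"``, default) or in one pooled 2SLS with the genetic
    PCs carrying ancestry (``model3_mode="pooled"``).
    """
    if model3_mode not in ("meta", "pooled"):
        raise ValueError(f"unknown model3_mode {model3_mode!r}")
    results: list[FitResult] = []
    for exposure in exposures:
        for outcome in outcomes:
            for tier in tiers:
                covs: tuple[str, ...] | None = None
                if tier == "model2" and model2_covariates == "footnote":
                    covs = tuple(["age", "gender", "stratum"] + MODEL2_EXTRAS_FOOTNOTE)
                spec = ModelSpec(
                    outcome=outcome, exposure=exposure, tier=tier,
                    covariates=covs, scale_per=scale_per,
                )
                if tier != "model3":
                    results.append(fit_ols(data, spec))
                    continue
                instrument = f"{grs_prefix}{exposure}"
                if model3_mode == "pooled":
                    results.append(
                        fit_2sls(data, spec, instrument,
                                 weak_f_threshold=weak_f_threshold)
                    )
                else:
                    per = fit_stratified(
                        data, spec, strata_column, fitter=fit_2sls,
                        instrument=instrument, weak_f_threshold=weak_f_threshold,
                    )
                    results.extend(per)
                    pool = meta_fixed if meta_method == "fixed" else meta_random
                    results.append(pool(per))
    return results


def results_table(results: Sequence[FitResult]) -> pd.DataFrame:
    """Flatten fit results into a tidy table (one row per fitted cell)."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome, "exposure": r.exposure, "tier": r.tier,
                "stratum": r.stratum, "method": r.method,
                "beta": r.beta, "se": r.se, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p_value": r.p_value, "n": r.n,
                "first_stage_f": r.first_stage_f, "q_stat": r.q_stat,
                "i2": r.i2, "warnings": ";".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}" if p < 0.01 else f"{p:.2f}"


_TIER_LABEL = {
    "model1": "Model 1",
    "model2": "Model 2",
    "model3": "Model 3: Mendelian randomisation",
}


def format_table2(results: Sequence[FitResult], scale_per: float = 10.0) -> str:
    """Text report: β (95% CI) and P per outcome, exposure and model tier."""
    summary = {
        (r.outcome, r.exposure, r.tier): r
        for r in results
        if r.stratum in ("pooled", "meta")
    }
    lines = [
        "Association between blood pressure and retinal vascular caliber",
        "(conventional linear regression vs. Mendelian randomisation)",
        "",
        f"{'':42s}  {'CRAE':>22s}  {'':>7s}  {'CRVE':>22s}",
        f"{'Blood pressure':42s}  {'beta (95% CI)':>22s}  {'P':>7s}  "
        f"{'beta (95% CI)':>22s}  {'P':>7s}",
    ]
    names = {"sbp": "Systolic blood pressure",
             "dbp": "Diastolic blood pressure",
             "map": "Mean arterial pressure"}
    for exposure in ("sbp", "dbp", "map"):
        lines.append(f"{names[exposure]}, per {scale_per:g} mm Hg")
        for tier in TIERS:
            cells = []
            for outcome in OUTCOMES:
                r = summary.get((outcome, exposure, tier))
                if r is None:
                    cells.extend(["--", "--"])
                else:
                    cells.extend(
                        [f"{r.beta:.1f} ({r.ci_low:.1f}, {r.ci_high:.1f})",
                         _fmt_p(r.p_value)]
                    )
            lines.append(
                f"  {_TIER_LABEL[tier]:40s}  {cells[0]:>22s}  {cells[1]:>7s}  "
                f"{cells[2]:>22s}  {cells[3]:>7s}"
            )
    return "\n".join(lines) + "\n"


def format_table3(pleio: pd.DataFrame) -> str:
    """Text report of GRS-confounder associations (pleiotropy check)."""
    grs_cols = list(dict.fromkeys(pleio["grs"]))
    lines = ["Associations between BP genetic risk scores and traditional confounders",
             ""]
    header = f"{'Confounder':28s}"
    for g in grs_cols:
        header += f"  {g + ' beta, SE':>20s}  {'P':>7s}"
    lines.append(header)
    for conf in dict.fromkeys(pleio["confounder"]):
        row = f"{conf:28s}"
        for g in grs_cols:
            r = pleio[(pleio.confounder == conf) & (pleio.grs == g)].iloc[0]
            row += f"  {r.beta:>12.3f}, {r.se:.3f}  {_fmt_p(r.p_value):>7s}"
        lines.append(row)
    return "\n".join(lines) + "\n"
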