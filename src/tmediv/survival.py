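"""Patient-level aggregation and the prognostic statistics layer.

Cores are sampled in triplicate per patient; the per-patient feature value
is the median over available cores, and intra-patient heterogeneity is
summarised by the coefficient of variation across cores. Features are then
tested as continuous covariates in Cox proportional-hazards models
(univariable, and adjusted for the FLIPI ordinal score 0–5), dichotomised
at an optimal cutpoint for Kaplan–Meier display (Greenwood variance for the
confidence band), and compared between POD24 groups by Mann–Whitney U and
logistic regression. Bonferroni controls the family-wise error over the
features tested in a run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu

from .cutpoint import DEFAULT_MIN_GROUP_FRACTION, CutpointResult, contal_oquigley_cutpoint
from .errors import FitError, ValidationError

log = logging.getLogger(__name__)

ENDPOINTS = {
    "OS": ("os_months", "os_event"),
    "PFS": ("pfs_months", "pfs_event"),
}


@dataclass(frozen=True)
class SurvivalFit:
    """One Cox model: hazard ratio per unit of the feature, 95% CI, Wald p."""

    feature: str
    endpoint: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    covariates: tuple[str, ...]


def aggregate_patient(
    features: pd.DataFrame, feature_columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Median over each patient's cores, one row per patient.

    ``features`` is the per-core table (must carry ``patient_id``). Missing
    core values are dropped per feature; a patient with zero cores cannot
    occur by construction, and an empty input raises.
    """
    if len(features) == 0:
        raise ValidationError("no cores to aggregate")
    if feature_columns is None:
        feature_columns = [
            c
            for c in features.columns
            if c not in ("core_id", "patient_id")
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    grouped = features.groupby("patient_id", sort=True)[list(feature_columns)]
    return grouped.median().reset_index()


def intra_patient_cov(
    features: pd.DataFrame, feature: str
) -> tuple[pd.Series, float]:
    """Coefficient of variation (%) across each patient's cores.

    CoV = 100 · sd / mean with the n−1 standard deviation. Patients with
    fewer than two cores or non-positive mean are skipped with a notice.
    Returns the per-patient series and the cohort median across
    contributing patients (NaN when none contribute).
    """
    out: dict[str, float] = {}
    for pid, grp in features.groupby("patient_id", sort=True):
        vals = grp[feature].dropna().to_numpy(float)
        if len(vals) < 2:
            log.info("patient %s: <2 cores for %s; CoV skipped", pid, feature)
            continue
        mean = vals.mean()
        if mean <= 0:
            log.warning("patient %s: non-positive mean for %s; CoV skipped", pid, feature)
            continue
        out[pid] = 100.0 * vals.std(ddof=1) / mean
    series = pd.Series(out, name=f"cov_{feature}", dtype=float)
    summary = float(series.median()) if len(series) else float("nan")
    return series, summary


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}; expected one of {list(ENDPOINTS)}")
    return ENDPOINTS[endpoint]


def cox_fit(
    patients: pd.DataFrame,
    endpoint: str,
    features: Sequence[str],
    adjust_for_flipi: bool = False,
) -> list[SurvivalFit]:
    """One Cox PH model per feature (continuous; Efron tie handling).

    With ``adjust_for_flipi`` the model is feature + FLIPI (ordinal 0–5);
    rows with missing FLIPI are dropped listwise and the reduced n is
    logged. Raises :class:`FitError` when there are no events or the design
    is degenerate (e.g. a constant feature).
    """
    time_col, event_col = _endpoint_columns(endpoint)
    fits: list[SurvivalFit] = []
    for feature in features:
        cols = [feature, time_col, event_col] + (["flipi"] if adjust_for_flipi else [])
        df = patients[cols].dropna().copy()
        covariates = (feature, "flipi") if adjust_for_flipi else (feature,)
        n, n_events = len(df), int(df[event_col].sum())
        if adjust_for_flipi:
            log.info(
                "%s/%s adjusted for FLIPI: n=%d (of %d) after dropping missing FLIPI",
                feature, endpoint, n, len(patients),
            )
        if n_events == 0:
            raise FitError(f"{feature}/{endpoint}: no events; Cox model undefined")
        if np.ptp(df[feature].to_numpy(float)) == 0:
            raise FitError(f"{feature}/{endpoint}: degenerate design (constant feature)")
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=time_col, event_col=event_col)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"{feature}/{endpoint}: Cox fit failed: {exc}") from exc
        with np.errstate(over="ignore"):  # HR may overflow to inf on tiny n
            hr = float(np.exp(cph.params_[feature]))
            lo = float(np.exp(cph.confidence_intervals_.loc[feature].iloc[0]))
            hi = float(np.exp(cph.confidence_intervals_.loc[feature].iloc[1]))
        fits.append(
            SurvivalFit(
                feature=feature,
                endpoint=endpoint,
                hazard_ratio=hr,
                ci_low=lo,
                ci_high=hi,
                p_value=float(cph.summary.loc[feature, "p"]),
                n=n,
                n_events=n_events,
                covariates=covariates,
            )
        )
    return fits


def fits_to_frame(fits: Iterable[SurvivalFit]) -> pd.DataFrame:
    rows = [
        {
            "feature": f.feature,
            "endpoint": f.endpoint,
            "hr": f.hazard_ratio,
            "ci_low": f.ci_low,
            "ci_high": f.ci_high,
            "p": f.p_value,
            "n": f.n,
            "n_events": f.n_events,
            "covariates": "+".join(f.covariates),
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def km_curves(
    patients: pd.DataFrame, endpoint: str, groups: pd.Series
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan–Meier estimate per group with Greenwood 95% CIs + log-rank p.

    The confidence band is the linear Greenwood interval
    S(t) ± 1.96·sqrt(Var_G[S(t)]), clipped to [0, 1], with
    Var_G[S(t)] = S(t)² Σ_{t_j≤t} d_j / (n_j (n_j − d_j)).
    """
    time_col, event_col = _endpoint_columns(endpoint)
    df = patients[[time_col, event_col]].copy()
    df["group"] = groups.to_numpy()
    df = df.dropna()
    curves: dict[str, pd.DataFrame] = {}
    for name, grp in df.groupby("group", sort=True):
        if len(grp) == 0:
            raise ValidationError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], grp[event_col])
        table = kmf.event_table
        s = kmf.survival_function_["KM_estimate"].to_numpy()
        at_risk = table["at_risk"].to_numpy(float)
        d = table["observed"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
            inc = np.where(d > 0, inc, 0.0)
        var = s**2 * np.cumsum(inc)
        se = np.sqrt(np.where(np.isfinite(var), var, 0.0))
        curves[str(name)] = pd.DataFrame(
            {
                "time": table.index.to_numpy(float),
                "survival": s,
                "ci_low": np.clip(s - 1.96 * se, 0.0, 1.0),
                "ci_high": np.clip(s + 1.96 * se, 0.0, 1.0),
                "at_risk": at_risk.astype(int),
                "events": d.astype(int),
            }
        )
    if df["group"].nunique() >= 2 and df[event_col].sum() > 0:
        lr = multivariate_logrank_test(df[time_col], df["group"], df[event_col])
        p = float(lr.p_value)
    else:
        p = float("nan")
    return curves, p


def optimal_cutpoints(
    patients: pd.DataFrame,
    endpoint: str,
    features: Sequence[str],
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> dict[str, CutpointResult]:
    """Contal–O'Quigley optimal cut per feature on the given endpoint."""
    time_col, event_col = _endpoint_columns(endpoint)
    out: dict[str, CutpointResult] = {}
    for feature in features:
        df = patients[[feature, time_col, event_col]].dropna()
        out[feature] = contal_oquigley_cutpoint(
            df[feature].to_numpy(float),
            df[time_col].to_numpy(float),
            df[event_col].to_numpy(float).astype(bool),
            min_group_fraction=min_group_fraction,
        )
    return out


def cutpoints_to_frame(results: Mapping[str, CutpointResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": name,
                "cut_value": r.cut_value,
                "q_statistic": r.q_statistic,
                "p_logrank": r.p_logrank,
                "p_adjusted": r.p_adjusted,
                "group_fraction_high": r.group_fraction_high,
                "n": r.n,
                "n_events": r.n_events,
            }
            for name, r in results.items()
        ]
    )


def pod24_tests(
    patients: pd.DataFrame,
    features: Sequence[str],
    adjust_for_flipi: bool = True,
) -> pd.DataFrame:
    """Mann–Whitney U and logistic regression per feature against POD24.

    POD24 (progression within 24 months of treatment start) must be defined
    — patients with missing ``pod24`` are dropped — and both classes must be
    present. Logistic odds ratios are per unit feature; the FLIPI-adjusted
    model drops rows with missing FLIPI.
    """
    import statsmodels.api as sm

    rows = []
    for feature in features:
        df = patients[[feature, "pod24"]].dropna()
        y = df["pod24"].astype(float).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValidationError("POD24 has a single class; tests undefined")
        x = df[feature].to_numpy(float)
        mw = mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        row = {"feature": feature, "mw_p": float(mw.pvalue), "n": len(df),
               "n_pod24": int(y.sum())}
        row.update(_logit_or(df, feature, None, prefix="or"))
        if adjust_for_flipi and "flipi" in patients.columns:
            dfa = patients[[feature, "pod24", "flipi"]].dropna()
            if dfa["pod24"].nunique() == 2:
                row.update(_logit_or(dfa, feature, "flipi", prefix="or_adj"))
        rows.append(row)
    return pd.DataFrame(rows)


def _logit_or(df: pd.DataFrame, feature: str, adjust: str | None, prefix: str) -> dict:
    import statsmodels.api as sm

    cols = [feature] + ([adjust] if adjust else [])
    X = sm.add_constant(df[cols].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(df["pod24"].astype(float), X).fit(disp=0)
        ci = fit.conf_int().loc[feature]
        return {
            prefix: float(np.exp(fit.params[feature])),
            f"{prefix}_ci_low": float(np.exp(ci.iloc[0])),
            f"{prefix}_ci_high": float(np.exp(ci.iloc[1])),
            f"{prefix}_p": float(fit.pvalues[feature]),
        }
    except Exception as exc:  # perfect separation etc. — report, don't crash
        log.warning("logistic fit failed for %s (%s): %s", feature, prefix, exc)
        return {
            prefix: float("nan"),
            f"{prefix}_ci_low": float("nan"),
            f"{prefix}_ci_high": float("nan"),
            f"{prefix}_p": float("nan"),
        }


def bonferroni_adjust(
    p_values: Sequence[float], family_alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Per-test threshold α/k and significance flags (closed ``<=`` rule)."""
    if not 0 < family_alpha < 1:
        raise ValidationError("family_alpha must be in (0, 1)")
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    threshold = family_alpha / p.size
    return float(threshold), p <= threshold
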