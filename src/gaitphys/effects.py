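"""Mixed-effects models of metric-covariate relationships.

For one metric of one series, fits a linear mixed model of the cycle-level
metric value on age, normalised walking speed, clinical condition (healthy
reference level) and the condition x age / condition x speed interactions,
with random intercepts for subject and for side nested within subject —
the grouping structure of repeated gait cycles.  The default backend is
REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM` with
Wald 95% confidence intervals; interval semantics are therefore
frequentist coverage, not posterior credibility.

For forest-plot-style reporting, coefficients are standardised by the
pooled (across-group) standard deviation of the response metric.

Age and speed are centred at 10 years and 1.0 1/s before fitting, so the
condition main effects are differences at the cohort's reference
covariates rather than extrapolations to age zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .data import Cohort, SubjectRecord

__all__ = ["EffectTerm", "EffectEstimates", "fit_metric_model",
           "standardise_effects", "pooled_sd"]

AGE_CENTRE = 10.0
SPEED_CENTRE = 1.0


@dataclass(frozen=True)
class EffectTerm:
    """One fixed-effect coefficient with its 95% interval."""

    name: str
    coef: float
    ci_low: float
    ci_high: float
    std_coef: float | None = None
    std_ci_low: float | None = None
    std_ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.coef <= self.ci_high):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] does not "
                f"contain coefficient {self.coef} for term {self.name!r}"
            )


@dataclass
class EffectEstimates:
    """Fixed-effect estimates for one (metric, series) response."""

    metric: str
    series: str
    terms: list[EffectTerm]
    n_subjects: int
    n_rows: int
    reference_group: str
    converged: bool
    warnings: list[str] = field(default_factory=list)
    pooled_sd: float | None = None

    def term(self, name_fragment: str) -> EffectTerm:
        """First term whose name contains ``name_fragment``."""
        for t in self.terms:
            if name_fragment in t.name:
                return t
        raise KeyError(name_fragment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.terms])


def _subject_map(subjects) -> Mapping[str, SubjectRecord]:
    if isinstance(subjects, Cohort):
        return subjects.subjects
    return subjects


def fit_metric_model(
    features: pd.DataFrame,
    subjects,
    metric: str,
    series: str,
    reference_group: str,
) -> EffectEstimates:
    """Fit the mixed model for one metric of one series.

    ``features`` is the long per-cycle table from
    :func:`~gaitphys.metrics.compute_features`; ``subjects`` a cohort or a
    subject-id -> :class:`~gaitphys.data.SubjectRecord` mapping supplying
    age and normalised walking speed.
    """
    smap = _subject_map(subjects)
    df = features[features["series"] == series].copy()
    if df.empty:
        raise ValueError(f"no rows for series {series!r}")
    if metric not in df.columns:
        raise ValueError(f"unknown metric {metric!r}")
    groups_present = sorted(df["group"].unique())
    if len(groups_present) < 2:
        raise ValueError("need at least two groups to model condition effects")
    if reference_group not in groups_present:
        raise ValueError(
            f"reference group {reference_group!r} absent from {groups_present}"
        )
    n_all = len(df)
    df = df.dropna(subset=[metric])
    if len(df) < 0.8 * n_all:
        raise ValueError(
            f"{metric} defined for only {len(df)}/{n_all} rows (< 80%)"
        )
    df["age_c"] = df["subject_id"].map(lambda s: smap[s].age) - AGE_CENTRE
    df["speed_c"] = (
        df["subject_id"].map(lambda s: smap[s].normalised_walking_speed)
        - SPEED_CENTRE
    )
    df["response"] = df[metric]

    formula = (
        "response ~ age_c + speed_c "
        f"+ C(group, Treatment(reference='{reference_group}')) "
        f"+ C(group, Treatment(reference='{reference_group}')):age_c "
        f"+ C(group, Treatment(reference='{reference_group}')):speed_c"
    )
    caught: list[str] = []
    result = None
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            formula,
            data=df,
            groups=df["subject_id"],
            re_formula="1",
            vc_formula={"side": "0 + C(side)"},
        )
        # variance components at the boundary routinely defeat a single
        # optimizer; try a sequence before declaring failure
        last_exc = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                candidate = model.fit(reml=True, method=method)
            except Exception as exc:  # singular matrices etc.
                last_exc = exc
                continue
            result = candidate
            if getattr(candidate, "converged", False):
                break
        caught = [str(w.message) for w in wlist]
    if result is None:
        raise RuntimeError(
            f"mixed model failed for metric={metric}, series={series}: {last_exc}"
        ) from last_exc
    if not getattr(result, "converged", True):
        raise RuntimeError(
            f"mixed model did not converge for metric={metric}, "
            f"series={series}; diagnostics: {caught}"
        )
    # near-zero variance components are legitimate boundary solutions;
    # surface them as warnings rather than failures
    try:
        vcomp = np.asarray(result.vcomp, dtype=float)
        if np.any(vcomp < 1e-10):
            caught.append("singular fit: side-within-subject variance ~ 0")
    except Exception:
        pass

    fe = result.fe_params
    ci = result.conf_int(alpha=0.05).loc[fe.index]
    terms = []
    for name in fe.index:
        pretty = (
            name.replace(
                f"C(group, Treatment(reference='{reference_group}'))", "condition"
            )
            .replace("[T.", "[")
        )
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        terms.append(EffectTerm(name=pretty, coef=float(fe[name]),
                                ci_low=lo, ci_high=hi))
    return EffectEstimates(
        metric=metric,
        series=series,
        terms=terms,
        n_subjects=df["subject_id"].nunique(),
        n_rows=len(df),
        reference_group=reference_group,
        converged=bool(getattr(result, "converged", True)),
        warnings=caught,
    )


def pooled_sd(values: np.ndarray, groups: np.ndarray) -> float:
    """Classic pooled standard deviation across groups.

    ``sqrt(sum_g (n_g - 1) s_g^2 / (N - G))`` with sample variances.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    num, den = 0.0, 0
    for g in labels:
        v = values[groups == g]
        v = v[np.isfinite(v)]
        if v.size < 2:
            continue
        num += (v.size - 1) * v.var(ddof=1)
        den += v.size - 1
    if den == 0 or num == 0:
        raise ValueError("pooled standard deviation is zero or undefined")
    return float(np.sqrt(num / den))


def standardise_effects(
    estimates: EffectEstimates, features: pd.DataFrame
) -> EffectEstimates:
    """Divide coefficients and intervals by the response's pooled sd.

    Raw values are retained alongside the standardised ones, so the same
    object serves numeric reporting and forest-plot display.
    """
    df = features[features["series"] == estimates.series]
    sd = pooled_sd(df[estimates.metric].to_numpy(), df["group"].to_numpy())
    new_terms = [
        replace(
            t,
            std_coef=t.coef / sd,
            std_ci_low=t.ci_low / sd,
            std_ci_high=t.ci_high / sd,
        )
        for t in estimates.terms
    ]
    out = replace_estimates(estimates, new_terms, sd)
    return out


def replace_estimates(est: EffectEstimates, terms, sd) -> EffectEstimates:
    return EffectEstimates(
        metric=est.metric,
        series=est.series,
        terms=terms,
        n_subjects=est.n_subjects,
        n_rows=est.n_rows,
        reference_group=est.reference_group,
        converged=est.converged,
        warnings=list(est.warnings),
        pooled_sd=sd,
    )
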