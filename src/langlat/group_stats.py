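"""Group-level inference: condition effects, hemisphere effects, and
age-group comparisons of lateralization, magnitude, and connectivity.

Mixed-effects models (REML) use crossed random intercepts for participants and
fROIs, realized as variance components in statsmodels' MixedLM. Singular or
non-converging fits degrade gracefully (fROI terms dropped first, then
hemisphere slopes, finally plain OLS), with the structure actually used
recorded on the result. Pairwise child-vs-adult comparisons are adjusted with
Sidak's method, p_adj = 1 - (1 - p)^m.

Wald tests use a configurable degrees-of-freedom rule in place of the
Satterthwaite approximation: ``residual`` (n - p, apt for within-subject
contrasts), ``groups`` (n_subjects - p, apt for between-subject terms), or
``z`` (large-sample normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

ADULT = "adult"
CHILD_GROUPS = ("early", "middle", "late")
FRONTAL_STEMS = ("IFG", "IFGorb", "MFG")
TEMPORAL_STEMS = ("AntTemp", "PostTemp")


@dataclass
class FixedEffect:
    term: str
    b: float
    se: float
    stat: float
    p: float
    df: float
    structure: str = "full"

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "b": self.b,
            "se": self.se,
            "stat": self.stat,
            "p": self.p,
            "df": self.df,
            "structure": self.structure,
        }


@dataclass
class ComparisonResult:
    label: str
    b: float
    se: float
    stat: float
    p: float
    p_adjusted: float
    adjustment: str = "sidak"

    def as_dict(self) -> dict:
        return {
            "contrast": self.label,
            "b": self.b,
            "se": self.se,
            "stat": self.stat,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "adjustment": self.adjustment,
        }


@dataclass
class ModelSpec:
    """Serializable description of a group-level model."""

    response: str
    fixed_effects: list[str]
    random_effects: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)

    def formula(self) -> str:
        terms = self.fixed_effects + self.covariates
        return f"{self.response} ~ " + (" + ".join(terms) if terms else "1")


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m, clipped."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    return np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0)


def add_motion_covariate(model_spec: ModelSpec, outlier_counts) -> ModelSpec:
    """Append the per-subject total outlier-volume count as a fixed covariate.

    A zero-variance covariate is dropped with a warning; the covariate is
    never added twice.
    """
    counts = np.asarray(list(outlier_counts.values()) if isinstance(outlier_counts, dict) else outlier_counts, dtype=float)
    if np.ptp(counts) == 0:
        warnings.warn("motion covariate has zero variance; dropped", UserWarning, stacklevel=2)
        return replace(model_spec, covariates=list(model_spec.covariates))
    cov = list(model_spec.covariates)
    if "motion_outliers" not in cov:
        cov.append("motion_outliers")
    return replace(model_spec, covariates=cov)


def _wald(res, term: str, df_value: float, structure: str) -> FixedEffect:
    b = float(res.params[term])
    se = float(res.bse[term])
    stat = b / se if se > 0 else np.nan
    if np.isinf(df_value):
        p = 2.0 * sps.norm.sf(abs(stat))
    else:
        p = 2.0 * sps.t.sf(abs(stat), df_value)
    return FixedEffect(term=term, b=b, se=se, stat=stat, p=float(p), df=float(df_value), structure=structure)


def _df_for(rule: str, data: pd.DataFrame, n_fixed: int) -> float:
    if rule == "z":
        return np.inf
    if rule == "groups":
        return max(1, data["subject"].nunique() - n_fixed)
    return max(1, len(data) - n_fixed)  # residual


def _mixed_fit(data: pd.DataFrame, formula: str, ladder: list[tuple[str, dict | None]]):
    """Fit a mixed model, degrading the random structure down ``ladder`` until
    convergence. Each ladder entry is (label, vc_formula | None); None means
    plain OLS. Returns (result, structure_label)."""
    last_err = None
    for label, vc in ladder:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if vc is None:
                    res = smf.ols(formula, data=data).fit()
                    return res, label
                groups = pd.Series(np.ones(len(data)), index=data.index)
                model = smf.mixedlm(formula, data=data, groups=groups, vc_formula=vc, re_formula="0")
                res = model.fit(reml=True, method=["lbfgs", "cg"])
            if res.converged and np.all(np.isfinite(res.bse.to_numpy(dtype=float))):
                return res, label
        except (np.linalg.LinAlgError, ValueError) as err:  # singular fits
            last_err = err
    raise RuntimeError(f"no model structure converged: {last_err}")


def _subset_frois(measures: pd.DataFrame, subset: str | None) -> pd.DataFrame:
    if subset is None:
        return measures
    stems = FRONTAL_STEMS if subset == "frontal" else TEMPORAL_STEMS
    keep = measures["froi"].map(lambda n: any(n.endswith(s) for s in stems))
    return measures[keep]


def fit_condition_model(
    measures: pd.DataFrame,
    subset: str | None = None,
    df_rule: str = "residual",
) -> FixedEffect:
    """Language>Control fixed effect on response magnitude.

    Linear mixed model (REML) of PSC on condition with crossed random
    intercepts for participants and fROIs; ``subset`` restricts to the
    frontal or temporal network component.
    """
    data = _subset_frois(measures, subset).copy()
    if set(data["condition"].unique()) != {"Language", "Control"}:
        raise ValueError("both conditions (Language, Control) are required")
    if data["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    formula = "psc ~ C(condition, Treatment('Control'))"
    term = "C(condition, Treatment('Control'))[T.Language]"
    ladder = [
        ("subject+froi", {"subject": "0 + C(subject)", "froi": "0 + C(froi)"}),
        ("subject", {"subject": "0 + C(subject)"}),
        ("ols", None),
    ]
    res, structure = _mixed_fit(data, formula, ladder)
    eff = _wald(res, term, _df_for(df_rule, data, 2), structure)
    eff.term = "Language>Control"
    return eff


def fit_hemisphere_models(
    magnitude: pd.DataFrame,
    volume: pd.DataFrame,
    df_rule: str = "groups",
) -> dict[str, FixedEffect]:
    """LH>RH fixed effects for response magnitude and activation volume.

    ``magnitude``: one row per subject x hemisphere with the fROI-averaged
    Language>Control contrast in ``value``. ``volume``: same shape with summed
    suprathreshold voxel counts. Each is modelled on hemisphere with a random
    participant intercept.
    """
    out = {}
    for name, df in (("magnitude", magnitude), ("volume", volume)):
        if set(df["hemisphere"].unique()) != {"LH", "RH"}:
            raise ValueError("both hemispheres required per subject")
        formula = "value ~ C(hemisphere, Treatment('RH'))"
        term = "C(hemisphere, Treatment('RH'))[T.LH]"
        ladder = [("subject", {"subject": "0 + C(subject)"}), ("ols", None)]
        res, structure = _mixed_fit(df, formula, ladder)
        eff = _wald(res, term, _df_for(df_rule, df, 2), structure)
        eff.term = f"{name}: LH>RH"
        out[name] = eff
    return out


def _group_contrasts(res, term_template: str, df_value: float, groups: tuple[str, ...]) -> list[ComparisonResult]:
    raw = []
    for g in groups:
        term = term_template.format(g)
        b = float(res.params[term])
        se = float(res.bse[term])
        stat = b / se if se > 0 else np.nan
        if np.isinf(df_value):
            p = 2.0 * sps.norm.sf(abs(stat))
        else:
            p = 2.0 * sps.t.sf(abs(stat), df_value)
        raw.append((g, b, se, stat, float(p)))
    p_adj = sidak_adjust([r[4] for r in raw], m=len(raw))
    return [
        ComparisonResult(label=f"{g.capitalize()} vs Adult", b=b, se=se, stat=stat, p=p, p_adjusted=float(pa))
        for (g, b, se, stat, p), pa in zip(raw, p_adj)
    ]


def compare_li_across_groups(laterality: pd.DataFrame, value_col: str = "li") -> list[ComparisonResult]:
    """Child-vs-adult comparisons of the laterality index.

    Linear regression of LI on age group (categorical, adult reference)
    followed by Sidak-adjusted pairwise child-vs-adult contrasts.
    """
    data = laterality.dropna(subset=[value_col]).copy()
    groups = set(data["group"].unique())
    if ADULT not in groups:
        raise ValueError("adult group required as the reference")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    children = tuple(g for g in CHILD_GROUPS if g in groups)
    res = smf.ols(f"{value_col} ~ C(group, Treatment('{ADULT}'))", data=data).fit()
    dfres = float(res.df_resid)
    return _group_contrasts(res, f"C(group, Treatment('{ADULT}'))[T.{{}}]", dfres, children)


def fit_interaction_model(
    magnitude_long: pd.DataFrame,
    df_rule: str = "groups",
) -> tuple[list[ComparisonResult], str]:
    """Age-group x hemisphere interaction on the Language>Control contrast.

    Mixed model with random intercepts and hemisphere slopes for participants
    and fROIs; returns Sidak-adjusted child-vs-adult interaction contrasts
    (does the LH advantage differ from adults?) and the random structure used.
    """
    data = magnitude_long.copy()
    if set(data["hemisphere"].unique()) != {"LH", "RH"}:
        raise ValueError("both hemispheres required")
    groups = set(data["group"].unique())
    if ADULT not in groups or len(groups) < 2:
        raise ValueError("adult group plus at least one child group required")
    data["hemi_lh"] = (data["hemisphere"] == "LH").astype(float)
    formula = f"value ~ C(group, Treatment('{ADULT}')) * C(hemisphere, Treatment('RH'))"
    ladder = [
        (
            "subject+slope+froi+slope",
            {
                "subject": "0 + C(subject)",
                "subject_hemi": "0 + C(subject):hemi_lh",
                "froi": "0 + C(froi)",
                "froi_hemi": "0 + C(froi):hemi_lh",
            },
        ),
        (
            "subject+slope+froi",
            {"subject": "0 + C(subject)", "subject_hemi": "0 + C(subject):hemi_lh", "froi": "0 + C(froi)"},
        ),
        ("subject+slope", {"subject": "0 + C(subject)", "subject_hemi": "0 + C(subject):hemi_lh"}),
        ("subject", {"subject": "0 + C(subject)"}),
        ("ols", None),
    ]
    res, structure = _mixed_fit(data, formula, ladder)
    children = tuple(g for g in CHILD_GROUPS if g in groups)
    template = (
        f"C(group, Treatment('{ADULT}'))[T.{{}}]:C(hemisphere, Treatment('RH'))[T.LH]"
    )
    dfv = _df_for(df_rule, data, len(res.params))
    results = _group_contrasts(res, template, dfv, children)
    for r in results:
        r.label += " x LH"
    return results, structure


def fit_continuous_age_model(
    records: pd.DataFrame,
    response: str = "psc",
    df_rule: str = "groups",
) -> FixedEffect:
    """Slope of a measure on age (years), children only.

    Mixed model with random intercepts for participants and (when present)
    fROIs; adult rows or constant age are contract violations.
    """
    data = records.copy()
    if "group" in data.columns and (data["group"] == ADULT).any():
        raise ValueError("continuous-age model is children-only; remove adult rows")
    if data["age"].nunique() < 2:
        raise ValueError("age is constant; slope undefined")
    formula = f"{response} ~ age"
    if "froi" in data.columns and data["froi"].nunique() > 1 and data["subject"].nunique() > 1:
        ladder = [
            ("subject+froi", {"subject": "0 + C(subject)", "froi": "0 + C(froi)"}),
            ("subject", {"subject": "0 + C(subject)"}),
            ("ols", None),
        ]
    elif data["subject"].duplicated().any():
        ladder = [("subject", {"subject": "0 + C(subject)"}), ("ols", None)]
    else:
        ladder = [("ols", None)]
    res, structure = _mixed_fit(data, formula, ladder)
    eff = _wald(res, "age", _df_for(df_rule, data, 2), structure)
    eff.term = f"{response} ~ age (children)"
    return eff


def compare_connectivity_across_groups(
    connectivity: pd.DataFrame, value_col: str = "lh_mean_z"
) -> list[ComparisonResult]:
    """Child-vs-adult comparisons of mean LH-network connectivity.

    Linear regression of each subject's mean Fisher z over the 10 LH fROI
    pairs on age group, with Sidak-adjusted pairwise contrasts.
    """
    return compare_li_across_groups(connectivity, value_col=value_col)


def fit_magnitude_group_model(
    measures: pd.DataFrame, df_rule: str = "groups"
) -> tuple[list[ComparisonResult], str]:
    """Child-vs-adult comparisons of LH-network response magnitude.

    Mixed model of the Language>Control contrast on age group with random
    intercepts for participants and fROIs, followed by Sidak-adjusted
    pairwise contrasts.
    """
    data = measures.copy()
    groups = set(data["group"].unique())
    if ADULT not in groups or len(groups) < 2:
        raise ValueError("adult group plus at least one child group required")
    formula = f"value ~ C(group, Treatment('{ADULT}'))"
    ladder = [
        ("subject+froi", {"subject": "0 + C(subject)", "froi": "0 + C(froi)"}),
        ("subject", {"subject": "0 + C(subject)"}),
        ("ols", None),
    ]
    res, structure = _mixed_fit(data, formula, ladder)
    children = tuple(g for g in CHILD_GROUPS if g in groups)
    dfv = _df_for(df_rule, data, len(res.params))
    return _group_contrasts(res, f"C(group, Treatment('{ADULT}'))[T.{{}}]", dfv, children), structure
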