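"""Group statistics on the acoustic score tables.

Proportion scores (differentiability, hit rate) are arcsine-square-root
transformed before inference to stabilize their variance.  The battery:
a two-way ANOVA for hearing group (NH vs CI) x analysis method (2D vs 3D),
a one-way repeated-measures ANOVA over tone contrasts or tone types with
Bonferroni-corrected paired post hoc tests, Pearson correlations between
measures/methods/demographics, and an OLS model of the transformed scores on
age at implantation, duration of device use and their interaction
(chronological age, being their sum, is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DemographicRecord",
    "AnovaResult",
    "GlmResult",
    "arcsine_transform",
    "two_way_anova",
    "rm_anova_oneway",
    "pearson",
    "glm_fit",
]

DEMOGRAPHIC_TOLERANCE_YEARS = 0.1


@dataclass(frozen=True)
class DemographicRecord:
    subject_id: str
    group: str
    chronological_age: float
    age_at_implantation: float | None = None
    duration_of_use: float | None = None

    def __post_init__(self) -> None:
        if self.group == "CI":
            if self.age_at_implantation is None or self.duration_of_use is None:
                raise ValueError(
                    f"CI subject {self.subject_id} requires both age fields"
                )
            gap = abs(
                self.chronological_age
                - (self.age_at_implantation + self.duration_of_use)
            )
            if gap > DEMOGRAPHIC_TOLERANCE_YEARS:
                raise ValueError(
                    f"subject {self.subject_id}: chronological age differs "
                    f"from implantation + duration by {gap:.2f} y"
                )


@dataclass
class AnovaResult:
    effects: list[str]
    F: dict[str, float]
    df: dict[str, tuple[float, float]]
    p: dict[str, float]
    p_gg: dict[str, float] = field(default_factory=dict)  # sphericity-corrected
    posthoc: pd.DataFrame | None = None
    table: pd.DataFrame | None = None


@dataclass
class GlmResult:
    coefficients: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float


def arcsine_transform(p) -> np.ndarray | float:
    """Variance-stabilizing arcsin(sqrt(p)) for proportions in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < -1e-9) | (arr > 1 + 1e-9)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def two_way_anova(
    scores: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "method",
    ss_type: int = 2,
    transform: bool = True,
) -> AnovaResult:
    """Factorial ANOVA with both main effects and their interaction.

    Scores are arcsine transformed by default.  Type II sums of squares suit
    the mildly unbalanced NH/CI group sizes; Types I and III are selectable.
    """
    df = scores[[value, factor_a, factor_b]].dropna().copy()
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    n_cells = df[factor_a].nunique() * df[factor_b].nunique()
    if len(counts) < n_cells or (counts < 2).any():
        raise ValueError(
            "unbalanced design: every factor-level cell needs >= 2 observations"
        )
    df["y"] = arcsine_transform(df[value].to_numpy()) if transform else df[value]
    model = smf.ols(f"y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)

    rename = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    dfe = float(tab.loc["Residual", "df"])
    effects, F, dof, p = [], {}, {}, {}
    for row, name in rename.items():
        effects.append(name)
        F[name] = float(tab.loc[row, "F"])
        dof[name] = (float(tab.loc[row, "df"]), dfe)
        p[name] = float(tab.loc[row, "PR(>F)"])
    return AnovaResult(effects=effects, F=F, df=dof, p=p, table=tab)


def rm_anova_oneway(
    scores: pd.DataFrame,
    value: str = "value",
    subject: str = "subject_id",
    within: str = "condition",
    transform: bool = True,
    posthoc_correction: str = "bonf",
) -> AnovaResult:
    """One-way repeated-measures ANOVA over a within-subject condition.

    Subjects missing any condition are dropped listwise.  Reports the
    uncorrected p alongside the Greenhouse-Geisser corrected one, plus
    Bonferroni-corrected paired t tests between all condition pairs.
    """
    df = scores[[subject, within, value]].dropna().copy()
    conditions = sorted(df[within].unique())
    if len(conditions) < 2:
        raise ValueError("need >= 2 within-subject conditions")
    complete = df.groupby(subject)[within].nunique() == len(conditions)
    df = df[df[subject].isin(complete[complete].index)]
    if df[subject].nunique() < 2:
        raise ValueError("need >= 2 complete subjects")
    if transform:
        df[value] = arcsine_transform(df[value].to_numpy())

    # degenerate guard: with no condition effect at all (all condition means
    # equal to rounding), the F ratio is 0/0; report F = 0, p = 1 directly
    cond_means = df.groupby(within)[value].mean()
    scale = max(float(df[value].abs().max()), 1.0)
    if float(cond_means.max() - cond_means.min()) < 1e-12 * scale:
        n_subj = df[subject].nunique()
        ddof1 = float(len(conditions) - 1)
        ddof2 = float(ddof1 * (n_subj - 1))
        return AnovaResult(
            effects=[within], F={within: 0.0},
            df={within: (ddof1, ddof2)}, p={within: 1.0},
            p_gg={within: 1.0},
        )

    aov = pg.rm_anova(
        data=df, dv=value, within=within, subject=subject, correction=True
    )
    row = aov.iloc[0]
    name = str(row["Source"])
    # column naming varies across pingouin versions
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    gg_col = "p_GG_corr" if "p_GG_corr" in aov.columns else "p-GG-corr"
    p_unc = float(row[p_col])
    p_gg = (
        float(row[gg_col])
        if gg_col in aov.columns and np.isfinite(row.get(gg_col, np.nan))
        else p_unc
    )

    post = pg.pairwise_tests(
        data=df, dv=value, within=within, subject=subject,
        padjust=posthoc_correction,
    )
    return AnovaResult(
        effects=[name],
        F={name: float(row["F"])},
        df={name: (float(row["ddof1"]), float(row["ddof2"]))},
        p={name: p_unc},
        p_gg={name: p_gg},
        posthoc=post,
        table=aov,
    )


def pearson(
    x, y, n_family: int = 1
) -> tuple[float, float, float]:
    """Pearson r with two-sided p; optional Bonferroni-adjusted p.

    Pairs with a missing member are deleted.  Returns ``(r, p_raw,
    p_bonferroni)`` where the adjusted p multiplies by the family size
    (capped at 1).  Zero variance in either input yields NaN r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), float(min(1.0, p * n_family))


def glm_fit(
    response: np.ndarray,
    demographics: list[DemographicRecord],
) -> GlmResult:
    """OLS of transformed scores on implantation age, use duration, and A x D.

    CI subjects only; chronological age is excluded as the exact sum of the
    two predictors.  Reports per-term beta, t and p plus overall R^2.
    """
    recs = [d for d in demographics if d.group == "CI"]
    y = np.asarray(response, dtype=float)
    if len(recs) != y.size:
        raise ValueError("response length must match number of CI records")
    df = pd.DataFrame(
        {
            "y": y,
            "age_at_implantation": [d.age_at_implantation for d in recs],
            "duration_of_use": [d.duration_of_use for d in recs],
        }
    ).dropna()
    model = smf.ols(
        "y ~ age_at_implantation * duration_of_use", data=df
    ).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank deficient")
    names = {
        "age_at_implantation": "age_at_implantation",
        "duration_of_use": "duration_of_use",
        "age_at_implantation:duration_of_use": "interaction",
        "Intercept": "intercept",
    }
    coeffs = {names[k]: float(v) for k, v in model.params.items()}
    tvals = {names[k]: float(v) for k, v in model.tvalues.items()}
    pvals = {names[k]: float(v) for k, v in model.pvalues.items()}
    return GlmResult(
        coefficients=coeffs, t=tvals, p=pvals,
        r_squared=float(model.rsquared),
    )
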