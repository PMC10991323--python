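"""Group-level statistics on the on-trail walking distance y.

The battery applied to each assay dataset: y is transformed to
Y = ln(y + 1) to meet parametric assumptions, a one-way ANOVA tests for
any dependence of Y on the trail preparation, Dunnett's many-to-one
procedure compares every preparation x concentration group against the
control with family-wise error control, and unpaired t-tests compare
compounds at matched concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .synthetic import GroupData

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 / 0.0001 levels."""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def log_transform(y) -> np.ndarray | float:
    """Y = ln(y + 1); strictly increasing, 0 at y = 0."""
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("walking distances must be non-negative")
    out = np.log1p(y_arr)
    return float(out) if np.isscalar(y) or out.ndim == 0 else out


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    mean_diff: float  # transformed scale, group minus control
    statistic: float
    p_adjusted: float
    stars: str


@dataclass(frozen=True)
class DunnettResult:
    comparisons: tuple[DunnettComparison, ...]
    control_label: str
    df_error: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": c.label,
                    "mean_diff_ln": c.mean_diff,
                    "t": c.statistic,
                    "p_adjusted": c.p_adjusted,
                    "stars": c.stars,
                }
                for c in self.comparisons
            ]
        )


def _transformed_groups(g: GroupData) -> dict[str, np.ndarray]:
    return {label: log_transform(g.values(label)) for label in g.labels}


def one_way_anova(g: GroupData) -> AnovaResult:
    """One-way ANOVA on Y = ln(y + 1) across all groups.

    With k groups of n ants each, df1 = k - 1 and df2 = k(n - 1): the
    13-group, n = 15 design gives (12, 182) and the 18-group design
    (17, 252).
    """
    groups = list(_transformed_groups(g).values())
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(v) < 2 for v in groups):
        raise ValueError("every group needs at least two observations")
    if all(np.ptp(v) == 0 for v in groups):
        raise ValueError("zero within-group variance everywhere: F undefined")
    res = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(v) for v in groups) - len(groups)
    return AnovaResult(F=float(res.statistic), df1=df1, df2=df2, p=float(res.pvalue))


def dunnett_vs_control(g: GroupData, alpha: float = 0.05, seed: int = 0) -> DunnettResult:
    """Two-sided Dunnett comparisons of every group against the control.

    Uses the multivariate-t distribution with the pooled within-group
    variance from all groups (error df = N - k, matching the ANOVA).
    The multivariate-t probabilities are evaluated by seeded
    quasi-Monte-Carlo integration, so results are reproducible.
    """
    transformed = _transformed_groups(g)
    if g.control_label not in transformed:
        raise ValueError(f"control group {g.control_label!r} missing")
    control = transformed.pop(g.control_label)
    labels = list(transformed)
    if not labels:
        raise ValueError("no treatment groups to compare")
    samples = [transformed[label] for label in labels]
    res = sps.dunnett(
        *samples, control=control, alternative="two-sided", rng=np.random.default_rng(seed)
    )
    df_error = sum(len(v) for v in samples) + len(control) - (len(samples) + 1)
    comparisons = tuple(
        DunnettComparison(
            label=label,
            mean_diff=float(samples[i].mean() - control.mean()),
            statistic=float(res.statistic[i]),
            p_adjusted=float(res.pvalue[i]),
            stars=star_code(float(res.pvalue[i])),
        )
        for i, label in enumerate(labels)
    )
    return DunnettResult(
        comparisons=comparisons, control_label=g.control_label, df_error=df_error, alpha=alpha
    )


def dunnett_critical_value(
    n_treatments: int,
    df_error: int,
    alpha: float = 0.05,
    seed: int = 7,
    maxpts: int = 200_000,
) -> float:
    """Two-sided equicoordinate critical value for balanced Dunnett
    comparisons (equicorrelation 1/2).

    ``max_i |t_i|`` exceeds this value exactly when the smallest
    Dunnett-adjusted p-value falls below ``alpha``; computing it once
    makes large Monte-Carlo family-wise-error studies cheap.
    """
    corr = np.full((n_treatments, n_treatments), 0.5)
    np.fill_diagonal(corr, 1.0)

    def coverage(c: float) -> float:
        return float(
            sps.multivariate_t.cdf(
                np.full(n_treatments, c),
                loc=np.zeros(n_treatments),
                shape=corr,
                df=df_error,
                lower_limit=np.full(n_treatments, -c),
                random_state=np.random.default_rng(seed),
                maxpts=maxpts,
            )
        )

    return float(brentq(lambda c: coverage(c) - (1.0 - alpha), 1.0, 8.0, xtol=1e-4))


def dunnett_statistics(g: GroupData) -> tuple[list[str], np.ndarray, int]:
    """Per-comparison t statistics (group vs control, pooled variance).

    Returns (labels, t, df_error); ``|t| > dunnett_critical_value``
    reproduces the Dunnett rejection decision without the multivariate-t
    integration per dataset.
    """
    transformed = _transformed_groups(g)
    control = transformed.pop(g.control_label)
    labels = list(transformed)
    samples = [transformed[label] for label in labels]
    all_groups = samples + [control]
    df_error = sum(len(v) for v in all_groups) - len(all_groups)
    pooled = sum(((v - v.mean()) ** 2).sum() for v in all_groups) / df_error
    t = np.array(
        [
            (v.mean() - control.mean()) / np.sqrt(pooled * (1 / len(v) + 1 / len(control)))
            for v in samples
        ]
    )
    return labels, t, df_error


def pairwise_t(
    g: GroupData, label_a: str, label_b: str, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided unpaired t-test between two groups on the ln(y + 1)
    scale (pooled-variance by default; ``equal_var=False`` for Welch)."""
    a = log_transform(g.values(label_a))
    b = log_transform(g.values(label_b))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def pairwise_t_table(
    g: GroupData, preparations: tuple[str, str], equal_var: bool = True
) -> pd.DataFrame:
    """Unpaired t-tests between two compounds at every shared
    concentration."""
    prep_a, prep_b = preparations
    df = g.data
    concs_a = set(df.loc[df["preparation"] == prep_a, "concentration"])
    concs_b = set(df.loc[df["preparation"] == prep_b, "concentration"])
    rows = []
    for conc in sorted(concs_a & concs_b):
        t, p = pairwise_t(g, f"{prep_a}@{conc}", f"{prep_b}@{conc}", equal_var=equal_var)
        rows.append(
            {"concentration": conc, "group_a": prep_a, "group_b": prep_b,
             "t": t, "p": p, "stars": star_code(p)}
        )
    return pd.DataFrame(rows)
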