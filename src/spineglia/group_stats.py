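"""Group-comparison statistics for morphometry tables.

Descriptives are mean ± SEM.  Two groups are compared with an unpaired
pooled-variance Student's t test; three or more with one-way ANOVA followed
by Tukey's HSD (Tukey–Kramer for unequal n); factorial designs with a
fixed-effects two-way ANOVA (type-II sums of squares) with Tukey or
Holm–Šidák pairwise correction.  Normality is checked with the
Kolmogorov–Smirnov test against a Normal fitted from the data (Lilliefors).
Significance is declared at alpha = 0.05 and starred at 0.05/0.01/0.001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one group comparison, including post hoc pairs."""

    test_name: str
    groups: list[str]
    statistic: float
    p_value: float
    post_hoc: list[dict] = field(default_factory=list)  # {pair, statistic, p_adj, significant}
    alpha: float = ALPHA
    terms: dict = field(default_factory=dict)  # extra effects (two-way ANOVA)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def significance_stars(p: float) -> str:
    """Figure-legend stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and standard error (sd with n-1 denominator over sqrt n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("mean_sem needs at least 2 values")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))


def t_test_unpaired(group_a, group_b, labels: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sided unpaired Student's t test with pooled variance.

    If both groups are degenerate (zero variance) with equal means the
    comparison is vacuous and reported as t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult("unpaired t test", list(labels), float(t), float(p))


def _tukey_pairs(groups: dict[str, np.ndarray]) -> list[dict]:
    """All-pairs Tukey HSD adjusted p values (Tukey–Kramer for unequal n).

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)), referred to the
    studentized range distribution with k groups and N - k error df.
    """
    names = list(groups)
    k = len(names)
    n = {g: groups[g].size for g in names}
    means = {g: groups[g].mean() for g in names}
    df_err = sum(n.values()) - k
    sse = sum(float(((groups[g] - means[g]) ** 2).sum()) for g in names)
    mse = sse / df_err
    pairs = []
    for g1, g2 in itertools.combinations(names, 2):
        denom = np.sqrt(mse / 2.0 * (1.0 / n[g1] + 1.0 / n[g2]))
        if denom == 0:
            q, p = 0.0, 1.0
        else:
            q = abs(means[g1] - means[g2]) / denom
            p = float(stats.studentized_range.sf(q, k, df_err))
        pairs.append(
            {"pair": (g1, g2), "statistic": float(q), "p_adj": min(p, 1.0),
             "significant": p < ALPHA, "stars": significance_stars(p)}
        )
    return pairs


def _group_arrays(table: pd.DataFrame, metric: str, by: str | list[str]) -> dict[str, np.ndarray]:
    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    if sub["value"].isna().any():
        raise ValueError(f"missing values in metric {metric!r}")
    groups: dict[str, np.ndarray] = {}
    for key, chunk in sub.groupby(by, sort=True):
        name = key if isinstance(key, str) else ":".join(map(str, key))
        groups[name] = chunk["value"].to_numpy(dtype=float)
    return groups


def anova_oneway_tukey(
    table: pd.DataFrame, metric: str, by: str | list[str] = "group"
) -> ComparisonResult:
    """One-way ANOVA across >=3 groups with Tukey HSD post hoc."""
    groups = _group_arrays(table, metric, by)
    if len(groups) < 3:
        raise ValueError("one-way ANOVA needs >= 3 groups; use t_test_unpaired for 2")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    arrays = list(groups.values())
    if all(v.std(ddof=1) == 0 for v in arrays) and len({v.mean() for v in arrays}) == 1:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
    return ComparisonResult(
        "one-way ANOVA + Tukey HSD", list(groups), float(f), float(p),
        post_hoc=_tukey_pairs(groups),
    )


def anova_twoway(
    table: pd.DataFrame,
    metric: str,
    factors: tuple[str, str] = ("genotype", "treatment"),
    post_hoc: str = "tukey",
) -> ComparisonResult:
    """Fixed-effects two-way ANOVA (type-II SS) with optional post hoc.

    ``post_hoc`` is "tukey" (HSD over the factor-cell means) or
    "holm-sidak" (pairwise pooled t tests, Holm–Šidák adjusted).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multitest import multipletests

    fa, fb = factors
    sub = table[table["metric"] == metric] if "metric" in table.columns else table
    cells = sub.groupby([fa, fb])["value"].count()
    levels_a = sub[fa].unique()
    levels_b = sub[fb].unique()
    if len(cells) < len(levels_a) * len(levels_b) or (cells < 1).any():
        raise ValueError("two-way ANOVA requires every factorial cell to be populated")
    data = sub.rename(columns={fa: "A", fb: "B"})
    model = smf.ols("value ~ C(A) * C(B)", data=data).fit()
    if model.ssr < 1e-12 and np.allclose(sub["value"], sub["value"].iloc[0]):
        terms = {t: {"F": 0.0, "p": 1.0, "ss": 0.0} for t in (fa, fb, f"{fa}:{fb}")}
        stat, p = 0.0, 1.0
    else:
        tab = sm.stats.anova_lm(model, typ=2)
        def _term(row):
            return {"F": float(tab.loc[row, "F"]), "p": float(tab.loc[row, "PR(>F)"]),
                    "ss": float(tab.loc[row, "sum_sq"])}
        terms = {fa: _term("C(A)"), fb: _term("C(B)"), f"{fa}:{fb}": _term("C(A):C(B)")}
        stat = terms[f"{fa}:{fb}"]["F"]
        p = terms[f"{fa}:{fb}"]["p"]

    cell_groups = _group_arrays(sub.assign(metric=metric), metric, [fa, fb])
    if post_hoc == "tukey":
        pairs = _tukey_pairs(cell_groups)
    elif post_hoc == "holm-sidak":
        names = list(cell_groups)
        raw = []
        for g1, g2 in itertools.combinations(names, 2):
            t, pr = stats.ttest_ind(cell_groups[g1], cell_groups[g2], equal_var=True)
            raw.append(((g1, g2), float(t), float(pr)))
        rej, p_adj, *_ = multipletests([r[2] for r in raw], alpha=ALPHA, method="holm-sidak")
        pairs = [
            {"pair": pair, "statistic": t, "p_adj": float(pa), "significant": bool(r),
             "stars": significance_stars(pa)}
            for (pair, t, _), pa, r in zip(raw, p_adj, rej)
        ]
    else:
        raise ValueError("post_hoc must be 'tukey' or 'holm-sidak'")
    return ComparisonResult(
        f"two-way ANOVA ({fa} x {fb})", list(cell_groups), float(stat), float(p),
        post_hoc=pairs, terms=terms,
    )


def ks_normality(values) -> tuple[float, float]:
    """Lilliefors Kolmogorov–Smirnov test against a fitted Normal.

    Returns (statistic, p).  p values come from the Monte-Carlo calibrated
    table in statsmodels.  Constant data are degenerate and rejected with an
    error rather than a p value.
    """
    from statsmodels.stats.diagnostic import lilliefors

    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("normality check needs at least 5 values")
    if values.std(ddof=1) == 0:
        raise ValueError("constant data: normality test is degenerate")
    stat, p = lilliefors(values, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change of comparison vs reference: 100*(c - r)/r."""
    if reference_mean == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    return 100.0 * (comparison_mean - reference_mean) / reference_mean
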