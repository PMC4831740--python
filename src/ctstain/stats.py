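"""Two-way ANOVA (day × stain) and Tukey HSD post-hoc comparisons.

The experimental design behind these tools is a staining study with a
handful of samples per contrast agent scanned daily: two crossed factors
(staining day, stain type).  With one observation per cell an additive
(no-interaction) model is the only estimable two-way decomposition, and
that is what is fitted; the interaction term is included automatically
when cell replicates exist.  Balanced designs use the exact closed-form
sums of squares; unbalanced designs fall back to a Type-II least-squares
decomposition (statsmodels OLS) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = ["AnovaResult", "two_way_anova", "tukey_hsd"]


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table plus design diagnostics.

    ``table`` rows are the two factors, optionally their interaction, and
    the residual, with columns (ss, df, F, p).
    """

    table: pd.DataFrame
    balanced: bool
    has_interaction: bool

    @property
    def total_ss(self) -> float:
        return float(self.table["ss"].sum())


def _balanced_two_way(y, a_codes, b_codes, na, nb, r):
    """Exact mean-decomposition sums of squares for a balanced design."""
    grand = y.mean()
    a_means = np.array([y[a_codes == i].mean() for i in range(na)])
    b_means = np.array([y[b_codes == j].mean() for j in range(nb)])
    ss_a = r * nb * float(np.sum((a_means - grand) ** 2))
    ss_b = r * na * float(np.sum((b_means - grand) ** 2))
    if r > 1:
        cell = np.zeros((na, nb))
        for i in range(na):
            for j in range(nb):
                cell[i, j] = y[(a_codes == i) & (b_codes == j)].mean()
        ss_ab = r * float(
            np.sum((cell - a_means[:, None] - b_means[None, :] + grand) ** 2)
        )
        fitted = cell[a_codes, b_codes]
        ss_e = float(np.sum((y - fitted) ** 2))
        df = [na - 1, nb - 1, (na - 1) * (nb - 1), na * nb * (r - 1)]
        rows = ["factor_a", "factor_b", "interaction", "residual"]
        ss = [ss_a, ss_b, ss_ab, ss_e]
    else:
        fitted = a_means[a_codes] + b_means[b_codes] - grand
        ss_e = float(np.sum((y - fitted) ** 2))
        df = [na - 1, nb - 1, (na - 1) * (nb - 1)]
        rows = ["factor_a", "factor_b", "residual"]
        ss = [ss_a, ss_b, ss_e]
    return rows, ss, df


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Two-way analysis of variance for two crossed categorical factors.

    Parameters are parallel sequences: observed values and the two factor
    labels (e.g. day and stain) per observation.  Returns the ANOVA table
    with F statistics and p-values from the F distribution.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Categorical(factor_a)
    b = pd.Categorical(factor_b)
    if y.ndim != 1 or len(a) != y.size or len(b) != y.size:
        raise ValidationError("values and factors must be 1D and matched")
    na, nb = len(a.categories), len(b.categories)
    if na < 2 or nb < 2:
        raise ValidationError("each factor needs at least 2 levels")

    counts = pd.crosstab(a, b).to_numpy()
    if (counts == 0).any():
        raise ValidationError("every factor-level combination needs observations")
    balanced = counts.min() == counts.max()

    if balanced:
        r = int(counts[0, 0])
        rows, ss, df = _balanced_two_way(
            y, np.asarray(a.codes), np.asarray(b.codes), na, nb, r
        )
        has_interaction = r > 1
    else:
        rows, ss, df = _unbalanced_two_way(y, a, b)
        has_interaction = "interaction" in rows

    ms = [s / d if d > 0 else np.nan for s, d in zip(ss, df)]
    mse, dfe = ms[-1], df[-1]
    F = [m / mse if name != "residual" and dfe > 0 and mse > 0 else np.nan
         for name, m in zip(rows, ms)]
    p = [float(sps.f.sf(f, d, dfe)) if np.isfinite(f) else np.nan
         for f, d in zip(F, df)]
    table = pd.DataFrame({"ss": ss, "df": df, "F": F, "p": p}, index=rows)
    table.loc["residual", ["F", "p"]] = np.nan
    return AnovaResult(table=table, balanced=bool(balanced),
                       has_interaction=has_interaction)


def _unbalanced_two_way(y, a, b):
    """Type-II decomposition via OLS for unbalanced designs."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = pd.crosstab(a, b).to_numpy()
    replicated = counts.min() > 1
    df_ = pd.DataFrame({"y": y, "a": a, "b": b})
    formula = "y ~ C(a) * C(b)" if replicated else "y ~ C(a) + C(b)"
    fit = smf.ols(formula, data=df_).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    rows, ss, df = [], [], []
    mapping = {"C(a)": "factor_a", "C(b)": "factor_b", "C(a):C(b)": "interaction",
               "Residual": "residual"}
    for name, row in tab.iterrows():
        rows.append(mapping.get(name, name))
        ss.append(float(row["sum_sq"]))
        df.append(int(row["df"]))
    return rows, ss, df


def tukey_hsd(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons.

    Studentized-range test on all group pairs using the pooled
    within-group mean square; handles unequal group sizes via the
    Tukey–Kramer standard error.  Returns a frame with columns
    (group1, group2, meandiff, q, p_adj, reject).
    """
    y = np.asarray(values, dtype=float)
    g = pd.Categorical(group_labels)
    if y.ndim != 1 or len(g) != y.size:
        raise ValidationError("values and group labels must be 1D and matched")
    groups = list(g.categories)
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least 2 groups")
    ns = {lvl: int((g == lvl).sum()) for lvl in groups}
    if min(ns.values()) < 2:
        raise ValidationError("every group needs at least 2 observations")
    means = {lvl: float(y[np.asarray(g == lvl)].mean()) for lvl in groups}
    n_total = y.size
    ss_within = sum(
        float(np.sum((y[np.asarray(g == lvl)] - means[lvl]) ** 2)) for lvl in groups
    )
    df_within = n_total - k
    mse = ss_within / df_within

    rows = []
    for g1, g2 in combinations(groups, 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
        rows.append(
            {"group1": g1, "group2": g2, "meandiff": diff, "q": q,
             "p_adj": p, "reject": p < alpha}
        )
    return pd.DataFrame(rows)
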