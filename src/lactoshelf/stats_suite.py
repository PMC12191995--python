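"""Statistical battery: ANOVA family, Tukey HSD, variance-homogeneity
tests, the moment-based normality gate, and Pearson chi-square for
categorical survey data.

One-way ANOVA is computed directly from its sums-of-squares
decomposition (it is also the primitive used in type-I-error
simulations, where a formula-based fit per replicate would dominate the
cost); balanced two-way and repeated-measures designs go through
statsmodels OLS + anova_lm.  Variance tests, Tukey and chi-square wrap
scipy.  Significance is assessed at alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import DegenerateInputError, InvalidArgumentError, ValidationError

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Per-term F statistics of a fitted ANOVA.

    ``terms`` maps term name -> dict(F, df, p, ss); ``residual`` carries
    the residual df and SS.  For balanced designs the term SS plus
    residual SS reproduce the total SS.
    """

    design: str
    terms: dict
    residual: dict
    total_ss: float

    def summary(self) -> str:
        lines = [f"ANOVA ({self.design})",
                 f"{'term':<22}{'SS':>12}{'df':>6}{'F':>10}{'p':>12}"]
        for name, t in self.terms.items():
            lines.append(
                f"{name:<22}{t['ss']:>12.4f}{t['df']:>6d}{t['F']:>10.4f}{t['p']:>12.4g}"
            )
        lines.append(
            f"{'residual':<22}{self.residual['ss']:>12.4f}{self.residual['df']:>6d}"
        )
        return "\n".join(lines)


def one_way_anova(groups: list) -> AnovaResult:
    """One-way fixed-effects ANOVA from the SS decomposition.

    With two groups the F statistic equals the square of the pooled-
    variance two-sample t statistic.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InvalidArgumentError("each group needs >= 2 observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        raise DegenerateInputError("zero within-group variance")
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        design="one_way",
        terms={"group": {"F": float(f), "df": df_b, "p": p, "ss": float(ssb)}},
        residual={"df": df_w, "ss": float(ssw)},
        total_ss=float(ssb + ssw),
    )


def _check_balanced(data: pd.DataFrame, factors: list[str]) -> None:
    counts = data.groupby(factors, observed=True).size()
    expected_cells = int(np.prod([data[f].nunique() for f in factors]))
    if len(counts) != expected_cells:
        raise ValidationError("unbalanced design: empty cell")
    if counts.nunique() != 1:
        raise ValidationError("unbalanced design: unequal cell sizes")


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> AnovaResult:
    """Balanced two-factor factorial ANOVA with optional interaction.

    Balanced designs only: sequential SS then coincide with the
    orthogonal decomposition, so no SS-type choice arises.  Requires
    >= 2 observations per cell when the interaction is estimated.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    _check_balanced(data, [factor_a, factor_b])
    cell_n = data.groupby([factor_a, factor_b], observed=True).size().iloc[0]
    if interaction and cell_n < 2:
        raise ValidationError("interaction requires >= 2 observations per cell")
    df = data.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    op = "*" if interaction else "+"
    model = smf.ols(f"_y ~ C(_a) {op} C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    names = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    terms = {}
    residual = {}
    for row_name, row in table.iterrows():
        entry = {
            "ss": float(row["sum_sq"]),
            "df": int(row["df"]),
        }
        if row_name == "Residual":
            residual = entry
        else:
            entry["F"] = float(row["F"])
            entry["p"] = float(row["PR(>F)"])
            terms[names[row_name]] = entry
    return AnovaResult(
        design="factorial_2way",
        terms=terms,
        residual=residual,
        total_ss=float(table["sum_sq"].sum()),
    )


def repeated_measures_anova(
    data: pd.DataFrame, response: str, within: str, subject: str
) -> AnovaResult:
    """Univariate repeated-measures ANOVA with subject as blocking factor.

    Requires complete subject x condition blocks; no sphericity
    correction is applied.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = data.groupby([subject, within], observed=True).size()
    n_cells = data[subject].nunique() * data[within].nunique()
    if len(counts) != n_cells or (counts != 1).any():
        raise ValidationError("repeated measures requires complete subject x condition blocks")
    df = data.rename(columns={response: "_y", within: "_w", subject: "_s"})
    model = smf.ols("_y ~ C(_s) + C(_w)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    w = table.loc["C(_w)"]
    s = table.loc["C(_s)"]
    resid = table.loc["Residual"]
    return AnovaResult(
        design="repeated_measures",
        terms={
            within: {"F": float(w["F"]), "df": int(w["df"]),
                     "p": float(w["PR(>F)"]), "ss": float(w["sum_sq"])},
            subject: {"F": float(s["F"]), "df": int(s["df"]),
                      "p": float(s["PR(>F)"]), "ss": float(s["sum_sq"])},
        },
        residual={"df": int(resid["df"]), "ss": float(resid["sum_sq"])},
        total_ss=float(table["sum_sq"].sum()),
    )


def anova(data, design: str = "one_way", **kwargs) -> AnovaResult:
    """Dispatch to the requested ANOVA design.

    ``one_way`` takes a list of group arrays; ``factorial_2way`` and
    ``repeated_measures`` take a tidy DataFrame plus column names.
    """
    if design == "one_way":
        return one_way_anova(data)
    if design == "factorial_2way":
        return two_way_anova(data, **kwargs)
    if design == "repeated_measures":
        return repeated_measures_anova(data, **kwargs)
    raise InvalidArgumentError(f"unknown design {design!r}")


@dataclass
class PairwiseComparison:
    """One Tukey-adjusted pairwise contrast."""

    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float
    significant: bool


def tukey_hsd(groups: dict) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD via the studentized-range distribution.

    ``groups`` maps label -> observations; significance at alpha = 0.05.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    if len(arrays) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise InvalidArgumentError("each group needs >= 2 observations")
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = float(arrays[i].mean() - arrays[j].mean())
            p = float(res.pvalue[i, j])
            out.append(
                PairwiseComparison(labels[i], labels[j], diff, p, p < ALPHA)
            )
    return out


def variance_homogeneity(groups: list, method: str = "brown_forsythe"):
    """Bartlett's chi-square test or Brown-Forsythe (median-centred Levene).

    Returns (statistic, p).  Degenerate when every group has zero
    within-group variance.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise InvalidArgumentError("need >= 2 groups with >= 2 observations each")
    if all(np.var(a) == 0 for a in arrays):
        raise DegenerateInputError("zero within-group variance in all groups")
    if method == "bartlett":
        stat, p = sps.bartlett(*arrays)
    elif method == "brown_forsythe":
        stat, p = sps.levene(*arrays, center="median")
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return float(stat), float(p)


@dataclass
class DiagnosticsReport:
    """Moment-based normality diagnostics of a residual vector.

    The gate passes when |skewness| <= 1 and |excess kurtosis| <= 2;
    kurtosis is excess (normal = 0), since a raw-kurtosis band of ±2
    would reject the normal distribution itself.
    """

    skewness: float
    excess_kurtosis: float
    normal_pass: bool
    variance_tests: dict = field(default_factory=dict)


def normality_gate(residuals, groups: list | None = None) -> DiagnosticsReport:
    """Bias-corrected sample skewness/kurtosis with the ±1/±2 pass rule.

    Optionally attaches Bartlett and Brown-Forsythe variance tests when
    group-structured data accompany the residuals.
    """
    x = np.asarray(residuals, dtype=float)
    if x.size < 4:
        raise InvalidArgumentError("need n >= 4 for moment diagnostics")
    skew = float(sps.skew(x, bias=False))
    kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    vtests = {}
    if groups is not None:
        for method in ("bartlett", "brown_forsythe"):
            stat, p = variance_homogeneity(groups, method)
            vtests[method] = {"statistic": stat, "p": p}
    return DiagnosticsReport(
        skewness=skew,
        excess_kurtosis=kurt,
        normal_pass=abs(skew) <= 1.0 and abs(kurt) <= 2.0,
        variance_tests=vtests,
    )


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence; no continuity correction.

    Returns (statistic, df, p); df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero row/column margin")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateInputError("table needs >= 2 rows and columns")
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise DegenerateInputError("expected counts must be > 0")
    return float(stat), int(dof), float(p)
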