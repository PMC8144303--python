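"""2×2 factorial ANOVA with interaction and Fisher's PLSD pairwise tests.

The balanced closed form (type-I sums of squares, identical to type-III
under balance) is implemented directly so that calibration simulations can
run tens of thousands of replicates cheaply; unbalanced layouts are
delegated to a type-III linear-model fit with a warning.  Fisher's PLSD
compares group means with the ANOVA residual mean square
(``t = Δmean / sqrt(mse·(1/n1 + 1/n2))``, df = n − 4) and, following the
"protected" convention loosely, reports every requested comparison but
flags those made while the omnibus test is non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA summary.

    F/p per effect (factor A, factor B, interaction), residual mean square
    and degrees of freedom, plus any pairwise PLSD rows appended later.
    """

    factors: tuple
    F: dict
    p: dict
    ss: dict
    df: dict
    mse: float
    n: int
    balanced: bool
    pairwise: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for eff in (self.factors[0], self.factors[1], "interaction"):
            rows.append({"effect": eff, "ss": self.ss[eff], "df": self.df[eff],
                         "F": self.F[eff], "p": self.p[eff]})
        rows.append({"effect": "residual", "ss": self.ss["residual"],
                     "df": self.df["residual"], "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows).set_index("effect")


def _cells(values: pd.Series, design) -> dict:
    cells = {}
    for a in design.levels[design.factors[0]]:
        for b in design.levels[design.factors[1]]:
            samples = design.samples_in((a, b))
            if not samples:
                raise ValueError(f"empty design cell {(a, b)}")
            cells[(a, b)] = values.loc[samples].to_numpy(dtype=float)
    return cells


def anova_2x2(values: pd.Series, design) -> AnovaResult:
    """Two-way ANOVA of a per-sample scalar on the crossed 2×2 design.

    ``values`` is indexed by sample id.  Balanced layouts use the exact
    closed form; unbalanced ones fall back to type-III sums of squares
    (sum-coded linear model) with a warning.
    """
    fa, fb = design.factors
    cells = _cells(values, design)
    ns = {c: len(v) for c, v in cells.items()}
    n = sum(ns.values())
    if n - 4 <= 0:
        raise ValueError("need n > 4 samples for residual df")
    balanced = len(set(ns.values())) == 1

    if balanced:
        r = next(iter(ns.values()))
        la = design.levels[fa]
        lb = design.levels[fb]
        grand = np.mean([v.mean() for v in cells.values()])
        mean_a = {a: np.mean([cells[(a, b)].mean() for b in lb]) for a in la}
        mean_b = {b: np.mean([cells[(a, b)].mean() for a in la]) for b in lb}
        ss_a = 2 * r * sum((mean_a[a] - grand) ** 2 for a in la)
        ss_b = 2 * r * sum((mean_b[b] - grand) ** 2 for b in lb)
        ss_ab = r * sum(
            (cells[(a, b)].mean() - mean_a[a] - mean_b[b] + grand) ** 2
            for a in la for b in lb
        )
        ss_res = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
        df_res = n - 4
        mse = ss_res / df_res
        ss = {fa: ss_a, fb: ss_b, "interaction": ss_ab, "residual": ss_res}
    else:
        warnings.warn("unbalanced 2x2 design: using type-III sums of squares", stacklevel=2)
        ss, mse, df_res = _type3_ss(values, design)

    df = {fa: 1, fb: 1, "interaction": 1, "residual": df_res}
    F, p = {}, {}
    for eff in (fa, fb, "interaction"):
        F[eff] = ss[eff] / 1.0 / mse if mse > 0 else np.inf
        p[eff] = float(stats.f.sf(F[eff], 1, df_res))
    return AnovaResult(factors=(fa, fb), F=F, p=p, ss=ss, df=df, mse=float(mse),
                       n=n, balanced=balanced)


def _type3_ss(values: pd.Series, design):
    """Type-III SS via sum-coded OLS (statsmodels), for unbalanced layouts."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = design.factors
    df = design.table.loc[values.index, [fa, fb]].copy()
    df["y"] = values.to_numpy(dtype=float)
    df = df.rename(columns={fa: "A", fb: "B"})
    model = smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    ss = {
        fa: float(table.loc["C(A, Sum)", "sum_sq"]),
        fb: float(table.loc["C(B, Sum)", "sum_sq"]),
        "interaction": float(table.loc["C(A, Sum):C(B, Sum)", "sum_sq"]),
        "residual": float(table.loc["Residual", "sum_sq"]),
    }
    df_res = int(table.loc["Residual", "df"])
    return ss, ss["residual"] / df_res, df_res


def plsd_pairwise(
    values: pd.Series,
    design,
    comparisons,
    anova: AnovaResult | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's PLSD for the requested group pairs.

    Each comparison is a pair of design cells (tuples of factor levels).
    The t statistic uses the ANOVA residual mean square with df = n − 4.
    ``protected`` records whether the omnibus test (any effect p < α) was
    significant when the comparison was made.
    """
    if anova is None:
        anova = anova_2x2(values, design)
    omnibus_sig = any(anova.p[eff] < alpha for eff in (*anova.factors, "interaction"))
    df_res = anova.df["residual"]
    rows = []
    for cell1, cell2 in comparisons:
        s1 = design.samples_in(tuple(cell1))
        s2 = design.samples_in(tuple(cell2))
        if not s1 or not s2:
            raise ValueError(f"unknown group in comparison {(cell1, cell2)}")
        m1 = float(values.loc[s1].mean())
        m2 = float(values.loc[s2].mean())
        se = np.sqrt(anova.mse * (1.0 / len(s1) + 1.0 / len(s2)))
        t = (m1 - m2) / se if se > 0 else np.inf * np.sign(m1 - m2)
        p = float(2.0 * stats.t.sf(abs(t), df_res))
        rows.append(
            {
                "group1": "/".join(cell1),
                "group2": "/".join(cell2),
                "mean_diff": m1 - m2,
                "t": float(t),
                "df": df_res,
                "p": p,
                "protected": omnibus_sig,
            }
        )
    table = pd.DataFrame(rows)
    anova.pairwise = table
    return table
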