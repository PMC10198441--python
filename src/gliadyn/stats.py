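"""Group comparisons on per-animal summary tables.

Unpaired Student's t (equal-variance by default, Welch by flag) for
treatment comparisons with sexes pooled; two-way ANOVA over treatment x sex
with Bonferroni post-hoc comparisons; paired t for within-animal layer
comparisons.  A repeated-measures variant with Greenhouse-Geisser correction
is available for longitudinal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "unpaired_t",
    "paired_t",
    "two_way_anova",
    "rm_anova",
    "bonferroni",
]


@dataclass
class StatsResult:
    test: str
    groups: list[str]
    statistic: float
    df: float | tuple
    p: float
    descriptives: pd.DataFrame = field(default_factory=pd.DataFrame)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _describe(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        rows.append(
            {
                "group": g,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sem": float(sps.sem(v)) if len(v) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def unpaired_t(
    values, group_labels, equal_var: bool = True
) -> StatsResult:
    """Two-sided two-sample t-test (Student by default, Welch by flag)."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups; got {len(groups)}")
    a = values[group_labels == groups[0]]
    b = values[group_labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    df = (
        len(a) + len(b) - 2
        if equal_var
        else _welch_df(a, b)
    )
    return StatsResult(
        test="unpaired t" + ("" if equal_var else " (Welch)"),
        groups=list(groups),
        statistic=float(t),
        df=float(df),
        p=float(p),
        descriptives=_describe(values, group_labels),
    )


def _welch_df(a, b) -> float:
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def paired_t(values_a, values_b, labels=("A", "B")) -> StatsResult:
    """Two-sided paired t on within-pair differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = a - b
    if np.var(diffs) == 0:
        if np.all(diffs == 0):
            t, p = 0.0, 1.0
        else:
            raise ValueError(
                "paired differences have zero variance; t statistic undefined"
            )
    else:
        t, p = sps.ttest_rel(a, b)
    desc = _describe(
        np.concatenate([a, b]),
        np.array([labels[0]] * len(a) + [labels[1]] * len(b)),
    )
    return StatsResult(
        test="paired t",
        groups=list(labels),
        statistic=float(t),
        df=float(len(a) - 1),
        p=float(p),
        descriptives=desc,
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * len(p))


def two_way_anova(
    data: pd.DataFrame,
    dv: str,
    factor_a: str = "treatment",
    factor_b: str = "sex",
    bonferroni_pairs: list[tuple[dict, dict]] | None = None,
) -> StatsResult:
    """Between-subjects two-way ANOVA with optional Bonferroni post-hocs.

    ``bonferroni_pairs`` lists (cell_filter_1, cell_filter_2) dicts, e.g.
    ``({'treatment': 'EtOH', 'sex': 'F'}, {'treatment': 'Saline', 'sex':
    'F'})``; pairwise t p-values are multiplied by the number of
    comparisons.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for fac in (factor_a, factor_b):
        counts = data.groupby([factor_a, factor_b], observed=True)[dv].count()
        if counts.min() < 2 or len(counts) < 4:
            raise ValueError("two-way ANOVA needs >= 2 observations per cell")
    values = data[dv].to_numpy(dtype=float)
    if np.all(values == values[0]):
        # zero variance everywhere: all F are 0 by convention
        table = pd.DataFrame(
            {
                "F": [0.0, 0.0, 0.0],
                "p": [1.0, 1.0, 1.0],
            },
            index=[factor_a, factor_b, f"{factor_a}:{factor_b}"],
        )
        main = (factor_a, 0.0, 1.0)
    else:
        df_work = data[[dv, factor_a, factor_b]].copy()
        df_work.columns = ["dv", "fa", "fb"]
        fit = ols("dv ~ C(fa) * C(fb)", data=df_work).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        table = pd.DataFrame(
            {
                "F": aov["F"].iloc[:3].to_numpy(),
                "p": aov["PR(>F)"].iloc[:3].to_numpy(),
                "df": aov["df"].iloc[:3].to_numpy(),
                "df_resid": float(aov["df"].iloc[3]),
            },
            index=[factor_a, factor_b, f"{factor_a}:{factor_b}"],
        )
        main = (factor_a, float(table["F"].iloc[0]), float(table["p"].iloc[0]))

    posthoc = pd.DataFrame()
    if bonferroni_pairs:
        raw = []
        for filt1, filt2 in bonferroni_pairs:
            v1 = _filter(data, filt1)[dv].to_numpy(dtype=float)
            v2 = _filter(data, filt2)[dv].to_numpy(dtype=float)
            t, p = sps.ttest_ind(v1, v2)
            raw.append({"comparison": f"{filt1} vs {filt2}", "t": float(t),
                        "p_raw": float(p)})
        posthoc = pd.DataFrame(raw)
        posthoc["p_adj"] = bonferroni(posthoc["p_raw"])
        posthoc["method"] = "Bonferroni"

    labels = (
        data[factor_a].astype(str) + "/" + data[factor_b].astype(str)
    ).to_numpy()
    return StatsResult(
        test="two-way ANOVA",
        groups=sorted(set(labels)),
        statistic=main[1],
        df=(
            float(table["df"].iloc[0]) if "df" in table else 1.0,
            float(table["df_resid"].iloc[0]) if "df_resid" in table else float("nan"),
        ),
        p=main[2],
        descriptives=_describe(data[dv].to_numpy(dtype=float), labels),
        table=table,
        posthoc=posthoc,
    )


def _filter(data: pd.DataFrame, filt: dict) -> pd.DataFrame:
    out = data
    for k, v in filt.items():
        out = out[out[k] == v]
    return out


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    correction: bool = True,
) -> StatsResult:
    """One-way repeated-measures ANOVA (Greenhouse-Geisser corrected)."""
    import pingouin as pg

    aov = pg.rm_anova(
        data=data, dv=dv, within=within, subject=subject, correction=correction
    )
    row = aov.iloc[0]
    use_gg = correction and "p_GG_corr" in aov.columns and not np.isnan(
        row.get("p_GG_corr", np.nan)
    )
    p = float(row["p_GG_corr"]) if use_gg else float(row["p_unc"])
    eps = float(row["eps"]) if use_gg else 1.0
    return StatsResult(
        test="repeated-measures ANOVA" + (" (GG)" if use_gg else ""),
        groups=sorted(data[within].astype(str).unique()),
        statistic=float(row["F"]),
        df=(float(row["ddof1"]) * eps, float(row["ddof2"]) * eps),
        p=p,
        table=aov,
    )
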