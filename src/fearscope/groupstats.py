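"""Group-comparison layer: assumption checks, outlier removal, mixed-design
repeated-measures ANOVA and Tukey multiple comparisons.

The study design compares one between-subjects factor (sex) against one
within-subjects factor (session epoch or tone block). Before testing,
normality (Shapiro-Wilk) and homogeneity of variance (Levene) are reported
and extreme values can be stripped with the recurrent two-sided Grubbs test.
Sphericity (Mauchly) is reported for within factors with more than two
levels; no epsilon correction is applied by default, though
Greenhouse-Geisser-corrected p-values are available from the underlying fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "grubbs_recurrent",
    "grubbs_critical_value",
    "normality_and_variance_checks",
    "rm_anova_2way",
    "tukey_hsd",
]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value:
    ``((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with
    ``t = t_{alpha/(2n), n-2}``."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_recurrent(values, alpha: float = 0.05):
    """Recurrent two-sided Grubbs outlier removal.

    Repeatedly removes the single most extreme point (largest
    |x - mean| / s) while its G statistic exceeds the critical value at
    ``alpha``, then stops. Returns ``(kept_values, removed_indices)`` with
    removed indices referring to the original array in removal order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    idx = np.arange(x.size)
    removed: list[int] = []
    while x.size >= 3:
        s = x.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(x - x.mean())
        j = int(np.argmax(dev))
        g = dev[j] / s
        if g <= grubbs_critical_value(x.size, alpha):
            break
        removed.append(int(idx[j]))
        x = np.delete(x, j)
        idx = np.delete(idx, j)
    return x, removed


def normality_and_variance_checks(groups: dict[str, np.ndarray]) -> dict:
    """Shapiro-Wilk p per group plus Levene's (center = mean) p across groups.

    Reported, not enforced; degenerate groups (n < 3 or constant) are
    flagged with a NaN p-value.
    """
    shapiro_p = {}
    flags = {}
    valid = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3 or np.ptp(vals) == 0:
            shapiro_p[name] = float("nan")
            flags[name] = "degenerate"
            continue
        shapiro_p[name] = float(stats.shapiro(vals).pvalue)
        valid.append(vals)
    levene_p = (float(stats.levene(*valid, center="mean").pvalue)
                if len(valid) >= 2 else float("nan"))
    return {"shapiro_p": shapiro_p, "levene_p": levene_p, "flags": flags}


def rm_anova_2way(table: pd.DataFrame, dv: str = "value",
                  subject: str = "subject_id", between: str = "between_factor",
                  within: str = "within_factor") -> pd.DataFrame:
    """Mixed-design ANOVA: one between-subjects and one within-subjects factor.

    Subjects missing any within level are dropped (with a warning) so the
    design is complete. Returns a tidy effect table (source, SS, df1, df2,
    F, p) whose ``attrs`` carry the sphericity report when the within factor
    has more than two levels.
    """
    for col in (dv, subject, between, within):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    n_within = table[within].nunique()
    counts = table.groupby(subject, observed=True)[within].nunique()
    complete = counts[counts == n_within].index
    dropped = sorted(set(table[subject]) - set(complete))
    if dropped:
        warnings.warn(f"dropping incomplete subjects: {dropped}", stacklevel=2)
        table = table[table[subject].isin(complete)]
    cell_counts = table.groupby([between, within], observed=True)[subject].nunique()
    if (cell_counts < 2).any():
        raise ValueError("need at least 2 subjects per cell")

    aov = pg.mixed_anova(data=table, dv=dv, within=within, subject=subject,
                         between=between)
    out = aov.rename(columns={"Source": "source", "SS": "ss", "DF1": "df1",
                              "DF2": "df2", "F": "F", "p_unc": "p",
                              "p-unc": "p"})
    out = out[["source", "ss", "df1", "df2", "F", "p"]].copy()
    out["source"] = out["source"].map(
        {between: "between", within: "within", "Interaction": "interaction"})
    if n_within > 2:
        spher = pg.sphericity(data=table, dv=dv, within=within, subject=subject)
        out.attrs["sphericity"] = {"W": float(spher.W), "p": float(spher.pval),
                                   "spher": bool(spher.spher)}
    return out


def tukey_hsd(table: pd.DataFrame, value: str = "value",
              group: str = "group") -> pd.DataFrame:
    """All pairwise comparisons of a factor's levels with studentized-range
    (Tukey HSD / Tukey-Kramer) adjusted p-values.

    Also reports the unadjusted pooled-variance t-test p for each pair;
    the adjusted p is never smaller.
    """
    levels = list(pd.unique(table[group]))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    samples = [np.asarray(table.loc[table[group] == lev, value], dtype=float)
               for lev in levels]
    res = stats.tukey_hsd(*samples)
    # pooled MSE for the unadjusted pairwise t statistics
    dfe = sum(s.size for s in samples) - len(samples)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / dfe
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = samples[i].mean() - samples[j].mean()
            se = np.sqrt(mse * (1 / samples[i].size + 1 / samples[j].size))
            t = diff / se if se > 0 else np.inf
            p_unadj = 2 * stats.t.sf(abs(t), dfe)
            rows.append({
                "level_a": levels[i],
                "level_b": levels[j],
                "mean_diff": diff,
                "p_adj": float(res.pvalue[i, j]),
                "p_unadj": float(p_unadj),
            })
    return pd.DataFrame(rows)
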