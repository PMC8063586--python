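"""ROI summaries, group statistics, and volumetric/thickness ratios.

Group comparisons follow a two-way ANOVA (group × frequency for ADC;
group × ROI for the dispersion slope), followed by post hoc Welch
(unequal-variance) two-sample t-tests at each level of the second factor.
No multiple-testing correction is applied by default; Holm correction is
available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datasets import ROILabelMap

__all__ = ["roi_summaries", "volume_reduction", "group_compare",
           "thickness_ratio", "DesignError"]


class DesignError(ValueError):
    pass


def roi_summaries(roi_map: ROILabelMap, metric_volumes: dict[str, np.ndarray],
                  *, subject: str = "", group: str = "") -> pd.DataFrame:
    """Per-ROI mean/SD/count/volume for each metric volume.

    ``metric_volumes`` maps metric name → 3-D volume on the label grid.
    Empty ROIs are recorded with count 0 and an ``empty`` flag.
    """
    rows = []
    for label, name in sorted(roi_map.names.items()):
        sel = roi_map.labels == label
        count = int(np.count_nonzero(sel))
        for metric, vol in metric_volumes.items():
            if vol.shape != roi_map.labels.shape:
                raise ValueError(f"metric {metric!r} grid mismatch")
            vals = vol[sel]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "subject": subject, "group": group, "roi": name,
                "label": label, "metric": metric,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                      if len(vals) == 1 else np.nan,
                "n_voxels": count,
                "volume_mm3": count * roi_map.voxel_volume,
                "empty": count == 0,
            })
    return pd.DataFrame(rows)


def volume_reduction(eu_mean: float, ts_mean: float) -> float:
    """Percent reduction 100·(1 − ts/eu); report layers round to integer %."""
    if eu_mean <= 0:
        raise ValueError("reference (Eu) mean volume must be positive")
    return 100.0 * (1.0 - ts_mean / eu_mean)


def anova_twoway(table: pd.DataFrame, value: str, factor_a: str,
                 factor_b: str) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction (type-II SS)."""
    df = table.rename(columns={value: "_y"})
    model = smf.ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov.index = [idx.replace(f"C({factor_a})", factor_a)
                    .replace(f"C({factor_b})", factor_b)
                 for idx in aov.index]
    return aov


def group_compare(table: pd.DataFrame, metric: str | None = None, *,
                  value: str = "value", group_col: str = "group",
                  within_col: str = "frequency", alpha: float = 0.05,
                  holm: bool = False) -> dict:
    """Two-way ANOVA (group × second factor) plus per-level Welch t-tests.

    ``table`` is long-format with one row per subject × level. Returns a
    dict with the ANOVA table, a post hoc DataFrame (level, means, t, p,
    significant), and the factor names.
    """
    df = table
    if metric is not None and "metric" in df.columns:
        df = df[df["metric"] == metric]
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise DesignError("group comparison needs two groups")
    if len(groups) > 2:
        raise DesignError("only two-group designs are supported")

    aov = anova_twoway(df, value, group_col, within_col)

    rows = []
    for level, sub in df.groupby(within_col):
        a = sub.loc[sub[group_col] == groups[0], value].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == groups[1], value].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise DesignError("post hoc tests need ≥2 subjects per cell")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({within_col: level,
                     f"mean_{groups[0]}": a.mean(),
                     f"mean_{groups[1]}": b.mean(),
                     "t": float(t), "p": float(p)})
    posthoc = pd.DataFrame(rows)
    if holm:
        order = np.argsort(posthoc["p"].to_numpy())
        m = len(posthoc)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * posthoc["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        posthoc["p_holm"] = adj
        posthoc["significant"] = posthoc["p_holm"] < alpha
    else:
        posthoc["significant"] = posthoc["p"] < alpha
    return {"anova": aov, "posthoc": posthoc, "groups": groups,
            "factors": (group_col, within_col), "alpha": alpha}


def thickness_ratio(ts_values, eu_values) -> tuple[float, float]:
    """Pairwise Ts/Eu ratios in percent: (mean, SEM).

    Pairs with a zero denominator are excluded (flagged via a warning-free
    drop; the count difference is visible in the inputs).
    """
    ts = np.asarray(ts_values, dtype=float)
    eu = np.asarray(eu_values, dtype=float)
    if len(ts) == 0 or len(eu) == 0:
        raise ValueError("both groups must be non-empty")
    if len(ts) != len(eu):
        raise ValueError("thickness ratio is pairwise; lengths must match")
    keep = eu != 0
    ratios = 100.0 * ts[keep] / eu[keep]
    if len(ratios) == 0:
        raise ValueError("all reference values are zero")
    sem = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) \
        if len(ratios) > 1 else 0.0
    return float(ratios.mean()), sem
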