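"""Percent-change dose-response tables and the accompanying statistics.

The dose-response readout of plate-based membrane-potential screening is the
per-well percentage change of each evaluation parameter from its pre-compound
baseline, summarized as mean ± SD per (drug, group, concentration).

Group comparisons follow the conventional decision tree: Shapiro-Wilk
normality check, an F-ratio test for variance homogeneity at α = 0.05, then
Student's t for homogeneous and Welch's t for heterogeneous variances; three
or more groups go through one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Well-summary columns that enter the dose-response tables.
DOSE_RESPONSE_PARAMETERS = (
    "beat_rate", "amplitude_mean", "v_up_mean", "v_down_mean",
    "pwd30", "pwd50", "pwd80",
    "pwd30cF", "pwd50cF", "pwd80cF", "pwd30_80", "plateau_ratio",
)


def percent_change(post_value: float, pre_value: float) -> float:
    """100 × (post − pre) / pre.

    Raises ``ValueError`` when the pre-compound baseline is undefined or
    zero (e.g. a well already arrested before compound addition); such wells
    are excluded upstream rather than coerced to 0%.
    """
    if pre_value is None or not np.isfinite(pre_value) or pre_value == 0:
        raise ValueError(f"pre-compound baseline undefined or zero: {pre_value!r}")
    if post_value is None or not np.isfinite(post_value):
        raise ValueError(f"post-compound value undefined: {post_value!r}")
    return 100.0 * (post_value - pre_value) / pre_value


def per_well_percent_changes(summaries: pd.DataFrame,
                             parameters: tuple[str, ...] = DOSE_RESPONSE_PARAMETERS,
                             ) -> pd.DataFrame:
    """Long table of per-well percent changes from paired pre/post summaries.

    ``summaries`` is the long per-well table produced by the pipeline (one
    row per well and phase, columns including ``well, phase, group, drug,
    concentration_uM`` and the parameter columns).  Wells whose post
    recording is arrested contribute to incidence elsewhere but are excluded
    here — their parameters are undefined (NaN) and percent change cannot be
    formed.
    """
    pre = summaries[summaries["phase"] == "pre"].set_index("well")
    post = summaries[summaries["phase"] == "post"].set_index("well")
    rows = []
    for well in post.index:
        if well not in pre.index:
            logger.info("well %s: no pre-phase summary; excluded from dose-response", well)
            continue
        for param in parameters:
            try:
                pct = percent_change(post.at[well, param], pre.at[well, param])
            except ValueError as e:
                logger.debug("well %s, %s: excluded (%s)", well, param, e)
                continue
            rows.append({
                "drug": post.at[well, "drug"], "group": post.at[well, "group"],
                "concentration_uM": post.at[well, "concentration_uM"],
                "parameter": param, "well": well, "pct_change": pct,
            })
    return pd.DataFrame(
        rows, columns=["drug", "group", "concentration_uM", "parameter", "well", "pct_change"])


def build_dose_response(summaries: pd.DataFrame,
                        parameters: tuple[str, ...] = DOSE_RESPONSE_PARAMETERS,
                        ) -> pd.DataFrame:
    """Per-condition mean ± SD percent changes from paired pre/post summaries.

    ``n`` counts the wells contributing to each (drug, group, concentration,
    parameter) cell; see :func:`per_well_percent_changes` for the exclusion
    rules.
    """
    per_well = per_well_percent_changes(summaries, parameters)
    if per_well.empty:
        return pd.DataFrame(columns=["drug", "group", "concentration_uM", "parameter",
                                     "mean_pct", "sd_pct", "n"])
    agg = (per_well.groupby(["drug", "group", "concentration_uM", "parameter"], dropna=False)
           ["pct_change"].agg(mean_pct="mean", sd_pct=lambda s: s.std(ddof=1), n="count")
           .reset_index())
    return agg.sort_values(["drug", "group", "parameter", "concentration_uM"]
                           ).reset_index(drop=True)


@dataclass
class StatResult:
    """Outcome of one statistical comparison."""

    comparison: str
    test: str                      # student_t | welch_t | anova_tukey | not_evaluable
    statistic: float = np.nan
    p: float = np.nan
    shapiro_p: tuple[float, ...] = ()
    variance_p: float = np.nan
    evaluable: bool = True
    tukey: pd.DataFrame | None = None   # pairwise adjusted p-values (ANOVA path)

    @property
    def sig05(self) -> bool:
        return bool(self.evaluable and self.p < 0.05)

    @property
    def sig01(self) -> bool:
        return bool(self.evaluable and self.p < 0.01)

    def to_row(self) -> dict:
        return {
            "comparison": self.comparison, "test": self.test,
            "shapiro_p_a": self.shapiro_p[0] if len(self.shapiro_p) > 0 else np.nan,
            "shapiro_p_b": self.shapiro_p[1] if len(self.shapiro_p) > 1 else np.nan,
            "variance_p": self.variance_p, "statistic": self.statistic, "p": self.p,
            "sig05": self.sig05, "sig01": self.sig01,
        }


def _f_ratio_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-ratio test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 and va == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p_one = sps.f.sf(f, len(a) - 1, len(b) - 1)
    p = 2.0 * min(p_one, 1.0 - p_one)
    return float(min(p, 1.0))


def compare_groups(samples_a, samples_b, comparison: str = "",
                   var_alpha: float = 0.05) -> StatResult:
    """Two-group comparison: Student's t or Welch's t, gated by an F-ratio test.

    Each sample needs n >= 3; otherwise the result is flagged not evaluable.
    Shapiro-Wilk normality p-values are recorded for both samples.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        return StatResult(comparison=comparison, test="not_evaluable", evaluable=False)
    with np.errstate(all="ignore"):
        sw_a = float(sps.shapiro(a).pvalue) if np.ptp(a) > 0 else np.nan
        sw_b = float(sps.shapiro(b).pvalue) if np.ptp(b) > 0 else np.nan
    p_var = _f_ratio_test(a, b)
    equal_var = p_var >= var_alpha
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: no variance at all; equal means -> t = 0, p = 1
        equal = np.mean(a) == np.mean(b)
        return StatResult(comparison=comparison,
                          test="student_t", statistic=0.0 if equal else np.inf,
                          p=1.0 if equal else 0.0, shapiro_p=(sw_a, sw_b),
                          variance_p=p_var)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(
        comparison=comparison, test="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic), p=float(res.pvalue),
        shapiro_p=(sw_a, sw_b), variance_p=p_var,
    )


def compare_multi(groups, comparison: str = "") -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise follow-up for >= 3 groups.

    Raises ``ValueError`` directing to :func:`compare_groups` when fewer than
    three groups are passed; groups with n < 3 make the result not evaluable.
    """
    arrays = [np.asarray(g, float) for g in groups]
    arrays = [g[np.isfinite(g)] for g in arrays]
    if len(arrays) < 3:
        raise ValueError("fewer than 3 groups: use compare_groups for the two-sample case")
    if any(len(g) < 3 for g in arrays):
        return StatResult(comparison=comparison, test="not_evaluable", evaluable=False)
    with np.errstate(all="ignore"):
        sw = tuple(float(sps.shapiro(g).pvalue) if np.ptp(g) > 0 else np.nan
                   for g in arrays)
    if all(np.var(g, ddof=1) == 0 for g in arrays) and len({float(g.mean()) for g in arrays}) == 1:
        k = len(arrays)
        tk = pd.DataFrame([(i, j, 1.0) for i in range(k) for j in range(i + 1, k)],
                          columns=["group_a", "group_b", "p_adj"])
        return StatResult(comparison=comparison, test="anova_tukey", statistic=0.0,
                          p=1.0, shapiro_p=sw, tukey=tk)
    f_res = sps.f_oneway(*arrays)
    tk_res = sps.tukey_hsd(*arrays)
    k = len(arrays)
    tk = pd.DataFrame(
        [(i, j, float(tk_res.pvalue[i, j])) for i in range(k) for j in range(i + 1, k)],
        columns=["group_a", "group_b", "p_adj"])
    return StatResult(
        comparison=comparison, test="anova_tukey",
        statistic=float(f_res.statistic), p=float(f_res.pvalue),
        shapiro_p=sw, tukey=tk,
    )


def group_comparison_table(per_well: pd.DataFrame) -> pd.DataFrame:
    """CT-vs-AM comparisons of percent changes per (drug, concentration, parameter).

    Runs :func:`compare_groups` wherever both groups contribute wells; rows
    for conditions with fewer than 3 wells per group are flagged not
    evaluable.  Returns the documented ``stats.csv`` shape.
    """
    rows = []
    for (drug, conc, param), g in per_well.groupby(
            ["drug", "concentration_uM", "parameter"], dropna=False):
        groups = dict(tuple(g.groupby("group")))
        if not {"CT", "AM"} <= set(groups):
            continue
        res = compare_groups(
            groups["CT"]["pct_change"], groups["AM"]["pct_change"],
            comparison=f"{drug} {conc} uM {param}: CT vs AM",
        )
        rows.append(res.to_row())
    return pd.DataFrame(rows, columns=["comparison", "test", "shapiro_p_a", "shapiro_p_b",
                                       "variance_p", "statistic", "p", "sig05", "sig01"])
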