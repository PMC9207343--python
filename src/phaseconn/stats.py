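"""Group-comparison statistics on complexity tables.

Comparisons are run on per-unit regional means (one value per subject or
simulation run, region, and measure). Real-EEG designs use Student's
t-test with a recorded Shapiro-Wilk normality check; simulated designs use
the Wilcoxon rank-sum (Mann-Whitney) test, since simulation ensembles
rarely meet parametric assumptions. Raw p-values are Benjamini-Hochberg
FDR-adjusted within each comparison's 3 regions x 3 measures grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .complexity import MEASURES, regional_means
from .regions import REGIONS

__all__ = ["compare_groups", "real_vs_simulated_anova"]

#: Minimum units per group for any cell test.
MIN_UNITS = 3


def _cell_values(unit_means: pd.DataFrame, region: str, measure: str) -> np.ndarray:
    sel = unit_means[(unit_means.region == region) & (unit_means.measure == measure)]
    return sel["value"].to_numpy()


def compare_groups(
    a: pd.DataFrame,
    b: pd.DataFrame,
    design: str = "real",
    alpha: float = 0.05,
    strict_normality: bool = False,
    group_names: tuple[str, str] = ("A", "B"),
    regions=REGIONS,
    measures=MEASURES,
) -> pd.DataFrame:
    """Region x measure group comparison between two complexity tables.

    Parameters
    ----------
    a, b:
        Long-format complexity tables (channel-level rows); per-unit
        regional means are computed first, so the unit of analysis is the
        subject (real design) or the simulation run (simulated design).
    design:
        ``"real"``: Shapiro-Wilk normality per group is evaluated and
        recorded, then Student's t-test is applied (a cell failing
        normality is flagged; with ``strict_normality`` the test switches
        to the rank-sum test for that cell). ``"simulated"``: Wilcoxon
        rank-sum throughout.
    alpha:
        Significance level applied to the FDR-adjusted p-values when
        assigning the direction label.

    Returns one row per (region, measure) with test name, statistic, raw
    and Benjamini-Hochberg-adjusted p-values, group means, and direction
    (``A>B`` / ``A<B`` / ``none``).
    """
    if design not in ("real", "simulated"):
        raise ValueError("design must be 'real' or 'simulated'")
    means_a = regional_means(a)
    means_b = regional_means(b)
    rows = []
    for region in regions:
        for measure in measures:
            va = _cell_values(means_a, region, measure)
            vb = _cell_values(means_b, region, measure)
            if va.size == 0 or vb.size == 0:
                raise ValueError(f"missing cell ({region}, {measure}) in one group")
            if va.size < MIN_UNITS or vb.size < MIN_UNITS:
                raise ValueError(
                    f"cell ({region}, {measure}): need >= {MIN_UNITS} units per group, "
                    f"got {va.size} and {vb.size}"
                )
            row = {"region": region, "measure": measure}
            if design == "real":
                row["shapiro_p_a"] = sps.shapiro(va).pvalue
                row["shapiro_p_b"] = sps.shapiro(vb).pvalue
                row["normality_ok"] = min(row["shapiro_p_a"], row["shapiro_p_b"]) >= alpha
                if strict_normality and not row["normality_ok"]:
                    stat = sps.ranksums(va, vb)
                    row["test_name"] = "wilcoxon-ranksum"
                else:
                    stat = sps.ttest_ind(va, vb, equal_var=True)
                    row["test_name"] = "students-t"
            else:
                stat = sps.ranksums(va, vb)
                row["test_name"] = "wilcoxon-ranksum"
            row["statistic"] = float(stat.statistic)
            row["p_raw"] = float(stat.pvalue)
            row["mean_a"] = float(va.mean())
            row["mean_b"] = float(vb.mean())
            rows.append(row)
    result = pd.DataFrame(rows)
    result["p_fdr"] = multipletests(result["p_raw"], method="fdr_bh")[1]
    result["direction"] = np.where(
        result["p_fdr"] < alpha,
        np.where(result["mean_a"] > result["mean_b"], "A>B", "A<B"),
        "none",
    )
    result["group_a"] = group_names[0]
    result["group_b"] = group_names[1]
    return result


def real_vs_simulated_anova(real: pd.DataFrame, sim: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA between real and simulated complexity values, per measure.

    Values are pooled over channels and units within each source; for each
    measure the two-group ANOVA F (which equals the square of the pooled
    t statistic) and its p-value are reported.
    """
    for name, table in (("real", real), ("simulated", sim)):
        if table.empty:
            raise ValueError(f"{name} complexity table is empty")
    rows = []
    for measure in MEASURES:
        vr = real.loc[real.measure == measure, "value"].to_numpy()
        vs = sim.loc[sim.measure == measure, "value"].to_numpy()
        if vr.size == 0 or vs.size == 0:
            raise ValueError(f"measure {measure} missing from one source")
        f = sps.f_oneway(vr, vs)
        # identical groups can give a tiny negative F and a NaN p by rounding
        statistic = max(float(f.statistic), 0.0)
        pvalue = float(f.pvalue)
        if not np.isfinite(pvalue):
            pvalue = float(sps.f.sf(statistic, 1, vr.size + vs.size - 2))
        rows.append(
            {
                "region": "all",
                "measure": measure,
                "test_name": "anova",
                "statistic": statistic,
                "p_raw": pvalue,
                "mean_a": float(vr.mean()),
                "mean_b": float(vs.mean()),
                "group_a": "real",
                "group_b": "simulated",
            }
        )
    result = pd.DataFrame(rows)
    result["p_fdr"] = multipletests(result["p_raw"], method="fdr_bh")[1]
    result["direction"] = np.where(
        result["p_fdr"] < 0.05,
        np.where(result["mean_a"] > result["mean_b"], "A>B", "A<B"),
        "none",
    )
    return result
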