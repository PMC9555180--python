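"""Demographic/clinical group comparisons and FC-clinical correlations.

Continuous variables are compared with the pooled-variance (Student)
two-sample t test — computable either from raw samples or from reported
group summaries (mean, SD, n) — and 2x2 categorical tables with Pearson's
chi-square without continuity correction.  Associations between
cluster-level FC strength and clinical severity scores use Pearson
correlation with Bonferroni control over all (cluster, variable) pairs
actually tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CONTINUOUS_VARIABLES = ("age", "education_years", "ybocs_total", "ybocs_obsessive",
                        "ybocs_compulsive", "hamd17", "hama", "mean_fd")


def pooled_two_sample_t(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> tuple[float, int]:
    """Student's pooled-variance t and df from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, df
        raise ValueError("zero pooled variance with unequal means")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df


def two_sample_t_from_samples(x, y) -> tuple[float, int]:
    """Pooled t from raw vectors; agrees exactly with the summary form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_two_sample_t(x.mean(), x.std(ddof=1), x.size,
                               y.mean(), y.std(ddof=1), y.size)


def chi_square_2x2(counts) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, _, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    return float(chi2), int(dof)


def group_summary_table(subjects: pd.DataFrame,
                        variables=CONTINUOUS_VARIABLES,
                        patient_label: str = "patient") -> pd.DataFrame:
    """Demographics-style table: group mean +/- SD, pooled t, and the sex chi2."""
    pat = subjects[subjects["group"] == patient_label]
    ctl = subjects[subjects["group"] != patient_label]
    rows = []
    for var in variables:
        t, df = two_sample_t_from_samples(pat[var], ctl[var])
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append({"variable": var,
                     "patients": f"{pat[var].mean():.2f} ± {pat[var].std(ddof=1):.2f}",
                     "controls": f"{ctl[var].mean():.2f} ± {ctl[var].std(ddof=1):.2f}",
                     "statistic": t, "p": p})
    if "sex" in subjects.columns:
        counts = [[(pat["sex"] == "M").sum(), (pat["sex"] == "F").sum()],
                  [(ctl["sex"] == "M").sum(), (ctl["sex"] == "F").sum()]]
        chi2, _ = chi_square_2x2(counts)
        p = stats.chi2.sf(chi2, 1)
        rows.insert(1, {"variable": "sex (male/female)",
                        "patients": f"{counts[0][0]}/{counts[0][1]}",
                        "controls": f"{counts[1][0]}/{counts[1][1]}",
                        "statistic": chi2, "p": p})
    return pd.DataFrame(rows)


def fc_clinical_correlations(cluster_means: pd.DataFrame, clinical: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r between each cluster-mean FC column and each clinical column.

    Subjects (rows) must align.  Significance is Bonferroni-controlled:
    a pair is flagged iff its raw p < alpha / n_tests, where n_tests counts
    the pairs actually tested (constant columns are reported as undefined
    and not counted).
    """
    if len(cluster_means) != len(clinical):
        raise ValueError("cluster_means and clinical must have matching rows")
    rows = []
    for cl in cluster_means.columns:
        for var in clinical.columns:
            x = cluster_means[cl].to_numpy(dtype=float)
            y = clinical[var].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"cluster": cl, "variable": var, "r": np.nan,
                             "p": np.nan, "defined": False})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"cluster": cl, "variable": var, "r": float(r),
                         "p": float(p), "defined": True})
    out = pd.DataFrame(rows)
    n_tests = int(out["defined"].sum())
    out["n_tests"] = n_tests
    out["significant"] = out["defined"] & (out["p"] < alpha / max(n_tests, 1))
    return out
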