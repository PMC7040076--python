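"""Leaf-trait survey data model, community-weighted means, group tests.

The flavonol index I_flav is a dimensionless optical index of leaf
epidermal UV-A absorbance (at 375 nm) measured repeatedly on individual
plants.  Community-weighted means (CWM) aggregate it to the measurement
point: species means are computed per point and date, then weighted by
the species' relative abundances, renormalised over the species actually
measured on that date so the CWM remains a proper mean.

Group comparisons follow the survey's analysis conventions: one-way
fixed-effects ANOVA across stands for each DOY, and two-sample t
(Welch by default) or Wilcoxon rank-sum tests for leaf-side contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("plant_id", "species", "stand", "point", "doy", "year",
                  "leaf_side", "leaf_age", "iflav")

#: I_flav above this is outside the optical clip's usual range.
IFLAV_FLAG_THRESHOLD = 3.0


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and I_flav range; flag out-of-range values."""
    missing = [c for c in ("species", "stand", "point", "doy", "iflav")
               if c not in records.columns]
    if missing:
        raise ValueError(f"I_flav records missing columns: {missing}")
    if (records["iflav"] < 0).any():
        raise ValueError("I_flav must be >= 0")
    n_high = int((records["iflav"] > IFLAV_FLAG_THRESHOLD).sum())
    if n_high:
        logger.warning("%d I_flav records exceed %.1f (outside the usual optical range)",
                       n_high, IFLAV_FLAG_THRESHOLD)
    return records


def validate_abundances(abundances: pd.DataFrame, tol: float = 1e-9) -> pd.DataFrame:
    """Relative abundances: >= 0 and summing to 1 per (stand, point)."""
    missing = [c for c in ("stand", "point", "species", "rel_abundance")
               if c not in abundances.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    if (abundances["rel_abundance"] < 0).any():
        raise ValueError("relative abundances must be >= 0")
    sums = abundances.groupby(["stand", "point"])["rel_abundance"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(f"abundances do not sum to 1 at: {list(bad.index)}")
    return abundances


def community_weighted_mean(records: pd.DataFrame, abundances: pd.DataFrame,
                            stand, point, doy, leaf_side: str | None = None) -> float:
    """CWM of I_flav at one measurement point and date.

    CWM = Σ_s p̃_s · mean(I_flav of species s), with weights p̃_s the
    point's relative abundances renormalised over the species measured on
    that date.
    """
    sel = records[(records["stand"] == stand) & (records["point"] == point)
                  & (records["doy"] == doy)]
    if leaf_side is not None and "leaf_side" in sel.columns:
        sel = sel[sel["leaf_side"] == leaf_side]
    species_means = sel.groupby("species")["iflav"].mean()
    ab = abundances[(abundances["stand"] == stand) & (abundances["point"] == point)]
    weights = ab.set_index("species")["rel_abundance"]
    common = species_means.index.intersection(weights.index)
    if len(common) == 0:
        raise ValueError(
            f"no overlap between measured species and the abundance table at "
            f"stand={stand!r} point={point!r} doy={doy}"
        )
    w = weights.loc[common]
    total = w.sum()
    if total <= 0:
        raise ValueError("measured species all have zero abundance")
    return float((species_means.loc[common] * (w / total)).sum())


def cwm_table(records: pd.DataFrame, abundances: pd.DataFrame,
              leaf_side: str | None = None) -> pd.DataFrame:
    """CWM per stand × point × DOY (skipping cells with no species overlap)."""
    validate_records(records)
    validate_abundances(abundances)
    rows = []
    for (stand, point, doy), _ in records.groupby(["stand", "point", "doy"]):
        try:
            value = community_weighted_mean(records, abundances, stand, point, doy,
                                            leaf_side)
        except ValueError:
            continue
        rows.append({"stand": stand, "point": point, "doy": doy, "cwm_iflav": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def anova_by_doy(records: pd.DataFrame, value: str = "iflav",
                 group: str = "stand") -> pd.DataFrame:
    """One-way fixed-effects ANOVA of ``value`` across ``group`` for each DOY.

    DOYs with fewer than 2 groups of >= 2 observations, or with zero
    within-group variance, give null rows with a reason code.
    """
    rows = []
    for doy, sub in records.groupby("doy"):
        samples = [g[value].to_numpy(dtype=float)
                   for _, g in sub.groupby(group) if len(g) >= 2]
        row = {"doy": doy, "n_groups": len(samples), "F": np.nan,
               "df_between": np.nan, "df_within": np.nan, "p": np.nan,
               "reason": ""}
        if len(samples) < 2:
            row["reason"] = "fewer than 2 groups with >= 2 observations"
        else:
            n = sum(len(s) for s in samples)
            k = len(samples)
            grand = np.concatenate(samples).mean()
            ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
            ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
            df_b, df_w = k - 1, n - k
            if ss_within <= 0:
                if ss_between <= 0:
                    row["reason"] = "zero variance within and between groups"
                else:
                    row.update(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
            else:
                f = (ss_between / df_b) / (ss_within / df_w)
                row.update(F=f, df_between=df_b, df_within=df_w,
                           p=float(stats.f.sf(f, df_b, df_w)))
        rows.append(row)
    return pd.DataFrame(rows)


def two_sample_compare(x, y, method: str = "t", equal_var: bool = False,
                       paired: bool = False) -> tuple[float, float]:
    """Two-sample comparison: Student/Welch t or Wilcoxon rank-sum.

    Returns ``(statistic, two_sided_p)``.  The rank-sum test uses exact
    enumeration for samples of <= 20 without ties and the tie-corrected
    normal approximation otherwise.  If every value in both samples is
    identical, (0, 1) is returned by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.info("all values tied across both samples; returning p = 1")
        return 0.0, 1.0
    if method == "t":
        if paired:
            res = stats.ttest_rel(x, y)
        else:
            res = stats.ttest_ind(x, y, equal_var=equal_var)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        small = max(x.size, y.size) <= 20
        has_ties = np.unique(pooled).size < pooled.size
        how = "exact" if small and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=how)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; use 't' or 'wilcoxon'")
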