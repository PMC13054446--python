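"""Cohort-level aggregation and rank-based comparisons.

Aggregates the master single-cell table (one row per called
IgG-secreting cell) into per-(organ, age) summaries: counts, specific
fraction, mean K_D and secretion rate, and low/medium/high affinity
class proportions; pools affinities into the three age groups used for
the longitudinal comparison (6-12, 23-35 and 54-87 weeks).

Inference is deliberately plain plumbing: Mann-Whitney rank-sum tests
between consecutive timepoints and a Kruskal-Wallis test across age
groups with Dunn's pairwise follow-up (Bonferroni-adjusted), two-sided
at alpha = 0.05.  Dunn's test is implemented here (rank-based z
statistics with tie correction) since no installed package provides it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import AFFINITY_HIGH, AFFINITY_LOW, AFFINITY_MEDIUM

__all__ = [
    "AGE_GROUPS_WEEKS",
    "CohortSummary",
    "summarize",
    "compare_timepoints",
    "kruskal_dunn",
    "screened_fraction_percent",
]


def screened_fraction_percent(n_analyzed: float, n_organ_cells: float) -> float:
    """Fraction of an organ screened per acquisition, as a percentage.

    One acquisition analyzes the cells held in 1-2-cell droplets
    (~20,000 of 60,000-80,000 droplets); against an organ of ~30
    million cells that is a 0.07% sample.
    """
    if n_organ_cells <= 0:
        raise ValueError("n_organ_cells must be > 0")
    return 100.0 * n_analyzed / n_organ_cells

#: pooled age groups (weeks, inclusive bounds) for the affinity comparison
AGE_GROUPS_WEEKS = ((6.0, 12.0), (23.0, 35.0), (54.0, 87.0))

KD_FLOOR_NM = 0.01  # 10 pM: extrapolated affinities are floored here


@dataclass
class CohortSummary:
    per_stratum: pd.DataFrame  # one row per (organ, age_weeks)
    age_group_kd_nm: dict = field(default_factory=dict)  # label -> array
    totals: dict = field(default_factory=dict)


def _floored_kd_nm(df: pd.DataFrame) -> pd.Series:
    return df["kd_nm"].clip(lower=KD_FLOOR_NM)


def summarize(records: pd.DataFrame, geometric_mean: bool = False) -> CohortSummary:
    """Aggregate the master table into per-stratum summaries.

    Expects columns: organ, age_weeks, secretion_rate, kd_nm, kd_flag,
    is_gpi_specific, affinity_class.  Censored values contribute at
    their censored value; extrapolated affinities are floored at 10 pM.
    Mean affinity is arithmetic on the nM scale by default, with a
    geometric-mean option.  Empty strata are simply absent.
    """
    required = {"organ", "age_weeks", "secretion_rate", "kd_nm", "is_gpi_specific"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"master table lacks columns: {sorted(missing)}")

    rows = []
    for (organ, age), grp in records.groupby(["organ", "age_weeks"], sort=True):
        spec = grp[grp["is_gpi_specific"].astype(bool)]
        kd = _floored_kd_nm(spec).dropna()
        if geometric_mean and len(kd):
            mean_kd = float(np.exp(np.mean(np.log(kd))))
        else:
            mean_kd = float(kd.mean()) if len(kd) else float("nan")
        n_spec = int(len(spec))
        props = {c: float("nan") for c in (AFFINITY_LOW, AFFINITY_MEDIUM, AFFINITY_HIGH)}
        if n_spec and "affinity_class" in grp.columns:
            counts = spec["affinity_class"].value_counts()
            for c in props:
                props[c] = float(counts.get(c, 0)) / n_spec
        rows.append(
            {
                "organ": organ,
                "age_weeks": age,
                "n_igg_sc": int(len(grp)),
                "n_gpi_specific": n_spec,
                "percent_specific": 100.0 * n_spec / len(grp) if len(grp) else float("nan"),
                "mean_kd_nm": mean_kd,
                "mean_secretion_rate": float(grp["secretion_rate"].mean()),
                "prop_low": props[AFFINITY_LOW],
                "prop_medium": props[AFFINITY_MEDIUM],
                "prop_high": props[AFFINITY_HIGH],
            }
        )
    per_stratum = pd.DataFrame(rows)

    spec_all = records[records["is_gpi_specific"].astype(bool)]
    age_group_kd = {}
    for lo, hi in AGE_GROUPS_WEEKS:
        sel = spec_all[(spec_all["age_weeks"] >= lo) & (spec_all["age_weeks"] <= hi)]
        if len(sel):
            age_group_kd[f"{lo:g}-{hi:g}w"] = _floored_kd_nm(sel).to_numpy()

    totals = {
        "n_igg_sc": int(len(records)),
        "n_gpi_specific": int(len(spec_all)),
    }
    if len(spec_all):
        totals["percent_low_affinity"] = float(
            100.0 * (spec_all["affinity_class"] == AFFINITY_LOW).mean()
        )
        totals["percent_high_affinity"] = float(
            100.0 * (spec_all["affinity_class"] == AFFINITY_HIGH).mean()
        )
        totals["mean_kd_nm"] = float(_floored_kd_nm(spec_all).mean())
    return CohortSummary(per_stratum=per_stratum, age_group_kd_nm=age_group_kd, totals=totals)


def compare_timepoints(
    records: pd.DataFrame,
    value_col: str,
    time_col: str = "age_weeks",
    min_n: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney tests between consecutive timepoints.

    Strata with fewer than ``min_n`` values are skipped with a notice
    row (statistic and p set to NaN, skipped=True).
    """
    out = []
    times = sorted(records[time_col].dropna().unique())
    for t1, t2 in zip(times[:-1], times[1:]):
        a = records.loc[records[time_col] == t1, value_col].dropna().to_numpy()
        b = records.loc[records[time_col] == t2, value_col].dropna().to_numpy()
        if len(a) < min_n or len(b) < min_n:
            out.append(
                {
                    "time_a": t1, "time_b": t2, "n_a": len(a), "n_b": len(b),
                    "statistic": float("nan"), "p_value": float("nan"),
                    "significant": False, "skipped": True,
                }
            )
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append(
            {
                "time_a": t1, "time_b": t2, "n_a": len(a), "n_b": len(b),
                "statistic": float(res.statistic), "p_value": float(res.pvalue),
                "significant": bool(res.pvalue <= alpha), "skipped": False,
            }
        )
    return pd.DataFrame(out)


def kruskal_dunn(groups: dict, alpha: float = 0.05):
    """Kruskal-Wallis across groups with Dunn's pairwise follow-up.

    ``groups`` maps label -> 1D array.  Dunn's z statistic for groups i,
    j uses the pooled mean ranks with the standard tie correction;
    p-values are two-sided normal tails, Bonferroni-adjusted over all
    pairs.  Returns (kw_result_dict, pairwise DataFrame); groups with
    fewer than 3 observations are dropped with a notice entry.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 3}
    skipped = sorted(set(groups) - set(usable))
    if len(usable) < 2:
        return {"statistic": float("nan"), "p_value": float("nan"), "skipped_groups": skipped}, pd.DataFrame()

    labels = sorted(usable)
    samples = [usable[k] for k in labels]
    kw = stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for lab, s in zip(labels, samples):
        mean_ranks[lab] = float(ranks[start : start + len(s)].mean())
        start += len(s)

    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        na, nb = len(usable[a]), len(usable[b])
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group_a": a, "group_b": b, "z": float(z),
                "p_value": float(p), "p_adjusted": float(p_adj),
                "significant": bool(p_adj <= alpha),
            }
        )
    kw_out = {
        "statistic": float(kw.statistic),
        "p_value": float(kw.pvalue),
        "skipped_groups": skipped,
    }
    return kw_out, pd.DataFrame(rows)
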