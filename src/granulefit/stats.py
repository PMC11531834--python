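"""Per-phenotype genotype comparisons.

One-way fixed-effects ANOVA followed by Tukey-adjusted all-pairs contrasts
with confidence intervals on the difference of means.  Unbalanced groups use
the Tukey–Kramer form (1/n_a + 1/n_b pairing).  No correction is applied
across phenotypes — adjustment is within each phenotype's pairwise family
only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "AnovaResult",
    "ComparisonResult",
    "anova_oneway",
    "tukey_pairwise",
    "run_comparisons",
]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_resid: int
    ms_between: float
    mse: float
    group_means: Dict[str, float]
    group_sizes: Dict[str, int]


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise contrast: difference of means with 95% CI and adjusted p."""

    phenotype: str
    group_a: str
    group_b: str
    diff_means: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    df_resid: int
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.diff_means <= self.ci_high):
            raise ValueError("CI must bracket the difference of means")
        if not (0.0 <= self.p_adjusted <= 1.0 or math.isnan(self.p_adjusted)):
            raise ValueError("p_adjusted outside [0, 1]")


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size:
            out[str(name)] = arr
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard one-way fixed-effects decomposition; F = MS_between/MS_within.

    Constant data (zero within- and between-group variance) yields
    ``F = nan`` rather than an error.
    """
    groups = _clean_groups(groups)
    k = len(groups)
    if k < 2:
        raise ValueError(f"need >= 2 non-empty groups, got {k}")
    n_total = sum(a.size for a in groups.values())
    df_resid = n_total - k
    if df_resid < 1:
        raise ValueError("zero residual degrees of freedom")
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in groups.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in groups.values())
    ms_between = ss_between / (k - 1)
    mse = ss_within / df_resid
    if mse == 0.0:
        f_stat = math.nan if ms_between == 0.0 else math.inf
        p = math.nan if ms_between == 0.0 else 0.0
    else:
        f_stat = ms_between / mse
        p = float(f_dist.sf(f_stat, k - 1, df_resid))
    return AnovaResult(
        f=float(f_stat), p=p, df_between=k - 1, df_resid=df_resid,
        ms_between=float(ms_between), mse=float(mse),
        group_means={g: float(a.mean()) for g, a in groups.items()},
        group_sizes={g: int(a.size) for g, a in groups.items()},
    )


def tukey_pairwise(groups: Mapping[str, Sequence[float]],
                   conf: float = 0.95,
                   phenotype: str = "") -> List[ComparisonResult]:
    """All unordered pairwise contrasts with Tukey HSD adjustment.

    CI half-width is (q/√2)·√(mse·(1/n_a + 1/n_b)) with q the 1−α quantile
    of the studentized range for k groups and the ANOVA residual df;
    p_adjusted is the studentized-range tail probability at the observed
    statistic.  For k = 2 this reduces exactly to the pooled two-sample t
    procedure.
    """
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    groups = _clean_groups(groups)
    anova = anova_oneway(groups)
    k = len(groups)
    df = anova.df_resid
    q_crit = float(studentized_range.ppf(conf, k, df))
    results = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        a, b = groups[ga], groups[gb]
        diff = float(a.mean() - b.mean())
        se = math.sqrt(anova.mse * (1.0 / a.size + 1.0 / b.size))
        half = q_crit / math.sqrt(2.0) * se
        if se > 0:
            q_obs = abs(diff) / (se / math.sqrt(2.0))
            p_adj = float(studentized_range.sf(q_obs, k, df))
        else:
            p_adj = math.nan if diff == 0 else 0.0
        results.append(ComparisonResult(
            phenotype=phenotype, group_a=ga, group_b=gb, diff_means=diff,
            ci_low=diff - half, ci_high=diff + half,
            p_adjusted=min(max(p_adj, 0.0), 1.0) if not math.isnan(p_adj) else p_adj,
            df_resid=df, n_a=int(a.size), n_b=int(b.size)))
    return results


def run_comparisons(table: pd.DataFrame,
                    phenotypes: Sequence[str],
                    group_col: str = "genotype",
                    stratify_by: Optional[str] = None,
                    conf: float = 0.95) -> pd.DataFrame:
    """Tidy long table of ANOVA + Tukey contrasts per phenotype (× stratum).

    Each phenotype is analysed with its own linear model; strata (e.g. dpa
    time points) are analysed independently.  Empty or single-group strata
    are skipped (recorded in the table's ``attrs['skipped']``).
    """
    if group_col not in table.columns:
        raise ValueError(f"group column {group_col!r} not in table; "
                         f"available: {sorted(table.columns)}")
    missing = [p for p in phenotypes if p not in table.columns]
    if missing:
        raise ValueError(f"phenotype columns {missing} not in table; "
                         f"available: {sorted(table.columns)}")
    strata = [None]
    if stratify_by is not None:
        if stratify_by not in table.columns:
            raise ValueError(f"stratification column {stratify_by!r} not in table")
        strata = sorted(table[stratify_by].dropna().unique())

    rows = []
    skipped = []
    for pheno in phenotypes:
        for stratum in strata:
            sub = table if stratum is None else table[table[stratify_by] == stratum]
            groups = {g: s[pheno].dropna().to_numpy()
                      for g, s in sub.groupby(group_col)}
            groups = {g: v for g, v in groups.items() if v.size}
            label = "" if stratum is None else stratum
            if len(groups) < 2 or sum(v.size for v in groups.values()) - len(groups) < 1:
                skipped.append((pheno, label))
                continue
            anova = anova_oneway(groups)
            for c in tukey_pairwise(groups, conf=conf, phenotype=pheno):
                rows.append({
                    "phenotype": pheno, "stratum": label,
                    "group_a": c.group_a, "group_b": c.group_b,
                    "diff_means": c.diff_means, "ci_low": c.ci_low,
                    "ci_high": c.ci_high, "p_adjusted": c.p_adjusted,
                    "F": anova.f, "p_anova": anova.p,
                    "df_resid": c.df_resid,
                    "n_a": c.n_a, "n_b": c.n_b,
                })
    out = pd.DataFrame(rows, columns=[
        "phenotype", "stratum", "group_a", "group_b", "diff_means",
        "ci_low", "ci_high", "p_adjusted", "F", "p_anova", "df_resid",
        "n_a", "n_b"])
    out.attrs["skipped"] = skipped
    out.attrs["conf"] = conf
    return out
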