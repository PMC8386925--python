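"""Between-sex comparison of per-individual posterior medians.

The unit of analysis is the per-individual posterior *median* diet fraction
— pooling posterior draws across individuals would fabricate sample size —
and groups are compared with a two-sided Wilcoxon rank-sum test at the 0.05
level (exact distribution for small untied samples, normal approximation
with tie correction otherwise).  No multiple-testing correction is applied
by default; a Bonferroni flag exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diet_model.fit import DietPosterior, PERCENTILES
from .errors import DomainError

ALPHA = 0.05


def _mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a, with midranks for ties."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def _enumerated_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    Every C(n1+n2, n1) split of the pooled values is equally likely under
    the null; the two-sided p doubles the smaller tail of the U statistic
    (capped at 1), which coincides with the classical exact convention for
    untied data and extends it to ties via midranks.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    u_obs = _mannwhitney_u(a, b)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array([sum(c) - offset for c in combinations(ranks, n1)])
    tol = 1e-9
    lo = np.mean(us <= u_obs + tol)
    hi = np.mean(us >= u_obs - tol)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(group_a: Sequence[float],
                      group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (p, statistic).

    Small samples (combined n ≤ 12) use full enumeration of group
    assignments, which handles ties exactly; untied samples up to combined
    n = 25 use the exact null distribution; anything larger falls back to
    the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:  # all observations identical
        return 1.0, float(a.size * b.size / 2.0)
    n = a.size + b.size
    ties = len(np.unique(np.concatenate([a, b]))) < n
    if n <= 12:
        return _enumerated_p(a, b), _mannwhitney_u(a, b)
    if not ties and n <= 25:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(min(res.pvalue, 1.0)), float(res.statistic)


@dataclass
class CohortResult:
    """Cohort summary: per-individual percentiles, per-sex group summaries,
    and per-source Wilcoxon p-values on posterior medians."""

    individuals: pd.DataFrame     # sample_id, sex, source, percentiles
    group_summary: pd.DataFrame   # source × sex: mean/sd/n of medians
    tests: pd.DataFrame           # source: statistic, p, significant
    notices: list[str] = field(default_factory=list)


def summarize_cohort(posteriors: Sequence[DietPosterior],
                     sexes: Mapping[str, str] | None = None,
                     alpha: float = ALPHA,
                     bonferroni: bool = False) -> CohortResult:
    """Summarize a cohort of fitted individuals and test for sex differences.

    ``sexes`` maps sample_id to sex; if omitted each posterior's sample_id
    must be resolvable from the ``posteriors`` ordering by the caller.  With
    a single-sex cohort summaries are still produced and the tests are
    skipped with a notice.
    """
    if not posteriors:
        raise DomainError("no posteriors supplied")
    sexes = dict(sexes or {})
    rows = []
    for post in posteriors:
        sex = sexes.get(post.sample_id, None)
        for src in post.source_names:
            row = {"sample_id": post.sample_id, "sex": sex, "source": src}
            for p in PERCENTILES:
                key = format(p, "g")
                row[f"p{key}"] = float(post.percentile_table.loc[src, key])
            rows.append(row)
    indiv = pd.DataFrame(rows)
    if indiv["sex"].isna().any():
        by_id = {p.sample_id: getattr(p, "sex", None) for p in posteriors}
        indiv["sex"] = indiv.apply(
            lambda r: r["sex"] or by_id.get(r["sample_id"]) or "unknown", axis=1)
    return _summarize(indiv, alpha=alpha, bonferroni=bonferroni)


def cohort_from_percentiles(df: pd.DataFrame, alpha: float = ALPHA,
                            bonferroni: bool = False) -> CohortResult:
    """Cohort summary from a per-individual percentile table (the
    ``percentiles.csv`` written by the fit CLI: sample_id, sex, source,
    p2.5 ... p97.5)."""
    required = {"sample_id", "sex", "source", "p50"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"percentile table missing column(s): {sorted(missing)}")
    return _summarize(df.copy(), alpha=alpha, bonferroni=bonferroni)


def _summarize(indiv: pd.DataFrame, alpha: float,
               bonferroni: bool) -> CohortResult:
    indiv = indiv.sort_values(["source", "sample_id"],
                              kind="stable").reset_index(drop=True)
    med = indiv.pivot_table(index=["sample_id", "sex"], columns="source",
                            values="p50", sort=True)
    sources = sorted(indiv["source"].unique())
    grp_rows, test_rows, notices = [], [], []
    sex_levels = [s for s in ("male", "female") if s in set(indiv["sex"])]
    for src in sources:
        by_sex = {}
        for sex in sorted(set(indiv["sex"])):
            vals = med.xs(sex, level="sex")[src].dropna().to_numpy() \
                if sex in med.index.get_level_values("sex") else np.array([])
            by_sex[sex] = vals
            if len(vals):
                grp_rows.append({"source": src, "sex": sex,
                                 "mean": float(np.mean(vals)),
                                 "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                                 "n": int(len(vals))})
        if len(sex_levels) == 2:
            males, females = by_sex.get("male", []), by_sex.get("female", [])
            p, u = wilcoxon_rank_sum(males, females)
            thresh = alpha / len(sources) if bonferroni else alpha
            ratio = (float(np.mean(males) / np.mean(females))
                     if len(females) and np.mean(females) != 0 else float("nan"))
            test_rows.append({"source": src, "statistic": u, "p": p,
                              "male_female_ratio": ratio,
                              "significant": p < thresh})
    if len(sex_levels) < 2:
        notices.append("single-sex cohort: between-sex tests skipped")
    tests = pd.DataFrame(test_rows, columns=["source", "statistic", "p",
                                             "male_female_ratio", "significant"])
    group = pd.DataFrame(grp_rows, columns=["source", "sex", "mean", "sd", "n"])
    return CohortResult(indiv, group, tests, notices)
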