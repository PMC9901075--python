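"""Longitudinal statistics on vessel-density records.

Implements the comparisons a 1-year repeated-measures vessel-density study
needs: one-way within-subjects (repeated-measures) ANOVA across visits with
Bonferroni-corrected paired post-hoc tests, the Mann–Whitney U test (a.k.a.
Wilcoxon rank-sum) for independent groups, the Wilcoxon signed-rank test for
paired differences, Fisher's exact test on 2×2 tables, and the per-cell
no-DR-minus-DR group-difference table.

Exact null distributions are enumerated for small samples (Mann–Whitney for
n_a + n_b <= 12, signed-rank for n <= 15); otherwise tie-corrected normal
approximations with continuity correction are used.  All tests are
two-sided; two-sided p-values are defined through the permutation /
enumeration convention ``P(|T - E[T]| >= |t_obs - E[T]|)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .perfusion import Slab
from .synthetic import LongitudinalCohort

_EPS = 1e-12

EXACT_MWU_MAX_N = 12
EXACT_WILCOXON_MAX_N = 15


class StatsError(ValueError):
    pass


class AllZeroDifferencesError(StatsError):
    """Every paired difference is zero; the signed-rank test is undefined."""


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmAnovaResult:
    """One-way within-subjects ANOVA summary.

    ``posthoc`` maps timepoint pairs (i, j) to Bonferroni-adjusted paired-t
    p-values (raw p multiplied by the number of pairs, capped at 1).
    """

    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    posthoc: dict[tuple[int, int], float] = field(default_factory=dict)
    posthoc_raw: dict[tuple[int, int], float] = field(default_factory=dict)
    n_subjects: int = 0
    n_timepoints: int = 0
    n_dropped: int = 0
    degenerate: bool = False
    gg_epsilon: float | None = None


def _gg_epsilon(panel: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity epsilon from the sample covariance."""
    t = panel.shape[1]
    s = np.cov(panel, rowvar=False)
    centered = (s - s.mean(axis=0, keepdims=True)
                - s.mean(axis=1, keepdims=True) + s.mean())
    num = np.trace(centered) ** 2
    den = (t - 1) * np.sum(centered * centered)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (t - 1), 1.0))


def rm_anova(panel: np.ndarray | pd.DataFrame,
             greenhouse_geisser: bool = False) -> RmAnovaResult:
    """One-way repeated-measures ANOVA (subjects × timepoints).

    Rows with any missing value are dropped listwise (count reported).
    Sphericity is assumed by default; ``greenhouse_geisser=True`` scales both
    degrees of freedom by the GG epsilon.
    """
    data = np.asarray(panel, dtype=float)
    if data.ndim != 2:
        raise StatsError("panel must be 2-D (subjects × timepoints)")
    complete = ~np.isnan(data).any(axis=1)
    dropped = int((~complete).sum())
    data = data[complete]
    n, t = data.shape
    if t < 2:
        raise StatsError("need >= 2 timepoints")
    if n < 3:
        raise StatsError("need >= 3 complete subjects")

    grand = data.mean()
    ss_total = float(((data - grand) ** 2).sum())
    ss_subject = float(t * ((data.mean(axis=1) - grand) ** 2).sum())
    ss_time = float(n * ((data.mean(axis=0) - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_time, 0.0)

    df_num = float(t - 1)
    df_den = float((n - 1) * (t - 1))
    ms_time = ss_time / df_num
    ms_error = ss_error / df_den

    eps: float | None = None
    degenerate = False
    # guard against pure rounding residue masquerading as signal
    tiny = _EPS * max(ss_total, 1.0)
    if ms_error <= tiny:
        if ms_time <= tiny:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = ms_time / ms_error
        if greenhouse_geisser:
            eps = _gg_epsilon(data)
            p = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
        else:
            p = float(sps.f.sf(f_stat, df_num, df_den))

    pairs = list(combinations(range(t), 2))
    raw: dict[tuple[int, int], float] = {}
    adj: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        diff = data[:, i] - data[:, j]
        if np.allclose(diff, diff[0]):
            p_pair = 1.0 if abs(diff.mean()) <= _EPS else 0.0
        else:
            p_pair = float(sps.ttest_rel(data[:, i], data[:, j]).pvalue)
        raw[(i, j)] = p_pair
        adj[(i, j)] = min(1.0, p_pair * len(pairs))

    return RmAnovaResult(f_statistic=f_stat, df_num=df_num, df_den=df_den,
                         p_value=p, posthoc=adj, posthoc_raw=raw,
                         n_subjects=n, n_timepoints=t, n_dropped=dropped,
                         degenerate=degenerate, gg_epsilon=eps)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def mann_whitney_u(group_a, group_b,
                   method: str = "auto") -> tuple[float, float]:
    """Mann–Whitney U (Wilcoxon rank-sum) test, two-sided.

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first
    group.  ``method`` is 'exact', 'approx' or 'auto' (exact permutation
    enumeration whenever n_a + n_b <= 12; midranks handle ties in both
    branches).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0

    if method == "auto":
        method = "exact" if na + nb <= EXACT_MWU_MAX_N else "approx"

    if method == "exact":
        obs_dev = abs(u_a - mu)
        hits = total = 0
        for idx in combinations(range(na + nb), na):
            r = ranks[list(idx)].sum() - na * (na + 1) / 2.0
            total += 1
            if abs(r - mu) >= obs_dev - _EPS:
                hits += 1
        return u_a, hits / total

    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_a, 1.0
    dev = abs(u_a - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    return u_a, float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_signed_rank(differences,
                         method: str = "auto") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences, two-sided.

    Zeros are dropped; tied magnitudes get midranks; ``W = min(W+, W-)``.
    Exact enumeration of all sign assignments for n <= 15, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise AllZeroDifferencesError(
            "all paired differences are zero; no signed-rank test possible")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)

    if method == "auto":
        method = "exact" if n <= EXACT_WILCOXON_MAX_N else "approx"

    if method == "exact":
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        obs_dev = abs(w_plus - total / 2.0)
        p = float(np.mean(np.abs(sums - total / 2.0) >= obs_dev - _EPS))
        return w, min(1.0, p)

    mu = total / 2.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = (n * (n + 1) * (2 * n + 1)) / 24.0 \
        - float((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return w, 1.0
    dev = abs(w_plus - mu)
    z = max(dev - 0.5, 0.0) / math.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(z)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.  A zero
    margin makes every admissible table certain, so p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise StatsError("table must be 2×2 non-negative integers")
    t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or (b + d) == 0 or (c + d) == 0:
        return 1.0
    dist = sps.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 - (n - c1)), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# group-difference table
# ---------------------------------------------------------------------------

TABLE_SECTORS = ("superior", "temporal", "inferior", "nasal", "mean")


def group_difference_table(cohort: LongitudinalCohort,
                           alpha: float = 0.05,
                           bonferroni_cells: bool = False) -> pd.DataFrame:
    """Per slab × visit × sector no-DR-minus-DR mean difference with p.

    Cells are tested with the Mann–Whitney U test (the rank test the study
    design calls for between independent DR / no-DR groups).  By default no
    multiplicity correction is applied across cells; ``bonferroni_cells``
    multiplies every cell p by the number of tested cells.
    """
    df = cohort.data
    rows = []
    for slab in (Slab.SCP, Slab.DCP):
        sub_slab = df[df["slab"] == slab.value]
        for visit in cohort.visits:
            sub_visit = sub_slab[sub_slab["visit"] == visit]
            for sector in TABLE_SECTORS:
                if sector == "mean":
                    cell = (sub_visit.groupby(["eye_id", "group"],
                                              as_index=False)["pvd"].mean())
                else:
                    cell = sub_visit[sub_visit["sector"] == sector]
                no_dr = cell.loc[cell["group"] == "no-DR", "pvd"].to_numpy()
                dr = cell.loc[cell["group"] == "DR", "pvd"].to_numpy()
                if no_dr.size == 0 or dr.size == 0:
                    rows.append((slab.value, visit, sector, float("nan"),
                                 float("nan"), False))
                    continue
                diff = float(no_dr.mean() - dr.mean())
                _, p = mann_whitney_u(no_dr, dr)
                rows.append((slab.value, visit, sector, diff, p, None))
    out = pd.DataFrame(rows, columns=["slab", "visit", "sector",
                                      "difference", "p_value", "significant"])
    if bonferroni_cells:
        n_cells = out["p_value"].notna().sum()
        out["p_value"] = (out["p_value"] * n_cells).clip(upper=1.0)
    out["significant"] = out["p_value"] < alpha
    return out


def format_difference_table(table: pd.DataFrame,
                            float_fmt: str = "{:+.3f}") -> str:
    """Render the group-difference table with visits as rows and
    slab × sector columns; significant cells are starred."""
    lines = []
    slabs = list(dict.fromkeys(table["slab"]))
    visits = list(dict.fromkeys(table["visit"]))
    header = ["visit"] + [f"{s}:{sec[:4]}" for s in slabs
                          for sec in TABLE_SECTORS]
    lines.append("  ".join(f"{h:>10}" for h in header))
    for visit in visits:
        cells = [f"{visit:>10}"]
        for slab in slabs:
            for sector in TABLE_SECTORS:
                row = table[(table["slab"] == slab)
                            & (table["visit"] == visit)
                            & (table["sector"] == sector)]
                if row.empty or np.isnan(row["difference"].iloc[0]):
                    cells.append(f"{'--':>10}")
                else:
                    txt = float_fmt.format(row["difference"].iloc[0])
                    if bool(row["significant"].iloc[0]):
                        txt += "*"
                    cells.append(f"{txt:>10}")
        lines.append("  ".join(cells))
    lines.append("difference = mean(no-DR) - mean(DR); * p < alpha "
                 "(Mann-Whitney U)")
    return "\n".join(lines)
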