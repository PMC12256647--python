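"""Group-comparison statistics: Welch's t, Mann–Whitney U, KS,
Kruskal–Wallis with Dunn's post hoc, one-way ANOVA with Tukey's HSD, and
mean ± SEM descriptives with t-based 95% confidence intervals.

All p-values are two-sided. Ties are handled with midranks and the usual
variance tie-corrections for the rank tests. Post hoc families: Dunn with
Bonferroni adjustment after Kruskal–Wallis; Tukey's HSD after ANOVA.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupDescriptives",
    "two_sample_test",
    "multi_group_test",
    "describe_group",
]

GroupDescriptives = namedtuple("GroupDescriptives", ["n", "mean", "sem", "ci95_low", "ci95_high"])


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with optional post hoc table."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    posthoc: list[dict] = field(default_factory=list)
    descriptives: dict[str, GroupDescriptives] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "posthoc": self.posthoc,
            "descriptives": {k: v._asdict() for k, v in self.descriptives.items()},
            "meta": self.meta,
        }


def describe_group(x) -> GroupDescriptives:
    """n, mean, SEM = SD/√n, and t-based 95% CI = mean ± t(0.975, n−1)·SEM."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("descriptives require n >= 2")
    n = x.size
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return GroupDescriptives(n, mean, sem, mean - tcrit * sem, mean + tcrit * sem)


def _welch(x: np.ndarray, y: np.ndarray) -> TestResult:
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate contract: both samples constant
        if x.mean() == y.mean():
            return TestResult("welch_t", 0.0, 1.0, df=float(len(x) + len(y) - 2))
        return TestResult("welch_t", float("inf"), 0.0, df=float(len(x) + len(y) - 2))
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue), df=float(res.df))


def two_sample_test(x, y, method: str = "welch") -> TestResult:
    """Two-sample comparison.

    ``welch``: unequal-variance t with Welch–Satterthwaite df (p = 1 when
    both samples are constant and equal). ``mannwhitney``: exact two-sided p
    when n_x + n_y <= 12 and the pooled sample is tie-free, otherwise the
    normal approximation with midranks and tie correction. ``ks``:
    two-sample sup-distance with asymptotic p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if method == "welch":
        if x.size < 2 or y.size < 2:
            raise ValueError("Welch's t requires n >= 2 per sample")
        return _welch(x, y)
    if method == "mannwhitney":
        pooled = np.concatenate([x, y])
        exact = x.size + y.size <= 12 and np.unique(pooled).size == pooled.size
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return TestResult(
            "mann_whitney_u",
            float(res.statistic),
            float(res.pvalue),
            meta={"method": "exact" if exact else "normal_approx_tie_corrected"},
        )
    if method == "ks":
        res = sps.ks_2samp(x, y, method="asymp")
        return TestResult("ks_2samp", float(res.statistic), float(min(res.pvalue, 1.0)))
    raise ValueError(f"unknown two-sample method {method!r}")


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> list[dict]:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment.

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − T) (1/n_i + 1/n_j) ),
    with midranks over the pooled sample and the tie term
    T = Σ(t³ − t) / (12(N − 1)).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append(
            {
                "comparison": f"{a} vs {b}",
                "statistic": float(z),
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * m)),
            }
        )
    return out


def multi_group_test(
    groups: dict[str, list | np.ndarray],
    method: str = "kruskal",
    posthoc: str | None = None,
) -> TestResult:
    """Omnibus comparison of >= 3 groups with all-pairs post hoc.

    ``kruskal`` pairs with Dunn's test (Bonferroni family-wise adjustment);
    ``anova`` (one-way) pairs with Tukey's HSD. Mixing families
    (e.g. kruskal + tukey) is an error.
    """
    arrays = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 3:
        raise ValueError("multi-group test requires >= 3 groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    if posthoc is None:
        posthoc = "dunn" if method == "kruskal" else "tukey"
    if (method, posthoc) not in {("kruskal", "dunn"), ("anova", "tukey")}:
        raise ValueError(f"incompatible method/posthoc pair: {method}/{posthoc}")

    values = list(arrays.values())
    descriptives = {k: describe_group(v) for k, v in arrays.items()}
    if method == "kruskal":
        h, p = sps.kruskal(*values)
        result = TestResult(
            "kruskal_wallis",
            float(h),
            float(p),
            df=float(len(arrays) - 1),
            posthoc=_dunn_posthoc(arrays),
            descriptives=descriptives,
            meta={"posthoc": "dunn_bonferroni"},
        )
    else:
        f, p = sps.f_oneway(*values)
        tukey = sps.tukey_hsd(*values)
        labels = list(arrays)
        pairs = []
        for i, j in itertools.combinations(range(len(labels)), 2):
            pairs.append(
                {
                    "comparison": f"{labels[i]} vs {labels[j]}",
                    "statistic": float(tukey.statistic[i, j]),
                    "p_adjusted": float(tukey.pvalue[i, j]),
                }
            )
        df1 = len(arrays) - 1
        df2 = sum(v.size for v in values) - len(arrays)
        result = TestResult(
            "one_way_anova",
            float(f),
            float(p),
            df=float(df1),
            posthoc=pairs,
            descriptives=descriptives,
            meta={"posthoc": "tukey_hsd", "df_within": df2},
        )
    return result
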