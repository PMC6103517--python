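"""Statistical comparisons: Welch and paired t-tests, OLS fits, genotype pooling.

All tests are two-tailed and raw p-values are reported without
multiple-testing correction, so users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    t: float
    df: float
    p: float
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    test: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def welch_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> StatResult:
    """Welch two-sample t-test from summary statistics.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2), df by Welch–Satterthwaite,
    two-tailed p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("standard deviations must be nonnegative and not both zero")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return StatResult(float(t), float(df), float(p), (m1, m2), (s1, s2), (n1, n2), "welch_t")


def welch_t_samples(a, b) -> StatResult:
    """Welch t-test from raw samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return welch_t(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def paired_t(values_a, values_b) -> StatResult:
    """Paired (one-sample-on-differences) t-test, two-tailed.

    A constant nonzero difference with zero spread has an undefined
    (infinite) t and is rejected rather than silently returning p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0 and diff.mean() != 0:
        raise ValueError("constant nonzero differences: t is infinite")
    if np.std(diff, ddof=1) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    return StatResult(
        float(t), float(len(a) - 1), float(p),
        (float(a.mean()), float(b.mean())),
        (float(a.std(ddof=1)), float(b.std(ddof=1))),
        (len(a), len(b)), "paired_t",
    )


def linear_fit(x, y) -> dict:
    """Ordinary least squares y = a + b·x with R² and the slope-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 matched observations")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
        "p": float(res.pvalue),
        "n": len(x),
    }


def pool_and_compare(
    groups: dict[str, np.ndarray], pooling: dict[str, str]
) -> dict:
    """Pool per-embryo values by genotype group and Welch-test the pools.

    ``pooling`` maps every genotype to exactly one of two pool labels.  The
    result carries the between-pool Welch test, the pooled means, and all
    within-pool pairwise Welch tests (the check that no genotype inside a
    pool differs from its poolmates).
    """
    pools: dict[str, list] = {}
    members: dict[str, list[str]] = {}
    for geno, values in groups.items():
        if geno not in pooling:
            raise ValueError(f"genotype {geno!r} is not mapped to a pool")
        lab = pooling[geno]
        pools.setdefault(lab, []).extend(np.asarray(values, dtype=float))
        members.setdefault(lab, []).append(geno)
    if len(pools) != 2:
        raise ValueError(f"expected exactly two pools, got {sorted(pools)}")
    labels = sorted(pools)
    arrs = {lab: np.asarray(v) for lab, v in pools.items()}
    for lab, arr in arrs.items():
        if arr.size == 0:
            raise ValueError(f"pool {lab!r} is empty")
    between = welch_t_samples(arrs[labels[0]], arrs[labels[1]])
    within = {}
    for lab in labels:
        for i, g1 in enumerate(members[lab]):
            for g2 in members[lab][i + 1:]:
                if len(groups[g1]) >= 2 and len(groups[g2]) >= 2:
                    within[f"{g1} vs {g2}"] = welch_t_samples(groups[g1], groups[g2])
    return {
        "pools": labels,
        "pooled_means": {lab: float(arrs[lab].mean()) for lab in labels},
        "pooled_sds": {lab: float(arrs[lab].std(ddof=1)) for lab in labels},
        "pooled_ns": {lab: int(arrs[lab].size) for lab in labels},
        "between": between,
        "within": within,
    }
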