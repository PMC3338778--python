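"""Group comparison machinery: mean +/- SEM, t-tests, Dunnett many-to-one.

The unpaired test is the classical pooled-variance Student t (Welch available
behind a flag); it can be computed either from raw samples or from
(n, mean, SEM) summaries, and the two routes agree algebraically.  Dunnett's
many-to-one procedure compares every group against a single control with
familywise adjustment obtained by Monte-Carlo simulation of the joint null
distribution of the correlated t statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SummaryStat",
    "TestResult",
    "mean_sem",
    "t_test",
    "t_test_from_summary",
    "dunnett",
]


@dataclass(frozen=True)
class SummaryStat:
    """Sample size, mean and standard error of the mean."""

    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2 for the SEM to be defined")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    adjusted: bool
    method: str
    contrast: str | None = None


def mean_sem(values: Sequence[float]) -> SummaryStat:
    """Mean and sd/sqrt(n) of a sample (n >= 2)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    return SummaryStat(
        n=int(arr.size),
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(arr.size)),
    )


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    equal_var: bool = True,
) -> TestResult:
    """Two-tailed Student's t-test.

    Unpaired tests pool the variance by default (``equal_var=False`` gives
    Welch).  Degenerate data with zero variance and equal means report p = 1.
    """
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        if x.size < 2:
            raise ValueError("paired test requires n >= 2")
        d = x - y
        sd = d.std(ddof=1)
        df = x.size - 1
        if sd == 0:
            t = 0.0 if d.mean() == 0 else math.inf * math.copysign(1, d.mean())
            return TestResult(t, df, 1.0 if t == 0 else 0.0, False, "paired t")
        t = float(d.mean() / (sd / math.sqrt(x.size)))
        return TestResult(t, float(df), _two_tailed_p(t, df), False, "paired t")

    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired test requires n >= 2 in each sample")
    if equal_var:
        return t_test_from_summary(mean_sem(x), mean_sem(y))
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    if se2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf
        return TestResult(t, float(x.size + y.size - 2), 1.0 if t == 0 else 0.0,
                          False, "welch t")
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return TestResult(t, float(df), _two_tailed_p(t, df), False, "welch t")


def t_test_from_summary(s1: SummaryStat, s2: SummaryStat) -> TestResult:
    """Pooled-variance two-tailed t from (n, mean, SEM) summaries.

    Algebraically identical to :func:`t_test` on raw data with those
    summaries.
    """
    n1, n2 = s1.n, s2.n
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * s1.sd**2 + (n2 - 1) * s2.sd**2) / df
    se2 = pooled_var * (1.0 / n1 + 1.0 / n2)
    if se2 == 0:
        equal = s1.mean == s2.mean
        return TestResult(
            0.0 if equal else math.inf, float(df), 1.0 if equal else 0.0,
            False, "unpaired t (pooled)",
        )
    t = float((s1.mean - s2.mean) / math.sqrt(se2))
    return TestResult(t, float(df), _two_tailed_p(t, df), False,
                      "unpaired t (pooled)")


def dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> list[TestResult]:
    """Many-to-one comparisons of each group against the control.

    The familywise-adjusted p-value of each contrast is
    P(max_j |T_j| >= |t_obs|) under the joint null, estimated by Monte-Carlo
    simulation of the correlated t statistics (same group sizes, shared
    pooled variance).  Adjusted p-values are clipped from below at the
    unadjusted two-sample p so the familywise guarantee
    ``adjusted >= unadjusted`` holds despite Monte-Carlo noise.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not present")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if n_mc < 1_000:
        raise ValueError(f"n_mc must be >= 1000, got {n_mc}")

    labels = [lab for lab in groups if lab != control]
    data = {lab: np.asarray(list(v), dtype=float) for lab, v in groups.items()}
    for lab, arr in data.items():
        if arr.size < 2:
            raise ValueError(f"group {lab!r} needs n >= 2")

    ns = {lab: arr.size for lab, arr in data.items()}
    N = sum(ns.values())
    k_groups = len(groups)
    df = N - k_groups
    pooled = sum((arr.size - 1) * arr.var(ddof=1) for arr in data.values()) / df

    def t_stat(lab: str, means: Mapping[str, float], s2: float) -> float:
        se = math.sqrt(s2 * (1.0 / ns[lab] + 1.0 / ns[control]))
        if se == 0:
            return 0.0 if means[lab] == means[control] else math.inf
        return (means[lab] - means[control]) / se

    means_obs = {lab: float(arr.mean()) for lab, arr in data.items()}
    t_obs = {lab: t_stat(lab, means_obs, pooled) for lab in labels}

    # Monte-Carlo null: standard-normal data with the observed group sizes.
    rng = np.random.default_rng(seed)
    order = [control] + labels
    sims_mean = {}
    ss_resid = np.zeros(n_mc)
    for lab in order:
        z = rng.standard_normal((n_mc, ns[lab]))
        sims_mean[lab] = z.mean(axis=1)
        ss_resid += ((z - sims_mean[lab][:, None]) ** 2).sum(axis=1)
    s2_null = ss_resid / df
    max_abs_t = np.zeros(n_mc)
    for lab in labels:
        se = np.sqrt(s2_null * (1.0 / ns[lab] + 1.0 / ns[control]))
        t_null = (sims_mean[lab] - sims_mean[control]) / se
        np.maximum(max_abs_t, np.abs(t_null), out=max_abs_t)

    results = []
    for lab in labels:
        t = t_obs[lab]
        raw_p = _two_tailed_p(t, df) if math.isfinite(t) else 0.0
        adj_p = float(np.mean(max_abs_t >= abs(t))) if math.isfinite(t) else 0.0
        adj_p = min(1.0, max(adj_p, raw_p))
        results.append(
            TestResult(
                statistic=float(t),
                df=float(df),
                p_value=adj_p,
                adjusted=True,
                method="dunnett (monte-carlo)",
                contrast=f"{lab} vs {control}",
            )
        )
    return results
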