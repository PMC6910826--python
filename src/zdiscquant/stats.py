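"""Intensity normalization and the two hypothesis tests of the pipeline.

Disc-size category counts are compared between genotypes with Fisher's
exact test for count data (2×2 exactly via the hypergeometric
distribution; R×C exactly by full enumeration over tables with fixed
margins when the total count is small, otherwise by a seeded Monte-Carlo
permutation estimate reported with its standard error). Relative
fluorescence intensities and aggregate-frequency estimates are compared
with Welch's two-sample t-test (unequal variances, Welch–Satterthwaite
degrees of freedom).

Two-sided Fisher p-values follow the "sum of table probabilities no larger
than the observed table's" convention used by mainstream statistics
environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "normalize_to_control",
    "bifc_signal",
    "fisher_exact",
    "welch_t_test",
]

#: relative slack when comparing table probabilities, absorbing float
#: round-off in the "probability <= observed" rule.
_ALMOST_1 = 1.0 + 1e-7

DEFAULT_EXACT_LIMIT = 200
DEFAULT_MC_REPLICATES = 100_000


@dataclass
class ContingencyTable:
    """R×C table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2×2")
        if np.any(c < 0) or not np.all(c == np.round(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("degenerate table: a row or column margin is zero")


@dataclass
class TestResult:
    """Outcome of a hypothesis test, with Monte-Carlo provenance if any."""

    method: str
    p_value: float
    statistic: float | None = None
    df: float | None = None
    mc_replicates: int | None = None
    mc_se: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValueError("df must be > 0 when present")


def normalize_to_control(values: Sequence[float], control_values: Sequence[float]) -> np.ndarray:
    """Express values relative to the control group's mean.

    The control group itself maps to mean exactly 1. Scale-equivariant:
    multiplying both inputs by a constant leaves the output unchanged.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    m = control.mean()
    if m <= 0:
        raise ValueError(f"control mean must be > 0, got {m}")
    return np.asarray(values, dtype=float) / m


def bifc_signal(
    zdisc_peak_values: Sequence[float], background_values: Sequence[float]
) -> np.ndarray:
    """Fluorescence-complementation signal relative to background noise.

    Each sample's Z-disc profile peak is divided by the mean off-disc
    background; ratios near 1 indicate no complementation.
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.size == 0:
        raise ValueError("background sample is empty")
    m = bg.mean()
    if m <= 0:
        raise ValueError(f"background mean must be > 0, got {m}")
    return np.asarray(zdisc_peak_values, dtype=float) / m


def _log_factorials(n: int) -> np.ndarray:
    return np.array([lgamma(k + 1) for k in range(n + 1)])


def _log_table_prob(table: np.ndarray, lf: np.ndarray, log_margins: float) -> float:
    return log_margins - lf[table].sum()


def _enumerate_fisher(counts: np.ndarray) -> float:
    """Exact R×C Fisher p by recursion over all tables with fixed margins."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    lf = _log_factorials(n)
    log_margins = lf[rows].sum() + lf[cols].sum() - lf[n]
    logp_obs = _log_table_prob(counts, lf, log_margins)
    cutoff = logp_obs + np.log(_ALMOST_1)
    R, C = counts.shape
    p_total = 0.0

    def recurse(r: int, col_left: np.ndarray, partial_lf: float) -> None:
        nonlocal p_total
        if r == R - 1:
            if np.all(col_left >= 0):
                logp = log_margins - (partial_lf + lf[col_left].sum())
                if logp <= cutoff:
                    p_total += float(np.exp(logp))
            return
        target = int(rows[r])

        def fill(c: int, left: int, row_cells: list[int]) -> None:
            if c == C - 1:
                if left <= col_left[c]:
                    cells = row_cells + [left]
                    recurse(
                        r + 1,
                        col_left - np.array(cells),
                        partial_lf + lf[np.array(cells)].sum(),
                    )
                return
            for v in range(min(target - sum(row_cells), int(col_left[c])) + 1):
                fill(c + 1, left - v, row_cells + [v])

        fill(0, target, [])

    recurse(0, cols.copy(), 0.0)
    return min(p_total, 1.0)


def _montecarlo_fisher(
    counts: np.ndarray, replicates: int, seed: int | None
) -> tuple[float, float]:
    """Monte-Carlo Fisher p via permutation of column labels; returns (p, se)."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    lf = _log_factorials(n)
    log_margins = lf[rows].sum() + lf[cols].sum() - lf[n]
    cutoff = _log_table_prob(counts, lf, log_margins) + np.log(_ALMOST_1)
    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(rows.size), rows)
    col_of = np.repeat(np.arange(cols.size), cols)
    hits = 0
    for _ in range(replicates):
        perm = rng.permutation(col_of)
        table = np.zeros_like(counts)
        np.add.at(table, (row_of, perm), 1)
        if _log_table_prob(table, lf, log_margins) <= cutoff:
            hits += 1
    p = (hits + 1) / (replicates + 1)
    se = float(np.sqrt(p * (1 - p) / replicates))
    return p, se


def fisher_exact(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    mc_replicates: int = DEFAULT_MC_REPLICATES,
    seed: int | None = None,
) -> TestResult:
    """Fisher's exact test for count data, two-sided.

    2×2 tables use the hypergeometric exact test. Larger tables with total
    count ≤ ``exact_limit`` are tested by full enumeration over tables with
    the observed margins; beyond that a seeded Monte-Carlo permutation
    estimate is returned together with its standard error.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if counts.shape == (2, 2):
        p = float(sps.fisher_exact(counts, alternative="two-sided")[1])
        return TestResult(method="Fisher exact (2x2)", p_value=min(p, 1.0))
    if counts.sum() <= exact_limit:
        p = _enumerate_fisher(counts)
        return TestResult(method="Fisher exact (RxC enumeration)", p_value=p)
    p, se = _montecarlo_fisher(counts, mc_replicates, seed)
    return TestResult(
        method="Fisher exact (Monte-Carlo)",
        p_value=p,
        mc_replicates=mc_replicates,
        mc_se=se,
        seed=seed,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b) with Welch–Satterthwaite
    degrees of freedom; p from the t distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        method="Welch two-sample t-test",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
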