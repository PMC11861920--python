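"""IVEP outcome rates, reference-bull normalization and comparison statistics.

In vitro embryo production (IVEP) performance per bull is summarized by the
cleavage rate (cleaved / inseminated oocytes), the embryonic development
rate (day-7 embryos / cleaved) and the blastocyst rate (blastocysts /
oocytes), each as a percentage.  Because plate-to-plate IVEP conditions are
not controllable, every tested bull's rate is re-expressed as a percentage
of a reference bull run in the same routine:

    normalized = 100 * rate_test / rate_reference   (two decimals)

The comparison layer provides Pearson correlation (t-transform p-value),
pairwise pooled two-proportion z-tests, the odds ratio with a Woolf
log-normal confidence interval (Haldane-Anscombe +0.5 on zero cells), and
Scott-Knott likelihood-ratio clustering of treatment means, which partitions
sorted means into contiguous homogeneous groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest


class UndefinedRateError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


@dataclass
class IVEPRecord:
    """Per-bull fertilization/embryo outcome counts (or precomputed rates)."""

    bull_id: str
    n_oocytes: int | None = None
    n_cleaved: int | None = None
    n_day7_embryos: int | None = None
    n_blastocysts: int | None = None
    cleavage_rate: float | None = None
    embryonic_development_rate: float | None = None
    blastocyst_rate: float | None = None

    def __post_init__(self) -> None:
        if self.n_oocytes is not None:
            if self.n_cleaved is not None and self.n_cleaved > self.n_oocytes:
                raise ValueError("n_cleaved exceeds n_oocytes")
            if (
                self.n_day7_embryos is not None
                and self.n_cleaved is not None
                and self.n_day7_embryos > self.n_cleaved
            ):
                raise ValueError("n_day7_embryos exceeds n_cleaved")
            if self.n_blastocysts is not None and self.n_blastocysts > self.n_oocytes:
                raise ValueError("n_blastocysts exceeds n_oocytes")
        for r in (self.cleavage_rate, self.embryonic_development_rate, self.blastocyst_rate):
            if r is not None and not (0 <= r <= 100):
                raise ValueError("rates must lie in [0, 100]")


@dataclass
class ORResult:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class ScottKnottResult:
    """Group labels are contiguous positive integers in sorted-mean order."""

    means: np.ndarray            # input order
    order: np.ndarray            # argsort of means (ascending)
    groups: np.ndarray           # group id per treatment, input order
    alpha: float

    def groups_sorted(self) -> np.ndarray:
        return self.groups[self.order]

    @property
    def n_groups(self) -> int:
        return int(self.groups.max())


# ---------------------------------------------------------------------------
# Rates and normalization
# ---------------------------------------------------------------------------

def compute_rates(rec: IVEPRecord) -> dict[str, float]:
    """Cleavage, embryonic-development and blastocyst rates (percent).

    Uses precomputed rates when counts are absent.
    """
    out: dict[str, float] = {}
    if rec.n_oocytes is not None and rec.n_cleaved is not None:
        if rec.n_oocytes <= 0:
            raise UndefinedRateError("n_oocytes must be positive")
        out["cleavage"] = 100.0 * rec.n_cleaved / rec.n_oocytes
        if rec.n_day7_embryos is not None:
            if rec.n_cleaved == 0:
                raise UndefinedRateError(
                    "embryonic development rate undefined with zero cleaved oocytes"
                )
            out["embryonic_development"] = 100.0 * rec.n_day7_embryos / rec.n_cleaved
        if rec.n_blastocysts is not None:
            out["blastocyst"] = 100.0 * rec.n_blastocysts / rec.n_oocytes
    for name, value in (
        ("cleavage", rec.cleavage_rate),
        ("embryonic_development", rec.embryonic_development_rate),
        ("blastocyst", rec.blastocyst_rate),
    ):
        if name not in out and value is not None:
            out[name] = float(value)
    if not out:
        raise UndefinedRateError(f"record {rec.bull_id!r} has neither counts nor rates")
    return out


def normalize_rate(test_rate: float, reference_rate: float) -> float:
    """Percent-of-reference, reported at two decimals (round half to even)."""
    if reference_rate <= 0:
        raise UndefinedRateError("reference rate must be positive")
    value = Decimal(100 * test_rate / reference_rate)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def normalized_rates_table(
    records: list[IVEPRecord], reference: IVEPRecord
) -> pd.DataFrame:
    """Per-bull raw and reference-normalized rates, one row per bull."""
    ref_rates = compute_rates(reference)
    rows = []
    for rec in records:
        rates = compute_rates(rec)
        row: dict[str, float | str] = {"bull_id": rec.bull_id}
        for name in ("cleavage", "embryonic_development", "blastocyst"):
            if name in rates:
                row[f"{name}_rate"] = rates[name]
                if name in ref_rates:
                    row[f"normalized_{name}"] = normalize_rate(rates[name], ref_rates[name])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-transform p-value.

    Requires n >= 3 and nonzero variance in both vectors; |r| = 1 reports
    p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    r, p = float(r), float(p)
    if 1.0 - abs(r) < 1e-14:  # exactly (anti)linear data up to float noise
        r, p = float(np.sign(r)), 0.0
    return CorrelationResult(r=r, p_value=p, n=n)


def correlation_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p matrices over the columns of ``df``."""
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, j in combinations(range(len(cols)), 2):
        res = pearson(df[cols[i]].to_numpy(), df[cols[j]].to_numpy())
        r.iloc[i, j] = r.iloc[j, i] = res.r
        p.iloc[i, j] = p.iloc[j, i] = res.p_value
    return r, p


# ---------------------------------------------------------------------------
# Odds ratio
# ---------------------------------------------------------------------------

def odds_ratio(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> ORResult:
    """Cross-product odds ratio with Woolf log-normal CI and normal p-value.

    The 2x2 table rows are (altered, normal) for the two groups/techniques.
    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError("a row of the 2x2 table is entirely zero")
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    if b_ * c_ == 0 or a_ * d_ == 0:  # pragma: no cover - unreachable after +0.5
        raise DegenerateTableError("degenerate table even after correction")
    or_value = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    log_or = np.log(or_value)
    ci_low = float(np.exp(log_or - z_crit * se))
    ci_high = float(np.exp(log_or + z_crit * se))
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return ORResult(
        or_value=float(or_value),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=min(p, 1.0),
        continuity_corrected=corrected,
    )


def odds_ratio_table(
    counts: dict[str, tuple[int, int]], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise OR table from per-technique (n_altered, n_total) counts.

    One row per ordered technique pair (first vs second), mirroring the
    shape of a published OR comparison table.
    """
    rows = []
    names = list(counts)
    for first, second in combinations(names, 2):
        a1, n1 = counts[first]
        a2, n2 = counts[second]
        res = odds_ratio(a1, n1 - a1, a2, n2 - a2, alpha=alpha)
        rows.append(
            {
                "technique_a": first,
                "technique_b": second,
                "or": res.or_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def compare_proportions_pairwise(
    successes, totals, bonferroni: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise pooled two-proportion z-tests (two-sided).

    Returns (z, p) matrices; z is antisymmetric, p symmetric with ones on
    the diagonal.  ``bonferroni`` multiplies p by the number of pairs.
    """
    successes = np.asarray(successes, dtype=int)
    totals = np.asarray(totals, dtype=int)
    k = len(successes)
    if k < 2:
        raise ValueError("need at least two groups")
    if (totals <= 0).any():
        raise ValueError("totals must be positive")
    z = np.zeros((k, k))
    p = np.ones((k, k))
    n_pairs = k * (k - 1) // 2
    for i, j in combinations(range(k), 2):
        zij, pij = proportions_ztest(
            [successes[i], successes[j]], [totals[i], totals[j]]
        )
        if bonferroni:
            pij = min(1.0, pij * n_pairs)
        z[i, j], z[j, i] = zij, -zij
        p[i, j] = p[j, i] = pij
    return z, p


# ---------------------------------------------------------------------------
# Scott-Knott
# ---------------------------------------------------------------------------

_SK_CONST = np.pi / (2.0 * (np.pi - 2.0))


def _best_split(ms: np.ndarray) -> tuple[float, int]:
    """Maximum between-group sum of squares over contiguous 2-way splits."""
    total = ms.sum()
    k = len(ms)
    best_b0, best_cut = -np.inf, 1
    csum = np.cumsum(ms)
    for cut in range(1, k):
        t1, k1 = csum[cut - 1], cut
        t2, k2 = total - t1, k - cut
        b0 = t1**2 / k1 + t2**2 / k2 - total**2 / k
        if b0 > best_b0:
            best_b0, best_cut = b0, cut
    return float(best_b0), best_cut


def scott_knott(
    means,
    treatment_sizes,
    error_mean_square: float,
    error_df: int,
    alpha: float = 0.05,
) -> ScottKnottResult:
    """Scott-Knott clustering of treatment means into homogeneous groups.

    At each node the contiguous split maximizing the between-group sum of
    squares B0 is tested with lambda = pi/(2(pi-2)) * B0 / sigma0^2 against
    the chi-square critical value at nu = k/(pi-2) degrees of freedom, where
    sigma0^2 pools the node's mean dispersion with the (externally supplied)
    error mean square scaled to the variance of a treatment mean
    (error_mean_square / replication).  Significant nodes recurse into both
    halves; others become one group.  Groups are always contiguous in
    sorted-mean order.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(treatment_sizes, dtype=float)
    if means.ndim != 1 or len(means) < 2:
        raise ValueError("need at least two treatment means")
    if sizes.shape != means.shape:
        raise ValueError("one size per treatment required")
    if error_mean_square <= 0 or error_df <= 0:
        raise ValueError("error mean square and df must be positive")
    order = np.argsort(means, kind="stable")
    ms = means[order]
    sz = sizes[order]
    groups_sorted = np.zeros(len(ms), dtype=int)
    next_group = 1

    def recurse(lo: int, hi: int) -> None:
        nonlocal next_group
        k = hi - lo
        if k == 1:
            groups_sorted[lo:hi] = next_group
            next_group += 1
            return
        node = ms[lo:hi]
        b0, cut = _best_split(node)
        s2y = error_mean_square * float(np.mean(1.0 / sz[lo:hi]))
        sigma0 = (np.sum((node - node.mean()) ** 2) + error_df * s2y) / (k + error_df)
        lam = _SK_CONST * b0 / sigma0
        nu = k / (np.pi - 2.0)
        crit = stats.chi2.ppf(1.0 - alpha, nu)
        if lam > crit:
            recurse(lo, lo + cut)
            recurse(lo + cut, hi)
        else:
            groups_sorted[lo:hi] = next_group
            next_group += 1

    recurse(0, len(ms))
    groups = np.zeros(len(ms), dtype=int)
    groups[order] = groups_sorted
    return ScottKnottResult(means=means, order=order, groups=groups, alpha=alpha)
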