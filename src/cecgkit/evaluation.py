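"""Error, agreement and group-comparison statistics.

Conventions, fixed throughout the package:

* ERR = RR_reference − RR_textile (seconds; reference minus capacitive);
* ERP = 100 · |ERR| / RR_reference (percent, absolute-valued — the error
  coverage bins start at 0, so a signed ERP would be meaningless there);
* error coverage bins: [0, 5], ]5, 10], ]10, 15], ]15, 20], ]20, ∞[ — the
  first closed, the rest left-open/right-closed;
* Bland–Altman limits of agreement at bias ± 1.96 · sd (sample sd, ddof=1);
* paired binomial sign test, exact and two-sided: ties are excluded and
  p = min(1, 2 · min(P(X ≤ k), P(X ≥ k))) with X ~ Binomial(n, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ERP_EDGES = (5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class ErrorPair:
    rr_reference: float    # s
    rr_textile: float      # s
    err: float             # s, reference - textile
    erp: float             # percent, absolute

    def __post_init__(self) -> None:
        if not self.rr_reference > 0:
            raise ValueError("rr_reference must be positive")


def rr_errors(rr_reference: float, rr_textile: float) -> ErrorPair:
    """ERR and ERP for one reference/textile RR pair."""
    if not (rr_reference > 0 and rr_textile > 0):
        raise ValueError("RR durations must be positive")
    err = rr_reference - rr_textile
    erp = 100.0 * abs(err) / rr_reference
    return ErrorPair(rr_reference, rr_textile, err, erp)


@dataclass(frozen=True)
class CoverageRates:
    """Percent of ERP values per bin; rates sum to 100."""

    rates: tuple[float, ...]
    edges: tuple[float, ...] = DEFAULT_ERP_EDGES

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be >= 0")
        if abs(sum(self.rates) - 100.0) > 1e-9:
            raise ValueError("rates must sum to 100")

    @property
    def labels(self) -> list[str]:
        e = self.edges
        out = [f"[0, {e[0]:g}]"]
        out += [f"]{a:g}, {b:g}]" for a, b in zip(e, e[1:])]
        out.append(f"]{e[-1]:g}, inf[")
        return out


def coverage_rates(erps: Sequence[float],
                   edges: Sequence[float] = DEFAULT_ERP_EDGES) -> CoverageRates:
    """Fraction (percent) of ERP values in each coverage bin.

    Bin membership: [0, e0] closed, then ]e_i, e_{i+1}] left-open, final bin
    unbounded above.  Negative ERPs are impossible under the absolute
    convention and rejected.
    """
    erps = np.asarray(list(erps), dtype=float)
    if erps.size == 0:
        raise ValueError("need at least one ERP value")
    if np.any(erps < 0):
        raise ValueError("ERP values must be >= 0 (absolute convention)")
    idx = np.searchsorted(np.asarray(edges, dtype=float), erps, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    rates = 100.0 * counts / erps.size
    return CoverageRates(rates=tuple(float(r) for r in rates),
                         edges=tuple(edges))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float        # s, mean difference
    sd: float          # s, sample standard deviation
    loa_low: float     # bias - 1.96 sd
    loa_high: float    # bias + 1.96 sd
    n: int


def bland_altman(errs: Sequence[float]) -> BlandAltmanResult:
    """Agreement summary of per-recording mean differences (seconds).

    ``errs`` follow the ERR sign convention (reference minus textile); the
    bias is their mean and the limits of agreement sit at ±1.96 sample
    standard deviations around it.
    """
    errs = np.asarray(list(errs), dtype=float)
    if errs.size < 2:
        raise ValueError("need at least 2 differences")
    bias = float(np.mean(errs))
    sd = float(np.std(errs, ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, n=errs.size)


def linfit_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares line and Pearson correlation: (slope, intercept, r)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    n_zero: int
    p: float
    all_zero: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def sign_test(a: Sequence[float], b: Sequence[float]) -> SignTestResult:
    """Exact two-sided paired binomial sign test on the differences a − b.

    Zero differences are excluded; with k positive signs among n non-zero
    differences, p = min(1, 2·min(P(X ≤ k), P(X ≥ k))), X ~ Binomial(n, ½).
    If every difference is zero the result carries p = 1 and ``all_zero``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValueError("need equal-length non-empty paired samples")
    d = a - b
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    n_zero = int(np.sum(d == 0))
    n = n_pos + n_neg
    if n == 0:
        return SignTestResult(0, 0, n_zero, p=1.0, all_zero=True)
    k = n_pos
    p = 2.0 * min(stats.binom.cdf(k, n, 0.5), stats.binom.sf(k - 1, n, 0.5))
    return SignTestResult(n_pos, n_neg, n_zero, p=float(min(1.0, p)))


@dataclass
class GroupComparisonTable:
    """Per-group summary rows plus pairwise sign-test p values."""

    grouping: str
    summary: pd.DataFrame        # index: group label; columns: median/mean/std/range/N
    p_values: pd.DataFrame       # square, symmetric, NaN diagonal
    sign_tests: dict = field(default_factory=dict)


def summarize_group(values: Sequence[float]) -> dict:
    v = np.asarray(list(values), dtype=float)
    return {
        "median": float(np.median(v)),
        "mean": float(np.mean(v)),
        "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "range": float(np.max(v) - np.min(v)),
        "N": int(v.size),
    }


def run_comparison(groups: Mapping[str, pd.DataFrame],
                   grouping: str = "") -> GroupComparisonTable:
    """Compare SQI groups pairwise with the sign test.

    Each group is a DataFrame with columns ``subject``, ``section`` and
    ``sqi``; pairs are aligned on (subject, section) — the same person and
    the same timeframe — and unpairable sections raise.
    """
    frames = {}
    for label, df in groups.items():
        missing = {"subject", "section", "sqi"} - set(df.columns)
        if missing:
            raise ValueError(f"group {label!r} missing columns {sorted(missing)}")
        frames[label] = df.set_index(["subject", "section"])["sqi"].sort_index()

    summary = pd.DataFrame(
        {label: summarize_group(s.to_numpy()) for label, s in frames.items()}
    ).T[["median", "mean", "std", "range", "N"]]

    labels = list(frames)
    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    tests: dict[tuple[str, str], SignTestResult] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            joined = pd.concat({"a": frames[la], "b": frames[lb]},
                               axis=1, join="inner")
            if len(joined) == 0:
                raise ValueError(f"groups {la!r} and {lb!r} share no "
                                 "(subject, section) pairs")
            if len(joined) < min(len(frames[la]), len(frames[lb])):
                raise ValueError(f"groups {la!r} and {lb!r} have unpairable sections")
            res = sign_test(joined["a"].to_numpy(), joined["b"].to_numpy())
            tests[(la, lb)] = res
            p.loc[la, lb] = p.loc[lb, la] = res.p
    return GroupComparisonTable(grouping=grouping, summary=summary,
                                p_values=p, sign_tests=tests)
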