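"""2x2 contingency tables and frequentist/Bayesian disproportionality metrics.

The counting unit is the drug-event pair.  With a target drug set D and
target event set E, the table is

    n11 = pairs with drug in D and event in E
    n12 = pairs with drug in D, event not in E
    n21 = pairs with drug not in D, event in E
    n22 = the remainder

Metrics: reporting odds ratio (ROR) with a log-symmetric Wald 95% CI and a
two-sided Fisher exact p-value; proportional reporting ratio (PRR) with Wald
CI and Yates-corrected chi-square (the MHRA convention); and the Bayesian
information component IC = log2((n11+0.5)/(E+0.5)) with an exact gamma
posterior credibility interval.  Signal rules follow the conventional
thresholds: n11>=3 with ROR025>1; n11>=3 with PRR025>2 and chi2>4; IC025>0;
EBGM05>=2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import CaseRecord, DrugEventPair

__all__ = [
    "ContingencyTable",
    "MetricResult",
    "SignalFlags",
    "build_contingency",
    "build_contingency_icsr",
    "ror",
    "prr",
    "fisher_exact",
    "bcpnn_ic",
    "apply_signal_rules",
]


@dataclass(frozen=True)
class ContingencyTable:
    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.n_total < 1:
            raise ValueError("contingency table must contain at least one pair")

    @property
    def n1p(self) -> int:
        return self.n11 + self.n12

    @property
    def n2p(self) -> int:
        return self.n21 + self.n22

    @property
    def np1(self) -> int:
        return self.n11 + self.n21

    @property
    def np2(self) -> int:
        return self.n12 + self.n22

    @property
    def n_total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def expected_n11(self) -> float:
        """Expected co-reporting count under row/column independence."""
        return self.n1p * self.np1 / self.n_total

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]], dtype=float)


@dataclass
class MetricResult:
    """A disproportionality point estimate with its interval.

    ``estimate``/``lower``/``upper`` are NaN when the metric is undefined for
    the table (zero cells without continuity correction); auxiliary statistics
    (Fisher p, chi-square, expected count) stay available in ``aux``.
    """

    name: str
    estimate: float
    lower: float
    upper: float
    level: float
    aux: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.estimate)

    @classmethod
    def undefined(cls, name: str, level: float, aux: Optional[dict] = None):
        return cls(name, math.nan, math.nan, math.nan, level, aux or {})


@dataclass(frozen=True)
class SignalFlags:
    ror_signal: bool
    prr_signal: bool
    ic_signal: bool
    ebgm_signal: bool
    n11: int


def build_contingency(
    pairs: Sequence[DrugEventPair],
    drug_set: "Iterable[str]",
    event_set: "Iterable[str]",
) -> ContingencyTable:
    """Classify every pair into the 2x2 table; cells sum to ``len(pairs)``."""
    if not pairs:
        raise ValueError("cannot build a contingency table from an empty pair universe")
    drugs, events = set(drug_set), set(event_set)
    n11 = n12 = n21 = n22 = 0
    for p in pairs:
        d, e = p.drug in drugs, p.pt_code in events
        if d and e:
            n11 += 1
        elif d:
            n12 += 1
        elif e:
            n21 += 1
        else:
            n22 += 1
    return ContingencyTable(n11, n12, n21, n22)


def build_contingency_icsr(
    cases: Sequence[CaseRecord],
    drug_set: "Iterable[str]",
    event_set: "Iterable[str]",
) -> ContingencyTable:
    """Report-level 2x2 table: each ICSR is classified once.

    A case counts as drug-exposed if any listed drug is in ``drug_set`` and as
    event-positive if any event is in ``event_set``.  This is the table whose
    odds ratio matches a report-level generative odds multiplier exactly; the
    pair-level table approximates it.
    """
    drugs, events = set(drug_set), set(event_set)
    n11 = n12 = n21 = n22 = 0
    for c in cases:
        d = any(x.identity in drugs for x in c.drugs)
        e = any(x.pt_code in events for x in c.events)
        if d and e:
            n11 += 1
        elif d:
            n12 += 1
        elif e:
            n21 += 1
        else:
            n22 += 1
    if n11 + n12 + n21 + n22 < 1:
        raise ValueError("no cases to classify")
    return ContingencyTable(n11, n12, n21, n22)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (point-probability method, fixed margins)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def _zcrit(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2))


def ror(
    table: ContingencyTable, level: float = 0.95, continuity: bool = False
) -> MetricResult:
    """Reporting odds ratio with log-symmetric Wald CI and Fisher p.

    ROR = (n11*n22)/(n12*n21); CI bounds are exp(ln ROR +- z*se) with
    se = sqrt(1/n11+1/n12+1/n21+1/n22), so sqrt(lower*upper) equals the point
    estimate by construction.  A table with any zero cell is undefined unless
    ``continuity`` applies the Haldane-Anscombe +0.5 to every cell.
    """
    p_value = fisher_exact(table)
    cells = [table.n11, table.n12, table.n21, table.n22]
    if min(cells) == 0:
        if not continuity:
            return MetricResult.undefined("ROR", level, {"p_value": p_value})
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = _zcrit(level)
    return MetricResult(
        "ROR",
        est,
        est * math.exp(-z * se),
        est * math.exp(z * se),
        level,
        {"p_value": p_value},
    )


def _yates_chi2(table: ContingencyTable, correction: bool) -> float:
    arr = table.as_array()
    if min(table.n1p, table.n2p, table.np1, table.np2) == 0:
        return math.nan
    chi2 = stats.chi2_contingency(arr, correction=correction)[0]
    return float(chi2)


def prr(
    table: ContingencyTable,
    level: float = 0.95,
    continuity: bool = False,
    yates: bool = True,
) -> MetricResult:
    """Proportional reporting ratio with Wald CI and (Yates) chi-square.

    PRR = [n11/n1+] / [n21/n2+]; CI = exp(ln PRR +- z*sqrt(1/n11 - 1/n1+ +
    1/n21 - 1/n2+)).
    """
    chi2 = _yates_chi2(table, yates)
    a, b, c, d = table.n11, table.n12, table.n21, table.n22
    if table.n1p == 0 or table.n2p == 0:
        return MetricResult.undefined("PRR", level, {"chi_square": chi2})
    if a == 0 or c == 0:
        if not continuity:
            return MetricResult.undefined("PRR", level, {"chi_square": chi2})
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    z = _zcrit(level)
    return MetricResult(
        "PRR",
        est,
        est * math.exp(-z * se),
        est * math.exp(z * se),
        level,
        {"chi_square": chi2},
    )


def bcpnn_ic(
    table: ContingencyTable, level: float = 0.95, variant: str = "gamma"
) -> MetricResult:
    """Information component with shrinkage and its credibility interval.

    Default (``variant="gamma"``): IC = log2((n11+0.5)/(E+0.5)) where
    E = n1+*n+1/n++, with the interval taken from the exact posterior
    Gamma(n11+0.5, rate E+0.5) of the reporting-rate ratio lambda.  The
    ``"moment"`` variant is the classical normal approximation to the
    full-Bayes IC (priors alpha1=beta1=1, gamma11=1).
    """
    if table.n1p == 0 or table.np1 == 0:
        raise ValueError("degenerate margins: expected count is zero")
    E = table.expected_n11
    n11 = table.n11
    if variant == "gamma":
        est = math.log2((n11 + 0.5) / (E + 0.5))
        post = stats.gamma(a=n11 + 0.5, scale=1.0 / (E + 0.5))
        alpha = (1 - level) / 2
        lower = math.log2(post.ppf(alpha))
        upper = math.log2(post.ppf(1 - alpha))
        return MetricResult("IC", est, lower, upper, level, {"expected": E})
    if variant == "moment":
        return _bcpnn_ic_moment(table, level)
    raise ValueError(f"unknown BCPNN variant: {variant!r}")


def _bcpnn_ic_moment(table: ContingencyTable, level: float) -> MetricResult:
    # Classical moment approximation (two-way shrinkage with Dirichlet-style
    # priors); kept behind a flag as an alternative interval construction.
    n11, n1p, np1, n = table.n11, table.n1p, table.np1, table.n_total
    a1 = b1 = 1.0
    a = b = 2.0
    g11 = 1.0
    g = g11 * (n + a) * (n + b) / ((n1p + a1) * (np1 + b1))
    est = math.log2(
        (n11 + g11) * (n + a) * (n + b) / ((n + g) * (n1p + a1) * (np1 + b1))
    )
    var = (
        (n - n11 + g - g11) / ((n11 + g11) * (1 + n + g))
        + (n - n1p + a - a1) / ((n1p + a1) * (1 + n + a))
        + (n - np1 + b - b1) / ((np1 + b1) * (1 + n + b))
    ) / math.log(2) ** 2
    z = _zcrit(level)
    sd = math.sqrt(var)
    return MetricResult(
        "IC", est, est - z * sd, est + z * sd, level, {"expected": table.expected_n11}
    )


def apply_signal_rules(
    n11: int,
    ror_result: Optional[MetricResult] = None,
    prr_result: Optional[MetricResult] = None,
    ic_result: Optional[MetricResult] = None,
    ebgm_result: Optional[MetricResult] = None,
) -> SignalFlags:
    """Evaluate the four signal criteria; NaN intervals never signal.

    ROR: n11>=3 and lower 95% bound > 1.  PRR: n11>=3, lower bound > 2
    (strict) and chi-square > 4.  IC: lower 95% credibility bound > 0.
    EBGM: lower 90% bound >= 2.0 (inclusive).
    """

    def _ok(m: Optional[MetricResult]) -> bool:
        return m is not None and m.defined

    ror_sig = _ok(ror_result) and n11 >= 3 and ror_result.lower > 1.0
    prr_sig = (
        _ok(prr_result)
        and n11 >= 3
        and prr_result.lower > 2.0
        and float(prr_result.aux.get("chi_square", math.nan)) > 4.0
    )
    ic_sig = _ok(ic_result) and ic_result.lower > 0.0
    ebgm_sig = _ok(ebgm_result) and ebgm_result.lower >= 2.0
    return SignalFlags(bool(ror_sig), bool(prr_sig), bool(ic_sig), bool(ebgm_sig), n11)
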