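"""Stratified disproportionality: sex, age, and BMI subgroups.

Age strata follow the banded JADER convention: decade bands "20s" through
"50s" map to the 20-50 stratum, "60s" and above to the >=60 stratum, and all
other bands (children, teens, unknown) are excluded.  BMI is derived from
banded anthropometry using band midpoints, since heights and weights are
recorded in 10-cm and 10-kg increments.  Reports missing the stratum
variable are excluded, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cases import expand_pairs
from .contingency import (
    ContingencyTable,
    MetricResult,
    SignalFlags,
    apply_signal_rules,
    bcpnn_ic,
    build_contingency,
    prr,
    ror,
)
from .model import CaseRecord

__all__ = [
    "StratumSpec",
    "StratumResult",
    "bmi_from_bands",
    "stratum_value",
    "sex_age_stratum",
    "STRATUM_LEVELS",
    "analyze_stratum",
    "stratified_analysis",
]

logger = logging.getLogger(__name__)

STRATUM_LEVELS: dict[str, tuple[str, str]] = {
    "sex": ("male", "female"),
    "age": ("ge60", "20to50"),
    "bmi": ("ge25", "lt25"),
}


@dataclass(frozen=True)
class StratumSpec:
    variable: str  # sex | age | bmi
    level: str

    def __post_init__(self) -> None:
        if self.variable not in STRATUM_LEVELS:
            raise ValueError(f"unknown stratum variable: {self.variable!r}")
        if self.level not in STRATUM_LEVELS[self.variable]:
            raise ValueError(
                f"unknown level {self.level!r} for variable {self.variable!r}"
            )


@dataclass
class StratumResult:
    spec: StratumSpec
    table: Optional[ContingencyTable]
    metrics: dict[str, MetricResult]
    flags: SignalFlags
    n_cases: int


def bmi_from_bands(
    height_band_cm: Optional[tuple[int, int]],
    weight_band_kg: Optional[tuple[int, int]],
) -> Optional[float]:
    """BMI from band midpoints: mid(weight) / (mid(height)/100)^2.

    Returns None when either band is missing (the report is then excluded
    from BMI strata).
    """
    if height_band_cm is None or weight_band_kg is None:
        return None
    h_mid = (height_band_cm[0] + height_band_cm[1]) / 2 / 100.0
    w_mid = (weight_band_kg[0] + weight_band_kg[1]) / 2
    return w_mid / (h_mid * h_mid)


def _age_stratum(age_band: Optional[str]) -> Optional[str]:
    if not age_band or not age_band.endswith("s"):
        return None
    try:
        decade = int(age_band[:-1])
    except ValueError:
        return None
    if 20 <= decade <= 50:
        return "20to50"
    if decade >= 60:
        return "ge60"
    return None


def stratum_value(case: CaseRecord, variable: str) -> Optional[str]:
    """Resolve a case's level for a stratum variable; None means excluded."""
    if variable == "sex":
        return case.sex.value if case.sex.value in ("male", "female") else None
    if variable == "age":
        return _age_stratum(case.age_band)
    if variable == "bmi":
        bmi = bmi_from_bands(case.height_band_cm, case.weight_band_kg)
        if bmi is None:
            return None
        return "ge25" if bmi >= 25.0 else "lt25"
    raise ValueError(f"unknown stratum variable: {variable!r}")


def sex_age_stratum(case: CaseRecord) -> str:
    """Joint sex x age label used for GPS expected-count stratification.

    Cases missing either variable fall into composite "unknown" levels rather
    than being dropped, so the pooled expected counts still cover every pair.
    """
    sex = stratum_value(case, "sex") or "unknown"
    age = _age_stratum(case.age_band) or "unknown"
    return f"{sex}|{age}"


def analyze_stratum(
    cases: Sequence[CaseRecord],
    drug_set: "Iterable[str]",
    event_set: "Iterable[str]",
    spec: StratumSpec,
    level: float = 0.95,
    continuity: bool = False,
) -> StratumResult:
    """Re-derive pairs within one stratum and recompute metrics and flags."""
    members = [c for c in cases if stratum_value(c, spec.variable) == spec.level]
    pairs = expand_pairs(members)
    metrics: dict[str, MetricResult] = {}
    if not pairs:
        flags = SignalFlags(False, False, False, False, 0)
        return StratumResult(spec, None, metrics, flags, len(members))
    table = build_contingency(pairs, drug_set, event_set)
    metrics["ROR"] = ror(table, level=level, continuity=continuity)
    metrics["PRR"] = prr(table, level=level, continuity=continuity)
    try:
        metrics["IC"] = bcpnn_ic(table, level=level)
    except ValueError:
        metrics["IC"] = MetricResult.undefined("IC", level)
    flags = apply_signal_rules(
        table.n11,
        ror_result=metrics["ROR"],
        prr_result=metrics["PRR"],
        ic_result=metrics["IC"],
    )
    return StratumResult(spec, table, metrics, flags, len(members))


def stratified_analysis(
    cases: Sequence[CaseRecord],
    drug_set: "Iterable[str]",
    event_set: "Iterable[str]",
    variable: str,
    level: float = 0.95,
    continuity: bool = False,
) -> dict[str, StratumResult]:
    """Run :func:`analyze_stratum` for both levels of one variable."""
    out = {}
    for lv in STRATUM_LEVELS[variable]:
        out[lv] = analyze_stratum(
            cases, drug_set, event_set, StratumSpec(variable, lv), level, continuity
        )
    return out
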