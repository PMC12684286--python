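"""Case-level assembly: merge raw SRS tables into :class:`CaseRecord` objects
and expand them into drug-event pairs.

Merge semantics are a left merge onto the demographics table: every DEMO row
yields exactly one case; DRUG/REAC (or HIST) rows attach by the case key, and
rows without a DEMO parent are dropped with a logged count.  For FAERS the
demographics table is deduplicated first (highest case version wins) and
child tables attach by ``primaryid`` so that children of superseded versions
are discarded as orphans.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dates import PartialDate, parse_partial_date
from .io import dedup_faers
from .lexicon import DEFAULT_LEXICON, compile_lexicon, match_drug
from .model import CaseRecord, DrugEntry, DrugEventPair, EventEntry, Reporter, Role, Sex

__all__ = [
    "merge_case_level",
    "expand_pairs",
    "filter_primary_suspect",
    "count_unique_icsrs",
    "JADER_COLS",
]

logger = logging.getLogger(__name__)

# JADER-dialect column names (our synthetic dialect mirrors the PMDA layout;
# generic ASCII aliases are accepted as fallbacks).
JADER_COLS = {
    "case_id": ("識別番号", "case_id"),
    "sex": ("性別", "sex"),
    "age": ("年齢", "age"),
    "height": ("身長", "height"),
    "weight": ("体重", "weight"),
    "reporter": ("報告者職種", "reporter"),
    "report_year": ("報告年", "report_year"),
    "drug_seq": ("医薬品連番", "drug_seq"),
    "role": ("医薬品の関与", "role"),
    "drug_name": ("医薬品（一般名）", "drug_name"),
    "ther_start": ("投与開始日", "ther_start"),
    "ther_end": ("投与終了日", "ther_end"),
    "pt_name": ("有害事象", "pt_name"),
    "pt_code": ("有害事象コード", "pt_code"),
    "onset": ("発現日", "onset"),
}

_JADER_ROLE = {
    "被疑薬": Role.PRIMARY_SUSPECT,  # JADER has no PS/SS split; see docs
    "併用薬": Role.CONCOMITANT,
    "相互作用": Role.INTERACTING,
}
_FAERS_ROLE = {
    "PS": Role.PRIMARY_SUSPECT,
    "SS": Role.SECONDARY_SUSPECT,
    "C": Role.CONCOMITANT,
    "I": Role.INTERACTING,
}
_JADER_SEX = {"男性": Sex.MALE, "女性": Sex.FEMALE}
_FAERS_SEX = {"M": Sex.MALE, "F": Sex.FEMALE}
_JADER_REPORTER = {
    "医療関係者": Reporter.HEALTHCARE_PROFESSIONAL,
    "消費者": Reporter.CONSUMER,
}
_FAERS_HCP = {"MD", "PH", "RN", "HP", "OT"}

_AGE_BAND_JA = re.compile(r"^(\d{1,3})歳代$")
_AGE_BAND_EN = re.compile(r"^(\d{1,3})s$")
_BAND_JA = re.compile(r"^(\d{1,3})(?:cm|kg)台$")


def _col(df: pd.DataFrame, key: str) -> Optional[str]:
    for cand in JADER_COLS[key]:
        if cand in df.columns:
            return cand
    return None


def _column(df: pd.DataFrame, key: str):
    """Stripped string values of a JADER-dialect column, or None if absent."""
    name = _col(df, key)
    if name is None:
        return None
    return df[name].fillna("").astype(str).str.strip().to_numpy()


def _blank(n: int):
    import numpy as np

    return np.full(n, "", dtype=object)


def parse_age_band(text: str) -> Optional[str]:
    """Normalize an age field to a decade-band label (``"60s"``)."""
    s = str(text).strip()
    if not s:
        return None
    m = _AGE_BAND_JA.match(s) or _AGE_BAND_EN.match(s)
    if m:
        return f"{int(m.group(1))}s"
    return None


def age_years_to_band(years: float) -> str:
    return f"{int(years // 10) * 10}s"


def parse_anthro_band(text: str) -> Optional[tuple[int, int]]:
    """Parse a 10-unit anthropometry band (``"160cm台"`` -> ``(160, 170)``)."""
    s = str(text).strip()
    if not s:
        return None
    m = _BAND_JA.match(s)
    if m:
        low = int(m.group(1))
        return (low, low + 10)
    if "-" in s:
        parts = s.split("-")
        try:
            return (int(parts[0]), int(parts[1]))
        except ValueError:
            return None
    return None


def _value_to_band(value: str) -> Optional[tuple[int, int]]:
    """Floor a numeric measurement to its 10-unit band."""
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    low = int(v // 10) * 10
    return (low, low + 10)


def _int_or_none(text: str) -> Optional[int]:
    try:
        return int(str(text).strip())
    except (TypeError, ValueError):
        return None


def merge_case_level(
    tables: Mapping[str, pd.DataFrame],
    dialect: str,
    lexicon: Optional[Mapping[str, list[str]]] = None,
    event_source: str = "reac",
) -> list[CaseRecord]:
    """Left-merge raw SRS tables into one :class:`CaseRecord` per DEMO row.

    Parameters
    ----------
    tables
        Raw string tables from :func:`srsignal.io.read_jader_tables` or
        :func:`~srsignal.io.read_faers_tables`.
    dialect
        ``"jader"`` or ``"faers"``.  FAERS demographics are deduplicated by
        case version before merging.
    lexicon
        Canonical->synonyms drug lexicon; defaults to the fibrate lexicon.
    event_source
        JADER only: which table carries the events (``"reac"`` or ``"hist"``).
    """
    compiled = compile_lexicon(lexicon if lexicon is not None else DEFAULT_LEXICON)
    if dialect == "jader":
        return _merge_jader(tables, compiled, event_source)
    if dialect == "faers":
        return _merge_faers(tables, compiled)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _group_indices(keys) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        out.setdefault(k, []).append(i)
    return out


class _Memo:
    """Memoized unary function; SRS columns repeat a few distinct values."""

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict = {}

    def __call__(self, value):
        try:
            return self.cache[value]
        except KeyError:
            result = self.fn(value)
            self.cache[value] = result
            return result


def _merge_jader(
    tables: Mapping[str, pd.DataFrame],
    compiled: Mapping[str, str],
    event_source: str,
) -> list[CaseRecord]:
    demo = tables["demo"]
    drug = tables.get("drug", pd.DataFrame())
    events_df = tables.get(event_source, pd.DataFrame())

    n = len(demo)
    cid_a = _column(demo, "case_id")
    if cid_a is None:
        raise ValueError("demo table lacks a case identifier column")
    sex_a = _column(demo, "sex")
    age_a = _column(demo, "age")
    height_a = _column(demo, "height")
    weight_a = _column(demo, "weight")
    reporter_a = _column(demo, "reporter")
    year_a = _column(demo, "report_year")

    d_cid = _column(drug, "case_id") if not drug.empty else None
    e_cid = _column(events_df, "case_id") if not events_df.empty else None
    drug_idx = _group_indices(d_cid) if d_cid is not None else {}
    evt_idx = _group_indices(e_cid) if e_cid is not None else {}
    d_name = _column(drug, "drug_name")
    d_role = _column(drug, "role")
    d_start = _column(drug, "ther_start")
    d_end = _column(drug, "ther_end")
    e_name = _column(events_df, "pt_name")
    e_code = _column(events_df, "pt_code")
    e_onset = _column(events_df, "onset")

    age_memo = _Memo(parse_age_band)
    band_memo = _Memo(parse_anthro_band)
    match_memo = _Memo(lambda raw: match_drug(raw, compiled))
    year_memo = _Memo(_int_or_none)

    cases: list[CaseRecord] = []
    seen: set[str] = set()
    for i in range(n):
        cid = cid_a[i]
        seen.add(cid)
        rec = CaseRecord(
            case_id=cid,
            sex=_JADER_SEX.get(sex_a[i], Sex.UNKNOWN) if sex_a is not None else Sex.UNKNOWN,
            age_band=age_memo(age_a[i]) if age_a is not None else None,
            height_band_cm=band_memo(height_a[i]) if height_a is not None else None,
            weight_band_kg=band_memo(weight_a[i]) if weight_a is not None else None,
            reporter=_JADER_REPORTER.get(reporter_a[i], Reporter.UNKNOWN)
            if reporter_a is not None
            else Reporter.UNKNOWN,
            report_year=year_memo(year_a[i]) if year_a is not None else None,
        )
        for j in drug_idx.get(cid, ()):
            raw = d_name[j] if d_name is not None else ""
            rec.drugs.append(
                DrugEntry(
                    raw_name=raw,
                    canonical_drug=match_memo(raw),
                    role=_JADER_ROLE.get(
                        d_role[j] if d_role is not None else "",
                        Role.SUSPECT_UNSPECIFIED,
                    ),
                    therapy_start=parse_partial_date(
                        d_start[j] if d_start is not None else ""
                    ),
                    therapy_end=parse_partial_date(
                        d_end[j] if d_end is not None else ""
                    ),
                )
            )
        for j in evt_idx.get(cid, ()):
            pt_name = e_name[j] if e_name is not None else ""
            pt_code = (e_code[j] if e_code is not None else "") or pt_name
            if not pt_code:
                continue
            rec.events.append(
                EventEntry(
                    pt_code=pt_code,
                    pt_name=pt_name,
                    onset=parse_partial_date(e_onset[j] if e_onset is not None else ""),
                )
            )
        cases.append(rec)

    _log_orphans("drug", drug_idx, seen)
    _log_orphans(event_source, evt_idx, seen)
    return cases


def _log_orphans(
    table: str, by_case: Mapping[str, list], parents: set[str]
) -> None:
    n = sum(len(rows) for cid, rows in by_case.items() if cid not in parents)
    if n:
        logger.warning("%s: dropped %d orphan row(s) without a DEMO parent", table, n)


def _faers_age_band(age: str, age_cod: str) -> Optional[str]:
    try:
        v = float(age)
    except (TypeError, ValueError):
        return None
    cod = (age_cod or "YR").strip().upper()
    years = {"YR": v, "DEC": v * 10, "MON": v / 12, "WK": v / 52, "DY": v / 365.25}.get(
        cod
    )
    if years is None:
        return None
    return age_years_to_band(years)


def _faers_column(df: pd.DataFrame, name: str):
    if df is None or df.empty or name not in df.columns:
        return None
    return df[name].fillna("").astype(str).str.strip().to_numpy()


def _merge_faers(
    tables: Mapping[str, pd.DataFrame], compiled: Mapping[str, str]
) -> list[CaseRecord]:
    demo = dedup_faers(tables["demo"])
    drug = tables.get("drug", pd.DataFrame())
    reac = tables.get("reac", pd.DataFrame())
    ther = tables.get("ther", pd.DataFrame())

    d_pid = _faers_column(drug, "primaryid")
    r_pid = _faers_column(reac, "primaryid")
    drug_idx = _group_indices(d_pid) if d_pid is not None else {}
    reac_idx = _group_indices(r_pid) if r_pid is not None else {}
    d_name = _faers_column(drug, "drugname")
    d_role = _faers_column(drug, "role_cod")
    d_seq = _faers_column(drug, "drug_seq")
    r_pt = _faers_column(reac, "pt")

    ther_by_key: dict[tuple[str, str], tuple] = {}
    t_pid = _faers_column(ther, "primaryid")
    if t_pid is not None:
        t_seq = _faers_column(ther, "dsg_drug_seq")
        t_start = _faers_column(ther, "start_dt")
        t_end = _faers_column(ther, "end_dt")
        for j in range(len(t_pid)):
            key = (t_pid[j], t_seq[j] if t_seq is not None else "")
            if key not in ther_by_key:
                ther_by_key[key] = (
                    parse_partial_date(t_start[j]) if t_start is not None else None,
                    parse_partial_date(t_end[j]) if t_end is not None else None,
                )

    pid_a = _faers_column(demo, "primaryid")
    cid_a = _faers_column(demo, "caseid")
    ver_a = _faers_column(demo, "caseversion")
    sex_a = _faers_column(demo, "sex")
    age_a = _faers_column(demo, "age")
    agec_a = _faers_column(demo, "age_cod")
    wt_a = _faers_column(demo, "wt")
    occp_a = _faers_column(demo, "occp_cod")
    evdt_a = _faers_column(demo, "event_dt")
    fda_a = _faers_column(demo, "fda_dt")

    match_memo = _Memo(lambda raw: match_drug(raw, compiled))
    wt_memo = _Memo(_value_to_band)

    cases: list[CaseRecord] = []
    seen_pids: set[str] = set()
    for i in range(len(demo)):
        pid = pid_a[i] if pid_a is not None else ""
        seen_pids.add(pid)
        event_dt = parse_partial_date(evdt_a[i]) if evdt_a is not None else None
        occp = (occp_a[i] if occp_a is not None else "").upper()
        reporter = (
            Reporter.HEALTHCARE_PROFESSIONAL
            if occp in _FAERS_HCP
            else Reporter.CONSUMER
            if occp == "CN"
            else Reporter.UNKNOWN
        )
        fda = parse_partial_date(fda_a[i]) if fda_a is not None else None
        rec = CaseRecord(
            case_id=cid_a[i] if cid_a is not None else pid,
            case_version=_int_or_none(ver_a[i]) if ver_a is not None else None,
            sex=_FAERS_SEX.get((sex_a[i] if sex_a is not None else "").upper(), Sex.UNKNOWN),
            age_band=_faers_age_band(
                age_a[i] if age_a is not None else "",
                agec_a[i] if agec_a is not None else "",
            ),
            height_band_cm=None,  # FAERS demographics carry no height
            weight_band_kg=wt_memo(wt_a[i]) if wt_a is not None else None,
            reporter=reporter,
            report_year=fda.year if fda else None,
        )
        for j in drug_idx.get(pid, ()):
            raw = d_name[j] if d_name is not None else ""
            start, end = ther_by_key.get(
                (pid, d_seq[j] if d_seq is not None else ""), (None, None)
            )
            rec.drugs.append(
                DrugEntry(
                    raw_name=raw,
                    canonical_drug=match_memo(raw),
                    role=_FAERS_ROLE.get(
                        (d_role[j] if d_role is not None else "").upper(),
                        Role.SUSPECT_UNSPECIFIED,
                    ),
                    therapy_start=start,
                    therapy_end=end,
                )
            )
        for j in reac_idx.get(pid, ()):
            pt = r_pt[j] if r_pt is not None else ""
            if not pt:
                continue
            # FAERS records one event date per case, not per reaction
            rec.events.append(EventEntry(pt_code=pt, pt_name=pt, onset=event_dt))
        cases.append(rec)

    for name, by_pid in (("drug", drug_idx), ("reac", reac_idx)):
        n = sum(len(rows) for pid, rows in by_pid.items() if pid not in seen_pids)
        if n:
            logger.warning(
                "%s: dropped %d orphan row(s) (no parent after dedup)", name, n
            )
    return cases


def expand_pairs(
    cases: Iterable[CaseRecord], collapse_duplicates: bool = False
) -> list[DrugEventPair]:
    """Expand cases into one pair per (drug occurrence, event occurrence).

    A report listing ``k`` drugs and ``m`` events yields ``k*m`` pairs.  With
    ``collapse_duplicates`` identical (case, drug, event, role) pairs arising
    from repeated drug listings collapse to one.
    """
    pairs: list[DrugEventPair] = []
    for case in cases:
        for d in case.drugs:
            ident = d.identity
            if not ident:
                continue
            for e in case.events:
                pairs.append(
                    DrugEventPair(
                        case_id=case.case_id,
                        drug=ident,
                        pt_code=e.pt_code,
                        role=d.role,
                    )
                )
    if collapse_duplicates:
        pairs = list(dict.fromkeys(pairs))
    return pairs


def filter_primary_suspect(pairs: Iterable[DrugEventPair]) -> list[DrugEventPair]:
    """Restrict pairs to primary-suspect drug listings (sensitivity analysis)."""
    return [p for p in pairs if p.role is Role.PRIMARY_SUSPECT]


def count_unique_icsrs(
    pairs: Iterable[DrugEventPair],
    drug_set: "Sequence[str] | set[str]",
    event_set: "Sequence[str] | set[str]",
) -> int:
    """Number of distinct cases with >=1 pair in ``drug_set`` x ``event_set``.

    Agent-level pair counts are not mutually exclusive (one report can list
    several target drugs); this is the honest report-level denominator.
    """
    drugs, events = set(drug_set), set(event_set)
    return len(
        {p.case_id for p in pairs if p.drug in drugs and p.pt_code in events}
    )
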