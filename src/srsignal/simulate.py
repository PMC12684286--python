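"""Synthetic SRS generator with known ground-truth association strength.

Generative model, per report: demographics are sampled from configured
marginals; each drug is taken independently with its exposure probability and
receives a reporter role; each event's reporting odds are

    odds(e) = baseline_odds(e) * prod over exposed drugs d of theta(d, e),

converted to a probability p = odds/(1+odds).  ``theta`` therefore is a
report-level odds multiplier: with no co-association on the same event, the
population reporting odds ratio of the (drug, event) report-level 2x2 table
equals theta exactly, which makes parameter recovery a clean end-to-end test.
Onsets for (drug, event) combinations governed by a Weibull time-to-onset law
fall ``round(Weibull(alpha, beta))`` days after that drug's therapy start;
other realized events get an arbitrary date.  Date components are blanked
with a configurable probability, and FAERS cases are emitted twice (with an
incremented case version) with the duplication probability.

The same draw is rendered in both dialects so every downstream stage can be
tested without database downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SimConfig",
    "SimConfigError",
    "ConfoundedEstimandError",
    "SimulatedData",
    "simulate_reports",
    "true_ror",
    "default_sim_config",
]

_ROLE_CODES = ("PS", "SS", "C", "I")
_JADER_ROLE_RENDER = {"PS": "被疑薬", "SS": "被疑薬", "C": "併用薬", "I": "相互作用"}

_EPOCH_START = np.datetime64("2015-01-01").astype("datetime64[D]").astype(int)
_WINDOW_DAYS = 3287  # 2015-01-01 .. 2023-12-31


class SimConfigError(ValueError):
    def __init__(self, violations: list[str]):
        super().__init__("invalid SimConfig: " + "; ".join(violations))
        self.violations = violations


class ConfoundedEstimandError(ValueError):
    """The queried reporting odds ratio is not identified by a single theta."""


@dataclass(frozen=True)
class DrugSpec:
    name: str
    exposure_prob: float
    role_distribution: dict[str, float] = field(
        default_factory=lambda: {"PS": 0.55, "SS": 0.15, "C": 0.25, "I": 0.05}
    )
    jader_name: Optional[str] = None  # display name in the JADER rendering
    faers_name: Optional[str] = None


@dataclass(frozen=True)
class EventSpec:
    pt_code: str
    pt_name: str
    baseline_odds: float


@dataclass
class SimConfig:
    n_reports: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    association_theta: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_ratio_male: float = 0.55
    age_band_probs: dict[str, float] = field(default_factory=dict)
    height_band_probs: dict[object, float] = field(default_factory=dict)
    weight_band_probs: dict[object, float] = field(default_factory=dict)
    tto_law: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    date_missing_prob: float = 0.2
    duplicate_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`SimConfigError` listing every violation at once."""
        v: list[str] = []
        if self.n_reports < 1:
            v.append("n_reports must be >= 1")
        if not self.drugs:
            v.append("at least one drug is required")
        if not self.events:
            v.append("at least one event is required")
        drug_names = {d.name for d in self.drugs}
        event_codes = {e.pt_code for e in self.events}
        if len(drug_names) != len(self.drugs):
            v.append("duplicate drug names")
        if len(event_codes) != len(self.events):
            v.append("duplicate event pt_codes")
        for d in self.drugs:
            if not 0 <= d.exposure_prob <= 1:
                v.append(f"exposure_prob out of [0,1] for {d.name}")
            s = sum(d.role_distribution.values())
            if abs(s - 1.0) > 1e-9 or any(
                p < 0 for p in d.role_distribution.values()
            ):
                v.append(f"role_distribution of {d.name} is not a distribution")
            if set(d.role_distribution) - set(_ROLE_CODES):
                v.append(f"unknown role code in role_distribution of {d.name}")
        for e in self.events:
            if e.baseline_odds <= 0:
                v.append(f"baseline_odds must be positive for {e.pt_code}")
        for (dn, ec), th in self.association_theta.items():
            if th <= 0:
                v.append(f"association_theta must be positive for ({dn},{ec})")
            if dn not in drug_names or ec not in event_codes:
                v.append(f"association_theta refers to unknown pair ({dn},{ec})")
        for (dn, ec), (a, b) in self.tto_law.items():
            if a <= 0 or b <= 0:
                v.append(f"tto_law alpha/beta must be positive for ({dn},{ec})")
            if dn not in drug_names or ec not in event_codes:
                v.append(f"tto_law refers to unknown pair ({dn},{ec})")
        if not 0 <= self.sex_ratio_male <= 1:
            v.append("sex_ratio_male out of [0,1]")
        for label, probs in (
            ("age_band_probs", self.age_band_probs),
            ("height_band_probs", self.height_band_probs),
            ("weight_band_probs", self.weight_band_probs),
        ):
            if probs:
                if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                    v.append(f"{label} is not a distribution")
        for label, p in (
            ("date_missing_prob", self.date_missing_prob),
            ("duplicate_prob", self.duplicate_prob),
        ):
            if not 0 <= p <= 1:
                v.append(f"{label} out of [0,1]")
        if v:
            raise SimConfigError(v)


@dataclass
class SimulatedData:
    jader: dict[str, pd.DataFrame]
    faers: dict[str, pd.DataFrame]
    config: SimConfig


def true_ror(config: SimConfig, drug: str, event: str) -> float:
    """Ground-truth report-level reporting odds ratio implied by the model.

    Equals theta(drug, event); defaults to 1.  Raises
    :class:`ConfoundedEstimandError` when another drug carries theta != 1 for
    the same event, since co-exposure mixing then biases the marginal table.
    """
    for (dn, ec), th in config.association_theta.items():
        if ec == event and dn != drug and th != 1.0:
            raise ConfoundedEstimandError(
                f"event {event} is also associated with {dn}; "
                "the marginal ROR is not theta"
            )
    return float(config.association_theta.get((drug, event), 1.0))


def _fmt_dates(ordinals: np.ndarray, day_missing: np.ndarray) -> np.ndarray:
    """Render day-epoch integers as YYYYMMDD, or YYYYMM where day is blanked."""
    iso = ordinals.astype("datetime64[D]").astype(str)  # YYYY-MM-DD
    full = np.char.replace(iso, "-", "")
    trunc = full.astype("<U6")
    return np.where(day_missing, trunc, full).astype(object)


def _df(columns: dict) -> pd.DataFrame:
    """DataFrame from string columns, coerced to object dtype up front.

    pandas re-sanitizes fixed-width unicode arrays element-wise, which
    dominates runtime at SRS scale; converting once here avoids that.
    """
    out = {}
    for k, v in columns.items():
        if isinstance(v, np.ndarray) and v.dtype.kind in ("U", "S"):
            v = v.astype(object)
        out[k] = v
    return pd.DataFrame(out)


def _within_case_seq(rows_i: np.ndarray, n: int) -> np.ndarray:
    """1-based position of each child row within its (sorted) case block."""
    if rows_i.size == 0:
        return np.array([], dtype=int)
    counts = np.bincount(rows_i, minlength=n)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    return np.arange(rows_i.size) - offsets + 1


def _sample_categorical(
    rng: np.random.Generator, probs: dict, size: int
) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array([probs[k] for k in keys], dtype=float)
    idx = rng.choice(len(keys), size=size, p=p)
    return keys[idx]


def simulate_reports(
    config: SimConfig, dialects: tuple[str, ...] = ("jader", "faers")
) -> SimulatedData:
    """Draw one synthetic dataset and render it in both dialects.

    The same underlying reports appear in the JADER and FAERS renderings;
    the FAERS demographics table additionally contains duplicate case
    versions.  Identical configs (including seed) produce identical tables.
    ``dialects`` restricts rendering when only one output is needed; the
    underlying draw is identical either way.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    D, E = len(config.drugs), len(config.events)
    drug_names = [d.name for d in config.drugs]
    event_codes = [e.pt_code for e in config.events]

    # demographics ---------------------------------------------------------
    male = rng.random(n) < config.sex_ratio_male
    age = _sample_categorical(rng, config.age_band_probs or {"60s": 1.0}, n)
    height = _sample_categorical(rng, config.height_band_probs or {160: 1.0}, n)
    weight = _sample_categorical(rng, config.weight_band_probs or {60: 1.0}, n)
    reporter = _sample_categorical(
        rng, {"hcp": 0.95, "consumer": 0.04, "unknown": 0.01}, n
    )

    # exposures and roles --------------------------------------------------
    expos_p = np.array([d.exposure_prob for d in config.drugs])
    X = rng.random((n, D)) < expos_p
    roles = np.empty((n, D), dtype=object)
    for j, d in enumerate(config.drugs):
        dist = {k: d.role_distribution.get(k, 0.0) for k in _ROLE_CODES}
        roles[:, j] = _sample_categorical(rng, dist, n)
    starts = _EPOCH_START + rng.integers(0, _WINDOW_DAYS, size=(n, D))

    # events ---------------------------------------------------------------
    log_theta = np.zeros((D, E))
    for (dn, ec), th in config.association_theta.items():
        log_theta[drug_names.index(dn), event_codes.index(ec)] = math.log(th)
    log_odds = np.log([e.baseline_odds for e in config.events])[None, :] + X @ log_theta
    p = 1.0 / (1.0 + np.exp(-log_odds))
    Y = rng.random((n, E)) < p

    # onsets: Weibull law where configured, else arbitrary date ------------
    onsets = _EPOCH_START + rng.integers(0, _WINDOW_DAYS, size=(n, E))
    assigned = np.zeros((n, E), dtype=bool)
    for (dn, ec), (alpha, beta) in config.tto_law.items():
        j, k = drug_names.index(dn), event_codes.index(ec)
        mask = X[:, j] & Y[:, k] & ~assigned[:, k]
        m = int(mask.sum())
        if m:
            delay = np.floor(alpha * rng.weibull(beta, size=m) + 0.5).astype(int)
            onsets[mask, k] = starts[mask, j] + np.maximum(delay, 0)
            assigned[mask, k] = True

    start_day_missing = rng.random((n, D)) < config.date_missing_prob
    onset_day_missing = rng.random((n, E)) < config.date_missing_prob
    duplicated = rng.random(n) < config.duplicate_prob

    # report year: latest event onset, else latest start, else window end
    year_anchor = np.where(
        Y.any(axis=1),
        np.where(Y, onsets, -(10**9)).max(axis=1),
        np.where(X, starts, -(10**9)).max(axis=1),
    )
    year_anchor = np.where(
        year_anchor > -(10**9), year_anchor, _EPOCH_START + _WINDOW_DAYS - 1
    )
    report_year = 1970 + year_anchor // 365.25
    report_year = report_year.astype(int)

    ctx = {
        "n": n,
        "male": male,
        "age": age,
        "height": height,
        "weight": weight,
        "reporter": reporter,
        "X": X,
        "roles": roles,
        "starts": starts,
        "Y": Y,
        "onsets": onsets,
        "start_day_missing": start_day_missing,
        "onset_day_missing": onset_day_missing,
        "duplicated": duplicated,
        "report_year": report_year,
    }
    return SimulatedData(
        jader=_render_jader(config, ctx) if "jader" in dialects else {},
        faers=_render_faers(config, ctx) if "faers" in dialects else {},
        config=config,
    )


def _case_ids_jader(n: int) -> np.ndarray:
    return np.char.add("JP", np.char.zfill((np.arange(n) + 1).astype(str), 8))


def _apply_unique(values: np.ndarray, fn) -> np.ndarray:
    """Apply ``fn`` per distinct value only; SRS columns have small domains."""
    s = values.astype(str)
    uniq, inverse = np.unique(s, return_inverse=True)
    mapped = np.array([fn(u) for u in uniq], dtype=object)
    return mapped[inverse]


def _render_band(values: np.ndarray, suffix: str, strip_s: bool = False) -> np.ndarray:
    """Render band labels (``"60s"``/``160``) as JADER text; unknown -> blank."""

    def fn(u: str) -> str:
        if u == "unknown":
            return ""
        return (u[:-1] if strip_s else u) + suffix

    return _apply_unique(values, fn)


def _map_values(values: np.ndarray, mapping: dict[str, str], default: str) -> np.ndarray:
    return _apply_unique(values, lambda u: mapping.get(u, default))


def _render_jader(config: SimConfig, ctx: dict) -> dict[str, pd.DataFrame]:
    n = ctx["n"]
    cids = _case_ids_jader(n)
    demo = _df(
        {
            "識別番号": cids,
            "性別": np.where(ctx["male"], "男性", "女性"),
            "年齢": _render_band(ctx["age"], strip_s=True, suffix="歳代"),
            "身長": _render_band(ctx["height"], suffix="cm台"),
            "体重": _render_band(ctx["weight"], suffix="kg台"),
            "報告者職種": _map_values(
                ctx["reporter"], {"hcp": "医療関係者", "consumer": "消費者"}, ""
            ),
            "報告年": ctx["report_year"].astype(str),
        }
    )

    rows_i, rows_j = np.nonzero(ctx["X"])
    start_strs = _fmt_dates(
        ctx["starts"][rows_i, rows_j], ctx["start_day_missing"][rows_i, rows_j]
    )
    seq = _within_case_seq(rows_i, n)
    drug = _df(
        {
            "識別番号": cids[rows_i],
            "医薬品連番": seq.astype(str),
            "医薬品の関与": _map_values(
                ctx["roles"][rows_i, rows_j], _JADER_ROLE_RENDER, "被疑薬"
            ),
            "医薬品（一般名）": np.array(
                [(d.jader_name or d.name) for d in config.drugs], dtype=object
            )[rows_j],
            "投与開始日": start_strs,
            "投与終了日": "",
        }
    )

    ev_i, ev_k = np.nonzero(ctx["Y"])
    onset_strs = _fmt_dates(
        ctx["onsets"][ev_i, ev_k], ctx["onset_day_missing"][ev_i, ev_k]
    )
    reac = _df(
        {
            "識別番号": cids[ev_i],
            "有害事象": np.array([e.pt_name for e in config.events], dtype=object)[ev_k],
            "有害事象コード": np.array(
                [e.pt_code for e in config.events], dtype=object
            )[ev_k],
            "発現日": onset_strs,
        }
    )
    hist = pd.DataFrame(columns=["識別番号", "有害事象", "有害事象コード", "発現日"])
    return {"demo": demo, "drug": drug, "reac": reac, "hist": hist}


def _render_faers(config: SimConfig, ctx: dict) -> dict[str, pd.DataFrame]:
    n = ctx["n"]
    caseids = (20_000_000 + np.arange(n)).astype(str)
    versions_per_case = np.where(ctx["duplicated"], 2, 1)

    # one block of child rows per emitted version; duplicates are exact
    # copies apart from caseversion and primaryid
    rep_case_idx = np.repeat(np.arange(n), versions_per_case)
    version_no = _within_case_seq(rep_case_idx, n)
    primaryids = np.char.add(caseids[rep_case_idx], version_no.astype(str))

    first_onset = np.where(ctx["Y"], ctx["onsets"], 2**31).min(axis=1)
    has_event = ctx["Y"].any(axis=1)
    event_dt = np.where(
        has_event,
        _fmt_dates(first_onset, ctx["onset_day_missing"].any(axis=1) & has_event),
        "",
    )
    age_mid = _apply_unique(
        ctx["age"], lambda u: "" if u == "unknown" else str(int(u[:-1]) + 5)
    )
    wt_mid = _apply_unique(
        ctx["weight"], lambda u: "" if u == "unknown" else str(int(u) + 5)
    )
    occp = _map_values(ctx["reporter"], {"hcp": "MD", "consumer": "CN"}, "")
    demo = _df(
        {
            "primaryid": primaryids,
            "caseid": caseids[rep_case_idx],
            "caseversion": version_no.astype(str),
            "event_dt": event_dt[rep_case_idx],
            "sex": np.where(ctx["male"], "M", "F")[rep_case_idx],
            "age": age_mid[rep_case_idx],
            "age_cod": np.where(age_mid != "", "YR", "")[rep_case_idx],
            "wt": wt_mid[rep_case_idx],
            "wt_cod": np.where(wt_mid != "", "KG", "")[rep_case_idx],
            "occp_cod": occp[rep_case_idx],
            "fda_dt": np.char.add(
                ctx["report_year"].astype(str), "0701"
            )[rep_case_idx],
        }
    )

    rows_i, rows_j = np.nonzero(ctx["X"])
    seq = _within_case_seq(rows_i, n)
    start_strs = _fmt_dates(
        ctx["starts"][rows_i, rows_j], ctx["start_day_missing"][rows_i, rows_j]
    )
    drug_blocks, ther_blocks, reac_blocks = [], [], []
    ev_i, ev_k = np.nonzero(ctx["Y"])
    pt_names = np.array([e.pt_name for e in config.events], dtype=object)[ev_k]
    faers_names = np.array(
        [(d.faers_name or d.name).upper() for d in config.drugs], dtype=object
    )[rows_j]
    for version in (1, 2):
        keep_case = versions_per_case >= version
        pid_by_case = np.char.add(caseids, str(version))
        d_keep = keep_case[rows_i]
        drug_blocks.append(
            _df(
                {
                    "primaryid": pid_by_case[rows_i[d_keep]],
                    "caseid": caseids[rows_i[d_keep]],
                    "drug_seq": seq[d_keep].astype(str),
                    "role_cod": ctx["roles"][rows_i[d_keep], rows_j[d_keep]],
                    "drugname": faers_names[d_keep],
                }
            )
        )
        ther_blocks.append(
            _df(
                {
                    "primaryid": pid_by_case[rows_i[d_keep]],
                    "caseid": caseids[rows_i[d_keep]],
                    "dsg_drug_seq": seq[d_keep].astype(str),
                    "start_dt": start_strs[d_keep],
                    "end_dt": "",
                }
            )
        )
        e_keep = keep_case[ev_i]
        reac_blocks.append(
            _df(
                {
                    "primaryid": pid_by_case[ev_i[e_keep]],
                    "caseid": caseids[ev_i[e_keep]],
                    "pt": pt_names[e_keep],
                }
            )
        )
    drug = pd.concat(drug_blocks, ignore_index=True)
    ther = pd.concat(ther_blocks, ignore_index=True)
    reac = pd.concat(reac_blocks, ignore_index=True)
    outc = _df(
        {
            "primaryid": primaryids,
            "caseid": caseids[rep_case_idx],
            "outc_cod": np.where(has_event[rep_case_idx], "OT", ""),
        }
    )
    return {"demo": demo, "drug": drug, "reac": reac, "ther": ther, "outc": outc}


# ---------------------------------------------------------------------------
# canonical study conditions
# ---------------------------------------------------------------------------

#: MedDRA-style PT codes used by the default configuration
PT_CHOLELITHIASIS = "10008629"
PT_CHOLECYSTITIS = "10008612"
PT_CHOLECYSTITIS_ACUTE = "10008614"


def default_sim_config(
    seed: int = 0,
    n_reports: int = 50_000,
    theta: Optional[dict[tuple[str, str], float]] = None,
) -> SimConfig:
    """The canonical synthetic study conditions.

    Three fibrates at realistic SRS exposure frequencies plus eight common
    background drugs; three biliary target PTs at low baseline reporting odds
    plus six background events (one high-frequency, so most reports carry at
    least one event).  The default association links pemafibrate to each
    biliary PT with an odds multiplier of 3.74, and biliary onsets under
    pemafibrate follow per-PT Weibull laws with scales near 470 days and
    shapes bracketing 1.6 (increasing hazard).  Pass ``theta`` to override
    the association map (e.g. a null or a stronger signal).
    """
    drugs = [
        DrugSpec("pemafibrate", 0.020, jader_name="ペマフィブラート", faers_name="PEMAFIBRATE"),
        DrugSpec("fenofibrate", 0.015, jader_name="フェノフィブラート", faers_name="FENOFIBRIC ACID"),
        DrugSpec("bezafibrate", 0.008, jader_name="ベザフィブラート", faers_name="BEZAFIBRATE"),
        DrugSpec("ASPIRIN", 0.20),
        DrugSpec("ATORVASTATIN", 0.15),
        DrugSpec("METFORMIN", 0.12),
        DrugSpec("AMLODIPINE", 0.12),
        DrugSpec("OMEPRAZOLE", 0.12),
        DrugSpec("LOXOPROFEN", 0.10),
        DrugSpec("ALLOPURINOL", 0.08),
        DrugSpec("WARFARIN", 0.06),
    ]
    events = [
        EventSpec(PT_CHOLELITHIASIS, "Cholelithiasis", 0.004),
        EventSpec(PT_CHOLECYSTITIS, "Cholecystitis", 0.002),
        EventSpec(PT_CHOLECYSTITIS_ACUTE, "Cholecystitis acute", 0.0015),
        EventSpec("10013709", "Drug ineffective", 0.25),
        EventSpec("10028813", "Nausea", 0.08),
        EventSpec("10012735", "Diarrhoea", 0.07),
        EventSpec("10037844", "Rash", 0.06),
        EventSpec("10019670", "Hepatic function abnormal", 0.05),
        EventSpec("10019211", "Headache", 0.05),
    ]
    biliary = (PT_CHOLELITHIASIS, PT_CHOLECYSTITIS, PT_CHOLECYSTITIS_ACUTE)
    if theta is None:
        theta = {("pemafibrate", pt): 3.74 for pt in biliary}
    tto_law = {
        ("pemafibrate", PT_CHOLELITHIASIS): (486.0, 2.05),
        ("pemafibrate", PT_CHOLECYSTITIS): (448.0, 1.29),
        ("pemafibrate", PT_CHOLECYSTITIS_ACUTE): (448.0, 1.29),
    }
    return SimConfig(
        n_reports=n_reports,
        drugs=drugs,
        events=events,
        association_theta=dict(theta),
        sex_ratio_male=0.55,
        age_band_probs={
            "10s": 0.02,
            "20s": 0.06,
            "30s": 0.09,
            "40s": 0.13,
            "50s": 0.16,
            "60s": 0.21,
            "70s": 0.19,
            "80s": 0.10,
            "unknown": 0.04,
        },
        height_band_probs={140: 0.08, 150: 0.28, 160: 0.33, 170: 0.19, 180: 0.04, "unknown": 0.08},
        weight_band_probs={40: 0.12, 50: 0.26, 60: 0.28, 70: 0.17, 80: 0.07, 90: 0.02, "unknown": 0.08},
        tto_law=tto_law,
        date_missing_prob=0.2,
        duplicate_prob=0.05,
        seed=seed,
    )
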