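"""Orchestration: primary, sensitivity, stratified, and time-to-onset runs.

Each ``run_*`` function takes merged case records plus the config mapping and
returns a tidy table (one row per drug, or per drug x stratum).  ``run_all``
bundles them and, given an output directory, writes a human CSV (two
decimals), a full-precision JSON mirror, and a meta record carrying the
config hash and seed so outputs are reproducible and self-describing.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from .cases import (
    count_unique_icsrs,
    expand_pairs,
    filter_primary_suspect,
    merge_case_level,
)
from .config import target_event_ids
from .contingency import (
    MetricResult,
    apply_signal_rules,
    bcpnn_ic,
    build_contingency,
    build_contingency_icsr,
    prr,
    ror,
)
from .gps import GPSConvergenceError, cell_counts, gps_fit, gps_posterior, pair_frame, target_cell
from .model import CaseRecord, Role
from .strata import STRATUM_LEVELS, analyze_stratum, sex_age_stratum, StratumSpec
from .tto import (
    bootstrap_weibull,
    collect_tto,
    tto_descriptives,
    weibull_plot_data,
)

__all__ = [
    "run_primary",
    "run_sensitivity",
    "run_stratified",
    "run_tto",
    "run_all",
    "config_hash",
]

logger = logging.getLogger(__name__)

ALL_DRUGS_ROW = "all_fibrates"


def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _metric_cols(m: Optional[MetricResult], prefix: str) -> dict[str, float]:
    if m is None:
        m = MetricResult.undefined(prefix, math.nan)
    out = {
        f"{prefix}": m.estimate,
        f"{prefix}_lower": m.lower,
        f"{prefix}_upper": m.upper,
    }
    for k, v in m.aux.items():
        out[f"{prefix}_{k}" if k not in ("p_value", "chi_square", "expected") else k] = v
    return out


def _analysis_options(config: Mapping[str, Any]) -> dict[str, Any]:
    a = config["analysis"]
    return {
        "level": float(a.get("level", 0.95)),
        "continuity": bool(a.get("continuity_correction", False)),
        "yates": bool(a.get("yates", True)),
        "table_unit": a.get("table_unit", "pair"),
        "event_source": a.get("event_source", "reac"),
        "gps_init": tuple(a.get("gps", {}).get("init", (1 / 3, 0.2, 0.1, 2.0, 4.0))),
        "gps_restarts": int(a.get("gps", {}).get("restarts", 4)),
        "strata": list(a.get("strata", ["sex", "age", "bmi"])),
    }


def _restrict_to_primary_suspect(cases: Sequence[CaseRecord]) -> list[CaseRecord]:
    out = []
    for c in cases:
        c2 = copy.copy(c)
        c2.drugs = [d for d in c.drugs if d.role is Role.PRIMARY_SUSPECT]
        c2.events = list(c.events)
        out.append(c2)
    return out


def _fit_gps(cases, pairs, opts, stratified: bool, seed: int):
    strata = (
        {c.case_id: sex_age_stratum(c) for c in cases} if stratified else None
    )
    frame = pair_frame(pairs, strata)
    cells = cell_counts(frame)
    try:
        hyper = gps_fit(
            cells["n"].to_numpy(),
            cells["E"].to_numpy(),
            init=opts["gps_init"],
            n_restarts=opts["gps_restarts"],
            seed=seed,
        )
    except GPSConvergenceError as exc:
        if exc.best is None:
            raise
        logger.warning("GPS fit did not formally converge; using best-so-far")
        hyper = exc.best
    return frame, hyper


def _disproportionality_table(
    cases: Sequence[CaseRecord],
    pairs,
    config: Mapping[str, Any],
    dialect: str,
    analysis: str,
    seed: int,
    compute_ebgm: bool,
) -> pd.DataFrame:
    opts = _analysis_options(config)
    events = target_event_ids(config, dialect)
    drug_names = list(config["drugs"].keys())
    all_drugs = set(drug_names)

    gps_frame = hyper = None
    if compute_ebgm and pairs:
        try:
            gps_frame, hyper = _fit_gps(
                cases, pairs, opts, stratified=(dialect == "jader"), seed=seed
            )
        except (ValueError, GPSConvergenceError) as exc:
            logger.warning("EBGM skipped: %s", exc)

    rows = []
    for name in drug_names + [ALL_DRUGS_ROW]:
        drug_set = all_drugs if name == ALL_DRUGS_ROW else {name}
        n_icsr = count_unique_icsrs(pairs, drug_set, events)
        row: dict[str, Any] = {"analysis": analysis, "drug": name, "n_icsr": n_icsr}
        try:
            if opts["table_unit"] == "icsr":
                table = build_contingency_icsr(cases, drug_set, events)
            else:
                table = build_contingency(pairs, drug_set, events)
        except ValueError:
            table = None
        if table is None or table.n11 == 0:
            n11 = table.n11 if table else 0
            row.update({"n11": n11})
            for prefix in ("ror", "prr", "ic", "ebgm"):
                row.update(_metric_cols(None, prefix))
            flags = apply_signal_rules(n11)
        else:
            ror_r = ror(table, opts["level"], opts["continuity"])
            prr_r = prr(table, opts["level"], opts["continuity"], opts["yates"])
            try:
                ic_r = bcpnn_ic(table, opts["level"])
            except ValueError:
                ic_r = MetricResult.undefined("IC", opts["level"])
            ebgm_r = None
            if hyper is not None:
                try:
                    n11_t, e_t = target_cell(gps_frame, drug_set, events)
                    ebgm_r = gps_posterior(n11_t, e_t, hyper)
                except ValueError as exc:
                    logger.warning("EBGM undefined for %s: %s", name, exc)
            row.update({"n11": table.n11})
            row.update(_metric_cols(ror_r, "ror"))
            row.update(_metric_cols(prr_r, "prr"))
            row.update(_metric_cols(ic_r, "ic"))
            row.update(_metric_cols(ebgm_r, "ebgm"))
            flags = apply_signal_rules(
                table.n11, ror_result=ror_r, prr_result=prr_r,
                ic_result=ic_r, ebgm_result=ebgm_r,
            )
        row.update(
            {
                "ror_signal": flags.ror_signal,
                "prr_signal": flags.prr_signal,
                "ic_signal": flags.ic_signal,
                "ebgm_signal": flags.ebgm_signal,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_primary(
    cases: Sequence[CaseRecord],
    config: Mapping[str, Any],
    dialect: str,
    seed: int = 0,
    compute_ebgm: Optional[bool] = None,
) -> pd.DataFrame:
    """Role-agnostic disproportionality: one row per drug plus an all-drugs row.

    ``n11`` counts drug-event pairs; ``n_icsr`` the distinct reports behind
    them (agent-level counts are not mutually exclusive).  EBGM defaults to
    the JADER dialect, where expected counts are pooled over sex x age strata;
    forcing it elsewhere computes an unstratified EBGM with a warning.
    """
    if compute_ebgm is None:
        compute_ebgm = dialect == "jader"
    elif compute_ebgm and dialect != "jader":
        logger.warning("computing unstratified EBGM for dialect %s", dialect)
    pairs = expand_pairs(cases)
    return _disproportionality_table(
        cases, pairs, config, dialect, "primary", seed, compute_ebgm
    )


def run_sensitivity(
    cases: Sequence[CaseRecord],
    config: Mapping[str, Any],
    dialect: str,
    seed: int = 0,
    compute_ebgm: Optional[bool] = None,
) -> pd.DataFrame:
    """Primary analysis restricted to primary-suspect drug listings."""
    if compute_ebgm is None:
        compute_ebgm = dialect == "jader"
    ps_cases = _restrict_to_primary_suspect(cases)
    pairs = filter_primary_suspect(expand_pairs(cases))
    return _disproportionality_table(
        ps_cases, pairs, config, dialect, "sensitivity", seed, compute_ebgm
    )


def run_stratified(
    cases: Sequence[CaseRecord],
    config: Mapping[str, Any],
    dialect: str,
) -> pd.DataFrame:
    """Per-drug metrics recomputed inside each demographic stratum."""
    opts = _analysis_options(config)
    events = target_event_ids(config, dialect)
    rows = []
    for drug in config["drugs"].keys():
        for variable in opts["strata"]:
            for level_name in STRATUM_LEVELS[variable]:
                try:
                    res = analyze_stratum(
                        cases,
                        {drug},
                        events,
                        StratumSpec(variable, level_name),
                        opts["level"],
                        opts["continuity"],
                    )
                except Exception as exc:  # per-stratum failure -> warning
                    logger.warning(
                        "stratum %s=%s failed for %s: %s", variable, level_name, drug, exc
                    )
                    continue
                row: dict[str, Any] = {
                    "analysis": "stratified",
                    "drug": drug,
                    "stratum_variable": variable,
                    "stratum_level": level_name,
                    "n_cases": res.n_cases,
                    "n11": res.table.n11 if res.table else 0,
                }
                for prefix, key in (("ror", "ROR"), ("prr", "PRR"), ("ic", "IC")):
                    row.update(_metric_cols(res.metrics.get(key), prefix))
                row.update(
                    {
                        "ror_signal": res.flags.ror_signal,
                        "prr_signal": res.flags.prr_signal,
                        "ic_signal": res.flags.ic_signal,
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def run_tto(
    cases: Sequence[CaseRecord],
    config: Mapping[str, Any],
    dialect: str,
    seed: int = 0,
) -> dict[str, Any]:
    """Time-to-onset descriptives plus bootstrapped Weibull fits.

    Produces an "overall" row over the whole target event set, one row per
    PT observed at least five times (or explicit ``tto.groups`` from config),
    and the plot-data table for the overall fit.
    """
    tto_cfg = config.get("tto", {})
    drug = tto_cfg.get("drug", "pemafibrate")
    B = int(tto_cfg.get("bootstrap_b", 2000))
    earliest = bool(tto_cfg.get("earliest_only", False))
    events = target_event_ids(config, dialect)

    records, excluded = collect_tto(cases, drug, events, earliest_only=earliest)
    groups: list[tuple[str, set[str]]] = []
    if tto_cfg.get("groups"):
        for g in tto_cfg["groups"]:
            groups.append((g["name"], set(map(str, g["pts"]))))
    else:
        by_pt: dict[str, int] = {}
        for r in records:
            by_pt[r.pt_code] = by_pt.get(r.pt_code, 0) + 1
        for pt, n in sorted(by_pt.items()):
            if n >= 5:
                groups.append((pt, {pt}))
    groups.append(("overall", set(events)))

    out_rows = []
    plot_data = None
    for name, pts in groups:
        days = [r.days for r in records if r.pt_code in pts]
        row: dict[str, Any] = {"group": name, "n": len(days)}
        # percentile bootstrap needs a handful of distinct resamples; below
        # five records the interval is meaningless and the fit often
        # degenerates, so such groups report descriptives only
        if len(days) >= 5 and len(set(days)) > 1:
            fit = bootstrap_weibull(days, B=B, seed=seed)
            desc = tto_descriptives(days)
            row.update(
                {
                    "beta": fit.beta,
                    "beta_lower": fit.beta_ci[0],
                    "beta_upper": fit.beta_ci[1],
                    "alpha": fit.alpha,
                    "alpha_lower": fit.alpha_ci[0],
                    "alpha_upper": fit.alpha_ci[1],
                    "median": desc["median"],
                    "median_lower": fit.median_ci[0],
                    "median_upper": fit.median_ci[1],
                    "q1": desc["q1"],
                    "q3": desc["q3"],
                    "min": desc["min"],
                    "max": desc["max"],
                    "classification": fit.classification,
                }
            )
            if name == "overall":
                plot_data = weibull_plot_data(days, fit)
        elif days:
            desc = tto_descriptives(days)
            row.update({k: desc[k] for k in ("median", "q1", "q3", "min", "max")})
            logger.warning(
                "TTO group %s too small for a Weibull fit (n=%d)", name, len(days)
            )
        out_rows.append(row)

    return {
        "drug": drug,
        "records": records,
        "excluded": excluded,
        "table": pd.DataFrame(out_rows),
        "plot_data": plot_data,
        "bootstrap_b": B,
        "seed": seed,
    }


def run_all(
    tables: Mapping[str, pd.DataFrame],
    config: Mapping[str, Any],
    dialect: str,
    seed: int = 0,
    out_dir: "Optional[Path | str]" = None,
    analyses: Sequence[str] = ("primary", "sensitivity", "stratified", "tto"),
) -> dict[str, Any]:
    """Merge raw tables once and run the selected analyses.

    With ``out_dir`` set, each result is written as a 2-decimal CSV, a
    full-precision JSON mirror, and a shared ``meta.json`` with the config
    hash and seed.
    """
    opts = _analysis_options(config)
    cases = merge_case_level(
        tables, dialect, lexicon=config["drugs"], event_source=opts["event_source"]
    )
    logger.info("merged %d case record(s) [%s]", len(cases), dialect)
    results: dict[str, Any] = {"dialect": dialect, "n_cases": len(cases)}
    if "primary" in analyses:
        results["primary"] = run_primary(cases, config, dialect, seed)
    if "sensitivity" in analyses:
        results["sensitivity"] = run_sensitivity(cases, config, dialect, seed)
    if "stratified" in analyses:
        results["stratified"] = run_stratified(cases, config, dialect)
    if "tto" in analyses:
        results["tto"] = run_tto(cases, config, dialect, seed)
    if out_dir is not None:
        _write_outputs(results, config, dialect, seed, Path(out_dir))
    return results


def _json_default(obj):
    if isinstance(obj, (pd.DataFrame,)):
        return obj.to_dict(orient="records")
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)


def _write_outputs(
    results: Mapping[str, Any],
    config: Mapping[str, Any],
    dialect: str,
    seed: int,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"# config_hash={chash} seed={seed} dialect={dialect}\n"
    for name in ("primary", "sensitivity", "stratified"):
        if name not in results:
            continue
        df: pd.DataFrame = results[name]
        with open(out_dir / f"{name}.csv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.2f", lineterminator="\n")
        payload = {
            "config_hash": chash,
            "seed": seed,
            "dialect": dialect,
            "rows": df.to_dict(orient="records"),
        }
        (out_dir / f"{name}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=_json_default)
        )
    if "tto" in results:
        t = results["tto"]
        with open(out_dir / "tto.csv", "w") as fh:
            fh.write(header)
            t["table"].to_csv(fh, index=False, float_format="%.2f", lineterminator="\n")
        payload = {
            "config_hash": chash,
            "seed": seed,
            "dialect": dialect,
            "drug": t["drug"],
            "excluded": t["excluded"],
            "bootstrap_b": t["bootstrap_b"],
            "rows": t["table"].to_dict(orient="records"),
            "records": [
                {
                    "case_id": r.case_id,
                    "pt_code": r.pt_code,
                    "start": r.start.compact(),
                    "onset": r.onset.compact(),
                    "days": r.days,
                }
                for r in t["records"]
            ],
        }
        (out_dir / "tto.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=_json_default)
        )
        if t["plot_data"] is not None:
            pd.DataFrame(
                {
                    "t": t["plot_data"]["t"],
                    "density": t["plot_data"]["density"],
                    "hazard": t["plot_data"]["hazard"],
                }
            ).to_csv(out_dir / "tto_plotdata.csv", index=False)
    (out_dir / "meta.json").write_text(
        json.dumps(
            {"config_hash": chash, "seed": seed, "dialect": dialect},
            indent=1,
            sort_keys=True,
        )
    )
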