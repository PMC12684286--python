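"""Run configuration: drug lexicon, target event set, analysis options.

Configs are TOML or YAML with sections ``[drugs]`` (canonical name ->
synonym list), ``[events]`` (HLT code plus PT list), ``[analysis]`` and
``[tto]``.  The default target event set is the biliary high-level grouping
"Cholecystitis and cholelithiasis" (HLT code 10008616); the shipped 14-PT
list is a working default that users should confirm against their licensed
MedDRA version, since PT membership is configuration here, not a computed
hierarchy traversal.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Mapping

import yaml

from .lexicon import DEFAULT_LEXICON

__all__ = [
    "DEFAULT_TARGET_HLT",
    "DEFAULT_TARGET_PTS",
    "load_config",
    "target_event_ids",
    "default_config",
]

DEFAULT_TARGET_HLT = "10008616"

#: (pt_code, pt_name) — verify codes against a licensed MedDRA distribution.
DEFAULT_TARGET_PTS: list[tuple[str, str]] = [
    ("10008629", "Cholelithiasis"),
    ("10008612", "Cholecystitis"),
    ("10008614", "Cholecystitis acute"),
    ("10008617", "Cholecystitis chronic"),
    ("10008618", "Cholecystitis infective"),
    ("10004663", "Biliary colic"),
    ("10008631", "Cholelithiasis obstructive"),
    ("10000692", "Acalculous cholecystitis"),
    ("10014530", "Empyema of gallbladder"),
    ("10017626", "Gallbladder disorder"),
    ("10017631", "Gallbladder enlargement"),
    ("10017638", "Gallbladder obstruction"),
    ("10017642", "Gallbladder rupture"),
    ("10017822", "Gangrenous cholecystitis"),
]


def default_config() -> dict[str, Any]:
    return {
        "drugs": {k: list(v) for k, v in DEFAULT_LEXICON.items()},
        "events": {
            "hlt": DEFAULT_TARGET_HLT,
            "pts": [{"code": c, "name": n} for c, n in DEFAULT_TARGET_PTS],
        },
        "analysis": {
            "level": 0.95,
            "continuity_correction": False,
            "yates": True,
            "table_unit": "pair",
            "strata": ["sex", "age", "bmi"],
            "event_source": "reac",
            "gps": {"init": [1 / 3, 0.2, 0.1, 2.0, 4.0], "restarts": 4},
        },
        "tto": {
            "drug": "pemafibrate",
            "bootstrap_b": 2000,
            "earliest_only": False,
        },
    }


def load_config(path: "Path | str") -> dict[str, Any]:
    """Load a TOML or YAML config and overlay it on the defaults."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    merged = default_config()
    _deep_update(merged, user)
    return merged


def _deep_update(base: dict, user: Mapping) -> None:
    for k, v in user.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def target_event_ids(config: Mapping[str, Any], dialect: str) -> set[str]:
    """The event identifiers that mark a pair as a target event.

    JADER-dialect events are identified by PT code; FAERS reaction rows carry
    the PT name, so both codes and names are accepted to keep the target set
    dialect-agnostic.
    """
    pts = config["events"]["pts"]
    ids = {str(p["code"]) for p in pts} | {str(p["name"]) for p in pts}
    return ids
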