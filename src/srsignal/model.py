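"""Case-level domain model shared by every analysis stage.

The unit of SRS analysis is the individual case safety report (ICSR): one
patient, a list of drugs with reporter-assigned roles, and a list of adverse
events coded as MedDRA Preferred Terms.  Disproportionality statistics are
computed on drug-event *pairs* expanded from these reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .dates import PartialDate

__all__ = [
    "Role",
    "Sex",
    "Reporter",
    "DrugEntry",
    "EventEntry",
    "CaseRecord",
    "DrugEventPair",
]


class Role(str, enum.Enum):
    """Reporter-assigned drug role.

    FAERS distinguishes primary from secondary suspects (PS/SS); JADER has a
    single suspect category, which this model maps to ``PRIMARY_SUSPECT`` so
    that the suspect-restricted sensitivity analysis has the same meaning in
    both dialects.
    """

    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    SUSPECT_UNSPECIFIED = "suspect_unspecified"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Reporter(str, enum.Enum):
    HEALTHCARE_PROFESSIONAL = "healthcare_professional"
    CONSUMER = "consumer"
    UNKNOWN = "unknown"


@dataclass
class DrugEntry:
    raw_name: str
    canonical_drug: Optional[str] = None
    role: Role = Role.SUSPECT_UNSPECIFIED
    therapy_start: Optional[PartialDate] = None
    therapy_end: Optional[PartialDate] = None

    @property
    def identity(self) -> str:
        """Canonical drug if the lexicon matched, else the normalized raw name."""
        from .lexicon import normalize_name

        return self.canonical_drug or normalize_name(self.raw_name)


@dataclass
class EventEntry:
    pt_code: str
    pt_name: str = ""
    onset: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if not self.pt_code:
            raise ValueError("EventEntry requires a non-empty pt_code")


@dataclass
class CaseRecord:
    """One deduplicated ICSR with demographics and its drug/event lists."""

    case_id: str
    case_version: Optional[int] = None
    sex: Sex = Sex.UNKNOWN
    age_band: Optional[str] = None  # decade label: "20s" ... "90s"
    height_band_cm: Optional[tuple[int, int]] = None  # [low, high)
    weight_band_kg: Optional[tuple[int, int]] = None  # [low, high)
    reporter: Reporter = Reporter.UNKNOWN
    report_year: Optional[int] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[EventEntry] = field(default_factory=list)


@dataclass(frozen=True)
class DrugEventPair:
    """One (case, drug occurrence, event occurrence) combination."""

    case_id: str
    drug: str  # canonical identifier or normalized raw name
    pt_code: str
    role: Role = Role.SUSPECT_UNSPECIFIED
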