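"""Drug-name normalization and the fibrate lexicon.

Matching is exact on a normalized form (uppercase, trimmed, internal
whitespace collapsed) against an explicit synonym list; no fuzzy matching.
The default lexicon covers the three fibrates marketed in Japan, with the
FAERS spelling variants of fenofibrate ("FENOFIBRIC ACID", "CHOLINE
FENOFIBRATE") and the Japanese generic names used by JADER.
"""

from __future__ import annotations

from typing import Mapping, Optional

__all__ = ["normalize_name", "compile_lexicon", "match_drug", "DEFAULT_LEXICON"]

#: canonical identifier -> synonyms (matched after normalization)
DEFAULT_LEXICON: dict[str, list[str]] = {
    "pemafibrate": ["PEMAFIBRATE", "ペマフィブラート"],
    "fenofibrate": [
        "FENOFIBRATE",
        "FENOFIBRIC ACID",
        "CHOLINE FENOFIBRATE",
        "フェノフィブラート",
    ],
    "bezafibrate": ["BEZAFIBRATE", "ベザフィブラート"],
}


def normalize_name(raw: str) -> str:
    """Uppercase, trim, and collapse internal whitespace (incl. full-width)."""
    return " ".join(str(raw).replace("　", " ").upper().split())


def compile_lexicon(lexicon: Mapping[str, list[str]]) -> dict[str, str]:
    """Flatten a canonical->synonyms mapping to normalized-synonym->canonical.

    The canonical identifier itself always matches.
    """
    compiled: dict[str, str] = {}
    for canonical, synonyms in lexicon.items():
        compiled[normalize_name(canonical)] = canonical
        for s in synonyms:
            compiled[normalize_name(s)] = canonical
    return compiled


def match_drug(raw_name: str, lexicon: Mapping[str, str]) -> Optional[str]:
    """Return the canonical drug for ``raw_name``, or ``None`` if unmatched.

    ``lexicon`` is the compiled normalized-synonym->canonical mapping from
    :func:`compile_lexicon`.
    """
    return lexicon.get(normalize_name(raw_name))
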