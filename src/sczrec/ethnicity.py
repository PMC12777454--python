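"""Ethnicity consolidation.

Source systems record ethnicity in fine-grained, dialect-specific strings
("WHITE - RUSSIAN", "HISPANIC/LATINO - PUERTO RICAN", ...). For analysis
these collapse into four retained categories; small groups (American
Indian/Alaska Native, Native Hawaiian/Pacific Islander, Multiracial,
Unknown/Declined/Other) are excluded. The dialect table ships as an
editable CSV resource so other hospital dialects can be added.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .errors import UnknownLabelError

#: Sentinel returned for labels whose group is excluded from analysis.
EXCLUDE = "EXCLUDE"

RETAINED_CATEGORIES = ("White", "Black/African American", "Hispanic/Latino", "Asian")


def load_dialect_table(path: str | Path | None = None) -> dict[str, str]:
    """Load a raw-label -> category table; default is the bundled resource.

    Keys are upper-cased so lookups are case-insensitive.
    """
    if path is None:
        src = resources.files("sczrec").joinpath("data/ethnicity_dialects.csv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        category = row["category"].strip()
        if category != EXCLUDE and category not in RETAINED_CATEGORIES:
            raise ValueError(f"dialect table maps to unknown category {category!r}")
        table[row["raw_label"].strip().upper()] = category
    return table


_DEFAULT_TABLE: dict[str, str] | None = None


def consolidate_ethnicity(raw: str, table: dict[str, str] | None = None) -> str:
    """Map a source ethnicity string to a retained category or EXCLUDE.

    Raises UnknownLabelError for strings absent from the dialect table;
    silent pass-through of unrecognised dialects would corrupt the cohort.
    """
    global _DEFAULT_TABLE
    if table is None:
        if _DEFAULT_TABLE is None:
            _DEFAULT_TABLE = load_dialect_table()
        table = _DEFAULT_TABLE
    key = str(raw).strip().upper()
    try:
        return table[key]
    except KeyError:
        raise UnknownLabelError(f"ethnicity label {raw!r} not in dialect table") from None
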