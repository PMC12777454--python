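"""ICD-9 to ICD-10 diagnosis-code handling for schizophrenia-spectrum codes.

The cohort is defined by ICD-9 295.x / ICD-10 F2x diagnoses. Source records
sometimes carry several comma-separated codes; only the first is analysed.
ICD-9 subtypes map onto ICD-10-CM F2 codes by their fourth digit (the
subtype digit), e.g. 295.7x (schizoaffective) -> F25.9 and 295.3x
(paranoid) -> F20.0.
"""

from __future__ import annotations

import re

from .errors import EmptyFieldError, UnknownCodeError

# Keyed on the ICD-9 subtype digit (295.<d>). Catatonic 295.2 is grouped
# with disorganised under F20.1 here, mirroring the grouping used to build
# the development cohort.
_ICD9_SUBTYPE_TO_ICD10: dict[str, str] = {
    "0": "F20.89",  # simple
    "1": "F20.1",   # disorganised
    "2": "F20.1",   # catatonic, consolidated with disorganised
    "3": "F20.0",   # paranoid
    "4": "F20.81",  # schizophreniform
    "5": "F21",     # latent / schizotypal
    "6": "F20.5",   # residual
    "7": "F25.9",   # schizoaffective
    "8": "F20.89",  # other specified
    "9": "F20.9",   # unspecified
}

_ICD9_295 = re.compile(r"^295\.?(\d)\d*$")


def first_code(raw: str) -> str:
    """Return the first code of a possibly comma-separated ICD field.

    Raises EmptyFieldError when the field (or its first entry) is blank.
    """
    if raw is None or not str(raw).strip():
        raise EmptyFieldError("blank ICD code field")
    head = str(raw).split(",", 1)[0].strip()
    if not head:
        raise EmptyFieldError(f"blank leading code in {raw!r}")
    return head


def map_icd9_to_icd10(code: str) -> str:
    """Map a schizophrenia-spectrum ICD-9 code to its ICD-10 equivalent.

    ICD-10 inputs (anything starting with a letter) pass through unchanged,
    which also makes the mapping idempotent. Codes outside the 295.x table
    raise UnknownCodeError.
    """
    if not code or not str(code).strip():
        raise EmptyFieldError("blank ICD code")
    code = str(code).strip()
    if code[0].isalpha():
        return code
    m = _ICD9_295.match(code)
    if m is None:
        raise UnknownCodeError(f"no ICD-10 mapping for ICD-9 code {code!r}")
    return _ICD9_SUBTYPE_TO_ICD10[m.group(1)]


def is_schizophrenia_spectrum(icd10_code: str) -> bool:
    """True for F2x codes (schizophrenia, schizotypal and delusional)."""
    return icd10_code.upper().startswith("F2")
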