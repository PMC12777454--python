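"""The closed set of treatment arms.

Fifteen unique antipsychotics observed in the development cohort plus an
explicit "no medication" arm. The arm set is fixed: recommendation lists
rank exactly these sixteen options and nothing else.
"""

from __future__ import annotations

NONE_ARM = "NONE"

ANTIPSYCHOTICS: tuple[str, ...] = (
    "aripiprazole",
    "asenapine",
    "chlorpromazine",
    "clozapine",
    "fluphenazine",
    "haloperidol",
    "iloperidone",
    "lurasidone",
    "olanzapine",
    "paliperidone",
    "perphenazine",
    "prochlorperazine",
    "risperidone",
    "thiothixene",
    "ziprasidone",
)

#: All sixteen arms; NONE competes as an ordinary arm in every ranking.
TREATMENT_ARMS: tuple[str, ...] = (NONE_ARM,) + ANTIPSYCHOTICS


def is_valid_arm(name: str) -> bool:
    return name in TREATMENT_ARMS
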