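"""Exception hierarchy for the recommender pipeline.

Every failure mode that callers are expected to handle gets its own class so
that the CV harness can distinguish recoverable degeneracies (e.g. a
single-class inner fold) from genuine contract violations (e.g. temporal
leakage).
"""


class SczrecError(Exception):
    """Base class for all package errors."""


class UnknownCodeError(SczrecError):
    """ICD code outside the shipped ICD-9 -> ICD-10 mapping table."""


class EmptyFieldError(SczrecError):
    """A required raw field was blank."""


class UnknownLabelError(SczrecError):
    """Ethnicity label absent from the dialect table."""


class TemporalLeakageError(SczrecError):
    """A feature vector or neighbour query touched future-visit information."""


class EmptyTrainingError(SczrecError):
    """Fit was attempted on an empty training set."""


class InvalidSwitchCountError(SczrecError):
    """Switch count outside {0, 1, 2}."""


class SingleClassError(SczrecError):
    """Binary-label fit requested but training labels contain one class."""


class AllMissingError(SczrecError):
    """Gower comparison found no feature comparable between two records."""


class NotFittedError(SczrecError):
    """Predict called before fit."""


class NoScorableArmError(SczrecError):
    """No treatment arm could be scored for a consultation."""


class TooFewPatientsError(SczrecError):
    """Cohort has fewer patients than requested folds."""


class EmptyPairsError(SczrecError):
    """RMSE requested on zero prediction/observation pairs."""


class NoEvaluableConsultationError(SczrecError):
    """MAP@3 requested but every consultation had an empty relevant set."""


class TooFewCasesError(SczrecError):
    """Disagreement analysis needs at least two paired cases."""


class SchemaMismatchError(SczrecError):
    """External cohort is missing columns required by the frozen model."""


class InvalidSpecError(SczrecError):
    """Synthetic cohort specification violates its invariants."""
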