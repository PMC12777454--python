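"""Composite treatment-outcome ("affinity") score.

Each patient-drug instance receives a score A in [0, 1] built from four
hospital-utilisation signals, each min-max normalised against *training-fold*
bounds and oriented so that larger means a better outcome:

    t  - time between admissions (longer gaps -> fewer relapses)
    s  - time between medication switches (longer -> greater stability)
    l  - 1 - norm(total length of stay)
    v  - 1 - norm(number of visits)

The base score is a weighted average (equal weights 1/4 by default),

    b = w_t * t + w_s * s + w_l * l + w_v * v,

from which a fixed switch penalty P is subtracted and the result clipped:

    A = clip(b - P, 0, 1),   P = -0.05 (no switch, a bonus),
                                  0.10 (first switch),
                                  0.20 (second switch).

Computation is limited to the first three visits and at most two switches.
Two sensitivity variants re-weight the components: a stability-heavy scheme
(up-weighting t and s) and a patient-burden-heavy scheme (up-weighting l
and v, with halved penalties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import EmptyTrainingError, InvalidSwitchCountError

MAX_SWITCHES = 2

#: Raw quantities tracked by the normalisation bounds.
RAW_QUANTITIES = ("inter_admission_days", "inter_switch_days", "los_days", "visit_count")

# Single-visit patients have no readmission gap and unswitched instances no
# inter-switch time; under the default "best" policy the missing component
# scores 1 (no observed readmission / no switch is the best outcome proxy).
# The alternative drops the component and renormalises the weights.
POLICY_BEST = "best"
POLICY_RENORMALIZE = "renormalize"


@dataclass(frozen=True)
class RawUtilization:
    """Raw utilisation quantities for one patient-drug instance.

    ``inter_admission_days`` / ``inter_switch_days`` are None when undefined
    (single-visit patient / no switch after initiation).
    """

    inter_admission_days: float | None
    inter_switch_days: float | None
    los_days: float
    visit_count: int
    switch_count: int


@dataclass(frozen=True)
class AffinityComponents:
    t: float
    s: float
    l: float
    v: float
    switch_count: int


@dataclass(frozen=True)
class AffinityScore:
    base_b: float
    penalty_P: float
    final_A: float
    components: AffinityComponents


@dataclass(frozen=True)
class WeightScheme:
    """Component weights (summing to 1) plus the switch-count penalty map."""

    name: str
    w_t: float = 0.25
    w_s: float = 0.25
    w_l: float = 0.25
    w_v: float = 0.25
    penalty_map: dict[int, float] = field(
        default_factory=lambda: {0: -0.05, 1: 0.10, 2: 0.20}
    )

    def __post_init__(self) -> None:
        total = self.w_t + self.w_s + self.w_l + self.w_v
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights of scheme {self.name!r} sum to {total}, not 1")
        if min(self.w_t, self.w_s, self.w_l, self.w_v) < 0:
            raise ValueError("weights must be non-negative")
        if set(self.penalty_map) != {0, 1, 2}:
            raise ValueError("penalty map must cover switch counts 0, 1, 2")

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.w_t, self.w_s, self.w_l, self.w_v)


def variant_schemes() -> dict[str, WeightScheme]:
    """The equal-weight scheme and the two sensitivity-analysis variants.

    Exact variant weights are configuration values: any weighting with
    w_t = w_s > w_l = w_v is "stability-heavy" and the mirror image
    "burden-heavy"; the burden-heavy variant additionally halves the switch
    penalties.
    """
    return {
        "equal": WeightScheme("equal"),
        "stability_heavy": WeightScheme("stability_heavy", 0.35, 0.35, 0.15, 0.15),
        "burden_heavy": WeightScheme(
            "burden_heavy", 0.15, 0.15, 0.35, 0.35,
            penalty_map={0: -0.025, 1: 0.05, 2: 0.10},
        ),
    }


class NormalizationBounds:
    """Per-quantity (min, max) fitted on a training fold.

    Bounds are fitted once on training instances and then applied,
    unmodified, to every test or external instance; test values outside the
    training range clip into [0, 1] rather than extrapolate. ``fitted_on``
    tags the provenance fold so leakage audits can assert that test-set
    scoring never read test-set extrema.
    """

    def __init__(self, bounds: dict[str, tuple[float, float]], fitted_on: str = ""):
        for name, (lo, hi) in bounds.items():
            if hi < lo:
                raise ValueError(f"max < min for {name}")
        self.bounds = dict(bounds)
        self.fitted_on = fitted_on

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def is_degenerate(self, name: str) -> bool:
        lo, hi = self.bounds[name]
        return hi == lo

    def __repr__(self) -> str:  # pragma: no cover
        return f"NormalizationBounds({self.bounds!r}, fitted_on={self.fitted_on!r})"


def fit_bounds(raw_instances: list[RawUtilization] | "object", fitted_on: str = "train") -> NormalizationBounds:
    """Fit min/max bounds for every raw quantity over training instances.

    Accepts a list of RawUtilization or a pandas DataFrame with the
    ``util_*`` columns produced by the cohort builder. Quantities that are
    undefined for an instance (no readmission, no switch) do not contribute
    to that quantity's bounds.
    """
    instances = _as_raw_list(raw_instances)
    if not instances:
        raise EmptyTrainingError("cannot fit normalisation bounds on an empty training set")
    bounds: dict[str, tuple[float, float]] = {}
    for name in RAW_QUANTITIES:
        values = [getattr(r, name if name != "visit_count" else "visit_count")
                  for r in instances]
        values = [float(x) for x in values if x is not None and not _isnan(x)]
        if not values:
            # no instance defines this quantity: degenerate zero-width bound
            bounds[name] = (0.0, 0.0)
        else:
            bounds[name] = (min(values), max(values))
    return NormalizationBounds(bounds, fitted_on=fitted_on)


def normalize(x: float, lo: float, hi: float, invert: bool = False) -> float:
    """Min-max scale ``x`` into [0, 1] against training bounds.

    Out-of-range values clip; a degenerate bound (hi == lo) returns the
    uninformative midpoint 0.5.
    """
    if hi == lo:
        val = 0.5
    else:
        val = (x - lo) / (hi - lo)
        val = min(1.0, max(0.0, val))
    return 1.0 - val if invert else val


def components_from_raw(
    raw: RawUtilization,
    bounds: NormalizationBounds,
    single_visit_policy: str = POLICY_BEST,
) -> tuple[AffinityComponents, tuple[float, ...] | None]:
    """Normalise raw quantities into the four oriented components.

    Returns ``(components, active_weight_mask)``: the mask is None under the
    default "best" policy; under "renormalize" it flags which of (t, s, l, v)
    are defined so the caller can renormalise weights.
    """
    if raw.switch_count > MAX_SWITCHES:
        raise InvalidSwitchCountError(f"switch count {raw.switch_count} exceeds {MAX_SWITCHES}")
    active = [True, True, True, True]

    if raw.inter_admission_days is None:
        t = 1.0
        if single_visit_policy == POLICY_RENORMALIZE:
            active[0] = False
    else:
        t = normalize(raw.inter_admission_days, *bounds["inter_admission_days"])

    if raw.inter_switch_days is None:
        s = 1.0
        if single_visit_policy == POLICY_RENORMALIZE:
            active[1] = False
    else:
        s = normalize(raw.inter_switch_days, *bounds["inter_switch_days"])

    l = normalize(raw.los_days, *bounds["los_days"], invert=True)
    v = normalize(float(raw.visit_count), *bounds["visit_count"], invert=True)

    comps = AffinityComponents(t=t, s=s, l=l, v=v, switch_count=raw.switch_count)
    mask = None if single_visit_policy == POLICY_BEST else tuple(float(a) for a in active)
    return comps, mask


def base_score(
    comps: AffinityComponents,
    scheme: WeightScheme | None = None,
    active_mask: tuple[float, ...] | None = None,
) -> float:
    """Weighted average of the four components (equal weights by default)."""
    scheme = scheme or WeightScheme("equal")
    w = list(scheme.weights)
    if active_mask is not None:
        w = [wi * m for wi, m in zip(w, active_mask)]
        total = sum(w)
        if total == 0:
            raise ValueError("no active component to average")
        w = [wi / total for wi in w]
    return w[0] * comps.t + w[1] * comps.s + w[2] * comps.l + w[3] * comps.v


def apply_penalty(b: float, switch_count: int, scheme: WeightScheme | None = None) -> float:
    """A = clip(b - P, 0, 1); no switch earns a bonus (P = -0.05)."""
    scheme = scheme or WeightScheme("equal")
    if switch_count not in scheme.penalty_map:
        raise InvalidSwitchCountError(f"switch count {switch_count} outside {{0,1,2}}")
    return min(1.0, max(0.0, b - scheme.penalty_map[switch_count]))


def compute_affinity(
    raw: RawUtilization,
    bounds: NormalizationBounds,
    scheme: WeightScheme | None = None,
    single_visit_policy: str = POLICY_BEST,
) -> AffinityScore:
    """Full pipeline: normalise -> weighted base score -> penalty -> clip."""
    scheme = scheme or WeightScheme("equal")
    comps, mask = components_from_raw(raw, bounds, single_visit_policy)
    b = base_score(comps, scheme, mask)
    penalty = scheme.penalty_map[raw.switch_count]
    return AffinityScore(
        base_b=b,
        penalty_P=penalty,
        final_A=apply_penalty(b, raw.switch_count, scheme),
        components=comps,
    )


def affinity_table(
    instances: "object",
    bounds: NormalizationBounds,
    scheme: WeightScheme | None = None,
    single_visit_policy: str = POLICY_BEST,
):
    """Score a frame of (patient, drug) instances; one audit row per instance.

    ``instances`` is a DataFrame with patient_id, drug and the util_*
    columns. The returned frame carries the raw quantities, the four
    components, b, P and the final A — the affinity audit record.
    """
    import pandas as pd

    scheme = scheme or WeightScheme("equal")
    raws = _as_raw_list(instances)
    rows = []
    for (_, inst), raw in zip(instances.iterrows(), raws):
        score = compute_affinity(raw, bounds, scheme, single_visit_policy)
        rows.append(
            {
                "patient_id": inst["patient_id"],
                "drug": inst["drug"],
                "util_inter_admission_days": raw.inter_admission_days,
                "util_inter_switch_days": raw.inter_switch_days,
                "util_los_days": raw.los_days,
                "util_visit_count": raw.visit_count,
                "util_switch_count": raw.switch_count,
                "t": score.components.t,
                "s": score.components.s,
                "l": score.components.l,
                "v": score.components.v,
                "b": score.base_b,
                "P": score.penalty_P,
                "A": score.final_A,
            }
        )
    return pd.DataFrame(rows)


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def _as_raw_list(obj) -> list[RawUtilization]:
    if isinstance(obj, list):
        return obj
    # duck-typed DataFrame path: expects util_* columns
    import pandas as pd  # local import keeps module import light

    if isinstance(obj, pd.DataFrame):
        out = []
        for _, row in obj.iterrows():
            out.append(
                RawUtilization(
                    inter_admission_days=_none_if_nan(row["util_inter_admission_days"]),
                    inter_switch_days=_none_if_nan(row["util_inter_switch_days"]),
                    los_days=float(row["util_los_days"]),
                    visit_count=int(row["util_visit_count"]),
                    switch_count=int(row["util_switch_count"]),
                )
            )
        return out
    raise TypeError(f"cannot interpret {type(obj)!r} as raw utilisation instances")


def _none_if_nan(x):
    return None if x is None or _isnan(x) else float(x)
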