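"""Model parameters: trial outcome tables, pooled entry distributions, and the
full cost/probability/utility registry for the basilar-artery-occlusion
cost-effectiveness model.

The registry covers two treatment strategies — endovascular thrombectomy (EVT)
and best medical care (BMC) — entering a lifetime Markov model in one of seven
90-day modified Rankin Scale (mRS) states (0 = no symptoms ... 6 = death).
Default values are the published U.S. base case: costs in 2022 USD, utilities
from a stroke-trial meta-analysis, recurrence risks from a pooled control
cohort, and willingness-to-pay anchored at 1x and 3x U.S. GDP per capita.
"""

from __future__ import annotations

import copy
import dataclasses
import difflib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

N_MRS_STATES = 7  # mRS 0..5 alive + mRS 6 / Dead

#: WTP thresholds (USD/QALY): 1x U.S. GDP per capita ("highly cost-effective")
#: and 3x ("cost-effective"), per WHO-CHOICE practice.
WTP_HIGHLY_COST_EFFECTIVE = 63_593.0
WTP_COST_EFFECTIVE = 190_779.0

#: mRS-specific long-term annual death hazard ratios for stroke survivors used
#: in the *reference* configuration (Hong & Saver's disability-adjusted
#: life-year analyses). The published input table prints an anomalous row for
#: this quantity (values < 1 that duplicate the recurrent-outcome
#: distribution); see ``build_default_parameters`` and the methods note.
LITERATURE_DEATH_HRS = (1.53, 1.52, 2.17, 3.18, 4.55, 6.55)

#: The death-HR row exactly as printed in the source input table. Shipped as
#: the literal default; a warning is emitted whenever it is used because the
#: values are implausible as excess-mortality hazard ratios.
PRINTED_DEATH_HRS = (0.129, 0.136, 0.164, 0.247, 0.135, 0.189)


class ParameterError(ValueError):
    """Invalid model input."""


# ---------------------------------------------------------------------------
# Trial outcome tables (the four randomized aBAO thrombectomy trials)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialOutcomeTable:
    """90-day mRS outcome counts for one arm of one randomized trial.

    ``counts[i]`` is the number of patients with mRS == i at 90 days;
    ``percentages`` are the published percentages (of ``n_total``), kept
    separately because published rounding does not always reproduce
    ``100 * count / n_total`` exactly.
    """

    trial_name: str
    arm: str  # "intervention" or "bmc"
    n_total: int
    counts: tuple[int, ...]
    percentages: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "bmc"):
            raise ParameterError(f"unknown arm {self.arm!r}")
        if len(self.counts) != N_MRS_STATES or len(self.percentages) != N_MRS_STATES:
            raise ParameterError("counts and percentages must have 7 entries (mRS 0..6)")
        if any(c < 0 for c in self.counts):
            raise ParameterError("counts must be non-negative")
        if sum(self.counts) > self.n_total:
            raise ParameterError("counts sum exceeds n_total")
        if any(not (0.0 <= p <= 100.0) for p in self.percentages):
            raise ParameterError("percentages must lie in [0, 100]")

    @classmethod
    def from_counts(cls, trial_name: str, arm: str, n_total: int,
                    counts: Sequence[int]) -> "TrialOutcomeTable":
        pct = tuple(round(100.0 * c / n_total, 1) for c in counts)
        return cls(trial_name, arm, n_total, tuple(int(c) for c in counts), pct)


def _trial(name: str, arm: str, n: int, rows: list[tuple[int, float]]) -> TrialOutcomeTable:
    return TrialOutcomeTable(name, arm, n,
                             tuple(c for c, _ in rows),
                             tuple(p for _, p in rows))


#: Published 90-day outcomes of the four aBAO thrombectomy trials
#: (count, percentage) for mRS 0..6, per arm.
DEFAULT_TRIALS: tuple[TrialOutcomeTable, ...] = (
    _trial("ATTENTION", "intervention", 225,
           [(11, 4.9), (34, 15.1), (29, 12.9), (29, 12.9), (11, 4.9), (27, 12.0), (84, 37.3)]),
    _trial("ATTENTION", "bmc", 115,
           [(5, 4.3), (5, 4.3), (3, 2.6), (14, 12.2), (6, 5.2), (19, 16.5), (63, 54.8)]),
    _trial("BAOCHE", "intervention", 102,
           [(7, 6.9), (19, 18.6), (16, 15.7), (8, 7.8), (9, 8.8), (12, 11.8), (31, 30.4)]),
    _trial("BAOCHE", "bmc", 100,
           [(1, 1.0), (6, 6.0), (8, 8.0), (11, 11.0), (19, 19.0), (14, 14.0), (41, 41.0)]),
    _trial("BASICS", "intervention", 154,
           [(8, 5.2), (19, 12.3), (27, 17.5), (14, 9.1), (10, 6.5), (17, 11.0), (59, 38.3)]),
    _trial("BASICS", "bmc", 146,
           [(6, 4.1), (13, 8.9), (25, 17.1), (11, 7.5), (16, 11.0), (12, 8.2), (63, 43.2)]),
    _trial("BEST", "intervention", 77,
           [(7, 9.1), (16, 20.8), (7, 9.1), (6, 7.8), (6, 7.8), (12, 15.6), (23, 29.9)]),
    _trial("BEST", "bmc", 54,
           [(3, 5.6), (5, 9.3), (2, 3.7), (3, 5.6), (11, 20.4), (6, 11.1), (24, 44.4)]),
)


# ---------------------------------------------------------------------------
# Outcome distributions and pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeDistribution:
    """Probability distribution over 90-day mRS 0..6."""

    p: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.p) != N_MRS_STATES:
            raise ParameterError("outcome distribution needs 7 probabilities (mRS 0..6)")
        if any(x < 0 or x > 1 for x in self.p):
            raise ParameterError("probabilities must lie in [0, 1]")
        if abs(sum(self.p) - 1.0) > 1e-9:
            raise ParameterError(f"probabilities sum to {sum(self.p)}, expected 1")

    @classmethod
    def from_unnormalized(cls, weights: Sequence[float]) -> "OutcomeDistribution":
        w = np.asarray(weights, dtype=float)
        if w.min() < 0:
            raise ParameterError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ParameterError("weights sum to zero")
        return cls(tuple(w / total))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


def pool_outcome_distributions(trials: Sequence[TrialOutcomeTable], arm: str,
                               weighting: str = "unweighted") -> OutcomeDistribution:
    """Pool per-trial 90-day mRS percentages into one entry distribution.

    ``weighting="unweighted"`` (default) averages the arm-level percentages
    across trials with equal weight, then renormalizes — this reproduces
    several cells of the published pooled table exactly.
    ``weighting="count"`` pools at the patient level (sums counts across
    trials and divides by total randomized).
    """
    if arm not in ("intervention", "bmc"):
        raise ParameterError(f"unknown arm {arm!r}")
    selected = [t for t in trials if t.arm == arm]
    if not trials:
        raise ParameterError("no trials supplied")
    if not selected:
        raise ParameterError(f"no trial reports arm {arm!r}")
    if weighting == "unweighted":
        mat = np.array([t.percentages for t in selected], dtype=float)
        pooled = mat.mean(axis=0)
    elif weighting == "count":
        counts = np.array([t.counts for t in selected], dtype=float).sum(axis=0)
        pooled = counts / sum(t.n_total for t in selected)
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")
    return OutcomeDistribution.from_unnormalized(pooled)


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death q(age) at integer ages.

    Ages are contiguous; q at the terminal age is 1 (everyone dies). Lookups
    above the terminal age clamp to 1; below the minimum age are an error.
    """

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx) or not self.ages:
            raise ParameterError("life table needs matching non-empty age and qx columns")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise ParameterError("life-table ages must be contiguous integers")
        if any(q < 0 or q > 1 for q in self.qx):
            raise ParameterError("qx must lie in [0, 1]")
        if abs(self.qx[-1] - 1.0) > 1e-12:
            raise ParameterError("terminal-age qx must equal 1")

    @property
    def min_age(self) -> int:
        return self.ages[0]

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def q(self, age: int) -> float:
        """Annual death probability at integer ``age`` (clamped to 1 above terminal)."""
        if age < self.min_age:
            raise ParameterError(f"age {age} below life-table minimum {self.min_age}")
        if age > self.max_age:
            return 1.0
        return self.qx[age - self.min_age]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "age" not in cols or "qx" not in cols:
            raise ParameterError("life-table CSV needs 'age' and 'qx' columns")
        df = df.sort_values(cols["age"])
        return cls(tuple(int(a) for a in df[cols["age"]]),
                   tuple(float(q) for q in df[cols["qx"]]))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Every input of the decision model.

    Cost fields are 2022 USD. ``cost_hosp`` is keyed by entry mRS group
    (0–2 / 3–5 / 6); the two post-discharge stacks (``cost_first90``,
    ``cost_day91_365``) apply only to survivors (groups 0–2 / 3–5) during the
    first model year. ``cost_longterm_annual`` (per mRS 0..5) applies from the
    second year on — the two cost systems never overlap.
    """

    start_age: int = 66
    discount_rate: float = 0.03
    wtp_per_qaly: float = WTP_HIGHLY_COST_EFFECTIVE
    wtp_3x: float = WTP_COST_EFFECTIVE

    # acute / first-year costs
    cost_hosp: tuple[float, float, float] = (26_705.0, 106_533.0, 88_159.0)
    cost_first90: tuple[float, float] = (15_213.0, 26_496.0)
    cost_day91_365: tuple[float, float] = (24_988.0, 35_140.0)
    cost_evt_addon: float = 17_103.0
    cost_stent_addon: float = 9_000.0
    cost_recurrent_acute: float = 29_259.0
    cost_longterm_annual: tuple[float, ...] = (
        14_230.0, 14_653.0, 16_952.0, 29_107.0, 58_913.0, 86_612.0)

    # decision-tree probabilities
    p_stenosis: float = 0.397
    p_stenosis_sd: float = 0.107  # published spread; metadata only, not drawn in PSA
    p_stent_given_stenosis_evt: float = 0.618

    # entry distributions (pooled 90-day outcomes as published)
    entry_dist_evt: OutcomeDistribution = field(default_factory=lambda: OutcomeDistribution(
        (0.065, 0.165, 0.14, 0.095, 0.07, 0.1275, 0.3375)))
    entry_dist_bmc: OutcomeDistribution = field(default_factory=lambda: OutcomeDistribution(
        (0.0375, 0.07, 0.08, 0.0925, 0.1375, 0.125, 0.4575)))

    # transition inputs
    p_recurrence_by_year: tuple[float, ...] = (
        0.059, 0.036, 0.025, 0.022, 0.022, 0.027, 0.027, 0.023, 0.028, 0.016)
    death_hr_by_mrs: tuple[float, ...] = PRINTED_DEATH_HRS
    recurrent_outcome_dist: tuple[float, ...] = (0.129, 0.136, 0.164, 0.247, 0.135, 0.189)
    rr_recurrence_stenosis: float = 3.4
    hr_instent_thrombosis: float = 1.057

    # utilities for mRS 0..5 (death fixed at 0)
    utilities: tuple[float, ...] = (1.00, 0.91, 0.76, 0.65, 0.33, 0.00)

    # modelling conventions (documented defaults; not published values)
    half_cycle_correction: bool = False
    recurrent_mrs01_mapping: str = "mrs1"  # "mrs1" | "mrs0" | "split"
    hr_space: str = "rate"   # hazard ratios applied on the rate scale
    rr_space: str = "prob"   # risk ratios applied on the probability scale
    max_age: int = 110

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self.copy(), **kwargs)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


#: BAOCHE-only entry distributions (late 6–24 h window subgroup).
_BAOCHE_EVT = OutcomeDistribution((0.069, 0.186, 0.157, 0.078, 0.088, 0.118, 0.304))
_BAOCHE_BMC = OutcomeDistribution((0.01, 0.06, 0.08, 0.11, 0.19, 0.14, 0.41))


def build_default_parameters(variant: str = "base_case") -> ParameterSet:
    """Published base-case inputs, verbatim.

    ``variant="baoche_subgroup"`` replaces the two entry distributions with
    the BAOCHE trial's own 90-day rows (late-window patients); stenosis
    prevalence and stenting probability are kept at the pooled values because
    no subgroup-specific estimates were published.

    .. warning:: the published death-HR row (``PRINTED_DEATH_HRS``) sums to 1
       and duplicates the recurrent-outcome distribution; it is almost
       certainly a typesetting duplication and is implausible as a set of
       excess-mortality hazard ratios. It ships verbatim here with this
       warning; use :func:`build_reference_parameters` for the corrected row.
    """
    if variant == "base_case":
        p = ParameterSet()
    elif variant == "baoche_subgroup":
        p = ParameterSet(entry_dist_evt=_BAOCHE_EVT, entry_dist_bmc=_BAOCHE_BMC)
    else:
        raise ParameterError(f"unknown variant {variant!r}")
    warnings.warn(
        "death_hr_by_mrs defaults to the printed row "
        f"{PRINTED_DEATH_HRS} which duplicates the recurrent-outcome "
        "distribution and contains ratios < 1; survivors would outlive the "
        "general population. Use build_reference_parameters() or supply an "
        "HR row >= 1 for realistic mortality.",
        UserWarning, stacklevel=2)
    return p


def build_reference_parameters(variant: str = "base_case") -> ParameterSet:
    """Reference configuration: base case with the corrected death-HR row.

    Identical to :func:`build_default_parameters` except ``death_hr_by_mrs``
    is replaced by mRS-specific survivor mortality hazard ratios from the
    stroke outcomes literature (:data:`LITERATURE_DEATH_HRS`), which yield
    lifetime costs and QALYs on the scale of the published results.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        p = build_default_parameters(variant)
    p.death_hr_by_mrs = LITERATURE_DEATH_HRS
    return p


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every structural invariant of a :class:`ParameterSet`.

    Report-only: never raises for an invalid value, never mutates input.
    """
    v: list[str] = []

    def _dist(name: str, seq: Sequence[float], n: int) -> None:
        if len(seq) != n:
            v.append(f"{name} must have {n} entries")
            return
        if any(x < 0 or x > 1 for x in seq):
            v.append(f"{name} entries must lie in [0, 1]")
        if abs(sum(seq) - 1.0) > 1e-9:
            v.append(f"{name} does not sum to 1 (sum={sum(seq):.6g})")

    _dist("entry_dist_evt", p.entry_dist_evt.p, 7)
    _dist("entry_dist_bmc", p.entry_dist_bmc.p, 7)
    _dist("recurrent_outcome_dist", p.recurrent_outcome_dist, 6)

    for name in ("cost_evt_addon", "cost_stent_addon", "cost_recurrent_acute"):
        if getattr(p, name) < 0:
            v.append(f"{name}: cost must be non-negative")
    for name, n in (("cost_hosp", 3), ("cost_first90", 2),
                    ("cost_day91_365", 2), ("cost_longterm_annual", 6)):
        seq = getattr(p, name)
        if len(seq) != n:
            v.append(f"{name} must have {n} entries")
        elif any(c < 0 for c in seq):
            v.append(f"{name}: cost must be non-negative")

    if not (0.0 <= p.discount_rate <= 0.2):
        v.append("discount_rate must lie in [0, 0.2]")
    for name in ("p_stenosis", "p_stent_given_stenosis_evt"):
        x = getattr(p, name)
        if not (0.0 <= x <= 1.0):
            v.append(f"{name} must be a probability in [0, 1]")
    if len(p.p_recurrence_by_year) != 10 or any(
            not (0.0 <= x <= 1.0) for x in p.p_recurrence_by_year):
        v.append("p_recurrence_by_year must be 10 probabilities in [0, 1]")
    if len(p.death_hr_by_mrs) != 6 or any(x <= 0 for x in p.death_hr_by_mrs):
        v.append("death_hr_by_mrs must be 6 positive ratios")
    if p.rr_recurrence_stenosis <= 0 or p.hr_instent_thrombosis <= 0:
        v.append("risk/hazard ratios must be positive")
    if len(p.utilities) != 6 or any(not (0.0 <= u <= 1.0) for u in p.utilities):
        v.append("utilities must be 6 values in [0, 1]")
    if p.wtp_per_qaly < 0 or p.wtp_3x < 0:
        v.append("willingness-to-pay must be non-negative")
    if p.recurrent_mrs01_mapping not in ("mrs1", "mrs0", "split"):
        v.append("recurrent_mrs01_mapping must be one of mrs1|mrs0|split")
    if p.hr_space not in ("rate", "prob") or p.rr_space not in ("rate", "prob"):
        v.append("hr_space/rr_space must be 'rate' or 'prob'")
    if not (0 < p.start_age < p.max_age):
        v.append("start_age must lie in (0, max_age)")

    return ValidationReport(passed=not v, violations=v)


# ---------------------------------------------------------------------------
# Parameter file IO
# ---------------------------------------------------------------------------

_DIST_FIELDS = ("entry_dist_evt", "entry_dist_bmc")
_SEQ_FIELDS = ("cost_hosp", "cost_first90", "cost_day91_365", "cost_longterm_annual",
               "p_recurrence_by_year", "death_hr_by_mrs", "recurrent_outcome_dist",
               "utilities")


def parameters_to_dict(p: ParameterSet) -> dict:
    d = {}
    for f in dataclasses.fields(ParameterSet):
        val = getattr(p, f.name)
        if isinstance(val, OutcomeDistribution):
            val = list(val.p)
        elif isinstance(val, tuple):
            val = list(val)
        d[f.name] = val
    return d


def apply_overrides(p: ParameterSet, overrides: dict) -> ParameterSet:
    """Return a copy of ``p`` with override keys applied.

    Unknown keys are a hard error with a close-match suggestion, so silently
    misspelled parameter names cannot slip through a config file.
    """
    out = p.copy()
    valid = ParameterSet.field_names()
    for key, val in overrides.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ParameterError(
                f"unknown parameter {key!r}{suggestion} Valid keys: {', '.join(valid)}")
        if key in _DIST_FIELDS:
            val = OutcomeDistribution(tuple(float(x) for x in val))
        elif key in _SEQ_FIELDS:
            val = tuple(float(x) for x in val)
        setattr(out, key, val)
    return out


def load_parameters(path: str | Path, base: ParameterSet | None = None) -> ParameterSet:
    """Load a YAML/JSON parameter file as overrides on top of ``base``
    (reference configuration by default)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError("parameter file must contain a mapping")
    if base is None:
        base = build_reference_parameters()
    return apply_overrides(base, data)


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    d = parameters_to_dict(p)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
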