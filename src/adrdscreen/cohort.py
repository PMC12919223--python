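"""Cohort construction: case/control labeling, index dates, observation windows.

Time is measured in integer weeks since a patient's first recorded DX code
(week 0); a year is 52 weeks for all window arithmetic.  Cases are patients
with ADRD evidence (a matching DX code, or an anti-dementia prescription);
their index date sits ``max(1, horizon)`` years before the first qualifying
event, so the model never sees the diagnostic run-up it is asked to predict.
Controls are anchored to end-of-record with a confirmation buffer: an
ADRD-free period after the index that guards against latent, not-yet-coded
cases contaminating the negative class.

All features downstream derive exclusively from the observation window, the
two years preceding the index date (half-open on the right: the index week
itself is excluded).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .codes import CHANNELS, CodeChannel, normalize_code

__all__ = [
    "WEEKS_PER_YEAR",
    "AGE_WEEKS_PER_YEAR",
    "CodedEvent",
    "PatientRecord",
    "CaseDefinition",
    "CohortConfig",
    "LabeledPatient",
    "label_patient",
    "first_qualifying_week",
    "assign_index",
    "apply_eligibility",
    "extract_window",
    "assign_risk_stratum",
    "build_cohort",
    "read_patients",
    "write_patients",
    "load_code_list",
    "consort_table",
]

#: Integer weeks per year for window/index arithmetic.
WEEKS_PER_YEAR = 52
#: Mean calendar weeks per year, used only for converting week spans to ages.
AGE_WEEKS_PER_YEAR = 52.1775

CASE = "case"
CONTROL = "control"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class CodedEvent:
    channel: str  # "DX" | "RX" | "PROC"
    code: str
    week: int  # weeks since the patient's first DX code

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.week < 0:
            raise ValueError("event week must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # "male" | "female"
    birth_week: int  # weeks relative to first DX code, <= 0
    record_end_week: int
    events: tuple[CodedEvent, ...]

    def __post_init__(self) -> None:
        if self.sex not in {"male", "female"}:
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.birth_week > 0:
            raise ValueError("birth_week must be <= 0 (before the first DX code)")
        weeks = [e.week for e in self.events]
        if weeks != sorted(weeks):
            object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.week)))
            weeks = sorted(weeks)
        if weeks and self.record_end_week < weeks[-1]:
            raise ValueError("record_end_week precedes the last event")

    @property
    def first_event_week(self) -> int:
        return self.events[0].week if self.events else 0

    @property
    def history_span_weeks(self) -> int:
        return self.record_end_week - self.first_event_week


@dataclass(frozen=True)
class CaseDefinition:
    """Externally supplied code-prefix lists defining case/control status.

    Prefix matching is used throughout so that a three-character list entry
    catches all of its child codes.
    """

    adrd_dx_codes: frozenset[str]
    anti_dementia_rx_codes: frozenset[str]
    exclusion_codes: frozenset[str]
    comorbidity_risk_codes: frozenset[str]


@dataclass(frozen=True)
class CohortConfig:
    min_age_years: float = 50.0
    min_history_years: float = 3.0
    observation_window_years: int = 2
    horizon_years: int = 1
    control_buffer_years: int = 2
    min_case_preindex_years: float = 3.0  # history required before the first ADRD code
    min_control_history_years: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.horizon_years <= 10:
            raise ValueError("horizon_years must be in [0, 10]")
        for name in ("min_age_years", "min_history_years", "observation_window_years",
                     "control_buffer_years"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class LabeledPatient:
    patient: PatientRecord
    label: str  # case | control | excluded
    exclusion_reason: Optional[str] = None
    index_week: Optional[int] = None
    age_at_index_years: Optional[float] = None
    risk_stratum: Optional[str] = None  # high | low
    window: Optional[dict[str, frozenset[str]]] = None

    def __post_init__(self) -> None:
        if (self.label == EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("label=excluded iff exclusion_reason present")


def _prefix_match(code: str, prefixes: frozenset[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def label_patient(patient: PatientRecord, defn: CaseDefinition) -> tuple[str, Optional[str]]:
    """Classify a patient as case / control / excluded (with reason).

    Case: any DX event matching the ADRD list, or any RX event matching the
    anti-dementia list.  Otherwise control, unless a DX event matches the
    exclusion list (conditions associated with or causally related to
    dementia), in which case the patient is excluded.
    """
    for e in patient.events:
        if e.channel == "DX" and _prefix_match(e.code, defn.adrd_dx_codes):
            return CASE, None
        if e.channel == "RX" and _prefix_match(e.code, defn.anti_dementia_rx_codes):
            return CASE, None
    for e in patient.events:
        if e.channel == "DX" and _prefix_match(e.code, defn.exclusion_codes):
            return EXCLUDED, "exclusion-code"
    return CONTROL, None


def first_qualifying_week(patient: PatientRecord, defn: CaseDefinition) -> int:
    """Week of the earliest ADRD-defining event (DX or anti-dementia RX)."""
    weeks = [
        e.week
        for e in patient.events
        if (e.channel == "DX" and _prefix_match(e.code, defn.adrd_dx_codes))
        or (e.channel == "RX" and _prefix_match(e.code, defn.anti_dementia_rx_codes))
    ]
    if not weeks:
        raise ValueError("patient has no ADRD-defining event")
    return min(weeks)


def assign_index(
    patient: PatientRecord,
    label: str,
    defn: CaseDefinition,
    config: CohortConfig,
) -> tuple[Optional[int], Optional[str]]:
    """Assign the index week, or return an exclusion reason.

    Cases: index = first ADRD-defining week − max(1, horizon)·52; excluded
    when less than ``min_case_preindex_years`` of history precede the first
    ADRD code.  Controls: index = end-of-record − max(buffer, horizon+1)·52;
    excluded when total history is shorter than ``min_control_history_years``.
    """
    if label == EXCLUDED:
        raise ValueError("cannot assign an index to an excluded patient")
    h = config.horizon_years
    if label == CASE:
        fw = first_qualifying_week(patient, defn)
        if fw - patient.first_event_week < config.min_case_preindex_years * WEEKS_PER_YEAR:
            return None, "case-history<%gy-before-first-ADRD" % config.min_case_preindex_years
        return fw - max(1, h) * WEEKS_PER_YEAR, None
    # control
    if patient.history_span_weeks < config.min_control_history_years * WEEKS_PER_YEAR:
        return None, "control-history<%gy" % config.min_control_history_years
    return patient.record_end_week - max(config.control_buffer_years, h + 1) * WEEKS_PER_YEAR, None


def age_at_week(patient: PatientRecord, week: int) -> float:
    return (week - patient.birth_week) / AGE_WEEKS_PER_YEAR


def apply_eligibility(
    patient: PatientRecord,
    label: str,
    index_week: int,
    config: CohortConfig,
) -> Optional[str]:
    """Return an exclusion reason, or None when the patient is eligible."""
    if age_at_week(patient, index_week) < config.min_age_years:
        return "age<%g" % config.min_age_years
    if patient.history_span_weeks < config.min_history_years * WEEKS_PER_YEAR:
        return "history<%gy" % config.min_history_years
    return None


def extract_window(
    patient: PatientRecord, index_week: int, config: CohortConfig
) -> dict[str, frozenset[str]]:
    """Per-channel code sets in the observation window [index−104, index).

    Half-open on the right: the index week itself is excluded.  Empty
    windows are permitted.
    """
    lo = index_week - config.observation_window_years * WEEKS_PER_YEAR
    out: dict[str, set[str]] = {name: set() for name in CHANNELS}
    for e in patient.events:
        if lo <= e.week < index_week:
            out[e.channel].add(e.code)
    return {name: frozenset(codes) for name, codes in out.items()}


def assign_risk_stratum(window: dict[str, frozenset[str]], defn: CaseDefinition) -> str:
    """``high`` iff any DX code in the window prefix-matches a known ADRD comorbidity."""
    for code in window.get("DX", frozenset()):
        if _prefix_match(code, defn.comorbidity_risk_codes):
            return "high"
    return "low"


def build_cohort(
    patients: Iterable[PatientRecord],
    defn: CaseDefinition,
    config: CohortConfig,
) -> tuple[list[LabeledPatient], Counter]:
    """Run the full labeling pipeline and keep CONSORT-style accounting.

    Returns every input patient exactly once, as included case/control (with
    index, age, window, risk stratum) or excluded with a machine-readable
    reason.  The accounting counter satisfies: included + sum over exclusion
    reasons == number of inputs.
    """
    out: list[LabeledPatient] = []
    tally: Counter = Counter()
    for p in patients:
        label, reason = label_patient(p, defn)
        if label == EXCLUDED:
            tally[f"excluded:{reason}"] += 1
            out.append(LabeledPatient(patient=p, label=EXCLUDED, exclusion_reason=reason))
            continue
        index_week, reason = assign_index(p, label, defn, config)
        if reason is None:
            reason = apply_eligibility(p, label, index_week, config)
        if reason is not None:
            tally[f"excluded:{reason}"] += 1
            out.append(LabeledPatient(patient=p, label=EXCLUDED, exclusion_reason=reason))
            continue
        window = extract_window(p, index_week, config)
        out.append(
            LabeledPatient(
                patient=p,
                label=label,
                index_week=index_week,
                age_at_index_years=age_at_week(p, index_week),
                risk_stratum=assign_risk_stratum(window, defn),
                window=window,
            )
        )
        tally[f"included:{label}"] += 1
    return out, tally


def consort_table(tally: Counter, path: str | Path | None = None) -> str:
    """Render (and optionally write) the reason -> count accounting as TSV."""
    lines = ["reason\tcount"]
    for reason in sorted(tally):
        lines.append(f"{reason}\t{tally[reason]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# JSON-lines I/O


def _patient_from_obj(obj: dict, normalize: bool) -> PatientRecord:
    for key in ("patient_id", "sex", "birth_week", "record_end_week", "events"):
        if key not in obj:
            raise ValueError(f"patient record missing field {key!r}")
    if not isinstance(obj["events"], list):
        raise ValueError("events must be a list")
    events = []
    for ev in obj["events"]:
        for key in ("channel", "code", "week"):
            if key not in ev:
                raise ValueError(f"event missing field {key!r}")
        code = str(ev["code"])
        if normalize:
            code = normalize_code(code, CHANNELS[ev["channel"]])
        events.append(CodedEvent(channel=ev["channel"], code=code, week=int(ev["week"])))
    return PatientRecord(
        patient_id=str(obj["patient_id"]),
        sex=obj["sex"],
        birth_week=int(obj["birth_week"]),
        record_end_week=int(obj["record_end_week"]),
        events=tuple(events),
    )


def read_patients(path: str | Path, normalize: bool = True) -> list[PatientRecord]:
    """Read patients from JSON-lines; codes are normalized unless disabled."""
    patients = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                patients.append(_patient_from_obj(obj, normalize))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed patient record: {exc}") from exc
    return patients


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in patients:
            obj = {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_week": p.birth_week,
                "record_end_week": p.record_end_week,
                "events": [
                    {"channel": e.channel, "code": e.code, "week": e.week} for e in p.events
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def load_code_list(path: str | Path) -> tuple[str, frozenset[str]]:
    """Read a plain-text code list: a ``# role: <role>`` header, one prefix per line."""
    role = None
    prefixes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("role:"):
                role = body[5:].strip()
            continue
        prefixes.append(line)
    if role is None:
        raise ValueError(f"{path}: missing '# role:' header")
    return role, frozenset(prefixes)
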