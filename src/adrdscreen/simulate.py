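"""Synthetic EHR cohort generator with known ground truth.

Real claims cohorts of the kind this package targets cannot be shared, so
every pipeline component is exercised against simulated patients that
reproduce the statistical structure the method assumes: per-channel code
streams over weekly time, case/control contrasts in code frequency
(planted per-code class-conditional rates), demographics, enrollment
geometry compatible with the cohort module's index rules, and label noise
with known sensitivity/specificity.

Codes are sampled independently given class — no within-patient
correlation — which is sufficient for effect-recovery tests; an optional
shared latent factor adds block correlation for robustness checks.
Planted codes are placed inside the observation window (so the configured
class-conditional window rates are the ground truth by construction);
background codes scatter uniformly over the whole record span.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import (
    WEEKS_PER_YEAR,
    AGE_WEEKS_PER_YEAR,
    CaseDefinition,
    CodedEvent,
    CohortConfig,
    PatientRecord,
)
from .lambda_or import NoisyTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "default_case_definition",
    "default_planted_effects",
    "generate_cohort",
    "corrupt_labels",
    "make_2x2",
    "simulate_noisy_table",
]


def default_case_definition() -> CaseDefinition:
    """Code-prefix lists used by the generator (stand-ins for real ICD lists).

    ADRD diagnoses live in the F0*/G30 families, the anti-dementia
    prescription stem is ``rxAD``, exclusions cover delirium and other
    degenerative diseases, and the comorbidity (high-risk) list names
    common cardiometabolic and pulmonary prefixes.
    """
    return CaseDefinition(
        adrd_dx_codes=frozenset({"F00", "F01", "F02", "F03", "G30"}),
        anti_dementia_rx_codes=frozenset({"rxAD"}),
        exclusion_codes=frozenset({"F05", "G31"}),
        comorbidity_risk_codes=frozenset({"E11", "I10", "I25", "I50", "J44"}),
    )


#: ADRD-defining DX codes appended after the index for true cases.
_ADRD_EVENT_CODES = ("G309", "F03", "F019")

#: DX initial letters for synthetic background/planted codes; F, G and S are
#: reserved for the case/exclusion definitions above.
_DX_LETTERS = "ABCDEHIJKLMNR"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters; the defaults are the study conditions.

    The default class mix (3.8% cases) mirrors large administrative-claims
    cohorts; planted-code rate contrasts span the 2–4× range typical of
    reported ADRD comorbidity prevalence ratios.
    """

    n_case: int = 380
    n_control: int = 9620
    seed: int = 0
    vocab_size: Mapping[str, int] = field(
        default_factory=lambda: {"DX": 150, "RX": 60, "PROC": 100}
    )
    n_planted: Mapping[str, int] = field(
        default_factory=lambda: {"DX": 10, "RX": 5, "PROC": 5}
    )
    planted_effects: Optional[Mapping[str, Mapping[str, tuple[float, float]]]] = None
    mean_codes_per_patient: Mapping[str, float] = field(
        default_factory=lambda: {"DX": 6.0, "RX": 3.0, "PROC": 4.0}
    )
    label_noise: Optional[tuple[float, float]] = None  # (p, q)
    sex_female_fraction: float = 0.55
    age_mean_case: float = 74.0
    age_mean_control: float = 68.0
    age_sd: float = 8.0
    min_preindex_history_years: float = 4.0
    max_preindex_history_years: float = 10.0
    horizon_years: int = 1
    observation_window_years: int = 2
    control_buffer_years: int = 2
    latent_factor_weight: float = 0.0  # optional block correlation in [0, 1)

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.planted_effects is not None:
            for ch, effects in self.planted_effects.items():
                for code, (rc, rn) in effects.items():
                    if not (0 <= rc <= 1 and 0 <= rn <= 1):
                        raise ValueError(f"rates for {code} must lie in [0, 1]")
        if not 0 <= self.latent_factor_weight < 1:
            raise ValueError("latent_factor_weight must lie in [0, 1)")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            horizon_years=self.horizon_years,
            observation_window_years=self.observation_window_years,
            control_buffer_years=self.control_buffer_years,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient true labels and the planted effects that generated them."""

    true_labels: dict[str, int]
    planted_effects: dict[str, dict[str, tuple[float, float]]]
    label_noise: Optional[tuple[float, float]]

    def true_rate_ratio(self, channel: str, code: str) -> float:
        rc, rn = self.planted_effects[channel][code]
        return rc / rn

    def true_odds_ratio(self, channel: str, code: str) -> float:
        rc, rn = self.planted_effects[channel][code]
        return (rc / (1 - rc)) / (rn / (1 - rn))


def _make_vocab(rng: np.random.Generator, channel: str, size: int) -> list[str]:
    codes: set[str] = set()
    while len(codes) < size:
        if channel == "DX":
            code = rng.choice(list(_DX_LETTERS)) + "".join(
                str(d) for d in rng.integers(0, 10, size=int(rng.integers(2, 5)))
            )
        elif channel == "RX":
            stem = "".join(rng.choice(list(string.ascii_uppercase), size=3))
            if stem.startswith("AD"):
                continue
            code = "rx" + stem + str(int(rng.integers(1, 10)))
        else:  # PROC
            code = "".join(str(d) for d in rng.integers(0, 10, size=5))
        codes.add(str(code))
    return sorted(codes)


def default_planted_effects(
    rng: np.random.Generator,
    vocabs: Mapping[str, Sequence[str]],
    n_planted: Mapping[str, int],
    rate_ratio_range: tuple[float, float] = (2.0, 4.0),
    control_rate_range: tuple[float, float] = (0.03, 0.30),
) -> dict[str, dict[str, tuple[float, float]]]:
    """Draw planted per-code (case-rate, control-rate) pairs from each vocabulary."""
    effects: dict[str, dict[str, tuple[float, float]]] = {}
    for ch, k in n_planted.items():
        chosen = rng.choice(len(vocabs[ch]), size=k, replace=False)
        effects[ch] = {}
        for i in chosen:
            lo, hi = control_rate_range
            rn = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ratio = float(rng.uniform(*rate_ratio_range))
            effects[ch][vocabs[ch][int(i)]] = (min(ratio * rn, 0.9), rn)
    return effects


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a synthetic cohort and its ground truth, deterministically.

    Each patient has an anchor DX event at week 0, background events over
    the record span, planted codes in the observation window at their
    class-conditional rates, and — for true cases — an ADRD-defining code
    placed exactly ``max(1, horizon)`` years after the index so the cohort
    module recovers the planted index and label.
    """
    rng = np.random.default_rng(config.seed)
    vocabs = {ch: _make_vocab(rng, ch, n) for ch, n in config.vocab_size.items()}
    effects = config.planted_effects
    if effects is None:
        effects = default_planted_effects(rng, vocabs, config.n_planted)
    effects = {ch: dict(codes) for ch, codes in effects.items()}
    planted = {ch: set(codes) for ch, codes in effects.items()}
    background = {
        ch: [c for c in vocabs[ch] if c not in planted.get(ch, set())] for ch in vocabs
    }

    h = config.horizon_years
    window_weeks = config.observation_window_years * WEEKS_PER_YEAR
    patients: list[PatientRecord] = []
    true_labels: dict[str, int] = {}
    n_total = config.n_case + config.n_control
    for i in range(n_total):
        is_case = i < config.n_case
        pid = f"P{i:06d}"
        true_labels[pid] = int(is_case)
        index_week = int(
            rng.integers(
                int(config.min_preindex_history_years * WEEKS_PER_YEAR),
                int(config.max_preindex_history_years * WEEKS_PER_YEAR) + 1,
            )
        )
        if is_case:
            first_adrd = index_week + max(1, h) * WEEKS_PER_YEAR
            record_end = first_adrd + int(rng.integers(0, WEEKS_PER_YEAR))
        else:
            record_end = index_week + max(config.control_buffer_years, h + 1) * WEEKS_PER_YEAR
        age_mean = config.age_mean_case if is_case else config.age_mean_control
        age = float(np.clip(rng.normal(age_mean, config.age_sd), 52.0, 95.0))
        birth_week = int(round(index_week - age * AGE_WEEKS_PER_YEAR))
        sex = "female" if rng.random() < config.sex_female_fraction else "male"

        events: list[CodedEvent] = []
        # anchor: the first DX code defines week 0
        events.append(CodedEvent("DX", str(rng.choice(background["DX"])), 0))
        # optional shared latent severity factor for block correlation
        w = config.latent_factor_weight
        latent = rng.random() if w > 0 else 0.5
        for ch, codes in effects.items():
            for code, (rate_case, rate_ctrl) in codes.items():
                rate = rate_case if is_case else rate_ctrl
                if w > 0:
                    rate = np.clip((1 - w) * rate + w * rate * 2 * latent, 0.0, 1.0)
                if rng.random() < rate:
                    week = int(rng.integers(index_week - window_weeks, index_week))
                    events.append(CodedEvent(ch, code, week))
        for ch, mean in config.mean_codes_per_patient.items():
            k = rng.poisson(mean)
            if k == 0:
                continue
            for code in rng.choice(background[ch], size=k, replace=True):
                week = int(rng.integers(0, record_end + 1))
                events.append(CodedEvent(ch, str(code), week))
        if is_case:
            events.append(
                CodedEvent("DX", str(rng.choice(_ADRD_EVENT_CODES)), first_adrd)
            )
        events.sort(key=lambda e: (e.week, e.channel, e.code))
        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                birth_week=birth_week,
                record_end_week=record_end,
                events=tuple(events),
            )
        )
    truth = GroundTruth(
        true_labels=true_labels,
        planted_effects=effects,
        label_noise=config.label_noise,
    )
    return patients, truth


def corrupt_labels(
    true_labels: Mapping[str, int], p: float, q: float, seed: int
) -> dict[str, int]:
    """Flip labels independently: cases kept with probability p (sensitivity),
    controls kept with probability q (specificity)."""
    if not (0 < p <= 1) or not (0 < q <= 1):
        raise ValueError("p and q must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    noisy = {}
    for pid in sorted(true_labels):
        y = true_labels[pid]
        u = rng.random()
        noisy[pid] = (1 if u < p else 0) if y == 1 else (1 if u >= q else 0)
    return noisy


def make_2x2(
    patients: Sequence[PatientRecord],
    noisy_labels: Mapping[str, int],
    code: str,
    channel: Optional[str] = None,
) -> NoisyTable:
    """Cross-tabulate exposure (exact code match anywhere in the record,
    optionally restricted to one channel) against noisy labels."""
    a = b = c = d = 0
    for p in patients:
        exposed = any(
            e.code == code and (channel is None or e.channel == channel)
            for e in p.events
        )
        y = noisy_labels[p.patient_id]
        if exposed and y == 1:
            a += 1
        elif exposed:
            b += 1
        elif y == 1:
            c += 1
        else:
            d += 1
    return NoisyTable(a, b, c, d)


def simulate_noisy_table(
    true_log_or: float,
    n: int,
    p: float,
    q: float,
    seed: int,
    exposure_rate: float = 0.3,
    base_rate: float = 0.3,
) -> tuple[NoisyTable, np.ndarray]:
    """Draw one noisy 2×2 table with a planted true log odds ratio.

    ``base_rate`` is the true-case probability among the unexposed; the
    exposed probability follows from the planted odds ratio.  Labels are
    flipped with sensitivity ``p`` and specificity ``q``.  Returns the
    observed table and the latent true table [[a, b], [c, d]].
    """
    rng = np.random.default_rng(seed)
    odds0 = base_rate / (1 - base_rate)
    odds1 = odds0 * np.exp(true_log_or)
    rate1 = odds1 / (1 + odds1)
    n_exp = rng.binomial(n, exposure_rate)
    n_unexp = n - n_exp
    a_true = rng.binomial(n_exp, rate1)
    b_true = n_exp - a_true
    c_true = rng.binomial(n_unexp, base_rate)
    d_true = n_unexp - c_true
    # independent per-subject flips, aggregated binomially
    a_obs = rng.binomial(a_true, p) + rng.binomial(b_true, 1 - q)
    b_obs = a_true + b_true - a_obs
    c_obs = rng.binomial(c_true, p) + rng.binomial(d_true, 1 - q)
    d_obs = c_true + d_true - c_obs
    true_table = np.array([[a_true, b_true], [c_true, d_true]], dtype=float)
    return NoisyTable(a_obs, b_obs, c_obs, d_obs), true_table
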