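"""Per-patient feature blocks: code-presence vectors and odds-ratio embeddings.

Each observation window yields six blocks — for every channel (DX, RX, PROC)
a binary presence vector over the augmented vocabulary, and a fixed-length
summary of the per-code cubed odds ratios of the window's codes.  Both
representations use membership semantics: a code repeated within one window
contributes once.

Odds-ratio dictionaries compare, per code, the fraction of case patients
whose window contains the code against the same fraction among controls,
and cube the ratio to sharpen contrast.  Fractions use additive
(Haldane–Anscombe-style) smoothing so codes absent from one class never
produce zero or infinite ratios.  Dictionaries and vocabularies are fitted
on the code inference split (the training split) only; each carries a
fingerprint of the patient ids it was fitted on so downstream assembly can
refuse leakage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .codes import CHANNELS, CodeChannel, CodeVocabulary, expand_prefixes

__all__ = [
    "DEFAULT_AGGREGATIONS",
    "AggregationSet",
    "ORDictionary",
    "FeatureBundle",
    "compute_presence",
    "fit_or_dictionary",
    "compute_or_embedding",
    "assemble_features",
    "build_feature_matrix",
    "split_fingerprint",
    "BLOCKS",
]

#: Canonical block order: presence then OR embedding, channels DX, RX, PROC.
BLOCKS = (
    "DX-presence",
    "RX-presence",
    "PROC-presence",
    "DX-OR",
    "RX-OR",
    "PROC-OR",
)


def _geometric_mean(v: np.ndarray) -> float:
    # values are nonnegative; any exact zero collapses the product
    if np.any(v <= 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


#: The 12 default aggregation summaries: location, scale, extremes and tail
#: quantiles of the window's OR multiset.  Every function has empty value 0.
DEFAULT_AGGREGATIONS: dict[str, Callable[[np.ndarray], float]] = {
    "min": lambda v: float(np.min(v)),
    "max": lambda v: float(np.max(v)),
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),
    "std": lambda v: float(np.std(v)),
    "sum": lambda v: float(np.sum(v)),
    "count": lambda v: float(v.size),
    "p10": lambda v: float(np.percentile(v, 10)),
    "p25": lambda v: float(np.percentile(v, 25)),
    "p75": lambda v: float(np.percentile(v, 75)),
    "p90": lambda v: float(np.percentile(v, 90)),
    "gmean": _geometric_mean,
}


@dataclass(frozen=True)
class AggregationSet:
    """Exactly 12 named summary functions mapping a multiset of reals to one real."""

    names: tuple[str, ...] = tuple(DEFAULT_AGGREGATIONS)
    functions: tuple[Callable[[np.ndarray], float], ...] = tuple(
        DEFAULT_AGGREGATIONS.values()
    )
    empty_value: float = 0.0

    def __post_init__(self) -> None:
        if len(self.names) != 12 or len(self.functions) != 12:
            raise ValueError("an AggregationSet must contain exactly 12 functions")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if values.size == 0:
            return np.full(12, self.empty_value)
        return np.array([f(values) for f in self.functions], dtype=float)


def split_fingerprint(patient_ids: Iterable[str]) -> str:
    """Order-independent digest of a patient-id split."""
    h = hashlib.sha256()
    for pid in sorted(patient_ids):
        h.update(pid.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


@dataclass(frozen=True)
class ORDictionary:
    """Per-code cubed odds ratios estimated on the labeled inference split."""

    channel: CodeChannel
    ratios: Mapping[str, float]
    case_n: int
    control_n: int
    smoothing: float = 0.5
    fingerprint: str = ""
    training_ids: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.ratios.values()):
            raise ValueError("odds ratios must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as (code, value) TSV with a JSON sidecar of metadata."""
        path = Path(path)
        lines = ["code\tcubed_or"]
        for code in sorted(self.ratios):
            lines.append(f"{code}\t{self.ratios[code]!r}")
        path.write_text("\n".join(lines) + "\n")
        meta = {
            "channel": self.channel.name,
            "case_n": self.case_n,
            "control_n": self.control_n,
            "smoothing": self.smoothing,
            "fingerprint": self.fingerprint,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ORDictionary":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        ratios = {}
        for line in path.read_text().splitlines()[1:]:
            code, value = line.split("\t")
            ratios[code] = float(value)
        return cls(
            channel=CHANNELS[meta["channel"]],
            ratios=ratios,
            case_n=meta["case_n"],
            control_n=meta["control_n"],
            smoothing=meta["smoothing"],
            fingerprint=meta["fingerprint"],
        )


def compute_presence(window: frozenset[str] | set[str], vocab: CodeVocabulary) -> np.ndarray:
    """Binary vector over the vocabulary for one window's code set.

    Bit i is set iff vocabulary entry i is a window code or a tracked-length
    prefix of a window code.  Codes entirely unseen at fit time contribute
    only through whatever of their prefixes the vocabulary knows.
    """
    observed: set[str] = set()
    for code in window:
        observed.update(expand_prefixes(code, vocab.channel))
    vec = np.zeros(len(vocab), dtype=np.uint8)
    index = vocab.index
    for entry in observed:
        i = index.get(entry)
        if i is not None:
            vec[i] = 1
    return vec


def fit_or_dictionary(
    case_windows: Sequence[frozenset[str]],
    control_windows: Sequence[frozenset[str]],
    channel: CodeChannel,
    smoothing: float = 0.5,
    case_ids: Optional[Iterable[str]] = None,
    control_ids: Optional[Iterable[str]] = None,
) -> ORDictionary:
    """Estimate the cubed odds-ratio dictionary for one channel.

    For each full code observed in the split (prefixes excluded), the ratio
    of the smoothed case patient-fraction carrying the code to the smoothed
    control patient-fraction, cubed:

        OR(c) = [ (k_case + s) / (n_case + 2s)  /  ((k_ctrl + s) / (n_ctrl + 2s)) ]^3
    """
    n_case, n_ctrl = len(case_windows), len(control_windows)
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("fitting an OR dictionary requires at least one case and one control")
    codes: set[str] = set()
    for w in case_windows:
        codes.update(w)
    for w in control_windows:
        codes.update(w)
    s = smoothing
    ratios: dict[str, float] = {}
    case_counts: dict[str, int] = {}
    ctrl_counts: dict[str, int] = {}
    for w in case_windows:
        for c in w:
            case_counts[c] = case_counts.get(c, 0) + 1
    for w in control_windows:
        for c in w:
            ctrl_counts[c] = ctrl_counts.get(c, 0) + 1
    for c in codes:
        f_case = (case_counts.get(c, 0) + s) / (n_case + 2 * s)
        f_ctrl = (ctrl_counts.get(c, 0) + s) / (n_ctrl + 2 * s)
        ratios[c] = (f_case / f_ctrl) ** 3
    ids: list[str] = []
    if case_ids is not None:
        ids.extend(case_ids)
    if control_ids is not None:
        ids.extend(control_ids)
    return ORDictionary(
        channel=channel,
        ratios=ratios,
        case_n=n_case,
        control_n=n_ctrl,
        smoothing=smoothing,
        fingerprint=split_fingerprint(ids) if ids else "",
        training_ids=frozenset(ids) if ids else None,
    )


def compute_or_embedding(
    window: frozenset[str] | set[str],
    or_dict: ORDictionary,
    aggs: AggregationSet = AggregationSet(),
) -> np.ndarray:
    """Summarize the window's dictionary ORs into the 12-vector embedding.

    Duplicate codes contribute once (membership semantics); codes absent
    from the dictionary are dropped; an empty collection yields each
    aggregation's declared empty value.
    """
    values = np.array(
        sorted(or_dict.ratios[c] for c in set(window) if c in or_dict.ratios),
        dtype=float,
    )
    return aggs.apply(values)


@dataclass(frozen=True)
class FeatureBundle:
    """The six feature blocks plus sex and age for one patient."""

    presence: dict[str, np.ndarray]  # channel -> binary vector
    or_embedding: dict[str, np.ndarray]  # channel -> 12-vector
    sex: int  # 0 = male, 1 = female
    age_at_index_years: float

    def __post_init__(self) -> None:
        for ch, vec in self.or_embedding.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite OR embedding for channel {ch}")


def assemble_features(
    windows: Mapping[str, frozenset[str]],
    vocabs: Mapping[str, CodeVocabulary],
    or_dicts: Mapping[str, ORDictionary],
    sex: int,
    age_at_index_years: float,
    aggs: AggregationSet = AggregationSet(),
    eval_patient_id: Optional[str] = None,
) -> FeatureBundle:
    """Assemble the full feature bundle for one patient.

    When ``eval_patient_id`` is given, refuses OR dictionaries whose
    training-id set contains the patient — the leakage guard for evaluation
    patients.
    """
    for name in ("DX", "RX", "PROC"):
        if name not in vocabs or name not in or_dicts:
            raise ValueError(f"missing vocabulary or OR dictionary for channel {name}")
        if vocabs[name].channel.name != name or or_dicts[name].channel.name != name:
            raise ValueError(f"channel mismatch for {name}")
    if eval_patient_id is not None:
        for name, d in or_dicts.items():
            if d.training_ids is not None and eval_patient_id in d.training_ids:
                raise ValueError(
                    f"leakage: OR dictionary for {name} was fitted on evaluation "
                    f"patient {eval_patient_id!r}"
                )
    presence = {
        name: compute_presence(windows.get(name, frozenset()), vocabs[name])
        for name in ("DX", "RX", "PROC")
    }
    or_emb = {
        name: compute_or_embedding(windows.get(name, frozenset()), or_dicts[name], aggs)
        for name in ("DX", "RX", "PROC")
    }
    return FeatureBundle(
        presence=presence,
        or_embedding=or_emb,
        sex=sex,
        age_at_index_years=age_at_index_years,
    )


def build_feature_matrix(
    window_list: Sequence[Mapping[str, frozenset[str]]],
    vocabs: Mapping[str, CodeVocabulary],
    or_dicts: Mapping[str, ORDictionary],
    aggs: AggregationSet = AggregationSet(),
) -> tuple[dict[str, np.ndarray], dict]:
    """Stack per-patient blocks into per-block matrices plus a manifest.

    Returns ``(blocks, manifest)`` where ``blocks`` maps each of the six
    block names to an (n_patients, n_features) array and ``manifest``
    records block dimensions and vocabulary fingerprints for downstream
    compatibility checks.
    """
    n = len(window_list)
    blocks: dict[str, np.ndarray] = {}
    for name in ("DX", "RX", "PROC"):
        pres = np.zeros((n, len(vocabs[name])), dtype=np.uint8)
        ors = np.zeros((n, 12), dtype=float)
        for i, windows in enumerate(window_list):
            w = windows.get(name, frozenset())
            pres[i] = compute_presence(w, vocabs[name])
            ors[i] = compute_or_embedding(w, or_dicts[name], aggs)
        blocks[f"{name}-presence"] = pres
        blocks[f"{name}-OR"] = ors
    manifest = {
        "blocks": {b: int(blocks[b].shape[1]) for b in BLOCKS},
        "vocab_fingerprints": {name: vocabs[name].fingerprint for name in vocabs},
        "aggregations": list(aggs.names),
    }
    return blocks, manifest
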