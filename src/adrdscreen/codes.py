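"""Code-system handling for multi-channel EHR streams.

Three channels of coded events are supported: diagnoses (``DX``, ICD-10),
prescriptions (``RX``, a custom therapeutic coding of NDC drug products) and
procedures (``PROC``).  Codes in all three systems are hierarchical: a longer
code refines a shorter one.  To let models generalize across coding
granularity, every code is expanded into the set of its prefixes at a fixed,
channel-specific list of lengths, and vocabularies track both the full codes
and the observed prefixes.

The RX scheme re-maps product-level NDC identifiers onto a readable
therapeutic hierarchy: ``"rx"`` + therapeutic group + class + subclass
(single characters, ``"X"`` when absent or not-elsewhere-classifiable)
+ a numeric ordinal identifying the generic drug within its five-character
therapeutic stem.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CodeChannel",
    "DX",
    "RX",
    "PROC",
    "CHANNELS",
    "CodeVocabulary",
    "DrugAttributeRow",
    "normalize_code",
    "expand_prefixes",
    "build_vocabulary",
    "build_rx_code",
    "assign_rx_ordinals",
    "read_drug_table",
]

#: Attribute values treated as "absent" when building rx codes (configurable
#: sentinel set; NEC = not elsewhere classifiable).
PLACEHOLDER_SENTINELS = frozenset({"", "NEC", "X", None})

#: Placeholder character substituted for absent therapeutic attributes.
PLACEHOLDER_CHAR = "X"


@dataclass(frozen=True)
class CodeChannel:
    """A coded-data channel and the prefix lengths tracked for it."""

    name: str
    prefix_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.name not in {"DX", "RX", "PROC"}:
            raise ValueError(f"unknown channel name {self.name!r}")
        if list(self.prefix_lengths) != sorted(set(self.prefix_lengths)):
            raise ValueError("prefix_lengths must be strictly increasing")


DX = CodeChannel("DX", (1, 2, 3, 5, 6))
RX = CodeChannel("RX", (3, 4, 5, 8))
PROC = CodeChannel("PROC", (1, 2, 3, 4, 5))

CHANNELS: Mapping[str, CodeChannel] = {"DX": DX, "RX": RX, "PROC": PROC}


def normalize_code(code: str, channel: CodeChannel) -> str:
    """Normalize a raw code string for ``channel``.

    Whitespace and dots are stripped (ICD-10 is conventionally written both
    dotted and dotless).  DX and PROC codes are uppercased; RX codes keep
    their lowercase ``rx`` marker with the remainder uppercased.
    """
    code = code.strip().replace(".", "")
    if channel.name == "RX" and code[:2].lower() == "rx":
        return "rx" + code[2:].upper()
    return code.upper()


def expand_prefixes(code: str, channel: CodeChannel) -> list[str]:
    """Return ``code`` plus every tracked-length prefix strictly shorter than it.

    The list is deduplicated and ordered short to long with the full code
    last.  The full code is always included, even when its own length is not
    a tracked prefix length.

    >>> expand_prefixes("I2510", DX)
    ['I', 'I2', 'I25', 'I2510']
    """
    if not code:
        raise ValueError("empty code")
    out = [code[:n] for n in channel.prefix_lengths if n < len(code)]
    out.append(code)
    return out


@dataclass(frozen=True)
class CodeVocabulary:
    """Ordered set of codes and tracked prefixes observed in an inference split."""

    channel: CodeChannel
    entries: tuple[str, ...]
    source_count: int = 0

    def __post_init__(self) -> None:
        if any(not e for e in self.entries):
            raise ValueError("vocabulary entries must be non-empty strings")
        if list(self.entries) != sorted(set(self.entries)):
            raise ValueError("vocabulary entries must be sorted and unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.index

    @property
    def index(self) -> dict[str, int]:
        """Entry -> position mapping (cached on first use)."""
        idx = self.__dict__.get("_index")
        if idx is None:
            idx = {e: i for i, e in enumerate(self.entries)}
            self.__dict__["_index"] = idx
        return idx

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.channel.name.encode())
        for e in self.entries:
            h.update(e.encode())
            h.update(b"\n")
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        """Write one entry per line, plain text."""
        Path(path).write_text("\n".join(self.entries) + ("\n" if self.entries else ""))

    @classmethod
    def load(cls, path: str | Path, channel: CodeChannel) -> "CodeVocabulary":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(channel=channel, entries=tuple(sorted(set(lines))))


def build_vocabulary(
    records: Iterable[Iterable[str]], channel: CodeChannel
) -> CodeVocabulary:
    """Build the augmented vocabulary from per-patient code sets.

    Every observed full code and each of its tracked-length prefixes enters
    the vocabulary.  The result is deterministic (lexicographic order) given
    the same input multiset.  Records must come from the designated code
    inference split only; fitting on evaluation patients leaks label
    information downstream.
    """
    entries: set[str] = set()
    n = 0
    for rec in records:
        n += 1
        for code in rec:
            entries.update(expand_prefixes(code, channel))
    if n == 0:
        warnings.warn(f"building {channel.name} vocabulary from zero records")
    return CodeVocabulary(channel=channel, entries=tuple(sorted(entries)), source_count=n)


@dataclass(frozen=True)
class DrugAttributeRow:
    """One NDC product with its therapeutic attributes and generic name."""

    ndc: str
    generic_name: str
    therapeutic_group: Optional[str] = None
    therapeutic_class: Optional[str] = None
    therapeutic_subclass: Optional[str] = None


def _attr_char(value: Optional[str], sentinels: frozenset = PLACEHOLDER_SENTINELS) -> str:
    if value is None or value in sentinels:
        return PLACEHOLDER_CHAR
    if len(value) != 1:
        raise ValueError(f"therapeutic attribute must be a single character, got {value!r}")
    return value


def build_rx_code(
    row: DrugAttributeRow,
    ordinal: int,
    sentinels: frozenset = PLACEHOLDER_SENTINELS,
) -> str:
    """Assemble the therapeutic rx code for one generic drug.

    ``"rx"`` + group + class + subclass characters (placeholder ``"X"`` for
    absent / not-elsewhere-classifiable attributes) + the decimal ordinal of
    the generic within its therapeutic stem, no padding.

    >>> build_rx_code(DrugAttributeRow("0", "zzz", "C", "H", "D"), 4)
    'rxCHD4'
    """
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    return (
        "rx"
        + _attr_char(row.therapeutic_group, sentinels)
        + _attr_char(row.therapeutic_class, sentinels)
        + _attr_char(row.therapeutic_subclass, sentinels)
        + str(ordinal)
    )


def assign_rx_ordinals(
    table: Sequence[DrugAttributeRow],
    sentinels: frozenset = PLACEHOLDER_SENTINELS,
) -> dict[str, str]:
    """Map every NDC to its therapeutic rx code.

    All NDC package variants of the same generic drug share one code.
    Within each five-character therapeutic stem, distinct generic drugs are
    numbered 1..k in lexicographic order of generic name, so the mapping is
    a pure function of the table contents (row order is irrelevant).
    """
    seen: set[str] = set()
    for row in table:
        if row.ndc in seen:
            raise ValueError(f"duplicate ndc {row.ndc!r}")
        seen.add(row.ndc)

    def stem(row: DrugAttributeRow) -> str:
        return (
            "rx"
            + _attr_char(row.therapeutic_group, sentinels)
            + _attr_char(row.therapeutic_class, sentinels)
            + _attr_char(row.therapeutic_subclass, sentinels)
        )

    # generic -> ordinal within each stem, lexicographic by generic name
    by_stem: dict[str, set[str]] = {}
    for row in table:
        by_stem.setdefault(stem(row), set()).add(row.generic_name)
    ordinals = {
        (s, g): i + 1
        for s, generics in by_stem.items()
        for i, g in enumerate(sorted(generics))
    }
    return {
        row.ndc: stem(row) + str(ordinals[(stem(row), row.generic_name)])
        for row in table
    }


def read_drug_table(path: str | Path) -> list[DrugAttributeRow]:
    """Read a drug attribute TSV (ndc, generic_name, therapeutic_group/class/subclass).

    Empty cells denote absent attributes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "ndc",
        "generic_name",
        "therapeutic_group",
        "therapeutic_class",
        "therapeutic_subclass",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            DrugAttributeRow(
                ndc=rec.ndc,
                generic_name=rec.generic_name,
                therapeutic_group=rec.therapeutic_group or None,
                therapeutic_class=rec.therapeutic_class or None,
                therapeutic_subclass=rec.therapeutic_subclass or None,
            )
        )
    return rows
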