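"""Declarative crosswalk from questionnaire items to ICF codes and qualifiers.

Rehabilitation outcome instruments (Barthel index, CIQ, PCRS/PCRSi, DRS,
GOSE, Rancho, ESIG, ...) each score the same underlying functioning
constructs on their own scales.  A *crosswalk* makes the translation
explicit and auditable: every rule names one instrument item, the ICF
category it measures (attribute standardization), and a total map from
the item's admissible raw values to ICF qualifiers (value
standardization).

The canonical worked example is the Barthel index *feeding* item, which
standardizes to *eating* (d550) with raw scores 10, 5 and 0 mapping to
qualifiers 0 (no involvement), 2 (moderate) and 4 (complete) — note the
inversion: Barthel raw scores increase with independence while ICF
qualifiers increase with severity.  Direction is always explicit in the
value map, never inferred.

Crosswalk files are YAML with the structure::

    version: my-crosswalk-1
    instruments:
      - instrument: Barthel
        items:
          - item: feeding
            icf_code: d550
            values: {10: 0, 5: 2, 0: 4}
          - item: total
            icf_code: d230
            values: {"0..20": 4, "21..60": 3, "61..90": 2, "91..99": 1, "100..100": 0}

Raw-value keys are exact matches (numeric or categorical) or closed
integer/float intervals written ``"lo..hi"``; intervals within one item
must not overlap.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .icf_model import ICFCode, Qualifier, parse_code

__all__ = [
    "CrosswalkError",
    "CrosswalkSchemaError",
    "UnmappedItemError",
    "ValueDomainError",
    "InstrumentItem",
    "ValueMatcher",
    "ExactMatch",
    "IntervalMatch",
    "CrosswalkRule",
    "Crosswalk",
    "load_crosswalk",
    "normalize_attribute",
    "normalize_value",
    "KNOWN_INSTRUMENTS",
]

KNOWN_INSTRUMENTS = (
    "Barthel", "CIQ", "PCRS", "PCRSi", "Rancho", "DRS", "GOSE", "ESIG",
)


class CrosswalkError(Exception):
    """Base class for crosswalk problems."""


class CrosswalkSchemaError(CrosswalkError):
    """The crosswalk file violates the documented schema."""


class UnmappedItemError(CrosswalkError, KeyError):
    """An (instrument, item) pair has no rule in the crosswalk."""

    def __init__(self, instrument: str, item: str):
        super().__init__(f"no crosswalk rule for instrument {instrument!r}, item {item!r}")
        self.instrument = instrument
        self.item = item


class ValueDomainError(CrosswalkError, ValueError):
    """A raw value falls outside the admissible domain of an item."""


@dataclass(frozen=True)
class InstrumentItem:
    """One scored item of a questionnaire instrument."""

    instrument: str
    item: str

    def __str__(self) -> str:
        return f"{self.instrument}/{self.item}"


def _coerce_number(value: Any) -> Any:
    """Return a float for numeric-looking values, else the value unchanged."""
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


class ValueMatcher:
    """Abstract admissibility test for one raw-value key of a value map."""

    def matches(self, raw: Any) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def example(self) -> Any:  # pragma: no cover - interface
        """A representative raw value accepted by this matcher."""
        raise NotImplementedError

    def as_key(self) -> Any:  # pragma: no cover - interface
        """The YAML key that round-trips to this matcher."""
        raise NotImplementedError


@dataclass(frozen=True)
class ExactMatch(ValueMatcher):
    value: Any

    def matches(self, raw: Any) -> bool:
        return _coerce_number(raw) == _coerce_number(self.value)

    def example(self) -> Any:
        return self.value

    def as_key(self) -> Any:
        return self.value


@dataclass(frozen=True)
class IntervalMatch(ValueMatcher):
    """Closed numeric interval [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise CrosswalkSchemaError(f"interval bounds out of order: {self.lo}..{self.hi}")

    def matches(self, raw: Any) -> bool:
        v = _coerce_number(raw)
        if not isinstance(v, float):
            return False
        return self.lo <= v <= self.hi

    def overlaps(self, other: "IntervalMatch") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi

    def example(self) -> Any:
        mid = (self.lo + self.hi) / 2.0
        return int(mid) if float(int(mid)) == mid else mid

    def as_key(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(int(x)) == x else str(x)

        return f"{fmt(self.lo)}..{fmt(self.hi)}"


def _parse_value_key(key: Any, where: str) -> ValueMatcher:
    if isinstance(key, str) and ".." in key:
        lo_s, _, hi_s = key.partition("..")
        try:
            return IntervalMatch(float(lo_s), float(hi_s))
        except ValueError as exc:
            raise CrosswalkSchemaError(f"{where}: bad interval key {key!r}") from exc
    return ExactMatch(key)


@dataclass(frozen=True)
class CrosswalkRule:
    """Maps one instrument item to an ICF code with a total value map."""

    source: InstrumentItem
    target: ICFCode
    value_map: tuple[tuple[ValueMatcher, Qualifier], ...]

    def qualifier_for(self, raw: Any) -> Qualifier:
        for matcher, qualifier in self.value_map:
            if matcher.matches(raw):
                return qualifier
        raise ValueDomainError(
            f"raw value {raw!r} is outside the admissible domain of {self.source}"
        )

    def domain_examples(self) -> list[Any]:
        """One representative raw value per value-map entry."""
        return [m.example() for m, _ in self.value_map]

    def raw_for_qualifier(self, q: Qualifier | int) -> Any:
        """A representative raw value mapping to qualifier ``q`` (inverse lookup)."""
        want = q.value if isinstance(q, Qualifier) else q
        for matcher, qualifier in self.value_map:
            if qualifier.value == want:
                return matcher.example()
        raise ValueDomainError(
            f"{self.source}: no raw value maps to qualifier {want}"
        )


@dataclass
class Crosswalk:
    """A versioned collection of crosswalk rules, keyed by (instrument, item)."""

    version: str = "unversioned"
    rules: dict[InstrumentItem, CrosswalkRule] = field(default_factory=dict)

    def add_rule(self, rule: CrosswalkRule) -> None:
        if rule.source in self.rules:
            raise CrosswalkSchemaError(f"duplicate crosswalk entry for {rule.source}")
        self.rules[rule.source] = rule

    def rule_for(self, instrument: str, item: str) -> CrosswalkRule:
        key = InstrumentItem(instrument, item)
        try:
            return self.rules[key]
        except KeyError:
            raise UnmappedItemError(instrument, item) from None

    def target_codes(self) -> set[ICFCode]:
        return {r.target for r in self.rules.values()}

    def items_for_code(self, code: ICFCode | str) -> list[InstrumentItem]:
        text = code.code if isinstance(code, ICFCode) else str(code)
        return [it for it, r in self.rules.items() if r.target.code == text]

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, key: InstrumentItem | tuple[str, str]) -> bool:
        if isinstance(key, tuple):
            key = InstrumentItem(*key)
        return key in self.rules

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        by_instrument: dict[str, list[dict]] = {}
        for item, rule in self.rules.items():
            by_instrument.setdefault(item.instrument, []).append(
                {
                    "item": item.item,
                    "icf_code": rule.target.code,
                    "values": {m.as_key(): q.value for m, q in rule.value_map},
                }
            )
        return {
            "version": self.version,
            "instruments": [
                {"instrument": name, "items": items}
                for name, items in by_instrument.items()
            ],
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_frame(self) -> pd.DataFrame:
        """Flattened one-row-per-value-map-entry table for audit/export."""
        rows = []
        for item, rule in self.rules.items():
            for matcher, qualifier in rule.value_map:
                rows.append(
                    {
                        "instrument": item.instrument,
                        "item": item.item,
                        "icf_code": rule.target.code,
                        "raw_value": matcher.as_key(),
                        "qualifier": qualifier.value,
                    }
                )
        return pd.DataFrame(
            rows, columns=["instrument", "item", "icf_code", "raw_value", "qualifier"]
        )


def _build_rule(instrument: str, entry: Mapping[str, Any], where: str) -> CrosswalkRule:
    if not isinstance(entry, Mapping):
        raise CrosswalkSchemaError(f"{where}: rule entry must be a mapping")
    for fld in ("item", "icf_code", "values"):
        if fld not in entry:
            raise CrosswalkSchemaError(f"{where}: missing required field {fld!r}")
    values = entry["values"]
    if not isinstance(values, Mapping) or not values:
        raise CrosswalkSchemaError(f"{where}: 'values' must be a non-empty mapping")

    pairs: list[tuple[ValueMatcher, Qualifier]] = []
    for raw_key, q in values.items():
        if not isinstance(q, int) or isinstance(q, bool):
            raise CrosswalkSchemaError(
                f"{where}: qualifier for raw value {raw_key!r} must be an integer, got {q!r}"
            )
        try:
            qualifier = Qualifier(q)
        except ValueError as exc:
            raise CrosswalkSchemaError(f"{where}: {exc}") from exc
        pairs.append((_parse_value_key(raw_key, where), qualifier))

    intervals = [m for m, _ in pairs if isinstance(m, IntervalMatch)]
    for i, a in enumerate(intervals):
        for b in intervals[i + 1:]:
            if a.overlaps(b):
                raise CrosswalkSchemaError(
                    f"{where}: overlapping intervals {a.as_key()} and {b.as_key()}"
                )

    try:
        target = parse_code(str(entry["icf_code"]))
    except ValueError as exc:
        raise CrosswalkSchemaError(f"{where}: {exc}") from exc

    return CrosswalkRule(
        source=InstrumentItem(instrument, str(entry["item"])),
        target=target,
        value_map=tuple(pairs),
    )


def load_crosswalk(source: Union[str, Path, io.TextIOBase]) -> Crosswalk:
    """Load and validate a crosswalk YAML file.

    Raises :class:`CrosswalkSchemaError` naming the offending instrument,
    rule index and field on any schema violation; duplicate
    (instrument, item) entries are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)

    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise CrosswalkSchemaError("top level of a crosswalk file must be a mapping")

    cw = Crosswalk(version=str(doc.get("version", "unversioned")))
    instruments = doc.get("instruments", [])
    if not isinstance(instruments, Sequence) or isinstance(instruments, str):
        raise CrosswalkSchemaError("'instruments' must be a list")

    for i, block in enumerate(instruments):
        if not isinstance(block, Mapping) or "instrument" not in block:
            raise CrosswalkSchemaError(f"instruments[{i}]: missing 'instrument' name")
        name = str(block["instrument"])
        items = block.get("items", [])
        if not isinstance(items, Sequence) or isinstance(items, str):
            raise CrosswalkSchemaError(f"instruments[{i}] ({name}): 'items' must be a list")
        for j, entry in enumerate(items):
            where = f"instruments[{i}] ({name}) items[{j}]"
            cw.add_rule(_build_rule(name, entry, where))

    if not cw.rules:
        import warnings

        warnings.warn("loaded an empty crosswalk (no rules)", stacklevel=2)
    return cw


def bundled_crosswalk() -> Crosswalk:
    """The crosswalk shipped with the package (Barthel worked example +
    illustrative rules for the other instruments)."""
    from importlib.resources import files

    with (files("icfmon") / "data" / "crosswalk_abi.yaml").open() as fh:
        return load_crosswalk(fh)


def normalize_attribute(item: InstrumentItem | tuple[str, str], cw: Crosswalk) -> ICFCode:
    """Attribute standardization: the ICF code an instrument item measures."""
    if isinstance(item, tuple):
        item = InstrumentItem(*item)
    return cw.rule_for(item.instrument, item.item).target


def normalize_value(
    item: InstrumentItem | tuple[str, str], raw: Any, cw: Crosswalk
) -> Qualifier:
    """Value standardization: the qualifier for one raw score of one item."""
    if isinstance(item, tuple):
        item = InstrumentItem(*item)
    return cw.rule_for(item.instrument, item.item).qualifier_for(raw)
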