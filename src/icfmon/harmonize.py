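"""Turn raw questionnaire observations into standardized ICF snapshots.

Standardization of one person-year proceeds in four steps:

1. *attribute standardization* — each (instrument, item) is mapped to the
   ICF category it measures;
2. *value standardization* — each raw score is mapped to a qualifier via
   the crosswalk's explicit value map;
3. *aggregation* — when several items target the same category (e.g.
   Barthel *feeding* and CIQ *competences at home/feeding* both measure
   eating, d550), their qualifiers are combined into one;
4. *inference* — a category with no direct value but with rated
   subcategories receives the rounded average of the subcategories that
   have a value (e.g. self-care d5 from d530/d540/d550), applied
   bottom-up so third-level inferences feed second-level ones.

Provenance is kept per datum: ``measured`` (one source item),
``aggregated`` (≥2 source items) or ``inferred`` (≥1 child category).
Directly measured or aggregated values are never overwritten by
inference.  Sentinel qualifiers (8/9) are excluded from all arithmetic;
a category whose only evidence is sentinels records 8 (not specified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Optional, Sequence

import pandas as pd

from .icf_model import Hierarchy, ICFCode, Qualifier, parse_code, rounded_mean
from .mapping import Crosswalk, InstrumentItem, UnmappedItemError

__all__ = [
    "Observation",
    "ICFDatum",
    "Snapshot",
    "AggregationPolicy",
    "standardize",
    "aggregate",
    "infer_missing",
    "select_view",
    "read_observations",
    "snapshots_to_frame",
]

PROVENANCES = ("measured", "aggregated", "inferred")


@dataclass(frozen=True)
class Observation:
    """One raw questionnaire answer for one person in one evaluation year."""

    person_id: str
    year: int
    instrument: str
    item: str
    value: Any

    @property
    def source(self) -> InstrumentItem:
        return InstrumentItem(self.instrument, self.item)


@dataclass(frozen=True)
class ICFDatum:
    """A qualifier for one ICF category, with provenance.

    ``sources`` lists contributing item keys (``"Barthel/feeding"``) for
    measured/aggregated data, or child category codes for inferred data.
    """

    code: ICFCode
    qualifier: Qualifier
    provenance: str
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        n = len(self.sources)
        if self.provenance == "measured" and n != 1:
            raise ValueError("measured data carry exactly one source item")
        if self.provenance == "aggregated" and n < 2:
            raise ValueError("aggregated data carry at least two source items")
        if self.provenance == "inferred" and n < 1:
            raise ValueError("inferred data carry at least one child code")


@dataclass
class Snapshot:
    """Standardized ICF state of one person in one year: code -> datum."""

    person_id: str
    year: int
    data: dict[str, ICFDatum] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __contains__(self, code: ICFCode | str) -> bool:
        return str(code) in self.data

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[ICFDatum]:
        return iter(self.data.values())

    def get(self, code: ICFCode | str) -> Optional[ICFDatum]:
        return self.data.get(str(code))

    def qualifier_of(self, code: ICFCode | str) -> Optional[Qualifier]:
        d = self.get(code)
        return d.qualifier if d is not None else None

    def ordered_value(self, code: ICFCode | str) -> Optional[int]:
        """Severity 0–4 for ``code``; None when absent or sentinel."""
        q = self.qualifier_of(code)
        return q.value if q is not None and q.is_ordered else None

    def put(self, datum: ICFDatum) -> None:
        self.data[datum.code.code] = datum

    def codes(self) -> list[str]:
        return list(self.data)


class AggregationPolicy:
    """How qualifiers from several items targeting one code are combined.

    ``mean``  – arithmetic mean of ordered values, halves rounded toward
    worse (the same rule used by hierarchical inference);
    ``worst`` – maximum ordered value (conservative);
    ``best``  – minimum ordered value.
    """

    CHOICES = ("mean", "worst", "best")

    def __init__(self, name: str = "mean"):
        if name not in self.CHOICES:
            raise ValueError(f"aggregation policy must be one of {self.CHOICES}")
        self.name = name

    def combine(self, ordered_values: Sequence[int]) -> int:
        if self.name == "worst":
            return max(ordered_values)
        if self.name == "best":
            return min(ordered_values)
        return rounded_mean(ordered_values)


def aggregate(
    values: Iterable[Qualifier | int], policy: AggregationPolicy | str = "mean"
) -> Qualifier:
    """Combine a non-empty multiset of qualifiers for one code into one.

    Sentinels (8/9) are excluded from arithmetic; if only sentinels are
    present the result is 8 (not specified).
    """
    if isinstance(policy, str):
        policy = AggregationPolicy(policy)
    qs = [v if isinstance(v, Qualifier) else Qualifier(v) for v in values]
    if not qs:
        raise ValueError("aggregate requires at least one qualifier")
    ordered = [q.value for q in qs if q.is_ordered]
    if not ordered:
        return Qualifier(8)
    return Qualifier(policy.combine(ordered))


def _dedupe(observations: Sequence[Observation], warnings: list[str]) -> list[Observation]:
    """Keep the last observation per (instrument, item) in input order."""
    seen: dict[InstrumentItem, int] = {}
    for i, obs in enumerate(observations):
        if obs.source in seen:
            warnings.append(
                f"duplicate observation for {obs.source} "
                f"(person {obs.person_id}, year {obs.year}); keeping the last"
            )
        seen[obs.source] = i
    return [observations[i] for i in sorted(seen.values())]


def standardize(
    observations: Sequence[Observation],
    cw: Crosswalk,
    hierarchy: Optional[Hierarchy] = None,
    policy: AggregationPolicy | str = "mean",
    infer: bool = True,
) -> Snapshot:
    """Standardize all observations of one person-year into a Snapshot.

    Unmapped items and out-of-domain values are collected in
    ``snapshot.warnings`` and skipped, never fatal.  All observations
    must share person id and year.
    """
    if not observations:
        return Snapshot(person_id="", year=0)

    persons = {o.person_id for o in observations}
    years = {o.year for o in observations}
    if len(persons) > 1 or len(years) > 1:
        raise ValueError(
            f"standardize expects one person-year, got persons={sorted(persons)} "
            f"years={sorted(years)}"
        )

    snap = Snapshot(person_id=observations[0].person_id, year=observations[0].year)
    deduped = _dedupe(list(observations), snap.warnings)

    # steps 1+2: normalize each observation to (code, qualifier)
    per_code: dict[str, list[tuple[Qualifier, str]]] = {}
    for obs in deduped:
        try:
            rule = cw.rule_for(obs.instrument, obs.item)
            qualifier = rule.qualifier_for(obs.value)
        except UnmappedItemError:
            snap.warnings.append(f"unmapped item {obs.source}; skipped")
            continue
        except Exception as exc:  # out-of-domain raw value
            snap.warnings.append(f"{obs.source}: {exc}; skipped")
            continue
        per_code.setdefault(rule.target.code, []).append((qualifier, str(obs.source)))

    # step 3a: aggregation per target code (input-order independent)
    for code_text in sorted(per_code):
        entries = sorted(per_code[code_text], key=lambda e: e[1])
        sources = tuple(s for _, s in entries)
        if len(entries) == 1:
            datum = ICFDatum(parse_code(code_text), entries[0][0], "measured", sources)
        else:
            q = aggregate([q for q, _ in entries], policy)
            datum = ICFDatum(parse_code(code_text), q, "aggregated", sources)
        snap.put(datum)

    # step 3b: hierarchical inference
    if infer:
        snap = infer_missing(snap, hierarchy)
    return snap


def infer_missing(snapshot: Snapshot, hierarchy: Optional[Hierarchy] = None) -> Snapshot:
    """Fill absent parent categories from the average of rated children.

    Applied bottom-up (fourth→third→second→chapter) using immediate
    children only at each pass, so lower-level inferences feed higher
    ones.  Existing data are never overwritten; children whose value is a
    sentinel contribute nothing.  Idempotent.
    """
    snap = Snapshot(
        person_id=snapshot.person_id,
        year=snapshot.year,
        data=dict(snapshot.data),
        warnings=list(snapshot.warnings),
    )
    if hierarchy is None:
        hierarchy = Hierarchy.from_codes(snap.codes(), close=True)
    else:
        hierarchy = Hierarchy.from_codes(
            [c.code for c in hierarchy.codes] + snap.codes(), close=True
        )

    # infer parents at each level, deepest children first
    for child_digits in (5, 4, 3):
        parents = sorted(
            {
                c.parent()
                for c in hierarchy
                if len(c.digits) == child_digits and c.parent() is not None
            },
            key=lambda c: c.code,
        )
        for parent in parents:
            if parent.code in snap.data:
                continue
            children = sorted(hierarchy.children_of(parent), key=lambda c: c.code)
            rated = [
                (c, snap.ordered_value(c))
                for c in children
                if snap.ordered_value(c) is not None
            ]
            if not rated:
                continue
            value = rounded_mean([v for _, v in rated])
            snap.put(
                ICFDatum(
                    parent,
                    Qualifier(value),
                    "inferred",
                    tuple(c.code for c, _ in rated),
                )
            )
    return snap


def select_view(
    snapshot: Snapshot,
    profile_codes: Sequence[ICFCode | str],
    keep_missing: bool = False,
) -> Snapshot:
    """Restrict a snapshot to a profile definition (e.g. an ABI core set).

    The output preserves the order of ``profile_codes``.  Codes absent
    from the snapshot are omitted, or recorded as qualifier 8 (not
    specified) when ``keep_missing`` is true.
    """
    out = Snapshot(
        person_id=snapshot.person_id, year=snapshot.year, warnings=list(snapshot.warnings)
    )
    for code in profile_codes:
        datum = snapshot.get(code)
        if datum is not None:
            out.put(datum)
        elif keep_missing:
            c = code if isinstance(code, ICFCode) else parse_code(str(code))
            out.put(ICFDatum(c, Qualifier(8), "inferred", (c.code,)))
    return out


# ---------------------------------------------------------------------------
# file-level I/O (long-format tables)
# ---------------------------------------------------------------------------

OBSERVATION_COLUMNS = ("person_id", "year", "instrument", "item", "value")


def read_observations(path: str | Path) -> list[Observation]:
    """Read a long-format observations CSV (person_id, year, instrument, item, value)."""
    df = pd.read_csv(path, comment="#")
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observations file {path} lacks columns: {sorted(missing)}")
    return [
        Observation(
            person_id=str(r.person_id),
            year=int(r.year),
            instrument=str(r.instrument),
            item=str(r.item),
            value=r.value,
        )
        for r in df.itertuples()
    ]


def standardize_table(
    observations: Iterable[Observation],
    cw: Crosswalk,
    hierarchy: Optional[Hierarchy] = None,
    policy: AggregationPolicy | str = "mean",
) -> tuple[list[Snapshot], list[str]]:
    """Group a mixed observation stream by (person, year) and standardize each.

    Returns the snapshots (sorted by person then year) and the pooled
    warning list.
    """
    groups: dict[tuple[str, int], list[Observation]] = {}
    for obs in observations:
        groups.setdefault((obs.person_id, obs.year), []).append(obs)
    snapshots = [
        standardize(groups[key], cw, hierarchy, policy) for key in sorted(groups)
    ]
    warnings = [w for s in snapshots for w in s.warnings]
    return snapshots, warnings


def snapshots_to_frame(snapshots: Iterable[Snapshot]) -> pd.DataFrame:
    """Long-format export: one row per (person, year, code) datum."""
    rows = []
    for snap in snapshots:
        for datum in snap:
            rows.append(
                {
                    "person_id": snap.person_id,
                    "year": snap.year,
                    "icf_code": datum.code.code,
                    "qualifier": datum.qualifier.value,
                    "provenance": datum.provenance,
                    "sources": ";".join(datum.sources),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["person_id", "year", "icf_code", "qualifier", "provenance", "sources"],
    )
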