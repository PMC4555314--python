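"""Socio-economic burden indicators derived from ICF profiles.

Three policy-dependent quantities summarize the economic effect of a
rehabilitation process:

* **QALYs gained** — the change in a health-state utility (derived from
  the ICF qualifiers) integrated over the elapsed time;
* **DALYs averted** — converted from the QALYs gained (1:1 by default,
  configurable);
* **savings** — monetary value of the DALYs averted minus the cost of
  the rehabilitation process.

No published mapping from ICF qualifiers to utilities exists for this
setting, so the utility policy is explicit and pluggable.  The default
is linear disutility: utility = 1 − (mean ordered qualifier over the
selected code set) / 4, giving 1.0 for no deficiency anywhere and 0.0
for complete deficiency everywhere.  Every output of this module is
policy-dependent and should be labeled as such in downstream reports.
Discounting and age-weighting of DALYs are deliberately off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .harmonize import Snapshot
from .icf_model import ICFCode

__all__ = [
    "EconomicParams",
    "EconomicSummary",
    "UndefinedUtilityError",
    "utility_of",
    "qalys_gained",
    "dalys_averted",
    "savings",
    "summarize",
]


class UndefinedUtilityError(ValueError):
    """Raised when a snapshot has no ordered qualifier to base a utility on."""


@dataclass(frozen=True)
class EconomicParams:
    """Monetary and conversion parameters for the burden indicators.

    cost_per_daly:
        Monetary value assigned to one DALY averted (currency units).
    rehab_cost:
        Cost of the rehabilitation process being evaluated.
    daly_per_qaly:
        Conversion factor from QALYs gained to DALYs averted (default 1:1).
    """

    cost_per_daly: float
    rehab_cost: float
    daly_per_qaly: float = 1.0

    def __post_init__(self) -> None:
        if self.cost_per_daly < 0 or self.rehab_cost < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class EconomicSummary:
    """Policy-dependent burden indicators for one rehabilitation interval."""

    utility_before: float
    utility_after: float
    years: float
    qalys_gained: float
    dalys_averted: float
    savings: float


UtilityPolicy = Callable[[Sequence[int]], float]


def _linear_disutility(ordered_values: Sequence[int]) -> float:
    return 1.0 - (sum(ordered_values) / len(ordered_values)) / 4.0


def utility_of(
    snapshot: Snapshot,
    codes: Optional[Sequence[ICFCode | str]] = None,
    policy: UtilityPolicy = _linear_disutility,
) -> float:
    """Health-state utility in [0, 1] from a snapshot's ordered qualifiers.

    ``codes`` restricts the evaluation to a code set (e.g. an ABI core
    set); by default every code in the snapshot contributes.  Sentinel
    qualifiers carry no information and are skipped.
    """
    if codes is None:
        values = [
            d.qualifier.value for d in snapshot if d.qualifier.is_ordered
        ]
    else:
        vals = [snapshot.ordered_value(c) for c in codes]
        values = [v for v in vals if v is not None]
    if not values:
        raise UndefinedUtilityError(
            f"snapshot {snapshot.person_id}@{snapshot.year} has no ordered qualifier"
        )
    u = policy(values)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"utility policy returned {u!r}, outside [0, 1]")
    return u


def qalys_gained(
    before: Snapshot,
    after: Snapshot,
    years: float,
    codes: Optional[Sequence[ICFCode | str]] = None,
    policy: UtilityPolicy = _linear_disutility,
) -> float:
    """(utility_after − utility_before) × years; signed, antisymmetric."""
    if years <= 0:
        raise ValueError("years must be positive")
    return (utility_of(after, codes, policy) - utility_of(before, codes, policy)) * years


def dalys_averted(qalys: float, factor: float = 1.0) -> float:
    """Convert QALYs gained to DALYs averted (default 1:1)."""
    return qalys * factor


def savings(dalys: float, params: EconomicParams) -> float:
    """Monetary value of DALYs averted minus the rehabilitation cost."""
    return dalys * params.cost_per_daly - params.rehab_cost


def summarize(
    before: Snapshot,
    after: Snapshot,
    years: float,
    params: EconomicParams,
    codes: Optional[Sequence[ICFCode | str]] = None,
    policy: UtilityPolicy = _linear_disutility,
) -> EconomicSummary:
    """Full burden summary for one person's rehabilitation interval."""
    u0 = utility_of(before, codes, policy)
    u1 = utility_of(after, codes, policy)
    q = (u1 - u0) * years
    d = dalys_averted(q, params.daly_per_qaly)
    return EconomicSummary(
        utility_before=u0,
        utility_after=u1,
        years=years,
        qalys_gained=q,
        dalys_averted=d,
        savings=savings(d, params),
    )
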