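"""Monitoring representations: individual evolution and population distributions.

The monitoring views follow a fixed color code for the severity
qualifier: blue/0 no problem, green/1 mild, yellow/2 moderate, orange/3
severe, red/4 complete; sentinel values render in neutral grey.  A
clinician scanning an evolution matrix can then spot the most impaired
categories (red) at a glance.

All representations are produced as data (pandas objects / dataclasses);
plotting is a thin optional export and correctness is always asserted on
the data, never on pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .harmonize import Snapshot
from .icf_model import ICFCode, Qualifier

__all__ = [
    "PersonProfile",
    "QualifierDistribution",
    "QUALIFIER_COLORS",
    "MISSING",
    "color_of",
    "individual_evolution",
    "evolution_colors",
    "population_snapshot",
    "population_evolution",
    "filter_cohort",
    "plot_evolution",
    "plot_distributions",
]

QUALIFIER_COLORS = {0: "blue", 1: "green", 2: "yellow", 3: "orange", 4: "red"}
SENTINEL_COLOR = "grey"
MISSING = "missing"


def color_of(q: Qualifier | int) -> str:
    """Fixed severity→color bijection on 0–4; sentinels map to grey."""
    value = q.value if isinstance(q, Qualifier) else int(q)
    if value in QUALIFIER_COLORS:
        return QUALIFIER_COLORS[value]
    Qualifier(value)  # raises on anything outside the scale
    return SENTINEL_COLOR


@dataclass
class PersonProfile:
    """Demographics plus the year-indexed ICF snapshots of one person."""

    person_id: str
    age: float
    gender: str
    years_from_diagnosis: float
    disease: str
    origin: str
    snapshots: dict[int, Snapshot] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValueError(f"profile {self.person_id} has no snapshots")
        self.snapshots = dict(sorted(self.snapshots.items()))

    @property
    def years(self) -> list[int]:
        return list(self.snapshots)

    @property
    def series_length(self) -> int:
        """Number of distinct measurement years."""
        return len(self.snapshots)

    def ordered_value(self, code: ICFCode | str, year: int) -> Optional[int]:
        snap = self.snapshots.get(year)
        return snap.ordered_value(code) if snap is not None else None


@dataclass
class QualifierDistribution:
    """Percentage of a population at each qualifier level of one code/year.

    ``percentages`` has integer keys 0–4 plus the ``"missing"`` bin
    (members evaluated that year without an ordered value for the code);
    it sums to 100 within floating tolerance.  ``n`` is the number of
    cohort members contributing to the denominator.
    """

    code: str
    year: int
    n: int
    percentages: dict[int | str, float]

    def as_series(self) -> pd.Series:
        keys = [0, 1, 2, 3, 4] + ([MISSING] if MISSING in self.percentages else [])
        return pd.Series(
            {k: self.percentages.get(k, 0.0) for k in keys}, name=f"{self.code}@{self.year}"
        )


def individual_evolution(
    profile: PersonProfile,
    codes: Sequence[ICFCode | str],
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Evolution matrix of one person: rows = ICF codes, columns = years.

    Cells hold the qualifier value (including sentinels 8/9); absent data
    are NaN.  Row order follows ``codes``.
    """
    if years is None:
        years = profile.years
    code_texts = [str(c) for c in codes]
    mat = pd.DataFrame(np.nan, index=code_texts, columns=list(years), dtype=float)
    for year in years:
        snap = profile.snapshots.get(year)
        if snap is None:
            continue
        for code in code_texts:
            q = snap.qualifier_of(code)
            if q is not None:
                mat.loc[code, year] = q.value
    return mat


def evolution_colors(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map an evolution matrix to color names ('white' for missing cells)."""
    return matrix.map(lambda v: "white" if pd.isna(v) else color_of(int(v)))


def population_snapshot(
    cohort: Sequence[PersonProfile],
    code: ICFCode | str,
    year: int,
    complete_case: bool = False,
) -> QualifierDistribution:
    """Distribution of one code's qualifier across a population in one year.

    Membership: profiles evaluated in ``year`` (i.e. having a snapshot
    for it).  Members without an ordered value for the code count in the
    explicit ``missing`` bin; ``complete_case=True`` instead restricts
    the denominator to members with an ordered value.  If nobody
    qualifies the distribution is a single 100% missing bin.
    """
    if not cohort:
        raise ValueError("population_snapshot requires a non-empty cohort")
    code_text = str(code)
    members = [p for p in cohort if year in p.snapshots]
    values = [p.ordered_value(code_text, year) for p in members]
    if complete_case:
        values = [v for v in values if v is not None]
    if not values:
        return QualifierDistribution(code_text, year, 0, {MISSING: 100.0})

    n = len(values)
    pct: dict[int | str, float] = {}
    for v in values:
        key: int | str = MISSING if v is None else v
        pct[key] = pct.get(key, 0.0) + 100.0 / n
    return QualifierDistribution(code_text, year, n, pct)


def population_evolution(
    cohort: Sequence[PersonProfile],
    code: ICFCode | str,
    years: Sequence[int],
    complete_case: bool = False,
) -> list[QualifierDistribution]:
    """One qualifier distribution per year, same membership rule throughout."""
    return [population_snapshot(cohort, code, y, complete_case) for y in years]


def filter_cohort(
    cohort: Iterable[PersonProfile],
    disease: Optional[str] = None,
    gender: Optional[str] = None,
    age_range: Optional[tuple[float, float]] = None,
    origin: Optional[str] = None,
) -> list[PersonProfile]:
    """Profiles satisfying ALL given criteria; no criterion = identity.

    ``age_range`` is inclusive on both ends.
    """
    if age_range is not None:
        lo, hi = age_range
        if lo > hi:
            raise ValueError(f"malformed age range ({lo}, {hi})")

    out = []
    for p in cohort:
        if disease is not None and p.disease != disease:
            continue
        if gender is not None and p.gender != gender:
            continue
        if origin is not None and p.origin != origin:
            continue
        if age_range is not None and not (age_range[0] <= p.age <= age_range[1]):
            continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# optional plot exports (data is authoritative; these are presentation only)
# ---------------------------------------------------------------------------

_RGB = {
    "blue": "#4575b4",
    "green": "#66bd63",
    "yellow": "#fee08b",
    "orange": "#f46d43",
    "red": "#d73027",
    "grey": "#bdbdbd",
    "white": "#ffffff",
}


def plot_evolution(matrix: pd.DataFrame, path: str, labels: Optional[dict] = None) -> None:
    """Render an evolution matrix as a colored grid and save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    colors = evolution_colors(matrix)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * len(matrix.columns), 0.8 + 0.4 * max(len(matrix), 1))
    )
    for i, code in enumerate(matrix.index):
        for j, year in enumerate(matrix.columns):
            ax.add_patch(
                plt.Rectangle(
                    (j, len(matrix) - 1 - i), 1, 1,
                    facecolor=_RGB[colors.loc[code, year]],
                    edgecolor="black", linewidth=0.5,
                )
            )
    ax.set_xlim(0, max(len(matrix.columns), 1))
    ax.set_ylim(0, max(len(matrix), 1))
    ax.set_xticks([j + 0.5 for j in range(len(matrix.columns))])
    ax.set_xticklabels(matrix.columns)
    ax.set_yticks([len(matrix) - 1 - i + 0.5 for i in range(len(matrix))])
    names = [labels.get(c, c) if labels else c for c in matrix.index]
    ax.set_yticklabels(names)
    ax.set_xlabel("evaluation year")
    handles = [
        Patch(facecolor=_RGB[name], edgecolor="black", label=f"{v} ({name})")
        for v, name in QUALIFIER_COLORS.items()
    ]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.02, 0.5), fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distributions(
    dists: Sequence[QualifierDistribution], path: str, title: str = ""
) -> None:
    """Render stacked-bar qualifier distributions (one bar per year)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 0.8 * len(dists), 3.2))
    keys: list[int | str] = [0, 1, 2, 3, 4, MISSING]
    colors = [_RGB[QUALIFIER_COLORS.get(k, "grey")] if k != MISSING else _RGB["grey"] for k in keys]
    bottoms = np.zeros(len(dists))
    xs = np.arange(len(dists))
    for key, color in zip(keys, colors):
        heights = np.array([d.percentages.get(key, 0.0) for d in dists])
        ax.bar(xs, heights, bottom=bottoms, color=color, edgecolor="black",
               linewidth=0.4, label=str(key))
        bottoms += heights
    ax.set_xticks(xs)
    ax.set_xticklabels([str(d.year) for d in dists])
    ax.set_ylabel("% of population")
    ax.set_title(title)
    ax.legend(fontsize=7, title="qualifier")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
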