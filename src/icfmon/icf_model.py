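"""Data model for ICF codes, qualifiers and the code hierarchy.

The WHO International Classification of Functioning, Disability and Health
(ICF) organizes functioning into four components — body functions (``b``),
body structures (``s``), activities and participation (``d``) and
environmental factors (``e``).  Codes are a component letter followed by
digits: one digit for a chapter (``d5`` is written with the chapter number
only in informal text, but formally chapters are letter + one digit, e.g.
``d5``), three digits for a second-level category (``d550``), four for a
third-level (``b1641``) and five for a fourth-level category.  Two-digit
forms do not exist.

Each category is rated with a generic qualifier: an ordinal severity from
0 (no problem) to 4 (complete problem), plus the sentinels 8 (not
specified) and 9 (not applicable).  Sentinels are never ordered against
the 0–4 scale and are excluded from every arithmetic operation in this
package.

The parent/child structure of ICF codes is fully determined by the code
text (shared prefix plus digit count), so the hierarchy here is derived
purely from the codes themselves; no external taxonomy file is needed for
any rollup this package performs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "ICFCode",
    "Qualifier",
    "Hierarchy",
    "InvalidCodeError",
    "SentinelComparisonError",
    "parse_code",
    "parent_of",
    "children_of",
    "ORDERED_QUALIFIER_VALUES",
    "SENTINEL_QUALIFIER_VALUES",
]

COMPONENTS = ("b", "s", "d", "e")

# digit count -> level name; 2-digit forms are invalid by construction
_LEVEL_BY_DIGITS = {1: "chapter", 3: "second", 4: "third", 5: "fourth"}
# digit count of the unique parent for each non-chapter level
_PARENT_DIGITS = {3: 1, 4: 3, 5: 4}

_CODE_RE = re.compile(r"^([bsde])(\d{1})(\d{2}(\d(\d)?)?)?$")

ORDERED_QUALIFIER_VALUES = (0, 1, 2, 3, 4)
SENTINEL_QUALIFIER_VALUES = (8, 9)

QUALIFIER_LABELS = {
    0: "no",
    1: "mild",
    2: "moderate",
    3: "severe",
    4: "complete",
    8: "not specified",
    9: "not applicable",
}


class InvalidCodeError(ValueError):
    """Raised when a text string is not a well-formed ICF code."""


class SentinelComparisonError(TypeError):
    """Raised when a sentinel qualifier (8/9) is compared on the severity order."""


@dataclass(frozen=True)
class ICFCode:
    """A validated ICF category code.

    Parameters
    ----------
    code:
        The textual code, e.g. ``"d550"``.
    """

    code: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise InvalidCodeError(
                f"{self.code!r} is not a valid ICF code: expected one of "
                f"b/s/d/e followed by 1, 3, 4 or 5 digits"
            )

    @property
    def component(self) -> str:
        """Component letter: b, s, d or e."""
        return self.code[0]

    @property
    def digits(self) -> str:
        return self.code[1:]

    @property
    def level(self) -> str:
        """Hierarchical level: chapter, second, third or fourth."""
        return _LEVEL_BY_DIGITS[len(self.digits)]

    @property
    def is_chapter(self) -> bool:
        return len(self.digits) == 1

    def parent(self) -> Optional["ICFCode"]:
        """The unique parent category, or ``None`` for chapter codes."""
        n = len(self.digits)
        if n == 1:
            return None
        return ICFCode(self.code[0] + self.digits[: _PARENT_DIGITS[n]])

    def ancestors(self) -> Iterator["ICFCode"]:
        """Parents up to (and including) the chapter, nearest first."""
        node = self.parent()
        while node is not None:
            yield node
            node = node.parent()

    def __str__(self) -> str:
        return self.code


def parse_code(text: str) -> ICFCode:
    """Parse and validate an ICF code string.

    >>> parse_code("d550").level
    'second'
    """
    if not text:
        raise InvalidCodeError("empty ICF code")
    return ICFCode(str(text).strip())


def parent_of(code: ICFCode | str) -> Optional[ICFCode]:
    """Parent category per the digit-count rule; ``None`` for chapters."""
    if isinstance(code, str):
        code = parse_code(code)
    return code.parent()


@dataclass(frozen=True, eq=False)
class Qualifier:
    """The ICF generic qualifier: severity 0–4 plus sentinels 8 and 9.

    Values 0–4 are totally ordered (higher = worse functioning).  The
    sentinels 8 (not specified) and 9 (not applicable) carry no position
    on that scale: any order comparison involving them raises
    :class:`SentinelComparisonError` rather than producing a silent
    ordering.
    """

    value: int

    def __post_init__(self) -> None:
        if self.value not in QUALIFIER_LABELS:
            raise ValueError(
                f"qualifier must be one of 0-4, 8, 9; got {self.value!r}"
            )

    @property
    def label(self) -> str:
        return QUALIFIER_LABELS[self.value]

    @property
    def is_ordered(self) -> bool:
        """True for severity values 0–4, False for the sentinels."""
        return self.value in ORDERED_QUALIFIER_VALUES

    @property
    def is_sentinel(self) -> bool:
        return not self.is_ordered

    # -- equality is by value (ints allowed for convenience) ------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Qualifier):
            return self.value == other.value
        if isinstance(other, int):
            return self.value == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.value)

    def _ordered_value(self, other: object) -> int:
        if isinstance(other, Qualifier):
            ov = other.value
        elif isinstance(other, int):
            ov = other
        else:
            raise TypeError(f"cannot order Qualifier against {type(other).__name__}")
        if not self.is_ordered or ov not in ORDERED_QUALIFIER_VALUES:
            raise SentinelComparisonError(
                "sentinel qualifiers (8, 9) have no position on the severity scale"
            )
        return ov

    def __lt__(self, other: object) -> bool:
        return self.value < self._ordered_value(other)

    def __le__(self, other: object) -> bool:
        return self.value <= self._ordered_value(other)

    def __gt__(self, other: object) -> bool:
        return self.value > self._ordered_value(other)

    def __ge__(self, other: object) -> bool:
        return self.value >= self._ordered_value(other)

    def __str__(self) -> str:
        return f"{self.value} ({self.label})"


@dataclass
class Hierarchy:
    """A set of known ICF codes with text-derived parent/child adjacency.

    Codes are placed by the prefix + digit-count rule alone, so
    well-formed codes that are absent from the published taxonomy (the
    "other specified" ``-8`` codes, for instance) are accepted and
    attached under their textual parent.
    """

    codes: set[ICFCode] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_codes(cls, codes: Iterable[ICFCode | str], close: bool = False) -> "Hierarchy":
        """Build a hierarchy from codes; ``close=True`` also adds all ancestors."""
        h = cls()
        for c in codes:
            h.add(c, close=close)
        return h

    def add(self, code: ICFCode | str, close: bool = False) -> ICFCode:
        if isinstance(code, str):
            code = parse_code(code)
        self.codes.add(code)
        if close:
            self.codes.update(code.ancestors())
        return code

    def __contains__(self, code: ICFCode | str) -> bool:
        if isinstance(code, str):
            code = parse_code(code)
        return code in self.codes

    def __iter__(self) -> Iterator[ICFCode]:
        return iter(sorted(self.codes, key=lambda c: c.code))

    def __len__(self) -> int:
        return len(self.codes)

    def children_of(self, code: ICFCode | str) -> set[ICFCode]:
        """Immediate children of ``code`` among the known codes."""
        if isinstance(code, str):
            code = parse_code(code)
        if code not in self.codes:
            raise KeyError(f"code {code} is not in the hierarchy")
        return {c for c in self.codes if c.parent() == code}

    def label_of(self, code: ICFCode | str) -> str:
        """Human-readable label; falls back to the code text."""
        text = code.code if isinstance(code, ICFCode) else str(code)
        return self.labels.get(text, text)

    def load_labels(self, path: str | Path) -> None:
        """Attach labels from a tab-separated ``code<TAB>label`` file."""
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code_text, _, label = line.partition("\t")
            parse_code(code_text)  # validate
            self.labels[code_text] = label.strip() or code_text


def children_of(code: ICFCode | str, hierarchy: Hierarchy) -> set[ICFCode]:
    """Immediate children of ``code`` within ``hierarchy`` (possibly empty)."""
    return hierarchy.children_of(code)


def rounded_mean(values: Iterable[int]) -> int:
    """Integer mean with halves rounded toward worse (up).

    Exact integer arithmetic: floor((2*sum + n) / (2*n)) is the
    round-half-up of sum/n for non-negative inputs.
    """
    vals = list(values)
    if not vals:
        raise ValueError("rounded_mean of empty collection")
    total, n = sum(vals), len(vals)
    return (2 * total + n) // (2 * n)
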