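"""Synthetic ABI rehabilitation cohorts with realistic longitudinal structure.

No clinical dataset is distributable, so this module generates cohorts
whose marginal structure matches the published summary of the real one:
ages 17–90 (mean ≈ 47, sd ≈ 15.5), roughly 1.8:1 male:female, series of
3–7 annual evaluations with mean length ≈ 4.2 (sd ≈ 1.0) ending in the
final study year, heavy year-dependent missingness in the target
category (e.g. 99% in 2007 falling to 0% in 2013 for emotional
functions), and a 5-class distribution of the target qualifier.

Observations are generated at the *instrument* level (Barthel, CIQ,
PCRS, DRS items) and pushed through the bundled crosswalk, so the
standardization pipeline is exercised on realistic raw inputs rather
than on pre-made ICF data.  Target-category missingness is
missing-completely-at-random against the per-year schedule (an
informative-missingness mode exists for robustness experiments).

:func:`plant_signal` rewrites the label-year target according to an
explicit stochastic transition from the previous state, which makes the
prognosis module testable against a known, closed-form Bayes rate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .harmonize import ICFDatum, Observation, Snapshot, standardize
from .icf_model import Qualifier, parse_code
from .mapping import Crosswalk, bundled_crosswalk
from .monitor import PersonProfile

__all__ = [
    "SignalSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate",
    "plant_signal",
    "emotional_preset",
    "executive_preset",
    "filter_demo_preset",
]

STUDY_YEARS = (2007, 2008, 2009, 2010, 2011, 2012, 2013)

# per-year probability that the target category is unmeasured, given an
# evaluation took place that year (final-year missingness is 0: the last
# measurement is what the prognosis validates against)
EMOTIONAL_MISSINGNESS = {
    2007: 0.99, 2008: 0.80, 2009: 0.54, 2010: 0.42,
    2011: 0.39, 2012: 0.52, 2013: 0.0,
}
EXECUTIVE_MISSINGNESS = {
    2007: 0.77, 2008: 0.69, 2009: 0.69, 2010: 0.45,
    2011: 0.37, 2012: 0.47, 2013: 0.0,
}

# 5-class distribution of the predicted qualifier
EMOTIONAL_LABEL_PROBS = {0: 120 / 419, 1: 130 / 419, 2: 112 / 419, 3: 39 / 419, 4: 18 / 419}
EXECUTIVE_LABEL_PROBS = {0: 100 / 477, 1: 69 / 477, 2: 103 / 477, 3: 91 / 477, 4: 114 / 477}

# discrete series-length law on {3..7} with mean 4.22 and sd ≈ 1.06
SERIES_LENGTH_PROBS = {3: 0.28, 4: 0.38, 5: 0.22, 6: 0.08, 7: 0.04}

EMOTIONAL_DISEASE_COUNTS = {
    "not assigned": 2, "Guillain-Barre": 18, "polio": 14, "plexus": 5,
    "mielomeningocele": 20, "traumatic brain injury": 213, "multiple sclerosis": 43,
    "other progressive diseases": 22, "children cerebral palsy": 103,
    "hemorrhagic stroke": 122, "thrombotic stroke": 26, "embolic stroke": 12,
    "undetermined ischemic brain stroke": 24, "other ischemic brain stroke": 9,
    "other degenerative diseases not traumatic": 84, "muscular dystrophy": 1,
    "poliradiculoneuritis": 7, "other": 4,
}
EXECUTIVE_DISEASE_COUNTS = {
    "not assigned": 2, "Guillain-Barre": 14, "polio": 7, "plexus": 3,
    "mielomeningocele": 14, "traumatic brain injury": 133, "multiple sclerosis": 23,
    "other progressive diseases": 13, "children cerebral palsy": 73,
    "hemorrhagic stroke": 87, "thrombotic stroke": 22, "embolic stroke": 10,
    "undetermined brain stroke": 14, "other ischemic brain stroke": 5,
    "other degenerative diseases not traumatic": 51, "muscular dystrophy": 1,
    "poliradiculoneuritis": 3, "other": 2,
}

EMOTIONAL_ORIGIN_COUNTS = {"traumatic": 131, "medic": 208, "undefined": 80}
EXECUTIVE_ORIGIN_COUNTS = {"traumatic": 134, "medic": 231, "undefined": 112}

# items emitted alongside the target, with per-year presence probability;
# their qualifiers track the target severity with ±1 jitter so the
# feature block carries signal without being a copy of the label
DEFAULT_CONTEXT_ITEMS = (
    ("Barthel", "feeding", 0.75),
    ("Barthel", "dressing", 0.70),
    ("CIQ", "home_feeding", 0.50),
    ("PCRS", "organization_planning", 0.60),
    ("DRS", "total", 0.50),
    ("CIQ", "social_leisure", 0.40),
)


def _normalized(freqs: dict) -> dict:
    total = float(sum(freqs.values()))
    return {k: v / total for k, v in freqs.items()}


@dataclass(frozen=True)
class SignalSpec:
    """Stochastic transition from the previous state to the label.

    With probability ``noise`` the label is uniform over 0–4; otherwise
    it stays at the previous state with probability ``stay``, moves one
    step worse with ``up`` or one step better with ``down`` (moves are
    clipped to [0, 4], so probability mass at the boundary folds onto
    staying).
    """

    noise: float = 0.0
    stay: float = 1.0
    up: float = 0.0
    down: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if min(self.stay, self.up, self.down) < 0:
            raise ValueError("transition probabilities must be non-negative")
        if abs(self.stay + self.up + self.down - 1.0) > 1e-9:
            raise ValueError("stay + up + down must sum to 1")

    def transition_probs(self, prev: int) -> np.ndarray:
        """P(label = 0..4 | previous state = prev)."""
        p = np.zeros(5)
        p[prev] += self.stay
        p[min(prev + 1, 4)] += self.up
        p[max(prev - 1, 0)] += self.down
        return (1.0 - self.noise) * p + self.noise / 5.0

    def bayes_accuracy(self, prev_probs: Sequence[float]) -> float:
        """Accuracy of the Bayes-optimal predictor given the previous-state
        distribution (closed form)."""
        prev_probs = np.asarray(prev_probs, dtype=float)
        return float(
            sum(
                prev_probs[s] * self.transition_probs(s).max()
                for s in range(5)
            )
        )


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    n: int
    seed: int = 0
    years: tuple[int, ...] = STUDY_YEARS
    age_range: tuple[float, float] = (17.0, 90.0)
    age_mean: float = 46.7
    age_sd: float = 15.5
    male_fraction: float = 274 / 419
    disease_probs: dict = field(
        default_factory=lambda: _normalized(EMOTIONAL_DISEASE_COUNTS)
    )
    origin_probs: dict = field(
        default_factory=lambda: _normalized(EMOTIONAL_ORIGIN_COUNTS)
    )
    years_from_diagnosis_range: tuple[float, float] = (4.0, 67.0)
    years_from_diagnosis_mean: float = 17.9
    years_from_diagnosis_sd: float = 15.7
    series_length_probs: dict = field(default_factory=lambda: dict(SERIES_LENGTH_PROBS))
    missingness: dict = field(default_factory=lambda: dict(EMOTIONAL_MISSINGNESS))
    label_probs: dict = field(default_factory=lambda: dict(EMOTIONAL_LABEL_PROBS))
    label_missing_rate: float = 0.0
    target_instrument: str = "PCRS"
    target_item: str = "emotional_control"
    context_items: tuple = DEFAULT_CONTEXT_ITEMS
    # within-person year-to-year drift of the latent target severity
    drift_stay: float = 0.6
    # informative mode: missingness probability is boosted for severe states
    informative_missingness: bool = False

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, probs in (
            ("series_length_probs", self.series_length_probs),
            ("label_probs", self.label_probs),
            ("disease_probs", self.disease_probs),
            ("origin_probs", self.origin_probs),
        ):
            vals = list(probs.values())
            if not vals or min(vals) < 0 or abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        for length in self.series_length_probs:
            if not 1 <= int(length) <= len(self.years):
                raise ValueError(
                    f"series length {length} outside the feasible range "
                    f"1..{len(self.years)}"
                )
        if set(self.label_probs) - {0, 1, 2, 3, 4}:
            raise ValueError("label_probs keys must be qualifiers 0-4")
        for year in self.years:
            rate = self.missingness.get(year)
            if rate is None or not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness must give a rate in [0,1] for year {year}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("malformed age range")
        if not 0.0 <= self.label_missing_rate <= 1.0:
            raise ValueError("label_missing_rate must be in [0, 1]")

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for output audit trails."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def emotional_preset(n: int = 419, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort emulating the emotional-functions prognosis population."""
    return CohortConfig(n=n, seed=seed, **overrides)


def executive_preset(n: int = 477, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort emulating the executive-functions prognosis population."""
    defaults = dict(
        male_fraction=313 / 477,
        disease_probs=_normalized(EXECUTIVE_DISEASE_COUNTS),
        origin_probs=_normalized(EXECUTIVE_ORIGIN_COUNTS),
        years_from_diagnosis_range=(2.0, 72.0),
        years_from_diagnosis_mean=19.0,
        years_from_diagnosis_sd=17.0,
        missingness=dict(EXECUTIVE_MISSINGNESS),
        label_probs=dict(EXECUTIVE_LABEL_PROBS),
        target_instrument="PCRSi",
        target_item="executive_functions",
    )
    defaults.update(overrides)
    return CohortConfig(n=n, seed=seed, **defaults)


def filter_demo_preset(n: int = 200, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort exercising the eligibility filter: series lengths 2–5 and a
    30% chance of an empty label-year target value."""
    defaults = dict(
        series_length_probs={2: 0.25, 3: 0.25, 4: 0.25, 5: 0.25},
        missingness={y: (0.0 if y == STUDY_YEARS[-1] else 0.30) for y in STUDY_YEARS},
        label_missing_rate=0.30,
    )
    defaults.update(overrides)
    return CohortConfig(n=n, seed=seed, **defaults)


@dataclass
class SyntheticCohort:
    """Generated observations, demographics and standardized profiles."""

    observations: pd.DataFrame
    demographics: pd.DataFrame
    profiles: list[PersonProfile]
    config: CohortConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def target_code(self) -> str:
        cw = bundled_crosswalk()
        return cw.rule_for(self.config.target_instrument, self.config.target_item).target.code

    @property
    def label_year(self) -> int:
        return self.config.years[-1]


def _raw_for(rule, q: int):
    """Raw value whose mapped qualifier is nearest to ``q`` (ties → worse).

    Coarse items (e.g. three-point Barthel scores) cannot express every
    severity level; the generator snaps to the closest representable one.
    """
    available = sorted({qq.value for _, qq in rule.value_map if qq.is_ordered})
    if not available:
        raise ValueError(f"{rule.source} maps no ordered qualifier")
    best = min(available, key=lambda a: (abs(a - q), -a))
    return rule.raw_for_qualifier(best)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _missingness_assignment(
    config: CohortConfig,
    rng: np.random.Generator,
    person_years: dict[str, tuple[int, ...]],
    severities: dict[tuple[str, int], int],
) -> set[tuple[str, int]]:
    """Choose which (person, year) target values are missing.

    Per year, exactly ``round(rate * n_measured)`` of the people measured
    that year are marked missing (quota sampling).  Selection is uniform
    at random — missing-completely-at-random by exchangeability — which
    pins the empirical per-year missingness to the schedule up to
    rounding regardless of cohort size.  In informative mode selection
    probability instead grows with severity (missing-not-at-random).
    """
    label_year = config.years[-1]
    missing: set[tuple[str, int]] = set()
    for year in config.years:
        members = [pid for pid, yrs in person_years.items() if year in yrs]
        if not members:
            continue
        rate = config.label_missing_rate if year == label_year else config.missingness[year]
        k = int(round(rate * len(members)))
        if k == 0:
            continue
        if config.informative_missingness and year != label_year:
            sev = np.array([severities[(pid, year)] for pid in members], dtype=float)
            w = 1.0 + sev  # worse states are likelier to go unreported
            idx = rng.choice(len(members), size=k, replace=False, p=w / w.sum())
        else:
            idx = rng.choice(len(members), size=k, replace=False)
        missing.update((members[i], year) for i in idx)
    return missing


def generate(config: CohortConfig, crosswalk: Optional[Crosswalk] = None) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from a validated config.

    Returns raw instrument-level observations, a demographics table and
    the standardized :class:`~icfmon.monitor.PersonProfile` objects
    produced by pushing the observations through the crosswalk.
    """
    config.validate()
    if crosswalk is None:
        crosswalk = bundled_crosswalk()
    rng = np.random.default_rng(config.seed)
    target_rule = crosswalk.rule_for(config.target_instrument, config.target_item)
    context_rules = [
        (crosswalk.rule_for(inst, item), inst, item, p_present)
        for inst, item, p_present in config.context_items
    ]

    # pass 1: demographics, series extent and latent severity trajectories
    demo_rows: list[dict] = []
    person_years: dict[str, tuple[int, ...]] = {}
    severities: dict[tuple[str, int], int] = {}
    for i in range(config.n):
        pid = f"P{i + 1:04d}"
        age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range)
        gender = "male" if rng.random() < config.male_fraction else "female"
        disease = _draw(rng, config.disease_probs)
        origin = _draw(rng, config.origin_probs)
        yfd = _truncated_normal(
            rng, config.years_from_diagnosis_mean, config.years_from_diagnosis_sd,
            *config.years_from_diagnosis_range,
        )
        length = int(_draw(rng, config.series_length_probs))
        years = config.years[-length:]
        person_years[pid] = years

        # latent target severity: sticky ±1 random walk started from the
        # configured 5-class label distribution
        q = int(_draw(rng, config.label_probs))
        for year in years:
            severities[(pid, year)] = q
            r = rng.random()
            if r >= config.drift_stay:
                q = int(np.clip(q + (1 if r < (1 + config.drift_stay) / 2 else -1), 0, 4))

        demo_rows.append(
            {
                "person_id": pid, "age": round(age, 1), "gender": gender,
                "years_from_diagnosis": round(yfd, 1), "disease": disease,
                "origin": origin,
            }
        )

    # pass 2: per-year missingness quotas for the target category
    missing = _missingness_assignment(config, rng, person_years, severities)

    # pass 3: emit instrument-level observations and standardize
    obs_rows: list[Observation] = []
    profiles: list[PersonProfile] = []
    pooled_warnings: list[str] = []
    for row in demo_rows:
        pid = row["person_id"]
        person_obs: dict[int, list[Observation]] = {}
        for year in person_years[pid]:
            q_year = severities[(pid, year)]
            person_obs[year] = []
            if (pid, year) not in missing:
                person_obs[year].append(
                    Observation(pid, year, config.target_instrument, config.target_item,
                                target_rule.raw_for_qualifier(q_year))
                )
            for rule, inst, item, p_present in context_rules:
                if rng.random() < p_present:
                    ctx_q = int(np.clip(q_year + rng.integers(-1, 2), 0, 4))
                    person_obs[year].append(
                        Observation(pid, year, inst, item, _raw_for(rule, ctx_q))
                    )
            if not person_obs[year]:
                # an evaluation took place: guarantee at least one answer
                rule, inst, item, _ = context_rules[0]
                ctx_q = int(np.clip(q_year + rng.integers(-1, 2), 0, 4))
                person_obs[year].append(
                    Observation(pid, year, inst, item, _raw_for(rule, ctx_q))
                )

        snapshots = {}
        for year in person_years[pid]:
            snap = standardize(person_obs[year], crosswalk)
            pooled_warnings.extend(snap.warnings)
            snapshots[year] = snap
            obs_rows.extend(person_obs[year])

        profiles.append(
            PersonProfile(
                person_id=pid, age=row["age"], gender=row["gender"],
                years_from_diagnosis=row["years_from_diagnosis"],
                disease=row["disease"], origin=row["origin"], snapshots=snapshots,
            )
        )

    observations = pd.DataFrame(
        [
            {
                "person_id": o.person_id, "year": o.year, "instrument": o.instrument,
                "item": o.item, "value": o.value,
            }
            for o in obs_rows
        ],
        columns=["person_id", "year", "instrument", "item", "value"],
    )
    demographics = pd.DataFrame(
        demo_rows,
        columns=["person_id", "age", "gender", "years_from_diagnosis", "disease", "origin"],
    )
    return SyntheticCohort(
        observations=observations, demographics=demographics, profiles=profiles,
        config=config, warnings=pooled_warnings,
    )


def plant_signal(
    profiles: Sequence[PersonProfile],
    spec: SignalSpec,
    seed: int = 0,
    target_code: str = "b152",
) -> list[PersonProfile]:
    """Rewrite each profile's label-year target per the transition model.

    The label year is each person's last measurement year.  If a profile
    has no ordered pre-label value of the target, one is first planted in
    the most recent pre-label year (uniform over 0–4) so the transition
    model applies to every profile.  Only the target category is
    rewritten; derived ancestor values are left as generated.
    """
    rng = np.random.default_rng(seed)
    code = parse_code(target_code)
    out: list[PersonProfile] = []
    for p in profiles:
        snapshots = {
            y: Snapshot(person_id=s.person_id, year=s.year, data=dict(s.data),
                        warnings=list(s.warnings))
            for y, s in p.snapshots.items()
        }
        years = sorted(snapshots)
        label_year = years[-1]

        prev = None
        prev_year = None
        for y in years[:-1]:
            v = snapshots[y].ordered_value(code)
            if v is not None:
                prev, prev_year = v, y
        if prev is None:
            prev = int(rng.integers(0, 5))
            prev_year = years[-2] if len(years) > 1 else label_year
            snapshots[prev_year].put(
                ICFDatum(code, Qualifier(prev), "measured", ("planted",))
            )

        label = int(rng.choice(5, p=spec.transition_probs(prev)))
        snapshots[label_year].put(
            ICFDatum(code, Qualifier(label), "measured", ("planted",))
        )
        out.append(
            PersonProfile(
                person_id=p.person_id, age=p.age, gender=p.gender,
                years_from_diagnosis=p.years_from_diagnosis, disease=p.disease,
                origin=p.origin, snapshots=snapshots,
            )
        )
    return out
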