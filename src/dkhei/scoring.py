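"""Danish Healthy Eating Index (HEI) component scoring.

The index quantifies adherence to the Danish food-based dietary guidelines
with eight components: fruits and vegetables, dietary fibre, fish, red meat,
saturated fatty acids (SFA), sodium, sugar-sweetened beverages (SSB), and
added sugar.  Each component is scored continuously on [0, 10] by linear
interpolation between a zero-point (0 points) and a full-point (10 points)
cutoff; the eight scores sum to a total on [0, 80].

Adequacy components (fruit & veg, fibre, fish) score upward with intake;
moderation components (red meat, SFA, sodium, SSB, added sugar) score
downward.  SFA and added sugar are scored on the percentage of total energy
they contribute (E%); the remaining components on absolute grams per day or
per week.  The fruit-and-vegetable score is halved when fruit intake exceeds
vegetable intake, reflecting the guideline that at least half of the
fruit-and-vegetable total should be vegetables.

Intakes are scored as absolute amounts; no energy standardisation is applied
before scoring even though the underlying guidelines are phrased per 10
MJ/day.  Boundary intakes score by the interpolation endpoints (e.g. sodium
at exactly 2.4 g/day scores 0), which is the unique continuous reading of
the cutoff table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentRule",
    "ComponentScore",
    "IntakeProfile",
    "HEIResult",
    "ScoringError",
    "DANISH_HEI",
    "ENERGY_FACTORS_KJ_PER_G",
    "energy_percent",
    "score_linear",
    "score_fruit_veg",
    "score_profile",
    "score_intakes",
]

#: Nordic convention energy conversion factors, kJ per gram.  Fat (hence SFA)
#: 37 kJ/g; carbohydrate (hence added sugar) and protein 17 kJ/g.
ENERGY_FACTORS_KJ_PER_G: dict[str, float] = {
    "fat": 37.0,
    "sfa": 37.0,
    "carbohydrate": 17.0,
    "added_sugar": 17.0,
    "protein": 17.0,
}


class ScoringError(ValueError):
    """Raised when a profile cannot be scored (bad energy, missing field)."""


@dataclass(frozen=True)
class ComponentRule:
    """Declarative definition of one HEI component.

    Parameters
    ----------
    name : str
        Component label, matching an :class:`IntakeProfile` field (the
        fruit-and-vegetable component draws on ``fruit`` + ``vegetables``).
    direction : {"adequacy", "moderation"}
        Whether higher intake raises (adequacy) or lowers (moderation) the
        score.
    zero_point, full_point : float
        Intakes (on the rule's basis and period) scoring 0 and 10 points.
    basis : {"grams", "energy_percent"}
        Whether the rule is evaluated on absolute mass or on the percent of
        total energy the nutrient contributes.
    period : {"day", "week"}
        Reference period of the cutoffs.
    energy_factor : float, optional
        kJ per gram, required for ``energy_percent`` rules when converting a
        gram mass to E%.
    """

    name: str
    direction: str
    zero_point: float
    full_point: float
    basis: str = "grams"
    period: str = "day"
    energy_factor: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("adequacy", "moderation"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.basis not in ("grams", "energy_percent"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.period not in ("day", "week"):
            raise ValueError(f"unknown period {self.period!r}")
        if self.zero_point == self.full_point:
            raise ValueError(f"{self.name}: zero_point == full_point")
        if self.direction == "adequacy" and not self.full_point > self.zero_point:
            raise ValueError(f"{self.name}: adequacy requires full_point > zero_point")
        if self.direction == "moderation" and not self.full_point < self.zero_point:
            raise ValueError(f"{self.name}: moderation requires full_point < zero_point")


#: The Danish HEI: eight components, cutoffs from the Danish food-based
#: dietary guidelines (foods) and the Nordic Nutrition Recommendations
#: (nutrients).  SSB cutoff treats 1 ml = 1 g (beverage density ~1).
DANISH_HEI: tuple[ComponentRule, ...] = (
    ComponentRule("fruit_veg", "adequacy", 0.0, 600.0, "grams", "day"),
    ComponentRule("dietary_fibre", "adequacy", 0.0, 30.0, "grams", "day"),
    ComponentRule("fish", "adequacy", 0.0, 350.0, "grams", "week"),
    ComponentRule("red_meat", "moderation", 500.0, 200.0, "grams", "week"),
    ComponentRule("sfa", "moderation", 10.0, 0.0, "energy_percent", "day",
                  ENERGY_FACTORS_KJ_PER_G["sfa"]),
    ComponentRule("sodium", "moderation", 2.4, 1.6, "grams", "day"),
    ComponentRule("ssb", "moderation", 500.0, 0.0, "grams", "week"),
    ComponentRule("added_sugar", "moderation", 10.0, 0.0, "energy_percent", "day",
                  ENERGY_FACTORS_KJ_PER_G["added_sugar"]),
)

#: IntakeProfile field(s) feeding each component.
_RULE_FIELDS: dict[str, tuple[str, ...]] = {
    "fruit_veg": ("fruit", "vegetables"),
    "dietary_fibre": ("dietary_fibre",),
    "fish": ("fish",),
    "red_meat": ("red_meat",),
    "sfa": ("sfa",),
    "sodium": ("sodium",),
    "ssb": ("ssb",),
    "added_sugar": ("added_sugar",),
}


@dataclass(frozen=True)
class IntakeProfile:
    """One subject's quantified daily/weekly intakes.

    Units: fruit, vegetables, dietary_fibre, sfa, sodium, added_sugar and the
    macronutrients in g/day; fish, red_meat, ssb in g/week; energy in kJ/day.
    """

    subject_id: str
    fruit: float
    vegetables: float
    dietary_fibre: float
    fish: float
    red_meat: float
    sfa: float
    sodium: float
    ssb: float
    added_sugar: float
    energy: float
    protein: float | None = None
    fat: float | None = None
    carbohydrate: float | None = None

    def __post_init__(self) -> None:
        for name in ("fruit", "vegetables", "dietary_fibre", "fish", "red_meat",
                     "sfa", "sodium", "ssb", "added_sugar"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ScoringError(
                    f"subject {self.subject_id}: {name} must be a non-negative "
                    f"number, got {v!r}"
                )


@dataclass(frozen=True)
class ComponentScore:
    name: str
    raw_value: float
    points: float
    halved: bool = False


@dataclass(frozen=True)
class HEIResult:
    """Eight component scores and their total (0-80 points)."""

    subject_id: str
    components: tuple[ComponentScore, ...]
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total is None:
            object.__setattr__(self, "total", float(sum(c.points for c in self.components)))

    def as_dict(self) -> dict[str, float]:
        d = {c.name: c.points for c in self.components}
        d["total"] = self.total
        return d


def energy_percent(nutrient_mass: float, energy_factor: float, total_energy: float,
                   subject_id: str = "?") -> float:
    """Percent of total energy contributed by ``nutrient_mass`` grams.

    E% = 100 * mass [g] * energy_factor [kJ/g] / total_energy [kJ].
    """
    if not total_energy > 0:
        raise ScoringError(
            f"subject {subject_id}: total energy must be positive to score an "
            f"energy-percent component, got {total_energy!r}"
        )
    if not energy_factor > 0:
        raise ScoringError(f"subject {subject_id}: energy factor must be positive")
    return 100.0 * nutrient_mass * energy_factor / total_energy


def score_linear(value, rule: ComponentRule):
    """Piecewise-linear component score on [0, 10].

    Linear interpolation between ``zero_point`` (0 points) and ``full_point``
    (10 points), clamped at both ends.  Vectorised: accepts scalars or arrays.
    """
    t = (np.asarray(value, dtype=float) - rule.zero_point) / (rule.full_point - rule.zero_point)
    pts = np.clip(10.0 * t, 0.0, 10.0)
    return float(pts) if np.isscalar(value) or np.ndim(value) == 0 else pts


def score_fruit_veg(fruit: float, vegetables: float,
                    rule: ComponentRule | None = None) -> ComponentScore:
    """Score the combined fruit-and-vegetable component.

    The base score is linear in fruit + vegetables; if fruit exceeds
    vegetables the (already clamped) score is multiplied by 0.5, so the
    maximum attainable with fruit > vegetables is 5 points.
    """
    if rule is None:
        rule = DANISH_HEI[0]
    total = fruit + vegetables
    base = score_linear(total, rule)
    halved = fruit > vegetables
    return ComponentScore("fruit_veg", total, 0.5 * base if halved else base, halved)


def score_profile(profile: IntakeProfile,
                  index: Sequence[ComponentRule] = DANISH_HEI,
                  precomputed_energy_percent: bool = False) -> HEIResult:
    """Score one intake profile against an index definition.

    E% components are computed from gram masses with the rule's kJ/g factor
    unless ``precomputed_energy_percent`` is set, in which case the profile's
    ``sfa`` / ``added_sugar`` fields are taken to hold E% directly.
    """
    comps = []
    for rule in index:
        fields = _RULE_FIELDS.get(rule.name)
        if fields is None:
            raise ScoringError(f"no profile field mapping for component {rule.name!r}")
        vals = []
        for f in fields:
            v = getattr(profile, f, None)
            if v is None:
                raise ScoringError(
                    f"subject {profile.subject_id}: missing field {f!r} required "
                    f"by component {rule.name!r}"
                )
            vals.append(v)
        if rule.name == "fruit_veg":
            comps.append(score_fruit_veg(vals[0], vals[1], rule))
            continue
        raw = vals[0]
        if rule.basis == "energy_percent" and not precomputed_energy_percent:
            raw = energy_percent(raw, rule.energy_factor, profile.energy,
                                 profile.subject_id)
        comps.append(ComponentScore(rule.name, float(raw), score_linear(raw, rule)))
    return HEIResult(profile.subject_id, tuple(comps))


def score_intakes(intakes: pd.DataFrame,
                  index: Sequence[ComponentRule] = DANISH_HEI,
                  precomputed_energy_percent: bool = False,
                  on_error: str = "raise") -> pd.DataFrame:
    """Vectorised scoring of an intake table.

    Parameters
    ----------
    intakes : DataFrame
        One row per subject with :class:`IntakeProfile` columns (``fruit``,
        ``vegetables``, ``dietary_fibre`` g/day; ``fish``, ``red_meat``,
        ``ssb`` g/week; ``sfa``, ``sodium``, ``added_sugar`` g/day;
        ``energy`` kJ/day).
    on_error : {"raise", "skip"}
        With ``"skip"``, rows that cannot be scored (negative intake,
        non-positive energy for an E% component) are dropped and listed in
        the returned frame's ``attrs["skipped"]`` rather than silently zeroed.

    Returns
    -------
    DataFrame with one column per component score, ``fruit_veg_halved``, and
    ``total``.
    """
    df = intakes.copy()
    intake_cols = sorted({f for fs in _RULE_FIELDS.values() for f in fs})
    missing = [c for c in intake_cols if c not in df.columns]
    if missing:
        raise ScoringError(f"intake table missing columns: {missing}")

    needs_energy = any(r.basis == "energy_percent" for r in index) and not precomputed_energy_percent
    bad = pd.Series(False, index=df.index)
    for c in intake_cols:
        v = pd.to_numeric(df[c], errors="coerce")
        bad |= v.isna() | (v < 0)
        df[c] = v
    if needs_energy:
        if "energy" not in df.columns:
            raise ScoringError("intake table missing 'energy' column required for E% scoring")
        e = pd.to_numeric(df["energy"], errors="coerce")
        bad |= e.isna() | (e <= 0)
        df["energy"] = e
    if bad.any():
        if on_error == "raise":
            ids = df.index[bad].tolist()[:5]
            raise ScoringError(
                f"{int(bad.sum())} row(s) cannot be scored (negative/missing intake "
                f"or non-positive energy); first offenders: {ids}"
            )
        skipped = df.index[bad].tolist()
        df = df.loc[~bad]
    else:
        skipped = []

    out = pd.DataFrame(index=df.index)
    for rule in index:
        if rule.name == "fruit_veg":
            total = df["fruit"].to_numpy() + df["vegetables"].to_numpy()
            base = score_linear(total, rule)
            halved = df["fruit"].to_numpy() > df["vegetables"].to_numpy()
            out["fruit_veg"] = np.where(halved, 0.5 * base, base)
            out["fruit_veg_halved"] = halved
            continue
        raw = df[rule.name].to_numpy(dtype=float)
        if rule.basis == "energy_percent" and not precomputed_energy_percent:
            raw = 100.0 * raw * rule.energy_factor / df["energy"].to_numpy(dtype=float)
        out[rule.name] = score_linear(raw, rule)
    score_cols = [r.name for r in index]
    out["total"] = out[score_cols].sum(axis=1)
    out.attrs["skipped"] = skipped
    return out
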