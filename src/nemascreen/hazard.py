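"""GHS acute-toxicity classification and aquatic hazard summarisation.

All interval schemes are left-open/right-closed: a boundary value
belongs to the more severe side (LD50 = 5 mg/kg is oral category 1).
A ``>`` qualifier means the true value exceeds the stated bound, so a
qualified input classifies as if it sat immediately above the bound.

Acute oral categories (mg/kg): (0,5] -> 1; (5,50] -> 2; (50,300] -> 3;
(300,2000] -> 4; (2000,5000] -> 5; above 5000 unclassified (or 5, by
configuration). Acute dermal (mg/kg): (0,50] -> 1; (50,200] -> 2;
(200,1000] -> 3; (1000,2000] -> 4; above 2000 -> 5. The six-band
toxicity-class scheme shares the oral cutoffs and adds band 6 above
5000 mg/kg.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

from nemascreen.registry import (
    EcotoxProfile,
    MammalianToxProfile,
    Qualified,
    Qualifier,
)

__all__ = [
    "ORAL_CUTOFFS",
    "DERMAL_CUTOFFS",
    "BOUNDARY_RULE",
    "HazardClassification",
    "AquaticHazardSummary",
    "classify_ghs_oral",
    "classify_ghs_dermal",
    "classify_toxicity_band",
    "aquatic_minimum",
    "classify_profiles",
    "severity_rank",
]

ORAL_CUTOFFS: tuple[float, ...] = (5.0, 50.0, 300.0, 2000.0, 5000.0)
DERMAL_CUTOFFS: tuple[float, ...] = (50.0, 200.0, 1000.0, 2000.0)

BOUNDARY_RULE = "left-open right-closed intervals; '>' classifies immediately above the bound"


def _as_qualified(ld50: Qualified | float) -> Qualified:
    return ld50 if isinstance(ld50, Qualified) else Qualified(float(ld50))


def _interval_index(value: Qualified, cutoffs: Sequence[float]) -> int | None:
    """0-based category index, or None when above the last cutoff.

    For an exact value the interval is found with bisect_left so that a
    value equal to a cutoff lands in the more severe category. A ``>``
    bound instead takes the first interval whose cutoff strictly
    exceeds the bound.
    """
    if value.value <= 0:
        raise ValueError(f"LD50 must be > 0, got {value.value}")
    if value.qualifier is Qualifier.GT:
        for i, cutoff in enumerate(cutoffs):
            if value.value < cutoff:
                return i
        return None
    i = bisect_left(cutoffs, value.value)
    return i if i < len(cutoffs) else None


def classify_ghs_oral(ld50: Qualified | float, above_top: str = "unclassified") -> int | None:
    """GHS acute oral category 1-5, or None above 5000 mg/kg.

    ``above_top="category_5"`` folds everything above the top cutoff
    into the least severe category instead of returning None.
    """
    idx = _interval_index(_as_qualified(ld50), ORAL_CUTOFFS)
    if idx is None:
        return 5 if above_top == "category_5" else None
    return idx + 1


def classify_ghs_dermal(ld50: Qualified | float) -> int:
    """GHS acute dermal category 1-5 (everything above 2000 is 5)."""
    idx = _interval_index(_as_qualified(ld50), DERMAL_CUTOFFS)
    return 5 if idx is None else idx + 1


def classify_toxicity_band(ld50: Qualified | float) -> int:
    """Six-band toxicity class: oral cutoffs plus band 6 above 5000."""
    idx = _interval_index(_as_qualified(ld50), ORAL_CUTOFFS)
    return 6 if idx is None else idx + 1


def severity_rank(oral_category: int | None) -> int:
    """Ordering helper: unclassified ranks least severe (6)."""
    return 6 if oral_category is None else oral_category


@dataclass(frozen=True)
class HazardClassification:
    compound_cas: str
    ghs_oral_category: int | None
    ghs_dermal_category: int | None
    toxicity_class_band: int | None
    boundary_rule: str = BOUNDARY_RULE
    qualifier_note: str = ""


@dataclass(frozen=True)
class AquaticHazardSummary:
    compound_cas: str
    min_threshold: float
    limiting_trophic_group: str
    qualifier: Qualifier


def aquatic_minimum(profile: EcotoxProfile) -> AquaticHazardSummary:
    """Smallest present aquatic endpoint with its trophic attribution.

    ``>``-qualified values compare by their bound; ties resolve in
    fish, algae, invertebrates order.
    """
    endpoints = profile.endpoints()
    if not endpoints:
        raise ValueError(f"{profile.compound_cas}: no aquatic endpoints present")
    group = min(endpoints, key=lambda g: endpoints[g].value)
    chosen = endpoints[group]
    return AquaticHazardSummary(
        compound_cas=profile.compound_cas,
        min_threshold=chosen.value,
        limiting_trophic_group=group,
        qualifier=chosen.qualifier,
    )


def classify_profiles(
    profiles: Iterable[MammalianToxProfile], above_top: str = "unclassified"
) -> list[HazardClassification]:
    """Classify each mammalian profile; absent endpoints yield None."""
    out = []
    for p in profiles:
        notes = []
        if p.oral_ld50 is not None and p.oral_ld50.qualifier is Qualifier.GT:
            notes.append(f"oral LD50 is a lower bound (>{p.oral_ld50.value:g} mg/kg)")
        if p.dermal_ld50 is not None and p.dermal_ld50.qualifier is Qualifier.GT:
            notes.append(f"dermal LD50 is a lower bound (>{p.dermal_ld50.value:g} mg/kg)")
        out.append(
            HazardClassification(
                compound_cas=p.compound_cas,
                ghs_oral_category=None
                if p.oral_ld50 is None
                else classify_ghs_oral(p.oral_ld50, above_top=above_top),
                ghs_dermal_category=None
                if p.dermal_ld50 is None
                else classify_ghs_dermal(p.dermal_ld50),
                toxicity_class_band=None
                if p.oral_ld50 is None
                else classify_toxicity_band(p.oral_ld50),
                qualifier_note="; ".join(notes),
            )
        )
    return out
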