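"""Synthetic compound sets and endpoint tables for pipeline testing.

Profiles target a partitioning mechanism (air-, water- or soil-seeking)
rather than matching any empirical property density: partition-relevant
properties are sampled log-uniformly, and the Henry's law constant is
sampled directly and then back-solved to a consistent vapour pressure
(VP = H * S / M) so generated records are always internally consistent.

Endpoint tables draw log-normally around per-class medians, which makes
parameter recovery checks possible: the empirical class median converges
to the configured one as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from nemascreen.registry import (
    ClassGroup,
    CompoundRecord,
    EcotoxProfile,
    MammalianToxProfile,
    Qualified,
    Qualifier,
)

__all__ = [
    "SyntheticProfile",
    "PROFILES",
    "generate_compound_set",
    "generate_endpoint_tables",
    "synthetic_cas",
]


@dataclass(frozen=True)
class SyntheticProfile:
    """Log-uniform sampling bounds plus the expected dominant compartment."""

    name: str
    h_range: tuple[float, float]  # Pa m^3/mol
    s_range: tuple[float, float]  # mg/L
    log_kow_range: tuple[float, float]
    tm_range_c: tuple[float, float]
    class_label: str | None  # expected dominant compartment, None for mixed

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("h_range", self.h_range),
            ("s_range", self.s_range),
            ("log_kow_range", self.log_kow_range),
            ("tm_range_c", self.tm_range_c),
        ):
            if not lo < hi:
                raise ValueError(f"{self.name}: {label} bounds must satisfy low < high, got ({lo}, {hi})")
        if self.h_range[0] <= 0 or self.s_range[0] <= 0:
            raise ValueError(f"{self.name}: H and S bounds must be positive")


PROFILES: dict[str, SyntheticProfile] = {
    "air_seeking": SyntheticProfile(
        "air_seeking", (1e2, 1e4), (1e1, 1e4), (0.46, 2.46), (-50.0, 20.0), "air"
    ),
    "water_seeking": SyntheticProfile(
        "water_seeking", (1e-6, 1e-3), (1e3, 1e6), (-1.0, 1.0), (-50.0, 20.0), "water"
    ),
    "soil_seeking": SyntheticProfile(
        "soil_seeking", (1e-1, 1e1), (1e0, 1e2), (4.5, 6.0), (-50.0, 20.0), "soil"
    ),
    "mixed": SyntheticProfile("mixed", (1e-4, 1e3), (1e0, 1e5), (-1.0, 5.0), (-50.0, 150.0), None),
}

_CLASS_CYCLE = tuple(ClassGroup)


def synthetic_cas(index: int) -> str:
    """A structurally valid CAS number reserved for synthetic records."""
    body = f"{9000000 + index:07d}" + "11"
    check = sum(int(d) * w for w, d in enumerate(reversed(body), start=1)) % 10
    return f"{body[:7]}-{body[7:]}-{check}"


def generate_compound_set(
    n: int,
    seed: int,
    profile: SyntheticProfile | str,
) -> tuple[list[CompoundRecord], list[str | None]]:
    """Sample ``n`` internally consistent records plus expected labels.

    Properties are log-uniform within the profile bounds (logKow and
    melting point uniform); molar mass is uniform in [100, 500] g/mol.
    The first record omits its Henry's law constant (derivable from
    VP/M/S) so downstream estimation paths are always exercised.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if isinstance(profile, str):
        profile = PROFILES[profile]
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    labels: list[str | None] = []
    for i in range(n):
        molar_mass = float(rng.uniform(100.0, 500.0))
        h = float(np.exp(rng.uniform(np.log(profile.h_range[0]), np.log(profile.h_range[1]))))
        s = float(np.exp(rng.uniform(np.log(profile.s_range[0]), np.log(profile.s_range[1]))))
        log_kow = float(rng.uniform(*profile.log_kow_range))
        tm = float(rng.uniform(*profile.tm_range_c))
        vp = h * s / molar_mass  # back-solved: derived H reproduces the sampled one
        records.append(
            CompoundRecord(
                name=f"synthetic-{profile.name}-{i:04d}",
                cas=synthetic_cas(i),
                class_group=_CLASS_CYCLE[i % len(_CLASS_CYCLE)],
                molar_mass=molar_mass,
                melting_point=tm,
                vapour_pressure=vp,
                water_solubility=s,
                log_kow=log_kow,
                henry_constant=None if i == 0 else h,
                koc=None,  # derivable via the Seth relation
            )
        )
        labels.append(profile.class_label)
    return records, labels


def generate_endpoint_tables(
    compounds: list[CompoundRecord],
    seed: int,
    aquatic_medians: Mapping[ClassGroup | str, float],
    oral_medians: Mapping[ClassGroup | str, float] | None = None,
    dispersion: float = 0.5,
    gt_fraction: float = 0.05,
) -> tuple[list[EcotoxProfile], list[MammalianToxProfile]]:
    """Class-structured aquatic and mammalian endpoint tables.

    Endpoints are drawn log-normally (base 10) around the class median
    with the given log-scale standard deviation; a ``gt_fraction`` of
    entries carry a ``>`` qualifier, with at least one guaranteed per
    non-empty batch when the fraction is positive.
    """
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    aquatic = {ClassGroup(k): float(v) for k, v in aquatic_medians.items()}
    oral = (
        {ClassGroup(k): float(v) for k, v in oral_medians.items()}
        if oral_medians is not None
        else {k: v * 100.0 for k, v in aquatic.items()}  # mg/kg scale default
    )
    for table in (aquatic, oral):
        for cls, median in table.items():
            if median <= 0:
                raise ValueError(f"median for {cls.value} must be > 0, got {median}")
    rng = np.random.default_rng(seed)
    ecotox: list[EcotoxProfile] = []
    mamm: list[MammalianToxProfile] = []
    any_gt = False
    for record in compounds:
        m_aq = aquatic[record.class_group]
        m_or = oral[record.class_group]

        def draw(median: float) -> float:
            return float(median * 10.0 ** rng.normal(0.0, dispersion))

        def qual() -> Qualifier:
            nonlocal any_gt
            hit = bool(rng.random() < gt_fraction)
            any_gt = any_gt or hit
            return Qualifier.GT if hit else Qualifier.EQ

        ecotox.append(
            EcotoxProfile(
                compound_cas=record.cas,
                fish_lc50=Qualified(draw(m_aq), qual()),
                algae_ec50=Qualified(draw(m_aq), qual()),
                invertebrate_ec50=Qualified(draw(m_aq), qual()),
                invertebrate_species="Daphnia magna",
            )
        )
        mamm.append(
            MammalianToxProfile(
                compound_cas=record.cas,
                oral_ld50=Qualified(draw(m_or), qual()),
                dermal_ld50=Qualified(draw(m_or * 2.0), qual()),
                dermal_model="rabbit",
            )
        )
    if gt_fraction > 0 and ecotox and not any_gt:
        first = ecotox[0]
        first.fish_lc50 = Qualified(first.fish_lc50.value, Qualifier.GT)
    return ecotox, mamm
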