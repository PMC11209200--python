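"""Level I Mackay equilibrium fugacity engine.

A fixed emission is introduced into a closed seven-compartment
evaluative world at equilibrium; each compartment's fugacity capacity
(Z, mol m^-3 Pa^-1) determines the fraction of mass it holds:

    f = n_total / sum(Z_c * V_c)        mass%_c = 100 * Z_c V_c / sum

Z-value formulation (water solubility route):

    Z_air       = 1 / (R T)
    Z_water     = 1 / H
    Z_soil      = Z_water * (rho_soil/1000) * foc_soil * Koc
    Z_sediment  = Z_water * (rho_sed/1000)  * foc_sed  * Koc
    Z_suspended = Z_water * (rho_susp/1000) * foc_susp * Koc
    Z_biota     = Z_water * (rho_biota/1000) * L * Kow
    Z_aerosols  = Z_air * 6e6 / P_L
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from nemascreen.properties import (
    DEFAULT_TEMPERATURE_K,
    DerivedProperties,
    derive_properties,
)
from nemascreen.registry import CompoundRecord

__all__ = [
    "COMPARTMENTS",
    "GAS_CONSTANT_R",
    "EvaluativeEnvironment",
    "ZValueSet",
    "PEDResult",
    "default_environment",
    "load_environment",
    "compute_z_values",
    "distribute",
    "batch_distribute",
    "write_ped_csv",
    "round_half_up",
]

# Table order used for output and deterministic tie-breaking
COMPARTMENTS = ("aerosols", "air", "biota", "sediment", "soil", "suspended_particles", "water")

GAS_CONSTANT_R = 8.314  # Pa m^3 / (mol K)

_AEROSOL_SORPTION_COEFF = 6.0e6  # dimensionless Kqa numerator over P_L (Pa)

_DEFAULT_VOLUMES = {
    "air": 1.0e14,
    "water": 2.0e11,
    "soil": 9.0e9,
    "sediment": 1.0e8,
    "suspended_particles": 1.0e6,
    "biota": 2.0e5,
    "aerosols": 2.0e3,
}
_DEFAULT_DENSITIES = {
    "soil": 2400.0,
    "sediment": 2400.0,
    "suspended_particles": 1500.0,
    "biota": 1000.0,
    "aerosols": 2000.0,
}
_DEFAULT_FOC = {"soil": 0.02, "sediment": 0.04, "suspended_particles": 0.2}

ENVIRONMENT_VERSION = "level1-standard-world/1.0"


@dataclass
class EvaluativeEnvironment:
    """The closed Level I world: volumes, solid compositions, T, E."""

    temperature: float = DEFAULT_TEMPERATURE_K  # K
    gas_constant: float = GAS_CONSTANT_R
    emission_mass_kg: float = 1.0e5
    volumes: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_VOLUMES))
    solids_density: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    organic_carbon_fraction: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FOC))
    lipid_fraction_biota: float = 0.05
    version: str = ENVIRONMENT_VERSION

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        missing = [c for c in COMPARTMENTS if c not in self.volumes]
        if missing:
            raise ValueError(f"volumes missing compartments: {missing}")
        for c, v in self.volumes.items():
            if v < 0:
                raise ValueError(f"volume of {c} must be >= 0, got {v}")
        for c, frac in self.organic_carbon_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"foc of {c} must be in [0, 1], got {frac}")
        if not 0 <= self.lipid_fraction_biota <= 1:
            raise ValueError(f"lipid fraction must be in [0, 1], got {self.lipid_fraction_biota}")

    def replace(self, **overrides) -> "EvaluativeEnvironment":
        """Copy with nested-dict-aware overrides."""
        data = {
            "temperature": self.temperature,
            "gas_constant": self.gas_constant,
            "emission_mass_kg": self.emission_mass_kg,
            "volumes": dict(self.volumes),
            "solids_density": dict(self.solids_density),
            "organic_carbon_fraction": dict(self.organic_carbon_fraction),
            "lipid_fraction_biota": self.lipid_fraction_biota,
            "version": self.version + "+modified",
        }
        for key, value in overrides.items():
            if isinstance(value, Mapping) and isinstance(data.get(key), dict):
                data[key].update(value)
            else:
                data[key] = value
        return EvaluativeEnvironment(**data)


def default_environment() -> EvaluativeEnvironment:
    """The standard Level I evaluative world: 298.15 K, 100,000 kg emission.

    Volumes (m^3): air 1e14, water 2e11, soil 9e9, sediment 1e8,
    suspended particles 1e6, biota 2e5, aerosols 2e3. foc: soil 0.02,
    sediment 0.04, suspended 0.2. Densities (kg/m^3): soil/sediment
    2400, suspended 1500, biota 1000, aerosols 2000. Biota lipid 0.05.
    """
    return EvaluativeEnvironment()


def load_environment(path: str | Path) -> EvaluativeEnvironment:
    """Default environment with overrides from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    overrides = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return default_environment().replace(**(overrides or {}))


@dataclass(frozen=True)
class ZValueSet:
    """Per-compartment fugacity capacities plus the parameters used."""

    z: dict[str, float]
    basis: dict[str, float]

    def __post_init__(self) -> None:
        if self.z["air"] <= 0:
            raise ValueError("Z_air must be > 0")
        bad = {c: v for c, v in self.z.items() if v < 0}
        if bad:
            raise ValueError(f"negative Z values: {bad}")


def compute_z_values(
    record: CompoundRecord,
    env: EvaluativeEnvironment,
    derived: DerivedProperties | None = None,
    h_policy: str = "printed_first",
) -> ZValueSet:
    """Fugacity capacities for all seven compartments.

    ``derived`` may be precomputed (e.g. to share a reconciliation
    policy across a batch); otherwise it is computed here.
    """
    if derived is None:
        derived = derive_properties(record, temperature_k=env.temperature, h_policy=h_policy)
    h = derived.henry_chosen
    if h <= 0:
        raise ValueError(f"{record.cas}: Henry constant must be > 0, got {h}")
    koc = derived.koc_chosen
    kow = derived.kow
    z_air = 1.0 / (env.gas_constant * env.temperature)
    z_water = 1.0 / h
    rho = env.solids_density
    foc = env.organic_carbon_fraction
    z = {
        "air": z_air,
        "water": z_water,
        "soil": z_water * (rho["soil"] / 1000.0) * foc["soil"] * koc,
        "sediment": z_water * (rho["sediment"] / 1000.0) * foc["sediment"] * koc,
        "suspended_particles": z_water
        * (rho["suspended_particles"] / 1000.0)
        * foc["suspended_particles"]
        * koc,
        "biota": z_water * (rho["biota"] / 1000.0) * env.lipid_fraction_biota * kow,
    }
    p_l = derived.subcooled_vp_pl
    z["aerosols"] = z_air * _AEROSOL_SORPTION_COEFF / p_l if p_l > 0 else 0.0
    basis = {
        "henry": h,
        "koc": koc,
        "kow": kow,
        "subcooled_vp_pl": p_l,
        "fugacity_ratio_f": derived.fugacity_ratio_f,
    }
    return ZValueSet(z=z, basis=basis)


@dataclass
class PEDResult:
    """Equilibrium distribution of the emitted mass (one table row)."""

    compound_cas: str
    name: str
    fugacity_pa: float
    total_moles: float
    mass_fraction_percent: dict[str, float]
    flags: list[str] = field(default_factory=list)
    error: str | None = None

    @property
    def dominant_compartment(self) -> str:
        """Arg-max compartment; ties resolve in table column order."""
        return max(COMPARTMENTS, key=lambda c: (self.mass_fraction_percent[c], -COMPARTMENTS.index(c)))

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        """Half-up presentation rounding; full precision is retained."""
        return {c: round_half_up(v, ndigits) for c, v in self.mass_fraction_percent.items()}


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def distribute(
    record: CompoundRecord,
    env: EvaluativeEnvironment | None = None,
    derived: DerivedProperties | None = None,
    h_policy: str = "printed_first",
) -> PEDResult:
    """Level I distribution of the environment's emission mass.

    total moles = E * 1000 / M; common fugacity f = n / sum(Z_c V_c);
    mass fraction of compartment c = Z_c V_c / sum(Z V).
    """
    if env is None:
        env = default_environment()
    if derived is None:
        derived = derive_properties(record, temperature_k=env.temperature, h_policy=h_policy)
    zset = compute_z_values(record, env, derived=derived)
    zv = {c: zset.z[c] * env.volumes[c] for c in COMPARTMENTS}
    total_zv = sum(zv.values())
    total_moles = env.emission_mass_kg * 1000.0 / record.molar_mass
    fugacity = total_moles / total_zv
    fractions = {c: 100.0 * zv[c] / total_zv for c in COMPARTMENTS}
    flags = []
    if derived.henry_consistency.value == "discrepant":
        flags.append("henry_discrepant")
    return PEDResult(
        compound_cas=record.cas,
        name=record.name,
        fugacity_pa=fugacity,
        total_moles=total_moles,
        mass_fraction_percent=fractions,
        flags=flags,
    )


def batch_distribute(
    records: Iterable[CompoundRecord],
    env: EvaluativeEnvironment | None = None,
    h_policy: str = "printed_first",
    reference: Mapping[str, Mapping[str, float]] | None = None,
    reference_tolerance_pp: float = 0.5,
) -> list[PEDResult]:
    """Distribute each record; per-row failures are collected, not raised.

    When ``reference`` (published percentages keyed by CAS) is given,
    rows whose computed distribution misses the reference by more than
    ``reference_tolerance_pp`` percentage points in any compartment are
    flagged ``non_reconstructable`` — the printed inputs cannot
    reproduce the printed outputs.
    """
    if env is None:
        env = default_environment()
    results: list[PEDResult] = []
    for record in records:
        try:
            result = distribute(record, env, h_policy=h_policy)
        except (ValueError, ZeroDivisionError) as exc:
            results.append(
                PEDResult(
                    compound_cas=record.cas,
                    name=record.name,
                    fugacity_pa=float("nan"),
                    total_moles=float("nan"),
                    mass_fraction_percent={c: float("nan") for c in COMPARTMENTS},
                    flags=["error"],
                    error=str(exc),
                )
            )
            continue
        if reference is not None and record.cas in reference:
            ref = reference[record.cas]
            if any(
                abs(result.mass_fraction_percent[c] - ref[c]) > reference_tolerance_pp
                for c in COMPARTMENTS
                if c in ref
            ):
                result.flags.append("non_reconstructable")
        results.append(result)
    return results


def write_ped_csv(results: Sequence[PEDResult], path: str | Path, ndigits: int = 1) -> None:
    """Write the distribution table in the documented compartment order."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cas", "name", *COMPARTMENTS, "flags"])
        for r in results:
            rounded = r.rounded(ndigits)
            writer.writerow(
                [r.compound_cas, r.name]
                + [f"{rounded[c]:.{ndigits}f}" for c in COMPARTMENTS]
                + [";".join(r.flags)]
            )
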