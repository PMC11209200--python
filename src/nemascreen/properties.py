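"""Partition-parameter estimation and cross-checking.

Fills the three parameters the Level I model needs when they are not
reported, and reconciles printed Henry's law constants against the value
implied by vapour pressure, molar mass and solubility:

* Seth relation: ``Koc = 0.35 * Kow``
* Henry's law: ``H = P * M / S`` with S in g/m^3 (== mg/L)
* solid fugacity ratio: ``F = exp(6.79 * (1 - Tm/T))`` for Tm > T,
  else 1; the subcooled liquid vapour pressure is ``P_L = P / F``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from nemascreen.registry import CompoundRecord, Provenance

__all__ = [
    "SETH_COEFFICIENT",
    "DEFAULT_TEMPERATURE_K",
    "HenryStatus",
    "HenryReconciliation",
    "DerivedProperties",
    "estimate_koc_seth",
    "round_sig",
    "derive_henry",
    "fugacity_ratio",
    "subcooled_vapour_pressure",
    "reconcile_henry",
    "derive_properties",
    "estimation_audit",
]

SETH_COEFFICIENT = 0.35
DEFAULT_TEMPERATURE_K = 298.15
# standard default entropy-of-fusion term, Delta_S_fus / R
_FUSION_ENTROPY_OVER_R = 6.79


def estimate_koc_seth(log_kow: float) -> float:
    """Soil organic carbon/water partition coefficient from logKow.

    ``Koc = 0.35 * 10**log_kow``. Use :func:`round_sig` with 3
    significant figures to match tabulated presentation.
    """
    if not math.isfinite(log_kow):
        raise ValueError(f"log_kow must be finite, got {log_kow}")
    return SETH_COEFFICIENT * 10.0 ** log_kow


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def derive_henry(vapour_pressure: float, molar_mass: float, solubility: float) -> float:
    """Henry's law constant ``H = P * M / S`` in Pa m^3/mol.

    ``solubility`` is mg/L, numerically equal to g/m^3, so no unit
    conversion is required.
    """
    if solubility <= 0:
        raise ValueError(f"solubility must be > 0, got {solubility}")
    if vapour_pressure < 0:
        raise ValueError(f"vapour_pressure must be >= 0, got {vapour_pressure}")
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be > 0, got {molar_mass}")
    return vapour_pressure * molar_mass / solubility


def fugacity_ratio(melting_point_c: float, temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Solid/subcooled-liquid fugacity ratio F in (0, 1].

    F = 1 for compounds liquid at the system temperature, else
    ``exp(6.79 * (1 - Tm/T))`` with temperatures in kelvin.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature_k}")
    tm_k = melting_point_c + 273.15
    if tm_k <= temperature_k:
        return 1.0
    return math.exp(_FUSION_ENTROPY_OVER_R * (1.0 - tm_k / temperature_k))


def subcooled_vapour_pressure(
    vapour_pressure: float, melting_point_c: float, temperature_k: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Subcooled liquid vapour pressure P_L = P / F (P_L >= P)."""
    return vapour_pressure / fugacity_ratio(melting_point_c, temperature_k)


class HenryStatus(str, Enum):
    CONSISTENT = "consistent"
    DISCREPANT = "discrepant"
    PRINTED_MISSING = "printed_missing"


@dataclass(frozen=True)
class HenryReconciliation:
    status: HenryStatus
    chosen: float
    printed: float | None
    derived: float | None
    discrepancy_ratio: float  # max(printed/derived, derived/printed); nan if one side missing
    policy: str


def reconcile_henry(
    record: CompoundRecord,
    tolerance_fold: float = 3.0,
    policy: str = "printed_first",
) -> HenryReconciliation:
    """Compare the printed H with the VP*M/S-derived one and pick one.

    ``policy`` is ``"printed_first"`` (default: tabulated value wins when
    present) or ``"derived_first"``. The discrepancy ratio is the fold
    difference between the two routes; above ``tolerance_fold`` the
    record is flagged discrepant but the chosen value still follows the
    policy — flagging is for reporting, not silent correction.
    """
    if policy not in ("printed_first", "derived_first"):
        raise ValueError(f"unknown H policy {policy!r}")
    printed = record.henry_constant
    derived: float | None = None
    if record.water_solubility > 0:
        derived = derive_henry(record.vapour_pressure, record.molar_mass, record.water_solubility)
    if printed is None and (derived is None or derived <= 0):
        raise ValueError(
            f"{record.cas}: no printed Henry constant and none derivable (VP={record.vapour_pressure})"
        )
    if printed is None:
        return HenryReconciliation(HenryStatus.PRINTED_MISSING, derived, None, derived, math.nan, policy)
    if derived is None or derived <= 0:
        return HenryReconciliation(HenryStatus.CONSISTENT, printed, printed, derived, math.nan, policy)
    ratio = max(printed / derived, derived / printed)
    status = HenryStatus.DISCREPANT if ratio > tolerance_fold else HenryStatus.CONSISTENT
    chosen = printed if policy == "printed_first" else derived
    return HenryReconciliation(status, chosen, printed, derived, ratio, policy)


@dataclass(frozen=True)
class DerivedProperties:
    """Everything the fugacity engine needs beyond the raw record."""

    koc_seth: float
    henry_derived: float | None
    henry_chosen: float
    henry_consistency: HenryStatus
    discrepancy_ratio: float
    fugacity_ratio_f: float
    subcooled_vp_pl: float
    koc_chosen: float
    kow: float
    h_policy: str


def derive_properties(
    record: CompoundRecord,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    tolerance_fold: float = 3.0,
    h_policy: str = "printed_first",
) -> DerivedProperties:
    """Resolve H, Koc, F and P_L for one record.

    Koc resolution mirrors the H policy shape but is simpler: the
    tabulated Koc wins when present, otherwise the Seth estimate is
    used.
    """
    rec = reconcile_henry(record, tolerance_fold=tolerance_fold, policy=h_policy)
    koc_seth = estimate_koc_seth(record.log_kow)
    koc = record.koc if record.koc is not None else koc_seth
    f = fugacity_ratio(record.melting_point, temperature_k)
    return DerivedProperties(
        koc_seth=koc_seth,
        henry_derived=rec.derived,
        henry_chosen=rec.chosen,
        henry_consistency=rec.status,
        discrepancy_ratio=rec.discrepancy_ratio,
        fugacity_ratio_f=f,
        subcooled_vp_pl=record.vapour_pressure / f,
        koc_chosen=koc,
        kow=record.kow,
        h_policy=h_policy,
    )


def estimation_audit(record: CompoundRecord, derived: DerivedProperties) -> dict:
    """One JSON-serialisable audit entry per compound.

    Lists, per property, where the value used by the model came from
    and any printed-vs-derived discrepancy flags.
    """
    prov = {k: v.value for k, v in record.provenance.items()}
    henry_source = {
        HenryStatus.PRINTED_MISSING: "derived",
        HenryStatus.CONSISTENT: "printed" if derived.h_policy == "printed_first" else "derived",
        HenryStatus.DISCREPANT: "printed" if derived.h_policy == "printed_first" else "derived",
    }[derived.henry_consistency]
    return {
        "cas": record.cas,
        "name": record.name,
        "provenance": prov,
        "henry": {
            "printed": record.henry_constant,
            "derived": derived.henry_derived,
            "chosen": derived.henry_chosen,
            "source": henry_source,
            "status": derived.henry_consistency.value,
            "discrepancy_ratio": None
            if math.isnan(derived.discrepancy_ratio)
            else derived.discrepancy_ratio,
        },
        "koc": {
            "printed": record.koc,
            "seth": derived.koc_seth,
            "chosen": derived.koc_chosen,
            "source": "printed" if record.koc is not None else "seth",
        },
        "fugacity_ratio": derived.fugacity_ratio_f,
        "subcooled_vp_pa": derived.subcooled_vp_pl,
    }
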