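"""Integrated exposure x hazard screening report.

Joins the predicted environmental distribution, aquatic ecotoxicity and
mammalian hazard tables per compound, applies transparent threshold
rules (all echoed in the report), computes fold-difference comparisons
between endpoint values, and writes CSV/JSON/markdown outputs. The
engine is rule-transparent: every flag is recomputable from the row's
own numbers plus the echoed configuration.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from nemascreen.fugacity import COMPARTMENTS, PEDResult, round_half_up
from nemascreen.hazard import (
    AquaticHazardSummary,
    HazardClassification,
    aquatic_minimum,
)
from nemascreen.registry import (
    CompoundRecord,
    EcotoxProfile,
    Qualified,
    Qualifier,
)

__all__ = [
    "FoldDifference",
    "ScreeningConfig",
    "ScreeningRow",
    "ScreeningReport",
    "fold_difference",
    "screen_compounds",
    "class_summary",
    "write_report",
]


@dataclass(frozen=True)
class FoldDifference:
    """How many fold lower value_a is than value_b (ratio = b / a)."""

    ratio: float
    qualifier: str  # "eq" | "ge" | "le" | "indeterminate"
    endpoint: str = ""
    compound_a: str = ""
    compound_b: str = ""

    @property
    def rounded_to_ten(self) -> float:
        """Display rounding to the nearest 10 (matches 'ca.' phrasing)."""
        return float(Decimal(repr(self.ratio)).quantize(Decimal("1E1"), rounding=ROUND_HALF_UP))


def fold_difference(value_a: Qualified | float, value_b: Qualified | float) -> FoldDifference:
    """Fold difference of a below b: ratio = value_b / value_a.

    A ``>`` on the numerator (value_b) makes the ratio a lower bound
    ("ge"); on the denominator, an upper bound ("le"); on both, the
    direction is indeterminate.
    """
    a = value_a if isinstance(value_a, Qualified) else Qualified(float(value_a))
    b = value_b if isinstance(value_b, Qualified) else Qualified(float(value_b))
    if a.value <= 0 or b.value <= 0:
        raise ValueError(f"fold_difference needs positive values, got {a.value}, {b.value}")
    a_gt, b_gt = a.qualifier is Qualifier.GT, b.qualifier is Qualifier.GT
    if a_gt and b_gt:
        qualifier = "indeterminate"
    elif b_gt:
        qualifier = "ge"
    elif a_gt:
        qualifier = "le"
    else:
        qualifier = "eq"
    return FoldDifference(ratio=b.value / a.value, qualifier=qualifier)


@dataclass(frozen=True)
class ScreeningConfig:
    """Threshold rules; defaults reproduce the qualitative groupings."""

    water_affine_min_pct: float = 50.0
    air_disperser_min_pct: float = 50.0
    soil_affine_min_pct: float = 50.0
    aquatic_concern_max_mg_l: float = 10.0
    mammalian_concern_max_oral_category: int = 2
    # (endpoint, cas_a, cas_b): how many fold lower is a's threshold than b's
    comparisons: tuple[tuple[str, str, str], ...] = (
        ("invertebrates", "23135-22-0", "1254304-22-7"),  # oxamyl vs fluazaindolizine
        ("invertebrates", "137-42-8", "1254304-22-7"),  # metam sodium vs fluazaindolizine
        ("invertebrates", "318290-98-1", "1254304-22-7"),  # fluensulfone vs fluazaindolizine
    )


@dataclass
class ScreeningRow:
    cas: str
    name: str
    class_group: str | None
    ped_percent: dict[str, float]
    dominant_compartment: str
    ped_flags: list[str]
    aquatic: AquaticHazardSummary | None
    hazard: HazardClassification | None
    flags: list[str] = field(default_factory=list)
    insufficient: list[str] = field(default_factory=list)


@dataclass
class ScreeningReport:
    rows: list[ScreeningRow]
    comparisons: list[FoldDifference]
    config_echo: dict

    def row(self, cas: str) -> ScreeningRow:
        for r in self.rows:
            if r.cas == cas:
                return r
        raise KeyError(cas)


_TROPHIC_FIELD = {"fish": "fish_lc50", "algae": "algae_ec50", "invertebrates": "invertebrate_ec50"}


def _row_flags(row: ScreeningRow, config: ScreeningConfig) -> list[str]:
    flags = []
    ped = row.ped_percent
    if ped["water"] >= config.water_affine_min_pct:
        flags.append("water_affine")
    if ped["air"] >= config.air_disperser_min_pct:
        flags.append("air_disperser")
    if ped["soil"] >= config.soil_affine_min_pct:
        flags.append("soil_affine")
    if (
        "water_affine" in flags
        and row.aquatic is not None
        and row.aquatic.min_threshold < config.aquatic_concern_max_mg_l
    ):
        flags.append("aquatic_concern")
    if (
        row.hazard is not None
        and row.hazard.ghs_oral_category is not None
        and row.hazard.ghs_oral_category <= config.mammalian_concern_max_oral_category
    ):
        flags.append("mammalian_concern")
    if "non_reconstructable" in row.ped_flags:
        flags.append("non_reconstructable_ped")
    return sorted(flags)


def screen_compounds(
    ped_results: Sequence[PEDResult],
    ecotox: Iterable[EcotoxProfile],
    hazard: Iterable[HazardClassification],
    config: ScreeningConfig | None = None,
    compounds: Iterable[CompoundRecord] | None = None,
) -> ScreeningReport:
    """Join the three tables on CAS and apply the flag rules.

    Missing endpoints never silently pass: rows lacking aquatic or
    mammalian data carry an entry in ``insufficient`` instead of a
    concern flag. Per-row join failures are reported in the row, not
    raised.
    """
    config = config or ScreeningConfig()
    ecotox_by_cas = {p.compound_cas: p for p in ecotox}
    hazard_by_cas = {h.compound_cas: h for h in hazard}
    class_by_cas = {r.cas: r.class_group.value for r in compounds} if compounds else {}
    rows = []
    for ped in ped_results:
        eco = ecotox_by_cas.get(ped.compound_cas)
        haz = hazard_by_cas.get(ped.compound_cas)
        insufficient = []
        aquatic = None
        if eco is None or not eco.endpoints():
            insufficient.append("no aquatic endpoints")
        else:
            aquatic = aquatic_minimum(eco)
        if haz is None or haz.toxicity_class_band is None:
            insufficient.append("no oral LD50")
        row = ScreeningRow(
            cas=ped.compound_cas,
            name=ped.name,
            class_group=class_by_cas.get(ped.compound_cas),
            ped_percent=dict(ped.mass_fraction_percent),
            dominant_compartment=ped.dominant_compartment,
            ped_flags=list(ped.flags),
            aquatic=aquatic,
            hazard=haz,
            insufficient=insufficient,
        )
        row.flags = _row_flags(row, config)
        rows.append(row)
    comparisons = []
    for endpoint, cas_a, cas_b in config.comparisons:
        pa, pb = ecotox_by_cas.get(cas_a), ecotox_by_cas.get(cas_b)
        if pa is None or pb is None:
            continue
        va = getattr(pa, _TROPHIC_FIELD[endpoint])
        vb = getattr(pb, _TROPHIC_FIELD[endpoint])
        if va is None or vb is None:
            continue
        fd = fold_difference(va, vb)
        comparisons.append(
            FoldDifference(fd.ratio, fd.qualifier, endpoint=endpoint, compound_a=cas_a, compound_b=cas_b)
        )
    return ScreeningReport(rows=rows, comparisons=comparisons, config_echo=asdict(config))


def class_summary(report: ScreeningReport) -> dict[str, dict]:
    """Per-class medians of the full-precision PED and flag counts.

    Rows without a class label are omitted. Output ordering is
    deterministic (sorted by class name).
    """
    groups: dict[str, list[ScreeningRow]] = {}
    for row in report.rows:
        if row.class_group is not None:
            groups.setdefault(row.class_group, []).append(row)
    summary: dict[str, dict] = {}
    for name in sorted(groups):
        rows = groups[name]
        medians = {c: statistics.median(r.ped_percent[c] for r in rows) for c in COMPARTMENTS}
        counts: dict[str, int] = {}
        for r in rows:
            for f in r.flags:
                counts[f] = counts.get(f, 0) + 1
        summary[name] = {"n": len(rows), "median_ped_percent": medians, "flag_counts": counts}
    return summary


def _report_payload(report: ScreeningReport) -> dict:
    rows = []
    for r in report.rows:
        rows.append(
            {
                "cas": r.cas,
                "name": r.name,
                "class_group": r.class_group,
                "ped_percent": {c: r.ped_percent[c] for c in COMPARTMENTS},
                "dominant_compartment": r.dominant_compartment,
                "ped_flags": r.ped_flags,
                "aquatic": None
                if r.aquatic is None
                else {
                    "min_threshold_mg_l": r.aquatic.min_threshold,
                    "limiting_trophic_group": r.aquatic.limiting_trophic_group,
                    "qualifier": r.aquatic.qualifier.value,
                },
                "hazard": None
                if r.hazard is None
                else {
                    "ghs_oral_category": r.hazard.ghs_oral_category,
                    "ghs_dermal_category": r.hazard.ghs_dermal_category,
                    "toxicity_class_band": r.hazard.toxicity_class_band,
                    "qualifier_note": r.hazard.qualifier_note,
                },
                "flags": r.flags,
                "insufficient": r.insufficient,
            }
        )
    comparisons = [
        {
            "endpoint": c.endpoint,
            "compound_a": c.compound_a,
            "compound_b": c.compound_b,
            "ratio": c.ratio,
            "rounded_to_ten": c.rounded_to_ten,
            "qualifier": c.qualifier,
        }
        for c in report.comparisons
    ]
    return {"rows": rows, "comparisons": comparisons, "config": report.config_echo}


def write_report(
    report: ScreeningReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json", "markdown"),
    stem: str = "screening_report",
) -> list[Path]:
    """Write the report; output is bit-stable for fixed input/config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    payload = _report_payload(report)
    if "json" in formats:
        path = out_dir / f"{stem}.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)
    if "csv" in formats:
        path = out_dir / f"{stem}.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["cas", "name", "class_group", *COMPARTMENTS, "dominant_compartment",
                 "min_aquatic_mg_l", "limiting_trophic_group", "ghs_oral", "ghs_dermal",
                 "toxicity_band", "flags", "insufficient"]
            )
            for r in payload["rows"]:
                aquatic = r["aquatic"] or {}
                hazard = r["hazard"] or {}
                writer.writerow(
                    [r["cas"], r["name"], r["class_group"] or ""]
                    + [f"{round_half_up(r['ped_percent'][c], 1):.1f}" for c in COMPARTMENTS]
                    + [
                        r["dominant_compartment"],
                        aquatic.get("min_threshold_mg_l", ""),
                        aquatic.get("limiting_trophic_group", ""),
                        hazard.get("ghs_oral_category", ""),
                        hazard.get("ghs_dermal_category", ""),
                        hazard.get("toxicity_class_band", ""),
                        ";".join(r["flags"]),
                        ";".join(r["insufficient"]),
                    ]
                )
        written.append(path)
    if "markdown" in formats:
        path = out_dir / f"{stem}.md"
        path.write_text(_render_markdown(payload))
        written.append(path)
    return written


def _render_markdown(payload: dict) -> str:
    lines = ["# Screening report", "", "## Predicted environmental distribution (%)", ""]
    header = ["compound"] + list(COMPARTMENTS) + ["dominant", "flags"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for r in payload["rows"]:
        cells = [r["name"]] + [f"{round_half_up(r['ped_percent'][c], 1):.1f}" for c in COMPARTMENTS]
        cells += [r["dominant_compartment"], ";".join(r["flags"]) or "-"]
        lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "## Hazard classification", ""]
    lines.append("| compound | min aquatic (mg/L) | limiting group | GHS oral | GHS dermal | band |")
    lines.append("|---|---|---|---|---|---|")
    for r in payload["rows"]:
        aquatic = r["aquatic"] or {}
        hazard = r["hazard"] or {}
        lines.append(
            "| "
            + " | ".join(
                str(x) if x not in (None, "") else "-"
                for x in [
                    r["name"],
                    aquatic.get("min_threshold_mg_l"),
                    aquatic.get("limiting_trophic_group"),
                    hazard.get("ghs_oral_category"),
                    hazard.get("ghs_dermal_category"),
                    hazard.get("toxicity_class_band"),
                ]
            )
            + " |"
        )
    lines += ["", "## Fold-difference comparisons", ""]
    for c in payload["comparisons"]:
        qualifier = {"ge": ">=", "le": "<=", "eq": "ca.", "indeterminate": "~"}[c["qualifier"]]
        lines.append(
            f"- {c['endpoint']}: {c['compound_a']} is {qualifier} {c['rounded_to_ten']:g}-fold "
            f"below {c['compound_b']} (exact ratio {c['ratio']:.6g})"
        )
    lines.append("")
    return "\n".join(lines)
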