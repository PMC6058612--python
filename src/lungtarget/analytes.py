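"""Analyte definitions: m/z windows for drugs, histological markers and nuisance ions.

The default table targets the dual-isotope salmeterol design: the inhaled drug
(salmeterol, [M+H]+) and its trideuterated isotopologue given intravenously
(d3-salmeterol, +3.0188 Da), plus the three endogenous histology markers used
to anchor compartments — Heme b for blood vessels, PC(32:0) for the
surfactant-rich alveolar bed and PC(36:4) for bronchiolar epithelium.

All default m/z values are monoisotopic [M+H]+ assumptions (adduct species for
the phospholipid markers are not uniquely determined by nominal mass alone) and
are meant to be overridden from a CSV/YAML table when instrument-calibrated
values are available.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

ROLES = (
    "drug_inhaled",
    "drug_iv",
    "marker_vessel",
    "marker_alveolar",
    "marker_bronchiolar",
    "other",
)

#: Mass difference between deuterium and protium times three, for d3 labelling.
D3_MASS_SHIFT = 3 * (2.014102 - 1.007825)


@dataclass(frozen=True)
class AnalyteDefinition:
    """One extractable ion: a named m/z window with a histological role.

    ``tolerance`` is interpreted in Da when ``tolerance_unit == "da"`` and in
    parts-per-million of ``mz_center`` when ``tolerance_unit == "ppm"``.
    """

    name: str
    mz_center: float
    tolerance: float = 0.1
    tolerance_unit: str = "da"
    role: str = "other"

    def __post_init__(self) -> None:
        if self.mz_center <= 0:
            raise ValueError(f"analyte {self.name!r}: mz_center must be > 0")
        if self.tolerance <= 0:
            raise ValueError(f"analyte {self.name!r}: tolerance must be > 0")
        if self.tolerance_unit not in ("da", "ppm"):
            raise ValueError(
                f"analyte {self.name!r}: tolerance_unit must be 'da' or 'ppm'"
            )
        if self.role not in ROLES:
            raise ValueError(f"analyte {self.name!r}: unknown role {self.role!r}")

    @property
    def half_width_da(self) -> float:
        if self.tolerance_unit == "ppm":
            return self.mz_center * self.tolerance * 1e-6
        return self.tolerance

    def window(self) -> tuple[float, float]:
        """Closed m/z interval [lo, hi] covered by this analyte."""
        hw = self.half_width_da
        return (self.mz_center - hw, self.mz_center + hw)

    def with_tolerance(self, tolerance: float, unit: str = "da") -> "AnalyteDefinition":
        return replace(self, tolerance=tolerance, tolerance_unit=unit)


def default_analyte_table() -> list[AnalyteDefinition]:
    """Default dual-isotope salmeterol analyte table (monoisotopic [M+H]+)."""
    salmeterol = 416.2795  # C25H37NO4 + H
    return [
        AnalyteDefinition("salmeterol", salmeterol, role="drug_inhaled"),
        AnalyteDefinition("d3_salmeterol", salmeterol + D3_MASS_SHIFT, role="drug_iv"),
        AnalyteDefinition("heme_b", 616.1773, role="marker_vessel"),
        AnalyteDefinition("pc_32_0", 734.5694, role="marker_alveolar"),
        AnalyteDefinition("pc_36_4", 782.5694, role="marker_bronchiolar"),
    ]


def by_role(analytes: Iterable[AnalyteDefinition], role: str) -> AnalyteDefinition:
    """Return the unique analyte with the given role, or raise."""
    hits = [a for a in analytes if a.role == role]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one analyte with role {role!r}, found {len(hits)}"
        )
    return hits[0]


def by_name(analytes: Iterable[AnalyteDefinition], name: str) -> AnalyteDefinition:
    for a in analytes:
        if a.name == name:
            return a
    raise KeyError(f"no analyte named {name!r}")


def load_analyte_table(path: str | Path) -> list[AnalyteDefinition]:
    """Read analytes from CSV (name,mz,tol,tol_unit,role) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        rows = yaml.safe_load(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        out.append(
            AnalyteDefinition(
                name=str(row["name"]),
                mz_center=float(row["mz"]),
                tolerance=float(row.get("tol", 0.1) or 0.1),
                tolerance_unit=str(row.get("tol_unit", "da") or "da"),
                role=str(row.get("role", "other") or "other"),
            )
        )
    return out


def save_analyte_table(analytes: Sequence[AnalyteDefinition], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "name": a.name,
            "mz": a.mz_center,
            "tol": a.tolerance,
            "tol_unit": a.tolerance_unit,
            "role": a.role,
        }
        for a in analytes
    ]
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(rows, sort_keys=False))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["name", "mz", "tol", "tol_unit", "role"])
            writer.writeheader()
            writer.writerows(rows)
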