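"""Normalized cell-density reporting.

The central question this module serves: should a stained-cell quantity be
normalized to the *epidermal length* (the arc length of the apical surface)
or to the *compartment area*? The two are linked by an exact identity,

    area_per_area[c] = area_per_length[c] * L / A[c],

with L the epidermal length and A[c] the compartment area, so their ratio in
a paired non-lesional (NL) vs lesional (LS) comparison isolates the change in
mean epidermal thickness A/L. In acanthotic (thickened) lesional skin the
per-area density is "diluted" by the grown denominator: for a thickness
factor k > 1 at equal length, the per-area relative increase is exactly the
per-length relative increase divided by k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ScaleCalibration
from .cells import CellSet, split_mask_by_compartment
from .errors import DensityError
from .geometry import CompartmentSet, area_um2

__all__ = [
    "COMPARTMENTS",
    "METRICS",
    "DensityReport",
    "PairedComparison",
    "build_density_report",
    "relative_increase",
    "area_dilution_factor",
    "percent_density_decrease",
    "compare_pair",
]

COMPARTMENTS = ("epidermis", "dermis", "total")
METRICS = ("area_per_length", "area_per_area", "count_per_mm", "count_per_mm2")


@dataclass
class DensityReport:
    """Per-compartment stained areas and counts with both normalizations.

    Inputs are per-compartment stained cell area (um^2), cell counts, and
    compartment areas (um^2) for epidermis and dermis (totals are their sums)
    plus the epidermal length (um). Derived metrics per compartment c:

    * ``area_per_length``: cell area / epidermal length (um^2/um)
    * ``area_per_area``: cell area / compartment area (dimensionless)
    * ``count_per_mm``: cells per mm of epidermal length
    * ``count_per_mm2``: cells per mm^2 of compartment area
    """

    cell_area_um2: dict[str, float]
    cell_count: dict[str, int]
    compartment_area_um2: dict[str, float]
    epidermal_length_um: float
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not (self.epidermal_length_um > 0):
            raise DensityError("epidermal length must be positive")
        for c in ("epidermis", "dermis"):
            for d in (self.cell_area_um2, self.cell_count, self.compartment_area_um2):
                if c not in d:
                    raise DensityError(f"missing compartment {c!r} in report inputs")
            if not (self.compartment_area_um2[c] > 0):
                raise DensityError(f"compartment area for {c!r} must be positive")
        for d in (self.cell_area_um2, self.cell_count, self.compartment_area_um2):
            d["total"] = d["epidermis"] + d["dermis"]

    def area_per_length(self, compartment: str) -> float:
        return self.cell_area_um2[compartment] / self.epidermal_length_um

    def area_per_area(self, compartment: str) -> float:
        return self.cell_area_um2[compartment] / self.compartment_area_um2[compartment]

    def count_per_mm(self, compartment: str) -> float:
        return self.cell_count[compartment] / (self.epidermal_length_um / 1000.0)

    def count_per_mm2(self, compartment: str) -> float:
        return self.cell_count[compartment] / (self.compartment_area_um2[compartment] / 1e6)

    def metric(self, name: str, compartment: str) -> float:
        if name not in METRICS:
            raise DensityError(f"unknown metric {name!r}; expected one of {METRICS}")
        if compartment not in COMPARTMENTS:
            raise DensityError(f"unknown compartment {compartment!r}")
        return float(getattr(self, name)(compartment))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in COMPARTMENTS:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "compartment": c,
                    "cell_area_um2": self.cell_area_um2[c],
                    "cell_count": self.cell_count[c],
                    "compartment_area_um2": self.compartment_area_um2[c],
                    "epidermal_length_um": self.epidermal_length_um,
                    **{m: self.metric(m, c) for m in METRICS},
                }
            )
        return pd.DataFrame(rows)


def build_density_report(
    cells: CellSet,
    comp: CompartmentSet,
    epidermal_length_um: float,
    calib: ScaleCalibration,
    sample_id: str = "sample",
) -> DensityReport:
    """Assemble a report from labeled cells and compartments. Stained area is
    split by exact pixel membership; counts follow each cell's centroid tag."""
    split = split_mask_by_compartment(cells.mask, comp)
    counts = cells.counts_by_compartment()
    return DensityReport(
        cell_area_um2={c: area_um2(split[c], calib) for c in ("epidermis", "dermis")},
        cell_count={c: counts[c] for c in ("epidermis", "dermis")},
        compartment_area_um2={
            c: area_um2(comp.mask(c), calib) for c in ("epidermis", "dermis")
        },
        epidermal_length_um=float(epidermal_length_um),
        sample_id=sample_id,
    )


def relative_increase(
    nl: DensityReport,
    ls: DensityReport,
    metric: str = "area_per_length",
    compartment: str = "total",
) -> float:
    """LS / NL ratio of the named metric (> 1 means denser lesional skin)."""
    v_nl = nl.metric(metric, compartment)
    if v_nl == 0:
        raise DensityError(
            f"relative increase undefined: NL {metric}[{compartment}] is zero"
        )
    return ls.metric(metric, compartment) / v_nl


def area_dilution_factor(nl: DensityReport, ls: DensityReport) -> float:
    """Ratio (per-area relative increase) / (per-length relative increase)
    = (L_ls / A_ls) / (L_nl / A_nl), the inverse ratio of mean epidermal
    thicknesses. Equals 1 iff mean thickness is unchanged; < 1 quantifies how
    much per-area normalization dilutes the apparent increase."""
    for rep, tag in ((nl, "NL"), (ls, "LS")):
        if not (rep.compartment_area_um2["epidermis"] > 0 and rep.epidermal_length_um > 0):
            raise DensityError(f"degenerate geometry in {tag} report")
    return (ls.epidermal_length_um / ls.compartment_area_um2["epidermis"]) / (
        nl.epidermal_length_um / nl.compartment_area_um2["epidermis"]
    )


def percent_density_decrease(nl: DensityReport, ls: DensityReport) -> float:
    """100 * (1 - area_dilution_factor): the percentage by which per-area
    normalization shrinks the apparent NL->LS increase relative to per-length
    normalization. Data-dependent (driven by the realized thickness change),
    not a constant of the method."""
    return 100.0 * (1.0 - area_dilution_factor(nl, ls))


@dataclass
class PairedComparison:
    """A paired NL/LS comparison: both reports plus the per-metric relative
    increases and the area-dilution factor."""

    nl: DensityReport
    ls: DensityReport
    increases: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for c in COMPARTMENTS:
            for m in METRICS:
                v_nl = self.nl.metric(m, c)
                rows.append(
                    {
                        "compartment": c,
                        "metric": m,
                        "nl": v_nl,
                        "ls": self.ls.metric(m, c),
                        "relative_increase": (
                            self.ls.metric(m, c) / v_nl if v_nl != 0 else np.nan
                        ),
                    }
                )
        self.increases = pd.DataFrame(rows)

    def relative_increase(self, metric: str = "area_per_length", compartment: str = "total") -> float:
        return relative_increase(self.nl, self.ls, metric, compartment)

    @property
    def dilution_factor(self) -> float:
        return area_dilution_factor(self.nl, self.ls)

    @property
    def percent_decrease(self) -> float:
        return percent_density_decrease(self.nl, self.ls)


def compare_pair(nl: DensityReport, ls: DensityReport) -> PairedComparison:
    return PairedComparison(nl=nl, ls=ls)
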