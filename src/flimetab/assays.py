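"""Microplate assay arithmetic: standard curves, consumption, normalisation.

Colorimetric readings (glucose, lactate, glutamine; PicoGreen DNA;
alizarin red) are converted to concentrations by inverse regression
against an ordinary-least-squares standard curve, scaled by the well
dilution factor.  Metabolite consumption is the difference between the
medium's initial and final concentration,

    delta[metabolite] = [metabolite]_initial - [metabolite]_final,

with defaults of 1000 mg/L initial glucose and 2.0 mM initial glutamine
(medium formulation values); lactate is reported directly as secretion,
corrected for exogenously supplemented lactate where applicable (7.5 mM
sodium lactate).  Mineralisation is normalised as alizarin-red
absorbance per DNA concentration.

Unit policy: glucose in mg/L, lactate and glutamine in mM; glucose
standards are prepared in mg/dL, so the explicit mg/dL -> mg/L
conversion lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "MetaboliteRecord",
    "AssayError",
    "fit_standard_curve",
    "reading_to_concentration",
    "metabolite_delta",
    "correct_exogenous_lactate",
    "ars_per_dna",
    "process_plate",
    "mg_per_dl_to_mg_per_l",
    "INITIAL_CONCENTRATIONS",
    "LACTATE_SUPPLEMENT_MM",
]

#: assumed initial medium concentrations (medium formulation)
INITIAL_CONCENTRATIONS = {"glucose": 1000.0, "glutamine": 2.0}  # mg/L, mM

#: exogenous sodium-lactate supplement in lactate-supplemented medium (mM)
LACTATE_SUPPLEMENT_MM = 7.5


class AssayError(ValueError):
    """Raised for invalid assay inputs."""


def mg_per_dl_to_mg_per_l(value: float) -> float:
    """1 dL = 0.1 L, so mg/dL -> mg/L multiplies by 10."""
    return value * 10.0


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration of a plate reading against known concentrations."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]
    reading_range: tuple[float, float]
    n_standards: int

    def reading_in_range(self, reading: float) -> bool:
        lo, hi = self.reading_range
        return min(lo, hi) <= reading <= max(lo, hi)


@dataclass(frozen=True)
class MetaboliteRecord:
    """Per-condition/timepoint concentration with consumption bookkeeping.

    ``delta = initial_conc - final_conc`` when populated; negative deltas
    (net secretion) are allowed and flagged.  ``no_consumption`` encodes
    an observed zero-consumption condition explicitly, distinct from a
    missing measurement.
    """

    analyte: str
    condition: str | None
    day: int | None
    reading: float
    dilution: float
    final_conc: float
    initial_conc: float | None = None
    delta: float | None = None
    out_of_range: bool = False
    net_secretion: bool = False
    no_consumption: bool = False


def fit_standard_curve(
    pairs: Iterable[tuple[float, float]] | pd.DataFrame,
    analyte: str = "",
    r2_warn: float = 0.99,
) -> StandardCurve:
    """Ordinary-least-squares fit of reading vs concentration.

    ``pairs`` is an iterable of (concentration, reading).  Requires at
    least 3 distinct concentrations; warns when R^2 falls below
    ``r2_warn`` (a poorly mixed or saturated plate).
    """
    if isinstance(pairs, pd.DataFrame):
        conc = pairs["true_conc"].to_numpy(dtype=float)
        reading = pairs["reading"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise AssayError("pairs must be (concentration, reading) tuples")
        conc, reading = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 3:
        raise AssayError("need >= 3 distinct standard concentrations")
    res = stats.linregress(conc, reading)
    r2 = float(res.rvalue**2)
    if r2 < r2_warn:
        warnings.warn(
            f"standard curve R^2 = {r2:.4f} < {r2_warn}", stacklevel=2
        )
    return StandardCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
        reading_range=(float(reading.min()), float(reading.max())),
        n_standards=int(conc.size),
    )


def reading_to_concentration(
    curve: StandardCurve, reading: float, dilution: float = 1.0
) -> float:
    """Inverse regression: ((reading - intercept) / slope) * dilution."""
    if curve.slope == 0:
        raise AssayError("standard curve has zero slope")
    if dilution <= 0:
        raise AssayError("dilution factor must be positive")
    return (reading - curve.intercept) / curve.slope * dilution


def metabolite_delta(initial: float, final: float) -> float:
    """Consumption from the medium: initial minus final concentration."""
    if initial < 0 or final < 0:
        raise AssayError("concentrations must be non-negative")
    return initial - final


def correct_exogenous_lactate(
    measured_total: float, supplement: float = LACTATE_SUPPLEMENT_MM
) -> float:
    """Secreted lactate after removing the exogenously added supplement.

    Negative results indicate net lactate uptake from the medium.
    """
    if measured_total < 0:
        raise AssayError("measured lactate must be non-negative")
    return measured_total - supplement


def ars_per_dna(ars_absorbance: float, dna_conc: float) -> float:
    """Mineralisation readout: alizarin-red absorbance per DNA (ng/mL)."""
    if dna_conc <= 0:
        raise AssayError("DNA concentration must be positive")
    return ars_absorbance / dna_conc


def process_plate(
    plate: pd.DataFrame,
    initial_concs: dict[str, float] | None = None,
    lactate_supplemented_conditions: Sequence[str] = (),
) -> list[MetaboliteRecord]:
    """Convert a long-format plate table into metabolite records.

    ``plate`` columns: well, role (standard|sample), analyte, reading,
    dilution, condition, day; standards additionally carry ``true_conc``.
    One standard curve is fitted per analyte; sample readings outside the
    calibrated response range are flagged, not extrapolated.  Glucose and
    glutamine records get consumption deltas against their initial medium
    concentrations; lactate is reported as secretion, corrected for the
    exogenous supplement in the listed conditions.
    """
    initial = dict(INITIAL_CONCENTRATIONS)
    if initial_concs:
        initial.update(initial_concs)
    records: list[MetaboliteRecord] = []
    for analyte, sub in plate.groupby("analyte", sort=False):
        standards = sub[sub["role"] == "standard"]
        if standards.empty:
            raise AssayError(f"no standards on the plate for {analyte}")
        curve = fit_standard_curve(standards, analyte=str(analyte))
        for _, row in sub[sub["role"] == "sample"].iterrows():
            conc = reading_to_concentration(
                curve, float(row["reading"]), float(row["dilution"])
            )
            out_of_range = not curve.reading_in_range(float(row["reading"]))
            condition = row.get("condition")
            day = row.get("day")
            day = int(day) if pd.notna(day) else None
            if analyte == "lactate":
                final = conc
                if condition in lactate_supplemented_conditions:
                    final = correct_exogenous_lactate(conc)
                records.append(MetaboliteRecord(
                    analyte="lactate", condition=condition, day=day,
                    reading=float(row["reading"]), dilution=float(row["dilution"]),
                    final_conc=final, out_of_range=out_of_range,
                    net_secretion=final > 0,
                ))
            else:
                init = initial.get(str(analyte))
                delta = metabolite_delta(init, conc) if init is not None else None
                tol = 1e-9 * max(1.0, abs(init)) if init is not None else 0.0
                records.append(MetaboliteRecord(
                    analyte=str(analyte), condition=condition, day=day,
                    reading=float(row["reading"]), dilution=float(row["dilution"]),
                    final_conc=conc, initial_conc=init, delta=delta,
                    out_of_range=out_of_range,
                    net_secretion=bool(delta is not None and delta < -tol),
                    no_consumption=bool(delta is not None and abs(delta) <= tol),
                ))
    return records
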