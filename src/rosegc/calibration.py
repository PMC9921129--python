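"""Internal-standard linear calibration, ICH detection limits and quantification.

Responses are the area ratio PA_analyte / PA_IS (the internal standard,
cis-3-hexen-1-ol, cancels injection-to-injection variability).  The curve is
an unweighted ordinary least-squares line of ratio on concentration; the
residual standard deviation σ (n − 2 degrees of freedom) and the slope S
give the ICH limits LoD = 3.3·σ/S and LoQ = 10·σ/S, converted to ng on
column via ``mass_conversion`` = injection volume (1 µL) × 1000 / split
ratio, i.e. ng per (mg/mL) of injected solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import AnalyteLibrary, PeakTable

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "fit_calibration",
    "lod_loq",
    "quantify",
    "select_dilution",
    "mass_conversion_for",
    "save_curves",
    "load_curves",
]

_LOQ_LOD_RATIO = 10.0 / 3.3


def mass_conversion_for(split_ratio: float, injection_volume_ul: float = 1.0) -> float:
    """ng on column per (mg/mL) injected: volume × 1000 / split ratio."""
    if split_ratio <= 0:
        raise ValueError("split ratio must be positive")
    return injection_volume_ul * 1000.0 / split_ratio


@dataclass
class CalibrationCurve:
    """IS-normalised linear response model for one analyte."""

    analyte: str
    slope: float  # response ratio per (mg/mL)
    intercept: float
    residual_sd: float
    range_low: float
    range_high: float
    r_squared: float
    lod_ng: float = 0.0
    loq_ng: float = 0.0
    mass_conversion: float = 20.0  # ng per (mg/mL); 1 µL at split 1:50
    n_points: int = 0

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration

    def invert(self, ratio: float) -> float:
        """Concentration (mg/mL injected) for a measured response ratio."""
        return (ratio - self.intercept) / self.slope

    @property
    def lod_mg_ml(self) -> float:
        return 3.3 * self.residual_sd / self.slope

    @property
    def loq_mg_ml(self) -> float:
        return 10.0 * self.residual_sd / self.slope


def fit_calibration(
    points: list[tuple[float, float, float]],
    analyte: str = "",
    mass_conversion: float = 20.0,
) -> CalibrationCurve:
    """Fit ratio = intercept + slope·concentration by unweighted OLS.

    *points* are (concentration mg/mL, analyte peak area, IS peak area)
    triples.  Requires at least three distinct concentrations and strictly
    positive IS areas.
    """
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in points], dtype=float)
    for i, (_, _, pa_is) in enumerate(points):
        if pa_is <= 0:
            raise ValueError(f"non-positive internal-standard area in injection {i + 1}")
    ratio = np.array([pa / pa_is for _, pa, pa_is in points], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("degenerate design: need at least 3 distinct concentrations")

    x = np.column_stack([np.ones_like(conc), conc])
    coef, _, _, _ = np.linalg.lstsq(x, ratio, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = ratio - (intercept + slope * conc)
    dof = len(points) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    curve = CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        range_low=float(conc.min()),
        range_high=float(conc.max()),
        r_squared=r_squared,
        mass_conversion=mass_conversion,
        n_points=len(points),
    )
    curve.lod_ng, curve.loq_ng = lod_loq(curve, mass_conversion)
    return curve


def lod_loq(curve: CalibrationCurve, mass_conversion: float | None = None) -> tuple[float, float]:
    """ICH limits from the residual SD and slope: LoD = 3.3·σ/S, LoQ = 10·σ/S.

    Returned in ng via *mass_conversion* (ng per mg/mL); LoQ/LoD = 10/3.3
    exactly by construction.
    """
    if curve.slope <= 0:
        raise ValueError("LoD/LoQ require a positive calibration slope")
    mc = curve.mass_conversion if mass_conversion is None else mass_conversion
    lod = 3.3 * curve.residual_sd / curve.slope * mc
    return float(lod), float(lod * _LOQ_LOD_RATIO)


@dataclass
class QuantResult:
    """Quantified concentration of one analyte in the undiluted oil."""

    analyte: str
    concentration: float | None  # mg/mL in the oil (None when below LoQ)
    concentration_injected: float | None
    dilution_factor: float
    flag: str  # below_loq | above_range | ok | missing_curve
    message: str = ""


def quantify(
    peak_table: PeakTable,
    curves: dict[str, CalibrationCurve],
    dilution_factor: float,
    internal_standard: str | None = None,
    analytes: list[str] | None = None,
) -> list[QuantResult]:
    """Quantify assigned peaks through their calibration curves.

    The measured ratio is inverted through the curve and scaled by the
    dilution factor.  Results below the LoQ-equivalent concentration carry no
    numeric value; results above the calibration range are flagged (and
    should be re-read from a higher dilution, see :func:`select_dilution`).
    Missing curves yield per-analyte error entries without aborting the rest.
    """
    is_name = internal_standard or peak_table.metadata.get("internal_standard")
    if not is_name:
        raise ValueError("internal standard name not given and not in table metadata")
    is_peak = peak_table.get(is_name)
    if is_peak is None or is_peak.area <= 0:
        raise ValueError("internal-standard peak missing or has non-positive area")

    names = analytes if analytes is not None else [
        n for n in (p.assigned_analyte for p in peak_table.assigned) if n != is_name
    ]
    results: list[QuantResult] = []
    for name in names:
        curve = curves.get(name)
        if curve is None:
            results.append(
                QuantResult(name, None, None, dilution_factor, "missing_curve",
                            f"no calibration curve for {name!r}")
            )
            continue
        peak = peak_table.get(name)
        if peak is None:
            results.append(
                QuantResult(name, None, None, dilution_factor, "below_loq",
                            "analyte not detected")
            )
            continue
        ratio = peak.area / is_peak.area
        conc_inj = curve.invert(ratio)
        if conc_inj < curve.loq_mg_ml:
            results.append(
                QuantResult(name, None, float(conc_inj), dilution_factor, "below_loq")
            )
        elif conc_inj > curve.range_high:
            results.append(
                QuantResult(name, float(conc_inj * dilution_factor), float(conc_inj),
                            dilution_factor, "above_range")
            )
        else:
            results.append(
                QuantResult(name, float(conc_inj * dilution_factor), float(conc_inj),
                            dilution_factor, "ok")
            )
    return results


def select_dilution(
    minor: list[QuantResult], major: list[QuantResult]
) -> list[QuantResult]:
    """Merge a low-dilution (minor-component) and high-dilution (major) run.

    The low-dilution value is preferred; an analyte flagged ``above_range``
    there is taken from the high-dilution measurement instead.
    """
    by_name = {r.analyte: r for r in major}
    merged: list[QuantResult] = []
    for r in minor:
        if r.flag == "above_range" and r.analyte in by_name:
            merged.append(by_name[r.analyte])
        else:
            merged.append(r)
    return merged


def save_curves(curves: dict[str, CalibrationCurve], path) -> None:
    payload = {
        name: {
            "analyte": c.analyte,
            "slope": c.slope,
            "intercept": c.intercept,
            "residual_sd": c.residual_sd,
            "range_low": c.range_low,
            "range_high": c.range_high,
            "r_squared": c.r_squared,
            "lod_ng": c.lod_ng,
            "loq_ng": c.loq_ng,
            "mass_conversion": c.mass_conversion,
            "n_points": c.n_points,
        }
        for name, c in curves.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_curves(path) -> dict[str, CalibrationCurve]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {name: CalibrationCurve(**kwargs) for name, kwargs in payload.items()}
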