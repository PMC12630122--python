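"""Calibration-based quantification of marker compounds.

Linear (unweighted OLS) calibration of peak area (mAU) against standard
concentration (mg/mL), inversion of sample areas to extract
concentrations, conversion to content in mg per g of powder under the
extraction scheme (default 0.5 g powder in 20 mL methanol), and the
standard accuracy check by spike recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float            # mAU per (mg/mL)
    intercept: float        # mAU
    r2: float = np.nan
    fit_range: tuple[float, float] | None = None  # mg/mL


@dataclass
class SamplePrep:
    """Extraction scheme: powder mass (g), solvent volume (mL), dilution."""

    mass: float = 0.5
    volume: float = 20.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.volume <= 0 or self.dilution < 1:
            raise ValueError("need mass > 0, volume > 0, dilution >= 1")


def fit_calibration(points, analyte: str = "", weighted: bool = False) -> CalibrationCurve:
    """OLS fit of area on concentration.

    ``points`` is an iterable of (concentration mg/mL, area mAU) pairs.
    ``weighted=True`` applies 1/x weights (rarely needed; the published
    curves are unweighted).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (conc, area) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all concentrations are equal")
    if weighted:
        if (x <= 0).any():
            raise ValueError("1/x weighting requires positive concentrations")
        w = 1.0 / x
        W = np.diag(w)
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
        yhat = slope * x + intercept
        r2 = 1.0 - float(((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        fit_range=(float(x.min()), float(x.max())),
    )


def concentration_from_area(curve: CalibrationCurve, area: float) -> float:
    """Invert the calibration: (area - intercept) / slope, in mg/mL.

    Areas below the intercept would give a negative concentration; those
    are clipped to 0 with a below-LOD warning since contents are physical
    quantities.  Areas outside the fitted range trigger an extrapolation
    warning.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    conc = (float(area) - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"{curve.analyte or 'analyte'}: area {area} below intercept; "
            "reporting 0 (below LOD)",
            stacklevel=2,
        )
        return 0.0
    if curve.fit_range is not None and not (
        curve.fit_range[0] <= conc <= curve.fit_range[1]
    ):
        warnings.warn(
            f"{curve.analyte or 'analyte'}: concentration {conc:.4g} mg/mL "
            f"outside calibrated range {curve.fit_range}",
            stacklevel=2,
        )
    return conc


def content(conc: float, prep: SamplePrep | None = None) -> float:
    """mg analyte per g powder: conc * volume * dilution / mass."""
    prep = prep or SamplePrep()
    return float(conc) * prep.volume * prep.dilution / prep.mass


def content_table(
    areas: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    prep: SamplePrep | None = None,
    add_total: bool = True,
) -> pd.DataFrame:
    """Batch x analyte peak areas -> content table in mg/g."""
    missing = [c for c in areas.columns if c not in curves]
    if missing:
        raise KeyError(f"no calibration curve for: {missing}")
    out = pd.DataFrame(
        {
            c: [
                content(concentration_from_area(curves[c], a), prep)
                for a in areas[c]
            ]
            for c in areas.columns
        },
        index=areas.index,
    )
    if add_total:
        out["total"] = out.sum(axis=1)
    return out


def spike_recovery(original: float, added: float, measured: float) -> float:
    """(measured - original) / added * 100, in percent."""
    if added <= 0:
        raise ValueError("spiked amount must be positive")
    return (float(measured) - float(original)) / float(added) * 100.0


def recovery_study(original: float, added, measured) -> pd.DataFrame:
    """Per-portion recoveries with mean and RSD summary attrs."""
    added = np.asarray(added, dtype=float)
    measured = np.asarray(measured, dtype=float)
    rec = np.array(
        [spike_recovery(original, a, m) for a, m in zip(added, measured)]
    )
    df = pd.DataFrame({"added_mg": added, "measured_mg": measured,
                       "recovery_pct": rec})
    from .fingerprint import rsd  # single RSD definition package-wide

    df.attrs["mean_recovery_pct"] = float(rec.mean())
    df.attrs["rsd_pct"] = rsd(rec) if len(rec) > 1 else float("nan")
    return df
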