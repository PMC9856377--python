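"""Tracer-flux permeability: calibration, flux J and permeability P = J / dc.

Timed basolateral samples of a fluorescent tracer (fluorescein, 332 Da, or
FITC-dextran-4000) appear linearly under sink conditions. The appearance
rate (OLS slope of amount vs time), normalised by exposed area, gives the
flux J; dividing by the apical driving concentration gives the apparent
permeability P in cm/s.

Units are the field's mixed convention — J in mol/(h cm^2), concentration
in mol/L, P in cm/s — which requires explicit conversion::

    P [cm/s] = J [mol h^-1 cm^-2] / 3600 / (dc [mol/L] * 1e-3 [L/cm^3])

i.e. J is converted to mol s^-1 cm^-2 and dc to mol cm^-3 before dividing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "CalibrationCurve",
    "FluxSeries",
    "PermeabilityResult",
    "fit_calibration",
    "flux_from_series",
]

DEFAULT_AREA_CM2 = 0.049  # exposed tissue area of the miniaturized chamber

_AMOUNT_TO_MOL = {"mol": 1.0, "mmol": 1e-3, "umol": 1e-6, "nmol": 1e-9, "pmol": 1e-12}


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence calibration: fluorescence = gain * conc + intercept."""

    concentrations: np.ndarray  # mol / L, unique dilution points
    fluorescence: np.ndarray  # a.u., duplicates already averaged
    gain: float
    intercept: float
    r_squared: float

    def to_concentration(self, fluorescence) -> np.ndarray:
        """Invert the calibration line: a.u. -> mol / L."""
        return (np.asarray(fluorescence, dtype=float) - self.intercept) / self.gain


def fit_calibration(dilutions, readings) -> CalibrationCurve:
    """OLS line through a dilution series, duplicates averaged first.

    Parameters
    ----------
    dilutions : array of float
        Concentrations in mol/L; >= 3 distinct values required. May repeat
        (one entry per reading) or be unique (readings then 2-D, one row of
        replicates per concentration).
    readings : array of float
        Fluorescence readings (a.u.) matching ``dilutions``.
    """
    conc = np.asarray(dilutions, dtype=float)
    y = np.asarray(readings, dtype=float)
    if y.ndim == 2:
        if y.shape[0] != conc.size:
            raise ValidationError("2-D readings need one row per concentration")
        y = y.mean(axis=1)
    elif y.shape != conc.shape:
        raise ValidationError("dilutions and readings differ in length")
    uniq, inv = np.unique(conc, return_inverse=True)
    if uniq.size < 3:
        raise ValidationError("calibration needs >= 3 distinct concentrations")
    mean_y = np.bincount(inv, weights=y) / np.bincount(inv)
    res = stats.linregress(uniq, mean_y)
    if not res.slope > 0:
        raise ValidationError(f"calibration gain must be > 0, got {res.slope:.4g}")
    return CalibrationCurve(
        concentrations=uniq,
        fluorescence=mean_y,
        gain=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class FluxSeries:
    """Timed basolateral tracer samples from one specimen.

    ``values`` are raw fluorescence (a.u., ``value_kind='fluorescence'``,
    needs a calibration) or already-converted amounts
    (``value_kind='amount'`` in ``amount_unit``).
    """

    tracer: str
    time_min: np.ndarray
    values: np.ndarray
    apical_conc_mol_l: float
    area_cm2: float = DEFAULT_AREA_CM2
    volume_ml: float = 1.0
    value_kind: str = "fluorescence"
    amount_unit: str = "mol"
    molar_mass: float | None = None
    specimen_id: str | None = None

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValidationError("time and value arrays differ in length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValidationError("sample times must increase from 0")
        if self.apical_conc_mol_l <= 0:
            raise ValidationError("apical concentration must be > 0")
        if self.area_cm2 <= 0 or self.volume_ml <= 0:
            raise ValidationError("area and basolateral volume must be > 0")
        if self.value_kind not in ("fluorescence", "amount"):
            raise ValidationError("value_kind must be 'fluorescence' or 'amount'")
        if self.value_kind == "amount" and self.amount_unit not in _AMOUNT_TO_MOL:
            raise ValidationError(f"unknown amount unit {self.amount_unit!r}")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PermeabilityResult:
    """Flux and permeability of one tracer series with slope diagnostics."""

    tracer: str
    flux_mol_h_cm2: float
    permeability_cm_s: float
    slope_mol_min: float
    r_squared: float
    n_points: int
    flagged: bool = False
    specimen_id: str | None = None


def flux_from_series(
    series: FluxSeries,
    calib: CalibrationCurve | None = None,
    skip_first: int = 0,
    replaced_volume_ml: float = 0.0,
) -> PermeabilityResult:
    """Appearance-rate OLS -> flux J -> permeability P = J / dc.

    Parameters
    ----------
    series : FluxSeries
    calib : CalibrationCurve, required when the series holds raw fluorescence.
    skip_first : int
        Drop this many leading samples (lag-phase handling); default keeps
        every sample including t = 0.
    replaced_volume_ml : float
        Volume withdrawn per sample and replaced with fresh buffer; the
        cumulative amount removed in earlier samples is added back before
        the slope fit. Default 0 (no replacement correction).
    """
    t = series.time_min[skip_first:]
    v = series.values[skip_first:]
    if t.size < 3:
        raise ValidationError("need >= 3 samples for the appearance-rate fit")

    if series.value_kind == "fluorescence":
        if calib is None:
            raise ValidationError("fluorescence series requires a calibration curve")
        conc = calib.to_concentration(v)  # mol / L
    else:
        conc = v * _AMOUNT_TO_MOL[series.amount_unit] / (series.volume_ml * 1e-3)

    amount = conc * series.volume_ml * 1e-3  # mol in the basolateral chamber
    if replaced_volume_ml > 0:
        removed = np.concatenate([[0.0], np.cumsum(conc[:-1] * replaced_volume_ml * 1e-3)])
        amount = amount + removed

    res = stats.linregress(t, amount)
    slope = float(res.slope)  # mol / min
    ss_tot = float(np.sum((amount - amount.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else float(res.rvalue**2)

    flux = slope * 60.0 / series.area_cm2  # mol h^-1 cm^-2
    dc_mol_cm3 = series.apical_conc_mol_l * 1e-3
    perm = flux / 3600.0 / dc_mol_cm3  # cm / s

    scale = float(np.max(np.abs(amount))) if amount.size else 0.0
    flagged = slope < 0 and abs(slope) * (t[-1] - t[0]) > 1e-3 * max(scale, 1e-300)
    return PermeabilityResult(
        tracer=series.tracer,
        flux_mol_h_cm2=flux,
        permeability_cm_s=perm,
        slope_mol_min=slope,
        r_squared=r2,
        n_points=int(t.size),
        flagged=flagged,
        specimen_id=series.specimen_id,
    )
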