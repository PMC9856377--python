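"""Quantification of electrogenic transport from short-circuit-current traces.

A short-circuit current (Isc) trace records the current (uA * cm^-2) needed
to clamp the transepithelial voltage to zero; drops after blocker addition
quantify the blocked transport pathway:

* bumetanide (NKCC1 inhibitor, serosal) -> electrogenic Cl- secretion,
  quantified as maximum Isc before addition minus Isc 20 min after;
* amiloride (ENaC blocker, mucosal, after aldosterone stimulation) ->
  electrogenic Na+ absorption J_Na, quantified as the plateau difference.

ΔIsc values convert to molar fluxes through Faraday's constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import physical_constants

from .exceptions import ValidationError

__all__ = [
    "DrugEvent",
    "IscTrace",
    "DrugResponse",
    "baseline_isc",
    "bumetanide_response",
    "amiloride_jna",
    "isc_to_molar_flux",
    "molar_flux_to_isc",
]

FARADAY = physical_constants["Faraday constant"][0]  # C / mol


@dataclass(frozen=True)
class DrugEvent:
    drug: str
    time_min: float
    side: str = "serosal"  # mucosal | serosal


@dataclass(frozen=True)
class IscTrace:
    """Sampled Isc time course with timed drug-addition events.

    Times are minutes (strictly increasing), currents uA * cm^-2.
    At most one event per drug.
    """

    time: np.ndarray
    isc: np.ndarray
    events: tuple[DrugEvent, ...] = ()
    specimen_id: str | None = None
    annotations: tuple[str, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.isc, dtype=float)
        if t.size != i.size or t.size < 2:
            raise ValidationError("trace needs >= 2 samples with matching time axis")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        drugs = [e.drug for e in self.events]
        if len(drugs) != len(set(drugs)):
            raise ValidationError("at most one event per drug")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "isc", i)
        object.__setattr__(self, "events", tuple(self.events))

    def event(self, drug: str) -> DrugEvent:
        for e in self.events:
            if e.drug == drug:
                return e
        raise ValidationError(f"no {drug!r} event in trace")

    def value_at(self, t: float, tol_min: float = 1.0) -> float:
        """Isc at time ``t``: nearest sample within ``tol_min``, else linear interpolation."""
        if t < self.time[0] or t > self.time[-1]:
            raise ValidationError(f"time {t} min outside the recorded trace")
        k = int(np.argmin(np.abs(self.time - t)))
        if abs(self.time[k] - t) <= tol_min:
            return float(self.isc[k])
        return float(np.interp(t, self.time, self.isc))


@dataclass(frozen=True)
class DrugResponse:
    """A signed ΔIsc quantification; ``delta_isc = pre_value - post_value`` exactly."""

    drug: str
    delta_isc: float
    pre_value: float
    post_value: float
    window: str
    flagged: bool = False

    def __post_init__(self):
        if not np.isclose(self.delta_isc, self.pre_value - self.post_value, atol=1e-12):
            raise ValidationError("delta_isc must equal pre_value - post_value")


def baseline_isc(trace: IscTrace) -> float:
    """Mean Isc over the pre-event window (all samples before the first event)."""
    if trace.events:
        t_first = min(e.time_min for e in trace.events)
        mask = trace.time < t_first
    else:
        mask = np.ones_like(trace.time, dtype=bool)
    if mask.sum() < 2:
        raise ValidationError("need >= 2 samples before the first event for a baseline")
    return float(np.mean(trace.isc[mask]))


def bumetanide_response(trace: IscTrace, horizon_min: float = 20.0) -> DrugResponse:
    """Bumetanide-sensitive ΔIsc: max Isc before addition minus Isc 20 min after."""
    ev = trace.event("bumetanide")
    t_post = ev.time_min + horizon_min
    if trace.time[-1] < t_post:
        raise ValidationError(
            f"trace ends at {trace.time[-1]} min; needs to extend to "
            f"{t_post} min ({horizon_min} min past bumetanide)"
        )
    pre_mask = trace.time < ev.time_min
    if not pre_mask.any():
        raise ValidationError("no samples before the bumetanide event")
    pre = float(np.max(trace.isc[pre_mask]))
    post = trace.value_at(t_post)
    return DrugResponse(
        drug="bumetanide",
        delta_isc=pre - post,
        pre_value=pre,
        post_value=post,
        window=f"max(t<{ev.time_min:g}) - Isc(t={t_post:g})",
    )


def amiloride_jna(
    trace: IscTrace,
    n_pre: int = 5,
    post_window_min: tuple[float, float] = (5.0, 15.0),
) -> DrugResponse:
    """Amiloride-sensitive ΔIsc (electrogenic Na+ absorption, J_Na equivalent).

    Plateau before (mean of the last ``n_pre`` pre-event samples) minus
    plateau after (mean of samples from +5 to +15 min past the event).
    A negative value is returned signed and flagged.
    """
    ev = trace.event("amiloride")
    pre_idx = np.nonzero(trace.time < ev.time_min)[0]
    if pre_idx.size < n_pre:
        raise ValidationError(f"need >= {n_pre} samples before amiloride")
    pre = float(np.mean(trace.isc[pre_idx[-n_pre:]]))
    lo, hi = ev.time_min + post_window_min[0], ev.time_min + post_window_min[1]
    post_mask = (trace.time >= lo) & (trace.time <= hi)
    if not post_mask.any():
        raise ValidationError(f"no samples in the post-amiloride window [{lo}, {hi}] min")
    post = float(np.mean(trace.isc[post_mask]))
    delta = pre - post
    return DrugResponse(
        drug="amiloride",
        delta_isc=delta,
        pre_value=pre,
        post_value=post,
        window=f"mean(last {n_pre} pre) - mean(+{post_window_min[0]:g}..+{post_window_min[1]:g} min)",
        flagged=delta < 0,
    )


def isc_to_molar_flux(delta_isc: float, charge: float = 1.0) -> float:
    """Convert ΔIsc (uA * cm^-2) to a molar flux (umol * h^-1 * cm^-2).

    flux = delta_isc * 1e-6 * 3600 / (charge * F), reported in umol.
    1 uA * cm^-2 of a monovalent ion corresponds to 0.0373 umol * h^-1 * cm^-2.
    """
    if charge == 0:
        raise ValidationError("charge must be non-zero")
    return delta_isc * 1e-6 * 3600.0 / (charge * FARADAY) * 1e6


def molar_flux_to_isc(flux_umol_h_cm2: float, charge: float = 1.0) -> float:
    """Inverse of :func:`isc_to_molar_flux` (umol * h^-1 * cm^-2 -> uA * cm^-2)."""
    if charge == 0:
        raise ValidationError("charge must be non-zero")
    return flux_umol_h_cm2 * charge * FARADAY / 3600.0
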