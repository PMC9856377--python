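"""Tricellulin delocalization statistic from junctional intensity profiles.

Tricellulin normally concentrates where three epithelial cells meet (the
tricellular tight junction, tTJ) and seals that corner against
macromolecules. Delocalization into the bicellular junction (bTJ) is
quantified from a 1-D fluorescence line profile along the junction: the
intensity at the tricellular anchor point divided by the intensity 2 um
away along the bicellular junction. A ratio near 1 means the protein is
fully dispersed; large ratios mean tight tricellular enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "BTJ_DISTANCE_UM",
    "IntensityProfile",
    "TricellularRatio",
    "ttj_btj_ratio",
    "aggregate_subject",
]

logger = logging.getLogger(__name__)

#: Distance along the junction at which the bicellular reference is read (um).
BTJ_DISTANCE_UM = 2.0


@dataclass(frozen=True)
class IntensityProfile:
    """Uniformly sampled junctional intensity line profile.

    ``ttj_anchor`` marks the tricellular meeting point (um); at least one
    side of the profile must extend ``BTJ_DISTANCE_UM`` beyond it.
    """

    positions: np.ndarray  # um
    intensities: np.ndarray  # a.u.
    ttj_anchor: float
    section_id: str | None = None
    subject_id: str | None = None
    profile_id: str | None = None

    def __post_init__(self):
        x = np.asarray(self.positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValidationError("profile needs >= 3 matching samples")
        dx = np.diff(x)
        if np.any(dx <= 0) or np.ptp(dx) > 1e-6 * dx.mean():
            raise ValidationError("positions must be uniformly increasing")
        if not (x[0] <= self.ttj_anchor <= x[-1]):
            raise ValidationError("tTJ anchor lies outside the profile")
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "intensities", y)

    @property
    def spacing_um(self) -> float:
        return float(np.mean(np.diff(self.positions)))


def _interp(profile: IntensityProfile, pos: float) -> float:
    return float(np.interp(pos, profile.positions, profile.intensities))


def ttj_btj_ratio(
    profile: IntensityProfile,
    distance_um: float = BTJ_DISTANCE_UM,
    local_max_radius_um: float = 0.0,
) -> tuple[float, bool]:
    """tTJ/bTJ intensity ratio of one profile.

    The bTJ reading is the mean of the intensities at ``anchor - distance``
    and ``anchor + distance`` (linear interpolation to sub-sample positions);
    if only one side lies inside the profile, that side alone is used and the
    result is flagged one-sided. ``local_max_radius_um > 0`` replaces the
    anchor-pixel reading with the local maximum within that radius.

    Returns ``(ratio, one_sided)``.
    """
    x0, x1 = profile.positions[0], profile.positions[-1]
    a = profile.ttj_anchor
    sides = [p for p in (a - distance_um, a + distance_um) if x0 <= p <= x1]
    if not sides:
        raise ValidationError(
            f"anchor is closer than {distance_um} um to both profile ends"
        )
    one_sided = len(sides) == 1
    btj = float(np.mean([_interp(profile, p) for p in sides]))
    if btj <= 0:
        raise ValidationError("bTJ reference intensity must be > 0")
    if local_max_radius_um > 0:
        mask = np.abs(profile.positions - a) <= local_max_radius_um
        ttj = float(np.max(profile.intensities[mask]))
    else:
        ttj = _interp(profile, a)
    ratio = ttj / btj
    if ratio <= 0:
        raise ValidationError("intensity ratio must be > 0")
    return ratio, one_sided


@dataclass(frozen=True)
class TricellularRatio:
    """Per-subject aggregation of tTJ/bTJ ratios.

    The subject mean is the flat mean over all measurements; the mean of the
    per-section means is also stored since with unbalanced sections (3-7 per
    patient, 3 measurements each) the two differ.
    """

    subject_id: str | None
    ratios: np.ndarray
    section_ids: tuple
    section_means: dict
    subject_mean: float
    section_mean_average: float
    n_measurements: int


def aggregate_subject(
    ratios_by_section: dict[str, list[float]],
    subject_id: str | None = None,
) -> TricellularRatio:
    """Aggregate per-measurement ratios into per-section and subject means."""
    sections = {k: np.asarray(v, dtype=float) for k, v in ratios_by_section.items()}
    sections = {k: v for k, v in sections.items() if v.size}
    if not sections:
        raise ValidationError("no measurements to aggregate")
    if any(np.any(v <= 0) for v in sections.values()):
        raise ValidationError("ratios must be > 0")
    all_ratios = np.concatenate(list(sections.values()))
    section_means = {k: float(v.mean()) for k, v in sections.items()}
    return TricellularRatio(
        subject_id=subject_id,
        ratios=all_ratios,
        section_ids=tuple(sections),
        section_means=section_means,
        subject_mean=float(all_ratios.mean()),
        section_mean_average=float(np.mean(list(section_means.values()))),
        n_measurements=int(all_ratios.size),
    )
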