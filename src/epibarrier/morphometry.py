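"""Crypt morphometry and apoptosis rate.

Transepithelial resistance and flux are normalised to the flat serosal
area of the chamber aperture, but colonic mucosa amplifies its surface by
crypt invaginations. Modelling each crypt as a right circular cylinder
(inner diameter d, length L, n crypts per cm^2 of serosal area) the
mucosal-to-serosal surface ratio is::

    ratio = 1 + n * pi * d * L          (flat bottoms; d, L in cm, n in cm^-2)

the crypt openings removed from the flat reference plane are exactly
compensated by the flat crypt bottoms, leaving the cylindrical wall term.
A hemispherical-bottom variant adds ``n * pi * d^2 / 4``.

The epithelial apoptosis rate is the percentage of apoptotic
(TUNEL-positive) nuclei among all DAPI-positive nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, ValidationError

__all__ = [
    "CryptGeometry",
    "NucleusCounts",
    "surface_ratio",
    "mesh_surface_ratio",
    "apoptosis_rate",
]


@dataclass(frozen=True)
class CryptGeometry:
    """Measured crypt geometry of one specimen (um, um, crypts / cm^2)."""

    inner_diameter_um: float
    crypt_length_um: float
    crypt_density_cm2: float
    specimen_id: str | None = None

    def __post_init__(self):
        if min(self.inner_diameter_um, self.crypt_length_um, self.crypt_density_cm2) <= 0:
            raise ValidationError("all crypt geometry values must be > 0")
        d_cm = self.inner_diameter_um * 1e-4
        if self.crypt_density_cm2 * np.pi * (d_cm / 2.0) ** 2 > 1.0:
            raise GeometryError(
                "crypt openings exceed the serosal reference plane "
                f"(density {self.crypt_density_cm2} cm^-2, diameter "
                f"{self.inner_diameter_um} um)"
            )


def surface_ratio(geom: CryptGeometry, bottom: str = "flat") -> float:
    """Mucosal-to-serosal surface area ratio under the cylindrical crypt model."""
    d = geom.inner_diameter_um * 1e-4  # cm
    length = geom.crypt_length_um * 1e-4
    n = geom.crypt_density_cm2
    ratio = 1.0 + n * np.pi * d * length
    if bottom == "flat":
        return float(ratio)
    if bottom == "hemisphere":
        # hemisphere area pi d^2 / 2 replaces the flat bottom pi d^2 / 4
        return float(ratio + n * np.pi * d**2 / 4.0)
    raise ValidationError(f"unknown bottom shape {bottom!r}; use 'flat' or 'hemisphere'")


def mesh_surface_ratio(
    geom: CryptGeometry, n_theta: int = 256, n_z: int = 64, bottom: str = "flat"
) -> float:
    """Brute-force cross-check: triangulated-mesh area of the crypt surface.

    Builds an explicit triangle mesh of one crypt (cylindrical wall from
    stacked rings of ``n_theta`` segments, plus a fan-triangulated bottom)
    and sums the triangle areas. Discretization error is O(1/n_theta^2);
    independent of the closed-form in :func:`surface_ratio`.
    """
    d = geom.inner_diameter_um * 1e-4
    length = geom.crypt_length_um * 1e-4
    r = d / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    z = np.linspace(0.0, length, n_z + 1)

    def tri_area(p, q, s):
        return 0.5 * np.linalg.norm(np.cross(q - p, s - p), axis=-1)

    # wall rings
    tt, zz = np.meshgrid(theta, z)
    verts = np.stack([r * np.cos(tt), r * np.sin(tt), zz], axis=-1)
    a = verts[:-1, :-1]
    b = verts[:-1, 1:]
    c = verts[1:, :-1]
    e = verts[1:, 1:]
    wall = float(np.sum(tri_area(a, b, c)) + np.sum(tri_area(b, e, c)))

    if bottom == "flat":
        center = np.array([0.0, 0.0, 0.0])
        ring = np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)], axis=-1)
        bottom_area = float(np.sum(tri_area(ring[:-1], ring[1:], center)))
    elif bottom == "hemisphere":
        phi = np.linspace(0.0, np.pi / 2.0, n_z + 1)
        pp, tt2 = np.meshgrid(phi, theta, indexing="ij")
        hv = np.stack(
            [r * np.cos(pp) * np.cos(tt2), r * np.cos(pp) * np.sin(tt2), -r * np.sin(pp)],
            axis=-1,
        )
        a, b, c, e = hv[:-1, :-1], hv[:-1, 1:], hv[1:, :-1], hv[1:, 1:]
        bottom_area = float(np.sum(tri_area(a, b, c)) + np.sum(tri_area(b, e, c)))
    else:
        raise ValidationError(f"unknown bottom shape {bottom!r}")

    opening = float(np.sum(tri_area(
        np.stack([r * np.cos(theta[:-1]), r * np.sin(theta[:-1]), np.zeros(n_theta)], axis=-1),
        np.stack([r * np.cos(theta[1:]), r * np.sin(theta[1:]), np.zeros(n_theta)], axis=-1),
        np.array([0.0, 0.0, 0.0]),
    )))
    per_crypt = wall + bottom_area - opening
    return float(1.0 + geom.crypt_density_cm2 * per_crypt)


@dataclass(frozen=True)
class NucleusCounts:
    """TUNEL-positive and total DAPI-positive nucleus counts."""

    apoptotic: int
    total_dapi: int
    specimen_id: str | None = None

    def __post_init__(self):
        if self.total_dapi <= 0:
            raise ValidationError("total DAPI count must be > 0")
        if not 0 <= self.apoptotic <= self.total_dapi:
            raise ValidationError("apoptotic count must lie in [0, total]")


def apoptosis_rate(counts: NucleusCounts) -> float:
    """Apoptosis rate in percent: 100 * apoptotic / total."""
    return 100.0 * counts.apoptotic / counts.total_dapi
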