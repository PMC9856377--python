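"""One-path equivalent-circuit analysis of transepithelial impedance spectra.

The epithelium is modelled as a parallel RC element (epithelial resistance
``R_epi`` and capacitance ``C``) in series with an ohmic subepithelial
resistance ``R_sub``::

    Z(f) = R_sub + R_epi / (1 + j * 2 * pi * f * R_epi * C)

The Nyquist locus of this circuit is a semicircle of diameter ``R_epi``
centred on the real axis: ``Re(Z)`` approaches ``R_sub + R_epi`` (the
transmural resistance ``R_t``) as ``f -> 0`` and ``R_sub`` as ``f -> inf``,
and the apex of ``-Im(Z)`` equals ``R_epi / 2`` at the characteristic
frequency ``f_c = 1 / (2 * pi * R_epi * C)``.

All resistances are area-normalised (Ohm * cm^2), capacitance is F / cm^2.
The sign convention is capacitive, ``Im(Z) <= 0``; Nyquist plots are drawn
with ``-Im(Z)`` on the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateInputError, StateError, ValidationError

__all__ = [
    "DEFAULT_FREQUENCIES",
    "ImpedanceSpectrum",
    "OnePathFit",
    "OnePathModel",
    "one_path_impedance",
    "correct_bath_resistance",
    "fit_one_path",
    "epithelial_resistance",
    "grid_search_one_path",
]

#: Default measurement grid: 48 log-spaced frequencies from 1.3 Hz to 65 kHz.
DEFAULT_FREQUENCIES: np.ndarray = np.logspace(np.log10(1.3), np.log10(65e3), 48)


def one_path_impedance(freqs, r_sub: float, r_epi: float, cap: float) -> np.ndarray:
    """Complex impedance of the one-path RC circuit at frequencies ``freqs`` (Hz)."""
    f = np.asarray(freqs, dtype=float)
    return r_sub + r_epi / (1.0 + 1j * 2.0 * np.pi * f * r_epi * cap)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """A measured (or simulated) complex impedance spectrum of one specimen.

    Parameters
    ----------
    freqs : array of float
        Frequencies in Hz, strictly positive and sorted ascending.
    z : array of complex
        Complex impedance per frequency, Ohm * cm^2.
    bath_corrected : bool
        Whether the bathing-solution series resistance has been subtracted.
    specimen_id : str, optional
    """

    freqs: np.ndarray
    z: np.ndarray
    bath_corrected: bool = False
    specimen_id: str | None = None

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if freqs.size == 0:
            raise ValidationError("spectrum has no frequencies")
        if freqs.size != z.size:
            raise ValidationError("freqs and z differ in length")
        if np.any(freqs <= 0):
            raise ValidationError("frequencies must be strictly positive")
        if np.any(np.diff(freqs) <= 0):
            raise ValidationError("frequencies must be sorted strictly ascending")
        if not np.all(np.isfinite(z.view(float))):
            raise ValidationError("impedance values must be finite")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "z", z)

    @property
    def n_freqs(self) -> int:
        return self.freqs.size


def correct_bath_resistance(spec: ImpedanceSpectrum, r_bath: float) -> ImpedanceSpectrum:
    """Subtract the bathing-solution series resistance from the real part.

    Raises :class:`StateError` if the spectrum is already corrected, and
    :class:`ValidationError` if ``r_bath`` exceeds the smallest real part
    (which would imply a negative tissue resistance).
    """
    if spec.bath_corrected:
        raise StateError("spectrum is already bath-corrected")
    if r_bath < 0:
        raise ValidationError("r_bath must be >= 0")
    if r_bath > float(np.min(spec.z.real)):
        raise ValidationError(
            f"r_bath={r_bath} exceeds the minimum Re(Z)={np.min(spec.z.real):.4g}; "
            "correction would imply negative resistance"
        )
    return replace(spec, z=spec.z - r_bath, bath_corrected=True)


def epithelial_resistance(r_t: float, r_sub: float) -> float:
    """Epithelial resistance ``R_epi = R_t - R_sub`` (Ohm * cm^2)."""
    if r_sub < 0 or r_t < r_sub:
        raise ValidationError(f"require r_t >= r_sub >= 0, got r_t={r_t}, r_sub={r_sub}")
    return r_t - r_sub


@dataclass
class OnePathFit:
    """Results of a one-path circuit fit.

    ``r_t`` is stored as the exact sum ``r_sub + r_epi``.
    """

    r_sub: float
    r_epi: float
    cap: float
    residual_norm: float
    converged: bool
    method: str = "ls"
    nfev: int = 0
    spectrum: ImpedanceSpectrum | None = field(default=None, repr=False)

    @property
    def r_t(self) -> float:
        return self.r_sub + self.r_epi

    @property
    def params(self) -> np.ndarray:
        return np.array([self.r_sub, self.r_epi, self.cap])

    @property
    def characteristic_frequency(self) -> float:
        """Apex frequency of the Nyquist semicircle, Hz."""
        return 1.0 / (2.0 * np.pi * self.r_epi * self.cap)

    def predict(self, freqs=None) -> np.ndarray:
        if freqs is None:
            if self.spectrum is None:
                raise ValidationError("no frequencies given and no attached spectrum")
            freqs = self.spectrum.freqs
        return one_path_impedance(freqs, self.r_sub, self.r_epi, self.cap)

    def summary(self) -> str:
        lines = [
            "One-path equivalent-circuit fit",
            "-" * 39,
            f"method            {self.method}",
            f"converged         {self.converged}",
            f"R_t   (Ohm cm^2)  {self.r_t:.4g}",
            f"R_sub (Ohm cm^2)  {self.r_sub:.4g}",
            f"R_epi (Ohm cm^2)  {self.r_epi:.4g}",
            f"C     (uF cm^-2)  {self.cap * 1e6:.4g}",
            f"f_c   (Hz)        {self.characteristic_frequency:.4g}",
            f"residual norm     {self.residual_norm:.4g}",
        ]
        return "\n".join(lines)

    def plot_nyquist(self, ax=None, n_curve: int = 300):
        """Nyquist diagram (-Im(Z) vs Re(Z)): data points and fitted semicircle."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.spectrum is not None:
            ax.plot(self.spectrum.z.real, -self.spectrum.z.imag, "o", ms=4, label="data")
            f = np.logspace(
                np.log10(self.spectrum.freqs[0]), np.log10(self.spectrum.freqs[-1]), n_curve
            )
        else:
            fc = self.characteristic_frequency
            f = np.logspace(np.log10(fc) - 3, np.log10(fc) + 3, n_curve)
        zf = self.predict(f)
        ax.plot(zf.real, -zf.imag, "-", label="one-path fit")
        ax.set_xlabel(r"Re(Z) ($\Omega\,cm^2$)")
        ax.set_ylabel(r"$-$Im(Z) ($\Omega\,cm^2$)")
        ax.set_aspect("equal", adjustable="datalim")
        ax.legend()
        return ax


def _check_fittable(spec: ImpedanceSpectrum) -> None:
    if spec.n_freqs < 8:
        raise ValidationError(f"need >= 8 frequencies to fit, got {spec.n_freqs}")
    if np.log10(spec.freqs[-1] / spec.freqs[0]) < 2.0:
        raise ValidationError("frequency grid must span at least two decades")
    # No reactive component: the RC arc is unidentifiable.
    span = np.ptp(spec.z.real)
    scale = max(span, float(np.max(np.abs(spec.z.real))))
    if float(np.max(-spec.z.imag)) < 1e-9 * max(scale, 1.0):
        raise DegenerateInputError(
            "spectrum has no reactive component (all Im(Z) ~ 0); r_epi ~ 0 "
            "and the circuit parameters are not identifiable"
        )


def _default_init(spec: ImpedanceSpectrum) -> np.ndarray:
    """Data-driven start values: end intercepts + apex frequency."""
    r_sub0 = max(float(spec.z.real[-1]), 1e-9)
    r_t0 = float(spec.z.real[0])
    r_epi0 = max(r_t0 - r_sub0, 1e-6 * max(r_t0, 1.0))
    i_apex = int(np.argmax(-spec.z.imag))
    f_apex = float(spec.freqs[i_apex])
    cap0 = 1.0 / (2.0 * np.pi * f_apex * r_epi0)
    return np.array([r_sub0, r_epi0, cap0])


class OnePathModel:
    """Least-squares estimator of the one-path circuit from an impedance spectrum.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        Bath-corrected spectrum (or pass ``r_bath`` to correct here).
    r_bath : float, optional
        Bathing-solution resistance to subtract before fitting.

    Examples
    --------
    >>> z = one_path_impedance(DEFAULT_FREQUENCIES, 10, 90, 3e-6)
    >>> fit = OnePathModel(ImpedanceSpectrum(DEFAULT_FREQUENCIES, z)).fit()
    >>> round(fit.r_epi, 6)
    90.0
    """

    def __init__(self, spectrum: ImpedanceSpectrum, r_bath: float | None = None):
        if r_bath is not None and r_bath > 0:
            spectrum = correct_bath_resistance(spectrum, r_bath)
        self.spectrum = spectrum

    def fit(self, init: Sequence[float] | None = None) -> OnePathFit:
        """Complex nonlinear least squares on (Re, Im) jointly, unweighted."""
        spec = self.spectrum
        _check_fittable(spec)
        x0 = np.asarray(init, dtype=float) if init is not None else _default_init(spec)
        if np.any(x0 <= 0):
            raise ValidationError("initial values must be strictly positive")

        f = spec.freqs
        zdat = spec.z

        def resid(x):
            zm = one_path_impedance(f, *x)
            d = zm - zdat
            return np.concatenate([d.real, d.imag])

        sol = least_squares(
            resid,
            x0,
            bounds=(np.full(3, 1e-15), np.full(3, np.inf)),
            x_scale=x0,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        converged = bool(sol.status > 0)
        r_sub, r_epi, cap = sol.x
        return OnePathFit(
            r_sub=float(r_sub),
            r_epi=float(r_epi),
            cap=float(cap),
            residual_norm=float(np.linalg.norm(sol.fun)),
            converged=converged,
            method="ls",
            nfev=int(sol.nfev),
            spectrum=spec,
        )

    def fit_intercept(self, n_end: int = 3) -> OnePathFit:
        """Frequency-end intercept reading.

        ``R_t`` is the mean real part over the ``n_end`` lowest frequencies and
        ``R_sub`` the mean over the ``n_end`` highest; the capacitance comes
        from the apex frequency of ``-Im(Z)``. Uses the ends of the grid only,
        so it is noisier than :meth:`fit` but assumption-light.
        """
        spec = self.spectrum
        _check_fittable(spec)
        if n_end < 1 or 2 * n_end > spec.n_freqs:
            raise ValidationError("n_end out of range")
        r_t = float(np.mean(spec.z.real[:n_end]))
        r_sub = float(np.mean(spec.z.real[-n_end:]))
        r_epi = epithelial_resistance(r_t, r_sub)
        i_apex = int(np.argmax(-spec.z.imag))
        cap = 1.0 / (2.0 * np.pi * float(spec.freqs[i_apex]) * max(r_epi, 1e-15))
        resid = one_path_impedance(spec.freqs, r_sub, r_epi, cap) - spec.z
        return OnePathFit(
            r_sub=r_sub,
            r_epi=r_epi,
            cap=cap,
            residual_norm=float(np.linalg.norm(np.concatenate([resid.real, resid.imag]))),
            converged=True,
            method="intercept",
            spectrum=spec,
        )


def fit_one_path(
    spec: ImpedanceSpectrum,
    init: Sequence[float] | None = None,
    method: str = "fit",
) -> OnePathFit:
    """Convenience wrapper: fit the one-path circuit to ``spec``."""
    model = OnePathModel(spec)
    if method == "fit":
        return model.fit(init=init)
    if method == "intercept":
        return model.fit_intercept()
    raise ValidationError(f"unknown method {method!r}; use 'fit' or 'intercept'")


def grid_search_one_path(
    spec: ImpedanceSpectrum,
    n_grid: int = 15,
    span: float = 10.0,
) -> OnePathFit:
    """Brute-force coarse-grid + refinement search for the least-squares optimum.

    Independent cross-check for :meth:`OnePathModel.fit`: evaluates the sum of
    squared (Re, Im) residuals on a log-spaced lattice around data-derived
    start values and polishes the best lattice point with derivative-free
    Nelder-Mead in log-parameter space. Slow by construction; intended for
    validation, not routine use.
    """
    from scipy.optimize import minimize

    _check_fittable(spec)
    x0 = _default_init(spec)
    centers = np.log10(x0)
    half = np.log10(span) / 2.0  # half-range per axis, decades
    f = spec.freqs[np.newaxis, :]
    axes = [np.linspace(c - half, c + half, n_grid) for c in centers]
    rs, re, cc = np.meshgrid(*axes, indexing="ij")
    p = 10.0 ** np.stack([rs.ravel(), re.ravel(), cc.ravel()], axis=1)
    zm = p[:, 0:1] + p[:, 1:2] / (1.0 + 1j * 2.0 * np.pi * f * p[:, 1:2] * p[:, 2:3])
    sse = np.sum(np.abs(zm - spec.z[np.newaxis, :]) ** 2, axis=1)
    k = int(np.argmin(sse))

    def objective(logx):
        zmod = one_path_impedance(spec.freqs, *(10.0**logx))
        return float(np.sum(np.abs(zmod - spec.z) ** 2))

    sol = minimize(
        objective,
        np.log10(p[k]),
        method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-300, "maxiter": 20000, "maxfev": 20000},
    )
    r_sub, r_epi, cap = 10.0**sol.x
    return OnePathFit(
        r_sub=float(r_sub),
        r_epi=float(r_epi),
        cap=float(cap),
        residual_norm=float(np.sqrt(sol.fun)),
        converged=True,
        method="grid",
        spectrum=spec,
    )
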