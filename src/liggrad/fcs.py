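"""Fluorescence correlation spectroscopy: model, fitting and calibration.

The autocorrelation of intensity fluctuations in a confocal volume is
modelled with a single free 3-D diffusion component and a triplet-blinking
term:

    G(t) = 1 + (1/N) * [1 - T(1 - exp(-t/tau_triplet))] / (1 - T)
               * (1 + t/tau_D)^-1 * (1 + t/(kappa^2 tau_D))^-1/2

where ``N`` is the mean particle number in the detection volume, ``T`` the
triplet fraction, ``tau_triplet`` the triplet correlation time, ``tau_D``
the diffusion correlation time and ``kappa`` the axial/lateral beam-shape
ratio.  The detection volume is the 3-D Gaussian
``V_C = pi^{3/2} * kappa * omega^3`` and the diffusion coefficient follows
from ``D = omega^2 / (4 tau_D)``.  Beam-waist calibration fits a curve of a
reference dye of known D (e.g. Alexa Fluor 546, 341 μm²/s at 25 °C) and
inverts that relation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .units import AVOGADRO, DEFAULT_CONFOCAL_VOLUME_UM3

__all__ = [
    "AcfParams",
    "AutocorrelationCurve",
    "BeamGeometry",
    "LifetimeComponents",
    "AcfFitResult",
    "FitFailure",
    "acf_model",
    "fit_acf",
    "calibrate_beam",
    "n_to_molar",
    "n_to_per_um3",
    "diffusion_from_tau",
    "intensity_weighted_lifetime",
    "average_curves",
]

DEFAULT_KAPPA = 5.0


class FitFailure(RuntimeError):
    """Raised when a least-squares fit cannot produce a meaningful result."""


@dataclass(frozen=True)
class AcfParams:
    """Parameters of the triplet + single-diffusion autocorrelation model.

    Attributes
    ----------
    N : float
        Mean number of particles in the confocal volume, > 0.
    T : float
        Triplet fraction, in [0, 1).
    tau_triplet : float
        Triplet correlation time in seconds, > 0.
    tau_D : float
        Diffusion correlation time in seconds, > 0.
    kappa : float
        Beam shape parameter (axial/lateral), > 1.
    """

    N: float
    T: float
    tau_triplet: float
    tau_D: float
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        vals = (self.N, self.T, self.tau_triplet, self.tau_D, self.kappa)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all ACF parameters must be finite")
        if self.N <= 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if not (0.0 <= self.T < 1.0):
            raise ValueError(f"T must be in [0, 1), got {self.T}")
        if self.tau_triplet <= 0:
            raise ValueError(f"tau_triplet must be > 0, got {self.tau_triplet}")
        if self.tau_D <= 0:
            raise ValueError(f"tau_D must be > 0, got {self.tau_D}")
        if self.kappa <= 1:
            raise ValueError(f"kappa must be > 1, got {self.kappa}")
        if self.tau_triplet >= self.tau_D:
            warnings.warn(
                "tau_triplet >= tau_D: triplet and diffusion decays overlap, "
                "fit is unlikely to be physically meaningful",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AutocorrelationCurve:
    """An FCS measurement: lag times (s) and autocorrelation values G(t)."""

    lags: np.ndarray
    values: np.ndarray
    n_runs: int = 1

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.ndim != 1 or lags.shape != values.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if lags.size == 0:
            raise ValueError("curve is empty")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("G values must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BeamGeometry:
    """Calibrated confocal detection geometry.

    ``confocal_volume`` is always the 3-D Gaussian volume
    pi^{3/2} * kappa * omega^3 (μm³).
    """

    omega: float
    kappa: float = DEFAULT_KAPPA
    confocal_volume: float = field(init=False)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if self.kappa <= 1:
            raise ValueError(f"kappa must be > 1, got {self.kappa}")
        object.__setattr__(
            self,
            "confocal_volume",
            math.pi ** 1.5 * self.kappa * self.omega**3,
        )


@dataclass(frozen=True)
class LifetimeComponents:
    """Amplitudes and lifetimes (ns) of a multi-exponential decay."""

    amplitudes: np.ndarray
    lifetimes: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        taus = np.asarray(self.lifetimes, dtype=float)
        if amps.shape != taus.shape or amps.ndim != 1 or amps.size == 0:
            raise ValueError("amplitudes and lifetimes must be equal-length 1-D")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        if np.any(taus <= 0):
            raise ValueError("lifetimes must be positive")
        if not np.any(amps > 0):
            raise ValueError("at least one amplitude must be positive")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "lifetimes", taus)


@dataclass(frozen=True)
class AcfFitResult:
    """Outcome of an ACF fit: parameters, uncertainties, diagnostics."""

    params: AcfParams
    stderr: dict[str, float | None]
    residual_norm: float
    converged: bool
    n_points: int


def acf_model(lags, params: AcfParams) -> np.ndarray:
    """Evaluate the triplet + single 3-D diffusion autocorrelation model.

    Parameters
    ----------
    lags : array-like
        Lag times in seconds, >= 0.
    params : AcfParams
        Model parameters (validated on construction).

    Returns
    -------
    numpy.ndarray
        G(t) evaluated elementwise; G(0) = 1 + 1/N for T = 0 and
        G -> 1 for t >> tau_D.
    """
    t = np.asarray(lags, dtype=float)
    if np.any(t < 0):
        raise ValueError("lags must be nonnegative")
    return _acf_eval(t, params.N, params.T, params.tau_triplet, params.tau_D, params.kappa)


def _acf_eval(t, N, T, tau_triplet, tau_D, kappa):
    triplet = (1.0 - T * (1.0 - np.exp(-t / tau_triplet))) / (1.0 - T)
    diff = 1.0 / ((1.0 + t / tau_D) * np.sqrt(1.0 + t / (kappa**2 * tau_D)))
    return 1.0 + triplet * diff / N


def _initial_guess(curve: AutocorrelationCurve, kappa: float) -> AcfParams:
    g0 = curve.values[0] - 1.0
    if g0 <= 0:
        raise FitFailure("no correlation amplitude: G(first lag) <= 1, nothing to fit")
    amp = curve.values - 1.0
    below = np.nonzero(amp <= 0.5 * g0)[0]
    tau_D = curve.lags[below[0]] if below.size else curve.lags[-1]
    return AcfParams(
        N=1.0 / g0, T=0.1, tau_triplet=min(5e-6, tau_D / 10), tau_D=tau_D, kappa=kappa
    )


def fit_acf(
    curve: AutocorrelationCurve,
    init: AcfParams | None = None,
    fix_kappa: bool = True,
    kappa: float = DEFAULT_KAPPA,
) -> AcfFitResult:
    """Fit the autocorrelation model to a measured curve.

    Unweighted least squares.  ``kappa`` is fixed by default because it is
    only weakly identifiable jointly with ``tau_D``; the triplet fraction is
    bounded to [0, 0.5] as a fitting constraint (to prevent exchange with
    the diffusion amplitude), not as physics.

    Raises
    ------
    FitFailure
        If the curve carries no decay (G == 1) or the minimizer fails.
    """
    if curve.lags.size < 10 or curve.lags[-1] / curve.lags[0] < 1e3:
        warnings.warn(
            "fewer than 10 lag points or span under 3 decades: "
            "fit may be poorly constrained",
            stacklevel=2,
        )
    if init is None:
        init = _initial_guess(curve, kappa)

    p = Parameters()
    p.add("N", value=init.N, min=1e-12)
    p.add("T", value=min(max(init.T, 0.0), 0.5), min=0.0, max=0.5)
    p.add("tau_triplet", value=init.tau_triplet, min=1e-12)
    p.add("tau_D", value=init.tau_D, min=1e-12)
    p.add("kappa", value=init.kappa if fix_kappa else kappa, vary=not fix_kappa, min=1.0 + 1e-9)

    def residual(pars):
        v = pars.valuesdict()
        return (
            _acf_eval(curve.lags, v["N"], v["T"], v["tau_triplet"], v["tau_D"], v["kappa"])
            - curve.values
        )

    out = minimize(residual, p, method="leastsq", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    if not out.success:
        raise FitFailure(f"ACF fit did not converge: {out.message}")
    v = out.params.valuesdict()
    fitted = AcfParams(
        N=v["N"], T=v["T"], tau_triplet=v["tau_triplet"], tau_D=v["tau_D"], kappa=v["kappa"]
    )
    stderr = {name: out.params[name].stderr for name in out.params}
    return AcfFitResult(
        params=fitted,
        stderr=stderr,
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=True,
        n_points=curve.lags.size,
    )


def calibrate_beam(
    curve_ref: AutocorrelationCurve,
    D_ref: float,
    kappa: float = DEFAULT_KAPPA,
) -> BeamGeometry:
    """Calibrate the beam waist from a reference-dye curve of known D.

    Fits the autocorrelation model for ``tau_D`` (kappa fixed) and inverts
    D = omega²/(4 tau_D) to obtain the lateral e⁻² radius omega.
    """
    if D_ref <= 0:
        raise ValueError(f"D_ref must be > 0, got {D_ref}")
    fit = fit_acf(curve_ref, fix_kappa=True, kappa=kappa)
    omega = math.sqrt(4.0 * D_ref * fit.params.tau_D)
    return BeamGeometry(omega=omega, kappa=kappa)


def n_to_molar(N: float, volume: float | BeamGeometry = DEFAULT_CONFOCAL_VOLUME_UM3) -> float:
    """Convert particles per confocal volume to a concentration in nM.

    ``volume`` may be a volume in μm³ or a calibrated :class:`BeamGeometry`.
    """
    V = volume.confocal_volume if isinstance(volume, BeamGeometry) else float(volume)
    if V <= 0:
        raise ValueError(f"confocal volume must be > 0, got {V}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    # N / (V_C [μm³] · N_A [1/mol]) in mol/μm³ -> ×1e15 L/μm³ ×1e9 nM/M
    return N / (V * AVOGADRO) * 1e15 * 1e9


def n_to_per_um3(N: float, volume: float | BeamGeometry = DEFAULT_CONFOCAL_VOLUME_UM3) -> float:
    """Convert particles per confocal volume to particles/μm³."""
    V = volume.confocal_volume if isinstance(volume, BeamGeometry) else float(volume)
    if V <= 0:
        raise ValueError(f"confocal volume must be > 0, got {V}")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    return N / V


def diffusion_from_tau(tau_D: float, omega: float) -> float:
    """Diffusion coefficient (μm²/s) from dwell time and beam waist: ω²/(4τ_D)."""
    if tau_D <= 0 or omega <= 0:
        raise ValueError("tau_D and omega must be > 0")
    return omega**2 / (4.0 * tau_D)


def intensity_weighted_lifetime(components: LifetimeComponents) -> float:
    """Intensity-weighted mean lifetime: Σ A_i τ_i² / Σ A_i τ_i (ns).

    Invariant to a common rescaling of all amplitudes.
    """
    a, tau = components.amplitudes, components.lifetimes
    return float(np.sum(a * tau**2) / np.sum(a * tau))


def average_curves(curves: list[AutocorrelationCurve]) -> AutocorrelationCurve:
    """Average several runs recorded on an identical lag grid."""
    if not curves:
        raise ValueError("no curves to average")
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves must share the same lag grid")
    values = np.mean([c.values for c in curves], axis=0)
    return AutocorrelationCurve(lags=lags, values=values, n_runs=sum(c.n_runs for c in curves))
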