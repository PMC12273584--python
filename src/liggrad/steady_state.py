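"""Closed-form steady-state concentration profiles around a spherical cell.

Two mechanisms that shape the ligand concentration outside a cell of
radius ``a`` (spherical symmetry, radial coordinate ``r`` from the cell
centre) admit closed forms:

* **Fick steady state, constant D.**  ``D ∇²c = 0`` gives
  ``c(r) = a (c_m − c_0)/r + c_0`` with membrane concentration ``c_m`` and
  bulk ``c_0``; the defining invariant is ``r² dc/dr = K1`` (constant).
  Sustaining such a gradient requires a membrane flux
  ``J = D (c_m − c_0)/a``.

* **Fokker–Planck steady state, spatially varying D(r).**  ``∇²(D c) = 0``
  gives ``r² d(Dc)/dr = K3`` and the closed form
  ``c(r) = (K4 r − K3) / (D(r) r)``, with K3, K4 fixed by two Dirichlet
  boundary conditions.  A local minimum of diffusivity (modelled as a
  parabola ``D(r) = p1 (r − p2)² + p3``) then produces an interior
  concentration maximum — hindered diffusion concentrates ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .units import CONC_UNITS, DIFFUSIVITY_UNIT

__all__ = [
    "RadialProfile",
    "FickSolution",
    "DiffusivityModel",
    "DiffusivityFit",
    "FokkerPlanckSolution",
    "DEFAULT_CELL_RADIUS",
    "fick_steady_profile",
    "membrane_flux",
    "fit_diffusivity_model",
    "fokker_planck_steady",
    "per_confocal_to_per_um3",
]

DEFAULT_CELL_RADIUS = 10.0  # μm

#: Integration constants printed in the original analysis for the default
#: diffusivity model with c(13)=c(35)=2; kept as reference metadata only —
#: constants are always recomputed from the supplied boundary conditions.
REFERENCE_FP_CONSTANTS = {"K3": 291.2, "K4": 275.56}


@dataclass(frozen=True)
class RadialProfile:
    """A quantity sampled along the radial coordinate.

    ``radii`` are distances from the cell centre (μm); ``distances``
    (from the membrane, d = r − a) are derived.  ``unit`` is one of
    ``per_confocal``, ``per_um3``, ``nM`` for concentrations or
    ``um2_per_s`` for diffusivities.
    """

    radii: np.ndarray
    values: np.ndarray
    unit: str
    a: float = DEFAULT_CELL_RADIUS

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if r.shape != v.shape or r.ndim != 1:
            raise ValueError("radii and values must be 1-D arrays of equal length")
        if self.unit not in CONC_UNITS + (DIFFUSIVITY_UNIT,):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.a <= 0:
            raise ValueError("cell radius must be > 0")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "values", v)

    @property
    def distances(self) -> np.ndarray:
        """Distance from the membrane, d = r − a (μm)."""
        return self.radii - self.a


@dataclass(frozen=True)
class FickSolution:
    """Steady-state Fick profile c(r) = a(c_m − c_0)/r + c_0.

    ``K1 = a (c_0 − c_m)`` and ``K2 = c_0`` are the integration constants
    of the general solution c = −K1/r + K2.
    """

    a: float
    c_m: float
    c_0: float
    unit: str = "per_um3"
    K1: float = field(init=False)
    K2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("cell radius must be > 0")
        if self.c_m < 0 or self.c_0 < 0:
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "K1", self.a * (self.c_0 - self.c_m))
        object.__setattr__(self, "K2", self.c_0)

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if np.any(r < self.a):
            raise ValueError("radii must be >= cell radius")
        return self.a * (self.c_m - self.c_0) / r + self.c_0


@dataclass(frozen=True)
class DiffusivityModel:
    """Parabolic diffusivity profile D(r) = p1 (r − p2)² + p3.

    ``p2`` (μm) locates the diffusivity minimum, ``p3`` (μm²/s) its depth;
    ``p1`` (1/s) sets the curvature.  D(r) >= p3 > 0 everywhere.
    """

    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.p1, self.p2, self.p3)):
            raise ValueError("diffusivity parameters must be finite")
        if self.p1 < 0:
            raise ValueError("p1 must be >= 0")
        if self.p3 <= 0:
            raise ValueError("p3 must be > 0")

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.p1 * (r - self.p2) ** 2 + self.p3


#: Diffusivity dip fitted to the measured D(r) of ErbB2-expressing cells.
DEFAULT_DIFFUSIVITY_MODEL = DiffusivityModel(p1=0.32, p2=23.47, p3=91.32)


@dataclass(frozen=True)
class DiffusivityFit:
    """Result of fitting the parabolic diffusivity model."""

    model: DiffusivityModel
    p2_identifiable: bool
    residual_norm: float


@dataclass(frozen=True)
class FokkerPlanckSolution:
    """Closed-form steady state c(r) = (K4 r − K3)/(D(r) r)."""

    model: DiffusivityModel
    K3: float
    K4: float
    bc: tuple[tuple[float, float], tuple[float, float]]

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (self.K4 * r - self.K3) / (self.model(r) * r)


def fick_steady_profile(
    a: float, c_m: float, c_0: float, radii, unit: str = "per_um3"
) -> tuple[FickSolution, RadialProfile]:
    """Evaluate the constant-D steady-state profile on a radial grid.

    Returns the solution object (carrying K1, K2) and the sampled profile.
    """
    sol = FickSolution(a=a, c_m=c_m, c_0=c_0, unit=unit)
    radii = np.asarray(radii, dtype=float)
    return sol, RadialProfile(radii=radii, values=sol(radii), unit=unit, a=a)


def membrane_flux(a: float, c_m: float, c_0: float, D: float) -> float:
    """Membrane flux J = D (c_m − c_0)/a sustaining a Fick gradient.

    Units follow the inputs: with concentrations in particles/μm³, D in
    μm²/s and a in μm, J is particles/(μm²·s).  J > 0 means ligand must be
    released outward at the membrane to maintain c_m > c_0.
    """
    if a <= 0:
        raise ValueError("length scale a must be > 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    if c_m < 0 or c_0 < 0:
        raise ValueError("concentrations must be >= 0")
    return D * (c_m - c_0) / a


def fit_diffusivity_model(radii, D_samples) -> DiffusivityFit:
    """Least-squares fit of D(r) = p1 (r − p2)² + p3 to measured samples.

    The parabola is fitted in original space (quadratic polynomial solve,
    refined with a p3 > 0 bound when needed).  With p1 ≈ 0 the minimum
    location p2 is unidentifiable and flagged as such.
    """
    r = np.asarray(radii, dtype=float)
    D = np.asarray(D_samples, dtype=float)
    if r.shape != D.shape or r.ndim != 1:
        raise ValueError("radii and D_samples must be 1-D of equal length")
    if r.size < 4:
        raise ValueError("need at least 4 samples")
    if np.unique(r).size < 3:
        raise ValueError("degenerate design: need at least 3 distinct radii")

    # quadratic solve: D = α r² + β r + γ with α = p1, β = −2 p1 p2
    alpha, beta, gamma = np.polyfit(r, D, 2)
    scale = np.mean(np.abs(D)) / max(np.ptp(r) ** 2, 1e-300)
    if alpha <= max(1e-10 * scale, 0.0):
        p3 = float(np.mean(D))
        model = DiffusivityModel(p1=0.0, p2=float(np.mean(r)), p3=p3)
        resid = float(np.linalg.norm(model(r) - D))
        return DiffusivityFit(model=model, p2_identifiable=False, residual_norm=resid)

    p1, p2 = alpha, -beta / (2 * alpha)
    p3 = gamma - beta**2 / (4 * alpha)
    if p3 <= 0:
        # refit with the positivity bound active
        pars = Parameters()
        pars.add("p1", value=max(p1, 1e-12), min=0.0)
        pars.add("p2", value=p2)
        pars.add("p3", value=max(p3, 1e-6), min=1e-12)
        out = minimize(
            lambda p: p["p1"] * (r - p["p2"]) ** 2 + p["p3"] - D, pars, method="leastsq"
        )
        v = out.params.valuesdict()
        p1, p2, p3 = v["p1"], v["p2"], v["p3"]
    model = DiffusivityModel(p1=float(p1), p2=float(p2), p3=float(p3))
    resid = float(np.linalg.norm(model(r) - D))
    return DiffusivityFit(model=model, p2_identifiable=True, residual_norm=resid)


def fokker_planck_steady(
    model: DiffusivityModel,
    bc: tuple[tuple[float, float], tuple[float, float]],
    radii=None,
    unit: str = "per_confocal",
    a: float = DEFAULT_CELL_RADIUS,
) -> tuple[FokkerPlanckSolution, RadialProfile | None]:
    """Steady state of ∇²(Dc) = 0 under two Dirichlet boundary conditions.

    Solves the 2×2 linear system ``D(r_i) c_i r_i = K4 r_i − K3`` for the
    integration constants and evaluates the closed form on ``radii`` (if
    given).  With constant D and equal boundary concentrations the profile
    is uniform; a diffusivity dip between the boundaries produces an
    interior concentration maximum.
    """
    (r1, c1), (r2, c2) = bc
    if r1 == r2:
        raise ValueError("boundary radii must be distinct")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("boundary radii must be positive")
    # [−1  r1][K3]   [D(r1) c1 r1]
    # [−1  r2][K4] = [D(r2) c2 r2]
    A = np.array([[-1.0, r1], [-1.0, r2]])
    b = np.array([float(model(r1)) * c1 * r1, float(model(r2)) * c2 * r2])
    K3, K4 = np.linalg.solve(A, b)
    sol = FokkerPlanckSolution(model=model, K3=float(K3), K4=float(K4), bc=bc)
    profile = None
    if radii is not None:
        radii = np.asarray(radii, dtype=float)
        profile = RadialProfile(radii=radii, values=sol(radii), unit=unit, a=a)
    return sol, profile


def per_confocal_to_per_um3(N: float, V_C: float) -> float:
    """Convert particles per confocal volume to particles/μm³ (N / V_C)."""
    if V_C <= 0:
        raise ValueError(f"confocal volume must be > 0, got {V_C}")
    if N < 0:
        raise ValueError("N must be >= 0")
    return N / V_C
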