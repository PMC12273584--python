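"""Seeded generators for every input kind the analysis modules consume.

Three measurement types are emulated, with the statistical structure of
the experimental system (micrometre-resolved FCS above an adherent cell):

* **autocorrelation curves** — the triplet + single 3-D diffusion forward
  model on a 200-point quasi-logarithmic lag grid (300 ns – 1 s), with
  additive Gaussian noise;
* **radial concentration/diffusivity profiles** — a membrane-proximal
  concentration peak (default 3× bulk, exponential decay over 5 μm,
  *uncorrelated* with diffusivity, emulating a membrane ligand source) plus
  a membrane-distal peak that is never drawn independently: it is derived
  from a parabolic diffusivity dip through the Fokker–Planck steady state,
  so the concentration–diffusivity anticorrelation is structural;
* **titration tables** — Hill saturation read out against bulk
  concentration through a bulk→membrane power mapping (identity mapping
  for vesicle-like controls without membrane turnover), with multiplicative
  log-normal noise.

A photon-arrival histogram generator for multi-exponential lifetime decays
(with a paired biexponential fitter) supports the molecular-rotor lifetime
workflow.

Every generator is a pure function of its spec and seed, and converges to
its noiseless forward model as σ → 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

from .binding import HillModel, PowerMapping, hill_saturation, power_map
from .fcs import AcfParams, AutocorrelationCurve, LifetimeComponents, acf_model
from .steady_state import (
    DEFAULT_CELL_RADIUS,
    DEFAULT_DIFFUSIVITY_MODEL,
    DiffusivityModel,
    RadialProfile,
    fokker_planck_steady,
)

__all__ = [
    "NoiseSpec",
    "ProfileSpec",
    "default_lag_grid",
    "default_profile_distances",
    "gen_acf_curves",
    "gen_radial_profiles",
    "profile_forward_model",
    "gen_titration",
    "gen_decay_histogram",
    "fit_biexponential",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: additive Gaussian or multiplicative log-normal, scale σ."""

    kind: str = "additive-gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive-gaussian", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return values.copy()
        if self.kind == "additive-gaussian":
            return values + rng.normal(0.0, self.sigma, size=values.shape)
        return values * rng.lognormal(0.0, self.sigma, size=values.shape)


def default_lag_grid(n: int = 200, t_min: float = 3e-7, t_max: float = 1.0) -> np.ndarray:
    """Quasi-logarithmic correlator lag grid: 200 points, 300 ns – 1 s."""
    return np.geomspace(t_min, t_max, n)


def default_profile_distances() -> np.ndarray:
    """Distances from the membrane sampled by the emulated experiment:
    every 1 μm up to 20 μm, then every 10 μm up to 100 μm."""
    return np.concatenate([np.arange(1.0, 21.0), np.arange(30.0, 101.0, 10.0)])


def gen_acf_curves(
    truth: AcfParams,
    lags: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.005),
    n_curves: int = 1,
) -> list[AutocorrelationCurve]:
    """Generate seeded noisy autocorrelation curves from known parameters."""
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    if lags is None:
        lags = default_lag_grid()
    clean = acf_model(lags, truth)
    rng = np.random.default_rng(noise.seed)
    return [
        AutocorrelationCurve(lags=lags, values=noise.apply(clean, rng))
        for _ in range(n_curves)
    ]


@dataclass(frozen=True)
class ProfileSpec:
    """Study conditions for a synthetic concentration/diffusivity profile pair.

    ``bulk`` is in particles per confocal volume.  The proximal peak is
    ``bulk·(1 + (proximal_fold−1)·exp(−d/proximal_decay))``; the distal
    peak is the Fokker–Planck excess of ``diffusivity`` over the window
    ``fp_window`` (radii from the cell centre) with the bulk level as both
    boundary conditions.  ``diffusivity=None`` means a flat profile at
    ``flat_D`` (no diffusivity dip, hence no distal peak — the phenotype of
    cells without the matrix-associated diffusion barrier).
    """

    bulk: float = 1.0
    proximal_fold: float = 3.0
    proximal_decay: float = 5.0
    diffusivity: DiffusivityModel | None = DEFAULT_DIFFUSIVITY_MODEL
    flat_D: float = 150.0
    fp_window: tuple[float, float] = (13.0, 35.0)
    a: float = DEFAULT_CELL_RADIUS
    noise_sigma: float = 0.05
    seed: int = 0
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bulk < 0 or self.proximal_fold < 0:
            raise ValueError("bulk and proximal_fold must be >= 0")
        if self.proximal_decay <= 0:
            raise ValueError("proximal decay length must be > 0")
        if self.flat_D <= 0:
            raise ValueError("flat_D must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def profile_forward_model(spec: ProfileSpec, distances: np.ndarray):
    """Noiseless concentration and diffusivity at given membrane distances."""
    d = np.asarray(distances, dtype=float)
    r = spec.a + d
    conc = spec.bulk * (1.0 + (spec.proximal_fold - 1.0) * np.exp(-d / spec.proximal_decay))
    if spec.diffusivity is not None:
        D_profile = spec.diffusivity(r)
        r_lo, r_hi = spec.fp_window
        sol, _ = fokker_planck_steady(
            spec.diffusivity, ((r_lo, spec.bulk), (r_hi, spec.bulk))
        )
        inside = (r >= r_lo) & (r <= r_hi)
        excess = np.zeros_like(r)
        excess[inside] = sol(r[inside]) - spec.bulk
        conc = conc + excess
    else:
        D_profile = np.full_like(r, spec.flat_D)
    return conc, D_profile


def gen_radial_profiles(spec: ProfileSpec) -> tuple[RadialProfile, RadialProfile]:
    """Generate a (concentration, diffusivity) profile pair.

    Noise is multiplicative log-normal applied last, independently to the
    two profiles.
    """
    d = spec.distances if spec.distances is not None else default_profile_distances()
    d = np.asarray(d, dtype=float)
    conc, D_profile = profile_forward_model(spec, d)
    rng = np.random.default_rng(spec.seed)
    noise = NoiseSpec(kind="multiplicative-lognormal", sigma=spec.noise_sigma)
    conc = noise.apply(conc, rng)
    D_profile = noise.apply(D_profile, rng)
    r = spec.a + d
    return (
        RadialProfile(radii=r, values=conc, unit="per_confocal", a=spec.a),
        RadialProfile(radii=r, values=D_profile, unit="um2_per_s", a=spec.a),
    )


def gen_titration(
    mapping: PowerMapping,
    truth: HillModel,
    concs: np.ndarray,
    noise: NoiseSpec = NoiseSpec(kind="multiplicative-lognormal", sigma=0.05),
) -> tuple[np.ndarray, np.ndarray]:
    """Titration table: response = Hill(power_map(c)) + noise.

    Identity mapping emulates a vesicle-like control in which the bulk
    concentration *is* the membrane concentration.
    """
    c = np.asarray(concs, dtype=float)
    clean = hill_saturation(power_map(c, mapping), truth)
    rng = np.random.default_rng(noise.seed)
    return c, noise.apply(clean, rng)


def _bin_probabilities(components: LifetimeComponents, edges: np.ndarray) -> np.ndarray:
    a, tau = components.amplitudes, components.lifetimes
    # integral of sum_i a_i exp(-t/tau_i) over each bin, normalized
    cdf = np.sum(
        a[None, :] * tau[None, :] * (1.0 - np.exp(-edges[:, None] / tau[None, :])), axis=1
    )
    p = np.diff(cdf)
    return p / p.sum()


def gen_decay_histogram(
    components: LifetimeComponents,
    total_counts: int = 100_000,
    bin_width: float = 0.064,
    t_max: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Photon-count histogram of a multi-exponential fluorescence decay.

    Multinomial draw of ``total_counts`` photons over bins of ``bin_width``
    (ns) up to ``t_max`` (default 10× the longest lifetime).  Returns
    (bin centres, counts).
    """
    if total_counts < 1000:
        raise ValueError("need at least 1000 counts for a meaningful histogram")
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if t_max is None:
        t_max = 10.0 * float(components.lifetimes.max())
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    p = _bin_probabilities(components, edges)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_counts, p)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def fit_biexponential(
    centers: np.ndarray, counts: np.ndarray, bin_width: float | None = None
) -> LifetimeComponents:
    """Fit a two-component exponential decay to a photon-count histogram.

    Least squares on expected bin counts; returns amplitudes (relative) and
    lifetimes (ns).  A vanishing second amplitude reduces to a
    monoexponential fit.
    """
    centers = np.asarray(centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if bin_width is None:
        bin_width = float(np.median(np.diff(centers)))
    total = counts.sum()
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])

    # crude moment-based initialization
    tbar = float(np.sum(centers * counts) / total)
    p = Parameters()
    p.add("a1", value=0.7, min=0.0, max=1.0)
    p.add("tau1", value=max(tbar * 0.5, 1e-3), min=1e-6)
    p.add("tau2", value=tbar * 2.0, min=1e-6)

    def residual(pars):
        comp = LifetimeComponents(
            amplitudes=np.array([pars["a1"].value, 1.0 - pars["a1"].value]),
            lifetimes=np.array([pars["tau1"].value, pars["tau2"].value]),
        )
        expected = total * _bin_probabilities(comp, edges)
        return (expected - counts) / np.sqrt(np.maximum(expected, 1.0))

    out = minimize(residual, p, method="leastsq", max_nfev=20000)
    if not out.success:
        raise RuntimeError(f"biexponential fit did not converge: {out.message}")
    v = out.params.valuesdict()
    return LifetimeComponents(
        amplitudes=np.array([v["a1"], 1.0 - v["a1"]]),
        lifetimes=np.array([v["tau1"], v["tau2"]]),
    )
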