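"""Concrete receptor-signaling models, dose-response sweeps and potency.

Two membrane reaction systems are provided:

* :class:`PD1Model` — an inhibitory receptor (PD-1 carrying a bound
  phosphatase) dephosphorylating a costimulatory receptor (CD28) that is
  phosphorylated by a first-order background reaction::

      CD28  --(lam)-->  CD28*
      CD28* + PD-1 --(kcat* sigma(r; L))--> CD28 + PD-1

* :class:`PushPullModel` — the standard kinase/phosphatase push–pull loop::

      S  + E --(kcat_e sigma(r; L_e))--> S* + E
      S* + F --(kcat_f sigma(r; L_f))--> S  + F

Both report the steady-state modified fraction; sweeping the enzyme
concentration yields dose-response curves and IC50/EC50 potencies.  The
steady-state detection policy and the reach-potency switch experiment live
here as well.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .constants import PER_UM2_TO_PER_NM2, convert_catalytic_2d, convert_catalytic_3d
from .kernels import GaussianReachKernel
from .lattice import (
    LatticeDomain,
    PairwiseRule,
    ReactionNetwork,
    SpeciesDef,
    UnimolecularRule,
)
from .ssa import EnsembleSummary, run_ensemble

__all__ = [
    "PD1Model",
    "PushPullModel",
    "DoseResponseResult",
    "SteadyStateResult",
    "steady_state_fraction",
    "relaxation_time",
    "dose_response",
    "potency_surface",
    "switch_experiment",
    "extract_half_max",
    "fit_hill",
]

#: multiple of the relaxation time integrated before declaring steady state
STEADY_STATE_MULTIPLE = 20.0


@dataclass(frozen=True)
class PD1Model:
    """Inhibitory-receptor model with its tabulated default parameters.

    Concentrations in nm⁻², diffusivities in μm² s⁻¹, ``kcat`` in μM⁻¹ s⁻¹
    for the 3D kernel or μM⁻¹ s⁻¹ m⁻¹ for the 2D kernel variant.  ``[PD-1]``
    denotes receptor–phosphatase complexes; enzyme recruitment is not
    modeled.
    """

    D: float = 0.1
    pd1_concentration: float = 1.0e-4
    cd28_concentration: float = 1.0e-4
    lam: float = 1.0
    kcat: float = 0.1
    L: float = 8.5
    kernel_dimension: int = 3
    side: float = 300.0
    voxels_per_axis: int = 128
    dimension: int = 2

    @property
    def kcat_internal(self) -> float:
        if self.kernel_dimension == 3:
            return convert_catalytic_3d(self.kcat)
        return convert_catalytic_2d(self.kcat)

    def kernel(self) -> GaussianReachKernel:
        return GaussianReachKernel(self.L, self.kcat_internal, self.kernel_dimension)

    def domain(self) -> LatticeDomain:
        return LatticeDomain(self.dimension, self.side, self.voxels_per_axis, "periodic")

    def species(self) -> list[SpeciesDef]:
        conc_scale = 1.0 if self.dimension == 2 else 1.0 / self.side
        # the 3D variant distributes the same molecule numbers in the cube
        return [
            SpeciesDef("CD28", self.D, self.cd28_concentration * conc_scale),
            SpeciesDef("CD28*", self.D, 0.0),
            SpeciesDef("PD1", self.D, self.pd1_concentration * conc_scale),
        ]

    def network(self) -> ReactionNetwork:
        return ReactionNetwork(
            species=self.species(),
            unimolecular=[UnimolecularRule("CD28", "CD28*", self.lam)],
            pairwise=[PairwiseRule("CD28*", "PD1", "CD28", "PD1", self.kernel())],
        )

    @property
    def modified_species(self) -> str:
        return "CD28*"

    @property
    def total_species(self) -> tuple[str, str]:
        return ("CD28", "CD28*")

    def forward_backward_rates(self) -> tuple[float, float]:
        """Mean-field modification and de-modification rates, s⁻¹."""
        ker = self.kernel()
        if self.dimension == 2:
            k_eff = ker.well_mixed_rate_2d()
            conc = self.pd1_concentration
        else:
            k_eff = ker.catalytic_efficiency
            conc = self.pd1_concentration / self.side
        return self.lam, k_eff * conc

    def direction_pair_diffusivities(self) -> tuple[tuple[float, float] | None, ...]:
        """Reactant diffusivities per direction; None for unimolecular."""
        return (None, (self.D, self.D))

    def sweep(self, concentration: float) -> "PD1Model":
        return replace(self, pd1_concentration=concentration)

    @property
    def response_direction(self) -> str:
        return "decreasing"


@dataclass(frozen=True)
class PushPullModel:
    """Kinase–phosphatase push–pull model with tabulated defaults.

    ``substrate/kinase/phosphatase_concentration`` are in μm⁻² (as tabulated:
    [S] = 100, [F] = 112 μm⁻²); ``kcat_e``/``kcat_f`` are μM⁻¹ s⁻¹ for the 3D
    kernel and μM⁻¹ s⁻¹ m⁻¹ for the 2D kernel (the tabulated 2D rates
    (4/3)e5 and (1/3)e5 correspond to 221.3736 and 55.3434 nm² s⁻¹).
    """

    substrate_concentration: float = 100.0
    kinase_concentration: float = 125.0
    phosphatase_concentration: float = 112.0
    D_S: float = 0.1
    D_E: float = 0.1
    D_F: float = 6.25e-4
    kcat_e_3d: float = 0.04
    kcat_f_3d: float = 0.01
    kcat_e_2d: float = (4.0 / 3.0) * 1.0e5
    kcat_f_2d: float = (1.0 / 3.0) * 1.0e5
    L_e: float = 10.0
    L_f: float = 15.0
    kernel_dimension: int = 3
    side: float = 300.0
    voxels_per_axis: int = 128
    dimension: int = 2

    def kernels(self) -> tuple[GaussianReachKernel, GaussianReachKernel]:
        if self.kernel_dimension == 3:
            ke = convert_catalytic_3d(self.kcat_e_3d)
            kf = convert_catalytic_3d(self.kcat_f_3d)
        else:
            ke = convert_catalytic_2d(self.kcat_e_2d)
            kf = convert_catalytic_2d(self.kcat_f_2d)
        return (
            GaussianReachKernel(self.L_e, ke, self.kernel_dimension),
            GaussianReachKernel(self.L_f, kf, self.kernel_dimension),
        )

    def domain(self) -> LatticeDomain:
        return LatticeDomain(self.dimension, self.side, self.voxels_per_axis, "periodic")

    def species(self) -> list[SpeciesDef]:
        scale = PER_UM2_TO_PER_NM2 * (1.0 if self.dimension == 2 else 1.0 / self.side)
        return [
            SpeciesDef("S", self.D_S, self.substrate_concentration * scale),
            SpeciesDef("S*", self.D_S, 0.0),
            SpeciesDef("E", self.D_E, self.kinase_concentration * scale),
            SpeciesDef("F", self.D_F, self.phosphatase_concentration * scale),
        ]

    def network(self) -> ReactionNetwork:
        ker_e, ker_f = self.kernels()
        return ReactionNetwork(
            species=self.species(),
            unimolecular=[],
            pairwise=[
                PairwiseRule("S", "E", "S*", "E", ker_e),
                PairwiseRule("S*", "F", "S", "F", ker_f),
            ],
        )

    @property
    def modified_species(self) -> str:
        return "S*"

    @property
    def total_species(self) -> tuple[str, str]:
        return ("S", "S*")

    def forward_backward_rates(self) -> tuple[float, float]:
        ker_e, ker_f = self.kernels()
        scale = PER_UM2_TO_PER_NM2
        if self.dimension == 2:
            return (
                ker_e.well_mixed_rate_2d() * self.kinase_concentration * scale,
                ker_f.well_mixed_rate_2d() * self.phosphatase_concentration * scale,
            )
        return (
            ker_e.catalytic_efficiency * self.kinase_concentration * scale / self.side,
            ker_f.catalytic_efficiency * self.phosphatase_concentration * scale / self.side,
        )

    def direction_pair_diffusivities(self) -> tuple[tuple[float, float] | None, ...]:
        return ((self.D_S, self.D_E), (self.D_S, self.D_F))

    def sweep(self, concentration: float) -> "PushPullModel":
        return replace(self, kinase_concentration=concentration)

    @property
    def response_direction(self) -> str:
        return "increasing"


def relaxation_time(model) -> float:
    """Steady-state relaxation time used by the detection policy.

    ``tau = tau_mf + max_dir min(tau_quench_dir, tau_mix_dir)``.  The first
    term is the mean-field linear relaxation ``1/(r_fwd + r_bwd)``.  The
    correction accounts for spatially quenched configurations: a substrate
    whose reaction partner for direction ``dir`` is out of reach relaxes at
    most at that direction's rate once the pair geometry re-randomizes, so
    each bimolecular direction contributes the smaller of its quenched bound
    ``1/r_dir`` and its pair mixing time ``(side/2)^2 / (4 (D_a + D_b))``.
    Unimolecular directions carry no geometry dependence and contribute
    nothing.  At fast diffusion the correction vanishes and the policy
    reduces to mean-field; at slow diffusion it extends the horizon enough
    for frozen-geometry modes to decay.
    """
    rf, rb = model.forward_backward_rates()
    if rf + rb <= 0:
        raise ValueError("model has no reactions; relaxation time undefined")
    tau_mf = 1.0 / (rf + rb)
    correction = 0.0
    for rate, pair in zip((rf, rb), model.direction_pair_diffusivities()):
        if pair is None or rate <= 0:
            continue
        d_rel = (pair[0] + pair[1]) * 1.0e6
        tau_mix = (model.side / 2.0) ** 2 / (4.0 * d_rel) if d_rel > 0 else math.inf
        correction = max(correction, min(1.0 / rate, tau_mix))
    return tau_mf + correction


@dataclass
class SteadyStateResult:
    fraction: float
    sem: float
    t_end: float
    n_trajectories: int
    converged: bool
    window_means: tuple[float, float]
    ensemble: EnsembleSummary = field(repr=False)


def steady_state_fraction(
    model,
    n_trajectories: int = 200,
    base_seed: int = 0,
    t_end: float | None = None,
    engine: str = "auto",
) -> SteadyStateResult:
    """Steady-state modified fraction with standard error.

    Each trajectory is integrated to ``t_end`` (default 20 relaxation times,
    see :func:`relaxation_time`) and the modified fraction is the exact time
    average over the final half of the run.  Convergence is declared when the
    ensemble means over the third and fourth quarters of ``[0, t_end]`` agree
    within twice their pooled standard error.
    """
    mod = model.modified_species
    tot_a, tot_b = model.total_species
    if t_end is None:
        t_end = STEADY_STATE_MULTIPLE * relaxation_time(model)
    # quarter-window samples for the convergence diagnostic
    q3 = np.linspace(0.5 * t_end, 0.75 * t_end, 8, endpoint=False)
    q4 = np.linspace(0.75 * t_end, t_end, 8, endpoint=False)
    ens = run_ensemble(
        model.domain(), model.species(), model.network(),
        n_trajectories, base_seed,
        until=t_end,
        average_window=0.5 * t_end,
        sample_times=np.concatenate([q3, q4]),
        engine=engine,
    )
    avg_mod = ens.observables[f"avg:{mod}"]
    avg_tot = ens.observables[f"avg:{tot_a}"] + ens.observables[f"avg:{tot_b}"]
    frac = avg_mod / avg_tot
    mean = float(np.mean(frac))
    sem = float(np.std(frac, ddof=1) / math.sqrt(len(frac))) if len(frac) > 1 else float("nan")
    # window diagnostic: ensemble-mean modified fraction over the third vs
    # fourth quarter of the run, compared against the pooled standard error
    names = [s.name for s in model.species()]
    imod = names.index(mod)
    itot = (names.index(tot_a), names.index(tot_b))
    mc = ens.mean_counts
    tot_counts = mc[:, itot[0]] + mc[:, itot[1]]
    fr_t = mc[:, imod] / np.maximum(tot_counts, 1e-12)
    w3 = float(np.mean(fr_t[:8]))
    w4 = float(np.mean(fr_t[8:]))
    pooled = 2.0 * sem if np.isfinite(sem) else float("inf")
    converged = abs(w3 - w4) <= max(2.0 * pooled, 1e-9)
    return SteadyStateResult(
        fraction=mean, sem=sem, t_end=float(t_end),
        n_trajectories=n_trajectories,
        converged=converged, window_means=(w3, w4), ensemble=ens,
    )


# ---------------------------------------------------------------------------
# dose-response and potency
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResult:
    concentrations: np.ndarray
    fractions: np.ndarray
    sems: np.ndarray
    half_max: float | None
    direction: str
    reference: float
    monotone_within_error: bool
    bracket: tuple[float, float] | None
    n_trajectories: int
    base_seed: int

    @property
    def ic50(self) -> float | None:
        return self.half_max if self.direction == "decreasing" else None

    @property
    def ec50(self) -> float | None:
        return self.half_max if self.direction == "increasing" else None


def extract_half_max(
    concentrations: np.ndarray,
    fractions: np.ndarray,
    direction: str = "decreasing",
    reference: float = 1.0,
) -> tuple[float | None, np.ndarray, tuple[float, float] | None]:
    """Half-maximal concentration by isotonic smoothing + log-linear interpolation.

    The mean curve is first projected onto the monotone cone matching
    ``direction``; the 50%-of-``reference`` crossing is then interpolated
    linearly in log-concentration between the bracketing grid points.
    Returns ``(c50, smoothed, bracket)``; ``c50`` is None when the smoothed
    curve does not cross the threshold (the bracketing bound is returned).
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 grid points")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    increasing = direction == "increasing"
    iso = optimize.isotonic_regression(f, increasing=increasing).x
    thr = 0.5 * reference
    above = iso > thr if not increasing else iso < thr
    # find the first index where the curve crosses the threshold
    cross = None
    for i in range(len(c) - 1):
        lo, hi = iso[i], iso[i + 1]
        if (lo - thr) * (hi - thr) <= 0 and lo != hi:
            cross = i
            break
    if cross is None:
        return None, iso, (float(c[0]), float(c[-1]))
    i = cross
    x0, x1 = math.log(c[i]), math.log(c[i + 1])
    y0, y1 = iso[i], iso[i + 1]
    x = x0 + (thr - y0) * (x1 - x0) / (y1 - y0)
    return float(math.exp(x)), iso, (float(c[i]), float(c[i + 1]))


def fit_hill(concentrations, fractions, direction="decreasing", reference=1.0):
    """Hill-equation fit ``f = ref / (1 + (c/c50)^h)`` (cross-check estimator)."""
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(fractions, dtype=float)

    def model(c, c50, h):
        r = (c / c50) ** h
        return reference / (1.0 + r) if direction == "decreasing" else reference * r / (1.0 + r)

    p0 = (math.exp(0.5 * (math.log(c[0]) + math.log(c[-1]))), 1.0)
    popt, _ = optimize.curve_fit(model, c, f, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1])


def dose_response(
    model,
    sweep: np.ndarray,
    n_trajectories: int = 200,
    base_seed: int = 0,
    reference: float | None = None,
    engine: str = "auto",
) -> DoseResponseResult:
    """Steady-state fraction across an enzyme-concentration grid, with c50.

    ``sweep`` is the grid of inhibitor ([PD-1], nm⁻²) or kinase ([E], μm⁻²)
    concentrations, depending on the model.  ``reference`` is the
    zero-enzyme baseline used for the 50% threshold; it defaults to 1 for
    the inhibitor model (all substrate modified without inhibitor) and to 1
    for activator curves normalized to full modification.
    """
    sweep = np.asarray(sweep, dtype=float)
    direction = model.response_direction
    if reference is None:
        reference = 1.0
    fr = np.empty(len(sweep))
    se = np.empty(len(sweep))
    for i, conc in enumerate(sweep):
        res = steady_state_fraction(
            model.sweep(conc), n_trajectories, base_seed + 1000 * i, engine=engine
        )
        fr[i] = res.fraction
        se[i] = res.sem
    half, iso, bracket = extract_half_max(sweep, fr, direction, reference)
    resid = np.abs(fr - iso)
    monotone = bool(np.all(resid <= np.maximum(3.0 * se, 1e-12)))
    if not monotone:
        warnings.warn("dose-response trend violates monotonicity beyond 3 SE")
    return DoseResponseResult(
        concentrations=sweep, fractions=fr, sems=se,
        half_max=half, direction=direction, reference=reference,
        monotone_within_error=monotone, bracket=bracket,
        n_trajectories=n_trajectories, base_seed=base_seed,
    )


def potency_surface(
    model,
    reach_grid: np.ndarray,
    diffusivity_grid: np.ndarray,
    sweep: np.ndarray,
    n_trajectories: int = 100,
    base_seed: int = 0,
    engine: str = "auto",
) -> np.ndarray:
    """Matrix of half-maximal concentrations over (reach, diffusivity).

    Entry ``[i, j]`` is the c50 at ``reach_grid[i]``, ``diffusivity_grid[j]``
    (NaN when the curve does not bracket 50%).  With the 3D kernel the
    potency order in the reach inverts between slow and fast diffusion; with
    the 2D kernel it does not.
    """
    reach_grid = np.asarray(reach_grid, dtype=float)
    diffusivity_grid = np.asarray(diffusivity_grid, dtype=float)
    if reach_grid.size == 0 or diffusivity_grid.size == 0:
        raise ValueError("grids must be non-empty")
    out = np.full((len(reach_grid), len(diffusivity_grid)), np.nan)
    for i, L in enumerate(reach_grid):
        for j, D in enumerate(diffusivity_grid):
            if isinstance(model, PD1Model):
                m = replace(model, L=L, D=D)
            else:
                m = replace(model, L_e=L, D_S=D, D_E=D)
            dr = dose_response(m, sweep, n_trajectories, base_seed + 17 * (i * 31 + j), engine=engine)
            if dr.half_max is not None:
                out[i, j] = dr.half_max
    return out


def switch_experiment(
    kernel_dimension: int = 3,
    reaches: tuple[float, float] = (1.0, 70.0),
    diffusivities: tuple[float, float] = (1.25e-6, 0.1),
    kinase_concentration: float = 125.0,
    n_trajectories: int = 500,
    base_seed: int = 0,
    voxels_per_axis: int = 128,
) -> dict[tuple[float, float], tuple[float, float]]:
    """Steady-state phospho-fraction of the push–pull model on a (L, D) grid.

    Returns ``{(L, D): (fraction, sem)}`` at fixed kinase concentration.
    With the 3D kernel the ordering of the two reaches inverts between the
    slow and fast diffusivities (the potency switch); with the 2D kernel the
    large reach is never significantly less effective.
    """
    out: dict[tuple[float, float], tuple[float, float]] = {}
    for i, L in enumerate(reaches):
        for j, D in enumerate(diffusivities):
            m = PushPullModel(
                kernel_dimension=kernel_dimension,
                L_e=L, D_S=D, D_E=D,
                kinase_concentration=kinase_concentration,
                voxels_per_axis=voxels_per_axis,
            )
            res = steady_state_fraction(m, n_trajectories, base_seed + 101 * i + 13 * j)
            out[(L, D)] = (res.fraction, res.sem)
    return out
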