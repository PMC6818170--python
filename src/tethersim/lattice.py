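"""Lattice domains, species, reaction rules and discretized kernels.

The simulator approximates continuum reaction–diffusion dynamics by a jump
process on a Cartesian mesh: molecules hop between voxels at rate ``D/h²``
per lattice direction and pairs react with a separation-dependent propensity.
As the voxel size shrinks this construction converges to the spatially
continuous volume-reactivity (Doi) model.

Pairwise Gaussian propensities are discretized by *voxel averaging*: the
Gaussian kernels factorize over axes, so the average of the kernel over a
pair of voxels is a product of one-dimensional closed-form (erf) factors.
Averaging preserves the summed (well-mixed) reaction rate exactly at any
resolution, which matters because physiological reaches (L = 1 nm) can be
narrower than any affordable voxel.  Indicator (Doi) interactions are
evaluated at voxel-center separations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .kernels import DoiCalibration, GaussianReachKernel

__all__ = [
    "LatticeDomain",
    "SpeciesDef",
    "UnimolecularRule",
    "PairwiseRule",
    "ReactionNetwork",
    "WorldState",
    "build_world",
    "pair_separation",
    "hop_propensity",
    "pair_propensity",
    "axis_kernel_table",
]


@dataclass(frozen=True)
class LatticeDomain:
    """Square (2D) or cubic (3D) simulation domain.

    Attributes
    ----------
    dimension : 2 or 3.
    side : edge length in nm.
    voxels_per_axis : mesh resolution (power of two preferred).
    boundary : "periodic" or "reflecting".
    """

    dimension: int
    side: float = 300.0
    voxels_per_axis: int = 128
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.side <= 0:
            raise ValueError("side must be > 0")
        if self.voxels_per_axis < 1:
            raise ValueError("voxels_per_axis must be >= 1")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError("boundary must be 'periodic' or 'reflecting'")

    @property
    def spacing(self) -> float:
        """Voxel edge length h in nm."""
        return self.side / self.voxels_per_axis

    @property
    def n_voxels(self) -> int:
        return self.voxels_per_axis**self.dimension

    @property
    def measure(self) -> float:
        """Domain area (nm²) or volume (nm³)."""
        return self.side**self.dimension

    def voxel_coords(self, index: int) -> tuple[int, ...]:
        """Unflatten a voxel index (row-major) to per-axis coordinates."""
        n = self.voxels_per_axis
        if not 0 <= index < self.n_voxels:
            raise IndexError(f"voxel index {index} out of range")
        coords = []
        for _ in range(self.dimension):
            coords.append(index % n)
            index //= n
        return tuple(coords)


@dataclass(frozen=True)
class SpeciesDef:
    """A molecular species with diffusivity and initial concentration.

    ``diffusivity`` is in μm² s⁻¹ (bench units, as tabulated);
    ``initial_concentration`` is in nm⁻² (2D) or nm⁻³ (3D).
    """

    name: str
    diffusivity: float = 0.0
    initial_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be >= 0")
        if self.initial_concentration < 0:
            raise ValueError("initial_concentration must be >= 0")

    @property
    def diffusivity_nm2(self) -> float:
        """Diffusivity in nm² s⁻¹."""
        return self.diffusivity * 1.0e6


@dataclass(frozen=True)
class UnimolecularRule:
    """First-order conversion ``reactant -> product`` at a fixed rate (s⁻¹)."""

    reactant: str
    product: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


@dataclass(frozen=True)
class PairwiseRule:
    """Separation-dependent bimolecular rule ``A + B -> A' + B'``.

    ``kernel`` is either a :class:`GaussianReachKernel` (propensity
    ``k_cat * sigma(r; L)``, truncated beyond ``r_cut_factor * L``) or a
    :class:`DoiCalibration` (indicator propensity ``lam * 1_[0,eps](r)``).
    A product of ``None`` removes the molecule (annihilation).
    """

    reactant_a: str
    reactant_b: str
    product_a: str | None
    product_b: str | None
    kernel: GaussianReachKernel | DoiCalibration
    r_cut_factor: float = 4.5

    @property
    def r_cut(self) -> float:
        if isinstance(self.kernel, GaussianReachKernel):
            return self.r_cut_factor * self.kernel.reach
        return self.kernel.epsilon


@dataclass
class ReactionNetwork:
    """Species definitions plus unimolecular and pairwise rules."""

    species: list[SpeciesDef]
    unimolecular: list[UnimolecularRule] = field(default_factory=list)
    pairwise: list[PairwiseRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self.index = {n: i for i, n in enumerate(names)}
        for r in self.unimolecular:
            for n in (r.reactant, r.product):
                if n not in self.index:
                    raise ValueError(f"unknown species {n!r} in unimolecular rule")
        for r in self.pairwise:
            for n in (r.reactant_a, r.reactant_b, r.product_a, r.product_b):
                if n is not None and n not in self.index:
                    raise ValueError(f"unknown species {n!r} in pairwise rule")
            if r.reactant_a == r.reactant_b:
                raise ValueError("pairwise rules require distinct reactant species")

    def species_by_name(self, name: str) -> SpeciesDef:
        return self.species[self.index[name]]


@dataclass
class WorldState:
    """Per-molecule state of one realization.

    ``species`` holds the species index of each molecule, ``positions`` the
    per-axis voxel coordinates (row ``i`` for molecule ``i``), both mutated by
    the simulator.  ``seed`` identifies the RNG stream.
    """

    domain: LatticeDomain
    species: np.ndarray
    positions: np.ndarray
    seed: int
    time: float = 0.0

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    def counts(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species)


def hop_propensity(species: SpeciesDef, domain: LatticeDomain) -> float:
    """Hop rate ``D / h²`` per lattice direction, s⁻¹.

    Each molecule has ``2 * dimension`` directions; on reflecting boundaries
    the outward hop is suppressed (realized as a null event, which is
    statistically identical by Poisson thinning).
    """
    h = domain.spacing
    if h <= 0:
        raise ValueError("spacing must be > 0")
    return species.diffusivity_nm2 / (h * h)


def pair_separation(domain: LatticeDomain, voxel_i, voxel_j) -> float:
    """Euclidean distance in nm between voxel centers.

    Accepts flat indices or per-axis coordinate tuples.  On periodic domains
    the minimal-image distance is returned.
    """
    ci = domain.voxel_coords(voxel_i) if np.isscalar(voxel_i) else tuple(voxel_i)
    cj = domain.voxel_coords(voxel_j) if np.isscalar(voxel_j) else tuple(voxel_j)
    if len(ci) != domain.dimension or len(cj) != domain.dimension:
        raise ValueError("voxel coordinates do not match domain dimension")
    n = domain.voxels_per_axis
    for c in (*ci, *cj):
        if not 0 <= c < n:
            raise IndexError("voxel coordinate out of range")
    d2 = 0.0
    for a, b in zip(ci, cj):
        delta = abs(a - b)
        if domain.boundary == "periodic":
            delta = min(delta, n - delta)
        d2 += float(delta) ** 2
    return math.sqrt(d2) * domain.spacing


def pair_propensity(rule: PairwiseRule, r: float) -> float:
    """Continuum pairwise propensity in s⁻¹ at separation ``r`` (nm).

    ``k_cat * sigma(r; L)`` for Gaussian rules (zero beyond the truncation
    radius), ``lam * 1_[0,eps](r)`` for indicator rules.  The engines use the
    voxel-averaged tabulated version of the same kernel.
    """
    if r < 0:
        raise ValueError("separation must be >= 0")
    if isinstance(rule.kernel, GaussianReachKernel):
        if r > rule.r_cut:
            return 0.0
        return float(rule.kernel.propensity(r))
    return float(rule.kernel.propensity(r))


def build_world(
    domain: LatticeDomain, species: list[SpeciesDef], seed: int, counts: dict[str, int] | None = None
) -> WorldState:
    """Place molecules uniformly at random on the lattice.

    The molecule count of each species is ``round(concentration * measure)``
    unless overridden via ``counts``; a warning is emitted when rounding
    changes the count by more than 5%.
    """
    if domain.n_voxels < 1:
        raise ValueError("domain has no voxels")
    rng = np.random.default_rng(seed)
    sp_idx: list[int] = []
    for i, sp in enumerate(species):
        if counts is not None and sp.name in counts:
            m = int(counts[sp.name])
        else:
            exact = sp.initial_concentration * domain.measure
            m = int(round(exact))
            if exact > 0 and abs(m - exact) / exact > 0.05:
                warnings.warn(
                    f"rounding changed {sp.name} count by more than 5% "
                    f"({exact:.3g} -> {m})"
                )
        if m < 0:
            raise ValueError("negative molecule count")
        sp_idx.extend([i] * m)
    nmol = len(sp_idx)
    positions = rng.integers(0, domain.voxels_per_axis, size=(nmol, domain.dimension))
    return WorldState(
        domain=domain,
        species=np.asarray(sp_idx, dtype=np.int64),
        positions=positions.astype(np.int64),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# discretized kernels
# ---------------------------------------------------------------------------

def _avg_1d_gaussian(delta_h: np.ndarray, h: float, s: float) -> np.ndarray:
    """Average of the N(0, s²) pdf over a voxel pair at axis offset ``delta_h``.

    ``G(c) = h⁻² ∫₀ʰ∫₀ʰ φ_s(c + u - v) du dv`` with ``c = delta_h`` (nm),
    in closed form via the normal cdf/pdf.  Units nm⁻¹; ``Σ_Δ h G(Δ h) = 1``.
    """
    c = np.asarray(delta_h, dtype=float)
    sq2 = s * math.sqrt(2.0)
    Phi = lambda x: 0.5 * (1.0 + special.erf(x / sq2))
    phi = lambda x: np.exp(-0.5 * (x / s) ** 2) / (s * math.sqrt(2.0 * math.pi))
    s2 = s * s
    upper = (h + c) * (Phi(c + h) - Phi(c)) + s2 * (phi(c + h) - phi(c))
    lower = (h - c) * (Phi(c) - Phi(c - h)) + s2 * (phi(c - h) - phi(c))
    return (upper + lower) / (h * h)


def axis_kernel_table(
    L: float, domain: LatticeDomain, r_cut: float | None = None
) -> np.ndarray:
    """Per-axis voxel-averaged Gaussian factor table.

    Entry ``g[k]`` is the voxel-pair average of the one-dimensional normal
    pdf with standard deviation ``s = L/sqrt(3)`` at axis offset ``k`` voxels
    (``k = 0 .. n-1``), with periodic images summed on periodic domains.
    The full pairwise rate is an amplitude times the product of per-axis
    factors (see :func:`tethersim.ssa.compile_network`).  Entries beyond
    ``r_cut`` are zeroed.
    """
    n = domain.voxels_per_axis
    h = domain.spacing
    s = L / math.sqrt(3.0)
    k = np.arange(n, dtype=float)
    if domain.boundary == "periodic":
        n_img = max(1, int(math.ceil((6.0 * s / domain.side))) + 1)
        g = np.zeros(n)
        for img in range(-n_img, n_img + 1):
            g += _avg_1d_gaussian((k + img * n) * h, h, s)
    else:
        g = _avg_1d_gaussian(k * h, h, s)
    if r_cut is not None:
        if domain.boundary == "periodic":
            dist = np.minimum(k, n - k) * h
        else:
            dist = k * h
        g[dist > r_cut] = 0.0
    return g
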