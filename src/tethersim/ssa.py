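"""Continuous-time stochastic simulation of lattice reaction–diffusion.

`simulate` runs one trajectory of a :class:`~tethersim.lattice.WorldState`
under a :class:`~tethersim.lattice.ReactionNetwork`; `run_ensemble` runs many
independent trajectories with deterministically derived seeds and aggregates
summary statistics.

Two exact engines are available (see :mod:`tethersim._engine`): the classic
direct SSA and a uniformized sampler that advances positions lazily through
the free-walk propagator and thins pairwise candidates against per-rule rate
bounds.  ``engine="auto"`` picks the uniformized engine whenever the total
hop rate exceeds the total candidate bound (i.e. whenever explicit hops would
dominate the event budget).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .kernels import DoiCalibration, GaussianReachKernel
from .lattice import (
    LatticeDomain,
    PairwiseRule,
    ReactionNetwork,
    SpeciesDef,
    WorldState,
    axis_kernel_table,
    build_world,
    hop_propensity,
)

__all__ = [
    "CompiledNetwork",
    "TrajectorySummary",
    "EnsembleSummary",
    "compile_network",
    "simulate",
    "run_ensemble",
    "trajectory_seed",
]


def trajectory_seed(base_seed: int, k: int, stream: int = 0) -> int:
    """Deterministic per-trajectory seed, splittable from ``(base_seed, k)``.

    Uses numpy's ``SeedSequence`` spawning convention; the result is reduced
    below 2**31 for the engine RNG.
    """
    ss = np.random.SeedSequence([int(base_seed), int(k), int(stream)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CompiledNetwork:
    """Array form of a reaction network for the numba engines."""

    domain: LatticeDomain
    network: ReactionNetwork
    hop_dir: np.ndarray
    uni_r: np.ndarray
    uni_p: np.ndarray
    uni_rate: np.ndarray
    pair_ra: np.ndarray
    pair_rb: np.ndarray
    pair_pa: np.ndarray
    pair_pb: np.ndarray
    pair_kind: np.ndarray
    pair_amp: np.ndarray
    pair_eps2: np.ndarray
    pair_rmax: np.ndarray
    tables: np.ndarray

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.network.species]


def compile_network(domain: LatticeDomain, network: ReactionNetwork) -> CompiledNetwork:
    """Tabulate kernels and pack the network into engine arrays.

    Gaussian rules become an amplitude times per-axis voxel-averaged factor
    tables; a 3D kernel used on a 2D (membrane) domain contributes the
    out-of-plane Gaussian factor ``1/(sqrt(2 pi) s)`` to the amplitude.
    """
    idx = network.index
    h = domain.spacing
    hop_dir = np.array(
        [hop_propensity(s, domain) for s in network.species], dtype=np.float64
    )
    nuni = len(network.unimolecular)
    uni_r = np.array([idx[r.reactant] for r in network.unimolecular], dtype=np.int64).reshape(nuni)
    uni_p = np.array([idx[r.product] for r in network.unimolecular], dtype=np.int64).reshape(nuni)
    uni_rate = np.array([r.rate for r in network.unimolecular], dtype=np.float64).reshape(nuni)

    npair = len(network.pairwise)
    n = domain.voxels_per_axis
    pair_ra = np.zeros(npair, np.int64)
    pair_rb = np.zeros(npair, np.int64)
    pair_pa = np.zeros(npair, np.int64)
    pair_pb = np.zeros(npair, np.int64)
    pair_kind = np.zeros(npair, np.int64)
    pair_amp = np.zeros(npair, np.float64)
    pair_eps2 = np.zeros(npair, np.float64)
    pair_rmax = np.zeros(npair, np.float64)
    tables = np.zeros((max(npair, 1), n), np.float64)
    for k, rule in enumerate(network.pairwise):
        pair_ra[k] = idx[rule.reactant_a]
        pair_rb[k] = idx[rule.reactant_b]
        pair_pa[k] = idx[rule.product_a] if rule.product_a is not None else -1
        pair_pb[k] = idx[rule.product_b] if rule.product_b is not None else -1
        if isinstance(rule.kernel, DoiCalibration):
            pair_kind[k] = 1
            pair_amp[k] = rule.kernel.lam
            pair_eps2[k] = (rule.kernel.epsilon / h) ** 2
            pair_rmax[k] = rule.kernel.lam
        elif isinstance(rule.kernel, GaussianReachKernel):
            ker = rule.kernel
            if ker.kernel_dimension == 2 and domain.dimension != 2:
                raise ValueError("2D kernels require a 2D domain")
            s = ker.reach / math.sqrt(3.0)
            amp = ker.catalytic_efficiency
            if ker.kernel_dimension == 3 and domain.dimension == 2:
                amp /= math.sqrt(2.0 * math.pi) * s
            g = axis_kernel_table(ker.reach, domain, r_cut=rule.r_cut)
            tables[k] = g
            pair_kind[k] = 0
            pair_amp[k] = amp
            pair_rmax[k] = amp * g[0] ** domain.dimension
        else:
            raise TypeError(f"unsupported kernel type {type(rule.kernel)!r}")
    return CompiledNetwork(
        domain=domain, network=network, hop_dir=hop_dir,
        uni_r=uni_r, uni_p=uni_p, uni_rate=uni_rate,
        pair_ra=pair_ra, pair_rb=pair_rb, pair_pa=pair_pa, pair_pb=pair_pb,
        pair_kind=pair_kind, pair_amp=pair_amp, pair_eps2=pair_eps2,
        pair_rmax=pair_rmax, tables=tables,
    )


_STATUS = {_engine.OK: "ok", _engine.STALLED: "stalled", _engine.REACTED: "reacted"}


@dataclass
class TrajectorySummary:
    """Time series, terminal state and event counts of one trajectory."""

    species_names: list[str]
    times: np.ndarray
    counts: np.ndarray
    t_final: float
    status: str
    event_counts: dict[str, int]
    reaction_time: float | None = None
    time_averages: dict[str, float] | None = None
    positions: np.ndarray | None = field(default=None, repr=False)
    final_species: np.ndarray | None = field(default=None, repr=False)
    final_positions: np.ndarray | None = field(default=None, repr=False)

    def count_series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species_names.index(name)]


def _select_engine(compiled: CompiledNetwork, species_arr: np.ndarray) -> str:
    counts = np.bincount(
        species_arr[species_arr >= 0], minlength=len(compiled.hop_dir)
    )
    hop_total = float(np.sum(counts * 2 * compiled.domain.dimension * compiled.hop_dir))
    bound = float(np.sum(counts[compiled.uni_r] * compiled.uni_rate)) if len(compiled.uni_r) else 0.0
    for k in range(len(compiled.pair_ra)):
        bound += counts[compiled.pair_ra[k]] * counts[compiled.pair_rb[k]] * compiled.pair_rmax[k]
    return "uniformized" if hop_total > bound else "direct"


def simulate(
    world: WorldState,
    network: ReactionNetwork,
    until: float,
    sample_times: np.ndarray | None = None,
    average_window: float | None = None,
    record_positions: bool = False,
    stop_on_reaction: bool = False,
    engine: str = "auto",
    seed: int | None = None,
    compiled: CompiledNetwork | None = None,
) -> TrajectorySummary:
    """Run one exact trajectory up to time ``until`` (seconds).

    Parameters
    ----------
    sample_times : times at which species counts (and positions, if
        ``record_positions``) are recorded.
    average_window : if given, exact time averages of species counts over
        ``[average_window, until]`` are returned.
    stop_on_reaction : stop at the first pairwise reaction event and report
        its time (used for mean-reaction-time experiments).
    engine : ``"direct"``, ``"uniformized"`` or ``"auto"``.
    seed : engine RNG seed; defaults to the world's seed.
    """
    if until <= 0:
        raise ValueError("until must be > 0")
    if compiled is None:
        compiled = compile_network(world.domain, network)
    if sample_times is None:
        sample_times = np.empty(0, dtype=np.float64)
    sample_times = np.asarray(sample_times, dtype=np.float64)
    if np.any(np.diff(sample_times) < 0):
        raise ValueError("sample_times must be sorted")
    species_arr = world.species.copy()
    pos_arr = world.positions.copy()
    if engine == "auto":
        engine = _select_engine(compiled, species_arr)
    if engine not in ("direct", "uniformized"):
        raise ValueError("engine must be 'direct', 'uniformized' or 'auto'")

    nspecies = len(compiled.hop_dir)
    nsamp = len(sample_times)
    nmol = len(species_arr)
    counts_out = np.zeros((nsamp, nspecies), np.int64)
    pos_out = np.zeros((nsamp if record_positions else 0, nmol, world.domain.dimension), np.int64)
    occ_int = np.zeros(nspecies, np.float64)
    uni_events = np.zeros(len(compiled.uni_r), np.int64)
    pair_events = np.zeros(len(compiled.pair_ra), np.int64)
    avg_start = float(average_window) if average_window is not None else float(until)
    eng_seed = int(world.seed if seed is None else seed) % (2**31)

    args = (
        eng_seed,
        world.domain.dimension, world.domain.voxels_per_axis,
        world.domain.boundary == "periodic",
        compiled.hop_dir,
        species_arr, pos_arr,
        compiled.uni_r, compiled.uni_p, compiled.uni_rate,
        compiled.pair_ra, compiled.pair_rb, compiled.pair_pa, compiled.pair_pb,
        compiled.pair_kind, compiled.pair_amp, compiled.pair_eps2, compiled.tables,
    )
    tail = (
        float(until), sample_times, avg_start,
        stop_on_reaction, record_positions,
        counts_out, pos_out, occ_int, uni_events, pair_events,
    )
    if engine == "direct":
        t_final, status, rtime = _engine.direct_engine(*args, *tail)
    else:
        t_final, status, rtime = _engine.uniformized_engine(
            *args, compiled.pair_rmax, *tail
        )

    names = compiled.species_names
    event_counts: dict[str, int] = {}
    for k, r in enumerate(network.unimolecular):
        event_counts[f"uni:{r.reactant}->{r.product}"] = int(uni_events[k])
    for k, r in enumerate(network.pairwise):
        event_counts[f"pair:{r.reactant_a}+{r.reactant_b}"] = int(pair_events[k])
    time_averages = None
    if average_window is not None and until > avg_start:
        time_averages = {
            nm: float(occ_int[i] / (until - avg_start)) for i, nm in enumerate(names)
        }
    return TrajectorySummary(
        species_names=names,
        times=sample_times,
        counts=counts_out,
        t_final=float(t_final),
        status=_STATUS[int(status)],
        event_counts=event_counts,
        reaction_time=float(rtime) if status == _engine.REACTED else None,
        time_averages=time_averages,
        positions=pos_out if record_positions else None,
        final_species=species_arr,
        final_positions=pos_arr,
    )


@dataclass
class EnsembleSummary:
    """Mean and standard error of per-trajectory observables."""

    n_trajectories: int
    base_seed: int
    observables: dict[str, np.ndarray]
    mean_counts: np.ndarray | None = None
    sample_times: np.ndarray | None = None

    def mean(self, name: str) -> float:
        return float(np.mean(self.observables[name]))

    def sem(self, name: str) -> float:
        x = self.observables[name]
        if len(x) < 2:
            return float("nan")
        return float(np.std(x, ddof=1) / math.sqrt(len(x)))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {k: (self.mean(k), self.sem(k)) for k in self.observables}


def run_ensemble(
    domain: LatticeDomain,
    species: list[SpeciesDef],
    network: ReactionNetwork,
    n_trajectories: int,
    base_seed: int,
    until: float,
    counts: dict[str, int] | None = None,
    average_window: float | None = None,
    stop_on_reaction: bool = False,
    engine: str = "auto",
    sample_times: np.ndarray | None = None,
) -> EnsembleSummary:
    """Run independent trajectories with seeds derived from ``base_seed``.

    Trajectory ``k`` draws its placement and dynamics seeds from
    ``SeedSequence([base_seed, k, stream])`` so results are reproducible
    bit-for-bit for a fixed ``base_seed`` and ordering.  Observables are the
    per-trajectory time-averaged species counts (when ``average_window``),
    final counts, and the reaction time (when ``stop_on_reaction``).
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    compiled = compile_network(domain, network)
    names = compiled.species_names
    obs: dict[str, list[float]] = {f"avg:{nm}": [] for nm in names}
    obs.update({f"final:{nm}": [] for nm in names})
    if stop_on_reaction:
        obs["reaction_time"] = []
    counts_acc = None
    for k in range(n_trajectories):
        w = build_world(domain, species, trajectory_seed(base_seed, k, 0), counts=counts)
        traj = simulate(
            w, network, until,
            sample_times=sample_times,
            average_window=average_window,
            stop_on_reaction=stop_on_reaction,
            engine=engine,
            seed=trajectory_seed(base_seed, k, 1),
            compiled=compiled,
        )
        final_counts = np.bincount(
            traj.final_species[traj.final_species >= 0], minlength=len(names)
        )
        for i, nm in enumerate(names):
            obs[f"final:{nm}"].append(float(final_counts[i]))
            if traj.time_averages is not None:
                obs[f"avg:{nm}"].append(traj.time_averages[nm])
        if stop_on_reaction:
            obs["reaction_time"].append(
                traj.reaction_time if traj.reaction_time is not None else float(until)
            )
        if sample_times is not None:
            if counts_acc is None:
                counts_acc = traj.counts.astype(np.float64)
            else:
                counts_acc += traj.counts
    return EnsembleSummary(
        n_trajectories=n_trajectories,
        base_seed=int(base_seed),
        observables={k: np.asarray(v) for k, v in obs.items() if len(v)},
        mean_counts=None if counts_acc is None else counts_acc / n_trajectories,
        sample_times=None if sample_times is None else np.asarray(sample_times, float),
    )
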