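"""Exactness and reproducibility of the stochastic simulator."""

import numpy as np
import pytest
from scipy import stats

from tethersim.fixtures import generate_fixture
from tethersim.lattice import (
    LatticeDomain,
    ReactionNetwork,
    SpeciesDef,
    UnimolecularRule,
    WorldState,
    build_world,
)
from tethersim.models import PushPullModel, steady_state_fraction
from tethersim.ssa import run_ensemble, simulate, trajectory_seed

ENGINES = ("direct", "uniformized")


@pytest.fixture(scope="module")
def static_pair():
    return generate_fixture("static-pair")


@pytest.mark.parametrize("engine", ENGINES)
def test_static_pair_waiting_time_is_exponential(static_pair, engine):
    """A single immobile reaction channel fires with an exponential clock."""
    w = static_pair.objects["world"]
    net = static_pair.objects["network"]
    rate = static_pair.expected["rate"]
    times = []
    for k in range(2000):
        tr = simulate(w, net, 100.0, stop_on_reaction=True, engine=engine,
                      seed=trajectory_seed(101, k, 1))
        times.append(tr.reaction_time)
    ks = stats.kstest(times, "expon", args=(0.0, 1.0 / rate))
    assert ks.pvalue > 0.01
    se = np.std(times, ddof=1) / np.sqrt(len(times))
    assert abs(np.mean(times) - 1.0 / rate) < 3 * se


def test_unimolecular_only_first_event_rate():
    """With n independent reactant copies the first conversion is Exp(n*lam)."""
    dom = LatticeDomain(2, 300.0, 32)
    lam, n = 0.7, 6
    net = ReactionNetwork(
        [SpeciesDef("A"), SpeciesDef("B")],
        [UnimolecularRule("A", "B", lam)],
    )
    firsts = []
    for k in range(2000):
        w = build_world(dom, [SpeciesDef("A", 0.0, n / 300.0**2), SpeciesDef("B")],
                        trajectory_seed(7, k, 0))
        # sample just after time zero onwards; first conversion time read from
        # the first sample where the A count drops
        tr = simulate(w, net, 20.0, stop_on_reaction=False,
                      sample_times=np.linspace(0.005, 20, 400),
                      engine="direct", seed=trajectory_seed(7, k, 1))
        a = tr.count_series("A")
        drop = np.argmax(a < n)
        firsts.append(tr.times[drop])
    ks = stats.kstest(firsts, "expon", args=(0.0, 1.0 / (n * lam)))
    # sampling at 50 ms resolution: compare means rather than the full KS
    se = np.std(firsts, ddof=1) / np.sqrt(len(firsts))
    assert abs(np.mean(firsts) - 1.0 / (n * lam)) < 3 * se + 0.05


@pytest.mark.parametrize("engine", ENGINES)
def test_mean_squared_displacement(engine):
    """Free diffusion: MSD = 2 d D t exactly on the periodic lattice."""
    dom = LatticeDomain(2, 300.0, 128, "periodic")
    D_nm = 0.01 * 1e6
    sp = SpeciesDef("M", 0.01)
    net = ReactionNetwork([sp])
    times = np.array([0.05, 0.1, 0.2])
    n_rep = 300
    msd = np.zeros(len(times))
    for k in range(n_rep):
        w = WorldState(dom, np.array([0]), np.array([[64, 64]]), seed=0)
        tr = simulate(w, net, 0.2001, sample_times=times, record_positions=True,
                      engine=engine, seed=trajectory_seed(55, k, 1))
        dx = (tr.positions[:, 0, :] - 64) * dom.spacing
        dx = np.where(dx > 150, dx - 300, np.where(dx < -150, dx + 300, dx))
        msd += np.sum(dx**2, axis=1)
    msd /= n_rep
    for i, t in enumerate(times):
        expected = 4 * D_nm * t
        # relative SE of an MSD estimate is ~sqrt(2/n) per axis pair
        assert abs(msd[i] - expected) < 4 * expected * np.sqrt(2.0 / n_rep)


def test_uniform_stationary_occupancy():
    """A single diffuser on a periodic lattice occupies voxels uniformly."""
    dom = LatticeDomain(2, 300.0, 8)
    sp = SpeciesDef("O", 0.01)
    net = ReactionNetwork([sp])
    t_mix = (300 / 2) ** 2 / (4 * 1e4)
    times = np.arange(1, 1501) * t_mix
    w = WorldState(dom, np.array([0]), np.array([[0, 0]]), seed=0)
    tr = simulate(w, net, times[-1] + 1, sample_times=times, record_positions=True,
                  engine="direct", seed=77)
    vox = tr.positions[:, 0, 0] * 8 + tr.positions[:, 0, 1]
    assert stats.chisquare(np.bincount(vox, minlength=64)).pvalue > 0.01


@pytest.mark.parametrize("engine", ENGINES)
def test_conservation_along_trajectory(engine):
    """S + S* and enzyme counts are conserved by every rule."""
    m = PushPullModel(voxels_per_axis=64, D_S=0.01, D_E=0.01, L_e=10.0)
    w = build_world(m.domain(), m.species(), 5)
    tr = simulate(w, m.network(), 30.0, sample_times=np.linspace(0.1, 30, 150),
                  engine=engine, seed=6)
    total = tr.count_series("S") + tr.count_series("S*")
    assert np.all(total == total[0])
    assert np.all(tr.count_series("E") == tr.count_series("E")[0])
    assert np.all(tr.count_series("F") == tr.count_series("F")[0])
    assert tr.event_counts["pair:S+E"] > 0


def test_pd1_conservation_and_events():
    from tethersim.models import PD1Model

    m = PD1Model(D=0.01, L=8.5, pd1_concentration=2e-4, voxels_per_axis=64)
    w = build_world(m.domain(), m.species(), 11)
    tr = simulate(w, m.network(), 10.0, sample_times=np.linspace(0.1, 10, 100),
                  engine="auto", seed=12)
    total = tr.count_series("CD28") + tr.count_series("CD28*")
    assert np.all(total == 9)
    assert np.all(tr.count_series("PD1") == 18)


def test_engines_agree_on_steady_state():
    """The direct and uniformized samplers draw from the same process."""
    m = PushPullModel(voxels_per_axis=64, D_S=0.003, D_E=0.003, L_e=10.0)
    r1 = steady_state_fraction(m, 120, 4, engine="direct")
    r2 = steady_state_fraction(m, 120, 4, engine="uniformized")
    gap = abs(r1.fraction - r2.fraction)
    assert gap < 3.5 * np.hypot(r1.sem, r2.sem)


def test_ensemble_reproducibility_and_seed_sensitivity():
    m = PushPullModel(voxels_per_axis=32, D_S=0.05, D_E=0.05, L_e=15.0)
    a = steady_state_fraction(m, 20, 9)
    b = steady_state_fraction(m, 20, 9)
    c = steady_state_fraction(m, 20, 10)
    assert a.fraction == b.fraction  # bit-for-bit for equal base seed
    assert a.fraction != c.fraction


def test_single_trajectory_ensemble_equals_trajectory():
    m = PushPullModel(voxels_per_axis=32, D_S=0.05, D_E=0.05, L_e=15.0)
    ens = run_ensemble(m.domain(), m.species(), m.network(), 1, 3,
                       until=5.0, average_window=2.5)
    tr_world = build_world(m.domain(), m.species(), trajectory_seed(3, 0, 0))
    tr = simulate(tr_world, m.network(), 5.0, average_window=2.5,
                  seed=trajectory_seed(3, 0, 1))
    assert ens.observables["avg:S*"][0] == pytest.approx(tr.time_averages["S*"])


def test_sem_scales_inversely_with_sqrt_n():
    """Ensemble standard error shrinks like 1/sqrt(n) between n=50 and n=200."""
    m = PushPullModel(voxels_per_axis=32, D_S=0.05, D_E=0.05, L_e=15.0)
    small = steady_state_fraction(m, 50, 21)
    large = steady_state_fraction(m, 200, 22)
    ratio = small.sem / large.sem
    assert 1.2 < ratio < 3.3  # expect ~2


def test_stalled_simulation_flag():
    dom = LatticeDomain(2, 300.0, 16)
    net = ReactionNetwork([SpeciesDef("A")])
    w = WorldState(dom, np.array([0]), np.array([[2, 2]]), seed=0)
    tr = simulate(w, net, 1.0, engine="direct", seed=1)  # immobile, no rules
    assert tr.status == "stalled"
    assert tr.t_final == 1.0


def test_refinement_stability_reaction_limited():
    """Doubling the mesh leaves the steady-state fraction within the noise
    (the voxel-averaged kernel preserves well-mixed rates at any h)."""
    base = dict(D_S=0.1, D_E=0.1, L_e=15.0)
    r16 = steady_state_fraction(PushPullModel(voxels_per_axis=16, **base), 150, 31)
    r32 = steady_state_fraction(PushPullModel(voxels_per_axis=32, **base), 150, 32)
    assert abs(r16.fraction - r32.fraction) <= 2.5 * np.hypot(r16.sem, r32.sem)
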