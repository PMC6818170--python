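"""Lattice geometry, molecule placement and discretized kernels."""

import math

import numpy as np
import pytest
from scipy import integrate

from tethersim.constants import convert_catalytic_3d
from tethersim.kernels import GaussianReachKernel, calibrate_doi, planar_integral_sigma3d
from tethersim.lattice import (
    LatticeDomain,
    PairwiseRule,
    SpeciesDef,
    axis_kernel_table,
    build_world,
    hop_propensity,
    pair_propensity,
    pair_separation,
)
from tethersim.ssa import compile_network
from tethersim.lattice import ReactionNetwork


def test_domain_properties():
    d = LatticeDomain(2, 300.0, 256)
    assert d.spacing == pytest.approx(300 / 256)
    assert d.n_voxels == 256**2
    assert d.measure == 300.0**2
    with pytest.raises(ValueError):
        LatticeDomain(4, 300.0, 64)
    with pytest.raises(ValueError):
        LatticeDomain(2, 300.0, 64, "absorbing")


def test_pair_separation_basic_and_wraparound():
    d = LatticeDomain(2, 300.0, 128, "periodic")
    h = d.spacing
    assert pair_separation(d, (5, 5), (5, 5)) == 0.0
    assert pair_separation(d, (5, 5), (6, 5)) == pytest.approx(h)
    # first and last voxel on one axis are adjacent through the boundary
    assert pair_separation(d, (0, 9), (127, 9)) == pytest.approx(h)
    assert pair_separation(d, (3, 4), (6, 8)) == pytest.approx(5 * h)
    r = LatticeDomain(2, 300.0, 128, "reflecting")
    assert pair_separation(r, (0, 9), (127, 9)) == pytest.approx(127 * h)
    # symmetry
    assert pair_separation(d, (3, 90), (100, 7)) == pair_separation(d, (100, 7), (3, 90))
    with pytest.raises(IndexError):
        pair_separation(d, (0, 0), (128, 0))


def test_hop_propensity():
    d = LatticeDomain(2, 300.0, 256)
    sp = SpeciesDef("X", diffusivity=0.1)
    assert hop_propensity(sp, d) == pytest.approx(1e5 / (300 / 256) ** 2)
    assert hop_propensity(SpeciesDef("Y", 0.0), d) == 0.0


def test_build_world_counts_and_determinism():
    d = LatticeDomain(2, 300.0, 128, "periodic")
    cd28 = SpeciesDef("CD28", 0.1, 1e-4)  # 0.0001 nm^-2 on 300x300 -> 9 copies
    zero = SpeciesDef("Z", 0.0, 0.0)
    w = build_world(d, [cd28, zero], seed=42)
    assert int(np.sum(w.species == 0)) == 9
    assert int(np.sum(w.species == 1)) == 0
    w2 = build_world(d, [cd28, zero], seed=42)
    assert np.array_equal(w.positions, w2.positions)
    w3 = build_world(d, [cd28, zero], seed=43)
    assert not np.array_equal(w.positions, w3.positions)


def test_build_world_rounding_warning():
    d = LatticeDomain(2, 300.0, 128)
    tiny = SpeciesDef("T", 0.0, 1.6e-5)  # 1.44 molecules -> rounds to 1 (>5% off)
    with pytest.warns(UserWarning, match="rounding"):
        build_world(d, [tiny], seed=0)


def test_pair_propensity_contract():
    kcat = convert_catalytic_3d(0.1)
    ker = GaussianReachKernel(8.5, kcat, 3)
    rule = PairwiseRule("A", "B", None, None, ker)
    # contact propensity with the tabulated efficiency is ~89 per second
    assert pair_propensity(rule, 0.0) == pytest.approx(
        kcat * (3 / (2 * math.pi * 8.5**2)) ** 1.5, rel=1e-12
    )
    assert pair_propensity(rule, 0.0) == pytest.approx(89.0, rel=0.01)
    assert pair_propensity(rule, 4.5 * 8.5 + 0.1) == 0.0
    cal = calibrate_doi(ker)
    irule = PairwiseRule("A", "B", None, None, cal)
    assert pair_propensity(irule, cal.epsilon * 0.99) == cal.lam
    assert pair_propensity(irule, cal.epsilon * 1.01) == 0.0
    with pytest.raises(ValueError):
        pair_propensity(rule, -1.0)


@pytest.mark.parametrize("L", [1.0, 8.5, 70.0])
@pytest.mark.parametrize("mesh", [32, 128])
def test_axis_table_is_unit_mass_and_matches_quadrature(L, mesh):
    """Voxel averaging preserves the 1D mass exactly and matches brute-force
    integration entry by entry."""
    d = LatticeDomain(2, 300.0, mesh, "periodic")
    g = axis_kernel_table(L, d)
    h = d.spacing
    assert np.sum(g) * h == pytest.approx(1.0, rel=1e-9)
    s = L / math.sqrt(3)
    phi = lambda x: math.exp(-0.5 * (x / s) ** 2) / (s * math.sqrt(2 * math.pi))
    for k in (0, 1, 3):
        brute = 0.0
        for img in (-1, 0, 1):
            val, _ = integrate.dblquad(
                lambda u, v: phi((k + img * mesh) * h + u - v), 0, h, 0, h
            )
            brute += val / h**2
        assert g[k] == pytest.approx(brute, rel=1e-7, abs=1e-15)


def test_compiled_kernel_preserves_well_mixed_rate():
    """Sum of tabulated pair rates over the lattice times the voxel area equals
    the continuum planar rate constant kcat * integral of sigma3d."""
    kcat = convert_catalytic_3d(0.04)
    for L, mesh in ((1.0, 32), (15.0, 64), (70.0, 128)):
        d = LatticeDomain(2, 300.0, mesh, "periodic")
        ker = GaussianReachKernel(L, kcat, 3)
        net = ReactionNetwork(
            [SpeciesDef("A"), SpeciesDef("B")],
            [],
            [PairwiseRule("A", "B", None, None, ker, r_cut_factor=1e9)],
        )
        c = compile_network(d, net)
        g = c.tables[0]
        total = c.pair_amp[0] * np.sum(g) ** 2 * d.spacing**2
        k_rl = kcat * planar_integral_sigma3d(L)
        assert total == pytest.approx(k_rl, rel=1e-9)


def test_network_validation():
    a, b = SpeciesDef("A"), SpeciesDef("B")
    ker = GaussianReachKernel(5.0, 1.0, 3)
    with pytest.raises(ValueError, match="duplicate"):
        ReactionNetwork([a, a])
    with pytest.raises(ValueError, match="unknown species"):
        ReactionNetwork([a], pairwise=[PairwiseRule("A", "C", None, None, ker)])
    with pytest.raises(ValueError, match="distinct"):
        ReactionNetwork([a, b], pairwise=[PairwiseRule("A", "A", None, None, ker)])
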