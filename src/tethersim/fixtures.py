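"""Named small scenarios with machine-checkable expected properties.

Each fixture returns the runnable objects plus the exact or analytic
expectations the test suite verifies against; every fixture runs end-to-end
in well under a minute on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .constants import convert_catalytic_3d
from .kernels import GaussianReachKernel, calibrate_doi
from .lattice import (
    LatticeDomain,
    PairwiseRule,
    ReactionNetwork,
    SpeciesDef,
    WorldState,
)
from .mrt import DoiProblem, equal_measure_radius, exact_mrt_2d_disc
from .ssa import compile_network

__all__ = ["Fixture", "generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("static-pair", "hill-curve", "doi-two-particle", "pushpull-micro")


@dataclass
class Fixture:
    name: str
    objects: dict[str, Any]
    expected: dict[str, Any]


def generate_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a named fixture; raises KeyError for unknown names."""
    if name == "static-pair":
        return _static_pair(seed)
    if name == "hill-curve":
        return _hill_curve(seed)
    if name == "doi-two-particle":
        return _doi_two_particle(seed)
    if name == "pushpull-micro":
        return _pushpull_micro(seed)
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _static_pair(seed: int) -> Fixture:
    """Two immobile molecules at a fixed 2-voxel separation.

    The single reaction channel fires with an exponential clock, so the
    reaction time is Exponential(rate) with the tabulated voxel-averaged
    rate returned under ``expected['rate']``.
    """
    domain = LatticeDomain(2, 300.0, 128, "periodic")
    kernel = GaussianReachKernel(8.5, convert_catalytic_3d(0.1), 3)
    net = ReactionNetwork(
        [SpeciesDef("A"), SpeciesDef("B")],
        [],
        [PairwiseRule("A", "B", None, None, kernel)],
    )
    world = WorldState(
        domain,
        np.array([0, 1], dtype=np.int64),
        np.array([[10, 10], [12, 10]], dtype=np.int64),
        seed=seed,
    )
    compiled = compile_network(domain, net)
    rate = float(compiled.pair_amp[0] * compiled.tables[0][2] * compiled.tables[0][0])
    return Fixture(
        name="static-pair",
        objects={"domain": domain, "network": net, "world": world},
        expected={"rate": rate, "mean_reaction_time": 1.0 / rate},
    )


def _hill_curve(seed: int) -> Fixture:
    """Synthetic inhibitor dose-response with known c50 = 10 and 1% noise."""
    rng = np.random.default_rng(seed)
    c0 = 10.0
    conc = np.geomspace(1.0, 100.0, 12)
    clean = 1.0 / (1.0 + conc / c0)
    noisy = clean + rng.normal(0.0, 0.01, size=conc.shape)
    return Fixture(
        name="hill-curve",
        objects={"concentrations": conc, "fractions": noisy, "clean": clean},
        expected={"c50": c0, "noise_sd": 0.01},
    )


def _doi_two_particle(seed: int) -> Fixture:
    """One fixed + one diffusing molecule with a calibrated indicator rule.

    The expected mean reaction time is the analytic well-mixed MRT on the
    equal-area disc; simulation on the reflecting square matches it within
    Monte-Carlo error at the chosen (D, L).
    """
    D_um, L = 1.25e-3, 25.0
    kcat = convert_catalytic_3d(0.1)
    cal = calibrate_doi(GaussianReachKernel(L, kcat, 3))
    domain = LatticeDomain(2, 300.0, 128, "reflecting")
    net = ReactionNetwork(
        [SpeciesDef("A", 0.0), SpeciesDef("B", D_um)],
        [],
        [PairwiseRule("A", "B", None, None, cal)],
    )
    R = equal_measure_radius(300.0, 2)
    T = exact_mrt_2d_disc(DoiProblem(2, R, D_um * 1e6, cal.epsilon, cal.lam)).T
    c = domain.voxels_per_axis // 2
    rng = np.random.default_rng(seed)
    posB = rng.integers(0, domain.voxels_per_axis, size=2)
    world = WorldState(
        domain,
        np.array([0, 1], dtype=np.int64),
        np.array([[c, c], list(posB)], dtype=np.int64),
        seed=seed,
    )
    return Fixture(
        name="doi-two-particle",
        objects={"domain": domain, "network": net, "world": world,
                 "calibration": cal, "D_um2_s": D_um, "L_nm": L},
        expected={"mean_reaction_time": T, "disc_radius": R},
    )


def _pushpull_micro(seed: int) -> Fixture:
    """9-substrate push–pull micro-world for conservation checks."""
    from .models import PushPullModel

    model = PushPullModel(voxels_per_axis=64, D_S=0.01, D_E=0.01, L_e=10.0)
    expected_counts = {
        "S_total": 9,   # 100 um^-2 on the 300 nm square
        "F": 10,        # 112 um^-2
        "E": 11,        # 125 um^-2
    }
    return Fixture(
        name="pushpull-micro",
        objects={"model": model},
        expected=expected_counts,
    )
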