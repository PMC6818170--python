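"""TOML configuration loading with unit-suffixed keys.

Quantities are declared with explicit units in the key name
(``side_nm``, ``diffusivity_um2_s``, ``kcat_uM_s``, ``rate_per_s``...) and
normalized to internal nm/s units on load.  Model sections apply the
tabulated defaults for omitted fields; validation collects every offending
key before raising.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .kernels import DoiCalibration, GaussianReachKernel
from .lattice import LatticeDomain, PairwiseRule, ReactionNetwork, SpeciesDef, UnimolecularRule
from .models import PD1Model, PushPullModel

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the full list of invalid keys/values."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    model: PD1Model | PushPullModel | None = None
    domain: LatticeDomain | None = None
    species: list[SpeciesDef] = field(default_factory=list)
    network: ReactionNetwork | None = None
    sweep_variable: str | None = None
    sweep_values: np.ndarray | None = None
    n_trajectories: int = 200
    base_seed: int = 1
    t_end: float | None = None
    engine: str = "auto"
    raw: dict[str, Any] = field(default_factory=dict, repr=False)


_PD1_FIELDS = {
    "D_um2_s": "D",
    "pd1_concentration_per_nm2": "pd1_concentration",
    "cd28_concentration_per_nm2": "cd28_concentration",
    "phosphorylation_rate_per_s": "lam",
    "kcat_uM_s": "kcat",
    "reach_nm": "L",
    "kernel_dimension": "kernel_dimension",
    "side_nm": "side",
    "voxels_per_axis": "voxels_per_axis",
    "dimension": "dimension",
}

_PUSHPULL_FIELDS = {
    "substrate_concentration_per_um2": "substrate_concentration",
    "kinase_concentration_per_um2": "kinase_concentration",
    "phosphatase_concentration_per_um2": "phosphatase_concentration",
    "D_substrate_um2_s": "D_S",
    "D_kinase_um2_s": "D_E",
    "D_phosphatase_um2_s": "D_F",
    "kcat_kinase_uM_s": "kcat_e_3d",
    "kcat_phosphatase_uM_s": "kcat_f_3d",
    "kcat_kinase_uM_s_m": "kcat_e_2d",
    "kcat_phosphatase_uM_s_m": "kcat_f_2d",
    "kinase_reach_nm": "L_e",
    "phosphatase_reach_nm": "L_f",
    "kernel_dimension": "kernel_dimension",
    "side_nm": "side",
    "voxels_per_axis": "voxels_per_axis",
    "dimension": "dimension",
}


def _map_fields(section: dict, mapping: dict, problems: list, where: str) -> dict:
    out = {}
    for key, val in section.items():
        if key not in mapping:
            problems.append(f"{where}: unknown key {key!r}")
            continue
        out[mapping[key]] = val
    return out


def _parse_species(items: list, problems: list) -> list[SpeciesDef]:
    out = []
    for i, item in enumerate(items):
        where = f"species[{i}]"
        kwargs = {}
        for key, val in item.items():
            if key == "name":
                kwargs["name"] = val
            elif key == "diffusivity_um2_s":
                kwargs["diffusivity"] = val
            elif key in ("concentration_per_nm2", "concentration_per_nm3"):
                kwargs["initial_concentration"] = val
            else:
                problems.append(f"{where}: unknown key {key!r}")
        try:
            out.append(SpeciesDef(**kwargs))
        except (TypeError, ValueError) as exc:
            problems.append(f"{where}: {exc}")
    return out


def _parse_kernel(item: dict, problems: list, where: str):
    kind = item.get("kernel", "gaussian")
    if kind == "indicator":
        try:
            return DoiCalibration(epsilon=item["epsilon_nm"], lam=item["lambda_per_s"])
        except KeyError as exc:
            problems.append(f"{where}: indicator kernel missing {exc}")
            return None
    kd = int(item.get("kernel_dimension", 3))
    from .constants import convert_catalytic_2d, convert_catalytic_3d

    if kd == 3 and "kcat_uM_s" in item:
        k = convert_catalytic_3d(item["kcat_uM_s"])
    elif kd == 2 and "kcat_uM_s_m" in item:
        k = convert_catalytic_2d(item["kcat_uM_s_m"])
    elif "kcat_nm_s" in item:
        k = item["kcat_nm_s"]
    else:
        problems.append(f"{where}: no catalytic efficiency given (kcat_uM_s / kcat_uM_s_m / kcat_nm_s)")
        return None
    try:
        return GaussianReachKernel(item["reach_nm"], k, kd)
    except KeyError:
        problems.append(f"{where}: gaussian kernel requires reach_nm")
        return None
    except ValueError as exc:
        problems.append(f"{where}: {exc}")
        return None


def load_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a TOML run configuration (or an equivalent dict)."""
    if isinstance(path, dict):
        data = path
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    problems: list[str] = []
    cfg = RunConfig(raw=data)

    known_top = {"model", "domain", "species", "reactions", "sweep", "run"}
    for key in data:
        if key not in known_top:
            problems.append(f"unknown top-level section {key!r}")

    if "model" in data:
        sec = dict(data["model"])
        kind = sec.pop("kind", None)
        if kind == "pd1":
            kwargs = _map_fields(sec, _PD1_FIELDS, problems, "model")
            try:
                cfg.model = PD1Model(**kwargs)
            except (TypeError, ValueError) as exc:
                problems.append(f"model: {exc}")
        elif kind == "pushpull":
            kwargs = _map_fields(sec, _PUSHPULL_FIELDS, problems, "model")
            try:
                cfg.model = PushPullModel(**kwargs)
            except (TypeError, ValueError) as exc:
                problems.append(f"model: {exc}")
        else:
            problems.append(f"model.kind must be 'pd1' or 'pushpull', got {kind!r}")

    if "domain" in data:
        sec = data["domain"]
        kwargs = {}
        for key, val in sec.items():
            if key == "dimension":
                kwargs["dimension"] = val
            elif key == "side_nm":
                kwargs["side"] = val
            elif key == "voxels_per_axis":
                kwargs["voxels_per_axis"] = val
            elif key == "boundary":
                kwargs["boundary"] = val
            else:
                problems.append(f"domain: unknown key {key!r}")
        try:
            cfg.domain = LatticeDomain(**kwargs)
        except (TypeError, ValueError) as exc:
            problems.append(f"domain: {exc}")

    if "species" in data:
        cfg.species = _parse_species(data["species"], problems)

    if "reactions" in data:
        uni = []
        for i, item in enumerate(data["reactions"].get("unimolecular", [])):
            try:
                uni.append(
                    UnimolecularRule(item["reactant"], item["product"], item["rate_per_s"])
                )
            except (KeyError, ValueError) as exc:
                problems.append(f"reactions.unimolecular[{i}]: {exc}")
        pair = []
        for i, item in enumerate(data["reactions"].get("pairwise", [])):
            where = f"reactions.pairwise[{i}]"
            ker = _parse_kernel(item, problems, where)
            if ker is None:
                continue
            try:
                ra, rb = item["reactants"]
                prods = item.get("products", [None, None])
                pair.append(PairwiseRule(ra, rb, prods[0], prods[1], ker))
            except (KeyError, ValueError) as exc:
                problems.append(f"{where}: {exc}")
        if cfg.species:
            try:
                cfg.network = ReactionNetwork(cfg.species, uni, pair)
            except ValueError as exc:
                problems.append(f"reactions: {exc}")

    if "sweep" in data:
        sec = data["sweep"]
        cfg.sweep_variable = sec.get("variable")
        vals = sec.get("values")
        if vals is None:
            problems.append("sweep: missing 'values'")
        else:
            cfg.sweep_values = np.asarray(vals, dtype=float)
        for key in sec:
            if key not in ("variable", "values"):
                problems.append(f"sweep: unknown key {key!r}")

    if "run" in data:
        sec = data["run"]
        for key, val in sec.items():
            if key == "n_trajectories":
                cfg.n_trajectories = int(val)
            elif key == "base_seed":
                cfg.base_seed = int(val)
            elif key == "t_end_s":
                cfg.t_end = float(val)
            elif key == "engine":
                cfg.engine = str(val)
            else:
                problems.append(f"run: unknown key {key!r}")

    if problems:
        raise ConfigError(problems)
    return cfg
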