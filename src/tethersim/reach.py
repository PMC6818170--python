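"""Worm-like-chain molecular reach arithmetic.

The molecular reach ``L`` of a tethered reaction summarizes how far the
reactive site of a membrane-anchored species can extend from its anchor.
For an unstructured peptide modeled as a worm-like chain with persistence
length ``l_p`` and contour length ``l_c``, the reach is ``sqrt(l_p * l_c)``.
Reaches of independent reaction components (receptor tail, enzyme, substrate
tail) combine as the root of the sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

#: Persistence length of unstructured amino-acid chains, nm.
DEFAULT_PERSISTENCE_LENGTH = 0.4

#: Cα–Cα bond length per residue, nm.
DEFAULT_BOND_LENGTH = 0.4


def contour_length(residue_count: int, bond_length: float = DEFAULT_BOND_LENGTH) -> float:
    """Contour length ``l_c = bond_length * N`` in nm.

    ``residue_count`` is the number of amino acids between the membrane
    anchor and the reactive site.
    """
    if residue_count < 0:
        raise ValueError(f"residue_count must be >= 0, got {residue_count}")
    if bond_length <= 0:
        raise ValueError(f"bond_length must be > 0, got {bond_length}")
    return bond_length * residue_count


def wlc_reach(persistence_length: float, contour_length: float) -> float:
    """Worm-like-chain reach ``sqrt(l_p * l_c)`` in nm."""
    if persistence_length < 0 or contour_length < 0:
        raise ValueError("persistence_length and contour_length must be >= 0")
    return math.sqrt(persistence_length * contour_length)


def combined_reach(components: Sequence[float]) -> float:
    """Combine component reaches as ``sqrt(sum(L_i**2))``.

    Permutation invariant and never smaller than the largest component.
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one reach component")
    if any(c < 0 for c in comps):
        raise ValueError("reach components must be >= 0")
    return math.sqrt(sum(c * c for c in comps))


@dataclass(frozen=True)
class WLCComponent:
    """One worm-like-chain component of a tethered reaction.

    Attributes
    ----------
    residue_count : number of amino acids between anchor and reactive site.
    persistence_length : nm.
    bond_length : nm per residue.
    """

    residue_count: int
    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH
    bond_length: float = DEFAULT_BOND_LENGTH

    def __post_init__(self) -> None:
        if self.residue_count < 0:
            raise ValueError("residue_count must be >= 0")
        if self.persistence_length < 0:
            raise ValueError("persistence_length must be >= 0")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")

    @property
    def contour_length(self) -> float:
        return contour_length(self.residue_count, self.bond_length)

    @property
    def reach(self) -> float:
        return wlc_reach(self.persistence_length, self.contour_length)


@dataclass(frozen=True)
class ReachParameter:
    """Molecular reach of a full reaction, optionally built from components."""

    value: float
    components: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("reach must be >= 0")

    @classmethod
    def from_components(cls, components: Sequence[float]) -> "ReachParameter":
        return cls(value=combined_reach(components), components=tuple(components))
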