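"""Physical constants and unit conversions.

Internal canonical units are nanometres, seconds and molecule counts.
Conversions from the bench units used in parameter tables (``μM⁻¹ s⁻¹``
catalytic efficiencies, ``μm² s⁻¹`` diffusivities, ``μm⁻²`` densities)
happen once, at the configuration boundary.
"""

from __future__ import annotations

#: Avogadro constant, mol⁻¹.  The slightly rounded historical value is kept
#: as the default because the tabulated 2D catalytic rates in the source
#: parameter set (221.3736, 55.3434, 553.4341 nm² s⁻¹) are reproduced to five
#: significant figures with it and not with the CODATA value.
AVOGADRO = 6.023e23

#: nm² per μm².
UM2_TO_NM2 = 1.0e6

#: nm⁻² per μm⁻².
PER_UM2_TO_PER_NM2 = 1.0e-6


def convert_catalytic_3d(k_uM: float, avogadro: float = AVOGADRO) -> float:
    """Convert a 3D catalytic efficiency from μM⁻¹ s⁻¹ to nm³ s⁻¹.

    1 μM = 1e-6 mol/L = ``1e-6 * N_A / 1e24 nm³`` molecules per nm³, hence
    1 μM⁻¹ = ``1e30 / N_A`` nm³.

    Parameters
    ----------
    k_uM : catalytic efficiency in μM⁻¹ s⁻¹ (must be >= 0).
    avogadro : Avogadro constant in mol⁻¹.
    """
    if k_uM < 0:
        raise ValueError(f"catalytic efficiency must be >= 0, got {k_uM}")
    if avogadro <= 0:
        raise ValueError(f"Avogadro constant must be > 0, got {avogadro}")
    return k_uM * 1.0e30 / avogadro


def convert_catalytic_2d(k_uM_per_m: float, avogadro: float = AVOGADRO) -> float:
    """Convert a 2D catalytic efficiency from μM⁻¹ s⁻¹ m⁻¹ to nm² s⁻¹.

    The idealized in-plane kernel carries units of inverse area, so the
    catalytic efficiency carries an extra inverse length (1 m = 1e9 nm)
    relative to the 3D convention.
    """
    return convert_catalytic_3d(k_uM_per_m, avogadro) / 1.0e9
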