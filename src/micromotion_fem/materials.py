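"""Isotropic linear-elastic material catalog.

All moduli are in MPa, consistent with lengths in micrometres: stresses come
out in MPa and strains are dimensionless. The catalog holds the probe and
tissue materials used throughout: stiff silicon, polyimide, the
polyvinyl-acetate cellulose-nanocrystal composite (PVAc-NC) in its soft
post-insertion state, a hypothetical probe whose modulus matches brain
tissue, and cortical grey matter itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Material", "lame_parameters", "material_catalog", "BRAIN_E_DEFAULT"]

#: Default brain elastic modulus, MPa. Cortical grey matter is ~6 kPa; on
#: this value the silicon shank is effectively rigid relative to the tissue
#: foundation, which is what produces the tip-dominated strain fields. A
#: megapascal-scale tissue modulus (sometimes quoted as 6,000 kPa) makes the
#: shank flexible at foundation scale and moves the maximum to the top for
#: every probe material; it can be run via the ``brain_E`` override.
BRAIN_E_DEFAULT = 6e-3


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Convert Young's modulus and Poisson ratio to Lamé constants.

    Parameters
    ----------
    E : float
        Elastic modulus, MPa. Must be positive.
    nu : float
        Poisson ratio, dimensionless, in ``[0, 0.5)``. The incompressible
        limit ``nu = 0.5`` is rejected (lambda diverges).

    Returns
    -------
    (lam, mu) : tuple of float
        First Lamé constant and shear modulus, MPa.
    """
    if E <= 0:
        raise ValueError(f"elastic modulus must be positive, got {E}")
    if not 0 <= nu < 0.5:
        raise ValueError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material.

    Attributes
    ----------
    name : str
    E : float
        Elastic modulus, MPa.
    nu : float
        Poisson ratio, dimensionless.
    lam, mu : float
        Lamé constants (MPa), derived from ``E`` and ``nu`` on construction.
    """

    name: str
    E: float
    nu: float
    lam: float = field(init=False)
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        lam, mu = lame_parameters(self.E, self.nu)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)


def material_catalog(brain_E: float = BRAIN_E_DEFAULT) -> dict[str, Material]:
    """Build the probe/tissue material catalog.

    Parameters
    ----------
    brain_E : float
        Brain (and hence hypothetical-probe) elastic modulus in MPa.
        Default 6e-3 MPa (6 kPa grey matter); pass ``6.0`` to run the
        megapascal reading instead.

    Returns
    -------
    dict mapping name to :class:`Material`. ``pvac_nc_pre`` is the stiff
    pre-insertion state of the composite, catalogued for reference but not
    used in any shipped simulation case.
    """
    return {
        "silicon": Material("silicon", 2.0e5, 0.278),
        "polyimide": Material("polyimide", 2.7e3, 0.33),
        "pvac_nc": Material("pvac_nc", 12.7, 0.3),
        "pvac_nc_pre": Material("pvac_nc_pre", 5.2e3, 0.38),
        "hypothetical": Material("hypothetical", brain_E, 0.33),
        "brain": Material("brain", brain_E, 0.45),
    }
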