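"""Elastic material properties for the layered long-bone model.

Internal unit system: lengths in mm, times in µs, densities in g/cm³.
Velocities are then mm/µs ≡ km/s and every printed number used by the
model enters without conversion factors. Lamé moduli come out in
g/cm³·(mm/µs)² = GPa.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidMaterialError(ValueError):
    """Material parameters violate physical constraints."""


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic elastic solid (or near-fluid) with attenuation.

    Parameters
    ----------
    density : float
        Mass density in g/cm³.
    v_long : float
        Bulk longitudinal wave velocity in mm/µs (≡ km/s).
    v_shear : float
        Bulk shear wave velocity in mm/µs.
    attenuation : float
        Amplitude attenuation coefficient in dB·cm⁻¹·MHz⁻¹.
    """

    density: float
    v_long: float
    v_shear: float = 0.0
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidMaterialError(f"density must be > 0, got {self.density}")
        if self.v_shear < 0:
            raise InvalidMaterialError(f"v_shear must be >= 0, got {self.v_shear}")
        if self.v_long <= self.v_shear:
            raise InvalidMaterialError(
                f"v_long ({self.v_long}) must exceed v_shear ({self.v_shear})"
            )
        if self.attenuation < 0:
            raise InvalidMaterialError(f"attenuation must be >= 0, got {self.attenuation}")


@dataclass(frozen=True)
class ElasticPlate:
    """A free plate of one material, the waveguide of the Lamb problem."""

    material: ElasticMaterial
    thickness_h: float  # mm

    def __post_init__(self) -> None:
        if self.thickness_h <= 0:
            raise InvalidMaterialError(f"thickness_h must be > 0, got {self.thickness_h}")


def lame_from_velocities(material: ElasticMaterial) -> tuple[float, float]:
    """Convert (ρ, V_L, V_T) to Lamé parameters (λ, μ).

    μ = ρ·V_T², λ = ρ·(V_L² − 2·V_T²).  Raises
    :class:`InvalidMaterialError` when λ would be negative
    (V_L < V_T·√2, unphysical for an isotropic solid).
    """
    mu = material.density * material.v_shear**2
    lam = material.density * (material.v_long**2 - 2.0 * material.v_shear**2)
    if lam < 0:
        raise InvalidMaterialError(
            f"negative lambda: v_long={material.v_long} < sqrt(2)*v_shear"
        )
    return lam, mu


def velocities_from_lame(lam: float, mu: float, density: float) -> tuple[float, float]:
    """Inverse of :func:`lame_from_velocities`: returns (V_L, V_T)."""
    v_shear = (mu / density) ** 0.5
    v_long = ((lam + 2.0 * mu) / density) ** 0.5
    return v_long, v_shear


# Reference tissue parameters of the bone model (ρ g/cm³, V_L km/s, V_T km/s,
# attenuation dB·cm⁻¹·MHz⁻¹). The marrow density is 1.00 g/cm³: soft biological
# tissue; the 0.10 sometimes quoted for marrow is nonphysical by an order of
# magnitude and is treated as a typo (overridable through the config layer).
CORTICAL_BONE = ElasticMaterial(density=2.00, v_long=4.20, v_shear=2.00, attenuation=5.09)
SOFT_TISSUE = ElasticMaterial(density=0.92, v_long=1.47, v_shear=0.10, attenuation=1.20)
MARROW = ElasticMaterial(density=1.00, v_long=1.40, v_shear=0.07, attenuation=0.80)

#: Cortical thickness of the default model (mm); with the 100 kHz excitation
#: this puts operation at f·h = 0.4 MHz·mm, below the first higher-mode cutoff.
DEFAULT_CORTICAL_THICKNESS = 4.0
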