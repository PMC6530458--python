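"""Elastic wall-material bookkeeping.

Holds the linear-elastic constants of the pharyngeal wall (modulus of
elasticity E, Poisson ratio ν, density), converts them to Lamé constants
and Neo-Hookean strain-energy coefficients, and provides the linear
silicone-thinner → modulus calibration used to fabricate soft replica
walls.

The Neo-Hookean coefficients are recorded for bookkeeping only; the
quasi-1D solver consumes (E, ν) through the tube law, never C1/D1.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElasticMaterial:
    """Linear-elastic wall material.

    Parameters
    ----------
    E : float
        Modulus of elasticity in Pa.  Must be positive.
    nu : float
        Poisson ratio, dimensionless, in [0, 0.5).
    density : float
        Material density in kg/m³.  Must be positive.
    """

    E: float
    nu: float = 0.48
    density: float = 1080.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"modulus of elasticity must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(
                f"Poisson ratio must lie in [0, 0.5); nu={self.nu} "
                "(nu = 0.5 is incompressible and has no finite Lamé lambda)"
            )
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")

    def to_config(self) -> dict:
        """Serialize to the JSON config keys."""
        return {"E_pa": self.E, "nu": self.nu, "density_kg_m3": self.density}

    @classmethod
    def from_config(cls, cfg: dict) -> "ElasticMaterial":
        return cls(E=cfg["E_pa"], nu=cfg.get("nu", 0.48),
                   density=cfg.get("density_kg_m3", 1080.0))


#: Ecoflex-style silicone preset (ν = 0.48, ρ = 1080 kg/m³) at its stiffest mix.
SILICONE = ElasticMaterial(E=30e3, nu=0.48, density=1080.0)

#: Soft tissue-like preset (E = 2 kPa).
TISSUE_LIKE = ElasticMaterial(E=2e3, nu=0.48, density=1080.0)


@dataclass(frozen=True)
class LameConstants:
    """First Lamé constant λ and shear modulus μ, both in Pa."""

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"shear modulus must be positive, got {self.mu}")
        if self.lam < 0:
            raise ValueError(f"first Lamé constant must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class NeoHookeanCoeffs:
    """Neo-Hookean strain-energy coefficients C1 = μ/2 and D1 = λ/2 (Pa).

    D1 is stored exactly as λ/2.  Note that finite-element packages often
    parameterize the volumetric term as 2/K with K the bulk modulus; this
    record keeps the λ/2 convention and nothing downstream consumes it.
    """

    C1: float
    D1: float

    def __post_init__(self) -> None:
        if not self.C1 > 0:
            raise ValueError(f"C1 must be positive, got {self.C1}")


def lame_constants(material: ElasticMaterial) -> LameConstants:
    """Lamé constants from (E, ν).

    λ = νE / ((1+ν)(1−2ν)),  μ = E / (2(1+ν)).

    Raises
    ------
    ValueError
        If ν ≥ 0.5 (incompressible limit) or E ≤ 0; enforced by
        :class:`ElasticMaterial`.
    """
    E, nu = material.E, material.nu
    lam = nu * E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return LameConstants(lam=lam, mu=mu)


def neo_hookean_coeffs(lc: LameConstants) -> NeoHookeanCoeffs:
    """Neo-Hookean coefficients C1 = μ/2 and D1 = λ/2 from Lamé constants."""
    return NeoHookeanCoeffs(C1=lc.mu / 2.0, D1=lc.lam / 2.0)


def elastic_from_lame(lc: LameConstants) -> ElasticMaterial:
    """Invert :func:`lame_constants`: E = μ(3λ+2μ)/(λ+μ), ν = λ/(2(λ+μ))."""
    E = lc.mu * (3.0 * lc.lam + 2.0 * lc.mu) / (lc.lam + lc.mu)
    nu = lc.lam / (2.0 * (lc.lam + lc.mu))
    return ElasticMaterial(E=E, nu=nu)


# Endpoints of the measured thinner → modulus calibration line:
# 0 % thinner -> 30 kPa, 25 % thinner by weight -> 15 kPa.
_THINNER_E0 = 30e3
_THINNER_SLOPE = -60e3  # Pa per unit mass fraction


def modulus_from_thinner(w: float) -> float:
    """Modulus of elasticity (Pa) of thinned silicone.

    Linear calibration through the two measured endpoints:
    E(w) = 30 kPa − 60 kPa · w for thinner mass fraction w ∈ [0, 0.25].
    Extrapolation outside the calibrated range is refused.
    """
    if not (0.0 <= w <= 0.25):
        raise ValueError(
            f"thinner mass fraction {w} outside calibrated range [0, 0.25]"
        )
    return _THINNER_E0 + _THINNER_SLOPE * w
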