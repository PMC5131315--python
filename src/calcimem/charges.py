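"""Electronic-continuum charge scaling and system-composition arithmetic.

Non-polarisable force fields neglect electronic polarisation of the medium.
The electronic continuum correction (ECC) recovers it in a mean-field way by
scaling ionic charges with f = 1/sqrt(ε_el), where ε_el ≈ 1.78 is the
electronic (optical-frequency, n²) part of the water dielectric constant.
For water this gives f ≈ 0.75, so Ca²⁺ carries +1.5e and Cl⁻ −0.75e in
simulation.  Lipid charges are left unscaled: the headgroup charges of the
underlying lipid force field already absorb polarisation implicitly, and
only then does a +1.5e cation count of 16 exactly neutralise 24 anionic
lipids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "WATER_MOLARITY",
    "ScaledChargeSet",
    "CompositionSpec",
    "scaling_factor",
    "scale_charges",
    "neutralizing_cation_count",
    "nominal_concentration",
    "ion_pairs_for_concentration",
]

#: Molar concentration of pure water (mol/L); the conversion constant for
#: "concentration with respect to the number of water molecules".
WATER_MOLARITY = 55.51

#: Electronic (optical-frequency) dielectric constant of water, n² at
#: visible wavelengths.
EPS_ELECTRONIC_WATER = 1.78


def scaling_factor(eps_electronic: float = EPS_ELECTRONIC_WATER) -> float:
    """ECC charge-scaling factor f = 1/sqrt(ε_el), full precision.

    Use ``round(f, 2)`` for the conventional displayed value (0.75 for
    water).  ε_el must exceed 1: a medium cannot be less polarisable than
    vacuum.
    """
    if eps_electronic <= 0:
        raise ValueError(f"eps_electronic must be positive, got {eps_electronic}")
    if eps_electronic < 1:
        raise ValueError(
            f"eps_electronic must be ≥ 1 (vacuum limit), got {eps_electronic}"
        )
    return 1.0 / math.sqrt(eps_electronic)


@dataclass
class ScaledChargeSet:
    """Formal and ECC-scaled charges per ionic species (units of e)."""

    factor: float
    formal: dict[str, float]
    scaled: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.factor <= 1):
            raise ValueError(f"scaling factor must be in (0, 1], got {self.factor}")
        self.scaled = {sp: self.factor * q for sp, q in self.formal.items()}


def scale_charges(formal: dict[str, float], f: float) -> ScaledChargeSet:
    """Scale formal ionic charges elementwise by f; no rounding is applied
    to the stored values."""
    return ScaledChargeSet(factor=f, formal=dict(formal))


def neutralizing_cation_count(net_lipid_charge: float, cation_charge: float) -> int:
    """Number of cations of charge q needed to neutralise a net lipid
    charge Q ≤ 0.

    Returns |Q|/q when integral; otherwise the integer minimising the
    residual |Q + n·q| and warns, reporting the residual.
    """
    if cation_charge == 0:
        raise ValueError("cation charge must be non-zero")
    if cation_charge < 0:
        raise ValueError("cation charge must be positive")
    if net_lipid_charge > 0:
        raise ValueError("net lipid charge must be ≤ 0 for cation neutralisation")
    exact = -net_lipid_charge / cation_charge
    n = round(exact)
    residual = net_lipid_charge + n * cation_charge
    if abs(residual) > 1e-9:
        warnings.warn(
            f"charge {net_lipid_charge}e is not an integer multiple of "
            f"{cation_charge}e; using n={n} with residual {residual:+.4f}e",
            UserWarning,
            stacklevel=2,
        )
    return int(n)


def nominal_concentration(
    n_ion_pairs: int, n_water: int, water_molarity: float = WATER_MOLARITY
) -> float:
    """Nominal salt concentration (mol/L) of n ion pairs relative to the
    water count: c = (n / n_water) × 55.51."""
    if n_water <= 0:
        raise ValueError("water count must be positive")
    return n_ion_pairs / n_water * water_molarity


def ion_pairs_for_concentration(
    concentration: float, n_water: int, water_molarity: float = WATER_MOLARITY
) -> int:
    """Inverse of :func:`nominal_concentration`: ion pairs needed for a
    target molarity, rounded to the nearest integer."""
    if n_water <= 0:
        raise ValueError("water count must be positive")
    return round(concentration * n_water / water_molarity)


@dataclass
class CompositionSpec:
    """Composition of one simulated system.

    Lipid charges enter unscaled; ionic charges are the ECC-scaled values.
    The net system charge is audited and flagged when non-zero.
    """

    lipid_counts: dict[str, int]
    lipid_charges: dict[str, float]  # formal charge per lipid species, e
    n_water: int
    n_cations: int = 0
    n_anions: int = 0
    cation_charge: float = 1.5
    anion_charge: float = -0.75

    def __post_init__(self) -> None:
        for name, n in self.lipid_counts.items():
            if n < 0:
                raise ValueError(f"negative lipid count for {name}")
        if self.n_water < 0 or self.n_cations < 0 or self.n_anions < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_lipids(self) -> int:
        return sum(self.lipid_counts.values())

    @property
    def net_lipid_charge(self) -> float:
        return sum(
            n * self.lipid_charges.get(name, 0.0)
            for name, n in self.lipid_counts.items()
        )

    @property
    def net_charge(self) -> float:
        return (
            self.net_lipid_charge
            + self.n_cations * self.cation_charge
            + self.n_anions * self.anion_charge
        )

    def report(self) -> dict:
        """Flat summary for JSON/CSV export; warns on non-neutral systems."""
        net = self.net_charge
        if abs(net) > 1e-9:
            warnings.warn(
                f"system carries net charge {net:+.4f}e", UserWarning, stacklevel=2
            )
        # CaCl2 stoichiometry: each added salt unit brings two anions, so
        # the nominal salt count excludes the neutralising cations.
        salt_pairs = self.n_anions // 2
        return {
            "lipids": dict(self.lipid_counts),
            "n_lipids": self.n_lipids,
            "net_lipid_charge_e": self.net_lipid_charge,
            "n_water": self.n_water,
            "n_cations": self.n_cations,
            "n_anions": self.n_anions,
            "cation_charge_e": self.cation_charge,
            "anion_charge_e": self.anion_charge,
            "net_charge_e": net,
            "nominal_concentration_M": nominal_concentration(salt_pairs, self.n_water)
            if self.n_water
            else float("nan"),
        }
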