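"""Physical and pharmacokinetic parameters of the sirolimus DCB model.

All quantities are kept in a single internal unit system: mm – s – g – mol.
Tissue density is commonly quoted in g/ml; it is converted to g/mm^3 on
construction (0.983 g/ml -> 9.83e-4 g/mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

# Tissue label codes shared across the package.
LUMEN = 0
HT = 1   # healthy tissue
FI = 2   # fibrous
FF = 3   # fibrofatty
NC = 4   # necrotic core
DC = 5   # dense calcium
EXTERIOR = 6

TISSUE_LABELS = (HT, FI, FF, NC, DC)
LABEL_NAMES = {LUMEN: "LUMEN", HT: "HT", FI: "FI", FF: "FF",
               NC: "NC", DC: "DC", EXTERIOR: "EXTERIOR"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Printed one-pixel side length of the source imaging grid, in mm
#: (8.48e-4 cm).
DEFAULT_PIXEL_SIZE_MM = 8.48e-3


def _default_diffusivities() -> Dict[int, float]:
    # mm^2/s.  FI and FF share a value, as do NC and DC (no separate data).
    return {
        FI: 1.0e-4,
        FF: 1.0e-4,
        NC: 8.42e-7,
        DC: 8.42e-7,
        HT: 8.42e-5,
    }


@dataclass(frozen=True)
class ModelParameters:
    """Baseline transport/binding parameter set for sirolimus.

    Attributes
    ----------
    rho_t : tissue density, g/mm^3 (constructor kwarg ``rho_t_g_per_ml``
        offers the conventional g/ml entry point).
    mu_t : interstitial plasma viscosity, g/(mm s).
    K : Darcy permeability of the wall, mm^2.
    V : transmural filtration speed prescribed on the lumen-tissue
        interface, mm/s.
    D_map : free-drug diffusivity per tissue label, mm^2/s.
    B_Rm, B_Em : maximum receptor / extracellular-matrix binding site
        densities, mol/mm^3.
    k_Ra, k_Ea : association rate constants, (mol mm^-3 s)^-1.
    k_Rd, k_Ed : dissociation rate constants, s^-1.
    k1 : balloon release rate constant, s^-1.
    a1 : balloon release capacity, ug/mm^2.
    t0 : balloon inflation time, s.
    D_MW : molecular weight of sirolimus, g/mol.
    coating_thickness : effective balloon contact-film thickness used by
        the reservoir release coupling, mm.
    """

    rho_t: float = 0.983e-3
    mu_t: float = 5.0e-3
    K: float = 1.43e-12
    V: float = 5.8e-5
    D_map: Dict[int, float] = field(default_factory=_default_diffusivities)
    B_Rm: float = 3.3e-12
    B_Em: float = 3.6e-10
    k_Ra: float = 8.0e11
    k_Ea: float = 2.0e9
    k_Rd: float = 1.6e-4
    k_Ed: float = 5.2e-3
    k1: float = 0.1135
    a1: float = 1.4618
    t0: float = 30.0
    D_MW: float = 914.2
    coating_thickness: float = 5.0e-3

    def __post_init__(self) -> None:
        for name in ("rho_t", "mu_t", "K", "V", "B_Rm", "B_Em", "k_Ra",
                     "k_Ea", "k_Rd", "k_Ed", "k1", "a1", "t0", "D_MW",
                     "coating_thickness"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"parameter {name!r} must be strictly "
                                 f"positive, got {value!r}")
        for label in TISSUE_LABELS:
            if label not in self.D_map:
                raise ValueError(f"D_map missing tissue label "
                                 f"{LABEL_NAMES[label]}")
            if not (self.D_map[label] > 0):
                raise ValueError(f"D_map[{LABEL_NAMES[label]}] must be "
                                 f"strictly positive")

    @classmethod
    def from_overrides(cls, rho_t_g_per_ml: float | None = None,
                       **overrides) -> "ModelParameters":
        """Build a parameter set from keyword overrides of the defaults.

        ``rho_t_g_per_ml`` accepts density in g/ml and converts it.
        Unknown keys raise ``ValueError`` so typos never pass silently.
        """
        valid = set(cls.__dataclass_fields__)
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        if rho_t_g_per_ml is not None:
            if "rho_t" in overrides:
                raise ValueError("give rho_t or rho_t_g_per_ml, not both")
            overrides["rho_t"] = rho_t_g_per_ml * 1e-3
        if "D_map" in overrides:
            base = _default_diffusivities()
            base.update({int(k): float(v)
                         for k, v in overrides["D_map"].items()})
            overrides["D_map"] = base
        return cls(**overrides)

    def with_(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        if "D_map" in overrides:
            merged = dict(self.D_map)
            merged.update(overrides["D_map"])
            overrides["D_map"] = merged
        return replace(self, **overrides)

    def diffusivity_array(self):
        """Diffusivity indexed by label code 0..6 (0 outside tissue)."""
        import numpy as np
        arr = np.zeros(7)
        for label, d in self.D_map.items():
            arr[label] = d
        return arr
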