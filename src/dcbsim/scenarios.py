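"""Shipped scenario suite mirroring the study's experiments.

Each helper returns ``(grid-or-spec, ScenarioSpec)`` building blocks for
the canonical runs: the circular-vessel validation, the reference-like
scattered phantom under both interface extremes with and without
convection, the hard/soft/healthy composition phantoms, the clustered
DC/NC offset ladder, and the filtration-velocity / permeability
sensitivity ranges.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .geometry import PhantomSpec, TissueLabelGrid, make_circular_phantom
from .parameters import DC, FF, FI, HT, NC
from .transport import ScenarioSpec

__all__ = [
    "REF_FRACTIONS", "HARD_FRACTIONS", "SOFT_FRACTIONS",
    "CLUSTERED_FRACTIONS", "V_SENSITIVITY_MM_PER_S",
    "K_SENSITIVITY_MM2", "VALIDATION_LUMEN_RADIUS_MM",
    "VALIDATION_WALL_THICKNESS_MM", "validation_geometry",
    "validation_scenario", "ref_phantom_spec", "hard_phantom_spec",
    "soft_phantom_spec", "clustered_phantom_spec",
]

#: Plaque composition of the reference (patient-derived) cross-section,
#: by area over tissue pixels.
REF_FRACTIONS: Dict[int, float] = {HT: 0.274, FI: 0.319, FF: 0.092,
                                   NC: 0.224, DC: 0.091}
#: Hard model: healthy plus dense-calcium/necrotic-core only.
HARD_FRACTIONS: Dict[int, float] = {HT: 0.274, NC: 0.363, DC: 0.363}
#: Soft model: healthy plus fibrous/fibrofatty only.
SOFT_FRACTIONS: Dict[int, float] = {HT: 0.274, FI: 0.363, FF: 0.363}
#: Idealised clustered models: HT 37%, FI+FF 44.8%, DC+NC 18.2%.
CLUSTERED_FRACTIONS: Dict[int, float] = {HT: 0.37, FI: 0.224, FF: 0.224,
                                         NC: 0.091, DC: 0.091}

#: Filtration-velocity sensitivity range (mm/s), low / baseline / high.
V_SENSITIVITY_MM_PER_S = (2.8e-5, 5.8e-5, 1.1e-4)
#: Darcy-permeability sensitivity range (mm^2), spanning two decades
#: around the baseline.
K_SENSITIVITY_MM2 = (1.43e-13, 1.43e-12, 1.43e-11)

#: Circular healthy validation vessel.  The study geometry follows a
#: cited prior circular model whose dimensions are not printed; this
#: package documents its own values: a 1.5 mm lumen radius and a 0.3 mm
#: wall, the typical healthy human coronary lumen and intima+media
#: thickness.
VALIDATION_LUMEN_RADIUS_MM = 1.5
VALIDATION_WALL_THICKNESS_MM = 0.3


def validation_geometry(pixel_size: float = 0.02) -> TissueLabelGrid:
    """Healthy circular cross-section used by the validation runs."""
    return make_circular_phantom(VALIDATION_LUMEN_RADIUS_MM,
                                 VALIDATION_WALL_THICKNESS_MM,
                                 pixel_size, label=HT)


def validation_scenario(t_post_minutes: float = 21.0) -> ScenarioSpec:
    """Validation run: 30 s inflation, no-flux interface, convection on."""
    return ScenarioSpec(interface_mode="no_flux", convection=True,
                        t0=30.0, t_end=30.0 + 60.0 * t_post_minutes,
                        output_every=30.0)


def _annulus_spec(fractions, mode="scattered", seed=7, pixel_size=0.04,
                  cluster_offset=0) -> PhantomSpec:
    return PhantomSpec(mode=mode, target_fractions=fractions,
                       cluster_offset=cluster_offset, seed=seed,
                       lumen_radius=1.5, wall_thickness=0.5,
                       pixel_size=pixel_size)


def ref_phantom_spec(seed: int = 7, pixel_size: float = 0.04
                     ) -> PhantomSpec:
    """Scattered phantom with the reference plaque composition."""
    return _annulus_spec(REF_FRACTIONS, seed=seed, pixel_size=pixel_size)


def hard_phantom_spec(seed: int = 7, pixel_size: float = 0.04
                      ) -> PhantomSpec:
    return _annulus_spec(HARD_FRACTIONS, seed=seed, pixel_size=pixel_size)


def soft_phantom_spec(seed: int = 7, pixel_size: float = 0.04
                      ) -> PhantomSpec:
    return _annulus_spec(SOFT_FRACTIONS, seed=seed, pixel_size=pixel_size)


def clustered_phantom_spec(offset: int, seed: int = 3,
                           pixel_size: float = 0.01696) -> PhantomSpec:
    """Clustered DC/NC band phantom: offset 0 covers the interface
    (type A); offsets 1, 2, 4 step the band away from it (A1, A2, A3)."""
    return _annulus_spec(CLUSTERED_FRACTIONS, mode="clustered", seed=seed,
                         pixel_size=pixel_size, cluster_offset=offset)
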