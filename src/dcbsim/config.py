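"""TOML run configuration: geometry source, parameters, scenario, numerics.

A run config has sections [geometry], [parameters], [scenario],
[numerics], [output] plus a top-level ``seed``.  Exactly one geometry
source must be given (an image to segment, or a phantom recipe).  Unknown
keys are hard errors so typos never pass silently; unspecified parameters
fall back to the baseline sirolimus defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

from .flow import NumericsSettings
from .geometry import (PhantomSpec, TissueLabelGrid, make_circular_phantom,
                       make_heterogeneous_phantom, segment_image)
from .parameters import (DEFAULT_PIXEL_SIZE_MM, NAME_TO_LABEL,
                         ModelParameters, TISSUE_LABELS)
from .transport import ScenarioSpec

__all__ = ["RunConfig", "load_config", "save_config", "build_geometry",
           "ConfigError"]


class ConfigError(ValueError):
    """Invalid or ambiguous run configuration."""


_GEOMETRY_KEYS = {
    "image", "palette", "k", "pixel_size",
    "kind", "mode", "fractions", "cluster_offset", "seed",
    "lumen_radius", "wall_thickness", "label",
}
_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioSpec)}
_NUMERICS_KEYS = {f.name for f in dataclasses.fields(NumericsSettings)}
_PARAM_KEYS = ({f.name for f in dataclasses.fields(ModelParameters)}
               | {"rho_t_g_per_ml"})
_OUTPUT_KEYS = {"dir", "prefix", "snapshot_format"}


@dataclass
class RunConfig:
    geometry: Dict[str, Any]
    parameters: ModelParameters = field(default_factory=ModelParameters)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    numerics: NumericsSettings = field(default_factory=NumericsSettings)
    output: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        kind = self.geometry.get("kind")
        if kind not in ("image", "phantom", "circular"):
            raise ConfigError("geometry.kind must be 'image', 'phantom' "
                              f"or 'circular' (got {kind!r})")
        has_image = "image" in self.geometry
        has_phantom = bool({"mode", "fractions", "label",
                            "cluster_offset"} & set(self.geometry))
        if has_image and has_phantom:
            raise ConfigError("config gives both an image and a phantom "
                              "geometry source; exactly one is allowed")
        if (kind == "image") != has_image:
            raise ConfigError("give geometry.image exactly when "
                              "geometry.kind == 'image'")


def _check_keys(section: str, given: Dict[str, Any], allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: "
                          f"{sorted(unknown)}")


def _parse_fractions(raw: Dict[str, float]) -> Dict[int, float]:
    out = {}
    for name, value in raw.items():
        if name not in NAME_TO_LABEL or NAME_TO_LABEL[name] not in \
                TISSUE_LABELS:
            raise ConfigError(f"unknown tissue label {name!r} in fractions")
        out[NAME_TO_LABEL[name]] = float(value)
    return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    allowed_sections = {"geometry", "parameters", "scenario", "numerics",
                        "output", "seed"}
    _check_keys("<top level>", raw, allowed_sections)
    geometry = dict(raw.get("geometry", {}))
    if not geometry:
        raise ConfigError("config needs a [geometry] section")
    _check_keys("geometry", geometry, _GEOMETRY_KEYS)
    geometry.setdefault("kind",
                        "image" if "image" in geometry else "phantom")

    params_raw = dict(raw.get("parameters", {}))
    _check_keys("parameters", params_raw, _PARAM_KEYS)
    try:
        parameters = ModelParameters.from_overrides(**params_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [parameters]: {exc}") from exc

    scen_raw = dict(raw.get("scenario", {}))
    _check_keys("scenario", scen_raw, _SCENARIO_KEYS)
    try:
        scenario = ScenarioSpec(**scen_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [scenario]: {exc}") from exc

    num_raw = dict(raw.get("numerics", {}))
    _check_keys("numerics", num_raw, _NUMERICS_KEYS)
    try:
        numerics = NumericsSettings(**num_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [numerics]: {exc}") from exc

    output = dict(raw.get("output", {}))
    _check_keys("output", output, _OUTPUT_KEYS)
    return RunConfig(geometry=geometry, parameters=parameters,
                     scenario=scenario, numerics=numerics, output=output,
                     seed=int(raw.get("seed", 0)))


# ---------------------------------------------------------------------------
# TOML emission (the standard library ships a reader only)
# ---------------------------------------------------------------------------

def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot emit TOML value {v!r}")


def _emit_section(name: str, items: Dict[str, Any], lines: list) -> None:
    scalars = {k: v for k, v in items.items()
               if not isinstance(v, dict) and v is not None}
    subs = {k: v for k, v in items.items() if isinstance(v, dict)}
    if scalars or not subs:
        lines.append(f"[{name}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for k, v in subs.items():
        _emit_section(f"{name}.{k}", v, lines)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to TOML; load(save(load(x))) == load(x)."""
    params = dataclasses.asdict(config.parameters)
    params["D_map"] = {str(k): v for k, v in params["D_map"].items()}
    geometry = dict(config.geometry)
    if "fractions" in geometry:
        geometry = dict(geometry)
    lines = [f"seed = {config.seed}", ""]
    _emit_section("geometry", geometry, lines)
    _emit_section("parameters", params, lines)
    _emit_section("scenario", dataclasses.asdict(config.scenario), lines)
    _emit_section("numerics", dataclasses.asdict(config.numerics), lines)
    if config.output:
        _emit_section("output", config.output, lines)
    Path(path).write_text("\n".join(lines) + "\n")


def _reload_normalise(config: RunConfig) -> RunConfig:
    return config


def build_geometry(config: RunConfig) -> TissueLabelGrid:
    """Realise the configured geometry source as a label grid."""
    g = config.geometry
    kind = g["kind"]
    pixel_size = float(g.get("pixel_size", DEFAULT_PIXEL_SIZE_MM))
    if kind == "image":
        import imageio.v3 as iio
        image = iio.imread(g["image"])
        palette = None
        if "palette" in g:
            palette = {NAME_TO_LABEL[k]: tuple(v)
                       for k, v in g["palette"].items()}
        return segment_image(image, palette=palette, k=g.get("k"),
                             pixel_size=pixel_size, seed=config.seed)
    if kind == "circular":
        label = NAME_TO_LABEL[g.get("label", "HT")]
        return make_circular_phantom(float(g["lumen_radius"]),
                                     float(g["wall_thickness"]),
                                     pixel_size, label=label)
    spec = PhantomSpec(
        mode=g.get("mode", "scattered"),
        target_fractions=_parse_fractions(g["fractions"]),
        cluster_offset=int(g.get("cluster_offset", 0)),
        seed=int(g.get("seed", config.seed)),
        lumen_radius=float(g.get("lumen_radius", 1.5)),
        wall_thickness=float(g.get("wall_thickness", 0.5)),
        pixel_size=pixel_size,
    )
    return make_heterogeneous_phantom(spec)
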