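"""Scenario configuration files (YAML or TOML).

Schema::

    habitats:
      - habitat_id: reef
        raster: reef_cover.tif
    scenarios:
      - scenario_id: s1_current_nutrients
        description: current nutrient load
        nutrient_multiplier: 1.0
        pressures:
          - pressure_id: nutrient_load
            raster: nutrient.tif
          - pressure_id: round_goby
            raster: goby.tif
          - pressure_id: wind_park
            geojson: parks.geojson
            turbine_diameter_m: 100
            turbine_spacing_m: 800

A wind-park pressure may be given either as a prepared intensity raster or as
a GeoJSON polygon file plus turbine geometry, in which case it is rasterized
onto the habitat grid.  Relative paths resolve against the config file.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .scenario import Scenario
from .seascape import (GridSpec, HabitatLayer, PressureLayer, align_layers,
                       rasterize_windparks, read_raster, read_windpark_geojson)


class ConfigError(ValueError):
    """Malformed scenario configuration."""


def load_config(path: str | Path) -> dict:
    """Parse a YAML or TOML config file into a plain dict."""
    path = Path(path)
    if path.suffix == ".toml":
        with path.open("rb") as fh:
            return tomllib.load(fh)
    with path.open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_habitats(cfg: dict, base: Path) -> list[HabitatLayer]:
    layers = []
    for spec in cfg.get("habitats", []):
        try:
            layer = read_raster(base / spec["raster"], "habitat",
                                layer_id=spec["habitat_id"])
        except KeyError as exc:
            raise ConfigError(f"habitat entry missing key {exc}") from exc
        layers.append(layer)
    if not layers:
        raise ConfigError("config lists no habitats")
    align_layers(layers)
    return layers


def build_scenario(spec: dict, grid: GridSpec, base: Path) -> Scenario:
    """Instantiate one scenario entry, rasterizing wind parks if needed."""
    try:
        scenario_id = spec["scenario_id"]
    except KeyError as exc:
        raise ConfigError("scenario entry missing scenario_id") from exc
    pressures: dict[str, PressureLayer] = {}
    for pspec in spec.get("pressures", []):
        pid = pspec.get("pressure_id")
        if pid is None:
            raise ConfigError(
                f"scenario {scenario_id!r}: pressure entry missing pressure_id")
        if "raster" in pspec:
            layer = read_raster(base / pspec["raster"], "pressure",
                                layer_id=pid)
        elif "geojson" in pspec:
            if pid != "wind_park":
                raise ConfigError(
                    f"scenario {scenario_id!r}: only wind_park pressures "
                    "may be given as GeoJSON")
            polys = read_windpark_geojson(base / pspec["geojson"])
            layer = rasterize_windparks(
                polys,
                float(pspec.get("turbine_diameter_m", 100.0)),
                float(pspec.get("turbine_spacing_m", 800.0)),
                grid)
        else:
            raise ConfigError(
                f"scenario {scenario_id!r}: pressure {pid!r} needs a "
                "'raster' or 'geojson' entry")
        pressures[pid] = layer
    return Scenario(
        scenario_id=scenario_id,
        pressures=pressures,
        nutrient_multiplier=float(spec.get("nutrient_multiplier", 1.0)),
        description=spec.get("description", ""))


def load_scenarios(cfg: dict, grid: GridSpec, base: Path,
                   only: str | None = None) -> list[Scenario]:
    specs = cfg.get("scenarios", [])
    if only is not None:
        specs = [s for s in specs if s.get("scenario_id") == only]
        if not specs:
            raise ConfigError(f"scenario {only!r} not found in config")
    if not specs:
        raise ConfigError("config lists no scenarios")
    return [build_scenario(s, grid, base) for s in specs]
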