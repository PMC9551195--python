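"""Scenario engine: per-cell application of sensitivity scores to habitat cover.

A scenario is a set of active pressures with their intensity layers plus a
nutrient-load multiplier (1.0 = business as usual, 0.75 = a 25 % load
reduction).  For every 1 km2 cell the engine combines the habitat's pooled
response ratios into one cell-level ratio and multiplies the habitat cover by
it; effects are strictly local (a pressure in one cell never changes a
neighbouring cell) and regional totals are sums over impacted cells.

Combination rule (multiplicative with intensity exponents):

    ln rr_cell = sum_p intensity_p * ln rr_p

so binary pressures at presence 1 contribute their full ratio, the nutrient
pressure contributes rr^(c * multiplier) for normalised concentration c, and
wind parks contribute rr^f for footprint fraction f.  When the set of active
binary pressures in a cell exactly matches a jointly-observed pressure set
(e.g. both invasive predators together), the direct joint score overrides the
product rule; a joint subset plus extra pressures composes the joint score
with the extras.

Confidence bounds propagate per pressure independently: the cell's low/high
ratios use every pressure's rr_low/rr_high respectively, a conservative
envelope without cross-pressure covariance.  New cover is clipped to [0, 1]:
a habitat already at full cover cannot gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .meta import SensitivityMatrix, SensitivityScore
from .seascape import (AlignmentError, BINARY_PRESSURES, HabitatLayer,
                       PressureLayer)

#: Pressures treated as continuous intensity exponents rather than presence.
CONTINUOUS_PRESSURES = frozenset({"nutrient_load", "wind_park"})


class CoverageGapError(KeyError):
    """No sensitivity score available for an active (habitat, pressure)."""

    def __init__(self, habitat_id: str, pressure: str):
        super().__init__(f"no sensitivity score for habitat {habitat_id!r} "
                         f"x pressure {pressure!r}")
        self.habitat_id = habitat_id
        self.pressure = pressure


@dataclass(frozen=True)
class Scenario:
    """An active pressure set with aligned intensity layers."""

    scenario_id: str
    pressures: Mapping[str, PressureLayer]
    nutrient_multiplier: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.nutrient_multiplier <= 0:
            raise ValueError("nutrient_multiplier must be > 0")
        for pid, layer in self.pressures.items():
            if pid != layer.pressure_id:
                raise ValueError(
                    f"pressure key {pid!r} does not match layer "
                    f"{layer.pressure_id!r}")
        grids = {layer.grid for layer in self.pressures.values()}
        if len(grids) > 1:
            raise AlignmentError("scenario pressure layers are not aligned")


@dataclass
class ImpactResult:
    """Predicted min/mean/max cover maps plus a Table-style summary row."""

    habitat_id: str
    scenario_id: str
    cover_min: np.ndarray
    cover_mean: np.ndarray
    cover_max: np.ndarray
    pct_change_mean: np.ndarray  # % change of within-cell cover; NaN if cover 0
    summary: dict = field(default_factory=dict)
    grid: object = None
    cover_in: np.ndarray | None = None


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (-15.5 -> -16)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_total_change(areal_change_km2: float,
                         total_cover_km2: float) -> int:
    """Signed integer percent change of total habitat cover.

    ``100 * areal_change / total_cover`` rounded half away from zero — the
    bookkeeping identity behind a summary table's "predicted total loss/gain
    of habitat (%)" column.
    """
    if total_cover_km2 == 0:
        raise ZeroDivisionError(
            "total habitat cover is zero; percent change undefined")
    return round_half_away(100.0 * areal_change_km2 / total_cover_km2)


def _score_lookup(matrix: SensitivityMatrix, habitat_id: str,
                  pset: frozenset[str]) -> SensitivityScore | None:
    return matrix.get((habitat_id, pset))


def _resolve_binary_set(matrix: SensitivityMatrix, habitat_id: str,
                        active: frozenset[str]) -> tuple[float, float, float]:
    """(ln rr_low, ln rr_mean, ln rr_high) for a set of co-present binary
    pressures, honouring direct joint-evidence overrides.

    Precedence: exact pressure-set match > largest joint subset composed with
    the remaining singles > product of singles.
    """
    if not active:
        return (0.0, 0.0, 0.0)
    direct = _score_lookup(matrix, habitat_id, active)
    if direct is not None:
        return (math.log(direct.rr_low), math.log(direct.rr_mean),
                math.log(direct.rr_high))
    # largest joint subset (size > 1) with a direct score, composed with singles
    subsets = sorted(
        (pset for (h, pset) in matrix if h == habitat_id
         and len(pset) > 1 and pset < active),
        key=len, reverse=True)
    lo = me = hi = 0.0
    remaining = active
    if subsets:
        joint = _score_lookup(matrix, habitat_id, subsets[0])
        lo += math.log(joint.rr_low)
        me += math.log(joint.rr_mean)
        hi += math.log(joint.rr_high)
        remaining = active - subsets[0]
    for p in sorted(remaining):
        score = _score_lookup(matrix, habitat_id, frozenset({p}))
        if score is None:
            raise CoverageGapError(habitat_id, p)
        lo += math.log(score.rr_low)
        me += math.log(score.rr_mean)
        hi += math.log(score.rr_high)
    return (lo, me, hi)


def combined_rr(matrix: SensitivityMatrix, habitat_id: str,
                intensities: Mapping[str, float],
                nutrient_multiplier: float = 1.0,
                ) -> tuple[float, float, float]:
    """Combined (rr_low, rr_mean, rr_high) for one cell's pressure intensities.

    ``intensities`` maps pressure_id to the cell's intensity; pressures at
    intensity 0 are inactive.  Binary pressures must be 0 or 1; the nutrient
    intensity is the normalised concentration (scaled by the scenario
    multiplier here); wind-park intensity is the turbine footprint fraction.
    """
    lo = me = hi = 0.0
    binary_active = set()
    for pid, intensity in intensities.items():
        if intensity == 0:
            continue
        if intensity < 0:
            raise ValueError(f"negative intensity for {pid!r}")
        if pid in BINARY_PRESSURES:
            if intensity != 1:
                raise ValueError(f"binary pressure {pid!r} must be 0 or 1")
            binary_active.add(pid)
        else:
            score = _score_lookup(matrix, habitat_id, frozenset({pid}))
            if score is None:
                raise CoverageGapError(habitat_id, pid)
            e = intensity * (nutrient_multiplier if pid == "nutrient_load"
                             else 1.0)
            lo += e * math.log(score.rr_low)
            me += e * math.log(score.rr_mean)
            hi += e * math.log(score.rr_high)
    b_lo, b_me, b_hi = _resolve_binary_set(matrix, habitat_id,
                                           frozenset(binary_active))
    return (math.exp(lo + b_lo), math.exp(me + b_me), math.exp(hi + b_hi))


def apply_scenario(habitat: HabitatLayer, scenario: Scenario,
                   matrix: SensitivityMatrix) -> ImpactResult:
    """Predict min/mean/max habitat cover under a scenario.

    Per cell, new cover = clip(cover x rr_cell, 0, 1) for each of the low,
    mean and high combined ratios.  Wind parks may additionally create
    habitat in previously empty cells where their score exceeds 1, bounded by
    the turbine footprint fraction.  Cells with no active pressure keep their
    input cover in all three maps.
    """
    if scenario.pressures:
        grids = {layer.grid for layer in scenario.pressures.values()}
        if grids != {habitat.grid}:
            raise AlignmentError(
                f"scenario layers not aligned with habitat {habitat.habitat_id!r}")
    cover_in = habitat.cover.astype(float)
    if not (np.nansum(cover_in > 0)):
        raise ValueError(f"habitat {habitat.habitat_id!r} has no cover anywhere")

    ln_lo = np.zeros_like(cover_in)
    ln_me = np.zeros_like(cover_in)
    ln_hi = np.zeros_like(cover_in)
    any_active = np.zeros(cover_in.shape, dtype=bool)

    binary_layers = {pid: layer for pid, layer in scenario.pressures.items()
                     if pid in BINARY_PRESSURES}
    if binary_layers:
        pids = sorted(binary_layers)
        stack = np.stack([np.nan_to_num(binary_layers[p].intensity) > 0
                          for p in pids])
        any_active |= stack.any(axis=0)
        patterns = stack.reshape(len(pids), -1)
        flat_codes = np.zeros(patterns.shape[1], dtype=int)
        for i in range(len(pids)):
            flat_codes |= patterns[i].astype(int) << i
        for code in np.unique(flat_codes):
            active = frozenset(p for i, p in enumerate(pids) if code >> i & 1)
            lo, me, hi = _resolve_binary_set(matrix, habitat.habitat_id, active)
            mask = (flat_codes == code).reshape(cover_in.shape)
            ln_lo[mask] += lo
            ln_me[mask] += me
            ln_hi[mask] += hi

    for pid, layer in scenario.pressures.items():
        if pid in BINARY_PRESSURES:
            continue
        intensity = np.nan_to_num(layer.intensity)
        e = intensity * (scenario.nutrient_multiplier
                         if pid == "nutrient_load" else 1.0)
        if not np.any(e > 0):
            continue
        score = _score_lookup(matrix, habitat.habitat_id, frozenset({pid}))
        if score is None:
            raise CoverageGapError(habitat.habitat_id, pid)
        any_active |= intensity > 0
        ln_lo += e * math.log(score.rr_low)
        ln_me += e * math.log(score.rr_mean)
        ln_hi += e * math.log(score.rr_high)

    cover_lo = np.clip(cover_in * np.exp(ln_lo), 0.0, 1.0)
    cover_me = np.clip(cover_in * np.exp(ln_me), 0.0, 1.0)
    cover_hi = np.clip(cover_in * np.exp(ln_hi), 0.0, 1.0)

    # Wind-park habitat creation on previously empty seafloor: the foundation
    # adds at most its footprint fraction of new cover where the habitat
    # responds positively (rr > 1).
    wind = scenario.pressures.get("wind_park")
    if wind is not None:
        score = _score_lookup(matrix, habitat.habitat_id,
                              frozenset({"wind_park"}))
        f = np.nan_to_num(wind.intensity)
        empty = (cover_in == 0) & (f > 0)
        if score is not None and np.any(empty):
            for arr, rr in ((cover_lo, score.rr_low), (cover_me, score.rr_mean),
                            (cover_hi, score.rr_high)):
                created = np.clip(f * (rr - 1.0), 0.0, f)
                arr[empty] = created[empty]

    nodata = ~np.isfinite(cover_in)
    for arr in (cover_lo, cover_me, cover_hi):
        arr[nodata] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        pct_change = 100.0 * (cover_me - cover_in) / cover_in
    pct_change[cover_in == 0] = np.nan

    result = ImpactResult(
        habitat_id=habitat.habitat_id, scenario_id=scenario.scenario_id,
        cover_min=cover_lo, cover_mean=cover_me, cover_max=cover_hi,
        pct_change_mean=pct_change, grid=habitat.grid, cover_in=cover_in)
    result.summary = summarize_scenario(result, _any_active=any_active)
    return result


def summarize_scenario(result: ImpactResult,
                       _any_active: np.ndarray | None = None) -> dict:
    """Table-style summary row for one habitat x scenario.

    Per-cell percent statistics (to 0.1) are taken over impacted cells —
    cells with habitat cover > 0 and at least one active pressure.  The total
    percent change is the signed integer
    ``100 * areal_change / total_cover`` (half away from zero).
    """
    cover_in = result.cover_in
    if cover_in is None:
        raise ValueError("result lacks the input cover needed for a summary")
    habitat_mask = np.nan_to_num(cover_in) > 0
    if _any_active is None:
        changed = np.zeros_like(habitat_mask)
        for arr in (result.cover_min, result.cover_mean, result.cover_max):
            with np.errstate(invalid="ignore"):
                changed |= np.nan_to_num(arr - cover_in) != 0
        impacted = habitat_mask & changed
    else:
        impacted = habitat_mask & _any_active

    total_cover = float(np.nansum(np.nan_to_num(cover_in)))
    if total_cover == 0:
        raise ZeroDivisionError("total habitat cover is zero")
    delta = np.nan_to_num(result.cover_mean) - np.nan_to_num(cover_in)
    areal_change = float(delta.sum())  # cell area is exactly 1 km2

    pct = result.pct_change_mean[impacted]
    pct = pct[np.isfinite(pct)]
    if pct.size:
        pct_min, pct_max, pct_mean = (round(float(pct.min()), 1),
                                      round(float(pct.max()), 1),
                                      round(float(pct.mean()), 1))
    else:
        pct_min = pct_max = pct_mean = 0.0
    return {
        "habitat_id": result.habitat_id,
        "scenario_id": result.scenario_id,
        "pct_min": pct_min,
        "pct_max": pct_max,
        "pct_mean": pct_mean,
        "n_habitat_cells": int(habitat_mask.sum()),
        "n_impacted_cells": int(impacted.sum()),
        "total_cover_km2": total_cover,
        "areal_change_km2": areal_change,
        "total_pct_change": percent_total_change(areal_change, total_cover),
    }


def compare_scenarios(a: ImpactResult, b: ImpactResult
                      ) -> tuple[np.ndarray, dict]:
    """Cell-wise difference of predicted mean cover, b - a, in percentage
    points of cell area, plus the delta of the total percent change."""
    if a.habitat_id != b.habitat_id:
        raise ValueError(f"habitat mismatch: {a.habitat_id} vs {b.habitat_id}")
    if a.grid != b.grid or a.cover_mean.shape != b.cover_mean.shape:
        raise AlignmentError("results are on different grids")
    diff_pp = 100.0 * (b.cover_mean - a.cover_mean)
    delta = {
        "habitat_id": a.habitat_id,
        "scenario_a": a.scenario_id,
        "scenario_b": b.scenario_id,
        "delta_total_pct_change": (b.summary["total_pct_change"]
                                   - a.summary["total_pct_change"]),
        "delta_areal_change_km2": (b.summary["areal_change_km2"]
                                   - a.summary["areal_change_km2"]),
    }
    return diff_pp, delta
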