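"""Meta-analysis of impact/reference evidence into sensitivity scores.

The effect size is the response ratio RR = mean_impact / mean_reference:
RR < 1 means the pressure reduces the habitat response (loss), RR > 1 means a
gain.  Analysis is done on the log scale, where the delta-method sampling
variance of ln RR is

    var(ln RR) = sd_i^2 / (n_i * mean_i^2) + sd_r^2 / (n_r * mean_r^2)

Studies for one habitat-pressure combination are pooled with a
DerSimonian-Laird random-effects model: the moment estimator of the
between-study variance tau^2 is combined with each study's sampling variance
into inverse-variance weights, and the pooled ln RR with its normal-theory
95 % CI is transformed back to the ratio scale.  The pooled RR with its CI is
the habitat x pressure "sensitivity score" that the scenario engine multiplies
into habitat cover.

A one-way ANOVA on the raw (ratio-scale) effect sizes, grouped by pressure
within one habitat, screens whether pressures differ in mean impact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import EvidenceRecord, PRESSURES

logger = logging.getLogger(__name__)

#: Normal 95 % two-sided multiplier; no small-sample t correction is applied.
Z_95 = 1.96

#: Zero impact means are floored at this fraction of the reference mean before
#: the log transform (the smallest ratio observed in practice in this
#: literature), so that complete-destruction records stay in the analysis.
ZERO_IMPACT_FLOOR = 1e-3

#: Floor on var(ln RR): some digitised studies report sd = 0, which would give
#: that study infinite weight.
VARIANCE_FLOOR = 1e-8


class MetaAnalysisError(ValueError):
    """Invalid input to an effect-size or pooling computation."""


@dataclass(frozen=True)
class EffectSize:
    """A single study's response ratio on both ratio and log scales."""

    rr: float
    ln_rr: float
    var_ln_rr: float
    habitat_id: str
    pressure_id: str
    study_id: str = ""


@dataclass(frozen=True)
class SensitivityScore:
    """Pooled response ratio with 95 % CI for one habitat x pressure set."""

    habitat_id: str
    pressure_set: frozenset[str]
    k: int
    rr_mean: float
    rr_low: float
    rr_high: float
    tau2: float
    evidence: str = "direct"  # direct | composed | expert
    #: Unweighted arithmetic mean of the per-study ratios, reported alongside
    #: the weighted pooled value for comparability with simple averages.
    rr_arith_mean: float = float("nan")

    def __post_init__(self) -> None:
        if not self.pressure_set:
            raise MetaAnalysisError("pressure_set must be non-empty")
        if not (self.rr_low <= self.rr_mean <= self.rr_high):
            raise MetaAnalysisError("CI must bracket the pooled ratio")
        if self.tau2 < 0:
            raise MetaAnalysisError("tau2 must be >= 0")
        if self.evidence == "direct" and self.k < 1:
            raise MetaAnalysisError("direct evidence requires k >= 1")


@dataclass(frozen=True)
class AnovaTable:
    df_factor: int
    df_resid: int
    ss_factor: float
    ss_resid: float
    f_value: float
    p_value: float
    ms_factor: float = field(init=False)
    ms_resid: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ms_factor", self.ss_factor / self.df_factor)
        object.__setattr__(self, "ms_resid", self.ss_resid / self.df_resid)


def _as_sd(dispersion: float, kind: str, n: int) -> float:
    """Normalise a dispersion to a standard deviation (sd = se * sqrt(n))."""
    return dispersion * math.sqrt(n) if kind == "se" else dispersion


def compute_effect_size(record: EvidenceRecord) -> EffectSize:
    """Log response ratio with delta-method variance for one record.

    A zero impact mean (total destruction of the habitat at the impact site)
    is floored at ``ZERO_IMPACT_FLOOR`` times the reference mean with a logged
    warning, never silently.
    """
    if record.mean_reference <= 0:
        raise MetaAnalysisError("mean_reference must be > 0 for a response ratio")
    mean_impact = record.mean_impact
    if mean_impact == 0:
        mean_impact = ZERO_IMPACT_FLOOR * record.mean_reference
        logger.warning(
            "zero impact mean in study %r (%s x %s): floored at %g x reference",
            record.study_id, record.habitat_id, record.pressure_id,
            ZERO_IMPACT_FLOOR)
    elif mean_impact < 0:
        raise MetaAnalysisError("mean_impact must be >= 0")

    sd_i = _as_sd(record.dispersion_impact, record.dispersion_kind_impact,
                  record.n_impact)
    sd_r = _as_sd(record.dispersion_reference, record.dispersion_kind_reference,
                  record.n_reference)
    rr = mean_impact / record.mean_reference
    var = (sd_i ** 2 / (record.n_impact * mean_impact ** 2)
           + sd_r ** 2 / (record.n_reference * record.mean_reference ** 2))
    return EffectSize(rr=rr, ln_rr=math.log(rr), var_ln_rr=var,
                      habitat_id=record.habitat_id,
                      pressure_id=record.pressure_id,
                      study_id=record.study_id)


def pool_effects(effects: list[EffectSize]) -> SensitivityScore:
    """DerSimonian-Laird random-effects pooling of one habitat x pressure group.

    Cochran's Q on fixed (inverse-variance) weights gives the moment estimate
    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))); random-effects
    weights 1/(v_i + tau^2) then yield the pooled log ratio and its SE.  With
    k = 1 the score is that study's own estimate and variance.
    """
    if not effects:
        raise MetaAnalysisError("cannot pool an empty list of effects")
    keys = {(e.habitat_id, e.pressure_id) for e in effects}
    if len(keys) > 1:
        raise MetaAnalysisError(
            f"effects must share one (habitat, pressure), got {sorted(keys)}")
    habitat_id, pressure_id = keys.pop()

    y = np.array([e.ln_rr for e in effects])
    v = np.maximum(np.array([e.var_ln_rr for e in effects]), VARIANCE_FLOOR)
    k = len(effects)

    w = 1.0 / v
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0

    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(math.sqrt(1.0 / np.sum(w_re)))

    return SensitivityScore(
        habitat_id=habitat_id,
        pressure_set=pressure_set_of(pressure_id),
        k=k,
        rr_mean=math.exp(mu),
        rr_low=math.exp(mu - Z_95 * se),
        rr_high=math.exp(mu + Z_95 * se),
        tau2=float(tau2),
        evidence="direct",
        rr_arith_mean=float(np.mean([e.rr for e in effects])),
    )


def pressure_set_of(pressure_id: str) -> frozenset[str]:
    """Expand a pressure identifier into its set of component pressures.

    Jointly observed invader pairs are direct evidence for the combined
    pressure set, not for either component alone.
    """
    if pressure_id == "round_goby_and_mud_crab":
        return frozenset({"round_goby", "mud_crab"})
    if pressure_id not in PRESSURES:
        raise MetaAnalysisError(f"unknown pressure_id {pressure_id!r}")
    return frozenset({pressure_id})


SensitivityMatrix = dict[tuple[str, frozenset[str]], SensitivityScore]


def build_sensitivity_matrix(
    records: list[EvidenceRecord],
    expert_scores: list[SensitivityScore] | None = None,
    allow_override: bool = False,
) -> SensitivityMatrix:
    """Pool all evidence into a (habitat, pressure set) -> score matrix.

    Expert-judgement scores (``evidence="expert"``) may be merged for
    combinations lacking evidence; overriding an evidence-backed key requires
    ``allow_override=True``.
    """
    groups: dict[tuple[str, str], list[EffectSize]] = {}
    for rec in records:
        groups.setdefault((rec.habitat_id, rec.pressure_id), []).append(
            compute_effect_size(rec))
    matrix: SensitivityMatrix = {}
    for (habitat_id, _), effs in sorted(groups.items()):
        score = pool_effects(effs)
        matrix[(habitat_id, score.pressure_set)] = score
    for expert in expert_scores or []:
        key = (expert.habitat_id, expert.pressure_set)
        if key in matrix and not allow_override:
            raise MetaAnalysisError(
                f"expert score conflicts with evidence-backed key {key}; "
                "pass allow_override=True to replace it")
        matrix[key] = expert
    return matrix


def matrix_to_frame(matrix: SensitivityMatrix) -> pd.DataFrame:
    """Serialise a sensitivity matrix to a flat table (pressure ids '+'-joined)."""
    rows = []
    for (habitat_id, pset), s in sorted(
            matrix.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))):
        rows.append({
            "habitat_id": habitat_id,
            "pressure_set": "+".join(sorted(pset)),
            "k": s.k, "rr_mean": s.rr_mean, "rr_low": s.rr_low,
            "rr_high": s.rr_high, "tau2": s.tau2, "evidence": s.evidence,
        })
    return pd.DataFrame(rows, columns=["habitat_id", "pressure_set", "k",
                                       "rr_mean", "rr_low", "rr_high",
                                       "tau2", "evidence"])


def frame_to_matrix(frame: pd.DataFrame) -> SensitivityMatrix:
    """Inverse of :func:`matrix_to_frame`."""
    matrix: SensitivityMatrix = {}
    for row in frame.itertuples(index=False):
        pset = frozenset(str(row.pressure_set).split("+"))
        score = SensitivityScore(
            habitat_id=row.habitat_id, pressure_set=pset, k=int(row.k),
            rr_mean=float(row.rr_mean), rr_low=float(row.rr_low),
            rr_high=float(row.rr_high), tau2=float(row.tau2),
            evidence=str(row.evidence))
        matrix[(row.habitat_id, pset)] = score
    return matrix


def anova_by_pressure(groups: dict[str, list[float]]) -> AnovaTable:
    """One-way ANOVA of raw (ratio-scale) effect sizes grouped by pressure.

    Empty groups are dropped with a warning; identical within-group values
    everywhere (zero residual sum of squares) raise a degenerate-ANOVA error.
    """
    cleaned = {}
    for name, values in groups.items():
        if len(values) == 0:
            logger.warning("dropping empty effect-size group %r", name)
            continue
        cleaned[name] = np.asarray(values, dtype=float)
    if len(cleaned) < 2:
        raise MetaAnalysisError("ANOVA needs >= 2 non-empty groups")
    n_total = sum(len(v) for v in cleaned.values())
    n_groups = len(cleaned)
    if n_total <= n_groups:
        raise MetaAnalysisError("ANOVA needs more observations than groups")

    grand = np.concatenate(list(cleaned.values())).mean()
    ss_factor = float(sum(len(v) * (v.mean() - grand) ** 2
                          for v in cleaned.values()))
    ss_resid = float(sum(((v - v.mean()) ** 2).sum() for v in cleaned.values()))
    df_factor = n_groups - 1
    df_resid = n_total - n_groups
    if ss_resid == 0:
        raise MetaAnalysisError("degenerate ANOVA: zero residual sum of squares")
    f_value = (ss_factor / df_factor) / (ss_resid / df_resid)
    p_value = float(stats.f.sf(f_value, df_factor, df_resid))
    return AnovaTable(df_factor=df_factor, df_resid=df_resid,
                      ss_factor=ss_factor, ss_resid=ss_resid,
                      f_value=f_value, p_value=p_value)


def anova_report(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Per-habitat ANOVA of effect sizes across pressures, as a flat table.

    Habitats with fewer than two pressure groups are skipped with a warning.
    Significance is flagged at p < 0.05.
    """
    by_habitat: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        eff = compute_effect_size(rec)
        by_habitat.setdefault(rec.habitat_id, {}).setdefault(
            rec.pressure_id, []).append(eff.rr)
    rows = []
    for habitat_id in sorted(by_habitat):
        groups = by_habitat[habitat_id]
        try:
            tab = anova_by_pressure(groups)
        except MetaAnalysisError as exc:
            logger.warning("skipping ANOVA for habitat %r: %s", habitat_id, exc)
            continue
        rows.append({
            "habitat_id": habitat_id, "df_factor": tab.df_factor,
            "df_resid": tab.df_resid, "ss_factor": tab.ss_factor,
            "ss_resid": tab.ss_resid, "ms_factor": tab.ms_factor,
            "ms_resid": tab.ms_resid, "f_value": tab.f_value,
            "p_value": tab.p_value, "significant": tab.p_value < 0.05,
        })
    return pd.DataFrame(rows, columns=[
        "habitat_id", "df_factor", "df_resid", "ss_factor", "ss_resid",
        "ms_factor", "ms_resid", "f_value", "p_value", "significant"])
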