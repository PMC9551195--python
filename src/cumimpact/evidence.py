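"""Evidence database: impact-vs-reference observations per habitat and pressure.

Each record is one quantitative comparison, extracted from a field survey or
manipulative experiment, of a benthic response variable (biomass, cover,
abundance) at a site exposed to a human pressure versus an unexposed reference
condition.  The comparison may be spatial (impact site vs control site) or
temporal (before vs after the pressure arrived at one site).  Records carry the
raw summary statistics (mean, dispersion, sample size per arm) so that effect
sizes and their variances can be computed downstream without information loss.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path

import pandas as pd

#: Controlled vocabulary of benthic habitats and associated biotopes.
HABITATS = frozenset({
    "reef", "sandbank", "fucus", "furcellaria", "suspension_feeders",
    "zostera", "charophytes", "higher_plants",
})

#: Controlled vocabulary of human-induced pressures.  The joint key
#: ``round_goby_and_mud_crab`` is a first-class pressure: studies observing
#: both invaders together are direct evidence for the combined effect.
PRESSURES = frozenset({
    "nutrient_load", "round_goby", "mud_crab", "round_goby_and_mud_crab",
    "wind_park",
})

COMPARISON_MODES = frozenset({"spatial", "temporal"})
DISPERSION_KINDS = frozenset({"sd", "se"})

#: Exact CSV header, in order.
CSV_COLUMNS = (
    "study_id", "habitat_id", "pressure_id", "comparison_mode",
    "mean_impact", "dispersion_impact", "dispersion_kind_impact", "n_impact",
    "mean_reference", "dispersion_reference", "dispersion_kind_reference",
    "n_reference", "response_unit", "source",
)


class EvidenceError(ValueError):
    """Schema or validation failure in an evidence table."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One impact-vs-reference comparison for a habitat under a pressure."""

    study_id: str
    habitat_id: str
    pressure_id: str
    comparison_mode: str
    mean_impact: float
    dispersion_impact: float
    dispersion_kind_impact: str
    n_impact: int
    mean_reference: float
    dispersion_reference: float
    dispersion_kind_reference: str
    n_reference: int
    response_unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.habitat_id not in HABITATS:
            raise EvidenceError(f"unknown habitat_id {self.habitat_id!r}")
        if self.pressure_id not in PRESSURES:
            raise EvidenceError(f"unknown pressure_id {self.pressure_id!r}")
        if self.comparison_mode not in COMPARISON_MODES:
            raise EvidenceError(
                f"comparison_mode must be spatial or temporal, got "
                f"{self.comparison_mode!r}")
        for kind in (self.dispersion_kind_impact, self.dispersion_kind_reference):
            if kind not in DISPERSION_KINDS:
                raise EvidenceError(f"dispersion kind must be sd or se, got {kind!r}")
        if self.mean_reference <= 0:
            raise EvidenceError("mean_reference must be > 0")
        if self.mean_impact < 0:
            raise EvidenceError("mean_impact must be >= 0")
        if self.dispersion_impact < 0 or self.dispersion_reference < 0:
            raise EvidenceError("dispersions must be >= 0")
        if self.n_impact < 1 or self.n_reference < 1:
            raise EvidenceError("sample sizes must be >= 1")


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Read a validated evidence table from CSV.

    The header must match :data:`CSV_COLUMNS` exactly (order included).  SE
    dispersions are kept as given; normalisation to SD happens at effect-size
    computation.  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        if header != CSV_COLUMNS:
            missing = set(CSV_COLUMNS) - set(header)
            extra = set(header) - set(CSV_COLUMNS)
            raise EvidenceError(
                f"evidence CSV header mismatch in {path.name}: "
                f"missing columns {sorted(missing)}, unknown columns {sorted(extra)}")
        records = []
        for i, row in enumerate(reader):
            try:
                records.append(EvidenceRecord(
                    study_id=row["study_id"],
                    habitat_id=row["habitat_id"],
                    pressure_id=row["pressure_id"],
                    comparison_mode=row["comparison_mode"],
                    mean_impact=float(row["mean_impact"]),
                    dispersion_impact=float(row["dispersion_impact"]),
                    dispersion_kind_impact=row["dispersion_kind_impact"],
                    n_impact=int(row["n_impact"]),
                    mean_reference=float(row["mean_reference"]),
                    dispersion_reference=float(row["dispersion_reference"]),
                    dispersion_kind_reference=row["dispersion_kind_reference"],
                    n_reference=int(row["n_reference"]),
                    response_unit=row["response_unit"],
                    source=row["source"],
                ))
            except (EvidenceError, KeyError, TypeError) as exc:
                raise EvidenceError(f"row {i + 1}: {exc}") from exc
            except ValueError as exc:  # float()/int() parse failures
                raise EvidenceError(f"row {i + 1}: {exc}") from exc
    return records


def write_evidence(records: list[EvidenceRecord], path: str | Path) -> Path:
    """Write records to CSV; ``read_evidence`` round-trips at full precision."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.study_id, rec.habitat_id, rec.pressure_id,
                rec.comparison_mode,
                repr(rec.mean_impact), repr(rec.dispersion_impact),
                rec.dispersion_kind_impact, rec.n_impact,
                repr(rec.mean_reference), repr(rec.dispersion_reference),
                rec.dispersion_kind_reference, rec.n_reference,
                rec.response_unit, rec.source,
            ])
    return path


def count_observations(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Observation counts per (habitat_id, pressure_id).

    Combinations without evidence are absent, not zero-filled — the output
    mirrors the structure of a published evidence-count table.
    """
    counts = Counter((r.habitat_id, r.pressure_id) for r in records)
    rows = [
        {"habitat_id": h, "pressure_id": p, "n_observations": n}
        for (h, p), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["habitat_id", "pressure_id", "n_observations"])


def records_to_frame(records: list[EvidenceRecord]) -> pd.DataFrame:
    """Evidence records as a pandas DataFrame (one row per record)."""
    cols = [f.name for f in dataclass_fields(EvidenceRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def demo_evidence_path() -> Path:
    """Path of the packaged demonstration evidence table.

    The file is synthetic but reproduces the published observation counts per
    habitat-pressure combination, so count-level examples need no external
    data.
    """
    return Path(__file__).parent / "data" / "demo_evidence.csv"


def load_demo_evidence() -> list[EvidenceRecord]:
    """Load the packaged synthetic demonstration evidence table."""
    return read_evidence(demo_evidence_path())
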