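"""Patient-level cohort handling: loading, selection filters, T staging,
and descriptive summaries.

The expected CSV schema (one row per pancreaticoduodenectomy patient)::

    patient_id, tumor_size_cm, t_stage, examined_nodes, positive_nodes,
    metastatic, histology_code, record_complete

``tumor_size_cm`` or ``t_stage`` may be blank (not both); ``metastatic``
and ``record_complete`` are booleans (true/false/1/0).  This is a minimal
documented schema, not a raw registry export format — registry case
listings are access-controlled and version-dependent, so conversion to
this schema is left to a site-specific step (see ``seer_converter_stub``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_CONFIG,
    CohortFormatError,
    ModelConfig,
    NodalStageError,
    StagingError,
)

logger = logging.getLogger("nodalstage")

PDAC_HISTOLOGY_CODES = frozenset({"8140/3", "8500/3"})  # ICD-O-3 adenocarcinoma codes

COHORT_COLUMNS = (
    "patient_id",
    "tumor_size_cm",
    "t_stage",
    "examined_nodes",
    "positive_nodes",
    "metastatic",
    "histology_code",
    "record_complete",
)

# AJCC 8th edition pancreas T categories by greatest tumour dimension
T_STAGE_SIZE_CUTOFFS_CM = ((2.0, "T1"), (4.0, "T2"), (float("inf"), "T3"))


class SummaryError(NodalStageError):
    """A summary was requested on an empty cohort."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    examined_nodes: int
    positive_nodes: int
    tumor_size_cm: float | None = None
    t_stage: str | None = None
    metastatic: bool = False
    histology_code: str = "8140/3"
    record_complete: bool = True
    true_involved: int | None = None  # simulator ground truth; never in the main CSV


@dataclass
class LoadedCohort:
    records: list[PatientRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "t", "yes"):
        return True
    if text in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def load_cohort(path: str | Path) -> LoadedCohort:
    """Parse a cohort CSV; malformed rows go to a rejects report."""
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise CohortFormatError(f"cohort CSV missing mandatory columns: {sorted(missing)}")
    result = LoadedCohort(records=[])
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            size = row.tumor_size_cm.strip()
            stage = row.t_stage.strip()
            rec = PatientRecord(
                patient_id=row.patient_id,
                tumor_size_cm=float(size) if size else None,
                t_stage=stage or None,
                examined_nodes=int(row.examined_nodes),
                positive_nodes=int(row.positive_nodes),
                metastatic=_parse_bool(row.metastatic),
                histology_code=row.histology_code.strip(),
                record_complete=_parse_bool(row.record_complete),
            )
            if rec.examined_nodes < 0 or rec.positive_nodes < 0:
                raise ValueError("node counts must be non-negative")
            if rec.positive_nodes > rec.examined_nodes:
                raise ValueError(
                    f"positive_nodes={rec.positive_nodes} exceeds "
                    f"examined_nodes={rec.examined_nodes}"
                )
            if rec.tumor_size_cm is not None and rec.tumor_size_cm <= 0:
                raise ValueError("tumor_size_cm must be positive")
        except (ValueError, TypeError) as exc:
            result.rejects.append((i, str(exc)))
            continue
        result.records.append(rec)
    if not result.records:
        logger.warning("cohort file %s produced no valid records", path)
    if result.rejects:
        logger.warning("%d malformed rows rejected from %s", len(result.rejects), path)
    return result


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "tumor_size_cm": "" if r.tumor_size_cm is None else r.tumor_size_cm,
                "t_stage": r.t_stage or "",
                "examined_nodes": r.examined_nodes,
                "positive_nodes": r.positive_nodes,
                "metastatic": r.metastatic,
                "histology_code": r.histology_code,
                "record_complete": r.record_complete,
            }
        )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


@dataclass
class SelectionResult:
    records: list[PatientRecord]
    exclusion_counts: dict[str, int]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


SELECTION_FILTERS = ("incomplete_record", "no_nodes_examined", "metastasis", "histology")


def apply_selection(
    cohort: Iterable[PatientRecord], config: ModelConfig = DEFAULT_CONFIG
) -> SelectionResult:
    """Apply the cohort selection filters, counting exclusions per filter.

    Order: incomplete record -> fewer than 1 node examined -> distant
    metastasis -> non-adenocarcinoma histology.  A record is counted under
    the first filter it fails.  Filters never raise; they count.
    """
    counts = dict.fromkeys(SELECTION_FILTERS, 0)
    kept: list[PatientRecord] = []
    for rec in cohort:
        if not rec.record_complete:
            counts["incomplete_record"] += 1
        elif rec.examined_nodes < 1:
            counts["no_nodes_examined"] += 1
        elif rec.metastatic:
            counts["metastasis"] += 1
        elif rec.histology_code not in PDAC_HISTOLOGY_CODES:
            counts["histology"] += 1
        else:
            kept.append(rec)
    return SelectionResult(records=kept, exclusion_counts=counts)


def assign_t_stage(record: PatientRecord) -> str:
    """T stage from the coded value, or from tumour size (AJCC 8th:
    T1 <= 2 cm < T2 <= 4 cm < T3).  A coded stage wins over a
    contradictory size, with a logged discrepancy."""
    size_stage = None
    if record.tumor_size_cm is not None:
        for cutoff, label in T_STAGE_SIZE_CUTOFFS_CM:
            if record.tumor_size_cm <= cutoff:
                size_stage = label
                break
    if record.t_stage is not None:
        if size_stage is not None and size_stage != record.t_stage:
            logger.info(
                "patient %s: coded stage %s disagrees with size-derived %s "
                "(%.1f cm); keeping the coded stage",
                record.patient_id, record.t_stage, size_stage, record.tumor_size_cm,
            )
        return record.t_stage
    if size_stage is None:
        raise StagingError(
            f"patient {record.patient_id} has neither a coded T stage nor a tumour size"
        )
    return size_stage


def stage_cohort(cohort: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Return records with ``t_stage`` filled in for every patient."""
    return [replace(rec, t_stage=assign_t_stage(rec)) for rec in cohort]


def n_category(positive_nodes: int, config: ModelConfig = DEFAULT_CONFIG) -> str:
    """AJCC N category from the positive-node count (N0 / N1 / N2)."""
    if positive_nodes == 0:
        return "N0"
    if positive_nodes < config.n2_cutoff:
        return "N1"
    return "N2"


@dataclass
class CohortSummary:
    per_stage: pd.DataFrame
    n_patients: int
    inadequate_proportion: float  # examined_nodes < total_nodes
    eln_category_counts: dict[str, int]  # "<10", "10-14", ">=15"

    def to_text(self) -> str:
        lines = [
            f"Patients: {self.n_patients}",
            f"Inadequate lymphadenectomy (< 15 examined): "
            f"{self.inadequate_proportion:.1%}",
            "Examined-node categories: "
            + ", ".join(f"{k}: {v}" for k, v in self.eln_category_counts.items()),
            "",
            "Per-stage (median ELN with 25th-75th percentile range):",
            self.per_stage.to_string(index=False),
        ]
        return "\n".join(lines) + "\n"


def summarize_cohort(
    cohort: Iterable[PatientRecord], config: ModelConfig = DEFAULT_CONFIG
) -> CohortSummary:
    """Per-stage nodal status summary plus cohort-wide adequacy figures.

    The examined-node spread is reported as the 25th-75th percentile range
    around the median (labelled as such in output).
    """
    records = list(cohort)
    if not records:
        raise SummaryError("cannot summarise an empty cohort")
    frame = pd.DataFrame(
        {
            "stage": [r.t_stage or "unstaged" for r in records],
            "eln": [r.examined_nodes for r in records],
            "pln": [r.positive_nodes for r in records],
        }
    )
    frame["n_cat"] = [n_category(p, config) for p in frame["pln"]]
    rows = []
    for stage, grp in frame.groupby("stage", sort=True):
        cats = grp["n_cat"].value_counts()
        total = len(grp)
        row = {
            "stage": stage,
            "patients": total,
            "eln_median": float(np.median(grp["eln"])),
            "eln_q1": float(np.percentile(grp["eln"], 25)),
            "eln_q3": float(np.percentile(grp["eln"], 75)),
        }
        for cat in ("N0", "N1", "N2"):
            count = int(cats.get(cat, 0))
            row[cat] = count
            row[f"{cat}_pct"] = round(100.0 * count / total, 1)
        rows.append(row)
    eln = frame["eln"].to_numpy()
    categories = {
        "<10": int((eln < 10).sum()),
        "10-14": int(((eln >= 10) & (eln < config.total_nodes)).sum()),
        ">=15": int((eln >= config.total_nodes).sum()),
    }
    return CohortSummary(
        per_stage=pd.DataFrame(rows),
        n_patients=len(records),
        inadequate_proportion=float((eln < config.total_nodes).mean()),
        eln_category_counts=categories,
    )


def seer_converter_stub(path: str | Path) -> None:
    """Placeholder for a site-specific converter from a registry case
    listing to the documented cohort schema.  Registry export formats are
    access-controlled and change between submissions, so no parser for
    them is shipped; adapt this function to your extract."""
    raise NotImplementedError(
        "convert your registry case listing to the documented cohort CSV "
        "schema (see module docstring) with a site-specific script"
    )
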