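"""Registry-like cohort simulator.

Generates pancreaticoduodenectomy cohorts with exactly the generative
structure the staging model assumes, so that every pipeline stage — and the
model's posterior probabilities themselves — can be checked against known
ground truth:

1. a T stage is drawn from the stage mixture;
2. the true involved-node count M is drawn from that stage's prior q(M);
3. the examined-node count n is drawn from the ELN distribution;
4. the observed positive count m is a hypergeometric draw of n nodes
   without replacement from the pool of ``total_nodes`` (involved nodes
   are exchangeable — no node is preferentially sampled);
5. a small fraction of records is contaminated (metastatic disease,
   incomplete records) to exercise the selection filters.

Patients whose ELN meets or exceeds the assumed pool size are complete
dissections: their observed count equals M.  The true M of every record is
kept in memory (``PatientRecord.true_involved``) and written to a sidecar
file, never to the main cohort CSV, so the main file has the shape of real
registry data.

Default parameters emulate the published SEER pancreaticoduodenectomy
cohort this model was built for: stage mixture 18.5/60.8/20.7% (T1/T2/T3),
examined-node mass 32.9/22.7/44.4% over the <10 / 10-14 / >=15 categories
(uniform within category, tail to 24 nodes; median 13), and stage priors
recovered by inverting the published per-stage accuracy tables, with q(0)
set to the published node-negative proportions (47.8/33.2/31.4%).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import PatientRecord, write_cohort
from .model import InputDomainError, ModelConfig
from .priors import NodalPrior

logger = logging.getLogger("nodalstage")

DEFAULT_STAGE_MIXTURE = {"T1": 0.185, "T2": 0.608, "T3": 0.207}
NODE_NEGATIVE_PROPORTIONS = {"T1": 0.478, "T2": 0.332, "T3": 0.314}
ELN_CATEGORY_MASS = {"<10": 0.329, "10-14": 0.227, ">=15": 0.444}
ELN_TAIL_MAX = 24  # registry ELN counts run past the 15-node model pool

# tumour-size bands (cm) per AJCC 8th pancreas T category, for record realism
STAGE_SIZE_BANDS = {"T1": (0.6, 2.0), "T2": (2.1, 4.0), "T3": (4.1, 8.0)}


def default_eln_distribution(total_nodes: int = 15) -> dict[int, float]:
    """Categorical ELN distribution matching the published <10 / 10-14 /
    >=15 category masses, uniform within each category."""
    probs: dict[int, float] = {}
    low = list(range(1, 10))
    mid = list(range(10, total_nodes))
    high = list(range(total_nodes, ELN_TAIL_MAX + 1))
    for ns, mass in ((low, ELN_CATEGORY_MASS["<10"]), (mid, ELN_CATEGORY_MASS["10-14"]),
                     (high, ELN_CATEGORY_MASS[">=15"])):
        for n in ns:
            probs[n] = mass / len(ns)
    return probs


@lru_cache(maxsize=None)
def default_stage_priors(total_nodes: int = 15) -> dict[str, NodalPrior]:
    """Stage priors for the simulator: the published per-stage accuracy
    tables inverted to q(M | M >= 1), rescaled so q(0) equals the
    published node-negative proportion of the stage."""
    from .inversion import invert_table, reference_cells

    config = ModelConfig(total_nodes=total_nodes)
    priors = {}
    for stage, q0 in NODE_NEGATIVE_PROPORTIONS.items():
        conditional = invert_table(
            reference_cells(stage, "accuracy"), config, stage_label=stage
        )
        probs = conditional.probs * (1.0 - q0)
        probs[0] = q0
        priors[stage] = NodalPrior(stage_label=stage, probs=probs / probs.sum())
    return priors


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for one simulated cohort."""

    n_patients: int = 10_000
    stage_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MIXTURE)
    )
    stage_priors: dict[str, NodalPrior] | None = None  # None -> published defaults
    total_nodes: int = 15
    eln_distribution: dict[int, float] | None = None  # None -> category defaults
    metastatic_rate: float = 0.03
    missingness_rate: float = 0.02
    seed: int = 0

    def resolved_priors(self) -> dict[str, NodalPrior]:
        if self.stage_priors is not None:
            return self.stage_priors
        return default_stage_priors(self.total_nodes)

    def resolved_eln(self) -> dict[int, float]:
        dist = self.eln_distribution or default_eln_distribution(self.total_nodes)
        total = sum(dist.values())
        return {int(n): p / total for n, p in sorted(dist.items())}

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InputDomainError("n_patients must be >= 1")
        if self.total_nodes < 1:
            raise InputDomainError("total_nodes must be >= 1")
        for name, rate in (("metastatic_rate", self.metastatic_rate),
                           ("missingness_rate", self.missingness_rate)):
            if not 0.0 <= rate < 1.0:
                raise InputDomainError(f"{name} must be in [0, 1), got {rate}")
        mix_total = sum(self.stage_mixture.values())
        if not np.isclose(mix_total, 1.0, rtol=0, atol=1e-6):
            raise InputDomainError(f"stage mixture must sum to 1, got {mix_total}")
        if any(p < 0 for p in self.stage_mixture.values()):
            raise InputDomainError("stage mixture probabilities must be non-negative")
        priors = self.resolved_priors()
        missing = set(self.stage_mixture) - set(priors)
        if missing:
            raise InputDomainError(f"no prior supplied for stages {sorted(missing)}")
        for prior in priors.values():
            if prior.total_nodes != self.total_nodes:
                raise InputDomainError(
                    f"prior for {prior.stage_label} covers 0..{prior.total_nodes}, "
                    f"expected 0..{self.total_nodes}"
                )
        eln = self.resolved_eln()
        if any(n < 1 for n in eln):
            raise InputDomainError("examined-node counts must be >= 1")

    @classmethod
    def from_mapping(cls, payload: Mapping) -> "SyntheticCohortSpec":
        payload = dict(payload)
        priors = payload.pop("stage_priors", None)
        if priors is not None:
            priors = {
                stage: NodalPrior(stage_label=stage, probs=np.asarray(q, dtype=float))
                for stage, q in priors.items()
            }
        eln = payload.pop("eln_distribution", None)
        if eln is not None:
            eln = {int(k): float(v) for k, v in eln.items()}
        return cls(stage_priors=priors, eln_distribution=eln, **payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortSpec":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortSpec":
        return cls.from_mapping(json.loads(Path(path).read_text()))


def simulate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """Draw a cohort from the spec; reproducible given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    priors = spec.resolved_priors()
    eln = spec.resolved_eln()
    N = spec.total_nodes

    stages = sorted(spec.stage_mixture)
    stage_p = np.array([spec.stage_mixture[s] for s in stages])
    stage_idx = rng.choice(len(stages), size=spec.n_patients, p=stage_p / stage_p.sum())

    M = np.empty(spec.n_patients, dtype=int)
    for i, stage in enumerate(stages):
        mask = stage_idx == i
        M[mask] = rng.choice(N + 1, size=int(mask.sum()), p=priors[stage].probs)

    eln_values = np.array(list(eln))
    n = rng.choice(eln_values, size=spec.n_patients, p=np.array(list(eln.values())))

    m = np.where(n >= N, M, 0)
    partial = n < N
    if partial.any():
        m[partial] = rng.hypergeometric(M[partial], N - M[partial], n[partial])

    metastatic = rng.random(spec.n_patients) < spec.metastatic_rate
    incomplete = rng.random(spec.n_patients) < spec.missingness_rate
    histology = np.where(rng.random(spec.n_patients) < 0.95, "8140/3", "8500/3")

    sizes = np.empty(spec.n_patients)
    for i, stage in enumerate(stages):
        mask = stage_idx == i
        lo, hi = STAGE_SIZE_BANDS.get(stage, (0.6, 8.0))
        sizes[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), 1)

    records = [
        PatientRecord(
            patient_id=f"S{i:07d}",
            tumor_size_cm=float(sizes[i]),
            t_stage=stages[stage_idx[i]],
            examined_nodes=int(n[i]),
            positive_nodes=int(m[i]),
            metastatic=bool(metastatic[i]),
            histology_code=str(histology[i]),
            record_complete=not bool(incomplete[i]),
            true_involved=int(M[i]),
        )
        for i in range(spec.n_patients)
    ]
    logger.info("simulated %d patients (seed %d)", spec.n_patients, spec.seed)
    return records


def write_truth_sidecar(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write the hidden true involved-node counts next to a cohort CSV."""
    pd.DataFrame(
        [{"patient_id": r.patient_id, "true_involved": r.true_involved} for r in records]
    ).to_csv(path, index=False)


def write_simulated_cohort(
    records: Iterable[PatientRecord], cohort_path: str | Path, truth_path: str | Path
) -> None:
    records = list(records)
    write_cohort(records, cohort_path)
    write_truth_sidecar(records, truth_path)
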