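"""Empirical priors over the true involved-node count.

Patients with at least ``total_nodes`` examined nodes are treated as
complete dissections: for them the observed positive count *is* the true
involved count M.  The stage-specific prior is the raw relative frequency

    q(M) = (# complete-dissection patients in the stage with M positives)
           / (# complete-dissection patients in the stage),

with no smoothing by default.  Patients reporting more positives than the
assumed node pool are capped at ``total_nodes`` (policy "cap") or dropped
(policy "exclude").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_CONFIG, EstimationError, InputDomainError, ModelConfig

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import PatientRecord

logger = logging.getLogger("nodalstage")


@dataclass(frozen=True)
class NodalPrior:
    """Probability vector q(M), M = 0..total_nodes, for one T stage.

    ``undetermined`` lists support points a table inversion could not
    identify — always M = 0 (every m >= 1 cell carries zero likelihood at
    M = 0), and any M no supplied cell probes (e.g. M = total_nodes when
    no cell has m = n).  For such priors ``probs`` is the distribution
    conditional on the identifiable support, which yields identical
    posteriors at every observation whose likelihood vanishes on the
    undetermined points.
    """

    stage_label: str
    probs: np.ndarray
    n_patients: int = 0
    undetermined: tuple[int, ...] = ()

    @property
    def q0_undetermined(self) -> bool:
        return 0 in self.undetermined

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 1 or probs.size < 2:
            raise InputDomainError("prior must be a 1-d vector over M = 0..total_nodes")
        if np.any(probs < 0):
            raise InputDomainError("prior probabilities must be non-negative")
        total = probs.sum()
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise InputDomainError(f"prior must sum to 1, got {total!r}")

    @property
    def total_nodes(self) -> int:
        return self.probs.size - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage_label": self.stage_label,
                "M": np.arange(self.probs.size),
                "q": self.probs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage_label": self.stage_label,
            "q": self.probs.tolist(),
            "n_patients": self.n_patients,
            "undetermined": list(self.undetermined),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NodalPrior":
        payload = json.loads(Path(path).read_text())
        return cls(
            stage_label=payload["stage_label"],
            probs=np.asarray(payload["q"], dtype=float),
            n_patients=int(payload.get("n_patients", 0)),
            undetermined=tuple(payload.get("undetermined", ())),
        )

    @classmethod
    def from_csv(cls, path: str | Path, stage_label: str | None = None) -> "NodalPrior":
        frame = pd.read_csv(path)
        if stage_label is not None:
            frame = frame[frame["stage_label"] == stage_label]
        elif frame["stage_label"].nunique() != 1:
            raise InputDomainError("prior CSV holds several stages; pass stage_label")
        frame = frame.sort_values("M")
        if not np.array_equal(frame["M"].to_numpy(), np.arange(len(frame))):
            raise InputDomainError("prior CSV must cover M = 0..total_nodes contiguously")
        return cls(
            stage_label=str(frame["stage_label"].iloc[0]),
            probs=frame["q"].to_numpy(dtype=float),
        )


def uniform_prior(config: ModelConfig = DEFAULT_CONFIG, stage_label: str = "uniform") -> NodalPrior:
    size = config.total_nodes + 1
    return NodalPrior(stage_label=stage_label, probs=np.full(size, 1.0 / size))


def point_prior(
    M: int, config: ModelConfig = DEFAULT_CONFIG, stage_label: str = "point"
) -> NodalPrior:
    if not 0 <= M <= config.total_nodes:
        raise InputDomainError(f"M={M} outside 0..{config.total_nodes}")
    probs = np.zeros(config.total_nodes + 1)
    probs[M] = 1.0
    return NodalPrior(stage_label=stage_label, probs=probs)


def estimate_prior(
    cohort: Iterable["PatientRecord"],
    stage: str | None,
    config: ModelConfig = DEFAULT_CONFIG,
    *,
    pseudocount: float = 0.0,
    overflow_policy: str = "cap",
) -> NodalPrior:
    """Estimate q(M) from the complete-dissection patients of one stage.

    Parameters
    ----------
    cohort:
        Patient records that already passed the selection filters.
    stage:
        T-stage label to restrict to, or None to pool all stages.
    pseudocount:
        Optional additive smoothing per count (default 0: the raw
        frequency rule).
    overflow_policy:
        How to treat patients with more positives than ``total_nodes``:
        "cap" counts them at M = total_nodes, "exclude" drops them.
    """
    if overflow_policy not in ("cap", "exclude"):
        raise InputDomainError(f"unknown overflow_policy {overflow_policy!r}")
    if pseudocount < 0:
        raise InputDomainError("pseudocount must be non-negative")
    N = config.total_nodes
    counts = [Fraction(0)] * (N + 1)
    n_patients = 0
    for rec in cohort:
        if stage is not None and rec.t_stage != stage:
            continue
        if rec.examined_nodes < N:
            continue  # incomplete dissection: true M not observed
        m = rec.positive_nodes
        if m > N:
            if overflow_policy == "exclude":
                logger.warning(
                    "patient %s has %d positive nodes > total_nodes=%d; excluded",
                    rec.patient_id, m, N,
                )
                continue
            logger.warning(
                "patient %s has %d positive nodes > total_nodes=%d; capped at %d",
                rec.patient_id, m, N, N,
            )
            m = N
        counts[m] += 1
        n_patients += 1
    if n_patients == 0:
        label = stage if stage is not None else "all stages"
        raise EstimationError(
            f"no complete-dissection patients (>= {N} examined nodes) in {label}"
        )
    if pseudocount:
        frac = Fraction(pseudocount).limit_denominator(10**9)
        counts = [c + frac for c in counts]
    total = sum(counts)
    probs = np.array([float(c / total) for c in counts])
    # rational counting, then a single float division per entry: the float
    # vector sums to 1 up to representation error only
    probs = probs / probs.sum()
    return NodalPrior(
        stage_label=stage if stage is not None else "all",
        probs=probs,
        n_patients=n_patients,
    )


def total_variation(p: Sequence[float] | np.ndarray, q: Sequence[float] | np.ndarray) -> float:
    """TV distance between two discrete distributions on the same support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise InputDomainError("distributions must share a support")
    return 0.5 * float(np.abs(p - q).sum())
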