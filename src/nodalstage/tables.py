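"""Accuracy and N2-probability tables, and adequacy threshold queries.

The tables grid the two posterior summaries over examined-node counts
(rows) and observed positive counts (columns), one table per T stage —
the clinician-facing output of the model.  Threshold queries answer
"how many nodes must be examined before the report can be trusted":
either to a stated accuracy level, or to rule out occult N2 stage
entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    DEFAULT_CONFIG,
    InferenceError,
    InputDomainError,
    ModelConfig,
    Observation,
    PriorLike,
    accuracy,
    prob_at_least,
)

logger = logging.getLogger("nodalstage")

DEFAULT_N_RANGE = range(4, 15)  # examined-node rows printed in the field's tables
DEFAULT_M_RANGE = range(1, 4)  # 1..3 observed positives (N1 territory)

TABLE_KINDS = ("accuracy", "n2_probability")


def round_percent(p: float, decimals: int = 1) -> float:
    """Round a probability to a percentage, half away from zero."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(p * 100.0)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class PosteriorTable:
    """Grid of posterior accuracy or N2-probability values over (n, m).

    ``values[(n, m)]`` is a probability; infeasible or failed cells are
    absent from the mapping rather than zero-filled.
    """

    kind: str
    stage_label: str
    n_values: Sequence[int]
    m_values: Sequence[int]
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise InputDomainError(f"kind must be one of {TABLE_KINDS}, got {self.kind!r}")

    def cell(self, n: int, m: int) -> float | None:
        return self.values.get((n, m))

    def to_dataframe(self, *, percent: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(index=list(self.n_values), columns=list(self.m_values), dtype=float)
        frame.index.name = "examined_nodes"
        frame.columns.name = "positive_nodes_observed"
        for (n, m), v in self.values.items():
            frame.loc[n, m] = round_percent(v) if percent else v
        return frame

    def to_csv(self, path: str | Path, *, percent: bool = True) -> None:
        self.to_dataframe(percent=percent).to_csv(path)

    def to_text(self) -> str:
        frame = self.to_dataframe(percent=True)
        body = frame.map(lambda v: "-" if pd.isna(v) else f"{v:.1f}%")
        title = {
            "accuracy": "Accuracy of the reported positive-node count",
            "n2_probability": "Probability of >= 4 positive lymph nodes",
        }[self.kind]
        return f"{title} ({self.stage_label})\n{body.to_string()}\n"


def _build_table(
    kind: str,
    prior: PriorLike,
    n_range: Iterable[int],
    m_range: Iterable[int],
    config: ModelConfig,
) -> PosteriorTable:
    n_values = list(n_range)
    m_values = list(m_range)
    for v in (*n_values, *m_values):
        if not 1 <= v <= config.total_nodes:
            raise InputDomainError(f"table range value {v} outside 1..{config.total_nodes}")
    stage = getattr(prior, "stage_label", "prior")
    table = PosteriorTable(kind=kind, stage_label=stage, n_values=n_values, m_values=m_values)
    for n in n_values:
        for m in m_values:
            if m > n:
                continue  # infeasible cell stays absent
            obs = Observation(n=n, m=m)
            try:
                if kind == "accuracy":
                    table.values[(n, m)] = accuracy(prior, obs, config)
                else:
                    table.values[(n, m)] = prob_at_least(prior, obs, config.n2_cutoff, config)
            except InferenceError as exc:
                logger.warning("cell (n=%d, m=%d) left absent: %s", n, m, exc)
    return table


def accuracy_table(
    prior: PriorLike,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    m_range: Iterable[int] = DEFAULT_M_RANGE,
    config: ModelConfig = DEFAULT_CONFIG,
) -> PosteriorTable:
    """Posterior accuracy r(m | n, m) over a grid of (n, m)."""
    return _build_table("accuracy", prior, n_range, m_range, config)


def n2_table(
    prior: PriorLike,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    m_range: Iterable[int] = DEFAULT_M_RANGE,
    config: ModelConfig = DEFAULT_CONFIG,
) -> PosteriorTable:
    """Posterior probability of N2 stage (>= n2_cutoff involved nodes)."""
    return _build_table("n2_probability", prior, n_range, m_range, config)


def min_eln_for_accuracy(
    prior: PriorLike,
    m: int,
    threshold: float | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> int | None:
    """Smallest number of examined nodes at which the posterior accuracy of
    an observation of ``m`` positives reaches ``threshold``.

    The comparison uses the unrounded probability (>=), not the displayed
    one-decimal percentage.  Defaults to the configured certainty level.
    """
    if threshold is None:
        threshold = config.certainty_threshold
    if not 0.0 < threshold <= 1.0:
        raise InputDomainError(f"threshold must be in (0, 1], got {threshold}")
    if m < 1:
        raise InputDomainError(f"m must be >= 1, got {m}")
    for n in range(m, config.total_nodes + 1):
        if accuracy(prior, Observation(n=n, m=m), config) >= threshold:
            return n
    return None


def min_eln_rule_out_n2(
    prior: PriorLike,
    m: int,
    config: ModelConfig = DEFAULT_CONFIG,
) -> int:
    """Smallest number of examined nodes at which the posterior probability
    of N2 stage is exactly zero, given ``m`` observed positives.

    For any prior with mass at or above the N2 cutoff this is
    ``total_nodes - (n2_cutoff - 1 - m)``: enough nodes must be examined
    that the unexamined remainder cannot hide a fourth involved node.
    """
    if not 1 <= m < config.n2_cutoff:
        raise InputDomainError(
            f"m must be in [1, {config.n2_cutoff - 1}] (an observation of "
            f">= {config.n2_cutoff} positives is already N2), got {m}"
        )
    for n in range(m, config.total_nodes + 1):
        if prob_at_least(prior, Observation(n=n, m=m), config.n2_cutoff, config) == 0.0:
            return n
    raise InferenceError(f"no examined-node count rules out N2 for m={m}")  # pragma: no cover


def threshold_report(
    prior: PriorLike,
    config: ModelConfig = DEFAULT_CONFIG,
    accuracy_levels: Sequence[float] = (0.80, 0.90),
) -> pd.DataFrame:
    """Adequacy thresholds for m = 1..n2_cutoff-1: the minimum examined-node
    counts to rule out N2 and to reach each accuracy level."""
    rows = []
    for m in range(1, config.n2_cutoff):
        row: dict[str, object] = {
            "positive_nodes_observed": m,
            "min_eln_zero_n2": min_eln_rule_out_n2(prior, m, config),
        }
        for level in accuracy_levels:
            row[f"min_eln_accuracy_{int(round(level * 100))}"] = min_eln_for_accuracy(
                prior, m, level, config
            )
        rows.append(row)
    return pd.DataFrame(rows)
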