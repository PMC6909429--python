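"""Recovering the empirical prior q(M) from a printed posterior table.

Each printed accuracy cell v at (n, m) satisfies

    v * sum_M q(M) P(n,m,N,M)  =  q(m) P(n,m,N,m),

and each N2-probability cell the analogous cumulative identity, so every
cell is one homogeneous linear constraint on the prior vector.  Stacking
the cells and appending a normalisation row gives a small non-negative
least-squares problem whose solution reproduces the prior that generated
the table — exactly for full-precision cells, and to within rounding noise
for cells printed at one decimal of a percent.

q(0) multiplies a zero likelihood in every cell with m >= 1 and is
therefore unidentifiable; the recovered prior is the distribution
conditional on M >= 1, with q(0) flagged undetermined.  Posteriors for any
observation with m >= 1 are unaffected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .model import (
    DEFAULT_CONFIG,
    InputDomainError,
    InversionError,
    ModelConfig,
    Observation,
    hypergeom_pmf,
)
from .priors import NodalPrior
from .tables import TABLE_KINDS, round_percent

logger = logging.getLogger("nodalstage")


@dataclass(frozen=True)
class TableCell:
    """One printed table cell: a posterior value at (n, m)."""

    n: int
    m: int
    value: float  # probability in [0, 1]
    kind: str  # "accuracy" or "n2_probability"

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise InputDomainError(f"kind must be one of {TABLE_KINDS}, got {self.kind!r}")
        if not 0.0 <= self.value <= 1.0:
            raise InputDomainError(f"cell value must be in [0, 1], got {self.value}")
        Observation(n=self.n, m=self.m)  # validates 0 <= m <= n


def load_cells(
    path: str | Path, *, stage: str | None = None, kind: str | None = None
) -> list[TableCell]:
    """Read table cells from a CSV with columns (kind, n, m, value_percent)
    and optionally a stage column."""
    frame = pd.read_csv(path)
    required = {"kind", "n", "m", "value_percent"}
    missing = required - set(frame.columns)
    if missing:
        raise InputDomainError(f"table CSV missing columns: {sorted(missing)}")
    if stage is not None:
        if "stage" not in frame.columns:
            raise InputDomainError("table CSV has no 'stage' column to filter on")
        frame = frame[frame["stage"] == stage]
    if kind is not None:
        frame = frame[frame["kind"] == kind]
    return [
        TableCell(n=int(r.n), m=int(r.m), value=float(r.value_percent) / 100.0, kind=str(r.kind))
        for r in frame.itertuples()
    ]


def reference_cells(stage: str, kind: str | None = None) -> list[TableCell]:
    """Cells of the published per-stage tables shipped with the package
    (SEER-based pancreaticoduodenectomy study, 15-node model)."""
    ref = resources.files("nodalstage.data").joinpath("reference_tables.csv")
    with resources.as_file(ref) as path:
        return load_cells(path, stage=stage, kind=kind)


def _dedupe(cells: Sequence[TableCell]) -> list[TableCell]:
    groups: dict[tuple[int, int, str], list[float]] = {}
    order: list[tuple[int, int, str]] = []
    for c in cells:
        key = (c.n, c.m, c.kind)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(c.value)
    out = []
    for key in order:
        vals = groups[key]
        if len(vals) > 1:
            logger.warning("duplicate cell (n=%d, m=%d, %s): averaging %d values", *key, len(vals))
        out.append(TableCell(n=key[0], m=key[1], value=float(np.mean(vals)), kind=key[2]))
    return out


def _constraint_row(cell: TableCell, config: ModelConfig) -> np.ndarray:
    """Homogeneous constraint coefficients over q(1)..q(N) for one cell."""
    N = config.total_nodes
    pmf = np.array([hypergeom_pmf(cell.n, cell.m, N, M) for M in range(N + 1)])
    if cell.kind == "accuracy":
        target = np.zeros(N + 1)
        target[cell.m] = pmf[cell.m]
    else:
        target = np.where(np.arange(N + 1) >= config.n2_cutoff, pmf, 0.0)
    row = cell.value * pmf - target
    return row[1:]  # q(0) column is identically zero for m >= 1 cells


def invert_table(
    cells: Iterable[TableCell],
    config: ModelConfig = DEFAULT_CONFIG,
    *,
    stage_label: str = "inverted",
    norm_weight: float = 1.0,
    residual_tol: float = 0.05,
) -> NodalPrior:
    """Recover the prior that generated a set of posterior table cells.

    Solves the stacked homogeneous system by non-negative least squares
    with an appended normalisation row (deterministic; no random
    initialisation).  A residual above ``residual_tol`` logs a warning —
    printed tables are rounded, so small residuals are expected and not
    an error — while a rank-deficient system raises
    :class:`~nodalstage.model.InversionError`.
    """
    cells = _dedupe(list(cells))
    N = config.total_nodes
    bad = [c for c in cells if c.m == 0]
    if bad:
        raise InversionError("cells with m=0 carry no information about q; remove them")
    if not cells:
        raise InversionError("no cells supplied")
    A = np.vstack([_constraint_row(c, config) for c in cells])
    # a support point M is identifiable only if some cell's likelihood
    # probes it; unprobed columns (always M=0, often M=N when no cell has
    # m=n) would otherwise soak up the normalisation mass
    pmf_mat = np.vstack(
        [[hypergeom_pmf(c.n, c.m, N, M) for M in range(1, N + 1)] for c in cells]
    )
    probed = np.any(pmf_mat > 0.0, axis=0)
    idx = np.flatnonzero(probed)
    undetermined = (0, *(int(M) + 1 for M in np.flatnonzero(~probed)))
    if len(cells) < idx.size:
        raise InversionError(
            f"need at least {idx.size} cells to identify the {idx.size} probed "
            f"support points, got {len(cells)}"
        )
    A_id = A[:, idx]
    rank = np.linalg.matrix_rank(np.vstack([A_id, np.ones((1, idx.size))]))
    if rank < idx.size:
        raise InversionError(
            f"cell system is rank-deficient (rank {rank} < {idx.size}); add "
            "cells at more (n, m) combinations"
        )
    stacked = np.vstack([A_id, norm_weight * np.ones((1, idx.size))])
    rhs = np.zeros(len(cells) + 1)
    rhs[-1] = norm_weight
    q_id, _ = scipy.optimize.nnls(stacked, rhs)
    total = q_id.sum()
    if total <= 0:
        raise InversionError("non-negative least squares returned the zero vector")
    q_id = q_id / total
    residual = float(np.linalg.norm(A_id @ q_id))
    if residual > residual_tol:
        logger.warning(
            "inversion residual %.3g exceeds tolerance %.3g; the input cells "
            "may be internally inconsistent beyond rounding noise",
            residual, residual_tol,
        )
    probs = np.zeros(N + 1)
    probs[idx + 1] = q_id
    logger.info(
        "inverted %d cells -> prior (residual %.3g; undetermined M: %s)",
        len(cells), residual, undetermined,
    )
    return NodalPrior(
        stage_label=stage_label, probs=probs, n_patients=0, undetermined=undetermined
    )


def predict_cells(
    prior: NodalPrior,
    requests: Iterable[tuple[int, int, str]],
    config: ModelConfig = DEFAULT_CONFIG,
) -> list[TableCell]:
    """Forward-compute requested (n, m, kind) cells from a prior.

    Infeasible requests are skipped with a logged reason rather than
    raising, mirroring how absent table cells are handled.
    """
    from .model import InferenceError, accuracy, prob_at_least

    out: list[TableCell] = []
    for n, m, kind in requests:
        if kind not in TABLE_KINDS:
            raise InputDomainError(f"kind must be one of {TABLE_KINDS}, got {kind!r}")
        try:
            obs = Observation(n=n, m=m)
            obs.validate_against(config)
            if kind == "accuracy":
                value = accuracy(prior, obs, config)
            else:
                value = prob_at_least(prior, obs, config.n2_cutoff, config)
        except (InputDomainError, InferenceError) as exc:
            logger.warning("cell (n=%d, m=%d, %s) not predicted: %s", n, m, kind, exc)
            continue
        out.append(TableCell(n=n, m=m, value=value, kind=kind))
    return out


def cells_to_frame(cells: Iterable[TableCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"kind": c.kind, "n": c.n, "m": c.m, "value_percent": round_percent(c.value)}
            for c in cells
        ]
    )
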