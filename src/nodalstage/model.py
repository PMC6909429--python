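"""Bayes-hypergeometric model of true nodal involvement.

A pancreaticoduodenectomy specimen is modelled as a fixed pool of ``N``
regional lymph nodes (default 15, the ISGPS adequacy standard) of which an
unknown ``M`` are truly involved by tumour.  A lymphadenectomy that examines
``n <= N`` of those nodes is a draw of ``n`` nodes without replacement, so the
number of observed positive nodes ``m`` follows the hypergeometric
distribution ``P(n, m, N, M)``.  Combining that likelihood with an empirical
prior ``q(M)`` over the true involved count gives the posterior

    r(M | n, m)  propto  q(M) * P(n, m, N, M),

normalised over ``M``.  Two summaries of ``r`` drive everything downstream:

* *accuracy* — ``r(m | n, m)``, the probability that the count of positives
  actually reported is the whole truth; and
* the *N2 probability* — ``sum_{M >= 4} r(M | n, m)``, the probability the
  patient is really N2 stage (>= 4 involved nodes, AJCC 8th edition) despite
  the observed count.

All probabilities here are exact up to float division: binomial coefficients
are computed as integers, so structural zeros (e.g. an observation that
leaves fewer than ``4 - m`` nodes unexamined) are exactly ``0.0`` and
complete-dissection accuracies are exactly ``1.0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence, Union

import numpy as np

logger = logging.getLogger("nodalstage")

DEFAULT_TOTAL_NODES = 15
DEFAULT_N2_CUTOFF = 4
DEFAULT_CERTAINTY = 0.90
STAGES = ("T1", "T2", "T3")


class NodalStageError(Exception):
    """Base class for errors raised by this package."""


class InputDomainError(NodalStageError, ValueError):
    """An argument is outside its mathematical or clinical domain."""


class InferenceError(NodalStageError):
    """A posterior cannot be formed (e.g. prior incompatible with data)."""


class EstimationError(NodalStageError):
    """A prior cannot be estimated (e.g. no eligible patients)."""


class InversionError(NodalStageError):
    """A printed table cannot be inverted to a prior."""


class CohortFormatError(NodalStageError):
    """A cohort file is malformed (e.g. missing mandatory columns)."""


class StagingError(NodalStageError):
    """A record carries neither a coded T stage nor a tumour size."""


@dataclass(frozen=True)
class ModelConfig:
    """Global model constants.

    Parameters
    ----------
    total_nodes:
        Number of regional nodes assumed present in the specimen (``N``).
    n2_cutoff:
        Minimum involved-node count defining N2 stage (AJCC 8th: 4).
    certainty_threshold:
        Probability level used for adequacy queries (default 0.90).
    """

    total_nodes: int = DEFAULT_TOTAL_NODES
    n2_cutoff: int = DEFAULT_N2_CUTOFF
    certainty_threshold: float = DEFAULT_CERTAINTY

    def __post_init__(self) -> None:
        if self.total_nodes < 1:
            raise InputDomainError(f"total_nodes must be >= 1, got {self.total_nodes}")
        if not 1 <= self.n2_cutoff <= self.total_nodes:
            raise InputDomainError(
                f"n2_cutoff must be in [1, {self.total_nodes}], got {self.n2_cutoff}"
            )
        if not 0.0 < self.certainty_threshold <= 1.0:
            raise InputDomainError(
                f"certainty_threshold must be in (0, 1], got {self.certainty_threshold}"
            )


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class Observation:
    """An (examined, observed-positive) node count pair.

    ``n`` examined lymph nodes of which ``m`` were positive.
    """

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.m < 0:
            raise InputDomainError(f"counts must be non-negative, got n={self.n}, m={self.m}")
        if self.m > self.n:
            raise InputDomainError(
                f"observed positives m={self.m} cannot exceed examined nodes n={self.n}"
            )

    def validate_against(self, config: ModelConfig) -> None:
        if self.n > config.total_nodes:
            raise InputDomainError(
                f"examined nodes n={self.n} exceeds total_nodes={config.total_nodes}"
            )


PriorLike = Union["NodalPriorProtocol", Sequence[float], np.ndarray, Mapping[int, float]]


def hypergeom_pmf(n: int, m: int, N: int, M: int) -> float:
    """P(n, m, N, M): probability of observing ``m`` positives among ``n``
    nodes examined, when ``M`` of the ``N`` regional nodes are involved.

    Computed with exact integer binomial coefficients; infeasible
    combinations return exactly ``0.0``.
    """
    if N < 0 or n < 0 or m < 0 or M < 0:
        raise InputDomainError(f"arguments must be non-negative: n={n}, m={m}, N={N}, M={M}")
    if n > N:
        raise InputDomainError(f"sample size n={n} exceeds population N={N}")
    if m > n:
        raise InputDomainError(f"successes m={m} exceed sample size n={n}")
    if M > N:
        raise InputDomainError(f"involved count M={M} exceeds population N={N}")
    if m > M or (n - m) > (N - M):
        return 0.0
    return comb(M, m) * comb(N - M, n - m) / comb(N, n)


def feasible_range(obs: Observation, config: ModelConfig = DEFAULT_CONFIG) -> tuple[int, int]:
    """Closed range [lo, hi] of true involved counts compatible with ``obs``.

    At least the ``m`` observed positives are involved; at most the
    ``N - n`` unexamined nodes can hide further involvement.
    """
    return obs.m, obs.m + config.total_nodes - obs.n


def _prior_vector(prior: PriorLike, config: ModelConfig) -> np.ndarray:
    """Coerce a prior (NodalPrior, sequence, or {M: q} mapping) to a
    length ``total_nodes + 1`` float vector."""
    probs = getattr(prior, "probs", prior)
    size = config.total_nodes + 1
    if isinstance(probs, Mapping):
        vec = np.zeros(size)
        for M, q in probs.items():
            if not 0 <= int(M) <= config.total_nodes:
                raise InputDomainError(f"prior support M={M} outside 0..{config.total_nodes}")
            vec[int(M)] = q
    else:
        vec = np.asarray(probs, dtype=float)
        if vec.shape != (size,):
            raise InputDomainError(
                f"prior must have length {size} (M = 0..{config.total_nodes}), got {vec.shape}"
            )
    if np.any(vec < 0):
        raise InputDomainError("prior probabilities must be non-negative")
    total = vec.sum()
    if total <= 0:
        raise InputDomainError("prior has no mass")
    return vec / total


@dataclass(frozen=True)
class PosteriorDistribution:
    """Posterior r(M | n, m) over the true involved-node count."""

    probs: np.ndarray  # indexed by M = 0..total_nodes
    observation: Observation
    config: ModelConfig = field(default=DEFAULT_CONFIG)

    def prob(self, M: int) -> float:
        return float(self.probs[M])

    def prob_at_least(self, k: int) -> float:
        # complement of the ordered partial sum below k, so that structural
        # zeros and the m=3 complement identity are bitwise exact
        total = _ordered_sum(self.probs, len(self.probs))
        below = _ordered_sum(self.probs, k)
        return 1.0 - below / total

    def as_dict(self) -> dict[int, float]:
        return {M: float(p) for M, p in enumerate(self.probs)}


def _ordered_sum(values: np.ndarray, stop: int) -> float:
    acc = 0.0
    for v in values[: max(stop, 0)]:
        acc += float(v)
    return acc


def _posterior_weights(
    prior: PriorLike, obs: Observation, config: ModelConfig
) -> tuple[np.ndarray, float]:
    obs.validate_against(config)
    q = _prior_vector(prior, config)
    N = config.total_nodes
    w = np.zeros(N + 1)
    for M in range(N + 1):
        if q[M] > 0.0:
            w[M] = q[M] * hypergeom_pmf(obs.n, obs.m, N, M)
    denom = _ordered_sum(w, N + 1)
    if denom <= 0.0:
        raise InferenceError(
            f"prior assigns no mass to any involved count compatible with "
            f"observation (n={obs.n}, m={obs.m})"
        )
    return w, denom


def posterior(
    prior: PriorLike, obs: Observation, config: ModelConfig = DEFAULT_CONFIG
) -> PosteriorDistribution:
    """Posterior distribution of the true involved-node count M given an
    observation, via Bayes' theorem with hypergeometric likelihood."""
    w, denom = _posterior_weights(prior, obs, config)
    return PosteriorDistribution(probs=w / denom, observation=obs, config=config)


def accuracy(
    prior: PriorLike, obs: Observation, config: ModelConfig = DEFAULT_CONFIG
) -> float:
    """r(m | n, m): posterior probability that the observed positive count
    is the true involved count — the 'accuracy' of the reported N status."""
    w, denom = _posterior_weights(prior, obs, config)
    return float(w[obs.m]) / denom


def prob_at_least(
    prior: PriorLike,
    obs: Observation,
    k: int | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> float:
    """Posterior probability that the true involved count is >= ``k``
    (default: the N2 cutoff).  Exactly 0.0 whenever fewer than ``k - m``
    nodes remain unexamined."""
    if k is None:
        k = config.n2_cutoff
    if not 0 <= k <= config.total_nodes + 1:
        raise InputDomainError(f"cutoff k={k} outside 0..{config.total_nodes + 1}")
    w, denom = _posterior_weights(prior, obs, config)
    below = _ordered_sum(w, k)
    return 1.0 - below / denom


class NodalPriorProtocol:
    """Anything with a ``probs`` vector over M = 0..total_nodes (see
    :class:`nodalstage.priors.NodalPrior`)."""

    probs: np.ndarray
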