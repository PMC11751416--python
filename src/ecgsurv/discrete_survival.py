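"""Discrete-time survival primitives: the 12-bin time grid, PMF/CIF algebra,
and the censoring-aware training loss.

The model discretises one year of follow-up into 12 monthly bins, where bin
``k`` covers the half-open interval ``(k, k+1]`` months. A network head emits
a probability mass function (PMF) over the bins; its cumulative sum is the
cumulative incidence function (CIF) ``F_k = P(event by end of bin k)``.

The loss follows the DeepHit single-event formulation: the negative
log-likelihood of the joint (time, event) distribution plus a pairwise
ranking penalty with a convex exponential kernel. A subject censored in bin
``c`` contributes the survivor mass ``sum_{k >= c} p_k`` — the censoring bin
itself is included, because the subject may still fail within it. With a
12-way softmax this convention also keeps censoring in the final bin
well-posed (the administratively censored majority would otherwise hit
``-log 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn.autograd import Tensor

__all__ = [
    "N_BINS", "HORIZON_MONTHS", "DAYS_PER_MONTH", "EPS",
    "TimeGrid", "SurvivalLabel", "LossConfig",
    "assign_bin", "validate_pmf", "pmf_to_cif", "cif_to_survival",
    "likelihood_loss", "ranking_loss", "total_loss",
    "total_loss_from_logits", "softmax_tensor", "labels_to_arrays",
]

N_BINS = 12
HORIZON_MONTHS = 12.0
DAYS_PER_MONTH = 30.44   # conversion for day-granularity follow-up labels
EPS = 1e-8               # log guard
_PMF_TOL = 1e-6


@dataclass(frozen=True)
class TimeGrid:
    """Monthly discretisation of one year: bin k covers (k, k+1] months."""

    n_bins: int = N_BINS
    horizon: float = HORIZON_MONTHS

    def __post_init__(self):
        if self.n_bins != N_BINS or self.horizon != HORIZON_MONTHS:
            raise ValueError("the model is defined on 12 monthly bins over "
                             "a 12-month horizon")

    @property
    def edges(self) -> np.ndarray:
        """Right bin edges in months: 1, 2, ..., 12."""
        return np.arange(1, self.n_bins + 1, dtype=float)


def assign_bin(time_months: float, grid: TimeGrid | None = None) -> int:
    """Map a positive follow-up time to its monthly bin.

    Bin ``k`` covers ``(k, k+1]`` months, so this is ``ceil(t) - 1`` clamped
    to the grid. Times beyond the horizon must already be administratively
    censored at 12 months by the caller.
    """
    grid = grid or TimeGrid()
    if not time_months > 0:
        raise ValueError(f"follow-up time must be positive, got {time_months}")
    return min(max(math.ceil(time_months) - 1, 0), grid.n_bins - 1)


@dataclass(frozen=True)
class SurvivalLabel:
    """Observed follow-up for one record: time, event indicator, derived bin."""

    record_id: str
    time_months: float
    event: int
    cause: str | None = None
    bin: int = field(init=False)

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        t = float(self.time_months)
        if not t > 0:
            raise ValueError(f"follow-up time must be positive, got {t}")
        if t > HORIZON_MONTHS + 1e-9:
            raise ValueError("times beyond 12 months must be administratively "
                             "censored at the horizon before labelling")
        object.__setattr__(self, "bin", assign_bin(t))


@dataclass(frozen=True)
class LossConfig:
    """Weights of the two loss terms.

    ``alpha`` scales the ranking term against the likelihood term and
    ``sigma`` sets the exponential kernel's scale. Defaults follow the
    DeepHit reference ballpark; both are exposed in every training config.
    """

    alpha: float = 0.1
    sigma: float = 0.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# PMF / CIF algebra
# ---------------------------------------------------------------------------

def validate_pmf(pmf: np.ndarray) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.shape[-1] != N_BINS:
        raise ValueError(f"PMF must have {N_BINS} bins, got shape {pmf.shape}")
    if np.any(pmf < -_PMF_TOL):
        raise ValueError("PMF has negative mass")
    if np.any(np.abs(pmf.sum(axis=-1) - 1.0) > _PMF_TOL):
        raise ValueError("PMF does not sum to 1 within tolerance")
    return pmf


def pmf_to_cif(pmf: np.ndarray) -> np.ndarray:
    """Cumulative incidence ``F_k = sum_{j<=k} p_j`` (same leading shape)."""
    return np.cumsum(validate_pmf(pmf), axis=-1)


def cif_to_survival(cif: np.ndarray) -> np.ndarray:
    """Survival view ``S_k = 1 - F_k``."""
    return 1.0 - np.asarray(cif, dtype=float)


# ---------------------------------------------------------------------------
# Closed-form (NumPy) loss terms
# ---------------------------------------------------------------------------

def likelihood_loss(pmf: np.ndarray, label: SurvivalLabel) -> float:
    """Negative log-likelihood of one subject under its predicted PMF.

    Event in bin k: ``-log(p_k)``. Censored in bin c: ``-log(sum_{k>=c} p_k)``
    (censoring bin included). A small guard keeps the log finite.
    """
    pmf = validate_pmf(pmf)
    if pmf.ndim != 1:
        raise ValueError("likelihood_loss takes a single PMF")
    if label.event == 1:
        return float(-np.log(pmf[label.bin] + EPS))
    return float(-np.log(pmf[label.bin:].sum() + EPS))


def ranking_loss(cifs: Sequence[np.ndarray], labels: Sequence[SurvivalLabel],
                 sigma: float = 0.1) -> float:
    """Mean exponential ranking penalty over acceptable pairs.

    A pair (i, j) is acceptable when i has an event in bin ``k_i`` and j's
    observed bin is strictly later. The penalty is
    ``exp(-(F_i(k_i) - F_j(k_i)) / sigma)`` — small when the earlier-failing
    subject is assigned the larger cumulative incidence at its event bin.
    Returns 0 when no pair is acceptable.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    F = np.stack([np.asarray(c, dtype=float) for c in cifs])
    n = len(labels)
    if F.shape[0] != n:
        raise ValueError("cifs and labels length mismatch")
    total, count = 0.0, 0
    for i in range(n):
        if labels[i].event != 1:
            continue
        k = labels[i].bin
        for j in range(n):
            if j == i or labels[j].bin <= k:
                continue
            total += math.exp(-(F[i, k] - F[j, k]) / sigma)
            count += 1
    return total / count if count else 0.0


def total_loss(pmfs: Sequence[np.ndarray], labels: Sequence[SurvivalLabel],
               cfg: LossConfig = LossConfig()) -> float:
    """Mean likelihood loss plus ``alpha`` times the ranking loss."""
    if len(labels) == 0:
        raise ValueError("empty batch")
    lik = float(np.mean([likelihood_loss(p, l) for p, l in zip(pmfs, labels)]))
    if cfg.alpha == 0.0:
        return lik
    cifs = [pmf_to_cif(np.asarray(p)) for p in pmfs]
    return lik + cfg.alpha * ranking_loss(cifs, labels, cfg.sigma)


# ---------------------------------------------------------------------------
# Differentiable (autograd) path used by the training harness
# ---------------------------------------------------------------------------

def labels_to_arrays(labels: Sequence[SurvivalLabel]) -> tuple[np.ndarray, np.ndarray]:
    """(bins, events) integer arrays for a batch of labels."""
    bins = np.array([l.bin for l in labels], dtype=np.int64)
    events = np.array([l.event for l in labels], dtype=np.int64)
    return bins, events


def softmax_tensor(logits: Tensor) -> Tensor:
    """Row-wise softmax via autograd ops (shift by a detached row max)."""
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def total_loss_from_logits(logits: Tensor, bins: np.ndarray,
                           events: np.ndarray,
                           cfg: LossConfig = LossConfig()) -> Tensor:
    """Batched differentiable total loss from raw head logits.

    Mirrors :func:`total_loss` exactly (a unit test pins the equivalence) but
    is expressed in autograd ops so the encoder can be trained through it.
    """
    n = logits.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    p = softmax_tensor(logits)                       # (N, 12)

    # survivor mass including the censoring bin: p @ U, U[k, c] = 1{k >= c}
    upper = np.tril(np.ones((N_BINS, N_BINS)))       # lower-tri: k >= c
    surv_incl = p @ upper.astype(p.data.dtype)       # (N, 12), col c = sum_{k>=c} p_k
    rows = np.arange(n)
    event_mass = p[rows, bins]                       # (N,)
    censor_mass = surv_incl[rows, bins]
    mass = Tensor(events.astype(p.data.dtype)) * event_mass \
        + Tensor((1 - events).astype(p.data.dtype)) * censor_mass
    lik = -((mass + EPS).log()).mean()

    if cfg.alpha == 0.0:
        return lik

    ev_idx = np.flatnonzero(events == 1)
    if ev_idx.size == 0:
        return lik
    F = p.cumsum(axis=-1)                            # (N, 12)
    kE = bins[ev_idx]
    A = F[:, kE]                                     # (N, E): A[j, e] = F_j(k_e)
    g = A[ev_idx, np.arange(ev_idx.size)]            # (E,): F_i(k_i)
    accept = (bins[None, :] > kE[:, None])           # (E, N)
    n_pairs = int(accept.sum())
    if n_pairs == 0:
        return lik
    diff = g.reshape(-1, 1) - A.transpose(1, 0)      # (E, N)
    kernel = ((-1.0 / cfg.sigma) * diff).exp()
    rank = (kernel * accept.astype(p.data.dtype)).sum() * (1.0 / n_pairs)
    return lik + cfg.alpha * rank
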