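"""Censored-data evaluation: time-dependent concordance, percentile
bootstrap, Kaplan-Meier product-limit curves, log-rank test, AUROC, and the
calibration comparison between mean predicted survival and the KM estimate.

The concordance estimator is the time-dependent form: a pair (i, j) is
comparable when i has an event in bin ``k_i`` and j is observed strictly
later (or censored in the same bin); the pair is concordant when the
predicted cumulative incidence of i at its own event bin exceeds that of j
at the same bin. Ties in predicted risk earn half credit; pairs of events in
the same bin are not comparable (standard Harrell/Antolini conventions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.metrics import roc_auc_score

from .discrete_survival import N_BINS, SurvivalLabel, labels_to_arrays

__all__ = [
    "KMCurve", "MetricResult",
    "time_dependent_cindex", "bootstrap_ci", "km_curve", "log_rank_test",
    "auroc", "calibration_gap",
]


class NoComparablePairsError(ValueError):
    """Raised when a censoring pattern admits no comparable pair."""


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _cindex_arrays(F: np.ndarray, bins: np.ndarray,
                   events: np.ndarray) -> float:
    n = F.shape[0]
    ev_idx = np.flatnonzero(events == 1)
    if ev_idx.size == 0:
        raise NoComparablePairsError("no events, hence no comparable pairs")
    kE = bins[ev_idx]
    # comparable: observed bin strictly later, or same bin with j censored
    later = bins[None, :] > kE[:, None]                          # (E, N)
    same_censored = (bins[None, :] == kE[:, None]) & (events[None, :] == 0)
    comparable = later | same_censored
    comparable[np.arange(ev_idx.size), ev_idx] = False
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise NoComparablePairsError("censoring pattern admits no "
                                     "comparable pair")
    Fi = F[ev_idx, kE][:, None]                                  # F_i(k_i)
    Fj = F[:, kE].T                                              # F_j(k_i)
    concordant = (Fi > Fj) & comparable
    tied = (Fi == Fj) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


def time_dependent_cindex(cifs: Sequence[np.ndarray] | np.ndarray,
                          labels: Sequence[SurvivalLabel]) -> float:
    """Fraction of comparable pairs ordered correctly by predicted
    cumulative incidence, evaluated at the earlier subject's event bin.

    ``cifs`` is an (n, 12) array (or sequence of 12-vectors) of per-subject
    cumulative incidence curves; any time-constant risk score can be passed
    as a constant row since only the ordering at each event bin matters.
    """
    F = np.asarray([np.asarray(c, dtype=float) for c in cifs])
    if F.ndim != 2 or F.shape[1] != N_BINS:
        raise ValueError(f"expected (n, {N_BINS}) CIF array, got {F.shape}")
    if F.shape[0] != len(labels):
        raise ValueError("cifs and labels length mismatch")
    if len(labels) < 2:
        raise ValueError("need at least two subjects")
    bins, events = labels_to_arrays(labels)
    return _cindex_arrays(F, bins, events)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricResult:
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    level: float = 0.95


def bootstrap_ci(metric_fn: Callable[[np.ndarray], float],
                 index_universe: int | Sequence[str],
                 n_boot: int = 200, level: float = 0.95,
                 seed: int = 0) -> MetricResult:
    """Percentile bootstrap of a metric over subject-level resamples.

    ``metric_fn`` receives an integer index array selecting subjects (with
    replacement) and returns the metric on that resample. When
    ``index_universe`` is a sequence of patient ids, resampling is done at
    the patient level (all records of a drawn patient enter together);
    otherwise it is the number of subjects.

    Raises if the metric is undefined on more than half of the resamples.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(index_universe, (int, np.integer)):
        groups = [np.array([i]) for i in range(int(index_universe))]
    else:
        ids = np.asarray(index_universe)
        groups = [np.flatnonzero(ids == u) for u in np.unique(ids)]
    point = metric_fn(np.concatenate(groups))
    values = []
    failures = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(groups), len(groups))
        idx = np.concatenate([groups[g] for g in pick])
        try:
            values.append(metric_fn(idx))
        except (NoComparablePairsError, ValueError):
            failures += 1
    if failures > n_boot / 2:
        raise RuntimeError(
            f"metric undefined on {failures}/{n_boot} bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return MetricResult(point=float(point), ci_low=float(lo),
                        ci_high=float(hi), n_boot=n_boot, seed=seed,
                        level=level)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with its risk/event tables."""

    event_times: np.ndarray     # sorted distinct observed times (events only)
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # n at risk just before each event time
    n_events: np.ndarray        # events at each event time

    def evaluate(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.event_times.size == 0:
            out = np.ones_like(t)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out if out.ndim else float(out)


def km_curve(labels: Sequence[SurvivalLabel]) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i / n_i)."""
    if len(labels) == 0:
        raise ValueError("need at least one subject")
    times = np.array([l.time_months for l in labels])
    events = np.array([l.event for l in labels])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events == 1])
    n = len(times)
    at_risk, d = [], []
    for t in distinct:
        at_risk.append(int(np.sum(times >= t)))
        d.append(int(np.sum((times == t) & (events == 1))))
    at_risk = np.array(at_risk, dtype=int)
    d = np.array(d, dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if len(distinct) else np.array([])
    return KMCurve(event_times=distinct, survival=surv,
                   at_risk=at_risk, n_events=d)


def log_rank_test(labels_a: Sequence[SurvivalLabel],
                  labels_b: Sequence[SurvivalLabel]) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    if not labels_a or not labels_b:
        raise ValueError("both groups must be nonempty")
    if not any(l.event for l in list(labels_a) + list(labels_b)):
        raise ValueError("log-rank test undefined without events")
    res = _ll_logrank(
        [l.time_months for l in labels_a], [l.time_months for l in labels_b],
        event_observed_A=[l.event for l in labels_a],
        event_observed_B=[l.event for l in labels_b])
    return float(res.test_statistic), float(res.p_value)


def auroc(scores: Sequence[float], binary_labels: Sequence[int]) -> float:
    """Rank-based AUROC with tie correction."""
    y = np.asarray(binary_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def calibration_gap(model_mean_survival: np.ndarray, km: KMCurve) -> float:
    """Mean absolute gap between mean predicted survival and KM at the
    monthly bin edges 1..12."""
    s = np.asarray(model_mean_survival, dtype=float)
    if s.shape != (N_BINS,):
        raise ValueError(f"expected a {N_BINS}-vector of mean survival, "
                         f"got shape {s.shape}")
    edges = np.arange(1, N_BINS + 1, dtype=float)
    km_s = km.evaluate(edges)
    return float(np.mean(np.abs(s - km_s)))
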