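"""Scalar risk estimation and the serial-risk sequence model.

The 12-point PMF is reduced to a scalar by the composite trapezoidal rule
(unit bin spacing), giving a per-examination risk estimate. A patient's
serial examinations become an interleaved sequence
``(e_1, i_1, e_2, i_2, ..., e_n)`` of risk estimates and whole-week
inter-exam intervals, zero-padded at the tail to length 23 (at most 12
estimates and 11 intervals). A temporal convolutional network (TCN) of four
dilated causal residual blocks maps the sequence to the probability of
death within one year after the last examination.

Two per-exam scalars are supported: the trapezoidal PMF-AUC (default) or
the predicted one-year survival probability ``S_11``; the alternative is a
configuration switch, not a separate code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .discrete_survival import validate_pmf
from .nn.autograd import Tensor

__all__ = [
    "SEQ_LEN", "RiskEstimate", "RiskSequence", "TCNConfig", "TCNClassifier",
    "trapezoid_risk", "survival_risk", "build_sequence", "tcn_predict",
    "train_tcn",
]

SEQ_LEN = 23
MAX_EXAMS = 12
DAYS_PER_WEEK = 7.0


def trapezoid_risk(pmf: np.ndarray) -> float:
    """Composite-trapezoid area under the 12-point PMF curve.

    With unit spacing this is ``sum_k (p_k + p_{k+1}) / 2`` over the 11
    consecutive bin pairs — equivalently ``1 - (p_0 + p_11) / 2``, so the
    value is linear in the PMF, equals 11/12 for the uniform PMF, 1 for any
    interior one-hot and 1/2 for a boundary one-hot.
    """
    p = validate_pmf(pmf)
    if p.ndim != 1:
        raise ValueError("trapezoid_risk takes a single PMF")
    return float(np.trapezoid(p))


def survival_risk(pmf: np.ndarray) -> float:
    """Predicted one-year survival probability S_11 = 1 - F_11.

    With a softmax PMF over bins that partition the year this is 0 up to
    normalisation error; it is offered because serial-model inputs may come
    from heads with relaxed normalisation, and as the alternative per-exam
    scalar described in the training protocol.
    """
    p = validate_pmf(pmf)
    return float(1.0 - p.sum())


@dataclass(frozen=True)
class RiskEstimate:
    """One examination's scalar risk with its timestamp."""

    value: float
    record_id: str
    exam_time: np.datetime64

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("risk estimate must be nonnegative")


@dataclass(frozen=True)
class RiskSequence:
    """Length-23 interleaved (estimate, interval-in-weeks) vector."""

    x: np.ndarray
    n_exams: int
    label: int
    patient_id: str = ""

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.shape != (SEQ_LEN,):
            raise ValueError(f"sequence must have length {SEQ_LEN}, "
                             f"got shape {x.shape}")
        if self.n_exams < 2:
            raise ValueError("sequences require at least two examinations")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        object.__setattr__(self, "x", x)


def build_sequence(estimates: Sequence[RiskEstimate], died_within_1yr: int,
                   patient_id: str = "") -> RiskSequence:
    """Interleave serial risk estimates with whole-week intervals.

    Patients with fewer than two examinations are excluded upstream and
    rejected here. Intervals are ``floor(days / 7)`` weeks (zero allowed for
    same-week exams). When more than 12 examinations exist, the 12 most
    recent are kept; the tail is zero-padded to length 23.
    """
    if len(estimates) < 2:
        raise ValueError("patients with fewer than two ECG examinations "
                         "are excluded from the sequence model")
    times = np.array([e.exam_time for e in estimates], dtype="datetime64[s]")
    if np.any(np.diff(times) < np.timedelta64(0, "s")):
        raise ValueError("estimates must be ordered by exam_time")
    estimates = list(estimates)[-MAX_EXAMS:]
    times = times[-MAX_EXAMS:]
    day_gaps = np.diff(times) / np.timedelta64(1, "D")
    weeks = np.floor(day_gaps / DAYS_PER_WEEK)
    x = np.zeros(SEQ_LEN)
    for i, est in enumerate(estimates):
        x[2 * i] = est.value
        if i < len(estimates) - 1:
            x[2 * i + 1] = weeks[i]
    return RiskSequence(x=x, n_exams=len(estimates),
                        label=int(died_within_1yr), patient_id=patient_id)


# ---------------------------------------------------------------------------
# TCN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TCNConfig:
    n_blocks: int = 4
    kernel: int = 3
    channels: int = 16
    dropout: float = 0.1
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.receptive_field < SEQ_LEN:
            raise ValueError(
                f"receptive field {self.receptive_field} < {SEQ_LEN}; "
                "increase n_blocks or kernel")

    @property
    def dilations(self) -> tuple[int, ...]:
        """Block L uses dilation 2^(L-1)."""
        return tuple(2 ** l for l in range(self.n_blocks))

    @property
    def receptive_field(self) -> int:
        # two convs per block, each widening by (kernel-1) * dilation
        return 1 + 2 * (self.kernel - 1) * sum(self.dilations)


class _TemporalBlock(nn.Module):
    """Two dilated causal convolutions with ReLU + dropout and a residual
    connection (1x1 projection when the channel count changes)."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int,
                 dropout: float, rng: np.random.Generator,
                 drop_rng: np.random.Generator):
        super().__init__()
        pad = ((kernel - 1) * dilation, 0)        # left-only: causal
        self.conv1 = nn.Conv1d(cin, cout, kernel, rng, padding=pad,
                               dilation=dilation)
        self.drop1 = nn.Dropout(dropout, drop_rng)
        self.conv2 = nn.Conv1d(cout, cout, kernel, rng, padding=pad,
                               dilation=dilation)
        self.drop2 = nn.Dropout(dropout, drop_rng)
        self.project = cin != cout
        if self.project:
            self.proj = nn.Conv1d(cin, cout, 1, rng, bias=False)

    def forward(self, x):
        h = self.drop1(self.conv1(x).relu())
        h = self.drop2(self.conv2(h).relu())
        skip = self.proj(x) if self.project else x
        return (h + skip).relu()


class TCNClassifier(nn.Module):
    """Four-block dilated causal TCN with a single fully connected output.

    The output layer reads the feature vector at the final sequence
    position, which — by causality — aggregates the entire padded sequence.
    """

    def __init__(self, config: TCNConfig = TCNConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
        drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 59]))
        blocks = []
        cin = config.in_channels
        for dilation in config.dilations:
            blocks.append(_TemporalBlock(cin, config.channels, config.kernel,
                                         dilation, config.dropout, rng,
                                         drop_rng))
            cin = config.channels
        self.blocks = nn.Sequential(*blocks)
        self.head = nn.Linear(config.channels, 1, rng)

    def features(self, x: Tensor) -> Tensor:
        """(N, C, 23) feature maps before the output layer."""
        return self.blocks(x)

    def forward(self, x: Tensor) -> Tensor:
        h = self.features(x)
        last = h[:, :, h.shape[-1] - 1]
        return self.head(last).sigmoid()


def _sequences_to_array(sequences: Sequence[RiskSequence] | np.ndarray
                        ) -> np.ndarray:
    if isinstance(sequences, np.ndarray):
        x = np.asarray(sequences, dtype=np.float32)
        if x.ndim == 1:
            x = x[None]
        return x[:, None, :] if x.ndim == 2 else x
    return np.stack([s.x for s in sequences]).astype(np.float32)[:, None, :]


def tcn_predict(model: TCNClassifier,
                seq: RiskSequence | Sequence[RiskSequence] | np.ndarray
                ) -> np.ndarray | float:
    """Probability of death within one year after the last examination."""
    single = isinstance(seq, RiskSequence) or (
        isinstance(seq, np.ndarray) and seq.ndim == 1)
    x = _sequences_to_array([seq] if isinstance(seq, RiskSequence) else seq)
    if x.shape[-1] != SEQ_LEN:
        raise ValueError(f"sequence length must be {SEQ_LEN}, "
                         f"got {x.shape[-1]}")
    was_training = model.training
    model.eval()
    out = model(Tensor(x)).data.ravel()
    model.train(was_training)
    return float(out[0]) if single else out.astype(np.float64)


def train_tcn(sequences: Sequence[RiskSequence],
              cfg: TCNConfig = TCNConfig(), lr: float = 5e-4,
              batch_size: int = 512, epochs: int = 10,
              verbose: bool = False) -> tuple[TCNClassifier, list[float]]:
    """Train the TCN with binary cross-entropy and Adam.

    Returns the trained model and the per-epoch mean loss trajectory.
    Refuses single-class data.
    """
    x = _sequences_to_array(sequences)
    y = np.array([s.label for s in sequences], dtype=np.float32)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = TCNClassifier(cfg)
    model.train()
    opt = nn.Adam(model.parameters(), lr=lr)
    order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 61]))
    n = x.shape[0]
    history = []
    eps = 1e-7
    for epoch in range(epochs):
        idx = order_rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            sel = idx[lo:lo + batch_size]
            prob = model(Tensor(x[sel]))
            prob = prob.reshape(len(sel))
            yb = Tensor(y[sel])
            loss = -(yb * (prob + eps).log()
                     + (1.0 - yb) * (1.0 - prob + eps).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}  bce {history[-1]:.4f}")
    model.eval()
    return model, history
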