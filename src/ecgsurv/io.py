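"""Readers and writers for waveform containers, label/sequence tables,
model archives, and run configuration.

The canonical waveform container is a single HDF5 file with one dataset per
record (named by ``record_id``) carrying patient id, acquisition timestamp,
sampling rate and lead names as attributes. Labels and sequences travel as
plain CSV. Every artifact records the seed and a hash of the resolved
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .discrete_survival import HORIZON_MONTHS, LossConfig, SurvivalLabel
from .risk_sequence import SEQ_LEN, RiskSequence, TCNClassifier, TCNConfig
from .synthetic_ecg import (
    LEAD_NAMES, SimConfig, SimulatedCohort, WaveformRecord,
)
from .waveform_net import EncoderConfig, TrainConfig

__all__ = [
    "WaveformIOError", "config_hash",
    "write_cohort", "read_waveforms", "read_labels", "write_labels",
    "read_sequences", "write_sequences", "save_tcn", "load_tcn",
    "RunConfig", "load_run_config",
]

WAVEFORM_FILE = "waveforms.h5"
LABEL_FILE = "labels.csv"


class WaveformIOError(OSError):
    """A malformed waveform container entry, naming the offending record."""


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a resolved configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# waveforms + labels
# ---------------------------------------------------------------------------

def write_waveforms(path: Path | str, records: Sequence[WaveformRecord],
                    seed: int | None = None,
                    cfg_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = float(records[0].sampling_rate)
        f.attrs["lead_names"] = list(LEAD_NAMES)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        f.attrs["config_hash"] = cfg_hash
        for rec in records:
            ds = f.create_dataset(rec.record_id, data=rec.signal)
            ds.attrs["patient_id"] = rec.patient_id
            ds.attrs["acquired_at"] = str(rec.acquired_at)


def read_waveforms(path: Path | str) -> list[WaveformRecord]:
    """Load and validate all records of an HDF5 waveform container."""
    path = Path(path)
    if path.is_dir():
        path = path / WAVEFORM_FILE
    if not path.exists():
        raise WaveformIOError(f"waveform container not found: {path}")
    records = []
    with h5py.File(path, "r") as f:
        fs = float(f.attrs.get("sampling_rate", 500.0))
        for rid in sorted(f.keys()):
            ds = f[rid]
            sig = np.asarray(ds)
            if sig.ndim != 2 or sig.shape[0] != len(LEAD_NAMES):
                raise WaveformIOError(
                    f"record {rid!r}: expected {len(LEAD_NAMES)} leads, "
                    f"got shape {sig.shape}")
            records.append(WaveformRecord(
                record_id=rid,
                patient_id=str(ds.attrs.get("patient_id", rid)),
                acquired_at=np.datetime64(
                    str(ds.attrs.get("acquired_at", "2000-01-01T00:00"))),
                signal=sig.astype(np.float32),
                sampling_rate=fs))
    return records


def write_labels(path: Path | str, labels: Sequence[SurvivalLabel],
                 patient_ids: Sequence[str] | None = None,
                 latent_risk: np.ndarray | None = None) -> None:
    df = pd.DataFrame({
        "record_id": [l.record_id for l in labels],
        "patient_id": (list(patient_ids) if patient_ids is not None
                       else [l.record_id for l in labels]),
        "time_months": [l.time_months for l in labels],
        "event": [l.event for l in labels],
    })
    if latent_risk is not None:
        df["z"] = np.asarray(latent_risk, dtype=float)
    df.to_csv(path, index=False)


def read_labels(path: Path | str) -> pd.DataFrame:
    """Labels table; times beyond the horizon are rejected, not clipped."""
    df = pd.read_csv(path)
    required = {"record_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labels table missing columns: {sorted(missing)}")
    if (df["time_months"] > HORIZON_MONTHS).any():
        raise ValueError("labels contain times beyond the 12-month horizon; "
                         "administratively censor them first")
    return df


def labels_from_frame(df: pd.DataFrame) -> list[SurvivalLabel]:
    return [SurvivalLabel(record_id=str(r.record_id),
                          time_months=float(r.time_months),
                          event=int(r.event))
            for r in df.itertuples()]


def write_cohort(directory: Path | str, cohort: SimulatedCohort) -> Path:
    """Write a simulated cohort as waveforms.h5 + labels.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(cohort.config)
    write_waveforms(directory / WAVEFORM_FILE, cohort.records,
                    seed=cohort.config.seed, cfg_hash=config_hash(cfg))
    write_labels(directory / LABEL_FILE, cohort.labels,
                 patient_ids=cohort.patient_ids,
                 latent_risk=cohort.latent_risk)
    return directory


def read_cohort(directory: Path | str
                ) -> tuple[list[WaveformRecord], list[SurvivalLabel], pd.DataFrame]:
    directory = Path(directory)
    records = read_waveforms(directory / WAVEFORM_FILE)
    df = read_labels(directory / LABEL_FILE)
    by_id = df.set_index("record_id")
    labels = []
    for rec in records:
        if rec.record_id not in by_id.index:
            raise WaveformIOError(f"record {rec.record_id!r} has no label")
        row = by_id.loc[rec.record_id]
        labels.append(SurvivalLabel(record_id=rec.record_id,
                                    time_months=float(row.time_months),
                                    event=int(row.event)))
    return records, labels, df


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def write_sequences(path: Path | str,
                    sequences: Sequence[RiskSequence]) -> None:
    rows = []
    for s in sequences:
        row = {"patient_id": s.patient_id, "n_exams": s.n_exams,
               "label": s.label}
        row.update({f"x{i + 1}": s.x[i] for i in range(SEQ_LEN)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sequences(path: Path | str) -> list[RiskSequence]:
    df = pd.read_csv(path)
    cols = [f"x{i + 1}" for i in range(SEQ_LEN)]
    missing = set(cols + ["n_exams", "label"]) - set(df.columns)
    if missing:
        raise ValueError(f"sequence table missing columns: {sorted(missing)}")
    return [RiskSequence(x=row[cols].to_numpy(dtype=float),
                         n_exams=int(row["n_exams"]), label=int(row["label"]),
                         patient_id=str(row.get("patient_id", "")))
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# TCN archive
# ---------------------------------------------------------------------------

def save_tcn(path: Path | str, model: TCNClassifier,
             history: Sequence[float] = ()) -> None:
    meta = {"config": dataclasses.asdict(model.config),
            "history": list(history)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(),
                                          dtype=np.uint8),
             **model.state_dict())


def load_tcn(path: Path | str) -> TCNClassifier:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = TCNClassifier(TCNConfig(**meta["config"]))
    model.load_state_dict(state)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "simulation": SimConfig,
    "encoder": EncoderConfig,
    "train": TrainConfig,
    "loss": LossConfig,
    "tcn": TCNConfig,
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a pipeline run, one section per module."""

    simulation: SimConfig = dataclasses.field(default_factory=SimConfig)
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    tcn: TCNConfig = dataclasses.field(default_factory=TCNConfig)
    n_boot: int = 200

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.as_dict())


def _build_section(cls, mapping: Mapping[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path: Path | str | None = None,
                    overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys.

    The YAML document has optional sections ``simulation``, ``encoder``,
    ``train`` (with a nested ``loss``), ``tcn``, and a top-level ``n_boot``.
    ``overrides`` is a nested mapping merged over the file contents.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    for key, value in (overrides or {}).items():
        if isinstance(value, Mapping):
            raw.setdefault(key, {})
            raw[key] = {**raw[key], **value}
        else:
            raw[key] = value
    unknown = set(raw) - {"simulation", "encoder", "train", "tcn", "n_boot"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    train_raw = dict(raw.get("train", {}))
    loss_raw = train_raw.pop("loss", {})
    kwargs: dict[str, Any] = {}
    kwargs["simulation"] = _build_section(SimConfig,
                                          raw.get("simulation", {}),
                                          "simulation")
    kwargs["encoder"] = _build_section(EncoderConfig, raw.get("encoder", {}),
                                       "encoder")
    loss = _build_section(LossConfig, loss_raw, "train.loss")
    train_raw["loss"] = loss
    kwargs["train"] = _build_section(TrainConfig, train_raw, "train")
    kwargs["tcn"] = _build_section(TCNConfig, raw.get("tcn", {}), "tcn")
    kwargs["n_boot"] = int(raw.get("n_boot", 200))
    return RunConfig(**kwargs)
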