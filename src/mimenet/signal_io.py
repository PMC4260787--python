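"""Reading, standardizing, windowing and stacking multichannel recordings."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultichannelRecording",
    "WindowSpec",
    "load_recording",
    "standardize",
    "segment_windows",
    "build_augmented",
]

#: minimum samples per analysis window (estimator floor)
MIN_WINDOW_SAMPLES = 100


@dataclasses.dataclass
class MultichannelRecording:
    """Synchronized channels × samples recording.

    data is stored channels-first: shape (n_channels, n_samples).
    ``block_boundaries`` maps a subject id to its half-open channel range
    for augmented (stacked multi-subject) recordings.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "S1"
    standardized: bool = False
    block_boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        k, n = self.data.shape
        if k < 2:
            raise ValueError("need at least 2 channels")
        if n < 2 * k:
            raise ValueError(f"need n_samples >= 2*n_channels, got {n} < {2 * k}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != k:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {k} channels"
            )
        if len(set(self.channel_labels)) != k:
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def copy(self, **changes) -> "MultichannelRecording":
        base = dict(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            subject_id=self.subject_id,
            standardized=self.standardized,
            block_boundaries=dict(self.block_boundaries)
            if self.block_boundaries else None,
        )
        base.update(changes)
        return MultichannelRecording(**base)


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """One analysis window. Indexing is 1-based; with 1-based sample times
    window i of length L seconds at rate fs covers ((i-1)*L + 1/fs, i*L]."""

    length_s: float
    index: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("window index is 1-based")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_recording(path: str | Path, format: str = "csv",
                   fs: float | None = None,
                   labels: list[str] | None = None,
                   subject_id: str | None = None) -> MultichannelRecording:
    """Load an unstandardized recording from a CSV/TSV matrix or an EDF file.

    CSV layout: one row per sample, one column per channel, with a header
    row of channel labels (an explicit ``labels`` list overrides the
    header). ``fs`` is mandatory for CSV; for EDF both the rate and the
    labels come from the header. EDF support requires the optional
    ``pyedflib`` dependency.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subject_id = subject_id or path.stem

    if format == "csv":
        if fs is None:
            raise ValueError("fs must be supplied for csv input")
        if fs <= 0:
            raise ValueError(f"fs must be positive, got {fs}")
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        try:
            data = df.to_numpy(dtype=np.float64).T
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
        if labels is None:
            labels = [str(c) for c in df.columns]
        if len(labels) != data.shape[0]:
            raise ValueError(
                f"{len(labels)} labels supplied for {data.shape[0]} columns"
            )
        return MultichannelRecording(data, fs, labels, subject_id)

    if format == "edf":
        try:
            import pyedflib
        except ImportError as exc:  # pragma: no cover - optional dep
            raise ImportError(
                "EDF input requires the optional dependency pyedflib "
                "(pip install mimenet[edf]); CSV input needs no extras"
            ) from exc
        with pyedflib.EdfReader(str(path)) as f:  # pragma: no cover
            edf_labels = f.getSignalLabels()
            rates = {f.getSampleFrequency(i) for i in range(f.signals_in_file)}
            if len(rates) != 1:
                raise ValueError("mixed per-signal sampling rates in EDF")
            data = np.vstack([f.readSignal(i) for i in range(f.signals_in_file)])
        return MultichannelRecording(data, rates.pop(), edf_labels, subject_id)

    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'edf')")


def standardize(rec: MultichannelRecording,
                scope: str = "global") -> MultichannelRecording:
    """Z-score every channel over its full span.

    ``scope`` is metadata here: per-window standardization is obtained by
    calling this on each window segment (see :func:`segment_windows`), and
    the argument exists so pipelines can record which convention they used.
    Raises on zero-variance channels, naming the offender.
    """
    if scope not in {"per_window", "global"}:
        raise ValueError(f"unknown scope {scope!r}")
    mean = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        bad = ", ".join(rec.channel_labels[i] for i in flat)
        raise ValueError(f"zero-variance channel(s): {bad}")
    return rec.copy(data=(rec.data - mean) / sd, standardized=True)


def segment_windows(rec: MultichannelRecording, length_s: float,
                    standardize_scope: str | None = None,
                    ) -> list[tuple[WindowSpec, MultichannelRecording]]:
    """Cut a recording into consecutive non-overlapping windows.

    The trailing partial window is discarded. Window indices are 1-based.
    If ``standardize_scope`` is ``"per_window"`` each window is z-scored
    independently after cutting.
    """
    win = int(round(length_s * rec.fs))
    if win < MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"window of {length_s} s at {rec.fs} Hz has {win} samples; "
            f"need at least {MIN_WINDOW_SAMPLES}"
        )
    n_windows = rec.n_samples // win
    if n_windows < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s shorter than one "
            f"{length_s} s window"
        )
    out = []
    for i in range(n_windows):
        seg = rec.copy(data=rec.data[:, i * win:(i + 1) * win].copy())
        if standardize_scope == "per_window":
            seg = standardize(seg, scope="per_window")
        spec = WindowSpec(
            length_s=length_s,
            index=i + 1,
            start_s=(i * win + 1) / rec.fs,
            end_s=(i + 1) * win / rec.fs,
        )
        out.append((spec, seg))
    return out


def build_augmented(recA: MultichannelRecording,
                    recB: MultichannelRecording) -> MultichannelRecording:
    """Stack two synchronized recordings into one augmented recording.

    Labels are prefixed with the subject id, and block boundaries record
    each subject's channel range so downstream code can split intra- from
    cross-subject blocks.
    """
    if recA.fs != recB.fs:
        raise ValueError(f"sampling rates differ: {recA.fs} vs {recB.fs}")
    if abs(recA.n_samples - recB.n_samples) > 1:
        raise ValueError(
            f"lengths differ beyond one sample: {recA.n_samples} vs "
            f"{recB.n_samples}"
        )
    if recA.subject_id == recB.subject_id:
        raise ValueError("augmented recordings need distinct subject ids")
    n = min(recA.n_samples, recB.n_samples)
    data = np.vstack((recA.data[:, :n], recB.data[:, :n]))
    labels = ([f"{recA.subject_id}:{c}" for c in recA.channel_labels]
              + [f"{recB.subject_id}:{c}" for c in recB.channel_labels])
    kA = recA.n_channels
    return MultichannelRecording(
        data=data,
        fs=recA.fs,
        channel_labels=labels,
        subject_id=f"{recA.subject_id}+{recB.subject_id}",
        standardized=recA.standardized and recB.standardized,
        block_boundaries={
            recA.subject_id: (0, kA),
            recB.subject_id: (kA, kA + recB.n_channels),
        },
    )
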