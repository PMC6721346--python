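"""Recording containers, delimited-text I/O, band-pass preprocessing, epoching.

Conventions
-----------
* In files, rows are time samples and columns are channels; the delimiter
  (comma or tab) is auto-detected on load.
* In memory, ``EEGRecording.samples`` has shape ``(n_channels, n_samples)``
  and sample indices are 0-based.
* Sampling rate and channel labels live in a flat key--value sidecar config
  (YAML), not in the numeric files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import signal as sps

#: Pass band of the sensorimotor-rhythm preprocessing filter (Hz).  The mu
#: (~7-13 Hz) and beta (~13-30 Hz) rhythms that index motor imagery both lie
#: inside 8-32 Hz; most content below 5 Hz is artifact.
DEFAULT_BAND = (8.0, 32.0)

#: Default trial length in samples (8 s at 250 Hz).
DEFAULT_TRIAL_LENGTH = 2000

#: Default sampling rate (Hz).
DEFAULT_FS = 250.0


@dataclass
class EEGRecording:
    """A sampled multichannel EEG segment.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel time series in microvolts (arbitrary units accepted).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered channel names, e.g. ``["C3", "C4"]``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one channel and one sample")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D series of a channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channel_labels}"
            ) from None
        return self.samples[idx]


@dataclass
class TrialSet:
    """Equal-length labelled trials from one or more recordings."""

    trials: list[EEGRecording]
    labels: list[str]
    trial_length: int = DEFAULT_TRIAL_LENGTH

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.trials):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.trials)} trials"
            )
        lengths = {t.n_samples for t in self.trials}
        if len(lengths) > 1:
            raise ValueError(f"trials have unequal lengths: {sorted(lengths)}")
        if self.trials:
            self.trial_length = self.trials[0].n_samples
            rates = {t.fs for t in self.trials}
            if len(rates) > 1:
                raise ValueError(f"trials have unequal sampling rates: {sorted(rates)}")

    def __len__(self) -> int:
        return len(self.trials)


def _detect_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def load_recording(
    path: str | os.PathLike,
    fs: float,
    channel_labels: Sequence[str],
) -> EEGRecording:
    """Load a delimited-text numeric matrix (rows = samples, cols = channels).

    The delimiter (comma, tab or whitespace) is auto-detected from the first
    non-empty line.  Column order maps onto ``channel_labels``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"recording file not found: {path}")
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if not first:
        raise ValueError(f"no samples in {path}")
    delim = _detect_delimiter(first)
    try:
        data = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    if data.shape[1] != len(channel_labels):
        raise ValueError(
            f"{path}: {data.shape[1]} columns but {len(channel_labels)} "
            f"channel labels {list(channel_labels)}"
        )
    return EEGRecording(data.T, fs=fs, channel_labels=list(channel_labels))


def save_recording(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as comma-separated text, full ``repr`` precision."""
    np.savetxt(os.fspath(path), rec.samples.T, delimiter=",", fmt="%.17g")


def save_trialset(
    trials: TrialSet, out_dir: str | os.PathLike, fs: float | None = None
) -> None:
    """Write one CSV per trial plus a ``labels.csv`` and sidecar ``config.yaml``."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for i, rec in enumerate(trials.trials):
        save_recording(rec, os.path.join(out_dir, f"trial_{i:04d}.csv"))
    with open(os.path.join(out_dir, "labels.csv"), "w") as fh:
        for i, lab in enumerate(trials.labels):
            fh.write(f"trial_{i:04d}.csv,{lab}\n")
    rec0 = trials.trials[0]
    cfg = {
        "fs": float(fs if fs is not None else rec0.fs),
        "trial_length": int(trials.trial_length),
        "channel_labels": list(rec0.channel_labels),
    }
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)


def load_trialset(in_dir: str | os.PathLike) -> TrialSet:
    """Load a trial directory written by :func:`save_trialset`."""
    in_dir = os.fspath(in_dir)
    cfg_path = os.path.join(in_dir, "config.yaml")
    labels_path = os.path.join(in_dir, "labels.csv")
    if not os.path.exists(labels_path):
        raise FileNotFoundError(f"no trials found: missing {labels_path}")
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    trials, labels = [], []
    with open(labels_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fname, lab = line.strip().split(",")
            rec = load_recording(
                os.path.join(in_dir, fname), cfg["fs"], cfg["channel_labels"]
            )
            trials.append(rec)
            labels.append(lab)
    if not trials:
        raise ValueError(f"no trials found in {in_dir}")
    return TrialSet(trials, labels)


def bandpass_filter(
    rec: EEGRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    A forward-backward (``sosfiltfilt``) 4th-order Butterworth is used so the
    filter introduces no phase distortion: downstream empirical mode
    decomposition keys on envelope extrema whose positions a causal filter
    would shift.  Output length equals input length.
    """
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return EEGRecording(filtered, fs=rec.fs, channel_labels=list(rec.channel_labels))


def epoch_trials(
    rec: EEGRecording,
    onsets: Sequence[int],
    labels: Sequence[str],
    length: int = DEFAULT_TRIAL_LENGTH,
) -> TrialSet:
    """Cut a continuous recording into fixed-length trials at given onsets."""
    if len(labels) != len(onsets):
        raise ValueError(f"{len(labels)} labels for {len(onsets)} onsets")
    trials = []
    for k, onset in enumerate(onsets):
        if onset < 0 or onset + length > rec.n_samples:
            raise ValueError(
                f"trial {k}: onset {onset} + length {length} exceeds "
                f"recording length {rec.n_samples}"
            )
        trials.append(
            EEGRecording(
                rec.samples[:, onset : onset + length],
                fs=rec.fs,
                channel_labels=list(rec.channel_labels),
            )
        )
    return TrialSet(trials, list(labels), trial_length=length)
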