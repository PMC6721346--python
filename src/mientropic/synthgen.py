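"""Synthetic two-channel motor-imagery EEG with ERD/ERS structure.

Real sensorimotor recordings show mu (~7-13 Hz) and beta (~13-30 Hz)
rhythms over the hand areas (electrodes C3, left hemisphere; C4, right)
whose amplitude is modulated while a subject imagines moving one hand:
event-related desynchronization (ERD) is a drop of rhythm amplitude,
event-related synchronization (ERS) an increase, and the modulation is
lateralized, which is what makes left vs right imagery classifiable.

Each generated trial is, per channel,

    mu tone + beta tone + 1/f background noise + slow (< 5 Hz) drift,

with tone phases randomized per trial and channel.  During the imagery
window the suppressed channel's mu and beta amplitudes are scaled by
``1 - erd_depth`` with short raised-cosine ramps at the window edges.  Which
channel is suppressed is a convention flag:

* ``laterality="paper"`` (default): left-hand imagery suppresses C3, so C4
  appears the more active electrode during left imagery (and conversely);
* ``laterality="classic"``: left-hand imagery suppresses C4, the textbook
  contralateral-ERD account.

The two conventions are mirror images; the classifier cannot tell them
apart, but the flag fixes which physical channel carries which class.

Timing defaults mimic an 8 s cued-imagery protocol sampled at 250 Hz:
2000-sample trials with the imagery period spanning seconds 4-7, i.e.
samples 1000-1750.

All randomness flows from one seed: per-trial generators are spawned by
counter from a single ``SeedSequence``, so datasets are reproducible and
individual trials do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import EEGRecording, TrialSet

CLASSES = ("left", "right")


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate a strong-contrast session."""

    fs: float = 250.0
    trial_length: int = 2000
    n_trials_per_class: int = 40
    mu_freq: float = 10.0
    beta_freq: float = 22.0
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    erd_depth: float = 0.8
    imagery_window: tuple[int, int] | None = None  # default: seconds 4-7 of 8 s
    noise_amp: float = 0.5
    artifact_amp: float = 0.5
    laterality: str = "paper"
    ramp_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (7 <= self.mu_freq <= 13):
            raise ValueError(f"mu_freq must lie in [7, 13] Hz, got {self.mu_freq}")
        if not (13 < self.beta_freq <= 30):
            raise ValueError(f"beta_freq must lie in (13, 30] Hz, got {self.beta_freq}")
        if not (0 <= self.erd_depth <= 1):
            raise ValueError(f"erd_depth must lie in [0, 1], got {self.erd_depth}")
        if self.imagery_window is None:
            # cue protocol: imagery spans seconds 4-7 of an 8 s trial
            self.imagery_window = (
                int(0.5 * self.trial_length),
                int(0.875 * self.trial_length),
            )
        self.imagery_window = (int(self.imagery_window[0]), int(self.imagery_window[1]))
        lo, hi = self.imagery_window
        if not (0 <= lo < hi <= self.trial_length):
            raise ValueError(
                f"imagery_window {self.imagery_window} must lie inside "
                f"[0, {self.trial_length}]"
            )
        if self.laterality not in ("paper", "classic"):
            raise ValueError(
                f"laterality must be 'paper' or 'classic', got {self.laterality!r}"
            )
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise by spectral shaping of white noise.

    Power is proportional to 1/f for f >= 0.5 Hz and flat below, so the
    divergence at DC is avoided.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shape[0] = 0.0  # no DC offset
    noise = np.fft.irfft(spec * shape, n=n)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _modulation(cfg: SynthConfig) -> np.ndarray:
    """Amplitude profile: 1 outside imagery, 1 - erd_depth inside, cosine ramps."""
    lo, hi = cfg.imagery_window
    mod = np.ones(cfg.trial_length)
    depth = cfg.erd_depth
    mod[lo:hi] = 1.0 - depth
    k = min(cfg.ramp_samples, (hi - lo) // 2)
    if k > 0:
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, k)))  # 1 -> 0
        mod[lo : lo + k] = 1.0 - depth * (1 - ramp)
        mod[hi - k : hi] = 1.0 - depth * ramp
    return mod


def _suppressed_channel(class_label: str, laterality: str) -> str:
    if laterality == "paper":
        return "C3" if class_label == "left" else "C4"
    return "C4" if class_label == "left" else "C3"


def generate_trial(
    class_label: str, cfg: SynthConfig, rng: np.random.Generator
) -> EEGRecording:
    """One 2-channel (C3, C4) trial for the given imagery class."""
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}, got {class_label!r}")
    n = cfg.trial_length
    t = np.arange(n) / cfg.fs
    mod = _modulation(cfg)
    suppressed = _suppressed_channel(class_label, cfg.laterality)
    channels = []
    for name in ("C3", "C4"):
        amp = mod if name == suppressed else np.ones(n)
        mu = cfg.mu_amp * amp * np.sin(
            2 * np.pi * cfg.mu_freq * t + rng.uniform(0, 2 * np.pi)
        )
        beta = cfg.beta_amp * amp * np.sin(
            2 * np.pi * cfg.beta_freq * t + rng.uniform(0, 2 * np.pi)
        )
        noise = cfg.noise_amp * _pink_noise(n, cfg.fs, rng)
        drift_freq = rng.uniform(0.3, 4.5)
        drift = cfg.artifact_amp * np.sin(
            2 * np.pi * drift_freq * t + rng.uniform(0, 2 * np.pi)
        )
        channels.append(mu + beta + noise + drift)
    return EEGRecording(
        np.vstack(channels), fs=cfg.fs, channel_labels=["C3", "C4"]
    )


def generate_dataset(cfg: SynthConfig) -> TrialSet:
    """Balanced, seeded, shuffled set of labelled trials.

    Trial i draws from its own spawned random stream, so any single trial
    can be regenerated independently of the rest.
    """
    n_total = 2 * cfg.n_trials_per_class
    labels = [CLASSES[i % 2] for i in range(n_total)]
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_total + 1)
    trials = [
        generate_trial(lab, cfg, np.random.default_rng(children[i]))
        for i, lab in enumerate(labels)
    ]
    order = np.random.default_rng(children[n_total]).permutation(n_total)
    return TrialSet(
        [trials[i] for i in order],
        [labels[i] for i in order],
        trial_length=cfg.trial_length,
    )
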