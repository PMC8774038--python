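"""Synthetic event-locked EEG with class-dependent planted ERD effects.

Each channel is a sum of an alpha-band and a beta-band oscillation plus
broadband Gaussian noise.  A band oscillation mixes two parts:

* a *stable carrier* -- a random-phase multisine on the 0.5 Hz grid of the
  2 s analysis window (one equal-power sinusoid per DFT bin inside the
  band).  Every component frequency is a multiple of 0.5 Hz, so any 2 s
  window contains a whole number of cycles of each component and carries
  identical carrier band power;
* a *fluctuating part* -- band-pass filtered white noise, whose 2 s band
  power varies from window to window the way real sensorimotor rhythms
  wax and wane.

``oscillation_stability`` is the fraction of band power carried by the
stable part (default 0.95, giving ~13% trial-to-trial band-power
variability).  Scaling the task window of a trial by sqrt(1 + ERD) makes
the expected task/rest band-power ratio 1 + ERD up to a small Jensen bias
from the fluctuating denominator (~1% at the default stability), so the
planted ground truth stays essentially analytic while trials retain
band-power variability.

The generator writes EDF+ files in the PhysioNet dialect (T1/T2 cue
annotations, ``SxxxRyy.edf`` naming) so the reader can be exercised on
generated data.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from mi_erd.data_io import (
    ChannelMap,
    Event,
    InputError,
    Recording,
    make_montage,
)
from mi_erd.features import BANDS


@dataclass(frozen=True)
class PlantedEffect:
    """Class-dependent ERD planted at one channel in one band.

    ``erd_class_a``/``erd_class_b`` are the relative task/rest band-power
    changes for the two classes (must be > -1; negative = desynchronisation).
    """

    channel: str
    band: str = "ERD_A"
    erd_class_a: float = -0.5
    erd_class_b: float = 0.0

    def __post_init__(self) -> None:
        if self.erd_class_a <= -1 or self.erd_class_b <= -1:
            raise InputError("planted ERD values must be > -1")
        if self.band not in ("ERD_A", "ERD_B"):
            raise InputError("planted band must be ERD_A (alpha) or ERD_B (beta)")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic recordings.

    Defaults emulate the real recordings' structure: 64 channels in the
    10-10 montage at 160 Hz, trials of 2 s rest + 2 s task, unit-RMS alpha
    and beta background rhythms, broadband noise at half that scale.
    """

    n_channels: int = 64
    fs: float = 160.0
    n_trials_per_class: int = 40
    class_labels: tuple[str, str] = ("A", "B")
    planted: tuple[PlantedEffect, ...] = ()
    background_alpha_power: float = 1.0
    background_beta_power: float = 1.0
    oscillation_stability: float = 0.95
    noise_sigma: float = 0.5
    inter_trial_gap_s: float = 1.0
    blink_rate_per_min: float = 0.0
    blink_amplitude: float = 50.0
    line_noise_amplitude: float = 0.0
    line_noise_hz: float = 50.0
    mixing_leakage: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise InputError("need at least one trial per class")
        highest = 25.0  # beta upper edge
        if self.fs <= 2 * highest:
            raise InputError(f"fs={self.fs} too low for the beta band")
        if not 1 <= self.n_channels <= 64:
            raise InputError("n_channels must be in [1, 64]")
        if not 0.0 <= self.oscillation_stability <= 1.0:
            raise InputError("oscillation_stability must be in [0, 1]")

    def montage(self) -> ChannelMap:
        return ChannelMap(names=make_montage().names[: self.n_channels])


def _multisine(n_samples: int, fs: float, low_hz: float, high_hz: float,
               rng: np.random.Generator, window_s: float = 2.0) -> np.ndarray:
    """Unit-RMS random-phase multisine on the window's frequency grid."""
    df = 1.0 / window_s
    freqs = np.arange(np.ceil(low_hz / df), np.floor(high_hz / df) + 1) * df
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    # All components are multiples of 1/window_s, so the multisine is
    # periodic with the window: synthesise one period and tile it.
    period = int(round(window_s * fs))
    t = np.arange(period) / fs
    template = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                             + phases[:, None]), axis=0)
    reps = int(np.ceil(n_samples / period))
    x = np.tile(template, reps)[:n_samples]
    return x * np.sqrt(2.0 / len(freqs))


def _band_noise(n_samples: int, fs: float, low_hz: float, high_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-pass filtered white noise (the fluctuating rhythm part)."""
    from scipy import signal as sps

    taps = sps.firwin(161, [low_hz, high_hz], pass_zero=False, fs=fs)
    x = sps.filtfilt(taps, [1.0], rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _band_oscillation(n_samples: int, fs: float, low_hz: float, high_hz: float,
                      stability: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-power band rhythm: stable carrier + fluctuating filtered noise."""
    parts = []
    if stability > 0:
        parts.append(np.sqrt(stability)
                     * _multisine(n_samples, fs, low_hz, high_hz, rng))
    if stability < 1:
        parts.append(np.sqrt(1.0 - stability)
                     * _band_noise(n_samples, fs, low_hz, high_hz, rng))
    return sum(parts)


def generate_recording(config: SimConfig) -> Recording:
    """Continuous multichannel signal with planted, class-dependent ERD.

    Trials are laid out sequentially (2 s rest + 2 s task + gap); class
    order is a seeded random interleaving with equal counts.  During a
    trial's task window, each planted (channel, band) oscillation is
    scaled by sqrt(1 + erd) for that trial's class.
    """
    rng = np.random.default_rng(config.seed)
    montage = config.montage()
    fs = config.fs
    half = int(round(2.0 * fs))
    gap = int(round(config.inter_trial_gap_s * fs))
    n_trials = 2 * config.n_trials_per_class
    trial_len = 2 * half + gap
    n_samples = n_trials * trial_len + gap
    if n_samples > 5_000_000:
        raise InputError("configuration asks for an unreasonably long recording")

    labels = np.array([config.class_labels[0]] * config.n_trials_per_class
                      + [config.class_labels[1]] * config.n_trials_per_class)
    rng.shuffle(labels)
    onsets = gap + half + np.arange(n_trials) * trial_len  # task starts here

    la, ha = BANDS["ERD_A"].low_hz, BANDS["ERD_A"].high_hz
    lb, hb = BANDS["ERD_B"].low_hz, BANDS["ERD_B"].high_hz
    planted_by_channel: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted:
        if eff.channel.upper() not in montage:
            raise InputError(f"planted channel {eff.channel!r} not in the montage")
        planted_by_channel.setdefault(eff.channel.upper(), []).append(eff)

    data = np.empty((len(montage), n_samples))
    stability = config.oscillation_stability
    for ci, name in enumerate(montage.names):
        alpha = _band_oscillation(n_samples, fs, la, ha, stability, rng)
        beta = _band_oscillation(n_samples, fs, lb, hb, stability, rng)
        env_a = np.ones(n_samples)
        env_b = np.ones(n_samples)
        for eff in planted_by_channel.get(name, ()):
            env = env_a if eff.band == "ERD_A" else env_b
            for onset, lab in zip(onsets, labels):
                erd = eff.erd_class_a if lab == config.class_labels[0] else eff.erd_class_b
                env[onset : onset + half] = np.sqrt(1.0 + erd)
        chan = (config.background_alpha_power * alpha * env_a
                + config.background_beta_power * beta * env_b)
        if config.noise_sigma > 0:
            chan = chan + config.noise_sigma * rng.standard_normal(n_samples)
        data[ci] = chan

    if config.mixing_leakage > 0:
        # Nearest-neighbour leakage in montage order, rows renormalised.
        n = len(montage)
        mix = np.eye(n)
        for i in range(n):
            if i > 0:
                mix[i, i - 1] = config.mixing_leakage
            if i < n - 1:
                mix[i, i + 1] = config.mixing_leakage
        mix /= mix.sum(axis=1, keepdims=True)
        data = mix @ data

    events = [Event(onset=int(o), label=str(lab)) for o, lab in zip(onsets, labels)]
    return Recording(data=data, fs=fs, channels=montage, events=events)


#: Frontal amplitude profile for blink injection (label -> weight).
_BLINK_PROFILE = {"FP1": 1.0, "FPZ": 1.0, "FP2": 1.0,
                  "AF7": 0.6, "AF3": 0.6, "AFZ": 0.6, "AF4": 0.6, "AF8": 0.6,
                  "F7": 0.3, "F5": 0.3, "F3": 0.3, "F1": 0.3, "FZ": 0.3,
                  "F2": 0.3, "F4": 0.3, "F6": 0.3, "F8": 0.3}
_BLINK_BASELINE = 0.05


def inject_artifacts(rec: Recording, config: SimConfig) -> Recording:
    """Add blink transients and line-noise sinusoid; events untouched.

    Blinks are raised-cosine pulses of 0.3-0.5 s at Poisson times, scaled
    per channel by a frontal spatial profile.  Line noise is a common
    sinusoid at ``line_noise_hz`` on every channel.
    """
    rng = np.random.default_rng(config.seed + 1)
    data = rec.data.copy()
    n = rec.n_samples
    profile = np.array([_BLINK_PROFILE.get(name, _BLINK_BASELINE)
                        for name in rec.channels.names])

    if config.blink_rate_per_min > 0 and config.blink_amplitude > 0:
        duration_min = n / rec.fs / 60.0
        n_blinks = rng.poisson(config.blink_rate_per_min * duration_min)
        for _ in range(n_blinks):
            width = int(rng.uniform(0.3, 0.5) * rec.fs)
            start = int(rng.integers(0, max(n - width, 1)))
            pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
            data[:, start : start + width] += (
                config.blink_amplitude * profile[:, None] * pulse[None, :width]
            )

    if config.line_noise_amplitude > 0:
        t = np.arange(n) / rec.fs
        line = config.line_noise_amplitude * np.sin(2 * np.pi * config.line_noise_hz * t)
        data += line[None, :]

    return Recording(data=data, fs=rec.fs, channels=rec.channels,
                     events=list(rec.events))


# ---------------------------------------------------------------------------
# Minimal EDF+C writer (16-bit), enough to round-trip through EDF+ readers.
# Annotations are stored as TALs in an 'EDF Annotations' signal.

def _tal(onset_s: float, text: str) -> bytes:
    return f"+{onset_s:.4f}".rstrip("0").rstrip(".").encode() + b"\x14" \
        + text.encode() + b"\x14\x00"


def write_edf(rec: Recording, path: str | Path, physical_max: float | None = None,
              annotation_codes: dict[str, str] | None = None) -> Path:
    """Write a Recording as a 16-bit EDF+C file with event annotations.

    Event labels are written verbatim as annotation texts unless
    ``annotation_codes`` maps them (e.g. ``{"A": "T1", "B": "T2"}`` for the
    PhysioNet dialect).  One data record per second.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise InputError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((rec.data.shape[0], n_records * spr))
    padded[:, : rec.n_samples] = rec.data

    if physical_max is None:
        physical_max = float(max(np.max(np.abs(padded)) * 1.05, 1.0))
    # The header stores physical min/max to one decimal; round up and use the
    # stored value for scaling so reader and writer agree exactly.
    physical_max = float(np.ceil(physical_max * 10) / 10)
    pmin, pmax = -physical_max, physical_max
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((padded - pmin) * scale + dmin), dmin, dmax).astype("<i2")

    codes = annotation_codes or {}
    tals_by_record: list[bytes] = []
    events_per_record: dict[int, list[bytes]] = {}
    for ev in rec.events:
        onset_s = ev.onset / fs
        record = min(int(onset_s), n_records - 1)
        text = codes.get(ev.label, ev.label)
        events_per_record.setdefault(record, []).append(_tal(onset_s, text))
    ann_len_candidates = []
    for r in range(n_records):
        body = _tal(float(r), "")  # timestamp TAL, mandatory per record
        body += b"".join(events_per_record.get(r, []))
        ann_len_candidates.append(body)
    ann_bytes = max(len(b) for b in ann_len_candidates) + 16
    ann_samples = int(np.ceil(ann_bytes / 2))
    tals_by_record = [b.ljust(ann_samples * 2, b"\x00") for b in ann_len_candidates]

    n_signals = rec.data.shape[0] + 1
    header_bytes = 256 + 256 * n_signals

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b.ljust(width, b" ")

    with open(path, "wb") as f:
        f.write(fixed("0", 8))
        f.write(fixed("X X X X", 80))                       # patient id
        f.write(fixed("Startdate 01-JAN-2020 X X X", 80))   # recording id
        f.write(fixed("01.01.20", 8))
        f.write(fixed("00.00.00", 8))
        f.write(fixed(str(header_bytes), 8))
        f.write(fixed("EDF+C", 44))
        f.write(fixed(str(n_records), 8))
        f.write(fixed("1", 8))                              # record duration (s)
        f.write(fixed(str(n_signals), 4))

        names = list(rec.channels.names) + ["EDF Annotations"]
        for name in names:
            f.write(fixed(name, 16))
        for _ in names:
            f.write(fixed("", 80))                          # transducer
        for i in range(n_signals):
            f.write(fixed("uV" if i < n_signals - 1 else "", 8))
        for i in range(n_signals):
            f.write(fixed(f"{pmin:.1f}" if i < n_signals - 1 else "-1", 8))
        for i in range(n_signals):
            f.write(fixed(f"{pmax:.1f}" if i < n_signals - 1 else "1", 8))
        for i in range(n_signals):
            f.write(fixed(str(dmin), 8))
        for i in range(n_signals):
            f.write(fixed(str(dmax), 8))
        for _ in names:
            f.write(fixed("", 80))                          # prefiltering
        for i in range(n_signals):
            f.write(fixed(str(spr if i < n_signals - 1 else ann_samples), 8))
        for _ in names:
            f.write(fixed("", 32))                          # reserved

        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes(order="C"))
            f.write(tals_by_record[r])
    return path


def write_physionet_run(rec: Recording, directory: str | Path, subject: int,
                        run: int, codes: dict[str, str] | None = None) -> Path:
    """Write ``SxxxRyy.edf`` in the PhysioNet naming/annotation dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"S{subject:03d}R{run:02d}.edf"
    return write_edf(rec, path, annotation_codes=codes or {})
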