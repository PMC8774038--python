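"""Montage registry, EDF+ reading, run concatenation and epoching.

The recordings follow the PhysioNet motor movement/imagery layout:
64 channels in the 10-10 system, 160 Hz, average reference, with cue
annotations T1/T2 inside each 2-minute run and files named ``SxxxRyy.edf``.
Runs 3/7/11 are real hand movement (RHM), 4/8/12 imagined hand movement
(IHM), 5/9/13 real fists-or-feet movement (RFM), 6/10/14 imagined
fists-or-feet movement (IFM); runs 1-2 are eyes-open/closed baselines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Channel order of the PhysioNet EDF files (10-10 labels, canonical casing).
PHYSIONET_64 = (
    "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2", "IZ",
)

#: Subjects whose annotations are known to be erroneous; excluded by default.
DEFAULT_EXCLUDED_SUBJECTS = (38, 88, 89, 92, 93, 94, 100, 104, 106)

# A-priori sensorimotor channel groups.  C3/C4 (and the centro-parietal
# CP3/CP4) sit over the left/right hand representation; the ROI variants take
# the surrounding neighbourhood, mirrored over both hemispheres.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "C3C4": ("C3", "C4"),
    "CP3CP4": ("CP3", "CP4"),
    "ROI_C3C4": ("FC3", "C5", "C3", "C1", "CP3", "FC4", "C2", "C4", "C6", "CP4"),
    "ROI_CP3CP4": ("C3", "CP5", "CP3", "CP1", "P3", "C4", "CP6", "CP4", "CP2", "P4"),
}

_RUNS_BY_TASK = {"RHM": (3, 7, 11), "IHM": (4, 8, 12), "RFM": (5, 9, 13), "IFM": (6, 10, 14)}

TASK_PAIR_NAMES = ("RHM_vs_IHM", "RFM_vs_IFM", "RHM_vs_RFM", "IHM_vs_IFM")


class ConfigurationError(ValueError):
    """Raised for unknown group/pair names or invalid configuration."""


class InputError(ValueError):
    """Raised for unreadable or structurally invalid input data."""


@dataclass(frozen=True)
class ChannelMap:
    """Ordered electrode labels with label -> 0-based index lookup."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("channel labels must be unique")

    def index_of(self, label: str) -> int:
        try:
            return self.names.index(label.upper())
        except ValueError:
            raise ConfigurationError(f"unknown channel label {label!r}") from None

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, label: str) -> bool:
        return label.upper() in self.names


@dataclass(frozen=True)
class Event:
    """A cue onset: 0-based sample index, class tag, and source run number."""

    onset: int
    label: str
    source_run: int = 0

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise InputError(f"event onset must be >= 0, got {self.onset}")


@dataclass
class Recording:
    """Continuous multichannel signal (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channels: ChannelMap
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("recording data must be channels x samples")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise InputError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        for ev in self.events:
            if ev.onset >= self.n_samples:
                raise InputError(f"event onset {ev.onset} beyond {self.n_samples} samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kwargs) -> "Recording":
        out = replace(self, **kwargs)
        return out


@dataclass
class EpochSet:
    """Event-locked trials: trials x channels x (rest + task) samples.

    The first ``n_pre`` samples of each trial are the 2 s pre-stimulus rest
    window, the last ``n_post`` the 2 s post-stimulus task window.
    """

    data: np.ndarray
    labels: list[str]
    fs: float
    n_pre: int
    n_post: int
    channels: ChannelMap

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InputError("epoch data must be trials x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise InputError("one label per trial required")
        if self.data.shape[2] != self.n_pre + self.n_post:
            raise InputError("sample count must equal n_pre + n_post")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def rest_windows(self) -> np.ndarray:
        return self.data[:, :, : self.n_pre]

    def task_windows(self) -> np.ndarray:
        return self.data[:, :, self.n_pre :]


@dataclass(frozen=True)
class TaskPair:
    """A binary task contrast with its run-number triples and class tags."""

    name: str
    runs_a: tuple[int, int, int]
    runs_b: tuple[int, int, int]
    label_a: str
    label_b: str

    def label_for_run(self, run: int) -> str:
        if run in self.runs_a:
            return self.label_a
        if run in self.runs_b:
            return self.label_b
        raise ConfigurationError(f"run {run} does not belong to task pair {self.name}")

    @property
    def runs(self) -> tuple[int, ...]:
        return self.runs_a + self.runs_b


def task_pair(name: str) -> TaskPair:
    """Return one of the four studied task contrasts by name."""
    if name not in TASK_PAIR_NAMES:
        raise ConfigurationError(f"unknown task pair {name!r}; choose from {TASK_PAIR_NAMES}")
    a, _, b = name.partition("_vs_")
    return TaskPair(name=name, runs_a=_RUNS_BY_TASK[a], runs_b=_RUNS_BY_TASK[b],
                    label_a=a, label_b=b)


def make_montage() -> ChannelMap:
    """The fixed 64-label PhysioNet 10-10 montage, in file order."""
    return ChannelMap(names=PHYSIONET_64)


def channel_group(name: str) -> list[str]:
    """Electrode labels of an a-priori sensorimotor group.

    ``C3C4`` and ``CP3CP4`` are the two-electrode hand-area pairs; the
    ``ROI_*`` groups are the ten-electrode neighbourhoods around them.
    """
    try:
        return list(CHANNEL_GROUPS[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown channel group {name!r}; choose from {sorted(CHANNEL_GROUPS)}"
        ) from None


def _normalise_label(raw: str) -> str:
    return raw.strip().rstrip(".").upper()


def parse_physionet_name(path: str | Path) -> tuple[int, int]:
    """Extract (subject, run) from a ``SxxxRyy.edf`` file name."""
    m = re.fullmatch(r"S(\d{3})R(\d{2})(?:\.edf)?", Path(path).name, flags=re.IGNORECASE)
    if not m:
        raise InputError(f"cannot parse subject/run from file name {Path(path).name!r}")
    return int(m.group(1)), int(m.group(2))


def read_edf_run(path: str | Path, pair: TaskPair, run: int | None = None) -> Recording:
    """Read one EDF+ run, keeping cue annotations (T1/T2) as events.

    Each cue is labelled with the run's class under ``pair`` (left/right or
    fists/feet cues are pooled into the run's task type).  Rest annotations
    (T0) are dropped: the ERD baseline is the 2 s before each cue, not the
    T0 blocks.
    """
    import mne

    path = Path(path)
    if run is None:
        _, run = parse_physionet_name(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for malformed files
        raise InputError(f"cannot read EDF file {path}: {exc}") from exc

    labels = tuple(_normalise_label(ch) for ch in raw.ch_names)
    if len(labels) != 64:
        raise InputError(f"{path}: expected 64 channels, found {len(labels)}")
    montage = make_montage()
    if set(labels) != set(montage.names):
        raise InputError(f"{path}: channel labels do not match the 10-10 montage")
    data = raw.get_data(units="uV")
    if labels != montage.names:  # reorder to canonical montage order
        order = [labels.index(name) for name in montage.names]
        data = data[order]

    fs = float(raw.info["sfreq"])
    cls = pair.label_for_run(run)
    events: list[Event] = []
    for ann in raw.annotations:
        code = str(ann["description"]).strip()
        if code in ("T1", "T2"):
            onset = int(round(ann["onset"] * fs))
            events.append(Event(onset=onset, label=cls, source_run=run))
    events.sort(key=lambda e: e.onset)
    if not events:
        logger.warning("%s: no T1/T2 cue annotations found", path)
    return Recording(data=data, fs=fs, channels=montage, events=events)


def concatenate_runs(recordings: list[Recording]) -> Recording:
    """Concatenate runs along time, shifting event onsets by the offsets."""
    if not recordings:
        raise InputError("cannot concatenate an empty list of recordings")
    first = recordings[0]
    for rec in recordings[1:]:
        if rec.fs != first.fs:
            raise InputError(f"sampling rates differ: {rec.fs} vs {first.fs}")
        if rec.channels.names != first.channels.names:
            raise InputError("channel sets differ between runs")
    data = np.concatenate([rec.data for rec in recordings], axis=1)
    events: list[Event] = []
    offset = 0
    for rec in recordings:
        for ev in rec.events:
            events.append(Event(onset=ev.onset + offset, label=ev.label,
                                source_run=ev.source_run))
        offset += rec.n_samples
    return Recording(data=data, fs=first.fs, channels=first.channels, events=events)


def epoch_events(rec: Recording, window_s: float = 2.0) -> EpochSet:
    """Cut one trial per event: [onset - 2 s, onset + 2 s), rest then task.

    The onset sample itself belongs to the task window.  Events too close to
    either recording edge are skipped (logged).
    """
    half = int(round(window_s * rec.fs))
    trials, labels, skipped = [], [], 0
    for ev in rec.events:
        start, stop = ev.onset - half, ev.onset + half
        if start < 0 or stop > rec.n_samples:
            skipped += 1
            continue
        trials.append(rec.data[:, start:stop])
        labels.append(ev.label)
    if skipped:
        logger.info("epoch_events: skipped %d events too close to an edge", skipped)
    if not trials:
        raise InputError("no events usable for epoching")
    return EpochSet(data=np.stack(trials), labels=labels, fs=rec.fs,
                    n_pre=half, n_post=half, channels=rec.channels)


def subject_run_files(data_dir: str | Path, pair: TaskPair,
                      excluded: tuple[int, ...] = DEFAULT_EXCLUDED_SUBJECTS,
                      ) -> dict[int, list[Path]]:
    """Map subject number -> sorted EDF paths for the pair's runs.

    Expects the PhysioNet layout ``<data_dir>/S001/S001R03.edf`` (a flat
    directory of EDF files also works).
    """
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise InputError(f"data directory {data_dir} does not exist")
    out: dict[int, list[Path]] = {}
    for path in sorted(data_dir.rglob("S*R*.edf")):
        try:
            subject, run = parse_physionet_name(path)
        except InputError:
            continue
        if subject in excluded or run not in pair.runs:
            continue
        out.setdefault(subject, []).append(path)
    return out
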