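"""Signal-to-noise improvement: band-pass filtering and ICA artifact rejection.

Two cleaning arms are provided: ``filter`` (zero-phase FIR band-pass,
default 1-48 Hz) and ``filter+ica`` (FastICA decomposition with automated
component rejection).  The ICA rejection criteria are simple and
conservative -- a component is flagged when its time course is strongly
non-Gaussian (high |kurtosis|, typical of blinks and electrode pops) or
when it is simultaneously frontal-dominated and low-frequency-dominated
(the ocular signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from mi_erd.data_io import InputError, Recording

logger = logging.getLogger(__name__)

#: Frontal labels used for the ocular-topography criterion.
FRONTAL_LABELS = ("FP1", "FPZ", "FP2", "AF7", "AF3", "AFZ", "AF4", "AF8")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR band-pass specification.

    ``order`` defaults to ``4 * fs / low_hz`` rounded to the next odd
    integer, giving a transition band narrow relative to the low edge.
    """

    low_hz: float = 1.0
    high_hz: float = 48.0
    order: int | None = None
    design: str = "hamming"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise InputError(
                f"passband [{self.low_hz}, {self.high_hz}] Hz invalid for fs={fs} Hz"
            )

    def n_taps(self, fs: float) -> int:
        if self.order is not None:
            n = int(self.order)
        else:
            n = int(round(4 * fs / self.low_hz))
        return n if n % 2 == 1 else n + 1


@dataclass
class IcaRejectionReport:
    """Which independent components were rejected, and their criterion scores."""

    n_components: int
    rejected: list[int]
    criteria_scores: dict[str, np.ndarray] = field(default_factory=dict)


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """FIR taps for the band-pass; exposed so tests can probe the response."""
    spec.validate(fs)
    n = spec.n_taps(fs)
    return sps.firwin(n, [spec.low_hz, spec.high_hz], pass_zero=False,
                      window=spec.design, fs=fs)


def bandpass_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase (forward-backward) FIR band-pass of every channel.

    Shape, sampling rate and events are unchanged.
    """
    spec = spec or FilterSpec()
    taps = design_bandpass(spec, rec.fs)
    if rec.n_samples < 3 * len(taps):
        raise InputError(
            f"signal of {rec.n_samples} samples too short for a "
            f"{len(taps)}-tap zero-phase filter (need >= {3 * len(taps)})"
        )
    filtered = sps.filtfilt(taps, [1.0], rec.data, axis=1)
    return Recording(data=filtered, fs=rec.fs, channels=rec.channels,
                     events=list(rec.events))


def _low_freq_power_fraction(x: np.ndarray, fs: float, cut_hz: float = 4.0) -> float:
    freqs, pxx = sps.periodogram(x, fs=fs)
    total = float(np.sum(pxx))
    if total == 0:
        return 0.0
    return float(np.sum(pxx[freqs <= cut_hz]) / total)


def ica_artifact_removal(
    rec: Recording,
    max_reject: int = 5,
    kurtosis_threshold: float = 8.0,
    frontal_fraction_threshold: float = 0.6,
    low_freq_fraction_threshold: float = 0.7,
    n_components: int | None = None,
    seed: int = 0,
) -> tuple[Recording, IcaRejectionReport]:
    """FastICA decomposition with automated rejection of artifact components.

    A component is flagged when ``|kurtosis| > kurtosis_threshold`` OR when
    its frontal mixing-weight fraction and sub-4 Hz power fraction both
    exceed their thresholds.  Flagged components are zeroed (highest
    composite score first, at most ``max_reject``) and the signal is
    reconstructed.  Deterministic for a fixed seed.
    """
    from sklearn.decomposition import FastICA

    n_ch, n_samp = rec.data.shape
    if n_samp <= n_ch * 20:
        raise InputError(f"need more than {n_ch * 20} samples for {n_ch}-channel ICA")
    n_comp = n_components if n_components is not None else n_ch

    ica = FastICA(n_components=n_comp, whiten="unit-variance", max_iter=1000,
                  tol=1e-4, random_state=seed)
    mean = rec.data.mean(axis=1, keepdims=True)
    try:
        sources = ica.fit_transform((rec.data - mean).T)  # samples x components
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise InputError(
            "ICA decomposition failed (rank-deficient data?); "
            "consider pruning flat or duplicated channels"
        ) from exc
    mixing = ica.mixing_  # channels x components

    frontal_idx = [rec.channels.index_of(l) for l in FRONTAL_LABELS
                   if l in rec.channels]
    kurt = np.array([stats.kurtosis(sources[:, c]) for c in range(n_comp)])
    abs_w = np.abs(mixing)
    col_sum = abs_w.sum(axis=0)
    col_sum[col_sum == 0] = 1.0
    frontal_frac = abs_w[frontal_idx].sum(axis=0) / col_sum if frontal_idx \
        else np.zeros(n_comp)
    low_frac = np.array([_low_freq_power_fraction(sources[:, c], rec.fs)
                         for c in range(n_comp)])

    # Composite score: how far past its threshold each criterion reaches.
    ocular = np.minimum(frontal_frac / frontal_fraction_threshold,
                        low_frac / low_freq_fraction_threshold)
    score = np.maximum(np.abs(kurt) / kurtosis_threshold, ocular)
    flagged = np.flatnonzero(
        (np.abs(kurt) > kurtosis_threshold)
        | ((frontal_frac > frontal_fraction_threshold)
           & (low_frac > low_freq_fraction_threshold))
    )
    rejected = sorted(flagged, key=lambda c: -score[c])[:max_reject]

    report = IcaRejectionReport(
        n_components=n_comp,
        rejected=[int(c) for c in rejected],
        criteria_scores={"kurtosis": kurt, "frontal_fraction": frontal_frac,
                         "low_freq_fraction": low_frac},
    )
    if not rejected:
        return rec.copy_with(data=rec.data.copy(), events=list(rec.events)), report
    logger.info("ICA rejecting %d/%d components: %s", len(rejected), n_comp, rejected)
    kept = sources.copy()
    kept[:, rejected] = 0.0
    cleaned = (kept @ mixing.T).T + mean
    return Recording(data=cleaned, fs=rec.fs, channels=rec.channels,
                     events=list(rec.events)), report
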