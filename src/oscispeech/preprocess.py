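"""EEG preprocessing chain: earlobe re-referencing, signal-space projection
(SSP) removal of blink/saccade artifacts, zero-phase bandpass filtering, and
epoch segmentation on the fixed trial timeline.

Every stage is linear, so the chain commutes with scaling and (when the
reference channels are excluded from the artifact patterns) re-referencing
and SSP commute with each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ContinuousEEG, EEGEpochSet, EpochTimeline

logger = logging.getLogger(__name__)


def rereference(epochs: EEGEpochSet, reference_labels=None) -> EEGEpochSet:
    """Subtract the instantaneous mean of the reference channels from every
    channel (average-earlobe reference)."""
    if reference_labels is None:
        reference_labels = epochs.montage.reference_labels
    try:
        ref_idx = epochs.montage.indices(reference_labels)
    except KeyError as err:
        raise ValueError(f"missing reference channel: {err}") from None
    ref_mean = epochs.data[:, ref_idx, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(epochs.data - ref_mean)


@dataclass(frozen=True)
class ProjectionOperator:
    """Orthogonal projection onto the complement of artifact spatial patterns.

    matrix is channel x channel, symmetric and idempotent with rank
    n_channels - n_components; patterns holds the removed spatial directions
    (columns, orthonormal).
    """

    matrix: np.ndarray
    patterns: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("projection matrix must be symmetric")
        if not np.allclose(m @ m, m, atol=1e-10):
            raise ValueError("projection matrix must be idempotent")

    @property
    def rank(self) -> int:
        return self.matrix.shape[0] - self.n_components

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Apply to (..., n_channels, n_samples) data."""
        return np.einsum("ij,...jt->...it", self.matrix, data)

    def apply_epochs(self, epochs: EEGEpochSet) -> EEGEpochSet:
        return epochs.copy_with(self.apply(epochs.data))


def fit_ssp(artifact_segments, n_components: int = 1, exclude_idx=None) -> ProjectionOperator:
    """Fit SSP spatial filters from artifact-dominated data segments.

    ``artifact_segments`` is an iterable of (n_channels, n_samples) arrays
    (or an array stacking them). The artifact patterns are the leading left
    singular vectors of the concatenated segments; the operator projects each
    channel vector onto their orthogonal complement. ``exclude_idx`` zeroes
    the listed channels (e.g. references) out of the patterns before fitting.
    """
    segs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in artifact_segments]
    if not segs:
        raise ValueError("need at least one artifact segment")
    stacked = np.concatenate(segs, axis=1)
    n_ch = stacked.shape[0]
    if n_components >= n_ch:
        raise ValueError("n_components must be smaller than the channel count")
    if exclude_idx is not None:
        stacked = stacked.copy()
        stacked[np.asarray(exclude_idx, dtype=int)] = 0.0
    u, _, _ = np.linalg.svd(stacked, full_matrices=False)
    patterns = u[:, :n_components]
    matrix = np.eye(n_ch) - patterns @ patterns.T
    return ProjectionOperator(matrix=matrix, patterns=patterns, n_components=n_components)


def bandpass(
    epochs: EEGEpochSet,
    low: float = 1.0,
    high: float = 400.0,
    order: int = 4,
) -> EEGEpochSet:
    """Zero-phase (forward-backward Butterworth) bandpass filter.

    ``high`` is clipped to 0.45 x sampling rate with a warning when it
    exceeds what the recording can represent (the nominal 400-Hz edge cannot
    be realized at desk-scale sampling rates).
    """
    fs = epochs.sampling_rate
    if not low < high:
        raise ValueError("low must be < high")
    max_high = 0.45 * fs
    if high > max_high:
        logger.warning("bandpass high edge %.3g Hz clipped to %.3g Hz (0.45 x fs)", high, max_high)
        high = max_high
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if epochs.data.shape[2] <= padlen:
        raise ValueError("epoch shorter than the filter transient")
    return epochs.copy_with(sosfiltfilt(sos, epochs.data, axis=2))


def segment_epochs(
    continuous: ContinuousEEG,
    timeline: EpochTimeline,
    cue_label: str = "cue",
) -> EEGEpochSet:
    """Cut fixed-length epochs around cue annotations.

    Each epoch spans round(timeline.duration x fs) samples and starts
    ``cue_time - epoch_start`` seconds before the cue sample. Cues too close
    to the recording edge are dropped with a log message.
    """
    fs = continuous.sampling_rate
    n_samples = timeline.n_samples(fs)
    pre_cue = timeline.to_index(timeline.cue_time, fs)
    total = continuous.data.shape[1]
    epochs, dropped = [], 0
    import pandas as pd

    rows = []
    for sample, label in continuous.events:
        if label != cue_label:
            continue
        start = sample - pre_cue
        if start < 0 or start + n_samples > total:
            dropped += 1
            continue
        epochs.append(continuous.data[:, start : start + n_samples])
        rows.append(
            {
                "cue_sample": pre_cue,
                "stimulus_sample": timeline.to_index(timeline.stimulus_onset, fs),
                "target_sample": timeline.to_index(timeline.target_onset, fs),
            }
        )
    if dropped:
        logger.warning("dropped %d trials whose epochs fall outside the recording", dropped)
    data = (
        np.stack(epochs)
        if epochs
        else np.empty((0, continuous.data.shape[0], n_samples))
    )
    return EEGEpochSet(
        data=data,
        montage=continuous.montage,
        sampling_rate=fs,
        timeline=timeline,
        info=pd.DataFrame(rows),
    )


def preprocess_epochs(
    epochs: EEGEpochSet,
    artifact_segments=None,
    n_components: int = 1,
    low: float = 1.0,
    high: float = 400.0,
) -> tuple[EEGEpochSet, dict]:
    """The full chain: re-reference, SSP (if artifact segments given),
    bandpass. Returns the cleaned epochs and a JSON-able processing log."""
    log: dict = {"steps": []}
    out = rereference(epochs)
    log["steps"].append({"step": "rereference", "reference": list(epochs.montage.reference_labels)})
    if artifact_segments is not None:
        ref_idx = epochs.montage.indices(epochs.montage.reference_labels)
        proj = fit_ssp(artifact_segments, n_components=n_components, exclude_idx=ref_idx)
        out = proj.apply_epochs(out)
        log["steps"].append({"step": "ssp", "n_components": n_components})
    fs = epochs.sampling_rate
    effective_high = min(high, 0.45 * fs)
    out = bandpass(out, low=low, high=high)
    log["steps"].append({"step": "bandpass", "low": low, "high": effective_high, "requested_high": high})
    return out, log
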