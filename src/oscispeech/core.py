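"""Core data containers: channel montage, epoch timeline, and epoch sets.

The study design these containers encode: 32 cephalic electrodes (Biosemi
A1-A32) plus two earlobe reference electrodes; each trial is a 5.25-s epoch
with a fixed visual-cue / masker-onset / target-onset timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Parieto-occipital channel group, where induced alpha power is strongest.
PARIETO_OCCIPITAL = tuple(f"A{i}" for i in range(9, 23))
#: Frontal channel group, where induced beta power is strongest.
FRONTAL = tuple(f"A{i}" for i in list(range(1, 7)) + list(range(25, 32)))
#: Earlobe reference electrodes (no scalp position; excluded from power maps).
REFERENCE_LABELS = ("EXG1", "EXG2")


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered channel labels, 2-D scalp positions, and named channel groups.

    ``positions`` maps each cephalic label to an (x, y) head-plane coordinate;
    reference (earlobe) channels carry no position.
    """

    labels: tuple[str, ...]
    positions: dict[str, np.ndarray]
    groups: dict[str, tuple[str, ...]]
    reference_labels: tuple[str, ...] = REFERENCE_LABELS

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for ref in self.reference_labels:
            if ref not in self.labels:
                raise ValueError(f"reference channel {ref!r} not in labels")
            if ref in self.positions:
                raise ValueError(f"reference channel {ref!r} must not carry a position")
        for name, members in self.groups.items():
            missing = set(members) - set(self.labels)
            if missing:
                raise ValueError(f"group {name!r} has unknown channels {sorted(missing)}")

    @property
    def cephalic_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.reference_labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}; known: {self.labels}") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=int)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in self.groups:
            raise KeyError(f"unknown channel group {group!r}; valid groups: {sorted(self.groups)}")
        return self.indices(self.groups[group])


def biosemi32_montage() -> ChannelMontage:
    """The 32-channel Biosemi montage (A1-A32) plus two earlobe references.

    Scalp coordinates come from MNE's bundled ``biosemi32`` standard montage,
    whose channel order is the Biosemi A1-A32 order; positions are projected
    onto the (x, y) head plane.
    """
    import mne

    std = mne.channels.make_standard_montage("biosemi32")
    labels = tuple(f"A{i}" for i in range(1, 33)) + REFERENCE_LABELS
    pos3d = std.get_positions()["ch_pos"]
    positions = {
        f"A{i + 1}": np.asarray(pos3d[name][:2], dtype=float)
        for i, name in enumerate(std.ch_names)
    }
    groups = {"parieto_occipital": PARIETO_OCCIPITAL, "frontal": FRONTAL}
    return ChannelMontage(labels=labels, positions=positions, groups=groups)


@dataclass(frozen=True)
class EpochTimeline:
    """Within-epoch event times in seconds.

    Epochs start 0.5 s before the "stay still and listen now" cue; the masker
    starts 1.0 s after the cue and the target sentence 1.25 s after the
    masker. The pre-stimulus window is the 1-s cue-to-masker interval and the
    during-stimulus window runs from masker onset to the end of the epoch
    (3.75 s). Windows are half-open, [start, end).
    """

    epoch_start: float = 0.0
    cue_time: float = 0.5
    stimulus_onset: float = 1.5
    target_onset: float = 2.75
    epoch_end: float = 5.25

    def __post_init__(self) -> None:
        if not (
            self.epoch_start < self.cue_time < self.stimulus_onset
            < self.target_onset < self.epoch_end
        ):
            raise ValueError("timeline events must be strictly increasing")

    @property
    def pre_window(self) -> tuple[float, float]:
        return (self.cue_time, self.stimulus_onset)

    @property
    def during_window(self) -> tuple[float, float]:
        return (self.stimulus_onset, self.epoch_end)

    @property
    def duration(self) -> float:
        return self.epoch_end - self.epoch_start

    def n_samples(self, sampling_rate: float) -> int:
        return int(round(self.duration * sampling_rate))

    def to_index(self, t: float, sampling_rate: float) -> int:
        """0-based sample index of time ``t`` relative to epoch start."""
        return int(round((t - self.epoch_start) * sampling_rate))


@dataclass
class EEGEpochSet:
    """A stack of per-trial multichannel epochs with montage and timeline.

    data
        Array of shape (n_epochs, n_channels, n_samples), volts.
    info
        One row of trial metadata per epoch (subject, condition, trial, ...).
    """

    data: np.ndarray
    montage: ChannelMontage
    sampling_rate: float
    timeline: EpochTimeline
    info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[1] != len(self.montage.labels):
            raise ValueError(
                f"data has {self.data.shape[1]} channels, montage has {len(self.montage.labels)}"
            )
        expected = self.timeline.n_samples(self.sampling_rate)
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epochs have {self.data.shape[2]} samples; timeline implies {expected}"
            )
        if len(self.info) and len(self.info) != self.data.shape[0]:
            raise ValueError("info rows must match n_epochs")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.timeline.epoch_start + np.arange(n) / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "EEGEpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ContinuousEEG:
    """A continuous multichannel recording with event annotations.

    events is a list of (sample_index, label) pairs; ``segment_epochs`` cuts
    fixed-timeline epochs around cue events.
    """

    data: np.ndarray
    montage: ChannelMontage
    sampling_rate: float
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
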