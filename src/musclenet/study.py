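"""Containers for multichannel EMG studies.

A *study* is a collection of trials organized as subjects x conditions x
trials, sharing one sampling rate and one channel set.  The default channel
set is the ten bilateral leg muscles used for standing posture work: rectus
femoris (RF), vastus medialis (VM), gastrocnemius (GM), tibialis anterior
(TA) and extensor digitorum longus (ED), right then left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import InvalidParameterError, InvalidInputError

#: Acquisition-order labels of the ten postural leg muscles.
DEFAULT_MUSCLES = [
    "RF_r", "VM_r", "GM_r", "TA_r", "ED_r",
    "RF_l", "VM_l", "GM_l", "TA_l", "ED_l",
]

#: Behavioral conditions of the standing protocol (labels only).
DEFAULT_CONDITIONS = ["control", "counting", "cup", "height"]


@dataclass(frozen=True)
class StudyDesign:
    """Recording geometry: subjects, conditions, trials, duration, rate, channels.

    Defaults emulate the standing-posture protocol: 10 muscles sampled at
    2 kHz, four 60-s trials in each of four conditions.
    """

    n_subjects: int = 18
    conditions: tuple[str, ...] = tuple(DEFAULT_CONDITIONS)
    trials_per_condition: int = 4
    trial_duration: float = 60.0
    fs: float = 2000.0
    channel_labels: tuple[str, ...] = tuple(DEFAULT_MUSCLES)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise InvalidParameterError("n_subjects and trials_per_condition must be >= 1")
        if self.fs <= 0 or self.trial_duration <= 0:
            raise InvalidParameterError("fs and trial_duration must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        if len(self.conditions) < 1:
            raise InvalidParameterError("at least one condition label is required")
        n = self.fs * self.trial_duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                f"trial_duration x fs = {n} is not an integer sample count"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "conditions": list(self.conditions),
            "trials_per_condition": self.trials_per_condition,
            "trial_duration": self.trial_duration,
            "fs": self.fs,
            "channel_labels": list(self.channel_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        return cls(
            n_subjects=int(d["n_subjects"]),
            conditions=tuple(d["conditions"]),
            trials_per_condition=int(d["trials_per_condition"]),
            trial_duration=float(d["trial_duration"]),
            fs=float(d["fs"]),
            channel_labels=tuple(d["channel_labels"]),
        )


@dataclass
class EmgTrial:
    """One trial: a channel x sample array plus its identifiers."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: tuple[str, ...]
    subject: int = 0
    condition: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidInputError("trial samples must be a 2-D channel x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise InvalidInputError(
                f"trial has {self.samples.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EmgStudy:
    """Hierarchical container of trials with study-level metadata.

    ``provenance`` records how the data came to be (generator spec + seed for
    synthetic studies, acquisition notes otherwise).
    """

    design: StudyDesign
    trials: list[EmgTrial] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.trials:
            self._check_trial(t)

    def _check_trial(self, t: EmgTrial) -> None:
        if t.fs != self.design.fs:
            raise InvalidInputError(
                f"trial fs {t.fs} differs from study fs {self.design.fs}"
            )
        if tuple(t.channel_labels) != tuple(self.design.channel_labels):
            raise InvalidInputError("trial channel labels differ from study labels")

    def add(self, trial: EmgTrial) -> None:
        self._check_trial(trial)
        self.trials.append(trial)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def subjects(self) -> list[int]:
        return sorted({t.subject for t in self.trials})

    @property
    def conditions(self) -> list[str]:
        return [c for c in self.design.conditions
                if any(t.condition == c for t in self.trials)]

    def select(self, subject: int | None = None,
               condition: str | None = None) -> list[EmgTrial]:
        """Trials matching the given subject and/or condition, in stored order."""
        out = []
        for t in self.trials:
            if subject is not None and t.subject != subject:
                continue
            if condition is not None and t.condition != condition:
                continue
            out.append(t)
        return out

    def iter_cells(self) -> Iterator[tuple[int, str, list[EmgTrial]]]:
        """Yield (subject, condition, trials) for every populated design cell."""
        for s in self.subjects:
            for c in self.design.conditions:
                cell = self.select(subject=s, condition=c)
                if cell:
                    yield s, c, cell
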