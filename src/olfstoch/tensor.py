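"""The trial-resolved response tensor exchanged between all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ResponseTensor:
    """ΔF/F values indexed by (cell, odor, trial, frame).

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_odors, n_trials, n_frames)`` holding
        fractional fluorescence changes.  Trial counts are equal across
        odors by construction.
    frame_duration
        Seconds per imaging frame.
    odor_onset_frame
        Index of the first post-onset frame; must lie strictly inside the
        frame range so that both a baseline and a response window exist.
    labels
        Odor identifiers, one per odor axis entry.
    """

    values: np.ndarray
    frame_duration: float
    odor_onset_frame: int
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(
                f"values must be 4-D (cell, odor, trial, frame), got {self.values.ndim}-D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response tensor contains non-finite values")
        n_frames = self.values.shape[3]
        if not (0 < self.odor_onset_frame < n_frames):
            raise ValueError(
                f"odor_onset_frame {self.odor_onset_frame} must lie strictly "
                f"inside the frame range (0, {n_frames})"
            )
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if not self.labels:
            self.labels = [f"odor{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("number of labels must match number of odors")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_odors(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def baseline_frames(self) -> np.ndarray:
        """Indices of the pre-onset frames."""
        return np.arange(0, self.odor_onset_frame)

    def response_frames(self) -> np.ndarray:
        """Indices of the post-onset frames."""
        return np.arange(self.odor_onset_frame, self.n_frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseTensor):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.frame_duration == other.frame_duration
            and self.odor_onset_frame == other.odor_onset_frame
            and list(self.labels) == list(other.labels)
        )
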