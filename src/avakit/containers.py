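"""In-memory containers shared by the analysis stages.

The central objects mirror how calcium-imaging avalanche studies carry their
data: a spike-probability raster ``lambda`` (neurons x frames, one row per
deconvolved neuron), a binarized raster derived from it by a threshold
``lambda_thr``, per-neuron dF/F traces, and an ordered tone-presentation
protocol (frequency, sound level, onset frame, duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ProtocolError


class Trial(NamedTuple):
    """One tone presentation."""

    frequency_hz: float
    level_db: float
    onset_frame: int
    duration_frames: int


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping tone trials on a fixed frame clock."""

    trials: tuple[Trial, ...]
    frame_rate: float
    isi_range: tuple[float, float] = (4.0, 6.0)

    def __post_init__(self):
        object.__setattr__(self, "trials", tuple(Trial(*t) for t in self.trials))
        prev_end = -1
        prev_onset = -1
        for t in self.trials:
            if t.duration_frames <= 0:
                raise ProtocolError(f"trial duration must be positive, got {t.duration_frames}")
            if t.onset_frame <= prev_onset:
                raise ProtocolError("trial onsets must be strictly increasing")
            if t.onset_frame <= prev_end:
                raise ProtocolError("trials must not overlap in frames")
            prev_onset = t.onset_frame
            prev_end = t.onset_frame + t.duration_frames - 1

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def frequencies(self) -> np.ndarray:
        """Distinct stimulus frequencies, ascending (Hz)."""
        return np.unique([t.frequency_hz for t in self.trials])

    @property
    def levels(self) -> np.ndarray:
        """Distinct sound levels, ascending (dB SPL)."""
        return np.unique([t.level_db for t in self.trials])

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray([t.onset_frame for t in self.trials], dtype=np.int64)

    @property
    def end_frame(self) -> int:
        """First frame after the last trial."""
        if not self.trials:
            return 0
        last = self.trials[-1]
        return last.onset_frame + last.duration_frames

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.trials)),
                "frequency_hz": [t.frequency_hz for t in self.trials],
                "level_db": [t.level_db for t in self.trials],
                "onset_frame": [t.onset_frame for t in self.trials],
                "duration_frames": [t.duration_frames for t in self.trials],
            }
        )

    def stimulus_mask(self, n_frames: int) -> np.ndarray:
        """Boolean mask of frames falling inside any stimulus window."""
        mask = np.zeros(n_frames, dtype=bool)
        for t in self.trials:
            mask[t.onset_frame : min(t.onset_frame + t.duration_frames, n_frames)] = True
        return mask


@dataclass
class SpikeProbRaster:
    """Spike-probability estimates lambda, one row per neuron, at a fixed frame rate."""

    lam: np.ndarray  # (n_neurons, n_frames), lambda >= 0
    frame_rate: float

    def __post_init__(self):
        self.lam = np.asarray(self.lam)
        if self.lam.ndim != 2:
            raise ValueError("lam must be a 2-D (neurons x frames) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_neurons(self) -> int:
        return self.lam.shape[0]

    @property
    def n_frames(self) -> int:
        return self.lam.shape[1]

    @property
    def dt(self) -> float:
        """Frame duration in seconds (~33 ms at 30 Hz)."""
        return 1.0 / self.frame_rate

    def threshold(self, lambda_thr: float) -> "BinaryRaster":
        """Binarize: a neuron is active in a frame iff lambda >= lambda_thr."""
        return BinaryRaster(
            active=self.lam >= lambda_thr,
            frame_rate=self.frame_rate,
            lambda_thr=float(lambda_thr),
        )


@dataclass
class BinaryRaster:
    """Thresholded raster; ``active[i, t]`` means neuron i spiked in frame t."""

    active: np.ndarray  # (n_neurons, n_frames) bool
    frame_rate: float
    lambda_thr: float = float("nan")

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.ndim != 2:
            raise ValueError("active must be a 2-D (neurons x frames) array")

    @property
    def n_neurons(self) -> int:
        return self.active.shape[0]

    @property
    def n_frames(self) -> int:
        return self.active.shape[1]

    def population_count(self) -> np.ndarray:
        """Number of active neurons per frame."""
        return self.active.sum(axis=0).astype(np.int64)


@dataclass
class DffTrace:
    """Relative fluorescence (F - F0)/F0 for one neuron."""

    values: np.ndarray
    neuron_id: int
    frame_rate: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FluorescencePair:
    """Raw soma and surrounding-neuropil fluorescence for one neuron."""

    f_soma: np.ndarray
    f_neuropil: np.ndarray
    neuron_id: int

    def __post_init__(self):
        self.f_soma = np.asarray(self.f_soma, dtype=np.float64)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=np.float64)
        if self.f_soma.shape != self.f_neuropil.shape:
            raise AlignmentError("soma and neuropil traces must have equal length")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Parameters sufficient to regenerate a synthetic raster bit-identically."""

    seed: int
    generating_exponent: float | None = None
    branching_parameter: float | None = None
    per_neuron_rate: float | None = None
    bf_assignment: tuple[float, ...] | None = None
    tuning_width: float | None = None
    extra: dict = field(default_factory=dict)


def stack_traces(traces: Sequence[DffTrace]) -> np.ndarray:
    """(n_neurons, n_frames) matrix from a list of equally long dF/F traces."""
    lengths = {len(t) for t in traces}
    if len(lengths) > 1:
        raise AlignmentError("traces have unequal lengths")
    return np.vstack([t.values for t in traces])
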