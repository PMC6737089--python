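"""Neuronal ensembles (avalanches): extraction, shuffle nulls, evoked labels.

An ensemble is a maximal run of contiguous frames each containing at least
one active neuron, bounded by silent frames.  Its size s is the number of
active neuron-frames summed over the run (each neuron counted once per frame
it is active) and its duration (lifetime) is the number of frames spanned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import BinaryRaster, SpikeProbRaster, StimulusProtocol
from .errors import InvalidParameterError, ProtocolError

__all__ = [
    "Ensemble",
    "EnsembleCatalog",
    "extract_ensembles",
    "shuffle_raster",
    "classify_evoked",
    "summarize_by_level",
    "LevelSummary",
]


@dataclass
class Ensemble:
    """One avalanche: frame span, size, duration, membership, evoked label."""

    start_frame: int
    end_frame: int  # inclusive
    size: int
    duration: int
    member_activity: dict[int, int] | None = None
    evoked: bool = False
    stimulus_id: int | None = None
    truncated: bool = False  # clipped by a recording boundary


@dataclass
class EnsembleCatalog:
    """Ordered, non-overlapping ensembles from one raster."""

    ensembles: list[Ensemble]
    n_neurons: int
    n_frames: int
    lambda_thr: float
    frame_rate: float
    shuffled: bool = False
    shuffle_seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ensembles)

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray([e.size for e in self.ensembles], dtype=np.int64)

    @property
    def durations(self) -> np.ndarray:
        return np.asarray([e.duration for e in self.ensembles], dtype=np.int64)

    @property
    def evoked_mask(self) -> np.ndarray:
        return np.asarray([e.evoked for e in self.ensembles], dtype=bool)

    def to_frame(self, protocol: StimulusProtocol | None = None) -> pd.DataFrame:
        level = [
            protocol.trials[e.stimulus_id].level_db
            if (protocol is not None and e.stimulus_id is not None)
            else np.nan
            for e in self.ensembles
        ]
        return pd.DataFrame(
            {
                "ensemble_id": np.arange(len(self.ensembles)),
                "start_frame": [e.start_frame for e in self.ensembles],
                "end_frame": [e.end_frame for e in self.ensembles],
                "size": [e.size for e in self.ensembles],
                "duration": [e.duration for e in self.ensembles],
                "evoked": [e.evoked for e in self.ensembles],
                "stimulus_id": [e.stimulus_id for e in self.ensembles],
                "level_db": level,
            }
        )


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start and end (inclusive) indices of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx, idx
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[brk + 1]))
    ends = np.concatenate((idx[brk], [idx[-1]]))
    return starts, ends


def count_ensembles(popcount: np.ndarray) -> int:
    """Number of maximal nonsilent runs, from the per-frame active count."""
    mask = popcount > 0
    if not mask.any():
        return 0
    return int(mask[0]) + int(np.count_nonzero(np.diff(mask.astype(np.int8)) == 1))


def extract_ensembles(
    raster: BinaryRaster, with_members: bool = True
) -> EnsembleCatalog:
    """Segment a binary raster into avalanches bounded by silent frames.

    ``with_members=False`` skips the per-ensemble neuron->frames-active map
    (cheaper on very large rasters); sizes and durations are unaffected.
    """
    active = raster.active
    n_neurons, n_frames = active.shape
    popcount = active.sum(axis=0, dtype=np.int64)
    starts, ends = _runs(popcount > 0)

    cs = np.concatenate(([0], np.cumsum(popcount)))
    sizes = cs[ends + 1] - cs[starts]
    durations = ends - starts + 1

    members_per_run: list[dict[int, int] | None]
    if with_members and starts.size:
        # reduceat from each run start to the next covers the trailing silent
        # gap too, but silent frames contribute zero, so counts are exact
        counts = np.add.reduceat(active.astype(np.int32), starts, axis=1)
        members_per_run = []
        for j in range(starts.size):
            col = counts[:, j]
            nz = np.flatnonzero(col)
            members_per_run.append({int(i): int(col[i]) for i in nz})
    else:
        members_per_run = [None] * starts.size

    ensembles = [
        Ensemble(
            start_frame=int(s),
            end_frame=int(e),
            size=int(sz),
            duration=int(d),
            member_activity=m,
            truncated=(s == 0 or e == n_frames - 1),
        )
        for s, e, sz, d, m in zip(starts, ends, sizes, durations, members_per_run)
    ]
    return EnsembleCatalog(
        ensembles=ensembles,
        n_neurons=n_neurons,
        n_frames=n_frames,
        lambda_thr=raster.lambda_thr,
        frame_rate=raster.frame_rate,
    )


def shuffle_raster(
    raster: SpikeProbRaster,
    lambda_thr: float,
    n_repeats: int = 10,
    seed: int = 0,
) -> SpikeProbRaster:
    """Per-neuron temporal permutation null, keeping the best of ``n_repeats``.

    Each repeat independently permutes every neuron's lambda values in time
    (exactly preserving per-neuron active-frame counts at any threshold);
    the repeat whose thresholded raster yields the most ensembles is
    returned, matching the shuffle control used for avalanche statistics.
    """
    if n_repeats < 1:
        raise InvalidParameterError("n_repeats must be >= 1")
    lam = raster.lam
    n_neurons, n_frames = lam.shape
    binary = (lam >= lambda_thr).astype(np.uint8)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)

    best_count, best_idx = -1, 0
    for r in range(n_repeats):
        rng = np.random.default_rng(children[r])
        popcount = np.zeros(n_frames, dtype=np.int32)
        for i in range(n_neurons):
            perm = rng.permutation(n_frames)
            popcount += binary[i, perm]
        c = count_ensembles(popcount)
        if c > best_count:
            best_count, best_idx = c, r

    rng = np.random.default_rng(children[best_idx])
    out = np.empty_like(lam)
    for i in range(n_neurons):
        perm = rng.permutation(n_frames)
        out[i] = lam[i, perm]
    return SpikeProbRaster(out, frame_rate=raster.frame_rate)


def classify_evoked(
    catalog: EnsembleCatalog, protocol: StimulusProtocol
) -> EnsembleCatalog:
    """Label ensembles initiated during a stimulus window as evoked.

    An ensemble is evoked iff its start frame lies within some trial's
    [onset, onset + duration) window, even if it continues after stimulus
    offset; it is assigned to that trial.  All others are ongoing.
    """
    onsets = protocol.onsets
    if len(protocol) == 0:
        for e in catalog.ensembles:
            e.evoked, e.stimulus_id = False, None
        return catalog
    # protocol invariants already forbid overlap; re-check against bounds
    for t in protocol.trials:
        if t.onset_frame + t.duration_frames > catalog.n_frames:
            raise ProtocolError("trial extends beyond the raster")
    durs = np.asarray([t.duration_frames for t in protocol.trials])
    for e in catalog.ensembles:
        j = int(np.searchsorted(onsets, e.start_frame, side="right")) - 1
        if j >= 0 and e.start_frame < onsets[j] + durs[j]:
            e.evoked, e.stimulus_id = True, j
        else:
            e.evoked, e.stimulus_id = False, None
    return catalog


@dataclass
class LevelSummary:
    """Mean evoked ensemble size/duration per sound level, with trend stats."""

    table: pd.DataFrame  # columns: level_db, n, mean_size, sd_size, mean_duration, sd_duration
    rho_size: float
    p_size: float
    rho_duration: float
    p_duration: float


def summarize_by_level(
    catalog: EnsembleCatalog, protocol: StimulusProtocol
) -> LevelSummary:
    """Group evoked ensembles by their trial's sound level.

    Reports per-level mean and SD of size and duration plus Spearman rank
    correlations of level against size and duration across evoked ensembles
    (the level-dependence trend).
    """
    rows = []
    levels_of = np.asarray([t.level_db for t in protocol.trials])
    ev = [e for e in catalog.ensembles if e.evoked and e.stimulus_id is not None]
    lv = np.asarray([levels_of[e.stimulus_id] for e in ev])
    sz = np.asarray([e.size for e in ev], dtype=float)
    du = np.asarray([e.duration for e in ev], dtype=float)

    for level in protocol.levels:
        m = lv == level
        n = int(m.sum())
        rows.append(
            {
                "level_db": float(level),
                "n": n,
                "mean_size": float(sz[m].mean()) if n else np.nan,
                "sd_size": float(sz[m].std(ddof=1)) if n > 1 else np.nan,
                "mean_duration": float(du[m].mean()) if n else np.nan,
                "sd_duration": float(du[m].std(ddof=1)) if n > 1 else np.nan,
            }
        )
    def _trend(y):
        if lv.size < 2 or np.unique(lv).size < 2 or np.unique(y).size < 2:
            return np.nan, np.nan
        return spearmanr(lv, y)

    rho_s, p_s = _trend(sz)
    rho_d, p_d = _trend(du)
    return LevelSummary(
        table=pd.DataFrame(rows),
        rho_size=float(rho_s),
        p_size=float(p_s),
        rho_duration=float(rho_d),
        p_duration=float(p_d),
    )
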