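"""Fluorescence trace processing and raster binarization.

dF/F uses a causal sliding sub-median baseline: for each frame, F0 is the
mean of the samples in the preceding 10-s window (300 frames at 30 Hz)
whose value lies strictly below that window's 50th percentile.  Neuropil
contamination is removed by subtracting alpha_np (default 0.9) times the
neuropil dF/F.  Sound-responsive neurons are flagged by one-way ANOVA
(p < 0.01) across pre-stimulus baseline windows and all frequency-level
stimulus conditions.  The spike-probability threshold lambda_thr is chosen
to maximize the number of extracted ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import f_oneway

from .avalanches import count_ensembles
from .containers import BinaryRaster, DffTrace, SpikeProbRaster, StimulusProtocol
from .errors import AlignmentError, DegenerateBaselineError, InvalidParameterError

__all__ = [
    "compute_dff",
    "neuropil_correct",
    "responsive_neurons",
    "optimize_lambda_thr",
    "ThresholdScan",
    "default_threshold_grid",
]


def _window_baseline(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sub-median mean per window row; fallback to the median for flat rows."""
    med = np.median(w, axis=-1)
    below = w < med[..., None]
    cnt = below.sum(axis=-1)
    ssum = np.where(below, w, 0.0).sum(axis=-1)
    return med, cnt, ssum


def compute_dff(
    f: Sequence[float],
    frame_rate: float = 30.0,
    window_s: float = 10.0,
    neuron_id: int = -1,
) -> DffTrace:
    """dF/F with a causal sliding sub-median baseline.

    For each frame t, the baseline F0(t) is the mean of the samples in the
    trailing ``window_s`` window (ending at t) that fall strictly below the
    window's median; if no sample is strictly below (a flat window), F0
    falls back to the window median, which keeps F0 equal to the quiescent
    level for constant or sparsely active traces.  Frames earlier than one
    full window use the partial available history.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 1:
        raise InvalidParameterError("f must be 1-D")
    win = int(round(window_s * frame_rate))
    if win < 1:
        raise InvalidParameterError("window must cover at least one frame")
    if f.size <= win:
        raise InvalidParameterError(
            f"trace length {f.size} must exceed the baseline window ({win} frames)"
        )

    f0 = np.empty_like(f)
    # partial-history head: window = f[0 : t+1]
    head = min(win - 1, f.size)
    for t in range(head):
        w = f[: t + 1]
        med, cnt, ssum = _window_baseline(w[None, :])
        f0[t] = ssum[0] / cnt[0] if cnt[0] else med[0]
    # full windows ending at t = win-1 .. n-1
    windows = sliding_window_view(f, win)  # row i covers [i, i+win-1]
    med, cnt, ssum = _window_baseline(windows)
    full = np.where(cnt > 0, ssum / np.maximum(cnt, 1), med)
    f0[win - 1 :] = full

    if np.any(f0 <= 0):
        raise DegenerateBaselineError("baseline F0 is zero or negative")
    return DffTrace(values=(f - f0) / f0, neuron_id=neuron_id, frame_rate=frame_rate)


def neuropil_correct(
    dff_soma: DffTrace, dff_np: DffTrace, alpha_np: float = 0.9
) -> DffTrace:
    """Subtract alpha_np times the neuropil dF/F from the soma dF/F."""
    if len(dff_soma) != len(dff_np):
        raise AlignmentError("soma and neuropil dF/F must have equal length")
    return DffTrace(
        values=dff_soma.values - alpha_np * dff_np.values,
        neuron_id=dff_soma.neuron_id,
        frame_rate=dff_soma.frame_rate,
    )


def responsive_neurons(
    dff: Sequence[DffTrace],
    protocol: StimulusProtocol,
    p_crit: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Sound-responsive mask by one-way ANOVA across baseline and conditions.

    Groups per neuron: one pooled baseline group (mean dF/F over the
    pre-stimulus window of every trial, window length = that trial's
    stimulus duration) plus one group per frequency-level condition (mean
    dF/F over the stimulus window, one value per repeat).  A neuron is
    responsive iff the ANOVA p-value is below ``p_crit``; degenerate
    (zero-variance) neurons are not responsive.

    Returns (mask, p_values).
    """
    if len(protocol) == 0:
        raise InvalidParameterError("ANOVA needs at least one stimulus trial")
    n_frames = min(len(t) for t in dff)
    for t in protocol.trials:
        if t.onset_frame + t.duration_frames > n_frames:
            raise InvalidParameterError("protocol extends beyond the traces")

    conditions: dict[tuple[float, float], list[tuple[int, int]]] = {}
    baseline_windows: list[tuple[int, int]] = []
    for t in protocol.trials:
        conditions.setdefault((t.frequency_hz, t.level_db), []).append(
            (t.onset_frame, t.onset_frame + t.duration_frames)
        )
        b0 = max(0, t.onset_frame - t.duration_frames)
        if b0 < t.onset_frame:
            baseline_windows.append((b0, t.onset_frame))
    if not conditions or not baseline_windows:
        raise InvalidParameterError("need baseline and stimulus groups")

    mask = np.zeros(len(dff), dtype=bool)
    pvals = np.ones(len(dff))
    for i, trace in enumerate(dff):
        v = trace.values
        groups = [[v[a:b].mean() for a, b in baseline_windows]]
        groups += [[v[a:b].mean() for a, b in wins] for wins in conditions.values()]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, p = f_oneway(*groups)
            except ValueError:
                p = np.nan
        if np.isfinite(p):
            pvals[i] = p
            mask[i] = p < p_crit
    return mask, pvals


@dataclass
class ThresholdScan:
    """Chosen lambda_thr, the resulting raster, and the full count curve."""

    lambda_thr: float
    raster: BinaryRaster
    curve: pd.DataFrame  # columns: threshold, n_ensembles
    degenerate: bool = False  # no candidate produced any ensemble


def default_threshold_grid(raster: SpikeProbRaster, n: int = 40) -> np.ndarray:
    """Candidate thresholds: ``n`` quantiles of the nonzero lambda values."""
    nz = raster.lam[raster.lam > 0]
    if nz.size == 0:
        return np.array([0.5])
    qs = np.linspace(0.0, 1.0, n, endpoint=False) + 1.0 / (2 * n)
    return np.unique(np.quantile(nz.astype(np.float64), qs))


def optimize_lambda_thr(
    raster: SpikeProbRaster,
    candidate_grid: Sequence[float] | None = None,
) -> ThresholdScan:
    """Pick the threshold maximizing the number of extracted ensembles.

    Both too-low thresholds (everything merges into few giant ensembles)
    and too-high thresholds (few spikes survive) reduce the count; the scan
    reports the whole count-vs-threshold curve and, on ties, the smallest
    maximizing threshold (retaining more activity).  A raster yielding zero
    ensembles everywhere returns the lowest candidate, flagged degenerate.
    """
    if candidate_grid is None:
        candidate_grid = default_threshold_grid(raster)
    grid = np.asarray(candidate_grid, dtype=np.float64)
    if grid.size == 0:
        raise InvalidParameterError("candidate_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise InvalidParameterError("candidate_grid must be sorted ascending")

    counts = np.empty(grid.size, dtype=np.int64)
    for k, thr in enumerate(grid):
        popcount = (raster.lam >= thr).sum(axis=0)
        counts[k] = count_ensembles(popcount)

    best = int(np.argmax(counts))  # argmax returns the first (smallest) maximizer
    thr = float(grid[best])
    curve = pd.DataFrame({"threshold": grid, "n_ensembles": counts})
    return ThresholdScan(
        lambda_thr=thr,
        raster=raster.threshold(thr),
        curve=curve,
        degenerate=bool(counts.max() == 0),
    )
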