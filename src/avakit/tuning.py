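"""Single-neuron and ensemble receptive fields.

A receptive field (RF) is the mean dF/F response to each frequency-level
combination over the 1-s stimulus window and all repeats.  Best frequency
(BF) is the RF's center of mass in log2-frequency (negative responses
rectified to zero).  An ensemble RF is the member RFs averaged with weights
equal to how many frames each member was active; IQR_BF is the interquartile
range of member BFs in octaves, and bandwidth is the half-maximum width (in
octaves) of the RF row containing the global peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .avalanches import Ensemble, EnsembleCatalog
from .containers import DffTrace, StimulusProtocol
from .errors import InvalidParameterError, MissingRfError, UndefinedFieldError

__all__ = [
    "ReceptiveField",
    "EnsembleRf",
    "BandwidthResult",
    "compute_rf",
    "best_frequency",
    "ensemble_rf",
    "rf_bandwidth",
    "tuning_vs_scale",
]


@dataclass
class ReceptiveField:
    """levels x frequencies response matrix for one neuron."""

    response: np.ndarray  # (n_levels, n_freqs) mean dF/F
    freq_axis: np.ndarray  # Hz, ascending log-spaced
    level_axis: np.ndarray  # dB, ascending
    neuron_id: int = -1

    def __post_init__(self):
        self.response = np.atleast_2d(np.asarray(self.response, dtype=np.float64))
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.level_axis = np.asarray(self.level_axis, dtype=np.float64)
        if self.response.shape != (self.level_axis.size, self.freq_axis.size):
            raise InvalidParameterError("response must be (n_levels, n_freqs)")

    @property
    def bf(self) -> float:
        return best_frequency(self)

    @property
    def bandwidth(self) -> float:
        return rf_bandwidth(self).octaves


class BandwidthResult(NamedTuple):
    octaves: float
    point_support: bool  # single responsive frequency, no half-max crossing


@dataclass
class EnsembleRf:
    """Activity-weighted compound RF of one ensemble."""

    response: np.ndarray
    freq_axis: np.ndarray
    level_axis: np.ndarray
    weights: dict[int, int]
    member_bfs: np.ndarray  # Hz, one per member
    iqr_bf: float  # octaves
    bandwidth: float  # octaves


def compute_rf(dff: DffTrace, protocol: StimulusProtocol) -> ReceptiveField:
    """Mean dF/F per frequency-level condition over the stimulus window."""
    freqs = protocol.frequencies
    levels = protocol.levels
    if freqs.size == 0:
        raise InvalidParameterError("protocol has no trials")
    n_frames = len(dff)
    acc = np.zeros((levels.size, freqs.size))
    cnt = np.zeros((levels.size, freqs.size), dtype=np.int64)
    li = {l: i for i, l in enumerate(levels)}
    fi = {f: i for i, f in enumerate(freqs)}
    for t in protocol.trials:
        if t.onset_frame + t.duration_frames > n_frames:
            raise InvalidParameterError("trial extends beyond the trace")
        resp = dff.values[t.onset_frame : t.onset_frame + t.duration_frames].mean()
        acc[li[t.level_db], fi[t.frequency_hz]] += resp
        cnt[li[t.level_db], fi[t.frequency_hz]] += 1
    if np.any(cnt == 0):
        raise InvalidParameterError("some frequency-level condition has zero trials")
    return ReceptiveField(
        response=acc / cnt, freq_axis=freqs, level_axis=levels, neuron_id=dff.neuron_id
    )


def best_frequency(rf: ReceptiveField, rectify: bool = True) -> float:
    """Center of mass of the RF in log2-frequency, in Hz.

    Frequency weights are the level-summed responses (rectified to zero by
    default, so suppression does not pull the center of mass); BF =
    2^(sum w_f log2 f / sum w_f).
    """
    r = rf.response.copy()
    if rectify:
        r = np.maximum(r, 0.0)
    w = r.sum(axis=0)
    total = w.sum()
    if total <= 0:
        raise UndefinedFieldError("all-nonpositive RF; BF undefined")
    return float(2.0 ** (np.dot(w, np.log2(rf.freq_axis)) / total))


def rf_bandwidth(
    rf: ReceptiveField | np.ndarray,
    level: float | str = "best",
    freq_axis: np.ndarray | None = None,
    half: float = 0.5,
) -> BandwidthResult:
    """Half-maximum width (octaves) of the RF at one level.

    ``level='best'`` evaluates the level row containing the global RF peak;
    a numeric level selects that row.  Bandwidth is the log2-span of the
    contiguous frequency run around the peak where the response is at least
    ``half`` of the peak, with linear interpolation (in log2-frequency) at
    the crossings.  A single-point responsive RF has no crossing and is
    reported as 0 octaves with ``point_support=True``.
    """
    if isinstance(rf, ReceptiveField):
        resp, faxis, laxis = rf.response, rf.freq_axis, rf.level_axis
    else:
        resp = np.atleast_2d(np.asarray(rf, dtype=np.float64))
        if freq_axis is None:
            raise InvalidParameterError("freq_axis required for a bare matrix")
        faxis = np.asarray(freq_axis, dtype=np.float64)
        laxis = np.arange(resp.shape[0], dtype=np.float64)

    if level == "best":
        if np.all(resp <= 0):
            raise UndefinedFieldError("all-nonpositive RF; bandwidth undefined")
        row = int(np.unravel_index(np.argmax(resp), resp.shape)[0])
    else:
        matches = np.flatnonzero(laxis == float(level))
        if matches.size == 0:
            raise InvalidParameterError(f"level {level} not in RF")
        row = int(matches[0])

    r = resp[row]
    if np.all(r <= 0):
        raise UndefinedFieldError("all-nonpositive RF row; bandwidth undefined")
    logf = np.log2(faxis)
    pk = int(np.argmax(r))
    thr = half * r[pk]

    # walk out from the peak while the response stays at or above threshold
    left = pk
    while left > 0 and r[left - 1] >= thr:
        left -= 1
    right = pk
    while right < r.size - 1 and r[right + 1] >= thr:
        right += 1

    if r.size == 1:
        return BandwidthResult(0.0, True)
    if left == right:
        # single-frequency run: with nonpositive neighbors there is no
        # half-max crossing to interpolate -> point support, 0 octaves
        left_np = left == 0 or r[left - 1] <= 0
        right_np = right == r.size - 1 or r[right + 1] <= 0
        if left_np and right_np:
            return BandwidthResult(0.0, True)

    # interpolated crossings; at matrix edges the span clips to the edge
    if left > 0 and r[left - 1] < thr:
        x0 = np.interp(thr, [r[left - 1], r[left]], [logf[left - 1], logf[left]])
    else:
        x0 = logf[left]
    if right < r.size - 1 and r[right + 1] < thr:
        x1 = np.interp(thr, [r[right + 1], r[right]], [logf[right + 1], logf[right]])
    else:
        x1 = logf[right]

    return BandwidthResult(float(x1 - x0), False)


def ensemble_rf(
    ensemble: Ensemble, rfs: Mapping[int, ReceptiveField]
) -> EnsembleRf:
    """Activity-weighted average of the member RFs, with IQR_BF and bandwidth.

    Weights are frames-active counts; the compound response is their convex
    combination.  IQR_BF is the interquartile range of the member BFs in
    log2 units, each member counted once regardless of weight.
    """
    if not ensemble.member_activity:
        raise MissingRfError("ensemble has no member activity map")
    members = sorted(ensemble.member_activity)
    for m in members:
        if m not in rfs:
            raise MissingRfError(f"neuron {m} has no receptive field")
    ref = rfs[members[0]]
    w = np.asarray([ensemble.member_activity[m] for m in members], dtype=np.float64)
    stack = np.stack([rfs[m].response for m in members])
    response = np.tensordot(w, stack, axes=1) / w.sum()

    bfs = np.asarray([best_frequency(rfs[m]) for m in members])
    log_bfs = np.log2(bfs)
    iqr = float(np.percentile(log_bfs, 75) - np.percentile(log_bfs, 25))

    compound = ReceptiveField(response, ref.freq_axis, ref.level_axis)
    try:
        bw = rf_bandwidth(compound).octaves
    except UndefinedFieldError:
        bw = np.nan
    return EnsembleRf(
        response=response,
        freq_axis=ref.freq_axis,
        level_axis=ref.level_axis,
        weights={m: ensemble.member_activity[m] for m in members},
        member_bfs=bfs,
        iqr_bf=iqr,
        bandwidth=bw,
    )


def tuning_vs_scale(
    catalog: EnsembleCatalog,
    rfs: Mapping[int, ReceptiveField],
    metric: str = "iqr_bf",
    axis: str = "size",
    n_bins: int = 8,
) -> tuple[pd.DataFrame, float, float]:
    """Tuning-diversity metric binned by log-spaced ensemble size or duration.

    Evoked ensembles only.  Returns (table, spearman_rho, spearman_p) where
    the correlation is computed across individual ensembles (metric vs the
    chosen scale axis) and the table gives mean +- SD per log bin.
    """
    if metric not in ("iqr_bf", "bandwidth"):
        raise InvalidParameterError("metric must be 'iqr_bf' or 'bandwidth'")
    if axis not in ("size", "duration"):
        raise InvalidParameterError("axis must be 'size' or 'duration'")

    ev = [e for e in catalog.ensembles if e.evoked]
    xs, ms = [], []
    for e in ev:
        if not e.member_activity:
            continue
        try:
            erf = ensemble_rf(e, rfs)
        except (MissingRfError, UndefinedFieldError):
            continue
        xs.append(e.size if axis == "size" else e.duration)
        ms.append(erf.iqr_bf if metric == "iqr_bf" else erf.bandwidth)
    xs = np.asarray(xs, dtype=np.float64)
    ms = np.asarray(ms, dtype=np.float64)
    if xs.size == 0:
        raise InvalidParameterError("no evoked ensembles with receptive fields")

    edges = np.geomspace(xs.min(), xs.max() * (1 + 1e-12), n_bins + 1)
    rows = []
    for k in range(n_bins):
        m = (xs >= edges[k]) & (xs < edges[k + 1])
        n = int(m.sum())
        rows.append(
            {
                "bin_lo": edges[k],
                "bin_hi": edges[k + 1],
                "n": n,
                "mean": float(ms[m].mean()) if n else np.nan,
                "sd": float(ms[m].std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
            }
        )
    if xs.size > 1 and np.unique(xs).size > 1 and np.unique(ms).size > 1:
        rho, p = spearmanr(xs, ms)
    else:
        rho, p = np.nan, np.nan
    return pd.DataFrame(rows), float(rho), float(p)
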