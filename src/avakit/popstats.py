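"""Per-neuron and pairwise statistics of ongoing and evoked activity.

Firing rate and CV of inter-spike intervals come from the binarized raster
(at most one spike per frame, ISIs in frame multiples of dt = 1/frame_rate);
pairwise correlation is the zero-lag Pearson correlation of the continuous
lambda traces over the whole session.  Two-sample comparisons use the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import BinaryRaster, SpikeProbRaster
from .errors import InvalidParameterError

__all__ = [
    "firing_rate",
    "cv_isi",
    "pairwise_xcorr",
    "compare_groups",
    "CorrMatrix",
    "neuron_stats_table",
]


def firing_rate(
    raster: BinaryRaster, frames_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-neuron spike rate (spikes/s) over the masked frames.

    rate = active frames within the mask / (masked frames / frame_rate).
    """
    active = raster.active
    if frames_mask is None:
        frames_mask = np.ones(raster.n_frames, dtype=bool)
    frames_mask = np.asarray(frames_mask, dtype=bool)
    if frames_mask.size != raster.n_frames:
        raise InvalidParameterError("frames_mask length must equal n_frames")
    n = int(frames_mask.sum())
    if n == 0:
        raise InvalidParameterError("frames_mask selects no frames")
    return active[:, frames_mask].sum(axis=1) * raster.frame_rate / n


def cv_isi(raster: BinaryRaster, min_spikes: int = 3) -> np.ndarray:
    """Coefficient of variation of inter-spike intervals, per neuron.

    ISIs are differences of consecutive active-frame indices times dt.
    Neurons with fewer than ``min_spikes`` spikes get NaN (CV undefined);
    CV is 0 for perfectly periodic and ~1 for Poisson-like spiking.
    """
    dt = 1.0 / raster.frame_rate
    out = np.full(raster.n_neurons, np.nan)
    for i in range(raster.n_neurons):
        t = np.flatnonzero(raster.active[i])
        if t.size < min_spikes:
            continue
        isi = np.diff(t) * dt
        m = isi.mean()
        out[i] = isi.std() / m if m > 0 else np.nan
    return out


@dataclass
class CorrMatrix:
    """Zero-lag Pearson correlations between lambda traces."""

    values: np.ndarray  # symmetric, unit diagonal
    neuron_ids: np.ndarray  # rows kept (non-constant lambda)
    excluded: np.ndarray  # constant-lambda neurons, flagged out

    def offdiag(self) -> np.ndarray:
        """Upper-triangle correlation values (each pair once)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def pairwise_xcorr(raster: SpikeProbRaster) -> CorrMatrix:
    """Zero-lag pairwise correlation of lambda traces across the session.

    Constant (zero-variance) neurons are excluded and reported in
    ``excluded``; at least two variable neurons are required.
    """
    lam = np.asarray(raster.lam, dtype=np.float64)
    sd = lam.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    excl = np.flatnonzero(sd == 0)
    if keep.size < 2:
        raise InvalidParameterError("need >= 2 neurons with non-constant lambda")
    c = np.corrcoef(lam[keep])
    np.fill_diagonal(c, 1.0)
    return CorrMatrix(values=c, neuron_ids=keep, excluded=excl)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (two-sided).

    Uses the normal approximation with tie correction; identical constant
    samples degenerate to (0, 1).  Returns (standardized statistic, p).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    # standardized rank-sum statistic (z-score) for reporting
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    ranks = pd.Series(pooled).rank().to_numpy()
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / ((n1 + n2) * (n1 + n2 - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term))
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return float(z), float(res.pvalue)


def neuron_stats_table(
    raster: BinaryRaster,
    frames_mask: np.ndarray | None = None,
    condition: str = "ongoing",
) -> pd.DataFrame:
    """Per-neuron rate and CV_ISI table (columns: neuron_id, rate_hz, cv_isi, condition)."""
    rates = firing_rate(raster, frames_mask)
    if frames_mask is not None:
        sub = BinaryRaster(
            raster.active[:, np.asarray(frames_mask, dtype=bool)],
            frame_rate=raster.frame_rate,
            lambda_thr=raster.lambda_thr,
        )
    else:
        sub = raster
    cvs = cv_isi(sub)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(raster.n_neurons),
            "rate_hz": rates,
            "cv_isi": cvs,
            "condition": condition,
        }
    )
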