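"""Synthetic rasters, fluorescence traces and stimulus protocols.

The study conditions these generators emulate: fields of view of ~100-250
neurons imaged at 30 Hz, ongoing firing near 1.8 spikes/s with irregular
(CV_ISI between 1 and 2) spiking, avalanche-structured population
correlations (power-law size and duration statistics), and 1-s tone trials
at 9 frequencies (3-48 kHz, 2 tones/octave) x 3 sound levels
(40/60/80 dB SPL) x 5 repeats with 4-6 s inter-stimulus intervals.

Every generator takes an explicit integer seed and is bit-reproducible;
no global random state is touched.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .containers import (
    FluorescencePair,
    SpikeProbRaster,
    StimulusProtocol,
    SyntheticGroundTruth,
    Trial,
)
from .errors import InvalidParameterError, NormalizationError

__all__ = [
    "make_stimulus_protocol",
    "simulate_branching_raster",
    "sample_powerlaw_ensembles",
    "render_raster_from_ensembles",
    "synth_tuned_population",
    "synth_fluorescence",
    "bernoulli_raster",
    "synth_session",
]


def make_stimulus_protocol(
    freq_lo: float = 3000.0,
    freq_hi: float = 48000.0,
    tones_per_octave: int = 2,
    levels: Sequence[float] = (40.0, 60.0, 80.0),
    reps: int = 5,
    stim_dur: float = 1.0,
    isi_range: tuple[float, float] = (4.0, 6.0),
    frame_rate: float = 30.0,
    seed: int = 0,
) -> StimulusProtocol:
    """Randomized tone protocol: log-spaced frequencies x levels x repeats.

    Frequencies are spaced at ``tones_per_octave`` per octave from
    ``freq_lo`` to ``freq_hi`` inclusive; the trial order is a seeded random
    permutation of all (frequency, level) x reps combinations, and the gap
    before every trial is drawn uniformly from ``isi_range`` seconds.

    With the 2-photon design (3-48 kHz, 2 tones/octave, 3 levels, 5 reps)
    this yields 9 frequencies and 135 trials; the wide-field design
    (1 tone/octave) yields 5 frequencies and 75 trials.
    """
    if freq_lo <= 0 or freq_hi <= 0:
        raise InvalidParameterError("frequencies must be positive")
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    if tones_per_octave < 1:
        raise InvalidParameterError("tones_per_octave must be >= 1")
    if isi_range[0] < 0 or isi_range[1] < isi_range[0]:
        raise InvalidParameterError("isi_range must be 0 <= lo <= hi")

    n_octaves = math.log2(freq_hi / freq_lo)
    n_steps = n_octaves * tones_per_octave
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError(
            "freq_hi/freq_lo must be a power of 2^(1/tones_per_octave)"
        )
    n_steps = round(n_steps)
    freqs = freq_lo * 2.0 ** (np.arange(n_steps + 1) / tones_per_octave)

    conditions = [(f, l) for f in freqs for l in levels for _ in range(reps)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))

    dur_frames = max(1, round(stim_dur * frame_rate))
    trials = []
    frame = 0
    for idx in order:
        f, l = conditions[idx]
        isi = rng.uniform(*isi_range)
        frame += max(1, round(isi * frame_rate))
        trials.append(Trial(float(f), float(l), int(frame), int(dur_frames)))
        frame += dur_frames
    return StimulusProtocol(tuple(trials), frame_rate=frame_rate, isi_range=tuple(isi_range))


def simulate_branching_raster(
    n_neurons: int,
    n_frames: int,
    branching_param: float = 1.0,
    drive_rate: float = 0.02,
    seed: int = 0,
    frame_rate: float = 30.0,
    jitter: bool = False,
) -> SpikeProbRaster:
    """Critical branching-process raster with avalanche-structured activity.

    External drive events arrive as Poisson(``drive_rate``) per frame, each
    activating one uniformly chosen neuron.  Every neuron active in frame t
    activates Poisson(``branching_param``) uniformly chosen neurons in frame
    t+1 (coincident activations collapse to one spike).  At
    ``branching_param`` = 1 the cascade is critical and avalanche sizes and
    durations are power-law distributed up to the system-size cutoff.

    The default drive (0.02 events/frame) keeps active and silent epochs
    roughly balanced for a few hundred neurons at criticality, so avalanches
    stay separated by silent frames rather than merging into one run.

    Output lambda is 1 at spikes and 0 elsewhere (uint8); with
    ``jitter=True`` spikes get values in (0.5, 1] and silent frames values
    in [0, 0.5), for threshold-search tests.
    """
    if branching_param < 0:
        raise InvalidParameterError("branching_param must be >= 0")
    if drive_rate < 0:
        raise InvalidParameterError("drive_rate must be >= 0")
    if n_neurons < 1 or n_frames < 1:
        raise InvalidParameterError("n_neurons and n_frames must be >= 1")

    rng = np.random.default_rng(seed)
    lam = np.zeros((n_neurons, n_frames), dtype=np.uint8)
    active = np.empty(0, dtype=np.int64)
    for t in range(n_frames):
        n_off = int(rng.poisson(branching_param * active.size)) if active.size else 0
        n_drive = int(rng.poisson(drive_rate))
        k = n_off + n_drive
        if k:
            targets = np.unique(rng.integers(0, n_neurons, size=k))
            lam[targets, t] = 1
            active = targets
        else:
            active = np.empty(0, dtype=np.int64)

    if jitter:
        noise = rng.random(lam.shape)
        out = np.where(lam == 1, 0.5 + 0.5 * noise, 0.5 * noise).astype(np.float32)
        return SpikeProbRaster(out, frame_rate=frame_rate)
    return SpikeProbRaster(lam, frame_rate=frame_rate)


def powerlaw_pmf(alpha: float, s_min: int, s_max: int) -> np.ndarray:
    """Exact normalized P(s) proportional to s^alpha on integers [s_min, s_max]."""
    support = np.arange(s_min, s_max + 1, dtype=np.float64)
    w = support**alpha
    return w / w.sum()


def sample_powerlaw_ensembles(
    alpha: float,
    n: int,
    s_min: int = 1,
    s_max: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. draws from the truncated discrete power law P(s) ~ s^alpha.

    Uses inverse-CDF sampling on the exactly normalized mass function, so the
    sample distribution is exact up to floating-point cumsum error.  ``alpha``
    is the (negative) slope, e.g. -2.23.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if s_min < 1:
        raise InvalidParameterError("s_min must be >= 1")
    if s_max is None or not np.isfinite(s_max):
        if alpha >= -1:
            raise NormalizationError(
                "P(s) ~ s^alpha with alpha >= -1 is not normalizable on unbounded support"
            )
        raise InvalidParameterError("pass a finite s_max (truncated sampler)")
    if s_max < s_min:
        raise InvalidParameterError("s_max must be >= s_min")

    pmf = powerlaw_pmf(alpha, s_min, s_max)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return (s_min + np.searchsorted(cdf, u, side="left")).astype(np.int64)


def render_raster_from_ensembles(
    sizes: Sequence[int],
    durations: Sequence[int],
    n_neurons: int,
    seed: int = 0,
    frame_rate: float = 30.0,
) -> SpikeProbRaster:
    """Realize (size, duration) pairs as avalanche blocks separated by silence.

    Each pair becomes a contiguous block of ``duration`` frames, every frame
    containing at least one active neuron and the block totalling ``size``
    active neuron-frames; consecutive blocks are separated by one silent
    frame.  Ensemble extraction on the output recovers the input multiset of
    (size, duration) pairs exactly.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    durations = np.asarray(durations, dtype=np.int64)
    if sizes.shape != durations.shape:
        raise InvalidParameterError("sizes and durations must have equal length")
    if np.any(durations < 1):
        raise InvalidParameterError("durations must be >= 1")
    if np.any(sizes < durations) or np.any(sizes > durations * n_neurons):
        raise InvalidParameterError(
            "need duration <= size <= duration * n_neurons for every ensemble"
        )

    rng = np.random.default_rng(seed)
    n_frames = int(durations.sum() + len(sizes) + 1)
    lam = np.zeros((n_neurons, n_frames), dtype=np.uint8)
    t = 1
    for s, d in zip(sizes, durations):
        extra = int(s - d)
        if extra and d:
            # distribute the surplus over frames without exceeding capacity
            per_frame = rng.multivariate_hypergeometric([n_neurons - 1] * int(d), extra)
        else:
            per_frame = np.zeros(int(d), dtype=np.int64)
        for j in range(int(d)):
            k = 1 + int(per_frame[j])
            neurons = rng.choice(n_neurons, size=k, replace=False)
            lam[neurons, t + j] = 1
        t += int(d) + 1
    return SpikeProbRaster(lam, frame_rate=frame_rate)


def synth_tuned_population(
    n_neurons: int,
    protocol: StimulusProtocol,
    rate_ongoing: float = 1.8,
    tuning_width: float = 0.5,
    gain_per_level: Sequence[float] = (4.0, 8.0, 16.0),
    n_frames: int | None = None,
    seed: int = 0,
) -> tuple[SpikeProbRaster, SyntheticGroundTruth]:
    """Bernoulli-spiking population with Gaussian log-frequency tuning.

    Each neuron draws a best frequency log-uniformly over the protocol's
    frequency range and fires at ``rate_ongoing`` spikes/s plus, during
    stimulus frames, an evoked rate ``gain * exp(-(log2 f - log2 BF)^2 /
    (2 w^2))`` whose gain (spikes/s) depends on the trial's sound level.
    """
    levels = protocol.levels
    gain_per_level = np.asarray(gain_per_level, dtype=np.float64)
    if len(protocol) and gain_per_level.size != levels.size:
        raise InvalidParameterError("gain_per_level must have one entry per sound level")
    if rate_ongoing < 0:
        raise InvalidParameterError("rate_ongoing must be >= 0")

    fr = protocol.frame_rate
    if n_frames is None:
        n_frames = protocol.end_frame + round(5 * fr)
    rng = np.random.default_rng(seed)

    if len(protocol):
        lo, hi = protocol.frequencies.min(), protocol.frequencies.max()
    else:
        lo = hi = 8000.0
    bfs = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi), size=n_neurons)

    p = np.full((n_neurons, n_frames), min(1.0, rate_ongoing / fr), dtype=np.float64)
    level_index = {l: i for i, l in enumerate(levels)}
    log_bfs = np.log2(bfs)
    for trial in protocol.trials:
        g = gain_per_level[level_index[trial.level_db]]
        d = log_bfs - math.log2(trial.frequency_hz)
        if tuning_width > 0:
            evoked = g * np.exp(-(d**2) / (2.0 * tuning_width**2))
        else:
            evoked = g * (np.abs(d) < 1e-12).astype(np.float64)
        sl = slice(trial.onset_frame, min(trial.onset_frame + trial.duration_frames, n_frames))
        p[:, sl] = np.minimum(1.0, rate_ongoing / fr + evoked[:, None] / fr)

    lam = (rng.random(p.shape) < p).astype(np.uint8)
    truth = SyntheticGroundTruth(
        seed=seed,
        per_neuron_rate=rate_ongoing,
        bf_assignment=tuple(float(b) for b in bfs),
        tuning_width=tuning_width,
        extra={"gain_per_level": tuple(float(g) for g in gain_per_level)},
    )
    return SpikeProbRaster(lam, frame_rate=fr), truth


def bernoulli_raster(
    n_neurons: int,
    n_frames: int,
    rate_hz: float = 1.8,
    frame_rate: float = 30.0,
    seed: int = 0,
) -> SpikeProbRaster:
    """Independent Bernoulli-per-frame spiking at a fixed rate (spikes/s)."""
    if rate_hz < 0:
        raise InvalidParameterError("rate_hz must be >= 0")
    p = min(1.0, rate_hz / frame_rate)
    rng = np.random.default_rng(seed)
    lam = (rng.random((n_neurons, n_frames)) < p).astype(np.uint8)
    return SpikeProbRaster(lam, frame_rate=frame_rate)


def synth_fluorescence(
    raster: SpikeProbRaster,
    kernel_tau: float = 0.7,
    np_contamination: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
    spike_amplitude: float = 0.25,
    kernel_cut: float = 5.0,
) -> list[FluorescencePair]:
    """Raw soma + neuropil fluorescence from a spike raster.

    The calcium transient is an exponential kernel of decay ``kernel_tau``
    seconds (truncated at ``kernel_cut`` time constants so traces return
    exactly to baseline), scaled to ``spike_amplitude`` dF/F per spike.  The
    neuropil signal is the population-pooled transient train; the soma trace
    is contaminated by ``np_contamination`` times the neuropil dF/F:

        f_soma = B * (1 + a * (kernel (*) spikes) + c * dff_np) + noise

    so that subtracting ``np_contamination`` x dF/F_neuropil from the soma
    dF/F recovers the contamination-free trace.
    """
    if not 0 <= np_contamination < 1:
        raise InvalidParameterError("np_contamination must be in [0, 1)")
    if kernel_tau <= 0:
        raise InvalidParameterError("kernel_tau must be positive")

    fr = raster.frame_rate
    spikes = np.asarray(raster.lam, dtype=np.float64)
    n_kernel = max(2, int(round(kernel_cut * kernel_tau * fr)))
    kernel = np.exp(-np.arange(n_kernel) / (kernel_tau * fr))

    conv = fftconvolve(spikes, kernel[None, :], axes=1)[:, : raster.n_frames]
    pooled = conv.mean(axis=0)
    dff_np = pooled / max(pooled.max(), 1e-12) * spike_amplitude if pooled.any() else pooled

    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(raster.n_neurons):
        soma = baseline * (1.0 + spike_amplitude * conv[i] + np_contamination * dff_np)
        npil = baseline * (1.0 + dff_np)
        if noise_sd > 0:
            soma = soma + rng.normal(0.0, noise_sd, soma.size)
            npil = npil + rng.normal(0.0, noise_sd, npil.size)
        pairs.append(FluorescencePair(f_soma=soma, f_neuropil=npil, neuron_id=i))
    return pairs


def synth_session(
    protocol: StimulusProtocol,
    n_neurons: int = 150,
    branching_param: float = 1.0,
    drive_rate: float = 0.02,
    rate_ongoing: float = 0.0,
    tuning_width: float = 0.5,
    evoked_drive_per_level: Sequence[float] = (0.05, 0.1, 0.2),
    seed: int = 0,
) -> tuple[SpikeProbRaster, SyntheticGroundTruth]:
    """Full synthetic session: a critical cascade driven harder during tones.

    One branching process runs for the whole session.  Background drive
    (``drive_rate`` events/frame, uniform targets) produces ongoing
    avalanches; during each 1-s tone, additional drive events arrive at
    ``evoked_drive_per_level[level]`` events/frame and target neurons with
    probability proportional to a Gaussian tuning kernel in log2-frequency
    around each neuron's best frequency (drawn log-uniformly over the
    protocol's range).  Because tones act through the same critical cascade,
    evoked ensembles keep heavy-tailed size/duration statistics while their
    mean size and duration grow with sound level, and stimulus-frequency
    selectivity is imprinted on which neurons the evoked avalanches recruit.

    ``rate_ongoing`` adds uniform Bernoulli background spiking (spikes/s per
    neuron) on top of the cascade; it is 0 by default because independent
    background spikes dilute the avalanche structure.
    """
    if branching_param < 0 or drive_rate < 0:
        raise InvalidParameterError("branching_param and drive_rate must be >= 0")
    levels = protocol.levels
    evoked_drive = np.asarray(evoked_drive_per_level, dtype=np.float64)
    if len(protocol) and evoked_drive.size != levels.size:
        raise InvalidParameterError("evoked_drive_per_level must have one entry per level")

    fr = protocol.frame_rate
    n_frames = protocol.end_frame + round(5 * fr)
    rng = np.random.default_rng(seed)

    if len(protocol):
        lo, hi = protocol.frequencies.min(), protocol.frequencies.max()
    else:
        lo = hi = 8000.0
    bfs = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi), size=n_neurons)
    log_bfs = np.log2(bfs)

    # per-trial evoked drive rate and tuned target weights
    level_index = {l: i for i, l in enumerate(levels)}
    trial_rate = np.zeros(n_frames)
    trial_of_frame = np.full(n_frames, -1, dtype=np.int64)
    weights = []
    for j, tr in enumerate(protocol.trials):
        d = log_bfs - math.log2(tr.frequency_hz)
        if tuning_width > 0:
            w = np.exp(-(d**2) / (2.0 * tuning_width**2))
        else:
            w = (np.abs(d) < 1e-12).astype(np.float64)
        w = w / w.sum() if w.sum() > 0 else np.full(n_neurons, 1.0 / n_neurons)
        weights.append(w)
        sl = slice(tr.onset_frame, min(tr.onset_frame + tr.duration_frames, n_frames))
        trial_rate[sl] = evoked_drive[level_index[tr.level_db]]
        trial_of_frame[sl] = j

    lam = np.zeros((n_neurons, n_frames), dtype=np.uint8)
    active = np.empty(0, dtype=np.int64)
    for t in range(n_frames):
        targets = []
        n_off = int(rng.poisson(branching_param * active.size)) if active.size else 0
        n_bg = int(rng.poisson(drive_rate))
        if n_off + n_bg:
            targets.append(rng.integers(0, n_neurons, size=n_off + n_bg))
        if trial_rate[t] > 0:
            n_ev = int(rng.poisson(trial_rate[t]))
            if n_ev:
                targets.append(
                    rng.choice(n_neurons, size=n_ev, p=weights[trial_of_frame[t]])
                )
        if targets:
            idx = np.unique(np.concatenate(targets))
            lam[idx, t] = 1
            active = idx
        else:
            active = np.empty(0, dtype=np.int64)

    if rate_ongoing > 0:
        extra = rng.random((n_neurons, n_frames)) < min(1.0, rate_ongoing / fr)
        lam = np.maximum(lam, extra.astype(np.uint8))

    truth = SyntheticGroundTruth(
        seed=seed,
        branching_parameter=branching_param,
        per_neuron_rate=rate_ongoing,
        bf_assignment=tuple(float(b) for b in bfs),
        tuning_width=tuning_width,
        extra={
            "drive_rate": drive_rate,
            "evoked_drive_per_level": tuple(float(g) for g in evoked_drive),
        },
    )
    return SpikeProbRaster(lam, frame_rate=fr), truth
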