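"""Generators: protocol arithmetic, samplers, rasters, fluorescence."""

import numpy as np
import pytest
from scipy import stats

import avakit as ak
from avakit.errors import InvalidParameterError, NormalizationError
from avakit.synthetic import powerlaw_pmf


class TestStimulusProtocol:
    @pytest.mark.parametrize(
        "tpo,n_freqs,n_trials",
        [(2, 9, 135), (1, 5, 75)],  # 2-photon and wide-field designs
    )
    def test_design_counts(self, tpo, n_freqs, n_trials):
        p = ak.make_stimulus_protocol(tones_per_octave=tpo, seed=0)
        assert p.frequencies.size == n_freqs
        assert len(p) == n_trials

    def test_degenerate_single_trial(self):
        p = ak.make_stimulus_protocol(
            freq_lo=8000, freq_hi=8000, tones_per_octave=1, levels=[60.0],
            reps=1, seed=0,
        )
        assert len(p) == 1

    def test_frequencies_log_spaced_inclusive(self):
        p = ak.make_stimulus_protocol(seed=3)
        f = p.frequencies
        assert f[0] == pytest.approx(3000.0) and f[-1] == pytest.approx(48000.0)
        np.testing.assert_allclose(np.diff(np.log2(f)), 0.5, atol=1e-12)

    def test_trial_order_is_seeded_permutation(self):
        p1 = ak.make_stimulus_protocol(seed=5)
        p2 = ak.make_stimulus_protocol(seed=5)
        p3 = ak.make_stimulus_protocol(seed=6)
        key = lambda p: [(t.frequency_hz, t.level_db) for t in p.trials]
        assert key(p1) == key(p2)
        assert key(p1) != key(p3)
        assert sorted(key(p1)) == sorted(key(p3))  # same multiset of conditions

    def test_isis_within_range(self):
        p = ak.make_stimulus_protocol(isi_range=(4.0, 6.0), seed=1)
        onsets = p.onsets
        gaps = np.diff(onsets) - 30  # stimulus lasts 30 frames
        assert gaps.min() >= 4.0 * 30 - 1 and gaps.max() <= 6.0 * 30 + 1

    @pytest.mark.parametrize(
        "kw", [{"freq_lo": -3000}, {"reps": 0}, {"freq_hi": 50000}]
    )
    def test_invalid_parameters(self, kw):
        with pytest.raises(InvalidParameterError):
            ak.make_stimulus_protocol(**kw, seed=0)


class TestPowerlawSampler:
    def test_extreme_slope_collapses_to_smin(self):
        s = ak.sample_powerlaw_ensembles(-50.0, 1000, s_min=1, s_max=100, seed=0)
        assert np.all(s == 1)

    def test_degenerate_support(self):
        s = ak.sample_powerlaw_ensembles(-2.0, 500, s_min=7, s_max=7, seed=0)
        assert np.all(s == 7)

    def test_p1_matches_exact_normalization(self):
        # P(1) = 1 / sum_{s=1..100} s^-2, within 3 binomial SDs at n = 1e5
        n = 100_000
        s = ak.sample_powerlaw_ensembles(-2.0, n, s_min=1, s_max=100, seed=11)
        p1 = 1.0 / np.sum(np.arange(1, 101.0) ** -2.0)
        obs = np.mean(s == 1)
        sd = np.sqrt(p1 * (1 - p1) / n)
        assert abs(obs - p1) < 3 * sd

    @pytest.mark.parametrize("seed", range(10))
    def test_chisquare_goodness_of_fit(self, seed):
        # empirical PMF converges to the exact normalized PMF
        n = 100_000
        alpha, s_max = -2.23, 1000
        s = ak.sample_powerlaw_ensembles(alpha, n, 1, s_max, seed=seed)
        pmf = powerlaw_pmf(alpha, 1, s_max)
        expected = n * pmf
        # pool the tail so every expected count is >= 5
        cut = np.searchsorted(np.cumsum(expected[::-1]), 5.0)
        k = s_max - cut
        obs = np.bincount(s, minlength=s_max + 1)[1:]
        obs_pooled = np.concatenate([obs[:k], [obs[k:].sum()]])
        exp_pooled = np.concatenate([expected[:k], [expected[k:].sum()]])
        _, p = stats.chisquare(obs_pooled, exp_pooled)
        assert p > 0.01

    def test_unbounded_support_errors(self):
        with pytest.raises(NormalizationError):
            ak.sample_powerlaw_ensembles(-0.5, 10, s_min=1, s_max=None, seed=0)
        with pytest.raises(InvalidParameterError):
            ak.sample_powerlaw_ensembles(-2.0, 10, s_min=1, s_max=None, seed=0)


class TestBranchingRaster:
    def test_no_drive_no_activity(self):
        r = ak.simulate_branching_raster(20, 500, 1.0, drive_rate=0.0, seed=0)
        assert r.lam.sum() == 0

    def test_zero_branching_gives_unit_durations(self):
        # drive sparse enough that no two independent drive events abut for
        # this seed, so any duration > 1 could only come from propagation
        r = ak.simulate_branching_raster(50, 5000, 0.0, drive_rate=0.005, seed=1)
        cat = ak.extract_ensembles(r.threshold(0.5))
        assert len(cat) > 0
        assert np.all(cat.durations == 1)

    def test_jitter_mode_preserves_spikes_at_half_threshold(self):
        r0 = ak.simulate_branching_raster(30, 2000, 1.0, 0.05, seed=9)
        r1 = ak.simulate_branching_raster(30, 2000, 1.0, 0.05, seed=9, jitter=True)
        np.testing.assert_array_equal(r0.lam == 1, r1.lam >= 0.5)


class TestRenderRaster:
    def test_single_neuron_frame(self):
        r = ak.render_raster_from_ensembles([1], [1], n_neurons=3, seed=0)
        assert r.lam.sum() == 1

    def test_forced_full_block(self):
        # size 6 over 2 frames with 3 neurons forces all neurons active twice
        r = ak.render_raster_from_ensembles([6], [2], n_neurons=3, seed=0)
        cat = ak.extract_ensembles(r.threshold(0.5))
        assert len(cat) == 1
        assert cat.ensembles[0].size == 6 and cat.ensembles[0].duration == 2
        assert r.lam.sum() == 6

    def test_roundtrip_recovers_multiset(self):
        rng = np.random.default_rng(4)
        sizes = ak.sample_powerlaw_ensembles(-2.0, 1000, 1, 200, seed=5)
        durations = np.minimum(sizes, 1 + rng.integers(0, 10, sizes.size))
        r = ak.render_raster_from_ensembles(sizes, durations, n_neurons=40, seed=6)
        cat = ak.extract_ensembles(r.threshold(0.5))
        got = sorted(zip(cat.sizes.tolist(), cat.durations.tolist()))
        want = sorted(zip(sizes.tolist(), durations.tolist()))
        assert got == want

    def test_infeasible_raises(self):
        with pytest.raises(InvalidParameterError):
            ak.render_raster_from_ensembles([10], [2], n_neurons=3, seed=0)
        with pytest.raises(InvalidParameterError):
            ak.render_raster_from_ensembles([1], [2], n_neurons=3, seed=0)


class TestTunedPopulation:
    def test_zero_gain_means_no_stimulus_signal(self, protocol_small):
        raster, _ = ak.synth_tuned_population(
            40, protocol_small, rate_ongoing=1.8, gain_per_level=[0.0, 0.0, 0.0],
            seed=0,
        )
        stim = protocol_small.stimulus_mask(raster.n_frames)
        p_stim = raster.lam[:, stim].mean()
        p_rest = raster.lam[:, ~stim].mean()
        n = raster.n_neurons * stim.sum()
        sd = np.sqrt(p_rest * (1 - p_rest) / n)
        assert abs(p_stim - p_rest) < 3 * sd

    def test_delta_tuning_only_hits_exact_bf(self, protocol_small):
        raster, truth = ak.synth_tuned_population(
            30, protocol_small, rate_ongoing=0.0, tuning_width=0.0,
            gain_per_level=[300.0, 300.0, 300.0], seed=1,
        )
        # BFs are drawn continuously, so no neuron matches a stimulus exactly
        assert raster.lam.sum() == 0

    def test_bf_recovery_from_high_gain_simulation(self, protocol_2p):
        raster, truth = ak.synth_tuned_population(
            60, protocol_2p, rate_ongoing=0.0, tuning_width=0.3,
            gain_per_level=[200.0, 200.0, 200.0], seed=2,
        )
        hits = 0
        for i in range(raster.n_neurons):
            trace = ak.DffTrace(raster.lam[i].astype(float), i, raster.frame_rate)
            rf = ak.compute_rf(trace, protocol_2p)
            bf = ak.best_frequency(rf)
            # within one frequency step (0.5 octave) of the assigned BF
            if abs(np.log2(bf) - np.log2(truth.bf_assignment[i])) <= 0.5:
                hits += 1
        assert hits / raster.n_neurons >= 0.95

    def test_rate_calibration(self):
        raster = ak.bernoulli_raster(100, 10_000, rate_hz=1.8, seed=3)
        rates = ak.firing_rate(raster.threshold(0.5))
        p = 1.8 / 30.0
        se = 30.0 * np.sqrt(p * (1 - p) / 10_000) / np.sqrt(100)
        assert abs(rates.mean() - 1.8) < 3 * se


class TestFluorescence:
    def test_empty_raster_constant_trace_zero_dff(self):
        raster = ak.SpikeProbRaster(np.zeros((2, 600), dtype=np.uint8), 30.0)
        pairs = ak.synth_fluorescence(raster, noise_sd=0.0, seed=0)
        soma = pairs[0].f_soma
        assert np.ptp(soma) == 0
        dff = ak.compute_dff(soma, frame_rate=30.0)
        np.testing.assert_allclose(dff.values, 0.0, atol=1e-12)

    def test_single_spike_exponential_transient(self):
        lam = np.zeros((1, 900), dtype=np.uint8)
        lam[0, 400] = 1
        raster = ak.SpikeProbRaster(lam, 30.0)
        pairs = ak.synth_fluorescence(raster, kernel_tau=0.7, noise_sd=0.0, seed=0)
        soma = pairs[0].f_soma
        base = soma[0]
        peak = soma[400] - base
        assert peak > 0
        # one frame later the transient has decayed by exp(-dt/tau)
        assert (soma[401] - base) / peak == pytest.approx(np.exp(-1 / (0.7 * 30)), rel=1e-9)
        assert np.all(soma[:400] == base)

    def test_neuropil_decontamination_recovers_clean_dff(self):
        # activity sparse enough that every 10-s baseline window is majority
        # quiescent, so F0 recovers the true baseline exactly and correction
        # with alpha matched to the contamination is an exact inverse
        rng = np.random.default_rng(8)
        lam = (rng.random((5, 1500)) < 0.002).astype(np.uint8)
        raster = ak.SpikeProbRaster(lam, 30.0)
        c = 0.5
        dirty = ak.synth_fluorescence(raster, kernel_tau=0.2, np_contamination=c,
                                      noise_sd=0.0, seed=1)
        clean = ak.synth_fluorescence(raster, kernel_tau=0.2, np_contamination=0.0,
                                      noise_sd=0.0, seed=1)
        i = 3
        d_soma = ak.compute_dff(dirty[i].f_soma, 30.0)
        d_np = ak.compute_dff(dirty[i].f_neuropil, 30.0)
        corrected = ak.neuropil_correct(d_soma, d_np, alpha_np=c)
        reference = ak.compute_dff(clean[i].f_soma, 30.0)
        np.testing.assert_allclose(corrected.values, reference.values, atol=1e-9)


class TestSeedDeterminism:
    @pytest.mark.parametrize(
        "factory",
        [
            lambda s: ak.make_stimulus_protocol(seed=s).to_frame().to_numpy(),
            lambda s: ak.simulate_branching_raster(20, 2000, 1.0, 0.05, seed=s).lam,
            lambda s: ak.sample_powerlaw_ensembles(-2.0, 5000, 1, 100, seed=s),
            lambda s: ak.render_raster_from_ensembles([5, 3], [2, 1], 10, seed=s).lam,
            lambda s: ak.bernoulli_raster(10, 2000, seed=s).lam,
        ],
        ids=["protocol", "branching", "sampler", "render", "bernoulli"],
    )
    def test_bit_identical_for_same_seed(self, factory):
        a, b, c = factory(123), factory(123), factory(124)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_session_generator_deterministic(self, protocol_small):
        r1, t1 = ak.synth_session(protocol_small, n_neurons=30, seed=9)
        r2, t2 = ak.synth_session(protocol_small, n_neurons=30, seed=9)
        np.testing.assert_array_equal(r1.lam, r2.lam)
        assert t1.bf_assignment == t2.bf_assignment
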