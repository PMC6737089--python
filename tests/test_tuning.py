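"""Receptive fields, best frequency, ensemble tuning metrics."""

import numpy as np
import pytest

import avakit as ak
from avakit.avalanches import Ensemble
from avakit.errors import MissingRfError, UndefinedFieldError
from avakit.tuning import ReceptiveField


def make_rf(matrix, freqs=None, levels=None, neuron_id=0):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if freqs is None:
        freqs = 3000.0 * 2.0 ** (np.arange(matrix.shape[1]) / 2)
    if levels is None:
        levels = np.array([40.0, 60.0, 80.0][: matrix.shape[0]])
    return ReceptiveField(matrix, freqs, levels, neuron_id=neuron_id)


def single_frame_ensemble(member_activity):
    size = sum(member_activity.values())
    return Ensemble(0, 0, size=size, duration=1, member_activity=member_activity)


class TestComputeRf:
    def test_all_zero_trace_zero_rf(self, protocol_small):
        n = protocol_small.end_frame + 10
        rf = ak.compute_rf(ak.DffTrace(np.zeros(n), 0, 30.0), protocol_small)
        assert rf.response.shape == (3, 9)
        np.testing.assert_array_equal(rf.response, 0.0)

    def test_indicator_condition(self, protocol_small):
        n = protocol_small.end_frame + 10
        target = protocol_small.trials[0]
        v = np.zeros(n)
        for t in protocol_small.trials:
            if (t.frequency_hz, t.level_db) == (target.frequency_hz, target.level_db):
                v[t.onset_frame : t.onset_frame + t.duration_frames] = 1.0
        rf = ak.compute_rf(ak.DffTrace(v, 0, 30.0), protocol_small)
        fi = np.flatnonzero(rf.freq_axis == target.frequency_hz)[0]
        li = np.flatnonzero(rf.level_axis == target.level_db)[0]
        expect = np.zeros((3, 9))
        expect[li, fi] = 1.0
        np.testing.assert_allclose(rf.response, expect)


class TestBestFrequency:
    def test_single_positive_entry(self):
        m = np.zeros((3, 9))
        m[1, 4] = 0.7
        rf = make_rf(m)
        assert ak.best_frequency(rf) == pytest.approx(rf.freq_axis[4])

    def test_log_midpoint_of_equal_masses(self):
        freqs = np.array([6000.0, 12000.0, 24000.0])
        m = np.array([[1.0, 0.0, 1.0]])
        rf = make_rf(m, freqs=freqs, levels=np.array([60.0]))
        assert ak.best_frequency(rf) == pytest.approx(12000.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.normal(0, 1, (3, 9))
            rf = make_rf(m)
            try:
                bf = ak.best_frequency(rf)
            except UndefinedFieldError:
                assert np.all(np.maximum(m, 0).sum(axis=0) == 0)
                continue
            w = np.maximum(m, 0.0).sum(axis=0)
            oracle = 2.0 ** (np.sum(w * np.log2(rf.freq_axis)) / w.sum())
            assert bf == pytest.approx(oracle, rel=1e-12)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(UndefinedFieldError):
            ak.best_frequency(make_rf(-np.ones((3, 9))))


class TestRfBandwidth:
    def test_indicator_rf_zero_with_point_flag(self):
        m = np.zeros((1, 9))
        m[0, 3] = 1.0
        bw = ak.rf_bandwidth(make_rf(m, levels=np.array([60.0])))
        assert bw.octaves == 0.0 and bw.point_support

    def test_rectangular_rf_on_fine_grid(self):
        # 2-octave rectangle sampled every 0.01 octave
        freqs = 3000.0 * 2.0 ** np.arange(0, 4, 0.01)
        r = ((freqs >= 6000.0) & (freqs <= 24000.0)).astype(float)[None, :]
        bw = ak.rf_bandwidth(make_rf(r, freqs=freqs, levels=np.array([60.0])))
        assert bw.octaves == pytest.approx(2.0, abs=0.02)

    def test_gaussian_rf_fwhm_closed_form(self):
        sigma = 0.5  # octaves
        freqs = 3000.0 * 2.0 ** np.arange(0, 4, 0.01)
        x = np.log2(freqs / 12000.0)
        r = np.exp(-(x**2) / (2 * sigma**2))[None, :]
        bw = ak.rf_bandwidth(make_rf(r, freqs=freqs, levels=np.array([60.0])))
        assert bw.octaves == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)), abs=0.02)

    def test_level_selection(self):
        m = np.zeros((3, 9))
        m[0, 2] = 0.8  # narrow response at 40 dB
        m[2, 2:5] = 1.0  # broad response at 80 dB holds the global peak
        rf = make_rf(m)
        bw_best = ak.rf_bandwidth(rf, level="best")
        bw_40 = ak.rf_bandwidth(rf, level=40.0)
        assert bw_best.octaves > bw_40.octaves
        assert bw_40.point_support

    def test_all_nonpositive_row_rejected(self):
        with pytest.raises(UndefinedFieldError):
            ak.rf_bandwidth(make_rf(-np.ones((1, 9)), levels=np.array([60.0])))


class TestEnsembleRf:
    def test_single_member_identity(self):
        rng = np.random.default_rng(1)
        rf = make_rf(np.abs(rng.normal(0, 1, (3, 9))))
        erf = ak.ensemble_rf(single_frame_ensemble({0: 3}), {0: rf})
        np.testing.assert_allclose(erf.response, rf.response)
        assert erf.iqr_bf == 0.0

    def test_two_equal_members_plain_average(self):
        rng = np.random.default_rng(2)
        rf0 = make_rf(np.abs(rng.normal(0, 1, (3, 9))), neuron_id=0)
        rf1 = make_rf(np.abs(rng.normal(0, 1, (3, 9))), neuron_id=1)
        e = Ensemble(0, 1, size=4, duration=2, member_activity={0: 2, 1: 2})
        erf = ak.ensemble_rf(e, {0: rf0, 1: rf1})
        np.testing.assert_allclose(erf.response, 0.5 * (rf0.response + rf1.response))

    def test_identical_bfs_different_shapes(self):
        # both RFs peak (and center) at the same frequency: IQR_BF is 0 but
        # the compound field still has positive bandwidth
        freqs = 3000.0 * 2.0 ** (np.arange(9) / 2)
        x = np.log2(freqs / freqs[4])
        narrow = np.exp(-(x**2) / (2 * 0.3**2))[None, :].repeat(3, axis=0)
        wide = np.exp(-(x**2) / (2 * 0.9**2))[None, :].repeat(3, axis=0)
        rfs = {0: make_rf(narrow, freqs=freqs), 1: make_rf(wide, freqs=freqs)}
        e = Ensemble(0, 0, size=2, duration=1, member_activity={0: 1, 1: 1})
        erf = ak.ensemble_rf(e, rfs)
        assert erf.iqr_bf == pytest.approx(0.0, abs=1e-9)
        assert erf.bandwidth > 0

    def test_convex_combination_invariant(self):
        rng = np.random.default_rng(3)
        rfs = {i: make_rf(rng.normal(0, 1, (3, 9)), neuron_id=i) for i in range(4)}
        e = Ensemble(0, 2, size=9, duration=3,
                     member_activity={0: 1, 1: 2, 2: 3, 3: 3})
        erf = ak.ensemble_rf(e, rfs)
        stack = np.stack([rfs[i].response for i in range(4)])
        assert np.all(erf.response >= stack.min(axis=0) - 1e-12)
        assert np.all(erf.response <= stack.max(axis=0) + 1e-12)

    def test_missing_rf_rejected(self):
        with pytest.raises(MissingRfError):
            ak.ensemble_rf(single_frame_ensemble({0: 1, 7: 1}), {0: make_rf(np.ones((3, 9)))})

    def test_iqr_invariant_to_relabeling_and_scaling(self):
        rng = np.random.default_rng(4)
        mats = [np.abs(rng.normal(0, 1, (3, 9))) for _ in range(3)]
        rfs = {i: make_rf(m, neuron_id=i) for i, m in enumerate(mats)}
        e = Ensemble(0, 0, size=3, duration=1, member_activity={0: 1, 1: 1, 2: 1})
        base = ak.ensemble_rf(e, rfs).iqr_bf
        # relabel neurons
        perm = {0: 2, 1: 0, 2: 1}
        rfs_r = {perm[i]: make_rf(mats[i], neuron_id=perm[i]) for i in range(3)}
        e_r = Ensemble(0, 0, size=3, duration=1,
                       member_activity={perm[i]: 1 for i in range(3)})
        assert ak.ensemble_rf(e_r, rfs_r).iqr_bf == pytest.approx(base)
        # uniform multiplicative scaling of all RFs
        rfs_s = {i: make_rf(5.0 * m, neuron_id=i) for i, m in enumerate(mats)}
        assert ak.ensemble_rf(e, rfs_s).iqr_bf == pytest.approx(base)


class TestTuningVsScale:
    def _population(self, n_neurons=60, shared_bf=False, seed=0):
        rng = np.random.default_rng(seed)
        freqs = 3000.0 * 2.0 ** (np.arange(9) / 2)
        rfs = {}
        for i in range(n_neurons):
            center = freqs[4] if shared_bf else 2.0 ** rng.uniform(
                np.log2(freqs[0]), np.log2(freqs[-1])
            )
            x = np.log2(freqs / center)
            m = np.exp(-(x**2) / (2 * 0.5**2))[None, :].repeat(3, axis=0)
            rfs[i] = make_rf(m, freqs=freqs, neuron_id=i)
        return rfs

    def _catalog(self, rfs, n_ensembles=150, seed=1):
        rng = np.random.default_rng(seed)
        n_neurons = len(rfs)
        ensembles = []
        frame = 0
        for _ in range(n_ensembles):
            k = int(rng.integers(1, n_neurons))
            members = rng.choice(n_neurons, size=k, replace=False)
            ensembles.append(
                Ensemble(frame, frame, size=k, duration=1,
                         member_activity={int(m): 1 for m in members},
                         evoked=True, stimulus_id=0)
            )
            frame += 2
        return ak.EnsembleCatalog(ensembles, n_neurons, frame, 0.5, 30.0)

    def test_iqr_bf_increases_with_size(self):
        rfs = self._population()
        cat = self._catalog(rfs)
        table, rho, p = ak.tuning_vs_scale(cat, rfs, metric="iqr_bf", axis="size")
        assert rho > 0 and p < 0.01

    def test_shared_bf_gives_zero_iqr_everywhere(self):
        rfs = self._population(shared_bf=True)
        cat = self._catalog(rfs)
        table, rho, p = ak.tuning_vs_scale(cat, rfs, metric="iqr_bf", axis="size")
        occupied = table[table.n > 0]
        np.testing.assert_allclose(occupied["mean"], 0.0, atol=1e-9)

    def test_constant_metric_zero_sd(self):
        rfs = self._population(shared_bf=True)
        cat = self._catalog(rfs)
        table, _, _ = ak.tuning_vs_scale(cat, rfs, metric="iqr_bf", axis="duration")
        occupied = table[table.n > 1]
        np.testing.assert_allclose(occupied["sd"], 0.0, atol=1e-12)

    def test_identically_tuned_members_keep_single_member_bandwidth(self):
        # selectivity is scale-invariant: the compound RF of identically
        # tuned members has exactly the single-member bandwidth
        rfs = self._population(shared_bf=True)
        single = ak.rf_bandwidth(rfs[0]).octaves
        cat = self._catalog(rfs)
        table, rho, p = ak.tuning_vs_scale(cat, rfs, metric="bandwidth", axis="size")
        occupied = table[table.n > 0]
        np.testing.assert_allclose(occupied["mean"], single, rtol=1e-9)
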