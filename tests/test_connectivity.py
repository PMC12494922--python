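import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import brainclock as bc
from brainclock.connectivity import devectorize_fc

from conftest import two_node_connectome


def sine_ts(freq, rate=512.0, duration=10.0, n_regions=1):
    t = np.arange(int(rate * duration)) / rate
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_regions, 1))
    return bc.RegionalTimeSeries(data, rate)


class TestBandpass:
    @pytest.mark.parametrize("freq,in_band", [(5.0, False), (20.0, True)])
    def test_sine_attenuation_matches_filter_response(self, freq, in_band):
        ts = sine_ts(freq)
        out = bc.bandpass_filter(ts, 8.0, 40.0, 3)
        # oracle: squared magnitude of the one-pass response (filtfilt = |H|^2)
        sos = sps.bessel(3, [8.0, 40.0], btype="bandpass", fs=512.0, output="sos")
        w, h = sps.sosfreqz(sos, worN=[freq], fs=512.0)
        expected = np.abs(h[0]) ** 2
        measured = out.data[0, 2000:-2000].std() / ts.data[0, 2000:-2000].std()
        assert measured == pytest.approx(expected, rel=0.05)
        if in_band:
            assert measured > 0.9
        else:
            assert measured < 0.1

    def test_zero_signal_maps_to_zero(self):
        ts = bc.RegionalTimeSeries(np.zeros((3, 1024)), 512.0)
        out = bc.bandpass_filter(ts)
        assert np.allclose(out.data, 0.0)

    def test_band_edge_at_nyquist_rejected(self):
        ts = sine_ts(10.0, rate=64.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bc.bandpass_filter(ts, 8.0, 40.0, 3)


class TestResample:
    def test_doubling_rate_doubles_samples(self):
        ts = bc.RegionalTimeSeries(np.random.default_rng(0).normal(size=(2, 2560)),
                                   256.0)
        out = bc.resample(ts, 512.0)
        assert out.n_samples == 5120
        assert out.sampling_rate == 512.0
        assert abs(out.duration - ts.duration) <= 1.0 / 512.0

    def test_identity_rate_returns_identical_data(self):
        ts = sine_ts(10.0)
        out = bc.resample(ts, ts.sampling_rate)
        assert np.array_equal(out.data, ts.data)

    def test_downsampling_preserves_spectral_peak(self):
        ts = sine_ts(10.0, rate=1024.0, duration=8.0)
        out = bc.resample(ts, 512.0)
        f, p = sps.welch(out.data[0], fs=512.0, nperseg=2048)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)


class TestComputeFC:
    def test_output_is_square_correlation_matrix(self, rng):
        ts = bc.RegionalTimeSeries(rng.normal(size=(78, 500)), 512.0)
        fc = bc.compute_fc(ts)
        assert fc.values.shape == (78, 78)
        assert fc.kind == "correlation"
        assert np.allclose(np.diag(fc.values), 1.0)

    def test_duplicated_region_gives_unit_correlation(self, rng):
        row = rng.normal(size=500)
        fc = bc.compute_fc(bc.RegionalTimeSeries(np.stack([row, row]), 512.0))
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.arange(5120) / 512.0
        data = np.stack([np.sin(2 * np.pi * 8 * t), np.cos(2 * np.pi * 8 * t)])
        fc = bc.compute_fc(bc.RegionalTimeSeries(data, 512.0))
        assert abs(fc.values[0, 1]) < 1e-10

    def test_zero_variance_region_named_in_error(self, rng):
        data = rng.normal(size=(3, 100))
        data[1] = 0.7
        ts = bc.RegionalTimeSeries(data, 512.0, ["A", "B", "C"])
        with pytest.raises(ValueError, match="B"):
            bc.compute_fc(ts)


class TestNodalStrength:
    def test_hand_computed_three_regions(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        s = bc.nodal_strength(bc.ConnectivityMatrix(m))
        assert np.allclose(s.values, 1.0)

    def test_zero_offdiagonal_gives_zero_strength(self):
        s = bc.nodal_strength(bc.ConnectivityMatrix(np.eye(4)))
        assert np.allclose(s.values, 0.0)

    def test_permutation_equivariance(self, rng):
        v = rng.uniform(-0.5, 0.9, size=(6, 6))
        m = np.clip((v + v.T) / 2, -1, 1)
        np.fill_diagonal(m, 1.0)
        perm = rng.permutation(6)
        s = bc.nodal_strength(bc.ConnectivityMatrix(m)).values
        sp = bc.nodal_strength(bc.ConnectivityMatrix(m[np.ix_(perm, perm)])).values
        assert np.allclose(sp, s[perm])


class TestProportionalThreshold:
    def test_78_regions_rho_point1_retains_300_edges(self, rng):
        v = rng.uniform(-1, 1, size=(78, 78))
        m = (v + v.T) / 2
        np.fill_diagonal(m, 1.0)
        b = bc.proportional_threshold(bc.ConnectivityMatrix(m), 0.1)
        assert b.values.sum() / 2 == 300

    def test_rho_one_gives_complete_graph(self, rng):
        v = rng.uniform(0.1, 0.9, size=(5, 5))
        m = (v + v.T) / 2
        np.fill_diagonal(m, 1.0)
        b = bc.proportional_threshold(bc.ConnectivityMatrix(m), 1.0)
        assert np.array_equal(b.values, 1.0 - np.eye(5))

    def test_deterministic_with_ties(self):
        m = np.full((6, 6), 0.4)
        np.fill_diagonal(m, 1.0)
        fc = bc.ConnectivityMatrix(m)
        b1 = bc.proportional_threshold(fc, 0.3)
        b2 = bc.proportional_threshold(fc, 0.3)
        assert np.array_equal(b1.values, b2.values)

    def test_zero_edge_request_rejected(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.5
        with pytest.raises(ValueError, match="zero edges"):
            bc.proportional_threshold(bc.ConnectivityMatrix(m), 0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_edge_sets_nested_across_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-1, 1, size=(10, 10))
        m = (v + v.T) / 2
        np.fill_diagonal(m, 1.0)
        fc = bc.ConnectivityMatrix(m)
        prev = None
        for rho in (0.1, 0.3, 0.6, 1.0):
            cur = bc.proportional_threshold(fc, rho).values
            if prev is not None:
                assert np.all(cur >= prev)  # edge set at smaller rho is a subset
            prev = cur


class TestVectorize:
    @pytest.mark.parametrize("n,length", [(78, 3003), (2, 1)])
    def test_feature_length(self, n, length, rng):
        v = rng.uniform(-0.9, 0.9, size=(n, n))
        m = (v + v.T) / 2
        np.fill_diagonal(m, 1.0)
        assert bc.vectorize_fc(bc.ConnectivityMatrix(m)).size == length

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        v = rng.uniform(-0.9, 0.9, size=(n, n))
        m = (v + v.T) / 2
        np.fill_diagonal(m, 1.0)
        fc = bc.ConnectivityMatrix(m)
        assert np.allclose(devectorize_fc(bc.vectorize_fc(fc)).values, m)


class TestHarmonize:
    def make_set(self, rng, n=4, size=6):
        out = []
        for _ in range(n):
            v = rng.uniform(-0.4, 0.6, size=(size, size))
            m = (v + v.T) / 2
            np.fill_diagonal(m, 1.0)
            out.append(bc.ConnectivityMatrix(m))
        return out

    def test_mean_moved_onto_reference(self, rng):
        target = self.make_set(rng)
        ref = self.make_set(rng, n=1)[0]
        out = bc.harmonize_fc(target, ref)
        mean_out = np.mean([m.values for m in out], axis=0)
        iu = np.triu_indices(6, k=1)
        assert np.allclose(mean_out[iu], ref.values[iu], atol=1e-12)

    def test_between_subject_differences_preserved(self, rng):
        target = self.make_set(rng)
        ref = self.make_set(rng, n=1)[0]
        out = bc.harmonize_fc(target, ref)
        iu = np.triu_indices(6, k=1)
        before = target[0].values[iu] - target[1].values[iu]
        after = out[0].values[iu] - out[1].values[iu]
        assert np.allclose(before, after, atol=1e-12)

    def test_identity_when_means_already_match(self, rng):
        target = self.make_set(rng, n=2)
        mean = np.mean([m.values for m in target], axis=0)
        np.fill_diagonal(mean, 1.0)
        out = bc.harmonize_fc(target, bc.ConnectivityMatrix(mean))
        for t, o in zip(target, out):
            assert np.allclose(t.values, o.values, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        target = self.make_set(rng, n=2, size=5)
        ref = self.make_set(rng, n=1, size=6)[0]
        with pytest.raises(ValueError, match="mismatch"):
            bc.harmonize_fc(target, ref)


def test_coupled_oscillators_more_correlated_than_uncoupled():
    """Simulation + FC smoke test: coupling raises inter-node correlation."""
    c = two_node_connectome()
    corr = {}
    for g in (0.0, 2.0):
        p = bc.HopfParameters(a=-0.2, f=10.0, beta=0.1, G=g, dt=0.002,
                              duration=120.0, seed=11)
        fc = bc.compute_fc(bc.simulate_hopf(c, p))
        corr[g] = fc.values[0, 1]
    assert corr[2.0] > corr[0.0] + 0.1
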