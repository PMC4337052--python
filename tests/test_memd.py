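"""Decomposition contracts: completeness, tone separation, determinism,
and exact degeneration to classic EMD on a single channel."""

import numpy as np
import pytest

from doaindex import memd as M
from doaindex.io_formats import Signal

from oracles import classic_emd_envelope_mean


@pytest.fixture(scope="module")
def two_tone():
    fs = 125.0
    t = np.arange(1250) / fs
    slow = np.sin(2 * np.pi * 2.0 * t)
    fast = np.sin(2 * np.pi * 20.0 * t)
    return fs, t, slow, fast


class TestDirections:
    def test_unit_norm(self):
        for d in (2, 3, 4):
            vecs = M.hammersley_directions(16, d).vectors
            np.testing.assert_allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-12)

    def test_plane_four_directions_well_spread(self):
        vecs = M.hammersley_directions(4, 2).vectors
        for i in range(4):
            for j in range(i + 1, 4):
                ang = np.degrees(np.arccos(np.clip(vecs[i] @ vecs[j], -1, 1)))
                assert ang >= 45.0 - 1e-9

    def test_deterministic(self):
        a = M.hammersley_directions(32, 3).vectors
        b = M.hammersley_directions(32, 3).vectors
        np.testing.assert_array_equal(a, b)

    def test_too_few_channels(self):
        with pytest.raises(ValueError, match="2 channels"):
            M.hammersley_directions(8, 1)


class TestEnvelopeMean:
    def test_symmetric_sinusoid_mean_near_zero(self):
        t = np.arange(1000) / 125.0
        x = np.sin(2 * np.pi * 5.0 * t)
        X = np.column_stack([x, x])
        m = M.envelope_mean(X, M.hammersley_directions(16, 2))
        assert np.max(np.abs(m)) < 0.05

    def test_constant_signal_is_trend_only(self):
        X = np.ones((100, 2))
        with pytest.raises(M.TrendOnlyError):
            M.envelope_mean(X, M.hammersley_directions(8, 2))

    def test_homogeneity(self, rng):
        X = rng.standard_normal((300, 2))
        dirs = M.hammersley_directions(16, 2)
        m1 = M.envelope_mean(X, dirs)
        m2 = M.envelope_mean(2.0 * X, dirs)
        np.testing.assert_allclose(m2, 2.0 * m1, atol=1e-12)

    def test_single_channel_degenerates_to_classic_emd(self, rng):
        """With the direction set {+1, -1} the multivariate envelope mean is
        exactly classic EMD's (max-spline + min-spline)/2."""
        for _ in range(5):
            x = np.cumsum(rng.standard_normal(256))  # smooth-ish random walk
            m = M.envelope_mean(x[:, None], M.sign_directions())[:, 0]
            np.testing.assert_allclose(m, classic_emd_envelope_mean(x), atol=1e-10)


class TestMemd:
    def test_completeness_random_input(self, rng):
        X = rng.standard_normal((512, 2))
        for imfset, col in zip(M.memd(X, M.SiftConfig()), X.T):
            rec = imfset.reconstruct_all()
            assert np.max(np.abs(rec - col)) / np.max(np.abs(col)) < 1e-8

    def test_mode_alignment_same_imf_count(self, rng):
        X = rng.standard_normal((512, 3))
        sets = M.memd(X, M.SiftConfig(K=16))
        counts = {s.n_imfs for s in sets}
        assert len(counts) == 1

    def test_two_tone_separation(self, two_tone):
        fs, t, slow, fast = two_tone
        X = np.column_stack(
            [slow + fast, np.sin(2 * np.pi * 2.0 * t + 0.4) + np.sin(2 * np.pi * 20.0 * t + 0.2)]
        )
        imfset = M.memd(X, M.SiftConfig(), fs=fs)[0]
        r_fast = [abs(np.corrcoef(c, fast)[0, 1]) for c in imfset.imfs]
        r_slow = [abs(np.corrcoef(c, slow)[0, 1]) for c in imfset.imfs]
        i_fast = int(np.argmax(r_fast))
        i_slow = int(np.argmax(r_slow))
        assert r_fast[i_fast] > 0.95
        assert r_slow[i_slow] > 0.95
        assert i_slow > i_fast  # IMFs ordered fast to slow

    def test_constant_input_pure_residue(self):
        X = np.full((100, 2), 3.0)
        sets = M.memd(X, M.SiftConfig())
        assert sets[0].n_imfs == 0
        np.testing.assert_array_equal(sets[0].residue, X[:, 0])

    def test_zero_crossing_rate_nonincreasing(self, rng):
        x = rng.standard_normal(1024)
        imfset = M.na_memd(Signal(x, 125.0), M.SiftConfig(noise_seed=1))
        rates = [np.count_nonzero(np.diff(np.signbit(c))) for c in imfset.imfs]
        violations = sum(1 for a, b in zip(rates, rates[1:]) if b > a)
        assert violations <= 1


class TestNaMemd:
    def test_completeness_against_original(self, rng):
        x = rng.standard_normal(600)
        imfset = M.na_memd(Signal(x, 125.0), M.SiftConfig(noise_seed=2))
        assert np.max(np.abs(imfset.reconstruct_all() - x)) / np.max(np.abs(x)) < 1e-8

    def test_determinism_under_noise_seed(self, rng):
        x = rng.standard_normal(400)
        a = M.na_memd(Signal(x, 125.0), M.SiftConfig(noise_seed=5))
        b = M.na_memd(Signal(x, 125.0), M.SiftConfig(noise_seed=5))
        assert a.n_imfs == b.n_imfs
        for ca, cb in zip(a.imfs, b.imfs):
            np.testing.assert_array_equal(ca, cb)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            M.na_memd(Signal(np.ones(100), 125.0))

    def test_two_tone_separation_single_channel(self, two_tone):
        fs, t, slow, fast = two_tone
        imfset = M.na_memd(Signal(slow + fast, fs), M.SiftConfig(noise_seed=3))
        r_fast = max(abs(np.corrcoef(c, fast)[0, 1]) for c in imfset.imfs)
        r_slow = max(abs(np.corrcoef(c, slow)[0, 1]) for c in imfset.imfs)
        assert r_fast > 0.95
        assert r_slow > 0.95


class TestReconstruct:
    def test_all_plus_residue_restores_signal(self, rng):
        x = rng.standard_normal(512)
        imfset = M.na_memd(Signal(x, 125.0), M.SiftConfig(noise_seed=4))
        rec = M.reconstruct(imfset, range(1, imfset.n_imfs + 1), include_residue=True)
        assert np.max(np.abs(rec.samples - x)) < 1e-8 * np.max(np.abs(x))

    def test_empty_selection_is_zero(self, rng):
        imfset = M.na_memd(Signal(rng.standard_normal(256), 125.0), M.SiftConfig())
        assert np.all(M.reconstruct(imfset, []).samples == 0.0)

    def test_out_of_range_index(self, rng):
        imfset = M.na_memd(Signal(rng.standard_normal(256), 125.0), M.SiftConfig())
        with pytest.raises(IndexError):
            M.reconstruct(imfset, [imfset.n_imfs + 1])

    def test_imf23_band_between_tones(self, two_tone):
        """The IMF 2 + IMF 3 reconstruction of the two-tone signal has its
        spectral peak at or below the fast tone and above the slow one."""
        fs, t, slow, fast = two_tone
        imfset = M.na_memd(Signal(slow + fast, fs), M.SiftConfig(noise_seed=3))
        rec = M.reconstruct(imfset, [2, 3]).samples
        freqs = np.fft.rfftfreq(rec.size, 1 / fs)
        peak = freqs[int(np.argmax(np.abs(np.fft.rfft(rec))))]
        assert 2.0 <= peak <= 20.0


class TestFilterSignal:
    def test_blocked_filtering_matches_length(self, rng):
        x = rng.standard_normal(25000)
        cfg = M.SiftConfig(K=16, block_len=10000, noise_seed=0)
        out = M.filter_signal(Signal(x, 125.0), cfg, (2, 3))
        assert out.samples.size == x.size
        assert np.all(np.isfinite(out.samples))

    def test_deterministic(self, rng):
        x = rng.standard_normal(5000)
        cfg = M.SiftConfig(K=16, noise_seed=9)
        a = M.filter_signal(Signal(x, 125.0), cfg)
        b = M.filter_signal(Signal(x, 125.0), cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
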