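"""Preprocessing chain: Beer-Lambert stages, detrending, TDDR, bandpass."""

import numpy as np
import pytest

from oxytouch.preprocess import (
    PreprocessConfig,
    bandpass,
    intensity_to_od,
    mbll,
    mbll_forward,
    polynomial_detrend,
    tddr,
)
from oxytouch.recording import FnirsRecording

FS = 6.78


def rec(data, kind="concentration", **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    kw.setdefault("chromophore", "HbO" if kind == "concentration" else None)
    return FnirsRecording(data=data, sampling_rate=FS, signal_kind=kind, **kw)


def demodulated_amplitude(x, freq, fs, trim_s=150.0):
    t = np.arange(x.size) / fs
    core = slice(int(trim_s * fs), x.size - int(trim_s * fs))
    return np.hypot(
        2 * np.mean(x[core] * np.sin(2 * np.pi * freq * t[core])),
        2 * np.mean(x[core] * np.cos(2 * np.pi * freq * t[core])),
    )


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        out = intensity_to_od(rec(np.full(100, 3.7), kind="intensity"))
        assert out.data == pytest.approx(0.0)
        assert out.signal_kind == "od"

    def test_sample_at_mean_times_e_gives_minus_one(self):
        I = np.ones(100)
        I[0] = np.e
        out = intensity_to_od(rec(I, kind="intensity"))
        assert out.data[0, 0] == pytest.approx(-np.log(np.e / I.mean()))
        # and a sample exactly at the mean maps to 0
        at_mean = np.isclose(I, I.mean())
        assert not at_mean.any() or out.data[0, at_mean] == pytest.approx(0.0)

    def test_round_trip(self, rng):
        I = np.exp(rng.normal(size=200))
        out = intensity_to_od(rec(I, kind="intensity"))
        np.testing.assert_allclose(np.exp(-out.data[0]) * I.mean(), I, rtol=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            intensity_to_od(rec([1.0, -0.5, 2.0], kind="intensity"))


class TestMbll:
    def test_zero_od_gives_zero_concentration(self):
        cfg = PreprocessConfig()
        pair = {w: rec(np.zeros((3, 50)), kind="od", wavelength=w) for w in cfg.wavelengths}
        hbo, hbr = mbll(pair, cfg)
        assert hbo.data == pytest.approx(0.0)
        assert hbr.data == pytest.approx(0.0)
        assert (hbo.chromophore, hbr.chromophore) == ("HbO", "HbR")

    def test_forward_inverse_round_trip(self, rng):
        cfg = PreprocessConfig()
        hbo = rec(rng.normal(size=(4, 80)))
        hbr = rec(rng.normal(size=(4, 80)), chromophore="HbR")
        od = mbll_forward(hbo, hbr, cfg)
        hbo2, hbr2 = mbll(od, cfg)
        np.testing.assert_allclose(hbo2.data, hbo.data, atol=1e-9)
        np.testing.assert_allclose(hbr2.data, hbr.data, atol=1e-9)

    def test_pathlength_scaling(self, rng):
        cfg = PreprocessConfig()
        double = PreprocessConfig(distance_cm=cfg.distance_cm * 2)
        pair = {
            w: rec(rng.normal(size=(2, 40)), kind="od", wavelength=w) for w in cfg.wavelengths
        }
        hbo1, _ = mbll(pair, cfg)
        hbo2, _ = mbll(pair, double)
        np.testing.assert_allclose(hbo2.data, hbo1.data / 2, atol=1e-12)

    def test_singular_extinction_rejected(self):
        cfg = PreprocessConfig(
            extinction={
                760.0: {"HbO": 1.0, "HbR": 2.0},
                850.0: {"HbO": 2.0, "HbR": 4.0},
            }
        )
        with pytest.raises(ValueError, match="singular"):
            cfg.extinction_matrix()

    def test_mismatched_channels_rejected(self):
        cfg = PreprocessConfig()
        pair = {
            760.0: rec(np.zeros((2, 10)), kind="od", wavelength=760.0),
            850.0: rec(np.zeros((3, 10)), kind="od", wavelength=850.0),
        }
        with pytest.raises(ValueError, match="channel"):
            mbll(pair, cfg)


class TestDetrend:
    def test_removes_linear_trend(self):
        t = np.arange(500) / FS
        out = polynomial_detrend(rec(2.0 + 0.3 * t), order=1)
        assert np.abs(out.data).max() < 1e-9

    def test_order_zero_is_mean_removal(self, rng):
        x = rng.normal(size=300)
        out = polynomial_detrend(rec(x), order=0)
        np.testing.assert_allclose(out.data[0], x - x.mean(), atol=1e-12)

    def test_preserves_oscillation_under_drift(self):
        t = np.arange(2000) / FS
        pure = np.sin(2 * np.pi * 0.05 * t)
        out = polynomial_detrend(rec(pure + 0.01 * t + 5), order=1)
        r = np.corrcoef(out.data[0], pure)[0, 1]
        assert r > 0.999

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            polynomial_detrend(rec([1.0, 2.0]), order=1)


class TestTddr:
    def test_constant_signal_unchanged(self):
        out = tddr(rec(np.full(100, 1.3)))
        np.testing.assert_allclose(out.data, 1.3, atol=1e-12)

    def test_clean_sinusoid_preserved(self):
        # session-length in-band sinusoid without artifacts: the biweight
        # reweighting leaves it essentially unchanged (the reference
        # recurrence yields corr = 0.996 on this fixture)
        t = np.arange(6102) / FS  # one 900 s session
        x = np.sin(2 * np.pi * 0.04 * t)
        out = tddr(rec(x))
        assert np.corrcoef(out.data[0], x)[0, 1] > 0.99

    def test_spike_suppression(self, rng):
        # a ~1 s motion spike (low-frequency content below the 0.5 Hz
        # split) of 10x the signal SD must be largely repaired
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 0.04 * t) + 0.05 * rng.normal(size=t.size)
        spiked = x.copy()
        spiked[1500:1507] += 10 * x.std()
        out = tddr(rec(spiked)).data[0]
        before = abs(spiked[1503] - x[1503])
        after = abs(out[1503] - x[1503])
        assert after < 0.2 * before

    def test_step_artifact_removed(self, rng):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 0.04 * t) + 0.05 * rng.normal(size=t.size)
        stepped = x.copy()
        stepped[2000:] += 5.0
        out = tddr(rec(stepped)).data[0]
        # the baseline discontinuity should essentially vanish
        jump = abs(np.mean(out[2000:2050]) - np.mean(out[1950:2000]))
        assert jump < 0.5

    def test_reapplication_is_bounded(self, rng):
        # the biweight reweighting re-shrinks derivative tails on every
        # pass, so exact idempotence does not hold; the reference
        # implementation changes a once-corrected fixture by ~6% RMS on
        # re-application, and the bound here guards against runaway
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 0.04 * t) + 0.05 * rng.normal(size=t.size)
        x[700:707] += 3
        once = tddr(rec(x))
        twice = tddr(once)
        rms = np.sqrt(np.mean((twice.data - once.data) ** 2))
        assert rms < 0.10 * np.sqrt(np.mean(once.data**2))

    def test_matches_reference_implementation(self, rng):
        """Independent oracle: the published reference recurrence as bundled
        with MNE."""
        from mne.preprocessing.nirs._tddr import _TDDR

        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 0.03 * t) + 0.1 * rng.normal(size=t.size)
        x[400] += 8
        x[1800:] += 2.5
        y = x * 0.5 - 1.0
        y[900] -= 6
        ours = tddr(rec(np.vstack([x, y]))).data
        theirs = np.vstack([_TDDR(x.copy(), FS), _TDDR(y.copy(), FS)])
        np.testing.assert_allclose(ours, theirs, atol=1e-3)


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(rec(np.full(4000, 2.0)))
        assert np.abs(out.data).mean() < 1e-3 * 2.0

    def test_passband_gain(self):
        t = np.arange(int(900 * FS)) / FS
        out = bandpass(rec(np.sin(2 * np.pi * 0.04 * t)))
        assert demodulated_amplitude(out.data[0], 0.04, FS) >= 0.95

    def test_stopband_attenuation(self):
        t = np.arange(int(900 * FS)) / FS
        out = bandpass(rec(np.sin(2 * np.pi * 1.0 * t)))
        assert demodulated_amplitude(out.data[0], 1.0, FS) <= 0.01

    def test_band_validation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec(np.zeros(100)), band=(0.01, 5.0))
        with pytest.raises(ValueError):
            bandpass(rec(np.zeros(100)), band=(0.08, 0.01))

    def test_linearity(self, rng):
        a = rng.normal(size=2000)
        b = rng.normal(size=2000)
        out_sum = bandpass(rec(a + b)).data
        sum_out = bandpass(rec(a)).data + bandpass(rec(b)).data
        np.testing.assert_allclose(out_sum, sum_out, atol=1e-10)


def test_stages_commute_with_channel_permutation(rng):
    """Every stage is channel-wise independent."""
    data = rng.normal(size=(5, 1200))
    data[2, 300] += 8  # an artifact for TDDR to chew on
    perm = rng.permutation(5)
    for op in (
        lambda r: polynomial_detrend(r, 1),
        tddr,
        bandpass,
    ):
        direct = op(rec(data)).data[perm]
        permuted = op(rec(data[perm])).data
        np.testing.assert_allclose(direct, permuted, atol=1e-10)
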