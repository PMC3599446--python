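import numpy as np
import pytest
from scipy import stats

from songseg.pulse_detect import NoiseEstimate, PulseCandidate
from songseg.pulse_model import (
    InsufficientPulsesError,
    build_pulse_model,
    classify_harmonic,
    model_cull,
    pulse_carrier_freq,
    pulse_llr,
    spectral_flatness,
)
from songseg.synthetic_song import render_pulse

FS = 10_000
L = 201  # matches the default +-10 ms detection window
NOISE = NoiseEstimate(sigma=0.05, window_s=1.0, quantile=0.1, n_windows_used=1)


def centered_gabor(carrier=220.0, amplitude=0.25):
    wave = render_pulse(FS, carrier, 0.0025, amplitude)
    out = np.zeros(L)
    h, c = len(wave) // 2, L // 2
    out[c - h : c + h + 1] = wave
    return out


def make_pulses(windows, stage="ipi_cull"):
    return [
        PulseCandidate(
            center_time_s=0.035 * i,
            peak_amplitude=float(np.max(np.abs(w))),
            best_scale_freq_hz=220.0,
            window=w,
            stage=stage,
        )
        for i, w in enumerate(windows)
    ]


@pytest.fixture(scope="module")
def gabor_model():
    rng = np.random.default_rng(7)
    truth = centered_gabor()
    windows = [truth + rng.normal(0, NOISE.sigma, L) for _ in range(300)]
    return build_pulse_model(make_pulses(windows), NOISE, FS)


class TestTemplateConstruction:
    def test_identical_noiseless_pulses_give_exact_template(self):
        truth = centered_gabor()
        model = build_pulse_model(make_pulses([truth.copy() for _ in range(200)]), NOISE, FS)
        expected = truth / np.linalg.norm(truth)
        assert np.max(np.abs(model.template_fund - expected)) < 1e-6
        assert np.linalg.norm(model.template_fund) == pytest.approx(1.0)

    def test_too_few_pulses_excluded(self):
        truth = centered_gabor()
        with pytest.raises(InsufficientPulsesError):
            build_pulse_model(make_pulses([truth] * 99), NOISE, FS, min_pulses=100)

    def test_noisy_recovery_snr2(self):
        rng = np.random.default_rng(3)
        truth = centered_gabor(amplitude=2 * NOISE.sigma)
        windows = [truth + rng.normal(0, NOISE.sigma, L) for _ in range(300)]
        model = build_pulse_model(make_pulses(windows), NOISE, FS)
        tu = truth / np.linalg.norm(truth)
        assert abs(np.corrcoef(model.template_fund, tu)[0, 1]) > 0.99

    def test_polarity_flips_do_not_corrupt_template(self, rng):
        truth = centered_gabor()
        windows = [((-1) ** i) * truth + rng.normal(0, 0.01, L) for i in range(200)]
        model = build_pulse_model(make_pulses(windows), NOISE, FS)
        tu = truth / np.linalg.norm(truth)
        assert abs(np.corrcoef(model.template_fund, tu)[0, 1]) > 0.99

    def test_rebuild_after_cull_converges(self, rng):
        # build -> cull -> rebuild on the same pulses barely changes the
        # template (the cull removes almost nothing from genuine pulses)
        truth = centered_gabor()
        windows = [truth + rng.normal(0, NOISE.sigma, L) for _ in range(300)]
        pulses = make_pulses(windows)
        model_a = build_pulse_model(pulses, NOISE, FS)
        kept = model_cull(pulses, model_a)
        model_b = build_pulse_model(kept, NOISE, FS)
        corr = abs(np.corrcoef(model_b.template_fund, model_a.template_fund)[0, 1])
        assert corr > 0.999


class TestCarrierAndHarmonics:
    @pytest.mark.parametrize("carrier", [100.0, 220.0, 440.0])
    def test_carrier_frequency_estimate(self, carrier):
        w = centered_gabor(carrier=carrier)
        assert pulse_carrier_freq(w, FS) == pytest.approx(carrier, abs=2.0)

    def test_classify_by_split_point(self):
        assert classify_harmonic(centered_gabor(220.0), 330.0, FS) == "fundamental"
        assert classify_harmonic(centered_gabor(440.0), 330.0, FS) == "harmonic"

    def test_noise_window_is_spectrally_flat(self, rng):
        flat = np.mean(
            [spectral_flatness(rng.normal(0, 1, L), FS) for _ in range(200)]
        )
        assert flat > 0.5
        assert spectral_flatness(centered_gabor(), FS) < 0.3

    def test_all_zero_window_rejected(self):
        with pytest.raises(ValueError):
            pulse_carrier_freq(np.zeros(L), FS)

    def test_harmonic_fraction_recovered_from_generator(self, synth60, seg60):
        # the generator injects ~17% second-harmonic pulses; classify the
        # detected pulses with the model's own split point
        _, _, _, events = synth60
        res = seg60
        frac = np.mean(
            [
                classify_harmonic(p.window, res.model.harmonic_split_hz, FS)
                == "harmonic"
                for p in res.model_culled
            ]
        )
        truth_frac = (events.query("kind == 'pulse'")["class"] == "harmonic").mean()
        assert frac == pytest.approx(truth_frac, abs=0.03)
        assert frac == pytest.approx(0.17, abs=0.04)


class TestLikelihoodRatio:
    def test_exact_multiple_of_template(self, gabor_model):
        a = 0.3
        x = a * gabor_model.template_fund
        expected = a**2 / (2 * gabor_model.sigma2)
        assert pulse_llr(x, gabor_model, max_lag_s=0.0) == pytest.approx(expected)

    def test_orthogonal_window_gives_zero(self, gabor_model):
        t = gabor_model.template_fund
        # construct an exactly orthogonal vector via Gram-Schmidt
        v = np.ones_like(t)
        v -= np.dot(v, t) * t
        assert pulse_llr(v, gabor_model, max_lag_s=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_sign_invariance(self, gabor_model, rng):
        x = rng.normal(0, 0.05, L)
        assert pulse_llr(x, gabor_model) == pytest.approx(
            pulse_llr(-x, gabor_model)
        )

    def test_joint_rescaling_invariance(self, gabor_model, rng):
        x = rng.normal(0, 0.05, L)
        llr = pulse_llr(x, gabor_model, max_lag_s=0.0)
        scaled_model = build_scaled(gabor_model, c=5.0)
        assert pulse_llr(5.0 * x, scaled_model, max_lag_s=0.0) == pytest.approx(llr)

    def test_noise_llr_matches_chi_square_null(self, gabor_model):
        # single template, no lag search: LLR ~ chi2(1)/2 on white noise
        rng = np.random.default_rng(11)
        sigma = np.sqrt(gabor_model.sigma2)
        llrs = np.array(
            [
                pulse_llr(rng.normal(0, sigma, L), gabor_model, max_lag_s=0.0)
                for _ in range(10_000)
            ]
        )
        assert llrs.mean() == pytest.approx(0.5, abs=0.05)
        retained = np.mean(llrs - 0.5 > 0)
        assert retained == pytest.approx(1 - stats.chi2.cdf(1, 1), abs=0.02)


def build_scaled(model, c):
    from songseg.pulse_model import PulseModel

    return PulseModel(
        template_fund=model.template_fund,
        template_harm=model.template_harm,
        n_pulses_used=model.n_pulses_used,
        sigma2=model.sigma2 * c**2,
        carrier_freq_hz=model.carrier_freq_hz,
        sample_rate=model.sample_rate,
        harmonic_split_hz=model.harmonic_split_hz,
    )


class TestModelCull:
    def test_template_pulses_all_retained(self, gabor_model):
        pulses = make_pulses([centered_gabor() for _ in range(20)])
        assert len(model_cull(pulses, gabor_model)) == 20

    def test_noise_windows_mostly_removed(self, gabor_model):
        rng = np.random.default_rng(4)
        sigma = np.sqrt(gabor_model.sigma2)
        real = make_pulses([centered_gabor() for _ in range(50)])
        junk = make_pulses([rng.normal(0, sigma, L) for _ in range(200)])
        real_times = {p.center_time_s for p in real}
        # offset junk times so the two groups are distinguishable
        junk = [
            type(p)(
                center_time_s=p.center_time_s + 1000.0,
                peak_amplitude=p.peak_amplitude,
                best_scale_freq_hz=p.best_scale_freq_hz,
                window=p.window,
                stage=p.stage,
            )
            for p in junk
        ]
        kept = model_cull(real + junk, gabor_model, max_lag_s=0.0)
        kept_real = sum(1 for p in kept if p.center_time_s in real_times)
        assert kept_real == 50
        # noise windows removed with probability ~ P(chi2(1) <= 1) ~ 0.68
        assert (len(kept) - kept_real) / 200 < 0.45

    def test_empty_input(self, gabor_model):
        assert model_cull([], gabor_model) == []

    def test_subset_and_stage(self, gabor_model, rng):
        pulses = make_pulses(
            [centered_gabor() + rng.normal(0, 0.05, L) for _ in range(30)]
        )
        kept = model_cull(pulses, gabor_model)
        assert {p.center_time_s for p in kept} <= {p.center_time_s for p in pulses}
        assert all(p.stage == "model_cull" for p in kept)
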