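"""Spectral chain: filter contract, PSD calibration, band extraction,
inclusion rules, and recovery of generated theta."""

import numpy as np
import pandas as pd
import pytest

from idatheta import simulate, spectral
from idatheta.spectral import (EpochSet, apply_inclusion_rules, compute_psd,
                               extract_theta, preprocess,
                               subject_condition_means)

SRATE = 500.0
N_PAD = round(SRATE * 2.5)  # 1.5 s window + 2 x 0.5 s padding


def make_epochs(signal_fn, n_trials=1):
    """Epochs with the given scalp signal and silent mastoids."""
    t = np.arange(N_PAD) / SRATE - 1.5  # pad start at -1.5 s
    data = np.zeros((n_trials, 5, N_PAD))
    for trial in range(n_trials):
        data[trial, :3, :] = signal_fn(t)
    return EpochSet(data=data, srate=SRATE)


def band_power(epochs, channel="Fz", band=(4.0, 5.0)):
    clean = preprocess(epochs)
    psd = compute_psd(clean)
    return extract_theta(psd, band=band, channels=(channel,)
                         )["theta_power"].to_numpy()


class TestPreprocess:
    def test_dc_offset_annihilated(self):
        out = preprocess(make_epochs(lambda t: np.full_like(t, 3.7)))
        assert np.allclose(out.data, 0.0, atol=1e-8)

    def test_linear_ramp_annihilated(self):
        # demean + detrend remove the ramp; only the band-pass filter's
        # edge transient remains (< 1% of the input's RMS)
        out = preprocess(make_epochs(lambda t: 2.0 * t + 1.0))
        assert np.abs(out.data).max() < 0.01 * (2.0 * 1.5)

    def test_theta_sinusoid_passband_attenuation_below_5pct(self):
        epochs = make_epochs(lambda t: np.sin(2 * np.pi * 4.4 * t))
        out = preprocess(epochs)
        # compare RMS amplitude in the analysis window against the ideal
        ideal = np.sin(2 * np.pi * 4.4 * (np.arange(750) / SRATE - 1.0))
        ideal = ideal - ideal.mean()
        ratio = out.data[0, 0].std() / ideal.std()
        assert ratio > 0.95

    def test_missing_mastoids_rejected(self):
        epochs = EpochSet(data=np.zeros((1, 3, N_PAD)), srate=SRATE,
                          channels=("Fz", "FCz", "Cz"))
        with pytest.raises(ValueError, match="mastoid"):
            preprocess(epochs)

    def test_epoch_length_validated(self):
        with pytest.raises(ValueError, match="expected"):
            EpochSet(data=np.zeros((1, 5, 700)), srate=SRATE)

    def test_chain_is_deterministic(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((3, 5, N_PAD))
        a = band_power(EpochSet(data=raw.copy(), srate=SRATE))
        b = band_power(EpochSet(data=raw.copy(), srate=SRATE))
        assert np.array_equal(a, b)


class TestPsdCalibration:
    def test_zero_signal_zero_spectrum(self):
        psd = compute_psd(preprocess(make_epochs(lambda t: t * 0.0)))
        assert np.allclose(psd.power, 0.0, atol=1e-12)

    def test_frequency_grid(self):
        psd = compute_psd(preprocess(make_epochs(lambda t: t * 0.0)))
        spacing = np.diff(psd.freqs)
        assert spacing == pytest.approx(2.0 / 3.0)
        assert psd.freqs.min() >= 3.0 and psd.freqs.max() <= 30.0
        in_band = psd.freqs[(psd.freqs >= 4) & (psd.freqs <= 5)]
        assert in_band == pytest.approx([4.0, 4.0 + 2 / 3])

    def test_bin_centred_unit_sinusoid_gives_half(self):
        # 4 Hz = 6 cycles in 1.5 s sits exactly on a bin centre
        psd = compute_psd(preprocess(make_epochs(
            lambda t: np.sin(2 * np.pi * 4.0 * t))))
        k = np.argmin(np.abs(psd.freqs - 4.0))
        assert psd.power[0, 0, k] == pytest.approx(0.5, rel=0.01)

    def test_quadratic_amplitude_scaling(self):
        p1 = band_power(make_epochs(lambda t: np.sin(2 * np.pi * 4.0 * t)))
        p2 = band_power(make_epochs(lambda t: 2 * np.sin(2 * np.pi * 4.0 * t)))
        assert p2[0] / p1[0] == pytest.approx(4.0, rel=1e-6)

    def test_out_of_band_component_separable(self):
        both = band_power(make_epochs(
            lambda t: np.sin(2 * np.pi * 4.5 * t) + np.sin(2 * np.pi * 10 * t)))
        alone = band_power(make_epochs(lambda t: np.sin(2 * np.pi * 4.5 * t)))
        assert both[0] == pytest.approx(alone[0], rel=0.01)

    def test_power_conservation_multi_sinusoid(self):
        # bin-centred components at 4, 20/3 and 12 Hz with amplitudes 1, 2, 0.5
        amps = {4.0: 1.0, 20 / 3: 2.0, 12.0: 0.5}

        def sig(t):
            return sum(a * np.sin(2 * np.pi * f * t) for f, a in amps.items())

        psd = compute_psd(preprocess(make_epochs(sig)))
        # amplitude-calibrated contract: each component's centre bin reads
        # A^2/2; summed centre-bin powers equal sum(A^2/2)
        total = 0.0
        for f, a in amps.items():
            k = np.argmin(np.abs(psd.freqs - f))
            assert psd.power[0, 0, k] == pytest.approx(a ** 2 / 2, rel=0.01)
            total += psd.power[0, 0, k]
        expected = sum(a ** 2 / 2 for a in amps.values())
        assert total == pytest.approx(expected, rel=0.01)

    def test_theta_band_captures_most_of_4p4hz_power(self):
        psd = compute_psd(preprocess(make_epochs(
            lambda t: np.sin(2 * np.pi * 4.4 * t))))
        in_band = (psd.freqs >= 4) & (psd.freqs <= 5)
        frac = psd.power[0, 0, in_band].sum() / psd.power[0, 0].sum()
        assert frac > 0.9

    def test_white_noise_flat_spectrum(self):
        # straight to the FFT (the 1-30 Hz filter would shape the edges)
        rng = np.random.default_rng(7)
        epochs = EpochSet(
            data=rng.standard_normal((3000, 1, 750)), srate=SRATE,
            channels=("Fz",), pad=0.0)
        psd = compute_psd(epochs)
        in_band = (psd.freqs >= 4) & (psd.freqs <= 5)
        mean_spec = psd.power[:, 0, :].mean(axis=0)
        band_share = mean_spec[in_band].sum() / mean_spec.sum()
        assert band_share == pytest.approx(in_band.sum() / len(psd.freqs),
                                           rel=0.05)

    def test_nonfinite_samples_rejected(self):
        epochs = make_epochs(lambda t: t * 0.0)
        epochs.data[0, 0, 5] = np.nan
        epochs.pad = 0.0
        epochs.data = epochs.data[:, :, :750]
        with pytest.raises(ValueError, match="non-finite"):
            compute_psd(epochs)

    def test_empty_band_guidance(self):
        psd = compute_psd(preprocess(make_epochs(lambda t: t * 0.0)))
        with pytest.raises(ValueError, match="bin spacing"):
            extract_theta(psd, band=(4.1, 4.2))


def trial_table(subject, condition, n, looked=None, theta=1.0):
    looked = np.ones(n, dtype=bool) if looked is None else looked
    return pd.DataFrame({
        "subject": subject, "condition": condition,
        "trial": np.arange(1, n + 1), "channel": "Fz",
        "theta_power": theta, "looked": looked})


class TestInclusionRules:
    def test_boundary_eight_trials_kept(self):
        df = pd.concat([trial_table("s1", c, 8) for c in ("normal", "high")]
                       + [trial_table("s1", "variable", 9)])
        kept, report = apply_inclusion_rules(df)
        assert report["n_subjects_retained"] == 1
        # variable lost its first retained trial: 8 remain
        assert (kept.condition == "variable").sum() == 8

    def test_seven_variable_trials_excluded(self):
        df = pd.concat([trial_table("s1", c, 12) for c in ("normal", "high")]
                       + [trial_table("s1", "variable", 8)])  # 8 - first = 7
        kept, report = apply_inclusion_rules(df)
        assert kept.empty
        assert report["excluded_subjects"][0]["retained"]["variable"] == 7

    @pytest.mark.parametrize("not_looked", [(0, 1), (0, 2), (1, 2)])
    def test_first_trial_rule_interacts_with_mask(self, not_looked):
        # 10 variable trials, 2 not-looked among the first 3 -> 7 retained
        looked = np.ones(10, dtype=bool)
        looked[list(not_looked)] = False
        df = trial_table("s1", "variable", 10, looked=looked)
        kept, report = apply_inclusion_rules(df, min_trials=1)
        assert (kept.condition == "variable").sum() == 7

    def test_subject_condition_means(self):
        df = pd.concat([
            trial_table("s1", "normal", 3, theta=2.0),
            trial_table("s1", "high", 3, theta=4.0)])
        means = subject_condition_means(df.drop(columns="looked"))
        assert set(means.theta_power) == {2.0, 4.0}


class TestRecoveryFromSyntheticEpochs:
    def test_subject_condition_theta_recovered(self, small_cohort):
        """Full chain on synthetic EEG: recovered mean theta tracks the
        generated ground truth at r > 0.9 across subject x condition."""
        recovered, truth_vals = [], []
        for subj in small_cohort.subjects:
            for cond, epochs in subj.epochs.items():
                p = band_power(epochs)
                recovered.append(p.mean())
                truth_vals.append(subj.trial_theta.loc[
                    subj.trial_theta.condition == cond, "theta_true"].mean())
        r = np.corrcoef(recovered, truth_vals)[0, 1]
        assert r > 0.9
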