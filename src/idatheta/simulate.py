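"""Synthetic cohorts with known ground truth.

Everything downstream of stimulus presentation can be exercised without the
real infant recordings: the generator emits per-subject movement sequences
with looked/not-looked attrition, trial-level theta power from a lognormal
generative model, raw EEG epochs (1/f background + an embedded ~4.4 Hz
oscillation calibrated so the spectral chain recovers the requested theta),
and binary exploration/learning outcomes coupled to subject-level theta.

Generative model for trial theta at a frontal channel:

    log theta_i = log(m_c) + b0 + u_s + b_I * z_surprise_i
                  + b_T * z_trialnum_i + eps_i,
    u_s ~ N(0, tau^2),  eps_i ~ N(0, sigma_log^2),

where m_c is the condition median (variable > normal ~ high, values taken
from the published channel-Fz condition means), and the subject intercept
variance tau^2 is chosen so that subject-level condition means have
approximately the requested repeated-measures correlation.
"""

from __future__ import annotations

import functools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import spectral
from .design import DesignConfig, MovementSequence, generate_condition_sequence
from .infomeasures import PriorSpec, build_predictor_table

#: Published retained-trial ranges per condition after artifact rejection.
RETAINED_RANGES = {"normal": (11, 20), "high": (11, 20), "variable": (9, 16)}


@dataclass
class GroundTruth:
    """Generative parameters; defaults state the emulated experiment.

    ``condition_means`` are the published channel-Fz theta means
    (median-scale here); ``b_surprise``/``b_trial`` are log-scale slopes on
    the z-scored predictors; ``sigma_log`` is the trial-level lognormal
    dispersion; ``rm_correlation`` is the target correlation among a
    subject's condition means (0.7, the value assumed by the power
    analysis the study was sized with).
    """

    b0: float = 0.0
    b_surprise: float = 0.3
    b_trial: float = 0.15
    sigma_log: float = 0.6
    theta_freq: float = 4.4
    condition_means: dict[str, float] = field(default_factory=lambda: {
        "normal": 8.53, "high": 7.84, "variable": 10.35})
    rm_correlation: float = 0.7
    n_subjects: int = 23
    behavior_weight: float = 1.0
    #: base rates of the three binary outcomes in the variable condition
    behavior_base_rates: dict[str, float] = field(default_factory=lambda: {
        "success_targets_only": 12 / 22,
        "first_touch_novel": 14 / 23,
        "success_all_objects": 6 / 23})
    #: "success_high": 1 codes success / novel first touch (positive
    #: theta-outcome correlation); "success_low" flips the coding and
    #: hence the correlation sign.
    binary_coding: str = "success_high"
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be positive")
        if any(m <= 0 for m in self.condition_means.values()):
            raise ValueError("condition means must be positive")
        if not 0 <= self.rm_correlation < 1:
            raise ValueError("rm_correlation must be in [0, 1)")
        if self.binary_coding not in ("success_high", "success_low"):
            raise ValueError("binary_coding must be success_high or success_low")

    def subject_sd(self, mean_trials: float = 14.0) -> float:
        """Subject-intercept SD implied by the target repeated-measures
        correlation: rho = tau^2 / (tau^2 + sigma_log^2 / n_bar) at the
        level of subject condition means."""
        rho = self.rm_correlation
        if rho == 0:
            return 0.0
        return float(np.sqrt(rho / (1 - rho) * self.sigma_log**2 / mean_trials))


def simulate_trial_theta(predictors: pd.DataFrame, truth: GroundTruth,
                         seed: int, offset: np.ndarray | float = 0.0
                         ) -> np.ndarray:
    """Draw per-trial theta power from the lognormal generative model.

    ``offset`` is added to the linear predictor on the log scale (used for
    condition medians and subject intercepts).  Rows with missing z-scores
    (excluded trials that still need an EEG epoch) contribute zero slope.
    """
    z_s = predictors["z_surprise"].to_numpy(float)
    z_t = predictors["z_trialnum"].to_numpy(float)
    if np.isinf(z_s).any() or np.isinf(z_t).any():
        raise ValueError("predictors contain non-finite values")
    z_s = np.nan_to_num(z_s)  # NaN marks excluded trials: zero slope
    z_t = np.nan_to_num(z_t)
    rng = np.random.default_rng(seed)
    mu = truth.b0 + truth.b_surprise * z_s + truth.b_trial * z_t + offset
    eps = rng.normal(0.0, truth.sigma_log, size=len(mu))
    return np.exp(mu + eps)


@functools.lru_cache(maxsize=16)
def _sinusoid_band_gain(freq: float, srate: float, window_len: float,
                        pad: float) -> float:
    """Extracted 4-5 Hz band power of a unit-amplitude sinusoid at ``freq``
    pushed through the full spectral chain (deterministic calibration)."""
    n = round(srate * (window_len + 2 * pad))
    t = np.arange(n) / srate
    data = np.zeros((1, 5, n))
    data[0, :len(spectral.SCALP_CHANNELS), :] = np.sin(2 * np.pi * freq * t)
    epochs = spectral.EpochSet(data=data, srate=srate, pad=pad)
    clean = spectral.preprocess(epochs)
    psd = spectral.compute_psd(clean)
    table = spectral.extract_theta(psd, channels=("Fz",))
    return float(table["theta_power"].iloc[0])


@functools.lru_cache(maxsize=16)
def _noise_band_power(srate: float, window_len: float, pad: float,
                      slope: float) -> float:
    """Mean extracted theta-band power of unit-scale 1/f background noise,
    estimated once from a fixed-seed calibration batch."""
    rng = np.random.default_rng(987654321)
    n = round(srate * (window_len + 2 * pad))
    data = _one_over_f(rng, (64, 1, n), srate, slope)
    data = np.concatenate([data, np.zeros((64, 4, n))], axis=1)
    epochs = spectral.EpochSet(data=data, srate=srate, pad=pad)
    clean = spectral.preprocess(epochs)
    psd = spectral.compute_psd(clean)
    table = spectral.extract_theta(psd, channels=("Fz",))
    return float(table["theta_power"].mean())


def _one_over_f(rng: np.random.Generator, shape: tuple[int, ...],
                srate: float, slope: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^slope."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-slope / 2.0)
    spec = amp * (rng.standard_normal(shape[:-1] + (len(freqs),))
                  + 1j * rng.standard_normal(shape[:-1] + (len(freqs),)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True).clip(min=1e-30)


def simulate_epochs(trial_theta: np.ndarray, truth: GroundTruth, seed: int,
                    srate: float = 500.0, window: tuple[float, float] = (-1.0, 0.5),
                    pad: float = 0.5) -> spectral.EpochSet:
    """Forward model: trial theta -> raw padded EEG epochs.

    Each scalp epoch is 1/f background noise plus a sinusoid at
    ``truth.theta_freq`` (random phase per trial, shared across scalp
    channels) whose amplitude is calibrated so that the 4-5 Hz band power
    extracted by the spectral chain equals the requested trial theta in
    expectation (the expected noise contribution to the band is
    subtracted before scaling).  Mastoid channels carry low-amplitude
    independent noise, so mastoid re-referencing stays consistent.
    """
    theta = np.asarray(trial_theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("requested theta power must be nonnegative")
    n_trials = len(theta)
    channels = spectral.SCALP_CHANNELS + spectral.DEFAULT_MASTOIDS
    n = round(srate * (window[1] - window[0] + 2 * pad))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / srate + (window[0] - pad)

    gain = _sinusoid_band_gain(truth.theta_freq, srate, window[1] - window[0], pad)
    noise_floor = (truth.noise_scale ** 2
                   * _noise_band_power(srate, window[1] - window[0], pad, 1.0))
    target = np.clip(theta - noise_floor, 0.0, None)
    amplitude = np.sqrt(target / gain)

    data = np.zeros((n_trials, len(channels), n))
    n_scalp = len(spectral.SCALP_CHANNELS)
    if truth.noise_scale > 0:
        data[:, :n_scalp, :] = truth.noise_scale * _one_over_f(
            rng, (n_trials, n_scalp, n), srate)
        data[:, n_scalp:, :] = 0.1 * truth.noise_scale * _one_over_f(
            rng, (n_trials, len(channels) - n_scalp, n), srate)
    phase = rng.uniform(0, 2 * np.pi, size=n_trials)
    osc = amplitude[:, None] * np.sin(
        2 * np.pi * truth.theta_freq * t[None, :] + phase[:, None])
    data[:, :n_scalp, :] += osc[:, None, :]
    return spectral.EpochSet(data=data, srate=srate, channels=channels,
                             window=window, pad=pad)


def simulate_behavior(subject_theta: np.ndarray, truth: GroundTruth,
                      seed: int) -> pd.DataFrame:
    """Binary exploration/learning outcomes coupled to subject theta.

    Each outcome is Bernoulli with logit = logit(base rate) +
    behavior_weight * z(subject theta) for the two theta-linked measures
    (target success with target objects only; first touch of a
    goal-novel object) and weight 0 for all-objects success.  The
    ``binary_coding`` flag controls which direction codes 1.
    """
    theta = np.asarray(subject_theta, dtype=float)
    z = (theta - theta.mean()) / theta.std(ddof=0) if theta.std() > 0 else theta * 0
    rng = np.random.default_rng(seed)
    weights = {"success_targets_only": truth.behavior_weight,
               "first_touch_novel": truth.behavior_weight,
               "success_all_objects": 0.0}
    out = {"subject": np.arange(1, len(theta) + 1), "theta_variable": theta}
    for name, w in weights.items():
        base = truth.behavior_base_rates[name]
        p = expit(np.log(base / (1 - base)) + w * z)
        draws = (rng.uniform(size=len(theta)) < p).astype(int)
        if truth.binary_coding == "success_low":
            draws = 1 - draws
        out[name] = draws
    return pd.DataFrame(out)


@dataclass
class SimulatedSubject:
    subject_id: str
    sequences: dict[str, MovementSequence]
    predictors: pd.DataFrame           # from build_predictor_table, looked trials only
    trial_theta: pd.DataFrame          # condition, trial_overall, theta_true
    epochs: dict[str, spectral.EpochSet] | None = None


@dataclass
class SimulatedCohort:
    truth: GroundTruth
    design: DesignConfig
    subjects: list[SimulatedSubject]
    behavior: pd.DataFrame

    def predictor_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = s.predictors.merge(
                s.trial_theta, on=["condition", "trial_overall"], how="left")
            df.insert(0, "subject", s.subject_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _looked_mask(rng: np.random.Generator, n_trials: int, n_keep: int
                 ) -> np.ndarray:
    mask = np.zeros(n_trials, dtype=bool)
    mask[rng.choice(n_trials, size=n_keep, replace=False)] = True
    return mask


def simulate_cohort(truth: GroundTruth | None = None,
                    design: DesignConfig | None = None,
                    make_epochs: bool = False,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate a full cohort: sequences + attrition, predictors, trial
    theta and (optionally) raw EEG epochs, plus behavioral outcomes.

    Retained-trial counts per condition are drawn uniformly from the
    published post-rejection ranges; the variable condition keeps one
    extra looked trial because its first retained trial is excluded
    downstream.
    """
    truth = truth or GroundTruth()
    design = design or DesignConfig()
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tau = truth.subject_sd()
    subjects: list[SimulatedSubject] = []
    for i in range(truth.n_subjects):
        sid = f"S{i + 1:02d}"
        u_s = rng.normal(0.0, tau)
        sequences: dict[str, MovementSequence] = {}
        for cond in design.conditions:
            seq = generate_condition_sequence(
                DesignConfig(seed=seed + 1000 * i, n_blocks=design.n_blocks,
                             movements_per_video=design.movements_per_video,
                             n_variable_orders=design.n_variable_orders),
                cond, order_index=i % design.n_variable_orders)
            lo, hi = RETAINED_RANGES.get(cond, (design.n_trials, design.n_trials))
            n_keep = int(rng.integers(lo, hi + 1))
            if cond == "variable":
                n_keep = min(n_keep + 1, design.n_trials)
            seq.looked = _looked_mask(rng, len(seq), n_keep)
            sequences[cond] = seq
        predictors = build_predictor_table(sequences)
        offsets = (np.log([truth.condition_means[c]
                           for c in predictors["condition"]]) + u_s)
        theta = simulate_trial_theta(
            predictors, truth, seed=int(rng.integers(2**31)), offset=offsets)
        trial_theta = predictors[["condition", "trial_overall"]].copy()
        trial_theta["theta_true"] = theta
        epochs = None
        if make_epochs:
            epochs = {}
            for cond in design.conditions:
                sel = predictors["condition"] == cond
                epochs[cond] = simulate_epochs(
                    theta[sel.to_numpy()], truth,
                    seed=int(rng.integers(2**31)))
                info = predictors.loc[sel, ["trial_overall", "included"]]
                epochs[cond].trial_info = info.reset_index(drop=True)
        subjects.append(SimulatedSubject(sid, sequences, predictors,
                                         trial_theta, epochs))
    # subject-level frontal theta in the variable condition drives behavior
    subj_theta = np.array([
        s.trial_theta.loc[s.trial_theta["condition"] == "variable",
                          "theta_true"].mean()
        for s in subjects])
    behavior = simulate_behavior(subj_theta, truth, seed=int(rng.integers(2**31)))
    behavior["subject"] = [s.subject_id for s in subjects]
    return SimulatedCohort(truth, design, subjects, behavior)


def ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2))
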