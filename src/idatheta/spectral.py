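"""EEG processing: epoched signals -> band-limited theta power.

The chain mirrors a standard infant frequency-domain pipeline: zero-phase
1-30 Hz band-pass on padded epochs, per-epoch demeaning, re-referencing to
the average of the mastoids, linear detrending, a Hann-tapered FFT over the
-1.0..+0.5 s analysis window (3-30 Hz retained), and extraction of mean
power in the 4-5 Hz theta band at fronto-central channels.

Power normalization contract: a unit-amplitude sinusoid centred on an FFT
bin yields band power 0.5 (= A^2/2), i.e. taper gain is compensated.  With
the 1.5 s window the bin spacing is 2/3 Hz, so the closed 4-5 Hz band
contains the bins at 4.000 and 4.667 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

DEFAULT_BAND = (4.0, 5.0)
DEFAULT_MASTOIDS = ("M1", "M2")
SCALP_CHANNELS = ("Fz", "FCz", "Cz")


@dataclass
class EpochSet:
    """Epoched EEG for one subject: trials x channels x samples.

    ``window`` is the analysis window in seconds relative to the
    goal-attainment event; ``pad`` seconds of extra signal on each side are
    present until :func:`preprocess` crops them (filter padding).
    """

    data: np.ndarray
    srate: float = 500.0
    channels: tuple[str, ...] = SCALP_CHANNELS + DEFAULT_MASTOIDS
    window: tuple[float, float] = (-1.0, 0.5)
    pad: float = 0.5
    trial_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        expected = round(self.srate * (self.window_length + 2 * self.pad))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"expected {expected} samples per epoch "
                f"(window {self.window} s + 2x{self.pad} s pad at {self.srate} Hz), "
                f"got {self.data.shape[2]}")

    @property
    def window_length(self) -> float:
        return self.window[1] - self.window[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None


@dataclass
class PowerSpectrum:
    """Per-trial power spectra on a common frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # trials x channels x freqs
    channels: tuple[str, ...]
    normalization: str = (
        "one-sided Hann-tapered FFT; bin-centred unit-amplitude sinusoid "
        "-> band power 0.5 (taper coherent gain compensated)")

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def preprocess(epochs: EpochSet, mastoids: tuple[str, str] = DEFAULT_MASTOIDS,
               band: tuple[float, float] = (1.0, 30.0)) -> EpochSet:
    """Band-pass, crop padding, demean, mastoid re-reference, detrend.

    The zero-phase (forward-backward) 4th-order Butterworth band-pass is
    applied on the padded epochs; the padding is then cropped so filter
    edge effects fall outside the analysis window.
    """
    missing = [m for m in mastoids if m not in epochs.channels]
    if missing:
        raise ValueError(f"mastoid channels missing: {missing}")
    if epochs.pad <= 0:
        raise ValueError("preprocess requires padded epochs (pad > 0)")
    n_pad = round(epochs.pad * epochs.srate)
    sos = signal.butter(4, band, btype="bandpass", fs=epochs.srate, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    data = data[:, :, n_pad:data.shape[2] - n_pad]
    data = data - data.mean(axis=-1, keepdims=True)
    m_idx = [epochs.channel_index(m) for m in mastoids]
    data = data - data[:, m_idx, :].mean(axis=1, keepdims=True)
    data = signal.detrend(data, axis=-1, type="linear")
    return replace(epochs, data=data, pad=0.0)


def compute_psd(epochs: EpochSet, fmin: float = 3.0,
                fmax: float = 30.0) -> PowerSpectrum:
    """Hann-tapered FFT power per trial and channel, 3-30 Hz retained."""
    if not np.all(np.isfinite(epochs.data)):
        raise ValueError("epochs contain non-finite samples")
    if epochs.pad:
        raise ValueError("compute_psd expects preprocessed (pad-free) epochs")
    n = epochs.data.shape[2]
    taper = signal.windows.hann(n, sym=False)
    spec = np.fft.rfft(epochs.data * taper, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.srate)
    power = 2.0 * np.abs(spec) ** 2 / taper.sum() ** 2
    keep = (freqs >= fmin) & (freqs <= fmax)
    return PowerSpectrum(freqs=freqs[keep], power=power[:, :, keep],
                         channels=epochs.channels)


def extract_theta(psd: PowerSpectrum, band: tuple[float, float] = DEFAULT_BAND,
                  channels: tuple[str, ...] = SCALP_CHANNELS,
                  trial_info: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean power over bins whose centre lies in the closed band.

    Returns a long table with one row per trial x channel and columns
    ``trial``, ``channel``, ``theta_power`` (plus any columns of
    ``trial_info``, aligned on trial order).
    """
    in_band = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not in_band.any():
        spacing = np.diff(psd.freqs).min()
        raise ValueError(
            f"no FFT bins inside band {band}; bin spacing is {spacing:.4g} Hz — "
            "use a longer epoch for finer resolution or widen the band")
    rows = []
    for ch in channels:
        ci = psd.channels.index(ch) if ch in psd.channels else None
        if ci is None:
            raise ValueError(f"channel {ch!r} absent from spectrum")
        theta = psd.power[:, ci, :][:, in_band].mean(axis=1)
        for t, val in enumerate(theta):
            rows.append({"trial": t + 1, "channel": ch, "theta_power": float(val)})
    out = pd.DataFrame(rows)
    if trial_info is not None:
        info = trial_info.reset_index(drop=True).copy()
        info["trial"] = np.arange(1, len(info) + 1)
        out = out.merge(info, on="trial", how="left")
    return out


def subject_condition_means(theta_trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial-level theta table to subject x condition x channel means."""
    keys = [k for k in ("subject", "condition", "channel") if k in theta_trials]
    return (theta_trials.groupby(keys, as_index=False)["theta_power"]
            .mean())


def apply_inclusion_rules(theta_trials: pd.DataFrame, min_trials: int = 8
                          ) -> tuple[pd.DataFrame, dict]:
    """Apply the trial/subject retention rules; return table + report.

    In order: (1) drop trials the infant did not look at; (2) in the
    variable condition drop each subject's first remaining trial (it
    carries no information about the movement variability); (3) drop
    subjects with fewer than ``min_trials`` retained trials in any
    condition ("at least eight" is inclusive).  The report lists per-rule
    counts and per-subject exclusion reasons.
    """
    df = theta_trials.reset_index(drop=True)
    required = {"subject", "condition", "trial"}
    if not required <= set(df.columns):
        raise ValueError(f"trial table must have columns {sorted(required)}")
    if "looked" not in df:
        df["looked"] = True

    report: dict = {"min_trials": min_trials, "dropped_not_looked": 0,
                    "dropped_first_variable": 0, "excluded_subjects": []}
    n0 = df[["subject", "condition", "trial"]].drop_duplicates().shape[0]
    df = df[df["looked"]].drop(columns="looked")
    report["dropped_not_looked"] = n0 - df[["subject", "condition", "trial"]
                                           ].drop_duplicates().shape[0]

    drop_idx = []
    for subj, grp in df[df["condition"] == "variable"].groupby("subject"):
        first_trial = grp["trial"].min()
        drop_idx.extend(grp.index[grp["trial"] == first_trial])
        report["dropped_first_variable"] += 1
    df = df.drop(index=drop_idx)

    counts = (df[["subject", "condition", "trial"]].drop_duplicates()
              .groupby(["subject", "condition"]).size().unstack(fill_value=0))
    conditions = sorted(theta_trials["condition"].unique())
    keep = []
    for subj in counts.index:
        low = {c: int(counts.loc[subj].get(c, 0)) for c in conditions
               if counts.loc[subj].get(c, 0) < min_trials}
        if low:
            report["excluded_subjects"].append(
                {"subject": subj, "reason": "insufficient retained trials",
                 "retained": {c: int(counts.loc[subj].get(c, 0))
                              for c in conditions}})
        else:
            keep.append(subj)
    df = df[df["subject"].isin(keep)].reset_index(drop=True)
    report["n_subjects_retained"] = len(keep)
    return df, report


def write_exclusion_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
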