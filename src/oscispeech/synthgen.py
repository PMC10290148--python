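"""Synthetic cohort generator: keyword behavior plus multichannel EEG epochs.

The generative model is the simplest latent-state structure consistent with
the analyses downstream. Each trial carries a standard-normal latent state z.
The five keyword outcomes are conditionally independent Bernoulli draws with
probability logistic(eta0_condition + eta1 * z); marginally over z this makes
keyword outcomes within a trial positively correlated (over-dispersed
relative to a binomial) whenever eta1 > 0, and exactly binomial when
eta1 = 0. The same z shifts the trial's log alpha and beta band power by
gamma_alpha / gamma_beta dB per unit z, on top of per-subject mean offsets
and trial-level log-normal noise.

Pre- and during-stimulus log power share a trial-level amplitude factor; the
mixing is set so the population squared correlation between pre and during
log power equals ``rho_period``. The during-stimulus alpha level is raised
by ``during_alpha_boost`` dB.

Waveforms are 1/f background noise plus narrowband-filtered Gaussian noise
(alpha centered at 10 Hz, 4-Hz bandwidth, on a parieto-occipital spatial
profile; beta centered at 20 Hz, 8-Hz bandwidth, frontal profile), a common-
mode signal shared with the earlobe electrodes (exercised by re-referencing),
and optional stereotyped blink transients. Oscillation amplitudes are
calibrated so the band power extracted by the spectrogram pipeline matches
each trial's ground-truth value.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .core import ChannelMontage, EEGEpochSet, EpochTimeline, biosemi32_montage

CONDITIONS = ("SiB", "SiSSN")

#: Center frequency and bandwidth (Hz) of the synthesized oscillations.
OSC_BANDS = {"alpha": (10.0, 4.0), "beta": (20.0, 8.0)}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design: 6 subjects x 175 trials x 2 masking
    conditions, ~50% mean intelligibility in both conditions, clearly
    correlated keyword outcomes (eta1 = 1), subject alpha/beta offsets
    spanning ~5-6 dB, a 3-dB during-stimulus alpha boost, and pre/during
    shared variance rho_period = 0.8.
    """

    n_subjects: int = 6
    n_trials_per_condition: int = 175
    sampling_rate: float = 256.0
    subject_alpha_mean: tuple[float, ...] | None = None  # dB re 1 uV^2
    subject_beta_mean: tuple[float, ...] | None = None
    gamma_alpha: float = 1.2  # dB per unit z
    gamma_beta: float = 1.2
    sigma_alpha_db: float = 3.0  # trial-to-trial sd of log band power, dB
    sigma_beta_db: float = 3.0
    eta0_SiB: float = 0.0  # keyword logit intercepts
    eta0_SiSSN: float = 0.0
    eta1: float = 1.0  # keyword logit slope on the latent state
    during_alpha_boost: float = 3.0  # dB added to alpha during the stimulus
    during_beta_boost: float = 0.0
    rho_period: float = 0.8  # pre/during shared-variance fraction (R^2)
    n_latents: int = 1  # 1: shared z; 2: separate alpha/beta latents
    noise_exponent: float = 1.0  # 1/f^exponent background slope
    noise_rms_uv: float = 4.0  # background RMS per channel, uV
    common_mode_rms_uv: float = 20.0
    sensor_noise_rms_uv: float = 0.5
    osc_coherence: float = 0.25  # across-channel coherence of each oscillation
    blink_rate: float = 1.0  # expected blink events per epoch
    blink_amplitude_uv: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_trials_per_condition <= 0:
            raise ValueError("counts must be positive")
        if self.sampling_rate < 128:
            raise ValueError("sampling_rate must be >= 128 Hz (2x the 30-Hz beta edge with margin)")
        if not 0.0 <= self.rho_period <= 1.0:
            raise ValueError("rho_period must lie in [0, 1]")
        if self.n_latents not in (1, 2):
            raise ValueError("n_latents must be 1 or 2")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be non-negative")
        if not 0.0 <= self.osc_coherence <= 1.0:
            raise ValueError("osc_coherence must lie in [0, 1]")
        finite_fields = (
            self.gamma_alpha, self.gamma_beta, self.sigma_alpha_db, self.sigma_beta_db,
            self.eta0_SiB, self.eta0_SiSSN, self.during_alpha_boost, self.during_beta_boost,
            self.noise_exponent, self.noise_rms_uv, self.common_mode_rms_uv,
            self.sensor_noise_rms_uv, self.blink_amplitude_uv,
        )
        if any(not math.isfinite(v) for v in finite_fields):
            raise ValueError("non-finite generator parameter")
        if math.isnan(self.eta1) or self.eta1 == -math.inf:
            raise ValueError("eta1 must be a number (or +inf for the all-or-none regime)")
        for band, gamma, sigma in (
            ("alpha", self.gamma_alpha, self.sigma_alpha_db),
            ("beta", self.gamma_beta, self.sigma_beta_db),
        ):
            if gamma**2 > self._shared_fraction() * sigma**2 + 1e-12:
                raise ValueError(
                    f"gamma_{band}^2 exceeds the shared variance budget "
                    f"rho_period**0.5 * sigma_{band}_db**2"
                )

    def _shared_fraction(self) -> float:
        # corr(pre, during) = shared fraction; R^2 = corr^2 = rho_period
        return math.sqrt(self.rho_period)

    def subject_means(self, band: str) -> np.ndarray:
        configured = self.subject_alpha_mean if band == "alpha" else self.subject_beta_mean
        if configured is not None:
            means = np.asarray(configured, dtype=float)
            if means.shape != (self.n_subjects,):
                raise ValueError(f"subject_{band}_mean must have length n_subjects")
            return means
        # offsets centered on the typical-subject level (a single subject sits
        # at the center, not at the end of the spread)
        n = self.n_subjects
        offsets = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
        if band == "alpha":  # ascending, span 5 dB around 15
            return 15.0 + 2.5 * offsets
        return 13.0 - 3.0 * offsets  # descending around 13: ratio crosses 1

    def eta0(self, condition: str) -> float:
        if condition == "SiB":
            return self.eta0_SiB
        if condition == "SiSSN":
            return self.eta0_SiSSN
        raise ValueError(f"unknown condition {condition!r}")


def _logistic(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(params: SynthParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the trial table: keyword outcomes, scores, and ground-truth
    log band powers, one row per (subject, condition, trial).

    Ground-truth columns carry a ``truth_`` prefix: the latent state(s), and
    pre-stimulus, during-stimulus, and combined (linear-power mean) alpha and
    beta levels in dB re 1 uV^2.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n = params.n_subjects * 2 * params.n_trials_per_condition
    subjects = np.repeat([f"S{i + 1}" for i in range(params.n_subjects)], 2 * params.n_trials_per_condition)
    conditions = np.tile(np.repeat(CONDITIONS, params.n_trials_per_condition), params.n_subjects)
    trials = np.tile(np.arange(params.n_trials_per_condition), 2 * params.n_subjects)

    z_alpha = rng.standard_normal(n)
    z_beta = z_alpha if params.n_latents == 1 else rng.standard_normal(n)
    z_kw = z_alpha if params.n_latents == 1 else (z_alpha + z_beta) / math.sqrt(2.0)

    eta0 = np.where(conditions == "SiB", params.eta0(CONDITIONS[0]), params.eta0(CONDITIONS[1]))
    with np.errstate(invalid="ignore"):
        logit = eta0 + params.eta1 * z_kw
    p = _logistic(np.nan_to_num(logit, nan=0.0, posinf=np.inf, neginf=-np.inf))
    keywords = (rng.random((n, 5)) < p[:, None]).astype(int)
    n_correct = keywords.sum(axis=1)

    out = {
        "subject": subjects,
        "condition": conditions,
        "trial": trials,
        **{f"kw{i + 1}": keywords[:, i] for i in range(5)},
        "n_correct": n_correct,
        "score": 20 * n_correct,
        "truth_z": z_kw,
        "truth_z_alpha": z_alpha,
        "truth_z_beta": z_beta,
    }

    subj_idx = np.repeat(np.arange(params.n_subjects), 2 * params.n_trials_per_condition)
    f = params._shared_fraction()
    for band, z_b, gamma, sigma, boost in (
        ("alpha", z_alpha, params.gamma_alpha, params.sigma_alpha_db, params.during_alpha_boost),
        ("beta", z_beta, params.gamma_beta, params.sigma_beta_db, params.during_beta_boost),
    ):
        mu = params.subject_means(band)[subj_idx]
        sigma_w = math.sqrt(max(f * sigma**2 - gamma**2, 0.0))
        shared = gamma * z_b + sigma_w * rng.standard_normal(n)
        sigma_period = math.sqrt((1.0 - f) * sigma**2)
        pre_db = mu + shared + sigma_period * rng.standard_normal(n)
        during_db = mu + shared + sigma_period * rng.standard_normal(n) + boost
        comb_db = 10.0 * np.log10(
            (10.0 ** (pre_db / 10.0) + 10.0 ** (during_db / 10.0)) / 2.0
        )
        out[f"truth_{band}_pre_db"] = pre_db
        out[f"truth_{band}_during_db"] = during_db
        out[f"truth_{band}_db"] = comb_db
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


#: Spatial field parameters per band: (montage group, field center override,
#: gaussian width in head-plane meters). The beta field sits fronto-medially
#: (F/FC row) rather than on the eye-adjacent Fp row, so blink removal by SSP
#: leaves most of the measured frontal beta intact.
OSC_FIELDS = {
    "alpha": ("parieto_occipital", None, 0.055),
    "beta": ("frontal", (0.0, 0.04), 0.05),
}


def _spatial_profile(
    montage: ChannelMontage,
    group: str,
    width: float = 0.055,
    center=None,
) -> np.ndarray:
    """Gaussian amplitude falloff around ``center`` (group centroid by
    default), normalized so the mean squared weight over the group's channels
    is 1 (reference channels 0)."""
    idx = montage.group_indices(group)
    if center is None:
        center = np.mean([montage.positions[montage.labels[i]] for i in idx], axis=0)
    center = np.asarray(center, dtype=float)
    g = np.zeros(len(montage.labels))
    for i, label in enumerate(montage.labels):
        if label in montage.positions:
            d = np.linalg.norm(montage.positions[label] - center)
            g[i] = np.exp(-(d**2) / (2.0 * width**2))
    g /= np.sqrt(np.mean(g[idx] ** 2))
    return g


def _band_noise(n: int, fs: float, center: float, bandwidth: float,
                rng: np.random.Generator, n_rows: int = 1) -> np.ndarray:
    """Unit-variance Gaussian noise bandpassed to [center +/- bandwidth/2];
    returns (n_rows, n) of independent realizations."""
    low, high = center - bandwidth / 2.0, center + bandwidth / 2.0
    sos = butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    pad = int(2 * fs)
    x = sosfiltfilt(sos, rng.standard_normal((n_rows, n + 2 * pad)), axis=1)[:, pad : pad + n]
    return x / x.std(axis=1, keepdims=True)


def _pink_noise(shape, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, unit variance, spectrum shaped from 1 Hz up."""
    shape = tuple(np.atleast_1d(shape))
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    nz = freqs >= 1.0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


@functools.lru_cache(maxsize=None)
def _band_power_calibration(band_name: str, fs: float) -> float:
    """Measured band power (V^2) per unit variance of the synthesized band
    noise, as seen by the default spectrogram pipeline.

    Computed once per (band, sampling rate) on a long unit-variance
    realization; the scale factor turns a target extracted band power into a
    waveform amplitude.
    """
    from . import tfr

    band = tfr.ALPHA_BAND if band_name == "alpha" else tfr.BETA_BAND
    center, bw = OSC_BANDS[band_name]
    rng = np.random.default_rng(987654321)
    n = int(40 * fs)
    x = _band_noise(n, fs, center, bw, rng)[0]
    freqs = np.arange(band.low, band.high + 0.5)
    bank = tfr.make_tapered_wavelets(freqs, fs)
    spec = tfr.spectrogram(x[None, :], bank)
    sel = spec.valid_mask.all(axis=0)
    return float(spec.power[0][:, sel].mean())


def _amplitude_envelope(
    n: int, fs: float, timeline: EpochTimeline, a_pre: float, a_during: float
) -> np.ndarray:
    """Piecewise amplitude: pre level up to stimulus onset, during level
    after, with a 100-ms raised-cosine ramp at the transition."""
    t = timeline.epoch_start + np.arange(n) / fs
    env = np.full(n, a_pre)
    ramp = 0.1
    t0 = timeline.stimulus_onset
    in_ramp = (t >= t0) & (t < t0 + ramp)
    env[t >= t0 + ramp] = a_during
    frac = (t[in_ramp] - t0) / ramp
    env[in_ramp] = a_pre + (a_during - a_pre) * 0.5 * (1 - np.cos(np.pi * frac))
    return env


def _truth_amplitude(db_value: float, band: str, fs: float) -> float:
    """Waveform amplitude (V, std of unit-variance carrier) realizing a target
    extracted band power of ``db_value`` dB re 1 uV^2."""
    power = 1e-12 * 10.0 ** (db_value / 10.0)
    return math.sqrt(power / _band_power_calibration(band, fs))


def synthesize_epoch(
    trial_row,
    montage: ChannelMontage,
    timeline: EpochTimeline,
    params: SynthParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synthesize one epoch (n_channels x n_samples, volts) for a trial row.

    The row must carry ``truth_{band}_{period}_db`` columns; oscillation
    amplitudes are calibrated so pipeline-extracted band power matches them.
    """
    fs = params.sampling_rate
    if fs < 2.0 * 30.0:
        raise ValueError("sampling rate too low for the 30-Hz beta band edge")
    n = timeline.n_samples(fs)
    n_ch = len(montage.labels)
    data = np.zeros((n_ch, n))

    ceph = montage.indices(montage.cephalic_labels)
    if params.noise_rms_uv > 0:
        data[ceph] += params.noise_rms_uv * 1e-6 * _pink_noise(
            (len(ceph), n), fs, params.noise_exponent, rng
        )

    for band in ("alpha", "beta"):
        pre_db = float(trial_row[f"truth_{band}_pre_db"])
        dur_db = float(trial_row[f"truth_{band}_during_db"])
        if np.isneginf(pre_db) and np.isneginf(dur_db):
            continue
        a_pre = _truth_amplitude(pre_db, band, fs)
        a_dur = _truth_amplitude(dur_db, band, fs)
        fc, bw = OSC_BANDS[band]
        group, field_center, width = OSC_FIELDS[band]
        profile = _spatial_profile(montage, group, width=width, center=field_center)
        kappa = params.osc_coherence
        carriers = _band_noise(n, fs, fc, bw, rng, n_rows=1 + (len(ceph) if kappa < 1 else 0))
        env = _amplitude_envelope(n, fs, timeline, a_pre, a_dur)
        if kappa >= 1:
            component = profile[:, None] * (env * carriers[0])[None, :]
        else:
            mix = np.zeros((n_ch, n))
            mix[ceph] = math.sqrt(kappa) * carriers[0][None, :] + math.sqrt(1 - kappa) * carriers[1:]
            component = profile[:, None] * mix * env[None, :]
        data += component

    if params.common_mode_rms_uv > 0:
        cm = params.common_mode_rms_uv * 1e-6 * _pink_noise(n, fs, 2.0, rng)
        data += cm[None, :]
    if params.sensor_noise_rms_uv > 0:
        data += params.sensor_noise_rms_uv * 1e-6 * rng.standard_normal((n_ch, n))
    return data


def blink_pattern(montage: ChannelMontage) -> np.ndarray:
    """Fixed frontal-dominant spatial pattern of the blink artifact (unit norm,
    zero on reference channels)."""
    eyes = np.array([0.0, 0.17])  # just anterior of the Fp row
    g = np.zeros(len(montage.labels))
    for i, label in enumerate(montage.labels):
        if label in montage.positions:
            d = np.linalg.norm(montage.positions[label] - eyes)
            g[i] = np.exp(-(d**2) / (2.0 * 0.018**2))
    return g / np.linalg.norm(g)


def inject_blinks(
    epoch: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    montage: ChannelMontage,
    sampling_rate: float,
    amplitude_uv: float = 100.0,
):
    """Add stereotyped blink transients at Poisson-distributed times.

    Each blink is a 300-ms raised-cosine bump on a fixed rank-1 frontal
    spatial pattern. Returns (modified copy, injected component array,
    pattern vector, onset sample indices) so removal can be checked exactly.
    """
    if rate < 0:
        raise ValueError("blink rate must be non-negative")
    epoch = np.asarray(epoch, dtype=float)
    out = epoch.copy()
    pattern = blink_pattern(montage)
    injected = np.zeros_like(epoch)
    dur = int(round(0.3 * sampling_rate))
    bump = amplitude_uv * 1e-6 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(dur) / dur))
    n = epoch.shape[1]
    n_events = rng.poisson(rate)
    onsets = []
    for _ in range(n_events):
        start = int(rng.integers(0, max(n - dur, 1)))
        injected[:, start : start + dur] += pattern[:, None] * bump[None, : n - start]
        onsets.append(start)
    out += injected
    return out, injected, pattern, np.array(sorted(onsets), dtype=int)


def synthesize_cohort(
    params: SynthParams,
    table: pd.DataFrame | None = None,
    montage: ChannelMontage | None = None,
    timeline: EpochTimeline | None = None,
):
    """Full synthetic cohort: behavior table plus EEG epochs with blinks.

    Epoch e draws from an independent child stream of the root seed, so any
    subset regenerates identically. Returns (EEGEpochSet, truth) where truth
    holds the blink pattern and per-epoch blink components and onsets.
    """
    montage = montage or biosemi32_montage()
    timeline = timeline or EpochTimeline()
    if table is None:
        table = simulate_behavior(params)
    n_epochs = len(table)
    n = timeline.n_samples(params.sampling_rate)
    data = np.empty((n_epochs, len(montage.labels), n))
    blink_components = np.zeros_like(data)
    blink_onsets = []
    children = np.random.SeedSequence([params.seed, 2]).spawn(n_epochs)
    for e, (_, row) in enumerate(table.iterrows()):
        rng = np.random.default_rng(children[e])
        epoch = synthesize_epoch(row, montage, timeline, params, rng)
        if params.blink_rate > 0:
            epoch, injected, _, onsets = inject_blinks(
                epoch, params.blink_rate, rng, montage, params.sampling_rate,
                amplitude_uv=params.blink_amplitude_uv,
            )
            blink_components[e] = injected
            blink_onsets.append(onsets)
        else:
            blink_onsets.append(np.array([], dtype=int))
        data[e] = epoch
    epochs = EEGEpochSet(
        data=data, montage=montage, sampling_rate=params.sampling_rate,
        timeline=timeline, info=table.reset_index(drop=True),
    )
    truth = {
        "blink_pattern": blink_pattern(montage),
        "blink_components": blink_components,
        "blink_onsets": blink_onsets,
    }
    return epochs, truth


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def save_epochs_h5(path, epochs: EEGEpochSet) -> None:
    """HDF5 layout: /data (trial x channel x sample), /labels, scalar attrs
    sampling_rate and the timeline anchors, /info as a CSV-encoded table."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("data", data=epochs.data, compression="gzip")
        h5.create_dataset(
            "labels", data=np.array(epochs.montage.labels, dtype=h5py.string_dtype())
        )
        h5.attrs["sampling_rate"] = epochs.sampling_rate
        for k, v in asdict(epochs.timeline).items():
            h5.attrs[f"timeline_{k}"] = v
        h5.attrs["info_csv"] = epochs.info.to_csv(index=False)


def load_epochs_h5(path, montage: ChannelMontage | None = None) -> EEGEpochSet:
    import io

    import h5py

    montage = montage or biosemi32_montage()
    with h5py.File(path, "r") as h5:
        data = h5["data"][()]
        labels = tuple(s.decode() if isinstance(s, bytes) else s for s in h5["labels"][()])
        if labels != montage.labels:
            raise ValueError("stored labels do not match the montage")
        timeline = EpochTimeline(**{
            k.removeprefix("timeline_"): float(v)
            for k, v in h5.attrs.items() if k.startswith("timeline_")
        })
        info = pd.read_csv(io.StringIO(h5.attrs["info_csv"]))
        return EEGEpochSet(
            data=data, montage=montage, sampling_rate=float(h5.attrs["sampling_rate"]),
            timeline=timeline, info=info,
        )
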