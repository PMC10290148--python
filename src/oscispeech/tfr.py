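"""Slepian-tapered complex-wavelet spectrograms and band-power summaries.

The single-trial spectrogram is computed by convolving each channel with a
bank of complex exponentials tapered by discrete prolate spheroidal (DPSS)
sequences. Each frequency uses a window of ``n_cycles / f`` seconds with a
fixed time-full-bandwidth product, which minimizes spectral leakage into
side lobes. Power is calibrated so a stationary sinusoid of amplitude A
yields A^2/2 (its variance) at its own frequency.

Band power is the unweighted mean of spectrogram power over the band's
frequencies (inclusive edges), the channels of the band's montage group, and
the edge-uncontaminated time bins of the requested period. Powers are in V^2
and converted to dB re 1 uV^2 as 10*log10(power / 1e-12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.signal.windows import dpss

from .core import ChannelMontage, EEGEpochSet, EpochTimeline

logger = logging.getLogger(__name__)

#: Reference power for dB conversion: 1 uV^2 expressed in V^2.
DB_REFERENCE = 1e-12

#: Default analysis grid, 2-40 Hz in 1-Hz steps.
DEFAULT_FREQS = np.arange(2.0, 41.0)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band tied to a montage channel group."""

    name: str
    low: float
    high: float
    channel_group: str

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")


ALPHA_BAND = BandDefinition("alpha", 7.0, 15.0, "parieto_occipital")
BETA_BAND = BandDefinition("beta", 13.0, 30.0, "frontal")


@dataclass
class WaveletBank:
    """DPSS-tapered complex wavelets, one window per frequency.

    wavelets[i] has shape (n_tapers, n_i) with odd n_i; ``scales[i]`` is the
    power scaling that realizes the A^2/2 sinusoid convention for freq i.
    """

    freqs: np.ndarray
    sampling_rate: float
    n_cycles: float
    time_bandwidth: float
    wavelets: list[np.ndarray]
    scales: np.ndarray
    dropped_freqs: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def half_widths(self) -> np.ndarray:
        """Per-frequency half window length in samples (edge-invalid margin)."""
        return np.array([(w.shape[1] - 1) // 2 for w in self.wavelets])


def make_tapered_wavelets(
    freqs,
    sampling_rate: float,
    n_cycles: float = 5.0,
    time_bandwidth: float = 2.0,
    epoch_duration: float | None = None,
) -> WaveletBank:
    """Build the DPSS-tapered wavelet bank.

    The window at frequency f spans ``n_cycles / f`` seconds (rounded to an
    odd number of samples so each wavelet has an exact center). The taper
    count is ``max(1, floor(time_bandwidth) - 1)``; with the default full
    time-bandwidth product of 2 this is a single taper. Frequencies whose
    window exceeds ``epoch_duration`` are dropped with a warning.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be positive and strictly increasing")
    if n_cycles <= 0:
        raise ValueError("n_cycles must be positive")
    if time_bandwidth < 2:
        raise ValueError("time_bandwidth must be >= 2 for a valid DPSS family")
    n_tapers = max(1, int(np.floor(time_bandwidth)) - 1)

    kept, wavelets, scales, dropped = [], [], [], []
    for f in freqs:
        duration = n_cycles / f
        if epoch_duration is not None and duration > epoch_duration:
            dropped.append(f)
            continue
        n = int(round(duration * sampling_rate))
        if n % 2 == 0:
            n += 1
        if n < 3:
            raise ValueError(f"window at {f} Hz has {n} samples; sampling rate too low")
        tapers = np.atleast_2d(dpss(n, time_bandwidth / 2.0, Kmax=n_tapers))
        # scipy returns unit-energy tapers when Kmax is given
        center = (n - 1) // 2
        phase = np.exp(2j * np.pi * f * (np.arange(n) - center) / sampling_rate)
        wavelets.append(tapers * phase[None, :])
        # Response of taper k to a unit-amplitude sinusoid at f is |sum(d_k)|/2;
        # scale the taper-mean power so that it equals 1/2 (i.e. A^2/2 for A=1).
        gains_sq = np.sum(tapers, axis=1) ** 2
        scales.append(2.0 / np.mean(gains_sq))
        kept.append(f)
    if dropped:
        logger.warning(
            "dropped %d frequencies with windows longer than the %.3g-s epoch: %s",
            len(dropped), epoch_duration, dropped,
        )
    if not kept:
        raise ValueError("no frequency has a window that fits in the epoch")
    return WaveletBank(
        freqs=np.asarray(kept),
        sampling_rate=sampling_rate,
        n_cycles=n_cycles,
        time_bandwidth=time_bandwidth,
        wavelets=wavelets,
        scales=np.asarray(scales),
        dropped_freqs=np.asarray(dropped),
    )


@dataclass
class Spectrogram:
    """Channel x frequency x time power array in V^2.

    ``valid_mask`` (frequency x time) marks bins whose wavelet support lies
    entirely inside the epoch; edge-contaminated bins are excluded from all
    band averages rather than zero-padded into them.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid_mask: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("power must be (n_channels, n_freqs, n_times)")


def spectrogram(
    data: np.ndarray,
    bank: WaveletBank,
    t0: float = 0.0,
) -> Spectrogram:
    """Single-epoch spectrogram: taper-mean squared magnitude of the wavelet
    transform at every sample, scaled to the A^2/2 sinusoid convention.

    ``data`` is (n_channels, n_samples) in volts (a 1-D array is treated as
    one channel). ``t0`` is the epoch-start time used for the time grid.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.ndim != 2:
        raise ValueError("data must be at most 2-D (channels x samples)")
    if np.isnan(data).any():
        raise ValueError("data contains NaN samples")
    n_ch, n_samp = data.shape
    n_f = len(bank.freqs)
    power = np.empty((n_ch, n_f, n_samp))
    valid = np.zeros((n_f, n_samp), dtype=bool)
    for i, wav in enumerate(bank.wavelets):
        n = wav.shape[1]
        if n > n_samp:
            raise ValueError(
                f"wavelet at {bank.freqs[i]} Hz ({n} samples) longer than epoch ({n_samp})"
            )
        acc = np.zeros((n_ch, n_samp))
        for w in wav:
            kernel = np.conj(w[::-1])[None, :]
            y = fftconvolve(data, kernel, mode="same", axes=1)
            acc += np.abs(y) ** 2
        power[:, i, :] = acc * (bank.scales[i] / wav.shape[0])
        half = (n - 1) // 2
        valid[i, half : n_samp - half] = True
    times = t0 + np.arange(n_samp) / bank.sampling_rate
    return Spectrogram(
        power=power,
        freqs=bank.freqs.copy(),
        times=times,
        valid_mask=valid,
        sampling_rate=bank.sampling_rate,
    )


def multitaper_stft_oracle(
    data: np.ndarray,
    bank: WaveletBank,
    sample_indices,
) -> np.ndarray:
    """Direct short-time DFT multitaper estimate at given window centers.

    Brute-force reference for :func:`spectrogram`: for each frequency and
    center, slice the window, taper it, and take the DFT coefficient at
    exactly that frequency. Returns (n_channels, n_freqs, n_centers); centers
    whose window does not fit are NaN.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    sample_indices = np.asarray(sample_indices, dtype=int)
    out = np.full((n_ch, len(bank.freqs), len(sample_indices)), np.nan)
    for i, (f, wav) in enumerate(zip(bank.freqs, bank.wavelets)):
        n = wav.shape[1]
        half = (n - 1) // 2
        tapers = np.real(wav * np.exp(-2j * np.pi * f * (np.arange(n) - half) / bank.sampling_rate))
        dft = np.exp(-2j * np.pi * f * (np.arange(n) - half) / bank.sampling_rate)
        for j, t in enumerate(sample_indices):
            if t - half < 0 or t + half >= n_samp:
                continue
            seg = data[:, t - half : t + half + 1]
            vals = np.einsum("cn,kn,n->ck", seg, tapers, dft)
            out[:, i, j] = np.mean(np.abs(vals) ** 2, axis=1) * bank.scales[i]
    return out


def _window_time_sel(spec: Spectrogram, window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    return (spec.times >= w0) & (spec.times < w1)


def band_period_power(
    spec: Spectrogram,
    band: BandDefinition,
    montage: ChannelMontage,
    window: tuple[float, float],
) -> float:
    """Mean power (V^2) over band frequencies, the band's channel group, and
    valid time bins within the half-open ``window``."""
    f_sel = (spec.freqs >= band.low) & (spec.freqs <= band.high)
    if not f_sel.any():
        raise ValueError(
            f"band [{band.low}, {band.high}] Hz has no frequencies on the grid"
        )
    ch_idx = montage.group_indices(band.channel_group)
    t_sel = _window_time_sel(spec, window)
    mask = spec.valid_mask[f_sel][:, t_sel]
    if not mask.any():
        raise ValueError(
            f"window {window} contains no valid time bins for band {band.name!r}"
        )
    block = spec.power[np.ix_(ch_idx, np.flatnonzero(f_sel), np.flatnonzero(t_sel))]
    chan_mean = block.mean(axis=0)
    return float(chan_mean[mask].mean())


def to_db(power) -> np.ndarray | float:
    """Convert power in V^2 to dB re 1 uV^2: 10*log10(power / 1e-12)."""
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive for dB conversion")
    out = 10.0 * np.log10(power / DB_REFERENCE)
    return float(out) if out.ndim == 0 else out


def from_db(db) -> np.ndarray | float:
    """Inverse of :func:`to_db`."""
    db = np.asarray(db, dtype=float)
    out = DB_REFERENCE * 10.0 ** (db / 10.0)
    return float(out) if out.ndim == 0 else out


def combine_periods(pre, during, domain: str = "linear"):
    """Combine pre- and during-stimulus power into a single per-trial value.

    ``linear`` (default) averages in the power domain; ``db`` averages the dB
    values (geometric mean of powers). Inputs and output are V^2.
    """
    pre = np.asarray(pre, dtype=float)
    during = np.asarray(during, dtype=float)
    if np.any(pre <= 0) or np.any(during <= 0):
        raise ValueError("powers must be strictly positive")
    if domain == "linear":
        out = (pre + during) / 2.0
    elif domain == "db":
        out = np.sqrt(pre * during)
    else:
        raise ValueError("domain must be 'linear' or 'db'")
    return float(out) if out.ndim == 0 else out


def channel_topography(
    specs,
    montage: ChannelMontage,
    band: tuple[float, float],
    window: tuple[float, float],
) -> pd.Series:
    """Per-cephalic-channel mean power over band frequencies, valid window
    bins, and all supplied spectrograms (epochs/subjects/conditions pooled)."""
    specs = list(specs)
    if not specs:
        raise ValueError("empty spectrogram collection")
    low, high = band
    ceph = montage.indices(montage.cephalic_labels)
    total = np.zeros(len(ceph))
    count = 0
    for spec in specs:
        f_sel = (spec.freqs >= low) & (spec.freqs <= high)
        t_sel = _window_time_sel(spec, window)
        mask = spec.valid_mask[f_sel][:, t_sel]
        if not mask.any():
            raise ValueError(f"window {window} has no valid bins")
        block = spec.power[np.ix_(ceph, np.flatnonzero(f_sel), np.flatnonzero(t_sel))]
        total += block[:, mask].mean(axis=1)
        count += 1
    return pd.Series(total / count, index=list(montage.cephalic_labels), name="power_v2")


def topography_proportion_change(during_map: pd.Series, pre_map: pd.Series) -> pd.Series:
    """Element-wise (during - pre) / pre proportion-change map."""
    pre = pre_map.astype(float)
    if (pre <= 0).any():
        raise ValueError("pre-stimulus map must be strictly positive")
    out = (during_map.astype(float) - pre) / pre
    out.name = "proportion_change"
    return out


def power_ratio(alpha_power, beta_power):
    """Linear alpha-to-beta power ratio (dimensionless)."""
    alpha_power = np.asarray(alpha_power, dtype=float)
    beta_power = np.asarray(beta_power, dtype=float)
    if np.any(alpha_power <= 0) or np.any(beta_power <= 0):
        raise ValueError("powers must be strictly positive")
    out = alpha_power / beta_power
    return float(out) if out.ndim == 0 else out


def ratio_summary(table: pd.DataFrame, alpha_col: str = "alpha_db", beta_col: str = "beta_db") -> pd.DataFrame:
    """Per-subject violin statistics of the alpha-to-beta power ratio:
    median, central 50% and central 95% intervals."""
    ratio = from_db(table[alpha_col].to_numpy()) / from_db(table[beta_col].to_numpy())
    df = pd.DataFrame({"subject": table["subject"], "ratio": ratio})
    qs = df.groupby("subject")["ratio"].quantile([0.025, 0.25, 0.5, 0.75, 0.975]).unstack()
    qs.columns = ["q025", "q25", "median", "q75", "q975"]
    return qs.reset_index()


def extract_band_power_table(
    epochs: EEGEpochSet,
    bands: tuple[BandDefinition, ...] = (ALPHA_BAND, BETA_BAND),
    freqs=None,
    n_cycles: float = 5.0,
    time_bandwidth: float = 2.0,
    combine_domain: str = "linear",
    return_spectrograms: bool = False,
):
    """Reduce an epoch set to a per-trial band-power table.

    For every epoch and band, averages the spectrogram over band frequencies
    and group channels separately in the pre- and during-stimulus windows,
    then combines the two periods. Output columns per band: ``{name}_pre_db``,
    ``{name}_during_db``, ``{name}_db``, joined to the epoch metadata.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    tl: EpochTimeline = epochs.timeline
    bank = make_tapered_wavelets(
        freqs, epochs.sampling_rate, n_cycles=n_cycles,
        time_bandwidth=time_bandwidth, epoch_duration=tl.duration,
    )
    rows = []
    specs = []
    for e in range(len(epochs)):
        spec = spectrogram(epochs.data[e], bank, t0=tl.epoch_start)
        if return_spectrograms:
            specs.append(spec)
        row = {}
        for band in bands:
            pre = band_period_power(spec, band, epochs.montage, tl.pre_window)
            dur = band_period_power(spec, band, epochs.montage, tl.during_window)
            comb = combine_periods(pre, dur, domain=combine_domain)
            row[f"{band.name}_pre_db"] = to_db(pre)
            row[f"{band.name}_during_db"] = to_db(dur)
            row[f"{band.name}_db"] = to_db(comb)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(epochs.info):
        out = pd.concat([epochs.info.reset_index(drop=True), out], axis=1)
    if return_spectrograms:
        return out, specs
    return out
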