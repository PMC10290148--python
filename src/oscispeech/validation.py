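"""Cohort-level validation experiments: the quantitative checks that the
simulation + analysis chain is calibrated.

Each function runs a self-contained experiment (design df reproduction,
spectrogram oracle agreement, null-test calibration and power, band-power
recovery, statistical power / type-I rates, pre/during shared-variance
recovery) and returns plain numbers. The problem sizes are chosen so the
whole suite runs on one desk-scale CPU in a few minutes; see
docs/methods.md for the rationale behind each size.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import behavior, preprocess, stats, synthgen, tfr
from .core import ContinuousEEG, EpochTimeline, biosemi32_montage


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


# --- design-determined quantities ------------------------------------------


def design_degrees_of_freedom(seed: int = 0) -> dict:
    """Run the default cohort design (6 subjects x 175 trials x 2
    conditions) through the score ANOVA and the pre/during regression and
    report the design-determined degrees of freedom and counts."""
    params = synthgen.SynthParams(seed=_child_seed(seed, 1))
    table = synthgen.simulate_behavior(params)
    anova = stats.power_score_anova(table, band="alpha")
    predur = stats.pre_during_correlation(table, band="alpha")
    return {
        "n_trials": int(len(table)),
        "trials_per_condition": int((table["condition"] == "SiB").sum()),
        "score_df_num": float(anova.term("score").df_num),
        "score_df_den": float(anova.term("score").df_den),
        "pre_during_df": float(predur.extras["df"]),
    }


def timeline_geometry(sampling_rate: float = 256.0) -> dict:
    """Segment a synthetic continuous recording on the fixed trial timeline
    and report the realized epoch geometry."""
    timeline = EpochTimeline()
    montage = biosemi32_montage()
    fs = sampling_rate
    n_total = int(60 * fs)
    rng = np.random.default_rng(0)
    cont = ContinuousEEG(
        rng.standard_normal((34, n_total)) * 1e-6, montage, fs,
        events=[(int(s), "cue") for s in np.arange(2, 55, 7) * fs],
    )
    epochs = preprocess.segment_epochs(cont, timeline)
    pre = timeline.pre_window
    during = timeline.during_window
    return {
        "epoch_duration_s": epochs.data.shape[2] / fs,
        "n_samples": int(epochs.data.shape[2]),
        "pre_window_s": pre[1] - pre[0],
        "during_window_s": during[1] - during[0],
        "n_epochs": int(len(epochs)),
    }


# --- spectrogram oracle ------------------------------------------------------


def spectrogram_oracle(seed: int = 0, fs: float = 256.0) -> dict:
    """Compare the wavelet spectrogram against the direct windowed-DFT
    multitaper estimate on a 2-s noise signal, and check the A^2/2 sinusoid
    calibration with a 2-uV 10-Hz tone."""
    rng = np.random.default_rng(_child_seed(seed, 2))
    bank = tfr.make_tapered_wavelets(tfr.DEFAULT_FREQS, fs, epoch_duration=2.0)
    x = rng.standard_normal((2, int(2 * fs))) * 1e-6
    centers = np.arange(int(0.8 * fs), int(1.2 * fs), 5)
    spec = tfr.spectrogram(x, bank)
    oracle = tfr.multitaper_stft_oracle(x, bank, centers)
    ours = spec.power[:, :, centers]
    ok = ~np.isnan(oracle)
    max_rel_err = float(np.max(np.abs(ours[ok] - oracle[ok]) / np.abs(oracle[ok])))

    t = np.arange(int(3 * fs)) / fs
    tone = 2e-6 * np.cos(2 * np.pi * 10.0 * t + 0.7)
    full_bank = tfr.make_tapered_wavelets(tfr.DEFAULT_FREQS, fs)
    tone_spec = tfr.spectrogram(tone, full_bank)
    i10 = int(np.flatnonzero(tone_spec.freqs == 10.0)[0])
    peak = float(tone_spec.power[0, i10, len(t) // 2])
    return {
        "oracle_max_rel_err": max_rel_err,
        "sinusoid_peak_power_v2": peak,
        "sinusoid_rel_err": abs(peak - 2e-12) / 2e-12,
    }


# --- keyword-independence null ----------------------------------------------


def _condition_pvalues(params: synthgen.SynthParams, n_mc: int, seed: int) -> list[float]:
    table = synthgen.simulate_behavior(params)
    rng = np.random.default_rng(seed)
    out = []
    for condition in ("SiB", "SiSSN"):
        hist = behavior.histogram_from_table(table, condition)
        res = behavior.independence_test(hist, n_mc=n_mc, seed=rng)
        out.append(res.p_value)
    return out


def null_test_calibration(
    seed: int = 0, n_datasets: int = 200, n_mc: int = 500
) -> dict:
    """Type-I error and p-value uniformity of the independence test under
    the no-coupling generator (eta1 = 0, ~50% intelligibility, 1050
    sentences per dataset)."""
    pvals = []
    k = 0
    while len(pvals) < n_datasets:
        params = synthgen.SynthParams(eta1=0.0, seed=_child_seed(seed, 100 + k))
        pvals.extend(_condition_pvalues(params, n_mc, _child_seed(seed, 5000 + k)))
        k += 1
    pvals = np.array(pvals[:n_datasets])
    ks = sps.kstest(pvals, "uniform")
    return {
        "type_i_rate": float(np.mean(pvals < 0.05)),
        "ks_distance": float(ks.statistic),
        "n_datasets": int(n_datasets),
    }


def null_test_power(seed: int = 0, eta1: float = 1.5, n_datasets: int = 100,
                    n_mc: int = 500) -> dict:
    """Rejection rate of the independence test under strong keyword-state
    coupling."""
    pvals = []
    k = 0
    while len(pvals) < n_datasets:
        params = synthgen.SynthParams(eta1=eta1, seed=_child_seed(seed, 300 + k))
        pvals.extend(_condition_pvalues(params, n_mc, _child_seed(seed, 7000 + k)))
        k += 1
    rate = float(np.mean(np.array(pvals[:n_datasets]) < 0.05))
    return {"rejection_rate": rate, "eta1": eta1, "n_datasets": int(n_datasets)}


# --- band-power recovery -----------------------------------------------------


def _extract_cohort(params: synthgen.SynthParams, freqs, bands):
    table = synthgen.simulate_behavior(params)
    epochs, truth = synthgen.synthesize_cohort(params, table)
    segments = [c for c in truth["blink_components"] if c.any()]
    clean, _ = preprocess.preprocess_epochs(epochs, artifact_segments=segments or None)
    return tfr.extract_band_power_table(clean, bands=bands, freqs=freqs)


def band_power_recovery(seed: int = 0, n_epochs: int = 200) -> dict:
    """Correlation between generator ground-truth log band power and the
    pipeline-extracted value over ``n_epochs`` epochs at default noise."""
    per_cond = max(1, n_epochs // 4)  # 2 subjects x 2 conditions
    params = synthgen.SynthParams(
        n_subjects=2, n_trials_per_condition=per_cond, seed=_child_seed(seed, 3)
    )
    bp = _extract_cohort(
        params, np.arange(7.0, 31.0), (tfr.ALPHA_BAND, tfr.BETA_BAND)
    )
    return {
        "alpha_truth_correlation": float(
            np.corrcoef(bp["truth_alpha_db"], bp["alpha_db"])[0, 1]
        ),
        "beta_truth_correlation": float(
            np.corrcoef(bp["truth_beta_db"], bp["beta_db"])[0, 1]
        ),
        "n_epochs": int(len(bp)),
    }


# --- statistical power and type-I of the score models ------------------------


def score_anova_rates(
    seed: int = 0, n_power: int = 100, n_null: int = 200, trials_per_condition: int = 25
) -> dict:
    """Score-main-effect rejection rates for reduced cohorts (50 trials per
    subject): power under the default coupling and type-I with the coupling
    removed."""
    sig = 0
    for k in range(n_power):
        params = synthgen.SynthParams(
            n_trials_per_condition=trials_per_condition, seed=_child_seed(seed, 400 + k)
        )
        table = synthgen.simulate_behavior(params)
        res = stats.power_score_anova(table, band="alpha")
        sig += res.term("score").p_value < 0.05
    null_sig = 0
    for k in range(n_null):
        params = synthgen.SynthParams(
            gamma_alpha=0.0, gamma_beta=0.0,
            n_trials_per_condition=trials_per_condition, seed=_child_seed(seed, 900 + k),
        )
        table = synthgen.simulate_behavior(params)
        res = stats.power_score_anova(table, band="alpha")
        null_sig += res.term("score").p_value < 0.05
    return {
        "power": sig / n_power,
        "type_i_rate": null_sig / n_null,
        "n_power_cohorts": n_power,
        "n_null_cohorts": n_null,
    }


def multinomial_contribution_rates(
    seed: int = 0, n_cohorts: int = 100, trials_per_condition: int = 25
) -> dict:
    """Multinomial deviance partitioning on reduced cohorts: with two
    independent latents both band terms should be significant; with a
    redundant predictor (beta = alpha + noise) the beta term should reject
    at the nominal rate."""
    both = 0
    for k in range(n_cohorts):
        params = synthgen.SynthParams(
            n_latents=2, n_trials_per_condition=trials_per_condition,
            seed=_child_seed(seed, 1400 + k),
        )
        table = synthgen.simulate_behavior(params)
        res = stats.multinomial_deviance(table)
        both += (res.term("alpha").p_value < 0.05) and (res.term("beta").p_value < 0.05)
    redundant = 0
    rng = np.random.default_rng(_child_seed(seed, 4))
    for k in range(n_cohorts):
        params = synthgen.SynthParams(
            n_trials_per_condition=trials_per_condition, seed=_child_seed(seed, 1900 + k)
        )
        table = synthgen.simulate_behavior(params).copy()
        table["alpha_db"] = table["truth_alpha_db"]
        table["beta_db"] = table["truth_alpha_db"] + rng.standard_normal(len(table))
        res = stats.multinomial_deviance(table)
        redundant += res.term("beta").p_value < 0.05
    return {
        "both_significant_rate": both / n_cohorts,
        "redundant_beta_rate": redundant / n_cohorts,
        "n_cohorts": n_cohorts,
    }


# --- pre/during shared-variance recovery -------------------------------------


def rho_period_recovery(
    seed: int = 0, n_cohorts: int = 100, trials_per_condition: int = 25
) -> dict:
    """Mean pipeline-extracted pre-vs-during alpha R^2 over single-subject
    cohorts with the default shared-variance fraction (0.8).

    Single-subject cohorts isolate the trial-level shared variance that
    ``rho_period`` configures (pooling subjects would add between-subject
    variance to both periods and inflate R^2). The truth-level R^2 (from the
    generator's recorded log powers) is reported alongside the extracted
    one; their difference is the attenuation contributed by spectral
    estimation noise in the 1-s pre-stimulus window.
    """
    r2, r2_truth = [], []
    for k in range(n_cohorts):
        params = synthgen.SynthParams(
            n_subjects=1, n_trials_per_condition=trials_per_condition,
            seed=_child_seed(seed, 2400 + k),
        )
        bp = _extract_cohort(params, np.arange(7.0, 16.0), (tfr.ALPHA_BAND,))
        res = stats.pre_during_correlation(bp, band="alpha")
        r2.append(res.extras["r_squared"])
        r2_truth.append(
            float(np.corrcoef(bp["truth_alpha_pre_db"], bp["truth_alpha_during_db"])[0, 1] ** 2)
        )
    return {
        "mean_r_squared": float(np.mean(r2)),
        "truth_mean_r_squared": float(np.mean(r2_truth)),
        "configured_rho": synthgen.SynthParams().rho_period,
        "n_cohorts": n_cohorts,
    }
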