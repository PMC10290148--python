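"""Keyword scoring and the compound-binomial null model for within-trial
keyword independence.

Each trial is scored on 5 pre-determined keywords; the percent-correct score
is 20 x (number correct). Under the null hypothesis of independent keyword
outcomes, each keyword is Bernoulli(p) with p the condition's average
proportion correct, so the number correct per sentence is Binomial(5, p) and
the count of sentences with exactly x correct (out of n sentences) is
Binomial(n, q_x) with q_x the Binomial(5, p) mass. The independence test
compares the observed keyword-correct histogram to this null with a
goodness-of-fit statistic calibrated by Monte Carlo simulation from the null
itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def score_trial(keyword_outcomes) -> int:
    """Percent-correct score: 20 x number of the 5 keywords reported."""
    flags = np.asarray(keyword_outcomes)
    if flags.shape != (5,):
        raise ValueError("exactly 5 keyword outcomes are required")
    if not np.isin(flags, [0, 1]).all():
        raise ValueError("keyword outcomes must be binary")
    return int(20 * flags.sum())


@dataclass(frozen=True)
class KeywordHistogram:
    """Observed counts of sentences with x in {0..5} keywords correct."""

    condition: str
    counts: np.ndarray
    n_sentences: int
    p_hat: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (6,):
            raise ValueError("counts must have 6 bins (0..5 keywords correct)")
        if counts.sum() != self.n_sentences:
            raise ValueError("counts must sum to n_sentences")
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError("p_hat must lie in [0, 1]")


def histogram_from_table(table: pd.DataFrame, condition: str) -> KeywordHistogram:
    """Build the per-condition histogram from a trial table with an
    ``n_correct`` column; p_hat is the plug-in mean proportion correct."""
    sub = table.loc[table["condition"] == condition]
    if not len(sub):
        raise ValueError(f"no trials for condition {condition!r}")
    counts = np.bincount(sub["n_correct"].to_numpy(), minlength=6)[:6]
    n = int(counts.sum())
    p_hat = float((counts * np.arange(6)).sum() / (5.0 * n))
    return KeywordHistogram(condition=condition, counts=counts, n_sentences=n, p_hat=p_hat)


@dataclass(frozen=True)
class NullModel:
    """Compound-binomial null over keyword-correct histograms.

    q[x] is the Binomial(5, p_hat) probability of x keywords correct;
    expected[x] = n_sentences * q[x]; envelope95 holds the per-bin exact
    binomial 2.5% / 97.5% count quantiles (the null confidence band)."""

    p_hat: float
    n_keywords: int
    n_sentences: int
    q: np.ndarray
    expected: np.ndarray
    envelope95: np.ndarray

    def sample_counts(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw histograms of n_sentences independent Binomial(5, p) sentences."""
        draws = rng.binomial(self.n_keywords, self.p_hat, size=(size, self.n_sentences))
        x = np.arange(self.n_keywords + 1)
        return (draws[:, :, None] == x[None, None, :]).sum(axis=1)


def build_null(p_hat: float, n_sentences: int, n_keywords: int = 5) -> NullModel:
    """Exact compound-binomial null model for a condition."""
    if n_sentences <= 0:
        raise ValueError("n_sentences must be positive")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    x = np.arange(n_keywords + 1)
    q = sps.binom.pmf(x, n_keywords, p_hat)
    expected = n_sentences * q
    lo = sps.binom.ppf(0.025, n_sentences, q)
    hi = sps.binom.ppf(0.975, n_sentences, q)
    envelope = np.stack([lo, hi], axis=1).astype(int)
    return NullModel(
        p_hat=float(p_hat), n_keywords=n_keywords, n_sentences=int(n_sentences),
        q=q, expected=expected, envelope95=envelope,
    )


def _gof_statistic(counts: np.ndarray, expected: np.ndarray, statistic: str) -> float:
    nz = expected > 0
    if statistic == "chi2":
        return float(((counts[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    if statistic == "loglik":  # G^2 likelihood-ratio statistic
        c = counts[nz]
        e = expected[nz]
        pos = c > 0
        return float(2.0 * (c[pos] * np.log(c[pos] / e[pos])).sum())
    raise ValueError("statistic must be 'chi2' or 'loglik'")


@dataclass(frozen=True)
class IndependenceTestResult:
    condition: str
    statistic: float
    statistic_name: str
    p_value: float
    n_mc: int
    null: NullModel
    observed: np.ndarray


def _mc_statistics(sims: np.ndarray, null: NullModel, statistic: str,
                   refit_p: bool) -> np.ndarray:
    """Goodness-of-fit statistics for simulated histograms, each replicate
    compared to expected counts at its own plug-in p (parametric bootstrap
    with re-estimation) or at the fixed null p."""
    n = null.n_sentences
    x = np.arange(null.n_keywords + 1)
    if refit_p:
        p_m = np.clip(
            (sims * x).sum(axis=1) / (null.n_keywords * n), 1e-12, 1 - 1e-12
        )[:, None]
        expected = n * sps.binom.pmf(x[None, :], null.n_keywords, p_m)
    else:
        expected = np.broadcast_to(null.expected, sims.shape)
    nz = expected > 0
    if statistic == "chi2":
        terms = np.where(nz, (sims - expected) ** 2 / np.where(nz, expected, 1.0), 0.0)
        return terms.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = sims * np.log(sims / np.where(nz, expected, 1.0))
    return 2.0 * np.where(sims > 0, logs, 0.0).sum(axis=1)


def independence_test(
    hist: KeywordHistogram,
    null: NullModel | None = None,
    n_mc: int = 2000,
    seed: int | np.random.Generator = 0,
    statistic: str = "chi2",
    refit_p: bool = True,
) -> IndependenceTestResult:
    """Monte-Carlo goodness-of-fit test of keyword independence.

    The statistic (Pearson chi-square by default, or the G^2 log-likelihood
    ratio) compares the observed histogram to the compound-binomial expected
    counts at the plug-in p_hat; its null distribution is simulated by
    drawing n_sentences independent Binomial(5, p_hat) sentences per
    replicate. Because p_hat is estimated from the data being tested, each
    replicate's statistic is by default computed against expected counts at
    the replicate's own re-estimated p (a parametric bootstrap), which keeps
    the test calibrated; ``refit_p=False`` keeps the fixed-p comparison,
    which is conservative. The p-value uses the add-one rule
    (1 + #{MC >= observed}) / (n_mc + 1), so it is never 0.
    """
    if null is None:
        null = build_null(hist.p_hat, hist.n_sentences)
    if null.n_sentences != hist.n_sentences:
        raise ValueError("histogram and null model disagree on n_sentences")
    if n_mc < 100:
        warnings.warn("n_mc < 100 gives a very coarse p-value", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed_stat = _gof_statistic(hist.counts, null.expected, statistic)
    sims = null.sample_counts(rng, size=n_mc)
    mc = _mc_statistics(sims, null, statistic, refit_p)
    p = (1.0 + np.sum(mc >= observed_stat - 1e-12)) / (n_mc + 1.0)
    return IndependenceTestResult(
        condition=hist.condition, statistic=observed_stat, statistic_name=statistic,
        p_value=float(p), n_mc=n_mc, null=null, observed=hist.counts.copy(),
    )


def keyword_null_analysis(
    table: pd.DataFrame,
    n_mc: int = 2000,
    seed: int = 0,
    statistic: str = "chi2",
) -> pd.DataFrame:
    """Per-condition histogram, null envelope, and independence p-value.

    Returns a tidy frame with one row per (condition, x) plus the test
    statistic and p-value repeated per condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for condition in sorted(table["condition"].unique()):
        hist = histogram_from_table(table, condition)
        res = independence_test(hist, n_mc=n_mc, seed=rng, statistic=statistic)
        for x in range(6):
            rows.append(
                {
                    "condition": condition,
                    "n_keywords_correct": x,
                    "observed": int(hist.counts[x]),
                    "expected": res.null.expected[x],
                    "envelope_lo": int(res.null.envelope95[x, 0]),
                    "envelope_hi": int(res.null.envelope95[x, 1]),
                    "p_hat": hist.p_hat,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
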