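"""Population-level analyses: onset-aligned PSTHs with per-bin significance,
per-neuron similarity regressions with permutation nulls, a mixed-effects
population association, and the one-sample power / sample-size formula.

Sign convention for "tutor similarity" in regressions: the dissimilarity
score (0 = perfect match, 2 = none) is reversed to a similarity axis
(``2 - score``) before regressing, so a positive slope means higher firing
for renditions more similar to the tutor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

log = logging.getLogger(__name__)

PSTH_WINDOW_S = 0.2
PSTH_BIN_S = 0.002
PSTH_SMOOTH_FWHM_S = 0.040
N_PERMUTATIONS = 1000
N_PERMUTATION_REPEATS = 20
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PopulationHistogram:
    """Mean-subtracted, smoothed population PSTH around syllable onsets."""

    bin_centers_ms: np.ndarray
    per_neuron: np.ndarray  # (n_neurons, n_bins), smoothed, spikes/s
    mean: np.ndarray
    sem: np.ndarray
    smooth_fwhm_ms: float

    @property
    def n_neurons(self) -> int:
        return self.per_neuron.shape[0]


@dataclass
class NeuronSimilarityResult:
    """Per-neuron regression of baseline-corrected rate on tutor similarity."""

    r: float
    slope: float
    n: int
    percentile: float = np.nan
    significant: bool = False


def _onset_aligned_rates(
    spikes: np.ndarray,
    onsets: np.ndarray,
    window: float,
    bin_s: float,
) -> np.ndarray:
    """Trial-averaged firing rate per bin over [-window, +window)."""
    edges = np.arange(-window, window + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    for t0 in onsets:
        rel = spikes[(spikes >= t0 - window) & (spikes < t0 + window)] - t0
        counts += np.histogram(rel, bins=edges)[0]
    return counts / (onsets.size * bin_s)


def population_psth(
    neurons: list[tuple[np.ndarray, np.ndarray]],
    window: float = PSTH_WINDOW_S,
    bin_s: float = PSTH_BIN_S,
    smooth_fwhm: float = PSTH_SMOOTH_FWHM_S,
) -> PopulationHistogram:
    """Population histogram of mean-subtracted rates around syllable onsets.

    ``neurons`` is a list of ``(spike_times, syllable_onsets)`` pairs.  For
    each neuron the onset-aligned rate over ±200 ms in 2 ms bins is computed,
    the mean over all bins is subtracted (so each neuron's trace averages
    exactly zero before smoothing), and the trace is smoothed with a
    Gaussian kernel (40 ms FWHM).  Neurons without onsets are excluded with
    a log message.
    """
    traces = []
    for spikes, onsets in neurons:
        onsets = np.asarray(onsets, float)
        if onsets.size == 0:
            log.info("neuron without onsets excluded from PSTH")
            continue
        rate = _onset_aligned_rates(np.asarray(spikes, float), onsets, window, bin_s)
        rate = rate - rate.mean()
        sigma_bins = smooth_fwhm * FWHM_TO_SIGMA / bin_s
        traces.append(gaussian_filter1d(rate, sigma_bins, mode="reflect"))
    if len(traces) < 2:
        raise ValueError("need >= 2 neurons with onsets")
    per_neuron = np.vstack(traces)
    centers = (np.arange(per_neuron.shape[1]) + 0.5) * bin_s - window
    return PopulationHistogram(
        bin_centers_ms=centers * 1000.0,
        per_neuron=per_neuron,
        mean=per_neuron.mean(axis=0),
        sem=per_neuron.std(axis=0, ddof=1) / np.sqrt(per_neuron.shape[0]),
        smooth_fwhm_ms=smooth_fwhm * 1000.0,
    )


def psth_significance(h: PopulationHistogram, alpha: float = 0.05) -> np.ndarray:
    """Pointwise per-bin significance mask for a population PSTH.

    A bin is significant when the population mean ± t_crit(alpha, n-1) × sem
    excludes zero.  Pointwise (uncorrected), matching the per-bin confidence
    bars of the source analysis; apply your own correction for exploratory
    windows.
    """
    if h.n_neurons < 2:
        raise ValueError("need >= 2 neurons")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, h.n_neurons - 1)
    return np.abs(h.mean) > t_crit * h.sem


def similarity_regression(
    rates: np.ndarray,
    similarity_scores: np.ndarray,
    min_n: int = 40,
    scores_are_distance: bool = True,
) -> NeuronSimilarityResult:
    """Pearson regression of baseline-corrected rate on tutor similarity.

    ``similarity_scores`` default to the 0-2 dissimilarity scale and are
    reversed (``2 - score``) so positive slope = higher firing for more
    tutor-similar renditions.
    """
    rates = np.asarray(rates, float)
    s = np.asarray(similarity_scores, float)
    if rates.size != s.size:
        raise ValueError("length mismatch")
    if rates.size < min_n:
        raise ValueError(f"need >= {min_n} renditions, got {rates.size}")
    sim = 2.0 - s if scores_are_distance else s
    if np.std(rates) == 0 or np.std(sim) == 0:
        log.warning("zero variance; regression undefined")
        return NeuronSimilarityResult(r=np.nan, slope=np.nan, n=rates.size)
    r = float(np.corrcoef(sim, rates)[0, 1])
    slope = r * np.std(rates, ddof=1) / np.std(sim, ddof=1)
    return NeuronSimilarityResult(r=r, slope=float(slope), n=rates.size)


def permutation_significance(
    rates: np.ndarray,
    similarity_scores: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    min_n: int = 40,
    scores_are_distance: bool = True,
) -> tuple[float, bool]:
    """Permutation test of one neuron's rate-similarity correlation.

    Shuffles the pairing between firing rate and tutor similarity
    ``n_perm`` times to build a null distribution of r; the neuron is
    flagged significant when its actual r lies above the .975 or below the
    .025 percentile of its own null.  Returns ``(percentile of actual r,
    flag)``; deterministic given the seed.
    """
    res = similarity_regression(rates, similarity_scores, min_n=min_n,
                                scores_are_distance=scores_are_distance)
    if np.isnan(res.r):
        return np.nan, False
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rates = np.asarray(rates, float)
    s = np.asarray(similarity_scores, float)
    sim = 2.0 - s if scores_are_distance else s
    n = rates.size
    zr = (rates - rates.mean()) / rates.std()
    zs = (sim - sim.mean()) / sim.std()
    perm = rng.permuted(np.tile(zr, (n_perm, 1)), axis=1)
    null_r = perm @ zs / n
    lo, hi = np.quantile(null_r, [0.025, 0.975])
    pct = float(np.mean(null_r < res.r))
    return pct, bool(res.r > hi or res.r < lo)


def population_significant_fraction(
    neuron_data: list[tuple[np.ndarray, np.ndarray]],
    n_perm: int = N_PERMUTATIONS,
    n_repeats: int = N_PERMUTATION_REPEATS,
    seed: int = 0,
    min_n: int = 40,
    scores_are_distance: bool = True,
) -> float:
    """Repeated-permutation estimate of the fraction of significant neurons.

    Each repeat runs an independent permutation test per neuron and records
    the fraction flagged; the estimate is the mean fraction across repeats.
    """
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_repeats):
        flags = []
        for rates, scores in neuron_data:
            _, flag = permutation_significance(
                rates, scores, n_perm=n_perm, seed=rng, min_n=min_n,
                scores_are_distance=scores_are_distance,
            )
            flags.append(flag)
        fracs.append(np.mean(flags))
    return float(np.mean(fracs))


def population_association(
    table: pd.DataFrame,
    min_neurons: int = 5,
    min_n: int = 40,
    scores_are_distance: bool = True,
    random_slope: bool = True,
) -> dict:
    """Mixed-effects population regression of rate on tutor similarity.

    Fits ``rate ~ similarity`` with a random intercept per neuron and (by
    default) a random slope for similarity, via statsmodels MixedLM; the
    model internals are treated as a callable contract.  ``table`` needs
    columns ``neuron``, ``rate`` and ``similarity`` (0-2 distance scale by
    default).  Returns the fixed-slope estimate with its t and p values; on
    non-convergence, falls back to a one-sample t summary of per-neuron r
    values (``fallback=True``).
    """
    counts = table.groupby("neuron").size()
    eligible = counts[counts >= min_n].index
    if len(eligible) < min_neurons:
        raise ValueError(
            f"need >= {min_neurons} neurons with >= {min_n} renditions"
        )
    df = table[table["neuron"].isin(eligible)].copy()
    df["sim_axis"] = (2.0 - df["similarity"]) if scores_are_distance else df["similarity"]
    try:
        import statsmodels.formula.api as smf

        md = smf.mixedlm(
            "rate ~ sim_axis",
            df,
            groups=df["neuron"],
            re_formula="~sim_axis" if random_slope else "1",
        )
        with np.errstate(all="ignore"):
            fit = md.fit(reml=True, method="lbfgs")
        if not fit.converged:
            raise RuntimeError("MixedLM did not converge")
        return {
            "fixed_slope": float(fit.params["sim_axis"]),
            "t": float(fit.tvalues["sim_axis"]),
            "p": float(fit.pvalues["sim_axis"]),
            "n_neurons": int(len(eligible)),
            "fallback": False,
        }
    except Exception as exc:  # non-convergence or singular fit
        log.warning("mixed model failed (%s); per-neuron r fallback", exc)
        rs = []
        for _, g in df.groupby("neuron"):
            res = similarity_regression(
                g["rate"].to_numpy(), g["sim_axis"].to_numpy(),
                min_n=min_n, scores_are_distance=False,
            )
            if not np.isnan(res.r):
                rs.append(res.r)
        t, p = stats.ttest_1samp(rs, 0.0)
        return {
            "fixed_slope": float(np.mean(rs)),
            "t": float(t),
            "p": float(p),
            "n_neurons": len(rs),
            "fallback": True,
        }


def power_sample_size(
    mu: float,
    mu0: float = 0.0,
    sigma: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.9,
) -> int:
    """One-sample, two-tailed normal power analysis.

    ``n = ceil((sigma * (z_{1-alpha/2} + z_{power}) / (mu - mu0))^2)``.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    if mu == mu0:
        raise ValueError("mu must differ from mu0")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return int(np.ceil((sigma * z / (mu - mu0)) ** 2))
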