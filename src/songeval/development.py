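"""Song-development staging from syllable-duration distributions.

Subsong syllable durations are approximately exponentially distributed; as
juveniles transition to plastic song, regular syllable types appear as peaks
and the exponential fit degrades.  A session's development index is a
Lilliefors-style goodness-of-fit statistic of the maximum-likelihood
exponential fit, scaled by a function of the number of syllables: smaller
values = more subsong-like (better exponential fit), larger = more developed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

MIN_SYLLABLES = 100


@dataclass
class DevelopmentIndex:
    session_id: str
    n_syllables: int
    gof: float  # scaled statistic; >= 0, smaller = more subsong-like
    unscaled_statistic: float  # max |ECDF - fitted exponential CDF|
    rate: float  # fitted exponential rate (1/s)


def exponential_gof(
    durations: np.ndarray,
    session_id: str = "",
    min_n: int = MIN_SYLLABLES,
    scaling: str = "sqrt",
) -> DevelopmentIndex:
    """Scaled exponential goodness-of-fit coefficient for one session.

    Fits an exponential by maximum likelihood (rate = 1/mean) and computes
    the Kolmogorov-Smirnov sup-distance between the empirical CDF and the
    fitted CDF (the Lilliefors setting: the parameter is estimated from the
    same sample; only the statistic is used, no null table).  The statistic
    is scaled by sqrt(n) by default (``scaling="n"`` multiplies by n
    instead) so sessions of 500-8000 syllables are comparable.

    The unscaled statistic is scale-equivariant: multiplying all durations
    by a constant leaves it unchanged.
    """
    d = np.asarray(durations, float)
    if d.size < min_n:
        raise ValueError(f"need >= {min_n} durations, got {d.size}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    mean = d.mean()
    stat = stats.kstest(d, "expon", args=(0.0, mean)).statistic
    if scaling == "sqrt":
        gof = stat * np.sqrt(d.size)
    elif scaling == "n":
        gof = stat * d.size
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return DevelopmentIndex(
        session_id=session_id,
        n_syllables=int(d.size),
        gof=float(gof),
        unscaled_statistic=float(stat),
        rate=float(1.0 / mean),
    )


def correlate_with_development(
    metric: np.ndarray, gof: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a per-session metric with development stage.

    Returns ``(r, two-sided p)``; requires >= 3 sessions and nonzero
    variance in both variables.
    """
    m = np.asarray(metric, float)
    g = np.asarray(gof, float)
    if m.size != g.size or m.size < 3:
        raise ValueError("need >= 3 paired sessions")
    if np.std(m) == 0 or np.std(g) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(m, g)
    return float(r), float(p)
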