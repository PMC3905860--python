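"""Scalar assay statistics.

Mutation-reporter colony screens (white/blue counts), agarose-gel
densitometry of plasmid topological forms (open circular OC, linear L,
closed circular CC), and ChIP percent immunoprecipitation all reduce to a
handful of well-defined ratios; multiple group comparisons are adjusted
with the Holm-Sidak step-down procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ColonyCount:
    """A blue/white colony screen: white colonies carry an inactivated reporter."""

    white: int
    blue: int

    def __post_init__(self) -> None:
        if self.white < 0 or self.blue < 0:
            raise ValueError("colony counts must be non-negative")

    @property
    def total(self) -> int:
        return self.white + self.blue


@dataclass
class GelQuant:
    """Band intensities of the plasmid topological forms (arbitrary units)."""

    oc: float
    l: float
    cc: float

    def __post_init__(self) -> None:
        if min(self.oc, self.l, self.cc) < 0:
            raise ValueError("band intensities must be non-negative")
        if self.oc + self.l + self.cc <= 0:
            raise ValueError("at least one band intensity must be positive")


@dataclass
class FrequencyEstimate:
    frequency: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CleavageResult:
    """Net nuclease cleavage: sample percentage minus mean control percentage."""

    f_s: float
    f_c: float

    @property
    def F(self) -> float:
        return self.f_s - self.f_c


def mutation_frequency(
    c: ColonyCount, alpha: float = 0.05, background: float = 0.0
) -> FrequencyEstimate:
    """Mutant fraction white/(white+blue) with a Wilson score interval.

    ``background`` optionally subtracts a known background mutation
    frequency (e.g. from the bacterial indicator population) from the
    point estimate and interval, floored at zero; by default frequencies
    are reported uncorrected.
    """
    if c.total == 0:
        raise ValueError("total colony count is zero")
    if not 0 <= background <= 1:
        raise ValueError("background frequency must lie in [0, 1]")
    low, high = proportion_confint(c.white, c.total, alpha=alpha, method="wilson")
    freq = c.white / c.total
    if background:
        freq = max(freq - background, 0.0)
        low = max(float(low) - background, 0.0)
        high = max(float(high) - background, 0.0)
    return FrequencyEstimate(freq, float(low), float(high), c.total)


def replicate_summary(frequencies: list[float]) -> tuple[float, float]:
    """Mean and sample s.d. of per-experiment frequencies."""
    if not frequencies:
        raise ValueError("at least one replicate frequency is required")
    arr = np.asarray(frequencies, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def fold_change(f_num: float, f_den: float) -> tuple[float, int]:
    """Ratio of two frequencies and its nearest-integer fold label."""
    if f_den <= 0:
        raise ValueError("denominator frequency must be positive")
    ratio = f_num / f_den
    return ratio, round(ratio)


def holm_sidak_adjust(
    pvalues, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjusted p-values and rejection decisions.

    Raw p-values are ranked ascending; the i-th smallest (1-based) of m is
    adjusted to ``1 - (1 - p)^(m - i + 1)`` with a running maximum to keep
    the adjusted values monotone in rank.  Hypotheses are rejected while
    the adjusted p-value is below ``alpha``.  Results are returned in the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj_sorted, 1.0)
    # step-down: reject in rank order until the first acceptance
    reject_sorted = np.zeros(m, dtype=bool)
    for i, a in enumerate(np.minimum(adj_sorted, 1.0)):
        if a < alpha:
            reject_sorted[i] = True
        else:
            break
    reject = np.empty(m, dtype=bool)
    reject[order] = reject_sorted
    return adjusted, reject


def percent_unwinding(g: GelQuant) -> float:
    """Percent of DNA in nicked (OC) or linear form: 100*(OC+L)/(OC+L+CC)."""
    return 100.0 * (g.oc + g.l) / (g.oc + g.l + g.cc)


def net_cleavage(sample: GelQuant, controls: list[GelQuant]) -> CleavageResult:
    """Net percent cleavage F = f_s - f_c.

    ``f_s`` is the sample's percent (OC+L)/(OC+L+CC); ``f_c`` the mean of
    the same percentage over the no-enzyme control lanes.
    """
    if not controls:
        raise ValueError("at least one control lane is required")
    f_s = percent_unwinding(sample)
    f_c = float(np.mean([percent_unwinding(g) for g in controls]))
    return CleavageResult(f_s=f_s, f_c=f_c)


def percent_ip(ip_signal: float, input_signal: float) -> float:
    """ChIP percent immunoprecipitation: 100 * IP / input."""
    if input_signal <= 0:
        raise ValueError("input signal must be positive")
    if ip_signal < 0:
        raise ValueError("IP signal must be non-negative")
    return 100.0 * ip_signal / input_signal


def compare_colony_counts(
    groups: dict[str, ColonyCount], alpha: float = 0.05
) -> list[dict]:
    """All pairwise two-proportion comparisons with Holm-Sidak adjustment.

    Colony screens are binomial, so group differences are assessed with
    pairwise two-proportion z-tests on the pooled counts, followed by
    step-down Sidak adjustment across the set of comparisons.
    """
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if not pairs:
        raise ValueError("need at least two groups")
    raw = []
    for a, b in pairs:
        ca, cb = groups[a], groups[b]
        pa, pb = ca.white / ca.total, cb.white / cb.total
        pool = (ca.white + cb.white) / (ca.total + cb.total)
        se = np.sqrt(pool * (1 - pool) * (1 / ca.total + 1 / cb.total))
        z = 0.0 if se == 0 else (pa - pb) / se
        raw.append(2 * sps.norm.sf(abs(z)))
    adjusted, reject = holm_sidak_adjust(raw, alpha=alpha)
    return [
        {"group_a": a, "group_b": b, "p_raw": float(p),
         "p_adjusted": float(q), "reject": bool(r)}
        for (a, b), p, q, r in zip(pairs, raw, adjusted, reject)
    ]


def compare_replicate_frequencies(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> list[dict]:
    """Pairwise Welch t-tests on per-experiment frequencies, Sidak-adjusted.

    Alternative mode for when replicate-level frequencies (rather than
    pooled counts) are the unit of analysis.
    """
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if not pairs:
        raise ValueError("need at least two groups")
    raw = [
        float(sps.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        for a, b in pairs
    ]
    adjusted, reject = holm_sidak_adjust(raw, alpha=alpha)
    return [
        {"group_a": a, "group_b": b, "p_raw": float(p),
         "p_adjusted": float(q), "reject": bool(r)}
        for (a, b), p, q, r in zip(pairs, raw, adjusted, reject)
    ]
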