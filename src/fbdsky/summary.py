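"""Posterior and replicate-level summaries: HPD intervals, ESS, coverage.

The coverage machinery follows the usual simulation-based-calibration logic:
for each replicate a data set is simulated at known parameter values, the
posterior is sampled, and the fraction of replicates whose 95% highest
posterior density (HPD) interval contains the generating value is reported
with its binomial Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["hpd_interval", "effective_sample_size", "ancestral_fraction",
           "per_fossil_ancestral_probability", "CoverageReport",
           "summarize_coverage"]


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` of the sorted samples.

    Ties between equally short windows are broken toward the lowest start.
    Requires at least 20 samples.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    k = int(np.ceil(mass * n))
    if k == n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[j]), float(x[j + k - 1])


def effective_sample_size(samples) -> float:
    """ESS via the initial positive sequence of autocorrelation pair sums.

    ``ESS = n / (1 + 2 sum_k rho_k)`` where the sum over lag pairs
    ``rho_{2t} + rho_{2t+1}`` is truncated at the first non-positive pair.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples for an ESS estimate")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        return float(n)
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / var
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))


def ancestral_fraction(k_counts, m_counts) -> float:
    """Posterior mean of k'/(k'+m') over sampled trees.

    ``k_counts``/``m_counts`` are per-sample numbers of sampled-ancestor and
    tip fossils.  Returns NaN when there are no fossils.
    """
    k = np.asarray(k_counts, dtype=float)
    m = np.asarray(m_counts, dtype=float)
    tot = k + m
    if np.all(tot == 0):
        return float("nan")
    with np.errstate(invalid="ignore"):
        frac = np.where(tot > 0, k / np.where(tot > 0, tot, 1.0), np.nan)
    return float(np.nanmean(frac))


def per_fossil_ancestral_probability(trees) -> dict[str, float]:
    """Posterior probability of each labelled fossil being ancestral.

    ``trees`` is an iterable of sampled :class:`~fbdsky.tree.FBDTree`
    posterior draws; every fossil label must appear in every tree.
    """
    counts: dict[str, int] = {}
    n = 0
    for tree in trees:
        n += 1
        for f in tree.fossils():
            counts[f.label] = counts.get(f.label, 0) + int(
                f.is_sampled_ancestor)
    if n == 0:
        return {}
    return {label: c / n for label, c in sorted(counts.items())}


@dataclass
class CoverageReport:
    """Replicate-wise recovery summary for a set of parameters."""

    parameters: list[str]
    truths: dict[str, list] = field(default_factory=dict)
    post_means: dict[str, list] = field(default_factory=dict)
    hpd_lows: dict[str, list] = field(default_factory=dict)
    hpd_highs: dict[str, list] = field(default_factory=dict)
    n_failed: int = 0

    def add_replicate(self, truth: dict, means: dict, hpds: dict):
        for par in self.parameters:
            self.truths.setdefault(par, []).append(truth[par])
            self.post_means.setdefault(par, []).append(means[par])
            lo, hi = hpds[par]
            self.hpd_lows.setdefault(par, []).append(lo)
            self.hpd_highs.setdefault(par, []).append(hi)

    @property
    def n_replicates(self) -> int:
        if not self.parameters:
            return 0
        return len(self.truths.get(self.parameters[0], []))

    def coverage(self, par: str) -> float:
        lo = np.asarray(self.hpd_lows[par])
        hi = np.asarray(self.hpd_highs[par])
        tr = np.asarray(self.truths[par])
        return float(np.mean((lo <= tr) & (tr <= hi)))

    def coverage_se(self, par: str) -> float:
        p = self.coverage(par)
        return float(np.sqrt(p * (1.0 - p) / self.n_replicates))

    def grand_mean(self, par: str) -> float:
        return float(np.mean(self.post_means[par]))

    def grand_mean_se(self, par: str) -> float:
        x = np.asarray(self.post_means[par])
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    def to_frame(self):
        import pandas as pd
        rows = []
        for par in self.parameters:
            rows.append({
                "parameter": par,
                "mean_truth": float(np.mean(self.truths[par])),
                "grand_post_mean": self.grand_mean(par),
                "grand_post_mean_se": self.grand_mean_se(par),
                "coverage": self.coverage(par),
                "coverage_se": self.coverage_se(par),
                "n_replicates": self.n_replicates,
            })
        return pd.DataFrame(rows)


def summarize_coverage(report: CoverageReport) -> str:
    """Plain-text table of a coverage report."""
    df = report.to_frame()
    return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")
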