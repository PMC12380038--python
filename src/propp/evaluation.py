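"""Operating-characteristic metrics over replicate posterior summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReplicateSummary", "rmse", "rmse_mcse", "type_one_error", "summarize_posterior"]


@dataclass(frozen=True)
class ReplicateSummary:
    """Posterior summary of one simulation replicate for one method."""

    method: str
    replicate: int
    theta_mean: float
    ci_lower: float
    ci_upper: float
    delta_mean: float | None = None
    delta_median: float | None = None


def rmse(estimates, truth: float) -> float:
    """Root mean squared error of the estimates around the known truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def rmse_mcse(estimates, truth: float) -> float:
    """Monte-Carlo standard error of the RMSE estimate (delta method).

    Var(RMSE) ≈ Var(squared errors) / (n · 4 · RMSE²); reported alongside
    every simulated RMSE so comparisons against published values can be
    judged against simulation noise.
    """
    est = np.asarray(estimates, dtype=float)
    sq = (est - truth) ** 2
    r = np.sqrt(sq.mean())
    if r == 0:
        return 0.0
    return float(np.sqrt(sq.var(ddof=1) / len(sq)) / (2.0 * r))


def type_one_error(summaries, truth: float) -> float:
    """Fraction of replicates whose 95% interval excludes the truth.

    Intervals are closed: lo ≤ truth ≤ hi counts as containing.
    """
    lo = np.asarray([s.ci_lower for s in summaries], dtype=float)
    hi = np.asarray([s.ci_upper for s in summaries], dtype=float)
    if lo.size == 0:
        raise ValueError("no summaries")
    return float(np.mean((truth < lo) | (truth > hi)))


def summarize_posterior(draws):
    """Empirical mean, median and equal-tailed 95% interval of draws."""
    d = np.asarray(draws, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two draws to summarise")
    lo, hi = np.quantile(d, [0.025, 0.975])
    return float(d.mean()), float(np.median(d)), (float(lo), float(hi))
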