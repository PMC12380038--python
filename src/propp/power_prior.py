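"""Closed-form Bernoulli posteriors for the weighted modified power prior.

The modified power prior (MPP) raises the external-data likelihood to a
power δ ∈ [0,1] that is estimated jointly with the response rate θ, with a
normalising constant C(δ) keeping the joint posterior proper.  The ProPP
additionally multiplies each external patient's log-likelihood contribution
by a propensity-based weight wᵢ ∈ [0,1], so the effective weight of patient
i is δ·wᵢ.

With a Bernoulli outcome, a uniform prior on θ and a Beta(α_δ, β_δ) prior on
δ, everything is conjugate.  Writing

    a_e = Σ wᵢyᵢ,  b_e = Σ wᵢ(1−yᵢ)   over external patients,
    a_0 = Σ wᵢyᵢ,  b_0 = Σ wᵢ(1−yᵢ)   over trial patients (wᵢ = 1 by default),

the scaling constant is C(δ) = B(δ·a_e + 1, δ·b_e + 1), the marginal
posterior of δ is

    π(δ | data) ∝ B(δ·a_e + a_0 + 1, δ·b_e + b_0 + 1) / C(δ) × π(δ),

and θ | δ ~ Beta(δ·a_e + a_0 + 1, δ·b_e + b_0 + 1).  δ is drawn by rejection
sampling with U(0,1) proposals scaled by the grid supremum of the density;
θ follows exactly from its conditional.  All Beta-function arithmetic stays
in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .data import SubjectTable

__all__ = [
    "PriorSpec",
    "WeightedCounts",
    "weighted_counts",
    "log_scaling_constant",
    "log_marginal_delta",
    "sample_delta",
    "sample_theta_given_delta",
    "effective_external_weight",
]

#: proposals per rejection-sampling batch
DEFAULT_N_PROPOSALS = 10_000

#: grid size used to locate the envelope supremum
_ENVELOPE_GRID = 2048


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the conjugate model: θ ~ U(0,1) fixed, δ ~ Beta(α_δ, β_δ)."""

    alpha_delta: float = 1.0
    beta_delta: float = 1.0

    def __post_init__(self):
        if self.alpha_delta <= 0 or self.beta_delta <= 0:
            raise ValueError("Beta prior shapes must be positive")

    @property
    def is_uniform(self) -> bool:
        return self.alpha_delta == 1.0 and self.beta_delta == 1.0

    def log_pdf(self, delta) -> np.ndarray:
        if self.is_uniform:
            return np.zeros_like(np.asarray(delta, dtype=float))
        return beta_dist.logpdf(delta, self.alpha_delta, self.beta_delta)


@dataclass(frozen=True)
class WeightedCounts:
    """Weighted sufficient statistics (responders / non-responders by source)."""

    a_e: float
    b_e: float
    a_0: float
    b_0: float

    def __post_init__(self):
        for name in ("a_e", "b_e", "a_0", "b_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def external_total(self) -> float:
        return self.a_e + self.b_e


def weighted_counts(subjects: SubjectTable, weights) -> WeightedCounts:
    """Weighted response / non-response sums split by data source."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (subjects.n,):
        raise ValueError("weights must align one-to-one with subjects")
    if np.any(w < 0):
        raise ValueError("negative weight")
    y, trial = subjects.y, subjects.z == 1
    return WeightedCounts(
        a_e=float(np.sum(w[~trial] * y[~trial])),
        b_e=float(np.sum(w[~trial] * (1 - y[~trial]))),
        a_0=float(np.sum(w[trial] * y[trial])),
        b_0=float(np.sum(w[trial] * (1 - y[trial]))),
    )


def log_scaling_constant(delta, counts: WeightedCounts):
    """log C(δ) = log B(δ·a_e + 1, δ·b_e + 1), vectorised over δ."""
    d = np.asarray(delta, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("delta must lie in [0, 1]")
    return betaln(d * counts.a_e + 1.0, d * counts.b_e + 1.0)


def log_marginal_delta(delta, counts: WeightedCounts, prior: PriorSpec = PriorSpec()):
    """Unnormalised log marginal posterior density of δ, vectorised."""
    d = np.asarray(delta, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("delta must lie in [0, 1]")
    out = (
        betaln(d * counts.a_e + counts.a_0 + 1.0, d * counts.b_e + counts.b_0 + 1.0)
        - log_scaling_constant(d, counts)
        + prior.log_pdf(d)
    )
    return out


def _log_envelope(counts: WeightedCounts, prior: PriorSpec) -> float:
    """Supremum of the log density: dense grid plus bounded local refinement."""
    grid = np.linspace(0.0, 1.0, _ENVELOPE_GRID)
    vals = log_marginal_delta(grid, counts, prior)
    if np.any(np.isposinf(vals)):
        raise RuntimeError("degenerate posterior: unbounded density for delta")
    k = int(np.argmax(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, _ENVELOPE_GRID - 1)]
    best = float(vals[k])
    if hi > lo:
        res = minimize_scalar(
            lambda d: -log_marginal_delta(d, counts, prior), bounds=(lo, hi), method="bounded"
        )
        if np.isfinite(res.fun):
            best = max(best, float(-res.fun))
    if not np.isfinite(best):
        raise RuntimeError("degenerate posterior: envelope is not finite")
    return best


def sample_delta(
    counts: WeightedCounts,
    prior: PriorSpec = PriorSpec(),
    n_proposals: int = DEFAULT_N_PROPOSALS,
    seed=None,
    min_draws: int | None = None,
    max_batches: int = 100,
):
    """Rejection-sample the marginal posterior of δ.

    Proposes δ ~ U(0,1) and accepts with probability π̃(δ)/M where M is the
    located supremum of the unnormalised density.  Returns ``(draws,
    acceptance_rate)``; the number of accepted draws is random unless
    ``min_draws`` forces additional proposal batches.

    When the external cohort carries no weight (a_e = b_e = 0) the posterior
    of δ is its prior and draws are taken directly from it.
    """
    if n_proposals < 1:
        raise ValueError("n_proposals must be >= 1")
    rng = np.random.default_rng(seed)
    if counts.external_total == 0:
        n = max(n_proposals, min_draws or 0)
        return rng.beta(prior.alpha_delta, prior.beta_delta, size=n), 1.0
    log_m = _log_envelope(counts, prior)
    draws: list[np.ndarray] = []
    proposed = accepted = 0
    target = min_draws or 1
    for _ in range(max_batches):
        cand = rng.uniform(0.0, 1.0, size=n_proposals)
        log_acc = log_marginal_delta(cand, counts, prior) - log_m
        keep = np.log(rng.uniform(size=n_proposals)) < log_acc
        draws.append(cand[keep])
        proposed += n_proposals
        accepted += int(keep.sum())
        if accepted >= target:
            break
    if accepted == 0:
        raise RuntimeError("rejection sampler accepted no draws; degenerate posterior")
    return np.concatenate(draws), accepted / proposed


def sample_theta_given_delta(delta_draws, counts: WeightedCounts, seed=None) -> np.ndarray:
    """One θ per δ draw from Beta(δ·a_e + a_0 + 1, δ·b_e + b_0 + 1)."""
    d = np.asarray(delta_draws, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("delta draws must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return rng.beta(d * counts.a_e + counts.a_0 + 1.0, d * counts.b_e + counts.b_0 + 1.0)


def effective_external_weight(external_weights, delta_draws) -> float:
    """Posterior mean of δ × Σ external wᵢ — the borrowed "patient count"."""
    w = np.asarray(external_weights, dtype=float)
    d = np.asarray(delta_draws, dtype=float)
    if d.size == 0:
        raise ValueError("no delta draws")
    return float(d.mean() * w.sum())


def conditional_theta_params(delta, counts: WeightedCounts) -> tuple[float, float]:
    """Beta parameters of θ | δ; exact path used by the fixed-δ comparators."""
    d = float(delta)
    return (d * counts.a_e + counts.a_0 + 1.0, d * counts.b_e + counts.b_0 + 1.0)
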