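"""Model / Results objects tying the propensity and power-prior stages together.

:class:`ProPPModel` is the user-facing entry point, organised the way
statsmodels organises estimators: construct the model from data, call
``fit()``, get a :class:`PowerPriorResults` carrying draws, summaries and
diagnostics.  Comparators are special cases:

* ``ProPPModel(data)``                     — the ProPP (propensity weights);
* ``ProPPModel(data, weighting="unit")``   — the plain modified power prior;
* ``FixedDeltaModel(data, delta=0)``       — Ignore (trial only, exact Beta);
* ``FixedDeltaModel(data, delta=1)``       — Pooling (exact Beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .data import SubjectTable
from .evaluation import summarize_posterior
from .power_prior import (
    DEFAULT_N_PROPOSALS,
    PriorSpec,
    WeightedCounts,
    conditional_theta_params,
    effective_external_weight,
    sample_delta,
    sample_theta_given_delta,
    weighted_counts,
)
from .propensity import PropensityFit, WeightScheme, compute_weights, fit_propensity

__all__ = ["ProPPModel", "FixedDeltaModel", "PowerPriorResults", "propp_posterior", "fixed_delta_posterior"]


@dataclass
class PowerPriorResults:
    """Posterior of (θ, δ) with summaries and borrowing diagnostics.

    ``theta_draws`` and ``delta_draws`` are paired samples from the joint
    posterior; for fixed-δ comparators the θ summaries come from the exact
    Beta posterior and draws are generated for interface uniformity.
    """

    theta_draws: np.ndarray
    delta_draws: np.ndarray
    summaries: pd.DataFrame
    effective_external_weight: float | None
    counts: WeightedCounts
    weights: np.ndarray | None
    propensity_fit: PropensityFit | None
    acceptance_rate: float | None
    n_draws: int
    seed: object
    exact_theta_params: tuple[float, float] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def theta_mean(self) -> float:
        return float(self.summaries.loc["theta", "mean"])

    @property
    def theta_interval(self) -> tuple[float, float]:
        row = self.summaries.loc["theta"]
        return (float(row["ci_lower"]), float(row["ci_upper"]))

    @property
    def delta_mean(self) -> float:
        return float(self.summaries.loc["delta", "mean"])

    def summary(self) -> str:
        """Plain-text summary table in the style of a regression printout."""
        lines = [
            "Weighted power prior posterior (binary outcome)",
            "=" * 64,
            f"{'parameter':<10}{'mean':>10}{'median':>10}{'2.5%':>10}{'97.5%':>10}",
            "-" * 64,
        ]
        for name, row in self.summaries.iterrows():
            lines.append(
                f"{name:<10}{row['mean']:>10.4f}{row['median']:>10.4f}"
                f"{row['ci_lower']:>10.4f}{row['ci_upper']:>10.4f}"
            )
        lines.append("-" * 64)
        if self.effective_external_weight is not None:
            lines.append(f"effective external weight: {self.effective_external_weight:.1f} patients")
        if self.acceptance_rate is not None:
            lines.append(f"rejection-sampler acceptance rate: {self.acceptance_rate:.3f}")
        lines.append(f"posterior draws: {self.n_draws}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "summaries": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.summaries.iterrows()
            },
            "effective_external_weight": self.effective_external_weight,
            "acceptance_rate": self.acceptance_rate,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "counts": {
                "a_e": self.counts.a_e,
                "b_e": self.counts.b_e,
                "a_0": self.counts.a_0,
                "b_0": self.counts.b_0,
            },
        }
        out.update(self.metadata)
        return out


def _summaries_from_draws(theta: np.ndarray, delta: np.ndarray) -> pd.DataFrame:
    rows = {}
    for name, draws in (("theta", theta), ("delta", delta)):
        mean, median, (lo, hi) = summarize_posterior(draws)
        rows[name] = {"mean": mean, "median": median, "ci_lower": lo, "ci_upper": hi}
    return pd.DataFrame.from_dict(rows, orient="index")


def _exact_theta_summary(a: float, b: float) -> dict:
    dist = beta_dist(a, b)
    lo, hi = dist.ppf([0.025, 0.975])
    return {
        "mean": a / (a + b),
        "median": float(dist.ppf(0.5)),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
    }


class ProPPModel:
    """Propensity-score-weighted modified power prior for a binary endpoint.

    Parameters
    ----------
    data : SubjectTable
        Trial (z=1) and external (z=0) patients with covariates.
    scheme : WeightScheme or str
        Propensity weighting scheme; default the capped trial-estimand
        ("att_trial") weights.
    prior : PriorSpec
        Beta prior on the power parameter δ (default uniform).
    weighting : {"propensity", "unit"}
        "unit" forces every weight to 1, which reduces the ProPP to the
        plain modified power prior.
    """

    def __init__(
        self,
        data: SubjectTable,
        scheme: WeightScheme | str = "att_trial",
        prior: PriorSpec | None = None,
        weighting: str = "propensity",
    ):
        if weighting not in ("propensity", "unit"):
            raise ValueError("weighting must be 'propensity' or 'unit'")
        self.data = data
        self.scheme = WeightScheme(scheme) if isinstance(scheme, str) else scheme
        self.prior = prior or PriorSpec()
        self.weighting = weighting

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates=None, **kwargs) -> "ProPPModel":
        return cls(SubjectTable(df, covariates=covariates), **kwargs)

    def fit(
        self,
        n_proposals: int = DEFAULT_N_PROPOSALS,
        min_draws: int | None = None,
        seed=None,
        weights: np.ndarray | None = None,
    ) -> PowerPriorResults:
        """Run the four-step sampler and return the posterior results.

        1. fit the membership logistic model (skipped for unit weights or
           when ``weights`` are supplied explicitly);
        2. convert fitted probabilities to borrowing weights;
        3. rejection-sample δ from its marginal posterior;
        4. draw θ from its conditional Beta given each accepted δ.
        """
        pfit = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)
        elif self.weighting == "unit":
            w = np.ones(self.data.n)
        else:
            pfit = fit_propensity(self.data)
            w = compute_weights(pfit, self.data, self.scheme)
        counts = weighted_counts(self.data, w)
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        s_delta, s_theta = ss.spawn(2)
        delta, acc = sample_delta(
            counts, self.prior, n_proposals=n_proposals, seed=s_delta, min_draws=min_draws
        )
        theta = sample_theta_given_delta(delta, counts, seed=s_theta)
        ext_w = w[self.data.z == 0]
        return PowerPriorResults(
            theta_draws=theta,
            delta_draws=delta,
            summaries=_summaries_from_draws(theta, delta),
            effective_external_weight=effective_external_weight(ext_w, delta),
            counts=counts,
            weights=w,
            propensity_fit=pfit,
            acceptance_rate=acc,
            n_draws=len(theta),
            seed=seed,
            metadata={"method": "propp" if self.weighting == "propensity" else "mpp"},
        )


class FixedDeltaModel:
    """Power prior with δ held fixed: Ignore (δ=0) and Pooling (δ=1).

    θ's posterior is the exact Beta(δ·a_e + a_0 + 1, δ·b_e + b_0 + 1);
    summaries use exact Beta quantiles, and draws are sampled from it so
    the results object has the same surface as the estimated-δ models.
    """

    def __init__(self, data: SubjectTable, delta: float, use_weights: bool = False,
                 scheme: WeightScheme | str = "att_trial"):
        if not 0.0 <= delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        self.data = data
        self.delta = float(delta)
        self.use_weights = use_weights
        self.scheme = WeightScheme(scheme) if isinstance(scheme, str) else scheme

    def fit(self, n_draws: int = DEFAULT_N_PROPOSALS, seed=None) -> PowerPriorResults:
        pfit = None
        if self.use_weights and self.delta > 0:
            pfit = fit_propensity(self.data)
            w = compute_weights(pfit, self.data, self.scheme)
        else:
            w = np.ones(self.data.n)
        counts = weighted_counts(self.data, w)
        a, b = conditional_theta_params(self.delta, counts)
        rng = np.random.default_rng(seed)
        theta = rng.beta(a, b, size=n_draws)
        delta = np.full(n_draws, self.delta)
        summ = pd.DataFrame.from_dict(
            {
                "theta": _exact_theta_summary(a, b),
                "delta": {"mean": self.delta, "median": self.delta,
                          "ci_lower": self.delta, "ci_upper": self.delta},
            },
            orient="index",
        )
        ext_w = w[self.data.z == 0]
        return PowerPriorResults(
            theta_draws=theta,
            delta_draws=delta,
            summaries=summ,
            effective_external_weight=float(self.delta * ext_w.sum()),
            counts=counts,
            weights=w,
            propensity_fit=pfit,
            acceptance_rate=None,
            n_draws=n_draws,
            seed=seed,
            exact_theta_params=(a, b),
            metadata={"method": {0.0: "ignore", 1.0: "pooling"}.get(self.delta, "fixed_delta")},
        )


def propp_posterior(
    subjects: SubjectTable,
    scheme: WeightScheme | str = "att_trial",
    prior: PriorSpec | None = None,
    n_draws: int = DEFAULT_N_PROPOSALS,
    seed=None,
    weighting: str = "propensity",
) -> PowerPriorResults:
    """Functional shorthand for ``ProPPModel(...).fit(...)``."""
    return ProPPModel(subjects, scheme=scheme, prior=prior, weighting=weighting).fit(
        n_proposals=n_draws, seed=seed
    )


def fixed_delta_posterior(
    subjects: SubjectTable, delta_fixed: float, use_weights: bool = False,
    n_draws: int = DEFAULT_N_PROPOSALS, seed=None,
) -> PowerPriorResults:
    """Functional shorthand for ``FixedDeltaModel(...).fit(...)``."""
    return FixedDeltaModel(subjects, delta_fixed, use_weights=use_weights).fit(
        n_draws=n_draws, seed=seed
    )
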