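"""Trial-membership propensity scores and borrowing weights.

The first stage of the ProPP: a logistic regression of the source indicator
z on the covariates yields, for every patient, the probability λ of being in
the internal trial given their characteristics.  λ is then converted into a
per-patient borrowing weight under one of three estimand-driven schemes:

====================  ==================  ==================
scheme                trial weight        external weight
====================  ==================  ==================
``ate``               1/λ                 1/(1−λ)
``att_trial``         1                   min{1, λ/(1−λ)}
``att_external``      (1−λ)/λ             1
====================  ==================  ==================

``att_trial`` — the default — targets the response rate in the trial
population and caps external weights at 1 so no external patient can count
for more than a trial patient.  With an intercept in the model, the logistic
MLE satisfies Σλ̂ᵢ = N₀ exactly, which bounds the total external weight by
roughly the trial sample size however large the external cohort is.

External patients whose covariate pattern never occurs in the trial (e.g. a
performance-status grade that was a trial exclusion criterion) drive λ̂ → 0
under quasi-separation; their capped odds weight is then ≈ 0 and they drop
out of the analysis rather than breaking it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import CovariateEncoding, SubjectTable

__all__ = [
    "PropensityFit",
    "WeightScheme",
    "fit_propensity",
    "compute_weights",
    "balance_summary",
    "PropensityError",
]

#: fitted probabilities at or beyond this distance from {0,1} are flagged as
#: (quasi-)separated
SEPARATION_TOL = 1e-8

#: clamp for reciprocal weights (ate / att_external schemes only)
RECIPROCAL_EPS = 1e-12


class PropensityError(RuntimeError):
    """Raised when the membership model cannot be fitted."""


@dataclass
class WeightScheme:
    """A row of the weighting-scheme table, named by its target estimand."""

    name: str = "att_trial"
    cap_at_one: bool = True

    _VALID = ("ate", "att_trial", "att_external")

    def __post_init__(self):
        if self.name not in self._VALID:
            raise ValueError(f"unknown weighting scheme {self.name!r}; choose from {self._VALID}")


@dataclass
class PropensityFit:
    """Fitted membership model: coefficients, λ̂ per subject, diagnostics."""

    coefficients: pd.Series
    lambda_: np.ndarray
    converged: bool
    separation_flags: np.ndarray
    encoding: CovariateEncoding
    deviance: float
    n_trial: int
    n: int
    n_iter: int | None = None
    warnings_: list[str] = field(default_factory=list)

    @property
    def separated(self) -> bool:
        return bool(self.separation_flags.any())

    def predict(self, subjects: SubjectTable) -> np.ndarray:
        """Apply the fitted coefficients to (possibly different) subjects."""
        X = sm.add_constant(subjects.design_matrix(self.encoding), has_constant="add")
        eta = X.to_numpy() @ self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "converged": self.converged,
            "n_separated": int(self.separation_flags.sum()),
            "deviance": self.deviance,
            "n_trial": self.n_trial,
            "n": self.n,
        }


def fit_propensity(subjects: SubjectTable, maxiter: int = 100, tol: float = 1e-8) -> PropensityFit:
    """Unpenalised logistic MLE of trial membership on the covariates.

    Raises
    ------
    PropensityError
        If one source is empty (no contrast in membership) or the IRLS
        solver fails to converge within ``maxiter`` iterations.
    """
    if subjects.n_trial == 0 or subjects.n_external == 0:
        raise PropensityError("no contrast in membership: both sources must be non-empty")
    enc = subjects.encoding()
    X = sm.add_constant(subjects.design_matrix(enc), has_constant="add")
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = sm.GLM(subjects.z, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter, tol=tol)
        caught = [str(w.message) for w in wlist]
    lam = np.asarray(res.fittedvalues, dtype=float)
    sep = (lam <= SEPARATION_TOL) | (lam >= 1.0 - SEPARATION_TOL)
    converged = bool(getattr(res, "converged", True))
    if not converged and not sep.any():
        raise PropensityError(
            f"membership model did not converge in {maxiter} iterations "
            f"(last deviance {res.deviance:.6g})"
        )
    fit = PropensityFit(
        coefficients=pd.Series(res.params, index=X.columns),
        lambda_=lam,
        converged=converged,
        separation_flags=sep,
        encoding=enc,
        deviance=float(res.deviance),
        n_trial=subjects.n_trial,
        n=subjects.n,
        n_iter=getattr(res, "fit_history", {}).get("iteration", None),
        warnings_=caught,
    )
    if sep.any():
        warnings.warn(
            f"quasi-separation: {int(sep.sum())} subjects have fitted membership "
            "probability numerically 0 or 1; their borrowing weights will be 0 "
            "(or capped) downstream",
            UserWarning,
            stacklevel=2,
        )
    return fit


def compute_weights(
    fit: PropensityFit, subjects: SubjectTable, scheme: WeightScheme | str = "att_trial"
) -> np.ndarray:
    """Per-subject borrowing weights under ``scheme`` (see module table)."""
    if isinstance(scheme, str):
        scheme = WeightScheme(scheme)
    lam = np.asarray(fit.lambda_, dtype=float)
    if len(lam) != subjects.n:
        raise ValueError("fit and subjects are not aligned")
    trial = subjects.z == 1
    w = np.empty(subjects.n)
    if scheme.name == "att_trial":
        w[trial] = 1.0
        # min{1, odds} is well-defined at both extremes of lambda
        odds = np.divide(
            lam[~trial],
            1.0 - lam[~trial],
            out=np.full((~trial).sum(), np.inf),
            where=(1.0 - lam[~trial]) > 0,
        )
        w[~trial] = np.minimum(1.0, odds) if scheme.cap_at_one else odds
    elif scheme.name == "ate":
        if np.any(lam[trial] <= RECIPROCAL_EPS) or np.any(1.0 - lam[~trial] <= RECIPROCAL_EPS):
            raise PropensityError("non-overlap: infinite weight under the ate scheme")
        w[trial] = 1.0 / lam[trial]
        w[~trial] = 1.0 / (1.0 - lam[~trial])
        if scheme.cap_at_one:
            w = np.minimum(1.0, w)
    else:  # att_external
        lam_t = np.clip(lam[trial], RECIPROCAL_EPS, None)
        w[trial] = (1.0 - lam_t) / lam_t
        w[~trial] = 1.0
        if scheme.cap_at_one:
            w = np.minimum(1.0, w)
    return w


def balance_summary(subjects: SubjectTable, weights) -> pd.DataFrame:
    """Standardised mean differences, external vs. trial, raw and weighted.

    Returns one row per encoded covariate column with ``smd_raw`` and
    ``smd_weighted``.  When the total external weight is zero the weighted
    column is reported as undefined (None) rather than NaN noise.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    X = subjects.design_matrix().to_numpy()
    names = list(subjects.design_matrix().columns)
    trial = subjects.z == 1
    xt, xe = X[trial], X[~trial]
    we = w[~trial]
    rows = []
    ext_defined = we.sum() > 0
    for j, name in enumerate(names):
        mt, me = xt[:, j].mean(), xe[:, j].mean()
        vt = xt[:, j].var(ddof=1) if len(xt) > 1 else 0.0
        ve = xe[:, j].var(ddof=1) if len(xe) > 1 else 0.0
        pooled = np.sqrt((vt + ve) / 2.0)
        smd_raw = (me - mt) / pooled if pooled > 0 else 0.0
        if ext_defined:
            mew = np.average(xe[:, j], weights=we)
            vew = np.average((xe[:, j] - mew) ** 2, weights=we)
            pooled_w = np.sqrt((vt + vew) / 2.0)
            smd_w = (mew - mt) / pooled_w if pooled_w > 0 else 0.0
        else:
            smd_w = None
        rows.append({"covariate": name, "smd_raw": smd_raw, "smd_weighted": smd_w})
    return pd.DataFrame(rows)
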