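"""Independent quadrature oracles for the conjugate power-prior posterior.

These deliberately avoid the package's log-Beta-function code path: the
normalising constant C(δ) is computed by numerical integration over θ and
the joint density is integrated on a 2-D trapezoid grid, so agreement with
the rejection sampler is a genuine cross-check.
"""

import numpy as np
from scipy.stats import beta as beta_dist


def joint_posterior_moments(counts, alpha_delta=1.0, beta_delta=1.0, n_theta=2001, n_delta=1001):
    """E[δ], Var[δ], E[θ] by 2-D trapezoid quadrature of the joint density.

    Joint (up to a constant):
        θ^(δ·a_e + a_0) (1−θ)^(δ·b_e + b_0) / C(δ) × prior(δ),
    with C(δ) itself obtained by quadrature over θ.
    """
    th = np.linspace(1e-9, 1.0 - 1e-9, n_theta)
    dl = np.linspace(0.0, 1.0, n_delta)
    log_th, log_1mth = np.log(th), np.log1p(-th)

    log_c = np.empty(n_delta)
    for i, d in enumerate(dl):
        f = d * counts.a_e * log_th + d * counts.b_e * log_1mth
        m = f.max()
        log_c[i] = m + np.log(np.trapezoid(np.exp(f - m), th))

    a = dl[:, None] * counts.a_e + counts.a_0
    b = dl[:, None] * counts.b_e + counts.b_0
    log_joint = a * log_th[None, :] + b * log_1mth[None, :] - log_c[:, None]
    if not (alpha_delta == 1.0 and beta_delta == 1.0):
        log_joint += beta_dist.logpdf(dl, alpha_delta, beta_delta)[:, None]
    joint = np.exp(log_joint - log_joint.max())

    marg_delta = np.trapezoid(joint, th, axis=1)
    z = np.trapezoid(marg_delta, dl)
    e_delta = np.trapezoid(dl * marg_delta, dl) / z
    var_delta = np.trapezoid(dl**2 * marg_delta, dl) / z - e_delta**2
    marg_theta = np.trapezoid(joint, dl, axis=0)
    e_theta = np.trapezoid(th * marg_theta, th) / np.trapezoid(marg_theta, th)
    return e_delta, var_delta, e_theta


def marginal_delta_density(counts, delta_grid, n_theta=100_001):
    """Unnormalised marginal density of δ on a grid, by θ-quadrature only."""
    th = np.linspace(1e-9, 1.0 - 1e-9, n_theta)
    log_th, log_1mth = np.log(th), np.log1p(-th)
    out = np.empty(len(delta_grid))
    for i, d in enumerate(delta_grid):
        num = (d * counts.a_e + counts.a_0) * log_th + (d * counts.b_e + counts.b_0) * log_1mth
        den = d * counts.a_e * log_th + d * counts.b_e * log_1mth
        mn, md = num.max(), den.max()
        out[i] = (
            mn + np.log(np.trapezoid(np.exp(num - mn), th))
            - md - np.log(np.trapezoid(np.exp(den - md), th))
        )
    return out
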