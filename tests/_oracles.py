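"""Independent reference solvers used only by tests."""

import numpy as np
from scipy.optimize import minimize

from crsim.trendfilter import second_difference_matrix


def trend_filter_dual_oracle(y, lam, polish_iters: int = 30):
    """Solve the trend-filter problem through its box-constrained dual QP.

    min_nu 0.5*||D2' nu||^2 - (D2 y)' nu  s.t. |nu| <= lam, then
    x* = y - D2' nu*.  L-BFGS-B provides the starting point; an exact
    active-set Newton polish (solve the reduced normal equations on the free
    variables, clip, repeat) removes the first-order solver's residual
    suboptimality.  Entirely independent of the package's ADMM route.
    """
    y = np.asarray(y, dtype=float)
    D = second_difference_matrix(y.size).toarray()
    dy = D @ y
    H = D @ D.T
    m = y.size - 2

    res = minimize(lambda nu: 0.5 * nu @ H @ nu - dy @ nu,
                   np.zeros(m), jac=lambda nu: H @ nu - dy,
                   method="L-BFGS-B", bounds=[(-lam, lam)] * m,
                   options={"maxiter": 50000, "ftol": 1e-18, "gtol": 1e-14})
    nu = np.clip(res.x, -lam, lam)
    tol = 1e-9 * max(lam, 1.0)
    for _ in range(polish_iters):
        grad = H @ nu - dy
        lower = (nu <= -lam + tol) & (grad > 0)
        upper = (nu >= lam - tol) & (grad < 0)
        active = lower | upper
        free = ~active
        nu_new = nu.copy()
        nu_new[lower] = -lam
        nu_new[upper] = lam
        if free.any():
            rhs = dy[free] - H[np.ix_(free, active)] @ nu_new[active]
            nu_new[free] = np.linalg.solve(H[np.ix_(free, free)], rhs)
        nu_new = np.clip(nu_new, -lam, lam)
        if np.allclose(nu_new, nu, atol=1e-14, rtol=0):
            nu = nu_new
            break
        nu = nu_new
    return y - D.T @ nu
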