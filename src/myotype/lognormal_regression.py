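"""Four-parameter log-normal regression of OOP against actin fraction.

The cardiomyocyte orientational order parameter as a function of the
cardiomyocyte actin fraction x is well described by the peak function

    y(x) = y0 + a * x * exp(-0.5 * (ln(x / x0) / b)^2),   x > 0,

an (inverted, for a < 0) log-normal shape whose extremum sits at
x = x0 * exp(b^2).  The fit is unconstrained nonlinear least squares
(Levenberg-Marquardt / trust region); coefficient standard errors and
p-values come from the asymptotic normal theory of the Jacobian at the
solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import uniform_filter1d


@dataclass
class LogNormalFitResult:
    a: float
    b: float
    x0: float
    y0: float
    r_squared: float  # NaN when SS_tot == 0 (undefined)
    std_errors: dict[str, float]
    p_values: dict[str, float]
    converged: bool
    n_iterations: int
    residuals: np.ndarray
    n_points: int
    n_excluded_zero_x: int = 0

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.x0, self.y0)

    @property
    def minimum_x(self) -> float:
        """Location of the curve's interior extremum, x0 * exp(b^2)."""
        return self.x0 * float(np.exp(self.b**2))

    def as_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "x0": self.x0,
            "y0": self.y0,
            "r_squared": self.r_squared,
            "std_errors": self.std_errors,
            "p_values": self.p_values,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_points": self.n_points,
            "n_excluded_zero_x": self.n_excluded_zero_x,
        }


def lognormal_eval(a: float, b: float, x0: float, y0: float, x) -> np.ndarray | float:
    """Evaluate the 4-parameter log-normal curve at x > 0."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0):
        raise ValueError("the log-normal curve is defined only for x > 0")
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if b == 0:
        raise ValueError("b must be nonzero")
    out = y0 + a * x_arr * np.exp(-0.5 * (np.log(x_arr / x0) / b) ** 2)
    return out if out.shape else float(out)


def default_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Heuristic start: dip of the smoothed data locates x0, amplitudes from range."""
    order = np.argsort(x)
    ys = uniform_filter1d(y[order], size=max(3, len(y) // 8), mode="nearest")
    y0 = float(np.max(y))
    x0 = float(np.clip(x[order][np.argmin(ys)], 1e-3, None))
    a = float((np.min(y) - np.max(y)) / x0)
    if a == 0:
        a = -0.1
    return a, 0.35, x0, y0


def fit_lognormal(
    x,
    y,
    init: tuple[float, float, float, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> LogNormalFitResult:
    """Unconstrained least-squares fit of the log-normal peak curve.

    Points with x = 0 (e.g. wells with no cardiomyocyte actin) are excluded
    with a recorded count, since the curve is undefined at 0.  A constant-y
    input is degenerate: SS_tot = 0, so ``r_squared`` is NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = x > 0
    n_excluded = int((~keep).sum())
    if np.any(x < 0):
        raise ValueError("x must be nonnegative actin fractions")
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("need at least 5 points with x > 0")

    p0 = np.asarray(init if init is not None else default_init(x, y), dtype=float)

    def resid(p):
        a, b, x0, y0 = p
        b = b if b != 0 else 1e-9
        x0 = abs(x0) if x0 != 0 else 1e-9
        return y0 + a * x * np.exp(-0.5 * (np.log(x / x0) / b) ** 2) - y

    sol = optimize.least_squares(
        resid, p0, method="lm", max_nfev=max_iter * 10, xtol=tol, ftol=tol, gtol=tol
    )
    a, b, x0, y0 = sol.x
    x0 = abs(x0)
    residuals = sol.fun
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    dof = max(x.size - 4, 1)
    names = ("a", "b", "x0", "y0")
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        cov = jtj_inv * ss_res / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    tvals = np.array([a, b, x0, y0]) / np.where(se > 0, se, np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    return LogNormalFitResult(
        a=float(a),
        b=float(b),
        x0=float(x0),
        y0=float(y0),
        r_squared=r_squared,
        std_errors=dict(zip(names, map(float, se))),
        p_values=dict(zip(names, map(float, pvals))),
        converged=bool(sol.status > 0),
        n_iterations=int(sol.nfev),
        residuals=residuals,
        n_points=int(x.size),
        n_excluded_zero_x=n_excluded,
    )
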