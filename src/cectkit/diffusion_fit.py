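"""Exponential saturation kinetics of contrast-agent uptake.

The bulk partition of one sample over immersion time follows

    P(t) = Pmax [1 - exp(-t / tau)]

where ``Pmax`` is the maximum (equilibrium) partition and ``tau`` the
diffusion time constant — the time to reach 63.2 % (1 - 1/e) of ``Pmax``.
Each sample is fitted separately by nonlinear least squares, and cohort
kinetics are the arithmetic means of the per-sample parameters with
t-distribution 95 % confidence intervals (not a pooled fit).

``Pmax`` is unbounded, including negative values: an agent that is excluded
from the tissue produces small negative partitions whose best exponential
fit can be wildly degenerate (enormous |Pmax| and tau); such fits are
reported verbatim with ``degenerate_flag`` set rather than constrained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = ["DiffusionFit", "CohortKinetics", "fit_sample", "predict", "aggregate_cohort"]

#: Fraction of Pmax reached at t = tau.
SATURATION_FRACTION = 1.0 - np.exp(-1.0)


@dataclass
class DiffusionFit:
    """Per-sample exponential fit with diagnostics."""

    p_max_pct: float
    tau_h: float
    sse: float
    degenerate_flag: bool
    covariance: np.ndarray | None = None
    n_points: int = 0

    def __iter__(self):  # convenient (p_max, tau) unpacking
        return iter((self.p_max_pct, self.tau_h))


@dataclass
class CohortKinetics:
    p_max_mean_pct: float
    p_max_ci_pct: tuple[float, float]
    tau_mean_h: float
    tau_ci_h: tuple[float, float]
    n: int


def predict(fit: DiffusionFit, t_h: np.ndarray | float) -> np.ndarray | float:
    """Partition (%) predicted at time(s) ``t_h >= 0``."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("immersion time must be non-negative")
    out = fit.p_max_pct * (1.0 - np.exp(-t / fit.tau_h))
    return float(out) if np.isscalar(t_h) else out


def _initial_guesses(times: np.ndarray, parts: np.ndarray) -> list[tuple[float, float]]:
    p0 = parts[-1]
    tau0 = times[-1] / 2.0
    if p0 != 0.0:
        frac = parts / p0
        hit = np.nonzero(frac >= SATURATION_FRACTION)[0]
        if hit.size and times[hit[0]] > 0:
            tau0 = float(times[hit[0]])
    tau0 = max(tau0, 1e-3)
    return [(p0, tau0), (p0, tau0 * 0.3), (1.5 * p0, tau0 * 3.0)]


def fit_sample(times_h: np.ndarray, partitions_pct: np.ndarray) -> DiffusionFit:
    """Nonlinear least-squares fit of P(t) = Pmax [1 - exp(-t/tau)].

    Requires at least 3 strictly increasing time points starting at 0.
    Initialization: Pmax from the last observed partition, tau from the time
    at which the partition first exceeds 63.2 % of it (fallback: half the
    observation window), with two further staggered restarts.  tau is
    bounded below at 1e-3 h; Pmax is unbounded.  ``degenerate_flag`` is set
    when the fitted tau exceeds three times the last observation (the data
    do not constrain the plateau).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(partitions_pct, dtype=float)
    if t.size != y.size:
        raise ValueError("times and partitions must have equal length")
    if t.size < 3:
        raise ValueError("at least 3 time points are required")
    if t[0] != 0.0:
        raise ValueError("the series must include the t = 0 baseline")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the series")

    if np.max(np.abs(y)) < 1e-12:
        return DiffusionFit(0.0, t[-1], 0.0, degenerate_flag=True, n_points=t.size)

    def resid(params):
        p_max, tau = params
        return p_max * (1.0 - np.exp(-t / tau)) - y

    best = None
    tried = []
    for x0 in _initial_guesses(t, y):
        res = least_squares(
            resid,
            x0,
            bounds=([-np.inf, 1e-3], [np.inf, np.inf]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        tried.append((x0, res.status, float(res.cost)))
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(f"exponential fit did not converge; attempts: {tried}")

    p_max, tau = best.x
    sse = 2.0 * float(best.cost)
    cov = None
    dof = t.size - 2
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / dof)
        except np.linalg.LinAlgError:
            cov = None
    return DiffusionFit(
        p_max_pct=float(p_max),
        tau_h=float(tau),
        sse=sse,
        degenerate_flag=bool(tau > 3.0 * t[-1]),
        covariance=cov,
        n_points=t.size,
    )


def aggregate_cohort(fits: list[DiffusionFit], level: float = 0.95) -> CohortKinetics:
    """Arithmetic means and t-based CIs of (Pmax, tau) across per-sample fits.

    Degenerate fits are included (they are data, reported verbatim), but at
    least two non-degenerate fits are required for the aggregate to mean
    anything.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    if sum(not f.degenerate_flag for f in fits) < 2:
        raise ValueError("at least 2 non-degenerate fits are required")
    p = np.array([f.p_max_pct for f in fits])
    tau = np.array([f.tau_h for f in fits])
    n = p.size

    def ci(x: np.ndarray) -> tuple[float, float]:
        m = float(x.mean())
        if n < 2 or np.allclose(x, x[0]):
            return (m, m)
        half = stats.t.ppf(0.5 + level / 2.0, n - 1) * x.std(ddof=1) / np.sqrt(n)
        return (m - half, m + half)

    return CohortKinetics(
        p_max_mean_pct=float(p.mean()),
        p_max_ci_pct=ci(p),
        tau_mean_h=float(tau.mean()),
        tau_ci_h=ci(tau),
        n=n,
    )
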