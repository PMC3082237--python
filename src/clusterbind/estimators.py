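"""Estimators turning raw trajectories into dose-response quantities.

Mirrors the measurement chain used for the simulated curves: time-averaged
equilibrium occupancy from c(t), a through-origin linear regression of
occupancy against dose restricted to low doses (l* <= 0.05) for the slope at
origin, a Hill-function fit c* = l*^a / (k^a + l*^a) for the EC50, and a
nonlinear regression of an exponential probability density for the mean first
passage time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "SlopeFit",
    "equilibrium_occupancy",
    "fit_slope_origin",
    "fit_hill_ec50",
    "fit_mfpt_exponential",
]


@dataclass
class DoseResponseCurve:
    """Replicate-averaged occupancy versus dimensionless dose.

    ``l_star`` is total ligand over kappa; ``c_star_mean``/``c_star_sd`` are
    the replicate mean and standard deviation of equilibrium occupancy c/r0;
    ``n_replicates`` per point.  ``meta`` carries layout/kinetics descriptors.
    """

    l_star: np.ndarray
    c_star_mean: np.ndarray
    c_star_sd: np.ndarray
    n_replicates: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.l_star = np.asarray(self.l_star, dtype=float)
        self.c_star_mean = np.asarray(self.c_star_mean, dtype=float)
        self.c_star_sd = np.asarray(self.c_star_sd, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        if len({len(self.l_star), len(self.c_star_mean), len(self.c_star_sd), len(self.n_replicates)}) != 1:
            raise ValueError("curve columns must have equal length")
        if len(np.unique(self.l_star)) < 2:
            raise ValueError("a dose-response curve needs at least 2 distinct doses")

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "l_star": self.l_star,
                "c_star_mean": self.c_star_mean,
                "c_star_sd": self.c_star_sd,
                "n_replicates": self.n_replicates,
            }
        )

    def sem(self) -> np.ndarray:
        """Replicate standard error of the mean per dose."""
        return self.c_star_sd / np.sqrt(np.maximum(self.n_replicates, 1))


@dataclass(frozen=True)
class HillFit:
    """Hill-function fit c* = l*^alpha / (ec50^alpha + l*^alpha)."""

    ec50: float
    alpha: float
    residual: float  # sum of squared errors


@dataclass(frozen=True)
class SlopeFit:
    """Through-origin slope of c* against l* on the low-dose window."""

    slope: float
    dose_window_max: float
    n_points: int


def equilibrium_occupancy(
    c_trace: np.ndarray, r0: int, burn_in: int, window: int
) -> tuple[float, float]:
    """Mean and s.d. of normalized occupancy c/r0 over the last ``window`` steps.

    The trace must be at least ``burn_in + window`` long so that the averaging
    window lies entirely after equilibration.
    """
    c_trace = np.asarray(c_trace)
    if window < 1 or burn_in < 0:
        raise ValueError("burn_in must be >= 0 and window >= 1")
    if len(c_trace) < burn_in + window:
        raise ValueError(
            f"trace of length {len(c_trace)} too short for burn_in={burn_in} + window={window}"
        )
    seg = c_trace[-window:] / float(r0)
    return float(seg.mean()), float(seg.std(ddof=0))


def fit_slope_origin(curve: DoseResponseCurve, dose_window_max: float = 0.05) -> SlopeFit:
    """Slope at the origin by through-origin least squares on l* <= window.

    c*(0) = 0 exactly, so the intercept is fixed at zero:
    slope = sum(l c) / sum(l^2) over the in-window points.
    """
    sel = (curve.l_star > 0) & (curve.l_star <= dose_window_max)
    if np.count_nonzero(sel) < 2:
        raise ValueError(
            f"need >= 2 doses in (0, {dose_window_max}] for the slope fit, "
            f"got {int(np.count_nonzero(sel))}"
        )
    l = curve.l_star[sel]
    c = curve.c_star_mean[sel]
    slope = float(np.dot(l, c) / np.dot(l, l))
    return SlopeFit(slope=slope, dose_window_max=dose_window_max, n_points=int(sel.sum()))


def _hill(l, log_k, log_a):
    # clip so a wandering optimizer cannot overflow the powers
    k = np.exp(np.clip(log_k, -30.0, 30.0))
    a = np.exp(np.clip(log_a, -3.0, 3.0))
    with np.errstate(over="ignore"):
        la = np.power(l, a)
        return la / (k**a + la)


_HILL_STARTS = [(k0, a0) for k0 in (0.5, 1.0, 2.0, 5.0) for a0 in (0.5, 1.0, 2.0)]


def fit_hill_ec50(curve: DoseResponseCurve) -> HillFit:
    """EC50 and Hill coefficient by unweighted nonlinear least squares.

    Multi-start over a small (ec50, alpha) grid, optimized in log-parameter
    space to keep both positive; the lowest-SSE solution wins.  The Hill form
    is an empirical EC50 reader, not a mechanistic model of clustered
    binding.  Raises if no start converges.
    """
    l = curve.l_star
    c = curve.c_star_mean
    if not (np.any(c < 0.5) and np.any(c > 0.5)):
        raise ValueError("doses must span the EC50 (points on both sides of c* = 0.5)")
    best = None
    for k0, a0 in _HILL_STARTS:
        try:
            res = least_squares(
                lambda th: _hill(l, th[0], th[1]) - c,
                x0=[np.log(k0), np.log(a0)],
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if res.success and (best is None or sse < best[0]):
            best = (sse, res.x)
    if best is None:
        raise RuntimeError(
            "Hill fit failed to converge from all starts "
            f"(doses {l.min():g}..{l.max():g}, occupancy {c.min():g}..{c.max():g})"
        )
    sse, (log_k, log_a) = best
    return HillFit(ec50=float(np.exp(log_k)), alpha=float(np.exp(log_a)), residual=sse)


def fit_mfpt_exponential(
    passage_times: np.ndarray, n_bins: int = 50, min_samples: int = 100
) -> tuple[float, float]:
    """MFPT from a nonlinear fit of an exponential pdf to the FPT histogram.

    The empirical density over ``n_bins`` equal-width bins is fitted with
    lam * exp(-lam t) by least squares with relative (1/density) weighting, so
    the tail bins carry the same weight as the early peak; MFPT = 1/lam.
    Returns (mfpt, stderr).  Rejects sample sets that are too small or
    clearly non-exponential (coefficient of variation far from 1).
    """
    t = np.asarray(passage_times, dtype=float)
    if t.size < min_samples:
        raise ValueError(f"need >= {min_samples} passage times, got {t.size}")
    mean = t.mean()
    if mean <= 0:
        raise ValueError("passage times must be positive on average")
    cv = t.std(ddof=1) / mean
    if cv < 0.2:
        raise ValueError(
            f"sample coefficient of variation {cv:.3f} is incompatible with an "
            "exponential law (cv = 1); refusing to fit"
        )
    bins = min(n_bins, max(5, int(np.sqrt(t.size))))
    hist, edges = np.histogram(t, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    dens = hist

    def resid(log_lam):
        lam = np.exp(log_lam[0])
        model = np.maximum(lam * np.exp(-lam * centers), 1e-300)
        # Poisson-standardized residuals: the sparse tail carries far more
        # weight than under plain least squares, but empty bins stay in and
        # are not over-counted
        return (dens - model) * np.sqrt(t.size * width / model)

    res = least_squares(resid, x0=[np.log(1.0 / mean)], xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise RuntimeError("exponential density fit did not converge")
    lam = float(np.exp(res.x[0]))
    mfpt = 1.0 / lam
    # delta-method stderr of 1/lam from the residual jacobian
    dof = max(centers.size - 1, 1)
    s2 = 2.0 * res.cost / dof
    jtj = float((res.jac.T @ res.jac).squeeze())
    var_loglam = s2 / jtj if jtj > 0 else float("nan")
    stderr = mfpt * float(np.sqrt(var_loglam))
    return mfpt, stderr
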