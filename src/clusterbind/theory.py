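"""Equilibrium theory of ligand binding to single and clustered receptors.

Classical (Michaelian) reversible binding of a monovalent ligand L to a
monovalent receptor R, L + R <-> C with rates k1, k-1, has the well-known
equilibrium occupancy

    c* = l* / (1 + l*),      l* = l / kappa,  c* = c / r0,  kappa = k-1/k1,

so the dimensionless EC50 is 1 and the slope at the origin is 1.

When n receptors stack their affinity zones exactly, a cluster behaves as one
macromolecule with n equivalent sites.  Keeping the microscopic rates
identical (k_i = k1) while a cluster with i bound ligands releases i times
faster (k_-i = i k_-1, i.e. kappa_i = i kappa), the site occupancy at
equilibrium is

    c*(l*, n) = sum_{i=1..n} i a_i / (n sum_{i=0..n} a_i),   a_i = l*^i / i!,

a truncated-Poisson mean over cluster occupation states.  Its corollaries:
slope at origin 1/n, saturation at 1, and EC50* ~ n/2 for large n.  The
*apparent* affinity therefore drops with cluster size even though the
microscopic affinity kappa never changes.

In the particle simulation, kappa maps onto per-step probabilities and the
space ratio: kappa = (p_unbind / p_bind) * (S_t / S_r), in ligand-count units.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "michaelis_occupancy",
    "cluster_occupancy",
    "slope_at_origin_theory",
    "ec50_exact",
    "ec50_largeN_approx",
    "kappa_from_params",
    "closed_system_occupancy",
    "tabulate_curves",
]


def _check_dose(l_star) -> np.ndarray:
    arr = np.asarray(l_star, dtype=float)
    if np.any(arr < 0):
        raise ValueError("dose l* must be non-negative")
    return arr


def _check_n(n: int) -> int:
    if not float(n).is_integer() or n < 1:
        raise ValueError(f"cluster size n must be a positive integer, got {n!r}")
    return int(n)


def michaelis_occupancy(l_star):
    """Fractional occupancy c* = l*/(1 + l*) of independent receptors."""
    arr = _check_dose(l_star)
    out = arr / (1.0 + arr)
    return out if out.ndim else float(out)


def cluster_occupancy(l_star, n: int):
    """Fractional site occupancy of n-site (over-stacked) receptor clusters.

    Evaluates ``sum(i * a_i) / (n * sum(a_i))`` with ``a_i = l*^i / i!`` via a
    multiplicative recurrence normalized by its running maximum, so it is
    stable for n up to at least 10^3 and for large doses where raw factorial
    terms would overflow.
    """
    n = _check_n(n)
    arr = np.atleast_1d(_check_dose(l_star))
    denom = np.ones_like(arr)  # sum a_i / a_max, built incrementally
    numer = np.zeros_like(arr)
    a = np.ones_like(arr)  # a_i / running scale
    for i in range(1, n + 1):
        a = a * arr / i
        numer += i * a
        denom += a
        # renormalize to keep terms in floating range for big n * big l*
        scale = np.maximum(a, 1.0)
        big = scale > 1e250
        if np.any(big):
            numer[big] /= scale[big]
            denom[big] /= scale[big]
            a[big] /= scale[big]
    out = numer / (n * denom)
    return out if np.ndim(l_star) else float(out[0])


def slope_at_origin_theory(n: int) -> float:
    """Slope of c*(l*) at l* = 0 for n-site clusters: 1/n."""
    return 1.0 / _check_n(n)


def ec50_exact(n: int) -> float:
    """Dimensionless dose at half occupancy, the root of c*(l*, n) = 1/2.

    c* is continuous, strictly increasing, 0 at 0 and -> 1 at infinity, so the
    root is unique; found by bracketed root search to 1e-12 relative tolerance.
    """
    n = _check_n(n)
    if n == 1:
        return 1.0
    f = lambda x: cluster_occupancy(x, n) - 0.5
    return float(brentq(f, 1e-6, 10.0 * n, xtol=1e-12, rtol=1e-12))


def ec50_largeN_approx(n: int) -> float:
    """Large-cluster approximation EC50* ~ n/2 (good even for modest n)."""
    return _check_n(n) / 2.0


def kappa_from_params(p_bind: float, p_unbind: float, area_ratio: float) -> float:
    """Dissociation constant kappa = (p_unbind/p_bind) * (S_t/S_r).

    Expressed in ligand-count units: kappa is the number of ligand molecules
    in the box that half-occupies independent receptors at equilibrium.
    """
    if not 0 < p_bind <= 1 or not 0 < p_unbind <= 1:
        raise ValueError("p_bind and p_unbind must lie in (0, 1]")
    if area_ratio <= 0:
        raise ValueError("area_ratio must be positive")
    return (p_unbind / p_bind) * area_ratio


def closed_system_occupancy(l_total: float, r0: int, kappa: float, n: int = 1) -> float:
    """Equilibrium bound count in a closed box with a finite ligand pool.

    The well-mixed theory is written in terms of *free* ligand; in a closed
    simulation box the free pool is depleted by binding.  Solves the
    self-consistency c = r0 * c*((l_total - c)/kappa, n) for the bound count
    c (unique fixed point by monotonicity).  With n = 1 this is the classical
    closed-system quadratic.
    """
    if l_total < 0:
        raise ValueError("l_total must be non-negative")
    if l_total == 0:
        return 0.0
    g = lambda c: c - r0 * cluster_occupancy(max(l_total - c, 0.0) / kappa, n)
    hi = min(float(l_total), float(r0))
    if g(hi) <= 0:  # everything that can bind is bound (degenerate corner)
        return hi
    return float(brentq(g, 0.0, hi, xtol=1e-10, rtol=1e-12))


def tabulate_curves(l_star_grid, cluster_sizes) -> "pd.DataFrame":
    """Tabulate analytic dose-response curves (columns l_star, c_star, n)."""
    import pandas as pd

    rows = []
    for n in cluster_sizes:
        c = np.atleast_1d(cluster_occupancy(l_star_grid, n))
        rows.append(pd.DataFrame({"l_star": np.atleast_1d(l_star_grid), "c_star": c, "n": n}))
    return pd.concat(rows, ignore_index=True)
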