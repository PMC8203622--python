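"""Exponential relaxation fits and time-constant ordering.

Each observable's approach to the double-membrane equilibrium is
modelled as f(t) = x_inf + (x0 - x_inf) exp(-t/tau) and fitted per
replica by nonlinear least squares. Medians of the per-replica tau
establish the temporal order of headgroup tilt, area shrinkage and
membrane thickening; a bootstrap over replicas quantifies the support
for each pairwise order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import RelaxationFit

__all__ = [
    "fit_relaxation",
    "fit_ensemble",
    "normalize_endpoints",
    "ensemble_average",
    "tau_ordering",
    "OrderingResult",
]


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Derivative-free start: x0 from the first sample, x_inf from the
    tail mean, tau from the 63% crossing time."""
    x0 = float(y[0])
    tail = max(1, y.size // 10)
    x_inf = float(y[-tail:].mean())
    span = x0 - x_inf
    if span != 0:
        frac = (y - x_inf) / span  # 1 at t=0, -> 0 at equilibrium
        crossed = np.nonzero(frac <= np.exp(-1.0))[0]
        tau = float(t[crossed[0]]) if crossed.size and t[crossed[0]] > 0 else float(
            t[-1] / 3.0
        )
    else:
        tau = float(t[-1] / 3.0)
    return x0, x_inf, max(tau, float(t[1] - t[0]))


def fit_relaxation(times_ns, values, init: tuple[float, float, float] | None = None) -> RelaxationFit:
    """Least-squares fit of (x0, x_inf, tau) with tau bounded positive.

    Returns ``converged=False`` (never raises) when the optimiser fails
    or tau is unidentifiable (e.g. a constant series). Needs at least 5
    strictly increasing time samples.
    """
    t = np.asarray(times_ns, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    if t.size < 5:
        raise ValueError("need at least 5 samples")
    if t.shape != y.shape:
        raise ValueError("times and values differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(y) == 0:
        return RelaxationFit(float(y[0]), float(y[0]), np.nan, 0.0, False, t.size)

    p0 = np.asarray(init if init is not None else _initial_guess(t, y))
    tau_min = 1e-6 * (t[-1] - t[0])

    def resid(p):
        x0, x_inf, tau = p
        return x_inf + (x0 - x_inf) * np.exp(-t / tau) - y

    def jac(p):
        x0, x_inf, tau = p
        e = np.exp(-t / tau)
        return np.column_stack([e, 1.0 - e, (x0 - x_inf) * e * t / tau ** 2])

    try:
        sol = least_squares(
            resid,
            np.array([p0[0], p0[1], max(p0[2], tau_min)]),
            jac=jac,
            bounds=([-np.inf, -np.inf, tau_min], [np.inf, np.inf, np.inf]),
            method="trf",
            max_nfev=200,
        )
    except Exception:
        return RelaxationFit(np.nan, np.nan, np.nan, np.nan, False, t.size)
    x0, x_inf, tau = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    ok = bool(sol.success) and np.isfinite(tau) and tau > tau_min
    # tau running off the data window means the decay was not observed
    if tau > 100.0 * (t[-1] - t[0]):
        ok = False
    return RelaxationFit(float(x0), float(x_inf), float(tau), rms, ok, t.size)


def fit_ensemble(times_ns, replicas: np.ndarray) -> list[RelaxationFit]:
    """Fit every row of a (n_replicas, n_times) array."""
    return [fit_relaxation(times_ns, row) for row in np.atleast_2d(replicas)]


def normalize_endpoints(values, x_single: float, x_double: float) -> np.ndarray:
    """Affine map sending the single-bilayer equilibrium to 0 and the
    double-bilayer equilibrium to 1: y = (x - x_single)/(x_double - x_single)."""
    if x_single == x_double:
        raise ValueError("endpoints must differ")
    return (np.asarray(values, dtype=np.float64) - x_single) / (x_double - x_single)


def ensemble_average(replicas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD over replicas sharing a time grid."""
    r = np.atleast_2d(np.asarray(replicas, dtype=np.float64))
    mean = r.mean(axis=0)
    sd = r.std(axis=0, ddof=1) if r.shape[0] > 1 else np.zeros(r.shape[1])
    return mean, sd


@dataclass
class OrderingResult:
    """Median tau per observable and bootstrap support per pairwise order."""

    median_tau_ns: dict[str, float]
    n_converged: dict[str, int]
    n_diverged: dict[str, int]
    pair_support: dict[tuple[str, str], float]  # P(tau_a < tau_b)
    declared_order: tuple[str, ...] | None
    support_threshold: float = 0.95
    meta: dict = field(default_factory=dict)


def tau_ordering(
    fits_by_observable: dict[str, list[RelaxationFit]],
    n_bootstrap: int = 1000,
    seed: int = 0,
    support_threshold: float = 0.95,
) -> OrderingResult:
    """Order observables by median relaxation time with bootstrap support.

    Diverged fits are excluded from the medians and counted. For each
    ordered pair (a, b) the support is the fraction of bootstrap
    resamples (over replicas, independently per observable) in which
    median tau_a < median tau_b. The full ordering is declared only if
    every adjacent pair of the median-sorted sequence reaches the
    support threshold; with a single replica per observable supports
    are undefined and no ordering is declared.
    """
    taus: dict[str, np.ndarray] = {}
    n_div: dict[str, int] = {}
    for name, fits in fits_by_observable.items():
        arr = np.array([f.tau_ns for f in fits if f.converged])
        if arr.size == 0:
            raise ValueError(f"all fits diverged for observable {name!r}")
        taus[name] = arr
        n_div[name] = sum(1 for f in fits if not f.converged)

    med = {k: float(np.median(v)) for k, v in taus.items()}
    names = sorted(med, key=med.get)
    rng = np.random.default_rng(seed)

    can_bootstrap = all(v.size >= 2 for v in taus.values())
    support: dict[tuple[str, str], float] = {}
    if can_bootstrap:
        boot_meds = {}
        for k, v in taus.items():
            idx = rng.integers(0, v.size, size=(n_bootstrap, v.size))
            boot_meds[k] = np.median(v[idx], axis=1)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                support[(a, b)] = float(np.mean(boot_meds[a] < boot_meds[b]))
        declared = tuple(names)
        for a, b in zip(names, names[1:]):
            if support[(a, b)] < support_threshold:
                declared = None
                break
    else:
        declared = None

    return OrderingResult(
        median_tau_ns=med,
        n_converged={k: int(v.size) for k, v in taus.items()},
        n_diverged=n_div,
        pair_support=support,
        declared_order=declared,
        support_threshold=support_threshold,
        meta={"n_bootstrap": n_bootstrap, "seed": seed},
    )
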