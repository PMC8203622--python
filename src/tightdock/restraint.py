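"""Headgroup-tilt angle restraint: energy, forces, and a toy relaxation.

The bias E(phi) = k (1 - cos(phi - phi0)) acts on the angle phi between
the P->N headgroup vector and the +z membrane normal. Placing phi0 at
90 deg drives separated bilayers towards tilted headgroups; phi0 at
0 deg drives close-apposed double bilayers towards upright headgroups.
The energy is non-negative, 2*pi-periodic, zero at phi0 and bounded by
2k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleRestraint",
    "restraint_energy",
    "restraint_forces",
    "demo_tilt_relaxation",
]

#: Boltzmann constant times 300 K, kJ/mol
KT_300K = 2.494


@dataclass
class AngleRestraint:
    """Force constant k (kJ/mol) and minimum position phi0 (radians).

    ``flip`` inverts the headgroup vector convention (N->P instead of
    P->N) for datasets labelled the other way round.
    """

    k: float
    phi0: float
    flip: bool = False

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if not 0.0 <= self.phi0 <= np.pi:
            raise ValueError("phi0 must lie in [0, pi]")


def restraint_energy(phi, restraint: AngleRestraint) -> np.ndarray | float:
    """E(phi) = k (1 - cos(phi - phi0)), elementwise over phi."""
    phi = np.asarray(phi, dtype=np.float64)
    e = restraint.k * (1.0 - np.cos(phi - restraint.phi0))
    return float(e) if e.ndim == 0 else e


def _tilt_geometry(p_pos: np.ndarray, n_pos: np.ndarray, flip: bool):
    v = np.asarray(n_pos, float) - np.asarray(p_pos, float)
    if flip:
        v = -v
    r = float(np.linalg.norm(v))
    if r == 0:
        raise ValueError("coincident P and N positions: angle undefined")
    return v, r


def restraint_forces(
    p_pos, n_pos, restraint: AngleRestraint
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic forces (-dE/dr) on the P and N particles, kJ/mol/nm.

    Written via cos(phi) = v_z/|v| and sin(phi) = |v_xy|/|v| of the
    (possibly flipped) headgroup vector v, which keeps the gradient
    smooth everywhere except on the polar axis; there the azimuth is
    degenerate and the in-plane force direction is taken as zero (the
    correct limit when phi0 is 0 or pi, and the symmetric choice
    otherwise). The pair forces sum to zero by construction.
    """
    v, r = _tilt_geometry(p_pos, n_pos, restraint.flip)
    z = v[2]
    rho = float(np.hypot(v[0], v[1]))
    # E = k (1 - cos phi cos phi0 - sin phi sin phi0)
    c0, s0 = np.cos(restraint.phi0), np.sin(restraint.phi0)
    # grad wrt v of cos phi = z/r
    g_cos = np.array([-z * v[0], -z * v[1], r * r - z * z]) / r ** 3
    if rho > 1e-12:
        g_sin = np.array(
            [v[0] * (r * r - rho * rho) / rho, v[1] * (r * r - rho * rho) / rho, -rho * z]
        ) / r ** 3
    else:
        g_sin = np.zeros(3)
    dE_dv = -restraint.k * (c0 * g_cos + s0 * g_sin)
    f_n = -dE_dv if not restraint.flip else dE_dv
    return -f_n, f_n  # (force on P, force on N)


def demo_tilt_relaxation(
    frame,
    restraint: AngleRestraint,
    friction: float = 1.0,
    dt_ns: float = 1e-4,
    n_steps: int = 1000,
    seed: int = 0,
    kT: float = KT_300K,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overdamped orientation dynamics of the headgroup vectors.

    Each lipid's P->N orientation relaxes on the unit sphere under the
    restraint torque plus thermal noise; the bond length stays fixed
    (orientation-only update) and orientations are reflected at the
    equator so headgroups never point into the membrane core (cos phi
    stays >= 0, matching the outward-hemisphere convention of the
    synthetic frames). Not molecular dynamics — a fixture generator for
    the kinetics analysis.

    ``frame`` is a BilayerFrame; the update acts on the outward-normal
    frame of each lipid, so leaflet orientation is already divided out.
    Returns (times_ns, mean cos phi series, per-lipid cos phi series of
    shape (n_steps+1, n_lipids)).
    """
    from .metrics import assign_leaflets

    n_mem = frame.truth["n_membranes"] if frame.truth else 1
    assignment = assign_leaflets(frame, n_mem)
    p_mask = frame.roles == "P"
    n_mask = frame.roles == "N"
    order_p = np.argsort(frame.lipid_index[p_mask])
    order_n = np.argsort(frame.lipid_index[n_mask])
    v = frame.positions[n_mask][order_n] - frame.positions[p_mask][order_p]
    sign = assignment.normal_sign.astype(float)
    v[:, 2] *= sign  # rotate every leaflet into the outward-normal frame
    u = v / np.linalg.norm(v, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    n_lip = len(u)
    cos_series = np.empty((n_steps + 1, n_lip))
    cos_series[0] = u[:, 2]
    sqrt_term = np.sqrt(2.0 * kT * dt_ns / friction)
    c0, s0 = np.cos(restraint.phi0), np.sin(restraint.phi0)
    for step in range(1, n_steps + 1):
        z = u[:, 2]
        rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
        # dE/dphi = k sin(phi - phi0); tangential gradient on the sphere
        sin_d = rho * c0 - z * s0  # sin(phi - phi0)
        torque = -restraint.k * sin_d
        # tangent direction of increasing phi at u
        with np.errstate(invalid="ignore", divide="ignore"):
            t_hat = np.where(
                rho[:, None] > 1e-12,
                np.column_stack([u[:, 0] * z / rho, u[:, 1] * z / rho, -rho]),
                np.column_stack([np.ones(n_lip), np.zeros(n_lip), np.zeros(n_lip)]),
            )
        drift = (torque / friction)[:, None] * t_hat * dt_ns
        noise = sqrt_term * rng.normal(size=(n_lip, 3))
        noise -= (noise * u).sum(1, keepdims=True) * u  # project to tangent
        u = u + drift + noise
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u[:, 2] = np.abs(u[:, 2])  # reflect at the equator
        cos_series[step] = u[:, 2]
    times = np.arange(n_steps + 1) * dt_ns
    return times, cos_series.mean(axis=1), cos_series
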