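"""Per-frame membrane observables from labeled particle coordinates.

The membrane normal is the z-axis throughout. Membrane surfaces are
defined by the mean z of the phosphate (P) layer of each leaflet:
thickness is the P-layer separation within a membrane, inter-membrane
distance the separation of the facing P layers, and volume the lateral
box area times the P-to-P thickness. Headgroup tilt is the cosine of
the angle between the P->N vector of each lipid and the leaflet outward
normal; chain order is the second-Legendre parameter of successive
chain-bead bonds; leaflet electrostatics is a cutoff Coulomb pair sum
within each leaflet with minimum-image convention in x and y.
"""

from __future__ import annotations

import numpy as np

from .datatypes import BilayerFrame, LeafletAssignment

__all__ = [
    "COULOMB_KJ_NM_E2",
    "assign_leaflets",
    "membrane_thickness",
    "intermembrane_distance",
    "lateral_area",
    "area_per_lipid",
    "membrane_volume",
    "headgroup_tilt",
    "chain_order",
    "waters_in_gap",
    "leaflet_electrostatic_energy",
    "frame_metrics",
]

#: Coulomb constant 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_KJ_NM_E2 = 138.935458


def _p_z_per_lipid(frame: BilayerFrame) -> tuple[np.ndarray, np.ndarray]:
    """(lipid ids, z of each lipid's P particle), sorted by lipid id."""
    mask = frame.roles == "P"
    lip = frame.lipid_index[mask]
    z = frame.positions[mask, 2]
    order = np.argsort(lip)
    return lip[order], z[order]


def assign_leaflets(frame: BilayerFrame, n_membranes: int) -> LeafletAssignment:
    """Cluster lipids into leaflets by their P z-coordinate.

    The 2*n_membranes clusters are cut at the largest gaps of the sorted
    P z-coordinates; this is the fixed point of 1D k-means with ordered
    initialisation when clusters are well separated. Clusters are
    ordered bottom-to-top and paired into membranes by adjacency.

    Raises when the z-distributions are not separable, i.e. when a
    boundary gap does not exceed every within-cluster neighbour gap.
    """
    if n_membranes not in (1, 2):
        raise ValueError("n_membranes must be 1 or 2")
    lipids, z = _p_z_per_lipid(frame)
    k = 2 * n_membranes
    if len(z) < k:
        raise ValueError("fewer lipids than leaflets")
    order = np.argsort(z)
    zs = z[order]
    gaps = np.diff(zs)
    if len(gaps) < k - 1 or np.all(gaps == 0):
        raise ValueError("P z-coordinates degenerate: leaflets not separable")
    cut_idx = np.sort(np.argsort(gaps)[-(k - 1):])
    boundary_gaps = gaps[cut_idx]
    within = np.delete(gaps, cut_idx)
    # separable only if every boundary gap clearly dominates the spread
    # inside the clusters (factor 3 margin on the largest within gap)
    if within.size and boundary_gaps.min() <= 3.0 * within.max():
        amb = np.sort(lipids[order][np.concatenate([cut_idx, cut_idx + 1])])
        raise ValueError(
            "leaflet z-distributions overlap; ambiguous lipids near the "
            f"cluster boundaries: {amb.tolist()}"
        )
    labels_sorted = np.zeros(len(z), dtype=int)
    for c in cut_idx:
        labels_sorted[c + 1:] += 1
    cluster = np.empty(len(z), dtype=int)
    cluster[order] = labels_sorted  # 0 = bottom leaflet ... k-1 = top
    membrane = cluster // 2
    leaflet = cluster % 2
    return LeafletAssignment(
        membrane_id=membrane,
        leaflet_id=leaflet,
        n_membranes=n_membranes,
        lipid_ids=lipids,
    )


def _leaflet_mean_pz(frame: BilayerFrame, assignment: LeafletAssignment,
                     membrane_id: int, leaflet_id: int) -> float:
    lipids = assignment.lipids_of(membrane_id, leaflet_id)
    if lipids.size == 0:
        raise ValueError("empty leaflet")
    mask = (frame.roles == "P") & np.isin(frame.lipid_index, lipids)
    return float(frame.positions[mask, 2].mean())


def membrane_thickness(frame: BilayerFrame, assignment: LeafletAssignment,
                       membrane_id: int = 0) -> float:
    """P-layer to P-layer thickness of one membrane (nm)."""
    top = _leaflet_mean_pz(frame, assignment, membrane_id, 1)
    bottom = _leaflet_mean_pz(frame, assignment, membrane_id, 0)
    return abs(top - bottom)


def intermembrane_distance(frame: BilayerFrame, assignment: LeafletAssignment) -> float:
    """Distance between the mean P layers of the two gap-facing leaflets."""
    if assignment.n_membranes != 2:
        raise ValueError("inter-membrane distance needs two membranes")
    (m0, l0), (m1, l1) = assignment.gap_facing()
    return abs(
        _leaflet_mean_pz(frame, assignment, m1, l1)
        - _leaflet_mean_pz(frame, assignment, m0, l0)
    )


def lateral_area(frame: BilayerFrame) -> float:
    """Lateral box area box_x * box_y (nm^2)."""
    return float(frame.box_nm[0] * frame.box_nm[1])


def area_per_lipid(frame: BilayerFrame, assignment: LeafletAssignment,
                   membrane_id: int = 0) -> float:
    """Lateral area divided by the lipid count of one leaflet."""
    n = assignment.lipids_of(membrane_id, 0).size
    if n == 0:
        raise ValueError("empty leaflet")
    return lateral_area(frame) / n


def membrane_volume(frame: BilayerFrame, assignment: LeafletAssignment,
                    membrane_id: int = 0) -> float:
    """Volume = lateral area x P-to-P thickness (nm^3)."""
    return lateral_area(frame) * membrane_thickness(frame, assignment, membrane_id)


def headgroup_tilt(
    frame: BilayerFrame,
    assignment: LeafletAssignment,
    membrane_id: int,
    leaflet_id: int,
) -> tuple[float, np.ndarray]:
    """Mean and per-lipid cos(phi) of the P->N vector vs the outward normal.

    The outward normal is +z for the top leaflet of a membrane and -z
    for the bottom one. Headgroups are assumed not to wrap across the
    periodic z boundary, so no minimum-image correction is applied to
    the P->N vector.
    """
    lipids = assignment.lipids_of(membrane_id, leaflet_id)
    if lipids.size == 0:
        raise ValueError("empty leaflet")
    sign = 1.0 if leaflet_id == 1 else -1.0
    p_mask = frame.roles == "P"
    n_mask = frame.roles == "N"
    p_by_lipid = dict(zip(frame.lipid_index[p_mask], frame.positions[p_mask]))
    n_by_lipid = dict(zip(frame.lipid_index[n_mask], frame.positions[n_mask]))
    v = np.array([n_by_lipid[l] - p_by_lipid[l] for l in lipids])
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("coincident P and N particles")
    cos_phi = sign * v[:, 2] / norms
    return float(cos_phi.mean()), cos_phi


def chain_order(
    frame: BilayerFrame, assignment: LeafletAssignment, membrane_id: int | None = None
) -> np.ndarray:
    """Order parameter S = (3<cos^2 theta> - 1)/2 per chain-bond index.

    theta is the angle of each successive chain-bead bond to the
    membrane normal (z-axis); the average runs over lipids (of one
    membrane, or all). Lipids need at least two chain beads.
    """
    chain_mask = frame.roles == "chain"
    lipids = np.unique(frame.lipid_index[chain_mask])
    if membrane_id is not None:
        keep = assignment.lipid_ids[assignment.membrane_id == membrane_id]
        lipids = lipids[np.isin(lipids, keep)]
    cos2_by_bond: dict[int, list[float]] = {}
    for l in lipids:
        beads = frame.positions[chain_mask & (frame.lipid_index == l)]
        if len(beads) < 2:
            continue
        bonds = np.diff(beads, axis=0)
        norms = np.linalg.norm(bonds, axis=1)
        cos2 = (bonds[:, 2] / norms) ** 2
        for b, c2 in enumerate(cos2):
            cos2_by_bond.setdefault(b, []).append(float(c2))
    if not cos2_by_bond:
        raise ValueError("no chain bonds in selection")
    n_bonds = max(cos2_by_bond) + 1
    return np.array(
        [(3.0 * np.mean(cos2_by_bond[b]) - 1.0) / 2.0 for b in range(n_bonds)]
    )


def waters_in_gap(frame: BilayerFrame, assignment: LeafletAssignment) -> float:
    """Water-oxygen count strictly between the facing P layers, per nm^2."""
    if assignment.n_membranes != 2:
        raise ValueError("gap hydration needs two membranes")
    (m0, l0), (m1, l1) = assignment.gap_facing()
    z_lo = _leaflet_mean_pz(frame, assignment, m0, l0)
    z_hi = _leaflet_mean_pz(frame, assignment, m1, l1)
    z_lo, z_hi = min(z_lo, z_hi), max(z_lo, z_hi)
    wz = frame.select("water")[:, 2]
    count = int(np.sum((wz > z_lo) & (wz < z_hi)))
    return count / lateral_area(frame)


def leaflet_electrostatic_energy(
    frame: BilayerFrame,
    assignment: LeafletAssignment,
    charges: dict[str, float],
    cutoff_nm: float = 1.2,
) -> dict:
    """Cutoff Coulomb pair energy within each leaflet (kJ/mol).

    E = sum_{i<j, r_ij <= cutoff} k q_i q_j / r_ij over all lipid
    particles of one leaflet, with minimum-image convention applied in
    x and y (not z: a leaflet does not wrap across the membrane
    normal). Returns per-leaflet energies keyed by (membrane, leaflet)
    plus ``inner_mean`` / ``outer_mean`` averages over the gap-facing
    and solvent-facing leaflets (for a single membrane both leaflets
    count as outer and ``inner_mean`` is absent).
    """
    for role in np.unique(frame.roles[frame.lipid_index >= 0]):
        if role not in charges:
            raise ValueError(f"missing charge for role {role!r}")
    box_xy = frame.box_nm[:2]
    energies: dict[tuple[int, int], float] = {}
    for m in range(assignment.n_membranes):
        for leaf in (0, 1):
            lipids = assignment.lipids_of(m, leaf)
            mask = np.isin(frame.lipid_index, lipids) & (frame.lipid_index >= 0)
            pos = frame.positions[mask]
            q = np.array([charges[r] for r in frame.roles[mask]])
            d = pos[None, :, :] - pos[:, None, :]
            d[..., :2] -= np.round(d[..., :2] / box_xy) * box_xy
            r = np.sqrt((d ** 2).sum(-1))
            iu = np.triu_indices(len(pos), k=1)
            rr = r[iu]
            qq = (q[:, None] * q[None, :])[iu]
            sel = rr <= cutoff_nm
            energies[(m, leaf)] = float(
                COULOMB_KJ_NM_E2 * np.sum(qq[sel] / rr[sel])
            )
    out: dict = {"per_leaflet": energies}
    if assignment.n_membranes == 2:
        inner = [energies[k] for k in assignment.gap_facing()]
        outer = [energies[(0, 0)], energies[(1, 1)]]
        out["inner_mean"] = float(np.mean(inner))
        out["outer_mean"] = float(np.mean(outer))
    else:
        out["outer_mean"] = float(np.mean(list(energies.values())))
    return out


def frame_metrics(
    frame: BilayerFrame,
    n_membranes: int,
    charges: dict[str, float] | None = None,
    cutoff_nm: float = 1.2,
) -> dict:
    """All per-frame observables in one pass (one dict per membrane plus
    system-level entries); convenience wrapper for the pipeline/CLI."""
    assignment = assign_leaflets(frame, n_membranes)
    out: dict = {
        "time_ns": frame.time_ns,
        "lateral_area_nm2": lateral_area(frame),
        "membranes": [],
    }
    for m in range(n_membranes):
        mean_cos = {
            leaf: headgroup_tilt(frame, assignment, m, leaf)[0] for leaf in (0, 1)
        }
        out["membranes"].append(
            {
                "membrane_id": m,
                "thickness_nm": membrane_thickness(frame, assignment, m),
                "area_per_lipid_nm2": area_per_lipid(frame, assignment, m),
                "volume_nm3": membrane_volume(frame, assignment, m),
                "mean_cos_bottom": mean_cos[0],
                "mean_cos_top": mean_cos[1],
                "chain_order_S": chain_order(frame, assignment, m).tolist(),
            }
        )
    if n_membranes == 2:
        out["intermembrane_distance_nm"] = intermembrane_distance(frame, assignment)
        out["waters_in_gap_per_nm2"] = waters_in_gap(frame, assignment)
    if charges is not None:
        elec = leaflet_electrostatic_energy(frame, assignment, charges, cutoff_nm)
        elec["per_leaflet"] = {
            f"membrane{m}_leaflet{l}": v for (m, l), v in elec["per_leaflet"].items()
        }
        out["electrostatics_kj_mol"] = elec
    return out
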