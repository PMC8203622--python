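"""Seeded generator of single- and double-bilayer coordinate frames.

Lipids sit on a jittered square lattice per leaflet. Each lipid is one P
particle (phosphate), one N particle (choline nitrogen) at a fixed bond
length from P, and a short straight chain of beads pointing into the
membrane core. The polar angle of the P->N vector relative to the
leaflet outward normal is arccos(mean_tilt_cos), with uniform random
azimuth, so the per-lipid cos(tilt) realises the requested mean exactly
at zero noise. Water-oxygen particles can be placed in the
inter-membrane gap for hydration metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import BilayerFrame

__all__ = ["BilayerFrameSpec", "generate_bilayer_frame", "DEFAULT_CHARGES"]

#: partial charges (e) per particle role; P and N carry the
#: phosphate/choline charges of a PC-like zwitterionic headgroup.
DEFAULT_CHARGES: dict[str, float] = {"P": -1.0, "N": 1.0, "chain": 0.0, "water": 0.0}


@dataclass
class BilayerFrameSpec:
    """Geometry of a generated frame.

    ``mean_tilt_cos`` is a pair (inner, outer): for a double-membrane
    system the inner value applies to the two gap-facing leaflets and
    the outer value to the two solvent-facing leaflets; a single
    membrane uses the outer value for both leaflets.
    ``intermembrane_distance_nm`` is the P-layer to P-layer distance of
    the facing leaflets and is ignored for a single membrane.
    """

    n_lipids_per_leaflet: int = 100
    n_membranes: int = 1
    intermembrane_distance_nm: float = 0.5
    thickness_nm: float = 4.0
    mean_tilt_cos: tuple[float, float] = (0.8, 0.8)  # (inner, outer)
    chain_beads_per_lipid: int = 4
    box_xy_nm: float = 8.1
    positional_noise_nm: float = 0.0
    pn_bond_nm: float = 0.45
    chain_spacing_nm: float = 0.35
    n_gap_waters: int = 0
    charges: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_membranes not in (1, 2):
            raise ValueError("n_membranes must be 1 or 2")
        if self.thickness_nm <= 0 or self.intermembrane_distance_nm <= 0:
            raise ValueError("thickness and distance must be positive")
        for c in self.mean_tilt_cos:
            if not 0.0 <= c <= 1.0:
                raise ValueError("mean_tilt_cos components must be in [0, 1]")
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        n_side = int(np.ceil(np.sqrt(self.n_lipids_per_leaflet)))
        if self.box_xy_nm / n_side <= 2 * self.positional_noise_nm:
            raise ValueError("box too small for the lipid lattice at this noise")
        if self.n_gap_waters and self.n_membranes != 2:
            raise ValueError("gap waters need a double-membrane system")

    @property
    def box_z_nm(self) -> float:
        core = self.thickness_nm * self.n_membranes
        if self.n_membranes == 2:
            core += self.intermembrane_distance_nm
        # leave headroom above and below the stack
        pad = 2 * (self.pn_bond_nm + 4.0)
        return core + pad


def _lattice_xy(n: int, box: float, rng: np.random.Generator, jitter: float) -> np.ndarray:
    n_side = int(np.ceil(np.sqrt(n)))
    pitch = box / n_side
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    xy = (np.stack([gx, gy], axis=-1).reshape(-1, 2)[:n] + 0.5) * pitch
    return xy + rng.uniform(-jitter, jitter, xy.shape)


def generate_bilayer_frame(spec: BilayerFrameSpec) -> BilayerFrame:
    """Build one frame realising the spec geometry exactly at zero noise.

    P-layer mean z-separations equal the requested thickness and
    inter-membrane distance before positional noise; leaflet membership
    and per-lipid tilt are stored as ground truth on the frame.
    """
    rng = np.random.default_rng(spec.seed)
    nL = spec.n_lipids_per_leaflet
    box = np.array([spec.box_xy_nm, spec.box_xy_nm, spec.box_z_nm])

    # membrane mid-plane z positions, stacked bottom-to-top
    if spec.n_membranes == 1:
        mids = [box[2] / 2.0]
    else:
        pitch = spec.thickness_nm + spec.intermembrane_distance_nm
        mids = [box[2] / 2.0 - pitch / 2.0, box[2] / 2.0 + pitch / 2.0]

    positions, roles, lipid_idx = [], [], []
    truth_membrane, truth_leaflet, truth_cos = [], [], []
    lipid = 0
    for m, zmid in enumerate(mids):
        for leaflet in (0, 1):  # 0 bottom, 1 top
            sign = 1.0 if leaflet == 1 else -1.0
            z_p = zmid + sign * spec.thickness_nm / 2.0
            # gap-facing leaflets take the inner tilt in a double system
            inner = spec.n_membranes == 2 and (
                (m == 0 and leaflet == 1) or (m == 1 and leaflet == 0)
            )
            cos_t = spec.mean_tilt_cos[0] if inner else spec.mean_tilt_cos[1]
            sin_t = float(np.sqrt(max(0.0, 1.0 - cos_t * cos_t)))
            xy = _lattice_xy(nL, spec.box_xy_nm, rng, 0.05 * spec.box_xy_nm / np.sqrt(nL))
            phi_az = rng.uniform(0.0, 2.0 * np.pi, nL)
            for i in range(nL):
                p = np.array([xy[i, 0], xy[i, 1], z_p])
                n_vec = spec.pn_bond_nm * np.array(
                    [
                        sin_t * np.cos(phi_az[i]),
                        sin_t * np.sin(phi_az[i]),
                        sign * cos_t,
                    ]
                )
                positions.append(p)
                roles.append("P")
                lipid_idx.append(lipid)
                positions.append(p + n_vec)
                roles.append("N")
                lipid_idx.append(lipid)
                for b in range(1, spec.chain_beads_per_lipid + 1):
                    bead = p - np.array([0.0, 0.0, sign * b * spec.chain_spacing_nm])
                    positions.append(bead)
                    roles.append("chain")
                    lipid_idx.append(lipid)
                truth_membrane.append(m)
                truth_leaflet.append(leaflet)
                truth_cos.append(cos_t)
                lipid += 1

    if spec.n_gap_waters:
        z_lo = mids[0] + spec.thickness_nm / 2.0
        z_hi = mids[1] - spec.thickness_nm / 2.0
        w = np.column_stack(
            [
                rng.uniform(0.0, spec.box_xy_nm, spec.n_gap_waters),
                rng.uniform(0.0, spec.box_xy_nm, spec.n_gap_waters),
                rng.uniform(z_lo + 1e-6, z_hi - 1e-6, spec.n_gap_waters),
            ]
        )
        positions.extend(w)
        roles.extend(["water"] * spec.n_gap_waters)
        lipid_idx.extend([-1] * spec.n_gap_waters)

    positions = np.asarray(positions, dtype=np.float64)
    if spec.positional_noise_nm > 0:
        positions = positions + rng.normal(0.0, spec.positional_noise_nm, positions.shape)

    truth = {
        "membrane_id": np.asarray(truth_membrane),
        "leaflet_id": np.asarray(truth_leaflet),
        "mean_tilt_cos": np.asarray(truth_cos),
        "thickness_nm": spec.thickness_nm,
        "intermembrane_distance_nm": spec.intermembrane_distance_nm
        if spec.n_membranes == 2
        else None,
        "n_membranes": spec.n_membranes,
        "charges": dict(spec.charges),
    }
    return BilayerFrame(
        positions=positions,
        roles=np.asarray(roles),
        lipid_index=np.asarray(lipid_idx),
        box_nm=box,
        time_ns=0.0,
        truth=truth,
    )
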