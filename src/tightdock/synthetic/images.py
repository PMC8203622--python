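"""Seeded generator of vesicle-pair micrograph-like images.

Each membrane is rendered as two Gaussian ridges — one per headgroup
layer — at signed distance ±t/2 from the vesicle mid-surface, so the
peak-to-peak distance across the membrane equals the true thickness t.
Docked pairs share a flat contact face (a chord of each sphere at the
common tangent), where tight interfaces are locally thickened and the
protein channel is scaled by the interface/free signal ratio.

All output is deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..datatypes import ImageWithScale

__all__ = [
    "VesicleImageSpec",
    "GroundTruth",
    "generate_vesicle_pair_image",
    "free_vesicle_spec",
    "docked_pair_spec",
]

DOCKING_TYPES = ("free", "loose", "tight")


@dataclass
class VesicleImageSpec:
    """Geometry, optics and noise of one synthetic vesicle image.

    ``centers_nm`` are (x, y) positions; the 0-based pixel-centre
    convention maps x to column index * pixel size and y to row index *
    pixel size. ``protein_interface_ratio`` is the true interface /
    free-membrane protein signal ratio (tight < 1, loose >= 1).
    """

    image_size_px: tuple[int, int]  # (rows, cols)
    pixel_size_nm: float = 0.5
    centers_nm: tuple[tuple[float, float], ...] = ()
    radii_nm: tuple[float, ...] = ()
    docking_type: str = "free"
    membrane_thickness_nm: float = 4.0
    interface_thickening_nm: float = 0.0
    contact_halfwidth_nm: float = 12.0
    headgroup_ridge_sigma_nm: float = 0.8
    protein_interface_ratio: float = 1.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.docking_type not in DOCKING_TYPES:
            raise ValueError(f"docking_type must be one of {DOCKING_TYPES}")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.protein_interface_ratio < 0:
            raise ValueError("protein_interface_ratio must be >= 0")
        if self.interface_thickening_nm < 0:
            raise ValueError("interface_thickening_nm must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.centers_nm) != len(self.radii_nm) or not self.centers_nm:
            raise ValueError("need one radius per vesicle centre")
        for r in self.radii_nm:
            if not r > self.membrane_thickness_nm:
                raise ValueError("radii must exceed the membrane thickness")
        if self.docking_type != "free":
            if len(self.centers_nm) != 2:
                raise ValueError("docked geometry needs exactly two vesicles")
            h = self.contact_halfwidth_nm
            if not 0 < h < min(self.radii_nm):
                raise ValueError("contact halfwidth must lie in (0, min radius)")
            if self.face_gap_nm() < 0:
                raise ValueError("vesicles overlap beyond the contact geometry")
        else:
            c = np.asarray(self.centers_nm, float)
            for i in range(len(c)):
                for j in range(i + 1, len(c)):
                    if np.linalg.norm(c[i] - c[j]) <= self.radii_nm[i] + self.radii_nm[j]:
                        raise ValueError("free vesicles must not touch")

    def chord_distances_nm(self) -> tuple[float, float]:
        """Distance from each centre to its flat contact face."""
        h = self.contact_halfwidth_nm
        return tuple(math.sqrt(r * r - h * h) for r in self.radii_nm)

    def face_gap_nm(self) -> float:
        """Mid-surface to mid-surface separation of the two contact faces."""
        c = np.asarray(self.centers_nm, float)
        a1, a2 = self.chord_distances_nm()
        return float(np.linalg.norm(c[1] - c[0]) - a1 - a2)

    def interface_thickness_nm(self) -> float:
        t = self.membrane_thickness_nm
        if self.docking_type == "tight":
            t += self.interface_thickening_nm
        return t


@dataclass
class GroundTruth:
    """Everything needed to score downstream measurements of one image."""

    docking_label: str
    protein_interface_ratio: float
    membrane_thickness_nm: float
    interface_thickness_nm: float
    centers_nm: tuple[tuple[float, float], ...]
    radii_nm: tuple[float, ...]
    contact_halfwidth_nm: float
    face_gap_nm: float | None
    contact_center_nm: tuple[float, float] | None
    contact_normal: tuple[float, float] | None  # unit vector vesicle0 -> 1
    meta: dict = field(default_factory=dict)

    def true_thickness_at(self, in_contact_zone: bool) -> float:
        return self.interface_thickness_nm if in_contact_zone else self.membrane_thickness_nm

    def headgroup_radii_nm(self, vesicle: int = 0) -> tuple[float, float]:
        """Radii of the two headgroup ridges of a free (spherical) part."""
        t = self.membrane_thickness_nm
        r = self.radii_nm[vesicle]
        return (r - t / 2.0, r + t / 2.0)


def _signed_distance(spec: VesicleImageSpec, xx: np.ndarray, yy: np.ndarray,
                     vesicle: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed distance to the vesicle mid-surface (+ outside) and a
    boolean mask of points whose nearest surface point lies on the flat
    contact face."""
    cx, cy = spec.centers_nm[vesicle]
    sx, sy = xx - cx, yy - cy
    r = np.hypot(sx, sy)
    if spec.docking_type == "free":
        return r - spec.radii_nm[vesicle], np.zeros_like(r, dtype=bool)

    other = 1 - vesicle
    ox, oy = spec.centers_nm[other]
    d = math.hypot(ox - cx, oy - cy)
    ux, uy = (ox - cx) / d, (oy - cy) / d
    a = spec.chord_distances_nm()[vesicle]
    h = spec.contact_halfwidth_nm
    R = spec.radii_nm[vesicle]

    along = sx * ux + sy * uy
    perp = np.abs(sx * (-uy) + sy * ux)
    # flat face: plane segment at distance a, lateral half-width h
    d_face = np.where(
        perp <= h,
        np.abs(along - a),
        np.hypot(along - a, perp - h),
    )
    sgn_face = np.sign(along - a)
    # spherical part, excluding the cap replaced by the chord
    with np.errstate(invalid="ignore"):
        mu = np.where(r > 0, along / np.maximum(r, 1e-300), 0.0)
    d_circ = np.where(mu <= a / R, np.abs(r - R), np.inf)
    sgn_circ = np.sign(r - R)

    on_face = d_face < d_circ
    sd = np.where(on_face, sgn_face * d_face, sgn_circ * d_circ)
    in_contact = on_face & (perp <= h)
    return sd, in_contact


def generate_vesicle_pair_image(
    spec: VesicleImageSpec,
) -> tuple[ImageWithScale, ImageWithScale, GroundTruth]:
    """Render the density and protein channels plus ground truth.

    Returns (density, protein, truth). Rendering is noise-free ridge
    sums; Gaussian noise of ``spec.noise_sigma`` is added afterwards,
    density channel first, from a generator seeded with ``spec.seed``.
    """
    ny, nx = spec.image_size_px
    px = spec.pixel_size_nm
    yy, xx = np.meshgrid(np.arange(ny) * px, np.arange(nx) * px, indexing="ij")
    sig = spec.headgroup_ridge_sigma_nm
    two_s2 = 2.0 * sig * sig

    density = np.zeros((ny, nx))
    protein = np.zeros((ny, nx))
    for v in range(len(spec.centers_nm)):
        sd, in_contact = _signed_distance(spec, xx, yy, v)
        t = np.where(
            in_contact & (spec.docking_type == "tight"),
            spec.interface_thickness_nm(),
            spec.membrane_thickness_nm,
        )
        half = t / 2.0
        density += np.exp(-((sd - half) ** 2) / two_s2)
        density += np.exp(-((sd + half) ** 2) / two_s2)
        amp = np.where(in_contact, spec.protein_interface_ratio, 1.0)
        protein += amp * np.exp(-(sd ** 2) / two_s2)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        density = density + rng.normal(0.0, spec.noise_sigma, density.shape)
        protein = protein + rng.normal(0.0, spec.noise_sigma, protein.shape)

    if spec.docking_type == "free":
        gap = contact_center = normal = None
    else:
        c = np.asarray(spec.centers_nm, float)
        d = np.linalg.norm(c[1] - c[0])
        u = (c[1] - c[0]) / d
        a1, _ = spec.chord_distances_nm()
        gap = spec.face_gap_nm()
        contact_center = tuple(c[0] + (a1 + gap / 2.0) * u)
        normal = (float(u[0]), float(u[1]))

    truth = GroundTruth(
        docking_label=spec.docking_type,
        protein_interface_ratio=spec.protein_interface_ratio,
        membrane_thickness_nm=spec.membrane_thickness_nm,
        interface_thickness_nm=spec.interface_thickness_nm(),
        centers_nm=spec.centers_nm,
        radii_nm=spec.radii_nm,
        contact_halfwidth_nm=spec.contact_halfwidth_nm,
        face_gap_nm=gap,
        contact_center_nm=contact_center,
        contact_normal=normal,
        meta={"seed": spec.seed, "pixel_size_nm": px},
    )
    return (
        ImageWithScale(density, px),
        ImageWithScale(protein, px),
        truth,
    )


def free_vesicle_spec(
    radius_nm: float = 30.0,
    membrane_thickness_nm: float = 4.0,
    pixel_size_nm: float = 0.5,
    margin_nm: float = 10.0,
    seed: int = 0,
    **kwargs,
) -> VesicleImageSpec:
    """A single free vesicle centred in a just-large-enough image."""
    half = radius_nm + membrane_thickness_nm + margin_nm
    n = int(round(2 * half / pixel_size_nm)) | 1
    c = (n // 2) * pixel_size_nm
    return VesicleImageSpec(
        image_size_px=(n, n),
        pixel_size_nm=pixel_size_nm,
        centers_nm=((c, c),),
        radii_nm=(radius_nm,),
        docking_type="free",
        membrane_thickness_nm=membrane_thickness_nm,
        seed=seed,
        **kwargs,
    )


def docked_pair_spec(
    docking_type: str,
    radius_nm: float = 30.0,
    membrane_thickness_nm: float = 4.0,
    interface_thickening_nm: float = 0.6,
    contact_halfwidth_nm: float = 12.0,
    gap_nm: float | None = None,
    protein_interface_ratio: float | None = None,
    pixel_size_nm: float = 0.5,
    margin_nm: float = 10.0,
    seed: int = 0,
    **kwargs,
) -> VesicleImageSpec:
    """A docked pair along the x axis with a given mid-surface face gap.

    Defaults encode the study conditions: tight interfaces are
    protein-depleted (ratio 0.2) and thickened by 0.6 nm; loose
    interfaces are protein-enriched (ratio 1.6) and not thickened. When
    ``gap_nm`` is omitted, the faces are separated so that the proximal
    headgroup ridges of the apposed membranes sit 2.5 nm apart and all
    four peaks are resolvable in a line profile.
    """
    if docking_type not in ("loose", "tight"):
        raise ValueError("docked pair must be 'loose' or 'tight'")
    if docking_type == "loose":
        interface_thickening_nm = 0.0
    t_int = membrane_thickness_nm + (
        interface_thickening_nm if docking_type == "tight" else 0.0
    )
    if gap_nm is None:
        gap_nm = t_int + 2.5
    if protein_interface_ratio is None:
        protein_interface_ratio = 0.2 if docking_type == "tight" else 1.6
    a = math.sqrt(radius_nm ** 2 - contact_halfwidth_nm ** 2)
    sep = 2 * a + gap_nm
    half_w = radius_nm + sep / 2.0 + membrane_thickness_nm + margin_nm
    half_h = radius_nm + membrane_thickness_nm + margin_nm
    nx = int(round(2 * half_w / pixel_size_nm)) | 1
    ny = int(round(2 * half_h / pixel_size_nm)) | 1
    cy = (ny // 2) * pixel_size_nm
    cx = (nx // 2) * pixel_size_nm
    centers = ((cx - sep / 2.0, cy), (cx + sep / 2.0, cy))
    return VesicleImageSpec(
        image_size_px=(ny, nx),
        pixel_size_nm=pixel_size_nm,
        centers_nm=centers,
        radii_nm=(radius_nm, radius_nm),
        docking_type=docking_type,
        membrane_thickness_nm=membrane_thickness_nm,
        interface_thickening_nm=interface_thickening_nm,
        contact_halfwidth_nm=contact_halfwidth_nm,
        protein_interface_ratio=protein_interface_ratio,
        seed=seed,
        **kwargs,
    )
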