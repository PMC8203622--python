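"""Shared containers for images, profiles, coordinate frames and fits.

Units are nanometres for lengths, nanoseconds for times, kJ/mol for
energies and elementary charges for partial charges throughout the
package; degrees appear only at the CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageWithScale",
    "IntensityProfile",
    "ThicknessMeasurement",
    "DockingCall",
    "GroupTestResult",
    "BilayerFrame",
    "LeafletAssignment",
    "RelaxationFit",
]

#: particle roles understood by the trajectory metrics
ROLES = ("P", "N", "chain", "water")


@dataclass
class ImageWithScale:
    """A single-channel 2D image with a physical pixel size.

    Pixel centres sit at integer (row, col) indices; physical position in
    nm is ``index * pixel_size_nm`` (0-based convention).
    """

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def extent_nm(self) -> tuple[float, float]:
        """Physical size (height, width) spanned by pixel centres."""
        return (
            (self.data.shape[0] - 1) * self.pixel_size_nm,
            (self.data.shape[1] - 1) * self.pixel_size_nm,
        )


@dataclass
class IntensityProfile:
    """1D intensity vs physical position along a line or a radius.

    ``positions_nm`` is strictly increasing with uniform spacing.
    ``valid`` flags samples whose value is defined (radial bins can be
    empty); undefined samples hold NaN.
    """

    positions_nm: np.ndarray
    intensities: np.ndarray
    provenance: dict = field(default_factory=dict)
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions_nm.ndim != 1 or self.positions_nm.size < 8:
            raise ValueError("profile needs at least 8 samples")
        if self.positions_nm.shape != self.intensities.shape:
            raise ValueError("positions and intensities differ in length")
        d = np.diff(self.positions_nm)
        if np.any(d <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.ptp(d) > 1e-9 * abs(d.mean()):
            raise ValueError("positions must be uniformly spaced")
        if self.valid is None:
            self.valid = np.isfinite(self.intensities)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def spacing_nm(self) -> float:
        return float(np.mean(np.diff(self.positions_nm)))


@dataclass
class ThicknessMeasurement:
    """Peak-to-peak membrane thickness from one intensity profile.

    ``thickness_nm`` is the distance between the two headgroup peaks
    assigned to one membrane; it is None when the peaks could not be
    resolved (``resolved`` False), e.g. when proximal ridges of a tight
    interface have blended.
    """

    peak_positions_nm: tuple[float, ...]
    thickness_nm: Optional[float]
    resolved: bool
    membrane_id: int = 0
    context: str = "free"

    def __post_init__(self) -> None:
        if self.resolved:
            if self.thickness_nm is None or len(self.peak_positions_nm) != 2:
                raise ValueError("resolved measurement needs exactly two peaks")
            lo, hi = sorted(self.peak_positions_nm)
            if not np.isclose(self.thickness_nm, hi - lo):
                raise ValueError("thickness must equal the peak separation")
        elif self.thickness_nm is not None:
            raise ValueError("unresolved measurement must not carry a thickness")


@dataclass
class DockingCall:
    """Loose/tight docking classification from protein-signal depletion."""

    label: str
    interface_ratio: float
    threshold: float

    def __post_init__(self) -> None:
        if self.label not in ("loose", "tight"):
            raise ValueError("label must be 'loose' or 'tight'")
        expected = "tight" if self.interface_ratio < self.threshold else "loose"
        if self.label != expected:
            raise ValueError("label inconsistent with ratio/threshold")


@dataclass
class GroupTestResult:
    """Outcome of a two-group comparison."""

    test: str
    statistic: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int
    alpha: float = 0.05
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class BilayerFrame:
    """Labeled particle coordinates of one or two bilayers.

    ``roles`` holds one of :data:`ROLES` per particle; ``lipid_index`` is
    -1 for particles not belonging to a lipid (water). Box is
    orthorhombic. Positions are wrapped into the box on construction.
    """

    positions: np.ndarray  # (n, 3) nm
    roles: np.ndarray  # (n,) str
    lipid_index: np.ndarray  # (n,) int, -1 for non-lipid
    box_nm: np.ndarray  # (3,)
    time_ns: float = 0.0
    truth: Optional[dict] = None  # generator ground truth, if any

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.roles = np.asarray(self.roles)
        self.lipid_index = np.asarray(self.lipid_index, dtype=np.int64)
        self.box_nm = np.asarray(self.box_nm, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        n = len(self.positions)
        if len(self.roles) != n or len(self.lipid_index) != n:
            raise ValueError("per-particle arrays disagree in length")
        if self.box_nm.shape != (3,) or np.any(self.box_nm <= 0):
            raise ValueError("box must be 3 positive lengths")
        bad = ~np.isin(self.roles, ROLES)
        if bad.any():
            raise ValueError(f"unknown roles: {set(self.roles[bad])}")
        # each lipid must carry exactly one P and one N
        for role in ("P", "N"):
            idx = self.lipid_index[self.roles == role]
            uniq, counts = np.unique(idx, return_counts=True)
            lipids = np.unique(self.lipid_index[self.lipid_index >= 0])
            if not np.array_equal(uniq, lipids) or np.any(counts != 1):
                raise ValueError(f"each lipid needs exactly one {role} particle")
        self.positions = self.positions % self.box_nm

    @property
    def n_lipids(self) -> int:
        return int(np.sum(self.roles == "P"))

    def select(self, role: str) -> np.ndarray:
        """Positions of all particles with the given role."""
        return self.positions[self.roles == role]


@dataclass
class LeafletAssignment:
    """Per-lipid membrane and leaflet labels.

    ``membrane_id`` in {0, .., n_membranes-1} ordered bottom-to-top in z;
    ``leaflet_id`` 0 = bottom leaflet, 1 = top leaflet of its membrane.
    ``normal_sign`` is +1 where the outward normal of the leaflet points
    along +z (the top leaflet of each membrane) and -1 otherwise.
    """

    membrane_id: np.ndarray  # (n_lipids,)
    leaflet_id: np.ndarray  # (n_lipids,)
    n_membranes: int
    lipid_ids: np.ndarray  # lipid index of each row

    def __post_init__(self) -> None:
        self.membrane_id = np.asarray(self.membrane_id, dtype=np.int64)
        self.leaflet_id = np.asarray(self.leaflet_id, dtype=np.int64)
        self.lipid_ids = np.asarray(self.lipid_ids, dtype=np.int64)

    @property
    def normal_sign(self) -> np.ndarray:
        return np.where(self.leaflet_id == 1, 1, -1)

    def lipids_of(self, membrane_id: int, leaflet_id: int) -> np.ndarray:
        mask = (self.membrane_id == membrane_id) & (self.leaflet_id == leaflet_id)
        return self.lipid_ids[mask]

    def gap_facing(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(membrane, leaflet) pairs of the two leaflets facing the gap."""
        if self.n_membranes != 2:
            raise ValueError("gap only defined for double-membrane systems")
        return (0, 1), (1, 0)


@dataclass
class RelaxationFit:
    """Parameters of f(t) = x_inf + (x0 - x_inf) exp(-t / tau)."""

    x0: float
    x_inf: float
    tau_ns: float
    residual_rms: float
    converged: bool
    n_points: int = 0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return self.x_inf + (self.x0 - self.x_inf) * np.exp(-t / self.tau_ns)
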