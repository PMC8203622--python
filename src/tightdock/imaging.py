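"""Membrane thickness from image intensity profiles.

Thickness is read out as the distance between the two intensity peaks
of a profile crossing a membrane — the peaks mark the lipid headgroup
layers of the two leaflets. Docking interfaces are profiled with line
scans perpendicular to the contact plane; free membranes with radial
(azimuthally averaged) profiles about the vesicle centre. Docking state
is called from protein-signal depletion at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .datatypes import DockingCall, ImageWithScale, IntensityProfile, ThicknessMeasurement

__all__ = [
    "PeakParams",
    "line_profile",
    "radial_profile",
    "detect_headgroup_peaks",
    "measure_thickness",
    "interface_line_endpoints",
    "classify_interface",
    "estimate_background",
]


@dataclass
class PeakParams:
    """Peak-detection settings shared by thickness measurements.

    smoothing_sigma_px: Gaussian smoothing before peak finding.
    min_separation_nm: peaks closer than this are not both reported.
    min_prominence_frac: prominence threshold as a fraction of the
    profile dynamic range.
    """

    smoothing_sigma_px: float = 1.0
    min_separation_nm: float = 1.0
    min_prominence_frac: float = 0.1


def line_profile(
    image: ImageWithScale,
    start_nm: tuple[float, float],
    end_nm: tuple[float, float],
    width_px: int = 1,
) -> IntensityProfile:
    """Sample intensity along a segment, averaged over parallel lines.

    Points are (x, y) in nm. Samples are spaced one pixel apart
    (bilinear interpolation); ``width_px`` (odd) parallel lines at
    integer-pixel perpendicular offsets are averaged.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be an odd positive integer")
    px = image.pixel_size_nm
    p0 = np.asarray(start_nm, float) / px  # (col, row)
    p1 = np.asarray(end_nm, float) / px
    ny, nx = image.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1):
            raise ValueError("profile endpoints must lie inside the image")
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("degenerate zero-length segment")
    n = int(np.floor(length)) + 1
    if n < 8:
        n = 8
    s = np.linspace(0.0, length, n)
    u = (p1 - p0) / length
    v = np.array([-u[1], u[0]])  # unit perpendicular
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    acc = np.zeros(n)
    for off in offsets:
        pts = p0 + s[:, None] * u + off * v  # (n, 2) in (col, row)
        acc += ndimage.map_coordinates(
            image.data, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
        )
    return IntensityProfile(
        positions_nm=s * px,
        intensities=acc / width_px,
        provenance={
            "kind": "line",
            "start_nm": tuple(start_nm),
            "end_nm": tuple(end_nm),
            "width_px": width_px,
        },
    )


def radial_profile(
    image: ImageWithScale,
    center_nm: tuple[float, float],
    r_max_nm: float,
    bin_width_px: float = 1.0,
) -> IntensityProfile:
    """Mean intensity vs distance from a centre, binned by pixel radius.

    Each pixel whose centre falls within ``r_max_nm`` contributes to the
    bin containing its distance. Empty bins are NaN and flagged invalid.
    """
    if r_max_nm <= 0 or bin_width_px <= 0:
        raise ValueError("r_max and bin width must be positive")
    px = image.pixel_size_nm
    cx, cy = np.asarray(center_nm, float) / px
    ny, nx = image.shape
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError("centre must lie inside the image")
    yy, xx = np.indices(image.shape)
    r_px = np.hypot(xx - cx, yy - cy)
    bw = bin_width_px
    n_bins = int(np.ceil(r_max_nm / (bw * px)))
    idx = np.floor(r_px / bw).astype(int)
    mask = idx < n_bins
    counts = np.bincount(idx[mask], minlength=n_bins)
    sums = np.bincount(idx[mask], weights=image.data[mask], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    centers = (np.arange(n_bins) + 0.5) * bw * px
    return IntensityProfile(
        positions_nm=centers,
        intensities=means,
        provenance={
            "kind": "radial",
            "center_nm": tuple(center_nm),
            "bin_width_px": bin_width_px,
        },
        valid=counts > 0,
    )


def _quadratic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample peak offset from a 3-point parabola through i-1,i,i+1."""
    if i == 0 or i == len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_headgroup_peaks(
    profile: IntensityProfile, params: PeakParams | None = None
) -> np.ndarray:
    """Positions (nm) of qualifying intensity maxima, sub-sample refined.

    Maxima of the Gaussian-smoothed profile whose prominence exceeds
    ``min_prominence_frac`` of the dynamic range and that are at least
    ``min_separation_nm`` apart; each is refined by a quadratic fit
    through the peak sample and its neighbours. Sorted by position;
    empty when nothing qualifies.
    """
    params = params or PeakParams()
    y = profile.intensities.copy()
    if profile.valid is not None and not profile.valid.all():
        # interpolate across flagged samples so smoothing stays defined
        good = profile.valid
        if good.sum() < 2:
            return np.array([])
        y[~good] = np.interp(
            profile.positions_nm[~good], profile.positions_nm[good], y[good]
        )
    if params.smoothing_sigma_px > 0:
        y = ndimage.gaussian_filter1d(y, params.smoothing_sigma_px, mode="nearest")
    rng_y = float(np.ptp(y))
    if rng_y == 0:
        return np.array([])
    spacing = profile.spacing_nm
    distance = max(1, int(round(params.min_separation_nm / spacing)))
    idx, _ = signal.find_peaks(
        y, prominence=params.min_prominence_frac * rng_y, distance=distance
    )
    pos = np.array(
        [profile.positions_nm[i] + _quadratic_refine(y, i) * spacing for i in idx]
    )
    return np.sort(pos)


def measure_thickness(
    profile: IntensityProfile,
    context: str = "free",
    params: PeakParams | None = None,
) -> list[ThicknessMeasurement]:
    """Per-membrane peak-to-peak thickness from one profile.

    ``context='free'`` expects the two headgroup peaks of a single
    membrane; ``context='interface'`` expects up to four peaks across
    the apposed double membrane, assigned outer/inner pairs to the two
    membranes by position order. Fewer peaks than expected (blended
    proximal ridges, unresolved leaflets) yield ``resolved=False``.
    """
    if context not in ("free", "interface"):
        raise ValueError("context must be 'free' or 'interface'")
    peaks = detect_headgroup_peaks(profile, params)
    if context == "free":
        if len(peaks) < 2:
            return [ThicknessMeasurement((), None, False, 0, context)]
        if len(peaks) > 2:
            # keep the two tallest of the qualifying peaks
            heights = np.interp(peaks, profile.positions_nm, profile.intensities)
            peaks = np.sort(peaks[np.argsort(heights)[-2:]])
        lo, hi = peaks
        return [ThicknessMeasurement((lo, hi), hi - lo, True, 0, context)]
    # interface: sorted peaks p0<p1 belong to membrane 0, p2<p3 to membrane 1
    if len(peaks) == 4:
        return [
            ThicknessMeasurement(
                (peaks[0], peaks[1]), peaks[1] - peaks[0], True, 0, context
            ),
            ThicknessMeasurement(
                (peaks[2], peaks[3]), peaks[3] - peaks[2], True, 1, context
            ),
        ]
    if len(peaks) > 4:
        heights = np.interp(peaks, profile.positions_nm, profile.intensities)
        peaks = np.sort(peaks[np.argsort(heights)[-4:]])
        return measure_thickness_from_peaks(peaks, context)
    # merged proximal ridges: per-membrane assignment is ambiguous
    return [
        ThicknessMeasurement(tuple(peaks), None, False, m, context) for m in (0, 1)
    ]


def measure_thickness_from_peaks(peaks: np.ndarray, context: str) -> list[ThicknessMeasurement]:
    """Thickness from already-detected (sorted) peak positions."""
    peaks = np.sort(np.asarray(peaks, float))
    if context == "free" and len(peaks) == 2:
        return [ThicknessMeasurement(tuple(peaks), peaks[1] - peaks[0], True, 0, context)]
    if context == "interface" and len(peaks) == 4:
        return [
            ThicknessMeasurement((peaks[0], peaks[1]), peaks[1] - peaks[0], True, 0, context),
            ThicknessMeasurement((peaks[2], peaks[3]), peaks[3] - peaks[2], True, 1, context),
        ]
    raise ValueError("unexpected peak count for context")


def estimate_background(image: ImageWithScale, border_px: int = 5) -> float:
    """Median intensity over a border frame of the image."""
    d = image.data
    if border_px < 1 or 2 * border_px >= min(d.shape):
        raise ValueError("invalid border width")
    frame = np.concatenate(
        [
            d[:border_px].ravel(),
            d[-border_px:].ravel(),
            d[border_px:-border_px, :border_px].ravel(),
            d[border_px:-border_px, -border_px:].ravel(),
        ]
    )
    return float(np.median(frame))


def interface_line_endpoints(
    truth, length_nm: float = 20.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Segment through the contact centre, perpendicular to the contact
    plane, suitable for an interface line profile (from ground truth)."""
    if truth.contact_center_nm is None:
        raise ValueError("image has no docking interface")
    c = np.asarray(truth.contact_center_nm)
    n = np.asarray(truth.contact_normal)
    return tuple(c - n * length_nm / 2.0), tuple(c + n * length_nm / 2.0)


def classify_interface(
    protein_image: ImageWithScale,
    interface_segment: tuple[tuple[float, float], tuple[float, float]],
    free_segment: tuple[tuple[float, float], tuple[float, float]],
    threshold: float = 0.6,
    width_px: int = 5,
    background: float | None = None,
) -> DockingCall:
    """Call loose vs tight docking from protein-signal depletion.

    The interface ratio is the background-subtracted peak protein signal
    of a line profile across the docking interface divided by the same
    quantity on the free membrane; a ratio below ``threshold`` means the
    protein is depleted from the contact and the pair is tightly docked
    (ties go to loose). Being a ratio, the call is invariant to global
    intensity rescaling when the background is estimated from the image.
    """
    if background is None:
        background = estimate_background(protein_image)
    prof_int = line_profile(protein_image, *interface_segment, width_px=width_px)
    prof_free = line_profile(protein_image, *free_segment, width_px=width_px)
    sig_free = float(prof_free.intensities.max()) - background
    if sig_free <= 0:
        raise ValueError("free-membrane protein signal does not exceed background")
    sig_int = float(prof_int.intensities.max()) - background
    ratio = sig_int / sig_free
    label = "tight" if ratio < threshold else "loose"
    return DockingCall(label=label, interface_ratio=ratio, threshold=threshold)
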