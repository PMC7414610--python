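"""Scan geometry: raster grids, visual-angle calibration, and polar resampling.

Hand-held OCT raster volumes are acquired on a strongly anisotropic grid
(A-scan spacing ~20 µm along a B-scan, B-scan spacing ~100 µm between
B-scans).  Circumpapillary RNFL analysis samples the segmented thickness map
along circles and annuli centred on the optic nerve head (ONH), with radii
expressed as visual angles.  This module owns the coordinate conventions:

* Image frame: x grows with A-scan index (columns), y with B-scan index
  (rows); the origin is the top-left pixel *centre* offset, i.e. pixel (row
  j, col i) is centred at ((i + 0.5)·dx, (j + 0.5)·dy) in mm.
* Anatomical TSNIT frame: theta = 0° temporal, 90° superior, 180° nasal,
  270° inferior.  For a right eye (OD) temporal maps to −x and superior to
  −y (image up); left eyes (OS) are mirrored about the vertical axis so
  nasal/temporal remain anatomically correct.
* Visual angle: lateral distance r (mm) relates to eccentricity r_deg
  (degrees) through a fixed scale, 288 µm per degree in the adult eye.

Thickness values are bilinearly interpolated in physical (mm) coordinates so
the anisotropic spacings are respected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AngleCalibration",
    "RasterScan",
    "QuadrantScheme",
    "CircumpapillaryProfile",
    "QUADRANTS",
    "deg_to_mm",
    "mm_to_deg",
    "crop_to_window",
    "sample_ring",
    "sample_annulus",
    "assign_quadrants",
    "tsnit_direction",
]

#: Canonical quadrant order (TSNIT).
QUADRANTS = ("temporal", "superior", "nasal", "inferior")


@dataclass(frozen=True)
class AngleCalibration:
    """Visual-angle calibration: retinal micrometres per degree of eccentricity."""

    um_per_degree: float = 288.0

    def __post_init__(self) -> None:
        if not self.um_per_degree > 0:
            raise ValueError("um_per_degree must be strictly positive")


def deg_to_mm(r_deg: float, cal: AngleCalibration = AngleCalibration()) -> float:
    """Convert a visual angle (degrees) to a lateral retinal distance in mm.

    With the default adult-eye scale of 288 µm/degree, 6° ≈ 1.73 mm — the
    conventional circumpapillary measurement radius.
    """
    r = np.asarray(r_deg, dtype=float)
    if np.any(r < 0):
        raise ValueError("visual-angle radius must be nonnegative")
    out = r * cal.um_per_degree / 1000.0
    return float(out) if np.isscalar(r_deg) else out


def mm_to_deg(r_mm: float, cal: AngleCalibration = AngleCalibration()) -> float:
    """Inverse of :func:`deg_to_mm`: lateral distance (mm) to visual angle (degrees)."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be nonnegative")
    out = r * 1000.0 / cal.um_per_degree
    return float(out) if np.isscalar(r_mm) else out


@dataclass
class RasterScan:
    """A segmented RNFL thickness map on a raster A-scan/B-scan grid.

    ``thickness`` is an (n_bscans, n_ascans) array of µm values;
    ``valid_mask`` flags pixels with a usable segmentation (the optic disc
    interior and any uncaptured quadrant are invalid).
    """

    thickness: np.ndarray
    valid_mask: np.ndarray
    extent_x_mm: float
    extent_y_mm: float
    onh_center_mm: tuple[float, float]
    laterality: str = "OD"
    quality: float = 1.0
    subject_id: str = ""
    scan_id: str = ""
    assessor_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.thickness.ndim != 2:
            raise ValueError("thickness must be a 2D (n_bscans, n_ascans) array")
        if self.valid_mask.shape != self.thickness.shape:
            raise ValueError("valid_mask shape must match thickness")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if not (0 < self.quality <= 1):
            raise ValueError("quality index must lie in (0, 1]")
        cx, cy = self.onh_center_mm
        if not (0 <= cx <= self.extent_x_mm and 0 <= cy <= self.extent_y_mm):
            raise ValueError("onh_center_mm must lie inside the scan extent")
        if np.any(self.thickness[self.valid_mask] < 0):
            raise ValueError("thickness must be nonnegative wherever valid")

    @property
    def n_ascans(self) -> int:
        return self.thickness.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.thickness.shape[0]

    @property
    def ascan_spacing_mm(self) -> float:
        return self.extent_x_mm / self.n_ascans

    @property
    def bscan_spacing_mm(self) -> float:
        return self.extent_y_mm / self.n_bscans

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) pixel-centre coordinate vectors in mm."""
        dx, dy = self.ascan_spacing_mm, self.bscan_spacing_mm
        x = (np.arange(self.n_ascans) + 0.5) * dx
        y = (np.arange(self.n_bscans) + 0.5) * dy
        return x, y


@dataclass(frozen=True)
class QuadrantScheme:
    """Angular partition of the circle into TSNIT quadrants.

    ``boundaries`` maps quadrant name -> (start_deg, end_deg) in the TSNIT
    frame, end exclusive, sectors wrapping mod 360.  Two built-ins are
    provided: ``equal90`` (four 90° sectors centred on 0/90/180/270) and
    ``gdx`` (unequal sectors after the GDx Nerve Fiber Analyzer: temporal
    50°, superior 120°, nasal 70°, inferior 120°).
    """

    boundaries: Mapping[str, tuple[float, float]]
    scheme_name: str = "custom"

    def __post_init__(self) -> None:
        if set(self.boundaries) != set(QUADRANTS):
            raise ValueError(f"scheme must define exactly the quadrants {QUADRANTS}")
        widths = sum((e - s) % 360.0 or 360.0 for s, e in self.boundaries.values())
        if abs(widths - 360.0) > 1e-9:
            raise ValueError("sector widths must sum to 360 degrees")

    def width_deg(self, quadrant: str) -> float:
        s, e = self.boundaries[quadrant]
        return (e - s) % 360.0 or 360.0

    def assign(self, theta_deg: np.ndarray) -> np.ndarray:
        """Label each TSNIT angle with its quadrant name."""
        th = np.asarray(theta_deg, dtype=float) % 360.0
        labels = np.empty(th.shape, dtype=object)
        for name, (s, e) in self.boundaries.items():
            s, e = s % 360.0, e % 360.0
            inside = (th >= s) & (th < e) if s < e else (th >= s) | (th < e)
            labels[inside] = name
        if (labels == None).any():  # noqa: E711 — object-array sentinel check
            raise RuntimeError("quadrant scheme does not cover the circle")
        return labels


EQUAL90 = QuadrantScheme(
    boundaries={
        "temporal": (315.0, 45.0),
        "superior": (45.0, 135.0),
        "nasal": (135.0, 225.0),
        "inferior": (225.0, 315.0),
    },
    scheme_name="equal90",
)

GDX = QuadrantScheme(
    boundaries={
        "temporal": (335.0, 25.0),
        "superior": (25.0, 145.0),
        "nasal": (145.0, 215.0),
        "inferior": (215.0, 335.0),
    },
    scheme_name="gdx",
)

SCHEMES: dict[str, QuadrantScheme] = {"equal90": EQUAL90, "gdx": GDX}


def get_scheme(name: str) -> QuadrantScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown quadrant scheme {name!r}; choose from {sorted(SCHEMES)}")


def tsnit_direction(theta_deg: np.ndarray, laterality: str) -> tuple[np.ndarray, np.ndarray]:
    """Unit vector (dx, dy) in the image frame for a TSNIT angle.

    OD: temporal (0°) points to −x, superior (90°) to −y (image up).
    OS mirrors about the vertical axis, so temporal points to +x.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    sign = -1.0 if laterality == "OD" else 1.0
    return sign * np.cos(th), -np.sin(th)


def image_theta(dx: np.ndarray, dy: np.ndarray, laterality: str) -> np.ndarray:
    """TSNIT angle (degrees, [0, 360)) of an image-frame offset from the ONH."""
    sign = -1.0 if laterality == "OD" else 1.0
    return np.rad2deg(np.arctan2(-np.asarray(dy), sign * np.asarray(dx))) % 360.0


@dataclass
class CircumpapillaryProfile:
    """Thickness sampled at polar points around the ONH.

    ``theta_deg`` holds the nominal TSNIT angles (any ``theta_offset`` used
    at sampling time rotates the physical positions only, so that a frame
    rotation of the scan can be compensated without relabelling sectors).
    ``weight`` carries the polar area element for annuli (∝ radius); rings
    have uniform weights.
    """

    theta_deg: np.ndarray
    r_deg: np.ndarray
    value_um: np.ndarray
    valid: np.ndarray
    weight: np.ndarray
    location: str = ""
    quadrant: np.ndarray | None = None

    def mean(self) -> float:
        """Weight-aware mean thickness over valid samples (NaN if none valid)."""
        v = self.valid
        if not v.any():
            return float("nan")
        w = self.weight[v]
        return float(np.sum(w * self.value_um[v]) / np.sum(w))


def _bilinear(scan: RasterScan, px: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of thickness at physical positions (mm).

    Returns (values, valid); a sample is valid only when all four
    contributing grid nodes are valid and the position lies within the
    pixel-centre bounding box.
    """
    x, y = scan.pixel_centers()
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = (px >= x[0]) & (px <= x[-1]) & (py >= y[0]) & (py <= y[-1])

    # clip so index arithmetic stays in range; out-of-grid samples are
    # flagged invalid regardless of the value computed
    cx = np.clip(px, x[0], x[-1])
    cy = np.clip(py, y[0], y[-1])
    i1 = np.clip(np.searchsorted(x, cx, side="right"), 1, len(x) - 1)
    j1 = np.clip(np.searchsorted(y, cy, side="right"), 1, len(y) - 1)
    i0, j0 = i1 - 1, j1 - 1
    tx = (cx - x[i0]) / (x[i1] - x[i0])
    ty = (cy - y[j0]) / (y[j1] - y[j0])

    t = scan.thickness
    m = scan.valid_mask
    v00, v01 = t[j0, i0], t[j0, i1]
    v10, v11 = t[j1, i0], t[j1, i1]
    vals = (
        v00 * (1 - tx) * (1 - ty)
        + v01 * tx * (1 - ty)
        + v10 * (1 - tx) * ty
        + v11 * tx * ty
    )
    ok = m[j0, i0] & m[j0, i1] & m[j1, i0] & m[j1, i1] & inside
    return vals, ok


def sample_ring(
    scan: RasterScan,
    r_deg: float,
    cal: AngleCalibration = AngleCalibration(),
    n_theta: int = 360,
    theta_offset_deg: float = 0.0,
) -> CircumpapillaryProfile:
    """Sample the thickness map on a circle of visual-angle radius ``r_deg``.

    Samples are taken at n_theta evenly spaced TSNIT angles; a nonzero
    ``theta_offset_deg`` rotates the physical sampling positions (e.g. to
    undo a known rotation of the scan frame) while the recorded angles stay
    nominal.  A ring that leaves the grid yields invalid samples rather than
    an exception.
    """
    if not r_deg > 0:
        raise ValueError("ring radius must be strictly positive")
    if n_theta < 4:
        raise ValueError("need at least 4 angular samples")
    theta = np.arange(n_theta) * 360.0 / n_theta
    r_mm = deg_to_mm(r_deg, cal)
    ux, uy = tsnit_direction(theta + theta_offset_deg, scan.laterality)
    cx, cy = scan.onh_center_mm
    vals, ok = _bilinear(scan, cx + r_mm * ux, cy + r_mm * uy)
    return CircumpapillaryProfile(
        theta_deg=theta,
        r_deg=np.full(n_theta, float(r_deg)),
        value_um=vals,
        valid=ok,
        weight=np.ones(n_theta),
        location=f"ring{r_deg:g}",
    )


def sample_annulus(
    scan: RasterScan,
    r_inner_deg: float,
    r_outer_deg: float,
    cal: AngleCalibration = AngleCalibration(),
    n_theta: int = 360,
    n_r: int = 8,
    theta_offset_deg: float = 0.0,
) -> CircumpapillaryProfile:
    """Sample the annulus between two visual-angle radii on a polar grid.

    Radii are midpoints of ``n_r`` equal-width shells; each sample carries
    weight ∝ its radius (the polar area element), so the weighted mean
    converges to the true area average of the annulus.
    """
    if not (0 < r_inner_deg < r_outer_deg):
        raise ValueError("need 0 < r_inner < r_outer")
    if n_theta < 4 or n_r < 1:
        raise ValueError("need n_theta >= 4 and n_r >= 1")
    edges = np.linspace(r_inner_deg, r_outer_deg, n_r + 1)
    radii = 0.5 * (edges[:-1] + edges[1:])
    theta = np.arange(n_theta) * 360.0 / n_theta

    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    ux, uy = tsnit_direction(tt + theta_offset_deg, scan.laterality)
    r_mm = deg_to_mm(rr, cal)
    cx, cy = scan.onh_center_mm
    vals, ok = _bilinear(scan, cx + r_mm * ux, cy + r_mm * uy)
    return CircumpapillaryProfile(
        theta_deg=tt.ravel(),
        r_deg=rr.ravel(),
        value_um=vals.ravel(),
        valid=ok.ravel(),
        weight=rr.ravel().copy(),
        location=f"annulus{r_inner_deg:g}-{r_outer_deg:g}",
    )


def assign_quadrants(
    profile: CircumpapillaryProfile,
    scheme: QuadrantScheme = EQUAL90,
    laterality: str | None = None,
) -> CircumpapillaryProfile:
    """Label each profile sample with its TSNIT quadrant.

    Profiles are sampled in the anatomical TSNIT frame (eye mirroring is
    handled at sampling time), so the labels follow directly from the
    recorded angles; ``laterality`` is accepted for interface symmetry but
    does not alter the binning.
    """
    profile.quadrant = scheme.assign(profile.theta_deg)
    return profile


def crop_to_window(
    scan: RasterScan,
    window_mm: tuple[float, float],
    center: tuple[float, float] | None = None,
) -> RasterScan:
    """Crop a scan to a window (mm) centred on the ONH (or a given centre).

    The window is clamped so it stays inside the source extent; the ONH
    centre is recomputed in the cropped frame and the applied offset is
    recorded in ``meta['crop_offset_mm']``.  A window at least as large as
    the source in both axes is a no-op (logged).
    """
    w, h = window_mm
    if w >= scan.extent_x_mm and h >= scan.extent_y_mm:
        logger.warning(
            "crop window %.3gx%.3g mm covers the whole %.3gx%.3g mm scan; no-op",
            w, h, scan.extent_x_mm, scan.extent_y_mm,
        )
        return scan
    cx, cy = center if center is not None else scan.onh_center_mm
    dx, dy = scan.ascan_spacing_mm, scan.bscan_spacing_mm

    def _axis(c: float, width: float, spacing: float, n: int):
        n_new = min(int(round(width / spacing)), n)
        start = int(round(c / spacing - n_new / 2.0))
        start = max(0, min(start, n - n_new))
        return start, n_new

    ci, nw = _axis(cx, w, dx, scan.n_ascans)
    cj, nh = _axis(cy, h, dy, scan.n_bscans)

    off_x, off_y = ci * dx, cj * dy
    new_cx = min(max(scan.onh_center_mm[0] - off_x, 0.0), nw * dx)
    new_cy = min(max(scan.onh_center_mm[1] - off_y, 0.0), nh * dy)
    meta = dict(scan.meta)
    meta["crop_offset_mm"] = (off_x, off_y)
    return replace(
        scan,
        thickness=scan.thickness[cj : cj + nh, ci : ci + nw].copy(),
        valid_mask=scan.valid_mask[cj : cj + nh, ci : ci + nw].copy(),
        extent_x_mm=nw * dx,
        extent_y_mm=nh * dy,
        onh_center_mm=(new_cx, new_cy),
        meta=meta,
    )
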