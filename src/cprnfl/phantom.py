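"""Synthetic retinal phantom: ground-truth RNFL fields and simulated scan pairs.

The circumpapillary RNFL of a healthy eye follows a "double-hump" profile:
thick superior and inferior arcuate bundles (~105 µm at 6° eccentricity)
over a thinner temporal/nasal baseline (~61/65 µm), all decaying with
distance from the optic nerve head.  Glaucomatous damage is modelled as
global multiplicative thinning.  The generator produces that field
analytically and renders it onto the hand-held OCT raster grid with a
variance-component error model:

* a between-subject offset (biological spread, SD ``sigma_subject_um``),
* a per-acquisition scan offset (probe repositioning, SD ``sigma_scan_um``),
* a per-segmentation assessor offset (SD ``sigma_assessor_um``),
* white pixel noise whose SD scales inversely with the scan quality index.

All offsets are additive and global, matching the quadrant-level resolution
of the downstream reliability analysis; every random draw is keyed by
(seed, subject, scan, assessor) so cohorts are reproducible and extensible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .geometry import (
    EQUAL90,
    AngleCalibration,
    QuadrantScheme,
    RasterScan,
    image_theta,
    mm_to_deg,
)

__all__ = [
    "PhantomParams",
    "GroundTruthField",
    "make_truth",
    "render_scan",
    "simulate_cohort",
    "simulate_quadrant_cohort",
]

Design = Literal["test_retest", "interassessor"]


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic cohort generator.

    The four thickness levels are the target quadrant means (µm) of the
    control field on the 6° ring under the equal90 scheme; the angular
    profile is calibrated so they are met exactly.  Noise SDs are in µm.
    """

    grid_n_ascans: int = 600
    grid_n_bscans: int = 80
    extent_x_mm: float = 12.0
    extent_y_mm: float = 8.0
    disc_radius_deg: float = 0.95
    base_temporal_um: float = 61.12
    base_nasal_um: float = 65.44
    peak_superior_um: float = 106.43
    peak_inferior_um: float = 104.64
    radial_decay_per_deg: float = 0.08
    glaucoma_factor: float = 1.0
    sigma_subject_um: float = 12.0
    sigma_scan_um: float = 3.5
    sigma_assessor_um: float = 1.8
    sigma_pixel_um: float = 8.0
    quality_high: float = 1.0
    quality_low: float = 0.5
    tilt_deg: float = 0.0
    missing_quadrant_prob: float = 0.06
    noise_ref_radius_deg: float | None = None
    um_per_degree: float = 288.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("sigma_subject_um", "sigma_scan_um", "sigma_assessor_um", "sigma_pixel_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.glaucoma_factor <= 1):
            raise ValueError("glaucoma_factor must lie in (0, 1]")
        for name in ("quality_high", "quality_low"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 <= self.missing_quadrant_prob <= 1):
            raise ValueError("missing_quadrant_prob must lie in [0, 1]")
        if self.disc_radius_deg >= 4.0:
            raise ValueError("disc radius must be < 4 degrees (inner measurement ring)")
        if self.disc_radius_deg <= 0:
            raise ValueError("disc radius must be positive")
        if 1.0 + self.radial_decay_per_deg * (self.disc_radius_deg - 4.0) <= 0:
            raise ValueError("radial decay too steep: thickness would diverge at the disc edge")
        if self.noise_ref_radius_deg is not None and self.noise_ref_radius_deg <= 0:
            raise ValueError("noise_ref_radius_deg must be positive when set")

    @property
    def calibration(self) -> AngleCalibration:
        return AngleCalibration(self.um_per_degree)


def _raised_cosine(theta_deg: np.ndarray, center_deg: float, half_width_deg: float = 60.0) -> np.ndarray:
    """Smooth bump: 0.5·(1 + cos(π·Δ/half_width)) for |Δ| ≤ half_width, else 0."""
    d = (np.asarray(theta_deg, dtype=float) - center_deg + 180.0) % 360.0 - 180.0
    out = np.where(
        np.abs(d) <= half_width_deg,
        0.5 * (1.0 + np.cos(np.pi * d / half_width_deg)),
        0.0,
    )
    return out


def _angular_basis(theta_deg: np.ndarray) -> np.ndarray:
    """The four angular shape functions: temporal/nasal cosine ramps + S/I bumps."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    f_t = 0.5 * (1.0 + np.cos(th))
    f_n = 0.5 * (1.0 - np.cos(th))
    f_s = _raised_cosine(theta_deg, 90.0)
    f_i = _raised_cosine(theta_deg, 270.0)
    return np.stack([f_t, f_n, f_s, f_i])


def _solve_angular_coeffs(params: PhantomParams, scheme: QuadrantScheme = EQUAL90) -> np.ndarray:
    """Coefficients of the angular basis so the 6° quadrant means hit the targets.

    The quadrant means at 6° are linear in the basis coefficients; the 4×4
    system is assembled by dense angular quadrature and solved exactly.
    """
    theta = np.arange(0.0, 360.0, 0.05)
    basis = _angular_basis(theta)
    labels = scheme.assign(theta)
    order = ("temporal", "nasal", "superior", "inferior")
    m = np.empty((4, 4))
    for qi, q in enumerate(order):
        sel = labels == q
        m[qi] = basis[:, sel].mean(axis=1)
    targets = np.array(
        [params.base_temporal_um, params.base_nasal_um, params.peak_superior_um, params.peak_inferior_um]
    )
    decay6 = _radial_decay(np.array(6.0), params)
    return np.linalg.solve(m, targets / decay6)


def _radial_decay(r_deg: np.ndarray, params: PhantomParams) -> np.ndarray:
    r = np.maximum(np.asarray(r_deg, dtype=float), params.disc_radius_deg)
    return 1.0 / (1.0 + params.radial_decay_per_deg * (r - 4.0))


@dataclass
class GroundTruthField:
    """Analytic ground-truth RNFL thickness T(r, theta) in the TSNIT frame.

    Periodic in theta (360°), nonnegative everywhere, identically zero
    inside the optic disc.
    """

    params: PhantomParams
    coeffs: np.ndarray
    onh_center_mm: tuple[float, float]
    laterality: str = "OD"

    def thickness(self, r_deg: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
        """Thickness (µm) at visual-angle radius r and TSNIT angle theta."""
        r = np.asarray(r_deg, dtype=float)
        angular = np.tensordot(self.coeffs, _angular_basis(theta_deg), axes=1)
        t = self.params.glaucoma_factor * angular * _radial_decay(r, self.params)
        return np.where(r >= self.params.disc_radius_deg, t, 0.0)

    def quadrant_ring_means(self, r_deg: float, scheme: QuadrantScheme = EQUAL90, n_theta: int = 7200) -> dict[str, float]:
        """Quadrant means of the field on a ring, by dense angular quadrature."""
        theta = np.arange(n_theta) * 360.0 / n_theta
        vals = self.thickness(np.full(n_theta, r_deg), theta)
        labels = scheme.assign(theta)
        return {q: float(vals[labels == q].mean()) for q in scheme.boundaries}

    def quadrant_annulus_means(
        self, r_inner_deg: float, r_outer_deg: float, scheme: QuadrantScheme = EQUAL90,
        n_theta: int = 1440, n_r: int = 64,
    ) -> dict[str, float]:
        """Area-weighted quadrant means over an annulus (dense polar quadrature)."""
        edges = np.linspace(r_inner_deg, r_outer_deg, n_r + 1)
        radii = 0.5 * (edges[:-1] + edges[1:])
        theta = np.arange(n_theta) * 360.0 / n_theta
        rr, tt = np.meshgrid(radii, theta, indexing="ij")
        vals = self.thickness(rr, tt)
        labels = scheme.assign(theta)
        out = {}
        for q in scheme.boundaries:
            sel = labels == q
            w = rr[:, sel]
            out[q] = float(np.sum(w * vals[:, sel]) / np.sum(w))
        return out


def make_truth(
    params: PhantomParams,
    onh_center_mm: tuple[float, float] | None = None,
    laterality: str = "OD",
) -> GroundTruthField:
    """Build the analytic ground-truth field for the given parameters.

    The angular profile is a cosine interpolation between the temporal and
    nasal levels plus raised-cosine superior/inferior bumps (half-width
    60°), scaled radially by 1/(1 + decay·(r − 4°)) and globally by the
    glaucoma factor; coefficients are solved so the equal90 quadrant means
    on the 6° ring reproduce the configured levels.
    """
    if onh_center_mm is None:
        onh_center_mm = (params.extent_x_mm / 2.0, params.extent_y_mm / 2.0)
    coeffs = _solve_angular_coeffs(params)
    return GroundTruthField(params=params, coeffs=coeffs, onh_center_mm=onh_center_mm, laterality=laterality)


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic RNG keyed by (seed, labels): stable across runs and platforms."""
    ints = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _offset(seed: int, sd: float, *keys: str) -> float:
    if sd == 0:
        return 0.0
    return float(_stream(seed, *keys).normal(0.0, sd))


def _pixel_noise_sd(params: PhantomParams, quality: float, r_deg: np.ndarray) -> np.ndarray:
    sd = params.sigma_pixel_um / quality
    if params.noise_ref_radius_deg is not None:
        sd = sd * params.noise_ref_radius_deg / np.maximum(r_deg, params.disc_radius_deg)
    return np.broadcast_to(np.asarray(sd, dtype=float), np.asarray(r_deg).shape)


def render_scan(
    truth: GroundTruthField,
    params: PhantomParams,
    subject_id: str,
    scan_id: str,
    assessor_id: str = "A1",
    quality: float = 1.0,
    subject_offset_keys: tuple[str, ...] | None = None,
    assessor_offset_keys: tuple[str, ...] | None = None,
) -> RasterScan:
    """Render one noisy raster scan of a ground-truth field.

    Samples the field at pixel centres (with the in-plane ``tilt_deg``
    rotation of the sampling frame about the ONH centre), adds the
    subject/scan/assessor offsets and quality-scaled pixel noise, clamps at
    0 µm, and masks the disc interior plus (with ``missing_quadrant_prob``)
    one full quadrant — emulating a partially captured circumpapillary
    region.
    """
    p = params
    x = (np.arange(p.grid_n_ascans) + 0.5) * (p.extent_x_mm / p.grid_n_ascans)
    y = (np.arange(p.grid_n_bscans) + 0.5) * (p.extent_y_mm / p.grid_n_bscans)
    xx, yy = np.meshgrid(x, y)
    cx, cy = truth.onh_center_mm
    dx, dy = xx - cx, yy - cy
    if p.tilt_deg:
        phi = np.deg2rad(p.tilt_deg)
        dx, dy = dx * np.cos(phi) - dy * np.sin(phi), dx * np.sin(phi) + dy * np.cos(phi)
    r_mm = np.hypot(dx, dy)
    r_deg = mm_to_deg(r_mm, p.calibration)
    theta = image_theta(dx, dy, truth.laterality)

    t = truth.thickness(r_deg, theta)

    s_keys = subject_offset_keys or (subject_id,)
    a_keys = assessor_offset_keys or (subject_id, scan_id, assessor_id)
    off = (
        _offset(p.seed, p.sigma_subject_um, "subject", *s_keys)
        + _offset(p.seed, p.sigma_scan_um, "scan", subject_id, scan_id)
        + _offset(p.seed, p.sigma_assessor_um, "assessor", *a_keys)
    )
    if p.sigma_pixel_um > 0:
        rng = _stream(p.seed, "pixel", subject_id, scan_id)
        noise = rng.normal(0.0, 1.0, size=t.shape) * _pixel_noise_sd(p, quality, r_deg)
    else:
        noise = 0.0
    thickness = np.maximum(t + off + noise, 0.0)

    valid = r_deg >= p.disc_radius_deg
    thickness = np.where(valid, thickness, 0.0)
    if p.missing_quadrant_prob > 0:
        rng_m = _stream(p.seed, "missing", subject_id, scan_id, assessor_id)
        if rng_m.random() < p.missing_quadrant_prob:
            drop = ("temporal", "superior", "nasal", "inferior")[rng_m.integers(4)]
            valid = valid & (EQUAL90.assign(theta) != drop)

    return RasterScan(
        thickness=thickness,
        valid_mask=valid,
        extent_x_mm=p.extent_x_mm,
        extent_y_mm=p.extent_y_mm,
        onh_center_mm=truth.onh_center_mm,
        laterality=truth.laterality,
        quality=quality,
        subject_id=subject_id,
        scan_id=scan_id,
        assessor_id=assessor_id,
        meta={"seed": p.seed},
    )


def _subject_ids(n_subjects: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n_subjects)]


def simulate_cohort(
    params: PhantomParams,
    n_subjects: int,
    design: Design = "test_retest",
    seed: int | None = None,
) -> list[RasterScan]:
    """Simulate a paired cohort of raster scans.

    ``test_retest``: two consecutive acquisitions per subject (scan1 high
    quality, scan2 low quality) with independent scan offsets, segmented by
    one assessor (the assessor offset is constant within a subject, so it
    folds into the between-subject component).  ``interassessor``: one
    acquisition per subject segmented twice with independent assessor
    offsets.  Both yield 2·n_subjects scans; fully reproducible from the
    seed.
    """
    if design not in ("test_retest", "interassessor"):
        raise ValueError(f"unknown design {design!r}")
    if seed is not None:
        params = PhantomParams(**{**params.__dict__, "seed": seed})
    truth = make_truth(params)
    scans: list[RasterScan] = []
    for sid in _subject_ids(n_subjects):
        if design == "test_retest":
            # same assessor segments both scans -> shared assessor offset
            shared = (sid, "A1")
            scans.append(render_scan(truth, params, sid, "scan1", "A1", params.quality_high,
                                     assessor_offset_keys=shared))
            scans.append(render_scan(truth, params, sid, "scan2", "A1", params.quality_low,
                                     assessor_offset_keys=shared))
        else:
            # same acquisition (identical scan offset + pixel noise), two segmentations
            scans.append(render_scan(truth, params, sid, "scan1", "A1", params.quality_high))
            scans.append(render_scan(truth, params, sid, "scan1", "A2", params.quality_high))
    return scans


_LOCATION_LABELS = ("ring4", "ring5", "ring6", "annulus4-5", "annulus5-6")


def simulate_quadrant_cohort(
    params: PhantomParams,
    n_subjects: int,
    design: Design = "test_retest",
    seed: int | None = None,
    scheme: QuadrantScheme = EQUAL90,
    locations: tuple[str, ...] = _LOCATION_LABELS,
) -> pd.DataFrame:
    """Measurement-level cohort simulation (no rasterization).

    With ``sigma_pixel_um = 0`` a rendered scan's quadrant mean equals the
    truth quadrant mean plus the scalar offsets, so quadrant summaries can
    be drawn directly; this is exact, and orders of magnitude faster than
    rendering, for variance-component studies.  Raises if pixel noise is
    requested, since that cannot be reproduced without the raster.

    Returns a tidy frame with columns subject_id, arm, location, quadrant,
    mean_um, n_valid, n_total, captured — the extraction interchange format.
    """
    if params.sigma_pixel_um != 0:
        raise ValueError("measurement-level simulation is exact only with sigma_pixel_um = 0")
    if design not in ("test_retest", "interassessor"):
        raise ValueError(f"unknown design {design!r}")
    if seed is not None:
        params = PhantomParams(**{**params.__dict__, "seed": seed})
    truth = make_truth(params)

    loc_means: dict[str, dict[str, float]] = {}
    for loc in locations:
        if loc.startswith("ring"):
            loc_means[loc] = truth.quadrant_ring_means(float(loc[4:]), scheme)
        else:
            lo, hi = loc[len("annulus"):].split("-")
            loc_means[loc] = truth.quadrant_annulus_means(float(lo), float(hi), scheme)

    p = params
    rows = []
    for sid in _subject_ids(n_subjects):
        subj = _offset(p.seed, p.sigma_subject_um, "subject", sid)
        if design == "test_retest":
            arms = [
                ("high_quality", "scan1", subj
                 + _offset(p.seed, p.sigma_scan_um, "scan", sid, "scan1")
                 + _offset(p.seed, p.sigma_assessor_um, "assessor", sid, "A1"), ("scan1", "A1")),
                ("low_quality", "scan2", subj
                 + _offset(p.seed, p.sigma_scan_um, "scan", sid, "scan2")
                 + _offset(p.seed, p.sigma_assessor_um, "assessor", sid, "A1"), ("scan2", "A1")),
            ]
        else:
            base = subj + _offset(p.seed, p.sigma_scan_um, "scan", sid, "scan1")
            arms = [
                ("assessor1", "scan1", base
                 + _offset(p.seed, p.sigma_assessor_um, "assessor", sid, "scan1", "A1"), ("scan1", "A1")),
                ("assessor2", "scan1", base
                 + _offset(p.seed, p.sigma_assessor_um, "assessor", sid, "scan1", "A2"), ("scan1", "A2")),
            ]
        for arm, scan_id, off, (mk_scan, mk_assessor) in arms:
            missing = None
            if p.missing_quadrant_prob > 0:
                rng_m = _stream(p.seed, "missing", sid, mk_scan, mk_assessor)
                if rng_m.random() < p.missing_quadrant_prob:
                    missing = ("temporal", "superior", "nasal", "inferior")[rng_m.integers(4)]
            for loc in locations:
                for q, mu in loc_means[loc].items():
                    captured = q != missing
                    rows.append({
                        "subject_id": sid, "arm": arm, "location": loc, "quadrant": q,
                        "mean_um": max(mu + off, 0.0) if captured else np.nan,
                        "n_valid": 360 if captured else 0, "n_total": 360,
                        "captured": captured,
                    })
    cols = ["subject_id", "arm", "location", "quadrant", "mean_um", "n_valid", "n_total", "captured"]
    return pd.DataFrame(rows, columns=cols)
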