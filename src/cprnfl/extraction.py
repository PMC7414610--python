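"""From thickness maps to the measurement table: quadrant means and pairing rules.

Each scan is reduced to one mean thickness per (location × quadrant), where a
location is a circumpapillary ring (4°, 5°, 6°) or annulus (4–5°, 5–6°).  A
quadrant counts as *captured* when at least ``capture_threshold`` of its
samples are valid.  Scan pairs enter the reliability analysis only when at
least three quadrants were captured in both arms (the same three); the
"Average" measure — the unweighted mean of the four quadrant means — is
formed only for subjects with all four quadrants in both arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    EQUAL90,
    AngleCalibration,
    CircumpapillaryProfile,
    QuadrantScheme,
    RasterScan,
    assign_quadrants,
    sample_annulus,
    sample_ring,
)

__all__ = [
    "LocationSpec",
    "DEFAULT_LOCATIONS",
    "QuadrantSummary",
    "MeasurementPair",
    "summarize_scan",
    "summaries_to_frame",
    "include_pair",
    "build_pairs",
]


@dataclass(frozen=True)
class LocationSpec:
    """A circumpapillary measurement location: ring at r, or annulus [r_inner, r_outer]."""

    kind: str  # "ring" | "annulus"
    r_deg: float = 0.0
    r_inner_deg: float = 0.0
    r_outer_deg: float = 0.0

    @property
    def label(self) -> str:
        if self.kind == "ring":
            return f"ring{self.r_deg:g}"
        return f"annulus{self.r_inner_deg:g}-{self.r_outer_deg:g}"

    @classmethod
    def ring(cls, r_deg: float) -> "LocationSpec":
        return cls(kind="ring", r_deg=r_deg)

    @classmethod
    def annulus(cls, r_inner_deg: float, r_outer_deg: float) -> "LocationSpec":
        return cls(kind="annulus", r_inner_deg=r_inner_deg, r_outer_deg=r_outer_deg)

    @classmethod
    def parse(cls, label: str) -> "LocationSpec":
        if label.startswith("ring"):
            return cls.ring(float(label[4:]))
        if label.startswith("annulus"):
            lo, hi = label[len("annulus"):].split("-")
            return cls.annulus(float(lo), float(hi))
        raise ValueError(f"cannot parse location label {label!r}")


DEFAULT_LOCATIONS: tuple[LocationSpec, ...] = (
    LocationSpec.ring(4.0),
    LocationSpec.ring(5.0),
    LocationSpec.ring(6.0),
    LocationSpec.annulus(4.0, 5.0),
    LocationSpec.annulus(5.0, 6.0),
)


@dataclass
class QuadrantSummary:
    """Mean cpRNFL thickness of one quadrant at one location of one scan."""

    subject_id: str
    scan_id: str
    assessor_id: str
    location: str
    quadrant: str
    mean_um: float
    n_valid: int
    n_total: int
    captured: bool


@dataclass
class MeasurementPair:
    """Matched measurements of one eye/quadrant/location from the two arms."""

    subject_id: str
    quadrant: str
    location: str
    value_a_um: float
    value_b_um: float
    arm_labels: tuple[str, str]


def summarize_scan(
    scan: RasterScan,
    locations: Sequence[LocationSpec] = DEFAULT_LOCATIONS,
    scheme: QuadrantScheme = EQUAL90,
    cal: AngleCalibration = AngleCalibration(),
    capture_threshold: float = 0.9,
    n_theta: int = 360,
    n_r: int = 8,
    theta_offset_deg: float = 0.0,
) -> list[QuadrantSummary]:
    """One QuadrantSummary per (location × quadrant) of a scan.

    The quadrant mean is the (area-weighted, for annuli) mean over valid
    samples; ``captured`` requires the valid fraction to reach
    ``capture_threshold``, and the mean is reported only when captured.
    """
    out: list[QuadrantSummary] = []
    for loc in locations:
        if loc.kind == "ring":
            prof = sample_ring(scan, loc.r_deg, cal, n_theta=n_theta, theta_offset_deg=theta_offset_deg)
        else:
            prof = sample_annulus(
                scan, loc.r_inner_deg, loc.r_outer_deg, cal,
                n_theta=n_theta, n_r=n_r, theta_offset_deg=theta_offset_deg,
            )
        assign_quadrants(prof, scheme)
        for q in scheme.boundaries:
            sel = prof.quadrant == q
            n_total = int(sel.sum())
            ok = sel & prof.valid
            n_valid = int(ok.sum())
            captured = n_valid >= 1 and n_valid / n_total >= capture_threshold
            if captured:
                w = prof.weight[ok]
                mean = float(np.sum(w * prof.value_um[ok]) / np.sum(w))
            else:
                mean = float("nan")
            out.append(
                QuadrantSummary(
                    subject_id=scan.subject_id,
                    scan_id=scan.scan_id,
                    assessor_id=scan.assessor_id,
                    location=loc.label,
                    quadrant=q,
                    mean_um=mean,
                    n_valid=n_valid,
                    n_total=n_total,
                    captured=captured,
                )
            )
    return out


def summaries_to_frame(summaries: Iterable[QuadrantSummary], arm_of=None) -> pd.DataFrame:
    """Flatten QuadrantSummary records into the tidy interchange frame.

    ``arm_of``: callable mapping a summary to its arm label; defaults to
    labelling by scan quality is not possible here, so the caller usually
    supplies e.g. ``lambda s: {"scan1": "high_quality", "scan2":
    "low_quality"}[s.scan_id]``.
    """
    rows = []
    for s in summaries:
        rows.append({
            "subject_id": s.subject_id,
            "arm": arm_of(s) if arm_of is not None else f"{s.scan_id}/{s.assessor_id}",
            "location": s.location,
            "quadrant": s.quadrant,
            "mean_um": s.mean_um,
            "n_valid": s.n_valid,
            "n_total": s.n_total,
            "captured": s.captured,
        })
    cols = ["subject_id", "arm", "location", "quadrant", "mean_um", "n_valid", "n_total", "captured"]
    return pd.DataFrame(rows, columns=cols)


def include_pair(
    summaries_a: Sequence[QuadrantSummary] | pd.DataFrame,
    summaries_b: Sequence[QuadrantSummary] | pd.DataFrame,
    location: str,
    min_common_quadrants: int = 3,
) -> dict:
    """Pair-inclusion rule: at least three quadrants captured in both arms.

    Returns ``{"included": bool, "common_quadrants": set}`` where
    common_quadrants are those captured in *both* arms at the location.
    """

    def _captured(s, loc):
        if isinstance(s, pd.DataFrame):
            sel = s[(s["location"] == loc) & s["captured"]]
            return set(sel["quadrant"])
        return {x.quadrant for x in s if x.location == loc and x.captured}

    common = _captured(summaries_a, location) & _captured(summaries_b, location)
    return {"included": len(common) >= min_common_quadrants, "common_quadrants": common}


def build_pairs(
    table: pd.DataFrame,
    arm_labels: tuple[str, str],
    min_common_quadrants: int = 3,
    per_location: bool = True,
) -> list[MeasurementPair]:
    """Build quadrant-level measurement pairs from the tidy cohort table.

    Per location (the default; ``per_location=False`` applies one inclusion
    decision per subject based on the first location), subjects pass the
    inclusion rule, then one pair per common quadrant is emitted plus an
    ``Average`` pair — the unweighted mean of the four quadrant means — for
    subjects with all four quadrants captured in both arms.
    """
    arm_a, arm_b = arm_labels
    arms_present = set(table["arm"].unique())
    if not {arm_a, arm_b} <= arms_present and len(table):
        raise ValueError(f"arm labels {arm_labels} not found in table arms {sorted(arms_present)}")
    ta = table[table["arm"] == arm_a]
    tb = table[table["arm"] == arm_b]
    subj_a, subj_b = set(ta["subject_id"]), set(tb["subject_id"])
    if subj_a != subj_b:
        odd = sorted(subj_a ^ subj_b)
        raise ValueError(f"mismatched subject sets between arms: {odd}")

    pairs: list[MeasurementPair] = []
    locations = list(dict.fromkeys(table["location"]))  # keep first-seen order
    gate_loc = locations[0] if locations else None
    for sid in sorted(subj_a):
        sa = ta[ta["subject_id"] == sid]
        sb = tb[tb["subject_id"] == sid]
        if not per_location and gate_loc is not None:
            gate = include_pair(sa, sb, gate_loc, min_common_quadrants)
        for loc in locations:
            dec = gate if not per_location else include_pair(sa, sb, loc, min_common_quadrants)
            if not dec["included"]:
                continue
            common = dec["common_quadrants"] if per_location else (
                include_pair(sa, sb, loc, min_common_quadrants=0)["common_quadrants"]
            )
            va = sa[sa["location"] == loc].set_index("quadrant")["mean_um"]
            vb = sb[sb["location"] == loc].set_index("quadrant")["mean_um"]
            qvals = []
            for q in sorted(common):
                pairs.append(MeasurementPair(sid, q, loc, float(va[q]), float(vb[q]), arm_labels))
                qvals.append((float(va[q]), float(vb[q])))
            if len(common) == 4:
                pairs.append(
                    MeasurementPair(
                        sid, "Average", loc,
                        float(np.mean([v[0] for v in qvals])),
                        float(np.mean([v[1] for v in qvals])),
                        arm_labels,
                    )
                )
    return pairs


def pairs_to_frame(pairs: Iterable[MeasurementPair]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "quadrant": p.quadrant,
            "location": p.location,
            "value_a_um": p.value_a_um,
            "value_b_um": p.value_b_um,
            "arm_a": p.arm_labels[0],
            "arm_b": p.arm_labels[1],
        }
        for p in pairs
    ]
    cols = ["subject_id", "quadrant", "location", "value_a_um", "value_b_um", "arm_a", "arm_b"]
    return pd.DataFrame(rows, columns=cols)
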