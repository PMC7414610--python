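"""Feasibility bookkeeping: acquisition attempts, exclusion factors, success rates.

A feasibility study tallies, per participant group, how many eyes scanning
was attempted in, how many yielded a usable 3D volume, which clinical
factors prevented acquisition (nystagmus, media opacity, refractive error,
small pupils, other), and — among imageable eyes — how often each
circumpapillary quadrant, and the full profile, was captured.  Success
rates can be expressed on two bases: per imageable eye ("possible") or per
attempt ("attempted").  When only printed percentages survive, integer
success counts are reconstructed by nearest-integer rounding so rates can
be cross-checked between bases and pooled across groups consistently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FeasibilityCounts",
    "success_rates",
    "reconstruct_counts",
    "pooled_rates",
    "round_rate",
    "load_counts_json",
    "load_example_feasibility",
]

MEASURES = ("nasal", "temporal", "inferior", "superior", "full")


def round_rate(rate: float, ndigits: int = 1) -> float:
    """Round half away from zero — the convention of printed rate tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(rate)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FeasibilityCounts:
    """Per-group feasibility tallies.

    ``factor_counts`` maps exclusion factor -> eyes; additivity
    eyes_possible + Σ factor_counts == eyes_attempted is enforced.
    ``success_possible`` maps quadrant ∪ {"full"} -> success count among
    imageable eyes.
    """

    group: str
    eyes_attempted: int
    eyes_possible: int
    factor_counts: dict[str, int] = field(default_factory=dict)
    success_possible: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eyes_attempted < 0 or self.eyes_possible < 0:
            raise ValueError("counts must be nonnegative")
        if self.eyes_possible > self.eyes_attempted:
            raise ValueError("eyes_possible cannot exceed eyes_attempted")
        excluded = sum(self.factor_counts.values())
        if self.eyes_possible + excluded != self.eyes_attempted:
            raise ValueError(
                "factor counts do not add up: possible "
                f"{self.eyes_possible} + excluded {excluded} != attempted {self.eyes_attempted}"
            )
        for k, v in self.success_possible.items():
            if not (0 <= v <= self.eyes_possible):
                raise ValueError(f"success count for {k!r} must lie in [0, eyes_possible]")

    @property
    def eyes_excluded(self) -> int:
        return self.eyes_attempted - self.eyes_possible


def success_rates(counts: FeasibilityCounts, basis: str = "possible", rounded: bool = False) -> dict[str, float]:
    """Success rate (%) per quadrant ∪ {full} on the chosen denominator basis.

    ``rounded=True`` applies the 1-decimal half-away-from-zero report
    rounding; full precision is the default.  A zero denominator yields NaN.
    """
    if basis == "possible":
        denom = counts.eyes_possible
    elif basis == "attempted":
        denom = counts.eyes_attempted
    else:
        raise ValueError("basis must be 'possible' or 'attempted'")
    out: dict[str, float] = {}
    for k, v in counts.success_possible.items():
        rate = float("nan") if denom == 0 else 100.0 * v / denom
        out[k] = round_rate(rate, 1) if (rounded and denom) else rate
    return out


def reconstruct_counts(rate_percent: float, denominator: int) -> tuple[int, float]:
    """Invert a printed percentage to the integer count it describes.

    Returns (count, residual) where residual = |count − rate/100·denom| is a
    consistency diagnostic (should stay below the half-count implied by the
    printed precision).
    """
    if denominator < 0:
        raise ValueError("denominator must be nonnegative")
    exact = rate_percent / 100.0 * denominator
    count = int(round(exact))
    return count, abs(count - exact)


def pooled_rates(
    groups: Sequence[FeasibilityCounts], basis: str = "possible", rounded: bool = False
) -> dict[str, float]:
    """Pool integer success counts and denominators across groups, then rate."""
    if not groups:
        raise ValueError("need at least one group")
    keys = list(groups[0].success_possible)
    denom = sum(g.eyes_possible if basis == "possible" else g.eyes_attempted for g in groups)
    out: dict[str, float] = {}
    for k in keys:
        succ = sum(g.success_possible[k] for g in groups)
        rate = float("nan") if denom == 0 else 100.0 * succ / denom
        out[k] = round_rate(rate, 1) if (rounded and denom) else rate
    return out


def _counts_from_dict(d: Mapping) -> FeasibilityCounts:
    success = dict(d.get("success_counts_possible", {}))
    if not success and "success_rate_possible_pct" in d:
        # reconstruct integer counts from printed possible-basis percentages
        for k, pct in d["success_rate_possible_pct"].items():
            success[k], _ = reconstruct_counts(float(pct), int(d["eyes_possible"]))
    return FeasibilityCounts(
        group=d["group"],
        eyes_attempted=int(d["eyes_attempted"]),
        eyes_possible=int(d["eyes_possible"]),
        factor_counts={k: int(v) for k, v in d.get("factor_counts", {}).items()},
        success_possible=success,
    )


def load_counts_json(path: str | Path) -> list[FeasibilityCounts]:
    """Load per-group feasibility counts from a JSON document.

    Schema: {"groups": [{"group", "eyes_attempted", "eyes_possible",
    "factor_counts": {...}, and either "success_counts_possible" or
    "success_rate_possible_pct"}]}.
    """
    doc = json.loads(Path(path).read_text())
    return [_counts_from_dict(g) for g in doc["groups"]]


def load_example_feasibility() -> list[FeasibilityCounts]:
    """The bundled example dataset: a two-group pediatric HH-OCT feasibility table."""
    here = Path(__file__).parent / "data" / "example_feasibility.json"
    return load_counts_json(here)
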