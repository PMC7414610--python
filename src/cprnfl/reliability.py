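"""Agreement statistics for paired circumpapillary measurements.

Implements the test–retest / interassessor reliability toolkit:

* ICC — two-way random-effects intraclass correlation from the two-way
  ANOVA mean squares, in the absolute-agreement single-measure form
  ICC(A,1) (default) or the consistency form ICC(C,1), each with an
  F-distribution 95% CI (McGraw–Wong).  Absolute agreement is the stricter
  choice for repeatability work because a systematic offset between arms
  counts against it.
* CoV — within-subject coefficient of variation, 100·S_w/grand mean with
  S_w = sqrt(Σ dᵢ²/(2n)) (Bland's within-subject SD from paired
  differences); a per-pair-CoV average is available as an alternative.
* bias — the arm effect of the balanced two-way additive model
  value = µ + arm + subject, which for two complete arms equals the mean
  paired difference, with t-based 95% CI and p (identical to a paired
  t-test).
* Bland–Altman — bias, 1.96·SD limits of agreement, and the OLS trend of
  differences on pair means.

All statistics operate on plain paired arrays; `reliability_table` maps
them over every (quadrant + Average) × location cell of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import MeasurementPair, pairs_to_frame

__all__ = [
    "ICCResult",
    "ReliabilityResult",
    "anova_mean_squares",
    "icc_absolute_agreement",
    "icc_consistency",
    "cov_percent",
    "bias_test",
    "bland_altman",
    "reliability_table",
    "icc_sweep",
]

_EPS = 1e-12


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str
    degenerate: bool = False

    def __iter__(self):
        return iter((self.icc, self.ci_low, self.ci_high))


def anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, cols=raters/arms).

    Returns (MSR, MSC, MSE): between-rows, between-columns and residual
    mean squares of the complete two-way layout.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 arms")
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + gm
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def _as_matrix(a, b=None) -> np.ndarray:
    if b is not None:
        return np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    return np.asarray(a, dtype=float)


def icc_absolute_agreement(a, b=None, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)), with the
    F-based CI on Satterthwaite degrees of freedom.  Zero total variance is
    a degenerate case (flagged, ICC = NaN); perfect agreement with
    between-subject variance gives ICC = 1 with a collapsed CI.
    """
    x = _as_matrix(a, b)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    msr, msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < _EPS and abs(msr - mse) < _EPS:
        return ICCResult(float("nan"), float("nan"), float("nan"), "A1", degenerate=True)
    icc = (msr - mse) / denom
    if mse < _EPS and msc < _EPS:
        # exact agreement between arms: CI collapses
        return ICCResult(icc, icc, icc, "A1")
    # Satterthwaite df for the denominator linear combination (McGraw-Wong)
    a_c = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b_c = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    num_v = (a_c * msc + b_c * mse) ** 2
    den_v = (a_c * msc) ** 2 / (k - 1) + (b_c * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v
    fu = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fl = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - fu * mse) / (fu * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (fl * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fl * msr)
    return ICCResult(float(icc), float(lo), float(hi), "A1")


def icc_consistency(a, b=None, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1): two-way, consistency, single measures (offset-insensitive)."""
    x = _as_matrix(a, b)
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    msr, _msc, mse = anova_mean_squares(x)
    denom = msr + (k - 1) * mse
    if abs(denom) < _EPS and abs(msr - mse) < _EPS:
        return ICCResult(float("nan"), float("nan"), float("nan"), "C1", degenerate=True)
    icc = (msr - mse) / denom
    if mse < _EPS:
        return ICCResult(icc, icc, icc, "C1")
    fobs = msr / mse
    df2 = (n - 1) * (k - 1)
    fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
    fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(lo), float(hi), "C1")


def icc(a, b=None, form: str = "A1", alpha: float = 0.05) -> ICCResult:
    if form == "A1":
        return icc_absolute_agreement(a, b, alpha)
    if form == "C1":
        return icc_consistency(a, b, alpha)
    raise ValueError("icc form must be 'A1' or 'C1'")


def cov_percent(a, b=None, method: str = "rms") -> float:
    """Within-subject coefficient of variation, in percent.

    ``rms`` (default): 100·S_w/grand mean with S_w = sqrt(Σdᵢ²/(2n)), the
    root-mean-square within-pair SD from paired differences.  ``per_pair``:
    the mean of per-pair CoVs (pair SD over pair mean).
    """
    x = _as_matrix(a, b)
    gm = x.mean()
    if gm <= 0:
        raise ValueError("CoV undefined for nonpositive grand mean")
    if method == "rms":
        d = x[:, 0] - x[:, 1]
        s_w = np.sqrt(np.sum(d**2) / (2 * len(d)))
        return float(100.0 * s_w / gm)
    if method == "per_pair":
        pair_sd = np.std(x, axis=1, ddof=1)
        pair_mean = x.mean(axis=1)
        if np.any(pair_mean <= 0):
            raise ValueError("CoV undefined for nonpositive pair mean")
        return float(100.0 * np.mean(pair_sd / pair_mean))
    raise ValueError("cov method must be 'rms' or 'per_pair'")


@dataclass
class BiasResult:
    bias: float
    ci: tuple[float, float]
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.bias, self.ci, self.p))


def bias_test(a, b=None, alpha: float = 0.05) -> BiasResult:
    """Systematic difference between arms (arm_a − arm_b) with 95% CI and p.

    The balanced two-way additive model value = µ + arm + subject estimated
    by least squares: with two complete arms the arm effect is exactly the
    mean paired difference, and inference reduces to the paired t-test on
    n−1 df.  Zero difference variance is flagged degenerate (p = 1 when the
    shift is 0, p = 0 otherwise).
    """
    x = _as_matrix(a, b)
    n = x.shape[0]
    if n < 2:
        raise ValueError("bias test needs at least 2 pairs")
    d = x[:, 0] - x[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd < _EPS:
        return BiasResult(bias, (bias, bias), 1.0 if abs(bias) < _EPS else 0.0, degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    tstat = bias / se
    p = float(2 * stats.t.sf(abs(tstat), n - 1))
    return BiasResult(bias, (bias - tcrit * se, bias + tcrit * se), p)


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_p: float
    points: np.ndarray  # (n, 2): mean, difference


def bland_altman(a, b=None) -> BlandAltman:
    """Bland–Altman agreement: bias, 1.96·SD limits, and the difference-vs-mean trend."""
    x = _as_matrix(a, b)
    m = x.mean(axis=1)
    d = x[:, 0] - x[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(m) < _EPS or sd < _EPS:
        # constant differences or constant means: no estimable trend
        slope, p = 0.0, float("nan")
    else:
        res = stats.linregress(m, d)
        slope, p = float(res.slope), float(res.pvalue)
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        trend_slope=slope,
        trend_p=p,
        points=np.column_stack([m, d]),
    )


@dataclass
class ReliabilityResult:
    """One row of the reliability table: a quadrant × location cell."""

    quadrant: str
    location: str
    n_pairs: int
    mean_a_um: float
    sd_a_um: float
    mean_b_um: float
    sd_b_um: float
    bias_um: float
    bias_ci: tuple[float, float]
    bias_p: float
    cov_percent: float
    icc: float
    icc_ci: tuple[float, float]
    icc_c1: float
    ba_loa: tuple[float, float]
    ba_trend_slope: float
    ba_trend_p: float
    degenerate: bool = False


_MEASURES = ("nasal", "temporal", "inferior", "superior", "Average")


def reliability_table(
    pairs: Sequence[MeasurementPair] | pd.DataFrame,
    locations: Sequence[str] | None = None,
    quadrants: Sequence[str] = _MEASURES,
    icc_form: str = "A1",
    cov_method: str = "rms",
) -> list[ReliabilityResult]:
    """Agreement statistics for every (quadrant + Average) × location cell."""
    frame = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    if locations is None:
        locations = list(dict.fromkeys(frame["location"])) if len(frame) else []
    results: list[ReliabilityResult] = []
    for loc in locations:
        for q in quadrants:
            cell = frame[(frame["location"] == loc) & (frame["quadrant"] == q)]
            if len(cell) < 3:
                continue
            va = cell["value_a_um"].to_numpy()
            vb = cell["value_b_um"].to_numpy()
            r_icc = icc(va, vb, form=icc_form)
            r_c1 = icc_consistency(va, vb)
            r_bias = bias_test(va, vb)
            ba = bland_altman(va, vb)
            results.append(
                ReliabilityResult(
                    quadrant=q,
                    location=loc,
                    n_pairs=len(cell),
                    mean_a_um=float(va.mean()),
                    sd_a_um=float(va.std(ddof=1)),
                    mean_b_um=float(vb.mean()),
                    sd_b_um=float(vb.std(ddof=1)),
                    bias_um=r_bias.bias,
                    bias_ci=r_bias.ci,
                    bias_p=r_bias.p,
                    cov_percent=cov_percent(va, vb, method=cov_method),
                    icc=r_icc.icc,
                    icc_ci=(r_icc.ci_low, r_icc.ci_high),
                    icc_c1=r_c1.icc,
                    ba_loa=(ba.loa_low, ba.loa_high),
                    ba_trend_slope=ba.trend_slope,
                    ba_trend_p=ba.trend_p,
                    degenerate=r_icc.degenerate or r_bias.degenerate,
                )
            )
    return results


def results_to_frame(results: Iterable[ReliabilityResult]) -> pd.DataFrame:
    """Reliability results as a flat table mirroring the per-cell column set."""
    rows = []
    for r in results:
        rows.append({
            "quadrant": r.quadrant,
            "location": r.location,
            "n": r.n_pairs,
            "mean_a_um": r.mean_a_um,
            "sd_a_um": r.sd_a_um,
            "mean_b_um": r.mean_b_um,
            "sd_b_um": r.sd_b_um,
            "bias_um": r.bias_um,
            "bias_p": r.bias_p,
            "bias_lci": r.bias_ci[0],
            "bias_uci": r.bias_ci[1],
            "cov_percent": r.cov_percent,
            "icc": r.icc,
            "icc_lci": r.icc_ci[0],
            "icc_uci": r.icc_ci[1],
            "icc_c1": r.icc_c1,
            "ba_loa_low": r.ba_loa[0],
            "ba_loa_high": r.ba_loa[1],
            "ba_trend_slope": r.ba_trend_slope,
            "ba_trend_p": r.ba_trend_p,
            "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows)


def icc_sweep(results: Iterable[ReliabilityResult]) -> pd.DataFrame:
    """ICC (with CI) against measurement location — the reliability-vs-radius sweep."""
    rows = [
        {
            "location": r.location,
            "quadrant": r.quadrant,
            "icc": r.icc,
            "ci_low": r.icc_ci[0],
            "ci_high": r.icc_ci[1],
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["location", "quadrant", "icc", "ci_low", "ci_high"])
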