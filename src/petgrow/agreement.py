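"""Agreement statistics between gold-standard and test measurements.

The validation workflow compares per-lesion segmentation results against a
pathology reference.  The reference model treats the fresh resected
specimen as an ellipsoid measured in three axes (a, b, c, in cm), giving a
volume of (π/6)·a·b·c ccm and a maximal diameter of 10·max(a, b, c) mm.

The statistics battery for a paired series (gold, test):

* Pearson correlation coefficient r,
* Bland–Altman analysis of *relative* differences (per-pair percentage
  difference, bias and 1.96·sd limits of agreement),
* the root-mean-square coefficient of variation (RMS COV) for duplicate
  measurements — each pair is treated as two measurements of the same
  lesion, so sd_i = |test−gold|/√2 and cv_i = sd_i / pair mean,
* Forkman's F-test for equality of two coefficients of variation,
* a lesion-size subgroup analysis (all lesions / above each pathological
  volume cutoff, default 3 and 45 ccm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PathologyMeasurement",
    "PairedSeries",
    "AgreementReport",
    "ellipsoid_volume",
    "pearson_r",
    "bland_altman_relative",
    "rms_cov",
    "forkman_cov_test",
    "subgroup_report",
]


def ellipsoid_volume(a_cm: float, b_cm: float, c_cm: float) -> float:
    """Ellipsoid volume (π/6)·a·b·c in ccm from three axis lengths in cm."""
    if a_cm <= 0 or b_cm <= 0 or c_cm <= 0:
        raise ValueError("ellipsoid axes must be positive")
    return math.pi / 6.0 * a_cm * b_cm * c_cm


@dataclass
class PathologyMeasurement:
    """Three-axis specimen measurement with derived volume and diameter."""

    axes: tuple[float, float, float]
    volume_ccm: float
    max_diameter_mm: float

    @classmethod
    def from_axes(cls, a_cm: float, b_cm: float, c_cm: float) -> "PathologyMeasurement":
        return cls(
            axes=(float(a_cm), float(b_cm), float(c_cm)),
            volume_ccm=ellipsoid_volume(a_cm, b_cm, c_cm),
            max_diameter_mm=10.0 * max(a_cm, b_cm, c_cm),
        )


@dataclass
class PairedSeries:
    """Positive paired (gold, test) measurements for a set of lesions."""

    gold: np.ndarray
    test: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.gold = np.asarray(self.gold, dtype=np.float64).ravel()
        self.test = np.asarray(self.test, dtype=np.float64).ravel()
        if self.gold.size != self.test.size:
            raise ValueError("gold and test series differ in length")
        if np.any(self.gold <= 0) or np.any(self.test <= 0):
            raise ValueError("measurements must be positive")

    @property
    def n(self) -> int:
        return int(self.gold.size)

    def subset(self, keep: np.ndarray, label: str | None = None) -> "PairedSeries":
        return PairedSeries(self.gold[keep], self.test[keep],
                            label=label if label is not None else self.label)


@dataclass
class AgreementReport:
    """Summary agreement statistics for one paired series (or subgroup)."""

    label: str
    n: int
    available: bool = True
    pearson_r: float | None = None
    mean_relative_difference_pct: float | None = None
    bias_pct: float | None = None
    loa_low_pct: float | None = None
    loa_high_pct: float | None = None
    cov_pct: float | None = None
    mean_gold: float | None = None
    mean_test: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "available": self.available,
            "pearson_r": self.pearson_r,
            "mean_relative_difference_pct": self.mean_relative_difference_pct,
            "bias_pct": self.bias_pct,
            "loa_low_pct": self.loa_low_pct,
            "loa_high_pct": self.loa_high_pct,
            "cov_pct": self.cov_pct,
            "mean_gold": self.mean_gold,
            "mean_test": self.mean_test,
        }


def pearson_r(series: PairedSeries) -> float:
    """Pearson product-moment correlation between gold and test."""
    if series.n < 3:
        raise ValueError("need at least 3 pairs for correlation")
    if np.std(series.gold) == 0 or np.std(series.test) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(series.gold, series.test).statistic)


def _relative_diffs(series: PairedSeries, denominator: str) -> np.ndarray:
    if denominator == "mean":
        denom = (series.test + series.gold) / 2.0
    elif denominator == "gold":
        denom = series.gold
    else:
        raise ValueError("denominator must be 'mean' or 'gold'")
    if np.any(denom == 0):
        raise ValueError("pair with zero denominator")
    return 100.0 * (series.test - series.gold) / denom


def bland_altman_relative(
    series: PairedSeries, denominator: str = "mean"
) -> tuple[float, float, float, np.ndarray]:
    """Bland–Altman bias and limits of agreement on relative differences.

    Per pair, ``d_i = 100·(test−gold)/((test+gold)/2)`` (percent of the
    pair mean; ``denominator="gold"`` switches to the gold-denominated
    variant).  Returns (bias, LoA low, LoA high, per-pair diffs) with
    LoA = bias ± 1.96 · sample sd.
    """
    if series.n < 2:
        raise ValueError("need at least 2 pairs")
    d = _relative_diffs(series, denominator)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, d


def rms_cov(series: PairedSeries) -> float:
    """Root-mean-square coefficient of variation for paired duplicates, %.

    Each (gold, test) pair is a duplicate measurement of one lesion:
    sd_i = |test−gold|/√2, m_i = pair mean, cv_i = sd_i/m_i; the result is
    ``100 · sqrt(mean(cv_i²))``.
    """
    if series.n < 1:
        raise ValueError("empty series")
    m = (series.test + series.gold) / 2.0
    if np.any(m == 0):
        raise ValueError("pair with zero mean")
    cv = (np.abs(series.test - series.gold) / math.sqrt(2.0)) / m
    return float(100.0 * np.sqrt(np.mean(cv ** 2)))


def forkman_cov_test(
    sample1: Sequence[float] | np.ndarray,
    sample2: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Forkman's F-test for equality of two coefficients of variation.

    For independent normal samples with sample CVs c_j = s_j / x̄_j, the
    statistic ``F = [c1²/(1+c1²(n1−1)/n1)] / [c2²/(1+c2²(n2−1)/n2)]`` is
    referred to an F(n1−1, n2−1) distribution (McKay's chi-square
    approximation applied to both samples).  Returns (F, two-sided p),
    the p-value obtained by doubling the smaller tail.
    """
    x1 = np.asarray(sample1, dtype=np.float64).ravel()
    x2 = np.asarray(sample2, dtype=np.float64).ravel()
    n1, n2 = x1.size, x2.size
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 observations per sample")
    m1, m2 = x1.mean(), x2.mean()
    if m1 <= 0 or m2 <= 0:
        raise ValueError("sample means must be positive")
    c1 = x1.std(ddof=1) / m1
    c2 = x2.std(ddof=1) / m2
    if c1 == 0 and c2 == 0:
        return 1.0, 1.0
    if c2 == 0 or c1 == 0:
        return float("inf") if c2 == 0 else 0.0, 0.0
    t1 = c1 ** 2 / (1.0 + c1 ** 2 * (n1 - 1) / n1)
    t2 = c2 ** 2 / (1.0 + c2 ** 2 * (n2 - 1) / n2)
    F = float(t1 / t2)
    dist = stats.f(n1 - 1, n2 - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return F, float(min(1.0, p))


def _report(series: PairedSeries, label: str,
            denominator: str = "mean") -> AgreementReport:
    n = series.n
    if n < 2:
        return AgreementReport(label=label, n=n, available=False)
    bias, lo, hi, _ = bland_altman_relative(series, denominator="mean")
    rep = AgreementReport(
        label=label, n=n,
        pearson_r=pearson_r(series) if (
            n >= 3 and np.std(series.gold) > 0 and np.std(series.test) > 0
        ) else None,
        mean_relative_difference_pct=float(
            np.mean(_relative_diffs(series, denominator))
        ),
        bias_pct=bias, loa_low_pct=lo, loa_high_pct=hi,
        cov_pct=rms_cov(series),
        mean_gold=float(series.gold.mean()),
        mean_test=float(series.test.mean()),
    )
    return rep


def subgroup_report(
    series: PairedSeries,
    pathology_volumes: Sequence[float] | np.ndarray,
    cutoffs: Sequence[float] = (3.0, 45.0),
    denominator: str = "mean",
) -> list[AgreementReport]:
    """Agreement reports for all lesions and per pathological-size subgroup.

    One report covers every lesion; one more is emitted per cutoff,
    restricted to lesions whose pathological volume exceeds it.  A
    subgroup with fewer than 2 lesions is returned flagged unavailable.
    """
    vols = np.asarray(pathology_volumes, dtype=np.float64).ravel()
    if vols.size != series.n:
        raise ValueError("pathology volumes not aligned with pairs")
    reports = [_report(series, label="all", denominator=denominator)]
    for cut in cutoffs:
        keep = vols > cut
        label = f">{cut:g} ccm"
        if keep.sum() < 2:
            reports.append(AgreementReport(label=label, n=int(keep.sum()),
                                           available=False))
        else:
            reports.append(_report(series.subset(keep), label=label,
                                   denominator=denominator))
    return reports
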