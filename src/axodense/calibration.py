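"""Linear bias correction and manual/automated agreement statistics.

Automated counting tools typically show a consistent linear bias against
manual counts. Following standard practice, the bias is estimated on a
validation subset by ordinary least squares of the automated count (AC)
on the mean manual count (MC), AC = a*MC + b, and removed on new images
as AC_corrected = (AC - b) / a. Agreement between corrected automated
and manual counts is summarized by the mean absolute error, the R^2 of
the corrected-vs-manual regression, Bland-Altman limits of agreement
(mean error +/- 1.96 SD of error), the success rate against per-image
95% confidence intervals built from four manual counts, and the median
per-image coefficient of variation of the manual counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CorrectionModel",
    "CountRecord",
    "AgreementReport",
    "LinearBiasCorrector",
    "fit_correction",
    "apply_correction",
    "bland_altman",
    "success_rate",
    "cov_stats",
    "evaluate",
]


@dataclass
class CorrectionModel:
    """Slope/intercept of the AC = a*MC + b validation fit."""

    a: float
    b: float
    fit_n: int = 0
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("correction slope a must be nonzero")


@dataclass
class CountRecord:
    """Manual counts and the automated count for one image."""

    image_id: str
    manual_counts: np.ndarray
    ac: float
    ac_corrected: float | None = None

    def __post_init__(self) -> None:
        self.manual_counts = np.asarray(self.manual_counts, dtype=float)
        if self.manual_counts.size == 0:
            raise ValueError("manual_counts must be nonempty")
        if self.ac < 0:
            raise ValueError("automated count must be nonnegative")

    @property
    def mc_mean(self) -> float:
        return float(self.manual_counts.mean())


@dataclass
class AgreementReport:
    mae: float
    r2: float
    loa: tuple[float, float]
    bias_mean: float
    success_rate: float | None
    median_cov: float | None


class LinearBiasCorrector(BaseEstimator):
    """Sklearn-style estimator for the linear count-bias correction.

    ``fit(mc, ac)`` regresses automated on mean manual counts by OLS;
    ``correct(ac)`` inverts the fitted bias, (ac - intercept_) / slope_.
    """

    def fit(self, mc: Sequence[float], ac: Sequence[float]) -> "LinearBiasCorrector":
        mc = np.asarray(mc, dtype=float).ravel()
        ac = np.asarray(ac, dtype=float).ravel()
        if mc.size < 3:
            raise ValueError("need at least 3 records to fit a correction")
        if np.ptp(mc) == 0:
            raise ValueError("manual counts are all identical: degenerate design")
        res = stats.linregress(mc, ac)
        if res.slope == 0:
            raise ValueError("fitted slope is zero: correction undefined")
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2)
        self.n_ = int(mc.size)
        return self

    def correct(self, ac):
        return (np.asarray(ac, dtype=float) - self.intercept_) / self.slope_

    def to_model(self) -> CorrectionModel:
        return CorrectionModel(self.slope_, self.intercept_, self.n_, self.r2_)


def fit_correction(records: Sequence[CountRecord]) -> CorrectionModel:
    """OLS of AC on mean MC over (validation-subset) records."""
    mc = [r.mc_mean for r in records]
    ac = [r.ac for r in records]
    return LinearBiasCorrector().fit(mc, ac).to_model()


def apply_correction(model: CorrectionModel, ac):
    """AC_corrected = (AC - b) / a."""
    return (np.asarray(ac, dtype=float) - model.b) / model.a


def bland_altman(
    records: Sequence[CountRecord],
) -> tuple[float, tuple[float, float]]:
    """Mean count error and its 1.96-SD limits of agreement.

    Error is corrected AC minus mean MC (falling back to raw AC when no
    correction was applied). Sample (n-1) SD, as is conventional for
    observer-agreement data.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    err = np.array(
        [(r.ac_corrected if r.ac_corrected is not None else r.ac) - r.mc_mean
         for r in records]
    )
    bias = float(err.mean())
    sd = float(err.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def success_rate(records: Sequence[CountRecord], n_required: int = 4) -> float:
    """Fraction of images whose corrected AC falls in the manual-count CI.

    The 95% confidence interval of the mean manual count is the t-based
    interval with ``n_required - 1`` degrees of freedom. Records without
    exactly ``n_required`` manual counts are excluded with a warning.
    """
    usable = [r for r in records if r.manual_counts.size == n_required]
    skipped = len(records) - len(usable)
    if skipped:
        warnings.warn(
            f"success_rate: excluded {skipped} records without exactly "
            f"{n_required} manual counts"
        )
    if not usable:
        raise ValueError(f"no records with {n_required} manual counts")
    tcrit = stats.t.ppf(0.975, df=n_required - 1)
    hits = 0
    for r in usable:
        mean = r.mc_mean
        half = tcrit * r.manual_counts.std(ddof=1) / np.sqrt(n_required)
        ac = r.ac_corrected if r.ac_corrected is not None else r.ac
        hits += mean - half <= ac <= mean + half
    return hits / len(usable)


def cov_stats(records: Sequence[CountRecord]) -> float:
    """Median over images of SD(manual counts) / mean(manual counts)."""
    covs = []
    for r in records:
        if r.manual_counts.size < 2:
            raise ValueError("coefficient of variation needs >= 2 counters")
        mean = r.mc_mean
        if mean > 0:
            covs.append(r.manual_counts.std(ddof=1) / mean)
    if not covs:
        raise ValueError("all records have zero mean manual count")
    return float(np.median(covs))


def evaluate(
    records: Sequence[CountRecord], correction: CorrectionModel | None = None
) -> AgreementReport:
    """Full agreement report for a set of test-subset records.

    If a correction model is given it is applied to every record's AC
    first (records are updated in place).
    """
    if correction is not None:
        for r in records:
            r.ac_corrected = float(apply_correction(correction, r.ac))
    ac = np.array(
        [r.ac_corrected if r.ac_corrected is not None else r.ac for r in records]
    )
    mc = np.array([r.mc_mean for r in records])
    mae = float(np.abs(ac - mc).mean())
    r2 = float(stats.linregress(mc, ac).rvalue ** 2) if np.ptp(mc) > 0 else float("nan")
    bias, loa = bland_altman(records)
    n4 = [r for r in records if r.manual_counts.size == 4]
    sr = success_rate(n4) if n4 else None
    multi = [r for r in records if r.manual_counts.size >= 2]
    cov = cov_stats(multi) if multi else None
    return AgreementReport(
        mae=mae, r2=r2, loa=loa, bias_mean=bias, success_rate=sr, median_cov=cov
    )
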