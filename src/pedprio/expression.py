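"""Expression-validation statistics.

Covers the three statistical procedures used to validate a candidate
gene's expression differences: a one-sample Kolmogorov-Smirnov normality
check, the pooled two-sample t-test (computable from raw values or from
published (mean, SD, n) summaries alone), and comparative-Ct qPCR
relative quantification (fold change = 2**-ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import ExpressionInputError

Summary = Tuple[float, float, int]  # (mean, sd, n)


@dataclass
class ExpressionGroup:
    """One comparison arm, held as raw values and/or summary moments."""

    label: str
    mean: float
    sd: float
    n: int
    raw_values: Optional[np.ndarray] = None

    @classmethod
    def from_raw(cls, label: str, values: Sequence[float]) -> "ExpressionGroup":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ExpressionInputError(f"group {label!r}: need n >= 2, got {arr.size}")
        return cls(
            label=label,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
            n=int(arr.size),
            raw_values=arr,
        )

    @classmethod
    def from_summary(cls, label: str, mean: float, sd: float, n: int) -> "ExpressionGroup":
        if n < 2:
            raise ExpressionInputError(f"group {label!r}: need n >= 2, got {n}")
        if sd <= 0:
            raise ExpressionInputError(f"group {label!r}: sd must be > 0, got {sd}")
        return cls(label=label, mean=float(mean), sd=float(sd), n=int(n))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_difference: float
    pooled_sd: float
    group1: str = "group1"
    group2: str = "group2"
    welch: bool = False

    def describe(self) -> str:
        return (
            f"{self.group1} - {self.group2}: diff={self.mean_difference:.4g}, "
            f"t={self.t:.3f}, df={self.df:.4g}, p={self.p:.4g}"
        )


@dataclass
class CtMeasurement:
    """One qPCR observation: target and reference-gene threshold cycles."""

    ct_target: float
    ct_reference: float
    condition: str = "sample"

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ExpressionInputError(f"{name} must be positive and finite, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


# ---------------------------------------------------------------------------


def ks_normality(
    values: Sequence[float], lilliefors: bool = False
) -> tuple[float, float]:
    """One-sample K-S test of normality with estimated mean and SD.

    Default p is the uncorrected asymptotic K-S probability (conservative
    when parameters are estimated, matching common statistical-package
    usage); ``lilliefors=True`` applies the Lilliefors correction.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ExpressionInputError(f"need n >= 4 values, got {arr.size}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ExpressionInputError("zero variance: normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(arr, dist="norm")
        return float(d), float(p)
    d, p = stats.kstest(arr, "norm", args=(arr.mean(), sd), mode="asymp")
    return float(d), float(p)


def _as_summary(group) -> tuple[str, float, float, int]:
    if isinstance(group, ExpressionGroup):
        return group.label, group.mean, group.sd, group.n
    mean, sd, n = group
    return "group", float(mean), float(sd), int(n)


def pooled_t_from_summary(
    group1: Union[ExpressionGroup, Summary],
    group2: Union[ExpressionGroup, Summary],
    welch: bool = False,
) -> TTestResult:
    """Two-sample t-test from (mean, sd, n) summaries.

    Pooled (equal-variance) by default: s2 = ((n1-1)s1^2 + (n2-1)s2^2) /
    (n1+n2-2), t = (m1-m2) / (s*sqrt(1/n1+1/n2)), df = n1+n2-2; Welch via
    flag.  The sign follows first-minus-second.
    """
    l1, m1, s1, n1 = _as_summary(group1)
    l2, m2, s2, n2 = _as_summary(group2)
    if n1 + n2 < 4 or min(n1, n2) < 2:
        raise ExpressionInputError("need n >= 2 per group and n1 + n2 >= 4")
    if s1 <= 0 or s2 <= 0:
        raise ExpressionInputError("group SDs must be > 0")
    t, p = stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        pooled_sd = math.sqrt((s1**2 + s2**2) / 2.0)
    else:
        df = n1 + n2 - 2
        pooled_sd = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    return TTestResult(
        t=float(t),
        df=float(df),
        p=float(p),
        mean_difference=m1 - m2,
        pooled_sd=pooled_sd,
        group1=l1,
        group2=l2,
        welch=welch,
    )


def pooled_t_from_raw(
    values1: Sequence[float],
    values2: Sequence[float],
    welch: bool = False,
    labels: tuple[str, str] = ("group1", "group2"),
) -> TTestResult:
    """Two-sample t-test from raw values.

    Identical to :func:`pooled_t_from_summary` applied to the groups'
    exact sample moments (the equivalence is a tested property).
    """
    g1 = ExpressionGroup.from_raw(labels[0], values1)
    g2 = ExpressionGroup.from_raw(labels[1], values2)
    return pooled_t_from_summary(g1, g2, welch=welch)


def ddct_fold_change(
    sample: Union[CtMeasurement, tuple[float, float]],
    calibrator: Union[CtMeasurement, tuple[float, float]],
) -> float:
    """Comparative-Ct relative quantification.

    ddCt = (Ct_target - Ct_reference)_sample
         - (Ct_target - Ct_reference)_calibrator; returns 2**-ddCt,
    the target's fold change in the sample relative to the calibrator,
    normalized to the reference gene.
    """
    if not isinstance(sample, CtMeasurement):
        sample = CtMeasurement(*sample, condition="sample")
    if not isinstance(calibrator, CtMeasurement):
        calibrator = CtMeasurement(*calibrator, condition="calibrator")
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0**-ddct)
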