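"""Interrater agreement statistics.

Implements the agreement battery used to validate semi-automated fluid
volumetry against manual segmentation:

* ICC(2,1) — two-way random-effects, absolute-agreement, single-rater
  intraclass correlation, with McGraw-Wong F-based 95% confidence intervals
  and the conventional interpretation bands (< 0.5 poor, 0.5-0.75 moderate,
  0.75-0.9 good, > 0.9 excellent).
* Bland-Altman mean difference and 95% limits of agreement
  (mean +/- 1.96 x sample SD of paired differences).
* Dice similarity coefficient between segmentation masks.
* Paired t-test on logit-transformed Dice coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import PFTQuantError

__all__ = [
    "RatingMatrix",
    "ICCResult",
    "BlandAltmanResult",
    "AgreementReport",
    "icc_2_1",
    "bland_altman",
    "dice",
    "logit",
    "paired_t_logit_dsc",
    "build_report",
]


@dataclass
class RatingMatrix:
    """n_exams x k_raters matrix of secretory-response measurements (mL)."""

    values: np.ndarray
    exam_ids: list[str] = field(default_factory=list)
    rater_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PFTQuantError("rating matrix must be 2D (exams x raters)")
        n, k = self.values.shape
        if n < 3 or k < 2:
            raise PFTQuantError(f"rating matrix needs n >= 3 exams and k >= 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise PFTQuantError("rating matrix has missing or non-finite cells")
        if not self.exam_ids:
            self.exam_ids = [f"exam{i}" for i in range(n)]
        if not self.rater_ids:
            self.rater_ids = [f"rater{j}" for j in range(k)]


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    label: str
    ms_rows: float
    ms_cols: float
    ms_error: float


@dataclass
class BlandAltmanResult:
    mean_diff: float
    loa: tuple[float, float]
    sd_diff: float


@dataclass
class AgreementReport:
    icc: ICCResult
    ba: BlandAltmanResult
    dsc_values: np.ndarray
    dsc_mean: float
    dsc_sd: float
    logit_t: tuple[float, int, float] | None  # (t, df, p), None if not computed


def interpret_icc(value: float) -> str:
    """Conventional agreement bands for ICC point estimates."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def icc_2_1(m: RatingMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with McGraw-Wong confidence interval.

    Two-way random-effects ANOVA with rows = exams and columns = raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    The CI uses the F-distribution construction with Satterthwaite degrees of
    freedom for the absolute-agreement single-rater coefficient.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise PFTQuantError("no variance: ICC undefined for a constant rating matrix")

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) interval for ICC(A,1), Satterthwaite df.
    if mse == 0 and msc == 0:
        ci = (1.0, 1.0)  # perfect agreement: interval degenerates
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
        ci = (float(np.clip(lower, -1.0, 1.0)), float(np.clip(upper, -1.0, 1.0)))

    return ICCResult(
        estimate=float(icc),
        ci95=ci,
        label=interpret_icc(float(icc)),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
    )


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Mean difference and 95% limits of agreement for paired measurements.

    Differences are x - y; limits are mean +/- 1.96 times the sample (n-1) SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise PFTQuantError("Bland-Altman requires two equal-length vectors with n >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa=(mean_diff - 1.96 * sd, mean_diff + 1.96 * sd),
        sd_diff=sd,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B|/(|A|+|B|).

    Two empty masks are defined to agree perfectly (DSC = 1): agreement on the
    absence of fluid.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise PFTQuantError(f"mask geometry mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def logit(v: float, clamp_eps: float | None = None) -> float:
    """ln(v / (1 - v)), mapping (0, 1) onto the real line.

    Boundary values are undefined; pass ``clamp_eps`` to opt in to clamping
    into [eps, 1-eps] (the clamp is explicit, never silent).
    """
    v = float(v)
    if clamp_eps is not None:
        v = min(max(v, clamp_eps), 1.0 - clamp_eps)
    if not 0.0 < v < 1.0:
        raise PFTQuantError("logit undefined at 0 or 1; pass clamp_eps to opt in to clamping")
    return float(np.log(v / (1.0 - v)))


def paired_t_logit_dsc(
    dsc_method1: np.ndarray,
    dsc_method2: np.ndarray,
    clamp_eps: float | None = None,
) -> tuple[float, int, float]:
    """Paired two-sided t-test on logit-transformed DSC pairs.

    Returns ``(t, df, p)`` with df = n - 1.
    """
    a = np.asarray(dsc_method1, dtype=float)
    b = np.asarray(dsc_method2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise PFTQuantError("paired t-test requires two equal-length vectors with n >= 2")
    la = np.array([logit(v, clamp_eps) for v in a])
    lb = np.array([logit(v, clamp_eps) for v in b])
    d = la - lb
    scale = max(1.0, float(np.abs(d).max()))
    if float(d.std(ddof=1)) <= 1e-12 * scale:
        raise PFTQuantError("zero variance of paired differences: t statistic undefined")
    res = stats.ttest_rel(la, lb)
    return float(res.statistic), a.size - 1, float(res.pvalue)


def build_report(
    ratings: RatingMatrix,
    mask_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    dsc_reference: np.ndarray | None = None,
    clamp_eps: float | None = None,
) -> AgreementReport:
    """Aggregate the full agreement battery for one set of rated exams.

    Bland-Altman compares the first two rater columns.  If ``mask_pairs`` is
    given, per-exam DSC values are computed; if ``dsc_reference`` (a second
    method's DSC vector) is also given, the paired logit t-test compares them.
    """
    icc = icc_2_1(ratings)
    ba = bland_altman(ratings.values[:, 0], ratings.values[:, 1])

    if mask_pairs:
        dsc_values = np.array([dice(a, b) for a, b in mask_pairs])
    else:
        dsc_values = np.array([])
    dsc_mean = float(dsc_values.mean()) if dsc_values.size else float("nan")
    dsc_sd = float(dsc_values.std(ddof=1)) if dsc_values.size > 1 else float("nan")

    logit_t = None
    if dsc_reference is not None and dsc_values.size:
        logit_t = paired_t_logit_dsc(dsc_values, dsc_reference, clamp_eps=clamp_eps)

    return AgreementReport(
        icc=icc,
        ba=ba,
        dsc_values=dsc_values,
        dsc_mean=dsc_mean,
        dsc_sd=dsc_sd,
        logit_t=logit_t,
    )
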