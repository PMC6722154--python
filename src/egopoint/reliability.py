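"""Internal-consistency and test-retest reliability for pointing angles.

Two-way intraclass correlation coefficients in the McGraw & Wong taxonomy
(consistency/absolute agreement, single/average measures), Cronbach's
alpha (numerically identical to ICC(C,k)), and a day-1 vs day-2
test-retest coefficient.  Azimuth angles are circular; before the linear
mean-square decomposition they are unwrapped about the pooled circular
mean (see :func:`unwrap_about_circular_mean`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circgeo import circ_distance, circ_mean

FORMS = ("ICC_C1", "ICC_Ck", "ICC_A1", "ICC_Ak", "alpha")


@dataclass(frozen=True)
class ReliabilityResult:
    estimate: float
    ci_low: float
    ci_high: float
    form: str
    n_subjects: int
    n_items: int
    degenerate: bool = False


def _mean_squares(x: np.ndarray):
    """Two-way decomposition: rows = subjects, columns = items/raters."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(matrix, form: str = "ICC_C1", ci: float = 0.95) -> ReliabilityResult:
    """Two-way ICC of a complete subjects x items matrix.

    Forms: ``ICC_C1``/``ICC_Ck`` (consistency, single/average measures,
    items treated as fixed) and ``ICC_A1``/``ICC_Ak`` (absolute agreement,
    items random).  ``alpha`` is an alias for ``ICC_Ck``.  Confidence
    intervals use the exact F interval for the C forms and the
    Satterthwaite approximation for the A forms.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {FORMS}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 items")
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains missing values; apply listwise "
                         "deletion before calling icc")
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("constant matrix: reliability undefined (zero variance)")
    msr, msc, mse = _mean_squares(x)
    if np.var(x.mean(axis=1)) == 0:
        return ReliabilityResult(0.0, np.nan, np.nan, form, n, k, degenerate=True)

    alpha_level = 1.0 - ci
    if form in ("ICC_C1", "ICC_Ck", "alpha"):
        if mse == 0:
            est = 1.0
            lo = hi = 1.0
        else:
            F = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = F / stats.f.ppf(1 - alpha_level / 2, df1, df2)
            fu = F * stats.f.ppf(1 - alpha_level / 2, df2, df1)
            if form == "ICC_C1":
                est = (msr - mse) / (msr + (k - 1) * mse)
                lo = (fl - 1) / (fl + k - 1)
                hi = (fu - 1) / (fu + k - 1)
            else:
                est = (msr - mse) / msr
                lo = 1 - 1 / fl
                hi = 1 - 1 / fu
    else:  # absolute agreement
        icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if mse == 0:
            lo_1 = hi_1 = 1.0
        else:
            fj = msc / mse
            a = (k * icc_a1 * fj + n * (1 + (k - 1) * icc_a1) - k * icc_a1)
            vn = (k - 1) * (n - 1) * a ** 2
            vd = ((n - 1) * k ** 2 * icc_a1 ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * icc_a1) - k * icc_a1) ** 2)
            v = vn / vd
            f_u = stats.f.ppf(1 - alpha_level / 2, n - 1, v)
            f_l = stats.f.ppf(1 - alpha_level / 2, v, n - 1)
            lo_1 = (n * (msr - f_u * mse)
                    / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi_1 = (n * (f_l * msr - mse)
                    / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
        if form == "ICC_A1":
            est, lo, hi = icc_a1, lo_1, hi_1
        else:
            est = (msr - mse) / (msr + (msc - mse) / n)
            lo = k * lo_1 / (1 + (k - 1) * lo_1)
            hi = k * hi_1 / (1 + (k - 1) * hi_1)
    return ReliabilityResult(float(est), float(lo), float(hi),
                             "alpha" if form == "alpha" else form, n, k)


def cronbach_alpha(matrix, ci: float = 0.95) -> ReliabilityResult:
    """Cronbach's alpha via the item-variance formula
    ``alpha = k/(k-1) (1 - sum var_i / var(sum))``; equals ICC(C,k) on the
    same matrix to machine precision.  The CI is the Feldt F interval."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 items")
    n, k = x.shape
    if np.ptp(x) == 0:
        raise ValueError("constant matrix: reliability undefined (zero variance)")
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        return ReliabilityResult(0.0, np.nan, np.nan, "alpha", n, k,
                                 degenerate=True)
    est = k / (k - 1) * (1.0 - np.sum(np.var(x, axis=0, ddof=1)) / total_var)
    ref = icc(x, form="alpha", ci=ci)
    return ReliabilityResult(float(est), ref.ci_low, ref.ci_high, "alpha",
                             n, k, degenerate=ref.degenerate)


def unwrap_about_circular_mean(angles_deg) -> np.ndarray:
    """Represent circular angles on a line: pooled circular mean plus the
    signed circular distance of each angle from it.  Makes linear
    mean-square machinery applicable to azimuth data."""
    a = np.asarray(angles_deg, dtype=float)
    mu = circ_mean(a.ravel()).mean_deg
    return mu + np.asarray(circ_distance(a, mu))


def test_retest(day1, day2, circular: bool = False,
                form: str = "ICC_C1", ci: float = 0.95) -> ReliabilityResult:
    """Test-retest reliability of matched per-target measurements across
    two days, treating days as two "items".

    ``circular=True`` unwraps both days' angles about their pooled circular
    mean first (required for azimuth).  Default form is ICC(C,1), the
    conventional single-measure test-retest coefficient; an average-measure
    (alpha-type) coefficient is available via ``form='ICC_Ck'``.
    """
    d1 = np.asarray(day1, dtype=float).ravel()
    d2 = np.asarray(day2, dtype=float).ravel()
    if d1.shape != d2.shape:
        raise ValueError("day1 and day2 must have matched units")
    if d1.size < 3:
        raise ValueError("test_retest requires >= 3 matched units")
    x = np.column_stack([d1, d2])
    if circular:
        x = unwrap_about_circular_mean(x)
    return icc(x, form=form, ci=ci)
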