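"""Method-comparison statistics for repeated, paired physiological measurements.

Three families, all operating on plain DataFrames:

* **Repeatability** of duplicate measurements: per-pair coefficient of
  variation (two-value sample SD over the pair mean), precision = 2 x CV,
  least significant change LSC = CV x 1.96 x sqrt(2), medians with BCa
  bootstrap confidence intervals.
* **Agreement** between a test and a reference method with a possibly
  non-constant bias: ordinary least squares of bias on reference (giving a
  conversion equation test = (1 + slope) x ref + intercept), a 95%
  prediction interval of the bias combining parameter uncertainty (subject-
  clustered bootstrap) with residual scatter, and the Critchley percentage
  error 2 x SD(bias) / mean(reference).
* **Trending**: four-quadrant sign concordance of paired consecutive
  changes with a Wilson score CI, and polar-plot statistics (angular bias
  relative to the line of identity, radial limits of agreement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, InsufficientDataError

__all__ = [
    "RepeatabilityResult",
    "AgreementResult",
    "TrendResult",
    "repeatability",
    "bland_altman",
    "four_quadrant",
    "polar_trend",
    "wilson_ci",
    "consecutive_deltas",
    "trend_analysis",
]

_Z95 = 1.959963984540054
LSC_OVER_PRECISION = _Z95 * np.sqrt(2.0) / 2.0  # ~1.386, exact per-pair ratio


# ---------------------------------------------------------------------------
# Repeatability


@dataclass
class RepeatabilityResult:
    """Duplicate-measurement repeatability, all percentages of the pair mean."""

    cv_pct: np.ndarray
    precision_pct: np.ndarray
    lsc_pct: np.ndarray
    median_cv_pct: float
    median_precision_pct: float
    median_lsc_pct: float
    ci95_precision_pct: tuple[float, float] | None
    ci95_lsc_pct: tuple[float, float] | None
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "median_cv_pct": self.median_cv_pct,
            "median_precision_pct": self.median_precision_pct,
            "median_lsc_pct": self.median_lsc_pct,
            "ci95_precision_pct": list(self.ci95_precision_pct)
            if self.ci95_precision_pct
            else None,
            "ci95_lsc_pct": list(self.ci95_lsc_pct) if self.ci95_lsc_pct else None,
        }


def _bca_ci_median(values: np.ndarray, n_boot: int, seed) -> tuple[float, float]:
    if np.ptp(values) == 0:  # degenerate set: the BCa jackknife is undefined
        v = float(values[0])
        return (v, v)
    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (values,),
        np.median,
        n_resamples=n_boot,
        confidence_level=0.95,
        method="BCa",
        rng=rng,
    )
    return float(res.confidence_interval.low), float(res.confidence_interval.high)


def repeatability(
    reps: pd.DataFrame, n_boot: int = 10_000, seed: int | None = 0
) -> RepeatabilityResult:
    """Repeatability of duplicate measurements.

    ``reps`` needs columns ``value_1`` and ``value_2`` (one row per
    replicate pair). Per pair the CV is the two-value sample SD
    (``|x1 - x2|/sqrt(2)``) divided by the pair mean; precision and LSC
    follow as 2 x CV and CV x 1.96 x sqrt(2). Medians over pairs are
    reported with BCa bootstrap 95% CIs (resampling pairs). With fewer than
    2 pairs the point estimates are returned and the CIs are ``None``.
    """
    x1 = np.asarray(reps["value_1"], dtype=float)
    x2 = np.asarray(reps["value_2"], dtype=float)
    if x1.size == 0:
        raise InsufficientDataError("no replicate pairs")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise DataError("non-finite replicate values")
    mean = (x1 + x2) / 2.0
    if np.any(mean <= 0):
        raise DataError("pair means must be positive for a CV")
    sd = np.abs(x1 - x2) / np.sqrt(2.0)
    cv = sd / mean * 100.0
    precision = 2.0 * cv
    lsc = cv * _Z95 * np.sqrt(2.0)

    ci_prec = ci_lsc = None
    if x1.size >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        ci_prec = _bca_ci_median(precision, n_boot, rng)
        ci_lsc = _bca_ci_median(lsc, n_boot, rng)

    return RepeatabilityResult(
        cv_pct=cv,
        precision_pct=precision,
        lsc_pct=lsc,
        median_cv_pct=float(np.median(cv)),
        median_precision_pct=float(np.median(precision)),
        median_lsc_pct=float(np.median(lsc)),
        ci95_precision_pct=ci_prec,
        ci95_lsc_pct=ci_lsc,
        n_pairs=int(x1.size),
    )


# ---------------------------------------------------------------------------
# Agreement (non-constant-bias Bland-Altman)


@dataclass
class AgreementResult:
    """Bland-Altman agreement with a reference-dependent (non-constant) bias."""

    bias: np.ndarray
    mean_bias: float
    bias_slope: float
    bias_intercept: float
    conversion_slope: float
    conversion_intercept: float
    sd_bias: float
    percentage_error_pct: float
    pi95_halfwidth: float | None
    n_obs: int
    n_subjects: int
    r2: float = float("nan")
    ref_grid: np.ndarray | None = field(default=None, repr=False)
    pi95_band: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "mean_bias": self.mean_bias,
            "bias_slope": self.bias_slope,
            "bias_intercept": self.bias_intercept,
            "conversion_slope": self.conversion_slope,
            "conversion_intercept": self.conversion_intercept,
            "sd_bias": self.sd_bias,
            "percentage_error_pct": self.percentage_error_pct,
            "pi95_halfwidth": self.pi95_halfwidth,
            "r2": self.r2,
        }


def bland_altman(
    series: pd.DataFrame, n_sim: int = 10_000, seed: int | None = 0
) -> AgreementResult:
    """Agreement between test and reference allowing a linear bias trend.

    ``series`` needs columns ``subject, value_test, value_ref``. The bias
    (test - ref) is regressed on the reference by OLS; the conversion
    equation follows as ``test = (1 + slope) x ref + intercept``. The 95%
    prediction interval of the bias at the mean reference combines
    parameter draws from a subject-clustered bootstrap (``n_sim``
    resamples; i.i.d. row bootstrap with a warning when only one subject is
    present) with Gaussian residual draws. ``n_sim=0`` skips the interval.
    """
    test = np.asarray(series["value_test"], dtype=float)
    ref = np.asarray(series["value_ref"], dtype=float)
    subj = np.asarray(series["subject"])
    if test.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if not (np.all(np.isfinite(test)) and np.all(np.isfinite(ref))):
        raise DataError("non-finite paired values")
    if np.ptp(ref) == 0:
        raise np.linalg.LinAlgError("reference is constant; bias slope unidentifiable")

    bias = test - ref
    X = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(X, bias, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    fitted = X @ coef
    resid = bias - fitted
    dof = max(1, bias.size - 2)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((bias - bias.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    subjects = pd.unique(subj)
    pi_halfwidth = None
    ref_grid = pi_band = None
    if n_sim > 0:
        rng = np.random.default_rng(seed)
        if len(subjects) < 2:
            warnings.warn(
                "single subject: falling back to i.i.d. bootstrap over rows",
                stacklevel=2,
            )
            groups = [np.array([i]) for i in range(bias.size)]
        else:
            groups = [np.flatnonzero(subj == s) for s in subjects]
        ref_mean = float(np.mean(ref))
        ref_grid = np.linspace(ref.min(), ref.max(), 25)
        draws = np.empty(n_sim)
        band_draws = np.empty((n_sim, ref_grid.size))
        k = len(groups)
        for b in range(n_sim):
            take = np.concatenate(
                [groups[i] for i in rng.integers(0, k, size=k)]
            )
            rb, bb = ref[take], bias[take]
            if np.ptp(rb) == 0:
                draws[b] = np.nan
                band_draws[b] = np.nan
                continue
            Xb = np.column_stack([np.ones_like(rb), rb])
            cb, *_ = np.linalg.lstsq(Xb, bb, rcond=None)
            sb = float(
                np.sqrt(np.sum((bb - Xb @ cb) ** 2) / max(1, bb.size - 2))
            )
            eps = rng.normal(0.0, sb)
            draws[b] = cb[0] + cb[1] * ref_mean + eps
            band_draws[b] = cb[0] + cb[1] * ref_grid + rng.normal(0.0, sb)
        lo, hi = np.nanpercentile(draws, [2.5, 97.5])
        pi_halfwidth = float((hi - lo) / 2.0)
        pi_band = np.nanpercentile(band_draws, [2.5, 97.5], axis=0)

    return AgreementResult(
        bias=bias,
        mean_bias=float(np.mean(bias)),
        bias_slope=beta,
        bias_intercept=alpha,
        conversion_slope=1.0 + beta,
        conversion_intercept=alpha,
        sd_bias=float(np.std(bias, ddof=1)),
        percentage_error_pct=float(
            2.0 * np.std(bias, ddof=1) / np.mean(ref) * 100.0
        ),
        pi95_halfwidth=pi_halfwidth,
        n_obs=int(bias.size),
        n_subjects=int(len(subjects)),
        r2=r2,
        ref_grid=ref_grid,
        pi95_band=pi_band,
    )


# ---------------------------------------------------------------------------
# Trending


@dataclass
class TrendResult:
    """Trending ability of a test method against a reference."""

    deltas: pd.DataFrame
    concordance_pct: float
    wilson_ci95_pct: tuple[float, float]
    angular_bias_deg: float
    angular_sd_deg: float
    radial_loa_deg: float

    def to_dict(self) -> dict:
        return {
            "n_deltas": int(len(self.deltas)),
            "concordance_pct": self.concordance_pct,
            "wilson_ci95_pct": list(self.wilson_ci95_pct),
            "angular_bias_deg": self.angular_bias_deg,
            "angular_sd_deg": self.angular_sd_deg,
            "radial_loa_deg": self.radial_loa_deg,
        }


def consecutive_deltas(series: pd.DataFrame) -> pd.DataFrame:
    """Within-subject changes between consecutive condition orders.

    ``series`` needs columns ``subject, order, value_test, value_ref``.
    """
    rows = []
    for subject, grp in series.groupby("subject", sort=False):
        grp = grp.sort_values("order")
        dt = np.diff(grp["value_test"].to_numpy(dtype=float))
        dr = np.diff(grp["value_ref"].to_numpy(dtype=float))
        for a, b in zip(dt, dr):
            rows.append({"subject": subject, "d_test": a, "d_ref": b})
    if not rows:
        raise InsufficientDataError("no consecutive within-subject pairs")
    return pd.DataFrame(rows)


def wilson_ci(successes: int, n: int) -> tuple[float, float]:
    """95% Wilson score interval for a proportion, in percent."""
    if n < 1:
        raise InsufficientDataError("n must be >= 1")
    if not 0 <= successes <= n:
        raise DataError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return float(lo * 100.0), float(hi * 100.0)


def four_quadrant(
    series: pd.DataFrame, exclusion_zone: float = 0.0
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Four-quadrant concordance of paired directional changes.

    Deltas are computed between consecutive conditions within subject; a
    delta pair is concordant when both methods changed in the same
    direction. With a positive ``exclusion_zone`` the pairs whose changes
    are both within it are dropped; the default of 0 excludes nothing.
    Returns ``(deltas, concordance %, Wilson 95% CI %)``.
    """
    deltas = consecutive_deltas(series)
    dt = deltas["d_test"].to_numpy(dtype=float)
    dr = deltas["d_ref"].to_numpy(dtype=float)
    if exclusion_zone > 0:
        keep = (np.abs(dt) > exclusion_zone) | (np.abs(dr) > exclusion_zone)
        dt, dr = dt[keep], dr[keep]
        deltas = deltas.loc[keep].reset_index(drop=True)
    if dt.size == 0:
        raise InsufficientDataError("all delta pairs fell in the exclusion zone")
    concordant = int(np.count_nonzero(dt * dr > 0))
    rate = concordant / dt.size * 100.0
    return deltas, float(rate), wilson_ci(concordant, dt.size)


def polar_trend(
    deltas: pd.DataFrame,
    method: str = "sd",
) -> tuple[float, float, float]:
    """Polar-plot trending statistics of paired deltas.

    Each delta pair maps to a signed angle from the line of identity,
    ``theta = atan2(d_test, d_ref) - 45 deg`` wrapped to (-180, 180];
    pairs in which both methods decreased are first reflected through the
    origin (negative deflections made positive), so a joint decrease along
    the identity line also scores 0 deg. Zero-length pairs are excluded
    with a warning. Angular bias is the mean angle; radial limits of
    agreement are ``1.96 x SD`` of the angles (``method='sd'``) or the
    97.5th percentile of ``|theta - bias|`` (``method='percentile'``).

    Returns ``(angular_bias_deg, angular_sd_deg, radial_loa_deg)``.
    """
    dt = np.asarray(deltas["d_test"], dtype=float)
    dr = np.asarray(deltas["d_ref"], dtype=float)
    nonzero = ~((dt == 0) & (dr == 0))
    if np.count_nonzero(~nonzero):
        warnings.warn(
            f"excluding {np.count_nonzero(~nonzero)} zero-length delta pair(s)",
            stacklevel=2,
        )
    dt, dr = dt[nonzero], dr[nonzero]
    if dt.size == 0:
        raise InsufficientDataError("all delta pairs have zero length")
    both_neg = (dt < 0) & (dr < 0)
    dt = np.where(both_neg, -dt, dt)
    dr = np.where(both_neg, -dr, dr)
    theta = np.degrees(np.arctan2(dt, dr)) - 45.0
    theta = (theta + 180.0) % 360.0 - 180.0
    theta[theta == -180.0] = 180.0
    bias = float(np.mean(theta))
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    if method == "sd":
        loa = _Z95 * sd
    elif method == "percentile":
        loa = float(np.percentile(np.abs(theta - bias), 97.5))
    else:
        raise ValueError("method must be 'sd' or 'percentile'")
    return bias, sd, float(loa)


def trend_analysis(series: pd.DataFrame, exclusion_zone: float = 0.0) -> TrendResult:
    """Four-quadrant + polar trending summary of a paired series."""
    deltas, rate, ci = four_quadrant(series, exclusion_zone=exclusion_zone)
    bias, sd, loa = polar_trend(deltas)
    return TrendResult(
        deltas=deltas,
        concordance_pct=rate,
        wilson_ci95_pct=ci,
        angular_bias_deg=bias,
        angular_sd_deg=sd,
        radial_loa_deg=loa,
    )
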