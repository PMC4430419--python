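"""qPCR quantification, two-sample tests, respiration rates, redox ratio.

Absolute mtDNA quantification follows the plasmid standard-curve design:
Ct is regressed on log10(copies) over a tenfold dilution series; unknown
Cts are inverted through the line and scaled by the lysis/dilution scheme
(5 worms lysed, 40x dilution, 2 ul template per reaction) to copies per
worm. Relative quantification normalizes to an unexposed reference and
propagates replicate Ct dispersion into a confidence interval on the
percent scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurve:
    """Log-linear qPCR calibration: Ct = slope * log10(copies) + intercept.

    A valid amplification curve has negative slope (more template, earlier
    Ct); slope -3.32 corresponds to 100% amplification efficiency.
    """

    slope: float
    intercept: float
    r_squared: float = 1.0

    def predict_ct(self, copies) -> np.ndarray:
        copies = np.asarray(copies, dtype=np.float64)
        if np.any(copies <= 0):
            raise ValueError("copies must be positive")
        return self.slope * np.log10(copies) + self.intercept

    def copies_from_ct(self, ct) -> np.ndarray:
        """Invert the curve: copies = 10 ** ((ct - intercept) / slope)."""
        if self.slope >= 0:
            raise ValueError("cannot invert a curve with non-negative slope")
        ct = np.asarray(ct, dtype=np.float64)
        return 10.0 ** ((ct - self.intercept) / self.slope)


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies)."""
    copies = np.asarray(copies, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if copies.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.any(copies <= 0):
        raise ValueError("copies must be positive")
    x = np.log10(copies)
    if np.allclose(x, x[0]):
        raise ValueError("all dilutions identical; cannot fit a line")
    res = stats.linregress(x, ct)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


@dataclass
class QPCRSample:
    """Replicate Ct measurements of one lysate, with the scaling scheme.

    Defaults follow the standard worm-lysis protocol: five adults lysed,
    lysate diluted 40x, 2 ul used as PCR template. ``lysate_volume_ul`` has
    no universal default and must be supplied for per-worm scaling.
    """

    ct_values: np.ndarray
    lysate_volume_ul: float
    dilution_factor: float = 40.0
    template_volume_ul: float = 2.0
    worms_per_lysate: int = 5
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.ct_values = np.asarray(self.ct_values, dtype=np.float64)
        if not np.all(np.isfinite(self.ct_values)):
            raise ValueError("non-finite Ct values")
        if min(self.dilution_factor, self.template_volume_ul,
               self.lysate_volume_ul) <= 0 or self.worms_per_lysate <= 0:
            raise ValueError("volumes/counts must be positive")

    @property
    def mean_ct(self) -> float:
        return float(self.ct_values.mean())

    @property
    def n(self) -> int:
        return int(self.ct_values.size)


def quantify_absolute(sample: QPCRSample, curve: StandardCurve) -> dict:
    """Absolute copies per worm from mean Ct through the standard curve.

    copies_reaction = 10 ** ((mean Ct - intercept) / slope)
    copies_per_worm = copies_reaction * dilution * (lysate/template volume)
                      / worms_per_lysate
    """
    copies_reaction = float(curve.copies_from_ct(sample.mean_ct))
    scale = (sample.dilution_factor
             * sample.lysate_volume_ul / sample.template_volume_ul
             / sample.worms_per_lysate)
    return {
        "sample_id": sample.sample_id,
        "condition": sample.condition,
        "mean_ct": sample.mean_ct,
        "copies_reaction": copies_reaction,
        "copies_per_worm": copies_reaction * scale,
    }


def quantify_relative(
    samples: list[QPCRSample],
    reference: QPCRSample,
    curve: StandardCurve,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Percent-of-reference quantification with confidence intervals.

    The log10 abundance ratio of sample vs reference is
    ``(mean_ct_s - mean_ct_r) / slope``; its standard error combines the
    replicate Ct dispersion of both groups through the pooled SD, and the
    CI uses the t quantile at ``n_s + n_r - 2`` degrees of freedom before
    back-transforming to the percent scale.
    """
    if reference.n > 1 and reference.ct_values.std(ddof=1) == 0:
        warnings.warn("reference replicates have zero variance", stacklevel=2)
    rows = []
    for s in samples:
        log_ratio = (s.mean_ct - reference.mean_ct) / curve.slope
        df = s.n + reference.n - 2
        sp = math.sqrt(
            ((s.n - 1) * s.ct_values.var(ddof=1)
             + (reference.n - 1) * reference.ct_values.var(ddof=1)) / df
        ) if df > 0 else 0.0
        se_log = sp * math.sqrt(1.0 / s.n + 1.0 / reference.n) / abs(curve.slope)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df) if df > 0 else float("inf")
        rows.append({
            "sample_id": s.sample_id,
            "condition": s.condition,
            "percent_of_reference": 100.0 * 10.0**log_ratio,
            "ci_low": 100.0 * 10.0 ** (log_ratio - tcrit * se_log),
            "ci_high": 100.0 * 10.0 ** (log_ratio + tcrit * se_log),
            "df": df,
        })
    return pd.DataFrame(rows)


@dataclass
class TwoSampleSummary:
    """Sufficient statistics of a two-group comparison."""

    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int

    @classmethod
    def from_samples(cls, g1, g2) -> "TwoSampleSummary":
        g1 = np.asarray(g1, dtype=np.float64)
        g2 = np.asarray(g2, dtype=np.float64)
        if g1.size < 2 or g2.size < 2:
            raise ValueError("each group needs at least 2 observations")
        return cls(float(g1.mean()), float(g2.mean()),
                   float(g1.var(ddof=1)), float(g2.var(ddof=1)),
                   int(g1.size), int(g2.size))

    @property
    def pooled_sd(self) -> float:
        df = self.n1 + self.n2 - 2
        return math.sqrt(((self.n1 - 1) * self.var1
                          + (self.n2 - 1) * self.var2) / df)


def pooled_t_test(g1, g2) -> dict:
    """Two-sample t-test with pooled variance.

    t = (mean1 - mean2) / (s_p * sqrt(1/n1 + 1/n2)),
    s_p = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)),  df = n1+n2-2,
    two-sided p. A zero pooled variance with unequal means gives an
    infinite t (flagged via a warning) and p = 0.
    """
    s = TwoSampleSummary.from_samples(g1, g2)
    df = s.n1 + s.n2 - 2
    sp = s.pooled_sd
    diff = s.mean1 - s.mean2
    if sp == 0:
        if diff == 0:
            return {"t": 0.0, "df": df, "p": 1.0, "s_p": 0.0}
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return {"t": math.copysign(float("inf"), diff), "df": df, "p": 0.0,
                "s_p": 0.0}
    t = diff / (sp * math.sqrt(1.0 / s.n1 + 1.0 / s.n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(min(p, 1.0)), "s_p": sp}


def f_test_variances(g1, g2, alpha: float = 0.05) -> dict:
    """Two-sided F-test for equality of variances.

    F is the larger over the smaller sample variance; p doubles the upper
    tail (capped at 1). ``equal_variance`` is the decision at ``alpha``.
    """
    s = TwoSampleSummary.from_samples(g1, g2)
    if s.var1 <= 0 or s.var2 <= 0:
        raise ValueError("zero variance in a group")
    if s.var1 >= s.var2:
        f, d1, d2 = s.var1 / s.var2, s.n1 - 1, s.n2 - 1
    else:
        f, d1, d2 = s.var2 / s.var1, s.n2 - 1, s.n1 - 1
    p = min(1.0, 2.0 * stats.f.sf(f, d1, d2))
    return {"F": float(f), "df": (d1, d2), "p": float(p),
            "equal_variance": p >= alpha}


@dataclass
class RespirationResult:
    """Oxygen consumption rate and the window it was fitted on."""

    rate_per_mg: float
    slope: float
    window: tuple[int, int]  # [start, stop) indices of the fitted segment
    r_squared: float
    used_full_trace: bool = False


def respiration_rate(
    time_min,
    o2,
    protein_mg: float,
    min_window_frac: float = 0.5,
    r2_threshold: float = 0.99,
) -> RespirationResult:
    """Oxygen consumption rate from the straight portion of an O2 trace.

    Scans contiguous windows covering at least ``min_window_frac`` of the
    trace and picks the best-fitting one: highest R^2 above threshold,
    ties broken toward the longer (then earlier) window, so an exact line
    selects the full trace while an equilibration transient is excluded.
    If no window qualifies the whole trace is used with a warning. The
    rate is ``-slope / protein_mg``.
    """
    t = np.asarray(time_min, dtype=np.float64)
    y = np.asarray(o2, dtype=np.float64)
    if t.size < 10:
        raise ValueError("need at least 10 points")
    if protein_mg <= 0:
        raise ValueError("protein_mg must be positive")
    n = t.size
    min_len = max(10, int(math.ceil(min_window_frac * n)))

    # prefix sums make every window fit O(1)
    c = np.concatenate
    S1 = c(([0.0], np.cumsum(np.ones(n))))
    St = c(([0.0], np.cumsum(t)))
    Sy = c(([0.0], np.cumsum(y)))
    Stt = c(([0.0], np.cumsum(t * t)))
    Sty = c(([0.0], np.cumsum(t * y)))
    Syy = c(([0.0], np.cumsum(y * y)))

    def fit(a: int, b: int) -> tuple[float, float]:
        m = S1[b] - S1[a]
        st, sy = St[b] - St[a], Sy[b] - Sy[a]
        stt, sty, syy = Stt[b] - Stt[a], Sty[b] - Sty[a], Syy[b] - Syy[a]
        sxx = stt - st * st / m
        sxy = sty - st * sy / m
        syy_c = syy - sy * sy / m
        slope = sxy / sxx
        r2 = 1.0 if syy_c <= 0 else min(1.0, sxy * sxy / (sxx * syy_c))
        return slope, r2

    best = None  # key = (rounded r2, length, -start); value = (r2, a, b, slope)
    for length in range(min_len, n + 1):
        for a in range(0, n - length + 1):
            slope, r2 = fit(a, a + length)
            if r2 < r2_threshold:
                continue
            key = (round(r2, 10), length, -a)
            if best is None or key > best[0]:
                best = (key, (r2, a, a + length, slope))

    used_full = best is None
    if best is None:
        slope, r2 = fit(0, n)
        best = (None, (r2, 0, n, slope))
        warnings.warn("no window met the linearity threshold; using full trace",
                      stacklevel=2)
    r2, a, b, slope = best[1]
    if slope > 0:
        warnings.warn("oxygen concentration increases over the fitted window",
                      stacklevel=2)
    return RespirationResult(rate_per_mg=-slope / protein_mg, slope=float(slope),
                             window=(a, b), r_squared=float(r2),
                             used_full_trace=used_full)


def redox_ratio(area_reduced: float, area_oxidized: float) -> float:
    """Percent reduced quinone: 100 * reduced / (reduced + oxidized)."""
    if area_reduced < 0 or area_oxidized < 0:
        raise ValueError("peak areas must be non-negative")
    total = area_reduced + area_oxidized
    if total == 0:
        raise ValueError("both peak areas are zero")
    return 100.0 * area_reduced / total
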