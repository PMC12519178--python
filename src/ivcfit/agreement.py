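"""Agreement statistics for paired diameter measurements.

Implements Lin's concordance correlation coefficient (CCC) with its
asymptotic 95% confidence interval on the Fisher-z scale, Pearson
correlation, the three-level agreement taxonomy used in vessel-sizing
studies (poor / fair to good / excellent), a bootstrap comparison of two
dependent CCCs that share a common variable, a Steiger-style Fisher-z
test for the same comparison, and Student's t tests for mean differences.

Moment convention: the CCC uses n-denominator (maximum-likelihood)
variances and covariance, following Lin's original estimator,

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2),

so that CCC = r * C_b where C_b is the bias-correction factor penalising
location and scale shifts.  The confidence interval uses Lin's (1989,
with the later erratum) variance of z = atanh(CCC):

    var(z) = 1/(n-2) * [ (1-r^2) p^2 / ((1-p^2) r^2)
                         + 2 p^3 (1-p) u^2 / (r (1-p^2)^2)
                         - p^4 u^4 / (2 r^2 (1-p^2)^2) ]

with p the sample CCC, r the Pearson correlation and
u = (xbar - ybar) / sqrt(s_x s_y) the standardised location shift.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import ValidationError

__all__ = [
    "DegenerateStatisticError",
    "PairedSample",
    "AgreementResult",
    "CCCComparisonResult",
    "MeanDiffResult",
    "pearson_r",
    "lin_ccc",
    "ccc_confidence_interval",
    "classify_agreement",
    "compare_dependent_ccc",
    "fisher_z_ccc_test",
    "mean_diff_test",
]

logger = logging.getLogger(__name__)

#: CCC breakpoints of the agreement taxonomy; boundary values belong to
#: the lower class (0.40 -> poor, 0.75 -> fair to good).
POOR_MAX = 0.40
FAIR_GOOD_MAX = 0.75


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined for the given sample."""


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length measurement vectors (mm) from the same subjects."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValidationError("paired sample vectors must be one-dimensional")
        if len(x) != len(y):
            raise ValidationError(f"length mismatch: x has {len(x)}, y has {len(y)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("paired sample contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AgreementResult:
    """CCC with 95% CI, Pearson correlation and agreement class."""

    ccc: float
    ci_low: float
    ci_high: float
    pearson: float
    n: int
    agreement_class: str
    level: float = 0.95


@dataclass(frozen=True)
class CCCComparisonResult:
    """Difference of two dependent CCCs sharing a common variable.

    ``delta`` = CCC(candidate_a, common) - CCC(candidate_b, common); the CI
    is a percentile bootstrap over subject resamples and the p-value the
    two-sided sign-crossing fraction with add-one correction.  The
    Steiger-style Fisher-z statistic and p-value for the same contrast are
    carried alongside, labelled as such.
    """

    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    seed: int
    ccc_a: float
    ccc_b: float
    fisher_z: float
    fisher_z_p: float


@dataclass(frozen=True)
class MeanDiffResult:
    """Student's t test of two measurement vectors."""

    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    t_statistic: float
    df: float
    p_value: float
    paired: bool


def _as_sample(sample, y=None) -> PairedSample:
    if isinstance(sample, PairedSample):
        return sample
    if y is not None:
        return PairedSample(np.asarray(sample), np.asarray(y))
    return PairedSample(*sample)


def _ml_moments(x: np.ndarray, y: np.ndarray):
    """Means, n-denominator variances and covariance."""
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    return mx, my, float(dx @ dx) / len(x), float(dy @ dy) / len(y), float(dx @ dy) / len(x)


def pearson_r(sample: PairedSample, y=None) -> float:
    """Product-moment correlation of a paired sample."""
    s = _as_sample(sample, y)
    if s.n < 2:
        raise ValidationError("pearson_r requires n >= 2")
    for vec, name in ((s.x, "x"), (s.y, "y")):
        if np.all(vec == vec[0]):
            raise DegenerateStatisticError(f"correlation undefined: vector {name} has zero variance")
    return float(stats.pearsonr(s.x, s.y).statistic)


def lin_ccc(sample: PairedSample, y=None) -> float:
    """Lin's concordance correlation coefficient (n-denominator moments)."""
    s = _as_sample(sample, y)
    if s.n < 2:
        raise ValidationError("lin_ccc requires n >= 2")
    mx, my, sx2, sy2, sxy = _ml_moments(s.x, s.y)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DegenerateStatisticError(
            "CCC undefined: both vectors are constant with equal means (0/0)"
        )
    # roundoff can push near-perfect concordance an epsilon past +/-1
    return float(min(1.0, max(-1.0, 2.0 * sxy / denom)))


def classify_agreement(ccc: float) -> str:
    """Map a CCC to the poor / fair to good / excellent taxonomy.

    Boundary membership: CCC <= 0.40 is poor, 0.40 < CCC <= 0.75 fair to
    good, CCC > 0.75 excellent.
    """
    if not (-1.0 <= ccc <= 1.0):
        raise ValidationError(f"CCC must lie in [-1, 1], got {ccc!r}")
    if ccc <= POOR_MAX:
        return "poor"
    if ccc <= FAIR_GOOD_MAX:
        return "fair to good"
    return "excellent"


def ccc_confidence_interval(sample: PairedSample, y=None, level: float = 0.95) -> AgreementResult:
    """CCC with an asymptotic confidence interval on the Fisher-z scale.

    The variance of atanh(CCC) follows Lin's asymptotic formula (see
    module docstring); the back-transformed bounds always lie in (-1, 1).
    Requires n >= 3, positive variances in both vectors and |CCC| < 1; a
    sample with |CCC| = 1 exactly (e.g. identical vectors) has a
    degenerate interval and raises :class:`DegenerateStatisticError`.
    """
    s = _as_sample(sample, y)
    if s.n < 3:
        raise ValidationError("ccc_confidence_interval requires n >= 3")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level!r}")
    mx, my, sx2, sy2, sxy = _ml_moments(s.x, s.y)
    if np.all(s.x == s.x[0]) or np.all(s.y == s.y[0]):
        raise DegenerateStatisticError("CI undefined: a vector has zero variance")
    p = lin_ccc(s)
    r = pearson_r(s)
    if abs(p) >= 1.0 or abs(r) >= 1.0:
        raise DegenerateStatisticError(
            f"CI degenerate at |CCC| = 1 (CCC = {p:.6g}); report the point value instead"
        )
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location shift / sqrt(s_x * s_y)
    one_m_p2 = 1.0 - p * p
    var_z = (
        (1.0 - r * r) * p * p / (one_m_p2 * r * r)
        + 2.0 * p**3 * (1.0 - p) * u * u / (r * one_m_p2**2)
        - p**4 * u**4 / (2.0 * r * r * one_m_p2**2)
    ) / (s.n - 2)
    z = math.atanh(p)
    q = stats.norm.ppf(0.5 + level / 2.0)
    half = q * math.sqrt(max(var_z, 0.0))
    return AgreementResult(
        ccc=p,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        pearson=r,
        n=s.n,
        agreement_class=classify_agreement(p),
        level=level,
    )


def _ccc_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise CCC for matrices of bootstrap resamples (may return nan)."""
    mx = x.mean(axis=1, keepdims=True)
    my = y.mean(axis=1, keepdims=True)
    dx, dy = x - mx, y - my
    sx2 = (dx * dx).mean(axis=1)
    sy2 = (dy * dy).mean(axis=1)
    sxy = (dx * dy).mean(axis=1)
    denom = sx2 + sy2 + (mx[:, 0] - my[:, 0]) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, 2.0 * sxy / denom, np.nan)


def fisher_z_ccc_test(common, candidate_a, candidate_b) -> tuple[float, float]:
    """Steiger-style Fisher-z test of two dependent CCCs.

    Both CCCs are mapped through atanh and their difference standardised
    using Lin-type variances and the correlation between the two candidate
    vectors as the dependence correction (the two coefficients share
    ``common``).  Returns (z statistic, two-sided p).  This mirrors the
    classical z-transformation comparison of dependent correlations and is
    approximate; the bootstrap comparison is the principal method.
    """
    common = np.asarray(common, dtype=float)
    a = np.asarray(candidate_a, dtype=float)
    b = np.asarray(candidate_b, dtype=float)
    n = len(common)
    ccc_a = lin_ccc(PairedSample(a, common))
    ccc_b = lin_ccc(PairedSample(b, common))
    r_ab = pearson_r(PairedSample(a, b))
    if abs(ccc_a) >= 1.0 or abs(ccc_b) >= 1.0:
        raise DegenerateStatisticError(
            f"Fisher z undefined at |CCC| = 1 (CCC_a = {ccc_a:.6g}, CCC_b = {ccc_b:.6g})"
        )
    za, zb = math.atanh(ccc_a), math.atanh(ccc_b)
    # Olkin-style variance of the difference of two z-transformed dependent
    # coefficients: var = 2 (1 - r_ab) / (n - 3).
    var = 2.0 * (1.0 - r_ab) / max(n - 3, 1)
    if var <= 0:  # candidates perfectly correlated, e.g. a is b
        z_stat = 0.0 if za == zb else math.copysign(math.inf, za - zb)
        p = 1.0 if za == zb else 0.0
        return z_stat, p
    z_stat = (za - zb) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z_stat))
    return float(z_stat), float(min(max(p, np.finfo(float).tiny), 1.0))


def compare_dependent_ccc(
    common,
    candidate_a,
    candidate_b,
    n_boot: int = 2000,
    seed: Optional[int] = None,
    max_redraw: int = 100,
) -> CCCComparisonResult:
    """Bootstrap comparison of two CCCs sharing a common variable.

    Resamples subjects with replacement; each resample yields
    delta* = CCC(a*, common*) - CCC(b*, common*).  The 95% CI is the
    percentile interval of delta*, and the two-sided p-value the
    sign-crossing fraction with add-one correction,
    p = 2 * (min(#delta* <= 0, #delta* >= 0) + 1) / (n_boot + 1), capped
    at 1.  Degenerate resamples (zero total variance) are redrawn up to
    ``max_redraw`` consecutive times, then an error is raised.
    """
    common = np.asarray(common, dtype=float)
    a = np.asarray(candidate_a, dtype=float)
    b = np.asarray(candidate_b, dtype=float)
    n = len(common)
    if not (len(a) == len(b) == n):
        raise ValidationError("compare_dependent_ccc requires three equal-length vectors")
    if n < 5:
        raise ValidationError("compare_dependent_ccc requires n >= 5")
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    if seed is None:
        raise ValidationError("a seed is required for reproducible comparisons")

    ccc_a = lin_ccc(PairedSample(a, common))
    ccc_b = lin_ccc(PairedSample(b, common))
    delta = ccc_a - ccc_b

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    filled = 0
    redraws = 0
    while filled < n_boot:
        need = n_boot - filled
        idx = rng.integers(0, n, size=(need, n))
        d = _ccc_rows(a[idx], common[idx]) - _ccc_rows(b[idx], common[idx])
        ok = np.isfinite(d)
        kept = int(ok.sum())
        deltas[filled : filled + kept] = d[ok]
        filled += kept
        if kept < need:
            redraws += 1
            if redraws > max_redraw:
                raise DegenerateStatisticError(
                    "bootstrap exceeded redraw cap: resamples repeatedly degenerate "
                    "(zero variance); the input vectors are too close to constant"
                )

    ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
    n_le = int((deltas <= 0).sum())
    n_ge = int((deltas >= 0).sum())
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    try:
        z_stat, z_p = fisher_z_ccc_test(common, a, b)
    except DegenerateStatisticError as exc:
        logger.warning("Fisher-z comparison degenerate, reporting bootstrap only: %s", exc)
        z_stat, z_p = float("nan"), float("nan")
    return CCCComparisonResult(
        delta=delta,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        n_boot=n_boot,
        seed=seed,
        ccc_a=ccc_a,
        ccc_b=ccc_b,
        fisher_z=z_stat,
        fisher_z_p=z_p,
    )


_TTestLike = namedtuple("_TTestLike", ["statistic", "pvalue"])


def mean_diff_test(x, y, paired: bool = True) -> MeanDiffResult:
    """Student's t test of two measurement vectors.

    ``paired=True`` (default) treats the vectors as per-subject stages
    (pre/post or predicted/observed) and runs a paired t test;
    ``paired=False`` runs a pooled-variance two-sample Student's t for
    independent groups, which may have unequal lengths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise ValidationError(f"paired test requires equal lengths, got {len(x)} and {len(y)}")
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs n >= 2")
    if paired:
        diff = x - y
        df = len(x) - 1
        if np.var(diff, ddof=1) == 0:
            if diff[0] == 0:
                raise DegenerateStatisticError(
                    "paired t undefined: the two vectors are identical"
                )
            # constant nonzero shift: the t statistic diverges
            res = _TTestLike(math.copysign(math.inf, diff[0]), 0.0)
        else:
            res = stats.ttest_rel(x, y)
    else:
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            raise DegenerateStatisticError("two-sample t undefined: both groups are constant")
        res = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
    return MeanDiffResult(
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sd_x=float(x.std(ddof=1)),
        sd_y=float(y.std(ddof=1)),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        paired=paired,
    )
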