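"""Bivariate OLS fits and the Breusch-Pagan heteroscedasticity screen.

A single regression line describes one homogeneous cloud of points. When
latent subgroups with different slopes are pooled, the residuals of the
pooled fit often fan out along x, so a heteroscedasticity test is a cheap
first-pass warning marker for aggregation problems — though homoscedastic
residuals do not rule them out (equal-mean clusters with opposite slopes
pass the screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import DataError, InsufficientDataError

__all__ = [
    "BivariateSample",
    "RegressionFit",
    "HeteroscedasticityResult",
    "fit_ols",
    "breusch_pagan",
]


@dataclass(frozen=True)
class BivariateSample:
    """Paired (x, y) observations with optional labels and covariates.

    ``group`` carries a manifest categorical label (e.g. gender), ``subject``
    a per-observation unit identifier for repeated-measures data, and
    ``features`` an (n, d) block of external covariates used for clustering
    people independently of the (x, y) association under study.
    """

    x: np.ndarray
    y: np.ndarray
    group: np.ndarray | None = None
    subject: np.ndarray | None = None
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise DataError("x and y must be 1-d and equal length")
        if len(x) < 1:
            raise DataError("empty sample")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise DataError("non-finite values in x or y; drop them at ingestion")
        for name in ("group", "subject"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col)
                object.__setattr__(self, name, col)
                if col.shape != x.shape:
                    raise DataError(f"{name} length differs from x")
        if self.features is not None:
            f = np.asarray(self.features, dtype=float)
            if f.ndim == 1:
                f = f[:, None]
            object.__setattr__(self, "features", f)
            if f.shape[0] != len(x):
                raise DataError("features row count differs from x")
            if not np.isfinite(f).all():
                raise DataError("non-finite values in features")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) point matrix, the input to latent clustering."""
        return np.column_stack([self.x, self.y])

    def take(self, idx: np.ndarray) -> "BivariateSample":
        """Row subset preserving all attached columns."""
        return BivariateSample(
            x=self.x[idx],
            y=self.y[idx],
            group=None if self.group is None else self.group[idx],
            subject=None if self.subject is None else self.subject[idx],
            features=None if self.features is None else self.features[idx],
        )


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of y on x with an intercept."""

    intercept: float
    slope: float
    n: int
    slope_se: float
    r: float
    r_df: int
    p_slope: float
    residuals: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class HeteroscedasticityResult:
    statistic: float
    df: int
    p_value: float
    studentized: bool


def fit_ols(sample: BivariateSample) -> RegressionFit:
    """Closed-form least squares of y on x with an intercept.

    Requires n >= 3 (so the slope t-test has at least one residual degree
    of freedom) and non-constant x.
    """
    if sample.n < 3:
        raise InsufficientDataError(f"need n >= 3 observations, got {sample.n}")
    if np.ptp(sample.x) == 0:
        raise DataError("x is constant; slope undefined")
    res = stats.linregress(sample.x, sample.y)
    residuals = sample.y - (res.intercept + res.slope * sample.x)
    return RegressionFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n=sample.n,
        slope_se=float(res.stderr),
        r=float(res.rvalue),
        r_df=sample.n - 2,
        p_slope=float(res.pvalue),
        residuals=residuals,
    )


def breusch_pagan(
    fit: RegressionFit, sample: BivariateSample, studentized: bool = True
) -> HeteroscedasticityResult:
    """Breusch-Pagan test of residual homoscedasticity against x.

    Squared residuals are regressed on x; under homoscedasticity the LM
    statistic is chi-square with df = 1. ``studentized=True`` (default)
    uses the Koenker form n*R^2, robust to non-normal errors; ``False``
    uses the original normality-based scaling (auxiliary explained sum of
    squares over 2, residual variance estimated as SSR/n).
    """
    if fit.n != sample.n:
        raise DataError("fit and sample sizes differ; fit must come from this sample")
    if np.allclose(fit.residuals, 0.0):
        raise DataError("zero residual variance (perfect fit); test degenerate")
    exog = np.column_stack([np.ones(sample.n), sample.x])
    lm, lm_pvalue, _, _ = het_breuschpagan(fit.residuals, exog, robust=studentized)
    return HeteroscedasticityResult(
        statistic=float(lm), df=1, p_value=float(lm_pvalue), studentized=studentized
    )
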