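"""Gene-level bias diagnostics.

Two diagnostics are provided.  ``binned_medians`` sorts units by one
covariate, groups them into consecutive bins of fixed size (500 by
default), and summarises each bin by the median covariate and the median
log expression — the classic "bias plot".  A least-squares slope through
the bin medians gives a single trend statistic per covariate.

``platform_sample_bias_test`` asks whether such a trend is a technical
artefact: expression measured for the same genes on two platforms (e.g.
sequencing vs RT-PCR) and two biological samples is standardised within
each platform x sample group and regressed on the covariate together with
platform and sample indicators and their interactions with the covariate.
A platform-specific slope (significant covariate x platform interaction)
with no sample-specific slope indicates a technical, not biological, bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .models import COVARIATE_COLUMNS, BiasCovariateTable, ExpressionTable


@dataclass
class BinnedBias:
    covariate_name: str
    bin_median_x: np.ndarray
    bin_median_y: np.ndarray
    bin_size: int
    n_bins: int
    trend_slope: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate_name,
                "bin_index": np.arange(self.n_bins),
                "median_x": self.bin_median_x,
                "median_y": self.bin_median_y,
            }
        )


@dataclass
class PlatformBiasTest:
    covariate_name: str
    p_platform: float
    p_sample: float
    coefficients: pd.Series = field(repr=False, default=None)
    std_errors: pd.Series = field(repr=False, default=None)
    p_values: pd.Series = field(repr=False, default=None)


def binned_medians(
    covariate: np.ndarray,
    log_expr: np.ndarray,
    bin_size: int = 500,
    covariate_name: str = "covariate",
) -> BinnedBias:
    """Median log expression per bin of ``bin_size`` units sorted by covariate.

    The sort is stable, so ties keep input order; all bins except possibly
    the last hold exactly ``bin_size`` units.  The trend slope is the
    ordinary least-squares slope of bin median y on bin median x.
    """
    covariate = np.asarray(covariate, float)
    log_expr = np.asarray(log_expr, float)
    if covariate.shape != log_expr.shape:
        raise ValueError("covariate and log_expr must have equal length")
    n = len(covariate)
    if n < bin_size:
        warnings.warn(
            f"only {n} units for bin_size={bin_size}; returning a single bin"
        )
        bin_size = max(n, 1)
    order = np.argsort(covariate, kind="stable")
    edges = list(range(0, n, bin_size))
    med_x, med_y = [], []
    for lo in edges:
        idx = order[lo : lo + bin_size]
        med_x.append(np.median(covariate[idx]))
        med_y.append(np.median(log_expr[idx]))
    med_x, med_y = np.array(med_x), np.array(med_y)

    degenerate = np.ptp(covariate) == 0 or len(med_x) < 2 or np.ptp(med_x) == 0
    if degenerate:
        slope = np.nan
    else:
        slope = np.polyfit(med_x, med_y, 1)[0]
    return BinnedBias(
        covariate_name=covariate_name,
        bin_median_x=med_x,
        bin_median_y=med_y,
        bin_size=bin_size,
        n_bins=len(med_x),
        trend_slope=float(slope),
        degenerate=bool(degenerate),
    )


def bias_trend_report(
    cov: BiasCovariateTable,
    expr: ExpressionTable,
    bin_size: int = 500,
    sample: str | None = None,
) -> list[BinnedBias]:
    """One binned-median trend per covariate, on log expression.

    Zero-expression units are dropped before the log.  Degenerate
    (constant) covariates are flagged, not fatal.
    """
    shared = cov.table.index.intersection(expr.Y.index)
    col = expr.Y.columns[0] if sample is None else sample
    y = expr.Y.loc[shared, col]
    positive = y > 0
    if positive.sum() < 2:
        raise ValueError("fewer than 2 positive-expression units")
    log_y = np.log(y[positive]).to_numpy()
    X = cov.table.loc[shared[positive.to_numpy()]]
    return [
        binned_medians(X[c].to_numpy(), log_y, bin_size=bin_size, covariate_name=c)
        for c in COVARIATE_COLUMNS
    ]


def trend_report_frame(report: list[BinnedBias]) -> pd.DataFrame:
    return pd.concat([b.to_frame() for b in report], ignore_index=True)


def platform_sample_bias_test(long_table: pd.DataFrame) -> PlatformBiasTest:
    """Test platform- and sample-specificity of one covariate's bias trend.

    ``long_table`` must carry columns ``log_expr``, ``covariate_value``,
    ``platform`` (2 levels) and ``sample`` (2 levels).  Expression is
    rescaled to mean 0, sd 1 within each platform x sample group, then an
    OLS fit of rescaled expression on covariate, platform, sample and the
    covariate x platform / covariate x sample interactions is performed.
    ``p_platform`` / ``p_sample`` are the two-sided t-test p-values of the
    interaction coefficients.
    """
    df = long_table.copy()
    for col in ("log_expr", "covariate_value", "platform", "sample"):
        if col not in df.columns:
            raise ValueError(f"long_table lacks column {col!r}")
    for col in ("platform", "sample"):
        if df[col].nunique() < 2:
            raise ValueError(f"{col!r} needs >= 2 levels")
    if np.ptp(df["covariate_value"].to_numpy(float)) == 0:
        raise ValueError("constant covariate: model is rank deficient")

    def _scale(x: pd.Series) -> pd.Series:
        return (x - x.mean()) / x.std(ddof=1)

    df["expr_scaled"] = df.groupby(["platform", "sample"], observed=True)[
        "log_expr"
    ].transform(_scale)

    fit = smf.ols(
        "expr_scaled ~ covariate_value + C(platform) + C(sample)"
        " + covariate_value:C(platform) + covariate_value:C(sample)",
        data=df,
    ).fit()
    names = fit.params.index
    plat_term = [t for t in names if t.startswith("covariate_value:C(platform)")]
    samp_term = [t for t in names if t.startswith("covariate_value:C(sample)")]
    covariate_name = str(long_table.attrs.get("covariate_name", "covariate"))
    return PlatformBiasTest(
        covariate_name=covariate_name,
        p_platform=float(fit.pvalues[plat_term[0]]),
        p_sample=float(fit.pvalues[samp_term[0]]),
        coefficients=fit.params,
        std_errors=fit.bse,
        p_values=fit.pvalues,
    )
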