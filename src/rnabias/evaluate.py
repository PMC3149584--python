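"""Evaluation of the correction: cross-platform correlation and depth robustness.

Two procedures mirror how a gene-level correction is judged in practice.

* ``stratified_correlation`` compares sequencing expression (before and
  after correction) with an independent platform (e.g. RT-PCR), overall
  and within three equal-count strata of |log fold change| between
  corrected and uncorrected values — genes the correction moved most
  should improve most.
* ``depth_robustness`` adds sequencing lanes one at a time, re-runs the
  correction, and reports the fraction of genes whose before/after log
  fold change is already within +/-5% of its final (all-lanes) value,
  stratified by final expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correct import correct_expression
from .models import BiasCovariateTable, CountTable
from .quantify import merge_lanes, rpkm

EXPRESSION_STRATA = ("low", "medium", "high")


def relative_improvement(r_before: float, r_after: float) -> float:
    """Percent relative improvement 100*(r_after - r_before)/r_before.

    Reported values are conventionally rounded to one decimal by callers.
    """
    if r_before == 0:
        raise ValueError("relative improvement undefined for r_before = 0")
    return 100.0 * (r_after - r_before) / r_before


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class StratifiedComparison:
    table: pd.DataFrame  # stratum, interval, n, r_before, r_after, relative_improvement
    strata_assignment: pd.Series

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["relative_improvement"] = out["relative_improvement"].round(1)
        out.to_csv(path, sep="\t", index=False, float_format="%.4g")


def _equal_count_strata(values: pd.Series, n_strata: int = 3, labels=None):
    """Partition by ascending value with unit-id tie-break; sizes differ <= 1."""
    order = sorted(values.index, key=lambda u: (values[u], str(u)))
    n = len(order)
    base, extra = divmod(n, n_strata)
    sizes = [base + (1 if i < extra else 0) for i in range(n_strata)]
    labels = labels or list(range(n_strata))
    assignment = {}
    pos = 0
    for lab, size in zip(labels, sizes):
        for u in order[pos : pos + size]:
            assignment[u] = lab
        pos += size
    return pd.Series(assignment).reindex(values.index)


def stratified_correlation(
    uncorrected_log: pd.Series,
    corrected_log: pd.Series,
    reference: pd.Series,
    min_units: int = 30,
) -> StratifiedComparison:
    """Pearson r with a reference platform, within |log fold change| tertiles.

    The fold change is corrected minus uncorrected log expression; genes
    are split into three equal-count strata by |fold change| (ascending),
    plus an overall row.  Degenerate strata (zero variance in any
    correlate) are flagged with NaN correlations rather than failing.
    """
    idx = uncorrected_log.index.intersection(corrected_log.index).intersection(
        reference.index
    )
    if len(idx) < min_units:
        raise ValueError(f"need at least {min_units} shared units")
    unc, cor, ref = (s.loc[idx].astype(float) for s in (uncorrected_log, corrected_log, reference))
    abs_delta = (cor - unc).abs()
    assignment = _equal_count_strata(abs_delta, 3, labels=[1, 2, 3])

    rows = []
    for stratum in (1, 2, 3, "overall"):
        sel = idx if stratum == "overall" else idx[(assignment == stratum).to_numpy()]
        rb = pearson_r(ref.loc[sel], unc.loc[sel])
        ra = pearson_r(ref.loc[sel], cor.loc[sel])
        lo, hi = abs_delta.loc[sel].min(), abs_delta.loc[sel].max()
        ri = relative_improvement(rb, ra) if np.isfinite(rb) and rb != 0 else np.nan
        rows.append(
            {
                "stratum": stratum,
                "interval": f"({lo:.3g}, {hi:.3g}]",
                "n": len(sel),
                "r_before": rb,
                "r_after": ra,
                "relative_improvement": ri,
                "degenerate": not (np.isfinite(rb) and np.isfinite(ra)),
            }
        )
    return StratifiedComparison(table=pd.DataFrame(rows), strata_assignment=assignment)


@dataclass
class RobustnessCurve:
    table: pd.DataFrame  # k, stratum, fraction, n
    strata_assignment: pd.Series

    def fractions(self) -> pd.DataFrame:
        return self.table.pivot(index="k", columns="stratum", values="fraction")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def depth_robustness(
    lane_tables: list[CountTable],
    cov: BiasCovariateTable,
    tolerance: float = 0.05,
    threshold: float = 0.95,
    abs_floor: float = 1e-6,
    **correct_kwargs,
) -> RobustnessCurve:
    """Stability of the correction as sequencing lanes accumulate.

    For k = 1..L lanes the first k lanes are pooled, expression is
    recomputed and corrected, and the before/after log fold change per
    gene is compared with its final (all-lanes) value: a gene is stable at
    k when |lfc_k - lfc_final| <= tolerance*|lfc_final| (an absolute band
    of ``tolerance`` is used when |lfc_final| < ``abs_floor``).  Genes are
    stratified into tertiles of final corrected log expression.  Only
    genes with positive counts in the first lane (hence fitted at every k)
    enter the curve.
    """
    from .models import BiasCovariateTable

    L = len(lane_tables)
    if L < 2:
        warnings.warn("single lane: robustness curve is trivial")
    lengths = cov.lengths()

    # one gene universe for the whole curve: genes already detected in the
    # first lane stay positive in every cumulative merge, so the same model
    # is fit at every depth and fold changes are comparable across k
    lane1 = lane_tables[0].counts.iloc[:, 0]
    common = cov.table.index.intersection(lane1.index[lane1 > 0])
    cov_common = BiasCovariateTable(cov.table.loc[common], cov.unit_kind)

    # smoothing penalties are selected once, on the full-depth data, and
    # held fixed for the partial-depth corrections: the curve then measures
    # how the correction estimate converges with sequencing depth, not how
    # the penalty optimiser's choices wander between overlapping datasets
    merged_all = merge_lanes(lane_tables, L)
    expr_all = rpkm(merged_all, lengths)
    final_corr = correct_expression(
        expr_all, cov_common, threshold=threshold, term_tests=False,
        **correct_kwargs,
    )
    final_alphas = np.array(
        [t.alpha for t in final_corr.fit.terms if not t.linear]
    )

    lfc = {L: (final_corr.corrected_log - final_corr.raw_log).dropna()}
    for k in range(1, L):
        merged = merge_lanes(lane_tables, k)
        expr = rpkm(merged, lengths)
        corr = correct_expression(
            expr, cov_common, threshold=threshold, alphas=final_alphas,
            term_tests=False, **correct_kwargs,
        )
        lfc[k] = (corr.corrected_log - corr.raw_log).dropna()
    for k in range(1, L + 1):
        common = common.intersection(lfc[k].index)
    final = lfc[L].loc[common]
    strata = _equal_count_strata(
        final_corr.corrected_log.loc[common], 3, labels=list(EXPRESSION_STRATA)
    )

    rows = []
    for k in range(1, L + 1):
        diff = (lfc[k].loc[common] - final).abs()
        band = np.where(final.abs() < abs_floor, tolerance, tolerance * final.abs())
        stable = pd.Series(diff.to_numpy() <= band, index=common)
        for stratum in EXPRESSION_STRATA:
            sel = strata == stratum
            rows.append(
                {
                    "k": k,
                    "stratum": stratum,
                    "fraction": float(stable[sel].mean()),
                    "n": int(sel.sum()),
                }
            )
    return RobustnessCurve(table=pd.DataFrame(rows), strata_assignment=strata)
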