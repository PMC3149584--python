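"""PCA + generalized-additive-model correction of gene-level biases.

The correction models log expression as an additive function of the 18
sequence covariates.  Because the 17 composition covariates (GC and the 16
dinucleotide frequencies) are strongly collinear, they are first reduced
by correlation-matrix PCA, keeping the smallest number K of components
whose cumulative variance share reaches 95%.  Log expression is then fit
as

    log(Y_i) = alpha + s(log L_i) + s(P_i1) + ... + s(P_iK) + eps_i

with penalized cubic B-spline smooths s(.) whose penalties are selected
by generalized cross-validation (GCV).  The corrected expression replaces
every fitted systematic contribution by the grand mean of log Y:

    corrected_log_i = mean(log Y) + eps_i

so the corrected values keep the observed mean but none of the modelled
covariate trends.  Units with zero expression cannot enter the log-scale
fit; they are passed through unchanged and flagged.

The additive fit is a direct penalized least-squares solve: for Gaussian
errors the GAM normal equations are (X'X + S) b = X'y with S the
block-diagonal spline roughness penalty, so the fit, its effective degrees
of freedom and the GCV score are all available in closed form.  Penalty
weights are optimised by deterministic per-term grid search with
coordinate descent, making the whole fit reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.gam.smooth_basis import BSplines

from .models import BiasCovariateTable, ExpressionTable

# ---------------------------------------------------------------------------
# principal components of the 17 composition covariates


@dataclass
class PCABasis:
    column_names: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    loadings: np.ndarray  # columns = components, orthonormal
    variance_share: np.ndarray
    K: int
    dropped_columns: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.column_means) / self.column_sds
        return Z @ self.loadings[:, : self.K]


@dataclass
class PCScores:
    unit_ids: list
    P: np.ndarray  # n x K


def select_component_count(variance_share, threshold: float = 0.95) -> int:
    """Smallest K whose cumulative variance share reaches ``threshold``.

    Ties at exactly the threshold count as reached (>= rule).
    """
    share = np.asarray(variance_share, float)
    K = int(np.searchsorted(np.cumsum(share), threshold - 1e-12) + 1)
    return min(K, len(share))


def principal_components(
    X_minus1: np.ndarray,
    threshold: float = 0.95,
    unit_ids=None,
    column_names=None,
) -> tuple[PCABasis, PCScores]:
    """Correlation-matrix PCA with the cumulative-variance K rule.

    Columns are centered and scaled to unit variance; K is the smallest
    component count whose cumulative variance share is >= ``threshold``.
    Sign convention: each component's largest-magnitude loading is
    positive, so results are reproducible across platforms.
    Constant columns are dropped with a warning.
    """
    X = np.asarray(X_minus1, float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows for PCA")
    if column_names is None:
        column_names = [f"x{j}" for j in range(m)]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [c for c, k in zip(column_names, keep) if not k]
    if not keep.any():
        raise ValueError("all columns constant: PCA undefined")
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant columns: {dropped}")
    X, means, sds = X[:, keep], means[keep], sds[keep]
    names = [c for c, k in zip(column_names, keep) if k]

    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    share = eigval / eigval.sum()
    K = select_component_count(share, threshold)

    basis = PCABasis(
        column_names=names,
        column_means=means,
        column_sds=sds,
        loadings=eigvec,
        variance_share=share,
        K=K,
        dropped_columns=dropped,
    )
    scores = PCScores(
        unit_ids=list(unit_ids) if unit_ids is not None else list(range(n)),
        P=Z @ eigvec[:, :K],
    )
    return basis, scores


# ---------------------------------------------------------------------------
# penalized additive fit


@dataclass
class SmoothTerm:
    name: str
    basis: np.ndarray = field(repr=False)
    penalty: np.ndarray = field(repr=False)
    alpha: float
    coef: np.ndarray = field(repr=False)
    edf: float
    contribution: np.ndarray = field(repr=False)
    linear: bool = False


@dataclass
class GAMFit:
    intercept: float
    terms: list[SmoothTerm]
    fitted: np.ndarray
    residuals: np.ndarray
    grand_mean: float
    edf_total: float
    gcv: float
    term_stats: pd.DataFrame  # term, edf, F, p
    unit_ids: list | None = None


def _spline_blocks(x_columns: list[np.ndarray], names: list[str], df: int, degree: int):
    mat = np.column_stack(x_columns)
    bs = BSplines(mat, df=[df] * mat.shape[1], degree=[degree] * mat.shape[1])
    blocks = []
    for j, name in enumerate(names):
        B = bs.smoothers[j].basis
        S = bs.smoothers[j].cov_der2
        blocks.append((name, B, S))
    return blocks


def _assemble(blocks, n, length_linear_col=None):
    """Design matrix [1 | (linear length) | spline blocks] and penalty list."""
    cols = [np.ones((n, 1))]
    slices, penalties = [], []
    start = 1
    if length_linear_col is not None:
        cols.append(length_linear_col.reshape(-1, 1))
        start += 1
    for _, B, S in blocks:
        cols.append(B)
        slices.append(slice(start, start + B.shape[1]))
        penalties.append(S)
        start += B.shape[1]
    return np.hstack(cols), slices, penalties


def _penalized_solve(X, y, slices, penalties, alphas, cache=None):
    """Solve (X'X + S)b = X'y; returns (beta, edf, rss).

    ``cache`` may carry precomputed (XtX, Xty, yty) so the GCV grid search
    does not recompute the cross-products.
    """
    if cache is None:
        cache = (X.T @ X, X.T @ y, float(y @ y))
    XtX, Xty, yty = cache
    A = XtX.copy()
    for sl, S, a in zip(slices, penalties, alphas):
        A[sl, sl] += a * S
    cf = linalg.cho_factor(A, lower=True)
    beta = linalg.cho_solve(cf, Xty)
    # edf = tr[(X'X + S)^-1 X'X]
    edf = float(np.trace(linalg.cho_solve(cf, XtX)))
    rss = float(yty - 2 * beta @ Xty + beta @ (XtX @ beta))
    return beta, max(edf, 0.0), max(rss, 0.0)


#: inflation on model degrees of freedom in the GCV score; plain GCV is known
#: to undersmooth, and 1.4 is the standard remedy (Wood's recommendation)
GCV_GAMMA = 1.4


def _gcv(n, rss, edf, gamma: float = GCV_GAMMA):
    denom = max(n - gamma * edf, 1e-8)
    return n * rss / denom**2


_ALPHA_GRID = 10.0 ** np.arange(-4.0, 8.5, 0.5)


#: parsimony window for penalty selection: among penalties whose GCV lies
#: within this relative margin of the minimum, the smoothest is preferred
#: (the glmnet lambda.1se idea).  GCV profiles are often nearly flat
#: between a wiggly and a smooth fit; taking the literal argmin would let
#: the fitted surface flip between near-tied basins on small perturbations.
GCV_PARSIMONY = 0.005


def _select_alphas(X, y, slices, penalties, n_sweeps: int = 2) -> np.ndarray:
    """Per-term GCV penalty selection: grid coordinate descent with a
    smoothest-within-window parsimony rule, then continuous within-basin
    refinement.  Fully deterministic given the data."""
    from scipy.optimize import minimize_scalar

    n = len(y)
    cache = (X.T @ X, X.T @ y, float(y @ y))
    alphas = np.ones(len(slices))

    def score_with(j, a):
        trial = alphas.copy()
        trial[j] = a
        _, edf, rss = _penalized_solve(X, y, slices, penalties, trial, cache=cache)
        return _gcv(n, rss, edf)

    for _ in range(n_sweeps):
        for j in range(len(slices)):
            scores = np.array([score_with(j, a) for a in _ALPHA_GRID])
            cutoff = scores.min() * (1 + GCV_PARSIMONY)
            alphas[j] = _ALPHA_GRID[np.nonzero(scores <= cutoff)[0][-1]]
    # continuous refinement inside the chosen basin so the penalty (hence
    # the fitted surface) varies smoothly with the data between grid points
    for j in range(len(slices)):
        lg = np.log10(alphas[j])
        res = minimize_scalar(
            lambda la, j=j: score_with(j, 10.0**la),
            bounds=(lg - 0.5, lg + 0.5),
            method="bounded",
            options={"xatol": 1e-3},
        )
        if res.fun <= score_with(j, alphas[j]):
            alphas[j] = 10.0**res.x
    return alphas


#: effective degrees of freedom of the fixed reference smoother used in the
#: per-term F-tests (the classical fixed-df additive-model test; 4 is the
#: traditional default smoother size)
TEST_EDF = 4.0


def _alpha_for_edf(S, target_edf, other_cache):
    """Penalty weight giving a single smooth term ~``target_edf`` effective
    parameters when added to an already-assembled model; bisection on
    log10(alpha) against the marginal edf of the term's block."""
    XtX, slices, penalties, alphas = other_cache

    def term_edf(log_a):
        A = XtX.copy()
        for sl, Sj, aj in zip(slices[:-1], penalties[:-1], alphas):
            A[sl, sl] += aj * Sj
        sl = slices[-1]
        A[sl, sl] += 10.0**log_a * S
        H = linalg.solve(A, XtX, assume_a="pos")
        return float(np.trace(H[sl, sl]))

    lo, hi = -6.0, 10.0
    if term_edf(lo) < target_edf:
        return 10.0**lo
    if term_edf(hi) > target_edf:
        return 10.0**hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if term_edf(mid) > target_edf:
            lo = mid
        else:
            hi = mid
    return 10.0 ** (0.5 * (lo + hi))


def _q_matrix(W, col_idx, slices, penalties, alphas):
    """Q = P W for the sub-model using ``col_idx`` columns of the full
    design, where the sub-model's hat matrix is H = X_sub G X_sub' and
    P embeds G into full coordinates.  Traces of any product of hat
    matrices equal traces of the same product of their Q matrices, so all
    moment computations stay p x p."""
    p = W.shape[0]
    Wrr = W[np.ix_(col_idx, col_idx)]
    A = Wrr.copy()
    for sl, S, a in zip(slices, penalties, alphas):
        A[sl, sl] += a * S
    G = linalg.inv(A)
    P = np.zeros((p, p))
    P[np.ix_(col_idx, col_idx)] = G
    return P @ W


def _sub_rss(X, y, col_idx, slices, penalties, alphas):
    Xs = X[:, col_idx]
    A = Xs.T @ Xs
    for sl, S, a in zip(slices, penalties, alphas):
        A[sl, sl] += a * S
    beta = linalg.solve(A, Xs.T @ y, assume_a="pos")
    resid = y - Xs @ beta
    return float(resid @ resid)


def _term_f_tests(y, blocks, smooth_names, length_col, length_linear, n):
    """Fixed-df F-test per term with two-moment (Satterthwaite) reference.

    Hypothesis testing is decoupled from the GCV-selected correction fit:
    every smooth enters the test models with a fixed ~``TEST_EDF``-edf
    reference smoother (penalty found by bisection against its marginal
    edf), so no data-driven smoothness selection leaks into the test.
    Because penalized smoothers are shrinkers rather than projections, the
    RSS difference is a weighted chi-square mixture; its first two moments
    are matched to a scaled chi-square (via traces of hat-matrix
    polynomials, computed in p x p space) to give a calibrated F
    reference.  The denominator degrees of freedom are moment-matched the
    same way.
    """
    # fixed-df penalty per smooth, calibrated marginally (intercept + term)
    fixed_alphas = []
    for name, B, S in blocks:
        X1, sl1, pen1 = _assemble([(name, B, S)], n)
        fixed_alphas.append(
            _alpha_for_edf(S, TEST_EDF, (X1.T @ X1, sl1, pen1, []))
        )
    fixed_alphas = np.array(fixed_alphas)

    full_X, full_sl, full_pen = _assemble(blocks, n, length_linear_col=length_col)
    p_full = full_X.shape[1]
    W = full_X.T @ full_X
    all_cols = np.arange(p_full)
    Qf = _q_matrix(W, all_cols, full_sl, full_pen, fixed_alphas)
    rss_full = _sub_rss(full_X, y, all_cols, full_sl, full_pen, fixed_alphas)

    # denominator: rss_full / sigma^2 is a weighted chi-square mixture with
    # mean tr(Dd) and variance 2 tr(Dd^2), Dd = (I - H)'(I - H)
    tr = lambda m: float(np.trace(m))
    Qf2 = Qf @ Qf
    tr_dd = n - 2 * tr(Qf) + tr(Qf2)
    tr_dd2 = n - 4 * tr(Qf) + 6 * tr(Qf2) - 4 * tr(Qf2 @ Qf) + tr(Qf2 @ Qf2)
    df_den = max(tr_dd**2 / max(tr_dd2, 1e-12), 1.0)
    sigma2 = rss_full / tr_dd if tr_dd > 0 else 0.0

    rows = []
    all_names = (["log_length"] if length_linear else []) + smooth_names
    for name in all_names:
        if length_linear and name == "log_length":
            col_idx = np.array([0] + list(range(2, p_full)))
            red_sl = [slice(s.start - 1, s.stop - 1) for s in full_sl]
            red_pen, red_alphas = full_pen, fixed_alphas
        else:
            j = smooth_names.index(name)
            drop = full_sl[j]
            col_idx = np.array(
                [c for c in range(p_full) if not (drop.start <= c < drop.stop)]
            )
            width = drop.stop - drop.start
            red_sl = [
                s if s.stop <= drop.start else slice(s.start - width, s.stop - width)
                for i, s in enumerate(full_sl)
                if i != j
            ]
            red_pen = [pen for i, pen in enumerate(full_pen) if i != j]
            red_alphas = np.delete(fixed_alphas, j)
        Qr = _q_matrix(W, col_idx, red_sl, red_pen, red_alphas)
        rss_red = _sub_rss(full_X, y, col_idx, red_sl, red_pen, red_alphas)

        # numerator: Delta rss / sigma^2 has mean tr(E) and variance
        # 2 tr(E^2) with E = 2(Qf - Qr) - (Qf^2 - Qr^2) in Q space
        E = 2 * (Qf - Qr) - (Qf2 - Qr @ Qr)
        tr_e = tr(E)
        tr_e2 = float(np.sum(E * E.T))
        df_num = max(tr_e**2 / max(tr_e2, 1e-12), 1.0)
        scale = tr_e / df_num if df_num > 0 else 1.0

        if sigma2 <= 0:  # perfect fit (e.g. constant response)
            F = 0.0 if rss_red - rss_full <= 1e-12 else np.inf
        else:
            F = max(rss_red - rss_full, 0.0) / max(scale * df_num, 1e-12) / sigma2
        p = float(stats.f.sf(F, df_num, df_den))
        rows.append({"term": name, "edf": tr_e, "F": float(F), "p": p})
    return rows


def fit_bias_gam(
    log_expr: np.ndarray,
    log_length: np.ndarray,
    scores: PCScores,
    n_splines: int = 10,
    length_linear: bool = False,
    unit_ids=None,
    alphas: np.ndarray | None = None,
    term_tests: bool = True,
) -> GAMFit:
    """Penalized additive fit of log expression on log length and PC scores.

    Each predictor gets a univariate cubic B-spline smooth (about
    ``n_splines`` basis functions) with a second-derivative roughness
    penalty; penalty weights are selected by GCV.  With ``length_linear``
    the length term is a single unpenalized linear coefficient, matching
    the bare linear length term of the classical formula.  Per-term
    significance comes from fixed-df F-tests with a two-moment-matched
    reference distribution (see ``_term_f_tests``), decoupled from the
    GCV-selected estimation fit.
    """
    y = np.asarray(log_expr, float)
    log_length = np.asarray(log_length, float)
    if not (np.isfinite(y).all() and np.isfinite(log_length).all()):
        raise ValueError("non-finite inputs; exclude zero-expression units first")
    n = len(y)
    P = scores.P
    K = P.shape[1] if P.size else 0
    if K == 0:
        warnings.warn("no PC scores supplied: fitting length term only")

    smooth_cols, smooth_names = [], []
    length_col = None
    if length_linear:
        length_col = log_length - log_length.mean()
    else:
        smooth_cols.append(log_length)
        smooth_names.append("log_length")
    for j in range(K):
        smooth_cols.append(P[:, j])
        smooth_names.append(f"PC{j + 1}")

    blocks = _spline_blocks(smooth_cols, smooth_names, df=n_splines, degree=3) if smooth_cols else []
    X, slices, penalties = _assemble(blocks, n, length_linear_col=length_col)
    if not smooth_cols:
        alphas = np.array([])
    elif alphas is None:
        alphas = _select_alphas(X, y, slices, penalties)
    else:
        alphas = np.asarray(alphas, float)
        if len(alphas) != len(slices):
            raise ValueError(
                f"got {len(alphas)} penalty weights for {len(slices)} smooth terms"
            )
    beta, edf, rss = _penalized_solve(X, y, slices, penalties, alphas)
    fitted = X @ beta
    residuals = y - fitted
    gcv = _gcv(n, rss, edf)

    if term_tests:
        term_rows = _term_f_tests(
            y, blocks, smooth_names, length_col, length_linear, n
        )
    else:
        term_rows = []
    terms: list[SmoothTerm] = []

    offset = 1 + (1 if length_linear else 0)
    if length_linear:
        terms.append(
            SmoothTerm(
                name="log_length",
                basis=length_col.reshape(-1, 1),
                penalty=np.zeros((1, 1)),
                alpha=0.0,
                coef=beta[1:2],
                edf=1.0,
                contribution=length_col * beta[1],
                linear=True,
            )
        )
    for (name, B, S), sl, a in zip(blocks, slices, alphas):
        coef = beta[sl]
        terms.append(
            SmoothTerm(
                name=name,
                basis=B,
                penalty=S,
                alpha=float(a),
                coef=coef,
                edf=np.nan,
                contribution=B @ coef,
            )
        )

    return GAMFit(
        intercept=float(beta[0]),
        terms=terms,
        fitted=fitted,
        residuals=residuals,
        grand_mean=float(y.mean()),
        edf_total=edf,
        gcv=float(gcv),
        term_stats=pd.DataFrame(term_rows),
        unit_ids=list(unit_ids) if unit_ids is not None else None,
    )


def term_significance(fit: GAMFit) -> pd.DataFrame:
    """Per-term table {term, edf, F, p}, in model order (length, PC1..PCK)."""
    return fit.term_stats.copy()


# ---------------------------------------------------------------------------
# the full correction pipeline


@dataclass
class CorrectedExpression:
    unit_ids: list
    raw_log: pd.Series
    corrected_log: pd.Series
    corrected_linear: pd.Series
    excluded_ids: list
    fit: GAMFit = field(repr=False, default=None)
    pca: PCABasis = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "raw_log": self.raw_log,
                "corrected_log": self.corrected_log,
                "corrected_linear": self.corrected_linear,
            }
        )
        df["excluded_flag"] = [int(u in set(self.excluded_ids)) for u in df.index]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="unit_id", float_format="%.10g")


def correct_expression(
    expr: ExpressionTable,
    cov: BiasCovariateTable,
    threshold: float = 0.95,
    sample: str | None = None,
    length_linear: bool = False,
    n_splines: int = 10,
    min_positive: int = 100,
    alphas: np.ndarray | None = None,
    term_tests: bool = True,
) -> CorrectedExpression:
    """Remove modelled length/composition trends from one sample's expression.

    Pipeline: drop zero-expression units -> natural log -> correlation PCA
    of the 17 composition covariates (K by the ``threshold`` variance
    rule) -> penalized additive fit -> corrected log expression =
    grand mean of log Y + residual.  Excluded (zero) units pass through
    unchanged and are flagged.
    """
    shared = cov.table.index.intersection(expr.Y.index)
    col = expr.Y.columns[0] if sample is None else sample
    y = expr.Y.loc[shared, col].astype(float)
    positive = y > 0
    n_pos = int(positive.sum())
    if n_pos < min_positive:
        raise ValueError(
            f"only {n_pos} units with positive expression (< {min_positive});"
            " cannot fit the correction model"
        )
    fit_ids = shared[positive.to_numpy()]
    log_y = np.log(y[positive])
    X = cov.table.loc[fit_ids]
    comp_cols = [c for c in cov.table.columns if c != "log_length"]
    basis, scores = principal_components(
        X[comp_cols].to_numpy(float),
        threshold=threshold,
        unit_ids=fit_ids,
        column_names=comp_cols,
    )
    fit = fit_bias_gam(
        log_y.to_numpy(),
        X["log_length"].to_numpy(),
        scores,
        n_splines=n_splines,
        length_linear=length_linear,
        unit_ids=fit_ids,
        alphas=alphas,
        term_tests=term_tests,
    )
    corrected_log = pd.Series(fit.grand_mean + fit.residuals, index=fit_ids)
    excluded = [u for u in shared if u not in set(fit_ids)]
    raw_log = pd.Series(np.nan, index=shared)
    raw_log.loc[fit_ids] = log_y
    corr_full = pd.Series(np.nan, index=shared)
    corr_full.loc[fit_ids] = corrected_log
    corr_lin = pd.Series(y, index=shared, dtype=float)  # excluded pass through
    corr_lin.loc[fit_ids] = np.exp(corrected_log)
    return CorrectedExpression(
        unit_ids=list(shared),
        raw_log=raw_log,
        corrected_log=corr_full,
        corrected_linear=corr_lin,
        excluded_ids=excluded,
        fit=fit,
        pca=basis,
    )
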