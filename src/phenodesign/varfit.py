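"""Mixed-model machinery: constrained REML, GLS treatment predictions,
pairwise-difference variances, error degrees of freedom and boundary-adjusted
REML likelihood-ratio tests.

The model is y ~ N(X beta, V) with V = sigma2_e (I + sum_k gamma_k Z_k Z_k'),
gamma_k = sigma2_k / sigma2_e >= 0 the variance ratio of random term k.
The REML log-likelihood is profiled over beta and sigma2_e and maximized over
the gamma by bound-constrained quasi-Newton iteration, so boundary zeros are
exact.  For balanced orthogonal structures the closed-form ANOVA
(method-of-moments) solution is also evaluated and kept whenever it attains
the better restricted likelihood -- on balanced data it is the exact REML
optimum, so the two estimators coincide to machine precision.

Treatment models use one-hot treatment coding (the treatment block of the
GLS covariance is then directly the prediction-variance matrix) and recover
inter-block information through the random block terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .designs import BlockFactors, Design
from .field import UniformityData

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge."""


class InestimabilityError(ValueError):
    """The requested fixed-effect structure is not estimable."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

TREND_CHOICES = (None, "global", "block_equal", "block_unequal")
RANDOM_CHOICES = ("replicate", "block", "row", "column")


@dataclass(frozen=True)
class VarianceModel:
    """Fixed and random structure of a treatment analysis.

    trend: None, 'global' (one linear position-trend column, centered on the
    layout), 'block_equal' (per-block centered scores, one shared slope) or
    'block_unequal' (a separate slope per block; needs >= 2 blocks).
    random_terms: any of 'replicate', 'block', 'row', 'column' ('row' and
    'column' are nested in replicates).  fixed_blocks puts block effects in
    the fixed part instead (the classical RCBD analysis).
    """

    trend: str | None = None
    random_terms: tuple[str, ...] = ()
    fixed_blocks: bool = False

    def __post_init__(self) -> None:
        if self.trend not in TREND_CHOICES:
            raise ValueError(f"trend must be one of {TREND_CHOICES}")
        bad = set(self.random_terms) - set(RANDOM_CHOICES)
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")
        if self.fixed_blocks and "block" in self.random_terms:
            raise ValueError("blocks cannot be both fixed and random")


def _dummies(levels: np.ndarray) -> np.ndarray:
    """Full one-hot matrix for a 1-based (or arbitrary-coded) factor."""
    uniq, inv = np.unique(levels, return_inverse=True)
    Z = np.zeros((levels.size, uniq.size))
    Z[np.arange(levels.size), inv] = 1.0
    return Z


def _nested_levels(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    return outer.astype(int) * (inner.max() + 1) + inner.astype(int)


def _trend_columns(design: Design, trend: str | None) -> np.ndarray | None:
    lay = design.layout
    if trend is None:
        return None
    if trend == "global":
        return lay.centered_positions().ravel()[:, None]
    if design.block is None:
        raise InestimabilityError("per-block trend slopes require a block structure")
    blocks = design.block.ravel()
    pos = lay.positions.astype(float).ravel()
    centered = pos.copy()
    for b in np.unique(blocks):
        centered[blocks == b] -= pos[blocks == b].mean()
    if trend == "block_equal":
        return centered[:, None]
    # block_unequal: one column per block
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise InestimabilityError("unequal per-block slopes require at least 2 blocks")
    cols = np.zeros((pos.size, uniq.size))
    for j, b in enumerate(uniq):
        cols[blocks == b, j] = centered[blocks == b]
    return cols


def build_matrices(
    data: UniformityData, design: Design, model: VarianceModel
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], list[str]]:
    """Response vector, fixed design matrix and random-term matrices.

    X holds the v one-hot treatment columns first, then fixed block dummies
    (reference coded) and trend columns.
    """
    if data.layout.n_cells != design.layout.n_cells:
        raise ValueError("data and design layouts differ")
    y = data.values.ravel()
    X_parts = [_dummies(design.treatment.ravel())]
    if model.fixed_blocks:
        if design.block is None:
            raise InestimabilityError("fixed_blocks requested but design has no blocks")
        X_parts.append(_dummies(design.block.ravel())[:, 1:])
    tr = _trend_columns(design, model.trend)
    if tr is not None:
        X_parts.append(tr)
    X = np.column_stack(X_parts)
    Zs, names = [], []
    for term in model.random_terms:
        fac = getattr(design, term if term != "replicate" else "replicate")
        if fac is None:
            raise InestimabilityError(f"design has no '{term}' factor")
        levels = fac.ravel()
        if term in ("row", "column") and design.replicate is not None:
            levels = _nested_levels(design.replicate.ravel(), levels)
        Zs.append(_dummies(levels))
        names.append(term)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InestimabilityError("fixed-effect structure is rank deficient")
    return y, X, Zs, names


# ---------------------------------------------------------------------------
# profiled REML engine
# ---------------------------------------------------------------------------


def _profile_negll(gamma: np.ndarray, y, X, ZZts):
    """Negative profiled REML log-likelihood and the profiled estimates."""
    n, p = X.shape
    H = np.eye(n)
    for g, ZZt in zip(gamma, ZZts):
        H += g * ZZt
    try:
        c = cho_factor(H, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover - H is PD by construction
        return np.inf, None
    Hi_y = cho_solve(c, y)
    Hi_X = cho_solve(c, X)
    XtHiX = X.T @ Hi_X
    try:
        cx = cho_factor(XtHiX, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = cho_solve(cx, X.T @ Hi_y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(c, resid))
    if quad <= 0:
        quad = np.finfo(float).tiny
    s2 = quad / (n - p)
    logdet_H = 2.0 * np.sum(np.log(np.diag(c[0])))
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    ll = -0.5 * ((n - p) * (_LOG2PI + np.log(s2) + 1.0) + logdet_H + logdet_X)
    cov_beta = s2 * cho_solve(cx, np.eye(p))
    return -ll, (beta, s2, cov_beta)


def _anova_candidate(y: np.ndarray, X: np.ndarray, Zs: Sequence[np.ndarray]):
    """Closed-form balanced-ANOVA variance components, as gamma candidates.

    Terms are swept coarse-to-fine in the given order after the fixed part;
    expected-mean-square coefficients are computed from the projections, so
    the construction is valid for any structure while being the exact REML
    solution only on balanced orthogonal data (where it is then preferred by
    likelihood).  Returns None when the system is unworkable.
    """
    n = y.size
    k = len(Zs)
    if k == 0:
        return None
    order = np.argsort([-Z.shape[1] for Z in Zs])[::-1]  # coarse (few levels) first
    basis = X
    P_prev = basis @ np.linalg.pinv(basis)
    df = np.zeros(k + 1)
    ms = np.zeros(k + 1)
    coef = np.zeros((k + 1, k))
    rank_prev = np.linalg.matrix_rank(basis)
    proj_list = []
    for idx in order:
        basis = np.column_stack([basis, Zs[idx]])
        P_cur = basis @ np.linalg.pinv(basis)
        rank_cur = np.linalg.matrix_rank(basis)
        P_term = P_cur - P_prev
        d = rank_cur - rank_prev
        if d <= 0:
            return None
        proj_list.append((idx, P_term, d))
        P_prev, rank_prev = P_cur, rank_cur
    P_resid = np.eye(n) - P_prev
    d_resid = n - rank_prev
    if d_resid <= 0:
        return None
    for row, (idx, P_term, d) in enumerate(proj_list):
        df[row] = d
        ms[row] = float(y @ P_term @ y) / d
        for col in range(k):
            coef[row, col] = float(np.trace(Zs[col].T @ P_term @ Zs[col])) / d
    df[k] = d_resid
    ms[k] = float(y @ P_resid @ y) / d_resid
    A = np.column_stack([coef, np.ones(k + 1)])
    sol, *_ = np.linalg.lstsq(A, ms, rcond=None)
    sigma2 = sol[:k]
    sigma2_e = sol[k]
    if sigma2_e <= 0:
        return None
    gamma = np.zeros(k)
    for row, (idx, _, _) in enumerate(proj_list):
        gamma[idx] = max(0.0, sigma2[row] / sigma2_e)
    return gamma


@dataclass
class MixedFitResult:
    """REML/GLS fit: variance components, fixed effects and diagnostics.

    ``components`` maps random-term names to variance estimates;
    ``cov_beta`` is the GLS covariance of the fixed effects;
    ``treatment_slice`` marks the one-hot treatment columns (treatment
    models only); ``d`` is the error degrees of freedom N - rank([X Z]).
    """

    sigma2_e: float
    components: dict[str, float]
    loglik: float
    beta: np.ndarray
    cov_beta: np.ndarray
    d: int
    n: int
    p: int
    converged: bool
    treatment_slice: slice | None = None
    fixed_names: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def treatment_effects(self) -> np.ndarray:
        if self.treatment_slice is None:
            raise ValueError("fit has no treatment structure")
        return self.beta[self.treatment_slice]

    @property
    def treatment_cov(self) -> np.ndarray:
        if self.treatment_slice is None:
            raise ValueError("fit has no treatment structure")
        return self.cov_beta[self.treatment_slice, self.treatment_slice]

    def to_json(self) -> str:
        return json.dumps(
            {
                "sigma2_e": self.sigma2_e,
                "components": self.components,
                "loglik": self.loglik,
                "error_df": self.d,
                "converged": self.converged,
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            "Mixed model fit (REML)",
            "=" * 46,
            f"{'observations':<28}{self.n:>10d}",
            f"{'fixed-effect rank':<28}{self.p:>10d}",
            f"{'error df':<28}{self.d:>10d}",
            f"{'REML log-likelihood':<28}{self.loglik:>14.4f}",
            f"{'converged':<28}{str(self.converged):>10}",
            "-" * 46,
            "Variance components",
        ]
        for name, val in self.components.items():
            lines.append(f"  {name:<26}{val:>14.5f}")
        lines.append(f"  {'residual':<26}{self.sigma2_e:>14.5f}")
        return "\n".join(lines)


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Zs: Sequence[np.ndarray],
    names: Sequence[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixedFitResult:
    """Constrained REML with profiled beta and sigma2_e.

    Candidates: bound-constrained L-BFGS-B optima from several starts, the
    all-zero boundary and the balanced-ANOVA closed form; the candidate with
    the highest restricted likelihood is returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k = len(Zs)
    names = tuple(names) if names is not None else tuple(f"vc{i + 1}" for i in range(k))
    d = n - int(np.linalg.matrix_rank(np.column_stack([X, *Zs]) if k else X))
    if d <= 0:
        raise InestimabilityError("no error degrees of freedom left")

    if k == 0:
        negll, aux = _profile_negll(np.zeros(0), y, X, [])
        beta, s2, cov_beta = aux
        return MixedFitResult(
            sigma2_e=s2, components={}, loglik=-negll, beta=beta, cov_beta=cov_beta,
            d=d, n=n, p=p, converged=True, fixed_names=names,
        )

    ZZts = [Z @ Z.T for Z in Zs]
    candidates: list[np.ndarray] = [np.zeros(k), np.full(k, 0.5)]
    anova = _anova_candidate(y, X, Zs)
    if anova is not None:
        candidates.append(anova)

    evaluated: list[tuple[float, np.ndarray, bool]] = []
    for g0 in candidates:
        val, aux = _profile_negll(g0, y, X, ZZts)
        if np.isfinite(val):
            evaluated.append((val, g0, True))
        res = optimize.minimize(
            lambda g: _profile_negll(g, y, X, ZZts)[0],
            x0=np.asarray(g0, dtype=float),
            method="L-BFGS-B",
            bounds=[(0.0, 1e8)] * k,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        if np.isfinite(res.fun):
            evaluated.append((float(res.fun), np.maximum(res.x, 0.0), bool(res.success)))
    if not evaluated:
        raise ConvergenceError("REML likelihood could not be evaluated")
    best_val, best_gamma, best_ok = min(evaluated, key=lambda t: t[0])
    negll, aux = _profile_negll(best_gamma, y, X, ZZts)
    beta, s2, cov_beta = aux
    components = {nm: float(g * s2) for nm, g in zip(names, best_gamma)}
    return MixedFitResult(
        sigma2_e=float(s2),
        components=components,
        loglik=-float(negll),
        beta=beta,
        cov_beta=cov_beta,
        d=d,
        n=n,
        p=p,
        converged=best_ok,
        fixed_names=names,
    )


# ---------------------------------------------------------------------------
# statsmodels-style model classes
# ---------------------------------------------------------------------------


class NullBlockModel:
    """Null mixed model of uniformity data: no treatments, random blocking.

    With ``blocking=None`` the model is intercept + residual and the error
    variance is the plain sample variance (n-1 divisor) of all observations.
    Otherwise the block (and, for row-column arrangements, row and column)
    terms are random with nonnegative variance components.
    """

    def __init__(self, data: UniformityData, blocking: BlockFactors | None = None):
        self.data = data
        self.blocking = blocking

    def fit(self) -> MixedFitResult:
        y = self.data.values.ravel()
        n = y.size
        X = np.ones((n, 1))
        if np.ptp(y) == 0.0:  # constant data: all components vanish
            res = MixedFitResult(
                sigma2_e=0.0, components={}, loglik=np.inf, beta=np.array([y[0]]),
                cov_beta=np.zeros((1, 1)), d=n - 1, n=n, p=1, converged=True,
            )
            if self.blocking is not None:
                res.components = {nm: 0.0 for nm in self._term_names()}
            return res
        if self.blocking is None:
            return reml_fit(y, X, [], names=())
        Zs, names = self._random_terms()
        return reml_fit(y, X, Zs, names=names)

    def _term_names(self) -> list[str]:
        names = ["block"]
        if self.blocking.row is not None:
            names += ["row", "column"]
        return names

    def _random_terms(self):
        blk = self.blocking
        Zs = [_dummies(blk.block.ravel())]
        names = ["block"]
        if blk.row is not None:
            Zs.append(_dummies(_nested_levels(blk.block.ravel(), blk.row.ravel())))
            names.append("row")
        if blk.column is not None:
            Zs.append(_dummies(_nested_levels(blk.block.ravel(), blk.column.ravel())))
            names.append("column")
        return Zs, names


class TreatmentModel:
    """Treatment analysis of a design overlaid on uniformity data.

    fit() runs constrained REML for the variance components, then GLS for
    the fixed effects (one-hot treatments first), recovering inter-block
    information through the random block terms.  The result's
    ``treatment_cov`` is the prediction-variance matrix of the v treatments.
    """

    def __init__(self, data: UniformityData, design: Design, model: VarianceModel):
        self.data = data
        self.design = design
        self.model = model
        self._y, self._X, self._Zs, self._names = build_matrices(data, design, model)

    def fit(self) -> MixedFitResult:
        res = reml_fit(self._y, self._X, self._Zs, names=self._names)
        res.treatment_slice = slice(0, self.design.v)
        res.meta = {"design": self.design.provenance.get("family"), "v": self.design.v}
        return res


def mean_pairwise_variance(fit: MixedFitResult) -> float:
    """Average variance of all v(v-1)/2 pairwise treatment differences."""
    cov = fit.treatment_cov
    v = cov.shape[0]
    if v < 2:
        raise ValueError("need at least 2 treatments")
    tr = float(np.trace(cov))
    s = float(cov.sum())
    return 2.0 * (v * tr - s) / (v * (v - 1))


def error_df(design: Design, model: VarianceModel, data: UniformityData | None = None) -> int:
    """Residual df of the working model: N - rank([X Z])."""
    if data is None:
        data = UniformityData(
            layout=design.layout,
            values=np.zeros((design.layout.n_lanes, design.layout.n_positions)),
        )
    _, X, Zs, _ = build_matrices(data, design, model)
    d = design.layout.n_cells - int(np.linalg.matrix_rank(np.column_stack([X, *Zs]) if Zs else X))
    if d <= 0:
        raise InestimabilityError("over-parameterized design: no error df")
    return d


def remlrt(fit_null: MixedFitResult, fit_alt: MixedFitResult, boundary: bool = True) -> dict:
    """Boundary-adjusted REML likelihood-ratio test for one variance component.

    statistic = max(0, 2 * (l_alt - l_null)); the p-value is the chi2_1
    upper tail, halved when the tested component is constrained nonnegative
    (the 50:50 chi2_0 / chi2_1 mixture).
    """
    if fit_null.p != fit_alt.p:
        raise ValueError("REMLRT requires the same fixed structure in both models")
    if not set(fit_null.components) <= set(fit_alt.components):
        raise ValueError("models are not nested in their random terms")
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    if boundary:
        p = 0.5 * p if stat > 0 else 0.5
    return {"statistic": stat, "p_value": p, "boundary_adjusted": boundary}
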