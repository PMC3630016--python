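"""Design comparison: relative precision, the modified A-optimality
criterion AP and Monte-Carlo relative efficiency RE_PDA.

AP = F_{1,d,1-alpha} * mean pairwise-difference variance; it penalizes both
imprecise predictions and scarce error degrees of freedom.  RE_PDA compares
a proposed design/analysis (PDA) with a completely randomized design:
RE_PDA = 100 * AP_CRD / AP_PDA (percent; > 100 favours the proposal).

For orthogonal analyses AP has a closed form from standard formulae; for
everything else it is approximated by a Monte-Carlo sample of the design's
restricted randomizations (regenerations, for trend-free designs), with a
mixed-model fit per randomization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import (
    BlockFactors,
    BlockingArrangement,
    Design,
    DesignError,
    make_blocks,
    make_crd,
    make_rcbd,
    make_resolved_ibd,
    make_row_column,
    make_trend_free,
    randomize,
)
from .field import UniformityData
from .layout import GridLayout
from .varfit import (
    MixedFitResult,
    NullBlockModel,
    TreatmentModel,
    VarianceModel,
    mean_pairwise_variance,
)


@dataclass(frozen=True)
class APCriterion:
    """Modified A-optimality criterion AP = F_{1,d,1-alpha} * sigma2diff_bar."""

    sigma2diff_bar: float
    d: float
    alpha: float
    f_quantile: float
    ap: float


def ap(sigma2diff_bar: float, d: float, alpha: float = 0.05) -> APCriterion:
    if d < 1:
        raise ValueError("error degrees of freedom must be >= 1")
    if sigma2diff_bar < 0:
        raise ValueError("sigma2diff_bar must be nonnegative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    f_q = float(stats.f.ppf(1.0 - alpha, 1, d))
    return APCriterion(
        sigma2diff_bar=float(sigma2diff_bar),
        d=float(d),
        alpha=alpha,
        f_quantile=f_q,
        ap=f_q * float(sigma2diff_bar),
    )


# ---------------------------------------------------------------------------
# uniformity-trial precision
# ---------------------------------------------------------------------------


def relative_precision(data: UniformityData, arrangement: BlockingArrangement) -> dict:
    """Precision of a blocking arrangement relative to no blocking.

    100 * (sample variance of all observations) / (REML residual variance
    under the arrangement); values > 100 favour blocking.  A zero residual
    variance is flagged as infinite precision rather than raising.
    """
    blocking = make_blocks(data.layout, arrangement)
    total_var = float(np.var(data.values, ddof=1))
    fit = NullBlockModel(data, blocking).fit()
    if fit.sigma2_e <= 0:
        warnings.warn("degenerate zero residual variance: infinite relative precision")
        rp = np.inf
    else:
        rp = 100.0 * total_var / fit.sigma2_e
    return {
        "series": arrangement.series,
        "label": arrangement.label,
        "block_lanes": arrangement.block_lanes,
        "block_positions": arrangement.block_positions,
        "no_blocking_variance": total_var,
        "sigma2_e": fit.sigma2_e,
        "relative_precision_pct": rp,
    }


def _ols_residual_var(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    df = y.size - int(np.linalg.matrix_rank(X))
    return rss / df, df


def pool_vs_separate_positions(data: UniformityData) -> dict:
    """Residual sd with and without a Positions term alongside Lanes.

    The 'separated' model has Lane and Position (factor) terms, the
    'pooled' model only Lane; the relative precision is 100 * pooled
    variance / separated variance (> 100 means isolating positions helps).
    """
    lay = data.layout
    y = data.values.ravel()
    lanes = pd.get_dummies(lay.lanes.ravel()).to_numpy(dtype=float)
    positions = pd.get_dummies(lay.positions.ravel()).to_numpy(dtype=float)[:, 1:]
    var_sep, _ = _ols_residual_var(y, np.column_stack([lanes, positions]))
    var_pool, _ = _ols_residual_var(y, lanes)
    return {
        "sd_separated": float(np.sqrt(var_sep)),
        "sd_pooled": float(np.sqrt(var_pool)),
        "relative_precision_pct": 100.0 * var_pool / var_sep,
    }


# ---------------------------------------------------------------------------
# closed-form AP for orthogonal designs
# ---------------------------------------------------------------------------


def exact_ap_crd(data: UniformityData, v: int, r: int, alpha: float = 0.05) -> APCriterion:
    """CRD AP from standard formulae: sigma2diff_bar = 2 s^2 / r with s^2
    the overall sample variance of the uniformity data, d = N - v."""
    n = data.layout.n_cells
    if v * r != n:
        raise DesignError("v*r must equal the number of cells")
    s2 = float(np.var(data.values, ddof=1))
    return ap(2.0 * s2 / r, n - v, alpha)


def exact_ap_rcbd(
    data: UniformityData, v: int, rep_shape: tuple[int, int], alpha: float = 0.05
) -> APCriterion:
    """Exact RCBD AP from the randomization expectation of the error mean
    square, which equals the pooled within-block mean square of the null
    analysis (within each block the treatment labels are exchangeable, so
    the treatment and error lines of the within-block stratum have equal
    expected mean squares).  d = (v-1)(b-1)."""
    lay = data.layout
    blocking = make_blocks(
        lay, BlockingArrangement("cross-lane", rep_shape[0], rep_shape[1])
    )
    b = blocking.n_blocks
    if lay.n_cells != v * b:
        raise DesignError("replicate shape inconsistent with v")
    y = data.values.ravel()
    blk = blocking.block.ravel()
    ss_within = sum(
        float(np.sum((y[blk == k] - y[blk == k].mean()) ** 2)) for k in np.unique(blk)
    )
    ms_within = ss_within / (lay.n_cells - b)
    d = (v - 1) * (b - 1)
    return ap(2.0 * ms_within / b, d, alpha)


# ---------------------------------------------------------------------------
# Monte-Carlo AP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonteCarloAP:
    criterion: APCriterion
    n_samples: int
    n_failures: int
    mc_se: float  # standard error of the AP estimate
    mean_d: float


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)])


def monte_carlo_ap(
    data: UniformityData,
    design: Design,
    model: VarianceModel,
    n_samples: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    regenerate: bool = False,
    max_failure_frac: float = 0.01,
) -> MonteCarloAP:
    """AP approximated over a Monte-Carlo sample of randomizations.

    Each sample randomizes (or, for trend-free designs, regenerates) the
    design, overlays the treatments on the uniformity data, fits the mixed
    model, and records the mean pairwise-difference variance and the error
    df; AP is built from the means over the sample.  Non-converged fits are
    excluded with a count; more than ``max_failure_frac`` failures aborts.
    """
    seeds = _spawn_seeds(seed, n_samples)
    s2diffs, dfs = [], []
    failures = 0
    for s in seeds:
        d_i = randomize(design, seed=int(s), regenerate=regenerate)
        try:
            fit = TreatmentModel(data, d_i, model).fit()
            if not fit.converged:
                raise RuntimeError("fit flagged non-converged")
        except Exception:
            failures += 1
            continue
        s2diffs.append(mean_pairwise_variance(fit))
        dfs.append(fit.d)
    if failures > max_failure_frac * n_samples:
        raise RuntimeError(
            f"{failures}/{n_samples} Monte-Carlo fits failed (> {max_failure_frac:.0%})"
        )
    s2diffs = np.asarray(s2diffs)
    mean_d = float(np.mean(dfs))
    crit = ap(float(np.mean(s2diffs)), mean_d, alpha)
    se = (
        crit.f_quantile * float(np.std(s2diffs, ddof=1)) / np.sqrt(s2diffs.size)
        if s2diffs.size > 1
        else 0.0
    )
    return MonteCarloAP(
        criterion=crit,
        n_samples=int(s2diffs.size),
        n_failures=failures,
        mc_se=se,
        mean_d=mean_d,
    )


# ---------------------------------------------------------------------------
# the design/analysis menu
# ---------------------------------------------------------------------------


def _menu_registry() -> dict[str, dict]:
    """Named design/analysis pairs for a 72-cart zone.

    The 36-line entries are twice replicated, the 24-line entries (suffix
    '24' or the 3x8 family) thrice replicated.
    """
    no_rt: tuple[str, ...] = ()
    reg = {
        "CRD": dict(v=36, r=2, kind="closed_form"),
        "CRD+Adj": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_crd(36, 2, lay, seed=s),
            model=VarianceModel(trend="global", random_terms=no_rt),
        ),
        "TFD": dict(
            v=36, r=2, kind="regenerate",
            build=lambda lay, s: make_trend_free(36, 2, lay, rep_shape=None, seed=s),
            model=VarianceModel(trend="global", random_terms=no_rt),
        ),
        "RCBD3x12": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_rcbd(36, lay, (3, 12), seed=s),
            model=VarianceModel(fixed_blocks=True),
        ),
        "RCBD3x12+Adj": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_rcbd(36, lay, (3, 12), seed=s),
            model=VarianceModel(fixed_blocks=True, trend="block_equal"),
        ),
        "TFCBD3x12EqLin": dict(
            v=36, r=2, kind="regenerate",
            build=lambda lay, s: make_trend_free(36, 2, lay, rep_shape=(3, 12), seed=s),
            model=VarianceModel(fixed_blocks=True, trend="block_equal"),
        ),
        "RRCD3x12": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_row_column(36, lay, (3, 12), seed=s),
            model=VarianceModel(random_terms=("replicate", "row", "column")),
        ),
        "RIBD3x1": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_resolved_ibd(36, 2, lay, (3, 1), seed=s),
            model=VarianceModel(random_terms=("replicate", "block")),
        ),
        "RIBD1x4": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_resolved_ibd(36, 2, lay, (1, 4), seed=s),
            model=VarianceModel(random_terms=("replicate", "block")),
        ),
        "RIBD3x6": dict(
            v=36, r=2, kind="randomize",
            build=lambda lay, s: make_resolved_ibd(36, 2, lay, (3, 6), seed=s),
            model=VarianceModel(random_terms=("replicate", "block")),
        ),
        # thrice-replicated 24-line variants
        "CRD24": dict(v=24, r=3, kind="closed_form"),
        "CRD24+Adj": dict(
            v=24, r=3, kind="randomize",
            build=lambda lay, s: make_crd(24, 3, lay, seed=s),
            model=VarianceModel(trend="global", random_terms=no_rt),
        ),
        "TFD24": dict(
            v=24, r=3, kind="regenerate",
            build=lambda lay, s: make_trend_free(24, 3, lay, rep_shape=None, seed=s),
            model=VarianceModel(trend="global", random_terms=no_rt),
        ),
        "RCBD3x8": dict(
            v=24, r=3, kind="randomize",
            build=lambda lay, s: make_rcbd(24, lay, (3, 8), seed=s),
            model=VarianceModel(fixed_blocks=True),
        ),
        "NTFCBD3x8EqLin": dict(
            v=24, r=3, kind="regenerate",
            build=lambda lay, s: make_trend_free(24, 3, lay, rep_shape=(3, 8), seed=s),
            model=VarianceModel(fixed_blocks=True, trend="block_equal"),
        ),
        "NTFCBD3x8UneqLin": dict(
            v=24, r=3, kind="regenerate",
            build=lambda lay, s: make_trend_free(24, 3, lay, rep_shape=(3, 8), seed=s),
            model=VarianceModel(fixed_blocks=True, trend="block_unequal"),
        ),
    }
    return reg


MENU_36 = (
    "CRD", "CRD+Adj", "TFD", "RCBD3x12", "RCBD3x12+Adj",
    "TFCBD3x12EqLin", "RRCD3x12", "RIBD3x1", "RIBD1x4", "RIBD3x6",
)
MENU_24 = ("CRD24", "CRD24+Adj", "TFD24", "RCBD3x8", "NTFCBD3x8EqLin", "NTFCBD3x8UneqLin")


@dataclass(frozen=True)
class EfficiencyResult:
    design: str
    ap_crd: APCriterion
    ap_pda: APCriterion
    re_percent: float
    n_samples: int
    mc_standard_error: float
    mean_df: float
    n_failures: int = 0


def compare_designs(
    data: UniformityData,
    menu=MENU_36,
    n_samples: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    trend_free_fraction: float = 0.2,
) -> list[EfficiencyResult]:
    """RE_PDA for every menu entry, against the closed-form CRD criterion.

    Trend-free entries are regenerated per sample and use
    ``trend_free_fraction * n_samples`` samples (the heavier optimizer run
    replaces the cheap restricted randomization).
    """
    registry = _menu_registry()
    unknown = [m for m in menu if m not in registry]
    if unknown:
        raise KeyError(
            f"unknown menu entries {unknown}; valid names: {sorted(registry)}"
        )
    lay = data.layout
    results = []
    seeds = _spawn_seeds(seed, len(menu))
    ap_crd_cache: dict[int, APCriterion] = {}
    for name, s in zip(menu, seeds):
        spec = registry[name]
        v, r = spec["v"], spec["r"]
        if r not in ap_crd_cache:
            ap_crd_cache[r] = exact_ap_crd(data, v, r, alpha)
        ap_crd = ap_crd_cache[r]
        if spec["kind"] == "closed_form":
            results.append(
                EfficiencyResult(
                    design=name, ap_crd=ap_crd, ap_pda=ap_crd, re_percent=100.0,
                    n_samples=1, mc_standard_error=0.0, mean_df=ap_crd.d,
                )
            )
            continue
        base = spec["build"](lay, int(s))
        regen = spec["kind"] == "regenerate"
        n_mc = max(1, int(round(n_samples * trend_free_fraction))) if regen else n_samples
        mc = monte_carlo_ap(
            data, base, spec["model"], n_samples=n_mc, alpha=alpha,
            seed=int(s) + 1, regenerate=regen,
        )
        re = 100.0 * ap_crd.ap / mc.criterion.ap
        re_se = re * mc.mc_se / mc.criterion.ap
        results.append(
            EfficiencyResult(
                design=name, ap_crd=ap_crd, ap_pda=mc.criterion, re_percent=re,
                n_samples=mc.n_samples, mc_standard_error=re_se,
                mean_df=mc.mean_d, n_failures=mc.n_failures,
            )
        )
    return results


def efficiency_table(results: list[EfficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "design": [r.design for r in results],
            "re_percent": [r.re_percent for r in results],
            "ap": [r.ap_pda.ap for r in results],
            "ap_crd": [r.ap_crd.ap for r in results],
            "mean_df": [r.mean_df for r in results],
            "mc_se": [r.mc_standard_error for r in results],
            "n_samples": [r.n_samples for r in results],
            "n_failures": [r.n_failures for r in results],
        }
    )
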