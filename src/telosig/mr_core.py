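"""Two-sample MR estimators, heterogeneity diagnostics and multivariable MR.

Case-control outcome betas are treated as log odds ratios throughout; the
reported ``beta`` is on that scale and callers exponentiate for ORs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonisedSet

__all__ = [
    "MREstimate",
    "HeterogeneityStats",
    "MVMRSet",
    "wald_ratio",
    "ivw_mre",
    "mr_egger",
    "weighted_median",
    "contamination_mixture",
    "leave_one_out",
    "mvmr_fit",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    method: str
    n_snps: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the estimate")

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float

    def __post_init__(self) -> None:
        if self.Q < 0 or self.tau2 < 0 or not (0 <= self.I2 < 1):
            raise ValueError("invalid heterogeneity statistics")


@dataclass
class MVMRSet:
    """Instrument-by-exposure design for multivariable MR."""

    b_X: np.ndarray  # instruments x exposures
    s_X: np.ndarray
    b_Y: np.ndarray
    s_Y: np.ndarray
    exposure_labels: list[str] = field(default_factory=list)
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        self.b_X = np.atleast_2d(np.asarray(self.b_X, dtype=float))
        self.s_X = np.atleast_2d(np.asarray(self.s_X, dtype=float))
        self.b_Y = np.asarray(self.b_Y, dtype=float)
        self.s_Y = np.asarray(self.s_Y, dtype=float)
        j, k = self.b_X.shape
        if self.s_X.shape != (j, k) or len(self.b_Y) != j or len(self.s_Y) != j:
            raise ValueError("MVMR array shapes disagree")
        if j < k + 1:
            raise ValueError("need at least exposures + 1 instruments")
        if not self.exposure_labels:
            self.exposure_labels = [f"exposure_{i + 1}" for i in range(k)]


def _normal_ci(beta: float, se: float) -> tuple[float, float]:
    return beta - _Z95 * se, beta + _Z95 * se


def _normal_p(beta: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(beta) / se))


def wald_ratio(b_x: float, s_x: float, b_y: float, s_y: float,
               second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate b_y / b_x.

    First-order delta SE is \\|s_y / b_x\\|; ``second_order`` adds the
    exposure-uncertainty term b_y^2 s_x^2 / b_x^4.
    """
    if b_x == 0:
        raise ValueError("b_x must be nonzero for a Wald ratio")
    beta = b_y / b_x
    var = (s_y / b_x) ** 2
    if second_order:
        var += (b_y ** 2) * (s_x ** 2) / (b_x ** 4)
    se = float(np.sqrt(var))
    lo, hi = _normal_ci(beta, se)
    return MREstimate("wald_ratio", 1, float(beta), se, lo, hi, _normal_p(beta, se))


def _dl_tau2(ratios: np.ndarray, ses: np.ndarray) -> float:
    """DerSimonian-Laird between-instrument variance on Wald ratios."""
    w = 1.0 / ses ** 2
    mu = np.sum(w * ratios) / np.sum(w)
    q = np.sum(w * (ratios - mu) ** 2)
    df = len(ratios) - 1
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - df) / denom))


def _heterogeneity(hs: HarmonisedSet, beta: float) -> HeterogeneityStats:
    w = 1.0 / hs.s_Y ** 2
    q = float(np.sum(w * (hs.b_Y - beta * hs.b_X) ** 2))
    df = hs.n_snps - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else np.nan
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    ratios = hs.b_Y / hs.b_X
    ratio_se = np.abs(hs.s_Y / hs.b_X)
    tau2 = _dl_tau2(ratios, ratio_se) if df > 0 else 0.0
    return HeterogeneityStats(q, df, p_q, i2, tau2)


def ivw_mre(hs: HarmonisedSet) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted regression of b_Y on b_X through the origin with weights
    1/s_Y^2; the SE is inflated by ``max(1, sqrt(Q / (J - 1)))``.
    """
    if hs.n_snps < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    if np.any(hs.b_X == 0):
        raise ValueError("zero exposure beta among instruments")
    w = 1.0 / hs.s_Y ** 2
    denom = np.sum(w * hs.b_X ** 2)
    beta = float(np.sum(w * hs.b_X * hs.b_Y) / denom)
    het = _heterogeneity(hs, beta)
    scale = max(1.0, np.sqrt(het.Q / het.df)) if het.df > 0 else 1.0
    se = float(np.sqrt(1.0 / denom) * scale)
    lo, hi = _normal_ci(beta, se)
    est = MREstimate("ivw_mre", hs.n_snps, beta, se, lo, hi, _normal_p(beta, se),
                     notes=f"overdispersion scale {scale:.4g}; tau2 via DL on Wald ratios")
    return est, het


def _oriented(hs: HarmonisedSet) -> HarmonisedSet:
    """Flip instruments so all exposure betas are non-negative."""
    sign = np.where(hs.b_X < 0, -1.0, 1.0)
    return HarmonisedSet(hs.exposure_label, hs.outcome_label, list(hs.variant_ids),
                         sign * hs.b_X, hs.s_X, sign * hs.b_Y, hs.s_Y,
                         proxy_map=dict(hs.proxy_map), dropped=dict(hs.dropped))


def mr_egger(hs: HarmonisedSet, with_intercept: bool = True,
             ) -> tuple[MREstimate, HeterogeneityStats]:
    """Weighted Egger regression; the intercept tests directional pleiotropy.

    Instruments are oriented to non-negative exposure betas first; weights
    are 1/s_Y^2 and the multiplicative overdispersion scale is floored at 1.
    With ``with_intercept=False`` this reduces exactly to IVW.
    """
    min_n = 3 if with_intercept else 2
    if hs.n_snps < min_n:
        raise ValueError(f"Egger needs >= {min_n} instruments")
    o = _oriented(hs)
    w = 1.0 / o.s_Y ** 2
    if with_intercept:
        X = np.column_stack([np.ones(o.n_snps), o.b_X])
    else:
        X = o.b_X[:, None]
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    coef = np.linalg.solve(xtwx, Xw.T @ o.b_Y)
    resid = o.b_Y - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = o.n_snps - X.shape[1]
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    cov = np.linalg.inv(xtwx) * scale ** 2
    ses = np.sqrt(np.diag(cov))

    if with_intercept:
        icpt, slope = coef
        icpt_se, slope_se = ses
    else:
        icpt, icpt_se = None, None
        slope, slope_se = coef[0], ses[0]

    het = HeterogeneityStats(q, df, float(stats.chi2.sf(q, df)) if df > 0 else np.nan,
                             max(0.0, (q - df) / q) if q > 0 else 0.0,
                             _dl_tau2(o.b_Y / o.b_X, np.abs(o.s_Y / o.b_X)))
    lo, hi = _normal_ci(float(slope), float(slope_se))
    est = MREstimate(
        "mr_egger" if with_intercept else "mr_egger_null_intercept",
        hs.n_snps, float(slope), float(slope_se), lo, hi,
        _normal_p(float(slope), float(slope_se)),
        intercept=None if icpt is None else float(icpt),
        intercept_se=None if icpt_se is None else float(icpt_se),
        intercept_pval=None if icpt is None else _normal_p(float(icpt), float(icpt_se)),
        notes=f"overdispersion scale {scale:.4g}")
    return est, het


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolation estimator of the weighted median."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(hs: HarmonisedSet, n_boot: int = 1000, seed: int = 0,
                    ) -> MREstimate:
    """Inverse-variance-weighted median of Wald ratios.

    The SE comes from a seeded parametric bootstrap: resample b_X and b_Y
    from their standard errors and recompute the weighted median.
    """
    if hs.n_snps < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios = hs.b_Y / hs.b_X
    wts = (hs.b_X / hs.s_Y) ** 2  # 1 / var(ratio), first order
    beta = _weighted_median_point(ratios, wts)

    rng = np.random.default_rng(seed)
    J = hs.n_snps
    bx = rng.normal(hs.b_X, hs.s_X, size=(n_boot, J))
    by = rng.normal(hs.b_Y, hs.s_Y, size=(n_boot, J))
    bx = np.where(bx == 0, 1e-12, bx)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _weighted_median_point(by[i] / bx[i], (bx[i] / hs.s_Y) ** 2)
    se = float(boot.std(ddof=1))
    se = max(se, 1e-12)
    lo, hi = _normal_ci(beta, se)
    return MREstimate("weighted_median", J, beta, se, lo, hi, _normal_p(beta, se),
                      notes=f"parametric bootstrap n={n_boot}, seed={seed}")


def contamination_mixture(hs: HarmonisedSet, psi: float | None = None,
                          grid_size: int = 512) -> MREstimate:
    """Profile-likelihood contamination-mixture estimate.

    Each instrument's Wald ratio is classified valid ~ N(theta, se_j^2) or
    invalid ~ N(0, se_j^2 + psi^2), whichever is more likely, on a theta
    grid spanning [min ratio - 1 SE, max ratio + 1 SE]; the estimate is the
    profile maximum and the CI is the chi-square(1) 95% likelihood region
    (envelope reported, flagged when disjoint).  ``psi`` defaults to 1.5x
    the SD of the Wald ratios.
    """
    if hs.n_snps < 3:
        raise ValueError("contamination mixture needs >= 3 instruments")
    ratios = hs.b_Y / hs.b_X
    ses = np.abs(hs.s_Y / hs.b_X)
    if psi is None:
        psi = 1.5 * float(np.std(ratios, ddof=1))
        if psi <= 0:
            psi = 1.0
    lo_grid = ratios.min() - ses[np.argmin(ratios)]
    hi_grid = ratios.max() + ses[np.argmax(ratios)]
    grid = np.linspace(lo_grid, hi_grid, grid_size)

    # (grid, J) log densities
    valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=ses[None, :])
    invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(ses ** 2 + psi ** 2))
    ll = np.maximum(valid, invalid[None, :]).sum(axis=1)
    if np.allclose(ll, ll[0], atol=1e-12):
        raise ValueError("flat contamination-mixture likelihood; no information")
    k = int(np.argmax(ll))
    beta = float(grid[k])
    # overdispersion-inflated likelihood cutoff (multiplicative
    # random-effects analogue): the larger of a Cochran-Q scale and a
    # MAD-based robust scale of the standardised residuals
    u = (ratios - beta) / ses
    mad_scale = 1.4826 * float(np.median(np.abs(u - np.median(u))))
    w_r = 1.0 / ses ** 2
    mu_r = np.sum(w_r * ratios) / np.sum(w_r)
    q_r = float(np.sum(w_r * (ratios - mu_r) ** 2))
    overdisp = max(1.0, q_r / (len(ratios) - 1), mad_scale ** 2)
    inside = 2 * (ll.max() - ll) < stats.chi2.ppf(0.95, 1) * overdisp
    lo, hi = float(grid[inside].min()), float(grid[inside].max())
    disjoint = bool(np.any(np.diff(np.flatnonzero(inside)) > 1))
    n_valid = int(np.sum(valid[k] >= invalid))
    se = max((hi - lo) / (2 * _Z95), 1e-12)
    notes = f"psi={psi:.4g}, grid={grid_size}, valid_instruments={n_valid}"
    if disjoint:
        notes += "; CI envelope over disjoint likelihood region"
    return MREstimate("contamination_mixture", hs.n_snps, beta, se,
                      min(lo, beta), max(hi, beta), _normal_p(beta, se), notes=notes)


def conmix_classification(hs: HarmonisedSet, theta: float, psi: float) -> np.ndarray:
    """Boolean valid/invalid classification at a given theta (True = valid)."""
    ratios = hs.b_Y / hs.b_X
    ses = np.abs(hs.s_Y / hs.b_X)
    valid = stats.norm.logpdf(ratios, loc=theta, scale=ses)
    invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(ses ** 2 + psi ** 2))
    return valid >= invalid


def leave_one_out(hs: HarmonisedSet, flag_threshold: float = 0.10) -> pd.DataFrame:
    """IVW re-estimated dropping each instrument in turn.

    Rows where the estimate moves by more than ``flag_threshold`` (relative
    to the full-set estimate) are flagged; the default 10% matches the
    outlier rule used for leave-one-out screening.
    """
    if hs.n_snps < 3:
        raise ValueError("leave-one-out needs >= 3 instruments")
    full, _ = ivw_mre(hs)
    rows = []
    for i in range(hs.n_snps):
        mask = np.ones(hs.n_snps, dtype=bool)
        mask[i] = False
        est, _ = ivw_mre(hs.subset(mask))
        abs_change = abs(est.beta - full.beta)
        if full.beta != 0:
            rel = abs_change / abs(full.beta)
            flagged = rel > flag_threshold
        else:
            rel = np.nan
            flagged = abs_change > 0  # undefined relative change; report absolute
        rows.append({"dropped": hs.variant_ids[i], "beta": est.beta, "se": est.se,
                     "abs_change": abs_change, "rel_change": rel, "flagged": bool(flagged)})
    out = pd.DataFrame(rows)
    out.attrs["beta_full"] = full.beta
    return out


def _mvmr_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              labels: list[str]) -> tuple[np.ndarray, np.ndarray, float, int]:
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular MVMR design; collinear exposures among {labels}")
    coef = np.linalg.solve(xtwx, Xw.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = X.shape[0] - X.shape[1]
    scale = max(1.0, np.sqrt(q / df)) if df > 0 else 1.0
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale
    return coef, ses, q, df


def mvmr_lasso_path(mv: MVMRSet, lam: float, max_iter: int = 500,
                    tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Solve the per-instrument-intercept L1 problem at one penalty.

    Minimises ``0.5 * sum_j w_j (b_Yj - alpha_j - x_j . theta)^2 +
    lam * sum_j |alpha_j|`` with theta unpenalised; returns (theta, alpha).
    """
    w = 1.0 / mv.s_Y ** 2
    X, y = mv.b_X, mv.b_Y
    alpha = np.zeros(len(y))
    theta = np.zeros(X.shape[1])
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    thr = lam / w
    for _ in range(max_iter):
        # theta first: the lam -> 0 limit then stays at the WLS fit rather
        # than collapsing to the saturated all-intercept solution
        theta_new = np.linalg.solve(xtwx, Xw.T @ (y - alpha))
        resid = y - X @ theta_new
        alpha_new = np.sign(resid) * np.maximum(np.abs(resid) - thr, 0.0)
        done = (np.max(np.abs(alpha_new - alpha)) < tol
                and np.max(np.abs(theta_new - theta)) < tol)
        alpha, theta = alpha_new, theta_new
        if done:
            break
    return theta, alpha


def mvmr_fit(mv: MVMRSet, method: str = "ivw",
             lambda_grid: np.ndarray | None = None) -> list[MREstimate]:
    """Multivariable MR by IVW, Egger or per-instrument-intercept LASSO.

    LASSO: the largest lambda whose post-selection IVW heterogeneity Q is
    below the chi-square 95th percentile is chosen, then a plain MVMR-IVW
    is refit on the instruments with zero intercept.
    """
    j, k = mv.b_X.shape
    w = 1.0 / mv.s_Y ** 2

    if method == "ivw":
        coef, ses, q, df = _mvmr_wls(mv.b_X, mv.b_Y, w, mv.exposure_labels)
        return [_mk_est("mvmr_ivw", j, c, s, lab)
                for c, s, lab in zip(coef, ses, mv.exposure_labels)]

    if method == "egger":
        if j < k + 2:
            raise ValueError("MVMR-Egger needs at least exposures + 2 instruments")
        sign = np.where(mv.b_X[:, 0] < 0, -1.0, 1.0)
        Xo = mv.b_X * sign[:, None]
        yo = mv.b_Y * sign
        X = np.column_stack([np.ones(j), Xo])
        coef, ses, q, df = _mvmr_wls(X, yo, w, ["intercept"] + mv.exposure_labels)
        out = []
        for idx, lab in enumerate(mv.exposure_labels, start=1):
            est = _mk_est("mvmr_egger", j, coef[idx], ses[idx], lab)
            est.intercept = float(coef[0])
            est.intercept_se = float(ses[0])
            est.intercept_pval = _normal_p(float(coef[0]), float(ses[0]))
            out.append(est)
        return out

    if method == "lasso":
        if lambda_grid is None:
            resid0 = mv.b_Y - mv.b_X @ np.linalg.lstsq(mv.b_X, mv.b_Y, rcond=None)[0]
            lam_max = float(np.max(np.abs(resid0) * w)) + 1e-12
            lambda_grid = np.geomspace(lam_max, lam_max * 1e-4, 40)
        lambda_grid = np.sort(np.asarray(lambda_grid))[::-1]
        q95 = stats.chi2.ppf(0.95, max(j - k - 1, 1))
        chosen = None
        for lam in lambda_grid:
            _, alpha = mvmr_lasso_path(mv, lam)
            valid = np.abs(alpha) < 1e-9
            if valid.sum() < k + 1:
                continue
            sub = MVMRSet(mv.b_X[valid], mv.s_X[valid], mv.b_Y[valid], mv.s_Y[valid],
                          list(mv.exposure_labels), mv.outcome_label)
            coef, ses, q, df = _mvmr_wls(sub.b_X, sub.b_Y, 1.0 / sub.s_Y ** 2,
                                         sub.exposure_labels)
            if q <= stats.chi2.ppf(0.95, max(df, 1)):
                chosen = (lam, valid, coef, ses)
                break
        if chosen is None:
            # fall back to the densest selection meeting the size constraint
            lam = lambda_grid[0]
            _, alpha = mvmr_lasso_path(mv, lam)
            valid = np.abs(alpha) < 1e-9
            sub = MVMRSet(mv.b_X[valid], mv.s_X[valid], mv.b_Y[valid], mv.s_Y[valid],
                          list(mv.exposure_labels), mv.outcome_label)
            coef, ses, _, _ = _mvmr_wls(sub.b_X, sub.b_Y, 1.0 / sub.s_Y ** 2,
                                        sub.exposure_labels)
            chosen = (lam, valid, coef, ses)
        lam, valid, coef, ses = chosen
        ests = [_mk_est("mvmr_lasso", int(valid.sum()), c, s, lab)
                for c, s, lab in zip(coef, ses, mv.exposure_labels)]
        for e in ests:
            e.notes += f"; lambda={lam:.4g}, instruments_kept={int(valid.sum())}/{j}"
        return ests

    raise ValueError(f"unknown MVMR method {method!r}")


def _mk_est(method: str, n: int, beta: float, se: float, label: str) -> MREstimate:
    beta, se = float(beta), float(se)
    lo, hi = _normal_ci(beta, se)
    return MREstimate(method, n, beta, se, lo, hi, _normal_p(beta, se),
                      notes=f"exposure={label}")
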