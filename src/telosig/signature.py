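"""Tumour transcriptome arm: count normalisation, expression PCA,
PRS-component association, Procrustes alignment, the LASSO gene signature
and feature-association models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn.linear_model import Lasso, lasso_path

from .instruments import PRSVector

__all__ = [
    "ExpressionMatrix",
    "PCModel",
    "SignatureModel",
    "normalise_counts",
    "fit_expression_pca",
    "top_loading_genes",
    "associate_prs_pcs",
    "align_pcs_rigid",
    "fit_lasso_signature",
    "apply_signature",
    "feature_association",
]


@dataclass
class ExpressionMatrix:
    """Raw RNA-seq counts, genes x samples, with per-gene length/GC metadata."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_meta: pd.DataFrame | None = None  # columns: length, gc

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape != (genes, samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.gene_meta is not None:
            self.gene_meta = self.gene_meta.loc[self.gene_ids]


@dataclass
class PCModel:
    loadings: np.ndarray       # genes x k, orthonormal columns
    scores: np.ndarray         # samples x k
    explained_var: np.ndarray  # fractions, nonincreasing
    center: np.ndarray
    scale: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if np.abs(gram - np.eye(self.loadings.shape[1])).max() > 1e-8:
            raise ValueError("loading columns must be orthonormal")
        if np.any(np.diff(self.explained_var) > 1e-12):
            raise ValueError("explained_var must be nonincreasing")

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class SignatureModel:
    """Portable weighted-gene signature for one expression component."""

    gene_ids: list[str]
    coefficients: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray
    component: int = 2
    rotation: np.ndarray | None = None
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if np.all(self.coefficients == 0):
            raise ValueError("signature must have at least one nonzero coefficient")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids,
                             "coefficient": self.coefficients,
                             "train_mean": self.train_mean,
                             "train_sd": self.train_sd})


def _binned_median_correction(logmat: np.ndarray, covariate: np.ndarray,
                              n_bins: int = 10) -> np.ndarray:
    """Subtract per-sample binned-median trends of logmat on a gene covariate."""
    qs = np.unique(np.quantile(covariate, np.linspace(0, 1, n_bins + 1)))
    if len(qs) < 3:  # covariate (nearly) constant: nothing to correct
        return logmat
    bins = np.clip(np.searchsorted(qs, covariate, side="right") - 1, 0, len(qs) - 2)
    out = logmat.copy()
    overall = np.median(logmat, axis=0)
    for b in np.unique(bins):
        sel = bins == b
        med = np.median(logmat[sel], axis=0)
        out[sel] -= med - overall
    return out


def normalise_counts(em: ExpressionMatrix, min_count: int = 5,
                     min_frac: float = 0.2, gc_correct: bool = True,
                     n_bins: int = 10, target_uq: float = 100.0) -> pd.DataFrame:
    """Filter, depth-normalise and GC/length-correct counts; return log2.

    Genes with fewer than ``min_frac`` of samples reaching ``min_count``
    reads are dropped.  Depth is equalised by scaling every sample to a
    fixed upper-quartile ``target_uq`` in count space (a fixed target makes
    integer depth rescaling of any one sample an exact no-op for the whole
    matrix), then within-sample GC and log-length trends are removed by a
    binned-median fit in log space.  Output is log2(normalised + 1),
    genes x samples.
    """
    counts = em.counts.astype(float)
    expressed = (counts >= min_count).mean(axis=1) >= min_frac
    if not expressed.any():
        raise ValueError("all genes fail the low-count filter")
    counts = counts[expressed]
    genes = [g for g, keep in zip(em.gene_ids, expressed) if keep]

    # between-sample: upper-quartile scaling to a fixed common depth
    uq = np.quantile(counts, 0.75, axis=0)
    if np.any(uq <= 0):
        raise ValueError("a sample has zero upper-quartile count after filtering")
    scaled = counts * (target_uq / uq)[None, :]
    logmat = np.log2(scaled + 1.0)

    if gc_correct:
        if em.gene_meta is None:
            raise ValueError("gene_meta with gc/length needed for GC correction")
        meta = em.gene_meta.loc[genes]
        logmat = _binned_median_correction(logmat, meta["gc"].to_numpy(float), n_bins)
        logmat = _binned_median_correction(
            logmat, np.log(meta["length"].to_numpy(float)), n_bins)

    return pd.DataFrame(logmat, index=genes, columns=em.sample_ids)


def fit_expression_pca(logmat: pd.DataFrame, k: int = 5,
                       outlier_sd: float = 6.0, unit_scale: bool = True,
                       ) -> PCModel:
    """Gene-standardised SVD of the expression matrix with outlier refit.

    A provisional decomposition flags samples beyond ``outlier_sd`` SDs on
    either of the first two components; the model is refit without them.
    The sign of each component is fixed so its largest-magnitude loading
    is positive.
    """
    genes = list(logmat.index)
    samples = list(logmat.columns)
    X = logmat.to_numpy(dtype=float).T  # samples x genes
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    if X.shape[0] < k + 2:
        raise ValueError("need at least k + 2 samples")

    def decompose(Xs: np.ndarray):
        center = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0) if unit_scale else np.ones_like(sd)
        Z = (Xs - center) / scale
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        return center, scale, Z, u, s, vt

    center, scale, Z, u, s, vt = decompose(X)
    prov_scores = u[:, :2] * s[:2]
    sds = prov_scores.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    outlier = np.any(np.abs(prov_scores / sds) > outlier_sd, axis=1)
    excluded = [samples[i] for i in np.flatnonzero(outlier)]
    if outlier.any():
        keep = ~outlier
        X = X[keep]
        samples = [s_ for s_, k_ in zip(samples, keep) if k_]
        center, scale, Z, u, s, vt = decompose(X)

    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        imax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[imax, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ev = (s ** 2) / np.sum(s ** 2)
    return PCModel(loadings, scores, ev[:k], center, scale, genes, samples,
                   excluded_samples=excluded)


def top_loading_genes(pc: PCModel, logmat: pd.DataFrame, component: int,
                      n_top: int = 500, alpha: float = 0.05,
                      ) -> tuple[list[str], list[str]]:
    """Top positively/negatively correlated genes for one component.

    Correlates every gene with the component score, Bonferroni-adjusts
    over genes x components tests, and returns up to ``n_top`` significant
    genes per direction ordered by |correlation|.  ``component`` is
    1-based.
    """
    if not 1 <= component <= pc.k:
        raise ValueError(f"component must be in 1..{pc.k}")
    score = pc.scores[:, component - 1]
    X = logmat[pc.sample_ids].to_numpy(dtype=float)
    r = _pearson_rows(X, score)
    n = len(score)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p_adj = np.minimum(1.0, p * len(r) * pc.k)
    sig = p_adj < alpha
    genes = np.asarray(logmat.index)
    order = np.argsort(-np.abs(r), kind="mergesort")
    pos = [genes[i] for i in order if sig[i] and r[i] > 0][:n_top]
    neg = [genes[i] for i in order if sig[i] and r[i] < 0][:n_top]
    return pos, neg


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc @ yc) / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _ols_table(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """OLS with intercept; classic SEs; rank-deficiency is an error."""
    names = list(X.columns)
    M = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        cur = M[:, :1]
        for i, nm in enumerate(names, start=1):
            cand = np.column_stack([cur, M[:, i]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                aliased.append(nm)
            else:
                cur = cand
        raise ValueError(f"rank-deficient design; aliased covariates: {aliased}")
    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    dof = len(y) - M.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "term": ["intercept"] + names, "beta": coef, "se": se,
        "ci_low": coef - z * se, "ci_high": coef + z * se, "pval": p})


def associate_prs_pcs(pc: PCModel, prs: PRSVector,
                      covariates: pd.DataFrame | None = None,
                      standardise_outcome: bool = True) -> pd.DataFrame:
    """Per-component linear model of expression scores on the PRS.

    Each component score (standardised to SD 1 by default) is regressed on
    the standardised PRS plus covariates; the reported beta is per SD of
    PRS.  Samples are matched by id across the three inputs.
    """
    prs_s = pd.Series(prs.std_score, index=prs.sample_ids)
    common = [s for s in pc.sample_ids if s in prs_s.index]
    if covariates is not None:
        common = [s for s in common if s in covariates.index]
        if len(common) < covariates.shape[1] + 5:
            raise ValueError("too few shared samples for the covariate set")
    idx = [pc.sample_ids.index(s) for s in common]

    rows = []
    for comp in range(pc.k):
        y = pc.scores[idx, comp]
        if standardise_outcome:
            sd = y.std()
            if sd > 0:
                y = (y - y.mean()) / sd
        X = pd.DataFrame({"prs": prs_s.loc[common].to_numpy()}, index=common)
        X["prs"] = (X["prs"] - X["prs"].mean()) / X["prs"].std()
        if covariates is not None:
            X = pd.concat([X, covariates.loc[common]], axis=1)
        tab = _ols_table(y, X)
        row = tab[tab["term"] == "prs"].iloc[0].to_dict()
        row["component"] = comp + 1
        rows.append(row)
    return pd.DataFrame(rows)[["component", "beta", "se", "ci_low", "ci_high", "pval"]]


def align_pcs_rigid(pc_train: PCModel, pc_val: PCModel,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes alignment of validation onto training PCs.

    Solves ``R = argmin || L_val R - L_train ||_F`` over orthogonal R via
    the SVD of ``L_val^T L_train`` and applies R to the validation scores.
    Centering during PCA already absorbed any translation.
    """
    if pc_train.gene_ids != pc_val.gene_ids:
        only_train = set(pc_train.gene_ids) - set(pc_val.gene_ids)
        only_val = set(pc_val.gene_ids) - set(pc_train.gene_ids)
        if only_train or only_val:
            raise ValueError(
                f"gene sets differ; train-only={sorted(only_train)[:5]}, "
                f"val-only={sorted(only_val)[:5]}")
        raise ValueError("gene order differs between the two models")
    R, _ = orthogonal_procrustes(pc_val.loadings, pc_train.loadings)
    return R, pc_val.scores @ R


def fit_lasso_signature(logmat_train: pd.DataFrame, pc_train: PCModel,
                        component: int = 2, fdr_q: float = 0.05,
                        n_boot: int = 1000, seed: int = 0,
                        n_lambda: int = 30) -> SignatureModel:
    """Sparse gene signature predicting one expression component.

    Genes are screened by BH-FDR < ``fdr_q`` on their correlation with the
    component score, z-scaled, and entered into a LASSO whose penalty is
    chosen to minimise the mean out-of-bag bootstrap RMSE over ``n_boot``
    seeded resamples; the final model is refit on all training samples at
    the chosen penalty.
    """
    if not 1 <= component <= pc_train.k:
        raise ValueError(f"component must be in 1..{pc_train.k}")
    y = pc_train.scores[:, component - 1]
    X_all = logmat_train[pc_train.sample_ids].to_numpy(dtype=float)
    genes = np.asarray(logmat_train.index)

    r = _pearson_rows(X_all, y)
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    keep = _bh_reject(p, fdr_q)
    if not keep.any():
        raise ValueError("no genes pass the FDR screen")
    Xs = X_all[keep].T  # samples x screened genes
    screened = genes[keep]
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xs - mu) / sd

    alphas = _lambda_grid(Z, y, n_lambda)
    rng = np.random.default_rng(seed)
    errs = np.zeros((n_boot, len(alphas)))
    counts = np.zeros(len(alphas))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        # loose tolerance: only the RMSE ranking across alphas matters here
        _, coefs, _ = lasso_path(Z[idx], y[idx] - y[idx].mean(), alphas=alphas,
                                 max_iter=2000, tol=1e-3)
        pred = Z[oob] @ coefs + y[idx].mean()
        errs[b] = np.sqrt(np.mean((y[oob, None] - pred) ** 2, axis=0))
        counts += 1
    mean_rmse = errs.sum(axis=0) / np.maximum(counts, 1)
    best = int(np.argmin(mean_rmse))
    lam = alphas[best]

    model = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000)
    model.fit(Z, y)
    nz = np.abs(model.coef_) > 1e-12
    if not nz.any():
        raise ValueError("all coefficients zero at the chosen penalty; "
                         "re-run with a denser/smaller lambda grid")
    return SignatureModel(
        gene_ids=[str(g) for g in screened[nz]],
        coefficients=model.coef_[nz],
        train_mean=mu[nz], train_sd=sd[nz],
        component=component, intercept=float(model.intercept_))


def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    keep = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        keep[order[: kmax + 1]] = True
    return keep


def _lambda_grid(Z: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.max(np.abs(Z.T @ yc)) / len(y)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def apply_signature(sig: SignatureModel, logmat_target: pd.DataFrame,
                    frozen_scaling: bool = False) -> pd.Series:
    """Score target samples with a fitted signature.

    Each signature gene is z-scaled within the target cohort (or with the
    frozen training mean/SD when ``frozen_scaling``) and the score is the
    coefficient-weighted sum.  Zero-variance genes in the target are
    dropped with a warning flag in ``attrs``.
    """
    missing = [g for g in sig.gene_ids if g not in logmat_target.index]
    if missing:
        raise ValueError(f"target matrix lacks signature genes: {missing}")
    X = logmat_target.loc[sig.gene_ids].to_numpy(dtype=float)  # genes x samples
    dropped: list[str] = []
    if frozen_scaling:
        mu, sd = sig.train_mean, sig.train_sd
    else:
        mu = X.mean(axis=1)
        sd = X.std(axis=1)
        zero = sd <= 0
        if zero.all():
            raise ValueError("all signature genes have zero variance in target")
        dropped = [g for g, z in zip(sig.gene_ids, zero) if z]
        sd = np.where(zero, 1.0, sd)
    Zt = (X - mu[:, None]) / sd[:, None]
    coefs = sig.coefficients.copy()
    for g in dropped:
        coefs[sig.gene_ids.index(g)] = 0.0
    scores = pd.Series(coefs @ Zt, index=logmat_target.columns, name="signature")
    scores.attrs["dropped_genes"] = dropped
    scores.attrs["scaling"] = "frozen" if frozen_scaling else "target-cohort"
    scores.attrs["cohort_mean"] = mu
    scores.attrs["cohort_sd"] = sd
    return scores


DEFAULT_FEATURES = ["age", "gender", "smoking", "stage", "prs",
                    "telomerase_activity", "proliferation", "cna", "hrd",
                    "tmb", "sbs1", "sbs4", "sbs5"]


def feature_association(outcome: pd.Series, features: pd.DataFrame,
                        mode: str = "multivariate",
                        prs_ancestry_covariates: pd.DataFrame | None = None,
                        ) -> pd.DataFrame:
    """Univariate and joint linear models of a score on tumour features.

    The outcome is standardised to SD 1; continuous features are
    standardised and binary features left 0/1.  In univariate mode each
    feature is fit alone, except the PRS which is additionally adjusted for
    the supplied ancestry covariates; multivariate mode fits all features
    jointly.
    """
    common = [s for s in outcome.index if s in features.index]
    y = outcome.loc[common].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std()
    F = features.loc[common].copy()
    for col in F.columns:
        vals = F[col].to_numpy(dtype=float)
        uniq = np.unique(vals[~np.isnan(vals)])
        if not set(uniq).issubset({0.0, 1.0}):
            sd = np.nanstd(vals)
            if sd > 0:
                F[col] = (vals - np.nanmean(vals)) / sd

    if mode == "multivariate":
        tab = _ols_table(y, F)
        return tab[tab["term"] != "intercept"].reset_index(drop=True)
    if mode != "univariate":
        raise ValueError("mode must be 'univariate' or 'multivariate'")

    rows = []
    for col in F.columns:
        X = F[[col]]
        if col == "prs" and prs_ancestry_covariates is not None:
            X = pd.concat([X, prs_ancestry_covariates.loc[common]], axis=1)
        tab = _ols_table(y, X)
        rows.append(tab[tab["term"] == col].iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)
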