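"""Cross-trait LD-score regression: SNP heritability, genetic correlation,
and delete-a-block jackknife uncertainty.

The regression model is E[z^2] = 1 + N h2 l_j / M for single traits and
E[z1 z2] = intercept + sqrt(N1 N2) rho_g l_j / M across traits, with the
cross-trait intercept absorbing sample overlap.  Weights are updated once
from an unweighted pass, and standard errors come from a delete-a-block
jackknife over contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDScoreTable",
    "LDSCResult",
    "ldsc_h2",
    "ldsc_rg",
    "bonferroni_adjust",
]

RG_CLAMP = 1.25


@dataclass
class LDScoreTable:
    variant_ids: list[str]
    ld_scores: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ld_scores = np.asarray(self.ld_scores, dtype=float)
        if len(self.ld_scores) != len(self.variant_ids):
            raise ValueError("ld_scores length != variant_ids")
        if not np.all(np.isfinite(self.ld_scores)):
            raise ValueError("ld_scores must be finite")
        if np.any(self.ld_scores < 1.0):
            raise ValueError("ld_scores must be >= 1 (self-correlation)")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class LDSCResult:
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    intercept_1: float
    intercept_2: float
    cross_intercept: float
    cross_intercept_se: float
    rg: float | None
    rg_se: float | None
    rg_p: float | None
    n_blocks: int
    rg_clamped: bool = False
    rg_undefined: bool = False


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _jackknife_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WLS fit + delete-a-block jackknife using per-block cross-products.

    Returns (coef, jackknife SEs, per-block delete-one coefficient matrix).
    """
    m, k = X.shape
    Xw = X * w[:, None]
    bounds = _block_bounds(m, n_blocks)
    xtwx_b = np.empty((n_blocks, k, k))
    xtwy_b = np.empty((n_blocks, k))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        xtwx_b[b] = X[sl].T @ Xw[sl]
        xtwy_b[b] = Xw[sl].T @ y[sl]
    xtwx = xtwx_b.sum(axis=0)
    xtwy = xtwy_b.sum(axis=0)
    coef = np.linalg.solve(xtwx, xtwy)
    loo = np.empty((n_blocks, k))
    for b in range(n_blocks):
        loo[b] = np.linalg.solve(xtwx - xtwx_b[b], xtwy - xtwy_b[b])
    mean = loo.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - mean) ** 2, axis=0))
    return coef, se, loo


def _h2_design(n, ld: LDScoreTable, m: int) -> np.ndarray:
    n = np.broadcast_to(np.asarray(n, dtype=float), (len(ld),))
    x = n * ld.ld_scores / m
    return np.column_stack([np.ones(len(ld)), x])


def ldsc_h2(z: np.ndarray, n, ld: LDScoreTable, m: int | None = None,
            n_blocks: int = 200) -> dict:
    """Single-trait LD-score regression of z^2 on N l_j / M.

    Weights ``1 / (2 (i0 + h2_0 N l_j / M)^2 l_j)`` come from one
    unweighted pass; SEs are delete-a-block jackknife over ``n_blocks``
    contiguous blocks (variants are assumed position-ordered).
    """
    z = np.asarray(z, dtype=float)
    if len(z) != len(ld):
        raise ValueError("z length != LD score table")
    if len(z) < 2 * n_blocks:
        raise ValueError(f"need >= {2 * n_blocks} variants for {n_blocks} blocks")
    if m is None:
        m = len(ld)
    X = _h2_design(n, ld, m)
    y = z ** 2

    coef0, _, _ = _jackknife_wls(X, y, np.ones(len(y)), n_blocks)
    i0, h20 = coef0
    pred = np.maximum(i0 + h20 * X[:, 1], 1e-8)
    w = 1.0 / (2.0 * pred ** 2 * ld.ld_scores)
    coef, se, loo = _jackknife_wls(X, y, w, n_blocks)
    return {"h2": float(coef[1]), "h2_se": float(se[1]),
            "intercept": float(coef[0]), "intercept_se": float(se[0]),
            "n_blocks": n_blocks, "_loo": loo, "_weights": w}


def ldsc_rg(z1: np.ndarray, z2: np.ndarray, n1, n2, ld: LDScoreTable,
            m: int | None = None, n_blocks: int = 200,
            n_overlap: float = 0.0) -> LDSCResult:
    """Cross-trait LD-score regression and genetic correlation.

    ``rg = rho_g / sqrt(h2_1 h2_2)`` with the jackknife applied to the
    full ratio (heritabilities re-estimated per deleted block).  A
    non-positive heritability leaves rg flagged missing; estimates beyond
    +/-1.25 are clamped with a flag.  ``n_overlap`` is accepted for
    bookkeeping only: the cross-trait intercept absorbs overlap.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if m is None:
        m = len(ld)
    r1 = ldsc_h2(z1, n1, ld, m, n_blocks)
    r2 = ldsc_h2(z2, n2, ld, m, n_blocks)

    n1v = np.broadcast_to(np.asarray(n1, dtype=float), (len(ld),))
    n2v = np.broadcast_to(np.asarray(n2, dtype=float), (len(ld),))
    x = np.sqrt(n1v * n2v) * ld.ld_scores / m
    X = np.column_stack([np.ones(len(ld)), x])
    y = z1 * z2

    coef0, _, _ = _jackknife_wls(X, y, np.ones(len(y)), n_blocks)
    a1 = np.maximum(r1["intercept"] + r1["h2"] * n1v * ld.ld_scores / m, 1e-8)
    a2 = np.maximum(r2["intercept"] + r2["h2"] * n2v * ld.ld_scores / m, 1e-8)
    c = coef0[0] + coef0[1] * x
    w = 1.0 / ((a1 * a2 + c ** 2) * ld.ld_scores)
    coef, se, loo = _jackknife_wls(X, y, w, n_blocks)
    rho_g = float(coef[1])

    res = LDSCResult(
        h2_1=r1["h2"], h2_1_se=r1["h2_se"], h2_2=r2["h2"], h2_2_se=r2["h2_se"],
        intercept_1=r1["intercept"], intercept_2=r2["intercept"],
        cross_intercept=float(coef[0]), cross_intercept_se=float(se[0]),
        rg=None, rg_se=None, rg_p=None, n_blocks=n_blocks)

    if r1["h2"] <= 0 or r2["h2"] <= 0:
        res.rg_undefined = True
        return res

    rg = rho_g / np.sqrt(r1["h2"] * r2["h2"])
    # jackknife on the full ratio: rho_g and both h2 re-estimated per block
    h2_1_loo = r1["_loo"][:, 1]
    h2_2_loo = r2["_loo"][:, 1]
    rho_loo = loo[:, 1]
    ok = (h2_1_loo > 0) & (h2_2_loo > 0)
    rg_loo = np.where(ok, rho_loo / np.sqrt(np.abs(h2_1_loo * h2_2_loo)), rg)
    b = len(rg_loo)
    rg_se = float(np.sqrt((b - 1) / b * np.sum((rg_loo - rg_loo.mean()) ** 2)))
    rg_se = max(rg_se, 1e-12)
    res.rg = float(np.clip(rg, -RG_CLAMP, RG_CLAMP))
    res.rg_clamped = bool(abs(rg) > RG_CLAMP)
    res.rg_se = rg_se
    res.rg_p = float(2 * stats.norm.sf(abs(rg) / rg_se))
    return res


def bonferroni_adjust(p, n_tests: int):
    """Bonferroni-adjusted p-values: min(1, p * n_tests)."""
    p = np.asarray(p, dtype=float)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    out = np.minimum(1.0, p * n_tests)
    return float(out) if out.ndim == 0 else out


def hla_mask(chrom, pos, hla_chrom: str = "6",
             start: int = 25_000_000, end: int = 34_000_000) -> np.ndarray:
    """Boolean mask that is True for variants OUTSIDE the HLA region."""
    chrom = pd.Series(chrom).astype(str).to_numpy()
    pos = np.asarray(pos)
    inside = (chrom == hla_chrom) & (pos >= start) & (pos <= end)
    return ~inside
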