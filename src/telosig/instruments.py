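"""Instrument selection, exposure/outcome harmonisation, PRS and MR power."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import LDMatrix, SummaryStats

__all__ = [
    "HarmonisedSet",
    "PRSVector",
    "select_instruments",
    "harmonise_pair",
    "compute_prs",
    "mr_power",
]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HarmonisedSet:
    """Exposure/outcome effects aligned to common effect alleles."""

    exposure_label: str
    outcome_label: str
    variant_ids: list[str]
    b_X: np.ndarray
    s_X: np.ndarray
    b_Y: np.ndarray
    s_Y: np.ndarray
    proxy_map: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b_X = np.asarray(self.b_X, dtype=float)
        self.s_X = np.asarray(self.s_X, dtype=float)
        self.b_Y = np.asarray(self.b_Y, dtype=float)
        self.s_Y = np.asarray(self.s_Y, dtype=float)
        n = len(self.variant_ids)
        for name in ("b_X", "s_X", "b_Y", "s_Y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of variants")
        if n < 1:
            raise ValueError("HarmonisedSet needs at least one instrument")
        if np.any(self.s_X <= 0) or np.any(self.s_Y <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def subset(self, mask) -> "HarmonisedSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return HarmonisedSet(
            self.exposure_label, self.outcome_label,
            [self.variant_ids[i] for i in idx],
            self.b_X[idx], self.s_X[idx], self.b_Y[idx], self.s_Y[idx],
            proxy_map=dict(self.proxy_map), dropped=dict(self.dropped))


@dataclass
class PRSVector:
    """Per-sample polygenic score, raw and standardised."""

    sample_ids: list[str]
    raw_score: np.ndarray
    std_score: np.ndarray
    n_variants: int = 0

    def __post_init__(self) -> None:
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        self.std_score = np.asarray(self.std_score, dtype=float)
        ok = np.isfinite(self.std_score)
        if ok.any():
            m = self.std_score[ok].mean()
            s = self.std_score[ok].std()
            if abs(m) > 1e-8 or abs(s - 1.0) > 1e-8:
                raise ValueError("std_score must have mean 0, SD 1")


def select_instruments(ss: SummaryStats, ld: LDMatrix, p_thresh: float = 5e-8,
                       r2_thresh: float = 0.01, maf_min: float = 0.01) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Candidates must pass ``p < p_thresh`` and ``MAF >= maf_min``; they are
    visited by ascending p (ties broken by variant_id) and accepted iff
    their squared correlation with every already-accepted variant is below
    ``r2_thresh``.  Defaults follow genome-wide significance, r2 < 0.01 and
    MAF > 1%.
    """
    tab = ss.table
    if tab["eaf"].isna().any():
        missing = tab.loc[tab["eaf"].isna(), "variant_id"].tolist()
        raise ValueError(f"eaf required for clumping; missing for {missing[:5]}")
    maf = np.minimum(tab["eaf"], 1.0 - tab["eaf"])
    cand = tab[(tab["pval"] < p_thresh) & (maf >= maf_min)].copy()
    cand = cand.sort_values(["pval", "variant_id"], kind="mergesort")

    accepted: list[str] = []
    for vid in cand["variant_id"]:
        if vid not in ld._index:
            raise ValueError(f"LD matrix lacks candidate variant {vid!r}")
        ok = True
        for kept in accepted:
            r = ld.r_between(vid, kept)
            if not np.isfinite(r):
                raise ValueError(f"LD undefined for pair ({vid!r}, {kept!r})")
            if r * r >= r2_thresh:
                ok = False
                break
        if ok:
            accepted.append(vid)
    return accepted


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC


def _complement(a: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(a, a)


def harmonise_pair(exposure: SummaryStats, outcome: SummaryStats,
                   variants: Sequence[str], ld: LDMatrix | None = None,
                   proxy_r2: float = 0.8, palindrome_maf_max: float = 0.3,
                   ) -> HarmonisedSet:
    """Align outcome effects to the exposure effect alleles.

    Sign-flips swapped alleles; drops strand-ambiguous palindromic variants
    when MAF > ``palindrome_maf_max`` in either trait (otherwise aligns by
    frequency); substitutes the highest-r2 proxy with r2 > ``proxy_r2``
    when the variant is missing from the outcome (requires a signed
    LDMatrix), else drops.  All drops are recorded in ``dropped``.
    """
    exp_tab = exposure.table.set_index("variant_id")
    out_tab = outcome.table.set_index("variant_id")
    out_ids = set(out_tab.index)

    ids: list[str] = []
    bX, sX, bY, sY = [], [], [], []
    proxy_map: dict[str, str] = {}
    dropped: dict[str, str] = {}

    for vid in variants:
        if vid not in exp_tab.index:
            dropped[vid] = "absent from exposure"
            continue
        e = exp_tab.loc[vid]
        target, ld_sign = vid, 1.0
        if vid not in out_ids:
            best, best_r = None, 0.0
            if ld is not None and vid in ld._index:
                for cand in out_tab.index:
                    if cand in ld._index and cand != vid:
                        r = ld.r_between(vid, cand)
                        if r * r > proxy_r2 and r * r > best_r * best_r:
                            best, best_r = cand, r
            if best is None:
                dropped[vid] = "absent from outcome, no proxy"
                continue
            target, ld_sign = best, np.sign(best_r)
            proxy_map[vid] = best
        o = out_tab.loc[target]

        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_y = float(o["beta"])
        if target != vid:
            # proxy alleles are mapped through the signed LD correlation
            beta_y *= ld_sign
            flip = 1.0
        elif _is_palindromic(e_ea, e_oa):
            # strand-ambiguous: allele labels are uninformative, use frequency
            if pd.isna(e["eaf"]) or pd.isna(o["eaf"]):
                dropped[vid] = "palindromic, missing frequency"
                continue
            mafs = [min(e["eaf"], 1 - e["eaf"]), min(o["eaf"], 1 - o["eaf"])]
            if max(mafs) > palindrome_maf_max:
                dropped[vid] = "palindromic, ambiguous frequency"
                continue
            flip = -1.0 if (e["eaf"] - 0.5) * (o["eaf"] - 0.5) < 0 else 1.0
        elif (o_ea, o_oa) == (e_ea, e_oa):
            flip = 1.0
        elif (o_ea, o_oa) == (e_oa, e_ea):
            flip = -1.0
        elif (o_ea, o_oa) == (_complement(e_ea), _complement(e_oa)):
            flip = 1.0  # strand flip, same orientation
        elif (o_ea, o_oa) == (_complement(e_oa), _complement(e_ea)):
            flip = -1.0
        else:
            dropped[vid] = f"incompatible alleles {o_ea}/{o_oa} vs {e_ea}/{e_oa}"
            continue

        ids.append(vid)
        bX.append(float(e["beta"]))
        sX.append(float(e["se"]))
        bY.append(flip * beta_y)
        sY.append(float(o["se"]))

    if not ids:
        raise ValueError("harmonisation produced an empty instrument set")
    return HarmonisedSet(exposure.trait_label, outcome.trait_label, ids,
                         np.array(bX), np.array(sX), np.array(bY), np.array(sY),
                         proxy_map=proxy_map, dropped=dropped)


def compute_prs(genotypes: pd.DataFrame, weights: Mapping[str, float] | pd.Series,
                ) -> PRSVector:
    """Beta-weighted dosage sum per sample, plus a standardised copy.

    ``genotypes`` is samples x variants with dosages in [0, 2]; missing
    dosages are mean-imputed per variant.  ``weights`` maps variant id to
    the per-effect-allele beta; variants absent from the genotypes are
    ignored, but zero overlap is an error.
    """
    w = pd.Series(weights, dtype=float)
    common = [v for v in w.index if v in genotypes.columns]
    if not common:
        raise ValueError("no overlap between weight variants and genotype columns")
    G = genotypes[common].to_numpy(dtype=float)
    if np.nanmin(G, initial=0.0) < -1e-9 or np.nanmax(G, initial=0.0) > 2 + 1e-9:
        raise ValueError("dosages must lie in [0, 2]")
    col_means = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G = np.where(nan_mask, col_means[None, :], G)
    raw = G @ w.loc[common].to_numpy()
    sd = raw.std()
    if sd <= 0:
        raise ValueError("raw scores have zero variance; cannot standardise")
    std = (raw - raw.mean()) / sd
    return PRSVector([str(s) for s in genotypes.index], raw, std,
                     n_variants=len(common))


def mr_power(n_cases: int, n_controls: int, r2_x: float, odds_ratio: float,
             alpha: float = 0.05) -> float:
    """Asymptotic two-sided power of two-sample MR with a binary outcome.

    With case fraction ``phi`` and ``N = n_cases + n_controls``, the Wald
    statistic is approximately normal with mean
    ``sqrt(N * r2_x * phi * (1 - phi)) * log(OR)``; power is the two-sided
    normal rejection probability, which equals ``alpha`` at OR = 1.
    """
    if not 0 < r2_x < 1:
        raise ValueError("r2_x must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    n = n_cases + n_controls
    phi = n_cases / n
    lam = np.sqrt(n * r2_x * phi * (1 - phi)) * np.log(odds_ratio)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))
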