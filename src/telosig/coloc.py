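"""Approximate-Bayes-factor colocalisation with conditioning, masking and
a simplified multi-trait divisive clustering.

Posterior probabilities PP0..PP4 follow the single-causal-variant
enumeration; the default per-SNP priors are p1 = 1e-3, p2 = 1e-4 and
p12 = 1e-5.  A region's posterior belief in colocalisation is the
unweighted average PP4 over the single/conditioning/masking runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .io_core import LDMatrix, RegionalDataset, TraitVector

__all__ = [
    "ColocResult",
    "MultiColocResult",
    "wakefield_labf",
    "trait_labf",
    "coloc_abf",
    "conditional_sumstats",
    "find_signals",
    "coloc_condmask_average",
    "multitrait_coloc",
]

DEFAULT_PRIORS = (1e-3, 1e-4, 1e-5)
#: prior effect SDs: quantitative traits (per sdY) and case-control (log-OR)
PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    method: str
    lead_pair: tuple[str, str]
    n_snps: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must have 5 entries")
        if np.any(self.pp < -1e-12) or abs(self.pp.sum() - 1.0) > 1e-8:
            raise ValueError("pp must be a probability vector")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass
class MultiColocResult:
    clusters: list[dict] = field(default_factory=list)
    dropped_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cl in self.clusters:
            if not (0.0 <= cl["posterior"] <= 1.0):
                raise ValueError("cluster posterior must lie in [0, 1]")


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for one or more variants.

    With shrinkage ``r = W / (W + se^2)`` (W the prior effect variance) and
    ``z = beta / se``: ``lABF = 0.5 log(1 - r) + 0.5 r z^2``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    W = prior_sd ** 2
    r = W / (W + se ** 2)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z ** 2


def trait_labf(tv: TraitVector) -> np.ndarray:
    """Per-SNP lABFs with the trait-type default prior SD."""
    if tv.trait_type == "case-control":
        prior_sd = PRIOR_SD_CC
    else:
        prior_sd = PRIOR_SD_QUANT * float(tv.scale)
    return wakefield_labf(tv.beta, tv.se, prior_sd)


def _pp_from_labf(l1: np.ndarray, l2: np.ndarray,
                  priors: tuple[float, float, float]) -> np.ndarray:
    p1, p2, p12 = priors
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    # H3: distinct causal variants, excluding the shared-index diagonal
    both = lsum1 + lsum2
    with np.errstate(divide="ignore"):
        lh3_body = both + np.log1p(-np.exp(np.clip(lsum12 - both, -np.inf, 0.0)))
    if not np.isfinite(lh3_body):  # degenerate single-SNP region
        lh3_body = -np.inf
    lh3 = np.log(p1) + np.log(p2) + lh3_body
    lh4 = np.log(p12) + lsum12
    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    return np.exp(lall - logsumexp(lall))


def coloc_abf(region: RegionalDataset, trait1: str, trait2: str,
              p1: float = DEFAULT_PRIORS[0], p2: float = DEFAULT_PRIORS[1],
              p12: float = DEFAULT_PRIORS[2], method: str = "single",
              ) -> ColocResult:
    """Single-causal-variant colocalisation of two traits in a region."""
    if region.n_snps < 2:
        raise ValueError("need >= 2 shared variants")
    tv1, tv2 = region.traits[trait1], region.traits[trait2]
    l1, l2 = trait_labf(tv1), trait_labf(tv2)
    pp = _pp_from_labf(l1, l2, (p1, p2, p12))
    lead = (region.variant_ids[int(np.argmax(np.abs(tv1.z)))],
            region.variant_ids[int(np.argmax(np.abs(tv2.z)))])
    return ColocResult(pp, method, lead, region.n_snps, (p1, p2, p12))


def coloc_abf_enumerate(region: RegionalDataset, trait1: str, trait2: str,
                        p1: float = DEFAULT_PRIORS[0], p2: float = DEFAULT_PRIORS[1],
                        p12: float = DEFAULT_PRIORS[2]) -> np.ndarray:
    """Literal enumeration over all causal-variant configurations.

    Independent oracle for :func:`coloc_abf`; O(n^2), small regions only.
    """
    l1 = trait_labf(region.traits[trait1])
    l2 = trait_labf(region.traits[trait2])
    n = region.n_snps
    s0 = 1.0
    s1 = sum(p1 * np.exp(l1[i]) for i in range(n))
    s2 = sum(p2 * np.exp(l2[j]) for j in range(n))
    s3 = sum(p1 * p2 * np.exp(l1[i] + l2[j])
             for i, j in product(range(n), range(n)) if i != j)
    s4 = sum(p12 * np.exp(l1[i] + l2[i]) for i in range(n))
    raw = np.array([s0, s1, s2, s3, s4])
    return raw / raw.sum()


def conditional_sumstats(region: RegionalDataset, trait: str, condition_on: str,
                         mask_r: float = 0.99) -> RegionalDataset:
    """Approximate conditional summary statistics for one trait.

    ``z_cond = (z - r_c z_c) / sqrt(1 - r_c^2)`` with ``r_c`` the signed LD
    with the conditioning variant; betas are rescaled as ``z_cond * se``.
    Variants with \\|r_c\\| >= ``mask_r`` (other than the conditioning variant
    itself, whose conditional z is 0) are removed and reported via attrs.
    """
    c_idx = region.ld.index_of(condition_on)
    r_c = region.ld.r[:, c_idx].copy()
    tv = region.traits[trait]
    z = tv.z
    z_c = z[c_idx]

    removed = [v for i, v in enumerate(region.variant_ids)
               if i != c_idx and abs(r_c[i]) >= mask_r]
    keep_ids = [v for v in region.variant_ids if v not in set(removed)]
    sub = region.subset(keep_ids)
    kidx = [region.ld.index_of(v) for v in keep_ids]
    r_k = r_c[kidx]
    denom = np.sqrt(np.maximum(1.0 - r_k ** 2, 1e-12))
    z_cond = (z[kidx] - r_k * z_c) / denom
    z_cond[sub.ld.index_of(condition_on)] = 0.0

    traits = dict(sub.traits)
    old = traits[trait]
    traits[trait] = TraitVector(z_cond * old.se, old.se, old.trait_type, old.scale)
    out = RegionalDataset(sub.window, sub.ld, traits, sub.positions)
    out.__dict__["masked_variants"] = removed
    return out


def find_signals(region: RegionalDataset, trait: str, p_signal: float = 1e-5,
                 max_signals: int = 3) -> list[str]:
    """Stepwise-conditioning signal detection for one trait.

    Takes the strongest variant, conditions on it, and repeats while the
    conditional lead p-value stays below ``p_signal`` (up to
    ``max_signals`` signals).
    """
    signals: list[str] = []
    current = region
    for _ in range(max_signals):
        tv = current.traits[trait]
        z = np.abs(tv.z)
        lead_i = int(np.argmax(z))
        p = 2 * stats.norm.sf(z[lead_i])
        if p >= p_signal:
            break
        lead = current.variant_ids[lead_i]
        signals.append(lead)
        current = conditional_sumstats(current, trait, lead)
    return signals


def _trait_variants(region: RegionalDataset, trait: str, signals: list[str],
                    r2_mask: float) -> list[tuple[str, RegionalDataset]]:
    """Enumerate the per-trait run variants: single, conditioned, masked."""
    runs = [("single", region)]
    for sec in signals[1:]:
        runs.append((f"conditioned:{sec}", conditional_sumstats(region, trait, sec)))
        lead_idx = region.ld.index_of(sec)
        r = region.ld.r[:, lead_idx]
        keep = [v for i, v in enumerate(region.variant_ids)
                if r[i] ** 2 <= r2_mask or v == sec]
        keep = [v for v in keep if v != sec]
        if len(keep) >= 2:
            runs.append((f"masked:{sec}", region.subset(keep)))
    return runs


def coloc_condmask_average(region: RegionalDataset, trait1: str, trait2: str,
                           max_signals: int = 3, r2_mask: float = 0.01,
                           priors: tuple[float, float, float] = DEFAULT_PRIORS,
                           p_signal: float = 1e-5,
                           ) -> tuple[float, list[ColocResult]]:
    """Average PP4 over single, conditioning and masking colocalisation runs.

    Secondary signals are detected per trait by stepwise conditioning; for
    every combination of per-trait dataset variants a plain ABF
    colocalisation is run on the common variants, and the unweighted mean
    PP4 across runs is returned.  Single-signal regions degenerate to one
    plain run.
    """
    if max_signals < 1:
        raise ValueError("max_signals must be >= 1")
    sig1 = find_signals(region, trait1, p_signal, max_signals)
    sig2 = find_signals(region, trait2, p_signal, max_signals)
    runs1 = _trait_variants(region, trait1, sig1, r2_mask)
    runs2 = _trait_variants(region, trait2, sig2, r2_mask)

    results: list[ColocResult] = []
    for (lab1, reg1), (lab2, reg2) in product(runs1, runs2):
        common = [v for v in reg1.variant_ids if v in set(reg2.variant_ids)]
        if len(common) < 2:
            continue
        a, b = reg1.subset(common), reg2.subset(common)
        merged = RegionalDataset(a.window, a.ld,
                                 {trait1: a.traits[trait1], trait2: b.traits[trait2]},
                                 a.positions)
        res = coloc_abf(merged, trait1, trait2, *priors,
                        method=f"{lab1}|{lab2}")
        results.append(res)
    avg_pp4 = float(np.mean([r.pp4 for r in results]))
    return avg_pp4, results


def _shared_posterior(region: RegionalDataset, traits: list[str],
                      prior_shared: float,
                      p_trait: float = 1e-3) -> tuple[float, str]:
    """Posterior that all listed traits share one causal variant.

    The all-share hypothesis (per-SNP prior ``prior_shared`` on the product
    of lABFs) is weighed against (a) every trait independently null or
    associated at its own variant (per-SNP prior ``p_trait``) and (b) each
    drop-one configuration where the remaining traits share and the dropped
    trait is free.  This makes a flat or discordant trait pull the
    posterior down rather than being absorbed.
    """
    labfs = {t: trait_labf(region.traits[t]) for t in traits}

    def l_share(subset: list[str]) -> float:
        total = np.zeros(region.n_snps)
        for t in subset:
            total += labfs[t]
        return np.log(prior_shared) + logsumexp(total)

    l_assoc = {t: np.log(p_trait) + logsumexp(labfs[t]) for t in traits}
    l_num = l_share(traits)
    terms = [sum(np.logaddexp(0.0, l_assoc[t]) for t in traits), l_num]
    if len(traits) > 2:
        for t in traits:
            rest = [u for u in traits if u != t]
            terms.append(l_share(rest) + np.logaddexp(0.0, l_assoc[t]))
    post = float(np.exp(l_num - logsumexp(terms)))
    total = np.zeros(region.n_snps)
    for t in traits:
        total += labfs[t]
    best = region.variant_ids[int(np.argmax(total))]
    return post, best


def multitrait_coloc(region: RegionalDataset, traits: list[str] | None = None,
                     prior_shared: float = 1e-4, drop_thresh: float = 0.7,
                     ) -> MultiColocResult:
    """Greedy divisive multi-trait clustering on shared-causal posteriors.

    Computes the posterior that all traits share a single causal variant;
    while it is below ``drop_thresh``, the trait whose removal most
    improves the posterior is set aside, and the removed traits are
    clustered recursively.  This is a deliberate simplification of
    branch-and-bound multi-trait colocalisation.
    """
    if traits is None:
        traits = list(region.traits)
    if len(traits) < 2:
        raise ValueError("need >= 2 traits")
    result = MultiColocResult()
    _cluster(region, list(traits), prior_shared, drop_thresh, result)
    return result


def _cluster(region: RegionalDataset, traits: list[str], prior_shared: float,
             drop_thresh: float, result: MultiColocResult) -> None:
    removed: list[str] = []
    current = list(traits)
    while len(current) >= 2:
        post, best = _shared_posterior(region, current, prior_shared)
        if post >= drop_thresh:
            result.clusters.append({"traits": tuple(current), "posterior": post,
                                    "candidate_snp": best})
            break
        # remove the trait whose absence maximises the remaining posterior
        best_post, best_drop = -1.0, None
        for t in current:
            rest = [u for u in current if u != t]
            p_rest, _ = _shared_posterior(region, rest, prior_shared)
            if p_rest > best_post:
                best_post, best_drop = p_rest, t
        removed.append(best_drop)
        current = [u for u in current if u != best_drop]
    else:
        result.dropped_traits.extend(current)
    if len(removed) >= 2:
        _cluster(region, removed, prior_shared, drop_thresh, result)
    else:
        result.dropped_traits.extend(removed)
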