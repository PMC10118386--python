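"""Ground-truth generators for every analysis stage.

All generators are pure functions of their parameters and a seed, return a
:class:`SimTruth` alongside the dataset, and emit objects that satisfy the
invariants of the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import HarmonisedSet
from .io_core import LDMatrix, RegionalDataset, TraitVector
from .ldsc import LDScoreTable
from .signature import ExpressionMatrix

__all__ = [
    "SimTruth",
    "simulate_mr_instruments",
    "simulate_coloc_region",
    "simulate_ldsc_traits",
    "simulate_tumour_cohort",
]


@dataclass
class SimTruth:
    """Generating parameters of a synthetic dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"scenario": self.scenario, "seed": self.seed, **self.params}


def simulate_mr_instruments(j: int = 100, theta: float = 0.5,
                            pleio_mean: float = 0.0, pleio_sd: float = 0.0,
                            n_exp: int = 2_000_000, n_out: int = 100_000,
                            seed: int = 0) -> tuple[HarmonisedSet, SimTruth]:
    """Instrument-level exposure/outcome betas under a linear causal model.

    True exposure effects are \\|N(0.03, 0.01^2)\\|; per-variant SEs scale as
    1/sqrt(N); pleiotropic effects alpha_j ~ N(pleio_mean, pleio_sd^2) are
    drawn independently of instrument strength (InSIDE holds); outcome
    betas are theta * b_X_true + alpha_j plus noise.
    """
    if j < 2:
        raise ValueError("need at least 2 instruments")
    rng = np.random.default_rng(seed)
    bx_true = np.abs(rng.normal(0.03, 0.01, size=j))
    s_x = np.full(j, 1.0 / np.sqrt(n_exp)) * rng.uniform(0.9, 1.1, size=j)
    s_y = np.full(j, 1.0 / np.sqrt(n_out)) * rng.uniform(0.9, 1.1, size=j)
    alpha = rng.normal(pleio_mean, pleio_sd, size=j)
    b_x = rng.normal(bx_true, s_x)
    b_y = rng.normal(theta * bx_true + alpha, s_y)
    ids = [f"rs{1000 + i}" for i in range(j)]
    hs = HarmonisedSet("exposure_sim", "outcome_sim", ids, b_x, s_x, b_y, s_y)
    truth = SimTruth("mr_instruments", seed, {
        "j": j, "theta": theta, "pleio_mean": pleio_mean, "pleio_sd": pleio_sd,
        "n_exp": n_exp, "n_out": n_out, "bx_true": bx_true, "alpha": alpha})
    return hs, truth


def ar1_ld(n_snps: int, rho: float, ids: list[str] | None = None) -> LDMatrix:
    """AR(1) correlation matrix r_ij = rho^|i-j|."""
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    if ids is None:
        ids = [f"snp{i + 1}" for i in range(n_snps)]
    return LDMatrix(ids, r)


def simulate_coloc_region(n_snps: int = 50, rho: float = 0.9,
                          causal_config: dict | None = None,
                          n_per_trait: dict | None = None,
                          trait_types: dict | None = None,
                          seed: int = 0) -> tuple[RegionalDataset, SimTruth]:
    """Regional multi-trait summary statistics over AR(1) LD.

    ``causal_config`` maps trait label -> {snp_index: effect_size} (effects
    in per-SD units); marginal z means are the causal z-vector propagated
    through LD (R @ z_causal), and observed z ~ MVN(mean, R).
    """
    if causal_config is None:
        causal_config = {"trait1": {n_snps // 2: 0.05},
                         "trait2": {n_snps // 2: 0.05}}
    n_per_trait = n_per_trait or {}
    trait_types = trait_types or {}
    rng = np.random.default_rng(seed)
    ld = ar1_ld(n_snps, rho)
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(n_snps))

    traits: dict[str, TraitVector] = {}
    for label, config in causal_config.items():
        n = n_per_trait.get(label, 10_000)
        z_causal = np.zeros(n_snps)
        for idx, eff in config.items():
            if not 0 <= idx < n_snps:
                raise ValueError(f"causal index {idx} outside region")
            z_causal[idx] = eff * np.sqrt(n)
        mean = ld.r @ z_causal
        z_obs = mean + chol @ rng.standard_normal(n_snps)
        se = np.full(n_snps, 1.0 / np.sqrt(n))
        traits[label] = TraitVector(z_obs * se, se,
                                    trait_type=trait_types.get(label, "quantitative"),
                                    scale=1.0 if trait_types.get(label) != "case-control" else 0.5)

    positions = 1_000_000 + np.arange(n_snps) * 1000
    region = RegionalDataset(("1", int(positions[0]), int(positions[-1])),
                             ld, traits, positions)
    truth = SimTruth("coloc_region", seed, {
        "n_snps": n_snps, "rho": rho, "causal_config": causal_config,
        "n_per_trait": dict(n_per_trait)})
    return region, truth


def simulate_ldsc_traits(m: int = 20_000, ld_scores: np.ndarray | None = None,
                         h2_1: float = 0.3, h2_2: float = 0.3, rg: float = 0.0,
                         n1: int = 50_000, n2: int = 50_000, n_overlap: int = 0,
                         seed: int = 0,
                         ) -> tuple[np.ndarray, np.ndarray, LDScoreTable, SimTruth]:
    """Genome-wide z-scores under the polygenic LD-score model.

    Per-SNP marginal effects are bivariate normal with variances
    ``h2 * l_j / M`` and correlation ``rg``; the noise component is
    correlated across traits in proportion to the sample overlap, with
    phenotypic correlation approximated by ``rg * sqrt(h2_1 h2_2)``.
    """
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    if not (0 <= h2_1 <= 1 and 0 <= h2_2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if ld_scores is None:
        ld_scores = 1.0 + rng.gamma(shape=2.0, scale=20.0, size=m)
    ld_scores = np.asarray(ld_scores, dtype=float)
    m = len(ld_scores)

    v1 = h2_1 * ld_scores / m
    v2 = h2_2 * ld_scores / m
    e = rng.standard_normal((m, 2))
    b1 = np.sqrt(v1) * e[:, 0]
    b2 = np.sqrt(v2) * (rg * e[:, 0] + np.sqrt(max(0.0, 1 - rg ** 2)) * e[:, 1])

    r_pheno = rg * np.sqrt(h2_1 * h2_2)
    noise_corr = np.clip(n_overlap / np.sqrt(n1 * n2) * r_pheno, -0.99, 0.99)
    u = rng.standard_normal((m, 2))
    eps1 = u[:, 0]
    eps2 = noise_corr * u[:, 0] + np.sqrt(1 - noise_corr ** 2) * u[:, 1]

    z1 = np.sqrt(n1) * b1 + eps1
    z2 = np.sqrt(n2) * b2 + eps2
    chrom = np.repeat("1", m)
    pos = np.arange(1, m + 1) * 1000
    table = LDScoreTable([f"snp{i + 1}" for i in range(m)], ld_scores, chrom, pos)
    truth = SimTruth("ldsc_traits", seed, {
        "m": m, "h2_1": h2_1, "h2_2": h2_2, "rg": rg,
        "n1": n1, "n2": n2, "n_overlap": n_overlap})
    return z1, z2, table, truth


def simulate_tumour_cohort(n_samples: int = 343, n_genes: int = 1500,
                           n_variants: int = 144, prs_effect: float = 0.17,
                           factor_structure: np.ndarray | None = None,
                           covariate_effects: dict | None = None,
                           nb_dispersion: float = 0.3, n_factors: int = 5,
                           module_size: int = 60, seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionMatrix, SimTruth]:
    """A tumour cohort with a genotype-driven latent factor in NB counts.

    Dosages are Binomial(2, f_j); the latent telomere score is the
    standardised weighted dosage sum; expression factor 2 loads on it with
    coefficient ``prs_effect`` (per SD) plus covariate effects and noise
    scaled to keep the factor near unit variance.  Counts are negative
    binomial around ``exp(baseline_g + loadings_g . F_s)``; factors load on
    disjoint gene modules with decreasing strength so the PCA ordering is
    identifiable.
    """
    if n_factors > 5:
        raise ValueError("at most 5 factors supported")
    covariate_effects = covariate_effects or {"sex": 0.1, "age": 0.05,
                                              "smoking": -0.1, "stage": 0.05}
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(0.1, 0.9, size=n_variants)
    dosages = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(float)
    weights = np.abs(rng.normal(0.03, 0.01, size=n_variants))
    raw = dosages @ weights
    latent = (raw - raw.mean()) / raw.std()

    sex = rng.binomial(1, 0.5, size=n_samples).astype(float)
    age = rng.normal(65, 10, size=n_samples)
    smoking = rng.binomial(1, 0.7, size=n_samples).astype(float)
    stage = rng.integers(1, 5, size=n_samples).astype(float)
    cov = pd.DataFrame({"sex": sex, "age": age, "smoking": smoking, "stage": stage},
                       index=[f"S{i + 1:04d}" for i in range(n_samples)])
    cov_std = (cov - cov.mean()) / cov.std(ddof=0)

    F = rng.standard_normal((n_samples, n_factors))
    cov_part = sum(covariate_effects.get(c, 0.0) * cov_std[c].to_numpy()
                   for c in ("sex", "age", "smoking", "stage"))
    explained = prs_effect ** 2 + float(np.var(cov_part))
    resid_sd = np.sqrt(max(0.05, 1.0 - explained))
    F[:, 1] = prs_effect * latent + cov_part + resid_sd * rng.standard_normal(n_samples)

    if factor_structure is None:
        # disjoint modules, decreasing loading strength: PCA order matches
        strengths = np.array([1.6, 1.2, 0.9, 0.7, 0.55])[:n_factors]
        module_size = min(module_size, max(1, n_genes // (n_factors + 1)))
        Lam = np.zeros((n_genes, n_factors))
        for f in range(n_factors):
            lo = f * module_size
            hi = min(lo + module_size, n_genes)
            Lam[lo:hi, f] = strengths[f] * rng.uniform(0.6, 1.0, size=hi - lo)
    else:
        Lam = np.asarray(factor_structure, dtype=float)

    baseline = rng.normal(4.0, 1.0, size=n_genes)
    log_mu = baseline[:, None] + Lam @ F.T
    mu = np.exp(np.clip(log_mu, -10, 14))
    shape = 1.0 / nb_dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_meta = pd.DataFrame({
        "length": rng.integers(500, 20_000, size=n_genes),
        "gc": rng.uniform(0.3, 0.7, size=n_genes)}, index=gene_ids)
    em = ExpressionMatrix(gene_ids, list(cov.index), counts, gene_meta)
    geno = pd.DataFrame(dosages, index=cov.index,
                        columns=[f"rs{2000 + i}" for i in range(n_variants)])
    truth = SimTruth("tumour_cohort", seed, {
        "n_samples": n_samples, "n_genes": n_genes, "n_variants": n_variants,
        "prs_effect": prs_effect, "covariate_effects": covariate_effects,
        "nb_dispersion": nb_dispersion, "weights": weights, "latent": latent,
        "factors": F, "loadings": Lam})
    return geno, cov, em, truth
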