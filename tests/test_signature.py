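import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telosig.instruments import PRSVector, compute_prs
from telosig.signature import (ExpressionMatrix, align_pcs_rigid,
                               apply_signature, associate_prs_pcs,
                               feature_association, fit_expression_pca,
                               fit_lasso_signature, normalise_counts,
                               top_loading_genes)
from telosig.simulate import simulate_tumour_cohort


def make_counts(n_genes=80, n_samples=40, seed=0, depth=1000):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(2.0, 1.0, size=n_genes)
    counts = rng.poisson(base[:, None] * rng.uniform(0.5, 2.0, size=n_samples)[None, :]
                         * depth / base.sum())
    meta = pd.DataFrame({"length": rng.integers(500, 10_000, n_genes),
                         "gc": rng.uniform(0.3, 0.7, n_genes)},
                        index=[f"g{i}" for i in range(n_genes)])
    return ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                            [f"s{i}" for i in range(n_samples)], counts, meta)


def make_prs(scores, sample_ids):
    scores = np.asarray(scores, dtype=float)
    std = (scores - scores.mean()) / scores.std()
    return PRSVector(list(sample_ids), scores, std)


class TestNormaliseCounts:
    def test_low_count_gene_dropped(self):
        em = make_counts(seed=1)
        em.counts[0] = 0
        em.counts[0, :3] = 6  # expressed in under 20% of 40 samples
        out = normalise_counts(em, min_count=5, min_frac=0.2)
        assert "g0" not in out.index

    def test_depth_doubling_is_exact_noop(self):
        em = make_counts(seed=2)
        doubled = em.counts.copy()
        doubled[:, 0] *= 2
        em2 = ExpressionMatrix(em.gene_ids, em.sample_ids, doubled, em.gene_meta)
        out1 = normalise_counts(em, gc_correct=True)
        out2 = normalise_counts(em2, gc_correct=True)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-6)

    def test_gc_flat_correction_noop(self):
        em = make_counts(seed=3)
        em.gene_meta["gc"] = 0.5
        em.gene_meta["length"] = 1000
        with_gc = normalise_counts(em, gc_correct=True)
        without = normalise_counts(em, gc_correct=False)
        np.testing.assert_allclose(with_gc.to_numpy(), without.to_numpy(),
                                   atol=1e-10)

    def test_all_filtered_error(self):
        em = make_counts(seed=4)
        em.counts[:] = 0
        with pytest.raises(ValueError, match="filter"):
            normalise_counts(em)

    def test_integer_depth_invariance_property(self):
        em = make_counts(seed=5)
        for c in (3, 7):
            scaled = em.counts.copy()
            scaled[:, 5] *= c
            em2 = ExpressionMatrix(em.gene_ids, em.sample_ids, scaled, em.gene_meta)
            np.testing.assert_allclose(
                normalise_counts(em).to_numpy(),
                normalise_counts(em2).to_numpy(), atol=1e-6)


class TestExpressionPCA:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(6)
        factor = rng.standard_normal(30)
        load = rng.standard_normal(50)
        mat = np.outer(load, factor) + 1e-4 * rng.standard_normal((50, 30))
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(30)])
        pc = fit_expression_pca(logmat, k=3, unit_scale=False)
        assert pc.explained_var[0] > 0.99

    def test_outlier_excluded(self):
        rng = np.random.default_rng(7)
        mat = rng.standard_normal((60, 40))
        mat[:, 0] += 30.0  # one sample displaced far along PC1
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(60)],
                              columns=[f"s{i}" for i in range(40)])
        pc = fit_expression_pca(logmat, k=3, outlier_sd=4.0)
        assert "s0" in pc.excluded_samples
        assert "s0" not in pc.sample_ids

    def test_orthonormal_loadings_and_sign_convention(self):
        rng = np.random.default_rng(8)
        logmat = pd.DataFrame(rng.standard_normal((50, 30)))
        logmat.index = [f"g{i}" for i in range(50)]
        logmat.columns = [f"s{i}" for i in range(30)]
        pc = fit_expression_pca(logmat, k=4)
        np.testing.assert_allclose(pc.loadings.T @ pc.loadings, np.eye(4),
                                   atol=1e-10)
        for j in range(4):
            imax = np.argmax(np.abs(pc.loadings[:, j]))
            assert pc.loadings[imax, j] > 0

    def test_eckart_young_reconstruction(self):
        rng = np.random.default_rng(9)
        logmat = pd.DataFrame(rng.standard_normal((30, 25)),
                              index=[f"g{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(25)])
        pc = fit_expression_pca(logmat, k=5, unit_scale=False)
        X = logmat.to_numpy().T
        Z = X - pc.center
        resid = Z - pc.scores @ pc.loadings.T
        s = np.linalg.svd(Z, compute_uv=False)
        assert np.linalg.norm(resid) == pytest.approx(
            np.sqrt(np.sum(s[5:] ** 2)), rel=1e-8)

    def test_k_too_large_error(self):
        logmat = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 8)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError):
            fit_expression_pca(logmat, k=9)

    def test_synthetic_cohort_top5_variance_share(self):
        _, _, em, truth = simulate_tumour_cohort(n_samples=200, n_genes=800,
                                                 seed=10)
        logmat = normalise_counts(em)
        pc = fit_expression_pca(logmat, k=5)
        # five planted factors: top-5 share within +/-10 points of ~0.5
        assert 0.15 < pc.explained_var.sum() < 0.9


class TestTopLoadingGenes:
    def test_planted_module_recovered(self):
        rng = np.random.default_rng(11)
        n_genes, n_samples = 100, 60
        factor = rng.standard_normal(n_samples)
        mat = rng.standard_normal((n_genes, n_samples)) * 0.3
        mat[:15] += np.outer(np.full(15, 2.0), factor)
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(n_samples)])
        pc = fit_expression_pca(logmat, k=3)
        pos, neg = top_loading_genes(pc, logmat, component=1, n_top=500)
        assert set(f"g{i}" for i in range(15)) <= set(pos)

    def test_noise_component_empty(self):
        rng = np.random.default_rng(12)
        logmat = pd.DataFrame(rng.standard_normal((100, 50)),
                              index=[f"g{i}" for i in range(100)],
                              columns=[f"s{i}" for i in range(50)])
        pc = fit_expression_pca(logmat, k=3)
        pos, neg = top_loading_genes(pc, logmat, component=3, n_top=500)
        # pure noise: at most a couple of false positives survive Bonferroni
        assert len(pos) + len(neg) <= 3

    def test_n_top_limit(self):
        rng = np.random.default_rng(13)
        factor = rng.standard_normal(60)
        mat = np.outer(rng.uniform(1, 2, 200), factor)
        mat += rng.standard_normal(mat.shape) * 0.05
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(200)],
                              columns=[f"s{i}" for i in range(60)])
        pc = fit_expression_pca(logmat, k=2)
        pos, neg = top_loading_genes(pc, logmat, component=1, n_top=50)
        assert len(pos) <= 50 and len(neg) <= 50


class TestAssociatePRSPCs:
    def test_orthogonal_prs_beta_zero(self):
        rng = np.random.default_rng(14)
        logmat = pd.DataFrame(rng.standard_normal((80, 50)),
                              index=[f"g{i}" for i in range(80)],
                              columns=[f"s{i}" for i in range(50)])
        pc = fit_expression_pca(logmat, k=2)
        score = pc.scores[:, 0]
        prs_raw = rng.standard_normal(len(score))
        prs_raw -= score * (prs_raw @ score) / (score @ score)
        prs = make_prs(prs_raw, pc.sample_ids)
        tab = associate_prs_pcs(pc, prs)
        assert tab.loc[tab["component"] == 1, "beta"].item() == pytest.approx(
            0.0, abs=1e-10)

    def test_planted_effect_recovered(self):
        n_rep = 30
        betas = []
        for i in range(n_rep):
            geno, cov, em, truth = simulate_tumour_cohort(
                n_samples=250, n_genes=600, prs_effect=0.17, seed=500 + i)
            logmat = normalise_counts(em)
            pc = fit_expression_pca(logmat, k=5)
            prs = compute_prs(geno, pd.Series(truth.params["weights"],
                                              index=geno.columns))
            tab = associate_prs_pcs(pc, prs)
            # identify the component tracking planted factor 2 by correlation
            f2 = truth.params["factors"][:, 1]
            keep = [i_ for i_, s in enumerate(
                [f"S{j + 1:04d}" for j in range(250)]) if s in pc.sample_ids]
            cors = [abs(np.corrcoef(pc.scores[:, c], f2[keep])[0, 1])
                    for c in range(5)]
            comp = int(np.argmax(cors)) + 1
            beta = tab.loc[tab["component"] == comp, "beta"].item()
            betas.append(abs(beta))
        betas = np.array(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(n_rep)
        assert abs(betas.mean() - 0.17) < max(3 * mc_se, 0.17 * 0.25)

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(15)
        logmat = pd.DataFrame(rng.standard_normal((60, 80)),
                              index=[f"g{i}" for i in range(60)],
                              columns=[f"s{i}" for i in range(80)])
        pc = fit_expression_pca(logmat, k=2)
        prs_raw = rng.standard_normal(80)
        pvals = []
        for _ in range(300):
            perm = rng.permutation(80)
            prs = make_prs(prs_raw[perm], pc.sample_ids)
            tab = associate_prs_pcs(pc, prs)
            pvals.append(tab.loc[tab["component"] == 1, "pval"].item())
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestAlignPCsRigid:
    def _pc(self, seed=16, n_genes=40, n_samples=30, k=4):
        rng = np.random.default_rng(seed)
        logmat = pd.DataFrame(rng.standard_normal((n_genes, n_samples)),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(n_samples)])
        return fit_expression_pca(logmat, k=k)

    def test_identity_recovery(self):
        pc = self._pc()
        R, aligned = align_pcs_rigid(pc, pc)
        np.testing.assert_allclose(R, np.eye(pc.k), atol=1e-10)
        np.testing.assert_allclose(aligned, pc.scores, atol=1e-10)

    def test_reflection_recovery(self):
        import copy
        pc = self._pc()
        pc_flip = copy.deepcopy(pc)
        pc_flip.loadings[:, :2] *= -1
        pc_flip.scores[:, :2] *= -1
        R, _ = align_pcs_rigid(pc, pc_flip)
        np.testing.assert_allclose(R, np.diag([-1, -1, 1, 1]), atol=1e-10)

    def test_random_rotation_recovered(self):
        import copy
        from scipy.stats import ortho_group
        pc = self._pc(k=4)
        Q = ortho_group.rvs(4, random_state=17)
        pc_rot = copy.deepcopy(pc)
        pc_rot.loadings = pc.loadings @ Q
        pc_rot.scores = pc.scores @ Q
        R, aligned = align_pcs_rigid(pc, pc_rot)
        np.testing.assert_allclose(R, Q.T, atol=1e-6)
        np.testing.assert_allclose(aligned, pc.scores, atol=1e-6)

    def test_2d_rotation_matches_grid_search_oracle(self):
        import copy
        pc = self._pc(k=2)
        angle = 0.3
        Q = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        pc_rot = copy.deepcopy(pc)
        pc_rot.loadings = pc.loadings @ Q
        pc_rot.scores = pc.scores @ Q
        R, _ = align_pcs_rigid(pc, pc_rot)
        # grid-search oracle over rotation angle
        best_angle, best_err = None, np.inf
        for a in np.linspace(-np.pi, np.pi, 20_001):
            Ra = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            err = np.linalg.norm(pc_rot.loadings @ Ra - pc.loadings)
            if err < best_err:
                best_angle, best_err = a, err
        Rg = np.array([[np.cos(best_angle), -np.sin(best_angle)],
                       [np.sin(best_angle), np.cos(best_angle)]])
        np.testing.assert_allclose(R, Rg, atol=1e-3)

    def test_orthogonality_and_roundtrip(self):
        pc1, pc2 = self._pc(seed=18), self._pc(seed=19)
        R12, _ = align_pcs_rigid(pc1, pc2)
        np.testing.assert_allclose(R12 @ R12.T, np.eye(4), atol=1e-10)
        R21, _ = align_pcs_rigid(pc2, pc1)
        np.testing.assert_allclose(R12 @ R21, np.eye(4), atol=1e-8)

    def test_gene_mismatch_error(self):
        pc1 = self._pc(seed=20)
        pc2 = self._pc(seed=21, n_genes=41)
        with pytest.raises(ValueError, match="gene sets differ"):
            align_pcs_rigid(pc1, pc2)


class TestLassoSignature:
    def test_single_perfect_gene(self):
        rng = np.random.default_rng(22)
        n = 60
        factor = rng.standard_normal(n)
        mat = rng.standard_normal((30, n)) * 0.1
        mat[0] = 5.0 * factor  # one gene reproduces the driver exactly
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(30)],
                              columns=[f"s{i}" for i in range(n)])
        pc = fit_expression_pca(logmat, k=2, unit_scale=False)
        sig = fit_lasso_signature(logmat, pc, component=1, n_boot=30, seed=0)
        assert "g0" in sig.gene_ids
        scores = apply_signature(sig, logmat)
        r2 = np.corrcoef(scores, pc.scores[:, 0])[0, 1] ** 2
        assert r2 > 0.99

    def test_planted_module_selected(self):
        hits = 0
        n_rep = 10
        for i in range(n_rep):
            rng = np.random.default_rng(700 + i)
            n_genes, n = 120, 80
            factor = rng.standard_normal(n)
            mat = rng.standard_normal((n_genes, n)) * 0.5
            module = list(range(10))
            for g in module:
                mat[g] += rng.uniform(1.0, 2.0) * factor
            logmat = pd.DataFrame(mat, index=[f"g{i_}" for i_ in range(n_genes)],
                                  columns=[f"s{i_}" for i_ in range(n)])
            pc = fit_expression_pca(logmat, k=2, unit_scale=False)
            sig = fit_lasso_signature(logmat, pc, component=1, n_boot=30, seed=i)
            outside = [g for g in sig.gene_ids
                       if g not in {f"g{m}" for m in module}]
            if set(sig.gene_ids) & {f"g{m}" for m in module} and len(outside) <= 2:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_no_screened_genes_error(self):
        rng = np.random.default_rng(23)
        logmat = pd.DataFrame(rng.standard_normal((20, 30)),
                              index=[f"g{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(30)])
        pc = fit_expression_pca(logmat, k=2)
        with pytest.raises(ValueError, match="FDR screen"):
            fit_lasso_signature(logmat, pc, component=2, fdr_q=1e-12,
                                n_boot=10, seed=0)

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(24)
        factor = rng.standard_normal(50)
        mat = rng.standard_normal((40, 50)) * 0.5
        mat[:8] += np.outer(rng.uniform(1, 2, 8), factor)
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(40)],
                              columns=[f"s{i}" for i in range(50)])
        pc = fit_expression_pca(logmat, k=2, unit_scale=False)
        s1 = fit_lasso_signature(logmat, pc, component=1, n_boot=20, seed=9)
        s2 = fit_lasso_signature(logmat, pc, component=1, n_boot=20, seed=9)
        assert s1.gene_ids == s2.gene_ids
        np.testing.assert_allclose(s1.coefficients, s2.coefficients)


class TestApplySignature:
    def _fitted(self, seed=25):
        rng = np.random.default_rng(seed)
        factor = rng.standard_normal(60)
        mat = rng.standard_normal((50, 60)) * 0.4
        mat[:10] += np.outer(rng.uniform(1, 2, 10), factor)
        logmat = pd.DataFrame(mat, index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(60)])
        pc = fit_expression_pca(logmat, k=2, unit_scale=False)
        sig = fit_lasso_signature(logmat, pc, component=1, n_boot=20, seed=0)
        return logmat, pc, sig

    def test_self_application_correlates(self):
        logmat, pc, sig = self._fitted()
        scores = apply_signature(sig, logmat)
        assert abs(np.corrcoef(scores, pc.scores[:, 0])[0, 1]) > 0.99

    def test_missing_gene_error(self):
        logmat, _, sig = self._fitted()
        target = logmat.drop(index=sig.gene_ids[0])
        with pytest.raises(ValueError, match="lacks signature genes"):
            apply_signature(sig, target)

    def test_gene_order_invariance(self):
        logmat, _, sig = self._fitted()
        shuffled = logmat.sample(frac=1, random_state=3)
        np.testing.assert_allclose(apply_signature(sig, logmat).to_numpy(),
                                   apply_signature(sig, shuffled).to_numpy())

    def test_non_signature_gene_rescaling_invariance(self):
        logmat, _, sig = self._fitted()
        other = [g for g in logmat.index if g not in sig.gene_ids][0]
        rescaled = logmat.copy()
        rescaled.loc[other] = rescaled.loc[other] * 5 + 2
        np.testing.assert_allclose(apply_signature(sig, logmat).to_numpy(),
                                   apply_signature(sig, rescaled).to_numpy())

    def test_zero_variance_gene_dropped_with_flag(self):
        logmat, _, sig = self._fitted()
        target = logmat.copy()
        if len(sig.gene_ids) < 2:
            pytest.skip("need >= 2 signature genes for the drop path")
        target.loc[sig.gene_ids[0]] = 1.0
        scores = apply_signature(sig, target)
        assert scores.attrs["dropped_genes"] == [sig.gene_ids[0]]

    def test_all_identical_samples_error(self):
        logmat, _, sig = self._fitted()
        target = logmat.copy()
        target.loc[:, :] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            apply_signature(sig, target)

    def test_frozen_scaling_mode(self):
        logmat, _, sig = self._fitted()
        s_frozen = apply_signature(sig, logmat, frozen_scaling=True)
        s_target = apply_signature(sig, logmat, frozen_scaling=False)
        np.testing.assert_allclose(s_frozen.to_numpy(), s_target.to_numpy(),
                                   atol=1e-8)


class TestFeatureAssociation:
    def _data(self, seed=26, n=200):
        rng = np.random.default_rng(seed)
        features = pd.DataFrame({
            "age": rng.normal(65, 10, n),
            "gender": rng.binomial(1, 0.5, n).astype(float),
            "smoking": rng.binomial(1, 0.6, n).astype(float),
            "prs": rng.standard_normal(n),
        }, index=[f"s{i}" for i in range(n)])
        return rng, features

    def test_planted_multivariate_recovery(self):
        n_rep = 60
        coefs = {"age": [], "gender": [], "prs": []}
        true = {"age": 0.3, "gender": 0.5, "prs": 0.2}
        for i in range(n_rep):
            rng, F = self._data(seed=900 + i)
            z = F.copy()
            z["age"] = (z["age"] - z["age"].mean()) / z["age"].std()
            y = (true["age"] * z["age"] + true["gender"] * z["gender"]
                 + true["prs"] * z["prs"] + rng.standard_normal(len(F)))
            tab = feature_association(pd.Series(y.to_numpy(), index=F.index), F)
            sd_y = y.std()
            for k in coefs:
                coefs[k].append(
                    tab.loc[tab["term"] == k, "beta"].item() * sd_y)
        for k, vals in coefs.items():
            vals = np.array(vals)
            target = true[k] * (F[k].std() if k == "prs" else 1.0)
            # outcome standardisation rescales; compare on the raw scale
            mc = vals.std(ddof=1) / np.sqrt(n_rep)
            expected = true[k] if k != "age" else true[k]
            assert abs(vals.mean() - expected) < 3 * mc + 0.02 * abs(expected)

    def test_uncorrelated_feature_near_zero(self):
        rng, F = self._data(seed=27)
        y = pd.Series(rng.standard_normal(len(F)), index=F.index)
        tab = feature_association(y, F, mode="univariate")
        row = tab[tab["term"] == "prs"].iloc[0]
        assert abs(row["beta"]) < 3 * row["se"]

    def test_univariate_prs_ancestry_adjusted(self):
        rng, F = self._data(seed=28)
        anc = pd.DataFrame(rng.standard_normal((len(F), 5)),
                           index=F.index,
                           columns=[f"ancestry_pc{i}" for i in range(1, 6)])
        y = pd.Series(F["prs"] + rng.standard_normal(len(F)), index=F.index)
        tab = feature_association(y, F, mode="univariate",
                                  prs_ancestry_covariates=anc)
        assert tab[tab["term"] == "prs"]["pval"].item() < 0.01

    def test_rank_deficiency_names_alias(self):
        rng, F = self._data(seed=29)
        F["smoking_copy"] = F["smoking"]
        y = pd.Series(rng.standard_normal(len(F)), index=F.index)
        with pytest.raises(ValueError, match="smoking_copy"):
            feature_association(y, F)


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_effect(self):
        # PRS -> normalisation -> PCA -> alignment -> LASSO -> association
        n_rep = 8
        inferred_cors, betas = [], []
        for i in range(n_rep):
            geno, cov, em, truth = simulate_tumour_cohort(
                n_samples=343, n_genes=900, prs_effect=0.17, seed=40 + i)
            rng = np.random.default_rng(1000 + i)
            samples = np.array(em.sample_ids)
            order = rng.permutation(len(samples))
            train = sorted(samples[order[:240]])
            val = sorted(samples[order[240:]])

            logmat = normalise_counts(em)
            lm_train, lm_val = logmat[train], logmat[val]
            pc_train = fit_expression_pca(lm_train, k=5)
            pc_val = fit_expression_pca(lm_val, k=5)
            R, aligned_scores = align_pcs_rigid(pc_train, pc_val)

            f2 = pd.Series(truth.params["factors"][:, 1], index=samples)
            cors = [abs(np.corrcoef(pc_train.scores[:, c],
                                    f2[pc_train.sample_ids])[0, 1])
                    for c in range(5)]
            comp = int(np.argmax(cors)) + 1

            sig = fit_lasso_signature(lm_train, pc_train, component=comp,
                                      n_boot=20, seed=i)
            inferred = apply_signature(sig, lm_val)
            obs = aligned_scores[:, comp - 1]
            keep = [j for j, s in enumerate(pc_val.sample_ids) if s in inferred.index]
            r = np.corrcoef(inferred[np.array(pc_val.sample_ids)[keep]],
                            obs[keep])[0, 1]
            inferred_cors.append(abs(r))

            prs = compute_prs(geno, pd.Series(truth.params["weights"],
                                              index=geno.columns))
            tab = associate_prs_pcs(pc_train, prs)
            betas.append(abs(tab.loc[tab["component"] == comp, "beta"].item()))

        assert np.mean(np.array(inferred_cors) > 0.9) >= 0.75
        mean_beta = np.mean(betas)
        assert abs(mean_beta - 0.17) < 0.25 * 0.17
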