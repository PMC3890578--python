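"""Normalization, gene filters, outlier rules and surrogate covariates."""

import numpy as np
import pandas as pd
import pytest

from eqtlqc import exprqc, synth


@pytest.fixture(scope="module")
def biased_expression():
    cfg = synth.SimulationConfig(
        n_samples=30, n_snps=300, n_genes=400, n_true_eqtls=0,
        n_null_catalog=20, batch_effect_sd=0.0, per_gene_outlier_rate=0.0,
        seed=55,
    )
    gm = synth.simulate_genotypes(cfg)
    expr, _ = synth.simulate_expression(gm, cfg)
    return expr


class TestNormalize:
    def test_log2_depth_invariant_to_sequencing_depth(self):
        counts = np.array([[10, 20], [30, 60], [5, 10]])
        out = exprqc.normalize(counts, method="log2_depth")
        assert np.allclose(out[:, 0], out[:, 1])

    def test_constant_matrix_stays_constant_through_gc_quantile(self):
        counts = np.full((50, 4), 9.0)
        ann = pd.DataFrame({"gc": np.linspace(0.3, 0.7, 50)})
        out = exprqc.normalize(counts, ann, "gc_quantile")
        assert np.allclose(out, out[0, 0])

    def test_gc_quantile_removes_most_of_the_gc_trend(self, biased_expression):
        expr = biased_expression
        gc = expr.genes["gc"].to_numpy()
        slopes = {}
        for method in ("log2_depth", "gc_quantile"):
            log2 = exprqc.normalize(expr.counts, expr.genes, method)
            slopes[method] = abs(np.polyfit(gc, log2.mean(axis=1), 1)[0])
        assert slopes["gc_quantile"] < 0.5 * slopes["log2_depth"]

    def test_external_matrix_ingested_and_shape_checked(self):
        counts = np.ones((4, 3))
        ext = np.arange(12, dtype=float).reshape(4, 3)
        assert (exprqc.normalize(counts, method="external", external=ext) == ext).all()
        with pytest.raises(ValueError):
            exprqc.normalize(counts, method="external", external=ext[:2])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            exprqc.normalize(np.ones((2, 2)), method="tpm")

    def test_order_invariance(self, biased_expression, rng):
        expr = biased_expression
        log2 = exprqc.normalize(expr.counts, expr.genes, "gc_quantile")
        gperm = rng.permutation(expr.n_genes)
        sperm = rng.permutation(expr.n_samples)
        log2p = exprqc.normalize(
            expr.counts[gperm][:, sperm],
            expr.genes.iloc[gperm].reset_index(drop=True),
            "gc_quantile",
        )
        assert np.allclose(log2p, log2[gperm][:, sperm])


class TestFilterGenes:
    def test_boundaries_inclusive(self):
        log2 = np.array([[50.0, 49.9], [50.0, 50.0], [0.0, 0.0]])
        counts = np.array([[5, 4], [5, 5], [0, 0]])
        analysis, decomposition = exprqc.filter_genes(log2, counts)
        assert list(analysis) == [False, True, False]  # 99.9 < 100 <= 100
        assert list(decomposition) == [False, True, False]  # 9 < 10 <= 10

    def test_all_zero_gene_excluded_from_both(self):
        log2 = np.zeros((1, 5))
        counts = np.zeros((1, 5))
        analysis, decomposition = exprqc.filter_genes(log2, counts)
        assert not analysis[0] and not decomposition[0]


class TestPcaSampleOutliers:
    def test_injected_global_outlier_flagged(self):
        cfg = synth.SimulationConfig(
            n_samples=40, n_snps=200, n_genes=200, n_true_eqtls=0,
            n_null_catalog=10, per_gene_outlier_rate=0.0,
            global_outlier_samples=(("S010", 10.0),), seed=13,
        )
        gm = synth.simulate_genotypes(cfg)
        expr, truth = synth.simulate_expression(gm, cfg)
        log2 = exprqc.normalize(expr.counts, expr.genes)
        flags, _, _ = exprqc.pca_sample_outliers(log2)
        assert flags[expr.sample_index("S010")]

    def test_five_sd_outliers_always_caught(self):
        # the 6-PC / 3-SD rule catches every >=5-SD global shift at n >= 30
        for seed in range(50):
            cfg = synth.SimulationConfig(
                n_samples=30, n_snps=100, n_genes=120, n_true_eqtls=0,
                n_null_catalog=5, per_gene_outlier_rate=0.0,
                global_outlier_samples=(("S005", 5.0),), seed=1000 + seed,
            )
            gm = synth.simulate_genotypes(cfg)
            expr, _ = synth.simulate_expression(gm, cfg)
            log2 = exprqc.normalize(expr.counts, expr.genes)
            flags, _, _ = exprqc.pca_sample_outliers(log2)
            assert flags[expr.sample_index("S005")], f"missed at seed {seed}"

    def test_homogeneous_data_rarely_flags(self):
        # null flag rate matches the 3-SD tail: a handful at most at n=60
        n_flags = []
        for seed in range(10):
            cfg = synth.SimulationConfig(
                n_samples=60, n_snps=100, n_genes=150, n_true_eqtls=0,
                n_null_catalog=5, batch_effect_sd=0.0,
                per_gene_outlier_rate=0.0, seed=2000 + seed,
            )
            gm = synth.simulate_genotypes(cfg)
            expr, _ = synth.simulate_expression(gm, cfg)
            log2 = exprqc.normalize(expr.counts, expr.genes)
            flags, _, _ = exprqc.pca_sample_outliers(log2)
            n_flags.append(flags.sum())
        # per run the expected count is ~6 PCs * 60 samples * P(|z|>3);
        # occasional flags are normal, many are not
        assert np.mean(n_flags) < 2
        assert max(n_flags) <= 4

    def test_infinite_threshold_flags_nothing(self, biased_expression):
        log2 = exprqc.normalize(
            biased_expression.counts, biased_expression.genes
        )
        flags, _, _ = exprqc.pca_sample_outliers(log2, sd_threshold=np.inf)
        assert not flags.any()

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError):
            exprqc.pca_sample_outliers(np.random.default_rng(0).normal(size=(20, 5)), n_pcs=5)


class TestPerGeneOutliers:
    def test_injected_entry_masked_exactly(self):
        cfg = synth.SimulationConfig(
            n_samples=40, n_snps=200, n_genes=300, n_true_eqtls=0,
            n_null_catalog=10, per_gene_outlier_rate=0.002,
            per_gene_outlier_shift=10.0, batch_effect_sd=0.0, seed=14,
        )
        gm = synth.simulate_genotypes(cfg)
        expr, truth = synth.simulate_expression(gm, cfg)
        log2 = exprqc.normalize(expr.counts, expr.genes)
        mask, frac = exprqc.per_gene_outliers(log2)
        assert truth.per_gene_outliers, "fixture should contain outliers"
        for gene_id, sample in truth.per_gene_outliers:
            gi = expr.gene_index(gene_id)
            si = expr.sample_index(sample)
            assert mask[gi, si], f"missed injected outlier {gene_id}/{sample}"
        assert frac > 0

    def test_constant_gene_produces_no_flags(self):
        x = np.vstack([np.full(10, 3.0), np.arange(10.0)])
        mask, _ = exprqc.per_gene_outliers(x)
        assert not mask[0].any()

    def test_exactly_three_sd_not_flagged(self):
        # nine zeros and a ten: population sd = 3, deviation = 9 = 3*sd
        # exactly; the strict inequality leaves it unflagged
        x = np.array([[0.0] * 9 + [10.0]])
        mask, _ = exprqc.per_gene_outliers(x, sd_threshold=3.0)
        assert not mask.any()
        # with ten zeros the lone spike sits at sqrt(10) > 3 SDs: flagged
        x2 = np.array([[0.0] * 10 + [10.0]])
        mask2, _ = exprqc.per_gene_outliers(x2, sd_threshold=3.0)
        assert mask2[0, -1]

    def test_null_rate_matches_gaussian_tail(self):
        # with no injected outliers the masked-entry rate tracks the 3-SD
        # tail of the noise law (non-zero, small)
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(400, 60))
            mask, _ = exprqc.per_gene_outliers(x)
            rates.append(mask.mean())
        # N(0,1) tail beyond 3 sample-SDs is slightly below 0.0027
        assert 0.0 < np.mean(rates) < 0.004

    def test_masking_nearly_idempotent_per_gene(self):
        # the rule is single-pass by design; excluding flagged entries
        # shrinks the per-gene SD, so a second pass can add flags — but
        # only at a tiny fraction of genes
        total_genes = new_flag_genes = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(100, 40))
            m1, _ = exprqc.per_gene_outliers(x)
            m2, _ = exprqc.per_gene_outliers(x, prior_mask=m1)
            total_genes += x.shape[0]
            new_flag_genes += int(((m2 & ~m1).any(axis=1)).sum())
        assert new_flag_genes / total_genes < 0.05

    def test_order_invariance(self, rng):
        x = rng.normal(size=(50, 20))
        x[3, 7] += 10
        mask, _ = exprqc.per_gene_outliers(x)
        perm = rng.permutation(20)
        maskp, _ = exprqc.per_gene_outliers(x[:, perm])
        assert (maskp == mask[:, perm]).all()


class TestSurrogates:
    def test_batch_recovered_by_first_pc(self):
        cfg = synth.SimulationConfig(
            n_samples=40, n_snps=200, n_genes=300, n_true_eqtls=0,
            n_null_catalog=10, batch_effect_sd=2.0, noise_sd=0.25,
            per_gene_outlier_rate=0.0, seed=15,
        )
        gm = synth.simulate_genotypes(cfg)
        expr, _ = synth.simulate_expression(gm, cfg)
        cov = synth.simulate_covariates(cfg)
        log2 = exprqc.normalize(expr.counts, expr.genes)
        scores = exprqc.compute_surrogates(log2, n_components=2)
        batch = cov["site"].to_numpy(dtype=float)
        r = abs(np.corrcoef(scores[:, 0], batch)[0, 1])
        assert r > 0.8

    def test_zero_components_yield_empty_set(self):
        out = exprqc.compute_surrogates(np.ones((5, 8)), n_components=0)
        assert out.shape == (8, 0)

    def test_identical_samples_give_zero_scores(self):
        x = np.tile(np.arange(6.0)[:, None], (1, 5))
        scores = exprqc.compute_surrogates(x, n_components=2)
        assert np.allclose(scores, 0.0, atol=1e-10)

    def test_rank_limit_enforced(self):
        with pytest.raises(ValueError):
            exprqc.compute_surrogates(np.ones((3, 5)), n_components=4)

    def test_empty_decomposition_set_rejected(self):
        with pytest.raises(ValueError):
            exprqc.compute_surrogates(
                np.ones((3, 5)), decomposition_genes=np.zeros(3, dtype=bool)
            )
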