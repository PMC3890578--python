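"""cis windowing, the regression engine vs an independent OLS oracle,
inflation adjustment and Storey q-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from eqtlqc import eqtl
from eqtlqc.datatypes import MISSING


class TestCisPairs:
    def _frames(self, snp_pos, gene_start, gene_end):
        snps = pd.DataFrame(
            {"snp_id": ["s1"], "chrom": ["chr1"], "pos": [snp_pos]}
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "chrom": ["chr1"],
                "start": [gene_start],
                "end": [gene_end],
            }
        )
        return snps, genes

    @pytest.mark.parametrize(
        "snp_pos,expected",
        [
            (3_000_000, True),   # exactly 1 Mb from the 3' end: inclusive
            (3_000_001, False),  # one bp beyond
            (1_500_000, True),   # inside the gene body
            (1, True),           # 1 Mb window upstream boundary region
        ],
    )
    def test_window_boundaries(self, snp_pos, expected):
        snps, genes = self._frames(snp_pos, 1_000_000, 2_000_000)
        pairs = eqtl.cis_pairs(snps, genes, window=1_000_000)
        assert (len(pairs) == 1) == expected

    def test_different_chromosome_never_cis(self):
        snps = pd.DataFrame(
            {"snp_id": ["s1"], "chrom": ["chr2"], "pos": [1_500_000]}
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "chrom": ["chr1"],
                "start": [1_000_000],
                "end": [2_000_000],
            }
        )
        assert len(eqtl.cis_pairs(snps, genes)) == 0


def _sm_oracle(y, g, covs=None):
    import statsmodels.api as sm

    X = np.column_stack([g] + ([covs] if covs is not None else []))
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return fit.params[1], fit.bse[1], fit.pvalues[1]


class TestEqtlRegression:
    def test_exact_linear_relationship(self):
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2])
        res = eqtl.eqtl_regression(2.0 * g, g)
        assert res.beta == pytest.approx(2.0)
        assert res.p_raw == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_oracle_with_covariates_and_mask(self, rng):
        for _ in range(100):
            n = 30
            g = rng.integers(0, 3, n).astype(float)
            covs = rng.normal(size=(n, 2))
            y = 0.4 * g + covs @ np.array([0.5, -0.2]) + rng.normal(size=n)
            mask = rng.random(n) < 0.15
            if np.unique(g[~mask]).size < 2:
                continue
            res = eqtl.eqtl_regression(y, g, covs, mask)
            b, se, p = _sm_oracle(y[~mask], g[~mask], covs[~mask])
            assert res.beta == pytest.approx(b, rel=1e-8)
            assert res.se == pytest.approx(se, rel=1e-8)
            assert res.p_raw == pytest.approx(p, rel=1e-6, abs=1e-12)

    def test_missing_genotypes_dropped_pairwise(self, rng):
        n = 40
        g = rng.integers(0, 3, n)
        y = 0.5 * g + rng.normal(size=n)
        g_miss = g.copy()
        g_miss[:5] = MISSING
        res = eqtl.eqtl_regression(y, g_miss)
        b, se, p = _sm_oracle(y[5:], g[5:].astype(float))
        assert res.n == n - 5
        assert res.beta == pytest.approx(b, rel=1e-8)

    def test_constant_genotype_reported_untested(self):
        res = eqtl.eqtl_regression(np.arange(10.0), np.ones(10))
        assert not res.tested
        assert res.reason == "constant genotype"

    def test_collinear_covariates_raise_naming_columns(self, rng):
        n = 20
        g = rng.integers(0, 3, n).astype(float)
        c = rng.normal(size=n)
        covs = np.column_stack([c, 2 * c])
        with pytest.raises(eqtl.CollinearityError):
            eqtl.eqtl_regression(rng.normal(size=n), g, covs)

    def test_permuted_genotype_pvalues_uniform(self, rng):
        # permutation oracle: under exchangeability p is Uniform(0,1)
        n = 50
        g = rng.integers(0, 3, n)
        y = rng.normal(size=n)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(n)
            res = eqtl.eqtl_regression(y, g[perm])
            ps.append(res.p_raw)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGenomicLambda:
    def test_all_half_pvalues_give_exactly_one(self):
        assert eqtl.genomic_lambda(np.full(500, 0.5)) == pytest.approx(1.0)

    def test_uniform_pvalues_give_about_one(self, rng):
        p = rng.random(10_000)
        assert eqtl.genomic_lambda(p) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self, rng):
        p = rng.random(5000)
        chi = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi, 1)
        lam1 = eqtl.genomic_lambda(p)
        lam2 = eqtl.genomic_lambda(p2)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_small_input_warns_empty_raises(self):
        with pytest.warns(UserWarning):
            eqtl.genomic_lambda(np.full(10, 0.5))
        with pytest.raises(ValueError):
            eqtl.genomic_lambda(np.array([]))


class TestGcAdjust:
    def test_identity_at_lambda_one_and_below(self, rng):
        p = rng.random(100)
        assert np.allclose(eqtl.gc_adjust(p, 1.0), p)
        assert np.allclose(eqtl.gc_adjust(p, 0.8), p)  # no deflation

    def test_known_value_against_chi2_oracle(self):
        # chi2 quantile of 0.05 is 3.8415; /2 = 1.9207 -> sf ~ 0.1658
        out = eqtl.gc_adjust(np.array([0.05]), 2.0)[0]
        oracle = stats.chi2.sf(stats.chi2.isf(0.05, 1) / 2.0, 1)
        assert out == pytest.approx(oracle)
        assert out == pytest.approx(0.1658, abs=5e-4)

    def test_inflation_strictly_increases_pvalues(self, rng):
        p = rng.random(200) * 0.999 + 1e-6
        adj = eqtl.gc_adjust(p, 1.7)
        assert (adj > p).all()

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            eqtl.gc_adjust(np.array([0.0]), 1.5)
        with pytest.raises(ValueError):
            eqtl.gc_adjust(np.array([0.5]), 0.0)


def _storey_q_oracle(p, pi0):
    """Independent definition: q_i = min over thresholds t >= p_i of
    pi0 * m * t / #{p <= t}."""
    p = np.asarray(p)
    m = p.size
    q = np.empty(m)
    for i, pi in enumerate(p):
        cands = p[p >= pi]
        q[i] = min(
            min(pi0 * m * t / (p <= t).sum() for t in cands), 1.0
        )
    return q


class TestStoreyQ:
    def test_matches_bruteforce_threshold_definition(self, rng):
        for _ in range(20):
            p = rng.random(40)
            q, pi0 = eqtl.storey_q(p)
            assert np.allclose(q, _storey_q_oracle(p, pi0), atol=1e-12)

    def test_pi0_formula_by_hand(self):
        p = np.array([0.1, 0.2, 0.6, 0.8, 0.9])
        # 3 of 5 p-values above 0.5 -> pi0 = 3 / (5 * 0.5) = 1.2 -> clipped
        _, pi0 = eqtl.storey_q(p, lambda0=0.5)
        assert pi0 == 1.0
        p2 = np.array([0.1, 0.2, 0.3, 0.4, 0.9])
        _, pi02 = eqtl.storey_q(p2, lambda0=0.5)
        assert pi02 == pytest.approx(1 / 2.5)

    def test_degenerate_single_pvalue(self):
        q, pi0 = eqtl.storey_q(np.array([0.01]), lambda0=0.5)
        assert pi0 == 0.0
        assert q[0] == 0.0

    def test_uniform_pvalues_give_pi1_near_zero(self, rng):
        p = rng.random(1000)
        assert eqtl.pi1(p) == pytest.approx(0.0, abs=0.08)

    def test_half_signal_mixture_recovers_pi1(self, rng):
        # E[pi1] = 0.5 for a 50/50 null/signal mixture; average over draws
        # to suppress the binomial noise of the tail count
        vals = [
            eqtl.pi1(np.concatenate([rng.random(500), np.full(500, 1e-8)]))
            for _ in range(10)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_all_tiny_pvalues_give_pi1_one(self):
        assert eqtl.pi1(np.full(20, 1e-7)) == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=50
        )
    )
    def test_q_monotone_in_p_and_order_invariant(self, plist):
        p = np.array(plist)
        q, _ = eqtl.storey_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        shuffled = np.random.default_rng(0).permutation(p.size)
        q2, _ = eqtl.storey_q(p[shuffled])
        assert np.allclose(q2, q[shuffled])
        assert ((q >= 0) & (q <= 1)).all()


class TestReplicationAndComparison:
    def test_report_on_clean_fixture(self, small_bundle):
        from eqtlqc import exprqc

        b = small_bundle
        b.expression.log2values = exprqc.normalize(
            b.expression.counts, b.expression.genes
        )
        gw = eqtl.cis_pairs(b.genotypes.snps, b.expression.genes)
        gw = gw.iloc[
            np.sort(
                np.random.default_rng(0).choice(len(gw), 1500, replace=False)
            )
        ]
        rep = eqtl.replication_report(
            b.catalog, b.genotypes, b.expression, None, gw, "none"
        )
        # 30% planted at a well-powered effect: replication well above null
        assert rep.pct_p05 > 0.15
        assert rep.pi1 > 0.1
        assert 0.8 < rep.lambda_gw < 1.3
        assert rep.n_tested + rep.n_untested == len(b.catalog)

    def test_compare_marks_best_condition(self):
        base = dict(
            per_pair=pd.DataFrame(), lambda_gw=1.0, pct_q05=0.1,
            n_tested=100, n_untested=0,
        )
        from eqtlqc.datatypes import ReplicationReport

        a = ReplicationReport(condition_label="a", pct_p05=0.2, pi1=0.1, **base)
        b = ReplicationReport(condition_label="b", pct_p05=0.3, pi1=0.4, **base)
        table = eqtl.compare_conditions([a, b])
        assert table.loc[table["condition"] == "b", "best_pct_p05"].item()
        assert table.loc[table["condition"] == "b", "best_pi1"].item()
        with pytest.raises(ValueError):
            eqtl.compare_conditions([a, a])
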