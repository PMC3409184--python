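"""Expression mixture, window enrichment and replication statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import strainscan as ss
from strainscan.enrichment import (
    EnrichmentError,
    classify_expression,
    expression_enrichment,
    gc_corrected_p,
)


def _draw_mixture(rng, n, w2=0.55, m=(2.0, 6.5), s=(0.5, 1.0)):
    labels = rng.random(n) < w2
    return np.where(labels, rng.normal(m[1], s[1], n), rng.normal(m[0], s[0], n))


class TestFitMixture2:
    def test_recovers_well_separated_components(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = _draw_mixture(rng, 4000)
            model = ss.fit_mixture2(x)
            assert model.converged
            assert model.means[0] == pytest.approx(2.0, abs=0.2)
            assert model.means[1] == pytest.approx(6.5, abs=0.2)
            assert model.weights[1] == pytest.approx(0.55, abs=0.05)

    def test_agrees_with_sklearn_gaussian_mixture(self):
        sklearn_mix = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(1)
        x = _draw_mixture(rng, 5000)
        mine = ss.fit_mixture2(x)
        gm = sklearn_mix.GaussianMixture(2, n_init=3, random_state=0).fit(x[:, None])
        ref_means = np.sort(gm.means_.ravel())
        np.testing.assert_allclose(mine.means, ref_means, atol=0.05)

    def test_single_component_data_is_flagged(self):
        rng = np.random.default_rng(2)
        model = ss.fit_mixture2(rng.normal(5.0, 0.3, 2000))
        # one component starves or the two collapse; either way flagged or
        # means nearly coincide
        assert model.flagged or abs(model.means[1] - model.means[0]) < 0.5

    def test_canonical_order_is_independent_of_data_order(self):
        rng = np.random.default_rng(3)
        x = _draw_mixture(rng, 3000)
        a = ss.fit_mixture2(x)
        b = ss.fit_mixture2(x[::-1])
        np.testing.assert_allclose(a.means, b.means, atol=1e-6)
        assert a.means[0] < a.means[1]

    def test_needs_ten_values(self):
        with pytest.raises(EnrichmentError):
            ss.fit_mixture2(np.arange(5.0))


class TestExpressionCutoffs:
    def _model(self, w=(0.5, 0.5), m=(2.0, 6.0), s=(1.0, 1.0)):
        return ss.MixtureModel(
            weights=np.array(w), means=np.array(m), sds=np.array(s),
            loglik=0.0, n_iter=1, converged=True,
        )

    def test_symmetric_components_straddle_the_midpoint(self):
        model = self._model()
        hi, lo = ss.expression_cutoffs(model, 0.95)
        mid = 4.0
        assert lo < mid < hi
        assert hi - mid == pytest.approx(mid - lo, abs=1e-9)

    def test_posterior_at_cutoff_equals_the_confidence(self):
        rng = np.random.default_rng(4)
        model = ss.fit_mixture2(_draw_mixture(rng, 4000))
        hi, lo = ss.expression_cutoffs(model, 0.95)
        assert float(model.posterior_high(hi)) == pytest.approx(0.95, abs=1e-6)
        assert float(model.posterior_high(lo)) == pytest.approx(0.05, abs=1e-6)

    def test_cutoff_lies_between_the_component_peaks(self):
        rng = np.random.default_rng(5)
        model = ss.fit_mixture2(_draw_mixture(rng, 4000))
        hi, lo = ss.expression_cutoffs(model, 0.95)
        assert 2.0 < hi < 6.5
        assert 2.0 < lo < 6.5 or lo < hi  # ambiguous band sits between peaks

    def test_invalid_confidence_rejected(self):
        with pytest.raises(EnrichmentError):
            ss.expression_cutoffs(self._model(), 0.4)


class TestGenesNearHits:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [100, 600_000, 2_000_000, 100],
            "end": [500, 650_000, 2_050_000, 500],
        })

    def test_closed_interval_boundary_is_included(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [100], "end": [500]})
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [500 + 10_000]})
        assert ss.genes_near_hits(genes, hits, window=10_000) == {"g"}
        hits2 = pd.DataFrame({"chrom": ["chr1"], "pos": [500 + 10_001]})
        assert ss.genes_near_hits(genes, hits2, window=10_000) == set()

    def test_no_hits_empty_set(self):
        assert ss.genes_near_hits(self._genes(), pd.DataFrame(columns=["chrom", "pos"])) == set()

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(6)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "start": rng.integers(1, 5_000_000, 200),
        })
        genes["end"] = genes["start"] + rng.integers(1_000, 100_000, 200)
        hits = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], 30),
            "pos": rng.integers(1, 5_000_000, 30),
        })
        w = 250_000
        got = ss.genes_near_hits(genes, hits, window=w)
        expected = set()
        for _, g in genes.iterrows():
            for _, h in hits.iterrows():
                if g["chrom"] == h["chrom"] and g["end"] >= h["pos"] - w and g["start"] <= h["pos"] + w:
                    expected.add(g["gene_id"])
        assert got == expected

    def test_monotone_in_window_size(self):
        genes, hits = self._genes(), pd.DataFrame({"chrom": ["chr1"], "pos": [700_000]})
        small = ss.genes_near_hits(genes, hits, window=100_000)
        large = ss.genes_near_hits(genes, hits, window=2_000_000)
        assert small <= large


class TestBinomialEnrichment:
    def test_replication_count_reproduces_printed_probability(self):
        p = ss.binomial_enrichment(8, 35, 0.05)
        assert float(f"{p:.0e}") == pytest.approx(3e-4)

    def test_zero_successes_has_full_tail(self):
        assert ss.binomial_enrichment(0, 35, 0.05) == pytest.approx(1.0)

    def test_upper_and_lower_tails_partition_unity(self):
        k, n, p0 = 12, 40, 0.2
        upper = ss.binomial_enrichment(k, n, p0)
        lower = float(stats.binom.cdf(k - 1, n, p0))
        assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_k_and_p0(self):
        assert ss.binomial_enrichment(9, 35, 0.05) < ss.binomial_enrichment(8, 35, 0.05)
        assert ss.binomial_enrichment(8, 35, 0.10) > ss.binomial_enrichment(8, 35, 0.05)

    def test_agrees_with_scipy_survival_function(self):
        for k, n, p0 in [(8, 35, 0.05), (354, 587, 0.55), (3, 10, 0.5)]:
            mine = ss.binomial_enrichment(k, n, p0)
            assert mine == pytest.approx(float(stats.binom.sf(k - 1, n, p0)), rel=1e-9)

    def test_window_gene_counts_give_milli_scale_probability(self):
        p = ss.binomial_enrichment(354, 587, 0.55)
        assert 1e-3 <= p <= 1e-2

    def test_invalid_inputs(self):
        with pytest.raises(EnrichmentError):
            ss.binomial_enrichment(5, 3, 0.5)
        with pytest.raises(EnrichmentError):
            ss.binomial_enrichment(1, 3, 0.0)


class TestExpressionEnrichmentReport:
    def test_enriched_windows_yield_small_p(self):
        rng = np.random.default_rng(7)
        x = _draw_mixture(rng, 2000)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(2000)],
            "chrom": "chr1",
            "start": np.arange(2000) * 10_000 + 1,
            "log_expr": x,
        })
        genes["end"] = genes["start"] + 5_000
        model = ss.fit_mixture2(x)
        # put hits where expressed genes concentrate
        labeled = classify_expression(genes, model)
        expressed_pos = labeled.loc[labeled.expression_class == "expressed", "start"]
        hits = pd.DataFrame({"chrom": "chr1", "pos": expressed_pos.iloc[:40].to_numpy()})
        rep = expression_enrichment(genes, model, hits, window=5_000)
        assert rep.window_fraction > rep.background_fraction
        assert rep.p_value < 0.05


class TestReplication:
    def _panel(self, seed, trait="t1"):
        cfg = ss.SimConfig(n_snps=400, n_clusters=22, block_len=1, flip_rate=0.0,
                           master_seed=seed, traits=(trait,), h2=0.6)
        G = ss.simulate_panel(cfg)
        Gf = ss.filter_informative(G)
        sdps = ss.collapse_sdps(Gf)
        K = ss.kinship_ibs(Gf)
        P = ss.simulate_phenotypes(G, cfg)
        return cfg, G, Gf, sdps, K, P

    def _primary_loci(self, Gf, sdps, scan, quantile=0.02):
        thr = np.nanquantile(scan.table["p"], quantile)
        ts = ss.ThresholdSet(alpha=0.05, strict_p=thr / 10, suggestive_p=thr,
                             n_sdps=len(sdps), n_scans=1, n_eff_pheno=1, n_eff_geno=1)
        return ss.classify_and_group(scan, ts, merge_distance=100_000)

    def test_self_replication_recovers_every_testable_locus(self):
        cfg, G, Gf, sdps, K, P = self._panel(21)
        sub = P[P.treatment == "ctr"]
        scan = ss.assoc_scan(ss.make_spec(sub, "t1", K), sdps)
        loci = self._primary_loci(Gf, sdps, scan)
        assert loci, "fixture must produce at least one locus"
        summary = ss.replicate_loci(
            loci, G, sub, "t1", alpha=0.5, gc_correct=False,
            primary_strains=G.strains, min_called=20,
        )
        assert summary.n_testable > 0
        assert summary.n_replicated == summary.n_testable

    def test_noise_phenotype_replicates_near_the_chance_rate(self):
        cfg, G, Gf, sdps, K, P = self._panel(22)
        sub = P[P.treatment == "ctr"]
        scan = ss.assoc_scan(ss.make_spec(sub, "t1", K), sdps)
        loci = self._primary_loci(Gf, sdps, scan, quantile=0.1)
        n_rep = n_test = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            noise = sub.copy()
            noise["t1"] = rng.normal(size=len(noise))
            summary = ss.replicate_loci(
                loci, G, noise, "t1", alpha=0.05,
                primary_strains=G.strains, min_called=20,
            )
            n_rep += summary.n_replicated
            n_test += summary.n_testable
        assert n_test > 50
        assert n_rep / n_test < 0.2  # near alpha, far from self-replication

    def test_insufficient_shared_strains_is_an_error(self):
        cfg, G, Gf, sdps, K, P = self._panel(23)
        with pytest.raises(EnrichmentError, match="shares only"):
            ss.replicate_loci([], G, P, "t1", primary_strains=G.strains[:5],
                              min_shared_strains=19)

    def test_gc_correction_is_identity_at_unit_lambda(self):
        assert gc_corrected_p(0.01, 1.0) == pytest.approx(0.01, rel=1e-9)
        assert gc_corrected_p(0.01, 2.0) > 0.01
        assert gc_corrected_p(0.01, 0.5) < 0.01
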