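"""Mixed-model REML and association scan, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import strainscan as ss
from strainscan.mixed_model import (
    ModelError,
    _maximize_delta,
    _reml_loglik,
    _restricted_spectrum,
)

from conftest import identity_kinship, make_genotypes, one_animal_table


def _random_panel(rng, m=150, n=22, missing_rate=0.0):
    calls = rng.integers(0, 2, size=(m, n)).astype(np.int8)
    if missing_rate:
        calls[rng.random((m, n)) < missing_rate] = -1
    return make_genotypes(calls)


class TestFitNull:
    def test_matches_closed_form_anova_reml_with_identity_kinship(self):
        """Balanced one-way design: REML equals the ANOVA estimators exactly."""
        rng = np.random.default_rng(7)
        n_s, r = 22, 9
        for _ in range(10):
            u = rng.normal(0, np.sqrt(0.6), n_s)
            y = np.repeat(u, r) + rng.normal(0, np.sqrt(0.4), n_s * r)
            df = pd.DataFrame({
                "animal_id": [f"a{i}" for i in range(n_s * r)],
                "strain": np.repeat([f"S{j}" for j in range(n_s)], r),
                "treatment": "ctr", "t": y,
            })
            vc = ss.fit_null(ss.make_spec(df, "t", identity_kinship(df["strain"].unique())))
            ybar = y.reshape(n_s, r).mean(1)
            msb = r * np.sum((ybar - ybar.mean()) ** 2) / (n_s - 1)
            msw = np.sum((y.reshape(n_s, r) - ybar[:, None]) ** 2) / (n_s * (r - 1))
            sg = (msb - msw) / r
            if sg <= 0:
                continue
            assert vc.sigma_g2 == pytest.approx(sg, rel=1e-5)
            assert vc.sigma_e2 == pytest.approx(msw, rel=1e-5)
            assert vc.h2 == pytest.approx(sg / (sg + msw), abs=1e-6)

    def test_pure_noise_has_near_zero_heritability(self):
        rng = np.random.default_rng(1)
        h2s = []
        for seed in range(20):
            y = rng.normal(size=22 * 9)
            df = pd.DataFrame({
                "animal_id": [f"a{i}" for i in range(len(y))],
                "strain": np.repeat([f"S{j}" for j in range(22)], 9),
                "treatment": "ctr", "t": y,
            })
            K = identity_kinship(df["strain"].unique())
            h2s.append(ss.fit_null(ss.make_spec(df, "t", K)).h2)
        assert np.median(h2s) < 0.1

    def test_strong_strain_signal_recovers_high_heritability(self, structured_panel):
        cfg, G, Gf, sdps, K, P = structured_panel
        rng = np.random.default_rng(5)
        # y = strain effect drawn with covariance K, tiny noise
        w, U = np.linalg.eigh(K.ridged())
        u = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(22))
        df = P[P.treatment == "ctr"].copy()
        strain_val = dict(zip(K.strains, u))
        df["t"] = df["strain"].map(strain_val) + rng.normal(0, 0.05, len(df))
        vc = ss.fit_null(ss.make_spec(df, "t", K))
        assert vc.h2 > 0.9

    def test_h2_consistent_with_variance_components(self, flat_panel):
        *_, K, P = flat_panel
        vc = ss.fit_null(ss.make_spec(P[P.treatment == "ate"], "t1", K))
        assert vc.h2 == pytest.approx(
            vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2), abs=1e-10
        )
        assert np.isfinite(vc.reml_loglik)

    def test_reml_optimum_beats_dense_log_grid(self, flat_panel):
        *_, K, P = flat_panel
        spec = ss.make_spec(P[P.treatment == "ctr"], "t1", K)
        vc = ss.fit_null(spec)
        xi, U = _restricted_spectrum(spec)
        eta2 = (U.T @ spec.y) ** 2
        best = vc.reml_loglik
        grid = np.exp(np.linspace(np.log(1e-5), np.log(1e5), 1000))
        assert all(_reml_loglik(d, xi, eta2) <= best + 1e-6 for d in grid)

    def test_singular_design_is_rejected(self):
        df = one_animal_table([f"S{i}" for i in range(5)], np.arange(5.0))
        K = identity_kinship(df["strain"])
        with pytest.raises(ModelError):
            ss.MixedModelSpec(
                y=df["t"].to_numpy(),
                X=np.ones((5, 2)),  # duplicated intercept
                Z=np.eye(5), K=K, strains=list(df["strain"]),
            )


class TestAssocScan:
    def test_identity_kinship_single_animal_equals_ols_f_test(self):
        """With K=I and one animal per strain the scan must reduce exactly
        to ordinary least squares."""
        rng = np.random.default_rng(42)
        G = _random_panel(rng, m=200)
        Gf = ss.filter_informative(G, min_called=22, min_minor_strains=1)
        sdps = ss.collapse_sdps(Gf)
        y = rng.normal(size=22)
        spec = ss.make_spec(one_animal_table(G.strains, y), "t",
                            identity_kinship(G.strains))
        scan = ss.assoc_scan(spec, sdps)
        for sdp in sdps[::5]:
            res = stats.linregress(sdp.pattern.astype(float), y)
            p_mm = scan.table.loc[sdp.sdp_id, "p"]
            assert abs(np.log10(res.pvalue) - np.log10(p_mm)) < 1e-6

    def test_member_snps_share_identical_statistics(self, structured_panel):
        *_, sdps, K, P = structured_panel
        spec = ss.make_spec(P[P.treatment == "ctr"], "t1", K)
        scan = ss.assoc_scan(spec, sdps)
        snps = scan.snp_table()
        per_sdp = snps[snps["flag"] != "degenerate"].groupby("sdp_id")[["p", "beta", "F"]]
        assert (per_sdp.nunique() <= 1).all().all()

    def test_pvalues_invariant_under_affine_response_transform(self, flat_panel):
        *_, sdps, K, P = flat_panel
        base = P[P.treatment == "ctr"].copy()
        spec0 = ss.make_spec(base, "t1", K)
        scan0 = ss.assoc_scan(spec0, sdps)
        shifted = base.copy()
        shifted["t1"] = 3.0 * shifted["t1"] - 11.0
        scan1 = ss.assoc_scan(ss.make_spec(shifted, "t1", K), sdps)
        # delta is re-estimated per scan, so agreement holds to the
        # optimizer's tolerance rather than machine precision
        np.testing.assert_allclose(
            scan0.table["p"].to_numpy(float), scan1.table["p"].to_numpy(float),
            rtol=1e-5, equal_nan=True,
        )

    def test_pvalues_invariant_under_sdp_order_permutation(self, flat_panel):
        *_, sdps, K, P = flat_panel
        spec = ss.make_spec(P[P.treatment == "ctr"], "t1", K)
        fwd = ss.assoc_scan(spec, sdps)
        rev = ss.assoc_scan(spec, list(reversed(sdps)))
        pd.testing.assert_frame_equal(fwd.table.sort_index(), rev.table.sort_index())

    def test_monomorphic_sdp_is_flagged_degenerate(self):
        rng = np.random.default_rng(3)
        G = _random_panel(rng, m=20)
        calls = G.calls.copy()
        calls[0] = 0  # monomorphic SNP
        G = make_genotypes(calls)
        sdps = ss.collapse_sdps(G)
        mono = [s for s in sdps if len(np.unique(s.pattern[~s.mask])) == 1]
        y = rng.normal(size=22)
        spec = ss.make_spec(one_animal_table(G.strains, y), "t",
                            identity_kinship(G.strains))
        scan = ss.assoc_scan(spec, sdps)
        for s in mono:
            assert scan.table.loc[s.sdp_id, "flag"] == "degenerate"

    def test_masked_strains_are_dropped_per_sdp(self, structured_panel):
        *_, sdps, K, P = structured_panel
        spec = ss.make_spec(P[P.treatment == "ctr"], "t1", K)
        scan = ss.assoc_scan(spec, sdps)
        for sdp in sdps:
            row = scan.table.loc[sdp.sdp_id]
            assert row["n_strains_used"] == 22 - int(sdp.mask.sum())

    def test_exact_reml_mode_agrees_with_fast_mode_when_delta_is_flat(self):
        # one animal per strain, K=I: the likelihood is flat in delta, so
        # per-SDP refits cannot change the F statistic
        rng = np.random.default_rng(8)
        G = _random_panel(rng, m=40)
        sdps = ss.collapse_sdps(ss.filter_informative(G, 22, 1))
        y = rng.normal(size=22)
        spec = ss.make_spec(one_animal_table(G.strains, y), "t",
                            identity_kinship(G.strains))
        fast = ss.assoc_scan(spec, sdps)
        exact = ss.assoc_scan(spec, sdps, exact_reml=True)
        ok = fast.table["flag"] != "degenerate"
        np.testing.assert_allclose(
            fast.table.loc[ok, "p"], exact.table.loc[ok, "p"], rtol=1e-6
        )


class TestVarianceExplained:
    def test_zero_coefficient_explains_nothing(self):
        strains = [f"S{i}" for i in range(8)]
        y = np.array([1.0, -1.0] * 4)
        sdp = ss.SDP(0, np.array([1, 1, 1, 1, 0, 0, 0, 0], np.int8),
                     np.zeros(8, bool), [("rs1", "chr1", 1)])
        spec = ss.make_spec(one_animal_table(strains, y), "t",
                            identity_kinship(strains))
        ve = ss.variance_explained(spec, sdp)
        assert ve == pytest.approx(0.0, abs=1e-10)

    def test_perfect_allele_code_fit_explains_everything(self):
        strains = [f"S{i}" for i in range(8)]
        pattern = np.array([1, 0, 1, 0, 1, 0, 1, 0], np.int8)
        y = 2.0 + 3.0 * pattern
        sdp = ss.SDP(0, pattern, np.zeros(8, bool), [("rs1", "chr1", 1)])
        spec = ss.make_spec(one_animal_table(strains, y.astype(float)), "t",
                            identity_kinship(strains))
        assert ss.variance_explained(spec, sdp) == pytest.approx(1.0, abs=1e-8)

    def test_equals_whitened_r2_oracle(self, flat_panel):
        *_, sdps, K, P = flat_panel
        spec = ss.make_spec(P[P.treatment == "ctr"], "t1", K)
        vc = ss.fit_null(spec)
        sdp = next(s for s in sdps if s.is_full)
        ve = ss.variance_explained(spec, sdp, vc)
        # independent recomputation: whiten by the null covariance, regress
        H = spec.Z @ spec.K.ridged() @ spec.Z.T
        lam, U = np.linalg.eigh(H)
        W = (U / np.sqrt(lam + vc.delta)).T
        ty, TX = W @ spec.y, W @ spec.X
        g = W @ (spec.Z @ sdp.pattern.astype(float))
        def rss(M):
            beta, *_ = np.linalg.lstsq(M, ty, rcond=None)
            r = ty - M @ beta
            return float(r @ r)
        expected = 1 - rss(np.column_stack([TX, g])) / rss(TX)
        assert ve == pytest.approx(expected, abs=1e-8)
        assert 0.0 <= ve <= 1.0


class TestDeltaSearch:
    def test_grid_plus_refine_finds_the_analytic_optimum(self):
        # single eigenvalue pair with known maximizer
        xi = np.array([4.0, 1.0, 0.5, 0.2])
        eta2 = np.array([2.0, 1.0, 0.7, 0.4])
        delta, ll, boundary = _maximize_delta(xi, eta2)
        dense = np.exp(np.linspace(np.log(1e-5), np.log(1e5), 20001))
        vals = [_reml_loglik(d, xi, eta2) for d in dense]
        assert ll >= max(vals) - 1e-9
        assert not boundary or delta in (pytest.approx(1e-5), pytest.approx(1e5))
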