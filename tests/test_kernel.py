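import numpy as np
import pytest

from fxiassoc import (
    LocusSpec,
    SimulationConfig,
    SlidingWindowKernelTest,
    build_windows,
    fit_linear,
    fit_null_model,
    merge_regions,
    permutation_fwer,
    simulate_genotypes,
    simulate_phenotype,
    skat_test,
    weights_beta,
)
from fxiassoc.kernel import VariantSet, imhof_sf, liu_sf


class TestBuildWindows:
    def test_interval_membership_by_hand(self):
        sets = build_windows(
            ["a", "b", "c"], ["chr1"] * 3, np.array([100, 600, 2300]), width_bp=2000
        )
        assert [s.member_ids for s in sets] == [["a", "b"], ["b", "c"], ["c"]]
        assert sets[0].window_start == 100 and sets[0].window_end == 2100

    def test_single_variant_singleton(self):
        sets = build_windows(["a"], ["chr1"], np.array([500]))
        assert len(sets) == 1 and sets[0].member_ids == ["a"]

    def test_windows_do_not_cross_chromosomes(self):
        sets = build_windows(
            ["a", "b"], ["chr3", "chr4"], np.array([100, 600]), width_bp=2000
        )
        assert [s.member_ids for s in sets] == [["a"], ["b"]]

    def test_every_window_spans_exactly_width(self):
        sets = build_windows(
            ["a", "b", "c"], ["chr1"] * 3, np.array([10, 20, 5000]), width_bp=2000
        )
        assert all(s.window_end - s.window_start == 2000 for s in sets)

    def test_empty_input(self):
        assert build_windows([], [], np.array([])) == []


class TestNullModel:
    def test_phenotype_in_covariate_span_gives_zero_residuals(self, rng):
        age = rng.uniform(18, 80, 50)
        y = 3.0 + 2.0 * age
        null = fit_null_model(y, age)
        np.testing.assert_allclose(null.residuals, 0, atol=1e-9)

    def test_intercept_only_centers(self, rng):
        y = rng.normal(100, 10, 40)
        null = fit_null_model(y, None)
        np.testing.assert_allclose(null.residuals, y - y.mean(), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        cov = np.column_stack([rng.uniform(18, 80, 80), rng.integers(0, 2, 80)])
        y = rng.normal(size=80)
        null = fit_null_model(y, cov)
        np.testing.assert_allclose(null.X.T @ null.residuals, 0, atol=1e-8)

    def test_rank_deficiency_is_error(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError):
            fit_null_model(rng.normal(size=30), np.column_stack([x, 2 * x]))


class TestWeights:
    def test_flat_when_uniform(self):
        assert weights_beta(0.37, 1, 1) == pytest.approx(1.0)

    def test_rare_limit(self):
        assert weights_beta(0.0, 1, 25) == pytest.approx(25.0)

    def test_closed_form_at_ten_percent(self):
        assert weights_beta(0.1, 1, 25) == pytest.approx(25 * 0.9**24)


class TestMixtureTail:
    def test_matches_monte_carlo_oracle(self, rng):
        for _ in range(5):
            lam = rng.uniform(0.1, 4.0, rng.integers(2, 8))
            draws = (lam * rng.chisquare(1, size=(100_000, lam.size))).sum(axis=1)
            for q in np.quantile(draws, [0.5, 0.9, 0.99]):
                mc = (draws > q).mean()
                if mc >= 1e-4:
                    assert imhof_sf(q, lam) == pytest.approx(mc, rel=0.15)

    def test_liu_close_to_imhof_in_bulk(self, rng):
        lam = np.array([2.0, 1.0, 0.4])
        for q in (1.0, 3.0, 6.0, 10.0):
            assert liu_sf(q, lam) == pytest.approx(imhof_sf(q, lam), abs=0.02)


class TestSkatTest:
    def test_all_zero_submatrix_no_test(self, rng):
        y = rng.normal(size=30)
        null = fit_null_model(y, None)
        res = skat_test(null, np.zeros((30, 3)), np.ones(3))
        assert res.Q == 0.0 and res.p == 1.0 and not res.tested

    def test_q_nonnegative_and_member_permutation_invariant(self, rng):
        n = 110
        G = rng.binomial(2, 0.05, (n, 6)).astype(float)
        y = rng.normal(120, 30, n)
        null = fit_null_model(y, rng.uniform(18, 80, n))
        w = weights_beta(G.mean(axis=0) / 2 + 1e-6)
        res = skat_test(null, G, w)
        assert res.Q >= 0
        perm = rng.permutation(6)
        res2 = skat_test(null, G[:, perm], w[perm])
        assert res2.Q == pytest.approx(res.Q, rel=1e-10)
        assert res2.p == pytest.approx(res.p, rel=1e-8)

    def test_single_variant_set_concordant_with_score_test(self, rng):
        n = 110
        hits = 0
        for _ in range(10):
            g = rng.binomial(2, 0.2, n).astype(float)
            age, sex = rng.uniform(18, 80, n), rng.integers(0, 2, n).astype(float)
            y = 120 + 0.2 * age - 5 * sex + 6 * g + rng.normal(0, 30, n)
            cov = np.column_stack([age, sex])
            null = fit_null_model(y, cov)
            res = skat_test(null, g[:, None], np.ones(1))
            ols = fit_linear(y, g, cov)
            if res.p == pytest.approx(ols.p, rel=0.10):
                hits += 1
        assert hits >= 9

    def test_null_pvalues_uniform(self):
        # fixed genotypes, 1000 phenotype redraws; analytic p should be uniform
        rng = np.random.default_rng(99)
        n = 110
        G = rng.binomial(2, rng.uniform(0.02, 0.09, 8), (n, 8)).astype(float)
        w = weights_beta(np.maximum(G.mean(axis=0) / 2, 1e-6))
        age, sex = rng.uniform(18, 80, n), rng.integers(0, 2, n).astype(float)
        cov = np.column_stack([age, sex])
        pvals = []
        for _ in range(1000):
            y = 120 + 0.2 * age - 5 * sex + rng.normal(0, 30, n)
            null = fit_null_model(y, cov)
            pvals.append(skat_test(null, G, w, tail_method="imhof").p)
        pvals = np.array(pvals)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        assert abs((pvals < 0.05).mean() - 0.05) <= 0.02


def _null_cohort(seed, n=110, m=40):
    mafs = tuple(np.linspace(0.02, 0.09, m))
    cfg = SimulationConfig(
        n_individuals=n,
        loci=(LocusSpec("L", "chr1", 1, 12_000, mafs=mafs, ld_blocks=((10, 0.7),) * (m // 10)),),
        beta_age=0.2,
        beta_sex=-5.0,
        resid_sd=30.0,
        seed=seed,
    )
    gm, recs = simulate_genotypes(cfg)
    ph = simulate_phenotype(gm, cfg)
    keep = [j for j in range(m) if np.ptp(gm.dosages[:, j]) > 0]
    sets = build_windows(
        [recs[j].variant_id for j in keep],
        ["chr1"] * len(keep),
        np.array([recs[j].pos for j in keep]),
    )
    return gm.dosages[:, keep], ph, sets


class TestPermutationFwer:
    def test_empirical_p_lower_bound_and_determinism(self):
        G, ph, sets = _null_cohort(3)
        y = ph["fxi_pct"].to_numpy()
        cov = ph[["age", "sex"]].to_numpy()
        permutation_fwer(y, cov, G, sets, B=99, seed=5)
        emp1 = [s.empirical_p for s in sets]
        assert all(e >= 1 / 100 for e in emp1)
        G2, ph2, sets2 = _null_cohort(3)
        permutation_fwer(y, cov, G2, sets2, B=99, seed=5)
        assert emp1 == [s.empirical_p for s in sets2]

    def test_empirical_p_monotone_in_analytic_p(self):
        G, ph, sets = _null_cohort(11)
        permutation_fwer(
            ph["fxi_pct"].to_numpy(), ph[["age", "sex"]].to_numpy(), G, sets, B=199, seed=2
        )
        order = np.argsort([s.p for s in sets])
        emp = np.array([s.empirical_p for s in sets])[order]
        assert (np.diff(emp) >= -1e-12).all()

    def test_invalid_b_rejected(self):
        G, ph, sets = _null_cohort(4)
        with pytest.raises(ValueError):
            permutation_fwer(
                ph["fxi_pct"].to_numpy(), None, G, sets, B=0
            )

    def test_planted_rare_effect_detected(self):
        # one low-frequency causal variant at 2 phenotype SD per allele:
        # its window should reach FWER significance in most replicates
        hits = 0
        n_rep = 25
        for r in range(n_rep):
            mafs = tuple(np.linspace(0.02, 0.09, 30))
            cfg = SimulationConfig(
                n_individuals=110,
                loci=(LocusSpec("L", "chr1", 1, 12_000, mafs=mafs),),
                causal_betas={15: 60.0},  # 2 x resid_sd
                beta_age=0.2,
                beta_sex=-5.0,
                resid_sd=30.0,
                seed=5000 + r,
            )
            gm, recs = simulate_genotypes(cfg)
            ph = simulate_phenotype(gm, cfg)
            causal_id = recs[15].variant_id
            keep = [j for j in range(30) if np.ptp(gm.dosages[:, j]) > 0]
            sets = build_windows(
                [recs[j].variant_id for j in keep],
                ["chr1"] * len(keep),
                np.array([recs[j].pos for j in keep]),
            )
            permutation_fwer(
                ph["fxi_pct"].to_numpy(),
                ph[["age", "sex"]].to_numpy(),
                gm.dosages[:, keep],
                sets,
                B=200,
                seed=r,
            )
            if any(
                s.significant_fwer and causal_id in s.member_ids for s in sets
            ):
                hits += 1
        assert hits / n_rep >= 0.5

    def test_freedman_lane_scheme_runs(self):
        G, ph, sets = _null_cohort(8)
        permutation_fwer(
            ph["fxi_pct"].to_numpy(),
            ph[["age", "sex"]].to_numpy(),
            G,
            sets,
            B=99,
            seed=1,
            scheme="freedman_lane",
        )
        assert all(s.empirical_p is not None for s in sets)


def _set(chrom, start, end, p=0.01, sig=True):
    return VariantSet(
        chrom=chrom,
        window_start=start,
        window_end=end,
        member_ids=[],
        member_idx=np.array([], dtype=int),
        p=p,
        significant_fwer=sig,
    )


class TestMergeRegions:
    def test_printed_overlapping_windows_form_one_region(self):
        anchors = [186_448_468, 186_448_470, 186_448_478, 186_448_482, 186_448_484]
        sets = [_set("chr3", a, a + 2000, p=0.0005) for a in anchors]
        regions = merge_regions(sets, tier="fwer")
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (186_448_468, 186_450_484)
        assert r.n_sets == 5

    def test_disjoint_windows_unchanged(self):
        sets = [_set("chr1", 100, 2100), _set("chr1", 5000, 7000)]
        regions = merge_regions(sets, tier="fwer")
        assert [(r.start, r.end) for r in regions] == [(100, 2100), (5000, 7000)]

    def test_nested_windows_give_outer_interval(self):
        sets = [_set("chr1", 100, 5000), _set("chr1", 1000, 2000)]
        regions = merge_regions(sets, tier="fwer")
        assert [(r.start, r.end) for r in regions] == [(100, 5000)]

    def test_idempotent_and_order_independent(self):
        sets = [
            _set("chr1", 100, 2100),
            _set("chr1", 1500, 3500),
            _set("chr2", 10, 2010),
        ]
        fwd = merge_regions(sets, tier="fwer")
        rev = merge_regions(sets[::-1], tier="fwer")
        assert fwd == rev
        again = merge_regions(
            [_set(r.chrom, r.start, r.end) for r in fwd], tier="fwer"
        )
        assert [(r.chrom, r.start, r.end) for r in again] == [
            (r.chrom, r.start, r.end) for r in fwd
        ]

    def test_nominal_tier_uses_pvalues(self):
        sets = [
            _set("chr1", 100, 2100, p=0.01, sig=False),
            _set("chr1", 9000, 11_000, p=0.5, sig=False),
        ]
        regions = merge_regions(sets, alpha=0.05, tier="nominal")
        assert len(regions) == 1 and regions[0].start == 100


class TestEstimator:
    def test_fit_populates_results_and_regions(self):
        G, ph, _ = _null_cohort(21, m=40)
        est = SlidingWindowKernelTest(B=99, random_state=3)
        # positions/chroms must align with the kept matrix; rebuild them
        mafs = tuple(np.linspace(0.02, 0.09, 40))
        cfg = SimulationConfig(
            n_individuals=110,
            loci=(LocusSpec("L", "chr1", 1, 12_000, mafs=mafs, ld_blocks=((10, 0.7),) * 4),),
            beta_age=0.2,
            beta_sex=-5.0,
            seed=21,
        )
        gm, recs = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        est.fit(
            gm.dosages,
            ph["fxi_pct"].to_numpy(),
            positions=np.array([r.pos for r in recs]),
            chroms=[r.chrom for r in recs],
            covariates=ph[["age", "sex"]].to_numpy(),
        )
        assert len(est.sets_) == len(est.low_frequency_ids_)
        assert set(est.results_.columns) >= {"Q", "p", "empirical_p"}
        assert est.get_params()["B"] == 99
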