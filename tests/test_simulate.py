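import numpy as np
import pandas as pd
import pytest

from fxiassoc import (
    LocusSpec,
    SimulationConfig,
    TailDesign,
    default_study_config,
    detection_power,
    genotype_r2,
    read_vcf,
    select_tails,
    simulate_genotypes,
    simulate_phenotype,
    simulate_study_cohort,
    write_vcf,
)
from fxiassoc.association import test_normality as shapiro_wilk
from fxiassoc.simulate import TailShortfallError


def _one_locus(mafs, blocks=None, **cfg_kw):
    locus = LocusSpec(
        "L", "chr1", 1, 100_000, mafs=tuple(mafs), ld_blocks=tuple(blocks or ())
    )
    return SimulationConfig(n_individuals=cfg_kw.pop("n", 100), loci=(locus,), **cfg_kw)


class TestSimulateGenotypes:
    def test_zero_maf_gives_all_reference(self):
        gm, _ = simulate_genotypes(_one_locus([0.0, 0.3], n=200, seed=3))
        assert (gm.dosages[:, 0] == 0).all()

    def test_realized_maf_matches_target(self):
        gm, _ = simulate_genotypes(_one_locus([0.05, 0.20, 0.45], n=5000, seed=11))
        np.testing.assert_allclose(gm.mafs(), [0.05, 0.20, 0.45], atol=0.02)

    def test_block_ld_reaches_target_r2(self):
        cfg = _one_locus([0.3, 0.35], blocks=[(2, 0.9)], n=5000, seed=5)
        gm, _ = simulate_genotypes(cfg)
        assert genotype_r2(gm.dosages[:, 0], gm.dosages[:, 1]) > 0.5

    def test_independent_blocks_uncorrelated(self):
        cfg = _one_locus([0.3, 0.3], blocks=[(1, 0.0), (1, 0.0)], n=5000, seed=5)
        gm, _ = simulate_genotypes(cfg)
        assert genotype_r2(gm.dosages[:, 0], gm.dosages[:, 1]) < 0.01

    def test_reproducible_given_seed(self):
        cfg = _one_locus([0.2, 0.1], n=50, seed=9)
        gm1, recs1 = simulate_genotypes(cfg)
        gm2, recs2 = simulate_genotypes(cfg)
        np.testing.assert_array_equal(gm1.dosages, gm2.dosages)
        assert [r.pos for r in recs1] == [r.pos for r in recs2]

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            _one_locus([0.7])
        with pytest.raises(ValueError):
            LocusSpec("L", "chr1", 1, 100, mafs=(0.1,), ld_blocks=((1, 1.5),))


class TestSimulatePhenotype:
    def test_noiseless_covariate_model_is_exact(self):
        cfg = _one_locus(
            [0.2], n=50, seed=2, beta_age=0.5, beta_sex=-4.0, mean=100.0, resid_sd=1e-9
        )
        gm, _ = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        expected = 100.0 + 0.5 * ph["age"] - 4.0 * ph["sex"]
        np.testing.assert_allclose(ph["fxi_pct"], expected, atol=1e-6)

    def test_causal_effect_recovered_by_ols(self):
        cfg = _one_locus(
            [0.3], n=5000, seed=4, causal_betas={0: 15.0}, beta_age=0.2,
            beta_sex=-5.0, resid_sd=25.0,
        )
        gm, _ = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        # normal-equations oracle
        X = np.column_stack(
            [np.ones(5000), gm.dosages[:, 0], ph["age"], ph["sex"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ ph["fxi_pct"].to_numpy())
        assert beta[1] == pytest.approx(15.0, abs=1.5)

    def test_sample_mean_near_configured_mean(self):
        cfg = _one_locus([0.2], n=5000, seed=6, mean=120.0, resid_sd=30.0)
        gm, _ = simulate_genotypes(cfg)
        ph = simulate_phenotype(gm, cfg)
        assert ph["fxi_pct"].mean() == pytest.approx(120.0, abs=2.0)

    def test_dimension_mismatch_is_error(self):
        cfg_small = _one_locus([0.2], n=10, seed=1)
        cfg_big = _one_locus([0.2], n=20, seed=1)
        gm, _ = simulate_genotypes(cfg_small)
        with pytest.raises(ValueError):
            simulate_phenotype(gm, cfg_big)

    def test_residuals_after_true_predictor_look_normal(self):
        # removing the known linear predictor should leave Gaussian noise
        passes = 0
        for seed in range(20):
            cfg = _one_locus(
                [0.3], n=1000, seed=seed, causal_betas={0: 10.0},
                beta_age=0.2, beta_sex=-5.0, resid_sd=30.0,
            )
            gm, _ = simulate_genotypes(cfg)
            ph = simulate_phenotype(gm, cfg)
            resid = (
                ph["fxi_pct"]
                - 120.0
                - 0.2 * ph["age"]
                + 5.0 * ph["sex"]
                - 10.0 * gm.dosages[:, 0]
            )
            if shapiro_wilk(resid.to_numpy()).p > 0.05:
                passes += 1
        assert passes >= 18  # >= 90% of seeds


class TestSelectTails:
    def _wide_cohort(self, seed=8):
        cfg = _one_locus([0.2], n=2000, seed=seed, mean=120.0, resid_sd=45.0)
        gm, _ = simulate_genotypes(cfg)
        return simulate_phenotype(gm, cfg)

    def test_selected_ids_respect_ranges(self):
        ph = self._wide_cohort()
        design = TailDesign(20, (36, 80), 20, (158, 250))
        ids = select_tails(ph, design, seed=1)
        assert len(ids) == 40
        sel = ph.set_index("id").loc[ids, "fxi_pct"]
        low, high = sel.iloc[:20], sel.iloc[20:]
        assert ((low >= 36) & (low <= 80)).all()
        assert ((high >= 158) & (high <= 250)).all()

    def test_shortfall_raises(self):
        ph = pd.DataFrame(
            {"id": ["a", "b", "c"], "fxi_pct": [50.0, 60.0, 170.0],
             "age": [30] * 3, "sex": [0] * 3}
        )
        with pytest.raises(TailShortfallError, match="requested 3"):
            select_tails(ph, TailDesign(3, (36, 80), 0, (158, 250)), seed=0)

    def test_deterministic_given_seed(self):
        ph = self._wide_cohort()
        design = TailDesign()
        assert select_tails(ph, design, seed=5) == select_tails(ph, design, seed=5)


class TestDetectionPower:
    @pytest.mark.parametrize(
        "maf, n, expected",
        [(0.0, 40, 0.0), (0.5, 1, 0.75)],
    )
    def test_closed_form(self, maf, n, expected):
        assert detection_power(maf, n) == pytest.approx(expected)

    def test_discovery_design_exceeds_98pct(self):
        assert detection_power(0.05, 40) > 0.98

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detection_power(0.7, 40)
        with pytest.raises(ValueError):
            detection_power(0.1, 0)


class TestVcfRoundTrip:
    def test_dosages_and_positions_survive(self, tmp_path):
        cfg = _one_locus(list(np.linspace(0.05, 0.5, 10)), n=5, seed=3,
                         missing_rate=0.1)
        gm, recs = simulate_genotypes(cfg)
        path = tmp_path / "g.vcf"
        write_vcf(gm, recs, str(path))
        gm2, recs2, n_multi = read_vcf(str(path))
        assert n_multi == 0
        assert [r.pos for r in recs2] == [r.pos for r in recs]
        np.testing.assert_array_equal(
            np.isnan(gm.dosages), np.isnan(gm2.dosages)
        )
        np.testing.assert_array_equal(
            np.nan_to_num(gm.dosages), np.nan_to_num(gm2.dosages)
        )

    def test_empty_variant_list_gives_header_only(self, tmp_path):
        cfg = _one_locus([0.2], n=3, seed=1)
        gm, _ = simulate_genotypes(cfg)
        path = tmp_path / "empty.vcf"
        from fxiassoc.variants import GenotypeMatrix

        empty = GenotypeMatrix(np.empty((3, 0)), gm.individual_ids, [])
        write_vcf(empty, [], str(path))
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []


class TestStudyCohort:
    def test_cohort_contains_full_tail_design(self):
        cfg = default_study_config(seed=3)
        genotypes, variants, phenotypes, discovery = simulate_study_cohort(cfg)
        assert genotypes.n_individuals == 110
        assert genotypes.n_variants == 762
        assert len(discovery) == 40
        ph = phenotypes.set_index("id")
        sel = ph.loc[discovery, "fxi_pct"]
        in_low = ((sel >= 36) & (sel <= 80)).sum()
        in_high = ((sel >= 158) & (sel <= 250)).sum()
        assert in_low == 20 and in_high == 20

    def test_two_printed_locus_spans(self):
        cfg = default_study_config(seed=0)
        spans = [(l.end_bp - l.start_bp + 1) for l in cfg.loci]
        assert spans == [25_581, 23_718]
        assert [l.n_variants for l in cfg.loci] == [504, 258]
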