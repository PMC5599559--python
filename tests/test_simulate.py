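import numpy as np
import pytest
from scipy.stats import chi2_contingency, kstest

from nhsa.simulate import (
    PenetranceModel,
    SimTruth,
    build_dme_model,
    generate_dataset,
    generate_null_dataset,
    heritability,
    marginal_penetrance,
    prevalence,
    read_truth,
    search_dnme_model,
    write_truth,
)


def brute_force_h2(mafs, table):
    """Direct enumeration over all genotype combinations."""
    import itertools

    def hwe(q):
        return [(1 - q) ** 2, 2 * q * (1 - q), q**2]

    k = len(mafs)
    cells = []
    for combo in itertools.product(range(3), repeat=k):
        p = 1.0
        for locus, g in enumerate(combo):
            p *= hwe(mafs[locus])[g]
        cells.append((p, table[combo]))
    K = sum(p * f for p, f in cells)
    var = sum(p * (f - K) ** 2 for p, f in cells)
    return var / (K * (1 - K))


class TestHeritability:
    def test_constant_table_zero(self):
        model = PenetranceModel((0.3, 0.3), np.full((3, 3), 0.2), "flat")
        assert heritability(model) == pytest.approx(0.0, abs=1e-15)

    def test_single_locus_brute_force(self):
        model = PenetranceModel((0.5,), np.array([0.0, 0.0, 1.0]), "test")
        assert prevalence(model) == pytest.approx(0.25)
        assert heritability(model) == pytest.approx(
            brute_force_h2((0.5,), np.array([0.0, 0.0, 1.0]))
        )

    def test_matches_brute_force_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, 4))
            mafs = tuple(rng.uniform(0.05, 0.5, size=k))
            table = rng.uniform(0.01, 0.99, size=(3,) * k)
            model = PenetranceModel(mafs, table, "rand")
            assert heritability(model) == pytest.approx(
                brute_force_h2(mafs, table), rel=1e-10
            )

    def test_allele_relabel_symmetry(self):
        # at MAF 0.5 relabeling the minor allele mirrors the table
        table = np.array([0.1, 0.5, 0.9])
        m1 = PenetranceModel((0.5,), table, "a")
        m2 = PenetranceModel((0.5,), table[::-1], "b")
        assert heritability(m1) == pytest.approx(heritability(m2))

    def test_degenerate_prevalence_rejected(self):
        # construction recomputes h2, which is undefined at prevalence 0
        with pytest.raises(ValueError):
            PenetranceModel((0.3,), np.zeros(3), "zero")


class TestMarginalPenetrance:
    def test_single_locus_identity(self):
        table = np.array([0.1, 0.2, 0.7])
        model = PenetranceModel((0.4,), table, "t")
        np.testing.assert_allclose(marginal_penetrance(model, 0), table)

    def test_additive_table_has_marginal_effect(self):
        g = np.add.outer(np.arange(3), np.arange(3)) / 8.0
        model = PenetranceModel((0.3, 0.3), 0.1 + g, "additive")
        marg = marginal_penetrance(model, 0)
        assert np.ptp(marg) > 0.01

    def test_dnme_marginals_flat(self, dnme_model):
        K = prevalence(dnme_model)
        for locus in range(dnme_model.k):
            dev = np.abs(marginal_penetrance(dnme_model, locus) - K).max()
            assert dev < 0.005


class TestBuildDmeModel:
    @pytest.mark.parametrize(
        "model_class,maf,h2",
        [
            ("multiplicative", 0.5, 0.005),
            ("multiplicative", 0.1, 0.01),
            ("threshold", 0.2, 0.02),
            ("threshold", 0.5, 0.05),
        ],
    )
    def test_heritability_self_consistency(self, model_class, maf, h2):
        model = build_dme_model(model_class, maf, h2)
        assert heritability(model) == pytest.approx(h2, abs=1e-6)
        assert model.k == 2

    def test_flat_table_limit(self):
        model = PenetranceModel((0.2, 0.2), np.full((3, 3), 0.1), "flat")
        assert heritability(model) == pytest.approx(0.0, abs=1e-15)

    def test_unreachable_target_reports_range(self):
        with pytest.raises(ValueError, match="attainable range"):
            build_dme_model("threshold", 0.05, 0.9)


class TestSearchDnmeModel:
    def test_acceptance_checks_hold(self, dnme_model):
        K = prevalence(dnme_model)
        assert abs(heritability(dnme_model) - 0.1) < 0.01
        for locus in range(3):
            assert np.abs(marginal_penetrance(dnme_model, locus) - K).max() < 0.005
        assert dnme_model.model_class == "dnme_searched"

    def test_prevalence_target_honored(self, dnme_model):
        assert prevalence(dnme_model) == pytest.approx(0.1, rel=0.1)

    def test_loose_tolerance_degenerates(self):
        model = search_dnme_model(
            2, 0.3, 0.02, marginal_tol=10.0, rng=np.random.default_rng(0)
        )
        assert abs(heritability(model) - 0.02) < 0.002

    def test_different_seeds_different_tables(self):
        m1 = search_dnme_model(3, 0.25, 0.1, 0.005, rng=np.random.default_rng(1))
        m2 = search_dnme_model(3, 0.25, 0.1, 0.005, rng=np.random.default_rng(2))
        assert not np.allclose(m1.table, m2.table)
        for model in (m1, m2):
            K = prevalence(model)
            for locus in range(3):
                assert np.abs(marginal_penetrance(model, locus) - K).max() < 0.005


class TestGenerateDataset:
    def test_empirical_penetrance_converges(self, threshold_model):
        # sample with quotas at the model's prevalence so P(case | genotype)
        # estimates the penetrance table directly; chi-square GOF
        K = prevalence(threshold_model)
        n = 50_000
        n_cases = round(K * n)
        ds, truth = generate_dataset(
            threshold_model, n_cases, n - n_cases, 0,
            rng=np.random.default_rng(10),
        )
        chi2_stat = 0.0
        cells = 0
        for g1 in range(3):
            for g2 in range(3):
                mask = (ds.genotypes[:, 0] == g1) & (ds.genotypes[:, 1] == g2)
                n_g = int(mask.sum())
                if n_g < 50:
                    continue
                f = threshold_model.table[g1, g2]
                observed_cases = int(ds.phenotype[mask].sum())
                chi2_stat += (observed_cases - n_g * f) ** 2 / (n_g * f * (1 - f))
                cells += 1
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2_stat, cells) > 0.001

    def test_background_snps_null_calibrated(self):
        model = build_dme_model("threshold", 0.3, 0.05)
        pvals = []
        for seed in range(200):
            ds, truth = generate_dataset(
                model, 250, 250, 1, background_maf_range=(0.3, 0.5),
                rng=np.random.default_rng(seed),
            )
            bg = next(
                i for i in range(ds.n_snps)
                if i not in truth.causal_column_indices
            )
            contingency = np.array(
                [
                    np.bincount(ds.genotypes[ds.phenotype == j, bg], minlength=3)
                    for j in (0, 1)
                ]
            )
            contingency = contingency[:, contingency.sum(axis=0) > 0]
            pvals.append(chi2_contingency(contingency).pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_background_hwe_proportions(self):
        from scipy.stats import chi2 as chi2_dist

        ds = generate_null_dataset(
            1000, 1000, 200, maf_range=(0.1, 0.5), rng=np.random.default_rng(3)
        )
        rejections = 0
        for snp in range(200):
            counts = np.bincount(ds.genotypes[:, snp], minlength=3)
            q = (counts[1] + 2 * counts[2]) / (2 * ds.n)
            expected = ds.n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            stat = ((counts - expected) ** 2 / expected).sum()
            if chi2_dist.sf(stat, 1) < 0.05:
                rejections += 1
        assert rejections / 200 <= 0.10

    def test_fixed_seed_reproducible(self, threshold_model):
        d1, t1 = generate_dataset(
            threshold_model, 100, 100, 20, rng=np.random.default_rng(5)
        )
        d2, t2 = generate_dataset(
            threshold_model, 100, 100, 20, rng=np.random.default_rng(5)
        )
        assert np.array_equal(d1.genotypes, d2.genotypes)
        assert np.array_equal(d1.phenotype, d2.phenotype)
        assert t1.causal_column_indices == t2.causal_column_indices

    def test_causal_columns_recorded(self, threshold_model):
        ds, truth = generate_dataset(
            threshold_model, 50, 50, 30, rng=np.random.default_rng(6)
        )
        assert ds.n_snps == 32
        assert len(truth.causal_column_indices) == 2
        assert truth.causal_snp_names == tuple(
            ds.snp_names[i] for i in truth.causal_column_indices
        )

    def test_impractical_prevalence_guard(self):
        model = PenetranceModel((0.3, 0.3), np.full((3, 3), 1e-6), "rare")
        with pytest.raises(ValueError, match="impractical"):
            generate_dataset(
                model, 1000, 1000, 0, rng=np.random.default_rng(0),
                max_expected_draws=10_000,
            )


class TestTruthIO:
    def test_round_trip(self, tmp_path, threshold_model):
        truth = SimTruth(
            causal_snp_names=("SNP3", "SNP17"),
            causal_column_indices=(3, 17),
            model=threshold_model,
            seed=9,
        )
        path = tmp_path / "truth.yaml"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.causal_snp_names == truth.causal_snp_names
        assert back.causal_column_indices == truth.causal_column_indices
        assert back.seed == 9
        np.testing.assert_allclose(back.model.table, threshold_model.table)
        assert back.model.mafs == threshold_model.mafs


class TestSearchDnmeFailure:
    def test_iteration_cap_reports_best_residuals(self):
        with pytest.raises(RuntimeError, match="best attempt"):
            # a near-unit heritability with flat marginals is infeasible
            search_dnme_model(
                3, 0.25, 0.98, marginal_tol=1e-6,
                rng=np.random.default_rng(0),
                max_restarts=3, max_iters=50,
            )
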