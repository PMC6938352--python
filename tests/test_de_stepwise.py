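import numpy as np
import pytest
from scipy import stats

from nilnet.data_io import CountMatrix, study_design
from nilnet.de_stepwise import (
    ModelError,
    NBFit,
    bh_adjust,
    design_matrix_full,
    detect_spe,
    fit_dispersion,
    fit_nb_glm,
    lrt,
    nb_deviance,
    nb_loglik,
    run_stepwise,
    stepwise_sets_from_significance,
    tmm_factors,
)


# ---------------------------------------------------------------------------
# TMM


def _brute_force_tmm_log2(y_s, y_r, N_s, N_r):
    """Independent re-derivation of the doubly trimmed weighted mean, using
    explicit sorting instead of rank arithmetic."""
    pairs = [(a, b) for a, b in zip(y_s, y_r) if a > 0 and b > 0]
    M = [np.log2((a / N_s) / (b / N_r)) for a, b in pairs]
    A = [0.5 * np.log2((a / N_s) * (b / N_r)) for a, b in pairs]
    w = [(N_s - a) / (N_s * a) + (N_r - b) / (N_r * b) for a, b in pairs]
    n = len(M)
    kM = int(np.floor(n * 0.3))
    kA = int(np.floor(n * 0.05))
    okM = set(np.argsort(M, kind="stable")[kM: n - kM])
    okA = set(np.argsort(A, kind="stable")[kA: n - kA])
    keep = sorted(okM & okA)
    num = sum(M[i] / w[i] for i in keep)
    den = sum(1.0 / w[i] for i in keep)
    return num / den


def _cm(counts):
    counts = np.asarray(counts)
    return CountMatrix([f"g{i}" for i in range(counts.shape[0])],
                       [f"s{j}" for j in range(counts.shape[1])], counts)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm(np.tile([[10], [20], [30], [5]], (1, 2)))
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_change_gives_unit_factors(self):
        col = np.array([10, 20, 30, 5, 80, 40])
        cm = _cm(np.column_stack([col, 2 * col]))
        nf = tmm_factors(cm)
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle_on_toy(self):
        rng = np.random.default_rng(3)
        # all counts distinct so the independent sort-based trimming in the
        # oracle and the rank-based trimming in the implementation coincide
        y1 = rng.permutation(50 + 3 * np.arange(40))
        y2 = rng.permutation(55 + 7 * np.arange(40))
        y2[0] = 5000  # one dominant gene distorts composition in sample 2
        cm = _cm(np.column_stack([y1, y2]))
        nf = tmm_factors(cm, reference="s0")
        expected_log2 = _brute_force_tmm_log2(y2, y1, y2.sum(), y1.sum())
        factors = 2.0 ** np.array([0.0, expected_log2])
        factors /= np.exp(np.mean(np.log(factors)))
        assert np.allclose(nf.factors, factors, atol=1e-10)

    def test_all_zero_sample_is_an_error(self):
        cm = _cm(np.column_stack([[1, 2, 3], [0, 0, 0]]))
        with pytest.raises(ModelError, match="all-zero"):
            tmm_factors(cm)

    def test_scaling_one_column_changes_only_its_library_size(self):
        """TMM equivariance: a pure depth change on one sample moves its
        library size, not its factor (composition unchanged)."""
        rng = np.random.default_rng(4)
        base = rng.poisson(50, size=(100, 3)) + 1
        cm1 = _cm(base)
        scaled = base.copy()
        scaled[:, 2] *= 3
        cm2 = _cm(scaled)
        f1 = tmm_factors(cm1, reference="s0")
        f2 = tmm_factors(cm2, reference="s0")
        # M-values are scale-free; only the inverse-variance weights shift,
        # bounding the factor change at O(1/count)
        assert np.allclose(f1.factors, f2.factors, atol=0.02)
        assert f2.library_sizes[2] == 3 * f1.library_sizes[2]


# ---------------------------------------------------------------------------
# NB GLM


class TestNBGLM:
    def test_intercept_only_fits_the_mean(self):
        y = np.array([10, 10, 10, 10])
        fit = fit_nb_glm(y, np.ones((4, 1)), np.zeros(4), phi=0.1)
        assert fit.mu == pytest.approx([10, 10, 10, 10], abs=1e-8)
        assert fit.converged

    def test_phi_zero_deviance_equals_poisson_glm(self):
        """As phi -> 0 the NB deviance must equal the Poisson GLM deviance;
        statsmodels is the independent oracle."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        off = np.log(rng.uniform(0.8, 1.2, size=6) * 1e4)
        y = rng.poisson(np.exp(off + X @ [np.log(2e-3), 1.0]))
        ours = fit_nb_glm(y, X, off, phi=0.0)
        sm_fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        assert ours.deviance == pytest.approx(sm_fit.deviance, abs=1e-6)
        assert np.allclose(ours.beta, sm_fit.params, atol=1e-6)

    def test_matches_statsmodels_negative_binomial(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(7), [0, 1, 0, 1, 0, 1, 0]])
        off = np.full(7, np.log(1e4))
        y = rng.poisson([40, 100, 35, 110, 50, 90, 44])
        phi = 0.1
        ours = fit_nb_glm(y, X, off, phi=phi)
        sm_fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                        offset=off).fit()
        assert np.allclose(ours.beta, sm_fit.params, atol=1e-6)

    def test_two_class_toy_recovers_log2fc_3(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(10), [0] * 5 + [1] * 5])
        mu = np.where(X[:, 1] == 0, 10.0, 80.0)
        y = rng.negative_binomial(1 / 0.05, (1 / 0.05) / (1 / 0.05 + mu))
        fit = fit_nb_glm(y, X, np.zeros(10), phi=0.05)
        assert fit.log2fc(1) == pytest.approx(3.0, abs=0.2)

    def test_loglik_matches_direct_pmf_evaluation(self):
        """NB log-likelihood agrees with direct summation of the NB pmf."""
        rng = np.random.default_rng(8)
        for phi in (0.05, 0.2, 1.0):
            y = rng.poisson(20, size=6)
            mu = rng.uniform(5, 40, size=6)
            r = 1.0 / phi
            direct = stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
            assert nb_loglik(y, mu, phi) == pytest.approx(direct, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ModelError, match="rank"):
            fit_nb_glm(np.array([1, 2, 3, 4]), X, np.zeros(4), phi=0.1)


class TestLRT:
    @staticmethod
    def _fit_like(dev):
        return NBFit(beta=np.zeros(1), phi=0.1, mu=np.ones(1), deviance=dev,
                     loglik=0.0, converged=True, n_iter=1)

    def test_identical_fits_give_p_one(self):
        stat, p = lrt(self._fit_like(5.0), self._fit_like(5.0), df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        stat, p = lrt(self._fit_like(1.0), self._fit_like(4.841), df=1)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_larger_negative_statistic_is_an_error(self):
        with pytest.raises(ModelError, match="nested"):
            lrt(self._fit_like(6.0), self._fit_like(5.0), df=1)

    def test_null_pvalues_are_uniform(self):
        """LRT p-values on no-effect NB data are ~Uniform(0,1)."""
        rng = np.random.default_rng(9)
        design = study_design()
        X = design_matrix_full(design)
        off = np.zeros(7)
        phi = 0.1
        pvals = []
        for _ in range(400):
            mu = rng.uniform(50, 500)
            y = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu), size=7)
            if y.sum() == 0:
                continue
            full = fit_nb_glm(y, X, off, phi)
            red = fit_nb_glm(y, X[:, :3], off, phi)
            pvals.append(lrt(full, red, 1)[1])
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.07


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == 0.42

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(12)
        design = study_design()
        X = design_matrix_full(design)
        mu = rng.uniform(50, 500, size=500)
        counts = rng.poisson(mu[:, None], size=(500, 7))
        counts = counts[counts.sum(axis=1) > 0]
        phi = fit_dispersion(counts, X, np.zeros(7), n_subsample=150)
        assert phi <= 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(13)
        design = study_design()
        X = design_matrix_full(design)
        true_phi = 0.2
        r = 1 / true_phi
        mu = rng.uniform(50, 500, size=800)
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(800, 7))
        counts = counts[counts.sum(axis=1) > 0]
        phi = fit_dispersion(counts, X, np.zeros(7), n_subsample=150)
        assert 0.1 <= phi <= 0.3

    def test_no_residual_df_is_an_error(self):
        with pytest.raises(ModelError, match="degrees of freedom"):
            fit_dispersion(np.array([[3, 4]]), np.eye(2), np.zeros(2))

    def test_all_zero_rows_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ModelError, match="all-zero"):
            fit_dispersion(np.array([[0, 0, 0, 0], [1, 2, 3, 4]]), X, np.zeros(4))


# ---------------------------------------------------------------------------
# stepwise procedure


class TestStepwise:
    def test_set_algebra_matches_the_procedure(self):
        sets = stepwise_sets_from_significance(
            step1_interaction_sig={"C"},
            step1_nil_sig={"D"},
            step2={1: {"A", "B", "C", "D"}, 2: {"A", "C", "E"}},
            step1_tested={"A", "B", "C", "D"},
        )
        assert sets.step3[1] == {"A", "B"}
        assert sets.step3[2] == {"A"}
        assert sets.final_common == {"A"}

    def test_invariants_hold_on_planted_run(self, planted_sim):
        _, cm, design, truth = planted_sim
        sets = run_stepwise(cm, design)
        sets.validate()  # raises on any violated invariant
        assert sets.final_common <= sets.step2[1] & sets.step2[2]

    def test_planted_allele_genes_recovered_at_strong_effect(self, planted_sim):
        """8-fold allele effects are recovered with low contamination by
        NIL-only / interaction genes."""
        _, cm, design, truth = planted_sim
        sets = run_stepwise(cm, design)
        allele = set(truth.genes_in_category("allele"))
        other = set(truth.genes_in_category("nil")) | set(
            truth.genes_in_category("interaction"))
        assert len(sets.final_common & allele) / len(allele) >= 0.8
        assert len(sets.final_common & other) <= 0.05 * max(len(sets.final_common), 1)

    def test_directions_are_concordant_signs(self, planted_sim):
        _, cm, design, truth = planted_sim
        sets = run_stepwise(cm, design)
        for g in sets.final_common:
            d = sets.direction[g]
            assert d in ("Up", "Down", "discordant")
            if g in truth.allele_log2fc and np.isfinite(truth.allele_log2fc[g]) \
                    and g in set(truth.genes_in_category("allele")):
                assert d == ("Up" if truth.allele_log2fc[g] > 0 else "Down")

    def test_missing_genotype_class_is_an_error(self, planted_sim):
        _, cm, design, _ = planted_sim
        partial = [d for d in design if d.genotype_class != "2_F288"]
        with pytest.raises(Exception, match="2_F288"):
            run_stepwise(cm.subset_samples([d.sample_id for d in partial]), partial)


# ---------------------------------------------------------------------------
# SPE


class TestSPE:
    def _flags(self, rows, max_silent=0, min_expressed=1):
        design = study_design()  # 2x F271(1), 1x F288(1), 2x F271(2), 2x F288(2)
        order = np.argsort([0 if d.allele == "F271" else 1 for d in design],
                           kind="stable")
        # rows given as (F271 counts..., F288 counts...)
        counts = np.empty((len(rows), 7), dtype=int)
        for i, r in enumerate(rows):
            counts[i, order] = r
        cm = CountMatrix([f"g{i}" for i in range(len(rows))],
                         [d.sample_id for d in design], counts)
        return detect_spe(cm, design, max_silent, min_expressed)

    def test_clean_structural_zero_is_spe_f288(self):
        (flag,) = self._flags([(0, 0, 0, 0, 3, 2, 5)])
        assert flag.pattern == "SPE_F288"

    def test_single_stray_count_blocks_the_call(self):
        (flag,) = self._flags([(0, 0, 1, 0, 3, 2, 5)])
        assert flag.pattern == "none"

    def test_max_silent_relaxation(self):
        (flag,) = self._flags([(0, 0, 1, 0, 3, 2, 5)], max_silent=1)
        assert flag.pattern == "SPE_F288"

    def test_planted_spe_fully_recovered_without_false_calls(self, planted_sim):
        _, cm, design, truth = planted_sim
        called = {f.gene_id: f.pattern for f in detect_spe(cm, design)
                  if f.pattern != "none"}
        for cat, label in (("spe_f288", "SPE_F288"), ("spe_f271", "SPE_F271")):
            for g in truth.genes_in_category(cat):
                assert called.get(g) == label
        high = {g for g, c in truth.category.items()
                if c == "null" and truth.class_means[g][0] >= 50}
        assert not (set(called) & high)
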