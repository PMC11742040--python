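import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from devocoevol._nbglm import FitError, estimate_dispersion, fit_nb_glm
from devocoevol._splines import SplineConfig, build_basis
from devocoevol.profiles import (DesignError, GeneFit, NormalizationError, _decide,
                                 build_design, coevolution_index,
                                 compare_divergence_proportions, divergence_per_organ,
                                 fit_gene, lrt, predict_curve, select_profile_model,
                                 size_factors, variance_decomposition, windowed_distance)
from devocoevol.synthetic import ProfilesSimConfig, simulate_profiles

from conftest import make_dataset


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 5, 100], "b": [10, 5, 100]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_library_gives_sqrt2_factors(self):
        counts = pd.DataFrame({"a": [10, 50, 100], "b": [20, 100, 200]})
        sf = size_factors(counts)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.negative_binomial(10, 0.05, size=(100, 6)) + 1)
        sf = size_factors(counts).to_numpy()
        # independent recomputation with plain loops
        mat = counts.to_numpy(float)
        geo = np.array([np.exp(np.mean(np.log(row))) for row in mat])
        raw = np.array([np.median(mat[:, j] / geo) for j in range(mat.shape[1])])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.abs(sf - expected).max() <= 1e-10

    def test_all_genes_with_zero_somewhere_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(NormalizationError):
            size_factors(counts)


class TestDesigns:
    def test_column_counts(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        nb = basis.n_basis
        assert nb == 6
        assert build_design(default_grid_samples, "simple", basis).X.shape[1] == nb + 1
        assert build_design(default_grid_samples, "species", basis).X.shape[1] == 2 * nb
        assert build_design(default_grid_samples, "tooth", basis).X.shape[1] == 2 * nb + 1
        assert build_design(default_grid_samples, "complex", basis).X.shape[1] == 4 * nb

    def test_nesting_by_projection_residual(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        designs = {c: build_design(default_grid_samples, c, basis).X
                   for c in ("simple", "species", "tooth", "complex")}
        for reduced, full in [("simple", "species"), ("simple", "tooth"),
                              ("simple", "complex"), ("species", "complex"),
                              ("tooth", "complex")]:
            q, _ = np.linalg.qr(designs[full])
            resid = designs[reduced] - q @ (q.T @ designs[reduced])
            assert np.abs(resid).max() <= 1e-10

    def test_partition_of_unity(self):
        basis = build_basis(SplineConfig(), np.linspace(0, 10, 8))
        B = basis.evaluate(np.linspace(0, 10, 57))
        assert B.min() >= 0
        assert np.abs(B.sum(axis=1) - 1).max() <= 1e-12

    def test_sparse_design_auto_reduces_to_quadratic(self):
        cfg = SplineConfig().reduced_for(np.array([0.0, 5.0, 10.0]))
        assert (cfg.degree, cfg.interior_knots) == (2, 0)

    def test_missing_group_is_a_design_error(self, default_grid_samples):
        single = default_grid_samples[default_grid_samples.organ == "lower"]
        basis = build_basis(SplineConfig(), np.asarray(single.relative_time))
        with pytest.raises(DesignError):
            build_design(single, "complex", basis)


class TestNBGLM:
    def test_intercept_only_closed_form(self):
        fit = fit_nb_glm(np.array([4.0, 4, 4, 4]), np.ones((4, 1)), 1.0, 1e-8)
        assert fit.coef[0] == pytest.approx(np.log(4.0), abs=1e-8)
        assert np.allclose(fit.mu, 4.0, atol=1e-6)

    def test_poisson_limit_matches_poisson_glm(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.poisson(np.exp(1.0 + 0.5 * X[:, 1]))
        mine = fit_nb_glm(y, X, 1.0, 1e-8)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-12)
        assert np.abs(mine.coef - pois.params).max() <= 1e-6

    def test_matches_statsmodels_nb_fit(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.normal(size=50), rng.normal(size=50)])
        mu = np.exp(2.0 + 0.4 * X[:, 1] - 0.3 * X[:, 2])
        y = rng.negative_binomial(1 / 0.3, 1 / (1 + 0.3 * mu))
        sf = np.exp(rng.normal(0, 0.2, 50))
        sf /= np.exp(np.mean(np.log(sf)))
        mine = fit_nb_glm(y, X, sf, 0.3)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.3),
                     offset=np.log(sf)).fit(tol=1e-12)
        assert np.abs(mine.coef - ref.params).max() <= 1e-5
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(FitError, match="collinear"):
            fit_nb_glm(np.arange(10.0) + 1, X, 1.0, 0.1)

    def test_recovers_generating_curve(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        design = build_design(default_grid_samples, "complex", basis)
        rng = np.random.default_rng(7)
        beta = rng.normal(7.0, 0.3, design.X.shape[1])
        # 2 replicates of the grid -> 64 samples; deep counts so the curve
        # is identifiable to ~0.1 on the log scale even at the endpoints
        X = np.vstack([design.X, design.X])
        mu = np.exp(X @ beta)
        y = rng.negative_binomial(1 / 1e-4, 1 / (1 + 1e-4 * mu))
        fit = fit_nb_glm(y, X, 1.0, 1e-4)
        assert np.abs(X @ fit.coef - X @ beta).max() <= 0.1


class TestDispersion:
    def test_poisson_gene_estimates_near_zero(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        X = build_design(default_grid_samples, "complex", basis).X
        rng = np.random.default_rng(3)
        y = rng.poisson(200.0, size=len(X)).astype(float)
        assert estimate_dispersion(y, X, 1.0) <= 0.01

    def test_nb_dispersion_recovery_band(self):
        # median over replicates of alpha-hat for a true alpha of 0.5
        rng = np.random.default_rng(12)
        X = np.ones((32, 1))
        estimates = []
        for _ in range(200):
            mu = 150.0
            y = rng.negative_binomial(1 / 0.5, 1 / (1 + 0.5 * mu), size=32).astype(float)
            estimates.append(estimate_dispersion(y, X, 1.0))
        assert 0.3 <= float(np.median(estimates)) <= 0.7

    def test_all_zero_gene_rejected(self):
        with pytest.raises(FitError):
            estimate_dispersion(np.zeros(16), np.ones((16, 1)), 1.0)


class TestLRT:
    def test_non_nested_designs_rejected(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        d_species = build_design(default_grid_samples, "species", basis)
        d_tooth = build_design(default_grid_samples, "tooth", basis)
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=len(d_species.X)).astype(float)
        f_species = fit_gene("g", y, d_species, np.ones(len(y)), 0.05)
        f_tooth = fit_gene("g", y, d_tooth, np.ones(len(y)), 0.05)
        with pytest.raises(ValueError, match="nested"):
            lrt(f_tooth, f_species)

    def test_mismatched_dispersion_rejected(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        d_simple = build_design(default_grid_samples, "simple", basis)
        d_complex = build_design(default_grid_samples, "complex", basis)
        rng = np.random.default_rng(0)
        y = rng.poisson(100, size=len(d_simple.X)).astype(float)
        sf = np.ones(len(y))
        with pytest.raises(ValueError, match="dispersion"):
            lrt(fit_gene("g", y, d_complex, sf, 0.1), fit_gene("g", y, d_simple, sf, 0.2))


class TestSelection:
    def test_model_nesting_holds_for_every_gene(self, small_profiles_sim):
        sel = select_profile_model(small_profiles_sim.dataset)
        t = sel.table.query("tested")
        assert (t.loglik_complex >= t.loglik_species - 1e-6).all()
        assert (t.loglik_complex >= t.loglik_tooth - 1e-6).all()
        assert (t.loglik_species >= t.loglik_simple - 1e-6).all()
        assert (t.loglik_tooth >= t.loglik_simple - 1e-6).all()

    def test_bh_adjustment_is_monotone(self, small_profiles_sim):
        sel = select_profile_model(small_profiles_sim.dataset)
        t = sel.table.query("tested")
        for fam in ("t1", "t2", "t3", "t4"):
            assert (t[f"padj_{fam}"] >= t[f"p_{fam}"] - 1e-12).all()
            order = t.sort_values(f"p_{fam}")
            assert order[f"padj_{fam}"].is_monotonic_increasing

    def test_classification_recovers_generating_classes(self, small_profiles_sim):
        sel = select_profile_model(small_profiles_sim.dataset)
        tab = sel.table.join(small_profiles_sim.truth)
        for cls in ("species", "tooth", "complex"):
            sub = tab[tab.true_class == cls]
            assert (sub.model_class == cls).mean() >= 0.75
        fpr = (tab[tab.true_class == "simple"].model_class != "simple").mean()
        assert fpr <= 0.15

    def test_low_count_genes_marked_untested(self, default_grid_samples):
        counts = np.vstack([np.zeros(32, int), np.full(32, 50, int)])
        ds = make_dataset(counts, default_grid_samples)
        sel = select_profile_model(ds)
        assert not sel.table.iloc[0].tested
        assert "total count" in sel.table.iloc[0].reason
        assert sel.table.iloc[1].tested

    @pytest.mark.parametrize("sig,expected", [
        ((False, False, False, False), "simple"),
        ((True, False, False, False), "species"),
        ((True, False, False, True), "complex"),
        ((False, True, False, False), "tooth"),
        ((False, True, True, False), "complex"),
        ((True, True, True, False), "complex"),
        ((True, True, False, True), "complex"),
    ])
    def test_decision_tree_branches(self, sig, expected):
        s = dict(zip(("t1", "t2", "t3", "t4"), sig))
        assert _decide(s, ll_species=-10.0, ll_tooth=-20.0) == expected

    def test_both_main_effects_without_escalation_uses_likelihood(self):
        s = {"t1": True, "t2": True, "t3": False, "t4": False}
        assert _decide(s, ll_species=-10.0, ll_tooth=-20.0) == "species"
        assert _decide(s, ll_species=-30.0, ll_tooth=-20.0) == "tooth"


class TestCoevolutionIndex:
    def _selection_from_counts(self, counts: dict) -> "pd.DataFrame":
        rows = []
        for cls, n in counts.items():
            for i in range(n):
                rows.append({"gene": f"{cls}{i}", "tested": True, "model_class": cls,
                             "informative": cls != "simple"})
        from devocoevol.profiles import SelectionResult
        return SelectionResult(pd.DataFrame(rows).set_index("gene"), alpha=0.05)

    def test_printed_formula_arithmetic(self):
        sel = self._selection_from_counts({"species": 740, "tooth": 100, "complex": 160})
        assert coevolution_index(sel) == pytest.approx(0.74)

    def test_zero_species_models(self):
        sel = self._selection_from_counts({"species": 0, "tooth": 5, "complex": 5})
        assert coevolution_index(sel) == 0.0

    def test_no_informative_genes_is_an_error(self):
        sel = self._selection_from_counts({"simple": 10})
        with pytest.raises(ValueError):
            coevolution_index(sel)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_equals_hand_computed_ratio(self, n_sp, n_to, n_cx, n_si):
        if n_sp + n_to + n_cx == 0:
            return
        sel = self._selection_from_counts({"species": n_sp, "tooth": n_to,
                                           "complex": n_cx, "simple": n_si})
        assert coevolution_index(sel) == pytest.approx(n_sp / (n_sp + n_to + n_cx))


class TestDivergence:
    def test_identical_counts_in_both_species_non_divergent(self, default_grid_samples):
        samples = default_grid_samples[default_grid_samples.organ == "lower"]
        rng = np.random.default_rng(5)
        half = rng.poisson(100, size=8)
        y = np.concatenate([half, half])  # same counts for both species
        ds = make_dataset(y[None, :].repeat(12, axis=0), samples)
        table, prop = divergence_per_organ(ds)
        assert (table.p > 0.999).all()
        assert not table.divergent.any()
        assert prop == 0.0

    def test_species_specific_curves_are_flagged(self):
        cfg = ProfilesSimConfig(n_per_class={"simple": 25, "species": 25,
                                             "tooth": 0, "complex": 0}, n_replicates=2)
        sim = simulate_profiles(cfg, seed=21)
        table, _ = divergence_per_organ(sim.dataset, "lower")
        j = table.join(sim.truth)
        assert j[j.true_class == "species"].divergent.mean() >= 0.8
        assert j[j.true_class == "simple"].divergent.mean() <= 0.1


class TestProportionTest:
    def test_equal_proportions_give_p_one(self):
        assert compare_divergence_proportions(0.2, 500, 0.2, 500) == pytest.approx(1.0)

    def test_extreme_contrast_small_n(self):
        assert compare_divergence_proportions(1.0, 10, 0.0, 10) < 1e-4

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            compare_divergence_proportions(0.5, 0, 0.5, 10)


def _complex_fit(samples, coef):
    basis = build_basis(SplineConfig(), np.asarray(samples.relative_time))
    design = build_design(samples, "complex", basis)
    return GeneFit(gene="g", design=design, coefficients=np.asarray(coef, float),
                   dispersion=0.05, log_likelihood=0.0, df=design.X.shape[1])


class TestCurvesAndDistances:
    def test_constant_coefficients_give_constant_curve(self, default_grid_samples):
        fit = _complex_fit(default_grid_samples, np.full(24, 2.5))
        vals = predict_curve(fit, np.linspace(0, 10, 20), ("hamster", "lower"))
        assert np.allclose(vals, 2.5, atol=1e-12)

    def test_prediction_at_sample_times_is_design_times_coef(self, default_grid_samples):
        rng = np.random.default_rng(8)
        coef = rng.normal(size=24)
        fit = _complex_fit(default_grid_samples, coef)
        X = fit.design.X
        t = np.asarray(default_grid_samples.relative_time, float)
        for group in [("hamster", "lower"), ("mouse", "upper")]:
            mask = ((default_grid_samples.species == group[0])
                    & (default_grid_samples.organ == group[1])).to_numpy()
            pred = predict_curve(fit, t[mask], group)
            assert np.abs(pred - X[mask] @ coef).max() <= 1e-12

    def test_matches_independent_cox_de_boor_evaluation(self, default_grid_samples):
        rng = np.random.default_rng(9)
        coef = rng.normal(size=24)
        fit = _complex_fit(default_grid_samples, coef)
        times = rng.uniform(0, 10, 100)
        pred = predict_curve(fit, times, ("hamster", "lower"))

        def bspline_basis(x, knots, degree, j):
            # Cox-de Boor recursion, written independently of scipy
            if degree == 0:
                last = j + 1 == len(knots) - 1 or knots[j + 1] == knots[-1]
                if last and x == knots[-1]:
                    return 1.0 if knots[j] <= x <= knots[j + 1] else 0.0
                return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
            out = 0.0
            if knots[j + degree] > knots[j]:
                out += (x - knots[j]) / (knots[j + degree] - knots[j]) \
                    * bspline_basis(x, knots, degree - 1, j)
            if knots[j + degree + 1] > knots[j + 1]:
                out += (knots[j + degree + 1] - x) / (knots[j + degree + 1] - knots[j + 1]) \
                    * bspline_basis(x, knots, degree - 1, j + 1)
            return out

        knots = fit.design.basis.knots
        roles = fit.design.roles
        sel = (roles.role == "curve") & (roles.species == "hamster") & (roles.organ == "lower")
        idx = np.where(sel.to_numpy())[0]
        oracle = np.array([
            sum(coef[j] * bspline_basis(x, knots, 3, int(roles.basis_index[j])) for j in idx)
            for x in times])
        assert np.abs(pred - oracle).max() <= 1e-10

    def test_identical_curves_give_zero_distances(self, default_grid_samples):
        coef = np.tile(np.linspace(1, 2, 6), 4)
        fit = _complex_fit(default_grid_samples, coef)
        d = windowed_distance(fit, ("hamster", "lower"), ("mouse", "lower"))
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_constant_offset_appears_in_every_window(self, default_grid_samples):
        rng = np.random.default_rng(2)
        base = rng.normal(size=6)
        c = 0.8
        coef = np.concatenate([base, base, base + c, base])  # groups sorted by (species, organ)
        fit = _complex_fit(default_grid_samples, coef)
        d = windowed_distance(fit, ("hamster", "lower"), ("mouse", "lower"))
        assert np.allclose(d, c, atol=1e-10)

    def test_symmetry_and_brute_force_oracle(self, default_grid_samples):
        rng = np.random.default_rng(3)
        fit = _complex_fit(default_grid_samples, rng.normal(size=24))
        a, b = ("hamster", "upper"), ("mouse", "lower")
        d_ab = windowed_distance(fit, a, b)
        d_ba = windowed_distance(fit, b, a)
        assert np.array_equal(d_ab, d_ba)
        times = np.linspace(0, 10, 100)
        diff = predict_curve(fit, times, a) - predict_curve(fit, times, b)
        oracle = np.array([np.sqrt(np.mean(diff[10 * w:10 * (w + 1)] ** 2))
                           for w in range(10)])
        assert np.abs(d_ab - oracle).max() <= 1e-10

    def test_non_complex_fit_rejected(self, default_grid_samples):
        basis = build_basis(SplineConfig(), np.asarray(default_grid_samples.relative_time))
        design = build_design(default_grid_samples, "simple", basis)
        fit = GeneFit("g", design, np.zeros(7), 0.05, 0.0, 7)
        with pytest.raises(ValueError):
            windowed_distance(fit, ("hamster", "lower"), ("mouse", "lower"))


class TestVarianceDecomposition:
    def test_species_separation_dominates_pc1(self):
        rng = np.random.default_rng(6)
        base = rng.normal(5, 1, size=(50, 1))
        a = np.exp(base + rng.normal(0, 0.01, size=(50, 8)))
        b = np.exp(base + 2.0 + rng.normal(0, 0.01, size=(50, 8)))
        normalized = pd.DataFrame(np.hstack([a, b]))
        factors = pd.DataFrame({"species": ["A"] * 8 + ["B"] * 8})
        shares, percomp = variance_decomposition(normalized, factors)
        assert shares["species"] > 0.95
        assert percomp["species"].iloc[0] > 0.95

    def test_permuted_labels_have_low_share(self):
        rng = np.random.default_rng(7)
        normalized = pd.DataFrame(np.exp(rng.normal(4, 1, size=(60, 16))))
        labels = np.array(["A", "B"] * 8)
        factors = pd.DataFrame({"noise": labels})
        shares, _ = variance_decomposition(normalized, factors)
        assert 0.0 <= shares["noise"] <= 0.35

    def test_constant_matrix_rejected(self):
        normalized = pd.DataFrame(np.ones((10, 6)))
        with pytest.raises(ValueError):
            variance_decomposition(normalized, pd.DataFrame({"f": ["A", "B"] * 3}))
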