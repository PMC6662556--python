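"""AICc model selection, averaging, importance and the treatment-effect models."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from telogel.inference import (
    MAIN_TERMS,
    SEX_INTERACTIONS,
    CandidateFit,
    ModelSpec,
    aicc,
    average_models,
    design_matrix,
    enumerate_candidates,
    enumerate_specs,
    fit_candidate,
    fledging_model,
    growth_model,
    mass_rank,
    morphometric_size_pc1,
    prepare_model_frame,
    relative_importance,
    retain_and_weight,
    vif,
    welch_t,
)
from telogel.simulate import PopulationSimConfig, simulate_population


class TestAICc:
    def test_formula_on_published_fits(self):
        assert aicc(-298.25, 7, 119) == pytest.approx(611.51, abs=0.01)
        assert aicc(-297.26, 8, 119) == pytest.approx(611.83, abs=0.01)

    def test_reduces_to_plain_aic_for_huge_n(self):
        assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-10.0, 5, 6)


class TestModelSpec:
    def test_marginality_enforced(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(frozenset({"chick_sex:maternal_tl", "chick_sex"}))
        ModelSpec(frozenset({"chick_sex:maternal_tl", "chick_sex", "maternal_tl"}))


class TestEnumerateSpecs:
    def test_two_mains_give_four_models(self):
        specs = enumerate_specs(("maternal_tl", "paternal_tl"), ())
        assert len(specs) == 4

    def test_interaction_with_marginality_gives_five(self):
        specs = enumerate_specs(
            ("chick_sex", "maternal_tl"), ("chick_sex:maternal_tl",)
        )
        assert len(specs) == 5

    def test_full_term_set_matches_bruteforce_count(self):
        """All subsets of 8 mains + 7 sex interactions under marginality."""
        terms = list(MAIN_TERMS) + list(SEX_INTERACTIONS)
        count = 0
        for r in range(len(terms) + 1):
            for subset in itertools.combinations(terms, r):
                s = set(subset)
                if all(
                    ":" not in t or set(t.split(":")) <= s for t in s
                ):
                    count += 1
        specs = enumerate_specs()
        assert len(specs) == count
        assert len({sp.sorted_terms() for sp in specs}) == len(specs)


def synthetic_candidates(betas_ses, weights=None, n=100):
    """Hand-built candidate list: each entry maps term -> (beta, se)."""
    cands = []
    for i, coefs in enumerate(betas_ses):
        k = len(coefs) + 2
        c = CandidateFit(
            spec=ModelSpec(frozenset(t for t in coefs if t != "Intercept")),
            loglik=-50.0 - i,
            k=k,
            n=n,
            aicc=aicc(-50.0 - i, k, n),
            coefficients=dict(coefs),
        )
        cands.append(c)
    if weights is not None:
        for c, w in zip(cands, weights):
            c.weight = w
            c.delta_aicc = 0.0
    return cands


class TestRetainAndWeight:
    def test_single_candidate_gets_unit_weight(self):
        cands = synthetic_candidates([{"maternal_tl": (1.0, 0.1)}])
        ret = retain_and_weight(cands)
        assert ret[0].weight == pytest.approx(1.0)

    def test_equal_aicc_split_evenly(self):
        cands = synthetic_candidates([{"maternal_tl": (1.0, 0.1)}] * 2)
        cands[1].aicc = cands[0].aicc
        ret = retain_and_weight(cands)
        assert [c.weight for c in ret] == pytest.approx([0.5, 0.5])

    def test_delta_cut_drops_poor_models(self):
        cands = synthetic_candidates(
            [{"maternal_tl": (1.0, 0.1)}, {"paternal_tl": (0.5, 0.1)}]
        )
        cands[1].aicc = cands[0].aicc + 5.0
        ret = retain_and_weight(cands, delta_cut=2.0)
        assert len(ret) == 1
        assert sum(c.weight for c in ret) == pytest.approx(1.0)


class TestAverageModels:
    def test_term_in_all_models_is_unshrunk(self):
        cands = synthetic_candidates(
            [{"maternal_tl": (0.6, 0.1)}, {"maternal_tl": (0.6, 0.1)}],
            weights=[0.3, 0.7],
        )
        out = average_models(cands)
        assert out.loc["maternal_tl", "full_estimate"] == pytest.approx(0.6)
        assert out.loc["maternal_tl", "conditional_estimate"] == pytest.approx(0.6)
        assert out.loc["maternal_tl", "importance"] == pytest.approx(1.0)

    def test_half_present_term_shrinks_by_half(self):
        cands = synthetic_candidates(
            [{"maternal_tl": (1.0, 0.1)}, {"paternal_tl": (0.4, 0.1)}],
            weights=[0.5, 0.5],
        )
        out = average_models(cands)
        assert out.loc["maternal_tl", "full_estimate"] == pytest.approx(0.5)
        assert out.loc["maternal_tl", "conditional_estimate"] == pytest.approx(1.0)
        assert out.loc["maternal_tl", "n_containing_models"] == 1

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        terms = ["a", "b", "c"]
        cands = []
        raw = rng.random(5)
        weights = raw / raw.sum()
        coef_store = []
        for i in range(5):
            present = [t for t in terms if rng.random() < 0.7] or ["a"]
            coefs = {t: (float(rng.normal()), float(rng.random() + 0.05)) for t in present}
            coef_store.append(coefs)
            c = CandidateFit(
                spec=ModelSpec(frozenset()), loglik=-10, k=3, n=200,
                aicc=aicc(-10, 3, 200), coefficients=coefs,
            )
            c.weight = float(weights[i])
            c.delta_aicc = 0.0
            cands.append(c)
        out = average_models(cands)
        for t in terms:
            if t not in out.index:
                continue
            betas = np.array([coef_store[i].get(t, (0.0,))[0] for i in range(5)])
            full = float(weights @ betas)
            assert out.loc[t, "full_estimate"] == pytest.approx(full, abs=1e-12)
            pres = np.array([t in coef_store[i] for i in range(5)])
            wc = weights[pres] / weights[pres].sum()
            cond = float(wc @ betas[pres])
            assert out.loc[t, "conditional_estimate"] == pytest.approx(cond, abs=1e-12)
            ses = np.array([coef_store[i].get(t, (0.0, 0.0))[1] for i in range(5)])
            se_full = float(weights @ np.sqrt(ses**2 + (betas - full) ** 2))
            assert out.loc[t, "full_se"] == pytest.approx(se_full, abs=1e-12)

    def test_full_average_never_exceeds_conditional(self):
        cands = synthetic_candidates(
            [
                {"maternal_tl": (0.8, 0.1), "paternal_tl": (0.3, 0.1)},
                {"maternal_tl": (0.7, 0.1)},
                {"paternal_tl": (0.25, 0.1)},
            ],
            weights=[0.5, 0.3, 0.2],
        )
        out = average_models(cands)
        partial = out[out["importance"] < 1]
        assert (
            partial["full_estimate"].abs() <= partial["conditional_estimate"].abs() + 1e-12
        ).all()


class TestRelativeImportance:
    def test_everywhere_term_has_unit_importance(self):
        cands = synthetic_candidates(
            [{"maternal_tl": (1, 0.1)}, {"maternal_tl": (1, 0.1), "paternal_tl": (0.2, 0.1)}],
            weights=[0.6, 0.4],
        )
        imp = relative_importance(cands)
        assert imp.loc["maternal_tl", "importance"] == pytest.approx(1.0)
        assert imp.loc["paternal_tl", "importance"] == pytest.approx(0.4)
        assert "mass_rank" not in imp.index


class TestFitCandidate:
    def test_zero_group_structure_equals_ols(self, population):
        frame = prepare_model_frame(population)
        frame = frame.copy()
        rng = np.random.default_rng(0)
        frame["tl_score"] = rng.normal(size=len(frame))  # no group signal
        spec = ModelSpec(frozenset({"maternal_tl"}))
        fit = fit_candidate(spec, frame, method="ML")
        X = design_matrix(spec, frame)
        ols = sm.OLS(frame["tl_score"], X).fit()
        for t in X.columns:
            assert fit.coefficients[t][0] == pytest.approx(float(ols.params[t]), abs=1e-4)

    def test_refit_deterministic(self, population):
        frame = prepare_model_frame(population)
        spec = ModelSpec(frozenset({"maternal_tl", "experimental_group"}))
        a = fit_candidate(spec, frame)
        b = fit_candidate(spec, frame)
        assert a.loglik == b.loglik

    def test_candidates_share_complete_case_n(self, population):
        cands = enumerate_candidates(
            population,
            main_terms=("experimental_group", "maternal_tl", "mass_rank"),
            interactions=(),
        )
        assert len({c.n for c in cands}) == 1
        assert len(cands) == 8
        deltas = [c.delta_aicc for c in cands]
        assert deltas == sorted(deltas)
        assert deltas[0] == 0.0


class TestMorphometricPC1:
    def test_collinear_columns_fully_explained(self):
        x = np.linspace(1, 10, 30)
        scores, explained = morphometric_size_pc1(x, 2 * x, 3 * x)
        assert explained == pytest.approx(1.0)
        assert np.corrcoef(scores, x)[0, 1] == pytest.approx(1.0)

    def test_known_covariance_fractions(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], size=50_000)
        tiny = rng.normal(0, 1e-6, 50_000)
        _, explained = morphometric_size_pc1(z[:, 0], z[:, 1], tiny)
        assert explained == pytest.approx(0.75, abs=0.01)

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(50, 3)) @ np.diag([3.0, 1.0, 0.5]) + 5
        scores, explained = morphometric_size_pc1(M[:, 0], M[:, 1], M[:, 2])
        evals, evecs = np.linalg.eigh(np.cov(M, rowvar=False))
        assert explained == pytest.approx(evals.max() / evals.sum(), abs=1e-10)
        v = evecs[:, np.argmax(evals)]
        v = v if v[0] > 0 else -v
        oracle = (M - M.mean(axis=0)) @ v
        assert np.allclose(scores, oracle, atol=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morphometric_size_pc1(np.ones(10), np.arange(10), np.arange(10))


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 2, 25)
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_o = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_o = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert t == pytest.approx(t_o, abs=1e-12)
        assert df == pytest.approx(df_o, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_o), df_o), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([1.0, 1.0], [1.0, 1.0])


class TestVif:
    def test_orthogonal_design_unit_vif(self):
        X = pd.DataFrame({"Intercept": 1.0, "a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
        assert np.allclose(vif(X).values, 1.0)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        X = pd.DataFrame({"Intercept": 1.0, "a": x, "b": x})
        v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=500)
        x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * rng.normal(size=500)
        X = pd.DataFrame({"Intercept": 1.0, "a": x1, "b": x2})
        r = np.corrcoef(x1, x2)[0, 1]
        assert vif(X)["a"] == pytest.approx(1 / (1 - r**2), rel=1e-10)


class TestMassRank:
    def test_heaviest_is_rank_one(self):
        df = pd.DataFrame({"rearing_box": ["b"] * 3, "mass_day12": [10.0, 8.0, 6.0]})
        assert mass_rank(df).tolist() == [1.0, 2.0, 3.0]

    def test_ties_get_average_rank(self):
        df = pd.DataFrame({"rearing_box": ["b"] * 3, "mass_day12": [10.0, 10.0, 6.0]})
        assert mass_rank(df).tolist() == [1.5, 1.5, 3.0]

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"rearing_box": rng.choice(["a", "b"], 20), "mass_day12": rng.normal(20, 3, 20)}
        )
        shuffled = df.sample(frac=1, random_state=1)
        r1 = mass_rank(df)
        r2 = mass_rank(shuffled).sort_index()
        assert (r1 == r2).all()


class TestGrowthModel:
    def test_detects_simulated_growth_deficit(self, population):
        out = growth_model(population)
        contrasts = out["group_contrast_by_measurement"]
        gaps = [contrasts[f"measurement_{m}"] for m in range(4)]
        assert gaps[3] < gaps[1] < 0.5  # widening deficit in enlarged broods
        assert out["interaction_p"] < 1e-6
        assert out["size_pc1_explained"] > 0.9

    def test_null_interaction_near_zero_without_treatment_effect(self):
        tab = simulate_population(
            PopulationSimConfig(n_pairs=8, treatment_effect_growth=0.0, seed=21)
        )
        out = growth_model(tab)
        assert abs(out["group_contrast_by_measurement"]["measurement_3"]) < 1.0
        assert out["interaction_p"] > 1e-4

    def test_null_pvalues_roughly_uniform(self):
        """Type-I calibration of the interaction LRT on null simulations."""
        ps = []
        for r in range(25):
            tab = simulate_population(
                PopulationSimConfig(n_pairs=6, treatment_effect_growth=0.0, seed=500 + r)
            )
            ps.append(growth_model(tab)["interaction_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFledgingModel:
    def test_detects_simulated_fledging_deficit(self, population):
        out = fledging_model(population)
        assert out["coefficient"] < 0
        assert out["lrt_p"] < 0.05

    def test_null_effect_is_not_significant(self):
        tab = simulate_population(
            PopulationSimConfig(n_pairs=10, fledging_logit_treatment=0.0, seed=77)
        )
        out = fledging_model(tab)
        assert out["lrt_p"] > 0.01

    def test_all_fledged_rejected(self, population):
        tab = population.copy()
        tab["fledged"] = True
        with pytest.raises(ValueError, match="identical"):
            fledging_model(tab)
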