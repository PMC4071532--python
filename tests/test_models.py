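import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from megafauna.errors import (
    ComparisonError,
    DesignError,
    DomainError,
    InvalidConfigError,
    NestingError,
    SparseCategoryError,
)
from megafauna.models import (
    CLIMATE_TERMS,
    ModelSpec,
    aic_select,
    arcsine_transform,
    build_design,
    enumerate_candidates,
    f_test_nested,
    fit_arcsine_glm,
    fit_quasibinomial_glm,
    lump_hominin_categories,
    ols_fit,
)
from megafauna.synthetic import HOMININ_CLASSES


def frame(proportion, hominin=None, **climate):
    n = len(proportion)
    df = pd.DataFrame({"proportion": proportion})
    for k, v in climate.items():
        df[k] = v
    df["hominin_class"] = hominin if hominin is not None else ["Homo-origin"] * n
    return df


class TestArcsineTransform:
    def test_endpoints_and_quarter(self):
        assert arcsine_transform(0.0) == 0.0
        assert np.isclose(arcsine_transform(0.25), np.pi / 6)
        assert np.isclose(arcsine_transform(1.0), np.pi / 2)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            arcsine_transform(1.2)
        with pytest.raises(DomainError):
            arcsine_transform(-0.1)


class TestOlsFit:
    def test_intercept_only_mean(self):
        y = np.array([0.2, 0.4, 0.6])
        fit = ols_fit(np.ones((3, 1)), y, ["intercept"])
        assert np.isclose(fit.params[0], 0.4)
        assert np.isclose(fit.rss, 0.08)

    def test_hand_anova_oracle(self):
        # one binary predictor separating equal-sized groups: F from
        # textbook one-way ANOVA arithmetic on the same six numbers
        y = np.array([0.1, 0.2, 0.15, 0.5, 0.6, 0.55])
        g = np.array([0, 0, 0, 1, 1, 1.0])
        X = np.column_stack([np.ones(6), g])
        fit = ols_fit(X, y, ["intercept", "g"])
        m1, m2, gm = y[:3].mean(), y[3:].mean(), y.mean()
        ss_between = 3 * ((m1 - gm) ** 2 + (m2 - gm) ** 2)
        ss_within = ((y[:3] - m1) ** 2).sum() + ((y[3:] - m2) ** 2).sum()
        f_hand = (ss_between / 1) / (ss_within / 4)
        assert np.isclose(fit.fstat, f_hand)
        assert fit.f_df == (1, 4)

    def test_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 3))])
        y = rng.normal(size=12)
        fit = ols_fit(X, y, list("abcd"))
        beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params, beta_ne, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(DesignError):
            ols_fit(X, np.zeros(5), ["intercept", "a", "a_copy"])

    def test_recovery_simulation(self):
        # beta within 2 SE in >= 93/100 seeds at n=229, sigma=0.1
        beta = np.array([0.2, 0.5, -0.3])
        ok = np.zeros(3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(229), rng.uniform(0, 1, (229, 2))])
            y = X @ beta + 0.1 * rng.standard_normal(229)
            fit = ols_fit(X, y, list("abc"))
            ok += (np.abs(fit.params - beta) <= 2 * fit.bse).astype(int)
        assert (ok >= 93).all()


class TestQuasibinomial:
    def test_two_group_slope_closed_form(self):
        df = frame([0.25] * 6 + [0.5] * 6, T_anom=[0.0] * 6 + [1.0] * 6)
        fit = fit_quasibinomial_glm(ModelSpec(climate=("T_anom",)), df)
        slope = fit.params[fit.names.index("T_anom")]
        assert np.isclose(slope, logit(0.5) - logit(0.25), atol=1e-6)

    def test_constant_response_zero_slope(self):
        df = frame([0.5] * 10, T_anom=np.linspace(0, 1, 10))
        fit = fit_quasibinomial_glm(ModelSpec(climate=("T_anom",)), df)
        assert np.isclose(fit.params[fit.names.index("T_anom")], 0.0, atol=1e-8)

    def test_sign_consistency_with_arcsine(self, rng):
        # a monotone simulated effect gets the same coefficient signs
        x = rng.uniform(0, 1, 120)
        p = np.clip(0.15 + 0.5 * x + 0.05 * rng.standard_normal(120), 0.01, 0.99)
        df = frame(p, T_anom=x)
        spec = ModelSpec(climate=("T_anom",))
        a = fit_arcsine_glm(spec, df)
        q = fit_quasibinomial_glm(spec, df)
        assert np.sign(a.params[1]) == np.sign(q.params[1]) == 1.0


class TestEnumeration:
    def test_exactly_eight_climate_specs(self):
        specs = enumerate_candidates("climate")
        assert len(specs) == 8
        # brute-force oracle: count valid subsets directly
        from itertools import chain, combinations

        valid = 0
        for sub in chain.from_iterable(
            combinations(CLIMATE_TERMS, r) for r in range(1, 5)
        ):
            if not ({"T_anom", "T_vel"} <= set(sub) or {"P_anom", "P_vel"} <= set(sub)):
                valid += 1
        assert valid == 8
        assert len({s.climate for s in specs}) == 8

    def test_exclusion_rule_exhaustive(self):
        for s in enumerate_candidates("climate"):
            assert not {"T_anom", "T_vel"} <= set(s.climate)
            assert not {"P_anom", "P_vel"} <= set(s.climate)
        with pytest.raises(InvalidConfigError):
            ModelSpec(climate=("T_anom", "T_vel"))

    def test_hominin_codings_include_arrival_time(self):
        specs = enumerate_candidates("hominin")
        assert {s.hominin for s in specs} == {"h3", "h5", "arrival"}

    def test_combined_includes_interactions(self):
        best_c = ModelSpec(climate=("T_anom", "P_vel"))
        best_h = ModelSpec(hominin="h3")
        specs = enumerate_candidates("combined", best_c, best_h)
        full = [s for s in specs if set(s.interactions) == {"T_anom", "P_vel"}]
        assert full, "full interaction model missing"
        X, names = build_design(
            full[0],
            frame([0.1, 0.2], hominin=["Homo_sapiens-only", "Archaic-late"],
                  T_anom=[0.1, 0.2], P_vel=[0.3, 0.4]),
        )
        assert "HSxT_anom" in names and "ACxT_anom" in names


class TestAicSelect:
    def _fit(self, k, aic, y=None):
        spec = ModelSpec(climate=("T_anom",))
        from megafauna.models import ModelFit

        y = np.zeros(5) if y is None else y
        return ModelFit(
            spec=spec, names=[f"c{i}" for i in range(k)], params=np.zeros(k),
            bse=np.zeros(k), tvalues=np.zeros(k), pvalues=np.zeros(k), n=5,
            df_resid=5 - k, rss=1.0, loglik=0.0, aic=aic, r2=0.0, fstat=None,
            f_df=None, f_pvalue=None, dispersion=None, fitted=y, residuals=y,
            response=y,
        )

    def test_lowest_aic_wins(self):
        best, ranked = aic_select([self._fit(2, 12.0), self._fit(2, 10.0)])
        assert best.aic == 10.0
        assert ranked["aic"].iloc[0] == 10.0

    def test_tie_breaks_toward_fewer_params(self):
        best, _ = aic_select([self._fit(3, 10.0), self._fit(2, 10.0)])
        assert len(best.params) == 2

    def test_mixed_responses_rejected(self):
        with pytest.raises(ComparisonError):
            aic_select([self._fit(2, 1.0, np.zeros(5)), self._fit(2, 2.0, np.ones(5))])

    def test_selection_consistency_small(self, rng):
        # hominin-true, climate-null: hominin spec should win
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            cls = np.repeat(list(HOMININ_CLASSES), 20)
            effect = {c: 0.0 for c in HOMININ_CLASSES}
            effect["Homo_sapiens-only"] = 0.9
            for c in HOMININ_CLASSES[1:4]:
                effect[c] = 0.5
            y_eta = np.array([0.3 + effect[c] for c in cls]) + 0.1 * r.standard_normal(100)
            df = frame(np.sin(np.clip(y_eta, 0, np.pi / 2)) ** 2, hominin=cls,
                       T_anom=r.uniform(0, 1, 100), T_vel=r.uniform(0, 1, 100),
                       P_anom=r.uniform(0, 1, 100), P_vel=r.uniform(0, 1, 100))
            fits = [fit_arcsine_glm(s, df) for s in enumerate_candidates("climate")]
            fits.append(fit_arcsine_glm(ModelSpec(hominin="h3"), df))
            best, _ = aic_select(fits)
            if best.spec.hominin == "h3":
                wins += 1
        assert wins >= 18


class TestNestedF:
    def test_identical_models(self):
        y = np.array([0.1, 0.3, 0.2, 0.4, 0.5])
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        fit = ols_fit(X, y, ["intercept", "x"])
        F, p, _ = f_test_nested(fit, fit)
        assert F == 0.0 and p == 1.0

    def test_hand_partial_f(self):
        # 6-point example checked against the textbook partial-F formula
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0])
        x1 = np.array([0.0, 1, 2, 3, 4, 5])
        x2 = np.array([1.0, 0, 1, 0, 1, 0])
        Xs = np.column_stack([np.ones(6), x1])
        Xb = np.column_stack([np.ones(6), x1, x2])
        fs = ols_fit(Xs, y, ["i", "x1"])
        fb = ols_fit(Xb, y, ["i", "x1", "x2"])
        F, p, df = f_test_nested(fs, fb)
        f_hand = ((fs.rss - fb.rss) / 1) / (fb.rss / 3)
        assert np.isclose(F, f_hand)
        assert df == (1, 3)
        assert np.isclose(p, float(stats.f.sf(f_hand, 1, 3)))

    def test_non_nested_rejected(self):
        y = np.zeros(5) + np.arange(5)
        f1 = ols_fit(np.column_stack([np.ones(5), np.arange(5.0)]), y, ["i", "a"])
        f2 = ols_fit(np.column_stack([np.ones(5), np.arange(5.0) ** 2]), y, ["i", "b"])
        with pytest.raises(NestingError):
            f_test_nested(f1, f2)

    def test_null_p_uniform(self):
        # adding a pure-noise column: p-values uniform on (0,1)
        pvals = []
        for seed in range(1000):
            r = np.random.default_rng(seed)
            y = r.standard_normal(20)
            x = r.standard_normal(20)
            fs = ols_fit(np.ones((20, 1)), y, ["i"])
            fb = ols_fit(np.column_stack([np.ones(20), x]), y, ["i", "x"])
            pvals.append(f_test_nested(fs, fb)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestLumping:
    def simulate(self, means, n_per, sigma, seed):
        rng = np.random.default_rng(seed)
        cls, p = [], []
        for c, m in zip(HOMININ_CLASSES, means):
            cls.extend([c] * n_per)
            eta = np.clip(m + sigma * rng.standard_normal(n_per), 0, np.pi / 2)
            p.extend(np.sin(eta) ** 2)
        return frame(p, hominin=cls)

    def test_middle_three_merge(self):
        df = self.simulate([0.10, 0.30, 0.30, 0.30, 0.55], 40, 0.05, seed=7)
        groups = lump_hominin_categories(df, alpha=0.05)
        assert len(groups) == 3
        assert groups[1] == tuple(HOMININ_CLASSES[1:4])

    def test_all_equal_single_group(self):
        df = self.simulate([0.3] * 5, 30, 0.02, seed=1)
        groups = lump_hominin_categories(df, alpha=0.05)
        assert len(groups) == 1

    def test_alpha_one_keeps_five_groups(self):
        # p > 1 is impossible, so nothing ever merges
        df = self.simulate([0.3] * 5, 10, 0.02, seed=2)
        groups = lump_hominin_categories(df, alpha=1.0)
        assert len(groups) == 5

    def test_sparse_category_rejected(self):
        df = frame([0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
                   hominin=["Homo-origin", "Homo-origin", "Archaic-early",
                            "Archaic-early", "Archaic-late", "Homo_sapiens-only"])
        with pytest.raises(SparseCategoryError):
            lump_hominin_categories(df)


class TestDesignAndR2:
    def test_hominin_only_beats_climate_on_reference_dgp(self, world229, ta229,
                                                         table1_params):
        from megafauna.synthetic import generate_extinctions

        ext = generate_extinctions(world229, ta229, table1_params, seed=77)
        df = frame(ext["true_proportion"].to_numpy(),
                   hominin=ext["hominin_class"].to_numpy(),
                   T_anom=ta229, T_vel=ta229 * 0.5,
                   P_anom=np.roll(ta229, 7), P_vel=np.roll(ta229, 11))
        fits_c = [fit_arcsine_glm(s, df) for s in enumerate_candidates("climate")]
        best_c, _ = aic_select(fits_c)
        fit_h = fit_arcsine_glm(ModelSpec(hominin="h3"), df)
        assert fit_h.r2 > best_c.r2
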