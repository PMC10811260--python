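"""REML variance components: oracles, model selection, BLUPs, heritability."""

import numpy as np
import pandas as pd
import pytest

from cloverpheno.studies import balanced_anova_components
from cloverpheno.vcmodels import (
    CANDIDATE_SPECS,
    ModelFit,
    ModelSpec,
    VarianceComponents,
    compute_blups,
    compute_heritability,
    enumerate_candidates,
    fit_variable,
    fit_vc_model,
    select_model,
)


def one_way(a, nrep, vg, vr, seed, mu=0.0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(vg), a)
    y = (mu + g[:, None] + rng.normal(0, np.sqrt(vr), (a, nrep))).ravel()
    return pd.DataFrame(
        {
            "accession_id": np.repeat([f"A{i:03d}" for i in range(a)], nrep),
            "block": 1,
            "column": 1,
            "row": 1,
            "value": y,
        }
    )


class TestCandidates:
    def test_exactly_six(self):
        assert len(enumerate_candidates()) == 6

    def test_first_structure_is_accession_only(self):
        assert enumerate_candidates()[0].random_terms == ("Accession",)

    def test_no_structure_mixes_block_and_column(self):
        for spec in enumerate_candidates():
            assert not ({"Block", "Column"} <= set(spec.random_terms))

    def test_invalid_structure_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(7, ("Accession", "Block", "Column"))


class TestREML:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_anova_identity(self, seed):
        """On balanced one-way data REML equals the classical ANOVA estimates."""
        df = one_way(25, 4, vg=3.0, vr=1.0, seed=seed, mu=50.0)
        vg_a, vr_a = balanced_anova_components(df)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        assert fit.components.V_G == pytest.approx(vg_a, rel=1e-6)
        assert fit.components.V_R == pytest.approx(vr_a, rel=1e-6)

    def test_noiseless_limit(self):
        """Identical replicates per accession: V_R -> 0, H² -> 1."""
        vals = np.repeat(np.arange(10, dtype=float), 3)
        df = pd.DataFrame(
            {
                "accession_id": np.repeat([f"A{i}" for i in range(10)], 3),
                "block": 1, "column": 1, "row": 1, "value": vals,
            }
        )
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        assert fit.components.V_R < 1e-6 * fit.components.V_G
        assert compute_heritability(fit).H2 > 0.999

    def test_grid_search_likelihood_oracle(self):
        """Optimum matches a dense scan of the profiled restricted likelihood."""
        from cloverpheno.vcmodels import _neg2_reml_and_grad, _design_matrix

        df = one_way(100, 2, vg=4.0, vr=1.0, seed=5)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        y = df["value"].to_numpy()
        scale = y.std()
        codes = pd.Categorical(df["accession_id"]).codes.astype(int)
        Z = _design_matrix(codes, 100)
        grid = np.arange(0.05, 12.0, 0.001)
        vals = [_neg2_reml_and_grad(np.array([g]), y / scale, [Z])[0] for g in grid]
        gamma_star = grid[int(np.argmin(vals))]
        ratio_hat = fit.components.V_G / fit.components.V_R
        assert ratio_hat == pytest.approx(gamma_star, abs=2e-3)

    def test_statsmodels_cross_check(self):
        """Independent mixed-model implementation agrees on components and loglik."""
        import statsmodels.formula.api as smf

        df = one_way(40, 3, vg=2.0, vr=1.5, seed=3, mu=10.0)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        sm_fit = smf.mixedlm("value ~ 1", df, groups=df["accession_id"]).fit(reml=True)
        assert fit.components.V_G == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert fit.components.V_R == pytest.approx(float(sm_fit.scale), rel=1e-4)
        assert fit.intercept == pytest.approx(float(sm_fit.params.iloc[0]), abs=1e-5)
        assert fit.loglik == pytest.approx(float(sm_fit.llf), abs=1e-5)

    @pytest.mark.parametrize("shift", [-100.0, 3.7, 1e4])
    def test_translation_invariance(self, shift):
        df = one_way(20, 3, vg=2.0, vr=1.0, seed=8)
        base = fit_vc_model(df, CANDIDATE_SPECS[0])
        shifted = df.assign(value=df["value"] + shift)
        fit = fit_vc_model(shifted, CANDIDATE_SPECS[0])
        assert fit.components.V_G == pytest.approx(base.components.V_G, rel=1e-5)
        assert fit.components.V_R == pytest.approx(base.components.V_R, rel=1e-5)
        assert fit.intercept == pytest.approx(base.intercept + shift, abs=1e-5)

    def test_singular_factor_rejected(self):
        df = one_way(1, 4, vg=1.0, vr=1.0, seed=0)
        with pytest.raises(ValueError):
            fit_vc_model(df, CANDIDATE_SPECS[0])

    def test_spatial_terms_estimated(self, small_table):
        obs = small_table[
            (small_table["field"] == "control")
            & (small_table["variable"] == "CH")
            & (small_table["doy"] == 256)
        ]
        fit = fit_vc_model(obs, CANDIDATE_SPECS[4])  # Accession + Block + Row
        assert fit.components.V_block is not None and fit.components.V_block >= 0
        assert fit.components.V_row is not None and fit.components.V_row >= 0
        assert set(fit.ranef) == {"Accession", "Block", "Row"}
        assert len(fit.ranef["Block"]) == 3
        assert len(fit.ranef["Row"]) == 5

    def test_aic_definition(self):
        df = one_way(20, 3, vg=2.0, vr=1.0, seed=4)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        # intercept + V_G + V_R
        assert fit.n_params == 3
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 3)


class TestSelection:
    def _dummy(self, aic, spec_idx=0):
        spec = CANDIDATE_SPECS[spec_idx]
        return ModelFit(
            variable="v", spec=spec, intercept=0.0,
            components=VarianceComponents(1.0, 1.0),
            ranef={"Accession": pd.Series(dtype=float)},
            loglik=0.0, aic=aic, n_obs=10, n_params=3,
        )

    def test_minimum_aic_wins(self):
        fits = [self._dummy(100.2), self._dummy(98.7, 1), self._dummy(99.5, 2)]
        assert select_model(fits).aic == 98.7

    def test_singleton(self):
        f = self._dummy(12.0)
        assert select_model([f]) is f

    def test_tie_prefers_fewer_components(self):
        tie = [self._dummy(50.0, 1), self._dummy(50.0, 0)]  # {A,Block} vs {A}
        assert select_model(tie).spec.structure_id == 1

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_structure_recovery_sanity(self):
        """AIC picks the generating structure when the spatial signal is strong."""
        hits = 0
        n_sims = 10
        for seed in range(n_sims):
            rng = np.random.default_rng(100 + seed)
            a, nrep = 60, 2
            rows_per_rep = 20
            g = rng.normal(0, 1.5, a)
            row_eff = rng.normal(0, np.sqrt(0.8), rows_per_rep)  # ≥ 0.5·V_R
            recs = []
            for i in range(a):
                for r in range(nrep):
                    row = rng.integers(rows_per_rep)
                    recs.append((f"A{i:02d}", 1, 1, row + 1, g[i] + row_eff[row] + rng.normal(0, 1.0)))
            df = pd.DataFrame(recs, columns=["accession_id", "block", "column", "row", "value"])
            best, _ = fit_variable(df, candidates=[CANDIDATE_SPECS[0], CANDIDATE_SPECS[3]])
            if best.spec.structure_id == 4:  # Accession + Row
                hits += 1
        assert hits >= 7


class TestBLUPs:
    def test_sum_rule(self):
        fit = ModelFit(
            variable="v", spec=CANDIDATE_SPECS[0], intercept=50.0,
            components=VarianceComponents(1.0, 1.0),
            ranef={"Accession": pd.Series({"A": 2.0, "B": -2.0})},
            loglik=0.0, aic=0.0, n_obs=4, n_params=3,
        )
        blups = compute_blups(fit)
        assert blups["A"] == 52.0 and blups["B"] == 48.0

    def test_zero_genetic_variance_full_shrinkage(self):
        """V_G = 0 in the data: every BLUP collapses to the intercept."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "accession_id": np.repeat([f"A{i}" for i in range(30)], 4),
                "block": 1, "column": 1, "row": 1,
                "value": rng.normal(20.0, 1.0, 120),  # no accession signal
            }
        )
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        blups = compute_blups(fit)
        assert np.allclose(blups, fit.intercept, atol=0.25)

    def test_balanced_shrinkage_closed_form(self):
        """BLUP_i = intercept + k(mean_i − grand mean), k = nV_G/(nV_G + V_R)."""
        df = one_way(30, 4, vg=3.0, vr=1.0, seed=6, mu=15.0)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        vg, vr = fit.components.V_G, fit.components.V_R
        k = 4 * vg / (4 * vg + vr)
        means = df.groupby("accession_id")["value"].mean()
        expected = fit.intercept + k * (means - means.mean())
        got = compute_blups(fit)
        pd.testing.assert_series_equal(
            got.sort_index(), expected.sort_index(), atol=1e-6, check_names=False
        )

    def test_effects_sum_to_zero_balanced(self):
        df = one_way(25, 3, vg=2.0, vr=1.0, seed=7)
        fit = fit_vc_model(df, CANDIDATE_SPECS[0])
        assert abs(fit.accession_effects.sum()) < 1e-8


class TestHeritability:
    @pytest.mark.parametrize("vg, vr, expected", [(2.0, 2.0, 0.5), (0.0, 3.0, 0.0), (3.0, 1.0, 0.75)])
    def test_formula(self, vg, vr, expected):
        fit = ModelFit(
            variable="v", spec=CANDIDATE_SPECS[0], intercept=0.0,
            components=VarianceComponents(vg, vr),
            ranef={"Accession": pd.Series(dtype=float)},
            loglik=0.0, aic=0.0, n_obs=10, n_params=3,
        )
        res = compute_heritability(fit)
        assert res.H2 == expected
        assert res.defined

    def test_undefined_when_no_variance(self):
        fit = ModelFit(
            variable="v", spec=CANDIDATE_SPECS[0], intercept=0.0,
            components=VarianceComponents(0.0, 0.0),
            ranef={"Accession": pd.Series(dtype=float)},
            loglik=0.0, aic=0.0, n_obs=10, n_params=3,
        )
        res = compute_heritability(fit)
        assert not res.defined and np.isnan(res.H2)
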