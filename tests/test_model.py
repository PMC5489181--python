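"""Robust-design likelihood, fitting, model selection and averaging."""

import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

import camrecap as cr
from camrecap.model import (
    DEAD,
    OFFGRID,
    ONGRID,
    ModelStructure,
    PackedData,
    ParameterMap,
    history_loglik,
    neg_loglik,
)
from camrecap.survey import CaptureHistory, Primary, SurveyDesign

probs = st.floats(0.0, 1.0, allow_nan=False)


def _history(design, rows, sexes=None):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    sexes = sexes or ["male"] * n
    return CaptureHistory([f"i{k}" for k in range(n)], sexes, rows, design)


class TestTransitionMatrix:
    def test_no_mortality_no_emigration_forces_on_grid(self):
        M = cr.transition_matrix(1.0, 0.0, 0.0)
        assert M[ONGRID, ONGRID] == 1.0
        assert M[OFFGRID, ONGRID] == 1.0

    def test_zero_survival_absorbs_into_death(self):
        M = cr.transition_matrix(0.0, 0.3, 0.6)
        assert M[ONGRID, DEAD] == 1.0 and M[OFFGRID, DEAD] == 1.0

    def test_multi_year_gap_is_matrix_power(self):
        M1 = cr.transition_matrix(0.78, 0.20, 0.20)
        M3 = cr.transition_matrix(0.78, 0.20, 0.20, dt=3)
        assert np.allclose(M3, M1 @ M1 @ M1)
        assert np.allclose(M3.sum(axis=1), 1.0)

    def test_dt_below_one_rejected(self):
        with pytest.raises(ValueError):
            cr.transition_matrix(0.5, 0.1, 0.1, dt=0)

    @given(probs, probs, probs, st.integers(1, 5))
    def test_row_stochastic_and_death_absorbing(self, phi, gpp, gp, dt):
        M = cr.transition_matrix(phi, gpp, gp, dt)
        assert np.allclose(M.sum(axis=1), 1.0)
        assert np.allclose(M[DEAD], [0.0, 0.0, 1.0])
        assert (M >= -1e-12).all()


class TestEmissionProb:
    def test_on_grid_bernoulli_product(self):
        assert cr.emission_prob([1, 0], ONGRID, 0.36) == pytest.approx(0.36 * 0.64)

    def test_off_grid_only_produces_zeros(self):
        assert cr.emission_prob([0, 0, 0], OFFGRID, 0.4) == 1.0
        assert cr.emission_prob([1, 0], OFFGRID, 0.4) == 0.0

    def test_dead_cannot_be_seen(self):
        assert cr.emission_prob([1, 0], DEAD, 0.4) == 0.0


class TestHistoryLoglik:
    def test_single_primary_closed_form(self, single_primary_design):
        p = 0.3
        det = np.array([[1, 0, 1, 0]])
        ll = history_loglik(
            det, 0, np.zeros(0), np.zeros(0), np.zeros(0),
            np.array([p]), single_primary_design,
        )
        expected = np.log(p * 0.7 * p * 0.7 / (1 - 0.7**4))
        assert ll == pytest.approx(expected)

    def test_no_state_uncertainty_is_binomial_product(self):
        # T=2, phi=1, gamma''=0: the animal is certainly on-grid in primary 2
        prim = tuple(
            Primary(y, date(y, 2, 1), date(y, 2, 15), 2, "film") for y in (2000, 2001)
        )
        design = SurveyDesign(prim, n_stations=5)
        p = np.array([0.4, 0.6])
        det = np.array([[1, 1], [0, 1]])
        ll = history_loglik(
            det, 0, np.ones(1), np.zeros(1), np.zeros(1), p, design
        )
        expected = np.log(0.4 * 0.4 / (1 - 0.6**2)) + np.log(0.4 * 0.6)
        assert ll == pytest.approx(expected)

    def test_probabilities_sum_to_one_over_all_histories(self, tiny_design, rng):
        """Exhaustive enumeration at T=3, K=2 (including the survey gap):
        summing exp(loglik) over every history detected in a given first
        primary gives exactly 1, for random parameter draws."""
        for _ in range(50):
            phi = rng.uniform(0.2, 0.98, 2)
            gpp = rng.uniform(0.02, 0.6, 2)
            gp = rng.uniform(0.02, 0.7, 2)
            p = rng.uniform(0.05, 0.9, 3)
            f = int(rng.integers(3))
            total = 0.0
            n_post = 2 * (2 - f)
            for yf in itertools.product([0, 1], repeat=2):
                if sum(yf) == 0:
                    continue
                for rest in itertools.product([0, 1], repeat=n_post):
                    det = np.zeros((3, 2), dtype=int)
                    det[f] = yf
                    for j in range(2 - f):
                        det[f + 1 + j] = rest[2 * j : 2 * j + 2]
                    total += np.exp(
                        history_loglik(det, f, phi, gpp, gp, p, tiny_design)
                    )
            assert total == pytest.approx(1.0, abs=1e-10)


class TestNegLoglik:
    def _random_data(self, design, rng, n=5):
        T = design.n_primaries
        rows = []
        while len(rows) < n:
            r = (rng.random((T, 2)) < 0.4).astype(np.int8)
            if r.any():
                rows.append(r)
        sexes = [("male", "female")[rng.integers(2)] for _ in range(n)]
        return _history(design, np.stack(rows), sexes)

    def test_matches_per_history_reference(self, tiny_design, rng):
        data = self._random_data(tiny_design, rng)
        structure = ModelStructure("sex", "markovian", "time", "sex*time")
        pm = ParameterMap.build(structure, tiny_design)
        packed = PackedData.from_history(data, structure)
        beta = rng.normal(0, 1, pm.n_params)
        phi, gpp, gp, p = pm.realize(beta)
        ref = 0.0
        for i in range(data.n_individuals):
            s = 0 if data.sexes[i] == "male" else 1
            ref -= history_loglik(
                data.detections[i, :, :2],
                int(data.first_primary[i]),
                phi[:, s], gpp, gp, p[:, s], tiny_design,
            )
        assert neg_loglik(beta, pm, packed) == pytest.approx(ref, rel=1e-10)

    def test_empty_data_gives_zero(self, tiny_design):
        structure = ModelStructure()
        pm = ParameterMap.build(structure, tiny_design)
        empty = PackedData(
            np.zeros((0, 3), dtype=int), np.zeros(0, dtype=int),
            np.zeros(0, dtype=int), np.zeros(0), 0, (0, 0, ()),
        )
        assert neg_loglik(np.zeros(pm.n_params), pm, empty) == 0.0

    def test_duplicating_individuals_doubles_objective(self, tiny_design, rng):
        data = self._random_data(tiny_design, rng)
        doubled = _history(
            tiny_design,
            np.concatenate([data.detections, data.detections]),
            data.sexes * 2,
        )
        structure = ModelStructure()
        pm = ParameterMap.build(structure, tiny_design)
        beta = rng.normal(0, 1, pm.n_params)
        v1 = neg_loglik(beta, pm, PackedData.from_history(data, structure))
        v2 = neg_loglik(beta, pm, PackedData.from_history(doubled, structure))
        assert v2 == pytest.approx(2 * v1, rel=1e-12)


class TestFitModel:
    def test_single_primary_matches_closed_m0_estimator(self, single_primary_design):
        """With one primary the model reduces to closed M0; the fitted p
        maximises the conditional binomial likelihood, cross-checked by a
        1-d grid/scalar optimisation oracle and the derived N against n/p*."""
        rng = np.random.default_rng(4)
        K, n, p_true = 4, 40, 0.35
        rows = []
        for _ in range(n):
            r = (rng.random(K) < p_true).astype(np.int8)
            if r.any():
                rows.append(r.reshape(1, K))
        data = _history(single_primary_design, np.stack(rows))
        structure = ModelStructure(p=".", gamma_mode="none")
        fit = cr.fit_model(structure, data, single_primary_design, n_starts=3, seed=0)
        d = data.counts.sum()
        m = len(rows)

        def m0_negll(p):
            return -(
                d * np.log(p) + (m * K - d) * np.log(1 - p)
                - m * np.log(1 - (1 - p) ** K)
            )

        oracle = minimize_scalar(m0_negll, bounds=(1e-4, 1 - 1e-4), method="bounded")
        p_hat = fit.real[fit.real["param"] == "p"]["estimate"].iloc[0]
        assert p_hat == pytest.approx(oracle.x, abs=1e-6)
        ab = cr.derived_abundance(fit, data, single_primary_design)
        n_hat = ab[ab["sex"] == "male"]["N_hat"].iloc[0]
        assert n_hat == pytest.approx(m / (1 - (1 - p_hat) ** K), rel=1e-9)

    def test_no_emigration_fit_recovers_truth(self):
        """Simulated data with no emigration, fitted with the no-emigration
        model, recovers the generating survival within Monte-Carlo error."""
        import dataclasses

        config = dataclasses.replace(cr.paper_preset(seed=21), gamma_pp=0.0, gamma_p=0.0)
        ests = []
        rng = np.random.default_rng(17)
        for _ in range(10):
            _, events = cr.simulate_population(config, seed=int(rng.integers(2**31)))
            hist, _ = cr.build_capture_histories(
                cr.filter_independent(events), config.design, drop_unknown_sex=True
            )
            fit = cr.fit_model(
                ModelStructure(gamma_mode="none"), hist, config.design,
                n_starts=1, seed=0, compute_vcov=False,
            )
            ests.append(fit.real[fit.real["param"] == "phi"]["estimate"].iloc[0])
        assert abs(np.mean(ests) - config.phi) < 0.03

    def test_perfect_detection_flags_boundary(self, single_primary_design):
        rows = np.ones((6, 1, 4), dtype=np.int8)
        data = _history(single_primary_design, rows)
        fit = cr.fit_model(
            ModelStructure(p=".", gamma_mode="none"),
            data, single_primary_design, n_starts=1, seed=0,
        )
        assert fit.boundary

    def test_reduces_to_cjs_with_no_emigration(self):
        """With K=1 secondaries and no emigration the likelihood collapses to
        Cormack-Jolly-Seber; survival agrees with an independent CJS fit."""
        prim = tuple(
            Primary(y, date(y, 2, 1), date(y, 2, 9), 1, "film")
            for y in range(2000, 2006)
        )
        design = SurveyDesign(prim, n_stations=5)
        rng = np.random.default_rng(8)
        phi_true, p_true = 0.7, 0.5
        rows = []
        for _ in range(150):
            alive, row = True, np.zeros((6, 1), dtype=np.int8)
            for t in range(6):
                if t and not (alive := alive and rng.random() < phi_true):
                    break
                row[t, 0] = rng.random() < p_true
            if row.any():
                rows.append(row)
        data = _history(design, np.stack(rows))
        fit = cr.fit_model(
            ModelStructure(phi=".", gamma_mode="none", p="."),
            data, design, n_starts=3, seed=0, compute_vcov=False,
        )

        # independent CJS implementation on the collapsed data
        Y = data.counts
        first = data.first_primary

        def cjs_negll(x):
            phi, p = expit(x)
            ll = 0.0
            for i in range(Y.shape[0]):
                chi = 1.0  # P(never seen after t), built backwards
                contrib = 0.0
                last = max(np.flatnonzero(Y[i]))
                for t in range(int(first[i]) + 1, 6):
                    contrib += np.log(phi) + (
                        np.log(p) if Y[i, t] else np.log(1 - p)
                    ) if t <= last else 0.0
                # probability of not being seen after `last`
                chi = 1.0
                for t in range(5, last, -1):
                    chi = 1 - phi + phi * (1 - p) * chi
                ll += contrib + np.log(chi)
            return -ll

        from scipy.optimize import minimize

        res = minimize(cjs_negll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        phi_cjs = expit(res.x[0])
        phi_fit = fit.real[fit.real["param"] == "phi"]["estimate"].iloc[0]
        assert phi_fit == pytest.approx(phi_cjs, abs=1e-4)

    def test_markovian_nests_random_model(self, tiny_design, rng):
        """At gamma' = gamma'' the Markovian likelihood equals the random one."""
        data = TestNegLoglik()._random_data(tiny_design, rng, n=6)
        rand = ModelStructure(gamma_mode="random", p="sex")
        mark = ModelStructure(gamma_mode="markovian", p="sex")
        pm_r = ParameterMap.build(rand, tiny_design)
        pm_m = ParameterMap.build(mark, tiny_design)
        packed = PackedData.from_history(data, rand)
        beta_r = rng.normal(0, 1, pm_r.n_params)
        # map the random coefficients onto the Markovian layout
        beta_m = np.zeros(pm_m.n_params)
        beta_m[pm_m.idx_phi] = beta_r[pm_r.idx_phi]
        beta_m[pm_m.idx_gpp] = beta_r[pm_r.idx_gpp]
        beta_m[pm_m.idx_gp] = beta_r[pm_r.idx_gpp]
        beta_m[pm_m.idx_p] = beta_r[pm_r.idx_p]
        assert neg_loglik(beta_m, pm_m, packed) == pytest.approx(
            neg_loglik(beta_r, pm_r, packed), rel=1e-12
        )


class TestDerivedAbundance:
    def _fit_like(self, design, p_hat, data):
        structure = ModelStructure(p=".", gamma_mode="none")
        pm = ParameterMap.build(structure, design)
        beta = np.zeros(pm.n_params)
        beta[pm.idx_p[0, 0]] = logit(p_hat)
        from camrecap.model import FitResult, _real_table

        vcov = np.zeros((pm.n_params, pm.n_params))
        return FitResult(
            structure, design, beta, vcov, 0.0, pm.n_params, 100.0, 0.0,
            _real_table(pm, beta, vcov), True, False, data.n_individuals, (),
        )

    def test_hand_computed_example(self, single_primary_design):
        # n=10, p=0.5, K=2 -> p*=0.75, N=13.33
        prim = (Primary(2005, date(2005, 2, 1), date(2005, 2, 15), 2, "film"),)
        design = SurveyDesign(prim, n_stations=5)
        rows = np.zeros((10, 1, 2), dtype=np.int8)
        rows[:, 0, 0] = 1
        data = _history(design, rows)
        fit = self._fit_like(design, 0.5, data)
        ab = cr.derived_abundance(fit, data, design)
        male = ab[ab["sex"] == "male"].iloc[0]
        assert male["p_star"] == pytest.approx(0.75)
        assert male["N_hat"] == pytest.approx(10 / 0.75)

    def test_perfect_detection_returns_count(self, single_primary_design):
        rows = np.zeros((7, 1, 4), dtype=np.int8)
        rows[:, 0, 0] = 1
        data = _history(single_primary_design, rows)
        fit = self._fit_like(single_primary_design, 1 - 1e-12, data)
        ab = cr.derived_abundance(fit, data, single_primary_design)
        assert ab[ab["sex"] == "male"]["N_hat"].iloc[0] == pytest.approx(7.0)

    def test_no_detections_flagged_not_estimable(self, single_primary_design):
        rows = np.zeros((3, 1, 4), dtype=np.int8)
        rows[:, 0, 0] = 1
        data = _history(single_primary_design, rows)  # males only
        fit = self._fit_like(single_primary_design, 0.4, data)
        ab = cr.derived_abundance(fit, data, single_primary_design)
        female = ab[ab["sex"] == "female"].iloc[0]
        assert not female["estimable"] and np.isnan(female["N_hat"])


class TestModelSelection:
    def test_equal_aicc_gives_equal_weights(self):
        tab = cr.akaike_weights([100.0, 100.0])
        assert np.allclose(tab["weight"], [0.5, 0.5])

    def test_weights_sum_to_one_and_shift_invariant(self, rng):
        a = rng.uniform(1000, 1100, 7)
        t1, t2 = cr.akaike_weights(a), cr.akaike_weights(a + 123.4)
        assert t1["weight"].sum() == pytest.approx(1.0)
        assert np.allclose(t1["weight"], t2["weight"])

    def test_mixed_datasets_rejected(self, tiny_design, rng):
        data1 = TestNegLoglik()._random_data(tiny_design, rng, n=5)
        data2 = TestNegLoglik()._random_data(tiny_design, rng, n=7)
        f1 = cr.fit_model(cr.ModelStructure(p="."), data1, tiny_design,
                          n_starts=1, seed=0, compute_vcov=False)
        f2 = cr.fit_model(cr.ModelStructure(p="."), data2, tiny_design,
                          n_starts=1, seed=0, compute_vcov=False)
        with pytest.raises(ValueError):
            cr.aicc_weights([f1, f2])


class TestModelAverage:
    def _table(self, est, se):
        return pd.DataFrame(
            {"param": ["phi"], "sex": ["male"], "year": [2002],
             "estimate": [est], "se": [se]}
        )

    def test_single_model_is_identity(self):
        t = self._table(0.78, 0.05)
        out = cr.model_average([t], [1.0])
        assert out["estimate"].iloc[0] == 0.78
        assert out["se"].iloc[0] == pytest.approx(0.05)

    def test_equal_estimates_average_the_ses(self):
        out = cr.model_average([self._table(0.5, 0.04), self._table(0.5, 0.08)],
                               [0.5, 0.5])
        assert out["se"].iloc[0] == pytest.approx(0.06)

    def test_hand_computed_three_model_average(self):
        tabs = [self._table(0.70, 0.05), self._table(0.80, 0.04),
                self._table(0.90, 0.03)]
        w = np.array([0.5, 0.3, 0.2])
        out = cr.model_average(tabs, w)
        theta = 0.5 * 0.70 + 0.3 * 0.80 + 0.2 * 0.90
        se = (0.5 * np.sqrt(0.05**2 + (0.70 - theta) ** 2)
              + 0.3 * np.sqrt(0.04**2 + (0.80 - theta) ** 2)
              + 0.2 * np.sqrt(0.03**2 + (0.90 - theta) ** 2))
        assert out["estimate"].iloc[0] == pytest.approx(theta)
        assert out["se"].iloc[0] == pytest.approx(se)

    def test_mismatched_grids_rejected(self):
        t2 = self._table(0.8, 0.05)
        t2["year"] = 2003
        with pytest.raises(ValueError):
            cr.model_average([self._table(0.7, 0.05), t2], [0.5, 0.5])


class TestStructureDsl:
    @pytest.mark.parametrize(
        "text",
        [
            "phi(.) gamma(random,.) p(sex*era(./time))",
            "phi(sex) gamma(markovian,time) p(sex*era)",
            "phi(sex(time/.)) gamma(none) p(.)",
        ],
    )
    def test_round_trip(self, text):
        st_ = cr.parse_structure(text)
        assert cr.parse_structure(st_.name) == st_

    def test_printed_candidate_set_matches_selection_table(self):
        names = [s.name for s in cr.printed_candidate_set()]
        assert names == cr.datasets.reference_model_selection()["model"].tolist()

    def test_no_emigration_has_no_gamma_coefficients(self, tiny_design):
        pm_none = ParameterMap.build(ModelStructure(gamma_mode="none", p="."),
                                     tiny_design)
        pm_rand = ParameterMap.build(ModelStructure(gamma_mode="random", p="."),
                                     tiny_design)
        assert pm_none.n_params == pm_rand.n_params - 1
        phi, gpp, gp, _ = pm_none.realize(np.zeros(pm_none.n_params))
        assert (gpp == 0).all() and (gp == 1).all()
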