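"""Joint GBLUP: covariance assembly, REML, LRT, genetic parameters and
BLUP prediction, checked against brute-force Kronecker and conditional-mean
oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from metgp import gblup, simdata, genotypes
from metgp.genotypes import KernelMatrix
from metgp.gblup import VarianceComponents


def _kernel(mat, ids, kind="additive"):
    return KernelMatrix(np.asarray(mat, dtype=float), ids, kind)


def _eblues_from_cells(values, hybrids, envs):
    rows = []
    vals = np.asarray(values, dtype=float)  # env-major (q, p)
    for j, e in enumerate(envs):
        for i, h in enumerate(hybrids):
            if not np.isnan(vals[j, i]):
                rows.append({"hybrid": h, "environment": e, "eblue": vals[j, i]})
    return pd.DataFrame(rows)


class TestBuildCovariance:
    def test_single_environment_has_no_correlation_terms(self):
        A = np.array([[1.0, 0.3], [0.3, 1.0]])
        D = np.array([[1.0, 0.1], [0.1, 1.0]])
        vc = VarianceComponents(model="AD", q=1, sigma2_ua=2.0, sigma2_ud=0.5,
                                sigma2_e=0.25)
        V = gblup.build_covariance(vc, _kernel(A, ["a", "b"]),
                                   _kernel(D, ["a", "b"], "dominance"))
        np.testing.assert_allclose(V, 2.0 * A + 0.5 * D + 0.25 * np.eye(2))

    def test_identity_kernel_zero_rho_gives_scaled_identity_block(self):
        vc = VarianceComponents(model="A", q=3, sigma2_ua=1.7, sigma2_e=0.0,
                                rho_a=0.0)
        V = gblup.build_covariance(vc, _kernel(np.eye(2), ["a", "b"]))
        np.testing.assert_allclose(V, 1.7 * np.eye(6), atol=1e-12)

    def test_matches_brute_force_kronecker_expansion(self):
        rng = np.random.default_rng(2)
        B = rng.standard_normal((2, 2))
        A = B @ B.T + np.eye(2)
        vc = VarianceComponents(model="A", q=2, sigma2_ua=1.0, sigma2_e=0.3,
                                rho_a=0.5)
        V = gblup.build_covariance(vc, _kernel(A, ["a", "b"]))
        CS = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = np.kron(CS, A) + 0.3 * np.eye(4)
        np.testing.assert_allclose(V, expected, atol=1e-12)

    def test_rho_at_lower_boundary_rejected(self):
        vc = VarianceComponents(model="A", q=3, sigma2_ua=1.0, sigma2_e=0.1,
                                rho_a=-0.5)
        with pytest.raises(ValueError, match="positive definite"):
            gblup.build_covariance(vc, _kernel(np.eye(2), ["a", "b"]))

    def test_masking_deletes_rows_and_columns(self):
        vc = VarianceComponents(model="A", q=2, sigma2_ua=1.0, sigma2_e=0.1,
                                rho_a=0.4)
        A = np.array([[1.0, 0.2], [0.2, 1.0]])
        obs = np.array([True, True, False, True])
        V_full = gblup.build_covariance(vc, _kernel(A, ["a", "b"]))
        V_obs = gblup.build_covariance(vc, _kernel(A, ["a", "b"]), obs=obs)
        np.testing.assert_allclose(V_obs, V_full[np.ix_(obs, obs)])


class TestRemlFit:
    def test_structured_and_dense_paths_agree(self, small_dataset):
        eb, A, D = (small_dataset[k] for k in ("eblues", "A", "D"))
        envs = small_dataset["environments"]
        mask = pd.DataFrame(False, index=A.ids, columns=envs)
        mask.iloc[:10, :2] = True  # partial-grid masking
        # exact agreement of the two objective implementations at fixed
        # parameters, and near-agreement of the resulting optima
        import metgp.gblup as g
        y, obs = gblup.cells_from_eblues(eb, A.ids, envs, "GY", mask)
        Av = A.values + 1e-6 * np.eye(A.n)
        Dv = D.values + 1e-6 * np.eye(D.n)
        struct = g._StructuredREML(np.nan_to_num(y), obs, Av, Dv, 4)
        dense = g._DenseREML(y, obs, Av, Dv, 4)
        for x in (g._pack_start("AD", 4), np.array([0.5, -0.3, 1.0, 0.2])):
            assert struct.neglik(x, "AD") == pytest.approx(
                dense.neglik(x, "AD"), abs=1e-7)
        fast = gblup.reml_fit(eb, A, D, model="AD", mask=mask, trait="GY",
                              environments=envs)
        ref = gblup.reml_fit(eb, A, D, model="AD", mask=mask, trait="GY",
                             environments=envs, dense=True)
        assert fast.logL == pytest.approx(ref.logL, abs=1e-3)
        assert fast.sigma2_ua == pytest.approx(ref.sigma2_ua, rel=1e-2)
        assert fast.rho_a == pytest.approx(ref.rho_a, abs=1e-2)

    def test_no_signal_null_keeps_additive_variance_small(self):
        # Pure-noise data (sigma2_ua = 0, sigma2_e = 1, 400 cells): the
        # fitted additive variance should collapse. A realized genomic
        # kernel is used rather than the identity — with A = I the cell
        # variance splits into sigma2_ua + sigma2_e along a likelihood
        # ridge and the additive component is not identified.
        cfg = simdata.SimConfig(
            n_lines_per_group={"dent": 40, "flint": 40, "C": 10},
            n_hybrids=100, n_snps=400, seed=123)
        _, hybrids, _ = simdata.simulate_hybrids(cfg)
        A = genotypes.vanraden_A(hybrids)
        envs = ["e1", "e2", "e3", "e4"]
        hits = 0
        for seed in range(20):
            y = np.random.default_rng(seed).standard_normal((4, A.n))
            eb = _eblues_from_cells(y, list(A.ids), envs)
            vc = gblup.reml_fit(eb, A, model="A", environments=envs)
            if vc.sigma2_ua < 0.1:
                hits += 1
        assert hits >= 18

    def test_logl_of_nested_models_ordered(self, small_dataset):
        eb, A, D = (small_dataset[k] for k in ("eblues", "A", "D"))
        envs = small_dataset["environments"]
        full = gblup.reml_fit(eb, A, D, model="AD", trait="GY", environments=envs)
        red = gblup.reml_fit(eb, A, model="A", trait="GY", environments=envs)
        assert full.logL >= red.logL - 1e-6

    def test_restricted_likelihood_invariant_to_fixed_effect_translation(
            self, small_dataset):
        eb, A, D = (small_dataset[k] for k in ("eblues", "A", "D"))
        envs = small_dataset["environments"]
        base = gblup.reml_fit(eb, A, D, model="AD", trait="GY", environments=envs)
        shifted = eb.copy()
        shifted.loc[shifted["environment"] == envs[1], "eblue"] += 11.0
        moved = gblup.reml_fit(shifted, A, D, model="AD", trait="GY",
                               environments=envs)
        assert moved.logL == pytest.approx(base.logL, abs=1e-4)

    def test_missing_environment_rejected(self, small_dataset):
        eb, A = small_dataset["eblues"], small_dataset["A"]
        envs = small_dataset["environments"]
        mask = pd.DataFrame(False, index=A.ids, columns=envs)
        mask.iloc[:, 0] = True
        with pytest.raises(ValueError, match="no observed cells"):
            gblup.reml_fit(eb, A, model="A", mask=mask, trait="GY",
                           environments=envs)


class TestWithinEnvironment:
    def test_equals_joint_fit_restricted_to_one_environment(self, small_dataset):
        eb, A, D = (small_dataset[k] for k in ("eblues", "A", "D"))
        env = small_dataset["environments"][0]
        a = gblup.fit_within_environment(eb, A, D, environment=env, trait="GY")
        sub = eb[eb["environment"] == env]
        b = gblup.reml_fit(sub, A, D, model="AD", environments=[env], trait="GY")
        assert a.logL == pytest.approx(b.logL, abs=1e-6)
        assert a.rho_a is None and a.q == 1

    def test_zero_noise_signal_drives_residual_variance_down(self):
        rng = np.random.default_rng(3)
        p = 60
        hybrids = [f"h{i}" for i in range(p)]
        B = rng.standard_normal((p, p))
        A = B @ B.T / p
        u = np.linalg.cholesky(A + 1e-8 * np.eye(p)) @ rng.standard_normal(p)
        eb = _eblues_from_cells(u[None, :], hybrids, ["e1"])
        vc = gblup.fit_within_environment(eb, _kernel(A, hybrids),
                                          environment="e1", model="A")
        assert vc.sigma2_e < 0.05 * vc.sigma2_ua

    def test_consistent_relabeling_leaves_estimates_unchanged(self, small_dataset):
        eb, A = small_dataset["eblues"], small_dataset["A"]
        env = small_dataset["environments"][1]
        base = gblup.fit_within_environment(eb, A, environment=env, model="A",
                                            trait="GY")
        ids = list(A.ids)
        swap = {old: f"relabel_{i}" for i, old in enumerate(ids)}
        A_re = KernelMatrix(A.values, [swap[h] for h in ids], "additive")
        eb2 = eb.copy()
        eb2["hybrid"] = eb2["hybrid"].map(swap)
        # relabelling eblues and kernel together describes the same model
        vc = gblup.fit_within_environment(eb2, A_re, environment=env,
                                          model="A", trait="GY")
        assert vc.logL == pytest.approx(base.logL, abs=1e-5)
        assert vc.sigma2_ua == pytest.approx(base.sigma2_ua, rel=1e-3)


class TestLRT:
    def test_two_logl_units_give_known_chi_square_tail(self):
        full = VarianceComponents(model="AD", q=4, sigma2_ua=1, sigma2_e=1,
                                  logL=-100.0)
        red = VarianceComponents(model="A", q=4, sigma2_ua=1, sigma2_e=1,
                                 logL=-102.0)
        res = gblup.lrt(full, red)
        assert res.statistic == pytest.approx(4.0)
        assert res.p_value == pytest.approx(chi2.sf(4.0, 1), abs=1e-12)
        assert res.p_value == pytest.approx(0.0455, abs=2e-4)
        assert res.significant

    def test_equal_likelihoods_not_significant(self):
        vc = VarianceComponents(model="A", q=4, sigma2_ua=1, sigma2_e=1,
                                logL=-50.0)
        res = gblup.lrt(vc, vc)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert not res.significant

    def test_critical_value_boundary_is_not_significant(self):
        full = VarianceComponents(model="AD", q=4, sigma2_ua=1, sigma2_e=1,
                                  logL=-100.0)
        red = VarianceComponents(model="A", q=4, sigma2_ua=1, sigma2_e=1,
                                 logL=-100.0 - 3.841 / 2)
        res = gblup.lrt(full, red)
        assert res.p_value == pytest.approx(0.05, abs=1e-4)
        assert not res.significant  # strict p < 0.05

    def test_negative_statistic_beyond_tolerance_errors(self):
        full = VarianceComponents(model="AD", q=4, sigma2_ua=1, sigma2_e=1,
                                  logL=-101.0)
        red = VarianceComponents(model="A", q=4, sigma2_ua=1, sigma2_e=1,
                                 logL=-100.0)
        with pytest.raises(ValueError, match="negative LRT"):
            gblup.lrt(full, red)


class TestGeneticParams:
    def test_pure_additive_limit(self):
        vc = VarianceComponents(model="A", q=1, sigma2_ua=2.0, sigma2_e=0.0)
        gp = gblup.genetic_params(vc)
        assert gp.h2 == 1.0 and gp.d2 == 0.0 and gp.H2 == 1.0

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gblup.heritability_partition(0.0, 0.0, 0.0)

    def test_partition_sums(self):
        gp = gblup.heritability_partition(0.6, 0.3, 0.9)
        assert gp.h2 + gp.d2 == pytest.approx(gp.H2)


class TestPredictCells:
    def test_unrelated_hybrid_gets_fixed_part_only(self):
        # hybrid c has zero kernel covariance with every observed hybrid
        A = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        ids = ["a", "b", "c"]
        vc = VarianceComponents(model="A", q=2, sigma2_ua=1.0, sigma2_e=0.5,
                                rho_a=0.6)
        envs = ["e1", "e2"]
        y = np.array([[1.0, 2.0, np.nan], [0.5, 1.5, np.nan]])
        eb = _eblues_from_cells(y, ids, envs)
        preds = gblup.predict_cells(vc, eb, _kernel(A, ids), environments=envs,
                                    jitter=0.0)
        fixed = preds.set_index(["hybrid", "environment"])["value"]
        # GLS environment means: balanced two observations per environment
        assert fixed[("c", "e1")] == pytest.approx(1.5, abs=1e-8)
        assert fixed[("c", "e2")] == pytest.approx(1.0, abs=1e-8)

    def test_perfect_correlation_copies_genetic_part_across_environments(self):
        # rho_a = 1, no dominance, hybrid c observed only in environment 1;
        # data symmetric across environments so both GLS environment means
        # agree -> the prediction for c must be identical in e1 and e2.
        rng = np.random.default_rng(1)
        B = rng.standard_normal((3, 3))
        A = B @ B.T + np.eye(3)
        ids = ["a", "b", "c"]
        envs = ["e1", "e2"]
        vc = VarianceComponents(model="A", q=2, sigma2_ua=1.0, sigma2_e=0.4,
                                rho_a=1.0 - 1e-9)
        y = np.array([[1.0, -0.5, np.nan], [1.0, -0.5, np.nan]])
        eb = _eblues_from_cells(y, ids, envs)
        preds = gblup.predict_cells(vc, eb, _kernel(A, ids), environments=envs,
                                    targets=[("c", "e1"), ("c", "e2")],
                                    jitter=0.0)
        v = preds.set_index("environment")["value"]
        assert v["e1"] == pytest.approx(v["e2"], abs=1e-6)

    def test_matches_joint_gaussian_conditional_mean_oracle(self):
        rng = np.random.default_rng(4)
        p, q = 3, 2
        ids = ["a", "b", "c"]
        envs = ["e1", "e2"]
        B = rng.standard_normal((p, p))
        A = B @ B.T / p + 0.5 * np.eye(p)
        C = rng.standard_normal((p, p))
        D = C @ C.T / p + 0.5 * np.eye(p)
        vc = VarianceComponents(model="AD", q=q, sigma2_ua=1.2, sigma2_ud=0.4,
                                sigma2_e=0.3, rho_a=0.5, rho_d=0.2)
        y = np.array([[0.3, -1.1, 0.7], [1.9, 0.4, np.nan]])
        eb = _eblues_from_cells(y, ids, envs)
        preds = gblup.predict_cells(vc, eb, _kernel(A, ids),
                                    _kernel(D, ids, "dominance"),
                                    environments=envs, jitter=0.0)

        # oracle: explicit conditional mean on the fully expanded covariance
        CSa = 1.2 * np.array([[1, 0.5], [0.5, 1]])
        CSd = 0.4 * np.array([[1, 0.2], [0.2, 1]])
        G = np.kron(CSa, A) + np.kron(CSd, D)
        V = G + 0.3 * np.eye(p * q)
        yflat = y.reshape(-1)
        obs = ~np.isnan(yflat)
        X = np.kron(np.eye(q), np.ones((p, 1)))
        Vo = V[np.ix_(obs, obs)]
        Vi = np.linalg.inv(Vo)
        Xo = X[obs]
        beta = np.linalg.solve(Xo.T @ Vi @ Xo, Xo.T @ Vi @ yflat[obs])
        resid = yflat[obs] - Xo @ beta
        t = np.flatnonzero(~obs)
        oracle = X[t] @ beta + G[np.ix_(t, np.flatnonzero(obs))] @ Vi @ resid
        np.testing.assert_allclose(preds["value"].to_numpy(), oracle, atol=1e-8)

    def test_single_kernel_q1_matches_textbook_gblup(self):
        # q = 1, D absent: u_hat = s2_ua A Z' V^-1 (y - X bhat)
        rng = np.random.default_rng(7)
        p = 8
        ids = [f"h{i}" for i in range(p)]
        B = rng.standard_normal((p, p))
        A = B @ B.T / p + 0.3 * np.eye(p)
        yv = rng.standard_normal(p)
        eb = _eblues_from_cells(np.concatenate([yv[:5], [np.nan] * 3])[None, :],
                                ids, ["e1"])
        vc = VarianceComponents(model="A", q=1, sigma2_ua=0.9, sigma2_e=0.2)
        preds = gblup.predict_cells(vc, eb, _kernel(A, ids),
                                    environments=["e1"], jitter=0.0)
        obs = slice(0, 5)
        V = 0.9 * A[obs, obs] + 0.2 * np.eye(5)
        Vi = np.linalg.inv(V)
        one = np.ones(5)
        mu = (one @ Vi @ yv[:5]) / (one @ Vi @ one)
        u = 0.9 * A[5:, obs] @ Vi @ (yv[:5] - mu)
        np.testing.assert_allclose(preds["value"].to_numpy(), mu + u, atol=1e-8)

    def test_unknown_target_hybrid_errors(self, small_dataset):
        eb, A = small_dataset["eblues"], small_dataset["A"]
        envs = small_dataset["environments"]
        vc = VarianceComponents(model="A", q=4, sigma2_ua=1.0, sigma2_e=0.5,
                                rho_a=0.3)
        with pytest.raises(KeyError, match="absent"):
            gblup.predict_cells(vc, eb, A, environments=envs,
                                targets=[("nonexistent", envs[0])])


class TestParameterRecovery:
    def test_reml_recovers_generative_components(self):
        # 8-seed Monte-Carlo at moderate size (the full 20-seed study-scale
        # version runs with the acceptance checks)
        truth = dict(sigma2_a=0.6, sigma2_d=0.3, sigma2_e=0.8,
                     rho_a=0.35, rho_d=0.8)
        est = []
        for seed in range(8):
            cfg = simdata.SimConfig(
                n_lines_per_group={"dent": 60, "flint": 60, "C": 10},
                n_hybrids=150, n_snps=600, seed=seed, **truth)
            _, hybrids, _ = simdata.simulate_hybrids(cfg)
            eff = simdata.simulate_effects(cfg, hybrids)
            eb = simdata.simulate_eblues(eff, cfg)
            A = genotypes.vanraden_A(hybrids)
            D = genotypes.vitezica_D(hybrids)
            vc = gblup.reml_fit(eb, A, D, model="AD", trait="GY",
                                environments=list(cfg.environments()["environment"]))
            est.append([vc.sigma2_ua, vc.sigma2_ud, vc.sigma2_e,
                        vc.rho_a, vc.rho_d])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 0.6) / 0.6 < 0.25
        assert abs(mean[1] - 0.3) / 0.3 < 0.35
        assert abs(mean[2] - 0.8) / 0.8 < 0.25
        assert abs(mean[3] - 0.35) < 0.15
        assert abs(mean[4] - 0.8) < 0.2
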