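"""Study-condition benchmark experiments.

Self-contained runners that exercise the pipeline under the study's
conditions (sample sizes, variance components, CV design) and return the
headline quantities: ratio arithmetic on the published variance-component
table, REML parameter recovery on synthetic panels, oracle-equivalence
error norms, CV masking audits, the qualitative scenario/model orderings,
and the ensemble combination-rule contracts. Both the test suite and the
reproduction script call these with fixed seeds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import crossval, gblup, genotypes, published, simdata, treeml

__all__ = [
    "table_arithmetic",
    "dominance_shares",
    "budget_numbers",
    "reml_recovery",
    "oracle_errors",
    "cv_machinery_counts",
    "cv_orderings",
    "ensemble_contracts",
]


# ---------------------------------------------------------------------------
# Published-table arithmetic (deterministic)
# ---------------------------------------------------------------------------

def table_arithmetic() -> dict:
    """Recompute h2 / d2 / H2 for every published analysis from its printed
    variance components and compare with the printed ratios."""
    tab = published.variance_components()
    n_match = 0
    computed = {}
    for _, row in tab.iterrows():
        gp = gblup.heritability_partition(row["sigma2_ua"], row["sigma2_ud"],
                                          row["sigma2_e"])
        key = f"{row['trait'].lower()}_{row['regime'].lower()}_{row['analysis'].lower()}"
        computed[key] = gp
        for est, printed in ((gp.h2, row["h2"]), (gp.d2, row["d2"]),
                             (gp.H2, row["H2"])):
            if abs(est - printed) <= 0.01:
                n_match += 1
    out = {"n_cells": 3 * len(tab), "n_match_within_0p01": n_match}
    for key in ("gy_ws_joint", "gy_ww_joint", "fft_ws_joint", "fft_ww_joint"):
        gp = computed[key]
        out[f"h2_{key}"] = round(gp.h2, 2)
        out[f"d2_{key}"] = round(gp.d2, 2)
        out[f"H2_{key}"] = round(gp.H2, 2)
    return out


def dominance_shares() -> dict:
    """Dominance share of the genetic variance, s2_ud / (s2_ua + s2_ud),
    from the joint fits, in percent."""
    tab = published.variance_components()
    joint = tab[tab["analysis"] == "joint"].set_index(["trait", "regime"])
    out = {}
    for (trait, regime), row in joint.iterrows():
        share = 100.0 * row["sigma2_ud"] / (row["sigma2_ua"] + row["sigma2_ud"])
        out[f"dominance_share_{trait.lower()}_{regime.lower()}_pct"] = round(share, 1)
    return out


def budget_numbers() -> dict:
    """The worked phenotyping-budget example."""
    inp = published.budget_inputs()
    out = crossval.budget_estimate(**inp)
    return {
        "phenotyping_budget_usd": out["phenotyping"],
        "savings_25pct_usd": out["savings"],
    }


# ---------------------------------------------------------------------------
# REML parameter recovery (stochastic)
# ---------------------------------------------------------------------------

def _recovery_config(seed: int, n_hybrids: int = 300, n_snps: int = 1000):
    per = n_hybrids // 3
    return simdata.SimConfig(
        n_lines_per_group={"dent": per, "flint": per, "C": per // 3},
        n_hybrids=n_hybrids, n_snps=n_snps,
        sigma2_a=0.6, sigma2_d=0.3, sigma2_e=0.8, rho_a=0.35, rho_d=0.8,
        seed=seed)


def reml_recovery(n_seeds: int = 20, n_hybrids: int = 300,
                  seed: int = 0) -> dict:
    """Fit GBLUP-AD (and -A) on synthetic panels generated from known
    components: truth (0.6, 0.3, 0.8, 0.35, 0.8) at 300 hybrids x 4
    environments. Returns mean estimates over seeds and the fraction of
    seeds with logL(AD) >= logL(A)."""
    rng = np.random.default_rng(seed)
    est, logl_ok = [], 0
    for _ in range(n_seeds):
        cfg = _recovery_config(int(rng.integers(2**31 - 1)), n_hybrids)
        _, hybrids, _ = simdata.simulate_hybrids(cfg)
        eff = simdata.simulate_effects(cfg, hybrids)
        eb = simdata.simulate_eblues(eff, cfg)
        A = genotypes.vanraden_A(hybrids)
        D = genotypes.vitezica_D(hybrids)
        envs = list(cfg.environments()["environment"])
        ad = gblup.reml_fit(eb, A, D, model="AD", trait="GY", environments=envs)
        a = gblup.reml_fit(eb, A, model="A", trait="GY", environments=envs)
        est.append([ad.sigma2_ua, ad.sigma2_ud, ad.sigma2_e, ad.rho_a, ad.rho_d])
        logl_ok += int(ad.logL >= a.logL - 1e-6)
    mean = np.mean(est, axis=0)
    return {
        "n_seeds": n_seeds, "n_hybrids": n_hybrids,
        "mean_sigma2_ua_hat": round(float(mean[0]), 4),
        "mean_sigma2_ud_hat": round(float(mean[1]), 4),
        "mean_sigma2_e_hat": round(float(mean[2]), 4),
        "mean_rho_a_hat": round(float(mean[3]), 4),
        "mean_rho_d_hat": round(float(mean[4]), 4),
        "frac_logl_ad_ge_a": logl_ok / n_seeds,
    }


# ---------------------------------------------------------------------------
# Oracle equivalence (deterministic)
# ---------------------------------------------------------------------------

def oracle_errors(seed: int = 0) -> dict:
    """Maximum absolute deviations of the implementation from brute-force
    oracles: Kronecker covariance assembly, joint-Gaussian conditional-mean
    prediction, and double-loop kernel computation."""
    rng = np.random.default_rng(seed)
    p, q = 4, 2
    ids = [f"h{i}" for i in range(p)]
    envs = ["e1", "e2"]
    B = rng.standard_normal((p, p))
    A = B @ B.T / p + 0.5 * np.eye(p)
    C = rng.standard_normal((p, p))
    D = C @ C.T / p + 0.5 * np.eye(p)
    Ak = genotypes.KernelMatrix(A, ids, "additive")
    Dk = genotypes.KernelMatrix(D, ids, "dominance")
    vc = gblup.VarianceComponents(model="AD", q=q, sigma2_ua=1.0,
                                  sigma2_ud=0.5, sigma2_e=0.3,
                                  rho_a=0.5, rho_d=0.2)
    # Kronecker oracle
    CSa = np.array([[1.0, 0.5], [0.5, 1.0]])
    CSd = 0.5 * np.array([[1.0, 0.2], [0.2, 1.0]])
    G = np.kron(CSa, A) + np.kron(CSd, D)
    V_oracle = G + 0.3 * np.eye(p * q)
    V = gblup.build_covariance(vc, Ak, Dk)
    kron_err = float(np.max(np.abs(V - V_oracle)))

    # conditional-mean oracle: observe 6 of 8 cells
    yflat = rng.standard_normal(p * q)
    yflat[[3, 6]] = np.nan
    rows = [{"hybrid": ids[i % p], "environment": envs[i // p],
             "eblue": yflat[i]} for i in range(p * q) if not np.isnan(yflat[i])]
    eb = pd.DataFrame(rows)
    preds = gblup.predict_cells(vc, eb, Ak, Dk, environments=envs, jitter=0.0)
    obs = ~np.isnan(yflat)
    X = np.kron(np.eye(q), np.ones((p, 1)))
    Vi = np.linalg.inv(V_oracle[np.ix_(obs, obs)])
    Xo = X[obs]
    beta = np.linalg.solve(Xo.T @ Vi @ Xo, Xo.T @ Vi @ yflat[obs])
    t = np.flatnonzero(~obs)
    cond = X[t] @ beta + G[np.ix_(t, np.flatnonzero(obs))] @ Vi @ (
        yflat[obs] - Xo @ beta)
    pred_err = float(np.max(np.abs(preds["value"].to_numpy() - cond)))

    # kernel double-loop oracles
    M = rng.choice([0.0, 1.0, 2.0], size=(50, 200))
    gm = genotypes.GenotypeMatrix(
        pd.DataFrame(M, index=[f"g{i}" for i in range(50)],
                     columns=[f"m{j}" for j in range(200)]), kind="hybrid")
    pfr = M.mean(axis=0) / 2.0
    W = M - 2 * pfr
    A_oracle = np.empty((50, 50))
    for i in range(50):
        for j in range(50):
            A_oracle[i, j] = np.dot(W[i], W[j])
    A_oracle /= 2 * np.sum(pfr * (1 - pfr))
    a_err = float(np.max(np.abs(genotypes.vanraden_A(gm).values - A_oracle)))
    H = np.where(M == 2, -2 * (1 - pfr) ** 2,
                 np.where(M == 1, 2 * pfr * (1 - pfr), -2 * pfr ** 2))
    D_oracle = H @ H.T / np.sum((2 * pfr * (1 - pfr)) ** 2)
    d_err = float(np.max(np.abs(genotypes.vitezica_D(gm).values - D_oracle)))
    return {
        "kron_covariance_max_abs_err": kron_err,
        "conditional_mean_max_abs_err": pred_err,
        "vanraden_max_abs_err": a_err,
        "vitezica_max_abs_err": d_err,
    }


# ---------------------------------------------------------------------------
# CV machinery (exact)
# ---------------------------------------------------------------------------

def cv_machinery_counts(seed: int = 0) -> dict:
    """Exact combinatorial checks of the fold/mask machinery at study size."""
    hybrids = [f"h{i}" for i in range(265)]
    folds = crossval.make_folds(hybrids, k=5, seed=seed)
    sizes = folds.value_counts()
    envs = ["J10", "T10", "J11", "T11"]
    per_hybrid = {}
    for scen in crossval.SCENARIOS:
        mask = crossval.build_mask(folds, 0, scen, envs, seed=seed + 1)
        per = mask.sum(axis=1)[folds == 0]
        per_hybrid[scen] = (int(per.min()), int(per.max()))
    return {
        "fold_size_265_k5": int(sizes.iloc[0]),
        "fold_sizes_all_equal": bool(sizes.nunique() == 1),
        "cv1_masked_envs_per_hybrid": per_hybrid["CV1"][0],
        "cv2_50_masked_envs_per_hybrid": per_hybrid["CV2_50"][0],
        "cv2_25_masked_envs_per_hybrid": per_hybrid["CV2_25"][0],
        "mask_counts_exact": bool(all(lo == hi for lo, hi in per_hybrid.values())),
    }


# ---------------------------------------------------------------------------
# Qualitative CV orderings (stochastic, study scale)
# ---------------------------------------------------------------------------

def cv_orderings(n_seeds: int = 20, seed: int = 0, repeats: int = 2,
                 n_snps: int = 1000) -> dict:
    """CV1 / CV2-50 / CV2-25 x GBLUP-A / GBLUP-AD at the study scale.

    Each seed simulates a fresh 265-hybrid panel under the grain-yield
    water-stress generative parameters, runs the paired CV design (shared
    folds, nested scenario masks, ability pooled over folds per repeat)
    and records whether mean ability satisfies CV2-25 >= CV2-50 >= CV1 for
    GBLUP-AD and whether GBLUP-AD >= GBLUP-A overall.
    """
    rng = np.random.default_rng(seed)
    order_ok = ad_ok = 0
    means = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_seeds):
            s = int(rng.integers(2**31 - 1))
            cfg = simdata.SimConfig(n_snps=n_snps, seed=s)
            parents, hybrids, crosses = simdata.simulate_hybrids(cfg)
            eff = simdata.simulate_effects(cfg, hybrids)
            eb = simdata.simulate_eblues(eff, cfg)
            A = genotypes.vanraden_A(hybrids)
            D = genotypes.vitezica_D(hybrids)
            strata = simdata.cross_strata(parents, crosses).to_dict()
            summary, _, _ = crossval.run_cv(
                eb, A, D, methods=("GBLUP-A", "GBLUP-AD"), repeats=repeats,
                k=5, seed=int(rng.integers(2**31 - 1)), trait="GY",
                strata=strata, pool_folds=True, nested_masks=True)
            m = summary.groupby(["method", "scenario"])["mean_r"].mean()
            ad, a = m["GBLUP-AD"], m["GBLUP-A"]
            order_ok += int(ad["CV2_25"] >= ad["CV2_50"] >= ad["CV1"])
            ad_ok += int(ad.mean() >= a.mean())
            means.append([ad["CV1"], ad["CV2_50"], ad["CV2_25"], a.mean()])
    mean = np.mean(means, axis=0)
    return {
        "n_seeds": n_seeds, "n_hybrids": 265,
        "ability_ad_cv1": round(float(mean[0]), 4),
        "ability_ad_cv2_50": round(float(mean[1]), 4),
        "ability_ad_cv2_25": round(float(mean[2]), 4),
        "ability_a_overall": round(float(mean[3]), 4),
        "seeds_with_cv_ordering": order_ok,
        "seeds_with_ad_ge_a": ad_ok,
    }


# ---------------------------------------------------------------------------
# Ensemble contracts
# ---------------------------------------------------------------------------

def _ensemble_task(n=100, p=25, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.choice([0.0, 1.0, 2.0], size=(n, p)),
                     columns=[f"m{j}" for j in range(p)])
    beta = rng.standard_normal(p) * 0.3
    y = X.to_numpy() @ beta + rng.standard_normal(n) * 0.5
    return treeml.FeatureTable(X, pd.Series(y),
                               [(f"h{i}", "e1") for i in range(n)])


def ensemble_contracts(seed: int = 0, n_variance_seeds: int = 20) -> dict:
    """The combination-rule identities and the variance-reduction property
    of bootstrap averaging, at the study's hyperparameters."""
    train = _ensemble_task(seed=seed)
    test = _ensemble_task(n=40, seed=seed + 1)

    one = treeml.fit_ensemble(train, treeml.EnsembleSpec("bagging", n_trees=1,
                                                         seed=seed))
    bag_identity = float(np.max(np.abs(
        one.predict(train) - one.trees[0].predict(train.X.to_numpy()))))

    boost = treeml.fit_ensemble(train, treeml.EnsembleSpec("boosting",
                                                           seed=seed))
    mse = boost.staged_train_mse(train)
    boost_monotone = bool((np.diff(mse) <= 1e-12).all())

    bag = treeml.fit_ensemble(train, treeml.EnsembleSpec("bagging", seed=seed))
    rf_all = treeml.fit_ensemble(
        train, treeml.EnsembleSpec("random_forest", m_try=train.n_predictors,
                                   seed=seed))
    rf_equals_bag = float(np.max(np.abs(bag.predict(test) - rf_all.predict(test))))

    bag_preds, tree_preds = [], []
    for s in range(n_variance_seeds):
        b = treeml.fit_ensemble(train, treeml.EnsembleSpec(
            "bagging", n_trees=100, seed=seed + 100 + s))
        bag_preds.append(b.predict(test))
        t = treeml.fit_ensemble(train, treeml.EnsembleSpec(
            "bagging", n_trees=1, seed=seed + 100 + s))
        tree_preds.append(t.predict(test))
    var_ratio = float(np.var(bag_preds, axis=0).mean()
                      / np.var(tree_preds, axis=0).mean())
    return {
        "bagging_one_tree_identity_max_abs_err": bag_identity,
        "boosting_train_mse_monotone": boost_monotone,
        "boosting_n_trees": int(boost.spec.n_trees),
        "rf_all_features_vs_bagging_max_abs_err": rf_equals_bag,
        "bagging_to_tree_seed_variance_ratio": round(var_ratio, 4),
    }
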