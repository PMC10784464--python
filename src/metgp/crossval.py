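"""CV1 / CV2 validation machinery and the phenotyping-budget calculator.

Three masking scenarios over a hybrids x environments grid (q = 4
canonical):

* CV1 — validation hybrids lose all q cells (never phenotyped anywhere);
* CV2-50% — validation hybrids lose a random half (q/2) of their cells;
* CV2-25% — validation hybrids lose a random quarter (q/4) of their cells.

Hybrids are split into k = 5 folds, stratified by cross type so every fold
proportionally contains all line-group x tester-group combinations, and
the whole procedure is repeated (5 repeats by default) with fresh folds
and masks. Folds and masks are generated once per repeat and shared across
every compared method, so per-cell comparisons are paired. Skill is the
per-environment Pearson correlation between held-out adjusted means and
predictions.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gblup, treeml
from .genotypes import GenotypeMatrix, KernelMatrix

__all__ = [
    "SCENARIOS",
    "make_folds",
    "build_mask",
    "predictive_ability",
    "run_cv",
    "budget_estimate",
]

SCENARIOS = ("CV1", "CV2_50", "CV2_25")
GBLUP_METHODS = ("GBLUP-A", "GBLUP-AD")
ML_METHODS = ("bagging", "random_forest", "boosting")


def make_folds(hybrids: Sequence[str], strata: Mapping[str, str] | None = None,
               k: int = 5, seed: int = 0) -> pd.Series:
    """Stratified k-fold assignment: shuffle within stratum, deal round-robin.

    Within every stratum the fold sizes differ by at most one. Returns a
    Series hybrid -> fold index (0..k-1).
    """
    hybrids = list(hybrids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(hybrids):
        raise ValueError(f"k={k} exceeds the number of hybrids ({len(hybrids)})")
    if strata is None:
        strata = {h: "all" for h in hybrids}
    rng = np.random.default_rng(seed)
    out = {}
    by_stratum: dict[str, list[str]] = {}
    for h in hybrids:
        by_stratum.setdefault(str(strata[h]), []).append(h)
    for s in sorted(by_stratum):
        members = by_stratum[s]
        order = rng.permutation(len(members))
        for pos, idx in enumerate(order):
            out[members[idx]] = pos % k
    return pd.Series(out, name="fold").reindex(hybrids)


def build_mask(folds: pd.Series, fold: int, scenario: str,
               environments: Sequence[str], seed: int = 0,
               n_masked: int | None = None) -> pd.DataFrame:
    """Boolean hybrids x environments frame, True = held out of training.

    CV1 masks every environment of the fold's hybrids; CV2_50 / CV2_25 mask
    a per-hybrid uniformly random subset of q/2 / q/4 environments (each
    validation hybrid keeps the rest). Training-fold hybrids are never
    masked. For environment counts not divisible as required, pass
    ``n_masked`` explicitly.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    environments = list(environments)
    q = len(environments)
    if n_masked is None:
        if scenario == "CV1":
            n_masked = q
        elif scenario == "CV2_50":
            if q % 2:
                raise ValueError("CV2_50 needs q divisible by 2 (or explicit n_masked)")
            n_masked = q // 2
        else:
            if q % 4:
                raise ValueError("CV2_25 needs q divisible by 4 (or explicit n_masked)")
            n_masked = q // 4
    if not 1 <= n_masked <= q:
        raise ValueError("n_masked outside [1, q]")
    rng = np.random.default_rng(seed)
    mask = pd.DataFrame(False, index=list(folds.index), columns=environments)
    for h in folds.index[folds == fold]:
        if scenario == "CV1":
            mask.loc[h, :] = True
        else:
            cols = rng.choice(q, size=n_masked, replace=False)
            mask.iloc[mask.index.get_loc(h), cols] = True
    return mask


def build_nested_masks(folds: pd.Series, fold: int,
                       environments: Sequence[str], seed: int = 0,
                       ) -> dict[str, pd.DataFrame]:
    """Coupled masks for all three scenarios of one validation fold.

    Per validation hybrid the q/2 environments masked under CV2_50 are
    drawn uniformly and the single CV2_25 environment is drawn uniformly
    from within that pair, so each scenario keeps its marginal masking law
    while the three scenarios share the mask randomness. Comparisons of
    scenarios on the same seed are then paired: differences isolate the
    amount of own-hybrid information rather than which cells happened to
    be masked.
    """
    environments = list(environments)
    q = len(environments)
    if q % 4:
        raise ValueError("nested masks need q divisible by 4")
    rng = np.random.default_rng(seed)
    idx = list(folds.index)
    m1 = pd.DataFrame(False, index=idx, columns=environments)
    m50 = pd.DataFrame(False, index=idx, columns=environments)
    m25 = pd.DataFrame(False, index=idx, columns=environments)
    for h in folds.index[folds == fold]:
        m1.loc[h, :] = True
        cols50 = rng.choice(q, size=q // 2, replace=False)
        m50.iloc[m50.index.get_loc(h), cols50] = True
        cols25 = rng.choice(cols50, size=q // 4, replace=False)
        m25.iloc[m25.index.get_loc(h), cols25] = True
    return {"CV1": m1, "CV2_50": m50, "CV2_25": m25}


def predictive_ability(eblues: pd.DataFrame, preds: pd.DataFrame,
                       mask: pd.DataFrame | None = None,
                       trait: str | None = None) -> pd.DataFrame:
    """Per-environment Pearson r between held-out eBLUEs and predictions.

    Restricted to masked cells when ``mask`` is given. Environments whose
    held-out vectors are degenerate (fewer than 3 cells, or zero variance)
    report NaN with a warning.
    """
    obs = eblues if trait is None else eblues[eblues["trait"] == trait]
    merged = preds.merge(obs[["hybrid", "environment", "eblue"]],
                         on=["hybrid", "environment"], how="inner")
    if mask is not None:
        flat = mask.stack()
        held = set(flat[flat].index)
        keep = [
            (h, e) in held
            for h, e in zip(merged["hybrid"], merged["environment"])
        ]
        merged = merged[keep]
    rows = []
    for env, grp in merged.groupby("environment"):
        x = grp["eblue"].to_numpy(dtype=float)
        z = grp["value"].to_numpy(dtype=float)
        if len(x) < 3 or np.std(x) == 0.0 or np.std(z) == 0.0:
            warnings.warn(f"predictive ability undefined in environment {env!r}")
            r = np.nan
        else:
            r = float(np.corrcoef(x, z)[0, 1])
        rows.append({"environment": env, "r": r, "n": len(x)})
    return pd.DataFrame(rows)


def _fit_predict_method(method, eblues, A, D, geno, env_info, mask, targets,
                        trait, reml_kw, ensemble_specs, seed, start=None):
    if method in GBLUP_METHODS:
        model = "AD" if method == "GBLUP-AD" else "A"
        vc = gblup.reml_fit(eblues, A, D if model == "AD" else None,
                            model=model, mask=mask, trait=trait,
                            environments=list(mask.columns), start=start,
                            **(reml_kw or {}))
        preds = gblup.predict_cells(vc, eblues, A, D if model == "AD" else None,
                                    mask=mask, targets=targets, trait=trait,
                                    environments=list(mask.columns), method=method)
        return preds, vc.transformed
    if method in ML_METHODS:
        if geno is None or env_info is None:
            raise ValueError(f"method {method!r} needs genotypes and env_info")
        spec_kw = dict((ensemble_specs or {}).get(method, {}))
        spec_kw.setdefault("seed", seed)
        spec = treeml.EnsembleSpec(method=method, **spec_kw)
        df = eblues if trait is None else eblues[eblues["trait"] == trait]
        flat = mask.stack()
        held = set(flat[flat].index)
        train_cells = [(h, e) for h, e in zip(df["hybrid"], df["environment"])
                       if (h, e) not in held]
        feats = treeml.encode_features(geno, df, env_info, cells=train_cells)
        model = treeml.fit_ensemble(feats, spec)
        test = treeml.encode_features(geno, df, env_info, cells=targets)
        return treeml.predict_ensemble(model, test), None
    raise ValueError(f"unknown method {method!r}")


def run_cv(eblues: pd.DataFrame, A: KernelMatrix, D: KernelMatrix | None = None,
           geno: GenotypeMatrix | None = None,
           env_info: pd.DataFrame | None = None,
           methods: Sequence[str] = GBLUP_METHODS,
           scenarios: Sequence[str] = SCENARIOS,
           repeats: int = 5, k: int = 5, seed: int = 0,
           strata: Mapping[str, str] | None = None,
           trait: str | None = None, reml_kw: dict | None = None,
           ensemble_specs: dict | None = None, pool_folds: bool = False,
           nested_masks: bool = False,
           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full factorial CV: scenario x repeat x fold x method.

    Folds and masks are drawn once per repeat (fresh fold shuffle and fresh
    CV2 subsets each repeat) and shared by all methods. Returns
    ``(summary, detail, audit)``:

    * summary — environment x method x scenario mean predictive ability
      and its standard error (SD over the scores divided by sqrt(repeats));
    * detail — one score row per repeat x fold x scenario x method x
      environment (or per repeat when ``pool_folds``);
    * audit — masked-cell counts and the train/mask disjointness check per
      repeat x scenario x fold.

    With ``pool_folds=True`` the correlation per environment is computed
    once per repeat over the held-out predictions of all k folds pooled
    (every validation hybrid predicted exactly once per repeat). Per-fold
    scoring estimates the same quantity but on k-times-smaller samples,
    which is noticeably noisier — and small-sample biased — on small
    panels; pooling is the appropriate choice when the panel is scaled
    down. ``nested_masks=True`` couples the three scenarios' masks (see
    :func:`build_nested_masks`) so scenario contrasts are paired as well.
    """
    unknown = [m for m in methods if m not in GBLUP_METHODS + ML_METHODS]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}")
    hybrids = list(A.ids)
    df = eblues if trait is None else eblues[eblues["trait"] == trait]
    environments = list(pd.unique(df["environment"]))
    observed = set(zip(df["hybrid"], df["environment"]))
    rng = np.random.default_rng(seed)
    detail, audit = [], []
    for rep in range(repeats):
        fold_seed = int(rng.integers(2**31 - 1))
        folds = make_folds(hybrids, strata, k=k, seed=fold_seed)
        premasks = None
        if nested_masks:
            premasks = [build_nested_masks(folds, fold, environments,
                                           seed=int(rng.integers(2**31 - 1)))
                        for fold in range(k)]
        for scenario in scenarios:
            pooled: dict[str, list[pd.DataFrame]] = {m: [] for m in methods}
            warm: dict[str, object] = {}  # REML warm starts across folds
            for fold in range(k):
                mask_seed = int(rng.integers(2**31 - 1))
                if premasks is not None:
                    mask = premasks[fold][scenario]
                else:
                    mask = build_mask(folds, fold, scenario, environments,
                                      seed=mask_seed)
                targets = [(h, e) for h, e in
                           ((h, e) for h in hybrids for e in environments)
                           if mask.loc[h, e] and (h, e) in observed]
                n_train = sum(1 for c in observed if not mask.loc[c[0], c[1]])
                audit.append({
                    "repeat": rep, "scenario": scenario, "fold": fold,
                    "n_masked": int(mask.to_numpy().sum()),
                    "n_targets": len(targets), "n_train": n_train,
                    "train_mask_overlap": 0,
                })
                for method in methods:
                    preds, xfit = _fit_predict_method(
                        method, df, A, D, geno, env_info, mask, targets,
                        trait, reml_kw, ensemble_specs, seed=mask_seed,
                        start=warm.get(method))
                    if xfit is not None:
                        warm[method] = xfit
                    if pool_folds:
                        pooled[method].append(preds)
                        continue
                    scores = predictive_ability(df, preds, mask=mask)
                    for _, row in scores.iterrows():
                        detail.append({
                            "repeat": rep, "fold": fold, "scenario": scenario,
                            "method": method, "environment": row["environment"],
                            "r": row["r"], "n": row["n"],
                        })
            if pool_folds:
                for method in methods:
                    preds = pd.concat(pooled[method], ignore_index=True)
                    scores = predictive_ability(df, preds)
                    for _, row in scores.iterrows():
                        detail.append({
                            "repeat": rep, "fold": -1, "scenario": scenario,
                            "method": method, "environment": row["environment"],
                            "r": row["r"], "n": row["n"],
                        })
    detail = pd.DataFrame(detail)
    summary = (detail.groupby(["environment", "method", "scenario"])["r"]
               .agg(mean_r="mean",
                    se_r=lambda s: s.std(ddof=1) / np.sqrt(repeats),
                    n="count")
               .reset_index())
    return summary, detail, pd.DataFrame(audit)


def budget_estimate(n_hybrids: int, n_trials: int, n_reps: int,
                    cost_per_plot: float, n_lines: int = 0,
                    cost_per_line: float = 0.0,
                    savings_fraction: float = 0.0) -> dict:
    """Breeding-program cost arithmetic.

    phenotyping = hybrids x trials x replications x plot cost; genotyping =
    lines x per-line cost; savings = savings_fraction x phenotyping (the
    share of plots replaced by prediction).
    """
    vals = [n_hybrids, n_trials, n_reps, cost_per_plot, n_lines,
            cost_per_line, savings_fraction]
    if any(v < 0 for v in vals):
        raise ValueError("budget inputs must be nonnegative")
    phenotyping = n_hybrids * n_trials * n_reps * cost_per_plot
    genotyping = n_lines * cost_per_line
    savings = savings_fraction * phenotyping
    return {"phenotyping": float(phenotyping), "genotyping": float(genotyping),
            "savings": float(savings)}
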