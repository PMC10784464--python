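"""Stage-1 fixed-effects analysis of plot-level trial data.

Each trial (location x year x water regime) is analysed independently with
an ordinary least-squares fit of

    y = mu + replicate + set + hybrid + e

(all effects fixed), producing one adjusted mean (eBLUE) per hybrid per
trial plus the trial's residual variance. Because hybrids are nested in
sets, the set/hybrid decomposition is aliased; the estimable quantity
reported as the eBLUE is mu + set(h) + hybrid(h) with replicate effects
averaged out, which reduces to the raw hybrid mean in balanced designs.

Outliers are flagged on the eBLUE scale per environment and trait using
Tukey fences: values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (closed
interval, quartiles by the linear-interpolation convention) are removed in
a single pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "InestimableError",
    "fit_trial_model",
    "fit_stage1",
    "remove_outliers",
]


class InestimableError(ValueError):
    """A hybrid adjusted mean is not estimable from the trial's design."""


def _dummies(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(values.unique())
    X = np.zeros((len(values), len(levels)))
    for j, lev in enumerate(levels):
        X[(values == lev).to_numpy(), j] = 1.0
    return X, levels


def fit_trial_model(plots: pd.DataFrame, trial: str, trait: str,
                    ) -> tuple[pd.DataFrame, float]:
    """OLS adjusted means for one trial and trait.

    Returns a fragment with columns hybrid, environment, location, year,
    regime, trait, eblue, together with the residual variance RSS /
    (n - rank).

    Raises
    ------
    InestimableError
        If a hybrid's adjusted mean does not lie in the row space of the
        design (disconnected/confounded layout).
    """
    sub = plots[(plots["trial"] == trial) & (plots["trait"] == trait)]
    if sub.empty:
        raise ValueError(f"no plots for trial {trial!r}, trait {trait!r}")
    y = sub["value"].to_numpy(dtype=float)
    Xr, reps = _dummies(sub["replicate"])
    Xs, sets = _dummies(sub["set"])
    Xh, hybrids = _dummies(sub["hybrid"])
    X = np.hstack([np.ones((len(y), 1)), Xr, Xs, Xh])

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    dof = len(y) - rank
    resid_var = rss / dof if dof > 0 else 0.0

    # Orthonormal basis of the row space, for estimability checks and to make
    # the reported means invariant to the particular minimum-norm solution.
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt[s > s[0] * 1e-10].T  # columns span row(X)

    set_of = sub.drop_duplicates("hybrid").set_index("hybrid")["set"]
    p = X.shape[1]
    rows = []
    meta = sub.iloc[0]
    for h in hybrids:
        x = np.zeros(p)
        x[0] = 1.0
        x[1:1 + len(reps)] = 1.0 / len(reps)  # replicate effects averaged
        x[1 + len(reps) + sets.index(set_of[h])] = 1.0
        x[1 + len(reps) + len(sets) + hybrids.index(h)] = 1.0
        proj = V @ (V.T @ x)
        if not np.allclose(proj, x, atol=1e-8 * max(1.0, np.linalg.norm(x))):
            raise InestimableError(
                f"adjusted mean for hybrid {h!r} in trial {trial!r} is not "
                "estimable (hybrid aliased with replicate/set structure)")
        rows.append({
            "hybrid": h,
            "environment": meta.get("environment", trial),
            "location": meta.get("location", ""),
            "year": meta.get("year", ""),
            "regime": meta.get("regime", ""),
            "trait": trait,
            "eblue": float(x @ beta),
        })
    return pd.DataFrame(rows), resid_var


def fit_stage1(plots: pd.DataFrame, exclude_checks: bool = True,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every (trial, trait) combination present in the plot table.

    Entries flagged as checks (``is_check`` column, when present) enter the
    trial model but are dropped from the returned eBLUE table: commercial
    cultivars calibrate the trial, they are not prediction targets.

    Returns the stacked eBLUE table and a per-(trial, trait) residual
    variance table.
    """
    frags, resids = [], []
    for (trial, trait), _ in plots.groupby(["trial", "trait"], sort=True):
        frag, rv = fit_trial_model(plots, trial, trait)
        frags.append(frag)
        resids.append({"trial": trial, "trait": trait, "resid_var": rv})
    eblues = pd.concat(frags, ignore_index=True)
    if exclude_checks and "is_check" in plots.columns:
        checks = set(plots.loc[plots["is_check"].astype(bool), "hybrid"])
        eblues = eblues[~eblues["hybrid"].isin(checks)].reset_index(drop=True)
    return eblues, pd.DataFrame(resids)


def remove_outliers(eblues: pd.DataFrame, trait: str | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass Tukey-fence filter on eBLUEs, per environment and trait.

    Quartiles use numpy's linear interpolation; the fences are closed, so
    values exactly on a fence (including the degenerate all-equal case,
    IQR = 0) are kept. Groups with fewer than 4 values pass through
    untouched. Returns (kept, removal log).
    """
    df = eblues if trait is None else eblues[eblues["trait"] == trait]
    rest = eblues.drop(df.index) if trait is not None else eblues.iloc[0:0]
    keep_mask = pd.Series(True, index=df.index)
    logs = []
    for (env, tr), grp in df.groupby(["environment", "trait"]):
        vals = grp["eblue"].to_numpy(dtype=float)
        if len(vals) < 4:
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out = (grp["eblue"] < lo) | (grp["eblue"] > hi)
        keep_mask.loc[grp.index[out]] = False
        for _, row in grp[out].iterrows():
            logs.append({"hybrid": row["hybrid"], "environment": env,
                         "trait": tr, "eblue": row["eblue"],
                         "fence_low": lo, "fence_high": hi})
    kept = pd.concat([df[keep_mask], rest]).sort_index().reset_index(drop=True)
    return kept, pd.DataFrame(logs, columns=["hybrid", "environment", "trait",
                                             "eblue", "fence_low", "fence_high"])
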