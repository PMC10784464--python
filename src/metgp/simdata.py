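"""Synthetic testcross-hybrid trial generator.

Emulates the data-generating structure of a maize single-cross breeding
program evaluated in multi-environment trials: inbred parents in three
heterotic groups (dent, flint, and a small unrelated group C) crossed to
two testers; additive and dominance genetic values correlated across
environments under a compound-symmetry law; plot-level records organised
in replicates and sets.

The generative model is the exact counterpart of the joint GBLUP model
fitted downstream: per-marker additive effect vectors across the q
environments are drawn with compound-symmetric correlation rho_a and
scaled by the VanRaden denominator of the realized panel, so that
Cov(u_a) = [I sigma2_a + rho_a sigma2_a (J - I)] kron A_realized holds
exactly (and analogously for dominance with the Vitezica coding). Marker
effects are shared across heterotic groups (allele-substitution effects
are assumed equal between pools) and markers are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, infer_hybrid_genotypes

__all__ = [
    "SimConfig",
    "TrueEffects",
    "default_environments",
    "simulate_parents",
    "make_crosses",
    "simulate_hybrids",
    "simulate_effects",
    "simulate_plots",
    "simulate_eblues",
    "assign_sets",
]

_LOCATIONS = ("J", "T")  # two trial locations, alternating across environments


def default_environments(q: int, regime: str = "WS") -> pd.DataFrame:
    """Environment metadata table: location x year combinations within a regime.

    For the canonical q = 4 this yields J10, T10, J11, T11 (two locations,
    two years). Larger q extends the year sequence.
    """
    rows = []
    for j in range(q):
        loc = _LOCATIONS[j % 2]
        year = 2010 + j // 2
        rows.append({"environment": f"{loc}{year % 100:02d}", "location": loc,
                     "year": str(year), "regime": regime})
    return pd.DataFrame(rows)


@dataclass
class SimConfig:
    """Study-design and genetic parameters of one simulated trial group.

    Defaults mirror a 188-line / 2-tester maize program evaluated in four
    water-stress environments: 85 dent + 86 flint + 17 group-C lines,
    265 hybrids, and grain-yield (t/ha) genetic parameters
    sigma2_a = 0.60, sigma2_d = 0.30, sigma2_e = 0.81, rho_a = 0.35,
    rho_d = 0.83 with environment means from the observed WS trial means.
    """

    n_lines_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"dent": 85, "flint": 86, "C": 17})
    n_testers: int = 2
    n_hybrids: int = 265
    n_snps: int = 2000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    group_divergence: float = 0.3
    q_env: int = 4
    regime: str = "WS"
    trait: str = "GY"
    env_means: Sequence[float] | None = (3.49, 2.86, 3.34, 4.93)
    sigma2_a: float = 0.60
    sigma2_d: float = 0.30
    sigma2_e: float = 0.81
    rho_a: float = 0.35
    rho_d: float = 0.83
    n_reps: int = 3
    n_sets: int = 6
    rep_effect_sd: float = 0.0
    set_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.env_means is not None:
            self.env_means = tuple(float(x) for x in self.env_means)
        self.maf_range = tuple(self.maf_range)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_lines_per_group.values()) < 0 or self.n_testers < 1:
            raise ValueError("line and tester counts must be positive")
        if self.n_snps < self.n_chromosomes:
            raise ValueError("n_snps must be at least n_chromosomes")
        if self.group_divergence < 0:
            raise ValueError("group_divergence must be nonnegative")
        for name in ("sigma2_a", "sigma2_d", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        rho_lo = -1.0 / (self.q_env - 1) if self.q_env > 1 else -1.0
        for name in ("rho_a", "rho_d"):
            r = getattr(self, name)
            if not (rho_lo < r <= 1.0):
                raise ValueError(
                    f"{name}={r} outside ({rho_lo:.4g}, 1]; compound symmetry "
                    "would not be positive semidefinite")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.env_means is not None and len(self.env_means) != self.q_env:
            raise ValueError("env_means length must equal q_env")
        n_lines = sum(self.n_lines_per_group.values())
        if self.n_hybrids > n_lines * self.n_testers:
            raise ValueError("n_hybrids exceeds possible line x tester crosses")

    @property
    def n_lines(self) -> int:
        return sum(self.n_lines_per_group.values())

    def environments(self) -> pd.DataFrame:
        return default_environments(self.q_env, self.regime)

    def intercepts(self) -> np.ndarray:
        if self.env_means is None:
            return np.zeros(self.q_env)
        return np.asarray(self.env_means, dtype=float)

    # -- serialisation ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["n_lines_per_group"] = dict(d["n_lines_per_group"])
        d["maf_range"] = list(d["maf_range"])
        if d["env_means"] is not None:
            d["env_means"] = [float(x) for x in d["env_means"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class TrueEffects:
    """Generative ground truth: marker effects and genetic values.

    ``alpha`` and ``delta`` are (n_markers x q) additive and dominance
    marker-effect matrices; ``u_a`` and ``u_d`` are (hybrids x q) genetic
    values reproducible exactly as design x effects.
    """

    alpha: pd.DataFrame
    delta: pd.DataFrame
    u_a: pd.DataFrame
    u_d: pd.DataFrame
    env_intercepts: pd.Series


# ---------------------------------------------------------------------------
# Parents and crosses
# ---------------------------------------------------------------------------

def simulate_parents(config: SimConfig) -> GenotypeMatrix:
    """Fully homozygous inbred parents (lines + testers) in heterotic groups.

    Each marker has a base reference-allele frequency drawn uniformly from
    ``maf_range``; each group's frequency is a logit-normal perturbation of
    the base with scale ``group_divergence``. Dosages are 2 x Bernoulli
    draws, hence strictly in {0, 2}. Markers are dealt to chromosomes
    round-robin (near-uniform counts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=m)
    group_names = list(config.n_lines_per_group)

    def group_freqs() -> np.ndarray:
        logit = np.log(base / (1.0 - base))
        shifted = logit + rng.normal(0.0, config.group_divergence, size=m)
        return 1.0 / (1.0 + np.exp(-shifted))

    freqs = {g: group_freqs() for g in group_names}
    rows, groups = {}, {}
    for g in group_names:
        for i in range(config.n_lines_per_group[g]):
            name = f"L_{g}_{i + 1:03d}"
            rows[name] = 2.0 * (rng.random(m) < freqs[g])
            groups[name] = g
    # Testers are inbreds drawn from the flint and dent pools in turn.
    tester_pool = [g for g in ("flint", "dent") if g in group_names] or group_names
    for t in range(config.n_testers):
        g = tester_pool[t % len(tester_pool)]
        name = f"T{t + 1}"
        rows[name] = 2.0 * (rng.random(m) < freqs[g])
        groups[name] = g
    marker_ids = [f"snp{k + 1:05d}" for k in range(m)]
    chrom = pd.Series([f"chr{(k % config.n_chromosomes) + 1}" for k in range(m)],
                      index=marker_ids)
    d = pd.DataFrame.from_dict(rows, orient="index", columns=marker_ids)
    return GenotypeMatrix(d, kind="inbred", chromosomes=chrom,
                          groups=pd.Series(groups))


def make_crosses(parents: GenotypeMatrix, n_hybrids: int, seed: int = 0,
                 ) -> dict[str, tuple[str, str]]:
    """Line x tester crossing design producing ``n_hybrids`` hybrids.

    Every line is crossed to at least one randomly chosen tester; if more
    hybrids are requested than there are lines, a random subset of lines is
    crossed to a second tester (mirroring programs where only part of the
    lines meet both testers).
    """
    rng = np.random.default_rng(seed)
    testers = [e for e in parents.entities if e.startswith("T")]
    lines = [e for e in parents.entities if e not in testers]
    if not testers:
        raise ValueError("no testers in parent panel")
    if n_hybrids > len(lines) * len(testers):
        raise ValueError("n_hybrids exceeds available line x tester combinations")
    crosses: dict[str, tuple[str, str]] = {}
    if n_hybrids <= len(lines):
        chosen = rng.choice(len(lines), size=n_hybrids, replace=False)
        for i in sorted(chosen):
            t = testers[rng.integers(len(testers))]
            crosses[f"{lines[i]}/{t}"] = (lines[i], t)
    else:
        first = rng.integers(len(testers), size=len(lines))
        for i, line in enumerate(lines):
            t = testers[first[i]]
            crosses[f"{line}/{t}"] = (line, t)
        extra = n_hybrids - len(lines)
        if len(testers) < 2 and extra > 0:
            raise ValueError("cannot form extra crosses with a single tester")
        chosen = rng.choice(len(lines), size=extra, replace=False)
        for i in sorted(chosen):
            others = [t for t in testers if t != testers[first[i]]]
            t = others[rng.integers(len(others))]
            crosses[f"{lines[i]}/{t}"] = (lines[i], t)
    return crosses


def cross_strata(parents: GenotypeMatrix,
                 crosses: Mapping[str, tuple[str, str]]) -> pd.Series:
    """Cross-type stratum label per hybrid, e.g. ``dent x flint``.

    Group pairs are unordered except that the line's group is named first,
    matching how testcross families are reported.
    """
    if parents.groups is None:
        raise ValueError("parent panel has no heterotic-group labels")
    labels = {}
    for h, (line, tester) in crosses.items():
        labels[h] = f"{parents.groups[line]}x{parents.groups[tester]}"
    return pd.Series(labels, name="stratum")


def simulate_hybrids(config: SimConfig,
                     ) -> tuple[GenotypeMatrix, GenotypeMatrix, dict[str, tuple[str, str]]]:
    """Convenience: parents, their testcross hybrids, and the crossing design."""
    parents = simulate_parents(config)
    crosses = make_crosses(parents, config.n_hybrids, seed=config.seed + 1)
    hybrids = infer_hybrid_genotypes(parents, crosses)
    return parents, hybrids, crosses


# ---------------------------------------------------------------------------
# Genetic effects
# ---------------------------------------------------------------------------

def _cs_factor(q: int, rho: float) -> np.ndarray:
    """Square root of the q x q unit-variance compound-symmetry correlation."""
    R = np.full((q, q), rho) + (1.0 - rho) * np.eye(q)
    w, v = np.linalg.eigh(R)
    w = np.clip(w, 0.0, None)  # rho = 1 makes R singular but still PSD
    return v * np.sqrt(w)


def simulate_effects(config: SimConfig, hybrids: GenotypeMatrix) -> TrueEffects:
    """Draw environment-correlated marker effects and hybrid genetic values.

    Additive effects: per marker, the q-vector across environments is
    MVN(0, s_a * CS(rho_a)) with s_a = sigma2_a / (2 sum p(1-p)) so that
    u_a = W_c alpha has Cov(u_a) = CS(sigma2_a, rho_a) kron A_realized
    exactly (frequencies estimated from the hybrid panel). Dominance
    effects use the Vitezica coding and s_d = sigma2_d / sum (2pq)^2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    M = hybrids.dosages.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("hybrid panel contains missing dosages")
    q = config.q_env
    m = M.shape[1]
    p = M.mean(axis=0) / 2.0
    pq = p * (1.0 - p)

    env_ids = list(config.environments()["environment"])
    marker_ids = hybrids.markers

    denom_a = 2.0 * np.sum(pq)
    La = _cs_factor(q, config.rho_a) * np.sqrt(config.sigma2_a / denom_a)
    alpha = (La @ rng.standard_normal((q, m))).T  # (m, q)
    Wc = M - 2.0 * p
    u_a = Wc @ alpha

    if config.sigma2_d > 0.0:
        denom_d = np.sum((2.0 * pq) ** 2)
        Ld = _cs_factor(q, config.rho_d) * np.sqrt(config.sigma2_d / denom_d)
        delta = (Ld @ rng.standard_normal((q, m))).T
        H = np.where(M == 2.0, -2.0 * (1.0 - p) ** 2,
                     np.where(M == 1.0, 2.0 * pq, -2.0 * p ** 2))
        u_d = H @ delta
    else:
        delta = np.zeros((m, q))
        u_d = np.zeros((M.shape[0], q))

    hyb = hybrids.entities
    return TrueEffects(
        alpha=pd.DataFrame(alpha, index=marker_ids, columns=env_ids),
        delta=pd.DataFrame(delta, index=marker_ids, columns=env_ids),
        u_a=pd.DataFrame(u_a, index=hyb, columns=env_ids),
        u_d=pd.DataFrame(u_d, index=hyb, columns=env_ids),
        env_intercepts=pd.Series(config.intercepts(), index=env_ids),
    )


# ---------------------------------------------------------------------------
# Plot-level trial data
# ---------------------------------------------------------------------------

def assign_sets(hybrids: Sequence[str], n_sets: int) -> pd.Series:
    """Deterministic round-robin allocation of hybrids to sets (reused across trials)."""
    return pd.Series({h: f"set{(i % n_sets) + 1}" for i, h in enumerate(hybrids)},
                     name="set")


def simulate_plots(effects: TrueEffects, config: SimConfig) -> pd.DataFrame:
    """Plot-level phenotype records for every trial (environment) in the group.

    value = env intercept + replicate effect + set effect + u_a + u_d + eps,
    eps ~ N(0, sigma2_e) independently per plot. Replicate and set effects
    default to zero (``rep_effect_sd`` / ``set_effect_sd`` make them
    nonzero) so the stage-1 adjustment can be exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    env_info = config.environments()
    hybrids = list(effects.u_a.index)
    sets = assign_sets(hybrids, config.n_sets)
    rows = []
    for _, env in env_info.iterrows():
        e = env["environment"]
        trial = f"{e}-{env['regime']}"
        rep_eff = rng.normal(0.0, config.rep_effect_sd, size=config.n_reps) \
            if config.rep_effect_sd > 0 else np.zeros(config.n_reps)
        set_ids = sorted(sets.unique())
        set_eff = pd.Series(
            rng.normal(0.0, config.set_effect_sd, size=len(set_ids))
            if config.set_effect_sd > 0 else np.zeros(len(set_ids)), index=set_ids)
        mu = effects.env_intercepts[e]
        g = effects.u_a[e] + effects.u_d[e]
        noise = rng.normal(0.0, np.sqrt(config.sigma2_e),
                           size=(config.n_reps, len(hybrids)))
        for r in range(config.n_reps):
            for i, h in enumerate(hybrids):
                rows.append({
                    "trial": trial, "environment": e,
                    "location": env["location"], "year": env["year"],
                    "regime": env["regime"], "replicate": f"rep{r + 1}",
                    "set": sets[h], "hybrid": h, "trait": config.trait,
                    "value": mu + rep_eff[r] + set_eff[sets[h]] + g[h]
                             + noise[r, i],
                })
    return pd.DataFrame(rows)


def simulate_eblues(effects: TrueEffects, config: SimConfig,
                    sigma2_e: float | None = None) -> pd.DataFrame:
    """Hybrid x environment adjusted means drawn directly at the cell level.

    Shortcut past the plot/stage-1 layers: value = intercept + u_a + u_d +
    N(0, sigma2_e). Useful when the object under test is the joint model,
    not the stage-1 adjustment.
    """
    rng = np.random.default_rng(config.seed + 4)
    s2 = config.sigma2_e if sigma2_e is None else sigma2_e
    env_info = config.environments()
    rows = []
    for _, env in env_info.iterrows():
        e = env["environment"]
        vals = (effects.env_intercepts[e] + effects.u_a[e] + effects.u_d[e]
                + rng.normal(0.0, np.sqrt(s2), size=len(effects.u_a)))
        for h, v in vals.items():
            rows.append({"hybrid": h, "environment": e, "location": env["location"],
                         "year": env["year"], "regime": env["regime"],
                         "trait": config.trait, "eblue": v})
    return pd.DataFrame(rows)
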