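"""SNP genotype handling for single-cross hybrid prediction.

Covers marker quality control, modal imputation, inference of hybrid
genotypes from homozygous parents (line x tester crosses), and the two
genomic relationship matrices used throughout: the additive kernel built
from centered dosages (VanRaden) and the dominance kernel built from the
breeding-value-orthogonal dominance coding (Vitezica).

Dosages count copies of the reference allele (0, 1, 2); missing calls are
stored as NaN and written as "NA" in the tab-separated dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KernelMatrix",
    "EmptyPanelError",
    "qc_filter",
    "impute",
    "force_homozygous",
    "infer_hybrid_genotypes",
    "vanraden_A",
    "vitezica_D",
]

_ALLOWED_DOSAGES = (0.0, 1.0, 2.0)


class EmptyPanelError(ValueError):
    """All markers were discarded (or none were supplied)."""


@dataclass
class GenotypeMatrix:
    """Entities x markers dosage table.

    Parameters
    ----------
    dosages
        DataFrame indexed by entity id with one column per marker id.
        Values in {0, 1, 2} or NaN for missing.
    kind
        ``"inbred"`` for parental lines/testers, ``"hybrid"`` for crosses.
    chromosomes
        Optional Series mapping marker id -> chromosome label.
    groups
        Optional Series mapping entity id -> heterotic group label.
    """

    dosages: pd.DataFrame
    kind: str = "inbred"
    chromosomes: pd.Series | None = None
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("inbred", "hybrid"):
            raise ValueError(f"unknown entity kind {self.kind!r}")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, _ALLOWED_DOSAGES))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.dosages.columns.duplicated().any():
            raise ValueError("marker ids must be unique")

    # -- basic accessors -------------------------------------------------
    @property
    def entities(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def markers(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_entities(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> pd.Series:
        """Reference-allele frequency per marker from non-missing dosages."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def minor_allele_frequencies(self) -> pd.Series:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def het_fraction(self) -> pd.Series:
        """Fraction of heterozygous calls among non-missing calls."""
        het = (self.dosages == 1).sum(axis=0)
        n = self.dosages.notna().sum(axis=0)
        return het / n.where(n > 0, np.nan)

    def subset(self, markers=None, entities=None) -> "GenotypeMatrix":
        d = self.dosages
        if markers is not None:
            d = d.loc[:, list(markers)]
        if entities is not None:
            d = d.loc[list(entities)]
        chrom = None
        if self.chromosomes is not None:
            chrom = self.chromosomes.loc[d.columns]
        groups = None
        if self.groups is not None:
            groups = self.groups.loc[d.index]
        return GenotypeMatrix(d.copy(), kind=self.kind, chromosomes=chrom, groups=groups)

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column entity id, then one column per marker."""
        out = self.dosages.copy()
        out.index.name = "entity"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "inbred",
                 chromosomes: pd.Series | None = None) -> "GenotypeMatrix":
        d = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        d.index.name = None
        return cls(d.astype(float), kind=kind, chromosomes=chromosomes)


def read_hapmap_like(path: str | Path, kind: str = "inbred") -> GenotypeMatrix:
    """Read a minimal HapMap-style table.

    Expected tab-separated columns: ``rs`` (marker id), ``chrom``, ``pos``,
    then one column per entity holding dosages (0/1/2 or NA). Markers are
    rows; the returned matrix is transposed to entities x markers with the
    chromosome map attached.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = {c.lower(): c for c in df.columns[:3]}
    for required in ("rs", "chrom", "pos"):
        if required not in meta:
            raise ValueError("expected leading columns rs, chrom, pos")
    df = df.set_index(meta["rs"])
    chrom = df[meta["chrom"]].astype(str)
    calls = df.drop(columns=[meta["chrom"], meta["pos"]])
    return GenotypeMatrix(calls.T.astype(float), kind=kind,
                          chromosomes=chrom)


@dataclass
class KernelMatrix:
    """Symmetric hybrid x hybrid genomic relationship matrix."""

    values: np.ndarray
    ids: list[str]
    kind: str  # "additive" | "dominance"
    freqs: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def with_jitter(self, eps: float = 1e-6) -> "KernelMatrix":
        """Return a copy with ``eps`` added to the diagonal (stabilises factorizations)."""
        return KernelMatrix(self.values + eps * np.eye(self.n), list(self.ids),
                            self.kind, self.freqs)

    def align(self, ids) -> "KernelMatrix":
        idx = [self.ids.index(i) for i in ids]
        return KernelMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind, self.freqs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, kind: str) -> "KernelMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.index), kind)


# ---------------------------------------------------------------------------
# Quality control and imputation
# ---------------------------------------------------------------------------

def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.05,
              max_missing: float = 0.20, max_het: float = 0.05,
              ) -> tuple[GenotypeMatrix, dict]:
    """Discard markers failing any of the three panel QC rules.

    A marker is kept iff MAF >= ``maf_min``, missing fraction <=
    ``max_missing`` and heterozygous fraction <= ``max_het`` (all computed
    from non-missing dosages). Returns the filtered matrix together with a
    report of per-rule discard counts; a marker violating several rules is
    counted once per rule it violates.
    """
    if geno.n_markers == 0:
        raise EmptyPanelError("no markers supplied")
    for name, v in [("maf_min", maf_min), ("max_missing", max_missing), ("max_het", max_het)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    maf = geno.minor_allele_frequencies()
    miss = geno.missing_fraction()
    het = geno.het_fraction()
    fail_maf = (maf < maf_min) | maf.isna()
    fail_miss = miss > max_missing
    fail_het = het > max_het
    keep = ~(fail_maf | fail_miss | fail_het)
    report = {
        "n_input": geno.n_markers,
        "discard_maf": int(fail_maf.sum()),
        "discard_missing": int(fail_miss.sum()),
        "discard_het": int(fail_het.sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_kept"] == 0:
        raise EmptyPanelError("all markers discarded by QC")
    return geno.subset(markers=geno.dosages.columns[keep]), report


def _modal_dosage(col: pd.Series, homozygous_only: bool) -> float:
    counts = col.value_counts()
    levels = (0.0, 2.0) if homozygous_only else (0.0, 1.0, 2.0)
    best, best_n = None, -1
    for lev in levels:  # ascending order => ties resolve to the lower dosage
        n = int(counts.get(lev, 0))
        if n > best_n:
            best, best_n = lev, n
    return best


def impute(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing dosages with the per-marker mode (ties -> lower dosage).

    Inbred panels receive homozygous fills only. Markers with no observed
    call at all should have been removed by QC and raise an error here.
    """
    d = geno.dosages.copy()
    homozygous_only = geno.kind == "inbred"
    for m in d.columns[d.isna().any(axis=0)]:
        col = d[m]
        nonmiss = col.dropna()
        if nonmiss.empty:
            raise EmptyPanelError(f"marker {m!r} entirely missing; run QC first")
        d[m] = col.fillna(_modal_dosage(nonmiss, homozygous_only))
    return GenotypeMatrix(d, kind=geno.kind, chromosomes=geno.chromosomes,
                          groups=geno.groups)


def force_homozygous(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace residual heterozygous calls in an inbred panel by the modal homozygote.

    QC allows up to 5% heterozygous calls per marker in parents; cross
    inference requires strictly homozygous parents, so the few survivors
    are coerced deterministically (ties -> dosage 0).
    """
    if geno.kind != "inbred":
        raise ValueError("force_homozygous applies to inbred panels only")
    d = geno.dosages.copy()
    for m in d.columns[(d == 1).any(axis=0)]:
        col = d[m]
        mode = _modal_dosage(col[col != 1].dropna(), homozygous_only=True)
        d.loc[col == 1, m] = mode
    return GenotypeMatrix(d, kind="inbred", chromosomes=geno.chromosomes,
                          groups=geno.groups)


# ---------------------------------------------------------------------------
# Hybrid genotypes
# ---------------------------------------------------------------------------

def infer_hybrid_genotypes(parents: GenotypeMatrix,
                           crosses: Mapping[str, tuple[str, str]],
                           ) -> GenotypeMatrix:
    """Derive hybrid dosages as the parental mean, (line + tester) / 2.

    Parents must be imputed and fully homozygous (dosage 0 or 2), so every
    hybrid dosage lands in {0, 1, 2} deterministically.
    """
    d = parents.dosages
    vals = d.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("parents contain missing dosages; impute first")
    if np.isin(vals, (1.0,)).any():
        raise ValueError("parents contain heterozygous dosages; force_homozygous first")
    rows = {}
    for hybrid, (line, tester) in crosses.items():
        for pid in (line, tester):
            if pid not in d.index:
                raise KeyError(f"cross {hybrid!r} references unknown parent {pid!r}")
        rows[hybrid] = (d.loc[line].to_numpy() + d.loc[tester].to_numpy()) / 2.0
    out = pd.DataFrame.from_dict(rows, orient="index", columns=d.columns)
    return GenotypeMatrix(out, kind="hybrid", chromosomes=parents.chromosomes)


# ---------------------------------------------------------------------------
# Genomic relationship matrices
# ---------------------------------------------------------------------------

def vanraden_A(hybrids: GenotypeMatrix) -> KernelMatrix:
    """Additive genomic relationship matrix.

    W = M - 2p with allele frequencies p estimated from the hybrid panel
    itself; A = W W' / (2 sum_k p_k (1 - p_k)). Centering on the panel's
    own frequencies makes every row of A sum to zero.
    """
    M = hybrids.dosages.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing dosages; impute before building kernels")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic; additive kernel undefined")
    W = M - 2.0 * p
    A = (W @ W.T) / denom
    return KernelMatrix(A, hybrids.entities, "additive", freqs=p)


def vitezica_D(hybrids: GenotypeMatrix) -> KernelMatrix:
    """Dominance genomic relationship matrix.

    Per marker with reference-allele frequency p (q = 1 - p) the dominance
    covariate is -2q^2, 2pq, -2p^2 for dosages 2, 1, 0; D = H H' /
    sum_k (2 p_k q_k)^2. This coding is orthogonal to the additive one
    under Hardy-Weinberg proportions.
    """
    M = hybrids.dosages.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing dosages; impute before building kernels")
    p = M.mean(axis=0) / 2.0
    q = 1.0 - p
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0.0:
        raise ValueError("all markers monomorphic; dominance kernel undefined")
    H = np.where(M == 2.0, -2.0 * q * q, np.where(M == 1.0, 2.0 * p * q, -2.0 * p * p))
    D = (H @ H.T) / denom
    return KernelMatrix(D, hybrids.entities, "dominance", freqs=p)
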