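"""Instrument selection for Mendelian randomization.

Selection proceeds in stages, each with an auditable exclusion list:

1. genome-wide significance filter (default p < 5e-8, strict inequality)
2. greedy LD clumping at an r-squared threshold (default 0.001), keeping
   the most strongly associated SNP of each correlated group
3. instrument-strength statistics: the per-SNP F statistic
   F_j = (gamma_hat_j / sigma_x_j)^2, conventionally requiring F > 10,
   and the total variance in the exposure explained by the instruments
4. a confounder-trait pleiotropy screen against a local trait-association
   catalog (a file standing in for a PhenoScanner query), excluding SNPs
   associated with a listed confounder at p below a screen threshold,
   directly or through an LD proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .sumstats_io import SummaryStatsTable

__all__ = [
    "InstrumentConfig", "LDMatrix", "TraitCatalog",
    "filter_by_pvalue", "ld_clump", "per_snp_f_stat", "f_statistics",
    "variance_explained", "screen_pleiotropy",
]


@dataclass(frozen=True)
class InstrumentConfig:
    """Thresholds governing instrument selection.

    Defaults follow standard practice: genome-wide significance 5e-8,
    clumping r² 0.001 (keep-strongest), weak-instrument bound F > 10,
    confounder screen at p = 1e-5 with LD proxies at R² ≥ 0.8.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    f_min: float = 10.0
    screen_p: float = 1e-5
    proxy_r2: float = 0.8

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        for name in ("clump_r2", "proxy_r2"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be non-negative")
        if not (0 < self.screen_p < 1):
            raise ConfigurationError("screen_p must lie in (0, 1)")


class LDMatrix:
    """Square symmetric matrix of pairwise r² with unit diagonal."""

    def __init__(self, snp_ids, values):
        values = np.asarray(values, dtype=float)
        snp_ids = [str(s) for s in snp_ids]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InputError("LD matrix must be square")
        if values.shape[0] != len(snp_ids):
            raise InputError("LD matrix size does not match snp_ids")
        if len(set(snp_ids)) != len(snp_ids):
            raise InputError("duplicate snp_id in LD matrix")
        if not np.allclose(values, values.T, atol=1e-12):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise InputError("LD matrix diagonal must be exactly 1")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise InputError("LD r² entries must lie in [0, 1]")
        self.snp_ids = snp_ids
        self.values = np.clip(values, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, snp_ids) -> np.ndarray:
        idx = [self._index[s] for s in snp_ids]
        return self.values[np.ix_(idx, idx)]

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(list(snp_ids))))

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.snp_ids, columns=self.snp_ids) \
            .to_csv(path, sep="\t", float_format="%.12g")


class TraitCatalog:
    """Local catalog of known SNP-trait associations (PhenoScanner stand-in).

    Maps snp_id → [(trait_name, pvalue), ...].
    """

    def __init__(self, entries: Optional[Mapping] = None):
        self.entries: dict[str, list[tuple[str, float]]] = {}
        if entries:
            for snp, assoc in entries.items():
                for trait, p in assoc:
                    self.add(snp, trait, p)

    def add(self, snp_id: str, trait: str, pvalue: float) -> None:
        if not (0 < pvalue <= 1):
            raise InputError(f"catalog p-value out of (0,1]: {pvalue}")
        self.entries.setdefault(str(snp_id), []).append((str(trait), float(pvalue)))

    def lookup(self, snp_id: str) -> list[tuple[str, float]]:
        return self.entries.get(snp_id, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    @classmethod
    def from_tsv(cls, path) -> "TraitCatalog":
        df = pd.read_csv(path, sep="\t")
        cat = cls()
        for row in df.itertuples(index=False):
            cat.add(row.snp_id, row.trait, row.pvalue)
        return cat

    def to_tsv(self, path) -> None:
        rows = [(s, t, p) for s, assoc in self.entries.items() for t, p in assoc]
        pd.DataFrame(rows, columns=["snp_id", "trait", "pvalue"]) \
            .to_csv(path, sep="\t", index=False, float_format="%.12g")


def filter_by_pvalue(table: SummaryStatsTable,
                     p_threshold: float = 5e-8) -> SummaryStatsTable:
    """Keep records with pvalue strictly below the threshold; order preserved."""
    mask = (table.df["pvalue"] < p_threshold).to_numpy()
    return table.subset(mask)


def ld_clump(table: SummaryStatsTable, ld: LDMatrix,
             clump_r2: float = 0.001) -> SummaryStatsTable:
    """Greedy LD clumping, keeping the most significant SNP of each clump.

    Repeatedly takes the remaining SNP with the smallest p-value (ties
    broken by larger \\|beta\\|, then lexicographic snp_id), retains it, and
    discards every remaining SNP with r² strictly greater than ``clump_r2``
    against it.  The retained set comes back sorted by p-value and is
    mutually independent at the threshold: no retained pair exceeds it.
    """
    df = table.df
    missing = [s for s in df["snp_id"] if s not in ld]
    if missing:
        raise InputError(f"SNP(s) absent from LD matrix: {missing[:5]}")
    order = sorted(
        range(len(df)),
        key=lambda i: (df["pvalue"].iat[i], -abs(df["beta"].iat[i]),
                       df["snp_id"].iat[i]))
    alive = [True] * len(df)
    retained: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        retained.append(i)
        alive[i] = False
        for j in order:
            if alive[j] and ld.r2(df["snp_id"].iat[i], df["snp_id"].iat[j]) > clump_r2:
                alive[j] = False
    sub = df.iloc[retained].reset_index(drop=True)
    return SummaryStatsTable(table.trait_name, table.trait_type, sub)


def per_snp_f_stat(gamma_hat: float, sigma_x: float) -> float:
    """Instrument strength F = (gamma_hat / sigma_x)²."""
    if not sigma_x > 0:
        raise InputError(f"sigma_x must be positive, got {sigma_x}")
    return (gamma_hat / sigma_x) ** 2


def f_statistics(table: SummaryStatsTable) -> pd.Series:
    """Per-SNP F statistics for a whole table, indexed by snp_id."""
    f = (table.df["beta"] / table.df["se"]) ** 2
    return pd.Series(f.to_numpy(), index=table.df["snp_id"].to_numpy(), name="F")


def variance_explained(table: SummaryStatsTable, method: str = "auto") -> dict:
    """Total fraction of exposure variance explained by the instruments.

    Two parameterizations are supported, summed over SNPs assuming
    post-clumping independence:

    * ``eaf``: R²_j = 2·eaf_j·(1−eaf_j)·gamma_hat_j² — valid when effects
      are in trait-standard-deviation units;
    * ``f_n``: R²_j = F_j / (F_j + n_j − 2) — from the per-SNP F statistic
      and sample size, unit-free.

    ``method="auto"`` uses ``eaf`` when every record has an allele
    frequency, else ``f_n``.  Returns ``{"r2": total, "method": used,
    "per_snp": Series}``; the total is clipped into [0, 1).
    """
    df = table.df
    if len(df) == 0:
        return {"r2": 0.0, "method": method if method != "auto" else "eaf",
                "per_snp": pd.Series(dtype=float)}
    have_eaf = df["eaf"].notna().all()
    have_n = df["n"].notna().all()
    if method == "auto":
        method = "eaf" if have_eaf else "f_n"
    if method == "eaf":
        if not have_eaf:
            raise InputError("variance_explained(method='eaf') requires eaf on "
                             "every record (missing field: eaf)")
        eaf = df["eaf"].to_numpy(float)
        r2 = 2.0 * eaf * (1.0 - eaf) * df["beta"].to_numpy(float) ** 2
    elif method == "f_n":
        if not have_n:
            raise InputError("variance_explained(method='f_n') requires n on "
                             "every record (missing field: n)")
        f = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
        n = df["n"].to_numpy(float)
        r2 = f / (f + n - 2.0)
    else:
        raise ConfigurationError(f"unknown variance_explained method {method!r}")
    total = float(min(max(r2.sum(), 0.0), np.nextafter(1.0, 0.0)))
    return {"r2": total, "method": method,
            "per_snp": pd.Series(r2, index=df["snp_id"].to_numpy(), name="r2")}


@dataclass
class ScreenExclusion:
    """One SNP excluded by the confounder screen and why."""

    snp_id: str
    trait: str
    pvalue: float
    via_proxy: Optional[str] = None  #: proxy snp_id when excluded through LD


def screen_pleiotropy(snps: SummaryStatsTable, catalog: TraitCatalog,
                      confounder_traits, screen_p: float = 1e-5,
                      proxy_r2: float = 0.8,
                      ld: Optional[LDMatrix] = None):
    """Exclude instruments associated with known confounder traits.

    A SNP is excluded iff it — or, when an LD matrix is given, any SNP in
    strong LD with it (r² ≥ ``proxy_r2``) — carries a catalog association
    with any listed confounder trait at p < ``screen_p``.

    Returns ``(retained_table, exclusions)`` where each exclusion records
    the SNP, the offending trait and p-value, and the proxy SNP when the
    hit was indirect.
    """
    confounders = {str(t) for t in confounder_traits}
    if not confounders:
        raise ConfigurationError("confounder_traits must be non-empty")

    def direct_hit(snp_id):
        hits = [(t, p) for t, p in catalog.lookup(snp_id)
                if t in confounders and p < screen_p]
        return min(hits, key=lambda tp: tp[1]) if hits else None

    exclusions: list[ScreenExclusion] = []
    keep_mask = []
    for snp in snps.df["snp_id"]:
        hit = direct_hit(snp)
        via = None
        if hit is None and ld is not None and snp in ld:
            # any cataloged SNP in strong LD with the instrument counts too
            for other in catalog.entries:
                if other != snp and other in ld and ld.r2(snp, other) >= proxy_r2:
                    h = direct_hit(other)
                    if h is not None and (hit is None or h[1] < hit[1]):
                        hit, via = h, other
        if hit is None:
            keep_mask.append(True)
        else:
            keep_mask.append(False)
            exclusions.append(ScreenExclusion(snp, hit[0], hit[1], via))
    retained = snps.subset(np.array(keep_mask, dtype=bool))
    return retained, exclusions
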