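"""Allele harmonization of exposure and outcome summary statistics.

Two-sample Mendelian randomization pairs, for each instrument j, the
SNP-exposure effect γ̂_j (SE σx_j) with the SNP-outcome effect Γ̂_j
(SE σy_j).  The two GWAS may report a SNP on different effect alleles or
opposite strands, so before any estimator runs the outcome effects are
re-expressed on the exposure's effect allele:

* same alleles               → kept as is
* swapped alleles            → outcome beta negated, frequency complemented
* complementary-strand match → alleles complemented first, then as above
* palindromic (A/T or C/G)   → strand is ambiguous; orientation is inferred
  from allele frequencies away from 0.5, or the SNP is dropped

Dropped SNPs never silently vanish: every input SNP is accounted for in the
audit counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .sumstats_io import SummaryStatsTable

__all__ = ["HarmonizedPair", "HarmonizedSet", "is_palindromic", "harmonize_sets"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUSES = ("aligned", "sign_flipped", "strand_flipped",
            "dropped_palindromic", "dropped_unmatched")


def _complement(allele: str) -> Optional[str]:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G in either order.

    Multi-base alleles (indels) are never palindromic.
    """
    if len(effect_allele) != 1 or len(other_allele) != 1:
        return False
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Allele-aligned exposure/outcome effects for one SNP."""

    snp_id: str
    gamma_hat: float     #: SNP-exposure effect on the shared effect allele
    sigma_x: float       #: SE of gamma_hat
    Gamma_hat: float     #: SNP-outcome effect on the same allele
    sigma_y: float       #: SE of Gamma_hat
    eaf: Optional[float]  #: aligned effect-allele frequency (exposure side)
    status: str = "aligned"

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ConfigurationError(f"unknown harmonization status {self.status!r}")
        if not self.status.startswith("dropped"):
            if not (self.sigma_x > 0 and self.sigma_y > 0):
                raise InputError(f"non-positive SE for retained SNP {self.snp_id}")


class HarmonizedSet:
    """The retained, allele-aligned instrument set feeding every estimator."""

    def __init__(self, exposure_name: str, outcome_name: str,
                 pairs: list[HarmonizedPair], audit: Optional[dict] = None,
                 outcome_type: str = "binary"):
        ids = [p.snp_id for p in pairs]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate snp_id among harmonized pairs")
        if any(p.status.startswith("dropped") for p in pairs):
            raise InputError("dropped pairs may not be retained in a HarmonizedSet")
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.pairs = list(pairs)
        self.audit = dict(audit) if audit else {s: 0 for s in STATUSES}
        self.outcome_type = outcome_type

    def __len__(self) -> int:
        return len(self.pairs)

    def __repr__(self) -> str:
        return (f"HarmonizedSet({self.exposure_name!r} -> {self.outcome_name!r}, "
                f"{len(self)} SNPs)")

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self):
        """(gamma_hat, sigma_x, Gamma_hat, sigma_y) as float arrays."""
        g = np.array([p.gamma_hat for p in self.pairs], dtype=float)
        sx = np.array([p.sigma_x for p in self.pairs], dtype=float)
        G = np.array([p.Gamma_hat for p in self.pairs], dtype=float)
        sy = np.array([p.sigma_y for p in self.pairs], dtype=float)
        return g, sx, G, sy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "gamma_hat": [p.gamma_hat for p in self.pairs],
            "sigma_x": [p.sigma_x for p in self.pairs],
            "Gamma_hat": [p.Gamma_hat for p in self.pairs],
            "sigma_y": [p.sigma_y for p in self.pairs],
            "eaf": [p.eaf for p in self.pairs],
            "status": [p.status for p in self.pairs],
        })

    @classmethod
    def from_arrays(cls, gamma_hat, sigma_x, Gamma_hat, sigma_y,
                    snp_ids=None, exposure_name: str = "exposure",
                    outcome_name: str = "outcome", outcome_type: str = "binary"):
        """Build a set directly from aligned effect arrays (testing / simulation)."""
        g = np.asarray(gamma_hat, float)
        if snp_ids is None:
            snp_ids = [f"snp_{i}" for i in range(len(g))]
        pairs = [HarmonizedPair(str(s), float(gj), float(sxj), float(Gj), float(syj),
                                eaf=None)
                 for s, gj, sxj, Gj, syj
                 in zip(snp_ids, g, np.asarray(sigma_x, float),
                        np.asarray(Gamma_hat, float), np.asarray(sigma_y, float))]
        audit = {s: 0 for s in STATUSES}
        audit["aligned"] = len(pairs)
        return cls(exposure_name, outcome_name, pairs, audit, outcome_type)

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = set(snp_ids)
        pairs = [p for p in self.pairs if p.snp_id in keep]
        return HarmonizedSet(self.exposure_name, self.outcome_name, pairs,
                             self.audit, self.outcome_type)


def _orient_palindromic(eaf_exp, eaf_out, window: float):
    """Infer orientation of a palindromic SNP from allele frequencies.

    Returns "aligned", "sign_flipped", or None when ambiguous (either
    frequency missing or within ``window`` of 0.5).
    """
    if eaf_exp is None or eaf_out is None or \
            np.isnan(eaf_exp) or np.isnan(eaf_out):
        return None
    if abs(eaf_exp - 0.5) <= window or abs(eaf_out - 0.5) <= window:
        return None
    # same side of 0.5: both GWAS report the same allele as the minor one
    return "aligned" if (eaf_exp - 0.5) * (eaf_out - 0.5) > 0 else "sign_flipped"


def harmonize_sets(exposure: SummaryStatsTable, outcome: SummaryStatsTable,
                   palindrome_policy: str = "infer_by_eaf",
                   eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles, SNP by SNP.

    Matching is by ``snp_id``.  ``palindrome_policy`` is one of
    ``infer_by_eaf`` (default: orient A/T and C/G SNPs by allele frequency
    when both frequencies are at least ``eaf_window`` away from 0.5, drop
    otherwise), ``drop_all`` (drop every palindromic SNP) or ``keep_as_is``
    (trust the reported strands).
    """
    if palindrome_policy not in ("drop_all", "infer_by_eaf", "keep_as_is"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")

    for tbl, side in ((exposure, "exposure"), (outcome, "outcome")):
        if tbl.df["snp_id"].duplicated().any():
            raise InputError(f"duplicate snp_id in {side} table")

    out_by_id = {row.snp_id: row for row in outcome.df.itertuples(index=False)}
    audit = {s: 0 for s in STATUSES}
    pairs: list[HarmonizedPair] = []

    for erow in exposure.df.itertuples(index=False):
        orow = out_by_id.get(erow.snp_id)
        if orow is None:
            audit["dropped_unmatched"] += 1
            continue
        e_ea, e_oa = erow.effect_allele, erow.other_allele
        o_ea, o_oa = orow.effect_allele, orow.other_allele
        eaf_exp = None if pd.isna(erow.eaf) else float(erow.eaf)
        eaf_out = None if pd.isna(orow.eaf) else float(orow.eaf)

        palindromic = is_palindromic(e_ea, e_oa)
        status = None
        flip_sign = False

        if palindromic and palindrome_policy != "keep_as_is":
            if {o_ea, o_oa} != {e_ea, e_oa}:
                audit["dropped_unmatched"] += 1
                continue
            if palindrome_policy == "drop_all":
                audit["dropped_palindromic"] += 1
                continue
            status = _orient_palindromic(eaf_exp, eaf_out, eaf_window)
            if status is None:
                audit["dropped_palindromic"] += 1
                continue
            flip_sign = status == "sign_flipped"
        else:
            c_ea, c_oa = _complement(o_ea), _complement(o_oa)
            if (o_ea, o_oa) == (e_ea, e_oa):
                status = "aligned"
            elif (o_ea, o_oa) == (e_oa, e_ea):
                status, flip_sign = "sign_flipped", True
            elif (c_ea, c_oa) == (e_ea, e_oa):
                status = "strand_flipped"
            elif (c_ea, c_oa) == (e_oa, e_ea):
                status, flip_sign = "strand_flipped", True
            else:
                audit["dropped_unmatched"] += 1
                continue

        Gamma = -float(orow.beta) if flip_sign else float(orow.beta)
        if eaf_out is not None and flip_sign:
            eaf_out = 1.0 - eaf_out
        audit[status] += 1
        pairs.append(HarmonizedPair(
            snp_id=erow.snp_id, gamma_hat=float(erow.beta),
            sigma_x=float(erow.se), Gamma_hat=Gamma, sigma_y=float(orow.se),
            eaf=eaf_exp if eaf_exp is not None else eaf_out, status=status))

    return HarmonizedSet(exposure.trait_name, outcome.trait_name, pairs, audit,
                         outcome_type=outcome.trait_type)
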