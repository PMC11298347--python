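"""Reading, validating and writing GWAS summary-statistics tables.

A summary-statistics table holds one record per genetic variant: identifier,
genomic coordinates (1-based), effect and other allele, effect-allele
frequency, the association beta (log odds ratio for binary traits,
trait-standard-deviation or raw units for quantitative ones), its standard
error, p-value and the analysed sample size.

Validation is conservative: rows violating a hard invariant (non-positive
standard error, p-value outside (0, 1], identical alleles, ...) are dropped
and counted, but numeric values are never silently altered.  Missing
effect-allele frequency or sample size is allowed at ingestion; downstream
operations that need them fail fast instead of imputing.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

__all__ = [
    "VariantAssociation",
    "SummaryStatsTable",
    "ValidationReport",
    "read_summary_stats",
    "write_report",
    "read_report",
    "map_positions_to_ids",
]

#: canonical column order of a summary-statistics table
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: fields that must be present in every column map
REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")

_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None


@dataclass
class ValidationReport:
    """Counts of rows dropped per reason plus soft warnings."""

    n_input: int = 0
    n_retained: int = 0
    drop_counts: dict = field(default_factory=dict)
    n_pvalue_inconsistent: int = 0
    warnings: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_counts.values())

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


class SummaryStatsTable:
    """An ordered, validated collection of variant associations for one trait.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; ``snp_id``
    is unique within a table.
    """

    def __init__(self, trait_name: str, trait_type: str, df: pd.DataFrame,
                 validation: Optional[ValidationReport] = None):
        if trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'quantitative', got {trait_type!r}")
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"summary-stats frame missing columns: {missing}")
        dup = df["snp_id"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate snp_id in table {trait_name!r}: "
                f"{sorted(df.loc[dup, 'snp_id'].unique()[:5])}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.df = df.loc[:, COLUMNS].reset_index(drop=True)
        self.validation = validation if validation is not None else ValidationReport(
            n_input=len(df), n_retained=len(df))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (f"SummaryStatsTable({self.trait_name!r}, {self.trait_type}, "
                f"{len(self)} variants)")

    @property
    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(VariantAssociation(
                snp_id=row.snp_id, chrom=row.chrom,
                pos=None if pd.isna(row.pos) else int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta), se=float(row.se), pvalue=float(row.pvalue),
                n=None if pd.isna(row.n) else float(row.n)))
        return out

    @classmethod
    def from_records(cls, trait_name: str, trait_type: str,
                     records: Iterable[VariantAssociation]) -> "SummaryStatsTable":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=COLUMNS) if rows else _empty_frame()
        return cls(trait_name, trait_type, df)

    def subset(self, mask_or_ids) -> "SummaryStatsTable":
        """New table restricted to a boolean mask or an id collection (order kept)."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and \
                len(mask_or_ids) == len(self.df) and \
                pd.api.types.is_bool_dtype(np.asarray(mask_or_ids)):
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            keep = set(mask_or_ids)
            sub = self.df[self.df["snp_id"].isin(keep)]
        return SummaryStatsTable(self.trait_name, self.trait_type,
                                 sub.reset_index(drop=True))

    def write(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("float64" if c in
                        ("eaf", "beta", "se", "pvalue", "n", "pos") else "object"))
                        for c in COLUMNS})


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_summary_stats(path, column_map: Mapping[str, str], trait_type: str,
                       trait_name: Optional[str] = None,
                       delimiter: Optional[str] = None,
                       dedup_policy: str = "error") -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Delimited text file with a header row.  The delimiter is
        auto-detected among tab / comma / whitespace unless ``delimiter``
        overrides it.
    column_map
        Mapping from canonical field name (``snp_id``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pvalue``, ``n``) to the source column name.  ``snp_id``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se`` and ``pvalue``
        are required; the rest are optional and come out missing when
        unmapped.
    trait_type
        ``"binary"`` (beta on the log-OR scale) or ``"quantitative"``.
    dedup_policy
        ``"error"`` rejects duplicate ``snp_id``; ``"min_p"`` keeps the
        record with the smallest p-value.

    Returns
    -------
    SummaryStatsTable
        with a :class:`ValidationReport` on ``.validation`` counting dropped
        rows per reason.  Row order of retained records is preserved.
    """
    path = Path(path)
    for fld in REQUIRED_FIELDS:
        if fld not in column_map:
            raise ConfigurationError(f"column_map is missing required field {fld!r}")
    unknown = set(column_map) - set(COLUMNS)
    if unknown:
        raise ConfigurationError(f"column_map has unknown fields: {sorted(unknown)}")

    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if raw.empty:
        raise InputError(f"{path} contains no data rows")
    for fld, col in column_map.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"source column {col!r} (mapped to {fld!r}) not found in {path.name}; "
                f"available: {list(raw.columns)}")

    df = pd.DataFrame(index=raw.index)
    for fld in COLUMNS:
        if fld in column_map:
            df[fld] = raw[column_map[fld]]
        else:
            df[fld] = np.nan
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("snp_id", "chrom"):
        df[col] = df[col].astype("string").str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype("string").str.strip().str.upper()

    report = ValidationReport(n_input=len(df))
    keep = pd.Series(True, index=df.index)

    def drop(mask: pd.Series, reason: str) -> None:
        mask = mask & keep
        if mask.any():
            report.drop_counts[reason] = int(mask.sum())
            keep[mask] = False

    drop(df["snp_id"].isna() | (df["snp_id"] == ""), "missing_snp_id")
    drop(~(df["se"] > 0) | ~np.isfinite(df["se"].to_numpy(dtype=float)), "nonpositive_se")
    drop(df["beta"].isna() | ~np.isfinite(df["beta"].to_numpy(dtype=float)), "missing_beta")
    drop(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1))
    drop(eaf_bad, "eaf_out_of_range")
    allele_ok = (df["effect_allele"].fillna("").str.match(_ALLELE_RE) &
                 df["other_allele"].fillna("").str.match(_ALLELE_RE))
    drop(~allele_ok, "invalid_alleles")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    drop(df["pos"].notna() & (df["pos"] < 1), "nonpositive_position")
    drop(df["n"].notna() & (df["n"] < 1), "invalid_sample_size")

    df = df.loc[keep].reset_index(drop=True)

    # soft check: p-value vs two-sided normal test of beta/se, within 10x.
    # Public files routinely carry truncated p-values, so this warns only.
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
        expected_p = 2.0 * stats.norm.sf(z)
    pv = df["pvalue"].to_numpy(float)
    comparable = (expected_p > 1e-300) & (pv > 1e-300)
    ratio = np.ones_like(pv)
    ratio[comparable] = pv[comparable] / expected_p[comparable]
    inconsistent = comparable & ((ratio > 10) | (ratio < 0.1))
    report.n_pvalue_inconsistent = int(inconsistent.sum())
    if report.n_pvalue_inconsistent:
        report.warnings.append(
            f"{report.n_pvalue_inconsistent} rows have p-values inconsistent with "
            "beta/se under a two-sided normal test (factor > 10); "
            "rows retained (truncated p-values are common in public files)")

    if df["snp_id"].duplicated().any():
        if dedup_policy == "min_p":
            n_before = len(df)
            df = (df.sort_values("pvalue", kind="stable")
                    .drop_duplicates("snp_id", keep="first")
                    .sort_index().reset_index(drop=True))
            report.drop_counts["duplicate_snp_id"] = n_before - len(df)
        else:
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].unique()
            raise InputError(f"duplicate snp_id in {path.name}: {sorted(dups[:5])}")

    report.n_retained = len(df)
    name = trait_name if trait_name is not None else path.stem
    return SummaryStatsTable(name, trait_type, df, validation=report)


def _as_record(result) -> dict:
    if isinstance(result, Mapping):
        return dict(result)
    if hasattr(result, "to_dict"):
        return result.to_dict()
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    raise InputError(f"cannot serialise result of type {type(result).__name__}")


def write_report(results, path, format: str = "tsv") -> None:
    """Write estimator / sensitivity results as TSV or JSON.

    Numeric fields are written with 12 significant digits so a written
    report re-read with :func:`read_report` reproduces them exactly at that
    precision (round-trip safe).
    """
    results = list(results) if not isinstance(results, Mapping) else [results]
    if not results:
        raise InputError("write_report called with no results")
    records = [_as_record(r) for r in results]
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame.from_records(records)
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serialisable: {type(o)}")
        path.write_text(json.dumps(records, indent=2, default=_default))
    else:
        raise ConfigurationError(f"unknown report format {format!r}")


def read_report(path, format: str = "tsv"):
    """Read back a report written by :func:`write_report`.

    Returns a DataFrame for TSV, a list of dicts for JSON.
    """
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return json.loads(path.read_text())
    raise ConfigurationError(f"unknown report format {format!r}")


def synthesized_id(chrom, pos, effect_allele, other_allele) -> str:
    """Fallback ``chrom:pos:EA:OA`` identifier for variants with no known id."""
    pos_s = "" if pos is None or (isinstance(pos, float) and math.isnan(pos)) else int(pos)
    return f"{chrom}:{pos_s}:{effect_allele}:{other_allele}"


def map_positions_to_ids(table: SummaryStatsTable,
                         lookup: Mapping) -> SummaryStatsTable:
    """Replace variant identifiers using a local (chrom, pos, alleles) lookup.

    ``lookup`` maps ``(chrom, pos, effect_allele, other_allele)`` to an
    identifier (typically an rsid); either allele order is accepted.
    Misses are not errors: those records get a synthesized
    ``chrom:pos:EA:OA`` identifier and are counted on the returned table's
    ``validation.warnings``.
    """
    df = table.df.copy()
    n_hit = 0
    new_ids = []
    for row in df.itertuples(index=False):
        pos = None if pd.isna(row.pos) else int(row.pos)
        key = (str(row.chrom), pos, row.effect_allele, row.other_allele)
        key_swapped = (str(row.chrom), pos, row.other_allele, row.effect_allele)
        if key in lookup:
            new_ids.append(str(lookup[key]))
            n_hit += 1
        elif key_swapped in lookup:
            new_ids.append(str(lookup[key_swapped]))
            n_hit += 1
        else:
            new_ids.append(synthesized_id(row.chrom, pos, row.effect_allele,
                                          row.other_allele))
    df["snp_id"] = new_ids
    out = SummaryStatsTable(table.trait_name, table.trait_type, df)
    out.validation.warnings.append(
        f"id lookup: {n_hit} hits, {len(df) - n_hit} synthesized identifiers")
    return out
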