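"""Semantic integration, unit standardization, and error exclusion.

Trait compilations merge datasets that name the same trait differently,
report it in different units, and include measurements that are not
representative of mature, healthy, field-grown plants.  The stages here map
free-text trait terms and metadata onto controlled vocabularies, convert
values to one standard unit per trait, flag whole datasets whose values sit a
decade (or more) off the rest — the signature of an upstream unit mistake —
and exclude records that are impossible (non-positive) or non-representative.

Every stage partitions its input into a kept table and a rejects table with
one machine-readable reason per rejected record; nothing is silently dropped.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .traits import (
    DEFAULT_METADATA_MAP,
    DEFAULT_TERM_MAP,
    LEAF_TRAITS,
    STANDARD_UNITS,
    UNIT_FACTORS,
)

__all__ = [
    "TermStandardizer",
    "UnitConverter",
    "DatasetOffsetDetector",
    "RepresentativenessFilter",
    "ImpossibleValueFilter",
    "standardize_terms",
    "convert_units",
    "detect_dataset_offsets",
    "filter_nonrepresentative",
    "drop_impossible",
    "add_flag",
]

_METADATA_AXES = ("maturity", "health", "growth_condition", "exposure")


def add_flag(flags: pd.Series, flag: str, mask=None) -> pd.Series:
    """Append ``flag`` to the semicolon-joined flag sets where ``mask`` holds."""
    flags = flags.fillna("").astype(str)
    if mask is None:
        mask = pd.Series(True, index=flags.index)

    def _merge(current: str) -> str:
        tokens = set(t for t in current.split(";") if t)
        tokens.add(flag)
        return ";".join(sorted(tokens))

    out = flags.copy()
    out[mask] = flags[mask].map(_merge)
    return out


def _reject_frame(records: pd.DataFrame, mask: pd.Series, stage: str,
                  reason) -> pd.DataFrame:
    rejects = records.loc[mask, ["record_id"]].copy()
    rejects["stage"] = stage
    rejects["reason"] = reason[mask] if isinstance(reason, pd.Series) else reason
    return rejects


class TermStandardizer(BaseEstimator):
    """Map free-text trait terms and metadata onto controlled vocabularies.

    Parameters
    ----------
    term_map : mapping of free-text term -> trait code; matching is
        case-insensitive on the stripped term.  Terms absent from the map are
        routed to the rejects stream (``trait_out_of_scope``).
    metadata_map : per-axis mapping of free-text metadata -> controlled value;
        unmapped metadata degrades to ``unknown`` rather than rejecting, since
        missing metadata never justifies exclusion on its own.
    """

    def __init__(self, term_map: Mapping[str, str] | None = None,
                 metadata_map: Mapping[str, Mapping[str, str]] | None = None):
        self.term_map = term_map
        self.metadata_map = metadata_map

    def fit(self, X: pd.DataFrame, y=None):
        term_map = self.term_map if self.term_map is not None else DEFAULT_TERM_MAP
        if not term_map:
            raise ValueError("term_map must not be empty")
        self.term_map_ = {str(k).strip().lower(): v for k, v in term_map.items()}
        self.metadata_map_ = {
            axis: {str(k).strip().lower(): v for k, v in table.items()}
            for axis, table in (self.metadata_map or DEFAULT_METADATA_MAP).items()
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "term_map_"):
            self.fit(X)
        records = X.copy()
        keys = records["trait_term"].astype(str).str.strip().str.lower()
        records["trait_code"] = keys.map(self.term_map_)

        for axis in _METADATA_AXES:
            table = self.metadata_map_.get(axis, {})
            vals = records[axis].fillna("").astype(str).str.strip().str.lower()
            records[axis] = vals.map(table).fillna("unknown")

        unmapped = records["trait_code"].isna()
        self.rejects_ = _reject_frame(records, unmapped, "standardize_terms",
                                      "trait_out_of_scope")
        kept = records.loc[~unmapped].copy()
        if "flags" not in kept.columns:
            kept["flags"] = ""
        return kept


class UnitConverter(BaseEstimator):
    """Convert record values to each trait's standard unit.

    The conversion table maps ``(trait_code, unit string)`` to a
    multiplicative factor; unknown combinations reject the record
    (``unknown_unit``).  Records converted with factor != 1 get the
    ``converted_unit`` flag.  Reciprocal-definition traits (SLA) are
    converted to their own standard unit here; inversion to LMA is an
    imputation, handled later.
    """

    def __init__(self, unit_table: Mapping[tuple[str, str], float] | None = None):
        self.unit_table = unit_table

    def fit(self, X: pd.DataFrame, y=None):
        table = self.unit_table if self.unit_table is not None else UNIT_FACTORS
        for (trait, unit), factor in table.items():
            if factor <= 0:
                raise ValueError(f"factor for ({trait}, {unit}) must be > 0")
        for trait, std in STANDARD_UNITS.items():
            if table.get((trait, std), 1.0) != 1.0:
                raise ValueError(f"standard unit of {trait} must map to 1")
        self.unit_table_ = dict(table)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "unit_table_"):
            self.fit(X)
        records = X.copy()
        units = records["unit"].fillna("").astype(str).str.strip()
        keys = list(zip(records["trait_code"], units))
        factors = np.array([self.unit_table_.get(k, np.nan) for k in keys])

        unknown = pd.Series(np.isnan(factors), index=records.index)
        self.rejects_ = _reject_frame(records, unknown, "convert_units",
                                      "unknown_unit")
        kept = records.loc[~unknown].copy()
        kf = factors[~unknown.to_numpy()]
        kept["value"] = kept["value"].astype(float) * kf
        kept["unit"] = kept["trait_code"].map(STANDARD_UNITS)
        if "flags" not in kept.columns:
            kept["flags"] = ""
        kept["flags"] = add_flag(kept["flags"], "converted_unit",
                                 pd.Series(kf != 1.0, index=kept.index))
        return kept


class DatasetOffsetDetector(BaseEstimator):
    """Diagnose whole-dataset order-of-magnitude offsets per trait.

    For each (dataset, trait) group with at least ``min_n`` records and at
    least ``min_n`` records elsewhere, the median log10 value in the group is
    compared to the median elsewhere.  A finding is emitted when the offset is
    within ``closeness`` of a non-zero integer ``k`` — i.e. the dataset sits a
    clean power of ten off the rest, the signature of a unit error.  Findings
    are reported; values are corrected (×10^−k, flag
    ``dataset_offset_corrected``) only when ``auto_correct`` is true, since
    tracing the cause is ordinarily a human step.
    """

    def __init__(self, min_n: int = 20, closeness: float = 0.2,
                 auto_correct: bool = False):
        self.min_n = min_n
        self.closeness = closeness
        self.auto_correct = auto_correct

    def fit(self, X: pd.DataFrame, y=None):
        findings = []
        values = X["value"].astype(float)
        if (values <= 0).any():
            raise ValueError("offset detection requires positive values")
        logs = np.log10(values)
        for (ds, trait), idx in X.groupby(["dataset_id", "trait_code"]).groups.items():
            in_group = logs.loc[idx]
            rest_mask = (X["trait_code"] == trait) & (X["dataset_id"] != ds)
            rest = logs.loc[rest_mask[rest_mask].index]
            if len(in_group) < self.min_n or len(rest) < self.min_n:
                continue
            offset = float(in_group.median() - rest.median())
            k = int(round(offset))
            if abs(k) >= 1 and abs(offset - k) <= self.closeness:
                findings.append({
                    "dataset_id": ds, "trait_code": trait, "k": k,
                    "median_offset": offset,
                    "n_group": len(in_group), "n_rest": len(rest),
                })
        self.findings_ = pd.DataFrame(
            findings, columns=["dataset_id", "trait_code", "k",
                               "median_offset", "n_group", "n_rest"])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "findings_"):
            self.fit(X)
        records = X.copy()
        if not self.auto_correct or self.findings_.empty:
            return records
        for finding in self.findings_.itertuples(index=False):
            mask = ((records["dataset_id"] == finding.dataset_id)
                    & (records["trait_code"] == finding.trait_code))
            records.loc[mask, "value"] *= 10.0 ** (-finding.k)
            records["flags"] = add_flag(records["flags"],
                                        "dataset_offset_corrected", mask)
        return records


class RepresentativenessFilter(BaseEstimator):
    """Exclude records not representative of mature, healthy, wild plants.

    Juvenile, experimentally grown, and unhealthy plants are rejected for all
    traits; shade-grown leaves only for leaf traits (height, stem density and
    seed mass are unaffected by leaf light environment).  Unknown metadata is
    retained — most legacy records carry none, and absence of metadata is not
    evidence of a problem.
    """

    def __init__(self, exclude_shade_leaves: bool = True,
                 leaf_traits: frozenset = LEAF_TRAITS):
        self.exclude_shade_leaves = exclude_shade_leaves
        self.leaf_traits = leaf_traits

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        records = X
        reasons = pd.Series("", index=records.index)
        reasons[records["exposure"].eq("shade")
                & records["trait_code"].isin(self.leaf_traits)
                & self.exclude_shade_leaves] = "shade_leaf"
        reasons[records["health"].eq("not_healthy")] = "not_healthy"
        reasons[records["growth_condition"].eq("experimental")] = "experimental"
        reasons[records["maturity"].eq("juvenile")] = "juvenile"
        bad = reasons != ""
        self.rejects_ = _reject_frame(records, bad, "filter_nonrepresentative",
                                      reasons)
        return records.loc[~bad].copy()


class ImpossibleValueFilter(BaseEstimator):
    """Reject non-positive or non-finite values (log scale requires > 0)."""

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        values = pd.to_numeric(X["value"], errors="coerce")
        bad = ~np.isfinite(values) | (values <= 0)
        self.rejects_ = _reject_frame(X, bad, "drop_impossible",
                                      "impossible_value")
        return X.loc[~bad].copy()


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def standardize_terms(records: pd.DataFrame,
                      term_map: Mapping[str, str] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map trait terms/metadata to controlled vocabularies; returns (kept, rejects)."""
    stage = TermStandardizer(term_map=term_map)
    kept = stage.fit(records).transform(records)
    return kept, stage.rejects_


def convert_units(records: pd.DataFrame,
                  unit_table: Mapping[tuple[str, str], float] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert values to standard units; returns (kept, rejects)."""
    stage = UnitConverter(unit_table=unit_table)
    kept = stage.fit(records).transform(records)
    return kept, stage.rejects_


def detect_dataset_offsets(records: pd.DataFrame, min_n: int = 20,
                           closeness: float = 0.2, auto_correct: bool = False,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (possibly corrected) records and the offset findings table."""
    stage = DatasetOffsetDetector(min_n=min_n, closeness=closeness,
                                  auto_correct=auto_correct)
    out = stage.fit(records).transform(records)
    return out, stage.findings_


def filter_nonrepresentative(records: pd.DataFrame,
                             exclude_shade_leaves: bool = True,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop juvenile/experimental/unhealthy (and shade-leaf) records."""
    stage = RepresentativenessFilter(exclude_shade_leaves=exclude_shade_leaves)
    kept = stage.fit(records).transform(records)
    return kept, stage.rejects_


def drop_impossible(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-positive / non-finite values; returns (kept, rejects)."""
    stage = ImpossibleValueFilter()
    kept = stage.fit(records).transform(records)
    return kept, stage.rejects_
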