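"""Duplicate exclusion, species-mean aggregation, and summary reporting.

Multi-source compilations inevitably contain the same measurement more than
once.  Two records are treated as duplicates when they refer to the same
species and trait, their values agree to within a small relative tolerance
(rounding noise from unit conversion and re-reporting), and there is no
positive evidence — a differing location or date — that they are distinct
measurements.  One representative per duplicate cluster is kept.

Species means are geometric: trait distributions are approximately
log-normal, so the mean is taken after log transformation.  The species
table joins per-species categorical traits (woodiness, growth form, …) from
closed vocabularies, and two validation reports are produced: the ten most
extreme species means per trait in each direction, and a per-trait summary
(species count, geometric mean of the species means, range, mean and median
number of records per species).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .traits import CATEGORICAL_TRAITS, CATEGORICAL_VOCABULARIES, CORE_TRAITS

__all__ = [
    "Deduplicator",
    "SpeciesAggregator",
    "geometric_mean",
    "deduplicate",
    "build_species_table",
    "extremes_report",
    "summary_table",
]

_META_FIELDS = ("maturity", "health", "growth_condition", "exposure",
                "location_id", "date")


def geometric_mean(values) -> float:
    """Geometric mean of positive values: 10^(mean of log10 values)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty collection")
    if (arr <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(10.0 ** np.log10(arr).mean())


def _distinct_provenance(loc_a, date_a, loc_b, date_b) -> bool:
    """True when there is positive evidence of different location or date."""
    if loc_a and loc_b and loc_a != loc_b:
        return True
    if date_a and date_b and date_a != date_b:
        return True
    return False


class Deduplicator(BaseEstimator):
    """Collapse near-identical same-species, same-trait records.

    Within each (accepted species, trait) group, records whose relative value
    difference is at most ``rel_tol`` and that carry no evidence of distinct
    location/date are linked; clusters are the transitive closure of that
    relation.  The cluster representative is the record with the most
    non-missing metadata fields, ties broken by input order.  After
    ``transform``, ``duplicates_`` lists the removed records with the id of
    the representative that absorbed each.
    """

    def __init__(self, rel_tol: float = 1e-3):
        self.rel_tol = rel_tol

    def fit(self, X=None, y=None):
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        records = X.reset_index(drop=True)
        values = records["value"].astype(float).to_numpy()
        locs = records.get("location_id", pd.Series("", index=records.index))
        dates = records.get("date", pd.Series("", index=records.index))
        locs = locs.fillna("").astype(str).to_numpy()
        dates = dates.fillna("").astype(str).to_numpy()

        meta_count = np.zeros(len(records), dtype=int)
        for fld in _META_FIELDS:
            if fld in records.columns:
                col = records[fld].fillna("").astype(str)
                meta_count += (~col.isin(["", "unknown"])).to_numpy()

        parent = np.arange(len(records))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        group_keys = ["accepted_name", "trait_code"]
        for _, idx in records.groupby(group_keys).groups.items():
            idx = np.fromiter(idx, dtype=int)
            if len(idx) < 2:
                continue
            # sort by value: only near-equal pairs can link, and those are
            # adjacent after sorting, so scan a forward window
            order = idx[np.argsort(values[idx], kind="stable")]
            for a_pos in range(len(order)):
                i = order[a_pos]
                for b_pos in range(a_pos + 1, len(order)):
                    j = order[b_pos]
                    hi = max(abs(values[i]), abs(values[j]))
                    if hi > 0 and (values[j] - values[i]) > self.rel_tol * hi:
                        break  # sorted: no later value can be close to i
                    diff = abs(values[i] - values[j])
                    if hi > 0 and diff / hi > self.rel_tol:
                        continue
                    if _distinct_provenance(locs[i], dates[i], locs[j], dates[j]):
                        continue
                    union(i, j)

        roots = np.array([find(i) for i in range(len(records))])
        keep = np.ones(len(records), dtype=bool)
        kept_id = {}
        for root in np.unique(roots):
            members = np.where(roots == root)[0]
            if len(members) < 2:
                continue
            # most metadata wins; ties -> earliest input position
            best = members[np.lexsort((members, -meta_count[members]))[0]]
            for m in members:
                if m != best:
                    keep[m] = False
                    kept_id[m] = records.at[best, "record_id"]

        dups = records.loc[~keep, ["record_id"]].copy()
        dups["stage"] = "deduplicate"
        dups["reason"] = "duplicate_removed"
        dups["kept_record_id"] = [kept_id[m] for m in np.where(~keep)[0]]
        self.duplicates_ = dups
        return records.loc[keep].copy()


class SpeciesAggregator(BaseEstimator):
    """Aggregate retained records into one row per species.

    Per core trait the row carries the geometric mean of the species' record
    values (standard units), the number of contributing records, and the
    fraction of those that were imputed.  Categorical traits are joined by
    accepted name; values outside the closed vocabularies are blanked and
    reported in ``categorical_rejects_`` (reason ``invalid_category``).
    Missing values are empty cells, never 0 or a sentinel.
    """

    def __init__(self, categorical: pd.DataFrame | None = None,
                 traits: tuple = CORE_TRAITS):
        self.categorical = categorical
        self.traits = traits

    def fit(self, X=None, y=None):
        cat = self.categorical
        rejects = []
        table = {}
        if cat is not None:
            cat = cat.fillna("")
            for row in cat.itertuples(index=False):
                entry = {}
                for col in CATEGORICAL_TRAITS:
                    value = str(getattr(row, col, ""))
                    if value and value not in CATEGORICAL_VOCABULARIES[col]:
                        rejects.append({"accepted_name": row.accepted_name,
                                        "column": col, "value": value,
                                        "reason": "invalid_category"})
                        value = ""
                    entry[col] = value
                table[row.accepted_name] = entry
        self.categorical_table_ = table
        self.categorical_rejects_ = pd.DataFrame(
            rejects, columns=["accepted_name", "column", "value", "reason"])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "categorical_table_"):
            self.fit()
        records = X
        flags = records.get("flags", pd.Series("", index=records.index))
        is_imputed = flags.fillna("").str.contains(r"\bimputed\b")

        rows = []
        for species, grp in records.groupby("accepted_name", sort=True):
            row = {
                "Species": species,
                "Genus": grp["genus"].iloc[0],
                "Family": grp["family"].iloc[0],
                "Group": grp["group"].iloc[0],
            }
            any_trait = False
            for trait in self.traits:
                sub = grp.loc[grp["trait_code"] == trait]
                if len(sub) == 0:
                    row[trait] = np.nan
                    row[f"{trait}_n"] = 0
                    row[f"{trait}_imputed_fraction"] = np.nan
                    continue
                any_trait = True
                row[trait] = geometric_mean(sub["value"].astype(float))
                row[f"{trait}_n"] = int(len(sub))
                row[f"{trait}_imputed_fraction"] = float(
                    is_imputed.loc[sub.index].mean())
            if not any_trait:
                continue
            cat = self.categorical_table_.get(species, {})
            for col in CATEGORICAL_TRAITS:
                row[col] = cat.get(col, "")
            review = flags.loc[grp.index].str.contains("review_pending").any()
            row["flags"] = "contains_review_band" if review else ""
            rows.append(row)

        columns = (["Species", "Genus", "Family", "Group"]
                   + [c for t in self.traits
                      for c in (t, f"{t}_n", f"{t}_imputed_fraction")]
                   + list(CATEGORICAL_TRAITS) + ["flags"])
        return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def extremes_report(table: pd.DataFrame, k: int = 10,
                    traits: tuple = CORE_TRAITS) -> pd.DataFrame:
    """The k smallest and k largest species means per trait.

    Ties at the boundary are broken by species name so the report is
    deterministic.  Columns: trait, direction, rank, Species, value.
    """
    rows = []
    for trait in traits:
        sub = table.loc[table[trait].notna(), ["Species", trait]]
        if sub.empty:
            continue
        for direction, ascending in (("smallest", True), ("largest", False)):
            ordered = sub.sort_values(
                [trait, "Species"], ascending=[ascending, True])
            for rank, row in enumerate(ordered.head(k).itertuples(index=False),
                                       start=1):
                rows.append({"trait": trait, "direction": direction,
                             "rank": rank, "Species": row.Species,
                             "value": getattr(row, trait)})
    return pd.DataFrame(rows, columns=["trait", "direction", "rank",
                                       "Species", "value"])


def summary_table(table: pd.DataFrame,
                  traits: tuple = CORE_TRAITS) -> pd.DataFrame:
    """Per-trait summary: species count, geometric mean of species means,
    min, max, and mean & median records per species."""
    rows = []
    for trait in traits:
        sub = table.loc[table[trait].notna()]
        if len(sub) == 0:
            rows.append({"trait": trait, "n_species": 0,
                         "geometric_mean": np.nan, "min": np.nan,
                         "max": np.nan, "mean_n_per_species": np.nan,
                         "median_n_per_species": np.nan})
            continue
        means = sub[trait].astype(float)
        counts = sub[f"{trait}_n"].astype(float)
        rows.append({
            "trait": trait,
            "n_species": int(len(sub)),
            "geometric_mean": geometric_mean(means),
            "min": float(means.min()),
            "max": float(means.max()),
            "mean_n_per_species": float(counts.mean()),
            "median_n_per_species": float(counts.median()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def deduplicate(records: pd.DataFrame, rel_tol: float = 1e-3,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove duplicate records; returns (kept, duplicates)."""
    stage = Deduplicator(rel_tol=rel_tol)
    kept = stage.fit().transform(records)
    return kept, stage.duplicates_


def build_species_table(records: pd.DataFrame,
                        categorical: pd.DataFrame | None = None,
                        ) -> pd.DataFrame:
    """One species-mean row per species with >= 1 core-trait record."""
    return SpeciesAggregator(categorical=categorical).fit().transform(records)
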