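"""Probabilistic outlier detection by hierarchical z-scores on log10 values.

Trait values are approximately log-normal, so on log10 scale each taxon's
records are treated as draws from a normal distribution.  A record's z-score
at a taxonomic level is ``(log10(value) − mean) / sd`` computed within its
species, genus, family, and across all records of the trait.  Under
normality fewer than 0.3% of true values fall beyond 3 SD and fewer than
0.1% beyond 4 SD, so a record more than 4 SD from at least one taxon mean is
almost certainly an error (wrong unit, misplaced decimal, wrong species) and
is excluded; the 3–4 SD band is flagged for review.

Small samples give unreliable SD estimates, so a taxon with fewer than
``n_min`` records (or a degenerate SD of zero) borrows the average of the
reliable SDs at its level — an approximation of the spread one would expect
for a typical taxon of that rank — falling back to higher ranks when a level
has no reliable taxon at all.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "HierarchicalOutlierDetector",
    "compute_taxon_stats",
    "level_average_sd",
    "zscores_for_record",
    "classify_records",
    "LEVELS",
]

#: Taxonomic levels, most specific first; the key column per level.
LEVELS = ("species", "genus", "family", "all")
_LEVEL_KEY = {"species": "accepted_name", "genus": "genus",
              "family": "family", "all": None}

Z_EXCLUDE = 4.0
Z_REVIEW = 3.0


def compute_taxon_stats(records: pd.DataFrame, level: str,
                        n_min: int = 5) -> pd.DataFrame:
    """Per-(taxon, trait) sample statistics of log10 values at one level.

    Returns columns ``taxon, level, trait_code, n, mean_log10, sd_log10,
    sd_used, backoff_applied``.  ``sd_log10`` is the sample SD (n−1
    denominator) when n ≥ 2, else NaN.  ``sd_used`` is filled here only for
    taxa with a reliable own SD (n ≥ n_min and sd > 0); the others are
    completed by :func:`level_average_sd` via the detector.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    values = records["value"].astype(float)
    if (values <= 0).any() or not np.isfinite(values).all():
        raise ValueError("taxon statistics require positive finite values")
    if level == "all" and len(records) == 0:
        raise ValueError("no records at level 'all'")
    logs = np.log10(values)
    frame = pd.DataFrame({
        "taxon": (records[_LEVEL_KEY[level]].astype(str)
                  if _LEVEL_KEY[level] else "all"),
        "trait_code": records["trait_code"],
        "log10_value": logs,
    })
    grouped = frame.groupby(["taxon", "trait_code"])["log10_value"]
    stats = grouped.agg(n="count", mean_log10="mean", sd_log10="std")
    stats = stats.reset_index()
    stats["level"] = level
    reliable = (stats["n"] >= n_min) & (stats["sd_log10"] > 0)
    stats["sd_used"] = stats["sd_log10"].where(reliable)
    stats["backoff_applied"] = ~reliable
    return stats[["taxon", "level", "trait_code", "n", "mean_log10",
                  "sd_log10", "sd_used", "backoff_applied"]]


def level_average_sd(stats: pd.DataFrame, trait: str) -> float:
    """Unweighted mean of the reliable own SDs at one level for one trait.

    Raises when no taxon at the level has a reliable SD for the trait; the
    detector then walks up the level chain.
    """
    own = stats.loc[(stats["trait_code"] == trait)
                    & ~stats["backoff_applied"], "sd_log10"]
    if len(own) == 0:
        raise ValueError(f"no reliable SD at this level for trait {trait}")
    return float(own.mean())


class HierarchicalOutlierDetector(BaseEstimator):
    """Fit per-taxon log10 statistics; score and classify records by z-score.

    Parameters
    ----------
    n_min : minimum records for a taxon's own SD to be trusted (default 5).
    review_policy : what to do with records in the 3–4 SD band — ``"retain"``
        keeps them with a ``review_pending`` flag (the default; expert review
        decides in production), ``"strict"`` excludes them.
    second_pass : recompute statistics once on the retained set and rescore
        (off by default; statistics are ordinarily a single pass).

    After ``fit``, ``stats_`` maps level name to its taxon-statistics table
    with ``sd_used`` completed by level-average backoff, and
    ``level_sds_`` maps (level, trait) to the level-average SD actually used
    for backoff at that level.
    """

    def __init__(self, n_min: int = 5, review_policy: str = "retain",
                 second_pass: bool = False):
        self.n_min = n_min
        self.review_policy = review_policy
        self.second_pass = second_pass

    def fit(self, X: pd.DataFrame, y=None):
        if self.review_policy not in ("retain", "strict"):
            raise ValueError("review_policy must be 'retain' or 'strict'")
        if len(X) == 0:
            raise ValueError("cannot fit outlier statistics on zero records")
        stats = {level: compute_taxon_stats(X, level, self.n_min)
                 for level in LEVELS}
        traits = sorted(X["trait_code"].astype(str).unique())

        # Backoff SD per (level, trait): own-level average of reliable SDs,
        # else the nearest higher level's average.
        level_sds: dict[tuple[str, str], float] = {}
        for trait in traits:
            chain: list[float] = []
            for level in reversed(LEVELS):  # all -> family -> genus -> species
                try:
                    avg = level_average_sd(stats[level], trait)
                except ValueError:
                    avg = chain[-1] if chain else np.nan
                chain.append(avg)
            for level, avg in zip(reversed(LEVELS), chain):
                level_sds[(level, trait)] = avg

        for level in LEVELS:
            table = stats[level]
            backoff = table["backoff_applied"]
            fill = [level_sds[(level, t)] for t in table.loc[backoff, "trait_code"]]
            table.loc[backoff, "sd_used"] = fill
            if table["sd_used"].isna().any():
                bad = table.loc[table["sd_used"].isna(), "trait_code"].unique()
                raise ValueError(
                    f"no usable SD anywhere in the hierarchy for traits {list(bad)}")

        self.stats_ = stats
        self.level_sds_ = level_sds
        return self

    def _level_lookup(self, level: str):
        table = self.stats_[level]
        return table.set_index(["taxon", "trait_code"])

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-record z-scores at every level, max |z|, and the decision.

        Columns: ``record_id, trait_code, z_species, z_genus, z_family,
        z_all, max_abs_z, decision``.  Levels whose taxon is absent from the
        fitted statistics yield NaN and do not enter the maximum.
        """
        values = X["value"].astype(float)
        if (values <= 0).any():
            raise ValueError("z-scores require positive values; "
                             "impossible values must be rejected upstream")
        logs = np.log10(values).to_numpy()
        out = pd.DataFrame({
            "record_id": X["record_id"].to_numpy(),
            "trait_code": X["trait_code"].to_numpy(),
        })
        for level in LEVELS:
            lookup = self._level_lookup(level)
            key_col = _LEVEL_KEY[level]
            taxa = (X[key_col].astype(str) if key_col
                    else pd.Series("all", index=X.index))
            keys = pd.MultiIndex.from_arrays(
                [taxa, X["trait_code"].astype(str)])
            aligned = lookup.reindex(keys)
            mean = aligned["mean_log10"].to_numpy()
            sd = aligned["sd_used"].to_numpy()
            out[f"z_{level}"] = (logs - mean) / sd
        z_cols = [f"z_{level}" for level in LEVELS]
        out["max_abs_z"] = np.nanmax(np.abs(out[z_cols].to_numpy()), axis=1)
        out["decision"] = np.select(
            [out["max_abs_z"] > Z_EXCLUDE, out["max_abs_z"] > Z_REVIEW],
            ["exclude", "review"], default="retain")
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Decision per record: ``retain``, ``review``, or ``exclude``."""
        return self.score_frame(X)["decision"].to_numpy()


def zscores_for_record(record: pd.Series,
                       detector: HierarchicalOutlierDetector) -> pd.Series:
    """Score a single record; returns the one-row slice of ``score_frame``."""
    frame = record.to_frame().T
    return detector.score_frame(frame).iloc[0]


def classify_records(records: pd.DataFrame, n_min: int = 5,
                     review_policy: str = "retain", second_pass: bool = False,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                pd.DataFrame]:
    """Partition records into (retained, review, excluded) plus the z report.

    Statistics are fitted on the full input in a single pass.  Review-band
    records appear in the review table; under the default ``retain`` policy
    they are also present in the retained table with a ``review_pending``
    flag, under ``strict`` they are not.
    """
    if len(records) == 0:
        empty = records.copy()
        report = pd.DataFrame(columns=["record_id", "trait_code", "z_species",
                                       "z_genus", "z_family", "z_all",
                                       "max_abs_z", "decision"])
        return empty, empty.copy(), empty.copy(), report

    det = HierarchicalOutlierDetector(
        n_min=n_min, review_policy=review_policy, second_pass=second_pass)
    det.fit(records)
    report = det.score_frame(records)
    decisions = pd.Series(report["decision"].to_numpy(), index=records.index)

    if second_pass:
        survivors = records.loc[decisions != "exclude"]
        det.fit(survivors)
        report = det.score_frame(records)
        decisions = pd.Series(report["decision"].to_numpy(),
                              index=records.index)

    excluded = records.loc[decisions == "exclude"].copy()
    review = records.loc[decisions == "review"].copy()
    if review_policy == "strict":
        retained = records.loc[decisions == "retain"].copy()
    else:
        retained = records.loc[decisions != "exclude"].copy()
        if len(review) and "flags" in retained.columns:
            from .harmonize import add_flag
            mask = pd.Series(decisions.loc[retained.index] == "review",
                             index=retained.index)
            retained["flags"] = add_flag(retained["flags"], "review_pending",
                                         mask)
    return retained, review, excluded, report
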