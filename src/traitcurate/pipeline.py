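"""End-to-end curation pipeline: raw heterogeneous records in, species-mean
table and QC reports out.

Stage order follows the curation sequence of trait-compilation practice:
semantic integration of terminologies → taxonomic name resolution → unit
conversion and impossible-value exclusion → dataset-offset diagnostics →
exclusion of non-representative records → imputation → hierarchical z-score
outlier screening → duplicate removal → geometric species means with
categorical traits → validation reports.

Every input record's fate is traceable: it either contributes to a species
mean or appears in exactly one of the rejects, exclusions, or duplicates
tables.  The run is fully deterministic given the same inputs and
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .aggregate import Deduplicator, SpeciesAggregator, extremes_report, summary_table
from .harmonize import (
    DatasetOffsetDetector,
    ImpossibleValueFilter,
    RepresentativenessFilter,
    TermStandardizer,
    UnitConverter,
)
from .impute import TraitImputer
from .outlier import classify_records
from .taxonomy import ReferenceTaxonomy, TaxonResolver

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable knobs of one curation run; unknown keys are rejected."""

    records: str | None = None          # input CSV paths (None when tables
    taxonomy: str | None = None         # are passed to run_pipeline directly)
    categorical: str | None = None
    out_dir: str | None = None

    offset_min_n: int = 20
    offset_closeness: float = 0.2
    auto_correct_offsets: bool = False
    exclude_shade_leaves: bool = True
    fuzzy_taxonomy: bool = False
    outlier_n_min: int = 5
    review_policy: str = "retain"       # "retain" | "strict"
    second_pass: bool = False
    dedup_rel_tol: float = 1e-3

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def validate(self) -> None:
        if self.review_policy not in ("retain", "strict"):
            raise ValueError("review_policy must be 'retain' or 'strict'")
        if self.dedup_rel_tol < 0:
            raise ValueError("dedup_rel_tol must be >= 0")
        if self.outlier_n_min < 2:
            raise ValueError("outlier_n_min must be >= 2")


@dataclass
class PipelineResult:
    """All artifacts of one run."""

    species_table: pd.DataFrame
    rejects: pd.DataFrame
    zscore_report: pd.DataFrame
    offset_findings: pd.DataFrame
    duplicates: pd.DataFrame
    excluded: pd.DataFrame
    summary: pd.DataFrame
    extremes: pd.DataFrame
    record_fates: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list = field(default_factory=list)
    n_input: int = 0

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.species_table.to_csv(out / "species_means.csv", index=False)
        self.rejects.to_csv(out / "rejects.csv", index=False)
        self.zscore_report.to_csv(out / "zscore_report.csv", index=False)
        self.offset_findings.to_csv(out / "offset_findings.csv", index=False)
        self.duplicates.to_csv(out / "duplicates.csv", index=False)
        self.excluded.to_csv(out / "excluded.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.extremes.to_csv(out / "extremes.csv", index=False)
        self.record_fates.to_csv(out / "record_fates.csv", index=False)
        with open(out / "pipeline_log.jsonl", "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def _log_entry(stage: str, n_in: int, n_out: int, rejects: pd.DataFrame | None,
               ) -> dict:
    entry = {"stage": stage, "records_in": int(n_in), "records_out": int(n_out)}
    if rejects is not None and len(rejects):
        entry["rejects_by_reason"] = {
            str(k): int(v)
            for k, v in rejects["reason"].value_counts().items()}
    return entry


def _lineage(record_id: str) -> str:
    """Map a record id back to its input ancestor (imputed ids end in -imp)."""
    rid = str(record_id)
    return rid[:-4] if rid.endswith("-imp") else rid


def _record_fates(inputs: pd.DataFrame, rejects: pd.DataFrame,
                  excluded: pd.DataFrame, review: pd.DataFrame,
                  duplicates: pd.DataFrame, final: pd.DataFrame,
                  review_policy: str) -> pd.DataFrame:
    """One fate per input record: where it ended up and why.

    Imputed records are traced to the input record they were derived from;
    species-level imputed records (no input ancestor) do not claim a fate.
    """
    from .traits import CORE_TRAITS

    input_ids = set(inputs["record_id"].astype(str))
    fates: dict[str, str] = {}

    def assign(rid, fate):
        orig = _lineage(rid)
        if orig in input_ids and orig not in fates:
            fates[orig] = fate

    for row in rejects.itertuples(index=False):
        assign(row.record_id, f"rejected:{row.reason}")
    for rid in excluded["record_id"].astype(str):
        assign(rid, "excluded_outlier")
    if review_policy == "strict":
        for rid in review["record_id"].astype(str):
            assign(rid, "review_excluded")
    for rid in duplicates["record_id"].astype(str):
        assign(rid, "duplicate_removed")
    core = set(CORE_TRAITS)
    for row in final.itertuples(index=False):
        assign(row.record_id,
               "aggregated" if row.trait_code in core else "retained_unreported")
    for rid in input_ids:
        fates.setdefault(rid, "consumed_no_descendant")
    return pd.DataFrame(sorted(fates.items()), columns=["record_id", "fate"])


def run_pipeline(config: PipelineConfig | None = None,
                 records: pd.DataFrame | None = None,
                 taxonomy: pd.DataFrame | None = None,
                 categorical: pd.DataFrame | None = None,
                 ) -> PipelineResult:
    """Run the full curation pipeline.

    Inputs come either from the config's CSV paths or as DataFrames passed
    directly (the latter win).  Returns a :class:`PipelineResult`; if the
    config names an ``out_dir`` the artifacts are also written there as CSV
    plus a JSON-lines stage log.
    """
    config = config or PipelineConfig()
    config.validate()

    if records is None:
        if config.records is None:
            raise ValueError("no input records: pass a table or set config.records")
        records = pd.read_csv(config.records, keep_default_na=False)
    if taxonomy is None:
        if config.taxonomy is None:
            raise ValueError("no reference taxonomy given")
        taxonomy = pd.read_csv(config.taxonomy, keep_default_na=False)
    if categorical is None and config.categorical is not None:
        categorical = pd.read_csv(config.categorical, keep_default_na=False)

    log: list[dict] = []
    all_rejects: list[pd.DataFrame] = []
    n_input = len(records)

    # 1. semantic integration
    terms = TermStandardizer()
    current = terms.fit(records).transform(records)
    all_rejects.append(terms.rejects_)
    log.append(_log_entry("standardize_terms", n_input, len(current),
                          terms.rejects_))

    # 2. taxonomy resolution
    resolver = TaxonResolver(reference=ReferenceTaxonomy(taxonomy),
                             fuzzy=config.fuzzy_taxonomy)
    n_in = len(current)
    current = resolver.fit().transform(current)
    all_rejects.append(resolver.rejects_)
    log.append(_log_entry("resolve_species", n_in, len(current),
                          resolver.rejects_))

    # 3. unit conversion
    units = UnitConverter()
    n_in = len(current)
    current = units.fit(current).transform(current)
    all_rejects.append(units.rejects_)
    log.append(_log_entry("convert_units", n_in, len(current), units.rejects_))

    # 4. impossible values (before anything takes logs)
    impossible = ImpossibleValueFilter()
    n_in = len(current)
    current = impossible.fit(current).transform(current)
    all_rejects.append(impossible.rejects_)
    log.append(_log_entry("drop_impossible", n_in, len(current),
                          impossible.rejects_))

    # 5. dataset offset diagnostics (report-only unless auto_correct)
    offsets = DatasetOffsetDetector(min_n=config.offset_min_n,
                                    closeness=config.offset_closeness,
                                    auto_correct=config.auto_correct_offsets)
    current = offsets.fit(current).transform(current)
    log.append({"stage": "detect_dataset_offsets",
                "records_in": len(current), "records_out": len(current),
                "findings": int(len(offsets.findings_))})

    # 6. representativeness
    rep = RepresentativenessFilter(
        exclude_shade_leaves=config.exclude_shade_leaves)
    n_in = len(current)
    current = rep.fit(current).transform(current)
    all_rejects.append(rep.rejects_)
    log.append(_log_entry("filter_nonrepresentative", n_in, len(current),
                          rep.rejects_))

    # 7. imputation
    woodiness = {}
    if categorical is not None:
        woodiness = dict(zip(categorical["accepted_name"],
                             categorical["woodiness"].fillna("")))
    imputer = TraitImputer(woodiness=woodiness)
    n_in = len(current)
    current = imputer.fit().transform(current)
    log.append({"stage": "impute", "records_in": n_in,
                "records_out": len(current),
                "imputed": int(imputer.n_imputed_)})

    # 8. outlier screening
    n_in = len(current)
    retained, review, excluded, zreport = classify_records(
        current, n_min=config.outlier_n_min,
        review_policy=config.review_policy,
        second_pass=config.second_pass)
    log.append({"stage": "classify_records", "records_in": n_in,
                "records_out": len(retained),
                "excluded": int(len(excluded)), "review": int(len(review))})

    # 9. duplicates
    dedup = Deduplicator(rel_tol=config.dedup_rel_tol)
    n_in = len(retained)
    current = dedup.fit().transform(retained)
    log.append({"stage": "deduplicate", "records_in": n_in,
                "records_out": len(current),
                "duplicates_removed": int(len(dedup.duplicates_))})

    # 10. species means + reports
    aggregator = SpeciesAggregator(categorical=categorical)
    species_table = aggregator.fit().transform(current)
    log.append({"stage": "build_species_table",
                "records_in": len(current),
                "records_out": int(len(species_table)),
                "invalid_categories": int(len(aggregator.categorical_rejects_))})

    rejects = (pd.concat(all_rejects, ignore_index=True)
               if all_rejects else pd.DataFrame(
                   columns=["record_id", "stage", "reason"]))

    fates = _record_fates(records, rejects, excluded, review, dedup.duplicates_,
                          current, config.review_policy)

    result = PipelineResult(
        species_table=species_table,
        rejects=rejects,
        zscore_report=zreport,
        offset_findings=offsets.findings_,
        duplicates=dedup.duplicates_,
        excluded=excluded,
        summary=summary_table(species_table),
        extremes=extremes_report(species_table),
        record_fates=fates,
        log=log,
        n_input=n_input,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
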