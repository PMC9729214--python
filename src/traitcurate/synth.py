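"""Synthetic TRY-like trait-record generator with ground truth and error injection.

Real compilations of plant trait records are aggregated from many independent
datasets with heterogeneous units and terminologies, strongly right-skewed
records-per-species counts, and a known zoo of errors: wrong units, decimal
shifts, wrong species attribution, non-representative (juvenile or
experimental) measurements, and duplicated records.  This module emulates all
of that with known ground truth, so every curation stage can be benchmarked
against what was actually injected.

Trait values are generated log-normally with variance partitioned across
taxonomic levels: ``log10(value) = mu + family + genus + species + within``,
each effect an independent zero-mean normal draw.  By default the
within-species spread (sd 0.1 on log10) is well below the between-species
spread (~0.38), so a decade-scale unit error is a huge z-score event while a
two-fold biological extreme is unremarkable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import CATEGORICAL_VOCABULARIES, GROUPS, UNIT_FACTORS

__all__ = [
    "TaxonomyTemplate",
    "TraitModel",
    "DatasetDialect",
    "ErrorInjectionSpec",
    "GeneratorConfig",
    "build_taxonomy",
    "build_categorical_table",
    "simulate_records",
    "corrupt_records",
    "generate_dataset",
    "DEFAULT_DATASET_LAYOUT",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "record_id", "dataset_id", "species_name", "trait_term", "value", "unit",
    "maturity", "health", "growth_condition", "exposure", "location_id", "date",
]

GROUND_TRUTH_COLUMNS = [
    "record_id", "true_species", "trait_code", "true_value",
    "species_mean_log10", "error_kind", "duplicate_of",
]

#: Traits the generator emits, in emission order.
GENERATOR_TRAITS = ("H", "SSD", "LA", "LMA", "Nmass", "SM", "LDMC")

_SYLLABLES = [
    "ba", "ce", "da", "fe", "ga", "hi", "ka", "lo", "mi", "na", "po", "ra",
    "se", "ti", "ul", "ve", "xa", "zo", "br", "cl",
]


def _coin(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _latin_word(rng: np.random.Generator, n_syll: int, suffix: str = "") -> str:
    word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
    return word + suffix


def _draw_count(rng: np.random.Generator, spec) -> int:
    """A count given either a fixed int or an inclusive (low, high) range."""
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


# ---------------------------------------------------------------------------
# Templates and models
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyTemplate:
    """Shape of the synthetic reference taxonomy.

    ``genera_per_family`` and ``species_per_genus`` are either fixed counts or
    inclusive ``(low, high)`` ranges sampled uniformly per family/genus.
    ``group_proportions`` assigns each family to one higher-rank group.
    ``synonym_fraction`` of species additionally receive one synonym name.
    """

    n_families: int = 12
    genera_per_family: int | tuple[int, int] = (1, 4)
    species_per_genus: int | tuple[int, int] = (1, 8)
    group_proportions: Mapping[str, float] = field(default_factory=lambda: {
        "angiosperm_monocot": 0.20,
        "angiosperm_eudicot_fabaceae": 0.10,
        "angiosperm_other": 0.50,
        "gymnosperm": 0.10,
        "pteridophyte": 0.10,
    })
    synonym_fraction: float = 0.2

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name, spec in (("genera_per_family", self.genera_per_family),
                           ("species_per_genus", self.species_per_genus)):
            lo = spec[0] if isinstance(spec, (tuple, list)) else spec
            if lo < 1:
                raise ValueError(f"{name} must request at least one")
        if not 0 <= self.synonym_fraction <= 1:
            raise ValueError("synonym_fraction must be in [0, 1]")
        unknown = set(self.group_proportions) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in proportions: {sorted(unknown)}")
        total = sum(self.group_proportions.values())
        if total <= 0:
            raise ValueError("group proportions must sum to a positive value")


# Default log10 means are realistic geometric means for vascular plants:
# height ~1.6 m, SSD ~0.47 mg/mm3, leaf area ~1300 mm2, LMA ~72 g/m2,
# Nmass ~19 mg/g, seed mass ~2.6 mg, LDMC ~0.25 g/g.
_DEFAULT_MEANS = {
    "H": 0.21, "SSD": -0.33, "LA": 3.13, "LMA": 1.86,
    "Nmass": 1.28, "SM": 0.42, "LDMC": -0.60,
}

# LDMC is a bounded ratio with genuinely low variance; its components are
# scaled down so values stay inside (0, 1).
_DEFAULT_SDS = {
    trait: {"family": 0.25, "genus": 0.20, "species": 0.20, "within": 0.10}
    for trait in GENERATOR_TRAITS
}
_DEFAULT_SDS["LDMC"] = {"family": 0.10, "genus": 0.08, "species": 0.08,
                        "within": 0.05}


@dataclass
class TraitModel:
    """Log10-scale location and variance components per trait.

    ``mean_log10[trait]`` is the global mean; ``sd_log10[trait][level]`` the
    SD of the family/genus/species/within effect.  ``correlation`` optionally
    couples the species-level effects across traits (symmetric PSD, unit
    diagonal, trait order = ``traits``).
    """

    traits: tuple[str, ...] = GENERATOR_TRAITS
    mean_log10: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS))
    sd_log10: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in _DEFAULT_SDS.items()})
    correlation: np.ndarray | None = None

    def validate(self) -> None:
        for trait in self.traits:
            if trait not in self.mean_log10:
                raise ValueError(f"missing mean_log10 for {trait}")
            comps = self.sd_log10.get(trait)
            if comps is None:
                raise ValueError(f"missing sd_log10 for {trait}")
            for level in ("family", "genus", "species", "within"):
                sd = comps[level]
                if sd < 0:
                    raise ValueError(
                        f"sd_log10[{trait}][{level}] must be >= 0, got {sd}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(self.traits)
            if corr.shape != (k, k):
                raise ValueError("correlation shape must match traits")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation must be positive semi-definite")

    def between_species_sd(self, trait: str) -> float:
        """Total SD of species-level log10 means around the global mean."""
        c = self.sd_log10[trait]
        return float(np.sqrt(c["family"] ** 2 + c["genus"] ** 2
                             + c["species"] ** 2))


@dataclass
class DatasetDialect:
    """One synthetic source dataset: its trait terms and reporting units."""

    dataset_id: str
    terms: Mapping[str, str]    # trait_code -> free-text term used
    units: Mapping[str, str]    # trait_code -> unit string used

    def validate(self) -> None:
        for trait, unit in self.units.items():
            if (trait, unit) not in UNIT_FACTORS:
                raise ValueError(
                    f"{self.dataset_id}: unit {unit!r} unknown for {trait}")


DEFAULT_DATASET_LAYOUT = (
    DatasetDialect(
        dataset_id="DS01",
        terms={"H": "plant height", "SSD": "stem specific density",
               "LA": "leaf area", "LMA": "leaf mass per area",
               "Nmass": "leaf nitrogen per mass", "SM": "seed mass",
               "LDMC": "leaf dry matter content", "SLA": "specific leaf area"},
        units={"H": "m", "SSD": "mg/mm3", "LA": "mm2", "LMA": "g/m2",
               "Nmass": "mg/g", "SM": "mg", "LDMC": "g/g", "SLA": "m2/g"},
    ),
    DatasetDialect(
        dataset_id="DS02",
        terms={"H": "H", "SSD": "SSD", "LA": "LA", "LMA": "LMA",
               "Nmass": "Nmass", "SM": "SM", "LDMC": "LDMC", "SLA": "SLA"},
        units={"H": "cm", "SSD": "g/cm3", "LA": "cm2", "LMA": "mg/cm2",
               "Nmass": "%", "SM": "g", "LDMC": "mg/g", "SLA": "cm2/g"},
    ),
    DatasetDialect(
        dataset_id="DS03",
        terms={"H": "height", "SSD": "wood density", "LA": "leaf size",
               "LMA": "leaf dry mass per area", "Nmass": "leaf n",
               "SM": "seed weight", "LDMC": "leaf dry matter content",
               "SLA": "specific leaf area"},
        units={"H": "m", "SSD": "kg/m3", "LA": "mm2", "LMA": "g/m2",
               "Nmass": "g/kg", "SM": "mg", "LDMC": "%", "SLA": "mm2/mg"},
    ),
)


@dataclass
class ErrorInjectionSpec:
    """Per-record rates for each injected error kind.

    ``unit_shift`` and ``decimal_shift`` multiply the stored value by ``10^k``
    with ``k`` drawn from ``k_choices`` (the two kinds differ only in label:
    one emulates a wrong reporting unit, the other a misplaced decimal point).
    ``species_swap`` attributes the value to a random other species.
    ``nonrepresentative`` marks the record juvenile or experimentally grown.
    ``duplicate`` appends a clone of the record with location/date blanked and
    an optional tiny value perturbation (rounding noise).
    """

    unit_shift: float = 0.0
    decimal_shift: float = 0.0
    species_swap: float = 0.0
    nonrepresentative: float = 0.0
    duplicate: float = 0.0
    k_choices: Sequence[int] = (-3, -2, -1, 1, 2, 3)
    perturb_duplicates: bool = True

    _KINDS = ("unit_shift", "decimal_shift", "species_swap",
              "nonrepresentative", "duplicate")

    def rates(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._KINDS}

    def validate(self) -> None:
        rates = self.rates()
        for kind, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {kind}={rate} outside [0, 1]")
        if sum(rates.values()) > 1.0 + 1e-12:
            raise ValueError("error rates must sum to <= 1 per record")
        if any(k == 0 for k in self.k_choices):
            raise ValueError("k_choices must exclude 0")


# ---------------------------------------------------------------------------
# Taxonomy generation
# ---------------------------------------------------------------------------

def build_taxonomy(template: TaxonomyTemplate | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Generate a reference taxonomy table.

    Returns a DataFrame with columns ``accepted_name, genus, family, group,
    synonyms`` (synonyms pipe-separated, possibly empty).  Deterministic for a
    fixed template and seed; all names are unique.
    """
    template = template or TaxonomyTemplate()
    template.validate()
    rng = np.random.default_rng(seed)

    groups = list(template.group_proportions)
    probs = np.array([template.group_proportions[g] for g in groups], float)
    probs = probs / probs.sum()

    used: set[str] = set()

    counter = [0]

    def unique_word(n_syll: int, suffix: str = "") -> str:
        for _ in range(50):
            w = _latin_word(rng, n_syll, suffix)
            if w not in used:
                used.add(w)
                return w
        # dense name spaces (very large taxonomies): extend deterministically
        while True:
            counter[0] += 1
            w = _latin_word(rng, n_syll, f"{counter[0]}{suffix}")
            if w not in used:
                used.add(w)
                return w

    rows = []
    fabaceae_named = False
    for _ in range(template.n_families):
        group = groups[int(rng.choice(len(groups), p=probs))]
        if group == "angiosperm_eudicot_fabaceae" and not fabaceae_named:
            family = "Fabaceae"
            used.add(family)
            fabaceae_named = True
        else:
            family = unique_word(2, "aceae").capitalize()
        for _ in range(_draw_count(rng, template.genera_per_family)):
            genus = unique_word(3).capitalize()
            for _ in range(_draw_count(rng, template.species_per_genus)):
                epithet = unique_word(3)
                accepted = f"{genus} {epithet}"
                synonyms = ""
                if _coin(rng, template.synonym_fraction):
                    synonyms = f"{genus} {unique_word(3)}"
                rows.append((accepted, genus, family, group, synonyms))

    taxonomy = pd.DataFrame(
        rows, columns=["accepted_name", "genus", "family", "group", "synonyms"])
    if taxonomy["accepted_name"].duplicated().any():  # pragma: no cover
        raise RuntimeError("generated species names are not unique")
    return taxonomy


def build_categorical_table(taxonomy: pd.DataFrame, seed: int = 0,
                            missing_fraction: float = 0.1) -> pd.DataFrame:
    """Assign categorical traits per species, consistent with its group.

    Pteridophytes become non-woody ferns, gymnosperms woody needleleaved
    trees, monocots graminoids; eudicots split between woody and herbaceous.
    ``missing_fraction`` of entries are blanked to emulate incomplete
    coverage.  The woodiness column drives the stem-density imputation rule
    downstream (only non-woody species are eligible).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tax in taxonomy.itertuples(index=False):
        group = tax.group
        if group == "pteridophyte":
            wood, form, leaf = "non-woody", "fern", "broadleaved"
        elif group == "gymnosperm":
            wood, form, leaf = "woody", "tree", "needleleaved"
        elif group == "angiosperm_monocot":
            wood = "non-woody"
            form = "bamboo graminoid" if _coin(rng, 0.1) else "herbaceous graminoid"
            leaf = "broadleaved"
        else:
            if _coin(rng, 0.4):
                wood = "woody"
                form = str(rng.choice(["tree", "shrub", "shrub/tree"]))
            else:
                wood = "non-woody"
                form = "herbaceous non-graminoid"
            leaf = "broadleaved"
        row = {
            "accepted_name": tax.accepted_name,
            "woodiness": wood,
            "growth_form": form,
            "succulence": "not succulent",
            "habitat_adaptation": "terrestrial",
            "nutrition_type": "independent",
            "leaf_type": leaf,
        }
        for col in CATEGORICAL_VOCABULARIES:
            if _coin(rng, missing_fraction):
                row[col] = ""
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Record simulation
# ---------------------------------------------------------------------------

def _zero_truncated_geometric(rng: np.random.Generator, mean: float,
                              size: int) -> np.ndarray:
    """Zero-truncated geometric counts with the given mean (mean > median)."""
    if mean < 1:
        raise ValueError("mean records per species must be >= 1")
    p = 1.0 / mean
    return rng.geometric(p, size=size)


def simulate_records(taxonomy: pd.DataFrame,
                     trait_model: TraitModel | None = None,
                     records_per_species: float = 6.0,
                     dataset_layout: Sequence[DatasetDialect] = DEFAULT_DATASET_LAYOUT,
                     seed: int = 0,
                     sla_fraction: float = 0.1,
                     synonym_use_rate: float = 0.15,
                     metadata_unknown_rate: float = 0.3,
                     location_rate: float = 0.7,
                     date_rate: float = 0.6,
                     ssd_skip_species: frozenset | set = frozenset(),
                     records_distribution: str = "ztg",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw trait records over a taxonomy.

    Every species gets, per trait, a zero-truncated-geometric number of
    records (``records_per_species`` is the distribution mean), each assigned
    to one synthetic dataset and expressed in that dataset's unit and
    terminology.  ``sla_fraction`` of LMA records are emitted as specific
    leaf area instead (value = 1/LMA, unit converted), exercising the
    reciprocal imputation downstream.  Species in ``ssd_skip_species`` get no
    SSD records (in real compilations stem density is rarely measured on
    herbaceous plants; the curation pipeline imputes it from LDMC).

    Returns ``(records, ground_truth)``; ground truth stores, per record, the
    true species, the true value in standard units, and the species-level
    log10 mean of the emitted trait (for parameter-recovery benchmarks).
    """
    trait_model = trait_model or TraitModel()
    trait_model.validate()
    if len(dataset_layout) < 2:
        raise ValueError("need at least two synthetic datasets")
    for dialect in dataset_layout:
        dialect.validate()
    rng = np.random.default_rng(seed)

    traits = list(trait_model.traits)
    k = len(traits)
    families = taxonomy["family"].unique()
    genera = taxonomy["genus"].unique()

    fam_eff = {(f, t): rng.normal(0.0, trait_model.sd_log10[t]["family"])
               for f in families for t in traits}
    gen_eff = {(g, t): rng.normal(0.0, trait_model.sd_log10[t]["genus"])
               for g in genera for t in traits}

    # Species-level effects, optionally correlated across traits.
    n_species = len(taxonomy)
    sd_sp = np.array([trait_model.sd_log10[t]["species"] for t in traits])
    if trait_model.correlation is not None:
        cov = np.outer(sd_sp, sd_sp) * np.asarray(trait_model.correlation, float)
        sp_eff = rng.multivariate_normal(np.zeros(k), cov, size=n_species,
                                         method="eigh")
    else:
        sp_eff = rng.normal(0.0, 1.0, size=(n_species, k)) * sd_sp

    synonym_map = {
        t.accepted_name: t.synonyms.split("|")[0]
        for t in taxonomy.itertuples(index=False) if t.synonyms
    }

    records: list[dict] = []
    truth: list[dict] = []
    rid = 0
    for si, tax in enumerate(taxonomy.itertuples(index=False)):
        for ti, trait in enumerate(traits):
            if trait == "SSD" and tax.accepted_name in ssd_skip_species:
                continue
            if records_distribution == "fixed":
                n_rec = int(round(records_per_species))
            elif records_distribution == "ztg":
                n_rec = int(_zero_truncated_geometric(
                    rng, records_per_species, 1)[0])
            else:
                raise ValueError("records_distribution must be 'ztg' or 'fixed'")
            mu = (trait_model.mean_log10[trait]
                  + fam_eff[(tax.family, trait)]
                  + gen_eff[(tax.genus, trait)]
                  + sp_eff[si, ti])
            sd_w = trait_model.sd_log10[trait]["within"]
            for _ in range(n_rec):
                true_value = 10.0 ** (mu + rng.normal(0.0, sd_w))
                dialect = dataset_layout[int(rng.integers(len(dataset_layout)))]

                emit_trait = trait
                emit_value = true_value
                if trait == "LMA" and _coin(rng, sla_fraction):
                    emit_trait = "SLA"
                    emit_value = 1.0 / true_value  # m2/g

                unit = dialect.units[emit_trait]
                term = dialect.terms[emit_trait]
                stored = emit_value / UNIT_FACTORS[(emit_trait, unit)]

                name = tax.accepted_name
                if name in synonym_map and _coin(rng, synonym_use_rate):
                    name = synonym_map[name]

                def meta(value: str) -> str:
                    return "unknown" if _coin(rng, metadata_unknown_rate) else value

                rid += 1
                record_id = f"R{rid:07d}"
                records.append({
                    "record_id": record_id,
                    "dataset_id": dialect.dataset_id,
                    "species_name": name,
                    "trait_term": term,
                    "value": stored,
                    "unit": unit,
                    "maturity": meta("mature"),
                    "health": meta("healthy"),
                    "growth_condition": meta("natural"),
                    "exposure": meta("sun"),
                    "location_id": (f"L{rng.integers(1, 500):04d}"
                                    if _coin(rng, location_rate) else ""),
                    "date": (f"{rng.integers(2000, 2016)}-"
                             f"{rng.integers(1, 13):02d}-"
                             f"{rng.integers(1, 29):02d}"
                             if _coin(rng, date_rate) else ""),
                })
                truth.append({
                    "record_id": record_id,
                    "true_species": tax.accepted_name,
                    "trait_code": emit_trait,
                    "true_value": emit_value,
                    # geometric mean of SLA is the reciprocal of LMA's
                    "species_mean_log10": -mu if emit_trait == "SLA" else mu,
                    "error_kind": "none",
                    "duplicate_of": "",
                })

    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    truth_df = pd.DataFrame(truth, columns=GROUND_TRUTH_COLUMNS)
    return records_df, truth_df


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def corrupt_records(records: pd.DataFrame, ground_truth: pd.DataFrame,
                    spec: ErrorInjectionSpec, seed: int = 0,
                    taxonomy: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject errors of known kinds into clean records.

    Each input record independently receives at most one error, drawn from
    the spec's rates.  Duplicates are appended after the originals with fresh
    record ids, blanked location/date, and (optionally) a value perturbation
    of up to 0.05% relative.  Returns the corrupted records and the updated
    ground truth; every injected error is logged there under ``error_kind``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    records = records.copy().reset_index(drop=True)
    truth = ground_truth.copy().set_index("record_id", drop=False)

    if not records["record_id"].is_unique:
        raise ValueError("record ids must be unique")
    missing = set(records["record_id"]) - set(truth.index)
    if missing:
        raise ValueError("records lack ground truth entries")

    rates = spec.rates()
    kinds = list(rates)
    edges = np.cumsum([rates[k] for k in kinds])
    draws = rng.random(len(records))

    species_pool = (list(taxonomy["accepted_name"])
                    if taxonomy is not None
                    else sorted(truth["true_species"].unique()))

    dup_rows: list[dict] = []
    dup_truth: list[dict] = []
    max_id = int(records["record_id"].str.lstrip("R").astype(int).max())

    for i in range(len(records)):
        d = draws[i]
        kind = None
        for j, edge in enumerate(edges):
            if d < edge:
                kind = kinds[j]
                break
        if kind is None:
            continue
        rid = records.at[i, "record_id"]

        if kind in ("unit_shift", "decimal_shift"):
            kk = int(rng.choice(spec.k_choices))
            records.at[i, "value"] = records.at[i, "value"] * 10.0 ** kk
            truth.at[rid, "error_kind"] = kind
        elif kind == "species_swap":
            current = records.at[i, "species_name"]
            choices = [s for s in species_pool if s != current]
            if choices:
                records.at[i, "species_name"] = choices[
                    int(rng.integers(len(choices)))]
                truth.at[rid, "error_kind"] = "species_swap"
        elif kind == "nonrepresentative":
            if _coin(rng, 0.5):
                records.at[i, "maturity"] = "juvenile"
            else:
                records.at[i, "growth_condition"] = "experimental"
            truth.at[rid, "error_kind"] = "nonrepresentative"
        elif kind == "duplicate":
            clone = records.iloc[i].to_dict()
            max_id += 1
            clone["record_id"] = f"R{max_id:07d}"
            clone["location_id"] = ""
            clone["date"] = ""
            # multi-source compilations re-report the same measurement in
            # another dataset; unit/term stay with the record
            all_ds = records["dataset_id"].unique()
            clone["dataset_id"] = str(all_ds[int(rng.integers(len(all_ds)))])
            if spec.perturb_duplicates:
                clone["value"] = clone["value"] * (
                    1.0 + rng.uniform(-5e-4, 5e-4))
            dup_rows.append(clone)
            src = truth.loc[rid]
            dup_truth.append({
                "record_id": clone["record_id"],
                "true_species": src["true_species"],
                "trait_code": src["trait_code"],
                "true_value": src["true_value"],
                "species_mean_log10": src["species_mean_log10"],
                "error_kind": "duplicate",
                "duplicate_of": rid,
            })

    if dup_rows:
        records = pd.concat([records, pd.DataFrame(dup_rows)],
                            ignore_index=True)
        truth = pd.concat(
            [truth.reset_index(drop=True), pd.DataFrame(dup_truth)],
            ignore_index=True)
    else:
        truth = truth.reset_index(drop=True)
    return records, truth[GROUND_TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# End-to-end generation with file output
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Everything needed to emit one synthetic benchmark dataset."""

    seed: int = 0
    taxonomy: TaxonomyTemplate = field(default_factory=TaxonomyTemplate)
    trait_model: TraitModel = field(default_factory=TraitModel)
    errors: ErrorInjectionSpec = field(default_factory=ErrorInjectionSpec)
    records_per_species: float = 6.0
    records_distribution: str = "ztg"   # or "fixed"
    sla_fraction: float = 0.1
    categorical_missing_fraction: float = 0.1
    #: stem density is rarely measured on herbs; by default non-woody species
    #: get no SSD records, exercising the LDMC-based imputation downstream
    ssd_woody_only: bool = True

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        kwargs = {}
        if "taxonomy" in data:
            kwargs["taxonomy"] = TaxonomyTemplate(**data.pop("taxonomy"))
        if "trait_model" in data:
            kwargs["trait_model"] = TraitModel(**data.pop("trait_model"))
        if "errors" in data:
            kwargs["errors"] = ErrorInjectionSpec(**data.pop("errors"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def generate_dataset(config: GeneratorConfig | None = None,
                     out_dir: str | Path | None = None,
                     ) -> dict[str, pd.DataFrame]:
    """Generate taxonomy, records, ground truth, and categorical tables.

    If ``out_dir`` is given the four tables are written there as UTF-8 CSV
    (``records.csv``, ``taxonomy.csv``, ``ground_truth.csv``,
    ``categorical.csv``).
    """
    config = config or GeneratorConfig()
    taxonomy = build_taxonomy(config.taxonomy, seed=config.seed)
    categorical = build_categorical_table(
        taxonomy, seed=config.seed + 1,
        missing_fraction=config.categorical_missing_fraction)
    skip = frozenset()
    if config.ssd_woody_only:
        skip = frozenset(categorical.loc[categorical["woodiness"]
                                         .eq("non-woody"), "accepted_name"])
    records, truth = simulate_records(
        taxonomy, config.trait_model,
        records_per_species=config.records_per_species,
        seed=config.seed + 2, sla_fraction=config.sla_fraction,
        ssd_skip_species=skip,
        records_distribution=config.records_distribution)
    records, truth = corrupt_records(
        records, truth, config.errors, seed=config.seed + 3,
        taxonomy=taxonomy)

    tables = {"records": records, "taxonomy": taxonomy,
              "ground_truth": truth, "categorical": categorical}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
    return tables
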