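"""Generator behaviour: determinism, hierarchy, skew, and error injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import traitcurate as tc
from traitcurate.synth import GENERATOR_TRAITS, simulate_records


class TestBuildTaxonomy:
    def test_degenerate_single_species(self):
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=1, genera_per_family=1, species_per_genus=1,
            synonym_fraction=0.0), seed=3)
        assert len(tax) == 1

    def test_seed_determinism(self):
        template = tc.TaxonomyTemplate()
        a = tc.build_taxonomy(template, seed=42)
        b = tc.build_taxonomy(template, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_species_count_is_product_of_counts(self):
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=5, genera_per_family=4, species_per_genus=10), seed=1)
        assert len(tax) == 200

    def test_names_unique_and_hierarchy_total(self):
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(n_families=20), seed=9)
        assert tax["accepted_name"].is_unique
        assert tax[["genus", "family", "group"]].notna().all().all()
        assert (tax.groupby("genus")["family"].nunique() == 1).all()

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            tc.build_taxonomy(tc.TaxonomyTemplate(n_families=0), seed=0)


class TestSimulateRecords:
    @pytest.fixture(scope="class")
    @staticmethod
    def taxonomy():
        return tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=6, genera_per_family=2, species_per_genus=4), seed=2)

    def test_zero_within_sd_gives_identical_values(self, taxonomy):
        model = tc.TraitModel()
        for trait in model.traits:
            model.sd_log10[trait]["within"] = 0.0
        records, truth = simulate_records(taxonomy, model, seed=4,
                                          sla_fraction=0.0)
        merged = records.merge(truth, on="record_id")
        spread = merged.groupby(["true_species", "trait_code"])["true_value"].agg(
            lambda v: v.max() - v.min())
        assert (spread < 1e-9 * merged["true_value"].mean()).all()

    def test_between_species_variance_exceeds_within(self, taxonomy):
        records, truth = simulate_records(taxonomy, seed=4, sla_fraction=0.0)
        h = truth[truth["trait_code"] == "H"]
        logs = np.log10(h["true_value"].astype(float))
        species_means = logs.groupby(h["true_species"]).mean()
        within_var = (logs - h["true_species"].map(species_means)).var()
        assert species_means.var() > within_var

    def test_mean_records_per_species_exceeds_median(self, taxonomy):
        records, truth = simulate_records(taxonomy, seed=8, sla_fraction=0.0)
        counts = truth.groupby(["true_species", "trait_code"]).size()
        assert counts.mean() > counts.median()

    def test_records_span_multiple_datasets_with_dialects(self, taxonomy):
        records, _ = simulate_records(taxonomy, seed=4)
        assert records["dataset_id"].nunique() >= 2
        by_ds = records[records["trait_term"].isin(["plant height", "H", "height"])]
        assert by_ds.groupby("dataset_id")["unit"].first().nunique() >= 2

    def test_negative_sd_component_rejected(self, taxonomy):
        model = tc.TraitModel()
        model.sd_log10["H"]["within"] = -0.1
        with pytest.raises(ValueError):
            simulate_records(taxonomy, model, seed=0)

    def test_log10_values_normal_per_trait(self):
        # marginal log10 distribution of clean values matches the configured
        # normal with variance summed over hierarchy levels; one record per
        # single-species family so draws are independent (records within a
        # family share its effect, which would distort a plain KS test)
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=10_000, genera_per_family=1, species_per_genus=1,
            synonym_fraction=0.0), seed=6)
        traits = ("H", "LA", "Nmass")
        model = tc.TraitModel(
            traits=traits,
            mean_log10={t: tc.TraitModel().mean_log10[t] for t in traits},
            sd_log10={t: dict(tc.TraitModel().sd_log10[t]) for t in traits})
        records, truth = simulate_records(tax, model, records_per_species=1.0,
                                          seed=6, sla_fraction=0.0)
        for trait in traits:
            vals = truth.loc[truth["trait_code"] == trait, "true_value"]
            logs = np.log10(vals.astype(float))
            total_sd = np.sqrt(sum(
                model.sd_log10[trait][lvl] ** 2
                for lvl in ("family", "genus", "species", "within")))
            _, p = stats.kstest(logs, "norm",
                                args=(model.mean_log10[trait], total_sd))
            assert p > 0.01, f"{trait}: KS rejects normality (p={p})"


class TestCorruptRecords:
    @pytest.fixture(scope="class")
    @staticmethod
    def clean():
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=8, genera_per_family=2, species_per_genus=4), seed=2)
        records, truth = simulate_records(tax, seed=3, sla_fraction=0.0)
        return tax, records, truth

    def test_zero_rates_identity(self, clean):
        tax, records, truth = clean
        out, out_truth = tc.corrupt_records(records, truth,
                                            tc.ErrorInjectionSpec(), seed=1)
        pd.testing.assert_frame_equal(out, records.reset_index(drop=True))
        assert (out_truth["error_kind"] == "none").all()

    def test_unit_shift_multiplies_by_power_of_ten(self, clean):
        tax, records, truth = clean
        spec = tc.ErrorInjectionSpec(unit_shift=1.0, k_choices=(3,))
        out, out_truth = tc.corrupt_records(records, truth, spec, seed=1)
        ratio = out["value"].to_numpy() / records["value"].to_numpy()
        assert np.allclose(ratio, 1000.0)
        assert (out_truth["error_kind"] == "unit_shift").all()
        # ground truth keeps the uncorrupted value
        pd.testing.assert_series_equal(out_truth["true_value"],
                                       truth["true_value"])

    def test_duplicate_count_within_binomial_band(self):
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(
            n_families=10, genera_per_family=2, species_per_genus=4), seed=2)
        records, truth = simulate_records(tax, records_per_species=4.0,
                                          seed=3, sla_fraction=0.0)
        records, truth = records.head(1000), truth.head(1000)
        out, out_truth = tc.corrupt_records(
            records, truth, tc.ErrorInjectionSpec(duplicate=0.1), seed=5)
        n_dup = int((out_truth["error_kind"] == "duplicate").sum())
        assert 70 <= n_dup <= 130  # 99% binomial band at p=0.1, n=1000

    def test_duplicates_match_dedup_criteria(self, clean):
        tax, records, truth = clean
        out, out_truth = tc.corrupt_records(
            records, truth, tc.ErrorInjectionSpec(duplicate=0.2), seed=7)
        dups = out_truth[out_truth["error_kind"] == "duplicate"]
        merged = dups.merge(out, on="record_id")
        src = out.set_index("record_id")
        for row in merged.itertuples(index=False):
            source = src.loc[row.duplicate_of]
            assert row.species_name == source["species_name"]
            assert abs(row.value - source["value"]) <= 6e-4 * source["value"]
            assert row.location_id == "" and row.date == ""

    def test_conservation_and_bijective_ground_truth(self, clean):
        tax, records, truth = clean
        spec = tc.ErrorInjectionSpec(unit_shift=0.02, duplicate=0.05)
        out, out_truth = tc.corrupt_records(records, truth, spec, seed=9)
        n_dup = int((out_truth["error_kind"] == "duplicate").sum())
        assert len(out) == len(records) + n_dup
        assert set(out["record_id"]) == set(out_truth["record_id"])
        assert out_truth["record_id"].is_unique

    def test_rates_summing_over_one_rejected(self):
        with pytest.raises(ValueError):
            tc.ErrorInjectionSpec(unit_shift=0.6, duplicate=0.6).validate()


class TestSeedDeterminism:
    def test_generate_dataset_is_reproducible(self):
        config = tc.GeneratorConfig(
            seed=13, errors=tc.ErrorInjectionSpec(unit_shift=0.01,
                                                  duplicate=0.02))
        a = tc.generate_dataset(config)
        b = tc.generate_dataset(config)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_correlated_species_effects_accepted(self):
        k = len(GENERATOR_TRAITS)
        corr = np.full((k, k), 0.3)
        np.fill_diagonal(corr, 1.0)
        model = tc.TraitModel(correlation=corr)
        tax = tc.build_taxonomy(tc.TaxonomyTemplate(n_families=3), seed=0)
        records, truth = simulate_records(tax, model, seed=0)
        assert (truth["true_value"] > 0).all()

    def test_invalid_correlation_rejected(self):
        k = len(GENERATOR_TRAITS)
        corr = np.eye(k)
        corr[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError):
            tc.TraitModel(correlation=corr).validate()
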