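"""Rule-based trait imputation: SSD from LDMC, LMA from SLA, Nmass from Narea,
and spore mass from spore radius.

Stem specific density (SSD) is abundantly measured on woody plants but rare
for herbs.  For herbaceous (non-woody) species it is estimated from leaf dry
matter content (LDMC) through group-specific linear regressions of stem dry
matter content (StDMC) on LDMC, exploiting the near-1:1 correspondence of
StDMC and SSD in herbaceous stems.  With LDMC and StDMC in g g⁻¹, the
prediction reads directly in mg mm⁻³.  The slopes differ significantly
between monocots, Fabaceae, and other dicots, so three group equations are
used, with a pooled all-species equation as fallback.

The remaining rules are unit conversions in disguise: LMA is the reciprocal
of SLA; Nmass is Narea/LMA when both come from the same leaf; fern spore
mass is density × sphere volume at the reported spore radius.  Every value
produced here carries the ``imputed`` flag, and a measured value is never
overwritten by an imputed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .aggregate import geometric_mean  # noqa: F401  (re-export convenience)
from .traits import STANDARD_UNITS

__all__ = [
    "ImputationCoefficients",
    "SporeModel",
    "TraitImputer",
    "impute_ssd_from_ldmc",
    "impute_lma_from_sla",
    "impute_nmass_from_narea",
    "impute_sporemass_from_radius",
]

#: StDMC ~ LDMC regression coefficients (slope, intercept), both traits in
#: g g⁻¹, prediction numerically equal to SSD in mg mm⁻³.
DEFAULT_COEFFICIENTS = {
    "monocot": (0.888, 0.027),
    "fabaceae": (0.692, 0.048),
    "other_dicot": (0.524, 0.096),
    "all": (0.698, 0.058),
}

#: Higher-rank group -> coefficient row used for its herbaceous species.
GROUP_DISPATCH = {
    "angiosperm_monocot": "monocot",
    "angiosperm_eudicot_fabaceae": "fabaceae",
    "angiosperm_other": "other_dicot",
}


@dataclass
class ImputationCoefficients:
    """Slope/intercept per plant group for the SSD←LDMC rule."""

    coefficients: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))

    def validate(self) -> None:
        for group in ("monocot", "fabaceae", "other_dicot", "all"):
            if group not in self.coefficients:
                raise ValueError(f"missing coefficient row for {group}")
            slope, _ = self.coefficients[group]
            if slope <= 0:
                raise ValueError(f"slope for {group} must be > 0")

    def row_for_group(self, group: str) -> tuple[float, float]:
        """Coefficient row for a higher-rank taxonomic group (fallback: all)."""
        return self.coefficients[GROUP_DISPATCH.get(group, "all")]


@dataclass
class SporeModel:
    """Spherical-spore assumption: mass = density × (4/3)πr³."""

    density: float = 0.5  # mg mm^-3

    def validate(self) -> None:
        if self.density <= 0:
            raise ValueError("spore density must be > 0")


def impute_ssd_from_ldmc(ldmc: float, group: str,
                         coeffs: ImputationCoefficients | None = None,
                         woody: bool = False) -> float:
    """Estimate SSD (mg mm⁻³) for a herbaceous species from LDMC (g g⁻¹).

    ``group`` is either a coefficient key (monocot/fabaceae/other_dicot/all)
    or a higher-rank group name; unknown groups fall back to the pooled
    all-species equation.  Raises for woody species (the rule does not apply)
    and for LDMC outside (0, 1) (a dry-to-saturated mass ratio).
    """
    if woody:
        raise ValueError("SSD imputation applies to non-woody species only")
    if not 0.0 < ldmc < 1.0:
        raise ValueError(f"LDMC must be in (0, 1) g/g, got {ldmc}")
    coeffs = coeffs or ImputationCoefficients()
    coeffs.validate()
    if group in coeffs.coefficients:
        slope, intercept = coeffs.coefficients[group]
    else:
        slope, intercept = coeffs.row_for_group(group)
    return slope * ldmc + intercept


def impute_lma_from_sla(sla: float) -> float:
    """LMA (g m⁻²) from SLA (m² g⁻¹): the reciprocal."""
    if sla <= 0:
        raise ValueError("SLA must be > 0")
    return 1.0 / sla


def impute_nmass_from_narea(narea: float, lma: float) -> float:
    """Nmass (mg g⁻¹) from same-leaf Narea (g m⁻²) and LMA (g m⁻²)."""
    if narea <= 0 or lma <= 0:
        raise ValueError("Narea and LMA must be > 0")
    return 1000.0 * narea / lma


def impute_sporemass_from_radius(radius: float,
                                 model: SporeModel | None = None) -> float:
    """Fern spore mass (mg) from spore radius (mm), spheres of fixed density."""
    if radius <= 0:
        raise ValueError("spore radius must be > 0")
    model = model or SporeModel()
    model.validate()
    return model.density * (4.0 / 3.0) * math.pi * radius ** 3


class TraitImputer(BaseEstimator):
    """Apply the four imputation rules to a standardized record table.

    transform() expects records after harmonization and taxonomy resolution
    (columns ``trait_code, value, accepted_name, group, flags``; values in
    standard units) plus, via ``woodiness``, a species→woodiness mapping for
    the SSD rule.  It returns the table with imputed records appended:

    * every SLA record becomes an LMA record (value = 1/SLA);
    * every Narea record with an LMA record of the same ``observation_id``
      becomes an Nmass record (skipped when no such pairing exists);
    * every SPORE_RADIUS record of a pteridophyte becomes an SM record;
    * each non-woody species with LDMC records but no measured SSD gets one
      species-level imputed SSD record, predicted from the geometric mean of
      its LDMC values (skipped if that mean falls outside (0, 1)).

    Imputed records carry the ``imputed`` flag and fresh record ids suffixed
    ``-imp``; source records are consumed (SLA/Narea/SPORE_RADIUS do not
    reach the species table themselves).  LDMC records are retained: the
    species table does not report LDMC, but outlier screening still covers it.
    """

    def __init__(self, coefficients: ImputationCoefficients | None = None,
                 spore_model: SporeModel | None = None,
                 woodiness: Mapping[str, str] | None = None,
                 semiwoody_is_woody: bool = True):
        self.coefficients = coefficients
        self.spore_model = spore_model
        self.woodiness = woodiness
        self.semiwoody_is_woody = semiwoody_is_woody

    def fit(self, X=None, y=None):
        self.coefficients_ = self.coefficients or ImputationCoefficients()
        self.coefficients_.validate()
        self.spore_model_ = self.spore_model or SporeModel()
        self.spore_model_.validate()
        self.woodiness_ = dict(self.woodiness or {})
        return self

    def _is_woody(self, species: str) -> bool | None:
        wood = self.woodiness_.get(species, "")
        if wood == "woody":
            return True
        if wood == "non-woody":
            return False
        if wood == "semi-woody":
            return self.semiwoody_is_woody
        return None  # unknown

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coefficients_"):
            self.fit()
        records = X.copy()
        from .harmonize import add_flag

        imputed_frames: list[pd.DataFrame] = []
        consumed = pd.Series(False, index=records.index)

        # --- LMA from SLA (record-level reciprocal) ---
        sla = records["trait_code"].eq("SLA")
        if sla.any():
            new = records.loc[sla].copy()
            new["trait_code"] = "LMA"
            new["value"] = 1.0 / new["value"].astype(float)
            new["unit"] = STANDARD_UNITS["LMA"]
            new["record_id"] = new["record_id"].astype(str) + "-imp"
            new["flags"] = add_flag(new["flags"], "imputed")
            imputed_frames.append(new)
            consumed |= sla

        # --- Nmass from Narea, same observation only ---
        narea = records["trait_code"].eq("Narea")
        if narea.any():
            consumed |= narea  # Narea never reaches the species table
            if "observation_id" in records.columns:
                lma_obs = (records.loc[records["trait_code"].eq("LMA")
                                       & records["observation_id"].notna()
                                       & records["observation_id"].ne("")]
                           .drop_duplicates("observation_id")
                           .set_index("observation_id")["value"])
                cand = records.loc[narea & records["observation_id"].notna()
                                   & records["observation_id"].ne("")]
                match = cand["observation_id"].map(lma_obs)
                cand = cand.loc[match.notna()]
                if len(cand):
                    new = cand.copy()
                    lma_vals = match.loc[cand.index].astype(float)
                    new["trait_code"] = "Nmass"
                    new["value"] = 1000.0 * new["value"].astype(float) / lma_vals
                    new["unit"] = STANDARD_UNITS["Nmass"]
                    new["record_id"] = new["record_id"].astype(str) + "-imp"
                    new["flags"] = add_flag(new["flags"], "imputed")
                    imputed_frames.append(new)

        # --- SM from spore radius (pteridophytes) ---
        spore = records["trait_code"].eq("SPORE_RADIUS")
        if spore.any():
            consumed |= spore
            ferns = spore & records["group"].eq("pteridophyte")
            if ferns.any():
                new = records.loc[ferns].copy()
                r = new["value"].astype(float)
                new["trait_code"] = "SM"
                new["value"] = (self.spore_model_.density
                                * (4.0 / 3.0) * np.pi * r ** 3)
                new["unit"] = STANDARD_UNITS["SM"]
                new["record_id"] = new["record_id"].astype(str) + "-imp"
                new["flags"] = add_flag(new["flags"], "imputed")
                imputed_frames.append(new)

        # --- species-level SSD from LDMC, non-woody species without SSD ---
        has_ssd = set(records.loc[records["trait_code"].eq("SSD"),
                                  "accepted_name"])
        ldmc = records.loc[records["trait_code"].eq("LDMC")]
        ssd_rows = []
        for species, grp in ldmc.groupby("accepted_name"):
            if species in has_ssd:
                continue  # measured > imputed
            if self._is_woody(species) is not False:
                continue  # woody or unknown woodiness: rule not applicable
            gm_ldmc = geometric_mean(grp["value"].astype(float).to_numpy())
            if not 0.0 < gm_ldmc < 1.0:
                continue
            group = grp["group"].iloc[0]
            slope, intercept = self.coefficients_.row_for_group(group)
            template = grp.iloc[0].copy()
            template["record_id"] = f"{species.replace(' ', '_')}-ssd-imp"
            template["trait_code"] = "SSD"
            template["value"] = slope * gm_ldmc + intercept
            template["unit"] = STANDARD_UNITS["SSD"]
            ssd_rows.append(template)
        if ssd_rows:
            new = pd.DataFrame(ssd_rows)
            new["flags"] = add_flag(new["flags"], "imputed")
            imputed_frames.append(new)

        kept = records.loc[~consumed]
        out = pd.concat([kept, *imputed_frames], ignore_index=True)
        self.n_imputed_ = int(sum(len(f) for f in imputed_frames))
        return out
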