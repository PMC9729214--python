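"""Species-name standardization against a local reference taxonomy.

Emulates consolidation of taxonomy with a deterministic lookup table
(accepted names + synonyms, each carrying genus, family, and higher-rank
group) instead of a live name-resolution service.  Matching is exact first,
then by synonym, then after orthographic normalization; anything else is
rejected rather than guessed — silent mis-resolution is worse than rejection.
An optional, clearly flagged fuzzy mode tolerates a single-character edit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ReferenceTaxonomy",
    "ResolvedTaxon",
    "TaxonResolver",
    "normalize_name",
    "resolve_species",
]

_RANK_MARKERS = {"subsp.", "ssp.", "var.", "f.", "subvar.", "cv."}


def normalize_name(raw: str, collapse_infraspecific: bool = True) -> str:
    """Canonicalize a species name string.

    Trims and collapses whitespace, capitalizes the genus, lowercases the
    epithet, and strips trailing authority tokens (capitalized or abbreviated
    tokens after the binomial, and anything parenthesized).  With
    ``collapse_infraspecific`` (default), infraspecific rank markers and what
    follows them are dropped, reducing the name to the binomial.
    """
    name = re.sub(r"\s+", " ", str(raw).strip())
    if not name:
        return ""
    tokens = name.split(" ")
    out = [tokens[0].capitalize()]
    if len(tokens) > 1:
        out.append(tokens[1].lower())
    for tok in tokens[2:]:
        low = tok.lower()
        if low in _RANK_MARKERS:
            if collapse_infraspecific:
                break
            out.append(low)
            continue
        # authority tokens: capitalized, abbreviated, or parenthesized
        if tok[:1] == "(" or tok[:1].isupper() or tok.endswith("."):
            break
        out.append(low)
    return " ".join(out)


@dataclass
class ResolvedTaxon:
    """Outcome of resolving one input name."""

    input_name: str
    accepted_name: str | None
    genus: str | None
    family: str | None
    group: str | None
    match_kind: str  # exact | synonym | normalized | fuzzy | unmatched


class ReferenceTaxonomy:
    """Accepted-name/synonym lookup with genus, family, and group per species.

    Built from a table with columns ``accepted_name, genus, family, group,
    synonyms`` (pipe-separated synonyms, possibly empty).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"accepted_name", "genus", "family", "group"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference taxonomy missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("reference taxonomy is empty")
        self.table = table.reset_index(drop=True)
        self.accepted: dict[str, tuple[str, str, str, str]] = {}
        self.synonyms: dict[str, str] = {}
        fam_of_genus: dict[str, str] = {}
        for row in self.table.itertuples(index=False):
            name = str(row.accepted_name)
            if name in self.accepted:
                raise ValueError(f"duplicate accepted name: {name}")
            prior = fam_of_genus.setdefault(row.genus, row.family)
            if prior != row.family:
                raise ValueError(f"genus {row.genus} mapped to two families")
            self.accepted[name] = (name, row.genus, row.family, row.group)
            syns = getattr(row, "synonyms", "") or ""
            for syn in str(syns).split("|"):
                syn = syn.strip()
                if syn:
                    self.synonyms[syn] = name
        orphans = set(self.synonyms.values()) - set(self.accepted)
        if orphans:
            raise ValueError(f"synonyms target unknown accepted names: {sorted(orphans)}")
        # Normalized lookup covers both accepted names and synonyms.
        self._normalized: dict[str, str] = {}
        for name in self.accepted:
            self._normalized.setdefault(normalize_name(name), name)
        for syn, target in self.synonyms.items():
            self._normalized.setdefault(normalize_name(syn), target)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTaxonomy":
        return cls(pd.read_csv(path, keep_default_na=False))

    def __len__(self) -> int:
        return len(self.accepted)


def _within_one_edit(a: str, b: str) -> bool:
    """Levenshtein distance <= 1, checked directly (no DP table needed)."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: try deleting each position's surplus character
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


class TaxonResolver(BaseEstimator):
    """Resolve species-name strings through a reference taxonomy.

    Match precedence: exact accepted > exact synonym > normalized > (optional)
    fuzzy at edit distance 1.  ``transform`` attaches ``accepted_name, genus,
    family, group, match_kind`` columns to a records table and routes
    unmatched names to ``rejects_`` (reason ``unresolved_taxon``).
    """

    def __init__(self, reference: ReferenceTaxonomy | pd.DataFrame | None = None,
                 fuzzy: bool = False,
                 collapse_infraspecific: bool = True):
        self.reference = reference
        self.fuzzy = fuzzy
        self.collapse_infraspecific = collapse_infraspecific

    def fit(self, X=None, y=None):
        ref = self.reference
        if ref is None:
            raise ValueError("a reference taxonomy is required")
        self.reference_ = (ref if isinstance(ref, ReferenceTaxonomy)
                           else ReferenceTaxonomy(ref))
        return self

    def resolve(self, name: str) -> ResolvedTaxon:
        if not hasattr(self, "reference_"):
            self.fit()
        ref = self.reference_
        name = str(name)
        if name in ref.accepted:
            acc, genus, family, group = ref.accepted[name]
            return ResolvedTaxon(name, acc, genus, family, group, "exact")
        if name in ref.synonyms:
            acc, genus, family, group = ref.accepted[ref.synonyms[name]]
            return ResolvedTaxon(name, acc, genus, family, group, "synonym")
        norm = normalize_name(name, self.collapse_infraspecific)
        if norm in ref._normalized:
            acc, genus, family, group = ref.accepted[ref._normalized[norm]]
            return ResolvedTaxon(name, acc, genus, family, group, "normalized")
        if self.fuzzy:
            candidates = [acc for cand, acc in ref._normalized.items()
                          if _within_one_edit(norm, cand)]
            if len(set(candidates)) == 1:
                acc, genus, family, group = ref.accepted[candidates[0]]
                return ResolvedTaxon(name, acc, genus, family, group, "fuzzy")
        return ResolvedTaxon(name, None, None, None, None, "unmatched")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            self.fit()
        records = X.copy()
        cache: dict[str, ResolvedTaxon] = {}
        cols = {"accepted_name": [], "genus": [], "family": [], "group": [],
                "match_kind": []}
        for name in records["species_name"].astype(str):
            res = cache.get(name)
            if res is None:
                res = cache[name] = self.resolve(name)
            cols["accepted_name"].append(res.accepted_name)
            cols["genus"].append(res.genus)
            cols["family"].append(res.family)
            cols["group"].append(res.group)
            cols["match_kind"].append(res.match_kind)
        for col, vals in cols.items():
            records[col] = vals
        unmatched = records["match_kind"].eq("unmatched")
        rejects = records.loc[unmatched, ["record_id"]].copy()
        rejects["stage"] = "resolve_species"
        rejects["reason"] = "unresolved_taxon"
        self.rejects_ = rejects
        return records.loc[~unmatched].copy()


def resolve_species(name: str, reference: ReferenceTaxonomy,
                    fuzzy: bool = False) -> ResolvedTaxon:
    """Resolve one name against the reference; see :class:`TaxonResolver`."""
    return TaxonResolver(reference=reference, fuzzy=fuzzy).fit().resolve(name)
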