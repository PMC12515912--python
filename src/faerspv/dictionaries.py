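"""Drug-name and endpoint (preferred-term group) dictionaries.

Cohort construction is driven by two lookup tables: verbatim drug name ->
study generic, and MedDRA preferred term -> arrhythmia endpoint. Both are
loaded from YAML and validated for pairwise disjointness, since a synonym
claimed by two generics (or a PT by two endpoints) would double-count
reports in separately tabulated strata.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

ENDPOINTS = ("qt_tdp", "af", "heart_block", "ventricular_arrhythmia")

ENDPOINT_LABELS = {
    "qt_tdp": "QT prolongation/TdP",
    "af": "Atrial fibrillation",
    "heart_block": "Heart block",
    "ventricular_arrhythmia": "Ventricular arrhythmia",
}

#: indication PTs defining the depression/MDD cohort
DEFAULT_INDICATION_TERMS = frozenset({"depression", "major depression"})

# tokens stripped from verbatim drug names: salt/ester suffixes and
# dosage-form noise; matching is exact after this normalization
_SALT_TOKENS = {
    "hydrobromide", "hydrochloride", "hcl", "fumarate", "oxalate", "maleate",
    "succinate", "mesylate", "besylate", "tartrate", "bitartrate", "citrate",
    "sodium", "calcium", "potassium", "hemihydrate", "dihydrate",
    "monohydrate", "tablet", "tablets", "capsule", "capsules",
}
_DOSE_RE = re.compile(r"\b\d+(\.\d+)?\s*(mg|mcg|ug|g|ml|mg/ml)\b")
_WS_RE = re.compile(r"\s+")


def normalize_drug_name(verbatim: str) -> str:
    """Case-fold, trim, and strip dosage and salt-form suffixes.

    Idempotent; purely rule-based (no fuzzy matching):

    >>> normalize_drug_name("CITALOPRAM HYDROBROMIDE 20MG")
    'citalopram'
    """
    name = verbatim.casefold().strip()
    name = _DOSE_RE.sub(" ", name)
    tokens = [t for t in name.split() if t not in _SALT_TOKENS]
    return _WS_RE.sub(" ", " ".join(tokens)).strip()


def _check_disjoint(sets: Mapping[str, frozenset[str]], what: str) -> None:
    keys = list(sets)
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            overlap = sets[ki] & sets[kj]
            if overlap:
                raise ValueError(
                    f"{what} {ki!r} and {kj!r} share entries: {sorted(overlap)[:3]}")


@dataclass(frozen=True)
class DrugDictionary:
    """generic -> set of normalized synonyms (the generic itself included)."""
    synonyms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError("drug dictionary is empty")
        _check_disjoint(self.synonyms, "drug synonym sets for")

    @property
    def generics(self) -> tuple[str, ...]:
        return tuple(self.synonyms)

    def lookup(self, verbatim: str) -> str | None:
        token = normalize_drug_name(verbatim)
        for generic, names in self.synonyms.items():
            if token in names:
                return generic
        return None

    def to_lookup_table(self) -> dict[str, str]:
        return {syn: generic for generic, names in self.synonyms.items()
                for syn in names}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "DrugDictionary":
        return cls({
            generic.casefold().strip(): frozenset(
                {normalize_drug_name(generic)}
                | {normalize_drug_name(s) for s in (syns or [])})
            for generic, syns in mapping.items()
        })

    @classmethod
    def from_yaml(cls, path: Path | str) -> "DrugDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@dataclass(frozen=True)
class EndpointDictionary:
    """endpoint -> set of preferred terms (matched case-insensitively)."""
    terms: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("endpoint dictionary is empty")
        for endpoint, pts in self.terms.items():
            if not pts:
                raise ValueError(f"endpoint {endpoint!r} has an empty PT set")
        _check_disjoint(self.terms, "endpoint PT sets for")

    @property
    def endpoints(self) -> tuple[str, ...]:
        return tuple(self.terms)

    def to_lookup_table(self) -> dict[str, str]:
        return {pt: endpoint for endpoint, pts in self.terms.items() for pt in pts}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "EndpointDictionary":
        return cls({endpoint: frozenset(pt.casefold().strip() for pt in pts)
                    for endpoint, pts in mapping.items()})

    @classmethod
    def from_yaml(cls, path: Path | str) -> "EndpointDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("faerspv").joinpath("data", name)))


def default_drug_dictionary() -> DrugDictionary:
    """The eight study antidepressants with common brand synonyms."""
    return DrugDictionary.from_yaml(_data_path("drug_dictionary.yaml"))


def default_endpoint_dictionary() -> EndpointDictionary:
    """Placeholder narrow-scope PT groups for the four arrhythmia endpoints."""
    return EndpointDictionary.from_yaml(_data_path("endpoint_dictionary.yaml"))
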