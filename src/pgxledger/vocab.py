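"""Controlled vocabularies: drugs, requester roles, access purposes, and the
drug–gene guideline table.

The tables ship as versioned CSV resources inside the package. Six drugs are
covered — the CYP2D6 opioids (codeine, tramadol), abacavir (HLA-B*57:01),
the fluoropyrimidines (capecitabine, fluorouracil; DPYD) and gentamicin
(MT-RNR1 m.1555A>G) — each with a per-phenotype prescribing recommendation
code (STANDARD, REDUCE_DOSE, AVOID). Permission triples and published
metadata are validated against these closed lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

VOCAB_VERSION = "1"

RECOMMENDATION_CODES = ("STANDARD", "REDUCE_DOSE", "AVOID")


@dataclass(frozen=True)
class GuidelineRow:
    drug: str
    gene: str
    phenotype: str
    recommendation: str


def _read_resource(name: str) -> list[dict[str, str]]:
    text = resources.files("pgxledger.resources").joinpath(name).read_text("utf-8")
    return list(csv.DictReader(text.splitlines()))


@lru_cache(maxsize=1)
def drug_table() -> dict[str, str]:
    """Mapping drug code -> governing pharmacogene."""
    return {row["drug"]: row["gene"] for row in _read_resource("drugs.csv")}


@lru_cache(maxsize=1)
def drugs() -> tuple[str, ...]:
    return tuple(drug_table())


@lru_cache(maxsize=1)
def roles() -> tuple[str, ...]:
    return tuple(row["role"] for row in _read_resource("roles.csv"))


@lru_cache(maxsize=1)
def purposes() -> tuple[str, ...]:
    return tuple(row["purpose"] for row in _read_resource("purposes.csv"))


@lru_cache(maxsize=1)
def guideline_table() -> tuple[GuidelineRow, ...]:
    return tuple(
        GuidelineRow(**row) for row in _read_resource("guidelines.csv")
    )


@lru_cache(maxsize=1)
def _guideline_index() -> dict[tuple[str, str], str]:
    return {
        (row.drug, row.phenotype): row.recommendation
        for row in guideline_table()
    }


def recommendation_for(drug: str, phenotype: str) -> str | None:
    """Guideline recommendation code for a drug given the phenotype of its
    governing gene, or None if the table has no matching row."""
    return _guideline_index().get((drug, phenotype))


def gene_for(drug: str) -> str | None:
    return drug_table().get(drug)


@lru_cache(maxsize=1)
def phenotypes_by_gene() -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for row in guideline_table():
        if row.phenotype not in out.setdefault(row.gene, []):
            out[row.gene].append(row.phenotype)
    return {g: tuple(ps) for g, ps in out.items()}


def all_triples() -> tuple[tuple[str, str, str], ...]:
    """The full drug × role × purpose cube."""
    return tuple(
        (d, r, p) for d in drugs() for r in roles() for p in purposes()
    )
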