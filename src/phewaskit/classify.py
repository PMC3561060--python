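"""Known / related / novel labelling of flagged groups.

A flagged (SNP, phenotype-class, stratum) group is compared against a catalog
of previously published SNP–trait links plus a curated class↔trait mapping:

* **known** — some catalog trait for the SNP maps to the group's class with
  relation ``same`` (the group replicates the published association);
* **related** — no ``same`` match, but some catalog trait maps with relation
  ``related`` (a phenotype-class judged closely related to a published one);
* **novel** — no catalog trait for the SNP maps to the class at all.

The same/related judgement is human curation shipped as a mapping file; this
module only performs the lookup.  Classification depends only on the SNP and
the class, never on effect sizes or p-values.  Catalog trait terms are
matched case-insensitively after whitespace normalization.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import (ClassGroup, ClassificationLabel, KnownAssociationCatalog,
                   SchemaError)

__all__ = [
    "ClassTraitMap",
    "read_class_trait_map",
    "write_class_trait_map",
    "classify_group",
    "classify_groups",
    "summarize_classification",
]

logger = logging.getLogger(__name__)

RELATIONS = ("same", "related")


def _norm(term: str) -> str:
    return " ".join(term.split()).casefold()


@dataclass
class ClassTraitMap:
    """Curated (class_id, trait_term, relation) records; relation ∈ {same,
    related}.  (class_id, trait_term) pairs are unique."""

    records: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, class_id: str, trait_term: str, relation: str) -> None:
        if relation not in RELATIONS:
            raise ValueError(f"relation must be one of {RELATIONS}, got "
                             f"{relation!r}")
        key = (class_id, _norm(trait_term))
        existing = self.records.get(key)
        if existing is not None and existing != relation:
            raise SchemaError(
                f"conflicting relation for {key}: {existing!r} vs "
                f"{relation!r}")
        self.records[key] = relation

    def relation(self, class_id: str, trait_term: str) -> str | None:
        return self.records.get((class_id, _norm(trait_term)))


def read_class_trait_map(path: str | Path) -> ClassTraitMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"class_id", "trait_term", "relation"}
    if not need.issubset(df.columns):
        raise SchemaError(f"class-trait map needs columns {sorted(need)}",
                          path, 1)
    out = ClassTraitMap()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.add(row.class_id, row.trait_term, row.relation)
        except (ValueError, SchemaError) as exc:
            raise SchemaError(str(exc), path, i) from exc
    return out


def write_class_trait_map(cmap: ClassTraitMap, path: str | Path) -> None:
    rows = [(c, t, r) for (c, t), r in sorted(cmap.records.items())]
    pd.DataFrame(rows, columns=["class_id", "trait_term", "relation"]
                 ).to_csv(path, sep="\t", index=False)


def classify_group(group: ClassGroup, catalog: KnownAssociationCatalog,
                   class_trait_map: ClassTraitMap) -> ClassificationLabel:
    """Label one flagged group as known, related or novel.

    A SNP absent from the catalog yields novel with empty support (logged as
    a warning, since an uncatalogued SNP usually means an incomplete catalog
    rather than a genuinely unstudied variant).
    """
    traits = catalog.traits_for(group.snp_id)
    if not traits:
        logger.warning("SNP %s absent from known-association catalog; "
                       "labelling %s/%s novel", group.snp_id, group.class_id,
                       group.stratum)
        return ClassificationLabel(group, "novel", [])
    same = [t for t in traits
            if class_trait_map.relation(group.class_id, t) == "same"]
    if same:
        return ClassificationLabel(group, "known", same)
    related = [t for t in traits
               if class_trait_map.relation(group.class_id, t) == "related"]
    if related:
        return ClassificationLabel(group, "related", related)
    return ClassificationLabel(group, "novel", [])


def classify_groups(groups: Iterable[ClassGroup],
                    catalog: KnownAssociationCatalog,
                    class_trait_map: ClassTraitMap,
                    flagged_only: bool = True) -> list[ClassificationLabel]:
    return [classify_group(g, catalog, class_trait_map) for g in groups
            if g.flagged or not flagged_only]


def summarize_classification(labels: Iterable[ClassificationLabel],
                             ) -> dict[str, int]:
    """Counts by label; known + related + novel partitions the labelled set."""
    counts = Counter(lbl.label for lbl in labels)
    return {k: counts.get(k, 0) for k in ("known", "related", "novel")}
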