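"""Cross-study alignment of association results.

Three concerns, mirroring what a coordinating center must do before results
from independently analyzed cohorts can be compared:

* **Allele alignment** — each site may have coded the additive dosage on
  either allele; results are rewritten onto a master registry's coded allele
  (beta negated, CAF complemented when flipped), with strand-ambiguous A/T and
  C/G SNPs flagged.
* **Class assignment** — study phenotypes are mapped to curated
  phenotype-classes; the curation itself is human work shipped as a mapping
  file, never inferred here.
* **Effective direction** — the sign of the effect after combining the beta's
  sign with the phenotype's polarity (e.g. "never hypertensive" carries
  polarity −1 within class Hypertension), so direction-of-effect consistency
  can be compared across differently phrased phenotypes.  Polarity ``None``
  means direction comparison is not phenotypically relevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (AssociationResult, PhenotypeClassMap, SchemaError,
                   SnpRecord, RESULT_COLUMNS, results_to_frame)

__all__ = [
    "EffectiveResult",
    "align_alleles",
    "assign_classes",
    "derive_class_candidates",
    "site_of",
    "EFFECTIVE_COLUMNS",
]

#: Result-frame columns after harmonization.
EFFECTIVE_COLUMNS = RESULT_COLUMNS + ["class_id", "effective_direction",
                                      "site_id"]


@dataclass(frozen=True)
class EffectiveResult:
    """An AssociationResult annotated with its class and effective direction."""

    result: AssociationResult
    class_id: str | None
    effective_direction: int  # +1 / -1 / 0 (none)

    def __post_init__(self):
        beta_sign = int(np.sign(self.result.beta))
        if self.effective_direction not in (-1, 0, 1):
            raise ValueError("effective_direction must be -1, 0 or +1")
        if self.effective_direction != 0 and beta_sign != 0 \
                and abs(self.effective_direction) != 1:
            raise ValueError("inconsistent direction")


def _as_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results.copy()
    return results_to_frame(results)


def align_alleles(results, master_registry: Mapping[str, SnpRecord] |
                  Iterable[SnpRecord],
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rewrite results onto the master registry's coded alleles.

    A result whose coded allele equals the registry's other allele gets its
    beta negated, CAF complemented and coded allele rewritten; one matching
    neither allele is an error.  Idempotent.  Returns ``(aligned, audit)``
    where audit records one row per flipped result plus a ``strand_ambiguous``
    flag column on the aligned frame.
    """
    frame = _as_frame(results)
    if not isinstance(master_registry, Mapping):
        master_registry = {s.snp_id: s for s in master_registry}
    missing = set(frame["snp_id"]) - set(master_registry)
    if missing:
        raise SchemaError(
            f"SNP(s) absent from master registry: {sorted(missing)[:5]}")

    flips = []
    ambiguous = np.zeros(len(frame), dtype=bool)
    for i, (snp_id, coded) in enumerate(
            zip(frame["snp_id"].to_numpy(), frame["coded_allele"].to_numpy())):
        rec = master_registry[snp_id]
        ambiguous[i] = rec.strand_ambiguous
        if coded == rec.coded_allele:
            continue
        if coded != rec.other_allele:
            raise SchemaError(
                f"{snp_id}: result coded allele {coded!r} matches neither "
                f"registry allele ({rec.coded_allele}/{rec.other_allele})")
        flips.append(i)
    if flips:
        idx = frame.index[flips]
        frame.loc[idx, "beta"] = -frame.loc[idx, "beta"]
        frame.loc[idx, "caf"] = 1.0 - frame.loc[idx, "caf"]
        frame.loc[idx, "coded_allele"] = [
            master_registry[s].coded_allele
            for s in frame.loc[idx, "snp_id"]]
    frame["strand_ambiguous"] = ambiguous
    audit = frame.iloc[flips][["study_id", "stratum", "snp_id",
                               "phenotype_name", "transform"]].copy()
    audit["flip"] = "allele"
    return frame, audit.reset_index(drop=True)


def site_of(study_id: str, site_map: Mapping[str, str] | None = None) -> str:
    """Collapse a substudy id to its study site (e.g. EAGLEIII → EAGLE).

    Replication counts distinct *sites*; substudy→site membership comes from
    an explicit mapping, defaulting to identity.
    """
    if site_map and study_id in site_map:
        return site_map[study_id]
    return study_id


def assign_classes(results, class_map: PhenotypeClassMap,
                   polarities: Mapping[tuple[str, str], int | None] |
                   None = None,
                   site_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Annotate results with class_id, effective direction and site id.

    Unmapped phenotypes are retained with an empty class_id (they are excluded
    from replication but still appear in per-SNP sun plots).  Transformed and
    untransformed rows of one phenotype share the phenotype name and therefore
    the class.  ``polarities`` maps (study_id, phenotype_name) to +1/−1/None;
    unlisted phenotypes default to +1.  Never changes beta, se, p or n.
    """
    frame = _as_frame(results)
    polarities = polarities or {}

    class_ids = []
    directions = []
    for row in frame.itertuples(index=False):
        cid = class_map.lookup(row.study_id, row.phenotype_name)
        class_ids.append(cid if cid is not None else "")
        pol = polarities.get((row.study_id, row.phenotype_name), 1)
        if pol is None:
            directions.append(0)
        else:
            directions.append(int(np.sign(row.beta)) * pol)
    frame["class_id"] = class_ids
    frame["effective_direction"] = directions
    frame["site_id"] = [site_of(s, site_map) for s in frame["study_id"]]
    return frame


def derive_class_candidates(results, p_threshold: float = 0.01,
                            ) -> dict[str, list[str]]:
    """Per-study deduplicated lists of phenotypes with any test below threshold.

    This is the curation input of the class-building workflow: filter each
    study's scan for p < threshold, list the distinct phenotype names, and
    hand those lists to a human curator who bins them into phenotype-classes.
    The binning judgement itself is outside this package.
    """
    frame = _as_frame(results)
    out: dict[str, list[str]] = {}
    hits = frame[frame["p"] < p_threshold]
    for study, sub in hits.groupby("study_id"):
        out[str(study)] = sorted(sub["phenotype_name"].unique())
    for study in frame["study_id"].unique():
        out.setdefault(str(study), [])
    return out
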