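"""Domain types and file IO for multi-study PheWAS analysis.

A PheWAS (phenome-wide association study) tests one or more genetic variants
against every available phenotype.  This module defines the record types shared
by all pipeline stages — SNP registry entries, phenotype descriptors, per-study
datasets, per-test association results, the phenotype→phenotype-class map, the
known-association catalog, and cross-study result groups — plus readers and
writers for the tab-delimited interchange formats.

Conventions
-----------
* All delimited files are UTF-8, tab-separated, '.'-decimal, with a header row.
* Missing values are empty fields; no sentinel codes.
* Genotypes are additive dosages in {0, 1, 2} (copies of the coded allele).
* Positions are 1-based (VCF convention) and used only for plotting.
* Strata (race/ethnicity groups such as EA, AA, H, API) are free strings, not
  an enum, so new groups need no code change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "SnpRecord",
    "PhenotypeDescriptor",
    "StudyDataset",
    "AssociationResult",
    "PhenotypeClassMap",
    "KnownAssociationCatalog",
    "ClassGroup",
    "ClassificationLabel",
    "RESULT_COLUMNS",
    "read_study",
    "read_vcf_dosages",
    "read_results",
    "write_results",
    "results_to_frame",
    "frame_to_results",
    "read_class_map",
    "write_class_map",
    "read_catalog",
    "write_catalog",
    "read_snp_registry",
    "write_snp_registry",
]

VALUE_KINDS = ("continuous", "binary", "categorical")

#: Column order of the standardized one-row-per-test result template.
RESULT_COLUMNS = [
    "study_id",
    "stratum",
    "snp_id",
    "coded_allele",
    "caf",
    "phenotype_name",
    "transform",
    "model",
    "beta",
    "se",
    "p",
    "n",
]


class SchemaError(ValueError):
    """Raised when an input file violates its documented schema."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line = line


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One entry of the coded-allele registry.

    ``coded_allele`` is the allele whose copies are counted by the additive
    dosage; ``other_allele`` the complementary allele at the site.
    """

    snp_id: str
    chrom: str
    pos: int
    coded_allele: str
    other_allele: str

    def __post_init__(self):
        if self.coded_allele == self.other_allele:
            raise ValueError(
                f"{self.snp_id}: coded and other allele are both "
                f"{self.coded_allele!r}")

    @property
    def strand_ambiguous(self) -> bool:
        """True for A/T and C/G SNPs, which cannot be strand-resolved."""
        pair = frozenset((self.coded_allele.upper(), self.other_allele.upper()))
        return pair in (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class PhenotypeDescriptor:
    """Dictionary entry for one study phenotype.

    ``polarity`` relates an increase in this phenotype to the canonical
    direction of its phenotype-class: +1 (same direction), -1 (opposite,
    e.g. "never hypertensive" within class Hypertension), or ``None`` when a
    direction comparison is not phenotypically relevant.
    """

    study_id: str
    name: str
    value_kind: str
    units: str = ""
    polarity: int | None = 1
    class_id: str | None = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"{self.name}: unknown value_kind {self.value_kind!r}")
        if self.polarity not in (1, -1, None):
            raise ValueError(
                f"{self.name}: polarity must be +1, -1 or None, got "
                f"{self.polarity!r}")


@dataclass
class StudyDataset:
    """One study site's genotypes, phenotypes, dictionary and strata.

    ``dosages`` is subjects × SNPs (float, NaN = missing); ``phenotypes`` is
    subjects × phenotype names with NaN allowed.  Every phenotype column must
    have a dictionary entry.
    """

    study_id: str
    subjects: list[str]
    strata: pd.Series            # index = subjects, values = stratum labels
    dosages: pd.DataFrame        # index = subjects, columns = snp ids
    snps: list[SnpRecord]
    phenotypes: pd.DataFrame     # index = subjects, columns = phenotype names
    dictionary: dict[str, PhenotypeDescriptor]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        subj = list(self.subjects)
        if len(set(subj)) != len(subj):
            raise SchemaError(f"{self.study_id}: duplicate subject ids")
        for frame, what in ((self.dosages, "genotype"),
                            (self.phenotypes, "phenotype")):
            if list(frame.index) != subj:
                raise SchemaError(
                    f"{self.study_id}: {what} matrix rows do not match the "
                    f"subject list")
        if list(self.strata.index) != subj:
            raise SchemaError(
                f"{self.study_id}: strata not aligned to subject list")
        snp_ids = [s.snp_id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise SchemaError(f"{self.study_id}: duplicate SNP ids in registry")
        if list(self.dosages.columns) != snp_ids:
            raise SchemaError(
                f"{self.study_id}: dosage columns do not match SNP registry")
        pheno_names = list(self.phenotypes.columns)
        if len(set(pheno_names)) != len(pheno_names):
            raise SchemaError(f"{self.study_id}: duplicate phenotype names")
        missing = [p for p in pheno_names if p not in self.dictionary]
        if missing:
            raise SchemaError(
                f"{self.study_id}: phenotype column(s) without dictionary "
                f"entry: {missing[:5]}")
        bad = self.dosages.values[~np.isnan(self.dosages.values.astype(float))]
        if bad.size and not np.isin(bad, (0.0, 1.0, 2.0)).all():
            raise SchemaError(
                f"{self.study_id}: dosages outside {{0,1,2,missing}}")

    @property
    def snp_index(self) -> dict[str, SnpRecord]:
        return {s.snp_id: s for s in self.snps}

    def stratum_labels(self) -> list[str]:
        return sorted(self.strata.dropna().unique())


@dataclass(frozen=True)
class AssociationResult:
    """One regression outcome: the row type of the standardized template.

    ``beta`` is the effect per copy of the coded allele (OLS slope for linear,
    log-odds for logistic); ``caf`` the coded-allele frequency among the
    analyzed (complete-case) subjects; ``transform`` is ``none`` or ``log1p``.
    """

    study_id: str
    stratum: str
    snp_id: str
    coded_allele: str
    caf: float
    phenotype_name: str
    transform: str
    model: str
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of [0,1]: {self.p}")
        if not self.se > 0:
            raise ValueError(f"se must be positive: {self.se}")
        if not (0.0 <= self.caf <= 1.0):
            raise ValueError(f"caf out of [0,1]: {self.caf}")
        if self.transform not in ("none", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.model not in ("linear", "logistic"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class PhenotypeClassMap:
    """Mapping (study_id, phenotype_name) → phenotype-class id.

    Phenotype-classes are curated bins of the same or closely related
    phenotypes measured across studies (e.g. "Hemoglobin"); they are the unit
    at which cross-study replication is assessed.
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)

    def add(self, study_id: str, phenotype_name: str, class_id: str) -> None:
        key = (study_id, phenotype_name)
        existing = self.entries.get(key)
        if existing is not None and existing != class_id:
            raise SchemaError(
                f"conflicting class for {key}: {existing!r} vs {class_id!r}")
        self.entries[key] = class_id
        self.class_labels.setdefault(class_id, class_id)

    def lookup(self, study_id: str, phenotype_name: str) -> str | None:
        return self.entries.get((study_id, phenotype_name))

    def classes(self) -> list[str]:
        return sorted(set(self.entries.values()))


@dataclass
class KnownAssociationCatalog:
    """Catalog of previously published SNP–trait links (snp, trait, PMID)."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, snp_id: str, trait_term: str, pmid: str = "") -> None:
        if not trait_term or not trait_term.strip():
            raise ValueError("trait_term must be non-empty")
        self.records.append((snp_id, trait_term, pmid))

    def traits_for(self, snp_id: str) -> list[str]:
        return [t for s, t, _ in self.records if s == snp_id]

    def snps(self) -> set[str]:
        return {s for s, _, _ in self.records}


@dataclass
class ClassGroup:
    """All results for one (SNP, phenotype-class, stratum) across studies.

    ``n_sites_significant`` counts distinct study *sites* (substudies collapse
    to their site) with at least one result below the significance threshold;
    ``flagged`` marks groups meeting the cross-study replication criterion.
    """

    snp_id: str
    class_id: str
    stratum: str
    results: list[AssociationResult] = field(default_factory=list)
    n_sites_available: int = 0
    n_sites_significant: int = 0
    flagged: bool = False
    consensus_direction: int = 0    # +1 / -1 / 0 (none)

    def __post_init__(self):
        if self.n_sites_significant > self.n_sites_available:
            raise ValueError(
                f"{self.snp_id}/{self.class_id}/{self.stratum}: significant "
                f"site count exceeds available site count")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.snp_id, self.class_id, self.stratum)


@dataclass
class ClassificationLabel:
    """known / related / novel label for a flagged group."""

    group: ClassGroup
    label: str
    supporting_catalog_terms: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in ("known", "related", "novel"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "known" and not self.supporting_catalog_terms:
            raise ValueError("label 'known' requires supporting catalog terms")


# ---------------------------------------------------------------------------
# Delimited-file readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing}", path, line=1)
    return df


def read_snp_registry(path: str | Path) -> list[SnpRecord]:
    df = _read_tsv(path, ["snp_id", "chrom", "pos", "coded_allele",
                          "other_allele"])
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.snp_id in seen:
            raise SchemaError(f"duplicate SNP id {row.snp_id}", path, i)
        seen.add(row.snp_id)
        try:
            records.append(SnpRecord(row.snp_id, str(row.chrom),
                                     int(row.pos), row.coded_allele,
                                     row.other_allele))
        except (TypeError, ValueError) as exc:
            raise SchemaError(str(exc), path, i) from exc
    return records


def write_snp_registry(records: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [(r.snp_id, r.chrom, r.pos, r.coded_allele, r.other_allele)
            for r in records]
    pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "coded_allele",
                                "other_allele"]
                 ).to_csv(path, sep="\t", index=False)


def _parse_polarity(raw, path, line) -> int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return 1
    text = str(raw).strip().lower()
    if text in ("", "1", "+1"):
        return 1
    if text == "-1":
        return -1
    if text == "none":
        return None
    raise SchemaError(f"polarity must be +1, -1 or none, got {raw!r}",
                      path, line)


def read_dictionary(path: str | Path) -> dict[str, PhenotypeDescriptor]:
    """Read a phenotype dictionary (study_id, phenotype_name, value_kind,
    units, polarity, class_id)."""
    df = _read_tsv(path, ["study_id", "phenotype_name", "value_kind"])
    out: dict[str, PhenotypeDescriptor] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = row.phenotype_name
        if name in out:
            raise SchemaError(f"duplicate phenotype name {name!r}", path, i)
        kind = row.value_kind
        if kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value_kind {kind!r} for {name!r}",
                              path, i)
        units = getattr(row, "units", "") or ""
        if isinstance(units, float) and math.isnan(units):
            units = ""
        polarity = _parse_polarity(getattr(row, "polarity", 1), path, i)
        class_id = getattr(row, "class_id", None)
        if isinstance(class_id, float) and math.isnan(class_id):
            class_id = None
        out[name] = PhenotypeDescriptor(row.study_id, name, kind, units,
                                        polarity, class_id)
    return out


def write_dictionary(descriptors: Iterable[PhenotypeDescriptor],
                     path: str | Path) -> None:
    rows = []
    for d in descriptors:
        pol = "none" if d.polarity is None else str(d.polarity)
        rows.append((d.study_id, d.name, d.value_kind, d.units, pol,
                     d.class_id or ""))
    pd.DataFrame(rows, columns=["study_id", "phenotype_name", "value_kind",
                                "units", "polarity", "class_id"]
                 ).to_csv(path, sep="\t", index=False)


def _numeric_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = _read_tsv(path, ["subject_id"])
    if df["subject_id"].duplicated().any():
        raise SchemaError(f"duplicate subject ids in {what} table", path)
    df = df.set_index("subject_id")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric value in {what} table: {exc}",
                          path) from exc


def read_study(genotype_path: str | Path,
               phenotype_path: str | Path,
               dictionary_path: str | Path,
               strata_path: str | Path,
               snp_path: str | Path,
               study_id: str | None = None) -> StudyDataset:
    """Read one study site from its five delimited tables.

    The genotype table is subjects × SNPs with additive dosages (0/1/2 or
    empty); ``snp_path`` is the coded-allele registry giving, for every
    genotype column, which allele the dosage counts.  Validation is strict:
    dimension mismatches, unknown value kinds and missing dictionary rows are
    hard errors with file context, never silent coercions.
    """
    snps = read_snp_registry(snp_path)
    dosages = _numeric_matrix(genotype_path, "genotype")
    phenotypes = _numeric_matrix(phenotype_path, "phenotype")
    dictionary = read_dictionary(dictionary_path)

    strata_df = _read_tsv(strata_path, ["subject_id", "stratum"])
    if strata_df["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject ids in strata table", strata_path)
    strata = strata_df.set_index("subject_id")["stratum"]

    subjects = list(dosages.index)
    if list(phenotypes.index) != subjects:
        raise SchemaError(
            "phenotype table subjects do not match genotype table",
            phenotype_path)
    if set(strata.index) != set(subjects):
        raise SchemaError("strata table subjects do not match genotype table",
                          strata_path)
    strata = strata.reindex(subjects)

    registry_ids = [s.snp_id for s in snps]
    geno_cols = list(dosages.columns)
    if set(geno_cols) - set(registry_ids):
        raise SchemaError(
            f"genotype columns absent from SNP registry: "
            f"{sorted(set(geno_cols) - set(registry_ids))[:5]}", genotype_path)
    snps = [s for s in snps if s.snp_id in set(geno_cols)]
    dosages = dosages[[s.snp_id for s in snps]]

    if study_id is None:
        ids = {d.study_id for d in dictionary.values()}
        if len(ids) != 1:
            raise SchemaError(
                f"cannot infer study_id from dictionary ({sorted(ids)}); "
                f"pass study_id explicitly", dictionary_path)
        study_id = ids.pop()

    return StudyDataset(study_id=study_id, subjects=subjects, strata=strata,
                        dosages=dosages, snps=snps, phenotypes=phenotypes,
                        dictionary=dictionary)


def read_vcf_dosages(vcf_path: str | Path,
                     snp_ids: Sequence[str] | None = None,
                     ) -> tuple[pd.DataFrame, list[SnpRecord]]:
    """Read additive dosages from a VCF (GT-based, diploid).

    The coded allele is the VCF ALT allele, so the dosage is the ALT-allele
    count per genotype; missing GT becomes NaN.  Multi-allelic sites are an
    error (split them upstream).  Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    wanted = set(snp_ids) if snp_ids is not None else None
    cols: dict[str, np.ndarray] = {}
    records: list[SnpRecord] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if wanted is not None and vid not in wanted:
            continue
        if len(var.ALT) != 1:
            raise SchemaError(
                f"multi-allelic site {vid} (ALT={var.ALT}); split before "
                f"loading", vcf_path)
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dose = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a = [x for x in gt[:-1] if x is not None and x >= 0]
            dose[i] = float(sum(1 for x in a if x == 1)) if len(a) == 2 \
                else np.nan
        cols[vid] = dose
        records.append(SnpRecord(vid, str(var.CHROM), int(var.POS),
                                 var.ALT[0], var.REF))
    frame = pd.DataFrame(cols, index=samples)
    return frame, records


# --- standardized result template ------------------------------------------

def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Convert result records to the standardized template DataFrame."""
    rows = [(r.study_id, r.stratum, r.snp_id, r.coded_allele, r.caf,
             r.phenotype_name, r.transform, r.model, r.beta, r.se, r.p, r.n)
            for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def frame_to_results(frame: pd.DataFrame) -> list[AssociationResult]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(AssociationResult(
            study_id=row.study_id, stratum=row.stratum, snp_id=row.snp_id,
            coded_allele=row.coded_allele, caf=float(row.caf),
            phenotype_name=row.phenotype_name, transform=row.transform,
            model=row.model, beta=float(row.beta), se=float(row.se),
            p=float(row.p), n=int(row.n)))
    return out


def write_results(results: Iterable[AssociationResult] | pd.DataFrame,
                  path: str | Path) -> None:
    """Write the standardized result template (lossless float round trip)."""
    frame = results if isinstance(results, pd.DataFrame) \
        else results_to_frame(results)
    frame = frame[RESULT_COLUMNS]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fields = [row.study_id, row.stratum, row.snp_id, row.coded_allele,
                      repr(float(row.caf)), row.phenotype_name, row.transform,
                      row.model, repr(float(row.beta)), repr(float(row.se)),
                      repr(float(row.p)), str(int(row.n))]
            fh.write("\t".join(fields) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a standardized result template into a DataFrame."""
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != RESULT_COLUMNS:
            raise SchemaError(
                f"unexpected result template header {header}", path, 1)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(RESULT_COLUMNS):
                raise SchemaError(
                    f"expected {len(RESULT_COLUMNS)} fields, got {len(parts)}",
                    path, lineno)
            try:
                rows.append((parts[0], parts[1], parts[2], parts[3],
                             float(parts[4]), parts[5], parts[6], parts[7],
                             float(parts[8]), float(parts[9]), float(parts[10]),
                             int(parts[11])))
            except ValueError as exc:
                raise SchemaError(f"malformed row: {exc}", path, lineno) \
                    from exc
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def read_class_map(path: str | Path) -> PhenotypeClassMap:
    """Read a phenotype→class map TSV (study_id, phenotype_name, class_id)."""
    df = _read_tsv(path, ["study_id", "phenotype_name", "class_id"])
    cmap = PhenotypeClassMap()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cmap.add(row.study_id, row.phenotype_name, row.class_id)
        except SchemaError as exc:
            raise SchemaError(str(exc), path, i) from exc
    return cmap


def write_class_map(cmap: PhenotypeClassMap, path: str | Path) -> None:
    rows = [(s, p, c) for (s, p), c in sorted(cmap.entries.items())]
    pd.DataFrame(rows, columns=["study_id", "phenotype_name", "class_id"]
                 ).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> KnownAssociationCatalog:
    """Read a known-association catalog TSV (snp_id, trait_term, pmid)."""
    df = _read_tsv(path, ["snp_id", "trait_term"])
    cat = KnownAssociationCatalog()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pmid = getattr(row, "pmid", "") or ""
        if isinstance(pmid, float) and math.isnan(pmid):
            pmid = ""
        try:
            cat.add(row.snp_id, row.trait_term, str(pmid))
        except ValueError as exc:
            raise SchemaError(str(exc), path, i) from exc
    return cat


def write_catalog(cat: KnownAssociationCatalog, path: str | Path) -> None:
    pd.DataFrame(cat.records, columns=["snp_id", "trait_term", "pmid"]
                 ).to_csv(path, sep="\t", index=False)
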