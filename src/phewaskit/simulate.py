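"""Synthetic multi-study PheWAS data with a ground-truth ledger.

Generates 2–5 study sites with differing sample sizes, overlapping SNP panels
drawn from one master registry, differing phenotype panels, one or more
race/ethnicity strata per site, and mixed continuous / binary / categorical
phenotypes — the statistical structure the downstream analysis assumes — so
every pipeline stage is testable without access to real cohort data.

Model
-----
* Genotypes: per-stratum Hardy–Weinberg, dosage ~ Binomial(2, MAF).  No
  linkage disequilibrium between SNPs (documented limitation).
* Continuous phenotypes: ``y = mean + sd·(√ρ·F_class + √(1−ρ)·ε) + Σ β·dosage``
  with one standard-normal factor F per (phenotype-class, subject), giving
  within-class equicorrelation ρ.
* Binary phenotypes: logistic model, ``logit P(y=1) = logit(prev) + Σ β·d``;
  planted log-odds are therefore directly recoverable by the analysis model.
* Categorical phenotypes: multinomial logits over k levels; a planted effect
  shifts the logit of level 1.
* Missingness: completely at random at configured genotype/phenotype rates.

All randomness flows from one master seed through per-study
``numpy.random.SeedSequence`` spawns, so identical configs give byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (KnownAssociationCatalog, PhenotypeClassMap,
                   PhenotypeDescriptor, SnpRecord, StudyDataset,
                   write_dictionary, write_snp_registry)
from .classify import ClassTraitMap

__all__ = [
    "PhenotypeSpec",
    "SnpSpec",
    "StudySpec",
    "EffectSpec",
    "SimulationConfig",
    "SimulationResult",
    "TruthTable",
    "simulate_studies",
    "default_config",
    "write_study_dir",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """Master-panel phenotype: distribution family plus class membership."""

    name: str
    value_kind: str               # continuous | binary | categorical
    class_id: str | None = None
    polarity: int | None = 1
    mean: float = 50.0            # continuous location
    sd: float = 10.0              # continuous scale (noise SD)
    prevalence: float = 0.3       # binary
    n_levels: int = 3             # categorical
    level_probs: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SnpSpec:
    """Registry entry plus per-stratum minor-allele frequency of the coded
    allele (a plain float applies to every stratum)."""

    record: SnpRecord
    maf: float | Mapping[str, float] = 0.25

    def maf_for(self, stratum: str) -> float:
        if isinstance(self.maf, Mapping):
            if stratum not in self.maf:
                raise ValueError(
                    f"{self.record.snp_id}: no MAF for stratum {stratum!r}")
            m = self.maf[stratum]
        else:
            m = self.maf
        if not (0.0 < m <= 0.5):
            raise ValueError(
                f"{self.record.snp_id}: MAF must be in (0, 0.5], got {m}")
        return float(m)


@dataclass(frozen=True)
class StudySpec:
    """One site: per-stratum sample sizes and its SNP/phenotype panels."""

    study_id: str
    strata: Mapping[str, int]     # stratum label -> sample size
    snp_ids: tuple[str, ...]
    phenotype_names: tuple[str, ...]


@dataclass(frozen=True)
class EffectSpec:
    """A planted genetic effect.

    ``target`` names either a master-panel phenotype or a phenotype-class (in
    which case the effect applies to every phenotype of that class, modelling
    pleiotropy at the class level).  ``stratum`` restricts the effect;
    ``None`` means all strata.  ``model`` is linear (beta on the phenotype
    scale) or logistic (beta on the log-odds scale).  ``known`` marks effects
    the generated known-association catalog should list.
    """

    snp_id: str
    target: str
    beta: float
    model: str = "linear"
    stratum: str | None = None
    known: bool = False


@dataclass
class TruthTable:
    """Ledger of planted (SNP, phenotype, stratum) effects for recovery
    tests; each planted effect appears exactly once."""

    records: pd.DataFrame         # snp_id, phenotype_name, stratum, true_beta, model
    class_map: PhenotypeClassMap


@dataclass
class SimulationConfig:
    seed: int
    snps: list[SnpSpec]
    phenotypes: list[PhenotypeSpec]
    studies: list[StudySpec]
    effects: list[EffectSpec] = field(default_factory=list)
    rho: float = 0.35             # within-class equicorrelation
    missing_genotype_rate: float = 0.02
    missing_phenotype_rate: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        for rate in (self.missing_genotype_rate, self.missing_phenotype_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("missingness rates must be in [0, 1)")
        for study in self.studies:
            for n in study.strata.values():
                if n < 1:
                    raise ValueError(
                        f"{study.study_id}: sample sizes must be >= 1")
        names = [p.name for p in self.phenotypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate master phenotype names")
        ids = [s.record.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate master SNP ids")


@dataclass
class SimulationResult:
    studies: list[StudyDataset]
    class_map: PhenotypeClassMap
    catalog: KnownAssociationCatalog
    class_trait_map: ClassTraitMap
    truth: TruthTable


def _resolve_effects(config: SimulationConfig
                     ) -> dict[str, list[tuple[str, float, str, str | None]]]:
    """Map phenotype name -> [(snp_id, beta, model, stratum), ...]."""
    by_class: dict[str, list[str]] = {}
    names = {p.name for p in config.phenotypes}
    for p in config.phenotypes:
        if p.class_id:
            by_class.setdefault(p.class_id, []).append(p.name)
    out: dict[str, list[tuple[str, float, str, str | None]]] = {}
    snp_ids = {s.record.snp_id for s in config.snps}
    for eff in config.effects:
        if eff.snp_id not in snp_ids:
            raise ValueError(f"effect SNP {eff.snp_id} not in master registry")
        if eff.target in names:
            targets = [eff.target]
        elif eff.target in by_class:
            targets = by_class[eff.target]
        else:
            raise ValueError(
                f"effect target {eff.target!r} matches no phenotype or "
                f"phenotype-class")
        for name in targets:
            out.setdefault(name, []).append(
                (eff.snp_id, eff.beta, eff.model, eff.stratum))
    return out


def _truth_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    effects = _resolve_effects(config)
    for name, lst in effects.items():
        for snp_id, beta, model, stratum in lst:
            rows.append((snp_id, name, stratum or "*", beta, model))
    frame = pd.DataFrame(
        rows, columns=["snp_id", "phenotype_name", "stratum", "true_beta",
                       "model"])
    if frame.duplicated(["snp_id", "phenotype_name", "stratum"]).any():
        raise ValueError("duplicate planted effects for one "
                         "(snp, phenotype, stratum)")
    return frame.sort_values(list(frame.columns)).reset_index(drop=True)


def _simulate_study(spec: StudySpec, config: SimulationConfig,
                    rng: np.random.Generator,
                    effects: Mapping[str, list]) -> StudyDataset:
    snp_specs = {s.record.snp_id: s for s in config.snps}
    pheno_specs = {p.name: p for p in config.phenotypes}
    for sid in spec.snp_ids:
        if sid not in snp_specs:
            raise ValueError(f"{spec.study_id}: SNP {sid} not in master "
                             f"registry")
    for name in spec.phenotype_names:
        if name not in pheno_specs:
            raise ValueError(f"{spec.study_id}: phenotype {name!r} not in "
                             f"master panel")

    subjects: list[str] = []
    strata_vals: list[str] = []
    dose_blocks: list[np.ndarray] = []
    pheno_blocks: list[np.ndarray] = []
    classes = sorted({pheno_specs[n].class_id for n in spec.phenotype_names
                      if pheno_specs[n].class_id})

    for stratum in sorted(spec.strata):
        n = int(spec.strata[stratum])
        subjects.extend(f"{spec.study_id}_{stratum}_{i:05d}"
                        for i in range(n))
        strata_vals.extend([stratum] * n)

        dose = np.empty((n, len(spec.snp_ids)))
        for j, sid in enumerate(spec.snp_ids):
            maf = snp_specs[sid].maf_for(stratum)
            dose[:, j] = rng.binomial(2, maf, size=n)
        dose_blocks.append(dose)

        factors = {c: rng.standard_normal(n) for c in classes}
        snp_col = {sid: j for j, sid in enumerate(spec.snp_ids)}
        pheno = np.empty((n, len(spec.phenotype_names)))
        for k, name in enumerate(spec.phenotype_names):
            ps = pheno_specs[name]
            genetic = np.zeros(n)
            for snp_id, beta, model, eff_stratum in effects.get(name, []):
                if eff_stratum is not None and eff_stratum != stratum:
                    continue
                if snp_id not in snp_col:
                    continue    # SNP not genotyped by this site
                genetic += beta * dose[:, snp_col[snp_id]]
            if ps.value_kind == "continuous":
                if ps.class_id and config.rho > 0:
                    noise = (math.sqrt(config.rho) * factors[ps.class_id]
                             + math.sqrt(1 - config.rho)
                             * rng.standard_normal(n))
                else:
                    noise = rng.standard_normal(n)
                pheno[:, k] = ps.mean + ps.sd * noise + genetic
            elif ps.value_kind == "binary":
                eta = math.log(ps.prevalence / (1 - ps.prevalence)) + genetic
                prob = 1.0 / (1.0 + np.exp(-eta))
                pheno[:, k] = rng.random(n) < prob
            elif ps.value_kind == "categorical":
                k_lev = ps.n_levels
                base = np.asarray(ps.level_probs if ps.level_probs
                                  else [1.0 / k_lev] * k_lev)
                logits = np.tile(np.log(base), (n, 1))
                logits[:, min(1, k_lev - 1)] += genetic
                expl = np.exp(logits - logits.max(axis=1, keepdims=True))
                probs = expl / expl.sum(axis=1, keepdims=True)
                u = rng.random(n)
                pheno[:, k] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            else:
                raise ValueError(f"unknown value_kind {ps.value_kind!r}")
        pheno_blocks.append(pheno)

    dosages = np.vstack(dose_blocks)
    phenos = np.vstack(pheno_blocks)
    if config.missing_genotype_rate > 0:
        dosages[rng.random(dosages.shape)
                < config.missing_genotype_rate] = np.nan
    if config.missing_phenotype_rate > 0:
        phenos[rng.random(phenos.shape)
               < config.missing_phenotype_rate] = np.nan

    dictionary = {}
    for name in spec.phenotype_names:
        ps = pheno_specs[name]
        dictionary[name] = PhenotypeDescriptor(
            study_id=spec.study_id, name=name, value_kind=ps.value_kind,
            units="", polarity=ps.polarity, class_id=ps.class_id)

    return StudyDataset(
        study_id=spec.study_id,
        subjects=subjects,
        strata=pd.Series(strata_vals, index=subjects, name="stratum"),
        dosages=pd.DataFrame(dosages, index=subjects,
                             columns=list(spec.snp_ids)),
        snps=[snp_specs[sid].record for sid in spec.snp_ids],
        phenotypes=pd.DataFrame(phenos, index=subjects,
                                columns=list(spec.phenotype_names)),
        dictionary=dictionary)


def simulate_studies(config: SimulationConfig) -> SimulationResult:
    """Generate all study sites plus the class map, catalog and truth ledger.

    The known-association catalog lists the class (or phenotype) of every
    effect marked ``known=True`` as a published trait for its SNP, and the
    class↔trait map records those as relation ``same`` — so planted "known"
    associations classify as known downstream.
    """
    effects = _resolve_effects(config)
    truth = _truth_frame(config)

    master_seq = np.random.SeedSequence(config.seed)
    children = master_seq.spawn(len(config.studies))
    studies = [
        _simulate_study(spec, config, np.random.default_rng(child), effects)
        for spec, child in zip(config.studies, children)]

    class_map = PhenotypeClassMap()
    pheno_by_name = {p.name: p for p in config.phenotypes}
    for study in config.studies:
        for name in study.phenotype_names:
            ps = pheno_by_name[name]
            if not ps.class_id:
                continue
            class_map.add(study.study_id, name, ps.class_id)
            if ps.value_kind == "categorical":
                # "A versus not A" bins emitted by the scan carry derived
                # names; map each to the parent phenotype's class
                for lev in range(ps.n_levels):
                    class_map.add(study.study_id, f"{name}={lev:g}",
                                  ps.class_id)

    catalog = KnownAssociationCatalog()
    ctm = ClassTraitMap()
    pheno_class = {p.name: p.class_id for p in config.phenotypes}
    for eff in config.effects:
        if not eff.known:
            continue
        trait = pheno_class.get(eff.target) or eff.target
        catalog.add(eff.snp_id, trait, pmid="0")
        ctm.add(trait, trait, "same")

    return SimulationResult(studies=studies, class_map=class_map,
                            catalog=catalog, class_trait_map=ctm,
                            truth=TruthTable(records=truth,
                                             class_map=class_map))


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T")]


def default_config(seed: int = 0, scale: float = 1.0) -> SimulationConfig:
    """Three heterogeneous study sites over a 45-SNP master registry.

    Site A resembles a large biracial cohort (EA 5,000 / AA 2,000), site B a
    smaller elderly cohort (EA 1,200 / AA 400), site C a large multiethnic
    cohort (EA 4,000 / AA 1,500 / H 800).  Panels overlap but differ: 40/28/34
    SNPs and 52/40/58 phenotypes drawn from a 60-phenotype master panel of 20
    phenotype-classes (60% continuous, 25% binary, 15% three-level
    categorical), within-class correlation ρ = 0.35, MCAR missingness 2%
    (genotype) / 5% (phenotype).  Planted effects: one pleiotropic SNP with
    linear effects in two classes (β = 2.0 raw units, i.e. roughly 0.15–0.4
    phenotype SDs per coded-allele copy), one catalogued lipid-like linear
    effect, one catalogued logistic effect (log-OR 0.25), and one
    stratum-specific effect.  ``scale`` multiplies all per-stratum sample
    sizes (floor 50) for quick test runs.
    """
    rng = np.random.default_rng(seed + 1_000_000)

    snps = []
    for i in range(45):
        coded, other = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        rec = SnpRecord(snp_id=f"rs{9000000 + i}",
                        chrom=str(rng.integers(1, 23)),
                        pos=int(rng.integers(1, 2.5e8)),
                        coded_allele=coded, other_allele=other)
        maf = {s: float(rng.uniform(0.08, 0.5)) for s in ("EA", "AA", "H")}
        snps.append(SnpSpec(record=rec, maf=maf))

    kinds = (["continuous"] * 6 + ["binary"] * 3 + ["categorical"]) * 6
    phenotypes = []
    for i in range(60):
        cls = f"Class{i % 20:02d}"
        kind = kinds[i]
        phenotypes.append(PhenotypeSpec(
            name=f"pheno_{i:03d}", value_kind=kind, class_id=cls,
            mean=float(rng.uniform(20, 120)), sd=float(rng.uniform(5, 15)),
            prevalence=float(rng.uniform(0.15, 0.45)), n_levels=3))

    def n(x):
        return max(50, int(round(x * scale)))

    all_snps = [s.record.snp_id for s in snps]
    all_phenos = [p.name for p in phenotypes]
    studies = [
        StudySpec("STUDY_A", {"EA": n(5000), "AA": n(2000)},
                  tuple(all_snps[:40]), tuple(all_phenos[:52])),
        StudySpec("STUDY_B", {"EA": n(1200), "AA": n(400)},
                  tuple(all_snps[10:38]), tuple(all_phenos[15:55])),
        StudySpec("STUDY_C", {"EA": n(4000), "AA": n(1500), "H": n(800)},
                  tuple(all_snps[5:39]), tuple(all_phenos[2:60])),
    ]

    # Planted effects.  Continuous-phenotype SDs are ~5-15 units, so a beta
    # of 0.25 SD-equivalents is expressed per phenotype through class-level
    # targeting; logistic betas are log-odds ratios typical of replicated
    # common-variant hits.
    effects = [
        # pleiotropic SNP: linear effects in two classes, all strata
        EffectSpec("rs9000011", "Class01", beta=2.0, model="linear"),
        EffectSpec("rs9000011", "Class03", beta=2.0, model="linear"),
        # a "known" lipid-like association
        EffectSpec("rs9000020", "Class05", beta=2.5, model="linear",
                   known=True),
        # binary outcome effect (log-odds per coded-allele copy)
        EffectSpec("rs9000025", "pheno_027", beta=0.25, model="logistic",
                   known=True),
        # stratum-specific effect (AA only)
        EffectSpec("rs9000030", "pheno_012", beta=2.0, model="linear",
                   stratum="AA"),
    ]

    return SimulationConfig(seed=seed, snps=snps, phenotypes=phenotypes,
                            studies=studies, effects=effects)


def write_study_dir(dataset: StudyDataset, out_dir: str | Path) -> None:
    """Write one study as the five documented TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_snp_registry(dataset.snps, out / "snps.tsv")
    write_dictionary(dataset.dictionary.values(), out / "dictionary.tsv")

    def fmt(x):
        return "" if (isinstance(x, float) and math.isnan(x)) else f"{x:g}"

    geno = dataset.dosages.map(fmt)
    geno.index.name = "subject_id"
    geno.to_csv(out / "genotypes.tsv", sep="\t")

    pheno = dataset.phenotypes.map(lambda x: "" if np.isnan(x) else repr(x))
    pheno.index.name = "subject_id"
    pheno.to_csv(out / "phenotypes.tsv", sep="\t")

    strata = dataset.strata.rename("stratum").to_frame()
    strata.index.name = "subject_id"
    strata.to_csv(out / "strata.tsv", sep="\t")


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML file (keys mirror the dataclass
    fields; see docs/methods.md for the schema)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    snps = [SnpSpec(record=SnpRecord(**{k: s[k] for k in
                                        ("snp_id", "chrom", "pos",
                                         "coded_allele", "other_allele")}),
                    maf=s.get("maf", 0.25))
            for s in raw["snps"]]
    phenotypes = [PhenotypeSpec(**p) for p in raw["phenotypes"]]
    studies = [StudySpec(study_id=s["study_id"], strata=s["strata"],
                         snp_ids=tuple(s["snp_ids"]),
                         phenotype_names=tuple(s["phenotype_names"]))
               for s in raw["studies"]]
    effects = [EffectSpec(**e) for e in raw.get("effects", [])]
    return SimulationConfig(
        seed=int(raw["seed"]), snps=snps, phenotypes=phenotypes,
        studies=studies, effects=effects,
        rho=float(raw.get("rho", 0.35)),
        missing_genotype_rate=float(raw.get("missing_genotype_rate", 0.02)),
        missing_phenotype_rate=float(raw.get("missing_phenotype_rate", 0.05)))
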