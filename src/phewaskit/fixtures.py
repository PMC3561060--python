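"""Curated worked-example data: published multi-study PheWAS results.

A small transcription of per-study association results for a handful of
well-replicated cardiovascular, lipid and hematologic SNPs across five large
US population-based cohorts (ARIC, CHS, WHI, EAGLE/NHANES, MEC), together
with the phenotype→class map, phenotype polarities, substudy→site map,
known-association catalog and class↔trait relations needed to push the rows
through replication and classification.  These rows drive the package's
worked examples and regression tests; they are inputs (printed summary
statistics), not outputs of this package.

The three LDL-cholesterol rows for rs4420638 are partially reconstructed:
their p-values, betas and studies are as published, but standard errors are
back-computed as |β|/Φ⁻¹(1−p/2) and sample sizes approximated from the same
studies' cholesterol panels (synthetic stand-ins; no downstream check uses
them).
"""

from __future__ import annotations


import pandas as pd
from scipy import stats

from .core import (KnownAssociationCatalog, PhenotypeClassMap, SnpRecord,
                   RESULT_COLUMNS)
from .classify import ClassTraitMap

__all__ = [
    "load_example_results",
    "example_registry",
    "example_class_map",
    "example_polarities",
    "example_site_map",
    "example_catalog",
    "example_class_trait_map",
]

# study, stratum, snp, coded allele, CAF, phenotype, transform, model,
# beta, se, p, n  — transcribed per-study rows, grouped by
# (SNP, phenotype-class, stratum).
_ROWS = [
    # --- rs599839 / ANGINA / EA (substudy count 3) ---
    ("ARIC", "EA", "rs599839", "A", 0.8, "Ever hospitalized for chest pain? (Y/N)", "none", "logistic", 0.55, 0.18, 2.57e-3, 568),
    ("CHS", "EA", "rs599839", "A", 0.8, "Angina status at baseline (Y/N)", "none", "logistic", 0.21, 0.08, 8.79e-3, 4482),
    ("WHI", "EA", "rs599839", "A", 0.8, "Angina (Y/N)", "none", "logistic", 0.25, 0.07, 2.10e-4, 13308),
    ("CHS", "EA", "rs599839", "A", 0.8, "Ever had pain/discomfort in your chest (Y/N)", "none", "logistic", 0.21, 0.05, 1.06e-4, 4477),
    # --- rs1333049 / ANGINA / EA (substudy count 3) ---
    ("ARIC", "EA", "rs1333049", "C", 0.5, "Chest pain or discomfort? (Y/N)", "none", "logistic", 0.08, 0.03, 4.69e-3, 9338),
    ("ARIC", "EA", "rs1333049", "C", 0.5, "See a doctor because of chest pain? (Y/N)", "none", "logistic", 0.32, 0.12, 8.80e-3, 572),
    ("CHS", "EA", "rs1333049", "C", 0.5, "Ever had pain/discomfort in your chest (Y/N)", "none", "logistic", 0.11, 0.04, 9.72e-3, 4472),
    ("WHI", "EA", "rs1333049", "C", 0.5, "Angina (Y/N)", "none", "logistic", 0.14, 0.05, 7.75e-3, 13331),
    # --- rs6511720 / Serum Cholesterol / EA (substudy count 2) ---
    ("ARIC", "EA", "rs6511720", "G", 0.9, "Total cholesterol (mmol/l)", "none", "linear", 0.18, 0.02, 6.84e-16, 10891),
    ("WHI", "EA", "rs6511720", "G", 0.9, "Total cholesterol (mg/dl)", "none", "linear", 12.05, 2.85, 2.64e-5, 924),
    ("ARIC", "EA", "rs6511720", "G", 0.9, "LN1 Total cholesterol (mmol/l)", "log1p", "linear", 0.03, 3.30e-3, 4.15e-17, 10891),
    ("WHI", "EA", "rs6511720", "G", 0.9, "High cholesterol requiring pills ever (Y/N)", "none", "logistic", 0.42, 0.06, 10.00e-12, 12431),
    ("WHI", "EA", "rs6511720", "G", 0.9, "LN1 Total cholesterol (mg/dl)", "log1p", "linear", 0.05, 0.01, 1.87e-5, 924),
    # --- rs10757278 / ANGINA / EA (substudy count 3; Rose angina polarity -1) ---
    ("CHS", "EA", "rs10757278", "A", 0.5, "Ever had pain/discomfort in your chest (Y/N)", "none", "logistic", -0.12, 0.04, 5.96e-3, 4474),
    ("WHI", "EA", "rs10757278", "A", 0.5, "Angina (Y/N)", "none", "logistic", -0.14, 0.05, 6.59e-3, 13313),
    ("ARIC", "EA", "rs10757278", "A", 0.5, "Chest pain or discomfort? (Y/N)", "none", "logistic", -0.07, 0.03, 9.73e-3, 11047),
    ("ARIC", "EA", "rs10757278", "A", 0.5, "See a doc because of chest pain? (Y/N)", "none", "logistic", -0.31, 0.11, 4.44e-3, 722),
    ("ARIC", "EA", "rs10757278", "A", 0.5, "Rose angina (Y/N)", "none", "logistic", 0.16, 0.06, 8.17e-3, 11040),
    # --- rs6548238 / Hypertension / AA (substudy count 2; "never hypertensive" polarity -1) ---
    ("ARIC", "AA", "rs6548238", "C", 0.9, "High blood pressure ever diagnosed?", "none", "logistic", 0.19, 0.07, 7.69e-3, 3946),
    ("WHI", "AA", "rs6548238", "C", 0.9, "Pills for hypertension now (Y/N)", "none", "logistic", 0.18, 0.07, 7.17e-3, 4122),
    ("WHI", "AA", "rs6548238", "C", 0.9, "Hypertension category: never hypertensive (Y/N)", "none", "logistic", -0.22, 0.07, 1.03e-3, 4076),
    ("WHI", "AA", "rs6548238", "C", 0.9, "Hypertension ever (Y/N)", "none", "logistic", 0.23, 0.07, 5.85e-4, 4206),
    ("WHI", "AA", "rs6548238", "C", 0.9, "Pills for hypertension ever (Y/N)", "none", "logistic", 0.19, 0.07, 6.30e-3, 4186),
    ("WHI", "AA", "rs6548238", "C", 0.9, "Hypertension category: treated hypertensive (Y/N)", "none", "logistic", 0.19, 0.07, 6.54e-3, 4076),
    # --- rs2228145 / White Blood Count / AA (substudy count 3; EAGLEIII is an EAGLE substudy) ---
    ("ARIC", "AA", "rs2228145", "A", 0.9, "White blood count", "none", "linear", -0.36, 0.06, 4.17e-8, 3806),
    ("EAGLEIII", "AA", "rs2228145", "A", 0.9, "White blood cell count", "none", "linear", -0.35, 0.10, 2.83e-4, 2038),
    ("CHS", "AA", "rs2228145", "A", 0.9, "LN1 white blood count (x1,000/cubic mm)", "log1p", "linear", -0.06, 0.02, 5.61e-4, 783),
    ("ARIC", "AA", "rs2228145", "A", 0.9, "LN1 white blood count", "log1p", "linear", -0.05, 8.70e-3, 8.42e-10, 3806),
    ("EAGLEIII", "AA", "rs2228145", "A", 0.9, "LN1 white blood cell count", "log1p", "linear", -0.04, 0.01, 3.57e-4, 2038),
    # --- rs4420638 / Serum Cholesterol / EA (substudy count 2) ---
    ("WHI", "EA", "rs4420638", "A", 0.8, "High cholesterol requiring pills ever (Y/N)", "none", "logistic", -0.22, 0.04, 1.18e-6, 12430),
    ("ARIC", "EA", "rs4420638", "A", 0.8, "Total cholesterol (mmol/l)", "none", "linear", -0.14, 0.02, 2.31e-12, 9323),
    ("ARIC", "EA", "rs4420638", "A", 0.8, "LN1 Total cholesterol (mmol/l)", "log1p", "linear", -0.02, 3.00e-3, 1.96e-13, 9323),
    # --- rs1333049 / Hemoglobin / AA (substudy count 2) ---
    ("EAGLEIII", "AA", "rs1333049", "C", 0.2, "Hemoglobin (g/dl)", "none", "linear", 0.15, 0.05, 5.40e-3, 2092),
    ("CHS", "AA", "rs1333049", "C", 0.2, "Hemoglobin (g/dl)", "none", "linear", 0.26, 0.10, 8.21e-3, 786),
    ("EAGLEIII", "AA", "rs1333049", "C", 0.2, "LN1 Hemoglobin (g/dl)", "log1p", "linear", 0.01, 3.95e-3, 4.07e-3, 2092),
]

# (study, beta, p, approx n): LDL-C rows with reconstructed SE / approximate n
_LDL_ROWS = [
    ("ARIC", -5.75, 1.27e-15, 9323),
    ("CHS", -7.06, 7.89e-12, 4469),
    ("WHI", -4.15, 0.06, 924),
]


def load_example_results() -> pd.DataFrame:
    """The transcribed per-study result rows as a standardized result frame."""
    rows = list(_ROWS)
    for study, beta, p, n in _LDL_ROWS:
        se = abs(beta) / stats.norm.isf(p / 2.0)
        rows.append((study, "EA", "rs4420638", "A", 0.8,
                     "LDL cholesterol (mg/dl)", "none", "linear",
                     beta, se, p, n))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def example_registry() -> dict[str, SnpRecord]:
    """Master coded-allele registry (GRCh37 positions) for the example SNPs."""
    records = [
        SnpRecord("rs599839", "1", 109822166, "A", "G"),
        SnpRecord("rs2228145", "1", 154426970, "A", "C"),
        SnpRecord("rs6548238", "2", 634905, "C", "T"),
        SnpRecord("rs1333049", "9", 22125503, "C", "G"),
        SnpRecord("rs10757278", "9", 22124477, "A", "G"),
        SnpRecord("rs6511720", "19", 11202306, "G", "T"),
        SnpRecord("rs4420638", "19", 45422946, "A", "G"),
    ]
    return {r.snp_id: r for r in records}


def example_class_map() -> PhenotypeClassMap:
    cmap = PhenotypeClassMap()
    class_of = {
        "Ever hospitalized for chest pain? (Y/N)": "ANGINA",
        "Angina status at baseline (Y/N)": "ANGINA",
        "Angina (Y/N)": "ANGINA",
        "Ever had pain/discomfort in your chest (Y/N)": "ANGINA",
        "Chest pain or discomfort? (Y/N)": "ANGINA",
        "See a doctor because of chest pain? (Y/N)": "ANGINA",
        "See a doc because of chest pain? (Y/N)": "ANGINA",
        "Rose angina (Y/N)": "ANGINA",
        "Total cholesterol (mmol/l)": "Serum Cholesterol",
        "Total cholesterol (mg/dl)": "Serum Cholesterol",
        "LN1 Total cholesterol (mmol/l)": "Serum Cholesterol",
        "LN1 Total cholesterol (mg/dl)": "Serum Cholesterol",
        "High cholesterol requiring pills ever (Y/N)": "Serum Cholesterol",
        "High blood pressure ever diagnosed?": "Hypertension",
        "Pills for hypertension now (Y/N)": "Hypertension",
        "Hypertension category: never hypertensive (Y/N)": "Hypertension",
        "Hypertension ever (Y/N)": "Hypertension",
        "Pills for hypertension ever (Y/N)": "Hypertension",
        "Hypertension category: treated hypertensive (Y/N)": "Hypertension",
        "White blood count": "White Blood Count",
        "White blood cell count": "White Blood Count",
        "LN1 white blood count (x1,000/cubic mm)": "White Blood Count",
        "LN1 white blood count": "White Blood Count",
        "LN1 white blood cell count": "White Blood Count",
        "Hemoglobin (g/dl)": "Hemoglobin",
        "LN1 Hemoglobin (g/dl)": "Hemoglobin",
        "LDL cholesterol (mg/dl)": "LDL-C",
    }
    frame = load_example_results()
    for row in frame.itertuples(index=False):
        cmap.add(row.study_id, row.phenotype_name,
                 class_of[row.phenotype_name])
    return cmap


def example_polarities() -> dict[tuple[str, str], int]:
    """Phenotype polarities: inverted items within their class."""
    return {
        ("ARIC", "Rose angina (Y/N)"): -1,
        ("WHI", "Hypertension category: never hypertensive (Y/N)"): -1,
    }


def example_site_map() -> dict[str, str]:
    """Substudy → study-site membership (replication counts sites)."""
    return {"EAGLEIII": "EAGLE"}


def example_catalog() -> KnownAssociationCatalog:
    """Previously published SNP–trait links for the example SNPs."""
    cat = KnownAssociationCatalog()
    for snp, trait, pmid in [
        ("rs599839", "LDL cholesterol", "18193043"),
        ("rs599839", "Coronary Artery Disease", "18262040"),
        ("rs599839", "Total cholesterol", "18193044"),
        ("rs1333049", "Coronary Artery Disease", "17554300"),
        ("rs1333049", "Type 2 Diabetes", "17634449"),
        ("rs1333049", "Hypertension", "17554300"),
        ("rs6511720", "LDL Cholesterol", "18193043"),
        ("rs10757278", "Myocardial infarction", "17478679"),
        ("rs6548238", "Body Mass Index", "19079261"),
        ("rs2228145", "C-reactive Protein", "20186139"),
        ("rs4420638", "LDL Cholesterol", "17474819"),
        ("rs4420638", "Total cholesterol", "19567438"),
        ("rs4420638", "Alzheimer's disease", "17463246"),
    ]:
        cat.add(snp, trait, pmid)
    return cat


def example_class_trait_map() -> ClassTraitMap:
    """Curated class↔catalog-trait relations for the example SNPs.

    The judgement of which published traits count as the "same" phenotype
    versus merely "related" is manual curation; the entries here reproduce
    the example groups' published labels.
    """
    ctm = ClassTraitMap()
    for cls, trait, rel in [
        ("ANGINA", "Coronary Artery Disease", "related"),
        ("ANGINA", "Myocardial infarction", "related"),
        ("Serum Cholesterol", "LDL Cholesterol", "related"),
        ("Serum Cholesterol", "Total cholesterol", "related"),
        ("LDL-C", "LDL Cholesterol", "same"),
        ("Hypertension", "Body Mass Index", "related"),
    ]:
        ctm.add(cls, trait, rel)
    return ctm
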