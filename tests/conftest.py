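import numpy as np
import pandas as pd
import pytest

from phewaskit import fixtures
from phewaskit.core import RESULT_COLUMNS
from phewaskit.simulate import (EffectSpec, PhenotypeSpec, SimulationConfig,
                                SnpSpec, StudySpec)
from phewaskit.core import SnpRecord


@pytest.fixture(scope="session")
def example_results():
    return fixtures.load_example_results()


@pytest.fixture(scope="session")
def example_effective():
    """The worked-example rows pushed through allele alignment and class
    assignment, ready for replication."""
    from phewaskit.harmonize import align_alleles, assign_classes

    aligned, _ = align_alleles(fixtures.load_example_results(),
                               fixtures.example_registry())
    return assign_classes(aligned, fixtures.example_class_map(),
                          fixtures.example_polarities(),
                          fixtures.example_site_map())


def make_snp(snp_id="rs1", chrom="1", pos=1000, coded="A", other="G",
             maf=0.3):
    return SnpSpec(record=SnpRecord(snp_id, chrom, pos, coded, other),
                   maf=maf)


def tiny_config(seed=0, n=300, n_studies=2, effects=(), rho=0.0,
                phenotypes=None, n_snps=3, missing=0.0, strata=("EA",)):
    """Small fully-specified simulation config for fast unit tests."""
    snps = [make_snp(f"rs{i+1}", pos=1000 * (i + 1), maf=0.3)
            for i in range(n_snps)]
    if phenotypes is None:
        phenotypes = [
            PhenotypeSpec("cont_a", "continuous", class_id="C1", mean=50,
                          sd=10),
            PhenotypeSpec("cont_b", "continuous", class_id="C1", mean=30,
                          sd=5),
            PhenotypeSpec("bin_a", "binary", class_id="C2", prevalence=0.4),
            PhenotypeSpec("cat_a", "categorical", class_id="C3", n_levels=3),
        ]
    names = tuple(p.name for p in phenotypes)
    snp_ids = tuple(s.record.snp_id for s in snps)
    studies = [StudySpec(f"S{i+1}", {s: n for s in strata}, snp_ids, names)
               for i in range(n_studies)]
    return SimulationConfig(seed=seed, snps=snps, phenotypes=phenotypes,
                            studies=studies, effects=list(effects), rho=rho,
                            missing_genotype_rate=missing,
                            missing_phenotype_rate=missing)


def make_result_row(**kw):
    row = dict(study_id="S1", stratum="EA", snp_id="rs1", coded_allele="A",
               caf=0.3, phenotype_name="pheno", transform="none",
               model="linear", beta=1.0, se=0.5, p=0.04, n=100)
    row.update(kw)
    return row


def make_effective_frame(rows):
    """Build a harmonized ('effective') result frame from row dicts; fills
    class/site/direction defaults from the result fields."""
    full = []
    for r in rows:
        base = make_result_row(**{k: v for k, v in r.items()
                                  if k in RESULT_COLUMNS})
        base["class_id"] = r.get("class_id", "C1")
        base["site_id"] = r.get("site_id", base["study_id"])
        base["effective_direction"] = r.get(
            "effective_direction", int(np.sign(base["beta"])))
        full.append(base)
    return pd.DataFrame(full)
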