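# phewaskit

Multi-study phenome-wide association scanning, cross-study replication, and
pleiotropy classification.

A **PheWAS** (phenome-wide association study) is the mirror image of a GWAS:
instead of testing many variants against one phenotype, it tests a panel of
SNPs against *every* available phenotype.  Run across several independent
epidemiologic cohorts, the design can both replicate known genotype–phenotype
associations and surface novel, potentially pleiotropic ones — but only after
solving the bookkeeping that multi-site analysis creates: each site has its
own sample, SNP panel, phenotype panel, phenotype naming, and allele coding.

`phewaskit` implements that pipeline end to end for consortium-style data:

1. **Association engine** — for every race/ethnicity stratum × SNP ×
   phenotype within one study: additive genetic model (dosage = 0/1/2 copies
   of the coded allele), OLS for continuous phenotypes on the raw scale and
   after a `log(1+y)` transform, logistic regression for binary phenotypes,
   and "A versus not A" binning with logistic fits for categorical
   phenotypes.  Two-sided t/Wald p-values; complete-case analysis with
   per-test coded-allele frequency (CAF) and sample size.
2. **Harmonization** — allele alignment onto a master registry (β negated
   and CAF complemented when a site coded the other allele), phenotype →
   phenotype-class assignment from a curated map, and effective direction of
   effect (sign(β) × phenotype polarity, so "never hypertensive" can agree
   with "hypertension ever").
3. **Replication** — a (SNP, phenotype-class, stratum) group is *flagged*
   when results with p < 0.01 come from ≥ 2 distinct study sites with a
   consistent effective direction.  Under the null with two sites this
   happens with probability p²/2 = 5×10⁻⁵.
4. **Classification** — flagged groups are labelled **known** / **related**
   / **novel** against a catalog of published SNP–trait links plus a curated
   class↔trait relation map.
5. **Visualization** — per-SNP radial *sun plots* (ray length = −log₁₀ p,
   clockwise from the most significant association) and cross-site *track
   plots* (presence boxes, p with direction glyphs, β, CAF, n).
6. **Synthetic data** — a multi-study generator (Hardy–Weinberg genotypes,
   within-class correlated phenotypes, planted single- and multi-class
   effects, MCAR missingness) with a ground-truth ledger, so every stage is
   testable without individual-level cohort data.

## Worked example

The package ships a transcription of published per-study results for a few
well-replicated SNPs (chest-pain/angina items for rs599839, white-blood-count
measures for rs2228145, cholesterol panels for rs6511720, among others)
across the ARIC, CHS, WHI and EAGLE cohorts:

```python
from phewaskit.pipeline import run_fixture_example
report = run_fixture_example()
print(report["groups"]["rs599839/ANGINA/EA"])
print(report["classification_summary"])
```

prints

```
{'substudy_count': 3, 'flagged': True, 'consensus_direction': 1}
{'known': 1, 'related': 6, 'novel': 2}
```

meaning: three distinct sites (ARIC, CHS, WHI) each had at least one
chest-pain phenotype associated with rs599839 at p < 0.01 in European
Americans with the same effective direction, so the group is flagged; and of
the nine flagged example groups, one replicates a published association
exactly (rs4420638 × LDL-C), six involve classes closely related to
published traits, and two (white blood count, hemoglobin) match nothing in
the catalog and are labelled novel.

The same stages run from the shell:

```bash
phewaskit simulate --seed 1 --out run/
phewaskit associate --study-dir run/studies/STUDY_A --out run/results_A.tsv
phewaskit harmonize --results run/results_A.tsv \
    --registry run/studies/STUDY_A/snps.tsv \
    --class-map run/class_map.tsv --out run/effective.tsv
phewaskit flag --results run/effective.tsv --groups-out run/groups.tsv
phewaskit run-all --seed 1 --out run_all/     # everything at once
```

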