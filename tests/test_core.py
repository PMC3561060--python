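"""Record types, validation, and delimited-file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phewaskit.core import (AssociationResult, ClassGroup,
                            PhenotypeDescriptor, SchemaError, SnpRecord,
                            RESULT_COLUMNS, frame_to_results, read_results,
                            read_study, read_vcf_dosages, results_to_frame,
                            write_results)
from phewaskit.simulate import write_study_dir, simulate_studies
from tests.conftest import tiny_config


# --- record invariants -----------------------------------------------------

def test_snp_record_rejects_identical_alleles():
    with pytest.raises(ValueError, match="coded and other"):
        SnpRecord("rs1", "1", 100, "A", "A")


@pytest.mark.parametrize("coded,other,ambiguous", [
    ("A", "T", True), ("C", "G", True), ("A", "G", False), ("C", "T", False),
])
def test_strand_ambiguity_flags_palindromic_pairs(coded, other, ambiguous):
    assert SnpRecord("rs1", "1", 1, coded, other).strand_ambiguous == ambiguous


def test_descriptor_rejects_unknown_kind_and_polarity():
    with pytest.raises(ValueError):
        PhenotypeDescriptor("S", "x", "ordinal")
    with pytest.raises(ValueError):
        PhenotypeDescriptor("S", "x", "binary", polarity=2)


@pytest.mark.parametrize("field,value", [
    ("p", 1.5), ("se", 0.0), ("caf", -0.1), ("transform", "sqrt"),
    ("model", "poisson"),
])
def test_association_result_invariants(field, value):
    kw = dict(study_id="S", stratum="EA", snp_id="rs1", coded_allele="A",
              caf=0.5, phenotype_name="x", transform="none", model="linear",
              beta=0.1, se=0.05, p=0.5, n=100)
    kw[field] = value
    with pytest.raises(ValueError):
        AssociationResult(**kw)


def test_class_group_rejects_more_significant_than_available_sites():
    with pytest.raises(ValueError):
        ClassGroup("rs1", "C1", "EA", n_sites_available=1,
                   n_sites_significant=2)


# --- study directory round trip --------------------------------------------

def _study_paths(d):
    return (d / "genotypes.tsv", d / "phenotypes.tsv", d / "dictionary.tsv",
            d / "strata.tsv", d / "snps.tsv")


def test_study_dir_round_trip_preserves_data(tmp_path):
    sim = simulate_studies(tiny_config(seed=3, n=40, n_studies=1,
                                       missing=0.1))
    ds = sim.studies[0]
    write_study_dir(ds, tmp_path)
    loaded = read_study(*_study_paths(tmp_path))
    assert loaded.study_id == ds.study_id
    assert loaded.subjects == ds.subjects
    assert list(loaded.strata) == list(ds.strata)
    np.testing.assert_array_equal(loaded.dosages.values, ds.dosages.values)
    np.testing.assert_allclose(loaded.phenotypes.values,
                               ds.phenotypes.values)
    assert loaded.snps == ds.snps
    assert loaded.dictionary == ds.dictionary


def test_read_study_rejects_phenotype_without_dictionary_row(tmp_path):
    sim = simulate_studies(tiny_config(seed=3, n=10, n_studies=1))
    write_study_dir(sim.studies[0], tmp_path)
    dict_path = tmp_path / "dictionary.tsv"
    lines = dict_path.read_text().splitlines()
    dict_path.write_text("\n".join(lines[:-1]) + "\n")  # drop one phenotype
    with pytest.raises(SchemaError, match="without dictionary"):
        read_study(*_study_paths(tmp_path))


def test_read_study_rejects_bad_dosage_value(tmp_path):
    sim = simulate_studies(tiny_config(seed=3, n=10, n_studies=1))
    write_study_dir(sim.studies[0], tmp_path)
    geno = tmp_path / "genotypes.tsv"
    lines = geno.read_text().splitlines()
    parts = lines[1].split("\t")
    parts[1] = "3"
    lines[1] = "\t".join(parts)
    geno.write_text("\n".join(lines) + "\n")
    with pytest.raises(SchemaError, match="dosages outside"):
        read_study(*_study_paths(tmp_path))


# --- standardized result template ------------------------------------------

_result_strategy = st.builds(
    AssociationResult,
    study_id=st.sampled_from(["ARIC", "CHS", "WHI"]),
    stratum=st.sampled_from(["EA", "AA", "H", "API"]),
    snp_id=st.from_regex(r"rs[0-9]{1,7}", fullmatch=True),
    coded_allele=st.sampled_from(list("ACGT")),
    caf=st.floats(0, 1, allow_nan=False),
    phenotype_name=st.text(
        st.characters(blacklist_characters="\t\n\r", min_codepoint=32,
                      blacklist_categories=("Cs",)),
        min_size=1, max_size=30),
    transform=st.sampled_from(["none", "log1p"]),
    model=st.sampled_from(["linear", "logistic"]),
    beta=st.floats(-50, 50, allow_nan=False),
    se=st.floats(1e-12, 100, allow_nan=False, exclude_min=True),
    p=st.floats(0, 1, allow_nan=False),
    n=st.integers(1, 100000),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(results=st.lists(_result_strategy, max_size=20))
def test_result_template_round_trip_is_identity(tmp_path_factory, results):
    """write_results ∘ read_results reproduces every field bit-for-bit."""
    path = tmp_path_factory.mktemp("rt") / "results.tsv"
    write_results(results, path)
    back = frame_to_results(read_results(path))
    assert back == results


def test_empty_result_list_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_results([], path)
    assert path.read_text().strip() == "\t".join(RESULT_COLUMNS)
    assert read_results(path).empty


def test_read_results_reports_malformed_row_number(tmp_path):
    path = tmp_path / "bad.tsv"
    write_results(frame_to_results(results_to_frame([])), path)
    with open(path, "a") as fh:
        fh.write("\t".join(["S", "EA", "rs1", "A", "x", "p", "none",
                            "linear", "1", "1", "0.5", "10"]) + "\n")
    with pytest.raises(SchemaError, match=":2"):
        read_results(path)


def test_example_fixture_has_four_angina_rows(example_results):
    """The packaged worked example carries the four per-study chest-pain
    results for rs599839 in European Americans."""
    sub = example_results[(example_results.snp_id == "rs599839")
                          & (example_results.stratum == "EA")]
    assert len(sub) == 4
    aric = sub[sub.study_id == "ARIC"].iloc[0]
    assert aric.phenotype_name == "Ever hospitalized for chest pain? (Y/N)"
    assert (aric.p, aric.beta, aric.n) == (2.57e-3, 0.55, 568)


# --- VCF input --------------------------------------------------------------

def _write_vcf(path, records, samples):
    head = ("##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n")
    body = "".join(
        f"{c}\t{p}\t{i}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        + "\n" for c, p, i, ref, alt, gts in records)
    path.write_text(head + body)


def test_vcf_alt_allele_counting_and_missing(tmp_path):
    path = tmp_path / "toy.vcf"
    _write_vcf(path, [("1", 100, "rs1", "A", "G",
                       ["0/0", "0/1", "1/1", "./."])],
               ["s1", "s2", "s3", "s4"])
    dose, recs = read_vcf_dosages(path)
    np.testing.assert_array_equal(dose["rs1"].values[:3], [0, 1, 2])
    assert np.isnan(dose["rs1"].values[3])
    assert recs[0].coded_allele == "G" and recs[0].other_allele == "A"


def test_vcf_multiallelic_site_is_an_error(tmp_path):
    path = tmp_path / "multi.vcf"
    _write_vcf(path, [("1", 100, "rs1", "A", "G,T", ["0/1", "1/2"])],
               ["s1", "s2"])
    with pytest.raises(SchemaError, match="multi-allelic"):
        read_vcf_dosages(path)


def test_vcf_dosages_match_naive_line_parser(tmp_path):
    """Dosages from the VCF reader equal per-site ALT counts computed by an
    independent text-level parse of the same file."""
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(20)]
    records = []
    for j in range(50):
        gts = []
        for _ in samples:
            if rng.random() < 0.05:
                gts.append("./.")
            else:
                gts.append(f"{rng.integers(0, 2)}/{rng.integers(0, 2)}")
        records.append(("2", 1000 + j, f"rs{j}", "C", "T", gts))
    path = tmp_path / "rand.vcf"
    _write_vcf(path, records, samples)

    dose, _ = read_vcf_dosages(path)

    expected = {}
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        vals = [float(g.count("1")) if "." not in g else np.nan
                for g in parts[9:]]
        expected[parts[2]] = vals
    for vid, vals in expected.items():
        np.testing.assert_array_equal(dose[vid].values, np.array(vals))
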