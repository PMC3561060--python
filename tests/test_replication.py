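"""Cross-study replication criterion, availability tabulation, and the
within-study Bonferroni comparison."""

import numpy as np
import pandas as pd
import pytest

from phewaskit.replication import (ReplicationConfig, bonferroni_report,
                                   group_and_flag, group_and_flag_frame,
                                   tabulate_by_availability)
from tests.conftest import make_effective_frame


def test_published_worked_example_substudy_counts(example_effective):
    """The transcribed per-study rows reproduce the published substudy
    counts: rs599839/ANGINA/EA = 3, rs2228145/White Blood Count/AA = 3,
    rs6511720/Serum Cholesterol/EA = 2, all flagged."""
    groups = {g.key: g for g in group_and_flag(example_effective)}
    expect = {
        ("rs599839", "ANGINA", "EA"): 3,
        ("rs2228145", "White Blood Count", "AA"): 3,
        ("rs6511720", "Serum Cholesterol", "EA"): 2,
    }
    for key, count in expect.items():
        g = groups[key]
        assert g.n_sites_significant == count
        assert g.flagged


def test_inverted_polarity_rescues_direction_consistency(example_effective):
    """rs10757278/ANGINA/EA mixes negative betas with the positively-coded
    'Rose angina' item; its −1 polarity keeps the group consistent."""
    groups = {g.key: g for g in group_and_flag(example_effective)}
    g = groups[("rs10757278", "ANGINA", "EA")]
    assert g.flagged and g.consensus_direction == -1
    betas = {r.phenotype_name: r.beta for r in g.results}
    assert betas["Rose angina (Y/N)"] > 0          # raw sign really differs


def test_direction_conflict_blocks_flag():
    frame = make_effective_frame([
        dict(study_id="A", p=0.005, beta=1.0),
        dict(study_id="B", p=0.005, beta=-1.0),
    ])
    [g] = group_and_flag(frame)
    assert g.n_sites_significant == 2
    assert not g.flagged
    assert g.consensus_direction == 0
    # without the direction requirement the same group flags
    [g2] = group_and_flag(frame, config=ReplicationConfig(
        require_direction=False))
    assert g2.flagged


def test_single_site_never_flags_no_matter_how_significant():
    frame = make_effective_frame([
        dict(study_id="A", p=1e-20, beta=1.0),
        dict(study_id="A", p=1e-8, beta=1.0, phenotype_name="other"),
    ])
    [g] = group_and_flag(frame)
    assert g.n_sites_significant == 1
    assert not g.flagged


def test_multiple_substudies_of_one_site_count_once():
    frame = make_effective_frame([
        dict(study_id="EAGLEII", site_id="EAGLE", p=0.001, beta=1.0),
        dict(study_id="EAGLEIII", site_id="EAGLE", p=0.002, beta=1.0),
    ])
    [g] = group_and_flag(frame)
    assert g.n_sites_significant == 1
    assert not g.flagged


def test_above_threshold_results_never_veto_direction():
    """Consistency binds only to sub-threshold results; a discordant
    non-significant result does not block the flag."""
    frame = make_effective_frame([
        dict(study_id="A", p=0.003, beta=1.0),
        dict(study_id="B", p=0.004, beta=1.0),
        dict(study_id="C", p=0.5, beta=-1.0),
    ])
    [g] = group_and_flag(frame)
    assert g.flagged and g.consensus_direction == 1


def test_direction_none_counts_toward_sites_but_not_direction():
    frame = make_effective_frame([
        dict(study_id="A", p=0.003, beta=1.0, effective_direction=0),
        dict(study_id="B", p=0.004, beta=-1.0),
    ])
    [g] = group_and_flag(frame)
    assert g.n_sites_significant == 2
    assert g.flagged and g.consensus_direction == -1


def test_unclassed_results_are_excluded_and_audited():
    frame = make_effective_frame([
        dict(study_id="A", p=0.001, beta=1.0, class_id=""),
        dict(study_id="B", p=0.001, beta=1.0),
    ])
    groups, audit = group_and_flag_frame(frame)
    assert audit["n_excluded_unclassed"] == 1
    assert len(groups) == 1 and not groups["flagged"].any()


def test_availability_table_from_explicit_input():
    frame = make_effective_frame([
        dict(study_id="A", p=0.001, beta=1.0),
        dict(study_id="B", p=0.002, beta=1.0),
    ])
    avail = pd.DataFrame({
        "snp_id": ["rs1"] * 4, "class_id": ["C1"] * 4,
        "stratum": ["EA"] * 4, "site_id": ["A", "B", "C", "D"]})
    [g] = group_and_flag(frame, availability=avail)
    assert g.n_sites_available == 4
    assert g.n_sites_significant == 2


def test_flag_threshold_monotonicity():
    """Lowering p_threshold never flags a previously unflagged group under
    the site-count criterion, and raising min_sites never grows the flagged
    set.  (With the direction requirement on, a stricter threshold can
    additionally rescue a group by dropping its only discordant sub-threshold
    result — consistency binds to sub-threshold results only — so the exact
    monotonicity statement is about the site-count criterion.)"""
    rng = np.random.default_rng(21)
    rows = []
    for gi in range(300):
        for site in "ABC":
            rows.append(dict(study_id=site, snp_id=f"rs{gi}",
                             p=float(rng.uniform(0, 0.05)),
                             beta=float(rng.choice([-1.0, 1.0]))))
    frame = make_effective_frame(rows)

    def flagged_keys(p_thr, min_sites=2, direction=True):
        groups, _ = group_and_flag_frame(frame, config=ReplicationConfig(
            p_threshold=p_thr, min_sites=min_sites,
            require_direction=direction))
        return set(groups.loc[groups.flagged, "snp_id"])

    loose = flagged_keys(0.02, direction=False)
    assert flagged_keys(0.005, direction=False) <= loose
    assert flagged_keys(0.02, min_sites=3, direction=False) <= loose
    # with direction on, the site-count requirement still binds
    assert flagged_keys(0.02) <= loose
    assert flagged_keys(0.02, min_sites=3) <= flagged_keys(0.02)


def test_null_flag_rate_matches_analytic_two_site_probability():
    """Two independent two-sided null tests per group: P(flag) = p²/2.
    Quick version at 200,000 groups and p=0.05 (rate 1.25e-3)."""
    rng = np.random.default_rng(22)
    n_groups = 200_000
    p_thr = 0.05
    frame = pd.DataFrame({
        "snp_id": np.repeat([f"g{i}" for i in range(n_groups)], 2),
        "class_id": "C", "stratum": "EA",
        "site_id": np.tile(["A", "B"], n_groups),
        "p": rng.uniform(size=2 * n_groups),
        "effective_direction": rng.choice([-1, 1], size=2 * n_groups),
    })
    groups, _ = group_and_flag_frame(frame, config=ReplicationConfig(
        p_threshold=p_thr))
    rate = groups["flagged"].mean()
    target = p_thr ** 2 / 2
    band = 2.576 * np.sqrt(target * (1 - target) / n_groups)
    assert abs(rate - target) < band


# --- availability tabulation ------------------------------------------------

def test_tabulation_partitions_groups():
    frame = pd.DataFrame({
        "n_sites_available": [2, 2, 3],
        "flagged": [True, False, False]})
    table = tabulate_by_availability(frame)
    assert table.values.tolist() == [["2", 2, 1], ["3", 1, 0],
                                     ["Total", 3, 1]]


def test_tabulation_of_empty_input_is_all_zero():
    table = tabulate_by_availability([])
    assert table.values.tolist() == [["Total", 0, 0]]


def test_tabulation_accepts_class_group_records(example_effective):
    groups = group_and_flag(example_effective)
    table = tabulate_by_availability(groups)
    total = table[table.n_sites_available == "Total"]
    assert int(total.n_groups_total.iloc[0]) == len(groups)
    body = table[table.n_sites_available != "Total"]
    assert body.n_groups_total.sum() == len(groups)


# --- Bonferroni comparison --------------------------------------------------

def test_bonferroni_threshold_and_survivors():
    frame = make_effective_frame(
        [dict(study_id="S1", phenotype_name=f"p{i}",
              p=0.4 if i else 1e-5) for i in range(100)])
    report = bonferroni_report(frame, alpha=0.05)
    row = report.iloc[0]
    assert row.bonferroni_threshold == pytest.approx(5e-4)
    assert row.n_surviving == 1
    assert bonferroni_report(frame.iloc[:0]).empty


def test_bonferroni_null_survivor_count_near_alpha():
    rng = np.random.default_rng(23)
    survivors = []
    for _ in range(40):
        frame = pd.DataFrame({"study_id": "S", "p": rng.uniform(size=10_000)})
        survivors.append(bonferroni_report(frame).n_surviving.iloc[0])
    assert np.mean(survivors) == pytest.approx(0.05, abs=0.15)
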