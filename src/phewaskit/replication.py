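"""Cross-study replication criterion and availability tabulation.

A (SNP, phenotype-class, stratum) group is *flagged* when results below the
significance threshold (default p < 0.01) come from at least ``min_sites``
(default 2) distinct study sites and, when direction checking is on, every
sub-threshold result with a phenotypically relevant direction shares one
effective sign.  Direction consistency is evaluated only among sub-threshold
results: results above the threshold never veto a flag.  Multiple significant
phenotypes within one site count once toward the site tally (the "substudy
count" is per site, not per phenotype).

Under the global null with two independent two-sided tests per group, the
probability a group is flagged is p²/2 (both below threshold, independent
signs agreeing) — the calibration target of the Monte-Carlo suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ClassGroup, frame_to_results
from .harmonize import EFFECTIVE_COLUMNS

__all__ = [
    "ReplicationConfig",
    "group_and_flag",
    "group_and_flag_frame",
    "groups_to_records",
    "tabulate_by_availability",
    "bonferroni_report",
]


@dataclass(frozen=True)
class ReplicationConfig:
    """p_threshold, minimum distinct sites, and the direction requirement."""

    p_threshold: float = 0.01
    min_sites: int = 2
    require_direction: bool = True

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_sites < 2:
            raise ValueError("min_sites must be >= 2")


def group_and_flag_frame(effective_results: pd.DataFrame,
                         availability: pd.DataFrame | None = None,
                         config: ReplicationConfig | None = None,
                         ) -> tuple[pd.DataFrame, dict]:
    """Vectorized grouping/flagging on a harmonized result frame.

    ``effective_results`` needs columns snp_id, class_id, stratum, site_id,
    p and effective_direction (see ``harmonize.assign_classes``).  Results
    with an empty class_id are excluded and counted in the audit dict.
    ``availability`` (optional) lists one row per (snp_id, class_id, stratum,
    site_id) where both the SNP was genotyped and at least one class phenotype
    measured; without it, availability defaults to the sites observed among
    the group's results.

    Returns ``(groups, audit)`` with one group row per (snp_id, class_id,
    stratum): n_results, n_sites_available, n_sites_significant,
    direction_consistent, consensus_direction, flagged.
    """
    config = config or ReplicationConfig()
    frame = effective_results
    missing = [c for c in ("snp_id", "class_id", "stratum", "site_id", "p",
                           "effective_direction") if c not in frame.columns]
    if missing:
        raise ValueError(f"effective result frame lacks column(s) {missing}")

    has_class = frame["class_id"].astype(str) != ""
    audit = {"n_excluded_unclassed": int((~has_class).sum())}
    frame = frame[has_class]

    keys = ["snp_id", "class_id", "stratum"]
    sig = frame["p"] < config.p_threshold
    direc = frame["effective_direction"].to_numpy()

    work = frame[keys + ["site_id"]].copy()
    work["sig"] = sig.to_numpy()
    work["sig_site"] = work["site_id"].where(work["sig"])
    # direction bookkeeping restricted to sub-threshold, direction-relevant rows
    rel = work["sig"] & (direc != 0)
    work["dir_pos"] = rel & (direc > 0)
    work["dir_neg"] = rel & (direc < 0)

    grouped = work.groupby(keys, sort=True)
    agg = grouped.agg(
        n_results=("site_id", "size"),
        n_sites_observed=("site_id", "nunique"),
        n_sites_significant=("sig_site", "nunique"),
        n_dir_pos=("dir_pos", "sum"),
        n_dir_neg=("dir_neg", "sum"),
    ).reset_index()

    if availability is not None:
        need = {"snp_id", "class_id", "stratum", "site_id"}
        if not need.issubset(availability.columns):
            raise ValueError(
                f"availability table needs columns {sorted(need)}")
        avail = (availability.groupby(keys)["site_id"].nunique()
                 .rename("n_sites_available").reset_index())
        agg = agg.merge(avail, on=keys, how="left")
        agg["n_sites_available"] = (
            agg["n_sites_available"].fillna(agg["n_sites_observed"])
            .astype(int))
        agg["n_sites_available"] = np.maximum(agg["n_sites_available"],
                                              agg["n_sites_observed"])
    else:
        agg["n_sites_available"] = agg["n_sites_observed"]

    consistent = (agg["n_dir_pos"] == 0) | (agg["n_dir_neg"] == 0)
    agg["direction_consistent"] = consistent
    agg["consensus_direction"] = np.where(
        consistent & (agg["n_dir_pos"] > 0), 1,
        np.where(consistent & (agg["n_dir_neg"] > 0), -1, 0))
    flagged = agg["n_sites_significant"] >= config.min_sites
    if config.require_direction:
        flagged &= consistent
    agg["flagged"] = flagged
    agg = agg.drop(columns=["n_dir_pos", "n_dir_neg", "n_sites_observed"])
    return agg, audit


def group_and_flag(effective_results,
                   availability: pd.DataFrame | None = None,
                   config: ReplicationConfig | None = None,
                   ) -> list[ClassGroup]:
    """Group harmonized results and apply the replication criterion.

    Accepts the harmonized frame from ``assign_classes`` (after
    ``align_alleles``).  Returns one ClassGroup per (SNP, class, stratum),
    with per-group member results attached.  This is a thin record-building
    wrapper over ``group_and_flag_frame``, which bulk callers use directly.
    """
    frame = effective_results
    agg, _audit = group_and_flag_frame(frame, availability, config)

    has_class = frame["class_id"].astype(str) != ""
    members: dict[tuple, list] = {}
    classed = frame[has_class]
    from .core import RESULT_COLUMNS
    result_records = frame_to_results(classed[RESULT_COLUMNS])
    for rec, key in zip(result_records,
                        zip(classed["snp_id"], classed["class_id"],
                            classed["stratum"])):
        members.setdefault(key, []).append(rec)

    groups = []
    for row in agg.itertuples(index=False):
        key = (row.snp_id, row.class_id, row.stratum)
        groups.append(ClassGroup(
            snp_id=row.snp_id, class_id=row.class_id, stratum=row.stratum,
            results=members.get(key, []),
            n_sites_available=int(row.n_sites_available),
            n_sites_significant=int(row.n_sites_significant),
            flagged=bool(row.flagged),
            consensus_direction=int(row.consensus_direction)))
    return groups


def groups_to_records(groups_frame: pd.DataFrame) -> pd.DataFrame:
    """Stable column subset of a groups frame for writing groups.tsv."""
    cols = ["snp_id", "class_id", "stratum", "n_results",
            "n_sites_available", "n_sites_significant",
            "direction_consistent", "consensus_direction", "flagged"]
    return groups_frame[cols]


def tabulate_by_availability(groups) -> pd.DataFrame:
    """Tabulate groups by the number of sites where SNP and class overlapped.

    One row per availability count with the number of groups and the number
    flagged, plus a Total row; the rows partition the groups.
    """
    if isinstance(groups, pd.DataFrame):
        avail = groups["n_sites_available"].to_numpy()
        flagged = groups["flagged"].to_numpy()
    else:
        avail = np.array([g.n_sites_available for g in groups], dtype=int)
        flagged = np.array([g.flagged for g in groups], dtype=bool)
    if avail.size == 0:
        return pd.DataFrame(
            [["Total", 0, 0]],
            columns=["n_sites_available", "n_groups_total",
                     "n_groups_flagged"])
    rows = []
    for level in sorted(np.unique(avail)):
        sel = avail == level
        rows.append([str(level), int(sel.sum()), int(flagged[sel].sum())])
    rows.append(["Total", int(avail.size), int(flagged.sum())])
    return pd.DataFrame(rows, columns=["n_sites_available", "n_groups_total",
                                       "n_groups_flagged"])


def bonferroni_report(results, alpha: float = 0.05) -> pd.DataFrame:
    """Per-study Bonferroni threshold (α / #tests) and surviving-test counts.

    Provided as the within-study multiple-testing comparison to the
    cross-study replication criterion; it ignores correlation between
    phenotypes, which is why the pipeline does not use it for discovery.
    """
    if not isinstance(results, pd.DataFrame):
        from .core import results_to_frame
        results = results_to_frame(results)
    rows = []
    for study, sub in results.groupby("study_id", sort=True):
        n_tests = len(sub)
        thr = alpha / n_tests
        rows.append([study, n_tests, thr, int((sub["p"] < thr).sum())])
    return pd.DataFrame(rows, columns=["study_id", "n_tests",
                                       "bonferroni_threshold", "n_surviving"])
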