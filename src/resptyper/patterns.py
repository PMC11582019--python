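"""Cross-treatment response-type patterns, succession groups, and roll-ups.

A response-type *pattern* is the ordered 4-tuple of an ASV's types over the
canonical treatment order (-A/-M, -A/+M, +A/-M, +A/+M). Patterns are ranked
by the summed median abundance of their member ASVs. ASVs susceptible to
grazing alone (decline under +A/-M but not in either -A arm) split into
succession groups by their behaviour under combined grazing + litter:
group I keeps declining (type A), group II peaks at day 4 (type D),
group III peaks at day 8 (type E).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CANONICAL_TREATMENTS, StudyDesign, samples_for_cell, treatment_flags
from .errors import IncompleteAssignmentError

DECLINE_TYPES = ("A", "B")  # abundance decline within the first 8 days
SUCCESSION_BY_COMBINED = {"A": "I", "D": "II", "E": "III"}


def assemble_patterns(assignments: pd.DataFrame, abund: pd.DataFrame) -> pd.DataFrame:
    """One pattern row per ASV: the 4 types in canonical treatment order plus
    the ASV's median (and mean) absolute abundance over all samples."""
    wide = assignments.pivot(index="asv_id", columns="treatment",
                             values="response_type")
    missing_cols = [t for t in CANONICAL_TREATMENTS if t not in wide.columns]
    if missing_cols or wide.isna().any().any():
        bad = missing_cols or sorted(
            wide.index[wide.isna().any(axis=1)].tolist())
        raise IncompleteAssignmentError(
            f"assignments do not cover all 4 treatments: {bad}")
    wide = wide[list(CANONICAL_TREATMENTS)]
    med = abund.loc[wide.index].median(axis=1)
    mean = abund.loc[wide.index].mean(axis=1)
    out = wide.copy()
    out["median_abundance"] = med
    out["mean_abundance"] = mean
    out.index.name = "asv_id"
    return out.sort_index()


def pattern_tuple(row) -> tuple[str, ...]:
    return tuple(row[t] for t in CANONICAL_TREATMENTS)


def rank_patterns(patterns: pd.DataFrame, coverage: float = 0.80
                  ) -> tuple[pd.DataFrame, float]:
    """Group ASVs by identical type tuples and keep the top patterns.

    Groups are scored by the summed median abundance of their members,
    sorted descending (ties broken by lexicographic tuple order); the
    shortest prefix whose cumulative score reaches ``coverage`` of the total
    is returned together with the achieved coverage.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    grp = patterns.groupby(list(CANONICAL_TREATMENTS), sort=False).agg(
        n_asvs=("median_abundance", "size"),
        summed_median_abundance=("median_abundance", "sum"),
    ).reset_index()
    grp["_tuple"] = grp[list(CANONICAL_TREATMENTS)].apply(tuple, axis=1)
    grp = grp.sort_values(
        by=["summed_median_abundance", "_tuple"],
        ascending=[False, True], kind="mergesort").reset_index(drop=True)
    total = float(grp["summed_median_abundance"].sum())
    if total <= 0:
        return grp.drop(columns="_tuple").iloc[:0], 0.0
    cum = grp["summed_median_abundance"].cumsum() / total
    n_sel = int(np.searchsorted(cum.to_numpy(), coverage * (1 - 1e-12)) + 1)
    sel = grp.iloc[:n_sel].drop(columns="_tuple").reset_index(drop=True)
    return sel, float(cum.iloc[n_sel - 1])


def succession_groups(patterns: pd.DataFrame) -> pd.DataFrame:
    """Succession group per ASV.

    An ASV is *eligible* (grazing-susceptible) when it declines under
    grazing alone but not without grazing: type(+A/-M) in {A, B} and
    neither -A arm in {A, B}. Eligible ASVs are grouped by their +A/+M
    type: A -> I, D -> II, E -> III; anything else (B, C, STABLE) stays
    NONE even when eligible.
    """
    rows = []
    for asv, row in patterns.iterrows():
        eligible = (row["+A/-M"] in DECLINE_TYPES
                    and row["-A/+M"] not in DECLINE_TYPES
                    and row["-A/-M"] not in DECLINE_TYPES)
        group = SUCCESSION_BY_COMBINED.get(row["+A/+M"], "NONE") if eligible else "NONE"
        rows.append((asv, group, eligible))
    out = pd.DataFrame(rows, columns=["asv_id", "group", "eligible"])
    return out.set_index("asv_id").sort_index()


def rollup_by_taxon(
    assignments: pd.DataFrame,
    taxonomy: pd.DataFrame,
    abund: pd.DataFrame,
    rank: str = "display_family",
) -> pd.DataFrame:
    """Summed median abundance per (taxon group x response type x treatment).

    Medians are computed per ASV over all samples and summed within groups;
    the grand total therefore equals the sum of the per-ASV medians.
    """
    med = abund.median(axis=1)
    df = assignments[["asv_id", "treatment", "response_type"]].copy()
    df["taxon"] = taxonomy.loc[df["asv_id"], rank].to_numpy()
    df["median_abundance"] = med.loc[df["asv_id"]].to_numpy()
    out = (df.groupby(["taxon", "response_type", "treatment"])["median_abundance"]
             .sum().rename("summed_median_abundance").reset_index())
    return out.sort_values(["taxon", "response_type", "treatment"]).reset_index(drop=True)


def type_contribution(
    assignments: pd.DataFrame,
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
) -> pd.DataFrame:
    """Contribution of each response type to total abundance over time.

    Per treatment and day, the replicate-mean abundance of every assigned
    ASV is summed within its response type (STABLE is its own stratum), so
    the strata partition the summed abundance of all assigned ASVs.
    """
    rows = []
    for treat in CANONICAL_TREATMENTS:
        maize, nematode = treatment_flags(treat)
        sub = assignments[assignments["treatment"] == treat]
        by_type = sub.groupby("response_type")["asv_id"].apply(list)
        for day in design.days:
            ids = samples_for_cell(meta, maize, nematode, day)
            day_mean = abund[ids].mean(axis=1)
            for rtype, asvs in by_type.items():
                rows.append((treat, day, rtype, float(day_mean.loc[asvs].sum())))
    out = pd.DataFrame(rows, columns=["treatment", "day", "response_type",
                                      "summed_abundance"])
    return out.sort_values(["treatment", "day", "response_type"]).reset_index(drop=True)
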