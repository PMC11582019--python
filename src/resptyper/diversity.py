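"""Absolute-abundance transform, Hill numbers, and the ASV selection cascade.

Selection of "dominant responsive" ASVs proceeds in three filters:

1. **dominance** — an ASV must rank among the effective number of dominant
   taxa (Hill number 2D, the inverse Simpson index) in at least one sample;
2. **prevalence** — it must be detected (>= 1 read) in at least 2 of 3
   replicates at every timepoint of every treatment combination;
3. **responsiveness (Pareto)** — ranked by the sum over treatments of its
   trajectory range (max - min of the replicate-mean abundance over days),
   the shortest prefix of ASVs covering 80% of the total summed range is
   retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign, cell_iter, samples_for_cell, treatment_label
from .errors import DesignError, NormalizationError, ZeroDepthError


def to_absolute(counts: pd.DataFrame, qpcr: pd.Series) -> pd.DataFrame:
    """Scale read counts to absolute abundances (copies per g dry soil).

    Each sample's relative read proportions are multiplied by its
    qPCR-measured total 16S copy number, so every column sums to its total.
    """
    missing = sorted(set(counts.columns) - set(qpcr.index))
    if missing:
        raise ZeroDepthError(f"samples without qPCR totals: {missing}")
    depth = counts.sum(axis=0)
    zero = depth.index[depth == 0].tolist()
    if zero:
        raise ZeroDepthError(f"samples with zero total reads: {zero}")
    return counts / depth * qpcr.loc[counts.columns]


def hill_number(p, q: int) -> float:
    """Effective number of taxa of order q from a relative-abundance vector.

    q=0 counts present taxa (richness), q=1 is the exponential of Shannon
    entropy ("abundant" taxa), q=2 the inverse Simpson index ("dominant"
    taxa).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise NormalizationError("relative abundances must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise NormalizationError(f"relative abundances sum to {p.sum()}, not 1")
    nz = p[p > 0]
    if q == 0:
        return float(nz.size)
    if q == 1:
        return float(np.exp(-(nz * np.log(nz)).sum()))
    if q == 2:
        return float(1.0 / (nz ** 2).sum())
    raise ValueError("q must be 0, 1 or 2")


def hill_triple(p) -> tuple[float, float, float]:
    """(0D, 1D, 2D) for one composition; always 0D >= 1D >= 2D."""
    return hill_number(p, 0), hill_number(p, 1), hill_number(p, 2)


def select_dominant_asvs(abund: pd.DataFrame) -> set[str]:
    """ASVs that are dominant in at least one sample.

    Per sample, the effective number of dominant taxa n_dom = round-half-up
    of that sample's 2D (minimum 1); the sample's dominant set is its n_dom
    most abundant ASVs (ties broken by lexicographic ASV id). The union over
    samples is returned.
    """
    if abund.shape[0] == 0 or abund.shape[1] == 0:
        raise ZeroDepthError("empty abundance table")
    out: set[str] = set()
    for sample in abund.columns:
        col = abund[sample]
        total = col.sum()
        if total <= 0:
            raise ZeroDepthError(f"sample {sample} has zero total abundance")
        d2 = hill_number((col / total).to_numpy(), 2)
        n_dom = max(1, math.floor(d2 + 0.5))
        order = sorted(col.index, key=lambda a: (-col[a], a))
        out.update(order[:n_dom])
    return out


def prevalence_filter(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    min_detected: int = 2,
    mode: str = "all_timepoints",
) -> set[str]:
    """ASVs consistently detected across the factorial design.

    ``mode="all_timepoints"`` (default, strict): kept iff detected (>= 1
    read) in at least ``min_detected`` replicates in EVERY treatment x day
    cell; day-0 shared samples count for both nematode arms.
    ``mode="any_timepoint"``: at least one qualifying day per treatment.
    The threshold scales as ceil(2/3 * n) for cells with n != 3 samples.
    """
    if mode not in ("all_timepoints", "any_timepoint"):
        raise ValueError(f"unknown prevalence mode {mode!r}")
    detected = counts > 0
    per_cell = {}
    for maize, nematode, day in cell_iter(design):
        ids = samples_for_cell(meta, maize, nematode, day)  # raises DesignError
        n = len(ids)
        thresh = min_detected if n == 3 else math.ceil(2 * n / 3)
        per_cell[(treatment_label(maize, nematode), day)] = (
            detected[ids].sum(axis=1) >= thresh)
    cells = pd.DataFrame(per_cell)
    if mode == "all_timepoints":
        keep = cells.all(axis=1)
    else:
        per_treat = cells.T.groupby(level=0).any().T
        keep = per_treat.all(axis=1)
    return set(counts.index[keep])


def mean_trajectories(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    asvs=None,
) -> pd.DataFrame:
    """Replicate-mean abundance per (ASV, treatment) over the day grid.

    Returns a frame indexed by (asv_id, treatment) with one column per day;
    day-0 values come from the shared baseline samples of the matching maize
    level.
    """
    if asvs is not None:
        asvs = sorted(asvs)
        abund = abund.loc[asvs]
    blocks = []
    keys = []
    for label in design.treatments:
        from .design import treatment_flags

        maize, nematode = treatment_flags(label)
        cols = {}
        for day in design.days:
            ids = samples_for_cell(meta, maize, nematode, day)
            cols[day] = abund[ids].mean(axis=1)
        block = pd.DataFrame(cols)
        blocks.append(block)
        keys.append(label)
    out = pd.concat(blocks, keys=keys, names=["treatment", "asv_id"])
    return out.swaplevel().sort_index()


@dataclass
class SelectionReport:
    """Result of the three-stage ASV selection cascade."""

    dominant_set: set[str]
    prevalent_set: set[str]
    responsive_set: set[str]
    scores: pd.Series = field(repr=False)  # summed abundance range per candidate
    coverage: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Per-candidate table: score, rank, and filter membership flags."""
        df = pd.DataFrame({"summed_range": self.scores.sort_values(ascending=False)})
        df.index.name = "asv_id"
        df["rank"] = np.arange(1, len(df) + 1)
        df["responsive"] = df.index.isin(sorted(self.responsive_set))
        return df


def pareto_responsive(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    candidates,
    fraction: float = 0.80,
) -> SelectionReport:
    """Retain the smallest top-scoring ASV set covering ``fraction`` of the
    total summed abundance range.

    The responsiveness score of an ASV is the sum over the four treatments
    of (max - min) of its replicate-mean trajectory. ASVs are ranked by
    score (descending, ties by id) and the shortest prefix whose cumulative
    score reaches ``fraction`` of the total is selected.
    """
    if not candidates:
        raise DesignError("no candidate ASVs for responsiveness ranking")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    traj = mean_trajectories(abund, meta, design, asvs=candidates)
    ranges = traj.max(axis=1) - traj.min(axis=1)
    scores = ranges.groupby(level="asv_id").sum()
    order = sorted(scores.index, key=lambda a: (-scores[a], a))
    ordered = scores.loc[order]
    total = float(ordered.sum())
    if total <= 0:
        # all-flat candidates: nothing is responsive, keep none
        return SelectionReport(set(), set(), set(), scores=ordered, coverage=0.0)
    cum = ordered.cumsum() / total
    n_sel = int(np.searchsorted(cum.to_numpy(), fraction * (1 - 1e-12)) + 1)
    selected = set(order[:n_sel])
    return SelectionReport(
        dominant_set=set(), prevalent_set=set(), responsive_set=selected,
        scores=ordered, coverage=float(cum.iloc[n_sel - 1]))


def select_responsive_asvs(
    abund: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    fraction: float = 0.80,
    min_detected: int = 2,
    prevalence_mode: str = "all_timepoints",
) -> SelectionReport:
    """Full cascade: dominance, prevalence, then Pareto responsiveness."""
    dominant = select_dominant_asvs(abund)
    prevalent = prevalence_filter(counts, meta, design,
                                  min_detected=min_detected, mode=prevalence_mode)
    candidates = dominant & prevalent
    if not candidates:
        return SelectionReport(dominant, prevalent, set(),
                               scores=pd.Series(dtype=float), coverage=0.0)
    rep = pareto_responsive(abund, meta, design, candidates, fraction=fraction)
    rep.dominant_set = dominant
    rep.prevalent_set = prevalent
    return rep
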