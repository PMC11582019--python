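"""Factorial study design: 2 x 2 treatments (maize litter x nematode addition)
sampled destructively over an incubation time course.

The design mirrors a soil-microcosm grazing experiment: four treatment
combinations (±maize litter M, ±bacterivorous nematode A), replicated
microcosms sampled at fixed days, with day-0 baseline samples shared between
the ±A arms of each maize level (the nematode was added at day 0, so both
arms start from the same community).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DesignError, SchemaError

#: Canonical treatment order used in every output: nematode (A) flag first,
#: maize (M) flag second, controls before additions.
CANONICAL_TREATMENTS: tuple[str, ...] = ("-A/-M", "-A/+M", "+A/-M", "+A/+M")

METADATA_COLUMNS = ("sample_id", "maize", "nematode", "day", "replicate", "shared_baseline")


def treatment_label(maize: bool, nematode: bool) -> str:
    """Return the canonical '<±>A/<±>M' label for a treatment combination."""
    return f"{'+' if nematode else '-'}A/{'+' if maize else '-'}M"


def treatment_flags(label: str) -> tuple[bool, bool]:
    """Inverse of :func:`treatment_label` -> (maize, nematode)."""
    if label not in CANONICAL_TREATMENTS:
        raise SchemaError(f"unknown treatment label {label!r}")
    return label[3] == "+", label[0] == "+"


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the incubation experiment.

    Parameters
    ----------
    days
        Strictly increasing sampling days, starting at 0.
    replicates
        Replicate microcosms per treatment x day cell (>= 2).
    baseline_shared_over_nematode
        Whether day-0 samples are shared between the ±nematode arms of each
        maize level (nematodes added at day 0).
    """

    days: tuple[int, ...]
    replicates: int = 3
    baseline_shared_over_nematode: bool = True
    maize_levels: tuple[bool, ...] = (False, True)
    nematode_levels: tuple[bool, ...] = (False, True)

    def __post_init__(self) -> None:
        if len(self.days) < 2:
            raise SchemaError("design needs at least 2 sampling days")
        if list(self.days) != sorted(set(self.days)):
            raise SchemaError("days must be strictly increasing")
        if self.days[0] != 0:
            raise SchemaError("first sampling day must be 0")
        if self.replicates < 2:
            raise SchemaError("need at least 2 replicates")

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(
            label for label in CANONICAL_TREATMENTS
            if treatment_flags(label)[0] in self.maize_levels
            and treatment_flags(label)[1] in self.nematode_levels)

    def n_samples(self) -> int:
        """Number of distinct molecular samples the design produces."""
        n_treat = len(self.treatments)
        later = (len(self.days) - 1) * n_treat * self.replicates
        if self.baseline_shared_over_nematode:
            day0 = len(self.maize_levels) * self.replicates
        else:
            day0 = n_treat * self.replicates
        return day0 + later


#: The published experiment: days {0,4,8,16,32}, 3 sequenced replicates,
#: shared day-0 baselines -> 6 + 4*4*3 = 54 samples.
DEFAULT_DESIGN = StudyDesign(days=(0, 4, 8, 16, 32), replicates=3)


def validate_metadata(meta: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Validate a sample metadata table and coerce dtypes.

    Requires columns ``sample_id, maize, nematode, day, replicate,
    shared_baseline``; flags are 0/1. Shared-baseline samples are only
    allowed at day 0.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample_id in metadata: {dups}")
    for col in ("maize", "nematode", "shared_baseline"):
        vals = set(pd.unique(meta[col]))
        if not vals <= {0, 1, True, False}:
            raise SchemaError(f"metadata column {col!r} must be 0/1, got {vals}")
        meta[col] = meta[col].astype(bool)
    meta["day"] = meta["day"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise SchemaError("replicate numbers must be positive")
    if (meta.loc[meta["shared_baseline"], "day"] != 0).any():
        raise SchemaError("shared_baseline samples are only allowed at day 0")
    if design is not None:
        bad = sorted(set(meta["day"]) - set(design.days))
        if bad:
            raise SchemaError(f"metadata days {bad} not in design days {list(design.days)}")
    return meta


def infer_design(meta: pd.DataFrame) -> StudyDesign:
    """Infer the :class:`StudyDesign` from a validated metadata table."""
    meta = validate_metadata(meta)
    days = tuple(sorted(meta["day"].unique()))
    shared = bool(meta["shared_baseline"].any())
    # replicates: modal count per (treatment, day) cell
    cell_sizes = meta.groupby(["maize", "nematode", "day"]).size()
    replicates = int(cell_sizes.mode().iloc[0])
    return StudyDesign(days=days, replicates=replicates,
                       baseline_shared_over_nematode=shared)


def samples_for_cell(meta: pd.DataFrame, maize: bool, nematode: bool, day: int) -> list[str]:
    """Sample ids belonging to one (treatment, day) cell.

    Day-0 shared-baseline samples of the matching maize level are counted in
    BOTH ±nematode arms (they were split before nematode addition).
    """
    m = (meta["maize"] == maize) & (meta["day"] == day)
    if day == 0:
        m &= (meta["nematode"] == nematode) | meta["shared_baseline"]
    else:
        m &= meta["nematode"] == nematode
    ids = meta.loc[m, "sample_id"].tolist()
    if not ids:
        raise DesignError(
            f"no samples in cell {treatment_label(maize, nematode)} day {day}")
    return sorted(ids)


def cell_iter(design: StudyDesign):
    """Yield (maize, nematode, day) for every cell of the design."""
    for label in design.treatments:
        maize, nematode = treatment_flags(label)
        for day in design.days:
            yield maize, nematode, day
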