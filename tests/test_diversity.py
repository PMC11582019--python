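"""Absolute-abundance transform, Hill numbers, and selection-filter oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import resptyper as rt
from resptyper.design import StudyDesign
from resptyper.diversity import (
    hill_number,
    hill_triple,
    mean_trajectories,
    pareto_responsive,
    prevalence_filter,
    select_dominant_asvs,
    to_absolute,
)
from resptyper.errors import NormalizationError, ZeroDepthError


class TestToAbsolute:
    def test_proportional_split(self):
        counts = pd.DataFrame({"S1": [50, 50]}, index=["a", "b"])
        qpcr = pd.Series({"S1": 2e8})
        out = to_absolute(counts, qpcr)
        assert out["S1"].tolist() == [1e8, 1e8]

    def test_closure_to_qpcr_totals(self, small_dataset, small_abund):
        ds, _ = small_dataset
        np.testing.assert_allclose(small_abund.sum(axis=0), ds.qpcr, rtol=1e-9)

    def test_zero_depth_sample_raises(self):
        counts = pd.DataFrame({"S1": [1, 2], "S2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ZeroDepthError):
            to_absolute(counts, pd.Series({"S1": 1e8, "S2": 1e8}))


class TestHillNumbers:
    def test_uniform_community(self):
        p = np.full(10, 0.1)
        assert hill_triple(p) == pytest.approx((10, 10, 10))

    def test_closed_form_values(self):
        d0, d1, d2 = hill_triple([0.8, 0.2])
        assert d0 == 2
        assert d1 == pytest.approx(1.6493849, abs=1e-6)
        assert d2 == pytest.approx(1.4705882, abs=1e-6)  # 1/0.68
        assert hill_number([0.4, 0.3, 0.2, 0.1], 2) == pytest.approx(1 / 0.30)

    def test_unnormalised_raises(self):
        with pytest.raises(NormalizationError):
            hill_number([0.5, 0.4], 1)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_ordering_property(self, raw):
        p = np.array(raw) / np.sum(raw)
        p = p / p.sum()
        d0, d1, d2 = hill_triple(p)
        assert d0 + 1e-9 >= d1 >= d2 - 1e-9


class TestDominance:
    def test_single_sample_closed_forms(self):
        # 2D = 1.47 -> n_dom = 1 -> top ASV only
        abund = pd.DataFrame({"S1": [0.8, 0.2]}, index=["a", "b"])
        assert select_dominant_asvs(abund) == {"a"}
        # 2D = 3.33 -> n_dom = 3
        abund = pd.DataFrame({"S1": [0.4, 0.3, 0.2, 0.1]},
                             index=["a", "b", "c", "d"])
        assert select_dominant_asvs(abund) == {"a", "b", "c"}

    def test_uniform_sample_keeps_all(self):
        abund = pd.DataFrame({"S1": [1.0] * 6}, index=list("abcdef"))
        assert select_dominant_asvs(abund) == set("abcdef")

    def test_brute_force_rank_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            vals = rng.pareto(1.2, size=8) + 0.01
            abund = pd.DataFrame({"S1": vals},
                                 index=[f"t{i}" for i in range(8)])
            p = vals / vals.sum()
            d2 = 1.0 / (p ** 2).sum()
            n_dom = max(1, math.floor(d2 + 0.5))
            order = sorted(abund.index, key=lambda a: (-abund.loc[a, "S1"], a))
            assert select_dominant_asvs(abund) == set(order[:n_dom])


def _toy_design_and_meta():
    """2-treatment x 2-day toy design (nematode factor only, 3 reps)."""
    design = StudyDesign(days=(0, 4), replicates=3,
                         baseline_shared_over_nematode=False,
                         maize_levels=(False,))
    rows = []
    for nem in (False, True):
        for day in (0, 4):
            for rep in (1, 2, 3):
                rows.append((f"S{int(nem)}{day}{rep}", False, nem, day, rep, False))
    meta = pd.DataFrame(rows, columns=["sample_id", "maize", "nematode",
                                       "day", "replicate", "shared_baseline"])
    return design, meta


class TestPrevalence:
    def test_exhaustive_toy_patterns_match_oracle(self):
        # every 12-sample presence pattern that is constant within cells:
        # enumerate detection counts (0-3) per cell and compare with the rule
        design, meta = _toy_design_and_meta()
        full = StudyDesign(days=(0, 4), replicates=3,
                           baseline_shared_over_nematode=False)
        # toy uses only maize=False cells; counts frame needs those samples
        for counts_per_cell in itertools.product(range(4), repeat=4):
            row = {}
            for (nem, day), k in zip(
                    itertools.product((False, True), (0, 4)), counts_per_cell):
                for rep in (1, 2, 3):
                    row[f"S{int(nem)}{day}{rep}"] = 1 if rep <= k else 0
            counts = pd.DataFrame(row, index=["asv"])
            kept = prevalence_filter(counts, meta, design)
            expected = all(k >= 2 for k in counts_per_cell)
            assert (("asv" in kept) == expected), counts_per_cell

    def test_shared_baseline_counts_for_both_arms(self, small_dataset):
        ds, _ = small_dataset
        # an ASV detected only in day-0 shared samples passes the day-0 cells
        # of BOTH nematode arms
        counts = ds.counts.copy()
        probe = pd.Series(0, index=counts.columns)
        shared = ds.meta.loc[ds.meta["shared_baseline"], "sample_id"]
        probe.loc[shared] = 5
        counts.loc["PROBE"] = probe
        # strict mode: later cells have no detection -> dropped
        assert "PROBE" not in prevalence_filter(counts, ds.meta, ds.design)
        # any-timepoint mode: the shared day-0 cell satisfies BOTH nematode
        # arms of each maize level, so every treatment has a qualifying day
        kept_any = prevalence_filter(counts, ds.meta, ds.design,
                                     mode="any_timepoint")
        assert "PROBE" in kept_any
        from resptyper.design import samples_for_cell, treatment_flags
        for label in rt.CANONICAL_TREATMENTS:
            m, n = treatment_flags(label)
            ids = samples_for_cell(ds.meta, m, n, 0)
            assert (counts.loc["PROBE", ids] > 0).sum() >= 2

    def test_single_cell_dropout_excludes(self, small_dataset):
        ds, _ = small_dataset
        counts = pd.DataFrame(1, index=["x"], columns=ds.counts.columns)
        from resptyper.design import samples_for_cell
        ids = samples_for_cell(ds.meta, True, True, 16)
        counts.loc["x", ids[:2]] = 0  # only 1/3 detected in one cell
        assert "x" not in prevalence_filter(counts, ds.meta, ds.design)
        assert "x" in prevalence_filter(counts, ds.meta, ds.design,
                                        mode="any_timepoint")


class TestPareto:
    def _dataset_from_scores(self, scores: dict[str, float]):
        """Build an abundance table whose per-ASV summed range equals the
        given scores (one treatment carries the whole range)."""
        design, meta = _toy_design_and_meta()
        abund = pd.DataFrame(0.0, index=list(scores),
                             columns=meta["sample_id"])
        for asv, s in scores.items():
            abund.loc[asv] = 100.0
            day4_ctrl = meta[(meta["day"] == 4) & ~meta["nematode"]]["sample_id"]
            abund.loc[asv, day4_ctrl] = 100.0 + s / 2.0  # two treatments sum
            day4_nem = meta[(meta["day"] == 4) & meta["nematode"]]["sample_id"]
            abund.loc[asv, day4_nem] = 100.0 + s / 2.0
        return design, meta, abund

    def test_prefix_examples(self):
        design, meta, abund = self._dataset_from_scores(
            {"a": 50.0, "b": 30.0, "c": 15.0, "d": 5.0})
        rep = pareto_responsive(abund, meta, design, {"a", "b", "c", "d"}, 0.8)
        assert rep.responsive_set == {"a", "b"}
        assert rep.coverage == pytest.approx(0.8)

    def test_tie_break_by_id(self):
        design, meta, abund = self._dataset_from_scores(
            {k: 10.0 for k in "edcba"})
        rep = pareto_responsive(abund, meta, design, set("abcde"), 0.8)
        assert rep.responsive_set == {"a", "b", "c", "d"}

    def test_single_candidate(self):
        design, meta, abund = self._dataset_from_scores({"solo": 7.0})
        rep = pareto_responsive(abund, meta, design, {"solo"}, 0.8)
        assert rep.responsive_set == {"solo"}
        assert rep.coverage == pytest.approx(1.0)

    def test_brute_force_prefix_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(25):
            n = rng.integers(2, 13)
            scores = {f"v{i:02d}": float(rng.uniform(0, 40)) for i in range(n)}
            frac = float(rng.uniform(0.2, 1.0))
            design, meta, abund = self._dataset_from_scores(scores)
            rep = pareto_responsive(abund, meta, design, set(scores), frac)
            # oracle: walk ranked scores, stop at first prefix >= frac*total
            ranked = sorted(scores, key=lambda a: (-scores[a], a))
            total = sum(scores.values())
            acc, chosen = 0.0, []
            for a in ranked:
                chosen.append(a)
                acc += scores[a]
                if acc >= frac * total - 1e-9 * total:
                    break
            assert rep.responsive_set == set(chosen), (trial, frac)

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(3)
        scores = {f"v{i}": float(rng.uniform(0, 20)) for i in range(10)}
        design, meta, abund = self._dataset_from_scores(scores)
        prev: set = set()
        for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
            sel = pareto_responsive(abund, meta, design, set(scores), frac
                                    ).responsive_set
            assert prev <= sel
            prev = sel


def test_mean_trajectories_shared_day0(small_dataset, small_abund):
    ds, _ = small_dataset
    traj = mean_trajectories(small_abund, ds.meta, ds.design,
                             asvs=list(ds.counts.index[:3]))
    assert traj.shape == (12, 5)
    for asv in ds.counts.index[:3]:
        # same maize level -> identical day-0 value in both nematode arms
        assert traj.loc[(asv, "-A/-M"), 0] == traj.loc[(asv, "+A/-M"), 0]
        assert traj.loc[(asv, "-A/+M"), 0] == traj.loc[(asv, "+A/+M"), 0]
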