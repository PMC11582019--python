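"""End-to-end orchestration: simulate/load -> filter -> classify -> patterns
-> composition (-> respiration), with a reproducibility manifest.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` so each stage is individually reproducible.
All outputs are plain TSV; the manifest (YAML) records the resolved
configuration, seed, package version, per-file checksums and warnings, and
is byte-identical between runs with the same config and seed. Stage timings
go to the log stream only.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import aitchison_pca, clr_transform, replace_zeros, variance_partition
from .design import DEFAULT_DESIGN, StudyDesign
from .diversity import select_responsive_asvs, to_absolute
from .errors import ConfigError
from .io import Dataset, load_inputs, write_results
from .patterns import (
    assemble_patterns,
    rank_patterns,
    rollup_by_taxon,
    succession_groups,
    type_contribution,
)
from .respiration import peak_days_by_treatment, rates_from_frame
from .response_types import assign_response_types, suggest_k
from .simulate import RespirationSimConfig, SimConfig, simulate_dataset, simulate_respiration

log = logging.getLogger("resptyper")

STAGES = ("simulate", "respire", "filter", "classify", "patterns", "compose")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 42
    simulate: SimConfig | None = None
    respiration_sim: RespirationSimConfig | None = None
    count_path: str | None = None
    meta_path: str | None = None
    qpcr_path: str | None = None
    taxonomy_path: str | None = None
    titration_path: str | None = None
    count_format: str = "tsv"
    pareto_fraction: float = 0.80
    min_detected: int = 2
    prevalence_mode: str = "all_timepoints"
    k: int = 9
    nstart: int = 25
    n_final: int = 5
    stability_theta: float = 0.75
    merge_map: dict | None = None
    run_k_selection: bool = True
    kmax: int = 12
    nboot: int = 50
    pattern_coverage: float = 0.80
    prior_strength: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            design_raw = sim.pop("design", None)
            design = StudyDesign(**{**design_raw, "days": tuple(design_raw["days"])}) \
                if design_raw else DEFAULT_DESIGN
            sim = SimConfig(design=design, **sim)
        resp = raw.pop("respiration_sim", None)
        if resp is not None:
            resp = RespirationSimConfig(**resp)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=sim, respiration_sim=resp, **raw)

    def resolved_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"]["design"]["days"] = list(self.simulate.design.days)
        return d


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one 31-bit seed per stage from the global seed."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(STAGES, states)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> tuple[dict, dict]:
    """Execute all stages and write every output table plus manifest.yaml.

    Returns ``(results, manifest)`` where ``results`` maps table names to
    in-memory frames. Identical (config, seed) produce byte-identical
    output files, manifest included.
    """
    out_dir = Path(out_dir)
    seeds = stage_seeds(config.seed)
    results: dict[str, pd.DataFrame | pd.Series] = {}
    warnings_log: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                log.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _T()

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        with stage("simulate"):
            ds, truth = simulate_dataset(config.simulate, seed=seeds["simulate"])
            results["sim_counts"] = ds.counts
            results["sim_metadata"] = ds.meta.set_index("sample_id")
            results["sim_qpcr"] = ds.qpcr.rename_axis("sample_id")
            results["sim_taxonomy"] = ds.taxonomy
            results["sim_truth_types"] = truth.types.rename_axis("asv_id")
    elif config.count_path:
        ds = load_inputs(config.count_path, config.meta_path, config.qpcr_path,
                         config.taxonomy_path, fmt=config.count_format)
    else:
        raise ConfigError("config must give either a simulation preset or input paths")

    titrations = None
    if config.respiration_sim is not None:
        titrations, curves = simulate_respiration(config.respiration_sim,
                                                  seed=seeds["respire"])
        results["sim_titrations"] = titrations.set_index("microcosm_id")
        results["sim_respiration_truth"] = curves.set_index("day")
    elif config.titration_path:
        titrations = pd.read_csv(config.titration_path, sep="\t")

    if titrations is not None:
        with stage("respire"):
            rates = rates_from_frame(titrations)
            results["respiration_rates"] = rates.set_index("microcosm_id")
            results["respiration_peaks"] = peak_days_by_treatment(rates).set_index("treatment")

    # --- selection cascade ------------------------------------------------
    with stage("filter"):
        abund = to_absolute(ds.counts, ds.qpcr)
        results["absolute_abundance"] = abund
        report = select_responsive_asvs(
            abund, ds.counts, ds.meta, ds.design,
            fraction=config.pareto_fraction, min_detected=config.min_detected,
            prevalence_mode=config.prevalence_mode)
        results["selection_report"] = report.to_frame()

    # --- response typing --------------------------------------------------
    with stage("classify"):
        selection = sorted(report.responsive_set)
        if not selection:
            raise ConfigError("selection cascade retained no ASVs")
        assignments, clf = assign_response_types(
            abund, ds.meta, ds.design, selection,
            k=config.k, nstart=config.nstart, n_final=config.n_final,
            stability_theta=config.stability_theta, merge_map=config.merge_map,
            seed=seeds["classify"])
        results["assignments"] = assignments.set_index(["asv_id", "treatment"])
        if clf.centroids_.size:
            cen = pd.DataFrame(clf.centroids_,
                               columns=[f"day_{d}" for d in ds.design.days])
            cen.index.name = "cluster_id"
            cen["response_type"] = [clf.cluster_to_type_[i] for i in cen.index]
            results["centroids"] = cen
        if config.run_k_selection and (~clf.stable_mask_).sum() > config.kmax:
            ksel = suggest_k(clf.scaled_[~clf.stable_mask_], kmax=config.kmax,
                             nboot=config.nboot, nstart=config.nstart,
                             seed=seeds["classify"])
            results["k_selection"] = ksel.to_frame()

    # --- patterns & succession -------------------------------------------
    with stage("patterns"):
        pats = assemble_patterns(assignments, abund)
        results["patterns"] = pats
        top, achieved = rank_patterns(pats, coverage=config.pattern_coverage)
        top.index.name = "pattern_rank"
        results["patterns_top"] = top
        results["succession"] = succession_groups(pats)
        if ds.taxonomy is not None:
            results["rollup_family"] = rollup_by_taxon(
                assignments, ds.taxonomy, abund).set_index("taxon")
        results["type_contribution"] = type_contribution(
            assignments, abund, ds.meta, ds.design).set_index("treatment")

    # --- compositional beta diversity ------------------------------------
    with stage("compose"):
        props = replace_zeros(ds.counts, prior_strength=config.prior_strength)
        clr_mat = clr_transform(props)
        results["clr"] = clr_mat.rename_axis("sample_id")
        ordn = aitchison_pca(clr_mat)
        results["pca_scores"] = ordn.scores.rename_axis("sample_id")
        results["distances"] = ordn.distances.rename_axis("sample_id")
        vp = variance_partition(clr_mat, ds.meta)
        vp_frame = pd.Series(vp.fractions, name="adjusted_r2").rename_axis("component")
        vp_frame = pd.concat([vp_frame, pd.Series(
            {"total_explained": vp.total_explained}, name="adjusted_r2")])
        results["varpart"] = vp_frame.rename_axis("component")

    paths = write_results(results, out_dir, overwrite=overwrite)
    manifest = {
        "package": "resptyper",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.resolved_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(paths)},
        "warnings": warnings_log,
        "pattern_coverage_achieved": float(achieved),
    }
    manifest_path = out_dir / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        from .errors import ExistsError

        raise ExistsError(f"{manifest_path} exists and overwrite is False")
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    log.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return results, manifest


def simulate_preset_config(seed: int = 42, s_asvs: int = 200,
                           depth: int = 10_000) -> PipelineConfig:
    """The default synthetic end-to-end preset (small test scale)."""
    return PipelineConfig(
        seed=seed,
        simulate=SimConfig(s_asvs=s_asvs, depth=depth),
        respiration_sim=RespirationSimConfig(),
    )
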