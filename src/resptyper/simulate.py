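"""Synthetic datasets with planted ground truth.

The generator emulates the soil-microcosm study conditions: a 2 x 2 factorial
(±maize litter x ±nematode) over days {0, 4, 8, 16, 32} with 3 sequenced
replicates and shared day-0 baselines (54 samples), a community total around
2.35e8 16S copies (g dry soil)^-1, multinomial read sampling, lognormal qPCR
measurement error, and per-(ASV, treatment) planted response archetypes.

Archetype shape templates (unit amplitude, on the day grid):

====== =========================================================
label  g(t)
====== =========================================================
A      -t / max(days)                 steady decline
B      -exp(-((t - 8) / w_B)^2)       minimum at day 8, recovery
C      +t / max(days)                 steady increase
D      exp(-((t - 4) / w_D)^2)        intermediate peak at day 4
E      exp(-((t - 8) / w_E)^2)        intermediate peak at day 8
STABLE 0                              no temporal response
====== =========================================================

Planted log abundance of ASV i in treatment tau at day t is
``log(baseline_i) + e * g_{type(i,tau)}(t)`` plus independent replicate noise
``N(0, sigma_rep^2)``; reads are multinomial draws from the per-sample
proportions (optionally Dirichlet-multinomial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .design import (
    CANONICAL_TREATMENTS,
    DEFAULT_DESIGN,
    StudyDesign,
    treatment_flags,
    treatment_label,
)
from .errors import ConfigError, UnknownTypeError
from .io import Dataset, resolve_display_family, TAXONOMY_RANKS

ARCHETYPES = ("A", "B", "C", "D", "E", "STABLE")

#: default Gaussian widths (days) of the bump/dip templates
DEFAULT_WIDTHS = {"B": 8.0, "D": 6.0, "E": 8.0}

#: prominent family (phylum) labels used for simulated taxonomies
FAMILY_POOL = [
    ("Nitrososphaeraceae", "Nitrososphaerota"),
    ("Chitinophagaceae", "Bacteroidota"),
    ("Gemmatimonadaceae", "Gemmatimonadota"),
    ("Sphingomonadaceae", "Pseudomonadota"),
    ("Xanthomonadaceae", "Pseudomonadota"),
    ("Comamonadaceae", "Pseudomonadota"),
    ("Blastocatellaceae", "Acidobacteriota"),
    ("Pyrinomonadaceae", "Acidobacteriota"),
    ("Nitrosomonadaceae", "Pseudomonadota"),
    ("Nitrospiraceae", "Nitrospirota"),
    ("Micrococcaceae", "Actinomycetota"),
    ("Bacillaceae", "Bacillota"),
]


def archetype_template(
    type_label: str,
    days,
    peak: float | None = None,
    width: float | None = None,
) -> np.ndarray:
    """Unit-amplitude response shape g(t) on the given day grid.

    ``max |g| = 1`` for every non-stable archetype; STABLE is identically 0.
    ``peak``/``width`` override the template's default bump position/width.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0 or days[0] != 0:
        raise ConfigError("day grid must start at 0")
    if width is not None and width <= 0:
        raise ConfigError("width must be positive")
    if type_label == "STABLE":
        return np.zeros_like(days)
    if type_label == "A":
        return -days / days.max()
    if type_label == "C":
        return days / days.max()
    if type_label in ("B", "D", "E"):
        p = peak if peak is not None else (8.0 if type_label in ("B", "E") else 4.0)
        w = width if width is not None else DEFAULT_WIDTHS[type_label]
        g = np.exp(-(((days - p) / w) ** 2))
        return -g if type_label == "B" else g
    raise UnknownTypeError(f"unknown archetype {type_label!r}")


def scaled_templates(days, widths: dict | None = None) -> pd.DataFrame:
    """Z-scored (ddof=1) archetype templates A-E, used for cluster labelling."""
    out = {}
    for label in ("A", "B", "C", "D", "E"):
        g = archetype_template(label, days, width=(widths or {}).get(label))
        out[label] = (g - g.mean()) / g.std(ddof=1)
    return pd.DataFrame(out, index=list(days)).T


@dataclass
class SimConfig:
    """Study conditions for the synthetic count/qPCR generator.

    Defaults are the emulated experiment: 54 samples, ~2.35e8 total copies/g,
    read depth 1e5 (use 1e4 with s_asvs=200 as the small test preset),
    replicate noise sigma_rep=0.2 on the natural-log scale, qPCR measurement
    cv 0.2, archetype mixture 15/15/15/20/20/15 % for A/B/C/D/E/STABLE with a
    0.3 probability of re-drawing the type independently per treatment.
    """

    design: StudyDesign = field(default_factory=lambda: DEFAULT_DESIGN)
    s_asvs: int = 200
    depth: int = 100_000
    sigma_rep: float = 0.2
    cv_qpcr: float = 0.2
    overdispersion: float | None = None
    effect_size: float = 1.5
    mixture: dict = field(default_factory=lambda: {
        "A": 0.15, "B": 0.15, "C": 0.15, "D": 0.20, "E": 0.20, "STABLE": 0.15})
    switch_prob: float = 0.3
    community_total: float = 2.35e8
    baseline_sigma: float = 1.0
    widths: dict = field(default_factory=lambda: dict(DEFAULT_WIDTHS))

    def __post_init__(self) -> None:
        if self.s_asvs < 2:
            raise ConfigError("need at least 2 ASVs")
        if self.depth < 100:
            raise ConfigError("depth must be >= 100")
        w = np.array([self.mixture.get(a, 0.0) for a in ARCHETYPES], dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ConfigError(f"mixture weights must be >= 0 and sum to 1, got {self.mixture}")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ConfigError("switch_prob must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated dataset."""

    types: pd.DataFrame          # ASV x treatment planted archetype labels
    effect_size: float
    baselines: pd.Series         # ASV -> baseline copies/g
    true_abundance: pd.DataFrame  # ASV x sample noise-free... incl. replicate noise
    true_totals: pd.Series       # sample -> true column total copies/g


def _draw_types(rng: np.random.Generator, cfg: SimConfig, asv_ids) -> pd.DataFrame:
    labels = np.array(ARCHETYPES)
    probs = np.array([cfg.mixture.get(a, 0.0) for a in ARCHETYPES])
    base = rng.choice(labels, size=len(asv_ids), p=probs)
    cols = {}
    for treat in CANONICAL_TREATMENTS:
        redraw = rng.random(len(asv_ids)) < cfg.switch_prob
        fresh = rng.choice(labels, size=len(asv_ids), p=probs)
        cols[treat] = np.where(redraw, fresh, base)
    return pd.DataFrame(cols, index=asv_ids)


def _sample_frame(design: StudyDesign) -> pd.DataFrame:
    rows = []
    for maize in design.maize_levels:
        for rep in range(1, design.replicates + 1):
            sid = f"d00_{'M1' if maize else 'M0'}_A*_r{rep}"
            rows.append((sid, maize, False, 0, rep, True))
    for day in design.days[1:]:
        for treat in CANONICAL_TREATMENTS:
            maize, nem = treatment_flags(treat)
            for rep in range(1, design.replicates + 1):
                sid = f"d{day:02d}_{'M1' if maize else 'M0'}_{'A1' if nem else 'A0'}_r{rep}"
                rows.append((sid, maize, nem, day, rep, False))
    return pd.DataFrame(rows, columns=[
        "sample_id", "maize", "nematode", "day", "replicate", "shared_baseline"])


def _simulate_taxonomy(rng: np.random.Generator, asv_ids) -> pd.DataFrame:
    idx = rng.integers(0, len(FAMILY_POOL), size=len(asv_ids))
    tax = pd.DataFrame("", index=pd.Index(asv_ids, name="asv_id"),
                       columns=list(TAXONOMY_RANKS))
    fams = np.array([FAMILY_POOL[i][0] for i in idx])
    phyla = np.array([FAMILY_POOL[i][1] for i in idx])
    tax["domain"] = np.where(phyla == "Nitrososphaerota", "Archaea", "Bacteria")
    tax["phylum"] = phyla
    tax["family"] = fams
    tax["order"] = "o_" + fams
    # ~5% of ASVs lack a family label to exercise the display fallback
    drop = rng.random(len(asv_ids)) < 0.05
    tax.loc[drop, "family"] = ""
    tax["display_family"] = resolve_display_family(tax)
    return tax


def simulate_dataset(config: SimConfig | None = None, seed: int = 0
                     ) -> tuple[Dataset, SimTruth]:
    """Generate a complete synthetic dataset with planted response types.

    Returns the validated :class:`~resptyper.io.Dataset` (counts, metadata,
    qPCR totals, taxonomy) plus the :class:`SimTruth` it was generated from.
    Identical ``(config, seed)`` yield identical output.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    design = cfg.design
    asv_ids = [f"ASV{i:04d}" for i in range(1, cfg.s_asvs + 1)]
    meta = _sample_frame(design)
    types = _draw_types(rng, cfg, asv_ids)

    # baselines: lognormal spread, rescaled to the configured community total
    raw = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=cfg.s_asvs)
    baselines = pd.Series(raw / raw.sum() * cfg.community_total, index=asv_ids)

    templates = {a: archetype_template(a, design.days, width=cfg.widths.get(a))
                 for a in ARCHETYPES}
    day_index = {d: j for j, d in enumerate(design.days)}

    true = np.empty((cfg.s_asvs, len(meta)))
    logbase = np.log(baselines.to_numpy())
    for s, row in meta.iterrows():
        day = int(row["day"])
        if day == 0:
            # day 0 is the pre-treatment community: effects develop only
            # after treatment onset, so every ASV sits at its baseline.
            # This also makes the shared day-0 samples consistent with the
            # planted types of BOTH ±nematode arms.
            g = np.zeros(cfg.s_asvs)
        else:
            treat = treatment_label(bool(row["maize"]), bool(row["nematode"]))
            g = np.array([templates[types.loc[a, treat]][day_index[day]]
                          for a in asv_ids])
        noise = rng.normal(0.0, cfg.sigma_rep, size=cfg.s_asvs)
        true[:, s] = np.exp(logbase + cfg.effect_size * g + noise)

    true_df = pd.DataFrame(true, index=pd.Index(asv_ids, name="asv_id"),
                           columns=meta["sample_id"])
    true_totals = true_df.sum(axis=0)

    # qPCR measurement: lognormal multiplicative error with unit mean
    s2 = np.log1p(cfg.cv_qpcr ** 2)
    qpcr = true_totals * rng.lognormal(-s2 / 2, np.sqrt(s2), size=len(meta))
    qpcr.name = "total_copies"

    # sequencing: (Dirichlet-)multinomial reads per sample
    props = true / true.sum(axis=0, keepdims=True)
    counts = np.empty_like(true, dtype=np.int64)
    for s in range(props.shape[1]):
        p = props[:, s]
        if cfg.overdispersion is not None:
            p = rng.dirichlet(p * cfg.overdispersion)
        counts[:, s] = rng.multinomial(cfg.depth, p)
    counts_df = pd.DataFrame(counts, index=true_df.index, columns=true_df.columns)

    taxonomy = _simulate_taxonomy(rng, asv_ids)
    ds = Dataset(counts=counts_df, meta=meta, qpcr=qpcr, taxonomy=taxonomy,
                 design=design)
    truth = SimTruth(types=types, effect_size=cfg.effect_size,
                     baselines=baselines, true_abundance=true_df,
                     true_totals=true_totals)
    return ds, truth


# ---------------------------------------------------------------------------
# respiration

@dataclass
class RespirationSimConfig:
    """Conditions for the synthetic alkali-trap titration generator.

    The true rate curve per treatment is ``r(t) = base + amp *
    exp(-((t - peak)/sigma)^2)`` in ug CO2 (g soil DW)^-1 h^-1; nematode
    treatments peak at day 6, controls at day 12 (the grazing-induced
    forward shift of maximum respiration).
    """

    peak_day_nematode: float = 6.0
    peak_day_control: float = 12.0
    amplitude: float = 1.2
    base_rate: float = 0.3
    sigma_days: float = 4.0
    soil_dw_g: float = 50.0
    hcl_blank_ml: float = 6.0
    noise_cv: float = 0.1
    interval_days: float = 2.0
    total_days: float = 32.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be positive")
        if self.interval_days <= 0 or self.total_days <= 0:
            raise ConfigError("interval grid must be positive")


def _rate_integral(cfg: RespirationSimConfig, peak: float,
                   a: float, b: float) -> float:
    """Exact integral of r(t) over [a, b] days, in ug/g/h * h."""
    base = cfg.base_rate * (b - a)
    s = cfg.sigma_days
    bump = cfg.amplitude * s * np.sqrt(np.pi) / 2 * (
        erf((b - peak) / s) - erf((a - peak) / s))
    return float((base + bump) * 24.0)


def true_rate_curve(cfg: RespirationSimConfig, nematode: bool, t) -> np.ndarray:
    peak = cfg.peak_day_nematode if nematode else cfg.peak_day_control
    t = np.asarray(t, dtype=float)
    return cfg.base_rate + cfg.amplitude * np.exp(-(((t - peak) / cfg.sigma_days) ** 2))


def simulate_respiration(config: RespirationSimConfig | None = None, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate titration records by inverting the CO2-rate formula.

    CO2 mass trapped per measurement interval is the exact integral of the
    true rate curve times soil dry weight; the consumed HCl difference is
    back-computed (0.1 M HCl ~ 2.2 mg CO2 per mL, x1000 to ug) and
    multiplicative lognormal noise is applied to it. Returns
    ``(titrations, true_curves)``.
    """
    cfg = config or RespirationSimConfig()
    rng = np.random.default_rng(seed)
    edges = np.arange(0.0, cfg.total_days + 1e-9, cfg.interval_days)
    s2 = np.log1p(cfg.noise_cv ** 2)
    rows = []
    for treat in CANONICAL_TREATMENTS:
        maize, nem = treatment_flags(treat)
        peak = cfg.peak_day_nematode if nem else cfg.peak_day_control
        for rep in range(1, cfg.replicates + 1):
            mid = f"mc_{'M1' if maize else 'M0'}_{'A1' if nem else 'A0'}_r{rep}"
            for a, b in zip(edges[:-1], edges[1:]):
                co2_ug = _rate_integral(cfg, peak, a, b) * cfg.soil_dw_g
                diff_ml = co2_ug / (2.2 * 1000.0)
                if cfg.noise_cv > 0:
                    diff_ml *= rng.lognormal(-s2 / 2, np.sqrt(s2))
                rows.append((mid, maize, nem, a, b, cfg.hcl_blank_ml,
                             cfg.hcl_blank_ml - diff_ml, cfg.soil_dw_g))
    titr = pd.DataFrame(rows, columns=[
        "microcosm_id", "maize", "nematode", "interval_start", "interval_end",
        "hcl_blank_ml", "hcl_sample_ml", "soil_dw_g"])
    grid = np.arange(0.0, cfg.total_days + 0.25, 0.5)
    curves = pd.DataFrame({
        "day": grid,
        "rate_nematode": true_rate_curve(cfg, True, grid),
        "rate_control": true_rate_curve(cfg, False, grid),
    })
    return titr, curves
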