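"""Response typing of per-(ASV, treatment) abundance trajectories.

The clustering unit is the z-scored replicate-mean trajectory of one ASV in
one treatment; trajectories of all four treatments are pooled into a single
k-means clustering (k=9, best of 25 starts), the nine centroids are merged
by complete-linkage agglomeration on (1 - Pearson correlation) down to five
groups, and each merged group is labelled with the response archetype (A-E)
whose z-scored shape template it correlates with best. Temporally stable
trajectories are screened out beforehand and bypass clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .design import StudyDesign
from .diversity import mean_trajectories
from .errors import (
    ConstantTrajectoryError,
    KTooLargeError,
    LabelConflictWarning,
    TooFewItemsError,
)
from .simulate import scaled_templates

RESPONSE_TYPES = ("A", "B", "C", "D", "E")
STABLE = "STABLE"


def build_trajectories(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    asvs,
) -> pd.DataFrame:
    """One replicate-mean trajectory per (selected ASV x treatment).

    Indexed by (asv_id, treatment); columns are the design days. Day-0
    values are computed from the shared baseline samples of the matching
    maize level, so they are identical between the ±nematode arms.
    """
    if not len(asvs):
        raise ValueError("ASV selection is empty")
    return mean_trajectories(abund, meta, design, asvs=asvs)


def screen_stability(values, theta: float = 0.75) -> bool:
    """True when a trajectory is temporally stable.

    A trajectory is stable when its range (max - min) is below ``theta``
    times its median, or when it has zero variance. The default theta is
    calibrated so that at the study's noise level (replicate and qPCR
    measurement error propagated into day means) flat trajectories fall
    below it while the weakest archetype response stays above it.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("trajectory contains non-finite values")
    if v.std() == 0:
        return True
    return bool(np.ptp(v) < theta * np.median(v))


def scale_trajectory(values) -> np.ndarray:
    """Z-score a trajectory to mean 0 and sample (ddof=1) sd 1."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ConstantTrajectoryError("cannot z-score a constant trajectory")
    return (v - v.mean()) / sd


@dataclass
class KSelectionReport:
    """Suggested cluster numbers from three diagnostics."""

    wss_k: int
    wss_curve: pd.Series
    silhouette_k: int
    silhouette_curve: pd.Series
    gap_k: int
    gap_curve: pd.Series
    gap_se: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "wss": self.wss_curve,
            "silhouette": self.silhouette_curve.reindex(self.wss_curve.index),
            "gap": self.gap_curve.reindex(self.wss_curve.index),
            "gap_se": self.gap_se.reindex(self.wss_curve.index),
        })
        df.index.name = "k"
        df.attrs["suggestions"] = {
            "wss": self.wss_k, "silhouette": self.silhouette_k, "gap": self.gap_k}
        return df


def _wss(X: np.ndarray, k: int, nstart: int, rng_seed: int) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=nstart, random_state=rng_seed).fit(X)
    return float(km.inertia_), km.labels_


def suggest_k(
    scaled: np.ndarray | pd.DataFrame,
    kmax: int = 12,
    nboot: int = 50,
    nstart: int = 25,
    seed: int = 0,
) -> KSelectionReport:
    """Scan k = 1..kmax with the elbow (WSS), silhouette and gap diagnostics.

    The gap statistic compares log within-cluster dispersion against
    ``nboot`` uniform reference datasets drawn over the PCA-aligned bounding
    box of the data; its suggestion is the smallest k with
    gap(k) >= gap(k+1) - se(k+1) (the one-standard-error rule).
    """
    X = np.asarray(scaled, dtype=float)
    if X.shape[0] < kmax + 1:
        raise TooFewItemsError(
            f"need more than kmax={kmax} trajectories, got {X.shape[0]}")
    rng = np.random.default_rng(seed)

    ks = np.arange(1, kmax + 1)
    wss = {}
    sil = {}
    for k in ks:
        inertia, labels = _wss(X, int(k), nstart, seed)
        wss[int(k)] = inertia
        if k >= 2 and len(np.unique(labels)) > 1:
            sil[int(k)] = float(silhouette_score(X, labels))
    wss_s = pd.Series(wss)
    sil_s = pd.Series(sil)
    # elbow: largest second difference of the WSS curve (interior k)
    d2 = wss_s.shift(1) - 2 * wss_s + wss_s.shift(-1)
    wss_k = int(d2.idxmax()) if d2.notna().any() else 1
    sil_k = int(sil_s.idxmax())

    # gap statistic on the PCA-aligned bounding box (Tibshirani et al.)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    log_w_ref = np.empty((nboot, len(ks)))
    for b in range(nboot):
        ref = rng.uniform(lo, hi, size=Xp.shape) @ Vt
        for j, k in enumerate(ks):
            inertia, _ = _wss(ref, int(k), 5, seed + 1000 + b)
            log_w_ref[b, j] = np.log(inertia) if inertia > 0 else -np.inf
    log_w_obs = np.array([np.log(wss_s[int(k)]) if wss_s[int(k)] > 0 else -np.inf
                          for k in ks])
    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0) * np.sqrt(1 + 1.0 / nboot)
    gap_s = pd.Series(gap, index=ks)
    se_s = pd.Series(se, index=ks)
    gap_k = int(ks[-1])
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - se[j + 1]:
            gap_k = int(ks[j])
            break
    return KSelectionReport(wss_k=wss_k, wss_curve=wss_s,
                            silhouette_k=sil_k, silhouette_curve=sil_s,
                            gap_k=gap_k, gap_curve=gap_s, gap_se=se_s)


def cluster_trajectories(
    scaled: np.ndarray | pd.DataFrame,
    k: int = 9,
    nstart: int = 25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-``nstart`` k-means on z-scored trajectories."""
    X = np.asarray(scaled, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise KTooLargeError(f"k={k} exceeds {n_distinct} distinct trajectories")
    km = KMeans(n_clusters=k, n_init=nstart, random_state=seed).fit(X)
    return km.labels_, km.cluster_centers_


def merge_and_label(
    centroids: np.ndarray,
    days,
    n_final: int = 5,
    manual_map: dict[int, str] | None = None,
    widths: dict | None = None,
) -> dict[int, str]:
    """Merge k-means centroids into ``n_final`` groups and label them A-E.

    Centroids are agglomerated by complete linkage on (1 - Pearson
    correlation); each merged group's mean centroid is labelled with the
    best-correlated z-scored archetype template, assigning the globally
    best-correlated (group, template) pairs first so labels stay unique.
    A ``manual_map`` (cluster id -> type) overrides everything, mirroring
    the visual-inspection merge of the original analysis.
    """
    if manual_map is not None:
        return dict(manual_map)
    C = np.asarray(centroids, dtype=float)
    n = C.shape[0]
    if n_final > n:
        raise KTooLargeError(f"n_final={n_final} exceeds {n} centroids")
    if n_final < n:
        corr = np.corrcoef(C)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="complete")
        groups = fcluster(Z, t=n_final, criterion="maxclust")
    else:
        groups = np.arange(1, n + 1)
    templates = scaled_templates(days, widths=widths)

    merged = {g: C[groups == g].mean(axis=0) for g in np.unique(groups)}
    # greedy unique labelling by descending correlation
    pairs = []
    for g, cen in merged.items():
        for label in templates.index:
            t = templates.loc[label].to_numpy()
            r = float(np.corrcoef(cen, t)[0, 1])
            pairs.append((r, g, label))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    group_label: dict[int, str] = {}
    used: set[str] = set()
    best_r: dict[int, float] = {}
    for r, g, label in pairs:
        if g in group_label or label in used:
            continue
        group_label[g] = label
        used.add(label)
        best_r[g] = r
    for g, r in best_r.items():
        if r < 0.5:
            warnings.warn(
                f"merged cluster group {g} correlates poorly with every "
                f"archetype (best r={r:.2f}); labelled {group_label[g]} anyway",
                LabelConflictWarning, stacklevel=2)
    return {int(c): group_label[int(g)] for c, g in zip(range(n), groups)}


class ResponseTypeClassifier(BaseEstimator):
    """Classify abundance trajectories into response types A-E or STABLE.

    A scikit-learn style estimator: ``fit(X)`` takes an (n_trajectories,
    n_days) array of raw replicate-mean trajectories, screens temporally
    stable ones, z-scores the rest, k-means clusters them, merges and labels
    the clusters against the archetype templates, and exposes the results as
    fitted attributes.

    Parameters
    ----------
    days : sequence of int
        The day grid the trajectory columns correspond to.
    k : int, default 9
        Number of initial k-means clusters.
    nstart : int, default 25
        Random k-means restarts (best inertia kept).
    n_final : int, default 5
        Number of merged response-type groups.
    stability_theta : float, default 0.75
        Range/median threshold of the stability screen.
    merge_map : dict, optional
        Manual cluster id -> type label override for the merge step.
    random_state : int, default 0

    Attributes
    ----------
    labels_ : ndarray of str, (n_trajectories,)
        Response type per trajectory ('A'..'E' or 'STABLE').
    cluster_ids_ : ndarray of float
        Initial k-means cluster per trajectory (NaN for stable ones).
    centroids_ : ndarray (k_eff, n_days)
    cluster_to_type_ : dict[int, str]
    template_correlation_ : ndarray of float
        Pearson correlation of each scaled trajectory with the z-scored
        template of its assigned type (NaN for stable trajectories).
    stable_mask_ : ndarray of bool
    """

    def __init__(self, days=(0, 4, 8, 16, 32), k: int = 9, nstart: int = 25,
                 n_final: int = 5, stability_theta: float = 0.75,
                 merge_map: dict | None = None, random_state: int = 0):
        self.days = days
        self.k = k
        self.nstart = nstart
        self.n_final = n_final
        self.stability_theta = stability_theta
        self.merge_map = merge_map
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.days):
            raise ValueError(f"X must be (n, {len(self.days)}) trajectories")
        n = X.shape[0]
        stable = np.array([screen_stability(row, self.stability_theta) for row in X])
        labels = np.full(n, STABLE, dtype=object)
        cluster_ids = np.full(n, np.nan)
        corrs = np.full(n, np.nan)
        self.scaled_ = np.full_like(X, np.nan)

        active = ~stable
        if active.any():
            Xs = np.vstack([scale_trajectory(row) for row in X[active]])
            self.scaled_[active] = Xs
            n_distinct = np.unique(Xs, axis=0).shape[0]
            k_eff = min(self.k, n_distinct)
            lab, cen = cluster_trajectories(Xs, k=k_eff, nstart=self.nstart,
                                            seed=self.random_state)
            n_final_eff = min(self.n_final, k_eff)
            mapping = merge_and_label(cen, self.days, n_final=n_final_eff,
                                      manual_map=self.merge_map)
            templates = scaled_templates(self.days)
            type_lab = np.array([mapping[int(c)] for c in lab], dtype=object)
            labels[active] = type_lab
            cluster_ids[active] = lab
            tmpl = {t: templates.loc[t].to_numpy() for t in templates.index}
            corrs[active] = [
                float(np.corrcoef(x, tmpl[t])[0, 1])
                for x, t in zip(Xs, type_lab)
            ]
            self.centroids_ = cen
            self.cluster_to_type_ = mapping
        else:
            self.centroids_ = np.empty((0, X.shape[1]))
            self.cluster_to_type_ = {}
        self.labels_ = labels
        self.cluster_ids_ = cluster_ids
        self.template_correlation_ = corrs
        self.stable_mask_ = stable
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def assign_response_types(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    design: StudyDesign,
    selection,
    k: int = 9,
    nstart: int = 25,
    n_final: int = 5,
    stability_theta: float = 0.75,
    merge_map: dict | None = None,
    seed: int = 42,
) -> tuple[pd.DataFrame, ResponseTypeClassifier]:
    """End-to-end typing of all selected ASVs across the four treatments.

    Pools the (ASV, treatment) trajectories of all treatments into one
    clustering so an ASV can carry different types per treatment while the
    type definitions stay comparable across treatments. Returns one row per
    (selected ASV x treatment) plus the fitted classifier.
    """
    traj = build_trajectories(abund, meta, design, asvs=selection)
    clf = ResponseTypeClassifier(
        days=tuple(design.days), k=k, nstart=nstart, n_final=n_final,
        stability_theta=stability_theta, merge_map=merge_map, random_state=seed)
    clf.fit(traj.to_numpy())
    out = pd.DataFrame({
        "asv_id": traj.index.get_level_values("asv_id"),
        "treatment": traj.index.get_level_values("treatment"),
        "response_type": clf.labels_,
        "cluster_id": clf.cluster_ids_,
        "template_correlation": clf.template_correlation_,
    }).reset_index(drop=True)
    return out, clf
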