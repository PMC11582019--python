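"""Compositional beta-diversity: zero replacement, CLR, Aitchison PCA, and
variance partitioning.

Read counts are compositions: only relative information is meaningful, so
beta diversity is computed in log-ratio space. Zeros are imputed with a
Bayesian-multiplicative replacement (posterior expected proportion under a
Dirichlet prior, non-zero parts rescaled multiplicatively), rows are
centred-log-ratio transformed, and the Euclidean geometry of CLR space
(the Aitchison distance) drives both the PCA ordination and redundancy-
analysis variance partitioning over the maize / nematode / time factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.composition import clr as _skbio_clr
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import NonPositiveError, SingularDesignError, ZeroDepthError


def replace_zeros(counts: pd.DataFrame, prior_strength: float = 0.5) -> pd.DataFrame:
    """Impute zero counts; returns a strictly positive sample x ASV
    proportion matrix.

    Bayesian-multiplicative replacement with a symmetric Dirichlet prior of
    ``prior_strength`` per part: a zero part j in a sample of depth n over S
    parts gets its posterior expected proportion s/(n + S*s); the observed
    (non-zero) parts are rescaled multiplicatively so the row still sums to
    1, which preserves all ratios among them. Rows without zeros are
    returned as plain proportions.
    """
    if prior_strength <= 0:
        raise ValueError("prior_strength must be positive")
    X = counts.to_numpy(dtype=float).T  # samples x ASVs
    depth = X.sum(axis=1)
    if (depth <= 0).any():
        bad = [counts.columns[i] for i in np.where(depth <= 0)[0]]
        raise ZeroDepthError(f"samples with zero total reads: {bad}")
    S = X.shape[1]
    s = prior_strength
    zero = X == 0
    repl = (s / (depth + S * s))[:, None] * zero
    props = X / depth[:, None]
    scale = 1.0 - repl.sum(axis=1)
    out = props * scale[:, None]
    out[zero] = repl[zero]
    return pd.DataFrame(out, index=counts.columns, columns=counts.index)


def clr_transform(props: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform per row: ln x_j - mean_j ln x_j."""
    X = np.asarray(props, dtype=float)
    if (X <= 0).any():
        raise NonPositiveError("CLR requires strictly positive entries")
    out = _skbio_clr(X)
    if isinstance(props, pd.DataFrame):
        return pd.DataFrame(out, index=props.index, columns=props.columns)
    return pd.DataFrame(out)


def aitchison_distances(clr_mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between CLR rows (Aitchison distance)."""
    d = squareform(pdist(np.asarray(clr_mat, dtype=float), metric="euclidean"))
    idx = clr_mat.index if isinstance(clr_mat, pd.DataFrame) else None
    return pd.DataFrame(d, index=idx, columns=idx)


@dataclass
class Ordination:
    """PCA of a CLR matrix: scores, loadings, explained-variance fractions,
    and the sample Aitchison distance matrix."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    distances: pd.DataFrame


def aitchison_pca(clr_mat: pd.DataFrame) -> Ordination:
    """PCA ordination by centred SVD of the CLR matrix.

    Pairwise Euclidean distances between the full-rank score rows equal the
    Aitchison distances between the samples (SVD is an isometry).
    """
    X = np.asarray(clr_mat, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for ordination")
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = sv > sv.max() * 1e-12 if sv.size else np.array([], dtype=bool)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    scores = U * sv
    explained = sv ** 2 / (sv ** 2).sum()
    idx = clr_mat.index if isinstance(clr_mat, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    feat = clr_mat.columns if isinstance(clr_mat, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    return Ordination(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        loadings=pd.DataFrame(Vt.T, index=feat, columns=cols),
        explained=explained,
        distances=aitchison_distances(clr_mat),
    )


class MultiplicativeZeroReplacer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`replace_zeros` (counts in
    ASV x sample orientation; output sample x ASV proportions)."""

    def __init__(self, prior_strength: float = 0.5):
        self.prior_strength = prior_strength

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return replace_zeros(X, prior_strength=self.prior_strength)


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`clr_transform`."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return clr_transform(X)


class AitchisonPCA(BaseEstimator, TransformerMixin):
    """PCA in Aitchison geometry as a scikit-learn transformer.

    ``fit`` stores the column means and principal axes of the CLR matrix;
    ``transform`` projects (new) CLR rows onto them. Fitted attributes:
    ``components_``, ``explained_variance_ratio_``, ``mean_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        ord_ = aitchison_pca(pd.DataFrame(np.asarray(X, dtype=float)))
        comps = ord_.loadings.to_numpy().T
        if self.n_components is not None:
            comps = comps[: self.n_components]
        self.mean_ = np.asarray(X, dtype=float).mean(axis=0)
        self.components_ = comps
        ratio = ord_.explained
        self.explained_variance_ratio_ = (
            ratio[: self.n_components] if self.n_components is not None else ratio)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T


# ---------------------------------------------------------------------------
# variance partitioning

def _dummy_matrix(meta: pd.DataFrame, factor: str) -> np.ndarray:
    if factor == "M":
        return meta["maize"].astype(float).to_numpy()[:, None]
    if factor == "A":
        return meta["nematode"].astype(float).to_numpy()[:, None]
    if factor == "D":
        d = pd.get_dummies(meta["day"].astype("category"), drop_first=True)
        return d.to_numpy(dtype=float)
    raise ValueError(f"unknown factor {factor!r}")


def _adjusted_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel-adjusted redundancy R^2 of the multivariate response Y on X."""
    n = Y.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xd)
    m = rank - 1
    if n - 1 - m <= 0:
        raise SingularDesignError("not enough residual degrees of freedom")
    beta, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    resid = Y - Xd @ beta
    Yc = Y - Y.mean(axis=0)
    ss_tot = float((Yc ** 2).sum())
    if ss_tot == 0:
        raise SingularDesignError("response matrix has zero total variance")
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - m)


@dataclass
class VariancePartition:
    """Unique and shared adjusted-R^2 fractions of the three factors.

    Keys: 'M', 'A', 'D' (unique fractions), 'M+A', 'A+D', 'M+D' (pairwise
    shared), 'M+A+D' (three-way shared). Small negative adjusted fractions
    are legitimate and reported as-is. The fractions sum to the full-model
    adjusted R^2 (``total_explained``) by construction.
    """

    fractions: dict[str, float]
    total_explained: float
    subset_r2: dict[str, float]


def variance_partition(
    clr_mat: pd.DataFrame,
    meta: pd.DataFrame,
    include_interactions: bool = True,
) -> VariancePartition:
    """Partition CLR community variance over maize (M), nematode (A) and
    incubation day (D, categorical) by redundancy-analysis adjusted R^2.

    Adjusted R^2 is computed for every non-empty factor subset; unique and
    shared fractions follow by inclusion-exclusion, so they sum exactly to
    the full-model adjusted R^2.
    """
    meta = meta.set_index("sample_id").loc[clr_mat.index].reset_index()
    Y = np.asarray(clr_mat, dtype=float)
    Y = Y - Y.mean(axis=0)
    mats = {f: _dummy_matrix(meta, f) for f in ("M", "A", "D")}
    for f, mat in mats.items():
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(meta)), mat])) < 2:
            raise SingularDesignError(f"factor {f} is constant across samples")

    def r2(*fs) -> float:
        return _adjusted_r2(Y, np.column_stack([mats[f] for f in fs]))

    R = {"M": r2("M"), "A": r2("A"), "D": r2("D"),
         "MA": r2("M", "A"), "MD": r2("M", "D"), "AD": r2("A", "D"),
         "MAD": r2("M", "A", "D")}
    a = R["MAD"] - R["AD"]           # unique M
    b = R["MAD"] - R["MD"]           # unique A
    c = R["MAD"] - R["MA"]           # unique D
    d = R["MAD"] - R["D"] - a - b    # shared M,A
    e = R["MAD"] - R["M"] - b - c    # shared A,D
    f = R["MAD"] - R["A"] - a - c    # shared M,D
    g = R["MAD"] - (a + b + c + d + e + f)
    fractions = {"M": a, "A": b, "D": c}
    if include_interactions:
        fractions.update({"M+A": d, "A+D": e, "M+D": f, "M+A+D": g})
    return VariancePartition(fractions=fractions, total_explained=R["MAD"],
                             subset_r2=R)
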