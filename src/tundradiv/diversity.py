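"""Alpha diversity and multi-scale distance-to-centroid beta diversity.

Alpha diversity: per-plot richness, logit-transformed cover, and scaled
Shannon evenness of station-pooled intercept counts (1 = perfectly even,
0 = single-species community).

Beta diversity follows the multivariate-dispersion approach: the binary
Bray–Curtis (Sørensen) dissimilarity matrix among plots is embedded in
principal-coordinate space — keeping negative-eigenvalue ("imaginary") axes
so squared dissimilarities are reproduced exactly — and each plot's beta
diversity at a spatial scale is its Euclidean distance to the centroid of
its group at that scale (station, transect, or altitude band across the
landscape).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .survey import AltitudeBand, CommunityMatrix, DEFAULT_BANDS, band_label

__all__ = [
    "EvennessValue",
    "scaled_shannon",
    "logit_cover",
    "COVER_LOGIT_EPS",
    "binary_bray_curtis",
    "sorensen_matrix",
    "PrincipalCoordinates",
    "pcoa",
    "centroid_distances",
    "beta_diversity_all_scales",
    "SCALES",
]

#: half the 1% resolution of visual cover estimates
COVER_LOGIT_EPS = 0.005

SCALES = ("station", "transect", "landscape")


@dataclass(frozen=True)
class EvennessValue:
    """Scaled Shannon evenness of one station's pooled intercept counts."""

    station: str
    H: float  # Shannon entropy, nats
    S: int  # number of species with positive counts
    J: float  # H / ln(S), in [0, 1]; 0 for a single-species community


def scaled_shannon(counts: Mapping[str, int], station: str = "") -> EvennessValue:
    """Scaled Shannon evenness: J = H / ln S, with J = 0 when S = 1.

    H is the Shannon entropy (nats) of the relative abundances; J = 1 means
    all species equally abundant, J = 0 a community with only one species.
    """
    pos = {s: c for s, c in counts.items() if c > 0}
    total = sum(pos.values())
    if total <= 0:
        raise ValueError("scaled_shannon needs at least one positive count")
    p = np.array(list(pos.values()), dtype=float) / total
    H = float(-(p * np.log(p)).sum())
    S = len(pos)
    J = 0.0 if S == 1 else float(H / np.log(S))
    return EvennessValue(station=station, H=H, S=S, J=J)


def logit_cover(p: float, eps: float = COVER_LOGIT_EPS) -> float:
    """Logit of a cover proportion, clamped to [eps, 1−eps] at the extremes."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"cover proportion outside [0, 1]: {p}")
    q = min(max(p, eps), 1.0 - eps)
    return float(np.log(q / (1.0 - q)))


def binary_bray_curtis(a: frozenset | set, b: frozenset | set) -> float:
    """Binary Bray–Curtis (Sørensen) dissimilarity, 1 − 2|a∩b|/(|a|+|b|).

    Two empty sets are defined as identical (0) with a warning: barren
    high-altitude plots must not break the pipeline.
    """
    na, nb = len(a), len(b)
    if na == 0 and nb == 0:
        warnings.warn(
            "Sørensen dissimilarity of two empty plots defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return 1.0 - 2.0 * len(set(a) & set(b)) / (na + nb)


def sorensen_matrix(incidence: np.ndarray) -> np.ndarray:
    """Pairwise Sørensen dissimilarity among the rows of a binary matrix."""
    A = np.asarray(incidence, dtype=float)
    shared = A @ A.T
    rich = A.sum(axis=1)
    denom = rich[:, None] + rich[None, :]
    both_empty = denom == 0
    if both_empty.any() and (rich == 0).any():
        warnings.warn(
            "empty plots present; their mutual Sørensen dissimilarity is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - 2.0 * shared / denom
    D[both_empty] = 0.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


class PrincipalCoordinates(BaseEstimator, TransformerMixin):
    """Principal-coordinate embedding of a dissimilarity matrix.

    Gower-centres −½ D∘D and eigendecomposes it.  Axes with positive
    eigenvalues are scaled by √λ (real part); axes with negative eigenvalues
    by √(−λ) (imaginary part).  Non-Euclidean dissimilarities such as
    Sørensen yield negative eigenvalues; keeping both parts makes the
    reconstruction Σ(Δreal)² − Σ(Δimag)² equal the squared input
    dissimilarities exactly, which is what downstream centroid distances
    require.

    Parameters
    ----------
    tol : relative eigenvalue magnitude below which axes are dropped.

    Attributes (after ``fit``)
    --------------------------
    eigenvalues_ : all retained eigenvalues, descending.
    coordinates_real_ : (n, k+) scores on positive-eigenvalue axes.
    coordinates_imag_ : (n, k−) scores on negative-eigenvalue axes.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, D: np.ndarray, y=None) -> "PrincipalCoordinates":
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be a square matrix")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("D must be symmetric")
        if (D < 0).any():
            raise ValueError("D must be non-negative")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("D must have a zero diagonal")
        n = D.shape[0]
        A = -0.5 * D * D
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        G = J @ A @ J
        G = 0.5 * (G + G.T)  # symmetrize against round-off
        lam, vec = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        if lam.size and np.abs(lam).max() > 0:
            keep = np.abs(lam) > self.tol * np.abs(lam).max()
        else:
            keep = np.zeros(lam.shape, dtype=bool)
        lam, vec = lam[keep], vec[:, keep]
        pos, neg = lam > 0, lam < 0
        self.eigenvalues_ = lam
        self.coordinates_real_ = vec[:, pos] * np.sqrt(lam[pos])
        self.coordinates_imag_ = vec[:, neg] * np.sqrt(-lam[neg])
        self.n_samples_ = n
        return self

    def transform(self, D: np.ndarray = None) -> np.ndarray:
        """Return the real-part coordinates of the fitted configuration.

        Classical scaling has no out-of-sample extension; like
        non-metric MDS in scikit-learn, transform is only defined for the
        training dissimilarities.
        """
        return self.coordinates_real_

    def reconstructed_squared_distances(self) -> np.ndarray:
        """Σ(Δreal)² − Σ(Δimag)² for every pair — equals D∘D exactly."""
        def sq(X):
            if X.shape[1] == 0:
                return np.zeros((X.shape[0], X.shape[0]))
            g = X @ X.T
            d = np.diag(g)
            return d[:, None] + d[None, :] - 2 * g

        return sq(self.coordinates_real_) - sq(self.coordinates_imag_)


def pcoa(D: np.ndarray, tol: float = 1e-10) -> PrincipalCoordinates:
    """Fit a :class:`PrincipalCoordinates` embedding on a dissimilarity matrix."""
    return PrincipalCoordinates(tol=tol).fit(D)


def centroid_distances(
    embedding: PrincipalCoordinates,
    groups: Sequence[str],
    scale: str = "group",
    plot_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Distance from each item to its group centroid in PCoA space.

    The centroid is the per-group arithmetic mean in both the real and the
    imaginary coordinates; the squared distance is Σ(real diffs)² − Σ(imag
    diffs)².  A negative squared distance (possible with imaginary axes) is
    clamped to 0 and flagged.
    """
    groups = np.asarray(groups, dtype=object)
    Xr, Xi = embedding.coordinates_real_, embedding.coordinates_imag_
    n = Xr.shape[0]
    if groups.shape[0] != n:
        raise ValueError("one group label per embedded item required")
    if plot_labels is None:
        plot_labels = [str(i) for i in range(n)]
    sq = np.zeros(n)
    for g in pd.unique(groups):
        mask = groups == g
        if Xr.shape[1]:
            cr = Xr[mask].mean(axis=0)
            sq[mask] += ((Xr[mask] - cr) ** 2).sum(axis=1)
        if Xi.shape[1]:
            ci = Xi[mask].mean(axis=0)
            sq[mask] -= ((Xi[mask] - ci) ** 2).sum(axis=1)
    clamped = sq < -1e-12
    dist = np.sqrt(np.clip(sq, 0.0, None))
    return pd.DataFrame(
        {
            "plot": list(plot_labels),
            "scale": scale,
            "group": groups,
            "distance": dist,
            "clamped": clamped,
        }
    )


def _pool_stations(matrix: CommunityMatrix) -> CommunityMatrix:
    """Collapse plots to stations (presence anywhere in the station)."""
    meta = matrix.row_meta
    key = meta["mountain"] + ":" + meta["transect"] + ":" + meta["station"]
    rows, metas = [], []
    for k in pd.unique(key):
        mask = (key == k).to_numpy()
        rows.append((matrix.incidence[mask].sum(axis=0) > 0).astype(np.int8))
        first = meta.loc[mask].iloc[0]
        metas.append(
            {
                "mountain": first["mountain"],
                "transect": first["transect"],
                "station": first["station"],
                "plot": "pooled",
                "altitude_m": meta.loc[mask, "altitude_m"].mean(),
            }
        )
    return CommunityMatrix(np.array(rows), pd.DataFrame(metas), matrix.species)


def beta_diversity_all_scales(
    matrix: CommunityMatrix,
    bands: Sequence[AltitudeBand] = DEFAULT_BANDS,
    pooling: str = "plot",
) -> pd.DataFrame:
    """Per-plot centroid distances at the station, transect and landscape scales.

    One shared PCoA embedding is computed from the full plot × plot Sørensen
    matrix (distances between fixed points do not depend on the grouping);
    the three scales differ only in how plots are grouped:

    * ``station`` — the five plots of one 25 × 25 m station;
    * ``transect`` — the 25 plots of one 1 km transect;
    * ``landscape`` — all plots in the same altitude band, across mountains.

    ``pooling="station"`` first collapses each station's plots to one pooled
    presence set, so distances are among stations instead of plots (the
    station scale then degenerates to zero).
    """
    if pooling not in ("plot", "station"):
        raise ValueError("pooling must be 'plot' or 'station'")
    if pooling == "station":
        matrix = _pool_stations(matrix)
    meta = matrix.row_meta
    D = sorensen_matrix(matrix.incidence)
    emb = pcoa(D)
    labels = matrix.plot_labels()
    station_g = (
        meta["mountain"] + ":" + meta["transect"] + ":" + meta["station"]
    ).to_numpy(dtype=object)
    transect_g = (meta["mountain"] + ":" + meta["transect"]).to_numpy(dtype=object)
    band_g = np.array(
        [band_label(a, bands) for a in meta["altitude_m"]], dtype=object
    )
    parts = [
        centroid_distances(emb, station_g, "station", labels),
        centroid_distances(emb, transect_g, "transect", labels),
        centroid_distances(emb, band_g, "landscape", labels),
    ]
    return pd.concat(parts, ignore_index=True)


class CentroidBetaDiversity(BaseEstimator, TransformerMixin):
    """Estimator wrapper around :func:`beta_diversity_all_scales`.

    ``fit`` computes the shared PCoA embedding and the three-scale centroid
    distance table for a :class:`CommunityMatrix`; ``transform`` returns the
    table.  Exposed as an estimator so the step composes with scikit-learn
    pipelines.
    """

    def __init__(self, bands: Sequence[AltitudeBand] = DEFAULT_BANDS):
        self.bands = bands

    def fit(self, matrix: CommunityMatrix, y=None) -> "CentroidBetaDiversity":
        self.distances_ = beta_diversity_all_scales(matrix, self.bands)
        return self

    def transform(self, matrix: CommunityMatrix = None) -> pd.DataFrame:
        return self.distances_


__all__.append("CentroidBetaDiversity")
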