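"""Nestedness (NODF) and bipartite modularity (Barber's Q via BRIM).

Both statistics operate on the binary plot × species incidence matrix.

* NODF (nestedness metric based on overlap and decreasing fill) averages,
  over ordered row pairs and ordered column pairs, the percentage overlap of
  the poorer line with the richer one, counting a pair only when its fill
  strictly decreases down/rightward.  It ranges from 0 (no nestedness) to
  100 (perfectly nested).  Because it depends on the row/column order, it is
  computed both under the optimal sorting (rows by richness, columns by
  frequency) and under altitude-imposed sortings, which turns it into a test
  of whether nestedness follows the gradient.

* Barber's Q extends Newman–Girvan modularity to bipartite networks:
  Q = (1/m) Σ_ij (B_ij − k_i d_j / m) δ(g_i, h_j), with m the total number
  of presences, k_i the plot richness and d_j the species frequency.  It is
  maximised with BRIM (Bipartite Recursively Induced Modules): alternating
  sweeps that assign each species to its Q-maximising module given the plot
  modules, and vice versa, with an adaptive search over the number of
  modules and random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .survey import AltitudeBand, CommunityMatrix, DEFAULT_BANDS, band_label

__all__ = [
    "MatrixOrdering",
    "NestednessResult",
    "ModularityResult",
    "nodf",
    "optimal_nestedness_ordering",
    "altitude_ordering",
    "reciprocal_averaging",
    "reciprocal_averaging_ordering",
    "barber_q",
    "brim_optimize",
    "BRIMModularity",
    "band_partition",
    "altitude_constrained_modularity",
    "render_incidence",
]


@dataclass(frozen=True)
class MatrixOrdering:
    """A row and column permutation of an incidence matrix."""

    row_order: np.ndarray
    col_order: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        for name in ("row_order", "col_order"):
            perm = np.asarray(getattr(self, name))
            if sorted(perm.tolist()) != list(range(perm.size)):
                raise ValueError(f"{name} is not a permutation")
            object.__setattr__(self, name, perm.astype(int))

    def apply(self, incidence: np.ndarray) -> np.ndarray:
        return np.asarray(incidence)[np.ix_(self.row_order, self.col_order)]


@dataclass(frozen=True)
class NestednessResult:
    nodf: float  # pooled over row and column pairs, in [0, 100]
    nodf_rows: float
    nodf_cols: float
    ordering: MatrixOrdering


@dataclass(frozen=True)
class ModularityResult:
    Q: float
    plot_modules: np.ndarray  # module id per matrix row
    species_modules: np.ndarray  # module id per matrix column
    n_modules: int
    restarts_used: int
    best_seed: int  # restart stream that produced the reported optimum


def _as_incidence(matrix) -> np.ndarray:
    if isinstance(matrix, CommunityMatrix):
        return matrix.incidence
    A = np.asarray(matrix)
    if A.ndim != 2:
        raise ValueError("incidence must be 2-D")
    return A


# ---------------------------------------------------------------------------
# orderings
# ---------------------------------------------------------------------------

def optimal_nestedness_ordering(matrix) -> MatrixOrdering:
    """Rows by decreasing richness, columns by decreasing frequency.

    Ties keep the input order (stable sort) for reproducibility.
    """
    A = _as_incidence(matrix)
    rows = np.argsort(-A.sum(axis=1), kind="stable")
    cols = np.argsort(-A.sum(axis=0), kind="stable")
    return MatrixOrdering(rows, cols, kind="optimal_nestedness")


def altitude_ordering(
    matrix: CommunityMatrix,
    within_mountain: bool = False,
    descending: bool = False,
) -> MatrixOrdering:
    """Rows by altitude (ascending by default), columns by decreasing frequency.

    Altitude ties break by transect then plot label.  With
    ``within_mountain``, mountains keep their input order and rows are
    altitude-sorted inside each.
    """
    meta = matrix.row_meta
    if meta["altitude_m"].isna().any():
        raise ValueError("altitude missing for some plots")
    alt = meta["altitude_m"].to_numpy(dtype=float)
    if descending:
        alt = -alt
    tr = meta["transect"].to_numpy(dtype=object)
    pl = meta["plot"].to_numpy(dtype=object)
    if within_mountain:
        mnt = meta["mountain"].to_numpy(dtype=object)
        first_seen = {m: i for i, m in reversed(list(enumerate(mnt)))}
        mkey = np.array([first_seen[m] for m in mnt])
        rows = np.lexsort((pl, tr, alt, mkey))
        kind = "altitude_within_mountain"
    else:
        rows = np.lexsort((pl, tr, alt))
        kind = "altitude"
    cols = np.argsort(-matrix.incidence.sum(axis=0), kind="stable")
    return MatrixOrdering(rows, cols, kind=kind)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _nodf_pair_sum(M: np.ndarray) -> float:
    """Σ over ordered row pairs (i above j) of 100·overlap/fill_j where
    fill decreases; zero-fill rows contribute nothing."""
    f = M.sum(axis=1).astype(float)
    O = (M @ M.T).astype(float)
    decreasing = f[None, :] < f[:, None]  # fill(j) < fill(i)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(f[None, :] > 0, 100.0 * O / f[None, :], 0.0)
    contrib = np.where(decreasing, contrib, 0.0)
    return float(np.triu(contrib, k=1).sum())


def nodf(matrix, ordering: MatrixOrdering | None = None) -> NestednessResult:
    """NODF of an incidence matrix under a given (or the optimal) ordering."""
    A = _as_incidence(matrix)
    if A.sum() == 0:
        raise ValueError("NODF is undefined for an all-zero matrix")
    if ordering is None:
        ordering = optimal_nestedness_ordering(A)
    M = ordering.apply(A)
    R, C = M.shape
    row_pairs = R * (R - 1) // 2
    col_pairs = C * (C - 1) // 2
    row_sum = _nodf_pair_sum(M)
    col_sum = _nodf_pair_sum(M.T)
    return NestednessResult(
        nodf=(row_sum + col_sum) / (row_pairs + col_pairs),
        nodf_rows=row_sum / row_pairs if row_pairs else 0.0,
        nodf_cols=col_sum / col_pairs if col_pairs else 0.0,
        ordering=ordering,
    )


# ---------------------------------------------------------------------------
# reciprocal averaging (correspondence analysis, first non-trivial axis)
# ---------------------------------------------------------------------------

def _ra_component(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First non-trivial CA axis of a connected incidence block.

    Solved as the SVD of the standardised residual matrix; row/column scores
    are the standard coordinates (zero weighted mean, unit weighted
    variance, weights = marginal masses).
    """
    m = A.sum()
    P = A / m
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv.size == 0 or sv[0] < 1e-12:
        return np.zeros(A.shape[0]), np.zeros(A.shape[1])
    u, v = U[:, 0], Vt[0, :]
    return u / np.sqrt(r), v / np.sqrt(c)


def _components(A: np.ndarray) -> np.ndarray:
    """Connected components of the bipartite incidence graph → row labels."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    R, C = A.shape
    rows, cols = np.nonzero(A)
    adj = csr_matrix(
        (np.ones(rows.size), (rows, cols + R)), shape=(R + C, R + C)
    )
    adj = adj + adj.T
    _, labels = connected_components(adj, directed=False)
    return labels


def reciprocal_averaging(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Row and column scores on the first non-trivial CA axis.

    Iterating "row score = weighted mean of its species' column scores" (and
    vice versa) to convergence is equivalent to this eigenproblem; the
    closed form is used.  All-zero rows/columns get score 0 with a warning.
    If the incidence graph is disconnected, scores are computed per
    component and offset so components occupy disjoint score ranges (in
    order of first row appearance), with a warning.  The sign is fixed so
    the highest-altitude plot (or the first row, if no altitude metadata is
    available) has a non-negative score.
    """
    A = _as_incidence(matrix).astype(float)
    R, C = A.shape
    row_scores = np.zeros(R)
    col_scores = np.zeros(C)
    zero_rows = A.sum(axis=1) == 0
    zero_cols = A.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn(
            "all-zero rows/columns get reciprocal-averaging score 0",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = _components(A)
    row_labels, col_labels = labels[:R], labels[R:]
    active = sorted(
        {l for i, l in enumerate(row_labels) if not zero_rows[i]},
        key=lambda l: int(np.nonzero(row_labels == l)[0][0]),
    )
    if len(active) > 1:
        warnings.warn(
            "incidence graph is disconnected; per-component scores with offsets",
            RuntimeWarning,
            stacklevel=2,
        )
    for k, lab in enumerate(active):
        rmask = (row_labels == lab) & ~zero_rows
        cmask = (col_labels == lab) & ~zero_cols
        u, v = _ra_component(A[np.ix_(rmask, cmask)])
        offset = 8.0 * k  # standardized scores live within ±~3
        row_scores[rmask] = u + offset
        col_scores[cmask] = v + offset

    if isinstance(matrix, CommunityMatrix):
        ref = int(np.argmax(matrix.row_meta["altitude_m"].to_numpy()))
    else:
        ref = 0
    if row_scores[ref] < 0:
        row_scores, col_scores = -row_scores, -col_scores
    return row_scores, col_scores


def reciprocal_averaging_ordering(matrix) -> MatrixOrdering:
    """Rows and columns sorted by their reciprocal-averaging scores."""
    u, v = reciprocal_averaging(matrix)
    return MatrixOrdering(
        np.argsort(u, kind="stable"),
        np.argsort(v, kind="stable"),
        kind="optimal_modularity",
    )


# ---------------------------------------------------------------------------
# Barber's Q and BRIM
# ---------------------------------------------------------------------------

def barber_q(matrix, plot_modules, species_modules) -> float:
    """Barber's bipartite modularity of a given two-sided partition."""
    A = _as_incidence(matrix).astype(float)
    m = A.sum()
    if m == 0:
        raise ValueError("Q is undefined for an all-zero matrix")
    r = np.asarray(plot_modules)
    c = np.asarray(species_modules)
    if r.shape[0] != A.shape[0] or c.shape[0] != A.shape[1]:
        raise ValueError("module label lengths must match matrix shape")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    q = 0.0
    for g in np.unique(np.concatenate([r, c])):
        rm, cm = r == g, c == g
        if rm.any() and cm.any():
            q += A[np.ix_(rm, cm)].sum() - k[rm].sum() * d[cm].sum() / m
    return float(q / m)


def _brim_sweeps(Bt: np.ndarray, row_mod: np.ndarray, K: int, m: float,
                 tol: float = 1e-10, max_iter: int = 200) -> tuple[float, np.ndarray, np.ndarray]:
    """Alternating BRIM label sweeps from a row partition; Q never decreases."""
    R = np.zeros((Bt.shape[0], K))
    R[np.arange(Bt.shape[0]), row_mod] = 1.0
    q_prev = -np.inf
    for _ in range(max_iter):
        T_scores = Bt.T @ R  # species × module
        col_mod = np.argmax(T_scores, axis=1)
        T = np.zeros((Bt.shape[1], K))
        T[np.arange(Bt.shape[1]), col_mod] = 1.0
        R_scores = Bt @ T
        row_mod = np.argmax(R_scores, axis=1)
        R = np.zeros((Bt.shape[0], K))
        R[np.arange(Bt.shape[0]), row_mod] = 1.0
        q = float(np.trace(R.T @ Bt @ T)) / m
        if q - q_prev < tol:
            break
        q_prev = q
    return q, row_mod, col_mod


def _relabel(row_mod: np.ndarray, col_mod: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    used = np.unique(np.concatenate([row_mod, col_mod]))
    remap = {g: i for i, g in enumerate(used)}
    rm = np.array([remap[g] for g in row_mod])
    cm = np.array([remap[g] for g in col_mod])
    return rm, cm, len(used)


def brim_optimize(
    matrix,
    n_restarts: int = 20,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_modules: int | None = None,
) -> ModularityResult:
    """Maximise Barber's Q with BRIM.

    For a candidate module count K, the best partition over ``n_restarts``
    random row-partition starts plus one reciprocal-averaging-binned start
    (plus the supplied ``init``, if any) is kept.  K is searched adaptively:
    start at 2, double while the best Q improves, then bisect between the
    last improving and the first non-improving K.  Deterministic for a fixed
    seed; the reported ``best_seed`` identifies the winning restart stream.
    """
    A = _as_incidence(matrix).astype(float)
    R, C = A.shape
    m = A.sum()
    if m == 0:
        raise ValueError("cannot optimise modularity of an all-zero matrix")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    Bt = A - np.outer(k, d) / m
    cap = max_modules or min(R, C, 30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ra_rows, _ = reciprocal_averaging(matrix)
    order = np.argsort(ra_rows, kind="stable")

    cache: dict[int, tuple[float, np.ndarray, np.ndarray, int]] = {}

    def best_at(K: int):
        K = min(K, cap)
        if K in cache:
            return cache[K]
        starts: list[tuple[int, np.ndarray]] = []
        rng = np.random.default_rng(np.random.SeedSequence((seed, K)))
        for rs in range(n_restarts):
            starts.append((rs, rng.integers(0, K, size=R)))
        # reciprocal-averaging quantile bins as a structured start
        bins = np.empty(R, dtype=int)
        bins[order] = np.minimum((np.arange(R) * K) // R, K - 1)
        starts.append((-1, bins))
        if init is not None:
            ri = np.asarray(init[0]) % K
            starts.append((-2, ri))
        best = (-np.inf, None, None, 0)
        for tag, start in starts:
            q, rm, cm = _brim_sweeps(Bt, start.copy(), K, m)
            if q > best[0] + 1e-12:
                best = (q, rm, cm, tag)
        cache[K] = best
        return best

    K = 2
    best_q, *_ = best_at(K)
    best_K = K
    while K < cap:
        K = min(2 * K, cap)
        q, *_ = best_at(K)
        if q > best_q + 1e-12:
            best_q, best_K = q, K
        else:
            break
        if K == cap:
            break
    # bisect between the best K and its failed successor
    lo, hi = best_K, min(2 * best_K, cap)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        q, *_ = best_at(mid)
        if q > best_q + 1e-12:
            best_q, lo = q, mid
        else:
            hi = mid
    q, rm, cm, tag = max(cache.values(), key=lambda t: t[0])
    rm, cm, n_mod = _relabel(rm, cm)
    return ModularityResult(
        Q=q,
        plot_modules=rm,
        species_modules=cm,
        n_modules=n_mod,
        restarts_used=n_restarts,
        best_seed=tag,
    )


class BRIMModularity:
    """scikit-learn-style clustering estimator around :func:`brim_optimize`.

    ``fit(A)`` on a binary plot × species incidence matrix sets
    ``modularity_``, ``row_labels_`` and ``column_labels_``; ``labels_``
    aliases the row (plot) labels as in scikit-learn clusterers.
    """

    def __init__(self, n_restarts: int = 20, seed: int = 0,
                 max_modules: int | None = None):
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_modules = max_modules

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "max_modules": self.max_modules,
        }

    def set_params(self, **params) -> "BRIMModularity":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, A, y=None) -> "BRIMModularity":
        res = brim_optimize(
            A, n_restarts=self.n_restarts, seed=self.seed,
            max_modules=self.max_modules,
        )
        self.result_ = res
        self.modularity_ = res.Q
        self.row_labels_ = res.plot_modules
        self.column_labels_ = res.species_modules
        self.labels_ = res.plot_modules
        self.n_modules_ = res.n_modules
        return self

    def fit_predict(self, A, y=None) -> np.ndarray:
        return self.fit(A).labels_


# ---------------------------------------------------------------------------
# altitude-constrained modularity
# ---------------------------------------------------------------------------

def band_partition(
    matrix: CommunityMatrix,
    bands=DEFAULT_BANDS,
    within_mountain: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Module partition imposed by altitude bands (optionally × mountain).

    Plots get their band (or mountain-crossed band) as a module; each
    species joins the band where most of its occurrences lie (ties to the
    lower band).
    """
    meta = matrix.row_meta
    labels = [band_label(a, bands) for a in meta["altitude_m"]]
    if within_mountain:
        labels = [f"{m}:{b}" for m, b in zip(meta["mountain"], labels)]
    uniq = list(dict.fromkeys(labels))
    lut = {l: i for i, l in enumerate(uniq)}
    rows = np.array([lut[l] for l in labels])
    counts = np.zeros((len(uniq), matrix.n_species))
    for g in range(len(uniq)):
        counts[g] = matrix.incidence[rows == g].sum(axis=0)
    cols = counts.argmax(axis=0)
    return rows, cols


def altitude_constrained_modularity(
    matrix: CommunityMatrix,
    bands=DEFAULT_BANDS,
    within_mountain: bool = False,
    n_restarts: int = 20,
    seed: int = 0,
) -> ModularityResult:
    """BRIM with an extra altitude-band initial partition.

    Barber's Q itself is invariant to row order, so "altitude-sorted"
    modularity is interpreted as seeding the optimisation with the partition
    the altitude bands impose, alongside the usual restarts.
    """
    init = band_partition(matrix, bands, within_mountain)
    return brim_optimize(matrix, n_restarts=n_restarts, seed=seed, init=init)


# ---------------------------------------------------------------------------
# incidence images
# ---------------------------------------------------------------------------

def render_incidence(matrix, ordering: MatrixOrdering | None = None,
                     path=None, cell: int = 3):
    """Write a monochrome raster of the (permuted) incidence matrix.

    One ``cell`` × ``cell`` pixel block per matrix cell, presences black on
    white.  Returns the pixel array.
    """
    from PIL import Image

    A = _as_incidence(matrix)
    if ordering is not None:
        A = ordering.apply(A)
    pixels = np.kron(A, np.ones((cell, cell), dtype=np.uint8))
    img = Image.fromarray(np.where(pixels > 0, 0, 255).astype(np.uint8), mode="L")
    if path is not None:
        img.save(path)
    return np.asarray(img)
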