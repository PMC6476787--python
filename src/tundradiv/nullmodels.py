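"""Fixed-species-frequency null model and Z-score inference.

The null model preserves each species' occurrence frequency: for every
species independently, its d_j presences are placed in d_j distinct plots
drawn uniformly at random.  Column sums are conserved exactly; row sums
(plot richnesses) are free, and rows may become empty (NODF treats
zero-fill rows as contributing nothing; Q is unaffected).

Observed nestedness/modularity values are compared to the null ensemble via
Z = (obs − null mean) / null SD (sample SD, n−1) and a one-tailed empirical
p in the direction of the deviation, p = (#{null at least as extreme} + 1) /
(n_reps + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .survey import AltitudeBand, CommunityMatrix, DEFAULT_BANDS
from .metacom import (
    altitude_constrained_modularity,
    altitude_ordering,
    brim_optimize,
    nodf,
)

__all__ = [
    "NullEnsemble",
    "NullTestResult",
    "randomize_fixed_frequencies",
    "null_test",
    "table1_analysis",
]


@dataclass(frozen=True)
class NullEnsemble:
    statistic: str
    n_reps: int
    null_values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.null_values, dtype=float)
        if vals.shape[0] != self.n_reps:
            raise ValueError("ensemble length != n_reps")
        object.__setattr__(self, "null_values", vals)


@dataclass(frozen=True)
class NullTestResult:
    observed: float
    expected: float  # null mean
    null_sd: float
    Z: float  # nan when the null ensemble is degenerate (sd = 0)
    p_empirical: float
    direction: str  # "above" or "below"


def randomize_fixed_frequencies(
    matrix: CommunityMatrix | np.ndarray,
    rng: np.random.Generator,
    allow_empty_rows: bool = True,
    max_tries: int = 1000,
) -> CommunityMatrix | np.ndarray:
    """One null draw: per-species uniform placement, column sums preserved.

    With ``allow_empty_rows=False`` the draw is repeated until every plot
    retains at least one species (an alternative null; off by default since
    empty plots are legitimate under the frequency-preserving model).
    """
    if isinstance(matrix, CommunityMatrix):
        A = matrix.incidence
    else:
        A = np.asarray(matrix)
    R, C = A.shape
    d = A.sum(axis=0)
    if (d > R).any():
        raise ValueError("a species has more presences than there are plots")

    def draw():
        out = np.zeros_like(A)
        for j in range(C):
            dj = int(d[j])
            if dj == R:
                out[:, j] = 1
            elif dj > 0:
                out[rng.choice(R, size=dj, replace=False), j] = 1
        return out

    out = draw()
    if not allow_empty_rows:
        for _ in range(max_tries):
            if (out.sum(axis=1) > 0).all():
                break
            out = draw()
        else:
            raise RuntimeError(
                "could not draw a null matrix without empty plots"
            )
    if isinstance(matrix, CommunityMatrix):
        return CommunityMatrix(out, matrix.row_meta, matrix.species)
    return out


def null_test(
    matrix: CommunityMatrix,
    statistic: Callable[[CommunityMatrix], float],
    n_reps: int = 1000,
    seed: int = 0,
    label: str = "statistic",
) -> tuple[NullTestResult, NullEnsemble]:
    """Observed-vs-null comparison of an arbitrary matrix statistic.

    The statistic is called on the observed matrix and on every null draw
    (each draw keeps the observed row metadata, so altitude-imposed
    orderings re-apply themselves, while optimal-ordering statistics
    re-optimise per draw).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 null replicates")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    observed = float(statistic(matrix))
    nulls = np.empty(n_reps)
    for i in range(n_reps):
        nulls[i] = statistic(randomize_fixed_frequencies(matrix, rng))
    expected = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    direction = "above" if observed >= expected else "below"
    if direction == "above":
        extreme = int((nulls >= observed).sum())
    else:
        extreme = int((nulls <= observed).sum())
    p = (extreme + 1) / (n_reps + 1)
    z = (observed - expected) / sd if sd > 0 else float("nan")
    return (
        NullTestResult(observed, expected, sd, z, p, direction),
        NullEnsemble(label, n_reps, nulls, seed),
    )


def _nodf_optimal(m: CommunityMatrix) -> float:
    return nodf(m).nodf


def _nodf_altitude(m: CommunityMatrix) -> float:
    return nodf(m, altitude_ordering(m)).nodf


def table1_analysis(
    matrix: CommunityMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    bands: Sequence[AltitudeBand] = DEFAULT_BANDS,
    brim_restarts: int = 20,
    null_brim_restarts: int = 5,
) -> pd.DataFrame:
    """The full metacommunity-structure results grid.

    For the pooled matrix and each mountain separately: NODF and Barber's Q
    under optimal and altitude-imposed sortings (plus altitude-within-
    mountain for the pooled modularity), each with its null expectation, Z
    and empirical p.  Per null draw, optimal-ordering statistics are
    re-optimised (NODF re-sorted, BRIM re-run with ``null_brim_restarts``
    restarts); altitude orderings are re-applied as fixed.
    """
    subsets: list[tuple[str, CommunityMatrix]] = [("All", matrix)]
    for m in dict.fromkeys(matrix.row_meta["mountain"]):
        subsets.append((str(m), matrix.subset_mountain(str(m))))

    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(64))
    rows = []

    def add(subset: str, sorting: str, stat_name: str,
            fn: Callable[[CommunityMatrix], float], mat: CommunityMatrix):
        s = int(next(child_seeds) % (2**31))
        res, _ = null_test(mat, fn, n_reps=n_reps, seed=s,
                           label=f"{stat_name}:{sorting}")
        rows.append(
            {
                "subset": subset,
                "sorting": sorting,
                "statistic": stat_name,
                "observed": res.observed,
                "expected": res.expected,
                "z": res.Z,
                "p_empirical": res.p_empirical,
                "n_reps": n_reps,
                "seed": s,
            }
        )

    for name, mat in subsets:
        bseed = int(next(child_seeds) % (2**31))

        def q_optimal(m, _s=bseed):
            return brim_optimize(
                m,
                n_restarts=brim_restarts if m is mat else null_brim_restarts,
                seed=_s,
            ).Q

        def q_altitude(m, _s=bseed, _wm=False):
            return altitude_constrained_modularity(
                m, bands=bands, within_mountain=_wm,
                n_restarts=brim_restarts if m is mat else null_brim_restarts,
                seed=_s,
            ).Q

        add(name, "optimal", "NODF", _nodf_optimal, mat)
        add(name, "altitude", "NODF", _nodf_altitude, mat)
        add(name, "optimal", "Q", q_optimal, mat)
        add(name, "altitude", "Q", q_altitude, mat)
        if name == "All":
            add(name, "altitude_within_mountain", "Q",
                lambda m, _s=bseed: altitude_constrained_modularity(
                    m, bands=bands, within_mountain=True,
                    n_restarts=brim_restarts if m is mat else null_brim_restarts,
                    seed=_s,
                ).Q,
                mat)
    return pd.DataFrame(rows)
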