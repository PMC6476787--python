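"""Hierarchical survey data model, matrix construction, and delimited-text I/O.

The sampling hierarchy is mountain ⊃ transect ⊃ station ⊃ plot.  Each 1 m²
plot carries an altitude, a visually estimated vegetation cover, and the set
of vascular-plant taxa observed in it.  Stations additionally carry
point-intercept touch counts used for relative-abundance (evenness)
estimation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotRecord",
    "InterceptCounts",
    "CommunityMatrix",
    "AltitudeBand",
    "DEFAULT_BANDS",
    "SurveyFormatError",
    "SurveyValidationError",
    "read_records",
    "write_records",
    "build_matrix",
    "matrix_to_records",
    "read_matrix",
    "write_matrix",
    "read_intercepts",
    "write_intercepts",
    "pool_station_counts",
    "assign_band",
    "band_label",
]


class SurveyFormatError(ValueError):
    """A delimited-text input does not have the expected columns/shape."""


class SurveyValidationError(ValueError):
    """Parsed data violates a survey invariant (range, uniqueness, hierarchy)."""


@dataclass(frozen=True)
class PlotRecord:
    """One 1 m² sample plot: hierarchy labels, altitude, cover, species set."""

    mountain: str
    transect: str
    station: str
    plot: str
    altitude: float
    cover: float
    species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("mountain", "transect", "station", "plot"):
            if not getattr(self, name):
                raise SurveyValidationError(f"empty hierarchy label: {name!r}")
        if not self.altitude > 0:
            raise SurveyValidationError(
                f"altitude must be > 0 m, got {self.altitude}"
            )
        if not 0.0 <= self.cover <= 1.0:
            raise SurveyValidationError(
                f"cover must be a proportion in [0, 1], got {self.cover}"
            )
        object.__setattr__(self, "species", frozenset(self.species))

    @property
    def richness(self) -> int:
        return len(self.species)

    def key(self) -> tuple[str, str, str, str]:
        return (self.mountain, self.transect, self.station, self.plot)


@dataclass(frozen=True)
class InterceptCounts:
    """Point-intercept touch counts for one station.

    The field design pools five 25-point plots, i.e. 125 points per station.
    """

    station: str
    counts: Mapping[str, int]
    n_points: int

    def __post_init__(self) -> None:
        if not self.station:
            raise SurveyValidationError("empty station label")
        if self.n_points <= 0:
            raise SurveyValidationError("n_points must be positive")
        counts = dict(self.counts)
        for sp, c in counts.items():
            if c < 0:
                raise SurveyValidationError(f"negative count for {sp!r}: {c}")
        object.__setattr__(self, "counts", counts)

    @property
    def total_touches(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class AltitudeBand:
    """Half-open altitude interval [lower, upper) in metres."""

    lower: float
    upper: float  # math.inf for an open top band

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SurveyValidationError(
                f"band lower bound must be < upper ({self.lower} >= {self.upper})"
            )

    def contains(self, altitude: float) -> bool:
        return self.lower <= altitude < self.upper

    @property
    def label(self) -> str:
        if np.isinf(self.upper):
            return f">{self.lower:g}m"
        return f"{self.lower:g}-{self.upper:g}m"


#: The four survey elevation bands (lower-inclusive, upper-exclusive).
DEFAULT_BANDS: tuple[AltitudeBand, ...] = (
    AltitudeBand(700.0, 900.0),
    AltitudeBand(900.0, 1100.0),
    AltitudeBand(1100.0, 1300.0),
    AltitudeBand(1300.0, np.inf),
)

_META_COLS = ["mountain", "transect", "station", "plot", "altitude_m"]


class CommunityMatrix:
    """Binary plot × species incidence matrix with aligned plot metadata.

    Parameters
    ----------
    incidence : (n_plots, n_species) array of {0, 1}
    row_meta : DataFrame with columns mountain, transect, station, plot,
        altitude_m — one row per matrix row, same order.
    species : sequence of unique species labels, one per column.
    """

    def __init__(
        self,
        incidence: np.ndarray,
        row_meta: pd.DataFrame,
        species: Sequence[str],
    ) -> None:
        incidence = np.asarray(incidence, dtype=np.int8)
        if incidence.ndim != 2:
            raise SurveyValidationError("incidence must be a 2-D matrix")
        if not np.isin(incidence, (0, 1)).all():
            raise SurveyValidationError("incidence entries must be 0/1")
        if len(row_meta) != incidence.shape[0]:
            raise SurveyValidationError(
                f"row_meta has {len(row_meta)} rows for "
                f"{incidence.shape[0]} matrix rows"
            )
        species = list(species)
        if len(species) != incidence.shape[1]:
            raise SurveyValidationError("species list length != column count")
        if len(set(species)) != len(species):
            raise SurveyValidationError("duplicate species columns")
        missing = [c for c in _META_COLS if c not in row_meta.columns]
        if missing:
            raise SurveyFormatError(f"row_meta missing columns: {missing}")
        self.incidence = incidence
        self.row_meta = row_meta.reset_index(drop=True)
        self.species = species

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    @property
    def n_plots(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    def row_sums(self) -> np.ndarray:
        """Per-plot species richness."""
        return self.incidence.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Per-species occurrence frequency."""
        return self.incidence.sum(axis=0)

    def plot_labels(self) -> list[str]:
        m = self.row_meta
        return [
            f"{r.mountain}:{r.transect}:{r.station}:{r.plot}"
            for r in m.itertuples()
        ]

    def species_sets(self) -> list[frozenset[str]]:
        sp = np.asarray(self.species, dtype=object)
        return [frozenset(sp[row.astype(bool)]) for row in self.incidence]

    def subset_rows(self, mask: np.ndarray) -> "CommunityMatrix":
        mask = np.asarray(mask)
        return CommunityMatrix(
            self.incidence[mask],
            self.row_meta.loc[mask].reset_index(drop=True),
            self.species,
        )

    def subset_mountain(self, mountain: str) -> "CommunityMatrix":
        mask = (self.row_meta["mountain"] == mountain).to_numpy()
        if not mask.any():
            raise SurveyValidationError(f"no plots on mountain {mountain!r}")
        sub = self.subset_rows(mask)
        keep = sub.col_sums() > 0
        return CommunityMatrix(
            sub.incidence[:, keep],
            sub.row_meta,
            [s for s, k in zip(sub.species, keep) if k],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"CommunityMatrix({self.n_plots} plots x {self.n_species} species)"


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------

def _detect_cover_dialect(values: pd.Series) -> str:
    """'percent' if any cover value exceeds 1, else 'proportion'."""
    return "percent" if (values > 1.0).any() else "proportion"


def read_records(path, cover_dialect: str | None = None) -> list[PlotRecord]:
    """Read long-format plot records from a delimited-text file.

    The file must have a header with the hierarchy columns, ``altitude_m``,
    ``cover``, and either a semicolon-separated ``species`` column or one
    binary 0/1 column per species (wide form).  Cover may be percent (0–100)
    or proportion (0–1); the dialect is auto-detected (any value > 1 implies
    percent) unless ``cover_dialect`` forces one.
    """
    df = pd.read_csv(path, comment="#")
    required = ["mountain", "transect", "station", "plot", "altitude_m", "cover"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"missing required column(s): {missing}")

    cover = pd.to_numeric(df["cover"], errors="raise").astype(float)
    dialect = cover_dialect or _detect_cover_dialect(cover)
    if dialect == "percent":
        if ((cover < 0) | (cover > 100)).any():
            raise SurveyValidationError("cover outside [0, 100] in percent dialect")
        cover = cover / 100.0
    elif dialect == "proportion":
        if ((cover < 0) | (cover > 1)).any():
            raise SurveyValidationError("cover outside [0, 1] in proportion dialect")
    else:
        raise ValueError(f"unknown cover dialect {dialect!r}")

    wide = "species" not in df.columns
    if wide:
        species_cols = [c for c in df.columns if c not in required]
        if not species_cols:
            raise SurveyFormatError(
                "need a 'species' column or per-species binary columns"
            )

    records: list[PlotRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    for i, row in df.iterrows():
        if wide:
            species = frozenset(
                c for c in species_cols if int(row[c]) == 1
            )
        else:
            raw = row["species"]
            raw = "" if pd.isna(raw) else str(raw)
            species = frozenset(s.strip() for s in raw.split(";") if s.strip())
        rec = PlotRecord(
            mountain=str(row["mountain"]),
            transect=str(row["transect"]),
            station=str(row["station"]),
            plot=str(row["plot"]),
            altitude=float(row["altitude_m"]),
            cover=float(cover.iloc[i]),
            species=species,
        )
        if rec.key() in seen:
            raise SurveyValidationError(
                f"duplicate (mountain, transect, station, plot) key: {rec.key()}"
            )
        seen.add(rec.key())
        records.append(rec)
    return records


def write_records(records: Iterable[PlotRecord], path, header_comment: str | None = None) -> None:
    """Write plot records in long form (proportion cover, ; species list)."""
    rows = [
        {
            "mountain": r.mountain,
            "transect": r.transect,
            "station": r.station,
            "plot": r.plot,
            "altitude_m": r.altitude,
            "cover": r.cover,
            "species": ";".join(sorted(r.species)),
        }
        for r in records
    ]
    _write_csv(pd.DataFrame(rows), path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_matrix(records: Sequence[PlotRecord]) -> CommunityMatrix:
    """Build the binary plot × species matrix from plot records.

    One row per record, in input order.  Columns are the species observed at
    least once, sorted by descending occurrence frequency, ties broken by
    label (stable, reproducible).  Species observed nowhere cannot arise from
    records and therefore never appear as columns.
    """
    records = list(records)
    if not records:
        raise SurveyValidationError("cannot build a matrix from zero records")
    freq: dict[str, int] = {}
    for r in records:
        for s in r.species:
            freq[s] = freq.get(s, 0) + 1
    species = sorted(freq, key=lambda s: (-freq[s], s))
    index = {s: j for j, s in enumerate(species)}
    incidence = np.zeros((len(records), len(species)), dtype=np.int8)
    for i, r in enumerate(records):
        for s in r.species:
            incidence[i, index[s]] = 1
    row_meta = pd.DataFrame(
        {
            "mountain": [r.mountain for r in records],
            "transect": [r.transect for r in records],
            "station": [r.station for r in records],
            "plot": [r.plot for r in records],
            "altitude_m": [r.altitude for r in records],
        }
    )
    return CommunityMatrix(incidence, row_meta, species)


def matrix_to_records(matrix: CommunityMatrix, cover: float = 0.0) -> list[PlotRecord]:
    """Reconstruct plot records from a matrix (cover is not stored in it)."""
    return [
        PlotRecord(
            mountain=str(m.mountain),
            transect=str(m.transect),
            station=str(m.station),
            plot=str(m.plot),
            altitude=float(m.altitude_m),
            cover=cover,
            species=sp,
        )
        for m, sp in zip(matrix.row_meta.itertuples(), matrix.species_sets())
    ]


def write_matrix(matrix: CommunityMatrix, path, header_comment: str | None = None) -> None:
    """Write the matrix as CSV: metadata columns then one 0/1 column per species."""
    sp = pd.DataFrame(matrix.incidence, columns=matrix.species)
    df = pd.concat([matrix.row_meta.reset_index(drop=True), sp], axis=1)
    _write_csv(df, path, header_comment)


def read_matrix(path, keep_empty_species: bool = False) -> CommunityMatrix:
    """Read a community matrix written by :func:`write_matrix`.

    Externally supplied matrices may contain all-zero species columns; these
    are dropped unless ``keep_empty_species`` is set (useful for exact
    round-tripping of external files).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"matrix file missing metadata column(s): {missing}")
    species = [c for c in df.columns if c not in _META_COLS]
    incidence = df[species].to_numpy()
    if not np.isin(incidence, (0, 1)).all():
        raise SurveyValidationError("matrix entries must be 0/1")
    if not keep_empty_species:
        keep = incidence.sum(axis=0) > 0
        incidence = incidence[:, keep]
        species = [s for s, k in zip(species, keep) if k]
    return CommunityMatrix(incidence.astype(np.int8), df[_META_COLS], species)


# ---------------------------------------------------------------------------
# intercept counts
# ---------------------------------------------------------------------------

def pool_station_counts(
    parts: Sequence[InterceptCounts], station: str | None = None
) -> InterceptCounts:
    """Pool per-plot intercept counts into one station total.

    All inputs must carry the same station label; counts are summed per
    species and sample points are summed (five 25-point plots give the
    design's 125 points per station).
    """
    parts = list(parts)
    if not parts:
        raise SurveyValidationError("nothing to pool")
    labels = {p.station for p in parts}
    if station is not None:
        labels.add(station)
    if len(labels) != 1:
        raise SurveyValidationError(f"mixed station labels in pool: {sorted(labels)}")
    counts: dict[str, int] = {}
    for p in parts:
        for s, c in p.counts.items():
            counts[s] = counts.get(s, 0) + int(c)
    return InterceptCounts(
        station=labels.pop(),
        counts=counts,
        n_points=sum(p.n_points for p in parts),
    )


def write_intercepts(
    intercepts: Iterable[InterceptCounts], path, header_comment: str | None = None
) -> None:
    """Write intercept counts in long form ``station,species,count,n_points``."""
    rows = []
    for ic in intercepts:
        for s in sorted(ic.counts):
            rows.append(
                {"station": ic.station, "species": s,
                 "count": ic.counts[s], "n_points": ic.n_points}
            )
        if not ic.counts:
            rows.append(
                {"station": ic.station, "species": "", "count": 0,
                 "n_points": ic.n_points}
            )
    _write_csv(pd.DataFrame(rows), path, header_comment)


def read_intercepts(path) -> list[InterceptCounts]:
    df = pd.read_csv(path, comment="#")
    required = ["station", "species", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"intercept file missing column(s): {missing}")
    out = []
    for station, grp in df.groupby("station", sort=False):
        counts = {
            str(r.species): int(r.count)
            for r in grp.itertuples()
            if isinstance(r.species, str) and r.species and r.count > 0
        }
        n_points = int(grp["n_points"].iloc[0]) if "n_points" in grp else 125
        out.append(InterceptCounts(str(station), counts, n_points))
    return out


# ---------------------------------------------------------------------------
# altitude bands
# ---------------------------------------------------------------------------

def assign_band(
    altitude: float, bands: Sequence[AltitudeBand] = DEFAULT_BANDS
) -> AltitudeBand:
    """Return the unique band containing the altitude (lower-inclusive)."""
    hits = [b for b in bands if b.contains(altitude)]
    if not hits:
        raise SurveyValidationError(f"altitude {altitude} m outside all bands")
    if len(hits) > 1:
        raise SurveyValidationError(f"altitude {altitude} m in overlapping bands")
    return hits[0]


def band_label(
    altitude: float, bands: Sequence[AltitudeBand] = DEFAULT_BANDS
) -> str:
    return assign_band(altitude, bands).label
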