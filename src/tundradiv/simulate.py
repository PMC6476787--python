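"""Synthetic altitude-gradient vegetation surveys.

Generates surveys with the statistical structure the downstream analysis
assumes, so every stage is testable without field data:

* Gaussian (bell-shaped) species niches along altitude, with a tunable split
  between wide-niche "core" species (which produce nested structure through
  heterogeneous occupancy) and narrow-niche specialists (which produce
  modular turnover along the gradient);
* nested random effects (mountain ⊃ transect ⊃ station) entering on the
  logit scale so occupancy probabilities stay in (0, 1);
* a unimodal vegetation-cover response to altitude on the logit scale;
* ITEX-style point-intercept counts (125 points per station) with "no touch"
  outcomes, so sparse high-altitude stations resemble field data.

The sampling design mirrors a 3-mountain survey: one 1 km transect per
mountain per elevation band, five stations per transect, five 1 m² plots per
station, 25 intercept points per plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .survey import (
    DEFAULT_BANDS,
    AltitudeBand,
    CommunityMatrix,
    InterceptCounts,
    PlotRecord,
    build_matrix,
)

__all__ = [
    "NicheSpec",
    "SimulationConfig",
    "SimulatedSurvey",
    "draw_pool",
    "simulate_survey",
    "expected_richness",
]

_PCLIP = 1e-9  # occupancy clamp before the logit link


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-np.asarray(p, dtype=float))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian altitude niche of one species."""

    species: str
    optimum: float  # niche centre, m a.s.l.
    tolerance: float  # niche SD, m
    max_occupancy: float  # occupancy probability at the optimum, in (0, 1]

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not 0 < self.max_occupancy <= 1:
            raise ValueError("max_occupancy must be in (0, 1]")

    def occupancy(self, altitude: float | np.ndarray) -> np.ndarray:
        """Occupancy probability at the given altitude (random effects at 0)."""
        z = (np.asarray(altitude, dtype=float) - self.optimum) / self.tolerance
        return self.max_occupancy * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants and generative knobs for one synthetic survey.

    The structural defaults reproduce the field design (3 mountains × 4
    elevation bands × 5 stations × 5 plots, 25 intercept points per plot);
    the generative defaults give a mid-gradient richness peak, moderate
    altitude turnover and station-level heterogeneity.
    """

    n_mountains: int = 3
    bands: tuple[AltitudeBand, ...] = DEFAULT_BANDS
    stations_per_transect: int = 5
    plots_per_station: int = 5
    points_per_plot: int = 25
    pool_size: int = 150
    #: log-scale location/spread of the baseline niche SD (metres);
    #: exp(5.0) ≈ 150 m, a moderately specialised tundra plant.
    niche_tolerance_log_mean: float = 5.0
    niche_tolerance_log_sd: float = 0.4
    #: fraction of wide-niche "core" species (nestedness knob);
    #: their tolerances are inflated 4-fold.
    core_fraction: float = 0.25
    #: shrink factor on specialist tolerances (modularity knob).
    turnover_strength: float = 2.0
    cover_peak_alt: float = 850.0  # m; unimodal cover maximum
    cover_peak_value: float = 0.6  # proportion at the peak
    cover_curvature: float = 6e-6  # logit decay per m² from the peak
    cover_noise_sd: float = 0.4  # logit-scale plot noise
    # nested random-intercept SDs on the logit-occupancy scale
    sd_mountain: float = 0.2
    sd_transect: float = 0.3
    sd_station: float = 0.5
    #: log-normal SD of per-species intercept-abundance weights
    abundance_log_sd: float = 1.0
    #: drop the top-band transect of the last mountain (11-transect design)
    drop_one_transect: bool = False
    top_band_span: float = 200.0  # sampled depth of the open top band, m
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mountains", "stations_per_transect", "plots_per_station",
            "points_per_plot", "pool_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("core_fraction", "cover_peak_value"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.turnover_strength <= 0:
            raise ValueError("turnover_strength must be > 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def n_transects(self) -> int:
        n = self.n_mountains * len(self.bands)
        return n - 1 if self.drop_one_transect else n

    @property
    def n_plots(self) -> int:
        return self.n_transects * self.stations_per_transect * self.plots_per_station

    def altitude_range(self) -> tuple[float, float]:
        """Range over which niche optima are spread: band floor − 100 m to
        the deepest sampled altitude + 100 m."""
        lo = min(b.lower for b in self.bands) - 100.0
        hi = max(
            b.lower + self.top_band_span if math.isinf(b.upper) else b.upper
            for b in self.bands
        ) + 100.0
        return lo, hi


@dataclass(frozen=True)
class SimulatedSurvey:
    """Generated records plus the generating truth (niches, random effects)."""

    config: SimulationConfig
    records: list[PlotRecord]
    intercepts: list[InterceptCounts]
    pool: list[NicheSpec]
    random_effects: dict[str, float] = field(default_factory=dict)

    def matrix(self) -> CommunityMatrix:
        return build_matrix(self.records)


def draw_pool(config: SimulationConfig, rng: np.random.Generator) -> list[NicheSpec]:
    """Draw the species pool.

    The first ``round(core_fraction · pool_size)`` species are wide-niche
    core species (baseline tolerance × 4); the rest are specialists
    (baseline tolerance / turnover_strength).  All optima are uniform over
    the sampled altitude range padded by 100 m.
    """
    lo, hi = config.altitude_range()
    n_core = int(round(config.core_fraction * config.pool_size))
    base_tol = rng.lognormal(
        config.niche_tolerance_log_mean,
        config.niche_tolerance_log_sd,
        size=config.pool_size,
    )
    optima = rng.uniform(lo, hi, size=config.pool_size)
    max_occ = rng.uniform(0.05, 0.95, size=config.pool_size)
    width = len(str(config.pool_size))
    pool = []
    for i in range(config.pool_size):
        tol = base_tol[i] * 4.0 if i < n_core else base_tol[i] / config.turnover_strength
        pool.append(
            NicheSpec(
                species=f"sp{i + 1:0{width}d}",
                optimum=float(optima[i]),
                tolerance=float(tol),
                max_occupancy=float(max_occ[i]),
            )
        )
    return pool


def expected_richness(pool: Sequence[NicheSpec], altitude: float) -> float:
    """Expected per-plot species count at an altitude, random effects at 0.

    The logit link with clamped input is the identity on (0, 1), so this is
    simply the sum of per-species occupancy probabilities.
    """
    p = np.array([s.occupancy(altitude) for s in pool])
    return float(np.clip(p, _PCLIP, 1 - _PCLIP).sum())


def _transect_base_altitude(band: AltitudeBand, span: float, rng: np.random.Generator) -> float:
    upper = band.lower + span if math.isinf(band.upper) else band.upper
    margin = min(40.0, (upper - band.lower) / 4)
    return float(rng.uniform(band.lower + margin, upper - margin))


def simulate_survey(config: SimulationConfig) -> SimulatedSurvey:
    """Generate one complete survey from a config; the seed fixes everything.

    Per-plot presence of species *s* is Bernoulli with probability
    ``expit(logit(clamp(occupancy_s(alt))) + u_mountain + u_transect +
    u_station)``.  Cover is an inverse-logit quadratic in altitude peaking at
    ``cover_peak_alt`` with value ``cover_peak_value``, plus logit-scale
    noise.  Each station's 125 intercept points touch a present species with
    probability equal to the station's mean cover, the species drawn
    proportionally to a per-species log-normal abundance weight; otherwise
    the point records no touch.

    Sub-streams are split per mountain so output is invariant to plot
    ordering within the generation loop.
    """
    root = np.random.SeedSequence(config.seed)
    pool_ss, effects_ss, *mountain_ss = root.spawn(2 + config.n_mountains)
    pool = draw_pool(config, np.random.default_rng(pool_ss))
    abundance = np.random.default_rng(effects_ss).lognormal(
        0.0, config.abundance_log_sd, size=config.pool_size
    )
    optima = np.array([s.optimum for s in pool])
    tols = np.array([s.tolerance for s in pool])
    max_occ = np.array([s.max_occupancy for s in pool])
    species_labels = np.array([s.species for s in pool], dtype=object)

    records: list[PlotRecord] = []
    intercepts: list[InterceptCounts] = []
    effects: dict[str, float] = {}
    logit_peak = float(_logit(config.cover_peak_value))

    for mi in range(config.n_mountains):
        mname = f"M{mi + 1}"
        mrng = np.random.default_rng(mountain_ss[mi])
        u_m = mrng.normal(0.0, config.sd_mountain)
        effects[mname] = float(u_m)
        for bi, band in enumerate(config.bands):
            if (
                config.drop_one_transect
                and mi == config.n_mountains - 1
                and bi == len(config.bands) - 1
            ):
                continue  # the unsampled highest-elevation transect
            tname = f"T{bi + 1}"
            u_t = mrng.normal(0.0, config.sd_transect)
            effects[f"{mname}:{tname}"] = float(u_t)
            base_alt = _transect_base_altitude(band, config.top_band_span, mrng)
            for si in range(config.stations_per_transect):
                sname = f"S{si + 1}"
                u_s = mrng.normal(0.0, config.sd_station)
                effects[f"{mname}:{tname}:{sname}"] = float(u_s)
                # stations along one transect sit at nearly the same altitude
                alt = float(np.clip(
                    base_alt + mrng.normal(0.0, 15.0),
                    band.lower,
                    np.nextafter(band.upper, -np.inf)
                    if math.isfinite(band.upper)
                    else band.lower + 2 * config.top_band_span,
                ))
                z = (alt - optima) / tols
                occ = np.clip(max_occ * np.exp(-0.5 * z * z), _PCLIP, 1 - _PCLIP)
                eta0 = _logit(occ) + u_m + u_t + u_s
                p_presence = _expit(eta0)
                station_recs = []
                for pi in range(config.plots_per_station):
                    present = mrng.random(config.pool_size) < p_presence
                    cov_eta = (
                        logit_peak
                        - config.cover_curvature * (alt - config.cover_peak_alt) ** 2
                        + mrng.normal(0.0, config.cover_noise_sd)
                    )
                    station_recs.append(
                        PlotRecord(
                            mountain=mname,
                            transect=tname,
                            station=sname,
                            plot=f"P{pi + 1}",
                            altitude=alt,
                            cover=float(_expit(cov_eta)),
                            species=frozenset(species_labels[present]),
                        )
                    )
                records.extend(station_recs)
                intercepts.append(
                    _station_intercepts(
                        station_recs, species_labels, abundance, config, mrng
                    )
                )
    return SimulatedSurvey(
        config=config,
        records=records,
        intercepts=intercepts,
        pool=pool,
        random_effects=effects,
    )


def _station_intercepts(
    station_recs: list[PlotRecord],
    species_labels: np.ndarray,
    abundance: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> InterceptCounts:
    present_union: set[str] = set()
    for r in station_recs:
        present_union.update(r.species)
    mean_cover = float(np.mean([r.cover for r in station_recs]))
    n_points = config.points_per_plot * len(station_recs)
    rec = station_recs[0]
    station_id = f"{rec.mountain}:{rec.transect}:{rec.station}"
    if not present_union:
        return InterceptCounts(station_id, {}, n_points)
    idx = np.array([i for i, s in enumerate(species_labels) if s in present_union])
    weights = abundance[idx]
    weights = weights / weights.sum()
    counts: dict[str, int] = {}
    n_touch = int(rng.binomial(n_points, mean_cover))
    if n_touch:
        draws = rng.choice(len(idx), size=n_touch, p=weights)
        for k in draws:
            s = str(species_labels[idx[k]])
            counts[s] = counts.get(s, 0) + 1
    return InterceptCounts(station_id, counts, n_points)
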