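"""End-to-end orchestration: run every analysis stage on real or simulated data.

Stages (each writes CSV tables with a header comment carrying the seed,
config hash and stage name):

* ``alpha`` — plot-level cover (raw + logit) and richness, station-level
  scaled Shannon evenness;
* ``beta`` — the three-scale centroid-distance table;
* ``trends`` — altitude trend models: cover (Gaussian, logit), richness
  (Poisson GLMM), evenness (Gaussian), beta diversity (scale × altitude
  interaction), with linear-vs-quadratic LRTs and Tukey scale contrasts;
* ``metacom`` — the nestedness/modularity grid with null-model inference,
  plus incidence-matrix images.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import diversity, metacom, models, nullmodels, survey
from .simulate import SimulationConfig, simulate_survey
from .survey import AltitudeBand, CommunityMatrix, DEFAULT_BANDS

logger = logging.getLogger("tundradiv")

__all__ = ["RunConfig", "run_pipeline", "alpha_tables", "trend_tables"]


@dataclass
class RunConfig:
    """One pipeline run: either input files or a simulation, never both."""

    records_path: str | None = None
    intercepts_path: str | None = None
    matrix_path: str | None = None
    simulation: SimulationConfig | None = None
    bands: tuple[AltitudeBand, ...] = DEFAULT_BANDS
    n_reps: int = 200
    seed: int = 0
    outdir: str = "tundradiv_out"
    stages: tuple[str, ...] = ("alpha", "beta", "trends", "metacom")
    render_images: bool = True
    brim_restarts: int = 20
    null_brim_restarts: int = 5

    def __post_init__(self) -> None:
        has_files = any([self.records_path, self.matrix_path])
        if has_files == (self.simulation is not None):
            raise ValueError(
                "supply exactly one of input paths or a simulation config"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        ``simulation`` holds SimulationConfig fields; ``band_edges`` is a
        list of ascending lower edges, the last band open-topped.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", None)
        if sim is not None:
            data["simulation"] = SimulationConfig(**sim)
        edges = data.pop("band_edges", None)
        if edges:
            bands = [
                AltitudeBand(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])
            ]
            bands.append(AltitudeBand(edges[-1], np.inf))
            data["bands"] = tuple(bands)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        # outdir is incidental to the analysis, so it stays out of the hash
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(self.__dict__.items())
             if k != "outdir"},
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig, stage: str) -> str:
    return (
        f"seed={config.seed} config_hash={config.config_hash()} stage={stage}"
    )


# ---------------------------------------------------------------------------
# stage computations (pure: DataFrames in, DataFrames out)
# ---------------------------------------------------------------------------

def alpha_tables(
    records: Sequence[survey.PlotRecord],
    intercepts: Sequence[survey.InterceptCounts] | None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Plot-level alpha diversity and station-level evenness tables."""
    plot_tbl = pd.DataFrame(
        {
            "mountain": [r.mountain for r in records],
            "transect": [r.transect for r in records],
            "station": [r.station for r in records],
            "plot": [r.plot for r in records],
            "altitude_m": [r.altitude for r in records],
            "cover": [r.cover for r in records],
            "cover_logit": [diversity.logit_cover(r.cover) for r in records],
            "richness": [r.richness for r in records],
        }
    )
    if intercepts is None:
        return plot_tbl, None
    station_alt = (
        plot_tbl.assign(
            station_id=plot_tbl["mountain"] + ":" + plot_tbl["transect"]
            + ":" + plot_tbl["station"]
        )
        .groupby("station_id")
        .agg(altitude_m=("altitude_m", "mean"))
    )
    rows = []
    for ic in intercepts:
        if ic.total_touches == 0:
            continue  # barren station: evenness undefined
        ev = diversity.scaled_shannon(ic.counts, station=ic.station)
        parts = ic.station.split(":")
        mountain, transect, station = (parts + ["", "", ""])[:3]
        rows.append(
            {
                "mountain": mountain,
                "transect": transect,
                "station": station,
                "station_id": ic.station,
                "altitude_m": float(station_alt["altitude_m"].get(ic.station, np.nan)),
                "H": ev.H,
                "S": ev.S,
                "evenness": ev.J,
                "n_points": ic.n_points,
                "touches": ic.total_touches,
            }
        )
    return plot_tbl, pd.DataFrame(rows)


def trend_tables(
    plot_tbl: pd.DataFrame,
    evenness_tbl: pd.DataFrame | None,
    distances: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Fit all altitude trend models and return result tables."""
    coef_rows, lrt_rows = [], []

    def record(response: str, fit: models.MixedAltitudeModel):
        for row in fit.coefficients_.itertuples():
            coef_rows.append(
                {
                    "response": response,
                    "term": row.term,
                    "estimate": row.estimate,
                    "se": row.se,
                    "z": row.z,
                    "p": row.p,
                    "converged": fit.converged_,
                }
            )

    cover_fit = models.MixedAltitudeModel(
        "cover_logit", 2, "gaussian", models.NESTING_THREE
    ).fit(plot_tbl)
    record("cover_logit", cover_fit)
    lrt = models.lrt_quadratic(models.ModelSpec("cover_logit"), plot_tbl)
    lrt_rows.append({"response": "cover_logit", "chi_square": lrt.chi_square,
                     "df": lrt.df, "p": lrt.p})

    rich_fit = models.MixedAltitudeModel(
        "richness", 2, "poisson", models.NESTING_THREE
    ).fit(plot_tbl)
    record("richness", rich_fit)
    lrt = models.lrt_quadratic(
        models.ModelSpec("richness", family="poisson"), plot_tbl
    )
    lrt_rows.append({"response": "richness", "chi_square": lrt.chi_square,
                     "df": lrt.df, "p": lrt.p})

    if evenness_tbl is not None and len(evenness_tbl) >= 6:
        ev_fit = models.MixedAltitudeModel(
            "evenness", 1, "gaussian", models.NESTING_TWO
        ).fit(evenness_tbl)
        record("evenness", ev_fit)
        lrt = models.lrt_quadratic(
            models.ModelSpec("evenness", nesting=models.NESTING_TWO), evenness_tbl
        )
        lrt_rows.append({"response": "evenness", "chi_square": lrt.chi_square,
                         "df": lrt.df, "p": lrt.p})

    # beta diversity: merge plot hierarchy back onto the distance table
    key = plot_tbl.assign(
        plot_key=plot_tbl["mountain"] + ":" + plot_tbl["transect"] + ":"
        + plot_tbl["station"] + ":" + plot_tbl["plot"]
    )[["plot_key", "mountain", "transect", "station", "altitude_m"]]
    beta = distances.merge(key, left_on="plot", right_on="plot_key", how="left")
    sfit = models.scale_interaction_fit(beta)
    lrt_rows.append(
        {"response": "beta_distance:interaction",
         "chi_square": sfit.interaction_lrt.chi_square,
         "df": sfit.interaction_lrt.df, "p": sfit.interaction_lrt.p}
    )
    subset_rows = []
    for scale, fit in sfit.subset_fits.items():
        for row in fit.coefficients_.itertuples():
            subset_rows.append(
                {"scale": scale, "term": row.term, "estimate": row.estimate,
                 "se": row.se, "z": row.z, "p": row.p}
            )
    contrast_rows = [
        {"scale_a": c.pair[0], "scale_b": c.pair[1], "difference": c.difference,
         "se": c.se, "t": c.t, "df": c.df, "p_tukey": c.p_tukey}
        for c in models.tukey_scale_contrasts(sfit)
    ]
    return {
        "trend_models": pd.DataFrame(coef_rows),
        "lrt": pd.DataFrame(lrt_rows),
        "beta_subset_models": pd.DataFrame(subset_rows),
        "scale_contrasts": pd.DataFrame(contrast_rows),
    }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = simulate_survey(config.simulation)
        return sim.records, sim.intercepts, sim.matrix()
    records = intercepts = matrix = None
    if config.records_path:
        records = survey.read_records(config.records_path)
        matrix = survey.build_matrix(records)
    if config.matrix_path:
        matrix = survey.read_matrix(config.matrix_path)
        if records is None:
            records = survey.matrix_to_records(matrix)
    if config.intercepts_path:
        intercepts = survey.read_intercepts(config.intercepts_path)
    return records, intercepts, matrix


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the output directory.

    Any stage failure raises with the stage name; tables already written are
    retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    logger.info("run start seed=%s hash=%s stages=%s",
                config.seed, config.config_hash(), config.stages)
    try:
        records, intercepts, matrix = _load_inputs(config)
        if matrix is None:
            raise FileNotFoundError("no records or matrix input available")
        if config.simulation is not None:
            survey.write_records(records, out / "records.csv",
                                 _header(config, "simulate"))
            if intercepts:
                survey.write_intercepts(intercepts, out / "intercepts.csv",
                                        _header(config, "simulate"))
            survey.write_matrix(matrix, out / "matrix.csv",
                                _header(config, "simulate"))
        plot_tbl = evenness_tbl = distances = None
        if "alpha" in config.stages:
            stage = "alpha"
            plot_tbl, evenness_tbl = alpha_tables(records, intercepts)
            survey._write_csv(plot_tbl, out / "alpha_plots.csv",
                              _header(config, stage))
            if evenness_tbl is not None:
                survey._write_csv(evenness_tbl, out / "alpha_evenness.csv",
                                  _header(config, stage))
            logger.info("alpha done: %d plots", len(plot_tbl))
        if "beta" in config.stages:
            stage = "beta"
            distances = diversity.beta_diversity_all_scales(matrix, config.bands)
            n_clamped = int(distances["clamped"].sum())
            if n_clamped:
                logger.info("beta: %d negative squared distances clamped", n_clamped)
            survey._write_csv(distances, out / "beta_distances.csv",
                              _header(config, stage))
            logger.info("beta done: %d rows", len(distances))
        if "trends" in config.stages:
            stage = "trends"
            if plot_tbl is None:
                plot_tbl, evenness_tbl = alpha_tables(records, intercepts)
            if distances is None:
                distances = diversity.beta_diversity_all_scales(matrix, config.bands)
            for name, tbl in trend_tables(plot_tbl, evenness_tbl, distances).items():
                survey._write_csv(tbl, out / f"{name}.csv", _header(config, stage))
            logger.info("trends done")
        if "metacom" in config.stages:
            stage = "metacom"
            tbl = nullmodels.table1_analysis(
                matrix, n_reps=config.n_reps, seed=config.seed,
                bands=config.bands, brim_restarts=config.brim_restarts,
                null_brim_restarts=config.null_brim_restarts,
            )
            survey._write_csv(tbl, out / "metacommunity.csv", _header(config, stage))
            if config.render_images:
                metacom.render_incidence(
                    matrix, metacom.optimal_nestedness_ordering(matrix),
                    out / "incidence_optimal_nestedness.png")
                metacom.render_incidence(
                    matrix, metacom.altitude_ordering(matrix),
                    out / "incidence_altitude.png")
                metacom.render_incidence(
                    matrix, metacom.reciprocal_averaging_ordering(matrix),
                    out / "incidence_optimal_modularity.png")
            logger.info("metacom done: %d rows", len(tbl))
        logger.info("run complete in %.1f s", time.time() - t0)
    except Exception as err:
        logger.error("stage failed: %s", err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
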