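"""Altitude trend models with nested random effects.

Responses are modelled against a linear or quadratic altitude polynomial
with nested random intercepts:

* logit cover and centroid distances — Gaussian mixed models (station
  nested in transect nested in mountain), fitted by ML through statsmodels
  MixedLM;
* station evenness — Gaussian, transect nested in mountain;
* plot richness — Poisson GLMM with a log link, fitted by a
  Laplace-approximation ML routine implemented here (profile over the
  random-effect standard deviations, joint Newton optimisation of fixed
  effects and random-effect modes), so that a genuine marginal
  log-likelihood is available for likelihood-ratio tests.

Altitude is mean-centred internally to tame collinearity between the linear
and quadratic terms; reported coefficients are back-transformed to the
raw-altitude parameterisation (delta-method standard errors), so signs and
magnitudes read directly in metres.  Linear-vs-quadratic comparisons use
likelihood-ratio tests on ML fits with identical random structure.
Pairwise scale differences in beta diversity use Tukey-adjusted contrasts
of estimated marginal means at the mean altitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "LRTResult",
    "ContrastResult",
    "MixedAltitudeModel",
    "fit_mixed",
    "lrt_quadratic",
    "likelihood_ratio",
    "scale_interaction_fit",
    "tukey_scale_contrasts",
    "ConvergenceError",
]

NESTING_THREE = ("mountain", "transect", "station")
NESTING_TWO = ("mountain", "transect")


class ConvergenceError(RuntimeError):
    """A mixed-model fit failed to converge after all restarts."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, altitude polynomial degree, family, nesting."""

    response: str
    degree: int = 2
    family: str = "gaussian"  # or "poisson"
    nesting: tuple[str, ...] = NESTING_THREE

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.family not in ("gaussian", "poisson"):
            raise ValueError("family must be 'gaussian' or 'poisson'")


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p: float


@dataclass(frozen=True)
class ContrastResult:
    pair: tuple[str, str]
    difference: float
    se: float
    t: float
    df: int
    p_tukey: float


# ---------------------------------------------------------------------------
# shared design helpers
# ---------------------------------------------------------------------------

def _prepare(data: pd.DataFrame, nesting: Sequence[str], altitude: str) -> pd.DataFrame:
    df = data.copy()
    if altitude not in df.columns:
        raise ValueError(f"missing altitude column {altitude!r}")
    # fully qualified nested group labels so identically named subunits on
    # different mountains stay distinct
    prev = None
    for level in nesting:
        if level not in df.columns:
            raise ValueError(f"missing nesting column {level!r}")
        col = df[level].astype(str)
        qual = col if prev is None else df[prev] + ":" + col
        df[f"_g_{level}"] = qual
        prev = f"_g_{level}"
    m = df[altitude].mean()
    df["_alt_c"] = df[altitude] - m
    df["_alt_c2"] = df["_alt_c"] ** 2
    df.attrs["alt_mean"] = float(m)
    return df


def _raw_scale_coefficients(
    names: list[str], beta: np.ndarray, cov: np.ndarray, m: float
) -> pd.DataFrame:
    """Back-transform centred-altitude coefficients to the raw scale."""
    idx = {n: i for i, n in enumerate(names)}
    i0 = idx.get("Intercept")
    i1 = idx.get("_alt_c")
    i2 = idx.get("_alt_c2")
    rows = []

    def wald_row(term, grad):
        g = np.zeros(len(names))
        for i, w in grad:
            g[i] = w
        est = float(g @ beta)
        se = float(np.sqrt(g @ cov @ g))
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"term": term, "estimate": est, "se": se, "z": z, "p": p})

    if i2 is not None:
        wald_row("(Intercept)", [(i0, 1.0), (i1, -m), (i2, m * m)])
        wald_row("altitude", [(i1, 1.0), (i2, -2 * m)])
        wald_row("altitude_sq", [(i2, 1.0)])
    elif i1 is not None:
        wald_row("(Intercept)", [(i0, 1.0), (i1, -m)])
        wald_row("altitude", [(i1, 1.0)])
    else:
        wald_row("(Intercept)", [(i0, 1.0)])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian backend: statsmodels MixedLM (ML)
# ---------------------------------------------------------------------------

_OPTIMIZERS = ("lbfgs", "bfgs", "powell", "cg")


def _fit_mixedlm(formula: str, df: pd.DataFrame, nesting: Sequence[str],
                 thorough: bool = False):
    """ML MixedLM with nested random intercepts.

    Optimizers are tried in turn; with ``thorough`` every optimizer runs and
    the best converged log-likelihood wins (used when a likelihood-ratio
    comparison lands in a local optimum).
    """
    groups = df[f"_g_{nesting[0]}"]
    vc = {
        level: f"0 + C(_g_{level})" for level in nesting[1:]
    }
    best = None
    last_err = None
    for method in _OPTIMIZERS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = smf.mixedlm(
                    formula, df, groups=groups, vc_formula=vc or None,
                    re_formula="1",
                )
                res = model.fit(reml=False, method=method, maxiter=500)
            if res.converged and np.isfinite(res.llf):
                if not thorough:
                    return res, True
                if best is None or res.llf > best.llf:
                    best = res
            else:
                last_err = res
        except Exception as err:  # noqa: BLE001 - keep trying optimizers
            last_err = err
    if best is not None:
        return best, True
    if hasattr(last_err, "llf") and np.isfinite(getattr(last_err, "llf", np.nan)):
        return last_err, False
    raise ConvergenceError(f"MixedLM failed for {formula!r}: {last_err}")


def _mixedlm_vc(res, nesting: Sequence[str]) -> dict[str, float]:
    vc = {nesting[0]: float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0}
    for name, val in zip(nesting[1:], np.atleast_1d(res.vcomp)):
        vc[name] = float(val)
    vc["residual"] = float(res.scale)
    return vc


# ---------------------------------------------------------------------------
# Poisson backend: Laplace-approximation ML
# ---------------------------------------------------------------------------

class _PoissonLaplace:
    """ML Poisson GLMM with independent nested random intercepts.

    For fixed log-SDs θ, fixed effects β and random-effect modes b are found
    by a joint damped Newton step on the penalised log-likelihood; the
    marginal log-likelihood is the Laplace approximation
    ℓ(y|η̂) − ½ b̂ᵀD⁻¹b̂ − ½ log|D| − ½ log|ZᵀWZ + D⁻¹|.
    θ is then profiled out with Nelder–Mead.
    """

    THETA_MIN, THETA_MAX = -8.0, 3.0

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 level_codes: list[np.ndarray], level_names: list[str]):
        self.X = X
        self.y = y.astype(float)
        self.level_names = level_names
        self.n, self.p = X.shape
        self.sizes = [int(c.max()) + 1 for c in level_codes]
        self.q = int(sum(self.sizes))
        Z = np.zeros((self.n, self.q))
        off = 0
        self.level_slices = []
        for codes, q_l in zip(level_codes, self.sizes):
            Z[np.arange(self.n), off + codes] = 1.0
            self.level_slices.append(slice(off, off + q_l))
            off += q_l
        self.C = np.hstack([X, Z])
        self.Z = Z
        self._const = float(-gammaln(self.y + 1).sum())

    def _dinv(self, theta: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for th, sl in zip(theta, self.level_slices):
            d[sl] = np.exp(-2.0 * th)
        return d

    def _inner(self, theta: np.ndarray, u0: np.ndarray | None = None):
        dinv = self._dinv(theta)
        pen = np.concatenate([np.zeros(self.p), dinv])
        u = np.zeros(self.p + self.q) if u0 is None else u0.copy()
        if u0 is None:
            u[0] = np.log(self.y.mean() + 0.5)  # intercept warm start

        def pll(uv):
            eta = self.C @ uv
            return float(self.y @ eta - np.exp(eta).sum()
                         - 0.5 * (pen * uv * uv).sum())

        cur = pll(u)
        for _ in range(100):
            eta = self.C @ u
            mu = np.exp(np.clip(eta, -30, 30))
            grad = self.C.T @ (self.y - mu) - pen * u
            H = (self.C.T * mu) @ self.C
            H[np.arange(self.p + self.q), np.arange(self.p + self.q)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = u + t * step
                val = pll(cand)
                if val >= cur - 1e-12:
                    break
                t *= 0.5
            if val < cur + 1e-10:
                u = cand
                cur = val
                break
            u, cur = cand, val
        return u, cur, H

    def marginal_ll(self, theta: np.ndarray, u0=None):
        u, pen_ll, H = self._inner(theta, u0)
        dinv = self._dinv(theta)
        Hbb = H[self.p:, self.p:]
        sign, logdet = np.linalg.slogdet(Hbb)
        if sign <= 0:
            return -np.inf, u, H
        logdetD = -np.log(dinv).sum()
        ll = pen_ll + self._const - 0.5 * logdetD - 0.5 * logdet
        return ll, u, H

    def fit(self, thorough: bool = False):
        n_levels = len(self.sizes)
        warm = {"u": None}

        def neg(theta):
            theta = np.clip(theta, self.THETA_MIN, self.THETA_MAX)
            ll, u, _ = self.marginal_ll(theta, warm["u"])
            warm["u"] = u
            return -ll if np.isfinite(ll) else 1e12

        starts = [np.full(n_levels, np.log(0.3)), np.full(n_levels, np.log(0.05))]
        if thorough:
            starts += [np.full(n_levels, np.log(1.0)), np.full(n_levels, -6.0)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg, x0, method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = np.clip(best.x, self.THETA_MIN, self.THETA_MAX)
        ll, u, H = self.marginal_ll(theta, warm["u"])
        cov = np.linalg.inv(H)[: self.p, : self.p]
        vc = {name: float(np.exp(2 * th))
              for name, th in zip(self.level_names, theta)}
        return {
            "beta": u[: self.p],
            "cov_beta": cov,
            "loglik": float(ll),
            "vc": vc,
            "converged": bool(best.success or np.isfinite(ll)),
            "modes": u[self.p:],
        }


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class MixedAltitudeModel(BaseEstimator):
    """Mixed model of a response against an altitude polynomial.

    Parameters
    ----------
    response : response column name.
    degree : altitude polynomial degree, 1 or 2.
    family : "gaussian" (MixedLM, ML) or "poisson" (Laplace-ML GLMM).
    nesting : random-intercept levels, outermost first.
    altitude : altitude column name (metres).

    Attributes (after ``fit``)
    --------------------------
    coefficients_ : DataFrame (term, estimate, se, z, p) on the raw altitude
        scale.
    loglik_ : ML (or Laplace-ML) log-likelihood.
    vc_ : variance components per random level (+ residual when Gaussian).
    peak_altitude_ : −β₁/(2β₂) for quadratic fits (the fitted optimum), with
        a warning when outside the sampled range.
    """

    def __init__(
        self,
        response: str = "y",
        degree: int = 2,
        family: str = "gaussian",
        nesting: tuple[str, ...] = NESTING_THREE,
        altitude: str = "altitude_m",
        thorough: bool = False,
    ):
        self.response = response
        self.degree = degree
        self.family = family
        self.nesting = nesting
        self.altitude = altitude
        self.thorough = thorough

    def fit(self, data: pd.DataFrame, y=None) -> "MixedAltitudeModel":
        ModelSpec(self.response, self.degree, self.family, tuple(self.nesting))
        if self.response not in data.columns:
            raise ValueError(f"missing response column {self.response!r}")
        df = _prepare(data, self.nesting, self.altitude)
        m = df.attrs["alt_mean"]
        terms = ["_alt_c"] + (["_alt_c2"] if self.degree == 2 else [])
        if self.family == "gaussian":
            formula = f"{self.response} ~ " + " + ".join(terms)
            res, converged = _fit_mixedlm(formula, df, self.nesting,
                                          thorough=self.thorough)
            names = list(res.fe_params.index)
            beta = res.fe_params.to_numpy()
            cov = res.cov_params().loc[names, names].to_numpy()
            self.loglik_ = float(res.llf)
            self.vc_ = _mixedlm_vc(res, self.nesting)
            self.converged_ = converged
            self.result_ = res
        else:
            X = np.column_stack(
                [np.ones(len(df))] + [df[t].to_numpy() for t in terms]
            )
            names = ["Intercept"] + terms
            codes = [
                pd.factorize(df[f"_g_{lev}"])[0] for lev in self.nesting
            ]
            y_ = df[self.response].to_numpy()
            if (y_ < 0).any() or not np.allclose(y_, np.round(y_)):
                raise ValueError("poisson family needs non-negative counts")
            fitter = _PoissonLaplace(X, y_, codes, list(self.nesting))
            out = fitter.fit(thorough=self.thorough)
            beta, cov = out["beta"], out["cov_beta"]
            self.loglik_ = out["loglik"]
            self.vc_ = out["vc"]
            self.converged_ = out["converged"]
            self.result_ = out
        if not self.converged_:
            warnings.warn(
                f"mixed model for {self.response!r} flagged as non-converged",
                RuntimeWarning,
                stacklevel=2,
            )
        self.alt_mean_ = m
        self.n_obs_ = len(df)
        self.coefficients_ = _raw_scale_coefficients(names, beta, cov, m)
        self._centered = dict(zip(names, beta))
        if self.degree == 2:
            b2 = self.coefficients_.set_index("term").loc["altitude_sq", "estimate"]
            b1 = self.coefficients_.set_index("term").loc["altitude", "estimate"]
            self.peak_altitude_ = float(-b1 / (2 * b2)) if b2 != 0 else np.nan
            lo, hi = data[self.altitude].min(), data[self.altitude].max()
            if not lo <= self.peak_altitude_ <= hi:
                warnings.warn(
                    f"fitted quadratic vertex {self.peak_altitude_:.0f} m lies "
                    "outside the sampled altitude range",
                    RuntimeWarning,
                    stacklevel=2,
                )
        return self

    def predict(self, altitudes: np.ndarray) -> np.ndarray:
        """Population-level linear predictor at given raw altitudes."""
        a = np.asarray(altitudes, dtype=float) - self.alt_mean_
        eta = np.full(a.shape, self._centered.get("Intercept", 0.0))
        eta += self._centered.get("_alt_c", 0.0) * a
        eta += self._centered.get("_alt_c2", 0.0) * a * a
        return np.exp(eta) if self.family == "poisson" else eta


def fit_mixed(spec: ModelSpec, data: pd.DataFrame,
              altitude: str = "altitude_m") -> MixedAltitudeModel:
    """Fit a :class:`MixedAltitudeModel` from a :class:`ModelSpec`."""
    return MixedAltitudeModel(
        response=spec.response, degree=spec.degree, family=spec.family,
        nesting=spec.nesting, altitude=altitude,
    ).fit(data)


def lrt_quadratic(spec: ModelSpec, data: pd.DataFrame,
                  altitude: str = "altitude_m") -> LRTResult:
    """Likelihood-ratio test of the quadratic vs the linear altitude model.

    Both fits use ML and the identical random structure; χ² = 2Δℓ with 1 df.
    A small negative Δℓ (convergence noise) is clamped to 0; a large one
    raises after restarts.
    """
    def pair(thorough: bool):
        full = MixedAltitudeModel(
            spec.response, 2, spec.family, spec.nesting, altitude,
            thorough=thorough,
        ).fit(data)
        reduced = MixedAltitudeModel(
            spec.response, 1, spec.family, spec.nesting, altitude,
            thorough=thorough,
        ).fit(data)
        return 2.0 * (full.loglik_ - reduced.loglik_)

    chi2 = pair(thorough=False)
    if chi2 < -1e-6:  # local optimum somewhere: refit with multiple starts
        chi2 = pair(thorough=True)
    return likelihood_ratio(chi2 / 2.0, 0.0, df=1)


def likelihood_ratio(ll_full: float, ll_reduced: float, df: int = 1,
                     tol: float = 1e-3) -> LRTResult:
    """χ² = 2(ℓ_full − ℓ_reduced) against the χ²_df upper tail.

    Identical fits give χ² = 0 and p = 1; a Δℓ below −tol (the nested model
    apparently fitting better) raises, smaller negatives clamp to 0 as
    convergence noise.
    """
    chi2 = 2.0 * (ll_full - ll_reduced)
    if chi2 < -2 * tol:
        raise ConvergenceError(
            f"full-model log-likelihood below reduced fit (Δ={chi2 / 2:.4g})"
        )
    chi2 = max(chi2, 0.0)
    return LRTResult(chi_square=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# scale × altitude interaction and Tukey contrasts
# ---------------------------------------------------------------------------

@dataclass
class ScaleInteractionFit:
    """Full interaction model over the three beta-diversity scales.

    ``result`` is the statsmodels MixedLM ML fit of
    ``distance ~ (alt + alt²) * scale`` with station-in-transect-in-mountain
    random intercepts; ``subset_fits`` maps each scale to its own quadratic
    altitude fit; ``interaction_lrt`` compares the full model against the
    additive (no interaction) one.
    """

    result: object
    converged: bool
    subset_fits: dict[str, MixedAltitudeModel]
    interaction_lrt: LRTResult
    scales: tuple[str, ...]
    n_obs: int
    resid_df: int
    alt_mean: float


def scale_interaction_fit(
    distances: pd.DataFrame,
    response: str = "distance",
    scale_col: str = "scale",
    nesting: tuple[str, ...] = NESTING_THREE,
    altitude: str = "altitude_m",
    degree: int = 2,
) -> ScaleInteractionFit:
    """Fit beta diversity against altitude × spatial scale.

    ``distances`` must hold one row per plot per scale with the response,
    the scale factor, altitude, and the nesting labels.  Exactly three
    scales are required.
    """
    scales = tuple(pd.unique(distances[scale_col]))
    if len(scales) != 3:
        raise ValueError(f"three scale levels required, got {list(scales)}")
    df = _prepare(distances, nesting, altitude)
    alt_terms = ["_alt_c"] + (["_alt_c2"] if degree == 2 else [])
    base = " + ".join(alt_terms)
    full_formula = f"{response} ~ ({base}) * C({scale_col})"
    add_formula = f"{response} ~ {base} + C({scale_col})"
    full, conv_full = _fit_mixedlm(full_formula, df, nesting)
    additive, _ = _fit_mixedlm(add_formula, df, nesting)
    chi2 = max(0.0, 2.0 * (full.llf - additive.llf))
    df_int = len(full.fe_params) - len(additive.fe_params)
    lrt = LRTResult(chi2, df_int, float(stats.chi2.sf(chi2, df_int)))
    subset = {}
    for s in scales:
        sub = distances[distances[scale_col] == s]
        subset[str(s)] = MixedAltitudeModel(
            response=response, degree=degree, family="gaussian",
            nesting=nesting, altitude=altitude,
        ).fit(sub)
    rank = np.linalg.matrix_rank(full.model.exog)
    return ScaleInteractionFit(
        result=full,
        converged=conv_full,
        subset_fits=subset,
        interaction_lrt=lrt,
        scales=scales,
        n_obs=len(df),
        resid_df=len(df) - rank,
        alt_mean=df.attrs["alt_mean"],
    )


def tukey_scale_contrasts(fit: ScaleInteractionFit) -> list[ContrastResult]:
    """All pairwise scale contrasts of estimated marginal means.

    Marginal means are evaluated at the mean altitude (centred terms = 0);
    p-values carry the Tukey (studentized-range) adjustment for the three
    comparisons, with the fit's residual df.
    """
    res = fit.result
    names = list(res.fe_params.index)
    beta = res.fe_params.to_numpy()
    cov = res.cov_params().loc[names, names].to_numpy()

    def emm_row(scale):
        g = np.zeros(len(names))
        for i, n in enumerate(names):
            if n == "Intercept":
                g[i] = 1.0
            elif n.startswith("C(") and f"[T.{scale}]" in n and ":" not in n:
                g[i] = 1.0
        return g

    k = len(fit.scales)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = fit.scales[j], fit.scales[i]  # later level minus earlier
            g = emm_row(a) - emm_row(b)
            diff = float(g @ beta)
            se = float(np.sqrt(g @ cov @ g))
            t = diff / se if se > 0 else np.nan
            p = float(
                stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, fit.resid_df)
            )
            out.append(
                ContrastResult(
                    pair=(str(a), str(b)), difference=diff, se=se, t=t,
                    df=fit.resid_df, p_tukey=min(1.0, p),
                )
            )
    return out
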