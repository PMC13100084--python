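"""Synthetic peri-induction cohort generator.

Emulates a pre-operative cohort of elective non-cardiac surgery patients:
clinical covariates (age, sex, BMI, ASA class, comorbidities, chronic
medication), baseline haemodynamics, echocardiographic measurements and
the derived ventriculo-arterial coupling block, plus a binary
post-induction hypotension (PIH) outcome following a configurable
logistic model.

Distribution defaults reproduce the marginal summaries of the study
population the generator emulates: symmetric variables are normal
(e.g. baseline MAP 105 +/- 14 mmHg), skewed variables are log-normal
matched to the published median and IQR, and proportions are Bernoulli /
categorical.  Two calibration steps anchor the cohort to its targets:

* the mean pre-ejection period is root-found so that the prevalence of
  ventriculo-arterial uncoupling (Ea/Ees > 1) matches its configured
  target (default 42/405 ~= 10.4%);
* the outcome-model intercept is root-found so that the mean simulated
  PIH probability matches the target prevalence (default 161/405 = 39.8%).

Covariates are drawn independently except for two deliberate couplings:
ASA class shifts with age (ordinal cumulative-logit shift) and baseline
MAP is derived exactly as (SAP + 2*DAP)/3 from the generated pressures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from . import elastance
from .errors import ConfigError, ConvergenceError, SchemaError

__all__ = [
    "CohortSpec",
    "calibrate_intercept",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "MANDATORY_COLUMNS",
]

# quantile of the standard normal at 0.75; converts an IQR into a
# log-normal sigma via sigma = (ln q75 - ln q25) / (2 * z75)
_Z75 = norm.ppf(0.75)

_CAL_SEED = 987_654_321  # internal seed for calibration draws
_CAL_N = 100_000


def _lognormal_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    mu = math.log(median)
    sigma = (math.log(q75) - math.log(q25)) / (2 * _Z75)
    return mu, sigma


def _default_covariate_params() -> dict:
    """Distribution parameters for every generated covariate.

    ``lognormal`` entries are (median, q25, q75); ``normal`` entries are
    (mean, sd); ``bernoulli`` entries are success probabilities.
    """
    return {
        # clinical
        "female": {"kind": "bernoulli", "p": 233 / 405},
        "age": {"kind": "lognormal", "median": 57, "q25": 47, "q75": 63},
        "bmi": {"kind": "lognormal", "median": 23, "q25": 21, "q75": 25},
        "asa": {
            "kind": "ordinal",
            # marginal class probabilities I / II / III-IV at the median age
            "p": (90 / 405, 249 / 405, 66 / 405),
            "age_slope_per_decade": 0.5,  # older patients shift towards III-IV
        },
        "smoking": {"kind": "bernoulli", "p": 28 / 405},
        "hypertension": {"kind": "bernoulli", "p": 183 / 405},
        "diabetes": {"kind": "bernoulli", "p": 62 / 405},
        "ccb": {"kind": "bernoulli", "p": 117 / 405},
        "beta_blocker": {"kind": "bernoulli", "p": 43 / 405},
        "acei_arb": {"kind": "bernoulli", "p": 69 / 405},
        "copd": {"kind": "bernoulli", "p": 1 / 405},
        "hr_t0": {"kind": "lognormal", "median": 75, "q25": 67, "q75": 84},
        "propofol": {"kind": "lognormal", "median": 2.0, "q25": 1.8, "q75": 2.3},
        # haemodynamics: MAP is built back from SAP/DAP, which are derived
        # from a normal MAP core and a normal pulse pressure
        "map_core": {"kind": "normal", "mean": 105.0, "sd": 13.5},
        "pulse_pressure": {"kind": "normal", "mean": 52.0, "sd": 10.0, "min": 25.0},
        # echo primitives
        "ef": {"kind": "normal", "mean": 0.611, "sd": 0.030, "min": 0.40, "max": 0.78},
        "sv": {"kind": "lognormal", "median": 65.0, "q25": 57.5, "q75": 73.5},
        "pep": {"kind": "normal", "mean": None, "sd": 12.0, "min": 25.0},  # mean calibrated
        "tsp": {"kind": "normal", "mean": 390.0, "sd": 30.0, "min": 250.0},
        "aod": {"kind": "lognormal", "median": 3.0, "q25": 2.85, "q75": 3.16},
        "aortic_strain": {"kind": "lognormal", "median": 7.1, "q25": 3.8, "q75": 11.1},
        # echo-derived structure / function
        "lvmi": {"kind": "lognormal", "median": 81, "q25": 70, "q75": 96},
        "gls_abs": {"kind": "lognormal", "median": 17.9, "q25": 16.4, "q75": 19.3},
        "edvi": {"kind": "lognormal", "median": 55, "q25": 48, "q75": 62},
        "esvi": {"kind": "lognormal", "median": 20.8, "q25": 18.7, "q75": 24.0},
        "ci": {"kind": "lognormal", "median": 2.7, "q25": 2.3, "q75": 3.2},
    }


def _default_effects() -> dict[str, float]:
    """Log odds ratios of the PIH outcome model.

    Binary effects use the study's adjusted odds ratios (ASA III-IV 6.66,
    Ea/Ees > 1 2.95, calcium channel blockers 0.43); continuous effects
    are mild log-linear slopes on centred covariates.
    """
    return {
        "asa34": math.log(6.66),
        "uncoupled": math.log(2.95),
        "ccb": math.log(0.43),
        "age_per_decade": math.log(1.35),
        "map_t0": -0.02,  # per mmHg above 105
        "lvmi": -0.012,  # per g/m^2 above 81
    }


# how each effect name maps onto a column of the generated table, and the
# centring applied to continuous terms before entering the linear predictor
_EFFECT_TRANSFORMS = {
    "asa34": ("asa34", 0.0, 1.0),
    "uncoupled": ("uncoupled", 0.0, 1.0),
    "ccb": ("ccb", 0.0, 1.0),
    "age_per_decade": ("age", 57.0, 10.0),  # (age - 57)/10
    "map_t0": ("map_t0", 105.0, 1.0),
    "lvmi": ("lvmi", 81.0, 1.0),
    "hr_t0": ("hr_t0", 75.0, 1.0),
    "bmi": ("bmi", 23.0, 1.0),
    "propofol": ("propofol", 2.0, 1.0),
    "ef": ("ef", 0.611, 1.0),
    "gls": ("gls", -17.9, 1.0),
    "edvi": ("edvi", 55.0, 1.0),
    "esvi": ("esvi", 20.8, 1.0),
    "ci": ("ci", 2.7, 1.0),
    "ea": ("ea", 1.9, 1.0),
    "ees": ("ees", 2.4, 1.0),
    "female": ("female", 0.0, 1.0),
    "hypertension": ("hypertension", 0.0, 1.0),
    "diabetes": ("diabetes", 0.0, 1.0),
    "smoking": ("smoking", 0.0, 1.0),
    "beta_blocker": ("beta_blocker", 0.0, 1.0),
    "acei_arb": ("acei_arb", 0.0, 1.0),
    "copd": ("copd", 0.0, 1.0),
}


@dataclass
class CohortSpec:
    """Configuration of one synthetic cohort."""

    n: int = 405
    seed: int = 0
    covariate_params: dict = field(default_factory=_default_covariate_params)
    effects: dict[str, float] = field(default_factory=_default_effects)
    target_prevalence: float = 161 / 405
    uncoupled_target: float = 42 / 405
    gls_missing_rate: float = 0.02

    def __post_init__(self):
        if not self.n > 0:
            raise ConfigError(f"n must be > 0, got {self.n!r}")
        if not 0 < self.target_prevalence < 1:
            raise ConfigError(
                f"target_prevalence must be in (0,1), got {self.target_prevalence!r}"
            )
        if not 0 < self.uncoupled_target < 1:
            raise ConfigError("uncoupled_target must be in (0,1)")
        if not 0 <= self.gls_missing_rate < 0.05:
            raise ConfigError("gls_missing_rate must be in [0, 0.05)")
        unknown = set(self.effects) - set(_EFFECT_TRANSFORMS)
        if unknown:
            raise ConfigError(
                f"effects reference covariates the generator does not produce: "
                f"{sorted(unknown)}"
            )


def _draw(rng: np.random.Generator, params: dict, n: int) -> np.ndarray:
    kind = params["kind"]
    if kind == "bernoulli":
        return rng.binomial(1, params["p"], n).astype(float)
    if kind == "normal":
        x = rng.normal(params["mean"], params["sd"], n)
        if "min" in params:
            x = np.maximum(x, params["min"])
        if "max" in params:
            x = np.minimum(x, params["max"])
        return x
    if kind == "lognormal":
        mu, sigma = _lognormal_params(params["median"], params["q25"], params["q75"])
        return rng.lognormal(mu, sigma, n)
    raise ConfigError(f"unknown distribution kind {kind!r}")


def _end_est_vec(
    ef: np.ndarray, pep: np.ndarray, tsp: np.ndarray, sap: np.ndarray, dap: np.ndarray
) -> np.ndarray:
    """Vectorised twin of :func:`vacpih.elastance.compute_end_est`."""
    tnd = np.clip(pep / tsp, *elastance.TND_CALIBRATION_RANGE)
    end_avg = np.zeros_like(tnd)
    for k, c in enumerate(elastance._END_AVG_COEFFS):
        end_avg = end_avg + c * tnd**k
    pes = elastance.PES_FACTOR * sap
    end = (
        elastance._END_EST_INTERCEPT
        + elastance._END_EST_EF_SLOPE * ef
        + elastance._END_EST_PRESSURE_SLOPE * (dap / pes)
        + elastance._END_EST_AVG_SLOPE * end_avg
    )
    return np.clip(end, 1e-6, 1 - 1e-6)


def _draw_pressures(rng, params, n):
    map_core = _draw(rng, params["map_core"], n)
    pp = _draw(rng, params["pulse_pressure"], n)
    sap = map_core + 2.0 / 3.0 * pp
    dap = map_core - pp / 3.0
    return sap, dap


def _calibrate_pep_mean(spec: CohortSpec) -> float:
    """Mean PEP such that P(Ea/Ees > 1) matches the uncoupling target.

    Uncoupling is equivalent to End(est) * 0.9 * SAP > DAP / 2, so the
    prevalence is monotone in the PEP mean (End(est) increases with
    tNd).  Root-found on one fixed calibration draw of the other echo
    primitives.
    """
    params = spec.covariate_params
    rng = np.random.default_rng(_CAL_SEED)
    sap, dap = _draw_pressures(rng, params, _CAL_N)
    ef = _draw(rng, params["ef"], _CAL_N)
    tsp = _draw(rng, params["tsp"], _CAL_N)
    pep_z = rng.normal(0.0, 1.0, _CAL_N)

    sd = params["pep"]["sd"]
    lo = params["pep"].get("min", 25.0)

    def excess(mu):
        pep = np.maximum(mu + sd * pep_z, lo)
        pep = np.minimum(pep, 0.95 * tsp)
        end = _end_est_vec(ef, pep, tsp, sap, dap)
        unc = end * elastance.PES_FACTOR * sap > dap / 2.0
        return unc.mean() - spec.uncoupled_target

    try:
        return brentq(excess, 30.0, 220.0, xtol=1e-3)
    except ValueError as exc:
        raise ConvergenceError(
            f"PEP-mean calibration failed to bracket the uncoupling target "
            f"{spec.uncoupled_target:.3f} on [30, 220] ms: {exc}"
        ) from exc


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator, n: int,
                     pep_mean: float) -> pd.DataFrame:
    p = spec.covariate_params
    d: dict[str, np.ndarray] = {}
    d["age"] = _draw(rng, p["age"], n)
    d["female"] = _draw(rng, p["female"], n)
    d["bmi"] = _draw(rng, p["bmi"], n)

    # ASA class: cumulative-logit ordinal with an age shift
    asa_p = p["asa"]["p"]
    slope = p["asa"]["age_slope_per_decade"]
    c1 = logit(asa_p[0])
    c2 = logit(asa_p[0] + asa_p[1])
    shift = slope * (d["age"] - p["age"]["median"]) / 10.0
    u = rng.uniform(size=n)
    p_le_1 = expit(c1 - shift)
    p_le_2 = expit(c2 - shift)
    asa_code = np.where(u < p_le_1, 0, np.where(u < p_le_2, 1, 2))
    d["asa"] = np.array(["I", "II", "III-IV"])[asa_code]
    d["asa34"] = (asa_code == 2).astype(float)

    for name in ["smoking", "hypertension", "diabetes", "ccb", "beta_blocker",
                 "acei_arb", "copd", "hr_t0", "propofol"]:
        d[name] = _draw(rng, p[name], n)

    sap, dap = _draw_pressures(rng, p, n)
    d["sap"], d["dap"] = sap, dap
    d["map_t0"] = (sap + 2.0 * dap) / 3.0

    d["ef"] = _draw(rng, p["ef"], n)
    d["sv"] = _draw(rng, p["sv"], n)
    tsp = _draw(rng, p["tsp"], n)
    pep = np.maximum(rng.normal(pep_mean, p["pep"]["sd"], n), p["pep"].get("min", 25.0))
    pep = np.minimum(pep, 0.95 * tsp)
    d["pep"], d["tsp"] = pep, tsp

    aod = _draw(rng, p["aod"], n)
    strain = _draw(rng, p["aortic_strain"], n)
    d["aod"] = aod
    d["aos"] = aod * (1.0 + strain / 100.0)

    d["lvmi"] = _draw(rng, p["lvmi"], n)
    d["gls"] = -_draw(rng, p["gls_abs"], n)
    d["edvi"] = _draw(rng, p["edvi"], n)
    d["esvi"] = _draw(rng, p["esvi"], n)
    d["ci"] = _draw(rng, p["ci"], n)

    frame = pd.DataFrame(d)

    # VAC block, exactly as the per-patient elastance routines compute it
    end = _end_est_vec(frame["ef"].values, pep, tsp, sap, dap)
    pes = elastance.PES_FACTOR * sap
    ea = pes / frame["sv"].values
    ees = (dap - end * pes) / (end * frame["sv"].values)
    # rare draws can put End(est) >= DAP/Pes (Ees <= 0); End(est) rises with
    # PEP, so shortening PEP to its floor restores a physiological beat while
    # keeping the stored primitives and the VAC block exactly consistent
    bad = dap - end * pes <= 0
    if bad.any():
        pep = np.where(bad, p["pep"].get("min", 25.0), pep)
        frame["pep"] = pep
        end = _end_est_vec(frame["ef"].values, pep, tsp, sap, dap)
        if (dap - end * pes <= 0).any():
            raise ConvergenceError("could not draw a physiological elastance")
        ees = (dap - end * pes) / (end * frame["sv"].values)
    frame["pes"] = pes
    frame["end_est"] = end
    frame["ea"] = ea
    frame["ees"] = ees
    # SV-free cancellation form, identical to the per-patient routine
    x = end * pes
    frame["ea_ees_ratio"] = x / (dap - x)
    frame["uncoupled"] = (frame["ea_ees_ratio"] > 1.0).astype(float)
    return frame


def _linear_predictor(frame: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(frame))
    for name, beta in effects.items():
        col, center, scale = _EFFECT_TRANSFORMS[name]
        lp += beta * (frame[col].values - center) / scale
    return lp


def calibrate_intercept(spec: CohortSpec) -> float:
    """Outcome-model intercept hitting the target PIH prevalence.

    Root-finds beta0 such that the mean of logistic(beta0 + linear
    predictor) equals ``spec.target_prevalence`` over a large fixed-seed
    calibration draw (n = 100,000).
    """
    pep_mean = _calibrate_pep_mean(spec)
    rng = np.random.default_rng(_CAL_SEED + 1)
    frame = _draw_covariates(spec, rng, _CAL_N, pep_mean)
    lp = _linear_predictor(frame, spec.effects)

    def excess(b0):
        return expit(b0 + lp).mean() - spec.target_prevalence

    lo, hi = -20.0, 20.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ConvergenceError(
            f"intercept calibration cannot bracket target "
            f"{spec.target_prevalence:.3f}: mean p on [{lo},{hi}] = "
            f"[{excess(lo) + spec.target_prevalence:.4f}, "
            f"{excess(hi) + spec.target_prevalence:.4f}]"
        )
    return brentq(excess, lo, hi, xtol=1e-8)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full synthetic cohort, reproducible given ``spec.seed``."""
    pep_mean = _calibrate_pep_mean(spec)
    beta0 = calibrate_intercept(spec)
    rng = np.random.default_rng(spec.seed)
    frame = _draw_covariates(spec, rng, spec.n, pep_mean)
    lp = beta0 + _linear_predictor(frame, spec.effects)
    frame["pih"] = rng.binomial(1, expit(lp)).astype(int)
    if spec.gls_missing_rate > 0:
        miss = rng.uniform(size=spec.n) < spec.gls_missing_rate
        frame.loc[miss, "gls"] = np.nan
    frame.insert(0, "id", np.arange(1, spec.n + 1))
    return frame


MANDATORY_COLUMNS = [
    "id", "age", "female", "bmi", "asa", "asa34", "ccb", "map_t0", "hr_t0",
    "sap", "dap", "ef", "sv", "pep", "tsp", "lvmi", "gls",
    "ea", "ees", "ea_ees_ratio", "uncoupled", "pih",
]


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (lossless round-trip with read_cohort)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort table missing mandatory columns: {missing}")
    frame.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the mandatory column dictionary."""
    frame = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file missing mandatory columns: {missing}")
    return frame
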