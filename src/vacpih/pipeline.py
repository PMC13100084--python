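"""End-to-end study pipeline.

Runs the full analysis replica under one seeded configuration:

    cohort (synthetic or CSV) -> VAC indices -> descriptive comparisons
    -> data hygiene (GLS imputation, sparse-binary exclusion)
    -> LASSO clinical screening -> M0 / Mecho / Mfull additive models
    -> nested added-value report (FNI, deviance, DeLong, one Holm family)
    -> bootstrap variable-contribution decomposition

Every number is written both as rounded report CSVs and as a
full-precision JSON bundle; two runs with the same configuration produce
byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import added_value as av
from . import descriptives as ds
from .cohort import CohortSpec, generate_cohort, read_cohort
from .errors import ConfigError, StageError
from .models import LassoConfig, ModelSpec, fit_additive_logistic, lasso_select

__all__ = ["RunConfig", "validate_config", "load_config", "run_study"]

_DEFAULT_CLINICAL_CANDIDATES = [
    "age", "female", "bmi", "asa34", "smoking", "hypertension", "diabetes",
    "ccb", "beta_blocker", "acei_arb", "copd", "hr_t0", "propofol",
]
_DEFAULT_ECHO_TERMS = ["lvmi", "gls", "edvi", "esvi", "ci"]
_DEFAULT_VAC_SMOOTH = ["ea", "ees"]
_DEFAULT_VAC_PARAMETRIC = ["uncoupled"]
# continuous clinical covariates are modelled as smooths; anything else
# selected by LASSO enters parametrically
_CONTINUOUS_CLINICAL = {"age", "bmi", "hr_t0", "propofol", "map_t0"}

_DESCRIPTIVE_VARS = [
    "age", "female", "bmi", "asa", "hypertension", "diabetes", "ccb",
    "map_t0", "hr_t0", "propofol", "lvmi", "gls", "edvi", "esvi", "ci",
    "ea", "ees", "uncoupled",
]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    n: int = 405
    input_path: str | None = None  # load a cohort CSV instead of simulating
    outdir: str = "vac_run"
    clinical_candidates: list[str] = field(
        default_factory=lambda: list(_DEFAULT_CLINICAL_CANDIDATES))
    force_m0_terms: list[str] | None = None  # bypass LASSO (regression tests)
    echo_terms: list[str] = field(default_factory=lambda: list(_DEFAULT_ECHO_TERMS))
    vac_smooth_terms: list[str] = field(
        default_factory=lambda: list(_DEFAULT_VAC_SMOOTH))
    vac_parametric_terms: list[str] = field(
        default_factory=lambda: list(_DEFAULT_VAC_PARAMETRIC))
    basis_df: int = 10
    lasso_folds: int = 10
    lasso_n_lambda: int = 50
    bootstrap_B: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.bootstrap_B < 1:
            raise ConfigError(f"bootstrap_B must be >= 1, got {self.bootstrap_B!r}")
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n!r}")
        if self.basis_df < 4:
            raise ConfigError("basis_df must be >= 4")


def validate_config(raw: dict) -> RunConfig:
    """Normalise a raw config mapping; every violation is listed at once."""
    known = set(RunConfig.__dataclass_fields__)
    problems = []
    unknown = set(raw) - known
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if "seed" not in raw:
        problems.append("missing mandatory key: seed")
    if "bootstrap_B" in raw and (not isinstance(raw["bootstrap_B"], int)
                                 or raw["bootstrap_B"] < 1):
        problems.append(f"bootstrap_B must be a positive integer, "
                        f"got {raw['bootstrap_B']!r}")
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(**raw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return validate_config(raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {
            (k.item() if isinstance(k, (np.integer, np.floating)) else k):
                _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _split_terms(names: list[str]) -> tuple[list[str], list[str]]:
    parametric = [t for t in names if t not in _CONTINUOUS_CLINICAL]
    smooth = [t for t in names if t in _CONTINUOUS_CLINICAL]
    return parametric, smooth


def run_study(config: RunConfig) -> dict:
    """Execute the pipeline; returns the report dict and writes artifacts.

    Artifacts in ``config.outdir``: descriptives.csv, model_summary.csv,
    auc_table.csv, fni_table.csv, contributions.csv, report.json.  Any
    stage failure aborts with a stage-tagged error and removes partial
    outputs.
    """
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
        return _T()

    with _stage("cohort"):
        if config.input_path is not None:
            cohort = read_cohort(config.input_path)
        else:
            cohort = generate_cohort(CohortSpec(n=config.n, seed=config.seed))

    with _stage("descriptives"):
        desc_vars = [v for v in _DESCRIPTIVE_VARS if v in cohort.columns]
        descriptives = ds.summary_table(cohort, desc_vars)

    with _stage("hygiene"):
        cohort = cohort.copy()
        cohort["gls"] = ds.impute_gls(cohort["gls"])
        candidates = [c for c in config.clinical_candidates
                      if c in cohort.columns]
        candidates, exclusion_log = ds.exclude_sparse_binaries(cohort, candidates)

    with _stage("lasso"):
        if config.force_m0_terms is not None:
            selected = list(config.force_m0_terms)
        else:
            selected = lasso_select(
                cohort, candidates,
                LassoConfig(n_folds=config.lasso_folds,
                            n_lambda=config.lasso_n_lambda, seed=config.seed),
            )
        # baseline MAP belongs to the clinical block of every model
        if "map_t0" not in selected and "map_t0" in cohort.columns:
            selected = selected + ["map_t0"]

    with _stage("models"):
        par0, smo0 = _split_terms(selected)
        m0_spec = ModelSpec("M0", par0, smo0, basis_df=config.basis_df)
        mecho_spec = ModelSpec(
            "Mecho", par0, smo0 + list(config.echo_terms),
            basis_df=config.basis_df, parent="M0")
        mfull_spec = ModelSpec(
            "Mfull", par0 + list(config.vac_parametric_terms),
            smo0 + list(config.echo_terms) + list(config.vac_smooth_terms),
            basis_df=config.basis_df, parent="Mecho")
        m0 = fit_additive_logistic(cohort, m0_spec)
        mecho = fit_additive_logistic(cohort, mecho_spec)
        mfull = fit_additive_logistic(cohort, mfull_spec)
        models = {"M0": m0, "Mecho": mecho, "Mfull": mfull}

    with _stage("comparisons"):
        y = cohort["pih"].to_numpy()
        pairs = [(m0, mecho), (m0, mfull), (mecho, mfull)]
        comparisons = [av.compare_nested(r, f, y) for r, f in pairs]
        # one Holm family of six tests: three DeLong + three likelihood-ratio
        family = [c.p_delong for c in comparisons] + [c.p_lr for c in comparisons]
        adjusted = av.holm_adjust(family)
        for i, c in enumerate(comparisons):
            c.p_delong_holm = float(adjusted[i])
            c.p_lr_holm = float(adjusted[i + len(comparisons)])
        # cross-module identities: exact by construction, asserted per run
        dev_e0, dev_f0, dev_fe = (c.deviance for c in comparisons)
        assert abs(dev_e0 + dev_fe - dev_f0) < 1e-9, "deviance additivity"
        fni_e0, fni_f0, fni_fe = (c.fni for c in comparisons)
        assert abs((1 - fni_f0) - (1 - fni_e0) * (1 - fni_fe)) < 1e-12, \
            "FNI composition"

    with _stage("contributions"):
        contributions = av.explained_variance_contributions(
            cohort, mfull_spec, B=config.bootstrap_B, seed=config.seed,
            fitted_full=mfull,
        )

    with _stage("report"):
        report = {
            "config": _jsonable(asdict(config)),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n": int(len(cohort)),
            "pih_prevalence": float(cohort["pih"].mean()),
            "lasso_selected": selected,
            "sparse_binary_exclusions": exclusion_log,
            "models": {
                name: {
                    "terms": m.spec.all_terms(),
                    "edf": m.edf,
                    "llf": m.llf,
                    "lr_chisq": m.lr_chisq,
                    "auc": av.auc(m.fitted, y),
                }
                for name, m in models.items()
            },
            "comparisons": [
                {
                    "reduced": c.reduced,
                    "full": c.full,
                    "deviance": c.deviance,
                    "df": c.df,
                    "p_lr": c.p_lr,
                    "p_lr_holm": c.p_lr_holm,
                    "fni": c.fni,
                    "auc_reduced": c.auc_reduced,
                    "auc_full": c.auc_full,
                    "delta_auc": c.delta_auc,
                    "delta_auc_ci": list(c.delta_auc_ci),
                    "p_delong": c.p_delong,
                    "p_delong_holm": c.p_delong_holm,
                }
                for c in comparisons
            ],
            "contributions": {
                "B": contributions.B,
                "terms": contributions.table.to_dict(orient="records"),
            },
        }
        report = _jsonable(report)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _write_csv(name, frame):
            path = outdir / name
            frame.to_csv(path, index=False)
            written.append(path)

        _write_csv("descriptives.csv", descriptives.assign(p=lambda d: d.p.round(3)))
        _write_csv("model_summary.csv", pd.DataFrame([
            {"model": name, "terms": ";".join(m.spec.all_terms()),
             "edf": round(m.edf, 2), "lr_chisq": round(m.lr_chisq, 2),
             "auc": round(av.auc(m.fitted, y), 3)}
            for name, m in models.items()
        ]))
        _write_csv("auc_table.csv", pd.DataFrame([
            {"comparison": f"{c.full} vs {c.reduced}",
             "auc_full": round(c.auc_full, 3),
             "delta_auc": round(c.delta_auc, 3),
             "ci_low": round(c.delta_auc_ci[0], 3),
             "ci_high": round(c.delta_auc_ci[1], 3),
             "p_unadjusted": round(c.p_delong, 4),
             "p_holm": round(c.p_delong_holm, 3)}
            for c in comparisons
        ]))
        _write_csv("fni_table.csv", pd.DataFrame([
            {"comparison": f"{c.full} vs {c.reduced}",
             "fni": round(c.fni, 2), "deviance": round(c.deviance, 2),
             "df": round(c.df, 2), "p_unadjusted": round(c.p_lr, 3),
             "p_holm": round(c.p_lr_holm, 3)}
            for c in comparisons
        ]))
        _write_csv("contributions.csv", contributions.table.round(
            {"percent": 2, "ci_low": 2, "ci_high": 2}))
        path = outdir / "report.json"
        with open(path, "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
        written.append(path)
        # run log (timings vary between runs, so it lives outside report.json,
        # which stays byte-identical for a given configuration)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"seed": config.seed,
                       "config_hash": report["config_hash"],
                       "timings_s": timings}, fh, sort_keys=True, indent=1)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError("write", str(exc)) from exc
    return {**report, "timings_s": timings}
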