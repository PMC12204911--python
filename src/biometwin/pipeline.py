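"""End-to-end orchestration: simulate/read, classify, fit, select, report.

The pipeline mirrors the study's flow: questionnaire cohort -> asthma
exclusion (for the obstruction / bronchitis / COPD analyses only; lung
function uses the whole population) -> spirometric classification -> twin
model fitting (saturated plus ACE/ADE/AE/CE) -> AIC/LRT selection ->
report tables.  Every stage logs subjects in and out, and every output
carries the configuration hash and seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cm
from . import liability as lb
from . import selection as sel
from .continuous import fit_continuous
from .cohort import Cohort, singleton_arrays
from .simulate import simulate_cohort, simulate_study, study_preset

logger = logging.getLogger("biometwin.pipeline")

CONTINUOUS_MODELS = ("SAT", "ACE", "ADE", "AE", "CE")
BINARY_MODELS = ("SAT", "ACE", "ADE", "AE", "CE")

#: cohort columns each case definition needs
_REQUIRED_COLUMNS = {
    "FR_AO": ["fev1_fvc_ratio"],
    "LLN25_AO": ["ratio_z"],
    "LLN5_AO": ["ratio_z"],
    "FR_COPD": ["fev1_fvc_ratio", "dyspnea", "cough", "nocturnal_symptoms"],
    "LLN25_COPD": ["ratio_z", "dyspnea", "cough", "nocturnal_symptoms"],
    "LLN5_COPD": ["ratio_z", "dyspnea", "cough", "nocturnal_symptoms"],
    "CHRONIC_BRONCHITIS": ["chronic_cough_sputum"],
    "RESP_SYMPTOMS": ["dyspnea", "cough", "nocturnal_symptoms"],
}

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": None,
    "cohort": {"preset": "survey2011", "scale": 1.0, "path": None},
    "traits": {
        "continuous": ["fev1_z", "fvc_z", "ratio_z"],
        "binary": ["FR_AO", "LLN25_AO", "LLN5_AO", "CHRONIC_BRONCHITIS",
                   "FR_COPD", "LLN25_COPD", "LLN5_COPD"],
    },
    "models": {"continuous": list(CONTINUOUS_MODELS),
               "binary": list(BINARY_MODELS)},
    "options": {
        "include_asthmatics": False,
        "include_singletons": False,
        "include_opposite_sex_dz": False,
        "boundary_mixture_lrt": False,
        "stratify_smoking": False,
        "ci_method": "delta",
        "n_restarts": 5,
    },
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Normalize a config mapping or YAML path against the defaults."""
    if source is None:
        cfg = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    return _merge(DEFAULT_CONFIG, cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Fitted models, selections, report tables and the stage funnel."""

    config: dict
    config_hash: str
    seed: int
    funnel: list[dict] = field(default_factory=list)
    fits: dict = field(default_factory=dict)
    selections: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    tetrachoric: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def audit_json(self) -> str:
        return json.dumps({
            "config_hash": self.config_hash,
            "seed": self.seed,
            "funnel": self.funnel,
            "selections": {
                t: {"selected": s.selected_label, "full": s.full_label,
                    "audit": s.audit}
                for t, s in self.selections.items()},
            "fits": {t: {lbl: f.to_dict() for lbl, f in fd.items()}
                     for t, fd in self.fits.items()},
            "tetrachoric": self.tetrachoric,
        }, indent=2)


def _check_columns(trait: str, cohort: Cohort) -> None:
    need = _REQUIRED_COLUMNS.get(trait, [trait])
    missing = [c for c in need if c not in cohort.df.columns]
    if missing:
        raise ValueError(
            f"trait {trait!r} requires missing column(s): {', '.join(missing)}")


def _fit_trait_continuous(cohort, trait, models, opts, seed):
    pairs, singles = cm.assemble_pairs(cohort, trait)
    singletons = singleton_arrays(singles, trait)
    fits = {}
    for lbl in models:
        fits[lbl] = fit_continuous(
            pairs, singletons, model_label=lbl,
            include_singletons=opts["include_singletons"],
            n_restarts=opts["n_restarts"], seed=seed,
            ci_method=opts["ci_method"], trait=trait)
    return fits, pairs


def _fit_trait_binary(cohort, trait, models, opts, seed):
    pairs, _ = cm.assemble_pairs(cohort, trait)
    pairs.y = pairs.y.astype(float)
    fits = {}
    for lbl in models:
        fits[lbl] = lb.fit_liability(
            pairs, model_label=lbl,
            include_opposite_sex_dz=opts["include_opposite_sex_dz"],
            n_restarts=opts["n_restarts"], seed=seed,
            ci_method=opts["ci_method"], trait=trait)
    # model-free tetrachoric correlations on same-sex pairs
    tet = {}
    for zyg, mask in (("MZ", pairs.is_mz),
                      ("DZ_same_sex", pairs.zygosity == "DZ_same_sex")):
        sub = pairs.subset(mask)
        if len(sub) == 0:
            continue
        table = lb.concordance_table(sub)
        try:
            est = lb.tetrachoric(table, zygosity=zyg)
            tet[zyg] = {"rho": est.rho, "ci95": list(est.ci95),
                        "n_pairs": est.n_pairs}
        except ValueError as exc:
            tet[zyg] = {"error": str(exc)}
    return fits, tet


def run_pipeline(config=None, seed: int | None = None) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    ``config`` may be a mapping, a YAML path, or None for the defaults
    (the survey-mimicking preset).  Any stage failure aborts with the
    stage name; outputs produced before the failure are preserved when an
    out_dir is configured.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    opts = cfg["options"]
    result = PipelineResult(cfg, config_hash(cfg), seed)
    out_dir = Path(cfg["out_dir"]) if cfg.get("out_dir") else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load_cohort"
    try:
        src = cfg["cohort"]
        if src.get("path"):
            cohort = cm.read_cohort(src["path"])
        elif src.get("preset") == "survey2011":
            cohort, truth = simulate_study(seed=seed,
                                           scale=src.get("scale", 1.0))
            result.ground_truth = truth
        else:
            raise ValueError("cohort config needs a 'path' or known 'preset'")
        result.funnel.append({"stage": stage, "n_in": len(cohort),
                              "n_out": len(cohort)})
        logger.info("cohort loaded: %d subjects", len(cohort))

        stage = "classify"
        binary_traits = list(cfg["traits"]["binary"])
        for trait in binary_traits:
            _check_columns(trait, cohort)
        cohort = cm.classify_cohort(cohort, [t for t in binary_traits
                                             if t in cm.CRITERIA])

        stage = "fit_continuous"
        for trait in cfg["traits"]["continuous"]:
            if trait not in cohort.df.columns:
                raise ValueError(f"continuous trait {trait!r} not in cohort")
            fits, pairs = _fit_trait_continuous(
                cohort, trait, cfg["models"]["continuous"], opts, seed)
            result.fits[trait] = fits
            result.funnel.append({
                "stage": f"pairs[{trait}]", "n_in": len(cohort),
                "n_out": 2 * len(pairs)})
            if all(l in fits for l in ("ACE", "ADE", "AE", "CE")):
                result.selections[trait] = sel.select_model(
                    fits, boundary_mixture=opts["boundary_mixture_lrt"])
            result.tables[trait] = sel.render_results(
                fits, result.selections.get(trait), style="table2")

        stage = "exclude_asthma"
        binary_cohort = cohort
        if binary_traits and not opts["include_asthmatics"]:
            binary_cohort = cm.exclude_asthma(cohort)
            result.funnel.append({
                "stage": stage, "n_in": len(cohort),
                "n_out": len(binary_cohort)})
            # re-classify: case columns were computed pre-exclusion but are
            # row-wise, so the subset is still valid
        stage = "fit_binary"
        for trait in binary_traits:
            style = ("table4" if "COPD" in trait or "BRONCH" in trait
                     else "table3")
            fits, tet = _fit_trait_binary(
                binary_cohort, trait, cfg["models"]["binary"], opts, seed)
            result.fits[trait] = fits
            result.tetrachoric[trait] = tet
            if all(l in fits for l in ("ACE", "ADE", "AE", "CE")):
                result.selections[trait] = sel.select_model(
                    fits, boundary_mixture=opts["boundary_mixture_lrt"])
            result.tables[trait] = sel.render_results(
                fits, result.selections.get(trait), style=style)

        stage = "stratify_smoking"
        if opts["stratify_smoking"]:
            for stratum in ("never", "former", "current"):
                mask = cohort.df["smoking"] == stratum
                sub = Cohort(cohort.df.loc[mask].reset_index(drop=True))
                for trait in cfg["traits"]["continuous"]:
                    fits, _ = _fit_trait_continuous(
                        sub, trait, cfg["models"]["continuous"], opts, seed)
                    key = f"{trait}[smoking={stratum}]"
                    result.fits[key] = fits
                    if all(l in fits for l in ("ACE", "ADE", "AE", "CE")):
                        result.selections[key] = sel.select_model(fits)
                    result.tables[key] = sel.render_results(
                        fits, result.selections.get(key), style="table2")

        stage = "write_outputs"
        if out_dir:
            for name, table in result.tables.items():
                safe = name.replace("[", "_").replace("]", "").replace("=", "-")
                table.to_csv(out_dir / f"{safe}.csv", index=False)
            (out_dir / "audit.json").write_text(result.audit_json())
            if result.ground_truth is not None:
                (out_dir / "ground_truth.json").write_text(
                    json.dumps(result.ground_truth, indent=2))
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        if out_dir:    # partial outputs already on disk are preserved
            (out_dir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise PipelineError(stage, exc) from exc
    return result
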