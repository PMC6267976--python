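"""Calibrate -> predict -> evaluate workflow with file artifacts.

Chains the library stages over CSV inputs and writes one artifact per
stage plus a manifest with checksums, so a run is auditable and
re-runnable. Stages:

1. *calibrate* — CWM traits from cover quadrats + GAM fits per trait,
   then CWM predictions at the treatment environments. Skipped when a
   constraints CSV is supplied directly (treatment x trait CWM targets).
2. *predict* — CATS maxent abundances for the focal species pool under
   each treatment's CWM constraints, with feasibility diagnostics.
3. *evaluate* — fit statistics against observed abundances (per-pot with
   a design table, or treatment means), permutation p-values, dominant-
   species accuracy, CWM concordance.
4. *permanova* — two-way light x soil tests on the per-pot community and
   univariate responses (available when per-pot data are supplied).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, maxent, permanova, trait_env
from .community import (
    CommunityMatrix,
    CWMTable,
    TraitTable,
    compute_cwm,
    read_community_matrix,
    read_cwm_table,
    read_environment_table,
    read_trait_table,
    relativize,
)
from .errors import CWMCatsError, ValidationError
from .simulate import DEFAULT_TREATMENTS, TRAITS


@dataclass
class PipelineConfig:
    """Inputs, treatment definitions and solver/evaluation settings."""

    trait_csv: str
    output_dir: str
    community_csv: str = None  # field quadrat cover (calibration)
    env_csv: str = None  # quadrat environments (calibration)
    constraints_csv: str = None  # treatment x trait CWM targets (skips calibration)
    observed_csv: str = None  # experimental abundances (pots or treatment means)
    design_csv: str = None  # pot -> treatment/light/soil labels
    species_subset: tuple = None  # maxent species pool; default: all species in traits
    treatments: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_TREATMENTS[["soil_ph", "pine_ba"]].copy()
    )
    tol: float = 1e-8
    max_iter: int = 10000
    on_infeasible: str = "error"
    n_perm: int = 999
    scheme: str = "within_row"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "treatments" in doc:
            tr = pd.DataFrame(doc.pop("treatments")).set_index("treatment")
            doc["treatments"] = tr[["soil_ph", "pine_ba"]]
        if "species_subset" in doc and doc["species_subset"] is not None:
            doc["species_subset"] = tuple(doc["species_subset"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def calibrate_stage(cfg: PipelineConfig, traits: TraitTable, outdir: Path):
    """Fit CWM ~ s(pH) + s(BA) per trait and predict treatment constraints."""
    cover = read_community_matrix(cfg.community_csv, kind="cover")
    env = read_environment_table(cfg.env_csv)
    rel = relativize(cover)
    cwm = compute_cwm(rel, traits)
    fits = {}
    for trait in TRAITS:
        fits[trait] = trait_env.fit_cwm_model(cwm, env, trait)
        (outdir / f"fit_{trait}.json").write_text(fits[trait].to_json())
    constraints = trait_env.predict_cwm_table(fits, cfg.treatments)
    constraints.to_csv(outdir / "predicted_cwm.csv")
    return fits, constraints


def predict_stage(cfg: PipelineConfig, traits: TraitTable, constraints: CWMTable, outdir: Path):
    """Solve the maxent problem per treatment; write abundances + diagnostics."""
    pool = traits.subset(cfg.species_subset) if cfg.species_subset else traits
    trait_names = [t for t in TRAITS if t in constraints.data.columns]
    rows, diags = [], {}
    for unit in constraints.units:
        target = constraints.data.loc[unit, trait_names].to_numpy(dtype=float)
        problem = maxent.MaxEntProblem(
            traits=pool.data[trait_names].to_numpy(dtype=float),
            constraints=target,
            species=pool.species,
            trait_names=trait_names,
        )
        sol = maxent.solve_maxent(
            problem, tol=cfg.tol, max_iter=cfg.max_iter, on_infeasible=cfg.on_infeasible
        )
        rows.append(pd.Series(sol.p, index=pool.species, name=unit))
        diags[unit] = {
            "entropy": sol.entropy,
            "lambdas": sol.lambdas,
            "log_partition": sol.log_partition,
            "residuals": sol.residuals,
            "raw_residuals": sol.raw_residuals,
            "iterations": sol.iterations,
            "feasible": sol.projection is None,
            "projection_distance": (
                0.0 if sol.projection is None else sol.projection.distance
            ),
        }
    predicted = pd.DataFrame(rows).rename_axis("unit_id")
    predicted.to_csv(outdir / "predicted_abundance.csv")
    (outdir / "maxent_diagnostics.json").write_text(
        json.dumps(diags, indent=2, default=_json_default)
    )
    return predicted, diags


def _observed_means(observed: CommunityMatrix, design: pd.DataFrame, treatments_index):
    """Treatment-mean relative abundances over non-empty pots."""
    rel = relativize(observed)
    keep = ~rel.zero_rows
    data = rel.data.loc[keep]
    labels = design.loc[data.index, "treatment"]
    means = data.groupby(labels).mean()
    return means.reindex(treatments_index), rel


def evaluate_stage(cfg: PipelineConfig, traits: TraitTable, predicted: pd.DataFrame, outdir: Path):
    """Fit statistics, permutation nulls, dominance calls, CWM concordance."""
    observed = read_community_matrix(cfg.observed_csv, kind="cover")
    per_pot = cfg.design_csv is not None
    if per_pot:
        design = pd.read_csv(cfg.design_csv).set_index("sample_id")
        means, rel = _observed_means(observed, design, predicted.index)
    else:
        rel = relativize(observed)
        means = rel.data.reindex(predicted.index)
        design = None
    if means.isna().any().any():
        raise ValidationError("observed data do not cover every treatment")
    means = means[predicted.columns]

    fa = evaluation.permutation_test(
        means,
        predicted,
        statistic="r2",
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        scheme=cfg.scheme,
    )
    pool = traits.subset(list(predicted.columns))
    obs_cwm = compute_cwm(
        CommunityMatrix(means, "relative"), pool
    ).data
    pred_cwm = compute_cwm(CommunityMatrix(predicted, "relative"), pool).data
    concord = evaluation.cwm_concordance(obs_cwm, pred_cwm)

    report = {
        "r2": fa.r2,
        "rmse_sqrt": fa.rmse_sqrt,
        "p_r2": fa.p_r2,
        "p_rmse": fa.p_rmse,
        "n_perm": fa.n_perm,
        "scheme": fa.scheme,
        "seed": fa.seed,
        "cwm_concordance": concord.reset_index().to_dict(orient="records"),
    }
    if per_pot:
        tops = evaluation.top_species_accuracy(
            rel.data, design["treatment"], predicted
        )
        report["per_treatment_hit"] = tops["per_treatment_hit"]
        report["pot_fraction"] = tops["pot_fraction"]
        report["predicted_dominant"] = tops["predicted_dominant"]
    (outdir / "evaluation.json").write_text(
        json.dumps(report, indent=2, default=_json_default)
    )
    pd.DataFrame({"null_r2": fa.null_r2, "null_rmse_sqrt": fa.null_rmse}).to_csv(
        outdir / "null_statistics.csv", index=False
    )
    return report, means, (design if per_pot else None), rel


def permanova_stage(cfg: PipelineConfig, traits: TraitTable, rel, design, outdir: Path):
    """Two-way light x soil PerMANOVA tables for community and univariate responses."""
    keep = ~rel.zero_rows
    data = rel.data.loc[keep]
    light = design.loc[data.index, "light"].rename("light")
    soil = design.loc[data.index, "soil"].rename("soil")
    tables = []
    dm = permanova.bray_curtis(CommunityMatrix(data, "relative"))
    res = permanova.permanova_2way(dm, light, soil, n_perm=cfg.n_perm, seed=cfg.seed)
    tables.append(res.table.assign(response="community"))
    for sp in data.columns:
        res = permanova.permanova_univariate(
            data[sp], light, soil, n_perm=cfg.n_perm, seed=cfg.seed
        )
        tables.append(res.table.assign(response=sp))
    pot_cwm = compute_cwm(CommunityMatrix(data, "relative"), traits.subset(data.columns))
    for trait in pot_cwm.data.columns:
        res = permanova.permanova_univariate(
            pot_cwm.data[trait], light, soil, n_perm=cfg.n_perm, seed=cfg.seed
        )
        tables.append(res.table.assign(response=f"cwm_{trait}"))
    out = pd.concat(tables).rename_axis("term").reset_index()
    out.to_csv(outdir / "permanova.csv", index=False)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; return a manifest of outputs.

    Any stage failure is re-raised annotated with the stage name;
    artifacts already written are retained alongside a failure marker.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "settings": {
        "tol": cfg.tol,
        "max_iter": cfg.max_iter,
        "on_infeasible": cfg.on_infeasible,
        "n_perm": cfg.n_perm,
        "scheme": cfg.scheme,
        "seed": cfg.seed,
        "treatments": cfg.treatments.reset_index().to_dict(orient="records"),
    }}
    stage = "load"
    try:
        traits = read_trait_table(cfg.trait_csv)
        if cfg.constraints_csv:
            constraints = read_cwm_table(cfg.constraints_csv)
            stage_used = "constraints_given"
        else:
            stage = "calibrate"
            if not (cfg.community_csv and cfg.env_csv):
                raise ValidationError(
                    "either constraints_csv or community_csv + env_csv is required"
                )
            _, constraints = calibrate_stage(cfg, traits, outdir)
            stage_used = "calibrated"
        manifest["stages"].append({"stage": "calibrate", "mode": stage_used})

        stage = "predict"
        predicted, diags = predict_stage(cfg, traits, constraints, outdir)
        manifest["stages"].append(
            {"stage": "predict", "treatments": list(predicted.index)}
        )

        if cfg.observed_csv:
            stage = "evaluate"
            report, means, design, rel = evaluate_stage(cfg, traits, predicted, outdir)
            manifest["stages"].append({"stage": "evaluate", "r2": report["r2"]})
            if design is not None:
                stage = "permanova"
                permanova_stage(cfg, traits, rel, design, outdir)
                manifest["stages"].append({"stage": "permanova"})
    except CWMCatsError as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise CWMCatsError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return manifest
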