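"""End-to-end workflow: simulate/load -> scan -> IUT -> models -> validation
-> epistasis -> clustering, driven by a single YAML config.

Every run writes its stage tables into the output directory together with
a manifest (package/library versions, seed, config hash), so reruns with
an identical config are reproducible: deterministic stages bit-identically,
seeded stochastic stages identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import scan_breed, write_assoc_table
from .clustering import breed_frequency_matrix, cluster_average_linkage, write_dendrogram
from .epistasis import pairwise_interaction
from .evaluate import evaluate_fit, validate
from .io import Cohort, allele_frequencies, merge_cohorts, read_cohort, write_cohort
from .iut import manhattan_export, run_iut
from .selection import lasso_path, refit_selected, select_by_aic, stepwise_forward
from .simulate import (
    BreedSpec,
    PlantedLocus,
    SimConfig,
    simulate_cohort,
    simulate_validation_cohort,
    write_truth_table,
)

ALL_STAGES = ("simulate", "assoc", "iut", "model", "validate", "epistasis", "cluster")


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SimConfig | None = None
    input_filesets: dict[str, tuple[Path, Path]] = field(default_factory=dict)
    iut_alpha: float = 0.05
    stepwise_alpha: float = 0.05
    epistasis_alpha: float = 0.05
    n_candidates: int = 20
    candidate_markers: tuple[str, ...] = ()
    model_cohorts: tuple[str, ...] = ()  # breeds and/or "generalized"
    validation: dict[str, int] | None = None  # breed/n_cases/n_controls
    min_individuals: int = 5
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in (self.iut_alpha, self.stepwise_alpha, self.epistasis_alpha):
            if not (0 < a < 1):
                raise ValueError("alpha values must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" in self.stages and self.simulate is None:
            raise ValueError("simulate stage requested but no simulate section")


def _sim_config_from_dict(d: dict[str, Any], seed: int) -> SimConfig:
    breeds = tuple(
        BreedSpec(b["label"], int(b["n_cases"]), int(b["n_controls"]))
        for b in d.get("breeds", [])
    ) or None
    planted = tuple(
        PlantedLocus(
            marker_index=int(p["marker_index"]),
            per_breed_effects={
                k: (float(v[0]), float(v[1]))
                for k, v in p.get("effects", {}).items()
            },
            fixation=dict(p.get("fixation", {})),
        )
        for p in d.get("planted", [])
    )
    kwargs: dict[str, Any] = dict(
        seed=int(d.get("seed", seed)),
        n_markers=int(d.get("n_markers", 1000)),
        maf_prior=tuple(d.get("maf_prior", (2.0, 2.0))),
        planted=planted,
        baseline_log_odds=float(d.get("baseline_log_odds", 0.0)),
        missing_rate=float(d.get("missing_rate", 0.0)),
        null_fixation_rate=float(d.get("null_fixation_rate", 0.0)),
        sex_log_odds=float(d.get("sex_log_odds", 0.0)),
    )
    if breeds is not None:
        kwargs["breeds"] = breeds
    return SimConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    seed = int(raw["seed"])
    sim = _sim_config_from_dict(raw["simulate"], seed) if "simulate" in raw else None
    filesets = {
        name: (Path(v["ped"]), Path(v["map"]))
        for name, v in raw.get("inputs", {}).items()
    }
    alphas = raw.get("alpha", {})
    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "run")),
        stages=tuple(raw.get("stages", ALL_STAGES)),
        simulate=sim,
        input_filesets=filesets,
        iut_alpha=float(alphas.get("iut", 0.05)),
        stepwise_alpha=float(alphas.get("stepwise", 0.05)),
        epistasis_alpha=float(alphas.get("epistasis", 0.05)),
        n_candidates=int(raw.get("n_candidates", 20)),
        candidate_markers=tuple(raw.get("candidate_markers", ())),
        model_cohorts=tuple(raw.get("model_cohorts", ())),
        validation=raw.get("validation"),
        min_individuals=int(raw.get("min_individuals", 5)),
        raw=raw,
    )


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.raw or str(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, stages_run: list[str]) -> None:
    import scipy
    import sklearn

    manifest = {
        "package": f"breedgwas {__version__}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": stages_run,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []
    cohorts: dict[str, Cohort] = {}
    truth = None

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    try:
        if "simulate" in cfg.stages:
            d = stage_dir("simulate")
            cohorts, truth = simulate_cohort(cfg.simulate)
            for label, c in cohorts.items():
                write_cohort(c, d / f"{label}.ped", d / f"{label}.map")
            write_truth_table(truth, d / "truth.tsv")
            stages_run.append("simulate")
        for name, (ped, mp) in cfg.input_filesets.items():
            cohorts[name] = read_cohort(ped, mp)
        if not cohorts:
            raise ValueError("no cohorts: provide a simulate section or inputs")

        merged = merge_cohorts(list(cohorts.values())) if len(cohorts) > 1 else \
            next(iter(cohorts.values()))

        scans: dict[str, pd.DataFrame] = {}
        if "assoc" in cfg.stages:
            d = stage_dir("assoc")
            for label, c in cohorts.items():
                scans[label] = scan_breed(c, label)
                write_assoc_table(scans[label], d / f"assoc_{label}.tsv")
            stages_run.append("assoc")

        iut_results = {}
        if "iut" in cfg.stages:
            if len(scans) < 2:
                raise RuntimeError("iut stage needs assoc scans of >= 2 breeds")
            d = stage_dir("iut")
            iut_results, thresholds = run_iut(scans, alpha=cfg.iut_alpha)
            thresholds.to_csv(d / "thresholds.tsv", sep="\t", index=False)
            manhattan_export(iut_results, thresholds, d)
            stages_run.append("iut")

        candidates = list(cfg.candidate_markers)
        if not candidates and iut_results:
            # top markers by Fisher-combined p in the all-breed set
            full = max(iut_results, key=lambda k: k.count("∩"))
            res = iut_results[full]
            res = res[res["valid"]].sort_values("fisher_p")
            candidates = res["marker_id"].head(cfg.n_candidates).tolist()

        models: dict[tuple[str, str], Any] = {}
        if "model" in cfg.stages:
            if not candidates:
                raise RuntimeError("model stage needs candidate markers")
            d = stage_dir("model")
            targets = list(cfg.model_cohorts) or (list(cohorts) + ["generalized"])
            rows = []
            for target in targets:
                data = merged if target == "generalized" else cohorts[target]
                covs = ("cohort", "sex") if target == "generalized" else ()
                spec, fit, design = stepwise_forward(
                    data, candidates, covariates=covs,
                    alpha_in=cfg.stepwise_alpha, alpha_out=cfg.stepwise_alpha,
                )
                models[(target, "stepwise")] = (spec, fit, design)
                path, ldesign = lasso_path(data, candidates, covariates=covs)
                lasso_terms = select_by_aic(path, ldesign)
                models[(target, "lasso")] = (lasso_terms, path, ldesign)
                for method, terms in (
                    ("stepwise", spec.selected_terms),
                    ("lasso", lasso_terms),
                ):
                    if terms:
                        rfit, rdesign, or_table = refit_selected(
                            data, terms, covariates=covs
                        )
                        or_table.insert(0, "model", f"{target}/{method}")
                        or_table.to_csv(
                            d / f"or_{target}_{method}.tsv", sep="\t", index=False
                        )
                        rep = evaluate_fit(rfit, y=rdesign.y)
                        null_aic = -2.0 * rep.n_used * np.log(0.5)
                        rows.append(
                            {
                                "cohort": target,
                                "method": method,
                                "n_parameters": rep.n_parameters,
                                "max_rescaled_r2": rep.max_rescaled_r2,
                                "aic_null": null_aic,
                                "aic_model": rep.aic,
                                "terms": ", ".join(map(str, terms)),
                                "hl_p": rep.hl_p,
                            }
                        )
                    else:
                        rows.append(
                            {"cohort": target, "method": method, "n_parameters": 0,
                             "max_rescaled_r2": 0.0, "aic_null": np.nan,
                             "aic_model": np.nan, "terms": "", "hl_p": np.nan}
                        )
            pd.DataFrame(rows).to_csv(d / "model_summary.tsv", sep="\t", index=False)
            stages_run.append("model")

        if "validate" in cfg.stages and cfg.validation and cfg.simulate is not None:
            d = stage_dir("validate")
            v = cfg.validation
            vc = simulate_validation_cohort(
                cfg.simulate, v["breed"], int(v["n_cases"]), int(v["n_controls"])
            )
            rows = []
            for (target, method), model in models.items():
                if target != v["breed"]:
                    continue
                terms = model[0].selected_terms if method == "stepwise" else model[0]
                if not terms:
                    continue
                rep, _ = validate([t for t in terms], vc)
                rows.append(
                    {"method": method, "terms": ", ".join(map(str, terms)),
                     "max_rescaled_r2": rep.max_rescaled_r2, "hl_p": rep.hl_p,
                     "percent_correct": rep.percent_correct, "n": rep.n_used}
                )
            pd.DataFrame(rows).to_csv(d / "validation.tsv", sep="\t", index=False)
            stages_run.append("validate")

        if "epistasis" in cfg.stages:
            if not candidates:
                raise RuntimeError("epistasis stage needs candidate markers")
            d = stage_dir("epistasis")
            table = pairwise_interaction(merged, candidates, alpha=cfg.epistasis_alpha)
            table.to_csv(d / "epistasis.tsv", sep="\t", index=False)
            stages_run.append("epistasis")

        if "cluster" in cfg.stages:
            if not candidates:
                raise RuntimeError("cluster stage needs candidate markers")
            d = stage_dir("cluster")
            freqs = allele_frequencies(merged, group_by="cohort")
            mat, n_imp = breed_frequency_matrix(
                freqs, candidates, min_individuals=cfg.min_individuals
            )
            dend = cluster_average_linkage(mat)
            write_dendrogram(dend, d / "breeds.nwk", d / "merge_heights.tsv")
            stages_run.append("cluster")
    except Exception as err:
        _write_manifest(cfg, out, stages_run)
        raise RuntimeError(
            f"pipeline halted at stage after {stages_run or ['start']}: {err}"
        ) from err

    _write_manifest(cfg, out, stages_run)
    return out
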