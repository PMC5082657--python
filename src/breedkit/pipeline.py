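"""End-to-end orchestration: simulate or load -> QC -> GRM -> fit -> CV.

A single YAML config drives every stage; all randomness is routed through
per-stage child seeds of one master seed, so a rerun with the same config
and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import crossval as cv_mod
from .grm import build_grm, pca
from .lmm import ModelSpec, heritability, reml
from .markers import apply_qc, encode, impute_missing, read_genotypes, read_map
from .pedigree import Pedigree
from .phenotypes import (
    PhenotypeTable,
    protein_yield,
    read_phenotypes,
    standardized_seed_weight,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parsed pipeline configuration."""

    output_dir: str
    seed: int
    traits: list
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    pca_components: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            output_dir=raw["output_dir"],
            seed=int(raw["seed"]),
            traits=list(raw["traits"]),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            qc=raw.get("qc", {}),
            cv=raw.get("cv", {}),
            pca_components=int(raw.get("pca_components", 10)),
        )

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")
        if not self.traits:
            raise ValueError("no traits configured")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_traits(pheno: PhenotypeTable) -> PhenotypeTable:
    df = pheno.records
    ssw = None
    py = None
    if "ssw" not in df.columns and {"f2.5", "f2.2"}.issubset(df.columns):
        ssw = standardized_seed_weight(pheno)
    if "py" not in df.columns and {"protein", "yield"}.issubset(df.columns):
        py = protein_yield(pheno)
    return pheno.with_derived(ssw=ssw, py=py)


def run(config: RunConfig) -> dict:
    """Execute the pipeline and return the machine-readable summary."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": [], "traits": {}}

    # ---- stage: data -----------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.seed})
        ds = simulate_dataset(sim_cfg)
        paths = write_dataset(ds, outdir / "data")
        raw, pheno, ped = ds.genotypes, ds.phenotypes, ds.pedigree
        marker_map = ds.map
        set_labels = ds.set_of_line
        summary["stages"].append({"stage": "simulate", "n_lines": len(raw.line_ids)})
        summary["inputs"] = {k: _sha256(Path(p)) for k, p in paths.items()}
    else:
        raw = read_genotypes(config.inputs["genotypes"])
        pheno = read_phenotypes(config.inputs["phenotypes"])
        ped = (
            Pedigree.from_csv(config.inputs["pedigree"])
            if "pedigree" in config.inputs
            else None
        )
        marker_map = read_map(config.inputs["map"]) if "map" in config.inputs else None
        set_labels = None
        if "sets" in config.inputs:
            set_labels = pd.read_csv(config.inputs["sets"], index_col=0).iloc[:, 0]
        summary["stages"].append({"stage": "load", "n_lines": len(raw.line_ids)})

    pheno = _derive_traits(pheno)
    unknown = [t for t in config.traits if t not in pheno.records.columns]
    if unknown:
        raise ValueError(f"configured traits not in phenotype data: {unknown}")

    # ---- stage: QC -------------------------------------------------------
    encoded = encode(raw)
    qc_kwargs = {k: v for k, v in config.qc.items() if v is not None}
    filtered, report = apply_qc(encoded, **qc_kwargs)
    report.to_json(outdir / "qc_report.json")
    imputed = impute_missing(filtered)
    summary["stages"].append(
        {
            "stage": "qc",
            "n_markers_retained": report.n_after_maf,
            "n_lines_retained": report.n_retained_lines,
        }
    )

    # ---- stage: GRM + PCA ------------------------------------------------
    grm = build_grm(imputed)
    grm.to_csv(outdir / "grm.csv")
    k = min(config.pca_components, grm.n)
    pcs = pca(grm, k=k)
    pcs.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    summary["stages"].append(
        {
            "stage": "grm",
            "mean_diag": float(pd.Series(grm.values.diagonal()).mean()),
            "pc_variance": [float(v) for v in pcs.proportion_variance[: min(5, k)]],
        }
    )

    # ---- stage: per-trait fit + CV ---------------------------------------
    designs = config.cv.get("designs", ["loo"])
    for trait in config.traits:
        spec = ModelSpec.for_trait(trait)
        vc = reml(spec, pheno, grm)
        h2 = heritability(vc)
        trait_summary = {
            "variance_components": vc.as_dict(),
            "h2": h2.h2,
            "h2_se": h2.se,
            "max_accuracy": h2.max_accuracy,
            "reml_iterations": vc.n_iterations,
            "cv": {},
        }
        if "loo" in designs:
            res = cv_mod.loo(spec, pheno, grm, vc)
            res.gebv.rename("gebv").to_csv(outdir / f"gebv_loo_{trait}.tsv", sep="\t")
            trait_summary["cv"]["loo"] = {"accuracy": res.accuracy, "bias": res.bias}
        if "lso" in designs and set_labels is not None:
            for lab, res in cv_mod.lso(spec, pheno, grm, vc, set_labels).items():
                trait_summary["cv"][f"lso_{lab}"] = {
                    "accuracy": res.accuracy,
                    "bias": res.bias,
                }
        if "lso_random" in designs and set_labels is not None:
            sizes = tuple(set_labels.value_counts().sort_index())
            opts = config.cv.get("lso_random", {})
            for gi, res in cv_mod.lso_random(
                spec, pheno, grm, vc, sizes=sizes, seed=config.seed, **opts
            ).items():
                trait_summary["cv"][f"lso_random_{gi}"] = {
                    "accuracy": res.accuracy,
                    "bias": res.bias,
                    "sd": res.sd_accuracy,
                }
        if "lfo" in designs and ped is not None:
            opts = config.cv.get("lfo", {})
            res = cv_mod.lfo(spec, pheno, grm, vc, ped, **opts)
            trait_summary["cv"]["lfo"] = {"accuracy": res.accuracy, "bias": res.bias}
        if "reduce_training" in designs:
            opts = config.cv.get("reduce_training", {})
            res = cv_mod.reduce_training(spec, pheno, grm, vc, seed=config.seed, **opts)
            res.table.to_csv(outdir / f"reduce_training_{trait}.tsv", sep="\t", index=False)
            trait_summary["cv"]["reduce_training"] = json.loads(
                res.summary().to_json(orient="index")
            )
        if "reduce_markers" in designs and marker_map is not None:
            opts = config.cv.get("reduce_markers", {})
            res = cv_mod.reduce_markers(
                spec, pheno, imputed, vc, marker_map, seed=config.seed, **opts
            )
            res.table.to_csv(outdir / f"reduce_markers_{trait}.tsv", sep="\t", index=False)
            trait_summary["cv"]["reduce_markers"] = json.loads(
                res.summary().to_json(orient="index")
            )
        summary["traits"][trait] = trait_summary

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
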