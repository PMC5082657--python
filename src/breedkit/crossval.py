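"""Cross-validation designs for genomic prediction in breeding populations.

Four designs: leave-one-out (LOO), leave-(breeding-)set-out (LSO), the same
with random sets of matched sizes (LSO_random), and leave-family-out (LFO,
one family per parent).  Two reduction experiments probe the effect of
training-population size and marker density on LOO accuracy.

Throughout, variance components are fixed at their full-data estimates, and
accuracies are pooled correlations between held-out GEBVs and per-line
phenotypes corrected with the full-data fixed-effect estimates, so folds and
designs are directly comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm import GRM, build_grm
from .lmm import (
    MMESystem,
    ModelSpec,
    VarianceComponents,
    accuracy_and_bias,
    corrected_phenotypes,
)
from .markers import MarkerMap, MarkerMatrix
from .pedigree import Pedigree
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class FoldSpec:
    """One fold of a cross-validation design."""

    design: str
    held_out: tuple
    training: tuple
    marker_subset: tuple | None = None
    replicate_index: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.held_out) & set(self.training):
            raise ValueError("held-out and training sets overlap")


@dataclass
class CVResult:
    """Held-out GEBVs and pooled prediction metrics for one design."""

    design: str
    gebv: pd.Series  # per-line held-out prediction
    accuracy: float
    bias: float
    per_fold: pd.DataFrame | None = None  # per-fold / per-replicate metrics
    sd_accuracy: float | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.accuracy) and not -1.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [-1, 1]")


@dataclass
class ReductionExperimentResult:
    """Raw per-replicate accuracies of a reduction experiment."""

    design: str
    table: pd.DataFrame  # columns: step_size, replicate, accuracy, bias

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("step_size")["accuracy"]
        return pd.DataFrame(
            {"mean": g.mean(), "sd": g.std(ddof=1), "min": g.min(), "max": g.max()}
        )


def _analysis_lines(system: MMESystem) -> list:
    return list(pd.unique(system.cells.lines))


def _full_fit_corrected(spec, pheno, grm, vc, system=None) -> pd.Series:
    system = system or MMESystem(spec, pheno, grm, vc)
    full = system.solve()
    cp = corrected_phenotypes(full, pheno, spec)
    return cp[cp.index.isin([str(l) for l in grm.line_ids])]


# ---------------------------------------------------------------------------
# designs


def loo(spec: ModelSpec, pheno: PhenotypeTable, grm: GRM, vc: VarianceComponents) -> CVResult:
    """Leave-one-out: each genotyped, phenotyped line is predicted from a
    model trained on all other lines."""
    system = MMESystem(spec, pheno, grm, vc)
    lines = _analysis_lines(system)
    if len(lines) < 10:
        warnings.warn("fewer than 10 lines: LOO correlation will be unstable")
    cp = _full_fit_corrected(spec, pheno, grm, vc, system=system)
    gebv = system.loo_gebvs()
    acc, bias = accuracy_and_bias(gebv, cp)
    return CVResult(design="LOO", gebv=gebv, accuracy=acc, bias=bias)


def lso(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    vc: VarianceComponents,
    set_labels: pd.Series,
) -> dict:
    """Leave-set-out: each breeding set is predicted from the other(s).

    Returns one :class:`CVResult` per held-out set label.
    """
    system = MMESystem(spec, pheno, grm, vc)
    lines = _analysis_lines(system)
    labels = set_labels.astype(str)
    labels.index = labels.index.astype(str)
    groups = {lab: [l for l in lines if labels.get(l) == lab] for lab in sorted(labels.unique())}
    if len(groups) < 2:
        raise ValueError("need at least two set labels")
    for lab, members in groups.items():
        if not members:
            raise ValueError(f"set {lab!r} has no analysis lines")
    cp = _full_fit_corrected(spec, pheno, grm, vc, system=system)
    out = {}
    for lab, held in groups.items():
        training = [l for l in lines if l not in set(held)]
        if not training:
            raise ValueError(f"holding out set {lab!r} leaves no training lines")
        gebv = system.solve(training_lines=training).gebv[held]
        acc, bias = accuracy_and_bias(gebv, cp)
        out[lab] = CVResult(design=f"LSO[{lab} held out]", gebv=gebv, accuracy=acc, bias=bias)
    return out


def lso_random(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    vc: VarianceComponents,
    sizes: tuple = (119, 190),
    n_reps: int = 10,
    seed: int = 0,
) -> dict:
    """Leave-random-set-out: repeated random partitions of the same sizes as
    the breeding sets; the between-replicate SD of accuracy is the reported
    standard error."""
    system = MMESystem(spec, pheno, grm, vc)
    lines = np.array(_analysis_lines(system))
    if sum(sizes) > len(lines):
        raise ValueError(f"partition sizes {sizes} exceed {len(lines)} lines")
    cp = _full_fit_corrected(spec, pheno, grm, vc, system=system)
    rng = np.random.default_rng([int(seed), 4])
    rows = []
    last_gebv: dict[int, pd.Series] = {}
    for rep in range(n_reps):
        perm = rng.permutation(lines)
        start = 0
        parts = []
        for sz in sizes:
            parts.append(list(perm[start : start + sz]))
            start += sz
        for gi, held in enumerate(parts):
            training = [l for l in lines if l not in set(held)]
            gebv = system.solve(training_lines=training).gebv[held]
            acc, bias = accuracy_and_bias(gebv, cp)
            rows.append({"group": gi, "replicate": rep, "accuracy": acc, "bias": bias})
            last_gebv[gi] = gebv
    table = pd.DataFrame(rows)
    out = {}
    for gi in range(len(sizes)):
        sub = table[table["group"] == gi]
        out[gi] = CVResult(
            design=f"LSO_random[size={sizes[gi]}]",
            gebv=last_gebv[gi],
            accuracy=float(sub["accuracy"].mean()),
            bias=float(sub["bias"].mean()),
            per_fold=sub.reset_index(drop=True),
            sd_accuracy=float(sub["accuracy"].std(ddof=1)),
        )
    return out


def lfo(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    vc: VarianceComponents,
    ped: Pedigree,
    min_family_size: int = 4,
) -> CVResult:
    """Leave-family-out: one family per parent (all lines sharing that
    parent); families smaller than ``min_family_size`` are skipped.  A line
    held out under both of its parents contributes the mean of its held-out
    GEBVs to the pooled correlation."""
    system = MMESystem(spec, pheno, grm, vc)
    lines = set(_analysis_lines(system))
    fams = {
        p: [l for l in members if l in lines]
        for p, members in ped.families(min_size=1).items()
    }
    fams = {p: m for p, m in fams.items() if len(m) >= min_family_size}
    if not fams:
        raise ValueError(f"no family of >= {min_family_size} lines")
    logger.info("LFO: %d qualifying families", len(fams))
    cp = _full_fit_corrected(spec, pheno, grm, vc, system=system)
    preds: dict[str, list] = {}
    fold_rows = []
    for parent, members in fams.items():
        gebv = system.holdout_gebvs(members)
        for line, val in gebv.items():
            preds.setdefault(line, []).append(float(val))
        fold_rows.append({"family": parent, "n_lines": len(members)})
    pooled = pd.Series({l: float(np.mean(v)) for l, v in preds.items()}, name="gebv_lfo")
    acc, bias = accuracy_and_bias(pooled, cp)
    return CVResult(
        design="LFO", gebv=pooled, accuracy=acc, bias=bias, per_fold=pd.DataFrame(fold_rows)
    )


# ---------------------------------------------------------------------------
# reduction experiments


def _step_sizes(base: int, n_steps: int, step_frac: float, compound: bool) -> list:
    # half-up rounding so e.g. half of an odd base rounds to the larger size
    if compound:
        return [int(base * (1.0 - step_frac) ** j + 0.5) for j in range(1, n_steps + 1)]
    return [int(base * (1.0 - j * step_frac) + 0.5) for j in range(1, n_steps + 1)]


def reduce_training(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    vc: VarianceComponents,
    n_steps: int = 9,
    step_frac: float = 0.10,
    n_reps: int = 100,
    seed: int = 0,
    compound: bool = False,
    min_lines: int = 10,
) -> ReductionExperimentResult:
    """LOO accuracy in randomly reduced training populations.

    Step sizes shrink by ``step_frac`` of the *original* population per step
    (``compound=True`` multiplies by 1 - step_frac instead).  Variance
    components stay fixed at the full-data estimates passed in.
    """
    system = MMESystem(spec, pheno, grm, vc)
    lines = np.array(_analysis_lines(system))
    cp = _full_fit_corrected(spec, pheno, grm, vc, system=system)
    rng = np.random.default_rng([int(seed), 5])
    rows = []
    for size in _step_sizes(len(lines), n_steps, step_frac, compound):
        if size < min_lines:
            warnings.warn(f"step size {size} below {min_lines}; skipped")
            continue
        for rep in range(n_reps):
            subset = list(rng.choice(lines, size=size, replace=False))
            sub_sys = MMESystem(spec, pheno, grm.subset(subset), vc)
            gebv = sub_sys.loo_gebvs()
            acc, bias = accuracy_and_bias(gebv, cp)
            rows.append({"step_size": size, "replicate": rep, "accuracy": acc, "bias": bias})
    return ReductionExperimentResult(design="reduced_lines", table=pd.DataFrame(rows))


def _select_markers(
    marker_map: MarkerMap,
    available: list,
    size: int,
    min_cm: float,
    rng: np.random.Generator,
) -> list:
    """Sample ``size`` markers spread over the chromosomes: per-chromosome
    quotas proportional to availability (largest remainder), and at least
    ``min_cm`` between selected markers, halving the spacing whenever a quota
    cannot otherwise be met."""
    tbl = marker_map.table[marker_map.table["marker"].isin(set(available))]
    chroms = sorted(tbl["chromosome"].unique())
    counts = tbl.groupby("chromosome").size()
    quota_f = counts / counts.sum() * size
    quotas = quota_f.astype(int)
    remainder = (quota_f - quotas).sort_values(ascending=False)
    for c in remainder.index[: size - int(quotas.sum())]:
        quotas[c] += 1
    chosen = []
    for c in chroms:
        sub = tbl[tbl["chromosome"] == c]
        markers = sub["marker"].to_numpy()
        pos = sub["cm"].to_numpy()
        order = rng.permutation(len(markers))
        need = int(quotas[c])
        picked_idx: list[int] = []
        spacing = min_cm
        while len(picked_idx) < need and spacing > 1e-9:
            for i in order:
                if len(picked_idx) >= need:
                    break
                if i in picked_idx:
                    continue
                if all(abs(pos[i] - pos[j]) >= spacing for j in picked_idx):
                    picked_idx.append(i)
            if len(picked_idx) < need:
                spacing /= 2.0  # relax the spacing when the quota is infeasible
        if len(picked_idx) < need:
            raise ValueError(f"cannot place {need} markers on chromosome {c}")
        chosen.extend(markers[picked_idx])
    return chosen


def reduce_markers(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    genotypes: MarkerMatrix,
    vc: VarianceComponents,
    marker_map: MarkerMap,
    n_steps: int = 9,
    step_frac: float = 0.10,
    n_reps: int = 100,
    min_cm: float = 1.0,
    seed: int = 0,
    compound: bool = False,
) -> ReductionExperimentResult:
    """LOO accuracy with randomly thinned marker panels.

    Only mapped markers are selectable (the spacing rule needs cM positions);
    the GRM is rebuilt from each marker subset while variance components stay
    at their full-panel estimates.
    """
    mapped = [m for m in genotypes.marker_ids if m in set(marker_map.mapped_markers)]
    if not mapped:
        raise ValueError("no mapped markers available")
    full_grm = build_grm(genotypes)
    cp = _full_fit_corrected(spec, pheno, full_grm, vc)
    rng = np.random.default_rng([int(seed), 6])
    rows = []
    for size in _step_sizes(genotypes.n_markers, n_steps, step_frac, compound):
        if size > len(mapped):
            raise ValueError(
                f"step size {size} exceeds the {len(mapped)} mapped markers"
            )
        for rep in range(n_reps):
            subset = _select_markers(marker_map, mapped, size, min_cm, rng)
            sub_grm = build_grm(genotypes.subset_markers(subset))
            sub_sys = MMESystem(spec, pheno, sub_grm, vc)
            gebv = sub_sys.loo_gebvs()
            acc, bias = accuracy_and_bias(gebv, cp)
            rows.append({"step_size": size, "replicate": rep, "accuracy": acc, "bias": bias})
    return ReductionExperimentResult(design="reduced_markers", table=pd.DataFrame(rows))
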