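"""GBLUP linear mixed models: AI-REML, Henderson's equations, heritability.

The model for a trait y observed on field plots is

    y = X t + Z1 g + Z1 l + Z2 c + e

with fixed environment effects t (year x location, or year x location x trial
for traits measured per trial), genomic breeding values g ~ N(0, G sg2),
residual line effects l ~ N(0, I sl2) capturing genetic variance the markers
miss, genotype-by-environment effects c ~ N(0, I sc2) indexed by
line x (year x location), and iid residuals e ~ N(0, I se2).  For traits
without a separable line effect (protein yield) the l term is dropped.

Implementation note: every random term except the residual is constant
within a (line, environment, trial) cell, so the restricted likelihood
factorizes exactly into (i) the cell means with residual variance se2 / r
and (ii) the within-cell contrasts, which are iid N(0, se2) and enter only
through their sum of squares.  REML therefore works on the cell-mean
covariance matrix (a few hundred rows) rather than the full plot-level one,
with no approximation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GRM
from .phenotypes import PhenotypeTable

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Which trait to analyse and how the design factors enter the model."""

    trait: str
    fixed_factors: tuple = ("year", "location")
    include_line_effect: bool = True
    env_factors: tuple = ("year", "location")

    @classmethod
    def for_trait(cls, trait: str) -> "ModelSpec":
        """Default model per trait: trial enters the fixed effect for traits
        measured on a per-trial basis (test weight, ergosterol); protein
        yield has no separable line effect."""
        trait_l = trait.lower()
        if trait_l in ("tw", "ergosterol"):
            return cls(trait, fixed_factors=("year", "location", "trial"))
        if trait_l == "py":
            return cls(trait, include_line_effect=False)
        return cls(trait)


@dataclass
class VarianceComponents:
    """REML estimates with the average-information (curvature) matrix."""

    sigma2_g: float
    sigma2_c: float
    sigma2_e: float
    sigma2_l: float | None = None
    info_matrix: pd.DataFrame | None = None  # curvature over estimated components
    converged: bool = True
    n_iterations: int = 0
    loglik: float = float("nan")
    component_names: tuple = ()

    def __post_init__(self) -> None:
        if not self.component_names:
            names = ["g"] + (["l"] if self.sigma2_l is not None else []) + ["c", "e"]
            self.component_names = tuple(names)

    @property
    def theta(self) -> np.ndarray:
        vals = {"g": self.sigma2_g, "l": self.sigma2_l, "c": self.sigma2_c, "e": self.sigma2_e}
        return np.array([vals[n] for n in self.component_names], dtype=float)

    def as_dict(self) -> dict:
        d = {"sigma2_g": self.sigma2_g, "sigma2_c": self.sigma2_c, "sigma2_e": self.sigma2_e}
        if self.sigma2_l is not None:
            d["sigma2_l"] = self.sigma2_l
        return d


@dataclass
class HeritabilityEstimate:
    """Line-mean heritability, its standard error and the accuracy ceiling."""

    h2: float
    se: float | None
    max_accuracy: float


@dataclass
class MMESolution:
    """Joint solutions of Henderson's mixed-model equations."""

    fixed_effects: pd.Series  # estimate per fixed level
    gebv: pd.Series  # breeding value per line in the GRM (trained or not)
    line_effects: pd.Series | None
    gxe_effects: pd.Series
    trait: str


class REMLConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# design assembly


@dataclass
class _CellData:
    """Plot records collapsed to (line, fixed level, environment) cells."""

    lines: np.ndarray  # cell -> line label
    fixed_level: np.ndarray
    env: np.ndarray
    ybar: np.ndarray
    r: np.ndarray  # plots per cell
    ssw_within: float  # within-cell residual sum of squares
    n_plots: int
    y_var: float  # plot-level phenotypic variance (for floors/starts)


def _require_columns(pheno: PhenotypeTable, spec: ModelSpec) -> tuple:
    cols = set(pheno.records.columns)
    fixed = tuple(f for f in spec.fixed_factors if f in cols)
    if fixed != tuple(spec.fixed_factors):
        dropped = set(spec.fixed_factors) - set(fixed)
        logger.warning("fixed factors %s absent from data; using %s", sorted(dropped), fixed)
    env = tuple(f for f in spec.env_factors if f in cols)
    return fixed, env


def _build_cells(spec: ModelSpec, pheno: PhenotypeTable, line_universe) -> _CellData:
    if spec.trait not in pheno.records.columns:
        raise ValueError(f"trait {spec.trait!r} not in phenotype table")
    fixed_factors, env_factors = _require_columns(pheno, spec)
    df = pheno.records
    keep = df[spec.trait].notna() & df["line"].astype(str).isin(set(map(str, line_universe)))
    df = df.loc[keep].copy()
    if not len(df):
        raise ValueError("no phenotyped, genotyped records for this trait")
    df["line"] = df["line"].astype(str)
    df["_fixed"] = df[list(fixed_factors)].astype(str).agg(":".join, axis=1)
    df["_env"] = df[list(env_factors)].astype(str).agg(":".join, axis=1)
    grouped = df.groupby(["line", "_fixed", "_env"], observed=True)[spec.trait]
    agg = grouped.agg(["mean", "count", "var"]).reset_index()
    within = agg["var"].fillna(0.0) * (agg["count"] - 1)
    y = df[spec.trait].to_numpy(dtype=float)
    return _CellData(
        lines=agg["line"].to_numpy(),
        fixed_level=agg["_fixed"].to_numpy(),
        env=agg["_env"].to_numpy(),
        ybar=agg["mean"].to_numpy(dtype=float),
        r=agg["count"].to_numpy(dtype=float),
        ssw_within=float(within.sum()),
        n_plots=int(len(df)),
        y_var=float(np.var(y, ddof=1)) if len(df) > 1 else 1.0,
    )


def _one_hot(labels: np.ndarray, levels: list) -> np.ndarray:
    pos = {lv: i for i, lv in enumerate(levels)}
    out = np.zeros((len(labels), len(levels)))
    out[np.arange(len(labels)), [pos[lb] for lb in labels]] = 1.0
    return out


# ---------------------------------------------------------------------------
# REML


def _collapsed_structures(cells: _CellData, grm_sub: np.ndarray, line_order: list):
    """Covariance building blocks on the cell grid: H matrices for g, l, c
    and the diagonal residual weight D = diag(1/r)."""
    line_pos = {l: i for i, l in enumerate(line_order)}
    li = np.array([line_pos[l] for l in cells.lines])
    h_g = grm_sub[np.ix_(li, li)]
    h_l = (li[:, None] == li[None, :]).astype(float)
    ce = pd.factorize(pd.Series(cells.lines) + "|" + pd.Series(cells.env))[0]
    h_c = (ce[:, None] == ce[None, :]).astype(float)
    d = 1.0 / cells.r
    n_c_levels = int(ce.max()) + 1
    return h_g, h_l, h_c, d, n_c_levels


def restricted_loglik(theta: np.ndarray, names: tuple, cells: _CellData, x: np.ndarray,
                      h_list: list, d: np.ndarray) -> float:
    """Exact restricted log-likelihood of the full plot-level data evaluated
    through the collapsed representation (all constants included)."""
    comp = dict(zip(names, theta))
    se2 = comp["e"]
    v = se2 * np.diag(d)
    for name, h in h_list:
        v = v + comp[name] * h
    cf = cho_factor(v, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    vinv_x = cho_solve(cf, x)
    xtvx = x.T @ vinv_x
    cfx = cho_factor(xtvx, lower=True)
    logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    vinv_y = cho_solve(cf, cells.ybar)
    beta = cho_solve(cfx, x.T @ vinv_y)
    py = vinv_y - vinv_x @ beta
    ypy = float(cells.ybar @ py)
    n, p = cells.n_plots, x.shape[1]
    dfw = n - len(cells.ybar)
    return -0.5 * (
        (n - p) * LOG2PI
        + logdet_v
        + float(np.sum(np.log(cells.r)))
        + dfw * math.log(se2)
        + logdet_xtvx
        + ypy
        + cells.ssw_within / se2
    )


def reml(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_theta: float = 1e-6,
    start: dict | None = None,
) -> VarianceComponents:
    """Average-information REML with EM fallback steps.

    AI (Newton-type) updates are taken whenever they keep every component at
    or above the floor of 1e-8 x phenotypic variance and do not decrease the
    restricted likelihood; otherwise an EM-REML step (guaranteed uphill) is
    substituted.  Convergence requires both |delta logL| < ``tol_loglik`` and
    a maximum relative component change below ``tol_theta``.
    """
    pheno_lines = set(pheno.records.loc[pheno.records[spec.trait].notna(), "line"].astype(str))
    model_lines = [l for l in map(str, grm.line_ids) if l in pheno_lines]
    if len(model_lines) < 2:
        raise ValueError("need at least two genotyped, phenotyped lines")
    g_sub = grm.subset(model_lines)
    cells = _build_cells(spec, pheno, model_lines)

    fixed_levels = sorted(set(cells.fixed_level))
    x = _one_hot(cells.fixed_level, fixed_levels)
    counts = x.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("empty fixed-effect level")  # cannot happen with observed levels

    h_g, h_l, h_c, d, n_c = _collapsed_structures(cells, g_sub.values, model_lines)
    names = ("g", "l", "c", "e") if spec.include_line_effect else ("g", "c", "e")
    h_list = [("g", h_g)] + ([("l", h_l)] if spec.include_line_effect else []) + [("c", h_c)]
    q_sizes = {"g": len(model_lines), "l": len(model_lines), "c": n_c, "e": cells.n_plots}

    y_var = cells.y_var
    floor = 1e-8 * y_var
    k = len(names)
    if start:
        theta = np.array([start[n] for n in names], dtype=float)
    else:
        theta = np.full(k, 0.5 * y_var / (k - 1))
        theta[-1] = 0.5 * y_var
    theta = np.maximum(theta, floor)

    def evaluate(th):
        comp = dict(zip(names, th))
        se2 = comp["e"]
        v = se2 * np.diag(d)
        for name, h in h_list:
            v = v + comp[name] * h
        cf = cho_factor(v, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vinv = cho_solve(cf, np.eye(len(d)))
        vinv_x = vinv @ x
        xtvx = x.T @ vinv_x
        cfx = cho_factor(xtvx, lower=True)
        logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        p_mat = vinv - vinv_x @ cho_solve(cfx, vinv_x.T)
        py = p_mat @ cells.ybar
        n, p = cells.n_plots, x.shape[1]
        dfw = n - len(cells.ybar)
        ll = -0.5 * (
            (n - p) * LOG2PI
            + logdet_v
            + float(np.sum(np.log(cells.r)))
            + dfw * math.log(se2)
            + logdet_xtvx
            + float(cells.ybar @ py)
            + cells.ssw_within / se2
        )
        # scores and AI working vectors
        score = np.zeros(k)
        u_vecs = []
        for i, name in enumerate(names):
            if name == "e":
                u = d * py
                tr = float(np.sum(np.diag(p_mat) * d))
                score[i] = -0.5 * (
                    tr - float(py @ u) + dfw / se2 - cells.ssw_within / se2**2
                )
            else:
                h = dict(h_list)[name]
                u = h @ py
                score[i] = -0.5 * (float(np.sum(p_mat * h)) - float(py @ u))
            u_vecs.append(u)
        u_mat = np.column_stack(u_vecs)
        ai = 0.5 * (u_mat.T @ p_mat @ u_mat)
        ai[names.index("e"), names.index("e")] += 0.5 * dfw / se2**2
        return ll, score, ai

    trajectory = []
    prev_ll = -np.inf
    prev_theta = theta.copy()
    converged = False
    n_iter = 0
    ll = score = ai = None
    for n_iter in range(1, max_iter + 1):
        ll, score, ai = evaluate(theta)
        trajectory.append({"iter": n_iter, "loglik": ll, **dict(zip(names, theta))})
        d_ll = ll - prev_ll
        # components pinned at the floor in two successive iterates are
        # boundary solutions and do not block convergence
        pinned = (theta <= floor * 1.01) & (prev_theta <= floor * 1.01)
        rel = np.abs(theta - prev_theta) / np.maximum(np.abs(prev_theta), floor)
        d_theta = float(np.max(np.where(pinned, 0.0, rel)))
        if n_iter > 1 and abs(d_ll) < tol_loglik and d_theta < tol_theta:
            converged = True
            break
        # AI (Newton) proposal projected onto the parameter space; components
        # held at the floor by a negative score are frozen out of the update
        # (active set), keeping the AI system well conditioned.  EM fallback
        # when the step is unavailable or decreases the restricted likelihood.
        free = ~((theta <= floor * 1.01) & (score < 0.0))
        delta = None
        if free.any():
            try:
                delta = np.zeros(k)
                delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
            except np.linalg.LinAlgError:
                delta = None
        proposal = None
        if delta is not None:
            for alpha in (1.0, 0.5, 0.25):
                cand = np.maximum(theta + alpha * delta, floor)
                if restricted_loglik(cand, names, cells, x, h_list, d) >= ll - 1e-10:
                    proposal = cand
                    break
        if proposal is None:
            q = np.array([q_sizes[n] for n in names])
            proposal = np.maximum(theta + 2.0 * theta**2 / q * score, floor)
        # boundary acceleration: a small component still being pushed down is
        # snapped to the floor outright when that does not cost likelihood,
        # avoiding a geometric crawl toward zero
        shrinking = (proposal < 0.01 * y_var) & (score < 0.0) & (proposal > floor)
        if shrinking.any():
            snapped = proposal.copy()
            snapped[shrinking] = floor
            if restricted_loglik(snapped, names, cells, x, h_list, d) >= restricted_loglik(
                proposal, names, cells, x, h_list, d
            ) - 1e-10:
                proposal = snapped
        prev_ll, prev_theta = ll, theta
        theta = proposal

    if not converged:
        raise REMLConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory
        )
    comp = dict(zip(names, theta))
    info = pd.DataFrame(ai, index=list(names), columns=list(names))
    return VarianceComponents(
        sigma2_g=comp["g"],
        sigma2_l=comp.get("l"),
        sigma2_c=comp["c"],
        sigma2_e=comp["e"],
        info_matrix=info,
        converged=True,
        n_iterations=n_iter,
        loglik=ll,
        component_names=names,
    )


# ---------------------------------------------------------------------------
# mixed-model equations


def _solve_sym(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a nominally symmetric positive-definite system, falling back to
    a symmetric-indefinite solve when extreme prior scaling (a variance
    component at its floor) makes the Cholesky break down numerically."""
    try:
        return cho_solve(cho_factor(a, lower=True), b)
    except np.linalg.LinAlgError:
        from scipy.linalg import solve as dense_solve

        return dense_solve(a, b, assume_a="sym")


class MMESystem:
    """Henderson's mixed-model equations for one trait at fixed variance
    components, assembled once so that folds (masked training sets) can be
    solved either directly or by low-rank downdating of the full system.

    Breeding values are carried for every line in the GRM; lines whose
    phenotypes are excluded from training still receive GEBVs through the
    off-diagonals of G.
    """

    def __init__(self, spec: ModelSpec, pheno: PhenotypeTable, grm: GRM,
                 vc: VarianceComponents):
        self.spec = spec
        self.grm = grm
        self.vc = vc
        self.lines = [str(l) for l in grm.line_ids]
        cells = _build_cells(spec, pheno, self.lines)
        self.cells = cells
        self.fixed_levels = sorted(set(cells.fixed_level))
        n, p = len(self.lines), len(self.fixed_levels)
        x = _one_hot(cells.fixed_level, self.fixed_levels)
        line_pos = {l: i for i, l in enumerate(self.lines)}
        zg = np.zeros((len(cells.ybar), n))
        zg[np.arange(len(cells.ybar)), [line_pos[l] for l in cells.lines]] = 1.0
        self.c_keys = pd.unique(pd.Series(cells.lines) + "|" + pd.Series(cells.env))
        ckey_pos = {kk: i for i, kk in enumerate(self.c_keys)}
        zc = np.zeros((len(cells.ybar), len(self.c_keys)))
        zc[
            np.arange(len(cells.ybar)),
            [ckey_pos[kk] for kk in pd.Series(cells.lines) + "|" + pd.Series(cells.env)],
        ] = 1.0

        blocks = [x, zg] + ([zg] if spec.include_line_effect else []) + [zc]
        self.w = np.hstack(blocks)
        self.n_fixed = p
        self.n_lines = n
        self.include_l = spec.include_line_effect
        self.sl_g = slice(p, p + n)
        self.sl_l = slice(p + n, p + 2 * n) if self.include_l else None
        off = p + (2 * n if self.include_l else n)
        self.sl_c = slice(off, off + len(self.c_keys))
        self.dim = off + len(self.c_keys)

        se2 = vc.sigma2_e
        self.weights = cells.r / se2  # per-cell residual precision
        g_inv = grm.chol_inverse()
        prior = np.zeros((self.dim, self.dim))
        prior[self.sl_g, self.sl_g] = g_inv / max(vc.sigma2_g, 1e-300)
        if self.include_l:
            prior[self.sl_l, self.sl_l] = np.eye(n) / max(vc.sigma2_l, 1e-300)
        prior[self.sl_c, self.sl_c] = np.eye(len(self.c_keys)) / max(vc.sigma2_c, 1e-300)
        wr = self.w * self.weights[:, None]
        self.c_full = self.w.T @ wr + prior
        self.b_full = self.w.T @ (self.weights * cells.ybar)
        self._a_inv = None  # cached inverse of the full coefficient matrix

    # -- direct solve ------------------------------------------------------

    def solve(self, training_lines=None) -> MMESolution:
        """Solve the MME using only the phenotypes of ``training_lines``
        (default: all).  Fixed levels with no training cells are dropped with
        a warning and reported as NaN."""
        if training_lines is None:
            c_mat, b = self.c_full, self.b_full
            cell_mask = np.ones(len(self.cells.ybar), dtype=bool)
        else:
            training = set(map(str, training_lines))
            cell_mask = np.array([l in training for l in self.cells.lines])
            if not cell_mask.any():
                raise ValueError("training mask excludes every phenotype record")
            drop = ~cell_mask
            wd = self.w[drop]
            wwd = wd * self.weights[drop][:, None]
            c_mat = self.c_full - wd.T @ wwd
            b = self.b_full - wd.T @ (self.weights[drop] * self.cells.ybar[drop])
        level_counts = (
            pd.Series(self.cells.fixed_level[cell_mask]).value_counts()
            .reindex(self.fixed_levels)
            .fillna(0)
        )
        empty = [lv for lv in self.fixed_levels if level_counts[lv] == 0]
        keep_idx = np.arange(self.dim)
        if empty:
            warnings.warn(f"fixed-effect levels with no training records dropped: {empty}")
            drop_cols = [self.fixed_levels.index(lv) for lv in empty]
            keep_idx = np.delete(keep_idx, drop_cols)
            c_mat = c_mat[np.ix_(keep_idx, keep_idx)]
            b = b[keep_idx]
        sol = np.zeros(self.dim)
        sol[keep_idx] = _solve_sym(c_mat, b)
        fixed = pd.Series(sol[: self.n_fixed], index=self.fixed_levels, name="fixed")
        fixed[empty] = np.nan
        return MMESolution(
            fixed_effects=fixed,
            gebv=pd.Series(sol[self.sl_g], index=self.lines, name="gebv"),
            line_effects=(
                pd.Series(sol[self.sl_l], index=self.lines, name="line") if self.include_l else None
            ),
            gxe_effects=pd.Series(sol[self.sl_c], index=list(self.c_keys), name="gxe"),
            trait=self.spec.trait,
        )

    # -- fast holdout via Woodbury downdate --------------------------------

    def _inverse(self) -> np.ndarray:
        if self._a_inv is None:
            self._a_inv = _solve_sym(self.c_full, np.eye(self.dim))
        return self._a_inv

    def holdout_gebvs(self, held_out) -> pd.Series:
        """GEBVs of ``held_out`` lines from a model trained on all other
        lines' phenotypes, via a rank-k downdate of the full-system inverse.

        Exact (matches :meth:`solve` with the complementary training set) as
        long as the removal empties no fixed-effect level; in that case it
        falls back to the direct solve.
        """
        held = set(map(str, held_out))
        j = np.array([l in held for l in self.cells.lines])
        if not j.any():  # nothing to remove: full-data solve
            sol = self.solve()
            return sol.gebv[sorted(held)]
        remaining_levels = set(self.cells.fixed_level[~j])
        if remaining_levels != set(self.fixed_levels):
            training = [l for l in set(self.cells.lines) if l not in held]
            return self.solve(training_lines=training).gebv[sorted(held)]
        a = self._inverse()
        u = self.w[j].T  # dim x k
        w_j = self.weights[j]
        y_j = self.cells.ybar[j]
        au = a @ u
        m = np.diag(1.0 / w_j) - u.T @ au
        s0 = a @ self.b_full
        ab_f = s0 - au @ (w_j * y_j)
        ut_ab_f = u.T @ ab_f
        correction = au @ np.linalg.solve(m, ut_ab_f)
        s_f = ab_f + correction
        gebv = pd.Series(s_f[self.sl_g], index=self.lines)
        return gebv[sorted(held)]

    def loo_gebvs(self) -> pd.Series:
        """Leave-one-out GEBVs for every phenotyped line (fast path)."""
        out = {}
        for line in pd.unique(self.cells.lines):
            out[line] = float(self.holdout_gebvs([line]).iloc[0])
        return pd.Series(out, name="gebv_loo")


def solve_mme(
    spec: ModelSpec,
    pheno: PhenotypeTable,
    grm: GRM,
    vc: VarianceComponents,
    training_lines=None,
) -> MMESolution:
    """One-shot Henderson solve (see :class:`MMESystem` for repeated folds)."""
    return MMESystem(spec, pheno, grm, vc).solve(training_lines=training_lines)


# ---------------------------------------------------------------------------
# derived quantities


def heritability_from_components(
    sigma2_g: float,
    sigma2_l: float | None,
    sigma2_c: float,
    sigma2_e: float,
    n_env: int = 2,
    n_reps: int = 6,
) -> float:
    """Line-mean heritability h2 = sg2 / (sg2 + sl2 + sc2/n_env + se2/n_reps),
    dropping the sl2 term when the model has no separable line effect."""
    denom = sigma2_g + (sigma2_l or 0.0) + sigma2_c / n_env + sigma2_e / n_reps
    if denom <= 0:
        raise ZeroDivisionError("zero denominator in heritability")
    return sigma2_g / denom


def heritability(vc: VarianceComponents, n_env: int = 2, n_reps: int = 6) -> HeritabilityEstimate:
    """Heritability of line means with a delta-method standard error from the
    inverse curvature (average-information) matrix."""
    h2 = heritability_from_components(
        vc.sigma2_g, vc.sigma2_l, vc.sigma2_c, vc.sigma2_e, n_env=n_env, n_reps=n_reps
    )
    se = None
    if vc.info_matrix is not None:
        names = list(vc.component_names)
        denom = (
            vc.sigma2_g
            + (vc.sigma2_l or 0.0)
            + vc.sigma2_c / n_env
            + vc.sigma2_e / n_reps
        )
        grad = {
            "g": (denom - vc.sigma2_g) / denom**2,
            "l": -vc.sigma2_g / denom**2,
            "c": -vc.sigma2_g / (n_env * denom**2),
            "e": -vc.sigma2_g / (n_reps * denom**2),
        }
        gvec = np.array([grad[n] for n in names])
        cov = np.linalg.pinv(vc.info_matrix.to_numpy())
        se = float(np.sqrt(max(gvec @ cov @ gvec, 0.0)))
    return HeritabilityEstimate(h2=h2, se=se, max_accuracy=math.sqrt(h2))


def corrected_phenotypes(
    solution: MMESolution, pheno: PhenotypeTable, spec: ModelSpec | None = None
) -> pd.Series:
    """Per-line mean of y - X t_hat over the line's plots.

    Fixed-effect estimates come from the given solution (conventionally the
    full-data fit, so folds of a cross-validation share one correction).
    """
    spec = spec or ModelSpec.for_trait(solution.trait)
    fixed_factors, _ = _require_columns(pheno, spec)
    df = pheno.records
    keep = df[spec.trait].notna()
    df = df.loc[keep].copy()
    df["line"] = df["line"].astype(str)
    level = df[list(fixed_factors)].astype(str).agg(":".join, axis=1)
    t_hat = level.map(solution.fixed_effects)
    resid = df[spec.trait].astype(float) - t_hat
    out = resid.groupby(df["line"]).mean()
    return out.dropna().rename("corrected")


def accuracy_and_bias(gebv: pd.Series, cp: pd.Series) -> tuple[float, float]:
    """Prediction accuracy and dispersion bias.

    Accuracy is the Pearson correlation between corrected phenotypes and
    GEBVs; bias is the slope of the regression of corrected phenotypes on
    GEBVs (1.0 = correctly dispersed predictions; below 1 means GEBVs are
    overdispersed).
    """
    common = gebv.index.intersection(cp.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping lines")
    g = gebv[common].to_numpy(dtype=float)
    c = cp[common].to_numpy(dtype=float)
    if np.std(g) == 0 or np.std(c) == 0:
        warnings.warn("zero variance in GEBVs or corrected phenotypes; accuracy undefined")
        return float("nan"), float("nan")
    acc = float(np.corrcoef(c, g)[0, 1])
    bias = float(np.cov(c, g, ddof=1)[0, 1] / np.var(g, ddof=1))
    return acc, bias


def expected_accuracy(n: int, h2: float, me: float) -> float:
    """Expected accuracy of genomic prediction,
    r = sqrt(N h2 / (N h2 + Me)), from training-set size N, entry-mean
    heritability h2 and the effective number of chromosome segments Me."""
    if n < 1 or not (0.0 <= h2 <= 1.0) or me <= 0:
        raise ValueError("require N >= 1, 0 <= h2 <= 1, Me > 0")
    return math.sqrt(n * h2 / (n * h2 + me))
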