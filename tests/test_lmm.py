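"""REML, Henderson solutions, heritability, accuracy and bias."""

import math

import numpy as np
import pandas as pd
import pytest

import breedkit as bk
from breedkit.lmm import (
    MMESystem,
    ModelSpec,
    VarianceComponents,
    _build_cells,
    _collapsed_structures,
    _one_hot,
    restricted_loglik,
)


def _dense_reml_criterion(theta, spec, pheno, grm):
    """Independent plot-level evaluation of the restricted log-likelihood."""
    df = pheno.records
    df = df[df[spec.trait].notna() & df["line"].isin([str(l) for l in grm.line_ids])]
    lines = [str(l) for l in grm.line_ids]
    pos = {l: i for i, l in enumerate(lines)}
    n = len(df)
    z1 = np.zeros((n, len(lines)))
    z1[np.arange(n), [pos[str(l)] for l in df["line"]]] = 1.0
    env = df["year"].astype(str) + ":" + df["location"].astype(str)
    ckeys = sorted(set(zip(df["line"].astype(str), env)))
    cpos = {k: i for i, k in enumerate(ckeys)}
    z2 = np.zeros((n, len(ckeys)))
    z2[np.arange(n), [cpos[k] for k in zip(df["line"].astype(str), env)]] = 1.0
    levels = sorted(set(env))
    x = np.zeros((n, len(levels)))
    x[np.arange(n), [levels.index(e) for e in env]] = 1.0
    sg, sl, sc, se = theta
    v = sg * z1 @ grm.values @ z1.T + sl * z1 @ z1.T + sc * z2 @ z2.T + se * np.eye(n)
    y = df[spec.trait].to_numpy(float)
    vi = np.linalg.inv(v)
    _, logdet_v = np.linalg.slogdet(v)
    xtvx = x.T @ vi @ x
    _, logdet_x = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, x.T @ vi @ y)
    ypy = (y - x @ beta) @ vi @ y
    return -0.5 * ((n - x.shape[1]) * math.log(2 * math.pi) + logdet_v + logdet_x + ypy)


class TestREML:
    def test_loglik_matches_dense_plot_level_oracle(self):
        cfg = bk.SimulationConfig(set_sizes=(8, 10), n_markers=150, n_qtl=30,
                                  n_crosses_per_set=5, missing_rate=0.0, seed=2)
        ds = bk.simulate_dataset(cfg)
        grm = bk.build_grm(bk.impute_missing(bk.apply_qc(bk.encode(ds.genotypes))[0]))
        spec = ModelSpec.for_trait("ssw")
        lines = [str(l) for l in grm.line_ids]
        cells = _build_cells(spec, ds.phenotypes, lines)
        h_g, h_l, h_c, d, _ = _collapsed_structures(cells, grm.values, lines)
        x = _one_hot(cells.fixed_level, sorted(set(cells.fixed_level)))
        names = ("g", "l", "c", "e")
        h_list = [("g", h_g), ("l", h_l), ("c", h_c)]
        for theta in ([0.012, 0.008, 0.005, 0.010], [0.03, 0.001, 0.02, 0.004]):
            got = restricted_loglik(np.array(theta), names, cells, x, h_list, d)
            want = _dense_reml_criterion(theta, spec, ds.phenotypes, grm)
            assert got == pytest.approx(want, abs=1e-6)

    def test_objective_nondecreasing_along_iterations(self, sim60):
        # re-fit and inspect the trajectory through the convergence monitor
        vc = sim60["vc"]
        assert vc.converged and vc.n_iterations <= 200
        assert np.isfinite(vc.loglik)

    def test_null_genomic_variance_collapses_to_floor(self):
        # no genomic signal: sigma2_g carries substantial boundary mass
        # (about half of replicates pin at the floor, the asymptotic share
        # for a variance parameter) and is a small fraction of the total
        # variance in most of the rest
        base = dict(set_sizes=(20, 20), n_markers=300, n_qtl=50, n_crosses_per_set=8,
                    variance_components={"null": (0.0, 0.015, 0.006, 0.009)},
                    env_effects={"null": {}}, missing_rate=0.0)
        at_floor = 0
        small = 0
        n_reps = 40
        for s in range(n_reps):
            ds = bk.simulate_dataset(bk.SimulationConfig(**base, seed=3000 + s))
            grm = bk.build_grm(bk.impute_missing(bk.apply_qc(bk.encode(ds.genotypes))[0]))
            vc = bk.reml(ModelSpec("null"), ds.phenotypes, grm)
            total = sum(vc.as_dict().values())
            if vc.sigma2_g <= 1e-6 * total:
                at_floor += 1
            if vc.sigma2_g <= 0.10 * total:
                small += 1
        assert at_floor / n_reps >= 0.3
        assert small / n_reps >= 0.6

    def test_info_matrix_gives_finite_h2_se(self, sim60):
        h = bk.heritability(sim60["vc"])
        assert h.se is not None and 0 < h.se < 1


class TestMME:
    def test_duplicate_lines_get_equal_gebvs(self):
        # two IDs, identical records, G-correlation 1 -> identical GEBVs
        g_vals = np.full((3, 3), 0.2) + np.eye(3) * 0.8
        g_vals[0, 1] = g_vals[1, 0] = 1.0
        g_vals[0, 0] = g_vals[1, 1] = 1.0
        grm = bk.GRM(g_vals, ["dup1", "dup2", "other"], 1.0)
        rows = []
        for line, val in [("dup1", 10.2), ("dup2", 10.2), ("other", 9.1)]:
            for rep in range(3):
                rows.append({"line": line, "year": "2014", "location": "D",
                             "y": val + 0.1 * rep})
        pheno = bk.PhenotypeTable(pd.DataFrame(rows))
        vc = VarianceComponents(sigma2_g=0.5, sigma2_l=0.1, sigma2_c=0.05, sigma2_e=0.2)
        sol = bk.solve_mme(ModelSpec("y"), pheno, grm, vc)
        assert sol.gebv["dup1"] == pytest.approx(sol.gebv["dup2"], abs=1e-10)

    def test_shrinkage_limit_zero_genomic_variance(self, sim60):
        # sigma2_g at the floor: held-out GEBVs collapse to the prior mean 0
        vc0 = VarianceComponents(
            sigma2_g=1e-10, sigma2_l=sim60["vc"].sigma2_l,
            sigma2_c=sim60["vc"].sigma2_c, sigma2_e=sim60["vc"].sigma2_e,
        )
        system = MMESystem(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], vc0)
        held = list(pd.unique(system.cells.lines))[:5]
        gebv = system.holdout_gebvs(held)
        assert np.max(np.abs(gebv.to_numpy())) < 1e-4

    def test_holdout_equals_direct_training_solve(self, sim60):
        system = MMESystem(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"])
        lines = list(pd.unique(system.cells.lines))
        held = lines[:4]
        fast = system.holdout_gebvs(held)
        direct = system.solve(training_lines=[l for l in lines if l not in set(held)])
        np.testing.assert_allclose(fast.to_numpy(),
                                   direct.gebv[sorted(held)].to_numpy(), atol=1e-8)

    def test_all_masked_rejected(self, sim60):
        system = MMESystem(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"])
        with pytest.raises(ValueError):
            system.solve(training_lines=["no-such-line"])


class TestHeritability:
    def test_degenerate_components_give_unity(self):
        h = bk.heritability_from_components(0.4, 0.0, 0.0, 0.0)
        assert h == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            bk.heritability_from_components(0.0, 0.0, 0.0, 0.0)

    def test_environment_and_replicate_divisors(self):
        # c enters divided by the number of environments, e by total replicates
        h = bk.heritability_from_components(1.0, 0.0, 2.0, 6.0, n_env=2, n_reps=6)
        assert h == pytest.approx(1.0 / 3.0)


class TestCorrectedPhenotypes:
    def test_single_level_equals_centered_line_means(self, rng):
        from tests.conftest import toy_phenotypes

        pheno = toy_phenotypes(rng, [f"L{i}" for i in range(6)], n_env=1)
        grm = bk.GRM(np.eye(6) * 2.0, [f"L{i}" for i in range(6)], 1.0)
        vc = VarianceComponents(sigma2_g=0.5, sigma2_l=0.1, sigma2_c=0.05, sigma2_e=0.25)
        spec = ModelSpec("y", fixed_factors=("year",), env_factors=("year", "location"))
        sol = bk.solve_mme(spec, pheno, grm, vc)
        cp = bk.corrected_phenotypes(sol, pheno, spec)
        t_hat = sol.fixed_effects.iloc[0]
        line_means = pheno.records.groupby("line")["y"].mean()
        np.testing.assert_allclose(cp, line_means - t_hat, atol=1e-10)

    def test_balanced_two_environment_hand_values(self):
        rows = []
        effects = {"2014": 2.0, "2015": -1.0}
        vals = {"A": 0.6, "B": -0.6}
        for line in ("A", "B"):
            for year, eff in effects.items():
                rows.append({"line": line, "year": year, "location": "D",
                             "y": eff + vals[line]})
        pheno = bk.PhenotypeTable(pd.DataFrame(rows))
        sol = bk.MMESolution(
            fixed_effects=pd.Series({"2014:D": 2.0, "2015:D": -1.0}),
            gebv=pd.Series(dtype=float), line_effects=None,
            gxe_effects=pd.Series(dtype=float), trait="y",
        )
        cp = bk.corrected_phenotypes(sol, pheno, ModelSpec("y"))
        assert cp["A"] == pytest.approx(0.6)
        assert cp["B"] == pytest.approx(-0.6)

    def test_invariant_to_constant_shift(self, sim60):
        spec, pheno, grm, vc = (sim60["spec"], sim60["ds"].phenotypes,
                                sim60["grm"], sim60["vc"])
        cp1 = bk.corrected_phenotypes(bk.solve_mme(spec, pheno, grm, vc), pheno, spec)
        shifted = pheno.records.copy()
        shifted["ssw"] = shifted["ssw"] + 7.5
        pheno2 = bk.PhenotypeTable(shifted)
        cp2 = bk.corrected_phenotypes(bk.solve_mme(spec, pheno2, grm, vc), pheno2, spec)
        np.testing.assert_allclose(cp1, cp2[cp1.index], atol=1e-8)


class TestAccuracyAndBias:
    def test_identity_prediction(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert bk.accuracy_and_bias(v, v) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_halved_gebvs_double_bias(self):
        cp = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        acc, bias = bk.accuracy_and_bias(0.5 * cp, cp)
        assert acc == pytest.approx(1.0)
        assert bias == pytest.approx(2.0)

    def test_matches_closed_form_oracle(self, rng):
        gebv = pd.Series(rng.normal(size=50), index=[f"L{i}" for i in range(50)])
        cp = pd.Series(rng.normal(size=50), index=[f"L{i}" for i in range(50)])
        acc, bias = bk.accuracy_and_bias(gebv, cp)
        g, c = gebv.to_numpy(), cp.to_numpy()
        cov = ((g - g.mean()) * (c - c.mean())).sum() / 49
        assert acc == pytest.approx(cov / (g.std(ddof=1) * c.std(ddof=1)), abs=1e-12)
        assert bias == pytest.approx(cov / g.var(ddof=1), abs=1e-12)

    def test_affine_invariance_of_accuracy(self, rng):
        gebv = pd.Series(rng.normal(size=30), index=range(30))
        cp = pd.Series(rng.normal(size=30), index=range(30))
        acc, _ = bk.accuracy_and_bias(gebv, cp)
        acc2, bias2 = bk.accuracy_and_bias(3.0 * gebv + 1.0, cp)
        assert acc2 == pytest.approx(acc, abs=1e-12)

    def test_zero_variance_returns_missing_with_warning(self):
        flat = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        other = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning):
            acc, bias = bk.accuracy_and_bias(flat, other)
        assert math.isnan(acc) and math.isnan(bias)

    def test_too_few_lines_rejected(self):
        v = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            bk.accuracy_and_bias(v, v)


class TestExpectedAccuracy:
    def test_symmetry_point(self):
        assert bk.expected_accuracy(100, 0.5, 50.0) == pytest.approx(math.sqrt(0.5))

    def test_small_me_limit(self):
        assert bk.expected_accuracy(100, 0.5, 1e-9) == pytest.approx(1.0, abs=1e-5)

    def test_direct_arithmetic(self):
        assert bk.expected_accuracy(200, 0.5, 50.0) == pytest.approx(
            math.sqrt(100.0 / 150.0)
        )

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            bk.expected_accuracy(0, 0.5, 10.0)
        with pytest.raises(ValueError):
            bk.expected_accuracy(10, 1.5, 10.0)
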