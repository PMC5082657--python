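"""Cross-validation designs: fold construction, leakage audit, pooling rules
and the reduction-experiment schedules."""

import numpy as np
import pandas as pd
import pytest

import breedkit as bk
from breedkit.crossval import FoldSpec, _select_markers, _step_sizes
from breedkit.lmm import MMESystem, ModelSpec, VarianceComponents


class TestFoldSpec:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            FoldSpec(design="LOO", held_out=("a",), training=("a", "b"))


class TestLOO:
    def test_no_signal_gives_near_zero_accuracy(self):
        # a single 100-line replicate has accuracy SD ~ 0.15 under the null,
        # so the check averages over seeds
        accs = []
        for seed in (31, 32, 33, 34, 35):
            cfg = bk.SimulationConfig(
                set_sizes=(50, 50), n_markers=250, n_qtl=40, n_crosses_per_set=15,
                variance_components={"null": (0.0, 0.012, 0.006, 0.009)},
                env_effects={"null": {}}, missing_rate=0.0, seed=seed,
            )
            ds = bk.simulate_dataset(cfg)
            grm = bk.build_grm(
                bk.impute_missing(bk.apply_qc(bk.encode(ds.genotypes))[0])
            )
            vc = VarianceComponents(sigma2_g=1e-6, sigma2_l=0.012, sigma2_c=0.006,
                                    sigma2_e=0.009)
            res = bk.loo(ModelSpec("null"), ds.phenotypes, grm, vc)
            accs.append(res.accuracy)
        assert abs(np.mean(accs)) <= 0.15
        assert max(abs(a) for a in accs) < 0.5

    def test_duplicate_line_predicted_from_its_twin(self, sim60):
        # append a twin of one line: same G row, same phenotypes, new id
        grm, ds = sim60["grm"], sim60["ds"]
        line = str(grm.line_ids[0])
        n = grm.n
        vals = np.zeros((n + 1, n + 1))
        vals[:n, :n] = grm.values
        vals[n, :n] = vals[:n, n] = grm.values[0, :]
        vals[n, n] = grm.values[0, 0]
        twin_grm = bk.GRM(vals, list(map(str, grm.line_ids)) + ["twin"], 1.0)
        recs = ds.phenotypes.records
        twin_rows = recs[recs["line"] == line].copy()
        twin_rows["line"] = "twin"
        pheno = bk.PhenotypeTable(pd.concat([recs, twin_rows], ignore_index=True))
        system = MMESystem(sim60["spec"], pheno, twin_grm, sim60["vc"])
        held = system.holdout_gebvs(["twin"])
        trained = system.solve().gebv[line]
        # the held-out twin's GEBV tracks its training twin's
        assert np.sign(held.iloc[0]) == np.sign(trained) or abs(trained) < 1e-6
        assert abs(held.iloc[0] - trained) < 0.6 * max(abs(trained), 1e-6) + 1e-6


class TestLSO:
    def test_each_direction_reported(self, sim60):
        res = bk.lso(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"],
                     sim60["ds"].set_of_line)
        assert set(res) == {"S2014", "S2015"}
        for r in res.values():
            assert -1 <= r.accuracy <= 1

    def test_single_label_rejected(self, sim60):
        labels = pd.Series("ALL", index=[str(l) for l in sim60["grm"].line_ids])
        with pytest.raises(ValueError):
            bk.lso(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"],
                   labels)

    def test_empty_set_rejected(self, sim60):
        labels = sim60["ds"].set_of_line.copy().astype(str)
        labels[:] = "S2014"
        # second label exists only on a line absent from the analysis
        labels = pd.concat([labels, pd.Series({"no-such-line": "GHOST"})])
        with pytest.raises(ValueError, match="no analysis lines"):
            bk.lso(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"],
                   labels)


class TestLSORandom:
    def test_seed_reproducibility(self, sim60):
        args = (sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"])
        a = bk.lso_random(*args, sizes=(25, 30), n_reps=3, seed=5)
        b = bk.lso_random(*args, sizes=(25, 30), n_reps=3, seed=5)
        for gi in a:
            assert a[gi].accuracy == b[gi].accuracy
            pd.testing.assert_frame_equal(a[gi].per_fold, b[gi].per_fold)

    def test_sd_over_exactly_n_reps(self, sim60):
        res = bk.lso_random(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"],
                            sim60["vc"], sizes=(25, 30), n_reps=4, seed=1)
        for r in res.values():
            assert len(r.per_fold) == 4
            assert r.sd_accuracy == pytest.approx(r.per_fold["accuracy"].std(ddof=1))

    def test_oversized_partition_rejected(self, sim60):
        with pytest.raises(ValueError):
            bk.lso_random(sim60["spec"], sim60["ds"].phenotypes, sim60["grm"],
                          sim60["vc"], sizes=(1000, 10), n_reps=1, seed=1)


class TestLFO:
    def _toy_system(self):
        rng = np.random.default_rng(8)
        lines = [f"L{i}" for i in range(12)]
        w = rng.normal(size=(12, 60))
        g = bk.GRM(w @ w.T / 60 + 0.5 * np.eye(12), lines, 1.0)
        rows = []
        for i, line in enumerate(lines):
            for rep in range(2):
                rows.append({"line": line, "year": "2014", "location": "D",
                             "y": rng.normal()})
        pheno = bk.PhenotypeTable(pd.DataFrame(rows))
        vc = VarianceComponents(sigma2_g=0.4, sigma2_l=0.2, sigma2_c=0.1, sigma2_e=0.5)
        return ModelSpec("y"), pheno, g, vc, lines

    def test_disjoint_full_sib_families_predict_each_line_once(self):
        spec, pheno, g, vc, lines = self._toy_system()
        ped = bk.Pedigree(pd.DataFrame({
            "line": lines,
            "parent1": ["P1"] * 6 + ["P3"] * 6,
            "parent2": ["P2"] * 6 + ["P4"] * 6,
        }))
        res = bk.lfo(spec, pheno, g, vc, ped, min_family_size=4)
        # every line belongs to exactly 2 qualifying families (both parents),
        # but the two families of a full-sib group are identical line sets
        assert len(res.per_fold) == 4
        assert len(res.gebv) == 12

    def test_line_in_two_qualifying_families_averaged(self):
        spec, pheno, g, vc, lines = self._toy_system()
        # L0 shares parent A with lines 1-5 and parent B with lines 6-10
        ped = bk.Pedigree(pd.DataFrame({
            "line": lines,
            "parent1": ["A"] * 6 + ["B"] * 5 + ["C"],
            "parent2": ["B"] + ["X"] * 5 + ["Y"] * 5 + ["D"],
        }))
        fams = ped.families(min_size=4)
        assert set(fams) >= {"A", "B"}
        assert "L0" in fams["A"] and "L0" in fams["B"]
        res = bk.lfo(spec, pheno, g, vc, ped, min_family_size=4)
        system = MMESystem(spec, pheno, g, vc)
        ga = system.holdout_gebvs(fams["A"])["L0"]
        gb = system.holdout_gebvs(fams["B"])["L0"]
        assert res.gebv["L0"] == pytest.approx((ga + gb) / 2.0, abs=1e-10)

    def test_min_family_size_threshold_count(self):
        sizes = {"P1": 2, "P2": 3, "P3": 4, "P4": 10}
        rows = []
        i = 0
        for parent, size in sizes.items():
            for _ in range(size):
                rows.append({"line": f"L{i}", "parent1": parent, "parent2": f"U{i}"})
                i += 1
        ped = bk.Pedigree(pd.DataFrame(rows))
        fams = ped.families(min_size=4)
        qualifying = {p: m for p, m in fams.items() if p in sizes}
        assert set(qualifying) == {"P3", "P4"}

    def test_no_qualifying_family_rejected(self):
        spec, pheno, g, vc, lines = self._toy_system()
        ped = bk.Pedigree(pd.DataFrame({
            "line": lines,
            "parent1": [f"P{i}" for i in range(12)],
            "parent2": [f"Q{i}" for i in range(12)],
        }))
        with pytest.raises(ValueError):
            bk.lfo(spec, pheno, g, vc, ped, min_family_size=4)


class TestReductionExperiments:
    def test_training_schedule_arithmetic(self):
        sizes = _step_sizes(309, n_steps=9, step_frac=0.10, compound=False)
        assert sizes == [278, 247, 216, 185, 155, 124, 93, 62, 31]
        compounded = _step_sizes(309, n_steps=2, step_frac=0.10, compound=True)
        assert compounded == [278, 250]

    def test_reduce_training_reproducible_and_leak_free(self, sim60):
        args = (sim60["spec"], sim60["ds"].phenotypes, sim60["grm"], sim60["vc"])
        a = bk.reduce_training(*args, n_steps=2, step_frac=0.25, n_reps=2, seed=3)
        b = bk.reduce_training(*args, n_steps=2, step_frac=0.25, n_reps=2, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        n = len(pd.unique(a.table["step_size"]))
        assert n == 2
        expected = {int(sim60["grm"].n * 0.75 + 0.5), int(sim60["grm"].n * 0.5 + 0.5)}
        assert set(a.table["step_size"]) == expected

    def test_tiny_subsets_skipped_with_warning(self, sim60):
        with pytest.warns(UserWarning, match="skipped"):
            res = bk.reduce_training(sim60["spec"], sim60["ds"].phenotypes,
                                     sim60["grm"], sim60["vc"],
                                     n_steps=9, step_frac=0.10, n_reps=1, seed=1,
                                     min_lines=40)
        assert (res.table["step_size"] >= 40).all()

    def test_marker_allocation_one_per_chromosome(self):
        rows = [{"marker": f"M{c}_{i}", "chromosome": c, "cm": float(10 * i)}
                for c in range(1, 8) for i in range(5)]
        mmap = bk.MarkerMap(pd.DataFrame(rows))
        rng = np.random.default_rng(0)
        chosen = _select_markers(mmap, [r["marker"] for r in rows], 7, 1.0, rng)
        chrom_of = mmap.chromosome_of()
        assert sorted(chrom_of[m] for m in chosen) == list(range(1, 8))

    def test_same_position_markers_never_coselected(self):
        rows = [
            {"marker": "dupA", "chromosome": 1, "cm": 10.0},
            {"marker": "dupB", "chromosome": 1, "cm": 10.0},
            {"marker": "far1", "chromosome": 1, "cm": 50.0},
            {"marker": "far2", "chromosome": 1, "cm": 90.0},
        ]
        mmap = bk.MarkerMap(pd.DataFrame(rows))
        rng = np.random.default_rng(0)
        for _ in range(30):
            chosen = set(_select_markers(mmap, [r["marker"] for r in rows], 3, 1.0, rng))
            assert not {"dupA", "dupB"} <= chosen

    def test_reduce_markers_requires_mapped_budget(self, sim60):
        # only a handful of mapped markers: requesting more must fail
        imputed = sim60["imputed"]
        small_map = bk.MarkerMap(
            sim60["ds"].map.table[sim60["ds"].map.table["marker"].isin(
                imputed.marker_ids[:10])]
        )
        with pytest.raises(ValueError, match="mapped"):
            bk.reduce_markers(sim60["spec"], sim60["ds"].phenotypes, imputed,
                              sim60["vc"], small_map, n_steps=1, step_frac=0.10,
                              n_reps=1, seed=1)

    def test_reduce_markers_runs_and_is_reproducible(self, sim60):
        args = dict(n_steps=2, step_frac=0.3, n_reps=2, seed=9)
        a = bk.reduce_markers(sim60["spec"], sim60["ds"].phenotypes, sim60["imputed"],
                              sim60["vc"], sim60["ds"].map, **args)
        b = bk.reduce_markers(sim60["spec"], sim60["ds"].phenotypes, sim60["imputed"],
                              sim60["vc"], sim60["ds"].map, **args)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert (a.table["accuracy"].abs() <= 1).all()
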