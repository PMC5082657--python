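import numpy as np
import pandas as pd
import pytest

import breedkit as bk
from breedkit.lmm import ModelSpec


@pytest.fixture(scope="session")
def sim60():
    """A 60-line synthetic breeding population with QC'd markers, GRM and a
    fitted SSW model, shared across tests that only read it."""
    cfg = bk.SimulationConfig(
        set_sizes=(25, 35),
        n_markers=400,
        n_qtl=60,
        n_crosses_per_set=10,
        seed=42,
    )
    ds = bk.simulate_dataset(cfg)
    filtered, report = bk.apply_qc(bk.encode(ds.genotypes))
    imputed = bk.impute_missing(filtered)
    grm = bk.build_grm(imputed)
    spec = ModelSpec.for_trait("ssw")
    vc = bk.reml(spec, ds.phenotypes, grm)
    return {
        "config": cfg,
        "ds": ds,
        "qc_report": report,
        "imputed": imputed,
        "grm": grm,
        "spec": spec,
        "vc": vc,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_marker_matrix(rng, n_lines=20, n_markers=50, missing_rate=0.0):
    """Random -1/0/+1 matrix with data-driven polymorphism."""
    vals = rng.choice([-1.0, 0.0, 1.0], size=(n_lines, n_markers), p=[0.45, 0.1, 0.45])
    mask = rng.random((n_lines, n_markers)) < missing_rate
    return bk.MarkerMatrix(
        vals, mask, [f"L{i}" for i in range(n_lines)], [f"M{j}" for j in range(n_markers)]
    )


def toy_phenotypes(rng, lines, n_env=2, n_reps=3, mean=10.0, line_sd=1.0, resid_sd=0.5):
    """Balanced plot table with a per-line shift and iid residuals."""
    rows = []
    shifts = {l: rng.normal(0.0, line_sd) for l in lines}
    plot = 0
    for line in lines:
        for e in range(n_env):
            year = "2014" if e == 0 else "2015"
            for rep in range(n_reps):
                plot += 1
                rows.append(
                    {
                        "line": line,
                        "year": year,
                        "location": "Loc",
                        "trial": f"{year}:T1",
                        "block": f"B{rep + 1}",
                        "plot": plot,
                        "y": mean + shifts[line] + rng.normal(0.0, resid_sd),
                    }
                )
    return bk.PhenotypeTable(pd.DataFrame(rows))
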