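"""Plot-level phenotype tables and derived traits.

The seed-size fractions from a 100 g sample (f2.8, f2.5, f2.2, in grams)
are heavily skewed, so a normally distributed standardized seed weight (SSW)
is derived by a rank-based inverse-normal transform of the two smaller
fractions.  Protein yield (PY) is protein content times grain yield.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ["line", "year", "location", "trial", "block", "plot"]
TRAIT_COLUMNS = ["f2.8", "f2.5", "f2.2", "protein", "tw", "ergosterol", "yield"]
DERIVED_COLUMNS = ["ssw", "py"]
REQUIRED_FACTORS = ["line", "year", "location"]


@dataclass
class PhenotypeTable:
    """Plot-level records: design factors plus one column per trait.

    Rows with missing trait values are retained (a missing cell simply drops
    out of that trait's analysis), mirroring trials where a measurement was
    obtained from only two of the three replicates.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_FACTORS if c not in self.records.columns]
        if missing:
            raise ValueError(f"phenotype table missing required factor columns: {missing}")
        self.records = self.records.reset_index(drop=True)
        for frac in ("f2.8", "f2.5", "f2.2"):
            if frac in self.records.columns and (self.records[frac].dropna() < 0).any():
                raise ValueError(f"negative seed-fraction weight in {frac}")

    @property
    def lines(self) -> list:
        return sorted(self.records["line"].astype(str).unique())

    @property
    def trait_columns(self) -> list:
        return [c for c in self.records.columns if c not in FACTOR_COLUMNS]

    def environment(self) -> pd.Series:
        """The year x location environment label of every plot."""
        return (
            self.records["year"].astype(str) + ":" + self.records["location"].astype(str)
        ).rename("environment")

    def with_derived(self, ssw: pd.Series | None = None, py: pd.Series | None = None):
        df = self.records.copy()
        if ssw is not None:
            df["ssw"] = ssw
        if py is not None:
            df["py"] = py
        return PhenotypeTable(df)


@dataclass
class TraitSummary:
    """Mean, SD and n per trait, overall and per year x location."""

    overall: pd.DataFrame  # index trait, columns mean/sd/n
    by_environment: pd.DataFrame  # index (trait, year, location)


def read_phenotypes(path, column_map: dict | None = None) -> PhenotypeTable:
    """Read a phenotype table from CSV (or XLSX via openpyxl).

    ``column_map`` renames file columns to the canonical names; columns that
    are neither factors nor known traits are kept but flagged with a warning.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    known = set(FACTOR_COLUMNS) | set(TRAIT_COLUMNS) | set(DERIVED_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("read_phenotypes: unknown columns kept as extra traits: %s", unknown)
    for factor in ("line", "year", "location", "trial", "block"):
        if factor in df.columns:
            df[factor] = df[factor].astype(str)
    return PhenotypeTable(df)


def write_phenotypes(t: PhenotypeTable, path) -> None:
    t.records.to_csv(path, index=False)


def inverse_normal_transform(x: pd.Series, offset: str = "half") -> pd.Series:
    """Rank-based inverse-normal transform with average ranks for ties.

    ``offset='half'`` uses quantiles (r - 0.5)/n; ``offset='blom'`` uses
    (r - 3/8)/(n + 1/4).
    """
    vals = x.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    n = int(obs.sum())
    if len(np.unique(vals[obs])) < 3:
        raise ValueError("inverse-normal transform needs at least 3 distinct values")
    ranks = rankdata(vals[obs], method="average")
    if offset == "half":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown quantile offset {offset!r}")
    out = np.full(len(vals), np.nan)
    out[obs] = ndtri(q)
    return pd.Series(out, index=x.index, name=x.name)


def standardized_seed_weight(
    t: PhenotypeTable,
    fractions: tuple[str, ...] = ("f2.5", "f2.2"),
    within_env: bool = False,
    offset: str = "half",
) -> pd.Series:
    """Per-plot SSW: average of the inverse-normal-transformed fraction
    weights, negated so that larger seeds give larger SSW.

    The two smaller fractions shrink as seeds grow, so the sign flip makes
    SSW correlate positively with the largest fraction.  By default the
    transform pools all plots; ``within_env=True`` ranks within each
    year x location instead.
    """
    for f in fractions:
        if f not in t.records.columns:
            raise ValueError(f"fraction column {f!r} not present")

    def _transform(series: pd.Series) -> pd.Series:
        return inverse_normal_transform(series, offset=offset)

    parts = []
    for f in fractions:
        col = t.records[f]
        if within_env:
            env = t.environment()
            part = col.groupby(env).transform(_transform)
        else:
            part = _transform(col)
        parts.append(part)
    ssw = -sum(parts) / len(parts)
    return ssw.rename("ssw")


def protein_yield(t: PhenotypeTable) -> pd.Series:
    """Per-plot protein yield PY = (protein% / 100) * yield, in hkg/ha."""
    for c in ("protein", "yield"):
        if c not in t.records.columns:
            raise ValueError(f"column {c!r} not present")
    protein = t.records["protein"]
    yld = t.records["yield"]
    if (protein.dropna() < 0).any() or (yld.dropna() < 0).any():
        raise ValueError("negative protein or yield")
    return (protein / 100.0 * yld).rename("py")


def summarize(t: PhenotypeTable, traits: list | None = None) -> TraitSummary:
    """Mean +/- SD and n per trait, overall and per year x location,
    excluding missing values pairwise."""
    if not len(t.records):
        raise ValueError("empty phenotype table")
    traits = traits or [c for c in t.trait_columns if pd.api.types.is_numeric_dtype(t.records[c])]
    overall = pd.DataFrame(
        {
            "mean": t.records[traits].mean(),
            "sd": t.records[traits].std(ddof=1),
            "n": t.records[traits].count(),
        }
    )
    overall.index.name = "trait"
    grouped = t.records.groupby(["year", "location"], observed=True)[traits]
    by_env = pd.concat(
        {
            "mean": grouped.mean(),
            "sd": grouped.std(ddof=1),
            "n": grouped.count(),
        },
        axis=1,
    )
    by_env = by_env.stack(level=1, future_stack=True)
    by_env.index.names = ["year", "location", "trait"]
    return TraitSummary(overall=overall, by_environment=by_env)
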