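"""Synthetic breeding-program generator.

Emulates the data structure of a two-set spring-barley programme: two
breeding sets of F6 lines derived from partially overlapping parent pools,
genotyped at biallelic SNPs spread over seven chromosomes, and phenotyped in
replicated field trials at two locations in the set's harvest year.  Traits
are generated under the additive model the downstream analysis assumes:

    y_plot = env + g + l + c + e

with genomic breeding values g built from marker QTL, a residual line effect
l, a line x environment interaction c, and iid plot residuals e.

Meiosis uses a Poisson crossover process at 1 crossover per 100 cM with no
interference (Haldane); founders are fully inbred with second-allele
frequencies drawn uniformly from a configurable range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerMap, RawGenotypeTable, write_genotypes, write_map
from .pedigree import Pedigree
from .phenotypes import PhenotypeTable, write_phenotypes

#: per-trait (sigma2_g, sigma2_l, sigma2_c, sigma2_e) on the trait's own scale;
#: a None line component means the trait's model carries no separable l term
DEFAULT_VARIANCE_COMPONENTS: dict[str, tuple] = {
    "ssw": (0.014, 0.009, 0.006, 0.009),
    "protein": (0.018, 0.018, 0.055, 0.145),
    "tw": (0.52, 0.13, 0.30, 1.30),
    "ergosterol": (1.16, 0.50, 0.39, 0.39),
    "yield": (12.0, 4.0, 8.0, 12.0),
}

#: fixed year x location effects per trait (trait means per environment)
DEFAULT_ENV_EFFECTS: dict[str, dict] = {
    "ssw": {"2014:Dyngby": 0.15, "2014:Holeby": 0.10, "2015:Dyngby": -0.10, "2015:Holeby": -0.15},
    "protein": {"2014:Dyngby": 10.3, "2014:Holeby": 9.4, "2015:Dyngby": 9.2, "2015:Holeby": 8.3},
    "tw": {"2014:Dyngby": 66.8, "2014:Holeby": 68.4, "2015:Dyngby": 68.5, "2015:Holeby": 68.9},
    "ergosterol": {"2014:Dyngby": 13.8, "2014:Holeby": 9.0, "2015:Dyngby": 14.6, "2015:Holeby": 14.0},
    "yield": {"2014:Dyngby": 93.0, "2014:Holeby": 88.0, "2015:Dyngby": 91.0, "2015:Holeby": 89.0},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic breeding programme.

    Defaults mirror the structure of the study population this generator
    emulates: 119 + 190 F6 lines from two parent pools sharing 16 parents,
    ~3,500 markers on 7 chromosomes, two locations x three replicates in the
    set's harvest year, and trait variance components on the scales of the
    reference analysis.
    """

    set_sizes: tuple = (119, 190)
    n_parents: int = 104
    n_shared_parents: int = 16
    n_chromosomes: int = 7
    chromosome_length: float = 150.0  # cM
    n_markers: int = 3500
    n_qtl: int = 100  # per trait
    variance_components: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_VARIANCE_COMPONENTS.items()}
    )
    env_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENV_EFFECTS.items()})
    years: tuple = ("2014", "2015")  # one per breeding set
    locations: tuple = ("Dyngby", "Holeby")
    n_replicates: int = 3
    selfing_generations: int = 5  # F6
    founder_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.01
    n_crosses_per_set: int = 50
    trial_size: int = 30  # lines per trial
    n_check_lines: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_parents > self.n_parents:
            raise ValueError("n_shared_parents cannot exceed n_parents")
        if any(s <= 0 for s in self.set_sizes):
            raise ValueError("set sizes must be positive")
        if self.n_parents < 2:
            raise ValueError("need at least 2 parents")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome length must be positive")
        for trait, comps in self.variance_components.items():
            for v in comps:
                if v is not None and v < 0:
                    raise ValueError(f"negative variance for trait {trait!r}")

    @property
    def n_lines(self) -> int:
        return int(sum(self.set_sizes))

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class SimulatedDataset:
    genotypes: RawGenotypeTable
    phenotypes: PhenotypeTable
    pedigree: Pedigree
    map: MarkerMap
    true_breeding_values: pd.DataFrame  # lines x traits
    true_components: dict  # trait -> (g, l, c, e)
    set_of_line: pd.Series  # line -> breeding-set label


# ---------------------------------------------------------------------------
# genetic map


def simulate_map(config: SimulationConfig) -> MarkerMap:
    """Assign markers to chromosomes in near-equal numbers (counts differ by
    at most one) with positions uniform on [0, chromosome_length], sorted
    within chromosome."""
    if config.n_markers < config.n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = config.rng(1)
    base, extra = divmod(config.n_markers, config.n_chromosomes)
    rows = []
    idx = 0
    for chrom in range(1, config.n_chromosomes + 1):
        count = base + (1 if chrom <= extra else 0)
        pos = np.sort(rng.uniform(0.0, config.chromosome_length, size=count))
        for p in pos:
            rows.append((f"M{idx:05d}", chrom, float(p)))
            idx += 1
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]))


# ---------------------------------------------------------------------------
# population


def _gamete(h1: np.ndarray, h2: np.ndarray, chrom_slices, chrom_positions, lengths,
            rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: Poisson crossovers at 1 per 100 cM, no
    interference, random starting strand per chromosome."""
    out = np.empty_like(h1)
    for sl, pos, length in zip(chrom_slices, chrom_positions, lengths):
        n_x = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if n_x == 0:
            src = h1 if start == 0 else h2
            out[sl] = src[sl]
            continue
        cuts = np.sort(rng.uniform(0.0, length, size=n_x))
        # segment index of each marker; even segments from the starting strand
        seg = np.searchsorted(cuts, pos, side="right")
        use_h1 = (seg % 2 == 0) if start == 0 else (seg % 2 == 1)
        out[sl] = np.where(use_h1, h1[sl], h2[sl])
    return out


def simulate_population(
    config: SimulationConfig, marker_map: MarkerMap
) -> tuple[RawGenotypeTable, Pedigree, np.ndarray, pd.Series]:
    """Simulate parents, crosses and F6 progeny.

    Returns the genotype table (with missing calls injected), the pedigree,
    the true -1/0/+1 codes before missingness, and the breeding-set label of
    every line.
    """
    rng = config.rng(2)
    m = len(marker_map.table)
    pos_all = marker_map.table["cm"].to_numpy()
    chroms = marker_map.table["chromosome"].to_numpy()
    chrom_ids = sorted(pd.unique(chroms))
    chrom_slices, chrom_positions, lengths = [], [], []
    for c in chrom_ids:
        idx = np.where(chroms == c)[0]
        chrom_slices.append(slice(idx[0], idx[-1] + 1))
        chrom_positions.append(pos_all[idx])
        lengths.append(config.chromosome_length)

    # fully inbred founders; second-allele frequency per locus
    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    parent_ids = [f"P{i:03d}" for i in range(config.n_parents)]
    parent_haps = (rng.random((config.n_parents, m)) < freqs).astype(np.int8)

    # parent pools: shared parents first, remainder split between the sets
    n_extra = config.n_parents - config.n_shared_parents
    s1, s2 = config.set_sizes
    extra1 = int(round(n_extra * s1 / (s1 + s2)))
    shared = parent_ids[: config.n_shared_parents]
    pool1 = shared + parent_ids[config.n_shared_parents : config.n_shared_parents + extra1]
    pool2 = shared + parent_ids[config.n_shared_parents + extra1 :]
    if min(len(pool1), len(pool2)) < 2:
        raise ValueError("fewer than 2 parents available for a breeding set")

    hap_of = {pid: parent_haps[i] for i, pid in enumerate(parent_ids)}
    lines, ped_rows, codes, set_labels = [], [], [], []
    line_no = 0
    for set_idx, (pool, size, year) in enumerate(
        zip((pool1, pool2), config.set_sizes, config.years)
    ):
        n_crosses = min(config.n_crosses_per_set, len(pool) * (len(pool) - 1) // 2)
        cross_parents = []
        seen = set()
        while len(cross_parents) < n_crosses:
            pair = tuple(sorted(rng.choice(len(pool), size=2, replace=False)))
            if pair not in seen:
                seen.add(pair)
                cross_parents.append((pool[pair[0]], pool[pair[1]]))
        assignment = rng.integers(n_crosses, size=size)
        for k in range(size):
            p1, p2 = cross_parents[assignment[k]]
            h1, h2 = hap_of[p1].copy(), hap_of[p2].copy()
            for _ in range(config.selfing_generations):
                g1 = _gamete(h1, h2, chrom_slices, chrom_positions, lengths, rng)
                g2 = _gamete(h1, h2, chrom_slices, chrom_positions, lengths, rng)
                h1, h2 = g1, g2
            line_id = f"L{line_no:04d}"
            line_no += 1
            lines.append(line_id)
            ped_rows.append((line_id, p1, p2))
            codes.append(h1.astype(np.int16) + h2.astype(np.int16) - 1)
            set_labels.append(f"S{year}")

    codes = np.array(codes, dtype=float)
    calls = np.empty(codes.shape, dtype=object)
    calls[codes == -1] = "AA"
    calls[codes == 0] = "AB"
    calls[codes == 1] = "BB"
    if config.missing_rate > 0:
        miss = rng.random(codes.shape) < config.missing_rate
        calls[miss] = None
    raw = RawGenotypeTable(
        pd.DataFrame(calls, index=lines, columns=marker_map.mapped_markers)
    )
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["line", "parent1", "parent2"]))
    return raw, ped, codes, pd.Series(set_labels, index=lines, name="set")


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: RawGenotypeTable,
    true_codes: np.ndarray | None = None,
    set_of_line: pd.Series | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Simulate replicated field-trial phenotypes for every configured trait.

    QTL effects are iid normal on a random marker subset.  sigma2_g is the
    GBLUP variance parameter, i.e. variance per unit of genomic relationship:
    because inbred lines have G-diagonal near 2, breeding values are rescaled
    to an empirical variance of sigma2_g times the mean G diagonal, so that
    REML on the simulated data recovers sigma2_g itself.  Line, G x E and
    plot-residual effects are drawn iid at their configured variances.  Two
    ungenotyped check lines are added to every trial replicate.  Returns the
    plot table and the true breeding values.
    """
    rng = config.rng(3)
    lines = genotypes.line_ids
    n = len(lines)
    if true_codes is None:
        from .markers import encode, impute_missing

        true_codes = impute_missing(encode(genotypes)).values
    if config.n_qtl > true_codes.shape[1]:
        raise ValueError("n_qtl exceeds the number of markers")
    if set_of_line is None:
        half = n // 2
        set_of_line = pd.Series(
            [f"S{config.years[0]}"] * half + [f"S{config.years[1]}"] * (n - half), index=lines
        )
    year_of_set = {f"S{y}": y for y in config.years}

    # mean diagonal of the relationship matrix implied by the true genotypes:
    # the GBLUP parameter sigma2_g is variance per unit of G
    pfreq = (true_codes + 1.0).mean(axis=0) / 2.0
    seg = (pfreq > 0) & (pfreq < 1)
    denom = 2.0 * float(np.sum(pfreq[seg] * (1.0 - pfreq[seg])))
    z = true_codes[:, seg] - 2.0 * (pfreq[seg] - 0.5)
    g_diag_scale = float(np.mean(np.sum(z * z, axis=1)) / denom)

    traits = list(config.variance_components)
    tbv = pd.DataFrame(index=lines, columns=traits, dtype=float)
    effects = {}
    for trait in traits:
        s2g, s2l, s2c, s2e = config.variance_components[trait]
        qtl = rng.choice(true_codes.shape[1], size=config.n_qtl, replace=False)
        beta = rng.normal(size=config.n_qtl)
        bv = true_codes[:, qtl] @ beta
        sd = bv.std(ddof=1)
        if s2g > 0 and sd > 0:
            bv = (bv - bv.mean()) / sd * np.sqrt(s2g * g_diag_scale)
        else:
            bv = np.zeros(n)
        l_eff = rng.normal(0.0, np.sqrt(s2l), size=n) if (s2l or 0) > 0 else np.zeros(n)
        tbv[trait] = bv
        effects[trait] = (bv, l_eff, s2c, s2e)

    # trial layout: each breeding set is chunked into trials reused at both
    # locations of its year
    trial_of: dict[str, str] = {}
    for set_label in sorted(set_of_line.unique()):
        members = [l for l in lines if set_of_line[l] == set_label]
        for i, line in enumerate(members):
            trial_of[line] = f"T{i // config.trial_size + 1}"

    check_ids = [f"CHECK{i + 1}" for i in range(config.n_check_lines)]
    check_effects = {
        trait: {
            c: rng.normal(0.0, np.sqrt(config.variance_components[trait][0] + (config.variance_components[trait][1] or 0)))
            for c in check_ids
        }
        for trait in traits
    }

    rows = []
    plot_no = 0
    # G x E draws per (line, env) including checks per (check, env)
    envs = [f"{y}:{loc}" for y in config.years for loc in config.locations]
    gxe: dict[str, dict] = {t: {} for t in traits}
    for trait in traits:
        s2c = effects[trait][2]
        for line in list(lines) + check_ids:
            for env in envs:
                gxe[trait][(line, env)] = (
                    rng.normal(0.0, np.sqrt(s2c)) if s2c > 0 else 0.0
                )

    line_idx = {l: i for i, l in enumerate(lines)}
    for line in lines:
        set_label = set_of_line[line]
        year = year_of_set[set_label]
        for loc in config.locations:
            env = f"{year}:{loc}"
            trial = f"{env}:{trial_of[line]}"
            for rep in range(1, config.n_replicates + 1):
                plot_no += 1
                row = {
                    "line": line,
                    "year": year,
                    "location": loc,
                    "trial": trial,
                    "block": f"B{rep}",
                    "plot": plot_no,
                }
                for trait in traits:
                    bv, l_eff, s2c, s2e = effects[trait]
                    i = line_idx[line]
                    env_eff = config.env_effects.get(trait, {}).get(env, 0.0)
                    noise = rng.normal(0.0, np.sqrt(s2e)) if s2e > 0 else 0.0
                    row[trait] = env_eff + bv[i] + l_eff[i] + gxe[trait][(line, env)] + noise
                rows.append(row)

    # check plots: once per trial replicate, in every trial of every environment
    trials_by_env: dict[str, set] = {}
    for line in lines:
        year = year_of_set[set_of_line[line]]
        for loc in config.locations:
            env = f"{year}:{loc}"
            trials_by_env.setdefault(env, set()).add(f"{env}:{trial_of[line]}")
    for env in sorted(trials_by_env):
        year, loc = env.split(":")
        for trial in sorted(trials_by_env[env]):
            for rep in range(1, config.n_replicates + 1):
                for check in check_ids:
                    plot_no += 1
                    row = {
                        "line": check,
                        "year": year,
                        "location": loc,
                        "trial": trial,
                        "block": f"B{rep}",
                        "plot": plot_no,
                    }
                    for trait in traits:
                        _, _, s2c, s2e = effects[trait]
                        env_eff = config.env_effects.get(trait, {}).get(env, 0.0)
                        noise = rng.normal(0.0, np.sqrt(s2e)) if s2e > 0 else 0.0
                        row[trait] = (
                            env_eff
                            + check_effects[trait][check]
                            + gxe[trait][(check, env)]
                            + noise
                        )
                    rows.append(row)

    df = pd.DataFrame(rows)
    if "ssw" in df.columns:
        df = _derive_fraction_weights(df)
    return PhenotypeTable(df), tbv


def _derive_fraction_weights(df: pd.DataFrame) -> pd.DataFrame:
    """Seed-fraction weights consistent in rank with the latent seed size:
    bigger seeds shift mass into the >2.8 mm fraction and out of the two
    smaller ones.  Fractions sum to 99 g of the 100 g sample (1 g dust)."""
    ssw = df["ssw"].to_numpy(dtype=float)
    u = (ssw - np.nanmean(ssw)) / (np.nanstd(ssw) or 1.0)
    f28 = np.clip(82.0 + 6.0 * u, 40.0, 97.0)
    rest = 99.0 - f28
    df = df.copy()
    df["f2.8"] = f28
    df["f2.5"] = 0.85 * rest
    df["f2.2"] = 0.15 * rest
    return df


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: map, population, pedigree and phenotypes."""
    marker_map = simulate_map(config)
    raw, ped, codes, set_of_line = simulate_population(config, marker_map)
    pheno, tbv = simulate_phenotypes(config, raw, true_codes=codes, set_of_line=set_of_line)
    return SimulatedDataset(
        genotypes=raw,
        phenotypes=pheno,
        pedigree=ped,
        map=marker_map,
        true_breeding_values=tbv,
        true_components={t: tuple(v) for t, v in config.variance_components.items()},
        set_of_line=set_of_line,
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict:
    """Write genotype, phenotype, pedigree and map CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "pedigree": outdir / "pedigree.csv",
        "map": outdir / "map.csv",
        "sets": outdir / "sets.csv",
    }
    write_genotypes(ds.genotypes, paths["genotypes"])
    write_phenotypes(ds.phenotypes, paths["phenotypes"])
    ds.pedigree.to_csv(paths["pedigree"])
    write_map(ds.map, paths["map"])
    ds.set_of_line.rename_axis("line").to_csv(paths["sets"])
    return paths
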