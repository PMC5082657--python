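"""Genotype tables, -1/0/+1 encoding, and marker/line quality control.

Genotype calls come in as two-letter strings (``AA``, ``AB``, ``BB``, or any
other pair of nucleotide/allele symbols).  Per marker, the two observed allele
symbols are ordered (lexicographically unless the dialect says otherwise) and
the *second* allele is counted, so the homozygote for the first allele encodes
as -1, the heterozygote as 0 and the homozygote for the second allele as +1.
The allele frequency ``p_i`` used downstream is the frequency of that counted
second allele.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: call tokens treated as missing under the default dialect
MISSING_TOKENS = frozenset({"", "NA", "N", "NN", "--", "-", "NC", "?", "nan"})


@dataclass
class GenotypeDialect:
    """How a genotype CSV is laid out and which tokens mean what."""

    missing_tokens: frozenset = MISSING_TOKENS
    line_column: int = 0  # column holding line IDs


@dataclass
class RawGenotypeTable:
    """Lines x markers categorical genotype calls (strings), pre-encoding."""

    calls: pd.DataFrame  # index = line IDs, columns = marker IDs, str or NaN

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate line IDs: {dups}")
        if self.calls.columns.has_duplicates:
            raise ValueError("duplicate marker IDs")

    @property
    def line_ids(self) -> list:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape


@dataclass
class MarkerMatrix:
    """Numeric marker matrix M with elements -1 (first homozygote), 0
    (heterozygote), +1 (second homozygote) and a missing-value mask."""

    values: np.ndarray  # (n_lines, n_markers) float, 0.0 placeholder where masked
    missing_mask: np.ndarray  # bool, True = missing
    line_ids: list
    marker_ids: list
    monomorphic: np.ndarray = field(default=None)  # bool per marker

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values/mask shape mismatch")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("ids do not match matrix shape")
        if self.monomorphic is None:
            self.monomorphic = _monomorphic_flags(self.values, self.missing_mask)

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, marker_ids) -> "MarkerMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return MarkerMatrix(
            self.values[:, idx], self.missing_mask[:, idx], list(self.line_ids), list(marker_ids)
        )

    def subset_lines(self, line_ids) -> "MarkerMatrix":
        idx = [self.line_ids.index(l) for l in line_ids]
        return MarkerMatrix(
            self.values[idx, :], self.missing_mask[idx, :], list(line_ids), list(self.marker_ids)
        )


@dataclass
class MarkerMap:
    """Genetic map: marker -> (chromosome, position in cM).

    Markers absent from the table are "unmapped"; they stay in the analysis
    but cannot take part in map-aware marker selection.
    """

    table: pd.DataFrame  # columns: marker, chromosome, cm

    def __post_init__(self) -> None:
        req = {"marker", "chromosome", "cm"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(req)}")
        if (self.table["cm"] < 0).any():
            raise ValueError("map positions must be >= 0")

    @property
    def mapped_markers(self) -> list:
        return list(self.table["marker"])

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("marker")["chromosome"]

    def position_of(self) -> pd.Series:
        return self.table.set_index("marker")["cm"]


@dataclass
class QCReport:
    """Counts along the marker/line editing chain, plus the per-marker and
    per-line statistics the filters were based on."""

    n_input_markers: int
    n_polymorphic: int
    n_after_missing: int
    n_after_maf: int
    n_input_lines: int
    n_retained_lines: int
    maf: pd.Series  # per retained marker (post line filter frequencies)
    line_missing_fraction: pd.Series  # per input line
    maf_min: float
    line_missing_max: float
    marker_missing_max: float | None = None

    def to_json(self, path) -> None:
        payload = {
            "n_input_markers": self.n_input_markers,
            "n_polymorphic": self.n_polymorphic,
            "n_after_missing": self.n_after_missing,
            "n_after_maf": self.n_after_maf,
            "n_input_lines": self.n_input_lines,
            "n_retained_lines": self.n_retained_lines,
            "maf_min": self.maf_min,
            "line_missing_max": self.line_missing_max,
            "marker_missing_max": self.marker_missing_max,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# reading / writing


def read_genotypes(path, dialect: GenotypeDialect | None = None) -> RawGenotypeTable:
    """Read a genotype CSV (first column line ID, one column per marker).

    Unrecognized call tokens (not two-symbol genotypes, not declared missing)
    are mapped to missing and counted in a logged warning.
    """
    dialect = dialect or GenotypeDialect()
    df = pd.read_csv(path, dtype=str, index_col=dialect.line_column)
    df.index = df.index.astype(str)
    n_unknown = 0
    cleaned = {}
    for col in df.columns:
        vals = df[col].astype(object)
        out = []
        for v in vals:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                out.append(None)
                continue
            tok = str(v).strip()
            if tok in dialect.missing_tokens:
                out.append(None)
            elif len(tok) == 2 and tok.isalnum():
                out.append(tok.upper())
            else:
                n_unknown += 1
                out.append(None)
        cleaned[col] = out
    if n_unknown:
        logger.warning("read_genotypes: %d unrecognized call tokens set to missing", n_unknown)
    out_df = pd.DataFrame(cleaned, index=df.index)
    return RawGenotypeTable(out_df)


def write_genotypes(raw: RawGenotypeTable, path) -> None:
    df = raw.calls.copy()
    df = df.fillna("NA")
    df.index.name = "line"
    df.to_csv(path)


def read_map(path) -> MarkerMap:
    df = pd.read_csv(path)
    df = df.rename(columns={c: c.lower() for c in df.columns})
    return MarkerMap(df[["marker", "chromosome", "cm"]])


def write_map(m: MarkerMap, path) -> None:
    m.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# encoding


def encode(raw: RawGenotypeTable) -> MarkerMatrix:
    """Encode categorical calls to the -1/0/+1 scale.

    Per marker, allele symbols are ordered lexicographically; homozygote for
    the first allele -> -1, heterozygote -> 0, homozygote for the second
    allele -> +1.  Markers with more than two alleles raise; markers with one
    observed allele are flagged monomorphic (coded -1 throughout).
    """
    calls = raw.calls
    n, m = calls.shape
    values = np.zeros((n, m), dtype=float)
    mask = np.zeros((n, m), dtype=bool)
    for j, col in enumerate(calls.columns):
        vals = calls[col]
        notna = vals.notna()
        mask[:, j] = ~notna.to_numpy()
        obs = vals[notna]
        alleles = sorted({ch for tok in obs for ch in tok})
        if len(alleles) > 2:
            raise ValueError(f"marker {col!r} has more than two alleles: {alleles}")
        if not alleles:
            continue  # all missing; stays masked
        if len(alleles) == 1:
            # single observed allele: it is the first-listed one, coded -1
            values[notna.to_numpy(), j] = -1.0
            continue
        second = alleles[1]
        # count of the second allele per call: 0, 1 or 2 -> -1, 0, +1
        counts = obs.map(lambda tok: tok.count(second) - 1)
        values[notna.to_numpy(), j] = counts.to_numpy(dtype=float)
    return MarkerMatrix(values, mask, list(calls.index), list(calls.columns))


def _monomorphic_flags(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """A marker is monomorphic when all non-missing calls are identical
    homozygotes (a single heterozygote still implies both alleles exist)."""
    vals = np.ma.masked_array(values, mask)
    has_obs = (~mask).any(axis=0)
    vmin = vals.min(axis=0).filled(np.nan)
    vmax = vals.max(axis=0).filled(np.nan)
    mono = has_obs & (vmin == vmax) & (np.abs(vmin) == 1)
    return np.asarray(mono, dtype=bool)


def allele_frequencies(m: MarkerMatrix) -> np.ndarray:
    """Frequency of the counted (second) allele at every marker:
    p_i = (#(+1) + 0.5 #(0)) / #non-missing."""
    vals = np.where(m.missing_mask, np.nan, m.values)
    n_obs = np.sum(~m.missing_mask, axis=0).astype(float)
    if (n_obs == 0).any():
        bad = [m.marker_ids[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"markers with no non-missing calls: {bad[:5]}")
    # coded value v in {-1,0,1} carries (v+1)/2 copies of the second allele per haplotype
    p = np.nansum((vals + 1.0) / 2.0, axis=0) / n_obs
    return p


def allele_frequency(m: MarkerMatrix, marker) -> float:
    """Second-allele frequency of one marker (convenience wrapper)."""
    j = m.marker_ids.index(marker)
    col = m.values[:, j]
    miss = m.missing_mask[:, j]
    n_obs = int(np.sum(~miss))
    if n_obs == 0:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    return float(np.sum((col[~miss] + 1.0) / 2.0) / n_obs)


# ---------------------------------------------------------------------------
# quality control


def apply_qc(
    m: MarkerMatrix,
    maf_min: float = 0.05,
    line_missing_max: float = 0.02,
    marker_missing_max: float | None = None,
) -> tuple[MarkerMatrix, QCReport]:
    """Marker/line editing:

    1. drop monomorphic markers;
    2. drop lines whose missing-call fraction exceeds ``line_missing_max``;
    3. optionally drop markers missing in more than ``marker_missing_max`` of
       lines (the alternative reading of a per-line missingness rule);
    4. recompute allele frequencies on the surviving lines and retain markers
       with minor allele frequency >= ``maf_min`` (inclusive).

    The filter order is fixed and logged; MAF is recomputed after line removal
    so the retained markers satisfy the threshold on the data actually used.
    """
    n_in_markers = m.n_markers
    n_in_lines = m.n_lines

    poly_keep = ~m.monomorphic & (~m.missing_mask).any(axis=0)
    n_poly = int(poly_keep.sum())
    logger.info("QC: %d/%d polymorphic markers", n_poly, n_in_markers)

    line_missing = m.missing_mask[:, poly_keep].mean(axis=1) if n_poly else np.zeros(n_in_lines)
    line_missing_ser = pd.Series(line_missing, index=m.line_ids, name="missing_fraction")
    line_keep = line_missing <= line_missing_max
    n_lines = int(line_keep.sum())
    logger.info(
        "QC: %d/%d lines kept (missing fraction <= %.3g)", n_lines, n_in_lines, line_missing_max
    )
    if n_lines == 0:
        raise ValueError("QC emptied the panel at the line-missingness stage")

    vals = m.values[np.ix_(line_keep, poly_keep)]
    mask = m.missing_mask[np.ix_(line_keep, poly_keep)]
    marker_ids = [mid for mid, k in zip(m.marker_ids, poly_keep) if k]
    line_ids = [lid for lid, k in zip(m.line_ids, line_keep) if k]

    if marker_missing_max is not None:
        mk = mask.mean(axis=0) <= marker_missing_max
        vals, mask = vals[:, mk], mask[:, mk]
        marker_ids = [mid for mid, k in zip(marker_ids, mk) if k]
    n_after_missing = len(marker_ids)
    if n_after_missing == 0:
        raise ValueError("QC emptied the panel at the marker-missingness stage")

    inter = MarkerMatrix(vals, mask, line_ids, marker_ids)
    p = allele_frequencies(inter)
    maf = np.minimum(p, 1.0 - p)
    maf_keep = maf >= maf_min
    n_after_maf = int(maf_keep.sum())
    logger.info("QC: %d/%d markers with MAF >= %.3g", n_after_maf, n_after_missing, maf_min)
    if n_after_maf == 0:
        raise ValueError("QC emptied the panel at the MAF stage")

    kept_ids = [mid for mid, k in zip(marker_ids, maf_keep) if k]
    out = MarkerMatrix(vals[:, maf_keep], mask[:, maf_keep], line_ids, kept_ids)
    report = QCReport(
        n_input_markers=n_in_markers,
        n_polymorphic=n_poly,
        n_after_missing=n_after_missing,
        n_after_maf=n_after_maf,
        n_input_lines=n_in_lines,
        n_retained_lines=n_lines,
        maf=pd.Series(maf[maf_keep], index=kept_ids, name="maf"),
        line_missing_fraction=line_missing_ser,
        maf_min=maf_min,
        line_missing_max=line_missing_max,
        marker_missing_max=marker_missing_max,
    )
    return out, report


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace every missing call by its marker's mean coded value 2p-1 and
    clear the mask.  Leaves the per-marker mean coded value exactly unchanged.
    """
    if not m.missing_mask.any():
        return MarkerMatrix(
            m.values.copy(),
            np.zeros_like(m.missing_mask),
            list(m.line_ids),
            list(m.marker_ids),
        )
    p = allele_frequencies(m)
    fill = 2.0 * p - 1.0
    vals = np.where(m.missing_mask, fill[np.newaxis, :], m.values)
    return MarkerMatrix(
        vals, np.zeros_like(m.missing_mask), list(m.line_ids), list(m.marker_ids)
    )
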