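"""Two-parent pedigree records for inbred breeding lines."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class Pedigree:
    """line -> (parent1, parent2).  A family is the set of lines sharing one
    given parent (half- and full-sibs together)."""

    table: pd.DataFrame  # columns: line, parent1, parent2

    def __post_init__(self) -> None:
        req = {"line", "parent1", "parent2"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"pedigree needs columns {sorted(req)}")
        if self.table["line"].duplicated().any():
            raise ValueError("duplicate lines in pedigree")
        self.table = self.table.astype(str).reset_index(drop=True)

    @property
    def lines(self) -> list:
        return list(self.table["line"])

    def parents_of(self, line) -> tuple[str, str]:
        row = self.table.loc[self.table["line"] == str(line)]
        if not len(row):
            raise KeyError(f"line {line!r} not in pedigree")
        return str(row.iloc[0]["parent1"]), str(row.iloc[0]["parent2"])

    def families(self, min_size: int = 1) -> dict:
        """One family per parent: all lines with that parent, keeping only
        families of at least ``min_size`` lines."""
        fams: dict[str, list] = {}
        for _, row in self.table.iterrows():
            for parent in (row["parent1"], row["parent2"]):
                fams.setdefault(parent, []).append(row["line"])
        return {p: ls for p, ls in sorted(fams.items()) if len(ls) >= min_size}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path, dtype=str))
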