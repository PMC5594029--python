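"""The samples × lipids abundance matrix with explicit missingness."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, parse_lipid_name

__all__ = ["LipidomeMatrix", "MOL_PERCENT", "PMOL"]

MOL_PERCENT = "mol_percent"
PMOL = "pmol"

#: relative tolerance for the 100 mol% closure check
_CLOSURE_RTOL = 1e-9


@dataclass
class LipidomeMatrix:
    """Samples × lipids abundance grid.

    ``data`` holds one row per sample and one column per lipid (canonical
    name strings); undetected lipids are ``NaN`` — never zero.  ``units`` is
    either :data:`PMOL` (absolute amounts) or :data:`MOL_PERCENT` (relative
    abundance closing to 100 per sample).
    """

    data: pd.DataFrame
    units: str = PMOL

    def __post_init__(self) -> None:
        if self.units not in (MOL_PERCENT, PMOL):
            raise ValueError(f"unknown units {self.units!r}")
        self.data = self.data.astype(float)
        self.validate()

    # -- views ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def lipids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def species(self) -> list[LipidSpecies]:
        """Parsed identities of the lipid columns."""
        return [parse_lipid_name(name) for name in self.data.columns]

    @property
    def n_samples(self) -> int:
        return len(self.data.index)

    @property
    def n_lipids(self) -> int:
        return len(self.data.columns)

    def detected_fraction(self) -> pd.Series:
        """Per lipid, the fraction of samples in which it was detected."""
        if self.n_samples == 0:
            return pd.Series(dtype=float)
        return self.data.notna().mean(axis=0)

    def is_complete(self) -> bool:
        return not self.data.isna().any().any()

    # -- consistency ---------------------------------------------------

    def validate(self) -> None:
        if (self.data.values < 0).any():
            bad = self.data.columns[(self.data < 0).any(axis=0)][0]
            raise ValueError(f"negative abundance in lipid {bad!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicated lipid column {dup!r}")
        if self.units == MOL_PERCENT and self.n_lipids and self.n_samples:
            totals = self.data.sum(axis=1, skipna=True)
            if not np.allclose(totals, 100.0, rtol=_CLOSURE_RTOL, atol=0):
                worst = totals.sub(100).abs().idxmax()
                raise ValueError(
                    f"mol% closure violated for sample {worst!r} "
                    f"(sum = {totals[worst]!r})"
                )

    # -- subsetting ----------------------------------------------------

    def subset_samples(self, samples: Iterable[str]) -> "LipidomeMatrix":
        """Row subset.

        Note: a mol% matrix restricted to fewer samples still closes (the
        closure is per sample), so units are preserved.
        """
        sub = self.data.loc[list(samples)]
        return LipidomeMatrix(sub, units=self.units)

    def subset_lipids(self, lipids: Iterable[str]) -> "LipidomeMatrix":
        """Column subset; a mol% matrix loses closure and is demoted to
        plain relative values only when columns are dropped, so the result
        keeps ``pmol`` semantics-free units by re-tagging as pmol when the
        subset is strict."""
        cols = list(lipids)
        sub = self.data[cols]
        units = self.units
        if units == MOL_PERCENT and set(cols) != set(self.data.columns):
            units = PMOL
        return LipidomeMatrix(sub, units=units)

    # -- IO ------------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write as a wide CSV: first column ``lipid``, one column per
        sample; missing values are empty cells."""
        self.data.T.rename_axis("lipid").to_csv(path)

    @classmethod
    def from_csv(cls, path: Union[str, Path], units: str = PMOL) -> "LipidomeMatrix":
        """Read a wide CSV (rows = lipids, columns = samples, empty cell =
        missing) as written by :meth:`to_csv`."""
        wide = pd.read_csv(path, index_col=0)
        wide.index = wide.index.astype(str).str.strip()
        for name in wide.index:
            parse_lipid_name(name)  # fail fast on malformed names
        return cls(wide.T, units=units)
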