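"""CSV readers and writers for the formats the pipeline consumes.

All on-disk formats are plain text:

* wide lipid table — first column ``lipid``, one column per sample, empty
  cell = missing (see :meth:`pulmolip.matrix.LipidomeMatrix.from_csv`);
* long intensity table — ``lipid,sample_id,intensity[,mass_error_ppm,ion_mode]``;
* internal standards — ``lipid_class,ion_mode,intensity,amount_pmol``;
* blanks — ``lipid,blank_intensity``;
* labels — ``sample_id,group``;
* panel — as written by :meth:`DiscriminationPanel.to_frame`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .ingest import IntensityRecord, InternalStandard
from .nomenclature import parse_lipid_name

__all__ = [
    "read_long_intensities",
    "read_wide_intensities",
    "read_standards",
    "read_blanks",
    "read_labels",
]

PathLike = Union[str, Path]

#: default ion mode per lipid class for wide tables that do not carry one
CLASS_ION_MODES: dict[str, str] = {
    "PC": "positive", "LPC": "positive", "SM": "positive", "TAG": "positive",
    "DAG": "positive", "CE": "positive", "Cer": "positive",
    "HexCer": "positive", "PC-O": "positive", "PE-O": "positive",
    "FC": "positive",
    "PE": "negative", "LPE": "negative", "PG": "negative", "LPG": "negative",
    "PI": "negative", "LPI": "negative", "PS": "negative", "LPS": "negative",
    "PA": "negative", "CL": "negative",
}


def read_long_intensities(path: PathLike) -> list[IntensityRecord]:
    """Read a long-format intensity table.

    Required columns: ``lipid``, ``sample_id``, ``intensity``.  Optional:
    ``mass_error_ppm`` (default 0) and ``ion_mode`` (default inferred from
    the lipid class).
    """
    table = pd.read_csv(path)
    required = {"lipid", "sample_id", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table misses columns {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        species = parse_lipid_name(str(row["lipid"]))
        mode = (
            str(row["ion_mode"])
            if "ion_mode" in table.columns and pd.notna(row.get("ion_mode"))
            else CLASS_ION_MODES[species.lipid_class]
        )
        ppm = (
            float(row["mass_error_ppm"])
            if "mass_error_ppm" in table.columns and pd.notna(row.get("mass_error_ppm"))
            else 0.0
        )
        records.append(
            IntensityRecord(
                species=species,
                sample_id=str(row["sample_id"]),
                intensity=float(row["intensity"]),
                mass_error_ppm=ppm,
                ion_mode=mode,
            )
        )
    return records


def read_wide_intensities(path: PathLike) -> list[IntensityRecord]:
    """Read a wide lipid × sample intensity table (empty cell = not
    detected) into records; mass errors default to 0 and ion modes are
    inferred from the lipid class."""
    wide = pd.read_csv(path, index_col=0)
    records = []
    for name, row in wide.iterrows():
        species = parse_lipid_name(str(name))
        mode = CLASS_ION_MODES[species.lipid_class]
        for sample, value in row.items():
            if pd.isna(value):
                continue
            records.append(
                IntensityRecord(
                    species=species,
                    sample_id=str(sample),
                    intensity=float(value),
                    ion_mode=mode,
                )
            )
    return records


def read_standards(path: PathLike) -> list[InternalStandard]:
    table = pd.read_csv(path)
    required = {"lipid_class", "ion_mode", "intensity", "amount_pmol"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"standards table misses columns {sorted(missing)}")
    return [
        InternalStandard(
            lipid_class=str(row["lipid_class"]),
            intensity=float(row["intensity"]),
            amount=float(row["amount_pmol"]),
            ion_mode=str(row["ion_mode"]),
        )
        for _, row in table.iterrows()
    ]


def read_blanks(path: PathLike) -> dict[str, float]:
    table = pd.read_csv(path)
    required = {"lipid", "blank_intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"blank table misses columns {sorted(missing)}")
    return {
        parse_lipid_name(str(row["lipid"])).format(): float(row["blank_intensity"])
        for _, row in table.iterrows()
    }


def read_labels(path: PathLike) -> pd.Series:
    table = pd.read_csv(path)
    required = {"sample_id", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"label table misses columns {sorted(missing)}")
    return pd.Series(
        table["group"].astype(str).to_numpy(), index=table["sample_id"].astype(str)
    )
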