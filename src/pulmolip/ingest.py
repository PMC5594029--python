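"""Identification filtering, internal-standard quantification and mol%
normalization.

The ingest chain mirrors a shotgun-lipidomics screen: records that fail the
mass-accuracy or blank-ratio gates are dropped; surviving intensities are
converted to pmol against spiked internal standards (same-class standard for
LPC/PC/PE/SM/TAG, sum of the mode's designated standard set otherwise);
amounts are then closed to 100 mol% per sample; finally lipids may be
required to be present in a minimum fraction of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .matrix import MOL_PERCENT, PMOL, LipidomeMatrix
from .nomenclature import LipidSpecies

__all__ = [
    "IntensityRecord",
    "InternalStandard",
    "CLASS_STANDARD_CLASSES",
    "SUM_STANDARD_SETS",
    "filter_identifications",
    "quantify",
    "normalize_relative",
    "presence_filter",
]

#: Classes quantified against their own internal standard.
CLASS_STANDARD_CLASSES: frozenset[str] = frozenset({"LPC", "PC", "PE", "SM", "TAG"})

#: Per ion mode, the standard classes whose summed intensity/amount
#: quantifies every class without a same-class standard.
SUM_STANDARD_SETS: Mapping[str, tuple[str, ...]] = {
    "positive": ("LPC", "SM", "PC", "TAG"),
    "negative": ("LPC", "PC", "PE"),
}

_ION_MODES = ("positive", "negative")


@dataclass(frozen=True)
class IntensityRecord:
    """One identified lipid signal in one sample."""

    species: LipidSpecies
    sample_id: str
    intensity: float
    mass_error_ppm: float = 0.0
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(
                f"negative intensity {self.intensity} for "
                f"{self.species.format()} in {self.sample_id}"
            )
        if self.ion_mode not in _ION_MODES:
            raise ValueError(f"unknown ion mode {self.ion_mode!r}")


@dataclass(frozen=True)
class InternalStandard:
    """A spiked standard of known amount for one lipid class and mode."""

    lipid_class: str
    intensity: float
    amount: float  # pmol
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"standard amount must be > 0, got {self.amount}")
        if self.intensity <= 0:
            raise ValueError(f"standard intensity must be > 0, got {self.intensity}")
        if self.ion_mode not in _ION_MODES:
            raise ValueError(f"unknown ion mode {self.ion_mode!r}")


def filter_identifications(
    records: Iterable[IntensityRecord],
    blanks: Optional[Mapping[str, float]] = None,
    max_ppm: float = 2.5,
    min_blank_ratio: float = 10.0,
) -> list[IntensityRecord]:
    """Apply the identification gates.

    A record is retained iff ``|mass_error_ppm| <= max_ppm`` and its
    intensity is at least ``min_blank_ratio`` times the blank intensity of
    its species.  ``blanks`` maps canonical lipid names to blank-control
    intensities; species absent from the map are treated as blank = 0 and
    always pass the ratio gate.
    """
    if max_ppm <= 0:
        raise ValueError(f"max_ppm must be > 0, got {max_ppm}")
    if min_blank_ratio <= 0:
        raise ValueError(f"min_blank_ratio must be > 0, got {min_blank_ratio}")
    blanks = dict(blanks or {})
    for name, value in blanks.items():
        if value < 0:
            raise ValueError(f"negative blank intensity for {name!r}")

    kept = []
    for rec in records:
        if abs(rec.mass_error_ppm) > max_ppm:
            continue
        blank = blanks.get(rec.species.format(), 0.0)
        if rec.intensity < min_blank_ratio * blank:
            continue
        kept.append(rec)
    return kept


def _standard_index(
    standards: Sequence[InternalStandard],
) -> dict[tuple[str, str], InternalStandard]:
    index: dict[tuple[str, str], InternalStandard] = {}
    for std in standards:
        key = (std.lipid_class, std.ion_mode)
        if key in index:
            raise ValueError(
                f"duplicate internal standard for class {std.lipid_class} "
                f"in {std.ion_mode} mode"
            )
        index[key] = std
    return index


def quantify(
    records: Sequence[IntensityRecord],
    standards: Sequence[InternalStandard],
) -> LipidomeMatrix:
    """Convert filtered intensities to amounts (pmol).

    Species of the classes LPC, PC, PE, SM and TAG are quantified against
    the same-class standard of their ion mode::

        amount = intensity / IS_intensity * IS_amount

    Every other class is quantified against the summed response of the
    mode's designated standard set (positive: LPC+SM+PC+TAG, negative:
    LPC+PC+PE)::

        amount = intensity / sum(IS intensities) * sum(IS amounts)

    Species not recorded for a sample are missing in the output, never zero.
    """
    index = _standard_index(standards)

    modes = {rec.ion_mode for rec in records}
    sum_sets: dict[str, tuple[float, float]] = {}
    for mode in modes:
        members = [
            index[(cls, mode)]
            for cls in SUM_STANDARD_SETS[mode]
            if (cls, mode) in index
        ]
        if not members:
            raise ValueError(
                f"no internal standards available for {mode} ion mode"
            )
        sum_sets[mode] = (
            sum(s.intensity for s in members),
            sum(s.amount for s in members),
        )

    amounts: dict[str, dict[str, float]] = {}
    for rec in records:
        cls = rec.species.lipid_class
        if cls in CLASS_STANDARD_CLASSES:
            std = index.get((cls, rec.ion_mode))
            if std is None:
                raise ValueError(
                    f"missing {cls} internal standard for {rec.ion_mode} "
                    f"ion mode"
                )
            amount = rec.intensity / std.intensity * std.amount
        else:
            total_intensity, total_amount = sum_sets[rec.ion_mode]
            amount = rec.intensity / total_intensity * total_amount
        name = rec.species.format()
        cell = amounts.setdefault(rec.sample_id, {})
        # summing duplicates (e.g. the same species seen in both modes)
        cell[name] = cell.get(name, 0.0) + amount

    data = pd.DataFrame.from_dict(amounts, orient="index")
    data = data.sort_index(axis=0).sort_index(axis=1)
    return LipidomeMatrix(data, units=PMOL)


def normalize_relative(matrix: LipidomeMatrix) -> LipidomeMatrix:
    """Close each sample to 100 mol% over its detected lipids.

    Missing values stay missing.  A sample with no detected lipid, or whose
    detected amounts sum to zero, is rejected by name.
    """
    data = matrix.data
    totals = data.sum(axis=1, skipna=True)
    detected = data.notna().any(axis=1)
    for sample in data.index:
        if not detected[sample]:
            raise ValueError(f"sample {sample!r} has no detected lipids")
        if totals[sample] <= 0:
            raise ValueError(f"sample {sample!r} has zero total abundance")
    rel = data.div(totals, axis=0) * 100.0
    return LipidomeMatrix(rel, units=MOL_PERCENT)


def presence_filter(matrix: LipidomeMatrix, min_fraction: float) -> LipidomeMatrix:
    """Keep lipids detected in at least ``min_fraction`` of the samples.

    The sample set is unchanged.  With ``min_fraction = 1`` the result has
    no missing values; with ``min_fraction = 0`` all lipids are kept.  The
    result is re-closed not at all — mol% values are left as they are, so a
    filtered mol% matrix is returned with ``pmol``-style (open) units when
    lipids were actually removed.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac = matrix.detected_fraction()
    keep = [lip for lip in matrix.lipids if frac[lip] >= min_fraction]
    return matrix.subset_lipids(keep)
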