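"""Synthetic lipidome cohorts with the structure the analysis assumes.

A cohort is drawn from a hierarchical log-normal model: every lipid has a
class-anchored baseline log2 abundance; tumour samples receive class- or
species-level log2 fold-change effects (neutral lipids up, surfactant
lipids down); designated species are coupled linearly to continuous
covariates (age, emphysema grade, inflammation) and to the tumour subtype;
patients contribute a random intercept (matched pairs correlate); log-normal
noise is added; a per-lipid, per-tissue detection model deletes values
(structured missingness); and detected amounts are closed to 100 mol%.

The ground truth of every cohort — planted panel lipids with their signs
and the covariate couplings — is returned alongside the data so recovery
can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .matrix import MOL_PERCENT, LipidomeMatrix
from .nomenclature import SPHINGOLIPID_CLASSES, LipidSpecies

__all__ = [
    "ClassEffect",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "build_catalogue",
    "generate_cohort",
    "paper_like_cohort",
]

TUMOUR = "tumour"
ALVEOLAR = "alveolar"

#: default species counts per class (sums to 311)
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "TAG": 60, "PC": 45, "PE": 30, "SM": 25, "PG": 25, "Cer": 25,
    "PI": 20, "PS": 20, "CE": 20, "DAG": 15, "CL": 10, "PC-O": 8,
    "PE-O": 8,
}

#: class-level geometric-mean log2 amounts (PC dominant, PG a substantial
#: surfactant class, neutral lipids lower in healthy tissue)
DEFAULT_CLASS_BASELINES: dict[str, float] = {
    "PC": 7.0, "PE": 6.0, "SM": 5.8, "TAG": 5.5, "PG": 5.8, "PI": 5.2,
    "PS": 5.0, "CE": 4.5, "DAG": 4.2, "Cer": 4.0, "CL": 3.6, "PC-O": 4.4,
    "PE-O": 4.4,
}

_CHAIN_RANGES: dict[str, tuple[int, int, int]] = {
    # (min carbons, max carbons, max double bonds); 2-carbon steps
    "TAG": (44, 58, 8), "PC": (28, 40, 6), "PE": (32, 40, 6),
    "SM": (30, 44, 3), "PG": (30, 40, 4), "PI": (32, 40, 6),
    "PS": (34, 42, 6), "CE": (14, 22, 6), "DAG": (30, 40, 4),
    "Cer": (30, 46, 2), "CL": (64, 76, 8), "PC-O": (30, 38, 6),
    "PE-O": (30, 38, 6), "HexCer": (32, 44, 2), "PA": (30, 40, 5),
}


def build_catalogue(
    class_counts: Mapping[str, int],
    seed: int = 0,
    include: tuple[str, ...] = (),
) -> list[str]:
    """Deterministically enumerate a lipid catalogue with the requested
    number of species per class (canonical names, unique within class).

    Names listed in ``include`` are guaranteed a slot in their class's
    allocation; the remaining slots are filled with a seeded draw from the
    class's [C:DB] grid.
    """
    rng = np.random.default_rng(seed)
    include_by_class: dict[str, list[str]] = {}
    for name in include:
        include_by_class.setdefault(name.split(" ")[0], []).append(name)

    names: list[str] = []
    for cls, count in class_counts.items():
        if count < 0:
            raise ValueError(f"negative species count for class {cls}")
        lo, hi, max_db = _CHAIN_RANGES.get(cls, (30, 44, 6))
        combo_names = []
        for c in range(lo, hi + 1, 2):
            for db in range(0, max_db + 1):
                if cls in SPHINGOLIPID_CLASSES:
                    combo_names.append(LipidSpecies(cls, c, db, 0).format())
                else:
                    combo_names.append(LipidSpecies(cls, c, db).format())
        wanted = include_by_class.get(cls, [])
        outside = [n for n in wanted if n not in combo_names]
        pool = combo_names + outside  # honour requests off the default grid
        if count > len(pool):
            raise ValueError(
                f"class {cls}: requested {count} species but only "
                f"{len(pool)} [C:DB] combinations available"
            )
        if len(wanted) > count:
            raise ValueError(
                f"class {cls}: {len(wanted)} forced species exceed the "
                f"count of {count}"
            )
        rest = [n for n in pool if n not in wanted]
        extra = sorted(
            map(int, rng.choice(len(rest), size=count - len(wanted), replace=False))
        )
        chosen = set(wanted) | {rest[k] for k in extra}
        names.extend(n for n in pool if n in chosen)
    return names


@dataclass(frozen=True)
class ClassEffect:
    """A tumour log2 fold change applied to ``n_species`` members of a
    class (all members when ``n_species`` is None)."""

    log2fc: float
    n_species: Optional[int] = None


@dataclass
class CohortConfig:
    """Everything :func:`generate_cohort` needs.

    Probabilities ``p_both``/``p_tumour_only``/``p_control_only`` give each
    patient's tissue availability; ``exact_availability`` overrides the
    random draw with fixed counts ``(n_both, n_tumour_only,
    n_control_only)``.  ``tumour_effects`` plants class-level tumour-vs-
    control log2 fold changes; ``diagnosis_effects`` plants SCC-vs-ADC
    shifts within tumour samples; ``covariate_couplings`` maps a covariate
    name to per-lipid slopes on the standardized covariate.
    ``detection`` maps ``(class, tissue)`` to detection probabilities and
    ``lipid_detection`` overrides them per lipid; planted lipids should be
    forced to probability 1 so they remain panel candidates.
    """

    n_patients: int = 26
    p_both: float = 0.65
    p_tumour_only: float = 0.23
    p_control_only: float = 0.12
    exact_availability: Optional[tuple[int, int, int]] = None
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    include_species: tuple[str, ...] = ()
    catalogue_seed: int = 0
    diagnosis_plan: Optional[list[str]] = None
    class_baselines: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_BASELINES)
    )
    baseline_spread: float = 1.2
    tumour_effects: Mapping[str, ClassEffect] = field(default_factory=dict)
    species_tumour_effects: Mapping[str, float] = field(default_factory=dict)
    diagnosis_effects: Mapping[str, float] = field(default_factory=dict)
    covariate_couplings: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    detection: Mapping[tuple[str, str], float] = field(default_factory=dict)
    lipid_detection: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    default_detection: float = 1.0
    noise_sigma: float = 0.3
    patient_sigma: float = 0.25
    age_emphysema_rho: float = 0.5
    diagnosis_proportions: tuple[float, float, float] = (0.42, 0.46, 0.12)  # ADC, SCC, other
    seed: Optional[int] = None

    def validate(self) -> None:
        probs = (self.p_both, self.p_tumour_only, self.p_control_only)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"availability probabilities must be in [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-9 and self.exact_availability is None:
            raise ValueError("availability probabilities must sum to 1")
        if not self.class_counts or sum(self.class_counts.values()) == 0:
            raise ValueError("empty lipid catalogue")
        if self.noise_sigma <= 0 or self.patient_sigma < 0:
            raise ValueError("noise parameters must be positive")
        if self.default_detection < 0 or self.default_detection > 1:
            raise ValueError("default_detection must be in [0,1]")


@dataclass
class GroundTruth:
    """What was planted: tumour/diagnosis log2 fold changes per lipid and
    covariate couplings (slope of log2 abundance per SD of covariate)."""

    tumour_log2fc: dict[str, float]
    diagnosis_log2fc: dict[str, float]
    covariate_couplings: dict[str, dict[str, float]]

    def panel(self) -> list[tuple[str, int]]:
        """Planted tumour panel with the sign convention of
        ``select_panel(group1=tumour, group2=alveolar)``."""
        return [
            (lipid, 1 if fc > 0 else -1)
            for lipid, fc in self.tumour_log2fc.items()
        ]


@dataclass
class SyntheticCohort:
    matrix: LipidomeMatrix
    metadata: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig


def _availability(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Per patient: 'both', 'tumour' or 'control'."""
    if config.exact_availability is not None:
        n_both, n_tum, n_ctl = config.exact_availability
        if n_both + n_tum + n_ctl != config.n_patients:
            raise ValueError("exact availability counts must sum to n_patients")
        kinds = ["both"] * n_both + ["tumour"] * n_tum + ["control"] * n_ctl
        return kinds
    draws = rng.choice(
        ["both", "tumour", "control"],
        size=config.n_patients,
        p=[config.p_both, config.p_tumour_only, config.p_control_only],
    )
    return list(draws)


def _spread_effects(
    catalogue: list[str], effects: Mapping[str, ClassEffect]
) -> dict[str, float]:
    """Expand class-level effects to per-lipid log2 fold changes."""
    per_lipid: dict[str, float] = {}
    by_class: dict[str, list[str]] = {}
    for name in catalogue:
        cls = name.split(" ")[0] if " " in name else name
        by_class.setdefault(cls, []).append(name)
    for cls, effect in effects.items():
        members = by_class.get(cls, [])
        if not members:
            raise ValueError(f"tumour effect references unknown class {cls!r}")
        take = members if effect.n_species is None else members[: effect.n_species]
        for name in take:
            per_lipid[name] = effect.log2fc
    return per_lipid


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Draw one cohort.  ``seed`` overrides ``config.seed``; the same
    configuration and seed yield bit-identical cohorts."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    catalogue = build_catalogue(
        config.class_counts, seed=config.catalogue_seed, include=config.include_species
    )
    n_lipids = len(catalogue)
    classes = np.array([name.split(" ")[0] for name in catalogue])

    tumour_fc = _spread_effects(catalogue, config.tumour_effects)
    for name, fc in config.species_tumour_effects.items():
        if name not in catalogue:
            raise ValueError(f"tumour effect references unknown lipid {name!r}")
        tumour_fc[name] = fc
    for name in config.diagnosis_effects:
        if name not in catalogue:
            raise ValueError(f"diagnosis effect references unknown lipid {name!r}")
    for cov, couplings in config.covariate_couplings.items():
        for name in couplings:
            if name not in catalogue:
                raise ValueError(
                    f"coupling of {cov!r} references unknown lipid {name!r}"
                )

    # fixed per-lipid baselines (shared across samples)
    base = np.array(
        [config.class_baselines.get(cls, 5.0) for cls in classes], dtype=float
    )
    base = base + rng.normal(0.0, config.baseline_spread, size=n_lipids)

    # --- patients and metadata -------------------------------------
    kinds = _availability(config, rng)
    patient_ids = [f"P{k + 1:02d}" for k in range(config.n_patients)]

    rho = config.age_emphysema_rho
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=config.n_patients
    )
    ages = np.clip(np.round(57.5 + 8.0 * z[:, 0]), 44, 71)
    emphysema = np.clip(np.round(3.0 + 2.2 * z[:, 1]), 0, 10)
    inflammation = rng.integers(0, 4, size=config.n_patients)
    macrophages = rng.integers(0, 4, size=config.n_patients)
    fibrosis = rng.integers(0, 4, size=config.n_patients)
    bmi = np.round(rng.normal(28.0, 4.0, size=config.n_patients), 1)
    pack_years = np.round(np.clip(rng.normal(40.0, 15.0, size=config.n_patients), 0, None))
    gold = rng.integers(0, 4, size=config.n_patients)
    gender = rng.choice(["male", "female"], size=config.n_patients, p=[0.75, 0.25])
    if config.diagnosis_plan is not None:
        if len(config.diagnosis_plan) != config.n_patients:
            raise ValueError("diagnosis_plan must name every patient")
        diagnosis = np.array(config.diagnosis_plan)
    else:
        diagnosis = rng.choice(
            ["ADC", "SCC", "other"],
            size=config.n_patients,
            p=list(config.diagnosis_proportions),
        )
    # tumour histology fractions (per patient, used for tumour samples)
    tissue_fracs = rng.dirichlet([2.5, 2.5, 1.0], size=config.n_patients) * 100.0

    # lipid-specific patient effects: a scalar intercept would cancel under
    # mol% closure, so matched-pair correlation needs per-lipid deviations
    patient_effect = rng.normal(
        0.0, config.patient_sigma, size=(config.n_patients, n_lipids)
    )

    rows = []
    for k, pid in enumerate(patient_ids):
        tissues = {"both": (TUMOUR, ALVEOLAR), "tumour": (TUMOUR,), "control": (ALVEOLAR,)}[
            kinds[k]
        ]
        for tissue in tissues:
            suffix = "T" if tissue == TUMOUR else "A"
            rows.append(
                {
                    "sample_id": f"{pid}{suffix}",
                    "patient_id": pid,
                    "tissue_type": tissue,
                    "diagnosis": diagnosis[k],
                    "gender": gender[k],
                    "age": ages[k],
                    "bmi": bmi[k],
                    "pack_years": pack_years[k],
                    "gold": gold[k],
                    "vital_pct": tissue_fracs[k, 0] if tissue == TUMOUR else np.nan,
                    "stroma_pct": tissue_fracs[k, 1] if tissue == TUMOUR else np.nan,
                    "necrosis_pct": tissue_fracs[k, 2] if tissue == TUMOUR else np.nan,
                    "inflammation": inflammation[k],
                    "emphysema": emphysema[k] if tissue == ALVEOLAR else np.nan,
                    "macrophages": macrophages[k] if tissue == ALVEOLAR else np.nan,
                    "fibrosis": fibrosis[k] if tissue == ALVEOLAR else np.nan,
                }
            )
    metadata = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(metadata)

    # --- log2 abundances -------------------------------------------
    log2_amount = np.tile(base, (n_samples, 1))
    tumour_mask = (metadata["tissue_type"] == TUMOUR).to_numpy()
    fc_vector = np.array([tumour_fc.get(name, 0.0) for name in catalogue])
    log2_amount[tumour_mask] += fc_vector

    scc_mask = (tumour_mask & (metadata["diagnosis"] == "SCC").to_numpy())
    diag_vector = np.array(
        [config.diagnosis_effects.get(name, 0.0) for name in catalogue]
    )
    log2_amount[scc_mask] += diag_vector

    for cov, couplings in config.covariate_couplings.items():
        values = metadata[cov].to_numpy(dtype=float)
        filled = np.where(np.isnan(values), np.nanmean(values), values)
        sd = filled.std()
        standardized = (filled - filled.mean()) / (sd if sd > 0 else 1.0)
        slope = np.array([couplings.get(name, 0.0) for name in catalogue])
        log2_amount += np.outer(standardized, slope)

    patient_row = metadata["patient_id"].map(
        {pid: k for k, pid in enumerate(patient_ids)}
    ).to_numpy()
    log2_amount += patient_effect[patient_row]
    log2_amount += rng.normal(0.0, config.noise_sigma, size=log2_amount.shape)

    # --- detection --------------------------------------------------
    det = np.empty((n_samples, n_lipids))
    tissue_per_sample = metadata["tissue_type"].to_numpy()
    for j, name in enumerate(catalogue):
        cls = classes[j]
        for tissue in (TUMOUR, ALVEOLAR):
            p_det = config.lipid_detection.get(name, {}).get(
                tissue,
                config.detection.get((cls, tissue), config.default_detection),
            )
            det[tissue_per_sample == tissue, j] = p_det
    detected = rng.random(size=det.shape) < det

    amounts = np.power(2.0, log2_amount)
    amounts[~detected] = np.nan

    # guard: a sample must detect something (guaranteed in practice)
    empty = ~np.isfinite(amounts).any(axis=1)
    if empty.any():
        raise ValueError(
            f"sample {metadata.index[empty][0]!r} detected no lipids; "
            f"detection probabilities too low"
        )

    totals = np.nansum(amounts, axis=1)
    mol_percent = amounts / totals[:, None] * 100.0
    matrix = LipidomeMatrix(
        pd.DataFrame(mol_percent, index=metadata.index, columns=catalogue),
        units=MOL_PERCENT,
    )

    truth = GroundTruth(
        tumour_log2fc=dict(tumour_fc),
        diagnosis_log2fc={k: v for k, v in config.diagnosis_effects.items() if v != 0},
        covariate_couplings={
            cov: dict(couplings)
            for cov, couplings in config.covariate_couplings.items()
        },
    )
    return SyntheticCohort(matrix=matrix, metadata=metadata, truth=truth, config=config)


def paper_like_config(seed: Optional[int] = None) -> CohortConfig:
    """Preset mirroring the study's dimensions: 26 patients, 43 samples
    (17 matched pairs, 6 tumour-only, 3 control-only), a 311-species
    catalogue, planted tumour effects on neutral vs surfactant lipids, a
    7-lipid tumour-subtype signature, age/emphysema coupling to long-chain
    PS/PI species, and a detection model tuned so roughly 45% of lipids
    pass a 90% presence filter and roughly 30% are detected everywhere."""
    # neutral lipids elevated in tumours ...
    up = [
        "TAG [48:2]", "TAG [50:2]", "TAG [52:3]", "TAG [54:4]", "TAG [56:4]",
        "CE [16:0]", "CE [18:1]", "CE [20:4]",
        "DAG [34:1]", "DAG [36:2]",
    ]
    # ... surfactant PG and saturated PC reduced
    down = [
        "PG [32:0]", "PG [34:1]", "PG [34:2]", "PG [36:1]", "PG [36:2]",
        "PG [38:4]",
        "PC [28:0]", "PC [30:0]", "PC [32:0]", "PC [34:0]",
    ]
    # tumour-subtype signature, elevated in SCC
    subtype = [
        "PE-O [36:4]", "Cer [42:1;0]", "PC [36:1]", "PI [36:1]",
        "CE [22:6]", "SM [34:1;0]", "PE [38:4]",
    ]
    # long-chain PS/PI coupled to age and emphysema grade
    ps_pi = ["PS [38:4]", "PI [38:4]", "PI [38:5]", "PS [40:4]"]
    infl_up = ["DAG [34:2]", "DAG [36:3]", "TAG [50:1]", "TAG [52:2]", "TAG [54:3]"]
    infl_down = ["SM [38:1;0]", "SM [40:1;0]", "PG [30:1]", "PG [40:2]"]

    forced = tuple(sorted(set(up + down + subtype + ps_pi + infl_up + infl_down)))
    catalogue = build_catalogue(DEFAULT_CLASS_COUNTS, seed=0, include=forced)

    species_effects = {name: 2.0 for name in up}
    species_effects.update({name: -2.0 for name in down})

    # detection tiers: always-detected core, a near-complete tier, a long
    # tail of sporadic species; planted lipids are all core.
    tier_rng = np.random.default_rng(20170911)
    lipid_detection: dict[str, dict[str, float]] = {}
    n_core = int(round(0.28 * len(catalogue)))
    n_mid = int(round(0.15 * len(catalogue)))
    forced_set = set(forced)
    core = set(forced)  # planted lipids must stay panel candidates
    mid: set[str] = set()
    for i in tier_rng.permutation(len(catalogue)):
        name = catalogue[i]
        if name in forced_set:
            continue
        if len(core) < n_core:
            core.add(name)
        elif len(mid) < n_mid:
            mid.add(name)
    for name in catalogue:
        cls = name.split(" ")[0]
        if name in core:
            p_t = p_a = 1.0
        elif name in mid:
            p_t = p_a = 0.96
        else:
            p_t = p_a = float(tier_rng.beta(2.0, 2.0) * 0.9)
            # structured missingness: neutral lipids scarce in controls,
            # surfactant PGs scarce in tumours
            if cls in ("TAG", "CE", "DAG"):
                p_a *= 0.35
            if cls == "PG":
                p_t *= 0.35
        lipid_detection[name] = {TUMOUR: p_t, ALVEOLAR: p_a}

    # 23 tumour-bearing patients (17 pairs + 6 tumour-only): 10 ADC, 10 SCC,
    # 3 other; the 3 control-only patients bring the totals to 11/12/3
    diagnosis_plan = (
        ["ADC"] * 10 + ["SCC"] * 7 + ["SCC"] * 3 + ["other"] * 3
        + ["ADC", "SCC", "SCC"]
    )

    config = CohortConfig(
        n_patients=26,
        exact_availability=(17, 6, 3),
        diagnosis_plan=diagnosis_plan,
        include_species=forced,
        species_tumour_effects=species_effects,
        diagnosis_effects={name: 1.8 for name in subtype},
        covariate_couplings={
            "age": {name: 0.5 for name in ps_pi},
            "emphysema": {name: 0.6 for name in ps_pi},
            "inflammation": {
                **{name: 0.5 for name in infl_up},
                **{name: -0.5 for name in infl_down},
            },
        },
        lipid_detection=lipid_detection,
        noise_sigma=0.3,
        patient_sigma=0.25,
        seed=seed,
    )
    return config


def paper_like_cohort(seed: Optional[int] = None) -> SyntheticCohort:
    """Generate one cohort from :func:`paper_like_config`."""
    return generate_cohort(paper_like_config(seed))
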