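"""Discriminative lipid panels: selection, the signed-sum score, and
ROC / Mann-Whitney evaluation.

A panel is the set of completely detected lipids that differ between two
groups with p below a significance bound (two-tailed Welch t-test) and an
absolute log2 fold change of the group means above a bound.  The per-sample
score is

    S = sum_i A_i * c_i

where A_i is +1 for lipids elevated in the first group and -1 for lipids
reduced in it, and c_i is the log2-transformed, cohort-mean-centred
abundance of panel lipid i.  With pooled-cohort centring the scores of the
reference cohort sum to zero, so the two groups land on opposite sides of
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .matrix import LipidomeMatrix

__all__ = [
    "PanelMember",
    "DiscriminationPanel",
    "ScoreResult",
    "RocCurve",
    "select_panel",
    "compute_score",
    "roc_auc",
    "mann_whitney_u",
]


@dataclass(frozen=True)
class PanelMember:
    """One panel lipid with its direction and selection statistics."""

    lipid: str
    sign: int  # +1: elevated in group1; -1: reduced in group1
    log2_fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be -1 or +1, got {self.sign}")


@dataclass
class DiscriminationPanel:
    """A two-group discrimination panel with its centring reference.

    ``reference_means`` holds, per member, the cohort mean of log2
    abundance used for centring; storing it with the panel makes the score
    reproducible on new samples and the centring convention swappable.
    """

    members: list[PanelMember]
    group1: str
    group2: str
    p_threshold: float
    log2fc_threshold: float
    reference_means: dict[str, float] = field(default_factory=dict)

    @property
    def lipids(self) -> list[str]:
        return [m.lipid for m in self.members]

    @property
    def signs(self) -> dict[str, int]:
        return {m.lipid: m.sign for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lipid": [m.lipid for m in self.members],
                "sign": [m.sign for m in self.members],
                "log2_fold_change": [m.log2_fold_change for m in self.members],
                "p_value": [m.p_value for m in self.members],
                "reference_mean": [
                    self.reference_means.get(m.lipid, np.nan) for m in self.members
                ],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        group1: str = "group1",
        group2: str = "group2",
        p_threshold: float = float("nan"),
        log2fc_threshold: float = float("nan"),
    ) -> "DiscriminationPanel":
        members = [
            PanelMember(
                lipid=str(row["lipid"]),
                sign=int(row["sign"]),
                log2_fold_change=float(row.get("log2_fold_change", np.nan)),
                p_value=float(row.get("p_value", np.nan)),
            )
            for _, row in frame.iterrows()
        ]
        ref = {
            str(row["lipid"]): float(row["reference_mean"])
            for _, row in frame.iterrows()
        }
        return cls(members, group1, group2, p_threshold, log2fc_threshold, ref)


@dataclass
class ScoreResult:
    """Per-sample panel scores (arbitrary units) with group labels."""

    scores: pd.Series
    groups: Optional[pd.Series] = None

    def by_group(self) -> dict[str, np.ndarray]:
        if self.groups is None:
            raise ValueError("score result carries no group labels")
        out: dict[str, np.ndarray] = {}
        for level in pd.unique(self.groups):
            out[level] = self.scores[self.groups == level].to_numpy()
        return out


@dataclass
class RocCurve:
    """ROC curve of a score against two class labels.

    ``positive`` names the class treated as positive after orienting the
    curve so that AUC >= 0.5; ``flipped`` records whether that orientation
    reversed the caller's group order.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    mwu_u: float
    mwu_p: float
    positive: str
    flipped: bool


def _as_frame(matrix: Union[LipidomeMatrix, pd.DataFrame]) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, LipidomeMatrix) else matrix


def _group_index(labels: pd.Series, group: str) -> pd.Index:
    idx = labels.index[labels == group]
    if len(idx) == 0:
        raise ValueError(f"group {group!r} has no samples")
    return idx


def select_panel(
    matrix: Union[LipidomeMatrix, pd.DataFrame],
    labels: Union[pd.Series, Mapping[str, str]],
    group1: str,
    group2: str,
    p_threshold: float = 0.01,
    log2fc_threshold: float = 1.0,
    pseudocount: float = 0.0,
) -> DiscriminationPanel:
    """Pick the lipids that discriminate ``group1`` from ``group2``.

    A lipid joins the panel iff the two-tailed Welch t-test p value is
    strictly below ``p_threshold`` and ``|log2(mean_1 / mean_2)|`` is
    strictly above ``log2fc_threshold``.  The fold change is taken on group
    means of the (relative) abundances.  ``sign`` is +1 when the lipid is
    elevated in ``group1`` and -1 when reduced.  Reference means for score
    centring are recorded from the full cohort (both groups pooled).

    The matrix must be complete over the samples of both groups (apply
    ``presence_filter(..., 1.0)`` first); ``pseudocount`` is added before
    every log2 only if explicitly set.
    """
    data = _as_frame(matrix)
    labels = pd.Series(labels)
    idx1 = _group_index(labels, group1)
    idx2 = _group_index(labels, group2)
    if len(idx1) < 2 or len(idx2) < 2:
        small = group1 if len(idx1) < 2 else group2
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    used = data.loc[idx1.union(idx2, sort=False)]
    if used.isna().any().any():
        bad = used.columns[used.isna().any(axis=0)][0]
        raise ValueError(
            f"matrix has missing values (e.g. lipid {bad!r}); apply a "
            f"complete-presence filter before panel selection"
        )

    x1 = data.loc[idx1].to_numpy(dtype=float) + pseudocount
    x2 = data.loc[idx2].to_numpy(dtype=float) + pseudocount
    _, p_values = sps.ttest_ind(x1, x2, axis=0, equal_var=False)
    log2fc = np.log2(x1.mean(axis=0)) - np.log2(x2.mean(axis=0))

    members = []
    cohort_log2 = np.log2(data.to_numpy(dtype=float) + pseudocount)
    cohort_means = cohort_log2.mean(axis=0)
    reference: dict[str, float] = {}
    for j, lipid in enumerate(data.columns):
        if p_values[j] < p_threshold and abs(log2fc[j]) > log2fc_threshold:
            sign = 1 if log2fc[j] > 0 else -1
            members.append(
                PanelMember(str(lipid), sign, float(log2fc[j]), float(p_values[j]))
            )
            reference[str(lipid)] = float(cohort_means[j])

    return DiscriminationPanel(
        members=members,
        group1=group1,
        group2=group2,
        p_threshold=p_threshold,
        log2fc_threshold=log2fc_threshold,
        reference_means=reference,
    )


def compute_score(
    matrix: Union[LipidomeMatrix, pd.DataFrame],
    panel: DiscriminationPanel,
    labels: Optional[Union[pd.Series, Mapping[str, str]]] = None,
    pseudocount: float = 0.0,
) -> ScoreResult:
    """Evaluate the signed-sum score S for every sample.

    For each panel lipid, c_i = log2(abundance) - reference mean; the score
    is the sum of A_i * c_i over the panel.  Every panel lipid must be
    detected in every scored sample.
    """
    data = _as_frame(matrix)
    if len(panel) == 0:
        scores = pd.Series(0.0, index=data.index)
    else:
        for member in panel.members:
            if member.lipid not in data.columns:
                raise ValueError(f"panel lipid {member.lipid!r} not in matrix")
            column = data[member.lipid]
            if column.isna().any():
                sample = column.index[column.isna()][0]
                raise ValueError(
                    f"panel lipid {member.lipid!r} missing in sample {sample!r}"
                )
        values = data[[m.lipid for m in panel.members]].to_numpy(dtype=float)
        centred = np.log2(values + pseudocount) - np.array(
            [panel.reference_means[m.lipid] for m in panel.members]
        )
        signs = np.array([m.sign for m in panel.members], dtype=float)
        scores = pd.Series(centred @ signs, index=data.index)

    group_series = None
    if labels is not None:
        group_series = pd.Series(labels).reindex(scores.index)
    return ScoreResult(scores=scores, groups=group_series)


def mann_whitney_u(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts the pairs in which a ``group1`` value
    exceeds a ``group2`` value (ties count half).  The p value comes from
    the exact permutation distribution when the combined sample size is at
    most 12 and there are no ties, and from the tie-corrected,
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_auc(result: ScoreResult, positive: Optional[str] = None) -> RocCurve:
    """ROC curve and AUC for a two-group score.

    The curve is oriented so the reported AUC is >= 0.5 unless ``positive``
    pins the positive class explicitly.  Ties receive half credit
    (trapezoidal integration), so AUC = U / (n1 * n2) for the favourable
    direction.  The Mann-Whitney p value of the two score groups is
    attached.
    """
    if result.groups is None:
        raise ValueError("score result carries no group labels")
    groups = result.groups
    levels = list(pd.unique(groups.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {levels!r}")

    scores = result.scores.to_numpy(dtype=float)

    def _curve(pos_level):
        y = (groups == pos_level).to_numpy()
        fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
        return fpr, tpr, thresholds, _trapezoid_auc(fpr, tpr)

    flipped = False
    if positive is None:
        positive = levels[0]
        fpr, tpr, thresholds, area = _curve(positive)
        if area < 0.5:
            positive = levels[1]
            flipped = True
            fpr, tpr, thresholds, area = _curve(positive)
    else:
        fpr, tpr, thresholds, area = _curve(positive)

    pos_scores = scores[(groups == positive).to_numpy()]
    neg_scores = scores[(groups != positive).to_numpy()]
    u_stat, p_value = mann_whitney_u(pos_scores, neg_scores)

    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(area),
        mwu_u=u_stat,
        mwu_p=p_value,
        positive=str(positive),
        flipped=flipped,
    )
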