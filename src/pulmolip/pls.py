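"""PLS2 regression (NIPALS) linking lipid profiles to phenotypes.

The workflow is: min-max scale predictors (lipid mol%) and responses
(clinical covariates and histology scores) to [0, 1]; fit a NIPALS PLS2
model on column-centred, unit-variance blocks; judge predictive power per
response by patient-grouped 10-segment cross-validation, where a response is
significant when at least one component reaches Q^2 >= 0.0975; read the
latent structure off the correlation circle; and check categorical
responses by comparing fitted values between levels with the Mann-Whitney U
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import mann_whitney_u

__all__ = [
    "Q2_SIGNIFICANCE",
    "ScaledBlock",
    "PlsModel",
    "CvReport",
    "minmax_scale",
    "fit_pls2",
    "cross_validate",
    "evaluate_categorical",
    "correlation_circle",
]

#: A response is significant when any component's Q^2 reaches this bound.
Q2_SIGNIFICANCE = 0.0975

_ArrayLike = Union[pd.DataFrame, np.ndarray]


@dataclass
class ScaledBlock:
    """A samples × variables table mapped to the unit interval.

    Keeps the per-variable original minima and maxima so the affine map is
    invertible (constant variables map to 0 and cannot be inverted
    uniquely; they are restored to their constant).
    """

    values: pd.DataFrame
    mins: pd.Series
    maxs: pd.Series
    kinds: Optional[dict[str, str]] = None  # variable -> continuous|categorical

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    def inverse(self, scaled: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Map unit-interval values back to the original scale."""
        if scaled is None:
            scaled = self.values
        out = scaled.mul(self.maxs - self.mins, axis=1).add(self.mins, axis=1)
        constant = self.maxs == self.mins
        for col in self.values.columns[constant]:
            out[col] = self.mins[col]
        return out


def minmax_scale(table: pd.DataFrame, kinds: Optional[Mapping[str, str]] = None) -> ScaledBlock:
    """Scale every variable to [0, 1] via x' = (x - min) / (max - min).

    Constant variables map to 0 (with a warning); a non-numeric cell is
    rejected naming its row and column.
    """
    columns = {}
    for col in table.columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = table.index[bad][0]
            raise ValueError(
                f"non-numeric value {table.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        columns[col] = converted.astype(float)
    numeric = pd.DataFrame(columns, index=table.index)

    mins = numeric.min(axis=0)
    maxs = numeric.max(axis=0)
    span = maxs - mins
    constant = span == 0
    if constant.any():
        names = list(numeric.columns[constant])
        warnings.warn(f"constant variables mapped to 0: {names}", stacklevel=2)
    safe_span = span.replace(0.0, 1.0)
    scaled = numeric.sub(mins, axis=1).div(safe_span, axis=1)
    scaled.loc[:, constant] = 0.0
    return ScaledBlock(
        values=scaled,
        mins=mins,
        maxs=maxs,
        kinds=dict(kinds) if kinds is not None else None,
    )


@dataclass
class PlsModel:
    """A fitted NIPALS PLS2 model.

    Matrices follow the usual two-block notation: per component h, ``t_h``
    (score), ``w_h`` (unit-norm X weight), ``p_h`` (X loading), ``c_h``
    (Y loading).  ``coefficients`` are standardized regression coefficients
    W (PᵀW)⁻¹ Cᵀ; ``r2`` holds the cumulative per-response explained
    variance after each component; ``cor_x``/``cor_y`` are the
    correlation-circle coordinates (Pearson correlation of each original
    variable with each score vector).
    """

    x_names: list[str]
    y_names: list[str]
    n_components: int
    scores: pd.DataFrame          # n x H, columns t1..tH
    x_weights: pd.DataFrame       # p x H
    x_loadings: pd.DataFrame      # p x H
    y_loadings: pd.DataFrame      # q x H
    coefficients: pd.DataFrame    # p x q, standardized
    r2: pd.DataFrame              # H x q, cumulative
    cor_x: pd.DataFrame           # p x H
    cor_y: pd.DataFrame           # q x H
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)
    y_scale: np.ndarray = field(repr=False, default=None)
    fitted: pd.DataFrame = field(repr=False, default=None)
    y_values: pd.DataFrame = field(repr=False, default=None)

    def predict(
        self, x: _ArrayLike, n_components: Optional[int] = None
    ) -> pd.DataFrame:
        """Predict responses (on the scale the model was fed) from new
        predictor rows, using the first ``n_components`` components."""
        h = self.n_components if n_components is None else min(n_components, self.n_components)
        values = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else np.asarray(x, float)
        x0 = (values - self.x_mean) / self.x_scale
        b = _coefficients(
            self.x_weights.to_numpy()[:, :h],
            self.x_loadings.to_numpy()[:, :h],
            self.y_loadings.to_numpy()[:, :h],
        )
        y0 = x0 @ b
        pred = y0 * self.y_scale + self.y_mean
        index = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(len(values))
        return pd.DataFrame(pred, index=index, columns=self.y_names)


def _block_values(block: Union[ScaledBlock, _ArrayLike]) -> pd.DataFrame:
    if isinstance(block, ScaledBlock):
        return block.values
    if isinstance(block, pd.DataFrame):
        return block
    arr = np.asarray(block, dtype=float)
    return pd.DataFrame(arr, columns=[f"v{j}" for j in range(arr.shape[1])])


def _coefficients(w: np.ndarray, p: np.ndarray, c: np.ndarray) -> np.ndarray:
    # B = W (P'W)^-1 C' on the standardized scale
    return w @ np.linalg.solve(p.T @ w, c.T)


def _standardize(values: np.ndarray, center: bool, scale: bool):
    mean = values.mean(axis=0) if center else np.zeros(values.shape[1])
    if scale:
        sd = values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns stay centred only
    else:
        sd = np.ones(values.shape[1])
    return (values - mean) / sd, mean, sd


def fit_pls2(
    x: Union[ScaledBlock, _ArrayLike],
    y: Union[ScaledBlock, _ArrayLike],
    n_components: int = 3,
    center: bool = True,
    scale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsModel:
    """Fit a PLS2 model with the NIPALS algorithm.

    Per component the inner loop iterates w ∝ Xᵀu, t = Xw, c = Yᵀt / tᵀt,
    u = Yc / cᵀc until t stabilises; X and Y are then deflated by the
    rank-one update t pᵀ (resp. t cᵀ).  Blocks are column-centred and, by
    default, scaled to unit variance first.

    Raises on non-convergence of a component; stops early (reporting fewer
    components) when the Y residual is exhausted.
    """
    x_df = _block_values(x)
    y_df = _block_values(y)
    if x_df.shape[0] != y_df.shape[0]:
        raise ValueError(
            f"X and Y disagree on samples: {x_df.shape[0]} vs {y_df.shape[0]}"
        )
    if not x_df.index.equals(y_df.index):
        raise ValueError("X and Y must be indexed by the same samples")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    x0, x_mean, x_scale = _standardize(x_df.to_numpy(dtype=float), center, scale)
    y0, y_mean, y_scale = _standardize(y_df.to_numpy(dtype=float), center, scale)
    n, p = x0.shape
    q = y0.shape[1]

    e, f = x0.copy(), y0.copy()
    t_list, w_list, p_list, c_list = [], [], [], []
    y_total = (y0**2).sum(axis=0)
    eps = np.finfo(float).eps

    fitted_components = 0
    for h in range(n_components):
        if np.sqrt((f**2).sum()) <= 1e-12 * max(1.0, np.sqrt((y0**2).sum())):
            break  # Y residual exhausted
        if np.sqrt((e**2).sum()) <= 1e-12 * max(1.0, np.sqrt((x0**2).sum())):
            break  # X residual exhausted (rank reached)
        u = f[:, int(np.argmax(f.var(axis=0)))].copy()
        if (u**2).sum() <= eps:
            u = f[:, int(np.argmax((f**2).sum(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = e.T @ u
            norm = np.linalg.norm(w)
            if norm <= eps:
                raise ValueError(f"degenerate X weights at component {h + 1}")
            w /= norm
            t = e @ w
            tt = t @ t
            if tt <= eps:
                raise ValueError(f"degenerate scores at component {h + 1}")
            c = f.T @ t / tt
            if q == 1:
                break  # single response: one pass is exact
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
            u = f @ c / (c @ c)
        else:
            raise ValueError(f"NIPALS did not converge for component {h + 1}")
        p_vec = e.T @ t / tt
        c = f.T @ t / tt
        e = e - np.outer(t, p_vec)
        f = f - np.outer(t, c)
        t_list.append(t)
        w_list.append(w)
        p_list.append(p_vec)
        c_list.append(c)
        fitted_components += 1

    if fitted_components == 0:
        raise ValueError("no component could be extracted (empty Y block?)")

    t_mat = np.column_stack(t_list)
    w_mat = np.column_stack(w_list)
    p_mat = np.column_stack(p_list)
    c_mat = np.column_stack(c_list)
    comp_names = [f"t{h + 1}" for h in range(fitted_components)]

    # cumulative per-response R2
    r2 = np.zeros((fitted_components, q))
    y_hat = np.zeros_like(y0)
    for h in range(fitted_components):
        y_hat = y_hat + np.outer(t_list[h], c_list[h])
        resid = ((y0 - y_hat) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[h] = np.where(y_total > 0, 1.0 - resid / y_total, np.nan)

    b = _coefficients(w_mat, p_mat, c_mat)
    fitted_std = x0 @ b
    fitted = pd.DataFrame(
        fitted_std * y_scale + y_mean, index=x_df.index, columns=list(y_df.columns)
    )

    cor_x = _safe_corr(x_df.to_numpy(dtype=float), t_mat)
    cor_y = _safe_corr(y_df.to_numpy(dtype=float), t_mat)

    return PlsModel(
        x_names=[str(cname) for cname in x_df.columns],
        y_names=[str(cname) for cname in y_df.columns],
        n_components=fitted_components,
        scores=pd.DataFrame(t_mat, index=x_df.index, columns=comp_names),
        x_weights=pd.DataFrame(w_mat, index=x_df.columns, columns=comp_names),
        x_loadings=pd.DataFrame(p_mat, index=x_df.columns, columns=comp_names),
        y_loadings=pd.DataFrame(c_mat, index=y_df.columns, columns=comp_names),
        coefficients=pd.DataFrame(b, index=x_df.columns, columns=y_df.columns),
        r2=pd.DataFrame(r2, index=comp_names, columns=y_df.columns),
        cor_x=pd.DataFrame(cor_x, index=x_df.columns, columns=comp_names),
        cor_y=pd.DataFrame(cor_y, index=y_df.columns, columns=comp_names),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        fitted=fitted,
        y_values=y_df.copy(),
    )


def _safe_corr(variables: np.ndarray, t_mat: np.ndarray) -> np.ndarray:
    """Pearson correlation of each variable column with each score column;
    zero-variance variables yield NaN (undefined), not 0."""
    n, p = variables.shape
    h = t_mat.shape[1]
    v0 = variables - variables.mean(axis=0)
    t0 = t_mat - t_mat.mean(axis=0)
    v_sd = np.sqrt((v0**2).sum(axis=0))
    t_sd = np.sqrt((t0**2).sum(axis=0))
    out = np.full((p, h), np.nan)
    valid = v_sd > 0
    num = v0.T @ t0
    out[valid] = num[valid] / np.outer(v_sd[valid], t_sd)
    return out


@dataclass
class CvReport:
    """Cross-validation outcome.

    ``segments`` maps each patient to its segment; ``q2`` is components ×
    responses; ``significant`` flags responses with any Q^2 >=
    :data:`Q2_SIGNIFICANCE`.
    """

    segments: pd.Series
    q2: pd.DataFrame
    press: pd.DataFrame
    rss: pd.DataFrame
    significant: dict[str, bool]

    def best_component(self, response: str) -> str:
        return str(self.q2[response].idxmax())


def cross_validate(
    x: Union[ScaledBlock, _ArrayLike],
    y: Union[ScaledBlock, _ArrayLike],
    groups: Optional[Sequence] = None,
    n_segments: int = 10,
    n_components: int = 3,
    seed: Optional[int] = None,
    center: bool = True,
    scale: bool = True,
) -> CvReport:
    """Patient-grouped segment cross-validation with per-component Q^2.

    Patients are partitioned at random into ``n_segments`` segments whose
    sizes differ by at most one; all samples of one patient share a
    segment, so matched pairs are never split between training and
    validation.  For each held-out segment a model fit on the remainder
    predicts it; per response and component h,

        Q^2_h = 1 - PRESS_h / RSS_{h-1}

    with RSS taken from the all-data model (RSS_0 being the residual sum of
    squares about the mean).  A response is significant when any
    component's Q^2 reaches 0.0975.
    """
    x_df = _block_values(x)
    y_df = _block_values(y)
    n = x_df.shape[0]
    if groups is None:
        groups = list(x_df.index)
    groups = pd.Series(list(groups), index=x_df.index)
    patients = pd.unique(groups)
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if len(patients) < n_segments:
        raise ValueError(
            f"need at least {n_segments} patients, got {len(patients)}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    assignment = {}
    for pos, patient_idx in enumerate(order):
        assignment[patients[patient_idx]] = pos % n_segments
    segments = pd.Series({p: assignment[p] for p in patients})

    full = fit_pls2(x_df, y_df, n_components, center=center, scale=scale)
    h_max = full.n_components
    q = y_df.shape[1]
    y_values = y_df.to_numpy(dtype=float)

    # RSS_0..RSS_{H-1} on the data scale, from the all-data model
    rss = np.zeros((h_max + 1, q))
    rss[0] = ((y_values - y_values.mean(axis=0)) ** 2).sum(axis=0)
    for h in range(1, h_max + 1):
        pred = full.predict(x_df, n_components=h).to_numpy()
        rss[h] = ((y_values - pred) ** 2).sum(axis=0)

    press = np.zeros((h_max, q))
    sample_segment = groups.map(segments)
    for seg in range(n_segments):
        held = (sample_segment == seg).to_numpy()
        if not held.any():
            continue
        model = fit_pls2(
            x_df.loc[~held], y_df.loc[~held], n_components, center=center, scale=scale
        )
        for h in range(1, h_max + 1):
            h_eff = min(h, model.n_components)
            pred = model.predict(x_df.loc[held], n_components=h_eff).to_numpy()
            press[h - 1] += ((y_values[held] - pred) ** 2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        q2 = 1.0 - press / rss[:h_max]

    comp_names = [f"t{h + 1}" for h in range(h_max)]
    y_names = [str(cname) for cname in y_df.columns]
    q2_df = pd.DataFrame(q2, index=comp_names, columns=y_names)
    significant = {
        name: bool(np.nanmax(q2_df[name].to_numpy()) >= Q2_SIGNIFICANCE)
        if np.isfinite(q2_df[name].to_numpy()).any()
        else False
        for name in y_names
    }
    return CvReport(
        segments=segments,
        q2=q2_df,
        press=pd.DataFrame(press, index=comp_names, columns=y_names),
        rss=pd.DataFrame(rss[:h_max], index=[f"t{h}" for h in range(h_max)], columns=y_names),
        significant=significant,
    )


def evaluate_categorical(
    model: PlsModel,
    response: str,
    level_pair: tuple[float, float],
) -> tuple[dict[float, np.ndarray], float]:
    """Compare the model's fitted values for a categorical response between
    two of its levels with the Mann-Whitney U test.

    ``level_pair`` gives two encoded level values of the response column the
    model was trained on.  Returns the fitted values split by true level
    and the two-sided p value.
    """
    if response not in model.y_names:
        raise ValueError(f"response {response!r} was not part of the model")
    truth = model.y_values[response]
    fitted = model.fitted[response]
    groups: dict[float, np.ndarray] = {}
    for level in level_pair:
        mask = np.isclose(truth.to_numpy(dtype=float), level)
        if mask.sum() < 2:
            raise ValueError(
                f"level {level!r} of response {response!r} has fewer than 2 samples"
            )
        groups[level] = fitted.to_numpy(dtype=float)[mask]
    _, p_value = mann_whitney_u(groups[level_pair[0]], groups[level_pair[1]])
    return groups, p_value


def correlation_circle(
    model: PlsModel, components: tuple[int, int] = (1, 2)
) -> pd.DataFrame:
    """Coordinates of every X and Y variable on a pair of t-components.

    Each coordinate is the Pearson correlation of the original variable
    with the score vector; zero-variance variables carry NaN (undefined),
    never 0.  All defined coordinates lie in the unit disc.
    """
    a, b = components
    for comp in (a, b):
        if not 1 <= comp <= model.n_components:
            raise ValueError(
                f"component {comp} not fitted (model has {model.n_components})"
            )
    rows = []
    for block, kind in ((model.cor_x, "X"), (model.cor_y, "Y")):
        part = block[[f"t{a}", f"t{b}"]].copy()
        part.columns = [f"t{a}", f"t{b}"]
        part.insert(0, "block", kind)
        rows.append(part)
    return pd.concat(rows)
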