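"""Shared fixtures and independent oracles.

The oracle implementations here are deliberately naive (enumeration,
pairwise counting, normal equations, dense eigendecomposition) and share no
code with the package, so they can vouch for it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pulmolip.simulate import ClassEffect, CohortConfig


# ---------------------------------------------------------------- oracles


def mwu_oracle_u(group1, group2) -> float:
    """U statistic by exhaustive pairwise comparison (ties count half)."""
    u = 0.0
    for a in group1:
        for b in group2:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mwu_oracle_exact_p(group1, group2) -> float:
    """Two-sided exact p by enumerating every labelling of the pooled
    values (no ties allowed)."""
    pooled = list(group1) + list(group2)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    n1 = len(group1)
    observed = mwu_oracle_u(group1, group2)
    n2 = len(group2)
    mean_u = n1 * n2 / 2.0
    dev = abs(observed - mean_u)
    count = 0
    total = 0
    for index_set in combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in index_set]
        rest = [pooled[i] for i in range(len(pooled)) if i not in index_set]
        u = mwu_oracle_u(chosen, rest)
        if abs(u - mean_u) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def auc_oracle(pos, neg) -> float:
    """AUC as the probability a positive outranks a negative."""
    return mwu_oracle_u(pos, neg) / (len(pos) * len(neg))


def ols_oracle(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients via lstsq on already-centred data."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def pca_oracle(values: np.ndarray):
    """Eigendecomposition of the covariance matrix of centred data;
    returns (explained variances desc, loadings as columns)."""
    centred = values - values.mean(axis=0)
    cov = centred.T @ centred / (values.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


# --------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture()
def tiny_matrix():
    """A 4-sample, 3-lipid complete pmol matrix."""
    from pulmolip import LipidomeMatrix

    data = pd.DataFrame(
        {
            "PC [32:0]": [2.0, 4.0, 1.0, 5.0],
            "PG [34:1]": [3.0, 1.0, 2.0, 2.0],
            "TAG [48:2]": [5.0, 5.0, 7.0, 3.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return LipidomeMatrix(data, units="pmol")


def planted_panel_config(seed=None) -> CohortConfig:
    """Two-arm cohort with 20 planted panel lipids (+2 on 10 TAG/CE, -2 on
    10 PG) among 100 fully detected species."""
    return CohortConfig(
        n_patients=40,
        exact_availability=(0, 20, 20),  # 20 tumour-only + 20 control-only
        class_counts={"TAG": 20, "CE": 10, "PG": 20, "PC": 25, "PE": 15, "SM": 10},
        tumour_effects={
            "TAG": ClassEffect(2.0, 5),
            "CE": ClassEffect(2.0, 5),
            "PG": ClassEffect(-2.0, 10),
        },
        noise_sigma=0.3,
        patient_sigma=0.1,
        seed=seed,
    )


@pytest.fixture()
def planted_cohort():
    from pulmolip import generate_cohort

    return generate_cohort(planted_panel_config(seed=7))
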