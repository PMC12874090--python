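"""Spearman rank correlation of gene abundances against hydrographic profiles.

Re-implements the rank correlation rather than delegating: average ranks
for ties, rho as the Pearson correlation of the rank vectors, a two-sided
asymptotic p from the t transform with n-2 degrees of freedom, and an
optional permutation p (exact enumeration for n <= 7).  A long-format
correlation matrix over joined abundance and environment tables mirrors
the heatmap analysis, with pairwise deletion of missing values and an
optional Benjamini-Hochberg column (off by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from hgscan.errors import InputError

ENV_COLUMNS = (
    "sample_id",
    "station",
    "depth_m",
    "temperature_C",
    "oxygen_umol_kg",
    "AOU_umol_kg",
    "NO3_uM",
    "PO4_uM",
    "SiO2_uM",
    "dTHg_pM",
    "dMeHg_pM",
    "dMeHg_over_dTHg",
    "cells_per_mL",
)


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    rho: float
    p_value: float
    n: int
    method: str  # "asymptotic" | "permutation"


def _ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x, y) -> tuple[float, float]:
    """(rho, two-sided asymptotic p) for two equal-length vectors, n >= 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("spearman needs two equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise InputError("spearman needs n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InputError("spearman input contains missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("spearman undefined for a constant vector")
    rho = _rho_of_ranks(_ranks(x), _ranks(y))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = float(np.finfo(float).tiny)
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
        p = max(min(p, 1.0), float(np.finfo(float).tiny))
    return rho, p


def spearman_permutation_p(x, y, n_perm: int = 999, seed: int = 0) -> float:
    """Two-sided permutation p for Spearman rho.

    Exact enumeration of all n! permutations for n <= 7; otherwise
    Monte Carlo with the add-one estimator (1 + k) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_obs, _ = spearman(x, y)
    rx, ry = _ranks(x), _ranks(y)
    n = len(x)
    if n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rho = _rho_of_ranks(rx, ry[list(perm)])
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rho = _rho_of_ranks(rx, ry[rng.permutation(n)])
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def validate_env_table(env: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing:
        raise InputError(f"environment table missing column(s): {', '.join(missing)}")
    if (env["depth_m"] <= 0).any():
        raise InputError("environment table: depth_m must be positive")
    ratio = env["dMeHg_pM"] / env["dTHg_pM"]
    if not np.allclose(env["dMeHg_over_dTHg"], ratio, rtol=1e-6):
        raise InputError("dMeHg_over_dTHg column inconsistent with dMeHg_pM / dTHg_pM")
    return env


def join_abundance_env(abundance: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """One row per sample: '<family>_pct' columns joined to environment columns."""
    wide = abundance.pivot(index="sample_id", columns="family", values="relative_pct")
    wide.columns = [f"{fam}_pct" for fam in wide.columns]
    wide = wide.reset_index()
    only_ab = set(wide["sample_id"]) - set(env["sample_id"])
    only_env = set(env["sample_id"]) - set(wide["sample_id"])
    if only_ab or only_env:
        raise InputError(
            "abundance/environment sample mismatch: "
            f"abundance-only={sorted(only_ab)}, env-only={sorted(only_env)}"
        )
    return wide.merge(env, on="sample_id", validate="one_to_one")


def correlation_matrix(
    joined: pd.DataFrame,
    variables: list[str],
    permutation: bool = False,
    n_perm: int = 999,
    seed: int = 0,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """All unordered variable pairs as a long-format correlation table.

    Rows with a missing value in either variable are dropped pairwise and
    the effective n is reported per pair.
    """
    unknown = [v for v in variables if v not in joined.columns]
    if unknown:
        raise InputError(f"unknown variable(s): {', '.join(unknown)}")
    rows = []
    for vx, vy in itertools.combinations_with_replacement(variables, 2):
        sub = joined[[vx, vy]].dropna() if vx != vy else joined[[vx]].dropna()
        if vx == vy:
            rows.append(
                CorrelationResult(vx, vy, 1.0, 1.0, len(sub), "identity")
            )
            continue
        x = sub[vx].to_numpy(dtype=float)
        y = sub[vy].to_numpy(dtype=float)
        if len(x) >= 3 and (np.all(x == x[0]) or np.all(y == y[0])):
            # rho undefined for a flat variable; report rather than abort
            rows.append(CorrelationResult(vx, vy, float("nan"), float("nan"), len(x), "undefined"))
            continue
        rho, p_asym = spearman(x, y)
        if permutation:
            p = spearman_permutation_p(x, y, n_perm=n_perm, seed=seed)
            method = "permutation"
        else:
            p, method = p_asym, "asymptotic"
        rows.append(CorrelationResult(vx, vy, rho, p, len(x), method))
    df = pd.DataFrame(
        {
            "variable_x": [r.variable_x for r in rows],
            "variable_y": [r.variable_y for r in rows],
            "rho": [r.rho for r in rows],
            "p_value": [r.p_value for r in rows],
            "n": [r.n for r in rows],
            "method": [r.method for r in rows],
        }
    )
    if bh_adjust:
        mask = df["variable_x"] != df["variable_y"]
        df.loc[mask, "p_bh"] = _benjamini_hochberg(df.loc[mask, "p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
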