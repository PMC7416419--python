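"""Community statistics for the abundance time series.

All resemblance-based analyses follow the same convention: relative
abundances (percent) are square-root transformed, pairwise Bray-Curtis
*similarity* is expressed on a 0-100 scale, and dissimilarity is
100 - similarity.  SIMPER decomposes those pairwise values into per-taxon
contributions; the distance-based ordination (distLM/dbRDA) regresses the
principal coordinates of the dissimilarity matrix on z-score-normalized
environmental variables, with Lingoes correction applied when the
dissimilarity matrix is not Euclidean-embeddable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROW_SUM_TOL = 1e-6

#: Environmental variables considered by the ordination.
ENV_VARIABLES = ("depth_m", "salinity_pct", "daylength_h", "sunlight_h", "air_temp_C")


def simpson_diversity(row: pd.Series) -> float:
    """Simpson's index of diversity, 1 - sum(p_i^2), over all columns of an
    abundance-table row (percent scale)."""
    total = float(row.sum())
    if abs(total - 100.0) > 1e-3:
        raise ValueError(f"abundance row sums to {total}, not 100")
    p = np.asarray(row, dtype=float) / 100.0
    return float(1.0 - np.sum(p * p))


def diversity_table(table: pd.DataFrame) -> pd.Series:
    out = pd.Series(
        {sid: simpson_diversity(table.loc[sid]) for sid in table.index},
        name="simpson_diversity",
    )
    out.index.name = "sample_id"
    return out


def _sqrt_transform(table: pd.DataFrame) -> np.ndarray:
    values = np.asarray(table, dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances")
    return np.sqrt(values)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis similarity (percent) on square-root-transformed
    relative abundances.

    S_jk = 100 * 2 * sum_i min(y_ij, y_ik) / sum_i (y_ij + y_ik), symmetric
    with a diagonal of 100.
    """
    y = _sqrt_transform(table)
    n = y.shape[0]
    sim = np.full((n, n), 100.0)
    for j in range(n):
        for k in range(j + 1, n):
            denom = float(np.sum(y[j] + y[k]))
            if denom == 0:
                raise ValueError("two all-zero rows have undefined similarity")
            s = 200.0 * float(np.sum(np.minimum(y[j], y[k]))) / denom
            sim[j, k] = sim[k, j] = s
    out = pd.DataFrame(sim, index=table.index, columns=table.index)
    out.index.name = table.index.name
    return out


@dataclass
class SimperResult:
    """Per-taxon contributions to within-group similarity and between-group
    dissimilarity, averaged over sample pairs and ranked descending."""

    within: dict[str, pd.Series]          # group -> taxon contributions (%)
    between: dict[tuple[str, str], pd.Series]  # (group, group) -> contributions
    mean_within: dict[str, float]
    mean_between: dict[tuple[str, str], float]


def _pair_terms(yj: np.ndarray, yk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon similarity and dissimilarity terms for one sample pair.

    Both sets of terms sum to the pair's Bray-Curtis similarity and
    dissimilarity respectively (the conservation identity SIMPER rests on).
    """
    denom = float(np.sum(yj + yk))
    if denom == 0:
        raise ValueError("two all-zero rows in SIMPER")
    sim_terms = 200.0 * np.minimum(yj, yk) / denom
    dis_terms = 100.0 * np.abs(yj - yk) / denom
    return sim_terms, dis_terms


def simper(table: pd.DataFrame, groups: Mapping[str, str]) -> SimperResult:
    """SIMPER decomposition over the groups (e.g. seasons) of the samples.

    Similarity contributions are averaged over within-group pairs; groups
    with fewer than two samples are skipped with a warning.  Dissimilarity
    contributions are averaged over between-group pairs for every group
    pair.
    """
    y = _sqrt_transform(table)
    index = {sid: i for i, sid in enumerate(table.index)}
    members: dict[str, list[str]] = {}
    for sid in table.index:
        members.setdefault(groups[sid], []).append(sid)
    taxa = table.columns

    within: dict[str, pd.Series] = {}
    mean_within: dict[str, float] = {}
    for group, sids in members.items():
        if len(sids) < 2:
            warnings.warn(
                f"group {group!r} has {len(sids)} sample(s); within-group "
                "similarity undefined", stacklevel=2)
            continue
        acc = np.zeros(len(taxa))
        pairs = list(combinations(sids, 2))
        for a, b in pairs:
            sim_terms, _ = _pair_terms(y[index[a]], y[index[b]])
            acc += sim_terms
        contributions = pd.Series(acc / len(pairs), index=taxa)
        within[group] = contributions.sort_values(ascending=False)
        mean_within[group] = float(contributions.sum())

    between: dict[tuple[str, str], pd.Series] = {}
    mean_between: dict[tuple[str, str], float] = {}
    for g1, g2 in combinations(sorted(members), 2):
        acc = np.zeros(len(taxa))
        count = 0
        for a in members[g1]:
            for b in members[g2]:
                _, dis_terms = _pair_terms(y[index[a]], y[index[b]])
                acc += dis_terms
                count += 1
        contributions = pd.Series(acc / count, index=taxa)
        between[(g1, g2)] = contributions.sort_values(ascending=False)
        mean_between[(g1, g2)] = float(contributions.sum())
    return SimperResult(within, between, mean_within, mean_between)


# ---------------------------------------------------------------------------
# Distance-based linear model / dbRDA
# ---------------------------------------------------------------------------

def env_matrix(
    env: pd.DataFrame, variables: Sequence[str] = ENV_VARIABLES
) -> pd.DataFrame:
    """Z-score-normalize the environmental table.

    Samples missing any requested variable are dropped (their count is
    reported via a warning), mirroring the practice of excluding a variable
    or sample not recorded for all sampling periods.
    """
    sub = env.loc[:, [v for v in variables if v in env.columns]]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} sample(s) with missing environmental data",
                      stacklevel=2)
    sd = complete.std(ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"environmental columns with zero variance: {flat}")
    return (complete - complete.mean()) / sd


@dataclass
class OrdinationResult:
    """dbRDA output: constrained-axis scores and variance bookkeeping."""

    scores: pd.DataFrame       # samples x axes (dbRDA1, dbRDA2, ...)
    pct_fitted: np.ndarray     # per-axis % of fitted variation
    pct_total: np.ndarray      # per-axis % of total variation
    r_squared: float           # trace(HGH) / trace(G)
    adjusted_r_squared: float
    selected: list[str]        # variables in selection order
    marginal_r_squared: dict[str, float]  # single-variable fits


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def _principal_coordinates(dissimilarity: np.ndarray, tol: float = 1e-8):
    """PCoA with additive (Lingoes) correction for negative eigenvalues.

    Returns the full-rank coordinate matrix (columns scaled by sqrt of the
    eigenvalues) and the centered Gower matrix actually decomposed.
    """
    d2 = dissimilarity ** 2
    g = _gower_center(d2)
    eigval = np.linalg.eigvalsh(g)
    min_eig = eigval.min()
    if min_eig < -tol * max(1.0, eigval.max()):
        # Lingoes: add 2c to all squared off-diagonal dissimilarities
        c = -min_eig
        d2 = d2 + 2.0 * c * (1.0 - np.eye(len(d2)))
        g = _gower_center(d2)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol * max(1.0, eigval.max())
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return coords, g


def _fit_r2(g: np.ndarray, x: np.ndarray) -> float:
    """trace(HGH)/trace(G) for a centered design matrix x."""
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    h = q @ q.T
    return float(np.trace(h @ g @ h) / np.trace(g))


def _adjusted(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def dbrda(
    resemblance: pd.DataFrame,
    env: pd.DataFrame,
    selection: str = "all",
    condition_tol: float = 1e8,
) -> OrdinationResult:
    """Distance-based redundancy analysis of a Bray-Curtis similarity
    matrix against environmental predictors.

    The dissimilarity matrix (100 - similarity) is embedded by principal
    coordinates (Lingoes-corrected if needed); the Gower matrix is then
    regressed on the predictors and the fitted part eigen-decomposed into
    dbRDA axes.  ``selection='forward-adjR2'`` runs step-wise forward
    selection with adjusted R^2 as the fitness measure; ``'all'`` uses every
    predictor.  Collinear predictors (condition number above
    ``condition_tol``) are rejected by name.
    """
    shared = [sid for sid in resemblance.index if sid in env.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples with environmental data")
    sim = resemblance.loc[shared, shared]
    x_all = env.loc[shared]

    cond = np.linalg.cond(np.asarray(x_all, dtype=float))
    if cond > condition_tol:
        raise ValueError(
            f"collinear environmental columns {list(x_all.columns)} "
            f"(condition number {cond:.3g})"
        )

    dissimilarity = 100.0 - np.asarray(sim, dtype=float)
    np.fill_diagonal(dissimilarity, 0.0)
    _, g = _principal_coordinates(dissimilarity)
    n = len(shared)

    variables = list(x_all.columns)
    marginal = {
        v: _fit_r2(g, np.asarray(x_all[[v]], dtype=float)) for v in variables
    }

    if selection == "forward-adjR2":
        selected: list[str] = []
        best_adj = -np.inf
        while True:
            candidates = [v for v in variables if v not in selected]
            if not candidates:
                break
            scored = []
            for v in candidates:
                r2 = _fit_r2(g, np.asarray(x_all[selected + [v]], dtype=float))
                scored.append((_adjusted(r2, n, len(selected) + 1), variables.index(v), v))
            adj, _, winner = max(scored, key=lambda t: (t[0], -t[1]))
            if adj <= best_adj:
                break
            best_adj = adj
            selected.append(winner)
        if not selected:  # nothing explains anything: keep the best single variable
            selected = [max(variables, key=lambda v: marginal[v])]
    elif selection == "all":
        selected = variables
    else:
        raise ValueError(f"unknown selection mode {selection!r}")

    x = np.asarray(x_all[selected], dtype=float)
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    h = q @ q.T
    g_fitted = h @ g @ h
    r2 = float(np.trace(g_fitted) / np.trace(g))
    eigval, eigvec = np.linalg.eigh(g_fitted)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-8 * max(1.0, abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)

    axes = [f"dbRDA{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=shared, columns=axes),
        pct_fitted=eigval / eigval.sum() * 100.0,
        pct_total=eigval / float(np.trace(g)) * 100.0,
        r_squared=r2,
        adjusted_r_squared=_adjusted(r2, n, len(selected)),
        selected=selected,
        marginal_r_squared=marginal,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def anova_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Simple linear regression with its ANOVA F test.

    Returns (slope, F, p); for one predictor F = t^2 and the p-value equals
    the two-sided slope test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for a constant predictor")
    fit = stats.linregress(x, y)
    df = len(x) - 2
    if fit.stderr == 0:
        return float(fit.slope), np.inf, 0.0
    t = fit.slope / fit.stderr
    return float(fit.slope), float(t * t), float(fit.pvalue)
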