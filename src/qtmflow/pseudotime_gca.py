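"""Cognition-ranked pseudo-time Granger causality on regional velocities.

Cross-sectional subjects are ordered from best to worst cognition (MMSE
descending, ties broken by RAVLT immediate recall, residual ties by subject
id) and the ordered regional velocity values are treated as a pseudo-time
series standing in for disease progression.  For every ordered region pair
(i -> j) a first-order bivariate model

    x_j(t) = A_ij * x_i(t-1) + B_j * x_j(t-1) + e(t),   t = 2..N

is fitted by least squares without intercept on z-scored series, so the
cross coefficients are comparable across regions when summed into driving
scores A_i = sum_{j != i} A_ij (positive and negative parts separately).
Significance is assessed by permuting the subject order and recomputing the
full analysis; empirical p-values use the add-one convention
p = (1 + #{perm >= obs}) / (n_perm + 1).

This is a lead-lag statistic on an ordered cross-section, not temporal
inference; results are tied to the ordering, whose hash is recorded.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_VELOCITY_PREFIX = "vel_"


def _hash_ordering(ids) -> str:
    return hashlib.sha256("|".join(str(i) for i in ids).encode()).hexdigest()[:16]


@dataclass
class PseudoTimeSeries:
    """Subjects x regions matrix, rows ordered best-to-worst cognition."""

    ordering: list  # subject ids, rank 1 first
    matrix: np.ndarray  # (n_subjects, n_regions), rows follow ordering
    region_names: list
    standardized: bool = False
    diagnosis: Optional[np.ndarray] = None  # per-subject labels, ordering-aligned

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.ordering), len(self.region_names)):
            raise ValueError("matrix shape does not match ordering/regions")

    @property
    def ordering_hash(self) -> str:
        return _hash_ordering(self.ordering)


def rank_subjects(
    cohort: pd.DataFrame,
    mmse_col: str = "mmse",
    recall_col: str = "ravlt_immediate",
    id_col: str = "subject_id",
) -> list:
    """Subject ids ordered best-to-worst cognition.

    Primary key: MMSE descending; ties: immediate recall descending;
    residual ties: subject id ascending (stable and deterministic).
    """
    if cohort[mmse_col].isna().any():
        raise ValueError("MMSE missing for some subjects; cannot rank")
    ordered = cohort.sort_values(
        [mmse_col, recall_col, id_col],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return ordered[id_col].tolist()


def build_pseudotime(
    cohort: pd.DataFrame,
    region_cols: Optional[Sequence[str]] = None,
    standardize: bool = True,
    id_col: str = "subject_id",
) -> PseudoTimeSeries:
    """Assemble the pseudo-time series from a cohort table.

    Region columns default to every column starting with ``vel_``; the
    region names drop that prefix.  Each region's series is z-scored
    (population SD) when ``standardize`` is set.
    """
    if region_cols is None:
        region_cols = [c for c in cohort.columns if c.startswith(DEFAULT_VELOCITY_PREFIX)]
    if len(region_cols) < 2:
        raise ValueError("need at least 2 region columns")
    ordering = rank_subjects(cohort, id_col=id_col)
    ordered = cohort.set_index(id_col).loc[ordering]
    X = ordered[list(region_cols)].to_numpy(dtype=float)
    names = [c.removeprefix(DEFAULT_VELOCITY_PREFIX) for c in region_cols]
    if standardize:
        sd = X.std(axis=0)
        degenerate = sd < 1e-12
        if degenerate.any():
            bad = [names[i] for i in np.where(degenerate)[0]]
            warnings.warn(f"constant regions left unstandardized: {bad}")
            sd = np.where(degenerate, 1.0, sd)
        X = (X - X.mean(axis=0)) / sd
    diagnosis = (
        ordered["diagnosis"].to_numpy() if "diagnosis" in ordered.columns else None
    )
    return PseudoTimeSeries(ordering, X, names, standardize, diagnosis)


# ---------------------------------------------------------------------------
# pairwise fits


def fit_pairwise_gca(series_i: np.ndarray, series_j: np.ndarray):
    """Least-squares lag-1 fit of j(t) on i(t-1) and j(t-1), no intercept.

    Returns (A_ij, B_j, residual_variance).  Raises on constant series or
    collinear regressors.
    """
    x = np.asarray(series_i, dtype=float)
    y = np.asarray(series_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series cannot be fitted")
    X = np.column_stack([x[:-1], y[:-1]])
    t = y[1:]
    G = X.T @ X
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det <= 1e-12 * G[0, 0] * G[1, 1]:
        raise ValueError("collinear regressors; coefficient undefined")
    coef = np.linalg.solve(G, X.T @ t)
    resid = t - X @ coef
    dof = max(len(t) - 2, 1)
    return float(coef[0]), float(coef[1]), float(resid @ resid / dof)


@dataclass
class GCAMatrix:
    """Pairwise lag-1 coefficients over the region set.

    A[i, j] is the cross coefficient from source region i to target region
    j (diagonal NaN); B[i, j] the target's self-lag coefficient from the
    same bivariate fit; resid_var the residual variance per pair.  Pairs
    with degenerate or collinear regressors are flagged, not fatal.
    """

    A: np.ndarray
    B: np.ndarray
    resid_var: np.ndarray
    region_names: list
    flagged: np.ndarray
    ordering_hash: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.region_names, columns=self.region_names)


def _batched_pair_coefficients(Xp: np.ndarray):
    """Closed-form bivariate lag-1 coefficients for a batch of series.

    Xp : (P, N, R) batch of subject-ordered matrices.
    Returns A, B, resid_var, valid, each (P, R, R) with source on axis 1 and
    target on axis 2 (diagonal NaN/invalid).
    """
    L = Xp[:, :-1, :]
    F = Xp[:, 1:, :]
    T = L.shape[1]
    G = np.matmul(L.transpose(0, 2, 1), L)  # G[i,k] = sum l_i l_k
    H = np.matmul(L.transpose(0, 2, 1), F)  # H[i,j] = sum l_i f_j
    Gd = np.diagonal(G, axis1=1, axis2=2)  # (P, R)
    Hd = np.diagonal(H, axis1=1, axis2=2)
    FF = np.einsum("ptj,ptj->pj", F, F)

    det = Gd[:, :, None] * Gd[:, None, :] - G**2
    valid = det > 1e-12 * np.maximum(Gd[:, :, None] * Gd[:, None, :], 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (H * Gd[:, None, :] - G * Hd[:, None, :]) / det
        B = (Gd[:, :, None] * Hd[:, None, :] - G * H) / det
        rv = (FF[:, None, :] - A * H - B * Hd[:, None, :]) / max(T - 2, 1)
    R = Xp.shape[2]
    diag = np.eye(R, dtype=bool)
    A[:, diag] = np.nan
    B[:, diag] = np.nan
    rv[:, diag] = np.nan
    valid[:, diag] = False
    A[~valid & ~diag] = np.nan
    return A, B, rv, valid


def gca_matrix(pseudo: PseudoTimeSeries) -> GCAMatrix:
    """All ordered-pair lag-1 coefficients for the pseudo-time series."""
    if len(pseudo.region_names) < 2:
        raise ValueError("need at least 2 regions")
    A, B, rv, valid = _batched_pair_coefficients(pseudo.matrix[None])
    R = len(pseudo.region_names)
    flagged = ~valid[0] & ~np.eye(R, dtype=bool)
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} region pairs flagged as degenerate")
    return GCAMatrix(A[0], B[0], rv[0], list(pseudo.region_names), flagged, pseudo.ordering_hash)


# ---------------------------------------------------------------------------
# driving scores and permutation significance


@dataclass
class DrivingScores:
    """Per-region outgoing-coefficient sums (total, positive, negative)."""

    table: pd.DataFrame  # region, total, positive, negative [, p_pos, p_neg]
    region_set: list
    ordering_hash: str = ""


def _scores_from_A(A: np.ndarray, idx: np.ndarray):
    """Row sums of A restricted to the region subset ``idx``.

    Returns (total, positive, negative), each of length len(idx), with NaN
    cross terms ignored.
    """
    sub = A[np.ix_(idx, idx)]
    pos = np.nansum(np.clip(sub, 0, None), axis=1)
    neg = np.nansum(np.clip(sub, None, 0), axis=1)
    return pos + neg, pos, neg


def driving_scores(gca: GCAMatrix, regions: Optional[Sequence[str]] = None) -> DrivingScores:
    """Driving scores A_i = sum_{j != i} A_ij over the selected region set,
    with positive and negative parts summed separately."""
    names = gca.region_names
    region_set = list(names) if regions is None else list(regions)
    idx = np.asarray([names.index(r) for r in region_set])
    total, pos, neg = _scores_from_A(gca.A, idx)
    return DrivingScores(
        pd.DataFrame(
            {"region": region_set, "total": total, "positive": pos, "negative": neg}
        ),
        region_set,
        gca.ordering_hash,
    )


@dataclass
class PermutationResult:
    observed: GCAMatrix
    scores: DrivingScores  # table includes p_pos / p_neg
    coefficient_p: np.ndarray  # (R, R) two-sided, NaN diagonal
    n_perm: int
    seed: int
    alpha: float
    ordering_hash: str

    def significant_positive(self) -> list:
        t = self.scores.table
        return t.loc[t["p_pos"] < self.alpha, "region"].tolist()

    def significant_negative(self) -> list:
        t = self.scores.table
        return t.loc[t["p_neg"] < self.alpha, "region"].tolist()


def permutation_significance(
    pseudo: PseudoTimeSeries,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    regions: Optional[Sequence[str]] = None,
) -> PermutationResult:
    """Permutation test of GCA coefficients and driving scores.

    Each permutation shuffles the subject order and recomputes the full
    pairwise analysis.  Positive scores are tested against the upper tail
    of their permutation distribution, negative scores against the lower
    tail, and individual coefficients two-sided; all p-values use the
    add-one convention and are therefore in [1/(n_perm+1), 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = pseudo.matrix
    n, R = X.shape
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [pseudo.region_names[i] for i in np.where(~keep)[0]]
        warnings.warn(f"excluding constant regions from permutation test: {dropped}")
        pseudo = PseudoTimeSeries(
            pseudo.ordering,
            X[:, keep],
            [n for n, k in zip(pseudo.region_names, keep) if k],
            pseudo.standardized,
            pseudo.diagnosis,
        )
        X = pseudo.matrix
        R = X.shape[1]

    obs = gca_matrix(pseudo)
    names = obs.region_names
    region_set = list(names) if regions is None else list(regions)
    idx = np.asarray([names.index(r) for r in region_set])
    _, obs_pos, obs_neg = _scores_from_A(obs.A, idx)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Xp = X[perms]  # (P, N, R)
    A_perm, _, _, _ = _batched_pair_coefficients(Xp)

    with np.errstate(invalid="ignore"):
        _, perm_pos, perm_neg = (
            None,
            np.nansum(np.clip(A_perm[:, idx][:, :, idx], 0, None), axis=2),
            np.nansum(np.clip(A_perm[:, idx][:, :, idx], None, 0), axis=2),
        )
        p_pos = (1.0 + np.sum(perm_pos >= obs_pos[None, :], axis=0)) / (n_perm + 1)
        p_neg = (1.0 + np.sum(perm_neg <= obs_neg[None, :], axis=0)) / (n_perm + 1)
        coef_p = (
            1.0 + np.nansum(np.abs(A_perm) >= np.abs(obs.A)[None], axis=0)
        ) / (n_perm + 1)
    coef_p[np.eye(R, dtype=bool)] = np.nan
    coef_p[np.isnan(obs.A)] = np.nan

    table = pd.DataFrame(
        {
            "region": region_set,
            "total": obs_pos + obs_neg,
            "positive": obs_pos,
            "negative": obs_neg,
            "p_pos": p_pos,
            "p_neg": p_neg,
        }
    )
    scores = DrivingScores(table, region_set, pseudo.ordering_hash)
    return PermutationResult(
        obs, scores, coef_p, n_perm, seed, alpha, pseudo.ordering_hash
    )
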