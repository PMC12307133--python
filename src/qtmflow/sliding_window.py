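"""Sliding-window GCA: driver-to-region coefficients along the ordering.

Overlapping stride-1 windows of ``window_length`` subjects are slid along
the cognition ranking; within each window the lag-1 coefficients from each
driving region to every other region are re-estimated (series re-z-scored
within the window) and tested by within-window order permutations, so the
appearance of lead-lag effects can be localized to a disease stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pseudotime_gca import PseudoTimeSeries, _batched_pair_coefficients


def enumerate_windows(n_subjects: int, window_length: int) -> list:
    """Stride-1 contiguous windows as 1-based inclusive (start, end) pairs."""
    if window_length < 10:
        raise ValueError("window_length must be >= 10")
    if window_length > n_subjects:
        raise ValueError(
            f"window_length {window_length} exceeds cohort size {n_subjects}"
        )
    return [(s + 1, s + window_length) for s in range(n_subjects - window_length + 1)]


@dataclass
class SlidingWindowResult:
    window_starts: np.ndarray  # 1-based
    drivers: list
    region_names: list
    coefficients: np.ndarray  # (n_windows, n_drivers, n_regions), NaN at driver
    p_values: np.ndarray  # same shape, two-sided permutation p
    significant: np.ndarray  # p < alpha
    group_counts: Optional[pd.DataFrame]  # per-window diagnostic composition
    window_length: int
    n_perm: int
    seed: int
    alpha: float
    ordering_hash: str

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: window_start, driver, target, coefficient, p, significant."""
        rows = []
        for w, start in enumerate(self.window_starts):
            for d, drv in enumerate(self.drivers):
                for r, tgt in enumerate(self.region_names):
                    if tgt == drv:
                        continue
                    rows.append(
                        (
                            int(start),
                            drv,
                            tgt,
                            self.coefficients[w, d, r],
                            self.p_values[w, d, r],
                            bool(self.significant[w, d, r]),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["window_start", "driver", "target", "coefficient", "p", "significant"],
        )


def sliding_gca(
    pseudo: PseudoTimeSeries,
    drivers: Sequence[str],
    window_length: int = 50,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SlidingWindowResult:
    """Driver-to-region coefficients and permutation p in each window.

    Permutations shuffle the subjects within the window only; each window
    draws from its own seeded stream (spawned from ``seed``), so individual
    windows are reproducible in isolation.  A region that is constant
    within some window is flagged NaN for that window only.
    """
    names = list(pseudo.region_names)
    missing = [d for d in drivers if d not in names]
    if missing:
        raise ValueError(f"drivers not among regions: {missing}")
    X = pseudo.matrix
    n, R = X.shape
    windows = enumerate_windows(n, window_length)
    d_idx = np.asarray([names.index(d) for d in drivers])
    W = len(windows)

    coef = np.full((W, len(drivers), R), np.nan)
    pval = np.full((W, len(drivers), R), np.nan)
    child_seeds = np.random.SeedSequence(seed).spawn(W)
    degenerate_windows = 0

    for w, (start, end) in enumerate(windows):
        sub = X[start - 1 : end]
        sd = sub.std(axis=0)
        ok = sd > 1e-12
        if not ok.all():
            degenerate_windows += 1
        mu = sub.mean(axis=0)
        Z = (sub - mu) / np.where(ok, sd, 1.0)

        A_obs, _, _, _ = _batched_pair_coefficients(Z[None])
        obs = A_obs[0][d_idx, :]  # (n_drivers, R)

        rng = np.random.default_rng(child_seeds[w])
        perms = np.stack([rng.permutation(window_length) for _ in range(n_perm)])
        A_perm, _, _, _ = _batched_pair_coefficients(Z[perms])
        perm_d = A_perm[:, d_idx, :]  # (P, n_drivers, R)
        with np.errstate(invalid="ignore"):
            p = (1.0 + np.nansum(np.abs(perm_d) >= np.abs(obs)[None], axis=0)) / (
                n_perm + 1
            )
        obs[:, ~ok] = np.nan
        p[np.isnan(obs)] = np.nan
        coef[w] = obs
        pval[w] = p

    if degenerate_windows:
        warnings.warn(
            f"{degenerate_windows} windows contained constant regions (flagged NaN)"
        )

    group_counts = None
    if pseudo.diagnosis is not None:
        labels = pd.unique(pseudo.diagnosis)
        counts = {
            lab: [
                int(np.sum(pseudo.diagnosis[s - 1 : e] == lab)) for s, e in windows
            ]
            for lab in labels
        }
        group_counts = pd.DataFrame(
            counts, index=pd.Index([s for s, _ in windows], name="window_start")
        )

    with np.errstate(invalid="ignore"):
        significant = pval < alpha
    return SlidingWindowResult(
        np.asarray([s for s, _ in windows]),
        list(drivers),
        names,
        coef,
        pval,
        significant,
        group_counts,
        window_length,
        n_perm,
        seed,
        alpha,
        pseudo.ordering_hash,
    )
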