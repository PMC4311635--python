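"""Non-negative matrix factorization of trial rate matrices with VAF rank selection.

Each trial's rate matrix ``X`` (m neurons x n samples) is decomposed as
``X ~ W H`` with ``W`` (m x r) a non-negative basis and ``H`` (r x n) the
non-negative component time courses, by multiplicative updates minimizing
the Frobenius residual. The factorization rank is the smallest ``r`` whose
variance accounted for,

    VAF = 1 - ||X - WH||_F^2 / ||X||_F^2,

exceeds a threshold (default 0.9), subject to the admissibility bound
``r < mn/(m+n)``. Within an animal the per-trial ranks are harmonized to
their maximum and every trial is refit at that common rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["NMFResult", "RankSelection", "factorize", "vaf", "select_rank", "harmonize_rank"]

_EPS = 1e-12


@dataclass
class NMFResult:
    """One trial's factorization: basis W (m x r), encoding H (r x n)."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    vaf: float
    n_iter: int
    objective: float  # final Frobenius residual ||X - WH||_F
    objective_history: np.ndarray = field(repr=False, default=None)


@dataclass
class RankSelection:
    """Per-trial ranks, the harmonized animal rank, and recomputed VAFs."""

    per_trial_rank: dict
    animal_rank: int
    per_trial_vaf_at_animal_rank: dict
    results: dict = field(repr=False, default=None)  # trial_id -> NMFResult at animal_rank


def vaf(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for: 1 - sum(e^2)/sum(X^2), e = X - WH."""
    X = np.asarray(X, dtype=float)
    denom = float(np.sum(X * X))
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero matrix")
    e = X - W @ H
    return 1.0 - float(np.sum(e * e)) / denom


def _mu_run(
    X: np.ndarray, r: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative-update run from a random non-negative start."""
    m, n = X.shape
    scale = np.sqrt(X.mean() / r)
    W = scale * rng.uniform(size=(m, r))
    H = scale * rng.uniform(size=(r, n))
    history = np.empty(max_iter + 1)
    history[0] = np.linalg.norm(X - W @ H)
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        history[it] = np.linalg.norm(X - W @ H)
        prev = history[it - 1]
        if prev > 0 and (prev - history[it]) / prev < tol:
            return W, H, history[: it + 1]
    return W, H, history


def factorize(
    X: np.ndarray,
    r: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NMFResult:
    """Best-of-restarts multiplicative-update NMF at fixed rank.

    Initialization is uniform random scaled by sqrt(mean(X)/r); update
    denominators are floored at 1e-12 so silent neurons or components never
    divide by zero. Each restart stops when the relative objective change
    drops below ``tol`` or after ``max_iter`` iterations; the restart with
    the smallest final residual wins.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not np.any(X):
        raise ValueError("cannot factorize an all-zero matrix")
    m, _ = X.shape
    if not (1 <= r <= m):
        raise ValueError(f"rank must lie in [1, {m}]")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        W, H, history = _mu_run(X, r, rng, max_iter, tol)
        if best is None or history[-1] < best[2][-1]:
            best = (W, H, history)
    W, H, history = best
    return NMFResult(
        W=W,
        H=H,
        rank=r,
        vaf=vaf(X, W, H),
        n_iter=len(history) - 1,
        objective=float(history[-1]),
        objective_history=history,
    )


def max_admissible_rank(m: int, n: int) -> int:
    """Largest integer rank satisfying r < mn/(m+n)."""
    bound = m * n / (m + n)
    r = int(np.floor(bound))
    if r == bound:  # strict inequality
        r -= 1
    return max(r, 1)


def select_rank(
    X: np.ndarray,
    threshold: float = 0.9,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
) -> int:
    """Smallest rank whose VAF exceeds ``threshold``.

    Ranks are tried in increasing order from 1 to m. If the first rank
    clearing the threshold violates the admissibility bound r < mn/(m+n),
    the largest admissible rank is returned with a warning (the bound wins).
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    r_adm = max_admissible_rank(m, n)
    for r in range(1, m + 1):
        res = factorize(X, r, seed=seed, n_restarts=n_restarts, max_iter=max_iter)
        if res.vaf > threshold:
            if r > r_adm:
                logger.warning(
                    "rank %d clears VAF %.2f but violates r < mn/(m+n)=%.2f; "
                    "returning admissible rank %d", r, threshold, m * n / (m + n), r_adm,
                )
                return r_adm
            return r
    logger.warning("no rank up to m=%d cleared VAF %.2f; returning %d", m, threshold, r_adm)
    return r_adm


def harmonize_rank(
    trials: list[tuple],
    threshold: float = 0.9,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
) -> RankSelection:
    """Common per-animal rank: maximum of per-trial selected ranks.

    Every trial is refit at the harmonized rank and its recomputed VAF is
    stored; by maximality each recomputed VAF should clear the threshold
    (verified, with a warning if a refit falls short).
    """
    if not trials:
        raise ValueError("need at least one trial")
    per_rank: dict = {}
    for trial_id, X in trials:
        per_rank[trial_id] = select_rank(
            X, threshold=threshold, seed=seed, n_restarts=n_restarts, max_iter=max_iter
        )
    animal_rank = max(per_rank.values())
    per_vaf: dict = {}
    results: dict = {}
    for trial_id, X in trials:
        res = factorize(X, animal_rank, seed=seed, n_restarts=n_restarts, max_iter=max_iter)
        per_vaf[trial_id] = res.vaf
        results[trial_id] = res
        if res.vaf < threshold:
            logger.warning(
                "trial %s: VAF %.3f at harmonized rank %d fell below %.2f",
                trial_id, res.vaf, animal_rank, threshold,
            )
    return RankSelection(per_rank, animal_rank, per_vaf, results)
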