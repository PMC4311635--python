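"""Sliding-window conditional Granger causality networks.

Within each moving window, the multivariate series (neuron rates or NMF
component time courses) is fit by a VAR(p) model whose order is selected
by BIC. The conditional Granger causality from node j to node i is

    F[i, j] = ln( rho_ii / Sigma_ii ),

where Sigma_ii is x_i's residual variance in the unrestricted model and
rho_ii its residual variance in the restricted model that omits x_j from
both the predictor and the predicted set. Each ordered pair is tested
with a nested-regression F-test on the target equation's residual sum of
squares; p-values are Benjamini-Hochberg corrected across all N(N-1)
pairs within the window, and non-significant connections are set to zero.

Rows are mean-centered per window before fitting (a constant-term
equivalent). Windows whose regression would be badly under-determined
fall back to a lightly ridge-regularized fit, and degenerate windows
(zero-variance rows, non-positive degrees of freedom) are flagged and
skipped rather than crashed on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "VARModel",
    "GCNetwork",
    "select_order",
    "fit_var",
    "conditional_gc",
    "significance_filter",
    "window_networks",
]


@dataclass
class VARModel:
    """Per-equation OLS fit of a VAR(p)."""

    order: int
    coeffs: np.ndarray  # (p, N, N): coeffs[k][i, j] = weight of x_j(t-k-1) in eq. i
    residuals: np.ndarray = field(repr=False)  # (T-p, N)
    resid_cov: np.ndarray = field(repr=False)  # (N, N), 1/(T-p) normalization
    rss: np.ndarray = field(repr=False)  # (N,) residual sum of squares per equation
    t_eff: int = 0
    ridge_used: bool = False


@dataclass
class GCNetwork:
    """Directed connectivity for one window: F[i, j] = causality j -> i."""

    node_ids: list
    F: np.ndarray
    pvalues: np.ndarray | None
    sig_mask: np.ndarray | None
    window_center: float
    space_tag: str  # "original" | "nmf"
    order: int = 1
    t_eff: int = 0
    rss_full: np.ndarray | None = field(default=None, repr=False)
    rss_restricted: np.ndarray | None = field(default=None, repr=False)
    valid: np.ndarray | None = field(default=None, repr=False)  # pairwise validity
    usable: bool = True
    floored: int = 0  # count of negative F estimates floored at 0
    ridge_used: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def _lag_design(series: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Targets Y (T-p, N) and lagged predictors Z (T-p, N*p)."""
    x = np.asarray(series, dtype=float)
    n_vars, T = x.shape
    Y = x[:, p:].T
    Z = np.empty((T - p, n_vars * p))
    for k in range(p):
        Z[:, k * n_vars:(k + 1) * n_vars] = x[:, p - k - 1:T - k - 1].T
    return Y, Z


def fit_var(
    series: np.ndarray,
    p: int,
    omit: int | None = None,
    ridge: bool = False,
    center: bool = True,
) -> VARModel:
    """OLS VAR(p) fit; with ``omit`` the j-th variable is dropped entirely.

    A singular (or deliberately ridge-flagged) regressor matrix falls back
    to ridge with lambda = 1e-8 * trace(Z'Z), logged once per fit.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be (n_vars, n_samples)")
    if omit is not None:
        x = np.delete(x, omit, axis=0)
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    n_vars, T = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if T - p < n_vars * p + 1:
        raise ValueError(
            f"insufficient samples: T={T} gives {T - p} rows for {n_vars * p} regressors"
        )
    Y, Z = _lag_design(x, p)
    ridge_used = False
    if ridge:
        gram = Z.T @ Z
        lam = 1e-8 * np.trace(gram)
        B = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), Z.T @ Y)
        ridge_used = True
    else:
        B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
        if rank < Z.shape[1]:
            gram = Z.T @ Z
            lam = 1e-8 * max(np.trace(gram), 1e-30)
            B = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), Z.T @ Y)
            ridge_used = True
            logger.debug("singular regressor matrix: ridge fallback engaged")
    E = Y - Z @ B
    t_eff = T - p
    resid_cov = E.T @ E / t_eff
    coeffs = np.stack([B[k * n_vars:(k + 1) * n_vars].T for k in range(p)])
    return VARModel(p, coeffs, E, resid_cov, np.sum(E * E, axis=0), t_eff, ridge_used)


def select_order(series: np.ndarray, p_max: int = 3, center: bool = True) -> int:
    """BIC order selection over 1..p_max.

    BIC(p) = ln det(Sigma_hat) + N^2 p ln(T_eff) / T_eff with T_eff = T - p.
    Orders whose regression is infeasible for this window are not candidates;
    if none is feasible the minimum sample requirement is reported.
    """
    x = np.asarray(series, dtype=float)
    n_vars, T = x.shape
    feasible = [p for p in range(1, p_max + 1) if T - p >= n_vars * p + 1]
    if not feasible:
        raise ValueError(
            f"no feasible VAR order: need T >= {n_vars + 2} samples for p=1, got {T}"
        )
    best_p, best_bic = feasible[0], np.inf
    for p in feasible:
        model = fit_var(x, p, center=center)
        sign, logdet = np.linalg.slogdet(model.resid_cov)
        if sign <= 0:
            continue
        k = n_vars * n_vars * p
        bic = logdet + k * np.log(model.t_eff) / model.t_eff
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def conditional_gc(
    series: np.ndarray,
    p: int | None = None,
    p_max: int = 3,
    node_ids: list | None = None,
    window_center: float = 0.0,
    space_tag: str = "original",
) -> GCNetwork:
    """Conditional Granger causality matrix for one stationary window.

    For every ordered pair (i, j), i != j, fits the unrestricted VAR on all
    N variables and the restricted VAR omitting x_j, and reports
    F[i, j] = ln(rho_ii / Sigma_ii), floored at 0. RSS bookkeeping for the
    nested F-tests is retained for :func:`significance_filter`.
    """
    x = np.asarray(series, dtype=float)
    n_vars, T = x.shape
    if n_vars < 2:
        raise ValueError("need at least two variables")
    x = x - x.mean(axis=1, keepdims=True)
    if p is None:
        p = select_order(x, p_max=p_max, center=False)
    # under-determination guard: lean on ridge when regressors crowd the window
    ridge = n_vars * p + 1 > T / 2
    if ridge:
        logger.debug("window near-underdetermined (N*p+1=%d > T/2=%.0f): ridge fits",
                     n_vars * p + 1, T / 2)
    full = fit_var(x, p, ridge=ridge, center=False)
    F = np.zeros((n_vars, n_vars))
    valid = ~np.eye(n_vars, dtype=bool)
    rss_restricted = np.full((n_vars, n_vars), np.nan)
    floored = 0
    for j in range(n_vars):
        restricted = fit_var(x, p, omit=j, ridge=ridge, center=False)
        keep = [i for i in range(n_vars) if i != j]
        for row, i in enumerate(keep):
            sigma_ii = full.resid_cov[i, i]
            rho_ii = restricted.resid_cov[row, row]
            if sigma_ii <= 0 or rho_ii <= 0:
                valid[i, j] = False
                logger.warning("pair (%d <- %d): non-positive residual variance", i, j)
                continue
            val = np.log(rho_ii / sigma_ii)
            if val < 0:
                floored += 1
                val = 0.0
            F[i, j] = val
            rss_restricted[i, j] = restricted.rss[row]
    return GCNetwork(
        node_ids=list(node_ids) if node_ids is not None else list(range(n_vars)),
        F=F,
        pvalues=None,
        sig_mask=None,
        window_center=window_center,
        space_tag=space_tag,
        order=p,
        t_eff=full.t_eff,
        rss_full=full.rss,
        rss_restricted=rss_restricted,
        valid=valid,
        floored=floored,
        ridge_used=full.ridge_used,
    )


def significance_filter(net: GCNetwork, alpha: float = 0.05) -> GCNetwork:
    """F-test every ordered pair, BH-correct within the window, zero the rest.

    F-statistic: ((RSS_r - RSS_u)/p) / (RSS_u/(T_eff - N*p - 1)) with
    df = (p, T_eff - N*p - 1). Invalid pairs keep p-value NaN and are never
    significant. A window with non-positive df is marked unusable.
    """
    if net.rss_full is None or net.rss_restricted is None:
        raise ValueError("network lacks RSS bookkeeping; run conditional_gc first")
    n = net.n_nodes
    p = net.order
    df2 = net.t_eff - n * p - 1
    if df2 <= 0:
        logger.warning("window at %.3f s: non-positive df (%d); marked unusable",
                       net.window_center, df2)
        return replace(net, usable=False, sig_mask=np.zeros((n, n), bool),
                       pvalues=np.full((n, n), np.nan), F=np.zeros((n, n)))
    pvals = np.full((n, n), np.nan)
    offdiag = ~np.eye(n, dtype=bool)
    test_mask = offdiag & net.valid
    rss_u = np.broadcast_to(net.rss_full[:, None], (n, n))
    with np.errstate(invalid="ignore"):
        fstat = ((net.rss_restricted - rss_u) / p) / (rss_u / df2)
    fstat = np.where(fstat > 0, fstat, 0.0)
    pvals[test_mask] = stats.f.sf(fstat[test_mask], p, df2)
    sig = np.zeros((n, n), dtype=bool)
    flat = pvals[test_mask]
    if flat.size:
        reject, _, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
        sig[test_mask] = reject
    F = np.where(sig, net.F, 0.0)
    return replace(net, F=F, pvalues=pvals, sig_mask=sig)


def window_networks(
    windows: list[tuple[float, np.ndarray]],
    space_tag: str = "original",
    p: int | None = None,
    p_max: int = 3,
    alpha: float = 0.05,
    node_ids: list | None = None,
) -> list[GCNetwork]:
    """One pruned GCNetwork per sliding window; degenerate windows are skipped.

    A window is skipped (not crashed on) when a row has (near-)zero variance
    or the regression is infeasible. If more than half the windows of a trial
    are skipped the caller should treat the trial as unanalyzable; the
    returned list simply omits skipped windows.
    """
    nets = []
    n_skipped = 0
    for center, segment in windows:
        row_var = segment.var(axis=1)
        if np.any(row_var < 1e-14):
            logger.warning("window at %.3f s: zero-variance row, skipped", center)
            n_skipped += 1
            continue
        try:
            net = conditional_gc(
                segment, p=p, p_max=p_max, node_ids=node_ids,
                window_center=center, space_tag=space_tag,
            )
            net = significance_filter(net, alpha=alpha)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("window at %.3f s: %s; skipped", center, exc)
            n_skipped += 1
            continue
        if not net.usable:
            n_skipped += 1
            continue
        nets.append(net)
    if windows and n_skipped > len(windows) / 2:
        logger.warning("trial unanalyzable: %d of %d windows skipped", n_skipped, len(windows))
    return nets
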