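"""Sparse canonical correlation analysis via penalized matrix decomposition.

Finds paired sparse weight vectors (u, v) maximizing u^T X^T Y v subject
to unit L2 norms and L1 budgets ||u||_1 <= c_x, ||v||_1 <= c_y, where X
and Y are column-standardized matrices over shared samples. The rank-1
problem is solved by alternating soft-thresholded power iteration
(penalized matrix decomposition, which realizes sparse CCA under the
identity within-set covariance approximation); further components come
from deflating the cross-product matrix. Penalties are parameterized as
a fraction f in (0, 1] with c = f * sqrt(p), one shared value for both
sides; f = 1 removes the constraint and reduces the fit to the truncated
SVD of the cross-product.

The surrounding machinery: an equally spaced penalty grid tuned by
leave-one-out cross-validated correlation, permutation significance with
Benjamini-Hochberg adjustment across components, and LOOCV extraction of
features whose weights are stably nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, ValidationError
from .differential import bh_adjust

log = logging.getLogger("mbcca")


def soft_threshold(w, delta: float) -> np.ndarray:
    """Soft-thresholding operator sign(w) * max(|w| - delta, 0)."""
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    w = np.asarray(w, dtype=float)
    return np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)


def l1_project(w, c: float, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """L2-normalized soft-thresholding with L1 norm at most c.

    Finds the smallest delta >= 0 such that
    ``S(w, delta) / ||S(w, delta)||_2`` has L1 norm <= c (bisection on
    delta; the L1 norm of the normalized vector is non-increasing in
    delta). Requires 1 <= c <= sqrt(len(w)); c = sqrt(p) deactivates the
    constraint (Cauchy-Schwarz), c = 1 selects the single
    largest-magnitude coordinate (ties broken by lowest index).
    """
    w = np.asarray(w, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValidationError("cannot project the zero vector")
    if not 1.0 <= c <= np.sqrt(len(w)) + 1e-9:
        raise ValidationError(
            f"c must lie in [1, sqrt(p)] = [1, {np.sqrt(len(w)):.4f}], got {c}"
        )
    u = w / norm
    if np.abs(u).sum() <= c + 1e-12:
        return u
    if c <= 1.0 + 1e-12:
        out = np.zeros_like(w)
        j = int(np.argmax(np.abs(w)))  # argmax takes the lowest tied index
        out[j] = np.sign(w[j]) if w[j] != 0 else 1.0
        return out
    lo, hi = 0.0, float(np.abs(w).max())
    feasible = None  # smallest delta seen whose normalized L1 <= c
    for _ in range(max_iter):
        delta = (lo + hi) / 2.0
        s = soft_threshold(w, delta)
        sn = np.linalg.norm(s)
        if sn > 0 and np.abs(s / sn).sum() <= c:
            hi = delta
            feasible = delta
        else:
            lo = delta
        if hi - lo < tol * max(1.0, np.abs(w).max()):
            break
    if feasible is None:
        # tied maxima can leave no feasible delta; the limit solution is
        # the single largest-magnitude coordinate (lowest index on ties)
        out = np.zeros_like(w)
        j = int(np.argmax(np.abs(w)))
        out[j] = np.sign(w[j])
        return out
    s = soft_threshold(w, feasible)
    return s / np.linalg.norm(s)


def pmd_rank1(
    Z: np.ndarray,
    c_x: float,
    c_y: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Rank-1 penalized matrix decomposition of a cross-product matrix.

    Alternates ``u <- l1_project(Z v, c_x)`` and
    ``v <- l1_project(Z^T u, c_y)`` from the leading right singular
    vector of Z until the largest iterate change drops below ``tol``.
    Returns ``(u, v, d, converged)`` with d = u^T Z v >= 0 and the sign
    fixed so the largest-|.| entry of u is positive.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValidationError("cross-product matrix must be finite")
    if not Z.any():
        raise ValidationError("cross-product matrix is zero")
    # initialization: leading right singular vector
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    u = np.zeros(Z.shape[0])
    converged = False
    for _ in range(max_iter):
        u_new = l1_project(Z @ v, c_x)
        v_new = l1_project(Z.T @ u_new, c_y)
        change = max(
            np.abs(u_new - u).max(initial=0.0),
            np.abs(v_new - v).max(initial=0.0),
        )
        u, v = u_new, v_new
        if change < tol:
            converged = True
            break
    if not converged:
        log.warning("pmd_rank1 did not converge in %d iterations", max_iter)
    d = float(u @ Z @ v)
    if d < 0:
        v = -v
        d = -d
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        u, v = -u, -v
    return u, v, d, converged


def penalty_grid(lo: float = 0.02, hi: float = 0.5, n: int = 20) -> np.ndarray:
    """n equally spaced penalty fractions spanning [lo, hi] inclusively."""
    if n < 2:
        raise ValidationError("penalty grid needs n >= 2")
    if not 0 < lo < hi <= 1:
        raise ValidationError(
            f"penalty grid needs 0 < lo < hi <= 1, got [{lo}, {hi}]"
        )
    return np.linspace(lo, hi, n)


@dataclass
class SccaComponent:
    """One canonical component: sparse weights and their statistics."""

    u: pd.Series  # host-side weights, unit L2, indexed by X features
    v: pd.Series  # microbe-side weights, indexed by Y features
    canonical_correlation: float
    d: float  # u^T Z v, the penalized singular value
    converged: bool = True
    raw_p: float | None = None
    adjusted_p: float | None = None
    robust_x: list[str] | None = None
    robust_y: list[str] | None = None

    @property
    def selected_x(self) -> list[str]:
        return self.u.index[self.u != 0].tolist()

    @property
    def selected_y(self) -> list[str]:
        return self.v.index[self.v != 0].tolist()


@dataclass
class SccaResult:
    """Full sparse-CCA fit: ordered components plus tuning provenance."""

    components: list[SccaComponent]
    penalty_x: float
    penalty_y: float
    tuning_table: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def correlations(self) -> np.ndarray:
        return np.array([c.canonical_correlation for c in self.components])

    def significant(self, alpha: float = 0.05) -> list[int]:
        return [
            i for i, c in enumerate(self.components)
            if c.adjusted_p is not None and c.adjusted_p < alpha
        ]

    def weights_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.components):
            for side, w in (("x", c.u), ("y", c.v)):
                nz = w[w != 0]
                for fid, weight in nz.items():
                    rows.append((i + 1, side, fid, weight))
        return pd.DataFrame(
            rows, columns=["component", "side", "feature_id", "weight"]
        )


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (standardized matrix, keep mask)."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    return (M[:, keep] - mu[keep]) / sd[keep], keep


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fit_core(
    Xs: np.ndarray,
    Ys: np.ndarray,
    K: int,
    c_x: float,
    c_y: float,
    tol: float,
    max_iter: int,
) -> list[tuple[np.ndarray, np.ndarray, float, float, bool]]:
    """PMD with deflation on standardized matrices.

    Returns per-component (u, v, d, canonical correlation, converged).
    """
    Z = Xs.T @ Ys
    out = []
    for _ in range(K):
        if not Z.any():
            break
        u, v, d, conv = pmd_rank1(Z, c_x, c_y, tol=tol, max_iter=max_iter)
        rho = _corr(Xs @ u, Ys @ v)
        out.append((u, v, d, rho, conv))
        Z = Z - d * np.outer(u, v)
    return out


def _tables_to_arrays(
    X: FeatureTable | pd.DataFrame | np.ndarray,
    Y: FeatureTable | pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    def unpack(M):
        if isinstance(M, FeatureTable):
            return M.values, M.feature_ids, M.sample_ids
        if isinstance(M, pd.DataFrame):
            return M.to_numpy(float), list(M.columns), list(M.index)
        M = np.asarray(M, dtype=float)
        return M, [f"f{j}" for j in range(M.shape[1])], None

    xv, xf, xs = unpack(X)
    yv, yf, ys = unpack(Y)
    if xv.shape[0] != yv.shape[0]:
        raise ValidationError("X and Y must share the sample dimension")
    if xs is not None and ys is not None and xs != ys:
        raise ValidationError("X and Y sample ids must match in order")
    return xv, yv, xf, yf


def scca_fit(
    X,
    Y,
    K: int,
    penalty_x: float,
    penalty_y: float | None = None,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> SccaResult:
    """Fit K sparse canonical components between X and Y.

    Columns are standardized (zero-variance columns dropped with a
    warning); the L1 budgets are ``penalty * sqrt(p)`` per side; each
    component's canonical correlation is the Pearson correlation of the
    projected scores. Components are extracted sequentially with
    deflation of the cross-product matrix.
    """
    if penalty_y is None:
        penalty_y = penalty_x
    for f in (penalty_x, penalty_y):
        if not 0 < f <= 1:
            raise ValidationError(f"penalty fraction must be in (0,1], got {f}")
    xv, yv, xf, yf = _tables_to_arrays(X, Y)
    Xs, keep_x = _standardize(xv)
    Ys, keep_y = _standardize(yv)
    if not keep_x.all() or not keep_y.all():
        log.warning(
            "dropped %d zero-variance columns before sCCA",
            int((~keep_x).sum() + (~keep_y).sum()),
        )
    xf = [f for f, k in zip(xf, keep_x) if k]
    yf = [f for f, k in zip(yf, keep_y) if k]
    if K < 1 or K > min(len(xf), len(yf)):
        raise ValidationError(
            f"K must be in [1, {min(len(xf), len(yf))}], got {K}"
        )
    c_x = max(1.0, penalty_x * np.sqrt(len(xf)))
    c_y = max(1.0, penalty_y * np.sqrt(len(yf)))
    comps = []
    for u, v, d, rho, conv in _fit_core(Xs, Ys, K, c_x, c_y, tol, max_iter):
        comps.append(
            SccaComponent(
                pd.Series(u, index=xf), pd.Series(v, index=yf), rho, d, conv
            )
        )
    return SccaResult(comps, penalty_x, penalty_y)


def _match_components(
    ref: list[np.ndarray], est: list[np.ndarray]
) -> list[tuple[int, float]]:
    """Greedy match of estimated to reference weight vectors by |cosine|.

    Returns, per reference component, (estimated index, signed cosine).
    """
    remaining = set(range(len(est)))
    out = []
    for r in ref:
        best_j, best_cos = -1, 0.0
        for j in remaining:
            denom = np.linalg.norm(r) * np.linalg.norm(est[j])
            cos = float(r @ est[j] / denom) if denom > 0 else 0.0
            if abs(cos) > abs(best_cos):
                best_j, best_cos = j, cos
        if best_j >= 0:
            remaining.discard(best_j)
        out.append((best_j, best_cos))
    return out


def tune_penalty(
    X,
    Y,
    K: int,
    grid=None,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[float, pd.DataFrame]:
    """Select the penalty fraction by leave-one-out cross-validation.

    For each grid value (shared by both sides), each sample is held out
    in turn, the model is refit on the rest, and the held-out projections
    are collected; the score is the mean over components of the Pearson
    correlation between held-out X and Y scores. Returns the argmax
    (ties broken toward the smallest penalty) and the full tuning table.
    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    if grid is None:
        grid = penalty_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty penalty grid")
    xv, yv, _, _ = _tables_to_arrays(X, Y)
    n = xv.shape[0]
    if n < 4:
        raise ValidationError("tuning needs at least 4 samples")
    Xs_full, keepx_full = _standardize(xv)
    Ys_full, keepy_full = _standardize(yv)
    p_x, p_y = xv.shape[1], yv.shape[1]
    rows = []
    for f in grid:
        # reference fit on all samples, for component matching/sign alignment
        cxf = max(1.0, f * np.sqrt(keepx_full.sum()))
        cyf = max(1.0, f * np.sqrt(keepy_full.sum()))
        full_fit = _fit_core(Xs_full, Ys_full, K, cxf, cyf, tol, max_iter)
        ref_u = []
        for u, *_rest in full_fit:
            r = np.zeros(p_x)
            r[keepx_full] = u
            ref_u.append(r)
        k_eff = len(ref_u)
        scores_x = np.zeros((n, k_eff))
        scores_y = np.zeros((n, k_eff))
        for i in range(n):
            mask = np.arange(n) != i
            Xi, keep_x = _standardize(xv[mask])
            Yi, keep_y = _standardize(yv[mask])
            mu_x = xv[mask][:, keep_x].mean(axis=0)
            sd_x = xv[mask][:, keep_x].std(axis=0, ddof=1)
            mu_y = yv[mask][:, keep_y].mean(axis=0)
            sd_y = yv[mask][:, keep_y].std(axis=0, ddof=1)
            c_x = max(1.0, f * np.sqrt(keep_x.sum()))
            c_y = max(1.0, f * np.sqrt(keep_y.sum()))
            fit = _fit_core(Xi, Yi, k_eff, c_x, c_y, tol, max_iter)
            est_u = [np.zeros(len(keep_x)) for _ in fit]
            est_v = [np.zeros(len(keep_y)) for _ in fit]
            for j, (u, v, _, _, _) in enumerate(fit):
                est_u[j][keep_x] = u
                est_v[j][keep_y] = v
            hx = (xv[i][keep_x] - mu_x) / sd_x
            hy = (yv[i][keep_y] - mu_y) / sd_y
            for k, (j, cos) in enumerate(_match_components(ref_u, est_u)):
                if j < 0:
                    continue
                sign = 1.0 if cos >= 0 else -1.0
                scores_x[i, k] = sign * hx @ est_u[j][keep_x]
                scores_y[i, k] = sign * hy @ est_v[j][keep_y]
        per_comp = [_corr(scores_x[:, k], scores_y[:, k]) for k in range(k_eff)]
        rows.append((float(f), float(np.mean(per_comp)) if per_comp else 0.0))
    table = pd.DataFrame(rows, columns=["penalty", "mean_cv_correlation"])
    scores = table["mean_cv_correlation"].to_numpy()
    # ties (within numerical noise) resolve to the smallest penalty
    best_idx = int(np.flatnonzero(scores >= scores.max() - 1e-10)[0])
    return float(table["penalty"].iloc[best_idx]), table


def permutation_significance(
    X,
    Y,
    penalty_x: float,
    penalty_y: float | None = None,
    K: int = 1,
    n_perm: int = 999,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Permutation test of the canonical correlations.

    The null refits all K components after permuting the sample order of
    Y (column standardization is permutation-invariant, so the
    standardized Y is permuted directly). Per component,
    raw_p = (1 + #{null corr >= observed}) / (n_perm + 1); adjusted
    p-values are BH across the K components.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if penalty_y is None:
        penalty_y = penalty_x
    xv, yv, _, _ = _tables_to_arrays(X, Y)
    Xs, keep_x = _standardize(xv)
    Ys, keep_y = _standardize(yv)
    c_x = max(1.0, penalty_x * np.sqrt(keep_x.sum()))
    c_y = max(1.0, penalty_y * np.sqrt(keep_y.sum()))
    obs_fit = _fit_core(Xs, Ys, K, c_x, c_y, tol, max_iter)
    obs = np.array([rho for *_, rho, _ in obs_fit])
    k_eff = len(obs)
    rng = np.random.default_rng(seed)
    counts = np.zeros(k_eff, dtype=int)
    n = Xs.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_fit = _fit_core(Xs, Ys[perm], k_eff, c_x, c_y, tol, max_iter)
        null = np.array([rho for *_, rho, _ in null_fit])
        counts += null >= obs[: len(null)]
    raw = (1 + counts) / (n_perm + 1)
    return pd.DataFrame(
        {
            "component": np.arange(1, k_eff + 1),
            "correlation": obs,
            "raw_p": raw,
            "adjusted_p": bh_adjust(raw),
        }
    )


def loocv_extract(
    X,
    Y,
    penalty_x: float,
    penalty_y: float | None = None,
    K: int = 1,
    retention: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[dict[str, list[str]]]:
    """LOOCV-stable feature sets per component.

    Refits with each sample left out, matches refit components to the
    full-fit components by maximal |cosine| of weight vectors, and calls
    a feature robust when its weight is nonzero in at least
    ``retention`` fraction of the n refits (and in the full fit, so
    robust sets are subsets of selected sets).
    """
    if not 0 < retention <= 1:
        raise ValidationError("retention must be in (0, 1]")
    if penalty_y is None:
        penalty_y = penalty_x
    xv, yv, xf, yf = _tables_to_arrays(X, Y)
    n = xv.shape[0]
    if n < 3:
        raise ValidationError("LOOCV extraction needs at least 3 samples")
    full = scca_fit(X, Y, K, penalty_x, penalty_y, tol=tol, max_iter=max_iter)
    p_x, p_y = xv.shape[1], yv.shape[1]
    keepx_full = xv.std(axis=0, ddof=1) > 0
    ref_u = []
    for c in full.components:
        r = np.zeros(p_x)
        r[keepx_full] = c.u.to_numpy()
        ref_u.append(r)
    k_eff = len(ref_u)
    count_x = np.zeros((k_eff, p_x), dtype=int)
    count_y = np.zeros((k_eff, p_y), dtype=int)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, keep_x = _standardize(xv[mask])
        Yi, keep_y = _standardize(yv[mask])
        c_x = max(1.0, penalty_x * np.sqrt(keep_x.sum()))
        c_y = max(1.0, penalty_y * np.sqrt(keep_y.sum()))
        fit = _fit_core(Xi, Yi, k_eff, c_x, c_y, tol, max_iter)
        est_u = [np.zeros(p_x) for _ in fit]
        est_v = [np.zeros(p_y) for _ in fit]
        for j, (u, v, *_rest) in enumerate(fit):
            est_u[j][keep_x] = u
            est_v[j][keep_y] = v
        for k, (j, _) in enumerate(_match_components(ref_u, est_u)):
            if j < 0:
                continue
            count_x[k] += est_u[j] != 0
            count_y[k] += est_v[j] != 0
    threshold = retention * n - 1e-9
    out = []
    for k, comp in enumerate(full.components):
        sel_x, sel_y = set(comp.selected_x), set(comp.selected_y)
        robust_x = [
            f for f, c in zip(xf, count_x[k]) if c >= threshold and f in sel_x
        ]
        robust_y = [
            f for f, c in zip(yf, count_y[k]) if c >= threshold and f in sel_y
        ]
        comp.robust_x, comp.robust_y = robust_x, robust_y
        out.append({"robust_x": robust_x, "robust_y": robust_y})
    return out
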