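"""The six missing-data handling methods under comparison.

Each method maps an incomplete panel to one complete data set (listwise
deletion, mean imputation, k-nearest-neighbor imputation, low-rank
soft-threshold SVD imputation) or to m = 5 completed data sets
(expectation-maximization-based and predictive-mean-matching-based
multiple imputation).  All methods operate on the n x 8 block of measured
variables; observed cells are never altered, imputed values are clipped to
[0, 1], and infeasibility raises the typed
:class:`~lwibench.failures.MethodFailure` signal rather than crashing the
sweep -- a method that cannot complete a data set simply has no bias
record for that replicate.

Method notes
------------
* kNN: k is the odd integer nearest sqrt(#complete rows); distances are
  Euclidean over the target row's observed coordinates, rescaled by the
  number of coordinates used; donor values are combined with Gaussian
  kernel weights exp(-d^2) (a uniform average is available).
* soft-impute: iterative SVD soft-thresholding on the column-centered
  block, with the shrinkage level lambda chosen by warm starts down a
  log-spaced grid from lambda_max, scored on a 5% held-out mask of
  observed cells.
* EM-MI: bootstrap-EM -- for each imputation, a row bootstrap is followed
  by EM for the multivariate-normal mean/covariance (pattern-wise sweep
  E-step, ridge-stabilized M-step); missing cells are then drawn from
  their conditional normals.
* PMM-MI: chained equations over the 8 variables (predictors: the other
  7 plus time), Bayesian linear regression with type-1 matching and a
  5-donor pool, 10 sweeps per imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .failures import MethodFailure
from .panel_re import MEASURED_VARS
from .synthetic_reference import PanelDataset

__all__ = [
    "HandlingResult",
    "METHODS",
    "SINGLE_METHODS",
    "MI_METHODS",
    "listwise_delete",
    "mean_impute",
    "choose_k",
    "knn_impute",
    "soft_impute",
    "em_mi",
    "pmm_mi",
    "handle",
]

SINGLE_METHODS = ("listwise", "mean", "knn", "lowrank")
MI_METHODS = ("em_mi", "pmm_mi")
METHODS = SINGLE_METHODS + MI_METHODS

_N_VARS = len(MEASURED_VARS)


@dataclass
class HandlingResult:
    """Outcome of applying one handling method to one incomplete panel."""

    method: str
    completed: list[PanelDataset]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 5 if self.method in MI_METHODS else 1
        if len(self.completed) != expected and not (
            self.method in MI_METHODS and len(self.completed) >= 1
        ):
            raise ValueError(
                f"{self.method}: expected {expected} completed data sets, "
                f"got {len(self.completed)}"
            )
        for ds in self.completed:
            if not ds.is_complete():
                raise ValueError(f"{self.method}: completed data set has missing cells")


def _block(panel: PanelDataset) -> np.ndarray:
    return panel.frame[list(MEASURED_VARS)].to_numpy(dtype=float)


def _with_block(panel: PanelDataset, block: np.ndarray) -> PanelDataset:
    out = panel.copy()
    out.frame[list(MEASURED_VARS)] = block
    return out


def _check_columns_observed(method: str, block: np.ndarray) -> None:
    n_obs = (~np.isnan(block)).sum(axis=0)
    if np.any(n_obs == 0):
        bad = [MEASURED_VARS[j] for j in np.flatnonzero(n_obs == 0)]
        raise MethodFailure(method, f"fully missing column(s): {', '.join(bad)}")


# ---------------------------------------------------------------------------
# complete-case analysis


def listwise_delete(incomplete: PanelDataset) -> HandlingResult:
    """Retain only rows with all 8 measured variables observed."""
    block = _block(incomplete)
    keep = ~np.isnan(block).any(axis=1)
    n_complete = int(keep.sum())
    if n_complete == 0:
        raise MethodFailure("listwise", "0 complete rows remain")
    reduced = PanelDataset(
        incomplete.frame.loc[keep].reset_index(drop=True),
        incomplete.n_units,
        incomplete.n_days,
    )
    return HandlingResult("listwise", [reduced], {"n_complete": n_complete})


# ---------------------------------------------------------------------------
# single imputation


def mean_impute(incomplete: PanelDataset) -> HandlingResult:
    """Substitute each missing cell with its variable's observed mean."""
    block = _block(incomplete)
    _check_columns_observed("mean", block)
    col_means = np.nanmean(block, axis=0)
    miss = np.isnan(block)
    filled = np.where(miss, col_means[np.newaxis, :], block)
    return HandlingResult(
        "mean", [_with_block(incomplete, filled)], {"n_imputed": int(miss.sum())}
    )


def choose_k(n_complete: int) -> int:
    """The odd integer nearest sqrt(n_complete); ties break downward."""
    if n_complete < 1:
        raise ValueError("n_complete must be >= 1")
    r = math.sqrt(n_complete)
    lo = math.floor(r)
    lo = lo if lo % 2 == 1 else lo - 1
    lo = max(lo, 1)
    hi = lo + 2
    return lo if (r - lo) <= (hi - r) else hi


def knn_impute(
    incomplete: PanelDataset, *, weighting: str = "gaussian"
) -> HandlingResult:
    """Impute each missing cell from the k nearest complete rows.

    Distances to donor rows use only the target row's observed measured
    coordinates, rescaled to a full-length Euclidean scale
    (``d = sqrt(8/n_obs * sum((x_i - x_j)^2))``); donors are the complete
    rows; the imputed value is the kernel-weighted average of the donors'
    values.  Fails when no donor exists, when k exceeds the donor count,
    or when a row has no observed measured value at all (no distance can
    be computed) -- the situation that stops kNN at high missingness.
    """
    if weighting not in ("gaussian", "uniform"):
        raise ValueError("weighting must be 'gaussian' or 'uniform'")
    block = _block(incomplete)
    miss = np.isnan(block)
    complete_rows = ~miss.any(axis=1)
    n_complete = int(complete_rows.sum())
    if n_complete == 0:
        raise MethodFailure("knn", "no complete rows to act as donors")
    k = choose_k(n_complete)
    if n_complete < k:
        raise MethodFailure("knn", f"{n_complete} complete rows < k={k}")
    if (miss.all(axis=1)).any():
        n_bad = int(miss.all(axis=1).sum())
        raise MethodFailure("knn", f"{n_bad} row(s) with all measured values missing")

    donors = block[complete_rows]
    filled = block.copy()
    for i in np.flatnonzero(miss.any(axis=1)):
        obs = ~miss[i]
        diff = donors[:, obs] - block[i, obs]
        d = np.sqrt((_N_VARS / obs.sum()) * np.einsum("ij,ij->i", diff, diff))
        nearest = np.argsort(d, kind="stable")[:k]
        w = np.exp(-d[nearest] ** 2) if weighting == "gaussian" else np.ones(k)
        w_sum = w.sum()
        if w_sum <= 0:  # numerically dead kernel; fall back to uniform
            w = np.ones(k)
            w_sum = float(k)
        filled[i, miss[i]] = (w @ donors[nearest][:, miss[i]]) / w_sum

    return HandlingResult(
        "knn",
        [_with_block(incomplete, filled)],
        {"k": k, "n_complete": n_complete, "weighting": weighting},
    )


# ---------------------------------------------------------------------------
# low-rank (soft-threshold SVD) imputation


def _svd_soft_threshold(z: np.ndarray, lam: float, max_rank: int):
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    s = np.maximum(s - lam, 0.0)
    s[max_rank:] = 0.0
    return (u * s) @ vt, s


def _soft_impute_solve(
    x: np.ndarray,
    train_mask: np.ndarray,
    lam: float,
    *,
    z0: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
    max_rank: int | None = None,
):
    """Iterate Z <- SoftThreshold_lambda(P_obs(X) + P_miss(Z)) to a fixed
    point.  ``x`` is the centered block; ``train_mask`` marks cells treated
    as observed.  Convergence uses the squared relative Frobenius change
    ``||Z_new - Z_old||_F^2 / ||Z_old||_F^2 < tol`` (the criterion of the
    canonical soft-impute algorithm).  Returns (Z, singular values,
    iterations)."""
    if max_rank is None:
        max_rank = min(x.shape) - 1
    z = np.zeros_like(x) if z0 is None else z0.copy()
    x_obs = np.where(train_mask, x, 0.0)
    # floor the convergence denominator at the data scale so the exact-zero
    # solution (lambda >= lambda_max) registers as converged despite
    # floating-point dust
    scale_floor = max(1e-6 * np.linalg.norm(x_obs), 1e-12)
    for it in range(1, max_iter + 1):
        filled = np.where(train_mask, x_obs, z)
        z_new, s = _svd_soft_threshold(filled, lam, max_rank)
        denom = max(np.linalg.norm(z), scale_floor)
        delta = (np.linalg.norm(z_new - z) / denom) ** 2
        z = z_new
        if delta < tol:
            return z, s, it
    raise MethodFailure(
        "lowrank",
        f"soft-impute did not converge in {max_iter} iterations (lambda={lam:.4g})",
    )


def soft_impute(
    incomplete: PanelDataset,
    *,
    lam: float | None = None,
    seed: int = 0,
    val_frac: float = 0.05,
    n_lambda: int = 20,
    tol: float = 1e-5,
    max_iter: int = 500,
    use_design: bool = True,
    max_rank: int | None = None,
) -> HandlingResult:
    """Low-rank matrix completion by iterative SVD soft-thresholding.

    With ``use_design=True`` (default) the completion runs on the full
    normalized study matrix -- unit dummies and time (always observed)
    alongside the 8 measured variables (884 x 49 for the default panel) --
    so the singular vectors can pick up unit-level structure; only the
    measured cells are ever imputed.  ``use_design=False`` restricts the
    matrix to the measured block.  Columns are centered on their observed
    means.

    When ``lam`` is None, the shrinkage level is selected by warm starts
    down a log-spaced grid of ``n_lambda`` values from lambda_max (the
    smallest lambda giving the all-zero solution) to lambda_max/100, each
    solution scored on a held-out validation mask of ``val_frac`` of the
    observed measured cells; the winner is then refit on all observed
    cells, warm-started from the winning solution.
    """
    from .synthetic_reference import build_design

    block = _block(incomplete)
    _check_columns_observed("lowrank", block)
    n_meas = block.shape[1]

    if use_design:
        mat = build_design(incomplete).to_numpy(dtype=float)
    else:
        mat = block.copy()
    meas_cols = np.arange(mat.shape[1] - n_meas, mat.shape[1])
    obs = ~np.isnan(mat)
    col_means = np.array([mat[obs[:, j], j].mean() for j in range(mat.shape[1])])
    x = np.where(obs, mat - col_means, 0.0)
    if max_rank is None:
        max_rank = min(mat.shape) - 1  # default cap, as in the R package's rank.max

    if lam is not None:
        z, s, iters = _soft_impute_solve(
            x, obs, lam, tol=tol, max_iter=max_iter, max_rank=max_rank
        )
        best_lam, val_rmse = float(lam), float("nan")
    else:
        rng = np.random.default_rng(seed)
        # validation cells come from the observed *measured* cells only:
        # the design columns are never imputation targets
        obs_idx = np.argwhere(obs[:, meas_cols])
        obs_idx[:, 1] += meas_cols[0]
        n_val = max(1, int(round(val_frac * len(obs_idx))))
        val_sel = rng.choice(len(obs_idx), size=n_val, replace=False)
        val_cells = obs_idx[val_sel]
        train = obs.copy()
        train[val_cells[:, 0], val_cells[:, 1]] = False
        if (train.sum(axis=0) == 0).any():
            # do not let the validation split empty out a column
            train = obs.copy()
            val_cells = np.empty((0, 2), dtype=int)

        lam_max = np.linalg.svd(np.where(train, x, 0.0), compute_uv=False)[0]
        grid = np.geomspace(lam_max, lam_max / 100.0, n_lambda)
        z_warm = None
        path = []  # (rmse, rmse_se, lambda, Z) down the warm-start path
        for g in grid:
            z_g, s_g, it_g = _soft_impute_solve(
                x, train, g, z0=z_warm, tol=tol, max_iter=max_iter, max_rank=max_rank
            )
            z_warm = z_g
            if len(val_cells):
                pred = z_g[val_cells[:, 0], val_cells[:, 1]]
                truth = x[val_cells[:, 0], val_cells[:, 1]]
                rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
            else:
                rmse = 0.0
            path.append((rmse, float(g), z_g))
        val_rmse, best_lam, z_best = min(path, key=lambda entry: entry[0])
        z, s, iters = _soft_impute_solve(
            x, obs, best_lam, z0=z_best, tol=tol, max_iter=max_iter, max_rank=max_rank
        )

    completed = block.copy()
    imputed = (z + col_means[np.newaxis, :])[:, meas_cols]
    miss = ~obs[:, meas_cols]
    completed[miss] = np.clip(imputed[miss], 0.0, 1.0)
    rank = int(np.sum(s > 1e-6))
    return HandlingResult(
        "lowrank",
        [_with_block(incomplete, completed)],
        {
            "lambda": best_lam,
            "rank": rank,
            "iterations": iters,
            "validation_rmse": val_rmse,
        },
    )


# ---------------------------------------------------------------------------
# EM-based multiple imputation (bootstrap-EM, multivariate normal)


def _em_mvn(
    x: np.ndarray,
    *,
    ridge: float = 1e-4,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """EM for the MVN mean/covariance of ``x`` with NaN missing entries.

    Rows are grouped by missing pattern; the E-step fills each group's
    missing block with its conditional mean and adds the conditional
    covariance to the sufficient statistics; the M-step re-estimates
    (mu, Sigma) with a ridge ``ridge * I`` for numerical stability.
    """
    n, d = x.shape
    obs = ~np.isnan(x)
    n_obs_col = obs.sum(axis=0)
    if np.any(n_obs_col < 2):
        bad = [MEASURED_VARS[j] for j in np.flatnonzero(n_obs_col < 2)]
        raise MethodFailure(
            "em_mi", f"variable(s) with <2 observed values: {', '.join(bad)}"
        )

    mu = np.nanmean(x, axis=0)
    var = np.nanvar(x, axis=0)
    sigma = np.diag(np.maximum(var, 1e-6)) + ridge * np.eye(d)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(obs, axis=0):
        rows = np.flatnonzero((obs == key).all(axis=1))
        patterns[key.tobytes()] = rows

    for _ in range(max_iter):
        ex = np.where(obs, x, 0.0)
        exx_miss = np.zeros((d, d))
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            if not m.any():
                continue
            if o.any():
                soo = sigma[np.ix_(o, o)]
                som = sigma[np.ix_(o, m)]
                try:
                    solve = np.linalg.solve(soo, som)  # Soo^-1 Som
                except np.linalg.LinAlgError:
                    raise MethodFailure("em_mi", "singular observed-block covariance")
                cond_mean = mu[m] + (x[np.ix_(rows, o)] - mu[o]) @ solve
                cond_cov = sigma[np.ix_(m, m)] - som.T @ solve
            else:
                cond_mean = np.tile(mu[m], (len(rows), 1))
                cond_cov = sigma[np.ix_(m, m)]
            ex[np.ix_(rows, m)] = cond_mean
            exx_miss[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = ex.mean(axis=0)
        sigma_new = (ex.T @ ex + exx_miss) / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2 + ridge * np.eye(d)
        change = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if change < tol:
            break
    return mu, sigma


def _conditional_draw(
    row: np.ndarray, mu: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw the row's missing coordinates from their conditional normal."""
    o = ~np.isnan(row)
    m = ~o
    if o.any():
        soo = sigma[np.ix_(o, o)]
        som = sigma[np.ix_(o, m)]
        solve = np.linalg.solve(soo, som)
        cmean = mu[m] + (row[o] - mu[o]) @ solve
        ccov = sigma[np.ix_(m, m)] - som.T @ solve
    else:
        cmean = mu[m]
        ccov = sigma[np.ix_(m, m)]
    ccov = (ccov + ccov.T) / 2
    w, v = np.linalg.eigh(ccov)
    half = v * np.sqrt(np.maximum(w, 0.0))
    out = row.copy()
    out[m] = cmean + half @ rng.standard_normal(m.sum())
    return out


def em_mi(incomplete: PanelDataset, m: int = 5, *, seed: int = 0) -> HandlingResult:
    """Bootstrap-EM multiple imputation under a multivariate normal model.

    For each of the ``m`` imputations: bootstrap-resample the rows, run EM
    for the MVN mean/covariance on the resample (this propagates parameter
    uncertainty between imputations), then draw each missing cell of the
    *original* data from its conditional normal given the row's observed
    values; draws are clipped to [0, 1].
    """
    block = _block(incomplete)
    _check_columns_observed("em_mi", block)
    n = block.shape[0]
    root = np.random.default_rng(seed)
    completed = []
    for _j in range(m):
        rng = np.random.default_rng(root.integers(2**31))
        boot = block[rng.integers(0, n, size=n)]
        mu, sigma = _em_mvn(boot)
        filled = np.array(
            [
                _conditional_draw(row, mu, sigma, rng) if np.isnan(row).any() else row
                for row in block
            ]
        )
        miss = np.isnan(block)
        filled[miss] = np.clip(filled[miss], 0.0, 1.0)
        completed.append(_with_block(incomplete, filled))
    return HandlingResult("em_mi", completed, {"m": m})


# ---------------------------------------------------------------------------
# predictive-mean-matching multiple imputation (chained equations)


def _bayes_regression_draw(
    dmat: np.ndarray, yv: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draw (beta*, and the posterior-mean beta-hat) for a normal
    linear model with the standard noninformative prior."""
    n, q = dmat.shape
    if n <= q:
        raise MethodFailure("pmm_mi", f"{n} observed rows <= {q} predictors")
    gram = dmat.T @ dmat + 1e-8 * np.eye(q)
    gram_inv = np.linalg.inv(gram)
    beta_hat = gram_inv @ (dmat.T @ yv)
    resid = yv - dmat @ beta_hat
    dof = max(n - q, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2_star = sigma2_hat * dof / rng.chisquare(dof)
    chol = np.linalg.cholesky((gram_inv + gram_inv.T) / 2 * sigma2_star)
    beta_star = beta_hat + chol @ rng.standard_normal(q)
    return beta_star, beta_hat


def pmm_mi(
    incomplete: PanelDataset,
    m: int = 5,
    *,
    seed: int = 0,
    n_sweeps: int = 10,
    donors: int = 5,
) -> HandlingResult:
    """Predictive-mean-matching multiple imputation via chained equations.

    For each target variable in turn (predictors: the other 7 measured
    variables, currently filled, plus time), a Bayesian linear regression
    is fit on the rows where the target is observed.  Donor rows are
    ranked by |posterior-mean prediction - posterior-draw prediction for
    the missing cell| (type-1 matching); each missing cell receives the
    observed value of one of its ``donors`` closest rows, drawn uniformly.
    Each of the ``m`` imputations runs an independent chain of
    ``n_sweeps`` sweeps from an independent random-observed-value fill.
    """
    block = _block(incomplete)
    miss = np.isnan(block)
    n_obs_col = (~miss).sum(axis=0)
    short = np.flatnonzero(n_obs_col < donors + 1)
    if short.size:
        bad = [MEASURED_VARS[j] for j in short]
        raise MethodFailure(
            "pmm_mi",
            f"donor pool unconstructible (<{donors + 1} observed): {', '.join(bad)}",
        )

    time_col = (
        (incomplete.frame["day_index"].to_numpy(dtype=float) - 1)
        / max(incomplete.n_days - 1, 1)
    )
    root = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        rng = np.random.default_rng(root.integers(2**31))
        filled = block.copy()
        for j in range(_N_VARS):  # initial fill: random observed draws
            mj = miss[:, j]
            if mj.any():
                obs_vals = block[~mj, j]
                filled[mj, j] = rng.choice(obs_vals, size=mj.sum(), replace=True)

        for _sweep in range(n_sweeps):
            for j in range(_N_VARS):
                mj = miss[:, j]
                if not mj.any():
                    continue
                others = [c for c in range(_N_VARS) if c != j]
                dmat = np.column_stack(
                    [np.ones(len(filled)), filled[:, others], time_col]
                )
                beta_star, beta_hat = _bayes_regression_draw(
                    dmat[~mj], block[~mj, j], rng
                )
                pred_obs = dmat[~mj] @ beta_hat
                pred_mis = dmat[mj] @ beta_star
                obs_vals = block[~mj, j]
                # for each missing cell: the `donors` observed rows with
                # closest predictions; impute a uniformly drawn donor value
                dists = np.abs(pred_obs[np.newaxis, :] - pred_mis[:, np.newaxis])
                pool = np.argpartition(dists, donors - 1, axis=1)[:, :donors]
                pick = pool[np.arange(len(pool)), rng.integers(donors, size=len(pool))]
                filled[mj, j] = obs_vals[pick]
        completed.append(_with_block(incomplete, filled))
    return HandlingResult(
        "pmm_mi", completed, {"m": m, "n_sweeps": n_sweeps, "donors": donors}
    )


# ---------------------------------------------------------------------------
# dispatch


def handle(
    method: str, incomplete: PanelDataset, *, seed: int = 0, m: int = 5
) -> HandlingResult:
    """Apply one of the six handling methods by name."""
    if method == "listwise":
        return listwise_delete(incomplete)
    if method == "mean":
        return mean_impute(incomplete)
    if method == "knn":
        return knn_impute(incomplete)
    if method == "lowrank":
        return soft_impute(incomplete, seed=seed)
    if method == "em_mi":
        return em_mi(incomplete, m, seed=seed)
    if method == "pmm_mi":
        return pmm_mi(incomplete, m, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
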