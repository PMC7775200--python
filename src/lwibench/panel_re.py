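"""One-way random-effects panel regression by Swamy-Arora feasible GLS.

The wellness index is a linear model

    y_it = b0 + sum_k b_k x_k,it + mu_i + u_it,

where ``mu_i ~ N(0, sigma_mu^2)`` is a unit (student) random effect and
``u_it ~ N(0, sigma_u^2)`` an idiosyncratic error.  Estimation follows the
classic two-step feasible GLS:

1. variance components from the within (fixed-effects) and between (unit
   means) regressions, with negative variance estimates truncated at zero;
2. OLS on quasi-demeaned data, with per-unit demeaning weight
   ``theta_i = 1 - sqrt(sigma_u^2 / (sigma_u^2 + T_i * sigma_mu^2))``
   so unbalanced panels are handled exactly.

Point estimates coincide with explicit GLS when the true variance components
are supplied; standard errors are the conventional FGLS ones,
``sqrt(sigma_u^2 * diag((X*'X*)^-1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .failures import MethodFailure

#: behavior variables, in fixed model order (slopes beta_1..beta_7)
BEHAVIOR_VARS: tuple[str, ...] = (
    "breakfast",
    "lunch",
    "dinner",
    "exercise",
    "step_ach",
    "sleep_ach",
    "golden_ach",
)
#: the 8 measured variables: 7 behaviors plus the proxy (perceived) score
MEASURED_VARS: tuple[str, ...] = BEHAVIOR_VARS + ("y",)

N_COEF = 8  # intercept + 7 behavior slopes
_RANK_TOL = 1e-8


@dataclass
class CoefficientSet:
    """The 8 estimated coefficients (intercept first) for one fitted model.

    ``p``, ``s`` and ``method`` tag which simulated data set and handling
    method produced the estimates; they are ``None`` for a direct fit.
    """

    beta: np.ndarray
    se: np.ndarray
    p: int | None = None
    s: int | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.beta.shape != (N_COEF,) or self.se.shape != (N_COEF,):
            raise ValueError(f"coefficient sets have exactly {N_COEF} entries")
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.se))):
            raise ValueError("coefficient sets must be finite")


@dataclass
class VarianceComponents:
    """Estimated variance components and per-unit quasi-demeaning weights."""

    sigma_mu2: float
    sigma_u2: float
    theta: pd.Series = field(repr=False)  # indexed by unit_id

    def __post_init__(self) -> None:
        if self.sigma_mu2 < 0:
            raise ValueError("sigma_mu2 must be >= 0")
        if self.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be > 0")
        th = np.asarray(self.theta, dtype=float)
        if np.any(th < 0) or np.any(th > 1):
            raise ValueError("theta weights lie in [0, 1]")


def _frame_of(panel) -> pd.DataFrame:
    """Accept a PanelDataset or a bare DataFrame."""
    return panel.frame if hasattr(panel, "frame") else panel


def fit_random_effects(
    panel,
    *,
    known_components: tuple[float, float] | None = None,
) -> tuple[CoefficientSet, VarianceComponents]:
    """Fit the one-way random-effects model on a complete panel.

    Parameters
    ----------
    panel
        Complete panel data (``unit_id``, ``day_index``, the 7 behavior
        columns and ``y``).  Unit identity comes from ``unit_id``; the
        one-hot dummy columns, when present, are ignored by the fit.
    known_components
        Optional ``(sigma_mu2, sigma_u2)``; when given, the Swamy-Arora
        estimation step is bypassed and the model reduces to exact GLS
        with those components (used for validation against explicit GLS).

    Returns
    -------
    (CoefficientSet, VarianceComponents)

    Raises
    ------
    MethodFailure
        If the regression is infeasible: fewer rows than parameters, a
        rank-deficient regressor matrix, fewer than 2 units, or all units
        observed once (within variance undefined).  This is precisely the
        failure mode that stops listwise deletion at high missingness.
    """
    df = _frame_of(panel)
    y = df["y"].to_numpy(dtype=float)
    X = df[list(BEHAVIOR_VARS)].to_numpy(dtype=float)
    units = df["unit_id"].to_numpy()
    n, k = X.shape

    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("fit_random_effects requires a complete data set")
    if n < N_COEF + 1:
        raise MethodFailure("panel_re", f"{n} rows < {N_COEF + 1} required")

    uniq, inv, counts = np.unique(units, return_inverse=True, return_counts=True)
    n_units = len(uniq)
    if n_units < 2:
        raise MethodFailure("panel_re", "fewer than 2 units")

    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc, tol=_RANK_TOL * max(1.0, np.abs(Xc).max())) < N_COEF:
        raise MethodFailure("panel_re", "rank-deficient regressor matrix")

    if known_components is not None:
        sigma_mu2, sigma_u2 = map(float, known_components)
    else:
        sigma_mu2, sigma_u2 = _swamy_arora(y, X, inv, counts, n_units)

    theta_vals = 1.0 - np.sqrt(sigma_u2 / (sigma_u2 + counts * sigma_mu2))
    theta = pd.Series(theta_vals, index=pd.Index(uniq, name="unit_id"))

    # quasi-demeaned GLS: subtract theta_i * unit mean from y, X and the
    # intercept column, then run OLS
    ybar = np.bincount(inv, weights=y) / counts
    Xbar = np.vstack([np.bincount(inv, weights=X[:, j]) / counts for j in range(k)]).T
    th = theta_vals[inv]
    y_star = y - th * ybar[inv]
    X_star = np.column_stack([1.0 - th, X - th[:, np.newaxis] * Xbar[inv]])

    XtX = X_star.T @ X_star
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught by rank check
        raise MethodFailure("panel_re", f"singular quasi-demeaned design: {exc}")
    beta = XtX_inv @ (X_star.T @ y_star)
    se = np.sqrt(sigma_u2 * np.diag(XtX_inv))

    return (
        CoefficientSet(beta=beta, se=se),
        VarianceComponents(sigma_mu2=sigma_mu2, sigma_u2=sigma_u2, theta=theta),
    )


def _swamy_arora(y, X, inv, counts, n_units) -> tuple[float, float]:
    """Swamy-Arora variance components for a possibly unbalanced panel.

    sigma_u^2 comes from the within (fixed-effects) residual sum of squares
    with N - n_units - K degrees of freedom; sigma_mu^2 from the between
    (unit-means) regression, debited by sigma_u^2 / T_h (harmonic mean unit
    size) and truncated at zero.
    """
    n, k = X.shape
    dof_within = n - n_units - k
    if dof_within <= 0:
        raise MethodFailure(
            "panel_re", f"within degrees of freedom {dof_within} <= 0 "
            "(too few repeated observations per unit)"
        )

    ybar = np.bincount(inv, weights=y) / counts
    Xbar = np.vstack([np.bincount(inv, weights=X[:, j]) / counts for j in range(k)]).T

    # within regression (no intercept: demeaning removes it)
    yw = y - ybar[inv]
    Xw = X - Xbar[inv]
    if np.linalg.matrix_rank(Xw, tol=_RANK_TOL * max(1.0, np.abs(Xw).max())) < k:
        raise MethodFailure("panel_re", "within-transformed regressors rank deficient")
    bw, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    ssr_within = float(np.sum((yw - Xw @ bw) ** 2))
    sigma_u2 = ssr_within / dof_within
    if sigma_u2 <= 0:
        raise MethodFailure("panel_re", "zero within variance")

    # between regression on unit means, with intercept
    dof_between = n_units - k - 1
    if dof_between <= 0:
        # cannot separate sigma_mu2; fall back to pooled OLS (theta = 0)
        return 0.0, sigma_u2
    Xb = np.column_stack([np.ones(n_units), Xbar])
    bb, *_ = np.linalg.lstsq(Xb, ybar, rcond=None)
    ssr_between = float(np.sum((ybar - Xb @ bb) ** 2))
    t_harm = n_units / float(np.sum(1.0 / counts))
    sigma_mu2 = max(0.0, ssr_between / dof_between - sigma_u2 / t_harm)
    return sigma_mu2, sigma_u2
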