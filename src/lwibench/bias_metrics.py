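"""Rubin pooling and the MAB / GAB bias measures.

For every (proportion p, replicate s, method m) the pipeline produces one
coefficient value set -- for the multiple-imputation methods, the m = 5
per-imputation sets pooled by Rubin's rules.  The mean of absolute biases
(MAB) compares that set against the reference coefficients:

    MAB_{p,s,m} = (1/8) * sum_k | beta_hat_{p,s,m,k} - a_hat_k |

and the grand mean of absolute biases (GAB) averages the MABs over the
replicates at one proportion:

    GAB_{p,m} = (1/S) * sum_s MAB_{p,s,m}.

A method that fails on any replicate at a proportion has *no* GAB there
(undefined), reproducing the semantics under which listwise deletion,
kNN and EM-based imputation drop out of the comparison at high
missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_re import N_COEF, CoefficientSet
from .synthetic_reference import ReferenceCoefficients

__all__ = [
    "BiasRecord",
    "GABRecord",
    "pool_rubin",
    "compute_mab",
    "compute_gab",
]


@dataclass
class BiasRecord:
    """MAB for one (p, s, method)."""

    p: int
    s: int
    method: str
    mab: float

    def __post_init__(self) -> None:
        if self.mab < 0:
            raise ValueError("MAB is nonnegative")


@dataclass
class GABRecord:
    """GAB for one (p, method); ``gab`` is None when undefined."""

    p: int
    method: str
    gab: float | None
    n_contributing: int

    @property
    def defined(self) -> bool:
        return self.gab is not None


def pool_rubin(sets: list[CoefficientSet]) -> CoefficientSet:
    """Pool per-imputation coefficient sets by Rubin's rules.

    Point estimate: the arithmetic mean of the m estimates.  Total
    variance: ``W + (1 + 1/m) * B`` with W the mean within-imputation
    variance (squared SE) and B the between-imputation sample variance of
    the estimates.
    """
    if not sets:
        raise ValueError("no coefficient sets to pool")
    betas = np.vstack([cs.beta for cs in sets])
    ses = np.vstack([cs.se for cs in sets])
    if betas.shape[1] != N_COEF:
        raise ValueError("mismatched coefficient set lengths")
    m = len(sets)
    pooled = betas.mean(axis=0)
    w_bar = (ses**2).mean(axis=0)
    b = betas.var(axis=0, ddof=1) if m > 1 else np.zeros(N_COEF)
    total_var = w_bar + (1.0 + 1.0 / m) * b
    first = sets[0]
    return CoefficientSet(
        beta=pooled, se=np.sqrt(total_var), p=first.p, s=first.s, method=first.method
    )


def compute_mab(cvs: CoefficientSet, ref: ReferenceCoefficients) -> BiasRecord:
    """Mean over the 8 coefficients (intercept included) of the absolute
    deviation from the reference values."""
    mab = float(np.mean(np.abs(cvs.beta - ref.a)))
    return BiasRecord(
        p=cvs.p if cvs.p is not None else -1,
        s=cvs.s if cvs.s is not None else -1,
        method=cvs.method or "",
        mab=mab,
    )


def compute_gab(
    records: list[BiasRecord],
    n_replicates: int = 200,
    *,
    allow_partial: bool = False,
) -> GABRecord:
    """Aggregate one (p, method)'s MABs into its GAB.

    GAB is defined only when every one of the ``n_replicates`` replicates
    produced an MAB; otherwise it is undefined (``gab=None``) with the
    count of successes recorded.  ``allow_partial=True`` switches to the
    mean over successful replicates (off by default).
    """
    if not records:
        raise ValueError("empty bias-record list")
    ps = {r.p for r in records}
    methods = {r.method for r in records}
    if len(ps) != 1 or len(methods) != 1:
        raise ValueError("records must share (p, method)")
    n = len(records)
    mean_mab = float(np.mean([r.mab for r in records]))
    if n == n_replicates or allow_partial:
        gab = mean_mab
    else:
        gab = None
    return GABRecord(p=ps.pop(), method=methods.pop(), gab=gab, n_contributing=n)
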