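"""Synthetic reference panel emulating the student health-behavior study.

The original development case collected daily lifelogs from 41 Korean
college students over 28 days (1148 unit-day observations, of which 884
were complete after excluding device/recording failures): 7 behavior
variables (meal quality ratings, exercise, step / sleep-duration /
golden-time achievement) plus a perceived wellness score, all min-max
normalized to [0, 1].  That data set was never deposited, so this module
generates a statistical stand-in with

* per-variable marginals matching the published means/SDs and supports
  (graded meals on {0, .33, .66, 1}, binary exercise, continuous
  achievements);
* a low-rank latent factor structure across the behavior variables, via a
  Gaussian copula (low-rank normal scores mapped through each variable's
  target quantile function) -- the low-rank character of behavior panels
  is what makes matrix-completion imputation interesting;
* the proxy score generated from the one-way random-effects model with
  known "true" coefficients, so coefficient recovery can be verified;
* the stated 884 x 49 design shape: 40 unit dummies + time + 7 behaviors
  + proxy.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import panel_re
from .panel_re import BEHAVIOR_VARS, MEASURED_VARS, CoefficientSet

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "PanelDataset",
    "ReferenceCoefficients",
    "normalize_minmax",
    "generate_reference",
    "build_design",
]

GRADED_SUPPORT = np.array([0.0, 0.33, 0.66, 1.0])


@dataclass(frozen=True)
class MarginalSpec:
    """Target marginal for one measured variable on the normalized scale.

    ``kind`` is ``"graded"`` (support {0, .33, .66, 1}), ``"binary"``
    (support {0, 1}) or ``"continuous"`` (an interval within [0, 1],
    matched by a scaled Beta distribution).
    """

    mean: float
    sd: float
    kind: str  # graded | binary | continuous
    lo: float = 0.0
    hi: float = 1.0


# Published descriptive statistics of the study data set, /100.
DEFAULT_BEHAVIOR_SPECS: dict[str, MarginalSpec] = {
    "breakfast": MarginalSpec(0.242, 0.362, "graded"),
    "lunch": MarginalSpec(0.635, 0.323, "graded"),
    "dinner": MarginalSpec(0.755, 0.275, "graded"),
    "exercise": MarginalSpec(0.053, 0.224, "binary"),
    "step_ach": MarginalSpec(0.746, 0.286, "continuous"),
    "sleep_ach": MarginalSpec(0.860, 0.193, "continuous", lo=0.067),
    "golden_ach": MarginalSpec(0.142, 0.251, "continuous"),
}

# Reference-model estimates (intercept, then the 7 behavior slopes) from
# the development case; used as the generator's ground truth.
DEFAULT_TRUE_COEFFICIENTS = np.array(
    [0.305, 0.097, 0.105, 0.088, 0.087, 0.061, 0.131, 0.066]
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic reference generator.

    ``n_collected`` unit-day rows are generated and ``n_excluded`` of them
    dropped uniformly at random (standing in for the study's ignorable
    device failures), leaving the reference data set.  ``sigma_mu`` and
    ``sigma_u`` are the unit-effect and error SDs of the proxy-score model
    on the normalized scale; their defaults (0.1 each) reproduce the
    published proxy-score SD of 0.159 given the behavior marginals.
    """

    n_units: int = 41
    n_days: int = 28
    n_collected: int = 1148
    n_excluded: int = 264
    behavior_specs: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_SPECS)
    )
    true_coefficients: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRUE_COEFFICIENTS.copy()
    )
    sigma_mu: float = 0.1
    sigma_u: float = 0.1
    latent_rank: int = 5
    #: fraction of each latent score's variance carried by the shared
    #: low-rank factors (the rest is independent noise)
    communality: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        if self.true_coefficients.shape != (8,):
            raise ValueError("true_coefficients must have 8 entries")
        if self.n_collected - self.n_excluded <= 0:
            raise ValueError("n_excluded must be smaller than n_collected")
        if self.n_collected > self.n_units * self.n_days:
            raise ValueError("n_collected exceeds n_units * n_days")
        n_ref = self.n_collected - self.n_excluded
        if not 1 <= self.latent_rank < min(n_ref, 8):
            raise ValueError("latent_rank must lie in [1, min(n_reference_rows, 8))")
        if set(self.behavior_specs) != set(BEHAVIOR_VARS):
            raise ValueError(f"behavior_specs must cover exactly {BEHAVIOR_VARS}")
        for name, spec in self.behavior_specs.items():
            if not (0 <= spec.lo < spec.hi <= 1):
                raise ValueError(f"{name}: support must be within [0, 1]")

    @property
    def n_reference(self) -> int:
        return self.n_collected - self.n_excluded


@dataclass
class PanelDataset:
    """Long-format panel: one row per (unit, day), 8 measured variables.

    ``frame`` holds columns ``unit_id``, ``day_index``, the 7 behavior
    variables and ``y``; missing cells (after MCAR injection) are NaN in
    the measured columns only.
    """

    frame: pd.DataFrame
    n_units: int
    n_days: int

    def __post_init__(self) -> None:
        required = ["unit_id", "day_index", *MEASURED_VARS]
        missing_cols = [c for c in required if c not in self.frame.columns]
        if missing_cols:
            raise ValueError(f"panel frame lacks columns {missing_cols}")
        if self.frame.duplicated(["unit_id", "day_index"]).any():
            raise ValueError("(unit_id, day_index) pairs must be unique")
        block = self.measured()
        with np.errstate(invalid="ignore"):
            if np.nanmin(block) < -1e-12 or np.nanmax(block) > 1 + 1e-12:
                raise ValueError("measured values must lie in [0, 1]")

    def measured(self) -> np.ndarray:
        """The n x 8 block of measured variables (NaN where missing)."""
        return self.frame[list(MEASURED_VARS)].to_numpy(dtype=float)

    def is_complete(self) -> bool:
        return not np.isnan(self.measured()).any()

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.frame.copy(), self.n_units, self.n_days)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, n_units: int, n_days: int) -> "PanelDataset":
        return cls(pd.read_csv(path), n_units=n_units, n_days=n_days)


@dataclass
class ReferenceCoefficients:
    """The 8 reference coefficient values a_0..a_7 (intercept first)."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.shape != (8,):
            raise ValueError("reference coefficients have exactly 8 entries")


def normalize_minmax(x: float, x_min: float, x_max: float) -> float:
    """Min-max normalization of ``x`` from [x_min, x_max] onto [0, 1]."""
    if x_max <= x_min:
        raise ValueError("degenerate range: x_max must exceed x_min (constant variable)")
    if not (x_min - 1e-12 <= x <= x_max + 1e-12):
        raise ValueError(f"x={x} outside [{x_min}, {x_max}]")
    return (x - x_min) / (x_max - x_min)


# ---------------------------------------------------------------------------
# marginal quantile maps for the Gaussian copula


def _beta_params(name: str, spec: MarginalSpec) -> tuple[float, float]:
    """Beta(a, b) matching the spec's mean/SD on its support interval."""
    width = spec.hi - spec.lo
    m = (spec.mean - spec.lo) / width
    s = spec.sd / width
    if not 0 < m < 1:
        raise ValueError(f"{name}: mean outside its support interval")
    nu = m * (1 - m) / s**2 - 1
    if nu <= 0:
        raise ValueError(f"{name}: SD {spec.sd} too large for mean {spec.mean} on "
                         f"[{spec.lo}, {spec.hi}]")
    return m * nu, (1 - m) * nu


def _graded_probs(name: str, spec: MarginalSpec) -> np.ndarray:
    """Probabilities on {0, .33, .66, 1} with the target mean (exact) and
    SD (as close as the support allows)."""
    v = GRADED_SUPPORT
    if not v[0] < spec.mean < v[-1]:
        raise ValueError(f"{name}: graded mean must lie strictly inside (0, 1)")

    def sd_of(q):
        qn = np.clip(q, 1e-12, None)
        qn = qn / qn.sum()
        m = np.sum(qn * v)
        return np.sqrt(max(np.sum(qn * v**2) - m**2, 0.0))

    x0 = np.array([1.0 - spec.mean, 0.02, 0.02, spec.mean])
    x0 = np.clip(x0, 0.02, None)
    x0 /= x0.sum()
    res = optimize.minimize(
        lambda q: (sd_of(q) - spec.sd) ** 2,
        x0=x0,
        method="SLSQP",
        bounds=[(1e-9, 1.0)] * 4,
        constraints=[
            {"type": "eq", "fun": lambda q: np.sum(q) - 1.0},
            {"type": "eq", "fun": lambda q: np.sum(q * v) - spec.mean},
        ],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    q = np.clip(res.x, 1e-9, 1.0)
    q /= q.sum()
    if abs(np.sum(q * v) - spec.mean) > 1e-6:
        raise ValueError(f"{name}: graded marginal unreachable (mean {spec.mean})")
    return q


def _quantile_map(name: str, spec: MarginalSpec, u: np.ndarray) -> np.ndarray:
    """Map uniforms ``u`` through the variable's target quantile function."""
    if spec.kind == "continuous":
        a, b = _beta_params(name, spec)
        return spec.lo + (spec.hi - spec.lo) * stats.beta.ppf(u, a, b)
    if spec.kind == "binary":
        if not 0 < spec.mean < 1:
            raise ValueError(f"{name}: binary mean must lie in (0, 1)")
        return (u >= 1.0 - spec.mean).astype(float)
    if spec.kind == "graded":
        q = _graded_probs(name, spec)
        return GRADED_SUPPORT[np.searchsorted(np.cumsum(q)[:-1], u)]
    raise ValueError(f"{name}: unknown marginal kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# generation


def generate_reference(
    config: GeneratorConfig | None = None,
) -> tuple[PanelDataset, ReferenceCoefficients]:
    """Generate the complete synthetic reference panel and its fitted
    reference coefficients.

    Behavior values arise from rank-``latent_rank`` Gaussian factor scores
    plus independent noise, pushed through each variable's quantile map;
    the proxy score follows the random-effects model with the configured
    true coefficients, clipped to [0, 1].  ``n_excluded`` of the
    ``n_collected`` rows are then dropped uniformly at random, and the
    random-effects model is refit on the surviving rows to produce the
    reference coefficient values used for bias measurement.
    """
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_collected
    k = len(BEHAVIOR_VARS)

    # low-rank latent normal scores: Z = F L' + noise, unit variance per column
    loadings = rng.standard_normal((k, cfg.latent_rank))
    loadings *= np.sqrt(cfg.communality) / np.linalg.norm(loadings, axis=1, keepdims=True)
    factors = rng.standard_normal((n, cfg.latent_rank))
    z = factors @ loadings.T
    z += np.sqrt(1.0 - cfg.communality) * rng.standard_normal((n, k))
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    u = stats.norm.cdf(z)

    X = np.column_stack(
        [
            _quantile_map(name, cfg.behavior_specs[name], u[:, j])
            for j, name in enumerate(BEHAVIOR_VARS)
        ]
    )

    # unit-day layout, row-major over (unit, day)
    grid_units = np.repeat(np.arange(1, cfg.n_units + 1), cfg.n_days)[:n]
    grid_days = np.tile(np.arange(1, cfg.n_days + 1), cfg.n_units)[:n]

    beta0, slopes = cfg.true_coefficients[0], cfg.true_coefficients[1:]
    mu = rng.normal(0.0, cfg.sigma_mu, size=cfg.n_units)
    u_err = rng.normal(0.0, cfg.sigma_u, size=n)
    y = np.clip(beta0 + X @ slopes + mu[grid_units - 1] + u_err, 0.0, 1.0)

    frame = pd.DataFrame({"unit_id": grid_units, "day_index": grid_days})
    for j, name in enumerate(BEHAVIOR_VARS):
        frame[name] = X[:, j]
    frame["y"] = y

    keep = np.sort(rng.choice(n, size=cfg.n_reference, replace=False))
    reference = PanelDataset(
        frame.iloc[keep].reset_index(drop=True), cfg.n_units, cfg.n_days
    )

    coef, _ = panel_re.fit_random_effects(reference)
    return reference, ReferenceCoefficients(a=coef.beta)


def build_design(panel: PanelDataset) -> pd.DataFrame:
    """Append the dummy/time design columns, yielding the full study shape.

    Column order: ``unit_2`` .. ``unit_{n_units}`` (one-hot, unit 1 as the
    reference category), ``time`` (day 1 -> 0, day n_days -> 1, linear),
    the 7 behavior variables, ``y`` -- 49 columns for the default 41-unit,
    28-day panel.  The dummies are design metadata for the stated data-set
    shape (and optional imputer predictors); the random-effects fit takes
    unit identity from ``unit_id`` instead.
    """
    df = panel.frame
    out = pd.DataFrame(index=df.index)
    for unit in range(2, panel.n_units + 1):
        out[f"unit_{unit}"] = (df["unit_id"] == unit).astype(float)
    out["time"] = (df["day_index"] - 1) / (panel.n_days - 1)
    for name in MEASURED_VARS:
        out[name] = df[name]
    return out


def config_to_dict(cfg: GeneratorConfig) -> dict:
    """JSON/YAML-serializable form of a GeneratorConfig."""
    d = dataclasses.asdict(cfg)
    d["true_coefficients"] = [float(v) for v in cfg.true_coefficients]
    d["behavior_specs"] = {
        name: dataclasses.asdict(spec) for name, spec in cfg.behavior_specs.items()
    }
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "behavior_specs" in d:
        d["behavior_specs"] = {
            name: MarginalSpec(**spec) for name, spec in d["behavior_specs"].items()
        }
    if "true_coefficients" in d:
        d["true_coefficients"] = np.asarray(d["true_coefficients"], dtype=float)
    return GeneratorConfig(**d)
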