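"""End-to-end benchmark orchestration.

Runs the whole simulation: generate the synthetic reference panel (step 0),
then for each missingness proportion inject MCAR masks, apply each handling
method, fit the random-effects model (pooling the multiple-imputation
methods by Rubin's rules), compute MAB/GAB, and run the DTK pairwise
comparison -- finally summing win counts over the standard proportion
ranges.  Every stage is seeded deterministically from one master seed, and
intermediate tables can be persisted as CSV (with a config hash embedded
for provenance) so interrupted sweeps resume per (p, s, method).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias_metrics, comparison, imputation, missingness, panel_re
from .bias_metrics import BiasRecord, GABRecord
from .comparison import DEFAULT_RANGES, ComparisonOutcome
from .failures import MethodFailure
from .imputation import METHODS, MI_METHODS
from .missingness import ProportionGrid, default_grid
from .synthetic_reference import (
    GeneratorConfig,
    PanelDataset,
    ReferenceCoefficients,
    config_to_dict,
    generate_reference,
)

__all__ = ["ExperimentConfig", "ExperimentResults", "run_experiment", "plot_results"]

logger = logging.getLogger("lwibench")

SMOKE_GRID = (10, 40, 70)
SMOKE_REPLICATES = 20


@dataclass
class ExperimentConfig:
    """All knobs of one benchmark run.

    ``scale="smoke"`` overrides the grid and replicate count with a small
    configuration (proportions 10/40/70%, 20 replicates) that exercises
    every stage in minutes; ``scale="full"`` uses the configured grid
    (default 1..80%) with 200 replicates.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid: ProportionGrid = field(default_factory=default_grid)
    n_replicates: int = 200
    methods: tuple[str, ...] = METHODS
    m_imputations: int = 5
    alpha: float = 0.05
    master_seed: int = 0
    output_dir: str | None = None
    scale: str = "full"  # full | smoke

    def __post_init__(self) -> None:
        if self.scale not in ("full", "smoke"):
            raise ValueError("scale must be 'full' or 'smoke'")
        if self.scale == "smoke":
            self.grid = ProportionGrid(SMOKE_GRID)
            self.n_replicates = SMOKE_REPLICATES
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.methods:
            raise ValueError("methods must be nonempty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = {
            "generator": config_to_dict(self.generator),
            "grid": list(self.grid),
            "n_replicates": self.n_replicates,
            "methods": list(self.methods),
            "m_imputations": self.m_imputations,
            "alpha": self.alpha,
            "master_seed": self.master_seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentResults:
    """Everything one run produces."""

    config: ExperimentConfig
    reference: PanelDataset
    reference_coefficients: ReferenceCoefficients
    bias_records: pd.DataFrame  # columns p, s, method, status, mab
    gab_records: list[GABRecord]
    outcomes: list[ComparisonOutcome]
    range_sums: pd.DataFrame  # rows: ranges, columns: methods

    def gab_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "p": g.p,
                    "method": g.method,
                    "gab": g.gab if g.defined else np.nan,
                    "n_contributing": g.n_contributing,
                }
                for g in self.gab_records
            ]
        )

    def wins_table(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            for method, w in o.wins.items():
                rows.append({"p": o.p, "method": method, "wins": w})
        return pd.DataFrame(rows)


def _method_seed(master_seed: int, p: int, s: int, method: str) -> int:
    idx = METHODS.index(method)
    ss = np.random.SeedSequence((int(master_seed), int(p), int(s), 1000 + idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _one_cell(
    reference: PanelDataset,
    ref_coefs: ReferenceCoefficients,
    p: int,
    s: int,
    method: str,
    cfg: ExperimentConfig,
) -> dict:
    """Run inject -> handle -> fit -> (pool) -> MAB for one (p, s, method)."""
    inj_seed = missingness.derive_seed(cfg.master_seed, p, s)
    incomplete, _ = missingness.inject_mcar(reference, p, inj_seed, s=s)
    seed = _method_seed(cfg.master_seed, p, s, method)
    try:
        result = imputation.handle(method, incomplete, seed=seed, m=cfg.m_imputations)
        coef_sets = []
        for ds in result.completed:
            coef, _ = panel_re.fit_random_effects(ds)
            coef.p, coef.s, coef.method = p, s, method
            coef_sets.append(coef)
        pooled = (
            bias_metrics.pool_rubin(coef_sets)
            if method in MI_METHODS
            else coef_sets[0]
        )
        record = bias_metrics.compute_mab(pooled, ref_coefs)
        return {"p": p, "s": s, "method": method, "status": "ok", "mab": record.mab}
    except MethodFailure as mf:
        logger.info("method failure at p=%d s=%d %s: %s", p, s, method, mf.reason)
        return {
            "p": p,
            "s": s,
            "method": method,
            "status": f"failed: {mf.reason}",
            "mab": np.nan,
        }


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResults:
    """Execute the full benchmark for one configuration.

    When ``config.output_dir`` is set, bias records are appended to
    ``bias_records.csv`` there as they are computed; a rerun with the same
    configuration resumes from the persisted records, and a rerun with a
    *different* configuration against the same directory is refused (the
    config hash is stored alongside the records).
    """
    cfg = config if config is not None else ExperimentConfig()
    chash = cfg.config_hash()

    out = Path(cfg.output_dir) if cfg.output_dir else None
    existing = pd.DataFrame()
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        hash_file = out / "config_hash.json"
        records_file = out / "bias_records.csv"
        if hash_file.exists():
            stored = json.loads(hash_file.read_text())["config_hash"]
            if stored != chash:
                raise RuntimeError(
                    f"output dir {out} holds a run with config hash {stored}; "
                    f"refusing to resume with mismatched config {chash}"
                )
            if records_file.exists():
                existing = pd.read_csv(records_file)
        else:
            hash_file.write_text(
                json.dumps({"config_hash": chash, "master_seed": cfg.master_seed})
            )

    reference, ref_coefs = generate_reference(cfg.generator)
    logger.info(
        "reference: %d rows, coefficients %s",
        len(reference.frame),
        np.round(ref_coefs.a, 3),
    )
    if out is not None:
        reference.to_csv(out / "reference.csv")

    done = (
        {(r.p, r.s, r.method) for r in existing.itertuples()}
        if len(existing)
        else set()
    )
    rows = [] if not len(existing) else existing.to_dict("records")
    for p in cfg.grid:
        for s in range(1, cfg.n_replicates + 1):
            for method in cfg.methods:
                if (p, s, method) in done:
                    continue
                rows.append(_one_cell(reference, ref_coefs, p, s, method, cfg))
        if out is not None:
            pd.DataFrame(rows).to_csv(out / "bias_records.csv", index=False)

    bias_df = pd.DataFrame(rows)

    gab_records = []
    for p in cfg.grid:
        for method in cfg.methods:
            sub = bias_df[
                (bias_df.p == p)
                & (bias_df.method == method)
                & (bias_df.status == "ok")
            ]
            recs = [
                BiasRecord(p=p, s=int(r.s), method=method, mab=float(r.mab))
                for r in sub.itertuples()
            ]
            if recs:
                gab_records.append(
                    bias_metrics.compute_gab(recs, n_replicates=cfg.n_replicates)
                )
            else:
                gab_records.append(
                    GABRecord(p=p, method=method, gab=None, n_contributing=0)
                )

    outcomes = []
    for p in cfg.grid:
        samples = {}
        for g in gab_records:
            if g.p == p and g.defined:
                sub = bias_df[
                    (bias_df.p == p)
                    & (bias_df.method == g.method)
                    & (bias_df.status == "ok")
                ]
                samples[g.method] = sub.mab.to_numpy()
        if len(samples) >= 2:
            outcomes.append(comparison.dtk_pairwise(samples, cfg.alpha, p=p))

    range_rows = {}
    for lo, hi in DEFAULT_RANGES:
        in_range = [o for o in outcomes if lo <= o.p <= hi]
        if in_range:
            range_rows[f"{lo}-{hi}%"] = comparison.sum_wins(in_range, (lo, hi))
    range_sums = pd.DataFrame(range_rows).T.fillna(0).astype(int)

    results = ExperimentResults(
        config=cfg,
        reference=reference,
        reference_coefficients=ref_coefs,
        bias_records=bias_df,
        gab_records=gab_records,
        outcomes=outcomes,
        range_sums=range_sums,
    )
    if out is not None:
        results.gab_table().assign(config_hash=chash).to_csv(
            out / "gab_records.csv", index=False
        )
        results.wins_table().assign(config_hash=chash).to_csv(
            out / "win_counts.csv", index=False
        )
        range_sums.to_csv(out / "range_sums.csv")
    return results


def plot_results(results: ExperimentResults, output_dir: str) -> list[Path]:
    """Write the GAB-vs-proportion and win-count figures.

    Curves for methods whose GAB is undefined beyond some proportion stop
    at the last defined point.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results.gab_records:
        raise ValueError("empty results: nothing to plot")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gab = results.gab_table()
    methods = list(results.config.methods)
    if not methods:
        raise ValueError("no methods to plot")

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for method in methods:
        sub = gab[(gab.method == method) & gab.gab.notna()].sort_values("p")
        ax.plot(sub.p, sub.gab, marker="o", label=method)
    ax.set_xlabel("missingness proportion (%)")
    ax.set_ylabel("GAB")
    ax.set_title("Grand mean of absolute biases by missingness proportion")
    ax.legend(fontsize=8)
    gab_path = out / "gab_by_proportion.png"
    fig.tight_layout()
    fig.savefig(gab_path, dpi=120)
    plt.close(fig)

    wins = results.wins_table()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ps = sorted(wins.p.unique())
    width = 0.8 / max(len(methods), 1)
    for i, method in enumerate(methods):
        sub = wins[wins.method == method].set_index("p").reindex(ps)
        ax.bar(
            np.arange(len(ps)) + i * width,
            sub.wins.fillna(0),
            width=width,
            label=method,
        )
    ax.set_xticks(np.arange(len(ps)) + 0.4)
    ax.set_xticklabels([str(p) for p in ps])
    ax.set_xlabel("missingness proportion (%)")
    ax.set_ylabel("pairwise comparisons won")
    ax.set_title("Statistically smaller bias: pairwise comparison wins")
    ax.legend(fontsize=8)
    wins_path = out / "win_counts.png"
    fig.tight_layout()
    fig.savefig(wins_path, dpi=120)
    plt.close(fig)
    return [gab_path, wins_path]
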