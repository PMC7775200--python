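"""Missingness grid and MCAR injection (simulated incomplete data sets).

The benchmark walks a grid of missingness proportions (1%..80% by 1%) and,
at each proportion, draws many independent missing-completely-at-random
masks over the *measured* cells of the reference panel: the 7 behavior
variables plus the proxy score (884 x 8 = 7072 eligible cells for the
default reference).  Dummy and time columns are bookkeeping, not collected
lifelogs, and are never masked.  Each mask deletes exactly
``round(p/100 * n_eligible)`` cells (round-half-to-even), chosen uniformly
without replacement and independently of all data values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_re import MEASURED_VARS
from .synthetic_reference import PanelDataset

__all__ = [
    "ProportionGrid",
    "MissingPattern",
    "default_grid",
    "n_masked_cells",
    "inject_mcar",
    "simulate_batch",
]


@dataclass(frozen=True)
class ProportionGrid:
    """Ordered missingness proportions, in percent."""

    proportions: tuple[int, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) == 0:
            raise ValueError("grid must be nonempty")
        if np.any(np.diff(p) <= 0):
            raise ValueError("proportions must be strictly increasing")
        if np.any(p <= 0) or np.any(p >= 100):
            raise ValueError("proportions must lie in (0, 100)")

    def __iter__(self):
        return iter(self.proportions)

    def __len__(self):
        return len(self.proportions)


def default_grid() -> ProportionGrid:
    """The benchmark grid: 1%, 2%, ..., 80%."""
    return ProportionGrid(tuple(range(1, 81)))


@dataclass
class MissingPattern:
    """One MCAR mask: which (row, variable) cells are deleted.

    ``cells`` is an (m, 2) integer array of (row position, measured-column
    index); column indices follow :data:`~lwibench.panel_re.MEASURED_VARS`.
    """

    p: int
    s: int
    seed: int
    cells: np.ndarray = field(repr=False)

    def cell_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.cells}

    def to_csv(self, path) -> None:
        """Serialize as (row_index, variable_name) rows."""
        import pandas as pd

        pd.DataFrame(
            {
                "row_index": self.cells[:, 0],
                "variable_name": [MEASURED_VARS[c] for c in self.cells[:, 1]],
            }
        ).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, p: int, s: int, seed: int) -> "MissingPattern":
        import pandas as pd

        df = pd.read_csv(path)
        cols = [MEASURED_VARS.index(v) for v in df["variable_name"]]
        cells = np.column_stack([df["row_index"].to_numpy(), cols])
        return cls(p=p, s=s, seed=seed, cells=cells)


def n_masked_cells(p: float, n_eligible: int) -> int:
    """Exact number of cells deleted at proportion ``p``% (half-to-even)."""
    return int(np.round(p / 100.0 * n_eligible))


def derive_seed(master_seed: int, p: int, s: int) -> int:
    """Deterministic per-replicate seed so any (p, s) cell is reproducible
    in isolation."""
    ss = np.random.SeedSequence((int(master_seed), int(p), int(s)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def inject_mcar(
    reference: PanelDataset, p: float, seed: int, s: int = 1
) -> tuple[PanelDataset, MissingPattern]:
    """Delete ``round(p/100 * n_eligible)`` measured cells uniformly at random.

    Returns the incomplete panel (NaN at masked cells) and the pattern.
    Deletion is independent of all values: missing completely at random.
    """
    if not 0 < p < 100:
        raise ValueError(f"missingness proportion must lie in (0, 100), got {p}")
    if not reference.is_complete():
        raise ValueError("reference panel must be complete")

    n_rows = len(reference.frame)
    n_cols = len(MEASURED_VARS)
    n_eligible = n_rows * n_cols
    m = n_masked_cells(p, n_eligible)

    rng = np.random.default_rng(seed)
    flat = rng.choice(n_eligible, size=m, replace=False)
    cells = np.column_stack([flat // n_cols, flat % n_cols])

    incomplete = reference.copy()
    block = incomplete.frame[list(MEASURED_VARS)].to_numpy(dtype=float)
    block[cells[:, 0], cells[:, 1]] = np.nan
    incomplete.frame[list(MEASURED_VARS)] = block

    return incomplete, MissingPattern(p=int(p), s=s, seed=int(seed), cells=cells)


def simulate_batch(
    reference: PanelDataset,
    p: float,
    n_replicates: int = 200,
    master_seed: int = 0,
) -> list[MissingPattern]:
    """The ``n_replicates`` independent MCAR patterns at proportion ``p``%.

    Per-replicate seeds derive deterministically from (master_seed, p, s),
    so the whole batch -- or any single replicate -- is reproducible.
    """
    patterns = []
    for s in range(1, n_replicates + 1):
        seed = derive_seed(master_seed, int(p), s)
        _, pattern = inject_mcar(reference, p, seed, s=s)
        patterns.append(pattern)
    return patterns


def apply_pattern(reference: PanelDataset, pattern: MissingPattern) -> PanelDataset:
    """Re-apply a stored pattern to the reference (for resumed runs)."""
    incomplete = reference.copy()
    block = incomplete.frame[list(MEASURED_VARS)].to_numpy(dtype=float)
    block[pattern.cells[:, 0], pattern.cells[:, 1]] = np.nan
    incomplete.frame[list(MEASURED_VARS)] = block
    return incomplete
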