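"""Grid evaluation over cluster-count pairs.

For every (n, m) pair in a user-supplied grid, the transformed response is
biclustered from ``trials`` random restarts; each restart contributes its
``sse_bc`` and the ``sse_ni`` of a blockwise fit of the *raw* phenotype under
that restart's partition.  Means and minima per pair are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .biclustering import bicluster
from .blockwise import fit_blockwise
from .phenotype_table import PhenotypeTable
from .responses import ResponseKind, transform


@dataclass(frozen=True)
class GridResult:
    """Mean/min SSEbc and SSEni per cluster-count pair."""

    row_counts: tuple[int, ...]
    col_counts: tuple[int, ...]
    mean_sse_bc: np.ndarray
    min_sse_bc: np.ndarray
    mean_sse_ni: np.ndarray
    min_sse_ni: np.ndarray
    trials: int
    response_kind: ResponseKind
    base_seed: int

    def __post_init__(self) -> None:
        shape = (len(self.row_counts), len(self.col_counts))
        for name in ("mean_sse_bc", "min_sse_bc", "mean_sse_ni", "min_sse_ni"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            object.__setattr__(self, name, arr)

    def to_dict(self) -> dict:
        return {
            "row_counts": list(self.row_counts),
            "col_counts": list(self.col_counts),
            "trials": self.trials,
            "response": int(self.response_kind),
            "base_seed": self.base_seed,
            "mean_sse_bc": self.mean_sse_bc.tolist(),
            "min_sse_bc": self.min_sse_bc.tolist(),
            "mean_sse_ni": self.mean_sse_ni.tolist(),
            "min_sse_ni": self.min_sse_ni.tolist(),
        }


def grid_search(table: PhenotypeTable, kind: ResponseKind | int,
                row_range: Sequence[int], col_range: Sequence[int],
                trials: int = 30, base_seed: int = 0,
                max_iter: int = 100, tol: float = 1e-8) -> GridResult:
    """Evaluate every (n, m) pair over ``trials`` seeded restarts.

    Each pair reuses the same seed block ``base_seed .. base_seed+trials-1``,
    so a fixed ``base_seed`` makes the whole grid reproducible bit-for-bit.
    SSEni is always computed on the raw phenotype, regardless of the response
    kind used for clustering.
    """
    kind = ResponseKind(kind)
    row_counts = tuple(int(n) for n in row_range)
    col_counts = tuple(int(m) for m in col_range)
    if not row_counts or not col_counts:
        raise ValueError("empty cluster-count range")
    g, e = table.shape
    for n in row_counts:
        if not 1 <= n <= g:
            raise ValueError(f"row cluster count {n} out of [1, {g}]")
    for m in col_counts:
        if not 1 <= m <= e:
            raise ValueError(f"column cluster count {m} out of [1, {e}]")
    transformed = transform(table, kind)
    shape = (len(row_counts), len(col_counts))
    mean_bc = np.empty(shape)
    min_bc = np.empty(shape)
    mean_ni = np.empty(shape)
    min_ni = np.empty(shape)
    for a, n in enumerate(row_counts):
        for b, m in enumerate(col_counts):
            bc = np.empty(trials)
            ni = np.empty(trials)
            for t in range(trials):
                res = bicluster(transformed, n, m, seed=base_seed + t,
                                max_iter=max_iter, tol=tol, response_kind=int(kind))
                bc[t] = res.sse_bc
                ni[t] = fit_blockwise(table, res.partition).sse_ni
            mean_bc[a, b], min_bc[a, b] = bc.mean(), bc.min()
            mean_ni[a, b], min_ni[a, b] = ni.mean(), ni.min()
    return GridResult(row_counts, col_counts, mean_bc, min_bc, mean_ni, min_ni,
                      trials, kind, base_seed)


def suggest_pair(grid: GridResult, tolerance: float = 0.10) -> tuple[int, int]:
    """Advisory pick: the smallest (n + m) pair whose min-SSEni is within
    ``tolerance`` (fractional) of the best achieved over the grid.

    Ties go to smaller n, then smaller m.  Reports should always show the
    full grid; this is a convenience, not a decision rule.
    """
    best = float(grid.min_sse_ni.min())
    threshold = best * (1.0 + tolerance) if best > 0 else best + tolerance * 0
    candidates: list[tuple[int, int, int, int, int]] = []
    for a, n in enumerate(grid.row_counts):
        for b, m in enumerate(grid.col_counts):
            if grid.min_sse_ni[a, b] <= threshold + 1e-12:
                candidates.append((n + m, n, m, a, b))
    candidates.sort()
    _, n, m, _, _ = candidates[0]
    return (n, m)


def plot_grid(grid: GridResult, path: str, metric: str = "sse_ni",
              stat: str = "mean") -> None:
    """Render one grid matrix as a heatmap PNG (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = getattr(grid, f"{stat}_{metric}")
    fig, ax = plt.subplots(figsize=(1.2 * len(grid.col_counts) + 2,
                                    0.8 * len(grid.row_counts) + 2))
    im = ax.imshow(arr, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(grid.col_counts)), [str(m) for m in grid.col_counts])
    ax.set_yticks(range(len(grid.row_counts)), [str(n) for n in grid.row_counts])
    ax.set_xlabel("environment clusters")
    ax.set_ylabel("genotype clusters")
    ax.set_title(f"{stat} {metric.upper().replace('_', '')}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
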