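"""Missing-data-tolerant biclustering of a two-way table.

Rows (genotypes) and columns (environments) are partitioned into ``n`` x ``m``
clusters so as to minimize the within-cell sum of squared deviations from the
cell means, computed over observed entries only (``sse_bc``).  The search is
an alternating local minimization with random restarts; an exhaustive
enumerator is provided as an oracle for tiny instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .phenotype_table import PhenotypeTable

_REL_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """Assignment of rows to ``n_row_clusters`` and columns to
    ``n_col_clusters`` clusters.

    Assignments are 0-based integer vectors; after fitting, every cluster is
    nonempty.
    """

    row_assignment: np.ndarray
    col_assignment: np.ndarray
    n_row_clusters: int
    n_col_clusters: int

    def __post_init__(self) -> None:
        ra = np.asarray(self.row_assignment, dtype=np.intp).copy()
        ca = np.asarray(self.col_assignment, dtype=np.intp).copy()
        if ra.ndim != 1 or ca.ndim != 1:
            raise ValueError("assignments must be 1-D vectors")
        n, m = int(self.n_row_clusters), int(self.n_col_clusters)
        if n < 1 or m < 1:
            raise ValueError("cluster counts must be >= 1")
        if n > ra.size or m > ca.size:
            raise ValueError("more clusters than items on an axis")
        if ra.size and (ra.min() < 0 or ra.max() >= n):
            raise ValueError("row assignment index out of range")
        if ca.size and (ca.min() < 0 or ca.max() >= m):
            raise ValueError("column assignment index out of range")
        ra.setflags(write=False)
        ca.setflags(write=False)
        object.__setattr__(self, "row_assignment", ra)
        object.__setattr__(self, "col_assignment", ca)
        object.__setattr__(self, "n_row_clusters", n)
        object.__setattr__(self, "n_col_clusters", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_assignment.size, self.col_assignment.size)

    def row_members(self, p: int) -> np.ndarray:
        return np.flatnonzero(self.row_assignment == p)

    def col_members(self, l: int) -> np.ndarray:
        return np.flatnonzero(self.col_assignment == l)


@dataclass(frozen=True)
class BiclusteringResult:
    """A fitted partition with its objective and run metadata."""

    partition: Partition
    sse_bc: float
    iterations: int
    converged: bool
    seed: Optional[int]
    response_kind: Optional[int] = None
    objective_history: tuple[float, ...] = field(default=())
    n_empty_cells: int = 0


def _check_dims(table: PhenotypeTable, partition: Partition) -> None:
    if partition.shape != table.shape:
        raise ValueError(
            f"partition shape {partition.shape} does not match table {table.shape}"
        )


def _cell_counts_means(values: np.ndarray, observed: np.ndarray,
                       ra: np.ndarray, ca: np.ndarray,
                       n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell observed counts and means (NaN for empty cells)."""
    idx = (ra[:, None] * m + ca[None, :])[observed]
    v = values[observed]
    counts = np.bincount(idx, minlength=n * m).astype(float)
    sums = np.bincount(idx, weights=v, minlength=n * m)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    return counts.reshape(n, m), means.reshape(n, m)


def sse_bc(table: PhenotypeTable, partition: Partition) -> float:
    """Within-cell sum of squared deviations from cell means over observed
    entries; cells with no observed entries contribute 0."""
    _check_dims(table, partition)
    ra, ca = partition.row_assignment, partition.col_assignment
    n, m = partition.n_row_clusters, partition.n_col_clusters
    idx = (ra[:, None] * m + ca[None, :])[table.observed]
    v = table.values[table.observed]
    counts = np.bincount(idx, minlength=n * m)
    sums = np.bincount(idx, weights=v, minlength=n * m)
    sumsq = np.bincount(idx, weights=v * v, minlength=n * m)
    nz = counts > 0
    sse = sumsq[nz] - sums[nz] ** 2 / counts[nz]
    return float(np.maximum(sse, 0.0).sum())


def _assignment_costs(values: np.ndarray, observed: np.ndarray,
                      other_assignment: np.ndarray, means: np.ndarray,
                      axis: int) -> np.ndarray:
    """Cost of putting each row (axis=0) or column (axis=1) into each cluster,
    against fixed cell means.  Entries mapping to empty cells cost 0."""
    if axis == 1:
        values = values.T
        observed = observed.T
        means = means.T
    # means: (n_clusters_this_axis, n_clusters_other); expand to item level
    centers = means[:, other_assignment]          # (k, n_other_items)
    k = centers.shape[0]
    n_items = values.shape[0]
    costs = np.empty((n_items, k))
    vals0 = np.where(observed, values, 0.0)
    for c in range(k):
        center = centers[c]
        usable = observed & np.isfinite(center)[None, :]
        diff = np.where(usable, vals0 - center[None, :], 0.0)
        costs[:, c] = np.einsum("ij,ij->i", diff, diff)
    return costs


def _repair_empty(assignment: np.ndarray, k: int, contributions: np.ndarray) -> None:
    """Move the highest-SSE-contributing item (from a cluster of size >= 2)
    into each empty cluster, in increasing cluster order.  In place."""
    sizes = np.bincount(assignment, minlength=k)
    for c in np.flatnonzero(sizes == 0):
        movable = sizes[assignment] >= 2
        if not movable.any():  # cannot happen when items >= k
            raise RuntimeError("no movable item for empty-cluster repair")
        cand = np.flatnonzero(movable)
        donor = cand[np.argmax(contributions[cand])]
        sizes[assignment[donor]] -= 1
        assignment[donor] = c
        sizes[c] += 1


def _item_contributions(values: np.ndarray, observed: np.ndarray,
                        ra: np.ndarray, ca: np.ndarray,
                        means: np.ndarray, axis: int) -> np.ndarray:
    """Each item's current contribution to the objective."""
    centers = means[ra[:, None], ca[None, :]]
    diff = np.where(observed & np.isfinite(centers), values - centers, 0.0)
    sq = np.where(np.isnan(diff), 0.0, diff * diff)
    return sq.sum(axis=1 - axis)


def bicluster(table: PhenotypeTable, n: int, m: int, seed: int = 0,
              max_iter: int = 100, tol: float = 1e-8,
              response_kind: Optional[int] = None) -> BiclusteringResult:
    """Alternating minimization of :func:`sse_bc` from one random start.

    Rows and columns are seeded uniformly at random subject to nonempty
    clusters; each sweep reassigns all rows against current cell means, then
    all columns, until assignments stabilize, the relative decrease drops
    below ``tol``, or ``max_iter`` sweeps elapse.  The objective after each
    full sweep is non-increasing (a sweep that would increase it is reverted
    and the run reported converged).  Fixed seed gives bitwise-identical
    results.
    """
    g, e = table.shape
    if not (1 <= n <= g):
        raise ValueError(f"n must be in [1, {g}], got {n}")
    if not (1 <= m <= e):
        raise ValueError(f"m must be in [1, {e}], got {m}")
    rng = np.random.default_rng(seed)
    values, observed = table.values, table.observed

    ra = _random_assignment(rng, g, n)
    ca = _random_assignment(rng, e, m)

    def objective(ra_, ca_):
        part = Partition(ra_, ca_, n, m)
        return sse_bc(table, part)

    history = [objective(ra, ca)]
    converged = False
    iterations = 0
    for sweep in range(1, max_iter + 1):
        iterations = sweep
        prev_ra, prev_ca = ra.copy(), ca.copy()

        _, means = _cell_counts_means(values, observed, ra, ca, n, m)
        costs = _assignment_costs(values, observed, ca, means, axis=0)
        ra = np.argmin(costs, axis=1).astype(np.intp)  # ties -> lowest index
        _repair_empty(ra, n, _item_contributions(values, observed, ra, ca, means, axis=0))

        _, means = _cell_counts_means(values, observed, ra, ca, n, m)
        costs = _assignment_costs(values, observed, ra, means, axis=1)
        ca = np.argmin(costs, axis=1).astype(np.intp)
        _repair_empty(ca, m, _item_contributions(values, observed, ra, ca, means, axis=1))

        obj = objective(ra, ca)
        if obj > history[-1] * (1.0 + _REL_EPS) + _REL_EPS:
            # batch moves into formerly-empty cells can overshoot; keep the
            # previous (better) state and stop
            ra, ca = prev_ra, prev_ca
            converged = True
            break
        history.append(obj)
        if np.array_equal(ra, prev_ra) and np.array_equal(ca, prev_ca):
            converged = True
            break
        prev_obj = history[-2]
        if prev_obj - obj <= tol * max(abs(prev_obj), 1.0) and sweep > 1:
            converged = True
            break

    partition = Partition(ra, ca, n, m)
    counts, _ = _cell_counts_means(values, observed, ra, ca, n, m)
    return BiclusteringResult(
        partition=partition,
        sse_bc=history[-1],
        iterations=iterations,
        converged=converged,
        seed=seed,
        response_kind=response_kind,
        objective_history=tuple(history),
        n_empty_cells=int((counts == 0).sum()),
    )


def _random_assignment(rng: np.random.Generator, n_items: int, k: int) -> np.ndarray:
    """Uniform random assignment guaranteed to leave no cluster empty."""
    asg = np.empty(n_items, dtype=np.intp)
    perm = rng.permutation(n_items)
    asg[perm[:k]] = np.arange(k)
    if n_items > k:
        asg[perm[k:]] = rng.integers(0, k, size=n_items - k)
    return asg


def best_of(table: PhenotypeTable, n: int, m: int, trials: int = 30,
            base_seed: int = 0, max_iter: int = 100, tol: float = 1e-8,
            response_kind: Optional[int] = None) -> BiclusteringResult:
    """Best of ``trials`` restarts with seeds ``base_seed .. base_seed+trials-1``.

    Returns the run with the smallest ``sse_bc``; ties go to the lowest seed.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    best: Optional[BiclusteringResult] = None
    for t in range(trials):
        res = bicluster(table, n, m, seed=base_seed + t, max_iter=max_iter,
                        tol=tol, response_kind=response_kind)
        if best is None or res.sse_bc < best.sse_bc:
            best = res
    assert best is not None
    return best


# -- exhaustive oracle ---------------------------------------------------

def _stirling2(n: int, k: int) -> int:
    if k > n or k < 0:
        return 0
    row = [1] + [0] * k
    for i in range(1, n + 1):
        new = [0] * (k + 1)
        for j in range(1, min(i, k) + 1):
            new[j] = j * row[j] + row[j - 1]
        new[0] = 1 if i == 0 else 0
        row = new
    return row[k]


def _partitions_into_k(n_items: int, k: int) -> Iterator[np.ndarray]:
    """All unordered set partitions of ``range(n_items)`` into exactly ``k``
    nonempty blocks, as canonical restricted-growth assignment vectors."""
    a = np.zeros(n_items, dtype=np.intp)

    def rec(i: int, mx: int) -> Iterator[np.ndarray]:
        if i == n_items:
            if mx + 1 == k:
                yield a.copy()
            return
        if mx + 1 + (n_items - i) < k:  # cannot reach k blocks
            return
        for v in range(min(mx + 1, k - 1) + 1):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    if n_items == 0:
        return iter(())
    return rec(1, 0) if n_items > 1 else iter([a.copy()] if k == 1 else [])


EXHAUSTIVE_LIMIT = 2_000_000


def exhaustive_bicluster(table: PhenotypeTable, n: int, m: int) -> BiclusteringResult:
    """Globally minimize ``sse_bc`` by enumerating every set partition of rows
    into ``n`` blocks crossed with every column partition into ``m`` blocks.

    Only feasible for tiny instances; guarded by :data:`EXHAUSTIVE_LIMIT`.
    """
    g, e = table.shape
    if not (1 <= n <= g and 1 <= m <= e):
        raise ValueError("cluster counts out of range")
    size = _stirling2(g, n) * _stirling2(e, m)
    if size > EXHAUSTIVE_LIMIT:
        raise ValueError(f"instance too large for exhaustive search ({size} partitions)")
    best_obj = math.inf
    best_part: Optional[Partition] = None
    col_parts = list(_partitions_into_k(e, m))
    for ra in _partitions_into_k(g, n):
        for ca in col_parts:
            part = Partition(ra, ca, n, m)
            obj = sse_bc(table, part)
            if obj < best_obj:
                best_obj = obj
                best_part = part
    assert best_part is not None
    return BiclusteringResult(partition=best_part, sse_bc=best_obj, iterations=1,
                              converged=True, seed=None)
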