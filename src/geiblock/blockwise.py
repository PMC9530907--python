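"""No-interaction models fitted separately inside every bicluster cell.

Each cell (row cluster x column cluster) gets its own additive fit on the raw
phenotype: value = mu + G_i + E~_j + error, where E~_j is the environment
effect local to the cell (it absorbs the cell's interaction with the
environment).  When missingness disconnects the cell's observed submatrix,
each connected component is fitted separately and its SSE summed; no
imputation and no cross-cell borrowing ever happens.  The aggregate over all
cells is ``sse_ni``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .biclustering import Partition
from .gei_models import _additive_lstsq
from .phenotype_table import PhenotypeTable


@dataclass(frozen=True)
class ComponentFit:
    """Additive fit on one connected component of a cell's observed cells."""

    genotypes: tuple[int, ...]     # table row indices with >=1 obs in component
    environments: tuple[int, ...]  # table column indices
    mu: float
    g_effects: dict[int, float]    # sum-to-zero over the component's genotypes
    e_tilde: dict[int, float]      # sum-to-zero over the component's environments
    n_obs: int
    sse: float
    df: int


@dataclass(frozen=True)
class CellFit:
    """All fits inside one cell (p, l), possibly several components."""

    p: int
    l: int
    genotypes: tuple[int, ...]     # full row-cluster membership
    environments: tuple[int, ...]  # full column-cluster membership
    components: tuple[ComponentFit, ...]
    n_obs: int
    sse: float
    df: int

    @property
    def mu(self) -> Optional[float]:
        """The cell-level intercept, defined when the cell is one component."""
        return self.components[0].mu if len(self.components) == 1 else None


@dataclass(frozen=True)
class BlockwiseModel:
    """Per-cell additive fits under a fixed partition, plus totals."""

    table: PhenotypeTable
    partition: Partition
    cells: tuple[CellFit, ...]
    sse_ni: float
    df_ni: int

    def cell(self, p: int, l: int) -> CellFit:
        return self.cells[p * self.partition.n_col_clusters + l]

    def predict(self, genotype: str, environment: str) -> Optional[float]:
        return predict_blockwise(self, genotype, environment)


def _fit_cell(values: np.ndarray, observed: np.ndarray, p: int, l: int,
              row_idx: np.ndarray, col_idx: np.ndarray) -> CellFit:
    sub_obs = observed[np.ix_(row_idx, col_idx)]
    sub_val = values[np.ix_(row_idx, col_idx)]
    gi, ej = np.nonzero(sub_obs)
    n_obs = gi.size
    if n_obs == 0:
        return CellFit(p, l, tuple(row_idx), tuple(col_idx), (), 0, 0.0, 0)

    # connected components of the cell's bipartite observed graph
    act_g = np.unique(gi)
    act_e = np.unique(ej)
    gpos = {int(v): i for i, v in enumerate(act_g)}
    epos = {int(v): i for i, v in enumerate(act_e)}
    ng, ne = act_g.size, act_e.size
    adj = coo_matrix(
        (np.ones(n_obs), ([gpos[int(v)] for v in gi], [ng + epos[int(v)] for v in ej])),
        shape=(ng + ne, ng + ne))
    ncomp, labels = connected_components(adj, directed=False)

    comps: list[ComponentFit] = []
    total_sse = 0.0
    total_df = 0
    for c in range(ncomp):
        cg = act_g[labels[:ng] == c]
        ce = act_e[labels[ng:] == c]
        mask = np.isin(gi, cg) & np.isin(ej, ce)
        cgi, cej = gi[mask], ej[mask]
        y = sub_val[cgi, cej]
        rows = np.searchsorted(cg, cgi)
        cols = np.searchsorted(ce, cej)
        mu, g_eff, e_eff, sse, rank = _additive_lstsq(y, rows, cols, cg.size, ce.size)
        df = y.size - rank
        if df == 0:
            sse = 0.0  # saturated component interpolates exactly
        comps.append(ComponentFit(
            genotypes=tuple(int(row_idx[v]) for v in cg),
            environments=tuple(int(col_idx[v]) for v in ce),
            mu=mu,
            g_effects={int(row_idx[v]): float(g_eff[i]) for i, v in enumerate(cg)},
            e_tilde={int(col_idx[v]): float(e_eff[j]) for j, v in enumerate(ce)},
            n_obs=y.size,
            sse=sse,
            df=df,
        ))
        total_sse += sse
        total_df += df
    return CellFit(p, l, tuple(int(v) for v in row_idx), tuple(int(v) for v in col_idx),
                   tuple(comps), n_obs, total_sse, total_df)


def fit_blockwise(table: PhenotypeTable, partition: Partition) -> BlockwiseModel:
    """Fit a separate no-interaction model in every cell of ``partition``.

    Fits are on the raw phenotype values of ``table`` (never on a transformed
    response).  Cell df = observed cells minus estimable parameters; cells
    with too few observations saturate with SSE 0 and df 0.
    """
    if partition.shape != table.shape:
        raise ValueError(
            f"partition shape {partition.shape} does not match table {table.shape}"
        )
    cells: list[CellFit] = []
    sse_ni = 0.0
    df_ni = 0
    for p in range(partition.n_row_clusters):
        rows = partition.row_members(p)
        for l in range(partition.n_col_clusters):
            cols = partition.col_members(l)
            cf = _fit_cell(table.values, table.observed, p, l, rows, cols)
            cells.append(cf)
            sse_ni += cf.sse
            df_ni += cf.df
    return BlockwiseModel(table, partition, tuple(cells), sse_ni, df_ni)


def predict_blockwise(model: BlockwiseModel, genotype: str,
                      environment: str) -> Optional[float]:
    """Predict the phenotype of (genotype, environment) from its cell's fit.

    Returns ``None`` when the pair is not jointly estimable, i.e. when the
    genotype and environment do not both carry observations inside the same
    connected component of their cell.  Never falls back to global effects.
    """
    i = model.table.genotype_index(genotype)
    j = model.table.environment_index(environment)
    p = int(model.partition.row_assignment[i])
    l = int(model.partition.col_assignment[j])
    cell = model.cell(p, l)
    for comp in cell.components:
        if i in comp.g_effects and j in comp.e_tilde:
            return comp.mu + comp.g_effects[i] + comp.e_tilde[j]
    return None
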