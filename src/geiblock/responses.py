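"""Response transformations applied before biclustering.

Four responses are supported, all computed from observed-cell margins:

1. ``RAW_CENTERED``          -- value minus the overall mean
2. ``DOUBLE_CENTERED``       -- value minus row and column means plus overall
   mean (the direct interaction expression)
3. ``GENOTYPE_CENTERED``     -- value minus the genotype (row) mean
4. ``ENVIRONMENT_CENTERED``  -- value minus the environment (column) mean

With missing data the margins are means over observed cells only, so the
double-centered response equals the interaction term only approximately; the
transforms are nevertheless applied directly to incomplete tables.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

from .phenotype_table import PhenotypeTable, margins


class ResponseKind(IntEnum):
    """The four biclustering responses, keyed by their conventional numbers."""

    RAW_CENTERED = 1
    DOUBLE_CENTERED = 2
    GENOTYPE_CENTERED = 3
    ENVIRONMENT_CENTERED = 4


def transform(table: PhenotypeTable, kind: ResponseKind | int) -> PhenotypeTable:
    """Return a new table with transformed values and an unchanged mask.

    The input table is never mutated.
    """
    kind = ResponseKind(kind)
    m = margins(table)
    vals = table.values
    if kind is ResponseKind.RAW_CENTERED:
        out = vals - m.overall_mean
    elif kind is ResponseKind.DOUBLE_CENTERED:
        out = vals - m.row_means[:, None] - m.col_means[None, :] + m.overall_mean
    elif kind is ResponseKind.GENOTYPE_CENTERED:
        out = vals - m.row_means[:, None]
    else:  # ENVIRONMENT_CENTERED
        out = vals - m.col_means[None, :]
    out = np.where(table.observed, out, np.nan)
    return table.with_values(out)
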