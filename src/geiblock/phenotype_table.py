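"""Two-way tables of phenotype means with missing entries.

The central data structure is :class:`PhenotypeTable`: a rectangular matrix of
phenotype means (rows = genotypes, columns = environments) together with a
boolean mask of observed positions.  Missing cells are the norm in
multi-environment trial data, so every downstream computation in this package
is written against the mask rather than assuming completeness.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class TableError(ValueError):
    """Invalid phenotype table or table file."""


class EmptyAxisError(TableError):
    """A genotype row or environment column has zero observed entries."""


class DuplicateLabelError(TableError):
    """Duplicate genotype or environment labels."""


#: Field contents treated as missing when reading delimited files.
MISSING_TOKENS = ("", "NA", "NaN", "nan", "N/A", "na", "null", "NULL", ".")


@dataclass(frozen=True)
class PhenotypeTable:
    """A two-way table of phenotype means with an observed/missing mask.

    Parameters
    ----------
    genotype_ids:
        Ordered unique row labels.
    environment_ids:
        Ordered unique column labels.
    values:
        Float matrix of shape ``(len(genotype_ids), len(environment_ids))``.
        Entries at unobserved positions are stored as NaN and carry no
        information.
    observed:
        Boolean mask of the same shape; True where a mean was observed.
    """

    genotype_ids: tuple[str, ...]
    environment_ids: tuple[str, ...]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        observed = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "genotype_ids", tuple(str(g) for g in self.genotype_ids))
        object.__setattr__(self, "environment_ids", tuple(str(e) for e in self.environment_ids))
        if len(set(self.genotype_ids)) != len(self.genotype_ids):
            raise DuplicateLabelError("genotype labels are not unique")
        if len(set(self.environment_ids)) != len(self.environment_ids):
            raise DuplicateLabelError("environment labels are not unique")
        shape = (len(self.genotype_ids), len(self.environment_ids))
        if values.shape != shape or observed.shape != shape:
            raise TableError(
                f"matrix shape {values.shape} does not match labels {shape}"
            )
        if not np.all(np.isfinite(values[observed])):
            raise TableError("non-finite value at an observed position")
        # unobserved positions carry no information
        values = values.copy()
        values[~observed] = np.nan
        row_ok = observed.any(axis=1)
        if not row_ok.all():
            bad = self.genotype_ids[int(np.flatnonzero(~row_ok)[0])]
            raise EmptyAxisError(f"genotype {bad!r} has no observed entries")
        col_ok = observed.any(axis=0)
        if not col_ok.all():
            bad = self.environment_ids[int(np.flatnonzero(~col_ok)[0])]
            raise EmptyAxisError(f"environment {bad!r} has no observed entries")
        values.setflags(write=False)
        observed = observed.copy()
        observed.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed)

    # -- basic geometry -------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_environments(self) -> int:
        return len(self.environment_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genotypes, self.n_environments)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def n_missing(self) -> int:
        return self.values.size - self.n_observed

    def with_values(self, values: np.ndarray) -> "PhenotypeTable":
        """Return a new table with the same labels/mask but new values."""
        return PhenotypeTable(self.genotype_ids, self.environment_ids, values, self.observed)

    def genotype_index(self, genotype: str) -> int:
        try:
            return self.genotype_ids.index(str(genotype))
        except ValueError:
            raise KeyError(f"unknown genotype {genotype!r}") from None

    def environment_index(self, environment: str) -> int:
        try:
            return self.environment_ids.index(str(environment))
        except ValueError:
            raise KeyError(f"unknown environment {environment!r}") from None

    # -- data frame views ----------------------------------------------

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.genotype_ids),
                          columns=list(self.environment_ids))
        df.index.name = "genotype"
        return df

    def to_long_frame(self) -> pd.DataFrame:
        gi, ej = np.nonzero(self.observed)
        return pd.DataFrame({
            "genotype": [self.genotype_ids[i] for i in gi],
            "environment": [self.environment_ids[j] for j in ej],
            "value": self.values[gi, ej],
        })


@dataclass(frozen=True)
class Margins:
    """Observed-cell means: overall, per genotype, per environment."""

    overall_mean: float
    row_means: np.ndarray
    col_means: np.ndarray


@dataclass(frozen=True)
class TableSummary:
    """Counts and missingness of a table (percent to one decimal)."""

    n_genotypes: int
    n_environments: int
    percent_missing: float


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if "\t" in header and "," not in header:
        return "\t"
    return ","


def read_table(path: str | Path, layout: str = "wide", sep: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype table.

    Wide layout: header row of environment labels, first column genotype
    labels, empty fields missing.  Long layout: three columns
    (genotype, environment, value); replicate records for the same
    (genotype, environment) pair are averaged to a single mean.
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    if sep is None:
        sep = _sniff_delimiter(path)
    if layout == "wide":
        return _read_wide(path, sep)
    return _read_long(path, sep)


def _read_wide(path: Path, sep: str) -> PhenotypeTable:
    with open(path, "r", newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    env_ids = [h.strip() for h in header[1:]]
    if len(set(env_ids)) != len(env_ids):
        raise DuplicateLabelError(f"duplicate environment header in {path}")
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=list(MISSING_TOKENS),
                     keep_default_na=False, skipinitialspace=True,
                     float_precision="round_trip")
    genotype_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    try:
        values = body.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise TableError(f"non-numeric value field in {path}: {exc}") from exc
    observed = ~np.isnan(values)
    return PhenotypeTable(genotype_ids, env_ids, values, observed)


def _read_long(path: Path, sep: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep=sep, na_values=list(MISSING_TOKENS),
                     keep_default_na=False, skipinitialspace=True,
                     float_precision="round_trip")
    if df.shape[1] < 3:
        raise TableError(f"long layout needs 3 columns, found {df.shape[1]} in {path}")
    df = df.iloc[:, :3]
    df.columns = ["genotype", "environment", "value"]
    df["genotype"] = df["genotype"].astype(str)
    df["environment"] = df["environment"].astype(str)
    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as exc:
        raise TableError(f"non-numeric value field in {path}: {exc}") from exc
    df = df.dropna(subset=["value"])
    # replicate (genotype, environment) records are averaged to a single mean
    means = df.groupby(["genotype", "environment"], sort=False)["value"].mean()
    genotype_ids = list(dict.fromkeys(df["genotype"]))
    env_ids = list(dict.fromkeys(df["environment"]))
    values = np.full((len(genotype_ids), len(env_ids)), np.nan)
    gpos = {g: i for i, g in enumerate(genotype_ids)}
    epos = {e: j for j, e in enumerate(env_ids)}
    for (g, e), v in means.items():
        values[gpos[g], epos[e]] = v
    return PhenotypeTable(genotype_ids, env_ids, values, ~np.isnan(values))


def write_table(table: PhenotypeTable, path: str | Path, layout: str = "wide",
                sep: str = ",") -> None:
    """Write a table in the same dialects accepted by :func:`read_table`."""
    path = Path(path)
    if layout == "wide":
        table.to_wide_frame().to_csv(path, sep=sep, na_rep="")
    elif layout == "long":
        table.to_long_frame().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def margins(table: PhenotypeTable) -> Margins:
    """Overall/row/column means computed over observed entries only."""
    vals = table.values
    with np.errstate(invalid="ignore"):
        overall = float(np.nanmean(vals))
        rows = np.nanmean(vals, axis=1)
        cols = np.nanmean(vals, axis=0)
    return Margins(overall, rows, cols)


def connectivity_check(table: PhenotypeTable) -> bool:
    """True iff the bipartite genotype/environment graph with an edge per
    observed cell is connected.

    A disconnected table does not support a unique global additive fit.
    """
    g, e = table.shape
    gi, ej = np.nonzero(table.observed)
    n = g + e
    adj = coo_matrix((np.ones(gi.size), (gi, g + ej)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return ncomp == 1


def summarize(table: PhenotypeTable) -> TableSummary:
    """Counts of genotypes/environments and percent missing (one decimal)."""
    pct = 100.0 * table.n_missing / table.values.size
    return TableSummary(table.n_genotypes, table.n_environments, round(pct, 1))
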