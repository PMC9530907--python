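"""Benchmark models for a two-way table of phenotype means.

Four classical models are fitted over the observed cells only:

* additive (no-interaction): value = mu + G_i + E_j + error
* cell means (all-interaction): one parameter per observed cell
* regression on the mean (Finlay-Wilkinson): a genotype-specific slope on the
  environment effect absorbs part of the interaction
* AMMI: multiplicative interaction terms from an SVD of additive residuals,
  with Gollob degrees of freedom per term

Each fit carries a sequential (Type I) ANOVA table: G entered before E, then
model-specific interaction terms, then Error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phenotype_table import PhenotypeTable, connectivity_check

_NEG_SS_TOL = 1e-8


class DisconnectedTableError(ValueError):
    """The observed-cell bipartite graph is disconnected; global additive
    effects are not uniquely estimable."""


class RankDeficiencyError(ValueError):
    """The additive design matrix is rank-deficient."""


@dataclass(frozen=True)
class AnovaTable:
    """Ordered (term, df, SS) rows for one model."""

    title: str
    rows: tuple[tuple[str, int, float], ...]

    def df(self, term: str) -> int:
        for name, df, _ in self.rows:
            if name == term:
                return df
        raise KeyError(term)

    def ss(self, term: str) -> float:
        for name, _, ss in self.rows:
            if name == term:
                return ss
        raise KeyError(term)

    def to_dict(self) -> dict:
        return {
            "model": self.title,
            "rows": [{"term": t, "df": d, "ss": s} for t, d, s in self.rows],
        }


def _additive_lstsq(y: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    n_rows: int, n_cols: int) -> tuple[float, np.ndarray, np.ndarray, float, int]:
    """Least-squares additive fit on (row, col, y) triples.

    Returns (mu, row_effects, col_effects, sse, rank) with sum-to-zero
    effects.  ``rows``/``cols`` are dense 0-based codes.
    """
    n = y.size
    p = 1 + (n_rows - 1) + (n_cols - 1)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for i in range(1, n_rows):
        X[rows == i, i] = 1.0
    for j in range(1, n_cols):
        X[cols == j, n_rows - 1 + j] = 1.0
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    sse = float(np.square(y - fitted).sum())
    g_ref = np.concatenate(([0.0], coef[1:n_rows]))
    e_ref = np.concatenate(([0.0], coef[n_rows:]))
    g_bar, e_bar = g_ref.mean(), e_ref.mean()
    mu = float(coef[0] + g_bar + e_bar)
    return mu, g_ref - g_bar, e_ref - e_bar, sse, int(rank)


@dataclass(frozen=True)
class AdditiveFit:
    """Global no-interaction fit mu + G_i + E_j on observed cells.

    Effects satisfy sum-to-zero constraints over their (fully observed by
    table invariant) supports; residuals are defined only on observed cells.
    """

    table: PhenotypeTable
    mu: float
    g_effects: np.ndarray
    e_effects: np.ndarray
    anova: AnovaTable

    def fitted_matrix(self) -> np.ndarray:
        """Fitted values at every position (also unobserved ones)."""
        return self.mu + self.g_effects[:, None] + self.e_effects[None, :]

    def residual_matrix(self) -> np.ndarray:
        """Residuals at observed positions, NaN elsewhere."""
        res = self.table.values - self.fitted_matrix()
        return np.where(self.table.observed, res, np.nan)

    @property
    def error_ss(self) -> float:
        return self.anova.ss("Error")

    @property
    def error_df(self) -> int:
        return self.anova.df("Error")


@dataclass(frozen=True)
class FWFit:
    """Finlay-Wilkinson regression-on-the-mean fit."""

    additive: AdditiveFit
    slopes: np.ndarray
    inestimable_genotypes: tuple[str, ...]
    anova: AnovaTable


@dataclass(frozen=True)
class AMMIFit:
    """AMMI fit: additive main effects plus K multiplicative terms."""

    additive: AdditiveFit
    K: int
    genotype_scores: np.ndarray   # (|I|, K) left factors scaled by sqrt(sv)
    environment_scores: np.ndarray  # (|J|, K)
    term_ss: np.ndarray
    anova: AnovaTable


def fit_additive(table: PhenotypeTable) -> AdditiveFit:
    """Fit the additive model and build its sequential ANOVA table.

    SS_G = SSE(mu) - SSE(mu+G); SS_E = SSE(mu+G) - SSE(mu+G+E);
    Error df = N_obs - (|I|-1) - (|J|-1) - 1.
    """
    if not connectivity_check(table):
        raise DisconnectedTableError(
            "observed-cell graph is disconnected; additive effects not estimable"
        )
    g, e = table.shape
    gi, ej = np.nonzero(table.observed)
    y = table.values[gi, ej]
    mu, g_eff, e_eff, sse_full, rank = _additive_lstsq(y, gi, ej, g, e)
    if rank < 1 + (g - 1) + (e - 1):
        raise RankDeficiencyError("additive design matrix is rank-deficient")
    n_obs = y.size
    sse_mu = float(np.square(y - y.mean()).sum())
    # per-genotype means model
    row_means = np.bincount(gi, weights=y, minlength=g) / np.bincount(gi, minlength=g)
    sse_g = float(np.square(y - row_means[gi]).sum())
    ss_g = max(sse_mu - sse_g, 0.0)
    ss_e = max(sse_g - sse_full, 0.0)
    err_df = n_obs - (g - 1) - (e - 1) - 1
    anova = AnovaTable("No-interaction model", (
        ("G", g - 1, ss_g),
        ("E", e - 1, ss_e),
        ("Error", err_df, sse_full),
    ))
    return AdditiveFit(table, mu, g_eff, e_eff, anova)


def fit_cell_means(table: PhenotypeTable) -> AnovaTable:
    """ANOVA of the all-interaction (cell means) model.

    On a table of means this model fits every observed cell exactly: the GEI
    row takes over the additive model's Error df and SS, and Error is (0, 0).
    """
    add = fit_additive(table)
    return AnovaTable("All-interaction model", (
        ("G", add.anova.df("G"), add.anova.ss("G")),
        ("E", add.anova.df("E"), add.anova.ss("E")),
        ("GEI", add.error_df, add.error_ss),
        ("Error", 0, 0.0),
    ))


def fit_finlay_wilkinson(table: PhenotypeTable) -> FWFit:
    """Two-stage regression-on-the-mean fit.

    After the additive fit, each genotype's residuals are regressed (no
    intercept) on the estimated environment effects over that genotype's
    observed environments.  Genotypes observed in fewer than two environments
    get slope 0 and are flagged.
    """
    add = fit_additive(table)
    g, e = table.shape
    res = add.residual_matrix()
    ehat = add.e_effects
    slopes = np.zeros(g)
    inestimable: list[str] = []
    ss_ind = 0.0
    for i in range(g):
        obs = table.observed[i]
        denom = float(np.square(ehat[obs]).sum())
        if obs.sum() < 2 or denom <= 0.0:
            inestimable.append(table.genotype_ids[i])
            continue
        b = float(np.dot(res[i, obs], ehat[obs])) / denom
        slopes[i] = b
        ss_ind += b * b * denom
    err_ss = add.error_ss - ss_ind
    if err_ss < 0:
        if -err_ss < _NEG_SS_TOL * max(add.error_ss, 1.0):
            err_ss = 0.0
        else:
            raise ValueError(f"negative FW error SS: {err_ss}")
    err_df = add.error_df - (g - 1)
    anova = AnovaTable("Regression on mean model", (
        ("G", add.anova.df("G"), add.anova.ss("G")),
        ("E", add.anova.df("E"), add.anova.ss("E")),
        ("GEI Ind", g - 1, ss_ind),
        ("Error", err_df, err_ss),
    ))
    return FWFit(add, slopes, tuple(inestimable), anova)


def gollob_df(g: int, e: int, k: int) -> int:
    """Degrees of freedom of the k-th multiplicative AMMI term: g + e - 1 - 2k."""
    if not 1 <= k <= min(g - 1, e - 1):
        raise ValueError(f"k must be in [1, {min(g - 1, e - 1)}], got {k}")
    return g + e - 1 - 2 * k


def fit_ammi(table: PhenotypeTable, K: int) -> AMMIFit:
    """Fit AMMI with K multiplicative terms.

    Additive residuals are assembled into a complete matrix with unobserved
    positions set to 0 (their conditional expectation under the additive
    model), decomposed by SVD, and each term's SS is accumulated over observed
    cells only.  ANOVA rows PC1..PCK carry Gollob df.
    """
    add = fit_additive(table)
    g, e = table.shape
    if not 1 <= K <= min(g - 1, e - 1):
        raise ValueError(f"K must be in [1, {min(g - 1, e - 1)}], got {K}")
    R = np.where(table.observed, add.residual_matrix(), 0.0)
    u, s, vt = np.linalg.svd(R, full_matrices=False)
    term_ss = np.empty(K)
    rows: list[tuple[str, int, float]] = [
        ("G", add.anova.df("G"), add.anova.ss("G")),
        ("E", add.anova.df("E"), add.anova.ss("E")),
    ]
    gscore = np.empty((g, K))
    escore = np.empty((e, K))
    df_used = 0
    for k in range(K):
        comp = s[k] * np.outer(u[:, k], vt[k])
        term_ss[k] = float(np.square(comp[table.observed]).sum())
        root = np.sqrt(s[k])
        gscore[:, k] = root * u[:, k]
        escore[:, k] = root * vt[k]
        dfk = gollob_df(g, e, k + 1)
        df_used += dfk
        rows.append((f"PC{k + 1}", dfk, term_ss[k]))
    err_ss = add.error_ss - float(term_ss.sum())
    if err_ss < 0:
        if -err_ss < _NEG_SS_TOL * max(add.error_ss, 1.0):
            err_ss = 0.0
        else:
            raise ValueError(f"negative AMMI error SS: {err_ss}")
    rows.append(("Error", add.error_df - df_used, err_ss))
    anova = AnovaTable("AMMI model", tuple(rows))
    return AMMIFit(add, K, gscore, escore, term_ss, anova)


def render_anova_report(tables: Sequence[AnovaTable], fmt: str = "text") -> str:
    """Render stacked ANOVA blocks as text or JSON.

    df are printed as integers; SS both at full precision (JSON) and rounded
    for the text view.
    """
    if not tables:
        raise ValueError("no ANOVA tables to render")
    if fmt == "json":
        return json.dumps([t.to_dict() for t in tables], indent=2)
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines: list[str] = []
    width = max(len(name) for t in tables for name, _, _ in t.rows)
    width = max(width, 4)
    for t in tables:
        lines.append(f"== {t.title} ==")
        lines.append(f"{'Term':<{width}}  {'df':>8}  {'SS':>18}")
        for name, df, ss in t.rows:
            lines.append(f"{name:<{width}}  {df:>8d}  {ss:>18,.2f}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
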