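"""Synthetic phenotype tables with planted block-interaction structure.

Tables are generated as mu + G_i + E_j + GEI_ij + noise, where the
interaction is constant within planted (row cluster, column cluster) cells
(``cell_constant``) or varies by environment within each row cluster
(``column_within_block``).  Structured missing-not-at-random masks emulate
trials where each genotype group is tested in only a subset of environments.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .biclustering import Partition
from .phenotype_table import PhenotypeTable, connectivity_check


class InfeasibleMissingnessError(ValueError):
    """Requested missing rate cannot keep every row and column observed."""


GEI_MODES = ("cell_constant", "column_within_block")
MISSING_MECHANISMS = ("none", "uniform", "cluster_mnar")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic table.

    ``gei_scale`` is the standard deviation of the planted interaction draws
    before double-centering; ``noise_sd`` the residual standard deviation.
    """

    n_genotypes: int
    n_environments: int
    n_row_clusters: int
    n_col_clusters: int
    mu: float = 100.0
    sd_g: float = 5.0
    sd_e: float = 5.0
    gei_mode: str = "cell_constant"
    gei_scale: float = 10.0
    noise_sd: float = 1.0
    missing_mechanism: str = "none"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_row_clusters > self.n_genotypes or self.n_col_clusters > self.n_environments:
            raise ValueError("planted cluster counts exceed table dimensions")
        if min(self.n_row_clusters, self.n_col_clusters) < 1:
            raise ValueError("cluster counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.gei_mode not in GEI_MODES:
            raise ValueError(f"gei_mode must be one of {GEI_MODES}")
        if self.missing_mechanism not in MISSING_MECHANISMS:
            raise ValueError(f"missing_mechanism must be one of {MISSING_MECHANISMS}")
        if self.noise_sd < 0 or self.gei_scale < 0 or self.sd_g < 0 or self.sd_e < 0:
            raise ValueError("scales must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure behind a generated table."""

    partition: Partition
    g_effects: np.ndarray
    e_effects: np.ndarray
    gei: np.ndarray          # full |I| x |J| planted interaction matrix
    noiseless: np.ndarray    # mu + G + E + GEI at every position
    noise_sd: float


def _balanced_assignment(rng: np.random.Generator, n_items: int, k: int) -> np.ndarray:
    """Shuffle items into k groups of near-equal size (all nonempty)."""
    base = np.arange(n_items) % k
    return base[rng.permutation(n_items)]


def _double_center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()


def _min_axis_separation(a: np.ndarray, axis: int) -> float:
    """Smallest RMS distance between any two slices along ``axis``."""
    b = a if axis == 0 else a.T
    k = b.shape[0]
    if k < 2:
        return np.inf
    return min(
        float(np.sqrt(np.mean((b[i] - b[j]) ** 2)))
        for i in range(k) for j in range(i + 1, k)
    )


def _draw_gamma(rng: np.random.Generator, shape: tuple[int, int], scale: float,
                check_cols: bool, min_sep_frac: float = 0.6,
                max_tries: int = 1000) -> np.ndarray:
    """Gaussian double-centered interaction draws, rescaled so their RMS is
    exactly ``scale``.

    Double-centering can leave the drawn contrasts much weaker than the
    nominal scale, so draws are rejected until every pair of cluster profiles
    is at least ``min_sep_frac * scale`` apart (RMS); when the geometry makes
    that impossible the most separated draw seen is kept.
    """
    best, best_sep = None, -np.inf
    for _ in range(max_tries):
        gamma = _double_center(rng.normal(0.0, scale, size=shape))
        rms = float(np.sqrt(np.mean(gamma ** 2)))
        if rms <= 0:
            return gamma  # degenerate geometry (single cluster): no interaction
        gamma *= scale / rms
        sep = _min_axis_separation(gamma, 0)
        if check_cols:
            sep = min(sep, _min_axis_separation(gamma, 1))
        if sep >= min_sep_frac * scale:
            return gamma
        if sep > best_sep:
            best, best_sep = gamma, sep
    assert best is not None
    return best


def _mask_uniform(rng: np.random.Generator, shape: tuple[int, int], rate: float) -> np.ndarray:
    return rng.random(shape) >= rate


#: Probability that a genotype skips each environment in its row cluster's
#: disfavored subset (the structured MNAR component).
_MNAR_DROP_PROB = 0.6


def _mask_cluster_mnar(rng: np.random.Generator, row_asg: np.ndarray,
                       n_env: int, rate: float) -> np.ndarray:
    """Cluster-driven MNAR: each row cluster has a cluster-specific subset of
    disfavored environments that its genotypes skip with high probability;
    independent dropout tops missingness up to ``rate``."""
    n_gen = row_asg.size
    observed = np.ones((n_gen, n_env), dtype=bool)
    # structured part targets roughly half the requested rate
    n_sub = int(round(0.5 * rate * n_env / _MNAR_DROP_PROB))
    n_sub = max(1, min(n_sub, n_env - 1))
    for p in np.unique(row_asg):
        subset = rng.choice(n_env, size=n_sub, replace=False)
        members = np.flatnonzero(row_asg == p)
        drops = rng.random((members.size, n_sub)) < _MNAR_DROP_PROB
        for k, j in enumerate(subset):
            observed[members[drops[:, k]], j] = False
    struct_rate = 1.0 - observed.mean()
    if struct_rate < rate:
        extra = (rate - struct_rate) / (1.0 - struct_rate)
        observed &= rng.random(observed.shape) >= extra
    return observed


def generate(spec: SyntheticSpec) -> tuple[PhenotypeTable, GroundTruth]:
    """Generate a table and its ground truth from ``spec``.

    Masks that would leave a row or column with no observations (or a
    disconnected table) are redrawn; after repeated failed attempts the rate is
    declared infeasible.
    """
    rng = np.random.default_rng(spec.seed)
    g, e = spec.n_genotypes, spec.n_environments
    row_asg = _balanced_assignment(rng, g, spec.n_row_clusters)
    col_asg = _balanced_assignment(rng, e, spec.n_col_clusters)
    partition = Partition(row_asg, col_asg, spec.n_row_clusters, spec.n_col_clusters)

    g_eff = rng.normal(0.0, spec.sd_g, size=g) if spec.sd_g > 0 else np.zeros(g)
    e_eff = rng.normal(0.0, spec.sd_e, size=e) if spec.sd_e > 0 else np.zeros(e)
    g_eff -= g_eff.mean()
    e_eff -= e_eff.mean()

    if spec.gei_scale > 0:
        if spec.gei_mode == "cell_constant":
            gamma = _draw_gamma(rng, (spec.n_row_clusters, spec.n_col_clusters),
                                spec.gei_scale, check_cols=True)
            gei = gamma[row_asg[:, None], col_asg[None, :]]
        else:  # column_within_block: interaction depends on j within each block
            gamma = _draw_gamma(rng, (spec.n_row_clusters, e),
                                spec.gei_scale, check_cols=False)
            gei = gamma[row_asg, :]
    else:
        gei = np.zeros((g, e))

    noiseless = spec.mu + g_eff[:, None] + e_eff[None, :] + gei
    noise = rng.normal(0.0, spec.noise_sd, size=(g, e)) if spec.noise_sd > 0 else np.zeros((g, e))
    values = noiseless + noise

    observed = _draw_mask(rng, spec, row_asg, col_asg)
    genotype_ids = tuple(f"g{i + 1}" for i in range(g))
    environment_ids = tuple(f"e{j + 1}" for j in range(e))
    table = PhenotypeTable(genotype_ids, environment_ids,
                           np.where(observed, values, np.nan), observed)
    truth = GroundTruth(partition, g_eff, e_eff, gei, noiseless, spec.noise_sd)
    return table, truth


def _draw_mask(rng: np.random.Generator, spec: SyntheticSpec,
               row_asg: np.ndarray, col_asg: np.ndarray) -> np.ndarray:
    g, e = spec.n_genotypes, spec.n_environments
    if spec.missing_mechanism == "none" or spec.missing_rate == 0.0:
        return np.ones((g, e), dtype=bool)
    n_col_clusters = int(col_asg.max()) + 1
    for _ in range(2000):
        if spec.missing_mechanism == "uniform":
            observed = _mask_uniform(rng, (g, e), spec.missing_rate)
        else:
            observed = _mask_cluster_mnar(rng, row_asg, e, spec.missing_rate)
        if not (observed.any(axis=1).all() and observed.any(axis=0).all()):
            continue
        if spec.missing_mechanism == "cluster_mnar":
            # every genotype is trialed in at least one environment of each
            # planted environment group (varieties span the target range)
            cov = np.stack([observed[:, col_asg == l].sum(axis=1)
                            for l in range(n_col_clusters)], axis=1)
            if (cov < 1).any():
                continue
        return observed
    raise InfeasibleMissingnessError(
        f"could not realize missing rate {spec.missing_rate} with every "
        "row and column observed")


def mask_cells_exact(table: PhenotypeTable, n_missing: int, seed: int = 0,
                     require_connected: bool = True) -> PhenotypeTable:
    """Mask exactly ``n_missing`` currently observed cells of ``table``.

    Redraws until every row/column keeps at least one observation (and the
    table stays connected when ``require_connected``).  Useful for rebuilding
    missingness patterns with known cell counts.
    """
    if n_missing < 0 or n_missing > table.n_observed:
        raise ValueError("n_missing out of range")
    rng = np.random.default_rng(seed)
    flat_obs = np.flatnonzero(table.observed.ravel())
    for _ in range(500):
        drop = rng.choice(flat_obs, size=n_missing, replace=False)
        observed = table.observed.copy()
        observed.ravel()[drop] = False
        if not (observed.any(axis=1).all() and observed.any(axis=0).all()):
            continue
        masked = PhenotypeTable(table.genotype_ids, table.environment_ids,
                                np.where(observed, table.values, np.nan), observed)
        if require_connected and not connectivity_check(masked):
            continue
        return masked
    raise InfeasibleMissingnessError(
        f"could not mask {n_missing} cells without emptying a row or column")


def partition_recovery_score(found: Partition, truth: Partition) -> tuple[float, float]:
    """Adjusted Rand index of found vs. planted partitions, per axis.

    1.0 means identical up to cluster relabeling; independent random
    assignments score near 0.
    """
    if found.shape != truth.shape:
        raise ValueError(f"partition shapes differ: {found.shape} vs {truth.shape}")
    row = adjusted_rand_score(truth.row_assignment, found.row_assignment)
    col = adjusted_rand_score(truth.col_assignment, found.col_assignment)
    return (float(row), float(col))
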