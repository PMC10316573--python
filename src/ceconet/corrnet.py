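"""Signed Spearman co-occurrence networks.

An edge between two taxa is a "robust correlation": the tie-aware Spearman
coefficient must exceed the magnitude threshold (default |rho| > 0.7,
strict) AND the associated P-value — Benjamini–Hochberg adjusted by default
— must fall below alpha (default 0.05, strict).  Edges carry the rho weight
and its sign; topology downstream is computed sign-agnostically.

P-values use the t approximation with n - 2 degrees of freedom, which is
the standard choice at the per-group sample sizes of feeding trials
(n = 16); a seeded permutation option is available for small panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .tables import AbundanceTable

log = logging.getLogger(__name__)


def midrank(vector) -> np.ndarray:
    """Average ("mid") ranks of a numeric vector; ties get the mean of the
    ranks they span, so ranks always sum to n(n+1)/2."""
    x = np.asarray(vector, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("midrank requires a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("midrank requires finite values")
    if np.all(x == x[0]):
        log.warning("midrank of an all-identical vector; downstream rho is undefined")
    return stats.rankdata(x, method="average")


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("P-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _bh_adjust_symmetric(p_raw: pd.DataFrame) -> pd.DataFrame:
    """BH over the strictly upper triangle of a symmetric P matrix, mirrored."""
    p = p_raw.to_numpy()
    iu = np.triu_indices_from(p, k=1)
    adj = np.zeros_like(p)
    adj[iu] = bh_adjust(p[iu])
    adj = adj + adj.T
    return pd.DataFrame(adj, index=p_raw.index, columns=p_raw.columns)


@dataclass
class CorrelationMatrixSet:
    """Symmetric rho / raw-P / BH-adjusted-P matrices over one taxon panel."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_samples: int
    constant_taxa: tuple = ()

    @property
    def taxon_ids(self) -> list:
        return list(self.rho.index)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided P from the t approximation with n - 2 df."""
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def spearman_matrix(
    table,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> CorrelationMatrixSet:
    """All-pairs tie-aware Spearman correlation of taxa across samples.

    rho is the Pearson correlation of midranks.  Pairs involving a constant
    taxon get rho = 0, P = 1 and the taxon is flagged.  With
    ``n_permutations`` set, raw P-values are estimated by seeded permutation
    (columns permuted independently) instead of the t approximation.
    """
    data = table.data if isinstance(table, AbundanceTable) else pd.DataFrame(table)
    n, t = data.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples for Spearman P-values, got {n}")
    if t < 2:
        raise ValueError("need at least 2 taxa")

    values = data.to_numpy(dtype=float)
    ranks = np.apply_along_axis(lambda c: stats.rankdata(c, method="average"), 0, values)
    constant = values.std(axis=0) == 0
    constant_taxa = tuple(data.columns[constant])
    if constant_taxa:
        log.warning("constant taxa flagged (rho set to 0): %s", list(constant_taxa))

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho[np.isnan(rho)] = 0.0
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    if n_permutations is not None:
        rng = np.random.default_rng(seed)
        exceed = np.zeros((t, t))
        obs = np.abs(rho)
        for _ in range(int(n_permutations)):
            perm = np.empty_like(ranks)
            for j in range(t):
                perm[:, j] = ranks[rng.permutation(n), j]
            with np.errstate(invalid="ignore", divide="ignore"):
                r0 = np.corrcoef(perm, rowvar=False)
            r0 = np.nan_to_num(np.asarray(r0))
            exceed += np.abs(r0) >= obs - 1e-12
        p = (exceed + 1.0) / (n_permutations + 1.0)
    else:
        p = _t_approx_p(rho, n)
    p = (p + p.T) / 2.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    ids = data.columns
    rho_df = pd.DataFrame(rho, index=ids, columns=ids)
    p_df = pd.DataFrame(p, index=ids, columns=ids)
    p_adj = _bh_adjust_symmetric(p_df)
    return CorrelationMatrixSet(rho_df, p_df, p_adj, n_samples=n, constant_taxa=constant_taxa)


@dataclass
class NetworkConfig:
    """Edge-inclusion rule for co-occurrence networks."""

    rho_threshold: float = 0.7
    alpha: float = 0.05
    use_adjusted_p: bool = True
    drop_isolated_nodes: bool = True

    def __post_init__(self):
        if not (0 < self.rho_threshold <= 1):
            raise ValueError(f"rho_threshold must be in (0, 1], got {self.rho_threshold}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class CoNetwork:
    """Signed, thresholded co-occurrence graph for one sample group."""

    graph: nx.Graph
    group_label: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    corr: CorrelationMatrixSet,
    config: NetworkConfig | None = None,
    group_label: str | None = None,
) -> CoNetwork:
    """Threshold a correlation set into a signed network.

    Edge (i, j) is included iff |rho_ij| > rho_threshold (strict) and the
    selected P (adjusted by default) < alpha (strict).  With
    ``drop_isolated_nodes`` (default), taxa with no surviving edge are
    excluded from the node set, which is why the node count can fall below
    the taxon count.
    """
    config = config or NetworkConfig()
    p = corr.p_adj if config.use_adjusted_p else corr.p_raw
    if list(p.index) != list(corr.rho.index) or list(p.columns) != list(corr.rho.columns):
        raise ValueError("taxon ordering mismatch between rho and P matrices")

    rho = corr.rho.to_numpy()
    pv = p.to_numpy()
    ids = list(corr.rho.index)
    mask = (np.abs(rho) > config.rho_threshold) & (pv < config.alpha)
    iu = np.triu_indices_from(mask, k=1)

    g = nx.Graph()
    if not config.drop_isolated_nodes:
        g.add_nodes_from(ids)
    for i, j in zip(*iu):
        if mask[i, j]:
            r = float(rho[i, j])
            g.add_edge(ids[i], ids[j], rho=r, sign="+" if r > 0 else "-")
    log.info(
        "network %s: %d nodes, %d edges from %d taxa",
        group_label, g.number_of_nodes(), g.number_of_edges(), len(ids),
    )
    return CoNetwork(g, group_label=group_label)
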