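"""Mutual information, CLR scores and thresholded co-expression networks.

MI is the plug-in estimator on jointly discretized profiles: each profile is
cut into equal-frequency (quantile) bins computed on the pairwise-complete
overlap, with ties broken by stable input order, and the joint histogram is
evaluated in bits.  The default bin count adapts to the overlap size as
``max(2, min(10, floor(cbrt(n))))``.

CLR combines, for each pair, the two z-scores of the pair's MI against each
gene's background of MI values to all other genes:
``clr(i, j) = sqrt(max(0, z_i(j))^2 + max(0, z_j(i))^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ContractError, DegenerateInputError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 20
MAX_BINS = 10


def adaptive_n_bins(n_obs: int) -> int:
    """Overlap-adaptive bin count: cube-root rule, floored at 2, capped at 10."""
    return max(2, min(MAX_BINS, int(np.cbrt(n_obs) + 1e-9)))


def quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin labels; ties broken by stable input order."""
    n = x.shape[0]
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> float:
    """Plug-in MI (bits) of two equal-length, fully observed vectors.

    A constant vector has zero entropy, so the result is 0 by definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be equal-length 1-d vectors")
    n = x.shape[0]
    if n == 0:
        raise ContractError("empty vectors")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    k = adaptive_n_bins(n) if n_bins is None else int(n_bins)
    bx = quantile_bins(x, k)
    by = quantile_bins(y, k)
    joint = np.bincount(bx * k + by, minlength=k * k).reshape(k, k).astype(float)
    return _mi_from_joint(joint)


@dataclass
class MIMatrix:
    """All-pairs MI with the pairwise-complete overlap counts and a defined mask."""

    gene_ids: list[str]
    mi: np.ndarray
    n_overlap: np.ndarray
    defined: np.ndarray


def _mi_matrix_dense(values: np.ndarray, n_bins: int | None) -> np.ndarray:
    """Fast all-pairs MI for a fully observed matrix via joint bin counts."""
    g, s = values.shape
    k = adaptive_n_bins(s) if n_bins is None else int(n_bins)
    bins = np.empty((g, s), dtype=np.int64)
    constant = np.zeros(g, dtype=bool)
    for i in range(g):
        constant[i] = bool(np.all(values[i] == values[i, 0]))
        bins[i] = quantile_bins(values[i], k)
    indicators = [np.ascontiguousarray((bins == a).astype(np.float64)) for a in range(k)]
    marg = np.stack([ind.sum(axis=1) for ind in indicators], axis=1)  # (g, k)
    mi = np.zeros((g, g))
    n = float(s)
    for a in range(k):
        for b in range(k):
            counts = indicators[a] @ indicators[b].T  # exact small integers
            denom = np.outer(marg[:, a], marg[:, b])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = (counts / n) * np.log2(counts * n / denom)
            term[counts == 0] = 0.0
            mi += term
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    mi = (mi + mi.T) / 2.0  # enforce exact symmetry despite float summation order
    np.fill_diagonal(mi, 0.0)
    return mi


def mi_matrix(
    m: ExpressionMatrix,
    n_bins: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MIMatrix:
    """All unordered pairs; entries with overlap < ``min_overlap`` are undefined."""
    if m.n_genes < 2:
        raise DegenerateInputError("need at least 2 genes")
    g, s = m.n_genes, m.n_samples
    if m.fully_observed:
        overlap = np.full((g, g), s, dtype=np.int64)
        defined = np.full((g, g), s >= min_overlap)
        np.fill_diagonal(defined, False)
        mi = _mi_matrix_dense(m.values, n_bins) if s >= min_overlap else np.zeros((g, g))
        return MIMatrix(list(m.gene_ids), mi, overlap, defined)

    obs = m.observed
    values = m.values
    mi = np.zeros((g, g))
    overlap = (obs.astype(np.int64)) @ (obs.astype(np.int64)).T
    defined = overlap >= min_overlap
    np.fill_diagonal(defined, False)
    for i in range(g):
        for j in range(i + 1, g):
            if not defined[i, j]:
                continue
            ov = obs[i] & obs[j]
            v = mutual_information(values[i, ov], values[j, ov], n_bins)
            mi[i, j] = mi[j, i] = v
    return MIMatrix(list(m.gene_ids), mi, overlap, defined)


@dataclass
class CLRNetwork:
    """Symmetric non-negative CLR z-score matrix over retained genes."""

    gene_ids: list[str]
    clr: np.ndarray
    excluded: list[str]

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=np.int64)


MIN_BACKGROUND_VALUES = 3


def clr_scores(mim: MIMatrix) -> CLRNetwork:
    """CLR z-scores from per-gene MI background statistics.

    Genes with fewer than three defined MI values have undefined background
    statistics and are excluded (logged).  A zero background spread maps all
    of that gene's z-scores to zero.
    """
    counts = mim.defined.sum(axis=1)
    keep = counts >= MIN_BACKGROUND_VALUES
    excluded = [g for g, k in zip(mim.gene_ids, keep) if not k]
    if excluded:
        logger.info("clr_scores: excluding %d genes with <%d defined MI values",
                    len(excluded), MIN_BACKGROUND_VALUES)
    idx = np.flatnonzero(keep)
    mi = mim.mi[np.ix_(idx, idx)]
    defined = mim.defined[np.ix_(idx, idx)]
    n = idx.size
    masked = np.where(defined, mi, np.nan)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(masked, axis=1)
        sd = np.nanstd(masked, axis=1)
    z = np.zeros((n, n))
    nonzero = sd > 0
    z[nonzero, :] = (mi[nonzero, :] - mu[nonzero, None]) / sd[nonzero, None]
    z = np.maximum(z, 0.0)
    z[~defined] = 0.0
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return CLRNetwork([mim.gene_ids[i] for i in idx], clr, excluded)


def threshold_network(
    net: CLRNetwork, tau: float, keep_isolated: bool = False
) -> nx.Graph:
    """Link genes with CLR strictly above ``tau``; isolated genes dropped by default."""
    if tau < 0:
        raise ContractError("tau must be non-negative")
    g = nx.Graph(threshold=float(tau))
    ii, jj = np.nonzero(np.triu(net.clr > tau, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(net.gene_ids[i], net.gene_ids[j], weight=float(net.clr[i, j]))
    if keep_isolated:
        g.add_nodes_from(net.gene_ids)
    return g
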