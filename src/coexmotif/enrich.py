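"""Fisher's exact enrichment, BH FDR, neighborhood motif enrichment and the
two permutation nulls (random gene lists and node-label-shuffled networks).

The single-table path uses exact integer hypergeometric summation; bulk paths
use vectorized ``scipy.stats.hypergeom`` survival functions (the two agree to
floating-point rounding and are cross-checked in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ContractError
from .netanalysis import shuffle_node_labels

logger = logging.getLogger(__name__)

DEFAULT_Q_FLAG = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d): in-set/with, in-set/without, out/with, out/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ContractError("contingency counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher p: P(X >= a), X ~ Hypergeom(N, a+c, a+b).

    Exact integer summation; a single float division at the end.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    carriers = a + c
    drawn = a + b
    hi = min(carriers, drawn)
    if a == 0:
        return 1.0
    numerator = sum(comb(carriers, k) * comb(n_total - carriers, drawn - k) for k in range(a, hi + 1))
    return numerator / comb(n_total, drawn)


def fisher_exact_greater_many(
    a: np.ndarray, carriers: np.ndarray, drawn: np.ndarray, n_total
) -> np.ndarray:
    """Vectorized upper-tail hypergeometric p-values (same quantity as above)."""
    a = np.asarray(a)
    p = hypergeom.sf(a - 1, n_total, carriers, drawn)
    p = np.where(a <= 0, 1.0, p)  # a = 0 is the whole tail; also guards empty tables
    return np.clip(p, 0.0, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class EnrichmentResult:
    feature_id: str
    table: ContingencyTable
    p: float
    q: float


def set_enrichment(
    gene_set: set[str],
    universe: set[str],
    feature_map: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Fisher enrichment of every feature occurring in the universe.

    BH correction is applied across all features tested together.  Features
    absent from the gene set are still tested (their p is 1 by construction
    when a = 0).
    """
    if not universe:
        raise ContractError("universe must be non-empty")
    extra = gene_set - universe
    if extra:
        raise ContractError(f"gene_set not contained in universe: {sorted(extra)[:5]}")
    carriers_of: dict[str, int] = {}
    in_set_of: dict[str, int] = {}
    for gene in universe:
        for feat in feature_map.get(gene, ()):
            carriers_of[feat] = carriers_of.get(feat, 0) + 1
            if gene in gene_set:
                in_set_of[feat] = in_set_of.get(feat, 0) + 1
    features = sorted(carriers_of)
    if not features:
        return []
    n_total = len(universe)
    n_set = len(gene_set)
    a = np.array([in_set_of.get(f, 0) for f in features])
    k = np.array([carriers_of[f] for f in features])
    p = fisher_exact_greater_many(a, k, n_set, n_total)
    q = bh_adjust(p)
    out = []
    for i, feat in enumerate(features):
        table = ContingencyTable(
            a=int(a[i]), b=n_set - int(a[i]), c=int(k[i]) - int(a[i]),
            d=n_total - n_set - int(k[i]) + int(a[i]),
        )
        out.append(EnrichmentResult(feat, table, float(p[i]), float(q[i])))
    return out


@dataclass
class SeedEnrichment:
    seed: str
    n_neighbors: int
    results: list[EnrichmentResult]
    enriched: bool


@dataclass
class NeighborhoodEnrichmentReport:
    seeds: list[SeedEnrichment] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    q_flag: float = DEFAULT_Q_FLAG

    @property
    def n_enriched(self) -> int:
        return sum(1 for s in self.seeds if s.enriched)

    @property
    def fraction_enriched(self) -> float:
        """Fraction over all requested seeds (skipped seeds count as not enriched)."""
        denom = len(self.seeds) + len(self.skipped)
        return self.n_enriched / denom if denom else 0.0


def neighborhood_motif_enrichment(
    net: nx.Graph,
    seeds: list[str],
    gene_to_motifs: dict[str, set[str]],
    q_flag: float = DEFAULT_Q_FLAG,
) -> NeighborhoodEnrichmentReport:
    """Per-seed motif enrichment in the immediate co-expression neighborhood.

    The universe is the network's gene set minus the seed; a seed is enriched
    iff at least one motif reaches q < ``q_flag``.  Seeds absent from the
    network are skipped and logged (they still count in the group fraction's
    denominator, mirroring per-group reporting over expressed genes).
    """
    report = NeighborhoodEnrichmentReport(q_flag=q_flag)
    nodes = set(net.nodes())
    for seed in seeds:
        if seed not in nodes:
            logger.info("neighborhood enrichment: seed %s not in network, skipped", seed)
            report.skipped.append(seed)
            continue
        neighbors = set(net.neighbors(seed)) - {seed}
        universe = nodes - {seed}
        if not neighbors:
            report.seeds.append(SeedEnrichment(seed, 0, [], False))
            continue
        results = set_enrichment(neighbors, universe, gene_to_motifs)
        enriched = any(r.q < q_flag for r in results)
        report.seeds.append(SeedEnrichment(seed, len(neighbors), results, enriched))
    return report


def enriched_flags(
    net: nx.Graph,
    gene_to_motifs: dict[str, set[str]],
    q_flag: float = DEFAULT_Q_FLAG,
    seeds: list[str] | None = None,
) -> dict[str, bool]:
    """Vectorized per-gene enriched-neighborhood flags.

    Computes, for each seed gene, the same per-motif Fisher + per-seed BH
    decision as :func:`neighborhood_motif_enrichment`, but batched over all
    seeds at once so permutation nulls stay cheap.
    """
    nodes = sorted(net.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    seed_list = nodes if seeds is None else [s for s in seeds if s in index]
    motifs = sorted({m for g in nodes for m in gene_to_motifs.get(g, ())})
    if not motifs or n < 2:
        return {s: False for s in seed_list}
    midx = {m: j for j, m in enumerate(motifs)}
    member = np.zeros((n, len(motifs)), dtype=np.float64)
    for g in nodes:
        for m in gene_to_motifs.get(g, ()):
            member[index[g], midx[m]] = 1.0
    adj = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    np.fill_diagonal(adj, 0.0)
    srows = np.array([index[s] for s in seed_list], dtype=np.int64)
    a = adj[srows] @ member  # in-neighborhood carriers per (seed, motif)
    total_carriers = member.sum(axis=0)
    k = total_carriers[None, :] - member[srows]  # carriers in universe (seed removed)
    drawn = adj[srows].sum(axis=1)[:, None] * np.ones((1, len(motifs)))
    n_total = n - 1
    tested = k > 0
    p = fisher_exact_greater_many(
        np.rint(a).astype(np.int64),
        np.rint(k).astype(np.int64),
        np.rint(drawn).astype(np.int64),
        n_total,
    )
    flags: dict[str, bool] = {}
    for r, seedg in enumerate(seed_list):
        mask = tested[r]
        if drawn[r, 0] == 0 or not mask.any():
            flags[seedg] = False
            continue
        q = bh_adjust(p[r, mask])
        flags[seedg] = bool((q < q_flag).any())
    return flags


@dataclass
class EmpiricalNull:
    samples: np.ndarray
    observed: float
    p_empirical: float


def empirical_p(samples: np.ndarray, observed: float) -> float:
    """(r + 1) / (n + 1) where r = #(null >= observed)."""
    samples = np.asarray(samples, dtype=float)
    r = int((samples >= observed).sum())
    return (r + 1) / (samples.size + 1)


def random_genelist_null(
    net: nx.Graph,
    gene_to_motifs: dict[str, set[str]],
    observed: float,
    n_lists: int = 1000,
    list_size: int = 100,
    seed: int = 0,
    q_flag: float = DEFAULT_Q_FLAG,
    flags: dict[str, bool] | None = None,
) -> EmpiricalNull:
    """Null of enriched fractions over random gene lists drawn from the network."""
    nodes = sorted(net.nodes())
    if len(nodes) < list_size:
        raise ContractError("network smaller than list_size")
    if flags is None:
        flags = enriched_flags(net, gene_to_motifs, q_flag)
    flag_arr = np.array([flags[g] for g in nodes], dtype=float)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_lists)
    for i in range(n_lists):
        pick = rng.choice(len(nodes), size=list_size, replace=False)
        samples[i] = flag_arr[pick].mean()
    return EmpiricalNull(samples, observed, empirical_p(samples, observed))


def shuffled_network_null(
    net: nx.Graph,
    seeds: list[str],
    gene_to_motifs: dict[str, set[str]],
    observed: float,
    n_shuffles: int = 99,
    seed: int = 0,
    q_flag: float = DEFAULT_Q_FLAG,
) -> EmpiricalNull:
    """Null of the seed-group enriched fraction in label-shuffled networks."""
    if n_shuffles < 1:
        raise ContractError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n_seeds = len(seeds)
    samples = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = shuffle_node_labels(net, int(rng.integers(0, 2**63 - 1)))
        flags = enriched_flags(shuffled, gene_to_motifs, q_flag, seeds=seeds)
        samples[i] = sum(flags.values()) / n_seeds if n_seeds else 0.0
    return EmpiricalNull(samples, observed, empirical_p(samples, observed))


def parameter_sweep(
    clr_variants: dict,
    hits,
    categories: dict[str, set[str]],
    taus=(3.0, 4.0, 5.0),
    q_grid=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
    q_flag: float = DEFAULT_Q_FLAG,
    n_shuffles: int = 0,
    seed: int = 0,
    expressed_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Fraction of enriched TF-group neighborhoods per (variant, tau, mapping q).

    ``clr_variants`` maps a variant name (e.g. ``complete``/``subset``) to a
    :class:`coexmotif.inference.CLRNetwork`; ``hits`` is a scanned
    :class:`MotifHit` list.  Each group's fraction uses the group's
    expressed-gene count as denominator.  With ``n_shuffles > 0`` an
    empirical p against the label-shuffled null is attached.
    """
    from .inference import threshold_network
    from .scan import gene_motif_map

    rows = []
    groups = sorted({c for cats in categories.values() for c in cats})
    for variant, clrnet in sorted(clr_variants.items()):
        for tau in taus:
            net = threshold_network(clrnet, tau)
            for q_threshold in q_grid:
                gm = gene_motif_map(hits, q_threshold)
                flags_all = enriched_flags(net, gm.gene_to_motifs, q_flag)
                for group in groups:
                    seeds = sorted(
                        g for g, cats in categories.items()
                        if group in cats and (expressed_genes is None or g in expressed_genes)
                    )
                    n_enriched = sum(bool(flags_all.get(s, False)) for s in seeds)
                    fraction = n_enriched / len(seeds) if seeds else 0.0
                    p_emp = np.nan
                    if n_shuffles > 0 and seeds:
                        null = shuffled_network_null(
                            net, seeds, gm.gene_to_motifs, fraction,
                            n_shuffles=n_shuffles, seed=seed, q_flag=q_flag,
                        )
                        p_emp = null.p_empirical
                    rows.append({
                        "variant": variant, "tau": tau, "q_threshold": q_threshold,
                        "group": group, "n_seeds": len(seeds),
                        "n_enriched": n_enriched, "fraction": fraction,
                        "p_empirical": p_emp,
                    })
    return pd.DataFrame(rows)
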