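"""Motif deduplication: IUPAC consensus, ungapped similarity, clustering and
central-motif selection.

Similarity compares two IUPAC consensus strings over all ungapped offsets of
one against the other (both orientations).  Aligned positions match iff
their base sets intersect; a match contributes ``2 - log2(|union|)`` (full
weight 2 for identical determinate bases, 0 for anything against N).  The
summed weight is normalized by ``2 * min(len_a, len_b)`` so the score lies
in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ContractError
from .meme import PSSM
from .netanalysis import Clustering, mcl_cluster

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_OF_BITS = {
    1: "A", 2: "C", 4: "G", 8: "T", 3: "M", 5: "R", 9: "W", 6: "S",
    10: "Y", 12: "K", 7: "V", 11: "H", 13: "D", 14: "B", 15: "N",
}
_BITS_OF_CODE = {c: b for b, c in _CODE_OF_BITS.items()}
# complement swaps A<->T and C<->G, i.e. reverses the 4-bit pattern
_COMP_BITS = {b: int(f"{b:04b}"[::-1], 2) for b in range(1, 16)}
_MATCH_WEIGHT = {u: 2.0 - np.log2(bin(u).count("1")) for u in range(1, 16)}

DEFAULT_INCLUDE_THRESHOLD = 0.3
DEFAULT_MIN_OVERLAP = 5
DEFAULT_SCORE_THRESHOLD = 0.7


@dataclass(frozen=True)
class ConsensusMotif:
    """A motif reduced to one IUPAC character per column."""

    id: str
    iupac: str

    def __post_init__(self) -> None:
        bad = [c for c in self.iupac if c not in _BITS_OF_CODE]
        if bad:
            raise ContractError(f"motif {self.id}: invalid IUPAC characters {bad}")

    def bits(self) -> list[int]:
        return [_BITS_OF_CODE[c] for c in self.iupac]

    def reverse_complement_bits(self) -> list[int]:
        return [_COMP_BITS[b] for b in reversed(self.bits())]


def consensus_from_pssm(
    m: PSSM, include_threshold: float = DEFAULT_INCLUDE_THRESHOLD
) -> ConsensusMotif:
    """IUPAC code of the base set with probability >= threshold per column.

    An empty set (all probabilities below threshold) yields ``N``.
    """
    if not 0 < include_threshold <= 0.5:
        raise ContractError("include_threshold must lie in (0, 0.5]")
    chars = []
    for row in m.probs:
        bits = 0
        for b, base in enumerate("ACGT"):
            if row[b] >= include_threshold:
                bits |= _BITS[base]
        chars.append(_CODE_OF_BITS[bits] if bits else "N")
    return ConsensusMotif(m.id, "".join(chars))


@dataclass(frozen=True)
class SimilarityMatch:
    score: float
    offset: int  # position of b[0] relative to a[0] in the best alignment
    orientation: str  # "forward" | "reverse"


def _alignment_score(a_bits: list[int], b_bits: list[int], offset: int) -> float:
    total = 0.0
    for i, bb in enumerate(b_bits):
        j = offset + i
        if 0 <= j < len(a_bits):
            inter = a_bits[j] & bb
            if inter:
                total += _MATCH_WEIGHT[a_bits[j] | bb]
    return total


def motif_similarity(
    a: ConsensusMotif, b: ConsensusMotif, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SimilarityMatch:
    """Best ungapped alignment score in [0, 1] over offsets and orientations.

    Ties prefer the smaller offset, and forward orientation before reverse.
    """
    if min_overlap < 3:
        raise ContractError("min_overlap must be >= 3")
    la, lb = len(a.iupac), len(b.iupac)
    if min_overlap > la or min_overlap > lb:
        raise ContractError("min_overlap exceeds a motif length; no alignment possible")
    a_bits = a.bits()
    norm = 2.0 * min(la, lb)
    best = SimilarityMatch(-1.0, 0, "forward")
    for orientation, b_bits in (("forward", b.bits()), ("reverse", b.reverse_complement_bits())):
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            overlap = min(la, offset + lb) - max(0, offset)
            if overlap < min_overlap:
                continue
            score = _alignment_score(a_bits, b_bits, offset) / norm
            if score > best.score + 1e-12:
                best = SimilarityMatch(score, offset, orientation)
    return SimilarityMatch(max(best.score, 0.0), best.offset, best.orientation)


def build_similarity_network(
    motifs: list[ConsensusMotif],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> nx.Graph:
    """All-pairs similarity graph; link iff score >= threshold."""
    g = nx.Graph(score_threshold=float(score_threshold))
    for m in motifs:
        g.add_node(m.id, iupac=m.iupac)
    ordered = sorted(motifs, key=lambda m: m.id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            match = motif_similarity(ordered[i], ordered[j], min_overlap)
            if match.score >= score_threshold:
                g.add_edge(
                    ordered[i].id, ordered[j].id, weight=match.score,
                    offset=match.offset, orientation=match.orientation,
                )
    return g


@dataclass
class CentralMotifLibrary:
    clusters: dict[str, int]  # motif id -> cluster id
    representatives: dict[int, str]  # cluster id -> central motif id

    @property
    def central_ids(self) -> list[str]:
        return sorted(self.representatives.values())

    def partition_sets(self) -> set[frozenset]:
        groups: dict[int, set[str]] = {}
        for mid, cid in self.clusters.items():
            groups.setdefault(cid, set()).add(mid)
        return {frozenset(v) for v in groups.values()}


def central_motifs(
    net: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> CentralMotifLibrary:
    """MCL clustering plus per-cluster betweenness-central representatives.

    Betweenness is computed on each cluster's induced subgraph; ties (e.g. a
    clique's all-zero betweenness) fall back to highest degree, then to the
    lexicographically smallest id.
    """
    clustering: Clustering = mcl_cluster(net, inflation, max_iter, tol, prune)
    reps: dict[int, str] = {}
    for cid, members in sorted(clustering.clusters().items()):
        sub = net.subgraph(members)
        if len(members) >= 3:
            betw = nx.betweenness_centrality(sub, normalized=True, weight=None)
        else:
            betw = {m: 0.0 for m in members}
        deg = dict(sub.degree())
        reps[cid] = min(members, key=lambda m: (-betw[m], -deg.get(m, 0), m))
    return CentralMotifLibrary(dict(clustering.partition), reps)


def dedup_library(
    pssms: list[PSSM],
    include_threshold: float = DEFAULT_INCLUDE_THRESHOLD,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    inflation: float = 2.0,
) -> tuple[CentralMotifLibrary, nx.Graph]:
    """Convenience wrapper: consensus -> similarity network -> central motifs."""
    consensus = [consensus_from_pssm(m, include_threshold) for m in pssms]
    net = build_similarity_network(consensus, score_threshold, min_overlap)
    return central_motifs(net, inflation=inflation), net
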