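"""Promoter extraction and FIMO-style PSSM scanning.

Scores are log2 odds of the pseudocount-regularized motif probabilities
against a background model.  P-values are exact under that background: each
column's log-odds values are discretized on a shared grid (``granularity``
bins per column range) and the null score distribution is obtained by
column-wise convolution; the p-value of a score is the null upper-tail mass.
Per motif, Benjamini-Hochberg correction over every scanned position on both
strands converts p-values into q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .enrich import bh_adjust
from .errors import ContractError, ParseError, UnknownContigError
from .meme import PSSM
from .synthetic import GeneFeature, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_LENGTH = 400
DEFAULT_GRANULARITY = 1000
DEFAULT_SCAN_Q = 0.3

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0, 4])


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ContractError(f"sequence contains non-ACGTN base {exc.args[0]!r}") from None


@dataclass
class Promoter:
    """An upstream window: gene-oriented sequence plus contig coordinates.

    ``start``/``end`` are 0-based half-open on the contig; for minus-strand
    genes ``seq`` is the reverse complement of that window.
    """

    gene: str
    seq: str
    contig: str
    start: int
    end: int
    strand: str


PromoterSet = dict[str, Promoter]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3(path) -> list[GeneFeature]:
    """Read gene features (type ``gene``) from a GFF3 file."""
    feats: list[GeneFeature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            if cols[6] not in "+-":
                raise ParseError(f"{path}:{lineno}: gene {gene_id} lacks a strand")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            feats.append(GeneFeature(gene_id, cols[0], start, end, cols[6]))
    return feats


def extract_promoters(
    genome: dict[str, str],
    features: list[GeneFeature],
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> PromoterSet:
    """Upstream windows of each gene, truncated at contig boundaries.

    Plus strand: ``[start - length, start - 1]``; minus strand: the
    ``length`` bases after the gene end, reverse complemented.  Zero-length
    windows (gene flush with the contig edge) are skipped with a warning.
    """
    out: PromoterSet = {}
    for f in features:
        if f.contig not in genome:
            raise UnknownContigError(f"gene {f.gene_id}: contig {f.contig!r} not in genome")
        contig_seq = genome[f.contig]
        clen = len(contig_seq)
        if f.strand == "+":
            end0 = f.start - 1  # 0-based exclusive end of the window
            start0 = max(0, end0 - length)
            window = contig_seq[start0:end0]
        else:
            start0 = f.end
            end0 = min(clen, f.end + length)
            window = reverse_complement(contig_seq[start0:end0])
        if not window:
            logger.warning("gene %s: zero-length promoter, skipped", f.gene_id)
            continue
        out[f.gene_id] = Promoter(f.gene_id, window, f.contig, start0, end0, f.strand)
    return out


def log_odds_score(m: PSSM, word: str, background: np.ndarray) -> float:
    """Sum of per-position log2 odds; ``N`` bases are background-neutral (0)."""
    if len(word) != m.width:
        raise ContractError(f"word length {len(word)} != motif width {m.width}")
    lods = m.log_odds(background)
    enc = encode_sequence(word)
    return float(sum(lods[k, b] for k, b in enumerate(enc) if b < 4))


@dataclass
class ScoreModel:
    """Discretized log-odds tables plus the exact null score distribution."""

    motif_id: str
    eps: float
    int_table: np.ndarray  # (width, 5); N column scores 0
    min_int: int
    sf: np.ndarray  # survival P(score >= min_int + i)

    @property
    def width(self) -> int:
        return self.int_table.shape[0]

    def int_score(self, enc_word: np.ndarray) -> int:
        return int(sum(self.int_table[k, b] for k, b in enumerate(enc_word)))

    def p_value(self, int_score) -> np.ndarray:
        idx = np.clip(np.asarray(int_score, dtype=np.int64) - self.min_int, 0, self.sf.size - 1)
        return self.sf[idx]


def score_distribution(
    m: PSSM, background: np.ndarray, granularity: int = DEFAULT_GRANULARITY
) -> ScoreModel:
    """Exact null distribution of the discretized score of a background word."""
    if granularity < 100:
        raise ContractError("granularity must be >= 100")
    bg = np.asarray(background, dtype=float)
    lods = m.log_odds(bg)
    ranges = lods.max(axis=1) - lods.min(axis=1)
    max_range = float(ranges.max())
    if max_range <= 0:
        # motif indistinguishable from background: every word scores 0, p = 1
        table = np.zeros((m.width, 5), dtype=np.int64)
        return ScoreModel(m.id, 1.0, table, 0, np.array([1.0]))
    eps = max_range / granularity
    ints = np.rint(lods / eps).astype(np.int64)
    table = np.zeros((m.width, 5), dtype=np.int64)
    table[:, :4] = ints
    dist = np.array([1.0])
    base = 0
    for k in range(m.width):
        col_min, col_max = int(ints[k].min()), int(ints[k].max())
        col = np.zeros(col_max - col_min + 1)
        for b in range(4):
            col[ints[k, b] - col_min] += bg[b]
        dist = np.convolve(dist, col)
        base += col_min
    sf = np.cumsum(dist[::-1])[::-1]
    sf = np.clip(sf, 0.0, 1.0)
    sf[0] = 1.0
    return ScoreModel(m.id, eps, table, base, sf)


@dataclass
class MotifHit:
    gene: str
    motif_id: str
    offset: int  # 0-based within the promoter sequence
    strand: str
    score: float  # exact log2-odds in bits
    p_value: float
    q_value: float


def _window_int_scores(enc: np.ndarray, table: np.ndarray) -> np.ndarray:
    w = table.shape[0]
    n_pos = enc.size - w + 1
    scores = np.zeros(n_pos, dtype=np.int64)
    for k in range(w):
        scores += table[k, enc[k : k + n_pos]]
    return scores


def estimate_background(promoters: PromoterSet) -> np.ndarray:
    counts = np.ones(4)
    for p in promoters.values():
        enc = encode_sequence(p.seq)
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    return counts / counts.sum()


def scan(
    promoters: PromoterSet,
    motifs: list[PSSM],
    background: np.ndarray | None = None,
    q_threshold: float = DEFAULT_SCAN_Q,
    granularity: int = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Score every promoter offset on both strands and keep hits with q < threshold.

    Q-values are computed per motif over all scanned positions genome-wide.
    Promoters shorter than a motif are skipped for that motif.
    """
    bg = np.asarray(background, dtype=float) if background is not None else estimate_background(promoters)
    genes = sorted(promoters)
    encoded = {g: encode_sequence(promoters[g].seq) for g in genes}
    hits: list[MotifHit] = []
    for m in motifs:
        model = score_distribution(m, bg, granularity)
        w = model.width
        table = model.int_table
        table_rc = table[::-1][:, _COMPLEMENT_INDEX]
        lods = m.log_odds(bg)
        per_gene: list[tuple[str, str, np.ndarray]] = []
        for g in genes:
            enc = encoded[g]
            if enc.size < w:
                continue
            per_gene.append((g, "+", _window_int_scores(enc, table)))
            per_gene.append((g, "-", _window_int_scores(enc, table_rc)))
        if not per_gene:
            continue
        lengths = [s.size for _, _, s in per_gene]
        all_scores = np.concatenate([s for _, _, s in per_gene])
        p = model.p_value(all_scores)
        q = bh_adjust(p)
        keep = np.flatnonzero(q < q_threshold)
        bounds = np.cumsum([0] + lengths)
        for flat in keep:
            block = int(np.searchsorted(bounds, flat, side="right")) - 1
            gene, strand, _ = per_gene[block]
            offset = int(flat - bounds[block])
            enc = encoded[gene][offset : offset + w]
            if strand == "+":
                word_enc = enc
            else:
                word_enc = _COMPLEMENT_INDEX[enc][::-1]
            score = float(sum(lods[k, b] for k, b in enumerate(word_enc) if b < 4))
            hits.append(MotifHit(gene, m.id, offset, strand, score, float(p[flat]), float(q[flat])))
    hits.sort(key=lambda h: (h.motif_id, h.gene, h.offset, h.strand))
    return hits


@dataclass
class GeneMotifMap:
    gene_to_motifs: dict[str, set[str]]
    motif_to_genes: dict[str, set[str]]
    n_mappings: int
    n_unique_motifs: int
    n_unique_genes: int


def gene_motif_map(hits: list[MotifHit], q_threshold: float | None = None) -> GeneMotifMap:
    """Deduplicated presence maps plus the three coverage statistics."""
    g2m: dict[str, set[str]] = {}
    m2g: dict[str, set[str]] = {}
    n_mappings = 0
    for h in hits:
        if q_threshold is not None and not h.q_value < q_threshold:
            continue
        n_mappings += 1
        g2m.setdefault(h.gene, set()).add(h.motif_id)
        m2g.setdefault(h.motif_id, set()).add(h.gene)
    return GeneMotifMap(g2m, m2g, n_mappings, len(m2g), len(g2m))


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    """FIMO-like hit table: gene, motif, offset, strand, score, p, q."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tmotif\toffset\tstrand\tscore\tp_value\tq_value\n")
        for h in hits:
            fh.write(
                f"{h.gene}\t{h.motif_id}\t{h.offset}\t{h.strand}\t"
                f"{h.score:.4f}\t{h.p_value:.6g}\t{h.q_value:.6g}\n"
            )


def read_hits_tsv(path) -> list[MotifHit]:
    hits: list[MotifHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene\t"):
            raise ParseError(f"{path}: unexpected hits header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            hits.append(
                MotifHit(cells[0], cells[1], int(cells[2]), cells[3],
                         float(cells[4]), float(cells[5]), float(cells[6]))
            )
    return hits
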