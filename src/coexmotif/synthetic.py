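"""Synthetic regulatory data with a complete ground-truth ledger.

Generates every input the pipeline consumes — a redundant motif library, a
TF -> target module structure, per-gene promoter contigs with planted motif
instances, a coupled expression matrix with missing-at-random entries, and
GO-like annotations — so that each downstream stage can be validated against
known truth.  All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidConfigError
from .expression import ExpressionMatrix
from .meme import ALPHABET, PSSM, UNIFORM_BACKGROUND

GENE_STUB_LENGTH = 30

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic regulatory system."""

    n_genes: int = 1000
    n_tfs: int = 20
    module_size: int = 30
    n_samples: int = 60
    coupling: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    promoter_length: int = 400
    motif_width_range: tuple[int, int] = (8, 20)
    library_redundancy: int = 3
    consensus_strength: float = 0.95
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise InvalidConfigError("n_genes must be >= 2")
        if self.n_tfs < 0 or self.module_size < 0:
            raise InvalidConfigError("n_tfs and module_size must be non-negative")
        if self.n_tfs * (self.module_size + 1) > self.n_genes:
            raise InvalidConfigError(
                "n_tfs * (module_size + 1) exceeds n_genes; not enough genes for the modules"
            )
        if self.n_samples < 4:
            raise InvalidConfigError("n_samples must be >= 4")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        lo, hi = self.motif_width_range
        if not (8 <= lo <= hi <= 20):
            raise InvalidConfigError("motif widths must lie within [8, 20]")
        if self.promoter_length < hi:
            raise InvalidConfigError("promoter_length shorter than the widest motif")
        if self.library_redundancy < 1:
            raise InvalidConfigError("library_redundancy must be >= 1")
        if not 0.3 < self.consensus_strength < 1.0:
            raise InvalidConfigError("consensus_strength must lie in (0.3, 1)")
        bg = np.asarray(self.background_freqs, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("background_freqs must be 4 positive probabilities summing to 1")

    @property
    def background(self) -> np.ndarray:
        return np.asarray(self.background_freqs, dtype=float)


@dataclass
class MotifInstance:
    gene: str
    motif_id: str
    offset: int
    strand: str
    word: str


@dataclass
class GroundTruth:
    """Ledger of everything the generators planted."""

    tf_assignments: dict[str, list[str]] = field(default_factory=dict)
    planted_motifs: dict[str, str] = field(default_factory=dict)
    motif_instances: list[MotifInstance] = field(default_factory=list)
    motif_clusters: dict[str, list[str]] = field(default_factory=dict)
    module_labels: dict[str, str] = field(default_factory=dict)
    gene_labels: dict[str, str] = field(default_factory=dict)
    gene_categories: dict[str, list[str]] = field(default_factory=dict)
    background_genes: list[str] = field(default_factory=list)

    @property
    def tf_genes(self) -> list[str]:
        return list(self.tf_assignments)

    @property
    def target_genes(self) -> list[str]:
        return [g for targets in self.tf_assignments.values() for g in targets]

    def tf_of_target(self) -> dict[str, str]:
        return {g: tf for tf, targets in self.tf_assignments.items() for g in targets}

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["motif_instances"] = [MotifInstance(**d) for d in payload["motif_instances"]]
        return cls(**payload)


def gene_names(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def _sample_base_motif(
    rng: np.random.Generator,
    width: int,
    strength: float,
    background: np.ndarray,
) -> np.ndarray:
    """One near-determinate motif: a random consensus letter per column."""
    probs = np.empty((width, 4))
    consensus = rng.integers(0, 4, size=width)
    for k in range(width):
        rest = np.delete(np.arange(4), consensus[k])
        rest_bg = background[rest] / background[rest].sum()
        probs[k, consensus[k]] = strength
        probs[k, rest] = (1.0 - strength) * rest_bg
    return probs


def _jitter_preserving_consensus(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Perturb column probabilities without changing the argmax letter set."""
    out = probs.copy()
    for k in range(out.shape[0]):
        dom = out[k].argmax()
        d = out[k, dom]
        # keep the dominant base dominant and above any consensus threshold
        d_new = float(np.clip(d + rng.uniform(-0.05, 0.03), 0.60, 0.995))
        rest = np.delete(np.arange(4), dom)
        rest_mass = out[k, rest]
        rest_mass = rest_mass / rest_mass.sum() if rest_mass.sum() > 0 else np.full(3, 1 / 3)
        out[k, dom] = d_new
        out[k, rest] = (1.0 - d_new) * rest_mass
    return out


def _shift_with_background(
    rng: np.random.Generator, probs: np.ndarray, background: np.ndarray
) -> np.ndarray:
    shift = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
    w = probs.shape[0]
    out = np.tile(background, (w, 1))
    if shift > 0:
        out[shift:, :] = probs[: w - shift, :]
    else:
        out[: w + shift, :] = probs[-shift:, :]
    return out


def generate_motif_library(
    n_base: int,
    redundancy: int,
    width_range: tuple[int, int] = (8, 20),
    background: np.ndarray | None = None,
    seed: int = 0,
    consensus_strength: float = 0.95,
) -> tuple[list[PSSM], dict[str, list[str]]]:
    """Build ``n_base * redundancy`` motifs plus the planted duplicate groups.

    Each base motif spawns ``redundancy - 1`` near-duplicates obtained by
    consensus-preserving jitter, a circular shift of at most two columns with
    background-filled ends, or reverse complementation.
    """
    if n_base < 1 or redundancy < 1:
        raise InvalidConfigError("n_base and redundancy must be >= 1")
    lo, hi = width_range
    if not (4 <= lo <= hi <= 30):
        raise InvalidConfigError("motif width range must lie within [4, 30]")
    bg = np.asarray(background, dtype=float) if background is not None else UNIFORM_BACKGROUND.copy()
    rng = np.random.default_rng(seed)
    motifs: list[PSSM] = []
    clusters: dict[str, list[str]] = {}
    for b in range(n_base):
        width = int(rng.integers(lo, hi + 1))
        base_probs = _sample_base_motif(rng, width, consensus_strength, bg)
        base_id = f"M{b:03d}"
        members = [f"{base_id}v0"]
        motifs.append(PSSM(id=members[0], probs=base_probs, background=bg.copy()))
        for k in range(1, redundancy):
            op = rng.integers(0, 3)
            if op == 0:
                probs = _jitter_preserving_consensus(rng, base_probs)
            elif op == 1:
                probs = _shift_with_background(rng, base_probs, bg)
            else:
                probs = base_probs[::-1, ::-1].copy()
            mid = f"{base_id}v{k}"
            members.append(mid)
            motifs.append(PSSM(id=mid, probs=probs, background=bg.copy()))
        clusters[base_id] = members
    return motifs, clusters


DECOY_LABELS = [f"GO:{9000 + j:07d}" for j in range(20)]


def generate_regulatory_structure(
    cfg: SimulationConfig, motif_ids: list[str]
) -> GroundTruth:
    """Assign TFs, disjoint target modules, motifs and GO-like labels."""
    cfg.validate()
    if len(motif_ids) < cfg.n_tfs:
        raise InvalidConfigError(
            f"need at least {cfg.n_tfs} motif groups, got {len(motif_ids)}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    genes = gene_names(cfg.n_genes)
    gt = GroundTruth()
    cursor = cfg.n_tfs
    for t in range(cfg.n_tfs):
        tf = genes[t]
        targets = genes[cursor : cursor + cfg.module_size]
        cursor += cfg.module_size
        gt.tf_assignments[tf] = targets
        gt.planted_motifs[tf] = motif_ids[t]
        label = f"GO:{1000 + t:07d}"
        gt.module_labels[tf] = label
        gt.gene_labels[tf] = label
        for g in targets:
            gt.gene_labels[g] = label
        gt.gene_categories[tf] = (
            ["regulatory"] if t % 2 == 0 else ["dna_binding"]
        )
    gt.background_genes = genes[cursor:]
    for g in gt.background_genes:
        gt.gene_labels[g] = DECOY_LABELS[int(rng.integers(0, len(DECOY_LABELS)))]
    return gt


def _random_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    idx = rng.choice(4, size=length, p=background)
    return "".join(ALPHABET[i] for i in idx)


def _sample_word(rng: np.random.Generator, pssm: PSSM) -> str:
    return "".join(
        ALPHABET[int(rng.choice(4, p=pssm.probs[k] / pssm.probs[k].sum()))]
        for k in range(pssm.width)
    )


@dataclass
class GeneFeature:
    """A gene record as written to / read from GFF3 (1-based, inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str


def generate_promoters(
    gt: GroundTruth,
    cfg: SimulationConfig,
    motifs: list[PSSM],
    seed: int | None = None,
) -> tuple[dict[str, str], list[GeneFeature], dict[str, str]]:
    """Write one contig per gene: a promoter window followed by a gene stub.

    Returns (genome, gene features, true promoter sequences) and records every
    planted instance in ``gt.motif_instances``.  Gene strands are drawn at
    random; coordinates are laid out so that the 400 bp (``promoter_length``)
    upstream window of each gene reproduces the written promoter exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    by_id = {m.id: m for m in motifs}
    tf_of = gt.tf_of_target()
    genome: dict[str, str] = {}
    features: list[GeneFeature] = []
    promoters: dict[str, str] = {}
    gt.motif_instances = []
    bg = cfg.background
    genes = gene_names(cfg.n_genes)
    for gene in genes:
        promoter = _random_sequence(rng, cfg.promoter_length, bg)
        if gene in tf_of:
            pssm = by_id[gt.planted_motifs[tf_of[gene]]]
            if pssm.width > cfg.promoter_length:
                raise InvalidConfigError("planted motif wider than the promoter")
            word = _sample_word(rng, pssm)
            offset = int(rng.integers(0, cfg.promoter_length - pssm.width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            written = word if strand == "+" else reverse_complement(word)
            promoter = promoter[:offset] + written + promoter[offset + pssm.width :]
            gt.motif_instances.append(
                MotifInstance(gene=gene, motif_id=pssm.id, offset=offset, strand=strand, word=word)
            )
        stub = _random_sequence(rng, GENE_STUB_LENGTH, bg)
        contig = f"ctg_{gene}"
        gene_strand = "+" if rng.random() < 0.5 else "-"
        concat = promoter + stub
        if gene_strand == "+":
            genome[contig] = concat
            start = cfg.promoter_length + 1
            end = cfg.promoter_length + GENE_STUB_LENGTH
        else:
            genome[contig] = reverse_complement(concat)
            start = 1
            end = GENE_STUB_LENGTH
        features.append(GeneFeature(gene, contig, start, end, gene_strand))
        promoters[gene] = promoter
    return genome, features, promoters


def generate_expression(
    gt: GroundTruth, cfg: SimulationConfig, seed: int | None = None
) -> ExpressionMatrix:
    """TF-coupled expression with Gaussian noise and MCAR missingness."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    genes = gene_names(cfg.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    values = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    for tf, targets in gt.tf_assignments.items():
        tf_profile = values[index[tf]]
        for g in targets:
            noise = rng.standard_normal(cfg.n_samples) * cfg.noise_sd
            values[index[g]] = cfg.coupling * tf_profile + noise
    observed = rng.random((cfg.n_genes, cfg.n_samples)) >= cfg.missing_rate
    values = values.copy()
    values[~observed] = np.nan
    sample_ids = [f"s{j:03d}" for j in range(cfg.n_samples)]
    return ExpressionMatrix(genes, sample_ids, values, observed)


def write_genome_fasta(genome: dict[str, str], path, line_width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for contig in genome:
            fh.write(f">{contig}\n")
            seq = genome[contig]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_gff3(features: list[GeneFeature], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tcoexmotif_sim\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tID={f.gene_id}\n"
            )
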