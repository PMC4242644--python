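import itertools

import numpy as np
import pytest

from coexmotif.errors import ContractError, ParseError, UnknownContigError
from coexmotif.meme import PSSM, read_meme, write_meme
from coexmotif.scan import (
    Promoter,
    encode_sequence,
    estimate_background,
    extract_promoters,
    gene_motif_map,
    log_odds_score,
    MotifHit,
    read_fasta,
    read_gff3,
    read_hits_tsv,
    scan,
    score_distribution,
    write_hits_tsv,
)
from coexmotif.synthetic import (
    GeneFeature,
    SimulationConfig,
    generate_motif_library,
    generate_promoters,
    generate_regulatory_structure,
    reverse_complement,
    write_genome_fasta,
    write_gff3,
)

UNIFORM = np.full(4, 0.25)


def strong_pssm(consensus: str, dominant: float = 0.97, motif_id: str = "m") -> PSSM:
    probs = np.full((len(consensus), 4), (1 - dominant) / 3)
    for k, base in enumerate(consensus):
        probs[k, "ACGT".index(base)] = dominant
    return PSSM(motif_id, probs, UNIFORM.copy())


class TestMemeIO:
    def test_round_trip_two_motifs(self, tmp_path):
        motifs, _ = generate_motif_library(2, 1, width_range=(8, 12), seed=1)
        path = tmp_path / "m.meme"
        write_meme(motifs, path)
        back = read_meme(path)
        assert [m.id for m in back] == [m.id for m in motifs]
        assert [m.width for m in back] == [m.width for m in motifs]
        for a, b in zip(motifs, back):
            assert np.allclose(a.probs, b.probs, atol=2e-6)

    def test_background_line_honored(self, tmp_path):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        motifs, _ = generate_motif_library(1, 1, background=bg, seed=0)
        path = tmp_path / "m.meme"
        write_meme(motifs, path, bg)
        back = read_meme(path)
        assert np.allclose(back[0].background, bg, atol=1e-6)

    def test_bad_row_sum_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nMOTIF broken\n"
            "letter-probability matrix: alength= 4 w= 4\n"
            " 0.9 0.4 0.0 0.0\n 1 0 0 0\n 1 0 0 0\n 1 0 0 0\n"
        )
        with pytest.raises(ParseError, match="broken"):
            read_meme(path)

    def test_wrong_column_count_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nMOTIF nope\n"
            "letter-probability matrix: alength= 4 w= 4\n"
            " 0.5 0.5 0.0\n 1 0 0 0\n 1 0 0 0\n 1 0 0 0\n"
        )
        with pytest.raises(ParseError, match="nope"):
            read_meme(path)


class TestExtractPromoters:
    def test_plus_strand_exact_fit(self):
        seq = "".join("ACGT"[i % 4] for i in range(430))
        genome = {"c1": seq}
        feats = [GeneFeature("g1", "c1", 401, 430, "+")]
        out = extract_promoters(genome, feats, 400)
        assert out["g1"].seq == seq[:400]
        assert (out["g1"].start, out["g1"].end) == (0, 400)

    def test_minus_strand_reverse_complement(self):
        seq = "AACCGGTTAACCGGTTAACC" * 25  # 500 bp
        genome = {"c1": seq}
        feats = [GeneFeature("g1", "c1", 1, 60, "-")]
        out = extract_promoters(genome, feats, 400)
        assert out["g1"].seq == reverse_complement(seq[60:460])

    def test_truncated_at_contig_edge(self):
        genome = {"c1": "ACGT" * 30}
        feats = [GeneFeature("g1", "c1", 41, 120, "+")]
        out = extract_promoters(genome, feats, 400)
        assert len(out["g1"].seq) == 40

    def test_zero_length_promoter_skipped(self):
        genome = {"c1": "ACGTACGTAC"}
        feats = [GeneFeature("g1", "c1", 1, 10, "+")]
        out = extract_promoters(genome, feats, 400)
        assert "g1" not in out

    def test_unknown_contig_raises(self):
        with pytest.raises(UnknownContigError):
            extract_promoters({"c1": "ACGT"}, [GeneFeature("g1", "cX", 1, 4, "+")])

    def test_matches_generator_promoters(self, small_world, tmp_path):
        genome_path = tmp_path / "g.fa"
        gff_path = tmp_path / "g.gff3"
        write_genome_fasta(small_world["genome"], genome_path)
        write_gff3(small_world["features"], gff_path)
        genome = read_fasta(genome_path)
        feats = read_gff3(gff_path)
        cfg = small_world["config"]
        out = extract_promoters(genome, feats, cfg.promoter_length)
        truth = small_world["promoters"]
        assert set(out) == set(truth)
        for gene, pr in out.items():
            assert pr.seq == truth[gene]


class TestLogOdds:
    def test_background_motif_scores_zero_everywhere(self):
        m = PSSM("bg", np.tile(UNIFORM, (5, 1)), UNIFORM.copy())
        for word in ("ACGTA", "TTTTT", "GCGCG"):
            assert log_odds_score(m, word, UNIFORM) == pytest.approx(0.0, abs=1e-12)

    def test_half_probability_column_scores_one_bit(self):
        probs = np.tile(np.array([0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]), (4, 1))
        m = PSSM("h", probs, UNIFORM.copy())
        # each A column contributes ~log2(0.5/0.25) = 1 bit
        assert log_odds_score(m, "AAAA", UNIFORM) == pytest.approx(4.0, abs=0.02)

    def test_matches_per_position_oracle(self, rng):
        for _ in range(20):
            w = int(rng.integers(4, 10))
            probs = rng.dirichlet(np.ones(4), size=w)
            m = PSSM("r", probs, UNIFORM.copy())
            word = "".join("ACGT"[i] for i in rng.integers(0, 4, size=w))
            reg = (probs + 0.001 * 0.25) / 1.001
            expected = sum(
                np.log2(reg[k, "ACGT".index(b)] / 0.25) for k, b in enumerate(word)
            )
            assert log_odds_score(m, word, UNIFORM) == pytest.approx(expected, abs=1e-9)

    def test_n_is_background_neutral(self):
        m = strong_pssm("ACGT")
        with_n = log_odds_score(m, "ACGN", UNIFORM)
        without = log_odds_score(m, "ACG" + "T", UNIFORM)
        t_contrib = m.log_odds(UNIFORM)[3, 3]
        assert with_n == pytest.approx(without - t_contrib, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            log_odds_score(strong_pssm("ACGT"), "ACG", UNIFORM)


def enumeration_p_values(m: PSSM, background: np.ndarray, model):
    """Exact p-values for every word by exhaustive 4^w enumeration on the
    same integer grid as the model (independent of the convolution)."""
    w = m.width
    words = list(itertools.product(range(4), repeat=w))
    ints = np.array([
        sum(int(model.int_table[k, b]) for k, b in enumerate(word)) for word in words
    ])
    probs = np.array([
        np.prod([background[b] for b in word]) for word in words
    ])
    order = np.argsort(-ints)
    sorted_ints = ints[order]
    tail = np.cumsum(probs[order])
    p_of_int = {}
    for i in range(len(words)):
        p_of_int[sorted_ints[i]] = tail[i]
    # p(s) = P(score >= s): for each distinct int, total mass at >= that int
    return ints, np.array([p_of_int[v] for v in ints])


class TestScoreDistribution:
    @pytest.mark.parametrize("w", [4, 6, 8])
    def test_matches_exhaustive_enumeration(self, w, rng):
        probs = rng.dirichlet(np.ones(4) * 0.5, size=w)
        m = PSSM("e", probs, UNIFORM.copy())
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        model = score_distribution(m, bg, granularity=500)
        ints, expected = enumeration_p_values(m, bg, model)
        got = model.p_value(ints)
        assert np.allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_degenerate_motif_best_word(self):
        m = strong_pssm("ACGTAC", dominant=0.999)
        model = score_distribution(m, UNIFORM)
        best = model.int_score(encode_sequence("ACGTAC"))
        assert model.p_value(best) == pytest.approx(0.25**6, rel=1e-9)

    def test_minimum_score_has_p_one(self, rng):
        probs = rng.dirichlet(np.ones(4), size=5)
        m = PSSM("p1", probs, UNIFORM.copy())
        model = score_distribution(m, UNIFORM)
        assert model.sf[0] == 1.0
        assert model.p_value(model.min_int) == 1.0

    def test_p_nonincreasing_in_score(self, rng):
        probs = rng.dirichlet(np.ones(4), size=6)
        model = score_distribution(PSSM("x", probs, UNIFORM.copy()), UNIFORM)
        assert np.all(np.diff(model.sf) <= 1e-15)

    def test_granularity_floor(self):
        with pytest.raises(ContractError):
            score_distribution(strong_pssm("ACGT"), UNIFORM, granularity=10)


def planted_promoter_world(n_promoters=200, n_targets=60, seed=0):
    cfg = SimulationConfig(
        n_genes=n_promoters, n_tfs=1, module_size=n_targets, n_samples=8,
        motif_width_range=(10, 10), library_redundancy=1,
        consensus_strength=0.997, seed=seed,
    )
    motifs, clusters = generate_motif_library(
        1, 1, (10, 10), seed=seed, consensus_strength=0.997
    )
    gt = generate_regulatory_structure(cfg, sorted(clusters))
    gt.planted_motifs = {tf: f"{b}v0" for tf, b in gt.planted_motifs.items()}
    _, _, promoters = generate_promoters(gt, cfg, motifs)
    prom_set = {
        g: Promoter(g, seq, f"ctg_{g}", 0, len(seq), "+") for g, seq in promoters.items()
    }
    return cfg, motifs, gt, prom_set


class TestScan:
    def test_recovers_planted_instances(self):
        _, motifs, gt, promoters = planted_promoter_world()
        hits = scan(promoters, motifs, background=UNIFORM, q_threshold=0.3)
        found = {(h.gene, h.offset, h.strand) for h in hits if h.q_value < 0.05}
        planted = {(i.gene, i.offset, i.strand) for i in gt.motif_instances}
        recall = len(found & planted) / len(planted)
        assert recall >= 0.9

    def test_background_motif_yields_no_hits(self):
        _, _, _, promoters = planted_promoter_world()
        bg_motif = PSSM("flat", np.tile(UNIFORM, (10, 1)), UNIFORM.copy())
        hits = scan(promoters, [bg_motif], background=UNIFORM, q_threshold=0.3)
        assert hits == []

    def test_reverse_complement_symmetry(self):
        _, motifs, _, promoters = planted_promoter_world(n_promoters=40, n_targets=20)
        hits = scan(promoters, motifs, background=UNIFORM, q_threshold=0.3)
        rc = {
            g: Promoter(g, reverse_complement(p.seq), p.contig, p.start, p.end, p.strand)
            for g, p in promoters.items()
        }
        rc_hits = scan(rc, motifs, background=UNIFORM, q_threshold=0.3)
        w = motifs[0].width

        def key(hs):
            return sorted((h.gene, h.offset, h.strand, round(h.score, 6)) for h in hs)

        mirrored = [
            MotifHit(h.gene, h.motif_id,
                     len(promoters[h.gene].seq) - w - h.offset,
                     "+" if h.strand == "-" else "-", h.score, h.p_value, h.q_value)
            for h in rc_hits
        ]
        assert key(hits) == key(mirrored)

    def test_invariant_to_promoter_order(self):
        _, motifs, _, promoters = planted_promoter_world(n_promoters=30, n_targets=15)
        shuffled = dict(reversed(list(promoters.items())))
        a = scan(promoters, motifs, background=UNIFORM)
        b = scan(shuffled, motifs, background=UNIFORM)
        assert [(h.gene, h.offset, h.strand, h.q_value) for h in a] == [
            (h.gene, h.offset, h.strand, h.q_value) for h in b
        ]

    def test_short_promoter_skipped(self):
        m = strong_pssm("ACGTACGTAC")
        promoters = {"tiny": Promoter("tiny", "ACGT", "c", 0, 4, "+")}
        assert scan(promoters, [m], background=UNIFORM) == []

    def test_hits_tsv_round_trip(self, tmp_path):
        _, motifs, _, promoters = planted_promoter_world(n_promoters=30, n_targets=15)
        hits = scan(promoters, motifs, background=UNIFORM)
        path = tmp_path / "hits.tsv"
        write_hits_tsv(hits, path)
        back = read_hits_tsv(path)
        assert [(h.gene, h.motif_id, h.offset, h.strand) for h in back] == [
            (h.gene, h.motif_id, h.offset, h.strand) for h in hits
        ]


class TestGeneMotifMap:
    def _hits(self):
        return [
            MotifHit("g1", "mA", 5, "+", 10.0, 1e-6, 0.01),
            MotifHit("g1", "mA", 40, "-", 9.0, 1e-5, 0.02),
            MotifHit("g1", "mA", 90, "+", 8.0, 1e-4, 0.08),
        ]

    def test_counting_example(self):
        gm = gene_motif_map(self._hits(), 0.3)
        assert gm.n_mappings == 3
        assert gm.n_unique_motifs == 1
        assert gm.n_unique_genes == 1

    def test_zero_threshold_empty(self):
        gm = gene_motif_map(self._hits(), 0.0)
        assert gm.gene_to_motifs == {}
        assert gm.n_mappings == 0

    def test_monotone_in_threshold(self):
        prev = (0, 0, 0)
        for q in (0.005, 0.015, 0.05, 0.1, 0.5):
            gm = gene_motif_map(self._hits(), q)
            cur = (gm.n_mappings, gm.n_unique_motifs, gm.n_unique_genes)
            assert cur >= prev
            prev = cur


def test_estimate_background_reflects_composition():
    promoters = {"g": Promoter("g", "AAAACCCC", "c", 0, 8, "+")}
    bg = estimate_background(promoters)
    assert bg[0] == pytest.approx(bg[1])
    assert bg[0] > bg[2]
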