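"""Insertion-aware DP: worked examples, oracle equivalence, gene location."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from Bio.Seq import Seq

from myxoedit import predict, synthetic
from myxoedit.seqio import ScoringModel
from tests.conftest import random_genomic

NEG = float("-inf")


def oracle_score(genomic: str, model: ScoringModel) -> float:
    """Reference maximum over all insertion sets and alignments.

    Top-down recursion over (consumed genomic, consumed model positions,
    last operation) with explicit affine-gap accounting; structured
    independently of the production DP (suffix recursion, no matrices, no
    traceback).
    """
    n, L = len(genomic), len(model)
    go, ge, pen = model.gap_open, model.gap_extend, model.insertion_penalty

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == n and j == L:
            return 0.0
        options = [NEG]
        if j < L:
            for k in range(4):
                if i + k > n:
                    continue
                g = genomic[i : i + k]
                for slots in itertools.combinations(range(3), k):
                    codon = ["C"] * 3
                    for s_, ch in zip(slots, g):
                        codon[s_] = ch
                    aa = str(Seq("".join(codon)).translate())
                    options.append(
                        model.score(j, aa)
                        - pen * (3 - k)
                        + best(i + k, j + 1, "m")
                    )
            options.append(-(ge if last == "x" else go) + best(i, j + 1, "x"))
        if i + 3 <= n:
            options.append(-(ge if last == "y" else go) + best(i + 3, j, "y"))
        return max(options)

    return best(0, 0, "m")


def oracle_score_enumerated(genomic: str, model: ScoringModel) -> float:
    """Second, fully enumerative oracle for tiny instances: every complete
    operation path is generated and scored from scratch."""
    n, L = len(genomic), len(model)
    go, ge, pen = model.gap_open, model.gap_extend, model.insertion_penalty
    best = [NEG]

    def walk(i, j, last, score):
        if i == n and j == L:
            best[0] = max(best[0], score)
            return
        if j < L:
            for k in range(4):
                if i + k > n:
                    continue
                for slots in itertools.combinations(range(3), k):
                    codon = ["C"] * 3
                    for s_, ch in zip(slots, genomic[i : i + k]):
                        codon[s_] = ch
                    aa = str(Seq("".join(codon)).translate())
                    walk(i + k, j + 1, "m", score + model.score(j, aa) - pen * (3 - k))
            walk(i, j + 1, "x", score - (ge if last == "x" else go))
        if i + 3 <= n:
            walk(i + 3, j, "y", score - (ge if last == "y" else go))

    walk(0, 0, "m", 0.0)
    return best[0]


class TestWorkedExamples:
    def test_single_insertion_restores_reading(self):
        # ATGAA needs one C before position 3 to encode MQ
        m = ScoringModel.from_protein("MQ", "BLOSUM62", gap_open=1000, gap_extend=1000)
        r = predict.predict_sites("ATGAA", m)
        assert [s.position for s in r.predicted_sites] == [3]
        assert r.aligned_protein == "MQ"
        assert r.score == 5 + 5  # BLOSUM62(M,M) + BLOSUM62(Q,Q)

    def test_exact_gene_needs_no_insertions(self):
        m = ScoringModel.from_protein("MQK", "BLOSUM62")
        r = predict.predict_sites("ATGCAAAAA", m)
        assert r.predicted_sites == []
        assert r.score == 5 + 5 + 5
        assert r.aligned_protein == "MQK"

    def test_result_is_self_consistent(self):
        m = ScoringModel.from_protein("MQKL", "BLOSUM62")
        r = predict.predict_sites("ATGAAAAACT", m)
        assert r.transcript.protein == r.aligned_protein
        assert r.transcript.gene.seq == "ATGAAAAACT"


def _random_model(rng) -> ScoringModel:
    go = float(rng.integers(4, 13))
    ge = float(rng.integers(1, 4))
    pen = float(rng.choice([0.0, 1.0, 2.5]))
    if rng.random() < 0.7:
        L = int(rng.integers(1, 9))
        protein = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), L))
        name = str(rng.choice(["BLOSUM62", "BLOSUM80", "BLOSUM90"]))
        return ScoringModel.from_protein(protein, name, gap_open=go, gap_extend=ge, insertion_penalty=pen)
    L = int(rng.integers(1, 7))
    pssm = [
        {a: int(rng.integers(-6, 12)) for a in "ARNDCQEGHILKMFPSTWYV"}
        for _ in range(L)
    ]
    return ScoringModel(mode="pssm", pssm=pssm, gap_open=go, gap_extend=ge, insertion_penalty=pen)


def test_dp_matches_recursion_oracle(rng):
    """DP score equals the reference recursion on random instances."""
    for _ in range(60):
        model = _random_model(rng)
        n = int(rng.integers(3, 25))
        genomic = random_genomic(rng, n)
        got = predict.predict_sites(genomic, model).score
        assert got == oracle_score(genomic, model)


def test_dp_matches_full_enumeration_on_tiny_instances(rng):
    for _ in range(15):
        model = _random_model(rng)
        model.reference = model.reference[:2] if model.mode == "matrix" else None
        if model.mode == "pssm":
            model.pssm = model.pssm[:2]
        n = int(rng.integers(3, 7))
        genomic = random_genomic(rng, n)
        got = predict.predict_sites(genomic, model).score
        assert got == oracle_score_enumerated(genomic, model)


def test_pssm_equivalent_to_matrix_gives_same_result(rng):
    """A PSSM whose rows copy the BLOSUM column of the reference residue
    reproduces matrix-mode scoring exactly."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    protein = "MKVLF"
    pssm = [
        {a: float(blosum[r, a]) for a in "ARNDCQEGHILKMFPSTWYV"}
        for r in protein
    ]
    mm = ScoringModel.from_protein(protein, "BLOSUM62")
    pm = ScoringModel(mode="pssm", pssm=pssm)
    for _ in range(5):
        genomic = random_genomic(rng, int(rng.integers(8, 20)))
        assert (
            predict.predict_sites(genomic, mm).score
            == predict.predict_sites(genomic, pm).score
        )


def test_insertion_penalty_monotonicity(rng):
    """Raising the per-insertion penalty never increases the number of
    predicted insertions."""
    for seed in range(5):
        cfg = synthetic.SimulationConfig(protein_len_range=(60, 80))
        truth = synthetic.simulate_gene_pair(cfg, seed, conservation_target=0.8)
        counts = []
        for pen in (0.0, 2.0, 5.0, 10.0):
            m = ScoringModel.from_protein(
                truth.protein_b, "BLOSUM90", insertion_penalty=pen
            )
            counts.append(len(predict.predict_sites(truth.transcript_a.gene.seq, m).predicted_sites))
        assert counts == sorted(counts, reverse=True)


def test_mostly_unedited_gene_predicts_few_sites():
    """On a gene whose homolog needs no frameshift repair, a calibrated
    insertion penalty keeps the prediction nearly insertion-free."""
    cfg = synthetic.SimulationConfig(protein_len_range=(120, 120), edit_density=1 / 400)
    truth = synthetic.simulate_gene_pair(cfg, 8, conservation_target=0.9)
    assert len(truth.transcript_a.sites) <= 1
    m = ScoringModel.from_protein(truth.protein_b, "BLOSUM90", insertion_penalty=4.0)
    r = predict.predict_sites(truth.transcript_a.gene.seq, m)
    assert len(r.predicted_sites) <= 4


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(77)
    cfg = synthetic.SimulationConfig(protein_len_range=(60, 60))
    truth = synthetic.simulate_gene_pair(cfg, 9, conservation_target=0.95)
    gene = truth.transcript_a.gene.seq
    flanks = [random_genomic(rng, 700), random_genomic(rng, 700)]
    genome = flanks[0] + gene + flanks[1]
    model = ScoringModel.from_protein(truth.protein_b, "BLOSUM90")
    return genome, gene, len(flanks[0]), model


class TestLocateGene:
    def test_planted_gene_recovered(self, planted):
        genome, gene, offset, model = planted
        r = predict.locate_gene(genome, model)
        assert r.found and r.strand == "+"
        lo, hi = offset, offset + len(gene)
        overlap = max(0, min(r.segment[1], hi) - max(r.segment[0], lo))
        assert overlap / len(gene) >= 0.9

    def test_reverse_strand_flips_flag_same_sites(self, planted):
        genome, gene, offset, model = planted
        fwd = predict.locate_gene(genome, model)
        rev_genome = str(Seq(genome).reverse_complement())
        rev = predict.locate_gene(rev_genome, model)
        assert rev.strand == "-"
        assert rev.score == fwd.score
        assert [s.position for s in rev.predicted_sites] == [
            s.position for s in fwd.predicted_sites
        ]
        # forward-coordinate segments describe the same genomic interval
        n = len(genome)
        assert (n - rev.segment[1], n - rev.segment[0]) == fwd.segment

    def test_higher_identity_paralog_wins(self):
        rng = np.random.default_rng(5)
        cfg = synthetic.SimulationConfig(protein_len_range=(60, 60), shared_site_fraction=1.0)
        close = synthetic.simulate_gene_pair(cfg, 13, conservation_target=0.98)
        far = synthetic.simulate_gene_pair(cfg, 13, conservation_target=0.65)
        # same reference protein (seed 13 ancestor); descendants differ in identity
        model = ScoringModel.from_protein(close.protein_b, "BLOSUM90")
        sep = random_genomic(rng, 400)
        genome = (
            random_genomic(rng, 200)
            + far.transcript_a.gene.seq
            + sep
            + close.transcript_a.gene.seq
            + random_genomic(rng, 200)
        )
        close_lo = 200 + len(far.transcript_a.gene.seq) + 400
        r = predict.locate_gene(genome, model, both_strands=False)
        mid = (r.segment[0] + r.segment[1]) / 2
        assert close_lo <= mid <= close_lo + len(close.transcript_a.gene.seq)

    def test_score_floor_reports_not_found(self):
        rng = np.random.default_rng(3)
        model = ScoringModel.from_protein("MKVLFWYHRDEN", "BLOSUM62")
        r = predict.locate_gene(random_genomic(rng, 300), model, score_floor=1e6)
        assert not r.found and r.predicted_sites == []


def test_empty_or_invalid_inputs_rejected():
    m = ScoringModel.from_protein("MQ", "BLOSUM62")
    with pytest.raises(ValueError):
        predict.predict_sites("AT", m)
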