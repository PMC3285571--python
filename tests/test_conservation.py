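"""Four-way alignments, backgrounds, shared sites, and binomial tests."""

import math

import numpy as np
import pytest

from myxoedit import conservation, synthetic
from myxoedit.conservation import (
    align_pair,
    background_frequencies,
    binomial_pvalue,
    build_four_way,
    conservation_pattern,
    extended_offset_conservation,
    find_shared_unambiguous_sites,
    offset_codon_position,
    profile_window,
)
from myxoedit.seqio import EditSite, EditedTranscript, GeneSequence
from tests.conftest import random_genomic


def _gotoh_score(a, b, match=2.0, mismatch=-1.0, go=5.0, ge=1.0):
    """Independent affine-gap global alignment score (reference for the
    library-backed aligner)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignPair:
    def test_identical_sequences_align_gap_free(self):
        ra, rb = align_pair("ACGTACGT", "ACGTACGT")
        assert ra == rb == "ACGTACGT"

    def test_single_codon_deletion_gives_one_gap_block(self):
        a = "ATGAAATTTGGGCCC"
        b = "ATGAAAGGGCCC"  # one codon removed
        ra, rb = align_pair(a, b)
        assert ra.replace("-", "") == a and rb.replace("-", "") == b
        gaps = [i for i, c in enumerate(rb) if c == "-"]
        assert len(gaps) == 3 and gaps == list(range(gaps[0], gaps[0] + 3))

    def test_score_matches_independent_gotoh(self, rng):
        for _ in range(20):
            a = random_genomic(rng, int(rng.integers(5, 40)))
            b = random_genomic(rng, int(rng.integers(5, 40)))
            lib = conservation._default_aligner().score(a, b)
            assert lib == _gotoh_score(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


def _pair(seq_a, sites_a, seq_b, sites_b, gene_id="g"):
    ta = EditedTranscript(gene=GeneSequence(f"{gene_id}_A", seq_a),
                          sites=[EditSite(position=p) for p in sites_a])
    tb = EditedTranscript(gene=GeneSequence(f"{gene_id}_B", seq_b),
                          sites=[EditSite(position=p) for p in sites_b])
    return build_four_way(ta, tb, gene_id)


class TestConservationPattern:
    def test_identical_rows_are_all_ones(self):
        fw = _pair("ATGAAATTT", [], "ATGAAATTT", [])
        pattern, valid = conservation_pattern(fw)
        assert pattern.all() and valid.all()

    def test_single_mismatch_single_zero(self):
        fw = _pair("ATGAAATTT", [], "ATGATATTT", [])
        pattern, valid = conservation_pattern(fw)
        assert valid.all()
        assert pattern.sum() == 8 and pattern[4] == 0

    def test_gap_column_is_zero_and_invalid(self):
        fw = _pair("ATGAAATTTGGG", [], "ATGTTTGGG", [])
        pattern, valid = conservation_pattern(fw)
        assert (~valid).sum() == 3
        assert pattern[~valid].sum() == 0

    def test_single_gene_toy_background(self):
        # one codon, mismatch at position 2 -> (1, 0, 1)
        fw = _pair("ATG", [], "AAG", [])
        assert background_frequencies([fw]) == (1.0, 0.0, 1.0)


class TestBackgrounds:
    def test_identical_organisms_give_unit_background(self):
        cfg = synthetic.SimulationConfig(
            n_genes=2, protein_len_range=(60, 80), shared_site_fraction=1.0,
            conservation_targets=1.0,
        )
        truths = synthetic.simulate_transcriptome(cfg, 4)
        alns = [build_four_way(t.transcript_a, t.transcript_b) for t in truths]
        assert background_frequencies(alns) == (1.0, 1.0, 1.0)

    def test_generator_calibration_recovered(self):
        """A pool generated at second-position identity 0.85 recovers
        per-position backgrounds near (0.77, 0.85, 0.66) within binomial
        error."""
        cfg = synthetic.SimulationConfig(
            n_genes=6, protein_len_range=(200, 250), conservation_targets=0.85
        )
        truths = synthetic.simulate_transcriptome(cfg, 8)
        alns = [build_four_way(t.transcript_a, t.transcript_b, t.gene_id) for t in truths]
        f1, f2, f3 = background_frequencies(alns)
        assert abs(f2 - 0.85) < 0.02
        assert abs(f1 - 0.772) < 0.03
        assert abs(f3 - 0.656) < 0.03

    def test_pooled_equals_weighted_mean_of_per_gene(self, small_transcriptome):
        alns = [
            build_four_way(t.transcript_a, t.transcript_b, t.gene_id)
            for t in small_transcriptome
        ]
        pooled = background_frequencies(alns)
        weights, per_gene = [], []
        for a in alns:
            pattern, valid = conservation_pattern(a)
            cps = conservation.column_codon_positions(a)
            weights.append([(valid & (cps == c)).sum() for c in (1, 2, 3)])
            per_gene.append(conservation.per_gene_background(a))
        weights = np.array(weights, dtype=float)
        per_gene = np.array(per_gene)
        manual = (weights * per_gene).sum(axis=0) / weights.sum(axis=0)
        assert np.allclose(manual, pooled)


class TestSharedSites:
    def test_organism_specific_site_not_shared(self):
        fw = _pair("ATGAAATTT", [4], "ATGAAATTT", [])
        assert find_shared_unambiguous_sites([fw]) == []

    def test_shared_site_flanked_by_cs_in_both_excluded(self):
        # inserted C inside a templated C-run in both organisms -> ambiguous
        seq = "ATCCAATTT"
        fw = _pair(seq, [2], seq, [2])
        shared_all = find_shared_unambiguous_sites([fw], unambiguous_only=False)
        assert len(shared_all) == 1 and not shared_all[0].unambiguous
        assert find_shared_unambiguous_sites([fw]) == []

    def test_one_side_unambiguous_is_enough(self):
        fw = _pair("ATCCAATTT", [2], "ATGGAATTT", [2])
        shared = find_shared_unambiguous_sites([fw])
        assert len(shared) == 1 and shared[0].unambiguous


class TestBinomial:
    def test_closed_form_upper_tail(self):
        p, direction = binomial_pvalue(10, 10, 0.5)
        assert p == pytest.approx(9.765625e-4, abs=1e-15)
        assert direction == "increased"

    def test_closed_form_lower_tail(self):
        p, direction = binomial_pvalue(0, 4, 0.5)
        assert p == pytest.approx(0.0625, abs=1e-15)
        assert direction == "decreased"

    def test_matches_direct_summation(self, rng):
        for _ in range(50):
            N = int(rng.integers(1, 60))
            n = int(rng.integers(0, N + 1))
            f = float(rng.uniform(0.05, 0.95))
            p, direction = binomial_pvalue(n, N, f)
            if n / N >= f:
                ref = sum(
                    math.comb(N, k) * f**k * (1 - f) ** (N - k) for k in range(n, N + 1)
                )
            else:
                ref = sum(
                    math.comb(N, k) * f**k * (1 - f) ** (N - k) for k in range(0, n + 1)
                )
            assert p == pytest.approx(ref, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(1, 0, 0.5)


class TestOffsetCodonPosition:
    @pytest.mark.parametrize(
        "cp,d,expected",
        [(3, 1, 1), (1, -1, 3), (1, 1, 2), (2, 2, 1), (3, -2, 1)],
    )
    def test_codon_arithmetic(self, cp, d, expected):
        assert offset_codon_position(cp, d) == expected

    @pytest.mark.parametrize("cp", [1, 2, 3])
    def test_period_three(self, cp):
        assert offset_codon_position(cp, 3) == cp
        assert offset_codon_position(cp, -3) == cp

    def test_offset_zero_rejected(self):
        with pytest.raises(ValueError):
            offset_codon_position(1, 0)


def _profile_inputs(seed, motif=None, n_genes=2, codons=(250, 300), target=0.848):
    cfg = synthetic.SimulationConfig(
        n_genes=n_genes,
        protein_len_range=codons,
        codon_position_weights=(0, 0, 1),
        conservation_targets=target,
        shared_site_fraction=1.0,
        motif_spec=motif,
    )
    truths = synthetic.simulate_transcriptome(cfg, seed)
    alns = [build_four_way(t.transcript_a, t.transcript_b, t.gene_id) for t in truths]
    shared = find_shared_unambiguous_sites(alns)
    return [s for s in shared if s.codon_position == 3], alns


class TestProfileWindow:
    def test_embedded_conserved_offsets_flagged_exactly(self):
        sites, alns = _profile_inputs(42, motif={1: 1.0, 2: 1.0})
        prof = profile_window(sites, background_frequencies(alns))
        flagged = set(prof[prof.significant].offset)
        assert flagged == {1, 2}

    def test_observed_equal_background_large_p(self):
        # observed == background at every offset -> two-sided-by-direction
        # tail is at least ~0.5
        bg = (0.5, 0.5, 0.5)
        site = _make_uniform_site()
        prof = profile_window([site], bg)
        assert (prof.dropna().p >= 0.5).all()

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            profile_window([], (0.5, 0.5, 0.5))


def _make_uniform_site():
    # one shared site in identical organisms: every offset conserved (n=N=1)
    fw = _pair("ATGAAATTTGGGAAATTTGGG", [10], "ATGAAATTTGGGAAATTTGGG", [10])
    (site,) = find_shared_unambiguous_sites([fw])
    return site


def test_observed_equal_background_all_offsets():
    """With a single fully conserved flank and f = 0.5, the increased-tail
    p-value is 0.5 at every in-range offset."""
    site = _make_uniform_site()
    prof = profile_window([site], (0.5, 0.5, 0.5))
    inr = prof[prof.N > 0]
    assert (inr.observed == 1.0).all()
    assert (inr.p == 0.5).all()


class TestExtendedOffsets:
    def test_no_secondary_sites_keeps_full_sample(self):
        sites, alns = _profile_inputs(7)
        # remove genes' other sites from consideration by taking isolated ones
        bg = background_frequencies(alns)
        lone = [
            s
            for s in sites
            if all(
                abs(e - s.edited_pos_a) > 30
                for e in s.aln.transcript_a.edited_positions()
                if e != s.edited_pos_a
            )
        ]
        N, n, p = extended_offset_conservation(lone, 12, bg)
        assert N == sum(
            1 for s in lone if s.edited_pos_a + 12 < len(s.aln.transcript_a.edited_seq)
        )

    def test_sample_size_monotone_in_distance(self):
        sites, alns = _profile_inputs(9)
        bg = background_frequencies(alns)
        Ns = [extended_offset_conservation(sites, d, bg)[0] for d in range(10, 26)]
        assert all(a >= b for a, b in zip(Ns, Ns[1:]))

    def test_intervening_site_halves_sample(self):
        # two shared sites 5 apart: probing past the neighbour drops the site
        seq = "ATGAAATTTGGGAAATTTGGGAAATTTGGGAAA"
        fw = _pair(seq, [10, 15], seq, [10, 15])
        shared = find_shared_unambiguous_sites([fw])
        by_cp = {}
        for s in shared:
            by_cp.setdefault(s.codon_position, []).append(s)
        (cp, group), = [(k, v) for k, v in by_cp.items() if len(v) == 2] or [
            (None, None)
        ]
        if group is None:
            pytest.skip("construction produced differing codon positions")
        N, _, _ = extended_offset_conservation(group, 11, (0.5, 0.5, 0.5))
        assert N == 1

    def test_small_offset_rejected(self):
        with pytest.raises(ValueError):
            extended_offset_conservation([], 5, (0.5, 0.5, 0.5))
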