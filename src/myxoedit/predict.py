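"""Editing-site prediction by insertion-aware DNA-to-protein alignment.

The predictor searches over all ways of inserting single Cs into an unedited
genomic sequence such that the translation of the result aligns best to a
reference protein (scored with a BLOSUM matrix) or to a PSSM.  Each aligned
codon draws k in {0,1,2,3} genomic nucleotides plus 3-k inserted Cs in any
within-codon arrangement; affine gaps are allowed on the protein side (a model
position aligned to nothing) and on the genomic side (a whole unaligned
codon).  The dynamic program is exact over this search space:

    M[i][j] = best score consuming i genomic nt and j model positions, ending
              in an aligned codon;
    X[i][j] = ... ending in a protein-side gap (model position skipped);
    Y[i][j] = ... ending in a genomic-side gap (3-nt codon skipped).

A gap of L units costs ``gap_open + (L-1) * gap_extend``; every inserted C
additionally costs ``insertion_penalty``.  Ties are broken deterministically,
preferring transitions that consume more genomic nucleotides (fewer
insertions) and then a fixed arrangement order, so reruns are bit-identical.

:func:`locate_gene` runs the same program in semi-global mode (free leading
and trailing genomic sequence) over both strands of a larger genomic segment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .seqio import EditSite, EditedTranscript, GeneSequence, ScoringModel

NEG = -np.inf

#: amino-acid code order used for score tables (21 = stop)
_AA_ORDER = "ARNDCQEGHILKMFPSTWYV*X"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}

# codon transitions in preference order: larger k first (fewer insertions),
# then arrangements with genomic slots leftmost
_TRANSITIONS: list[tuple[int, tuple[int, ...]]] = []
for _k in (3, 2, 1, 0):
    for _slots in itertools.combinations(range(3), _k):
        _TRANSITIONS.append((_k, _slots))


@dataclass
class PredictionResult:
    """Outcome of a prediction run on one genomic segment.

    ``predicted_sites`` positions are local to the scanned segment on the
    scanned strand; ``segment`` is the (start, end) interval in forward
    coordinates of the input sequence; ``found`` is False when no window beat
    the score floor in :func:`locate_gene`.
    """

    predicted_sites: list[EditSite]
    score: float
    aligned_protein: str
    segment: tuple[int, int]
    strand: str = "+"
    found: bool = True
    transcript: EditedTranscript | None = field(default=None, repr=False)


def _score_table(model: ScoringModel) -> np.ndarray:
    S = np.empty((len(model), len(_AA_ORDER)))
    for j in range(len(model)):
        for a, idx in _AA_INDEX.items():
            S[j, idx] = model.score(j, a)
    return S


def _codon_amino_acid(codon: str) -> int:
    return _AA_INDEX[str(Seq(codon).translate())]


def _precompute_codons(genomic: str) -> list[np.ndarray]:
    """For each transition t, an (n+1,) array of amino-acid codes for the
    codon ending at genomic position i (k genomic nt + 3-k Cs); -1 where the
    prefix is too short."""
    n = len(genomic)
    out = []
    cache: dict[str, int] = {}
    for k, slots in _TRANSITIONS:
        codes = np.full(n + 1, -1, dtype=np.int16)
        for i in range(k, n + 1):
            g = genomic[i - k : i]
            codon = ["C"] * 3
            for pos, ch in zip(slots, g):
                codon[pos] = ch
            key = "".join(codon)
            if key not in cache:
                cache[key] = (
                    _AA_INDEX["X"] if "N" in key else _codon_amino_acid(key)
                )
            codes[i] = cache[key]
        out.append(codes)
    return out


def _run_dp(
    genomic: str, model: ScoringModel, semiglobal: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three DP matrices; returns (M, X, Y, S)."""
    n, L = len(genomic), len(model)
    S = _score_table(model)
    codes = _precompute_codons(genomic)
    go, ge, pen = model.gap_open, model.gap_extend, model.insertion_penalty

    M = np.full((L + 1, n + 1), NEG)
    X = np.full((L + 1, n + 1), NEG)
    Y = np.full((L + 1, n + 1), NEG)
    M[0, 0] = 0.0
    if semiglobal:
        M[0, :] = 0.0
    else:
        for i in range(3, n + 1, 3):
            Y[0, i] = (Y[0, i - 3] - ge) if Y[0, i - 3] > NEG else (M[0, 0] - go)
    for j in range(1, L + 1):
        prev_best = np.maximum(np.maximum(M[j - 1], X[j - 1]), Y[j - 1])
        # aligned codon: consume k genomic nt + (3-k) Cs and model position j
        cands = np.full((len(_TRANSITIONS), n + 1), NEG)
        for t, (k, _slots) in enumerate(_TRANSITIONS):
            code = codes[t]
            valid = code >= 0
            row = np.full(n + 1, NEG)
            row[valid] = (
                prev_best[np.nonzero(valid)[0] - k]
                + S[j - 1, code[valid]]
                - pen * (3 - k)
            )
            cands[t] = row
        M[j] = cands.max(axis=0)
        # protein-side gap
        X[j] = np.maximum(
            M[j - 1] - go, np.maximum(X[j - 1] - ge, Y[j - 1] - go)
        )
        # genomic-side codon gap: sequential in i (exactly reproducible in
        # the traceback)
        for i in range(3, n + 1):
            Y[j, i] = max(M[j, i - 3] - go, X[j, i - 3] - go, Y[j, i - 3] - ge)
    return M, X, Y, S


def _traceback(
    genomic: str, model: ScoringModel, M, X, Y, S, end_i: int
) -> tuple[list[int], int]:
    """Recover insertion positions and the alignment start from the matrices.

    Predecessors are re-derived by exact score comparison in the same
    preference order used forward (M over X over Y; transitions in
    ``_TRANSITIONS`` order), so the traced path is the one the forward pass
    scored.
    """
    n, L = len(genomic), len(model)
    go, ge, pen = model.gap_open, model.gap_extend, model.insertion_penalty
    codes = _precompute_codons(genomic)
    mats = {"M": M, "X": X, "Y": Y}
    i, j = end_i, L
    state = max(("M", "X", "Y"), key=lambda s: mats[s][j, i])
    insertions: list[int] = []
    while True:
        if state == "M":
            if j == 0:
                break  # global start (0,0) or free semi-global start (i,0)
            matched = False
            for t, (k, slots) in enumerate(_TRANSITIONS):
                if i < k or codes[t][i] < 0:
                    continue
                for ps in ("M", "X", "Y"):
                    prev = mats[ps][j - 1, i - k]
                    if np.isneginf(prev):
                        continue
                    if (prev + S[j - 1, codes[t][i]]) - pen * (3 - k) == M[j, i]:
                        for cs in (s for s in range(3) if s not in slots):
                            before = sum(1 for s in slots if s < cs)
                            insertions.append(i - k + before)
                        i, j, state = i - k, j - 1, ps
                        matched = True
                        break
                if matched:
                    break
            if not matched:  # pragma: no cover - defensive
                raise AssertionError(f"traceback stuck at M[{j},{i}]")
        elif state == "X":
            if M[j - 1, i] - go == X[j, i]:
                j, state = j - 1, "M"
            elif Y[j - 1, i] - go == X[j, i]:
                j, state = j - 1, "Y"
            else:
                j, state = j - 1, "X"
        else:  # Y
            if M[j, i - 3] - go == Y[j, i]:
                i, state = i - 3, "M"
            elif X[j, i - 3] - go == Y[j, i]:
                i, state = i - 3, "X"
            else:
                i, state = i - 3, "Y"
    return sorted(insertions), i


def _build_result(
    genomic: str, model: ScoringModel, insertions: list[int], score: float,
    segment: tuple[int, int], strand: str = "+",
) -> PredictionResult:
    seg_seq = genomic[segment[0] : segment[1]] if strand == "+" else genomic
    local = [p - (segment[0] if strand == "+" else 0) for p in insertions]
    gene = GeneSequence("segment", seg_seq) if seg_seq else None
    if gene is None:
        return PredictionResult([], score, "", segment, strand, found=False)
    t = EditedTranscript(
        gene=gene, sites=[EditSite(position=p, base="C") for p in local]
    )
    return PredictionResult(
        predicted_sites=t.sites,
        score=score,
        aligned_protein=t.protein,
        segment=segment,
        strand=strand,
        transcript=t,
    )


def predict_sites(genomic: str | GeneSequence, model: ScoringModel) -> PredictionResult:
    """Globally optimal C-insertion set for one genomic gene sequence.

    Returns the insertion set maximising alignment score minus insertion
    penalties over the full search space described in the module docstring.
    """
    seq = genomic.seq if isinstance(genomic, GeneSequence) else genomic.upper()
    if len(seq) < 3:
        raise ValueError("genomic sequence shorter than one codon")
    if len(model) == 0:
        raise ValueError("empty scoring model")
    M, X, Y, S = _run_dp(seq, model, semiglobal=False)
    n, L = len(seq), len(model)
    score = max(M[L, n], X[L, n], Y[L, n])
    insertions, _ = _traceback(seq, model, M, X, Y, S, n)
    return _build_result(seq, model, insertions, float(score), (0, n))


def _scan_strand(seq: str, model: ScoringModel) -> tuple[float, list[int], int, int]:
    M, X, Y, S = _run_dp(seq, model, semiglobal=True)
    L = len(model)
    totals = np.maximum(np.maximum(M[L], X[L]), Y[L])
    end_i = int(np.argmax(totals))
    score = float(totals[end_i])
    insertions, start_i = _traceback(seq, model, M, X, Y, S, end_i)
    return score, insertions, start_i, end_i


def locate_gene(
    genome_segment: str | GeneSequence,
    model: ScoringModel,
    score_floor: float = 0.0,
    both_strands: bool = True,
) -> PredictionResult:
    """Locate the best-scoring gene copy in a larger genomic segment.

    Semi-global alignment (free end gaps on the genomic side) over the forward
    and, optionally, reverse-complement strand; the higher-scoring strand
    wins.  Site positions in the result are local to the located segment on
    the scanned strand; ``segment`` is reported in forward coordinates.
    Returns ``found=False`` when no window reaches ``score_floor``.
    """
    seq = (
        genome_segment.seq
        if isinstance(genome_segment, GeneSequence)
        else genome_segment.upper()
    )
    n = len(seq)
    fwd = _scan_strand(seq, model)
    best = (fwd, "+")
    if both_strands:
        rc = str(Seq(seq).reverse_complement())
        rev = _scan_strand(rc, model)
        if rev[0] > fwd[0]:
            best = (rev, "-")
    (score, insertions, start_i, end_i), strand = best
    if score < score_floor:
        return PredictionResult([], score, "", (0, 0), strand, found=False)
    if strand == "+":
        segment = (start_i, end_i)
        local_seq = seq[start_i:end_i]
    else:
        segment = (n - end_i, n - start_i)  # forward coordinates
        rc = str(Seq(seq).reverse_complement())
        local_seq = rc[start_i:end_i]
    local = [p - start_i for p in insertions]
    gene = GeneSequence("segment", local_seq)
    t = EditedTranscript(
        gene=gene, sites=[EditSite(position=p, base="C") for p in local]
    )
    return PredictionResult(
        predicted_sites=t.sites,
        score=score,
        aligned_protein=t.protein,
        segment=segment,
        strand=strand,
        transcript=t,
    )
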