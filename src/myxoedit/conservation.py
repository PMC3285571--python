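"""Cross-species conservation around shared editing sites.

For each homologous gene the two organisms' edited mRNAs are aligned; shared
C-insertion sites are those edited at the same alignment column in both.
Flanking positions at signed offsets d in [-9, +9] from each shared
unambiguous site are turned into 0/1 conservation patterns (1 = same base at
the same relative mRNA position in both organisms), compared per codon
position against the gene-wide background conservation, and tested with exact
binomial tail probabilities.  Offsets beyond the 9-nt window are handled by
discarding sites with an intervening editing site, which keeps codon phase
well defined at the cost of shrinking sample size with distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import binom

from .seqio import EditSite, EditedTranscript

#: Bonferroni-style default cutoff: 18 offsets x 2 codon-position strata
DEFAULT_CUTOFF = 0.05 / 36
#: genes with 2nd-codon-position background below this are "less conserved"
LESS_CONSERVED_THRESHOLD = 0.85


def _default_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2.0
    a.mismatch_score = -1.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -1.0
    return a


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global affine alignment of two homologous mRNAs; returns the two
    gap-padded rows.  The first optimal alignment reported by the aligner is
    used, which is deterministic for fixed inputs."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _default_aligner().align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    return ra, rb


@dataclass
class FourWayAlignment:
    """Aligned mRNA rows for one gene pair plus site bookkeeping.

    The DNA rows are the mRNA rows with inserted (edited) characters replaced
    by gaps, so de-gapping each row recovers the respective input sequence.
    """

    gene_id: str
    transcript_a: EditedTranscript
    transcript_b: EditedTranscript
    row_mrna_a: str
    row_mrna_b: str

    #: per-row mapping: mRNA position -> alignment column
    col_of_a: np.ndarray = field(init=False, repr=False)
    col_of_b: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        for row, seq in (
            (self.row_mrna_a, self.transcript_a.edited_seq),
            (self.row_mrna_b, self.transcript_b.edited_seq),
        ):
            if row.replace("-", "") != seq:
                raise ValueError(f"{self.gene_id}: alignment row does not match mRNA")
        self.col_of_a = np.flatnonzero(np.frombuffer(self.row_mrna_a.encode(), dtype=np.uint8) != ord("-"))
        self.col_of_b = np.flatnonzero(np.frombuffer(self.row_mrna_b.encode(), dtype=np.uint8) != ord("-"))

    @property
    def row_dna_a(self) -> str:
        return self._dna_row(self.row_mrna_a, self.col_of_a, self.transcript_a)

    @property
    def row_dna_b(self) -> str:
        return self._dna_row(self.row_mrna_b, self.col_of_b, self.transcript_b)

    @staticmethod
    def _dna_row(row: str, col_of: np.ndarray, t: EditedTranscript) -> str:
        chars = list(row)
        for e in t.edited_positions():
            chars[col_of[e]] = "-"
        return "".join(chars)


def build_four_way(ta: EditedTranscript, tb: EditedTranscript, gene_id: str | None = None) -> FourWayAlignment:
    ra, rb = align_pair(ta.edited_seq, tb.edited_seq)
    return FourWayAlignment(
        gene_id=gene_id or ta.gene.id, transcript_a=ta, transcript_b=tb,
        row_mrna_a=ra, row_mrna_b=rb,
    )


def conservation_pattern(aln: FourWayAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (pattern, valid): pattern is 1 where both organisms carry
    the same base, 0 otherwise; columns with a gap in either row are 0 and
    flagged invalid (excluded from backgrounds)."""
    a = np.frombuffer(aln.row_mrna_a.encode(), dtype=np.uint8)
    b = np.frombuffer(aln.row_mrna_b.encode(), dtype=np.uint8)
    valid = (a != ord("-")) & (b != ord("-"))
    return ((a == b) & valid).astype(np.int8), valid


def column_codon_positions(aln: FourWayAlignment) -> np.ndarray:
    """Codon position (1..3) per alignment column, from organism A's edited
    reading frame (organism B's where A is gapped)."""
    n_cols = len(aln.row_mrna_a)
    cp = np.zeros(n_cols, dtype=np.int8)
    cp[aln.col_of_b] = np.arange(len(aln.col_of_b)) % 3 + 1
    cp[aln.col_of_a] = np.arange(len(aln.col_of_a)) % 3 + 1
    return cp


def background_frequencies(genes: list[FourWayAlignment]) -> tuple[float, float, float]:
    """Pooled per-codon-position conservation over whole genes."""
    if not genes:
        raise ValueError("no genes")
    ones = np.zeros(3)
    totals = np.zeros(3)
    for g in genes:
        pattern, valid = conservation_pattern(g)
        cps = column_codon_positions(g)
        for c in (1, 2, 3):
            mask = valid & (cps == c)
            totals[c - 1] += mask.sum()
            ones[c - 1] += pattern[mask].sum()
    if (totals == 0).any():
        raise ValueError("no columns at some codon position")
    return tuple(float(x) for x in ones / totals)


def per_gene_background(aln: FourWayAlignment) -> tuple[float, float, float]:
    return background_frequencies([aln])


@dataclass(frozen=True)
class SharedSite:
    """A C-insertion edited at the same alignment column in both organisms."""

    gene_id: str
    site_a: EditSite
    site_b: EditSite
    edited_pos_a: int
    edited_pos_b: int
    codon_position: int
    unambiguous: bool
    aln: FourWayAlignment = field(compare=False, hash=False, repr=False)


def find_shared_unambiguous_sites(
    genes: list[FourWayAlignment], unambiguous_only: bool = True
) -> list[SharedSite]:
    """Shared C-insertion sites, optionally restricted to unambiguous ones.

    A site pair is unambiguous when in at least one organism the inserted C
    has no equal neighbouring base.  Pairs whose codon positions disagree
    between the organisms are excluded with a warning.
    """
    out = []
    for g in genes:
        a_sites = {
            int(g.col_of_a[e]): (s, e)
            for s, e in zip(g.transcript_a.sites, g.transcript_a.edited_positions())
            if s.base == "C"
        }
        b_sites = {
            int(g.col_of_b[e]): (s, e)
            for s, e in zip(g.transcript_b.sites, g.transcript_b.edited_positions())
            if s.base == "C"
        }
        for col in sorted(set(a_sites) & set(b_sites)):
            sa, ea = a_sites[col]
            sb, eb = b_sites[col]
            if sa.codon_position != sb.codon_position:
                warnings.warn(
                    f"{g.gene_id}: shared site at column {col} with codon-"
                    f"position disagreement ({sa.codon_position} vs "
                    f"{sb.codon_position}); excluded",
                    stacklevel=2,
                )
                continue
            unamb = not (sa.ambiguous and sb.ambiguous)
            if unambiguous_only and not unamb:
                continue
            out.append(
                SharedSite(
                    gene_id=g.gene_id, site_a=sa, site_b=sb,
                    edited_pos_a=ea, edited_pos_b=eb,
                    codon_position=sa.codon_position, unambiguous=unamb, aln=g,
                )
            )
    return out


def binomial_pvalue(n: int, N: int, f: float) -> tuple[float, str]:
    """Exact binomial tail probability of the observed conservation count.

    Upper tail P(X >= n) when the observed frequency n/N is at or above the
    background f, lower tail P(X <= n) otherwise.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n <= N:
        raise ValueError("need 0 <= n <= N")
    if not 0 < f < 1:
        raise ValueError("background must be in (0,1)")
    if n / N >= f:
        return float(binom.sf(n - 1, N, f)), "increased"
    return float(binom.cdf(n, N, f)), "decreased"


def offset_codon_position(site_cp: int, d: int) -> int:
    """Codon position of the neighbour at signed edited-mRNA offset ``d``
    from a site at codon position ``site_cp``."""
    if d == 0:
        raise ValueError("offset 0 is the inserted C itself")
    return (site_cp - 1 + d) % 3 + 1


def _offset_sample(
    sites: list[SharedSite], d: int, require_no_intervening: bool = False
) -> tuple[int, int]:
    """(N, n) at offset d: sample size and conserved count."""
    N = n = 0
    for s in sites:
        seq_a = s.aln.transcript_a.edited_seq
        seq_b = s.aln.transcript_b.edited_seq
        pa, pb = s.edited_pos_a + d, s.edited_pos_b + d
        if not (0 <= pa < len(seq_a) and 0 <= pb < len(seq_b)):
            continue
        if require_no_intervening:
            ed_a = s.aln.transcript_a.edited_positions()
            ed_b = s.aln.transcript_b.edited_positions()
            lo_a, hi_a = sorted((s.edited_pos_a, pa))
            lo_b, hi_b = sorted((s.edited_pos_b, pb))
            if any(lo_a < e < hi_a for e in ed_a) or any(lo_b < e < hi_b for e in ed_b):
                continue
        N += 1
        n += seq_a[pa] == seq_b[pb]
    return N, n


def profile_window(
    shared_sites: list[SharedSite],
    backgrounds: tuple[float, float, float],
    window: int = 9,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Offset-wise conservation profile around shared sites of one stratum.

    One row per offset d in [-window, window] excluding 0: sample size N,
    conserved count n, the offset's codon position, background f, observed
    frequency, binomial p-value, direction, and a significance call at the
    (Bonferroni-style) cutoff.
    """
    if not shared_sites:
        raise ValueError("empty stratum")
    cps = {s.codon_position for s in shared_sites}
    if len(cps) != 1:
        raise ValueError("stratify sites by codon position before profiling")
    site_cp = cps.pop()
    rows = []
    for d in range(-window, window + 1):
        if d == 0:
            continue
        N, n = _offset_sample(shared_sites, d)
        ocp = offset_codon_position(site_cp, d)
        f = backgrounds[ocp - 1]
        if N == 0:
            rows.append((d, 0, 0, ocp, f, float("nan"), float("nan"), "", False))
            continue
        p, direction = binomial_pvalue(n, N, f)
        rows.append((d, N, n, ocp, f, n / N, p, direction, p < cutoff))
    return pd.DataFrame(
        rows,
        columns=["offset", "N", "n", "codon_position", "f", "observed", "p", "direction", "significant"],
    )


def extended_offset_conservation(
    shared_sites: list[SharedSite],
    d: int,
    backgrounds: tuple[float, float, float],
) -> tuple[int, int, float]:
    """Conservation at |d| > 9, discarding sites with an intervening editing
    site between the primary site and the probed position (in either
    organism).  Returns (N_d, n_d, p); N_d = 0 yields an empty result with
    p = nan."""
    if abs(d) <= 9:
        raise ValueError("use profile_window for |d| <= 9")
    cps = {s.codon_position for s in shared_sites}
    if len(cps) != 1:
        raise ValueError("stratify sites by codon position first")
    site_cp = cps.pop()
    N, n = _offset_sample(shared_sites, d, require_no_intervening=True)
    if N == 0:
        return 0, 0, float("nan")
    f = backgrounds[offset_codon_position(site_cp, d) - 1]
    p, _ = binomial_pvalue(n, N, f)
    return N, n, p
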