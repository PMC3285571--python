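"""Analytic model of the sequence information needed to specify an editing site.

If the information locating a C-insertion event is stored in the identities of
the ~19 nucleotides surrounding the site, that 19-nt pattern must be (nearly)
unique in the mitochondrial genome.  In a random sequence of length G with GC
content g, two nucleotides agree by chance with probability

    p = 2 (g/2)^2 + 2 ((1-g)/2)^2,

so a motif with f fixed positions (the rest free) recurs about G * p^f times.
The smallest f keeping the expected recurrence near one per genome, combined
with the background conservation of the non-fixed positions, gives the lowest
cross-species conservation such a recognition region could exhibit — and an
exact binomial computation says whether that conservation would have been
detectable at a given sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom

#: Physarum polycephalum mitochondrial genome length (NC_002508), nt.
PHYSARUM_MT_GENOME_LEN = 62862
#: Approximate GC fraction of that genome.
PHYSARUM_MT_GC = 0.25
#: Experimentally implicated recognition window: 9 nt either side + the site.
DEFAULT_MOTIF_LEN = 19
#: Lowest per-codon-position background conservation observed between the two
#: organisms (third codon position, less-conserved gene group).
MIN_BACKGROUND_CONSERVATION = 0.633


@dataclass(frozen=True)
class RecognitionParams:
    genome_len: int = PHYSARUM_MT_GENOME_LEN
    gc: float = PHYSARUM_MT_GC
    motif_len: int = DEFAULT_MOTIF_LEN
    background: float = MIN_BACKGROUND_CONSERVATION

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.genome_len <= 0 or self.motif_len <= 0:
            raise ValueError("lengths must be positive")
        if not 0 < self.background <= 1:
            raise ValueError("background must be in (0,1]")


def match_probability(gc: float) -> float:
    """Chance that two random nucleotides agree, at the given GC content.

    Each of C and G has frequency gc/2, each of A and T (1-gc)/2; agreement
    probability is the sum of squared frequencies.  Minimised (0.25) at
    gc = 0.5.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0,1)")
    return 2 * (gc / 2) ** 2 + 2 * ((1 - gc) / 2) ** 2


def expected_motif_hits(params: RecognitionParams, n_fixed: int) -> float:
    """Expected chance occurrences in the genome of a motif with ``n_fixed``
    fixed positions (the remaining positions free)."""
    return params.genome_len * match_probability(params.gc) ** n_fixed


def min_fixed_positions(
    params: RecognitionParams = RecognitionParams(), max_expected_hits: float = 2.0
) -> int:
    """Smallest number of fixed positions keeping expected chance hits at or
    below ``max_expected_hits`` ("close to one per genome").

    The threshold defaults to 2 expected hits: with the Physarum parameters
    (62862 nt, 25% GC) this yields 9 fixed positions out of 19 (expected
    recurrence 1.79 per genome); a strict threshold of 1 would demand 10.
    """
    if max_expected_hits < 1:
        raise ValueError("max_expected_hits must be >= 1")
    p = match_probability(params.gc)
    f = 0
    expected = float(params.genome_len)
    while expected > max_expected_hits:
        f += 1
        expected *= p
        if f > params.motif_len:
            raise ValueError(
                f"even {params.motif_len} fixed positions leave "
                f"{expected / p:.3g} expected hits > {max_expected_hits}"
            )
    return f


def lowest_expected_conservation(
    n_fixed: int, motif_len: int = DEFAULT_MOTIF_LEN,
    background: float = MIN_BACKGROUND_CONSERVATION,
) -> float:
    """Average conservation of a motif with ``n_fixed`` invariant positions.

    Fixed positions are conserved at 100%; the remaining positions drift at
    the background rate, so the region-wide average is the mixture
    ``(n_fixed + (motif_len - n_fixed) * background) / motif_len``.
    """
    if not 0 <= n_fixed <= motif_len:
        raise ValueError("n_fixed must be in [0, motif_len]")
    return (n_fixed * 1.0 + (motif_len - n_fixed) * background) / motif_len


def detectability_check(target_conservation: float, n_sites: int, background: float) -> float:
    """Upper-tail binomial p-value if the observed per-offset conservation
    were ``target_conservation`` at sample size ``n_sites`` against the given
    background.

    A small value means a recognition region conserved at that level *would*
    have produced a significant signal at this sample size, so a null outcome
    in real data is informative.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    n = round(target_conservation * n_sites)
    return float(binom.sf(n - 1, n_sites, background))
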