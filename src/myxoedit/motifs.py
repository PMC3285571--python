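"""Uniqueness of sequence context around editing sites over a transcriptome.

If flanking sequence alone specified where Cs are inserted, the k nucleotides
downstream (or upstream) of every editing site — or the m upstream plus n
downstream nucleotides straddling it — would have to be unique to editing
sites.  These scans ask the converse: what is the largest context that still
occurs both at an unambiguous C-insertion site and at a locus that is
definitely not edited?  Contexts are tested at the edited (mRNA) and unedited
(DNA) level, since the recognition substrate is unknown.

Placement ambiguity is treated conservatively: every sequence position (or
junction) at which an inserted base *could* lie under an equivalent placement
within its homopolymer run is removed from the negative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import EditedTranscript

MAX_FLANK = 9


@dataclass
class Transcriptome:
    """A set of edited transcripts with context indices at both levels."""

    transcripts: list[EditedTranscript]

    #: per transcript: set of edited-sequence char positions that may hold an
    #: inserted base under some equivalent placement
    _possible_inserted: list[set[int]] = field(init=False, repr=False)
    #: per transcript: set of genomic junction indices that may be edited
    _possible_junctions: list[set[int]] = field(init=False, repr=False)

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError("empty transcriptome")
        self._possible_inserted = []
        self._possible_junctions = []
        for t in self.transcripts:
            edited = t.edited_seq
            genomic = t.gene.seq
            chars: set[int] = set()
            junctions: set[int] = set()
            for s, e in zip(t.sites, t.edited_positions()):
                if s.ambiguous:
                    lo = e
                    while lo > 0 and edited[lo - 1] == s.base:
                        lo -= 1
                    hi = e
                    while hi + 1 < len(edited) and edited[hi + 1] == s.base:
                        hi += 1
                    chars.update(range(lo, hi + 1))
                else:
                    chars.add(e)
                r = s.position
                while r < len(genomic) and genomic[r] == s.base:
                    r += 1
                junctions.update(range(s.position, r + 1))
            self._possible_inserted.append(chars)
            self._possible_junctions.append(junctions)

    # -- context extraction -------------------------------------------------

    def site_flanks(self, side: str, level: str, k: int) -> set[str]:
        """k-mers immediately up-/downstream of unambiguous C sites."""
        out: set[str] = set()
        for t in self.transcripts:
            edited, genomic = t.edited_seq, t.gene.seq
            for s, e in zip(t.sites, t.edited_positions()):
                if s.base != "C" or s.ambiguous:
                    continue
                if level == "edited":
                    frag = edited[e + 1 : e + 1 + k] if side == "downstream" else edited[max(0, e - k) : e]
                else:
                    p = s.position
                    frag = genomic[p : p + k] if side == "downstream" else genomic[max(0, p - k) : p]
                if len(frag) == k:
                    out.add(frag)
        return out

    def negative_flanks(self, side: str, level: str, k: int) -> set[str]:
        """k-mers at loci definitely not adjacent to any editing site."""
        out: set[str] = set()
        for idx, t in enumerate(self.transcripts):
            if level == "edited":
                seq = t.edited_seq
                excl = self._possible_inserted[idx]
                for q in range(len(seq) - k + 1):
                    if side == "downstream":
                        if q - 1 in excl:
                            continue
                    else:
                        if q + k in excl:
                            continue
                    out.add(seq[q : q + k])
            else:
                seq = t.gene.seq
                excl = self._possible_junctions[idx]
                for j in range(len(seq) + 1):
                    if j in excl:
                        continue
                    frag = seq[j : j + k] if side == "downstream" else seq[max(0, j - k) : j]
                    if len(frag) == k:
                        out.add(frag)
        return out

    def site_contexts(self, m: int, n: int, level: str) -> set[str]:
        """Straddling m+n contexts (inserted C removed) of unambiguous C
        sites with full flanks in range."""
        out: set[str] = set()
        for t in self.transcripts:
            edited, genomic = t.edited_seq, t.gene.seq
            for s, e in zip(t.sites, t.edited_positions()):
                if s.base != "C" or s.ambiguous:
                    continue
                if level == "edited":
                    if e - m < 0 or e + 1 + n > len(edited):
                        continue
                    out.add(edited[e - m : e] + edited[e + 1 : e + 1 + n])
                else:
                    p = s.position
                    if p - m < 0 or p + n > len(genomic):
                        continue
                    out.add(genomic[p - m : p] + genomic[p : p + n])
        return out

    def negative_contexts(self, m: int, n: int, level: str) -> set[str]:
        """Contiguous (m+n)-mers whose internal junction is definitely not an
        editing junction."""
        out: set[str] = set()
        for idx, t in enumerate(self.transcripts):
            if level == "edited":
                seq = t.edited_seq
                excl = self._possible_inserted[idx]
                for q in range(len(seq) - (m + n) + 1):
                    j = q + m
                    if j - 1 in excl or j in excl:
                        continue
                    out.add(seq[q : q + m + n])
            else:
                seq = t.gene.seq
                excl = self._possible_junctions[idx]
                for q in range(len(seq) - (m + n) + 1):
                    if q + m in excl:
                        continue
                    out.add(seq[q : q + m + n])
        return out


def max_nonunique_flank(
    tx: Transcriptome, side: str, level: str, max_k: int | None = None
) -> tuple[int, set[str]]:
    """Largest k with a k-mer occurring both adjacent to an unambiguous C
    site and at a definitely-non-edited locus; returns (k*, witnesses).

    Non-uniqueness is monotone in k (a shorter flank of a non-unique flank is
    non-unique), so k* fully summarises the single-sided scan.  k* = 0 means
    every 1-mer context is already unique.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be upstream or downstream")
    if level not in ("edited", "unedited"):
        raise ValueError("level must be edited or unedited")
    limit = max_k or max(len(t.edited_seq) for t in tx.transcripts)
    best_k, witnesses = 0, set()
    for k in range(1, limit + 1):
        hits = tx.site_flanks(side, level, k) & tx.negative_flanks(side, level, k)
        if not hits:
            break
        best_k, witnesses = k, hits
    return best_k, witnesses


def mn_motif_nonunique(
    tx: Transcriptome, m: int, n: int, level: str
) -> tuple[bool, set[str]]:
    """Is some straddling m+n context of an unambiguous C site also found,
    C removed, at a definitely-non-edited locus?"""
    if not (1 <= m <= MAX_FLANK and 1 <= n <= MAX_FLANK):
        raise ValueError(f"m, n must be in 1..{MAX_FLANK}")
    hits = tx.site_contexts(m, n, level) & tx.negative_contexts(m, n, level)
    return bool(hits), hits


def specificity_frontier(
    tx: Transcriptome, level: str, max_mn: int = MAX_FLANK
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Maximal non-unique (m, n) combinations and the minimal sufficient set.

    The frontier is the maximal antichain of the non-unique region under the
    componentwise order; the minimal sufficient set contains the minimal
    (m, n) whose context is always unique — the smallest recognition regions
    that could still specify every site.
    """
    nonunique = {
        (m, n)
        for m in range(1, max_mn + 1)
        for n in range(1, max_mn + 1)
        if mn_motif_nonunique(tx, m, n, level)[0]
    }
    frontier = {
        (m, n)
        for (m, n) in nonunique
        if not any((m2, n2) != (m, n) and m2 >= m and n2 >= n for (m2, n2) in nonunique)
    }
    unique = {
        (m, n)
        for m in range(1, max_mn + 1)
        for n in range(1, max_mn + 1)
        if (m, n) not in nonunique
    }
    minimal_sufficient = {
        (m, n)
        for (m, n) in unique
        if not any((m2, n2) != (m, n) and m2 <= m and n2 <= n for (m2, n2) in unique)
    }
    return frontier, minimal_sufficient
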