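"""Sequence containers and file dialects for insertional-editing analysis.

Coordinate convention
---------------------
An :class:`EditSite` records an insertion *before* a 0-based index into the
unedited genomic sequence: ``position=p`` means the base is inserted between
genomic positions ``p-1`` and ``p`` (``p`` may equal ``len(genomic)`` for a
terminal insertion).  Within a run of genomic Cs every placement of an
inserted C yields the same edited sequence; the canonical representative is
the **leftmost** placement.  A site is *ambiguous* when either genomic
neighbour of the (canonical) insertion point is a C, i.e. exactly when the
placement within the C-run is not unique.

Edited-FASTA dialect
--------------------
Lowercase letters are genome-templated nucleotides, uppercase letters are
editing insertions.  Stripping the uppercase letters recovers the genomic
sequence exactly.  RNA input (u/U) is normalised to the DNA alphabet on read.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_VALID_GENOMIC = set("ACGTN")


class EditedFastaError(ValueError):
    """Raised for malformed edited-FASTA input (names the offending line)."""


@dataclass(frozen=True)
class GeneSequence:
    """A plain nucleotide sequence, genomic or mRNA."""

    id: str
    seq: str
    kind: str = "genomic"  # {"genomic", "mrna"}

    def __post_init__(self):
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - _VALID_GENOMIC
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")
        if "N" in seq:
            warnings.warn(f"{self.id}: sequence contains N", stacklevel=2)
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class EditSite:
    """A single insertional editing event on an unedited genomic sequence.

    ``codon_position`` is the 1-based position of the inserted base within its
    codon in the *edited* reading frame (frame starting at edited position 0).
    ``ambiguous`` is True iff the inserted base is flanked in the edited
    sequence by an equal base (templated or inserted), so the placement within
    the run is not unique.
    """

    position: int
    base: str = "C"
    codon_position: int = 0
    ambiguous: bool = False

    def __post_init__(self):
        if self.base not in NUCLEOTIDES:
            raise ValueError(f"inserted base {self.base!r} not a nucleotide")


def canonicalize_site(genomic: str, position: int, base: str = "C") -> int:
    """Leftmost equivalent placement of an inserted ``base`` in ``genomic``.

    Inserting X before index p and before index p-1 give the same string
    whenever genomic[p-1] == X, so slide left over a run of matching bases.
    """
    p = position
    while p > 0 and genomic[p - 1] == base:
        p -= 1
    return p


def is_ambiguous(genomic: str, position: int, base: str = "C") -> bool:
    """True iff a genomic neighbour of the insertion point equals the base."""
    left = position > 0 and genomic[position - 1] == base
    right = position < len(genomic) and genomic[position] == base
    return left or right


def apply_edits(gene: GeneSequence | str, sites: list[EditSite]) -> str:
    """Insert the sites' bases into the genomic sequence (plain uppercase).

    Sites must be sorted by position; several insertions may share one
    canonical slot (a multi-C insertion), in which case they are applied in
    list order.
    """
    seq = gene.seq if isinstance(gene, GeneSequence) else gene.upper()
    out = []
    prev = 0
    for s in sites:
        if not 0 <= s.position <= len(seq):
            raise ValueError(f"site position {s.position} outside [0, {len(seq)}]")
        if s.position < prev:
            raise ValueError("sites not sorted by position")
        out.append(seq[prev : s.position])
        out.append(s.base)
        prev = s.position
    out.append(seq[prev:])
    return "".join(out)


def _derive_codon_positions(sites: list[EditSite]) -> list[EditSite]:
    """Fill codon_position from the edited reading frame (frame 0)."""
    out = []
    for i, s in enumerate(sorted(sites)):
        edited_index = s.position + i
        out.append(replace(s, codon_position=(edited_index % 3) + 1))
    return out


@dataclass
class EditedTranscript:
    """An unedited genomic gene plus its ordered set of insertion sites.

    Invariants: deleting the inserted characters from :attr:`edited_seq`
    recovers ``gene.seq`` exactly, and ``len(edited_seq) == len(gene) +
    len(sites)``.
    """

    gene: GeneSequence
    sites: list[EditSite] = field(default_factory=list)

    def __post_init__(self):
        canon = sorted(
            replace(s, position=canonicalize_site(self.gene.seq, s.position, s.base))
            for s in self.sites
        )
        canon = _derive_codon_positions(canon)
        # ambiguity judged on the edited sequence: an inserted base flanked by
        # an equal base (templated or inserted) has no unique placement
        edited = apply_edits(self.gene, canon)
        final = []
        for i, s in enumerate(canon):
            e = s.position + i
            amb = (e > 0 and edited[e - 1] == s.base) or (
                e + 1 < len(edited) and edited[e + 1] == s.base
            )
            final.append(replace(s, ambiguous=amb))
        self.sites = final

    @property
    def edited_seq(self) -> str:
        return apply_edits(self.gene, self.sites)

    @property
    def protein(self) -> str:
        """Translation of the edited mRNA (standard code, trailing partial
        codon dropped)."""
        s = self.edited_seq
        return str(Seq(s[: len(s) - len(s) % 3]).translate())

    def c_sites(self, unambiguous_only: bool = False) -> list[EditSite]:
        return [
            s
            for s in self.sites
            if s.base == "C" and not (unambiguous_only and s.ambiguous)
        ]

    def edited_positions(self) -> list[int]:
        """0-based indices of the inserted bases within the edited sequence."""
        return [s.position + i for i, s in enumerate(self.sites)]

    def to_edited_string(self) -> str:
        """Edited sequence with insertions uppercase, templated lowercase."""
        chars = list(self.gene.seq.lower())
        for i, s in enumerate(self.sites):
            chars.insert(s.position + i, s.base.upper())
        return "".join(chars)


def parse_edited_sequence(gene_id: str, text: str) -> EditedTranscript:
    """Parse one edited-sequence body (lowercase templated / uppercase
    inserted) into an :class:`EditedTranscript`."""
    genomic = []
    raw_sites = []  # (genomic position, base)
    for ch in text:
        c = ch.replace("u", "t").replace("U", "T") if ch in "uU" else ch
        if c.islower():
            if c.upper() not in _VALID_GENOMIC:
                raise EditedFastaError(f"{gene_id}: illegal character {ch!r}")
            genomic.append(c.upper())
        elif c.isupper():
            if c not in _VALID_GENOMIC:
                raise EditedFastaError(f"{gene_id}: illegal character {ch!r}")
            if c != "C":
                warnings.warn(
                    f"{gene_id}: non-C insertion {c!r}; excluded from C-site "
                    "statistics downstream",
                    stacklevel=2,
                )
            raw_sites.append((len(genomic), c))
        else:
            raise EditedFastaError(f"{gene_id}: illegal character {ch!r}")
    gene = GeneSequence(gene_id, "".join(genomic), kind="genomic")
    sites = [EditSite(position=p, base=b) for p, b in raw_sites]
    return EditedTranscript(gene=gene, sites=sites)


def read_edited_fasta(source) -> list[EditedTranscript]:
    """Read an edited-FASTA file or string into transcripts.

    ``source`` may be a path, an open handle, or the text itself (anything
    starting with ``>``).
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle = io.StringIO(source)
    elif hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    out = []
    header = None
    body: list[str] = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                out.append(parse_edited_sequence(header, "".join(body)))
            header = line[1:].split()[0]
            body = []
        else:
            if header is None:
                raise EditedFastaError(f"line {lineno}: sequence before header")
            body.append(line)
    if header is not None:
        out.append(parse_edited_sequence(header, "".join(body)))
    return out


def write_edited_fasta(transcripts: list[EditedTranscript], path=None, width: int = 70) -> str:
    """Write transcripts in the edited-FASTA dialect; returns the text."""
    chunks = []
    for t in transcripts:
        s = t.to_edited_string()
        lines = [s[i : i + width] for i in range(0, len(s), width)]
        chunks.append(f">{t.gene.id}\n" + "\n".join(lines) + "\n")
    text = "".join(chunks)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_fasta(source) -> list[GeneSequence]:
    """Plain FASTA (genomic or protein used as nucleotide container)."""
    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = io.StringIO(source)
    return [
        GeneSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")
    ]


# ---------------------------------------------------------------------------
# Scoring models: BLOSUM + reference protein, or PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_BLOSUM_CACHE: dict[str, object] = {}


def _blosum(name: str):
    if name not in _BLOSUM_CACHE:
        _BLOSUM_CACHE[name] = substitution_matrices.load(name)
    return _BLOSUM_CACHE[name]


@dataclass
class ScoringModel:
    """Per-model-position amino-acid scores for the insertion-aware aligner.

    ``matrix`` mode scores position *j* of the model as
    ``BLOSUM(reference[j], aa)``; ``pssm`` mode looks up a per-position table
    of log-odds scores.  Gap costs follow the convention that a gap of length
    L costs ``gap_open + (L-1) * gap_extend``; ``insertion_penalty`` is charged
    per inserted C.
    """

    mode: str  # {"matrix", "pssm"}
    reference: str | None = None
    matrix_name: str = "BLOSUM62"
    pssm: list[dict[str, float]] | None = None
    gap_open: float = 11.0
    gap_extend: float = 1.0
    insertion_penalty: float = 0.0

    def __post_init__(self):
        if self.mode == "matrix":
            if not self.reference:
                raise ValueError("matrix mode requires a reference protein")
            self.reference = self.reference.upper()
        elif self.mode == "pssm":
            if not self.pssm:
                raise ValueError("pssm mode requires a non-empty table")
            for i, row in enumerate(self.pssm):
                missing = set(AMINO_ACIDS) - set(row)
                if missing:
                    raise ValueError(f"PSSM row {i} missing scores for {sorted(missing)}")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.reference) if self.mode == "matrix" else len(self.pssm)

    def score(self, j: int, aa: str) -> float:
        """Score of amino acid ``aa`` at model position ``j`` (0-based)."""
        if self.mode == "matrix":
            m = _blosum(self.matrix_name)
            try:
                return float(m[self.reference[j], aa])
            except IndexError:
                return float(m[self.reference[j], "X"])
        row = self.pssm[j]
        return float(row.get(aa, min(row.values())))

    @classmethod
    def from_protein(cls, protein: str, matrix_name: str = "BLOSUM62", **kw) -> "ScoringModel":
        return cls(mode="matrix", reference=protein, matrix_name=matrix_name, **kw)


def read_pssm(source) -> ScoringModel:
    """Read a PSI-BLAST ASCII position-specific scoring matrix.

    Expects the standard layout: a column-header line listing 20 amino acids,
    then one row per model position starting with the position index and the
    query residue followed by (at least) 20 integer log-odds scores.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    aas: list[str] | None = None
    rows: list[dict[str, float]] = []
    for line in lines:
        toks = line.split()
        if aas is None:
            # header: at least 20 single-letter amino-acid columns
            letters = [t for t in toks if len(t) == 1 and t in AMINO_ACIDS]
            if len(letters) >= 20:
                aas = letters[:20]
            continue
        if len(toks) >= 22 and toks[0].isdigit() and re.fullmatch(r"[A-Z]", toks[1]):
            try:
                scores = [float(t) for t in toks[2:22]]
            except ValueError as exc:
                raise EditedFastaError(f"malformed PSSM row: {line!r}") from exc
            rows.append(dict(zip(aas, scores)))
        elif toks and toks[0].isdigit():
            raise EditedFastaError(f"malformed PSSM row (column count): {line!r}")
    if aas is None or not rows:
        raise EditedFastaError("no PSSM table found in input")
    return ScoringModel(mode="pssm", pssm=rows)


def write_pssm(model: ScoringModel) -> str:
    """Serialise a pssm-mode model back to the PSI-BLAST ASCII layout."""
    if model.mode != "pssm":
        raise ValueError("only pssm-mode models can be written")
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + "  ".join(AMINO_ACIDS)]
    for i, row in enumerate(model.pssm, 1):
        scores = " ".join(f"{int(row[a]):3d}" for a in AMINO_ACIDS)
        lines.append(f"{i:5d} X  {scores}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["gene_id", "position", "base", "codon_position", "ambiguous"]


def sites_to_frame(transcripts: list[EditedTranscript]) -> pd.DataFrame:
    rows = [
        (t.gene.id, s.position, s.base, s.codon_position, s.ambiguous)
        for t in transcripts
        for s in t.sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> dict[str, list[EditSite]]:
    out: dict[str, list[EditSite]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append(
            EditSite(
                position=int(row.position),
                base=str(row.base),
                codon_position=int(row.codon_position),
                ambiguous=bool(row.ambiguous),
            )
        )
    return out
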