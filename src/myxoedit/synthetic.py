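"""Synthetic paired-organism edited genes with ground truth.

The generator emulates a pair of related myxomycete mitochondrial genes: a
common ancestral edited mRNA (an in-frame ORF with ~25% GC) acquires single-C
insertion sites at a density of about one per 25 nt under a mutation-selection
filter — a candidate site replaces the ancestral base with a C at the RNA
level, and is accepted always when synonymous but only with probability
(1 - conservation target) when it changes the encoded amino acid.  This is
what couples codon-position bias to selection strength.  The two descendants
then diverge by per-codon-position substitutions calibrated so the realized
second-codon-position identity equals the requested target, with first/third
position divergence scaled by the empirically observed ratios.

Editing sites lost in one descendant remain as genome-templated Cs there (the
mRNA column is unchanged), so the two edited mRNAs stay column-aligned against
the ancestral coordinate system; the ground truth records exactly which sites
are edited in which organism and which are shared.

A ``motif_spec`` mapping ``{offset: conservation_level}`` embeds a recognition
signal: columns at the given mRNA offsets from every shared site are held at
the requested cross-species conservation level (1.0 = fully conserved).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .seqio import EditSite, EditedTranscript, GeneSequence

#: Ratio of first/third codon-position divergence to second-position
#: divergence, from the observed all-gene background conservations
#: (76.9 / 84.8 / 65.1 percent identity).
DIVERGENCE_RATIO_1 = (1 - 0.769) / (1 - 0.848)
DIVERGENCE_RATIO_3 = (1 - 0.651) / (1 - 0.848)

NT = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the paired-organism generator.

    Defaults follow the observed system: 25% GC, one insertion per 25 nt,
    second-position identity between organisms in the 60-100% range, and
    proposal weights over codon positions chosen so that, after the
    mutation-selection filter at mid-range conservation, the realized share of
    sites per codon position is near the observed ~34/10/56 split.
    """

    n_genes: int = 16
    protein_len_range: tuple[int, int] = (100, 300)
    gc_content: float = 0.25
    edit_density: float = 1 / 25
    codon_position_weights: tuple[float, float, float] = (0.45, 0.25, 0.30)
    conservation_targets: float | tuple[float, float] | list[float] = (0.60, 1.00)
    shared_site_fraction: float = 0.7
    motif_spec: dict[int, float] | None = None
    translation_table: int = 1

    def __post_init__(self):
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if not 0 < self.edit_density < 1:
            raise ValueError("edit_density must be in (0,1)")
        w = self.codon_position_weights
        if len(w) != 3 or any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("codon_position_weights must be 3 nonnegative, sum>0")
        if not 0 <= self.shared_site_fraction <= 1:
            raise ValueError("shared_site_fraction must be in [0,1]")
        if self.motif_spec:
            for d, lvl in self.motif_spec.items():
                if d == 0 or not -9 <= d <= 9:
                    raise ValueError("motif offsets must be in [-9,9], nonzero")
                if not 0 <= lvl <= 1:
                    raise ValueError("motif conservation levels must be in [0,1]")

    def base_frequencies(self) -> np.ndarray:
        g = self.gc_content
        return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


@dataclass
class GenePairTruth:
    """One simulated gene pair with complete bookkeeping."""

    gene_id: str
    transcript_a: EditedTranscript
    transcript_b: EditedTranscript
    protein_a: str
    protein_b: str
    #: canonical EditSite pairs (organism A, organism B) for shared sites
    shared_sites: list[tuple[EditSite, EditSite]]
    #: ancestral-mRNA positions of the shared sites
    shared_mrna_positions: list[int]
    #: realized per-codon-position identity fractions between the two mRNAs
    identity: tuple[float, float, float]
    conservation_target: float = field(default=float("nan"))


def _codon_tools(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = set(table.stop_codons)

    def translate_codon(codon: str) -> str | None:
        return None if codon in stops else table.forward_table[codon]

    return stops, translate_codon


def _stop_adjusted_frequencies(pi: np.ndarray, stops) -> np.ndarray:
    """Tilted per-base frequencies whose stop-rejected codon draw realises
    the requested composition (rejection of the AT-rich stop codons would
    otherwise enrich GC)."""
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    idx = np.array([[NT.tolist().index(ch) for ch in c] for c in codons])
    keep = np.array([c not in stops for c in codons])
    q = pi.copy()
    for _ in range(100):
        w = q[idx].prod(axis=1)
        w[~keep] = 0.0
        w /= w.sum()
        realized = np.zeros(4)
        for b in range(4):
            realized[b] = (w[:, None] * (idx == b)).sum() / 3
        q = q * pi / realized
        q /= q.sum()
    return q


def _draw_orf(rng: np.random.Generator, n_codons: int, pi: np.ndarray, stops) -> list[str]:
    """IID codons with stop rejection; base draw tilted so the realised
    nucleotide composition matches ``pi``."""
    q = _stop_adjusted_frequencies(pi, stops)
    seq: list[str] = []
    while len(seq) < 3 * n_codons:
        codon = "".join(rng.choice(NT, size=3, p=q))
        if codon not in stops:
            seq.extend(codon)
    return seq


def _position_targets(target2: float) -> tuple[float, float, float]:
    f1 = max(0.30, 1 - DIVERGENCE_RATIO_1 * (1 - target2))
    f3 = max(0.30, 1 - DIVERGENCE_RATIO_3 * (1 - target2))
    return f1, target2, f3


def simulate_gene_pair(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    gene_id: str = "gene",
    conservation_target: float | None = None,
) -> GenePairTruth:
    """Simulate one homologous gene pair with editing and divergence.

    ``conservation_target`` overrides the config's target for this gene (used
    by :func:`simulate_transcriptome` to spread genes over a range).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stops, _ = _codon_tools(config.translation_table)
    pi = config.base_frequencies()

    if conservation_target is None:
        ct = config.conservation_targets
        if isinstance(ct, (int, float)):
            conservation_target = float(ct)
        elif isinstance(ct, tuple) and len(ct) == 2:
            conservation_target = float(rng.uniform(*ct))
        else:
            raise ValueError("per-gene targets require simulate_transcriptome")
    if not 0 < conservation_target <= 1:
        raise ValueError("conservation target must be in (0,1]")

    lo, hi = config.protein_len_range
    n_codons = int(rng.integers(lo, hi + 1))
    mrna = _draw_orf(rng, n_codons, pi, stops)
    n_nt = 3 * n_codons

    # --- editing-site creation under mutation-selection -------------------
    n_sites = int(rng.poisson(n_nt * config.edit_density))
    w = np.asarray(config.codon_position_weights, dtype=float)
    w = w / w.sum()
    accept_nonsyn = 1.0 - conservation_target
    site_positions: set[int] = set()
    attempts = 0
    while len(site_positions) < n_sites and attempts < 400 * max(n_sites, 1):
        attempts += 1
        cp = int(rng.choice(3, p=w))  # 0-based codon offset
        codon_idx = int(rng.integers(n_codons))
        pos = 3 * codon_idx + cp
        if pos in site_positions:
            continue
        codon = "".join(mrna[3 * codon_idx : 3 * codon_idx + 3])
        new_codon = codon[:cp] + "C" + codon[cp + 1 :]
        if new_codon in stops:
            continue
        table = CodonTable.unambiguous_dna_by_id[config.translation_table]
        synonymous = (
            codon not in stops and table.forward_table[codon] == table.forward_table[new_codon]
        )
        if not synonymous and rng.random() >= accept_nonsyn:
            continue
        # two sites in one C-run would collapse onto the same canonical
        # insertion slot; keep at most one site per run
        left, right = pos, pos
        while left > 0 and mrna[left - 1] == "C":
            left -= 1
        while right + 1 < n_nt and mrna[right + 1] == "C":
            right += 1
        if any(q in site_positions for q in range(left, right + 1)):
            continue
        site_positions.add(pos)
        mrna[pos] = "C"
    if len(site_positions) < n_sites:
        warnings.warn(
            f"{gene_id}: placed {len(site_positions)}/{n_sites} sites "
            "(selection too strict for requested density)",
            stacklevel=2,
        )
    sites_sorted = sorted(site_positions)

    # --- retention in the descendants -------------------------------------
    edited_a: set[int] = set()
    edited_b: set[int] = set()
    for pos in sites_sorted:
        if rng.random() < config.shared_site_fraction:
            edited_a.add(pos)
            edited_b.add(pos)
        elif rng.random() < 0.5:
            edited_a.add(pos)
        else:
            edited_b.add(pos)
    shared = sorted(edited_a & edited_b)

    # --- divergence with exact per-position mismatch counts ----------------
    seq_a = list(mrna)
    seq_b = list(mrna)
    site_adjacent = {p - 1 for p in site_positions} | {p + 1 for p in site_positions}
    protected = set(site_positions)

    # motif columns: controlled conservation around shared sites
    motif_columns: dict[int, float] = {}
    if config.motif_spec:
        for d, level in config.motif_spec.items():
            cols = [
                q + d
                for q in shared
                if 0 <= q + d < n_nt and (q + d) not in site_positions
            ]
            for c in cols:
                motif_columns[c] = min(motif_columns.get(c, 1.0), level)
    protected |= set(motif_columns)

    def mutate_column(col: int) -> bool:
        """Substitute one lineage at ``col``; returns False when the single
        composition-weighted draw is unusable (same base, C next to a site,
        or a stop codon), in which case another column is tried instead —
        retrying the same column would bias the stationary composition."""
        target_seq = seq_a if rng.random() < 0.5 else seq_b
        current = target_seq[col]
        b = str(rng.choice(NT, p=pi))
        if b == current:
            return False
        if b == "C" and col in site_adjacent:
            return False  # keep C-run structure identical around sites
        codon_start = 3 * (col // 3)
        codon = target_seq[codon_start : codon_start + 3]
        codon[col - codon_start] = b
        if "".join(codon) in stops:
            return False
        target_seq[col] = b
        return True

    targets = _position_targets(conservation_target)
    for cp in range(3):
        total_c = n_codons  # columns at this codon position
        pool = [
            p
            for p in range(cp, n_nt, 3)
            if p not in protected and not (p in site_adjacent and mrna[p] == "C")
        ]
        n_mismatch = min(round((1 - targets[cp]) * total_c), len(pool))
        remaining = [pool[i] for i in rng.permutation(len(pool))]
        done = 0
        for _ in range(4):  # extra passes when the single draw was unusable
            if done >= n_mismatch or not remaining:
                break
            still = []
            for col in remaining:
                if done < n_mismatch and mutate_column(col):
                    done += 1
                else:
                    still.append(col)
            remaining = still

    # motif columns at partial conservation: exact-count mismatches
    if motif_columns:
        by_level: dict[float, list[int]] = {}
        for c, lvl in motif_columns.items():
            by_level.setdefault(lvl, []).append(c)
        for lvl, cols in by_level.items():
            n_mismatch = round((1 - lvl) * len(cols))
            remaining = [cols[i] for i in rng.permutation(len(cols))]
            done = 0
            for _ in range(4):
                if done >= n_mismatch or not remaining:
                    break
                still = []
                for col in remaining:
                    if done < n_mismatch and mutate_column(col):
                        done += 1
                    else:
                        still.append(col)
                remaining = still

    # --- assemble organisms ------------------------------------------------
    def build(org: str, seq: list[str], edited: set[int]) -> EditedTranscript:
        edited_sorted = sorted(edited)
        genomic = [b for i, b in enumerate(seq) if i not in edited]
        raw = [
            EditSite(position=q - rank, base="C")
            for rank, q in enumerate(edited_sorted)
        ]
        t = EditedTranscript(
            gene=GeneSequence(f"{gene_id}_{org}", "".join(genomic)), sites=raw
        )
        assert t.edited_seq == "".join(seq)
        return t

    ta = build("A", seq_a, edited_a)
    tb = build("B", seq_b, edited_b)
    pos_a = sorted(edited_a)
    pos_b = sorted(edited_b)
    shared_pairs = [
        (ta.sites[pos_a.index(q)], tb.sites[pos_b.index(q)]) for q in shared
    ]
    ident = tuple(
        float(
            np.mean([seq_a[p] == seq_b[p] for p in range(cp, n_nt, 3)])
        )
        for cp in range(3)
    )
    return GenePairTruth(
        gene_id=gene_id,
        transcript_a=ta,
        transcript_b=tb,
        protein_a=ta.protein,
        protein_b=tb.protein,
        shared_sites=shared_pairs,
        shared_mrna_positions=shared,
        identity=ident,
        conservation_target=conservation_target,
    )


def simulate_transcriptome(config: SimulationConfig, seed: int) -> list[GenePairTruth]:
    """Simulate ``config.n_genes`` independent gene pairs, deterministically
    under ``seed``; per-gene conservation targets are drawn from the config
    range (or taken from a per-gene list)."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(config.n_genes)
    ct = config.conservation_targets
    if isinstance(ct, list):
        if len(ct) != config.n_genes:
            raise ValueError("per-gene target list length != n_genes")
        targets = [float(x) for x in ct]
    elif isinstance(ct, tuple) and len(ct) == 2:
        targets = list(
            np.random.default_rng(root.spawn(1)[0]).uniform(ct[0], ct[1], config.n_genes)
        )
    else:
        targets = [float(ct)] * config.n_genes
    out = []
    for i, (child, tgt) in enumerate(zip(children, targets)):
        out.append(
            simulate_gene_pair(
                config,
                np.random.default_rng(child),
                gene_id=f"gene{i:03d}",
                conservation_target=tgt,
            )
        )
    return out
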