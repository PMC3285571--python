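"""Codon-position bias of C-insertion sites and its link to selection.

Under the mutation-selection model of editing-site origin, a genomic deletion
followed by restorative C insertion replaces the original nucleotide with a C
at the RNA level.  Changes at the third codon position are usually synonymous
and survive selection; changes at the second almost never are.  Genes under
stronger selection (higher cross-species conservation) should therefore show
a stronger excess of third- over second-position sites.  The bias is
quantified as R = N3/N2 with the counting-error propagation
sigma_R = R * sqrt(1/N2 + 1/N3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .seqio import EditedTranscript

#: Conservation range over which gene groups are formed.
GROUP_RANGE = (0.60, 1.00)


@dataclass(frozen=True)
class BiasEstimate:
    """Pooled unambiguous C-site counts per codon position with the bias
    ratio R = N3/N2 and its propagated counting error."""

    n1: int
    n2: int
    n3: int
    group: str = ""

    @property
    def ratio(self) -> float:
        if self.n2 == 0:
            raise ZeroDivisionError("N2 = 0: bias ratio undefined")
        return self.n3 / self.n2

    @property
    def sigma(self) -> float:
        if self.n2 == 0 or self.n3 == 0:
            raise ZeroDivisionError("sigma undefined for zero counts")
        return self.ratio * math.sqrt(1 / self.n2 + 1 / self.n3)


def count_sites(
    transcripts: list[EditedTranscript], unambiguous_only: bool = True
) -> tuple[int, int, int]:
    """Pooled (N1, N2, N3) of C-insertion sites over the given transcripts.

    Pass the union of both organisms' transcripts to count shared sites twice
    (once per organism), as in the all-unambiguous-site tallies.
    """
    counts = [0, 0, 0]
    for t in transcripts:
        for s in t.c_sites(unambiguous_only=unambiguous_only):
            counts[s.codon_position - 1] += 1
    return tuple(counts)


def bias_ratio(n2: int, n3: int) -> tuple[float, float]:
    """R = N3/N2 and its error from independent sqrt-N counting errors."""
    if n2 <= 0:
        raise ZeroDivisionError("N2 must be positive")
    r = n3 / n2
    if n3 == 0:
        return r, 0.0
    return r, r * math.sqrt(1 / n2 + 1 / n3)


def codon_position_shares(n1: int, n2: int, n3: int) -> tuple[float, float, float]:
    """Percentage share of each codon position among the counted sites."""
    total = n1 + n2 + n3
    if total == 0:
        raise ValueError("no sites")
    return tuple(100.0 * n / total for n in (n1, n2, n3))


def assign_group(
    conservation2: float, n_groups: int = 2, bounds: tuple[float, float] = GROUP_RANGE
) -> int:
    """Group index (0 = least conserved) under an equal split of ``bounds``.

    Genes exactly on an interior boundary go to the upper group; values are
    clipped into the range.
    """
    lo, hi = bounds
    x = min(max(conservation2, lo), hi)
    width = (hi - lo) / n_groups
    # epsilon guards float representation of interval edges (0.80 -> upper)
    idx = int((x - lo) / width + 1e-9)
    return min(idx, n_groups - 1)


def group_and_trend(
    genes: list[tuple[float, EditedTranscript]] | list[tuple[float, list[EditedTranscript]]],
    n_groups: int = 2,
    bounds: tuple[float, float] = GROUP_RANGE,
) -> pd.DataFrame:
    """Pool site counts per conservation group and report R with errors.

    ``genes`` is a list of (conservation2, transcript-or-transcripts) pairs;
    a pair per organism may share one conservation value by passing both
    transcripts in a list.  Returns one row per occupied group with columns
    group, lo, hi, N1, N2, N3, R, sigma; empty groups are omitted.  The
    ``trend`` attribute (``df.attrs['monotone_beyond_1sigma']``) records
    whether the most conserved occupied group exceeds the least conserved one
    by more than their combined 1-sigma errors.
    """
    pooled: dict[int, list[int]] = {}
    for conservation2, tx in genes:
        txs = tx if isinstance(tx, list) else [tx]
        g = assign_group(conservation2, n_groups, bounds)
        n1, n2, n3 = count_sites(txs)
        acc = pooled.setdefault(g, [0, 0, 0])
        acc[0] += n1
        acc[1] += n2
        acc[2] += n3
    lo, hi = bounds
    width = (hi - lo) / n_groups
    rows = []
    for g in sorted(pooled):
        n1, n2, n3 = pooled[g]
        if n2 > 0:
            r, sig = bias_ratio(n2, n3)
        else:
            r, sig = float("nan"), float("nan")
        rows.append((g, lo + g * width, lo + (g + 1) * width, n1, n2, n3, r, sig))
    df = pd.DataFrame(
        rows, columns=["group", "lo", "hi", "N1", "N2", "N3", "R", "sigma"]
    )
    df.attrs["monotone_beyond_1sigma"] = False
    if len(df) >= 2:
        first, last = df.iloc[0], df.iloc[-1]
        if not (math.isnan(first.R) or math.isnan(last.R)):
            gap = last.R - first.R
            err = math.hypot(first.sigma, last.sigma)
            df.attrs["monotone_beyond_1sigma"] = bool(gap > err)
    return df


def predicted_vs_true_agreement(
    true_pairs: list[tuple[float, list[EditedTranscript]]],
    predicted_pairs: list[tuple[float, list[EditedTranscript]]],
) -> pd.DataFrame:
    """Per-gene (conservation2, R) computed from true and predicted edits.

    Returns a frame with one row per gene: conservation and bias ratio both
    ways plus their deviations, for judging whether predicted transcripts can
    stand in for unknown real ones.
    """
    rows = []
    for (c_true, tx_t), (c_pred, tx_p) in zip(true_pairs, predicted_pairs):
        n1t, n2t, n3t = count_sites(tx_t)
        n1p, n2p, n3p = count_sites(tx_p)
        rt = n3t / n2t if n2t else float("nan")
        rp = n3p / n2p if n2p else float("nan")
        rows.append(
            (
                tx_t[0].gene.id,
                len(tx_t[0].gene),
                c_true,
                c_pred,
                rt,
                rp,
                abs(c_pred - c_true),
                abs(rp - rt) if not (math.isnan(rt) or math.isnan(rp)) else float("nan"),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gene_len",
            "conservation2_true",
            "conservation2_pred",
            "R_true",
            "R_pred",
            "conservation2_dev",
            "R_dev",
        ],
    )
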