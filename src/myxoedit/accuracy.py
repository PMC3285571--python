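"""Scoring of predicted editing sites against experimentally known ones.

Each true C-insertion site is matched greedily to the nearest predicted site
within 2 nt of genomic distance and classified as correct (exact), one away,
or two away; unmatched interior sites — missed or spuriously added — count as
"three or more away".  True sites near the gene termini that the prediction
missed are excluded (the predictor is unreliable at gene ends), as are true
non-C insertions and any prediction in their immediate vicinity.  Percentages
are reported relative to the number of sites the prediction actually scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seqio import EditSite, EditedTranscript

#: window (nt) at each gene end within which missed true sites are not scored
DEFAULT_END_MARGIN = 9
#: predictions within this distance of a non-C true insertion are excluded
NON_C_VICINITY = 1


@dataclass
class AccuracyReport:
    """Counts per distance class; percentages are relative to n_scored."""

    correct: int = 0
    one_away: int = 0
    two_away: int = 0
    three_plus: int = 0
    excluded_end_sites: int = 0
    excluded_non_c: int = 0

    @property
    def n_scored(self) -> int:
        return self.correct + self.one_away + self.two_away + self.three_plus

    def percentages(self) -> dict[str, float]:
        n = self.n_scored
        if n == 0:
            return {k: float("nan") for k in ("correct", "one_away", "two_away", "three_plus")}
        return {
            "correct": 100 * self.correct / n,
            "one_away": 100 * self.one_away / n,
            "two_away": 100 * self.two_away / n,
            "three_plus": 100 * self.three_plus / n,
        }

    def __add__(self, other: "AccuracyReport") -> "AccuracyReport":
        return AccuracyReport(
            self.correct + other.correct,
            self.one_away + other.one_away,
            self.two_away + other.two_away,
            self.three_plus + other.three_plus,
            self.excluded_end_sites + other.excluded_end_sites,
            self.excluded_non_c + other.excluded_non_c,
        )


def classify_predictions(
    predicted: list[EditSite],
    truth: EditedTranscript,
    end_margin: int = DEFAULT_END_MARGIN,
) -> AccuracyReport:
    """Classify predicted C-insertion sites against the true transcript.

    Matching is greedy nearest-neighbour over genomic insertion positions
    with an eligibility window of |distance| <= 2; remaining unmatched true
    sites are excluded if within ``end_margin`` nt of either gene terminus,
    otherwise scored as three-plus, as is every unmatched prediction.
    """
    n = len(truth.gene)
    true_c = [s for s in truth.sites if s.base == "C"]
    true_non_c = [s for s in truth.sites if s.base != "C"]
    rep = AccuracyReport(excluded_non_c=0)

    pred = sorted(predicted, key=lambda s: s.position)
    keep = []
    for p in pred:
        if any(abs(p.position - s.position) <= NON_C_VICINITY for s in true_non_c):
            rep.excluded_non_c += 1
        else:
            keep.append(p)
    pred = keep
    rep.excluded_non_c += len(true_non_c)

    # greedy nearest-neighbour: smallest distances first, deterministic order
    pairs = sorted(
        (
            (abs(t.position - p.position), ti, pi)
            for ti, t in enumerate(true_c)
            for pi, p in enumerate(pred)
            if abs(t.position - p.position) <= 2
        ),
    )
    used_t: set[int] = set()
    used_p: set[int] = set()
    for d, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        if d == 0:
            rep.correct += 1
        elif d == 1:
            rep.one_away += 1
        else:
            rep.two_away += 1

    for ti, t in enumerate(true_c):
        if ti in used_t:
            continue
        if t.position <= end_margin or t.position >= n - end_margin:
            rep.excluded_end_sites += 1
        else:
            rep.three_plus += 1
    rep.three_plus += sum(1 for pi in range(len(pred)) if pi not in used_p)
    return rep


def accuracy_by_group(
    reports: dict[str, AccuracyReport], gene_groups: dict[str, str]
) -> dict[str, AccuracyReport]:
    """Pool per-gene reports by group label before computing percentages.

    ``gene_groups`` maps every gene id in ``reports`` to exactly one group.
    """
    missing = set(reports) - set(gene_groups)
    if missing:
        raise ValueError(f"genes with no group: {sorted(missing)}")
    out: dict[str, AccuracyReport] = {}
    for gid, rep in reports.items():
        g = gene_groups[gid]
        out[g] = out.get(g, AccuracyReport()) + rep
    return out


def report_frame(reports: dict[str, AccuracyReport]) -> pd.DataFrame:
    rows = []
    for key, r in reports.items():
        pct = r.percentages()
        rows.append(
            (
                key,
                r.n_scored,
                r.correct,
                r.one_away,
                r.two_away,
                r.three_plus,
                r.excluded_end_sites,
                r.excluded_non_c,
                pct["correct"],
                pct["one_away"],
                pct["two_away"],
                pct["three_plus"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_scored",
            "correct",
            "one_away",
            "two_away",
            "three_plus",
            "excluded_end_sites",
            "excluded_non_c",
            "pct_correct",
            "pct_one_away",
            "pct_two_away",
            "pct_three_plus",
        ],
    )
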