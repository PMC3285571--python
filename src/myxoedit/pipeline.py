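"""One-seed end-to-end run: simulate -> predict -> score -> conserve -> motif -> bias.

Every stage writes plain TSV artifacts into a run directory and contributes a
headline entry to ``summary.json``; all randomness flows from the single seed
in :class:`RunConfig`, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import accuracy, codon_bias, conservation, motifs, predict, seqio, synthetic

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str | Path
    seed: int
    sim: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    matrix_name: str = "BLOSUM90"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    insertion_penalty: float = 0.0
    window: int = 9
    cutoff: float = conservation.DEFAULT_CUTOFF
    stages: tuple[str, ...] = ("predict", "conserve", "motif", "bias")
    #: cap on genes pushed through the (costlier) predictor stage
    predict_max_genes: int | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    t0 = time.perf_counter()
    truths = synthetic.simulate_transcriptome(config.sim, config.seed)
    seqio.write_edited_fasta([t.transcript_a for t in truths], out / "organismA.edited.fasta")
    seqio.write_edited_fasta([t.transcript_b for t in truths], out / "organismB.edited.fasta")
    seqio.sites_to_frame([t.transcript_a for t in truths]).to_csv(
        out / "sites_A.tsv", sep="\t", index=False
    )
    seqio.sites_to_frame([t.transcript_b for t in truths]).to_csv(
        out / "sites_B.tsv", sep="\t", index=False
    )
    summary["n_genes"] = len(truths)
    summary["total_sites_A"] = sum(len(t.transcript_a.sites) for t in truths)
    log.info("simulate: %d genes in %.1fs", len(truths), time.perf_counter() - t0)

    alignments = [
        conservation.build_four_way(t.transcript_a, t.transcript_b, t.gene_id)
        for t in truths
    ]
    per_gene_f2 = {
        t.gene_id: conservation.per_gene_background(a)[1]
        for t, a in zip(truths, alignments)
    }

    if "predict" in config.stages:
        t0 = time.perf_counter()
        try:
            reports: dict[str, accuracy.AccuracyReport] = {}
            subset = truths[: config.predict_max_genes]
            for truth in subset:
                model = seqio.ScoringModel.from_protein(
                    truth.protein_b,
                    config.matrix_name,
                    gap_open=config.gap_open,
                    gap_extend=config.gap_extend,
                    insertion_penalty=config.insertion_penalty,
                )
                res = predict.predict_sites(truth.transcript_a.gene.seq, model)
                reports[truth.gene_id] = accuracy.classify_predictions(
                    res.predicted_sites, truth.transcript_a
                )
            groups = {
                gid: "more_conserved"
                if per_gene_f2[gid] >= conservation.LESS_CONSERVED_THRESHOLD
                else "less_conserved"
                for gid in reports
            }
            pooled = accuracy.accuracy_by_group(reports, groups)
            pooled["all"] = sum(reports.values(), accuracy.AccuracyReport())
            accuracy.report_frame(pooled).to_csv(
                out / "prediction_accuracy.tsv", sep="\t", index=False
            )
            summary["prediction_pct_correct"] = pooled["all"].percentages()["correct"]
        except Exception as exc:  # noqa: BLE001
            raise StageError("predict", exc) from exc
        log.info("predict: %.1fs", time.perf_counter() - t0)

    if "conserve" in config.stages:
        t0 = time.perf_counter()
        try:
            backgrounds = conservation.background_frequencies(alignments)
            shared = conservation.find_shared_unambiguous_sites(alignments)
            summary["backgrounds"] = [round(f, 4) for f in backgrounds]
            summary["n_shared_unambiguous"] = len(shared)
            profiles = []
            n_significant = 0
            for cp in (1, 3):
                stratum = [s for s in shared if s.codon_position == cp]
                if not stratum:
                    continue
                prof = conservation.profile_window(
                    stratum, backgrounds, window=config.window, cutoff=config.cutoff
                )
                prof.insert(0, "site_codon_position", cp)
                profiles.append(prof)
                n_significant += int(prof["significant"].sum())
            if profiles:
                pd.concat(profiles).to_csv(
                    out / "conservation_profile.tsv", sep="\t", index=False
                )
            summary["n_significant_offsets"] = n_significant
        except Exception as exc:  # noqa: BLE001
            raise StageError("conserve", exc) from exc
        log.info("conserve: %.1fs", time.perf_counter() - t0)

    if "motif" in config.stages:
        t0 = time.perf_counter()
        try:
            tx = motifs.Transcriptome([t.transcript_a for t in truths])
            rows = []
            for level in ("edited", "unedited"):
                for side in ("upstream", "downstream"):
                    kstar, _ = motifs.max_nonunique_flank(tx, side, level)
                    rows.append((level, side, kstar))
                frontier, sufficient = motifs.specificity_frontier(tx, level)
                summary[f"motif_frontier_{level}"] = sorted(frontier)
                summary[f"motif_min_sufficient_{level}"] = sorted(sufficient)
            pd.DataFrame(rows, columns=["level", "side", "max_nonunique_k"]).to_csv(
                out / "motif_flanks.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("motif", exc) from exc
        log.info("motif: %.1fs", time.perf_counter() - t0)

    if "bias" in config.stages:
        t0 = time.perf_counter()
        try:
            genes = [
                (per_gene_f2[t.gene_id], [t.transcript_a, t.transcript_b])
                for t in truths
            ]
            tables = []
            for k in (2, 4):
                df = codon_bias.group_and_trend(genes, n_groups=k)
                df.insert(0, "n_groups", k)
                if k == 2:
                    summary["bias_trend_2group"] = df.attrs["monotone_beyond_1sigma"]
                tables.append(df)
            pd.concat(tables).to_csv(out / "codon_bias.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("bias", exc) from exc
        log.info("bias: %.1fs", time.perf_counter() - t0)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
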